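"""Spectral-library construction, transformation and TSV serialization.

A :class:`SpectralLibrary` holds precursor entries keyed by (modified
sequence, charge).  Libraries can be predicted from trained models, merged
into hybrids (experimental evidence wins on collision), focused to the
identifications of an initial search, appended with reversed-sequence
decoys, combined into two-species entrapment libraries, and screened over
grids of filter settings.  Serialization is a Spectronaut-importable TSV
with one row per fragment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .peptide_codec import (
    ModifiedPeptide,
    Precursor,
    format_compact,
    format_library_text,
    parse_compact,
    parse_library_text,
)
from .ion_space import (
    CHANNELS,
    IonChannel,
    Peak,
    channel_index,
    fragment_mz,
    matrix_from_peaks,
    peaks_from_matrix,
    precursor_mz,
    validity_mask,
)

__all__ = [
    "LibraryEntry",
    "SpectralLibrary",
    "LibraryFilters",
    "CalibrationFit",
    "generate_predicted_library",
    "calibrate_irt",
    "merge_hybrid",
    "build_focused",
    "reverse_peptide",
    "build_decoy_appended_library",
    "build_entrapment_library",
    "screen_parameter_grid",
    "write_library_tsv",
    "read_library_tsv",
    "read_id_table",
]

SOURCES = ("experimental_DDA", "direct_DIA", "predicted", "decoy", "entrapment")


@dataclass(frozen=True)
class LibraryEntry:
    """One precursor with its fragment peaks, iRT and provenance."""

    precursor: Precursor
    precursor_mz: float
    irt: float
    peaks: tuple
    protein_ids: tuple = ()
    localization_prob: float | None = None
    source: str = "predicted"
    species: str = ""

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not self.peaks:
            raise ValueError("library entries require at least one peak")

    @property
    def key(self):
        return self.precursor.key


@dataclass
class LibraryFilters:
    """Precursor/fragment restrictions applied when building a library."""

    precursor_mz_range: tuple = (0.0, float("inf"))
    fragment_mz_range: tuple = (200.0, 2000.0)
    peptide_length_range: tuple = (7, 50)
    max_phospho: int | None = None
    charges: tuple | None = None
    top_n_fragments: int | None = 25
    intensity_floor: float = 0.05

    def __post_init__(self):
        for name in ("precursor_mz_range", "fragment_mz_range", "peptide_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")

    def admits_precursor(self, pr: Precursor, mz: float) -> bool:
        lo, hi = self.precursor_mz_range
        llo, lhi = self.peptide_length_range
        if not lo <= mz <= hi:
            return False
        if not llo <= len(pr.peptide) <= lhi:
            return False
        if self.max_phospho is not None and pr.peptide.n_phospho > self.max_phospho:
            return False
        if self.charges is not None and pr.charge not in self.charges:
            return False
        return True


class SpectralLibrary:
    """Collection of :class:`LibraryEntry` with unique precursor keys."""

    def __init__(self, entries=(), provenance: str = "", filters: LibraryFilters | None = None):
        self.entries: dict = {}
        self.provenance = provenance
        self.filters = filters
        for e in entries:
            self.add(e)

    def add(self, entry: LibraryEntry):
        if entry.key in self.entries:
            raise ValueError(f"duplicate library key {entry.key}")
        self.entries[entry.key] = entry

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __contains__(self, key):
        return key in self.entries

    def get(self, key):
        return self.entries.get(key)

    def keys(self):
        return self.entries.keys()

    def copy(self) -> "SpectralLibrary":
        lib = SpectralLibrary(provenance=self.provenance, filters=self.filters)
        lib.entries = dict(self.entries)
        return lib

    def n_peaks(self) -> int:
        return sum(len(e.peaks) for e in self)


@dataclass
class CalibrationFit:
    """OLS fit mapping predicted iRT onto an experimental RT scale."""

    slope: float
    intercept: float
    r2: float
    median_abs_residual: float
    n: int

    def apply(self, irt):
        return self.slope * np.asarray(irt, dtype=float) + self.intercept


# ------------------------------------------------------------------- builders
def generate_predicted_library(
    precursors: list[Precursor],
    ion_model,
    rt_ensemble,
    filters: LibraryFilters | None = None,
    rt_scale=None,
    source: str = "predicted",
    species: str = "",
) -> SpectralLibrary:
    """Predict spectra and iRT for precursors and assemble a library.

    Precursors violating precursor-level filters are dropped (counted in
    ``lib.dropped``); fragment peaks outside the fragment m/z window or
    below the intensity floor are removed; at most ``top_n_fragments``
    peaks are kept per precursor.
    """
    from .neural_model import predict_ion_matrices, predict_irt

    filters = filters or LibraryFilters()
    kept, dropped = [], 0
    for pr in precursors:
        if filters.admits_precursor(pr, precursor_mz(pr)):
            kept.append(pr)
        else:
            dropped += 1
    lib = SpectralLibrary(provenance=source, filters=filters)
    lib.dropped = dropped
    if not kept:
        import warnings

        warnings.warn("no precursors passed the library filters", stacklevel=2)
        return lib
    matrices = predict_ion_matrices(ion_model, kept)
    peptides = [pr.peptide for pr in kept]
    irts = predict_irt(rt_ensemble, peptides, rt_scale)
    for pr, mat, irt in zip(kept, matrices, irts):
        peaks = peaks_from_matrix(
            pr.peptide, mat, floor=filters.intensity_floor, top_n=None
        )
        lo, hi = filters.fragment_mz_range
        peaks = [p for p in peaks if lo <= p.mz <= hi]
        if filters.top_n_fragments is not None:
            peaks = peaks[: filters.top_n_fragments]
        if not peaks:
            continue
        lib.add(
            LibraryEntry(
                precursor=pr,
                precursor_mz=precursor_mz(pr),
                irt=float(irt),
                peaks=tuple(peaks),
                source=source,
                species=species,
            )
        )
    return lib


def calibrate_irt(
    lib: SpectralLibrary, observed_pairs: dict
) -> tuple[CalibrationFit, SpectralLibrary]:
    """Fit observed RT = slope * predicted iRT + intercept on shared keys
    and return the fit plus a library with transformed iRT values."""
    xs, ys = [], []
    for key, rt in observed_pairs.items():
        entry = lib.get(key)
        if entry is not None:
            xs.append(entry.irt)
            ys.append(rt)
    if len(xs) < 3:
        raise ValueError(f"need >=3 shared peptides for calibration, got {len(xs)}")
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predicted-iRT variance")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    fit = CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot,
        median_abs_residual=float(np.median(np.abs(y - pred))),
        n=len(xs),
    )
    out = SpectralLibrary(provenance=lib.provenance, filters=lib.filters)
    for e in lib:
        out.add(replace(e, irt=float(fit.apply(e.irt))))
    return fit, out


def merge_hybrid(dia_lib: SpectralLibrary, predicted_lib: SpectralLibrary) -> SpectralLibrary:
    """Union of an experimental and a predicted library.

    On key collision the experimental entry wins entirely (spectrum and
    iRT); the result is idempotent under re-merging with the predicted
    library.
    """
    out = SpectralLibrary(provenance="hybrid", filters=dia_lib.filters)
    for e in dia_lib:
        out.add(e)
    for e in predicted_lib:
        if e.key not in out:
            out.add(e)
    return out


EXPERIMENTAL_SOURCES = ("experimental_DDA", "direct_DIA")


def build_focused(
    initial_lib: SpectralLibrary,
    identified_keys,
    keep_experimental_whole: bool = True,
) -> SpectralLibrary:
    """Restrict a library to the identifications of an initial search.

    Predicted-source entries are filtered to ``identified_keys``.
    Experimental entries are kept whole when ``keep_experimental_whole``
    (the hybrid-library rule for iterative searching), else filtered too.
    Identified keys absent from the initial library are logged and dropped.
    """
    identified = set(identified_keys)
    unknown = identified - set(initial_lib.keys())
    out = SpectralLibrary(provenance="focused", filters=initial_lib.filters)
    out.unknown_keys = sorted(unknown)
    for e in initial_lib:
        experimental = e.source in EXPERIMENTAL_SOURCES
        if (experimental and keep_experimental_whole) or e.key in identified:
            out.add(e)
    if len(out) == 0:
        raise ValueError("focused library is empty")
    return out


def reverse_peptide(p: ModifiedPeptide) -> ModifiedPeptide:
    """Reverse residues 1..n-1, keep the C-terminal residue in place.

    Modifications travel with their residues; the N-terminal acetyl flag is
    retained.  Applying the operation twice restores the input.
    """
    n = len(p)
    if n < 2:
        raise ValueError("cannot reverse a peptide shorter than 2 residues")
    order = list(range(n - 2, -1, -1)) + [n - 1]  # 0-based source positions
    residues = "".join(p.residues[j] for j in order)
    mods = {}
    for new_pos, old0 in enumerate(order, start=1):
        kind = p.mods.get(old0 + 1)
        if kind:
            mods[new_pos] = kind
    return ModifiedPeptide(residues, mods, p.nterm_acetyl)


def build_decoy_appended_library(
    lib: SpectralLibrary, ion_model, rt_ensemble, rt_scale=None
) -> SpectralLibrary:
    """Append one predicted reversed-sequence decoy per target entry.

    Decoys keep the target's charge.  A reversed sequence colliding with
    any target key (palindrome) is dropped and counted in
    ``out.palindromic_dropped``.
    """
    targets = list(lib)
    decoy_precursors, owners = [], []
    for e in targets:
        rev = reverse_peptide(e.precursor.peptide)
        decoy_precursors.append(Precursor(rev, e.precursor.charge))
        owners.append(e)
    out = lib.copy()
    out.provenance = "target+decoy"
    target_keys = set(lib.keys())
    admitted, dropped = [], 0
    seen = set()
    for pr in decoy_precursors:
        if pr.key in target_keys or pr.key in seen:
            dropped += 1
            continue
        seen.add(pr.key)
        admitted.append(pr)
    decoy_lib = generate_predicted_library(
        admitted,
        ion_model,
        rt_ensemble,
        filters=lib.filters or LibraryFilters(),
        rt_scale=rt_scale,
        source="decoy",
    )
    for e in decoy_lib:
        out.add(e)
    out.palindromic_dropped = dropped
    return out


def build_entrapment_library(
    main_lib: SpectralLibrary,
    entrapment_lib: SpectralLibrary,
    main_species: str = "main",
    entrapment_species: str = "entrapment",
):
    """Concatenate a main-species and a foreign-species library.

    Modified sequences present in both species are dropped from the
    entrapment side and counted.  Returns ``(library, sizes)`` where sizes
    hold the unique-phosphopeptide counts per species used by the
    entrapment FDR normalization.
    """
    if main_species == entrapment_species:
        raise ValueError("species tags must differ")
    out = SpectralLibrary(provenance="entrapment", filters=main_lib.filters)
    main_seqs = {key[0] for key in main_lib.keys()}
    overlap_dropped = 0
    for e in main_lib:
        out.add(replace(e, species=main_species))
    for e in entrapment_lib:
        if e.key[0] in main_seqs:
            overlap_dropped += 1
            continue
        out.add(replace(e, species=entrapment_species, source="entrapment"))
    sizes = {
        main_species: len({k[0] for k, e in out.entries.items() if e.species == main_species}),
        entrapment_species: len(
            {k[0] for k, e in out.entries.items() if e.species == entrapment_species}
        ),
        "overlap_dropped": overlap_dropped,
    }
    return out, sizes


def screen_parameter_grid(
    precursors: list[Precursor],
    grid: dict,
    ion_model,
    rt_ensemble,
    rt_scale=None,
) -> pd.DataFrame:
    """Build one predicted library per filter combination and summarize.

    ``grid`` maps LibraryFilters field names to lists of candidate values;
    the Cartesian product defines the combinations.  Returns a DataFrame
    with one row per combination: the filter values, entry count and peak
    count.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    names = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        filters = LibraryFilters(**dict(zip(names, combo)))
        lib = generate_predicted_library(
            precursors, ion_model, rt_ensemble, filters, rt_scale
        )
        row = {n: v for n, v in zip(names, combo)}
        row["n_entries"] = len(lib)
        row["n_peaks"] = lib.n_peaks()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- TSV
TSV_COLUMNS = [
    "PrecursorMz",
    "PrecursorCharge",
    "ModifiedPeptide",
    "StrippedPeptide",
    "iRT",
    "FragmentMz",
    "RelativeIntensity",
    "FragmentType",
    "FragmentNumber",
    "FragmentCharge",
    "FragmentLossType",
    "ProteinId",
    "Source",
]


def write_library_tsv(lib: SpectralLibrary, path):
    """Write one row per fragment with the fixed column set (m/z and
    intensity rounded to 4 decimals)."""
    rows = []
    for e in lib:
        mod_text = format_library_text(e.precursor.peptide, "bracket")
        for pk in e.peaks:
            rows.append(
                {
                    "PrecursorMz": round(e.precursor_mz, 4),
                    "PrecursorCharge": e.precursor.charge,
                    "ModifiedPeptide": mod_text,
                    "StrippedPeptide": e.precursor.peptide.residues,
                    "iRT": round(e.irt, 4),
                    "FragmentMz": round(pk.mz, 4),
                    "RelativeIntensity": round(pk.intensity, 4),
                    "FragmentType": pk.channel.series,
                    "FragmentNumber": pk.fragment_number,
                    "FragmentCharge": pk.channel.frag_charge,
                    "FragmentLossType": pk.channel.loss,
                    "ProteinId": ";".join(e.protein_ids),
                    "Source": e.source,
                }
            )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library_tsv(path) -> SpectralLibrary:
    """Read a library TSV back; validates fragment annotations against the
    peptide's channel space (an H3PO4 loss on a phosphate-free fragment is
    an error)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library TSV is missing columns {sorted(missing)}")
    lib = SpectralLibrary(provenance="tsv")
    for (mod_text, charge), group in df.groupby(
        ["ModifiedPeptide", "PrecursorCharge"], sort=False
    ):
        pep = parse_library_text(mod_text)
        pr = Precursor(pep, int(charge))
        mask = validity_mask(pep, len(pep))
        peaks = []
        for _, row in group.iterrows():
            ch = IonChannel(
                str(row["FragmentType"]), int(row["FragmentCharge"]), str(row["FragmentLossType"])
            )
            i = int(row["FragmentNumber"])
            if not 1 <= i <= len(pep) - 1 or not mask[i - 1, channel_index(ch)]:
                raise ValueError(
                    f"fragment {ch.label(i)} impossible for {pep.residues}"
                )
            peaks.append(Peak(ch, i, float(row["FragmentMz"]), float(row["RelativeIntensity"])))
        first = group.iloc[0]
        protein_ids = tuple(p for p in str(first["ProteinId"]).split(";") if p)
        lib.add(
            LibraryEntry(
                precursor=pr,
                precursor_mz=float(first["PrecursorMz"]),
                irt=float(first["iRT"]),
                peaks=tuple(peaks),
                protein_ids=protein_ids,
                source=str(first["Source"]),
            )
        )
    return lib


# ------------------------------------------------------------------ id tables
ID_DIALECTS = ("normalized", "maxquant_msms", "spectronaut_report")

_DIALECT_COLUMNS = {
    # column-name adapters; each maps the normalized field -> dialect column
    "normalized": {
        "sequence": "ModifiedPeptide",
        "charge": "PrecursorCharge",
        "rt": "iRT",
        "localization": "LocalizationProb",
        "peaks": "Peaks",
    },
    "maxquant_msms": {
        "sequence": "Modified sequence",
        "charge": "Charge",
        "rt": "Retention time",
        "localization": "Localization prob",
        "peaks": "Matches",
    },
    "spectronaut_report": {
        "sequence": "EG.ModifiedSequence",
        "charge": "FG.Charge",
        "rt": "EG.iRTEmpirical",
        "localization": "EG.PTMLocalizationProbabilities",
        "peaks": "F.Peaks",
    },
}


def _parse_peak_blob(pep: ModifiedPeptide, blob: str) -> tuple:
    """Parse 'b3+1-noloss:0.8;y2+1-H3PO4:0.1' peak annotations.

    Peaks addressing channels outside the 8-channel space are dropped; the
    entry survives with its remaining peaks.
    """
    mask = validity_mask(pep, len(pep))
    peaks = []
    for item in str(blob).split(";"):
        item = item.strip()
        if not item:
            continue
        try:
            label, value = item.rsplit(":", 1)
            series = label[0]
            rest, loss = label[1:].split("-", 1)
            num, fq = rest.split("+")
            ch = IonChannel(series, int(fq), loss)
            i = int(num)
            if not mask[i - 1, channel_index(ch)]:
                continue
            peaks.append(Peak(ch, i, fragment_mz(pep, ch, i), float(value)))
        except (ValueError, IndexError):
            continue
    return tuple(peaks)


def read_id_table(
    path, dialect: str = "normalized", min_localization: float = 0.75
) -> list[LibraryEntry]:
    """Read a simplified identification table into library entries.

    Records with localization probability not strictly above
    ``min_localization`` are excluded (class-I site convention).
    Unparseable rows are skipped and counted on the returned list's
    ``skipped`` attribute.
    """
    if dialect not in ID_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECT_COLUMNS[dialect]
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(cols.values()) - set(df.columns)
    if missing:
        raise ValueError(f"id table is missing columns {sorted(missing)}")
    entries, skipped = [], 0
    seen = set()
    for _, row in df.iterrows():
        try:
            loc = float(row[cols["localization"]])
            if not loc > min_localization:
                continue
            text = str(row[cols["sequence"]])
            pep = parse_compact(text) if text[0] in "*@" else parse_library_text(text)
            pr = Precursor(pep, int(row[cols["charge"]]))
            if pr.key in seen:
                continue
            peaks = _parse_peak_blob(pep, row[cols["peaks"]])
            if not peaks:
                skipped += 1
                continue
            entries.append(
                LibraryEntry(
                    precursor=pr,
                    precursor_mz=precursor_mz(pr),
                    irt=float(row[cols["rt"]]),
                    peaks=peaks,
                    localization_prob=loc,
                    source="direct_DIA",
                )
            )
            seen.add(pr.key)
        except (ValueError, KeyError):
            skipped += 1
    if not entries:
        raise ValueError("no identification rows survived parsing/filtering")
    out = _EntryList(entries)
    out.skipped = skipped
    return out


class _EntryList(list):
    """A list of entries that also records how many rows were skipped."""

    skipped: int = 0
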