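"""In silico tryptic digestion and phosphosite-driven precursor enumeration.

Reproduces the phosphosite-database library construction: digest each
protein with trypsin (cleavage C-terminal to K/R, by default suppressed
before proline), keep peptides of 7-30 residues with no missed cleavage,
place phosphates on the sites registered for that protein (at most one per
peptide by default), deduplicate by modified sequence, and emit each unique
phosphopeptide at charges 2, 3 and 4.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from pyteomics import parser as _ptparser

from .peptide_codec import (
    AMINO_ACIDS,
    ModifiedPeptide,
    PHOSPHO,
    PHOSPHO_RESIDUES,
    Precursor,
    format_compact,
)

__all__ = [
    "DigestConfig",
    "SiteTable",
    "DigestedPeptide",
    "tryptic_digest",
    "enumerate_phosphoforms",
    "build_sitedb_precursors",
    "read_fasta",
    "read_site_table",
]

_ENZYME_REGEX = {
    "trypsin": r"[KR](?!P)",
    "trypsin/P": r"[KR]",
}


@dataclass
class DigestConfig:
    enzyme: str = "trypsin"
    min_len: int = 7
    max_len: int = 30
    missed_cleavages: int = 0
    max_phospho_per_peptide: int = 1
    precursor_charges: tuple = (2, 3, 4)
    skip_nonstandard: bool = True  # warn & skip proteins with unknown residues

    def __post_init__(self):
        if self.enzyme not in _ENZYME_REGEX:
            raise ValueError(f"unknown enzyme rule {self.enzyme!r}")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass
class SiteTable:
    """protein id -> {position: residue} of registered phosphosites."""

    sites: dict = field(default_factory=dict)

    def add(self, protein_id: str, position: int, residue: str):
        residue = residue.upper()
        if residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"phosphosite residue must be S/T/Y, got {residue!r}")
        self.sites.setdefault(protein_id, {})[position] = residue

    def validate_against(self, sequences: dict):
        for pid, positions in self.sites.items():
            seq = sequences.get(pid)
            if seq is None:
                continue
            for pos, res in positions.items():
                if not 1 <= pos <= len(seq) or seq[pos - 1] != res:
                    raise ValueError(
                        f"site {pid}:{pos}{res} does not match protein sequence"
                    )


@dataclass(frozen=True)
class DigestedPeptide:
    """A tryptic peptide with 1-based inclusive protein coordinates."""

    sequence: str
    start: int
    end: int
    protein_id: str = ""


def tryptic_digest(
    protein: str, cfg: DigestConfig, protein_id: str = ""
) -> list[DigestedPeptide]:
    """Digest one protein sequence; peptides outside the length window drop."""
    protein = protein.strip().upper()
    bad = set(protein) - set(AMINO_ACIDS)
    if bad:
        if cfg.skip_nonstandard:
            warnings.warn(
                f"protein {protein_id or '<anonymous>'} has non-standard residues "
                f"{sorted(bad)}; skipped",
                stacklevel=2,
            )
            return []
        raise ValueError(f"non-standard residues {sorted(bad)} in {protein_id}")
    out = []
    for start0, pep in _ptparser.icleave(
        protein, _ENZYME_REGEX[cfg.enzyme], missed_cleavages=cfg.missed_cleavages
    ):
        if cfg.min_len <= len(pep) <= cfg.max_len:
            out.append(
                DigestedPeptide(pep, start0 + 1, start0 + len(pep), protein_id)
            )
    out.sort(key=lambda d: (d.start, d.end))
    return out


def enumerate_phosphoforms(
    peptide: DigestedPeptide, sites: SiteTable, cfg: DigestConfig
) -> list[ModifiedPeptide]:
    """All phosphoforms of one digested peptide given the registered sites.

    Emits one form per nonempty site combination of size up to
    ``max_phospho_per_peptide``; the unmodified peptide is never emitted.
    """
    registered = sites.sites.get(peptide.protein_id, {})
    local = []
    for pos, res in sorted(registered.items()):
        if peptide.start <= pos <= peptide.end:
            k = pos - peptide.start + 1
            if peptide.sequence[k - 1] != res:
                raise ValueError(
                    f"site {peptide.protein_id}:{pos}{res} mismatches peptide "
                    f"{peptide.sequence} at local position {k}"
                )
            local.append(k)
    forms = []
    for r in range(1, cfg.max_phospho_per_peptide + 1):
        for combo in itertools.combinations(local, r):
            forms.append(
                ModifiedPeptide(peptide.sequence, {k: PHOSPHO for k in combo})
            )
    return forms


def build_sitedb_precursors(
    proteome: dict, sites: SiteTable, cfg: DigestConfig | None = None
) -> list[Precursor]:
    """Digest a proteome and enumerate unique phosphopeptide precursors.

    ``proteome`` maps protein id -> sequence.  Duplicate modified sequences
    arising from different proteins collapse to one entry; each unique
    phosphopeptide is emitted at every configured charge state.  Output
    order is canonical (sorted by modified sequence, then charge) and hence
    independent of protein order.
    """
    cfg = cfg or DigestConfig()
    shared = set(proteome) & set(sites.sites)
    if not shared:
        raise ValueError("no protein ids shared between the FASTA and the site table")
    sites.validate_against(proteome)
    by_seq: dict[str, set] = {}
    for pid in sorted(proteome):
        for dp in tryptic_digest(proteome[pid], cfg, protein_id=pid):
            for form in enumerate_phosphoforms(dp, sites, cfg):
                by_seq.setdefault(format_compact(form), set()).add(pid)
    precursors = []
    for key in sorted(by_seq):
        from .peptide_codec import parse_compact

        pep = parse_compact(key, min_len=1, max_len=10**9)
        for q in cfg.precursor_charges:
            precursors.append(Precursor(pep, q))
    return precursors


def read_fasta(path) -> dict:
    """Read a FASTA file into {accession: sequence}.

    UniProt-style ``>db|ACCESSION|NAME`` headers yield the accession;
    otherwise the first whitespace-delimited word is used.
    """
    proteome = {}
    pid, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if pid is not None:
                    proteome[pid] = "".join(chunks)
                head = line[1:].split()[0]
                parts = head.split("|")
                pid = parts[1] if len(parts) >= 3 else head
                chunks = []
            elif line:
                chunks.append(line)
    if pid is not None:
        proteome[pid] = "".join(chunks)
    return proteome


def read_site_table(path) -> SiteTable:
    """Read a TSV of (protein_id, position, residue) into a SiteTable."""
    table = SiteTable()
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if i == 0 and fields[0].lower() in ("protein_id", "protein"):
                continue
            pid, pos, res = fields[0], int(fields[1]), fields[2]
            table.add(pid, pos, res)
    return table
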