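"""Seeded generators for every input the rest of the package consumes.

The generators emulate the *structure* of phosphoproteomics data — not its
instrument physics: random tryptic-looking phosphopeptides; a smooth,
deterministic fragmentation rule that a sequence model can learn; an
additive residue-coefficient retention model; identification tables with a
localization-probability column; and a two-species dilution-series
quantification table.  Every function is reproducible from the seed in its
config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptide_codec import (
    AMINO_ACIDS,
    ModifiedPeptide,
    PHOSPHO,
    Precursor,
    format_compact,
)
from .ion_space import CHANNELS, SENTINEL, validity_mask
from .error_control import QuantMatrix

__all__ = [
    "GeneratorConfig",
    "TwoProteomeConfig",
    "RT_COEFFICIENTS",
    "RT_PHOSPHO_OFFSET",
    "RT_ACETYL_OFFSET",
    "gen_peptides",
    "gen_ground_truth_spectra",
    "gen_ground_truth_rt",
    "gen_identification_tables",
    "gen_two_proteome_quant",
]


@dataclass
class GeneratorConfig:
    """Knobs of the peptide/spectrum/RT generators.

    Defaults mirror the data regime the models are meant for: tryptic
    peptides of 7-30 residues, a mono-phosphosite majority
    (1 site w.p. 0.7, 2 w.p. 0.25, 3 w.p. 0.05), precursor charges 2-4,
    multiplicative (lognormal) intensity noise and additive Gaussian RT
    noise.
    """

    seed: int = 0
    n_peptides: int = 100
    min_len: int = 7
    max_len: int = 30
    residue_freqs: dict | None = None  # default: uniform over the 20 residues
    phospho_count_probs: tuple = ((1, 0.70), (2, 0.25), (3, 0.05))
    charge_probs: tuple = ((2, 0.5), (3, 0.35), (4, 0.15))
    nterm_acetyl_prob: float = 0.1
    oxidation_prob: float = 0.1  # per peptide, applied to one random M if any
    spectrum_noise_sd: float = 0.0  # lognormal sigma on intensities
    rt_noise_sd: float = 0.0  # Gaussian SD in RT units

    def __post_init__(self):
        for probs in (self.phospho_count_probs, self.charge_probs):
            total = sum(p for _, p in probs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities sum to {total}, expected 1")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


# ------------------------------------------------------------------ peptides
def gen_peptides(cfg: GeneratorConfig) -> list[Precursor]:
    """Random unique phosphopeptide precursors.

    Each peptide is guaranteed at least as many S/T/Y residues as its drawn
    phosphosite count; tryptic character is approximated by a C-terminal
    K/R.  Uniqueness is by modified sequence + charge.
    """
    rng = np.random.default_rng(cfg.seed)
    residues = np.array(list(AMINO_ACIDS))
    if cfg.residue_freqs is None:
        freqs = np.full(len(residues), 1.0 / len(residues))
    else:
        freqs = np.array([cfg.residue_freqs.get(a, 0.0) for a in residues])
        if freqs.sum() <= 0:
            raise ValueError("residue frequencies sum to zero")
        freqs = freqs / freqs.sum()
    sty_possible = sum(freqs[list(AMINO_ACIDS).index(a)] for a in "STY")
    if sty_possible == 0:
        raise ValueError("zero S/T/Y frequency but phosphosites are required")
    k_counts = np.array([k for k, _ in cfg.phospho_count_probs])
    k_probs = np.array([p for _, p in cfg.phospho_count_probs])
    q_vals = np.array([q for q, _ in cfg.charge_probs])
    q_probs = np.array([p for _, p in cfg.charge_probs])

    out, seen = [], set()
    attempts = 0
    while len(out) < cfg.n_peptides:
        attempts += 1
        if attempts > 200 * cfg.n_peptides:
            raise RuntimeError("generator cannot satisfy the uniqueness constraints")
        n = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        n_phospho = int(rng.choice(k_counts, p=k_probs))
        body = rng.choice(residues, size=n - 1, p=freqs)
        cterm = rng.choice(["K", "R"])
        seq = "".join(body) + cterm
        sty = [i + 1 for i, a in enumerate(seq) if a in "STY"]
        if len(sty) < n_phospho:
            # force the required number of phosphorylatable residues
            replace_at = rng.choice(
                [i for i in range(n - 1) if (i + 1) not in sty],
                size=n_phospho - len(sty),
                replace=False,
            )
            seq_list = list(seq)
            for i in replace_at:
                seq_list[i] = rng.choice(list("STY"))
            seq = "".join(seq_list)
            sty = [i + 1 for i, a in enumerate(seq) if a in "STY"]
        sites = rng.choice(sty, size=n_phospho, replace=False)
        mods = {int(pos): PHOSPHO for pos in sites}
        m_positions = [i + 1 for i, a in enumerate(seq) if a == "M"]
        if m_positions and rng.random() < cfg.oxidation_prob:
            from .peptide_codec import OXIDATION

            pos = int(rng.choice(m_positions))
            if pos not in mods:
                mods[pos] = OXIDATION
        pep = ModifiedPeptide(seq, mods, bool(rng.random() < cfg.nterm_acetyl_prob))
        pep.validate(min_len=cfg.min_len, max_len=cfg.max_len)
        charge = int(rng.choice(q_vals, p=q_probs))
        key = (format_compact(pep), charge)
        if key in seen:
            continue
        seen.add(key)
        out.append(Precursor(pep, charge))
    return out


# ------------------------------------------------------------------- spectra
# boundary-residue factors give the fragmentation rule sequence dependence
_BOUNDARY_FACTOR = {a: 0.6 + 0.4 * (i % 5) / 4 for i, a in enumerate(AMINO_ACIDS)}
_LOSS_FRACTION = 0.4  # loss-channel intensity relative to its noloss partner
_SERIES_CENTER = {"b": 0.35, "y": 0.65}
_BUMP_WIDTH = 0.25


def _noiseless_matrix(pr: Precursor, L: int) -> np.ndarray:
    """The deterministic fragmentation rule (before noise/normalization).

    Intensity of a noloss channel at fragment i is a Gaussian bump over the
    relative fragment position (series-specific center), scaled by a
    precursor-charge factor and by a factor of the residue at the cleavage
    site; loss channels are a fixed fraction of their noloss partner.
    """
    pep = pr.peptide
    n = len(pep)
    mask = validity_mask(pep, L)
    m = np.where(mask, 0.0, SENTINEL)
    charge_gain = {2: 1.0, 3: 0.85, 4: 0.7}.get(pr.charge, 0.6)
    two_plus_gain = 0.5 if pr.charge >= 3 else 0.1
    for i in range(1, n):
        rel = i / n
        boundary = _BOUNDARY_FACTOR[pep.residues[i - 1]]
        for col, ch in enumerate(CHANNELS):
            if not mask[i - 1, col]:
                continue
            if ch.loss == "H3PO4":
                continue  # filled from the noloss partner below
            center = _SERIES_CENTER[ch.series]
            pos = rel if ch.series == "b" else 1.0 - rel
            bump = np.exp(-((pos - center) ** 2) / (2 * _BUMP_WIDTH**2))
            gain = charge_gain * (two_plus_gain if ch.frag_charge == 2 else 1.0)
            m[i - 1, col] = bump * gain * boundary
        for col, ch in enumerate(CHANNELS):
            if mask[i - 1, col] and ch.loss == "H3PO4":
                partner = CHANNELS.index(
                    next(
                        c
                        for c in CHANNELS
                        if c.series == ch.series
                        and c.frag_charge == ch.frag_charge
                        and c.loss == "noloss"
                    )
                )
                m[i - 1, col] = _LOSS_FRACTION * m[i - 1, partner]
    return m


def gen_ground_truth_spectra(
    precursors: list[Precursor], cfg: GeneratorConfig, L: int | None = None
) -> np.ndarray:
    """Ground-truth fragment matrices for the given precursors.

    Deterministic at ``spectrum_noise_sd == 0``; otherwise each valid cell
    is multiplied by an independent lognormal factor.  Matrices are
    max-normalized with impossible channels at -1.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if L is None:
        L = max(len(pr.peptide) for pr in precursors)
    out = np.empty((len(precursors), L, 8))
    for r, pr in enumerate(precursors):
        m = _noiseless_matrix(pr, L)
        valid = m != SENTINEL
        if cfg.spectrum_noise_sd > 0:
            noise = rng.lognormal(0.0, cfg.spectrum_noise_sd, size=int(valid.sum()))
            m[valid] = m[valid] * noise
        top = m[valid].max(initial=0.0)
        if top > 0:
            m[valid] = m[valid] / top
        out[r] = m
    return out


# ----------------------------------------------------------------------- RT
# additive retention coefficients (iRT-like units); fixed and public so tests
# can recover them by least squares
RT_COEFFICIENTS = {
    "A": 1.1, "C": 0.2, "D": -0.6, "E": -0.2, "F": 7.8, "G": -0.5,
    "H": -2.1, "I": 6.5, "K": -3.2, "L": 7.2, "M": 4.1, "N": -1.1,
    "P": 0.8, "Q": -0.8, "R": -2.9, "S": -0.4, "T": 0.5, "V": 4.4,
    "W": 9.3, "Y": 3.6,
}
RT_PHOSPHO_OFFSET = -2.5
RT_OXIDATION_OFFSET = -1.8
RT_ACETYL_OFFSET = 3.0


def gen_ground_truth_rt(peptides: list[ModifiedPeptide], cfg: GeneratorConfig) -> np.ndarray:
    """Additive-model retention times with optional Gaussian noise."""
    from .peptide_codec import OXIDATION

    rng = np.random.default_rng(cfg.seed + 2)
    rts = np.empty(len(peptides))
    for r, pep in enumerate(peptides):
        rt = sum(RT_COEFFICIENTS[a] for a in pep.residues)
        for kind in pep.mods.values():
            rt += RT_PHOSPHO_OFFSET if kind == PHOSPHO else RT_OXIDATION_OFFSET
        if pep.nterm_acetyl:
            rt += RT_ACETYL_OFFSET
        rts[r] = rt
    if cfg.rt_noise_sd > 0:
        rts = rts + rng.normal(0.0, cfg.rt_noise_sd, size=len(peptides))
    return rts


# ------------------------------------------------------------------ id tables
def gen_identification_tables(
    precursors: list[Precursor],
    spectra: np.ndarray,
    rts: np.ndarray,
    cfg: GeneratorConfig,
    fraction_below: float = 0.0,
) -> pd.DataFrame:
    """A normalized-dialect identification table as a DataFrame.

    Exactly ``round(fraction_below * n)`` records (chosen by the seed) get
    a localization probability <= 0.75 so downstream class-I filtering can
    be exercised; the rest draw from (0.75, 1.0].
    """
    rng = np.random.default_rng(cfg.seed + 3)
    n = len(precursors)
    n_below = int(round(fraction_below * n))
    below = set(rng.choice(n, size=n_below, replace=False)) if n_below else set()
    rows = []
    for r, pr in enumerate(precursors):
        if r in below:
            loc = float(rng.uniform(0.30, 0.75))
        else:
            loc = float(rng.uniform(0.7501, 1.0))
        mat = spectra[r]
        items = []
        for i in range(mat.shape[0]):
            for col, ch in enumerate(CHANNELS):
                v = mat[i, col]
                if v != SENTINEL and v > 0:
                    items.append(f"{ch.series}{i + 1}+{ch.frag_charge}-{ch.loss}:{v:.6f}")
        rows.append(
            {
                "ModifiedPeptide": format_compact(pr.peptide),
                "PrecursorCharge": pr.charge,
                "iRT": float(rts[r]),
                "LocalizationProb": loc,
                "Peaks": ";".join(items),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- two-proteome
@dataclass
class TwoProteomeConfig:
    """The spike-in dilution design: a fixed background proteome plus a
    second proteome diluted across conditions at known ratios."""

    seed: int = 0
    n_background: int = 200
    n_spike: int = 100
    ratios: tuple = (0.25, 0.5, 1.5, 2.0)
    n_replicates: int = 6
    noise_sd: float = 0.1  # lognormal sigma on each replicate intensity
    missing_prob: float = 0.0
    control_name: str = "1:1"
    background_species: str = "background"
    spike_species: str = "spike"


def gen_two_proteome_quant(cfg: TwoProteomeConfig) -> QuantMatrix:
    """Two-species dilution-series quantification table.

    Spike-species precursor means scale with the condition ratio; the
    background stays at ratio 1.  Replicates carry independent lognormal
    noise; rows can be dropped at random to emulate missingness.
    """
    rng = np.random.default_rng(cfg.seed)
    conditions = {cfg.control_name: None}
    for r in cfg.ratios:
        conditions[f"{r:g}:1"] = r
    rows = []
    for species, count in (
        (cfg.background_species, cfg.n_background),
        (cfg.spike_species, cfg.n_spike),
    ):
        base = rng.lognormal(np.log(1e5), 0.8, size=count)
        for j in range(count):
            prec = f"{species}_{j:04d}"
            for cond, ratio in conditions.items():
                scale = 1.0 if (species == cfg.background_species or ratio is None) else ratio
                for rep in range(1, cfg.n_replicates + 1):
                    if cfg.missing_prob > 0 and rng.random() < cfg.missing_prob:
                        continue
                    noise = rng.lognormal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 1.0
                    rows.append(
                        {
                            "precursor": prec,
                            "species": species,
                            "condition": cond,
                            "replicate": rep,
                            "intensity": base[j] * scale * noise,
                        }
                    )
    expected = {f"{r:g}:1": r for r in cfg.ratios}
    return QuantMatrix(
        intensities=pd.DataFrame(rows),
        control=cfg.control_name,
        expected_ratios=expected,
    )
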