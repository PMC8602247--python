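"""The L x 8 fragment-ion channel space for phosphopeptides.

Each fragmentation-pattern row ``i`` (1-based fragment number) holds eight
intensity channels in a fixed column order::

    b(i)+1 noloss | b(i)+2 noloss | b(i)+1 -H3PO4 | b(i)+2 -H3PO4 |
    y(i)+1 noloss | y(i)+2 noloss | y(i)+1 -H3PO4 | y(i)+2 -H3PO4

Channels that cannot physically exist — fragment numbers beyond ``n-1``,
and phosphoric-acid loss from a fragment that contains no phosphosite —
carry the sentinel value ``-1``; all real intensities are max-normalized
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import mass as _ptmass

from .peptide_codec import ModifiedPeptide, PHOSPHO, OXIDATION, Precursor

__all__ = [
    "IonChannel",
    "CHANNELS",
    "N_CHANNELS",
    "MassTable",
    "Peak",
    "channel_index",
    "validity_mask",
    "fragment_mz",
    "precursor_mz",
    "peptide_neutral_mass",
    "matrix_from_peaks",
    "peaks_from_matrix",
]

SENTINEL = -1.0
N_CHANNELS = 8

PROTON = 1.007276
WATER = 18.010565
H3PO4 = 97.976896

DELTA_PHOSPHO = 79.96633
DELTA_OXIDATION = 15.99491
DELTA_ACETYL = 42.01057
DELTA_CARBAMIDOMETHYL = 57.02146


@dataclass(frozen=True, order=True)
class IonChannel:
    """One of the eight (series, fragment charge, neutral loss) channels."""

    series: str        # 'b' or 'y'
    frag_charge: int   # 1 or 2
    loss: str          # 'noloss' or 'H3PO4'

    def __post_init__(self):
        if self.series not in ("b", "y"):
            raise ValueError(f"series must be 'b' or 'y', got {self.series!r}")
        if self.frag_charge not in (1, 2):
            raise ValueError(f"fragment charge must be 1 or 2, got {self.frag_charge}")
        if self.loss not in ("noloss", "H3PO4"):
            raise ValueError(f"loss must be 'noloss' or 'H3PO4', got {self.loss!r}")

    def label(self, i: int) -> str:
        return f"{self.series}{i}+{self.frag_charge}-{self.loss}"


# fixed printed column order
CHANNELS = (
    IonChannel("b", 1, "noloss"),
    IonChannel("b", 2, "noloss"),
    IonChannel("b", 1, "H3PO4"),
    IonChannel("b", 2, "H3PO4"),
    IonChannel("y", 1, "noloss"),
    IonChannel("y", 2, "noloss"),
    IonChannel("y", 1, "H3PO4"),
    IonChannel("y", 2, "H3PO4"),
)
_CHANNEL_INDEX = {c: j for j, c in enumerate(CHANNELS)}


def channel_index(c: IonChannel) -> int:
    """Column 0..7 of a channel in the fixed printed order (bijective)."""
    return _CHANNEL_INDEX[c]


class MassTable:
    """Monoisotopic residue masses and modification deltas (Da).

    Residue masses come from pyteomics' standard table; cysteine is treated
    as carbamidomethylated by default, matching common fixed-modification
    search settings.
    """

    def __init__(self, carbamidomethyl_cys: bool = True):
        self.residue = dict(_ptmass.std_aa_mass)
        if carbamidomethyl_cys:
            self.residue["C"] = self.residue["C"] + DELTA_CARBAMIDOMETHYL
        self.delta = {
            PHOSPHO: DELTA_PHOSPHO,
            OXIDATION: DELTA_OXIDATION,
        }

    def residue_mass(self, p: ModifiedPeptide, pos: int) -> float:
        """Mass of residue ``pos`` (1-based) including its modification."""
        m = self.residue[p.residues[pos - 1]]
        kind = p.mods.get(pos)
        if kind:
            m += self.delta[kind]
        return m

    def segment_mass(self, p: ModifiedPeptide, start: int, stop: int) -> float:
        """Sum of modified residue masses over 1-based inclusive [start, stop]."""
        return sum(self.residue_mass(p, j) for j in range(start, stop + 1))


_DEFAULT_MASSES = MassTable()


@dataclass(frozen=True)
class Peak:
    """A single annotated fragment peak."""

    channel: IonChannel
    fragment_number: int
    mz: float
    intensity: float


def validity_mask(p: ModifiedPeptide, L: int) -> np.ndarray:
    """Boolean L x 8 mask of physically possible channels for ``p``.

    Row ``i`` (0-based ``i-1``) is valid only for fragment numbers
    ``1 <= i <= n-1``.  H3PO4-loss columns additionally require the fragment
    (b_i = residues 1..i, y_i = residues n-i+1..n) to contain at least one
    phosphorylated residue.
    """
    n = len(p)
    if n > L:
        raise ValueError(f"peptide length {n} exceeds matrix height L={L}")
    mask = np.zeros((L, N_CHANNELS), dtype=bool)
    phospho = np.zeros(n + 1, dtype=int)  # prefix counts of phosphosites
    for pos in range(1, n + 1):
        phospho[pos] = phospho[pos - 1] + (p.mods.get(pos) == PHOSPHO)
    total = phospho[n]
    for i in range(1, n):
        row = i - 1
        b_has = phospho[i] > 0
        y_has = (total - phospho[n - i]) > 0
        for j, c in enumerate(CHANNELS):
            if c.loss == "noloss":
                mask[row, j] = True
            else:
                mask[row, j] = b_has if c.series == "b" else y_has
    return mask


def peptide_neutral_mass(p: ModifiedPeptide, masses: MassTable = _DEFAULT_MASSES) -> float:
    """Neutral monoisotopic peptide mass (residues + water + mods)."""
    m = masses.segment_mass(p, 1, len(p)) + WATER
    if p.nterm_acetyl:
        m += DELTA_ACETYL
    return m


def fragment_mz(
    p: ModifiedPeptide,
    c: IonChannel,
    i: int,
    masses: MassTable = _DEFAULT_MASSES,
) -> float:
    """m/z of fragment ``i`` in channel ``c``.

    b ions carry the N terminus (including an acetyl group when present);
    y ions gain one water.  H3PO4-loss channels subtract 97.976896 Da from
    the neutral fragment before dividing by the fragment charge.
    """
    n = len(p)
    if not 1 <= i <= n - 1:
        raise ValueError(f"fragment number {i} invalid for peptide of length {n}")
    mask = validity_mask(p, n)
    if not mask[i - 1, channel_index(c)]:
        raise ValueError(f"channel {c.label(i)} impossible for {p.residues}")
    if c.series == "b":
        neutral = masses.segment_mass(p, 1, i)
        if p.nterm_acetyl:
            neutral += DELTA_ACETYL
    else:
        neutral = masses.segment_mass(p, n - i + 1, n) + WATER
    if c.loss == "H3PO4":
        neutral -= H3PO4
    z = c.frag_charge
    return (neutral + PROTON * z) / z


def precursor_mz(pr: Precursor, masses: MassTable = _DEFAULT_MASSES) -> float:
    """(neutral peptide mass + q protons) / q."""
    q = pr.charge
    return (peptide_neutral_mass(pr.peptide, masses) + PROTON * q) / q


def matrix_from_peaks(
    p: ModifiedPeptide,
    peaks: list[Peak],
    L: int,
    on_invalid: str = "raise",
) -> np.ndarray:
    """Assemble a max-normalized L x 8 fragment matrix from a peak list.

    Invalid cells are -1; valid cells default to 0; present peaks are
    normalized so the largest equals 1.  A peak addressing an impossible
    channel raises (``on_invalid='raise'``) or is silently dropped
    (``on_invalid='drop'``).
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    mask = validity_mask(p, L)
    m = np.where(mask, 0.0, SENTINEL)
    for pk in peaks:
        row, col = pk.fragment_number - 1, channel_index(pk.channel)
        if row >= L or not mask[row, col]:
            if on_invalid == "raise":
                raise ValueError(
                    f"peak on impossible channel {pk.channel.label(pk.fragment_number)} "
                    f"for {p.residues}"
                )
            continue
        if pk.intensity < 0:
            raise ValueError("peak intensity must be nonnegative")
        m[row, col] = pk.intensity
    top = m[mask].max(initial=0.0)
    if top > 0:
        m[mask] = m[mask] / top
    return m


def peaks_from_matrix(
    p: ModifiedPeptide,
    m: np.ndarray,
    floor: float = 0.0,
    top_n: int | None = None,
    masses: MassTable = _DEFAULT_MASSES,
) -> list[Peak]:
    """Emit peaks for valid cells above ``floor``, keeping at most ``top_n``.

    Ordering for the top-N cut and for ties is deterministic: descending
    intensity, then (series, fragment number, charge, loss) channel order.
    """
    L = m.shape[0]
    mask = validity_mask(p, L)
    if m.shape != mask.shape:
        raise ValueError(f"matrix shape {m.shape} does not match ({L}, {N_CHANNELS})")
    candidates = []
    for row in range(L):
        for col in range(N_CHANNELS):
            if mask[row, col] and m[row, col] > floor:
                c = CHANNELS[col]
                sort_key = (c.series, row + 1, c.frag_charge, c.loss)
                candidates.append((-float(m[row, col]), sort_key, row + 1, c))
    candidates.sort(key=lambda t: (t[0], t[1]))
    if top_n is not None:
        candidates = candidates[:top_n]
    return [
        Peak(c, i, fragment_mz(p, c, i, masses), -neg)
        for neg, _, i, c in candidates
    ]
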