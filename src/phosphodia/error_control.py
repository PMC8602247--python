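"""Error-rate estimators for library-based DIA phosphoproteomics.

Implements the reverse-decoy FDR, the two-species entrapment FDR with its
library-size normalization and 1% tolerance offset, the synthetic-peptide
false localization rate (FLR), and the two-proteome quantification
statistics: per-precursor measured ratios against a control condition,
false quantification rate (FQR) curves over relative-error thresholds, and
replicate coefficients of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HitCounts",
    "QuantMatrix",
    "fdr_reverse",
    "fdr_entrapment",
    "flr_synthetic",
    "measured_ratios",
    "fqr_curve",
    "replicate_cv",
]

#: the error thresholds the two-proteome evaluation always reports
FQR_REFERENCE_THRESHOLDS = (0.30, 0.50)


@dataclass
class HitCounts:
    """Identification counts feeding the FDR estimators."""

    hits_original: int = 0
    hits_reverse: int = 0
    hits_true: int = 0
    hits_false: int = 0
    libsize_main: int = 0
    libsize_entrapment: int = 0

    def __post_init__(self):
        for name in (
            "hits_original",
            "hits_reverse",
            "hits_true",
            "hits_false",
            "libsize_main",
            "libsize_entrapment",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def fdr_reverse(h: HitCounts) -> float:
    """Reverse-decoy FDR: ``2 * Hits_reverse / (Hits_original + Hits_reverse)``."""
    denom = h.hits_original + h.hits_reverse
    if denom == 0:
        raise ZeroDivisionError("no hits at all; FDR undefined")
    return 2.0 * h.hits_reverse / denom


def fdr_entrapment(h: HitCounts, tolerance: float = 0.01) -> float:
    """Two-species entrapment FDR.

    False hits are normalized by the main/entrapment library-size ratio and
    inflated by ``1/(1 - tolerance)`` to offset the search engine's own
    error tolerance (1% by default)::

        NormHits_False = Hits_False * (LibSize_main / LibSize_entrapment) / (1 - tol)
        FDR            = NormHits_False / (Hits_True + NormHits_False)
    """
    if h.libsize_main <= 0 or h.libsize_entrapment <= 0:
        raise ValueError("library sizes must be positive for entrapment FDR")
    norm_false = (
        h.hits_false * (h.libsize_main / h.libsize_entrapment) / (1.0 - tolerance)
    )
    denom = h.hits_true + norm_false
    if denom == 0:
        raise ZeroDivisionError("no true or normalized-false hits; FDR undefined")
    return norm_false / denom


def flr_synthetic(identified_sites, truth_sites) -> tuple[float, float]:
    """False localization rate on a synthetic-peptide ground-truth set.

    Sites are hashable identifiers (e.g. ``(peptide, position)``).  Returns
    ``(FLR, recovery)`` where FLR is the fraction of identified sites not
    in the truth set and recovery the fraction of truth sites identified.
    """
    truth = set(truth_sites)
    if not truth:
        raise ValueError("ground-truth site set is empty")
    identified = set(identified_sites)
    if not identified:
        raise ValueError("no identified sites; FLR undefined")
    false = len(identified - truth)
    flr = false / len(identified)
    recovery = len(identified & truth) / len(truth)
    return flr, recovery


@dataclass
class QuantMatrix:
    """Precursor x condition x replicate intensity table.

    ``intensities`` is a DataFrame with columns ``precursor``, ``species``,
    ``condition``, ``replicate``, ``intensity`` (de-normalized; missing
    observations are simply absent rows).  ``expected_ratios`` maps each
    non-control condition to its spike-in dilution ratio vs the control.
    """

    intensities: pd.DataFrame
    control: str
    expected_ratios: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"precursor", "species", "condition", "replicate", "intensity"}
        missing = required - set(self.intensities.columns)
        if missing:
            raise ValueError(f"quant table is missing columns {sorted(missing)}")
        if self.control not in set(self.intensities["condition"]):
            raise ValueError(f"control condition {self.control!r} not present")
        if (self.intensities["intensity"] <= 0).any():
            raise ValueError("intensities must be positive (drop missing rows)")

    def conditions(self) -> list[str]:
        return sorted(c for c in set(self.intensities["condition"]) if c != self.control)


def measured_ratios(q: QuantMatrix) -> pd.DataFrame:
    """Mean-over-replicates condition/control ratio per precursor.

    A precursor contributes at a condition only when it is observed (>= 1
    replicate) in both that condition and the control.  Columns:
    ``precursor``, ``species``, ``condition``, ``ratio``.
    """
    means = (
        q.intensities.groupby(["precursor", "species", "condition"])["intensity"]
        .mean()
        .reset_index()
    )
    control = means[means["condition"] == q.control].set_index(["precursor", "species"])[
        "intensity"
    ]
    rows = []
    for (prec, spec, cond), value in means.set_index(
        ["precursor", "species", "condition"]
    )["intensity"].items():
        if cond == q.control or (prec, spec) not in control.index:
            continue
        rows.append(
            {
                "precursor": prec,
                "species": spec,
                "condition": cond,
                "ratio": value / control.loc[(prec, spec)],
            }
        )
    if not rows:
        raise ValueError("no precursor observed in both a condition and the control")
    return pd.DataFrame(rows)


def fqr_curve(
    ratios: pd.DataFrame,
    expected_ratios: dict,
    thresholds=None,
    log_scale: bool = False,
) -> pd.DataFrame:
    """False quantification rate as a function of the error threshold.

    The relative error of a measurement is ``|measured/expected - 1|``
    (or ``|log2(measured/expected)|`` with ``log_scale``); FQR(t) is the
    fraction of (precursor, condition) measurements with error > t.  The
    reference thresholds 0.30 and 0.50 are always included.  FQR is
    nonincreasing in t by construction.
    """
    if ratios.empty:
        raise ValueError("empty ratio table")
    missing = set(ratios["condition"]) - set(expected_ratios)
    if missing:
        raise ValueError(f"expected ratios missing for conditions {sorted(missing)}")
    expected = ratios["condition"].map(expected_ratios).astype(float)
    rel = ratios["ratio"].to_numpy() / expected.to_numpy()
    err = np.abs(np.log2(rel)) if log_scale else np.abs(rel - 1.0)
    extra = () if thresholds is None else tuple(float(t) for t in thresholds)
    grid = sorted(set(FQR_REFERENCE_THRESHOLDS) | set(extra))
    return pd.DataFrame(
        {
            "threshold": grid,
            "fqr": [float((err > t).mean()) for t in grid],
            "n": len(err),
        }
    )


def replicate_cv(q: QuantMatrix) -> pd.DataFrame:
    """Percent coefficient of variation across replicates.

    ``100 * sample SD / mean`` per precursor per condition; conditions with
    fewer than two observed replicates yield no row (never imputed).
    """
    rows = []
    for (prec, spec, cond), group in q.intensities.groupby(
        ["precursor", "species", "condition"]
    ):
        vals = group["intensity"].to_numpy()
        if vals.size < 2:
            continue
        rows.append(
            {
                "precursor": prec,
                "species": spec,
                "condition": cond,
                "cv_percent": 100.0 * vals.std(ddof=1) / vals.mean(),
                "n_replicates": vals.size,
            }
        )
    return pd.DataFrame(rows, columns=["precursor", "species", "condition", "cv_percent", "n_replicates"])
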