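"""Inter-rater reliability: percent agreement, Cohen's kappa and PABAK.

Percent agreement ignores chance; Cohen's kappa corrects for it but is
depressed by skewed prevalence or rater bias; the prevalence-adjusted
bias-adjusted kappa PABAK = (k*po - 1)/(k - 1) depends only on the observed
agreement po and the number of categories k.  Coefficients are mapped onto
the qualitative bands commonly used for reliability reporting:
excellent [0.80, 1.00], substantial [0.61, 0.80), moderate [0.41, 0.61),
fair [0.21, 0.41), slight-to-poor below 0.21.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .perceptual import Phase, RatingValue, PARAMETER_INVENTORY

__all__ = [
    "ConfusionTable",
    "AgreementResult",
    "percent_agreement",
    "cohens_kappa",
    "pabak",
    "interpret",
    "agreement_result",
    "confusion_from_ratings",
    "per_parameter_agreement",
]


@dataclass(frozen=True)
class ConfusionTable:
    """k x k cross-tabulation of two raters (rows = rater A, cols = B)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if counts.shape[0] < 2:
            raise ValueError("need at least 2 categories")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AgreementResult:
    percent_agreement: float
    kappa: float  # NaN when chance agreement is 1 (both raters constant)
    pabak: float
    band: str  # band of the chosen headline coefficient (PABAK)
    n: int


def percent_agreement(t: ConfusionTable) -> float:
    """Observed agreement po = trace / n."""
    if t.n == 0:
        raise ValueError("empty table: agreement undefined")
    return float(np.trace(t.counts) / t.n)


def cohens_kappa(t: ConfusionTable) -> float:
    """kappa = (po - pe) / (1 - pe), pe from the marginal products.

    Returns NaN in the degenerate case pe = 1 (both raters constant).
    """
    if t.n == 0:
        raise ValueError("empty table: kappa undefined")
    po = percent_agreement(t)
    row = t.counts.sum(axis=1) / t.n
    col = t.counts.sum(axis=0) / t.n
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def pabak(t: ConfusionTable) -> float:
    """Prevalence-adjusted bias-adjusted kappa: (k*po - 1)/(k - 1)."""
    po = percent_agreement(t)
    return (t.k * po - 1.0) / (t.k - 1.0)


_BANDS = [  # (lower bound inclusive, label)
    (0.80, "excellent"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
]


def interpret(coefficient: float) -> str:
    """Reliability band for a coefficient in [-1, 1].

    The printed band edges overlap at 0.80 and skip (0.20, 0.21); the
    repaired total partition assigns each edge to the upper band:
    >= 0.80 excellent, [0.61, 0.80) substantial, [0.41, 0.61) moderate,
    [0.21, 0.41) fair, < 0.21 slight_to_poor.
    """
    if math.isnan(coefficient) or not -1.0 <= coefficient <= 1.0:
        raise ValueError(f"coefficient {coefficient} outside [-1, 1]")
    for lower, label in _BANDS:
        if coefficient >= lower:
            return label
    return "slight_to_poor"


def agreement_result(t: ConfusionTable) -> AgreementResult:
    """All three statistics plus the band of PABAK (the headline figure)."""
    pab = pabak(t)
    return AgreementResult(
        percent_agreement=percent_agreement(t),
        kappa=cohens_kappa(t),
        pabak=pab,
        band=interpret(pab),
        n=t.n,
    )


def confusion_from_ratings(
    values_a: Iterable[str], values_b: Iterable[str],
    categories: tuple[str, ...] = ("yes", "no"),
) -> ConfusionTable:
    """Cross-tabulate paired nominal ratings over a fixed category set.

    Pairs where either rating falls outside the category set (e.g.
    cannot_be_determined) are dropped pairwise, mirroring available-case
    denominators.
    """
    idx = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for a, b in zip(values_a, values_b, strict=True):
        if a in idx and b in idx:
            counts[idx[a], idx[b]] += 1
    return ConfusionTable(counts)


def per_parameter_agreement(ratings: pd.DataFrame) -> pd.DataFrame:
    """Two-rater agreement per perceptual parameter from a long ratings table.

    Expects the perceptual-module CSV layout with exactly two rater_ids;
    outputs one row per (phase, parameter):
    phase,parameter,n_pairs,percent_agreement,kappa,pabak,band.
    """
    raters = sorted(ratings["rater_id"].unique())
    if len(raters) != 2:
        raise ValueError(f"need exactly 2 raters, found {raters}")
    wide = ratings.pivot_table(
        index=["phase", "parameter", "neonate_id"], columns="rater_id",
        values="value", aggfunc="first",
    )
    rows = []
    for phase, names in PARAMETER_INVENTORY.items():
        for name in names:
            try:
                sub = wide.loc[(phase.value, name)]
            except KeyError:
                continue
            t = confusion_from_ratings(sub[raters[0]], sub[raters[1]])
            if t.n == 0:
                continue
            res = agreement_result(t)
            rows.append({
                "phase": phase.value,
                "parameter": name,
                "n_pairs": res.n,
                "percent_agreement": res.percent_agreement,
                "kappa": res.kappa,
                "pabak": res.pabak,
                "band": res.band,
            })
    return pd.DataFrame(rows)
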