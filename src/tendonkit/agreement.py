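"""Inter-assessor reliability for ordinal 0–3 histology scores.

Two blinded assessors rate the same items; agreement is summarized by the
raw percent agreement, Cohen's kappa (chance-corrected), and weighted kappa
(partial credit for near-miss disagreements).  The category set is fixed at
{0, 1, 2, 3} regardless of which scores actually occur in a table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "AgreementResult",
    "confusion_matrix",
    "percent_agreement",
    "cohens_kappa",
    "weighted_kappa",
    "assess_agreement",
]

CATEGORIES = (0, 1, 2, 3)
_K = len(CATEGORIES)


def _scores(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    a = table["assessor_a"].to_numpy(dtype=int)
    b = table["assessor_b"].to_numpy(dtype=int)
    if a.size != b.size:
        raise ValueError("assessor columns differ in length")
    if a.size == 0:
        raise ValueError("empty rating table")
    for arr, name in ((a, "assessor_a"), (b, "assessor_b")):
        if arr.min() < 0 or arr.max() > 3:
            raise ValueError(f"{name} scores outside 0..3")
    return a, b


def confusion_matrix(table: pd.DataFrame) -> np.ndarray:
    """4×4 count table; rows = assessor A's score, columns = assessor B's."""
    a, b = _scores(table)
    m = np.zeros((_K, _K), dtype=int)
    np.add.at(m, (a, b), 1)
    return m


def percent_agreement(table: pd.DataFrame) -> float:
    """Percentage of items given identical scores, in [0, 100]."""
    a, b = _scores(table)
    return float(100.0 * np.mean(a == b))


def cohens_kappa(table: pd.DataFrame) -> float:
    """κ = (p_o − p_e)/(1 − p_e) with chance agreement from the marginals.

    If both assessors use a single identical category throughout (p_e = 1,
    p_o = 1) the table is perfectly concordant and κ = 1 by convention.
    """
    a, b = _scores(table)
    if a.size < 2:
        raise ValueError("need at least 2 items for kappa")
    m = confusion_matrix(table).astype(float)
    n = m.sum()
    p_o = np.trace(m) / n
    p_e = float(m.sum(axis=1) @ m.sum(axis=0)) / n**2
    if p_e == 1.0:
        return 1.0  # both marginals degenerate on the same category
    return float((p_o - p_e) / (1.0 - p_e))


def _weight_matrix(scheme: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(_K), np.arange(_K), indexing="ij")
    if scheme == "linear":
        return np.abs(i - j) / (_K - 1)
    if scheme == "quadratic":
        return ((i - j) / (_K - 1)) ** 2
    if scheme == "identity":
        return (i != j).astype(float)
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def weighted_kappa(table: pd.DataFrame, weights: str = "linear") -> float:
    """κ_w = 1 − Σw·observed / Σw·expected with disagreement weights
    |i−j|/3 (linear, default) or ((i−j)/3)² (quadratic)."""
    a, b = _scores(table)
    if a.size < 2:
        raise ValueError("need at least 2 items for kappa")
    w = _weight_matrix(weights)
    m = confusion_matrix(table).astype(float)
    n = m.sum()
    expected = np.outer(m.sum(axis=1), m.sum(axis=0)) / n
    denom = float((w * expected).sum())
    num = float((w * m).sum())
    if denom == 0.0:
        if num > 0.0:
            raise ValueError("zero expected disagreement with disagreement present")
        return 1.0
    return float(1.0 - num / denom)


@dataclass
class AgreementResult:
    """Reliability summary for one scored parameter."""

    parameter: str
    n: int
    percent_agreement: float
    kappa: float
    weighted_kappa: float
    weighting: str
    confusion: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "n": self.n,
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "weighted_kappa": self.weighted_kappa,
            "weighting": self.weighting,
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def assess_agreement(table: pd.DataFrame, weights: str = "linear") -> AgreementResult:
    """All three reliability metrics plus the confusion table in one call."""
    name = ""
    if "parameter" in table.columns and len(table):
        name = str(table["parameter"].iloc[0])
    return AgreementResult(
        parameter=name,
        n=len(table),
        percent_agreement=percent_agreement(table),
        kappa=cohens_kappa(table),
        weighted_kappa=weighted_kappa(table, weights=weights),
        weighting=weights,
        confusion=confusion_matrix(table),
    )
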