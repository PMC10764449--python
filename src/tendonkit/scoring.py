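"""Ordinal histomorphometric scoring rubric and Total Histological Score.

Six parameters are each scored 0 (worst) to 3 (healthy-like) per tendon:

* cellularity — fold change of nuclei count vs. healthy tendons;
* cell alignment — direction ratio vs. healthy, with angle dispersion;
* COL1 fiber alignment — number of areas (of 5) with aligned fibers;
* vascularity — blood-vessel organization category;
* chondrometaplasia / osteometaplasia — number of areas with ectopic foci.

The Total Histological Score (THS) is their sum, 0–18.  The quantitative
band boundaries live in a versioned, serializable :class:`ScoringRules`
table so every threshold and its inclusivity is auditable.  The packaged
boundary conventions (documented in the rule file): cellularity score 1 is
(2, 3] and score 2 is [1.3, 2]; the alignment score-1 band is (2.1, 3] and
score 2 absorbs every ratio ≤ 2.1 that does not qualify for score 3.
"""

from __future__ import annotations

import enum
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

__all__ = [
    "Vascularity",
    "SemiQuantObservation",
    "ScoringRules",
    "ScoreCard",
    "score_cellularity",
    "score_alignment",
    "score_col1",
    "score_vascularity",
    "score_metaplasia",
    "total_histological_score",
    "score_tendon",
]


class Vascularity(str, enum.Enum):
    """Blood-vessel organization categories, worst to best."""

    PLEXUS = "plexus"
    SCATTERED_OR_ALIGNED_LE1_AREA = "scattered_or_aligned_le1_area"
    ALIGNED_1_TO_4_AREAS = "aligned_1_to_4_areas"
    FEW_ALIGNED_AS_HEALTHY = "few_aligned_as_healthy"


_VASCULARITY_SCORE = {
    Vascularity.PLEXUS: 0,
    Vascularity.SCATTERED_OR_ALIGNED_LE1_AREA: 1,
    Vascularity.ALIGNED_1_TO_4_AREAS: 2,
    Vascularity.FEW_ALIGNED_AS_HEALTHY: 3,
}


@dataclass
class SemiQuantObservation:
    """Per-tendon semi-quantitative observations entering the rubric.

    ``col1_aligned_areas`` counts areas (0–5) with aligned COL1 fibers; −1
    encodes "no COL1 expression".  Metaplasia fields count areas containing
    chondrocyte / calcification foci.
    """

    col1_aligned_areas: int
    vascularity_category: Vascularity
    chondro_foci_areas: int
    osteo_foci_areas: int

    def validate(self) -> None:
        if not -1 <= self.col1_aligned_areas <= 5:
            raise ValueError(f"col1_aligned_areas {self.col1_aligned_areas} outside -1..5")
        Vascularity(self.vascularity_category)
        for name in ("chondro_foci_areas", "osteo_foci_areas"):
            v = getattr(self, name)
            if not 0 <= v <= 5:
                raise ValueError(f"{name} {v} outside 0..5")


@dataclass
class ScoringRules:
    """Versioned quantitative band boundaries of the rubric.

    ``cellularity_bounds`` = (b_low, b_mid, b_high): fold change < b_low
    scores 3, [b_low, b_mid] scores 2, (b_mid, b_high] scores 1, > b_high
    scores 0.  ``alignment_bounds`` = (r_healthy, r_mid, r_high): ratio >
    r_high scores 0, (r_mid, r_high] scores 1, ratio < r_healthy with
    dispersion < ``dispersion_percent`` scores 3, everything else scores 2.
    """

    version: str = "1"
    cellularity_bounds: tuple[float, float, float] = (1.3, 2.0, 3.0)
    alignment_bounds: tuple[float, float, float] = (1.0, 2.1, 3.0)
    dispersion_percent: float = 25.0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cellularity_bounds"] = list(self.cellularity_bounds)
        d["alignment_bounds"] = list(self.alignment_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScoringRules":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cellularity_bounds"] = tuple(d["cellularity_bounds"])
        d["alignment_bounds"] = tuple(d["alignment_bounds"])
        return cls(**d)


_DEFAULT = ScoringRules()


def score_cellularity(fold_change: float, rules: ScoringRules = _DEFAULT) -> int:
    """0–3 from the cellularity fold change (hypercellularity scores low)."""
    if not np.isfinite(fold_change) or fold_change <= 0:
        raise ValueError(f"fold change must be positive and finite, got {fold_change!r}")
    lo, mid, hi = rules.cellularity_bounds
    if fold_change > hi:
        return 0
    if fold_change > mid:
        return 1
    if fold_change >= lo:
        return 2
    return 3


def score_alignment(
    ratio: float, dispersion_percent: float, rules: ScoringRules = _DEFAULT
) -> int:
    """0–3 from the direction ratio vs. healthy and the angle dispersion."""
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"direction ratio must be positive and finite, got {ratio!r}")
    if not np.isfinite(dispersion_percent) or dispersion_percent < 0:
        raise ValueError(f"dispersion must be nonnegative, got {dispersion_percent!r}")
    healthy, mid, hi = rules.alignment_bounds
    if ratio > hi:
        return 0
    if ratio > mid:
        return 1
    if ratio < healthy and dispersion_percent < rules.dispersion_percent:
        return 3
    return 2


def score_col1(observation: SemiQuantObservation) -> int:
    """0–3 from the number of areas with aligned COL1 fibers."""
    observation.validate()
    n = observation.col1_aligned_areas
    if n <= 0:  # -1 = no COL1 expression; 0 = expression but nothing aligned
        return 0
    if n <= 2:
        return 1
    if n <= 4:
        return 2
    return 3


def score_vascularity(category: Vascularity | str) -> int:
    """0–3 from the blood-vessel organization category."""
    return _VASCULARITY_SCORE[Vascularity(category)]


def score_metaplasia(foci_areas: int) -> int:
    """0–3 from how many of the 5 areas contain ectopic foci (fewer = better).

    Shared by chondrometaplasia and osteometaplasia.
    """
    if not 0 <= foci_areas <= 5:
        raise ValueError(f"foci_areas {foci_areas} outside 0..5")
    if foci_areas == 5:
        return 0
    if foci_areas >= 2:
        return 1
    if foci_areas == 1:
        return 2
    return 3


@dataclass
class ScoreCard:
    """The six sub-scores and their sum for one tendon."""

    tendon_id: str
    cellularity_score: int
    alignment_score: int
    col1_score: int
    vascularity_score: int
    chondro_score: int
    osteo_score: int
    ths: int = field(init=False)

    def __post_init__(self) -> None:
        subs = self.subscores()
        missing = [name for name, v in subs.items() if v is None]
        if missing:
            raise ValueError(f"missing sub-scores: {missing}")
        for name, v in subs.items():
            if v not in (0, 1, 2, 3):
                raise ValueError(f"{name} = {v!r} outside 0..3")
        self.ths = sum(subs.values())

    def subscores(self) -> dict[str, int]:
        return {
            "cellularity_score": self.cellularity_score,
            "alignment_score": self.alignment_score,
            "col1_score": self.col1_score,
            "vascularity_score": self.vascularity_score,
            "chondro_score": self.chondro_score,
            "osteo_score": self.osteo_score,
        }


def total_histological_score(
    tendon_id: str,
    cellularity_score: int | None,
    alignment_score: int | None,
    col1_score: int | None,
    vascularity_score: int | None,
    chondro_score: int | None,
    osteo_score: int | None,
) -> ScoreCard:
    """Assemble a :class:`ScoreCard`; THS is the exact integer sum (0–18)."""
    subs = {
        "cellularity_score": cellularity_score,
        "alignment_score": alignment_score,
        "col1_score": col1_score,
        "vascularity_score": vascularity_score,
        "chondro_score": chondro_score,
        "osteo_score": osteo_score,
    }
    missing = [k for k, v in subs.items() if v is None]
    if missing:
        raise ValueError(f"missing sub-scores: {missing}")
    return ScoreCard(tendon_id=tendon_id, **subs)


def score_tendon(
    tendon_id: str,
    fold_change: float,
    direction_ratio: float,
    dispersion_percent: float,
    observation: SemiQuantObservation,
    rules: ScoringRules = _DEFAULT,
) -> ScoreCard:
    """Score one tendon from its quantitative metrics and observations."""
    return total_histological_score(
        tendon_id,
        score_cellularity(fold_change, rules),
        score_alignment(direction_ratio, dispersion_percent, rules),
        score_col1(observation),
        score_vascularity(observation.vascularity_category),
        score_metaplasia(observation.chondro_foci_areas),
        score_metaplasia(observation.osteo_foci_areas),
    )
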