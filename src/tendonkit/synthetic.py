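"""Synthetic study data with known ground truth.

Every downstream stage of the pipeline — activity metrics, nuclei counting,
directionality, scoring, agreement, correlation — is exercised against data
produced here, so each generator records the latent quantities it draws
(nucleus positions and orientations, injury-recovery factors, true ordinal
scores) in a :class:`GroundTruth` object that suffices to recompute every
expected value without re-simulation.

The packaged "study scenario" presets encode the experimental conditions of
the emulated study: a 12/12 h light/dark schedule with activity peaking in
the first dark 3-h bin, a multiplicative activity dip on the surgery day
followed by exponential recovery whose asymptote depends on lesion type and
wheel access, healthy tendon fields with ~70 nuclei per field oriented
around 17.02° from the longitudinal axis, and a tendon-level metric
correlation structure with r(activity, alignment) = 0.41,
r(activity, dispersion) = −0.76 and r(cellularity, alignment) = 0.54.

All generators take an explicit integer seed; identical (preset, seed) pairs
yield bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Any

import numpy as np
import pandas as pd

from .activity import ActivityTrace
from .histomorph import FieldImage, fold_angle

__all__ = [
    "ActivityPreset",
    "HistologyPreset",
    "MetricCorrelationSpec",
    "CohortDesign",
    "GroundTruth",
    "simulate_activity",
    "simulate_histology_field",
    "simulate_metric_cohort",
    "simulate_assessors",
    "injury_factor",
    "study_activity_preset",
    "study_histology_preset",
    "study_correlation_spec",
    "study_cohort_design",
    "GROUPS",
]

MINUTES_PER_DAY = 1440
BIN_MINUTES = 180

#: (lesion, wheel) tags of the study groups.
GROUPS = (
    ("none", "blocked"),
    ("none", "free"),
    ("unilateral", "blocked"),
    ("unilateral", "free"),
    ("bilateral", "blocked"),
    ("bilateral", "free"),
)


@dataclass
class GroundTruth:
    """Generator-side record of every latent quantity, JSON-serializable."""

    kind: str
    seed: int
    preset: dict[str, Any]
    data: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# --------------------------------------------------------------------------
# activity traces
# --------------------------------------------------------------------------

@dataclass
class ActivityPreset:
    """Parameters of one group's simulated locomotion-index trace.

    ``circadian_template`` holds the expected locomotion index in each of
    the eight 3-h bins of a baseline day (bin 0 starts at lights-on); the
    injury multiplies it by ``1 − dip_depth`` on the surgery day and relaxes
    exponentially (time constant ``recovery_tau`` days) toward
    ``recovery_gain`` (final-to-baseline night activity ratio).
    """

    circadian_template: tuple[float, ...] = (
        0.10, 0.07, 0.06, 0.10, 0.48, 0.38, 0.28, 0.18)
    dip_depth: float = 0.6
    recovery_tau: float = 4.0
    recovery_gain: float = 1.0
    noise_sd: float = 0.05
    n_days_pre: int = 7
    n_days_post: int = 27

    def validate(self) -> None:
        tpl = np.asarray(self.circadian_template, dtype=float)
        if tpl.shape != (8,) or not np.all(np.isfinite(tpl)) or tpl.min() < 0:
            raise ValueError("circadian_template needs 8 finite nonnegative levels")
        for name in ("dip_depth", "recovery_tau", "recovery_gain", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0 <= self.dip_depth <= 1:
            raise ValueError(f"dip_depth {self.dip_depth} outside [0, 1]")
        if self.recovery_tau <= 0 or self.recovery_gain <= 0:
            raise ValueError("recovery_tau and recovery_gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_days_pre < 0 or self.n_days_post < 0:
            raise ValueError("negative day counts")

    @property
    def n_days(self) -> int:
        return self.n_days_pre + 1 + self.n_days_post


def injury_factor(day: np.ndarray | int, preset: ActivityPreset) -> np.ndarray:
    """Multiplicative activity factor per day index (0 = surgery day).

    1 before surgery; ``1 − dip_depth`` on day 0; then exponential
    relaxation toward ``recovery_gain``:
    ``gain + (1 − dip − gain) · exp(−d / tau)``.
    """
    d = np.asarray(day, dtype=float)
    floor = 1.0 - preset.dip_depth
    f = preset.recovery_gain + (floor - preset.recovery_gain) * np.exp(
        -np.maximum(d, 0.0) / preset.recovery_tau
    )
    return np.where(d < 0, 1.0, f)


_STUDY_ACTIVITY: dict[tuple[str, str], dict[str, float]] = {
    # recovery kinetics ordered to match the observed group contrast:
    # bilateral-free recovers highest, unilateral-free fastest early,
    # blocked-wheel groups end below their baseline
    ("none", "blocked"): dict(dip_depth=0.0, recovery_tau=4.0, recovery_gain=1.0),
    ("none", "free"): dict(dip_depth=0.0, recovery_tau=4.0, recovery_gain=1.0),
    ("unilateral", "blocked"): dict(dip_depth=0.55, recovery_tau=5.0, recovery_gain=0.95),
    ("unilateral", "free"): dict(dip_depth=0.55, recovery_tau=2.5, recovery_gain=1.05),
    ("bilateral", "blocked"): dict(dip_depth=0.65, recovery_tau=6.0, recovery_gain=0.90),
    ("bilateral", "free"): dict(dip_depth=0.65, recovery_tau=4.0, recovery_gain=1.25),
}


def study_activity_preset(lesion: str = "none", wheel: str = "blocked") -> ActivityPreset:
    """The packaged study-scenario preset for one (lesion, wheel) group."""
    if (lesion, wheel) not in _STUDY_ACTIVITY:
        raise KeyError(f"unknown group {(lesion, wheel)!r}; valid: {GROUPS}")
    return ActivityPreset(**_STUDY_ACTIVITY[(lesion, wheel)])


#: fixed calendar anchor for simulated studies (arbitrary but stable)
SURGERY_DATE = date(2021, 6, 1)


def simulate_activity(
    preset: ActivityPreset,
    group: tuple[str, str] = ("none", "blocked"),
    seed: int = 0,
    cage_id: str | None = None,
) -> tuple[ActivityTrace, GroundTruth]:
    """Simulate one cage's minute-resolution locomotion trace.

    The expected value at minute *t* is ``template[bin(t)] ×
    injury_factor(day(t))``, plus Gaussian noise, clipped to [0, 1].  The
    trace starts at lights-on of the first pre-surgery day.
    """
    preset.validate()
    rng = np.random.default_rng(seed)
    tpl = np.asarray(preset.circadian_template, dtype=float)
    day_profile = np.repeat(tpl, BIN_MINUTES)  # 1440 samples
    days = np.arange(-preset.n_days_pre, preset.n_days_post + 1)
    factors = injury_factor(days, preset)
    expected = np.concatenate([day_profile * f for f in factors])
    noise = rng.normal(0.0, preset.noise_sd, expected.size) if preset.noise_sd else 0.0
    values = np.clip(expected + noise, 0.0, 1.0)
    lights_on = time(7, 0)
    start = datetime.combine(SURGERY_DATE - timedelta(days=int(preset.n_days_pre)),
                             lights_on)
    cage = cage_id or f"{group[0]}-{group[1]}-s{seed}"
    trace = ActivityTrace(
        cage_id=cage,
        start=start,
        values=values,
        period=60,
        surgery_day=SURGERY_DATE,
        group=f"{group[0]}-{group[1]}",
    )
    truth = GroundTruth(
        kind="activity",
        seed=seed,
        preset=asdict(preset),
        data={
            "group": list(group),
            "cage_id": cage,
            "day_index": days.tolist(),
            "injury_factor": factors.tolist(),
            "expected_bin_means": [(tpl * f).tolist() for f in factors],
        },
    )
    return trace, truth


# --------------------------------------------------------------------------
# histology fields
# --------------------------------------------------------------------------

@dataclass
class HistologyPreset:
    """Parameters of one group's simulated nuclei fields.

    Lengths in μm; intensities in camera counts on a 16-bit scale.  The
    default field of 370 × 250 μm makes the 5-area × 4-field tendon scheme
    total exactly 1.85 mm².
    """

    nuclei_per_field_mean: float = 70.0
    orientation_mean: float = 17.02  # degrees from the tendon long axis
    orientation_sd: float = 8.0
    nucleus_axes: tuple[float, float] = (14.0, 2.8)  # full (major, minor), μm
    min_center_distance: float = 15.0
    background_level: float = 400.0
    nucleus_intensity: float = 2500.0
    noise_sd: float = 80.0
    pixel_size: float = 0.5  # μm per pixel
    field_size: tuple[float, float] = (370.0, 250.0)  # (width, height), μm
    max_placement_attempts: int = 200

    def validate(self) -> None:
        if self.nuclei_per_field_mean < 0:
            raise ValueError("nuclei_per_field_mean must be nonnegative")
        if not -90.0 < self.orientation_mean <= 90.0:
            raise ValueError("orientation_mean must lie in (-90, 90]")
        if self.orientation_sd < 0:
            raise ValueError("orientation_sd must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        major, minor = self.nucleus_axes
        if major <= 0 or minor <= 0 or minor > major:
            raise ValueError("nucleus_axes must be positive with major >= minor")
        w, h = self.field_size
        if major > min(w, h):
            raise ValueError("field too small to contain a single nucleus")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def shape_px(self) -> tuple[int, int]:
        w, h = self.field_size
        return int(round(h / self.pixel_size)), int(round(w / self.pixel_size))


_STUDY_HISTOLOGY: dict[tuple[str, str], dict[str, float]] = {
    # healing groups: hypercellular, more dispersed, direction drifts off
    # the healthy angle; qualitative ordering bilateral-free (best healing)
    # -> unilateral-blocked (worst)
    ("none", "blocked"): dict(),
    ("none", "free"): dict(),
    ("unilateral", "blocked"): dict(
        nuclei_per_field_mean=135.0, orientation_mean=48.0, orientation_sd=28.0),
    ("unilateral", "free"): dict(
        nuclei_per_field_mean=125.0, orientation_mean=40.0, orientation_sd=24.0),
    ("bilateral", "blocked"): dict(
        nuclei_per_field_mean=120.0, orientation_mean=34.0, orientation_sd=20.0),
    ("bilateral", "free"): dict(
        nuclei_per_field_mean=110.0, orientation_mean=26.0, orientation_sd=14.0),
}


def study_histology_preset(lesion: str = "none", wheel: str = "blocked") -> HistologyPreset:
    """Packaged histology preset per group; CTR is the healthy reference."""
    if (lesion, wheel) not in _STUDY_HISTOLOGY:
        raise KeyError(f"unknown group {(lesion, wheel)!r}; valid: {GROUPS}")
    return HistologyPreset(**_STUDY_HISTOLOGY[(lesion, wheel)])


def simulate_histology_field(
    preset: HistologyPreset,
    area_index: int = 1,
    field_index: int = 1,
    seed: int = 0,
    tendon_id: str = "",
) -> tuple[FieldImage, GroundTruth]:
    """Render one nuclei field as anti-aliased filled ellipses plus noise.

    The nucleus count is Poisson; centers are placed by rejection sampling
    below ``min_center_distance`` (after ``max_placement_attempts`` failures
    the point is placed anyway and recorded as forced); orientations are
    Normal(mean, sd) folded to (−90°, 90°].
    """
    preset.validate()
    rng = np.random.default_rng(seed)
    w_um, h_um = preset.field_size
    major, minor = preset.nucleus_axes
    a = major / 2.0  # semi-axes, μm
    b = minor / 2.0
    n = int(rng.poisson(preset.nuclei_per_field_mean))
    centers: list[tuple[float, float]] = []
    forced: list[int] = []
    min_d2 = preset.min_center_distance**2
    for i in range(n):
        placed = False
        for _ in range(preset.max_placement_attempts):
            cx = rng.uniform(a, w_um - a)
            cy = rng.uniform(a, h_um - a)
            if all((cx - px) ** 2 + (cy - py) ** 2 >= min_d2 for px, py in centers):
                placed = True
                break
        if not placed:
            forced.append(i)
        centers.append((cx, cy))
    orientations = fold_angle(
        rng.normal(preset.orientation_mean, preset.orientation_sd, n)
    ) if n else np.empty(0)
    orientations = np.atleast_1d(orientations)

    shape = preset.shape_px
    img = np.zeros(shape, dtype=float)
    px = preset.pixel_size
    for (cx, cy), theta in zip(centers, orientations):
        _render_ellipse(img, cx / px, cy / px, a / px, b / px, theta)
    img = preset.background_level + preset.nucleus_intensity * np.clip(img, 0.0, 1.0)
    if preset.noise_sd:
        img = img + rng.normal(0.0, preset.noise_sd, img.shape)
    img = np.clip(img, 0.0, 65535.0)

    image = FieldImage(
        pixels=img,
        pixel_size=px,
        area_index=area_index,
        field_index=field_index,
        tendon_id=tendon_id,
    )
    truth = GroundTruth(
        kind="histology_field",
        seed=seed,
        preset=asdict(preset),
        data={
            "tendon_id": tendon_id,
            "area_index": area_index,
            "field_index": field_index,
            "n_nuclei": n,
            "centers_um": [list(c) for c in centers],
            "orientations_deg": np.asarray(orientations).tolist(),
            "semi_axes_um": [a, b],
            "forced_placements": forced,
        },
    )
    return image, truth


def _render_ellipse(img: np.ndarray, cx: float, cy: float, a: float, b: float,
                    theta_deg: float) -> None:
    """Accumulate an anti-aliased filled ellipse (max blend) in place.

    Pixel coverage is approximated by a linear ramp of ~1 px around the
    ellipse boundary in normalized radius units.
    """
    h, w = img.shape
    r = int(np.ceil(a)) + 2
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    t = np.radians(theta_deg)
    # +y points down the rows; angles measured from +x toward +y
    u = np.cos(t) * dx + np.sin(t) * dy
    v = -np.sin(t) * dx + np.cos(t) * dy
    d = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    cov = np.clip(0.5 + (1.0 - d) * b, 0.0, 1.0)
    np.maximum(img[y0:y1, x0:x1], cov, out=img[y0:y1, x0:x1])


# --------------------------------------------------------------------------
# tendon-level metric cohorts
# --------------------------------------------------------------------------

@dataclass
class MetricCorrelationSpec:
    """Joint Gaussian model of the tendon-level quantitative metrics."""

    variables: tuple[str, ...] = (
        "normalized_night_activity",
        "cell_alignment",
        "angle_dispersion",
        "cellularity",
    )
    means: tuple[float, ...] = (1.0, 1.8, 30.0, 1.8)
    sds: tuple[float, ...] = (0.25, 0.45, 8.0, 0.5)
    rho: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rho is None:
            self.rho = np.eye(len(self.variables))
        self.rho = np.asarray(self.rho, dtype=float)

    def validate(self) -> np.ndarray:
        """Check and lightly repair the correlation matrix; return it.

        The matrix is symmetrized and eigenvalues in [−1e−10, 0) are clipped
        to 0 (numerical round-off); anything more negative is an error.
        """
        k = len(self.variables)
        if len(self.means) != k or len(self.sds) != k or self.rho.shape != (k, k):
            raise ValueError("means, sds and rho must match the variable count")
        if any(s <= 0 for s in self.sds):
            raise ValueError("all sds must be positive")
        r = 0.5 * (self.rho + self.rho.T)
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("rho must have a unit diagonal")
        w = np.linalg.eigvalsh(r)
        if w.min() < -1e-10:
            raise ValueError(
                f"rho is not positive semi-definite (smallest eigenvalue {w.min():.3e})"
            )
        if w.min() >= 0.0:
            return r
        w_clip, v = np.linalg.eigh(r)
        return (v * np.clip(w_clip, 0.0, None)) @ v.T


def study_correlation_spec() -> MetricCorrelationSpec:
    """The packaged scenario: activity–alignment 0.41, activity–dispersion
    −0.76, cellularity–alignment 0.54, all other off-diagonals 0."""
    rho = np.eye(4)
    rho[0, 1] = rho[1, 0] = 0.41
    rho[0, 2] = rho[2, 0] = -0.76
    rho[3, 1] = rho[1, 3] = 0.54
    return MetricCorrelationSpec(rho=rho)


def simulate_metric_cohort(
    spec: MetricCorrelationSpec, n: int, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw ``n`` tendons' metrics from the joint Gaussian model.

    The correlation matrix is factorized by symmetric eigendecomposition
    (A = V·diag(√λ)·Vᵀ), which also handles rank-deficient matrices such as
    exact ±1 correlations; samples are mean + sd ⊙ (A z) with z standard
    normal.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    r = spec.validate()
    w, v = np.linalg.eigh(r)
    a = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(spec.variables)))
    x = z @ a.T
    x = np.asarray(spec.means) + x * np.asarray(spec.sds)
    df = pd.DataFrame(x, columns=list(spec.variables))
    truth = GroundTruth(
        kind="metric_cohort",
        seed=seed,
        preset={
            "variables": list(spec.variables),
            "means": list(spec.means),
            "sds": list(spec.sds),
            "rho": r.tolist(),
        },
        data={"n": n},
    )
    return df, truth


# --------------------------------------------------------------------------
# assessor rating tables
# --------------------------------------------------------------------------

def simulate_assessors(
    true_scores: list[int] | np.ndarray,
    confusion: float = 0.1,
    seed: int = 0,
    parameter: str = "",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two independent blinded assessors rating the same ordinal items.

    Each assessor reports the true 0–3 score, perturbed by ±1 (equal
    probability each way) with probability ``confusion``, clipped to [0, 3].
    """
    truth_arr = np.asarray(true_scores, dtype=int)
    if truth_arr.size == 0:
        raise ValueError("true_scores is empty")
    if truth_arr.min() < 0 or truth_arr.max() > 3:
        raise ValueError("true scores must lie in 0..3")
    if not 0.0 <= confusion <= 0.5:
        raise ValueError(f"confusion {confusion} outside [0, 0.5]")
    rng = np.random.default_rng(seed)

    def rate() -> np.ndarray:
        flip = rng.random(truth_arr.size) < confusion
        step = rng.choice([-1, 1], size=truth_arr.size)
        return np.clip(truth_arr + flip * step, 0, 3)

    table = pd.DataFrame(
        {
            "item": np.arange(truth_arr.size),
            "assessor_a": rate(),
            "assessor_b": rate(),
            "parameter": parameter,
        }
    )
    gt = GroundTruth(
        kind="ratings",
        seed=seed,
        preset={"confusion": confusion, "parameter": parameter},
        data={"true_scores": truth_arr.tolist()},
    )
    return table, gt


# --------------------------------------------------------------------------
# semi-quantitative observations
# --------------------------------------------------------------------------

#: modal true sub-scores (col1, vascularity, chondro, osteo) per group.
#: Healing quality is ordered bilateral-free (best) -> unilateral-blocked
#: (worst); chondrometaplasia is widespread in every lesioned group while
#: calcification stays rare.
_SEMIQUANT_TRUTH: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("none", "blocked"): (3, 3, 3, 3),
    ("none", "free"): (3, 3, 3, 3),
    ("unilateral", "blocked"): (1, 1, 0, 3),
    ("unilateral", "free"): (1, 1, 0, 2),
    ("bilateral", "blocked"): (1, 2, 0, 3),
    ("bilateral", "free"): (2, 2, 0, 3),
}

# representative raw observations per score band (inverse of the rubric)
_COL1_FOR_SCORE = {0: (0,), 1: (1, 2), 2: (3, 4), 3: (5,)}
_FOCI_FOR_SCORE = {0: (5,), 1: (2, 3, 4), 2: (1,), 3: (0,)}
_VASC_FOR_SCORE = {
    0: "plexus",
    1: "scattered_or_aligned_le1_area",
    2: "aligned_1_to_4_areas",
    3: "few_aligned_as_healthy",
}


def simulate_semiquant(
    lesion: str, wheel: str, n_tendons: int, seed: int = 0, jitter: float = 0.25
) -> tuple[list, GroundTruth]:
    """Per-tendon semi-quantitative observations with known true scores.

    Each tendon's true sub-score is the group's modal score, shifted by ±1
    (clipped to 0–3) with probability ``jitter``; the raw observation is a
    uniformly drawn representative of the true score's band, so re-scoring
    the observation recovers the true score exactly.
    """
    from .scoring import SemiQuantObservation, Vascularity

    if (lesion, wheel) not in _SEMIQUANT_TRUTH:
        raise KeyError(f"unknown group {(lesion, wheel)!r}; valid: {GROUPS}")
    if n_tendons <= 0:
        raise ValueError("n_tendons must be positive")
    rng = np.random.default_rng(seed)
    modal = _SEMIQUANT_TRUTH[(lesion, wheel)]
    observations = []
    true_scores = []
    for _ in range(n_tendons):
        scores = []
        for m in modal:
            s = m
            if rng.random() < jitter:
                s = int(np.clip(m + rng.choice([-1, 1]), 0, 3))
            scores.append(s)
        col1_s, vasc_s, chondro_s, osteo_s = scores
        obs = SemiQuantObservation(
            col1_aligned_areas=int(rng.choice(_COL1_FOR_SCORE[col1_s])),
            vascularity_category=Vascularity(_VASC_FOR_SCORE[vasc_s]),
            chondro_foci_areas=int(rng.choice(_FOCI_FOR_SCORE[chondro_s])),
            osteo_foci_areas=int(rng.choice(_FOCI_FOR_SCORE[osteo_s])),
        )
        observations.append(obs)
        true_scores.append(
            {"col1": col1_s, "vascularity": vasc_s, "chondro": chondro_s,
             "osteo": osteo_s}
        )
    truth = GroundTruth(
        kind="semiquant",
        seed=seed,
        preset={"lesion": lesion, "wheel": wheel, "jitter": jitter},
        data={"true_scores": true_scores},
    )
    return observations, truth


# --------------------------------------------------------------------------
# cohort design
# --------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Group sizes: (lesion, wheel, n_animals, n_tendons) per group."""

    groups: tuple[tuple[str, str, int, int], ...]

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort design has no groups")
        for lesion, wheel, n_animals, n_tendons in self.groups:
            if (lesion, wheel) not in GROUPS:
                raise ValueError(f"unknown group {(lesion, wheel)!r}")
            if n_animals <= 0 or n_tendons < 0:
                raise ValueError(
                    f"group {(lesion, wheel)}: invalid sizes "
                    f"({n_animals} animals, {n_tendons} tendons)"
                )

    @property
    def n_animals(self) -> int:
        return sum(g[2] for g in self.groups)

    @property
    def n_tendons(self) -> int:
        return sum(g[3] for g in self.groups)


def study_cohort_design() -> CohortDesign:
    """The study's group sizes: 8 CTR, 12 unilateral and 12 bilateral mice
    per wheel condition (64 mice), with 8/6/12 tendons per group (52)."""
    return CohortDesign(
        groups=(
            ("none", "blocked", 8, 8),
            ("none", "free", 8, 8),
            ("unilateral", "blocked", 12, 6),
            ("unilateral", "free", 12, 6),
            ("bilateral", "blocked", 12, 12),
            ("bilateral", "free", 12, 12),
        )
    )
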