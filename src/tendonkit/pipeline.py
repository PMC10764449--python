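"""End-to-end study orchestration: simulate → metrics → scores → inference.

A :class:`StudyConfig` plus a master seed fully determines a run.  Stage
seeds are derived from the master seed through ``SeedSequence([master,
stage_id, unit_index])`` so each cage, tendon and table gets an independent,
reproducible stream.  Every stage writes its tables to the run directory so
any stage can be re-run or audited independently, and the
:class:`ReportBundle` lists everything that was produced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, agreement, histomorph, scoring, stats, synthetic
from .activity import (
    aggregate_bins_by_period,
    bin_3h,
    normalize_to_baseline,
    normalize_to_control,
    split_day_night,
    weekly_periods,
)
from .io import write_field_tiff, write_trace_csv

__all__ = ["StudyConfig", "ReportBundle", "default_config", "validate_config", "run_all"]

log = logging.getLogger("tendonkit")

_STAGE_IDS = {
    "activity": 1,
    "histology": 2,
    "scoring": 3,
    "agreement": 4,
    "correlation": 5,
}


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-unit seed below 2**31."""
    ss = np.random.SeedSequence([int(master), _STAGE_IDS[stage], int(index)])
    return int(ss.generate_state(1)[0] >> 1)


@dataclass
class StudyConfig:
    """Everything needed to reproduce a run (serializable to YAML)."""

    design: synthetic.CohortDesign = field(
        default_factory=synthetic.study_cohort_design
    )
    # image simulation is the expensive stage; the demo default measures 2
    # tendons per group at 2 fields per area (the full scheme is 4)
    histology_tendons_per_group: int = 2
    fields_per_area: int = 2
    baseline_days: int = 3
    exclude_days: tuple[int, ...] = (0, 14)  # light-period analyses only
    kappa_weights: str = "linear"
    welch: bool = False
    direction_mode: str = "ratio"  # or "deviation"
    correlation_n: int = 52
    assessor_confusion: float = 0.1
    seed: int = 0
    outdir: str = "tendonkit_run"
    write_traces: bool = True
    write_images: bool = False

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["design"] = [list(g) for g in self.design.groups]
        d["exclude_days"] = list(self.exclude_days)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["design"] = synthetic.CohortDesign(
            groups=tuple(tuple(g) for g in d["design"])
        )
        d["exclude_days"] = tuple(d.get("exclude_days", (0, 14)))
        return cls(**d)


def default_config(outdir: str = "tendonkit_run", seed: int = 0) -> StudyConfig:
    """The packaged study-scenario configuration at demo image scale."""
    return StudyConfig(outdir=outdir, seed=seed)


def validate_config(config: StudyConfig) -> list[str]:
    """All invariant violations, each with a path into the config."""
    v: list[str] = []
    try:
        config.design.validate()
    except ValueError as exc:
        v.append(f"design: {exc}")
    if config.fields_per_area < 1 or config.fields_per_area > 4:
        v.append(f"fields_per_area: {config.fields_per_area} outside 1..4")
    if config.histology_tendons_per_group < 0:
        v.append("histology_tendons_per_group: must be nonnegative")
    if config.baseline_days < 3:
        v.append(f"baseline_days: {config.baseline_days} below the 3-day minimum")
    if config.kappa_weights not in ("linear", "quadratic"):
        v.append(f"kappa_weights: unknown scheme {config.kappa_weights!r}")
    if config.direction_mode not in ("ratio", "deviation"):
        v.append(f"direction_mode: unknown mode {config.direction_mode!r}")
    if not 0.0 <= config.assessor_confusion <= 0.5:
        v.append(f"assessor_confusion: {config.assessor_confusion} outside [0, 0.5]")
    if config.correlation_n <= 3:
        v.append(f"correlation_n: {config.correlation_n} too small for Fisher CIs")
    spec = synthetic.study_correlation_spec()
    try:
        spec.validate()
    except ValueError as exc:
        v.append(f"correlation_spec.rho: {exc}")
    for lesion, wheel, *_ in config.design.groups:
        try:
            synthetic.study_activity_preset(lesion, wheel)
            synthetic.study_histology_preset(lesion, wheel)
        except KeyError as exc:
            v.append(f"design.groups[{lesion},{wheel}]: missing preset ({exc})")
    return v


@dataclass
class ReportBundle:
    """Paths of every artifact a run produced, plus the config snapshot."""

    outdir: str
    config_path: str
    log_path: str
    tables: dict[str, str]
    version: str = __version__

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def run_all(config: StudyConfig, force: bool = False) -> ReportBundle:
    """Execute every stage in order and return the report bundle.

    Raises if the output directory already holds a run (unless ``force``)
    or if the configuration is invalid.
    """
    out = Path(config.outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n" + "\n".join(violations))
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    tables: dict[str, str] = {}
    try:
        config_path = out / "config.yaml"
        config.to_yaml(config_path)
        log.info("run started: seed=%d outdir=%s version=%s",
                 config.seed, out, __version__)
        log.info(
            "flags: baseline_days=%d exclude_days=%s kappa_weights=%s welch=%s "
            "direction_mode=%s correlation_n=%d assessor_confusion=%.3f",
            config.baseline_days, config.exclude_days, config.kappa_weights,
            config.welch, config.direction_mode, config.correlation_n,
            config.assessor_confusion,
        )
        norm_by_cage = _stage_activity(config, out, tables)
        tendon_metrics = _stage_histology(config, out, tables)
        _stage_scoring(config, out, tables, tendon_metrics)
        _stage_agreement(config, out, tables)
        _stage_correlation(config, out, tables)
        bundle = ReportBundle(
            outdir=str(out),
            config_path=str(config_path),
            log_path=str(log_path),
            tables=tables,
        )
        bundle.to_json(out / "bundle.json")
        log.info("run complete: %d tables", len(tables))
        return bundle
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage_activity(config: StudyConfig, out: Path, tables: dict) -> dict:
    adir = out / "activity"
    adir.mkdir(exist_ok=True)
    daily_rows, binned_rows = [], []
    norm_by_group: dict[tuple[str, str], list[pd.DataFrame]] = {}
    unit = 0
    for lesion, wheel, n_animals, _ in config.design.groups:
        preset = synthetic.study_activity_preset(lesion, wheel)
        for i in range(n_animals):
            seed = stage_seed(config.seed, "activity", unit)
            unit += 1
            trace, _ = synthetic.simulate_activity(
                preset, (lesion, wheel), seed=seed,
                cage_id=f"{lesion}-{wheel}-{i:02d}",
            )
            if config.write_traces:
                tdir = out / "traces"
                tdir.mkdir(exist_ok=True)
                write_trace_csv(trace, tdir / f"{trace.cage_id}.csv")
            daily = split_day_night(trace)
            daily["group"] = f"{lesion}-{wheel}"
            daily_rows.append(daily)
            b = bin_3h(trace)
            b["group"] = f"{lesion}-{wheel}"
            binned_rows.append(b)
            norm = normalize_to_baseline(daily, config.baseline_days)
            norm_by_group.setdefault((lesion, wheel), []).append(norm)
    daily_all = pd.concat(daily_rows, ignore_index=True)
    # the surgery and food-supplementation days distort the light period only
    light_mask = daily_all["day_index"].isin(list(config.exclude_days))
    daily_all.loc[light_mask, "light_mean"] = np.nan
    daily_all.to_csv(adir / "daily_summary.csv", index=False)
    tables["daily_summary"] = str(adir / "daily_summary.csv")
    binned_all = pd.concat(binned_rows, ignore_index=True)
    binned_all.to_csv(adir / "binned_3h.csv", index=False)
    tables["binned_3h"] = str(adir / "binned_3h.csv")
    periods = weekly_periods()
    periods["baseline"] = sorted(d for d in binned_all["day_index"].unique() if d < 0)
    agg = aggregate_bins_by_period(binned_all, periods)
    agg.to_csv(adir / "bin_period_means.csv", index=False)
    tables["bin_period_means"] = str(adir / "bin_period_means.csv")
    norm_all = pd.concat(
        [df.assign(group=f"{k[0]}-{k[1]}") for k, v in norm_by_group.items() for df in v],
        ignore_index=True,
    )
    norm_all.to_csv(adir / "normalized_night.csv", index=False)
    tables["normalized_night"] = str(adir / "normalized_night.csv")

    # control-normalization: lesioned groups vs the wheel-matched CTR
    ratio_rows = []
    for (lesion, wheel), series in norm_by_group.items():
        if lesion == "none":
            continue
        control = norm_by_group.get(("none", wheel))
        if not control:
            log.warning("no wheel-matched control for %s-%s; skipped", lesion, wheel)
            continue
        ratios = normalize_to_control(series, control)
        ratio_rows += [
            {"group": f"{lesion}-{wheel}", "animal": i, "ratio": r}
            for i, r in enumerate(ratios)
        ]
    ratios_df = pd.DataFrame(ratio_rows)
    ratios_df.to_csv(adir / "control_normalized.csv", index=False)
    tables["control_normalized"] = str(adir / "control_normalized.csv")
    ttests = {}
    if not ratios_df.empty:
        for lesion in ("unilateral", "bilateral"):
            a = ratios_df.loc[ratios_df["group"] == f"{lesion}-free", "ratio"].to_numpy()
            b = ratios_df.loc[ratios_df["group"] == f"{lesion}-blocked", "ratio"].to_numpy()
            if a.size >= 2 and b.size >= 2:
                t, p = stats.independent_t_test(a, b, welch=config.welch)
                ttests[f"{lesion}_free_vs_blocked"] = {"t": t, "p": p}
    with open(adir / "t_tests.json", "w") as fh:
        json.dump(ttests, fh, indent=1)
    tables["activity_t_tests"] = str(adir / "t_tests.json")
    log.info("activity stage: %d cages", unit)
    return norm_by_group


def _measure_tendon_fields(config: StudyConfig, preset, tendon_id: str,
                           base_unit: int, out: Path) -> pd.DataFrame:
    rows = []
    unit = base_unit
    for area in range(1, histomorph.N_AREAS + 1):
        for fi in range(1, config.fields_per_area + 1):
            seed = stage_seed(config.seed, "histology", unit)
            unit += 1
            image, _ = synthetic.simulate_histology_field(
                preset, area_index=area, field_index=fi, seed=seed,
                tendon_id=tendon_id,
            )
            if config.write_images:
                idir = out / "histology" / "images"
                idir.mkdir(parents=True, exist_ok=True)
                write_field_tiff(
                    image, idir / f"{tendon_id}_a{area}f{fi}.tiff", seed=seed
                )
            nuclei = histomorph.detect_nuclei(image)
            direc = histomorph.directionality(image)
            rows.append(
                {
                    "tendon_id": tendon_id,
                    "area_index": area,
                    "field_index": fi,
                    "count": len(nuclei),
                    "direction": direc.direction,
                    "dispersion": direc.dispersion,
                    "goodness": direc.goodness,
                    "reliable": direc.reliable,
                    "field_area_mm2": image.field_area_um2 / 1e6,
                }
            )
    return pd.DataFrame(rows)


def _stage_histology(config: StudyConfig, out: Path, tables: dict) -> pd.DataFrame:
    hdir = out / "histology"
    hdir.mkdir(exist_ok=True)
    unit = 0
    fields_per_tendon = histomorph.N_AREAS * config.fields_per_area
    field_tables: list[tuple[str, str, str, pd.DataFrame]] = []
    for lesion, wheel, _, n_tendons in config.design.groups:
        n_meas = min(n_tendons, config.histology_tendons_per_group)
        preset = synthetic.study_histology_preset(lesion, wheel)
        for t in range(n_meas):
            tendon_id = f"{lesion}-{wheel}-T{t:02d}"
            ft = _measure_tendon_fields(config, preset, tendon_id, unit, out)
            unit += fields_per_tendon
            field_tables.append((lesion, wheel, tendon_id, ft))
    all_fields = pd.concat([ft for *_, ft in field_tables], ignore_index=True)
    all_fields.to_csv(hdir / "fields.csv", index=False)
    tables["histology_fields"] = str(hdir / "fields.csv")

    # healthy reference from the CTR tendons
    ctr = [ft for lesion, *_, ft in field_tables if lesion == "none"]
    if not ctr:
        raise RuntimeError("histology stage: design contains no control tendons")
    ctr_fields = pd.concat(ctr, ignore_index=True)
    healthy_counts = ctr_fields["count"].to_numpy()
    w = ctr_fields["goodness"].to_numpy()
    ang = np.radians(2.0 * ctr_fields["direction"].to_numpy())
    healthy_dir = histomorph.fold_angle(0.5 * np.degrees(np.arctan2(
        np.average(np.sin(ang), weights=w), np.average(np.cos(ang), weights=w))))
    healthy_ref = histomorph.DirectionalityResult(
        direction=float(healthy_dir),
        dispersion=float(np.average(ctr_fields["dispersion"], weights=w)),
        goodness=1.0,
    )
    log.info("healthy reference: %.1f cells/field, direction %.2f deg",
             healthy_counts.mean(), healthy_ref.direction)

    rows = []
    for lesion, wheel, tendon_id, ft in field_tables:
        tm = histomorph.assemble_tendon_metrics(
            ft, healthy_counts, healthy_ref, tendon_id=tendon_id
        )
        if config.direction_mode == "deviation":
            ratio = histomorph.direction_deviation(
                histomorph.DirectionalityResult(tm.direction, tm.dispersion, 1.0),
                healthy_ref,
            )
        else:
            ratio = tm.direction_ratio
        rows.append(
            {
                "tendon_id": tendon_id,
                "lesion": lesion,
                "wheel": wheel,
                "mean_count": tm.mean_count,
                "fold_change": tm.fold_change,
                "direction": tm.direction,
                "dispersion": tm.dispersion,
                "direction_ratio": ratio,
                "total_area_mm2": tm.total_area_mm2,
            }
        )
    tendons = pd.DataFrame(rows)
    tendons.to_csv(hdir / "tendons.csv", index=False)
    tables["tendon_metrics"] = str(hdir / "tendons.csv")
    log.info("histology stage: %d tendons, %d fields", len(tendons), len(all_fields))
    return tendons


def _stage_scoring(config: StudyConfig, out: Path, tables: dict,
                   tendons: pd.DataFrame) -> None:
    sdir = out / "scores"
    sdir.mkdir(exist_ok=True)
    cards = []
    for gi, (lesion, wheel, *_rest) in enumerate(config.design.groups):
        sub = tendons[(tendons["lesion"] == lesion) & (tendons["wheel"] == wheel)]
        if sub.empty:
            continue
        obs_list, _ = synthetic.simulate_semiquant(
            lesion, wheel, len(sub), seed=stage_seed(config.seed, "scoring", gi)
        )
        for (_, row), obs in zip(sub.iterrows(), obs_list):
            dispersion_pct = 100.0 * row["dispersion"] / 90.0
            card = scoring.score_tendon(
                row["tendon_id"],
                fold_change=row["fold_change"],
                direction_ratio=row["direction_ratio"],
                dispersion_percent=dispersion_pct,
                observation=obs,
            )
            cards.append({"lesion": lesion, "wheel": wheel, **asdict(card)})
    cards_df = pd.DataFrame(cards)
    cards_df.to_csv(sdir / "scorecards.csv", index=False)
    tables["scorecards"] = str(sdir / "scorecards.csv")
    summary = (
        cards_df.groupby(["lesion", "wheel"])["ths"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"count": "n"})
    )
    summary.to_csv(sdir / "ths_summary.csv", index=False)
    tables["ths_summary"] = str(sdir / "ths_summary.csv")
    log.info("scoring stage: %d score cards", len(cards_df))


def _stage_agreement(config: StudyConfig, out: Path, tables: dict) -> None:
    gdir = out / "agreement"
    gdir.mkdir(exist_ok=True)
    results = {}
    for pi, param in enumerate(("col1", "vascularity", "chondro", "osteo")):
        truths = []
        for gi, (lesion, wheel, _, n_tendons) in enumerate(config.design.groups):
            n_meas = min(n_tendons, config.histology_tendons_per_group)
            if n_meas == 0:
                continue
            _, gt = synthetic.simulate_semiquant(
                lesion, wheel, n_meas, seed=stage_seed(config.seed, "scoring", gi)
            )
            truths += [t[param] for t in gt.data["true_scores"]]
        table, _ = synthetic.simulate_assessors(
            truths, confusion=config.assessor_confusion,
            seed=stage_seed(config.seed, "agreement", pi), parameter=param,
        )
        res = agreement.assess_agreement(table, weights=config.kappa_weights)
        res.to_json(gdir / f"{param}.json")
        pd.DataFrame(res.confusion).to_csv(gdir / f"confusion_{param}.csv", index=False)
        results[param] = res
    tables["agreement"] = str(gdir)
    log.info(
        "agreement stage: %s",
        {k: round(v.kappa, 3) for k, v in results.items()},
    )


def _stage_correlation(config: StudyConfig, out: Path, tables: dict) -> None:
    cdir = out / "correlation"
    cdir.mkdir(exist_ok=True)
    lesioned = [g for g in config.design.groups if g[0] != "none"]
    if not lesioned:
        log.info("correlation stage skipped: design has no lesioned groups, "
                 "so there is no healing variance to correlate")
        return
    spec = synthetic.study_correlation_spec()
    cohort, _ = synthetic.simulate_metric_cohort(
        spec, n=config.correlation_n, seed=stage_seed(config.seed, "correlation", 0)
    )
    cohort.to_csv(cdir / "metric_cohort.csv", index=False)
    tables["metric_cohort"] = str(cdir / "metric_cohort.csv")
    results = stats.pearson_matrix(cohort)
    frame = stats.correlation_frame(results)
    frame.to_csv(cdir / "pairs.csv", index=False)
    tables["correlation_pairs"] = str(cdir / "pairs.csv")
    mat = pd.DataFrame(np.eye(len(spec.variables)), index=spec.variables,
                       columns=spec.variables)
    for r in results:
        mat.loc[r.var_x, r.var_y] = r.r
        mat.loc[r.var_y, r.var_x] = r.r
    mat.to_csv(cdir / "matrix.csv")
    tables["correlation_matrix"] = str(cdir / "matrix.csv")
    log.info("correlation stage: n=%d, %d pairs", config.correlation_n, len(results))
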