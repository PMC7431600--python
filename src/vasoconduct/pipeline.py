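"""End-to-end orchestration: simulate or ingest recordings, reduce them to
profiles, pool per group, fit the decay model, bootstrap, and compare
WT/KO pairs.  All outputs are tidy CSVs plus a JSON run log."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .bootstrap import (DEFAULT_N_REPS, BootstrapResult, bootstrap_fit,
                        compare_decay_rates, difference_interval)
from .decay import (ALPHA, DistanceTestResult, ExpFit, compare_local,
                    fit_exponential, per_distance_tests, predict)
from .io import read_recordings, write_recordings
from .synthetic import (DEFAULT_GROUP_LABELS, GroupParams, StimulationProtocol,
                        VesselRecording, default_group_params,
                        default_protocol, generate_cohort)
from .traces import (ConstrictionProfile, InclusionDecision, PooledGroupData,
                     apply_inclusion_criteria, build_profile, pool_group,
                     resting_diameter)

__all__ = ["PipelineConfig", "GroupReport", "PairReport", "AnalysisReport",
           "run_pipeline", "summarize_cohort", "significance_extent",
           "load_config", "default_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full description of one pipeline run.

    ``input_mode`` is either ``"simulate"`` (synthetic cohort from
    ``group_params``) or ``"csv"`` (recordings read from ``input_path``).
    """

    input_mode: str = "simulate"
    input_path: str | None = None
    group_params: tuple[GroupParams, ...] = ()
    protocol: StimulationProtocol = field(default_factory=default_protocol)
    n_bootstrap: int = DEFAULT_N_REPS
    master_seed: int = 0
    alpha: float = ALPHA
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.input_mode not in ("simulate", "csv"):
            raise ValueError("input_mode must be 'simulate' or 'csv'")
        if self.input_mode == "simulate" and self.input_path is not None:
            raise ValueError("simulate mode must not set input_path")
        if self.input_mode == "csv":
            if self.input_path is None:
                raise ValueError("csv mode requires input_path")
            if self.group_params:
                raise ValueError("csv mode must not set group_params")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")


def default_config(master_seed: int = 0,
                   n_bootstrap: int = DEFAULT_N_REPS,
                   output_dir: str | None = None) -> PipelineConfig:
    """Simulate-mode configuration with the four default genotype groups."""
    return PipelineConfig(
        input_mode="simulate",
        group_params=tuple(default_group_params(lbl)
                           for lbl in DEFAULT_GROUP_LABELS),
        master_seed=master_seed, n_bootstrap=n_bootstrap,
        output_dir=output_dir)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML configuration mirroring the config fields one-to-one."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    protocol = StimulationProtocol(**raw.get("protocol", {}))
    groups = tuple(GroupParams(**g) for g in raw.get("groups", []))
    return PipelineConfig(
        input_mode=raw.get("input_mode", "simulate"),
        input_path=raw.get("input_path"),
        group_params=groups,
        protocol=protocol,
        n_bootstrap=int(raw.get("n_bootstrap", DEFAULT_N_REPS)),
        master_seed=int(raw.get("master_seed", 0)),
        alpha=float(raw.get("alpha", ALPHA)),
        output_dir=raw.get("output_dir"))


@dataclass(frozen=True)
class GroupReport:
    group_label: str
    n_input: int
    n_included: int
    decisions: tuple[InclusionDecision, ...]
    pooled: PooledGroupData
    fit: ExpFit
    bootstrap: BootstrapResult
    distance_tests: tuple[DistanceTestResult, ...]
    significance_extent_um: float | None


@dataclass(frozen=True)
class PairReport:
    group_a: str
    group_b: str
    local_anova_f: float
    local_anova_p: float
    decay_t: float
    decay_p: float
    decay_diff_ci: tuple[float, float]


@dataclass(frozen=True)
class AnalysisReport:
    config: PipelineConfig
    groups: tuple[GroupReport, ...]
    pairs: tuple[PairReport, ...]
    cohort_summary: pd.DataFrame


def significance_extent(tests: list[DistanceTestResult]) -> float | None:
    """Largest distance up to which constriction is continuously significant.

    The extent is the largest distance d such that the test at d is
    significant and every shorter testable distance is significant too;
    an isolated significant point beyond a non-significant one does not
    extend it.  ``None`` when even the shortest testable distance is not
    significant.
    """
    extent = None
    for t in sorted(tests, key=lambda t: t.distance):
        if not t.testable:
            continue
        if t.significant:
            extent = t.distance
        else:
            break
    return extent


def summarize_cohort(recordings: list[VesselRecording],
                     decisions: list[InclusionDecision]) -> pd.DataFrame:
    """Per-group n, resting diameter at 0 um (mean +/- SEM) and traceable
    length (mean +/- SEM), over included vessels only."""
    by_id = {d.vessel_id: d for d in decisions}
    missing = [r.vessel_id for r in recordings if r.vessel_id not in by_id]
    if missing:
        raise ValueError(f"no inclusion decision for vessels {missing}")
    rows = []
    for rec in recordings:
        if not by_id[rec.vessel_id].included:
            continue
        rows.append((rec.group_label, resting_diameter(rec, 0.0),
                     rec.traceable_length))
    df = pd.DataFrame(rows, columns=["group", "diameter_um", "length_um"])
    out = []
    for label, sub in df.groupby("group", sort=False):
        n = len(sub)
        sem = (lambda v: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan)
        out.append({
            "group": label, "n": n,
            "diameter_mean_um": float(sub["diameter_um"].mean()),
            "diameter_sem_um": sem(sub["diameter_um"]),
            "length_mean_um": float(sub["length_um"].mean()),
            "length_sem_um": sem(sub["length_um"]),
        })
    return pd.DataFrame(out)


def _split_label(label: str) -> tuple[str, str] | None:
    """Split 'Cx40 WT' -> ('Cx40', 'WT'); None if no WT/KO token."""
    parts = label.split()
    for geno in ("WT", "KO"):
        if geno in parts:
            rest = " ".join(p for p in parts if p != geno)
            return rest, geno
    return None


def _wt_ko_pairs(labels: list[str]) -> list[tuple[str, str]]:
    """WT-vs-KO pairs sharing a strain prefix; (WT, KO) ordering."""
    strains: dict[str, dict[str, str]] = {}
    for lbl in labels:
        split = _split_label(lbl)
        if split is None:
            continue
        strain, geno = split
        strains.setdefault(strain, {})[geno] = lbl
    pairs = [(d["WT"], d["KO"]) for d in strains.values()
             if "WT" in d and "KO" in d]
    if not pairs and len(labels) == 2:
        pairs = [(labels[0], labels[1])]
    return pairs


def _stage_seed(master_seed: int, stage: str, key: str = "") -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}|{stage}|{key}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis and (optionally) write the report CSVs.

    Stages: generate or ingest recordings -> per-vessel profiles ->
    inclusion screening -> per-group pooling -> pooled exponential fit ->
    per-distance one-sample t-tests -> bootstrap resample-and-refit ->
    WT/KO comparisons (local ANOVA, decay-rate t-test).
    """
    if config.input_mode == "simulate":
        if not config.group_params:
            raise ValueError("simulate mode requires at least one group")
        recordings = generate_cohort(list(config.group_params),
                                     config.protocol, config.master_seed)
    else:
        recordings = read_recordings(config.input_path)

    profiles: dict[str, ConstrictionProfile] = {}
    decisions: list[InclusionDecision] = []
    for rec in recordings:
        prof = build_profile(rec)
        profiles[rec.vessel_id] = prof
        decisions.append(apply_inclusion_criteria(prof, rec))
    decided = {d.vessel_id: d for d in decisions}

    labels = list(dict.fromkeys(r.group_label for r in recordings))
    group_reports = []
    for label in labels:
        group_recs = [r for r in recordings if r.group_label == label]
        included = [profiles[r.vessel_id] for r in group_recs
                    if decided[r.vessel_id].included]
        if not included:
            raise ValueError(
                f"group {label!r}: no vessels passed the inclusion criteria")
        pooled = pool_group(included, label)
        fit = fit_exponential(pooled.point_array())
        tests = per_distance_tests(pooled, alpha=config.alpha)
        boot = bootstrap_fit(pooled, n_reps=config.n_bootstrap,
                             seed=_stage_seed(config.master_seed,
                                              "bootstrap", label))
        group_reports.append(GroupReport(
            group_label=label, n_input=len(group_recs),
            n_included=len(included),
            decisions=tuple(decided[r.vessel_id] for r in group_recs),
            pooled=pooled, fit=fit, bootstrap=boot,
            distance_tests=tuple(tests),
            significance_extent_um=significance_extent(tests)))

    by_label = {g.group_label: g for g in group_reports}
    pair_reports = []
    for la, lb in _wt_ko_pairs(labels):
        ga, gb = by_label[la], by_label[lb]
        f, p_local = compare_local(ga.pooled.values_at(0.0),
                                   gb.pooled.values_at(0.0))
        t, p_decay = compare_decay_rates(ga.bootstrap, gb.bootstrap)
        ci = difference_interval(
            ga.bootstrap, gb.bootstrap,
            seed=_stage_seed(config.master_seed, "diff", f"{la}|{lb}"))
        pair_reports.append(PairReport(group_a=la, group_b=lb,
                                       local_anova_f=f, local_anova_p=p_local,
                                       decay_t=t, decay_p=p_decay,
                                       decay_diff_ci=ci))

    report = AnalysisReport(config=config, groups=tuple(group_reports),
                            pairs=tuple(pair_reports),
                            cohort_summary=summarize_cohort(recordings,
                                                            decisions))
    if config.output_dir is not None:
        _write_report(report, recordings, Path(config.output_dir))
    return report


# ---------------------------------------------------------------- reporting

def _config_hash(config: PipelineConfig) -> str:
    # identifies the analysis, not the destination
    import dataclasses
    blob = repr(dataclasses.replace(config, output_dir=None)).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_report(report: AnalysisReport, recordings, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = report.config

    if cfg.input_mode == "simulate":
        write_recordings(recordings, outdir / "recordings.csv")

    prof_rows = []
    for g in report.groups:
        for _, r in g.pooled.points.iterrows():
            prof_rows.append((g.group_label, r["vessel_id"], r["distance_um"],
                              r["constriction"]))
    pd.DataFrame(prof_rows, columns=["group", "vessel_id", "distance_um",
                                     "constriction"]).to_csv(
        outdir / "profiles.csv", index=False)

    pooled_rows = []
    for g in report.groups:
        tests = {t.distance: t for t in g.distance_tests}
        for _, r in g.pooled.per_distance.iterrows():
            t = tests[r["distance_um"]]
            pooled_rows.append((g.group_label, r["distance_um"], r["mean"],
                                r["sem"], int(r["n"]), t.p_value,
                                predict(g.fit, r["distance_um"])))
    pd.DataFrame(pooled_rows, columns=["group", "distance_um", "mean", "sem",
                                       "n", "p_value", "fitted_value"]).to_csv(
        outdir / "pooled_profiles.csv", index=False)

    fit_rows = [(g.group_label, g.fit.a, g.fit.b, g.fit.length_constant_um,
                 g.fit.se_a, g.fit.se_b, g.fit.n_points, g.fit.converged)
                for g in report.groups]
    pd.DataFrame(fit_rows, columns=["group", "a", "b", "length_constant_um",
                                    "se_a", "se_b", "n_points",
                                    "converged"]).to_csv(
        outdir / "fits.csv", index=False)

    boot_rows = []
    for g in report.groups:
        b = g.bootstrap
        boot_rows.append((g.group_label, b.n_reps, b.n_failed,
                          float(np.median(b.a_samples)), *b.ci_a,
                          float(np.median(b.b_samples)), *b.ci_b, b.seed))
    pd.DataFrame(boot_rows, columns=["group", "n_reps", "n_failed", "a_median",
                                     "a_ci_low", "a_ci_high", "b_median",
                                     "b_ci_low", "b_ci_high", "seed"]).to_csv(
        outdir / "bootstrap_summary.csv", index=False)

    pair_rows = [(f"{p.group_a} vs {p.group_b}", p.local_anova_f,
                  p.local_anova_p, p.decay_t, p.decay_p,
                  p.decay_diff_ci[0], p.decay_diff_ci[1])
                 for p in report.pairs]
    pd.DataFrame(pair_rows, columns=["group_pair", "local_anova_f",
                                     "local_anova_p", "decay_t", "decay_p",
                                     "decay_diff_ci_low",
                                     "decay_diff_ci_high"]).to_csv(
        outdir / "comparisons.csv", index=False)

    report.cohort_summary.to_csv(outdir / "cohort_summary.csv", index=False)

    excl_rows = []
    for g in report.groups:
        for d in g.decisions:
            reasons = ";".join(f"{k}={v:.4g}"
                               for k, v in d.failed_criteria.items())
            excl_rows.append((g.group_label, d.vessel_id, d.included, reasons))
    pd.DataFrame(excl_rows, columns=["group", "vessel_id", "included",
                                     "failed_criteria"]).to_csv(
        outdir / "inclusion_decisions.csv", index=False)

    extents = {g.group_label: g.significance_extent_um for g in report.groups}
    log = {
        "config_hash": _config_hash(cfg),
        "master_seed": cfg.master_seed,
        "n_bootstrap": cfg.n_bootstrap,
        "alpha": cfg.alpha,
        "input_mode": cfg.input_mode,
        "significance_extent_um": extents,
        "versions": {
            "vasoconduct": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "exclusions": {
            g.group_label: {d.vessel_id: list(d.failed_criteria)
                            for d in g.decisions if not d.included}
            for g in report.groups
        },
    }
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
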