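"""End-to-end analysis stages: sweep, correlations, comparison, mean-dose window.

The pipeline consumes a labeled cohort of structure observations and
produces the study-style result artifacts:

* **sweep** — the AUC surface of EUD_V_D over the (threshold D, exponent a)
  grid for the whole-brain and half-brain structure classes, with the
  per-threshold maximal AUC (mAUC) and optimal ``a``;
* **correlations** — the Pearson matrix between D, mAUC and optimal ``a``
  (both classes), by default restricted to D <= 55 Gy where the
  relationship is monotone;
* **comparison** — ROC operating points for the critical-dose-volume EUD,
  the best simple point metrics D_V and V_D, and the whole-volume EUD, plus
  the paired comparison of EUD_V_crit against whole-volume EUD across the
  ``a`` grid;
* **window** — the AUC of the mean dose of V_D per threshold (the a = 1
  column of the sweep) against the whole-volume-EUD and best-point
  references, reporting the non-inferiority window.

All stage outputs are pure functions of (cohort, config); CSVs are written
with a fixed float format so identical inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dvh import FractionationScheme
from .eud import (
    EudGrid,
    MetricMatrix,
    build_metric_matrix,
    compute_eud_profile,
    default_dv_volumes,
    default_vd_doses,
)
from .roc import (
    DegenerateInputWarning,
    RocSummary,
    SweepResult,
    TTestResult,
    UndefinedStatisticError,
    auc_matrix,
    paired_t,
    pearson_r,
    roc_auc,
    scan_point_parameters,
)
from .synth import (
    STRUCTURE_BRAIN,
    STRUCTURE_LEFT,
    STRUCTURE_RIGHT,
    StructureObservation,
)
from . import dvh as _dvh
from . import __version__

__all__ = [
    "PipelineConfig",
    "CorrelationTables",
    "ComparisonResult",
    "run_sweep_stage",
    "run_correlation_stage",
    "run_comparison_stage",
    "run_mean_dose_window_stage",
    "run_pipeline",
    "CLASS_BRAIN",
    "CLASS_HALF",
]

CLASS_BRAIN = "brain"
CLASS_HALF = "half_brain"
_FLOAT_FMT = "%.12g"


@dataclasses.dataclass
class PipelineConfig:
    """Grids, thresholds and options for a full analysis run."""

    grid: EudGrid = dataclasses.field(default_factory=EudGrid)
    dv_volumes: np.ndarray = dataclasses.field(default_factory=default_dv_volumes)
    vd_doses: np.ndarray = dataclasses.field(default_factory=default_vd_doses)
    critical_dose_gy: float = 55.0
    correlation_dmax_gy: float | None = 55.0
    dominance_a_max: float = 22.0
    scheme: FractionationScheme = dataclasses.field(default_factory=FractionationScheme)
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = {}
        if "a_values" in raw or "threshold_doses" in raw:
            default = EudGrid()
            kwargs["grid"] = EudGrid(
                a_values=np.asarray(raw.get("a_values", default.a_values), dtype=float),
                threshold_doses=np.asarray(
                    raw.get("threshold_doses", default.threshold_doses), dtype=float
                ),
            )
        for key in ("dv_volumes", "vd_doses"):
            if key in raw:
                kwargs[key] = np.asarray(raw[key], dtype=float)
        for key in ("critical_dose_gy", "correlation_dmax_gy", "dominance_a_max", "make_plots"):
            if key in raw:
                kwargs[key] = raw[key]
        if "n_fractions" in raw or "alpha_beta_gy" in raw:
            kwargs["scheme"] = FractionationScheme(
                n_fractions=int(raw.get("n_fractions", 31)),
                alpha_beta_gy=float(raw.get("alpha_beta_gy", 3.0)),
            )
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "a_values": list(map(float, self.grid.a_values)),
            "threshold_doses": list(map(float, self.grid.threshold_doses)),
            "dv_volumes": list(map(float, self.dv_volumes)),
            "vd_doses": list(map(float, self.vd_doses)),
            "critical_dose_gy": self.critical_dose_gy,
            "correlation_dmax_gy": self.correlation_dmax_gy,
            "dominance_a_max": self.dominance_a_max,
            "n_fractions": self.scheme.n_fractions,
            "alpha_beta_gy": self.scheme.alpha_beta_gy,
            "make_plots": self.make_plots,
        }


def _class_observations(
    cohort: Sequence[StructureObservation], structure_class: str
) -> list[StructureObservation]:
    if structure_class == CLASS_BRAIN:
        wanted = (STRUCTURE_BRAIN,)
    else:
        wanted = (STRUCTURE_LEFT, STRUCTURE_RIGHT)
    obs = [o for o in cohort if o.structure in wanted]
    if any(o.injury is None for o in obs):
        raise ValueError("cohort must be labeled before analysis")
    return obs


def run_sweep_stage(
    cohort: Sequence[StructureObservation], config: PipelineConfig
) -> dict[str, SweepResult]:
    """AUC surface over (threshold D, a) per structure class.

    Whole brains contribute one observation per patient; half-brains two,
    with side-specific labels.  Grid cells whose scores are constant
    cohort-wide (e.g. an empty high-dose tail for everyone) are flagged as
    NaN rather than fabricated.
    """
    grid = config.grid
    results: dict[str, SweepResult] = {}
    for structure_class in (CLASS_BRAIN, CLASS_HALF):
        obs = _class_observations(cohort, structure_class)
        labels = np.array([o.injury for o in obs])
        surface = np.empty((grid.threshold_doses.size, grid.a_values.size))
        for i, d in enumerate(grid.threshold_doses):
            scores = np.vstack(
                [
                    compute_eud_profile(
                        _dvh.restrict_above_dose(o.dvh, float(d)), grid.a_values
                    )
                    for o in obs
                ]
            )
            surface[i] = auc_matrix(scores, labels)
        results[structure_class] = SweepResult(
            structure_class, grid.threshold_doses, grid.a_values, surface
        )
    return results


@dataclasses.dataclass
class CorrelationTables:
    """Pearson r and p matrices between D, mAUC and optimal a."""

    r: pd.DataFrame
    p: pd.DataFrame
    d_values: np.ndarray
    notes: list[str] = dataclasses.field(default_factory=list)


def run_correlation_stage(
    sweeps: dict[str, SweepResult], config: PipelineConfig
) -> CorrelationTables:
    """Pearson correlations between D, mAUC and a for both classes.

    Restricted to thresholds D <= ``correlation_dmax_gy`` (default 55 Gy),
    the region where mAUC and the optimal ``a`` vary monotonically with D;
    set the option to None to use the full threshold grid.  Undefined
    correlations (a constant series) are flagged as NaN with a note.
    """
    brain = sweeps[CLASS_BRAIN]
    half = sweeps[CLASS_HALF]
    d = brain.threshold_doses
    mask = np.ones(d.size, dtype=bool)
    if config.correlation_dmax_gy is not None:
        mask = d <= config.correlation_dmax_gy
    series = {
        "D": d[mask],
        "mAUC (brain)": brain.m_auc[mask],
        "a (brain)": brain.a_opt[mask],
        "mAUC (half-brain)": half.m_auc[mask],
        "a (half-brain)": half.a_opt[mask],
    }
    names = list(series)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    notes: list[str] = []
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if j <= i:
                continue
            xi, xj = series[ni], series[nj]
            ok = np.isfinite(xi) & np.isfinite(xj)
            try:
                res = pearson_r(xi[ok], xj[ok])
                rij, pij = res.r, res.pvalue
            except (UndefinedStatisticError, ValueError) as exc:
                rij, pij = np.nan, np.nan
                notes.append(f"r({ni}, {nj}) undefined: {exc}")
            r.loc[ni, nj] = r.loc[nj, ni] = rij
            p.loc[ni, nj] = p.loc[nj, ni] = pij
    return CorrelationTables(r, p, d[mask], notes)


def _summary_row(name: str, structure_class: str, summary: RocSummary, unit: str) -> dict:
    return {
        "structure_class": structure_class,
        "parameter": name,
        "auc": summary.auc,
        "ci95_low": summary.ci95[0],
        "ci95_high": summary.ci95[1],
        "cutoff": summary.cutoff,
        "cutoff_unit": unit,
        "sensitivity": summary.sensitivity,
        "specificity": summary.specificity,
        "youden_j": summary.youden_j,
        "n_pos": summary.n_pos,
        "n_neg": summary.n_neg,
        "degenerate": summary.degenerate,
    }


@dataclasses.dataclass
class ComparisonResult:
    """Operating-point table plus the EUD_V_crit vs whole-EUD dominance check."""

    table: pd.DataFrame
    dominance: pd.DataFrame
    paired_tests: dict[str, TTestResult]
    best_points: dict[str, dict[str, float]]


def run_comparison_stage(
    cohort: Sequence[StructureObservation],
    config: PipelineConfig,
    sweeps: dict[str, SweepResult] | None = None,
    matrix: MetricMatrix | None = None,
) -> ComparisonResult:
    """Head-to-head comparison of the candidate predictors per class.

    For each structure class the table reports, with DeLong CIs and Youden
    operating points: the critical-dose-volume EUD at its optimal ``a``,
    the whole-volume EUD at its optimal ``a``, and the best simple D_V and
    V_D points.  The dominance frame compares AUC of EUD_V_crit against the
    whole-volume EUD at every ``a`` up to ``dominance_a_max``, with a
    paired t-test across the grid.
    """
    if sweeps is None:
        sweeps = run_sweep_stage(cohort, config)
    if matrix is None:
        matrix = build_metric_matrix(
            cohort, config.grid, config.dv_volumes, config.vd_doses
        )
    crit = config.critical_dose_gy
    rows: list[dict] = []
    dom_rows: list[dict] = []
    paired_tests: dict[str, TTestResult] = {}
    best_points: dict[str, dict[str, float]] = {}
    for structure_class in (CLASS_BRAIN, CLASS_HALF):
        obs = _class_observations(cohort, structure_class)
        labels = np.array([o.injury for o in obs])
        keys = [(o.patient_id, o.structure) for o in obs]
        sub = matrix.values.loc[keys]
        sweep = sweeps[structure_class]

        grid = config.grid
        i_crit = int(np.argmin(np.abs(grid.threshold_doses - crit)))
        i_whole = int(np.argmin(np.abs(grid.threshold_doses)))
        a_crit = sweep.a_opt[i_crit]
        a_whole = sweep.a_opt[i_whole]

        def eud_scores(threshold_idx: int, a: float) -> np.ndarray:
            d = float(grid.threshold_doses[threshold_idx])
            return np.array(
                [
                    compute_eud_profile(
                        _dvh.restrict_above_dose(o.dvh, d), [a]
                    )[0]
                    for o in obs
                ]
            )

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateInputWarning)
            if np.isfinite(a_crit):
                s = roc_auc(eud_scores(i_crit, float(a_crit)), labels)
                rows.append(
                    _summary_row(
                        f"EUD_V{crit:g}Gy (a={a_crit:g})", structure_class, s, "Gy"
                    )
                )
            if np.isfinite(a_whole):
                s = roc_auc(eud_scores(i_whole, float(a_whole)), labels)
                rows.append(
                    _summary_row(
                        f"EUD_whole (a={a_whole:g})", structure_class, s, "Gy"
                    )
                )
            sub_matrix = MetricMatrix(sub, matrix.columns)
            ranked = scan_point_parameters(sub_matrix, labels)
            best: dict[str, float] = {}
            for family in ("d_v", "v_d"):
                fam = [(m, s) for m, s in ranked if m.family == family]
                if fam:
                    meta, summary = fam[0]
                    unit = "Gy" if family == "d_v" else "cc"
                    rows.append(
                        _summary_row(meta.name, structure_class, summary, unit)
                    )
                    best[meta.name] = summary.auc
            best_points[structure_class] = best

        a_mask = grid.a_values <= config.dominance_a_max
        auc_crit = sweep.auc[i_crit, a_mask]
        auc_whole = sweep.auc[i_whole, a_mask]
        for a, ac, aw in zip(grid.a_values[a_mask], auc_crit, auc_whole):
            dom_rows.append(
                {
                    "structure_class": structure_class,
                    "a": a,
                    "auc_eud_v_crit": ac,
                    "auc_eud_whole": aw,
                    "difference": ac - aw,
                }
            )
        ok = np.isfinite(auc_crit) & np.isfinite(auc_whole)
        if ok.sum() >= 2:
            paired_tests[structure_class] = paired_t(auc_crit[ok], auc_whole[ok])
    return ComparisonResult(
        pd.DataFrame(rows), pd.DataFrame(dom_rows), paired_tests, best_points
    )


def run_mean_dose_window_stage(
    cohort: Sequence[StructureObservation],
    config: PipelineConfig,
    sweeps: dict[str, SweepResult] | None = None,
    comparison: ComparisonResult | None = None,
) -> pd.DataFrame:
    """Feasibility window of the mean dose of V_D as the predictor.

    The mean dose of V_D is exactly the a = 1 column of the sweep surface.
    Per threshold D the stage reports its AUC next to two references — the
    whole-volume EUD mAUC and the best simple-point AUC — and flags
    non-inferiority against each; the window is the set of thresholds where
    the flag holds (empty when there is no signal).
    """
    if sweeps is None:
        sweeps = run_sweep_stage(cohort, config)
    if comparison is None:
        comparison = run_comparison_stage(cohort, config, sweeps=sweeps)
    rows = []
    for structure_class in (CLASS_BRAIN, CLASS_HALF):
        sweep = sweeps[structure_class]
        j_a1 = int(np.argmin(np.abs(sweep.a_values - 1.0)))
        i_whole = int(np.argmin(np.abs(sweep.threshold_doses)))
        ref_eud = sweep.m_auc[i_whole]
        points = comparison.best_points.get(structure_class, {})
        ref_points = max(points.values()) if points else np.nan
        for i, d in enumerate(sweep.threshold_doses):
            auc_mean = sweep.auc[i, j_a1]
            rows.append(
                {
                    "structure_class": structure_class,
                    "threshold_gy": d,
                    "auc_mean_dose": auc_mean,
                    "ref_auc_whole_eud": ref_eud,
                    "ref_auc_best_point": ref_points,
                    "noninferior_vs_eud": bool(
                        np.isfinite(auc_mean) and auc_mean >= ref_eud
                    ),
                    "noninferior_vs_points": bool(
                        np.isfinite(auc_mean)
                        and np.isfinite(ref_points)
                        and auc_mean >= ref_points
                    ),
                }
            )
    return pd.DataFrame(rows)


def _sweep_frames(sweeps: dict[str, SweepResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    long_rows = []
    summary_rows = []
    for structure_class, sweep in sweeps.items():
        for i, d in enumerate(sweep.threshold_doses):
            for j, a in enumerate(sweep.a_values):
                long_rows.append(
                    {
                        "structure_class": structure_class,
                        "threshold_gy": d,
                        "a": a,
                        "auc": sweep.auc[i, j],
                    }
                )
            summary_rows.append(
                {
                    "structure_class": structure_class,
                    "threshold_gy": d,
                    "m_auc": sweep.m_auc[i],
                    "a_opt": sweep.a_opt[i],
                }
            )
    return pd.DataFrame(long_rows), pd.DataFrame(summary_rows)


def run_pipeline(
    cohort: Sequence[StructureObservation],
    config: PipelineConfig,
    out_dir: str | Path,
    provenance_extra: dict | None = None,
) -> dict[str, Path]:
    """Run all stages and write the canonical CSV artifacts.

    Everything is computed before anything is written, so a failing stage
    leaves no partial output.  Returns the paths written.
    """
    sweeps = run_sweep_stage(cohort, config)
    matrix = build_metric_matrix(
        cohort, config.grid, config.dv_volumes, config.vd_doses
    )
    correlations = run_correlation_stage(sweeps, config)
    comparison = run_comparison_stage(cohort, config, sweeps=sweeps, matrix=matrix)
    window = run_mean_dose_window_stage(
        cohort, config, sweeps=sweeps, comparison=comparison
    )
    sweep_long, sweep_summary = _sweep_frames(sweeps)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        frame.to_csv(path, index=index, float_format=_FLOAT_FMT)
        paths[name] = path

    write("sweep.csv", sweep_long)
    write("sweep_summary.csv", sweep_summary)
    corr = correlations.r.copy()
    corr.index.name = "series"
    write("correlations.csv", corr, index=True)
    corr_p = correlations.p.copy()
    corr_p.index.name = "series"
    write("correlations_p.csv", corr_p, index=True)
    write("comparison.csv", comparison.table)
    write("dominance.csv", comparison.dominance)
    write("window.csv", window)

    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_observations": len(cohort),
        "paired_tests": {
            k: {"statistic": v.statistic, "pvalue": v.pvalue, "note": v.note}
            for k, v in comparison.paired_tests.items()
        },
        "correlation_notes": correlations.notes,
    }
    if provenance_extra:
        provenance["cohort"] = provenance_extra
    prov_path = out / "provenance.json"
    prov_path.write_text(
        json.dumps(provenance, indent=1, sort_keys=True), encoding="utf-8"
    )
    paths["provenance.json"] = prov_path

    if config.make_plots:
        from .plots import plot_average_dvh, plot_mean_dose_window, plot_sweep

        paths["sweep.png"] = plot_sweep(sweeps, out / "sweep.png")
        paths["window.png"] = plot_mean_dose_window(window, out / "window.png")
        paths["average_dvh.png"] = plot_average_dvh(cohort, out / "average_dvh.png")
    return paths
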