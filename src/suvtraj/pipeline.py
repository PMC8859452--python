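"""End-to-end trajectory pipeline: estimator class and file-based runner.

The chain is: AD-continuum selection -> normative reference -> per-interval
slopes -> penalized-spline rate fit -> RK4 integration from the anchor ->
landmark crossing times (-> stratified comparison when configured).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import (
    compute_cutoff,
    derive_normative_reference,
    load_long_table,
    select_ad_continuum,
    write_long_table,
)
from .config import PipelineConfig
from .exceptions import PipelineStageError
from .slopes import compute_interval_slopes, write_slopes
from .spline import fit_rate_function
from .stratify import StratifiedTrajectoryEstimator
from .trajectory import (
    integrate_trajectory,
    landmark_times,
    landmarks_to_json,
    write_curve_csv,
)

logger = logging.getLogger(__name__)


class TrajectoryEstimator(BaseEstimator):
    """Full trajectory reconstruction as a scikit-learn style estimator.

    ``fit`` consumes a validated long-format observation table and exposes
    the fitted products as trailing-underscore attributes: ``normative_``,
    ``cutoff_``, ``slopes_``, ``rate_function_``, ``curve_``, ``landmarks_``.
    ``predict(times)`` returns the curve's level at the requested times;
    ``time_to_level`` inverts it.

    Parameters mirror :class:`~suvtraj.config.PipelineConfig`; ``anchor`` is
    ``"normative"`` (the estimated normative mean, default) or an explicit
    SUVR value.
    """

    def __init__(
        self,
        select_continuum: bool = True,
        reference: str = "interval_start",
        min_interval: float = 0.25,
        slope_scheme: str = "consecutive",
        trim_quantile: float | None = None,
        n_basis: int = 40,
        knot_strategy: str = "quantile",
        lam: float | None = None,
        smoothing: str = "efs",
        weight_by_interval: bool = False,
        z_magnitude: float = 2.0,
        anchor: str | float = "normative",
        step: float = 0.01,
        t_max: float = 40.0,
        stall_threshold: float = 1e-5,
        extrapolation: str = "clamp",
        landmarks: dict | None = None,
    ):
        self.select_continuum = select_continuum
        self.reference = reference
        self.min_interval = min_interval
        self.slope_scheme = slope_scheme
        self.trim_quantile = trim_quantile
        self.n_basis = n_basis
        self.knot_strategy = knot_strategy
        self.lam = lam
        self.smoothing = smoothing
        self.weight_by_interval = weight_by_interval
        self.z_magnitude = z_magnitude
        self.anchor = anchor
        self.step = step
        self.t_max = t_max
        self.stall_threshold = stall_threshold
        self.extrapolation = extrapolation
        self.landmarks = landmarks

    def fit(self, table: pd.DataFrame, y=None):
        def stage(name, fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate failures with the stage name
                raise PipelineStageError(name, exc) from exc

        if self.select_continuum:
            table = stage("select_ad_continuum", select_ad_continuum, table)
        self.table_ = table
        self.normative_ = stage(
            "derive_normative_reference", derive_normative_reference, table
        )
        self.cutoff_ = stage(
            "compute_cutoff", compute_cutoff, self.normative_, self.z_magnitude
        )
        self.slopes_ = stage(
            "compute_interval_slopes",
            compute_interval_slopes,
            table,
            reference=self.reference,
            min_interval=self.min_interval,
            scheme=self.slope_scheme,
            trim_quantile=self.trim_quantile,
        )
        self.rate_function_ = stage(
            "fit_rate_function",
            fit_rate_function,
            self.slopes_,
            n_basis=self.n_basis,
            knot_strategy=self.knot_strategy,
            lam=self.lam,
            smoothing=self.smoothing,
            weight_by_interval=self.weight_by_interval,
            extrapolation=self.extrapolation,
        )
        anchor = (
            self.normative_.mean if self.anchor == "normative" else float(self.anchor)
        )
        self.anchor_level_ = anchor
        self.curve_ = stage(
            "integrate_trajectory",
            integrate_trajectory,
            self.rate_function_,
            anchor,
            t_max=self.t_max,
            step=self.step,
            stall_threshold=self.stall_threshold,
        )
        self.landmarks_ = stage(
            "landmark_times",
            landmark_times,
            self.curve_,
            self.normative_,
            self.cutoff_,
            extra_levels=self.landmarks,
        )
        return self

    def predict(self, times):
        """Level of the reconstructed curve at the requested time(s)."""
        return self.curve_.level_at(np.asarray(times, dtype=float))

    def time_to_level(self, level: float) -> float | None:
        return self.curve_.time_to_level(level)

    def time_to_cutoff(self) -> float | None:
        return self.curve_.time_to_level(self.cutoff_.cutoff_value)


def run_pipeline(config: PipelineConfig, table_path: str | Path) -> dict:
    """Execute the configured pipeline on a table file and write the report
    bundle (curve CSV, landmark CSV/JSON, normative/cutoff JSON, optional
    stratified comparison, and a run log with every setting and the config
    hash).  Returns a report dict with output paths and headline numbers."""
    out_dir = Path(config.output_dir or "suvtraj_output")
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    report: dict = {"config_hash": chash, "complete": False, "outputs": {}}
    log_path = out_dir / "run_log.json"

    def save_log():
        log = {
            "config": config.to_dict(),
            "config_hash": chash,
            "seed": config.seed,
            "input": str(table_path),
            "report": report,
        }
        log_path.write_text(json.dumps(log, sort_keys=True, indent=2, default=str) + "\n")

    try:
        table = load_long_table(table_path, column_map=config.column_map)
        est = TrajectoryEstimator(
            select_continuum=config.select_continuum,
            reference=config.reference,
            min_interval=config.min_interval,
            slope_scheme=config.slope_scheme,
            trim_quantile=config.trim_quantile,
            n_basis=config.n_basis,
            knot_strategy=config.knot_strategy,
            lam=config.lam,
            smoothing=config.smoothing,
            weight_by_interval=config.weight_by_interval,
            z_magnitude=config.z_magnitude,
            anchor=config.anchor,
            step=config.step,
            t_max=config.t_max,
            stall_threshold=config.stall_threshold,
            extrapolation=config.extrapolation,
            landmarks=config.landmarks,
        )
        est.fit(table)

        write_long_table(est.table_, out_dir / "selected_table.csv")
        write_slopes(est.slopes_, out_dir / "slopes.csv")
        est.normative_.to_json(out_dir / "normative.json")
        est.cutoff_.to_json(out_dir / "cutoff.json")
        rf_json = json.loads(est.rate_function_.to_json())
        rf_json["config_hash"] = chash
        (out_dir / "rate_function.json").write_text(
            json.dumps(rf_json, sort_keys=True, indent=2) + "\n"
        )
        write_curve_csv(
            est.curve_, out_dir / "curve.csv", ref=est.normative_, config_hash=chash
        )
        est.landmarks_.to_csv(out_dir / "landmarks.csv", index=False)
        landmarks_to_json(est.landmarks_, out_dir / "landmarks.json")
        report["outputs"] = {
            "selected_table": "selected_table.csv",
            "slopes": "slopes.csv",
            "normative": "normative.json",
            "cutoff": "cutoff.json",
            "rate_function": "rate_function.json",
            "curve": "curve.csv",
            "landmarks": "landmarks.csv",
        }
        ttc = est.time_to_cutoff()
        report["anchor_level"] = est.anchor_level_
        report["cutoff_value"] = est.cutoff_.cutoff_value
        report["time_to_cutoff_years"] = ttc
        report["stall_time"] = est.curve_.stall_time

        if config.stratify_by:
            strat = StratifiedTrajectoryEstimator(
                stratum_field=config.stratify_by,
                shared_anchor=config.shared_anchor,
                anchor=None if config.anchor == "normative" else float(config.anchor),
                cutoff_level=est.cutoff_.cutoff_value,
                z_magnitude=config.z_magnitude,
                reference=config.reference,
                min_interval=config.min_interval,
                n_basis=config.n_basis,
                knot_strategy=config.knot_strategy,
                lam=config.lam,
                smoothing=config.smoothing,
                step=config.step,
                t_max=config.t_max,
                stall_threshold=config.stall_threshold,
                bootstrap=config.bootstrap,
                ci_level=config.ci_level,
                seed=config.seed,
            )
            strat.fit(est.table_)
            comp = strat.comparison_
            comp.to_frame().to_csv(out_dir / "deltas.csv", index=False)
            comp_json = {
                "config_hash": chash,
                "landmark_level": comp.landmark_level,
                "stratum_labels": comp.stratum_labels,
                "times": comp.times,
                "deltas": {f"{a}|{b}": d for (a, b), d in comp.delta_years.items()},
                "n_slopes_per_stratum": comp.n_slopes_per_stratum,
            }
            if comp.bootstrap_ci:
                comp_json["bootstrap_ci"] = {
                    f"{a}|{b}": list(ci) for (a, b), ci in comp.bootstrap_ci.items()
                }
            (out_dir / "comparison.json").write_text(
                json.dumps(comp_json, sort_keys=True, indent=2) + "\n"
            )
            for lab, fit in strat.fits_.items():
                write_curve_csv(
                    fit.curve,
                    out_dir / f"curve_{lab}.csv",
                    ref=est.normative_,
                    config_hash=chash,
                )
            report["outputs"]["comparison"] = "comparison.json"
            report["outputs"]["deltas"] = "deltas.csv"
            report["deltas"] = comp_json["deltas"]

        report["complete"] = True
        return report
    finally:
        save_log()
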