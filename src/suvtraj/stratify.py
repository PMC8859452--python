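"""Stratified trajectory fitting and descriptive time-to-landmark comparison.

Runs the slope -> spline -> ODE pipeline separately within strata (sex,
APOE e4 carrier status, or any label column) and compares the times at which
the per-stratum curves cross a landmark level.  The comparison is
descriptive, as in the underlying method; an optional subject-level
bootstrap (resampling subjects with replacement within stratum) attaches
percentile intervals to the pairwise time differences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CutoffSpec, compute_cutoff, derive_normative_reference
from .exceptions import InsufficientDataError
from .slopes import compute_interval_slopes
from .spline import RateFunction, fit_rate_function
from .trajectory import TrajectoryCurve, integrate_trajectory

logger = logging.getLogger(__name__)

MIN_SLOPE_ROWS = 10


@dataclass
class StratumFit:
    """Per-stratum pipeline products (kept so bootstrap can re-run the fit)."""

    label: str
    table: pd.DataFrame
    slopes: pd.DataFrame
    rate_function: RateFunction
    curve: TrajectoryCurve
    anchor: float


@dataclass
class StratumComparison:
    """Pairwise crossing-time comparison at a landmark level.

    ``delta_years[(a, b)]`` is positive when stratum ``a`` (first-listed)
    reaches the landmark earlier than ``b``; None marks a stratum that never
    reached it (not-comparable).
    """

    stratum_labels: list[str]
    landmark_level: float
    times: dict[str, float | None]
    delta_years: dict[tuple[str, str], float | None]
    n_slopes_per_stratum: dict[str, int]
    bootstrap_ci: dict[tuple[str, str], tuple[float, float]] | None = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), d in self.delta_years.items():
            ci = (self.bootstrap_ci or {}).get((a, b))
            rows.append(
                {
                    "stratum_a": a,
                    "stratum_b": b,
                    "time_a": np.nan if self.times[a] is None else self.times[a],
                    "time_b": np.nan if self.times[b] is None else self.times[b],
                    "delta_years": np.nan if d is None else d,
                    "ci_low": np.nan if ci is None else ci[0],
                    "ci_high": np.nan if ci is None else ci[1],
                }
            )
        return pd.DataFrame(rows)


def _fit_curve(
    table: pd.DataFrame,
    anchor: float,
    reference: str = "interval_start",
    min_interval: float = 0.25,
    n_basis: int = 40,
    knot_strategy: str = "quantile",
    lam: float | None = None,
    smoothing: str = "efs",
    weight_by_interval: bool = False,
    step: float = 0.01,
    t_max: float = 40.0,
    stall_threshold: float = 1e-5,
    extrapolation: str = "clamp",
):
    """slope -> spline -> integration chain on one table (shared by strata
    and by the bootstrap)."""
    slopes = compute_interval_slopes(
        table, reference=reference, min_interval=min_interval
    )
    if len(slopes) < MIN_SLOPE_ROWS:
        raise InsufficientDataError(
            f"only {len(slopes)} slope rows (< {MIN_SLOPE_ROWS})"
        )
    f = fit_rate_function(
        slopes,
        n_basis=n_basis,
        knot_strategy=knot_strategy,
        lam=lam,
        smoothing=smoothing,
        weight_by_interval=weight_by_interval,
        extrapolation=extrapolation,
    )
    curve = integrate_trajectory(
        f, anchor, t_max=t_max, step=step, stall_threshold=stall_threshold
    )
    return slopes, f, curve


def fit_stratified(
    table: pd.DataFrame,
    stratum_field: str,
    shared_anchor: bool = True,
    anchor: float | None = None,
    **fit_kwargs,
) -> dict[str, StratumFit]:
    """Fit the full pipeline within each level of ``stratum_field``.

    The anchor is, in order of precedence: the explicit ``anchor`` value;
    the pooled normative mean (``shared_anchor=True``, default, so every
    stratum starts from a common initial level); or each stratum's own
    normative mean.  Strata with too few slope rows are skipped with a
    warning; if all are skipped an error is raised.
    """
    if stratum_field not in table.columns:
        raise KeyError(f"stratum field {stratum_field!r} not in table")
    values = table[stratum_field]
    known = values.notna() & (values.astype(str) != "unknown")
    if (~known).any():
        logger.warning(
            "dropping %d row(s) with unknown %s", int((~known).sum()), stratum_field
        )
    table = table[known]

    pooled_anchor = anchor
    if pooled_anchor is None and shared_anchor:
        pooled_anchor = derive_normative_reference(table).mean

    fits: dict[str, StratumFit] = {}
    for label, sub in table.groupby(stratum_field, sort=True):
        label = str(label)
        a = pooled_anchor
        if a is None:
            a = derive_normative_reference(sub).mean
        try:
            slopes, f, curve = _fit_curve(sub, a, **fit_kwargs)
        except InsufficientDataError as exc:
            logger.warning("skipping stratum %r: %s", label, exc)
            continue
        fits[label] = StratumFit(
            label=label,
            table=sub.reset_index(drop=True),
            slopes=slopes,
            rate_function=f,
            curve=curve,
            anchor=float(a),
        )
    if not fits:
        raise InsufficientDataError("every stratum was below the minimum data size")
    return fits


def compare_time_to_cutoff(
    fits: dict[str, StratumFit] | dict[str, TrajectoryCurve],
    cutoff: CutoffSpec | float,
    bootstrap: int | None = None,
    ci_level: float = 0.95,
    seed: int | None = None,
    **fit_kwargs,
) -> StratumComparison:
    """Pairwise differences in time-to-landmark between strata.

    ``bootstrap`` (number of replicates, e.g. 200) resamples subjects with
    replacement within each stratum, re-runs the pipeline and attaches
    percentile intervals; it requires ``fits`` to be :class:`StratumFit`
    objects (which retain their tables).
    """
    level = cutoff.cutoff_value if isinstance(cutoff, CutoffSpec) else float(cutoff)
    labels = list(fits)
    if len(labels) < 2:
        raise InsufficientDataError("need >= 2 strata to compare")

    def curve_of(v):
        return v.curve if isinstance(v, StratumFit) else v

    times = {lab: curve_of(fits[lab]).time_to_level(level) for lab in labels}
    deltas: dict[tuple[str, str], float | None] = {}
    for a, b in itertools.combinations(labels, 2):
        if times[a] is None or times[b] is None:
            deltas[(a, b)] = None
        else:
            deltas[(a, b)] = times[b] - times[a]  # positive: a reaches earlier

    n_slopes = {
        lab: (len(fits[lab].slopes) if isinstance(fits[lab], StratumFit) else -1)
        for lab in labels
    }

    ci = None
    if bootstrap:
        if not all(isinstance(fits[lab], StratumFit) for lab in labels):
            raise ValueError("bootstrap needs StratumFit inputs (with tables)")
        rng = np.random.default_rng(seed)
        draws: dict[tuple[str, str], list[float]] = {k: [] for k in deltas}
        index_maps = {
            lab: fits[lab].table.groupby("subject_id").indices for lab in labels
        }
        for _ in range(int(bootstrap)):
            boot_times = {}
            for lab in labels:
                fit = fits[lab]
                idx_map = index_maps[lab]
                ids = np.array(list(idx_map))
                pick = rng.choice(ids, size=ids.size, replace=True)
                chunks = [idx_map[sid] for sid in pick]
                rows = np.concatenate(chunks)
                resampled = fit.table.iloc[rows].copy()
                # relabel so repeated draws of a subject stay distinct subjects
                resampled["subject_id"] = np.repeat(
                    [f"b{j}" for j in range(len(pick))],
                    [len(c) for c in chunks],
                )
                resampled = resampled.sort_values(
                    ["subject_id", "visit_time"], kind="mergesort"
                ).reset_index(drop=True)
                try:
                    _, _, curve = _fit_curve(resampled, fit.anchor, **fit_kwargs)
                    boot_times[lab] = curve.time_to_level(level)
                except InsufficientDataError:
                    boot_times[lab] = None
            for (a, b) in deltas:
                ta, tb = boot_times.get(a), boot_times.get(b)
                if ta is not None and tb is not None:
                    draws[(a, b)].append(tb - ta)
        alpha = (1.0 - ci_level) / 2.0
        ci = {}
        for key, vals in draws.items():
            if vals:
                lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
                ci[key] = (float(lo), float(hi))
    return StratumComparison(
        stratum_labels=labels,
        landmark_level=level,
        times=times,
        delta_years=deltas,
        n_slopes_per_stratum=n_slopes,
        bootstrap_ci=ci,
        metadata={"ci_level": ci_level, "bootstrap": bootstrap},
    )


class StratifiedTrajectoryEstimator(BaseEstimator):
    """Stratified trajectory comparison as a scikit-learn style estimator.

    ``fit(table)`` runs the full per-stratum pipeline and stores the fits and
    the pairwise time-to-cutoff comparison.  ``cutoff_level=None`` derives
    the cutoff from the pooled normative reference at ``z_magnitude``.
    """

    def __init__(
        self,
        stratum_field: str = "sex",
        shared_anchor: bool = True,
        anchor: float | None = None,
        cutoff_level: float | None = None,
        z_magnitude: float = 2.0,
        reference: str = "interval_start",
        min_interval: float = 0.25,
        n_basis: int = 40,
        knot_strategy: str = "quantile",
        lam: float | None = None,
        smoothing: str = "efs",
        step: float = 0.01,
        t_max: float = 40.0,
        stall_threshold: float = 1e-5,
        bootstrap: int | None = None,
        ci_level: float = 0.95,
        seed: int | None = None,
    ):
        self.stratum_field = stratum_field
        self.shared_anchor = shared_anchor
        self.anchor = anchor
        self.cutoff_level = cutoff_level
        self.z_magnitude = z_magnitude
        self.reference = reference
        self.min_interval = min_interval
        self.n_basis = n_basis
        self.knot_strategy = knot_strategy
        self.lam = lam
        self.smoothing = smoothing
        self.step = step
        self.t_max = t_max
        self.stall_threshold = stall_threshold
        self.bootstrap = bootstrap
        self.ci_level = ci_level
        self.seed = seed

    def _fit_kwargs(self) -> dict:
        return dict(
            reference=self.reference,
            min_interval=self.min_interval,
            n_basis=self.n_basis,
            knot_strategy=self.knot_strategy,
            lam=self.lam,
            smoothing=self.smoothing,
            step=self.step,
            t_max=self.t_max,
            stall_threshold=self.stall_threshold,
        )

    def fit(self, table: pd.DataFrame, y=None):
        cutoff_level = self.cutoff_level
        if cutoff_level is None:
            ref = derive_normative_reference(table)
            cutoff_level = compute_cutoff(ref, self.z_magnitude).cutoff_value
        self.fits_ = fit_stratified(
            table,
            self.stratum_field,
            shared_anchor=self.shared_anchor,
            anchor=self.anchor,
            **self._fit_kwargs(),
        )
        self.cutoff_level_ = float(cutoff_level)
        self.comparison_ = compare_time_to_cutoff(
            self.fits_,
            cutoff_level,
            bootstrap=self.bootstrap,
            ci_level=self.ci_level,
            seed=self.seed,
            **self._fit_kwargs(),
        )
        return self
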