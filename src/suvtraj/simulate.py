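"""Synthetic longitudinal cohorts with closed-form ground truth.

The generator emulates the data structure the trajectory method assumes:
subjects follow a common sigmoidal (logistic) accumulation curve with
staggered onsets, are observed at a handful of visits 1-2 years apart with
additive Gaussian measurement noise, and a normative subgroup sits flat at
the curve's floor (far pre-onset), providing the amyloid-negative
cognitively-normal reference.  Because the onsets are staggered across the
whole transition, short individual follow-ups tile the full trajectory -
the core assumption that makes rate-vs-level integration work.

Ground-truth oracles (the logistic rate function and the closed-form
time-at-level) let every pipeline stage be scored against known truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import validate_table
from .exceptions import ConfigError, DomainError

TRAJECTORY_KINDS = ("logistic", "linear")

#: half-width of the automatic onset window in logistic-argument units;
#: uniform(-6/r, 6/r) onsets put baseline levels within ~0.25% of both
#: asymptotes, so staggered subjects tile the whole (floor, ceiling) range.
_AUTO_ONSET_SPAN = 6.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort; defaults are the package's standard
    study conditions (N=500, 3-4 visits 1-2 years apart, noise SD 0.02 SUVR,
    logistic floor 0.8 / ceiling 1.9 / growth rate 0.3 per year)."""

    n_subjects: int = 500
    floor: float = 0.8
    ceiling: float = 1.9
    growth_rate: float = 0.3
    onset_range: tuple[float, float] | None = None  # None -> +-6/growth_rate
    visits_per_subject: int | tuple[int, int] = (3, 4)
    visit_spacing: float | tuple[float, float] = (1.0, 2.0)
    noise_sd: float = 0.02
    normative_fraction: float = 0.3
    trajectory: str = "logistic"
    positivity_z: float = 2.0
    mci_level: float = 1.2
    dementia_level: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not self.ceiling > self.floor:
            raise ConfigError("ceiling must exceed floor")
        if not self.growth_rate > 0:
            raise ConfigError("growth_rate must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.normative_fraction <= 1:
            raise ConfigError("normative_fraction must be in [0, 1]")
        if self.trajectory not in TRAJECTORY_KINDS:
            raise ConfigError(f"trajectory must be one of {TRAJECTORY_KINDS}")
        v = self.visits_per_subject
        vmin = v if isinstance(v, int) else v[0]
        if vmin < 1:
            raise ConfigError("every subject needs at least one visit")

    @property
    def resolved_onset_range(self) -> tuple[float, float]:
        if self.onset_range is not None:
            return (float(self.onset_range[0]), float(self.onset_range[1]))
        half = _AUTO_ONSET_SPAN / self.growth_rate
        return (-half, half)

    @property
    def positivity_cutoff(self) -> float:
        """Noise-free level at which accumulators are flagged amyloid-positive."""
        return self.floor + self.positivity_z * self.noise_sd

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


@dataclass
class GroundTruth:
    """Closed-form truth of a generated cohort.

    ``onset`` holds each subject's logistic midpoint tau_i (NaN for
    normative subjects, which are flat at the floor).
    """

    spec: SyntheticCohortSpec
    subject_ids: list[str]
    onset: np.ndarray
    is_normative: np.ndarray
    metadata: dict = field(default_factory=dict)

    def trajectory_value(self, t, tau):
        """Noise-free level of a subject with onset tau at time(s) t."""
        A, K, r = self.spec.floor, self.spec.ceiling, self.spec.growth_rate
        t = np.asarray(t, dtype=float)
        if self.spec.trajectory == "logistic":
            return A + (K - A) / (1.0 + np.exp(-r * (t - tau)))
        return np.clip(A + r * (t - tau), A, K)

    def rate(self, level):
        """Population rate-vs-level function g(S); zero outside [floor, ceiling]."""
        A, K, r = self.spec.floor, self.spec.ceiling, self.spec.growth_rate
        s = np.asarray(level, dtype=float)
        if self.spec.trajectory == "logistic":
            g = r * (s - A) * (K - s) / (K - A)
        else:
            g = np.full_like(s, r)
        return np.where((s >= A) & (s <= K), np.maximum(g, 0.0), 0.0)

    def time_at_level(self, level) -> float:
        """Time (relative to the logistic midpoint) at which the reference
        trajectory attains ``level``; requires floor < level < ceiling."""
        A, K, r = self.spec.floor, self.spec.ceiling, self.spec.growth_rate
        level = float(level)
        if not (A < level < K):
            raise DomainError(f"level {level} outside ({A}, {K})")
        if self.spec.trajectory == "logistic":
            return -(1.0 / r) * math.log((K - A) / (level - A) - 1.0)
        return (level - A) / r

    def oracle_time_to_level(self, anchor: float, level: float) -> float:
        return self.time_at_level(level) - self.time_at_level(anchor)


def oracle_time_to_level(truth: GroundTruth, anchor: float, level: float) -> float:
    """Closed-form years from ``anchor`` to ``level`` on the reference trajectory."""
    return truth.oracle_time_to_level(anchor, level)


def _draw_visit_times(rng, spec: SyntheticCohortSpec) -> np.ndarray:
    v = spec.visits_per_subject
    k = int(v) if isinstance(v, int) else int(rng.integers(v[0], v[1] + 1))
    sp = spec.visit_spacing
    if isinstance(sp, (int, float)):
        gaps = np.full(k - 1, float(sp))
    else:
        gaps = rng.uniform(sp[0], sp[1], size=k - 1)
    return np.r_[0.0, np.cumsum(gaps)]


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an observation table plus its ground truth.

    Reproducible for a fixed seed.  Normative-fraction subjects are flat at
    the floor (onset effectively infinite), always CN and amyloid-negative;
    accumulating subjects get per-visit diagnosis from their noise-free level
    and are flagged amyloid-positive once the noise-free level crosses the
    spec's positivity cutoff.  Measurement noise is additive Gaussian,
    truncated (by redraw) to keep observed SUVR > 0.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_norm = int(round(spec.normative_fraction * n))
    is_norm = np.zeros(n, dtype=bool)
    is_norm[:n_norm] = True

    lo, hi = spec.resolved_onset_range
    onset = np.where(is_norm, np.nan, rng.uniform(lo, hi, size=n))
    subject_ids = [f"S{i:04d}" for i in range(n)]
    sex = rng.choice(["female", "male"], size=n)
    apoe = rng.choice([False, True], size=n)

    truth = GroundTruth(
        spec=spec,
        subject_ids=subject_ids,
        onset=onset,
        is_normative=is_norm,
    )

    cut = spec.positivity_cutoff
    rows = []
    for i in range(n):
        times = _draw_visit_times(rng, spec)
        if is_norm[i]:
            clean = np.full(times.size, spec.floor)
        else:
            clean = truth.trajectory_value(times, onset[i])
        noise = rng.normal(0.0, spec.noise_sd, size=times.size)
        obs = clean + noise
        bad = obs <= 0
        while bad.any():  # truncation: redraw to keep SUVR positive
            obs[bad] = clean[bad] + rng.normal(0.0, spec.noise_sd, size=int(bad.sum()))
            bad = obs <= 0
        for j, t in enumerate(times):
            if is_norm[i]:
                dx, pos = "CN", False
            else:
                lvl = clean[j]
                dx = (
                    "Dementia"
                    if lvl >= spec.dementia_level
                    else "MCI" if lvl >= spec.mci_level else "CN"
                )
                pos = bool(lvl >= cut)
            rows.append(
                (subject_ids[i], float(t), float(obs[j]), sex[i], bool(apoe[i]), dx, pos)
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "visit_time",
            "suvr",
            "sex",
            "apoe4_carrier",
            "diagnosis",
            "amyloid_positive",
        ],
    )
    return validate_table(table), truth


def spec_with_time_shift(
    spec: SyntheticCohortSpec,
    delta_years: float,
    anchor: float,
    level: float,
    seed: int | None = None,
) -> SyntheticCohortSpec:
    """A spec whose oracle time from ``anchor`` to ``level`` is ``delta_years``
    longer than ``spec``'s.

    A pure shift of the onset distribution leaves the autonomous rate-vs-level
    relation - and hence every landmark time - unchanged, so a landmark-time
    shift is injected by rescaling the growth rate: for the logistic,
    T(r) = C / r with C the logit span between the two levels, so
    r' = C / (T(r) + delta).  The onset window is auto-widened with 1/r'
    (default window) so the slower stratum still tiles the level range.
    """
    A, K = spec.floor, spec.ceiling
    if not (A < anchor < level < K):
        raise DomainError("need floor < anchor < level < ceiling")
    if spec.trajectory == "logistic":
        C = math.log((level - A) / (K - level)) - math.log((anchor - A) / (K - anchor))
    else:
        C = level - anchor
    t_base = C / spec.growth_rate
    if t_base + delta_years <= 0:
        raise ValueError("shift would make the landmark time non-positive")
    new_rate = C / (t_base + delta_years)
    kwargs = {"growth_rate": new_rate}
    if spec.onset_range is None:
        kwargs["onset_range"] = None  # auto window rescales with the new rate
    if seed is not None:
        kwargs["seed"] = seed
    return replace(spec, **kwargs)


def write_cohort(
    table: pd.DataFrame, truth: GroundTruth, prefix: str | Path
) -> tuple[Path, Path]:
    """Write the long-format CSV plus a ground-truth JSON next to it."""
    from .cohort import write_long_table

    prefix = Path(prefix)
    table_path = prefix.with_suffix(".csv")
    truth_path = prefix.with_suffix(".truth.json")
    write_long_table(table, table_path)
    payload = {
        "spec": asdict(truth.spec),
        "subject_ids": truth.subject_ids,
        "onset": [None if math.isnan(v) else v for v in truth.onset],
        "is_normative": truth.is_normative.tolist(),
    }
    truth_path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    return table_path, truth_path
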