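"""Pipeline configuration: validated settings shared by the CLI and library."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError


@dataclass
class PipelineConfig:
    """All settings of an end-to-end run, one biomarker per run.

    ``anchor`` is either the string ``"normative"`` (anchor the integration
    at the estimated normative mean, the default) or an explicit SUVR value.
    Landmarks are named extra levels (e.g. diagnostic-group mean SUVRs)
    annotated on the curve.
    """

    biomarker: str = "suvr"
    column_map: dict = field(default_factory=dict)
    select_continuum: bool = True
    # slope settings
    reference: str = "interval_start"
    min_interval: float = 0.25
    slope_scheme: str = "consecutive"
    trim_quantile: float | None = None
    # spline settings
    n_basis: int = 40
    knot_strategy: str = "quantile"
    lam: float | None = None
    smoothing: str = "efs"
    weight_by_interval: bool = False
    # cutoff / anchoring
    z_magnitude: float = 2.0
    anchor: str | float = "normative"
    # integrator settings
    step: float = 0.01
    t_max: float = 40.0
    stall_threshold: float = 1e-5
    extrapolation: str = "clamp"
    # landmarks and stratification
    landmarks: dict = field(default_factory=dict)
    stratify_by: str | None = None
    shared_anchor: bool = True
    bootstrap: int | None = None
    ci_level: float = 0.95
    # bookkeeping
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.reference not in ("interval_start", "interval_midpoint"):
            raise ConfigError(f"invalid reference {self.reference!r}")
        if self.smoothing not in ("efs", "grid"):
            raise ConfigError(f"invalid smoothing {self.smoothing!r}")
        if self.extrapolation not in ("clamp", "linear", "error"):
            raise ConfigError(f"invalid extrapolation {self.extrapolation!r}")
        if not self.min_interval > 0:
            raise ConfigError("min_interval must be > 0")
        if not (self.step > 0 and self.t_max > 0):
            raise ConfigError("step and t_max must be > 0")
        if self.z_magnitude < 0:
            raise ConfigError("z_magnitude must be >= 0")
        if isinstance(self.anchor, str) and self.anchor != "normative":
            raise ConfigError(
                f"anchor must be 'normative' or a number, got {self.anchor!r}"
            )
        if self.stratify_by is not None and self.stratify_by not in (
            "sex",
            "apoe4_carrier",
        ):
            # custom stratification columns are allowed but must be non-empty
            if not str(self.stratify_by).strip():
                raise ConfigError("stratify_by must name a column")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        """Short stable hash identifying the analytic configuration
        (the output location does not affect it)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
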