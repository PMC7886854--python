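"""Run configuration: schema, validation, seeds and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .projection import PROJECTION_DECADES, RCP_IDS
from .sdm_core import ALGORITHM_IDS
from .synthetic_world import DEFAULT_GCM_IDS

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end synthetic run.

    Every stochastic step consumes a named seed from ``seeds`` so reruns
    are byte-identical.
    """

    species: str = "Synthetus exemplaris"
    grid: dict = field(
        default_factory=lambda: {
            "lon_min": 0.0, "lon_max": 6.0, "lat_min": 40.0, "lat_max": 44.0,
            "resolution": 0.1,
        }
    )
    niche: dict = field(
        default_factory=lambda: {
            "mu": {"SBT": 15.0, "SBTrange": 6.0},
            "sigma": {"SBT": 3.0, "SBTrange": 3.0},
            "s_max": 0.9,
        }
    )
    n_occurrences: int = 500
    factor_candidates: list = field(default_factory=lambda: ["SBT", "SBTrange", "SBTvar", "SSS"])
    algorithms: list = field(default_factory=lambda: ["NPPEN", "GLM"])
    hull_quantiles: list = field(default_factory=lambda: [[2.5, 97.5], [5.0, 95.0], [10.0, 90.0]])
    bin_widths: dict = field(default_factory=dict)  # defaults applied downstream
    cv: dict = field(default_factory=lambda: {"n_rep": 10, "frac": 0.7})
    cbi: dict = field(
        default_factory=lambda: {"threshold": 0.5, "window_width": 0.1, "n_windows": 101}
    )
    filters: dict = field(
        default_factory=lambda: {"depth_max": 300.0, "coast_km": 50.0, "depth_cutoff": 1000.0}
    )
    scenarios: dict = field(
        default_factory=lambda: {
            "gcm_ids": list(DEFAULT_GCM_IDS),
            "rcp_ids": list(RCP_IDS),
            "decades": list(PROJECTION_DECADES),
            "bias_scale": 1.0,
        }
    )
    include_coast_candidates: bool = False
    pre_screen: bool = True
    seeds: dict = field(
        default_factory=lambda: {
            "world": 1, "occurrences": 2, "pseudo_absence": 3, "cv": 4, "gcm": 5,
        }
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_occurrences < 1:
            raise ValueError("n_occurrences must be positive")
        for alg in self.algorithms:
            if alg not in ALGORITHM_IDS:
                raise ValueError(f"unknown algorithm {alg!r}; expected one of {ALGORITHM_IDS}")
        for rcp in self.scenarios.get("rcp_ids", []):
            if rcp not in RCP_IDS:
                raise ValueError(f"unknown RCP label {rcp!r}; expected one of {RCP_IDS}")
        for dec in self.scenarios.get("decades", []):
            if dec not in PROJECTION_DECADES:
                raise ValueError(
                    f"unknown decade {dec!r}; expected one of {PROJECTION_DECADES}"
                )
        for q in self.hull_quantiles:
            lo, hi = q
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"invalid hull quantile pair {q}")
        for key in ("world", "occurrences", "pseudo_absence", "cv", "gcm"):
            if key not in self.seeds:
                raise ValueError(f"missing seed {key!r}")
        mu, sigma = self.niche.get("mu", {}), self.niche.get("sigma", {})
        if set(mu) != set(sigma):
            raise ValueError("niche mu and sigma must cover the same factors")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def reseed(self, base_seed: int) -> "RunConfig":
        """Derive all named seeds deterministically from one base seed."""
        cfg = RunConfig(**{**self.to_dict(), "seeds": {
            "world": base_seed,
            "occurrences": base_seed + 1000,
            "pseudo_absence": base_seed + 2000,
            "cv": base_seed + 3000,
            "gcm": base_seed + 4000,
        }})
        return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)
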