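"""Pipeline configuration: YAML-backed, validated on load."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .exposure import SCENARIOS
from .validation import DEFAULT_THRESHOLDS


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs besides the input files.

    Edge lists are the four interior class boundaries for the fixed-bin
    variables; protective distances are metres per habitat class;
    ``buffer_km`` is the population-exposure radius; thresholds are the
    exposed/less-exposed cut points (%) for validation.
    """

    seed: int = 0
    relief_edges: tuple = (2.0, 4.0, 8.0, 12.0)
    wave_edges: tuple = (0.75, 3.0, 18.75, 48.0)
    protective_distances_m: dict = field(
        default_factory=lambda: {"coral_reef": 2000.0, "mangrove": 1000.0, "seagrass": 500.0}
    )
    missing_change_rank: int = 3
    ie_classing: str = "round"
    buffer_km: float = 5.0
    scenarios: tuple = tuple(SCENARIOS)
    thresholds: tuple = DEFAULT_THRESHOLDS
    ln_offset: float = 1.0

    def __post_init__(self):
        self.relief_edges = tuple(float(e) for e in self.relief_edges)
        self.wave_edges = tuple(float(e) for e in self.wave_edges)
        for key in ("relief_edges", "wave_edges"):
            edges = getattr(self, key)
            if len(edges) != 4 or not all(a < b for a, b in zip(edges, edges[1:])):
                raise ValueError(f"config key '{key}': need 4 strictly ascending edges")
        for cls, dist in self.protective_distances_m.items():
            if dist <= 0:
                raise ValueError(
                    f"config key 'protective_distances_m.{cls}': must be > 0"
                )
        if self.missing_change_rank not in (1, 2, 3, 4, 5):
            raise ValueError("config key 'missing_change_rank': must be 1..5")
        if self.ie_classing not in ("round", "quantile"):
            raise ValueError("config key 'ie_classing': must be 'round' or 'quantile'")
        if self.buffer_km <= 0:
            raise ValueError("config key 'buffer_km': must be > 0")
        self.scenarios = tuple(self.scenarios)
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"config key 'scenarios': unknown scenario {s!r}")
        self.thresholds = tuple(float(t) for t in self.thresholds)
        for t in self.thresholds:
            if not 0 < t < 100:
                raise ValueError("config key 'thresholds': values must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["relief_edges"] = list(self.relief_edges)
        d["wave_edges"] = list(self.wave_edges)
        d["scenarios"] = list(self.scenarios)
        d["thresholds"] = list(self.thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
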