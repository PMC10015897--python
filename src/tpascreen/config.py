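"""Run configuration: one JSON-serializable object, one hash, one base seed.

Every pipeline stage draws its parameters (and all randomness) from a
RunConfig; artifacts embed the config hash so any output is traceable to
the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults for every stage; CLI flags override individual fields."""

    seed: int = 0
    # featurization
    radius: int = 4
    min_support: int = 2
    include_mff_moe: bool = True
    # dataset filter / collapse
    lambda_min: float = 600.0
    lambda_max: float = 1100.0
    banned_elements: list[str] = field(default_factory=lambda: ["P", "Si", "I"])
    collapse_policy: str = "max-sigma"
    # evaluation protocol
    n_runs: int = 240
    test_fraction: float = 0.15
    regressor: str = "xgboost"
    # selection
    selection_n_runs: int = 24
    refresh_every: int = 10
    forward_tolerance: float = 1e-3
    selection_max_corr: float = 0.95
    seed_feature: str = "Conju-Max-Distance"
    # generator
    family: str = "mixed"
    n_min: int = 2
    n_max: int = 9
    beta: float = 1.8
    gamma_da: float = 0.5
    sigma_noise: float = 0.3
    n_samples: int = 400

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def hash(self) -> str:
        """Stable short hash: canonical (key-sorted) JSON, sha256, 12 hex chars."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
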