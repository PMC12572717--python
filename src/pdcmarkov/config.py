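"""Run configuration for the command-line pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

_KNOWN_KEYS = {
    "inputs", "simulate", "n_states", "horizon", "model_terms", "knots",
    "hospital_credit", "bootstrap_reps", "seed", "outdir", "profiles",
}
_DEFAULT_TERMS = [
    "rcs4:age", "rcs4:chads_vasc", "rcs4:days_w1", "rcs4:days_w2",
    "rcs4:days_w3 * time", "rcs4:days_w4 * time", "prev:categorical",
]
# covered-day predictors pile up at 90 and the integer risk score has
# few distinct values, so quantile knots degenerate; fixed knots (outer
# knot at 89 covered days) are the default
_DEFAULT_KNOTS = {
    **{f"days_w{k}": [30.0, 60.0, 80.0, 89.0] for k in range(1, 5)},
    "chads_vasc": [2.0, 4.0, 5.0, 7.0],
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (flat YAML key/values)."""

    inputs: dict | None = None        # dispensing/hospital/baseline paths
    simulate: dict | None = None      # {n: int, seed: int}
    n_states: int = 10
    horizon: int = 20
    model_terms: list = field(default_factory=lambda: list(_DEFAULT_TERMS))
    knots: dict = field(default_factory=lambda: dict(_DEFAULT_KNOTS))
    hospital_credit: str = "union"
    bootstrap_reps: int = 100
    seed: int = 0
    outdir: str = "out"
    profiles: list = field(default_factory=list)

    def __post_init__(self):
        if self.hospital_credit not in ("union", "sum"):
            raise ValueError("hospital_credit must be union|sum")
        if not 2 <= self.n_states <= 10:
            raise ValueError("n_states must be in 2..10")
        if self.horizon < 5:
            raise ValueError("horizon must be >= 5")
        if self.inputs is not None:
            missing = {"dispensing", "hospital", "baseline"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs missing keys {sorted(missing)}")
        if self.simulate is not None and "n" not in self.simulate:
            raise ValueError("simulate block needs 'n'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def knots_arrays(self) -> dict:
        return {k: np.asarray(v, float) for k, v in self.knots.items()}

    def out(self) -> Path:
        p = Path(self.outdir)
        p.mkdir(parents=True, exist_ok=True)
        return p
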