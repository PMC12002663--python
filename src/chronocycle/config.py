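"""Experiment configuration: a fully serialisable description of one
simulation campaign, with deterministic per-run seed derivation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

EXPERIMENTS = ("simulate", "entrainment", "cmi", "kl001_sweep", "growth",
               "phases", "custom")

#: desk-scale profile: every headline experiment finishes in minutes on one
#: CPU; the full-scale profile runs 100-run ensembles.
PROFILES = {
    "desk": {"n_runs": 20, "max_population": 128},
    "full": {"n_runs": 100, "max_population": 256},
}


@dataclass
class ExperimentConfig:
    experiment: str = "cmi"
    model_id: int = 2
    overrides: dict = field(default_factory=dict)
    C1: float = 0.55
    C2: float = 0.0
    kl001_factors: tuple = (1.0,)
    autonomous_TCC: float = 20.0
    clock_period: float = 24.0
    noise_mode: str = "constant"
    noise_level: float = 0.065
    clock_noise_scale: float = 1.0
    omega: float = 100.0
    dt: float = 0.01
    record_every: int = 10
    n_ancestors: int = 8
    stop: dict = field(default_factory=lambda: {"max_population": 128})
    n_runs: int = 20
    base_seed: int = 0
    ancestor_mode: str = "random_times"
    out_dir: str = "chronocycle_out"
    profile: str = "desk"

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; one of {EXPERIMENTS}")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    def with_profile(self, profile: str) -> "ExperimentConfig":
        from dataclasses import replace

        p = PROFILES[profile]
        stop = dict(self.stop)
        if "max_population" in stop:
            stop["max_population"] = p["max_population"]
        return replace(self, profile=profile, n_runs=p["n_runs"], stop=stop)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kl001_factors"] = list(self.kl001_factors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "kl001_factors" in d:
            d["kl001_factors"] = tuple(d["kl001_factors"])
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_seed(base_seed: int, run_index: int) -> int:
    """Stable per-run seed; independent of scheduling order."""
    ss = np.random.SeedSequence([int(base_seed), int(run_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))
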