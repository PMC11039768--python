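"""Run configuration: one serializable object holding every tunable."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import yaml

from .gimme import SearchConfig
from .simulate import OutcomeCoeffs, SimulationParams


@dataclass(frozen=True)
class StabilityConfig:
    alpha_step: float = 0.01
    n_reps: int = 100
    benchmark_fraction: float = 0.20
    stability_threshold: float = 0.20

    def alpha_grid(self):
        import numpy as np

        return np.arange(self.alpha_step, 1.0 + 1e-9, self.alpha_step)


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; serializes to/from YAML and is written
    alongside every result directory."""

    seed: int = 0
    tr_seconds: float = 0.72
    density_mode: str = "possible"
    eligibility_threshold: float = 0.25
    outcome_alpha: float = 0.05
    # covariate codings, recorded for reproducibility
    sex_coding: dict = field(default_factory=lambda: {"male": 1, "female": 0})
    treatment_coding: dict = field(
        default_factory=lambda: {"patch_plus_ecig": 1, "patch_only": 0}
    )
    simulation: SimulationParams = field(default_factory=SimulationParams)
    search: SearchConfig = field(default_factory=SearchConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)

    def to_yaml(self, path) -> None:
        blob = dataclasses.asdict(self)
        # tuples -> lists for clean YAML
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, list):
                return [clean(v) for v in obj]
            return obj

        FsPath(path).write_text(yaml.safe_dump(clean(blob), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        blob = yaml.safe_load(FsPath(path).read_text()) or {}
        return cls.from_dict(blob)

    @classmethod
    def from_dict(cls, blob: dict) -> "RunConfig":
        blob = dict(blob)
        sim = dict(blob.pop("simulation", {}))
        if "outcome_coeffs" in sim:
            sim["outcome_coeffs"] = OutcomeCoeffs(**sim["outcome_coeffs"])
        for key in ("ar_range", "group_range", "subgroup_range", "individual_range",
                    "subgroup_sizes", "subgroup_n_paths"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        search = SearchConfig(**blob.pop("search", {}))
        stability = StabilityConfig(**blob.pop("stability", {}))
        return cls(
            simulation=SimulationParams(**sim), search=search, stability=stability, **blob
        )

    def with_seed(self, seed: int) -> "RunConfig":
        sim = dataclasses.replace(self.simulation, seed=seed)
        return dataclasses.replace(self, seed=seed, simulation=sim)
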