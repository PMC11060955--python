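"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from tempro.matrix import TISSUES

DEFAULT_DAYS = (0, 3, 7, 10, 14, 21)


def default_archetypes(n_clusters: int = 7, n_timepoints: int = 5) -> np.ndarray:
    """Row-standardized temporal archetype profiles (cluster × timepoint).

    The default seven shapes mirror the patterns a growing-tumor time course
    exhibits once the pre-implantation point is excluded: an early peak with
    decline, a rise/dip/rise, mid-course peaks, late monotone rises, a late
    jump, and a V-shaped dip.  Any set of mutually distinguishable profiles
    works for recovery tests; these are peak functions shifted across the
    time axis.
    """
    if n_clusters < 1 or n_timepoints < 1:
        raise ValueError("need n_clusters >= 1 and n_timepoints >= 1")
    if n_timepoints == 1:
        # degenerate single-timepoint design: no temporal structure to plant
        return np.zeros((n_clusters, 1))
    base = [
        [2.0, 1.0, 0.0, -1.0, -2.0],     # early high, steady decline
        [-1.0, 1.0, -1.0, 0.0, 1.0],     # rise, dip, late rise
        [-1.0, 0.0, 2.0, 0.0, -1.0],     # mid-course peak
        [-1.0, -0.5, 0.0, 2.0, 0.0],     # late-mid peak
        [-2.0, -1.0, 0.0, 1.0, 2.0],     # steady rise
        [-1.0, -1.0, -1.0, 0.0, 2.5],    # late jump
        [1.5, 0.0, -1.5, 0.0, 1.5],      # V shape
    ]
    profiles = []
    for i in range(n_clusters):
        if n_timepoints == 5 and i < len(base):
            p = np.asarray(base[i], dtype=float)
        else:
            # Gaussian bump sliding across the axis; guarantees distinct shapes.
            t = np.arange(n_timepoints, dtype=float)
            center = i * (n_timepoints - 1) / max(n_clusters - 1, 1)
            p = np.exp(-0.5 * ((t - center) / (0.18 * n_timepoints)) ** 2)
        p = (p - p.mean()) / p.std(ddof=1)
        profiles.append(p)
    return np.vstack(profiles)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study generator.

    Defaults emulate the design of the study: four tissues (tumor and three
    immune organs), six days spanning three weeks, three replicates, seven
    temporal expression patterns, log-normal intensities spanning several
    orders of magnitude, and per-sample missingness of peptide observations.
    """

    n_genes: int = 1000
    tissues: tuple[str, ...] = TISSUES
    days: tuple[int, ...] = DEFAULT_DAYS
    n_replicates: int = 3
    n_temporal_clusters: int = 7
    cluster_archetypes: np.ndarray | None = None
    archetypes_exclude_day0: bool = True
    tissue_unique_fraction: float = 0.05
    dropout_rate: float = 0.2
    intensity_log_sd: float = 0.2
    n_celltypes: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    @property
    def archetype_days(self) -> tuple[int, ...]:
        """Days over which archetypes are defined (D0 excluded by default)."""
        if self.archetypes_exclude_day0:
            return tuple(d for d in self.days if d != min(self.days))
        return tuple(self.days)

    def archetypes(self) -> np.ndarray:
        if self.cluster_archetypes is not None:
            return np.asarray(self.cluster_archetypes, dtype=float)
        return default_archetypes(self.n_temporal_clusters, len(self.archetype_days))

    def validate(self) -> None:
        for name in ("n_genes", "n_replicates", "n_temporal_clusters", "n_celltypes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.tissues) < 1 or len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissues must be non-empty and unique")
        if len(self.days) < 2 or len(set(self.days)) != len(self.days):
            raise ValueError("days must be >= 2 distinct integers")
        for name in ("tissue_unique_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.intensity_log_sd < 0:
            raise ValueError("intensity_log_sd must be >= 0")
        arch = self.archetypes()
        n_tp = len(self.archetype_days)
        if arch.shape != (self.n_temporal_clusters, n_tp):
            raise ValueError(
                f"archetype matrix must be {self.n_temporal_clusters} x {n_tp}, "
                f"got {arch.shape}"
            )


# ---------------------------------------------------------------------------
# Pipeline configuration

PIPELINE_STAGES = (
    "simulate",
    "filter",
    "quantify",
    "de",
    "cluster",
    "modules",
    "deconv",
    "enrich",
    "targets",
)

_DEFAULT_PARAMS: dict[str, dict] = {
    "simulate": {"n_genes": 1000},
    "filter": {},
    "quantify": {"min_len": 7, "max_len": 30, "missed_cleavages": 0},
    "de": {"fc_threshold": 2.0, "alpha": 0.05, "pseudo": 0.1},
    "cluster": {"k": 7, "m": None, "exclude_day0": True},
    "modules": {"min_module_size": 50, "merge_cut_height": 0.3,
                "r2_target": 0.8, "trait_threshold": 0.6},
    "deconv": {"n_permutations": 1000},
    "enrich": {"alpha": 0.05},
    "targets": {"alpha": 0.05, "ratio": 1.2},
}


@dataclass
class PipelineConfig:
    """End-to-end run configuration: enabled stages, their parameters, seeds.

    Every source of randomness flows from ``seed`` (split per stage).  Unknown
    stage names or parameter keys are rejected so that a config file always
    round-trips losslessly.
    """

    stages: tuple[str, ...] = PIPELINE_STAGES
    params: dict = field(default_factory=dict)
    seed: int = 0
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(PIPELINE_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage, p in self.params.items():
            if stage not in PIPELINE_STAGES:
                raise ValueError(f"parameters for unknown stage {stage!r}")
            bad = set(p) - set(_DEFAULT_PARAMS[stage])
            if bad:
                raise ValueError(f"unknown keys for stage {stage!r}: {sorted(bad)}")

    def stage_params(self, stage: str) -> dict:
        merged = dict(_DEFAULT_PARAMS[stage])
        merged.update(self.params.get(stage, {}))
        return merged

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed (< 2^31)."""
        return (self.seed * 1009 + PIPELINE_STAGES.index(stage) + 1) % (2**31 - 1)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {"stages": list(self.stages), "params": self.params, "seed": self.seed}
        if self.simulation is not None:
            sim = asdict(self.simulation)
            if sim["cluster_archetypes"] is not None:
                sim["cluster_archetypes"] = np.asarray(sim["cluster_archetypes"]).tolist()
            sim["tissues"] = list(sim["tissues"])
            sim["days"] = list(sim["days"])
            d["simulation"] = sim
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {"stages", "params", "seed", "simulation"}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        sim = d.get("simulation")
        if sim is not None:
            sim = dict(sim)
            bad = set(sim) - {f.name for f in dc_fields(SimulationConfig)}
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            for key in ("tissues", "days"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if sim.get("cluster_archetypes") is not None:
                sim["cluster_archetypes"] = np.asarray(sim["cluster_archetypes"], dtype=float)
            sim = SimulationConfig(**sim)
        return cls(
            stages=tuple(d.get("stages", PIPELINE_STAGES)),
            params=d.get("params", {}),
            seed=int(d.get("seed", 0)),
            simulation=sim,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
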