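"""Run configuration for the droplet-culture simulator and analysis pipeline.

Target naming: the four telomerase (hTERT) splice variants are labelled
``a+/b+`` (full length), ``a-/b+``, ``a+/b-`` and ``a-/b-`` for the alpha
and/or beta deletions; ``hTR`` is the telomerase RNA component and ``GAPDH``
the housekeeping control used to gate live cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import yaml

from .errors import ConfigError

VARIANTS: tuple[str, ...] = ("a+/b+", "a-/b+", "a+/b-", "a-/b-")
ALPHA_MINUS: tuple[str, ...] = ("a-/b+", "a-/b-")
TARGETS: tuple[str, ...] = VARIANTS + ("hTR", "GAPDH")


def _default_burst_rates() -> dict[str, float]:
    # Bursts per cell per day.  Relative weights follow the measured per-cell
    # copy-number ordering (a+/b- dominant at ~12.5 copies/cell, a-/b-
    # intermediate, the two others rare); the total keeps the instantaneous
    # bursting fraction below 25% of cells.
    return {"a+/b+": 0.01, "a-/b+": 0.01, "a+/b-": 0.20, "a-/b-": 0.02}


@dataclass
class CurcuminConfig:
    """Sub-lethal curcumin exposure: constitutive alpha-minus upregulation
    from ``onset_day`` onwards plus desynchronised division."""

    enabled: bool = False
    alpha_minus_fold: float = 300.0
    division_cv_multiplier: float = 3.0
    growth_rate_multiplier: float = 1.0
    onset_day: int = 2


@dataclass
class SimConfig:
    """Ground-truth generator settings.

    ``seed`` is mandatory: every stochastic operation derives its stream from
    it, so identical configs give bit-identical output.
    """

    seed: int
    droplet_volume_nl: float = 5.9
    mean_cells_per_droplet: float = 0.1
    n_droplets: int = 2000
    days: int = 2
    doubling_time_h: float = 20.0
    division_cv: float = 0.1
    capacity_cells_per_nl: float = 2.5
    variant_burst_rates: Mapping[str, float] = field(default_factory=_default_burst_rates)
    burst_size_mean: float = 70.0
    burst_size_shape: float = 10.0
    baseline_mean: float = 0.6
    htr_mean: float = 2000.0
    htr_cell_cv: float = 0.5
    gapdh_mean: float = 1000.0
    gapdh_cell_cv: float = 0.3
    curcumin: CurcuminConfig = field(default_factory=CurcuminConfig)
    detection_prob: float = 0.5
    area_per_molecule: float = 100.0
    area_noise_cv: float = 0.3

    def __post_init__(self):
        if isinstance(self.curcumin, dict):
            self.curcumin = _build(CurcuminConfig, self.curcumin, "curcumin")
        self.validate()

    def validate(self) -> None:
        problems = []
        if self.seed is None or int(self.seed) < 0:
            problems.append("seed must be a non-negative integer")
        if not 0.0 <= self.mean_cells_per_droplet < 1.0:
            problems.append("mean_cells_per_droplet must be in [0, 1)")
        if self.n_droplets < 0:
            problems.append("n_droplets must be >= 0")
        if self.droplet_volume_nl <= 0:
            problems.append("droplet_volume_nl must be > 0")
        if not 0.0 < self.detection_prob <= 1.0:
            problems.append("detection_prob must be in (0, 1]")
        if set(self.variant_burst_rates) != set(VARIANTS):
            problems.append(f"variant_burst_rates must have keys {VARIANTS}")
        elif any(r < 0 for r in self.variant_burst_rates.values()):
            problems.append("variant_burst_rates must be >= 0")
        for name in ("days", "doubling_time_h", "division_cv", "capacity_cells_per_nl",
                     "burst_size_mean", "burst_size_shape", "baseline_mean", "htr_mean",
                     "htr_cell_cv", "gapdh_mean", "gapdh_cell_cv", "area_per_molecule",
                     "area_noise_cv"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class RunConfig:
    """Pipeline settings: simulator config plus analysis options.

    Significance defaults follow the published rule: Mann-Whitney
    ``P <= 0.01`` together with a fold change above 2 or below 0.5.
    """

    sim: SimConfig
    out_dir: str = "emulsim_out"
    sample_days: list[int] | None = None
    dip_bootstrap: int = 2000
    day_pair: tuple[int, int] = (1, 2)
    p_threshold: float = 0.01
    fc_upper: float = 2.0
    fc_lower: float = 0.5
    lambda_per_cell: Mapping[str, float] = field(
        default_factory=lambda: {"a+/b-": 12.5, "a-/b-": 1.4, "a-/b+": 0.16, "a+/b+": 0.19}
    )
    dilution_steps: int = 9
    dilution_reactions: int = 18

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = _build(SimConfig, self.sim, "sim")
        if self.dip_bootstrap < 100:
            raise ConfigError("dip_bootstrap must be >= 100")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must be in (0, 1)")
        if isinstance(self.day_pair, list):
            self.day_pair = tuple(self.day_pair)


def _build(cls, data: Mapping, where: str):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid {where} section: {exc}") from exc


def load_sim_config(path) -> SimConfig:
    """Read a :class:`SimConfig` from YAML, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return _build(SimConfig, data, "sim config")


def load_run_config(path) -> RunConfig:
    """Read a :class:`RunConfig` from YAML, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return _build(RunConfig, data, "run config")


def config_to_dict(cfg) -> dict:
    """Plain-dict view of a config dataclass (for manifests and hashing)."""
    d = asdict(cfg)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    return clean(d)
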