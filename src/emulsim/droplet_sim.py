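"""Synthetic droplet single-cell culture with ground truth.

The generator emulates the experimental chain: Poisson-dilute encapsulation
of lymphoblasts into nanolitre culture droplets, colony growth limited by the
droplet's nutrient carrying capacity, bursty transcription of one dominant
hTERT splice variant per cell alongside stable high-copy hTR and GAPDH,
optional sub-lethal curcumin exposure (constitutive alpha-minus variant
upregulation and desynchronised division), and finally an RT-PCR /
capillary-electrophoresis readout in which each molecule is detected with
fixed probability and detected molecules produce noisy fragment peak areas.

Every droplet's true state (cell counts, per-cell dominant variant, molecule
counts) is retained so analysis results can be checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ALPHA_MINUS, SimConfig, TARGETS, VARIANTS
from .errors import ConfigError

__all__ = [
    "DropletColony",
    "encapsulate",
    "effective_concentration",
    "grow",
    "transcribe",
    "readout",
    "simulate_dilution_series",
    "simulate_experiment",
]

#: fraction of cells surviving each day once a colony has exhausted nutrients
_DECLINE_FACTOR = 0.6


@dataclass
class DropletColony:
    """One droplet's ground truth at a given day."""

    droplet_id: int
    founding_cells: int
    day: int
    cell_count: int
    per_cell_variant: list[str]
    # burst state is set at cell birth and inherited: transcriptional bursts
    # outlast the short culture window, which is what sustains abundance
    # bimodality through colony growth
    per_cell_bursting: list[bool] = field(default_factory=list)
    molecule_counts: dict[str, int] = field(default_factory=dict)
    viable: bool = True
    capacity_day: int | None = None
    # absolute scheduled division time (hours) per live cell
    _division_times: list[float] = field(default_factory=list, repr=False)


def effective_concentration(droplet_volume_nl: float, cells: int = 1) -> float:
    """Bulk-culture cell concentration (cells/ml) equivalent to ``cells``
    in one droplet of the given volume.

    One cell in a 5.9 nl droplet corresponds to ~170,000 cells/ml; the
    concentration depends only on droplet volume, not on how dilute the
    cell suspension was.
    """
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    return cells * 1e6 / droplet_volume_nl


def _generation_time(config: SimConfig, rng, size: int) -> np.ndarray:
    mean = config.doubling_time_h
    cv = config.division_cv
    if config.curcumin.enabled:
        mean = mean / config.curcumin.growth_rate_multiplier
        cv = cv * config.curcumin.division_cv_multiplier
    if cv <= 0:
        return np.full(size, mean)
    g = rng.normal(mean, cv * mean, size)
    return np.maximum(g, 0.1 * mean)


def _draw_variants(config: SimConfig, rng, size: int) -> list[str]:
    rates = np.array([config.variant_burst_rates[v] for v in VARIANTS], dtype=float)
    total = rates.sum()
    p = rates / total if total > 0 else np.full(len(VARIANTS), 1.0 / len(VARIANTS))
    idx = rng.choice(len(VARIANTS), size=size, p=p)
    return [VARIANTS[i] for i in idx]


def encapsulate(config: SimConfig, rng=None) -> list[DropletColony]:
    """Load cells into droplets: founding cells are i.i.d. Poisson with the
    configured mean occupancy (<1 to minimise co-encapsulation).  Empty
    droplets are retained with ``founding_cells = 0``."""
    if config.n_droplets <= 0:
        raise ConfigError("encapsulation requires n_droplets > 0")
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    founders = rng.poisson(config.mean_cells_per_droplet, config.n_droplets)
    p_on = 1.0 - math.exp(-float(sum(config.variant_burst_rates.values())))
    colonies = []
    for i, k in enumerate(founders):
        k = int(k)
        variants = _draw_variants(config, rng, k) if k else []
        bursting = list(rng.random(k) < p_on) if k else []
        gens = _generation_time(config, rng, k) if k else np.empty(0)
        colonies.append(
            DropletColony(
                droplet_id=i,
                founding_cells=k,
                day=0,
                cell_count=k,
                per_cell_variant=variants,
                per_cell_bursting=bursting,
                _division_times=list(gens),
            )
        )
    return colonies


def _capacity(config: SimConfig) -> int:
    return max(1, math.floor(config.capacity_cells_per_nl * config.droplet_volume_nl))


def grow(colonies: list[DropletColony], config: SimConfig, rng=None) -> list[DropletColony]:
    """Advance every colony by one day.

    Each cell divides when its sampled generation time elapses (mean
    ``doubling_time_h``, coefficient of variation ``division_cv``; daughters
    inherit the mother's dominant variant and burst state).  Burst states
    switch on slowly: each day an off cell ignites its dominant variant with
    probability ``1 - exp(-sum(rates))``, and stays on for the remainder of
    the short culture window, so the high-abundance colony population grows
    from under 25% of single cells at encapsulation towards a balanced
    mixture by day 2.  Once a colony has grown to the droplet's carrying
    capacity (``capacity_cells_per_nl x volume``) it stops dividing; from the
    next day it is flagged non-viable and declines as nutrient exhaustion
    kills cells.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed + 1)
    cap = _capacity(config)
    p_ignite = 1.0 - math.exp(-float(sum(config.variant_burst_rates.values())))
    for col in colonies:
        t_end = (col.day + 1) * 24.0
        col.day += 1
        if col.cell_count == 0:
            continue
        if col.capacity_day is not None and col.capacity_day < col.day:
            # starving since a previous day: no divisions, cells die off
            col.viable = False
            keep = math.floor(col.cell_count * _DECLINE_FACTOR)
            col.cell_count = keep
            col.per_cell_variant = col.per_cell_variant[:keep]
            col.per_cell_bursting = col.per_cell_bursting[:keep]
            col._division_times = col._division_times[:keep]
            continue
        while col.cell_count < cap:
            tmin = min(col._division_times)
            if tmin > t_end:
                break
            i = col._division_times.index(tmin)
            gens = _generation_time(config, rng, 2)
            col._division_times[i] = tmin + gens[0]
            col._division_times.append(tmin + gens[1])
            col.per_cell_variant.append(col.per_cell_variant[i])
            col.per_cell_bursting.append(col.per_cell_bursting[i])
            col.cell_count += 1
        if col.cell_count >= cap and col.capacity_day is None:
            col.capacity_day = col.day
        if p_ignite > 0:
            for ci in range(col.cell_count):
                if not col.per_cell_bursting[ci] and rng.random() < p_ignite:
                    col.per_cell_bursting[ci] = True
    return colonies


def _baseline_means(config: SimConfig) -> dict[str, float]:
    """Per-variant leaky transcription: ``baseline_mean`` molecules per cell
    in total, split across variants in proportion to their burst rates (a
    variant that bursts often also leaks more)."""
    rates = config.variant_burst_rates
    total = float(sum(rates.values()))
    if total <= 0:
        return {v: config.baseline_mean / len(VARIANTS) for v in VARIANTS}
    return {v: config.baseline_mean * rates[v] / total for v in VARIANTS}


def expected_variant_mean(config: SimConfig, variant: str, day: int = 0) -> float:
    """Expected untreated per-cell molecule count of one splice variant at a
    given culture day: baseline leakage plus the burst contribution
    ``P(cell is burst-on by that day) x burst size``.  Burst states ignite at
    the total burst rate and persist, so the on-fraction is
    ``1 - exp(-R * (day + 1))``."""
    base = _baseline_means(config)[variant]
    rates = config.variant_burst_rates
    total = float(sum(rates.values()))
    if total <= 0:
        return base
    p_on = 1.0 - math.exp(-total * (day + 1))
    p_v = (rates[variant] / total) * p_on
    return base + p_v * config.burst_size_mean


def _nb_draw(rng, mean: float, shape: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.negative_binomial(shape, shape / (shape + mean)))


def transcribe(colonies: list[DropletColony], config: SimConfig, rng=None) -> list[DropletColony]:
    """Draw molecule counts for every colony at its current day.

    A cell in the high-burst state (set at birth with the competing-risk
    probability ``1 - exp(-sum(rates))``, inherited through division)
    expresses its dominant variant at a negative-binomial burst size (mean
    ``burst_size_mean``, shape ``burst_size_shape``); otherwise variants leak
    a few molecules (Poisson, ``baseline_mean`` per cell in total, split in
    proportion to the burst rates).  At most one variant is
    therefore in the high state per cell at any sampling time.  hTR and GAPDH
    are high-copy and independent of hTERT: per-cell Poisson around a
    lognormal cell-to-cell mean.

    With curcumin enabled, from ``onset_day`` both alpha-minus variants
    switch to constitutive expression in every cell, at ``alpha_minus_fold x``
    their untreated per-cell mean on the day before onset — the bursty on/off
    pattern is replaced by uniformly high output, which removes the
    low-abundance colony population and makes the measured day-to-day fold
    change track ``alpha_minus_fold``.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed + 2)
    curc = config.curcumin.enabled
    pre_onset = max(0, config.curcumin.onset_day - 1)
    induced = {
        v: config.curcumin.alpha_minus_fold * expected_variant_mean(config, v, pre_onset)
        for v in ALPHA_MINUS
    }
    baseline = _baseline_means(config)
    shape = config.burst_size_shape
    for col in colonies:
        counts = {t: 0 for t in TARGETS}
        ncells = col.cell_count
        if ncells > 0:
            amplified = curc and col.day >= config.curcumin.onset_day
            for ci in range(ncells):
                dom = col.per_cell_variant[ci]
                bursting = col.per_cell_bursting[ci]
                for v in VARIANTS:
                    if amplified and v in ALPHA_MINUS:
                        counts[v] += _nb_draw(rng, induced[v], shape)
                    elif v == dom and bursting:
                        counts[v] += _nb_draw(rng, config.burst_size_mean, shape)
                    elif baseline[v] > 0:
                        counts[v] += int(rng.poisson(baseline[v]))
            for name, mean, cv in (
                ("hTR", config.htr_mean, config.htr_cell_cv),
                ("GAPDH", config.gapdh_mean, config.gapdh_cell_cv),
            ):
                if cv > 0:
                    s = math.sqrt(math.log1p(cv * cv))
                    cell_means = mean * rng.lognormal(-0.5 * s * s, s, ncells)
                else:
                    cell_means = np.full(ncells, mean)
                counts[name] = int(rng.poisson(cell_means).sum())
        col.molecule_counts = counts
    return colonies


def readout(
    colonies: list[DropletColony],
    config: SimConfig,
    target_map,
    rng=None,
    condition: str = "control",
) -> pd.DataFrame:
    """CE fragment-analysis readout of whole colonies.

    Each molecule is reverse-transcribed and detected with probability
    ``detection_prob`` (binomial thinning); detected molecules of a target
    yield one fragment peak whose area is ``detected x area_per_molecule``
    with multiplicative lognormal noise (CV ``area_noise_cv``, unit mean).
    A target is called positive iff at least one molecule is detected.  One
    ROX size-standard row is emitted per sample so every assayed droplet
    appears in the table even when no target amplified.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed + 3)
    if config.area_noise_cv > 0:
        s = math.sqrt(math.log1p(config.area_noise_cv ** 2))
    else:
        s = 0.0
    rows = []
    for col in colonies:
        sample_id = f"d{col.droplet_id:05d}_day{col.day}"
        rows.append(
            {
                "sample_id": sample_id,
                "day": col.day,
                "condition": condition,
                "cells": col.cell_count,
                "dye": target_map.size_standard_dye,
                "size_bp": 500.0,
                "height": 1000.0,
                "area": 10000.0,
                "target": "size-standard",
            }
        )
        for target in TARGETS:
            mol = col.molecule_counts.get(target, 0)
            if mol <= 0:
                continue
            detected = int(rng.binomial(mol, config.detection_prob))
            if detected == 0:
                continue
            noise = rng.lognormal(-0.5 * s * s, s) if s > 0 else 1.0
            area = detected * config.area_per_molecule * noise
            dye, size_bp, _ = target_map.entry(target)
            rows.append(
                {
                    "sample_id": sample_id,
                    "day": col.day,
                    "condition": condition,
                    "cells": col.cell_count,
                    "dye": dye,
                    "size_bp": float(size_bp),
                    "height": area / 10.0,
                    "area": float(area),
                    "target": target,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "day", "condition", "cells", "dye", "size_bp",
                 "height", "area", "target"],
    )


def simulate_dilution_series(
    lambda_per_cell: float,
    dilutions,
    n_reactions: int,
    rng=None,
):
    """Simulate a limiting-dilution digital RT-PCR series.

    At dilution ``d`` of a one-cell-equivalent lysate carrying
    ``lambda_per_cell`` copies, the number of positive reactions among
    ``n_reactions`` is binomial with success probability ``1 - exp(-lambda*d)``
    (the Poisson zero-class).
    """
    from .digital_quant import DilutionSeries

    dilutions = np.asarray(dilutions, dtype=float)
    if dilutions.size == 0:
        raise ConfigError("dilution list must not be empty")
    if np.any((dilutions <= 0) | (dilutions > 1)):
        raise ConfigError("dilution factors must lie in (0, 1]")
    if n_reactions < 1:
        raise ConfigError("n_reactions must be >= 1")
    if lambda_per_cell < 0:
        raise ConfigError("lambda_per_cell must be >= 0")
    rng = np.random.default_rng(rng)
    p = 1.0 - np.exp(-lambda_per_cell * dilutions)
    k = rng.binomial(n_reactions, p)
    return DilutionSeries(
        target="sim",
        d=dilutions,
        k=k.astype(int),
        n=np.full(dilutions.size, int(n_reactions)),
    )


def ground_truth_frame(colonies: list[DropletColony], condition: str = "control") -> pd.DataFrame:
    """Tabulate colony ground truth (one row per assayed droplet)."""
    rows = []
    for col in colonies:
        row = {
            "droplet_id": col.droplet_id,
            "day": col.day,
            "condition": condition,
            "founding_cells": col.founding_cells,
            "cell_count": col.cell_count,
            "viable": col.viable,
        }
        for t in TARGETS:
            row[f"mol_{t}"] = col.molecule_counts.get(t, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_experiment(
    config: SimConfig,
    target_map=None,
    sample_days=None,
    condition: str = "control",
    rng=None,
):
    """Full generator run: encapsulate, grow day by day, and destructively
    harvest an equal share of droplets for readout on each sampling day.

    Returns ``(peaks, truth)``: the CE peak table over all harvested samples
    and the matching ground-truth table.
    """
    from .fragment_io import default_target_map

    if target_map is None:
        target_map = default_target_map()
    if sample_days is None:
        sample_days = list(range(config.days + 1))
    sample_days = sorted(set(int(d) for d in sample_days))
    if sample_days and sample_days[-1] > config.days:
        raise ConfigError("sample_days beyond configured number of days")
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    colonies = encapsulate(config, rng)
    harvest_day = np.array([sample_days[i % len(sample_days)] for i in range(len(colonies))])
    peaks_parts = []
    truth_parts = []
    for day in range(0, config.days + 1):
        if day > 0:
            alive = [c for c in colonies if harvest_day[c.droplet_id] >= day]
            grow(alive, config, rng)
        if day in sample_days:
            batch = [c for c in colonies if harvest_day[c.droplet_id] == day]
            transcribe(batch, config, rng)
            peaks_parts.append(readout(batch, config, target_map, rng, condition))
            truth_parts.append(ground_truth_frame(batch, condition))
    peaks = pd.concat(peaks_parts, ignore_index=True) if peaks_parts else pd.DataFrame()
    truth = pd.concat(truth_parts, ignore_index=True) if truth_parts else pd.DataFrame()
    return peaks, truth
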