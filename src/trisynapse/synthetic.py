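"""Synthetic fixtures with planted, recoverable structure.

Generators for the statistical shapes the analyses assume: planted-partition
graphs (modular weighted directed, optionally signed) for the community
pipeline, Poisson spike rasters for rate analyses, and response tables with
planted target populations for the learning readout. All generators are
seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simulate import SpikeRaster


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """K equally-sized modules with dense within- and sparse between-module
    connectivity."""

    n_nodes: int = 200
    n_modules: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    weight_in: float = 1.0
    weight_out: float = 1.0
    weight_sd: float = 0.1
    directed: bool = True
    inhibitory_fraction: float = 0.0  # fraction of nodes with negative out-edges
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_in <= self.p_out:
            raise ValueError("need p_in > p_out for detectable structure")
        if self.n_nodes < self.n_modules:
            raise ValueError("need at least one node per module")


def make_planted_partition(spec: PlantedPartitionSpec
                           ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sample a planted-partition graph; returns (matrix, true labels)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    labels = np.sort(rng.permutation(np.repeat(
        np.arange(spec.n_modules), int(np.ceil(n / spec.n_modules)))[:n]))
    same = labels[:, None] == labels[None, :]
    p = np.where(same, spec.p_in, spec.p_out)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    if not spec.directed:
        mask = np.triu(mask)
        mask = mask | mask.T
    mean = np.where(same, spec.weight_in, spec.weight_out)
    w = np.abs(rng.normal(mean, spec.weight_sd))
    if spec.inhibitory_fraction > 0:
        inh = rng.random(n) < spec.inhibitory_fraction
        w = np.where(inh[:, None], -w, w)
    W = sp.csr_matrix(np.where(mask, w, 0.0))
    return W, labels


def make_raster(rates: np.ndarray, duration: float, seed: int = 0,
                t_start: float = 0.0) -> SpikeRaster:
    """Homogeneous Poisson spike trains at the given per-neuron rates (Hz)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates * duration / 1000.0)
    neurons = np.repeat(np.arange(rates.size), counts)
    times = t_start + rng.uniform(0.0, duration, size=int(counts.sum()))
    return SpikeRaster(neurons, times, t_start, t_start + duration, rates.size)


@dataclass(frozen=True)
class SyntheticResponseSpec:
    """Response tables with planted target populations.

    Planted targets multiply their untrained response by ``effect_size``
    after training; everything else fluctuates with lognormal noise of
    sigma ``noise_sd``. The two patterns' planted target sets overlap by
    ``target_overlap`` (fraction of n_targets).
    """

    neurons_per_region: int = 400
    n_targets: int = 50
    effect_size: float = 5.0
    noise_sd: float = 0.2
    target_overlap: float = 0.0
    baseline_rate: float = 2.0
    regions: tuple[str, ...] = ("DG", "CA3", "CA1")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 1.0:
            raise ValueError("effect_size must be >= 1")
        if not 0.0 <= self.target_overlap <= 1.0:
            raise ValueError("target_overlap must lie in [0, 1]")
        n_common = int(round(self.n_targets * self.target_overlap))
        if 2 * self.n_targets - n_common > self.neurons_per_region:
            raise ValueError("overlap infeasible for the population size")


def make_response_tables(spec: SyntheticResponseSpec
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Untrained + trained response tables and the planted ground truth.

    Returns (untrained, trained, truth) where truth maps
    (region, pattern) -> planted target index array (indices are global:
    region_offset + local index).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.neurons_per_region
    n_common = int(round(spec.n_targets * spec.target_overlap))
    rows_u, rows_t = [], []
    truth = {}
    for r_i, region in enumerate(spec.regions):
        offset = r_i * n
        ids = offset + np.arange(n)
        perm = rng.permutation(n)
        common = perm[:n_common]
        uniq1 = perm[n_common:spec.n_targets]
        uniq2 = perm[spec.n_targets:2 * spec.n_targets - n_common]
        t1 = np.sort(offset + np.concatenate([common, uniq1]))
        t2 = np.sort(offset + np.concatenate([common, uniq2]))
        truth[(region, "P1")] = t1
        truth[(region, "P2")] = t2
        for pattern, tgt in (("P1", t1), ("P2", t2)):
            base = rng.gamma(2.0, spec.baseline_rate / 2.0, size=n) + 0.1
            gain = np.where(np.isin(ids, tgt), spec.effect_size, 1.0)
            noise = rng.lognormal(0.0, spec.noise_sd, size=n)
            trained = base * gain * noise
            rows_u.append(pd.DataFrame({"neuron": ids, "region": region,
                                        "pattern": pattern, "response": base}))
            rows_t.append(pd.DataFrame({"neuron": ids, "region": region,
                                        "pattern": pattern, "response": trained}))
    untrained = pd.concat(rows_u, ignore_index=True)
    trained = pd.concat(rows_t, ignore_index=True)
    return untrained, trained, truth
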