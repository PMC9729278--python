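"""Construction of the three-region hippocampal network.

The network is a signed, weighted, directed graph stored as a sparse matrix
``W`` with ``W[i, j]`` the synaptic weight of the edge ``i -> j`` (positive
for excitatory sources, negative for inhibitory sources). Neuron indices are
0-based and contiguous per subtype, in the canonical subtype order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .config import (SUBTYPES, REGIONS, ConfigurationError, NetworkConfig,
                     NeuronTypeSpec)


@dataclass(frozen=True)
class PopulationLayout:
    """Per-subtype counts and contiguous global index ranges."""

    counts: dict[str, int]
    scale: float = 1.0

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for s in SUBTYPES:
            n = self.counts[s]
            out[s] = slice(start, start + n)
            start += n
        return out

    def indices(self, subtype: str) -> np.ndarray:
        sl = self.slices[subtype]
        return np.arange(sl.start, sl.stop)

    def region_indices(self, region: str) -> np.ndarray:
        return np.concatenate([self.indices(s) for s in SUBTYPES
                               if _REGION_OF[s] == region])

    def subtype_of(self) -> np.ndarray:
        """Array of subtype-name strings per neuron index."""
        out = np.empty(self.n_total, dtype=object)
        for s, sl in self.slices.items():
            out[sl] = s
        return out


_REGION_OF = {s: ("DG" if s.startswith("dg") else s.split("_")[0].upper())
              for s in SUBTYPES}


@dataclass
class HippocampalNetwork:
    """Populations, signed weighted directed synapse matrix, type map."""

    layout: PopulationLayout
    weights: sp.csr_matrix
    config: NetworkConfig
    seed: int = 0

    # cached per-neuron annotation arrays
    _subtype: np.ndarray = field(default=None, repr=False)

    @property
    def n_neurons(self) -> int:
        return self.layout.n_total

    @property
    def subtype(self) -> np.ndarray:
        if self._subtype is None:
            self._subtype = self.layout.subtype_of()
        return self._subtype

    @property
    def region(self) -> np.ndarray:
        return np.array([_REGION_OF[s] for s in self.subtype], dtype=object)

    @property
    def excitatory(self) -> np.ndarray:
        exc = {name: t.excitatory for name, t in self.config.neuron_types.items()}
        return np.array([exc[s] for s in self.subtype], dtype=bool)

    def type_of(self, i: int) -> NeuronTypeSpec:
        return self.config.neuron_types[self.subtype[i]]

    def param_arrays(self) -> dict[str, np.ndarray]:
        """Expand per-subtype Izhikevich parameters to per-neuron arrays."""
        fields = ("a", "b", "c", "d", "k", "C", "v_r", "v_t_mem", "v_p",
                  "W_max", "r_target")
        out = {f: np.empty(self.n_neurons) for f in fields}
        for name, sl in self.layout.slices.items():
            t = self.config.neuron_types[name]
            for f in fields:
                out[f][sl] = getattr(t, f)
        return out

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.arange(self.n_neurons),
            "subtype": self.subtype,
            "region": self.region,
            "excitatory": self.excitatory,
        })


def _scaled_counts(counts: dict[str, int], scale: float) -> dict[str, int]:
    if scale == 1.0:
        return dict(counts)
    return {s: int(round(n * scale)) for s, n in counts.items()}


def build_network(config: NetworkConfig | None = None, scale: float = 1.0,
                  seed: int = 0) -> HippocampalNetwork:
    """Construct the hippocampal network at ``scale`` times full size.

    Connections are sampled independently per projection as Bernoulli(p)
    edges with clipped-normal weight magnitudes; identical
    ``(config, scale, seed)`` reproduce the identical matrix. Self-loops are
    never created.
    """
    if config is None:
        config = NetworkConfig()
    if not 0.0 < scale <= 1.0:
        raise ConfigurationError(f"scale must lie in (0, 1], got {scale}")
    config.validate()

    layout = PopulationLayout(_scaled_counts(config.counts, scale), scale)
    n = layout.n_total
    if n == 0:
        raise ConfigurationError("scaled network is empty")
    slices = layout.slices
    rng = np.random.default_rng(seed)

    rows, cols, vals = [], [], []
    for rule in config.projections:  # fixed order => determinism
        ns = layout.counts[rule.source]
        nt = layout.counts[rule.target]
        if ns == 0 or nt == 0 or rule.p == 0.0:
            continue
        total = ns * nt
        n_edges = rng.binomial(total, rule.p)
        if n_edges == 0:
            continue
        flat = rng.choice(total, size=n_edges, replace=False)
        r = flat // nt + slices[rule.source].start
        c = flat % nt + slices[rule.target].start
        if rule.source == rule.target:
            keep = r != c
            r, c = r[keep], c[keep]
        w = rng.normal(rule.weight_mean, rule.weight_sd, size=r.size)
        tgt_wmax = config.neuron_types[rule.target].W_max
        w = np.clip(w, config.min_weight, tgt_wmax)
        if not config.neuron_types[rule.source].excitatory:
            w = -w
        rows.append(r)
        cols.append(c)
        vals.append(w)

    if rows:
        W = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    else:
        W = sp.csr_matrix((n, n))
    W.sum_duplicates()
    return HippocampalNetwork(layout=layout, weights=W, config=config, seed=seed)


def extract_subnetwork(net: HippocampalNetwork, regions) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Submatrix restricted to the named regions, with node metadata.

    Returns the weight submatrix (rows/cols reindexed contiguously) and a
    metadata table carrying original indices, subtype, region, and
    excitatory flag.
    """
    regions = set(regions)
    if not regions:
        raise ValueError("region set must be non-empty")
    unknown = regions - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown regions: {sorted(unknown)}")
    mask = np.isin(net.region, sorted(regions))
    idx = np.flatnonzero(mask)
    sub = net.weights[np.ix_(idx, idx)].tocsr()
    meta = net.node_table().iloc[idx].reset_index(drop=True)
    meta = meta.rename(columns={"index": "original_index"})
    return sub, meta


def validate_topology(net: HippocampalNetwork) -> dict[str, bool]:
    """Report structural invariant checks; never mutates the network.

    Checks: zero diagonal, no granule-granule edges, presence of CA3
    recurrent collaterals and of the DG->CA3 and CA3->CA1 feedforward
    pathways, absence of back-projections (CA1->DG, CA1->CA3, CA3->DG), and
    sign consistency of every edge with its source neuron.
    """
    W = net.weights.tocoo()
    region = net.region
    exc = net.excitatory
    sub = net.subtype

    src_r = region[W.row]
    tgt_r = region[W.col]
    src_s = sub[W.row]
    tgt_s = sub[W.col]

    checks = {}
    checks["zero_diagonal"] = not np.any(W.row == W.col)
    checks["no_granule_granule"] = not np.any(
        (src_s == "dg_granule") & (tgt_s == "dg_granule"))
    checks["ca3_recurrent_present"] = bool(np.any(
        (src_s == "ca3_pyramidal") & (tgt_s == "ca3_pyramidal")))
    checks["dg_to_ca3_present"] = bool(np.any((src_r == "DG") & (tgt_r == "CA3")))
    checks["ca3_to_ca1_present"] = bool(np.any((src_r == "CA3") & (tgt_r == "CA1")))
    checks["no_ca1_to_dg"] = not np.any((src_r == "CA1") & (tgt_r == "DG"))
    checks["no_ca1_to_ca3"] = not np.any((src_r == "CA1") & (tgt_r == "CA3"))
    checks["no_ca3_to_dg"] = not np.any((src_r == "CA3") & (tgt_r == "DG"))
    nonzero = W.data != 0
    checks["sign_consistency"] = bool(np.all(
        (W.data[nonzero] > 0) == exc[W.row[nonzero]]))
    return checks


def inhibitory_fraction(net: HippocampalNetwork) -> dict[str, float]:
    """Fraction of inhibitory neurons per region."""
    out = {}
    for r in REGIONS:
        m = net.region == r
        out[r] = float((~net.excitatory[m]).sum() / m.sum()) if m.any() else float("nan")
    return out


# -- persistence ----------------------------------------------------------

def save_network(net: HippocampalNetwork, outdir) -> None:
    """Write weights.mtx (Matrix Market), nodes.csv, and config.yaml."""
    os.makedirs(outdir, exist_ok=True)
    mmwrite(os.path.join(outdir, "weights.mtx"), net.weights.tocoo())
    net.node_table().to_csv(os.path.join(outdir, "nodes.csv"), index=False)
    d = net.config.to_dict()
    d["_layout"] = {"counts": dict(net.layout.counts),
                    "scale": net.layout.scale, "seed": net.seed}
    import yaml
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_network(indir) -> HippocampalNetwork:
    import yaml
    with open(os.path.join(indir, "config.yaml")) as fh:
        d = yaml.safe_load(fh)
    lay = d.pop("_layout")
    config = NetworkConfig.from_dict(d)
    W = sp.csr_matrix(mmread(os.path.join(indir, "weights.mtx")))
    layout = PopulationLayout({k: int(v) for k, v in lay["counts"].items()},
                              float(lay["scale"]))
    return HippocampalNetwork(layout=layout, weights=W, config=config,
                              seed=int(lay.get("seed", 0)))
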