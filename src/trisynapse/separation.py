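"""Learning readout: normalized responses, target selection, and
pattern-separation metrics.

After training, each neuron's stimulus response (mean spike count in the
200 ms epoch after each stimulus event) is normalized by its untrained
response. Per region and pattern, the top-n neurons by normalized response
form the *target* population; the remaining principal excitatory neurons
are *off-target*. Separation is quantified by

* percent overlap between the two patterns' target sets,
* the change in population distance PDdelta = D_out - D_in, where D is the
  Hamming distance between binary membership vectors over a reference
  population (PDdelta > 0 means the network separated the patterns),
* the Spearman distance SD = 1 - rho between the two patterns' normalized
  rate responses on common target neurons (range 0-2), and
* the signal-to-noise ratio SNR = mean target / mean off-target normalized
  response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats


@dataclass
class TargetAssignment:
    """Per region x pattern: target indices; the rest are off-target."""

    targets: dict[tuple[str, str], np.ndarray]
    off_targets: dict[tuple[str, str], np.ndarray]
    n_per_set: int


def normalize_responses(trained: pd.DataFrame, untrained: pd.DataFrame,
                        epsilon: float) -> pd.DataFrame:
    """Per-neuron normalized response = trained / untrained.

    Both tables need columns (neuron, region, pattern, response) over the
    same neuron x pattern set. Silent untrained neurons would make the bare
    ratio undefined, so both numerator and denominator are offset by
    ``epsilon`` (conventionally one spike over the whole test, i.e.
    1 / n_epochs): normalized = (trained + eps) / (untrained + eps).
    """
    keys = ["neuron", "region", "pattern"]
    a = trained.set_index(keys)["response"].sort_index()
    b = untrained.set_index(keys)["response"].sort_index()
    if not a.index.equals(b.index):
        raise ValueError("trained and untrained tables cover different neurons")
    out = ((a + epsilon) / (b + epsilon)).rename("normalized").reset_index()
    out["trained"] = a.to_numpy()
    out["untrained"] = b.to_numpy()
    return out


def select_targets(normalized: pd.DataFrame, n: int,
                   eligible: dict[str, np.ndarray],
                   excluded: np.ndarray | None = None) -> TargetAssignment:
    """Top-n neurons by normalized response per region and pattern.

    ``eligible`` maps region -> principal excitatory neuron indices; any
    neuron listed in ``excluded`` (e.g. the stimulated inputs) is removed
    before selection. Ties break by ascending neuron index (the sort is on
    (-rate, index)), making selection deterministic.
    """
    excluded = set() if excluded is None else set(np.asarray(excluded).tolist())
    targets, off = {}, {}
    for region, pool in eligible.items():
        pool = np.array([i for i in np.asarray(pool) if i not in excluded])
        sub = normalized[normalized["region"] == region]
        for pattern in sorted(sub["pattern"].unique()):
            rates = sub[sub["pattern"] == pattern].set_index("neuron")["normalized"]
            pool_rates = rates.reindex(pool).to_numpy()
            if np.any(np.isnan(pool_rates)):
                raise ValueError(f"missing responses for region {region}")
            if pool.size <= n:
                raise ValueError(
                    f"region {region}: {pool.size} eligible neurons, need > {n}")
            order = np.lexsort((pool, -pool_rates))
            sel = np.sort(pool[order[:n]])
            targets[(region, pattern)] = sel
            off[(region, pattern)] = np.setdiff1d(pool, sel)
    return TargetAssignment(targets, off, n)


def snr(assignment: TargetAssignment, normalized: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized target response over mean off-target response."""
    rows = []
    for (region, pattern), tgt in assignment.targets.items():
        rates = normalized[(normalized["region"] == region)
                           & (normalized["pattern"] == pattern)
                           ].set_index("neuron")["normalized"]
        t = rates.reindex(tgt).to_numpy()
        o = rates.reindex(assignment.off_targets[(region, pattern)]).to_numpy()
        if o.size == 0 or np.mean(o) == 0:
            raise ValueError("off-target mean response is zero or empty")
        rows.append({"region": region, "pattern": pattern,
                     "target_mean": float(np.mean(t)),
                     "off_target_mean": float(np.mean(o)),
                     "snr": float(np.mean(t) / np.mean(o))})
    return pd.DataFrame(rows)


def percent_overlap(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """100 * |A intersect B| / |A| for equal-sized sets."""
    a, b = set(np.asarray(set_a).tolist()), set(np.asarray(set_b).tolist())
    if len(a) != len(b):
        raise ValueError("sets must have equal size")
    if not a:
        raise ValueError("sets must be non-empty")
    return 100.0 * len(a & b) / len(a)


def hamming_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Fraction of positions at which two binary vectors differ."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size == 0:
        raise ValueError("vectors must be non-empty")
    return float(np.mean(x != y))


def membership_vector(members: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Binary vector over ``reference`` marking the given members."""
    return np.isin(reference, members).astype(np.int8)


def population_distance_delta(input_a, input_b, output_a, output_b,
                              input_reference, output_reference) -> dict:
    """PDdelta = D_out - D_in with membership vectors over the stated
    reference populations (inputs over the stimulated region's principal
    cells, outputs over the analysed region's)."""
    for s, ref, what in ((input_a, input_reference, "input A"),
                         (input_b, input_reference, "input B"),
                         (output_a, output_reference, "output A"),
                         (output_b, output_reference, "output B")):
        if not np.all(np.isin(s, ref)):
            raise ValueError(f"{what} members missing from its reference population")
    d_in = hamming_distance(membership_vector(input_a, input_reference),
                            membership_vector(input_b, input_reference))
    d_out = hamming_distance(membership_vector(output_a, output_reference),
                             membership_vector(output_b, output_reference))
    return {"d_in": d_in, "d_out": d_out, "pd_delta": d_out - d_in}


def spearman_distance(x_s: np.ndarray, x_t: np.ndarray) -> float:
    """1 - Spearman rank correlation; 0 for identical rankings, 2 for
    exactly reversed. Ties receive average ranks."""
    x_s = np.asarray(x_s, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    if x_s.shape != x_t.shape or x_s.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    r_s = _stats.rankdata(x_s)
    r_t = _stats.rankdata(x_t)
    if np.allclose(r_s.var(), 0) or np.allclose(r_t.var(), 0):
        raise ValueError("undefined correlation: constant vector")
    ds, dt_ = r_s - r_s.mean(), r_t - r_t.mean()
    rho = float(ds @ dt_ / np.sqrt((ds @ ds) * (dt_ @ dt_)))
    return 1.0 - rho


@dataclass
class SeparationMetrics:
    per_region: pd.DataFrame
    snr_table: pd.DataFrame
    assignment: TargetAssignment = field(repr=False, default=None)


def separation_report(assignment: TargetAssignment, normalized: pd.DataFrame,
                      pattern_members: dict[str, np.ndarray],
                      input_reference: np.ndarray,
                      output_references: dict[str, np.ndarray]
                      ) -> SeparationMetrics:
    """Aggregate overlap, PDdelta, and Spearman distance per region.

    ``pattern_members`` maps pattern label -> stimulated input indices;
    ``output_references`` maps region -> that region's principal excitatory
    population. Spearman distance uses the common responders (intersection
    of the two target sets); regions with fewer than 3 common responders
    report NaN there.
    """
    labels = sorted(pattern_members)
    if len(labels) != 2:
        raise ValueError("need exactly two patterns")
    p1, p2 = labels
    snr_table = snr(assignment, normalized)
    regions = sorted({r for (r, _) in assignment.targets})
    rows = []
    for region in regions:
        t1 = assignment.targets[(region, p1)]
        t2 = assignment.targets[(region, p2)]
        ov = percent_overlap(t1, t2)
        pd_d = population_distance_delta(
            pattern_members[p1], pattern_members[p2], t1, t2,
            input_reference, output_references[region])
        common = np.intersect1d(t1, t2)
        if common.size >= 3:
            r1 = normalized[(normalized["region"] == region)
                            & (normalized["pattern"] == p1)
                            ].set_index("neuron")["normalized"].reindex(common)
            r2 = normalized[(normalized["region"] == region)
                            & (normalized["pattern"] == p2)
                            ].set_index("neuron")["normalized"].reindex(common)
            try:
                sd = spearman_distance(r1.to_numpy(), r2.to_numpy())
            except ValueError:
                sd = float("nan")
        else:
            sd = float("nan")
        srow = snr_table[snr_table["region"] == region]
        rows.append({"region": region, "overlap_pct": ov, "d_in": pd_d["d_in"],
                     "d_out": pd_d["d_out"], "pd_delta": pd_d["pd_delta"],
                     "spearman_distance": sd, "n_common": int(common.size),
                     "snr": float(srow["snr"].mean())})
    return SeparationMetrics(pd.DataFrame(rows), snr_table, assignment)
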