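"""Model configuration: neuron subtypes, population layout, and projections.

The circuit contains ten neuron subtypes across the dentate gyrus (DG),
CA3, and CA1. Izhikevich parameters default to the published regular-spiking,
intrinsically-bursting, fast-spiking, and low-threshold-spiking archetypes,
assigned by electrophysiological class; every value can be overridden from a
YAML config file. Population counts at full scale total 8,885 neurons with
~10% inhibitory cells per region, split in rat-like proportions
(DG >> CA1 >= CA3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import yaml

REGIONS = ("DG", "CA3", "CA1")

#: canonical subtype ordering; neuron index blocks follow this order
SUBTYPES = (
    "dg_granule",
    "dg_mossy",
    "dg_basket",
    "dg_interneuron",
    "ca3_pyramidal",
    "ca3_basket",
    "ca3_interneuron",
    "ca1_pyramidal",
    "ca1_basket",
    "ca1_interneuron",
)


class ConfigurationError(ValueError):
    """Raised when a network configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class NeuronTypeSpec:
    """Izhikevich parameters and plasticity references for one subtype.

    ``v_t_mem`` is the membrane threshold potential of the quadratic model
    (distinct from the homeostatic target rate ``r_target``, in Hz).
    ``W_max`` bounds the excitatory synaptic weights onto neurons of this
    subtype (nS).
    """

    name: str
    region: str
    excitatory: bool
    a: float
    b: float
    c: float
    d: float
    k: float
    C: float          # membrane capacitance, pF
    v_r: float        # resting potential, mV
    v_t_mem: float    # threshold potential, mV
    v_p: float        # spike peak, mV
    W_max: float = 10.0
    r_target: float = 2.0  # homeostatic target rate, Hz (fallback)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigurationError(f"{self.name}: capacitance C must be > 0")
        if not (self.v_r < self.v_t_mem < self.v_p):
            raise ConfigurationError(
                f"{self.name}: require v_r < v_t_mem < v_p "
                f"(got {self.v_r}, {self.v_t_mem}, {self.v_p})"
            )
        if self.W_max <= 0:
            raise ConfigurationError(f"{self.name}: W_max must be > 0")
        if self.r_target <= 0:
            raise ConfigurationError(f"{self.name}: r_target must be > 0")
        if self.region not in REGIONS:
            raise ConfigurationError(f"{self.name}: unknown region {self.region!r}")


@dataclass(frozen=True)
class ConnectivityRule:
    """One projection: Bernoulli(p) connectivity with clipped-normal weights.

    The sign of realised weights follows the source subtype (excitatory
    sources yield non-negative weights, inhibitory sources non-positive).
    """

    source: str
    target: str
    p: float
    weight_mean: float
    weight_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ConfigurationError(
                f"{self.source}->{self.target}: probability must lie in [0, 1]"
            )
        if self.weight_mean <= 0 or self.weight_sd < 0:
            raise ConfigurationError(
                f"{self.source}->{self.target}: weight distribution invalid"
            )


# Izhikevich archetypes (capacitance form of the quadratic model):
#   RS  - regular spiking pyramidal-like cell
#   IB  - intrinsically bursting pyramidal cell (CA3 pyramidal cells burst)
#   FS  - fast-spiking basket cell
#   LTS - low-threshold-spiking interneuron
_RS = dict(a=0.03, b=-2.0, c=-50.0, d=100.0, k=0.7, C=100.0, v_r=-60.0,
           v_t_mem=-40.0, v_p=35.0)
_IB = dict(a=0.01, b=5.0, c=-56.0, d=130.0, k=1.2, C=150.0, v_r=-75.0,
           v_t_mem=-45.0, v_p=50.0)
_FS = dict(a=0.2, b=0.0, c=-45.0, d=2.0, k=1.0, C=20.0, v_r=-55.0,
           v_t_mem=-40.0, v_p=25.0)
_LTS = dict(a=0.03, b=8.0, c=-53.0, d=20.0, k=1.0, C=100.0, v_r=-56.0,
            v_t_mem=-42.0, v_p=40.0)


def default_neuron_types() -> dict[str, NeuronTypeSpec]:
    """The ten subtypes with archetype electrophysiology.

    Granule cells use a hyperpolarised RS variant (sparse firing); CA3
    pyramidal cells the bursting archetype; baskets FS; other interneurons
    LTS. Inhibitory cells get a higher homeostatic target rate.
    """
    t = {}
    t["dg_granule"] = NeuronTypeSpec("dg_granule", "DG", True, r_target=0.5,
                                     **{**_RS, "v_r": -70.0, "d": 120.0})
    t["dg_mossy"] = NeuronTypeSpec("dg_mossy", "DG", True, r_target=2.0, **_RS)
    t["dg_basket"] = NeuronTypeSpec("dg_basket", "DG", False, r_target=10.0, **_FS)
    t["dg_interneuron"] = NeuronTypeSpec("dg_interneuron", "DG", False,
                                         r_target=5.0, **_LTS)
    t["ca3_pyramidal"] = NeuronTypeSpec("ca3_pyramidal", "CA3", True,
                                        r_target=2.0, **_IB)
    t["ca3_basket"] = NeuronTypeSpec("ca3_basket", "CA3", False, r_target=10.0, **_FS)
    t["ca3_interneuron"] = NeuronTypeSpec("ca3_interneuron", "CA3", False,
                                          r_target=5.0, **_LTS)
    t["ca1_pyramidal"] = NeuronTypeSpec("ca1_pyramidal", "CA1", True,
                                        r_target=2.0, **_RS)
    t["ca1_basket"] = NeuronTypeSpec("ca1_basket", "CA1", False, r_target=10.0, **_FS)
    t["ca1_interneuron"] = NeuronTypeSpec("ca1_interneuron", "CA1", False,
                                          r_target=5.0, **_LTS)
    return t


#: full-scale per-subtype counts; totals 8,885 with 10% inhibitory per region
DEFAULT_COUNTS: dict[str, int] = {
    "dg_granule": 4900,
    "dg_mossy": 262,
    "dg_basket": 343,
    "dg_interneuron": 230,
    "ca3_pyramidal": 1215,
    "ca3_basket": 81,
    "ca3_interneuron": 54,
    "ca1_pyramidal": 1620,
    "ca1_basket": 108,
    "ca1_interneuron": 72,
}


def default_projections() -> list[ConnectivityRule]:
    """Default projection set.

    Qualitative constraints honoured: predominantly feedforward
    DG -> CA3 -> CA1; granule cells never contact one another; CA3
    pyramidal cells carry recurrent collaterals; no back-projections out of
    CA1 or CA3. Probabilities and weight statistics are documented defaults
    (the quantitative connectome is configurable, not ground truth).
    """
    R = ConnectivityRule
    return [
        # DG internal (weak mossy-cell associational feedback)
        R("dg_granule", "dg_mossy", 0.03, 4.0, 1.0),
        R("dg_granule", "dg_basket", 0.02, 4.0, 1.0),
        R("dg_granule", "dg_interneuron", 0.02, 4.0, 1.0),
        R("dg_mossy", "dg_granule", 0.035, 3.0, 1.0),
        R("dg_mossy", "dg_basket", 0.01, 3.0, 1.0),
        R("dg_basket", "dg_granule", 0.03, 5.0, 1.0),
        R("dg_interneuron", "dg_granule", 0.02, 4.0, 1.0),
        R("dg_interneuron", "dg_mossy", 0.02, 4.0, 1.0),
        # DG -> CA3 (mossy-fibre pathway: sparse, strong)
        R("dg_granule", "ca3_pyramidal", 0.025, 6.0, 1.5),
        R("dg_granule", "ca3_basket", 0.01, 4.0, 1.0),
        # CA3 internal (dense recurrent collaterals)
        R("ca3_pyramidal", "ca3_pyramidal", 0.12, 4.0, 1.0),
        R("ca3_pyramidal", "ca3_basket", 0.05, 4.0, 1.0),
        R("ca3_pyramidal", "ca3_interneuron", 0.05, 4.0, 1.0),
        R("ca3_basket", "ca3_pyramidal", 0.12, 5.0, 1.0),
        R("ca3_interneuron", "ca3_pyramidal", 0.08, 4.0, 1.0),
        # CA3 -> CA1 (Schaffer collaterals: sparse, strong)
        R("ca3_pyramidal", "ca1_pyramidal", 0.03, 5.0, 1.0),
        R("ca3_pyramidal", "ca1_basket", 0.05, 4.0, 1.0),  # feedforward inhibition
        R("ca3_pyramidal", "ca1_interneuron", 0.02, 4.0, 1.0),
        # CA1 internal (no pyramidal-pyramidal recurrence)
        R("ca1_pyramidal", "ca1_basket", 0.05, 4.0, 1.0),
        R("ca1_pyramidal", "ca1_interneuron", 0.05, 4.0, 1.0),
        R("ca1_basket", "ca1_pyramidal", 0.12, 5.0, 1.0),
        R("ca1_interneuron", "ca1_pyramidal", 0.08, 4.0, 1.0),
    ]


@dataclass
class NetworkConfig:
    """Complete structural configuration of the hippocampal model."""

    neuron_types: dict[str, NeuronTypeSpec] = field(default_factory=default_neuron_types)
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    projections: list[ConnectivityRule] = field(default_factory=default_projections)
    min_weight: float = 0.1  # clip floor for initial |weights|, nS

    def validate(self) -> None:
        missing = [s for s in SUBTYPES if s not in self.neuron_types]
        if missing:
            raise ConfigurationError(f"missing neuron type definitions: {missing}")
        missing_counts = [s for s in SUBTYPES if s not in self.counts]
        if missing_counts:
            raise ConfigurationError(f"missing population counts: {missing_counts}")
        for s, n in self.counts.items():
            if n < 0:
                raise ConfigurationError(f"count for {s} must be >= 0 (got {n})")
        for rule in self.projections:
            for end in (rule.source, rule.target):
                if end not in self.neuron_types:
                    raise ConfigurationError(
                        f"projection references undefined subtype {end!r}"
                    )
            if rule.source == "dg_granule" and rule.target == "dg_granule":
                raise ConfigurationError(
                    "granule->granule projections are not permitted"
                )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "neuron_types": {k: asdict(v) for k, v in self.neuron_types.items()},
            "counts": dict(self.counts),
            "projections": [asdict(r) for r in self.projections],
            "min_weight": self.min_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        cfg = cls()
        if "neuron_types" in d:
            types = dict(cfg.neuron_types)
            for name, kw in d["neuron_types"].items():
                base = asdict(types[name]) if name in types else {}
                base.update(kw)
                types[name] = NeuronTypeSpec(**base)
            cfg.neuron_types = types
        if "counts" in d:
            cfg.counts.update(d["counts"])
        if "projections" in d:
            cfg.projections = [ConnectivityRule(**r) for r in d["projections"]]
        if "min_weight" in d:
            cfg.min_weight = float(d["min_weight"])
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_type(self, name: str, **overrides) -> "NetworkConfig":
        """Return a copy with one subtype's parameters overridden."""
        types = dict(self.neuron_types)
        types[name] = replace(types[name], **overrides)
        cfg = NetworkConfig(neuron_types=types, counts=dict(self.counts),
                            projections=list(self.projections),
                            min_weight=self.min_weight)
        return cfg
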