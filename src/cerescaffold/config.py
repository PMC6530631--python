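"""Configuration for the cerebellar scaffold.

Every quantity the pipeline uses — volume geometry, per-type densities and
soma radii, leaky integrate-and-fire (LIF) neuron parameters, synaptic
weights/delays, connection-rule geometry, and stimulation protocols — lives
in a single :class:`ScaffoldConfig` bundle.  The built-in defaults
(:func:`default_config`) reproduce the reference mouse cerebellar volume:
a 400 x 400 um^2 cortical base with 330 um height (granular 150, Purkinje
30, molecular 150) plus a 200 x 200 x 600 um^3 deep-cerebellar-nuclei (DCN)
block placed below the cortex.

Axis convention (fixed for the whole package): ``x`` is parasagittal,
``y`` is vertical (0 at the bottom of the granular layer, negative in the
DCN), ``z`` is transversal — the parallel-fiber axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

__all__ = [
    "ConfigError",
    "VolumeConfig",
    "NeuronTypeSpec",
    "LIFParams",
    "SynapseSpec",
    "ConnectionRule",
    "SimParams",
    "ScaffoldConfig",
    "default_config",
    "load_config",
    "save_config",
    "expected_counts",
    "scale_config",
    "NEURON_TYPES",
    "CONNECTION_TYPES",
]


class ConfigError(ValueError):
    """A configuration value violates an invariant; message names the field."""


# type codes 1-7, in the order of the neuron-parameter table
NEURON_TYPES = ("GoC", "Glom", "GrC", "PC", "BC", "SC", "DCNC")

# the sixteen synaptic connection types; golgi_to_glomerulus is a structural
# intermediate fused into golgi_to_granule and carries no synapse of its own
CONNECTION_TYPES = (
    "glomerulus_to_granule",
    "glomerulus_to_golgi",
    "golgi_to_granule",
    "golgi_to_golgi",
    "ascending_axon_to_golgi",
    "parallel_fiber_to_golgi",
    "stellate_to_stellate",
    "basket_to_basket",
    "parallel_fiber_to_stellate",
    "parallel_fiber_to_basket",
    "stellate_to_purkinje",
    "basket_to_purkinje",
    "ascending_axon_to_purkinje",
    "parallel_fiber_to_purkinje",
    "purkinje_to_dcn",
    "glomerulus_to_dcn",
)


@dataclass
class VolumeConfig:
    """Geometry of the reconstructed volume, all lengths in micrometers."""

    cortical_base_x: float = 400.0
    cortical_base_z: float = 400.0
    granular_height: float = 150.0
    pc_layer_height: float = 30.0
    molecular_height: float = 150.0
    dcn_base_x: float = 200.0
    dcn_base_z: float = 200.0
    dcn_height: float = 600.0

    @property
    def cortical_height(self) -> float:
        return self.granular_height + self.pc_layer_height + self.molecular_height

    def layer_bounds(self, layer: str) -> tuple[float, float]:
        """Vertical (y) extent of a named layer.

        The DCN sits below the cortical slab, so its bounds are negative.
        """
        g, p, m = self.granular_height, self.pc_layer_height, self.molecular_height
        bounds = {
            "granular": (0.0, g),
            "purkinje": (g, g + p),
            "molecular": (g + p, g + p + m),
            "molecular_lower": (g + p, g + p + m / 2.0),
            "molecular_upper": (g + p + m / 2.0, g + p + m),
            "dcn": (-self.dcn_height, 0.0),
        }
        if layer not in bounds:
            raise ConfigError(f"unknown layer {layer!r}")
        return bounds[layer]

    def layer_base(self, layer: str) -> tuple[float, float, float, float]:
        """(x_lo, x_hi, z_lo, z_hi) footprint of a named layer.

        The DCN base is centered under the cortical base.
        """
        if layer == "dcn":
            cx, cz = self.cortical_base_x / 2.0, self.cortical_base_z / 2.0
            return (cx - self.dcn_base_x / 2.0, cx + self.dcn_base_x / 2.0,
                    cz - self.dcn_base_z / 2.0, cz + self.dcn_base_z / 2.0)
        return (0.0, self.cortical_base_x, 0.0, self.cortical_base_z)

    def layer_volume(self, layer: str) -> float:
        y0, y1 = self.layer_bounds(layer)
        x0, x1, z0, z1 = self.layer_base(layer)
        return (x1 - x0) * (z1 - z0) * (y1 - y0)

    def validate(self) -> None:
        for name in ("cortical_base_x", "cortical_base_z", "granular_height",
                     "pc_layer_height", "molecular_height", "dcn_base_x",
                     "dcn_base_z", "dcn_height"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"volume.{name} must be > 0")


@dataclass
class NeuronTypeSpec:
    """Per-type placement parameters.

    ``density`` is volumetric (cells/um^3) for every type except the PC,
    for which it is planar (cells/um^2) over the PC-layer base.
    """

    name: str
    type_code: int
    soma_radius: float
    density: float
    layer: str
    is_parrot: bool = False

    def validate(self) -> None:
        if self.name not in NEURON_TYPES:
            raise ConfigError(f"neuron.name {self.name!r} not one of {NEURON_TYPES}")
        if not 1 <= self.type_code <= 7:
            raise ConfigError(f"neuron[{self.name}].type_code must be in 1..7")
        if self.soma_radius <= 0:
            raise ConfigError(f"neuron[{self.name}].soma_radius must be > 0")
        if self.density < 0:
            raise ConfigError(f"neuron[{self.name}].density must be >= 0")


@dataclass
class LIFParams:
    """Conductance-based LIF parameters for one neuron type.

    Units: C_m pF, tau_m ms, E_L/V_r/V_th mV, dt_ref ms, I_e pA,
    tau_exc/tau_inh ms (decay constants of the exponential synaptic
    conductances).
    """

    C_m: float
    tau_m: float
    E_L: float
    dt_ref: float
    I_e: float
    V_r: float
    V_th: float
    tau_exc: float
    tau_inh: float

    def validate(self, name: str = "?") -> None:
        if self.tau_m <= 0:
            raise ConfigError(f"lif[{name}].tau_m must be > 0")
        if self.C_m <= 0:
            raise ConfigError(f"lif[{name}].C_m must be > 0")
        if self.V_r >= self.V_th:
            raise ConfigError(f"lif[{name}].V_r must be < V_th")
        if self.tau_exc <= 0 or self.tau_inh <= 0:
            raise ConfigError(f"lif[{name}].tau_exc/tau_inh must be > 0")
        if self.dt_ref < 0:
            raise ConfigError(f"lif[{name}].dt_ref must be >= 0")


# presynaptic sources whose output is inhibitory (GABAergic)
_INHIBITORY_SOURCES = ("golgi", "stellate", "basket", "purkinje")


@dataclass
class SynapseSpec:
    """Weight (nS, signed: negative = inhibitory) and delay (ms) of one
    connection type."""

    connection_name: str
    weight: float
    delay: float

    def validate(self) -> None:
        if self.connection_name not in CONNECTION_TYPES:
            raise ConfigError(
                f"synapse.connection_name {self.connection_name!r} unknown")
        if self.delay <= 0:
            raise ConfigError(f"synapse[{self.connection_name}].delay must be > 0")
        pre = self.connection_name.split("_to_")[0]
        inhibitory = any(pre.startswith(s) for s in _INHIBITORY_SOURCES)
        if inhibitory and self.weight > 0:
            raise ConfigError(
                f"synapse[{self.connection_name}].weight must be <= 0 "
                f"(inhibitory source)")
        if not inhibitory and self.weight < 0:
            raise ConfigError(
                f"synapse[{self.connection_name}].weight must be >= 0 "
                f"(excitatory source)")


@dataclass
class ConnectionRule:
    """Geometry predicate parameters and pruning targets for one connection.

    ``geometry`` is a free-form mapping interpreted by the connectivity
    module (axis extents, radii, the parallel-fiber half-length bound ...).
    ``convergence`` / ``divergence`` are the mean afferents-per-post /
    efferents-per-pre targets; ``None`` means the geometric candidates pass
    through unpruned on that side.  ``pruning_scales`` are per-axis Gaussian
    decay lengths (um) of the distance-based selection probability;
    ``None`` means distance-flat selection.
    """

    name: str
    pre_type: str
    post_type: str
    geometry: dict = field(default_factory=dict)
    convergence: Optional[float] = None
    divergence: Optional[float] = None
    pruning_scales: Optional[tuple[Optional[float], Optional[float], Optional[float]]] = None

    def validate(self) -> None:
        if self.pre_type not in NEURON_TYPES or self.post_type not in NEURON_TYPES:
            raise ConfigError(f"rule[{self.name}] references unknown neuron type")
        for tgt, label in ((self.convergence, "convergence"),
                           (self.divergence, "divergence")):
            if tgt is not None and tgt < 0:
                raise ConfigError(f"rule[{self.name}].{label} must be >= 0")


@dataclass
class SimParams:
    """Engine-level simulation parameters."""

    dt: float = 0.1            # ms
    E_exc: float = 0.0         # mV, excitatory reversal potential
    E_inh: float = -85.0       # mV, inhibitory reversal potential
    burst_mode: str = "regular"  # "regular" or "poisson" burst spike trains

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigError("sim.dt must be > 0")
        if self.burst_mode not in ("regular", "poisson"):
            raise ConfigError("sim.burst_mode must be 'regular' or 'poisson'")


@dataclass
class ScaffoldConfig:
    """The full configuration bundle: single source of truth for every
    stage of the pipeline."""

    volume: VolumeConfig
    neurons: dict[str, NeuronTypeSpec]
    lif: dict[str, LIFParams]
    synapses: dict[str, SynapseSpec]
    rules: dict[str, ConnectionRule]
    sim: SimParams
    seed: int = 0

    def validate(self) -> "ScaffoldConfig":
        self.volume.validate()
        if set(self.neurons) != set(NEURON_TYPES):
            raise ConfigError(
                f"neurons must define exactly {NEURON_TYPES}, got {sorted(self.neurons)}")
        codes = sorted(n.type_code for n in self.neurons.values())
        if codes != list(range(1, 8)):
            raise ConfigError("neuron type_codes must be a permutation of 1..7")
        for n in self.neurons.values():
            n.validate()
            self.volume.layer_bounds(n.layer)  # raises on unknown layer
        for name, p in self.lif.items():
            p.validate(name)
        if set(self.synapses) != set(CONNECTION_TYPES):
            missing = set(CONNECTION_TYPES) - set(self.synapses)
            extra = set(self.synapses) - set(CONNECTION_TYPES)
            raise ConfigError(f"synapses mismatch: missing={sorted(missing)} "
                              f"extra={sorted(extra)}")
        for s in self.synapses.values():
            s.validate()
        for r in self.rules.values():
            r.validate()
        self.sim.validate()
        return self

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "volume": asdict(self.volume),
            "neurons": {k: asdict(v) for k, v in self.neurons.items()},
            "lif": {k: asdict(v) for k, v in self.lif.items()},
            "synapses": {k: asdict(v) for k, v in self.synapses.items()},
            "rules": {k: asdict(v) for k, v in self.rules.items()},
            "sim": asdict(self.sim),
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScaffoldConfig":
        try:
            rules = {}
            for k, v in d.get("rules", {}).items():
                v = dict(v)
                if v.get("pruning_scales") is not None:
                    v["pruning_scales"] = tuple(v["pruning_scales"])
                rules[k] = ConnectionRule(**v)
            cfg = cls(
                volume=VolumeConfig(**d["volume"]),
                neurons={k: NeuronTypeSpec(**v) for k, v in d["neurons"].items()},
                lif={k: LIFParams(**v) for k, v in d["lif"].items()},
                synapses={k: SynapseSpec(**v) for k, v in d["synapses"].items()},
                rules=rules,
                sim=SimParams(**d.get("sim", {})),
                seed=int(d.get("seed", 0)),
            )
        except KeyError as e:
            raise ConfigError(f"missing configuration section or field: {e}") from e
        except TypeError as e:
            raise ConfigError(str(e)) from e
        return cfg.validate()


def load_config(path) -> ScaffoldConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: not a mapping")
    return ScaffoldConfig.from_dict(d)


def save_config(cfg: ScaffoldConfig, path) -> None:
    """Write a configuration bundle to YAML (round-trips losslessly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def expected_counts(volume: VolumeConfig,
                    neurons: dict[str, NeuronTypeSpec]) -> dict[str, int]:
    """Target cell count per type: round(density x layer volume), except the
    PC whose planar density multiplies the base area.

    These are targets; the self-avoiding random walk may fall short of them
    when a layer saturates (the granule-cell layer does at the reference
    density), so placed counts can be lower.
    """
    out = {}
    for name, spec in neurons.items():
        if name == "PC":
            x0, x1, z0, z1 = volume.layer_base(spec.layer)
            out[name] = int(round(spec.density * (x1 - x0) * (z1 - z0)))
        else:
            out[name] = int(round(spec.density * volume.layer_volume(spec.layer)))
    return out


def scale_config(cfg: ScaffoldConfig, scale: float) -> ScaffoldConfig:
    """Reduced-volume variant for fast tests: base dimensions scale by
    sqrt(scale) (so cell counts scale by ~``scale``); densities, heights and
    all rules are untouched.  ``scale=1`` returns an identical copy."""
    if not 0 < scale <= 1:
        raise ConfigError("scale must be in (0, 1]")
    d = cfg.to_dict()
    f = math.sqrt(scale)
    for k in ("cortical_base_x", "cortical_base_z", "dcn_base_x", "dcn_base_z"):
        d["volume"][k] = cfg.to_dict()["volume"][k] * f
    return ScaffoldConfig.from_dict(d)


# ---------------------------------------------------------------------------
# reference defaults
# ---------------------------------------------------------------------------

def _default_neurons() -> dict[str, NeuronTypeSpec]:
    # densities in cells/um^3 (PC: cells/um^2), radii in um
    return {
        "GoC":  NeuronTypeSpec("GoC", 1, 8.0, 9e-6, "granular"),
        "Glom": NeuronTypeSpec("Glom", 2, 1.5, 3e-4, "granular", is_parrot=True),
        "GrC":  NeuronTypeSpec("GrC", 3, 2.5, 3.9e-3, "granular"),
        "PC":   NeuronTypeSpec("PC", 4, 7.5, 0.45e-3, "purkinje"),
        "BC":   NeuronTypeSpec("BC", 5, 6.0, 0.5e-4, "molecular_lower"),
        "SC":   NeuronTypeSpec("SC", 6, 4.0, 0.5e-4, "molecular_upper"),
        "DCNC": NeuronTypeSpec("DCNC", 7, 10.0, 5e-7, "dcn"),
    }


def _default_lif() -> dict[str, LIFParams]:
    #                 C_m  tau_m  E_L  dt_ref  I_e   V_r  V_th  t_exc t_inh
    return {
        "GoC":  LIFParams(76, 21, -65, 2.0, 36.8, -75, -55, 0.5, 10),
        "GrC":  LIFParams(3, 2, -74, 1.5, 0.0, -84, -42, 0.5, 10),
        "PC":   LIFParams(620, 88, -62, 0.8, 600, -72, -47, 0.5, 1.6),
        "BC":   LIFParams(14.6, 14.6, -68, 1.6, 15.6, -78, -53, 0.64, 2),
        "SC":   LIFParams(14.6, 14.6, -68, 1.6, 15.6, -78, -53, 0.64, 2),
        "DCNC": LIFParams(89, 57, -59, 3.7, 55.8, -69, -48, 7.1, 13.6),
    }


def _default_synapses() -> dict[str, SynapseSpec]:
    w = {
        "glomerulus_to_granule": (9.0, 4.0),
        "glomerulus_to_golgi": (2.0, 4.0),
        "golgi_to_granule": (-5.0, 2.0),
        "golgi_to_golgi": (-8.0, 1.0),
        "ascending_axon_to_golgi": (20.0, 2.0),
        "parallel_fiber_to_golgi": (0.4, 5.0),
        "stellate_to_stellate": (-2.0, 1.0),
        "basket_to_basket": (-2.5, 1.0),
        "parallel_fiber_to_stellate": (0.2, 5.0),
        "parallel_fiber_to_basket": (0.2, 5.0),
        "stellate_to_purkinje": (-8.5, 5.0),
        "basket_to_purkinje": (-9.0, 4.0),
        "ascending_axon_to_purkinje": (75.0, 2.0),
        "parallel_fiber_to_purkinje": (0.02, 5.0),
        "purkinje_to_dcn": (-0.0075, 4.0),
        "glomerulus_to_dcn": (0.006, 4.0),
    }
    return {k: SynapseSpec(k, *v) for k, v in w.items()}


# half-length bound of a parallel fiber along z (the full pf spans 400 um)
PF_HALF_LENGTH = 200.0


def _default_rules() -> dict[str, ConnectionRule]:
    """Connection-rule geometry and convergence/divergence targets.

    Geometry extents come from the anatomy of each projection (dendrite
    reach, axonal plexus size, parallel-fiber length bound).  Convergence /
    divergence targets are configuration inputs: where the literature states
    a number it is used directly (e.g. 4 glomeruli per granule cell);
    elsewhere the values are the package's calibration, chosen so the
    assembled network reproduces the published population firing regime
    (see docs/methods.md).
    """
    R: dict[str, ConnectionRule] = {}
    R["glomerulus_to_granule"] = ConnectionRule(
        "glomerulus_to_granule", "Glom", "GrC",
        geometry={"max_dendrite_length": 40.0},
        convergence=4,
        # short decay so pruning favours the nearest glomeruli, reproducing
        # the experimental mean dendrite length (~12-13 um)
        pruning_scales=(8.0, 8.0, 8.0))
    R["glomerulus_to_golgi"] = ConnectionRule(
        "glomerulus_to_golgi", "Glom", "GoC",
        geometry={"basolateral_radius_xz": 50.0},
        convergence=20, pruning_scales=None)
    R["golgi_to_glomerulus"] = ConnectionRule(
        "golgi_to_glomerulus", "GoC", "Glom",
        geometry={"axon_halfwidth_x": 160.0, "axon_halfwidth_z": 160.0},
        divergence=12, pruning_scales=(160.0, None, 160.0))
    R["golgi_to_granule"] = ConnectionRule(
        # fusion of golgi_to_glomerulus with glomerulus_to_granule
        "golgi_to_granule", "GoC", "GrC", geometry={"fused": True})
    R["golgi_to_golgi"] = ConnectionRule(
        "golgi_to_golgi", "GoC", "GoC",
        geometry={"max_distance": 160.0},
        convergence=4, pruning_scales=(160.0, 160.0, 160.0))
    R["ascending_axon_to_golgi"] = ConnectionRule(
        "ascending_axon_to_golgi", "GrC", "GoC",
        geometry={"basolateral_radius_xz": 50.0},
        convergence=25, pruning_scales=None)
    R["parallel_fiber_to_golgi"] = ConnectionRule(
        "parallel_fiber_to_golgi", "GrC", "GoC",
        geometry={"apical_radius_x": 100.0, "pf_half_length": PF_HALF_LENGTH},
        convergence=1200, pruning_scales=(100.0, None, PF_HALF_LENGTH))
    R["stellate_to_stellate"] = ConnectionRule(
        "stellate_to_stellate", "SC", "SC",
        geometry={"max_distance": 100.0},
        convergence=4, pruning_scales=(100.0, 100.0, 100.0))
    R["basket_to_basket"] = ConnectionRule(
        "basket_to_basket", "BC", "BC",
        geometry={"max_distance": 100.0},
        convergence=4, pruning_scales=(100.0, 100.0, 100.0))
    R["parallel_fiber_to_stellate"] = ConnectionRule(
        "parallel_fiber_to_stellate", "GrC", "SC",
        geometry={"dendrite_radius": 15.0, "pf_half_length": PF_HALF_LENGTH},
        convergence=500, pruning_scales=(None, None, PF_HALF_LENGTH))
    R["parallel_fiber_to_basket"] = ConnectionRule(
        "parallel_fiber_to_basket", "GrC", "BC",
        geometry={"dendrite_radius": 15.0, "pf_half_length": PF_HALF_LENGTH},
        convergence=500, pruning_scales=(None, None, PF_HALF_LENGTH))
    R["stellate_to_purkinje"] = ConnectionRule(
        # SC axon runs transversally ("on-beam"): long in z, thin in x
        "stellate_to_purkinje", "SC", "PC",
        geometry={"axon_halfwidth_x": 30.0, "axon_halfwidth_z": 150.0,
                  "slab_halfwidth_x": 150.0, "slab_halfwidth_z": 15.0},
        convergence=10, pruning_scales=(30.0, None, 150.0))
    R["basket_to_purkinje"] = ConnectionRule(
        # BC axon runs sagittally ("off-beam"): long in x, thin in z
        "basket_to_purkinje", "BC", "PC",
        geometry={"axon_halfwidth_x": 150.0, "axon_halfwidth_z": 30.0,
                  "slab_halfwidth_x": 150.0, "slab_halfwidth_z": 15.0},
        convergence=10, pruning_scales=(150.0, None, 30.0))
    R["ascending_axon_to_purkinje"] = ConnectionRule(
        "ascending_axon_to_purkinje", "GrC", "PC",
        geometry={"slab_halfwidth_x": 150.0, "contact_halfwidth_z": 5.0},
        convergence=150, pruning_scales=None)
    R["parallel_fiber_to_purkinje"] = ConnectionRule(
        "parallel_fiber_to_purkinje", "GrC", "PC",
        geometry={"slab_halfwidth_x": 150.0, "pf_half_length": PF_HALF_LENGTH},
        convergence=5000, pruning_scales=(None, None, PF_HALF_LENGTH))
    R["purkinje_to_dcn"] = ConnectionRule(
        # every local PC converges on each DCN cell (the volume holds far
        # fewer PCs than the biological convergence)
        "purkinje_to_dcn", "PC", "DCNC", geometry={})
    R["glomerulus_to_dcn"] = ConnectionRule(
        "glomerulus_to_dcn", "Glom", "DCNC", geometry={},
        convergence=50, pruning_scales=None)
    return R


def default_config(seed: int = 0) -> ScaffoldConfig:
    """The reference configuration reproducing the published network."""
    cfg = ScaffoldConfig(
        volume=VolumeConfig(),
        neurons=_default_neurons(),
        lif=_default_lif(),
        synapses=_default_synapses(),
        rules=_default_rules(),
        sim=SimParams(),
        seed=seed,
    )
    return cfg.validate()
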