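"""Default network configuration: geometry, populations, connectivity,
drives and condition switches.

The modelled volume is a cylinder of 300 µm diameter spanning the full
1350 µm cortical depth, partitioned into layers 1, 2/3, 4, 5A, 5B and 6.
Per-layer neuron densities, excitatory fractions and the within-class
ratio rules (IT:PT5B = 1:1 in L5B, IT:CT = 1:1 in L6, PV:SOM = 2:1 per
layer, PV5A/SOM5A covering layers 4 and 5A jointly) determine the
population counts; at full scale the default configuration places
10,073 neurons.  Absolute per-layer densities are not published alongside
the circuit description (they derive from external histology sources), so
the defaults here are chosen to reproduce the published total and ratios;
they can be overridden from YAML/JSON.

Connection probabilities and unitary PSP amplitudes for every population
pair are likewise configurable; defaults use class-level values (E->E,
E->I, I->E, I->I) with the exponential distance kernel (length constant
100 µm) providing spatial specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CylinderGeometry",
    "LayerSpec",
    "ConnectivityRule",
    "DriveSpec",
    "ConditionFlags",
    "NetworkConfig",
    "default_config",
    "load_config",
    "save_config",
    "E_POPULATIONS",
    "I_POPULATIONS",
]

E_POPULATIONS = ("IT2/3", "IT4", "IT5A", "IT5B", "PT5B", "IT6", "CT6")
I_POPULATIONS = ("PV2/3", "SOM2/3", "PV5A", "SOM5A", "PV5B", "SOM5B", "PV6", "SOM6")


@dataclass(frozen=True)
class CylinderGeometry:
    """Cylindrical cortical volume; depths in µm from the pia."""

    diameter_um: float = 300.0
    height_um: float = 1350.0
    # boundaries partition [0, height]; L1 holds no modeled somata
    layer_bounds_um: dict = field(default_factory=lambda: {
        "L1": (0.0, 135.0),
        "L2/3": (135.0, 391.5),
        "L4": (391.5, 499.5),
        "L5A": (499.5, 634.5),
        "L5B": (634.5, 1080.0),
        "L6": (1080.0, 1350.0),
    })

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2

    def layer_volume_mm3(self, layer: str) -> float:
        lo, hi = self.layer_bounds_um[layer]
        area = np.pi * (self.radius_um * 1e-3) ** 2
        return area * (hi - lo) * 1e-3

    def validate(self) -> None:
        bounds = sorted(self.layer_bounds_um.values())
        if bounds[0][0] != 0.0 or bounds[-1][1] != self.height_um:
            raise ValueError("layer boundaries must span [0, height]")
        for (a, b), (c, d) in zip(bounds[:-1], bounds[1:]):
            if not b == c:
                raise ValueError("layer boundaries must partition the depth axis")
            if not (b > a and d > c):
                raise ValueError("layers must have positive thickness")


@dataclass(frozen=True)
class LayerSpec:
    """Per-layer density (neurons/mm^3) and excitatory fraction."""

    density_per_mm3: float
    e_fraction: float


# densities chosen so the full-scale column totals 10,073 neurons
DEFAULT_LAYERS: dict[str, LayerSpec] = {
    "L2/3": LayerSpec(124097.4, 0.85),
    "L4": LayerSpec(134921.5, 0.90),
    "L5A": LayerSpec(112652.9, 0.85),
    "L5B": LayerSpec(107333.8, 0.85),
    "L6": LayerSpec(122503.5, 0.90),
}


@dataclass(frozen=True)
class ConnectivityRule:
    """Distance-modulated connection rule between two populations.

    ``pcon`` is the acceptance probability at zero somatic distance;
    acceptance decays as ``exp(-d / lambda_um)``.  ``vcon`` is the unitary
    somatic PSP amplitude (mV) used to scale the synaptic weight, so the
    projection strength is ``Scon = pcon * vcon``.
    """

    pre: str
    post: str
    pcon: float
    vcon_mv: float
    lambda_um: float = 100.0
    border_correction: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.pcon <= 1:
            raise ValueError("pcon must lie in [0, 1]")
        if self.lambda_um <= 0:
            raise ValueError("length constant must be positive")

    @property
    def scon(self) -> float:
        return self.pcon * self.vcon_mv


# class-level default connection parameters (pcon at d=0, unitary PSP mV)
_CLASS_PCON = {("E", "E"): 0.10, ("E", "I"): 0.20,
               ("I", "E"): 0.25, ("I", "I"): 0.25}
_CLASS_VCON = {("E", "E"): 0.5, ("E", "I"): 0.8,
               ("I", "E"): 0.8, ("I", "I"): 1.0}


def default_rules() -> list[ConnectivityRule]:
    rules = []
    pops = E_POPULATIONS + I_POPULATIONS
    for pre in pops:
        for post in pops:
            key = ("E" if pre in E_POPULATIONS else "I",
                   "E" if post in E_POPULATIONS else "I")
            rules.append(ConnectivityRule(pre, post, _CLASS_PCON[key],
                                          _CLASS_VCON[key]))
    return rules


@dataclass(frozen=True)
class DriveSpec:
    """Long-range Poisson drive from one input region.

    Each region holds ``n_generators`` independent Poisson sources whose
    constant rates are drawn uniformly from ``rate_range_hz`` at build
    time; each generator contacts neurons in the target layers with
    probability ``p_connect``.  ``motor_thalamus`` marks the regions whose
    rate range switches to the activated-state value.
    """

    region: str
    rate_range_hz: tuple[float, float]
    target_layers: tuple[str, ...]
    n_generators: int = 1000
    p_connect: float = 0.1
    weight_ns: float = 1.5
    motor_thalamus: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.rate_range_hz
        if lo < 0 or hi < lo:
            raise ValueError("rate range must be 0 <= lo <= hi")


#: activated-state rate range for motor-thalamic regions (uniform 0-10 Hz)
ACTIVATED_THALAMIC_RANGE = (0.0, 10.0)


def default_drives() -> list[DriveSpec]:
    return [
        DriveSpec("VL", (0.0, 2.5), ("L4", "L5B"), motor_thalamus=True),
        DriveSpec("VM", (0.0, 5.0), ("L2/3", "L4", "L5A"), motor_thalamus=True),
        DriveSpec("S1", (0.0, 5.0), ("L2/3", "L5A")),
        DriveSpec("S2", (0.0, 5.0), ("L2/3", "L5A")),
        DriveSpec("cM1", (0.0, 2.5), ("L5B", "L6")),
        DriveSpec("M2", (0.0, 2.5), ("L5B", "L6")),
        DriveSpec("OC", (0.0, 5.0), ("L6",)),
    ]


@dataclass(frozen=True)
class ConditionFlags:
    """Condition switches: disease state and behavioural state.

    ``activated`` doubles the motor-thalamic drive range (uniform 0-10 Hz)
    and scales the PT5B h-like conductance to 25%; ``parkinsonian`` swaps
    the PT5B surrogate parameters for the reduced-excitability calibration.
    """

    parkinsonian: bool = False
    activated: bool = False

    @property
    def ih_scale(self) -> float:
        return 0.25 if self.activated else 1.0

    @property
    def label(self) -> str:
        cond = "parkinsonian" if self.parkinsonian else "control"
        state = "activated" if self.activated else "rest"
        return f"{cond}_{state}"


@dataclass
class NetworkConfig:
    """Complete description of a surrogate network build."""

    geometry: CylinderGeometry = field(default_factory=CylinderGeometry)
    layers: dict[str, LayerSpec] = field(default_factory=lambda: dict(DEFAULT_LAYERS))
    rules: list[ConnectivityRule] = field(default_factory=default_rules)
    drives: list[DriveSpec] = field(default_factory=default_drives)
    scale: float = 1.0  # multiplies all densities

    def validate(self) -> None:
        self.geometry.validate()
        for name in self.layers:
            if name not in self.geometry.layer_bounds_um:
                raise ValueError(f"layer {name!r} has no boundaries")


def default_config(scale: float = 1.0) -> NetworkConfig:
    cfg = NetworkConfig(scale=scale)
    cfg.validate()
    return cfg


def _to_plain(obj):
    if isinstance(obj, (CylinderGeometry, LayerSpec, ConnectivityRule, DriveSpec)):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg: NetworkConfig, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "geometry": _to_plain(cfg.geometry),
        "layers": {k: _to_plain(v) for k, v in cfg.layers.items()},
        "rules": [_to_plain(r) for r in cfg.rules],
        "drives": [_to_plain(d) for d in cfg.drives],
        "scale": cfg.scale,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_config(path: str | Path) -> NetworkConfig:
    doc = yaml.safe_load(Path(path).read_text())
    geo = doc.get("geometry", {})
    geometry = CylinderGeometry(
        diameter_um=geo.get("diameter_um", 300.0),
        height_um=geo.get("height_um", 1350.0),
        layer_bounds_um={k: tuple(v) for k, v in geo.get(
            "layer_bounds_um", CylinderGeometry().layer_bounds_um).items()},
    )
    layers = {k: LayerSpec(**v) for k, v in doc.get("layers", {}).items()} \
        or dict(DEFAULT_LAYERS)
    rules = [ConnectivityRule(**r) for r in doc.get("rules", [])] or default_rules()
    drives = [DriveSpec(**{**d, "rate_range_hz": tuple(d["rate_range_hz"]),
                           "target_layers": tuple(d["target_layers"])})
              for d in doc.get("drives", [])] or default_drives()
    cfg = NetworkConfig(geometry, layers, rules, drives, doc.get("scale", 1.0))
    cfg.validate()
    return cfg
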