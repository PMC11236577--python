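"""Parameter sets for the CA1 PV-interneuron model and variants.

All conductances are specific (mS/cm^2), potentials in mV, times in ms,
capacitance in µF/cm^2, membrane area in cm^2.  Applied currents and
synaptic conductances are given as whole-cell quantities (pA, nS) and
converted to densities through the membrane area.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = ["PVINParameters", "load_params", "builtin_config_path"]

# Layout of the flat float64 vector handed to the compiled integrator.
PARAM_LAYOUT = (
    "C_M", "area", "g_L", "g_Kv3", "g_Kv1", "g_Na",
    "E_L", "E_K", "E_Na", "V_h", "k",
    "tau_m", "tau_p", "tau_q_floor", "tau_scale",
    "tau_q_mode_flag", "tau_q_const", "tau_h_floor", "tau_h_amp",
)


@dataclass(frozen=True)
class PVINParameters:
    """Biophysical constants of the single-compartment PV-IN model.

    The default values are the CA1 variant: Kv3 delayed rectifier and
    transient Na kinetics of the Erisir/Golomb lineage with a slowly
    inactivating Kv1 current whose inactivation time constant grows
    linearly with voltage (``tau_q = k * (V + 105)``, floored).
    """

    C_M: float = 1.0               # µF/cm^2
    area: float = 5.09e-5          # cm^2, fixed so C_total = 50.9 pF
    g_L: float = 0.25              # mS/cm^2
    g_Kv3: float = 223.0           # mS/cm^2
    g_Kv1: float = 5.0             # mS/cm^2
    g_Na: float = 112.5            # mS/cm^2
    E_L: float = -70.0             # mV (calibrated; see docs/methods.md)
    E_K: float = -90.0             # mV
    E_Na: float = 50.0             # mV
    V_h: float = -22.0             # mV, Na activation half-voltage
    k: float = 7.5                 # ms/mV, slope of tau_q
    tau_m: float = 0.001           # ms
    tau_p: float = 0.448           # ms
    tau_h_floor: float = 0.5       # ms, depolarized limit of tau_h
    tau_h_amp: float = 14.0        # ms, hyperpolarized amplitude of tau_h
    tau_q_floor: float = 0.1       # ms, keeps tau_q > 0 below -105 mV
    tau_q_mode: str = "linear"     # "linear" or "constant"
    tau_q_const: float = 150.0     # ms, used only in "constant" mode
    temperature: float = 23.0      # °C
    T_base: float = 23.0           # °C, temperature at which taus are stated
    Q10: float = 2.0
    length_um: float = 126.0       # provenance metadata, not used numerically
    name: str = "ca1_chamberland_modified"

    def __post_init__(self) -> None:
        for g in ("g_L", "g_Kv3", "g_Kv1", "g_Na"):
            if getattr(self, g) < 0:
                raise ValueError(f"{g} must be >= 0, got {getattr(self, g)}")
        if self.area <= 0:
            raise ValueError("area must be > 0")
        for t in ("tau_m", "tau_p", "tau_q_floor"):
            if getattr(self, t) <= 0:
                raise ValueError(f"{t} must be > 0")
        if not (self.E_K < self.E_L < self.E_Na):
            raise ValueError(
                f"reversal potentials must satisfy E_K < E_L < E_Na, got "
                f"E_K={self.E_K}, E_L={self.E_L}, E_Na={self.E_Na}"
            )
        if self.tau_q_mode not in ("linear", "constant"):
            raise ValueError(f"unknown tau_q_mode {self.tau_q_mode!r}")
        if self.Q10 <= 0:
            raise ValueError("Q10 must be > 0")

    # ------------------------------------------------------------------
    @property
    def tau_scale(self) -> float:
        """Factor applied to every gating time constant (Q10 rule)."""
        return self.Q10 ** (-(self.temperature - self.T_base) / 10.0)

    @property
    def C_total_pF(self) -> float:
        return self.C_M * self.area * 1e6  # µF/cm^2 * cm^2 -> µF -> pF

    @property
    def pA_to_uA_per_cm2(self) -> float:
        """Convert a whole-cell current (pA) to a density (µA/cm^2)."""
        return 1e-6 / self.area

    @property
    def nS_to_mS_per_cm2(self) -> float:
        """Convert a whole-cell conductance (nS) to a density (mS/cm^2)."""
        return 1e-6 / self.area

    def replace(self, **changes) -> "PVINParameters":
        return dataclasses.replace(self, **changes)

    def as_vector(self):
        import numpy as np

        vec = np.empty(len(PARAM_LAYOUT), dtype=np.float64)
        for i, key in enumerate(PARAM_LAYOUT):
            if key == "tau_scale":
                vec[i] = self.tau_scale
            elif key == "tau_q_mode_flag":
                vec[i] = 0.0 if self.tau_q_mode == "linear" else 1.0
            else:
                vec[i] = getattr(self, key)
        return vec

    def digest(self) -> str:
        """Short stable hash used to tag result files."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def builtin_config_path(name: str) -> Path:
    """Path of a packaged parameter file (without the .toml suffix)."""
    p = resources.files("pvin") / "configs" / f"{name}.toml"
    return Path(str(p))


def load_params(source: str | Path) -> PVINParameters:
    """Load a parameter set from a TOML file or a built-in config name.

    Built-in names: ``ca1_chamberland_modified`` (default CA1 model),
    ``chamberland_2023`` (pre-modification variant), ``golomb_like``
    (constant 150 ms Kv1 inactivation time constant).
    """
    path = Path(source)
    if not path.suffix:
        path = builtin_config_path(str(source))
    if not path.exists():
        raise FileNotFoundError(f"no parameter config at {path}")
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    model = data.get("model", data)
    valid = {f.name for f in dataclasses.fields(PVINParameters)}
    unknown = set(model) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return PVINParameters(**model)
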