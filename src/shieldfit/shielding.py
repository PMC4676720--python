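"""Boltzmann charge-shielding model of PIP2 availability to PLC.

The substrate (a water-soluble PIP2 analog) is treated as a point charge
with local potential psi (negative).  Cations accumulate around it according
to the Boltzmann factor exp(-z*Y*q*psi / kB*T); the accumulated "effective"
concentration both screens the substrate (Hill-type term with half-maximal
effective concentration L) and binds it chemically (association constant K),
reducing the free substrate seen by the enzyme.  Normalized activity is the
substrate-saturation ratio v(dose)/v(0) with an effective enzyme-substrate
dissociation constant Kd; the neomycin plateau is a residual unshieldable
substrate pool W.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml
from scipy import constants as sc
from scipy import optimize

__all__ = [
    "CationSpec",
    "ShieldingParams",
    "boltzmann_factor",
    "half_maximal_concentration",
    "free_pip2",
    "normalized_activity",
    "asymptotic_activity",
    "ic50",
    "load_default_params",
    "load_default_cations",
]


@dataclass(frozen=True)
class CationSpec:
    """A cation acting on the substrate.

    ``y_factor`` reduces the effective valence of large organic polycations
    (crowding / charge-separation); 1 for small inorganic ions.  ``k_assoc``
    is the association constant (M-1) for chemical binding on the
    effective-concentration scale.
    """

    name: str
    valence: int
    y_factor: float = 1.0
    k_assoc: float = 0.0
    plateau_capable: bool = False

    def __post_init__(self):
        if self.valence < 1:
            raise ValueError("valence must be >= 1")
        if not 0.0 < self.y_factor <= 1.0:
            raise ValueError("Y factor must be in (0, 1]")
        if self.k_assoc < 0:
            raise ValueError("association constant must be >= 0")


@dataclass(frozen=True)
class ShieldingParams:
    """Model parameters shared across cations.

    ``l_ref`` (molar) is the half-maximal effective cation concentration
    anchored at the reference valence ``z_ref`` (the small divalent used to
    calibrate it); for other valences L scales as l_ref * z_ref / z
    (``l_scaling='inverse_valence'``) or stays fixed (``'constant'``).
    ``w`` (molar) is the unshieldable residual substrate (nonzero only for
    plateau-capable cations such as neomycin).
    """

    psi: float = -0.025            # V, local potential of the substrate
    temperature: float = 295.15    # K (room temperature)
    l_ref: float = 0.032           # M
    z_ref: int = 2
    pip2_total: float = 30e-6      # M
    w: float = 0.0                 # M
    kd: float = 50e-6              # M
    l_scaling: str = "inverse_valence"

    def __post_init__(self):
        if self.psi > 0:
            raise ValueError("psi must be <= 0 for a polyanionic substrate")
        if self.temperature <= 0 or self.l_ref <= 0 or self.kd <= 0:
            raise ValueError("temperature, l_ref and kd must be positive")
        if not 0 <= self.w < self.pip2_total:
            raise ValueError("w must satisfy 0 <= w < pip2_total")
        if self.l_scaling not in ("inverse_valence", "constant"):
            raise ValueError(f"unknown l_scaling {self.l_scaling!r}")

    def with_(self, **kwargs) -> "ShieldingParams":
        return replace(self, **kwargs)


def boltzmann_factor(cation: CationSpec, params: ShieldingParams) -> float:
    """Enhancement exp(-z*Y*q*psi / (kB*T)) of the local over the bulk
    concentration; > 1 whenever psi < 0."""
    kt_over_q = sc.Boltzmann * params.temperature / sc.elementary_charge
    return math.exp(-cation.valence * cation.y_factor * params.psi / kt_over_q)


def half_maximal_concentration(cation: CationSpec, params: ShieldingParams) -> float:
    """Valence-scaled half-maximal effective concentration L_z (molar)."""
    if params.l_scaling == "inverse_valence":
        return params.l_ref * params.z_ref / cation.valence
    return params.l_ref


def free_pip2(bulk, cation: CationSpec, params: ShieldingParams):
    """Free (enzyme-accessible) substrate at a bulk cation dose (molar).

    ([PIP2]_tot - W) * L_z/(L_z + C_eff) * 1/(1 + K*C_eff) + W with
    C_eff = bulk * boltzmann_factor; decreasing in dose, bounded in
    [W, PIP2_total].  Accepts scalar or array dose.
    """
    bulk = np.asarray(bulk, dtype=float)
    if np.any(bulk < 0):
        raise ValueError("bulk concentration must be >= 0")
    c_eff = bulk * boltzmann_factor(cation, params)
    lz = half_maximal_concentration(cation, params)
    shield = lz / (lz + c_eff)
    binding = 1.0 / (1.0 + cation.k_assoc * c_eff)
    out = (params.pip2_total - params.w) * shield * binding + params.w
    return float(out) if out.ndim == 0 else out


def _saturation(free_substrate, kd: float):
    return free_substrate / (free_substrate + kd)


def normalized_activity(bulk, cation: CationSpec, params: ShieldingParams):
    """Enzyme activity relative to the cation-free condition, i.e.
    v(dose)/v(0) with v = [free]/([free]+Kd); equals 1 at zero dose."""
    v0 = _saturation(params.pip2_total, params.kd)
    v = _saturation(free_pip2(bulk, cation, params), params.kd)
    return v / v0


def multi_cation_activity(
    doses: dict[str, float], cations: dict[str, CationSpec], params: ShieldingParams
) -> float:
    """Optional multiplicative multi-cation mode: the suppression factors
    L/(L+C_eff) * 1/(1+K*C_eff) of each cation multiply on the shieldable
    substrate pool."""
    suppression = 1.0
    for name, dose in doses.items():
        cat = cations[name]
        c_eff = dose * boltzmann_factor(cat, params)
        lz = half_maximal_concentration(cat, params)
        suppression *= (lz / (lz + c_eff)) / (1.0 + cat.k_assoc * c_eff)
    free = (params.pip2_total - params.w) * suppression + params.w
    return _saturation(free, params.kd) / _saturation(params.pip2_total, params.kd)


def asymptotic_activity(params: ShieldingParams) -> float:
    """Normalized activity in the saturating-dose limit (free substrate -> W)."""
    return _saturation(params.w, params.kd) / _saturation(params.pip2_total, params.kd)


def ic50(
    cation: CationSpec,
    params: ShieldingParams,
    rel_tol: float = 1e-6,
) -> float | None:
    """Bulk dose (molar) at which normalized activity crosses 0.5, by
    bracketing and bisection on log dose; None when the plateau sits above
    half-inhibition."""
    if asymptotic_activity(params) >= 0.5:
        return None
    lo, hi = -12.0, 0.0  # log10 molar bracket
    while normalized_activity(10.0**hi, cation, params) > 0.5:
        hi += 1.0
        if hi > 6.0:  # pragma: no cover - unreachable with finite asymptote < 0.5
            return None
    while normalized_activity(10.0**lo, cation, params) < 0.5:
        lo -= 1.0
    f = lambda lx: normalized_activity(10.0**lx, cation, params) - 0.5
    lx = optimize.brentq(f, lo, hi, xtol=rel_tol / 10, rtol=8.9e-16)
    x = 10.0**lx
    # polish on the linear scale to the stated relative tolerance
    return float(optimize.brentq(
        lambda b: normalized_activity(b, cation, params) - 0.5,
        x * (1 - 1e-3), x * (1 + 1e-3), rtol=rel_tol,
    ))


def load_default_params(path=None) -> ShieldingParams:
    """Packaged reference parameter set (psi = -25 mV, L_ref = 32 mM,
    Kd = 50 uM, substrate total 30 uM), or the same schema from ``path``."""
    params, _ = _load_defaults(path)
    return params


def load_default_cations(path=None) -> dict[str, CationSpec]:
    """Packaged per-cation valence / Y / K reference values."""
    _, cations = _load_defaults(path)
    return cations


def _load_defaults(path=None) -> tuple[ShieldingParams, dict[str, CationSpec]]:
    if path is None:
        with resources.files("shieldfit.data").joinpath("default_params.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    p = raw["shielding"]
    params = ShieldingParams(
        psi=p["psi_mV"] * 1e-3,
        temperature=p["temperature_K"],
        l_ref=p["l_ref_mM"] * 1e-3,
        z_ref=p["z_ref"],
        pip2_total=p["pip2_total_uM"] * 1e-6,
        kd=p["kd_uM"] * 1e-6,
        w=0.0,
    )
    cations = {}
    for name, c in raw["cations"].items():
        cations[name] = CationSpec(
            name=name,
            valence=c["valence"],
            y_factor=c["y_factor"],
            k_assoc=c["k_assoc_per_M"],
            plateau_capable=c.get("plateau_capable", False),
        )
    return params, cations


def default_w_uM(path=None) -> float:
    """Reference plateau (unshieldable substrate) for neomycin, in uM."""
    if path is None:
        with resources.files("shieldfit.data").joinpath("default_params.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return float(raw["shielding"]["w_neomycin_uM"])
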