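"""Synthetic data with the statistical structure the analysis assumes.

Two generators: (1) noisy normalized dose-response curves drawn from the
shielding model with i.i.d. Gaussian replicate noise, and (2) fluorogenic
Michaelis-Menten progress curves passed through a linear fluorescence
standard curve.  All randomness flows through one seeded generator per call,
so datasets are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import lambertw

from shieldfit.fitting import DoseResponseDataset
from shieldfit.shielding import CationSpec, ShieldingParams, normalized_activity

__all__ = [
    "NoiseModel",
    "TimeCourseSpec",
    "default_dose_grid",
    "generate_dose_response",
    "generate_time_course",
    "mm_progress_product",
]

ACTIVITY_FLOOR = -0.05  # normalized-activity clip applied to noisy replicates


@dataclass(frozen=True)
class NoiseModel:
    """Replicate structure of the enzyme assay: n replicates per dose with
    additive Gaussian noise on normalized activity (default SD 0.05,
    emulating 4-8 replicates per condition)."""

    n_replicates: int = 6
    sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.sd < 0:
            raise ValueError("noise SD must be >= 0")


def default_dose_grid(cation: CationSpec, n: int = 12) -> np.ndarray:
    """Log-spaced bulk-dose grid spanning the ranges probed experimentally:
    10 uM - 100 mM for small divalents, 0.1 uM - 10 mM for neomycin and
    other high-valence organics."""
    if cation.valence >= 6 or cation.plateau_capable:
        lo, hi = 1e-7, 1e-2
    elif cation.valence > 2:
        lo, hi = 1e-6, 3e-2
    else:
        # small divalents and divalent organics (putrescine) inhibit only in
        # the tens-of-millimolar range
        lo, hi = 1e-5, 1e-1
    return np.logspace(np.log10(lo), np.log10(hi), n)


def generate_dose_response(
    cation: CationSpec,
    params: ShieldingParams,
    doses: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    enzyme: str = "PLCb1",
) -> DoseResponseDataset:
    """Draw a noisy dose-response dataset from the shielding model.

    Replicates are model(dose) + N(0, sd), clipped below at -0.05; the
    reported activity at each dose is the replicate mean.  With sd = 0 the
    dataset equals the model curve exactly.
    """
    if doses is None:
        doses = default_dose_grid(cation)
    doses = np.asarray(doses, dtype=float)
    model = np.asarray(normalized_activity(doses, cation, params), dtype=float)
    rng = np.random.default_rng(noise.seed)
    reps = model[:, None] + noise.sd * rng.standard_normal((doses.size, noise.n_replicates))
    reps = np.clip(reps, ACTIVITY_FLOOR, None)
    means = np.clip(reps.mean(axis=1), ACTIVITY_FLOOR, 1.2)
    return DoseResponseDataset(
        enzyme=enzyme,
        cation=cation,
        doses=doses,
        activities=means,
        replicate_sd=reps.std(axis=1, ddof=1) if noise.n_replicates > 1 else None,
        n_replicates=np.full(doses.size, noise.n_replicates),
        replicates=reps,
        provenance=f"synthetic(seed={noise.seed}, sd={noise.sd}, "
                   f"cation={cation.name}, l_ref={params.l_ref})",
    )


@dataclass(frozen=True)
class TimeCourseSpec:
    """Specification of a fluorogenic progress-curve experiment."""

    enzyme_ng: float                  # enzyme per reaction
    specific_activity: float          # mol product min-1 mg-1
    km: float                         # M
    substrate_total: float = 30e-6    # M
    times_min: np.ndarray | tuple = tuple(np.arange(0.0, 91.0, 1.0))
    volume_l: float = 20e-6
    slope_au_per_m: float = 1e7       # fluorescence AU per molar product
    intercept_au: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "times_min", np.asarray(self.times_min, dtype=float))
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        for name in ("specific_activity", "km", "substrate_total", "volume_l",
                     "slope_au_per_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.enzyme_ng < 0:
            raise ValueError("enzyme amount must be >= 0")

    @property
    def vmax(self) -> float:
        """Maximal rate in molar per minute."""
        return self.enzyme_ng * 1e-6 * self.specific_activity / self.volume_l


def mm_progress_product(spec: TimeCourseSpec, times_min: np.ndarray | None = None) -> np.ndarray:
    """Closed-form product concentration P(t) of the irreversible
    Michaelis-Menten progress curve dS/dt = -Vmax*S/(Km+S).

    The implicit solution Km*ln(S0/S) + (S0-S) = Vmax*t inverts to
    S(t) = Km * W((S0/Km) * exp((S0 - Vmax t)/Km)) with W the principal
    Lambert function.
    """
    t = spec.times_min if times_min is None else np.asarray(times_min, float)
    s0, km, vmax = spec.substrate_total, spec.km, spec.vmax
    if vmax == 0:
        return np.zeros_like(t)
    # evaluate W(exp(log_arg)) stably for large arguments via the asymptotic
    # expansion W(e^x) ~ x - log(x) + log(x)/x for x >> 1
    log_arg = np.log(s0 / km) + (s0 - vmax * t) / km
    s = np.empty_like(t)
    small = log_arg < 50
    s[small] = km * np.real(lambertw(np.exp(log_arg[small])))
    x = log_arg[~small]
    lx = np.log(x)
    s[~small] = km * (x - lx + lx / x)
    return s0 - s


def generate_time_course(
    spec: TimeCourseSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fluorescence time series for a progress-curve experiment.

    fluorescence = slope * P(t) + intercept + N(0, noise_sd); columns
    ``time_min`` and ``fluorescence_au``.
    """
    product = mm_progress_product(spec)
    rng = np.random.default_rng(seed)
    fluo = spec.slope_au_per_m * product + spec.intercept_au
    if noise_sd > 0:
        fluo = fluo + noise_sd * rng.standard_normal(fluo.shape)
    return pd.DataFrame({"time_min": spec.times_min, "fluorescence_au": fluo})
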