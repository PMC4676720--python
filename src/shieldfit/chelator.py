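"""Free-ion speciation for chelator-buffered assay solutions.

Solves the simultaneous mass-action / mass-balance system for mixtures of
metals (Ca2+, Mg2+, Ba2+, ...) and chelating ligands (EGTA, ...) at a fixed
pH, ionic strength and temperature, the calculation Ca2+-buffer calculators
such as Maxchelator perform.  Protonation of the ligand is folded into an
apparent (conditional) association constant per metal-ligand pair; ionic
strength is handled with a Davies-equation activity correction and
temperature with a van't Hoff correction when enthalpies are available.

All concentrations are molar internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "BindingConstantRecord",
    "AssaySolution",
    "SpeciationResult",
    "SpeciationError",
    "MissingConstantError",
    "apparent_constant",
    "solve_speciation",
    "load_constants",
    "debye_huckel_a",
]

R_GAS = 8.31446261815324  # J mol-1 K-1
LN10 = math.log(10.0)


class SpeciationError(RuntimeError):
    """Raised when the speciation solver fails to converge; carries the last
    relative residual norm in ``residual``."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class MissingConstantError(KeyError):
    def __init__(self, metal: str, ligand: str):
        super().__init__(f"no binding-constant record for ({metal}, {ligand})")
        self.pair = (metal, ligand)


@dataclass(frozen=True)
class BindingConstantRecord:
    """Stability constants for one metal-ligand pair.

    ``log_k_ml`` refers to M + L -> ML and ``log_k_mhl`` to M + HL -> MHL,
    both on the concentration scale at the stated reference ionic strength
    and temperature.  ``pkas`` are the ligand protonation constants in
    strictly decreasing order (pKa1 first).  Enthalpies (kJ/mol, optional)
    enable van't Hoff temperature adjustment.
    """

    ligand: str
    metal: str
    log_k_ml: float
    pkas: tuple[float, ...]
    metal_charge: int
    ligand_charge: int
    log_k_mhl: float | None = None
    ref_ionic_strength: float = 0.1
    ref_temperature: float = 293.15
    dh_ml: float | None = None
    dh_mhl: float | None = None
    dh_pkas: tuple[float, ...] | None = None
    source: str = ""

    def __post_init__(self):
        if not math.isfinite(self.log_k_ml):
            raise ValueError("log_k_ml must be finite")
        if any(not math.isfinite(p) for p in self.pkas):
            raise ValueError("pKa values must be finite")
        if any(a <= b for a, b in zip(self.pkas[1:], self.pkas[2:])):
            # strictly decreasing below pKa1; pKa1 >= pKa2 enforced too
            raise ValueError("pKa list must be strictly decreasing")
        if len(self.pkas) >= 2 and self.pkas[0] <= self.pkas[1]:
            raise ValueError("pKa list must be strictly decreasing")
        if not (self.ref_ionic_strength > 0 and self.ref_temperature > 0):
            raise ValueError("reference conditions must be positive")


@dataclass(frozen=True)
class AssaySolution:
    """Total (added) composition of an assay solution.

    Species not listed (HEPES, KCl, DTT, BSA...) are treated as inert except
    through the stated ionic strength.
    """

    metals: dict[str, float]
    ligands: dict[str, float]
    ph: float
    ionic_strength: float
    temperature: float = 293.15

    def __post_init__(self):
        for name, tot in {**self.metals, **self.ligands}.items():
            if tot < 0:
                raise ValueError(f"total concentration of {name} is negative")
        if not 0 < self.ph < 14:
            raise ValueError(f"pH {self.ph} outside (0, 14)")
        if self.ionic_strength <= 0:
            raise ValueError("ionic strength must be positive")
        if not 273.0 <= self.temperature <= 320.0:
            raise ValueError("temperature outside [273, 320] K")


@dataclass
class SpeciationResult:
    free_metal: dict[str, float]
    bound: dict[tuple[str, str], float]
    free_ligand: dict[str, float]
    converged: bool
    residual_norm: float
    apparent_constants: dict[tuple[str, str], float] = field(default_factory=dict)


def debye_huckel_a(temperature: float) -> float:
    """Debye-Hueckel limiting-law constant A (log10 scale) for water.

    Uses the empirical dielectric constant of water; A ~ 0.509 at 25 C,
    ~ 0.505 at 20 C.
    """
    t = temperature - 273.15
    eps = 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3
    return 1.82483e6 / (eps * temperature) ** 1.5


def _davies_f(ionic_strength: float) -> float:
    s = math.sqrt(ionic_strength)
    return s / (1.0 + s) - 0.3 * ionic_strength


def _adjust_logk(
    logk: float,
    delta_z2: float,
    record: BindingConstantRecord,
    ionic_strength: float,
    temperature: float,
    dh: float | None,
) -> float:
    """Move a log10 concentration constant from the record's reference
    conditions to (ionic_strength, temperature).

    ``delta_z2`` is sum(z_reactants^2) - sum(z_products^2) for the
    association as written; the Davies correction is
    logK(I) = logK(I_ref) + delta_z2 * (A_ref f(I_ref) - A f(I)).
    """
    a_ref = debye_huckel_a(record.ref_temperature)
    a = debye_huckel_a(temperature)
    out = logk + delta_z2 * (
        a_ref * _davies_f(record.ref_ionic_strength) - a * _davies_f(ionic_strength)
    )
    if dh is not None:
        out -= (dh * 1e3 / (LN10 * R_GAS)) * (1.0 / temperature - 1.0 / record.ref_temperature)
    return out


def _adjusted_pkas(
    record: BindingConstantRecord, ionic_strength: float, temperature: float
) -> list[float]:
    pkas = []
    for j, pka in enumerate(record.pkas, start=1):
        # H+ + H_{j-1}L -> H_jL ; charges: +1, b+j-1 -> b+j
        b = record.ligand_charge
        dz2 = 1 + (b + j - 1) ** 2 - (b + j) ** 2
        dh = record.dh_pkas[j - 1] if record.dh_pkas else None
        pkas.append(_adjust_logk(pka, dz2, record, ionic_strength, temperature, dh))
    return pkas


def proton_competition_factor(
    record: BindingConstantRecord,
    ph: float,
    ionic_strength: float | None = None,
    temperature: float | None = None,
) -> float:
    """alpha_H = [L]_pooled / [L^b-]: the factor by which ligand protonation
    dilutes the fully deprotonated species at the given pH."""
    ionic_strength = ionic_strength or record.ref_ionic_strength
    temperature = temperature or record.ref_temperature
    pkas = _adjusted_pkas(record, ionic_strength, temperature)
    alpha, cum = 1.0, 0.0
    for j, pka in enumerate(pkas, start=1):
        cum += pka
        alpha += 10.0 ** (cum - j * ph)
    return alpha


def apparent_constant(
    record: BindingConstantRecord,
    ph: float,
    ionic_strength: float,
    temperature: float,
) -> float:
    """Apparent (conditional) association constant K_app (M-1) of the metal
    for the pooled free ligand (all protonation states) at the given pH,
    ionic strength and temperature.

    Includes the ML and, when tabulated, the protonated MHL complex;
    monotone increasing in pH over the range where acidic protons compete.
    """
    if not 0 < ph < 14:
        raise ValueError(f"pH {ph} outside (0, 14)")
    if ionic_strength <= 0 or temperature <= 0:
        raise ValueError("ionic strength and temperature must be positive")
    zm, b = record.metal_charge, record.ligand_charge
    dz2_ml = zm**2 + b**2 - (zm + b) ** 2
    log_kml = _adjust_logk(
        record.log_k_ml, dz2_ml, record, ionic_strength, temperature, record.dh_ml
    )
    numerator = 10.0**log_kml
    pkas = _adjusted_pkas(record, ionic_strength, temperature)
    if record.log_k_mhl is not None:
        dz2_mhl = zm**2 + (b + 1) ** 2 - (zm + b + 1) ** 2
        log_kmhl = _adjust_logk(
            record.log_k_mhl, dz2_mhl, record, ionic_strength, temperature, record.dh_mhl
        )
        # [HL]/[L] at this pH weights the MHL route
        numerator += 10.0**log_kmhl * 10.0 ** (pkas[0] - ph)
    alpha, cum = 1.0, 0.0
    for j, pka in enumerate(pkas, start=1):
        cum += pka
        alpha += 10.0 ** (cum - j * ph)
    return numerator / alpha


def load_constants() -> list[BindingConstantRecord]:
    """Load the packaged stability-constant table (TSV)."""
    with resources.files("shieldfit.data").joinpath("stability_constants.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    records = []
    for _, row in table.iterrows():
        records.append(
            BindingConstantRecord(
                ligand=row["ligand"],
                metal=row["metal"],
                log_k_ml=float(row["log_k_ml"]),
                log_k_mhl=None if pd.isna(row["log_k_mhl"]) else float(row["log_k_mhl"]),
                pkas=tuple(float(x) for x in str(row["pkas"]).split(",")),
                metal_charge=int(row["metal_charge"]),
                ligand_charge=int(row["ligand_charge"]),
                ref_ionic_strength=float(row["ref_ionic_strength"]),
                ref_temperature=float(row["ref_temperature_k"]),
                dh_ml=None if pd.isna(row["dh_ml_kj"]) else float(row["dh_ml_kj"]),
                dh_pkas=(
                    None
                    if pd.isna(row["dh_pkas_kj"])
                    else tuple(float(x) for x in str(row["dh_pkas_kj"]).split(","))
                ),
                source=str(row["source"]),
            )
        )
    return records


def _constant_map(
    solution: AssaySolution, constants: list[BindingConstantRecord]
) -> dict[tuple[str, str], float]:
    lookup = {(r.metal, r.ligand): r for r in constants}
    kapp: dict[tuple[str, str], float] = {}
    for metal in solution.metals:
        for ligand in solution.ligands:
            rec = lookup.get((metal, ligand))
            if rec is None:
                raise MissingConstantError(metal, ligand)
            kapp[(metal, ligand)] = apparent_constant(
                rec, solution.ph, solution.ionic_strength, solution.temperature
            )
    return kapp


def solve_speciation(
    solution: AssaySolution,
    constants: list[BindingConstantRecord] | None = None,
    rel_tol: float = 1e-12,
    max_iter: int = 200,
) -> SpeciationResult:
    """Solve the coupled mass-action / mass-balance system for free metal and
    (pooled) free ligand concentrations.

    Newton-type iteration on log10 free concentrations (positivity
    preserving); converged when every relative mass-balance residual is
    below ``rel_tol``.
    """
    if constants is None:
        constants = load_constants()
    kapp = _constant_map(solution, constants)

    metals = [m for m, tot in solution.metals.items() if tot > 0]
    ligands = [l for l, tot in solution.ligands.items() if tot > 0]
    m_tot = np.array([solution.metals[m] for m in metals])
    l_tot = np.array([solution.ligands[l] for l in ligands])
    nm, nl = len(metals), len(ligands)
    kmat = np.array(
        [[kapp.get((m, l), 0.0) for l in ligands] for m in metals]
    ).reshape(nm, nl)

    free_metal = {m: 0.0 for m in solution.metals}
    free_ligand = {l: 0.0 for l in solution.ligands}
    bound = {(m, l): 0.0 for m in solution.metals for l in solution.ligands}

    if nm == 0 and nl == 0:
        return SpeciationResult(free_metal, bound, free_ligand, True, 0.0, kapp)
    if nl == 0 or nm == 0:
        for m, tot in zip(metals, m_tot):
            free_metal[m] = tot
        for l, tot in zip(ligands, l_tot):
            free_ligand[l] = tot
        return SpeciationResult(free_metal, bound, free_ligand, True, 0.0, kapp)

    totals = np.concatenate([m_tot, l_tot])

    def residual(log_free: np.ndarray) -> np.ndarray:
        mf = 10.0 ** log_free[:nm]
        lf = 10.0 ** log_free[nm:]
        m_calc = mf * (1.0 + kmat @ lf)
        l_calc = lf * (1.0 + kmat.T @ mf)
        return (np.concatenate([m_calc, l_calc]) - totals) / totals

    # damped fixed-point pass (positivity preserving) to seed Newton
    mf = m_tot.copy()
    lf = l_tot.copy()
    for _ in range(500):
        mf_new = m_tot / (1.0 + kmat @ lf)
        lf_new = l_tot / (1.0 + kmat.T @ mf)
        mf = np.sqrt(mf * mf_new)  # geometric damping
        lf = np.sqrt(lf * lf_new)
    x0 = np.log10(np.concatenate([mf, lf]))
    sol = optimize.root(residual, x0, method="hybr", options={"xtol": 1e-15, "maxfev": 200 * (nm + nl)})
    x = sol.x
    res = residual(x)
    # polish with damped Newton if hybr stopped short of the tight tolerance
    it = 0
    while np.max(np.abs(res)) > rel_tol and it < max_iter:
        jac = optimize.approx_fprime(x, residual, 1e-9)
        try:
            step = np.linalg.solve(jac, -res)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -1.0, 1.0)
        x = x + step
        res = residual(x)
        it += 1
    norm = float(np.max(np.abs(res)))
    if norm > rel_tol * 10:
        raise SpeciationError(
            f"speciation did not converge (relative residual {norm:.3e})", norm
        )

    mf = 10.0 ** x[:nm]
    lf = 10.0 ** x[nm:]
    for m, v in zip(metals, mf):
        free_metal[m] = float(v)
    for l, v in zip(ligands, lf):
        free_ligand[l] = float(v)
    for i, m in enumerate(metals):
        for j, l in enumerate(ligands):
            bound[(m, l)] = float(kmat[i, j] * mf[i] * lf[j])
    return SpeciationResult(free_metal, bound, free_ligand, norm <= rel_tol * 10, norm, kapp)
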