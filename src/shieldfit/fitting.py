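"""Staged nonlinear least-squares estimation of the shielding parameters.

The estimation mirrors how the model was calibrated experimentally:

1. stage L  - the half-maximal effective concentration L is fitted on
   reference-divalent (Mg2+) dose-response curves, one L per enzyme, then
   averaged;
2. stage K  - with L frozen, the chemical association constant K is fitted
   per cation;
3. stage Y  - the organic-cation accumulation factor Y is fitted jointly
   with putrescine's K against a putrescine / reference-divalent pair and
   then frozen for all organic polycations;
4. stage W  - the unshieldable-substrate plateau W is fitted on neomycin
   curves.

The local potential psi and the enzyme-substrate Kd are never fitted
(identifiability: a rescaling of psi can be absorbed exactly into L and K).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from shieldfit.shielding import (
    CationSpec,
    ShieldingParams,
    ic50,
    load_default_cations,
    normalized_activity,
)
from shieldfit.units import to_molar

__all__ = [
    "DoseResponseDataset",
    "FitResult",
    "fit_stage_L",
    "fit_stage_K",
    "fit_stage_Y",
    "fit_stage_W",
    "staged_fit",
    "joint_fit",
    "bootstrap_ci",
    "read_dose_response_csv",
    "write_dose_response_csv",
]

_FLAT_SIGNAL = 1e-3  # activity span below which a curve carries no information


@dataclass
class DoseResponseDataset:
    """Normalized-activity dose-response curve for one enzyme x cation."""

    enzyme: str
    cation: CationSpec
    doses: np.ndarray
    activities: np.ndarray
    replicate_sd: np.ndarray | None = None
    n_replicates: np.ndarray | None = None
    replicates: np.ndarray | None = None  # (n_doses, n_rep) raw replicate values
    provenance: str = "measured"

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.doses.size < 4:
            raise ValueError("at least 4 dose levels are required")
        if np.any(self.doses < 0) or np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be >= 0 and strictly increasing")
        if np.any(self.activities < -0.05) or np.any(self.activities > 1.2):
            raise ValueError("normalized activities outside [-0.05, 1.2]")
        if self.doses.shape != self.activities.shape:
            raise ValueError("doses and activities must have equal length")

    @property
    def label(self) -> str:
        return f"{self.enzyme}:{self.cation.name}"

    def with_activities(self, activities: np.ndarray) -> "DoseResponseDataset":
        return dataclasses.replace(self, activities=np.asarray(activities, float),
                                   replicates=None)


@dataclass
class FitResult:
    """Parameter estimates with stage provenance and fit diagnostics."""

    parameters: dict[str, float]
    stages: dict[str, str]
    fixed: dict[str, float]
    rss: dict[str, float] = field(default_factory=dict)
    ic50s: dict[str, float | None] = field(default_factory=dict)
    diagnostics: dict[str, object] = field(default_factory=dict)
    bootstrap: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("success", False))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": k, "estimate": v, "stage": self.stages.get(k, "")}
            for k, v in self.parameters.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model evaluation and generic bounded least squares
# ---------------------------------------------------------------------------

def _curve(dataset: DoseResponseDataset, params: ShieldingParams,
           cation: CationSpec | None = None) -> np.ndarray:
    return normalized_activity(dataset.doses, cation or dataset.cation, params)


def _residuals(dataset, params, cation=None, weighted=False):
    r = _curve(dataset, params, cation) - dataset.activities
    if weighted and dataset.replicate_sd is not None:
        sd = np.where(dataset.replicate_sd > 0, dataset.replicate_sd, np.inf)
        r = r / sd
    return r


def _grid_start(objective, lo: float, hi: float, n: int = 60) -> float:
    grid = np.logspace(np.log10(lo), np.log10(hi), n) if lo > 0 else np.linspace(lo, hi, n)
    sse = [float(np.sum(objective(g) ** 2)) for g in grid]
    return float(grid[int(np.argmin(sse))])


def _bounded_fit(objective, x0, bounds):
    sol = least_squares(objective, x0, bounds=bounds, method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, x_scale="jac")
    sol.cost_path = (float(np.sum(np.asarray(objective(np.asarray(x0))) ** 2)) / 2,
                     float(sol.cost))
    x = np.atleast_1d(sol.x)
    lo, hi = np.atleast_1d(bounds[0]), np.atleast_1d(bounds[1])
    at_bound = []
    for v, l, h in zip(x, lo, hi):
        span = (h - l) if np.isfinite(h) else max(1.0, abs(v))
        tol = max(1e-8 * span, 1e-10)
        at_bound.append(bool((v - l) <= tol or (np.isfinite(h) and (h - v) <= tol)))
    return sol, at_bound


def _signal_span(dataset: DoseResponseDataset) -> float:
    return float(np.max(dataset.activities) - np.min(dataset.activities))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def fit_stage_L(
    datasets: list[DoseResponseDataset],
    params: ShieldingParams,
    bounds_mM: tuple[float, float] = (0.1, 1000.0),
    weighted: bool = False,
) -> FitResult:
    """Stage 1: estimate L per enzyme on reference-divalent curves, then
    average.  The cation's K stays at its (small) reference value."""
    per_enzyme: dict[str, float] = {}
    diags: dict[str, object] = {"success": True, "boundary": [], "warnings": []}
    rss: dict[str, float] = {}
    lo, hi = bounds_mM[0] * 1e-3, bounds_mM[1] * 1e-3
    for ds in datasets:
        if _signal_span(ds) < _FLAT_SIGNAL:
            diags["success"] = False
            diags["warnings"].append(f"{ds.label}: flat curve, L not identifiable")
            per_enzyme[ds.enzyme] = float("nan")
            continue

        def obj(l_ref, ds=ds):
            l_ref = float(np.atleast_1d(l_ref)[0])
            return _residuals(ds, params.with_(l_ref=l_ref), weighted=weighted)

        x0 = _grid_start(obj, lo, hi)
        sol, at_bound = _bounded_fit(obj, [x0], ([lo], [hi]))
        diags.setdefault("cost_path", []).append(sol.cost_path)
        per_enzyme[ds.enzyme] = float(sol.x[0])
        rss[ds.label] = float(2 * sol.cost)
        diags["success"] = diags["success"] and sol.success
        if any(at_bound):
            diags["boundary"].append(f"{ds.label}:L")
        # ill-conditioning check: need doses on both sides of the transition
        in_transition = np.sum((ds.activities > 0.2) & (ds.activities < 0.8))
        if in_transition < 2:
            diags["warnings"].append(f"{ds.label}: <2 doses in transition region")
    values = [v for v in per_enzyme.values() if np.isfinite(v)]
    l_avg = float(np.mean(values)) if values else float("nan")
    return FitResult(
        parameters={"L_ref": l_avg, **{f"L:{e}": v for e, v in per_enzyme.items()}},
        stages={"L_ref": "stage-1", **{f"L:{e}": "stage-1" for e in per_enzyme}},
        fixed={"psi": params.psi, "kd": params.kd, "pip2_total": params.pip2_total},
        rss=rss,
        diagnostics=diags,
    )


def fit_stage_K(
    dataset: DoseResponseDataset,
    params: ShieldingParams,
    k_max: float = 1e6,
    weighted: bool = False,
) -> FitResult:
    """Stage 2: with L (and W, Y) frozen, estimate the cation's association
    constant K >= 0 by least squares."""
    diags: dict[str, object] = {"success": True, "boundary": [], "warnings": []}
    if _signal_span(dataset) < _FLAT_SIGNAL:
        diags["success"] = False
        diags["warnings"].append(f"{dataset.label}: flat curve, K not identifiable")
        k_est, rss = float("nan"), float("nan")
    else:
        def obj(k):
            k = float(np.atleast_1d(k)[0])
            cat = replace(dataset.cation, k_assoc=k)
            return _residuals(dataset, params, cation=cat, weighted=weighted)

        x0 = max(_grid_start(obj, 1e-3, k_max), 1e-3)
        sol, at_bound = _bounded_fit(obj, [x0], ([0.0], [k_max]))
        diags.setdefault("cost_path", []).append(sol.cost_path)
        k_est, rss = float(sol.x[0]), float(2 * sol.cost)
        diags["success"] = sol.success
        if at_bound[0]:
            diags["boundary"].append(f"{dataset.label}:K")
    name = f"K:{dataset.cation.name}"
    return FitResult(
        parameters={name: k_est},
        stages={name: "stage-2"},
        fixed={"psi": params.psi, "kd": params.kd, "L_ref": params.l_ref},
        rss={dataset.label: rss},
        diagnostics=diags,
    )


def fit_stage_Y(
    organic_dataset: DoseResponseDataset,
    reference_dataset: DoseResponseDataset,
    params: ShieldingParams,
    k_max: float = 1e6,
    weighted: bool = False,
) -> FitResult:
    """Stage 3: estimate the accumulation factor Y of a large organic cation
    jointly with its K, against a small-divalent reference curve for the
    same enzyme.  Y is then frozen for all organic polycations."""
    if organic_dataset.enzyme != reference_dataset.enzyme:
        raise ValueError("stage-Y pair must share the enzyme")
    diags: dict[str, object] = {"success": True, "boundary": [], "warnings": []}

    def obj(x):
        y, k = float(x[0]), float(x[1])
        cat = replace(organic_dataset.cation, y_factor=y, k_assoc=k)
        r_org = _residuals(organic_dataset, params, cation=cat, weighted=weighted)
        r_ref = _residuals(reference_dataset, params, weighted=weighted)
        return np.concatenate([r_org, r_ref])

    # coarse 2-D scan over (Y, K) for a start; Y and K are only weakly
    # separable for divalent organics, so a joint scan avoids collapsing
    # onto a bound
    y_grid = np.linspace(0.02, 1.0, 25)
    k_grid = np.concatenate([[0.0], np.logspace(-3, 4, 22)])
    best, y0, k0 = np.inf, 0.5, max(organic_dataset.cation.k_assoc, 1e-3)
    for y in y_grid:
        for k in k_grid:
            sse = float(np.sum(obj([y, k]) ** 2))
            if sse < best:
                best, y0, k0 = sse, float(y), float(max(k, 1e-3))
    sol, at_bound = _bounded_fit(obj, [y0, k0], ([1e-6, 0.0], [1.0, k_max]))
    diags.setdefault("cost_path", []).append(sol.cost_path)
    diags["success"] = sol.success
    if at_bound[0]:
        diags["boundary"].append(f"{organic_dataset.label}:Y")
    if at_bound[1]:
        diags["boundary"].append(f"{organic_dataset.label}:K")
    kname = f"K:{organic_dataset.cation.name}"
    return FitResult(
        parameters={"Y": float(sol.x[0]), kname: float(sol.x[1])},
        stages={"Y": "stage-3", kname: "stage-3"},
        fixed={"psi": params.psi, "kd": params.kd, "L_ref": params.l_ref},
        rss={organic_dataset.label: float(2 * sol.cost)},
        diagnostics=diags,
    )


def fit_stage_W(
    dataset: DoseResponseDataset,
    params: ShieldingParams,
    fit_k: bool = False,
    k_max: float = 1e6,
    weighted: bool = False,
) -> FitResult:
    """Stage 4: estimate the unshieldable-substrate plateau W in
    [0, PIP2_total) for a plateau-capable cation (neomycin); optionally
    refit the cation's K jointly."""
    if not dataset.cation.plateau_capable:
        raise ValueError(f"{dataset.cation.name} is not flagged plateau-capable")
    diags: dict[str, object] = {"success": True, "boundary": [], "warnings": []}
    w_hi = params.pip2_total * (1 - 1e-9)

    if fit_k:
        def obj(x):
            w, k = float(x[0]), float(x[1])
            cat = replace(dataset.cation, k_assoc=k)
            return _residuals(dataset, params.with_(w=w), cation=cat, weighted=weighted)

        k0 = max(dataset.cation.k_assoc, 1e-3)
        sol, at_bound = _bounded_fit(obj, [params.pip2_total / 10, k0],
                                     ([0.0, 0.0], [w_hi, k_max]))
        parameters = {"W": float(sol.x[0]), f"K:{dataset.cation.name}": float(sol.x[1])}
        stages = {"W": "stage-4", f"K:{dataset.cation.name}": "stage-4"}
        bound_names = ["W", "K"]
    else:
        def obj(w):
            w = float(np.atleast_1d(w)[0])
            return _residuals(dataset, params.with_(w=w), weighted=weighted)

        x0 = _grid_start(obj, params.pip2_total * 1e-4, w_hi)
        sol, at_bound = _bounded_fit(obj, [x0], ([0.0], [w_hi]))
        parameters = {"W": float(sol.x[0])}
        stages = {"W": "stage-4"}
        bound_names = ["W"]
    diags.setdefault("cost_path", []).append(sol.cost_path)
    diags["success"] = sol.success
    for flag, nm in zip(at_bound, bound_names):
        if flag:
            diags["boundary"].append(f"{dataset.label}:{nm}")
    return FitResult(
        parameters=parameters,
        stages=stages,
        fixed={"psi": params.psi, "kd": params.kd, "L_ref": params.l_ref,
               "Y": dataset.cation.y_factor},
        rss={dataset.label: float(2 * sol.cost)},
        diagnostics=diags,
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def staged_fit(
    datasets: list[DoseResponseDataset],
    params: ShieldingParams,
    reference_cation: str = "Mg",
    organic_reference: str = "putrescine",
    weighted: bool = False,
    compute_ic50: bool = True,
) -> FitResult:
    """Run the full L -> K -> Y -> W staged pipeline on a collection of
    dose-response datasets and merge the stage fragments."""
    by_cation: dict[str, list[DoseResponseDataset]] = {}
    for ds in datasets:
        by_cation.setdefault(ds.cation.name, []).append(ds)
    if reference_cation not in by_cation:
        raise ValueError(f"no {reference_cation} datasets for stage 1")

    result = fit_stage_L(by_cation[reference_cation], params, weighted=weighted)
    params = params.with_(l_ref=result.parameters["L_ref"])

    y_frozen: float | None = None
    if organic_reference in by_cation:
        org = by_cation[organic_reference][0]
        ref_enzyme = [d for d in by_cation[reference_cation] if d.enzyme == org.enzyme]
        frag = fit_stage_Y(org, ref_enzyme[0] if ref_enzyme else by_cation[reference_cation][0],
                           params, weighted=weighted)
        y_frozen = frag.parameters["Y"]
        _merge(result, frag)

    for name, group in by_cation.items():
        if name in (reference_cation, organic_reference):
            continue
        for ds in group:
            cat = ds.cation if y_frozen is None or ds.cation.y_factor == 1.0 \
                else replace(ds.cation, y_factor=y_frozen)
            ds_eff = dataclasses.replace(ds, cation=cat)
            if cat.plateau_capable:
                frag = fit_stage_W(ds_eff, params, fit_k=True, weighted=weighted)
            else:
                frag = fit_stage_K(ds_eff, params, weighted=weighted)
            _merge(result, frag)

    if compute_ic50:
        cations = {}
        for ds in datasets:
            k = result.parameters.get(f"K:{ds.cation.name}", ds.cation.k_assoc)
            y = y_frozen if (y_frozen is not None and ds.cation.y_factor != 1.0) \
                else ds.cation.y_factor
            cations[ds.cation.name] = replace(ds.cation, k_assoc=k, y_factor=y)
        for ds in datasets:
            w = result.parameters.get("W", 0.0) if ds.cation.plateau_capable else 0.0
            result.ic50s[ds.label] = ic50(cations[ds.cation.name], params.with_(w=w))
    return result


def _merge(result: FitResult, frag: FitResult) -> None:
    result.parameters.update(frag.parameters)
    result.stages.update(frag.stages)
    result.rss.update(frag.rss)
    d, f = result.diagnostics, frag.diagnostics
    d["success"] = bool(d.get("success", True)) and bool(f.get("success", True))
    d.setdefault("boundary", []).extend(f.get("boundary", []))
    d.setdefault("warnings", []).extend(f.get("warnings", []))


def joint_fit(
    datasets: list[DoseResponseDataset],
    params: ShieldingParams,
    reference_cation: str = "Mg",
    organic_reference: str = "putrescine",
) -> FitResult:
    """Comparison mode: one global simultaneous least-squares fit of L, the
    shared organic Y, every non-reference K and the plateau W over all
    datasets.  The staged fit remains canonical."""
    staged = staged_fit(datasets, params, reference_cation, organic_reference,
                        compute_ic50=False)
    names = ["L_ref"]
    x0, lo, hi = [max(staged.parameters["L_ref"], 1e-4)], [1e-5], [1.0]
    has_y = any(d.cation.y_factor < 1.0 for d in datasets)
    if has_y:
        names.append("Y")
        x0.append(min(max(staged.parameters.get("Y", 0.5), 1e-3), 1.0))
        lo.append(1e-6)
        hi.append(1.0)
    k_cations = sorted({d.cation.name for d in datasets if d.cation.name != reference_cation})
    for name in k_cations:
        names.append(f"K:{name}")
        x0.append(max(staged.parameters.get(f"K:{name}", 1.0), 1e-3))
        lo.append(0.0)
        hi.append(1e6)
    if any(d.cation.plateau_capable for d in datasets):
        names.append("W")
        x0.append(min(max(staged.parameters.get("W", 1e-6), 1e-9), params.pip2_total / 2))
        lo.append(0.0)
        hi.append(params.pip2_total * (1 - 1e-9))

    def obj(x):
        vals = dict(zip(names, x))
        p = params.with_(l_ref=float(vals["L_ref"]))
        res = []
        for ds in datasets:
            cat = ds.cation
            if f"K:{cat.name}" in vals:
                cat = replace(cat, k_assoc=float(vals[f"K:{cat.name}"]))
            if has_y and ds.cation.y_factor < 1.0:
                cat = replace(cat, y_factor=float(vals["Y"]))
            w = float(vals.get("W", 0.0)) if cat.plateau_capable else 0.0
            res.append(_residuals(ds, p.with_(w=w), cation=cat))
        return np.concatenate(res)

    sol, at_bound = _bounded_fit(obj, x0, (lo, hi))
    return FitResult(
        parameters=dict(zip(names, (float(v) for v in sol.x))),
        stages={n: "joint" for n in names},
        fixed={"psi": params.psi, "kd": params.kd, "pip2_total": params.pip2_total},
        rss={"all": float(2 * sol.cost)},
        diagnostics={"success": bool(sol.success),
                     "boundary": [n for n, b in zip(names, at_bound) if b],
                     "cost_path": [sol.cost_path], "warnings": []},
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    fit_fn,
    dataset: DoseResponseDataset,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Case-resampling bootstrap over dose-level replicates.

    ``fit_fn`` maps a DoseResponseDataset to a FitResult; replicates are
    resampled with replacement within each dose level and the fit repeated.
    Returns percentile intervals per parameter; reproducible under a fixed
    seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if dataset.replicates is None:
        raise ValueError("dataset carries no replicate values to resample")
    rng = np.random.default_rng(seed)
    reps = np.asarray(dataset.replicates, dtype=float)
    n_dose, n_rep = reps.shape
    samples: dict[str, list[float]] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, n_rep, size=(n_dose, n_rep))
        means = np.clip(np.take_along_axis(reps, idx, axis=1).mean(axis=1), -0.05, 1.2)
        est = fit_fn(dataset.with_activities(means))
        for k, v in est.parameters.items():
            samples.setdefault(k, []).append(v)
    q = (1 - level) / 2
    return {
        k: (float(np.nanquantile(v, q)), float(np.nanquantile(v, 1 - q)))
        for k, v in samples.items()
    }


# ---------------------------------------------------------------------------
# CSV I/O (columns: enzyme, cation, dose, dose_unit, activity_norm,
# replicate_sd, n_rep)
# ---------------------------------------------------------------------------

def write_dose_response_csv(datasets: list[DoseResponseDataset], path) -> None:
    rows = []
    for ds in datasets:
        for i, (d, a) in enumerate(zip(ds.doses, ds.activities)):
            rows.append({
                "enzyme": ds.enzyme,
                "cation": ds.cation.name,
                "dose": d,
                "dose_unit": "M",
                "activity_norm": a,
                "replicate_sd": ds.replicate_sd[i] if ds.replicate_sd is not None else 0.0,
                "n_rep": int(ds.n_replicates[i]) if ds.n_replicates is not None else 1,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dose_response_csv(path, cations: dict[str, CationSpec] | None = None,
                           provenance: str = "measured") -> list[DoseResponseDataset]:
    if cations is None:
        cations = load_default_cations()
    table = pd.read_csv(path)
    required = {"enzyme", "cation", "dose", "dose_unit", "activity_norm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"dose-response CSV lacks columns {sorted(missing)}")
    datasets = []
    for (enzyme, cation), grp in table.groupby(["enzyme", "cation"], sort=False):
        doses = np.array([
            to_molar(v, u) for v, u in zip(grp["dose"], grp["dose_unit"])
        ])
        order = np.argsort(doses)
        if cation not in cations:
            raise ValueError(f"unknown cation {cation!r}; provide a CationSpec")
        datasets.append(DoseResponseDataset(
            enzyme=enzyme,
            cation=cations[cation],
            doses=doses[order],
            activities=grp["activity_norm"].to_numpy()[order],
            replicate_sd=(grp["replicate_sd"].to_numpy()[order]
                          if "replicate_sd" in grp else None),
            n_replicates=(grp["n_rep"].to_numpy()[order]
                          if "n_rep" in grp else None),
            provenance=provenance,
        ))
    return datasets
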