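"""Global fitting of the linked-equilibrium model to heterogeneous datasets.

DSC thermograms at several K+ levels, CD melting curves at several K+ levels
and ITC isotherms at several temperatures are fitted simultaneously with
shared thermodynamic parameters and per-dataset nuisance parameters.

Design: the nonlinear optimiser (bounded trust-region least squares with
Latin-hypercube multi-starts) only sees the shared thermodynamic parameters
and the per-curve CD normalisation coefficients fI; all nuisance parameters
that enter the signal linearly (quadratic DSC intrinsic baselines, linear CD
instrument baselines, constant ITC dilution offsets) are profiled out in
closed form at every objective evaluation (variable projection).  Datasets
are weighted by 1/(n * estimated noise variance) by default so that signals
of very different magnitude contribute comparably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .core_model import (
    ReferenceConditions,
    SiteThermo,
    SystemModel,
    equilibrium_constant,
    gibbs_energy,
)
from .observables import TitrationSeries, cd_melting_curve, dsc_excess_cp, itc_heats

__all__ = [
    "ExperimentDataset",
    "FitProblem",
    "FitResult",
    "objective",
    "fit_global",
    "estimate_uncertainty",
    "compare_mechanisms",
    "SHARED_PARAMETERS",
]

logger = logging.getLogger(__name__)

#: canonical ordering of the shared thermodynamic parameters
SHARED_PARAMETERS = (
    "UI.dG0", "UI.dH0", "UI.dCp", "UI.n",
    "IQ.dG0", "IQ.dH0", "IQ.dCp", "IQ.n",
    "site1.dG0", "site1.dH0", "site1.dCp",
    "site2.dG0", "site2.dH0", "site2.dCp",
)

_PENALTY = 1e3


@dataclass
class ExperimentDataset:
    """One measured (or simulated) dataset with its conditions.

    ``data`` columns: DSC -> temperature_C, cp_kcal_mol_K;
    CD -> temperature_C, ellipticity; ITC -> injection_index, volume_uL,
    heat_kcal_per_mol_DNA (conditions then live in ``protocol``).
    """

    kind: str
    data: pd.DataFrame
    cK: float = 0.1
    cDNA: float = 1e-4
    protocol: TitrationSeries | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("dsc", "cd", "itc"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if self.kind == "itc" and self.protocol is None:
            raise ValueError("itc dataset requires a TitrationSeries protocol")


@dataclass
class FitProblem:
    """Datasets plus the shared-parameter specification.

    ``free`` maps shared parameter names (see SHARED_PARAMETERS) to finite
    (lower, upper) bounds; parameters not listed stay fixed at the values of
    ``base_model``.  Each CD dataset automatically contributes one nonlinear
    nuisance fI (bounds (-0.5, 1.5)).
    """

    datasets: list[ExperimentDataset]
    base_model: SystemModel
    free: dict[str, tuple[float, float]]
    weight_mode: str = "auto"  # "auto" (1/(n*var)) or "unit"

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset required")
        for name, (lo, hi) in self.free.items():
            if name not in SHARED_PARAMETERS:
                raise KeyError(f"unknown free parameter {name!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"free parameter {name!r} needs finite bounds lo < hi")
        if self.weight_mode not in ("auto", "unit"):
            raise ValueError("weight_mode must be 'auto' or 'unit'")


@dataclass
class FitResult:
    estimates: dict[str, float]
    uncertainties: dict[str, float]
    residuals: list[np.ndarray]
    nuisances: list[dict]
    objective: float
    restarts: list[tuple[int, float]]
    seed: int
    success: bool = True


# ---------------------------------------------------------------------------
# internal machinery


def _observed(ds: ExperimentDataset) -> np.ndarray:
    if ds.kind == "dsc":
        return ds.data["cp_kcal_mol_K"].to_numpy(dtype=float)
    if ds.kind == "cd":
        return ds.data["ellipticity"].to_numpy(dtype=float)
    return ds.data["heat_kcal_per_mol_DNA"].to_numpy(dtype=float)


def _noise_variance(y: np.ndarray) -> float:
    """First-difference noise variance estimate with a relative floor."""
    v = float(np.var(np.diff(y)) / 2.0) if y.size > 2 else 0.0
    floor = 1e-12 * (float(np.ptp(y)) ** 2 + 1e-30)
    return max(v, floor, 1e-300)


def _dataset_residual(ds: ExperimentDataset, model: SystemModel,
                      fI: float | None, y: np.ndarray | None = None):
    """Residual after closed-form profiling of linear nuisances.

    Returns (residual array, nuisance dict).
    """
    y = _observed(ds) if y is None else y
    if ds.kind == "dsc":
        t = ds.data["temperature_C"].to_numpy(dtype=float)
        curve = dsc_excess_cp(model, t, ds.cK, cDNA=ds.cDNA)
        ts = t / 100.0
        A = np.vstack([np.ones_like(ts), ts, ts**2]).T
        coef, *_ = np.linalg.lstsq(A, y - curve, rcond=None)
        resid = y - curve - A @ coef
        base = (coef[0], coef[1] / 100.0, coef[2] / 100.0**2)
        return resid, {"baseline": base}
    if ds.kind == "cd":
        t = ds.data["temperature_C"].to_numpy(dtype=float)
        f = cd_melting_curve(model, t, ds.cK, fI)
        ts = t / 100.0
        A = np.vstack([np.ones_like(ts), ts, f, f * ts]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        baseQ = (coef[0], coef[1] / 100.0)
        baseU = (coef[0] + coef[2], (coef[1] + coef[3]) / 100.0)
        return resid, {"baselineQ": baseQ, "baselineU": baseU, "fI": fI}
    proto = replace(ds.protocol, heats=None, dilution_offset=0.0)
    h = itc_heats(model, proto)
    offset = float(np.mean(y - h))
    resid = y - h - offset
    return resid, {"dilution_offset": offset}


class _Assembled:
    """Flattened free-parameter vector: shared parameters then per-CD fI."""

    def __init__(self, problem: FitProblem):
        self.problem = problem
        self.shared_names = [p for p in SHARED_PARAMETERS if p in problem.free]
        self.fI_index = [i for i, d in enumerate(problem.datasets) if d.kind == "cd"]
        self.names = list(self.shared_names) + [f"fI[{i}]" for i in self.fI_index]
        lo = [problem.free[p][0] for p in self.shared_names] + [-0.5] * len(self.fI_index)
        hi = [problem.free[p][1] for p in self.shared_names] + [1.5] * len(self.fI_index)
        self.lo = np.array(lo)
        self.hi = np.array(hi)
        ys = [_observed(d) for d in problem.datasets]
        self.m = sum(y.size for y in ys)
        if problem.weight_mode == "auto":
            self.sqrtw = [np.sqrt(1.0 / (y.size * _noise_variance(y))) for y in ys]
        else:
            self.sqrtw = [1.0 for _ in ys]

    def model_for(self, x: np.ndarray) -> SystemModel:
        updates = dict(zip(self.shared_names, x[: len(self.shared_names)]))
        return self.problem.base_model.with_updates(**updates)

    def fI_for(self, x: np.ndarray, dataset_index: int) -> float | None:
        if dataset_index not in self.fI_index:
            return None
        pos = len(self.shared_names) + self.fI_index.index(dataset_index)
        return float(x[pos])

    def residual_vector(self, x: np.ndarray, ys: list | None = None) -> np.ndarray:
        try:
            model = self.model_for(x)
            parts = []
            for i, ds in enumerate(self.problem.datasets):
                y = None if ys is None else ys[i]
                r, _ = _dataset_residual(ds, model, self.fI_for(x, i), y=y)
                parts.append(r * self.sqrtw[i])
            return np.concatenate(parts)
        except Exception as exc:
            logger.warning("forward model failed at %s: %s", x, exc)
            return np.full(self.m, _PENALTY)


def objective(problem: FitProblem, params: dict[str, float]) -> float:
    """Weighted sum of squared residuals at the given free-parameter values.

    ``params`` must provide every free shared parameter and, for each CD
    dataset i, a key ``fI[i]``.
    """
    asm = _Assembled(problem)
    x = np.array([params[n] for n in asm.names])
    r = asm.residual_vector(x)
    return float(r @ r)


def _starts(asm: _Assembled, n_starts: int, seed: int) -> np.ndarray:
    mid = 0.5 * (asm.lo + asm.hi)
    if n_starts <= 1:
        return mid[None, :]
    sampler = qmc.LatinHypercube(d=asm.lo.size, seed=seed)
    pts = asm.lo + sampler.random(n_starts - 1) * (asm.hi - asm.lo)
    return np.vstack([mid, pts])


def fit_global(problem: FitProblem, n_starts: int = 20, seed: int = 0,
               x0: np.ndarray | None = None) -> FitResult:
    """Multi-start bounded least squares over shared and nuisance parameters.

    Deterministic given ``seed``; returns the best of ``n_starts`` local
    solutions with Jacobian-based standard errors (see
    :func:`estimate_uncertainty` for bootstrap errors).
    """
    asm = _Assembled(problem)
    starts = _starts(asm, n_starts, seed) if x0 is None else np.atleast_2d(x0)
    best = None
    restarts: list[tuple[int, float]] = []
    for i, s in enumerate(starts):
        try:
            res = least_squares(asm.residual_vector, s, bounds=(asm.lo, asm.hi),
                                method="trf", x_scale="jac", ftol=1e-12, xtol=1e-12)
            restarts.append((i, float(2 * res.cost)))
            if best is None or res.cost < best.cost:
                best = res
        except Exception as exc:  # pragma: no cover
            logger.warning("start %d failed: %s", i, exc)
            restarts.append((i, float("nan")))
    if best is None:
        raise RuntimeError(f"all {len(starts)} starts failed: {restarts}")

    x = best.x
    model = asm.model_for(x)
    residuals, nuisances = [], []
    ssr = 0.0
    for i, ds in enumerate(problem.datasets):
        r, nuis = _dataset_residual(ds, model, asm.fI_for(x, i))
        residuals.append(r)
        nuisances.append(nuis)
        ssr += float((r * asm.sqrtw[i]) @ (r * asm.sqrtw[i]))

    # Jacobian-based standard errors
    dof = max(asm.m - x.size, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
        stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except Exception:  # pragma: no cover
        stderr = np.full(x.size, np.nan)

    return FitResult(
        estimates=dict(zip(asm.names, map(float, x))),
        uncertainties=dict(zip(asm.names, map(float, stderr))),
        residuals=residuals,
        nuisances=nuisances,
        objective=ssr,
        restarts=restarts,
        seed=seed,
        success=bool(best.success),
    )


def estimate_uncertainty(problem: FitProblem, result: FitResult,
                         n_boot: int = 50, seed: int = 0) -> dict[str, float]:
    """Residual-bootstrap standard errors.

    Residuals are resampled within each dataset, added back to the fitted
    curves, and the problem is refitted from the solution; the standard
    deviation of the bootstrap estimates is reported.  If fewer than half of
    the bootstrap refits converge, a warning is logged and the intervals are
    widened (doubled) as a convergence flag.
    """
    asm = _Assembled(problem)
    x_hat = np.array([result.estimates[n] for n in asm.names])
    model = asm.model_for(x_hat)
    fits = []
    for i, ds in enumerate(problem.datasets):
        r, _ = _dataset_residual(ds, model, asm.fI_for(x_hat, i))
        fits.append((_observed(ds) - r, r))
    rng = np.random.default_rng(seed)
    samples, n_ok = [], 0
    for _ in range(n_boot):
        ys = [fit + rng.choice(r, size=r.size, replace=True) for fit, r in fits]
        try:
            res = least_squares(lambda x: asm.residual_vector(x, ys), x_hat,
                                bounds=(asm.lo, asm.hi), method="trf",
                                x_scale="jac", ftol=1e-10, xtol=1e-10)
            if res.success:
                n_ok += 1
            samples.append(res.x)
        except Exception:  # pragma: no cover
            continue
    if not samples:
        raise RuntimeError("no bootstrap refit converged")
    std = np.std(np.asarray(samples), axis=0, ddof=1)
    if n_ok < 0.5 * n_boot:
        logger.warning("only %d/%d bootstrap refits converged; widening intervals",
                       n_ok, n_boot)
        std = 2.0 * std
    return dict(zip(asm.names, map(float, std)))


# ---------------------------------------------------------------------------
# mechanism comparison (ITC)


def _rigid_q_heats(protocol: TitrationSeries, betas, ells, enths) -> np.ndarray:
    """Titration heats for a rigid-quadruplex binding mechanism.

    ``betas`` are cumulative formation constants of the ligated species
    (relative to ligand-free Q), ``ells`` their ligand stoichiometries and
    ``enths`` their cumulative binding enthalpies.  The injected DNA is taken
    as pure Q (the enthalpy reference), so only binding heats appear.
    """
    from scipy.optimize import brentq

    betas = np.asarray(betas, float)
    ells = np.asarray(ells, float)
    enths = np.asarray(enths, float)
    V0 = protocol.cell_volume
    c_dna, c_lig = 0.0, protocol.cell_ligand

    def content(c_dna, c_lig):
        if c_dna == 0.0 or c_lig == 0.0:
            return 0.0  # no complexes -> zero enthalpy content
        def g(x):
            L = x * c_lig
            w = np.concatenate([[1.0], betas * L**ells])
            bound = c_dna * float(ells @ w[1:]) / float(w.sum())
            return (L + bound - c_lig) / c_lig
        x = brentq(g, 0.0, 1.0, xtol=1e-16, rtol=8.9e-16, maxiter=200)
        L = x * c_lig
        w = np.concatenate([[1.0], betas * L**ells])
        conc = c_dna * w / w.sum()
        return float(enths @ conc[1:])

    h_before = content(c_dna, c_lig)
    heats = np.empty(protocol.injection_volumes.size)
    for k, dV in enumerate(protocol.injection_volumes):
        f = dV / V0
        c_dna = c_dna * (1 - f) + protocol.syringe_dna * f
        c_lig = c_lig * (1 - f)
        h_after = content(c_dna, c_lig)
        heats[k] = V0 * (h_after - (1 - f) * h_before) / (dV * protocol.syringe_dna)
        h_before = h_after
    return heats


def _site_record(site: int, p3) -> SiteThermo:
    return SiteThermo(site, dG0=float(p3[0]), dH0=float(p3[1]), dCp=float(p3[2]))


def _mechanism_heats(name: str, params: np.ndarray, protocol: TitrationSeries,
                     base_model: SystemModel) -> np.ndarray:
    T = protocol.temperature + 273.15
    ref = base_model.ref
    if name == "full":
        model = base_model.with_updates(
            **{"site1.dG0": params[0], "site1.dH0": params[1], "site1.dCp": params[2],
               "site2.dG0": params[3], "site2.dH0": params[4], "site2.dCp": params[5]})
        return itc_heats(model, replace(protocol, heats=None, dilution_offset=0.0))

    def K_and_H(p3):
        rec = _site_record(1, p3)
        K = equilibrium_constant(gibbs_energy(rec, T, protocol.cK, ref), T)
        return K, p3[1] + p3[2] * (T - ref.T0)

    if name == "one-site":
        K, dH = K_and_H(params[0:3])
        return _rigid_q_heats(protocol, [K], [1], [dH])
    if name == "two-independent-sites":
        Ka, dHa = K_and_H(params[0:3])
        Kb, dHb = K_and_H(params[3:6])
        return _rigid_q_heats(protocol, [Ka, Kb, Ka * Kb], [1, 1, 2],
                              [dHa, dHb, dHa + dHb])
    if name == "sequential-two-site":
        K1, dH1 = K_and_H(params[0:3])
        K2, dH2 = K_and_H(params[3:6])
        return _rigid_q_heats(protocol, [K1, K1 * K2], [1, 2], [dH1, dH1 + dH2])
    raise ValueError(f"unknown mechanism {name!r}")


_MECH_NPARAMS = {"full": 6, "one-site": 3, "two-independent-sites": 6,
                 "sequential-two-site": 6}
_SITE_BOUNDS = ([-13.0, -45.0, -0.5], [-4.0, 5.0, 0.1])


def compare_mechanisms(datasets: list[ExperimentDataset],
                       mechanisms=("full", "two-independent-sites", "sequential-two-site"),
                       base_model: SystemModel | None = None,
                       n_starts: int = 6, seed: int = 0) -> pd.DataFrame:
    """Fit each candidate binding mechanism to the ITC datasets and rank by
    small-sample-corrected AIC.

    Candidates: the full seven-species mechanism with folding coupling
    ("full"), a rigid quadruplex with two non-equivalent independent sites,
    a rigid quadruplex with sequential two-site binding, and optionally a
    rigid one-site model.  Per-isotherm dilution offsets are profiled.
    """
    if base_model is None:
        base_model = SystemModel.default()
    itc = [d for d in datasets if d.kind == "itc"]
    if not itc:
        raise ValueError("mechanism comparison needs at least one ITC dataset")
    ys = [_observed(d) for d in itc]
    n_total = sum(y.size for y in ys)
    rows = []
    for mech in mechanisms:
        k = _MECH_NPARAMS[mech]
        lo = np.array(_SITE_BOUNDS[0] * (k // 3))
        hi = np.array(_SITE_BOUNDS[1] * (k // 3))

        def resid(x, mech=mech):
            try:
                parts = []
                for d, y in zip(itc, ys):
                    h = _mechanism_heats(mech, x, d.protocol, base_model)
                    offset = float(np.mean(y - h))
                    parts.append(y - h - offset)
                return np.concatenate(parts)
            except Exception:
                return np.full(n_total, _PENALTY)

        sampler = qmc.LatinHypercube(d=k, seed=seed)
        starts = np.vstack([0.5 * (lo + hi),
                            lo + sampler.random(max(n_starts - 1, 1)) * (hi - lo)])
        best_ssr, best_x = np.inf, None
        for s in starts:
            res = least_squares(resid, s, bounds=(lo, hi), method="trf",
                                x_scale="jac", ftol=1e-10, xtol=1e-10)
            ssr = float(2 * res.cost)
            if ssr < best_ssr:
                best_ssr, best_x = ssr, res.x
        k_eff = k + len(itc)  # free parameters + profiled offsets
        denom = max(n_total - k_eff - 1, 1)
        aicc = n_total * np.log(best_ssr / n_total) + 2 * k_eff \
            + 2 * k_eff * (k_eff + 1) / denom
        rows.append({"mechanism": mech, "n_params": k_eff, "ssr": best_ssr,
                     "aicc": float(aicc), "params": best_x})
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
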