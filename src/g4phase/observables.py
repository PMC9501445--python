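"""Forward models mapping speciation to the measured signals.

Three experiment types are modelled:

* CD melting at a single wavelength.  The normalised signal is
  ``f = (theta - thetaQ)/(thetaU - thetaQ) = alpha_I*fI + alpha_U`` with
  linear-in-temperature pre- and post-transitional instrument baselines
  thetaQ(T), thetaU(T) and a temperature-independent normalisation
  coefficient fI for the intermediate.

* DSC.  The measured partial molar heat capacity is decomposed into a smooth
  intrinsic (conformation-weighted) baseline, approximated by a quadratic in
  T, plus the excess heat capacity dCp_ex(T) = d<dH>/dT where
  <dH>(T) = sum_s alpha_s(T) * H_s(T) is the population-weighted enthalpy
  relative to a reference species.

* ITC reverse titration (DNA titrated into ligand).  Heats are per mole of
  DNA injected, with instantaneous-displacement bookkeeping for the
  perfusion cell and one constant dilution offset per isotherm.

A nearest-neighbour extinction-coefficient utility for single-stranded DNA
at 260 nm / 25 °C is included for concentration determination.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    Conditions,
    SPECIES,
    SystemModel,
    folding_fractions,
    solve_speciation,
    species_enthalpies,
)

__all__ = [
    "CDMeltingCurve",
    "Thermogram",
    "SpectraMatrix",
    "TitrationSeries",
    "cd_normalized",
    "cd_denormalize",
    "cd_normalize",
    "cd_melting_curve",
    "mean_excess_enthalpy",
    "dsc_excess_cp",
    "dsc_intrinsic_baseline",
    "itc_heats",
    "estimate_intermediate_spectrum",
    "nn_extinction",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class CDMeltingCurve:
    """Single-wavelength melting curve (ellipticity normalised to 1 M DNA,
    1 cm pathlength)."""

    temperatures: np.ndarray  # °C, strictly increasing
    ellipticity: np.ndarray
    wavelength: float = 290.0  # nm
    baselineQ: tuple[float, float] = (0.0, 0.0)  # intercept, slope vs °C
    baselineU: tuple[float, float] = (1.0, 0.0)
    fI: float = 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 10:
            raise ValueError("melting curve needs at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if t.min() < 0 or t.max() > 100:
            raise ValueError("temperatures must lie within [0, 100] °C")
        self.temperatures = t
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)


@dataclass
class Thermogram:
    """DSC thermogram: partial molar heat capacity vs temperature."""

    temperatures: np.ndarray  # °C
    cp: np.ndarray            # kcal mol^-1 K^-1
    intrinsic: np.ndarray | None = None  # quadratic coefficients (c0, c1, c2)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.temperatures.shape != self.cp.shape:
            raise ValueError("temperature and cp grids must match")

    @property
    def excess(self) -> np.ndarray:
        """cp minus the intrinsic quadratic baseline, pointwise."""
        if self.intrinsic is None:
            raise ValueError("intrinsic baseline not set")
        c0, c1, c2 = self.intrinsic
        t = self.temperatures
        return self.cp - (c0 + c1 * t + c2 * t * t)


@dataclass
class SpectraMatrix:
    """Temperature series of CD spectra (wavelength x temperature)."""

    wavelengths: np.ndarray   # nm
    temperatures: np.ndarray  # °C
    values: np.ndarray        # shape (n_wavelength, n_temperature)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.wavelengths.size, self.temperatures.size):
            raise ValueError("matrix dimensions inconsistent with axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite cells")


@dataclass
class TitrationSeries:
    """ITC reverse-titration protocol (DNA in the syringe, ligand in the cell).

    Heats are expressed per mole of DNA added per injection (kcal/mol);
    ``dilution_offset`` is one constant per-injection heat.
    """

    cell_volume: float          # L
    syringe_dna: float          # mol/L
    cell_ligand: float          # mol/L
    injection_volumes: np.ndarray  # L per injection
    temperature: float          # °C
    cK: float = 0.1             # mol/L
    heats: np.ndarray | None = None
    dilution_offset: float = 0.0

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("all volumes must be positive")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise ValueError("heats length must equal injections length")


# ---------------------------------------------------------------------------
# CD


def cd_normalized(alpha_i, alpha_u, fI: float):
    """Normalised CD melting signal f = alpha_I * fI + alpha_U."""
    return np.asarray(alpha_i, dtype=float) * fI + np.asarray(alpha_u, dtype=float)


def _baseline_values(temps_c, baselineQ, baselineU):
    t = np.asarray(temps_c, dtype=float)
    thetaQ = baselineQ[0] + baselineQ[1] * t
    thetaU = baselineU[0] + baselineU[1] * t
    return thetaQ, thetaU


def cd_denormalize(f, temps_c, baselineQ, baselineU):
    """Raw ellipticity from the normalised signal and linear baselines:
    theta = thetaQ(T) + f * (thetaU(T) - thetaQ(T))."""
    thetaQ, thetaU = _baseline_values(temps_c, baselineQ, baselineU)
    if np.any(thetaU == thetaQ):
        raise ValueError("degenerate baselines: thetaU(T) equals thetaQ(T)")
    return thetaQ + np.asarray(f, dtype=float) * (thetaU - thetaQ)


def cd_normalize(theta, temps_c, baselineQ, baselineU):
    """Exact inverse of :func:`cd_denormalize`."""
    thetaQ, thetaU = _baseline_values(temps_c, baselineQ, baselineU)
    if np.any(thetaU == thetaQ):
        raise ValueError("degenerate baselines: thetaU(T) equals thetaQ(T)")
    return (np.asarray(theta, dtype=float) - thetaQ) / (thetaU - thetaQ)


def cd_melting_curve(model: SystemModel, temps_c, cK: float, fI: float):
    """Normalised ligand-free melting signal over a °C grid."""
    T = np.asarray(temps_c, dtype=float) + 273.15
    a_u, a_i, _ = folding_fractions(model, T, cK)
    return cd_normalized(a_i, a_u, fI)


# ---------------------------------------------------------------------------
# DSC


def _fractions_on_grid(model: SystemModel, T_grid, cK, cDNA, cL):
    """Species fractions (7 x n) on a Kelvin grid."""
    if cL == 0.0:
        a_u, a_i, a_q = folding_fractions(model, T_grid, cK)
        out = np.zeros((len(SPECIES), T_grid.size))
        out[0], out[1], out[2] = a_u, a_i, a_q
        return out
    out = np.empty((len(SPECIES), T_grid.size))
    for j, T in enumerate(T_grid):
        sp = solve_speciation(model, Conditions(T=float(T), cK=cK, cDNA=cDNA, cL=cL))
        out[:, j] = [sp.fractions[s] for s in SPECIES]
    return out


def mean_excess_enthalpy(model: SystemModel, T_grid, cK, cDNA=1e-4, cL=0.0,
                         reference: str = "U"):
    """Population-weighted enthalpy <dH>(T) relative to ``reference`` species."""
    T_grid = np.asarray(T_grid, dtype=float)
    alphas = _fractions_on_grid(model, T_grid, cK, cDNA, cL)
    H = species_enthalpies(model, T_grid)
    h_ref = H[reference]
    mean_h = np.zeros_like(T_grid)
    for idx, s in enumerate(SPECIES):
        mean_h += alphas[idx] * (np.asarray(H[s]) - h_ref)
    return mean_h


def dsc_excess_cp(model: SystemModel, temps_c, cK, cDNA=1e-4, cL=0.0,
                  step: float = 0.1, reference: str = "U"):
    """Model excess heat capacity dCp_ex(T) = d<dH>/dT on a °C data grid.

    Evaluated by centred differences of the population-weighted enthalpy on
    an internal Kelvin grid of spacing ``step`` and interpolated back to the
    data grid.  The integral over the full transition equals
    <dH>(T_high) - <dH>(T_low) (checked in the test suite at the 1% level).
    """
    temps_c = np.asarray(temps_c, dtype=float)
    if step > 1.0:
        logger.warning("dsc_excess_cp: grid step %.3g K is coarse (> 1 K)", step)
    lo = temps_c.min() + 273.15 - step
    hi = temps_c.max() + 273.15 + step
    n = int(math.ceil((hi - lo) / step)) + 1
    grid = np.linspace(lo, hi, n)
    h = mean_excess_enthalpy(model, grid, cK, cDNA, cL, reference)
    dcp = np.gradient(h, grid)
    return np.interp(temps_c + 273.15, grid, dcp)


def dsc_intrinsic_baseline(temps_c, cp, low_window=(0.5, 15.0), high_window=(85.0, 95.0)):
    """Quadratic intrinsic baseline fitted to the pre- and post-transition
    windows of a thermogram.

    Returns (coefficients (c0, c1, c2), rms residual over the window points).
    """
    t = np.asarray(temps_c, dtype=float)
    y = np.asarray(cp, dtype=float)
    masks = {}
    for name, (a, b) in (("low", low_window), ("high", high_window)):
        m = (t >= a) & (t <= b)
        if m.sum() < 5:
            raise ValueError(f"{name} window [{a}, {b}] °C contains fewer than 5 points")
        masks[name] = m
    m = masks["low"] | masks["high"]
    A = np.vstack([np.ones(m.sum()), t[m], t[m] ** 2]).T
    coef, *_ = np.linalg.lstsq(A, y[m], rcond=None)
    resid = y[m] - A @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    return tuple(coef), rms


# ---------------------------------------------------------------------------
# ITC


def itc_heats(model: SystemModel, protocol: TitrationSeries) -> np.ndarray:
    """Per-injection enthalpy of interaction, kcal per mole of DNA injected.

    Bookkeeping uses the instantaneous-displacement convention: each injected
    volume dV displaces an equal volume of the pre-injection cell content.
    The heat of injection k is the change in enthalpy content of the cell,
    counting the injected DNA at its syringe speciation (folded at the cell
    temperature, no ligand), divided by the moles of DNA injected, plus the
    constant dilution offset.
    """
    T = protocol.temperature + 273.15
    cK = protocol.cK
    V0 = protocol.cell_volume
    H = species_enthalpies(model, T)
    h_vec = np.array([float(H[s]) for s in SPECIES])

    syr = solve_speciation(
        model, Conditions(T=T, cK=cK, cDNA=protocol.syringe_dna, cL=0.0)
    )
    conc_syr = protocol.syringe_dna * np.array([syr.fractions[s] for s in SPECIES])
    h_syr = float(h_vec @ conc_syr)  # enthalpy content per L of syringe solution

    c_dna = 0.0
    c_lig = protocol.cell_ligand

    def cell_content(c_dna, c_lig):
        """Species concentrations and free ligand in the cell."""
        if c_dna == 0.0 and c_lig == 0.0:
            return np.zeros(len(SPECIES)), 0.0
        sp = solve_speciation(model, Conditions(T=T, cK=cK, cDNA=c_dna, cL=c_lig))
        conc = c_dna * np.array([sp.fractions[s] for s in SPECIES])
        return conc, sp.free_ligand

    conc_before, _ = cell_content(c_dna, c_lig)
    heats = np.empty(protocol.injection_volumes.size)
    for k, dV in enumerate(protocol.injection_volumes):
        f = dV / V0
        c_dna = c_dna * (1.0 - f) + protocol.syringe_dna * f
        c_lig = c_lig * (1.0 - f)
        try:
            conc_after, _ = cell_content(c_dna, c_lig)
        except Exception as exc:
            raise RuntimeError(f"speciation failed at injection {k + 1}") from exc
        q = V0 * float(h_vec @ conc_after) \
            - V0 * (1.0 - f) * float(h_vec @ conc_before) \
            - dV * h_syr
        heats[k] = q / (dV * protocol.syringe_dna) + protocol.dilution_offset
        conc_before = conc_after
    return heats


# ---------------------------------------------------------------------------
# intermediate spectrum


def estimate_intermediate_spectrum(spectra: SpectraMatrix, alpha_q, alpha_i, alpha_u,
                                   spectrum_q, spectrum_u):
    """Least-squares estimate of the intermediate spectrum.

    Given model-predicted fractions per temperature and reference spectra of
    the folded (Q) and unfolded (U) forms, solves per wavelength
    ``theta(l, T) - aQ(T) Q(l) - aU(T) U(l) = aI(T) I(l)``.

    Returns (I_spectrum, rms residual of the full reconstruction).
    """
    a_q = np.asarray(alpha_q, dtype=float)
    a_i = np.asarray(alpha_i, dtype=float)
    a_u = np.asarray(alpha_u, dtype=float)
    denom = float(a_i @ a_i)
    if denom < 1e-12:
        raise ValueError("intermediate fraction is ~0 everywhere: spectrum unidentifiable")
    q = np.asarray(spectrum_q, dtype=float)
    u = np.asarray(spectrum_u, dtype=float)
    resid = spectra.values - np.outer(q, a_q) - np.outer(u, a_u)
    i_spec = resid @ a_i / denom
    full_resid = resid - np.outer(i_spec, a_i)
    rms = float(np.sqrt(np.mean(full_resid**2)))
    return i_spec, rms


# ---------------------------------------------------------------------------
# nearest-neighbour extinction coefficient

# Single-strand values at 260 nm, 25 °C (M^-1 cm^-1): dinucleotide table and
# internal-monomer corrections (Cantor, Warshaw & Shapiro single-strand set).
_NN_DIMER = {
    "AA": 27400, "AC": 21200, "AG": 25000, "AT": 22800,
    "CA": 21200, "CC": 14600, "CG": 18000, "CT": 15200,
    "GA": 25200, "GC": 17600, "GG": 21600, "GT": 20000,
    "TA": 23400, "TC": 16200, "TG": 19000, "TT": 16800,
}
_NN_MONO = {"A": 15400, "C": 7400, "G": 11500, "T": 8700}


def nn_extinction(sequence: str) -> float:
    """Nearest-neighbour molar extinction coefficient of single-stranded DNA
    at 260 nm and 25 °C.

    epsilon = sum over adjacent dinucleotides - sum over internal monomers.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    for pos, base in enumerate(seq):
        if base not in _NN_MONO:
            raise ValueError(f"invalid base {base!r} at position {pos}")
    dimer_sum = sum(_NN_DIMER[seq[i:i + 2]] for i in range(len(seq) - 1))
    mono_sum = sum(_NN_MONO[b] for b in seq[1:-1])
    return float(dimer_sum - mono_sum)
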