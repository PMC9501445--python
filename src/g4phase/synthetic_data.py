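"""Seeded synthetic DSC, CD and ITC datasets.

No raw thermograms, melting curves or isotherms are deposited for the 22GT /
360A system, so this module generates datasets with the statistical
structure the analysis assumes: forward-model signals at the published
parameter set, smooth instrument baselines, white Gaussian measurement
noise, and the reverse-titration injection protocol with displacement
dilution.  Truth parameters and noiseless curves are stored alongside every
dataset so that parameter-recovery tests can compare against them.

Default experimental design mirrors the study conditions: DSC at 1/10/100 mM
K+ over 0.5-95 °C (100 µM strand), CD melting at 290 nm over 5-95 °C (10 µM
strand) at the same K+ levels, temperature-series CD spectra at 10 mM K+,
and ITC at 15/25/40 °C at 100 mM K+ titrating 70 µM DNA into 10 µM ligand
(25 x 10 µL injections into 1.4 mL).  Default noise levels (DSC 0.05 kcal
mol-1 K-1, CD 2% of signal range, ITC 0.2 kcal per mol injectant) are
plausible instrument magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import SystemModel, folding_fractions
from .observables import (
    SpectraMatrix,
    TitrationSeries,
    cd_denormalize,
    cd_melting_curve,
    dsc_excess_cp,
    itc_heats,
)

__all__ = ["NoiseSpec", "ScenarioSpec", "SyntheticDataset",
           "make_dsc", "make_cd", "make_itc", "basis_spectra", "as_experiment"]


@dataclass(frozen=True)
class NoiseSpec:
    """White Gaussian noise: absolute sigma, or a fraction of signal range
    when ``relative`` is set."""

    sigma: float
    relative: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def sample(self, rng: np.random.Generator, signal: np.ndarray) -> np.ndarray:
        s = self.sigma * float(np.ptp(signal)) if self.relative else self.sigma
        return rng.normal(0.0, s, size=np.shape(signal)) if s > 0 else np.zeros_like(signal)


@dataclass
class ScenarioSpec:
    """Full synthetic-experiment design; defaults reproduce the study
    conditions at desk scale with the published parameter set as truth."""

    model: SystemModel = field(default_factory=SystemModel.default)
    seed: int = 0
    # DSC
    dsc_cK: tuple = (0.001, 0.01, 0.1)      # mol/L
    dsc_t_range: tuple = (0.5, 95.0)        # °C
    dsc_step: float = 0.5                   # °C data grid
    dsc_cDNA: float = 1e-4                  # mol/L
    dsc_baseline: tuple = (1.5, 4e-3, 2e-5)  # intrinsic quadratic (c0, c1, c2) vs °C
    dsc_noise: NoiseSpec = NoiseSpec(0.05)
    # CD melting
    cd_cK: tuple = (0.001, 0.01, 0.1)
    cd_t_range: tuple = (5.0, 95.0)
    cd_step: float = 1.0
    cd_cDNA: float = 1e-5
    cd_fI: float = 0.35
    cd_baselineQ: tuple = (-2.4e6, 2.0e3)   # intercept, slope vs °C
    cd_baselineU: tuple = (-0.2e6, -1.0e3)
    cd_noise: NoiseSpec = NoiseSpec(0.02, relative=True)
    # CD spectra matrix
    spectra_cK: float = 0.01
    spectra_temps: tuple = tuple(float(t) for t in range(5, 96, 5))
    spectra_wavelengths: tuple = tuple(float(w) for w in range(210, 331))
    spectra_noise: NoiseSpec = NoiseSpec(0.02, relative=True)
    # ITC
    itc_temps: tuple = (15.0, 25.0, 40.0)   # °C
    itc_cK: float = 0.1
    itc_syringe_dna: float = 7e-5           # mol/L
    itc_cell_ligand: float = 1e-5           # mol/L
    itc_cell_volume: float = 1.4e-3         # L
    itc_n_injections: int = 25
    itc_injection_volume: float = 10e-6     # L
    itc_dilution_offset: float = -0.5       # kcal per mol DNA injected
    itc_noise: NoiseSpec = NoiseSpec(0.2)


@dataclass
class SyntheticDataset:
    """One generated dataset plus its ground truth (noiseless signal and the
    parameters that produced it)."""

    kind: str
    data: pd.DataFrame
    cK: float
    cDNA: float
    truth: dict
    protocol: TitrationSeries | None = None
    name: str = ""


def as_experiment(ds: SyntheticDataset):
    """View a synthetic dataset as a fit-ready :class:`ExperimentDataset`."""
    from .global_fit import ExperimentDataset

    return ExperimentDataset(kind=ds.kind, data=ds.data, cK=ds.cK, cDNA=ds.cDNA,
                             protocol=ds.protocol, name=ds.name)


# ---------------------------------------------------------------------------
# DSC


def make_dsc(scenario: ScenarioSpec, rng: np.random.Generator | None = None
             ) -> list[SyntheticDataset]:
    """Synthetic thermograms: quadratic intrinsic baseline + model excess
    heat capacity + white noise, one per K+ level."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    lo, hi = scenario.dsc_t_range
    t = np.arange(lo, hi + 1e-9, scenario.dsc_step)
    c0, c1, c2 = scenario.dsc_baseline
    out = []
    for cK in scenario.dsc_cK:
        excess = dsc_excess_cp(scenario.model, t, cK, cDNA=scenario.dsc_cDNA)
        clean = c0 + c1 * t + c2 * t * t + excess
        noisy = clean + scenario.dsc_noise.sample(rng, clean)
        df = pd.DataFrame({"temperature_C": t, "cp_kcal_mol_K": noisy})
        out.append(SyntheticDataset(
            kind="dsc", data=df, cK=cK, cDNA=scenario.dsc_cDNA,
            truth={"model": scenario.model, "noiseless": clean,
                   "excess": excess, "baseline": scenario.dsc_baseline,
                   "noise": scenario.dsc_noise},
            name=f"dsc_K{cK * 1e3:g}mM"))
    return out


# ---------------------------------------------------------------------------
# CD

_BANDS = {
    # centre (nm), width (nm), amplitude (normalised ellipticity units):
    # synthetic band-shaped spectra with extrema mimicking an antiparallel
    # quadruplex (Q: maxima 290/245, minima 265/235, shoulder 270; I: max 290,
    # min 260; U: weak residual stacking signal)
    "Q": ((290, 11, 1.0), (245, 9, 0.55), (265, 8, -0.5), (235, 6, -0.45),
          (270, 6, 0.25)),
    "I": ((290, 13, 0.85), (260, 10, -0.6), (240, 8, 0.2)),
    "U": ((275, 20, 0.15), (250, 15, -0.1)),
}


def basis_spectra(wavelengths) -> dict[str, np.ndarray]:
    """Synthetic Q/I/U basis CD spectra built from Gaussian bands."""
    wl = np.asarray(wavelengths, dtype=float)
    out = {}
    for s, bands in _BANDS.items():
        spec = np.zeros_like(wl)
        for centre, width, amp in bands:
            spec += amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)
        out[s] = 2.5e6 * spec  # deg cm^2 dmol^-1 scale
    return out


def make_cd(scenario: ScenarioSpec, rng: np.random.Generator | None = None
            ) -> tuple[list[SyntheticDataset], list[SyntheticDataset]]:
    """Synthetic CD data: (melting curves at 290 nm per K+ level,
    temperature-series spectra matrices)."""
    rng = np.random.default_rng(scenario.seed + 1) if rng is None else rng
    lo, hi = scenario.cd_t_range
    t = np.arange(lo, hi + 1e-9, scenario.cd_step)
    curves = []
    for cK in scenario.cd_cK:
        f = cd_melting_curve(scenario.model, t, cK, scenario.cd_fI)
        clean = cd_denormalize(f, t, scenario.cd_baselineQ, scenario.cd_baselineU)
        noisy = clean + scenario.cd_noise.sample(rng, clean)
        df = pd.DataFrame({"temperature_C": t, "ellipticity": noisy})
        curves.append(SyntheticDataset(
            kind="cd", data=df, cK=cK, cDNA=scenario.cd_cDNA,
            truth={"model": scenario.model, "noiseless": clean, "f": f,
                   "fI": scenario.cd_fI, "baselineQ": scenario.cd_baselineQ,
                   "baselineU": scenario.cd_baselineU, "noise": scenario.cd_noise},
            name=f"cd_K{cK * 1e3:g}mM"))

    wl = np.array(scenario.spectra_wavelengths)
    temps = np.array(scenario.spectra_temps)
    basis = basis_spectra(wl)
    a_u, a_i, a_q = folding_fractions(scenario.model, temps + 273.15,
                                      scenario.spectra_cK)
    clean = (np.outer(basis["Q"], a_q) + np.outer(basis["I"], a_i)
             + np.outer(basis["U"], a_u))
    noisy = clean + scenario.spectra_noise.sample(rng, clean)
    matrix = SpectraMatrix(wavelengths=wl, temperatures=temps, values=noisy)
    cols = {"wavelength_nm": wl}
    cols.update({f"{tc:g}": noisy[:, j] for j, tc in enumerate(temps)})
    spectra = [SyntheticDataset(
        kind="spectra", data=pd.DataFrame(cols), cK=scenario.spectra_cK,
        cDNA=scenario.cd_cDNA,
        truth={"model": scenario.model, "noiseless": clean, "basis": basis,
               "fractions": (a_q, a_i, a_u), "matrix": matrix,
               "noise": scenario.spectra_noise},
        name=f"spectra_K{scenario.spectra_cK * 1e3:g}mM")]
    return curves, spectra


# ---------------------------------------------------------------------------
# ITC


def make_itc(scenario: ScenarioSpec, rng: np.random.Generator | None = None
             ) -> list[SyntheticDataset]:
    """Synthetic reverse-titration isotherms, one per temperature."""
    rng = np.random.default_rng(scenario.seed + 2) if rng is None else rng
    out = []
    volumes = np.full(scenario.itc_n_injections, scenario.itc_injection_volume)
    for t_c in scenario.itc_temps:
        proto = TitrationSeries(
            cell_volume=scenario.itc_cell_volume,
            syringe_dna=scenario.itc_syringe_dna,
            cell_ligand=scenario.itc_cell_ligand,
            injection_volumes=volumes.copy(),
            temperature=t_c, cK=scenario.itc_cK,
            dilution_offset=scenario.itc_dilution_offset)
        clean = itc_heats(scenario.model, proto)
        noisy = clean + scenario.itc_noise.sample(rng, clean)
        proto.heats = noisy
        df = pd.DataFrame({
            "injection_index": np.arange(1, volumes.size + 1),
            "volume_uL": volumes * 1e6,
            "heat_kcal_per_mol_DNA": noisy})
        out.append(SyntheticDataset(
            kind="itc", data=df, cK=scenario.itc_cK, cDNA=scenario.itc_syringe_dna,
            truth={"model": scenario.model, "noiseless": clean,
                   "dilution_offset": scenario.itc_dilution_offset,
                   "noise": scenario.itc_noise},
            protocol=proto, name=f"itc_{t_c:g}C"))
    return out
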