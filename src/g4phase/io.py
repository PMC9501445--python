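"""Plain-text file formats and parameter-file handling.

All files are UTF-8 CSV with a header row.  Temperatures in files are °C and
concentrations are mM or µM as labelled; they are converted to the internal
units (K, mol/L, kcal) at this boundary.

Schemas
-------
CD melting:  temperature_C, ellipticity
Spectra:     wavelength_nm, then one column per temperature named in °C
DSC:         temperature_C, cp_kcal_mol_K
ITC:         injection_index, volume_uL, heat_kcal_per_mol_DNA

The parameter file is YAML with blocks ``reference`` (T0_C, cref_mM),
``transitions`` (U->I, I->Q: dG0, dH0, dCp, n) and ``sites`` (site1, site2:
dG0, dH0, dCp); it round-trips bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import ReferenceConditions, SiteThermo, SystemModel, TransitionThermo
from .global_fit import ExperimentDataset
from .observables import SpectraMatrix, TitrationSeries

__all__ = [
    "DATASET_SCHEMAS",
    "read_dataset",
    "write_dataset",
    "read_spectra",
    "write_spectra",
    "load_parameters",
    "save_parameters",
]

DATASET_SCHEMAS = {
    "cd": ["temperature_C", "ellipticity"],
    "dsc": ["temperature_C", "cp_kcal_mol_K"],
    "itc": ["injection_index", "volume_uL", "heat_kcal_per_mol_DNA"],
}


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, kind: str, path) -> None:
    expected = DATASET_SCHEMAS[kind]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: schema mismatch for kind '{kind}': "
            f"missing columns {missing}, unexpected columns {extra}"
        )


def _check_monotone_temperature(df: pd.DataFrame, path) -> None:
    t = df["temperature_C"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        row = int(bad[0]) + 2  # 1-based data row after the offending step
        raise SchemaError(
            f"{path}: temperatures must be strictly increasing; "
            f"first offending row {row} (T = {t[bad[0] + 1]} °C)"
        )


def read_dataset(path, kind: str, cK_mM: float = 100.0, cDNA_uM: float = 100.0,
                 temperature_C: float = 25.0, cell_volume_mL: float = 1.4,
                 syringe_dna_uM: float = 70.0, cell_ligand_uM: float = 10.0,
                 ) -> ExperimentDataset:
    """Read one CSV dataset, validate its schema and attach conditions.

    Concentration/temperature keywords supply the conditions the file format
    does not carry; they are converted to internal units here.
    """
    path = Path(path)
    if kind not in DATASET_SCHEMAS:
        raise ValueError(f"unknown dataset kind {kind!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, kind, path)
    protocol = None
    if kind in ("cd", "dsc"):
        _check_monotone_temperature(df, path)
    else:
        protocol = TitrationSeries(
            cell_volume=cell_volume_mL * 1e-3,
            syringe_dna=syringe_dna_uM * 1e-6,
            cell_ligand=cell_ligand_uM * 1e-6,
            injection_volumes=df["volume_uL"].to_numpy(dtype=float) * 1e-6,
            temperature=temperature_C,
            cK=cK_mM * 1e-3,
            heats=df["heat_kcal_per_mol_DNA"].to_numpy(dtype=float))
    return ExperimentDataset(kind=kind, data=df, cK=cK_mM * 1e-3,
                             cDNA=cDNA_uM * 1e-6, protocol=protocol,
                             name=path.stem)


def _roundtrip_repr(v) -> str:
    # shortest decimal representation that parses back to the same float
    return repr(float(v))


def write_dataset(path, dataset) -> None:
    """Write a dataset's table back to CSV (bit-exact float round trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.data.to_csv(path, index=False, float_format=_roundtrip_repr)


def read_spectra(path) -> SpectraMatrix:
    """Read a spectra CSV (wavelength_nm + temperature-named columns)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "wavelength_nm":
        raise SchemaError(f"{path}: first column must be 'wavelength_nm'")
    try:
        temps = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SchemaError(f"{path}: spectra columns must be named by °C") from exc
    return SpectraMatrix(
        wavelengths=df["wavelength_nm"].to_numpy(dtype=float),
        temperatures=temps,
        values=df.iloc[:, 1:].to_numpy(dtype=float))


def write_spectra(path, matrix: SpectraMatrix) -> None:
    cols = {"wavelength_nm": matrix.wavelengths}
    cols.update({f"{t:g}": matrix.values[:, j]
                 for j, t in enumerate(matrix.temperatures)})
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_roundtrip_repr)


# ---------------------------------------------------------------------------
# parameter files


def save_parameters(path, model: SystemModel) -> None:
    doc = {
        "reference": {"T0_C": model.ref.T0 - 273.15,
                      "cref_mM": model.ref.cref * 1e3},
        "transitions": {
            t.name: {"dG0": t.dG0, "dH0": t.dH0, "dCp": t.dCp, "n": t.n}
            for t in model.transitions},
        "sites": {
            f"site{s.site}": {"dG0": s.dG0, "dH0": s.dH0, "dCp": s.dCp}
            for s in model.sites},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_parameters(path) -> SystemModel:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    expected = {"reference", "transitions", "sites"}
    unknown = set(doc) - expected
    if unknown:
        raise SchemaError(f"{path}: unknown blocks {sorted(unknown)}; "
                          f"valid blocks are {sorted(expected)}")
    ref = ReferenceConditions(T0=doc["reference"]["T0_C"] + 273.15,
                              cref=doc["reference"]["cref_mM"] * 1e-3)
    transitions = tuple(
        TransitionThermo(name, **doc["transitions"][name])
        for name in ("U->I", "I->Q"))
    sites = tuple(
        SiteThermo(i, **doc["sites"][f"site{i}"]) for i in (1, 2))
    return SystemModel(transitions=transitions, sites=sites, ref=ref)
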