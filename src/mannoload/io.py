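"""Delimited-text readers and writers for titrations, spectra and uptake tables.

CSV is the interchange format throughout.  Floats are serialized with 12
significant digits so that write→read round trips are lossless at test
tolerance.  Parse errors name the offending row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binding import TitrationSeries
from .spectra import Spectrum
from .uptake import UptakeTable

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectrum_series_csv",
    "write_spectrum_series_csv",
    "read_uptake_csv",
    "write_uptake_csv",
]

FLOAT_FMT = "%.12g"


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna() & df[col].notna()]
    if len(bad):
        # +2: header line and 1-based counting
        raise ValueError(
            f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
        )
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0])
        raise ValueError(f"{path}: empty cell in column {col!r} at line {row + 2}")
    return vals.to_numpy(dtype=float)


def read_titration_csv(path) -> TitrationSeries:
    """Read a titration (columns: ligand_conc_M, signal), sorted ascending."""
    df = _read_csv(path)
    _require_columns(df, ("ligand_conc_M", "signal"), path)
    conc = _numeric(df, "ligand_conc_M", path)
    sig = _numeric(df, "signal", path)
    neg = np.flatnonzero(conc <= 0)
    if neg.size:
        raise ValueError(
            f"{path}: non-positive ligand concentration at line {neg[0] + 2}"
        )
    order = np.argsort(conc)
    return TitrationSeries(ligand_conc=conc[order], signal=sig[order])


def write_titration_csv(series: TitrationSeries, path) -> None:
    pd.DataFrame(
        {"ligand_conc_M": series.ligand_conc, "signal": series.signal}
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_spectrum_csv(path) -> Spectrum:
    """Two-column format: wavenumber_cm1, absorbance."""
    df = _read_csv(path)
    _require_columns(df, ("wavenumber_cm1", "absorbance"), path)
    return Spectrum(
        _numeric(df, "wavenumber_cm1", path), _numeric(df, "absorbance", path)
    )


def write_spectrum_csv(s: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": s.wavenumbers, "absorbance": s.absorbance}
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_spectrum_series_csv(path) -> list[Spectrum]:
    """Wide format: one wavenumber column, one column per titration level."""
    df = _read_csv(path)
    _require_columns(df, ("wavenumber_cm1",), path)
    nu = _numeric(df, "wavenumber_cm1", path)
    levels = [c for c in df.columns if c != "wavenumber_cm1"]
    if not levels:
        raise ValueError(f"{path}: no absorbance columns")
    return [Spectrum(nu, _numeric(df, c, path)) for c in levels]


def write_spectrum_series_csv(spectra: list[Spectrum], path, labels=None) -> None:
    if not spectra:
        raise ValueError("no spectra to write")
    nu = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, nu):
            raise ValueError("spectra in a series must share one grid")
    if labels is None:
        labels = [f"level_{i}" for i in range(len(spectra))]
    data = {"wavenumber_cm1": nu}
    data.update({lab: s.absorbance for lab, s in zip(labels, spectra)})
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_uptake_csv(path) -> UptakeTable:
    """Columns: time_min, analyte, c_solution, c_adsorbed, c_absorbed, dose.

    Times in hours may be given via a time_h column instead; they are
    converted to minutes on ingest.  ``dose`` must be constant per analyte.
    """
    df = _read_csv(path)
    if "time_h" in df.columns and "time_min" not in df.columns:
        df = df.rename(columns={"time_h": "time_min"})
        df["time_min"] = _numeric(df, "time_min", path) * 60.0
    _require_columns(
        df, ("time_min", "analyte", "c_solution", "c_adsorbed", "c_absorbed", "dose"),
        path,
    )
    for col in ("time_min", "c_solution", "c_adsorbed", "c_absorbed", "dose"):
        df[col] = _numeric(df, col, path)
    dose = {}
    for an, grp in df.groupby("analyte"):
        vals = grp["dose"].unique()
        if len(vals) != 1:
            raise ValueError(f"{path}: dose for analyte {an!r} is not constant")
        dose[an] = float(vals[0])
    return UptakeTable(data=df.drop(columns=["dose"]), dose=dose)


def write_uptake_csv(table: UptakeTable, path) -> None:
    df = table.data.copy()
    df["dose"] = df["analyte"].map(table.dose)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
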