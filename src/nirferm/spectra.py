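"""Data model and CSV I/O for NIR spectra and reference concentrations.

Conventions
-----------
* The canonical spectral-axis unit is wavenumber (cm^-1), ascending.  The
  low-cost spectrometer reports wavelength (nm); such axes are converted on
  load so that all region arithmetic (truncation windows, saturated bands,
  noise-analysis intervals) lives in a single unit.
* Spectra CSV schema: metadata columns ``sample_id, experiment_id, time_h,
  instrument, modality, vessel_volume_L`` followed by one column per spectral
  channel.  Channel headers carry the unit as a prefix, e.g. ``cm-1:4000.0``
  or ``nm:2000.0``.
* Concentration CSV schema: ``sample_id`` plus one column per constituent in
  g/L.  Missing contaminant columns are treated as 0 g/L.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AxisError,
    DuplicateIdError,
    EmptyJoinError,
    ParseError,
    SchemaError,
)

WAVENUMBER = "cm-1"
WAVELENGTH = "nm"
UNITS = (WAVENUMBER, WAVELENGTH)

META_COLUMNS = [
    "sample_id",
    "experiment_id",
    "time_h",
    "instrument",
    "modality",
    "vessel_volume_L",
]
REQUIRED_META = ["sample_id", "experiment_id", "time_h", "instrument", "modality"]

#: The five constituents quantified by the calibration models (g/L).
CONSTITUENTS = ["glucose", "xylose", "bdo_total", "acetoin", "glycerol"]
#: Contaminants produced by bacterial contamination; used only for filtering.
CONTAMINANTS = ["ethanol", "lactic_acid", "acetic_acid"]


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered spectral channel positions with an explicit unit.

    Values are canonicalized to strictly ascending order on construction.
    ``bdo_total`` is 2,3-butanediol reported as the sum of its stereoisomers.
    """

    values: np.ndarray
    unit: str

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if self.unit not in UNITS:
            raise AxisError(f"unknown axis unit {self.unit!r}; expected one of {UNITS}")
        if vals.ndim != 1 or vals.size < 2:
            raise AxisError("spectral axis must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise AxisError("spectral axis values must be finite and > 0")
        vals = np.sort(vals)
        if np.any(np.diff(vals) <= 0):
            raise AxisError("spectral axis values must be distinct")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)

    def in_wavenumber(self) -> np.ndarray:
        """Channel positions expressed in cm^-1 (ascending order NOT guaranteed)."""
        if self.unit == WAVENUMBER:
            return self.values
        return 1e7 / self.values


def convert_axis(axis: SpectralAxis, target_unit: str) -> SpectralAxis:
    """Convert between wavenumber (cm^-1) and wavelength (nm).

    The mapping v -> 1e7 / v is an involution, so round trips return the
    original values to floating-point accuracy.  Converting to the axis's
    own unit is the identity.
    """
    if target_unit not in UNITS:
        raise AxisError(f"unknown target unit {target_unit!r}")
    if target_unit == axis.unit:
        return axis
    return SpectralAxis(1e7 / axis.values, target_unit)


def _canonical_meta(meta: pd.DataFrame, n_rows: int) -> pd.DataFrame:
    meta = meta.copy().reset_index(drop=True)
    for col in REQUIRED_META:
        if col not in meta.columns:
            raise SchemaError(f"missing required metadata column {col!r}")
    if "vessel_volume_L" not in meta.columns:
        meta["vessel_volume_L"] = np.nan
    meta = meta[META_COLUMNS]
    if len(meta) != n_rows:
        raise SchemaError(f"metadata has {len(meta)} rows, spectra have {n_rows}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["experiment_id"] = meta["experiment_id"].astype(str)
    meta["time_h"] = pd.to_numeric(meta["time_h"], errors="coerce").astype(float)
    meta["vessel_volume_L"] = pd.to_numeric(meta["vessel_volume_L"], errors="coerce").astype(float)
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicateIdError(f"duplicate sample_id values: {sorted(set(dups))}")
    if (meta["experiment_id"].str.len() == 0).any():
        raise SchemaError("experiment_id must be non-empty")
    return meta


@dataclass
class SpectraSet:
    """Absorbance matrix (n_samples x n_channels) with axis and sample metadata."""

    axis: SpectralAxis
    absorbance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self):
        ab = np.asarray(self.absorbance, dtype=float)
        if ab.ndim != 2:
            raise SchemaError("absorbance must be a 2-D matrix")
        if ab.shape[1] != len(self.axis):
            raise SchemaError(
                f"absorbance has {ab.shape[1]} columns but axis has {len(self.axis)} channels"
            )
        if ab.size and not np.all(np.isfinite(ab)):
            raise SchemaError("absorbance values must all be finite")
        self.absorbance = ab
        self.meta = _canonical_meta(self.meta, ab.shape[0])

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.meta["sample_id"].tolist()

    def select_rows(self, index: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(index, dtype=int)
        return SpectraSet(self.axis, self.absorbance[idx], self.meta.iloc[idx])

    def select_channels(self, mask: np.ndarray) -> "SpectraSet":
        axis = SpectralAxis(self.axis.values[mask], self.axis.unit)
        return SpectraSet(axis, self.absorbance[:, mask], self.meta)

    def to_wavenumber(self) -> "SpectraSet":
        """Return the set on the canonical ascending cm^-1 axis."""
        if self.axis.unit == WAVENUMBER:
            return self
        nu = 1e7 / self.axis.values  # descending
        order = np.argsort(nu)
        axis = SpectralAxis(nu[order], WAVENUMBER)
        return SpectraSet(axis, self.absorbance[:, order], self.meta)


def _format_float(v: float) -> str:
    return repr(float(v))


def write_spectra_table(spectra: SpectraSet, path) -> None:
    """Write the CSV schema accepted by :func:`read_spectra_table` (lossless floats)."""
    channel_cols = [f"{spectra.axis.unit}:{_format_float(v)}" for v in spectra.axis.values]
    channels = pd.DataFrame(spectra.absorbance, columns=channel_cols)
    df = pd.concat([spectra.meta.reset_index(drop=True), channels], axis=1)
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_table(path) -> SpectraSet:
    """Read a spectra CSV and return a validated :class:`SpectraSet` in cm^-1.

    Channel columns are recognized by their ``cm-1:`` / ``nm:`` header prefix,
    parsed in file order, canonicalized to ascending order, and (for nm axes)
    converted to wavenumber.
    """
    df = pd.read_csv(path, float_precision="round_trip",
                     dtype={c: str for c in ("sample_id", "experiment_id", "instrument", "modality")})
    chan_cols, positions, units = [], [], set()
    for col in df.columns:
        for unit in UNITS:
            prefix = unit + ":"
            if col.startswith(prefix):
                try:
                    positions.append(float(col[len(prefix):]))
                except ValueError as exc:
                    raise SchemaError(f"cannot parse channel header {col!r}") from exc
                chan_cols.append(col)
                units.add(unit)
    if not chan_cols:
        raise SchemaError("no channel columns found (headers must start with 'cm-1:' or 'nm:')")
    if len(units) > 1:
        raise SchemaError("mixed axis units in channel headers")
    for col in chan_cols:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[bad.isna() & df[col].notna()].tolist()
            raise ParseError(f"non-numeric absorbance in column {col!r}, rows {rows}") from exc
    missing = [c for c in REQUIRED_META if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required metadata column(s) {missing}")
    axis = SpectralAxis(np.array(positions), units.pop())
    order = np.argsort(np.asarray(positions))
    absorbance = df[chan_cols].to_numpy(dtype=float)[:, order]
    return SpectraSet(axis, absorbance, df).to_wavenumber()


@dataclass
class ConcentrationTable:
    """Per-sample constituent concentrations (g/L).

    Required columns: ``sample_id`` plus the five modeled constituents.
    Contaminant columns are optional and filled with 0 g/L when absent
    (absence of evidence of contamination).  Extra columns such as
    ``experiment_id``, ``time_h`` or simulator diagnostics are carried along
    untouched.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy().reset_index(drop=True)
        if "sample_id" not in df.columns:
            raise SchemaError("concentration table must have a sample_id column")
        df["sample_id"] = df["sample_id"].astype(str)
        missing = [c for c in CONSTITUENTS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing constituent column(s) {missing}")
        for col in CONTAMINANTS:
            if col not in df.columns:
                df[col] = 0.0
        for col in CONSTITUENTS + CONTAMINANTS:
            try:
                df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
            except (ValueError, TypeError) as exc:
                raise ParseError(f"non-numeric concentration in column {col!r}") from exc
            df[col] = df[col].fillna(0.0)
            if (df[col] < 0).any():
                raise SchemaError(f"negative concentration in column {col!r}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise DuplicateIdError(f"duplicate sample_id values: {sorted(set(dups))}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def matrix(self, columns: Sequence[str] = CONSTITUENTS) -> np.ndarray:
        return self.data[list(columns)].to_numpy(dtype=float)

    def subset(self, sample_ids: Sequence[str]) -> "ConcentrationTable":
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ConcentrationTable(df)


def write_concentration_table(conc: ConcentrationTable, path) -> None:
    conc.data.to_csv(path, index=False, float_format="%.17g")


def read_concentration_table(path) -> ConcentrationTable:
    return ConcentrationTable(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class JoinedDataset:
    """Spectra paired with reference concentrations on sample_id."""

    spectra: SpectraSet
    conc: ConcentrationTable
    n_unmatched_spectra: int
    n_unmatched_conc: int


def join_dataset(spectra: SpectraSet, conc: ConcentrationTable) -> JoinedDataset:
    """Inner-join spectra and concentrations on sample_id.

    Output preserves the spectra row order restricted to matched ids and the
    concentration table is re-ordered to align row-for-row with the spectra.
    """
    spec_ids = spectra.sample_ids
    conc_ids = set(conc.sample_ids)
    keep = [i for i, sid in enumerate(spec_ids) if sid in conc_ids]
    if not keep:
        raise EmptyJoinError("no sample_id is shared between spectra and concentrations")
    matched_ids = [spec_ids[i] for i in keep]
    joined_spectra = spectra.select_rows(np.asarray(keep))
    joined_conc = conc.subset(matched_ids)
    return JoinedDataset(
        spectra=joined_spectra,
        conc=joined_conc,
        n_unmatched_spectra=len(spec_ids) - len(keep),
        n_unmatched_conc=len(conc_ids - set(matched_ids)),
    )
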