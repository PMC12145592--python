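"""Spectral preprocessing chain: truncation, region removal, SNV, SG derivative.

The fixed step order is: pre-truncation -> saturated-region removal -> SNV ->
Savitzky-Golay derivative -> post-truncation.  Mean centering is deliberately
NOT part of this chain: centering is split-aware (validation rows must be
centered with the calibration mean) and therefore belongs to model fitting.

Numerical conventions, recorded in each result's provenance:

* SNV uses the sample (n-1) standard deviation, the dominant chemometrics
  convention; any consistent choice only rescales rows.
* The SG derivative is taken with respect to channel *index*, unscaled by the
  physical channel spacing, so models are not portable across resolutions
  without re-fitting.  Edges are trimmed ((window-1)/2 channels per side)
  rather than padded: padding would fabricate data, and the workflow
  truncates again after smoothing anyway.
* SG requires a uniform grid.  An axis is accepted when it is uniform either
  in its stored unit or in the reciprocal unit (a wavelength-native grid is
  uniform in nm but not in cm^-1); tolerance 1e-6 relative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import (
    AxisError,
    DegenerateSpectrumError,
    DimensionError,
    EmptySpectrumError,
    ParameterError,
)
from .spectra import SpectralAxis, SpectraSet, WAVENUMBER

SG_WINDOW_RANGE = (3, 21)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``sg_window=None`` disables Savitzky-Golay filtering (used e.g. when the
    chain is reduced to SNV alone).  Intervals are (lo, hi) in cm^-1.
    """

    pre_truncation: tuple[float, float] | None = None
    removed_regions: tuple[tuple[float, float], ...] = ()
    snv: bool = True
    sg_window: int | None = 11
    sg_polyorder: int = 2
    sg_deriv: int = 1
    post_truncation: tuple[float, float] | None = None

    def __post_init__(self):
        if self.sg_window is not None:
            w = self.sg_window
            if w % 2 == 0 or not (SG_WINDOW_RANGE[0] <= w <= SG_WINDOW_RANGE[1]):
                raise ParameterError(
                    f"sg_window must be odd and in {SG_WINDOW_RANGE}, got {w}"
                )
            if w <= self.sg_polyorder:
                raise ParameterError("sg_window must exceed sg_polyorder")
            if self.sg_deriv < 0 or self.sg_deriv > self.sg_polyorder:
                raise ParameterError("sg_deriv must be in [0, sg_polyorder]")
        for iv in ([self.pre_truncation] if self.pre_truncation else []) + \
                  list(self.removed_regions) + \
                  ([self.post_truncation] if self.post_truncation else []):
            lo, hi = iv
            if not lo < hi:
                raise ParameterError(f"interval {iv} must satisfy lo < hi")
        object.__setattr__(self, "removed_regions",
                           tuple(tuple(map(float, r)) for r in self.removed_regions))

    def to_dict(self) -> dict:
        return {
            "pre_truncation": list(self.pre_truncation) if self.pre_truncation else None,
            "removed_regions": [list(r) for r in self.removed_regions],
            "snv": self.snv,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_deriv": self.sg_deriv,
            "post_truncation": list(self.post_truncation) if self.post_truncation else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(
            pre_truncation=tuple(d["pre_truncation"]) if d.get("pre_truncation") else None,
            removed_regions=tuple(tuple(r) for r in d.get("removed_regions", ())),
            snv=bool(d.get("snv", True)),
            sg_window=d.get("sg_window"),
            sg_polyorder=int(d.get("sg_polyorder", 2)),
            sg_deriv=int(d.get("sg_deriv", 1)),
            post_truncation=tuple(d["post_truncation"]) if d.get("post_truncation") else None,
        )


@dataclass
class PreprocessedMatrix:
    """Transformed spectra ready for splitting/modeling.

    ``axis_cm1`` tracks the retained channel positions through every step;
    ``provenance`` lists the applied steps and their parameters.
    """

    matrix: np.ndarray
    axis_cm1: np.ndarray
    meta: pd.DataFrame
    provenance: list = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.meta["sample_id"].tolist()


def truncate_axis(spectra: SpectraSet, lo_cm1: float, hi_cm1: float) -> SpectraSet:
    """Retain channels with lo <= nu <= hi (inclusive), in cm^-1."""
    if not lo_cm1 < hi_cm1:
        raise ParameterError("truncation window must satisfy lo < hi")
    sp = spectra.to_wavenumber()
    mask = (sp.axis.values >= lo_cm1) & (sp.axis.values <= hi_cm1)
    if not mask.any():
        raise EmptySpectrumError(
            f"truncation to [{lo_cm1}, {hi_cm1}] cm^-1 leaves no channels"
        )
    return sp.select_channels(mask)


def remove_regions(
    spectra: SpectraSet, intervals: Sequence[tuple[float, float]]
) -> SpectraSet:
    """Drop channels falling inside any (lo, hi) cm^-1 interval (inclusive)."""
    if not intervals:
        return spectra
    sp = spectra.to_wavenumber()
    drop = np.zeros(len(sp.axis), dtype=bool)
    for lo, hi in intervals:
        if not lo < hi:
            raise ParameterError(f"interval ({lo}, {hi}) must satisfy lo < hi")
        drop |= (sp.axis.values >= lo) & (sp.axis.values <= hi)
    if drop.all():
        raise EmptySpectrumError("region removal leaves no channels")
    return sp.select_channels(~drop)


def snv_transform(spectra: SpectraSet) -> SpectraSet:
    """Standard Normal Variate: each row becomes (x - mean) / sd, sd with n-1.

    Corrects per-sample affine scatter: SNV(a*x + b) == SNV(x) for a > 0.
    """
    x = spectra.absorbance
    if x.shape[1] < 3:
        raise ParameterError("SNV needs at least 3 channels per row")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        bad = [spectra.sample_ids[i] for i in flat]
        raise DegenerateSpectrumError(f"constant spectrum (sd = 0) for sample(s) {bad}")
    return SpectraSet(spectra.axis, (x - mu) / sd, spectra.meta)


def _uniform_spacing(values: np.ndarray, rtol: float = 1e-6) -> bool:
    d = np.diff(values)
    return bool(np.all(np.abs(d - d[0]) <= rtol * np.abs(d[0])))


def _axis_segments(values: np.ndarray, rtol: float = 1e-6) -> list[slice]:
    """Contiguous uniformly spaced runs of the axis.

    A grid uniform in its stored unit, or uniform in the reciprocal unit
    (a wavelength-native axis expressed in cm^-1), is a single segment.
    Otherwise the axis is split at spacing jumps (gaps left by saturated-
    region removal) and each run must be uniform.
    """
    if _uniform_spacing(values, rtol) or _uniform_spacing(1e7 / values, rtol):
        return [slice(0, len(values))]
    d = np.diff(values)
    base = np.median(d)
    breaks = np.flatnonzero(np.abs(d - base) > rtol * base) + 1
    segments, start = [], 0
    for b in list(breaks) + [len(values)]:
        if b > start:
            seg = values[start:b]
            if len(seg) > 2 and not _uniform_spacing(seg, rtol):
                raise AxisError("SG filtering requires uniformly spaced channel runs")
            segments.append(slice(start, b))
        start = b
    return segments


def savitzky_golay(
    spectra: SpectraSet, window: int, polyorder: int = 2, deriv: int = 1
) -> SpectraSet:
    """Savitzky-Golay local polynomial derivative, edges trimmed.

    The derivative is per channel index (spacing 1); output loses
    (window-1)/2 channels at each end.  When saturated-region removal has
    left gaps in the grid, the filter runs independently within each
    contiguous uniform run, so no derivative spans a seam; each run then
    loses its own edges.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ParameterError("SG window must be odd and exceed polyorder")
    if not (SG_WINDOW_RANGE[0] <= window <= SG_WINDOW_RANGE[1]):
        raise ParameterError(f"SG window must lie in {SG_WINDOW_RANGE}")
    values = spectra.axis.values
    if window > len(values):
        raise ParameterError("SG window exceeds the number of channels")
    segments = _axis_segments(values)
    half = (window - 1) // 2
    filt = np.empty_like(spectra.absorbance)
    mask = np.zeros(len(values), dtype=bool)
    for seg in segments:
        if seg.stop - seg.start < window:
            raise AxisError(
                f"axis run of {seg.stop - seg.start} channels is shorter than the "
                f"SG window {window}"
            )
        filt[:, seg] = savgol_filter(
            spectra.absorbance[:, seg], window_length=window, polyorder=polyorder,
            deriv=deriv, delta=1.0, axis=1, mode="interp",
        )
        mask[seg.start + half:seg.stop - half] = True
    axis = SpectralAxis(values[mask], spectra.axis.unit)
    return SpectraSet(axis, filt[:, mask], spectra.meta)


def mean_center(
    matrix: np.ndarray, center: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column-center a matrix.

    Calibration mode (``center=None``): compute and subtract this matrix's
    own column means, returning them.  Validation mode: subtract the given
    calibration center — validation rows are never centered on themselves.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ParameterError("cannot center an empty matrix")
    if center is None:
        center = matrix.mean(axis=0)
    else:
        center = np.asarray(center, dtype=float)
        if center.shape != (matrix.shape[1],):
            raise DimensionError(
                f"center has length {center.shape}, matrix has {matrix.shape[1]} columns"
            )
    return matrix - center, center


def run_preprocess(spectra: SpectraSet, config: PreprocessConfig) -> PreprocessedMatrix:
    """Apply the full chain in fixed order and record provenance."""
    sp = spectra.to_wavenumber()
    steps: list[dict] = [{"step": "to_wavenumber"}]
    if config.pre_truncation:
        lo, hi = config.pre_truncation
        sp = truncate_axis(sp, lo, hi)
        steps.append({"step": "pre_truncation", "lo": lo, "hi": hi})
    if config.removed_regions:
        sp = remove_regions(sp, config.removed_regions)
        steps.append({"step": "remove_regions",
                      "intervals": [list(r) for r in config.removed_regions]})
    if config.snv:
        sp = snv_transform(sp)
        steps.append({"step": "snv", "sd": "n-1"})
    if config.sg_window is not None:
        sp = savitzky_golay(sp, config.sg_window, config.sg_polyorder, config.sg_deriv)
        steps.append({"step": "savitzky_golay", "window": config.sg_window,
                      "polyorder": config.sg_polyorder, "deriv": config.sg_deriv,
                      "edges": "trimmed", "derivative_scale": "per-channel-index"})
    if config.post_truncation:
        lo, hi = config.post_truncation
        sp = truncate_axis(sp, lo, hi)
        steps.append({"step": "post_truncation", "lo": lo, "hi": hi})
    return PreprocessedMatrix(
        matrix=sp.absorbance, axis_cm1=sp.axis.values, meta=sp.meta, provenance=steps
    )


def default_preprocess_config(profile_name: str, sg_window: int | None = 11) -> PreprocessConfig:
    """Per-modality defaults mirroring the published workflow.

    Lab-grade spectra are truncated to 9000-4000 cm^-1; nothing is removed
    from the low-cost spectra; the on-line configuration additionally drops
    the saturated water regions (5400-4800 cm^-1 and everything below
    4300 cm^-1) before transformation.
    """
    if profile_name == "low_cost_at_line":
        return PreprocessConfig(sg_window=sg_window)
    removed: tuple = ()
    if profile_name == "lab_on_line":
        removed = ((4800.0, 5400.0), (0.0, 4300.0))
    return PreprocessConfig(pre_truncation=(4000.0, 9000.0), removed_regions=removed,
                            sg_window=sg_window)


def select_sg_window(
    spectra: SpectraSet,
    conc,
    base_config: PreprocessConfig,
    candidates: Sequence[int],
    a_max: int = 10,
) -> int:
    """Choose the SG smoothing window by cross-validated model performance.

    For each candidate window the full preprocess + PLS leave-one-out
    protocol is run and scored as the mean range-normalized minimum RMSECV
    across constituents; the window minimizing the score wins, ties broken
    toward the smaller window.
    """
    from .pls import loo_cross_validate  # local import to avoid a cycle
    from .spectra import CONSTITUENTS

    candidates = sorted(set(int(w) for w in candidates))
    if not candidates:
        raise ParameterError("candidate window set is empty")
    for w in candidates:
        if w % 2 == 0 or not (SG_WINDOW_RANGE[0] <= w <= SG_WINDOW_RANGE[1]):
            raise ParameterError(f"candidate windows must be odd in {SG_WINDOW_RANGE}, got {w}")
    if spectra.n_samples < 10:
        raise ParameterError("window selection needs at least 10 samples")
    y = conc.matrix(CONSTITUENTS)
    ranges = y.max(axis=0) - y.min(axis=0)
    if np.any(ranges <= 0):
        raise ParameterError("every constituent needs a nonzero concentration range")
    best_w, best_score = None, np.inf
    for w in candidates:
        cfg = dataclasses.replace(base_config, sg_window=w)
        pm = run_preprocess(spectra, cfg)
        cv = loo_cross_validate(pm.matrix, y, a_max=min(a_max, spectra.n_samples - 2))
        score = float(np.mean(cv.rmsecv.min(axis=1) / ranges))
        if score < best_score - 1e-12:
            best_w, best_score = w, score
    return int(best_w)
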