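"""Validation metrics, heteroscedasticity screening, noise analysis, monitoring.

Four RMSE families summarize a model: RMSEC on the calibration set, RMSECV
from leave-one-out cross-validation, RMSEP on the independent (Kennard-Stone)
validation set, and RMSEP_unq on the wholly held-out unique experiment.  Each
is also reported divided by the constituent's calibration-set concentration
range, which makes errors comparable across constituents and datasets.

The published workflow screens residual-vs-predicted plots visually for
funneling; here a one-sided Spearman rank correlation between |residual| and
prediction serves as a reproducible proxy, and the plot data are always
emitted so the visual check remains possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateRangeError,
    DimensionError,
    ParameterError,
    RangeError,
    SampleSizeError,
    UndefinedStatisticError,
)
from .pls import CVResult, PLSModel, predict_pls
from .preprocess import PreprocessConfig, run_preprocess
from .spectra import CONSTITUENTS, ConcentrationTable, SpectraSet


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared difference; symmetric in its arguments."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape or observed.size < 1:
        raise DimensionError("observed and predicted must have equal length >= 1")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def normalized_rmse(rmse_value: float, calibration_range: float) -> float:
    """RMSE divided by the constituent's calibration-set concentration range."""
    if calibration_range <= 0:
        raise DegenerateRangeError("calibration range must be > 0")
    return float(rmse_value) / float(calibration_range)


def heteroscedasticity_check(
    predicted: np.ndarray, residuals: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float, float]:
    """Rank-correlation screen for funnel-shaped residual spread.

    Returns (flag, Spearman rho, one-sided p) where the alternative is that
    |residual| increases with the predicted value.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    residuals = np.asarray(residuals, dtype=float).ravel()
    if predicted.shape != residuals.shape:
        raise DimensionError("predicted and residuals must have equal length")
    if predicted.size < 10:
        raise SampleSizeError("heteroscedasticity check needs >= 10 pairs")
    if np.ptp(predicted) == 0:
        raise UndefinedStatisticError("predictions are constant; rank correlation undefined")
    rho, p = stats.spearmanr(np.abs(residuals), predicted, alternative="greater")
    return bool(p < alpha), float(rho), float(p)


@dataclass
class MetricsReport:
    """Per-constituent RMSE table plus screening flags and tidy plot data."""

    table: pd.DataFrame                       # indexed by constituent
    ranges: dict[str, float]
    counts: dict[str, int]
    heteroscedasticity: dict[str, dict[str, tuple[bool, float, float]]]
    plot_data: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "metrics": {c: {k: (None if pd.isna(v) else float(v))
                            for k, v in row.items()}
                        for c, row in self.table.to_dict(orient="index").items()},
            "ranges": self.ranges,
            "counts": self.counts,
            "heteroscedasticity": {
                subset: {c: {"flag": f, "statistic": s, "p_value": p}
                         for c, (f, s, p) in d.items()}
                for subset, d in self.heteroscedasticity.items()
            },
        }


_METRIC_KEYS = {"calibration": "rmsec", "cv": "rmsecv",
                "validation": "rmsep", "unique": "rmsep_unq"}


def evaluate_model(
    model: PLSModel,
    calibration: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    unique: tuple[np.ndarray, np.ndarray] | None = None,
    cv: CVResult | None = None,
    constituents: Sequence[str] = CONSTITUENTS,
) -> MetricsReport:
    """Compute all four RMSE families per constituent from one shared model.

    RMSECV is taken from ``cv`` at each response's selected component count.
    Normalization uses the calibration-set range of each constituent.  Absent
    subsets are reported as missing, not as errors.
    """
    constituents = list(constituents)
    m = len(constituents)
    if model.n_responses != m:
        raise DimensionError("model responses do not match the constituent list")
    Xc, Yc = calibration
    ranges = {c: float(Yc[:, j].max() - Yc[:, j].min()) for j, c in enumerate(constituents)}
    for c, r in ranges.items():
        if r <= 0:
            raise DegenerateRangeError(f"calibration range for {c} must be > 0")

    subsets: dict[str, tuple[np.ndarray, np.ndarray]] = {"calibration": (Xc, Yc)}
    if validation is not None and len(validation[0]):
        subsets["validation"] = validation
    if unique is not None and len(unique[0]):
        subsets["unique"] = unique

    rows = {c: {} for c in constituents}
    het: dict[str, dict[str, tuple[bool, float, float]]] = {}
    plot_data: dict[str, pd.DataFrame] = {}
    counts = {name: int(len(x)) for name, (x, _) in subsets.items()}
    for name, (X, Y) in subsets.items():
        pred = predict_pls(model, X)
        resid = pred - Y
        frame = []
        het[name] = {}
        for j, c in enumerate(constituents):
            val = rmse(Y[:, j], pred[:, j])
            key = _METRIC_KEYS[name]
            rows[c][key] = val
            rows[c]["n" + key] = normalized_rmse(val, ranges[c])
            if len(Y) >= 10 and np.ptp(pred[:, j]) > 0:
                het[name][c] = heteroscedasticity_check(pred[:, j], resid[:, j])
            frame.append(pd.DataFrame({
                "constituent": c, "sample": np.arange(len(Y)),
                "measured": Y[:, j], "predicted": pred[:, j], "residual": resid[:, j],
            }))
        plot_data[name] = pd.concat(frame, ignore_index=True)
    if cv is not None:
        counts["cv"] = int(len(Xc))
        for j, c in enumerate(constituents):
            a_j = int(model.selected[j])
            val = float(cv.rmsecv[j, a_j - 1])
            rows[c]["rmsecv"] = val
            rows[c]["nrmsecv"] = normalized_rmse(val, ranges[c])

    cols = ["rmsec", "rmsecv", "rmsep", "rmsep_unq",
            "nrmsec", "nrmsecv", "nrmsep", "nrmsep_unq"]
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)
    table.index.name = "constituent"
    table["range"] = [ranges[c] for c in table.index]
    table["selected_components"] = model.selected
    return MetricsReport(table=table, ranges=ranges, counts=counts,
                         heteroscedasticity=het, plot_data=plot_data)


@dataclass
class NoiseReport:
    """Mean replicate SD over the noise-analysis channels, per instrument."""

    mean_sd: dict[str, float]
    channels: dict[str, list[float]]
    reference: str
    ratio_to_reference: dict[str, float]


#: Default blank preprocessing for the noise comparison: the SG derivative
#: used for modeling, but no SNV.  SNV rescales each blank by its own spread,
#: which would conflate the two instruments' different water-spectrum shapes
#: with their channel noise; the index-based SG derivative applies the same
#: linear filter on both grids and preserves the noise ratio.
NOISE_PREPROCESS = PreprocessConfig(snv=False, sg_window=11)


def spectral_noise_analysis(
    blanks_by_instrument: Mapping[str, SpectraSet],
    lo: float = 4300.0,
    hi: float = 4480.0,
    n_channels: int = 10,
    preprocess_config: PreprocessConfig = NOISE_PREPROCESS,
) -> NoiseReport:
    """Compare instrument noise on processed water blanks.

    ``n_channels`` evenly spaced target wavenumbers on [lo, hi] (the most
    constituent-associated slice of the combination region) are snapped to
    each instrument's nearest retained channel, accounting for the different
    grids.  The per-channel SD across replicate blanks is averaged and each
    instrument's mean SD is reported as a ratio to the first (reference)
    instrument's.
    """
    if not blanks_by_instrument:
        raise ParameterError("need at least one instrument's blank set")
    targets = np.linspace(lo, hi, n_channels)
    mean_sd: dict[str, float] = {}
    channels: dict[str, list[float]] = {}
    for name, blanks in blanks_by_instrument.items():
        if blanks.n_samples < 2:
            raise SampleSizeError(f"instrument {name!r}: need >= 2 blank spectra")
        pm = run_preprocess(blanks, preprocess_config)
        axis = pm.axis_cm1
        if lo < axis.min() or hi > axis.max():
            raise RangeError(
                f"instrument {name!r}: interval [{lo}, {hi}] outside retained axis "
                f"[{axis.min():.1f}, {axis.max():.1f}]"
            )
        picked = sorted({int(np.argmin(np.abs(axis - t))) for t in targets})
        if len(picked) < n_channels:
            raise RangeError(
                f"instrument {name!r}: fewer than {n_channels} distinct channels in [{lo}, {hi}]"
            )
        sds = pm.matrix[:, picked].std(axis=0, ddof=1)
        mean_sd[name] = float(np.mean(sds))
        channels[name] = [float(axis[i]) for i in picked]
    reference = next(iter(blanks_by_instrument))
    ref_sd = mean_sd[reference]
    ratio = {name: (sd / ref_sd if ref_sd > 0 else np.nan) for name, sd in mean_sd.items()}
    return NoiseReport(mean_sd=mean_sd, channels=channels,
                       reference=reference, ratio_to_reference=ratio)


@dataclass
class TimeCoursePrediction:
    """Time-ordered model predictions, joinable against off-line measurements."""

    predictions: pd.DataFrame
    residuals: pd.DataFrame | None = None


def predict_timecourse(
    model: PLSModel,
    preprocess_config: PreprocessConfig,
    stream: SpectraSet,
    measured: ConcentrationTable | None = None,
    constituents: Sequence[str] = CONSTITUENTS,
) -> TimeCoursePrediction:
    """Apply the frozen preprocessing + model to an on-line spectra stream.

    Output rows are ordered by time (stable for ties).  Where sparse off-line
    reference measurements exist for a sample id, residuals are reported.
    """
    constituents = list(constituents)
    cols = ["sample_id", "time_h"] + constituents
    if stream.n_samples == 0:
        return TimeCoursePrediction(predictions=pd.DataFrame(columns=cols))
    pm = run_preprocess(stream, preprocess_config)
    if pm.matrix.shape[1] != model.n_channels:
        raise DimensionError(
            f"stream yields {pm.matrix.shape[1]} channels after preprocessing, "
            f"model expects {model.n_channels}"
        )
    pred = predict_pls(model, pm.matrix)
    out = pd.DataFrame(pred, columns=constituents)
    out.insert(0, "time_h", pm.meta["time_h"].to_numpy())
    out.insert(0, "sample_id", pm.meta["sample_id"].to_numpy())
    out = out.sort_values("time_h", kind="stable").reset_index(drop=True)
    residuals = None
    if measured is not None:
        ref = measured.data.set_index("sample_id")
        common = [s for s in out["sample_id"] if s in ref.index]
        if common:
            sub = out.set_index("sample_id").loc[common]
            res = {c: sub[c].to_numpy() - ref.loc[common, c].to_numpy()
                   for c in constituents}
            residuals = pd.DataFrame({"sample_id": common,
                                      "time_h": sub["time_h"].to_numpy(), **res})
    return TimeCoursePrediction(predictions=out, residuals=residuals)
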