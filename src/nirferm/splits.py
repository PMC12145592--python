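"""Contamination filtering and the three-way split design.

The split protocol: (1) all samples of one "unique" fermentation experiment
are removed wholesale and kept as an across-run generalization test;
(2) PCA scores explaining 95% of the transformed spectral variance are
computed on the remaining samples; (3) the Kennard-Stone algorithm picks the
calibration set in that score space; the unselected remainder is the
independent validation set.  Experiment leakage into calibration or
validation is impossible by construction.

PCA for the split is computed after removing the unique experiment, so no
information about the held-out run enters the score space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateDataError,
    ParameterError,
    SampleSizeError,
)
from .preprocess import PreprocessedMatrix
from .spectra import CONTAMINANTS, ConcentrationTable

CONTAMINATION_THRESHOLD_G_PER_L = 2.5


@dataclass
class FilterResult:
    kept_ids: list[str]
    excluded_ids: list[str]
    reasons: dict[str, str] = field(default_factory=dict)


def filter_contaminated(
    conc: ConcentrationTable, threshold_g_per_L: float = CONTAMINATION_THRESHOLD_G_PER_L
) -> FilterResult:
    """Exclude samples whose ethanol, lactic or acetic acid exceeds the threshold.

    The inequality is strict: a sample at exactly the threshold is kept.
    """
    kept, excluded, reasons = [], [], {}
    for _, row in conc.data.iterrows():
        sid = row["sample_id"]
        over = [c for c in CONTAMINANTS if row[c] > threshold_g_per_L]
        if over:
            excluded.append(sid)
            reasons[sid] = ", ".join(
                f"{c} = {row[c]:.3g} g/L > {threshold_g_per_L} g/L" for c in over
            )
        else:
            kept.append(sid)
    return FilterResult(kept_ids=kept, excluded_ids=excluded, reasons=reasons)


def pca_scores(
    matrix: np.ndarray, variance_threshold: float = 0.95
) -> tuple[np.ndarray, int, float]:
    """PCA scores retaining the smallest k components reaching the variance target.

    Columns are mean-centered internally; components come from an SVD of the
    centered matrix.  Returns (n x k scores, k, variance explained).
    """
    if not (0 < variance_threshold <= 1):
        raise ParameterError("variance_threshold must be in (0, 1]")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ParameterError("PCA needs a matrix with at least 3 rows")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0 or s[0] <= np.finfo(float).eps * max(x.shape) * 10:
        raise DegenerateDataError("matrix has no variance (all rows identical)")
    rank = int(np.sum(s > s[0] * np.finfo(float).eps * max(x.shape)))
    ratios = s**2 / total
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, rank)
    scores = u[:, :k] * s[:k]
    return scores, k, float(cum[k - 1])


def kennard_stone(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic greedy max-min (Kennard-Stone) subset selection.

    The first two selections are a pair at maximum Euclidean distance; each
    subsequent selection maximizes its minimum distance to the already
    selected set.  Ties break toward the lowest index.  Returns the selected
    indices in selection order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if not (2 <= k <= n):
        raise ParameterError(f"k must satisfy 2 <= k <= n = {n}, got {k}")
    sq = np.sum(pts**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (pts @ pts.T)
    np.maximum(d2, 0.0, out=d2)
    # farthest pair; np.argmax returns the first (lowest flat index) maximum,
    # which is the lexicographically smallest (i, j) pair
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    selected = [min(i, j), max(i, j)]
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    while len(selected) < k:
        min_d2[selected] = -np.inf
        nxt = int(np.argmax(min_d2))
        selected.append(nxt)
        np.minimum(min_d2, d2[nxt], out=min_d2)
    return np.asarray(selected)


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the three-way split.

    ``validation_fraction`` is 0.40 for the large lab-grade at-line dataset
    and 0.25 for the smaller low-cost and on-line datasets.  The unique
    experiment may be named explicitly; ``"auto"`` picks the experiment whose
    mean preprocessed spectrum is nearest the grand mean, a deterministic
    proxy for the expert judgment of "representative" (``seed`` is reserved
    for alternative auto policies and unused by this one).
    """

    unique_experiment_id: str = "auto"
    validation_fraction: float = 0.40
    pca_variance_threshold: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.validation_fraction < 1):
            raise ParameterError("validation_fraction must be in (0, 1)")
        if not (0 < self.pca_variance_threshold <= 1):
            raise ParameterError("pca_variance_threshold must be in (0, 1]")


@dataclass
class SplitResult:
    calibration_ids: list[str]
    validation_ids: list[str]
    unique_ids: list[str]
    unique_experiment_id: str
    n_components: int
    variance_explained: float
    rounding: str = "half-away-from-zero"

    def to_dict(self) -> dict:
        return {
            "calibration_ids": self.calibration_ids,
            "validation_ids": self.validation_ids,
            "unique_ids": self.unique_ids,
            "unique_experiment_id": self.unique_experiment_id,
            "n_components": self.n_components,
            "variance_explained": self.variance_explained,
            "rounding": self.rounding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitResult":
        return cls(**d)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def make_splits(pre: PreprocessedMatrix, spec: SplitSpec) -> SplitResult:
    """Produce the unique / calibration / validation partition.

    The three id sets are pairwise disjoint, their union is the whole input,
    and no sample of the unique experiment appears elsewhere.
    """
    meta = pre.meta
    ids = np.asarray(pre.sample_ids)
    experiments = meta["experiment_id"].to_numpy()
    uniq_experiments = sorted(set(experiments))
    if len(uniq_experiments) < 2:
        raise SampleSizeError("need at least 2 experiments to hold one out")
    if len(ids) < 10:
        raise SampleSizeError("need at least 10 samples to split")

    if spec.unique_experiment_id == "auto":
        grand = pre.matrix.mean(axis=0)
        best, best_d = None, np.inf
        for e in uniq_experiments:
            m = pre.matrix[experiments == e].mean(axis=0)
            d = float(np.linalg.norm(m - grand))
            if d < best_d:
                best, best_d = e, d
        unique_exp = best
    else:
        if spec.unique_experiment_id not in uniq_experiments:
            raise LookupError(f"unknown experiment id {spec.unique_experiment_id!r}")
        unique_exp = spec.unique_experiment_id

    unique_mask = experiments == unique_exp
    unique_ids = ids[unique_mask].tolist()
    rest_idx = np.flatnonzero(~unique_mask)
    n_rest = rest_idx.size
    scores, k, varexp = pca_scores(pre.matrix[rest_idx], spec.pca_variance_threshold)
    n_cal = _round_half_away((1.0 - spec.validation_fraction) * n_rest)
    if not (2 <= n_cal <= n_rest - 1):
        raise SampleSizeError(
            f"calibration size {n_cal} infeasible for {n_rest} remaining samples"
        )
    cal_local = kennard_stone(scores, n_cal)
    cal_set = set(cal_local.tolist())
    calibration_ids = ids[rest_idx[sorted(cal_set)]].tolist()
    validation_ids = ids[[i for j, i in enumerate(rest_idx) if j not in cal_set]].tolist()
    return SplitResult(
        calibration_ids=calibration_ids,
        validation_ids=validation_ids,
        unique_ids=unique_ids,
        unique_experiment_id=str(unique_exp),
        n_components=k,
        variance_explained=varexp,
    )
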