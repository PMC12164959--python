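"""Single-trial and condition-level GLM estimation for event-related BOLD runs.

Implements the least-squares-single (LSS) estimator: each trial is fit by its
own GLM in which the target trial is one explanatory variable (EV), all other
trials are collapsed into a second EV, plus an intercept.  Trial activation is
propagated downstream as a t-statistic map (beta / SE), the conventional
single-trial output for pattern-similarity analyses.

Also provides the canonical double-gamma haemodynamic response function (HRF),
boxcar convolution on the TR grid, and condition-level contrasts (category
effect, subsequent-memory effect) computed either from a condition GLM on raw
BOLD or directly from single-trial estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

# SPM-convention double-gamma parameters (seconds): response gamma with peak
# delay 6 and dispersion 1, undershoot gamma with delay 16 and dispersion 1,
# undershoot ratio 1/6, kernel length 32.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0

#: Memory outcomes counted as "forgotten" in subsequent-memory contrasts.
FORGOTTEN_OUTCOMES = ("assoc_miss", "item_hit", "item_miss")
REMEMBERED_OUTCOME = "assoc_hit"


def hrf_double_gamma(tr: float, length: float = HRF_LENGTH) -> np.ndarray:
    """Sample the canonical double-gamma HRF at interval ``tr``.

    The kernel is the difference of two gamma densities (peak minus
    undershoot, ratio 1:6) and is peak-normalised so that ``max == 1``.

    Parameters
    ----------
    tr : sampling interval in seconds (> 0).
    length : kernel duration in seconds; must be >= tr.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    if length < tr:
        raise ValueError(f"kernel length {length} shorter than tr {tr}")
    t = np.arange(0.0, length + 1e-9, tr)
    peak = sps.gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
    under = sps.gamma.pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, scale=HRF_UNDERSHOOT_DISP
    )
    h = peak - under / HRF_RATIO
    return h / h.max()


def boxcar_regressor(
    onsets: np.ndarray,
    duration: float,
    n_timepoints: int,
    tr: float,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Boxcar event regressor on the TR grid, optionally convolved with an HRF.

    A time point ``k`` is inside the boxcar when ``onset <= k*tr < onset +
    duration``.  Convolution is linear ('full' mode truncated to the run
    length), so non-overlapping events superpose additively.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    grid = np.arange(n_timepoints) * tr
    box = np.zeros(n_timepoints)
    for onset in np.atleast_1d(onsets):
        box += ((grid >= onset) & (grid < onset + duration)).astype(float)
    if kernel is None:
        return box
    return np.convolve(box, kernel)[:n_timepoints]


@dataclass
class DesignMatrix:
    """Time x regressor design with labels, for one GLM fit."""

    matrix: np.ndarray
    labels: list[str]
    tr: float
    convolution: str = "double-gamma"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("design matrix / label mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, tr: float) -> "DesignMatrix":
        return cls(frame.to_numpy(), list(frame.columns), tr)


def build_lss_design(
    onsets: np.ndarray,
    target_index: int,
    n_timepoints: int,
    tr: float,
    duration: float = 4.0,
    kernel: np.ndarray | None = None,
) -> DesignMatrix:
    """LSS design for one target trial: [target EV, all-other-trials EV, 1].

    The target trial is modelled as its own convolved boxcar; every remaining
    trial in the run is pooled into a single second EV.
    """
    onsets = np.asarray(onsets, dtype=float)
    if not 0 <= target_index < len(onsets):
        raise ValueError(f"target trial {target_index} not in run")
    if onsets[target_index] >= n_timepoints * tr:
        raise ValueError("target onset outside run duration")
    if kernel is None:
        kernel = hrf_double_gamma(tr)
    target = boxcar_regressor(onsets[[target_index]], duration, n_timepoints, tr, kernel)
    others_idx = np.delete(np.arange(len(onsets)), target_index)
    if len(others_idx):
        others = boxcar_regressor(onsets[others_idx], duration, n_timepoints, tr, kernel)
    else:
        others = np.zeros(n_timepoints)
    X = np.column_stack([target, others, np.ones(n_timepoints)])
    return DesignMatrix(X, ["target", "others", "intercept"], tr)


def _ols_tstats(X: np.ndarray, Y: np.ndarray, contrast: np.ndarray):
    """OLS of every column of Y on X; return (c'beta, t, df) for a contrast.

    Y may be (T, V); returns per-voxel contrast estimates and t-statistics.
    """
    T, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = T - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.sum(resid**2, axis=0) / df
    c = np.asarray(contrast, dtype=float)
    est = c @ beta
    se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    return est, t, df


def fit_lss(
    bold: np.ndarray,
    onsets: np.ndarray,
    tr: float,
    duration: float = 4.0,
    kernel: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares-single estimation for every trial of one run.

    Parameters
    ----------
    bold : (T, V) run matrix for one ROI.
    onsets : trial onsets in seconds.

    Returns
    -------
    betas, tvals : (n_trials, V) arrays of target-EV estimates and their
        t-statistics (beta / SE, residual df = T - 3).
    """
    bold = np.asarray(bold, dtype=float)
    T = bold.shape[0]
    if kernel is None:
        kernel = hrf_double_gamma(tr)
    n_trials = len(onsets)
    betas = np.empty((n_trials, bold.shape[1]))
    tvals = np.empty_like(betas)
    c = np.array([1.0, 0.0, 0.0])
    for j in range(n_trials):
        design = build_lss_design(onsets, j, T, tr, duration, kernel)
        X = design.matrix
        cj = c
        if not X[:, 1].any():  # single-trial run: drop the empty others EV
            X = X[:, [0, 2]]
            cj = np.array([1.0, 0.0])
        try:
            est, t, _ = _ols_tstats(X, bold, cj)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"rank-deficient LSS design for trial {j}"
            ) from err
        betas[j] = est
        tvals[j] = t
    return betas, tvals


# ---------------------------------------------------------------------------
# Condition-level contrasts
# ---------------------------------------------------------------------------

def _memory_class(outcomes: pd.Series) -> np.ndarray:
    """Map the five study outcomes to remembered / forgotten / excluded."""
    out = np.full(len(outcomes), "excluded", dtype=object)
    out[outcomes.to_numpy() == REMEMBERED_OUTCOME] = "remembered"
    out[np.isin(outcomes.to_numpy(), FORGOTTEN_OUTCOMES)] = "forgotten"
    return out


def _two_cell_glm(Y: np.ndarray, is_pos: np.ndarray) -> dict:
    """Closed-form two-indicator GLM per voxel: cell means, shared residual
    variance, and t statistics for [1,-1] and each cell-vs-baseline."""
    n1 = int(is_pos.sum())
    n2 = int((~is_pos).sum())
    m1 = Y[is_pos].mean(axis=0)
    m2 = Y[~is_pos].mean(axis=0)
    resid = Y - np.where(is_pos, 1.0, 0.0)[:, None] * m1 - np.where(is_pos, 0.0, 1.0)[:, None] * m2
    df = Y.shape[0] - 2
    sigma2 = np.sum(resid**2, axis=0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_diff = (m1 - m2) / np.sqrt(sigma2 * (1.0 / n1 + 1.0 / n2))
        t_pos = m1 / np.sqrt(sigma2 / n1)
        t_neg = m2 / np.sqrt(sigma2 / n2)
    return {
        "t_diff": t_diff, "t_pos": t_pos, "t_neg": t_neg,
        "m_pos": m1, "m_neg": m2, "df": df,
    }


def condition_contrast(
    patterns: np.ndarray,
    trials: pd.DataFrame,
    contrast: str,
    memory_condition: str | None = None,
    min_per_cell: int = 3,
    memclass: np.ndarray | None = None,
    categories: np.ndarray | None = None,
) -> dict:
    """Condition-level contrast from single-trial estimates of one ROI.

    A GLM across trials with one EV per condition cell is fit per voxel and
    the requested contrast's t-statistic is averaged over voxels.

    Parameters
    ----------
    patterns : (n_trials, V) single-trial t (or beta) patterns, rows aligned
        with ``trials``.
    contrast : ``"face_vs_place"`` or ``"rem_vs_forg"``.
    memory_condition : for ``face_vs_place``, restrict to ``"remembered"``
        or ``"forgotten"`` trials (None = all responded trials).

    Returns
    -------
    dict with ``mean_t``, per-voxel ``tvals``, per-cell voxel means, ``df``
    and a ``flag`` ("ok" or the reason the participant should be flagged).
    """
    patterns = np.asarray(patterns, dtype=float)
    if len(trials) != patterns.shape[0]:
        raise ValueError("trials / patterns row mismatch")
    if memclass is None:
        memclass = _memory_class(trials["memory_outcome"])

    if contrast == "face_vs_place":
        keep = memclass != "excluded"
        if memory_condition is not None:
            keep &= memclass == memory_condition
        if categories is None:
            categories = trials["category"].to_numpy()
        labels = categories[keep]
        pos, neg = "face", "place"
    elif contrast == "rem_vs_forg":
        keep = memclass != "excluded"
        labels = memclass[keep]
        pos, neg = "remembered", "forgotten"
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    is_pos = labels == pos
    n_pos = int(is_pos.sum())
    n_neg = int(len(labels) - n_pos)
    if min(n_pos, n_neg) < min_per_cell:
        return {
            "mean_t": np.nan,
            "tvals": None,
            "cell_means": {},
            "df": 0,
            "flag": f"cell below {min_per_cell} trials ({pos}={n_pos}, {neg}={n_neg})",
        }
    res = _two_cell_glm(patterns[keep], is_pos)
    return {
        "mean_t": float(np.mean(res["t_diff"])),
        "tvals": res["t_diff"],
        "cell_means": {pos: float(np.mean(res["t_pos"])), neg: float(np.mean(res["t_neg"]))},
        "mean_est": float(np.mean(res["m_pos"] - res["m_neg"])),
        "cell_ests": {pos: float(np.mean(res["m_pos"])), neg: float(np.mean(res["m_neg"]))},
        "df": res["df"],
        "flag": "ok",
    }


def condition_contrast_bold(
    bold: np.ndarray,
    trials: pd.DataFrame,
    tr: float,
    contrast: str,
    duration: float = 4.0,
    memory_condition: str | None = None,
    kernel: np.ndarray | None = None,
) -> dict:
    """Condition-level contrast fit directly on a BOLD run.

    One convolved boxcar EV per study condition (the five subsequent-memory
    outcomes crossed with stimulus category), plus an intercept; the contrast
    t is averaged over voxels.  Used to cross-check the pattern-based route.
    """
    bold = np.asarray(bold, dtype=float)
    T = bold.shape[0]
    if kernel is None:
        kernel = hrf_double_gamma(tr)
    cells = (
        trials["category"].astype(str) + ":" + trials["memory_outcome"].astype(str)
    ).to_numpy()
    uniq = sorted(set(cells))
    cols, labels = [], []
    for cell in uniq:
        onsets = trials.loc[cells == cell, "onset_seconds"].to_numpy()
        cols.append(boxcar_regressor(onsets, duration, T, tr, kernel))
        labels.append(cell)
    cols.append(np.ones(T))
    labels.append("intercept")
    X = np.column_stack(cols)

    memclass = {c: _memory_class(pd.Series([c.split(":")[1]]))[0] for c in uniq}
    weights = np.zeros(len(labels))
    if contrast == "face_vs_place":
        pos = [
            i for i, c in enumerate(uniq)
            if c.startswith("face") and memclass[c] != "excluded"
            and (memory_condition is None or memclass[c] == memory_condition)
        ]
        neg = [
            i for i, c in enumerate(uniq)
            if c.startswith("place") and memclass[c] != "excluded"
            and (memory_condition is None or memclass[c] == memory_condition)
        ]
    elif contrast == "rem_vs_forg":
        pos = [i for i, c in enumerate(uniq) if memclass[c] == "remembered"]
        neg = [i for i, c in enumerate(uniq) if memclass[c] == "forgotten"]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if not pos or not neg:
        return {"mean_t": np.nan, "tvals": None, "df": 0, "flag": "empty cell"}
    weights[pos] = 1.0 / len(pos)
    weights[neg] = -1.0 / len(neg)
    est, t, df = _ols_tstats(X, bold, weights)
    return {"mean_t": float(np.mean(t)), "tvals": t, "est": est, "df": df, "flag": "ok"}
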