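"""ROI neural selectivity: univariate contrasts, leave-one-out ROI masks, and
trial-level pattern-similarity selectivity.

Univariate selectivity of a category-preferring ROI is the mean
preferred-minus-nonpreferred contrast t over the ROI's voxels, extracted
separately for subsequently remembered (associative hit) and forgotten
(associative miss, item hit, item miss) trials.  Face-selective ROIs (FFA,
OFA) use face - place, place-selective ROIs (PPA, OPA, RSC) the reverse; all
individual-difference analyses use the mean across each ROI group.

Trial-level selectivity is a pattern-similarity statistic: a trial's mean
Fisher-z similarity to other same-category trials minus its mean similarity
to other-category trials, restricted to associative-hit trials, excluding
same-run pairs, after regressing the pair-mean activation out of the z
similarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import trialglm

MIN_ROI_VOXELS = 30


@dataclass
class RoiMask:
    """Voxel index set defining one ROI for one (held-out) participant."""

    name: str
    voxels: np.ndarray
    preferred_category: str | None
    provenance: str = "atlas"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.size == 0:
            raise ValueError(f"empty ROI mask {self.name}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.size)

    @property
    def excluded(self) -> bool:
        """True when the mask falls below the minimum usable size."""
        return self.n_voxels < MIN_ROI_VOXELS


def loo_roi_define(
    contrast_maps: dict,
    held_out: str,
    prior_mask: RoiMask,
    alpha: float = 0.001,
) -> RoiMask:
    """Define a participant's ROI from everyone else's category contrast.

    A voxelwise one-sample t test of the face-vs-place contrast is run across
    all participants except ``held_out``; voxels significant at the two-sided
    parametric threshold ``alpha`` are intersected with the prior (atlas)
    mask.  The held-out participant's own data never enter, so the returned
    mask is statistically independent of their patterns.
    """
    others = [pid for pid in contrast_maps if pid != held_out]
    if len(others) < 3:
        raise ValueError("need at least 3 non-held-out participants")
    stack = np.stack([contrast_maps[pid] for pid in others])
    tstat, pval = sps.ttest_1samp(stack, 0.0, axis=0)
    supra = np.flatnonzero(pval < alpha)
    voxels = np.intersect1d(supra, prior_mask.voxels)
    if voxels.size == 0:
        raise ValueError(
            f"empty intersection for ROI {prior_mask.name!r} (held out {held_out}); "
            "consider relaxing the voxelwise threshold"
        )
    return RoiMask(prior_mask.name, voxels, prior_mask.preferred_category, "loo-intersected")


def loo_roi_define_all(
    contrast_maps: dict,
    prior_mask: RoiMask,
    alpha: float = 0.001,
) -> dict:
    """Leave-one-out masks for every participant at once.

    Identical to calling :func:`loo_roi_define` per participant (the
    one-sample t over the n-1 others is computed from leave-one-out sums),
    at a fraction of the cost.
    """
    pids = list(contrast_maps)
    n = len(pids)
    if n - 1 < 3:
        raise ValueError("need at least 3 non-held-out participants")
    X = np.stack([contrast_maps[pid] for pid in pids])
    S = X.sum(axis=0)
    SS = (X**2).sum(axis=0)
    m = (S - X) / (n - 1)                      # per held-out voxel mean
    ss = SS - X**2 - (n - 1) * m**2            # residual sum of squares
    var = ss / (n - 2)
    se = np.sqrt(var / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, m / se, 0.0)
    pval = 2 * sps.t.sf(np.abs(t), n - 2)
    out = {}
    for k, pid in enumerate(pids):
        supra = np.flatnonzero(pval[k] < alpha)
        voxels = np.intersect1d(supra, prior_mask.voxels)
        if voxels.size == 0:
            raise ValueError(
                f"empty intersection for ROI {prior_mask.name!r} (held out {pid}); "
                "consider relaxing the voxelwise threshold"
            )
        out[pid] = RoiMask(
            prior_mask.name, voxels, prior_mask.preferred_category, "loo-intersected"
        )
    return out


def roi_selectivity(
    patterns: dict,
    trials: pd.DataFrame,
    masks: dict,
    memory_conditions: tuple = ("remembered", "forgotten"),
) -> pd.DataFrame:
    """Per-participant, per-ROI selectivity by subsequent-memory condition.

    Parameters
    ----------
    patterns : ``patterns[pid][roi]`` = (n_trials, V) single-trial t patterns
        (rows aligned with the participant's trials sorted by run, trial).
    masks : ``masks[pid][roi]`` -> :class:`RoiMask` (or ``masks[roi]`` shared).

    Returns a tidy frame with selectivity (preferred - nonpreferred mean
    contrast t over mask voxels), preferred and nonpreferred activity vs
    baseline, and a missing flag where a cell is unusable.
    """
    rows = []
    by_pid = {
        pid: sub.sort_values(["run_index", "trial_index"])
        for pid, sub in trials.groupby("participant_id", sort=False)
    }
    for pid, rois in patterns.items():
        tsub = by_pid[pid]
        memclass = trialglm._memory_class(tsub["memory_outcome"])
        cats = tsub["category"].to_numpy()
        pmasks = masks[pid] if pid in masks else masks
        for roi, pat in rois.items():
            if roi not in pmasks:
                continue
            mask = pmasks[roi]
            pref = mask.preferred_category
            if pref is None:
                continue
            nonpref = "place" if pref == "face" else "face"
            vox = pat[:, mask.voxels]
            for cond in memory_conditions:
                if mask.excluded:
                    rows.append(
                        {
                            "participant_id": pid, "roi": roi, "memory_condition": cond,
                            "selectivity": np.nan, "preferred_activity": np.nan,
                            "nonpreferred_activity": np.nan, "missing": True,
                            "flag": f"mask below {MIN_ROI_VOXELS} voxels",
                        }
                    )
                    continue
                res = trialglm.condition_contrast(
                    vox, tsub, "face_vs_place", memory_condition=cond,
                    memclass=memclass, categories=cats,
                )
                sign = 1.0 if pref == "face" else -1.0
                missing = res["flag"] != "ok"
                rows.append(
                    {
                        "participant_id": pid, "roi": roi, "memory_condition": cond,
                        "selectivity": sign * res["mean_t"],
                        "preferred_activity": res["cell_means"].get(pref, np.nan),
                        "nonpreferred_activity": res["cell_means"].get(nonpref, np.nan),
                        # contrast-estimate scale, where selectivity equals
                        # preferred minus nonpreferred exactly
                        "selectivity_est": sign * res.get("mean_est", np.nan),
                        "preferred_est": res.get("cell_ests", {}).get(pref, np.nan),
                        "nonpreferred_est": res.get("cell_ests", {}).get(nonpref, np.nan),
                        "missing": missing, "flag": res["flag"],
                    }
                )
    return pd.DataFrame(rows)


def group_selectivity(records: pd.DataFrame, groups: dict | None = None) -> pd.DataFrame:
    """Average member-ROI selectivity records into ROI-group records.

    Default groups: ``face_group`` = mean(FFA, OFA), ``place_group`` =
    mean(PPA, OPA, RSC); the arithmetic mean over the member ROIs present
    (missing members are dropped, with the record flagged if none remain).
    """
    if groups is None:
        groups = {"face_group": ["FFA", "OFA"], "place_group": ["PPA", "OPA", "RSC"]}
    rows = []
    for gname, members in groups.items():
        sub = records[records["roi"].isin(members) & ~records["missing"]]
        agg = (
            sub.groupby(["participant_id", "memory_condition"])[
                ["selectivity", "preferred_activity", "nonpreferred_activity"]
            ]
            .mean()
            .reset_index()
        )
        agg.insert(1, "roi_group", gname)
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)


def attenuation_broadening(group_records: pd.DataFrame) -> pd.DataFrame:
    """Preferred / nonpreferred activity per ROI group on remembered trials.

    The table feeds age x category models that ask whether selectivity loss
    reflects attenuation (reduced preferred activity) or broadening
    (elevated nonpreferred activity).
    """
    rem = group_records[group_records["memory_condition"] == "remembered"]
    long = rem.melt(
        id_vars=["participant_id", "roi_group"],
        value_vars=["preferred_activity", "nonpreferred_activity"],
        var_name="category_role",
        value_name="activity",
    )
    long["category_role"] = long["category_role"].str.replace("_activity", "", regex=False)
    return long


def dan_sme(
    patterns: dict, trials: pd.DataFrame, masks: dict, roi: str = "DAN"
) -> pd.DataFrame:
    """Per-participant subsequent-memory effect in an attention network ROI:
    mean remembered-vs-forgotten contrast t over the network's voxels."""
    rows = []
    by_pid = {
        pid: sub.sort_values(["run_index", "trial_index"])
        for pid, sub in trials.groupby("participant_id", sort=False)
    }
    for pid, rois in patterns.items():
        if roi not in rois:
            continue
        tsub = by_pid[pid]
        pmasks = masks[pid] if pid in masks else masks
        vox = rois[roi][:, pmasks[roi].voxels]
        memclass = trialglm._memory_class(tsub["memory_outcome"])
        res = trialglm.condition_contrast(vox, tsub, "rem_vs_forg", memclass=memclass)
        rows.append(
            {
                "participant_id": pid, "roi": roi, "sme": res["mean_t"],
                "missing": res["flag"] != "ok", "flag": res["flag"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trial-level pattern-similarity selectivity
# ---------------------------------------------------------------------------

_CLIP = 1.0 - 1e-15


def _psa_one_roi(
    pat: np.ndarray,
    runs: np.ndarray,
    cats: np.ndarray,
    separate_pair_means: bool = False,
):
    """Within/across residualized similarity per trial for one ROI.

    Steps: Pearson correlation between every included trial pair, excluding
    same-run pairs; Fisher z; regression of z on the pair-mean activation
    (one covariate plus intercept, fit over all eligible pairs); residual
    means over same-category and other-category partners.
    """
    T = pat.shape[0]
    C = np.corrcoef(pat)
    Z = np.arctanh(np.clip(C, -_CLIP, _CLIP))
    a = pat.mean(axis=1)
    iu, ju = np.triu_indices(T, k=1)
    elig = runs[iu] != runs[ju]
    ii, jj = iu[elig], ju[elig]
    z = Z[ii, jj]
    if separate_pair_means:
        X = np.column_stack([np.ones(len(z)), a[ii], a[jj]])
    else:
        X = np.column_stack([np.ones(len(z)), (a[ii] + a[jj]) / 2.0])
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    R = np.zeros((T, T))
    R[ii, jj] = resid
    R += R.T
    E = runs[:, None] != runs[None, :]
    same = cats[:, None] == cats[None, :]
    W = E & same
    A = E & ~same
    n_w = W.sum(axis=1)
    n_a = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        within = np.where(n_w > 0, (R * W).sum(axis=1) / np.maximum(n_w, 1), np.nan)
        across = np.where(n_a > 0, (R * A).sum(axis=1) / np.maximum(n_a, 1), np.nan)
    return within, across, n_w, n_a


def psa_trial_selectivity(
    patterns: dict,
    trials: pd.DataFrame,
    rois,
    separate_pair_means: bool = False,
) -> pd.DataFrame:
    """Trial-level selectivity for one participant over an ROI group.

    Parameters
    ----------
    patterns : ``patterns[roi]`` = (n_trials, V) single-trial t patterns for
        one participant, rows aligned with ``trials`` sorted by (run, trial).
    trials : that participant's trial table; only associative-hit trials are
        included in the similarity computation.
    rois : member ROIs of the group; the residualization is run per ROI and
        the per-trial within/across means are averaged across members.

    Returns one row per included trial with ``within_sim``, ``across_sim``,
    ``trial_selectivity`` (= within - across) and a ``missing`` flag for
    trials with no eligible partner in either category.
    """
    tsub = trials.reset_index(drop=True)
    order = tsub.sort_values(["run_index", "trial_index"]).index.to_numpy()
    tsub = tsub.iloc[order].reset_index(drop=True)
    hit = (tsub["memory_outcome"] == "assoc_hit").to_numpy()
    sub = tsub[hit]
    runs = sub["run_index"].to_numpy()
    cats = sub["category"].to_numpy()
    if len(np.unique(runs)) < 2:
        raise ValueError("pattern-similarity selectivity needs >= 2 runs")
    for cat in ("face", "place"):
        if (cats == cat).sum() < 2:
            raise ValueError(f"need >= 2 associative-hit {cat} trials")
    acc_w = np.zeros(len(sub))
    acc_a = np.zeros(len(sub))
    for roi in rois:
        pat = np.asarray(patterns[roi], dtype=float)[order][hit]
        w, a, n_w, n_a = _psa_one_roi(pat, runs, cats, separate_pair_means)
        acc_w = acc_w + w
        acc_a = acc_a + a
    within = acc_w / len(list(rois))
    across = acc_a / len(list(rois))
    out = sub[["participant_id", "run_index", "trial_index", "category"]].copy()
    out["within_sim"] = within
    out["across_sim"] = across
    out["trial_selectivity"] = within - across
    out["n_within_partners"] = n_w
    out["n_across_partners"] = n_a
    out["missing"] = ~np.isfinite(out["trial_selectivity"].to_numpy())
    return out.reset_index(drop=True)
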