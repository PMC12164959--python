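"""Independent brute-force reference implementations used only by tests.

These deliberately use explicit Python loops and separate small computations
so they share no code path with the package implementations they check.
"""

import math

import numpy as np


def psa_brute_force(patterns_by_roi, trials, rois):
    """Trial-level pattern-similarity selectivity by explicit double loops.

    Mirrors the contract of ``selectmem.selectivity.psa_trial_selectivity``:
    associative-hit trials only, same-run pairs excluded, Pearson
    correlation -> Fisher z -> per-ROI regression of z on the pair-mean
    activation (intercept + one covariate, via a separate normal-equations
    solve) -> residual within/across means averaged over ROIs.
    """
    tsub = trials.sort_values(["run_index", "trial_index"]).reset_index(drop=True)
    keep = [i for i in range(len(tsub)) if tsub.loc[i, "memory_outcome"] == "assoc_hit"]
    runs = [int(tsub.loc[i, "run_index"]) for i in keep]
    cats = [tsub.loc[i, "category"] for i in keep]
    T = len(keep)

    per_roi_within = []
    per_roi_across = []
    for roi in rois:
        pat = np.asarray(patterns_by_roi[roi], dtype=float)[keep]
        # pairwise correlations and z transform, one pair at a time
        zs = {}
        covs = {}
        for i in range(T):
            for j in range(i + 1, T):
                if runs[i] == runs[j]:
                    continue
                xi, xj = pat[i], pat[j]
                r = float(np.corrcoef(xi, xj)[0, 1])
                r = max(min(r, 1.0 - 1e-15), -1.0 + 1e-15)
                zs[(i, j)] = math.atanh(r)
                covs[(i, j)] = (float(xi.mean()) + float(xj.mean())) / 2.0
        # separate least-squares residualization via normal equations
        pairs = sorted(zs)
        zvec = np.array([zs[p] for p in pairs])
        cvec = np.array([covs[p] for p in pairs])
        A = np.column_stack([np.ones(len(pairs)), cvec])
        coef = np.linalg.solve(A.T @ A, A.T @ zvec)
        resid = {p: zs[p] - (coef[0] + coef[1] * covs[p]) for p in pairs}

        within = np.full(T, np.nan)
        across = np.full(T, np.nan)
        for i in range(T):
            w, a = [], []
            for j in range(T):
                if i == j or runs[i] == runs[j]:
                    continue
                key = (min(i, j), max(i, j))
                if cats[i] == cats[j]:
                    w.append(resid[key])
                else:
                    a.append(resid[key])
            if w:
                within[i] = sum(w) / len(w)
            if a:
                across[i] = sum(a) / len(a)
        per_roi_within.append(within)
        per_roi_across.append(across)

    within = np.mean(per_roi_within, axis=0)
    across = np.mean(per_roi_across, axis=0)
    return within, across, within - across


def all_subsets_r2(y, predictors):
    """R-squared of OLS for every subset of predictors, by direct fits."""
    import itertools

    names = list(predictors)
    out = {}
    for k in range(len(names) + 1):
        for subset in itertools.combinations(names, k):
            X = np.column_stack(
                [np.ones(len(y))] + [np.asarray(predictors[nm], float) for nm in subset]
            )
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            tss = float(np.sum((y - y.mean()) ** 2))
            out[frozenset(subset)] = 1.0 - float(resid @ resid) / tss
    return out


def bootstrap_corr_difference(x, y1, y2, n_boot=10000, seed=0):
    """Percentile bootstrap CI for cor(x,y1) - cor(x,y2), loop-free oracle."""
    rng = np.random.default_rng(seed)
    n = len(x)
    deltas = np.empty(n_boot)
    data = np.column_stack([x, y1, y2])
    for b in range(n_boot):
        d = data[rng.integers(0, n, n)]
        c = np.corrcoef(d, rowvar=False)
        deltas[b] = c[0, 1] - c[0, 2]
    return np.percentile(deltas, [2.5, 97.5])
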