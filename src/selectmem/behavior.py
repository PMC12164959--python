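"""Signal-detection memory scores and recall proportions.

Scores the in-scanner word-picture associative cued-recall test (associative
d'), the postscan exemplar cued-recall test (proportion correct), and the
mnemonic similarity task (MST; lure/new and old/lure d' per target-lure
similarity level, and the per-participant similarity slope).

Associative d' = Z(correct associate category | old) - Z(associate category |
new); trials with no response are excluded before rates are formed.  Hit and
false-alarm rates of exactly 0 or 1 are corrected to 1/(2N) and 1 - 1/(2N)
before the inverse-normal transform, so d' is always finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

PROBE_TYPES = ("old_face", "old_place", "new")
RESPONSES = ("face", "place", "old", "new", "none")


def corrected_rate(count: int, n: int) -> float:
    """Proportion with the Macmillan-Creelman 0/1 correction applied."""
    if n <= 0:
        raise ValueError("rate undefined for zero trials")
    rate = count / n
    if rate <= 0.0:
        return 1.0 / (2 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def _dprime(hit_count: int, n_old: int, fa_count: int, n_new: int) -> float:
    return float(
        norm.ppf(corrected_rate(hit_count, n_old)) - norm.ppf(corrected_rate(fa_count, n_new))
    )


def associative_dprime(responses: pd.DataFrame, scope: str = "overall") -> float:
    """Associative d' for one participant's test-phase response table.

    Parameters
    ----------
    responses : rows of (probe_type in {old_face, old_place, new},
        response in {face, place, old, new, none}).
    scope : ``"overall"`` pools both categories (false alarms are any
        category response to a new probe); ``"face"``/``"place"`` restrict
        hits to that category's old probes and false alarms to that category
        response on new probes.
    """
    if scope not in ("overall", "face", "place"):
        raise ValueError(f"unknown scope {scope!r}")
    resp = responses[responses["response"] != "none"]
    old = resp[resp["probe_type"].str.startswith("old")]
    new = resp[resp["probe_type"] == "new"]
    if scope in ("face", "place"):
        old = old[old["probe_type"] == f"old_{scope}"]
        hits = int((old["response"] == scope).sum())
        fas = int((new["response"] == scope).sum())
    else:
        hits = int(
            (old["response"] == old["probe_type"].str.removeprefix("old_")).sum()
        )
        fas = int(new["response"].isin(["face", "place"]).sum())
    if len(old) == 0 or len(new) == 0:
        raise ValueError("need at least one old and one new probe with a response")
    return _dprime(hits, len(old), fas, len(new))


def exemplar_recall_rate(posttest: pd.DataFrame) -> dict:
    """Proportion of old words whose specific exemplar was recalled.

    ``posttest`` has one row per studied word with columns ``category`` and
    ``exemplar_correct`` (0/1).  Returns overall and per-category rates.
    """
    if len(posttest) == 0:
        raise ValueError("empty posttest table")
    out = {"overall": float(posttest["exemplar_correct"].mean())}
    for cat in ("face", "place"):
        sub = posttest[posttest["category"] == cat]
        out[cat] = float(sub["exemplar_correct"].mean()) if len(sub) else np.nan
    return out


def mst_dprime(mst: pd.DataFrame, index: str, level: int) -> float:
    """MST sensitivity at one target-lure similarity level.

    ``mst`` rows: (probe_type in {target, lure, foil}, similarity_level for
    lures, response in {old, similar, new}).

    index = "lure_new": Z(similar | lure at level) - Z(similar | foil);
    index = "old_lure": Z(old | target) - Z(old | lure at level).
    """
    lures = mst[(mst["probe_type"] == "lure") & (mst["similarity_level"] == level)]
    if len(lures) == 0:
        raise ValueError(f"no lure probes at similarity level {level}")
    if index == "lure_new":
        foils = mst[mst["probe_type"] == "foil"]
        return _dprime(
            int((lures["response"] == "similar").sum()), len(lures),
            int((foils["response"] == "similar").sum()), len(foils),
        )
    if index == "old_lure":
        targets = mst[mst["probe_type"] == "target"]
        return _dprime(
            int((targets["response"] == "old").sum()), len(targets),
            int((lures["response"] == "old").sum()), len(lures),
        )
    raise ValueError(f"unknown MST index {index!r}")


def mst_similarity_slope(dprimes, levels=None) -> float:
    """Least-squares slope of per-level d' on similarity-level index.

    The field-standard summary is the participant slope from a random-slope
    mixed model; the per-participant OLS slope used here is identical up to
    shrinkage and needs no group fit.  Requires >= 3 finite values.
    """
    d = np.asarray(dprimes, dtype=float)
    if levels is None:
        levels = np.arange(1, len(d) + 1, dtype=float)
    levels = np.asarray(levels, dtype=float)
    ok = np.isfinite(d)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite d' values")
    x, y = levels[ok], d[ok]
    return float(np.polyfit(x, y, 1)[0])


def flag_low_trial_participants(trials: pd.DataFrame, min_trials: int = 3) -> pd.DataFrame:
    """Inclusion gate for individual-difference analyses.

    Flags participants with fewer than ``min_trials`` study trials in any of
    the four category x memory (remembered / forgotten) cells; no-response
    trials belong to neither cell.
    """
    rem = trials["memory_outcome"] == "assoc_hit"
    forg = trials["memory_outcome"].isin(["assoc_miss", "item_hit", "item_miss"])
    cell = np.select([rem, forg], ["remembered", "forgotten"], default="none")
    tab = pd.crosstab(
        trials["participant_id"], [trials["category"], pd.Series(cell, index=trials.index)]
    )
    out = pd.DataFrame({"participant_id": tab.index})
    cols = []
    for cat in ("face", "place"):
        for mc in ("remembered", "forgotten"):
            name = f"{cat}_{mc}"
            cols.append(name)
            out[name] = (
                tab[(cat, mc)].to_numpy() if (cat, mc) in tab.columns else 0
            )
    out.insert(1, "excluded", (out[cols] < min_trials).any(axis=1))
    return out.reset_index(drop=True)


def _corrected_rates(counts: np.ndarray, n: np.ndarray) -> np.ndarray:
    if np.any(n <= 0):
        raise ValueError("rate undefined for zero trials")
    rate = counts / n
    rate = np.where(rate <= 0.0, 1.0 / (2 * n), rate)
    return np.where(rate >= 1.0, 1.0 - 1.0 / (2 * n), rate)


def score_memory(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant associative d' (overall, face, place) from a pooled
    response table covering many participants.

    Vectorised equivalent of calling :func:`associative_dprime` per
    participant and scope (counts are aggregated once, then corrected and
    transformed in bulk).
    """
    r = responses[responses["response"] != "none"]
    is_old = r["probe_type"].str.startswith("old").to_numpy()
    old = r[is_old]
    new = r[~is_old]
    oldcat = old["probe_type"].str.removeprefix("old_")
    pid_order = responses["participant_id"].unique()

    def counts(frame, flag):
        g = frame.groupby("participant_id")
        total = g.size().reindex(pid_order)
        k = (
            pd.Series(flag, index=frame.index)
            .groupby(frame["participant_id"]).sum().reindex(pid_order)
        )
        return k.to_numpy(dtype=float), total.to_numpy(dtype=float)

    out = {"participant_id": pid_order}
    # overall: correct-category responses to old words; any category FA to new
    h, n_old = counts(old, (old["response"] == oldcat).to_numpy())
    f, n_new = counts(new, new["response"].isin(["face", "place"]).to_numpy())
    out["d_overall"] = norm.ppf(_corrected_rates(h, n_old)) - norm.ppf(
        _corrected_rates(f, n_new)
    )
    for cat in ("face", "place"):
        sub = old[(oldcat == cat).to_numpy()]
        h, n_o = counts(sub, (sub["response"] == cat).to_numpy())
        f, n_n = counts(new, (new["response"] == cat).to_numpy())
        out[f"d_{cat}"] = norm.ppf(_corrected_rates(h, n_o)) - norm.ppf(
            _corrected_rates(f, n_n)
        )
    return pd.DataFrame(out)
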