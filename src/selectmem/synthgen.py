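"""Synthetic cohorts for the encoding-phase selectivity analysis.

Generates participant tables, per-participant study trial tables, test-phase
response tables, per-trial voxel activation patterns per ROI, and (optionally)
raw BOLD run matrices, with the statistical structure the downstream analysis
assumes.

The individual-difference structure follows a user-declared recursive path
system on standardized variables:

    M1 = k1 + a1*X + e1          (age -> plasma pTau181)
    M3 =      a3*X + e3          (age -> top-down attention, DAN SME)
    M2 = k2 + a2*X + d21*M1 + d23*M3 + e2   (-> neural selectivity)
    Y  = k3 + c'*X + b1*M1 + b2*M2 + b3*M3 + e4  (-> memory propensity)

Residual SDs default to the values that give every variable unit population
variance, so the declared coefficients are simultaneously the raw and the
completely standardized path values.  Trial-level memory outcomes are drawn
from a logistic link on the participant's memory propensity plus a per-trial
signal-quality latent; voxel patterns are category templates scaled by a
participant selectivity gain that is linear in M2 (remembered trials) plus a
run-shared nuisance component and white noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import trialglm

FACE_ROIS = ("OFA", "FFA")
PLACE_ROIS = ("OPA", "PPA", "RSC")
ATTENTION_ROIS = ("DAN", "VAN")
DEFAULT_ROIS = FACE_ROIS + PLACE_ROIS + ATTENTION_ROIS

MEMORY_OUTCOMES = ("assoc_hit", "assoc_miss", "item_hit", "item_miss", "no_response")

#: Paths with the signs reported for the aging cohort: pTau rises with age,
#: DAN SME and selectivity fall with age, pTau suppresses selectivity, DAN
#: engagement raises it, and selectivity supports memory.
DEFAULT_TRUE_PATHS = {
    "a1": 0.35,   # age -> pTau181
    "a2": -0.25,  # age -> selectivity (direct)
    "a3": -0.30,  # age -> DAN SME
    "d21": -0.25, # pTau181 -> selectivity
    "d23": 0.35,  # DAN SME -> selectivity
    "b1": -0.20,  # pTau181 -> memory (direct)
    "b2": 0.40,   # selectivity -> memory
    "b3": 0.25,   # DAN SME -> memory (direct)
    "c_prime": -0.20,  # age -> memory (direct)
}

NULL_TRUE_PATHS = {k: 0.0 for k in DEFAULT_TRUE_PATHS}


@dataclass
class GenerativeConfig:
    """All knobs of the generative model, with cohort-realistic defaults."""

    n_participants: int = 150
    n_runs: int = 5
    trials_per_run: int = 24          # half face, half place
    n_voxels_per_roi: int = 40
    roi_names: tuple = DEFAULT_ROIS
    true_paths: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_PATHS))
    noise_sd: dict | float | None = None  # None -> unit-variance residuals
    category_signal: float = 1.0
    rem_gain: float = 1.0             # preferred-category gain level, remembered trials
    forg_gain: float = 0.5            # same, forgotten trials (no M2 dependence)
    sel_gain: float = 0.5             # gain change per SD of latent selectivity (M2)
    dan_base_sme: float = 0.5         # DAN remembered-trial amplitude boost at M3 = 0
    dan_gain: float = 0.5             # boost change per SD of DAN latent (M3)
    van_sme: float = 0.15             # constant VAN subsequent-memory amplitude
    nonpref_gain: float = 0.3         # nonpreferred-category response level
    pattern_gain: float = 1.0         # strength of the category spatial pattern
    quality_coupling: float = 0.2     # trial signal-quality -> pattern gain
    run_nuisance_sd: float = 0.3
    pattern_noise_sd: float = 1.0
    memory_link: dict = field(
        default_factory=lambda: {"intercept": -0.3, "slope": 0.7, "quality_slope": 0.4}
    )
    nonhit_proportions: tuple = (0.40, 0.30, 0.20, 0.10)  # miss/item_hit/item_miss/none
    fa_category_rate: float = 0.20    # category responses to new test probes
    new_probes_per_run: int = 6
    age_range: tuple = (60.0, 88.0)
    tr_seconds: float = 2.0
    event_duration_seconds: float = 4.0
    iti_seconds: float = 4.0
    bold_noise_sd: float = 0.5
    bold_tail_seconds: float = 16.0
    seed: int = 0

    # -- derived -----------------------------------------------------------
    @property
    def face_rois(self) -> tuple:
        return tuple(r for r in self.roi_names if r in FACE_ROIS)

    @property
    def place_rois(self) -> tuple:
        return tuple(r for r in self.roi_names if r in PLACE_ROIS)

    def preferred_category(self, roi: str) -> str | None:
        if roi in FACE_ROIS:
            return "face"
        if roi in PLACE_ROIS:
            return "place"
        return None

    def validate(self) -> None:
        if self.n_participants < 3:
            raise ValueError("n_participants must be >= 3")
        for name in ("n_runs", "trials_per_run", "n_voxels_per_roi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trials_per_run % 2:
            raise ValueError("trials_per_run must be even (half face, half place)")
        if self.n_voxels_per_roi < 2:
            raise ValueError("n_voxels_per_roi must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        vals = np.array([self.true_paths[k] for k in DEFAULT_TRUE_PATHS], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite path coefficient in true_paths")
        if abs(sum(self.nonhit_proportions) - 1.0) > 1e-9:
            raise ValueError("nonhit_proportions must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_names"] = list(self.roi_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeConfig":
        d = dict(d)
        if "roi_names" in d:
            d["roi_names"] = tuple(d["roi_names"])
        for key in ("nonhit_proportions", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _streams(config: GenerativeConfig, n: int) -> list[np.random.Generator]:
    """Deterministic independent substreams derived from the config seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


# ---------------------------------------------------------------------------
# Path system
# ---------------------------------------------------------------------------

def residual_sds_for_unit_variance(paths: dict) -> dict:
    """Residual SDs e1..e4 that give every endogenous variable unit variance.

    Derived from the implied covariance algebra of the recursive system with
    standardized X; floored at 0.2 so a near-saturated system stays stochastic.
    """
    a1, a2, a3 = paths["a1"], paths["a2"], paths["a3"]
    d21, d23 = paths["d21"], paths["d23"]
    b1, b2, b3, cp = paths["b1"], paths["b2"], paths["b3"], paths["c_prime"]

    def sd(explained: float) -> float:
        return float(np.sqrt(max(1.0 - explained, 0.04)))

    s1 = sd(a1**2)
    s3 = sd(a3**2)
    # covariance matrix of (x, m1, m3) with unit variances
    cov_xm = np.array([[1, a1, a3], [a1, 1, a1 * a3], [a3, a1 * a3, 1]])
    w2 = np.array([a2, d21, d23])
    s2 = sd(float(w2 @ cov_xm @ w2))
    # extend to (x, m1, m3, m2)
    c_xm2 = a2 + d21 * a1 + d23 * a3
    c_m1m2 = a2 * a1 + d21 + d23 * a1 * a3
    c_m3m2 = a2 * a3 + d21 * a1 * a3 + d23
    cov4 = np.array(
        [
            [1, a1, a3, c_xm2],
            [a1, 1, a1 * a3, c_m1m2],
            [a3, a1 * a3, 1, c_m3m2],
            [c_xm2, c_m1m2, c_m3m2, 1],
        ]
    )
    w4 = np.array([cp, b1, b3, b2])
    s4 = sd(float(w4 @ cov4 @ w4))
    return {"e1": s1, "e2": s2, "e3": s3, "e4": s4}


def _resolve_noise(config: GenerativeConfig) -> dict:
    if config.noise_sd is None:
        return residual_sds_for_unit_variance(config.true_paths)
    if np.isscalar(config.noise_sd):
        return {k: float(config.noise_sd) for k in ("e1", "e2", "e3", "e4")}
    return {k: float(config.noise_sd[k]) for k in ("e1", "e2", "e3", "e4")}


def simulate_path_system(
    config: GenerativeConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw n observations of (x, m1, m2, m3, y) plus inert covariates.

    ``x`` is standard normal (a standardized age proxy); the endogenous
    variables follow the declared linear equations exactly before noise is
    added.  ``sex`` and ``education_z`` carry no true effect.
    """
    p = config.true_paths
    s = _resolve_noise(config)
    x = rng.standard_normal(n)
    m1 = p["a1"] * x + rng.standard_normal(n) * s["e1"]
    m3 = p["a3"] * x + rng.standard_normal(n) * s["e3"]
    m2_struct = p["a2"] * x + p["d21"] * m1 + p["d23"] * m3
    m2 = m2_struct + rng.standard_normal(n) * s["e2"]
    y_struct = p["c_prime"] * x + p["b1"] * m1 + p["b2"] * m2 + p["b3"] * m3
    y = y_struct + rng.standard_normal(n) * s["e4"]
    sex = (rng.random(n) < 0.57).astype(int)
    educ = rng.standard_normal(n)
    return pd.DataFrame(
        {
            "x": x, "m1": m1, "m2": m2, "m3": m3, "y": y,
            "m2_structural": m2_struct, "y_structural": y_struct,
            "sex": sex, "education_z": educ,
        }
    )


# ---------------------------------------------------------------------------
# Cohort and trials
# ---------------------------------------------------------------------------

def generate_cohort(
    config: GenerativeConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the participant table and the pooled per-trial table.

    Returns
    -------
    participants : one row per participant with demographics, biomarkers and
        the generation-only latents (``latent_selectivity``, ``dan_sme_true``,
        ``y_propensity``).
    trials : one row per study trial (participant_id, run_index, trial_index,
        category, onset_seconds, signal_quality, memory_outcome).
    """
    config.validate()
    rng_path, rng_demo, rng_trial = _streams(config, 5)[:3]
    n = config.n_participants

    lat = simulate_path_system(config, n, rng_path)

    lo, hi = config.age_range
    age = rng_demo.uniform(lo, hi, n)
    # standardized age drives the path system: replace x by z(age) while
    # keeping the conditional draws; equivalent to conditioning on age.
    pop_sd = (hi - lo) / np.sqrt(12.0)
    x = (age - (lo + hi) / 2.0) / pop_sd
    p = config.true_paths
    s = _resolve_noise(config)
    m1 = p["a1"] * x + (lat["m1"] - p["a1"] * lat["x"]).to_numpy()
    m3 = p["a3"] * x + (lat["m3"] - p["a3"] * lat["x"]).to_numpy()
    e2 = (lat["m2"] - lat["m2_structural"]).to_numpy()
    m2 = p["a2"] * x + p["d21"] * m1 + p["d23"] * m3 + e2
    e4 = (lat["y"] - lat["y_structural"]).to_numpy()
    y = p["c_prime"] * x + p["b1"] * m1 + p["b2"] * m2 + p["b3"] * m3 + e4

    sex = (rng_demo.random(n) < 0.57).astype(int)
    education = np.clip(np.round(rng_demo.normal(16.7, 2.0, n)), 8, 30)
    abeta = 0.10 + 0.01 * (-0.4 * m1 + rng_demo.standard_normal(n) * np.sqrt(1 - 0.16))

    ids = [f"sub-{i + 1:03d}" for i in range(n)]
    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "age": age,
            "age_z": x,
            "sex": sex,
            "education": education,
            "ptau181": 1.59 + 0.54 * m1,
            "ptau181_z": m1,
            "abeta_ratio": abeta,
            "latent_selectivity": m2,
            "dan_sme_true": m3,
            "y_propensity": y,
        }
    )
    if not np.all(np.isfinite(participants.select_dtypes(float).to_numpy())):
        raise ValueError("non-finite biomarker values generated")

    trials = _generate_trials(config, participants, rng_trial)
    return participants, trials


def _generate_trials(
    config: GenerativeConfig, participants: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    half = config.trials_per_run // 2
    spacing = config.event_duration_seconds + config.iti_seconds
    link = config.memory_link
    nonhit = np.asarray(config.nonhit_proportions, dtype=float)
    n = len(participants)
    blocks = n * config.n_runs
    tn = config.trials_per_run

    cats = np.tile(
        np.array([0] * half + [1] * half, dtype=np.int8), (blocks, 1)
    )
    cats = rng.permuted(cats, axis=1)  # independent shuffle per run
    quality = rng.standard_normal((blocks, tn))
    y = np.repeat(participants["y_propensity"].to_numpy(), config.n_runs)[:, None]
    logit = link["intercept"] + link["slope"] * y + link["quality_slope"] * quality
    p_hit = 1.0 / (1.0 + np.exp(-logit))
    hit = rng.random((blocks, tn)) < p_hit
    # conditional draw of the non-hit class via the inverse CDF
    cls = 1 + np.searchsorted(np.cumsum(nonhit), rng.random((blocks, tn)))
    cls = np.minimum(cls, len(MEMORY_OUTCOMES) - 1)
    cls[hit] = 0
    outcomes = np.asarray(MEMORY_OUTCOMES, dtype=object)[cls]

    return pd.DataFrame(
        {
            "participant_id": np.repeat(
                participants["participant_id"].to_numpy(), config.n_runs * tn
            ),
            "run_index": np.tile(
                np.repeat(np.arange(1, config.n_runs + 1), tn), n
            ),
            "trial_index": np.tile(np.arange(1, tn + 1), blocks),
            "category": np.where(cats.ravel() == 0, "face", "place"),
            "onset_seconds": np.tile(np.arange(tn) * spacing, blocks),
            "signal_quality": quality.ravel(),
            "memory_outcome": outcomes.ravel(),
        }
    )


def generate_responses(
    config: GenerativeConfig, participants: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Test-phase response table implied by the study-trial outcomes.

    Studied words map outcomes to responses (associative hit -> correct
    category; associative miss -> wrong category; item hit -> "old"; item
    miss -> "new"; no response -> "none").  New (foil) probes draw category
    false alarms at the configured rate, split evenly between categories.
    """
    rng = _streams(config, 5)[3]
    cat = trials["category"].to_numpy()
    out = trials["memory_outcome"].to_numpy()
    other = np.where(cat == "face", "place", "face")
    resp = np.select(
        [out == "assoc_hit", out == "assoc_miss", out == "item_hit", out == "item_miss"],
        [cat, other, "old", "new"],
        default="none",
    )
    old = pd.DataFrame(
        {
            "participant_id": trials["participant_id"],
            "probe_type": "old_" + trials["category"],
            "response": resp,
        }
    )
    pids = trials["participant_id"].unique()
    n_new = config.new_probes_per_run * config.n_runs
    u = rng.random((len(pids), n_new))
    new_resp = np.select(
        [u < config.fa_category_rate / 2, u < config.fa_category_rate],
        ["face", "place"],
        default="new",
    )
    new = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, n_new),
            "probe_type": "new",
            "response": new_resp.ravel(),
        }
    )
    return pd.concat([old, new], ignore_index=True)


def generate_posttest(
    config: GenerativeConfig, participants: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Postscan cued-recall table: exemplar-correct flags for all old words.

    Exemplar-specific recall is most likely on associative-hit trials and
    scales with the participant's memory propensity.
    """
    rng = _streams(config, 5)[4]
    ymap = participants.set_index("participant_id")["y_propensity"]
    logit = -0.5 + 0.5 * trials["participant_id"].map(ymap).to_numpy()
    base = 1.0 / (1.0 + np.exp(-logit))
    p_correct = np.where(trials["memory_outcome"] == "assoc_hit", base, 0.1 * base)
    correct = rng.random(len(trials)) < p_correct
    return pd.DataFrame(
        {
            "participant_id": trials["participant_id"],
            "category": trials["category"],
            "exemplar_correct": correct.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# Patterns and BOLD
# ---------------------------------------------------------------------------

def roi_templates(config: GenerativeConfig) -> dict:
    """Fixed per-ROI voxel templates (mean 1 so ROI means track responses).

    Every ROI has a ``base`` template shared by all trials; category-selective
    ROIs add face/place response templates, attention ROIs a task template.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[5])
    templates = {}
    for roi in config.roi_names:
        tmpl = {"base": 1.0 + rng.standard_normal(config.n_voxels_per_roi)}
        if config.preferred_category(roi) is None:
            tmpl["task"] = 1.0 + rng.standard_normal(config.n_voxels_per_roi)
        else:
            # zero-mean multivoxel category patterns: category information
            # lives in the spatial pattern, mean activation is carried
            # separately, so pattern similarity is not a pure amplitude effect
            for cat in ("face", "place"):
                z = rng.standard_normal(config.n_voxels_per_roi)
                tmpl[cat] = z - z.mean()
        templates[roi] = tmpl
    return templates


def trial_responses(
    config: GenerativeConfig, prow: pd.Series, tsub: pd.DataFrame, roi: str
) -> np.ndarray:
    """Noise-free scalar response of each trial's category/task template.

    Category-selective ROIs: preferred-category trials respond with
    ``category_signal`` times a gain that is linear in the participant's
    latent selectivity on remembered trials (constant on forgotten trials)
    plus a per-trial quality term; nonpreferred trials respond at the fixed
    ``nonpref_gain`` level.  Attention ROIs respond only on remembered
    trials (DAN magnitude linear in the attention latent; VAN constant).
    """
    pref = config.preferred_category(roi)
    rem = (tsub["memory_outcome"] == "assoc_hit").to_numpy()
    if pref is None:
        if roi == "DAN":
            boost = config.dan_base_sme + config.dan_gain * prow["dan_sme_true"]
        else:
            boost = config.van_sme
        return boost * rem.astype(float)
    is_pref = (tsub["category"] == pref).to_numpy()
    gain = np.where(
        rem,
        config.rem_gain + config.sel_gain * prow["latent_selectivity"],
        config.forg_gain,
    )
    gain = gain + config.quality_coupling * tsub["signal_quality"].to_numpy()
    return config.category_signal * np.where(is_pref, gain, config.nonpref_gain)


def generate_patterns(
    config: GenerativeConfig, participants: pd.DataFrame, trials: pd.DataFrame
) -> dict:
    """Per-trial voxel activation patterns for every participant and ROI.

    Returns ``patterns[pid][roi]`` = (n_trials, V) array whose rows align
    with the participant's trials sorted by (run_index, trial_index):
    category template x trial amplitude + run-shared nuisance + white noise.
    """
    config.validate()
    templates = roi_templates(config)
    seqs = np.random.SeedSequence(config.seed).spawn(7)[6].spawn(len(participants))
    patterns: dict = {}
    by_pid = {
        pid: sub.sort_values(["run_index", "trial_index"])
        for pid, sub in trials.groupby("participant_id", sort=False)
    }
    for (_, prow), seq in zip(participants.iterrows(), seqs):
        pid = prow["participant_id"]
        rng = np.random.default_rng(seq)
        tsub = by_pid[pid]
        runs = tsub["run_index"].to_numpy()
        patterns[pid] = {}
        # one shared nuisance vector per run per ROI
        for roi in config.roi_names:
            tmpl = templates[roi]
            resp = trial_responses(config, prow, tsub, roi)
            pref = config.preferred_category(roi)
            if pref is None:
                base = tmpl["base"] + np.outer(resp, tmpl["task"])
            else:
                # uniform mean-activation response plus a fixed-strength
                # category pattern (preferred category engages its pattern
                # more strongly than the nonpreferred one)
                is_pref = (tsub["category"] == pref).to_numpy()
                rho = (
                    config.category_signal * config.pattern_gain
                    * np.where(is_pref, 1.0, config.nonpref_gain)
                )
                cat_t = np.stack([tmpl[c] for c in tsub["category"]])
                base = tmpl["base"] + resp[:, None] + cat_t * rho[:, None]
            nuis = {
                r: rng.normal(0.0, config.run_nuisance_sd, config.n_voxels_per_roi)
                for r in np.unique(runs)
            }
            noise = rng.normal(0.0, config.pattern_noise_sd, base.shape)
            patterns[pid][roi] = base + np.stack([nuis[r] for r in runs]) + noise
    return patterns


@dataclass
class BoldRun:
    """One simulated BOLD run: per-ROI time x voxel signal plus ground truth."""

    participant_id: str
    run_index: int
    tr_seconds: float
    signal: dict            # roi -> (T, V)
    true_amplitudes: dict   # roi -> (n_trials, V)
    onsets: np.ndarray


def generate_bold(
    config: GenerativeConfig,
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    patterns: dict,
) -> dict:
    """Simulate BOLD runs: convolved boxcars weighted by pattern amplitudes.

    ``signal[:, v] = sum_trials pattern[t, v] * (boxcar(onset, dur) * HRF)(time)
    + noise``; the per-trial voxel patterns act as ground-truth amplitudes and
    are stored on each run for estimator validation.

    Returns ``bold[pid][run_index]`` = :class:`BoldRun`.
    """
    if config.tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    kernel = trialglm.hrf_double_gamma(config.tr_seconds)
    seqs = np.random.SeedSequence((config.seed, 17)).spawn(len(participants))
    out: dict = {}
    dur = config.event_duration_seconds
    by_pid = {
        pid: sub.sort_values(["run_index", "trial_index"])
        for pid, sub in trials.groupby("participant_id", sort=False)
    }
    for (_, prow), seq in zip(participants.iterrows(), seqs):
        pid = prow["participant_id"]
        rng = np.random.default_rng(seq)
        tsub = by_pid[pid]
        out[pid] = {}
        row_offset = 0
        for run in sorted(tsub["run_index"].unique()):
            rsub = tsub[tsub["run_index"] == run]
            onsets = rsub["onset_seconds"].to_numpy()
            T = int(np.ceil((onsets[-1] + dur + config.bold_tail_seconds) / config.tr_seconds)) + 1
            X = np.column_stack(
                [
                    trialglm.boxcar_regressor(np.array([o]), dur, T, config.tr_seconds, kernel)
                    for o in onsets
                ]
            )
            signal, amps = {}, {}
            for roi in config.roi_names:
                A = patterns[pid][roi][row_offset : row_offset + len(rsub)]
                clean = X @ A
                signal[roi] = clean + rng.normal(0.0, config.bold_noise_sd, clean.shape)
                amps[roi] = A
            out[pid][int(run)] = BoldRun(pid, int(run), config.tr_seconds, signal, amps, onsets)
            row_offset += len(rsub)
    return out


# ---------------------------------------------------------------------------
# Disk I/O
# ---------------------------------------------------------------------------

def save_cohort(
    outdir: str | Path,
    config: GenerativeConfig,
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    patterns: dict | None = None,
) -> None:
    """Write participants.csv, trials.csv, config.json and pattern arrays."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants.to_csv(outdir / "participants.csv", index=False)
    trials.to_csv(outdir / "trials.csv", index=False)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    if patterns is not None:
        pdir = outdir / "patterns"
        pdir.mkdir(exist_ok=True)
        sidecar = {}
        for pid, rois in patterns.items():
            for roi, arr in rois.items():
                name = f"{pid}_{roi}.npy"
                np.save(pdir / name, arr)
                sidecar[name] = {"participant_id": pid, "roi": roi, "shape": list(arr.shape)}
        (pdir / "manifest.json").write_text(json.dumps(sidecar, indent=2))


def load_cohort(outdir: str | Path):
    outdir = Path(outdir)
    config = GenerativeConfig.from_dict(json.loads((outdir / "config.json").read_text()))
    participants = pd.read_csv(outdir / "participants.csv")
    trials = pd.read_csv(outdir / "trials.csv")
    patterns = None
    pdir = outdir / "patterns"
    if pdir.exists():
        patterns = {}
        manifest = json.loads((pdir / "manifest.json").read_text())
        for name, meta in manifest.items():
            patterns.setdefault(meta["participant_id"], {})[meta["roi"]] = np.load(pdir / name)
    return config, participants, trials, patterns
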