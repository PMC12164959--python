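"""End-to-end pipeline: generate -> score -> estimate -> select -> infer -> paths.

Runs the full synthetic study: cohort and trial generation, behavioral
scoring, (optionally) BOLD simulation + least-squares-single estimation,
ROI selectivity and attention-network SMEs, pattern-similarity trial
selectivity, mixed-model and dependent-correlation inference, and the
mediation / SEM / variance-partition stage.  Artifacts are versioned CSV/JSON
files plus a human-readable markdown report; identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, paths, selectivity, stats, synthgen, trialglm

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage toggles and global options around a generative config."""

    generative: synthgen.GenerativeConfig = field(
        default_factory=synthgen.GenerativeConfig
    )
    simulate_bold: bool = False      # run the BOLD + LSS stage instead of
                                     # using generated patterns directly
    loo_masks: bool = True           # leave-one-participant-out ROI masks
    loo_alpha: float = 0.01          # voxelwise threshold for LOO masks; the
                                     # synthetic ROIs have tens of voxels, so
                                     # a lenient default keeps masks above
                                     # the 30-voxel minimum
    run_psa: bool = True
    n_boot: int = 1000
    seed: int | None = None          # overrides generative.seed when set
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.generative, dict):
            self.generative = synthgen.GenerativeConfig.from_dict(self.generative)
        if self.seed is not None:
            self.generative = dataclasses.replace(self.generative, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generative"] = self.generative.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        try:
            return cls.from_dict(d)
        except (TypeError, ValueError, KeyError) as err:
            raise ConfigError(str(err)) from err


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise StageError(name, str(err)) from err
            log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@_stage("synth")
def _stage_synth(cfg: PipelineConfig):
    g = cfg.generative
    participants, trials = synthgen.generate_cohort(g)
    responses = synthgen.generate_responses(g, participants, trials)
    posttest = synthgen.generate_posttest(g, participants, trials)
    patterns = synthgen.generate_patterns(g, participants, trials)
    return participants, trials, responses, posttest, patterns


@_stage("trialglm")
def _stage_trialglm(cfg: PipelineConfig, participants, trials, patterns):
    """Optionally simulate BOLD and re-estimate trial patterns with LSS."""
    if not cfg.simulate_bold:
        return patterns
    g = cfg.generative
    bold = synthgen.generate_bold(g, participants, trials, patterns)
    kernel = trialglm.hrf_double_gamma(g.tr_seconds)
    est: dict = {}
    for pid, runs in bold.items():
        est[pid] = {roi: [] for roi in g.roi_names}
        for run_index in sorted(runs):
            br = runs[run_index]
            for roi in g.roi_names:
                _, tvals = trialglm.fit_lss(
                    br.signal[roi], br.onsets, g.tr_seconds,
                    g.event_duration_seconds, kernel,
                )
                est[pid][roi].append(tvals)
        est[pid] = {roi: np.vstack(chunks) for roi, chunks in est[pid].items()}
    return est


@_stage("behavior")
def _stage_behavior(responses, posttest, trials):
    scores = behavior.score_memory(responses)
    overall = posttest.groupby("participant_id", sort=False)["exemplar_correct"].mean()
    bycat = (
        posttest.groupby(["participant_id", "category"], sort=False)["exemplar_correct"]
        .mean()
        .unstack()
    )
    recall = pd.DataFrame(
        {
            "participant_id": overall.index,
            "recall_overall": overall.to_numpy(),
            "recall_face": bycat.reindex(overall.index)["face"].to_numpy(),
            "recall_place": bycat.reindex(overall.index)["place"].to_numpy(),
        }
    )
    gate = behavior.flag_low_trial_participants(trials)
    return scores.merge(recall, on="participant_id"), gate


@_stage("masks")
def _stage_masks(cfg: PipelineConfig, patterns, trials):
    g = cfg.generative
    full = {
        roi: selectivity.RoiMask(
            roi, np.arange(g.n_voxels_per_roi), g.preferred_category(roi), "atlas"
        )
        for roi in g.roi_names
    }
    if not cfg.loo_masks:
        return {pid: full for pid in patterns}, pd.DataFrame()
    # per-participant category contrast maps per category-selective ROI
    cat_rois = [r for r in g.roi_names if g.preferred_category(r) is not None]
    cmap = {roi: {} for roi in cat_rois}
    by_pid = {
        pid: sub.sort_values(["run_index", "trial_index"])
        for pid, sub in trials.groupby("participant_id", sort=False)
    }
    for pid, rois in patterns.items():
        tsub = by_pid[pid]
        memclass = trialglm._memory_class(tsub["memory_outcome"])
        cats = tsub["category"].to_numpy()
        for roi in cat_rois:
            res = trialglm.condition_contrast(
                rois[roi], tsub, "face_vs_place", memclass=memclass, categories=cats
            )
            cmap[roi][pid] = res["tvals"]
    masks = {pid: dict(full) for pid in patterns}
    flagged = []
    for roi in cat_rois:
        loo = selectivity.loo_roi_define_all(cmap[roi], full[roi], cfg.loo_alpha)
        for pid, m in loo.items():
            masks[pid][roi] = m
            if m.excluded:
                flagged.append({"participant_id": pid, "roi": roi,
                                "n_voxels": m.n_voxels})
    return masks, pd.DataFrame(flagged)


@_stage("selectivity")
def _stage_selectivity(cfg: PipelineConfig, patterns, trials, masks):
    records = selectivity.roi_selectivity(patterns, trials, masks)
    grouped = selectivity.group_selectivity(records)
    act = selectivity.attenuation_broadening(grouped)
    dan = selectivity.dan_sme(patterns, trials, masks, "DAN").rename(
        columns={"sme": "dan_sme"}
    )[["participant_id", "dan_sme"]]
    van = selectivity.dan_sme(patterns, trials, masks, "VAN").rename(
        columns={"sme": "van_sme"}
    )[["participant_id", "van_sme"]]
    psa = None
    if cfg.run_psa:
        out = []
        by_pid = dict(tuple(trials.groupby("participant_id", sort=False)))
        for pid, rois in patterns.items():
            tsub = by_pid[pid]
            try:
                df = selectivity.psa_trial_selectivity(
                    rois, tsub, cfg.generative.place_rois or cfg.generative.face_rois
                )
            except ValueError as err:
                log.warning("PSA skipped for %s: %s", pid, err)
                continue
            out.append(df)
        psa = pd.concat(out, ignore_index=True) if out else pd.DataFrame()
    return records, grouped, act, dan, van, psa


@_stage("stats")
def _stage_stats(participants, grouped, scores, gate):
    keep = set(gate.loc[~gate["excluded"], "participant_id"])
    wide = grouped.pivot_table(
        index="participant_id", columns=["roi_group", "memory_condition"],
        values="selectivity",
    )
    wide.columns = [f"{g}_{m}" for g, m in wide.columns]
    wide = wide.reset_index()
    table = grouped.merge(participants, on="participant_id")
    table = table[table["participant_id"].isin(keep)].dropna(subset=["selectivity"])
    spec = stats.ModelSpec(
        outcome="selectivity",
        fixed="age_z * C(memory_condition) * C(roi_group)",
        covariates=("sex", "education"),
        contrasts=({"focal": "age_z", "by": "memory_condition"},),
    )
    lmm = stats.fit_lmm(spec, table)
    idtable = (
        participants.merge(wide, on="participant_id")
        .merge(scores, on="participant_id")
    )
    idtable = idtable[idtable["participant_id"].isin(keep)]
    comp = None
    sub = idtable.dropna(
        subset=["d_overall", "place_group_remembered", "place_group_forgotten"]
    )
    if len(sub) >= 10:
        comp = stats.compare_dependent_correlations(
            sub["d_overall"], sub["place_group_remembered"],
            sub["place_group_forgotten"],
        )
    return lmm, comp, idtable


@_stage("paths")
def _stage_paths(cfg: PipelineConfig, idtable, dan):
    table = idtable.merge(dan, on="participant_id")
    table = table.rename(
        columns={"place_group_remembered": "selectivity", "d_place": "memory"}
    )
    med = paths.mediation_multiple(
        table, x="age_z", m1="ptau181", m2="dan_sme", y="selectivity",
        covariates=("sex", "education"),
        n_boot=cfg.n_boot, seed=cfg.generative.seed,
    )
    sem = paths.fit_path_system(
        paths.sem_system(), table, n_boot=cfg.n_boot, seed=cfg.generative.seed
    )
    vp_sel = paths.variance_partition(
        table, "selectivity", ("age_z", "dan_sme", "ptau181"),
        ("sex", "education"),
    )
    vp_mem = paths.variance_partition(
        table, "memory", ("age_z", "selectivity", "dan_sme", "ptau181"),
        ("sex", "education"),
    )
    return table, med, sem, vp_sel, vp_mem


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage; optionally write artifacts + report to ``outdir``.

    Returns a results dict with all stage outputs (tables, fits, partitions)
    and the headline summary used by the report.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    participants, trials, responses, posttest, patterns = _stage_synth(config)
    est_patterns = _stage_trialglm(config, participants, trials, patterns)
    scores, gate = _stage_behavior(responses, posttest, trials)
    masks, mask_flags = _stage_masks(config, est_patterns, trials)
    records, grouped, act, dan, van, psa = _stage_selectivity(
        config, est_patterns, trials, masks
    )
    lmm, comp, idtable = _stage_stats(participants, grouped, scores, gate)
    table, med, sem, vp_sel, vp_mem = _stage_paths(config, idtable, dan)

    sel_by_cond = (
        grouped[grouped["roi_group"] == "place_group"]
        .groupby("memory_condition")["selectivity"].mean()
        .to_dict()
    )
    results = {
        "config": config,
        "participants": participants,
        "trials": trials,
        "scores": scores,
        "gate": gate,
        "mask_flags": mask_flags,
        "selectivity_records": records,
        "selectivity_grouped": grouped,
        "activity_long": act,
        "dan": dan,
        "van": van,
        "psa": psa,
        "lmm": lmm,
        "corr_comparison": comp,
        "analysis_table": table,
        "mediation": med,
        "sem": sem,
        "vp_selectivity": vp_sel,
        "vp_memory": vp_mem,
        "summary": {
            "selectivity_remembered": sel_by_cond.get("remembered", np.nan),
            "selectivity_forgotten": sel_by_cond.get("forgotten", np.nan),
            "sem_a2": sem.coef("selectivity", "age_z", standardized=True),
            "sem_d21": sem.coef("selectivity", "ptau181", standardized=True),
            "sem_d23": sem.coef("selectivity", "dan_sme", standardized=True),
            "sem_b2": sem.coef("memory", "selectivity", standardized=True),
            "n_excluded": int(gate["excluded"].sum()),
        },
    }
    if outdir is not None:
        _write_artifacts(Path(outdir), results)
    return results


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4f}") -> str:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: floatfmt.format(v) if pd.notna(v) else "")
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def _write_artifacts(outdir: Path, results: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config: PipelineConfig = results["config"]
    for name in (
        "participants", "trials", "scores", "gate", "selectivity_records",
        "selectivity_grouped", "activity_long", "dan", "van", "psa",
        "analysis_table",
    ):
        df = results[name]
        if df is not None and len(df):
            df.to_csv(outdir / f"{name}.csv", index=False)
    results["mediation"].products.to_csv(outdir / "mediation_products.csv", index=False)
    results["sem"].products.to_csv(outdir / "sem_products.csv", index=False)
    results["sem"].coefficients.to_csv(outdir / "sem_coefficients.csv", index=False)

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.generative.seed,
        "n_participants": int(len(results["participants"])),
        "n_excluded": results["summary"]["n_excluded"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "report.md").write_text(render_report(results))


def significant_paths(fit: paths.PathModelFit) -> pd.DataFrame:
    """Products whose bootstrap CI excludes zero (empty if no bootstrap)."""
    p = fit.products.dropna(subset=["ci_low", "ci_high"])
    return p[(p["ci_low"] > 0) | (p["ci_high"] < 0)].reset_index(drop=True)


def render_report(results: dict) -> str:
    summary = results["summary"]
    med: paths.PathModelFit = results["mediation"]
    sem: paths.PathModelFit = results["sem"]
    parts = ["# Encoding selectivity pipeline report", ""]

    parts += ["## 1. Selectivity by subsequent-memory condition", ""]
    bycond = (
        results["selectivity_grouped"]
        .groupby(["roi_group", "memory_condition"])["selectivity"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    parts += [_md_table(bycond), ""]

    parts += ["## 2. Age / attention / biomarker associations with selectivity", ""]
    parts += [_md_table(results["lmm"].params), ""]
    if len(results["lmm"].followups):
        parts += ["Follow-up age slopes (Holm-corrected):", "",
                  _md_table(results["lmm"].followups), ""]
    comp = results["corr_comparison"]
    if comp is not None:
        parts += [
            f"Dependent-correlation comparison (memory score vs selectivity, "
            f"remembered r1={comp.r1:.3f} vs forgotten r2={comp.r2:.3f}): "
            f"delta={comp.delta:.3f}, 95% CI [{comp.ci_low:.3f}, {comp.ci_high:.3f}].",
            "",
        ]

    parts += ["## 3. Multiple mediation (age -> pTau181 / DAN SME -> selectivity)", ""]
    parts += [_md_table(med.products), ""]
    if len(med.contrasts):
        parts += [_md_table(med.contrasts), ""]

    parts += ["## 4. Path system (SEM) for memory", ""]
    parts += [_md_table(sem.coefficients), "", _md_table(sem.products), ""]
    parts += [
        f"Total effect c = {sem.total_effect:.4f}; direct c' = {sem.direct_effect:.4f}; "
        f"identity gap = {sem.identity_gap():.2e}.",
        "",
    ]
    sig = significant_paths(sem)
    parts += ["### Significant paths", ""]
    parts += [_md_table(sig) if len(sig) else "(none)", ""]

    parts += ["## 5. Variance partitions", ""]
    for key in ("vp_selectivity", "vp_memory"):
        vp: paths.VariancePartition = results[key]
        rows = [{"component": "total", "R2": vp.r2_total}]
        rows += [{"component": f"unique:{k}", "R2": v} for k, v in vp.unique.items()]
        rows += [
            {"component": "shared:" + "&".join(sorted(k)), "R2": v}
            for k, v in vp.shared.items()
        ]
        parts += [f"Outcome: **{vp.outcome}** (n={vp.n_used})", "",
                  _md_table(pd.DataFrame(rows)), ""]

    parts += ["## 6. Behavior summary", ""]
    beh = results["scores"][["d_overall", "d_face", "d_place"]].agg(["mean", "std"])
    beh = beh.reset_index().rename(columns={"index": "stat"})
    parts += [_md_table(beh), ""]
    parts += [
        f"Participants excluded by the <3-trials-per-cell gate: {summary['n_excluded']}.",
        "",
    ]
    flags = results["mask_flags"]
    if flags is not None and len(flags):
        parts += ["ROI masks below the 30-voxel minimum:", "", _md_table(flags), ""]
    return "\n".join(parts)
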