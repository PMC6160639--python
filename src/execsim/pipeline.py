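"""End-to-end orchestration: simulate -> GLM -> overlap -> connectivity
-> similarity -> stats, under one seeded config.

Every participant's data are simulated and analyzed in a stream (one run
at a time) so the desk-scale default config stays within laptop memory.
Master-seed substreams are counter-based: adding participants or cohorts
never reshuffles existing participants' data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from execsim import connectivity as conn_mod
from execsim import glm as glm_mod
from execsim import overlap as overlap_mod
from execsim import similarity as sim_mod
from execsim import stats as stats_mod
from execsim.core import (
    TASK_TYPES,
    AcquisitionSpec,
    CohortConfig,
    GroundTruth,
    as_rng,
    substream,
)
from execsim.rois import ROISet, connection_labels, reference_executive_rois
from execsim.synth import (
    build_attention_schedule,
    build_nback_schedule,
    make_activation_atlas,
    make_connectivity_structure,
    simulate_behavior,
    simulate_bold,
)
from execsim.synth.behavior import BehaviorParams, default_behavior_params
from execsim.synth.bold import (
    DESK_ROI_CENTERS_MM,
    default_roi_set,
    perturb_connectivity,
    proxy_region_masks,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "glm", "overlap", "connectivity", "similarity", "stats")


def default_cohorts() -> list:
    return [
        CohortConfig(
            label="middle_adolescent",
            overlap_target=0.15,
            similarity_target=0.3,
        ),
        CohortConfig(
            label="late_adolescent",
            overlap_target=0.25,
            similarity_target=0.6,
        ),
        CohortConfig(
            label="young_adult",
            overlap_target=0.40,
            similarity_target=0.9,
        ),
    ]


@dataclass
class PipelineConfig:
    master_seed: int = 1
    grid_shape: tuple = (24, 28, 24)
    voxel_size_mm: float = 3.0
    tr_seconds: float = 2.5
    attention_volumes: int = 222
    nback_volumes: int = 155
    n_dummy: int = 4
    n_attention_runs: int = 3
    n_nback_runs: int = 2
    cohorts: list = field(default_factory=default_cohorts)

    # planted activation
    amplitude: float = 1.0  # percent signal change at blob peak
    blob_sigma_mm: float = 10.0
    threshold_frac: float = 0.5

    # analysis
    smoothing_fwhm_mm: float = 6.0
    hp_cutoff_seconds: float = 128.0
    hrf_lag_frames: int = 2
    group_t_min: float = 2.7
    group_k_min: int = 20  # desk-scale extent threshold
    calibrate_group_threshold: bool = True
    participant_t_min: float = 1.3
    participant_k_min: int = 10
    cluster_connectivity: int = 26

    # connectivity simulation / analysis
    roi_mode: str = "planted"  # planted | derive | fixture
    roi_radius_mm: float = 7.0
    roi_noise_sd: float = 1.2
    drift_sd: float = 0.5
    n_perm: int = 499
    mds_dim: int = 2

    stages: tuple = ALL_STAGES
    behavior: BehaviorParams = field(default_factory=default_behavior_params)

    def attention_acq(self) -> AcquisitionSpec:
        return AcquisitionSpec(
            tr_seconds=self.tr_seconds,
            n_volumes=self.attention_volumes,
            n_dummy=self.n_dummy,
            grid_shape=tuple(self.grid_shape),
            voxel_size_mm=(self.voxel_size_mm,) * 3,
        )

    def nback_acq(self) -> AcquisitionSpec:
        return AcquisitionSpec(
            tr_seconds=self.tr_seconds,
            n_volumes=self.nback_volumes,
            n_dummy=self.n_dummy,
            grid_shape=tuple(self.grid_shape),
            voxel_size_mm=(self.voxel_size_mm,) * 3,
        )

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cohorts = [CohortConfig(**c) for c in raw.pop("cohorts", [])]
        behavior = BehaviorParams(**raw.pop("behavior", {}))
        kwargs = {k: v for k, v in raw.items()}
        cfg = cls(**kwargs)
        if cohorts:
            cfg.cohorts = cohorts
        cfg.behavior = behavior
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def validate_config(config: PipelineConfig) -> list:
    """Cross-field checks.  Returns (level, message) findings."""
    findings = []
    try:
        att = config.attention_acq()
        nb = config.nback_acq()
    except ValueError as exc:
        return [("error", str(exc))]
    for run_idx in range(1, config.n_attention_runs + 1):
        try:
            build_attention_schedule(run_idx, att, rng_seed=0)
        except ValueError as exc:
            findings.append(("error", f"attention run {run_idx}: {exc}"))
    for run_idx in range(1, config.n_nback_runs + 1):
        try:
            build_nback_schedule(run_idx, nb, rng_seed=0)
        except ValueError as exc:
            findings.append(("error", f"n-back run {run_idx}: {exc}"))
    if config.roi_radius_mm < config.voxel_size_mm / 2:
        findings.append(
            ("warning", "ROI radius smaller than half a voxel; spheres may be empty")
        )
    if not config.cohorts:
        findings.append(("error", "no cohorts configured"))
    for c in config.cohorts:
        if c.n_participants < 2:
            findings.append(("error", f"cohort {c.label}: needs >= 2 participants"))
    if config.roi_mode not in ("planted", "derive", "fixture"):
        findings.append(("error", f"unknown roi_mode {config.roi_mode!r}"))
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        findings.append(("error", f"unknown stages: {unknown}"))
    if config.roi_mode == "fixture":
        rois = reference_executive_rois(config.roi_radius_mm)
    else:
        rois = default_roi_set(config.roi_radius_mm)
    member = rois.membership(tuple(config.grid_shape), att.affine)
    empty = [n for n, m in member.items() if not m.any()]
    if empty:
        findings.append(
            ("error", f"ROIs outside the simulation grid: {empty}")
        )
    return findings


# ---------------------------------------------------------------------------
# Per-participant processing
# ---------------------------------------------------------------------------


def _participant_contrast_maps(run_fits) -> dict:
    """Combine per-run contrast effects into participant maps.

    ``run_fits``: list of (GLMResult, {name: ContrastSpec}) — specs are
    built per run so a cell missing from one run only drops that run.
    """
    names = []
    for _, specs in run_fits:
        for n in specs:
            if n not in names:
                names.append(n)
    maps = {}
    for name in names:
        effects, variances, dfs = [], [], []
        mask = affine = None
        for res, specs in run_fits:
            if name not in specs:
                continue
            e, v = glm_mod.contrast_effect_variance(res, specs[name])
            effects.append(e)
            variances.append(v)
            dfs.append(res.df)
            mask, affine = res.mask, res.affine
        effect = np.mean(effects, axis=0)
        var = np.sum(variances, axis=0) / len(effects) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, effect / np.sqrt(var), 0.0)
        t3 = np.zeros(mask.shape)
        e3 = np.zeros(mask.shape)
        t3[mask] = t
        e3[mask] = effect
        maps[name] = glm_mod.ContrastMap(
            t=t3, effect=e3, df=float(sum(dfs)), level="participant",
            affine=affine, mask=mask, name=name,
        )
    return maps


def _process_run(sim_run, acq, config, do_glm, roi_set, proxies):
    """Dummy removal, smoothing, GLM fit and ROI extraction for one run."""
    vol, events = glm_mod.drop_dummies(sim_run.volume, acq.n_dummy, sim_run.events)
    motion = sim_run.motion[acq.n_dummy:]
    if config.smoothing_fwhm_mm > 0:
        vol = glm_mod.smooth_gaussian(vol, config.smoothing_fwhm_mm)
    design = glm_mod.build_design_matrix(
        events,
        (vol.n_frames, acq.tr_seconds),
        motion=motion,
        hp_cutoff_seconds=config.hp_cutoff_seconds,
    )
    fit = None
    specs = None
    if do_glm:
        fit = glm_mod.fit_glm_ols(vol, design)
        specs = glm_mod.make_executive_contrasts(design)

    roi_resid = None
    qc = None
    if roi_set is not None:
        qc = conn_mod.qc_report(vol, motion)
        series = conn_mod.extract_roi_timecourses(vol, roi_set)
        task_cols = design.values[
            [lab for lab, cv in design.convolved.items() if cv]
        ]
        confounds = conn_mod.ConfoundSet(
            motion=motion,
            wm=vol.data[proxies["wm_proxy"]].mean(axis=0),
            csf=vol.data[proxies["csf_proxy"]].mean(axis=0),
            task_columns=task_cols,
            outlier_flags=qc.outlier_flags,
        )
        roi_resid = conn_mod.regress_confounds(series, confounds)
    return dict(
        events=events,
        fit=fit,
        specs=specs,
        roi_resid=roi_resid,
        qc=qc,
        tr=acq.tr_seconds,
    )


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    findings = validate_config(config)
    errors = [msg for lvl, msg in findings if lvl == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    for lvl, msg in findings:
        logger.warning("config: %s", msg)

    stages = set(config.stages)
    if "overlap" in stages:
        stages.add("glm")
    if "similarity" in stages:
        stages.add("connectivity")
    do_glm = "glm" in stages
    do_conn = "connectivity" in stages

    seed = config.master_seed
    att_acq = config.attention_acq()
    nb_acq = config.nback_acq()

    roi_set = None
    if do_conn:
        if config.roi_mode == "fixture":
            roi_set = reference_executive_rois(config.roi_radius_mm)
        else:  # planted (derive-mode connectivity also uses planted spheres)
            roi_set = default_roi_set(config.roi_radius_mm)
    proxies = proxy_region_masks(att_acq)

    report = {
        "config_hash": config.config_hash(),
        "master_seed": seed,
        "stages": sorted(stages),
        "cohorts": {},
    }
    behavior_rows = []
    scored_blocks = []
    participant_scores_meta = []
    cohort_artifacts = {}

    for ci, cohort in enumerate(config.cohorts):
        atlas = realized_overlap = None
        if do_glm:
            atlas, realized_overlap, centers = make_activation_atlas(
                cohort.overlap_target,
                att_acq,
                amplitude=config.amplitude,
                sigma_mm=config.blob_sigma_mm,
                threshold_frac=config.threshold_frac,
            )
        conn_struct = realized_sim = None
        if do_conn:
            conn_struct, realized_sim = make_connectivity_structure(
                cohort.similarity_target, len(roi_set), substream(seed, ci, 901)
            )

        truth = GroundTruth(
            overlap_fractions=(
                np.full((4, 4), cohort.overlap_target) if do_glm else None
            ),
            connectivity_similarity=cohort.similarity_target,
            activation_amplitude=config.amplitude,
            roi_centers_mm=(
                {r.name: list(r.center_mm) for r in roi_set} if roi_set else None
            ),
            behavior_means={
                t: config.behavior.task_means[t]
                + config.behavior.cohort_offsets.get(cohort.label, 0.0)
                for t in TASK_TYPES
            },
            behavior_sds=dict(config.behavior.task_sds),
            realized_overlaps=realized_overlap,
            realized_similarities=realized_sim,
            seed=seed,
        )

        participant_maps = []  # list of {contrast: ContrastMap}
        z_stacks = []  # per participant (28, 4)
        qc_summaries = []
        participant_overlaps = []

        for pid in range(cohort.n_participants):
            prng = substream(seed, ci, pid, 999)
            gender = "female" if pid < round(
                cohort.female_fraction * cohort.n_participants
            ) else "male"
            gpa = float(np.clip(7.0 + 2.0 * prng.random(), 7.0, 10.0))
            participant_offset = (
                config.behavior.participant_sd * prng.standard_normal()
            )
            p_conn = (
                perturb_connectivity(
                    conn_struct, cohort.pattern_noise_sd, prng
                )
                if do_conn
                else {}
            )
            amp_scale = 1.0 + cohort.amplitude_jitter * prng.standard_normal()
            p_atlas = (
                {k: amp_scale * v for k, v in atlas.items()} if atlas else {}
            )

            run_fits = []
            conn_runs = []
            pname = f"{cohort.label}_p{pid:02d}"

            run_defs = [("att", r + 1, att_acq) for r in range(config.n_attention_runs)]
            run_defs += [("nb", r + 1, nb_acq) for r in range(config.n_nback_runs)]
            for kind_idx, (kind, run_idx, acq) in enumerate(run_defs):
                rrng = substream(seed, ci, pid, kind_idx)
                if kind == "att":
                    schedule = build_attention_schedule(run_idx, acq, rrng)
                else:
                    schedule = build_nback_schedule(run_idx, acq, rrng)
                sim_run = simulate_bold(
                    schedule,
                    p_atlas,
                    p_conn,
                    acq,
                    cohort=cohort,
                    rng_seed=substream(seed, ci, pid, kind_idx, 1),
                    roi_noise_sd=config.roi_noise_sd,
                    drift_sd=config.drift_sd,
                    roi_set=roi_set,
                    hrf_lag_frames=config.hrf_lag_frames,
                )
                out = _process_run(
                    sim_run, acq, config, do_glm, roi_set if do_conn else None, proxies
                )
                if do_glm:
                    run_fits.append((out["fit"], out["specs"]))
                if do_conn:
                    conn_runs.append((out["roi_resid"], out["events"], out["tr"]))
                    qc_summaries.append(out["qc"].to_jsonable())

                scored = simulate_behavior(
                    cohort,
                    schedule,
                    rng_seed=substream(seed, ci, pid, kind_idx, 2),
                    params=config.behavior,
                    gender=gender,
                    participant_offset=participant_offset,
                )
                behavior_rows.append(
                    dict(participant=pname, cohort=cohort.label, events=scored)
                )
                scored_blocks.append(
                    stats_mod.block_scores(scored, participant=pname)
                )

            participant_scores_meta.append(
                dict(
                    participant=pname,
                    cohort=cohort.label,
                    gender=gender,
                    gpa=gpa,
                )
            )

            if do_glm:
                cmaps = _participant_contrast_maps(run_fits)
                participant_maps.append(cmaps)
                spec = overlap_mod.ThresholdSpec.participant(
                    config.participant_t_min,
                    config.participant_k_min,
                    config.cluster_connectivity,
                )
                participant_overlaps.append(
                    overlap_mod.participant_overlap_analysis(cmaps, spec)
                )
            if do_conn:
                vectors = {
                    task: conn_mod.taskwise_connectivity(
                        conn_runs,
                        task,
                        roi_set,
                        participant=pname,
                        hrf_lag_frames=config.hrf_lag_frames,
                    )
                    for task in TASK_TYPES
                }
                z_stacks.append(
                    np.column_stack([vectors[t].z for t in TASK_TYPES])
                )

        cohort_report = {"ground_truth": truth.to_jsonable()}
        cohort_artifacts[cohort.label] = dict(
            truth=truth,
            participant_maps=participant_maps,
            z_stack=np.array(z_stacks) if z_stacks else None,
            participant_overlaps=participant_overlaps,
        )
        if qc_summaries:
            cohort_report["qc"] = dict(
                n_runs=len(qc_summaries),
                mean_dvars=float(
                    np.mean([q["dvars_mean"] for q in qc_summaries])
                ),
                n_excluded=sum(q["excluded"] for q in qc_summaries),
            )
        report["cohorts"][cohort.label] = cohort_report

    if do_glm and "overlap" in stages:
        _overlap_stage(config, report, cohort_artifacts)
    if do_conn and "similarity" in stages:
        _similarity_stage(config, report, cohort_artifacts, roi_set)
    if "stats" in stages:
        _stats_stage(
            config,
            report,
            scored_blocks,
            behavior_rows,
            participant_scores_meta,
        )
    leftover = report.pop("_distance_tables", None)
    if leftover is not None:
        all_dt = pd.concat(leftover, ignore_index=True)
        report["distance_means"] = (
            all_dt.groupby("cohort")["distance"].mean().to_dict()
        )
    return report


def _overlap_stage(config, report, cohort_artifacts):
    conjunctions = {}
    for label, art in cohort_artifacts.items():
        maps_by_contrast = {
            name: [pm[name] for pm in art["participant_maps"] if name in pm]
            for name in TASK_TYPES
        }
        group_maps = {
            name: glm_mod.group_level_t(ms) for name, ms in maps_by_contrast.items()
        }
        t_min = config.group_t_min
        if config.calibrate_group_threshold:
            # Per-voxel Student t is jitter-dominated (sd scales with the
            # effect itself), so for amplitude recovery the group maps are
            # replaced by effect z maps: mean effect scaled by the
            # homoscedastic estimation noise.  The planted amplitude
            # contour then maps exactly onto the z threshold.
            sds = []
            for name, ms in maps_by_contrast.items():
                stack = np.stack([m.effect[m.mask] for m in ms], axis=-1)
                sds.append(np.median(stack.std(axis=-1, ddof=1)))
            sd_est = max(float(np.median(sds)), 1e-12)
            n = len(art["participant_maps"])
            scale = np.sqrt(n) / sd_est
            contour = config.threshold_frac * config.amplitude
            t_min = contour * scale
            group_maps = {
                name: glm_mod.ContrastMap(
                    t=gm.effect * scale,
                    effect=gm.effect,
                    df=gm.df,
                    level="group",
                    affine=gm.affine,
                    mask=gm.mask,
                    name=gm.name,
                )
                for name, gm in group_maps.items()
            }
        spec = overlap_mod.ThresholdSpec.group(
            t_min, config.group_k_min, config.cluster_connectivity
        )
        clusters = {
            name: overlap_mod.threshold_and_cluster(gm, spec)
            for name, gm in group_maps.items()
        }
        matrix = overlap_mod.overlap_matrix(clusters)
        counts = overlap_mod.conjunction_count_map(clusters)
        conjunctions[label] = counts == 4

        planted = art["truth"].overlap_fractions
        part = art["participant_overlaps"]
        part_mean = (
            float(
                np.mean(
                    [np.mean(list(p["overlap_percent"].values())) for p in part]
                )
            )
            if part
            else None
        )
        iu = np.triu_indices(4, 1)
        report["cohorts"][label]["overlap"] = dict(
            threshold_t=float(t_min),
            threshold_k=config.group_k_min,
            matrix=matrix.to_dict(),
            mean_pairwise_percent=float(matrix.to_numpy()[iu].mean()),
            planted_percent=float(100 * planted[iu].mean()),
            participant_mean_percent=part_mean,
            cluster_sizes={
                name: cm.table["size"].tolist() for name, cm in clusters.items()
            },
        )

    if config.roi_mode == "derive":
        affine = config.attention_acq().affine
        prototypes = {
            name[1:]: center
            for name, center in DESK_ROI_CENTERS_MM.items()
            if name.startswith("r")
        }
        derived = overlap_mod.derive_executive_rois(
            list(conjunctions.values()),
            affine,
            radius_mm=config.roi_radius_mm,
            k_min=config.participant_k_min,
            connectivity=config.cluster_connectivity,
            prototypes=prototypes,
        )
        report["derived_rois"] = derived.to_jsonable()


def _similarity_stage(config, report, cohort_artifacts, roi_set: ROISet):
    labels = connection_labels(roi_set)
    conn_ids = [lab["connection"] for lab in labels]
    matrices = {}
    stacks = {}
    distance_tables = []
    for label, art in cohort_artifacts.items():
        stack = art["z_stack"]  # (n, 28, 4)
        if stack is None:
            continue
        stacks[label] = stack
        z_table = pd.DataFrame(
            stack.mean(axis=0), index=conn_ids, columns=list(TASK_TYPES)
        )
        csim = sim_mod.cohort_connection_similarity(z_table)
        matrices[label] = csim
        embedding = sim_mod.mds_embed(csim, dim=config.mds_dim)
        dt = sim_mod.distance_table(
            embedding.coords, labels, cohort=label, node_names=conn_ids
        )
        distance_tables.append(dt)
        # participant-level 4x4 task similarity, averaged
        task_sims = [
            sim_mod.participant_task_similarity(
                {t: stack[p, :, k] for k, t in enumerate(TASK_TYPES)}
            )
            for p in range(stack.shape[0])
        ]
        mean_task_sim = sum(s.to_numpy() for s in task_sims) / len(task_sims)
        report["cohorts"][label]["similarity"] = dict(
            planted_similarity=art["truth"].connectivity_similarity,
            mean_distance=float(dt["distance"].mean()),
            mean_offdiag_connection_r=float(
                sim_mod._triu(csim.to_numpy()).mean()
            ),
            mean_task_similarity=pd.DataFrame(
                mean_task_sim, index=TASK_TYPES, columns=TASK_TYPES
            ).to_dict(),
            mds_eigenvalues=embedding.eigenvalues[:4].tolist(),
        )

    tests = {}
    names = list(matrices)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = sim_mod.matrix_similarity_test(
                matrices[a].to_numpy(),
                matrices[b].to_numpy(),
                n_perm=config.n_perm,
                rng_seed=substream(config.master_seed, 77, i),
                z_tables=(stacks[a], stacks[b]),
            )
            tests[f"{a}--{b}"] = dict(
                r=res.r,
                p_similarity=res.p_similarity,
                p_difference=res.p_difference,
            )
    report["similarity_tests"] = tests
    report["_distance_tables"] = distance_tables  # consumed by the stats stage


def _stats_stage(config, report, scored_blocks, behavior_rows, meta):
    blocks = pd.concat(scored_blocks, ignore_index=True)
    retained, exclusion_log = stats_mod.exclude_outlier_blocks(blocks)
    retained_ids = set(retained["block"] + "|" + retained["participant"])

    meta_df = pd.DataFrame(meta).set_index("participant")
    rows = []
    by_participant = {}
    for item in behavior_rows:
        by_participant.setdefault(item["participant"], []).append(item["events"])
    for pname, evs in by_participant.items():
        events = pd.concat(evs, ignore_index=True)
        keep = {
            b
            for b in events["block"].unique()
            if f"{b}|{pname}" in retained_ids
        }
        scores = stats_mod.compute_task_scores(events, retained_blocks=keep)
        for task, score in scores.items():
            rows.append(
                dict(
                    participant=pname,
                    task=task,
                    score=score,
                    cohort=meta_df.loc[pname, "cohort"],
                    gender=meta_df.loc[pname, "gender"],
                    gpa=meta_df.loc[pname, "gpa"],
                )
            )
    long = pd.DataFrame(rows)

    anova = stats_mod.rm_ancova(
        long,
        dv="score",
        within="task",
        subject="participant",
        between=["cohort", "gender"],
        covariate="gpa",
    )
    wide = long.pivot_table(index="participant", columns="task", values="score")
    wide = wide.join(meta_df)
    partials = {}
    for a, b in [(x, y) for i, x in enumerate(TASK_TYPES) for y in TASK_TYPES[i + 1:]]:
        sub = wide.dropna(subset=[a, b])
        r, p = stats_mod.partial_correlation(
            sub[a], sub[b], covariates=[sub["gender"], sub["cohort"]]
        )
        partials[f"{a}--{b}"] = dict(r=r, p=p)

    report["behavior"] = dict(
        exclusion=exclusion_log,
        task_means={t: float(long[long["task"] == t]["score"].mean()) for t in TASK_TYPES},
        cohort_means=long.groupby("cohort")["score"].mean().to_dict(),
        anova_effects=anova.effects.to_dict(orient="records"),
        anova_posthoc=anova.posthoc.to_dict(orient="records"),
        mauchly=anova.mauchly,
        epsilon=anova.epsilon,
        partial_correlations=partials,
    )

    dts = report.pop("_distance_tables", None)
    if dts:
        all_dt = pd.concat(dts, ignore_index=True)
        results = {}
        for factor in ("hemisphere_type", "range_type"):
            sub = all_dt[all_dt[factor] != "mixed"]
            if sub[factor].nunique() > 1 and sub["cohort"].nunique() > 1:
                res = stats_mod.univariate_anova(
                    sub, dv="distance", factors=["cohort", factor]
                )
                results[factor] = dict(
                    effects=res.effects.to_dict(orient="records"),
                    posthoc=res.posthoc.to_dict(orient="records"),
                )
        report["distance_anova"] = results
        report["distance_means"] = (
            all_dt.groupby("cohort")["distance"].mean().to_dict()
        )


# ---------------------------------------------------------------------------
# Behavior-only study (power experiments)
# ---------------------------------------------------------------------------


_SCORE_SELECTIONS = ("DivA", "DistrA", "WM", "ModSwi")


def _schedule_block_specs(schedule, params: BehaviorParams):
    """Precompute per-block trial means and score-category masks."""
    from execsim.core import COND_DIVIDED, DISTRACTED_CONDITIONS
    from execsim.synth.behavior import trial_means

    trial_mask = (
        schedule["task"].isin(["attention", "nback"])
        & (schedule["condition"] != "rest")
    ).to_numpy()
    means_all = trial_means(schedule, params)
    blocks = schedule["block"].to_numpy()
    cond = schedule["condition"].to_numpy()
    switch = schedule["switch"].to_numpy()
    task = schedule["task"].to_numpy()
    cat = {
        "DivA": cond == COND_DIVIDED,
        "DistrA": np.isin(cond, DISTRACTED_CONDITIONS),
        "WM": (cond == "2back") & (switch == "nonswitch"),
        "ModSwi": np.isin(cond, ("1back", "2back")) & (switch == "post_switch"),
    }
    specs = []
    for block in pd.unique(blocks[trial_mask]):
        idx = np.flatnonzero(trial_mask & (blocks == block))
        means = means_all[idx]
        specs.append(
            dict(
                block=block,
                family=task[idx[0]],
                means=means,
                center=float(np.nanmean(means)),
                cats={k: v[idx] for k, v in cat.items()},
            )
        )
    return specs


def simulate_behavior_study(
    n_per_cohort: int = 55,
    master_seed: int = 1,
    behavior: BehaviorParams = None,
    config: PipelineConfig = None,
    fast: bool = True,
) -> pd.DataFrame:
    """Simulate behavior for a full three-cohort study and score it.

    Returns a long table (participant, cohort, gender, gpa, task, score)
    after block exclusion — the input the accuracy ANCOVA expects.  Run
    schedules are shared across participants (block order does not
    affect scoring).  With ``fast=True`` the per-trial bookkeeping is
    vectorized while drawing the exact same random numbers as the
    event-table path (the equivalence is covered by a unit test).
    """
    from execsim.synth.behavior import _truncnorm_draw, default_behavior_params

    if config is None:
        config = PipelineConfig()
    params = behavior or config.behavior or default_behavior_params()
    att_acq, nb_acq = config.attention_acq(), config.nback_acq()
    schedules = [
        build_attention_schedule(r + 1, att_acq, substream(master_seed, 501, r))
        for r in range(config.n_attention_runs)
    ] + [
        build_nback_schedule(r + 1, nb_acq, substream(master_seed, 502, r))
        for r in range(config.n_nback_runs)
    ]
    block_specs = [_schedule_block_specs(s, params) for s in schedules]

    block_rows = []
    cat_counts = {}  # participant -> {block_id: {task: (correct, total)}}
    meta = {}
    events_by_participant = {}
    for ci, label in enumerate(
        ("middle_adolescent", "late_adolescent", "young_adult")
    ):
        cohort = CohortConfig(label=label, n_participants=n_per_cohort)
        for pid in range(n_per_cohort):
            prng = substream(master_seed, 601, ci, pid)
            pname = f"{label}_p{pid:03d}"
            gender = "female" if pid % 2 == 0 else "male"
            gpa = float(np.clip(7.0 + 2.0 * prng.random(), 7.0, 10.0))
            offset = params.participant_sd * prng.standard_normal()
            offset_full = (
                params.cohort_offsets.get(label, 0.0)
                + (params.gender_offset_female if gender == "female" else 0.0)
                + offset
            )
            meta[pname] = dict(cohort=label, gender=gender, gpa=gpa)

            if fast:
                counts = {}
                for k, specs in enumerate(block_specs):
                    rng = substream(master_seed, 601, ci, pid, k + 1)
                    for spec in specs:
                        bid = f"{spec['block']}"
                        score = _truncnorm_draw(
                            spec["center"] + offset_full, params.block_sd, rng
                        )
                        trial_p = (
                            np.clip(
                                score + (spec["means"] - spec["center"]), 0.0, 100.0
                            )
                            / 100.0
                        )
                        draws = rng.random(len(trial_p)) < trial_p
                        block_rows.append(
                            (pname, bid, spec["family"], 100.0 * draws.mean())
                        )
                        counts[bid] = {
                            t: (int(draws[m].sum()), int(m.sum()))
                            for t, m in spec["cats"].items()
                        }
                cat_counts[pname] = counts
            else:
                scored = [
                    simulate_behavior(
                        cohort,
                        sch,
                        rng_seed=substream(master_seed, 601, ci, pid, k + 1),
                        params=params,
                        gender=gender,
                        participant_offset=offset,
                    )
                    for k, sch in enumerate(schedules)
                ]
                events = pd.concat(scored, ignore_index=True)
                events_by_participant[pname] = events
                bs = stats_mod.block_scores(events, participant=pname)
                block_rows.extend(
                    bs[["participant", "block", "task_family", "score"]].itertuples(
                        index=False, name=None
                    )
                )

    all_blocks = pd.DataFrame(
        block_rows, columns=["participant", "block", "task_family", "score"]
    )
    retained, _ = stats_mod.exclude_outlier_blocks(all_blocks)
    retained_ids = set(retained["participant"] + "|" + retained["block"])

    rows = []
    if fast:
        for pname, counts in cat_counts.items():
            totals = {t: [0, 0] for t in _SCORE_SELECTIONS}
            for bid, per_task in counts.items():
                if f"{pname}|{bid}" not in retained_ids:
                    continue
                for t, (c, n) in per_task.items():
                    totals[t][0] += c
                    totals[t][1] += n
            for t, (c, n) in totals.items():
                rows.append(
                    dict(
                        participant=pname,
                        task=t,
                        score=100.0 * c / n if n else np.nan,
                        **meta[pname],
                    )
                )
    else:
        for pname, events in events_by_participant.items():
            keep = {
                b for b in events["block"].unique() if f"{pname}|{b}" in retained_ids
            }
            scores = stats_mod.compute_task_scores(events, retained_blocks=keep)
            for task, score in scores.items():
                rows.append(
                    dict(participant=pname, task=task, score=score, **meta[pname])
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    return str(obj)


def write_report(report: dict, path) -> None:
    from pathlib import Path

    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, allow_nan=True)
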