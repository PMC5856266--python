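"""End-to-end orchestration: simulate -> GLM -> localize -> decode -> stats.

Stages communicate through on-disk artifacts (NIfTI volumes, TSV tables,
JSON), so each stage can be run on its own from the CLI and a full run
is reproducible bit-for-bit from one config and one master seed. The
BOLD volumes are simulated and fitted subject-by-subject, so peak memory
stays at a single subject's data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm, roi as roi_mod, stats as stats_mod
from . import decoding as dec
from .conditions import CONDITIONS_OF_INTEREST, SEARCH_TYPES
from ._seeds import seed_sequence
from .synth import (
    BehaviorParams,
    DesignParams,
    EffectParams,
    NoiseParams,
    ROISpec,
    default_roi_specs,
    generate_behavior,
    generate_design,
    generate_scene,
)
from .synth import io as synth_io
from .synth.bold import simulate_run

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "glm",
    "localize",
    "decode",
    "permtest",
    "cross_session",
    "feature_curve",
    "stats",
    "report",
)


@dataclass
class LocalizerConfig:
    p_peak: float = 0.001
    alpha: float = 0.05
    n_perm: int = 1000
    connectivity: int = 18
    min_voxels: int = 25


@dataclass
class DecodingConfig:
    C: float = 1.0
    n_perm: int = 1000
    normalize: bool = False
    feature_sizes: tuple[int, ...] = dec.DEFAULT_FEATURE_SIZES
    feature_draws: int = 10
    feature_rois: tuple[str, ...] | None = None  # None -> all recovered ROIs
    hemisphere_pair: tuple[str, str] = ("L_IFG", "R_IFG")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "rulemvpa_out"
    grid_shape: tuple[int, int, int] = (36, 36, 30)
    design: DesignParams = field(default_factory=DesignParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    effect: EffectParams = field(default_factory=EffectParams)
    roi_specs: tuple[ROISpec, ...] | None = None
    localizer: LocalizerConfig = field(default_factory=LocalizerConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    stages: tuple[str, ...] = ALL_STAGES
    write_bold: bool = True

    def validate(self) -> None:
        self.design.validate()
        self.noise.validate()
        self.effect.validate()
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.roi_specs is not None:
            d["roi_specs"] = [dataclasses.asdict(s) for s in self.roi_specs]
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            dd = dict(d["design"])
            for k in ("mean_epoch_duration", "blank_range"):
                if k in dd:
                    dd[k] = tuple(dd[k])
            d["design"] = DesignParams(**dd)
        if "noise" in d:
            d["noise"] = NoiseParams(**d["noise"])
        if "effect" in d:
            d["effect"] = EffectParams(**d["effect"])
        if "behavior" in d:
            bd = dict(d["behavior"])
            for k in ("session_means", "domain_effects", "search_effects"):
                if k in bd:
                    bd[k] = tuple(tuple(x) if isinstance(x, list) else x for x in bd[k])
            d["behavior"] = BehaviorParams(**bd)
        if "localizer" in d:
            d["localizer"] = LocalizerConfig(**d["localizer"])
        if "decoding" in d:
            dc = dict(d["decoding"])
            for k in ("feature_sizes", "feature_rois", "hemisphere_pair"):
                if dc.get(k) is not None:
                    dc[k] = tuple(dc[k])
            d["decoding"] = DecodingConfig(**dc)
        if d.get("roi_specs") is not None:
            d["roi_specs"] = tuple(
                ROISpec(
                    name=s["name"],
                    center=tuple(s["center"]),
                    radii=tuple(s["radii"]),
                    role=s.get("role", "localizer-only"),
                )
                for s in d["roi_specs"]
            )
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # -- paths -------------------------------------------------------------
    @property
    def out(self) -> Path:
        return Path(self.out_dir)

    def path(self, *parts) -> Path:
        p = self.out.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig):
    """Simulate and write the dataset tree (subject-by-subject)."""
    design = generate_design(cfg.design, cfg.seed)
    scene = generate_scene(
        grid_shape=cfg.grid_shape,
        roi_specs=cfg.roi_specs,
        effect=cfg.effect,
        seed=cfg.seed,
        n_sessions=cfg.design.n_sessions,
    )
    root = cfg.path("dataset", "dataset.json").parent
    run_index = []
    for subject in design.subjects:
        for session in design.sessions:
            for run in design.runs:
                key = (subject, session, run)
                bold = simulate_run(design, scene, cfg.noise, key, cfg.seed)
                d = root / f"sub-{subject:02d}" / f"ses-{session}"
                d.mkdir(parents=True, exist_ok=True)
                stem = f"sub-{subject:02d}_ses-{session}_run-{run}"
                synth_io.save_volume(d / f"{stem}_bold.nii.gz", bold.data)
                epochs = design.epochs[key]
                pd.DataFrame(
                    {
                        "onset": [e.onset for e in epochs],
                        "duration": [e.duration for e in epochs],
                        "trial_type": [e.condition for e in epochs],
                    }
                ).to_csv(d / f"{stem}_events.tsv", sep="\t", index=False)
                pd.DataFrame(bold.motion, columns=synth_io.MOTION_COLUMNS).to_csv(
                    d / f"{stem}_motion.tsv", sep="\t", index=False
                )
                run_index.append(
                    {
                        "subject": subject,
                        "session": session,
                        "run": run,
                        "n_scans": bold.n_scans,
                        "run_duration_s": design.run_duration_s[key],
                    }
                )
    sidecar = {
        "seed": cfg.seed,
        "design_params": dataclasses.asdict(cfg.design),
        "noise_params": dataclasses.asdict(cfg.noise),
        "scene": {
            "grid_shape": list(cfg.grid_shape),
            "seed": cfg.seed,
            "n_sessions": cfg.design.n_sessions,
            "effect": dataclasses.asdict(cfg.effect),
            "roi_specs": [
                dataclasses.asdict(s)
                for s in (cfg.roi_specs or default_roi_specs(cfg.grid_shape))
            ],
        },
        "runs": run_index,
    }
    (root / "dataset.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    logger.info("simulate: wrote %d runs under %s", len(run_index), root)


def _beta_stem(subject: int, session: int) -> str:
    return f"sub-{subject:02d}_ses-{session}"


def stage_glm(cfg: RunConfig):
    """Fit the GLM per subject/session; write betas and localizer maps."""
    ds_root = cfg.out / "dataset"
    design = synth_io.read_design(ds_root)
    glm_dir = cfg.path("glm", "x").parent
    index_rows = []
    contrast_maps: dict[int, list[np.ndarray]] = {}
    for subject in design.subjects:
        for session in design.sessions:
            runs = list(design.runs)
            epochs = [design.epochs[(subject, session, r)] for r in runs]
            n_scans = [design.n_scans((subject, session, r)) for r in runs]
            bold_runs, motion = [], []
            for r in runs:
                br = synth_io.read_run(ds_root, subject, session, r)
                bold_runs.append(br.data)
                motion.append(br.motion)
            X = glm.build_design_matrix(
                epochs, design.params.tr, n_scans, motion=motion
            )
            betas = glm.fit_glm(bold_runs, X)
            stem = _beta_stem(subject, session)
            vols = []
            for r in runs:
                for cond in CONDITIONS_OF_INTEREST:
                    vols.append(betas.condition_beta(cond, r))
                    index_rows.append(
                        {
                            "subject": subject,
                            "session": session,
                            "condition": cond,
                            "run": r,
                            "path": f"glm/{stem}_betas.nii.gz",
                            "volume": len(vols) - 1,
                        }
                    )
            synth_io.save_volume(
                glm_dir / f"{stem}_betas.nii.gz", np.stack(vols, axis=-1)
            )
            con = glm.contrast_estimate(betas, glm.LOCALIZER_WEIGHTS)
            tmap = glm.contrast_t(betas, glm.LOCALIZER_WEIGHTS)
            synth_io.save_volume(glm_dir / f"{stem}_localizer_con.nii.gz", con)
            synth_io.save_volume(glm_dir / f"{stem}_localizer_t.nii.gz", tmap.values)
            contrast_maps.setdefault(session, []).append(con)
    pd.DataFrame(index_rows).to_csv(glm_dir / "beta_index.tsv", sep="\t", index=False)
    group_info = {}
    for session, vols in contrast_maps.items():
        gmap = glm.group_map(vols)
        synth_io.save_volume(glm_dir / f"group_localizer_t_ses-{session}.nii.gz", gmap.values)
        group_info[str(session)] = {"dof": gmap.dof, "n_subjects": len(vols)}
    (glm_dir / "group_info.json").write_text(json.dumps(group_info, indent=1, sort_keys=True))
    logger.info("glm: fitted %d subject-sessions", len(index_rows) // 16)


def _load_session_contrasts(cfg: RunConfig, session: int) -> list[np.ndarray]:
    design = synth_io.read_design(cfg.out / "dataset")
    return [
        synth_io.load_volume(
            cfg.out / "glm" / f"{_beta_stem(subject, session)}_localizer_con.nii.gz"
        )
        for subject in design.subjects
    ]


def stage_localize(cfg: RunConfig):
    """Define ROIs from the session-1 group localizer map."""
    loc = cfg.localizer
    glm_dir = cfg.out / "glm"
    group_info = json.loads((glm_dir / "group_info.json").read_text())
    t_vol = synth_io.load_volume(glm_dir / "group_localizer_t_ses-1.nii.gz")
    gmap = glm.StatMap(values=t_vol, dof=group_info["1"]["dof"])
    binary = roi_mod.threshold_peaks(gmap, loc.p_peak)
    clusters = roi_mod.label_clusters(binary, loc.connectivity, stat_map=t_vol)
    contrasts = _load_session_contrasts(cfg, session=1)
    extent = roi_mod.cluster_extent_threshold(
        contrasts,
        p_peak=loc.p_peak,
        alpha=loc.alpha,
        n_perm=loc.n_perm,
        seed=int(seed_sequence(cfg.seed, "extent-null").generate_state(1)[0] % 2**31),
        connectivity=loc.connectivity,
    )
    rois = roi_mod.select_rois(clusters, extent, loc.min_voxels)
    scene = synth_io.read_scene(cfg.out / "dataset")
    rois = roi_mod.match_rois_to_reference(rois, scene.masks)

    roi_dir = cfg.path("roi", "x").parent
    rows = []
    for e in rois.entries:
        synth_io.save_volume(roi_dir / f"mask_{e.name}.nii.gz", rois.masks[e.name].astype(float))
        rows.append(
            {
                "name": e.name,
                "size": e.size,
                "peak_x": e.peak[0],
                "peak_y": e.peak[1],
                "peak_z": e.peak[2],
                "peak_stat": e.peak_stat,
            }
        )
    pd.DataFrame(rows, columns=["name", "size", "peak_x", "peak_y", "peak_z", "peak_stat"]).to_csv(
        roi_dir / "clusters.tsv", sep="\t", index=False
    )
    (roi_dir / "extent.json").write_text(
        json.dumps(
            {
                "extent_threshold": extent,
                "min_voxels": loc.min_voxels,
                "p_peak": loc.p_peak,
                "alpha": loc.alpha,
                "n_clusters_suprathreshold": len(clusters.clusters),
            },
            indent=1,
            sort_keys=True,
        )
    )
    logger.info("localize: %d ROIs survive (extent >= %d)", len(rois), max(extent, loc.min_voxels))


def load_roi_masks(cfg: RunConfig) -> dict[str, np.ndarray]:
    roi_dir = cfg.out / "roi"
    if not (roi_dir / "clusters.tsv").exists():
        raise FileNotFoundError(f"no localization artifacts under {roi_dir}; run 'localize' first")
    table = pd.read_csv(roi_dir / "clusters.tsv", sep="\t")
    return {
        str(name): synth_io.load_volume(roi_dir / f"mask_{name}.nii.gz") > 0.5
        for name in table["name"]
    }


def load_patterns(
    cfg: RunConfig, masks: dict[str, np.ndarray]
) -> dict[tuple[str, int], list[dec.BetaPatternSet]]:
    """(roi, session) -> per-subject complete 16-sample pattern sets."""
    design = synth_io.read_design(cfg.out / "dataset")
    out: dict[tuple[str, int], list[dec.BetaPatternSet]] = {}
    for subject in design.subjects:
        for session in design.sessions:
            stem = _beta_stem(subject, session)
            vols4d = synth_io.load_volume(cfg.out / "glm" / f"{stem}_betas.nii.gz")
            mapping = {}
            i = 0
            for r in design.runs:
                for cond in CONDITIONS_OF_INTEREST:
                    mapping[(cond, r)] = vols4d[..., i]
                    i += 1
            for name, mask in masks.items():
                ps = dec.extract_patterns(
                    mapping,
                    mask,
                    normalize=cfg.decoding.normalize,
                    subject=subject,
                    session=session,
                    roi=name,
                )
                out.setdefault((name, session), []).append(ps)
    return out


def stage_decode(cfg: RunConfig):
    """Within-session LORO decoding per ROI, session, and search type."""
    masks = load_roi_masks(cfg)
    patterns = load_patterns(cfg, masks)
    rows = []
    for (name, session), subject_sets in sorted(patterns.items()):
        for search in SEARCH_TYPES:
            subsets = [ps.split_by_search()[search] for ps in subject_sets]
            result = dec.group_decode(subsets, C=cfg.decoding.C)
            for ps, acc in zip(subsets, result.subject_accuracies):
                rows.append(
                    {
                        "roi": name,
                        "session": session,
                        "search": search,
                        "subject": ps.subject,
                        "accuracy": acc,
                    }
                )
            rows.append(
                {
                    "roi": name,
                    "session": session,
                    "search": search,
                    "subject": "group",
                    "accuracy": result.mean,
                    "sem": result.sem,
                }
            )
    path = cfg.path("decode", "accuracies.tsv")
    pd.DataFrame(
        rows, columns=["roi", "session", "search", "subject", "accuracy", "sem"]
    ).to_csv(path, sep="\t", index=False)
    logger.info("decode: wrote %s", path)


def stage_permtest(cfg: RunConfig):
    """Permutation nulls and critical values per ROI, session, search."""
    masks = load_roi_masks(cfg)
    patterns = load_patterns(cfg, masks)
    nulls = {}
    for (name, session), subject_sets in sorted(patterns.items()):
        for search in SEARCH_TYPES:
            subsets = [ps.split_by_search()[search] for ps in subject_sets]
            seed = int(
                seed_sequence(cfg.seed, "permtest", name, session, search).generate_state(1)[0]
                % 2**31
            )
            null = dec.permutation_null(
                subsets, n_perm=cfg.decoding.n_perm, seed=seed, C=cfg.decoding.C
            )
            nulls[f"{name}|ses-{session}|{search}"] = {
                "critical_value": null.critical_value,
                "n_perm": len(null.values),
                "seed": seed,
                "values": [float(v) for v in null.values],
            }
    cfg.path("decode", "nulls.json").write_text(json.dumps(nulls, indent=1, sort_keys=True))
    logger.info("permtest: %d nulls", len(nulls))


def stage_cross_session(cfg: RunConfig):
    """Train on one session's patterns, test on the other's, both directions."""
    masks = load_roi_masks(cfg)
    patterns = load_patterns(cfg, masks)
    if not any(s == 2 for (_, s) in patterns):
        logger.warning("cross-session: only one session present; skipped")
        return
    rows = []
    for name in sorted(masks):
        for search in SEARCH_TYPES:
            s1 = [ps.split_by_search()[search] for ps in patterns[(name, 1)]]
            s2 = [ps.split_by_search()[search] for ps in patterns[(name, 2)]]
            for direction, (tr, te) in (("1to2", (s1, s2)), ("2to1", (s2, s1))):
                result = dec.cross_session_decode(tr, te, C=cfg.decoding.C)
                for ps, acc in zip(te, result.subject_accuracies):
                    rows.append(
                        {
                            "roi": name,
                            "direction": direction,
                            "search": search,
                            "subject": ps.subject,
                            "accuracy": acc,
                        }
                    )
                rows.append(
                    {
                        "roi": name,
                        "direction": direction,
                        "search": search,
                        "subject": "group",
                        "accuracy": result.mean,
                        "sem": result.sem,
                    }
                )
    path = cfg.path("decode", "cross_session.tsv")
    pd.DataFrame(
        rows, columns=["roi", "direction", "search", "subject", "accuracy", "sem"]
    ).to_csv(path, sep="\t", index=False)
    logger.info("cross-session: wrote %s", path)


def stage_feature_curve(cfg: RunConfig):
    """Accuracy vs voxel-subset size per ROI, session, and search."""
    masks = load_roi_masks(cfg)
    which = cfg.decoding.feature_rois or tuple(sorted(masks))
    masks = {k: v for k, v in masks.items() if k in which}
    patterns = load_patterns(cfg, masks)
    rows = []
    for (name, session), subject_sets in sorted(patterns.items()):
        for search in SEARCH_TYPES:
            subsets = [ps.split_by_search()[search] for ps in subject_sets]
            if min(cfg.decoding.feature_sizes) > subsets[0].n_voxels:
                logger.warning("feature curve: ROI %s too small; skipped", name)
                continue
            seed = int(
                seed_sequence(cfg.seed, "feature", name, session, search).generate_state(1)[0]
                % 2**31
            )
            curve = dec.feature_curve(
                subsets,
                sizes=cfg.decoding.feature_sizes,
                n_draws=cfg.decoding.feature_draws,
                seed=seed,
                C=cfg.decoding.C,
            )
            for j, size in enumerate(curve.sizes):
                rows.append(
                    {
                        "roi": name,
                        "session": session,
                        "search": search,
                        "size": size,
                        "accuracy": float(curve.group_mean[j]),
                        "n_draws": curve.n_draws,
                    }
                )
    path = cfg.path("decode", "feature_curves.tsv")
    pd.DataFrame(
        rows, columns=["roi", "session", "search", "size", "accuracy", "n_draws"]
    ).to_csv(path, sep="\t", index=False)
    logger.info("feature-curve: wrote %s", path)


def stage_stats(cfg: RunConfig):
    """Confound table, hemisphere x session RM-ANOVA, behavioral t-tests."""
    masks = load_roi_masks(cfg)
    patterns = load_patterns(cfg, masks)
    session1 = {name: patterns[(name, 1)] for (name, s) in patterns if s == 1}
    out: dict = {}
    if session1:
        table = stats_mod.mean_beta_table(session1)
        stats_dir = cfg.path("stats", "x").parent
        combined = table.means.round(6).astype(str) + "±" + table.sds.round(6).astype(str)
        combined.to_csv(stats_dir / "confound_table.tsv", sep="\t")
        table.differences.to_csv(stats_dir / "confound_differences.tsv", sep="\t")
        roi_max, search_max, value_max = table.max_difference()
        out["confound"] = {
            "means": json.loads(table.means.to_json()),
            "differences": json.loads(table.differences.to_json()),
            "max_difference": {"roi": roi_max, "search": search_max, "value": value_max},
        }

    # hemisphere x session RM-ANOVA on decoding accuracies, per search type
    acc_path = cfg.out / "decode" / "accuracies.tsv"
    left, right = cfg.decoding.hemisphere_pair
    if acc_path.exists() and not (acc := pd.read_csv(acc_path, sep="\t")).empty:
        acc = acc[acc.subject != "group"]
        have = set(acc.roi.unique())
        sessions = sorted(acc.session.unique())
        if {left, right} <= have and len(sessions) == 2:
            out["rm_anova"] = {}
            for search in SEARCH_TYPES:
                sub = acc[acc.search == search]
                piv = sub.pivot_table(
                    index="subject", columns=["roi", "session"], values="accuracy"
                )
                data = np.stack(
                    [
                        np.stack([piv[(h, s)].to_numpy() for s in sessions], axis=1)
                        for h in (left, right)
                    ],
                    axis=1,
                )
                res = stats_mod.rm_anova_2x2(data, factor_names=("hemisphere", "session"))
                out["rm_anova"][search] = {
                    k: {"F": v.F, "df": list(v.df), "p": v.p} for k, v in res.effects.items()
                }
        else:
            logger.warning(
                "rm-anova skipped: needs ROIs %s and %s across 2 sessions", left, right
            )

    behavior = generate_behavior(cfg.behavior, seed=cfg.seed)
    sm = behavior.session_means()
    out["behavior"] = {
        "session_means": [float(sm[s].mean()) for s in sm.columns],
    }
    if len(sm.columns) == 2:
        t = stats_mod.paired_t(sm[1].to_numpy(), sm[2].to_numpy())
        out["behavior"]["session1_vs_session2"] = {
            "t": t.t,
            "df": t.df,
            "p": t.p,
            "mean_difference": t.mean_difference,
            "degenerate": t.degenerate,
        }
    cfg.path("stats", "stats.json").write_text(json.dumps(out, indent=1, sort_keys=True))
    logger.info("stats: wrote stats.json")


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    config: dict
    provenance: dict
    roi_table: list[dict]  # per roi x session x search
    cross_session: list[dict]
    feature_curves: list[dict]
    stats: dict
    rois: list[dict]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def build_report(cfg: RunConfig) -> RunReport:
    """Consolidate stage artifacts into one report object."""
    import sklearn

    rois, roi_table, cross_rows, feature_rows = [], [], [], []
    stats_out: dict = {}
    clusters_path = cfg.out / "roi" / "clusters.tsv"
    if clusters_path.exists():
        rois = pd.read_csv(clusters_path, sep="\t").to_dict("records")
    nulls = {}
    nulls_path = cfg.out / "decode" / "nulls.json"
    if nulls_path.exists():
        nulls = json.loads(nulls_path.read_text())
    acc_path = cfg.out / "decode" / "accuracies.tsv"
    if acc_path.exists() and not (acc := pd.read_csv(acc_path, sep="\t")).empty:
        group = acc[acc.subject == "group"]
        for row in group.itertuples():
            key = f"{row.roi}|ses-{row.session}|{row.search}"
            crit = nulls.get(key, {}).get("critical_value")
            roi_table.append(
                {
                    "roi": row.roi,
                    "session": int(row.session),
                    "search": row.search,
                    "accuracy": float(row.accuracy),
                    "sem": float(row.sem),
                    "critical_value": crit,
                    "significant": (crit is not None) and (row.accuracy > crit),
                    "null_values": nulls.get(key, {}).get("values"),
                }
            )
    cs_path = cfg.out / "decode" / "cross_session.tsv"
    if cs_path.exists() and not (cs := pd.read_csv(cs_path, sep="\t")).empty:
        cross_rows = cs[cs.subject == "group"].drop(columns=["subject"]).to_dict("records")
    fc_path = cfg.out / "decode" / "feature_curves.tsv"
    if fc_path.exists():
        feature_rows = pd.read_csv(fc_path, sep="\t").to_dict("records")
    stats_path = cfg.out / "stats" / "stats.json"
    if stats_path.exists():
        stats_out = json.loads(stats_path.read_text())

    import rulemvpa

    return RunReport(
        config=cfg.to_dict(),
        provenance={
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "versions": {
                "rulemvpa": getattr(rulemvpa, "__version__", "0"),
                "numpy": np.__version__,
                "scikit-learn": sklearn.__version__,
            },
        },
        roi_table=roi_table,
        cross_session=cross_rows,
        feature_curves=feature_rows,
        stats=stats_out,
        rois=rois,
    )


def render_report(report: RunReport, out_dir, fmt: str = "tsv") -> list[Path]:
    """Write consolidated tables and a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    (out / "report.json").write_text(report.to_json())
    written.append(out / "report.json")

    if report.roi_table:
        df = pd.DataFrame(report.roi_table).drop(columns=["null_values"])
        wide = df.pivot_table(
            index="roi", columns=["session", "search"], values="accuracy"
        )
        wide.columns = [f"ses{s}_{search}" for (s, search) in wide.columns]
        order = [
            f"ses{s}_{search}"
            for s in sorted({r["session"] for r in report.roi_table})
            for search in SEARCH_TYPES
        ]
        wide = wide[[c for c in order if c in wide.columns]] * 100.0
        wide.round(2).to_csv(out / "accuracy_table.tsv", sep="\t")
        written.append(out / "accuracy_table.tsv")

    if report.cross_session:
        df = pd.DataFrame(report.cross_session)
        wide = df.pivot_table(index="roi", columns=["direction", "search"], values="accuracy")
        wide.columns = [f"{d}_{s}" for (d, s) in wide.columns]
        (wide * 100.0).round(2).to_csv(out / "cross_session_table.tsv", sep="\t")
        written.append(out / "cross_session_table.tsv")

    if report.feature_curves:
        pd.DataFrame(report.feature_curves).to_csv(
            out / "feature_curves.tsv", sep="\t", index=False
        )
        written.append(out / "feature_curves.tsv")

    lines = [
        "rulemvpa run report",
        f"config hash: {report.provenance['config_hash']}  seed: {report.provenance['seed']}",
        "",
    ]
    if not report.rois:
        lines.append("no ROIs survived localization")
    else:
        lines.append(f"{len(report.rois)} ROIs: " + ", ".join(str(r["name"]) for r in report.rois))
    for row in report.roi_table:
        crit = row["critical_value"]
        crit_s = f"{crit * 100:.1f}%" if crit is not None else "n/a"
        flag = " *" if row["significant"] else ""
        lines.append(
            f"  {row['roi']:>12s} ses-{row['session']} {row['search']:>9s}: "
            f"{row['accuracy'] * 100:5.1f}% ± {row['sem'] * 100:.1f} (criterion {crit_s}){flag}"
        )
    if "confound" in report.stats:
        m = report.stats["confound"]["max_difference"]
        lines.append(
            f"largest |verbal-spatial| mean-beta difference: {m['value']:.3f} "
            f"({m['roi']}, {m['search']} search)"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    written.append(out / "summary.txt")
    return written


def stage_report(cfg: RunConfig) -> RunReport:
    report = build_report(cfg)
    render_report(report, cfg.out / "report")
    return report


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "glm": stage_glm,
    "localize": stage_localize,
    "decode": stage_decode,
    "permtest": stage_permtest,
    "cross_session": stage_cross_session,
    "feature_curve": stage_feature_curve,
    "stats": stage_stats,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run the enabled stages in dependency order; return the report.

    The config is serialized verbatim into the output directory before
    any stage runs. A stage failure is re-raised with the stage name and
    output directory in the message.
    """
    cfg.validate()
    cfg.out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(cfg.out / "config.yaml")
    report = None
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            result = STAGE_FUNCS[stage](cfg)
        except Exception as err:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed (artifacts under {cfg.out}): {err}"
            ) from err
        if stage == "report":
            report = result
    if report is None:
        report = build_report(cfg)
    return report
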