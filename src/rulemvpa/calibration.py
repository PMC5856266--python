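"""Reduced-scale simulation studies for statistical calibration.

These helpers run the full analysis path (design -> scene -> BOLD ->
GLM -> pattern extraction) on a single-ROI scene small enough to repeat
dozens of times: a 12 x 12 x 10 grid holding one ~50-voxel ellipsoidal
ROI, 13 subjects, 4 runs. Effect parameters select the study condition:
``sigma_pat = 0`` and ``confound_delta = 0`` give a noise-only dataset
(decoding must sit at chance), nonzero values plant a domain code or a
uniform magnitude confound.
"""

from __future__ import annotations

import numpy as np

from . import glm
from .conditions import CONDITIONS_OF_INTEREST
from .decoding import BetaPatternSet, extract_patterns
from .synth import (
    DesignParams,
    EffectParams,
    NoiseParams,
    ROISpec,
    generate_design,
    generate_scene,
)
from .synth.bold import simulate_run

CAL_GRID = (12, 12, 10)
#: ~50-voxel ellipsoid (49 voxels on the calibration grid)
CAL_ROI = ROISpec("roi", (5, 5, 4), (2.3, 2.3, 2.2), "pattern-carrier")


def noise_only_effect() -> EffectParams:
    """Localizer response present, zero domain signal, zero confound."""
    return EffectParams(sigma_pat=0.0, confound_delta=0.0)


def simulate_study_patterns(
    seed: int,
    effect: EffectParams | None = None,
    n_subjects: int = 13,
    n_sessions: int = 1,
    roi_spec: ROISpec = CAL_ROI,
    grid_shape: tuple[int, int, int] = CAL_GRID,
    noise: NoiseParams | None = None,
    mean_epoch_duration: tuple[float, ...] = (17.0, 10.0),
) -> dict[int, list[BetaPatternSet]]:
    """Simulate one study and fit it end to end.

    Returns, per session, one complete 16-sample pattern set per subject
    for the single ROI (ground-truth mask; the localization stage is
    exercised elsewhere). Everything is deterministic given ``seed``.
    """
    effect = effect if effect is not None else noise_only_effect()
    noise = noise or NoiseParams()
    params = DesignParams(
        n_subjects=n_subjects,
        n_sessions=n_sessions,
        mean_epoch_duration=mean_epoch_duration[:n_sessions],
    )
    design = generate_design(params, seed)
    scene = generate_scene(
        grid_shape=grid_shape,
        roi_specs=(roi_spec,),
        effect=effect,
        seed=seed,
        n_sessions=n_sessions,
    )
    mask = scene.masks[roi_spec.name]

    out: dict[int, list[BetaPatternSet]] = {s: [] for s in design.sessions}
    for subject in design.subjects:
        for session in design.sessions:
            runs = list(design.runs)
            epochs = [design.epochs[(subject, session, r)] for r in runs]
            n_scans = [design.n_scans((subject, session, r)) for r in runs]
            bold, motion = [], []
            for r in runs:
                br = simulate_run(design, scene, noise, (subject, session, r), seed)
                bold.append(br.data)
                motion.append(br.motion)
            X = glm.build_design_matrix(epochs, params.tr, n_scans, motion=motion)
            betas = glm.fit_glm(bold, X)
            out[session].append(
                extract_patterns(
                    betas,
                    mask,
                    conditions=CONDITIONS_OF_INTEREST,
                    subject=subject,
                    session=session,
                    roi=roi_spec.name,
                )
            )
    return out


def class_mean_pattern_correlation(patterns: BetaPatternSet, search: str) -> float:
    """Correlation across voxels of the verbal vs spatial mean patterns.

    Near 1 when the two classes share the same voxel-wise response
    profile and differ only in overall magnitude — the signature of a
    univariate confound rather than a genuine multivoxel code.
    """
    sub = patterns.subset(patterns.searches == search)
    mv = sub.X[sub.domains == "verbal"].mean(axis=0)
    ms = sub.X[sub.domains == "spatial"].mean(axis=0)
    return float(np.corrcoef(mv, ms)[0, 1])
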