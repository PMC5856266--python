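"""Forward BOLD simulation.

Each voxel's time course is the sum over conditions of the voxel's mean
amplitude times the boxcar-convolved canonical HRF regressor, plus
optional polynomial drift, optional motion leakage, and Gaussian noise
(i.i.d. or AR(1)). The forward model deliberately matches the GLM design
matrix, so a noise-free simulate-then-fit round trip recovers the
planted amplitudes to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import glm
from .._seeds import rng_for
from .design import ExperimentDesign, RunKey
from .scene import GroundTruthScene


@dataclass
class NoiseParams:
    sigma: float = 1.0  # marginal noise sd
    ar1_rho: float = 0.0  # temporal autocorrelation
    drift_order: int = 0  # 0 = no drift
    drift_sd: float = 0.5  # sd of drift polynomial coefficients
    motion_walk_sd: float = 0.02  # per-step sd of the 6 motion traces
    motion_mix: float = 0.0  # 0 = motion does not contaminate the signal

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not -1 < self.ar1_rho < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.drift_order < 0:
            raise ValueError("drift_order must be >= 0")


@dataclass
class BOLDRun:
    data: np.ndarray  # (x, y, z, t)
    motion: np.ndarray  # (t, 6)

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]


@dataclass
class BOLDDataset:
    design: ExperimentDesign
    scene: GroundTruthScene
    noise: NoiseParams
    seed: int
    runs: dict[RunKey, BOLDRun] = field(default_factory=dict)


def _ar1_noise(rng: np.random.Generator, shape, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd ``sigma`` (burn-in 50)."""
    n_t = shape[0]
    if rho == 0.0:
        return sigma * rng.standard_normal(shape)
    burn = 50
    e = rng.standard_normal((n_t + burn, *shape[1:]))
    x = np.empty_like(e)
    x[0] = e[0]
    innov = np.sqrt(1.0 - rho**2)
    for t in range(1, n_t + burn):
        x[t] = rho * x[t - 1] + innov * e[t]
    return sigma * x[burn:]


def simulate_run(
    design: ExperimentDesign,
    scene: GroundTruthScene,
    noise: NoiseParams,
    key: RunKey,
    seed: int,
    hrf: glm.HRFKernel | None = None,
) -> BOLDRun:
    """Simulate one run; deterministic given (seed, subject, session, run)."""
    subject, session, run = key
    tr = design.params.tr
    n_scans = design.n_scans(key)
    epochs = design.epochs[key]
    last_end = max(e.onset + e.duration for e in epochs)
    if n_scans * tr < last_end:
        raise ValueError(f"run {key} shorter than its design ({n_scans * tr}s < {last_end}s)")

    regs, present = glm.condition_regressors(epochs, tr, n_scans, hrf=hrf)
    nvox = int(np.prod(scene.grid_shape))
    amps = np.stack(
        [scene.amplitude(subject, session, c).reshape(-1) for c in present]
    )  # (n_cond, nvox)
    signal = regs @ amps  # (n_scans, nvox)

    rng = rng_for(seed, "bold", subject, session, run)
    motion = np.cumsum(
        noise.motion_walk_sd * rng.standard_normal((n_scans, 6)), axis=0
    )
    if noise.motion_mix != 0.0:
        loadings = noise.motion_mix * rng.standard_normal((6, nvox))
        signal = signal + motion @ loadings

    if noise.drift_order > 0:
        t_norm = np.linspace(-1.0, 1.0, n_scans)
        coefs = noise.drift_sd * rng.standard_normal(noise.drift_order)
        drift = sum(
            coefs[k - 1] * np.polynomial.legendre.Legendre.basis(k)(t_norm)
            for k in range(1, noise.drift_order + 1)
        )
        signal = signal + drift[:, None]

    if noise.sigma > 0:
        signal = signal + _ar1_noise(rng, (n_scans, nvox), noise.sigma, noise.ar1_rho)

    data = signal.T.reshape(*scene.grid_shape, n_scans)
    return BOLDRun(data=np.ascontiguousarray(data), motion=motion)


def simulate_bold(
    design: ExperimentDesign,
    scene: GroundTruthScene,
    noise: NoiseParams | None = None,
    hrf: glm.HRFKernel | None = None,
    seed: int = 0,
    subjects=None,
    sessions=None,
) -> BOLDDataset:
    """Simulate all (or selected) subjects/sessions of a design.

    Per-run draws derive their generator from (seed, subject, session,
    run), so restricting ``subjects``/``sessions`` yields the same
    volumes those subjects would get in a full simulation.
    """
    noise = noise or NoiseParams()
    noise.validate()
    conds_in_design = {e.condition for eps in design.epochs.values() for e in eps}
    conds_in_scene = {c for (_, c) in scene.base_amplitudes}
    if not conds_in_design <= conds_in_scene:
        raise ValueError(
            f"design conditions {sorted(conds_in_design - conds_in_scene)} "
            "missing from the scene's vocabulary"
        )
    if scene.n_sessions < design.params.n_sessions and sessions is None:
        raise ValueError("scene has fewer sessions than the design")

    dataset = BOLDDataset(design=design, scene=scene, noise=noise, seed=seed)
    subjects = list(subjects) if subjects is not None else list(design.subjects)
    sessions = list(sessions) if sessions is not None else list(design.sessions)
    for subject in subjects:
        for session in sessions:
            for run in design.runs:
                key = (subject, session, run)
                dataset.runs[key] = simulate_run(design, scene, noise, key, seed, hrf=hrf)
    return dataset
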