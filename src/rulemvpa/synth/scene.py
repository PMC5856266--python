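"""Ground-truth activation scenes.

A scene assigns every voxel a mean response amplitude per condition and
session. Inside ellipsoidal ROIs all task conditions respond (the
localizer contrast rule-discovery > control is positive everywhere in an
ROI); outside ROIs all condition amplitudes are equal (zero). Three ROI
roles exist:

* ``localizer-only`` — responds to the task but carries no domain
  information (verbal and spatial amplitude maps identical);
* ``pattern-carrier`` — additionally carries a zero-mean multivoxel
  domain code (sd ``sigma_pat``), drawn independently per subject
  (voxel-level codes do not align across participants), constant across
  runs within a session and, when ``session_remap`` is on, independently
  redrawn per session;
* ``magnitude-confound`` — verbal rule-discovery amplitudes uniformly
  exceed spatial ones by ``confound_delta`` with no multivoxel
  structure, the signature of a univariate confound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..conditions import (
    ALL_CONDITIONS,
    CONDITIONS_OF_INTEREST,
    ERROR_CONDITION,
    domain_of,
)
from .._seeds import rng_for

ROI_ROLES = ("localizer-only", "pattern-carrier", "magnitude-confound")


@dataclass(frozen=True)
class ROISpec:
    name: str
    center: tuple[int, int, int]
    radii: tuple[float, float, float]
    role: str = "localizer-only"

    def __post_init__(self):
        if self.role not in ROI_ROLES:
            raise ValueError(f"unknown ROI role {self.role!r}")
        if min(self.radii) <= 0:
            raise ValueError("ellipsoid radii must be positive")


@dataclass
class EffectParams:
    """Planted effect sizes, in signal units (noise sd defaults to 1)."""

    amp_discovery: float = 1.0
    amp_confirmation: float = 0.6
    amp_control: float = 0.3
    amp_error: float = 0.2
    sigma_pat: float = 0.5  # sd of the zero-mean domain pattern
    confound_delta: float = 0.48  # uniform verbal - spatial amplitude difference
    amp_heterogeneity: float = 0.3  # sd of per-voxel multiplicative gain in ROIs
    session_remap: bool = True

    def validate(self) -> None:
        if self.amp_discovery <= self.amp_control:
            raise ValueError(
                "rule-discovery amplitude must exceed control amplitude "
                "(the localizer contrast must be positive inside ROIs)"
            )
        if self.sigma_pat < 0 or self.amp_heterogeneity < 0:
            raise ValueError("spread parameters must be non-negative")

    def base_amplitude(self, condition: str) -> float:
        if condition == ERROR_CONDITION:
            return self.amp_error
        if condition.startswith("disc_"):
            return self.amp_discovery
        if condition.startswith("conf_"):
            return self.amp_confirmation
        if condition.startswith("ctrl_"):
            return self.amp_control
        raise ValueError(f"unknown condition {condition!r}")


def ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    center: tuple[int, int, int],
    radii: tuple[float, float, float],
) -> np.ndarray:
    """Boolean mask of voxels inside the ellipsoid (boundary included)."""
    coords = np.indices(grid_shape, dtype=float)
    d2 = sum(
        ((coords[i] - center[i]) / radii[i]) ** 2 for i in range(3)
    )
    return d2 <= 1.0


def default_roi_specs(grid_shape: tuple[int, int, int] = (36, 36, 30)) -> tuple[ROISpec, ...]:
    """Six ROIs sized like typical localizer clusters (tens to hundreds of
    voxels), with one pattern carrier, one homologous comparison region,
    and one magnitude-confound region."""
    gx, gy, gz = grid_shape
    return (
        ROISpec("L_IFG", (8, 12, 18), (5.0, 5.3, 4.3), "pattern-carrier"),  # ~460 vox
        ROISpec("R_IFG", (gx - 9, 12, 18), (3.6, 3.7, 3.0), "localizer-only"),  # ~165
        ROISpec("R_SFG", (gx - 10, 25, 22), (3.1, 3.1, 2.6), "localizer-only"),  # ~100
        ROISpec("L_OG", (8, 25, 8), (2.1, 2.1, 1.8), "magnitude-confound"),  # ~32
        ROISpec("R_OG", (gx - 9, 25, 8), (2.0, 2.0, 1.7), "localizer-only"),  # ~27
        ROISpec("L_Cer", (12, 6, 6), (4.4, 4.5, 3.7), "localizer-only"),  # ~300
    )


@dataclass
class GroundTruthScene:
    grid_shape: tuple[int, int, int]
    roi_specs: tuple[ROISpec, ...]
    effect: EffectParams
    seed: int
    n_sessions: int
    masks: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    #: per (session, condition) voxel-wise mean response shared by all
    #: subjects (localizer amplitudes and the uniform confound offset)
    base_amplitudes: dict[tuple[int, str], np.ndarray] = field(
        default_factory=dict, repr=False
    )
    #: lazily drawn per (roi, subject, session, domain) pattern offsets
    _pattern_cache: dict[tuple[str, int, int, str], np.ndarray] = field(
        default_factory=dict, repr=False
    )

    def rois_by_role(self, role: str) -> list[ROISpec]:
        return [s for s in self.roi_specs if s.role == role]

    def domain_pattern(
        self, roi: str, subject: int, session: int, domain: str
    ) -> np.ndarray:
        """Zero-mean domain-code offset over the ROI's voxels.

        Drawn deterministically from (scene seed, roi, subject, session,
        domain); each subject carries their own code. Without
        ``session_remap`` the session-1 code is reused in every session.
        """
        if not self.effect.session_remap:
            session = 1
        key = (roi, subject, session, domain)
        if key not in self._pattern_cache:
            nvox = int(self.masks[roi].sum())
            rng = rng_for(self.seed, "scene-pattern", roi, subject, session, domain)
            p = self.effect.sigma_pat * rng.standard_normal(nvox)
            if nvox > 1:
                p -= p.mean()  # exact zero-mean offset
            self._pattern_cache[key] = p
        return self._pattern_cache[key]

    def amplitude(self, subject: int, session: int, condition: str) -> np.ndarray:
        """Voxel-wise mean response of one condition for one subject."""
        vol = self.base_amplitudes[(session, condition)]
        if condition not in CONDITIONS_OF_INTEREST:
            return vol
        carriers = self.rois_by_role("pattern-carrier")
        if not carriers:
            return vol
        vol = vol.copy()
        for spec in carriers:
            pattern = self.domain_pattern(
                spec.name, subject, session, domain_of(condition)
            )
            vol[self.masks[spec.name]] += pattern
        return vol


def generate_scene(
    grid_shape: tuple[int, int, int] = (36, 36, 30),
    roi_specs: tuple[ROISpec, ...] | None = None,
    effect: EffectParams | None = None,
    seed: int = 0,
    n_sessions: int = 2,
) -> GroundTruthScene:
    """Build a scene: masks, per-condition amplitude volumes, domain patterns.

    Raises if ellipsoids do not fit inside the grid or if any two ROIs
    overlap (overlap would confound the localizer-based ROI definition).
    """
    if roi_specs is None:
        roi_specs = default_roi_specs(grid_shape)
    effect = effect or EffectParams()
    effect.validate()

    masks: dict[str, np.ndarray] = {}
    occupied = np.zeros(grid_shape, dtype=bool)
    for spec in roi_specs:
        for i in range(3):
            if spec.center[i] - spec.radii[i] < 0 or spec.center[i] + spec.radii[i] > grid_shape[i] - 1:
                raise ValueError(f"ROI {spec.name!r} ellipsoid does not fit inside the grid")
        mask = ellipsoid_mask(grid_shape, spec.center, spec.radii)
        if (occupied & mask).any():
            raise ValueError(f"ROI {spec.name!r} overlaps another ROI")
        occupied |= mask
        masks[spec.name] = mask

    scene = GroundTruthScene(
        grid_shape=grid_shape,
        roi_specs=tuple(roi_specs),
        effect=effect,
        seed=seed,
        n_sessions=n_sessions,
        masks=masks,
    )

    # per-voxel multiplicative gain, shared across conditions and sessions
    gains: dict[str, np.ndarray] = {}
    for spec in roi_specs:
        rng = rng_for(seed, "scene-gain", spec.name)
        g = 1.0 + effect.amp_heterogeneity * rng.standard_normal(int(masks[spec.name].sum()))
        gains[spec.name] = np.clip(g, 0.1, None)  # keep amplitudes positive

    for session in range(1, n_sessions + 1):
        amps = {c: np.zeros(grid_shape) for c in ALL_CONDITIONS}
        for spec in roi_specs:
            m = masks[spec.name]
            for cond in ALL_CONDITIONS:
                amps[cond][m] = effect.base_amplitude(cond) * gains[spec.name]

        for spec in scene.rois_by_role("magnitude-confound"):
            m = masks[spec.name]
            for cond in CONDITIONS_OF_INTEREST:
                if domain_of(cond) == "verbal":
                    amps[cond][m] += effect.confound_delta

        for cond in ALL_CONDITIONS:
            scene.base_amplitudes[(session, cond)] = amps[cond]

    # sanity: conditions vocabulary is complete
    assert set(c for (_, c) in scene.base_amplitudes) == set(ALL_CONDITIONS)
    return scene
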