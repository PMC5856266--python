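import numpy as np
import pytest

from rulemvpa.conditions import CONDITIONS_OF_INTEREST, domain_of, search_of
from rulemvpa.decoding import BetaPatternSet
from rulemvpa.synth import (
    DesignParams,
    EffectParams,
    NoiseParams,
    ROISpec,
    generate_design,
    generate_scene,
    simulate_bold,
)


@pytest.fixture(scope="session")
def tiny_design():
    """2 subjects, 1 session, 4 runs, short epochs: fast but complete."""
    params = DesignParams(n_subjects=2, n_sessions=1, mean_epoch_duration=(8.0,))
    return generate_design(params, seed=101)


@pytest.fixture(scope="session")
def tiny_scene():
    """Single ~50-voxel pattern-carrier ROI on a 12x12x10 grid."""
    return generate_scene(
        grid_shape=(12, 12, 10),
        roi_specs=(ROISpec("pat", (5, 5, 4), (2.3, 2.3, 2.2), "pattern-carrier"),),
        effect=EffectParams(sigma_pat=0.5),
        seed=101,
        n_sessions=1,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design, tiny_scene):
    return simulate_bold(tiny_design, tiny_scene, NoiseParams(sigma=0.5), seed=101)


def make_pattern_set(
    rng,
    n_voxels=30,
    runs=(1, 2, 3, 4),
    class_shift=0.0,
    pattern_sd=0.0,
    noise_sd=1.0,
    subject=1,
    session=1,
):
    """Synthetic 16-sample pattern set built directly at the beta level.

    ``class_shift`` adds a uniform verbal-minus-spatial magnitude offset;
    ``pattern_sd`` plants a zero-mean multivoxel domain code shared
    across runs.
    """
    codes = {
        "verbal": pattern_sd * rng.standard_normal(n_voxels),
        "spatial": pattern_sd * rng.standard_normal(n_voxels),
    }
    rows, dom, sea, rn = [], [], [], []
    for r in runs:
        for cond in CONDITIONS_OF_INTEREST:
            d = domain_of(cond)
            row = codes[d] + noise_sd * rng.standard_normal(n_voxels)
            if d == "verbal":
                row = row + class_shift
            rows.append(row)
            dom.append(d)
            sea.append(search_of(cond))
            rn.append(r)
    return BetaPatternSet(
        X=np.asarray(rows),
        domains=np.asarray(dom),
        searches=np.asarray(sea),
        runs=np.asarray(rn),
        subject=subject,
        session=session,
        roi="synthetic",
    )
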