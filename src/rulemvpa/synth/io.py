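"""On-disk dataset layout: NIfTI-1 volumes plus BIDS-style TSV/JSON.

Layout::

    <root>/dataset.json                          parameters, seeds, run index
    <root>/sub-01/ses-1/sub-01_ses-1_run-1_bold.nii.gz
    <root>/sub-01/ses-1/sub-01_ses-1_run-1_events.tsv   onset/duration/trial_type
    <root>/sub-01/ses-1/sub-01_ses-1_run-1_motion.tsv   6 columns

Volumes are written as float64 so a write/read round trip reproduces the
arrays bit-exactly. The ground-truth scene is stored as its generating
parameters + seed (regenerated verbatim on read).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bold import BOLDDataset, BOLDRun, NoiseParams
from .design import DesignParams, Epoch, ExperimentDesign
from .scene import EffectParams, ROISpec, generate_scene

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _run_stem(subject: int, session: int, run: int) -> str:
    return f"sub-{subject:02d}_ses-{session}_run-{run}"


def _run_dir(root: Path, subject: int, session: int) -> Path:
    return root / f"sub-{subject:02d}" / f"ses-{session}"


def save_volume(path: Path, data: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))
    try:
        nib.save(img, str(path))
    except OSError as err:
        raise OSError(f"failed to write NIfTI volume {path}: {err}") from err


def load_volume(path: Path) -> np.ndarray:
    try:
        return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    except OSError as err:
        raise OSError(f"failed to read NIfTI volume {path}: {err}") from err


def write_dataset(dataset: BOLDDataset, directory) -> Path:
    """Write a simulated dataset as a NIfTI/TSV/JSON file tree."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)

    run_index = []
    for (subject, session, run), bold in sorted(dataset.runs.items()):
        d = _run_dir(root, subject, session)
        d.mkdir(parents=True, exist_ok=True)
        stem = _run_stem(subject, session, run)
        save_volume(d / f"{stem}_bold.nii.gz", bold.data)
        epochs = dataset.design.epochs[(subject, session, run)]
        pd.DataFrame(
            {
                "onset": [e.onset for e in epochs],
                "duration": [e.duration for e in epochs],
                "trial_type": [e.condition for e in epochs],
            }
        ).to_csv(d / f"{stem}_events.tsv", sep="\t", index=False)
        pd.DataFrame(bold.motion, columns=MOTION_COLUMNS).to_csv(
            d / f"{stem}_motion.tsv", sep="\t", index=False
        )
        run_index.append(
            {
                "subject": subject,
                "session": session,
                "run": run,
                "n_scans": bold.n_scans,
                "run_duration_s": dataset.design.run_duration_s[(subject, session, run)],
            }
        )

    scene = dataset.scene
    sidecar = {
        "seed": dataset.seed,
        "design_params": dataclasses.asdict(dataset.design.params),
        "noise_params": dataclasses.asdict(dataset.noise),
        "scene": {
            "grid_shape": list(scene.grid_shape),
            "seed": scene.seed,
            "n_sessions": scene.n_sessions,
            "effect": dataclasses.asdict(scene.effect),
            "roi_specs": [dataclasses.asdict(s) for s in scene.roi_specs],
        },
        "runs": run_index,
    }
    (root / "dataset.json").write_text(json.dumps(sidecar, indent=1))
    return root


def _design_params_from_json(d: dict) -> DesignParams:
    d = dict(d)
    for k in ("mean_epoch_duration", "blank_range"):
        d[k] = tuple(d[k])
    return DesignParams(**d)


def read_run(root: Path, subject: int, session: int, run: int) -> BOLDRun:
    d = _run_dir(Path(root), subject, session)
    stem = _run_stem(subject, session, run)
    data = load_volume(d / f"{stem}_bold.nii.gz")
    motion = pd.read_csv(d / f"{stem}_motion.tsv", sep="\t").to_numpy(dtype=float)
    return BOLDRun(data=data, motion=motion)


def read_events(root: Path, subject: int, session: int, run: int) -> list[Epoch]:
    d = _run_dir(Path(root), subject, session)
    stem = _run_stem(subject, session, run)
    ev = pd.read_csv(d / f"{stem}_events.tsv", sep="\t")
    return [
        Epoch(condition=row.trial_type, onset=float(row.onset), duration=float(row.duration))
        for row in ev.itertuples()
    ]


def read_sidecar(directory) -> dict:
    return json.loads((Path(directory) / "dataset.json").read_text())


def read_design(directory) -> ExperimentDesign:
    """Reconstruct the ExperimentDesign from events TSVs + sidecar."""
    root = Path(directory)
    meta = read_sidecar(root)
    design = ExperimentDesign(params=_design_params_from_json(meta["design_params"]))
    for entry in meta["runs"]:
        key = (entry["subject"], entry["session"], entry["run"])
        design.epochs[key] = tuple(read_events(root, *key))
        design.run_duration_s[key] = float(entry["run_duration_s"])
    return design


def read_scene(directory):
    meta = read_sidecar(directory)["scene"]
    specs = tuple(
        ROISpec(
            name=s["name"],
            center=tuple(s["center"]),
            radii=tuple(s["radii"]),
            role=s["role"],
        )
        for s in meta["roi_specs"]
    )
    return generate_scene(
        grid_shape=tuple(meta["grid_shape"]),
        roi_specs=specs,
        effect=EffectParams(**meta["effect"]),
        seed=meta["seed"],
        n_sessions=meta["n_sessions"],
    )


def read_dataset(directory, subjects=None, sessions=None) -> BOLDDataset:
    """Read a dataset tree back into memory (optionally a subject subset)."""
    root = Path(directory)
    meta = read_sidecar(root)
    design = read_design(root)
    scene = read_scene(root)
    noise = NoiseParams(**meta["noise_params"])
    dataset = BOLDDataset(design=design, scene=scene, noise=noise, seed=meta["seed"])
    for entry in meta["runs"]:
        key = (entry["subject"], entry["session"], entry["run"])
        if subjects is not None and key[0] not in subjects:
            continue
        if sessions is not None and key[1] not in sessions:
            continue
        dataset.runs[key] = read_run(root, *key)
    return dataset
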