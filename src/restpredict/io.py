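"""Cohort serialisation and real-data adapters.

Synthetic cohorts round-trip losslessly through a directory of per-session
TSV matrices plus a JSON manifest (config, subject table, ground truth).
Real preprocessed data enter through ``load_real_subject``: a 4-D NIfTI
image, a matching 3-D label image, and a TSV confounds table.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthgen import CohortConfig, GroundTruth, SubjectSession

_FLOAT_FMT = "%.17g"  # lossless float64 round-trip


def _session_stem(s: SubjectSession) -> str:
    return f"{s.subject_id}_t{s.timepoint}"


def write_cohort(sessions: list[SubjectSession], truth: GroundTruth,
                 config: CohortConfig, outdir: str | Path) -> Path:
    """Write a cohort to ``outdir`` (per-session TSVs + manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects = []
    for s in sessions:
        stem = _session_stem(s)
        np.savetxt(outdir / f"{stem}_voxels.tsv", s.voxel_ts,
                   delimiter="\t", fmt=_FLOAT_FMT)
        np.savetxt(outdir / f"{stem}_nuisance.tsv", s.nuisance_ts,
                   delimiter="\t", fmt=_FLOAT_FMT)
        subjects.append({"subject_id": s.subject_id, "timepoint": s.timepoint,
                         "group": s.group, "sas": s.sas, "sds": s.sds})
    manifest = {
        "config": config.to_dict(),
        "subjects": subjects,
        "ground_truth": {
            "informative_voxel_ids": truth.informative_voxel_ids.tolist(),
            "informative_edge_ids": truth.informative_edge_ids.tolist(),
            "true_score_weights": truth.true_score_weights,
            "region_labels": truth.region_labels.tolist(),
            "feature_ids": truth.feature_ids,
            "planted_feature_values": {
                f"{sid}|{tp}": v.tolist()
                for (sid, tp), v in truth.planted_feature_values.items()},
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def read_cohort(indir: str | Path):
    """Inverse of :func:`write_cohort`; returns (sessions, truth, config)."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    config = CohortConfig.from_dict(manifest["config"])
    sessions = []
    for row in manifest["subjects"]:
        stem = f"{row['subject_id']}_t{row['timepoint']}"
        voxels = np.loadtxt(indir / f"{stem}_voxels.tsv", delimiter="\t", ndmin=2)
        nuis = np.loadtxt(indir / f"{stem}_nuisance.tsv", delimiter="\t", ndmin=2)
        sessions.append(SubjectSession(row["subject_id"], row["timepoint"],
                                       row["group"], voxels, nuis,
                                       row["sas"], row["sds"]))
    gt = manifest["ground_truth"]
    truth = GroundTruth(
        informative_voxel_ids=np.array(gt["informative_voxel_ids"], dtype=int),
        informative_edge_ids=np.array(gt["informative_edge_ids"], dtype=int),
        true_score_weights=gt["true_score_weights"],
        region_labels=np.array(gt["region_labels"], dtype=int),
        feature_ids=gt["feature_ids"],
        planted_feature_values={
            (k.split("|")[0], int(k.split("|")[1])): np.array(v)
            for k, v in gt["planted_feature_values"].items()},
    )
    return sessions, truth, config


def load_real_subject(func_image_path, label_image_path, confounds_path, *,
                      subject_id: str = "sub-001", timepoint: int = 1,
                      group: str = "survivor", drop_initial: int = 0,
                      valid_labels=None, sas=None, sds=None):
    """Build a :class:`SubjectSession` from preprocessed NIfTI + confounds TSV.

    The 4-D functional image is flattened to (T, V) over in-mask voxels
    (label > 0) in row-major grid order; the label image supplies the region
    vector.  ``drop_initial`` discards leading volumes (e.g. the 5 dummy
    volumes of a 205-volume run).  Labels absent from ``valid_labels`` (when
    given) are excluded with a warning.

    Returns ``(session, region_labels, meta)`` where ``meta`` records the
    retained voxel indices (row-major flat indices into the image grid).
    """
    func = nib.load(str(func_image_path))
    atlas = nib.load(str(label_image_path))
    if func.ndim != 4:
        raise ValueError(f"functional image must be 4-D, got shape {func.shape}")
    if func.shape[:3] != atlas.shape:
        raise ValueError(
            f"grid mismatch: functional {func.shape[:3]} vs labels {atlas.shape}")
    data = np.asarray(func.dataobj, dtype=float)
    labels3d = np.asarray(atlas.dataobj).astype(int)
    if drop_initial:
        data = data[..., drop_initial:]
    n_t = data.shape[-1]

    mask = labels3d.ravel(order="C") > 0
    labels = labels3d.ravel(order="C")[mask]
    if valid_labels is not None:
        ok = np.isin(labels, np.asarray(list(valid_labels)))
        if not ok.all():
            dropped = sorted(set(labels[~ok].tolist()))
            warnings.warn(f"excluding voxels with labels not in atlas table: {dropped}")
        keep = np.flatnonzero(mask)[ok]
        labels = labels[ok]
    else:
        keep = np.flatnonzero(mask)
    voxel_ts = data.reshape(-1, n_t, order="C")[keep].T

    confounds = pd.read_csv(confounds_path, sep="\t")
    if len(confounds) == n_t + drop_initial:
        confounds = confounds.iloc[drop_initial:]
    if len(confounds) != n_t:
        raise ValueError(
            f"confounds table has {len(confounds)} rows for {n_t} retained volumes")
    session = SubjectSession(subject_id, timepoint, group, voxel_ts,
                             confounds.to_numpy(dtype=float), sas, sds)
    meta = {"voxel_indices": keep, "confound_names": list(confounds.columns)}
    return session, labels, meta


def write_alff_nifti(values: np.ndarray, voxel_indices: np.ndarray,
                     grid_shape, affine, path) -> None:
    """Scatter a flat ALFF vector back into a 3-D NIfTI map."""
    vol = np.zeros(int(np.prod(grid_shape)))
    vol[np.asarray(voxel_indices, dtype=int)] = values
    nib.save(nib.Nifti1Image(vol.reshape(grid_shape, order="C"), affine), str(path))
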