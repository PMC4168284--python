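"""Feature extraction and end-to-end orchestration.

``extract_features`` turns a cohort of sessions into the two per-subject
feature blocks the MVPA consumes: the normalised ALFF map (one value per
voxel) and the upper-triangle FC vector (one value per region pair), both
computed from detrended, band-passed series, with nuisance regression
applied to the regional series before correlation.

``run_pipeline`` chains generation -> conditioning -> features -> LOOCV
classification and prediction (and optionally permutation testing), writing
TSV/JSON outputs plus a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alff import compute_alff, normalize_global
from .connectivity import fc_matrix, nuisance_regress, regional_means
from .mvpa import GroupClassifier, SymptomPredictor, SURVIVOR, CONTROL
from .permtest import permutation_test
from .signal import BandpassSpec, condition
from .synthgen import CohortConfig, SubjectSession, generate_cohort

log = logging.getLogger("restpredict")


@dataclass
class CohortFeatures:
    """Per-subject feature blocks for one cohort.

    Time-1 rows cover every subject (survivors then controls); Time-2 blocks
    are aligned with ``t2_index`` into the Time-1 survivor rows.
    """

    subject_ids: np.ndarray
    groups: np.ndarray
    labels: np.ndarray  # +1 survivor / -1 control
    alff: np.ndarray
    fc: np.ndarray
    sas: np.ndarray
    sds: np.ndarray
    t2_index: np.ndarray
    alff_t2: np.ndarray
    fc_t2: np.ndarray
    sas_t2: np.ndarray
    sds_t2: np.ndarray

    @property
    def survivor_rows(self) -> np.ndarray:
        return np.flatnonzero(self.labels == SURVIVOR)

    def classifier(self, **params) -> GroupClassifier:
        return GroupClassifier(self.alff, self.fc, self.labels,
                               self.subject_ids, **params)

    def predictor(self, score_name: str = "sas", **params) -> SymptomPredictor:
        rows = self.survivor_rows
        scores = {"sas": self.sas, "sds": self.sds}[score_name][rows]
        scores_t2 = {"sas": self.sas_t2, "sds": self.sds_t2}[score_name]
        # map t2_index (positions among all T1 rows) to survivor-row positions
        pos = {int(r): j for j, r in enumerate(rows)}
        t2_surv = np.array([pos[int(i)] for i in self.t2_index], dtype=int)
        return SymptomPredictor(
            self.alff[rows], self.fc[rows], scores, self.subject_ids[rows],
            t2_index=t2_surv, alff_t2=self.alff_t2, fc_t2=self.fc_t2,
            scores_t2=scores_t2, score_name=score_name, **params)


def extract_session_features(session: SubjectSession, region_labels: np.ndarray,
                             spec: BandpassSpec) -> tuple[np.ndarray, np.ndarray]:
    """(normalised ALFF vector, FC upper-triangle vector) for one session."""
    ts = condition(session.voxel_ts, spec)
    alff = normalize_global(
        compute_alff(ts, (spec.low_hz, spec.high_hz), spec.tr_seconds)).values
    nuis = condition(session.nuisance_ts, spec)
    residuals = nuisance_regress(regional_means(ts, region_labels), nuis)
    return alff, fc_matrix(residuals).upper


def extract_features(sessions: list[SubjectSession], region_labels: np.ndarray,
                     spec: BandpassSpec | None = None,
                     tr_seconds: float | None = None) -> CohortFeatures:
    """Feature blocks for a whole cohort (both timepoints)."""
    if spec is None:
        spec = BandpassSpec(tr_seconds=tr_seconds if tr_seconds else 2.0)
    t1 = [s for s in sessions if s.timepoint == 1]
    t2 = [s for s in sessions if s.timepoint == 2]
    feats1 = [extract_session_features(s, region_labels, spec) for s in t1]
    feats2 = [extract_session_features(s, region_labels, spec) for s in t2]
    ids1 = np.array([s.subject_id for s in t1])
    id_pos = {sid: i for i, sid in enumerate(ids1)}
    nan = lambda xs: np.array([x if x is not None else np.nan for x in xs], dtype=float)
    return CohortFeatures(
        subject_ids=ids1,
        groups=np.array([s.group for s in t1]),
        labels=np.array([SURVIVOR if s.group == "survivor" else CONTROL for s in t1]),
        alff=np.array([f[0] for f in feats1]),
        fc=np.array([f[1] for f in feats1]),
        sas=nan([s.sas for s in t1]),
        sds=nan([s.sds for s in t1]),
        t2_index=np.array([id_pos[s.subject_id] for s in t2], dtype=int),
        alff_t2=(np.array([f[0] for f in feats2]) if t2 else np.empty((0, 0))),
        fc_t2=(np.array([f[1] for f in feats2]) if t2 else np.empty((0, 0))),
        sas_t2=nan([s.sas for s in t2]),
        sds_t2=nan([s.sds for s in t2]),
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _config_hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config, outdir: str | Path):
    """Execute the full pipeline per a :class:`~restpredict.config.PipelineConfig`.

    Writes feature tables, prediction tables, a summary JSON and a manifest;
    idempotent given the configured seeds.  Returns the summary dict.
    """
    from .config import PipelineConfig  # local import to avoid a cycle

    assert isinstance(config, PipelineConfig)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    log.info("stage synthgen: generating cohort (seed=%d)", config.cohort.seed)
    sessions, truth = generate_cohort(config.cohort)
    spec = config.bandpass_spec()
    log.info("stage features: conditioning + ALFF + FC for %d sessions", len(sessions))
    feats = extract_features(sessions, truth.region_labels, spec)

    def save_tsv(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(name)

    save_tsv("alff_features.tsv",
             pd.DataFrame(feats.alff).assign(subject=feats.subject_ids)
             .set_index("subject").reset_index())
    save_tsv("fc_features.tsv",
             pd.DataFrame(feats.fc).assign(subject=feats.subject_ids)
             .set_index("subject").reset_index())

    summary: dict = {"n_subjects": int(feats.labels.size),
                     "n_fc_features": int(feats.fc.shape[1])}
    mvpa_kw = config.mvpa_params()

    log.info("stage mvpa: LOOCV classification (%s)", ", ".join(config.modalities))
    summary["classification"] = {}
    for modality in config.modalities:
        res = feats.classifier(modality=modality, seed=config.seed, **mvpa_kw).fit()
        log.info("  %-6s accuracy %.2f%%", modality, 100 * res.accuracy)
        summary["classification"][modality] = {
            "accuracy": res.accuracy, "sensitivity": res.sensitivity,
            "specificity": res.specificity}
        folds = [{"held_out": f.held_out_id,
                  "selected_alff": f.selected_alff.tolist(),
                  "selected_fc": f.selected_fc.tolist()}
                 for f in res.fold_results]
        with open(outdir / f"selection_{modality}.json", "w") as fh:
            json.dump({"params": mvpa_kw, "seed": config.seed, "folds": folds}, fh)
        written.append(f"selection_{modality}.json")

    summary["prediction"] = {}
    for score in config.scores:
        log.info("stage mvpa: LOOCV %s prediction", score.upper())
        pres = feats.predictor(score, seed=config.seed, C=config.svr_c,
                               epsilon=config.epsilon, **mvpa_kw).fit()
        save_tsv(f"predictions_{score}.tsv", pres.predictions)
        summary["prediction"][score] = {
            "r_t1": pres.r_t1, "mse_t1": pres.mse_t1,
            "r_t2": pres.r_t2, "mse_t2": pres.mse_t2,
            "r_change": pres.r_change, "mse_change": pres.mse_change}

    if config.n_perm > 0:
        log.info("stage permtest: %d permutations of classification", config.n_perm)
        null = permutation_test(
            feats.classifier(modality="hybrid", seed=config.seed, **mvpa_kw),
            n_perm=config.n_perm, seed=config.seed)
        pd.DataFrame({"null_accuracy": null.null_values}).to_csv(
            outdir / "null_accuracy.tsv", sep="\t", index=False)
        written.append("null_accuracy.tsv")
        summary["permutation"] = {"observed_accuracy": null.observed,
                                  "p_value": null.p_value,
                                  "n_perm": config.n_perm}

    cfg_dict = config.to_dict()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    written.append("summary.json")
    manifest = {"package_version": __version__, "config": cfg_dict,
                "config_hash": _config_hash(cfg_dict), "outputs": sorted(written)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
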