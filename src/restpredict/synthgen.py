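"""Synthetic longitudinal resting-state cohorts.

The generator emits cohorts with the statistical structure the downstream
analysis assumes, so every stage is testable without scanner data:

* per-subject BOLD-like voxel series — band-limited oscillation (sum of
  random-phase sinusoids inside the analysis band, variance-normalised so
  amplitude is controlled exactly), a region-shared latent inducing baseline
  inter-regional correlation, a linear drift, and white noise;
* a planted sparse signal: on *informative voxels* the oscillation amplitude
  is shifted by ``alff_effect`` times a subject-level severity variable, and
  on *informative edges* the loading of an edge-specific shared series is
  shifted by ``fc_effect`` times the same variable, so both the group
  contrast and the symptom scores are carried by a small, known feature set;
* anxiety/depression scores (SAS/SDS) constructed as a linear function of
  the planted feature values plus Gaussian noise, with moments matched to
  the study population (Time-1 SAS 48.4 +/- 11.4, SDS 46.8 +/- 10.8; Time-2
  means lower: 34.1 and 37.7);
* a Time-2 session for a follow-up subset of survivors, whose severity
  variable drifts so that feature change and score change stay coupled;
* six motion series (smoothed random walks) and global/CSF/WM series (noisy
  mixtures of the latent signals) as nuisance regressors.

The severity variable is ``m = 1{survivor} + 0.5 z`` with ``z ~ N(0, 1)``
for survivors and ``m = 0`` for controls, so the same planted features carry
both the classification and the prediction signal.

Geometry is deliberately absent: voxels are flat indices with a separate
region-label vector, because every in-scope computation consumes indices,
not coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .connectivity import upper_triangle_index_pairs

# population score moments the generator matches (mean, sd) per timepoint
SCORE_MOMENTS = {
    "sas": {1: (48.4, 11.4), 2: (34.1, 10.2)},
    "sds": {1: (46.8, 10.8), 2: (37.7, 9.7)},
}

_N_SINUSOIDS = 12
_SEVERITY_COUPLING = 0.5  # dm/dz for survivors
_REGION_SHARE = 0.5  # variance fraction of a voxel tied to its region latent
_BASE_REGION_CORR = 0.2  # loading^2 of the cohort-wide latent in each region
_FC_BASE_LOADING = 0.3  # informative-edge shared loading at m = 0
_DRIFT_SD = 0.5  # sd of the total linear drift over the run
_T2_DRIFT_MEAN = -1.0  # mean severity change z2 - z1 (symptoms abate)
_T2_DRIFT_SD = 0.6


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters (defaults are the study conditions)."""

    n_survivors: int = 44
    n_controls: int = 44
    n_followup: int = 22
    n_voxels: int = 2000
    n_regions: int = 116
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    signal_band_hz: tuple[float, float] = (0.01, 0.08)
    n_informative_voxels: int = 100
    n_informative_edges: int = 30
    alff_effect: float = 0.8
    fc_effect: float = 0.6
    noise_sd: float = 1.0
    score_noise_sd: float = 3.0
    score_effect: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        low, high = self.signal_band_hz
        nyq = 0.5 / self.tr_seconds
        if not (0.0 < low < high < nyq):
            raise ConfigurationError(
                f"signal band {self.signal_band_hz} must lie strictly inside (0, {nyq}) Hz"
            )
        if self.n_followup > self.n_survivors:
            raise ConfigurationError("n_followup cannot exceed n_survivors")
        if self.n_regions > self.n_voxels:
            raise ConfigurationError("n_regions cannot exceed n_voxels")
        if self.n_informative_voxels > self.n_voxels:
            raise ConfigurationError("more informative voxels than voxels")
        max_edges = self.n_regions * (self.n_regions - 1) // 2
        if self.n_informative_edges > max_edges:
            raise ConfigurationError(f"more informative edges than region pairs ({max_edges})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signal_band_hz"] = list(self.signal_band_hz)
        return d

    @staticmethod
    def from_dict(d: dict) -> "CohortConfig":
        d = dict(d)
        d["signal_band_hz"] = tuple(d["signal_band_hz"])
        return CohortConfig(**d)


@dataclass
class SubjectSession:
    """One subject's data at one timepoint."""

    subject_id: str
    timepoint: int
    group: str  # "survivor" | "control"
    voxel_ts: np.ndarray  # (T, V)
    nuisance_ts: np.ndarray  # (T, 9): 6 motion + global + CSF + WM
    sas: float | None = None
    sds: float | None = None


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping for recovery testing."""

    informative_voxel_ids: np.ndarray
    informative_edge_ids: np.ndarray  # flat upper-triangle indices
    true_score_weights: dict  # score name -> {feature id -> coefficient}
    region_labels: np.ndarray
    feature_ids: list  # order of planted features ("alff:<v>", "fc:<e>")
    planted_feature_values: dict = field(default_factory=dict)  # (subject, tp) -> vector


def assign_parcellation(n_voxels: int, n_regions: int, seed: int = 0) -> np.ndarray:
    """Random voxel-to-region labels 1..n_regions with every region non-empty."""
    if n_regions > n_voxels:
        raise ConfigurationError(f"{n_regions} regions cannot cover {n_voxels} voxels")
    rng = np.random.default_rng(seed)
    labels = np.empty(n_voxels, dtype=int)
    order = rng.permutation(n_voxels)
    labels[order[:n_regions]] = np.arange(1, n_regions + 1)
    labels[order[n_regions:]] = rng.integers(1, n_regions + 1, size=n_voxels - n_regions)
    return labels


def _band_signal(rng: np.random.Generator, n_t: int, tr: float, band, n_series: int) -> np.ndarray:
    """(T, n_series) unit-variance sums of random-phase in-band sinusoids."""
    t = np.arange(n_t)[:, None] * tr
    freqs = rng.uniform(band[0], band[1], size=(_N_SINUSOIDS, n_series))
    phases = rng.uniform(0, 2 * np.pi, size=(_N_SINUSOIDS, n_series))
    sig = np.zeros((n_t, n_series))
    for j in range(_N_SINUSOIDS):
        sig += np.sin(2 * np.pi * t * freqs[j] + phases[j])
    sd = sig.std(axis=0)
    sd[sd == 0] = 1.0
    return sig / sd


def _planted_values(cfg: CohortConfig, voxel_gain, edge_gain, m: float):
    """Planted feature values (amplitudes then edge loadings) at severity m."""
    amp = 1.0 + cfg.alff_effect * voxel_gain * m
    lam = _FC_BASE_LOADING + cfg.fc_effect * edge_gain * m
    return np.clip(amp, 0.05, None), np.clip(lam, 0.0, None)


def _simulate_session(rng, cfg: CohortConfig, labels, info_vox, edge_pairs,
                      voxel_gain, edge_gain, m: float):
    """One session's voxel and nuisance matrices; returns planted values too."""
    n_t, n_v, n_r = cfg.n_timepoints, cfg.n_voxels, cfg.n_regions
    tr, band = cfg.tr_seconds, cfg.signal_band_hz

    cohort_latent = _band_signal(rng, n_t, tr, band, 1)[:, 0]
    region_own = _band_signal(rng, n_t, tr, band, n_r)
    region_latent = (
        np.sqrt(1 - _BASE_REGION_CORR) * region_own
        + np.sqrt(_BASE_REGION_CORR) * cohort_latent[:, None]
    )
    amp, lam = _planted_values(cfg, voxel_gain, edge_gain, m)
    edge_shared = _band_signal(rng, n_t, tr, band, len(edge_pairs))
    for e, (a, b) in enumerate(edge_pairs):
        region_latent[:, a] += lam[e] * edge_shared[:, e]
        region_latent[:, b] += lam[e] * edge_shared[:, e]

    private = _band_signal(rng, n_t, tr, band, n_v)
    amplitudes = np.ones(n_v)
    amplitudes[info_vox] = amp
    voxel_ts = amplitudes * (
        np.sqrt(1 - _REGION_SHARE) * private
        + np.sqrt(_REGION_SHARE) * region_latent[:, labels - 1]
    )
    ramp = (np.arange(n_t) / max(n_t - 1, 1))[:, None]
    voxel_ts += ramp * rng.normal(0.0, _DRIFT_SD, size=n_v)
    voxel_ts += rng.normal(0.0, cfg.noise_sd, size=(n_t, n_v))

    # nuisance: 6 smoothed random-walk motion series, then global/CSF/WM
    steps = rng.normal(0.0, 0.02, size=(n_t, 6))
    motion = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    for c in range(6):
        motion[:, c] = np.convolve(motion[:, c], kernel, mode="same")
    global_sig = voxel_ts.mean(axis=1) + rng.normal(0.0, 0.1, size=n_t)
    csf = 0.7 * cohort_latent + rng.normal(0.0, 0.3, size=n_t)
    wm = 0.5 * cohort_latent + 0.5 * region_latent.mean(axis=1) + rng.normal(0.0, 0.3, size=n_t)
    nuisance = np.column_stack([motion, global_sig, csf, wm])
    return voxel_ts, nuisance, np.concatenate([amp, lam])


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectSession], GroundTruth]:
    """Generate a full longitudinal cohort plus its ground truth.

    Returns all Time-1 sessions (survivors then controls) followed by the
    Time-2 sessions of the follow-up survivors.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    labels = assign_parcellation(cfg.n_voxels, cfg.n_regions, seed=cfg.seed)
    info_vox = np.sort(rng.choice(cfg.n_voxels, size=cfg.n_informative_voxels, replace=False))
    n_pairs = cfg.n_regions * (cfg.n_regions - 1) // 2
    info_edges = np.sort(rng.choice(n_pairs, size=cfg.n_informative_edges, replace=False))
    edge_pairs = upper_triangle_index_pairs(cfg.n_regions)[info_edges]

    voxel_gain = rng.uniform(0.8, 1.2, size=cfg.n_informative_voxels)
    edge_gain = rng.uniform(0.8, 1.2, size=cfg.n_informative_edges)
    feature_ids = [f"alff:{v}" for v in info_vox] + [f"fc:{e}" for e in info_edges]

    # linear score model: weights scaled so sd over survivors matches the
    # Time-1 population sd (f is linear in m, and sd(m) = coupling for z~N(0,1))
    dfdm = np.concatenate([cfg.alff_effect * voxel_gain, cfg.fc_effect * edge_gain])
    weights, intercepts, t2_shift = {}, {}, {}
    f_at_m1 = np.concatenate(_planted_values(cfg, voxel_gain, edge_gain, 1.0))
    for name in ("sas", "sds"):
        raw = rng.uniform(0.5, 1.5, size=len(feature_ids))
        slope = _SEVERITY_COUPLING * float(raw @ dfdm)
        mean1, sd1 = SCORE_MOMENTS[name][1]
        mean2, _ = SCORE_MOMENTS[name][2]
        w = cfg.score_effect * raw * (sd1 / slope if slope > 0 else 1.0)
        weights[name] = w
        intercepts[name] = mean1 - float(w @ f_at_m1)
        feature_drop = float(w @ dfdm) * _SEVERITY_COUPLING * _T2_DRIFT_MEAN
        t2_shift[name] = (mean2 - mean1) - feature_drop

    survivors = [f"surv-{i + 1:03d}" for i in range(cfg.n_survivors)]
    controls = [f"ctrl-{i + 1:03d}" for i in range(cfg.n_controls)]
    followup = set(survivors[: cfg.n_followup])
    z1 = rng.normal(0.0, 1.0, size=cfg.n_survivors)
    z2 = z1 + rng.normal(_T2_DRIFT_MEAN, _T2_DRIFT_SD, size=cfg.n_survivors)

    truth = GroundTruth(
        informative_voxel_ids=info_vox,
        informative_edge_ids=info_edges,
        true_score_weights={n: dict(zip(feature_ids, map(float, weights[n]))) for n in weights},
        region_labels=labels,
        feature_ids=feature_ids,
    )

    def scores(f: np.ndarray, timepoint: int) -> dict:
        out = {}
        for name in ("sas", "sds"):
            base = intercepts[name] + float(weights[name] @ f)
            if timepoint == 2:
                base += t2_shift[name]
            out[name] = base + rng.normal(0.0, cfg.score_noise_sd)
        return out

    sessions: list[SubjectSession] = []
    t2_sessions: list[SubjectSession] = []
    for i, sid in enumerate(survivors):
        m1 = 1.0 + _SEVERITY_COUPLING * z1[i]
        ts, nuis, f1 = _simulate_session(rng, cfg, labels, info_vox, edge_pairs,
                                         voxel_gain, edge_gain, m1)
        truth.planted_feature_values[(sid, 1)] = f1
        s1 = scores(f1, 1)
        sessions.append(SubjectSession(sid, 1, "survivor", ts, nuis, s1["sas"], s1["sds"]))
        if sid in followup:
            m2 = 1.0 + _SEVERITY_COUPLING * z2[i]
            ts2, nuis2, f2 = _simulate_session(rng, cfg, labels, info_vox, edge_pairs,
                                               voxel_gain, edge_gain, m2)
            truth.planted_feature_values[(sid, 2)] = f2
            s2 = scores(f2, 2)
            t2_sessions.append(
                SubjectSession(sid, 2, "survivor", ts2, nuis2, s2["sas"], s2["sds"])
            )
    for sid in controls:
        ts, nuis, _ = _simulate_session(rng, cfg, labels, info_vox, edge_pairs,
                                        voxel_gain, edge_gain, 0.0)
        sessions.append(SubjectSession(sid, 1, "control", ts, nuis))
    return sessions + t2_sessions, truth


def high_snr_reduced_config(seed: int = 0, **overrides) -> CohortConfig:
    """Reduced-scale, high signal-to-noise study conditions.

    20 + 20 subjects, 2000 voxels, 30 regions, strong planted effects and low
    noise — the regime where the full pipeline should detect the planted
    signal almost perfectly.
    """
    params = dict(
        n_survivors=20, n_controls=20, n_followup=10,
        n_voxels=2000, n_regions=30,
        n_informative_voxels=60, n_informative_edges=12,
        alff_effect=1.5, fc_effect=1.0, noise_sd=0.3, score_noise_sd=0.0,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


def null_tiny_config(seed: int = 0, **overrides) -> CohortConfig:
    """Tiny no-signal cohort for permutation-calibration studies."""
    params = dict(
        n_survivors=5, n_controls=5, n_followup=0,
        n_voxels=40, n_regions=6, n_timepoints=60,
        n_informative_voxels=4, n_informative_edges=2,
        alff_effect=0.0, fc_effect=0.0, score_effect=0.0,
        noise_sd=1.0, score_noise_sd=5.0,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)
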