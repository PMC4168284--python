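import numpy as np
import pytest
import scipy.stats

from restpredict.alff import compute_alff, normalize_global
from restpredict.synthgen import (
    CohortConfig,
    ConfigurationError,
    assign_parcellation,
    generate_cohort,
)

from conftest import tiny_signal_config


def micro_config(seed=0, **overrides):
    params = dict(
        n_survivors=5, n_controls=5, n_followup=2,
        n_voxels=30, n_regions=5, n_timepoints=60,
        n_informative_voxels=6, n_informative_edges=2,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


class TestParcellation:
    def test_116_regions_all_non_empty(self):
        labels = assign_parcellation(2000, 116, seed=0)
        counts = np.bincount(labels, minlength=117)[1:]
        assert counts.min() >= 1 and len(counts) == 116

    def test_single_region(self):
        assert np.all(assign_parcellation(10, 1, seed=0) == 1)

    def test_equal_counts_is_permutation(self):
        labels = assign_parcellation(10, 10, seed=3)
        assert sorted(labels.tolist()) == list(range(1, 11))

    def test_more_regions_than_voxels_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_parcellation(5, 6)


class TestGenerateCohort:
    def test_fixed_seed_reproducible(self):
        a, ta = generate_cohort(micro_config(seed=1))
        b, tb = generate_cohort(micro_config(seed=1))
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            assert np.array_equal(sa.voxel_ts, sb.voxel_ts)
            assert np.array_equal(sa.nuisance_ts, sb.nuisance_ts)
            assert sa.sas == sb.sas
        assert np.array_equal(ta.informative_voxel_ids, tb.informative_voxel_ids)

    def test_default_sample_sizes_give_88_time1_sessions(self):
        cfg = CohortConfig(n_voxels=60, n_regions=8, n_timepoints=60,
                           n_informative_voxels=5, n_informative_edges=2)
        sessions, _ = generate_cohort(cfg)
        t1 = [s for s in sessions if s.timepoint == 1]
        t2 = [s for s in sessions if s.timepoint == 2]
        assert len(t1) == 88
        assert len(t2) == 22

    def test_followup_sessions_share_subject_ids(self):
        sessions, _ = generate_cohort(micro_config())
        t1_ids = {s.subject_id for s in sessions if s.timepoint == 1}
        for s in sessions:
            if s.timepoint == 2:
                assert s.subject_id in t1_ids
                assert s.group == "survivor"

    def test_controls_have_no_scores_and_one_session(self):
        sessions, _ = generate_cohort(micro_config())
        ctrl = [s for s in sessions if s.group == "control"]
        assert all(s.sas is None and s.sds is None for s in ctrl)
        assert len({s.subject_id for s in ctrl}) == len(ctrl)

    def test_no_missing_values(self):
        sessions, _ = generate_cohort(micro_config())
        for s in sessions:
            assert np.isfinite(s.voxel_ts).all()
            assert np.isfinite(s.nuisance_ts).all()

    def test_invalid_band_rejected(self):
        with pytest.raises(ConfigurationError, match="band"):
            generate_cohort(micro_config(signal_band_hz=(0.08, 0.01)))
        with pytest.raises(ConfigurationError, match="band"):
            generate_cohort(micro_config(signal_band_hz=(0.01, 0.3)))

    def test_time2_scores_lower_on_average(self):
        cfg = micro_config(n_survivors=20, n_followup=20, score_noise_sd=1.0)
        sessions, _ = generate_cohort(cfg)
        sas1 = np.mean([s.sas for s in sessions if s.timepoint == 1 and s.group == "survivor"])
        sas2 = np.mean([s.sas for s in sessions if s.timepoint == 2])
        assert sas2 < sas1


def _mean_alff_contrast(cfg):
    """Group contrast of mean normalised ALFF over informative voxels."""
    sessions, truth = generate_cohort(cfg)
    iv = truth.informative_voxel_ids
    by_group = {"survivor": [], "control": []}
    for s in sessions:
        if s.timepoint != 1:
            continue
        vals = normalize_global(
            compute_alff(s.voxel_ts, cfg.signal_band_hz, cfg.tr_seconds)).values
        by_group[s.group].append(vals[iv].mean())
    return np.mean(by_group["survivor"]) - np.mean(by_group["control"])


def test_effect_monotonicity():
    """Mean informative-voxel ALFF contrast grows with alff_effect."""
    contrasts = []
    for effect in (0.0, 0.75, 1.5):
        per_seed = [
            _mean_alff_contrast(micro_config(seed=s, alff_effect=effect, fc_effect=0.0))
            for s in range(20)
        ]
        contrasts.append(np.mean(per_seed))
    assert contrasts[0] < contrasts[1] < contrasts[2]


def test_null_cohort_informative_voxels_indistinguishable():
    """With all effects zero the 'informative' voxels carry no group signal:
    two-sample t-test p-values over seeds are consistent with uniformity."""
    pvals = []
    for seed in range(40):
        cfg = micro_config(seed=seed, alff_effect=0.0, fc_effect=0.0, score_effect=0.0)
        sessions, truth = generate_cohort(cfg)
        iv = truth.informative_voxel_ids
        surv, ctrl = [], []
        for s in sessions:
            if s.timepoint != 1:
                continue
            vals = compute_alff(s.voxel_ts, cfg.signal_band_hz, cfg.tr_seconds).values
            (surv if s.group == "survivor" else ctrl).append(vals[iv].mean())
        pvals.append(scipy.stats.ttest_ind(surv, ctrl).pvalue)
    assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01
    assert 0.25 < np.mean(pvals) < 0.75


def test_scores_exact_linear_in_planted_features_when_noiseless():
    cfg = micro_config(n_survivors=20, n_controls=2, n_followup=0,
                       n_informative_voxels=3, n_informative_edges=2,
                       score_noise_sd=0.0)
    sessions, truth = generate_cohort(cfg)
    surv = [s for s in sessions if s.group == "survivor" and s.timepoint == 1]
    F = np.array([truth.planted_feature_values[(s.subject_id, 1)] for s in surv])
    sas = np.array([s.sas for s in surv])
    design = np.column_stack([np.ones(len(surv)), F])
    resid = sas - design @ np.linalg.lstsq(design, sas, rcond=None)[0]
    assert np.abs(resid).max() < 1e-8


def test_config_invariant_violations_rejected():
    with pytest.raises(ConfigurationError):
        micro_config(n_followup=6).validate()
    with pytest.raises(ConfigurationError):
        micro_config(n_informative_voxels=31).validate()
    with pytest.raises(ConfigurationError):
        micro_config(n_informative_edges=11).validate()  # 5 regions -> 10 pairs


def test_tiny_signal_fixture_has_expected_shape(tiny_signal_features):
    feats, truth, cfg = tiny_signal_features
    assert feats.alff.shape == (12, 60)
    assert feats.fc.shape == (12, 8 * 7 // 2)
    assert feats.t2_index.size == 3
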