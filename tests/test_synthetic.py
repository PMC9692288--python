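import dataclasses

import numpy as np
import pytest

from gaitnirs import (
    CohortSpec,
    GroundTruth,
    build_design,
    generate_beta_cohort,
    generate_cohort,
    generate_recording,
    recording_to_hemoglobin,
)


def quiet_truth(montage, **kw):
    """All oscillators, artifacts and noise off unless overridden."""
    base = dict(
        beta_hbo=np.zeros((1, montage.n_long)),
        superficial_gain=np.zeros(montage.n_long),
        noise_sd=0.0,
        cardiac_amp=0.0,
        mayer_amp=0.0,
        resp_amp=0.0,
        drift_amp=0.0,
        spike_rate=0.0,
        shift_rate=0.0,
    )
    base.update(kw)
    return GroundTruth(**base)


class TestGenerateRecording:
    def test_default_montage_yields_38_channel_series(self, montage, short_paradigm):
        truth = GroundTruth.default(montage, seed=0)
        rec = generate_recording(montage, short_paradigm, truth, fs=10.0, seed=0)
        assert rec.intensity.shape == (short_paradigm.n_samples(10.0), 38, 2)

    def test_zero_signal_gives_constant_intensity(self, montage, short_paradigm):
        truth = quiet_truth(montage)
        rec = generate_recording(montage, short_paradigm, truth, fs=10.0, seed=1)
        assert np.allclose(rec.intensity, rec.intensity[0], atol=1e-12)

    def test_same_seed_is_bit_identical(self, montage, short_paradigm):
        truth = GroundTruth.default(montage, seed=5)
        a = generate_recording(montage, short_paradigm, truth, fs=10.0, seed=7)
        b = generate_recording(montage, short_paradigm, truth, fs=10.0, seed=7)
        assert np.array_equal(a.intensity, b.intensity)

    def test_dimension_mismatch_names_channel_axis(self, montage, short_paradigm):
        truth = GroundTruth(beta_hbo=np.zeros((1, 5)), superficial_gain=np.zeros(5))
        with pytest.raises(ValueError, match="channel axis"):
            generate_recording(montage, short_paradigm, truth, fs=10.0, seed=0)

    def test_sampling_must_resolve_fastest_oscillator(self, montage, short_paradigm):
        truth = GroundTruth.default(montage, seed=0)
        with pytest.raises(ValueError, match="fs"):
            generate_recording(montage, short_paradigm, truth, fs=2.0, seed=0)

    def test_mbll_inversion_recovers_constructed_concentrations(
        self, montage, short_paradigm
    ):
        # noise-free, artifact-free signal: optics chain must return the
        # constructed series exactly (up to the baseline constant)
        beta = np.linspace(0.5, 1.5, montage.n_long)[None, :]
        truth = quiet_truth(montage, beta_hbo=beta)
        rec = generate_recording(montage, short_paradigm, truth, fs=10.0, seed=2)
        hemo = recording_to_hemoglobin(rec, age=truth.age)
        task = build_design(short_paradigm, 10.0, hemo.time.size, drift_order=0).X[:, 0]
        for c in range(montage.n_long):
            expect = beta[0, c] * task
            got = hemo.hbo[:, c]
            assert np.allclose(got - got.mean(), expect - expect.mean(), atol=1e-8)

    def test_short_channels_carry_no_task_locked_power(self, montage, short_paradigm):
        truth = GroundTruth.default(montage, seed=3)
        rec = generate_recording(montage, short_paradigm, truth, fs=10.0, seed=3)
        hemo = recording_to_hemoglobin(rec, age=truth.age)
        task = build_design(short_paradigm, 10.0, hemo.time.size, drift_order=0).X[:, 0]
        for k in range(hemo.n_short):
            r = np.corrcoef(task, hemo.short_hbo[:, k])[0, 1]
            assert abs(r) < 0.1


class TestGenerateCohort:
    def test_eight_subjects_three_sessions(self, montage, short_paradigm):
        spec = CohortSpec(n_subjects=8, seed=0)
        recs, clinical, truths = generate_cohort(spec, montage, short_paradigm, fs=5.0)
        assert len(clinical) == 8
        assert len(recs) == 24
        assert len(truths) == 8

    def test_cohort_requires_two_subjects(self):
        with pytest.raises(ValueError, match="n_subjects"):
            CohortSpec(n_subjects=1)

    def test_null_link_freezes_gmfm(self, montage, short_paradigm):
        spec = CohortSpec(
            n_subjects=4, seed=1, gmfm_link_slope=0.0, gmfm_noise_sd=0.0,
            beta_step=0.0, beta_step_sd=0.0,
        )
        _, clinical, _ = generate_cohort(spec, montage, short_paradigm, fs=5.0)
        for rec in clinical:
            assert rec.gmfm88["T2"] == pytest.approx(rec.gmfm88["T0"])

    def test_positive_link_preserves_rank_order(self, montage, short_paradigm):
        spec = CohortSpec(n_subjects=6, seed=2, gmfm_noise_sd=0.0)
        _, clinical, truths = generate_cohort(spec, montage, short_paradigm, fs=5.0)
        info = [c - 1 for c in spec.informative_channels]
        dbeta = [
            truths[r.subject].beta_hbo[-1, info].mean()
            - truths[r.subject].beta_hbo[0, info].mean()
            for r in clinical
        ]
        dgmfm = [r.gmfm88["T2"] - r.gmfm88["T0"] for r in clinical]
        assert np.array_equal(np.argsort(dbeta), np.argsort(dgmfm))

    def test_cohort_deterministic_for_fixed_seed(self, montage, short_paradigm):
        spec = CohortSpec(n_subjects=3, seed=9)
        a = generate_cohort(spec, montage, short_paradigm, fs=5.0)
        b = generate_cohort(spec, montage, short_paradigm, fs=5.0)
        assert all(
            np.array_equal(x.intensity, y.intensity) for x, y in zip(a[0], b[0])
        )
        assert [c.gmfm88 for c in a[1]] == [c.gmfm88 for c in b[1]]


class TestBetaCohort:
    def test_tidy_shape_and_determinism(self):
        spec = CohortSpec(n_subjects=5, seed=3)
        df, clinical = generate_beta_cohort(spec, n_channels=10)
        assert len(df) == 5 * 3 * 10 * 2
        assert set(df.chromophore) == {"hbo", "hhb"}
        df2, _ = generate_beta_cohort(spec, n_channels=10)
        assert df.equals(df2)

    def test_hhb_antiphase_to_hbo(self):
        spec = CohortSpec(n_subjects=6, seed=4)
        df, _ = generate_beta_cohort(spec, n_channels=8)
        wide = df.pivot_table(
            index=["subject", "session", "channel"], columns="chromophore", values="beta"
        )
        r = np.corrcoef(wide["hbo"], wide["hhb"])[0, 1]
        assert r < -0.8
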