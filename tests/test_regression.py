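import numpy as np
import pandas as pd
import pytest

from gaitnirs import (
    BetaMap,
    ClinicalRecord,
    FeatureTable,
    assemble_features,
    loso_gpr,
    wrapper_select,
)


def make_betamap(subject, session, values):
    channels = list(range(1, len(values) + 1))
    beta = np.column_stack([values, -np.asarray(values) / 3.0])
    zeros = np.zeros_like(beta)
    return BetaMap(
        channels=channels, beta=beta, se=zeros, residual_var=zeros,
        subject=subject, session=session,
    )


def cohort_maps(n_subjects, n_channels=4, seed=0):
    rng = np.random.default_rng(seed)
    maps, clinical = [], []
    for i in range(n_subjects):
        s = f"S{i + 1:02d}"
        v0 = rng.normal(0.6, 0.2, n_channels)
        v2 = v0 + rng.normal(0.3, 0.1, n_channels)
        maps += [make_betamap(s, "T0", v0), make_betamap(s, "T2", v2)]
        clinical.append(
            ClinicalRecord(subject=s, gmfcs=3, gmfm88={"T0": 20.0 + i, "T2": 30.0 + i})
        )
    return maps, clinical


def table_from(X, y, groups=None):
    n = len(y)
    if groups is None:
        groups = [f"S{i}" for i in range(n)]
    return FeatureTable(
        X=pd.DataFrame(X, columns=[f"ch{j + 1}" for j in range(X.shape[1])]),
        y=np.asarray(y, float),
        groups=np.asarray(groups),
        target_scale="a.u.",
    )


class TestAssemble:
    def test_default_layout_gives_one_row_per_subject_timepoint(self):
        maps, clinical = cohort_maps(8)
        tab = assemble_features(maps, clinical)
        assert len(tab.X) == 16
        assert tab.n_subjects == 8

    def test_feature_keys_addressable_by_channel(self):
        maps, clinical = cohort_maps(4, n_channels=20)
        tab = assemble_features(maps, clinical)
        for ch in (7, 12, 14):
            assert f"ch{ch}_hbo" in tab.X.columns
            assert f"ch{ch}_hhb" in tab.X.columns

    def test_single_subject_rejected(self):
        maps, clinical = cohort_maps(1)
        with pytest.raises(ValueError, match="subject"):
            assemble_features(maps, clinical)

    def test_missing_session_listed(self):
        maps, clinical = cohort_maps(3)
        del maps[1]  # S01 T2
        with pytest.raises(ValueError, match="S01"):
            assemble_features(maps, clinical)

    def test_alternative_layouts(self):
        maps, clinical = cohort_maps(5, n_channels=3)
        concat = assemble_features(maps, clinical, layout="concat_sessions")
        assert len(concat.X) == 5
        assert "ch1_hbo_T0" in concat.X.columns
        delta = assemble_features(maps, clinical, layout="delta")
        assert len(delta.X) == 5
        assert delta.target_scale.startswith("GMFM-88 change")
        assert np.allclose(delta.y, 10.0)


class TestWrapper:
    def test_planted_linear_feature_found_first(self):
        r = np.random.default_rng(3)
        X = r.normal(size=(12, 6))
        y = 3.0 * X[:, 2] + 0.1 * r.normal(size=12)
        sel = wrapper_select(table_from(X, y), seed=3)
        assert sel[0] == "ch3"

    def test_single_candidate_selected_iff_beats_mean_model(self):
        r = np.random.default_rng(4)
        x = r.normal(size=(10, 1))
        informative = wrapper_select(table_from(x, 2 * x[:, 0]), seed=0)
        assert informative == ["ch1"]
        pure_noise = wrapper_select(table_from(x, r.normal(size=10)), seed=0)
        assert pure_noise in ([], ["ch1"])  # may or may not beat the mean...
        # ...but a target independent of a *constant-ish* feature never selects
        sel = wrapper_select(table_from(np.tile([[1e-12]], (10, 1)), 2 * x[:, 0]), seed=0)
        assert sel == []

    def test_degenerate_target_rejected(self):
        r = np.random.default_rng(5)
        with pytest.raises(ValueError, match="zero variance"):
            wrapper_select(table_from(r.normal(size=(8, 2)), np.ones(8)), seed=0)

    def test_deterministic_given_seed(self):
        r = np.random.default_rng(6)
        X = r.normal(size=(10, 5))
        y = X[:, 1] + 0.3 * r.normal(size=10)
        tab = table_from(X, y)
        assert wrapper_select(tab, seed=9) == wrapper_select(tab, seed=9)


class TestLosoGpr:
    def test_constant_target_reports_undefined_r(self):
        r = np.random.default_rng(7)
        tab = table_from(r.normal(size=(6, 2)), np.full(6, 42.0))
        rep = loso_gpr(tab, features=["ch1"], seed=0)
        assert np.allclose(rep.predicted, 42.0)
        assert rep.rmse == 0.0
        assert rep.r is None

    def test_noiseless_linear_link_recovered(self):
        r = np.random.default_rng(8)
        X = r.normal(size=(12, 3))
        y = 2.0 * X[:, 0]
        rep = loso_gpr(table_from(X, y), features=["ch1"], seed=1)
        assert rep.r > 0.95

    def test_predictions_blind_to_held_out_target(self):
        # leakage check: perturbing one subject's target must not move
        # that subject's own prediction (per-fold selection, own fold only)
        r = np.random.default_rng(9)
        X = r.normal(size=(8, 3))
        y = 1.5 * X[:, 0] + 0.2 * r.normal(size=8)
        tab = table_from(X, y)
        rep = loso_gpr(tab, features=["ch1"], seed=2)
        y2 = y.copy()
        y2[3] += 100.0
        rep2 = loso_gpr(table_from(X, y2), features=["ch1"], seed=2)
        assert rep2.predicted[3] == pytest.approx(rep.predicted[3], rel=1e-9)

    def test_deterministic_given_seed(self):
        r = np.random.default_rng(10)
        X = r.normal(size=(9, 4))
        y = X[:, 0] + 0.1 * r.normal(size=9)
        tab = table_from(X, y)
        a = loso_gpr(tab, seed=5, select_per_fold=True, max_features=2)
        b = loso_gpr(tab, seed=5, select_per_fold=True, max_features=2)
        assert a.selected_features == b.selected_features
        assert np.array_equal(a.predicted, b.predicted)

    def test_groups_held_out_jointly(self):
        # two rows per subject: both must be absent from their training fold
        r = np.random.default_rng(11)
        X = r.normal(size=(12, 2))
        y = X[:, 0]
        groups = np.repeat([f"S{i}" for i in range(6)], 2)
        tab = table_from(X, y, groups=groups)
        rep = loso_gpr(tab, features=["ch1"], seed=3)
        y2 = y.copy()
        y2[1] += 50.0  # second row of S0
        rep2 = loso_gpr(table_from(X, y2, groups=groups), features=["ch1"], seed=3)
        assert rep2.predicted[0] == pytest.approx(rep.predicted[0], rel=1e-9)

    def test_too_few_subjects_rejected(self):
        r = np.random.default_rng(12)
        tab = table_from(r.normal(size=(2, 2)), [1.0, 2.0])
        with pytest.raises(ValueError, match="3 subjects"):
            loso_gpr(tab, features=["ch1"], seed=0)


def test_end_to_end_feature_pipeline_recovers_link():
    # betas rise with session; GMFM tracks mean beta -> strong LOSO fit
    rng = np.random.default_rng(13)
    maps, clinical = [], []
    for i in range(10):
        s = f"S{i + 1:02d}"
        v0 = rng.normal(0.5, 0.05, 6)
        lift = rng.normal(0.4, 0.15)
        v2 = v0 + lift
        maps += [make_betamap(s, "T0", v0), make_betamap(s, "T2", v2)]
        g0 = 20.0
        clinical.append(
            ClinicalRecord(
                subject=s, gmfcs=3,
                gmfm88={"T0": g0, "T2": float(np.clip(g0 + 60 * lift, 0, 100))},
            )
        )
    tab = assemble_features(maps, clinical)
    rep = loso_gpr(tab, features=["ch1_hbo"], seed=4)
    assert rep.r > 0.7
    assert rep.target_scale == "GMFM-88 points (0-100)"
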