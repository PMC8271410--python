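import numpy as np
import pandas as pd
import pytest

from pbde_synergy.qsar.pls import (
    QsarDataset,
    field_fractions,
    fit_pls_loo,
    quality_report,
    r2_pred,
    split_train_test,
)
from pbde_synergy.simulate import FieldDatasetSpec, gen_field_dataset


def nipals_pls1(X, y, n_components):
    """Independent reference PLS1 (NIPALS deflation), prediction function."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    x_mean, y_mean = X.mean(0), y.mean()
    Xc, yc = X - x_mean, y - y_mean
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        p = Xc.T @ t / tt
        q = (yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - q * t
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)

    def predict(Xnew):
        return (np.asarray(Xnew, float) - x_mean) @ B + y_mean

    return predict


def loo_q2_oracle(X, y, n_components):
    """Explicit refit-per-left-out-molecule q^2 using the reference PLS."""
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        pred = nipals_pls1(X[mask], y[mask], n_components)
        press += (y[i] - pred(X[i : i + 1])[0]) ** 2
    return 1.0 - press / ((y - y.mean()) ** 2).sum()


class TestFitPlsLoo:
    def test_noiseless_single_component(self):
        ds, _ = gen_field_dataset(
            FieldDatasetSpec(n_molecules=20, n_components=1, noise_scale=0.0, x_noise=0.0),
            seed=1,
        )
        m = fit_pls_loo(ds.X.to_numpy(), ds.y.to_numpy(), max_components=3)
        assert m.n_components == 1
        assert m.q2 == pytest.approx(1.0, abs=1e-6)

    def test_planted_three_component_recovery(self):
        ds, truth = gen_field_dataset(
            FieldDatasetSpec(n_molecules=40, n_components=3, noise_scale=0.1), seed=7
        )
        m = fit_pls_loo(ds.X.to_numpy(), ds.y.to_numpy())
        assert abs(m.n_components - truth["n_components"]) <= 1
        assert m.q2 > 0.8

    def test_permuted_y_null(self):
        ds, _ = gen_field_dataset(
            FieldDatasetSpec(n_molecules=40, n_components=3, noise_scale=0.1), seed=7
        )
        yp = np.random.default_rng(0).permutation(ds.y.to_numpy())
        m = fit_pls_loo(ds.X.to_numpy(), yp)
        assert m.q2 <= 0.3

    def test_loo_matches_refit_oracle(self):
        # small training sets, every candidate component count
        for seed, n in ((0, 10), (1, 12), (2, 9)):
            ds, _ = gen_field_dataset(
                FieldDatasetSpec(
                    n_molecules=n, n_steric=8, n_electro=8, n_components=2,
                    noise_scale=0.2,
                ),
                seed=seed,
            )
            X, y = ds.X.to_numpy(), ds.y.to_numpy()
            m = fit_pls_loo(X, y, max_components=3)
            for a, q2 in m.q2_by_ncomp.items():
                assert q2 == pytest.approx(loo_q2_oracle(X, y, a), abs=1e-8)

    def test_constant_y_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="constant"):
            fit_pls_loo(X, np.ones(10))

    def test_too_small_train_rejected(self):
        X = np.zeros((4, 3))
        with pytest.raises(ValueError, match="at least 5"):
            fit_pls_loo(X, np.arange(4.0))

    def test_max_components_cap(self):
        ds, _ = gen_field_dataset(FieldDatasetSpec(n_molecules=12), seed=0)
        with pytest.raises(ValueError, match="max_components"):
            fit_pls_loo(ds.X.to_numpy(), ds.y.to_numpy(), max_components=20)

    def test_statistics_consistency(self):
        ds, _ = gen_field_dataset(FieldDatasetSpec(n_molecules=30), seed=2)
        m = fit_pls_loo(ds.X.to_numpy(), ds.y.to_numpy())
        y = ds.y.to_numpy()
        resid = y - m.predict(ds.X.to_numpy())
        rss = (resid**2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert m.r2 == pytest.approx(1 - rss / ss_tot, abs=1e-10)
        dof = len(y) - m.n_components - 1
        assert m.see == pytest.approx(np.sqrt(rss / dof), abs=1e-10)


class TestR2Pred:
    def test_perfect_predictions(self):
        assert r2_pred([2.0, 4.0], [2.0, 4.0], 3.0) == pytest.approx(1.0)

    def test_training_mean_predictions(self):
        assert r2_pred([2.0, 4.0], [3.0, 3.0], 3.0) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert r2_pred([2.0, 4.0], [1.0, 5.0], 3.0) == pytest.approx(0.0)

    def test_degenerate_test_set_rejected(self):
        with pytest.raises(ValueError, match="training mean"):
            r2_pred([3.0, 3.0], [1.0, 2.0], 3.0)

    def test_empty_test_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            r2_pred([], [], 3.0)


class TestQualityReport:
    def test_good_model_passes(self):
        rep = quality_report(q2=0.910, r2=0.988)
        assert rep["reliable"] and rep["no_overfit"]
        assert rep["overfit_pct"] == pytest.approx(7.89, abs=0.005)

    def test_low_q2_fails_reliability(self):
        assert not quality_report(q2=0.4, r2=0.9)["reliable"]

    def test_overfit_detected(self):
        rep = quality_report(q2=0.356, r2=1.000)
        assert rep["overfit_pct"] == pytest.approx(64.4, abs=0.05)
        assert not rep["no_overfit"]

    def test_external_threshold(self):
        assert quality_report(0.9, 0.95, r2pred=0.998)["external_ok"]
        assert not quality_report(0.9, 0.95, r2pred=0.5)["external_ok"]


class TestFieldFractions:
    def test_zeroed_electrostatic_block(self):
        ds, _ = gen_field_dataset(
            FieldDatasetSpec(n_molecules=30, n_components=2, mass_split=(1.0, 0.0)),
            seed=3,
        )
        X = ds.X.to_numpy().copy()
        elec = (ds.columns["field"] == "electrostatic").to_numpy()
        X[:, elec] = 0.0
        m = fit_pls_loo(X, ds.y.to_numpy(), columns=ds.columns)
        frac = field_fractions(m, X)
        assert frac["steric"] == pytest.approx(100.0)
        assert frac["electrostatic"] == pytest.approx(0.0)

    def test_symmetric_duplicate_blocks(self):
        rng = np.random.default_rng(6)
        half = rng.normal(size=(25, 10))
        X = np.hstack([half, half])  # identical steric/electrostatic blocks
        y = half @ rng.normal(size=10)
        cols = pd.DataFrame({"field": ["steric"] * 10 + ["electrostatic"] * 10})
        m = fit_pls_loo(X, y, max_components=5, columns=cols)
        frac = field_fractions(m, X)
        assert frac["steric"] == pytest.approx(50.0, abs=1e-6)

    def test_planted_one_to_three_split(self):
        ds, _ = gen_field_dataset(
            FieldDatasetSpec(
                n_molecules=80, n_components=4, mass_split=(1.0, 3.0),
                noise_scale=0.02, x_noise=0.02,
            ),
            seed=5,
        )
        m = fit_pls_loo(ds.X.to_numpy(), ds.y.to_numpy(), columns=ds.columns)
        frac = field_fractions(m, ds.X.to_numpy())
        assert frac["steric"] == pytest.approx(25.0, abs=5.0)
        assert frac["electrostatic"] == pytest.approx(75.0, abs=5.0)

    def test_fractions_sum_exactly_100(self):
        ds, _ = gen_field_dataset(FieldDatasetSpec(n_molecules=25), seed=9)
        m = fit_pls_loo(ds.X.to_numpy(), ds.y.to_numpy(), columns=ds.columns)
        frac = field_fractions(m, ds.X.to_numpy())
        assert frac["steric"] + frac["electrostatic"] == 100.0


class TestSplit:
    def test_40_molecules_split_30_10(self):
        y = pd.Series(np.random.default_rng(0).normal(size=40))
        train = split_train_test(y, seed=1)
        assert train.sum() == 30

    def test_deterministic(self):
        y = pd.Series(np.random.default_rng(0).normal(size=40))
        assert (split_train_test(y, seed=5) == split_train_test(y, seed=5)).all()

    def test_177_molecules_about_3_to_1(self, table1):
        from pbde_synergy.queuing import composite_scores

        cs = composite_scores(table1).cs
        train = split_train_test(cs, seed=0)
        assert abs((~train).sum() - 44) <= 1

    def test_stratified_spans_activity_range(self):
        y = pd.Series(np.arange(40.0))
        train = split_train_test(y, seed=2)
        test_vals = y[~train]
        # at least one test molecule per activity quartile
        for lo, hi in ((0, 10), (10, 20), (20, 30), (30, 40)):
            assert ((test_vals >= lo) & (test_vals < hi)).any()

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(pd.Series(np.arange(5.0)))


class TestQsarDataset:
    def test_missing_entries_rejected(self):
        X = pd.DataFrame(np.ones((6, 2)))
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            QsarDataset(X, pd.Series(np.arange(6.0)), pd.DataFrame({"field": ["steric"] * 2}))

    def test_index_mismatch_rejected(self):
        X = pd.DataFrame(np.ones((4, 2)), index=list("abcd"))
        y = pd.Series(np.arange(4.0), index=list("abce"))
        with pytest.raises(ValueError, match="index"):
            QsarDataset(X, y, pd.DataFrame({"field": ["steric"] * 2}))
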