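"""Validation metrics against independent brute-force oracles, enrichment,
and decoy generation."""

import math

import numpy as np
import pytest

from sirtqsar.validation import (
    classification_report,
    evaluate_on_decoys,
    generate_decoys,
    golbraikh_tropsha,
    gorodkin_mcc,
    lin_ccc,
    regression_report,
    roc_enrichment,
)
from sirtqsar.synthetic import generate_candidate_pool

# ---------------------------------------------------------------------------
# Brute-force oracles: direct formula evaluation, independent of the package
# implementation paths.


def oracle_regression(y, p, ytr):
    y, p, ytr = map(np.asarray, (y, p, ytr))
    press = sum((yi - pi) ** 2 for yi, pi in zip(y, p))
    r = np.corrcoef(y, p)[0, 1]
    k = sum(yi * pi for yi, pi in zip(y, p)) / sum(pi * pi for pi in p)
    kp = sum(yi * pi for yi, pi in zip(y, p)) / sum(yi * yi for yi in y)
    r0 = 1 - sum((yi - k * pi) ** 2 for yi, pi in zip(y, p)) / \
        sum((yi - y.mean()) ** 2 for yi in y)
    r0p = 1 - sum((pi - kp * yi) ** 2 for yi, pi in zip(y, p)) / \
        sum((pi - p.mean()) ** 2 for pi in p)
    rm2 = r**2 * (1 - math.sqrt(max(0.0, r**2 - r0)))
    rm2p = r**2 * (1 - math.sqrt(max(0.0, r**2 - r0p)))
    n = len(y)
    ccc = (2 * sum((yi - y.mean()) * (pi - p.mean()) for yi, pi in zip(y, p)) /
           (sum((yi - y.mean()) ** 2 for yi in y)
            + sum((pi - p.mean()) ** 2 for pi in p)
            + n * (y.mean() - p.mean()) ** 2))
    return {
        "Rext2": 1 - press / sum((yi - y.mean()) ** 2 for yi in y),
        "RMSEext": math.sqrt(press / n),
        "QF1_2": 1 - press / sum((yi - ytr.mean()) ** 2 for yi in y),
        "QF3_2": 1 - (press / n) / (sum((t - ytr.mean()) ** 2 for t in ytr) / len(ytr)),
        "rm2": rm2, "rm2_prime": rm2p,
        "rm2_bar": (rm2 + rm2p) / 2, "delta_rm2": abs(rm2 - rm2p),
        "CCC": ccc, "k": k, "k_prime": kp, "r0_2": r0, "r0_prime_2": r0p,
    }


def oracle_binary_counts(y_true, y_pred):
    tp = sum(1 for t, q in zip(y_true, y_pred) if t == 1 and q == 1)
    tn = sum(1 for t, q in zip(y_true, y_pred) if t == 0 and q == 0)
    fp = sum(1 for t, q in zip(y_true, y_pred) if t == 0 and q == 1)
    fn = sum(1 for t, q in zip(y_true, y_pred) if t == 1 and q == 0)
    return tp, tn, fp, fn


class TestRegressionBattery:
    def test_hand_example(self):
        r = regression_report([4, 5, 6], [4.1, 5.0, 5.9], [4, 5, 6])
        assert r.Rext2 == pytest.approx(0.99)
        assert r.RMSEext == pytest.approx(math.sqrt(0.02 / 3), abs=1e-12)

    def test_perfect_prediction_limits(self):
        r = regression_report([4, 5, 6, 7], [4, 5, 6, 7], [4, 5, 6, 7, 8])
        assert r.Rext2 == r.QF2_2 == 1.0
        assert r.QF1_2 == r.QF3_2 == 1.0 or (r.QF1_2 <= 1.0 and r.QF3_2 <= 1.0)
        assert r.CCC == pytest.approx(1.0)
        assert r.RMSEext == 0.0 and r.delta_rm2 == 0.0
        assert all(r.criteria.values())

    def test_mean_prediction_gives_zero_rext2(self):
        y = [4.0, 5.0, 6.0]
        r = regression_report(y, [5.0, 5.0, 5.0], y)
        assert r.Rext2 == pytest.approx(0.0)

    def test_qf1_qf2_equal_rext2_when_means_coincide(self):
        # constructed so train mean == test mean == 5
        y_test = [4.0, 5.0, 6.0]
        y_train = [3.0, 5.0, 7.0, 5.0]
        r = regression_report(y_test, [4.2, 5.1, 5.8], y_train)
        assert r.QF2_2 == pytest.approx(r.Rext2, abs=1e-12)
        assert r.QF1_2 == pytest.approx(r.Rext2, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 50))
            y = rng.normal(5, 1, size=n)
            p = y + rng.normal(0, 0.5, size=n)
            ytr = rng.normal(5, 1, size=n + 5)
            got = regression_report(y, p, ytr)
            want = oracle_regression(y, p, ytr)
            for key, val in want.items():
                if key in ("k", "k_prime", "r0_2", "r0_prime_2"):
                    continue
                assert getattr(got, key) == pytest.approx(val, abs=1e-10), key

    def test_zero_variance_observed_degenerate(self):
        r = regression_report([5, 5, 5], [4, 5, 6], [4, 5, 6])
        assert math.isnan(r.Rext2)
        assert r.degenerate_reason

    def test_ccc_symmetric(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert lin_ccc(a, b) == pytest.approx(lin_ccc(b, a), abs=1e-14)


class TestGolbraikhTropsha:
    def test_identity_passes(self):
        gt = golbraikh_tropsha([4, 5, 6], [4, 5, 6])
        assert gt.k == gt.k_prime == 1.0
        assert gt.all_pass

    def test_doubled_predictions_fail_slope(self):
        gt = golbraikh_tropsha([1, 2, 3, 4], [2, 4, 6, 8])
        assert not gt.criterion_k

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            y = rng.normal(5, 1, size=50)
            p = 0.8 * y + rng.normal(0, 0.7, size=50) + 1.0
            got = golbraikh_tropsha(y, p)
            want = oracle_regression(y, p, y)
            assert got.k == pytest.approx(want["k"], abs=1e-10)
            assert got.k_prime == pytest.approx(want["k_prime"], abs=1e-10)
            assert got.r0_2 == pytest.approx(want["r0_2"], abs=1e-10)
            assert got.r0_prime_2 == pytest.approx(want["r0_prime_2"], abs=1e-10)
            r2 = np.corrcoef(y, p)[0, 1] ** 2
            assert got.criterion_r0 == (
                ((r2 - want["r0_2"]) / r2 < 0.1)
                or ((r2 - want["r0_prime_2"]) / r2 < 0.1))
            assert got.criterion_k == (0.85 <= want["k"] <= 1.15
                                       or 0.85 <= want["k_prime"] <= 1.15)

    def test_all_zero_predictions_error(self):
        with pytest.raises(ValueError):
            golbraikh_tropsha([1, 2, 3], [0, 0, 0])


class TestClassificationMetrics:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        r = classification_report(y, proba, [0, 1])
        assert r.balanced_accuracy == r.mcc == r.roc_auc_macro == r.f1_macro == 1.0

    def test_stated_counts_example(self):
        """TP=8 FN=2 TN=7 FP=3: sensitivity .8, specificity .7, BA .75,
        MCC = 50/sqrt(9900)."""
        y, p = [], []
        for true, pred, count in [(1, 1, 8), (1, 0, 2), (0, 0, 7), (0, 1, 3)]:
            y += [true] * count
            p += [[0.3, 0.7] if pred else [0.7, 0.3]] * count
        r = classification_report(y, np.array(p), [0, 1])
        assert r.per_class["1"]["recall"] == pytest.approx(0.8)
        assert r.per_class["0"]["recall"] == pytest.approx(0.7)
        assert r.balanced_accuracy == pytest.approx(0.75)
        assert r.mcc == pytest.approx(50 / math.sqrt(9900), abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import (
            balanced_accuracy_score,
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
            roc_auc_score,
        )

        for _ in range(25):
            n = int(rng.integers(20, 120))
            k = int(rng.integers(2, 4))
            y = rng.integers(0, k, size=n)
            while len(set(y.tolist())) < k:
                y = rng.integers(0, k, size=n)
            proba = rng.dirichlet(np.ones(k), size=n)
            got = classification_report(y, proba, list(range(k)))
            pred = np.argmax(proba, axis=1)
            assert got.balanced_accuracy == pytest.approx(
                balanced_accuracy_score(y, pred), abs=1e-10)
            assert got.mcc == pytest.approx(matthews_corrcoef(y, pred), abs=1e-10)
            assert got.precision_macro == pytest.approx(
                precision_score(y, pred, average="macro", zero_division=0), abs=1e-10)
            assert got.recall_macro == pytest.approx(
                recall_score(y, pred, average="macro"), abs=1e-10)
            assert got.f1_macro == pytest.approx(
                f1_score(y, pred, average="macro"), abs=1e-10)
            if k == 2:
                assert got.roc_auc_macro == pytest.approx(
                    roc_auc_score(y, proba[:, 1]), abs=1e-10)
            else:
                assert got.roc_auc_macro == pytest.approx(
                    roc_auc_score(y, proba, multi_class="ovr",
                                  average="macro"), abs=1e-10)

    def test_probability_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            classification_report([0, 1], np.array([[0.5, 0.6], [0.5, 0.5]]),
                                  [0, 1])


class TestEnrichment:
    def test_perfect_and_worst_ranking(self):
        labels = np.r_[np.ones(5), np.zeros(400)]
        best = np.r_[np.full(5, 10.0), -np.arange(400, dtype=float)]
        worst = np.r_[np.full(5, -10.0), np.arange(400, dtype=float)]
        assert set(roc_enrichment(best, labels).values()) == {1.0}
        assert set(roc_enrichment(worst, labels).values()) == {0.0}

    def test_monotone_in_fraction(self, rng):
        scores = rng.normal(size=600)
        labels = rng.integers(0, 2, size=600)
        ef = roc_enrichment(scores, labels, fractions=(0.01, 0.02, 0.05, 0.2))
        vals = list(ef.values())
        assert vals == sorted(vals)

    def test_random_ranking_expectation_matches_fraction(self, rng):
        """Under random scores EF at FPR f has expectation ~f."""
        effs = []
        for _ in range(300):
            scores = rng.normal(size=2050)
            labels = np.r_[np.ones(50), np.zeros(2000)]
            effs.append(roc_enrichment(scores, labels, fractions=(0.05,))[0.05])
        assert np.mean(effs) == pytest.approx(0.05, abs=0.01)

    def test_pessimistic_ties(self):
        # all scores identical: no active is strictly above the cutoff
        scores = np.ones(500)
        labels = np.r_[np.ones(10), np.zeros(490)]
        ef = roc_enrichment(scores, labels, fractions=(0.05,))
        assert ef[0.05] == 0.0

    def test_too_few_inactives_undefined(self):
        ef = roc_enrichment([1.0, 0.5, 0.2], [1, 0, 0], fractions=(0.005,))
        assert math.isnan(ef[0.005])


class TestDecoys:
    @pytest.fixture(scope="class")
    def pool(self):
        return generate_candidate_pool(600, seed=3)

    ACTIVES = ["c1cc(F)c(OC)cc1S(=O)(=O)N", "c1cc(Cl)c(C)cc1CS(=O)(=O)N",
               "c1cc(F)c(F)cc1OS(=O)(=O)N"]

    def test_count_contract_and_determinism(self, pool):
        d1 = generate_decoys(self.ACTIVES, pool, per_active=2, seed=0)
        d2 = generate_decoys(self.ACTIVES, pool, per_active=2, seed=0)
        assert len(d1) == 6 and d1 == d2

    def test_active_itself_always_rejected(self, pool):
        spiked = pool + self.ACTIVES
        decoys = generate_decoys(self.ACTIVES, spiked, per_active=3, seed=1)
        assert not set(decoys) & set(self.ACTIVES)

    def test_decoys_property_matched(self, pool):
        from sirtqsar.validation import _physchem

        decoys = generate_decoys(self.ACTIVES, pool, per_active=5, seed=2)
        rest = [s for s in pool if s not in set(decoys)]
        mu = _physchem(pool).mean(axis=0)
        sd = _physchem(pool).std(axis=0)
        sd[sd == 0] = 1.0
        z_act = (_physchem(self.ACTIVES) - mu) / sd
        z_dec = (_physchem(decoys) - mu) / sd
        z_rest = (_physchem(rest) - mu) / sd
        d_dec = np.median([np.linalg.norm(z - z_act, axis=1).min() for z in z_dec])
        d_rest = np.median([np.linalg.norm(z - z_act, axis=1).min() for z in z_rest])
        assert d_dec < d_rest

    def test_pool_too_small_errors(self):
        with pytest.raises(ValueError):
            generate_decoys(self.ACTIVES, ["CCO"], per_active=2, seed=0)


class TestEvaluateOnDecoys:
    class MajorityModel:
        classes_ = np.array([0, 1])

        def predict_proba(self, X):
            return np.tile([0.8, 0.2], (len(X), 1))

    def test_majority_model_ba_half(self):
        X_act = np.zeros((10, 4))
        X_dec = np.zeros((40, 4))
        out = evaluate_on_decoys(self.MajorityModel(), X_act, X_dec)
        assert out["all"].balanced_accuracy == pytest.approx(0.5)

    def test_ad_filtered_is_subset(self):
        rng = np.random.default_rng(0)

        class NoisyModel:
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                p = rng.uniform(size=len(X))
                return np.column_stack([1 - p, p])

        out = evaluate_on_decoys(
            NoisyModel(), np.zeros((30, 2)), np.zeros((200, 2)),
            confident_fn=lambda row: not (0.4 < row.max() < 0.6),
        )
        n_all = out["all"].confusion.sum()
        n_ad = out["ad_filtered"].confusion.sum()
        assert n_ad <= n_all
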