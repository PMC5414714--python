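"""Boosting ensembles: fitting, voting, determinism, and the model bank."""


import numpy as np
import pytest

import tumortyper as tt
from tumortyper.boost import _derived_seed


def reference_adaboost(X, y, n_rounds):
    """Independent discrete-AdaBoost oracle (no subsampling, lr=1).

    Scans stumps "gene amplified?" with both polarities, picking the lowest
    weighted error (ties: positive polarity before negative, then lowest gene
    index), and applies the classical weight update.  Written loop-wise,
    independent of the package's vectorized path.
    """
    n, g = X.shape
    w = [1.0 / n] * n
    rounds = []
    for _ in range(n_rounds):
        best = None
        for pol in (1, -1):
            for gi in range(g):
                err = sum(
                    wi
                    for wi, xi, yi in zip(w, X[:, gi], y)
                    if pol * (2 * xi - 1) != yi
                )
                if best is None or err < best[0] - 1e-15:
                    best = (err, gi, pol)
        err, gi, pol = best
        eps = min(max(err, 1e-10), 1 - 1e-10)
        a = 0.5 * np.log((1 - eps) / eps)
        rounds.append((gi, pol, a))
        w = [
            wi * np.exp(-a * yi * pol * (2 * xi - 1))
            for wi, xi, yi in zip(w, X[:, gi], y)
        ]
        total = sum(w)
        w = [wi / total for wi in w]
    return rounds


def ensemble_scores(rounds, X):
    return np.array(
        [sum(a * pol * (2 * x[gi] - 1) for gi, pol, a in rounds) for x in X]
    )


@pytest.fixture()
def separable():
    """One gene amplified in all of class A (+1), never in B (-1)."""
    X = np.array([[1, 0], [1, 1], [1, 0], [0, 0], [0, 1], [0, 0]], dtype=np.int8)
    y = np.array([1, 1, 1, -1, -1, -1])
    return X, y


class TestFitBoost:
    def test_separable_training_error_zero(self, separable):
        X, y = separable
        ens = tt.fit_boost(X, y, tt.BoostConfig(n_rounds=5, seed=0))
        assert (ens.predict_labels(X) == y).all()
        # the first stump alone already separates
        assert ens.gene_index[0] == 0 and ens.polarity[0] == 1

    def test_deterministic_given_seed(self, separable):
        X, y = separable
        cfg = tt.BoostConfig(n_rounds=20, subsample_fraction=0.5, seed=42)
        a = tt.fit_boost(X, y, cfg)
        b = tt.fit_boost(X, y, cfg)
        np.testing.assert_array_equal(a.gene_index, b.gene_index)
        np.testing.assert_array_equal(a.alpha, b.alpha)

    def test_label_flip_flips_every_prediction(self, separable):
        X, y = separable
        cfg = tt.BoostConfig(n_rounds=15, subsample_fraction=0.5, seed=3)
        a = tt.fit_boost(X, y, cfg)
        b = tt.fit_boost(X, -y, cfg)
        np.testing.assert_array_equal(a.predict_labels(X), -b.predict_labels(X))

    def test_single_class_rejected(self):
        X = np.array([[1], [0]], dtype=np.int8)
        with pytest.raises(ValueError, match="degenerate pair training set"):
            tt.fit_boost(X, [1, 1])

    def test_matches_independent_adaboost_oracle(self):
        """Full-sample fits equal a loop-wise discrete AdaBoost on random
        small instances (<= 20 samples x 5 genes)."""
        rng = np.random.default_rng(9)
        for trial in range(10):
            n = int(rng.integers(4, 21))
            g = int(rng.integers(1, 6))
            X = rng.integers(0, 2, (n, g)).astype(np.int8)
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if len(np.unique(y)) < 2:
                y[0] = -y[1]
            cfg = tt.BoostConfig(n_rounds=8, subsample_fraction=1.0, seed=trial)
            ens = tt.fit_boost(X, y, cfg)
            ref = reference_adaboost(X, y, 8)
            np.testing.assert_array_equal(ens.gene_index, [r[0] for r in ref])
            np.testing.assert_array_equal(ens.polarity, [r[1] for r in ref])
            np.testing.assert_allclose(
                ens.alpha, [r[2] for r in ref], rtol=1e-10, atol=1e-12
            )
            np.testing.assert_allclose(
                ens.decision_scores(X), ensemble_scores(ref, X), rtol=1e-9, atol=1e-9
            )

    def test_training_error_nonincreasing_without_subsampling(self):
        rng = np.random.default_rng(21)
        X = rng.integers(0, 2, (30, 6)).astype(np.int8)
        y = np.where(X[:, 0] + X[:, 1] + rng.random(30) * 0.8 > 1, 1, -1)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        errs = []
        for rounds in (1, 3, 6, 12, 25):
            ens = tt.fit_boost(
                X, y, tt.BoostConfig(n_rounds=rounds, subsample_fraction=1.0, seed=0)
            )
            errs.append(float((ens.predict_labels(X) != y).mean()))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))


class TestPredictVote:
    def test_signature_sample_votes_its_type(self, separable):
        X, y = separable
        ens = tt.fit_boost(
            X, y, tt.BoostConfig(n_rounds=5, seed=0),
            pair=("ALPHA", "BETA"), feature_genes=["gA", "gB"],
        )
        assert tt.predict_vote(ens, {"gA": 1, "gB": 0}) == "ALPHA"
        assert tt.predict_vote(ens, {"gA": 0, "gB": 0}) == "BETA"

    def test_missing_genes_treated_as_zero(self, separable):
        X, y = separable
        ens = tt.fit_boost(
            X, y, tt.BoostConfig(n_rounds=5, seed=0),
            pair=("ALPHA", "BETA"), feature_genes=["gA", "gB"],
        )
        assert tt.predict_vote(ens, {}) == tt.predict_vote(ens, {"gA": 0, "gB": 0})


class TestModelBank:
    @pytest.mark.parametrize(
        "n_types,n_terms,expected",
        [(2, 12, 12), (3, 2, 6), (5, 3, 30)],
    )
    def test_cardinality(self, n_types, n_terms, expected):
        ds = tt.generate(
            tt.SyntheticConfig(
                n_types=n_types, samples_per_type=8, n_genes=80,
                genes_per_signature=5, n_go_terms=n_terms, seed=4,
            )
        )
        bank = tt.build_model_bank(
            ds.calls, ds.labels, ds.annotation, boost=tt.BoostConfig(n_rounds=3, seed=4)
        )
        assert len(bank) == expected

    def test_empty_terms_marked_not_fitted(self, toy_calls_labels):
        calls, labels = toy_calls_labels
        annotation = tt.make_annotation({"GO:1": ["g1"], "GO:2": ["g5"]})
        bank = tt.build_model_bank(
            calls, labels, annotation, boost=tt.BoostConfig(n_rounds=3, seed=0)
        )
        assert bank.get("A", "B", "GO:1") is not None
        assert bank.get("A", "B", "GO:2") is None  # g5 not differential

    def test_json_round_trip_bit_exact(self, small_model, tmp_path):
        model, _, _ = small_model
        path = tmp_path / "bank.json"
        model.bank.save(path)
        back = tt.PairModelBank.load(path)
        assert back.types == model.bank.types
        assert set(back.models) == set(model.bank.models)
        for key, ens in model.bank.models.items():
            other = back.models[key]
            if ens is None:
                assert other is None
                continue
            assert other.feature_genes == ens.feature_genes
            np.testing.assert_array_equal(other.gene_index, ens.gene_index)
            np.testing.assert_array_equal(other.polarity, ens.polarity)
            assert other.alpha.tolist() == ens.alpha.tolist()  # bit-exact

    def test_derived_seeds_stable_and_distinct(self):
        s1 = _derived_seed(0, "A", "B", "GO:1")
        assert s1 == _derived_seed(0, "A", "B", "GO:1")
        assert s1 != _derived_seed(0, "A", "B", "GO:2")
        assert s1 != _derived_seed(1, "A", "B", "GO:1")
        assert 0 <= s1 < 2**31
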