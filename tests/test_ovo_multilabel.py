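"""One-vs-one multilabel decomposition, mixed machines, three-way voting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from cofsvm import (
    ClusteredFuzzyOvoClassifier,
    FuzzyTrainingSet,
    KernelSpec,
    MembershipStrategy,
    SubproblemSpec,
    aggregate,
    decompose,
    fit_mixed_subproblem,
    fsvm_decision,
    fsvm_fit,
    three_way_decision,
)


def multilabel_fixture():
    """Tiny 3-label target with single, dual and every-pair coverage."""
    Y = np.array(
        [
            [1, 0, 0],
            [1, 0, 0],
            [0, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [0, 0, 1],
            [1, 1, 0],
            [0, 1, 1],
        ]
    )
    return Y


class TestDecompose:
    @pytest.mark.parametrize("z", range(2, 11))
    def test_subproblem_count(self, z):
        rng = np.random.default_rng(z)
        Y = np.zeros((3 * z, z), dtype=int)
        Y[np.arange(3 * z), np.arange(3 * z) % z] = 1
        assert len(decompose(Y)) == z * (z - 1) // 2

    def test_six_labels_give_fifteen_subproblems(self):
        Y = np.zeros((12, 6), dtype=int)
        Y[np.arange(12), np.arange(12) % 6] = 1
        assert len(decompose(Y)) == 15

    def test_roles_and_exclusion(self):
        Y = multilabel_fixture()
        specs = {s.pair: s for s in decompose(Y)}
        s01 = specs[(0, 1)]
        # dual {0,1} sample has role 0; samples with neither label excluded
        assert 6 in s01.sample_indices
        assert s01.roles[list(s01.sample_indices).index(6)] == 0
        assert 4 not in s01.sample_indices and 5 not in s01.sample_indices
        # role partition covers all non-excluded samples
        for s in specs.values():
            has = Y[:, s.pair[0]] | Y[:, s.pair[1]]
            assert len(s.sample_indices) == int(has.sum())

    def test_lexicographic_order_and_correlation_reorder(self):
        Y = multilabel_fixture()
        pairs = [s.pair for s in decompose(Y)]
        assert pairs == [(0, 1), (0, 2), (1, 2)]
        corr = np.array([[1.0, 0.1, 0.9], [0.1, 1.0, 0.5], [0.9, 0.5, 1.0]])
        reordered = [s.pair for s in decompose(Y, correlation=corr)]
        assert reordered == [(0, 2), (1, 2), (0, 1)]

    def test_single_label_column_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.ones((4, 1), dtype=int))
        with pytest.raises(ValueError):
            decompose(np.zeros((4, 3), dtype=int))  # empty label sets


class TestThreeWayDecision:
    @pytest.mark.parametrize(
        "f,expected",
        [
            (1.5, "positive"),
            (1.0, "mixed"),
            (0.0, "mixed"),
            (-1.0, "mixed"),
            (-2.0, "negative"),
            (1.0000001, "positive"),
        ],
    )
    def test_boundaries(self, f, expected):
        assert three_way_decision(f) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(allow_nan=False, allow_infinity=False))
    def test_every_real_gets_exactly_one_outcome(self, f):
        out = three_way_decision(f)
        expected = "positive" if f > 1 else ("negative" if f < -1 else "mixed")
        assert out == expected

    def test_partitions_the_reals(self):
        rng = np.random.default_rng(0)
        f = np.concatenate([rng.normal(0, 3, 500), [-1.0, 1.0, 0.0]])
        out = three_way_decision(f)
        pos = (f > 1).sum()
        neg = (f < -1).sum()
        mix = ((f >= -1) & (f <= 1)).sum()
        assert (out == "positive").sum() == pos
        assert (out == "negative").sum() == neg
        assert (out == "mixed").sum() == mix
        assert pos + neg + mix == len(f)


class TestAggregate:
    def test_two_labels_positive(self):
        assert aggregate({(0, 1): "positive"}, 2).tolist() == [1, 0]
        assert aggregate({(0, 1): "negative"}, 2).tolist() == [0, 1]

    def test_unanimous_label_always_selected(self):
        out = {(0, 1): "positive", (0, 2): "positive", (1, 2): "mixed"}
        for theta in (0.25, 0.5, 0.75, 1.0):
            assert aggregate(out, 3, theta)[0] == 1

    def test_mixed_votes_select_both_pair_labels(self):
        out = {(0, 1): "mixed", (0, 2): "positive", (1, 2): "positive"}
        pred = aggregate(out, 3, theta=0.5)
        assert pred[0] == 1 and pred[1] == 1

    def test_nonempty_prediction_guarantee(self):
        out = {(0, 1): "mixed", (0, 2): "mixed", (1, 2): "mixed"}
        pred = aggregate(out, 3, theta=1.0)
        assert pred.sum() >= 1

    def test_incomplete_outcomes_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            aggregate({(0, 1): "positive"}, 3)


def six_point_spec():
    """Printed 6-point instance: two samples per role."""
    X = np.array(
        [
            [2.0, 0.0],
            [3.0, 1.0],
            [-2.0, 0.0],
            [-3.0, -1.0],
            [0.0, 0.5],
            [0.0, -0.5],
        ]
    )
    spec = SubproblemSpec(
        pair=(0, 1),
        sample_indices=np.arange(6),
        roles=np.array([1, 1, -1, -1, 0, 0]),
    )
    mu = np.array([1.0, 0.8, 1.0, 0.7, 0.9, 1.0])
    return X, spec, mu


def primal_oracle(X, roles, mu, penalty):
    """Dense generic solve of the mixed-class primal with slack variables,
    via SLSQP; independent of the dual path."""
    n, d = X.shape
    pos = np.flatnonzero(roles == 1)
    neg = np.flatnonzero(roles == -1)
    mix = np.flatnonzero(roles == 0)
    n_slack = len(pos) + len(neg) + 2 * len(mix)

    def unpack(v):
        return v[:d], v[d], v[d + 1 :]

    def fun(v):
        w, h, s = unpack(v)
        return 0.5 * w @ w + penalty * float(
            np.sum(mu[pos] * s[: len(pos)])
            + np.sum(mu[neg] * s[len(pos) : len(pos) + len(neg)])
            + np.sum(mu[mix] * (s[len(pos) + len(neg) : len(pos) + len(neg) + len(mix)]
                                + s[len(pos) + len(neg) + len(mix) :]))
        )

    cons = []
    for k, i in enumerate(pos):
        cons.append({"type": "ineq",
                     "fun": lambda v, i=i, k=k: unpack(v)[0] @ X[i] + unpack(v)[1] - 1 + unpack(v)[2][k]})
    for k, i in enumerate(neg):
        cons.append({"type": "ineq",
                     "fun": lambda v, i=i, k=k: -(unpack(v)[0] @ X[i] + unpack(v)[1]) - 1 + unpack(v)[2][len(pos) + k]})
    for k, i in enumerate(mix):
        cons.append({"type": "ineq",
                     "fun": lambda v, i=i, k=k: 1 + unpack(v)[2][len(pos) + len(neg) + k] - (unpack(v)[0] @ X[i] + unpack(v)[1])})
        cons.append({"type": "ineq",
                     "fun": lambda v, i=i, k=k: unpack(v)[0] @ X[i] + unpack(v)[1] + 1 + unpack(v)[2][len(pos) + len(neg) + len(mix) + k]})
    bounds = [(None, None)] * (d + 1) + [(0.0, None)] * n_slack
    res = minimize(fun, np.zeros(d + 1 + n_slack), method="SLSQP",
                   constraints=cons, bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12})
    assert res.success
    return res.fun


class TestMixedSubproblem:
    def test_no_mixed_samples_collapses_to_binary_fsvm(self, separable_binary):
        X, y = separable_binary
        spec = SubproblemSpec(pair=(0, 1), sample_indices=np.arange(len(y)), roles=y)
        mu = np.ones(len(y))
        mixed = fit_mixed_subproblem(X, spec, mu, penalty=1.0, kernel=KernelSpec("linear"))
        binary = fsvm_fit(FuzzyTrainingSet(X, y, mu), C=1.0, kernel=KernelSpec("linear"))
        Xt = np.random.default_rng(0).normal(size=(20, 2))
        np.testing.assert_allclose(mixed.decision(Xt), fsvm_decision(binary, Xt), atol=1e-5)

    def test_midline_mixed_sample_is_slack_free(self):
        X, spec, _ = six_point_spec()
        mu = np.ones(6)
        model = fit_mixed_subproblem(X, spec, mu, penalty=5.0, kernel=KernelSpec("linear"))
        f_mixed = model.decision(X[4:6])
        assert np.all(np.abs(f_mixed) <= 1.0 + 1e-8)

    def test_objective_matches_dense_primal_oracle(self):
        X, spec, mu = six_point_spec()
        model = fit_mixed_subproblem(X, spec, mu, penalty=2.0, kernel=KernelSpec("linear"))
        expected = primal_oracle(X, spec.roles, mu, 2.0)
        assert model.primal_objective() == pytest.approx(expected, abs=1e-6)

    def test_missing_role_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        spec = SubproblemSpec(pair=(0, 1), sample_indices=np.arange(4),
                              roles=np.array([1, 1, 0, 0]))
        with pytest.raises(ValueError):
            fit_mixed_subproblem(X, spec, np.ones(4))

    def test_role_counts_partition_training_set(self):
        X, spec, mu = six_point_spec()
        l_pos = (spec.roles == 1).sum()
        l_neg = (spec.roles == -1).sum()
        l_mix = (spec.roles == 0).sum()
        assert l_pos + l_neg + l_mix == len(spec.sample_indices)


def three_class_blobs(n_per=30, seed=0):
    rng = np.random.default_rng(seed)
    means = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
    X = np.vstack([m + rng.normal(0, 0.8, (n_per, 2)) for m in means])
    labels = np.repeat(np.arange(3), n_per)
    Y = np.zeros((len(X), 3), dtype=int)
    Y[np.arange(len(X)), labels] = 1
    return X, Y, labels


class TestPipeline:
    def test_collapse_to_standard_ovo_on_single_label_data(self):
        """Without dual-labelled samples the mixed machinery is inert: the
        pipeline's label predictions match one-vs-one voting over plain
        binary machines built from the same data."""
        X, Y, labels = three_class_blobs()
        Xt, _, labels_t = three_class_blobs(n_per=40, seed=99)
        clf = ClusteredFuzzyOvoClassifier(
            membership=MembershipStrategy("constant-one"),
            prune=False,
            kernel=KernelSpec("linear"),
        ).fit(X, Y)
        F = clf.decision_matrix(Xt)
        votes = np.zeros((len(Xt), 3))
        for k, (w, t) in enumerate(clf.pairs_):
            mask = (labels == w) | (labels == t)
            roles = np.where(labels[mask] == w, 1, -1)
            m = fsvm_fit(
                FuzzyTrainingSet(X[mask], roles, np.ones(mask.sum())),
                C=1.0,
                kernel=KernelSpec("linear"),
            )
            f = fsvm_decision(m, Xt)
            # the trained pairwise machines ARE plain binary fuzzy SVMs
            np.testing.assert_allclose(F[:, k], f, atol=1e-5)
            votes[f > 0, w] += 1
            votes[f <= 0, t] += 1
        # where no decision falls inside the three-way band, the aggregated
        # prediction coincides with classic sign-voting OvO
        pred = clf.predict(Xt)
        outside = np.all(np.abs(F) > 1.0, axis=1)
        assert outside.sum() > 20
        np.testing.assert_array_equal(
            pred[outside].argmax(axis=1), votes[outside].argmax(axis=1)
        )
        # and on clearly separated blobs every such prediction is correct
        np.testing.assert_array_equal(pred[outside].argmax(axis=1), labels_t[outside])

    def test_bundle_round_trip_preserves_decisions(self):
        X, Y, _ = three_class_blobs(seed=3)
        clf = ClusteredFuzzyOvoClassifier(kernel=KernelSpec("linear")).fit(X, Y)
        import json

        from cofsvm.ovo_multilabel import MixedFSVMModel

        blobs = [json.dumps(m.to_dict()) for m in clf.models_]
        restored = [MixedFSVMModel.from_dict(json.loads(b)) for b in blobs]
        for m, r in zip(clf.models_, restored):
            assert np.array_equal(m.decision(X), r.decision(X))

    def test_label_correlation_captured(self):
        X, Y, _ = three_class_blobs()
        clf = ClusteredFuzzyOvoClassifier(kernel=KernelSpec("linear")).fit(X, Y)
        M = clf.label_correlation_
        assert M.shape == (3, 3)
        assert np.allclose(M, M.T)
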