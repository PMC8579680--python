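import numpy as np
import pytest
from sklearn.svm import SVC

from rsgsa import (
    EnsembleConfig,
    ExpressionDataset,
    RunRanking,
    SyntheticSpec,
    aggregate_ranks,
    aggregate_weights,
    balance_classes,
    bootstrap_sample,
    flip_labels,
    generate,
    rsgsa,
    ssvm_rfe_rank,
    train_weight_vector,
)
from rsgsa.stable_rfe import WeightVector, _standardize


# ---------------------------------------------------------------------------
# independent oracle: classical single-SVM RFE, coded from scratch
# ---------------------------------------------------------------------------

def plain_svm_rfe(values, labels, target, elimination_fraction=0.10, C=1.0):
    """Reference SVM-RFE: one linear SVM per step, squared-weight scores.

    Deliberately avoids the package's gram-matrix path: fits libsvm with
    an explicit linear kernel on the standardized feature matrix and ranks
    by raw squared weights (normalisation is a positive scalar and cannot
    change the order).
    """
    import math

    n = values.shape[1]
    surviving = list(range(n))
    batches = []
    while True:
        X = values[:, surviving]
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C).fit((X - mu) / sd, labels)
        w2 = np.asarray(clf.coef_).ravel() ** 2
        if len(surviving) <= target:
            final_w2 = w2
            break
        k = max(1, math.ceil(elimination_fraction * len(surviving)))
        k = min(k, len(surviving) - target)
        order = sorted(range(len(surviving)),
                       key=lambda i: (-w2[i], surviving[i]))
        dropped = order[len(surviving) - k:]
        batches.append([surviving[i] for i in dropped])
        surviving = [surviving[i] for i in sorted(
            set(range(len(surviving))) - set(dropped))]
        if len(surviving) <= target:
            X = values[:, surviving]
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            clf = SVC(kernel="linear", C=C).fit((X - mu) / sd, labels)
            final_w2 = np.asarray(clf.coef_).ravel() ** 2
            break
    ranks = np.empty(n, dtype=int)
    r = 0
    for i in sorted(range(len(surviving)),
                    key=lambda i: (-final_w2[i], surviving[i])):
        ranks[surviving[i]] = r
        r += 1
    for batch in reversed(batches):
        for g in batch:
            ranks[g] = r
            r += 1
    return ranks


class TestFlipLabels:
    def test_zero_fraction_identity(self, rng):
        labels = np.array(["a", "b"] * 10, dtype=object)
        out = flip_labels(labels, 0.0, rng)
        assert list(out) == list(labels)

    def test_three_percent_of_100_flips_exactly_3(self, rng):
        labels = np.array(["a", "b"] * 50, dtype=object)
        out = flip_labels(labels, 0.03, rng)
        assert int(np.sum(out != labels)) == 3

    def test_flipped_position_changes_class(self, rng):
        labels = np.array(["a", "b", "c"] * 10, dtype=object)
        for _ in range(20):
            out = flip_labels(labels, 0.2, rng)
            changed = out != labels
            assert changed.sum() == 6
            assert all(out[i] != labels[i] for i in np.where(changed)[0])

    def test_half_or_more_rejected(self, rng):
        with pytest.raises(ValueError):
            flip_labels(np.array(["a", "b"] * 5, dtype=object), 0.5, rng)


class TestBalanceClasses:
    def test_balanced_input_unchanged(self, tiny_dataset, rng):
        out = balance_classes(tiny_dataset, rng)
        assert out is tiny_dataset

    def test_10_vs_4_becomes_10_vs_10(self, rng):
        values = rng.normal(size=(14, 5))
        labels = np.array(["maj"] * 10 + ["min"] * 4, dtype=object)
        ds = ExpressionDataset(values, labels, [f"g{i}" for i in range(5)])
        out = balance_classes(ds, rng)
        _, counts = np.unique(out.labels.astype(str), return_counts=True)
        assert sorted(counts.tolist()) == [10, 10]

    def test_synthetic_samples_lie_on_minority_segments(self, rng):
        values = rng.normal(size=(13, 4))
        labels = np.array(["maj"] * 10 + ["min"] * 3, dtype=object)
        ds = ExpressionDataset(values, labels, [f"g{i}" for i in range(4)])
        out = balance_classes(ds, rng)
        minority = values[10:]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        synth = out.values[13:]
        assert synth.shape == (7, 4)
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)
        assert all(lbl == "min" for lbl in out.labels[13:])

    def test_singleton_minority_jitter_fallback(self, rng):
        values = rng.normal(size=(6, 4))
        labels = np.array(["maj"] * 5 + ["min"], dtype=object)
        ds = ExpressionDataset(values, labels, [f"g{i}" for i in range(4)])
        out = balance_classes(ds, rng)
        synth = out.values[6:]
        assert synth.shape == (4, 4)
        # jitter is 1% of per-gene SD: synthetic copies hug the original
        assert np.all(np.abs(synth - values[5]) < values.std(axis=0))


class TestTrainWeightVector:
    def test_informative_gene_dominates(self, rng):
        values = rng.normal(size=(20, 5))
        labels = np.array(["a", "b"] * 10, dtype=object)
        values[:, 3] += np.where(labels == "b", 4.0, 0.0)
        ds = ExpressionDataset(values, labels, [f"g{i}" for i in range(5)])
        wv = train_weight_vector(ds, rng, noise_fraction=0.0)
        w = np.abs(wv.normalized).sum(axis=0)
        assert int(np.argmax(w)) == 3
        assert w[3] > max(np.delete(w, 3))

    def test_unit_1_norm(self, tiny_dataset, rng):
        wv = train_weight_vector(tiny_dataset, rng, noise_fraction=0.1)
        for row in wv.normalized:
            assert np.abs(row).sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_with_fixed_seed(self, tiny_dataset):
        wv1 = train_weight_vector(tiny_dataset, np.random.default_rng(5), 0.0)
        wv2 = train_weight_vector(tiny_dataset, np.random.default_rng(5), 0.0)
        np.testing.assert_array_equal(wv1.normalized, wv2.normalized)

    def test_multiclass_one_row_per_class(self, rng):
        values = rng.normal(size=(30, 6))
        labels = np.array(["a", "b", "c"] * 10, dtype=object)
        ds = ExpressionDataset(values, labels, [f"g{i}" for i in range(6)])
        wv = train_weight_vector(ds, rng, 0.0)
        assert wv.normalized.shape == (3, 6)
        for row in wv.normalized:
            assert np.abs(row).sum() == pytest.approx(1.0, abs=1e-12)

    def test_gram_weights_match_explicit_linear_kernel(self, rng):
        # dual-route check of the gram shortcut against libsvm's own
        # linear-kernel coefficients
        values = rng.normal(size=(16, 8))
        labels = np.array(["a", "b"] * 8, dtype=object)
        values[:, 0] += np.where(labels == "b", 1.5, 0.0)
        ds = ExpressionDataset(values, labels, [f"g{i}" for i in range(8)])
        wv = train_weight_vector(ds, rng, 0.0)
        X = _standardize(ds.values)
        ref = SVC(kernel="linear", C=1.0).fit(X, labels.astype(str))
        np.testing.assert_allclose(
            wv.raw.ravel(), np.asarray(ref.coef_).ravel(), atol=1e-9
        )


class TestAggregateWeights:
    def test_squares_ignore_sign(self):
        v = WeightVector(raw=np.array([[0.5, -0.5]]),
                         normalized=np.array([[0.5, -0.5]]))
        np.testing.assert_allclose(aggregate_weights([v]), [0.25, 0.25])

    def test_additivity_and_direct_arithmetic(self):
        a = WeightVector(raw=np.array([[0.5, -0.5]]),
                         normalized=np.array([[0.5, -0.5]]))
        b = WeightVector(raw=np.array([[0.5, 0.5]]),
                         normalized=np.array([[0.5, 0.5]]))
        np.testing.assert_allclose(aggregate_weights([a, a]), [0.5, 0.5])
        np.testing.assert_allclose(aggregate_weights([a, b]), [0.5, 0.5])

    def test_global_negation_invariance(self, rng):
        w = rng.normal(size=(1, 7))
        w /= np.abs(w).sum()
        v = WeightVector(raw=w, normalized=w)
        neg = WeightVector(raw=-w, normalized=-w)
        np.testing.assert_allclose(aggregate_weights([v]),
                                   aggregate_weights([neg]))

    def test_mismatched_lengths_rejected(self):
        a = WeightVector(raw=np.ones((1, 3)), normalized=np.ones((1, 3)) / 3)
        b = WeightVector(raw=np.ones((1, 4)), normalized=np.ones((1, 4)) / 4)
        with pytest.raises(ValueError):
            aggregate_weights([a, b])


class TestSsvmRfeRank:
    def test_full_permutation(self, tiny_dataset, rng):
        cfg = EnsembleConfig(ensemble_size=2, noise_fraction=0.0,
                             target_gene_count=2, bootstrap_runs=1)
        ranking = ssvm_rfe_rank(tiny_dataset, cfg, rng)
        assert sorted(ranking.ranks.tolist()) == list(range(6))

    def test_target_at_n_is_single_round(self, tiny_dataset, rng):
        cfg = EnsembleConfig(ensemble_size=1, noise_fraction=0.0,
                             target_gene_count=10, bootstrap_runs=1)
        ranking = ssvm_rfe_rank(tiny_dataset, cfg, rng)
        assert sorted(ranking.ranks.tolist()) == list(range(6))
        # single round: order must equal descending first-step importance
        imp = ranking.first_step_importance
        order = np.argsort(ranking.ranks)
        assert list(order) == sorted(range(6), key=lambda i: (-imp[i], i))

    def test_planted_gene_ranks_high(self):
        hits = 0
        for seed in range(10):
            spec = SyntheticSpec(n_samples=30, n_genes=200, n_informative=1,
                                 block_size=0, effect_size=2.0, seed=seed)
            ds, truth = generate(spec)
            cfg = EnsembleConfig(ensemble_size=5, target_gene_count=20)
            ranking = ssvm_rfe_rank(ds, cfg, np.random.default_rng(seed))
            planted = ds.gene_ids.index(truth.informative[0])
            if ranking.ranks[planted] < 10:
                hits += 1
        assert hits >= 9

    def test_degenerate_config_matches_plain_svm_rfe_oracle(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            values = rng.normal(size=(30, 100))
            labels = np.array(["a", "b"] * 15, dtype=object)
            values[:, :3] += np.where(labels == "b", 1.0, 0.0)[:, None]
            ds = ExpressionDataset(values, labels,
                                   [f"g{i}" for i in range(100)])
            cfg = EnsembleConfig(ensemble_size=1, noise_fraction=0.0,
                                 target_gene_count=10, bootstrap_runs=1)
            ours = ssvm_rfe_rank(ds, cfg, np.random.default_rng(0))
            oracle = plain_svm_rfe(values, labels.astype(str), target=10)
            np.testing.assert_array_equal(ours.ranks, oracle)


class TestBootstrapSample:
    def test_reproducible(self, tiny_dataset):
        b1 = bootstrap_sample(tiny_dataset, np.random.default_rng(3))
        b2 = bootstrap_sample(tiny_dataset, np.random.default_rng(3))
        np.testing.assert_array_equal(b1.values, b2.values)
        np.testing.assert_array_equal(b1.labels, b2.labels)

    def test_single_sample_identity(self):
        ds = ExpressionDataset(np.ones((1, 3)), ["a"], ["g0", "g1", "g2"])
        b = bootstrap_sample(ds, np.random.default_rng(0))
        np.testing.assert_array_equal(b.values, ds.values)

    def test_unique_fraction_approaches_1_minus_1_over_e(self):
        # expected unique fraction of a full-size bootstrap -> 1 - 1/e
        rng = np.random.default_rng(42)
        e = 200
        ds = ExpressionDataset(
            np.arange(e, dtype=float)[:, None], ["a", "b"] * (e // 2),
            ["g0"],
        )
        fracs = []
        for _ in range(1000):
            b = bootstrap_sample(ds, rng)
            fracs.append(len(np.unique(b.values[:, 0])) / e)
        assert np.mean(fracs) == pytest.approx(1 - 1 / np.e, abs=0.02)

    def test_preserves_all_classes(self, rng):
        ds = ExpressionDataset(
            np.arange(20, dtype=float)[:, None],
            ["rare"] * 2 + ["common"] * 18, ["g0"],
        )
        for _ in range(25):
            b = bootstrap_sample(ds, rng)
            assert set(b.labels.astype(str)) == {"rare", "common"}


class TestAggregateRanks:
    def _run(self, ranks, idx=0):
        return RunRanking(ranks=np.array(ranks),
                          gene_ids=[f"g{i}" for i in range(len(ranks))],
                          run_index=idx)

    def test_identical_runs_preserve_order(self):
        runs = [self._run([2, 0, 1], i) for i in range(4)]
        agg = aggregate_ranks(runs)
        assert agg.ordered_gene_ids == ["g1", "g2", "g0"]
        assert agg.rank_sums.tolist() == [8, 0, 4]

    def test_rank_sum_arithmetic_and_tiebreak(self):
        r1 = self._run([0, 1, 2], 0)
        r2 = self._run([1, 0, 2], 1)
        agg = aggregate_ranks([r1, r2])
        assert agg.rank_sums.tolist() == [1, 1, 4]
        # tie between g0 and g1 without importances: gene index wins
        assert agg.ordered_gene_ids == ["g0", "g1", "g2"]

    def test_importance_breaks_ties(self):
        r1 = self._run([0, 1, 2], 0)
        r2 = self._run([1, 0, 2], 1)
        r1.first_step_importance = np.array([0.1, 0.9, 0.5])
        r2.first_step_importance = np.array([0.1, 0.9, 0.5])
        agg = aggregate_ranks([r1, r2])
        assert agg.ordered_gene_ids == ["g1", "g0", "g2"]

    def test_sum_monotonicity_property(self, rng):
        # if gene a outranks gene b in every run, a precedes b overall
        for _ in range(20):
            n = 8
            runs = [self._run(list(rng.permutation(n)), i) for i in range(5)]
            agg = aggregate_ranks(runs)
            position = {g: i for i, g in enumerate(agg.ordered_gene_ids)}
            for a in range(n):
                for b in range(n):
                    if a == b:
                        continue
                    if all(r.ranks[a] < r.ranks[b] for r in runs):
                        assert position[f"g{a}"] < position[f"g{b}"]

    def test_rank_sum_conservation(self, rng):
        n, m = 12, 7
        runs = [self._run(list(rng.permutation(n)), i) for i in range(m)]
        agg = aggregate_ranks(runs)
        assert agg.rank_sums.sum() == m * n * (n - 1) // 2

    def test_inconsistent_gene_sets_rejected(self):
        r1 = self._run([0, 1])
        r2 = RunRanking(ranks=np.array([0, 1]), gene_ids=["x", "y"])
        with pytest.raises(ValueError):
            aggregate_ranks([r1, r2])


class TestRsgsaPipeline:
    def test_leaders_plus_members_partition_genes(self, planted_dataset):
        dataset, _ = planted_dataset
        cfg = EnsembleConfig(ensemble_size=2, bootstrap_runs=2,
                             target_gene_count=20)
        ranking, assignment = rsgsa(dataset, config=cfg,
                                    rng=np.random.default_rng(0))
        covered = set(assignment.leaders_ids)
        for ms in assignment.members_by_id.values():
            covered.update(ms)
        assert covered == set(dataset.gene_ids)
        assert set(ranking.gene_ids) == set(assignment.leaders_ids)

    def test_rank_sum_conservation_through_pipeline(self, planted_dataset):
        dataset, _ = planted_dataset
        m = 3
        cfg = EnsembleConfig(ensemble_size=2, bootstrap_runs=m,
                             target_gene_count=10)
        ranking, _ = rsgsa(dataset, config=cfg, rng=np.random.default_rng(1))
        n = len(ranking.gene_ids)
        assert ranking.rank_sums.sum() == m * n * (n - 1) // 2

    def test_planted_leaders_rank_top(self, planted_dataset):
        dataset, truth = planted_dataset
        cfg = EnsembleConfig(ensemble_size=5, bootstrap_runs=5,
                             target_gene_count=10)
        ranking, assignment = rsgsa(dataset, config=cfg,
                                    rng=np.random.default_rng(2))
        # each planted block contributes one leader; all 4 should rank
        # within the top 8 of ~112 leaders
        id_to_block_leader = {}
        leaders = set(assignment.leaders_ids)
        for inf, comps in truth.blocks.items():
            block = {inf, *comps}
            (leader,) = block & leaders
            id_to_block_leader[inf] = leader
        top8 = set(ranking.top(8))
        hits = sum(1 for l in id_to_block_leader.values() if l in top8)
        assert hits >= 3

    def test_reproducible_given_seed(self, planted_dataset):
        dataset, _ = planted_dataset
        cfg = EnsembleConfig(ensemble_size=2, bootstrap_runs=2,
                             target_gene_count=20)
        r1, _ = rsgsa(dataset, config=cfg, rng=np.random.default_rng(9))
        r2, _ = rsgsa(dataset, config=cfg, rng=np.random.default_rng(9))
        assert r1.ordered_gene_ids == r2.ordered_gene_ids
        np.testing.assert_array_equal(r1.rank_sums, r2.rank_sums)


class TestEnsembleConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(ensemble_size=0),
        dict(noise_fraction=0.5),
        dict(noise_fraction=-0.01),
        dict(elimination_fraction=0.0),
        dict(target_gene_count=0),
        dict(bootstrap_runs=0),
        dict(bootstrap_fraction=1.5),
        dict(svm_regularization=0.0),
    ])
    def test_bounds(self, kwargs):
        with pytest.raises(ValueError):
            EnsembleConfig(**kwargs)
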