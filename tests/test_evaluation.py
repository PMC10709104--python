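import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repvar.dms_data import CANONICAL_AA, DmsDataset, DmsRecord, Mutation
from repvar.embeddings import SyntheticProvider
from repvar.evaluation import (
    EvalResult,
    fraction_split,
    kfold_split,
    position_split,
    run_fewshot,
    run_leave_position_out,
    run_tenfold,
    run_zeroshot,
    spearman,
    write_report,
)
from repvar.head_model import HeadConfig
from repvar.synthetic_data import (
    PlantedModelSpec,
    RECOVERY_HEAD_CONFIG,
    RECOVERY_PRETRAIN_CONFIG,
    make_multitask_suite,
    make_planted_dataset,
)
from repvar.training import FinetuneConfig, PretrainConfig, pretrain

from conftest import random_dataset


def rank_average(v):
    """Explicit average ranks: ties get the mean of their rank range."""
    v = list(v)
    n = len(v)
    order = sorted(range(n), key=lambda i: v[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_bruteforce(x, y):
    """Independent oracle: rank covariance by direct summation."""
    rx, ry = rank_average(x), rank_average(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry)) / n
    sx = (sum((a - mx) ** 2 for a in rx) / n) ** 0.5
    sy = (sum((b - my) ** 2 for b in ry) / n) ** 0.5
    return cov / (sx * sy)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_reversed(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_bruteforce(self):
        x, y = (1, 2, 2, 3), (1, 3, 2, 4)
        expected = spearman_bruteforce(x, y)
        assert expected == pytest.approx(0.9486832980505138)
        assert spearman(x, y) == pytest.approx(expected)

    def test_random_vectors_match_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.standard_normal(n)
            if len(set(x)) < 2:
                continue
            assert spearman(x, y) == pytest.approx(spearman_bruteforce(x, y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2, 3])

    def test_degenerate_constant(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    @given(st.lists(st.integers(min_value=-50, max_value=50), min_size=3, max_size=30))
    @settings(max_examples=100)
    def test_invariant_under_increasing_transform(self, xs):
        if len(set(xs)) < 2:
            return
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**32)
        y = rng.standard_normal(len(xs)).tolist()
        base = spearman(xs, y)
        transformed = [np.exp(0.3 * v) + 2 * v for v in xs]  # strictly increasing
        assert spearman(transformed, y) == pytest.approx(base, abs=1e-12)


class TestKfoldSplit:
    def test_singleton_folds(self):
        plan = kfold_split(10, 10, seed=0)
        assert all(len(test) == 1 for _, test in plan.folds)

    def test_balanced_103_by_10(self):
        plan = kfold_split(103, 10, seed=1)
        sizes = sorted(len(test) for _, test in plan.folds)
        assert sizes == [10] * 7 + [11] * 3

    def test_partition(self):
        plan = kfold_split(57, 7, seed=2)
        plan.validate(57)
        all_test = np.concatenate([t for _, t in plan.folds])
        assert sorted(all_test.tolist()) == list(range(57))

    def test_n_smaller_than_k(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10, seed=0)

    def test_seeded(self):
        p1 = kfold_split(50, 5, seed=3)
        p2 = kfold_split(50, 5, seed=3)
        for (a, b), (c, d) in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(b, d)


class TestPositionSplit:
    def test_grouping(self):
        wt = "ACDEF"
        recs = [
            DmsRecord(Mutation("C", 2, "G"), 0.1),
            DmsRecord(Mutation("C", 2, "W"), 0.2),
            DmsRecord(Mutation("F", 5, "L"), 0.3),
        ]
        plan = position_split(DmsDataset("x", wt, recs))
        assert len(plan.folds) == 2
        sizes = sorted(len(test) for _, test in plan.folds)
        assert sizes == [1, 2]

    def test_no_position_leaks(self, tiny_dataset):
        plan = position_split(tiny_dataset)
        positions = np.array([r.mutation.position for r in tiny_dataset.records])
        for train, test in plan.folds:
            assert set(positions[train]).isdisjoint(set(positions[test]))

    def test_partition_total(self, tiny_dataset):
        plan = position_split(tiny_dataset)
        assert sum(len(test) for _, test in plan.folds) == len(tiny_dataset.records)

    def test_single_position_error(self):
        ds = DmsDataset("x", "ACD", [DmsRecord(Mutation("A", 1, "G"), 1.0)])
        with pytest.raises(ValueError):
            position_split(ds)


class TestFractionSplit:
    def test_sizes(self):
        plan = fraction_split(100, 0.3, seed=0)
        train, test = plan.folds[0]
        assert (len(train), len(test)) == (30, 70)

    def test_rounding(self):
        plan = fraction_split(2, 0.5, seed=0)
        train, test = plan.folds[0]
        assert (len(train), len(test)) == (1, 1)

    def test_repeats_distinct(self):
        plan = fraction_split(100, 0.3, seed=0, repeats=5)
        trains = {tuple(t.tolist()) for t, _ in plan.folds}
        assert len(trains) == 5

    def test_empty_side_error(self):
        with pytest.raises(ValueError):
            fraction_split(3, 0.01, seed=0)

    def test_disjoint(self):
        plan = fraction_split(40, 0.25, seed=1, repeats=3)
        plan.validate()


class TestSplitInvariantsSweep:
    """Partition/disjointness invariants over many random datasets."""

    def test_fifty_random_datasets(self):
        rng = np.random.default_rng(123)
        for i in range(50):
            n = int(rng.integers(20, 200))
            k = 10
            plan = kfold_split(n, k, seed=i)
            plan.validate(n)
            sizes = [len(t) for _, t in plan.folds]
            assert max(sizes) - min(sizes) <= 1

            f = float(rng.uniform(0.1, 0.9))
            fplan = fraction_split(n, f, seed=i, repeats=2)
            fplan.validate()
            assert all(len(tr) == round(f * n) for tr, _ in fplan.folds)

            ds = random_dataset(rng, min(n, 19 * 12), 12, name=f"r{i}")
            pplan = position_split(ds)
            pplan.validate(len(ds.records))
            positions = np.array([r.mutation.position for r in ds.records])
            for train, test in pplan.folds:
                assert set(positions[train]).isdisjoint(positions[test])


class TestEvalResult:
    def test_mean_is_unweighted(self):
        r = EvalResult("kfold", "d", [0.5, 0.7, 0.9], [1, 1, 1], [1, 1, 1])
        assert r.mean_srcc == pytest.approx(0.7)

    def test_srcc_range_enforced(self):
        with pytest.raises(ValueError):
            EvalResult("kfold", "d", [1.5], [1], [1])

    def test_report_files(self, tmp_path):
        r = EvalResult(
            "fraction", "d", [0.5, 0.7], [3, 3], [7, 7],
            rows=[{"repeat": 0, "fold": 0, "n_train": 3, "n_test": 7},
                  {"repeat": 1, "fold": 0, "n_train": 3, "n_test": 7}],
        )
        csv_path, json_path = write_report(r, tmp_path)
        assert csv_path.exists() and json_path.exists()
        import pandas as pd

        detail = pd.read_csv(csv_path)
        assert list(detail["srcc"]) == [0.5, 0.7]


@pytest.fixture(scope="module")
def shared_suite():
    """Six planted datasets sharing branch mechanism and output head."""
    template = PlantedModelSpec(
        seed=21, n_variants=600, seq_length=80, noise_sd=0.05, noise_sd_relative=True
    )
    suite = make_multitask_suite(
        6, shared_branch_seed=77, per_dataset_head_seeds=[9] * 6,
        template=template, provider_seed=21,
    )
    return [d for d, _ in suite]


@pytest.fixture(scope="module")
def suite_provider():
    return SyntheticProvider(21, dim=64)


class TestRunZeroshot:
    def test_shared_mechanism_recovery(self, shared_suite, suite_provider):
        result = run_zeroshot(
            shared_suite[:5], shared_suite[5], suite_provider,
            RECOVERY_PRETRAIN_CONFIG, head_config=RECOVERY_HEAD_CONFIG,
        )
        assert result.mean_srcc >= 0.9

    def test_target_in_pool_rejected(self, shared_suite, suite_provider):
        with pytest.raises(ValueError):
            run_zeroshot(shared_suite, shared_suite[0], suite_provider, RECOVERY_PRETRAIN_CONFIG)

    def test_scores_only_enter_through_ranks(self, shared_suite, suite_provider):
        """A strictly increasing transform of the target's scores leaves the
        zero-shot SRCC unchanged: target measurements are never used in
        training, only ranked at evaluation."""
        target = shared_suite[5]
        warped = DmsDataset(
            target.name, target.wt_sequence,
            [DmsRecord(r.mutation, float(np.exp(r.score))) for r in target.records],
            target.measurement_label,
        )
        cfg = PretrainConfig(epochs=5, batch_size=64, learning_rate=1e-3, seed=11)
        r1 = run_zeroshot(shared_suite[:5], target, suite_provider, cfg, head_config=RECOVERY_HEAD_CONFIG)
        r2 = run_zeroshot(shared_suite[:5], warped, suite_provider, cfg, head_config=RECOVERY_HEAD_CONFIG)
        assert r1.mean_srcc == pytest.approx(r2.mean_srcc, abs=1e-12)

    def test_pool_of_one(self, shared_suite, suite_provider):
        cfg = PretrainConfig(epochs=2, batch_size=64, learning_rate=1e-3, seed=11)
        result = run_zeroshot(shared_suite[:1], shared_suite[5], suite_provider, cfg,
                              head_config=RECOVERY_HEAD_CONFIG)
        assert -1.0 <= result.mean_srcc <= 1.0

    def test_average_head_strategy(self, shared_suite, suite_provider):
        cfg = PretrainConfig(epochs=2, batch_size=64, learning_rate=1e-3, seed=11)
        result = run_zeroshot(shared_suite[:2], shared_suite[5], suite_provider, cfg,
                              head_config=RECOVERY_HEAD_CONFIG, head_strategy="average")
        assert result.metadata["head_strategy"] == "average"


class TestRunFewshot:
    FT = FinetuneConfig(epochs=60, batch_size=8, lr_head=3e-3, lr_shared=3e-4, seed=11)

    def test_transfer_benefit(self, shared_suite, suite_provider):
        kwargs = dict(
            fraction=0.1, repeats=3, seed=5, head_config=RECOVERY_HEAD_CONFIG,
        )
        with_pre = run_fewshot(shared_suite[:5], shared_suite[5], suite_provider,
                               RECOVERY_PRETRAIN_CONFIG, self.FT, **kwargs)
        without = run_fewshot(shared_suite[:5], shared_suite[5], suite_provider,
                              RECOVERY_PRETRAIN_CONFIG, self.FT, skip_pretraining=True, **kwargs)
        assert with_pre.mean_srcc > without.mean_srcc

    def test_fraction_in_metadata(self, shared_suite, suite_provider):
        r = run_fewshot(shared_suite[:1], shared_suite[5], suite_provider,
                        PretrainConfig(epochs=1, batch_size=64, learning_rate=1e-3, seed=1),
                        FinetuneConfig(epochs=1, seed=1), fraction=0.3, repeats=1,
                        head_config=RECOVERY_HEAD_CONFIG)
        assert r.metadata["fraction"] == 0.3
        assert len(r.per_repeat_srcc) == 1


class TestRunTenfold:
    def test_planted_recovery(self, suite_provider):
        template = PlantedModelSpec(seed=21, n_variants=400, seq_length=60, noise_sd=0.0)
        suite = make_multitask_suite(3, shared_branch_seed=77, per_dataset_head_seeds=[9] * 3,
                                     template=template, provider_seed=21)
        pool = [d for d, _ in suite[:2]]
        target = suite[2][0]
        pcfg = PretrainConfig(epochs=300, batch_size=64, learning_rate=1e-3, seed=11)
        fcfg = FinetuneConfig(epochs=150, batch_size=32, lr_head=5e-3, lr_shared=1e-4, seed=11)
        result = run_tenfold(target, pool, suite_provider, pcfg, fcfg, repeats=2, seed=3)
        assert result.mean_srcc >= 0.95
        assert len(result.per_repeat_srcc) == 2
        # every record tested exactly once per repeat
        per_repeat_rows = [r for r in result.rows if r["repeat"] == 0]
        assert sum(r["n_test"] for r in per_repeat_rows) == len(target.records)

    def test_target_not_in_pool(self, shared_suite, suite_provider):
        with pytest.raises(ValueError):
            run_tenfold(shared_suite[0], shared_suite, suite_provider,
                        RECOVERY_PRETRAIN_CONFIG, FinetuneConfig(seed=1))

    def test_target_absent_from_pretraining_heads(self, shared_suite, suite_provider):
        pool = shared_suite[:2]
        pre = pretrain(pool, suite_provider,
                       PretrainConfig(epochs=1, batch_size=64, learning_rate=1e-3, seed=1),
                       RECOVERY_HEAD_CONFIG)
        assert shared_suite[5].name not in pre.model.heads


class TestRunLeavePositionOut:
    def test_residue_identity_generalizes(self, suite_provider):
        """Scores depending only on the mutant residue generalize to unseen
        positions; a pretrained start (same mechanism, different protein)
        keeps per-fold models calibrated consistently."""
        rng = np.random.default_rng(2)
        res_map = {aa: float(rng.standard_normal()) for aa in CANONICAL_AA}

        def resonly(seed, name):
            d, _ = make_planted_dataset(
                PlantedModelSpec(seed=seed, n_variants=450, seq_length=35, name=name),
                provider_seed=21,
            )
            jit = np.random.default_rng(seed + 1).normal(0, 0.01, len(d.records))
            recs = [DmsRecord(r.mutation, res_map[r.mutation.mt_aa] + float(j))
                    for r, j in zip(d.records, jit)]
            return DmsDataset(name, d.wt_sequence, recs)

        provider = SyntheticProvider(21, dim=64, base_weight=0.1, context_weight=0.02)
        pool = resonly(70, "resonly_pool")
        target = resonly(33, "resonly")
        pre = pretrain([pool], provider,
                       PretrainConfig(epochs=200, batch_size=64, learning_rate=1e-3, seed=11),
                       RECOVERY_HEAD_CONFIG)
        fcfg = FinetuneConfig(epochs=80, batch_size=32, lr_head=1e-3, lr_shared=1e-4, seed=11)
        result = run_leave_position_out(target, provider, fcfg, pretrained=pre, seed=4)
        assert result.mean_srcc >= 0.9

    def test_position_lookup_fails(self, suite_provider):
        """Scores that are a pure per-position lookup cannot be ranked at
        held-out positions (designed failure mode)."""
        base, _ = make_planted_dataset(
            PlantedModelSpec(seed=33, n_variants=400, seq_length=60), provider_seed=21
        )
        rng = np.random.default_rng(5)
        pos_map = {}
        recs = []
        for r in base.records:
            p = r.mutation.position
            if p not in pos_map:
                pos_map[p] = float(rng.standard_normal())
            recs.append(DmsRecord(r.mutation, pos_map[p] + 0.001 * float(rng.standard_normal())))
        ds = DmsDataset("posonly", base.wt_sequence, recs)
        fcfg = FinetuneConfig(epochs=120, batch_size=32, lr_head=3e-3, lr_shared=1e-3, seed=11)
        result = run_leave_position_out(ds, suite_provider, fcfg,
                                        head_config=RECOVERY_HEAD_CONFIG, seed=4)
        assert abs(result.mean_srcc) <= 0.2

    def test_fold_count_equals_distinct_positions(self, suite_provider, tiny_dataset):
        fcfg = FinetuneConfig(epochs=1, batch_size=2, seed=1)
        result = run_leave_position_out(tiny_dataset, suite_provider, fcfg,
                                        head_config=HeadConfig(input_dim=64, hidden_dim=2), seed=0)
        n_positions = len({r.mutation.position for r in tiny_dataset.records})
        assert result.metadata["n_positions"] == n_positions
        assert len([r for r in result.rows]) == n_positions
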