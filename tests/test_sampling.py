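import numpy as np
import pytest

from tcrbind.data_io import ControlPool, Dataset, TCRRecord
from tcrbind.sampling import (
    NegativeSpec,
    SplitError,
    audit_leakage,
    balance_downsample,
    build_cv_dataset,
    control_negatives,
    mixed_negatives,
    nested_cv_plan,
    random_kfold,
    shuffle_negatives,
    strict_split,
)

from conftest import make_record


def _positives(n_peptides, per_peptide, seed=0):
    """Distinct positive pairs: peptide i x TCR j (unique CDR3b per pair)."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    recs = []
    for i in range(n_peptides):
        pep = "".join(alphabet[(i + k) % 20] for k in range(9))
        for j in range(per_peptide):
            cdr3b = "CASS" + alphabet[i % 20] + alphabet[j % 20] \
                + alphabet[(j // 20) % 20] + alphabet[(i + j) % 20] + "QYF"
            recs.append(make_record(pep, cdr3b))
    return Dataset(recs).drop_duplicate_positives()


class TestRandomKFold:
    def test_near_equal_fold_sizes(self):
        ds = _positives(2, 5)
        plan = random_kfold(ds, k=5, seed=0)
        assert plan.fold_sizes() == [2, 2, 2, 2, 2]

    def test_large_split_exact_counts(self):
        ds = _positives(10, 100)
        plan = random_kfold(ds, k=5, seed=1)
        assert plan.fold_sizes() == [200] * 5

    def test_determinism_and_seed_sensitivity(self):
        ds = _positives(4, 10)
        a = random_kfold(ds, 5, seed=3)
        b = random_kfold(ds, 5, seed=3)
        c = random_kfold(ds, 5, seed=4)
        assert a.fold_of_record == b.fold_of_record
        assert a.fold_of_record != c.fold_of_record

    def test_too_few_records_errors(self):
        with pytest.raises(SplitError):
            random_kfold(_positives(1, 3), k=5, seed=0)


class TestStrictSplit:
    def test_peptides_disjoint_across_folds(self):
        ds = _positives(10, 5)
        plan = strict_split(ds, k=5, seed=0)
        pep_sets = []
        for f in range(5):
            peps = {ds.records[i].peptide for i in plan.fold_indices(f)}
            pep_sets.append(peps)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not (pep_sets[i] & pep_sets[j])
        # 10 peptides round-robin over 5 folds -> 2 peptides each
        assert all(len(s) == 2 for s in pep_sets)

    def test_too_few_peptides_errors(self):
        with pytest.raises(SplitError):
            strict_split(_positives(4, 5), k=5, seed=0)

    @pytest.mark.parametrize("seed", range(100))
    def test_disjointness_holds_over_many_seeds(self, seed):
        rng = np.random.default_rng(seed)
        ds = _positives(int(rng.integers(5, 12)), int(rng.integers(1, 6)))
        plan = strict_split(ds, k=5, seed=seed)
        seen = {}
        for i, f in enumerate(plan.fold_of_record):
            p = ds.records[i].peptide
            assert seen.setdefault(p, f) == f


class TestNestedCVPlan:
    def test_structure_for_k5(self):
        plan = nested_cv_plan(5)
        assert len(plan.triples) == 5
        tests = [t for t, _, _ in plan.triples]
        assert sorted(tests) == list(range(5))
        for t, v, tr in plan.triples:
            folds = {t, v, *tr}
            assert folds == set(range(5))
            assert len(tr) == 3 and t != v and t not in tr and v not in tr

    def test_k_below_three_errors(self):
        with pytest.raises(SplitError):
            nested_cv_plan(2)


class TestShuffleNegatives:
    def test_two_peptide_enumeration(self):
        # only eligible negative for each positive is the other peptide's TCR
        recs = [make_record("AAAAAAAAA", "CASSAAAAF"), make_record("CCCCCCCCC", "CASSCCCCF")]
        negs = shuffle_negatives(recs, NegativeSpec("shuffle", (1, 1), seed=0))
        pairs = {(n.peptide, n.cdr3b) for n in negs}
        assert pairs == {("AAAAAAAAA", "CASSCCCCF"), ("CCCCCCCCC", "CASSAAAAF")}
        assert all(n.label == 0 and n.origin == "shuffled_negative" for n in negs)

    def test_single_peptide_partition_yields_nothing(self):
        recs = [make_record("AAAAAAAAA", "CASSAAAAF"), make_record("AAAAAAAAA", "CASSCCCCF")]
        with pytest.warns(UserWarning, match="could not reach"):
            negs = shuffle_negatives(recs, NegativeSpec("shuffle", (1, 1), seed=0))
        assert negs == []

    def test_ratio_counts_and_no_positive_collision(self):
        ds = _positives(6, 50)
        negs = shuffle_negatives(list(ds.records), NegativeSpec("shuffle", (1, 5), seed=1))
        assert len(negs) == 5 * len(ds)
        pos_pairs = {r.pair for r in ds.records}
        assert not pos_pairs & {n.pair for n in negs}
        assert len({n.pair for n in negs}) == len(negs)  # no duplicate negatives

    def test_strict_flag_raises_on_shortfall(self):
        recs = [make_record("AAAAAAAAA", "CASSAAAAF"), make_record("CCCCCCCCC", "CASSCCCCF")]
        with pytest.raises(SplitError, match="could not reach"):
            shuffle_negatives(recs, NegativeSpec("shuffle", (1, 5), seed=0), strict=True)

    def test_determinism(self):
        ds = _positives(4, 10)
        a = shuffle_negatives(list(ds.records), NegativeSpec("shuffle", (1, 2), seed=5))
        b = shuffle_negatives(list(ds.records), NegativeSpec("shuffle", (1, 2), seed=5))
        assert [r.pair for r in a] == [r.pair for r in b]


def _pool(n, seed=0):
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    tcrs = set()
    while len(tcrs) < n:
        tcrs.add(tuple("".join(alphabet[i] for i in rng.integers(0, 20, 6)) for _ in range(6)))
    return ControlPool(sorted(tcrs))


class TestControlNegatives:
    def test_one_to_one_counts_and_origin(self):
        ds = _positives(1, 3)
        negs = control_negatives(list(ds.records), _pool(100), NegativeSpec("control", (1, 1), 0))
        assert len(negs) == 3
        assert all(n.origin == "control_negative" and n.label == 0 for n in negs)

    def test_ratio_scales_count(self):
        ds = _positives(2, 4)
        negs = control_negatives(list(ds.records), _pool(100), NegativeSpec("control", (1, 2), 0))
        assert len(negs) == 2 * len(ds)

    def test_sampled_tcrs_subset_of_pool(self):
        pool = _pool(50)
        ds = _positives(3, 5)
        negs = control_negatives(list(ds.records), pool, NegativeSpec("control", (1, 2), 1))
        assert {n.tcr for n in negs} <= set(pool.tcrs)

    def test_pool_exhaustion_errors(self):
        ds = _positives(1, 10)
        with pytest.raises(SplitError, match="pool"):
            control_negatives(list(ds.records), _pool(5), NegativeSpec("control", (1, 1), 0))


class TestMixedNegatives:
    def test_component_counts_add_up(self):
        ds = _positives(5, 2)  # 10 positives
        negs = mixed_negatives(list(ds.records), _pool(200), (1, 3), (1, 2), seed=0)
        shuffled = [n for n in negs if n.origin == "shuffled_negative"]
        control = [n for n in negs if n.origin == "control_negative"]
        assert len(shuffled) == 30 and len(control) == 20 and len(negs) == 50

    def test_zero_ratio_degenerates(self):
        ds = _positives(4, 3)
        only_ctrl = mixed_negatives(list(ds.records), _pool(100), (1, 0), (1, 1), seed=0)
        assert all(n.origin == "control_negative" for n in only_ctrl)
        only_shuf = mixed_negatives(list(ds.records), _pool(100), (1, 1), (1, 0), seed=0)
        assert all(n.origin == "shuffled_negative" for n in only_shuf)


class TestBalanceDownsample:
    def test_caps_large_peptides_keeps_small(self):
        ds = Dataset(_positives(1, 150).records + _positives(2, 30).records[30:])
        out = balance_downsample(ds, cap=100, seed=0)
        counts = {p: len(ix) for p, ix in out.peptide_index.items()}
        assert sorted(counts.values()) == [30, 100]

    @pytest.mark.parametrize("cap", [1, 17, 100, 500])
    def test_per_peptide_counts_are_min_count_cap(self, cap):
        ds = _positives(4, 60)
        out = balance_downsample(ds, cap=cap, seed=3)
        for p, ix in out.peptide_index.items():
            assert len(ix) == min(60, cap)

    def test_order_independence(self):
        ds = _positives(3, 40)
        shuffled = Dataset(list(reversed(ds.records)))
        a = balance_downsample(ds, cap=10, seed=9)
        b = balance_downsample(shuffled, cap=10, seed=9)
        assert {r.pair for r in a} == {r.pair for r in b}


class TestAuditLeakage:
    def test_clean_partitions(self, toy_dataset):
        train = toy_dataset.subset([0, 1, 2])
        test = toy_dataset.subset([3, 4, 5])
        assert audit_leakage(train, test).clean

    def test_planted_conflict_detected(self, toy_dataset):
        train = toy_dataset.subset([0, 1, 2])
        leak = toy_dataset.records[0]
        bad = TCRRecord(leak.peptide, *leak.tcr, label=0)
        test = Dataset([bad] + list(toy_dataset.subset([3, 4]).records))
        rep = audit_leakage(train, test)
        assert not rep.clean and len(rep.conflicting_pairs) == 1

    def test_strict_split_always_audits_clean(self):
        ds = _positives(8, 6)
        for seed in range(5):
            plan = strict_split(ds, 4, seed)
            assigned = plan.apply(ds)
            tr = Dataset([r for r in assigned.records if r.partition != 0])
            te = Dataset([r for r in assigned.records if r.partition == 0])
            assert audit_leakage(tr, te, mode="strict").clean

    def test_strict_mode_flags_shared_peptides(self):
        ds = _positives(3, 4)
        rep = audit_leakage(ds.subset([0, 1]), ds.subset([2, 3]), mode="strict")
        assert not rep.clean and rep.shared_peptides


class TestBuildCVDataset:
    def test_fold_local_negatives_and_full_guard(self):
        ds = _positives(6, 20)
        plan = random_kfold(ds, 3, seed=0)
        full = build_cv_dataset(ds, plan, negative="shuffle", ratio=(1, 2), seed=1)
        pos_pairs = {r.pair for r in full.records if r.label == 1}
        for r in full.records:
            if r.label == 0:
                assert r.pair not in pos_pairs
                assert r.partition is not None

    def test_negative_tcrs_come_from_same_partition(self):
        ds = _positives(6, 20)
        plan = random_kfold(ds, 3, seed=0)
        full = build_cv_dataset(ds, plan, negative="shuffle", ratio=(1, 1), seed=1)
        tcrs_by_fold = {}
        for r in full.records:
            if r.label == 1:
                tcrs_by_fold.setdefault(r.partition, set()).add(r.tcr)
        for r in full.records:
            if r.label == 0:
                assert r.tcr in tcrs_by_fold[r.partition]
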