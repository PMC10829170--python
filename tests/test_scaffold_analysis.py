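"""Frequent-pattern mining, profile matrices, clustering and bit similarities."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ddikit as dk
from ddikit.chemio import Fingerprint
from ddikit.classifier import DDIExample
from ddikit.errors import DegenerateVectorError
from ddikit.scaffold_analysis import TransactionSet


def apriori_oracle(transactions, min_support):
    """Brute-force enumeration of every itemset over the item universe."""
    universe = sorted(set().union(*transactions)) if transactions else []
    n = len(transactions)
    out = {}
    for r in range(1, len(universe) + 1):
        for combo in combinations(universe, r):
            s = frozenset(combo)
            count = sum(1 for t in transactions if s <= t)
            if count / n >= min_support - 1e-12:
                out[s] = count / n
    return out


TOY = TransactionSet.from_iterables([{"A", "B"}, {"A", "B"}, {"A", "C"}, {"B"}])


class TestFPGrowth:
    def test_toy_worked_example(self):
        result = dict(dk.fp_growth(TOY, 0.5))
        assert result == {
            frozenset({"A"}): 0.75,
            frozenset({"B"}): 0.75,
            frozenset({"A", "B"}): 0.5,
        }

    def test_full_support_threshold(self):
        trans = TransactionSet.from_iterables([{"A", "B"}, {"A"}, {"A", "C"}])
        assert dict(dk.fp_growth(trans, 1.0)) == {frozenset({"A"}): 1.0}

    def test_no_empty_itemset_and_empty_result(self):
        trans = TransactionSet.from_iterables([{"A"}, {"B"}])
        result = dk.fp_growth(trans, 0.9)
        assert result == []
        assert all(len(i) > 0 for i, _ in dk.fp_growth(trans, 0.3))

    def test_min_support_bounds(self):
        with pytest.raises(ValueError):
            dk.fp_growth(TOY, 0.0)
        with pytest.raises(ValueError):
            dk.fp_growth(TOY, 1.5)

    def test_matches_apriori_on_random_transaction_sets(self):
        rng = np.random.default_rng(5)
        items = [chr(ord("a") + i) for i in range(10)]
        for trial in range(100):
            n_trans = int(rng.integers(3, 40))
            trans = [
                frozenset(rng.choice(items, size=rng.integers(1, 6), replace=False))
                for _ in range(n_trans)
            ]
            min_support = float(rng.choice([0.05, 0.1, 0.25, 0.5]))
            got = dict(dk.fp_growth(TransactionSet(tuple(trans)), min_support))
            want = apriori_oracle(trans, min_support)
            assert got.keys() == want.keys(), f"trial {trial}"
            for k in want:
                assert got[k] == pytest.approx(want[k])


class TestAssociationRules:
    def test_toy_hand_arithmetic(self):
        freq = dk.fp_growth(TOY, 0.5)
        rules = {
            (r.antecedent, r.consequent): r
            for r in dk.association_rules(freq, TOY, min_confidence=0.0)
        }
        r = rules[(frozenset({"A"}), frozenset({"B"}))]
        assert r.support == pytest.approx(0.5)
        assert r.confidence == pytest.approx(0.5 / 0.75)
        assert r.lift == pytest.approx((0.5 / 0.75) / 0.75)

    def test_perfect_cooccurrence_gives_confidence_one(self):
        trans = TransactionSet.from_iterables([{"X", "Y"}, {"X", "Y"}, {"Z"}])
        freq = dk.fp_growth(trans, 0.3)
        rules = dk.association_rules(freq, trans, 0.0)
        xy = next(r for r in rules if r.antecedent == {"X"} and r.consequent == {"Y"})
        assert xy.confidence == pytest.approx(1.0)

    def test_independent_items_have_unit_lift(self):
        # A in half the transactions, B in half, jointly in a quarter
        trans = TransactionSet.from_iterables(
            [{"A", "B"}, {"A"}, {"B"}, set("Q")]
        )
        freq = dk.fp_growth(trans, 0.25)
        rules = dk.association_rules(freq, trans, 0.0)
        ab = next(r for r in rules if r.antecedent == {"A"} and r.consequent == {"B"})
        assert ab.lift == pytest.approx(1.0)

    def test_min_confidence_filters(self):
        freq = dk.fp_growth(TOY, 0.5)
        assert dk.association_rules(freq, TOY, min_confidence=0.99) == []


PAIRS = [
    DDIExample("Cc1ccccc1", "CCc1ccncc1", 0),
    DDIExample("Cc1ccccc1", "CCc1ccncc1", 1),  # same scaffold combination
    DDIExample("CCO", "Cc1ccccc1", 1),
    DDIExample("NC1CCCCC1", "CCO", 0),
]


class TestProfileMatrix:
    def test_repeated_combination_stays_binary(self):
        m = dk.build_profile_matrix(PAIRS[:2], "interaction")
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == 1

    def test_interaction_matrix_matches_exhaustive_scan(self):
        m = dk.build_profile_matrix(PAIRS, "interaction")
        scaf = dk.murcko_scaffold
        hits = {(scaf(p.drug1_smiles), scaf(p.drug2_smiles)) for p in PAIRS}
        for i, r in enumerate(m.row_names):
            for j, c in enumerate(m.col_names):
                assert m.values[i, j] == int((r, c) in hits)

    def test_side_effect_mode_scaffolds_from_either_position(self):
        m = dk.build_profile_matrix(PAIRS, "side_effect")
        assert set(m.col_names) == {"label:0", "label:1"}
        benzene_row = m.values[m.row_names.index("c1ccccc1")]
        assert benzene_row.tolist() == [1, 1]

    def test_empty_input_gives_empty_matrix(self):
        m = dk.build_profile_matrix([], "interaction")
        assert m.values.shape == (0, 0)

    def test_invariant_to_duplicated_pairs(self):
        a = dk.build_profile_matrix(PAIRS, "interaction")
        b = dk.build_profile_matrix(PAIRS + PAIRS, "interaction")
        assert np.array_equal(a.values, b.values)
        assert a.row_names == b.row_names and a.col_names == b.col_names


def vec(*on, n=16):
    v = np.zeros(n, dtype=np.uint8)
    v[list(on)] = 1
    return v


class TestBitSimilarity:
    A = vec(0, 1, 2, 3)           # a = 4
    B = vec(1, 2, 3, 4, 5, 6)     # b = 6, c = 3

    def test_worked_values(self):
        assert dk.bit_similarity(self.A, self.B, "tanimoto") == pytest.approx(3 / 7)
        assert dk.bit_similarity(self.A, self.B, "dice") == pytest.approx(0.6)
        assert dk.bit_similarity(self.A, self.B, "kulczynski") == pytest.approx(0.625)
        assert dk.bit_similarity(self.A, self.B, "asymmetric") == pytest.approx(0.75)

    def test_rogot_goldberg_matches_rdkit(self):
        from rdkit import DataStructs

        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.integers(0, 2, size=64).astype(np.uint8)
            b = rng.integers(0, 2, size=64).astype(np.uint8)
            if a.sum() == 0 or b.sum() == 0 or a.sum() + b.sum() == 128:
                continue
            bva = DataStructs.CreateFromBitString("".join(map(str, a)))
            bvb = DataStructs.CreateFromBitString("".join(map(str, b)))
            assert dk.bit_similarity(a, b, "rogot_goldberg") == pytest.approx(
                DataStructs.RogotGoldbergSimilarity(bva, bvb), abs=1e-9
            )

    @pytest.mark.parametrize("metric", ["tanimoto", "dice", "kulczynski", "asymmetric"])
    def test_identical_vectors_score_one(self, metric):
        assert dk.bit_similarity(self.A, self.A, metric) == pytest.approx(1.0)

    def test_disjoint_vectors_score_zero(self):
        assert dk.bit_similarity(vec(0, 1), vec(2, 3), "tanimoto") == 0.0
        assert dk.bit_similarity(vec(0, 1), vec(2, 3), "dice") == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.booleans(), min_size=4, max_size=32),
           st.lists(st.booleans(), min_size=4, max_size=32))
    def test_symmetry_and_tanimoto_dice_order(self, xs, ys):
        n = max(len(xs), len(ys))
        a = np.zeros(n, dtype=np.uint8)
        b = np.zeros(n, dtype=np.uint8)
        a[: len(xs)] = xs
        b[: len(ys)] = ys
        for metric in ("tanimoto", "dice", "kulczynski", "asymmetric", "rogot_goldberg"):
            try:
                fwd = dk.bit_similarity(a, b, metric)
            except DegenerateVectorError:
                with pytest.raises(DegenerateVectorError):
                    dk.bit_similarity(b, a, metric)
                continue
            assert fwd == pytest.approx(dk.bit_similarity(b, a, metric))
        if a.sum() or b.sum():
            assert dk.bit_similarity(a, b, "tanimoto") <= dk.bit_similarity(a, b, "dice") + 1e-12

    def test_zero_denominator_raises(self):
        with pytest.raises(DegenerateVectorError):
            dk.bit_similarity(vec(), vec(), "tanimoto")
        with pytest.raises(DegenerateVectorError):
            dk.bit_similarity(vec(0), vec(), "asymmetric")


def profile(rows):
    arr = np.array(rows, dtype=np.uint8)
    return dk.ProfileMatrix(
        values=arr,
        row_names=[f"s{i}" for i in range(arr.shape[0])],
        col_names=[f"c{j}" for j in range(arr.shape[1])],
    )


class TestClusterBinaryProfiles:
    def test_duplicated_rows_co_cluster(self):
        labels = dk.cluster_binary_profiles(profile([[1, 1, 0], [1, 1, 0], [0, 0, 1]]))
        assert labels[0] == labels[1]

    def test_orthogonal_rows_become_singletons_under_strict_threshold(self):
        labels = dk.cluster_binary_profiles(
            profile(np.eye(4, dtype=np.uint8)), threshold=0.5, criterion="distance"
        )
        assert len(set(labels)) == 4

    def test_five_row_hand_traced_partition(self):
        # two tight families {r0,r1,r2} and {r3,r4}; the bridging merge at
        # Jaccard distance 1 is inconsistent and is cut
        rows = [
            [1, 1, 0, 0, 0, 0],
            [1, 1, 0, 0, 0, 0],
            [1, 1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1, 0],
            [0, 0, 0, 1, 1, 1],
        ]
        labels = dk.cluster_binary_profiles(profile(rows), threshold=1.0)
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4]
        assert labels[0] != labels[3]

    def test_all_zero_rows_singleton_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            labels = dk.cluster_binary_profiles(profile([[1, 1, 0], [0, 0, 0], [1, 1, 0]]))
        assert labels[0] == labels[2] != labels[1]
        assert any("all-zero" in r.message for r in caplog.records)


class TestClusterSimilaritySummary:
    def test_identical_fingerprints_intra_one(self):
        fp = Fingerprint(bits=vec(0, 3, 5), n_bits=16, radius=0)
        intra, _, table = dk.cluster_similarity_summary(np.array([1, 1, 1]), [fp, fp, fp])
        assert intra == pytest.approx(1.0)
        assert table["n_pairs"].sum() == 3

    def test_block_structured_families_intra_above_inter(self):
        fam1 = [Fingerprint(vec(0, 1, 2, i), 16, 0) for i in (3, 4, 5)]
        fam2 = [Fingerprint(vec(10, 11, 12, i), 16, 0) for i in (13, 14, 15)]
        labels = np.array([1, 1, 1, 2, 2, 2])
        intra, inter, _ = dk.cluster_similarity_summary(labels, fam1 + fam2)
        assert intra > inter

    def test_pair_count_combinatorics(self):
        fps = [Fingerprint(vec(i), 16, 0) for i in range(6)]
        labels = np.array([1, 1, 1, 2, 2, 3])
        _, _, table = dk.cluster_similarity_summary(labels, fps)
        assert table["n_pairs"].sum() == 3 + 1 + 0

    def test_all_singletons_rejected(self):
        fps = [Fingerprint(vec(i), 16, 0) for i in range(3)]
        with pytest.raises(ValueError):
            dk.cluster_similarity_summary(np.array([1, 2, 3]), fps)
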