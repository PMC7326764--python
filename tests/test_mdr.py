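import itertools

import numpy as np
import pytest

from strokenet import (CohortSimSpec, GenotypeMatrix, MdrClassifier,
                       entropy_graph, mdr_cross_validate, mdr_fit,
                       mdr_permutation_test, mdr_search, simulate_epistasis,
                       xor_penetrance)
from strokenet.mdr import MdrError


def _gm(dosages, snp_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    snp_ids = snp_ids or [f"rs{j}" for j in range(dosages.shape[1])]
    subjects = [f"s{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(subjects, snp_ids, dosages)


def brute_force_mdr(X, y):
    """Independent cell-by-cell oracle for the MDR labeling and pooled table."""
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    cells = {}
    for row, yi in zip(map(tuple, X.astype(int)), y):
        c = cells.setdefault(row, [0, 0])
        c[0 if yi == 1 else 1] += 1
    labels = {}
    for cell, (nc, nn) in cells.items():
        # ratio >= T with controls=0 -> high; ties -> high
        labels[cell] = "high" if nc / max(nn, 1e-300) >= n1 / n0 else "low"
    a = sum(nc for cell, (nc, nn) in cells.items() if labels[cell] == "high")
    b = sum(nn for cell, (nc, nn) in cells.items() if labels[cell] == "high")
    c = n1 - a
    d = n0 - b
    return labels, np.array([[a, b], [c, d]], dtype=float)


class TestMdrFit:
    def test_hand_enumerated_single_snp(self):
        # cells (10 cases/2 ctrl, 5/5, 2/10); T = 17/17 = 1
        dos = [0] * 12 + [1] * 10 + [2] * 12
        y = np.array([1] * 10 + [0] * 2 + [1] * 5 + [0] * 5 + [1] * 2 + [0] * 10)
        m = mdr_fit(_gm(np.array(dos)[:, None]), y, ["rs0"])
        np.testing.assert_array_equal(m.classifier.cell_high_, [True, True, False])
        assert m.odds_ratio == pytest.approx(150 / 14)
        np.testing.assert_array_equal(m.classifier.pooled_table_, [[15, 7], [2, 10]])

    def test_all_cells_tied_all_high_degenerate_or(self):
        dos = [0] * 10 + [1] * 10
        y = np.array(([1] * 5 + [0] * 5) * 2)
        m = mdr_fit(_gm(np.array(dos)[:, None]), y, ["rs0"])
        assert m.classifier.cell_high_[:2].all()
        assert m.classifier.degenerate_ and np.isnan(m.odds_ratio)

    def test_empty_attribute_list_rejected(self, tiny_genotypes):
        with pytest.raises(MdrError):
            mdr_fit(tiny_genotypes, np.array([1, 0, 1, 0]), [])

    def test_matches_brute_force_enumeration(self):
        """Labeling and pooled table equal the cell-by-cell oracle (200 instances)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(1, 4)
            n = rng.integers(10, 61)
            X = rng.integers(0, 3, size=(n, k))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            clf = MdrClassifier().fit(X, y)
            labels, pooled = brute_force_mdr(X, y)
            for cell, lab in labels.items():
                code = 0
                for v in cell:
                    code = code * 3 + v
                assert clf.cell_high_[code] == (lab == "high")
            np.testing.assert_array_equal(clf.pooled_table_, pooled)

    def test_or_invariant_to_subject_and_column_order(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(120, 2))
        y = rng.integers(0, 2, size=120)
        g1 = _gm(X, ["rsA", "rsB"])
        m1 = mdr_fit(g1, y, ["rsA", "rsB"])
        perm = rng.permutation(120)
        g2 = _gm(X[perm], ["rsA", "rsB"])
        m2 = mdr_fit(g2, y[perm], ["rsA", "rsB"])
        m3 = mdr_fit(g1, y, ["rsB", "rsA"])
        assert m1.odds_ratio == pytest.approx(m2.odds_ratio)
        assert m1.odds_ratio == pytest.approx(m3.odds_ratio)

    def test_training_balanced_accuracy_at_least_half(self):
        rng = np.random.default_rng(2)
        for _ in range(50)        :
            X = rng.integers(0, 3, size=(40, 2))
            y = rng.integers(0, 2, size=40)
            if y.sum() in (0, 40):
                continue
            clf = MdrClassifier().fit(X, y)
            assert clf.balanced_accuracy_ >= 0.5 - 1e-12

    def test_woolf_ci_contains_or(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(300, 2))
        y = rng.integers(0, 2, size=300)
        m = mdr_fit(_gm(X), y, ["rs0", "rs1"])
        if not m.classifier.degenerate_:
            assert m.or_ci[0] <= m.odds_ratio <= m.or_ci[1]


class TestCrossValidation:
    def test_perfect_separator_scores_one(self):
        dos = np.array([0] * 50 + [2] * 50, dtype=float)[:, None]
        y = np.array([1] * 50 + [0] * 50)
        cv = mdr_cross_validate(_gm(dos), y, ["rs0"], n_folds=10, seed=0)
        assert cv["testing_accuracy"] == pytest.approx(1.0)
        assert all(a == pytest.approx(1.0) for a in cv["fold_test_accuracy"])

    def test_null_labels_near_chance(self):
        """Permuted labels give mean testing accuracy ~0.5 across seeds."""
        spec = CohortSimSpec(seed=5, mafs=[0.3, 0.4],
                             penetrance=xor_penetrance(["rs9000000", "rs9000001"],
                                                       low=0.5, high=0.5))
        g, _ = simulate_epistasis(spec, n_subjects=1000)
        accs = []
        rng = np.random.default_rng(6)
        for seed in range(20):
            y = rng.permutation(np.repeat([0, 1], 500))
            cv = mdr_cross_validate(g, y, ["rs9000000", "rs9000001"],
                                    n_folds=10, seed=seed)
            accs.append(cv["testing_accuracy"])
        assert 0.45 <= np.mean(accs) <= 0.55

    def test_seed_fixes_folds_and_accuracies(self):
        rng = np.random.default_rng(7)
        g = _gm(rng.integers(0, 3, size=(200, 2)))
        y = rng.integers(0, 2, size=200)
        cv1 = mdr_cross_validate(g, y, ["rs0", "rs1"], seed=11)
        cv2 = mdr_cross_validate(g, y, ["rs0", "rs1"], seed=11)
        np.testing.assert_array_equal(cv1["fold_assignment"], cv2["fold_assignment"])
        assert cv1["fold_test_accuracy"] == cv2["fold_test_accuracy"]


class TestSearch:
    def test_subset_count_and_cap(self):
        rng = np.random.default_rng(8)
        g = _gm(rng.integers(0, 3, size=(100, 14)))
        y = rng.integers(0, 2, size=100)
        assert len(list(itertools.combinations(range(14), 2))) == 91
        models = mdr_search(g, y, k_min=2, k_max=2, n_folds=5, seed=0)
        assert len(models) == 1 and len(models[0].attributes) == 2
        with pytest.raises(MdrError, match="cap"):
            mdr_search(g, y, k_min=2, k_max=2, seed=0, max_subsets=10)

    def test_planted_xor_pair_ranked_first(self):
        """Pure two-locus epistasis is recovered as the best k=2 model."""
        hits = 0
        for seed in range(20):
            spec = CohortSimSpec(seed=seed, mafs=[0.5, 0.5] + [0.3] * 10,
                                 penetrance=xor_penetrance(
                                     ["rs9000000", "rs9000001"], low=0.3, high=0.7))
            g, status = simulate_epistasis(spec, n_subjects=1600)
            best = mdr_search(g, status, k_min=2, k_max=2, n_folds=10,
                              seed=1000 + seed)[0]
            hits += set(best.attributes) == {"rs9000000", "rs9000001"}
        assert hits >= 18

    def test_cvc_bounded_by_folds(self):
        rng = np.random.default_rng(9)
        g = _gm(rng.integers(0, 3, size=(200, 4)))
        y = rng.integers(0, 2, size=200)
        models = mdr_search(g, y, k_min=1, k_max=2, n_folds=10, seed=3)
        assert all(0 <= m.cvc <= 10 for m in models)


class TestPermutationTest:
    def test_formula_floor(self):
        """An observed statistic beating all 99 permutations gives p = 0.01."""
        dos = np.array([0] * 80 + [2] * 80, dtype=float)[:, None]
        y = np.array([1] * 80 + [0] * 80)
        g = _gm(dos)
        model = mdr_search(g, y, k_min=1, k_max=1, n_folds=5, seed=0)[0]
        p = mdr_permutation_test(g, y, model, n_perm=99, seed=1, n_folds=5)
        assert p == pytest.approx(1 / 100)

    def test_too_few_permutations_rejected(self):
        dos = np.array([0, 1, 2, 0, 1, 2], dtype=float)[:, None]
        y = np.array([1, 0, 1, 0, 1, 0])
        g = _gm(dos)
        model = mdr_search(g, y, k_min=1, k_max=1, n_folds=2, seed=0)[0]
        with pytest.raises(MdrError):
            mdr_permutation_test(g, y, model, n_perm=10)

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(10)
        g = _gm(rng.integers(0, 3, size=(300, 3)))
        y = rng.integers(0, 2, size=300)
        model = mdr_search(g, y, k_min=1, k_max=2, n_folds=5, seed=4)[0]
        p = mdr_permutation_test(g, y, model, n_perm=39, seed=5, n_folds=5)
        assert p > 0.025  # null data should not look significant


class TestEntropyGraph:
    def test_hand_computed_information_gain(self):
        # balanced 8/8; SNP cells (4 cases/0, 0/4, 4/4) -> IG = 0.5 bits = 50%
        dos = np.array([0] * 4 + [1] * 4 + [2] * 8, dtype=float)[:, None]
        y = np.array([1] * 4 + [0] * 4 + [1] * 4 + [0] * 4)
        eg = entropy_graph(_gm(dos), y, ["rs0"])
        assert eg.class_entropy == pytest.approx(1.0)
        assert eg.info_gain["rs0"] == pytest.approx(0.5)
        assert eg.info_gain_pct["rs0"] == pytest.approx(50.0)

    def test_independent_snp_zero_gain(self):
        # proportional counts: each genotype 50/50 cases/controls
        dos = np.repeat([0, 1, 2], 20).astype(float)[:, None]
        y = np.tile([1, 0], 30)
        eg = entropy_graph(_gm(dos), y, ["rs0"])
        assert eg.info_gain["rs0"] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_snp_is_redundant(self):
        rng = np.random.default_rng(11)
        col = rng.integers(0, 3, size=200).astype(float)
        y = (col + rng.integers(0, 2, 200) >= 2).astype(int)
        g = _gm(np.column_stack([col, col]), ["rsA", "rsB"])
        eg = entropy_graph(g, y)
        assert eg.pairwise_gain[("rsA", "rsB")] < 0

    def test_gain_bounds_and_mi_decomposition(self):
        """0 <= IG <= H(C) and the decomposition equals direct MI summation."""
        rng = np.random.default_rng(12)
        X = rng.integers(0, 3, size=(300, 3))
        y = rng.integers(0, 2, size=300)
        eg = entropy_graph(_gm(X), y)
        for snp, ig in eg.info_gain.items():
            assert -1e-12 <= ig <= eg.class_entropy + 1e-12
            j = int(snp[2:])
            # direct double summation of I(A;C)
            mi = 0.0
            n = len(y)
            for a in range(3):
                for c in range(2):
                    pj = np.sum((X[:, j] == a) & (y == c)) / n
                    pa = np.sum(X[:, j] == a) / n
                    pc = np.sum(y == c) / n
                    if pj > 0:
                        mi += pj * np.log2(pj / (pa * pc))
            assert ig == pytest.approx(mi, abs=1e-12)

    def test_zero_entropy_class_rejected(self, tiny_genotypes):
        with pytest.raises(MdrError, match="entropy"):
            entropy_graph(tiny_genotypes, np.ones(4, dtype=int))

    def test_xor_pure_epistasis_signature(self):
        """Flat-margin XOR: single-SNP IG ~ 0, pairwise synergy > 0."""
        spec = CohortSimSpec(seed=13, mafs=[0.5, 0.5, 0.3],
                             penetrance=xor_penetrance(
                                 ["rs9000000", "rs9000001"], low=0.2, high=0.8))
        g, status = simulate_epistasis(spec, n_subjects=4000)
        eg = entropy_graph(g, status)
        assert eg.info_gain_pct["rs9000000"] < 1.0
        assert eg.info_gain_pct["rs9000001"] < 1.0
        assert eg.pairwise_gain_pct[("rs9000000", "rs9000001")] > 5.0

    def test_newick_dendrogram_contains_all_snps(self):
        rng = np.random.default_rng(14)
        g = _gm(rng.integers(0, 3, size=(200, 4)))
        y = rng.integers(0, 2, size=200)
        nwk = entropy_graph(g, y).to_newick()
        assert nwk.endswith(";")
        for snp in g.snp_ids:
            assert snp in nwk
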