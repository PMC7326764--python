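"""Multifactor dimensionality reduction (MDR) for SNP-SNP interaction search.

MDR pools the multilocus genotype cells of a k-SNP subset into a single
binary attribute: each cell is labeled high-risk when its case:control
ratio is at least the dataset-wide threshold T = total cases / total
controls (ties -> high; a cell with cases but no controls -> high), and
low-risk otherwise.  The labeling is a classifier (high -> predicted case),
scored by balanced accuracy, cross-validated with stratified 10-fold CV,
and ranked over exhaustive subsets of each size.  Significance of the best
model comes from a label-permutation ("substitution") test.  Entropy-based
information gain quantifies each SNP's main effect and each pair's synergy
or redundancy relative to case status.

``MdrClassifier`` follows the scikit-learn estimator contract (fit/predict,
get_params/set_params, trailing-underscore fitted attributes) and composes
with sklearn model selection; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io_cohort import GenotypeMatrix

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # normal 97.5% quantile for the Woolf interval


class MdrError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cell machinery


def _encode_cells(X: np.ndarray) -> np.ndarray:
    """Map each row of a (n, k) dosage matrix to a base-3 cell index."""
    X = np.asarray(X)
    code = np.zeros(X.shape[0], dtype=np.int64)
    for j in range(X.shape[1]):
        code = code * 3 + X[:, j].astype(np.int64)
    return code


def _cell_counts(code: np.ndarray, y: np.ndarray, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    cases = np.bincount(code[y == 1], minlength=n_cells)
    controls = np.bincount(code[y == 0], minlength=n_cells)
    return cases, controls


def _label_cells(cases: np.ndarray, controls: np.ndarray,
                 n_case: int, n_control: int) -> tuple[np.ndarray, np.ndarray]:
    """(high, empty) boolean masks per cell under the ratio-vs-threshold rule.

    high iff cases/controls >= T = n_case/n_control, evaluated without
    division so that a cases>0/controls=0 cell is high and ties go high.
    """
    occupied = (cases + controls) > 0
    high = occupied & (cases * n_control >= controls * n_case)
    return high, ~occupied


def _balanced_accuracy(code: np.ndarray, y: np.ndarray, high: np.ndarray) -> float:
    pred = high[code]
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    sens = (pred & (y == 1)).sum() / n1 if n1 else np.nan
    spec = (~pred & (y == 0)).sum() / n0 if n0 else np.nan
    return float((sens + spec) / 2.0)


# ---------------------------------------------------------------------------
# estimator


class MdrClassifier(BaseEstimator, ClassifierMixin):
    """MDR cell-labeling rule as a scikit-learn binary classifier.

    Fit on a (n_subjects, k) matrix of 0/1/2 dosages and a 0/1 case vector;
    ``predict`` maps each subject's multilocus genotype cell to 1 (high-risk)
    or 0 (low-risk / unseen cell).

    Attributes (after fit)
    ----------------------
    threshold_ : float
        Case:control ratio threshold T.
    cell_cases_, cell_controls_ : ndarray
        Counts per multilocus cell (length 3**k).
    cell_high_, cell_empty_ : ndarray of bool
        High-risk and empty masks per cell.
    pooled_table_ : ndarray (2, 2)
        [[cases_high, controls_high], [cases_low, controls_low]].
    odds_ratio_, or_ci_, chi2_p_ : pooled-table statistics (Woolf CI).
    balanced_accuracy_ : training balanced accuracy of the labeling.
    """

    def __init__(self, haldane: bool = True):
        self.haldane = haldane

    def fit(self, X, y) -> "MdrClassifier":
        X = np.asarray(X)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or X.shape[1] == 0:
            raise MdrError("X must be a (n, k) dosage matrix with k >= 1")
        if np.isnan(np.asarray(X, dtype=float)).any():
            raise MdrError("missing genotypes must be removed before MDR fitting")
        if not set(np.unique(y)) <= {0, 1}:
            raise MdrError("y must be 0/1 case status")
        n1, n0 = int((y == 1).sum()), int((y == 0).sum())
        if n1 == 0 or n0 == 0:
            raise MdrError("both cases and controls are required")
        k = X.shape[1]
        n_cells = 3 ** k
        code = _encode_cells(X)
        cases, controls = _cell_counts(code, y, n_cells)
        high, empty = _label_cells(cases, controls, n1, n0)

        self.n_features_in_ = k
        self.classes_ = np.array([0, 1])
        self.threshold_ = n1 / n0
        self.cell_cases_, self.cell_controls_ = cases, controls
        self.cell_high_, self.cell_empty_ = high, empty
        low = ~high & ~empty
        a, b = int(cases[high].sum()), int(controls[high].sum())
        c, d = int(cases[low].sum()), int(controls[low].sum())
        self.pooled_table_ = np.array([[a, b], [c, d]], dtype=float)
        self.degenerate_ = (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0)
        self.zero_cell_corrected_ = False
        if self.degenerate_:
            self.odds_ratio_ = np.nan
            self.or_ci_ = (np.nan, np.nan)
            self.chi2_p_ = np.nan
        else:
            ta, tb, tc, td = float(a), float(b), float(c), float(d)
            if self.haldane and 0 in (a, b, c, d):
                ta, tb, tc, td = a + 0.5, b + 0.5, c + 0.5, d + 0.5
                self.zero_cell_corrected_ = True
            self.odds_ratio_ = (ta * td) / (tb * tc)
            se = np.sqrt(1 / ta + 1 / tb + 1 / tc + 1 / td)
            self.or_ci_ = (float(np.exp(np.log(self.odds_ratio_) - _Z95 * se)),
                           float(np.exp(np.log(self.odds_ratio_) + _Z95 * se)))
            chi2, p, _, _ = stats.chi2_contingency(self.pooled_table_, correction=False)
            self.chi2_p_ = float(p)
        self.balanced_accuracy_ = _balanced_accuracy(code, y, high)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cell_high_")
        code = _encode_cells(np.asarray(X))
        return self.cell_high_[code].astype(int)

    def score(self, X, y) -> float:
        """Balanced accuracy of the high/low labeling on (X, y)."""
        code = _encode_cells(np.asarray(X))
        return _balanced_accuracy(code, np.asarray(y).astype(int), self.cell_high_)


@dataclass
class MdrModel:
    """One attribute subset with its labeling and evaluation statistics."""

    attributes: tuple[str, ...]
    classifier: MdrClassifier
    training_accuracy: float
    testing_accuracy: float | None = None
    cvc: int | None = None
    n_folds: int | None = None
    permutation_p: float | None = None
    fold_accuracies: list[float] = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        return self.classifier.odds_ratio_

    @property
    def or_ci(self) -> tuple[float, float]:
        return self.classifier.or_ci_

    @property
    def chi2_p(self) -> float:
        return self.classifier.chi2_p_


# ---------------------------------------------------------------------------
# module-level operations


def _select(g: GenotypeMatrix, status: np.ndarray, attributes: list[str]):
    idx = [g.snp_ids.index(a) if a in g.snp_ids else None for a in attributes]
    if None in idx:
        raise MdrError(f"unknown SNP in attribute set: {attributes[idx.index(None)]}")
    X = g.dosages[:, idx]
    y = np.asarray(status).astype(float)
    keep = ~np.isnan(X).any(axis=1) & np.isfinite(y)
    return X[keep].astype(int), y[keep].astype(int)


def mdr_fit(g: GenotypeMatrix, status: np.ndarray, attributes: list[str]) -> MdrModel:
    """Fit the MDR labeling for one attribute subset on the full data."""
    if not attributes:
        raise MdrError("empty attribute list")
    if not 1 <= len(attributes) <= 4:
        raise MdrError("attribute subsets of size 1..4 are supported")
    X, y = _select(g, status, attributes)
    clf = MdrClassifier().fit(X, y)
    return MdrModel(tuple(attributes), clf, training_accuracy=clf.balanced_accuracy_)


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per subject, stratified by case status."""
    fold = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _cv_matrices(code: np.ndarray, y: np.ndarray, fold: np.ndarray, n_folds: int,
                 n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """(train_accuracy, test_accuracy) per fold for one cell encoding."""
    train_acc = np.empty(n_folds)
    test_acc = np.empty(n_folds)
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        n1, n0 = (y[tr] == 1).sum(), (y[tr] == 0).sum()
        cases, controls = _cell_counts(code[tr], y[tr], n_cells)
        high, _ = _label_cells(cases, controls, n1, n0)  # unseen cells -> low
        train_acc[f] = _balanced_accuracy(code[tr], y[tr], high)
        test_acc[f] = _balanced_accuracy(code[te], y[te], high)
    return train_acc, test_acc


def mdr_cross_validate(g: GenotypeMatrix, status: np.ndarray, attributes: list[str],
                       n_folds: int = 10, seed: int | None = None) -> dict:
    """Stratified k-fold CV of one attribute subset.

    Cells unseen in a training split are predicted low-risk on the held-out
    fold.  If a fold ends up single-class the data are refolded with a new
    derived seed (logged).
    """
    if n_folds < 2:
        raise MdrError("n_folds must be >= 2")
    X, y = _select(g, status, attributes)
    n_cells = 3 ** X.shape[1]
    code = _encode_cells(X)
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        fold = _stratified_folds(y, n_folds, rng)
        ok = all(len(np.unique(y[fold == f])) == 2 for f in range(n_folds))
        if ok:
            break
        logger.warning("fold with a single class; refolding (attempt %d)", attempt + 1)
    else:
        raise MdrError("could not build folds with both classes present")
    train_acc, test_acc = _cv_matrices(code, y, fold, n_folds, n_cells)
    return {
        "attributes": tuple(attributes),
        "fold_train_accuracy": train_acc.tolist(),
        "fold_test_accuracy": test_acc.tolist(),
        "testing_accuracy": float(test_acc.mean()),
        "fold_assignment": fold,
    }


def mdr_search(g: GenotypeMatrix, status: np.ndarray, k_min: int = 1, k_max: int = 3,
               n_folds: int = 10, seed: int | None = None,
               max_subsets: int = 20000) -> list[MdrModel]:
    """Exhaustive MDR search over all attribute subsets of sizes k_min..k_max.

    Every subset is cross-validated on one shared stratified fold assignment;
    the best model per size is the one with the highest mean testing balanced
    accuracy, with cross-validation consistency (CVC) counting the folds in
    which that subset had the best within-fold training accuracy.  The
    returned list holds the best model per size, sorted best-first by testing
    accuracy (CVC breaks ties).
    """
    total = sum(len(list(itertools.combinations(range(g.n_snps), k)))
                for k in range(k_min, k_max + 1))
    if total > max_subsets:
        raise MdrError(f"{total} subsets exceeds the cap {max_subsets}; reduce k_max")
    y_full = np.asarray(status).astype(float)
    rng = np.random.default_rng(seed)
    best_per_k: list[MdrModel] = []
    for k in range(k_min, k_max + 1):
        subsets = list(itertools.combinations(range(g.n_snps), k))
        n_cells = 3 ** k
        results = []  # (mean_test, subset, per-fold train accuracy vector)
        fold_cache: dict[tuple, np.ndarray] = {}
        for subset in subsets:
            X = g.dosages[:, list(subset)]
            keep = ~np.isnan(X).any(axis=1) & np.isfinite(y_full)
            Xk, yk = X[keep].astype(int), y_full[keep].astype(int)
            key = tuple(np.flatnonzero(keep))
            if key not in fold_cache:
                sub_rng = np.random.default_rng(rng.integers(2**31 - 1))
                fold_cache[key] = _stratified_folds(yk, n_folds, sub_rng)
            fold = fold_cache[key]
            code = _encode_cells(Xk)
            train_acc, test_acc = _cv_matrices(code, yk, fold, n_folds, n_cells)
            results.append((float(test_acc.mean()), subset, train_acc, test_acc))
        # within-fold best by training accuracy -> CVC
        train_matrix = np.array([r[2] for r in results])         # (n_subsets, n_folds)
        fold_best = train_matrix.argmax(axis=0)
        best_i = int(np.argmax([r[0] for r in results]))
        cvc = int((fold_best == best_i).sum())
        mean_test, subset, _, test_acc = results[best_i]
        attrs = [g.snp_ids[j] for j in subset]
        model = mdr_fit(g, status, attrs)
        model.testing_accuracy = mean_test
        model.cvc = cvc
        model.n_folds = n_folds
        model.fold_accuracies = test_acc.tolist()
        best_per_k.append(model)
    best_per_k.sort(key=lambda m: (m.testing_accuracy, m.cvc), reverse=True)
    return best_per_k


def mdr_permutation_test(g: GenotypeMatrix, status: np.ndarray, model: MdrModel,
                         n_perm: int = 1000, seed: int | None = None,
                         k_min: int | None = None, k_max: int | None = None,
                         n_folds: int = 10) -> float:
    """Substitution (label-permutation) test for the best model.

    The full search statistic — best mean testing accuracy over all subsets
    of the searched sizes — is recomputed under each permutation of the case
    labels; p = (1 + #perm >= observed) / (n_perm + 1).
    """
    if n_perm < 19:
        raise MdrError("n_perm must be >= 19 to resolve alpha = 0.05")
    k = len(model.attributes)
    k_min = k if k_min is None else k_min
    k_max = k if k_max is None else k_max
    observed = model.testing_accuracy
    if observed is None:
        raise MdrError("model must carry a cross-validated testing accuracy")
    rng = np.random.default_rng(seed)
    y = np.asarray(status).astype(int)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        best = mdr_search(g, perm, k_min=k_min, k_max=k_max, n_folds=n_folds,
                          seed=int(rng.integers(2**31 - 1)))[0]
        if best.testing_accuracy >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# entropy-based interaction graph


def _entropy_bits(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum()
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


@dataclass
class EntropyGraph:
    """Class entropy, per-SNP information gain, and pairwise synergy.

    Gains are in bits and as a percentage of the class entropy H(C);
    positive pairwise values indicate synergy, negative redundancy.
    """

    attributes: list[str]
    class_entropy: float                               # H(C), bits
    info_gain: dict[str, float]                        # I(A;C), bits
    pairwise_gain: dict[tuple[str, str], float]        # I(A,B;C)-I(A;C)-I(B;C), bits
    linkage_matrix: np.ndarray | None = None

    @property
    def info_gain_pct(self) -> dict[str, float]:
        return {a: 100.0 * v / self.class_entropy for a, v in self.info_gain.items()}

    @property
    def pairwise_gain_pct(self) -> dict[tuple[str, str], float]:
        return {k: 100.0 * v / self.class_entropy for k, v in self.pairwise_gain.items()}

    def to_newick(self) -> str:
        """Interaction dendrogram (average linkage) as a Newick string."""
        if self.linkage_matrix is None:
            raise MdrError("dendrogram requires >= 2 attributes")
        names = self.attributes
        Z = self.linkage_matrix
        n = len(names)

        def node(i: int) -> str:
            if i < n:
                return names[i]
            a, b, dist, _ = Z[i - n]
            return f"({node(int(a))},{node(int(b))}):{dist:.6g}"

        return node(2 * n - 2) + ";"


def _mutual_information(code: np.ndarray, y: np.ndarray, n_cells: int) -> float:
    """I(A;C) in bits via H(C) - H(C|A) on empirical counts."""
    h_c = _entropy_bits(np.bincount(y, minlength=2))
    n = len(y)
    h_c_given = 0.0
    cases, controls = _cell_counts(code, y, n_cells)
    for c1, c0 in zip(cases, controls):
        tot = c1 + c0
        if tot:
            h_c_given += (tot / n) * _entropy_bits(np.array([c1, c0]))
    return h_c - h_c_given


def entropy_graph(g: GenotypeMatrix, status: np.ndarray,
                  attributes: list[str] | None = None,
                  dendro_eps: float = 1e-6) -> EntropyGraph:
    """Information-gain decomposition of SNP main effects and pair synergies."""
    attributes = attributes or list(g.snp_ids)
    if not attributes:
        raise MdrError("at least one attribute required")
    X, y = _select(g, status, attributes)
    if len(np.unique(y)) < 2:
        raise MdrError("class entropy is zero (all case or all control)")
    h_c = _entropy_bits(np.bincount(y, minlength=2))
    single = {}
    codes = {}
    for j, a in enumerate(attributes):
        codes[a] = X[:, j].astype(np.int64)
        single[a] = _mutual_information(codes[a], y, 3)
    pairwise = {}
    for a, b in itertools.combinations(attributes, 2):
        joint = codes[a] * 3 + codes[b]
        ig_joint = _mutual_information(joint, y, 9)
        pairwise[(a, b)] = ig_joint - single[a] - single[b]
    link = None
    if len(attributes) >= 2:
        syn = np.zeros((len(attributes), len(attributes)))
        for (a, b), v in pairwise.items():
            i, j = attributes.index(a), attributes.index(b)
            syn[i, j] = syn[j, i] = v
        min_syn = min(pairwise.values())
        dist = 1.0 / (syn - min_syn + dendro_eps)
        np.fill_diagonal(dist, 0.0)
        link = linkage(squareform(dist, checks=False), method="average")
    return EntropyGraph(list(attributes), h_c, single, pairwise, link)
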