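"""Exhaustive k-way MDR search over genotype cells with cross-validation.

The procedure collapses each k-SNP genotype table (k = 1-3) to a binary
high/low-risk attribute: a cell is high-risk when the residual scores of
the training subjects falling in it sum to a positive value. Model quality
is a score-mass balanced accuracy: with P the total positive score mass
and N the total negative mass, sensitivity is the positive mass captured
by high-risk cells / P, specificity the negative mass captured by low-risk
cells / N, and BA their average. A 5-fold cross-validation scores every
combination per fold; the run-best model is selected either by testing
balanced accuracy (TBA) or by cross-validation consistency (CVC) with the
earliest-in-file tie-break, and repeated runs with fresh fold partitions
are summarised by the most frequent (SNPs + high-cell set) consensus.

The enumeration is lexicographic over current column order and evaluated
in chunks with one weighted bincount per chunk, so results are independent
of chunk size and the 2-/3-way scans stay vectorised.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

from .types import (
    DataError,
    FoldResult,
    GenotypeMatrix,
    RiskModel,
    RunResult,
    TopModel,
    UninformativeScoresError,
)

from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "count_combinations",
    "make_cv_folds",
    "classify_cells",
    "balanced_accuracy",
    "cv_search",
    "repeated_search",
    "MDRSearch",
]

DEFAULT_CHUNK = 4096


def count_combinations(n_snps: int, orders) -> int:
    """Number of distinct k-SNP combinations summed over the given orders."""
    orders = sorted(set(int(k) for k in np.atleast_1d(list(orders))))
    if not orders:
        raise DataError("no interaction orders given")
    if max(orders) > n_snps:
        raise DataError("interaction order exceeds the number of SNPs")
    if min(orders) < 1:
        raise DataError("interaction orders must be positive")
    return sum(comb(int(n_snps), k) for k in orders)


def make_cv_folds(n_subjects: int, n_folds: int = 5, seed=None, stratify=None) -> np.ndarray:
    """Random partition into folds of size floor(n/f) or ceil(n/f).

    ``stratify`` (optional binary array, e.g. the event indicator) balances
    the strata across folds; off by default.
    """
    if n_subjects < n_folds:
        raise DataError("fewer subjects than folds")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n_subjects, dtype=np.int64)
    if stratify is None:
        perm = rng.permutation(n_subjects)
        fold_of[perm] = np.arange(n_subjects) % n_folds
    else:
        stratify = np.asarray(stratify)
        for level in np.unique(stratify):
            idx = np.flatnonzero(stratify == level)
            perm = rng.permutation(idx)
            fold_of[perm] = np.arange(len(idx)) % n_folds
    return fold_of


def _resolve_matrix(geno):
    """Accept a GenotypeMatrix or a plain dosage array."""
    if isinstance(geno, GenotypeMatrix):
        if np.any(geno.dosage < 0):
            raise DataError("missing genotypes present; run QC first")
        return geno.dosage.astype(np.int8, copy=False), np.asarray(geno.snp_ids, dtype=object)
    d = np.asarray(geno)
    if np.any((d < 0) | (d > 2)):
        raise DataError("dosages must be in {0,1,2}")
    ids = np.array([f"snp{j}" for j in range(d.shape[1])], dtype=object)
    return d.astype(np.int8, copy=False), ids


def _cell_codes(dosage: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """(n, n_combos) base-3 cell codes; first SNP is the most significant digit."""
    codes = dosage[:, combos[:, 0]].astype(np.int64)
    for j in range(1, combos.shape[1]):
        codes = codes * 3 + dosage[:, combos[:, j]]
    return codes


def _cell_masses(codes: np.ndarray, pos_w: np.ndarray, neg_w: np.ndarray, ncells: int):
    """Per-combo, per-cell positive and negative score mass via one bincount each."""
    n, nc = codes.shape
    offset = codes + (np.arange(nc, dtype=np.int64) * ncells)[None, :]
    flat = offset.ravel()
    length = nc * ncells
    pos = np.bincount(flat, weights=np.repeat(pos_w, nc), minlength=length).reshape(-1, ncells) if n else np.zeros((nc, ncells))
    neg = np.bincount(flat, weights=np.repeat(neg_w, nc), minlength=length).reshape(-1, ncells) if n else np.zeros((nc, ncells))
    return pos, neg


def _code_to_cell(code: int, k: int) -> tuple:
    code = int(code)
    digits = []
    for _ in range(k):
        digits.append(code % 3)
        code //= 3
    return tuple(reversed(digits))


def classify_cells(dosage_sub, scores, threshold: float = 0.0) -> frozenset:
    """High-risk cell set for one SNP combination.

    A cell is high-risk when the scores of subjects in it sum strictly above
    ``threshold``; sums at or below the threshold — and cells with no
    subjects — are low-risk.
    """
    d = np.asarray(dosage_sub)
    if d.ndim == 1:
        d = d[:, None]
    s = np.asarray(scores, dtype=float)
    if len(s) != len(d):
        raise DataError("scores not aligned with the dosage submatrix")
    if np.all(s == 0):
        raise UninformativeScoresError("all scores are zero; cells cannot be classified")
    k = d.shape[1]
    combos = np.arange(k, dtype=np.int64)[None, :]
    codes = _cell_codes(d.astype(np.int8), combos)
    sums = np.bincount(codes[:, 0], weights=s, minlength=3**k)
    return frozenset(_code_to_cell(c, k) for c in np.flatnonzero(sums > threshold))


def balanced_accuracy(high_cells, dosage_sub, scores) -> float:
    """Score-mass balanced accuracy of a high/low cell labelling.

    sensitivity = positive score mass inside high cells / total positive
    mass; specificity = negative mass inside low cells / total negative
    mass; BA = (sensitivity + specificity) / 2.
    """
    d = np.asarray(dosage_sub)
    if d.ndim == 1:
        d = d[:, None]
    if len(d) == 0:
        raise DataError("empty evaluation set")
    s = np.asarray(scores, dtype=float)
    k = d.shape[1]
    pos = np.maximum(s, 0.0)
    neg = np.maximum(-s, 0.0)
    P, N = pos.sum(), neg.sum()
    if P == 0 or N == 0:
        raise DataError("balanced accuracy undefined: one-sided score mass")
    codes = _cell_codes(d.astype(np.int8), np.arange(k, dtype=np.int64)[None, :])[:, 0]
    high_codes = {sum(g * 3 ** (k - 1 - j) for j, g in enumerate(cell)) for cell in high_cells}
    in_high = np.isin(codes, sorted(high_codes)) if high_codes else np.zeros(len(codes), bool)
    sens = pos[in_high].sum() / P
    spec = neg[~in_high].sum() / N
    return float((sens + spec) / 2.0)


def _fold_search(dosage, s, train_mask, test_mask, k, threshold, chunk_size):
    """Best combo on the training fold + its TBA on the test fold."""
    m = dosage.shape[1]
    ncells = 3**k
    s_tr = s[train_mask]
    pos_tr = np.maximum(s_tr, 0.0)
    neg_tr = np.maximum(-s_tr, 0.0)
    P_tr, N_tr = pos_tr.sum(), neg_tr.sum()
    if P_tr == 0 or N_tr == 0:
        raise DataError("training fold has one-sided score mass")
    d_tr = dosage[train_mask]

    best_ba = -np.inf
    best_combo = None
    best_high = None
    combo_iter = itertools.combinations(range(m), k)
    while True:
        chunk = np.fromiter(
            itertools.chain.from_iterable(itertools.islice(combo_iter, chunk_size)),
            dtype=np.int64,
        ).reshape(-1, k)
        if chunk.size == 0:
            break
        codes = _cell_codes(d_tr, chunk)
        pos, neg = _cell_masses(codes, pos_tr, neg_tr, ncells)
        high = (pos - neg) > threshold
        sens = (pos * high).sum(axis=1) / P_tr
        spec = (neg * ~high).sum(axis=1) / N_tr
        ba = (sens + spec) / 2.0
        j = int(np.argmax(ba))
        if ba[j] > best_ba:  # strict: earliest combo wins ties, chunk-size invariant
            best_ba = float(ba[j])
            best_combo = tuple(int(c) for c in chunk[j])
            best_high = frozenset(
                _code_to_cell(c, k) for c in np.flatnonzero(high[j])
            )
    tba = balanced_accuracy(best_high, dosage[test_mask][:, list(best_combo)], s[test_mask])
    return best_combo, best_high, float(best_ba), tba


def _select_run_best(fold_results, strategy, snp_ids):
    """Collapse the five fold-best models into the run-best combination."""
    by_combo: dict = {}
    for fr in fold_results:
        by_combo.setdefault(fr.best_cols, []).append(fr)
    entries = []
    for cols, frs in by_combo.items():
        mean_tba = float(np.mean([f.testing_ba for f in frs]))
        entries.append((cols, len(frs), mean_tba))
    if strategy == "tba":
        # order-invariant: tie on TBA broken by sorted snp-id names
        def key(e):
            return (-e[2], tuple(sorted(str(snp_ids[c]) for c in e[0])))
    elif strategy == "cvc_first_in_file":
        # classic generalized-MDR behaviour: highest CVC, ties to the
        # earliest column positions (hence order-dependent by design)
        def key(e):
            return (-e[1], e[0])
    else:
        raise DataError(f"unknown selection strategy {strategy!r}")
    cols, cvc, mean_tba = min(entries, key=key)
    return cols, cvc, mean_tba


def cv_search(
    geno,
    scores,
    k: int,
    seed=None,
    folds=None,
    n_folds: int = 5,
    strategy: str = "tba",
    threshold: float = 0.0,
    stratify=None,
    chunk_size: int = DEFAULT_CHUNK,
) -> RunResult:
    """One cross-validated exhaustive search for the best k-SNP model.

    Per fold, every combination is trained on the 4/5 training scores and
    the fold-best (highest training BA, ties to the earliest combination in
    file order) is evaluated on the held-out 1/5 (TBA). The run-best model
    is then chosen by ``strategy`` ("tba" or "cvc_first_in_file") and
    retrained on the full data to fix its cell labels.
    """
    dosage, snp_ids = _resolve_matrix(geno)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(dosage):
        raise DataError("scores not aligned with genotype rows")
    if np.all(s == 0):
        raise UninformativeScoresError("all scores are zero; cells cannot be classified")
    if k not in (1, 2, 3):
        raise DataError("k must be 1, 2 or 3")
    if dosage.shape[1] < k:
        raise DataError("fewer SNPs than the interaction order")
    if folds is None:
        folds = make_cv_folds(len(s), n_folds, seed=seed, stratify=stratify)
    folds = np.asarray(folds)
    fold_results = []
    for f in range(int(folds.max()) + 1):
        test_mask = folds == f
        train_mask = ~test_mask
        cols, high, ba_tr, tba = _fold_search(dosage, s, train_mask, test_mask, k, threshold, chunk_size)
        fold_results.append(
            FoldResult(
                fold=f + 1,
                best_combo=tuple(str(snp_ids[c]) for c in cols),
                best_cols=cols,
                training_ba=ba_tr,
                testing_ba=tba,
                high_cells=high,
            )
        )
    cols, cvc, mean_tba = _select_run_best(fold_results, strategy, snp_ids)
    full_high = classify_cells(dosage[:, list(cols)], s, threshold)
    model = RiskModel(
        snp_ids=tuple(str(snp_ids[c]) for c in cols),
        col_indices=cols,
        high_cells=full_high,
    )
    return RunResult(
        seed=seed,
        fold_results=fold_results,
        best_model=model,
        cvc=cvc,
        mean_tba=mean_tba,
        selection_strategy=strategy,
    )


def repeated_search(
    geno,
    scores,
    k: int,
    n_runs: int = 20,
    base_seed=0,
    strategy: str = "tba",
    threshold: float = 0.0,
    n_folds: int = 5,
    stratify=None,
) -> tuple[TopModel, list]:
    """Repeat cv_search over fresh fold partitions and form the consensus.

    Run-best models are grouped by (SNP ids, high-cell set); the top model
    has the highest frequency among the ``n_runs`` run-bests, with ties
    broken by mean TBA and then by CVC.
    """
    if n_runs < 1:
        raise DataError("n_runs must be at least 1")
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(base_seed).spawn(n_runs)]
    runs = [
        cv_search(geno, scores, k, seed=s, strategy=strategy, threshold=threshold,
                  n_folds=n_folds, stratify=stratify)
        for s in seeds
    ]
    groups: dict = {}
    for r in runs:
        groups.setdefault(r.best_model.identity(), []).append(r)
    entries = []
    for ident, rs in groups.items():
        freq = len(rs)
        mean_tba = float(np.mean([r.mean_tba for r in rs]))
        mean_cvc = float(np.mean([r.cvc for r in rs]))
        entries.append((freq, mean_tba, mean_cvc, rs[0].best_model))
    entries.sort(key=lambda e: (-e[0], -e[1], -e[2], e[3].snp_ids))
    freq, mean_tba, mean_cvc, model = entries[0]
    top = TopModel(model=model, frequency=freq, n_runs=n_runs, mean_tba=mean_tba, cvc=mean_cvc)
    return top, runs


class MDRSearch(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style estimator around the repeated k-way MDR search.

    fit(X, y) takes the dosage matrix X (n_subjects x n_snps, entries in
    {0,1,2}) and the residual score vector y; it runs ``n_runs``
    cross-validated exhaustive searches and stores the consensus
    ``top_model_``. predict(X) maps subjects to their risk group (1 = cell
    labelled high-risk, 0 otherwise); score(X, y) is the balanced accuracy
    of the fitted model on new scores.

    Parameters
    ----------
    k : interaction order (1-3).
    n_folds, n_runs : cross-validation folds and repeated runs.
    strategy : "tba" (highest testing balanced accuracy) or
        "cvc_first_in_file" (highest cross-validation consistency, ties to
        the earliest SNP in the dataset — deliberately order-dependent).
    threshold : cell-sum classification threshold (0 by default).
    random_state : base seed for the fold partitions.
    """

    def __init__(self, k=2, n_folds=5, n_runs=20, strategy="tba", threshold=0.0, random_state=None):
        self.k = k
        self.n_folds = n_folds
        self.n_runs = n_runs
        self.strategy = strategy
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        dosage, _ = _resolve_matrix(X)
        self.n_features_in_ = dosage.shape[1]
        base = self.random_state if self.random_state is not None else 0
        self.top_model_, self.run_results_ = repeated_search(
            X, y, self.k, n_runs=self.n_runs, base_seed=base,
            strategy=self.strategy, threshold=self.threshold, n_folds=self.n_folds,
        )
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self):
        if not hasattr(self, "top_model_"):
            raise DataError("MDRSearch instance is not fitted yet")

    def predict(self, X):
        self._check_fitted()
        dosage, _ = _resolve_matrix(X)
        if dosage.shape[1] != self.n_features_in_:
            raise DataError("feature count changed between fit and predict")
        model = self.top_model_.model
        sub = dosage[:, list(model.col_indices)]
        codes = _cell_codes(sub, np.arange(model.k, dtype=np.int64)[None, :])[:, 0]
        high_codes = {
            sum(g * 3 ** (model.k - 1 - j) for j, g in enumerate(cell))
            for cell in model.high_cells
        }
        return np.isin(codes, sorted(high_codes)).astype(int)

    def score(self, X, y):
        self._check_fitted()
        dosage, _ = _resolve_matrix(X)
        model = self.top_model_.model
        return balanced_accuracy(model.high_cells, dosage[:, list(model.col_indices)], y)
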