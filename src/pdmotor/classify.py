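"""Feature selection and classification for the two study cases.

Case A discriminates healthy subjects from PD patients (positive = PD);
Case B discriminates mild from moderate PD (positive = mild).  Each (subject,
side) pair is one instance.  Feature subsets are chosen by correlation-based
feature selection (CFS) with best-first search; classifiers are SVMs with
linear / quadratic / cubic / Gaussian kernels and a feed-forward ANN whose
topology is optimised by a genetic algorithm.  Evaluation is stratified
5-fold cross-validation reporting accuracy, sensitivity and specificity
(mean +/- SD across folds, percent):

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

SVM_KERNELS = ("linear", "quadratic", "cubic", "gaussian")


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.n

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Binary confusion counts; labels are booleans (True = positive)."""
    y_true = np.asarray(y_true, bool)
    y_pred = np.asarray(y_pred, bool)
    return ConfusionMatrix(
        TP=int(np.sum(y_true & y_pred)), FP=int(np.sum(~y_true & y_pred)),
        FN=int(np.sum(y_true & ~y_pred)), TN=int(np.sum(~y_true & ~y_pred)))


@dataclass
class ClassifierReport:
    """Cross-validated performance of one classifier spec (percent)."""

    spec: str
    features: tuple
    accuracy: float
    accuracy_sd: float
    sensitivity: float
    sensitivity_sd: float
    specificity: float
    specificity_sd: float
    folds: list = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"model": self.spec,
                "n_features": len(self.features),
                "accuracy": f"{self.accuracy:.1f}±{self.accuracy_sd:.1f}",
                "sensitivity": f"{self.sensitivity:.1f}±{self.sensitivity_sd:.1f}",
                "specificity": f"{self.specificity:.1f}±{self.specificity_sd:.1f}"}


# ---------------------------------------------------------------------------
# CFS feature selection

def _cfs_correlations(X: np.ndarray, y: np.ndarray):
    """|point-biserial| feature-class and |Pearson| feature-feature
    correlations; constant features get correlation 0 everywhere."""
    n, p = X.shape
    yc = y.astype(float) - y.mean()
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = yc.std()
    ok = sx > 0
    rcf = np.zeros(p)
    if sy > 0:
        rcf[ok] = np.abs((Xc[:, ok] * yc[:, None]).mean(axis=0) / (sx[ok] * sy))
    rff = np.zeros((p, p))
    if ok.any():
        Z = Xc[:, ok] / sx[ok]
        rff_ok = np.abs(Z.T @ Z / n)
        rff[np.ix_(ok, ok)] = rff_ok
    np.fill_diagonal(rff, 1.0)
    return rcf, rff


def cfs_merit(subset, rcf: np.ndarray, rff: np.ndarray) -> float:
    """CFS merit M(S) = k r_cf / sqrt(k + k (k-1) r_ff).

    r_cf is the mean absolute feature-class correlation over the subset and
    r_ff the mean absolute pairwise feature correlation; the merit rewards
    class-relevant features and penalises redundancy.
    """
    idx = list(subset)
    k = len(idx)
    if k == 0:
        return 0.0
    mean_cf = rcf[idx].mean()
    if k == 1:
        return float(mean_cf)
    sub = rff[np.ix_(idx, idx)]
    mean_ff = (sub.sum() - k) / (k * (k - 1))
    return float(k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff))


def cfs_select(table: pd.DataFrame, labels, stale_limit: int = 5) -> list:
    """CFS subset selection with best-first forward search.

    Expands the highest-merit open subset by adding one feature at a time and
    stops after ``stale_limit`` consecutive expansions without improving the
    best merit found (classic best-first subset search).  Returns the selected feature
    names in table-column order.
    """
    X = table.to_numpy(float)
    y = np.asarray(labels, bool)
    names = list(table.columns)
    rcf, rff = _cfs_correlations(X, y)
    p = X.shape[1]

    best_subset, best_merit = frozenset(), 0.0
    visited = {frozenset()}
    stale = 0
    counter = itertools.count()
    heap = [(-0.0, next(counter), frozenset())]
    while heap and stale < stale_limit:
        neg_m, _, subset = heapq.heappop(heap)
        improved = False
        for j in range(p):
            if j in subset:
                continue
            child = subset | {j}
            if child in visited:
                continue
            visited.add(child)
            m = cfs_merit(child, rcf, rff)
            heapq.heappush(heap, (-m, next(counter), child))
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, child
                improved = True
        stale = 0 if improved else stale + 1
    return [names[j] for j in sorted(best_subset)]


def cfs_select_exhaustive(table: pd.DataFrame, labels) -> list:
    """Brute-force CFS: enumerate every subset (small p only)."""
    X = table.to_numpy(float)
    y = np.asarray(labels, bool)
    names = list(table.columns)
    rcf, rff = _cfs_correlations(X, y)
    p = X.shape[1]
    if p > 16:
        raise ValueError("exhaustive search only for small feature counts")
    best, best_m = (), 0.0
    for r in range(1, p + 1):
        for comb in itertools.combinations(range(p), r):
            m = cfs_merit(comb, rcf, rff)
            if m > best_m + 1e-12:
                best, best_m = comb, m
    return [names[j] for j in best]


# ---------------------------------------------------------------------------
# classifiers

class SVMClassifier(BaseEstimator, ClassifierMixin):
    """SVM with the four study kernels on z-scored features.

    quadratic/cubic are inhomogeneous polynomial kernels of degree 2/3; the
    Gaussian kernel bandwidth defaults to the inverse median pairwise
    distance of the standardised training data (gamma = 1 / (2 d_med^2)).
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0, gamma=None):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold contains a single class")
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        if self.kernel == "linear":
            svc = SVC(kernel="linear", C=self.C)
        elif self.kernel == "quadratic":
            svc = SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=self.C)
        elif self.kernel == "cubic":
            svc = SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale", C=self.C)
        elif self.kernel == "gaussian":
            gamma = self.gamma
            if gamma is None:
                d = pairwise_distances(Z)
                med = np.median(d[np.triu_indices_from(d, k=1)])
                gamma = 1.0 / (2 * med ** 2) if med > 0 else "scale"
            svc = SVC(kernel="rbf", gamma=gamma, C=self.C)
        else:
            raise ValueError(f"unknown kernel {self.kernel!r}; use one of {SVM_KERNELS}")
        self.svc_ = svc.fit(Z, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        return self.svc_.predict(self.scaler_.transform(np.asarray(X, float)))


def train_svm(table: pd.DataFrame, labels, kernel: str, C: float = 1.0) -> SVMClassifier:
    """Fit one SVM on the full table (features z-scored internally)."""
    return SVMClassifier(kernel=kernel, C=C).fit(table.to_numpy(float),
                                                 np.asarray(labels, bool))


class ANNClassifier(BaseEstimator, ClassifierMixin):
    """Feed-forward sigmoid network on z-scored features.

    Trained with a fixed iteration budget (L-BFGS); topology is one or two
    hidden layers, normally chosen by the genetic search in optimize_ann.
    """

    def __init__(self, hidden=(8,), max_iter: int = 500, seed: int = 0):
        self.hidden = hidden
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold contains a single class")
        self.scaler_ = StandardScaler().fit(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence at fixed budget
            self.net_ = MLPClassifier(hidden_layer_sizes=tuple(self.hidden),
                                      activation="logistic", solver="lbfgs",
                                      max_iter=self.max_iter,
                                      random_state=self.seed).fit(
                self.scaler_.transform(X), y)
        self.classes_ = self.net_.classes_
        return self

    def predict(self, X):
        return self.net_.predict(self.scaler_.transform(np.asarray(X, float)))


@dataclass
class GAConfig:
    """Genetic search over ANN topologies.

    Fitness of a topology is the mean held-out accuracy over
    ``n_permutations`` random stratified train/validation splits, each
    network trained with a fixed iteration budget.
    """

    population: int = 20
    generations: int = 15
    crossover_rate: float = 0.7
    mutation_rate: float = 0.2
    hidden_range: tuple = (2, 16)
    max_layers: int = 2
    train_iters: int = 500
    n_permutations: int = 3
    val_fraction: float = 0.3
    tournament: int = 3
    seed: int = 0

    def validate(self):
        if self.hidden_range[0] > self.hidden_range[1] or self.hidden_range[0] < 1:
            raise ValueError("empty hidden-layer size range")
        if self.max_layers not in (1, 2):
            raise ValueError("1 or 2 hidden layers supported")


@dataclass
class GAResult:
    topology: tuple
    fitness: float
    classifier: ANNClassifier
    history: list          # best fitness per generation
    config: GAConfig


def _topology_fitness(topology, X, y, cfg: GAConfig, rng_seed: int, cache: dict):
    if topology in cache:
        return cache[topology]
    rng = np.random.default_rng(rng_seed)
    n = len(y)
    accs = []
    for r in range(cfg.n_permutations):
        perm = _stratified_split(y, cfg.val_fraction, rng)
        train, val = perm
        clf = ANNClassifier(hidden=topology, max_iter=cfg.train_iters,
                            seed=int(rng.integers(2 ** 31)))
        clf.fit(X[train], y[train])
        accs.append(np.mean(clf.predict(X[val]) == y[val]))
    fit = float(np.mean(accs))
    cache[topology] = fit
    return fit


def _stratified_split(y, val_fraction, rng):
    """Random permutation split keeping both classes in both parts."""
    train, val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return np.array(train), np.array(val)


def optimize_ann(table: pd.DataFrame, labels, config: GAConfig | None = None) -> GAResult:
    """GA search for the ANN topology with the best held-out accuracy.

    Individuals encode (layers, h1, h2); selection is tournament, crossover
    one-point, mutation resamples a gene; the best individual is kept across
    generations (elitism), so best-so-far fitness is monotone.  Fully
    deterministic for a given config seed.
    """
    cfg = config or GAConfig()
    cfg.validate()
    X = table.to_numpy(float)
    y = np.asarray(labels, bool)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.hidden_range
    cache: dict = {}

    def random_individual():
        layers = int(rng.integers(1, cfg.max_layers + 1))
        return (int(rng.integers(lo, hi + 1)),) + (
            (int(rng.integers(lo, hi + 1)),) if layers == 2 else ())

    def fitness(ind):
        return _topology_fitness(ind, X, y, cfg, rng_seed=cfg.seed + 7919, cache=cache)

    pop = [random_individual() for _ in range(cfg.population)]
    fits = [fitness(ind) for ind in pop]
    best_i = int(np.argmax(fits))
    best, best_fit = pop[best_i], fits[best_i]
    history = [best_fit]

    for gen in range(cfg.generations):
        new_pop = [best]  # elitism
        while len(new_pop) < cfg.population:
            a = _tournament(pop, fits, cfg.tournament, rng)
            b = _tournament(pop, fits, cfg.tournament, rng)
            child = _crossover(a, b, rng) if rng.random() < cfg.crossover_rate else a
            child = _mutate(child, cfg, rng)
            new_pop.append(child)
        pop = new_pop
        fits = [fitness(ind) for ind in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = pop[gen_best], fits[gen_best]
        history.append(best_fit)

    final = ANNClassifier(hidden=best, max_iter=cfg.train_iters, seed=cfg.seed)
    final.fit(X, y)
    return GAResult(topology=best, fitness=best_fit, classifier=final,
                    history=history, config=cfg)


def _tournament(pop, fits, k, rng):
    idx = rng.integers(0, len(pop), size=k)
    return pop[idx[int(np.argmax([fits[i] for i in idx]))]]


def _crossover(a, b, rng):
    # genes: (layers, h1, h2); one-point on the flattened representation
    la, lb = len(a), len(b)
    layers = la if rng.random() < 0.5 else lb
    h1 = a[0] if rng.random() < 0.5 else b[0]
    if layers == 1:
        return (h1,)
    h2_pool = [g for g in (a[1:2] or ()) + (b[1:2] or ())]
    h2 = h2_pool[int(rng.integers(len(h2_pool)))] if h2_pool else h1
    return (h1, int(h2))


def _mutate(ind, cfg, rng):
    lo, hi = cfg.hidden_range
    genes = list(ind)
    if rng.random() < cfg.mutation_rate:  # flip layer count
        if len(genes) == 1 and cfg.max_layers == 2:
            genes.append(int(rng.integers(lo, hi + 1)))
        elif len(genes) == 2:
            genes = genes[:1]
    for i in range(len(genes)):
        if rng.random() < cfg.mutation_rate:
            genes[i] = int(rng.integers(lo, hi + 1))
    return tuple(genes)


# ---------------------------------------------------------------------------
# cross-validated evaluation

def evaluate_cv(table: pd.DataFrame, labels, estimator, k: int = 5,
                seed: int = 0, groups=None, spec: str = "") -> ClassifierReport:
    """Stratified k-fold cross-validation with confusion-matrix metrics.

    ``estimator`` is cloned and refitted per fold.  With ``groups`` (subject
    ids) folds are additionally group-disjoint, keeping both sides of a
    subject in the same fold (deviates from treating sides as fully
    independent instances; off by default).  Folds whose test part lacks a
    class are skipped with a warning.  Metrics are percent, SD is the
    population SD across folds.
    """
    X = table.to_numpy(float)
    y = np.asarray(labels, bool)
    # canonical instance order before fold assignment: metrics then depend
    # only on the data content and the seed, not on row order
    order = np.lexsort(tuple(X.T) + (y,))
    Xo, yo = X[order], y[order]
    if groups is not None:
        go = np.asarray(groups)[order]
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(Xo, yo, go)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(Xo, yo)
    X, y = Xo, yo
    folds, acc, sens, spec_ = [], [], [], []
    for train, test in splits:
        if len(np.unique(y[test])) < 2:
            warnings.warn("fold skipped: test part lacks a class")
            continue
        clf = clone(estimator)
        clf.fit(X[train], y[train])
        cm = confusion_matrix(y[test], np.asarray(clf.predict(X[test]), bool))
        folds.append(cm)
        acc.append(cm.accuracy)
        sens.append(cm.sensitivity)
        spec_.append(cm.specificity)
    if not folds:
        raise ValueError("no evaluable folds")
    return ClassifierReport(
        spec=spec, features=tuple(table.columns), seed=seed, folds=folds,
        accuracy=100 * float(np.mean(acc)), accuracy_sd=100 * float(np.std(acc)),
        sensitivity=100 * float(np.mean(sens)), sensitivity_sd=100 * float(np.std(sens)),
        specificity=100 * float(np.mean(spec_)), specificity_sd=100 * float(np.std(spec_)))


# ---------------------------------------------------------------------------
# study grid

from .gait import GAIT_FEATURES  # noqa: E402
from .tapping import TAP_FEATURES  # noqa: E402

_FIT = tuple(f"fit_{f}" for f in TAP_FEATURES)
_FOT = tuple(f"fot_{f}" for f in TAP_FEATURES)

#: feature columns per (domain, subcase)
SUBCASE_FEATURES = {
    ("gait", 1): GAIT_FEATURES, ("gait", 2): "cfs",
    ("tapping", 1): _FIT, ("tapping", 2): _FOT, ("tapping", 3): _FIT + _FOT,
}


def case_labels(cohort: pd.DataFrame, case: str) -> tuple:
    """Select the case's instances and binary labels (True = positive).

    Case A: healthy vs PD over all instances, positive = PD.
    Case B: mild vs moderate PD only, positive = mild.
    """
    case = case.upper()
    if case == "A":
        sub = cohort
        y = sub["group"].isin(["mild", "moderate", "pd"]).to_numpy()
    elif case == "B":
        sub = cohort[cohort["group"].isin(["mild", "moderate"])].reset_index(drop=True)
        y = (sub["group"] == "mild").to_numpy()
    else:
        raise ValueError("case must be 'A' or 'B'")
    return sub, y


def run_study(cohort: pd.DataFrame, case: str, domain: str = "gait",
              subcases=None, seed: int = 0, ga_config: GAConfig | None = None,
              models=SVM_KERNELS + ("ann",),
              cfs_in_cv: bool = False) -> pd.DataFrame:
    """Run the study grid for one case: subcases x (4 SVM kernels + GA-ANN).

    Gait subcases: 1 = all 16 features, 2 = CFS-selected subset.  Tapping
    subcases: 1 = finger features, 2 = foot features, 3 = both.  Feature
    selection runs once on the full table (subsets reported globally), unless
    ``cfs_in_cv`` keeps it inside each training fold to avoid selection bias.
    Returns a tidy DataFrame shaped like the study report tables.
    """
    if domain not in ("gait", "tapping"):
        raise ValueError("domain must be 'gait' or 'tapping'")
    if subcases is None:
        subcases = (1, 2) if domain == "gait" else (1, 2, 3)
    sub, y = case_labels(cohort, case)
    rows = []
    for sc in subcases:
        key = (domain, sc)
        if key not in SUBCASE_FEATURES:
            raise ValueError(f"unknown subcase {sc} for domain {domain}")
        feat = SUBCASE_FEATURES[key]
        if feat == "cfs":
            missing = [c for c in GAIT_FEATURES if c not in sub.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            selected = cfs_select(sub[list(GAIT_FEATURES)], y)
            feat = tuple(selected) if selected else GAIT_FEATURES
        missing = [c for c in feat if c not in sub.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        table = sub[list(feat)]
        for model in models:
            if model == "ann":
                cfg = ga_config or GAConfig(seed=seed)
                ga = optimize_ann(table, y, cfg)
                est = ANNClassifier(hidden=ga.topology, max_iter=cfg.train_iters,
                                    seed=cfg.seed)
                spec_name = f"ann{ga.topology}"
            else:
                est = SVMClassifier(kernel=model)
                spec_name = f"svm-{model}"
            rep = evaluate_cv(table, y, est, seed=seed, spec=spec_name)
            row = {"case": case.upper(), "subcase": f"{case.upper()}.{sc}",
                   **rep.to_dict()}
            row["features"] = ";".join(feat)
            rows.append(row)
    return pd.DataFrame(rows)
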