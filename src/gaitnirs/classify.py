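"""GA-driven feature-subset search with SVM leave-one-subject-out fitness.

Candidate features (the ANOVA-filtered feature specs of both hemoglobin
signal kinds) are recombined by a genetic algorithm whose crossover and
mutation probabilities adapt to population fitness: individuals near the
population maximum are perturbed gently, individuals below the mean at
the full rates,

    pc = pc1 - (pc1 - pc2) * (f' - f_avg) / (f_max - f_avg)   if f' >= f_avg
       = pc1                                                  otherwise

and analogously for pm with the fitness f of the mutation candidate.
The fitness of a feature subset is its mean leave-one-subject-out SVM
accuracy over the training cohort; every subject contributes one
instance per gait state, so folds never mix a subject between train and
test sides.  The best subset is then trained once on the full training
cohort and scored on the held-out subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ValidationError
from .selection import FeatureSpec, FeatureMatrixTable, extract_feature_value
from .states import GaitState, STATES, dimension_classes


@dataclass
class GAParams:
    """Adaptive-GA settings.

    ``pc1``/``pc2`` bound the crossover probability and ``pm1``/``pm2``
    the mutation probability (upper/lower critical values).  The search
    budget ``n_iterations`` counts distinct fitness evaluations by
    default (``budget_unit="evaluations"``); set
    ``budget_unit="generations"`` to read it as generation count.
    """

    pc1: float = 0.9
    pc2: float = 0.6
    pm1: float = 0.1
    pm2: float = 0.01
    population_size: int = 50
    n_iterations: int = 20000
    budget_unit: str = "evaluations"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pc2 <= self.pc1 <= 1 and 0 < self.pm2 <= self.pm1 <= 1):
            raise ValidationError("need 0 < pc2 <= pc1 <= 1 and 0 < pm2 <= pm1 <= 1")
        if self.population_size < 2 or self.n_iterations < 1:
            raise ValidationError("population_size >= 2 and n_iterations >= 1 required")
        if self.budget_unit not in ("evaluations", "generations"):
            raise ValidationError("budget_unit must be 'evaluations' or 'generations'")


@dataclass
class FitnessStats:
    """Population fitness summary used by the adaptive probabilities."""

    f_max: float
    f_avg: float
    f_prime: float = 0.0  # larger fitness of the pair to be crossed
    f: float = 0.0  # fitness of the individual to be mutated

    def __post_init__(self) -> None:
        if self.f_max < self.f_avg - 1e-12:  # tolerate mean/max rounding
            raise ValidationError("f_max must be >= f_avg")


def _adaptive(f_val: float, f_avg: float, f_max: float, p1: float, p2: float) -> float:
    if f_max <= f_avg:  # degenerate population: no spread to adapt to
        return p1
    if f_val < f_avg:
        return p1
    p = p1 - (p1 - p2) * (f_val - f_avg) / (f_max - f_avg)
    return min(max(p, p2), p1)  # guard rounding at the endpoints


def adaptive_probabilities(stats: FitnessStats, params: GAParams) -> tuple[float, float]:
    """Crossover and mutation probabilities for one pairing/individual.

    Both outputs lie in [pc2, pc1] and [pm2, pm1]; a fitness at the
    population mean gets the upper critical value, one at the maximum
    the lower.
    """
    pc = _adaptive(stats.f_prime, stats.f_avg, stats.f_max, params.pc1, params.pc2)
    pm = _adaptive(stats.f, stats.f_avg, stats.f_max, params.pm1, params.pm2)
    return pc, pm


def make_svm() -> object:
    """Standardized RBF SVM (C = 1, gamma = 1/n_features, one-vs-one)."""
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="auto"))


def loso_fitness(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Mean leave-one-subject-out accuracy of the masked feature set.

    Each fold trains on all instances of the other subjects and scores
    the held-out subject's instances; the fitness is the unweighted mean
    of the per-fold accuracies, in [0, 1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValidationError("empty feature mask")
        X = X[:, mask]
    if X.ndim != 2 or X.shape[0] != y.size or y.size != groups.size:
        raise ValidationError("X, y and groups must be congruent")
    accs = []
    for g in np.unique(groups):
        held = groups == g
        if np.unique(y[~held]).size < 2:
            raise ValidationError(f"training fold without class contrast (held out {g})")
        clf = make_svm()
        clf.fit(X[~held], y[~held])
        accs.append(float(np.mean(clf.predict(X[held]) == y[held])))
    return float(np.mean(accs))


@dataclass
class GAResult:
    best_mask: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness per generation
    n_evaluations: int


def ga_select(
    n_candidates: int,
    fitness_fn: Callable[[np.ndarray], float],
    params: GAParams,
) -> GAResult:
    """Search feature subsets with the adaptive GA.

    Generational loop with fitness-proportional (roulette) selection,
    single-point crossover, bit-flip mutation and elitism of one; both
    probabilities adapt per pairing/individual.  Fitness values are
    cached by bitmask, and only cache misses consume the evaluation
    budget.  Deterministic for a fixed ``params.seed``.
    """
    if n_candidates < 1:
        raise ValidationError("need at least one candidate feature")
    rng = np.random.default_rng(params.seed)
    cache: dict[bytes, float] = {}
    n_evals = 0

    def evaluate(mask: np.ndarray) -> float:
        nonlocal n_evals
        key = mask.tobytes()
        if key not in cache:
            cache[key] = 0.0 if not mask.any() else float(fitness_fn(mask))
            n_evals += 1
        return cache[key]

    def ensure_nonempty(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask[rng.integers(n_candidates)] = True
        return mask

    pop = rng.random((params.population_size, n_candidates)) < 0.5
    pop = np.array([ensure_nonempty(m) for m in pop])
    fits = np.array([evaluate(m) for m in pop])

    best_i = int(fits.argmax())
    best_mask, best_fit = pop[best_i].copy(), float(fits[best_i])
    trace = [best_fit]

    def budget_left(generation: int) -> bool:
        if params.budget_unit == "generations":
            return generation < params.n_iterations
        return n_evals < params.n_iterations

    generation = 0
    stalled = 0
    # stop when the budget is spent, every mask has been tried, or the
    # search has stopped producing unseen masks (tiny search spaces)
    while budget_left(generation) and 2**n_candidates > len(cache) and stalled < 20:
        evals_before = n_evals
        f_avg, f_max = float(fits.mean()), float(fits.max())
        new = [pop[int(fits.argmax())].copy()]  # elitism of 1
        while len(new) < params.population_size:
            i, j = _roulette(fits, rng), _roulette(fits, rng)
            a, b = pop[i].copy(), pop[j].copy()
            f_pair = float(max(fits[i], fits[j]))
            stats = FitnessStats(f_max=f_max, f_avg=f_avg, f_prime=f_pair, f=f_pair)
            pc, pm = adaptive_probabilities(stats, params)
            if n_candidates > 1 and rng.random() < pc:
                point = int(rng.integers(1, n_candidates))
                a[point:], b[point:] = b[point:].copy(), a[point:].copy()
            for child in (a, b)[: params.population_size - len(new)]:
                flips = rng.random(n_candidates) < pm
                child ^= flips
                new.append(ensure_nonempty(child))
        pop = np.array(new)
        fits = np.array([evaluate(m) for m in pop])
        gen_best = int(fits.argmax())
        if fits[gen_best] > best_fit:
            best_fit, best_mask = float(fits[gen_best]), pop[gen_best].copy()
        trace.append(best_fit)
        generation += 1
        stalled = stalled + 1 if n_evals == evals_before else 0

    return GAResult(
        best_mask=best_mask,
        best_fitness=best_fit,
        trace=np.asarray(trace),
        n_evaluations=n_evals,
    )


def _roulette(fits: np.ndarray, rng: np.random.Generator) -> int:
    total = fits.sum()
    if total <= 0:
        return int(rng.integers(fits.size))
    return int(rng.choice(fits.size, p=fits / total))


# ---------------------------------------------------------------------------
# instance construction and final evaluation


def build_instances(
    featmats: FeatureMatrixTable,
    subjects: Sequence[str],
    specs: Sequence[FeatureSpec],
    dimension: str,
    states: Sequence[GaitState] = STATES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix, class labels and subject groups for a cohort.

    One instance per (subject, gait state); column j holds feature spec
    j evaluated on that trial's 6 x 22 slope matrix, and the label is
    the state's class along ``dimension``.
    """
    X, y, groups = [], [], []
    for subject in subjects:
        for state in states:
            row = [
                extract_feature_value(featmats[(subject, state.label, s.signal_kind)], s)
                for s in specs
            ]
            X.append(row)
            y.append(state.class_of(dimension))
            groups.append(subject)
    return (
        np.asarray(X, dtype=float).reshape(len(y), len(specs)),
        np.asarray(y),
        np.asarray(groups),
    )


def majority_class(y: np.ndarray) -> str:
    values, counts = np.unique(y, return_counts=True)
    return str(values[int(counts.argmax())])


def train_and_test(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    dimension: str,
) -> dict:
    """Train once on the training cohort, score the held-out cohort.

    Returns the accuracy as correct/total over all test instances
    (11 subjects x 6 states = 66 in the reference split) plus a 3 x 3
    confusion matrix in canonical class order.  With an empty feature
    set the majority training class is predicted — the class-prior
    baseline.
    """
    classes = list(dimension_classes(dimension))
    y_test = np.asarray(y_test)
    if np.asarray(X_train).size and np.asarray(X_train).shape[1] > 0:
        clf = make_svm()
        clf.fit(X_train, y_train)
        pred = clf.predict(X_test)
    else:
        pred = np.full(y_test.shape, majority_class(np.asarray(y_train)))
    correct = int((pred == y_test).sum())
    total = int(y_test.size)
    confusion = [
        [int(((y_test == a) & (pred == b)).sum()) for b in classes] for a in classes
    ]
    return {
        "dimension": dimension,
        "classes": classes,
        "accuracy": correct / total,
        "correct": correct,
        "total": total,
        "confusion": confusion,
    }


def permutation_null_accuracies(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    dimension: str,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Test accuracies after shuffling the training labels.

    The resulting distribution is the no-information baseline against
    which a pipeline accuracy can be judged (e.g. its 97.5th
    percentile).
    """
    rng = np.random.default_rng(seed)
    y_train = np.asarray(y_train)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(y_train.size)
        report = train_and_test(X_train, y_train[perm], X_test, y_test, dimension)
        accs[i] = report["accuracy"]
    return accs
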