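"""Improved grey-wolf-optimizer (GWO) wrapper feature selection.

The search is continuous over the unit hypercube [0,1]^D, one coordinate per
gene.  A position is binarized at a threshold (default 0.5) to a gene subset;
the subset is scored by a wrapper objective

    fitness = alpha * gamma(S) + beta * (|D| - |S|) / |D|,

where gamma(S) is the internal cross-validated accuracy of a fast classifier
trained on the selected columns, |S| the subset size and |D| the total gene
count.  alpha = 0.9 and beta = 1 - alpha = 0.1, so classification quality
dominates and parsimony breaks ties.

Wolves move toward the three best solutions found so far (the alpha, beta and
delta leaders) with an attack coefficient drawn from a schedule that decays
linearly from 2 to 0 over the run.  The "improved" part is an adaptive
beta-hill-climbing (AbHC) local search applied to the current alpha leader
each outer iteration: a shrinking-bandwidth neighborhood operator plus a
probabilistic per-dimension random reset, accepting only strict improvements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .datasets import ExpressionDataset
from .exceptions import DimensionMismatchError, InvalidConfigError, InvalidInputError

__all__ = [
    "GWOConfig",
    "AbhcConfig",
    "WrapperConfig",
    "FeatureSubset",
    "coefficient_b",
    "sample_coefficients",
    "leader_update",
    "binarize",
    "wrapper_quality",
    "subset_fitness",
    "abhc_bandwidth",
    "abhc_refine",
    "run_igwo_fs",
]


@dataclass(frozen=True)
class GWOConfig:
    """Grey-wolf search settings.

    ``alpha_weight``/``beta_weight`` are the fitness weights on classification
    quality and parsimony; they must sum to 1.  ``pack_size`` must be >= 4
    (three leaders plus at least one follower).
    """

    pack_size: int = 10
    max_iter: int = 100
    alpha_weight: float = 0.9
    beta_weight: float = 0.1
    binarize_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pack_size < 4:
            raise InvalidConfigError("pack_size must be >= 4 (3 leaders + followers)")
        if abs(self.alpha_weight + self.beta_weight - 1.0) > 1e-12:
            raise InvalidConfigError("alpha_weight + beta_weight must equal 1")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise InvalidConfigError("binarize_threshold must lie in (0,1)")
        if self.max_iter < 0:
            raise InvalidConfigError("max_iter must be >= 0")


@dataclass(frozen=True)
class AbhcConfig:
    """Adaptive beta-hill-climbing settings.

    ``K`` shapes the bandwidth decay (larger K keeps the bandwidth wide for
    longer); ``beta_rate`` is the per-dimension probability of a uniform
    random reset (the beta operator).
    """

    K: float = 4.0
    beta_rate: float = 0.05
    inner_iters: int = 30

    def __post_init__(self) -> None:
        if self.K < 1.0:
            raise InvalidConfigError("K must be >= 1")
        if not 0.0 <= self.beta_rate <= 1.0:
            raise InvalidConfigError("beta_rate must lie in [0,1]")
        if self.inner_iters < 0:
            raise InvalidConfigError("inner_iters must be >= 0")


@dataclass(frozen=True)
class WrapperConfig:
    """Internal wrapper-classifier settings for gamma(S).

    Defaults to 5-nearest-neighbour accuracy under seeded stratified 3-fold
    cross-validation: fast, deterministic given the seed, and standard in the
    wrapper feature-selection literature.
    """

    n_neighbors: int = 5
    cv_folds: int = 3
    seed: int = 0


@dataclass
class FeatureSubset:
    """A selected gene subset with its wrapper quality and weighted fitness."""

    mask: np.ndarray
    quality: float
    fitness: float

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def gene_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def coefficient_b(u: int, m_i: int) -> float:
    """Attack-coefficient schedule: 2 - u * (2 / m_i), linear from 2 down to 0."""
    if m_i <= 0:
        raise InvalidConfigError("total iteration count must be positive")
    return 2.0 - u * (2.0 / m_i)


def sample_coefficients(b: float, rng: np.random.Generator, dim: int = 1):
    """Draw the stochastic attack and prey-weighting vectors.

    A = 2*b*s1 - b with s1 ~ U(0,1)^dim, so each component lies in [-b, b];
    C = 2*s2 with s2 ~ U(0,1)^dim, so each component lies in [0, 2].
    """
    s1 = rng.uniform(size=dim)
    s2 = rng.uniform(size=dim)
    return 2.0 * b * s1 - b, 2.0 * s2


def leader_update(
    position: np.ndarray,
    leaders: list[np.ndarray],
    b: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move one wolf toward the three leaders and clip to [0,1]^D.

    For each leader X_k the candidate is X_k - A_k * |C_k * X_k - X| with
    freshly sampled A_k, C_k; the new position is the arithmetic mean of the
    three candidates.
    """
    position = np.asarray(position, dtype=float)
    if len(leaders) != 3:
        raise InvalidConfigError("exactly three leaders (alpha, beta, delta) required")
    dim = position.shape[0]
    candidates = np.empty((3, dim))
    for k, xk in enumerate(leaders):
        xk = np.asarray(xk, dtype=float)
        if xk.shape != position.shape:
            raise DimensionMismatchError("leader and wolf dimensions differ")
        a_k, c_k = sample_coefficients(b, rng, dim)
        d_k = np.abs(c_k * xk - position)
        candidates[k] = xk - a_k * d_k
    return np.clip(candidates.mean(axis=0), 0.0, 1.0)


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Map a continuous position to a gene mask: selected iff coordinate > threshold.

    An empty mask is repaired by forcing on the single largest coordinate, so
    every wolf always encodes a non-empty subset.
    """
    position = np.asarray(position, dtype=float)
    mask = position > threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


def wrapper_quality(
    X: np.ndarray, y: np.ndarray, wrapper: WrapperConfig = WrapperConfig()
) -> float:
    """gamma(S): stratified k-fold CV accuracy of k-NN on the selected columns."""
    n = len(y)
    counts = np.bincount(y, minlength=2)
    folds = min(wrapper.cv_folds, counts[counts > 0].min())
    if folds < 2:
        raise InvalidInputError("wrapper CV needs >= 2 samples in each class")
    skf = StratifiedKFold(n_splits=int(folds), shuffle=True, random_state=wrapper.seed)
    correct = 0
    for train, test in skf.split(X, y):
        k = min(wrapper.n_neighbors, len(train))
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(X[train], y[train])
        correct += int((clf.predict(X[test]) == y[test]).sum())
    return correct / n


def subset_fitness(
    mask: np.ndarray,
    dataset: ExpressionDataset,
    wrapper: WrapperConfig = WrapperConfig(),
    alpha_weight: float = 0.9,
    beta_weight: float = 0.1,
) -> FeatureSubset:
    """Score a gene mask: alpha * quality + beta * (|D| - |S|) / |D|."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("cannot score an empty gene subset")
    quality = wrapper_quality(dataset.values[:, mask], dataset.labels, wrapper)
    parsimony = (mask.size - mask.sum()) / mask.size
    fitness = alpha_weight * quality + beta_weight * parsimony
    return FeatureSubset(mask=mask, quality=quality, fitness=float(fitness))


def abhc_bandwidth(t: float, K: float, maxiter: float) -> float:
    """Neighborhood bandwidth N(t) = 1 - t^(1/K) / maxiter^(1/K), in [0,1]."""
    if maxiter <= 0:
        raise InvalidConfigError("maxiter must be positive")
    if K < 1.0:
        raise InvalidConfigError("K must be >= 1")
    t = min(max(t, 0.0), maxiter)
    return 1.0 - (t ** (1.0 / K)) / (maxiter ** (1.0 / K))


def abhc_refine(
    x: np.ndarray,
    fitness_fn,
    cfg: AbhcConfig,
    t: int,
    maxiter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Greedy adaptive beta-hill-climbing around ``x`` (maximization).

    Each inner iteration perturbs every dimension by +/- U(0,1) * N (sign
    uniform), then the beta operator independently resets each dimension to
    U(0,1) with probability ``beta_rate``.  A candidate replaces ``x`` only if
    strictly fitter, so the returned fitness never drops below the input's.

    The bandwidth schedule advances with global progress: when called once per
    outer iteration ``t`` of ``maxiter``, inner step j sits at position
    t*inner_iters + j of maxiter*inner_iters, so the neighborhood keeps
    shrinking smoothly across the whole run.
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    fx = fitness_fn(x)
    if cfg.inner_iters == 0:
        return x, fx
    total = max(maxiter, 1) * cfg.inner_iters
    for j in range(cfg.inner_iters):
        step = min(t * cfg.inner_iters + j, total)
        n_t = abhc_bandwidth(step, cfg.K, total)
        signs = rng.choice([-1.0, 1.0], size=x.shape)
        cand = x + signs * rng.uniform(size=x.shape) * n_t
        reset = rng.uniform(size=x.shape) < cfg.beta_rate
        cand[reset] = rng.uniform(size=int(reset.sum()))
        cand = np.clip(cand, 0.0, 1.0)
        f_cand = fitness_fn(cand)
        if f_cand > fx:
            x, fx = cand, f_cand
    return x, fx


class _MaskFitnessCache:
    """Memoize subset_fitness over binarized masks (positions repeat often)."""

    def __init__(self, dataset, wrapper, alpha_weight, beta_weight, threshold):
        self.dataset = dataset
        self.wrapper = wrapper
        self.alpha_weight = alpha_weight
        self.beta_weight = beta_weight
        self.threshold = threshold
        self._cache: dict[bytes, FeatureSubset] = {}

    def subset(self, position: np.ndarray) -> FeatureSubset:
        mask = binarize(position, self.threshold)
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is None:
            hit = subset_fitness(
                mask, self.dataset, self.wrapper, self.alpha_weight, self.beta_weight
            )
            self._cache[key] = hit
        return hit

    def fitness(self, position: np.ndarray) -> float:
        return self.subset(position).fitness


def run_igwo_fs(
    dataset: ExpressionDataset,
    gwo_cfg: GWOConfig = GWOConfig(),
    abhc_cfg: AbhcConfig = AbhcConfig(),
    wrapper: WrapperConfig | None = None,
) -> tuple[FeatureSubset, dict]:
    """Run the full improved-GWO feature selection on a normalized dataset.

    Returns the best subset found and a history dict with the best-so-far
    fitness after each outer iteration (monotone non-decreasing by elitism:
    leaders persist and the hill climber only accepts improvements).
    """
    if wrapper is None:
        wrapper = WrapperConfig(seed=gwo_cfg.seed)
    cache = _MaskFitnessCache(
        dataset, wrapper, gwo_cfg.alpha_weight, gwo_cfg.beta_weight,
        gwo_cfg.binarize_threshold,
    )
    rng = np.random.default_rng(gwo_cfg.seed)
    dim = dataset.n_genes
    positions = rng.uniform(size=(gwo_cfg.pack_size, dim))

    best: FeatureSubset | None = None
    trace: list[float] = []

    def consider(sub: FeatureSubset) -> None:
        nonlocal best
        if best is None or sub.fitness > best.fitness:
            best = sub

    subsets = [cache.subset(p) for p in positions]
    for s in subsets:
        consider(s)
    if gwo_cfg.max_iter == 0:
        trace.append(best.fitness)
        return best, _history(trace, gwo_cfg, abhc_cfg, best)

    for u in range(gwo_cfg.max_iter):
        order = np.argsort([-s.fitness for s in subsets], kind="stable")
        leaders = [positions[order[k]].copy() for k in range(3)]
        alpha_idx = int(order[0])
        b = coefficient_b(u, gwo_cfg.max_iter)
        new_positions = np.empty_like(positions)
        for i in range(gwo_cfg.pack_size):
            new_positions[i] = leader_update(positions[i], leaders, b, rng)
        refined, _ = abhc_refine(
            leaders[0], cache.fitness, abhc_cfg, u, gwo_cfg.max_iter, rng
        )
        new_positions[alpha_idx] = refined  # elitist slot for the refined leader
        positions = new_positions
        subsets = [cache.subset(p) for p in positions]
        for s in subsets:
            consider(s)
        trace.append(best.fitness)

    return best, _history(trace, gwo_cfg, abhc_cfg, best)


def _history(trace, gwo_cfg, abhc_cfg, best) -> dict:
    return {
        "best_fitness_per_iter": list(trace),
        "final_fitness": best.fitness,
        "final_quality": best.quality,
        "n_selected": best.n_selected,
        "pack_size": gwo_cfg.pack_size,
        "max_iter": gwo_cfg.max_iter,
        "abhc_inner_iters": abhc_cfg.inner_iters,
    }
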