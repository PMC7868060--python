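"""Synthetic group-structured regression data.

The generator emulates a simulation design in which K subgroups have
Gaussian feature distributions with subgroup-specific means and sparse
random precision matrices (standing in for the correlation structure of
gene-expression panels), and true coefficient vectors are Bernoulli-sparse
with truncated-standard-normal effect sizes.  A subset ``V0`` of ``K0``
subgroups — the mutually most similar ones by symmetrised KL divergence —
shares a single coefficient vector, so ``K0`` dials how useful information
sharing is: ``K0 = K`` favors pooling, ``K0 = 1`` favors subgroup-wise fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data import GroupedDataset, split_by_group, standardize_subgroups
from .weights import SubgroupModel, symmetrised_kl_gaussian

#: above this many candidate subsets, subset search switches to greedy
EXHAUSTIVE_LIMIT = 5000


@dataclass
class SimulationDesign:
    """Parameters of one simulated study.

    Defaults mirror the reference design: ``K=9`` subgroups, ``p=200``
    features, total ``n=250`` samples split equally, true coefficients with
    support rate 0.1 and nonzero magnitudes at least 0.1.
    """

    K: int = 9
    K0: int = 4
    p: int = 200
    n: int = 250
    proportions: np.ndarray | None = None
    sparsity: float = 0.1
    truncation: float = 0.1
    noise_scale: float = 1.0
    heterogeneity: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.K0 <= self.K:
            raise ValueError("K0 must lie in [1, K]")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must lie in (0, 1]")
        if self.proportions is None:
            self.proportions = np.full(self.K, 1.0 / self.K)
        else:
            self.proportions = np.asarray(self.proportions, dtype=float)
            if len(self.proportions) != self.K or not math.isclose(
                self.proportions.sum(), 1.0, abs_tol=1e-8
            ):
                raise ValueError("proportions must have length K and sum to 1")

    def group_sizes(self) -> np.ndarray:
        """Integer subgroup sizes following the proportions, summing to n."""
        sizes = np.maximum(np.floor(self.proportions * self.n).astype(int), 2)
        while sizes.sum() > self.n:
            sizes[np.argmax(sizes)] -= 1
        frac = self.proportions * self.n - sizes
        while sizes.sum() < self.n:
            i = int(np.argmax(frac))
            sizes[i] += 1
            frac[i] -= 1.0
        return sizes


@dataclass
class SimulationTruth:
    """Ground truth underlying one simulated dataset."""

    B: np.ndarray  # p x K, original (raw) scale
    V0: list[int]
    models: list[SubgroupModel]
    noise_scale: float
    design: SimulationDesign = field(repr=False, default=None)


def _random_sparse_precision(p: int, rng: np.random.Generator, density: float = 0.04):
    """Sparse symmetric diagonally-dominant precision matrix (hence PD)."""
    theta = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.2, 0.6, mask.sum()) * rng.choice([-1.0, 1.0], mask.sum())
    theta[iu[0][mask], iu[1][mask]] = vals
    theta += theta.T
    np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + 0.5)
    return theta


def make_subgroup_models(
    K: int, p: int, heterogeneity: float, seed: int | np.random.Generator
) -> list[SubgroupModel]:
    """Gaussian feature models whose pairwise separation scales with
    ``heterogeneity``.

    All subgroups share one sparse random precision matrix (emulating a
    common correlation backbone, as in expression panels where scales are
    comparable across subgroups); each subgroup gets its own mean vector
    scaled by the heterogeneity knob, so 0 gives identical models and
    larger values give larger pairwise divergences.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    rng = np.random.default_rng(seed)
    theta0 = _random_sparse_precision(p, rng)
    sigma0 = np.linalg.inv(theta0)
    models = []
    for _ in range(K):
        mu = heterogeneity * rng.standard_normal(p)
        models.append(SubgroupModel(mu=mu, sigma=sigma0, precision=theta0))
    return models


def _kl_matrix(models: list[SubgroupModel]) -> np.ndarray:
    K = len(models)
    d = np.zeros((K, K))
    for k, l in combinations(range(K), 2):
        d[k, l] = d[l, k] = symmetrised_kl_gaussian(models[k], models[l])
    return d


def select_shared_subgroups(models: list[SubgroupModel], K0: int) -> list[int]:
    """The K0 subgroups minimizing the within-subset sum of symmetrised KL.

    Exhaustive search over subsets when there are at most
    ``EXHAUSTIVE_LIMIT`` candidates, greedy forward selection otherwise.
    With ``K0 = 1`` the between-subgroup divergence plays no role and the
    first subgroup is returned.
    """
    K = len(models)
    if not 1 <= K0 <= K:
        raise ValueError("K0 must lie in [1, K]")
    if K0 == K:
        return list(range(K))
    if K0 == 1:
        return [0]
    d = _kl_matrix(models)

    def subset_cost(idx):
        return sum(d[a, b] for a, b in combinations(idx, 2))

    if math.comb(K, K0) <= EXHAUSTIVE_LIMIT:
        return list(min(combinations(range(K), K0), key=subset_cost))
    # greedy: best pair, then cheapest additions
    best = list(min(combinations(range(K), 2), key=lambda ab: d[ab[0], ab[1]]))
    while len(best) < K0:
        rest = [k for k in range(K) if k not in best]
        best.append(min(rest, key=lambda k: d[k, best].sum()))
    return sorted(best)


def _draw_sparse_vector(p, sparsity, truncation, rng) -> np.ndarray:
    """Bernoulli support, truncated-normal effects; redrawn if empty.

    Nonzeros are standard normal conditioned on magnitude >= ``truncation``
    (rejection sampling), so effects are never vanishingly small.  An
    all-zero draw is redrawn: a subgroup with no signal would make a
    noiseless response degenerate.
    """
    while True:
        support = rng.random(p) < sparsity
        if support.any():
            break
    beta = np.zeros(p)
    idx = np.flatnonzero(support)
    need = len(idx)
    vals = np.empty(0)
    while len(vals) < need:
        draw = rng.standard_normal(2 * need + 8)
        vals = np.concatenate([vals, draw[np.abs(draw) >= truncation]])
    beta[idx] = vals[:need]
    return beta


def draw_coefficients(
    design: SimulationDesign, V0: list[int], seed: int | np.random.Generator
) -> np.ndarray:
    """True coefficient matrix: one shared draw for V0, one per other subgroup."""
    rng = np.random.default_rng(seed)
    B = np.zeros((design.p, design.K))
    shared = _draw_sparse_vector(design.p, design.sparsity, design.truncation, rng)
    for k in V0:
        B[:, k] = shared
    for k in range(design.K):
        if k not in V0:
            B[:, k] = _draw_sparse_vector(
                design.p, design.sparsity, design.truncation, rng
            )
    return B


def simulate_from_truth(
    truth: SimulationTruth, n: int, seed: int | np.random.Generator
) -> GroupedDataset:
    """Draw a new dataset (standardized) from an existing ground truth.

    Useful for generating independent test sets governed by the same
    subgroup models and coefficients as a training set.
    """
    design = truth.design
    rng = np.random.default_rng(seed)
    sizes = SimulationDesign(
        K=design.K, K0=design.K0, p=design.p, n=n,
        proportions=design.proportions, sparsity=design.sparsity,
        truncation=design.truncation, noise_scale=design.noise_scale,
        heterogeneity=design.heterogeneity,
    ).group_sizes()
    Xs, ys, labels = [], [], []
    width = len(str(design.K - 1))
    for k in range(design.K):
        m = truth.models[k]
        chol = np.linalg.cholesky(m.sigma)
        Xk = rng.standard_normal((sizes[k], design.p)) @ chol.T + m.mu
        yk = Xk @ truth.B[:, k] + truth.noise_scale * rng.standard_normal(sizes[k])
        Xs.append(Xk)
        ys.append(yk)
        labels.append(np.repeat(f"g{k:0{width}d}", sizes[k]))
    ds = split_by_group(
        np.vstack(Xs), np.concatenate(ys), np.concatenate(labels)
    )
    return standardize_subgroups(ds)


def simulate_dataset(
    design: SimulationDesign, seed: int
) -> tuple[GroupedDataset, SimulationTruth]:
    """Generate one simulated study: standardized dataset plus ground truth.

    Reproducible: the same ``(design, seed)`` yields an identical dataset.
    The truth's coefficient matrix is on the raw feature/response scale.
    """
    rng = np.random.default_rng(seed)
    models = make_subgroup_models(design.K, design.p, design.heterogeneity, rng)
    V0 = select_shared_subgroups(models, design.K0)
    B = draw_coefficients(design, V0, rng)
    truth = SimulationTruth(
        B=B, V0=V0, models=models, noise_scale=design.noise_scale, design=design
    )
    ds = simulate_from_truth(truth, design.n, rng)
    return ds, truth
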