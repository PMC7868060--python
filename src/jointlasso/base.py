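"""Shared dataclasses: penalty specification and fit results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TAU_MODES = ("unweighted", "mean-distance", "symmetrised-KL", "user-supplied")


@dataclass
class FusionSpec:
    """Tuning parameters of the joint lasso penalty.

    Parameters
    ----------
    lam:
        Weight of the l1 sparsity penalty on every coefficient, ``>= 0``.
    gamma:
        Weight of the pairwise fusion penalty between subgroup coefficient
        vectors, ``>= 0``.
    tau:
        Optional ``K x K`` symmetric matrix of pair weights in ``[0, 1]``
        with zero diagonal, modulating fusion strength per subgroup pair.
        ``None`` means unweighted fusion (all off-diagonal weights equal 1).
    mode:
        How ``tau`` was constructed; one of ``unweighted``, ``mean-distance``,
        ``symmetrised-KL`` or ``user-supplied``.  Informational except that
        ``unweighted`` forces ``tau`` to all ones off the diagonal.
    """

    lam: float
    gamma: float
    tau: np.ndarray | None = None
    mode: str = "unweighted"

    def __post_init__(self) -> None:
        if self.lam < 0 or self.gamma < 0:
            raise ValueError("lambda and gamma must be non-negative")
        if self.mode not in TAU_MODES:
            raise ValueError(f"unknown tau mode {self.mode!r}; expected one of {TAU_MODES}")
        if self.tau is not None:
            self.tau = np.asarray(self.tau, dtype=float)

    def tau_matrix(self, K: int) -> np.ndarray:
        """Return the validated ``K x K`` pair-weight matrix.

        In unweighted mode (or when no matrix was supplied) every
        off-diagonal entry is 1.
        """
        if self.tau is None or self.mode == "unweighted":
            tau = np.ones((K, K)) - np.eye(K)
            return tau
        tau = self.tau
        if tau.shape != (K, K):
            raise ValueError(f"tau must be {K} x {K}, got {tau.shape}")
        if not np.allclose(tau, tau.T, atol=1e-10):
            raise ValueError("tau must be symmetric")
        if np.any(np.diag(tau) != 0):
            raise ValueError("tau must have a zero diagonal")
        if np.any(tau < 0):
            raise ValueError("tau entries must be non-negative")
        return tau


@dataclass
class FitResult:
    """Outcome of one joint-lasso fit.

    ``B`` is the ``p x K`` coefficient matrix on the standardized scale
    (column ``k`` is the coefficient vector of subgroup ``k``).
    """

    B: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    solver: str
    spec: FusionSpec
    group_names: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)

    @property
    def support(self) -> np.ndarray:
        """Boolean ``p x K`` mask of nonzero coefficients."""
        return self.B != 0.0
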