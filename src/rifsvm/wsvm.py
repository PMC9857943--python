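"""Per-instance-weighted soft-margin SVM: kernels, dual QP, bias, decision.

The primal penalizes each slack by s_i * C, so the dual box constraint becomes
0 <= alpha_i <= s_i C: an instance's fuzzy value directly caps how much
influence it can exert on the separating surface. ``fit`` composes the full
pipeline: fuzzy weights (relative-density intuitionistic, centroid
intuitionistic, or unit) -> Gram matrix -> SMO dual solve -> bias recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._smo import smo_solve
from .datasets import LabeledDataset
from .memberships import FuzzyWeights, IFConfig, ifsvm_weights_from_gram, rif_weights
from .relative_density import KPolicy

__all__ = [
    "KernelSpec",
    "DualSolution",
    "TrainedModel",
    "kernel_matrix",
    "solve_weighted_dual",
    "compute_bias",
    "decision_values",
    "fit",
]

SV_THRESHOLD_SCALE = 1e-8  # alpha_i > 1e-8 * C * max(s) counts as a support vector


@dataclass(frozen=True)
class KernelSpec:
    """Kernel: 'rbf' with K(x,x') = exp(-h ||x-x'||^2), or 'linear'."""

    kind: str = "rbf"
    h: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ValueError("kernel kind must be 'rbf' or 'linear'")
        if self.kind == "rbf" and self.h <= 0:
            raise ValueError("rbf spread h must be > 0")


def kernel_matrix(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix with entry (i, j) = K(a_i, b_j)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if spec.kind == "linear":
        return A @ B.T
    return np.exp(-spec.h * cdist(A, B, "sqeuclidean"))


def rbf_gram_from_sqdist(sqdist: np.ndarray, h: float) -> np.ndarray:
    """RBF Gram from a precomputed squared-distance matrix (grid-search fast path)."""
    return np.exp(-h * sqdist)


@dataclass
class DualSolution:
    """KKT point of the weighted dual QP."""

    alpha: np.ndarray
    objective: float
    gradient: np.ndarray  # grad_i = (Q alpha)_i - 1 of the minimization form
    kkt_gap: float  # m - M violating-pair gap at termination
    iterations: int
    upper: np.ndarray  # per-instance box bound s_i * C
    support: np.ndarray = field(init=False)
    at_bound: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        thresh = SV_THRESHOLD_SCALE * max(self.upper.max(), 1e-300)
        self.support = self.alpha > thresh
        self.at_bound = self.alpha >= self.upper - thresh


def solve_weighted_dual(
    K: np.ndarray,
    y: np.ndarray,
    s,
    C: float,
    tol: float = 1e-6,
    max_iter: int = 10_000_000,
    check_psd: bool = False,
) -> DualSolution:
    """Maximize sum(a) - 1/2 a'(yy'∘K)a s.t. y'a = 0, 0 <= a_i <= s_i C.

    Deterministic SMO (see :mod:`rifsvm._smo`). ``check_psd`` additionally
    verifies K is symmetric PSD, adding a 1e-10 diagonal jitter for marginal
    eigenvalue violations and raising beyond that; it is off by default since
    RBF/linear self-Grams are PSD by construction.
    """
    K = np.ascontiguousarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = s.s if isinstance(s, FuzzyWeights) else np.asarray(s, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n) or y.shape != (n,) or weights.shape != (n,):
        raise ValueError("K, y, s must share the instance dimension")
    if C <= 0:
        raise ValueError("C must be > 0")
    if check_psd:
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kernel matrix is not symmetric")
        w_min = float(np.linalg.eigvalsh(K).min())
        if w_min < -1e-6 * max(1.0, float(np.abs(K).max())):
            raise ValueError(f"kernel matrix is not PSD (min eigenvalue {w_min:.3g})")
        if w_min < 0:
            K = K + 1e-10 * np.eye(n)
    u = weights * C
    for label in (1.0, -1.0):
        if not np.any((y == label) & (u > 0)):
            raise ValueError(f"no trainable instances in class {int(label):+d}")

    Q = np.ascontiguousarray((y[:, None] * y[None, :]) * K)
    alpha, grad, m, M, iters = smo_solve(Q, y, np.ascontiguousarray(u, dtype=float), tol, max_iter)
    objective = 0.5 * float(np.sum(alpha) - alpha @ grad)
    return DualSolution(alpha, objective, grad, float(m - M), int(iters), u)


def compute_bias(solution: DualSolution, K: np.ndarray, y: np.ndarray) -> float:
    """Bias from free support vectors: mean of y_i - sum_j a_j y_j K_ij.

    Falls back to the midpoint of the feasible interval implied by the bound
    constraints when no support vector is strictly inside the box.
    """
    y = np.asarray(y, dtype=float)
    if not np.any(solution.support):
        raise ValueError("no support vectors: cannot recover bias")
    free = solution.support & ~solution.at_bound
    # for a free SV, y_i - (K alpha y)_i = -y_i grad_i
    neg_yg = -y * solution.gradient
    if np.any(free):
        return float(neg_yg[free].mean())
    up = ((y > 0) & (solution.alpha < solution.upper)) | ((y < 0) & (solution.alpha > 0))
    low = ((y > 0) & (solution.alpha > 0)) | ((y < 0) & (solution.alpha < solution.upper))
    return float((neg_yg[up].max() + neg_yg[low].min()) / 2.0)


@dataclass
class TrainedModel:
    """Fitted weighted SVM: support expansion, bias, kernel, and provenance."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i for support vectors
    bias: float
    kernel: KernelSpec
    C: float
    scheme: str
    weights: FuzzyWeights | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError("dimension mismatch with training features")
        return kernel_matrix(X, self.support_vectors, self.kernel) @ self.dual_coef + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_function(X)
        return np.where(f >= 0, 1, -1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": {"kind": self.kernel.kind, "h": self.kernel.h},
                "C": self.C,
                "scheme": self.scheme,
                "bias": self.bias,
                "support_vectors": self.support_vectors.tolist(),
                "dual_coef": self.dual_coef.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            bias=float(d["bias"]),
            kernel=KernelSpec(**d["kernel"]),
            C=float(d["C"]),
            scheme=d["scheme"],
        )


def decision_values(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Pre-sign decision values f(x) = sum_i a_i y_i K(x_i, x) + b."""
    return model.decision_function(X)


def compute_weights(
    dataset: LabeledDataset,
    scheme: str,
    kernel: KernelSpec,
    policy: KPolicy | None = None,
    if_config: IFConfig | None = None,
    K: np.ndarray | None = None,
) -> FuzzyWeights:
    """Fuzzy values for a training set under the requested scheme."""
    if scheme == "rif":
        return rif_weights(dataset, policy=policy)
    if scheme == "ifsvm":
        if K is None:
            K = kernel_matrix(dataset.X, dataset.X, kernel)
        return ifsvm_weights_from_gram(K, dataset.y, if_config)
    if scheme == "unit":
        return FuzzyWeights(np.ones(dataset.n), dataset.imbalance_ratio, "unit")
    raise ValueError("scheme must be 'rif', 'ifsvm', or 'unit'")


def fit(
    dataset: LabeledDataset,
    scheme: str = "rif",
    C: float = 1.0,
    kernel: KernelSpec | None = None,
    policy: KPolicy | None = None,
    if_config: IFConfig | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000_000,
    weights: FuzzyWeights | None = None,
    K: np.ndarray | None = None,
) -> TrainedModel:
    """End-to-end weighted-SVM fit: weights -> Gram -> dual solve -> bias.

    ``weights``/``K`` may be supplied to reuse precomputed values (the
    cross-validation loop does); otherwise they are derived from ``scheme``.
    """
    kernel = kernel or KernelSpec()
    dataset.require_trainable()
    if K is None:
        K = kernel_matrix(dataset.X, dataset.X, kernel)
    if weights is None:
        weights = compute_weights(dataset, scheme, kernel, policy, if_config, K=K)
    solution = solve_weighted_dual(K, dataset.y, weights, C, tol=tol, max_iter=max_iter)
    bias = compute_bias(solution, K, dataset.y)
    sv = solution.support
    return TrainedModel(
        support_vectors=dataset.X[sv],
        dual_coef=solution.alpha[sv] * dataset.y[sv],
        bias=bias,
        kernel=kernel,
        C=C,
        scheme=scheme,
        weights=weights,
    )
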