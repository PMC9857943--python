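"""Fuzzy instance weights for weighted soft-margin SVM training.

Three families are provided:

* **RIF** — the relative-density intuitionistic scheme. Majority instances get
  an intuitionistic pair (μ, ν) built from within-/between-class k-th NN
  distances through the exponential decay 2/(1+exp(d/D)); their weight is the
  imbalance ratio times the score H = (1−ν)/(2−μ−ν) (zero when ν dominates).
  Minority instances are weighted by their membership degree alone, so sparse
  minority points are never written off as noise.
* **IFSVM** — the kernel-space centroid baseline: membership from the distance
  to the class center relative to the class radius, non-membership from the
  fraction of opposite-class points inside a β₁-ball, score applied to both
  classes.
* Classic one-parameter membership curves (linear, exponential, Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import LabeledDataset
from .relative_density import DensityProfile, KPolicy, density_profile

__all__ = [
    "IntuitionisticAssignment",
    "FuzzyWeights",
    "IFConfig",
    "rif_majority_membership",
    "rif_majority_nonmembership",
    "rif_score",
    "rif_weights",
    "if_membership",
    "if_nonmembership",
    "if_weights",
    "ifsvm_weights",
    "ifsvm_weights_from_gram",
    "classic_membership",
]


@dataclass(frozen=True)
class IntuitionisticAssignment:
    """Per-instance intuitionistic values: membership μ, non-membership ν,
    opposite-class affinity ρ, and score H. Entries are NaN where a quantity
    is not defined for that instance under the scheme."""

    mu: np.ndarray
    nu: np.ndarray
    rho: np.ndarray
    H: np.ndarray


@dataclass(frozen=True)
class FuzzyWeights:
    """Final per-instance fuzzy values s ∈ [0,1] plus the imbalance ratio."""

    s: np.ndarray
    IR: float
    scheme: str
    assignment: IntuitionisticAssignment | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("fuzzy values must lie in [0, 1]")
        object.__setattr__(self, "s", np.clip(s, 0.0, 1.0))

    def to_frame(self, labels=None):
        """Per-instance table (label, mu, nu, rho, H, s) for inspection/export."""
        import pandas as pd

        a = self.assignment
        data = {"s": self.s}
        if labels is not None:
            data = {"label": np.asarray(labels), **data}
        if a is not None:
            data.update({"mu": a.mu, "nu": a.nu, "rho": a.rho, "H": a.H})
        return pd.DataFrame(data)


@dataclass(frozen=True)
class IFConfig:
    """IFSVM parameters: ball slack δ and ball radius β₁ ('auto' = min(R+,R-)/5)."""

    delta: float = 1e-4
    beta1: float | str = "auto"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.beta1 != "auto" and self.beta1 <= 0:
            raise ValueError("beta1 must be > 0 or 'auto'")


def _exp_decay(d: np.ndarray, D: float) -> np.ndarray:
    """2 / (1 + exp(d/D)); all ones when the normalizer D degenerates to 0."""
    d = np.asarray(d, dtype=float)
    if D <= 0:
        return np.ones_like(d)
    return 2.0 / (1.0 + np.exp(d / D))


def rif_majority_membership(profile: DensityProfile) -> np.ndarray:
    """Majority membership μ⁻ from within-class k-th NN distances."""
    maj = profile.labels == -1
    return _exp_decay(profile.d_within[maj], profile.max_within_neg)


def rif_majority_nonmembership(
    profile: DensityProfile, mu_neg: np.ndarray, normalizer: str = "majority"
) -> tuple[np.ndarray, np.ndarray]:
    """Majority (ρ, ν⁻) from between-class (majority→minority) distances.

    ``normalizer`` picks the denominator of the decay: ``"majority"`` (default)
    uses the maximum between-class distance over the majority instances being
    scored; ``"minority-within"`` uses the minority class's maximum
    within-class distance instead.
    """
    maj = profile.labels == -1
    if normalizer == "majority":
        B = profile.max_between_neg
    elif normalizer == "minority-within":
        B = profile.max_within_pos
    else:
        raise ValueError("normalizer must be 'majority' or 'minority-within'")
    rho = _exp_decay(profile.d_between[maj], B)
    nu = (1.0 - mu_neg) * rho
    return rho, nu


def rif_score(mu: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Intuitionistic score: 0 where μ < ν, else (1−ν)/(2−μ−ν)."""
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    return np.where(mu < nu, 0.0, (1.0 - nu) / (2.0 - mu - nu))


def rif_weights(
    dataset: LabeledDataset,
    profile: DensityProfile | None = None,
    policy: KPolicy | None = None,
    normalizer: str = "majority",
) -> FuzzyWeights:
    """Relative-density intuitionistic fuzzy values for the whole training set.

    Majority: s = IR · H(μ⁻, ν⁻). Minority: s = μ⁺ from within-class distances.
    """
    if profile is None:
        profile = density_profile(dataset, policy)
    maj = profile.labels == -1
    mu_neg = rif_majority_membership(profile)
    rho_neg, nu_neg = rif_majority_nonmembership(profile, mu_neg, normalizer)
    H_neg = rif_score(mu_neg, nu_neg)
    IR = dataset.imbalance_ratio
    mu_pos = _exp_decay(profile.d_within[~maj], profile.max_within_pos)

    n = dataset.n
    mu = np.full(n, np.nan)
    nu = np.full(n, np.nan)
    rho = np.full(n, np.nan)
    H = np.full(n, np.nan)
    s = np.empty(n)
    mu[maj], nu[maj], rho[maj], H[maj] = mu_neg, nu_neg, rho_neg, H_neg
    mu[~maj] = mu_pos
    s[maj] = IR * H_neg
    s[~maj] = mu_pos
    return FuzzyWeights(s, IR, "rif", IntuitionisticAssignment(mu, nu, rho, H))


def _center_distances(K: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Kernel-space distance of every instance to its own class mean.

    Uses the Gram expansion ||φ(x_i) − c||² = K_ii − (2/N) Σ_j K_ij + (1/N²) ΣΣ K_mn
    with sums over the instance's own class.
    """
    d2 = np.empty(len(y))
    diag = np.diag(K)
    for label in (1, -1):
        mask = y == label
        Kc = K[np.ix_(mask, mask)]
        d2[mask] = diag[mask] - 2.0 * Kc.mean(axis=1) + Kc.mean()
    return np.sqrt(np.maximum(d2, 0.0))


def _class_radii(d_center: np.ndarray, y: np.ndarray) -> dict[int, float]:
    return {label: float(d_center[y == label].max()) for label in (1, -1)}


def _if_membership_from_gram(K: np.ndarray, y: np.ndarray, config: IFConfig) -> np.ndarray:
    d = _center_distances(K, y)
    radii = _class_radii(d, y)
    mu = np.empty(len(y))
    for label in (1, -1):
        mask = y == label
        mu[mask] = 1.0 - d[mask] / (radii[label] + config.delta)
    return mu


def _if_nonmembership_from_gram(
    K: np.ndarray, y: np.ndarray, config: IFConfig, mu: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if config.beta1 == "auto":
        radii = _class_radii(_center_distances(K, y), y)
        beta1 = min(radii[1], radii[-1]) / 5.0
    else:
        beta1 = float(config.beta1)
    diag = np.diag(K)
    d = np.sqrt(np.maximum(diag[:, None] + diag[None, :] - 2.0 * K, 0.0))
    within = d <= beta1
    opposite = y[:, None] != y[None, :]
    rho = (within & opposite).sum(axis=1) / within.sum(axis=1)
    nu = (1.0 - mu) * rho
    return rho, nu


def if_membership(dataset: LabeledDataset, kernel, config: IFConfig | None = None) -> np.ndarray:
    """Centroid membership μ = 1 − ||φ(x)−c_class|| / (R_class + δ)."""
    from .wsvm import kernel_matrix

    K = kernel_matrix(dataset.X, dataset.X, kernel)
    return _if_membership_from_gram(K, dataset.y, config or IFConfig())


def if_nonmembership(
    dataset: LabeledDataset, kernel, config: IFConfig | None = None, mu: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ball-count non-membership: ρ = (#opposite within β₁) / (#all within β₁).

    Pairwise distances are taken in kernel space; the counting ball always
    contains the instance itself, so the denominator is at least 1.
    """
    from .wsvm import kernel_matrix

    config = config or IFConfig()
    K = kernel_matrix(dataset.X, dataset.X, kernel)
    if mu is None:
        mu = _if_membership_from_gram(K, dataset.y, config)
    return _if_nonmembership_from_gram(K, dataset.y, config, mu)


def if_weights(mu: np.ndarray, nu: np.ndarray, IR: float = 1.0) -> FuzzyWeights:
    """Score-function weights applied to both classes (IFSVM baseline).

    s = μ when ν = 0; 0 when μ < ν; else (1−ν)/(2−μ−ν).
    """
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    s = np.where(nu == 0.0, mu, np.where(mu < nu, 0.0, (1.0 - nu) / (2.0 - mu - nu)))
    rho = np.full_like(mu, np.nan)
    return FuzzyWeights(s, IR, "ifsvm", IntuitionisticAssignment(mu, nu, rho, s))


def ifsvm_weights_from_gram(
    K: np.ndarray, y: np.ndarray, config: IFConfig | None = None
) -> FuzzyWeights:
    """IFSVM weighting pipeline on a precomputed self-Gram matrix."""
    config = config or IFConfig()
    y = np.asarray(y)
    mu = _if_membership_from_gram(K, y, config)
    rho, nu = _if_nonmembership_from_gram(K, y, config, mu)
    fw = if_weights(mu, nu, float(np.sum(y == 1) / np.sum(y == -1)))
    return FuzzyWeights(fw.s, fw.IR, "ifsvm", IntuitionisticAssignment(mu, nu, rho, fw.s))


def ifsvm_weights(dataset: LabeledDataset, kernel, config: IFConfig | None = None) -> FuzzyWeights:
    """Full IFSVM weighting pipeline: μ, then (ρ, ν), then score-function s."""
    from .wsvm import kernel_matrix

    K = kernel_matrix(dataset.X, dataset.X, kernel)
    return ifsvm_weights_from_gram(K, dataset.y, config)


def classic_membership(d: np.ndarray, kind: str, **params) -> np.ndarray:
    """Classic one-parameter membership curves over distances ``d`` >= 0.

    linear: 1 − d/(max(d)+Δ); exponential: 2/(1+exp(β d));
    gaussian: exp(−(d−μ)²/(2σ²)).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if kind == "linear":
        delta = params.get("delta", 1e-4)
        if delta <= 0:
            raise ValueError("delta must be > 0")
        return 1.0 - d / (d.max() + delta)
    if kind == "exponential":
        beta = params.get("beta", 1.0)
        if not 0 <= beta <= 1:
            raise ValueError("beta must lie in [0, 1]")
        return 2.0 / (1.0 + np.exp(beta * d))
    if kind == "gaussian":
        mu = params.get("mu", 0.0)
        sigma = params.get("sigma", 1.0)
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        return np.exp(-((d - mu) ** 2) / (2.0 * sigma**2))
    raise ValueError("kind must be 'linear', 'exponential', or 'gaussian'")
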