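"""Fisher-Z accuracy theory for predicted breeding values.

Core quantities:

* ``Z = log((1+R)/(1-R))``, approximately normal with mean
  ``log((1+rho)/(1-rho))`` and variance ``4/(n-3)`` for a realized
  correlation R around a true correlation rho;
* the erosion model ``E(Z|erosion) = r * mu_Z`` where r in [0, 1] is the
  index of genetic correlation (IGC) between reference and target
  populations, which back-transforms to::

      E(R|erosion) = ((1+rho)^r - (1-rho)^r) / ((1+rho)^r + (1-rho)^r)

* reference comparators from Henderson's mixed-model equations: the mean
  theoretical GBLUP reliability of the target population and the average
  weighted reference-target relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .mixed_model import VarianceComponents

__all__ = [
    "AccuracyEstimate",
    "ErosionExpectation",
    "GBLUPReference",
    "fisher_z",
    "inv_fisher_z",
    "rho_cap",
    "expected_R_erosion",
    "correlation_ci",
    "expected_R_gblup",
    "r_gblup",
    "erosion_expectation",
]


@dataclass
class AccuracyEstimate:
    """A realized accuracy with its Fisher transform and confidence interval."""

    R: float
    n: int
    Z: float
    ci_low: float
    ci_high: float


@dataclass
class ErosionExpectation:
    """Expected target-population accuracy under erosion."""

    rho: float
    r: float
    mu_z: float
    expected_R: float


@dataclass
class GBLUPReference:
    """Henderson-MME comparators for the erosion expectation and the IGC."""

    expected_R_gblup: float
    r_gblup: float


def fisher_z(R):
    """Fisher transform ``Z = log((1+R)/(1-R))`` (twice the usual atanh)."""
    R = np.asarray(R, dtype=float)
    if np.any(np.abs(R) >= 1.0):
        raise ValueError("|R| must be < 1")
    out = np.log((1.0 + R) / (1.0 - R))
    return float(out) if out.ndim == 0 else out

def inv_fisher_z(Z):
    """Inverse transform ``R = (e^Z - 1)/(e^Z + 1)``."""
    Z = np.asarray(Z, dtype=float)
    out = np.tanh(Z / 2.0)
    return float(out) if out.ndim == 0 else out


def rho_cap(cor_ref: float, h2: float) -> float:
    """Reference accuracy ``rho = min{cor(g1_hat, y1), sqrt(h2)}``, floored at 0.

    The cap applies when the model cannot separate genetic from residual
    effects and the training correlation exceeds the theoretical ceiling.
    """
    if not -1.0 < cor_ref < 1.0:
        raise ValueError("cor_ref must be in (-1, 1)")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    rho = min(cor_ref, float(np.sqrt(h2)))
    if rho < 0.0:
        warnings.warn("negative reference accuracy floored at 0", stacklevel=2)
        return 0.0
    return rho


def expected_R_erosion(rho, r):
    """Expected accuracy of PBV under erosion.

    Evaluates ``((1+rho)^r - (1-rho)^r) / ((1+rho)^r + (1-rho)^r)``; equals
    rho at r = 1 (no erosion) and 0 at r = 0 (target unrelated to
    reference), and is monotone increasing in both arguments.
    """
    rho = np.asarray(rho, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any((rho < 0.0) | (rho >= 1.0)):
        raise ValueError("rho must be in [0, 1)")
    if np.any((r < 0.0) | (r > 1.0)):
        raise ValueError("r must be in [0, 1]")
    up = (1.0 + rho) ** r
    dn = (1.0 - rho) ** r
    out = (up - dn) / (up + dn)
    return float(out) if out.ndim == 0 else out


def erosion_expectation(rho: float, r: float) -> ErosionExpectation:
    """Bundle rho, r, mu_Z and E(R|erosion) into one record."""
    return ErosionExpectation(
        rho=rho,
        r=r,
        mu_z=fisher_z(rho),
        expected_R=expected_R_erosion(rho, r),
    )


def correlation_ci(R: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Normal-theory interval on the Fisher-Z scale, back-transformed.

    Uses ``SE(Z) = 2 / sqrt(n - 3)`` matching the variance ``4/(n-3)`` of
    ``Z = log((1+R)/(1-R))``.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    z = fisher_z(R)
    half = norm.ppf(1.0 - alpha / 2.0) * 2.0 / np.sqrt(n - 3.0)
    return (inv_fisher_z(z - half), inv_fisher_z(z + half))


def accuracy_estimate(R: float, n: int, alpha: float = 0.05) -> AccuracyEstimate:
    low, high = correlation_ci(R, n, alpha)
    return AccuracyEstimate(R=R, n=n, Z=fisher_z(R), ci_low=low, ci_high=high)


def _floored_sqrt_diag(mat: np.ndarray, what: str) -> np.ndarray:
    d = np.diag(mat).copy()
    neg = d < 0.0
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} negative diagonal terms floored at 0 in {what}",
            stacklevel=3,
        )
        d[neg] = 0.0
    return np.sqrt(d)


def expected_R_gblup(
    W11: np.ndarray,
    W12: np.ndarray,
    W21: np.ndarray,
    vc: VarianceComponents,
    h2_hat: float | None = None,
) -> float:
    """Mean theoretical GBLUP reliability of the target population.

    Evaluates, with ``LHS = I/sigma2_e + W11^-1/sigma2_g`` (the mixed-model
    left-hand side for the no-fixed-effect animal model)::

        sqrt(h2_hat)/n2 * sum_i sqrt([W21 W11^-1 (W11 - (LHS sigma2_g)^-1)
                                      W11^-1 W12]_ii)

    Negative bracket diagonals (numerical prediction-error artifacts) are
    floored at 0 with a warning.
    """
    W11 = np.asarray(W11, dtype=float)
    W12 = np.asarray(W12, dtype=float)
    W21 = np.asarray(W21, dtype=float)
    n1 = W11.shape[0]
    n2 = W21.shape[0]
    h2 = vc.h2 if h2_hat is None else float(h2_hat)
    try:
        W11_inv = np.linalg.inv(W11)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"W11 is singular; condition number {np.linalg.cond(W11):.3e}"
        ) from exc
    ratio = vc.sigma2_g / vc.sigma2_e
    middle_inv = np.linalg.inv(ratio * np.eye(n1) + W11_inv)  # (LHS*s2g)^-1
    bracket = W21 @ W11_inv @ (W11 - middle_inv) @ W11_inv @ W12
    roots = _floored_sqrt_diag(bracket, "E(R|GBLUP)")
    return float(np.sqrt(h2) / n2 * roots.sum())


def r_gblup(W11: np.ndarray, W21: np.ndarray, W12: np.ndarray | None = None) -> float:
    """Average weighted reference-target relationship,
    ``(1/n2) sum_i sqrt([W21 W11^-1 W12]_ii)``."""
    W11 = np.asarray(W11, dtype=float)
    W21 = np.asarray(W21, dtype=float)
    W12 = W21.T if W12 is None else np.asarray(W12, dtype=float)
    try:
        sol = np.linalg.solve(W11, W12)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"W11 is singular; condition number {np.linalg.cond(W11):.3e}"
        ) from exc
    bracket = W21 @ sol
    roots = _floored_sqrt_diag(bracket, "r_GBLUP")
    return float(roots.mean())


def gblup_reference_eig(
    eigvals: np.ndarray,
    P: np.ndarray,
    vc: VarianceComponents,
    h2_hat: float | None = None,
) -> GBLUPReference:
    """Spectral fast path for the two Henderson-MME comparators.

    ``eigvals``/``P`` come from ``W11 = Q diag(lam) Q'`` with ``P = W21 Q``;
    both quantities reduce to weighted row sums of ``P**2``, which makes the
    evaluation cheap inside replicate loops.  Must agree with the dense
    formulas to numerical precision.
    """
    lam = np.asarray(eigvals, dtype=float)
    h2 = vc.h2 if h2_hat is None else float(h2_hat)
    ratio = vc.sigma2_g / vc.sigma2_e
    P2 = P**2
    # W11^-1 (W11 - (LHS s2g)^-1) W11^-1 is diag(ratio / (ratio*lam + 1))
    # in the eigenbasis of W11 (algebraic simplification of the bracket)
    f_rel = ratio / (ratio * lam + 1.0)
    d1 = P2 @ f_rel
    d1[d1 < 0] = 0.0
    e_r = float(np.sqrt(h2) / P.shape[0] * np.sqrt(d1).sum())
    with np.errstate(divide="ignore"):
        f_r = np.where(lam > 0, 1.0 / lam, 0.0)
    d2 = P2 @ f_r
    d2[d2 < 0] = 0.0
    r_g = float(np.sqrt(d2).mean())
    return GBLUPReference(expected_R_gblup=e_r, r_gblup=r_g)
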