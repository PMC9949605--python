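"""Causal-effect estimators for two-sample MR with correlated instruments.

All estimators consume a :class:`~cismr.gwas_io.HarmonizedSet` (allele-aligned
exposure effects bx ± sx, outcome log-odds effects by ± sy, and the signed LD
correlation R among the instruments) and return a :class:`CausalEstimate` on
the outcome's log-odds scale per unit of exposure, with the odds-ratio
transform applied for reporting.

Methods
-------
wald_ratio
    Single-instrument ratio by/bx, with a first-order (sy/|bx|) or
    second-order delta-method standard error.
ivw_correlated
    Fixed-effects inverse-variance weighting generalized to correlated
    instruments: a GLS regression of by on bx through the origin with
    error covariance Omega, Omega_kl = sy_k sy_l R_kl. With identity R this
    reduces exactly to the classical fixed-effects IVW.
ivw_pca
    The same GLS after projecting instruments onto the leading principal
    components of the weighted correlation matrix Psi,
    Psi_kl = bx_k bx_l R_kl / (sy_k sy_l), retaining the fewest components
    whose eigenvalues explain at least the requested variance fraction.
    Handles near-collinear instrument sets on which Omega is singular.

Linear systems are solved directly; no explicit matrix inverse is formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .errors import EstimationError
from .gwas_io import HarmonizedSet

__all__ = [
    "CausalEstimate",
    "GlsWeightMatrices",
    "build_gls_weights",
    "to_odds_scale",
    "wald_ratio",
    "ivw_correlated",
    "ivw_pca",
    "invert_direction",
]

#: Components with eigenvalue below this fraction of the largest are never
#: retained, regardless of the variance threshold (noise-amplification guard).
EIGENVALUE_FLOOR = 1e-10

#: Omega condition guard for the dense GLS path.
CONDITION_FLOOR = 1e-10


class OddsScale(NamedTuple):
    or_point: float
    ci_low: float
    ci_high: float
    pval: float


def to_odds_scale(beta_hat: float, se_hat: float, level: float = 0.95) -> OddsScale:
    """Exponentiate a log-odds estimate into OR, normal CI, and two-sided p."""
    if se_hat <= 0:
        raise EstimationError("se_hat must be > 0")
    if not 0 < level < 1:
        raise EstimationError("level must lie in (0, 1)")
    z = stats.norm.ppf((1 + level) / 2)
    pval = 2 * stats.norm.sf(abs(beta_hat) / se_hat)
    return OddsScale(
        float(np.exp(beta_hat)),
        float(np.exp(beta_hat - z * se_hat)),
        float(np.exp(beta_hat + z * se_hat)),
        float(pval),
    )


@dataclass(frozen=True)
class CausalEstimate:
    """A method's causal effect on the log-odds scale, with its OR transform."""

    method: str
    beta_hat: float
    se_hat: float
    or_point: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    n_components: Optional[int] = None
    variance_explained: Optional[float] = None

    def __post_init__(self) -> None:
        if self.se_hat <= 0:
            raise EstimationError("se_hat must be > 0")
        if not self.ci_low < self.or_point < self.ci_high:
            raise EstimationError("CI must bracket the point estimate")


def _finish(method, beta_hat, se_hat, n_snps, level=0.95, **extra) -> CausalEstimate:
    odds = to_odds_scale(beta_hat, se_hat, level)
    return CausalEstimate(
        method, float(beta_hat), float(se_hat), odds.or_point, odds.ci_low,
        odds.ci_high, odds.pval, int(n_snps), **extra,
    )


def invert_direction(est: CausalEstimate) -> CausalEstimate:
    """Re-express an estimate per unit *decrement* of the exposure (1/OR framing)."""
    return CausalEstimate(
        est.method, -est.beta_hat, est.se_hat, 1 / est.or_point, 1 / est.ci_high,
        1 / est.ci_low, est.pval, est.n_snps, est.n_components, est.variance_explained,
    )


def wald_ratio(h: HarmonizedSet, se_order: str = "first", level: float = 0.95) -> CausalEstimate:
    """Single-instrument causal estimate by/bx.

    The first-order delta-method SE is sy/|bx| (exposure uncertainty ignored,
    the two-sample MR convention); the second-order SE adds the bx term:
    sqrt(sy²/bx² + by²·sx²/bx⁴).
    """
    if len(h) != 1:
        raise EstimationError(f"wald_ratio needs exactly one variant, got {len(h)}")
    bx, sx, by, sy = h.bx[0], h.sx[0], h.by[0], h.sy[0]
    if bx == 0:
        raise EstimationError("exposure effect is zero; ratio undefined")
    beta_hat = by / bx
    if se_order == "first":
        se_hat = sy / abs(bx)
    elif se_order == "second":
        se_hat = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        raise EstimationError("se_order must be 'first' or 'second'")
    return _finish("wald", beta_hat, se_hat, 1, level)


@dataclass
class GlsWeightMatrices:
    """Weight matrices shared by the correlated-IVW estimators.

    ``omega`` is the covariance of the outcome effect vector,
    omega_kl = sy_k sy_l R_kl; ``psi`` is the weighted correlation matrix whose
    spectrum drives component retention in PCA-IVW,
    psi_kl = bx_k bx_l R_kl / (sy_k sy_l). ``eigenvalues`` (descending) and
    ``components`` (matching columns) are psi's symmetric eigendecomposition.
    """

    omega: np.ndarray
    psi: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray


def build_gls_weights(h: HarmonizedSet) -> GlsWeightMatrices:
    r = h.ld.r
    omega = np.outer(h.sy, h.sy) * r
    w = h.bx / h.sy
    psi = np.outer(w, w) * r
    ev, vec = np.linalg.eigh(psi)
    order = np.argsort(ev)[::-1]
    return GlsWeightMatrices(omega, psi, ev[order], vec[:, order])


def _gls(bx: np.ndarray, by: np.ndarray, omega: np.ndarray, context: str) -> tuple[float, float]:
    ev = np.linalg.eigvalsh(omega)
    if ev.min() <= CONDITION_FLOOR * ev.max():
        cond = np.inf if ev.min() <= 0 else ev.max() / ev.min()
        raise EstimationError(
            f"{context}: outcome covariance is numerically singular "
            f"(condition number {cond:.3e}); consider ivw_pca for collinear instruments"
        )
    sol = np.linalg.solve(omega, np.column_stack([bx, by]))
    denom = float(bx @ sol[:, 0])
    num = float(bx @ sol[:, 1])
    if denom <= 0:
        raise EstimationError(f"{context}: non-positive GLS precision; degenerate exposure effects")
    return num / denom, denom**-0.5


def ivw_correlated(
    h: HarmonizedSet,
    weights: Optional[GlsWeightMatrices] = None,
    level: float = 0.95,
) -> CausalEstimate:
    """Fixed-effects IVW accounting for LD correlation between instruments.

    beta_hat = (bxᵀ Ω⁻¹ by)/(bxᵀ Ω⁻¹ bx), se_hat = (bxᵀ Ω⁻¹ bx)^(-1/2). On a
    single instrument this collapses to the Wald ratio with first-order SE;
    with identity LD it equals classical fixed-effects IVW.
    """
    if len(h) < 1:
        raise EstimationError("at least one instrument required")
    weights = weights or build_gls_weights(h)
    beta_hat, se_hat = _gls(h.bx, h.by, weights.omega, "ivw_correlated")
    return _finish("ivw_correlated", beta_hat, se_hat, len(h), level)


def ivw_pca(
    h: HarmonizedSet,
    variance_threshold: float = 0.99,
    weights: Optional[GlsWeightMatrices] = None,
    level: float = 0.95,
) -> CausalEstimate:
    """IVW on the leading principal components of the weighted correlation matrix.

    The minimal number of components whose cumulative eigenvalue fraction
    reaches ``variance_threshold`` is retained (never components below the
    eigenvalue floor); bx, by and Omega are projected onto those components
    and the GLS estimate computed there. With threshold 1 on a full-rank
    matrix this equals :func:`ivw_correlated`.
    """
    if not 0 < variance_threshold <= 1:
        raise EstimationError("variance_threshold must lie in (0, 1]")
    if len(h) < 1:
        raise EstimationError("at least one instrument required")
    weights = weights or build_gls_weights(h)
    ev = weights.eigenvalues
    total = ev.sum()
    if ev[0] <= 0 or total <= 0:
        raise EstimationError("degenerate weight matrix: no positive eigenvalues")
    eligible = int(np.sum(ev > EIGENVALUE_FLOOR * ev[0]))
    cumfrac = np.cumsum(ev) / total
    k = int(np.searchsorted(cumfrac, variance_threshold - 1e-12) + 1)
    k = max(1, min(k, eligible))
    w_mat = weights.components[:, :k]
    bx_p = w_mat.T @ h.bx
    by_p = w_mat.T @ h.by
    omega_p = w_mat.T @ weights.omega @ w_mat
    omega_p = (omega_p + omega_p.T) / 2
    beta_hat, se_hat = _gls(bx_p, by_p, omega_p, "ivw_pca")
    return _finish(
        "ivw_pca", beta_hat, se_hat, len(h), level,
        n_components=k, variance_explained=float(min(cumfrac[k - 1], 1.0)),
    )
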