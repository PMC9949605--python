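"""Synthetic paired GWAS summary statistics with known causal structure.

Generates exposure and outcome summary-statistics tables under the standard
two-sample MR summary-data model, so every downstream stage (harmonization,
selection, estimation) can be exercised against a known ground truth:

* true joint variant→exposure effects gamma are drawn i.i.d. N(0, gamma_sd²);
* marginal exposure effects are the LD-convolved beta_x = R·gamma;
* marginal outcome effects are beta_y = theta·beta_x + R·alpha, where theta is
  the causal effect on the log-odds scale and alpha (spread ``pleiotropy_sd``)
  are direct variant→outcome effects — zero alpha means valid instruments;
* reported standard errors follow the standardized-trait approximation
  se = 1/sqrt(2·n·p·(1−p)); for a binary outcome with case fraction phi the
  logistic score variance adds a factor 1/sqrt(phi·(1−phi));
* observed betas are the true marginals plus ``noise_scale`` × correlated
  Gaussian noise with covariance diag(se)·R·diag(se), matching the covariance
  of marginal GWAS estimates from a single sample.

Everything is deterministic under a fixed seed. A genotype-panel sampler
(Gaussian-copula threshold model, tetrachorically calibrated so the genotype
correlation matches the requested r) and an empirical LD estimator are
provided so the pipeline can also be run against panel-estimated LD, the way
a reference panel would be used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, LdError
from .gwas_io import LdMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_ld_matrix",
    "parse_ld_structure",
    "marginal_se",
    "sample_genotype_panel",
    "estimate_ld",
    "simulate_paired_studies",
    "write_sim_truth",
]

#: Structure spec: "independent", ("ar1", r) or ("block", sizes, r).
LdStructure = Union[str, tuple]

# GRCh37 TNFRSF1A window used for synthetic variant coordinates.
_POS_LO, _POS_HI = 6_437_923, 6_451_280
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T"), ("C", "A"), ("T", "G")]


def parse_ld_structure(text: str) -> LdStructure:
    """Parse a compact textual structure spec.

    ``independent`` | ``ar1:0.5`` | ``block:2,2:0.84``
    """
    parts = text.strip().split(":")
    if parts[0] == "independent" and len(parts) == 1:
        return "independent"
    if parts[0] == "ar1" and len(parts) == 2:
        return ("ar1", float(parts[1]))
    if parts[0] == "block" and len(parts) == 3:
        sizes = tuple(int(s) for s in parts[1].split(","))
        return ("block", sizes, float(parts[2]))
    raise ConfigError(f"unrecognized LD structure spec: {text!r}")


def make_ld_matrix(m: int, structure: LdStructure = "independent") -> LdMatrix:
    """Build a signed LD correlation matrix with a given structure.

    ``independent`` is the identity; ``("ar1", r)`` has entries r^|i−j|;
    ``("block", sizes, r)`` has r off-diagonal within consecutive blocks and 0
    between. All are positive semidefinite for |r| <= 1 (ar1 requires |r| < 1
    off the trivial case, block requires r >= -1/(size-1) to stay PSD, which
    holds for r >= 0).
    """
    if m < 1:
        raise LdError("m must be >= 1")
    labels = [f"rs{9_000_001 + i}" for i in range(m)]
    if isinstance(structure, str):
        if structure != "independent":
            return make_ld_matrix(m, parse_ld_structure(structure))
        return LdMatrix.identity(labels)
    kind = structure[0]
    if kind == "ar1":
        r = float(structure[1])
        if not -1 <= r <= 1:
            raise LdError("ar1 parameter r must lie in [-1, 1]")
        idx = np.arange(m)
        mat = r ** np.abs(np.subtract.outer(idx, idx)).astype(float)
        return LdMatrix(labels, mat)
    if kind == "block":
        sizes, r = tuple(structure[1]), float(structure[2])
        if not -1 <= r <= 1:
            raise LdError("block parameter r must lie in [-1, 1]")
        if sum(sizes) != m:
            raise LdError(f"block sizes {sizes} must sum to m={m}")
        mat = np.eye(m)
        start = 0
        for s in sizes:
            mat[start:start + s, start:start + s] = r
            start += s
        np.fill_diagonal(mat, 1.0)
        return LdMatrix(labels, mat)
    raise LdError(f"unknown LD structure kind: {kind!r}")


def marginal_se(eaf, n, case_fraction: Optional[float] = None):
    """Large-sample SE of a per-allele marginal effect.

    For a standardized quantitative trait, se = 1/sqrt(2·n·p·(1−p)). For a
    binary trait analysed by logistic regression with case fraction phi, the
    score variance contributes an extra phi·(1−phi) factor:
    se = 1/sqrt(2·n·p·(1−p)·phi·(1−phi)).
    """
    eaf = np.asarray(eaf, dtype=float)
    denom = 2.0 * n * eaf * (1.0 - eaf)
    if case_fraction is not None:
        if not 0 < case_fraction < 1:
            raise ConfigError("case_fraction must lie in (0, 1)")
        denom = denom * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(denom)


# ---------------------------------------------------------------------------
# Genotype panel (Gaussian-copula threshold model)


def _psd_factor(r: np.ndarray) -> np.ndarray:
    """Square root L with L Lᵀ ≈ r, tolerant of semidefinite input."""
    ev, vec = np.linalg.eigh(r)
    ev = np.clip(ev, 0.0, None)
    return vec * np.sqrt(ev)


def _bvn_cdf(t1: float, t2: float, rho: float) -> float:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf([t1, t2]))


def _latent_rho(r_target: float, p1: float, p2: float) -> float:
    """Latent Gaussian correlation whose thresholded-Bernoulli phi equals r_target."""
    if abs(r_target) < 1e-12:
        return 0.0
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    scale = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def phi_gap(rho):
        return (_bvn_cdf(t1, t2, rho) - p1 * p2) / scale - r_target

    lo, hi = -0.9999, 0.9999
    flo, fhi = phi_gap(lo), phi_gap(hi)
    if flo > 0 or fhi < 0:
        # target correlation unattainable for these frequencies; saturate
        warnings.warn(
            f"LD r={r_target:.3f} unattainable for eaf pair ({p1:.3f}, {p2:.3f}); "
            "saturating the latent correlation", stacklevel=2,
        )
        return hi if fhi < 0 else lo
    return float(optimize.brentq(phi_gap, lo, hi, xtol=1e-10))


def sample_genotype_panel(ld: LdMatrix, eaf: Sequence[float], n: int, seed: int) -> np.ndarray:
    """Sample an n × m genotype dosage matrix (values 0/1/2) with target LD.

    Two haplotypes per individual are drawn by thresholding correlated latent
    Gaussians; the latent correlation is tetrachorically calibrated per pair
    so the sampled genotype correlation converges to the requested signed r,
    and the empirical allele frequency to ``eaf``.
    """
    eaf = np.asarray(eaf, dtype=float)
    m = len(ld)
    if eaf.shape != (m,):
        raise ConfigError(f"eaf must have length {m}")
    if np.any(eaf <= 0) or np.any(eaf >= 1):
        raise ConfigError("eaf entries must lie strictly in (0, 1)")
    if n < 2:
        raise ConfigError("panel size n must be >= 2")
    latent = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            latent[i, j] = latent[j, i] = _latent_rho(ld.r[i, j], eaf[i], eaf[j])
    # eigen-clip in case pairwise calibration left the matrix slightly non-PSD
    ev, vec = np.linalg.eigh(latent)
    latent = (vec * np.clip(ev, 1e-10, None)) @ vec.T
    d = np.sqrt(np.diag(latent))
    latent = latent / np.outer(d, d)
    factor = _psd_factor(latent)

    rng = np.random.default_rng(seed)
    thresholds = stats.norm.ppf(eaf)
    genotypes = np.zeros((n, m), dtype=np.int64)
    for _ in range(2):  # two haplotypes per individual
        z = rng.standard_normal((n, m)) @ factor.T
        genotypes += (z < thresholds).astype(np.int64)
    return genotypes


def estimate_ld(genotypes: np.ndarray, labels: Optional[Sequence[str]] = None) -> LdMatrix:
    """Empirical signed LD: pairwise Pearson correlation of genotype dosages."""
    genotypes = np.asarray(genotypes, dtype=float)
    if genotypes.ndim != 2 or genotypes.shape[0] < 2:
        raise LdError("genotype matrix must be 2-D with at least 2 individuals")
    m = genotypes.shape[1]
    labels = [str(l) for l in labels] if labels is not None else [f"v{i}" for i in range(m)]
    sd = genotypes.std(axis=0)
    mono = [labels[i] for i in np.flatnonzero(sd == 0)]
    if mono:
        raise LdError(f"monomorphic variant(s): {', '.join(mono)}")
    r = np.corrcoef(genotypes, rowvar=False)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LdMatrix(labels, r)


# ---------------------------------------------------------------------------
# Paired-study simulation


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic two-sample cis-MR study.

    Defaults emulate the CRP → periodontitis setting: exposure GWAS of
    N=575,531 on a standardized trait, outcome GWAS of 45,563 with case
    fraction 17,353/45,563, per-variant joint effect spread 0.02 (the order of
    the strongest cis associations), valid instruments, and full sampling
    noise. ``theta`` is the causal effect of the exposure on the outcome's
    log-odds scale.
    """

    m: int
    theta: float = 0.0
    ld_structure: LdStructure = "independent"
    eaf_range: tuple[float, float] = (0.1, 0.9)
    n_exposure: int = 575_531
    n_outcome: int = 45_563
    case_fraction: Optional[float] = 17_353 / 45_563
    gamma_sd: float = 0.02
    pleiotropy_sd: float = 0.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ConfigError("sample sizes must be >= 2")
        lo, hi = self.eaf_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("eaf_range must satisfy 0 < lo <= hi < 1")
        if min(self.gamma_sd, self.pleiotropy_sd, self.noise_scale) < 0:
            raise ConfigError("gamma_sd, pleiotropy_sd and noise_scale must be >= 0")
        if self.case_fraction is not None and not 0 < self.case_fraction < 1:
            raise ConfigError("case_fraction must lie in (0, 1) or be None")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a synthetic study: theta, per-variant effects, and LD."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    ld: LdMatrix

    def __post_init__(self) -> None:
        m = len(self.ld)
        if np.shape(self.gamma) != (m,) or np.shape(self.alpha) != (m,):
            raise ConfigError("gamma and alpha must each have one entry per variant")


def _sumstats_frame(rsids, pos, ea, nea, eaf, beta, se, n) -> pd.DataFrame:
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    pval = np.maximum(2 * stats.norm.sf(np.abs(beta) / se), 1e-300)
    return pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": "12",
            "pos": np.asarray(pos, dtype=np.int64),
            "ea": ea,
            "nea": nea,
            "eaf": np.asarray(eaf, dtype=float),
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": np.int64(n),
        }
    )


def simulate_paired_studies(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (exposure table, outcome table, truth) under ``config``.

    Bit-identical output for identical configs (including the seed). With
    ``noise_scale=0`` and ``pleiotropy_sd=0``, by/bx equals theta exactly for
    every variant with nonzero bx.
    """
    rng = np.random.default_rng(config.seed)
    m = config.m
    ld = make_ld_matrix(m, config.ld_structure)
    r = ld.r
    factor = _psd_factor(r)

    eaf = rng.uniform(config.eaf_range[0], config.eaf_range[1], size=m)
    gamma = rng.normal(0.0, config.gamma_sd, size=m) if config.gamma_sd else np.zeros(m)
    alpha = rng.normal(0.0, config.pleiotropy_sd, size=m) if config.pleiotropy_sd else np.zeros(m)

    bx_true = r @ gamma
    by_true = config.theta * bx_true + r @ alpha
    sx = marginal_se(eaf, config.n_exposure)
    sy = marginal_se(eaf, config.n_outcome, config.case_fraction)

    zx = rng.standard_normal(m)
    zy = rng.standard_normal(m)
    bx = bx_true + config.noise_scale * sx * (factor @ zx)
    by = by_true + config.noise_scale * sy * (factor @ zy)

    pos = np.linspace(_POS_LO, _POS_HI, m).round().astype(np.int64) if m > 1 else np.array([_POS_LO])
    ea = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0] for i in range(m)]
    nea = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1] for i in range(m)]

    exposure = _sumstats_frame(ld.labels, pos, ea, nea, eaf, bx, sx, config.n_exposure)
    outcome = _sumstats_frame(ld.labels, pos, ea, nea, eaf, by, sy, config.n_outcome)
    truth = SimTruth(config.theta, gamma, alpha, ld)
    return exposure, outcome, truth


def write_sim_truth(truth: SimTruth, path: str | Path, seed: Optional[int] = None) -> Path:
    """Write the truth manifest: a '# theta=... seed=...' header plus a TSV body."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# theta={truth.theta!r} seed={seed!r}\n")
        pd.DataFrame(
            {"rsid": truth.ld.labels, "gamma": truth.gamma, "alpha": truth.alpha}
        ).to_csv(fh, sep="\t", index=False)
    return path
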