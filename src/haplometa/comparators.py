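"""Competitor meta-analyses for the power study.

Three references the haplotype meta-analysis is benchmarked against:

* single-variant inverse-variance-weighted meta-analysis, with the smallest
  per-variant p-value Bonferroni-adjusted by the effective number of
  independent tests (simpleM eigenvalue rule);
* a burden test and SKAT on pooled score statistics with Wu weights
  (Beta(1, 25) density at the minor allele frequency), the seqMeta-style
  generalization to family data: per-cohort scores are computed from the
  null mixed model's whitened residuals and summed across cohorts.

SKAT p-values come from the tail of a positively weighted mixture of
1-df chi-squares, evaluated by Imhof characteristic-function inversion with
a moment-matching (Liu-type) fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SnvMetaInput",
    "ScoreSummary",
    "ivw_meta",
    "effective_tests",
    "min_p_test",
    "burden_skat_meta",
    "wu_weights",
    "chi2_mixture_sf",
]


@dataclass
class SnvMetaInput:
    """Per-cohort single-variant summary statistics on a shared variant list."""

    variant_ids: list[str]
    beta: np.ndarray  # (n_cohorts, q)
    se: np.ndarray    # (n_cohorts, q)
    n: np.ndarray     # (n_cohorts,)
    maf: np.ndarray   # (n_cohorts, q)

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.se = np.atleast_2d(np.asarray(self.se, dtype=float))
        self.maf = np.atleast_2d(np.asarray(self.maf, dtype=float))
        self.n = np.atleast_1d(np.asarray(self.n, dtype=float))
        if self.beta.shape != self.se.shape or self.beta.shape[1] != len(self.variant_ids):
            raise ValueError("summary statistic dimensions mismatch")
        if (self.se <= 0).any():
            raise ValueError("standard errors must be positive")


@dataclass
class ScoreSummary:
    """One cohort's score vector and covariance from the null mixed model."""

    cohort_id: str
    variant_ids: list[str]
    U: np.ndarray         # (q,)
    V: np.ndarray         # (q, q)
    maf: np.ndarray       # (q,)
    n: int

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        q = len(self.variant_ids)
        if self.U.shape != (q,) or self.V.shape != (q, q):
            raise ValueError("score summary dimensions mismatch")
        if not np.allclose(self.V, self.V.T, atol=1e-8):
            raise ValueError("score covariance must be symmetric")


def ivw_meta(inp: SnvMetaInput) -> np.ndarray:
    """Inverse-variance-weighted pooled estimate per variant.

    Returns an array of rows (pooled beta, pooled SE, two-sided normal p)
    with one row per variant.
    """
    w = 1.0 / inp.se**2
    wsum = w.sum(axis=0)
    beta = (w * inp.beta).sum(axis=0) / wsum
    se = wsum**-0.5
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.column_stack([beta, se, p])


def effective_tests(genotype_correlation: np.ndarray, share: float = 0.995) -> int:
    """Effective number of independent variants (simpleM).

    The smallest number of leading eigenvalues of the genotype correlation
    matrix whose sum exceeds ``share`` of the eigenvalue total.
    """
    C = np.asarray(genotype_correlation, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    ev = np.linalg.eigvalsh(C)[::-1]
    if ev[-1] < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    ev = np.maximum(ev, 0.0)
    cum = np.cumsum(ev)
    meff = int(np.searchsorted(cum, share * cum[-1]) + 1)
    return min(max(meff, 1), C.shape[0])


def min_p_test(
    meta_p: Sequence[float], meff: int, alpha: float
) -> tuple[float, bool]:
    """Bonferroni-adjust the smallest meta-analysis p-value by ``meff``."""
    p = np.asarray(meta_p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    adjusted = min(1.0, meff * float(p.min()))
    return adjusted, adjusted < alpha


def wu_weights(maf: np.ndarray) -> np.ndarray:
    """Beta(1, 25) density at the MAF: ``25 (1 - maf)^24``, upweighting rare
    variants."""
    maf = np.asarray(maf, dtype=float)
    return stats.beta.pdf(maf, 1, 25)


# ---------------------------------------------------------------------------
# tail of a mixture of chi-square(1) variables

def _chernoff_tail_point(lam: np.ndarray, tol: float) -> float:
    """Smallest t (by doubling) with Chernoff bound P(sum lam chi2_1 > t) < tol."""
    s = np.linspace(1e-3, 0.5 / lam.max(), 200, endpoint=False)[1:]
    log_mgf = -0.5 * np.sum(np.log1p(-2.0 * s[:, None] * lam[None, :]), axis=1)
    t = float(np.sum(lam)) + 2.0
    for _ in range(60):
        if np.min(log_mgf - s * t) < np.log(tol):
            return t
        t *= 1.5
    return t


def _imhof_sf(q: float, lam: np.ndarray, abs_tol: float = 1e-9) -> float:
    """P(sum lam_k chi2_1 > q) by numerical inversion of the characteristic
    function (Imhof's integrand on a Davies-style midpoint grid).

    The Gil-Pelaez integral is evaluated by the midpoint rule with spacing
    ``delta``; the rule's aliasing error is the probability mass beyond
    ``2*pi/delta - q``, controlled through a Chernoff bound, and the
    truncation error uses the integrand envelope
    ``1 / (u * prod(1 + lam_k^2 u^2)^(1/4))`` which decays like
    ``u^(-(1 + K/2))``.
    """
    K = len(lam)
    # aliasing control: probability mass outside +-2*pi/delta of q
    t_star = _chernoff_tail_point(lam, 0.25 * abs_tol)
    delta = 2.0 * np.pi / (q + t_star)
    tol = 0.25 * abs_tol

    def pieces(i0: int, n: int):
        u = (np.arange(i0, i0 + n) + 0.5) * delta
        theta = 0.5 * np.sum(np.arctan(lam[None, :] * u[:, None]), axis=1) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p((lam[None, :] * u[:, None]) ** 2), axis=1)
        env = np.exp(-log_rho) / u
        return u, theta, np.sin(theta) * env, env

    # Once the phase derivative locks below -q/4 (sum lam/(1+lam^2 u^2) <
    # q/2), the integrand alternates under the monotone envelope 1/(u rho)
    # with half-periods below 4*pi/q.  The Gil-Pelaez tail beyond a zero of
    # sin(theta) is an alternating series of half-period areas a_0, a_1, ...
    # summing to a_0/2 up to |a_0 - a_1|/2, which the relative envelope
    # decay s/u controls; integrating to the next zero and adding half of
    # the following half-period therefore leaves an error below
    # env * (4/q) * (2 pi s) / (q u).
    s_exp = 1.0 + 0.5 * K
    chunk = 1 << 13
    total = 0.0
    max_pts = 64_000_000
    i0 = 0
    theta_last = None
    while i0 < max_pts:
        u, theta, contrib, env = pieces(i0, chunk)
        total += float(np.sum(contrib)) * delta / np.pi
        i0 += chunk
        phase_locked = float(np.sum(lam / (1.0 + (lam * u[-1]) ** 2))) < 0.5 * q
        err_bound = env[-1] * (4.0 / q) * (2.0 * np.pi * s_exp) / (q * u[-1])
        if phase_locked and err_bound < tol:
            theta_last = theta[-1]
            break
    else:
        raise FloatingPointError("characteristic-function inversion did not converge")

    # Euler step: weight 1 up to the next sin(theta) zero, 1/2 across the
    # following half-period, 0 beyond (~1.5 half-periods of extra grid).
    n_extra = int(np.ceil(3.0 * (q + t_star) / q)) + 64
    u, theta, contrib, env = pieces(i0, n_extra)
    crossings = np.floor(theta_last / np.pi) - np.floor(theta / np.pi)
    weight = np.where(crossings < 1, 1.0, np.where(crossings < 2, 0.5, 0.0))
    if crossings[-1] < 2:  # zero not bracketed; extend conservatively
        raise FloatingPointError("characteristic-function tail step too short")
    total += float(np.sum(contrib * weight)) * delta / np.pi
    return 0.5 + total


def _liu_sf(q: float, lam: np.ndarray) -> float:
    """Moment-matching approximation to the mixture tail (fallback)."""
    c = [float(np.sum(lam**k)) for k in (1, 2, 3, 4)]
    s1 = c[2] / c[1] ** 1.5
    s2 = c[3] / c[1] ** 2
    mu_q, sigma_q = c[0], np.sqrt(2.0 * c[1])
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        ncp = s1 * a**3 - a**2
        df = a**2 - 2.0 * ncp
    else:
        df = 1.0 / s2
        ncp = 0.0
        a = np.sqrt(df)
    mu_x = df + ncp
    sigma_x = np.sqrt(2.0 * (df + 2.0 * ncp))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, df, ncp)) if ncp > 0 else float(
        stats.chi2.sf(t, df)
    )


def chi2_mixture_sf(q: float, lam: np.ndarray) -> float:
    """Survival function of ``sum_k lam_k chi2_1`` at ``q`` (lam_k >= 0)."""
    lam = np.asarray(lam, dtype=float)
    scale = lam.max(initial=0.0)
    if scale <= 0:
        return 1.0 if q <= 0 else 0.0
    # normalize; eigenvalues this far below the largest carry negligible mass
    lam = lam[lam > 1e-8 * scale] / scale
    q = q / scale
    if q <= 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))
    try:
        p = _imhof_sf(q, lam)
        if not np.isfinite(p) or p < -1e-6 or p > 1 + 1e-6:
            raise FloatingPointError
        return float(min(max(p, 1e-300), 1.0))
    except FloatingPointError:
        return _liu_sf(q, lam)


def burden_skat_meta(
    scores: list[ScoreSummary], weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Meta-analysis burden and SKAT p-values from pooled score statistics.

    Per-cohort scores ``U_i`` and covariances ``V_i`` (computed under the
    null model with covariates and the kinship random effect, no genotypes)
    are summed; with per-variant weights ``w`` (default Wu weights at the
    2n-pooled MAF):

    * burden:  ``T = (w'U)^2 / (w'Vw)`` against chi-square(1);
    * SKAT:    ``Q = sum_j w_j^2 U_j^2`` against the eigenvalue mixture of
      ``diag(w) V diag(w)``.
    """
    if not scores:
        raise ValueError("no score summaries supplied")
    ref = scores[0].variant_ids
    for s in scores[1:]:
        if s.variant_ids != ref:
            raise ValueError("variant lists differ across score summaries")
    U = np.sum([s.U for s in scores], axis=0)
    V = np.sum([s.V for s in scores], axis=0)
    if weights is None:
        tot = float(sum(2 * s.n for s in scores))
        pooled_maf = np.sum([2 * s.n * s.maf for s in scores], axis=0) / tot
        weights = wu_weights(pooled_maf)
    w = np.asarray(weights, dtype=float)
    if not (w != 0).any():
        raise ValueError("all-zero variant weights")

    denom = float(w @ V @ w)
    if denom <= 0:
        raise FloatingPointError("degenerate burden variance")
    t_burden = float(w @ U) ** 2 / denom
    p_burden = float(stats.chi2.sf(t_burden, 1))

    q_skat = float(np.sum((w * U) ** 2))
    wvw = (w[:, None] * V) * w[None, :]
    lam = np.linalg.eigvalsh(0.5 * (wvw + wvw.T))
    p_skat = chi2_mixture_sf(q_skat, lam)
    return p_burden, p_skat
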