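"""Multivariate GLS meta-analysis of cohort haplotype effects.

Cohort ``i`` contributes an effect vector ``beta_i`` over its ``K_i``
observed haplotypes and its covariance ``var(beta_i)``.  With ``K'``
haplotypes observed in at least one cohort, the stacked model is

    beta_hat = W beta + e,   e ~ N(0, Sigma),

where each ``W_i`` is a 0/1 selection matrix mapping the cohort's haplotype
order onto the union order and ``Sigma`` is block diagonal (independent
cohorts).  The pooled estimate is the generalized weighted least squares
solution ``beta_tilde = (W' Sigma^-1 W)^-1 W' Sigma^-1 beta_hat`` with
covariance ``V = (W' Sigma^-1 W)^-1``.

Because the cohort model carries no intercept (haplotype dosages sum to 2),
only contrasts between haplotype effects are identified; the global null is
equality of all pooled effects, tested by a Wald chi-square on the
``K' - 1`` contrasts against a baseline haplotype, with
``V*_jj' = V_jj' - V_j1 - V_j'1 + V_11``.  The statistic does not depend on
which baseline is chosen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .cohort import CohortSummary

__all__ = [
    "MetaDesign",
    "MetaResult",
    "build_meta_design",
    "gls_combine",
    "global_test",
    "haplotype_contrasts",
    "meta_analyze",
    "default_baseline",
]

logger = logging.getLogger(__name__)

_COND_WARN = 1e10


@dataclass
class MetaDesign:
    """Stacked GLS layout: union labels, selection matrices, beta and Sigma."""

    labels: list[str]                 # union order, K'
    selections: list[np.ndarray]      # W_i, (K_i, K')
    beta_stacked: np.ndarray          # (sum K_i,)
    sigma_blocks: list[np.ndarray]    # var(beta_i)
    cohort_ids: list[str]
    frequencies: list[np.ndarray]     # per-cohort haplotype frequencies
    cohort_sizes: list[int]

    @property
    def n_union(self) -> int:
        return len(self.labels)


@dataclass
class MetaResult:
    labels: list[str]
    beta: np.ndarray       # pooled effects, (K',)
    covariance: np.ndarray  # V, (K', K')
    cohort_ids: list[str]
    frequency_range: np.ndarray  # (K', 2) min/max observed frequency
    condition_number: float
    baseline: str | None = None
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None
    contrasts: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        import json

        doc = {
            "labels": self.labels,
            "beta": self.beta.tolist(),
            "covariance": self.covariance.ravel().tolist(),
            "cohorts": self.cohort_ids,
            "baseline": self.baseline,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    def to_tsv(self, path: str | Path) -> None:
        if self.contrasts is None:
            raise ValueError("run haplotype_contrasts before writing the table")
        df = self.contrasts.copy()
        df.insert(1, "freq_min", self.frequency_range[:, 0])
        df.insert(2, "freq_max", self.frequency_range[:, 1])
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_meta_design(summaries: list[CohortSummary]) -> MetaDesign:
    """Align cohort haplotype sets onto their union and stack effects.

    All cohorts must have analysed the same variant list in the same order.
    Union labels are ordered by decreasing sample-size-weighted mean
    frequency (ties broken lexicographically); haplotypes seen in a single
    cohort are retained.
    """
    if not summaries:
        raise ValueError("no cohort summaries supplied")
    ref = [
        (v.id, v.chrom, v.pos, v.minor, v.major) for v in summaries[0].variants
    ]
    for s in summaries[1:]:
        cur = [(v.id, v.chrom, v.pos, v.minor, v.major) for v in s.variants]
        if cur != ref:
            raise ValueError(
                f"cohort {s.cohort_id!r} analysed a different variant list"
            )
    for s in summaries:
        ev = np.linalg.eigvalsh(s.covariance)
        if ev.min() < -1e-8 * max(1.0, ev.max()):
            raise ValueError(f"cohort {s.cohort_id!r} covariance is not PSD")

    pooled: dict[str, float] = {}
    weight: dict[str, float] = {}
    for s in summaries:
        for lab, f in zip(s.labels, s.frequencies):
            pooled[lab] = pooled.get(lab, 0.0) + 2 * s.n * float(f)
            weight[lab] = weight.get(lab, 0.0) + 2 * s.n
    labels = sorted(pooled, key=lambda l: (-pooled[l] / weight[l], l))
    col = {lab: j for j, lab in enumerate(labels)}

    selections, freqs = [], []
    for s in summaries:
        W = np.zeros((len(s.labels), len(labels)))
        for r, lab in enumerate(s.labels):
            W[r, col[lab]] = 1.0
        selections.append(W)
        freqs.append(np.asarray(s.frequencies, dtype=float))
    return MetaDesign(
        labels=labels,
        selections=selections,
        beta_stacked=np.concatenate([s.beta for s in summaries]),
        sigma_blocks=[s.covariance for s in summaries],
        cohort_ids=[s.cohort_id for s in summaries],
        frequencies=freqs,
        cohort_sizes=[s.n for s in summaries],
    )


def gls_combine(design: MetaDesign) -> MetaResult:
    """Pool cohort effect vectors by generalized weighted least squares."""
    Kp = design.n_union
    A = np.zeros((Kp, Kp))      # W' Sigma^-1 W
    c = np.zeros(Kp)            # W' Sigma^-1 beta_hat
    offset = 0
    for W, Sig in zip(design.selections, design.sigma_blocks):
        k = W.shape[0]
        b = design.beta_stacked[offset : offset + k]
        offset += k
        try:
            chol = cho_factor(Sig)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "cohort covariance block is singular"
            ) from None
        A += W.T @ cho_solve(chol, W)
        c += W.T @ cho_solve(chol, b)

    diag = np.diag(A)
    if (diag <= 0).any():
        missing = [design.labels[j] for j in np.flatnonzero(diag <= 0)]
        raise np.linalg.LinAlgError(
            f"haplotype(s) {missing} carry zero meta-analysis weight"
        )
    cond = float(np.linalg.cond(A))
    if cond > _COND_WARN:
        logger.warning("meta GLS normal equations ill-conditioned: cond=%.3g", cond)
    try:
        chol = cho_factor(A)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"singular meta design (cond={cond:.3g}); labels: {design.labels}"
        ) from None
    beta = cho_solve(chol, c)
    V = cho_solve(chol, np.eye(Kp))
    V = 0.5 * (V + V.T)

    fr = np.empty((Kp, 2))
    fr[:, 0], fr[:, 1] = np.inf, -np.inf
    for W, f in zip(design.selections, design.frequencies):
        cols = W.argmax(axis=1)
        fr[cols, 0] = np.minimum(fr[cols, 0], f)
        fr[cols, 1] = np.maximum(fr[cols, 1], f)
    return MetaResult(
        labels=design.labels,
        beta=beta,
        covariance=V,
        cohort_ids=design.cohort_ids,
        frequency_range=fr,
        condition_number=cond,
    )


def default_baseline(design: MetaDesign) -> str:
    """Baseline haplotype: observed in every cohort, highest pooled frequency.

    Falls back to the highest-frequency haplotype overall if none is shared
    by all cohorts.  The global Wald statistic does not depend on this
    choice; it only anchors per-haplotype contrast reporting.
    """
    Kp = design.n_union
    seen = np.zeros(Kp, dtype=int)
    for W in design.selections:
        seen[W.argmax(axis=1)] += 1
    everywhere = seen == len(design.selections)
    candidates = (
        [l for l, e in zip(design.labels, everywhere) if e] or design.labels
    )
    return candidates[0]  # labels are ordered by decreasing pooled frequency


def _contrast_cov(V: np.ndarray, base: int) -> tuple[np.ndarray, np.ndarray, list[int]]:
    Kp = V.shape[0]
    others = [j for j in range(Kp) if j != base]
    Vs = (
        V[np.ix_(others, others)]
        - V[np.ix_(others, [base] * len(others))]
        - V[np.ix_([base] * len(others), others)]
        + V[base, base]
    )
    return Vs, np.asarray(others), others


def global_test(
    result: MetaResult, baseline_label: str | None = None
) -> tuple[float, int, float]:
    """Global Wald test of equality of all pooled haplotype effects.

    Returns ``(chi2, df, p)`` with ``df = K' - 1``; invariant to the
    baseline used to form the contrasts.
    """
    Kp = len(result.labels)
    if Kp < 2:
        raise ValueError("global test undefined for a single haplotype")
    if baseline_label is None:
        baseline_label = result.baseline or result.labels[0]
    try:
        base = result.labels.index(baseline_label)
    except ValueError:
        raise KeyError(f"baseline label {baseline_label!r} not in meta result") from None
    others = [j for j in range(Kp) if j != base]
    gamma = result.beta[others] - result.beta[base]
    Vs, _, _ = _contrast_cov(result.covariance, base)
    try:
        chol = cho_factor(Vs)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular contrast covariance V*") from None
    chi2 = float(gamma @ cho_solve(chol, gamma))
    df = Kp - 1
    p = float(stats.chi2.sf(chi2, df))
    result.baseline = baseline_label
    result.chi2, result.df, result.p_value = chi2, df, p
    return chi2, df, p


def haplotype_contrasts(
    result: MetaResult, baseline_label: str | None = None
) -> pd.DataFrame:
    """Per-haplotype effects relative to the baseline, with normal p-values.

    The baseline row is reported blank (NaN), mirroring the usual reference
    row in haplotype association tables.
    """
    if baseline_label is None:
        baseline_label = result.baseline or result.labels[0]
    try:
        base = result.labels.index(baseline_label)
    except ValueError:
        raise KeyError(f"baseline label {baseline_label!r} not in meta result") from None
    Vs, others, _ = _contrast_cov(result.covariance, base)
    est = np.full(len(result.labels), np.nan)
    se = np.full(len(result.labels), np.nan)
    est[others] = result.beta[others] - result.beta[base]
    var = np.diag(Vs).copy()
    if (var < 0).any():
        warnings.warn("negative contrast variance clipped to zero", stacklevel=2)
        var = np.maximum(var, 0.0)
    se[others] = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    df = pd.DataFrame(
        {
            "label": result.labels,
            "estimate": est,
            "se": se,
            "p_value": p,
            "baseline": [l == baseline_label for l in result.labels],
        }
    )
    result.contrasts = df
    return df


def meta_analyze(
    summaries: list[CohortSummary], baseline_label: str | None = None
) -> MetaResult:
    """End-to-end stage 2: align, pool, test, and tabulate contrasts."""
    design = build_meta_design(summaries)
    result = gls_combine(design)
    if baseline_label is None:
        baseline_label = default_baseline(design)
    if len(result.labels) >= 2:
        global_test(result, baseline_label)
        haplotype_contrasts(result, baseline_label)
    return result
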