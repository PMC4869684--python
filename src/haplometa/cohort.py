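"""Cohort-level haplotype association under a kinship linear mixed model.

The stage-1 model for a quantitative trait ``Y`` is

    Y = X a + sum_m beta_m h_m + b + e,    b ~ N(0, sigma_a^2 Phi),
                                           e ~ N(0, sigma_e^2 I),

where ``X`` holds covariates WITHOUT an intercept, ``h_m`` are the expected
haplotype dosages (which sum to 2 across haplotypes, absorbing the
intercept), and ``Phi`` is the pedigree relationship matrix.  Variance
components are estimated by maximum likelihood, profiling the fixed effects
and the error variance over the heritability ratio
``gamma = sigma_a^2/sigma_e^2`` after a one-off eigendecomposition of
``Phi``, so each likelihood evaluation is a diagonal weighted least squares.
The haplotype effects and their covariance — the generalized-least-squares
estimate ``(Xo' Omega^-1 Xo)^-1 Xo' Omega^-1 Y`` and the haplotype block of
``(Xo' Omega^-1 Xo)^-1`` — form the cohort summary exchanged with the
meta-analysis stage.  With ``Phi = I`` the fit reduces to ordinary least
squares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .em import DosageMatrix, Variant
from .pedigree import RelationshipMatrix

__all__ = [
    "TraitVector",
    "CovariateMatrix",
    "VarianceComponents",
    "CohortSummary",
    "fit_variance_components",
    "estimate_effects",
    "read_trait_table",
]

_LOG_GAMMA_BOUNDS = (-12.0, 12.0)


@dataclass
class TraitVector:
    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids),):
            raise ValueError("trait length does not match ids")
        if not np.isfinite(self.values).all():
            raise ValueError("trait values must be finite")


@dataclass
class CovariateMatrix:
    subject_ids: list[str]
    names: list[str]
    values: np.ndarray  # (n, p), no intercept column

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.names)):
            raise ValueError("covariate matrix shape mismatch")

    def reorder(self, ids: Sequence[str]) -> "CovariateMatrix":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in ids]
        return CovariateMatrix(list(ids), self.names, self.values[idx])


@dataclass
class VarianceComponents:
    sigma_a2: float  # additive (polygenic) variance, trait units^2
    sigma_e2: float  # residual variance, trait units^2
    log_likelihood: float = float("nan")
    boundary: bool = False     # ML solution on the sigma_a2 = 0 boundary
    degenerate: bool = False   # both components collapse (constant trait)

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")


@dataclass
class CohortSummary:
    """One cohort's stage-1 output: the stage-1 -> stage-2 exchange object."""

    cohort_id: str
    n: int
    variants: list[Variant]
    labels: list[str]
    frequencies: np.ndarray
    beta: np.ndarray               # haplotype effects, trait units per copy
    covariance: np.ndarray         # (K, K) haplotype block of (Xo' Omega^-1 Xo)^-1
    covariate_names: list[str]
    alpha: np.ndarray              # covariate effect estimates
    vc: VarianceComponents

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        K = len(self.labels)
        if len(set(self.labels)) != K:
            raise ValueError("haplotype labels must be unique")
        if self.beta.shape != (K,) or self.covariance.shape != (K, K):
            raise ValueError("effect vector / covariance dimension mismatch")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        ev = np.linalg.eigvalsh(self.covariance)
        if ev.min() < -1e-8 * max(1.0, ev.max()):  # relative PSD tolerance
            raise ValueError("covariance must be positive semi-definite")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "cohort_id": self.cohort_id,
            "n": self.n,
            "variants": [asdict(v) for v in self.variants],
            "labels": list(self.labels),
            "frequencies": self.frequencies.tolist(),
            "beta": self.beta.tolist(),
            "covariance": self.covariance.ravel().tolist(),
            "covariate_names": list(self.covariate_names),
            "alpha": self.alpha.tolist(),
            "sigma_a2": self.vc.sigma_a2,
            "sigma_e2": self.vc.sigma_e2,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSummary":
        with open(path) as fh:
            doc = json.load(fh)
        K = len(doc["labels"])
        return cls(
            cohort_id=doc["cohort_id"],
            n=int(doc["n"]),
            variants=[Variant(**v) for v in doc["variants"]],
            labels=list(doc["labels"]),
            frequencies=np.asarray(doc["frequencies"], dtype=float),
            beta=np.asarray(doc["beta"], dtype=float),
            covariance=np.asarray(doc["covariance"], dtype=float).reshape(K, K),
            covariate_names=list(doc["covariate_names"]),
            alpha=np.asarray(doc["alpha"], dtype=float),
            vc=VarianceComponents(doc["sigma_a2"], doc["sigma_e2"]),
        )


# ---------------------------------------------------------------------------
# profiled ML machinery (shared with the simulation engine, which supplies
# family-block eigendecompositions instead of a dense one)

def _profile_nll(log_gamma: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Negative profiled log-likelihood at heritability ratio exp(log_gamma).

    ``d, yt, Xt`` are the Phi eigenvalues and eigenrotated trait/design.
    Fixed effects and sigma_e^2 are profiled out in closed form.
    """
    g = np.exp(log_gamma)
    w = 1.0 / (g * d + 1.0)
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    c = Xw.T @ yt
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        return 1e300, None  # finite sentinel keeps the scalar search stable
    n = len(yt)
    rss = float(yt @ (w * yt) - c @ beta)
    sigma_e2 = max(rss / n, 1e-300)
    nll = 0.5 * (n * np.log(sigma_e2) + np.sum(np.log(g * d + 1.0)) + n)
    return nll, (beta, sigma_e2, A)


def _fit_ml(d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Maximize the profiled likelihood over log gamma in a bounded interval."""
    res = minimize_scalar(
        lambda lg: _profile_nll(lg, d, yt, Xt)[0],
        bounds=_LOG_GAMMA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    lo, hi = _LOG_GAMMA_BOUNDS
    candidates = [float(res.x), lo, hi]
    best_lg, best_nll = None, np.inf
    for lg in candidates:
        nll, _ = _profile_nll(lg, d, yt, Xt)
        if nll < best_nll:
            best_lg, best_nll = lg, nll
    boundary = best_lg <= lo + 1e-6
    gamma = 0.0 if boundary else float(np.exp(best_lg))
    nll, aux = _profile_nll(np.log(gamma) if gamma > 0 else lo - 30.0, d, yt, Xt)
    if aux is None:
        raise np.linalg.LinAlgError("singular profiled design")
    beta, sigma_e2, A = aux
    n = len(yt)
    loglik = -nll - 0.5 * n * np.log(2.0 * np.pi)
    return gamma, sigma_e2, loglik, boundary, beta, A


def _eigen_transform(phi: np.ndarray, y: np.ndarray, X: np.ndarray):
    d, Q = eigh(phi)
    d = np.maximum(d, 0.0)
    return d, Q.T @ y, Q.T @ X


def fit_variance_components(
    trait: TraitVector,
    design: np.ndarray,
    phi: RelationshipMatrix,
) -> VarianceComponents:
    """ML estimates of (sigma_a^2, sigma_e^2) given a full fixed-effect design.

    ``design`` is the complete fixed-effect matrix (covariates plus haplotype
    dosage columns).  The boundary value ``sigma_a^2 = 0`` is permitted and
    flagged; a residual variance collapsing to zero (constant trait) flags the
    fit as degenerate.
    """
    phi_m = phi.reorder(trait.subject_ids).values
    y = trait.values
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("design matrix misaligned with trait")
    d, yt, Xt = _eigen_transform(phi_m, y, X)
    gamma, sigma_e2, loglik, boundary, _, _ = _fit_ml(d, yt, Xt)
    if not np.isfinite(loglik):
        raise FloatingPointError(
            f"non-finite mixed-model likelihood (cond(design)={np.linalg.cond(X):.3g})"
        )
    degenerate = sigma_e2 < 1e-12
    if degenerate:
        sigma_e2 = 0.0
    return VarianceComponents(
        sigma_a2=gamma * sigma_e2,
        sigma_e2=sigma_e2,
        log_likelihood=loglik,
        boundary=boundary or degenerate,
        degenerate=degenerate,
    )


def _gls_from_transform(d, yt, Xt, gamma, sigma_e2):
    """GLS coefficients and covariance at fixed variance components."""
    w = 1.0 / (gamma * d + 1.0)
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    c = Xw.T @ yt
    try:
        chol = cho_factor(A)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular design in GLS solve: {e}") from None
    coef = cho_solve(chol, c)
    cov = sigma_e2 * cho_solve(chol, np.eye(A.shape[0]))
    cov = 0.5 * (cov + cov.T)  # exact symmetry against solve round-off
    return coef, cov


def estimate_effects(
    trait: TraitVector,
    covariates: CovariateMatrix | None,
    dosages: DosageMatrix,
    phi: RelationshipMatrix,
    vc: VarianceComponents | None = None,
    cohort_id: str = "cohort",
    frequencies: np.ndarray | None = None,
    variants: list[Variant] | None = None,
) -> CohortSummary:
    """Stage-1 fit: GLS haplotype effects and covariance under the LMM.

    The overall design is ``Xo = [covariates | dosage columns]`` with no
    intercept (the dosage columns sum to 2 and absorb it).  If ``vc`` is
    omitted the variance components are first estimated by ML on the same
    design.  ``frequencies`` defaults to column means of the dosages / 2.
    """
    ids = trait.subject_ids
    if covariates is not None:
        cov = covariates.reorder(ids)
        X = cov.values
        cov_names = cov.names
    else:
        X = np.empty((len(ids), 0))
        cov_names = []
    dpos = {s: i for i, s in enumerate(dosages.subject_ids)}
    H = dosages.values[[dpos[s] for s in ids]]
    K = H.shape[1]
    Xo = np.column_stack([X, H]) if X.size else H

    if np.linalg.matrix_rank(Xo) < Xo.shape[1]:
        bad = _deficient_columns(Xo, list(cov_names) + list(dosages.labels))
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; offending column(s): {bad}"
        )

    phi_m = phi.reorder(ids).values
    d, yt, Xt = _eigen_transform(phi_m, trait.values, Xo)
    if vc is None:
        gamma, sigma_e2, loglik, boundary, _, _ = _fit_ml(d, yt, Xt)
        vc = VarianceComponents(
            sigma_a2=gamma * sigma_e2,
            sigma_e2=sigma_e2,
            log_likelihood=loglik,
            boundary=boundary,
        )
    gamma = 0.0 if vc.sigma_e2 == 0 else vc.sigma_a2 / vc.sigma_e2
    coef, cov_all = _gls_from_transform(d, yt, Xt, gamma, vc.sigma_e2)

    p = Xo.shape[1] - K
    freqs = (
        np.asarray(frequencies, dtype=float)
        if frequencies is not None
        else H.mean(axis=0) / 2.0
    )
    return CohortSummary(
        cohort_id=cohort_id,
        n=len(ids),
        variants=variants or [],
        labels=list(dosages.labels),
        frequencies=freqs,
        beta=coef[p:],
        covariance=cov_all[p:, p:],
        covariate_names=list(cov_names),
        alpha=coef[:p],
        vc=vc,
    )


def _deficient_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy scan, error path only)."""
    bad = []
    rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == rank:
            bad.append(names[j] if j < len(names) else f"col{j}")
    return bad or ["<unidentified>"]


def read_trait_table(
    path: str | Path, trait_col: str = "trait"
) -> tuple[TraitVector, CovariateMatrix]:
    """Read a TSV with header (id, trait, covariates...) into aligned
    trait/covariate containers."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    ids = df["id"].tolist()
    cov_cols = [c for c in df.columns if c not in ("id", trait_col)]
    return (
        TraitVector(ids, df[trait_col].to_numpy(dtype=float)),
        CovariateMatrix(ids, cov_cols, df[cov_cols].to_numpy(dtype=float)),
    )
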