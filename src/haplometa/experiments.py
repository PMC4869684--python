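"""End-to-end simulation experiments: type-I error, power, estimate bias.

Each replicate simulates every cohort of a study design, runs the full
pipeline (EM haplotype inference, rare-haplotype collapsing, the cohort
mixed model, GLS meta-analysis, global Wald test) and, for power runs, the
three comparator meta-analyses (effective-tests-corrected min-P over
single-variant inverse-variance meta, burden and SKAT on pooled family
score statistics) on the same data.

Replicates draw from independent generator streams keyed by
``(seed, design, scenario, replicate)``, so any replicate is reproducible
in isolation and results are byte-identical across runs with the same
arguments.  Replicate-level numerical failures (e.g. a singular cohort
design) are excluded from the denominator and counted; an experiment with
more than 1% failures aborts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortSummary, VarianceComponents, _fit_ml, _gls_from_transform
from .comparators import (
    ScoreSummary,
    SnvMetaInput,
    burden_skat_meta,
    effective_tests,
    ivw_meta,
    min_p_test,
)
from .em import (
    GenotypeMatrix,
    collapse_rare,
    em_haplotype_frequencies,
    expected_dosages,
)
from .meta import build_meta_design, default_baseline, global_test, gls_combine, haplotype_contrasts
from .simulate import (
    EffectScenario,
    ReferencePanel,
    SimulatedCohort,
    calibrate_effects,
    load_panel,
    simulate_cohort,
    study_design,
)

__all__ = [
    "ExperimentResult",
    "analyze_cohort",
    "run_type1",
    "run_power",
    "run_estimate_bias",
]

_SCEN_CODE = {"null": 0, "1SNV": 1, "2SNV": 2, "1HAP": 3, "2HAP": 4}
_MAX_FAIL_FRAC = 0.01


@dataclass
class ExperimentResult:
    experiment: str
    design_id: int
    gene: str
    scenario: str
    n_sims: int
    n_completed: int
    n_failed: int
    alpha: float
    seed: int
    rejections: dict[str, int]
    runtime_s: float
    extras: dict = field(default_factory=dict)

    @property
    def rates(self) -> dict[str, float]:
        return {k: v / self.n_completed for k, v in self.rejections.items()}

    @property
    def mc_se(self) -> dict[str, float]:
        out = {}
        for k, r in self.rates.items():
            out[k] = float(np.sqrt(r * (1.0 - r) / self.n_completed))
        return out

    def summary_table(self) -> str:
        lines = ["method\trejections\trate\tmc_se"]
        for k in self.rejections:
            lines.append(
                f"{k}\t{self.rejections[k]}\t{self.rates[k]:.5f}\t{self.mc_se[k]:.5f}"
            )
        return "\n".join(lines)


_ID_CACHE: dict[int, list[str]] = {}


def _subject_ids(n: int) -> list[str]:
    if n not in _ID_CACHE:
        _ID_CACHE[n] = [f"S{i + 1}" for i in range(n)]
    return _ID_CACHE[n]


def analyze_cohort(
    sim: SimulatedCohort,
    cohort_id: str = "cohort",
    collapse_threshold: float = 0.001,
) -> CohortSummary:
    """Stage-1 pipeline on one simulated cohort.

    EM haplotype frequencies and expected dosages from the unphased
    genotypes (phase is deliberately ignored), rare haplotypes collapsed,
    then the kinship mixed model fitted with age and sex as covariates using
    per-family eigendecompositions of the block-diagonal relationship
    matrix.
    """
    gm = GenotypeMatrix(
        _subject_ids(sim.n), sim.panel.variants, sim.genotypes
    )
    table = em_haplotype_frequencies(gm)
    dosages = expected_dosages(gm, table)
    dosages, table = collapse_rare(dosages, table, collapse_threshold)

    M = np.column_stack([sim.trait, sim.ages, sim.sexes, dosages.values])
    d, Mt = sim.structure.eigen_transform(M)
    yt, Xt = Mt[:, 0], Mt[:, 1:]
    gamma, sigma_e2, loglik, boundary, _, _ = _fit_ml(d, yt, Xt)
    coef, cov = _gls_from_transform(d, yt, Xt, gamma, sigma_e2)
    K = len(table.labels)
    return CohortSummary(
        cohort_id=cohort_id,
        n=sim.n,
        variants=sim.panel.variants,
        labels=list(table.labels),
        frequencies=table.frequencies,
        beta=coef[2:],
        covariance=cov[2:, 2:],
        covariate_names=["age", "sex"],
        alpha=coef[:2],
        vc=VarianceComponents(
            sigma_a2=gamma * sigma_e2,
            sigma_e2=sigma_e2,
            log_likelihood=loglik,
            boundary=boundary,
        ),
    )


def _global_p(summaries: list[CohortSummary]) -> float:
    design = build_meta_design(summaries)
    result = gls_combine(design)
    _, _, p = global_test(result, default_baseline(design))
    return p


def _replicate_rng(seed: int, design_id: int, scenario: str, rep: int):
    return np.random.default_rng([seed, design_id, _SCEN_CODE[scenario], rep])


def run_type1(
    design_id: int,
    gene: str,
    n_sims: int = 2000,
    alpha: float = 0.01,
    seed: int = 0,
) -> ExperimentResult:
    """Empirical type-I error of the global haplotype meta-analysis test.

    Per replicate: simulate all cohorts of the design under the null
    phenotype model, run the two-stage pipeline, and record whether the
    global Wald p-value falls below ``alpha``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    design = study_design(design_id)
    panel = load_panel(gene)
    t0 = time.perf_counter()
    rej = failed = 0
    for rep in range(n_sims):
        rng = _replicate_rng(seed, design_id, "null", rep)
        try:
            summaries = [
                analyze_cohort(
                    simulate_cohort(spec, panel, None, rng), f"cohort{i + 1}"
                )
                for i, spec in enumerate(design.cohorts)
            ]
            p = _global_p(summaries)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            failed += 1
            _check_failures(failed, n_sims)
            continue
        rej += p < alpha
    return ExperimentResult(
        experiment="type1",
        design_id=design_id,
        gene=gene.upper(),
        scenario="null",
        n_sims=n_sims,
        n_completed=n_sims - failed,
        n_failed=failed,
        alpha=alpha,
        seed=seed,
        rejections={"haplotype_meta": rej},
        runtime_s=time.perf_counter() - t0,
    )


def _check_failures(failed: int, n_sims: int) -> None:
    if failed > max(_MAX_FAIL_FRAC * n_sims, 1):
        raise RuntimeError(
            f"{failed} replicate failures out of {n_sims}: experiment aborted"
        )


def _comparator_stats(sim: SimulatedCohort):
    """Single-variant LMM estimates and null-model score statistics for one
    cohort, sharing the family-block eigen transform with the main fit."""
    q = sim.genotypes.shape[1]
    n = sim.n
    ones = np.ones(n)
    M = np.column_stack([sim.trait, ones, sim.ages, sim.sexes, sim.genotypes])
    d, Mt = sim.structure.eigen_transform(M)
    yt = Mt[:, 0]
    Ct = Mt[:, 1:4]   # intercept, age, sex
    Gt = Mt[:, 4:]

    # per-variant effect estimates under the kinship LMM (full ML per fit)
    beta = np.full(q, np.nan)
    se = np.full(q, np.nan)
    mono = sim.genotypes.var(axis=0) == 0
    for j in range(q):
        if mono[j]:
            continue
        Xt = np.column_stack([Ct, Gt[:, j]])
        gamma, sigma_e2, _, _, _, _ = _fit_ml(d, yt, Xt)
        coef, cov = _gls_from_transform(d, yt, Xt, gamma, sigma_e2)
        beta[j] = coef[-1]
        se[j] = np.sqrt(cov[-1, -1])

    # score statistics from the covariates-only null model
    gamma0, sigma_e2_0, _, _, alpha0, _ = _fit_ml(d, yt, Ct)
    w = 1.0 / (gamma0 * d + 1.0)
    resid = yt - Ct @ alpha0
    U = Gt.T @ (w * resid) / sigma_e2_0
    GtW = Gt * w[:, None]
    CtW = Ct * w[:, None]
    A = Ct.T @ CtW
    B = Ct.T @ GtW          # (3, q)
    V = (Gt.T @ GtW - B.T @ np.linalg.solve(A, B)) / sigma_e2_0
    maf = sim.genotypes.mean(axis=0) / 2.0
    return beta, se, U, 0.5 * (V + V.T), maf


def run_power(
    design_id: int,
    gene: str,
    scenario: str,
    n_sims: int = 500,
    alpha: float = 0.001,
    seed: int = 0,
    r2: float = 0.01,
) -> ExperimentResult:
    """Power comparison of four meta-analyses on identical replicates.

    Methods: the haplotype-meta global Wald test; min-P over single-variant
    inverse-variance meta with the effective-tests (simpleM) Bonferroni
    correction; burden and SKAT with Wu weights on pooled family score
    statistics.  ``scenario = "null"`` turns this into a joint type-I error
    calibration of all four methods.
    """
    design = study_design(design_id)
    panel = load_panel(gene)
    scen = EffectScenario.for_gene(scenario, gene, r2=r2)
    var_ids = [v.id for v in panel.variants]
    q = len(var_ids)
    t0 = time.perf_counter()
    methods = ("haplotype_meta", "min_p", "burden", "skat")
    rej = dict.fromkeys(methods, 0)
    failed = 0
    for rep in range(n_sims):
        rng = _replicate_rng(seed, design_id, scenario, rep)
        try:
            sims = [
                simulate_cohort(spec, panel, scen, rng) for spec in design.cohorts
            ]
            summaries = []
            betas, ses, ns, mafs, scores = [], [], [], [], []
            pooled_geno = []
            for i, sim in enumerate(sims):
                summaries.append(analyze_cohort(sim, f"cohort{i + 1}"))
                b, s, U, V, maf = _comparator_stats(sim)
                betas.append(b)
                ses.append(s)
                ns.append(sim.n)
                mafs.append(maf)
                scores.append(
                    ScoreSummary(f"cohort{i + 1}", var_ids, U, V, maf, sim.n)
                )
                pooled_geno.append(sim.genotypes)
            p_hap = _global_p(summaries)

            # min-P: IVW per variant over cohorts with an estimate
            beta_arr = np.array(betas)
            se_arr = np.array(ses)
            p_var = np.full(q, np.nan)
            for j in range(q):
                ok = np.isfinite(se_arr[:, j])
                if not ok.any():
                    continue
                inp = SnvMetaInput(
                    [var_ids[j]],
                    beta_arr[ok, j][:, None],
                    se_arr[ok, j][:, None],
                    np.array(ns)[ok],
                    np.array(mafs)[ok, j][:, None],
                )
                p_var[j] = ivw_meta(inp)[0, 2]
            G = np.concatenate(pooled_geno, axis=0).astype(float)
            poly = G.var(axis=0) > 0
            corr = np.corrcoef(G[:, poly], rowvar=False)
            meff = effective_tests(np.atleast_2d(corr))
            have = np.isfinite(p_var)
            p_min_adj, _ = min_p_test(np.clip(p_var[have], 1e-300, 1.0), meff, alpha)

            p_burden, p_skat = burden_skat_meta(scores)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            failed += 1
            _check_failures(failed, n_sims)
            continue
        rej["haplotype_meta"] += p_hap < alpha
        rej["min_p"] += p_min_adj < alpha
        rej["burden"] += p_burden < alpha
        rej["skat"] += p_skat < alpha
    return ExperimentResult(
        experiment="power",
        design_id=design_id,
        gene=gene.upper(),
        scenario=scenario,
        n_sims=n_sims,
        n_completed=n_sims - failed,
        n_failed=failed,
        alpha=alpha,
        seed=seed,
        rejections=rej,
        runtime_s=time.perf_counter() - t0,
        extras={"r2": r2, "effects": calibrate_effects(scen, panel)},
    )


def run_estimate_bias(
    design_id: int,
    gene: str,
    scenario: str,
    n_sims: int = 500,
    seed: int = 0,
    r2: float = 0.01,
) -> ExperimentResult:
    """Bias check: pooled causal-haplotype contrasts against their generating
    values.

    Contrasts are taken against the most frequent non-causal haplotype (so
    the true contrast of a causal haplotype equals its simulated effect);
    the result's ``extras["bias"]`` maps each causal label to (mean
    estimate, SE of the mean, true effect).
    """
    if scenario not in ("1HAP", "2HAP"):
        raise ValueError("bias experiment requires a causal haplotype scenario")
    design = study_design(design_id)
    panel = load_panel(gene)
    scen = EffectScenario.for_gene(scenario, gene, r2=r2)
    effects = calibrate_effects(scen, panel)
    causal = list(scen.causal_haps)
    t0 = time.perf_counter()
    estimates: dict[str, list[float]] = {lab: [] for lab in causal}
    failed = 0
    for rep in range(n_sims):
        rng = _replicate_rng(seed, design_id, scenario, rep)
        try:
            summaries = [
                analyze_cohort(
                    simulate_cohort(spec, panel, scen, rng), f"cohort{i + 1}"
                )
                for i, spec in enumerate(design.cohorts)
            ]
            mdesign = build_meta_design(summaries)
            result = gls_combine(mdesign)
            baseline = next(
                lab for lab in result.labels if lab not in causal
            )
            table = haplotype_contrasts(result, baseline)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError, StopIteration):
            failed += 1
            _check_failures(failed, n_sims)
            continue
        lookup = dict(zip(table["label"], table["estimate"]))
        for lab in causal:
            if lab in lookup and np.isfinite(lookup[lab]):
                estimates[lab].append(float(lookup[lab]))
    bias = {}
    for lab in causal:
        vals = np.asarray(estimates[lab])
        bias[lab] = {
            "mean_estimate": float(vals.mean()),
            "se_of_mean": float(vals.std(ddof=1) / np.sqrt(len(vals))),
            "true_effect": effects[lab],
            "n_estimates": int(len(vals)),
        }
    return ExperimentResult(
        experiment="bias",
        design_id=design_id,
        gene=gene.upper(),
        scenario=scenario,
        n_sims=n_sims,
        n_completed=n_sims - failed,
        n_failed=failed,
        alpha=float("nan"),
        seed=seed,
        rejections={},
        runtime_s=time.perf_counter() - t0,
        extras={"bias": bias, "r2": r2},
    )
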