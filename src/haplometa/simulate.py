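"""Simulation engine: study designs, pedigrees, gene dropping, phenotypes.

Cohorts are composed of three unit types: NF2 (nuclear family with two
offspring), NFv (nuclear family with Uniform{1..4} offspring) and U
(unrelated singleton).  Genotypes are gene-dropped from a reference panel of
haplotype frequencies: founders draw two haplotypes iid from the panel and
each offspring inherits one uniformly chosen haplotype from each parent
without recombination.  Ages follow a constructive sampler that satisfies
the generation rules exactly (first offspring Uniform(30, 50); later
offspring within 5 years of the first with pairwise gaps of at least 1
year; mother 20-45 years older than the oldest offspring; father within 5
years of the mother and at least 20 years older than the oldest offspring).
Sexes are coded 1 = male, 2 = female.

Quantitative traits are drawn from a multivariate normal with mean
``0.02*age + 0.5*sex`` plus optional genetic terms, and covariance
``sigma_a^2 Phi + sigma_e^2 I`` (defaults 0.5 / 0.5), sampled family block
by family block.  Genetic effect sizes are calibrated so that a causal
variant with minor allele frequency ``MAF`` gets
``b_g = sqrt(R^2 / (4 MAF (1 - MAF)))`` and a causal haplotype with mean
dosage ``hbar`` gets ``b_h = sqrt(R^2 / (2 hbar (1 - hbar/2)))``; when only
one causal term is present its effect is doubled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .em import GenotypeMatrix, Variant
from .pedigree import Pedigree, PedigreeRecord

__all__ = [
    "ReferencePanel",
    "StudyDesign",
    "EffectScenario",
    "SimulatedCohort",
    "load_panel",
    "study_design",
    "DESIGN_IDS",
    "CAUSAL_CHOICES",
    "generate_pedigrees",
    "assign_ages",
    "drop_genes",
    "calibrate_effects",
    "simulate_phenotype",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# reference panels

@dataclass
class ReferencePanel:
    """Haplotype frequency panel over a fixed variant list."""

    name: str
    variants: list[Variant]
    labels: list[str]
    frequencies: np.ndarray  # renormalized to sum to 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.labels) != len(self.frequencies):
            raise ValueError("labels/frequencies mismatch")
        total = self.frequencies.sum()
        if not 0 < total <= 1 + 1e-9 or 1 - total > 1e-3:
            raise ValueError(
                f"panel frequencies sum to {total:.4f}; remainder above rounding slack"
            )
        self.frequencies = self.frequencies / total
        q = len(self.variants)
        for lab in self.labels:
            if len(lab) != q:
                raise ValueError(f"haplotype {lab!r} length != {q} variants")
            for a, v in zip(lab, self.variants):
                if a not in (v.minor, v.major):
                    raise ValueError(f"allele {a!r} invalid at {v.id}")
        # bit j of a haplotype code = minor allele at variant j
        self.codes = np.array(
            [
                sum(1 << j for j, (a, v) in enumerate(zip(lab, self.variants)) if a == v.minor)
                for lab in self.labels
            ],
            dtype=np.int64,
        )
        self.minor_counts = ((self.codes[:, None] >> np.arange(q)) & 1).astype(np.int8)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def minor_allele_freqs(self) -> np.ndarray:
        """Panel-implied minor allele frequency at each variant."""
        return self.frequencies @ self.minor_counts

    def hap_frequency(self, label: str) -> float:
        return float(self.frequencies[self.labels.index(label)])


def _read_panel(name: str, var_file: str, hap_file: str) -> ReferencePanel:
    pkg = importlib.resources.files("haplometa") / "panels"
    vdf = pd.read_csv(pkg / var_file, sep="\t", dtype={"chrom": str})
    variants = [
        Variant(r.id, str(r.chrom), int(r.pos), r.minor, r.major)
        for r in vdf.itertuples()
    ]
    hdf = pd.read_csv(pkg / hap_file, sep="\t")
    labels = ["".join(row[v.id] for v in variants) for _, row in hdf.iterrows()]
    return ReferencePanel(name, variants, labels, hdf["frequency"].to_numpy(float))


_PANEL_FILES = {
    "G6PC2": ("g6pc2_variants.tsv", "g6pc2_haplotypes.tsv"),
    "JAZF1": ("jazf1_variants.tsv", "jazf1_haplotypes.tsv"),
}
_PANEL_CACHE: dict[str, ReferencePanel] = {}


def load_panel(gene: str) -> ReferencePanel:
    """Load a packaged reference panel (``"G6PC2"`` or ``"JAZF1"``)."""
    gene = gene.upper()
    if gene not in _PANEL_FILES:
        raise KeyError(f"unknown panel {gene!r}; available: {sorted(_PANEL_FILES)}")
    if gene not in _PANEL_CACHE:
        _PANEL_CACHE[gene] = _read_panel(gene, *_PANEL_FILES[gene])
    return _PANEL_CACHE[gene]


# ---------------------------------------------------------------------------
# study designs

@dataclass
class StudyDesign:
    """Cohort composition: each cohort is a list of (unit_type, n_units)."""

    design_id: int
    cohorts: list[list[tuple[str, int]]]

    def __post_init__(self) -> None:
        for spec in self.cohorts:
            for unit, count in spec:
                if unit not in ("NF2", "NFv", "U"):
                    raise ValueError(f"unknown unit type {unit!r}")
                if count < 1:
                    raise ValueError("unit counts must be >= 1")

    @property
    def n_cohorts(self) -> int:
        return len(self.cohorts)


def _rep(spec: list[tuple[str, int]], times: int) -> list[list[tuple[str, int]]]:
    return [list(spec) for _ in range(times)]


_DESIGNS: dict[int, list[list[tuple[str, int]]]] = {
    1: _rep([("NF2", 250)], 5),
    2: _rep([("NFv", 250)], 5),
    3: [[("NF2", 100)], [("NF2", 175)], [("U", 400)], [("U", 700)], [("U", 1000)]],
    4: [[("NFv", 100)], [("NFv", 175)], [("U", 400)], [("U", 700)], [("U", 1000)]],
    5: [[("NFv", 100)], [("NFv", 175)], [("NFv", 250)], [("NFv", 325)], [("NFv", 400)]],
    6: _rep([("NF2", 250)], 5) + _rep([("U", 1000)], 5),
    7: [[("U", n)] for n in (400, 700, 1000, 1300, 1600)] * 2,
    8: [[("NF2", n)] for n in (100, 175, 250, 325, 400)],
    9: [
        [("NF2", 250), ("U", 1000)],
        [("NF2", 125), ("U", 500)],
        [("NF2", 125), ("U", 500)],
        [("NF2", 375), ("U", 1500)],
        [("NF2", 375), ("U", 1500)],
    ],
    10: _rep([("NFv", 250)], 7) + _rep([("U", 1000)], 3),
}

DESIGN_IDS = tuple(sorted(_DESIGNS))


def study_design(design_id: int) -> StudyDesign:
    if design_id not in _DESIGNS:
        raise KeyError(f"unknown study design {design_id}; valid: {DESIGN_IDS}")
    return StudyDesign(design_id, [list(c) for c in _DESIGNS[design_id]])


# ---------------------------------------------------------------------------
# internal cohort structure (individuals ordered unit by unit:
# father, mother, offspring... for families; single row for unrelated)

_EIG_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_CHOL_CACHE: dict[tuple[int, float, float], np.ndarray] = {}


def family_phi_block(n_offspring: int) -> np.ndarray:
    """Twice-kinship block for one nuclear family (father, mother, k offspring)."""
    s = n_offspring + 2
    phi = np.eye(s)
    phi[0, 2:] = phi[2:, 0] = 0.5
    phi[1, 2:] = phi[2:, 1] = 0.5
    for i in range(2, s):
        for j in range(2, s):
            if i != j:
                phi[i, j] = 0.5
    return phi


def _block_eigen(k: int) -> tuple[np.ndarray, np.ndarray]:
    if k not in _EIG_CACHE:
        d, Q = np.linalg.eigh(family_phi_block(k))
        _EIG_CACHE[k] = (np.maximum(d, 0.0), Q)
    return _EIG_CACHE[k]


def _block_chol(k: int, sigma_a2: float, sigma_e2: float) -> np.ndarray:
    key = (k, float(sigma_a2), float(sigma_e2))
    if key not in _CHOL_CACHE:
        cov = sigma_a2 * family_phi_block(k) + sigma_e2 * np.eye(k + 2)
        _CHOL_CACHE[key] = np.linalg.cholesky(cov)
    return _CHOL_CACHE[key]


@dataclass
class CohortStructure:
    """Array layout of one simulated cohort's pedigree."""

    n_offspring: np.ndarray  # per unit; -1 marks an unrelated singleton

    def __post_init__(self) -> None:
        self.n_offspring = np.asarray(self.n_offspring, dtype=np.int64)
        self.unit_sizes = np.where(self.n_offspring < 0, 1, self.n_offspring + 2)
        self.unit_starts = np.concatenate([[0], np.cumsum(self.unit_sizes)[:-1]])
        self.n = int(self.unit_sizes.sum())
        # parent indices per individual (-1 for founders/unrelated)
        father = np.full(self.n, -1, dtype=np.int64)
        mother = np.full(self.n, -1, dtype=np.int64)
        for start, k in zip(self.unit_starts, self.n_offspring):
            if k >= 1:
                father[start + 2 : start + 2 + k] = start
                mother[start + 2 : start + 2 + k] = start + 1
        self.father = father
        self.mother = mother
        self._groups: dict[int, np.ndarray] | None = None

    def size_groups(self) -> dict[int, np.ndarray]:
        """Family units grouped by offspring count: k -> (F_k, k+2) row indices;
        key -1 collects unrelated singleton rows as a flat array."""
        if self._groups is None:
            groups: dict[int, list] = {}
            for start, k in zip(self.unit_starts, self.n_offspring):
                groups.setdefault(int(k), []).append(start)
            out: dict[int, np.ndarray] = {}
            for k, starts in groups.items():
                starts_arr = np.asarray(starts)
                if k < 0:
                    out[-1] = starts_arr
                else:
                    out[k] = starts_arr[:, None] + np.arange(k + 2)[None, :]
            self._groups = out
        return self._groups

    def eigen_transform(self, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rotate rows of ``M`` (n, m) into the eigenbasis of block-diagonal
        Phi; returns (eigenvalues d, rotated matrix).  Row order is permuted
        relative to the input (harmless for sums over components)."""
        d_parts, m_parts = [], []
        for k, idx in self.size_groups().items():
            if k < 0:
                m_parts.append(M[idx])
                d_parts.append(np.ones(len(idx)))
            else:
                d, Q = _block_eigen(k)
                block = M[idx]                      # (F, s, m)
                rot = np.einsum("ji,fjm->fim", Q, block)
                m_parts.append(rot.reshape(-1, M.shape[1]))
                d_parts.append(np.tile(d, len(idx)))
        return np.concatenate(d_parts), np.concatenate(m_parts, axis=0)

    def to_pedigree(self, sexes: np.ndarray, family_prefix: str = "F") -> Pedigree:
        records = []
        for u, (start, k) in enumerate(zip(self.unit_starts, self.n_offspring)):
            fam = f"{family_prefix}{u + 1}"
            if k < 0:
                records.append(
                    PedigreeRecord(fam, f"{fam}_1", None, None, int(sexes[start]))
                )
                continue
            fid, mid = f"{fam}_1", f"{fam}_2"
            records.append(PedigreeRecord(fam, fid, None, None, 1))
            records.append(PedigreeRecord(fam, mid, None, None, 2))
            for o in range(k):
                records.append(
                    PedigreeRecord(
                        fam, f"{fam}_{o + 3}", fid, mid, int(sexes[start + 2 + o])
                    )
                )
        return Pedigree(records)

    def individual_ids(self) -> list[str]:
        ids = []
        for u, (start, k) in enumerate(zip(self.unit_starts, self.n_offspring)):
            fam = f"F{u + 1}"
            ids.extend(f"{fam}_{i + 1}" for i in range(self.unit_sizes[u]))
        return ids


def build_structure(
    spec: list[tuple[str, int]], rng: np.random.Generator
) -> CohortStructure:
    """Instantiate a cohort spec; NFv offspring counts drawn Uniform{1..4}."""
    n_off = []
    for unit, count in spec:
        if unit == "NF2":
            n_off.extend([2] * count)
        elif unit == "U":
            n_off.extend([-1] * count)
        else:  # NFv
            n_off.extend(rng.integers(1, 5, size=count).tolist())
    return CohortStructure(np.asarray(n_off))


# ---------------------------------------------------------------------------
# ages and sexes

def _assign_ages_structure(
    struct: CohortStructure, rng: np.random.Generator
) -> np.ndarray:
    ages = np.empty(struct.n)
    starts, n_off = struct.unit_starts, struct.n_offspring
    # unrelated subjects and first offspring: Uniform(30, 50)
    single = starts[n_off < 0]
    ages[single] = rng.uniform(30.0, 50.0, size=len(single))
    fam = np.flatnonzero(n_off >= 1)
    first = starts[fam] + 2
    ages[first] = rng.uniform(30.0, 50.0, size=len(fam))

    # second offspring: uniform on [a1-5, a1+5] minus the no-twin zone (a1-1, a1+1)
    two_plus = np.flatnonzero(n_off >= 2)
    if len(two_plus):
        a1 = ages[starts[two_plus] + 2]
        u = rng.uniform(0.0, 8.0, size=len(two_plus))
        ages[starts[two_plus] + 3] = np.where(u < 4.0, a1 - 5.0 + u, a1 + u - 3.0)

    # third and later offspring: uniform on the anchored window minus all
    # (+-1 year) exclusion zones around existing siblings
    for order in (2, 3):
        units = np.flatnonzero(n_off >= order + 1)
        for u_idx in units:
            start = starts[u_idx]
            a1 = ages[start + 2]
            sibs = ages[start + 2 : start + 2 + order]
            lo, hi = a1 - 5.0, a1 + 5.0
            holes = sorted((max(s - 1.0, lo), min(s + 1.0, hi)) for s in sibs)
            segments, cursor = [], lo
            for h0, h1 in holes:
                if h0 > cursor:
                    segments.append((cursor, h0))
                cursor = max(cursor, h1)
            if cursor < hi:
                segments.append((cursor, hi))
            lengths = np.array([b - a for a, b in segments])
            x = rng.uniform(0.0, lengths.sum())
            seg = int(np.searchsorted(np.cumsum(lengths), x))
            offset = x - (np.cumsum(lengths)[seg] - lengths[seg])
            ages[start + 2 + order] = segments[seg][0] + offset

    # parents anchored to the oldest offspring
    if len(fam):
        oldest = np.array(
            [ages[s + 2 : s + 2 + k].max() for s, k in zip(starts[fam], n_off[fam])]
        )
        mother = oldest + rng.uniform(20.0, 45.0, size=len(fam))
        f_lo = np.maximum(mother - 5.0, oldest + 20.0)
        father = rng.uniform(f_lo, mother + 5.0)
        ages[starts[fam]] = father
        ages[starts[fam] + 1] = mother
    return ages


def _assign_sexes(struct: CohortStructure, rng: np.random.Generator) -> np.ndarray:
    sexes = rng.integers(1, 3, size=struct.n).astype(np.int8)
    fam = struct.n_offspring >= 1
    sexes[struct.unit_starts[fam]] = 1      # father
    sexes[struct.unit_starts[fam] + 1] = 2  # mother
    return sexes


# ---------------------------------------------------------------------------
# gene dropping

def _drop_genes_structure(
    panel: ReferencePanel, struct: CohortStructure, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (haplotype index pairs (n, 2) into the panel, genotype counts)."""
    n = struct.n
    hap = np.empty((n, 2), dtype=np.int64)
    founders = struct.father < 0
    hap[founders] = rng.choice(
        len(panel.frequencies), size=(int(founders.sum()), 2), p=panel.frequencies
    )
    offspring = np.flatnonzero(~founders)
    if len(offspring):
        pick = rng.integers(0, 2, size=(len(offspring), 2))
        hap[offspring, 0] = hap[struct.father[offspring], pick[:, 0]]
        hap[offspring, 1] = hap[struct.mother[offspring], pick[:, 1]]
    genotypes = panel.minor_counts[hap[:, 0]] + panel.minor_counts[hap[:, 1]]
    return hap, genotypes.astype(np.int8)


# ---------------------------------------------------------------------------
# effect scenarios and phenotypes

CAUSAL_CHOICES = {
    "G6PC2": {"snvs": ("rs560887", "rs2232323"), "haps": ("CCAC", "TCAG")},
    "JAZF1": {"snvs": ("rs849134", "rs38523"), "haps": ("GTATA", "GCGCG")},
}

SCENARIO_KINDS = ("null", "1SNV", "2SNV", "1HAP", "2HAP")


@dataclass
class EffectScenario:
    """Genetic architecture of the alternative: which labels are causal and
    the per-term variance-explained parameter R^2."""

    kind: str
    causal_snvs: tuple[str, ...] = ()
    causal_haps: tuple[str, ...] = ()
    r2: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind != "null" and not 0 < self.r2 < 1:
            raise ValueError("R^2 must be in (0, 1)")

    @classmethod
    def for_gene(cls, kind: str, gene: str, r2: float = 0.01) -> "EffectScenario":
        gene = gene.upper()
        choice = CAUSAL_CHOICES[gene]
        if kind == "null":
            return cls("null")
        if kind == "1SNV":
            return cls(kind, causal_snvs=choice["snvs"][:1], r2=r2)
        if kind == "2SNV":
            return cls(kind, causal_snvs=choice["snvs"], r2=r2)
        if kind == "1HAP":
            return cls(kind, causal_haps=choice["haps"][:1], r2=r2)
        if kind == "2HAP":
            return cls(kind, causal_haps=choice["haps"], r2=r2)
        raise ValueError(kind)


def calibrate_effects(
    scenario: EffectScenario, panel: ReferencePanel
) -> dict[str, float]:
    """Effect size per causal label, from panel frequencies.

    ``b_g = sqrt(R^2 / (4 MAF (1 - MAF)))`` for variants and
    ``b_h = sqrt(R^2 / (2 hbar (1 - hbar/2)))`` for haplotypes (``hbar`` =
    mean dosage = twice the frequency); a lone causal term is doubled.
    """
    effects: dict[str, float] = {}
    if scenario.kind == "null":
        return effects
    mafs = dict(zip([v.id for v in panel.variants], panel.minor_allele_freqs()))
    for snv in scenario.causal_snvs:
        maf = mafs[snv]
        if not 0 < maf < 1:
            raise ValueError(f"undefined effect: MAF of {snv} is {maf}")
        effects[snv] = float(np.sqrt(scenario.r2 / (4.0 * maf * (1.0 - maf))))
    for hap in scenario.causal_haps:
        hbar = 2.0 * panel.hap_frequency(hap)
        if not 0 < hbar < 2:
            raise ValueError(f"undefined effect: mean dosage of {hap} is {hbar}")
        effects[hap] = float(np.sqrt(scenario.r2 / (2.0 * hbar * (1.0 - hbar / 2.0))))
    if len(effects) == 1:
        (lab,) = effects
        effects[lab] *= 2.0
    return effects


def _phenotype_structure(
    struct: CohortStructure,
    ages: np.ndarray,
    sexes: np.ndarray,
    genetic: np.ndarray,
    rng: np.random.Generator,
    sigma_a2: float = 0.5,
    sigma_e2: float = 0.5,
) -> np.ndarray:
    mean = 0.02 * ages + 0.5 * sexes + genetic
    noise = np.empty(struct.n)
    for k, idx in struct.size_groups().items():
        if k < 0:
            noise[idx] = rng.normal(
                0.0, np.sqrt(sigma_a2 + sigma_e2), size=len(idx)
            )
        else:
            L = _block_chol(k, sigma_a2, sigma_e2)
            z = rng.standard_normal((len(idx), k + 2))
            noise[idx] = z @ L.T
    return mean + noise


def _genetic_mean(
    panel: ReferencePanel,
    scenario: EffectScenario,
    hap: np.ndarray,
    genotypes: np.ndarray,
) -> np.ndarray:
    """Causal contribution to the trait mean from true gene-drop dosages."""
    n = len(hap)
    g = np.zeros(n)
    if scenario.kind == "null":
        return g
    effects = calibrate_effects(scenario, panel)
    var_ids = [v.id for v in panel.variants]
    for snv in scenario.causal_snvs:
        g += effects[snv] * genotypes[:, var_ids.index(snv)]
    for lab in scenario.causal_haps:
        h_idx = panel.labels.index(lab)
        dosage = (hap[:, 0] == h_idx).astype(float) + (hap[:, 1] == h_idx)
        g += effects[lab] * dosage
    return g


# ---------------------------------------------------------------------------
# public container and pedigree-level operations

@dataclass
class SimulatedCohort:
    """One simulated cohort: pedigree layout, true phased haplotypes,
    unphased genotypes, covariates and trait."""

    structure: CohortStructure
    panel: ReferencePanel
    ages: np.ndarray
    sexes: np.ndarray
    hap_indices: np.ndarray    # (n, 2) true phased haplotypes (panel indices)
    genotypes: np.ndarray      # (n, q) minor-allele counts, phase stripped
    trait: np.ndarray
    scenario: EffectScenario = field(default_factory=lambda: EffectScenario("null"))

    @property
    def n(self) -> int:
        return self.structure.n

    def genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            self.structure.individual_ids(), self.panel.variants, self.genotypes
        )

    def to_pedigree(self) -> Pedigree:
        return self.structure.to_pedigree(self.sexes)


def simulate_cohort(
    spec: list[tuple[str, int]],
    panel: ReferencePanel,
    scenario: EffectScenario | None = None,
    rng: np.random.Generator | int | None = None,
    sigma_a2: float = 0.5,
    sigma_e2: float = 0.5,
) -> SimulatedCohort:
    """Simulate one cohort end to end under a study-design spec."""
    rng = np.random.default_rng(rng)
    scenario = scenario or EffectScenario("null")
    struct = build_structure(spec, rng)
    ages = _assign_ages_structure(struct, rng)
    sexes = _assign_sexes(struct, rng)
    hap, genotypes = _drop_genes_structure(panel, struct, rng)
    genetic = _genetic_mean(panel, scenario, hap, genotypes)
    trait = _phenotype_structure(
        struct, ages, sexes, genetic, rng, sigma_a2, sigma_e2
    )
    return SimulatedCohort(struct, panel, ages, sexes, hap, genotypes, trait, scenario)


def generate_pedigrees(
    design: StudyDesign, seed: int | np.random.Generator | None = None
) -> list[Pedigree]:
    """One pedigree per cohort of the design (with randomized offspring sexes)."""
    rng = np.random.default_rng(seed)
    out = []
    for spec in design.cohorts:
        struct = build_structure(spec, rng)
        out.append(struct.to_pedigree(_assign_sexes(struct, rng)))
    return out


def _structure_from_pedigree(pedigree: Pedigree) -> tuple[CohortStructure, np.ndarray]:
    """Recover the unit layout from a nuclear-family pedigree; returns the
    structure and the permutation mapping structure rows to pedigree rows."""
    n_off, perm = [], []
    for fam, members in pedigree.families().items():
        founders = [r for r in members if r.father is None]
        offspring = [r for r in members if r.father is not None]
        index = {r.individual: i for i, r in enumerate(pedigree.records)}
        pos = {
            r.individual: pedigree._index[(fam, r.individual)] for r in members
        }
        if len(members) == 1 and not offspring:
            n_off.append(-1)
            perm.append(pos[members[0].individual])
            continue
        if len(founders) != 2 or not offspring:
            raise ValueError(
                f"family {fam!r} is not a nuclear family (needs 2 founders + offspring)"
            )
        father = next((r for r in founders if r.sex == 1), founders[0])
        mother = next((r for r in founders if r is not father), founders[1])
        n_off.append(len(offspring))
        perm.append(pos[father.individual])
        perm.append(pos[mother.individual])
        perm.extend(pos[r.individual] for r in offspring)
    return CohortStructure(np.asarray(n_off)), np.asarray(perm)


def assign_ages(
    pedigree: Pedigree, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Ages (years) for a nuclear-family/unrelated pedigree, in record order."""
    rng = np.random.default_rng(seed)
    struct, perm = _structure_from_pedigree(pedigree)
    ages = _assign_ages_structure(struct, rng)
    out = np.empty(len(pedigree))
    out[perm] = ages
    return out


def drop_genes(
    panel: ReferencePanel,
    pedigree: Pedigree,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], GenotypeMatrix]:
    """Gene-drop the panel through a pedigree.

    Returns the true phased haplotype label pairs (record order) and the
    unphased genotype matrix.
    """
    rng = np.random.default_rng(seed)
    struct, perm = _structure_from_pedigree(pedigree)
    hap, genotypes = _drop_genes_structure(panel, struct, rng)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    phased = [
        (panel.labels[hap[i, 0]], panel.labels[hap[i, 1]]) for i in inv
    ]
    counts = genotypes[inv]
    return phased, GenotypeMatrix(
        [r.individual for r in pedigree.records], panel.variants, counts
    )


def simulate_phenotype(
    pedigree: Pedigree,
    ages: np.ndarray,
    sexes: np.ndarray,
    genetic: np.ndarray,
    seed: int | np.random.Generator | None = None,
    sigma_a2: float = 0.5,
    sigma_e2: float = 0.5,
) -> np.ndarray:
    """Draw one trait vector (record order) with mean ``0.02*age + 0.5*sex +
    genetic`` and covariance ``sigma_a^2 Phi + sigma_e^2 I``."""
    rng = np.random.default_rng(seed)
    struct, perm = _structure_from_pedigree(pedigree)
    ages = np.asarray(ages, dtype=float)[perm]
    sexes = np.asarray(sexes, dtype=float)[perm]
    genetic = np.asarray(genetic, dtype=float)[perm]
    y = _phenotype_structure(struct, ages, sexes, genetic, rng, sigma_a2, sigma_e2)
    out = np.empty(len(pedigree))
    out[perm] = y
    return out
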