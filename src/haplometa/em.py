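"""Haplotype frequency estimation and expected dosages from unphased genotypes.

Given unphased genotypes at ``q`` nearby biallelic variants, the phase of a
subject heterozygous at ``H`` sites is ambiguous among ``2^(H-1)`` diplotypes
(unordered haplotype pairs).  Haplotype population frequencies are estimated
by an EM algorithm on the phase-unknown multinomial likelihood; the expected
haplotype dosage of subject ``j`` for haplotype ``m`` is the posterior mean
number of copies of ``m`` carried, ``E[h_mj | G_j]``, which always sums to 2
over haplotypes.  Rare haplotypes can be collapsed into a single pooled
category to stabilise the downstream regression.

Haplotypes are represented internally as integers whose bit ``j`` indicates
the minor allele at variant ``j``; labels are the corresponding allele
strings (e.g. ``"TCAG"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "HaplotypeTable",
    "DosageMatrix",
    "RARE_LABEL",
    "enumerate_diplotypes",
    "em_haplotype_frequencies",
    "expected_dosages",
    "collapse_rare",
    "read_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "write_vcf",
]

#: Sentinel label for the pooled rare-haplotype category.  It is a fixed
#: string so that pooled categories align by label across cohorts.
RARE_LABEL = "_RARE_"


@dataclass(frozen=True)
class Variant:
    id: str
    chrom: str
    pos: int
    minor: str
    major: str


@dataclass
class GenotypeMatrix:
    """Minor-allele counts (0/1/2, -1 for missing) for n subjects x q variants."""

    subject_ids: list[str]
    variants: list[Variant]
    counts: np.ndarray  # (n, q) int8

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        n, q = self.counts.shape
        if n != len(self.subject_ids) or q != len(self.variants):
            raise ValueError("genotype matrix shape does not match ids/variants")
        if q < 1:
            raise ValueError("need at least one variant")
        valid = np.isin(self.counts, [-1, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype counts must be 0, 1, 2 or -1 (missing)")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def complete_cases(self) -> "GenotypeMatrix":
        """Drop subjects with any missing genotype in the region."""
        keep = ~(self.counts < 0).any(axis=1)
        return GenotypeMatrix(
            [s for s, k in zip(self.subject_ids, keep) if k],
            self.variants,
            self.counts[keep],
        )


@dataclass
class HaplotypeTable:
    """Haplotype allele strings with population frequencies (sum to 1)."""

    labels: list[str]
    frequencies: np.ndarray
    variants: list[Variant]
    converged: bool = True
    log_likelihood: float = float("nan")
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.labels) != len(self.frequencies):
            raise ValueError("labels/frequencies length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("haplotype labels must be unique")
        if (self.frequencies < -1e-12).any():
            raise ValueError("negative haplotype frequency")
        if abs(self.frequencies.sum() - 1.0) > 1e-10:
            raise ValueError("haplotype frequencies must sum to 1")

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for lab, f in zip(self.labels, self.frequencies):
            row = {"label": lab}
            if lab != RARE_LABEL:
                for v, a in zip(self.variants, lab):
                    row[v.id] = a
            row["frequency"] = f
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, variants: list[Variant]) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"label": str})
        return cls(
            labels=df["label"].tolist(),
            frequencies=df["frequency"].to_numpy(dtype=float),
            variants=variants,
        )


@dataclass
class DosageMatrix:
    """Expected haplotype counts per subject; each row sums to 2."""

    subject_ids: list[str]
    labels: list[str]
    values: np.ndarray  # (n, K) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.labels)):
            raise ValueError("dosage matrix shape mismatch")
        if self.values.size:
            if (self.values < -1e-8).any() or (self.values > 2 + 1e-8).any():
                raise ValueError("dosages must lie in [0, 2]")
            if not np.allclose(self.values.sum(axis=1), 2.0, atol=1e-8):
                raise ValueError("each dosage row must sum to 2")


# ---------------------------------------------------------------------------
# diplotype enumeration

# cache: genotype row (as bytes) -> (hapA array, hapB array) of integer codes
_PAIR_CACHE: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}


def _enumerate_pairs(row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    key = row.tobytes()
    hit = _PAIR_CACHE.get(key)
    if hit is not None:
        return hit
    het = np.flatnonzero(row == 1)
    base = 0
    for j in np.flatnonzero(row == 2):
        base |= 1 << int(j)
    if len(het) == 0:
        pairs = (np.array([base], dtype=np.int64), np.array([base], dtype=np.int64))
    else:
        # first het site assigned to haplotype A: each unordered pair once
        first, rest = int(het[0]), het[1:]
        m = len(rest)
        a = np.full(1 << m, base | (1 << first), dtype=np.int64)
        b = np.full(1 << m, base, dtype=np.int64)
        for i, j in enumerate(rest):
            bit = (np.arange(1 << m) >> i) & 1
            a |= bit.astype(np.int64) << int(j)
            b |= (1 - bit).astype(np.int64) << int(j)
        pairs = (a, b)
    _PAIR_CACHE[key] = pairs
    return pairs


def _code_to_label(code: int, variants: Sequence[Variant]) -> str:
    return "".join(
        v.minor if (code >> j) & 1 else v.major for j, v in enumerate(variants)
    )


def _label_to_code(label: str, variants: Sequence[Variant]) -> int:
    code = 0
    for j, (a, v) in enumerate(zip(label, variants)):
        if a == v.minor:
            code |= 1 << j
        elif a != v.major:
            raise ValueError(f"allele {a!r} at {v.id} matches neither {v.minor}/{v.major}")
    return code


def enumerate_diplotypes(genotype_row: np.ndarray) -> set[tuple[int, int]]:
    """All phase configurations consistent with one genotype row.

    Returns unordered pairs of integer haplotype codes (bit ``j`` = minor
    allele at variant ``j``); there are ``max(1, 2^(H-1))`` of them for a row
    heterozygous at ``H`` sites.
    """
    row = np.asarray(genotype_row, dtype=np.int8)
    if (row < 0).any():
        raise ValueError("genotype row contains missing values")
    a, b = _enumerate_pairs(row)
    return {tuple(sorted((int(x), int(y)))) for x, y in zip(a, b)}


# ---------------------------------------------------------------------------
# EM

def _build_support(counts: np.ndarray):
    """Group identical genotype rows and enumerate their compatible pairs."""
    n, q = counts.shape
    codes = counts.astype(np.int64) @ (3 ** np.arange(q, dtype=np.int64))
    _, first_idx, inverse, group_n = np.unique(
        codes, return_index=True, return_inverse=True, return_counts=True
    )
    pair_a, pair_b, pair_group = [], [], []
    for g, i0 in enumerate(first_idx):
        a, b = _enumerate_pairs(counts[i0])
        pair_a.append(a)
        pair_b.append(b)
        pair_group.append(np.full(len(a), g, dtype=np.int64))
    pair_a = np.concatenate(pair_a)
    pair_b = np.concatenate(pair_b)
    pair_group = np.concatenate(pair_group)
    # compact haplotype indexing over the union of supported haplotypes
    hap_codes, pair_idx = np.unique(np.concatenate([pair_a, pair_b]), return_inverse=True)
    idx_a = pair_idx[: len(pair_a)]
    idx_b = pair_idx[len(pair_a):]
    mult = np.where(pair_a == pair_b, 1.0, 2.0)
    return hap_codes, idx_a, idx_b, pair_group, mult, inverse, group_n.astype(float)


def em_haplotype_frequencies(
    genotypes: GenotypeMatrix,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int | None = None,
    n_restarts: int = 0,
    trace: list | None = None,
    min_frequency: float | None = None,
) -> HaplotypeTable:
    """EM estimate of haplotype frequencies from unphased genotypes.

    The phase-unknown log-likelihood is non-decreasing across iterations;
    convergence is declared when its absolute change drops below ``tol``.
    Deterministic initialisation at the product of observed allele
    frequencies; ``seed`` only feeds optional random restarts
    (``n_restarts > 0``), whose best fixed point is returned.

    Haplotypes fitted below ``min_frequency`` are pruned and the table
    renormalized.  The default floor is half a chromosome's worth of
    support, ``0.25/n``: fitted frequencies below it represent phase
    configurations with essentially no posterior weight, and keeping them
    produces all-but-zero dosage columns that make the downstream
    regression singular.  A haplotype any subject carries unambiguously is
    estimated at ``>= 1/(2n)`` and can never be pruned by this floor.
    """
    counts = genotypes.counts
    if (counts < 0).any():
        raise ValueError("missing genotypes: call complete_cases() first")
    n, q = counts.shape
    hap_codes, idx_a, idx_b, pair_group, mult, _, group_n = _build_support(counts)
    n_grp = len(group_n)

    maf = counts.mean(axis=0) / 2.0
    bits = (hap_codes[:, None] >> np.arange(q)) & 1
    init = np.prod(np.where(bits == 1, maf, 1.0 - maf), axis=1)
    if init.sum() <= 0:
        init = np.ones(len(hap_codes))
    starts = [init / init.sum()]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            p = rng.dirichlet(np.ones(len(hap_codes)))
            starts.append(p)

    best = None
    for p0 in starts:
        p, ll, it, conv = _em_run(
            p0, idx_a, idx_b, pair_group, mult, group_n, n_grp, 2.0 * n, tol,
            max_iter, trace,
        )
        if best is None or ll > best[1]:
            best = (p, ll, it, conv)
    p, ll, it, conv = best

    # prune-and-polish: zero out sub-floor frequencies and re-converge on the
    # reduced support (zeros are absorbing under EM updates), so the returned
    # table is again a fixed point of the restricted likelihood
    floor = max(0.25 / n if min_frequency is None else min_frequency, 1e-12)
    for _ in range(len(p)):
        drop = (p < floor) & (p > 0)
        if not drop.any():
            break
        p = np.where(drop, 0.0, p)
        p = p / p.sum()
        p, ll, it2, conv = _em_run(
            p, idx_a, idx_b, pair_group, mult, group_n, n_grp, 2.0 * n, tol,
            max_iter,
        )
        it += it2
    if not conv:
        warnings.warn("haplotype EM did not converge", stacklevel=2)

    keep = p > 0
    p = p[keep] / p[keep].sum()
    hap_codes = hap_codes[keep]
    order = np.argsort(-p, kind="stable")
    labels = [_code_to_label(int(c), genotypes.variants) for c in hap_codes[order]]
    return HaplotypeTable(
        labels=labels,
        frequencies=p[order],
        variants=genotypes.variants,
        converged=conv,
        log_likelihood=ll,
        n_iter=it,
    )


def _em_run(p, idx_a, idx_b, pair_group, mult, group_n, n_grp, denom, tol,
            max_iter, trace=None):
    p = np.asarray(p, dtype=float)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pw = mult * p[idx_a] * p[idx_b]
        gsum = np.bincount(pair_group, weights=pw, minlength=n_grp)
        ll = float(np.dot(group_n, np.log(np.maximum(gsum, 1e-300))))
        if trace is not None:
            trace.append(ll)
        post = pw / np.maximum(gsum[pair_group], 1e-300) * group_n[pair_group]
        new = np.bincount(idx_a, weights=post, minlength=len(p))
        new += np.bincount(idx_b, weights=post, minlength=len(p))
        p = new / denom
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return p, prev_ll, it, converged


def expected_dosages(genotypes: GenotypeMatrix, freqs: HaplotypeTable) -> DosageMatrix:
    """Posterior-expected haplotype counts per subject given EM frequencies.

    Each subject's compatible diplotypes are re-enumerated, weighted by
    ``mult * f_a * f_b`` and normalised; the dosage of haplotype ``m`` is the
    posterior-weighted number of copies carried.  Rows sum to 2; subjects
    with at most one heterozygous site get integer rows.
    """
    counts = genotypes.counts
    if (counts < 0).any():
        raise ValueError("missing genotypes: call complete_cases() first")
    if RARE_LABEL in freqs.labels:
        raise ValueError("compute dosages before collapsing rare haplotypes")
    n, q = counts.shape
    hap_codes, idx_a, idx_b, pair_group, mult, inverse, _ = _build_support(counts)
    table_codes = np.array(
        [_label_to_code(lab, freqs.variants) for lab in freqs.labels], dtype=np.int64
    )
    code_to_col = {int(c): k for k, c in enumerate(table_codes)}
    col = np.array([code_to_col.get(int(c), -1) for c in hap_codes], dtype=np.int64)
    f = np.zeros(len(hap_codes))
    known = col >= 0
    f[known] = freqs.frequencies[col[known]]

    n_grp = int(pair_group.max()) + 1 if len(pair_group) else 0
    pw = mult * f[idx_a] * f[idx_b]
    gsum = np.bincount(pair_group, weights=pw, minlength=n_grp)
    dead = np.flatnonzero(gsum <= 0)
    if len(dead):
        bad_grp = set(dead.tolist())
        bad = [s for s, g in zip(genotypes.subject_ids, inverse) if int(g) in bad_grp]
        raise ValueError(
            f"zero posterior support for subject(s) {bad[:5]}: genotypes "
            "incompatible with every haplotype pair of nonzero frequency"
        )
    post = pw / gsum[pair_group]

    K = len(freqs.labels)
    grp_dos = np.zeros((n_grp, K))
    np.add.at(grp_dos, (pair_group, col[idx_a]), post)
    np.add.at(grp_dos, (pair_group, col[idx_b]), post)
    values = grp_dos[inverse]
    values *= 2.0 / values.sum(axis=1, keepdims=True)  # exact conservation
    return DosageMatrix(list(genotypes.subject_ids), list(freqs.labels), values)


def collapse_rare(
    dosages: DosageMatrix,
    freqs: HaplotypeTable,
    threshold: float = 0.001,
) -> tuple[DosageMatrix, HaplotypeTable]:
    """Merge haplotypes with frequency below ``threshold`` into one pooled
    category labelled :data:`RARE_LABEL` (dosages and frequencies summed)."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    rare = freqs.frequencies < threshold
    if not rare.any():
        return dosages, freqs
    if rare.all():
        raise ValueError("all haplotypes fall below the collapse threshold")
    keep = ~rare
    labels = [lab for lab, k in zip(freqs.labels, keep) if k] + [RARE_LABEL]
    new_freq = np.append(freqs.frequencies[keep], freqs.frequencies[rare].sum())
    new_vals = np.column_stack(
        [dosages.values[:, keep], dosages.values[:, rare].sum(axis=1)]
    )
    table = HaplotypeTable(
        labels=labels,
        frequencies=new_freq,
        variants=freqs.variants,
        converged=freqs.converged,
        log_likelihood=freqs.log_likelihood,
        n_iter=freqs.n_iter,
    )
    return DosageMatrix(dosages.subject_ids, labels, new_vals), table


# ---------------------------------------------------------------------------
# I/O

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic sites from a VCF; dosage = ALT (minor) allele count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    variants: list[Variant] = []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"site {rec.ID or rec.POS} is not biallelic")
        variants.append(
            Variant(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=rec.CHROM,
                pos=rec.POS,
                minor=rec.ALT[0],
                major=rec.REF,
            )
        )
        gt = np.asarray(rec.genotype.array())[:, :2]
        row = np.where((gt < 0).any(axis=1), -1, (gt > 0).sum(axis=1))
        rows.append(row.astype(np.int8))
    return GenotypeMatrix(subject_ids, variants, np.array(rows, dtype=np.int8).T)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as a minimal uncompressed VCF (GT field, unphased)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in genotypes.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        for j, v in enumerate(genotypes.variants):
            calls = "\t".join(gt_strings[int(c)] for c in genotypes.counts[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.major}\t{v.minor}\t.\t.\t.\tGT\t{calls}\n")


def read_genotype_tsv(
    path: str | Path, variants_path: str | Path | None = None
) -> GenotypeMatrix:
    """Read a TSV of 0/1/2 minor-allele counts (rows = subjects, first column
    ``id``).  Variant metadata comes from ``variants_path`` (columns id,
    chrom, pos, minor, major) or defaults to placeholder alleles."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    subject_ids = df["id"].tolist()
    var_ids = [c for c in df.columns if c != "id"]
    if variants_path is not None:
        vdf = pd.read_csv(variants_path, sep="\t", dtype=str)
        meta = {r["id"]: r for _, r in vdf.iterrows()}
        variants = [
            Variant(
                id=v,
                chrom=str(meta[v].get("chrom", "1")),
                pos=int(meta[v].get("pos", i + 1)),
                minor=meta[v]["minor"],
                major=meta[v]["major"],
            )
            for i, v in enumerate(var_ids)
        ]
    else:
        variants = [Variant(v, "1", i + 1, "A", "B") for i, v in enumerate(var_ids)]
    counts = df[var_ids].fillna(-1).to_numpy(dtype=np.int8)
    return GenotypeMatrix(subject_ids, variants, counts)


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.counts, columns=[v.id for v in genotypes.variants]
    )
    df.insert(0, "id", genotypes.subject_ids)
    df.to_csv(path, sep="\t", index=False)
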