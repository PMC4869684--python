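import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from haplometa import (
    RARE_LABEL,
    collapse_rare,
    em_haplotype_frequencies,
    enumerate_diplotypes,
    expected_dosages,
    load_panel,
    read_vcf,
    write_vcf,
)
from haplometa.em import HaplotypeTable, _label_to_code

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# diplotype enumeration

@pytest.mark.parametrize(
    "row, expected_pairs",
    [
        ([0, 0, 0], 1),
        ([2, 2, 2], 1),
        ([0, 2, 1], 1),   # one het site: single unordered pair
        ([1, 1, 0], 2),   # 2^(2-1)
        ([1, 1, 1], 4),   # 2^(3-1)
        ([1, 1, 1, 1], 8),
    ],
)
def test_diplotype_counts(row, expected_pairs):
    pairs = enumerate_diplotypes(np.array(row))
    assert len(pairs) == expected_pairs
    q = len(row)
    for a, b in pairs:
        for j in range(q):
            assert ((a >> j) & 1) + ((b >> j) & 1) == row[j]


# ---------------------------------------------------------------------------
# EM frequencies

def test_monomorphic_sample_single_haplotype():
    gm = make_genotypes(np.zeros((10, 3)))
    table = em_haplotype_frequencies(gm)
    assert table.labels == ["AAA"]
    assert table.frequencies[0] == pytest.approx(1.0)


def test_em_recovers_panel_frequencies_from_gene_drop():
    """2,000 unrelated subjects gene-dropped from the G6PC2 panel: EM should
    recover each frequency within 3 binomial SEs at 2n chromosomes."""
    panel = load_panel("G6PC2")
    rng = np.random.default_rng(2024)
    n = 2000
    hap = rng.choice(len(panel.frequencies), size=(n, 2), p=panel.frequencies)
    counts = panel.minor_counts[hap[:, 0]] + panel.minor_counts[hap[:, 1]]
    table = em_haplotype_frequencies(make_genotypes(counts, panel.variants))
    est = dict(zip(table.labels, table.frequencies))
    for lab, f in zip(panel.labels, panel.frequencies):
        se = np.sqrt(f * (1 - f) / (2 * n))
        assert abs(est.get(lab, 0.0) - f) <= 3 * se + 1e-9, lab


def test_em_monotone_loglik():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 3, size=(40, 4))
    trace: list[float] = []
    em_haplotype_frequencies(make_genotypes(counts), trace=trace)
    diffs = np.diff(np.array(trace))
    assert (diffs >= -1e-9).all()


def test_em_matches_direct_likelihood_maximization():
    """On small problems the EM fixed point must attain the same maximum as a
    direct numerical maximization of the phase-unknown likelihood."""
    rng = np.random.default_rng(11)
    for _ in range(4):
        q = int(rng.integers(2, 5))
        n = int(rng.integers(8, 30))
        counts = rng.integers(0, 3, size=(n, q))
        gm = make_genotypes(counts)
        table = em_haplotype_frequencies(gm, tol=1e-12)

        # direct maximization over the probability simplex of all supported
        # haplotypes, softmax-parameterized, multi-start
        pair_sets = [enumerate_diplotypes(row) for row in counts]
        haps = sorted({h for pairs in pair_sets for pair in pairs for h in pair})
        hidx = {h: i for i, h in enumerate(haps)}

        def negll(z):
            p = np.exp(z - z.max())
            p = p / p.sum()
            ll = 0.0
            for pairs in pair_sets:
                lik = sum(
                    (2.0 if a != b else 1.0) * p[hidx[a]] * p[hidx[b]]
                    for a, b in pairs
                )
                ll += np.log(max(lik, 1e-300))
            return -ll

        best = np.inf
        for s in range(6):
            z0 = np.random.default_rng(s).normal(0, 1, len(haps))
            res = minimize(negll, z0, method="Nelder-Mead",
                           options={"maxiter": 20000, "fatol": 1e-12, "xatol": 1e-8})
            best = min(best, res.fun)
        assert table.log_likelihood >= -best - 1e-4


def test_double_heterozygote_ridge_is_stationary():
    """Every subject heterozygous at both of 2 SNVs: the likelihood only
    depends on f_AB*f_ab + f_Ab*f_aB, so the deterministic allele-frequency
    initialization sits at the symmetric stationary point while random
    restarts can reach the boundary maxima."""
    n = 12
    counts = np.ones((n, 2), dtype=np.int8)
    gm = make_genotypes(counts)
    table = em_haplotype_frequencies(gm)
    # symmetric stationary point: all four haplotypes at 1/4 -> P(G) = 1/4
    assert table.log_likelihood == pytest.approx(n * np.log(0.25), abs=1e-6)
    assert table.converged
    # a boundary maximum (two complementary haplotypes at 1/2) attains
    # P(G) = 1/2; restarts may find it, and can never do worse
    restarted = em_haplotype_frequencies(gm, seed=1, n_restarts=5)
    assert restarted.log_likelihood >= table.log_likelihood - 1e-9
    assert restarted.log_likelihood <= n * np.log(0.5) + 1e-9


# ---------------------------------------------------------------------------
# expected dosages

def test_unambiguous_subject_integer_row(two_snv_variants):
    counts = np.array([[0, 2], [2, 0], [1, 0]])
    gm = make_genotypes(counts, two_snv_variants)
    table = em_haplotype_frequencies(gm)
    dos = expected_dosages(gm, table)
    assert np.allclose(dos.values, np.round(dos.values))
    assert np.allclose(dos.values.sum(axis=1), 2.0)


def test_double_het_dosage_matches_enumeration_oracle(two_snv_variants):
    """Double heterozygote under fixed frequencies: posterior over the two
    diplotypes from brute-force enumerate-and-normalize."""
    f = {"ab": 0.4, "AB": 0.4, "aB": 0.1, "Ab": 0.1}
    table = HaplotypeTable(
        labels=list(f), frequencies=np.array(list(f.values())),
        variants=two_snv_variants,
    )
    gm = make_genotypes(np.array([[1, 1]]), two_snv_variants)
    dos = expected_dosages(gm, table)
    # P(ab/AB) ∝ 2*0.4*0.4 ; P(aB/Ab) ∝ 2*0.1*0.1
    w1, w2 = 2 * 0.4 * 0.4, 2 * 0.1 * 0.1
    post1 = w1 / (w1 + w2)
    expected = {
        "ab": post1, "AB": post1,
        "aB": 1 - post1, "Ab": 1 - post1,
    }
    got = dict(zip(dos.labels, dos.values[0]))
    for lab, val in expected.items():
        assert got[lab] == pytest.approx(val, abs=1e-12)


def test_zero_support_subject_raises(two_snv_variants):
    table = HaplotypeTable(
        labels=["AB"], frequencies=np.array([1.0]), variants=two_snv_variants
    )
    gm = make_genotypes(np.array([[2, 2]]), two_snv_variants)
    with pytest.raises(ValueError, match="S1"):
        expected_dosages(gm, table)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_dosage_rows_always_sum_to_two(seed):
    rng = np.random.default_rng(seed)
    n, q = int(rng.integers(2, 25)), int(rng.integers(1, 5))
    counts = rng.integers(0, 3, size=(n, q))
    gm = make_genotypes(counts)
    table = em_haplotype_frequencies(gm, tol=1e-12)
    dos = expected_dosages(gm, table)
    assert np.allclose(dos.values.sum(axis=1), 2.0, atol=1e-8)
    assert (dos.values >= -1e-12).all() and (dos.values <= 2 + 1e-12).all()
    # frequency consistency at the (tightly converged) fixed point
    np.testing.assert_allclose(
        dos.values.mean(axis=0) / 2.0, table.frequencies, atol=1e-6
    )


# ---------------------------------------------------------------------------
# rare-haplotype collapsing

def _panel_dosages(gene, n=400, seed=0):
    panel = load_panel(gene)
    rng = np.random.default_rng(seed)
    hap = rng.choice(len(panel.frequencies), size=(n, 2), p=panel.frequencies)
    counts = panel.minor_counts[hap[:, 0]] + panel.minor_counts[hap[:, 1]]
    gm = make_genotypes(counts, panel.variants)
    table = HaplotypeTable(
        labels=list(panel.labels), frequencies=panel.frequencies.copy(),
        variants=panel.variants,
    )
    return expected_dosages(gm, table), table


def test_collapse_g6pc2_pools_the_four_rare_haplotypes():
    dos, table = _panel_dosages("G6PC2")
    cdos, ctable = collapse_rare(dos, table, 0.001)
    assert ctable.labels[-1] == RARE_LABEL
    assert len(ctable.labels) == 5  # 4 named + pool
    assert ctable.frequencies[-1] == pytest.approx(4 * 0.0009 / 0.9996)
    assert np.allclose(cdos.values.sum(axis=1), 2.0, atol=1e-8)


def test_collapse_jazf1_pools_only_haplotype_14():
    dos, table = _panel_dosages("JAZF1")
    cdos, ctable = collapse_rare(dos, table, 0.001)
    # only the 0.0005-frequency haplotype is below 0.1%: 13 named + pool
    assert len(ctable.labels) == 14
    assert ctable.labels[-1] == RARE_LABEL
    assert ctable.frequencies[-1] == pytest.approx(0.0005 / 0.9999)
    assert "GCGTA" not in ctable.labels


def test_collapse_threshold_zero_is_identity():
    dos, table = _panel_dosages("G6PC2")
    cdos, ctable = collapse_rare(dos, table, 0.0)
    assert ctable.labels == table.labels
    assert cdos is dos


def test_collapse_all_rare_errors(two_snv_variants):
    table = HaplotypeTable(
        labels=["AB", "ab"], frequencies=np.array([0.5, 0.5]),
        variants=two_snv_variants,
    )
    gm = make_genotypes(np.array([[0, 0]]), two_snv_variants)
    dos = expected_dosages(gm, table)
    with pytest.raises(ValueError, match="all haplotypes"):
        collapse_rare(dos, table, 0.9)


# ---------------------------------------------------------------------------
# I/O

def test_vcf_round_trip(tmp_path):
    panel = load_panel("G6PC2")
    rng = np.random.default_rng(3)
    hap = rng.choice(len(panel.frequencies), size=(25, 2), p=panel.frequencies)
    counts = panel.minor_counts[hap[:, 0]] + panel.minor_counts[hap[:, 1]]
    gm = make_genotypes(counts, panel.variants)
    path = tmp_path / "cohort.vcf"
    write_vcf(gm, path)
    back = read_vcf(path)
    assert back.subject_ids == gm.subject_ids
    assert [v.id for v in back.variants] == [v.id for v in gm.variants]
    np.testing.assert_array_equal(back.counts, gm.counts)


def test_haplotype_table_round_trip(tmp_path):
    panel = load_panel("JAZF1")
    table = HaplotypeTable(
        labels=list(panel.labels), frequencies=panel.frequencies.copy(),
        variants=panel.variants,
    )
    path = tmp_path / "haps.tsv"
    table.to_tsv(path)
    back = HaplotypeTable.from_tsv(path, panel.variants)
    assert back.labels == table.labels
    np.testing.assert_allclose(back.frequencies, table.frequencies)
    assert [_label_to_code(l, panel.variants) for l in back.labels] == [
        _label_to_code(l, panel.variants) for l in table.labels
    ]
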