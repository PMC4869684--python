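import numpy as np
import pytest

from haplometa import (
    EffectScenario,
    calibrate_effects,
    compute_relationship,
    drop_genes,
    generate_pedigrees,
    assign_ages,
    load_panel,
    simulate_cohort,
    simulate_phenotype,
    study_design,
)
from haplometa.simulate import (
    DESIGN_IDS,
    CohortStructure,
    build_structure,
    family_phi_block,
)

from conftest import kinship_oracle


# ---------------------------------------------------------------------------
# panels

def test_panel_frequencies_normalized_and_consistent():
    for gene, n_haps, q in (("G6PC2", 8, 4), ("JAZF1", 14, 5)):
        panel = load_panel(gene)
        assert len(panel.labels) == n_haps
        assert panel.n_variants == q
        assert panel.frequencies.sum() == pytest.approx(1.0)
        maf = panel.minor_allele_freqs()
        assert ((maf > 0) & (maf < 1)).all()


def test_g6pc2_panel_top_frequencies():
    panel = load_panel("G6PC2")
    top = dict(zip(panel.labels, panel.frequencies))
    assert top["CCAC"] == pytest.approx(0.46, abs=0.001)
    assert top["TCAG"] == pytest.approx(0.29, abs=0.001)
    assert top["CCAG"] == pytest.approx(0.24, abs=0.001)


# ---------------------------------------------------------------------------
# study designs and pedigrees

def test_design_registry_shapes():
    assert DESIGN_IDS == tuple(range(1, 11))
    assert study_design(1).n_cohorts == 5
    assert study_design(6).n_cohorts == 10
    assert study_design(7).n_cohorts == 10
    assert study_design(9).n_cohorts == 5
    with pytest.raises(KeyError):
        study_design(11)


def test_design1_cohort_has_1000_individuals():
    peds = generate_pedigrees(study_design(1), seed=0)
    assert len(peds) == 5
    assert all(len(p) == 1000 for p in peds)  # 250 families x 4


def test_unrelated_cohort_is_singleton_founders():
    (ped,) = generate_pedigrees(
        study_design(3), seed=0
    )[2:3]  # 400 U cohort
    assert len(ped) == 400
    assert all(r.father is None for r in ped.records)


def test_nfv_offspring_mean():
    rng = np.random.default_rng(1)
    struct = build_structure([("NFv", 10_000)], rng)
    mean = struct.n_offspring.mean()
    se = np.sqrt(np.var([1, 2, 3, 4]) / 10_000)
    assert abs(mean - 2.5) <= 3 * se


def test_structure_phi_matches_pedigree_kinship():
    """The per-family eigen blocks must agree with the recursive kinship
    algorithm applied to the exported pedigree."""
    struct = CohortStructure(np.array([2, 3, -1, 1]))
    sexes = np.ones(struct.n, dtype=np.int8)
    ped = struct.to_pedigree(sexes)
    dense = compute_relationship(ped).values
    np.testing.assert_allclose(dense, kinship_oracle(ped), atol=1e-12)
    pos = 0
    for k in struct.n_offspring:
        s = 1 if k < 0 else k + 2
        block = np.eye(1) if k < 0 else family_phi_block(k)
        np.testing.assert_allclose(dense[pos:pos + s, pos:pos + s], block)
        pos += s


# ---------------------------------------------------------------------------
# ages

def test_age_constraints_hold_for_every_family():
    rng = np.random.default_rng(7)
    for _ in range(20):
        struct = build_structure([("NFv", 200), ("U", 50)], rng)
        sim_ages = _ages(struct, rng)
        starts, n_off = struct.unit_starts, struct.n_offspring
        for start, k in zip(starts, n_off):
            if k < 0:
                assert 30 <= sim_ages[start] <= 50
                continue
            father, mother = sim_ages[start], sim_ages[start + 1]
            kids = sim_ages[start + 2:start + 2 + k]
            first, oldest = kids[0], kids.max()
            assert 30 <= first <= 50
            # siblings: within 5 years of the first, pairwise gap >= 1
            assert (np.abs(kids - first) <= 5 + 1e-9).all()
            for i in range(k):
                for j in range(i + 1, k):
                    assert abs(kids[i] - kids[j]) >= 1 - 1e-9
            assert 20 - 1e-9 <= mother - oldest <= 45 + 1e-9
            assert abs(father - mother) <= 5 + 1e-9
            assert father - oldest >= 20 - 1e-9


def _ages(struct, rng):
    from haplometa.simulate import _assign_ages_structure

    return _assign_ages_structure(struct, rng)


def test_first_offspring_age_mean():
    rng = np.random.default_rng(9)
    struct = build_structure([("U", 100_000)], rng)
    ages = _ages(struct, rng)
    se = np.sqrt((20**2 / 12) / 100_000)
    assert abs(ages.mean() - 40.0) <= 3 * se


def test_assign_ages_public_wrapper():
    ped = generate_pedigrees(study_design(1), seed=5)[0]
    ages = assign_ages(ped, seed=1)
    assert len(ages) == len(ped)
    assert np.isfinite(ages).all()


# ---------------------------------------------------------------------------
# gene dropping

def test_single_haplotype_panel_everyone_homozygous(two_snv_variants):
    from haplometa.simulate import ReferencePanel

    panel = ReferencePanel("toy", two_snv_variants, ["ab"], np.array([1.0]))
    ped = generate_pedigrees(study_design(1), seed=2)[0]
    phased, gm = drop_genes(panel, ped, seed=3)
    assert all(pair == ("ab", "ab") for pair in phased)
    assert (gm.counts == 2).all()


def test_founder_haplotype_frequencies_match_panel():
    panel = load_panel("G6PC2")
    rng = np.random.default_rng(11)
    struct = build_structure([("U", 50_000)], rng)
    from haplometa.simulate import _drop_genes_structure

    hap, _ = _drop_genes_structure(panel, struct, rng)
    freq = np.mean(hap == panel.labels.index("CCAC"))
    f = panel.hap_frequency("CCAC")
    se = np.sqrt(f * (1 - f) / 100_000)
    assert abs(freq - f) <= 3 * se


def test_offspring_haplotypes_are_mendelian():
    panel = load_panel("JAZF1")
    ped = generate_pedigrees(study_design(1), seed=4)[0]
    phased, gm = drop_genes(panel, ped, seed=5)
    by_id = dict(zip([r.individual for r in ped.records], phased))
    for r in ped.records:
        if r.father is None:
            continue
        kid = by_id[r.individual]
        dad, mom = by_id[r.father], by_id[r.mother]
        assert kid[0] in dad and kid[1] in mom
    # genotype = allele count of the two true haplotypes
    codes = {lab: i for i, lab in enumerate(panel.labels)}
    counts = np.array([
        panel.minor_counts[codes[a]] + panel.minor_counts[codes[b]]
        for a, b in phased
    ])
    np.testing.assert_array_equal(counts, gm.counts)


# ---------------------------------------------------------------------------
# effect calibration

def test_effect_size_closed_forms():
    from haplometa.em import Variant
    from haplometa.simulate import ReferencePanel

    v = [Variant("v1", "1", 1, "a", "A")]
    panel = ReferencePanel("toy", v, ["a", "A"], np.array([0.5, 0.5]))
    eff = calibrate_effects(EffectScenario("1SNV", causal_snvs=("v1",), r2=0.01), panel)
    assert eff["v1"] == pytest.approx(2 * 0.1)  # doubled lone effect
    scen_h = EffectScenario("1HAP", causal_haps=("a",), r2=0.01)
    eff_h = calibrate_effects(scen_h, panel)
    assert eff_h["a"] == pytest.approx(2 * 0.1)


def test_gtata_effect_arithmetic_oracle():
    panel = load_panel("JAZF1")
    scen = EffectScenario.for_gene("2HAP", "JAZF1")
    eff = calibrate_effects(scen, panel)
    f = panel.hap_frequency("GTATA")
    hbar = 2 * f
    assert eff["GTATA"] == pytest.approx(np.sqrt(0.01 / (2 * hbar * (1 - hbar / 2))))
    assert f == pytest.approx(0.2327 / 0.9999)


# ---------------------------------------------------------------------------
# phenotypes

def test_null_unrelated_trait_moments():
    rng = np.random.default_rng(13)
    sim = simulate_cohort([("U", 40_000)], load_panel("G6PC2"), None, rng)
    resid = sim.trait - 0.02 * sim.ages - 0.5 * sim.sexes
    assert abs(resid.mean()) <= 3 * np.sqrt(1.0 / 40_000)
    assert abs(resid.var() - 1.0) <= 3 * np.sqrt(2.0 / 40_000)


def test_sibling_trait_covariance():
    """Across 10,000 NF2 families, sib-sib residual covariance should match
    sigma_a2 * Phi_sib = 0.5 * 0.5 = 0.25."""
    rng = np.random.default_rng(15)
    sim = simulate_cohort([("NF2", 10_000)], load_panel("G6PC2"), None, rng)
    resid = sim.trait - 0.02 * sim.ages - 0.5 * sim.sexes
    sib1 = resid[2::4]
    sib2 = resid[3::4]
    cov = np.cov(sib1, sib2)[0, 1]
    assert cov == pytest.approx(0.25, abs=3 * 1.25 / np.sqrt(10_000))
    par = resid[0::4]
    assert np.cov(par, sib1)[0, 1] == pytest.approx(0.25, abs=3 * 1.25 / np.sqrt(10_000))


def test_phenotype_public_wrapper_matches_moments():
    ped = generate_pedigrees(study_design(1), seed=21)[0]
    ages = assign_ages(ped, seed=22)
    sexes = np.array([r.sex for r in ped.records], dtype=float)
    y = simulate_phenotype(ped, ages, sexes, np.zeros(len(ped)), seed=23)
    resid = y - 0.02 * ages - 0.5 * sexes
    assert abs(resid.var() - 1.0) < 0.15


def test_causal_haplotype_shifts_trait():
    rng = np.random.default_rng(17)
    scen = EffectScenario.for_gene("1HAP", "G6PC2")
    panel = load_panel("G6PC2")
    sim = simulate_cohort([("U", 30_000)], panel, scen, rng)
    eff = calibrate_effects(scen, panel)["CCAC"]
    idx = panel.labels.index("CCAC")
    dosage = (sim.hap_indices == idx).sum(axis=1)
    resid = sim.trait - 0.02 * sim.ages - 0.5 * sim.sexes
    slope = np.polyfit(dosage, resid, 1)[0]
    assert slope == pytest.approx(eff, abs=0.02)
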