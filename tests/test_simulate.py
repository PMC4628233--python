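import numpy as np
import pytest

from strpopgen import (DiseaseModel, FrequencyTable, SimulationConfig,
                       assign_phenotypes, drop_genes, simulate_cohort,
                       simulate_pedigree)


def test_seed_reproducibility_byte_identical():
    cfg = SimulationConfig(seed=13, n_founders=30, n_generations=2, pop_size=50)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    assert a.genotypes == b.genotypes
    assert a.metadata.equals(b.metadata)
    assert a.true_diplotypes == b.true_diplotypes
    assert [r for r in a.pedigree.records.values()] == \
        [r for r in b.pedigree.records.values()]


def test_zero_generations_founders_only():
    cfg = SimulationConfig(seed=1, n_founders=25, n_generations=0)
    ped = simulate_pedigree(cfg)
    assert len(ped) == 25
    assert all(ped.parents(i) == (None, None) for i in ped.individuals)


def test_zero_pop_size_rejected():
    with pytest.raises(ValueError):
        simulate_pedigree(SimulationConfig(seed=1, n_founders=10,
                                           n_generations=1, pop_size=0))


def test_uniform_sire_use_at_zero_concentration():
    """With concentration 0 the busiest of ~50 sires stays within
    binomial expectation of the 1/50 share."""
    cfg = SimulationConfig(seed=2, n_founders=100, n_generations=1,
                           pop_size=1000, sire_concentration=0.0,
                           litter_size=1.0)
    ped = simulate_pedigree(cfg)
    counts: dict[str, int] = {}
    n_off = 0
    for rec in ped.records.values():
        if rec.sire is not None:
            counts[rec.sire] = counts.get(rec.sire, 0) + 1
            n_off += 1
    n_sires = sum(1 for i, r in ped.records.items()
                  if r.sire is None and r.sex == "M")
    p = 1 / n_sires
    se = np.sqrt(n_off * p * (1 - p))
    assert max(counts.values()) <= n_off * p + 3 * se + 3 * np.sqrt(n_off * p)


def test_concentration_increases_top_sire_share():
    shares = {0.0: [], 5.0: []}
    for conc in shares:
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_founders=40, n_generations=1,
                                   pop_size=200, sire_concentration=conc)
            ped = simulate_pedigree(cfg)
            counts: dict[str, int] = {}
            for rec in ped.records.values():
                if rec.sire is not None:
                    counts[rec.sire] = counts.get(rec.sire, 0) + 1
            shares[conc].append(max(counts.values()) / 200)
    assert np.mean(shares[5.0]) > np.mean(shares[0.0])


def test_allele_frequency_conserved_one_generation():
    from strpopgen import allele_frequencies
    ft = FrequencyTable({"L1": {100: 0.5, 102: 0.5}})
    cfg = SimulationConfig(seed=4, n_founders=2000, n_generations=1,
                           pop_size=5000, founder_freqs=ft)
    cohort = drop_genes(simulate_pedigree(cfg), cfg)
    kids = [i for i in cohort.genotypes.individuals if i.startswith("G1")]
    est = allele_frequencies(cohort.genotypes.subset(individuals=kids))
    assert est.freqs["L1"][100] == pytest.approx(0.5, abs=0.02)


def test_no_recombination_preserves_founder_pairings():
    pairings = [((1, 1, 1, 1), (5, 5, 5), 0.5), ((2, 2, 2, 2), (6, 6, 6), 0.5)]
    cfg = SimulationConfig(seed=6, n_founders=50, n_generations=3,
                           pop_size=100, interblock_recombination=0.0,
                           dla_founder_haplotypes=pairings)
    cohort = drop_genes(simulate_pedigree(cfg), cfg)
    declared = {(p[0], p[1]) for p in pairings}
    for haps in cohort.true_diplotypes.values():
        for h in haps:
            assert h in declared


def test_recombination_creates_new_pairings():
    pairings = [((1, 1, 1, 1), (5, 5, 5), 0.5), ((2, 2, 2, 2), (6, 6, 6), 0.5)]
    cfg = SimulationConfig(seed=6, n_founders=50, n_generations=3,
                           pop_size=300, interblock_recombination=0.5,
                           dla_founder_haplotypes=pairings)
    cohort = drop_genes(simulate_pedigree(cfg), cfg)
    seen = {h for haps in cohort.true_diplotypes.values() for h in haps}
    assert ((1, 1, 1, 1), (6, 6, 6)) in seen


def test_case_fraction_matches_intercept():
    cfg = SimulationConfig(
        seed=8, n_founders=5000, n_generations=0,
        disease=DiseaseModel(b0=np.log(0.3 / 0.7), b_hap_i=0.0,
                             b_hap_ii=0.0, b_genome=0.0, b_sex=0.0))
    cohort = simulate_cohort(cfg)
    frac = (cohort.metadata["status"] == "case").mean()
    assert frac == pytest.approx(0.3, abs=0.02)


def test_female_bias_under_sex_effect():
    ratios = []
    for seed in range(20):
        cfg = SimulationConfig(
            seed=seed, n_founders=400, n_generations=0,
            disease=DiseaseModel(b0=-1.0, b_hap_i=0.0, b_hap_ii=0.0,
                                 b_genome=0.0, b_sex=np.log(2.0)))
        cohort = simulate_cohort(cfg)
        meta = cohort.metadata
        cases = meta[meta["status"] == "case"]
        m = (cases["sex"] == "M").sum()
        ratios.append((cases["sex"] == "F").sum() / max(m, 1))
    assert np.mean(ratios) > 1.0


def test_mean_ir_rises_with_sire_concentration():
    """Popular-sire breeding inflates mean internal relatedness of later
    generations when scored against founder-population frequencies
    (averaged over seeds).

    Scored against the cohort's own frequencies IR is self-centering, so
    the accumulating inbreeding only shows against the base population.
    """
    from strpopgen import allele_frequencies, internal_relatedness
    means = {0.0: [], 4.0: []}
    for conc in means:
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, n_founders=30,
                                   n_generations=3, pop_size=60,
                                   sire_concentration=conc)
            cohort = drop_genes(simulate_pedigree(cfg), cfg)
            genomic = cohort.genotypes.loci_of_class("genomic")
            founders = [i for i in cohort.genotypes.individuals
                        if i.startswith("G0")]
            base = allele_frequencies(cohort.genotypes.subset(
                individuals=founders, loci=genomic))
            kids = [i for i in cohort.genotypes.individuals
                    if i.startswith("G3")]
            res = internal_relatedness(
                cohort.genotypes.subset(individuals=kids, loci=genomic),
                freqs=base)
            means[conc].append(np.mean([r.ir for r in res]))
    assert np.mean(means[4.0]) > np.mean(means[0.0])


def test_config_yaml_roundtrip(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text(
        "seed: 5\nn_founders: 12\nn_generations: 1\npop_size: 20\n"
        "sire_concentration: 2.0\ndisease:\n  b0: -1.5\n  b_sex: 0.0\n")
    cfg = SimulationConfig.from_yaml(p)
    assert cfg.seed == 5 and cfg.n_founders == 12
    assert cfg.disease.b0 == -1.5 and cfg.disease.b_sex == 0.0
    simulate_cohort(cfg)  # runs end to end
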