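import itertools

import numpy as np
import pytest

from strpopgen import (DLA_CLASS_I, DLA_CLASS_II, em_phase, name_haplotypes,
                       extended_linkage_correct, haplotype_frequency_table,
                       nonzero_haplotype_count, cumulative_share, datasets)
from strpopgen.dla import _compatible_pairs, _em
from strpopgen.io import DLA_I_LOCI, DLA_II_LOCI
from conftest import make_table
from oracles import ml_haplotype_loglik

I_CLASSES = {l: DLA_CLASS_I for l in DLA_I_LOCI}


def test_compatible_pairs_enumeration():
    # two het loci -> two phase configurations
    pairs = _compatible_pairs([(1, 2), (3, 4)])
    assert pairs == [((1, 3), (2, 4)), ((1, 4), (2, 3))]
    # homozygous everywhere -> single pair
    assert _compatible_pairs([(1, 1), (3, 3)]) == [((1, 3), (1, 3))]


def test_homozygote_has_posterior_one():
    gt = make_table(
        {"i1": [(386, 386), (373, 373), (289, 289), (182, 182)],
         "i2": [(380, 386), (371, 373), (277, 289), (182, 186)]},
        DLA_I_LOCI, I_CLASSES)
    _, dip = em_phase(gt, DLA_CLASS_I)
    assert dip.assignments["i1"].posterior == pytest.approx(1.0)
    assert dip.assignments["i1"].homozygous


def test_anchored_phase_beats_alternative():
    """Double heterozygotes plus one homozygote anchoring the phase: EM
    must put its mass on the anchored haplotypes, matching the direct
    likelihood-maximization oracle."""
    rows = {f"h{k}": [(1, 2), (3, 4)] for k in range(4)}
    rows["anchor"] = [(1, 1), (3, 3)]
    gt = make_table(rows, ["A", "B"],
                    {"A": DLA_CLASS_I, "B": DLA_CLASS_I})
    cat, dip = em_phase(gt, DLA_CLASS_I, loci=["A", "B"])
    assert cat.frequencies[(1, 3)] > cat.frequencies.get((1, 4), 0.0)
    assert dip.assignments["h0"].pair == ((1, 3), (2, 4))
    # cross-check achieved likelihood against scipy optimization
    pls = [_compatible_pairs(r) for r in rows.values()]
    ll_oracle, _ = ml_haplotype_loglik(pls)
    assert cat.log_likelihood == pytest.approx(ll_oracle, abs=1e-5)


def test_em_matches_ml_oracle_on_small_instances():
    """EM attains the maximum likelihood found by direct optimization on
    a batch of random <=5-individual, <=3-locus, <=3-allele instances."""
    rng = np.random.default_rng(0)
    for trial in range(12):
        n_ind = int(rng.integers(2, 6))
        n_loc = int(rng.integers(1, 4))
        rows = {}
        for i in range(n_ind):
            rows[f"i{i}"] = [tuple(sorted(rng.integers(1, 4, size=2)))
                             for _ in range(n_loc)]
        loci = [f"L{j}" for j in range(n_loc)]
        gt = make_table(rows, loci, {l: DLA_CLASS_I for l in loci})
        cat, _ = em_phase(gt, DLA_CLASS_I, loci=loci, seed=trial)
        ll_oracle, _ = ml_haplotype_loglik(
            [_compatible_pairs(r) for r in rows.values()], seed=trial)
        assert cat.log_likelihood >= ll_oracle - 1e-4, \
            f"trial {trial}: EM {cat.log_likelihood} < oracle {ll_oracle}"


def test_excluded_individuals_logged():
    gt = make_table(
        {"ok": [(386, 386), (373, 373), (289, 289), (182, 182)],
         "gap": [(386, 386), (0, 0), (289, 289), (182, 182)]},
        DLA_I_LOCI, I_CLASSES)
    _, dip = em_phase(gt, DLA_CLASS_I)
    assert dip.excluded == ["gap"]
    assert "gap" not in dip.assignments


def test_simulator_truth_recovered_without_recombination():
    """With zero interblock recombination and tightly linked loci, best
    pairs match the simulated true haplotypes for >=99% of individuals."""
    from strpopgen import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(seed=3, n_founders=120, n_generations=2,
                           pop_size=250, interblock_recombination=0.0)
    cohort = simulate_cohort(cfg)
    gt = cohort.genotypes
    cat_i, dip_i = em_phase(gt, DLA_CLASS_I, seed=1)
    hits = total = 0
    for ind, d in dip_i.assignments.items():
        true_pair = tuple(sorted([cohort.true_diplotypes[ind][0][0],
                                  cohort.true_diplotypes[ind][1][0]]))
        hits += d.pair == true_pair
        total += 1
    assert hits / total >= 0.99


def test_name_haplotypes_known_and_novel():
    lookup = datasets.dla_haplotype_lookup()
    gt = make_table(
        {"i1": [(386, 386), (373, 373), (289, 289), (182, 182)],
         "i2": [(111, 111), (222, 222), (333, 333), (444, 444)]},
        DLA_I_LOCI, I_CLASSES)
    cat, _ = em_phase(gt, DLA_CLASS_I)
    name_haplotypes(cat, lookup)
    assert cat.names[(386, 373, 289, 182)] == "1008"
    assert cat.names[(111, 222, 333, 444)] == "novel-I-1"


def test_class_ii_lookup_names():
    lookup = datasets.dla_haplotype_lookup()
    assert lookup.name(DLA_CLASS_II, (343, 322, 280)) == "2017"


def test_extended_correction_restores_founder_pairing():
    """Strict linkage: haplotypes A1-B1 and A2-B2 only.  An individual
    het at both regions is ambiguous region-by-region, but the joint EM
    must pick the founder pairings."""
    loci = list(DLA_I_LOCI) + list(DLA_II_LOCI)
    classes = {**I_CLASSES, **{l: DLA_CLASS_II for l in DLA_II_LOCI}}
    h = {
        "A1": (1, 1, 1, 1), "A2": (2, 2, 2, 2),
        "B1": (5, 5, 5), "B2": (6, 6, 6),
    }
    def dog(p1, p2):
        return [tuple(sorted(x)) for x in zip(h[p1[0]] + h[p1[1]],
                                              h[p2[0]] + h[p2[1]])]
    rows = {
        "hom1": dog(("A1", "B1"), ("A1", "B1")),
        "hom2": dog(("A2", "B2"), ("A2", "B2")),
        "het1": dog(("A1", "B1"), ("A2", "B2")),
        "het2": dog(("A1", "B1"), ("A2", "B2")),
        "het3": dog(("A1", "B1"), ("A2", "B2")),
    }
    gt = make_table(rows, loci, classes)
    cat_i, dip_i = em_phase(gt, DLA_CLASS_I)
    cat_ii, dip_ii = em_phase(gt, DLA_CLASS_II)
    ext, c_i, c_ii = extended_linkage_correct(dip_i, dip_ii, gt,
                                              cat_i, cat_ii)
    observed = {k for k, f in ext.frequencies.items() if f > 0.01}
    assert observed == {(h["A1"], h["B1"]), (h["A2"], h["B2"])}
    assert c_i.assignments["het1"].pair == ((1, 1, 1, 1), (2, 2, 2, 2))


def test_extended_support_bounded_by_founder_pairings():
    from strpopgen import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(seed=9, n_founders=100, n_generations=2,
                           pop_size=200, interblock_recombination=0.0)
    cohort = simulate_cohort(cfg)
    gt = cohort.genotypes
    cat_i, dip_i = em_phase(gt, DLA_CLASS_I, seed=2)
    cat_ii, dip_ii = em_phase(gt, DLA_CLASS_II, seed=2)
    ext, _, _ = extended_linkage_correct(dip_i, dip_ii, gt, cat_i, cat_ii)
    truth_pairs = {(d[0], d[1]) for dd in cohort.true_diplotypes.values()
                   for d in dd}
    strong = {k for k, f in ext.frequencies.items() if f > 0.005}
    assert strong <= truth_pairs


def test_frequency_table_sums_and_shares():
    gt = make_table(
        {"i1": [(386, 386), (373, 373), (289, 289), (182, 182)],
         "i2": [(380, 386), (371, 373), (277, 289), (182, 186)],
         "i3": [(380, 380), (371, 371), (277, 277), (186, 186)]},
        DLA_I_LOCI, I_CLASSES)
    cat, dip = em_phase(gt, DLA_CLASS_I)
    tab = haplotype_frequency_table(dip)
    assert tab["freq_all"].sum() == pytest.approx(1.0)
    assert tab["count_all"].sum() == 6  # 2 chromosomes x 3 dogs
    with pytest.raises(ValueError, match="no phased"):
        haplotype_frequency_table(dip, groups={"empty": []})


def test_published_catalog_counts_and_shares():
    """The bundled class I/II catalogs reproduce the published nonzero
    haplotype counts and dominant-haplotype cumulative shares."""
    c1 = datasets.dla_class_i_catalog().set_index("name")
    c2 = datasets.dla_class_ii_catalog().set_index("name")
    assert nonzero_haplotype_count(c1["freq_eu"]) == 14
    assert nonzero_haplotype_count(c1["freq_usa"]) == 15
    assert nonzero_haplotype_count(c2["freq_usa"]) == 14
    assert nonzero_haplotype_count(c2["freq_eu"]) == 12
    usa_top4 = cumulative_share(c1["freq_usa"], ["1008", "1044", "1052", "1053"])
    assert usa_top4 == pytest.approx(0.72, abs=0.005)
    usa_six = cumulative_share(
        c2["freq_usa"], ["2017", "2029", "2032", "2034", "2035", "2036"])
    assert usa_six == pytest.approx(0.83, abs=0.005)
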