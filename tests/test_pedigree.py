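import numpy as np
import pytest

from strpopgen import (Pedigree, PedigreeRecord, ancestor_contribution,
                       ancestor_homozygous_contribution,
                       ancestor_homozygous_contribution_exact,
                       ancestor_occurrence_scan, cohort_pedigree_contrast,
                       inbreeding_coefficient, inbreeding_coefficients)
from oracles import (enumerate_homozygous_contribution,
                     path_counting_inbreeding)


def half_sib_pedigree():
    return Pedigree([
        PedigreeRecord("A", None, None, "M"),
        PedigreeRecord("B", None, None, "F"),
        PedigreeRecord("C", None, None, "F"),
        PedigreeRecord("P1", "A", "B", "M"),
        PedigreeRecord("P2", "A", "C", "F"),
        PedigreeRecord("x", "P1", "P2", "F"),
    ])


def first_cousin_pedigree():
    return Pedigree([
        PedigreeRecord("G1", None, None, "M"),
        PedigreeRecord("G2", None, None, "F"),
        PedigreeRecord("S1", "G1", "G2", "M"),
        PedigreeRecord("S2", "G1", "G2", "F"),
        PedigreeRecord("E1", None, None, "F"),
        PedigreeRecord("E2", None, None, "M"),
        PedigreeRecord("P1", "S1", "E1", "M"),
        PedigreeRecord("P2", "E2", "S2", "F"),
        PedigreeRecord("x", "P1", "P2", "F"),
    ])


def test_textbook_inbreeding_values(full_sib_pedigree):
    assert inbreeding_coefficient(full_sib_pedigree, "x") == pytest.approx(0.25)
    assert inbreeding_coefficient(half_sib_pedigree(), "x") == pytest.approx(0.125)
    assert inbreeding_coefficient(first_cousin_pedigree(), "x") == \
        pytest.approx(0.0625)
    assert inbreeding_coefficient(full_sib_pedigree, "GS") == 0.0


@pytest.mark.parametrize("builder", [half_sib_pedigree, first_cousin_pedigree])
def test_recursive_coi_matches_path_counting(builder):
    ped = builder()
    for ind in ped.individuals:
        assert inbreeding_coefficient(ped, ind) == \
            pytest.approx(path_counting_inbreeding(ped, ind))


def test_path_counting_on_compound_pedigree():
    """A pedigree with an inbred common ancestor exercises the (1+F_A)
    factor in both routes."""
    ped = Pedigree([
        PedigreeRecord("F1", None, None), PedigreeRecord("F2", None, None),
        PedigreeRecord("A", "F1", "F2"), PedigreeRecord("B", "F1", "F2"),
        PedigreeRecord("C", "A", "B"),       # inbred: F = 0.25
        PedigreeRecord("D", None, None),
        PedigreeRecord("P1", "C", "D"), PedigreeRecord("P2", "C", "D"),
        PedigreeRecord("x", "P1", "P2"),
    ])
    assert inbreeding_coefficient(ped, "x") == \
        pytest.approx(path_counting_inbreeding(ped, "x"))


def test_depth_cap_truncates_ancestry():
    ped = first_cousin_pedigree()
    # the shared grandparents sit 3 generations above x
    assert inbreeding_coefficient(ped, "x", depth_cap=2) == 0.0
    assert inbreeding_coefficient(ped, "x", depth_cap=3) == pytest.approx(0.0625)


def test_ancestor_contribution_basics(full_sib_pedigree):
    ped = full_sib_pedigree
    assert ancestor_contribution(ped, "x", "S1") == pytest.approx(50.0)
    # grandsire through both parents: 25 + 25
    assert ancestor_contribution(ped, "x", "GS") == pytest.approx(50.0)
    assert ancestor_contribution(ped, "x", "x") == 100.0
    unrelated = Pedigree(list(ped.records.values())
                         + [PedigreeRecord("Z", None, None)])
    assert ancestor_contribution(unrelated, "x", "Z") == 0.0


def test_founder_contributions_sum_to_hundred(small_cohort):
    _, cohort = small_cohort
    ped = cohort.pedigree
    founders = ped.founders()
    ind = [i for i in ped.individuals if i.startswith("G3")][0]
    total = sum(ancestor_contribution(ped, ind, f) for f in founders)
    assert total == pytest.approx(100.0)


def test_homozygous_contribution_great_grandsire_sixteenth():
    """A great-grandsire reached via both parental lines: both of x's
    alleles descend through him with probability (1/4)^2 = 6.25%."""
    ped = Pedigree([
        PedigreeRecord("A", None, None, "M"),
        PedigreeRecord("Dm", None, None, "F"),
        PedigreeRecord("S1", "A", "Dm", "M"),
        PedigreeRecord("S2", "A", "Dm", "M"),
        PedigreeRecord("E1", None, None, "F"),
        PedigreeRecord("E2", None, None, "F"),
        PedigreeRecord("P1", "S1", "E1", "M"),
        PedigreeRecord("P2", "S2", "E2", "F"),
        PedigreeRecord("x", "P1", "P2", "F"),
    ])
    exact = ancestor_homozygous_contribution_exact(ped, "x", "A")
    assert exact == pytest.approx(6.25)
    assert enumerate_homozygous_contribution(ped, "x", "A") == \
        pytest.approx(exact)


@pytest.mark.parametrize("individual,ancestor,expected", [
    ("x", "x", 100.0),
    ("x", "GS", 25.0),   # grandsire on both sides: (1/2)^2
])
def test_homozygous_contribution_exact_values(full_sib_pedigree,
                                              individual, ancestor, expected):
    exact = ancestor_homozygous_contribution_exact(
        full_sib_pedigree, individual, ancestor)
    assert exact == pytest.approx(expected)


def test_gene_dropping_converges_to_enumeration(full_sib_pedigree):
    ped = full_sib_pedigree
    exact = enumerate_homozygous_contribution(ped, "x", "GS")
    est, se = ancestor_homozygous_contribution(ped, "x", "GS",
                                               reps=20000, seed=2)
    assert abs(est - exact) <= 3 * se
    assert ancestor_homozygous_contribution_exact(ped, "x", "GS") == \
        pytest.approx(exact)


def test_homozygous_bounded_by_contribution(small_cohort):
    _, cohort = small_cohort
    ped = cohort.pedigree
    founders = ped.founders()
    ind = [i for i in ped.individuals if i.startswith("G3")][0]
    anc = founders[0]
    hom, se = ancestor_homozygous_contribution(ped, ind, anc,
                                               reps=5000, seed=1)
    assert hom <= ancestor_contribution(ped, ind, anc) + 3 * se + 1e-9


def test_unrelated_ancestor_zero(full_sib_pedigree):
    ped = Pedigree(list(full_sib_pedigree.records.values())
                   + [PedigreeRecord("Z", None, None)])
    est, _ = ancestor_homozygous_contribution(ped, "x", "Z",
                                              reps=2000, seed=3)
    assert est == 0.0


def test_occurrence_scan_counts_positions(full_sib_pedigree):
    ped = full_sib_pedigree
    counts, pct = ancestor_occurrence_scan(ped, ["x"], "GS", generations=10)
    assert counts["x"] == 2  # paternal and maternal grandsire positions
    assert pct == 100.0
    # parent within range
    counts, _ = ancestor_occurrence_scan(ped, ["x"], "S1", generations=10)
    assert counts["x"] == 1


def test_occurrence_cap_boundary(full_sib_pedigree):
    counts, pct = ancestor_occurrence_scan(full_sib_pedigree, ["x"], "GS",
                                           generations=1)
    assert counts["x"] == 0 and pct == 0.0
    counts, _ = ancestor_occurrence_scan(full_sib_pedigree, ["x"], "GS",
                                         generations=2)
    assert counts["x"] == 2


def test_popular_sire_penetration_rises_over_generations():
    """Under strong sire concentration the top founder sire's presence in
    10-generation pedigrees grows across generations."""
    from strpopgen import SimulationConfig, simulate_pedigree
    pcts = []
    for seed in (1, 2, 3):
        cfg = SimulationConfig(seed=seed, n_founders=40, n_generations=5,
                               pop_size=80, sire_concentration=4.0)
        ped = simulate_pedigree(cfg)
        sires = {}
        for rec in ped.records.values():
            if rec.sire and rec.sire.startswith("G0"):
                sires[rec.sire] = sires.get(rec.sire, 0) + 1
        top = max(sorted(sires), key=lambda s: sires[s])
        traj = []
        for g in range(1, 6):
            cohort = [i for i in ped.individuals if i.startswith(f"G{g}-")]
            _, pct = ancestor_occurrence_scan(ped, cohort, top, 10)
            traj.append(pct)
        pcts.append(traj)
    mean_traj = np.mean(pcts, axis=0)
    assert mean_traj[-1] > mean_traj[0]
    assert np.all(np.diff(mean_traj) >= -5.0)  # near-monotone rise


def test_cohort_contrast_simulated_cases_more_inbred():
    """Cases drawn from a genome-homozygosity liability are more inbred
    (higher COI) than controls when breeding concentrates kinship."""
    from strpopgen import DiseaseModel, SimulationConfig, simulate_cohort
    cfg = SimulationConfig(
        seed=31, n_founders=30, n_generations=4, pop_size=150,
        sire_concentration=3.0,
        disease=DiseaseModel(b0=-2.0, b_hap_i=0.0, b_hap_ii=0.0,
                             b_genome=8.0, b_sex=0.0))
    cohort = simulate_cohort(cfg)
    meta = cohort.metadata.set_index("id")
    last = [i for i in cohort.genotypes.individuals if i.startswith("G4-")]
    cases = [i for i in last if meta.at[i, "status"] == "case"]
    controls = [i for i in last if meta.at[i, "status"] == "control"]
    res = cohort_pedigree_contrast(cohort.pedigree, cases, controls,
                                   ancestor=cohort.pedigree.founders()[0],
                                   reps=1000, seed=1)
    assert res.case_means["coi_pct"] > res.control_means["coi_pct"]


def test_contrast_degenerate_singletons(full_sib_pedigree):
    res = cohort_pedigree_contrast(full_sib_pedigree, ["x"], ["S1"],
                                   ancestor="GS", reps=1000, seed=1)
    assert np.isnan(res.p_values["coi_pct"])
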