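"""Forward-time breeding simulator for a closed breed.

Emulates the statistical structure the analyses assume: a founder
bottleneck, discrete non-overlapping generations, a tunable popular-sire
effect concentrating paternity, 33 unlinked genomic STRs gene-dropped
Mendelian, a tightly linked DLA block transmitted as intact class I +
class II haplotype pairings with rare interblock recombination, and a
liability (logistic) disease whose log-odds rise with DLA and genome-wide
homozygosity and with female sex.  Disease is assigned post hoc from
realized genotypes; there is no selection during breeding.

All randomness flows through a single generator keyed by the config seed,
consumed in documented order (pedigree, then gene dropping, then
phenotypes), so identical seed + config reproduces the cohort exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import (DLA_I_LOCI, DLA_II_LOCI, DLA_CLASS_I, DLA_CLASS_II, GENOMIC,
                 FrequencyTable, GenotypeTable, Pedigree, PedigreeRecord)

#: default founder DLA pairings: catalog vectors with plausible extended
#: class I / class II linkages at roughly the USA cohort frequencies
DEFAULT_DLA_PAIRINGS: list[tuple[str, str, float]] = [
    ("1008", "2017", 0.21),
    ("1044", "2034", 0.21),
    ("1052", "2017", 0.19),
    ("1053", "2036", 0.11),
    ("1059", "2035", 0.09),
    ("1059", "2029", 0.05),
    ("1016", "2032", 0.06),
    ("1030", "2031", 0.03),
    ("1040", "2039", 0.04),
    ("1012", "2003", 0.01),
]


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


@dataclass
class DiseaseModel:
    """Logistic liability: log-odds = b0 + b_hap_i*hom(DLA-I)
    + b_hap_ii*hom(DLA-II) + b_genome*homozygous_fraction + b_sex*female."""

    b0: float = _logit(0.30)
    b_hap_i: float = float(np.log(2.0))
    b_hap_ii: float = float(np.log(2.5))
    b_genome: float = 2.0
    b_sex: float = float(np.log(2.0))


@dataclass
class SimulationConfig:
    seed: int
    n_founders: int = 100
    n_generations: int = 5
    pop_size: int = 200
    sire_concentration: float = 0.0
    litter_size: float = 4.0
    n_loci: int = 33
    alleles_per_locus: tuple[int, int] = (4, 8)
    dirichlet_concentration: float = 1.0
    founder_freqs: FrequencyTable | None = None
    dla_founder_haplotypes: list[tuple[tuple, tuple, float]] | None = None
    interblock_recombination: float = 0.01
    disease: DiseaseModel = field(default_factory=DiseaseModel)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.interblock_recombination <= 1:
            raise ValueError("interblock_recombination must be in [0, 1]")
        if self.dla_founder_haplotypes is not None:
            total = sum(f for _, _, f in self.dla_founder_haplotypes)
            if abs(total - 1.0) > 1e-6:
                raise ValueError("DLA pairing frequencies must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        disease = DiseaseModel(**raw.pop("disease", {}))
        if "alleles_per_locus" in raw:
            raw["alleles_per_locus"] = tuple(raw["alleles_per_locus"])
        return cls(disease=disease, **raw)


def default_dla_pairings() -> list[tuple[tuple, tuple, float]]:
    """The default founder pairings resolved to allele vectors via the
    bundled catalog data."""
    from .datasets import dla_class_i_catalog, dla_class_ii_catalog

    vec_i = {row["name"]: tuple(int(row[f"allele{k}"]) for k in range(1, 5))
             for _, row in dla_class_i_catalog().iterrows()}
    vec_ii = {row["name"]: tuple(int(row[f"allele{k}"]) for k in range(1, 4))
              for _, row in dla_class_ii_catalog().iterrows()}
    return [(vec_i[a], vec_ii[b], f) for a, b, f in DEFAULT_DLA_PAIRINGS]


@dataclass
class SimulatedCohort:
    pedigree: Pedigree
    genotypes: GenotypeTable
    metadata: pd.DataFrame | None
    founder_freqs: FrequencyTable
    true_diplotypes: dict[str, tuple[tuple, tuple]]  # id -> 2 extended haps
    covariates: pd.DataFrame | None = None  # hom fractions, liability


def simulate_pedigree(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> Pedigree:
    """Generational pedigree with a popular-sire knob.

    Each sire receives a heavy-tailed (log-normal) weight once; sires are
    drawn with probability proportional to weight**sire_concentration, so
    concentration 0 is uniform sire use and larger values concentrate
    paternity.  Dams are drawn per litter, with litter sizes around the
    configured mean.
    """
    if config.pop_size < 1 or config.n_founders < 1:
        raise ValueError("population sizes must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records: list[PedigreeRecord] = []
    current: list[tuple[str, str]] = []  # (id, sex)
    for i in range(config.n_founders):
        sex = "M" if rng.random() < 0.5 else "F"
        ind = f"G0-{i:05d}"
        records.append(PedigreeRecord(ind, None, None, sex, 0))
        current.append((ind, sex))
    for g in range(1, config.n_generations + 1):
        males = [i for i, s in current if s == "M"]
        females = [i for i, s in current if s == "F"]
        if not males or not females:
            raise ValueError(f"generation {g - 1} lacks one sex")
        weights = rng.lognormal(0.0, 1.0, size=len(males))
        w = weights ** config.sire_concentration
        w = w / w.sum()
        nxt: list[tuple[str, str]] = []
        born = 0
        while born < config.pop_size:
            sire = males[rng.choice(len(males), p=w)]
            dam = females[rng.integers(len(females))]
            litter = max(1, int(rng.poisson(config.litter_size)))
            litter = min(litter, config.pop_size - born)
            for _ in range(litter):
                sex = "M" if rng.random() < 0.5 else "F"
                ind = f"G{g}-{born:05d}"
                records.append(PedigreeRecord(ind, sire, dam, sex, g))
                nxt.append((ind, sex))
                born += 1
        current = nxt
    return Pedigree(records)


def _generate_founder_freqs(config: SimulationConfig,
                            rng: np.random.Generator) -> FrequencyTable:
    lo, hi = config.alleles_per_locus
    freqs: dict[str, dict[int, float]] = {}
    for j in range(config.n_loci):
        k = int(rng.integers(lo, hi + 1))
        # STR-like integer allele sizes on a dinucleotide ladder
        start = 100 + 2 * int(rng.integers(0, 50))
        sizes = [start + 2 * a for a in range(k)]
        p = rng.dirichlet(np.full(k, config.dirichlet_concentration))
        p = np.maximum(p, 1e-4)
        p = p / p.sum()
        freqs[f"L{j + 1:02d}"] = {s: float(x) for s, x in zip(sizes, p)}
    return FrequencyTable(freqs)


def drop_genes(pedigree: Pedigree, config: SimulationConfig,
               rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Gene-drop genomic STRs and the linked DLA block through a pedigree.

    Founders draw genomic alleles from the founder frequencies and two
    extended DLA haplotypes from the founder pairing distribution;
    children receive one random allele per parent per genomic locus, and
    per parent one extended haplotype, recombined between the class I and
    class II sub-blocks with the configured probability.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    founder_freqs = config.founder_freqs or _generate_founder_freqs(config, rng)
    pairings = config.dla_founder_haplotypes or default_dla_pairings()
    pair_p = np.array([f for _, _, f in pairings])
    pair_p = pair_p / pair_p.sum()

    genomic_loci = list(founder_freqs.freqs)
    loci = genomic_loci + list(DLA_I_LOCI) + list(DLA_II_LOCI)
    classes = {l: GENOMIC for l in genomic_loci}
    classes.update({l: DLA_CLASS_I for l in DLA_I_LOCI})
    classes.update({l: DLA_CLASS_II for l in DLA_II_LOCI})
    allele_arrays = {
        l: (np.array(list(founder_freqs.freqs[l])),
            np.array(list(founder_freqs.freqs[l].values())))
        for l in genomic_loci
    }

    from .pedigree import _topological_order
    order = _topological_order(pedigree)
    genomes: dict[str, np.ndarray] = {}           # (n_genomic, 2) allele sizes
    diplos: dict[str, tuple[tuple, tuple]] = {}    # two extended haplotypes

    ng = len(genomic_loci)
    for ind in order:
        sire, dam = pedigree.parents(ind)
        if sire is None and dam is None:
            g = np.empty((ng, 2), dtype=np.int64)
            for j, l in enumerate(genomic_loci):
                sizes, p = allele_arrays[l]
                g[j] = rng.choice(sizes, size=2, p=p)
            genomes[ind] = g
            k1, k2 = rng.choice(len(pairings), size=2, p=pair_p)
            diplos[ind] = ((tuple(pairings[k1][0]), tuple(pairings[k1][1])),
                           (tuple(pairings[k2][0]), tuple(pairings[k2][1])))
        else:
            g = np.empty((ng, 2), dtype=np.int64)
            for slot, parent in enumerate((sire, dam)):
                pg = genomes[parent]
                pick = rng.integers(0, 2, size=ng)
                g[:, slot] = pg[np.arange(ng), pick]
            genomes[ind] = g
            haps = []
            for parent in (sire, dam):
                h1, h2 = diplos[parent]
                keep, other = (h1, h2) if rng.random() < 0.5 else (h2, h1)
                if rng.random() < config.interblock_recombination:
                    haps.append((keep[0], other[1]))
                else:
                    haps.append(keep)
            diplos[ind] = (haps[0], haps[1])

    individuals = list(pedigree.individuals)
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    for i, ind in enumerate(individuals):
        calls[i, :ng, :] = genomes[ind]
        (i1, ii1), (i2, ii2) = diplos[ind]
        dla = np.array(list(zip(i1 + ii1, i2 + ii2)))
        calls[i, ng:, :] = dla
    genotypes = GenotypeTable(individuals, loci, calls, classes)
    return SimulatedCohort(pedigree, genotypes, None, founder_freqs,
                           {i: diplos[i] for i in individuals})


def assign_phenotypes(cohort: SimulatedCohort, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw disease status from the logistic liability model.

    Sex comes from the pedigree records; the covariates are DLA class I /
    class II haplotype homozygosity (identical inherited extended
    sub-haplotypes) and the individual's homozygous fraction over genomic
    loci.  Returns the metadata frame and stores covariates on the cohort.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m = config.disease
    gt = cohort.genotypes
    genomic = [l for l in gt.loci if gt.locus_class[l] == GENOMIC]
    cols = [gt._locus_index[l] for l in genomic]
    rows = []
    for i, ind in enumerate(gt.individuals):
        (i1, ii1), (i2, ii2) = cohort.true_diplotypes[ind]
        hom_i = float(i1 == i2)
        hom_ii = float(ii1 == ii2)
        calls = gt.calls[i, cols, :]
        hom_frac = float((calls[:, 0] == calls[:, 1]).mean())
        sex = cohort.pedigree.records[ind].sex
        female = float(sex == "F")
        eta = (m.b0 + m.b_hap_i * hom_i + m.b_hap_ii * hom_ii
               + m.b_genome * hom_frac + m.b_sex * female)
        p = 1.0 / (1.0 + np.exp(-eta))
        diseased = rng.random() < p
        rows.append({"id": ind, "population": "simulated",
                     "status": "case" if diseased else "control",
                     "sex": sex, "hom_dla_i": hom_i, "hom_dla_ii": hom_ii,
                     "hom_fraction": hom_frac, "liability": eta,
                     "p_disease": p})
    df = pd.DataFrame(rows)
    cohort.covariates = df[["id", "hom_dla_i", "hom_dla_ii", "hom_fraction",
                            "liability", "p_disease"]]
    cohort.metadata = df[["id", "population", "status", "sex"]]
    return cohort.metadata


def full_sib_ir_experiment(seed: int,
                           n_base: int = 500,
                           n_offspring: int = 1000,
                           n_loci: int = 33,
                           alleles_per_locus: tuple[int, int] = (4, 8),
                           dirichlet_concentration: float = 1.0) -> dict:
    """Mean internal relatedness of offspring of full-sibling matings.

    Simulates a random-bred base population at Hardy-Weinberg
    equilibrium, estimates allele frequencies in that base, then for each
    replicate draws a random base pair, breeds two full siblings from it,
    mates the siblings, and scores the offspring's IR against the
    base-cohort frequencies.  The expected value is the offspring
    inbreeding coefficient, 0.25.

    Returns a dict with the per-offspring IR values and their mean.
    """
    from .diversity import allele_frequencies
    from .relatedness import internal_relatedness

    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(seed=seed, n_loci=n_loci,
                           alleles_per_locus=alleles_per_locus,
                           dirichlet_concentration=dirichlet_concentration)
    founder = _generate_founder_freqs(cfg, rng)
    loci = list(founder.freqs)
    base = np.empty((n_base, n_loci, 2), dtype=np.int64)
    for j, l in enumerate(loci):
        sizes = np.array(list(founder.freqs[l]))
        p = np.array(list(founder.freqs[l].values()))
        base[:, j, :] = rng.choice(sizes, size=(n_base, 2), p=p)
    base_table = GenotypeTable([f"B{i}" for i in range(n_base)], loci, base)
    base_freqs = allele_frequencies(base_table)

    def mendel(parent_calls: np.ndarray) -> np.ndarray:
        pick = rng.integers(0, 2, size=n_loci)
        return parent_calls[np.arange(n_loci), pick]

    kids = np.empty((n_offspring, n_loci, 2), dtype=np.int64)
    for k in range(n_offspring):
        g1, g2 = rng.choice(n_base, size=2, replace=False)
        sib1 = np.stack([mendel(base[g1]), mendel(base[g2])], axis=1)
        sib2 = np.stack([mendel(base[g1]), mendel(base[g2])], axis=1)
        kids[k] = np.stack([mendel(sib1), mendel(sib2)], axis=1)
    kid_table = GenotypeTable([f"O{k}" for k in range(n_offspring)], loci, kids)
    results = internal_relatedness(kid_table, freqs=base_freqs)
    values = np.array([r.ir for r in results])
    return {"ir_values": values, "mean_ir": float(values.mean()),
            "n_offspring": int(n_offspring)}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Pedigree, genotypes and phenotypes from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    pedigree = simulate_pedigree(config, rng)
    cohort = drop_genes(pedigree, config, rng)
    assign_phenotypes(cohort, config, rng)
    return cohort
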