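"""EM phasing of DLA-linked STR haplotypes and haplotype tabulation.

The dog MHC (DLA) carries four class I-linked and three class II-linked
STRs in tight linkage, so multilocus genotypes resolve into a small set of
haplotypes.  Phasing uses an Excoffier-Slatkin-style EM over the haplotype
pairs compatible with each multilocus genotype; a joint EM over the
combined 7-locus system, restricted to products of the region-level
haplotypes, exploits class I-II linkage to correct region-level phasing
errors.  Named catalogs map allele vectors to published haplotype IDs
(e.g. 1008, 2017).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (DLA_CLASS_I, DLA_CLASS_II, MISSING, GenotypeTable,
                 HaplotypeLookup)

Vector = tuple[int, ...]
Pair = tuple[Vector, Vector]

_REGION_TAG = {DLA_CLASS_I: "I", DLA_CLASS_II: "II"}


@dataclass
class HaplotypeCatalog:
    """EM-estimated haplotype frequencies for one region.

    ``counts`` are expected copy counts from the final E-step (reals);
    ``names`` is filled by :func:`name_haplotypes`.
    """

    region: str
    loci: list[str]
    frequencies: dict[Vector, float]
    counts: dict[Vector, float]
    n_individuals: int
    log_likelihood: float
    names: dict[Vector, str] = field(default_factory=dict)

    def name_of(self, vector: Vector) -> str:
        return self.names.get(vector, "/".join(map(str, vector)))


@dataclass
class Diplotype:
    individual: str
    pair: Pair  # canonically (lexicographically) ordered
    posterior: float

    @property
    def homozygous(self) -> bool:
        return self.pair[0] == self.pair[1]


@dataclass
class DiplotypeSet:
    region: str
    loci: list[str]
    assignments: dict[str, Diplotype]
    excluded: list[str]  # individuals with missing region genotypes

    @property
    def individuals(self) -> list[str]:
        return list(self.assignments)


def _compatible_pairs(genotype: list[tuple[int, int]],
                      allowed: set[Vector] | None = None) -> list[Pair]:
    """Unordered haplotype pairs consistent with a multilocus genotype."""
    het = [j for j, (a, b) in enumerate(genotype) if a != b]
    pairs: set[Pair] = set()
    for flips in itertools.product((0, 1), repeat=len(het)):
        h1, h2 = [], []
        fi = 0
        for j, (a, b) in enumerate(genotype):
            if a == b:
                h1.append(a)
                h2.append(b)
            else:
                if flips[fi]:
                    h1.append(b)
                    h2.append(a)
                else:
                    h1.append(a)
                    h2.append(b)
                fi += 1
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        pairs.add(pair)
    if allowed is not None:
        pairs = {p for p in pairs if p[0] in allowed and p[1] in allowed}
    return sorted(pairs)


def _em(individuals: list[str],
        pair_lists: list[list[Pair]],
        tol: float = 1e-6,
        max_iter: int = 1000,
        prune: float = 1e-8,
        n_restarts: int = 5,
        seed: int = 0):
    """Core EM over haplotype frequencies.

    Restart 0 initializes uniformly over compatible haplotypes; further
    restarts perturb with a seeded Dirichlet draw.  The best final
    log-likelihood wins.  The log-likelihood is asserted non-decreasing
    within each run.
    """
    haps = sorted({h for pl in pair_lists for p in pl for h in p})
    hap_index = {h: k for k, h in enumerate(haps)}
    nh = len(haps)
    n = len(individuals)
    # pair structure per individual as index arrays
    pair_idx = [np.array([(hap_index[p[0]], hap_index[p[1]]) for p in pl])
                for pl in pair_lists]
    pair_mult = [np.array([1.0 if p[0] == p[1] else 2.0 for p in pl])
                 for pl in pair_lists]
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            f = np.full(nh, 1.0 / nh)
        else:
            f = rng.dirichlet(np.ones(nh))
            f = np.maximum(f, 1e-12)
            f /= f.sum()
        prev_ll = -np.inf
        for _ in range(max_iter):
            new_f = np.zeros(nh)
            ll = 0.0
            for idx, mult in zip(pair_idx, pair_mult):
                w = mult * f[idx[:, 0]] * f[idx[:, 1]]
                total = w.sum()
                if total <= 0:
                    # all mass pruned away: re-seed uniformly over this
                    # individual's pairs
                    w = np.ones_like(w)
                    total = w.sum()
                    ll += -np.inf
                else:
                    ll += np.log(total)
                w /= total
                np.add.at(new_f, idx[:, 0], w)
                np.add.at(new_f, idx[:, 1], w)
            new_f /= 2 * n
            assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
            delta = np.abs(new_f - f).max()
            f = new_f
            prev_ll = ll
            if delta < tol:
                break
        if best is None or prev_ll > best[0]:
            best = (prev_ll, f.copy())
    ll, f = best
    # final E-step quantities under the winning frequencies
    posteriors: list[tuple[Pair, float]] = []
    counts = np.zeros(nh)
    for pl, idx, mult in zip(pair_lists, pair_idx, pair_mult):
        w = mult * f[idx[:, 0]] * f[idx[:, 1]]
        w = w / w.sum()
        np.add.at(counts, idx[:, 0], w)
        np.add.at(counts, idx[:, 1], w)
        # max posterior, ties broken lexicographically (pl is sorted)
        k = int(np.argmax(w > w.max() - 1e-12))
        posteriors.append((pl[k], float(w[k])))
    keep = f > prune
    freqs = {h: float(f[k]) for h, k in hap_index.items() if keep[k]}
    total = sum(freqs.values())
    freqs = {h: v / total for h, v in freqs.items()}
    exp_counts = {h: float(counts[hap_index[h]]) for h in freqs}
    return freqs, exp_counts, posteriors, float(ll)


def em_phase(genotypes: GenotypeTable,
             region: str = DLA_CLASS_I,
             loci: list[str] | None = None,
             tol: float = 1e-6,
             max_iter: int = 1000,
             prune: float = 1e-8,
             n_restarts: int = 5,
             seed: int = 0) -> tuple[HaplotypeCatalog, DiplotypeSet]:
    """Phase one DLA region by EM.

    Individuals with any missing call at the region loci are excluded
    from phasing and listed on the returned :class:`DiplotypeSet`.
    """
    if loci is None:
        loci = genotypes.loci_of_class(region)
    if not loci:
        raise ValueError(f"no loci of class {region!r} in table")
    gt = genotypes.subset(loci=loci)
    included, pair_lists, excluded = [], [], []
    for i, ind in enumerate(gt.individuals):
        row = [tuple(gt.calls[i, j]) for j in range(len(loci))]
        if any(a == MISSING for a, _ in row):
            excluded.append(ind)
            continue
        pairs = _compatible_pairs(row)
        if not pairs:
            raise ValueError(f"no compatible haplotype pair for {ind!r}")
        included.append(ind)
        pair_lists.append(pairs)
    if not included:
        raise ValueError("no fully typed individuals to phase")
    freqs, counts, posteriors, ll = _em(
        included, pair_lists, tol=tol, max_iter=max_iter, prune=prune,
        n_restarts=n_restarts, seed=seed)
    catalog = HaplotypeCatalog(region, list(loci), freqs, counts,
                               len(included), ll)
    assignments = {
        ind: Diplotype(ind, pair, post)
        for ind, (pair, post) in zip(included, posteriors)
    }
    return catalog, DiplotypeSet(region, list(loci), assignments, excluded)


def name_haplotypes(catalog: HaplotypeCatalog,
                    lookup: HaplotypeLookup) -> HaplotypeCatalog:
    """Attach catalog names from a lookup; unseen vectors get systematic
    names ``novel-<region>-<k>`` in descending-frequency order."""
    tag = _REGION_TAG.get(catalog.region, catalog.region)
    names = {}
    novel = []
    for vec in sorted(catalog.frequencies,
                      key=lambda v: (-catalog.frequencies[v], v)):
        known = lookup.name(catalog.region, vec)
        if known is not None:
            names[vec] = known
        else:
            novel.append(vec)
    for k, vec in enumerate(novel, start=1):
        names[vec] = f"novel-{tag}-{k}"
    catalog.names = names
    return catalog


@dataclass
class ExtendedHaplotypeTable:
    """Class I x class II haplotype pairings from the joint 7-locus EM."""

    frequencies: dict[tuple[Vector, Vector], float]
    counts: dict[tuple[Vector, Vector], float]

    @property
    def n_pairings(self) -> int:
        return len(self.frequencies)


def extended_linkage_correct(diplotypes_i: DiplotypeSet,
                             diplotypes_ii: DiplotypeSet,
                             genotypes: GenotypeTable,
                             catalog_i: HaplotypeCatalog | None = None,
                             catalog_ii: HaplotypeCatalog | None = None,
                             prune: float = 1e-8,
                             seed: int = 0,
                             ) -> tuple[ExtendedHaplotypeTable,
                                        DiplotypeSet, DiplotypeSet]:
    """Joint EM over both regions; its assignments override region-level ones.

    The joint haplotype space is restricted to concatenations of a class I
    and a class II region-level haplotype, so extended linkage (rather
    than new within-region phase solutions) drives any correction.
    """
    haps_i = (set(catalog_i.frequencies) if catalog_i is not None
              else {h for d in diplotypes_i.assignments.values() for h in d.pair})
    haps_ii = (set(catalog_ii.frequencies) if catalog_ii is not None
               else {h for d in diplotypes_ii.assignments.values() for h in d.pair})
    allowed = {hi + hii for hi in haps_i for hii in haps_ii}
    loci = list(diplotypes_i.loci) + list(diplotypes_ii.loci)
    gt = genotypes.subset(loci=loci)
    shared = [i for i in diplotypes_i.assignments if i in diplotypes_ii.assignments]
    included, pair_lists = [], []
    ncut = len(diplotypes_i.loci)
    for ind in shared:
        i = gt._ind_index[ind]
        row = [tuple(gt.calls[i, j]) for j in range(len(loci))]
        pairs = _compatible_pairs(row, allowed=allowed)
        if not pairs:
            continue  # genotype incompatible with the restricted space
        included.append(ind)
        pair_lists.append(pairs)
    if not included:
        raise ValueError("no individuals compatible with the joint space")
    freqs, counts, posteriors, _ = _em(included, pair_lists, prune=prune,
                                       seed=seed)
    ext_freqs: dict[tuple[Vector, Vector], float] = {}
    ext_counts: dict[tuple[Vector, Vector], float] = {}
    for h, f in freqs.items():
        key = (h[:ncut], h[ncut:])
        ext_freqs[key] = ext_freqs.get(key, 0.0) + f
        ext_counts[key] = ext_counts.get(key, 0.0) + counts[h]
    new_i = dict(diplotypes_i.assignments)
    new_ii = dict(diplotypes_ii.assignments)
    for ind, (pair, post) in zip(included, posteriors):
        pi = tuple(sorted((pair[0][:ncut], pair[1][:ncut])))
        pii = tuple(sorted((pair[0][ncut:], pair[1][ncut:])))
        new_i[ind] = Diplotype(ind, pi, post)
        new_ii[ind] = Diplotype(ind, pii, post)
    table = ExtendedHaplotypeTable(ext_freqs, ext_counts)
    return (table,
            DiplotypeSet(diplotypes_i.region, diplotypes_i.loci, new_i,
                         diplotypes_i.excluded),
            DiplotypeSet(diplotypes_ii.region, diplotypes_ii.loci, new_ii,
                         diplotypes_ii.excluded))


def haplotype_frequency_table(diplotypes: DiplotypeSet,
                              groups: dict[str, list[str]] | None = None,
                              names: dict[Vector, str] | None = None,
                              ) -> pd.DataFrame:
    """Haplotype copy counts and frequencies, overall or per group.

    Frequency = copies / (2 x phased individuals in the group).  Raises on
    an empty group.
    """
    if groups is None:
        groups = {"all": list(diplotypes.assignments)}
    rows: dict[Vector, dict[str, float]] = {}
    for group, members in groups.items():
        members = [m for m in members if m in diplotypes.assignments]
        if not members:
            raise ValueError(f"group {group!r} has no phased individuals")
        denom = 2 * len(members)
        for m in members:
            for h in diplotypes.assignments[m].pair:
                rec = rows.setdefault(h, {})
                rec[f"count_{group}"] = rec.get(f"count_{group}", 0) + 1
        for h, rec in rows.items():
            rec[f"freq_{group}"] = rec.get(f"count_{group}", 0) / denom
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df.index = pd.Index(
        ["/".join(map(str, v)) if names is None or v not in names
         else names[v] for v in rows],
        name="haplotype")
    return df.sort_index()


def nonzero_haplotype_count(frequencies: pd.Series | dict) -> int:
    """Number of haplotypes with frequency > 0."""
    vals = frequencies.values() if isinstance(frequencies, dict) else frequencies
    return int(sum(1 for v in vals if v > 0))


def cumulative_share(frequencies: pd.Series | dict, subset) -> float:
    """Summed frequency of a named subset of haplotypes."""
    if isinstance(frequencies, dict):
        return float(sum(frequencies.get(k, 0.0) for k in subset))
    return float(frequencies.reindex(list(subset)).fillna(0.0).sum())
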