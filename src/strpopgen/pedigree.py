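"""Pedigree algebra: Wright's inbreeding coefficient, ancestor genetic
contribution, ancestor contribution in the homozygous state, and
generation-limited ancestor occurrence scans.

Kinship is computed by memoized recursion (equivalent to the tabular
method) with founders taken as unrelated and non-inbred:

    phi(x, x) = (1 + F_x) / 2,   F_x = phi(sire_x, dam_x)
    phi(x, y) = (phi(sire_x, y) + phi(dam_x, y)) / 2

recursing on whichever individual is later in topological order (so never
on an ancestor of the other); unknown parents contribute founder behavior.
An optional depth cap truncates ancestry at g generations (generation 1 =
parents), mirroring registry analyses done on 10-generation pedigrees.
"""
from __future__ import annotations

import itertools
import sys
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Pedigree


class KinshipCalculator:
    """Memoized kinship over one pedigree (cache shared across queries)."""

    def __init__(self, pedigree: Pedigree, depth_cap: int | None = None):
        self.ped = pedigree
        self.depth_cap = depth_cap
        self._cache: dict[tuple, float] = {}
        self._depth: dict[str, int] = {}
        self._compute_depths()
        sys.setrecursionlimit(max(sys.getrecursionlimit(), 10000))

    def _compute_depths(self) -> None:
        # topological depth: founders 0, child = 1 + max(parent depths)
        order = []
        state: dict[str, int] = {}
        for start in self.ped.individuals:
            if start in state:
                continue
            stack = [start]
            while stack:
                node = stack[-1]
                if state.get(node) == 2:
                    stack.pop()
                    continue
                state[node] = 1
                pending = [p for p in self.ped.parents(node)
                           if p is not None and state.get(p) != 2]
                if pending:
                    stack.extend(pending)
                else:
                    state[node] = 2
                    parents = [p for p in self.ped.parents(node) if p is not None]
                    self._depth[node] = (
                        1 + max(self._depth[p] for p in parents)
                        if parents else 0)
                    order.append(node)
                    stack.pop()

    def _parents(self, ind: str, remaining: int | None):
        if remaining is not None and remaining <= 0:
            return (None, None)  # truncated: treat as founder
        return self.ped.parents(ind)

    def kinship(self, a: str | None, b: str | None,
                depth_a: int | None = None, depth_b: int | None = None) -> float:
        """phi(a, b); unknown individuals (None) act as unique founders."""
        if depth_a is None:
            depth_a = self.depth_cap
        if depth_b is None:
            depth_b = self.depth_cap
        if a is None or b is None:
            return 0.0
        key = (a, b, depth_a, depth_b)
        alt = (b, a, depth_b, depth_a)
        if key in self._cache:
            return self._cache[key]
        if alt in self._cache:
            return self._cache[alt]
        if a == b:
            sire, dam = self._parents(a, depth_a)
            val = 0.5 * (1.0 + self.kinship(
                sire, dam,
                None if depth_a is None else depth_a - 1,
                None if depth_a is None else depth_a - 1))
        else:
            # recurse on the individual later in topological order; it
            # cannot be an ancestor of the other
            if self._depth[a] >= self._depth[b]:
                later, dl, other, do = a, depth_a, b, depth_b
            else:
                later, dl, other, do = b, depth_b, a, depth_a
            sire, dam = self._parents(later, dl)
            nxt = None if dl is None else dl - 1
            val = 0.5 * (self.kinship(sire, other, nxt, do)
                         + self.kinship(dam, other, nxt, do))
        self._cache[key] = val
        return val

    def inbreeding(self, individual: str) -> float:
        sire, dam = self._parents(individual, self.depth_cap)
        nxt = None if self.depth_cap is None else self.depth_cap - 1
        return self.kinship(sire, dam, nxt, nxt)


def inbreeding_coefficient(pedigree: Pedigree, individual: str,
                           depth_cap: int | None = None) -> float:
    """Wright's F for one individual: the kinship of its parents."""
    if individual not in pedigree:
        raise KeyError(individual)
    return KinshipCalculator(pedigree, depth_cap).inbreeding(individual)


def inbreeding_coefficients(pedigree: Pedigree, individuals,
                            depth_cap: int | None = None) -> dict[str, float]:
    """F for many individuals sharing one kinship cache."""
    calc = KinshipCalculator(pedigree, depth_cap)
    return {i: calc.inbreeding(i) for i in individuals}


def ancestor_contribution(pedigree: Pedigree, individual: str, ancestor: str,
                          depth_cap: int | None = None) -> float:
    """Expected percent of ``individual``'s genome descending from
    ``ancestor``: c(A) = 100 if x = A, else mean of parental values."""
    cache: dict[tuple, float] = {}

    def c(x: str | None, remaining: int | None) -> float:
        if x is None:
            return 0.0
        if x == ancestor:
            return 1.0
        if remaining is not None and remaining <= 0:
            return 0.0
        key = (x, remaining)
        if key not in cache:
            sire, dam = pedigree.parents(x)
            nxt = None if remaining is None else remaining - 1
            cache[key] = 0.5 * c(sire, nxt) + 0.5 * c(dam, nxt)
        return cache[key]

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10000))
    return 100.0 * c(individual, depth_cap)


def _topological_order(pedigree: Pedigree) -> list[str]:
    order: list[str] = []
    state: dict[str, int] = {}
    for start in pedigree.individuals:
        stack = [start]
        while stack:
            node = stack[-1]
            if state.get(node) == 2:
                stack.pop()
                continue
            state[node] = 1
            pending = [p for p in pedigree.parents(node)
                       if p is not None and state.get(p) != 2]
            if pending:
                stack.extend(pending)
            else:
                state[node] = 2
                order.append(node)
                stack.pop()
    return order


def ancestor_homozygous_contribution(pedigree: Pedigree, individual: str,
                                     ancestor: str, reps: int = 100_000,
                                     seed: int | None = None,
                                     ) -> tuple[float, float]:
    """Percent of loci at which BOTH of ``individual``'s alleles descend
    through ``ancestor``, by Monte Carlo gene dropping.

    The ancestor's two allele slots are labeled and dropped Mendelian
    through the pedigree ``reps`` times; returns (percent, Monte Carlo SE
    in percent).  ``seed`` is required for reproducibility.
    """
    if reps < 1000:
        import warnings
        warnings.warn("fewer than 1000 gene-dropping reps: SE will be large")
    if individual == ancestor:
        return 100.0, 0.0
    rng = np.random.default_rng(seed)
    order = _topological_order(pedigree)
    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    # labels: 1 = descends through the ancestor, 0 = not
    genome = np.zeros((reps, n, 2), dtype=np.int8)
    for ind in order:
        k = idx[ind]
        if ind == ancestor:
            genome[:, k, :] = 1  # both of A's allele slots
            continue
        sire, dam = pedigree.parents(ind)
        for slot, parent in enumerate((sire, dam)):
            if parent is None:
                continue  # founder allele: label 0 already
            pick = rng.integers(0, 2, size=reps)
            genome[:, k, slot] = genome[np.arange(reps), idx[parent], pick]
    both = genome[:, idx[individual], :].all(axis=1)
    p = both.mean()
    se = np.sqrt(p * (1 - p) / reps)
    return 100.0 * float(p), 100.0 * float(se)


def ancestor_homozygous_contribution_exact(pedigree: Pedigree,
                                           individual: str,
                                           ancestor: str) -> float:
    """Exact value of :func:`ancestor_homozygous_contribution` by
    enumeration of every inheritance configuration (small pedigrees only:
    cost 4^non-founders)."""
    if individual == ancestor:
        return 100.0
    order = _topological_order(pedigree)
    non_founders = [i for i in order
                    if any(p is not None for p in pedigree.parents(i))]
    if len(non_founders) > 10:
        raise ValueError("exact enumeration limited to 10 non-founders")
    total = 0.0
    count = 0
    for choices in itertools.product((0, 1), repeat=2 * len(non_founders)):
        pick = dict(zip(non_founders,
                        (choices[2 * k: 2 * k + 2]
                         for k in range(len(non_founders)))))
        genome: dict[str, tuple[int, int]] = {}
        for ind in order:
            if ind == ancestor:
                genome[ind] = (1, 1)
                continue
            sire, dam = pedigree.parents(ind)
            alleles = []
            for slot, parent in enumerate((sire, dam)):
                if parent is None:
                    alleles.append(0)
                else:
                    alleles.append(genome[parent][pick[ind][slot]])
            genome[ind] = tuple(alleles)
        total += genome[individual][0] and genome[individual][1]
        count += 1
    return 100.0 * total / count


def ancestor_occurrence_scan(pedigree: Pedigree, cohort, ancestor: str,
                             generations: int = 10):
    """Count pedigree positions occupied by ``ancestor`` within
    ``generations`` of each cohort member (generation 1 = parents; an
    ancestor reached via k distinct positions counts k).

    Returns (per-individual counts, percent of the cohort with >= 1).
    """
    cache: dict[tuple[str, int], int] = {}

    def occ(x: str, remaining: int) -> int:
        if remaining <= 0:
            return 0
        key = (x, remaining)
        if key not in cache:
            total = 0
            for p in pedigree.parents(x):
                if p is None:
                    continue
                total += (p == ancestor) + occ(p, remaining - 1)
            cache[key] = total
        return cache[key]

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10000))
    counts = {ind: occ(ind, generations) for ind in cohort}
    pct = 100.0 * np.mean([c >= 1 for c in counts.values()]) if counts else 0.0
    return counts, float(pct)


@dataclass
class PedigreeContrast:
    """Group means of COI, ancestor contribution and homozygous
    contribution for cases vs controls, with Welch t p-values."""

    case_means: dict[str, float]
    control_means: dict[str, float]
    p_values: dict[str, float]


def cohort_pedigree_contrast(pedigree: Pedigree, case_ids, control_ids,
                             ancestor: str, depth_cap: int | None = 10,
                             reps: int = 10_000, seed: int | None = None,
                             ) -> PedigreeContrast:
    """COI / %ancestor / %ancestor-homozygous group contrast.

    COI and contribution honor ``depth_cap``; the gene-dropping
    homozygous contribution uses the full pedigree.  Welch t p-values are
    NaN for degenerate (singleton or zero-variance) groups.
    """
    calc = KinshipCalculator(pedigree, depth_cap)
    metrics: dict[str, dict[str, np.ndarray]] = {}
    for label, ids in (("case", list(case_ids)), ("control", list(control_ids))):
        if not ids:
            raise ValueError(f"empty {label} group")
        coi = np.array([calc.inbreeding(i) for i in ids]) * 100.0
        contrib = np.array([
            ancestor_contribution(pedigree, i, ancestor, depth_cap)
            for i in ids])
        hom = np.array([
            ancestor_homozygous_contribution(pedigree, i, ancestor,
                                             reps=reps, seed=seed)[0]
            for i in ids])
        metrics[label] = {"coi_pct": coi, "contribution_pct": contrib,
                          "homozygous_pct": hom}
    p_values = {}
    for key in ("coi_pct", "contribution_pct", "homozygous_pct"):
        a, b = metrics["case"][key], metrics["control"][key]
        if len(a) < 2 or len(b) < 2 or (a.std() == 0 and b.std() == 0):
            p_values[key] = float("nan")
        else:
            p_values[key] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return PedigreeContrast(
        case_means={k: float(v.mean()) for k, v in metrics["case"].items()},
        control_means={k: float(v.mean()) for k, v in metrics["control"].items()},
        p_values=p_values,
    )
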