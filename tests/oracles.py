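"""Independent oracles used by the test suite.

These deliberately take different routes from the package implementation:
haplotype-frequency ML by direct numerical optimization over the simplex,
inbreeding by classical path counting, and ancestor homozygosity by pure
Python enumeration of inheritance configurations.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize


def ml_haplotype_loglik(pair_lists, n_starts: int = 8, seed: int = 0):
    """Maximum log-likelihood over haplotype frequencies by direct
    softmax-parameterized optimization (independent of the EM route).

    ``pair_lists``: per individual, the list of compatible unordered
    haplotype pairs.  Returns (best log-likelihood, frequency dict).
    """
    haps = sorted({h for pl in pair_lists for p in pl for h in p})
    index = {h: k for k, h in enumerate(haps)}
    pairs = [np.array([(index[a], index[b]) for a, b in pl])
             for pl in pair_lists]
    mults = [np.array([1.0 if a == b else 2.0 for a, b in pl])
             for pl in pair_lists]

    def neg_ll(theta):
        e = np.exp(theta - theta.max())
        f = e / e.sum()
        ll = 0.0
        for idx, m in zip(pairs, mults):
            ll += np.log((m * f[idx[:, 0]] * f[idx[:, 1]]).sum() + 1e-300)
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = np.zeros(len(haps)) if s == 0 else rng.normal(0, 2, len(haps))
        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-10,
                                         "fatol": 1e-12})
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x)
    e = np.exp(best[1] - best[1].max())
    f = e / e.sum()
    return -best[0], {h: f[index[h]] for h in haps}


def _paths_to_ancestor(pedigree, start, ancestor):
    """All ascending parent chains from ``start`` to ``ancestor``; each
    path is the tuple of intermediate individuals (start included,
    ancestor excluded)."""
    paths = []

    def walk(node, trail):
        if node == ancestor:
            paths.append(tuple(trail))
            return
        for p in pedigree.parents(node):
            if p is not None:
                walk(p, trail + [node])

    walk(start, [])
    return paths


def path_counting_inbreeding(pedigree, individual: str) -> float:
    """Wright's F by enumeration of loops through common ancestors:
    F = sum over common ancestors A and internally disjoint path pairs of
    (1/2)^(n1+n2+1) * (1 + F_A)."""
    sire, dam = pedigree.parents(individual)
    if sire is None or dam is None:
        return 0.0
    common = ({sire} | pedigree.ancestors(sire)) & ({dam} | pedigree.ancestors(dam))
    total = 0.0
    for anc in common:
        f_anc = path_counting_inbreeding(pedigree, anc)
        for p1 in _paths_to_ancestor(pedigree, sire, anc):
            for p2 in _paths_to_ancestor(pedigree, dam, anc):
                if set(p1) & set(p2):
                    continue  # loops must be internally disjoint
                total += 0.5 ** (len(p1) + len(p2) + 1) * (1 + f_anc)
    return total


def enumerate_homozygous_contribution(pedigree, individual, ancestor) -> float:
    """Exact percent of loci with both alleles descending through
    ``ancestor``: average over every equally likely inheritance
    configuration (pure-Python route, independent of the package's)."""
    order = []
    seen = set()

    def visit(node):
        if node in seen:
            return
        seen.add(node)
        for p in pedigree.parents(node):
            if p is not None:
                visit(p)
        order.append(node)

    for node in pedigree.individuals:
        visit(node)
    non_founders = [n for n in order
                    if any(p is not None for p in pedigree.parents(n))]
    hits = 0
    total = 0
    for bits in itertools.product((0, 1), repeat=2 * len(non_founders)):
        pick = dict(zip(non_founders,
                        [bits[2 * i:2 * i + 2]
                         for i in range(len(non_founders))]))
        alleles = {}
        for node in order:
            if node == ancestor:
                alleles[node] = ("A", "A")
                continue
            got = []
            for slot, p in enumerate(pedigree.parents(node)):
                got.append("." if p is None else alleles[p][pick[node][slot]])
            alleles[node] = tuple(got)
        hits += alleles[individual] == ("A", "A")
        total += 1
    return 100.0 * hits / total
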