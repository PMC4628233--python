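"""Codominant genotypic distance and principal coordinate analysis.

The pairwise distance is the squared codominant genotypic distance of
Smouse & Peakall, summed over loci typed in both individuals: per locus,
identical genotypes score 0; genotypes sharing one allele (ii vs ij, or
ij vs ik) score 1; disjoint heterozygotes (ij vs kl) 2; a homozygote vs a
disjoint heterozygote (ii vs jk) 3; disjoint homozygotes (ii vs jj) 4.
PCoA is classical metric MDS: Gower double-centering of -D/2 followed by
eigendecomposition; only positive-eigenvalue axes carry coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .io import MISSING, GenotypeTable


def _locus_distance(a1: int, a2: int, b1: int, b2: int) -> int:
    if (a1, a2) == (b1, b2):  # pairs are stored sorted
        return 0
    shared = len({a1, a2} & {b1, b2})
    if shared:
        return 1
    return 2 + (a1 == a2) + (b1 == b2)


@dataclass
class DistanceMatrix:
    individuals: list[str]
    values: np.ndarray            # squared distances, symmetric, zero diagonal
    shared_loci: np.ndarray       # per pair, count of loci typed in both


def genotypic_distance(genotypes: GenotypeTable,
                       impute_missing_pairs: bool = False) -> DistanceMatrix:
    """Squared codominant genotypic distance between all individual pairs.

    Pairs sharing no typed locus are an error unless
    ``impute_missing_pairs`` is set, in which case they receive the mean
    distance over defined pairs.  Distances are locus sums without
    rescaling by the shared-locus count (GenAlEx behavior); the count is
    recorded per pair.
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    calls = genotypes.calls
    n = genotypes.n_individuals
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for k in range(i + 1, n):
            total = 0
            nloc = 0
            for j in range(genotypes.n_loci):
                a1, a2 = calls[i, j]
                b1, b2 = calls[k, j]
                if a1 == MISSING or b1 == MISSING:
                    continue
                total += _locus_distance(a1, a2, b1, b2)
                nloc += 1
            dist[i, k] = dist[k, i] = total
            shared[i, k] = shared[k, i] = nloc
    undefined = (shared == 0) & ~np.eye(n, dtype=bool)
    if undefined.any():
        if not impute_missing_pairs:
            i, k = np.argwhere(undefined)[0]
            raise ValueError(
                f"individuals {genotypes.individuals[i]!r} and "
                f"{genotypes.individuals[k]!r} share no typed locus"
            )
        defined = ~undefined & ~np.eye(n, dtype=bool)
        dist[undefined] = dist[defined].mean()
    return DistanceMatrix(list(genotypes.individuals), dist, shared)


@dataclass
class PCoAResult:
    individuals: list[str]
    coordinates: np.ndarray       # individuals x positive axes
    eigenvalues: np.ndarray       # all eigenvalues, descending
    percent_variance: np.ndarray  # per positive axis, of positive total

    def axis(self, k: int) -> np.ndarray:
        """Coordinates on axis ``k`` (1-based)."""
        return self.coordinates[:, k - 1]


def pcoa(distances: DistanceMatrix, eig_tol: float = 1e-9) -> PCoAResult:
    """Principal coordinate analysis of a squared-distance matrix.

    Coordinates are eigenvector * sqrt(eigenvalue) for eigenvalues above
    ``eig_tol`` x largest; negative eigenvalues (non-Euclidean input) are
    reported but carry no coordinates.  Axis signs are fixed by making the
    largest-magnitude loading positive.
    """
    d = np.asarray(distances.values, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d @ j
    g = (g + g.T) / 2
    eigvals, eigvecs = linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0) if n else 1.0
    positive = eigvals > eig_tol * scale
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigvals[positive].sum()
    pct = 100.0 * eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return PCoAResult(
        individuals=list(distances.individuals),
        coordinates=coords,
        eigenvalues=eigvals,
        percent_variance=pct,
    )
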