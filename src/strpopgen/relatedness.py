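"""Internal relatedness (IR) and its reference-adjusted variant (IRVD).

IR is a per-individual homozygosity index that up-weights sharing of rare
alleles: over an individual's N typed loci with H homozygous loci,

    IR = (2H - sum f_i) / (2N - sum f_i)

where the sum runs over the frequency f_i of each of the individual's 2N
allele copies (both copies counted at homozygous loci).  Scored with
frequencies from the individual's own cohort, IR measures how related its
parents were relative to that cohort; substituting frequencies from a
maximally diverse reference panel (village dogs) yields IRVD, which also
reflects diversity lost during breed formation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, FrequencyTable, GenotypeTable


@dataclass
class IRResult:
    individual: str
    n_loci_typed: int
    n_homozygous: int
    sum_freq: float
    ir: float
    variant: str = "IR"  # or "IRVD"


def _score(genotypes: GenotypeTable, freqs: FrequencyTable, variant: str,
           floor: float | None) -> list[IRResult]:
    results = []
    loci_avail = [l for l in genotypes.loci if l in freqs.freqs]
    cols = [genotypes.loci.index(l) for l in loci_avail]
    for i, ind in enumerate(genotypes.individuals):
        n = h = 0
        sum_f = 0.0
        for j, locus in zip(cols, loci_avail):
            a1, a2 = genotypes.calls[i, j]
            if a1 == MISSING:
                continue
            n += 1
            if a1 == a2:
                h += 1
            for allele in (int(a1), int(a2)):
                f = freqs.frequency(locus, allele)
                if f == 0.0:
                    if floor is None:
                        raise ValueError(
                            f"allele {allele} at {locus!r} absent from "
                            f"frequency table and no floor set"
                        )
                    f = floor
                sum_f += f
        if n == 0:
            continue  # untyped individual: omitted
        results.append(IRResult(
            individual=ind, n_loci_typed=n, n_homozygous=h, sum_freq=sum_f,
            ir=(2 * h - sum_f) / (2 * n - sum_f), variant=variant,
        ))
    return results


def internal_relatedness(genotypes: GenotypeTable,
                         freqs: FrequencyTable | None = None,
                         subset: list[str] | None = None) -> list[IRResult]:
    """Score IR for every typed individual.

    ``freqs`` defaults to frequencies estimated from the cohort itself
    (the intra-breed convention); individuals typed at zero loci are
    omitted.
    """
    from .diversity import allele_frequencies

    gt = genotypes.subset(individuals=subset) if subset is not None else genotypes
    if freqs is None:
        freqs = allele_frequencies(gt)
    return _score(gt, freqs, "IR", floor=None)


def internal_relatedness_adjusted(genotypes: GenotypeTable,
                                  reference: FrequencyTable,
                                  floor: float | None = None,
                                  subset: list[str] | None = None) -> list[IRResult]:
    """IRVD: the IR formula with allele frequencies from a reference panel.

    Alleles absent from the reference receive ``floor`` (default
    1/(2*panel_size + 1), with panel_size the largest recorded reference
    sample); loci absent from the reference are excluded.
    """
    gt = genotypes.subset(individuals=subset) if subset is not None else genotypes
    if floor is None:
        panel = max((n for n in reference.n_typed.values()), default=0)
        floor = 1.0 / (2 * panel + 1) if panel else 1e-3
    return _score(gt, reference, "IRVD", floor=floor)


@dataclass
class IRDistributionSummary:
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    median: float
    peak: float  # midpoint of the modal bin
    fraction_above: dict[float, float]


def ir_distribution_summary(results: list[IRResult],
                            bin_width: float = 0.025,
                            thresholds: tuple[float, ...] = (0.20, 0.40),
                            ) -> IRDistributionSummary:
    """Histogram and summary of a set of IR scores.

    Bins are aligned to multiples of ``bin_width`` spanning [-1, 1] plus
    the data range, so binning is deterministic; the peak is the midpoint
    of the modal bin (first such bin on ties).
    """
    if not results:
        raise ValueError("no IR results to summarize")
    values = np.array([r.ir for r in results])
    lo = min(-1.0, np.floor(values.min() / bin_width) * bin_width)
    hi = max(1.0, np.ceil(values.max() / bin_width) * bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    k = int(np.argmax(counts))
    return IRDistributionSummary(
        bin_edges=edges,
        counts=counts,
        mean=float(values.mean()),
        median=float(np.median(values)),
        peak=float((edges[k] + edges[k + 1]) / 2),
        fraction_above={t: float((values > t).mean()) for t in thresholds},
    )
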