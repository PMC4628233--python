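"""Allele frequencies and population diversity statistics.

Per-locus statistics follow the GenAlEx conventions used throughout dog
diversity surveys: allele count ``a``, effective alleles ``ae = 1/sum(p^2)``,
observed heterozygosity ``ho``, biased expected heterozygosity
``he = 1 - sum(p^2)`` (no small-sample correction) and the fixation index
``fis = (he - ho)/he``.  Across-locus values are unweighted means with
SE = sd/sqrt(L); monomorphic loci (he = 0) are dropped from the FIS mean.
Missing data are excluded locus-wise, so every locus carries its own typed
count.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, FrequencyTable, GenotypeTable


def allele_frequencies(genotypes: GenotypeTable,
                       subset: list[str] | None = None) -> FrequencyTable:
    """Estimate per-locus allele frequencies over non-missing calls.

    Loci with zero typed individuals in the subset are excluded (their
    names are recorded on the returned table as ``skipped``).
    """
    gt = genotypes.subset(individuals=subset) if subset is not None else genotypes
    freqs: dict[str, dict[int, float]] = {}
    n_typed: dict[str, int] = {}
    skipped: list[str] = []
    for j, locus in enumerate(gt.loci):
        col = gt.calls[:, j, :]
        typed = col[col[:, 0] != MISSING]
        if typed.size == 0:
            skipped.append(locus)
            continue
        alleles, counts = np.unique(typed.ravel(), return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(a): c / total for a, c in zip(alleles, counts)}
        n_typed[locus] = len(typed)
    table = FrequencyTable(freqs, n_typed)
    table.skipped = skipped
    return table


@dataclass
class DiversitySummary:
    """Per-locus diversity statistics plus across-locus means and SEs."""

    per_locus: pd.DataFrame  # index locus; columns n_typed, a, ae, ho, he, fis
    n_individuals: int

    def _mean_se(self, col: str) -> tuple[float, float]:
        vals = self.per_locus[col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            return float("nan"), float("nan")
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 \
            else float("nan")
        return float(vals.mean()), se

    @property
    def means(self) -> dict[str, float]:
        return {k.capitalize() if k != "fis" else "FIS": self._mean_se(k)[0]
                for k in ("a", "ae", "ho", "he", "fis")}

    def as_frame(self) -> pd.DataFrame:
        """Summary rows (Mean, SE) x columns Aa, Ae, Ho, He, FIS."""
        cols = {"a": "Aa", "ae": "Ae", "ho": "Ho", "he": "He", "fis": "FIS"}
        data = {new: self._mean_se(old) for old, new in cols.items()}
        return pd.DataFrame(data, index=["Mean", "SE"])


def _per_locus_from_freqs(freqs: FrequencyTable) -> pd.DataFrame:
    rows = {}
    for locus, table in freqs.freqs.items():
        p = np.array([f for f in table.values() if f > 0])
        sum_p2 = float((p ** 2).sum())
        rows[locus] = {
            "n_typed": freqs.n_typed.get(locus, np.nan),
            "a": len(p),
            "ae": 1.0 / sum_p2,
            "he": 1.0 - sum_p2,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def diversity_from_frequencies(freqs: FrequencyTable) -> DiversitySummary:
    """Diversity statistics computable from allele frequencies alone
    (a, ae, he); ho and fis require genotypes and are left NaN.

    Useful when only a published frequency table is available.
    """
    per_locus = _per_locus_from_freqs(freqs)
    per_locus["ho"] = np.nan
    per_locus["fis"] = np.nan
    n = max((v for v in freqs.n_typed.values()), default=0)
    return DiversitySummary(per_locus[["n_typed", "a", "ae", "ho", "he", "fis"]], n)


def diversity_summary(genotypes: GenotypeTable,
                      subset: list[str] | None = None,
                      loci: list[str] | None = None) -> DiversitySummary:
    """Full per-locus and across-locus diversity summary for a cohort."""
    gt = genotypes.subset(individuals=subset, loci=loci)
    freqs = allele_frequencies(gt)
    per_locus = _per_locus_from_freqs(freqs)
    ho = {}
    for j, locus in enumerate(gt.loci):
        if locus not in freqs.freqs:
            continue
        col = gt.calls[:, j, :]
        typed = col[col[:, 0] != MISSING]
        ho[locus] = float((typed[:, 0] != typed[:, 1]).mean())
    per_locus["ho"] = pd.Series(ho)
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = (per_locus["he"] - per_locus["ho"]) / per_locus["he"]
    per_locus["fis"] = fis.where(per_locus["he"] > 0)  # undefined if monomorphic
    per_locus = per_locus.loc[[l for l in gt.loci if l in per_locus.index]]
    return DiversitySummary(
        per_locus[["n_typed", "a", "ae", "ho", "he", "fis"]],
        gt.n_individuals,
    )


@dataclass
class PairedFisResult:
    loci: list[str]
    fis_a: np.ndarray
    fis_b: np.ndarray
    mean_difference: float
    t_statistic: float
    p_value: float
    ci99: tuple[float, float]


def fis_per_locus_pair(genotypes_a: GenotypeTable,
                       genotypes_b: GenotypeTable,
                       loci: list[str] | None = None) -> PairedFisResult:
    """Paired-by-locus FIS contrast between two cohorts.

    Returns the per-locus FIS vectors, the paired t statistic, its
    two-sided p value, and the 99% CI of the mean difference, matching the
    way case/control fixation-index contrasts are reported in breed
    studies.
    """
    sa = diversity_summary(genotypes_a, loci=loci).per_locus["fis"]
    sb = diversity_summary(genotypes_b, loci=loci).per_locus["fis"]
    shared = [l for l in sa.index if l in sb.index
              and np.isfinite(sa[l]) and np.isfinite(sb[l])]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared informative loci")
    fa = sa[shared].to_numpy(dtype=float)
    fb = sb[shared].to_numpy(dtype=float)
    diff = fa - fb
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]) and np.isclose(diff.std(ddof=1), 0.0):
        # degenerate: identical per-locus differences
        t = 0.0 if np.isclose(mean_diff, 0.0) else np.inf
        p = 1.0 if t == 0.0 else 0.0
        half = 0.0
    else:
        t, p = stats.ttest_rel(fa, fb)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        half = float(stats.t.ppf(0.995, len(diff) - 1) * se)
    return PairedFisResult(
        loci=shared, fis_a=fa, fis_b=fb, mean_difference=mean_diff,
        t_statistic=float(t), p_value=float(p),
        ci99=(mean_diff - half, mean_diff + half),
    )
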