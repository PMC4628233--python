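"""Bundled reference tables from a published Italian Greyhound diversity
and autoimmune-disease survey.

These are the survey's printed summary tables, transcribed to CSV: allele
frequencies for 33 genomic STRs in the Continental European (n = 174) and
USA (n = 213) cohorts; the STR-associated DLA class I and class II
haplotype catalogs with cohort frequencies; per-disease sex counts for
the 91-dog autoimmune case series and 104 controls; and the case/control
DLA homozygosity and haplotype count tables.  They serve as worked-example
inputs and as the published values the acceptance checks recompute.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import DLA_CLASS_I, DLA_CLASS_II, FrequencyTable, HaplotypeLookup


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def genomic_str_frequencies() -> pd.DataFrame:
    """Printed allele frequencies (columns locus, allele, freq_eu,
    freq_usa) for the 33 genomic STR loci."""
    return _read("ig_genomic_str_frequencies.csv")


def genomic_frequency_table(population: str = "usa",
                            normalize: bool = True) -> FrequencyTable:
    """The printed frequencies as a :class:`FrequencyTable` for one
    population ("usa" or "eu").

    Printed values are rounded, so per-locus sums stray slightly from 1;
    ``normalize`` rescales each locus (required for the container's
    sum-to-one invariant).
    """
    df = genomic_str_frequencies()
    col = {"usa": "freq_usa", "eu": "freq_eu"}[population.lower()]
    freqs: dict[str, dict[int, float]] = {}
    for locus, sub in df.groupby("locus", sort=False):
        vals = sub[sub[col] > 0]
        total = vals[col].sum() if normalize else 1.0
        freqs[locus] = {int(a): float(f) / total
                        for a, f in zip(vals["allele"], vals[col])}
    n = {"usa": 213, "eu": 174}[population.lower()]
    return FrequencyTable(freqs, {l: n for l in freqs})


def dla_class_i_catalog() -> pd.DataFrame:
    """Published class I haplotypes: name, allele1..4, freq_eu, freq_usa."""
    return _read("ig_dla_class_i_haplotypes.csv", dtype={"name": str})


def dla_class_ii_catalog() -> pd.DataFrame:
    """Published class II haplotypes: name, allele1..3, freq_eu, freq_usa,
    and the corresponding sequence-based DRB1/DQA1/DQB1 designation."""
    return _read("ig_dla_class_ii_haplotypes.csv", dtype={"name": str})


def dla_haplotype_lookup() -> HaplotypeLookup:
    """Allele-vector -> catalog-name lookup built from both catalogs."""
    tables = {DLA_CLASS_I: {}, DLA_CLASS_II: {}}
    for _, row in dla_class_i_catalog().iterrows():
        vec = tuple(int(row[f"allele{k}"]) for k in range(1, 5))
        tables[DLA_CLASS_I][vec] = str(row["name"])
    for _, row in dla_class_ii_catalog().iterrows():
        vec = tuple(int(row[f"allele{k}"]) for k in range(1, 4))
        tables[DLA_CLASS_II][vec] = str(row["name"])
    return HaplotypeLookup(tables)


def autoimmune_sex_counts() -> pd.DataFrame:
    """Per-disease-form female/male counts for the case series, plus the
    affected and healthy totals (dogs with two forms count once per form)."""
    return _read("ig_autoimmune_sex_counts.csv")


def dla_homozygosity_counts() -> pd.DataFrame:
    """Case/control homozygote counts per DLA STR locus and per region
    haplotype (85 cases, 104 controls)."""
    return _read("ig_dla_homozygosity_counts.csv", dtype={"marker": str})


def dla_case_control_haplotypes() -> pd.DataFrame:
    """Case/control chromosome counts per DLA haplotype."""
    return _read("ig_dla_case_control_haplotypes.csv", dtype={"name": str})
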