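"""End-to-end analysis pipeline over a simulated cohort.

One seeded config drives simulate -> diversity -> IR -> DLA phasing ->
case/control association -> pedigree metrics, writing every result as CSV
so a rerun with the same config is byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .association import homozygosity_risk_table, sex_ratio_summary
from .dla import (em_phase, extended_linkage_correct, haplotype_frequency_table,
                  name_haplotypes)
from .diversity import diversity_summary
from .io import DLA_CLASS_I, DLA_CLASS_II, write_genotypes, write_pedigree
from .pedigree import KinshipCalculator, ancestor_occurrence_scan
from .relatedness import internal_relatedness
from .simulate import SimulationConfig, simulate_cohort


def run_pipeline(config: SimulationConfig, out_dir) -> dict:
    """Run every analysis stage on one simulated cohort.

    Writes genotypes, pedigree, metadata, diversity, IR, DLA catalogs and
    diplotypes, the homozygosity risk table and pedigree metrics under
    ``out_dir``; returns a small summary dict (also written as JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    gt = cohort.genotypes
    meta = cohort.metadata

    write_genotypes(out / "genotypes.csv", gt, meta)
    write_pedigree(out / "pedigree.csv", cohort.pedigree)
    meta.to_csv(out / "metadata.csv", index=False)

    last_gen = f"G{config.n_generations}-"
    cohort_ids = [i for i in gt.individuals if i.startswith(last_gen)]
    sub = gt.subset(individuals=cohort_ids)
    sub_meta = meta[meta["id"].isin(cohort_ids)]

    div = diversity_summary(sub, loci=sub.loci_of_class("genomic"))
    div.per_locus.round(6).to_csv(out / "diversity_per_locus.csv")
    div.as_frame().round(6).to_csv(out / "diversity_summary.csv")

    ir = internal_relatedness(sub)
    pd.DataFrame([{"id": r.individual, "n_loci": r.n_loci_typed,
                   "ir": round(r.ir, 6)} for r in ir]
                 ).to_csv(out / "ir.csv", index=False)

    lookup = datasets.dla_haplotype_lookup()
    cat_i, dip_i = em_phase(sub, DLA_CLASS_I, seed=config.seed)
    cat_ii, dip_ii = em_phase(sub, DLA_CLASS_II, seed=config.seed)
    ext, dip_i, dip_ii = extended_linkage_correct(
        dip_i, dip_ii, sub, cat_i, cat_ii, seed=config.seed)
    for cat, tag in ((cat_i, "class_i"), (cat_ii, "class_ii")):
        name_haplotypes(cat, lookup)
        rows = [{"name": cat.names[v], "vector": "/".join(map(str, v)),
                 "frequency": round(f, 6),
                 "count": round(cat.counts.get(v, 0.0), 3)}
                for v, f in sorted(cat.frequencies.items(),
                                   key=lambda kv: (-kv[1], kv[0]))]
        pd.DataFrame(rows).to_csv(out / f"dla_catalog_{tag}.csv", index=False)
    dip_rows = []
    for ind in dip_i.individuals:
        di = dip_i.assignments[ind]
        dii = dip_ii.assignments.get(ind)
        dip_rows.append({
            "id": ind,
            "class_i_pair": " | ".join("/".join(map(str, h)) for h in di.pair),
            "class_i_posterior": round(di.posterior, 6),
            "class_i_homozygous": di.homozygous,
            "class_ii_pair": " | ".join("/".join(map(str, h)) for h in dii.pair)
            if dii else "",
            "class_ii_posterior": round(dii.posterior, 6) if dii else np.nan,
            "class_ii_homozygous": dii.homozygous if dii else np.nan,
        })
    pd.DataFrame(dip_rows).to_csv(out / "dla_diplotypes.csv", index=False)
    freq_i = haplotype_frequency_table(dip_i, names=cat_i.names)
    freq_i.round(6).to_csv(out / "dla_frequencies_class_i.csv")

    assoc = homozygosity_risk_table(
        sub, sub_meta,
        diplotypes={"DLA-I": dip_i, "DLA-II": dip_ii})
    assoc.round(6).to_csv(out / "homozygosity_risk.csv")
    sex_ratio_summary(sub_meta).to_csv(out / "sex_ratios.csv")

    # pedigree analytics around the most-used sire
    sire_counts: dict[str, int] = {}
    for rec in cohort.pedigree.records.values():
        if rec.sire is not None:
            sire_counts[rec.sire] = sire_counts.get(rec.sire, 0) + 1
    top_sire = max(sorted(sire_counts), key=lambda s: sire_counts[s])
    calc = KinshipCalculator(cohort.pedigree)
    coi = {i: calc.inbreeding(i) for i in cohort_ids}
    _, pct_with_sire = ancestor_occurrence_scan(
        cohort.pedigree, cohort_ids, top_sire, generations=10)
    pd.DataFrame({"id": list(coi), "coi": [round(v, 6) for v in coi.values()]}
                 ).to_csv(out / "pedigree_coi.csv", index=False)

    summary = {
        "seed": config.seed,
        "n_individuals": gt.n_individuals,
        "final_cohort": len(cohort_ids),
        "mean_He": round(float(div.per_locus["he"].mean()), 6),
        "mean_FIS": round(float(div.per_locus["fis"].dropna().mean()), 6),
        "mean_IR": round(float(np.mean([r.ir for r in ir])), 6),
        "class_i_haplotypes": len(cat_i.frequencies),
        "class_ii_haplotypes": len(cat_ii.frequencies),
        "extended_pairings": ext.n_pairings,
        "top_sire": top_sire,
        "top_sire_offspring": sire_counts[top_sire],
        "pct_cohort_with_top_sire_10gen": round(pct_with_sire, 3),
        "mean_COI": round(float(np.mean(list(coi.values()))), 6),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
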