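"""Case/control association analyses.

Exposure is homozygosity — at a single DLA STR locus (two identical
alleles) or at a region haplotype (identical haplotype pair).  Relative
risk is the ratio of within-group exposure proportions,
RR = (a/n_case)/(c/n_control), with a log-normal 95% CI.  Significance
uses a chi-square test without continuity correction, switching to a
two-sided Fisher exact test when any expected cell is below 5; no
multiple-testing correction is applied by default, with Bonferroni /
Benjamini-Hochberg available by flag.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeTable
from .dla import DiplotypeSet
from .diversity import diversity_summary, fis_per_locus_pair
from .relatedness import internal_relatedness


@dataclass
class Assoc2x2:
    """A 2x2 case/control x exposed/unexposed table with RR, CI and p."""

    a: int  # case, exposed
    b: int  # case, unexposed
    c: int  # control, exposed
    d: int  # control, unexposed

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d

    @property
    def rr(self) -> float:
        p_case = self.a / self.n_case if self.n_case else np.nan
        p_ctrl = self.c / self.n_control if self.n_control else np.nan
        if p_ctrl == 0:
            return np.inf if p_case > 0 else np.nan
        return p_case / p_ctrl

    def rr_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Log-normal (Katz) confidence interval for the relative risk."""
        if 0 in (self.a, self.c) or not np.isfinite(self.rr):
            return (np.nan, np.nan)
        se = np.sqrt(1 / self.a - 1 / self.n_case
                     + 1 / self.c - 1 / self.n_control)
        z = stats.norm.ppf(0.5 + level / 2)
        log_rr = np.log(self.rr)
        return (float(np.exp(log_rr - z * se)), float(np.exp(log_rr + z * se)))

    def test(self) -> tuple[float, str]:
        """Two-sided p value and the test used ('chi2' or 'fisher')."""
        table = np.array([[self.a, self.b], [self.c, self.d]])
        if table.sum() == 0:
            return np.nan, "none"
        expected = stats.contingency.expected_freq(table) \
            if table.sum(axis=0).all() and table.sum(axis=1).all() else None
        if expected is None or (expected < 5).any():
            _, p = stats.fisher_exact(table, alternative="two-sided")
            return float(p), "fisher"
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(p), "chi2"


def _adjust(pvals: pd.Series, method: str | None) -> pd.Series:
    if method is None:
        return pvals
    p = pvals.to_numpy(dtype=float)
    m = np.isfinite(p).sum()
    if method == "bonferroni":
        return pd.Series(np.minimum(p * m, 1.0), index=pvals.index)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return pd.Series(out, index=pvals.index)
    raise ValueError(f"unknown adjustment {method!r}")


def _status_groups(metadata: pd.DataFrame) -> tuple[list[str], list[str]]:
    meta = metadata.set_index("id") if "id" in metadata.columns else metadata
    cases = meta.index[meta["status"] == "case"].tolist()
    controls = meta.index[meta["status"] == "control"].tolist()
    return cases, controls


def homozygosity_risk_table(genotypes: GenotypeTable,
                            metadata: pd.DataFrame,
                            diplotypes: dict[str, DiplotypeSet] | None = None,
                            loci: list[str] | None = None,
                            adjust: str | None = None) -> pd.DataFrame:
    """Relative risk of disease associated with homozygosity, per DLA STR
    locus and (when diplotypes are supplied) per region haplotype.

    Denominators are the individuals typed at each locus / phased at each
    region.  Returns one row per marker with the 2x2 counts, RR, its 95%
    CI, p and the test used.
    """
    cases, controls = _status_groups(metadata)
    if not cases or not controls:
        raise ValueError("need both case and control individuals")
    loci = loci if loci is not None else [
        l for l in genotypes.loci
        if genotypes.locus_class[l] != "genomic"
    ]
    rows = []
    for locus in loci:
        j = genotypes._locus_index[locus]
        counts = {}
        for label, members in (("case", cases), ("control", controls)):
            idx = [genotypes._ind_index[m] for m in members
                   if m in genotypes._ind_index]
            calls = genotypes.calls[idx, j, :]
            typed = calls[calls[:, 0] != MISSING]
            counts[label] = (int((typed[:, 0] == typed[:, 1]).sum()), len(typed))
        t = Assoc2x2(counts["case"][0], counts["case"][1] - counts["case"][0],
                     counts["control"][0],
                     counts["control"][1] - counts["control"][0])
        p, method = t.test()
        lo, hi = t.rr_ci()
        rows.append({"marker": locus, "kind": "locus",
                     "case_homozygous": t.a, "n_case": t.n_case,
                     "control_homozygous": t.c, "n_control": t.n_control,
                     "rr": t.rr, "rr_lo": lo, "rr_hi": hi,
                     "p": p, "test": method})
    for region, dset in (diplotypes or {}).items():
        counts = {}
        for label, members in (("case", cases), ("control", controls)):
            phased = [m for m in members if m in dset.assignments]
            hom = sum(dset.assignments[m].homozygous for m in phased)
            counts[label] = (hom, len(phased))
        t = Assoc2x2(counts["case"][0], counts["case"][1] - counts["case"][0],
                     counts["control"][0],
                     counts["control"][1] - counts["control"][0])
        p, method = t.test()
        lo, hi = t.rr_ci()
        rows.append({"marker": region, "kind": "haplotype",
                     "case_homozygous": t.a, "n_case": t.n_case,
                     "control_homozygous": t.c, "n_control": t.n_control,
                     "rr": t.rr, "rr_lo": lo, "rr_hi": hi,
                     "p": p, "test": method})
    df = pd.DataFrame(rows).set_index("marker")
    if adjust:
        df["p_adjusted"] = _adjust(df["p"], adjust)
    return df


def haplotype_case_control_table(diplotypes: DiplotypeSet,
                                 metadata: pd.DataFrame,
                                 adjust: str | None = None) -> pd.DataFrame:
    """Per-haplotype chromosome counts and frequencies in cases vs
    controls, with a 2x2 carrier-chromosome test per haplotype.

    Haplotypes absent from both groups are excluded.  Frequencies per
    group sum to 1 over the region's haplotypes.
    """
    cases, controls = _status_groups(metadata)
    groups = {"case": [m for m in cases if m in diplotypes.assignments],
              "control": [m for m in controls if m in diplotypes.assignments]}
    for label, members in groups.items():
        if not members:
            raise ValueError(f"no phased {label} individuals")
    counts: dict[tuple, dict[str, int]] = {}
    denom = {}
    for label, members in groups.items():
        denom[label] = 2 * len(members)
        for m in members:
            for h in diplotypes.assignments[m].pair:
                counts.setdefault(h, {"case": 0, "control": 0})[label] += 1
    rows = []
    for h, c in sorted(counts.items()):
        t = Assoc2x2(c["case"], denom["case"] - c["case"],
                     c["control"], denom["control"] - c["control"])
        p, method = t.test()
        rows.append({"haplotype": "/".join(map(str, h)),
                     "case_count": c["case"],
                     "case_freq": c["case"] / denom["case"],
                     "control_count": c["control"],
                     "control_freq": c["control"] / denom["control"],
                     "rr": t.rr, "p": p, "test": method})
    df = pd.DataFrame(rows).set_index("haplotype")
    if adjust:
        df["p_adjusted"] = _adjust(df["p"], adjust)
    return df


def sex_ratio_summary(metadata: pd.DataFrame,
                      disease_forms: pd.DataFrame | None = None) -> pd.DataFrame:
    """Female/male counts and F/M ratio (1 decimal) per group.

    ``disease_forms`` may give per-form female/male counts (an individual
    with two forms counts once per form); rows with zero males report the
    ratio as NaN.
    """
    meta = metadata.set_index("id") if "id" in metadata.columns else metadata
    rows = []
    if disease_forms is not None:
        for _, r in disease_forms.iterrows():
            f = float(r["female"]) if pd.notna(r["female"]) and r["female"] != "" else np.nan
            m = float(r["male"]) if pd.notna(r["male"]) and r["male"] != "" else np.nan
            rows.append({"group": r.get("disease", r.get("group", "form")),
                         "female": f, "male": m})
    for status, label in (("case", "Total affected"),
                          ("control", "Total healthy")):
        sub = meta[meta["status"] == status]
        if len(sub):
            rows.append({"group": label,
                         "female": int((sub["sex"] == "F").sum()),
                         "male": int((sub["sex"] == "M").sum())})
    df = pd.DataFrame(rows).set_index("group")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["female"] / df["male"]
    df["fm_ratio"] = np.round(ratio.replace([np.inf, -np.inf], np.nan), 1)
    return df


@dataclass
class GroupDiversityContrast:
    summaries: dict[str, "pd.DataFrame"]
    fis_paired: dict[str, object]         # per locus-set: PairedFisResult
    ir_anova: tuple[float, float]          # F, p over IR by group
    tukey: pd.DataFrame                    # pairwise group contrasts on IR


def group_diversity_contrast(genotypes: GenotypeTable,
                             metadata: pd.DataFrame,
                             group_col: str = "status",
                             locus_sets: dict[str, list[str]] | None = None,
                             min_group_size: int = 10,
                             ) -> GroupDiversityContrast:
    """Per-group diversity summaries plus FIS (paired t over loci, per
    locus set) and IR (one-way ANOVA + Tukey HSD) contrasts.

    Groups below ``min_group_size`` are still computed (small-sample
    caution is the caller's).
    """
    meta = metadata.set_index("id") if "id" in metadata.columns else metadata
    groups = {g: meta.index[meta[group_col] == g].tolist()
              for g in meta[group_col].unique() if g != "unknown"}
    groups = {g: [m for m in members if m in genotypes._ind_index]
              for g, members in groups.items()}
    groups = {g: m for g, m in groups.items() if m}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if locus_sets is None:
        genomic = genotypes.loci_of_class("genomic")
        dla = [l for l in genotypes.loci if l not in genomic]
        locus_sets = {"genomic": genomic}
        if dla:
            locus_sets["dla"] = dla
    summaries = {
        g: diversity_summary(genotypes, subset=m).as_frame()
        for g, m in groups.items()
    }
    names = list(groups)
    fis_paired = {}
    if len(names) == 2:
        ga = genotypes.subset(individuals=groups[names[0]])
        gb = genotypes.subset(individuals=groups[names[1]])
        for set_name, loci in locus_sets.items():
            loci = [l for l in loci if l in genotypes.loci]
            if len(loci) >= 2:
                fis_paired[set_name] = fis_per_locus_pair(ga, gb, loci=loci)
    ir_by_group = {}
    for g, members in groups.items():
        res = internal_relatedness(genotypes, subset=members)
        ir_by_group[g] = np.array([r.ir for r in res])
    f_stat, p = stats.f_oneway(*ir_by_group.values())
    identical = all(
        np.array_equal(ir_by_group[names[0]], v) for v in ir_by_group.values())
    if identical:
        f_stat, p = 0.0, 1.0
        tukey_df = pd.DataFrame(
            [{"group_a": a, "group_b": b, "difference": 0.0, "p": 1.0}
             for i, a in enumerate(names) for b in names[i + 1:]])
    else:
        res = stats.tukey_hsd(*ir_by_group.values())
        rows = []
        for i, a in enumerate(names):
            for k in range(i + 1, len(names)):
                rows.append({"group_a": a, "group_b": names[k],
                             "difference": float(ir_by_group[a].mean()
                                                 - ir_by_group[names[k]].mean()),
                             "p": float(res.pvalue[i, k])})
        tukey_df = pd.DataFrame(rows)
    return GroupDiversityContrast(summaries, fis_paired,
                                  (float(f_stat), float(p)), tukey_df)
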