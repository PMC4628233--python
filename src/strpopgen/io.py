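"""Core data containers and CSV codecs.

The universal input is a diploid codominant STR genotype table: two integer
allele sizes (base pairs) per individual per locus, with all-or-nothing
missing data (a half-missing pair is rejected as a genotyping artifact).
Companion containers hold sample metadata, per-locus allele frequencies,
sire/dam pedigrees and the catalog that names DLA haplotype allele vectors.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0  # sentinel allele size for an untyped call

GENOMIC = "genomic"
DLA_CLASS_I = "dla_class_I"
DLA_CLASS_II = "dla_class_II"
LOCUS_CLASSES = (GENOMIC, DLA_CLASS_I, DLA_CLASS_II)

#: canonical DLA-linked STR locus names (4 class I, 3 class II)
DLA_I_LOCI = ("3CCA", "4ACA", "4BCT", "1131")
DLA_II_LOCI = ("5ACA", "5ACT", "5BCA")

STATUS_VALUES = ("case", "control", "unknown")
SEX_VALUES = ("F", "M", "unknown")


class ValidationError(ValueError):
    """Raised when an input file violates a container invariant."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele-size calls.

    ``calls`` has shape (n_individuals, n_loci, 2); each pair is stored
    sorted ascending, with (0, 0) meaning missing.  ``locus_class`` maps
    each locus to one of :data:`LOCUS_CLASSES`.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    locus_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual IDs")
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("duplicate locus names")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValidationError(
                f"half-missing genotype for individual "
                f"{self.individuals[i]!r} at locus {self.loci[j]!r}"
            )
        if (self.calls < 0).any():
            raise ValidationError("negative allele size")
        self.calls = np.sort(self.calls, axis=2)
        for locus in self.loci:
            self.locus_class.setdefault(locus, GENOMIC)
            if self.locus_class[locus] not in LOCUS_CLASSES:
                raise ValidationError(
                    f"unknown locus class {self.locus_class[locus]!r}"
                )
        self._ind_index = {ind: i for i, ind in enumerate(self.individuals)}
        self._locus_index = {loc: j for j, loc in enumerate(self.loci)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def genotype(self, individual: str, locus: str) -> tuple[int, int]:
        return tuple(self.calls[self._ind_index[individual],
                                self._locus_index[locus]])

    def is_missing(self, individual: str, locus: str) -> bool:
        return self.genotype(individual, locus)[0] == MISSING

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) array, True where untyped."""
        return self.calls[:, :, 0] == MISSING

    def subset(self, individuals=None, loci=None) -> "GenotypeTable":
        """Restrict to the given individuals and/or loci (order preserved)."""
        inds = list(individuals) if individuals is not None else self.individuals
        locs = list(loci) if loci is not None else self.loci
        rows = [self._ind_index[i] for i in inds]
        cols = [self._locus_index[l] for l in locs]
        return GenotypeTable(
            individuals=inds,
            loci=locs,
            calls=self.calls[np.ix_(rows, cols)],
            locus_class={l: self.locus_class[l] for l in locs},
        )

    def loci_of_class(self, locus_class: str) -> list[str]:
        return [l for l in self.loci if self.locus_class[l] == locus_class]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.individuals == other.individuals
            and self.loci == other.loci
            and self.locus_class == other.locus_class
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class FrequencyTable:
    """Per-locus allele -> relative frequency, with typed sample sizes.

    Used both for cohort-estimated frequencies (``n_typed`` = individuals
    successfully typed per locus) and for an external reference panel such
    as village-dog frequencies (``n_typed`` = panel size).
    """

    freqs: dict[str, dict[int, float]]
    n_typed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            total = sum(table.values())
            if table and abs(total - 1.0) > 1e-6:
                raise ValidationError(
                    f"frequencies at {locus!r} sum to {total}, not 1"
                )
            if any(f <= 0 for f in table.values()):
                raise ValidationError(f"non-positive frequency at {locus!r}")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def frequency(self, locus: str, allele: int, default: float = 0.0) -> float:
        return self.freqs.get(locus, {}).get(allele, default)


# Backwards-compatible aliases matching the two roles the table plays.
AlleleFrequencyTable = FrequencyTable
ReferenceFrequencies = FrequencyTable


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: str | None
    dam: str | None
    sex: str = "unknown"
    birth_year: int | None = None


class Pedigree:
    """A forest of sire/dam records; parents referenced but not listed are
    auto-created as founders.  Construction verifies acyclicity."""

    def __init__(self, records: list[PedigreeRecord]):
        self.records: dict[str, PedigreeRecord] = {}
        for rec in records:
            if rec.id in self.records:
                raise ValidationError(f"duplicate pedigree id {rec.id!r}")
            self.records[rec.id] = rec
        for rec in list(self.records.values()):
            for parent in (rec.sire, rec.dam):
                if parent is not None and parent not in self.records:
                    self.records[parent] = PedigreeRecord(parent, None, None)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self.records}
        for start in self.records:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(self.parents(start)))]
            color[start] = GREY
            path = [start]
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if nxt is None:
                        continue
                    if color[nxt] == GREY:
                        cycle = path[path.index(nxt):] + [nxt]
                        raise ValidationError(
                            "pedigree cycle: " + " -> ".join(cycle)
                        )
                    if color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, iter(self.parents(nxt))))
                        path.append(nxt)
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()
                    path.pop()

    def __contains__(self, individual: str) -> bool:
        return individual in self.records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def individuals(self) -> list[str]:
        return list(self.records)

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        rec = self.records[individual]
        return rec.sire, rec.dam

    def founders(self) -> list[str]:
        return [i for i, r in self.records.items()
                if r.sire is None and r.dam is None]

    def ancestors(self, individual: str, max_generations: int | None = None):
        """IDs of all ancestors within ``max_generations`` (1 = parents)."""
        seen: set[str] = set()
        frontier = [individual]
        g = 0
        while frontier and (max_generations is None or g < max_generations):
            nxt = []
            for ind in frontier:
                for p in self.parents(ind):
                    if p is not None:
                        nxt.append(p)
                        seen.add(p)
            frontier = nxt
            g += 1
        return seen


@dataclass
class HaplotypeLookup:
    """Allele vector -> catalog name, per DLA region.

    Vectors have length 4 for class I and 3 for class II.
    """

    tables: dict[str, dict[tuple[int, ...], str]]

    def __post_init__(self) -> None:
        lengths = {DLA_CLASS_I: 4, DLA_CLASS_II: 3}
        for region, table in self.tables.items():
            want = lengths.get(region)
            names = list(table.values())
            if len(set(names)) != len(names):
                raise ValidationError(f"duplicate haplotype names in {region}")
            for vec in table:
                if want is not None and len(vec) != want:
                    raise ValidationError(
                        f"{region} vector {vec} has length {len(vec)}, "
                        f"expected {want}"
                    )

    def name(self, region: str, vector: tuple[int, ...]) -> str | None:
        return self.tables.get(region, {}).get(tuple(vector))


# ---------------------------------------------------------------------------
# CSV codecs
# ---------------------------------------------------------------------------

_META_COLS = ("population", "status", "sex")


def _parse_allele(token: str, where: str) -> int:
    token = token.strip()
    if token in ("", "0", "0.0", "NA", "nan"):
        return MISSING
    try:
        val = int(float(token))
    except ValueError as exc:
        raise ValidationError(f"bad allele {token!r} at {where}") from exc
    if val < 0:
        raise ValidationError(f"negative allele {token!r} at {where}")
    return val


def read_genotypes(path, locus_classes: dict[str, str] | None = None) -> GenotypeTable:
    """Read a genotype CSV: columns ``id[,population,status,sex]`` then two
    columns ``<locus>.1``, ``<locus>.2`` per locus.  Missing calls are coded
    0 or blank; a half-missing pair raises :class:`ValidationError`.

    DLA-linked loci named in :data:`DLA_I_LOCI` / :data:`DLA_II_LOCI` are
    classed automatically; ``locus_classes`` overrides.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValidationError("genotype CSV lacks an 'id' column")
    loci: list[str] = []
    for col in df.columns:
        if col.endswith(".1"):
            locus = col[:-2]
            if f"{locus}.2" not in df.columns:
                raise ValidationError(f"locus {locus!r} lacks a second column")
            loci.append(locus)
    if not loci:
        raise ValidationError("no '<locus>.1'/'<locus>.2' column pairs found")
    individuals = df["id"].tolist()
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for i, (a1, a2) in enumerate(zip(df[f"{locus}.1"], df[f"{locus}.2"])):
            where = f"individual {individuals[i]!r}, locus {locus!r}"
            calls[i, j, 0] = _parse_allele(a1, where)
            calls[i, j, 1] = _parse_allele(a2, where)
    classes = {}
    for locus in loci:
        if locus in DLA_I_LOCI:
            classes[locus] = DLA_CLASS_I
        elif locus in DLA_II_LOCI:
            classes[locus] = DLA_CLASS_II
        else:
            classes[locus] = GENOMIC
    if locus_classes:
        classes.update(locus_classes)
    return GenotypeTable(individuals, loci, calls, classes)


def write_genotypes(path, table: GenotypeTable,
                    metadata: pd.DataFrame | None = None) -> None:
    """Write a genotype CSV (round-trips through :func:`read_genotypes`).

    If ``metadata`` is given, its population/status/sex columns are written
    after ``id``.
    """
    out: dict[str, list] = {"id": table.individuals}
    if metadata is not None:
        meta = metadata.set_index("id") if "id" in metadata.columns else metadata
        for col in _META_COLS:
            if col in meta.columns:
                out[col] = [meta.at[i, col] for i in table.individuals]
    for j, locus in enumerate(table.loci):
        out[f"{locus}.1"] = table.calls[:, j, 0].tolist()
        out[f"{locus}.2"] = table.calls[:, j, 1].tolist()
    pd.DataFrame(out).to_csv(path, index=False)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata (id, population, status, sex[, age]) from a
    metadata CSV or from the metadata columns of a genotype CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValidationError("metadata CSV lacks an 'id' column")
    meta = pd.DataFrame({"id": df["id"]})
    for col in _META_COLS:
        meta[col] = df[col] if col in df.columns else "unknown"
    meta["status"] = meta["status"].replace("", "unknown")
    meta["sex"] = meta["sex"].replace("", "unknown")
    if "age" in df.columns:
        meta["age"] = pd.to_numeric(df["age"], errors="coerce")
    bad = ~meta["status"].isin(STATUS_VALUES)
    if bad.any():
        raise ValidationError(
            f"invalid status {meta.loc[bad, 'status'].iloc[0]!r}")
    bad = ~meta["sex"].isin(SEX_VALUES)
    if bad.any():
        raise ValidationError(f"invalid sex {meta.loc[bad, 'sex'].iloc[0]!r}")
    return meta


_UNKNOWN_PARENT = ("", "0", "NA", "UNKNOWN", "unknown")


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with columns id,sire,dam[,sex,birth_year].

    Unknown parents are blank or "0"; referenced-but-absent parents are
    auto-created as founders; cycles raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise ValidationError(f"pedigree CSV lacks column {col!r}")
    records = []
    for _, row in df.iterrows():
        sire = None if row["sire"].strip() in _UNKNOWN_PARENT else row["sire"].strip()
        dam = None if row["dam"].strip() in _UNKNOWN_PARENT else row["dam"].strip()
        sex = row.get("sex", "unknown") or "unknown"
        year = row.get("birth_year", "")
        records.append(PedigreeRecord(
            row["id"].strip(), sire, dam, sex,
            int(year) if str(year).strip() else None,
        ))
    return Pedigree(records)


def write_pedigree(path, pedigree: Pedigree) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sire", "dam", "sex", "birth_year"])
        for rec in pedigree.records.values():
            w.writerow([rec.id, rec.sire or "", rec.dam or "", rec.sex,
                        rec.birth_year if rec.birth_year is not None else ""])


def read_frequencies(path) -> FrequencyTable:
    """Read a locus,allele,frequency CSV (optional n_typed column)."""
    df = pd.read_csv(path)
    freqs: dict[str, dict[int, float]] = {}
    n_typed: dict[str, int] = {}
    for _, row in df.iterrows():
        freqs.setdefault(row["locus"], {})[int(row["allele"])] = float(row["frequency"])
        if "n_typed" in df.columns and not pd.isna(row["n_typed"]):
            n_typed[row["locus"]] = int(row["n_typed"])
    return FrequencyTable(freqs, n_typed)


def write_frequencies(path, table: FrequencyTable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["locus", "allele", "frequency", "n_typed"])
        for locus, alleles in table.freqs.items():
            for allele in sorted(alleles):
                w.writerow([locus, allele, repr(alleles[allele]),
                            table.n_typed.get(locus, "")])


def read_haplotype_lookup(path) -> HaplotypeLookup:
    """Read region,name,allele1..allele4 CSV (allele4 blank for class II)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    tables: dict[str, dict[tuple[int, ...], str]] = {}
    for _, row in df.iterrows():
        vec = tuple(
            int(row[c]) for c in ("allele1", "allele2", "allele3", "allele4")
            if c in df.columns and row[c].strip()
        )
        tables.setdefault(row["region"], {})[vec] = row["name"]
    return HaplotypeLookup(tables)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MendelianViolation:
    child: str
    parent: str
    locus: str
    child_genotype: tuple[int, int]
    parent_genotype: tuple[int, int]


def validate_mendelian(genotypes: GenotypeTable,
                       pedigree: Pedigree) -> list[MendelianViolation]:
    """Flag child/parent genotype pairs sharing no allele at a locus.

    Missing genotypes on either side are skipped; an empty list means no
    detectable Mendelian inconsistency.
    """
    violations = []
    for child in genotypes.individuals:
        if child not in pedigree:
            continue
        for parent in pedigree.parents(child):
            if parent is None or parent not in genotypes._ind_index:
                continue
            for locus in genotypes.loci:
                cg = genotypes.genotype(child, locus)
                pg = genotypes.genotype(parent, locus)
                if cg[0] == MISSING or pg[0] == MISSING:
                    continue
                if not set(cg) & set(pg):
                    violations.append(
                        MendelianViolation(child, parent, locus, cg, pg))
    return violations
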