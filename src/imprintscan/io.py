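"""File formats and core record types.

Intensity tables are plain TSV with fixed columns (sample_id, snp_id, assay,
x_raw, y_raw, genotype) — a lossless text rendering of the two-channel
allele signals the pipeline consumes.  Pedigrees are whitespace-delimited
PED-style files.  Gene models and locus calls travel as BED6; internal
coordinates are 1-based inclusive and converted on the way out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "ASSAYS",
    "GENOTYPES",
    "SnpDef",
    "IntensityRecord",
    "PedigreeMember",
    "Pedigree",
    "GeneModel",
    "ParseError",
    "read_intensity_table",
    "write_intensity_table",
    "read_pedigree",
    "write_pedigree",
    "read_gene_models_bed",
    "write_loci_bed",
]

ASSAYS = ("gDNA", "cDNA")
GENOTYPES = ("AA", "AB", "BB", "missing")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True, order=True)
class SnpDef:
    """A bi-allelic array SNP at a 1-based genomic position."""

    chrom: str
    pos: int
    snp_id: str
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")


@dataclass(frozen=True)
class IntensityRecord:
    """One two-channel measurement for a sample x SNP x assay."""

    sample_id: str
    snp_id: str
    assay: str
    x_raw: float
    y_raw: float
    genotype: str

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.x_raw < 0 or self.y_raw < 0:
            raise ValueError("raw intensities must be non-negative")

    @property
    def total(self) -> float:
        return self.x_raw + self.y_raw


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # '1' male, '2' female, '0' unknown
    generation: int = 0


@dataclass
class Pedigree:
    """A set of families with resolved parent links and generations."""

    members: list[PedigreeMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.individual_id: m for m in self.members}

    def __iter__(self) -> Iterator[PedigreeMember]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def get(self, individual_id: str) -> PedigreeMember:
        return self._by_id[individual_id]

    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    def children(self) -> list[PedigreeMember]:
        """Members with both parents present in the pedigree."""
        return [
            m
            for m in self.members
            if m.father_id in self._by_id and m.mother_id in self._by_id
        ]

    def families(self) -> dict[str, list[PedigreeMember]]:
        fams: dict[str, list[PedigreeMember]] = {}
        for m in self.members:
            fams.setdefault(m.family_id, []).append(m)
        return fams

    def trios(self) -> list[tuple[PedigreeMember, PedigreeMember, PedigreeMember]]:
        """(father, mother, child) triples for every child with both parents."""
        out = []
        for child in self.children():
            out.append((self._by_id[child.father_id], self._by_id[child.mother_id], child))
        return out

    def sibling_pairs(self) -> list[tuple[str, str]]:
        """Unordered pairs of full siblings (same father and mother)."""
        by_parents: dict[tuple[str, str], list[str]] = {}
        for c in self.children():
            by_parents.setdefault((c.father_id, c.mother_id), []).append(c.individual_id)
        pairs = []
        for sibs in by_parents.values():
            sibs = sorted(sibs)
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    pairs.append((sibs[i], sibs[j]))
        return pairs


@dataclass(frozen=True)
class GeneModel:
    """A transcript span, 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start must be < end")


# ---------------------------------------------------------------------------
# intensity tables

_INTENSITY_COLUMNS = ("sample_id", "snp_id", "assay", "x_raw", "y_raw", "genotype")


def read_intensity_table(
    path: str | Path, assay_filter: Optional[str] = None
) -> list[IntensityRecord]:
    """Parse a TSV intensity table, optionally keeping one assay only.

    Raises :class:`ParseError` naming the line for any malformed row.
    """
    if assay_filter is not None and assay_filter not in ASSAYS:
        raise ValueError(f"unknown assay {assay_filter!r}")
    records: list[IntensityRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _INTENSITY_COLUMNS:
            raise ParseError(
                f"{path}: bad header {header!r}, expected {list(_INTENSITY_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            sample_id, snp_id, assay, x_s, y_s, genotype = parts
            try:
                x_raw, y_raw = float(x_s), float(y_s)
                if not (math.isfinite(x_raw) and math.isfinite(y_raw)):
                    raise ValueError("non-finite intensity")
                rec = IntensityRecord(sample_id, snp_id, assay, x_raw, y_raw, genotype)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if assay_filter is None or rec.assay == assay_filter:
                records.append(rec)
    return records


def write_intensity_table(records: Iterable[IntensityRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_INTENSITY_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.snp_id}\t{r.assay}\t{r.x_raw:.6g}\t{r.y_raw:.6g}\t{r.genotype}\n"
            )


# ---------------------------------------------------------------------------
# pedigrees

def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a PED-style file: family, individual, father, mother, sex.

    '0' parent codes mean founder.  Generations are inferred from parent
    chains (founders are generation 1).  Dangling parent ids and cyclic
    parentage raise :class:`ParseError`.
    """
    rows: list[tuple[str, str, str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 columns")
            fam, ind, fa, mo, sex = parts[:5]
            rows.append((fam, ind, fa, mo, sex))
    ids = {ind for _, ind, _, _, _ in rows}
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    for fam, ind, fa, mo, sex in rows:
        fa_id = None if fa == "0" else fa
        mo_id = None if mo == "0" else mo
        for pid in (fa_id, mo_id):
            if pid is not None and pid not in ids:
                raise ParseError(f"{path}: individual {ind} references unknown parent {pid}")
        parents[ind] = (fa_id, mo_id)

    generation: dict[str, int] = {}

    def _gen(ind: str, stack: frozenset[str]) -> int:
        if ind in generation:
            return generation[ind]
        if ind in stack:
            raise ParseError(f"{path}: cyclic parentage involving {ind}")
        fa_id, mo_id = parents[ind]
        if fa_id is None and mo_id is None:
            g = 1
        else:
            stack = stack | {ind}
            g = 1 + max(_gen(p, stack) for p in (fa_id, mo_id) if p is not None)
        generation[ind] = g
        return g

    members = []
    for fam, ind, fa, mo, sex in rows:
        fa_id, mo_id = parents[ind]
        members.append(
            PedigreeMember(ind, fam, fa_id, mo_id, sex, _gen(ind, frozenset()))
        )
    return Pedigree(members)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in pedigree:
            fh.write(
                f"{m.family_id}\t{m.individual_id}\t{m.father_id or 0}\t"
                f"{m.mother_id or 0}\t{m.sex}\n"
            )


# ---------------------------------------------------------------------------
# BED

def read_gene_models_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open) into 1-based inclusive."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = parts[:3]
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "unknown"
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            models.append(GeneModel(name, chrom, start0 + 1, end0, strand))
    return models


def write_loci_bed(loci: Sequence, path: str | Path, track_name: str = "imprintscan_loci") -> None:
    """Write locus calls as BED6; name is the classification, score 100x mean
    magnitude capped at 1000.  Accepts any objects with chrom/start/end,
    classification and mean_magnitude attributes (1-based inclusive spans).
    """
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for locus in loci:
            score = min(1000, round(100 * float(locus.mean_magnitude)))
            fh.write(
                f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t"
                f"{locus.classification}\t{score}\t.\n"
            )
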