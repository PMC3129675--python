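"""Deterministic Mendelian phasing of trios and three-generation families.

Phase is deduced site by site from transmission constraints: the child's
genotype must be composed of one allele drawn from each parent, and whenever
only one such composition exists the parental origin of each child allele is
fixed.  The one undecidable configuration is the triple heterozygote
(child, father and mother all AB).  Within a locus, assuming no intra-locus
recombination in a single meiosis, triple-het sites are resolved by
identifying which parental haplotype was transmitted (when the parent is
itself phased, e.g. through grandparents) or, as a last-resort heuristic,
by copying the assignment of the nearest unambiguously phased flanking SNP.

The same transmitted-haplotype bookkeeping yields identical-by-descent (IBD)
sharing between siblings: two sibs share their paternal haplotype at a locus
when both received the same grandparental haplotype from the father.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .normalization import AEPoint

__all__ = [
    "PhasedGenotype",
    "TransmissionObservation",
    "IbdState",
    "alleles_of",
    "phase_trio_site",
    "resolve_ambiguous_by_flank",
    "phase_family_locus",
    "transmitted_haplotype",
    "parental_origin",
    "ibd_at_locus",
]

MENDELIAN = "mendelian"
FOUNDER_UNPHASED = "founder_unphased"
AMBIGUOUS = "ambiguous"
MENDELIAN_ERROR = "mendelian_error"


@dataclass(frozen=True)
class PhasedGenotype:
    individual_id: str
    snp_id: str
    paternal_allele: str  # 'A', 'B' or 'unknown'
    maternal_allele: str
    phase_source: str  # mendelian | founder_unphased | ambiguous | mendelian_error

    @property
    def is_phased(self) -> bool:
        return self.paternal_allele != "unknown" and self.maternal_allele != "unknown"


@dataclass(frozen=True)
class TransmissionObservation:
    """Parental origin of the overexpressed allele for one child at a locus/SNP."""

    child_id: str
    locus_id: str
    origin_of_overexpressed: str  # 'paternal' | 'maternal' | 'unknown'
    magnitude: float


@dataclass(frozen=True)
class IbdState:
    sibling_pair: tuple[str, str]
    locus_id: str
    shared_paternal: bool
    shared_maternal: bool

    @property
    def shared_both(self) -> bool:
        return self.shared_paternal and self.shared_maternal


def alleles_of(genotype: str) -> tuple[str, str]:
    if genotype not in ("AA", "AB", "BB"):
        raise ValueError(f"uncalled genotype {genotype!r}")
    return genotype[0], genotype[1]


def phase_trio_site(
    child: str,
    father: str,
    mother: str,
    child_id: str = "child",
    snp_id: str = "snp",
) -> PhasedGenotype:
    """Phase one child site from trio genotypes.

    Enumerates every (paternal, maternal) allele pair the parents could have
    transmitted; a unique compatible pair phases the site, several pairs
    (the triple heterozygote) leave it ambiguous, and none flags a Mendelian
    error (the site is excluded downstream).
    """
    child_set = tuple(sorted(alleles_of(child)))
    options = {
        (f, m)
        for f in set(alleles_of(father))
        for m in set(alleles_of(mother))
        if tuple(sorted((f, m))) == child_set
    }
    if not options:
        return PhasedGenotype(child_id, snp_id, "unknown", "unknown", MENDELIAN_ERROR)
    if len(options) == 1:
        f, m = next(iter(options))
        return PhasedGenotype(child_id, snp_id, f, m, MENDELIAN)
    return PhasedGenotype(child_id, snp_id, "unknown", "unknown", AMBIGUOUS)


def resolve_ambiguous_by_flank(
    phased: Mapping[str, PhasedGenotype], snp_order: Sequence[str]
) -> dict[str, PhasedGenotype]:
    """Heuristically resolve ambiguous sites from flanking phased SNPs.

    For each ambiguous (triple-het) site, the nearest unambiguously phased
    SNPs to the left and right within the locus are consulted; if the flanks
    that exist agree on which allele label sits on the paternal haplotype,
    the ambiguous site inherits that assignment (no intra-locus
    recombination assumed).  Conflicting flanks leave the site ambiguous.
    Use :func:`phase_family_locus` with parental phases when grandparental
    information is available; this label-copy fallback is only exact when
    haplotypes are allele-coherent across the locus.
    """
    order = [s for s in snp_order if s in phased]
    out = dict(phased)
    for i, snp in enumerate(order):
        pg = phased[snp]
        if pg.phase_source != AMBIGUOUS:
            continue
        left = next(
            (phased[order[j]] for j in range(i - 1, -1, -1)
             if phased[order[j]].phase_source == MENDELIAN and phased[order[j]].is_phased),
            None,
        )
        right = next(
            (phased[order[j]] for j in range(i + 1, len(order))
             if phased[order[j]].phase_source == MENDELIAN and phased[order[j]].is_phased),
            None,
        )
        votes = {f.paternal_allele for f in (left, right) if f is not None}
        if len(votes) == 1:
            pat = votes.pop()
            mat = "B" if pat == "A" else "A"
            out[snp] = PhasedGenotype(pg.individual_id, snp, pat, mat, MENDELIAN)
    return out


def transmitted_haplotype(
    child_phased: Mapping[str, PhasedGenotype],
    parent_phased: Mapping[str, PhasedGenotype],
    side: str,
) -> Optional[str]:
    """Which of the parent's haplotypes ('paternal'/'maternal', i.e. the
    grandparental origin) was transmitted to the child, judged over all
    decisive locus sites.  Returns None when no site is informative or when
    sites conflict (which would indicate recombination or a genotyping
    error, both excluded here).
    """
    votes = set()
    for snp, cpg in child_phased.items():
        ppg = parent_phased.get(snp)
        if ppg is None or not ppg.is_phased or not cpg.is_phased:
            continue
        if ppg.paternal_allele == ppg.maternal_allele:
            continue  # parent homozygous: uninformative
        child_allele = cpg.paternal_allele if side == "father" else cpg.maternal_allele
        votes.add("paternal" if ppg.paternal_allele == child_allele else "maternal")
    if len(votes) == 1:
        return votes.pop()
    return None


def phase_family_locus(
    child_genotypes: Mapping[str, str],
    father_genotypes: Mapping[str, str],
    mother_genotypes: Mapping[str, str],
    snp_order: Sequence[str],
    child_id: str = "child",
    father_phased: Optional[Mapping[str, PhasedGenotype]] = None,
    mother_phased: Optional[Mapping[str, PhasedGenotype]] = None,
    use_flank_heuristic: bool = False,
) -> dict[str, PhasedGenotype]:
    """Phase a child across one locus, resolving triple-hets where possible.

    Per-site Mendelian phasing first; then, if a parent's own phase is
    supplied (three-generation families), the transmitted grandparental
    haplotype is identified from decisive sites and used to fill ambiguous
    ones.  Without parental phase, triple-hets are genuinely unresolvable
    and stay ambiguous unless ``use_flank_heuristic`` opts into the
    label-copy approximation of :func:`resolve_ambiguous_by_flank`.
    """
    phased: dict[str, PhasedGenotype] = {}
    for snp in snp_order:
        if snp not in child_genotypes:
            continue
        phased[snp] = phase_trio_site(
            child_genotypes[snp], father_genotypes[snp], mother_genotypes[snp],
            child_id=child_id, snp_id=snp,
        )
    resolved = dict(phased)
    trans_f = (
        transmitted_haplotype(phased, father_phased, "father") if father_phased else None
    )
    trans_m = (
        transmitted_haplotype(phased, mother_phased, "mother") if mother_phased else None
    )
    if trans_f is not None or trans_m is not None:
        for snp, pg in phased.items():
            if pg.phase_source != AMBIGUOUS:
                continue
            pat: Optional[str] = None
            if trans_f is not None and father_phased is not None:
                fpg = father_phased.get(snp)
                if fpg is not None and fpg.is_phased:
                    pat = (
                        fpg.paternal_allele if trans_f == "paternal" else fpg.maternal_allele
                    )
            if pat is None and trans_m is not None and mother_phased is not None:
                mpg = mother_phased.get(snp)
                if mpg is not None and mpg.is_phased:
                    mat = (
                        mpg.paternal_allele if trans_m == "paternal" else mpg.maternal_allele
                    )
                    pat = "B" if mat == "A" else "A"  # child is AB at a triple-het
            if pat is not None:
                resolved[snp] = PhasedGenotype(
                    pg.individual_id, snp, pat, "B" if pat == "A" else "A", MENDELIAN
                )
        return resolved
    if use_flank_heuristic:
        return resolve_ambiguous_by_flank(phased, snp_order)
    return resolved


def parental_origin(
    ae_point: AEPoint, phased: PhasedGenotype, locus_id: str = ""
) -> TransmissionObservation:
    """Assign the parental origin of the overexpressed allele at one SNP."""
    if (
        not ae_point.informative
        or ae_point.overexpressed_allele is None
        or not phased.is_phased
        or phased.phase_source in (AMBIGUOUS, MENDELIAN_ERROR)
    ):
        return TransmissionObservation(
            ae_point.sample_id, locus_id, "unknown", ae_point.magnitude
        )
    origin = (
        "paternal"
        if ae_point.overexpressed_allele == phased.paternal_allele
        else "maternal"
    )
    return TransmissionObservation(ae_point.sample_id, locus_id, origin, ae_point.magnitude)


def ibd_at_locus(
    sib1_phased: Mapping[str, PhasedGenotype],
    sib2_phased: Mapping[str, PhasedGenotype],
    father_phased: Mapping[str, PhasedGenotype],
    mother_phased: Mapping[str, PhasedGenotype],
    pair: tuple[str, str],
    locus_id: str = "",
) -> Optional[IbdState]:
    """IBD sharing for a sibling pair at one locus.

    Each sibling's transmitted grandparental haplotype is resolved through
    the parent's phase; the pair shares the paternal (maternal) haplotype
    when both received the same grandparental haplotype from the father
    (mother).  Returns None when grandparental origin is unresolvable for
    either sibling on either side.
    """
    t1f = transmitted_haplotype(sib1_phased, father_phased, "father")
    t2f = transmitted_haplotype(sib2_phased, father_phased, "father")
    t1m = transmitted_haplotype(sib1_phased, mother_phased, "mother")
    t2m = transmitted_haplotype(sib2_phased, mother_phased, "mother")
    if None in (t1f, t2f, t1m, t2m):
        return None
    return IbdState(pair, locus_id, t1f == t2f, t1m == t2m)
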