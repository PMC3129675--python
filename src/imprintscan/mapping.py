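"""Heritability mapping: is an allelic-expression locus explained by a
local cis-regulatory variant?

Under a cis-genetic model, allelic imbalance appears exactly in individuals
heterozygous for the regulatory variant (homozygotes carry two equal-output
copies), and the overexpressed haplotype is the one in cis with the
high-expression regulatory allele.  The test scores, for every candidate
SNP near the locus, the fraction of unrelated individuals whose observed
allelic-expression status (and direction, where a phase is available)
matches that prediction; a concordance of at least ``mapping_concordance``
maps the locus.  Imprinting produces allelic imbalance in (nearly) all
informative individuals regardless of local genotype, so imprinted loci
should not map.

Mapped candidates are then checked for Mendelian transmission in the
pedigrees: every informative transmission must carry the allelic-expression
status along with the candidate genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .config import RunConfig

__all__ = ["IndividualAe", "MappingResult", "map_ae_to_cis_snp", "check_mendelian_transmission"]


@dataclass(frozen=True)
class IndividualAe:
    """One unrelated individual's allelic-expression call at a locus.

    ``cis_allele_by_candidate`` gives, per candidate SNP at which the
    individual is heterozygous, the candidate allele lying on the
    overexpressed haplotype — when a phase between the candidate and the
    expressed site could be established (e.g. through transmission to a
    child); otherwise the direction is left unknown and only presence or
    absence of allelic expression is scored.
    """

    individual_id: str
    ae_present: bool
    genotype_by_candidate: Mapping[str, str]  # candidate snp -> AA/AB/BB
    cis_allele_by_candidate: Mapping[str, str] = None  # type: ignore[assignment]

    def cis_allele(self, candidate: str) -> Optional[str]:
        if not self.cis_allele_by_candidate:
            return None
        return self.cis_allele_by_candidate.get(candidate)


@dataclass(frozen=True)
class MappingResult:
    locus_id: str
    candidate_snp: Optional[str]
    concordance_score: float
    mapped: bool
    n_individuals: int
    mendelian_transmission: str = "not_informative"  # yes | no | not_informative


def map_ae_to_cis_snp(
    locus_id: str,
    individuals: Sequence[IndividualAe],
    candidate_snps: Iterable[str],
    config: RunConfig | None = None,
) -> MappingResult:
    """Scan candidate SNPs for one whose heterozygosity predicts the AE.

    For a candidate with high-expression allele H, the prediction per
    individual is: heterozygote -> AE present with the overexpressed
    haplotype carrying H; homozygote -> no AE.  The score for a candidate is
    the best match fraction over both orientations of H; the locus maps when
    the best candidate reaches ``config.mapping_concordance`` with at least
    ``config.min_mapping_individuals`` scoreable individuals.
    """
    config = config or RunConfig()
    best_snp: Optional[str] = None
    best_score = 0.0
    n_used = 0
    for cand in candidate_snps:
        scored = [ind for ind in individuals if cand in ind.genotype_by_candidate]
        if len(scored) < config.min_mapping_individuals:
            continue
        for high_allele in ("A", "B"):
            matches = 0
            for ind in scored:
                het = ind.genotype_by_candidate[cand] == "AB"
                if het:
                    cis = ind.cis_allele(cand)
                    ok = ind.ae_present and (cis is None or cis == high_allele)
                else:
                    ok = not ind.ae_present
                matches += ok
            score = matches / len(scored)
            if score > best_score or (score == best_score and best_snp is None):
                best_snp, best_score, n_used = cand, score, len(scored)
    mapped = best_snp is not None and best_score >= config.mapping_concordance
    return MappingResult(
        locus_id=locus_id,
        candidate_snp=best_snp if mapped else None,
        concordance_score=best_score,
        mapped=mapped,
        n_individuals=n_used,
    )


def check_mendelian_transmission(
    candidate_snp: str,
    trios: Sequence[tuple[str, str, str]],  # (father gt, mother gt, child gt)
    child_ae_present: Sequence[bool],
    config: RunConfig | None = None,
) -> str:
    """Does the mapped variant travel with the AE through the pedigrees?

    A transmission is informative when at least one parent is heterozygous
    at the candidate (so the child's regulatory genotype is not forced).
    Prediction: the child shows allelic expression iff heterozygous at the
    candidate.  Any contradiction -> 'no'; no informative transmission ->
    'not_informative'; otherwise 'yes'.
    """
    informative = 0
    for (father_gt, mother_gt, child_gt), ae in zip(trios, child_ae_present):
        if "AB" not in (father_gt, mother_gt):
            continue
        informative += 1
        predicted = child_gt == "AB"
        if predicted != ae:
            return "no"
    return "yes" if informative else "not_informative"
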