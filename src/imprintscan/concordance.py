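"""Allelic-expression concordance in identical-by-descent sibling pairs.

Siblings sharing both parental haplotypes at a locus carry identical
genotype and identical parental origins there, so imprinted or cis-heritable
allelic expression should look the same in both: same overexpressed
haplotype, both above the 1.5-fold bias threshold.  Random monoallelic
expression, by contrast, silences a haplotype independently per cell line,
producing discordance despite IBD.  The 2x2 association between treatment
response and IBD discordance is tested with both an uncorrected chi-square
and a two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .config import RunConfig
from .phasing import IbdState

__all__ = ["PairConcordance", "ConcordanceTable", "classify_pair", "aggregate_and_test"]


@dataclass(frozen=True)
class PairConcordance:
    locus_id: str
    pair: tuple[str, str]
    status: str  # 'concordant' | 'discordant' | 'uninformative'
    reason: str = ""


@dataclass(frozen=True)
class ConcordanceTable:
    group_labels: tuple[str, str]
    concordant: tuple[int, int]
    discordant: tuple[int, int]
    discordance_percent: tuple[float, float]  # nearest-integer percentages
    chi_square: float
    p_chi: float
    p_fisher: float
    odds_ratio: float


def classify_pair(
    sib1: tuple[float, Optional[str]],
    sib2: tuple[float, Optional[str]],
    ibd: Optional[IbdState],
    config: RunConfig | None = None,
    locus_id: str = "",
    pair: tuple[str, str] = ("sib1", "sib2"),
) -> PairConcordance:
    """Concordance of one IBD sibling pair at one locus.

    ``sib1``/``sib2`` are (allelic magnitude, overexpressed haplotype) where
    the haplotype is 'paternal'/'maternal' or None for balanced expression.
    Requires the pair to share both parental haplotypes at the locus;
    otherwise the call is uninformative.  Both sibs biased (> ibd_fold)
    toward the same haplotype -> concordant; one biased and the other
    biallelic (<= ibd_fold), or both biased toward opposite haplotypes ->
    discordant; neither biased -> uninformative.
    """
    config = config or RunConfig()
    if ibd is None or not (ibd.shared_paternal and ibd.shared_maternal):
        return PairConcordance(locus_id, pair, "uninformative", "pair not IBD at locus")
    m1, h1 = sib1
    m2, h2 = sib2
    b1 = m1 > config.ibd_fold
    b2 = m2 > config.ibd_fold
    if b1 and b2:
        status = "concordant" if (h1 is not None and h1 == h2) else "discordant"
        reason = "" if status == "concordant" else "opposite haplotype overexpressed"
        return PairConcordance(locus_id, pair, status, reason)
    if b1 != b2:
        return PairConcordance(locus_id, pair, "discordant", "one sibling biallelic")
    return PairConcordance(locus_id, pair, "uninformative", "both siblings biallelic")


def aggregate_and_test(
    calls_by_group: Mapping[str, Iterable[PairConcordance]],
) -> ConcordanceTable:
    """2x2 association between group membership and pair discordance.

    ``calls_by_group`` maps exactly two group labels (e.g. treatment-affected
    vs unaffected loci) to their pair calls; uninformative calls are dropped.
    Reports chi-square (1 df, no continuity correction), two-sided Fisher
    exact, the sample odds ratio, and each group's discordance percentage
    rounded to the nearest integer.
    """
    if len(calls_by_group) != 2:
        raise ValueError("exactly two groups required")
    labels = tuple(calls_by_group)
    conc, disc = [], []
    for label in labels:
        calls = [c for c in calls_by_group[label] if c.status != "uninformative"]
        if not calls:
            raise ValueError(f"group {label!r} has no informative pair calls")
        conc.append(sum(c.status == "concordant" for c in calls))
        disc.append(sum(c.status == "discordant" for c in calls))
    table = np.array([[conc[0], disc[0]], [conc[1], disc[1]]])
    chi2, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
    odds_ratio, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    pct = tuple(
        round(100.0 * d / (c + d)) for c, d in zip(conc, disc)
    )
    return ConcordanceTable(
        group_labels=labels,
        concordant=tuple(conc),
        discordant=tuple(disc),
        discordance_percent=pct,
        chi_square=float(chi2),
        p_chi=float(p_chi),
        p_fisher=float(p_fisher),
        odds_ratio=float(odds_ratio),
    )
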