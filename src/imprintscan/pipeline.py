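"""End-to-end discovery pipeline and truth-based scoring.

Order of operations mirrors the reference analysis: the bias curve is
calibrated on genomic-DNA heterozygotes of the whole panel and applied to
both assays; allelic-expression points are computed per sample at
informative sites; the extreme scan (> 2.9-fold) finds candidate windows
among the panel's children, which merge into loci; each locus is phased
through the pedigrees to obtain the parental origin of the overexpressed
allele per child, and mapped against local SNP genotypes of the unrelated
founders; consistent parental origin with a negative mapping is called
imprinted, a positive mapping heritable.  A second, moderate scan
(2-2.9-fold) feeds the partial-imprinting screen after excluding the
neighbourhoods of classically imprinted loci.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import RunConfig
from .io import IntensityRecord, Pedigree, SnpDef
from .mapping import IndividualAe, MappingResult, map_ae_to_cis_snp
from .normalization import (
    AEPoint,
    BiasCurve,
    beta_observation,
    fit_bias_curve,
    make_ae_points,
)
from .phasing import (
    PhasedGenotype,
    TransmissionObservation,
    parental_origin,
    phase_family_locus,
    phase_trio_site,
)
from .scan import (
    Locus,
    SiteTransmission,
    classify_locus,
    classify_transmission,
    detect_partial_imprinting,
    merge_windows_to_loci,
    scan_windows,
)
from .simulate import Simulation

__all__ = [
    "DiscoveryResult",
    "ae_points_by_sample",
    "locus_magnitude",
    "run_discovery",
    "score_against_truth",
    "treatment_records_for_loci",
]


@dataclass
class DiscoveryResult:
    curve: BiasCurve
    ae_points: dict[str, dict[str, AEPoint]]
    extreme_loci: list[Locus]
    partial_loci: list[Locus]
    moderate_heritable_loci: list[Locus]
    mapping_by_locus: dict[str, MappingResult]
    transmissions_by_locus: dict[str, list[TransmissionObservation]]
    site_observations_by_locus: dict[str, list[SiteTransmission]]

    @property
    def classified_loci(self) -> list[Locus]:
        return self.extreme_loci + self.partial_loci + self.moderate_heritable_loci


def ae_points_by_sample(
    records: Sequence[IntensityRecord],
    curve: BiasCurve,
    config: RunConfig,
) -> dict[str, dict[str, AEPoint]]:
    """sample -> snp -> AEPoint from a mixed gDNA/cDNA record collection."""
    gdna = defaultdict(list)
    cdna = defaultdict(list)
    for r in records:
        (gdna if r.assay == "gDNA" else cdna)[r.sample_id].append(r)
    out: dict[str, dict[str, AEPoint]] = {}
    for sample, recs in cdna.items():
        pts = make_ae_points(recs, gdna.get(sample, []), curve, config)
        out[sample] = {p.snp_id: p for p in pts}
    return out


def locus_magnitude(
    points: Mapping[str, AEPoint], snp_ids: Sequence[str]
) -> Optional[float]:
    mags = [points[s].magnitude for s in snp_ids if s in points and points[s].informative]
    return sum(mags) / len(mags) if mags else None


# ---------------------------------------------------------------------------
# phasing helpers

def _genotype_table(records: Sequence[IntensityRecord]) -> dict[tuple[str, str], str]:
    """(sample, snp) -> genotype call, from the gDNA assay."""
    gt = {}
    for r in records:
        if r.assay == "gDNA" and r.genotype != "missing":
            gt[(r.sample_id, r.snp_id)] = r.genotype
    return gt


def _phase_individual_locus(
    ind: str,
    snp_ids: Sequence[str],
    gt: Mapping[tuple[str, str], str],
    pedigree: Pedigree,
    _cache: dict,
) -> Optional[dict[str, PhasedGenotype]]:
    """Phase one (non-founder) individual over a locus, recursively phasing
    the parents when they have parents of their own (three-generation
    families)."""
    key = (ind, tuple(snp_ids))
    if key in _cache:
        return _cache[key]
    member = pedigree.get(ind)
    if member.father_id is None or member.mother_id is None:
        _cache[key] = None
        return None

    def geno_of(who: str) -> dict[str, str]:
        return {s: gt[(who, s)] for s in snp_ids if (who, s) in gt}

    child_g = geno_of(ind)
    father_g = geno_of(member.father_id)
    mother_g = geno_of(member.mother_id)
    usable = [s for s in snp_ids if s in child_g and s in father_g and s in mother_g]
    father_ph = _phase_individual_locus(member.father_id, snp_ids, gt, pedigree, _cache)
    mother_ph = _phase_individual_locus(member.mother_id, snp_ids, gt, pedigree, _cache)
    phased = phase_family_locus(
        {s: child_g[s] for s in usable},
        father_g,
        mother_g,
        usable,
        child_id=ind,
        father_phased=father_ph,
        mother_phased=mother_ph,
    )
    _cache[key] = phased
    return phased


def _locus_transmissions(
    locus: Locus,
    children: Sequence[str],
    ae_points: Mapping[str, Mapping[str, AEPoint]],
    gt: Mapping[tuple[str, str], str],
    pedigree: Pedigree,
    config: RunConfig,
    phase_cache: dict,
) -> tuple[list[TransmissionObservation], list[SiteTransmission]]:
    """Per-child locus-level origin votes plus the per-site records.

    A child's locus-level origin is the majority of its per-site origins
    over sites with genuine allelic bias (magnitude at or above the
    moderate-AE floor); a tie or no voting site leaves it unknown.
    """
    transmissions: list[TransmissionObservation] = []
    site_obs: list[SiteTransmission] = []
    for child in children:
        phased = _phase_individual_locus(child, locus.snp_ids, gt, pedigree, phase_cache)
        if phased is None:
            continue
        votes = {"paternal": 0, "maternal": 0}
        mags: list[float] = []
        points = ae_points.get(child, {})
        for snp in locus.snp_ids:
            ae = points.get(snp)
            pg = phased.get(snp)
            if ae is None or pg is None:
                continue
            obs = parental_origin(ae, pg, locus.locus_id)
            site_obs.append(
                SiteTransmission(child, snp, obs.origin_of_overexpressed,
                                 ae.overexpressed_allele, ae.magnitude)
            )
            if (
                obs.origin_of_overexpressed != "unknown"
                and ae.magnitude >= config.partial_fold_low
            ):
                votes[obs.origin_of_overexpressed] += 1
                mags.append(ae.magnitude)
        if votes["paternal"] > votes["maternal"]:
            origin = "paternal"
        elif votes["maternal"] > votes["paternal"]:
            origin = "maternal"
        else:
            origin = "unknown"
        transmissions.append(
            TransmissionObservation(
                child, locus.locus_id, origin,
                float(np.mean(mags)) if mags else 1.0,
            )
        )
    return transmissions, site_obs


# ---------------------------------------------------------------------------
# founder phase reconstruction for cis mapping

def _founder_cis_data(
    founder: str,
    locus: Locus,
    candidates: Sequence[str],
    ae_points: Mapping[str, Mapping[str, AEPoint]],
    gt: Mapping[tuple[str, str], str],
    pedigree: Pedigree,
    config: RunConfig,
) -> Optional[IndividualAe]:
    """One founder's AE status and phased direction info at a locus.

    The founder's haplotype pair is partially reconstructed from transmission
    to its first child (the transmitted allele at every site where the trio
    phases that child decisively); the overexpressed haplotype is then voted
    over the locus' informative sites, and its allele read off at each
    phased candidate.
    """
    points = ae_points.get(founder, {})
    mag = locus_magnitude(points, locus.snp_ids)
    if mag is None:
        return None
    ae_present = mag >= config.partial_fold_low

    child = next(
        (
            m.individual_id
            for m in pedigree.children()
            if founder in (m.father_id, m.mother_id)
        ),
        None,
    )
    hap_t: dict[str, str] = {}
    hap_u: dict[str, str] = {}
    if child is not None:
        member = pedigree.get(child)
        side = "father" if member.father_id == founder else "mother"
        co_parent = member.mother_id if side == "father" else member.father_id
        for snp in candidates:
            trio = [(child, snp), (member.father_id, snp), (member.mother_id, snp)]
            if any(k not in gt for k in trio):
                continue
            pg = phase_trio_site(
                gt[(child, snp)], gt[(member.father_id, snp)], gt[(member.mother_id, snp)]
            )
            if not pg.is_phased:
                continue
            transmitted = pg.paternal_allele if side == "father" else pg.maternal_allele
            f_gt = gt[(founder, snp)]
            if f_gt == "AB":
                hap_t[snp] = transmitted
                hap_u[snp] = "B" if transmitted == "A" else "A"

    # which reconstructed haplotype is the overexpressed one, voted over
    # the locus' informative sites
    votes = {"T": 0, "U": 0}
    for snp in locus.snp_ids:
        ae = points.get(snp)
        if ae is None or not ae.informative or ae.overexpressed_allele is None:
            continue
        if ae.magnitude < config.partial_fold_low or snp not in hap_t:
            continue
        votes["T" if ae.overexpressed_allele == hap_t[snp] else "U"] += 1
    over_hap = None
    if votes["T"] > votes["U"]:
        over_hap = "T"
    elif votes["U"] > votes["T"]:
        over_hap = "U"

    genotype_by_candidate = {
        snp: gt[(founder, snp)] for snp in candidates if (founder, snp) in gt
    }
    cis: dict[str, str] = {}
    if ae_present and over_hap is not None:
        source = hap_t if over_hap == "T" else hap_u
        for snp in candidates:
            if genotype_by_candidate.get(snp) == "AB" and snp in source:
                cis[snp] = source[snp]
    return IndividualAe(founder, ae_present, genotype_by_candidate, cis)


def _map_locus(
    locus: Locus,
    snps: Sequence[SnpDef],
    ae_points: Mapping[str, Mapping[str, AEPoint]],
    gt: Mapping[tuple[str, str], str],
    pedigree: Pedigree,
    config: RunConfig,
) -> MappingResult:
    candidates = [
        s.snp_id
        for s in snps
        if s.chrom == locus.chrom
        and locus.start - config.cis_window_bp <= s.pos <= locus.end + config.cis_window_bp
    ]
    individuals = []
    for founder in pedigree.founders():
        data = _founder_cis_data(
            founder.individual_id, locus, candidates, ae_points, gt, pedigree, config
        )
        if data is not None:
            individuals.append(data)
    return map_ae_to_cis_snp(locus.locus_id, individuals, candidates, config)


# ---------------------------------------------------------------------------
# full discovery

def run_discovery(
    records: Sequence[IntensityRecord],
    pedigree: Pedigree,
    snps: Sequence[SnpDef],
    config: RunConfig | None = None,
) -> DiscoveryResult:
    """Run the complete discovery pipeline on one cell-type panel."""
    config = config or RunConfig()
    gdna_hets = [
        beta_observation(r)
        for r in records
        if r.assay == "gDNA" and r.genotype == "AB" and r.total > 0
    ]
    curve = fit_bias_curve(gdna_hets, config)
    ae_points = ae_points_by_sample(records, curve, config)
    gt = _genotype_table(records)
    children = [m.individual_id for m in pedigree.children()]
    child_ae = {c: ae_points.get(c, {}) for c in children}
    phase_cache: dict = {}

    mapping_by_locus: dict[str, MappingResult] = {}
    transmissions_by_locus: dict[str, list[TransmissionObservation]] = {}
    site_obs_by_locus: dict[str, list[SiteTransmission]] = {}

    def annotate(locus: Locus) -> None:
        trans, site_obs = _locus_transmissions(
            locus, children, ae_points, gt, pedigree, config, phase_cache
        )
        transmissions_by_locus[locus.locus_id] = trans
        site_obs_by_locus[locus.locus_id] = site_obs
        mapping_by_locus[locus.locus_id] = _map_locus(
            locus, snps, ae_points, gt, pedigree, config
        )

    # extreme scan
    extreme_windows = scan_windows(child_ae, snps, config)
    extreme_loci = merge_windows_to_loci(extreme_windows, config)
    classified: list[Locus] = []
    for locus in extreme_loci:
        annotate(locus)
        t_class = classify_transmission(transmissions_by_locus[locus.locus_id], config)
        locus = classify_locus(locus, t_class, mapping_by_locus[locus.locus_id].mapped)
        locus.transmissions = tuple(transmissions_by_locus[locus.locus_id])
        classified.append(locus)

    # moderate scan and partial-imprinting screen
    moderate_windows = scan_windows(
        child_ae, snps, config, fold_range=(config.partial_fold_low, config.partial_fold_high)
    )
    moderate_loci = merge_windows_to_loci(moderate_windows, config)
    for locus in moderate_loci:
        annotate(locus)
    classic = [
        l for l in classified
        if l.classification in ("imprinted_paternal_expressed", "imprinted_maternal_expressed")
    ]
    partial = detect_partial_imprinting(
        moderate_loci,
        classic,
        {lid: m.mapped for lid, m in mapping_by_locus.items()},
        transmissions_by_locus,
        site_obs_by_locus,
        config,
    )
    moderate_heritable = [
        classify_locus(l, "unclassified", True)
        for l in moderate_loci
        if mapping_by_locus[l.locus_id].mapped
    ]
    return DiscoveryResult(
        curve=curve,
        ae_points=ae_points,
        extreme_loci=classified,
        partial_loci=partial,
        moderate_heritable_loci=moderate_heritable,
        mapping_by_locus=mapping_by_locus,
        transmissions_by_locus=transmissions_by_locus,
        site_observations_by_locus=site_obs_by_locus,
    )


def treatment_records_for_loci(
    untreated_ae: Mapping[str, Mapping[str, AEPoint]],
    treated_ae_by_timepoint: Mapping[str, Mapping[str, Mapping[str, AEPoint]]],
    locus_snp_ids: Mapping[str, Sequence[str]],
    samples: Sequence[str],
    final_timepoint: Optional[str] = None,
):
    """Per-locus untreated/treated magnitude records for treatment calls.

    ``treated_ae_by_timepoint`` maps timepoint -> sample -> snp -> AEPoint.
    The treated magnitude of a sample is taken at ``final_timepoint`` (the
    last key by default); all timepoints populate the record's time course.
    """
    from .treatment import TreatmentRecord

    timepoints = list(treated_ae_by_timepoint)
    final_timepoint = final_timepoint or timepoints[-1]
    out: dict[str, list[TreatmentRecord]] = {}
    for locus_id, snp_ids in locus_snp_ids.items():
        records = []
        for sample in samples:
            mu = locus_magnitude(untreated_ae.get(sample, {}), snp_ids)
            if mu is None:
                continue
            by_tp = {}
            for tp in timepoints:
                m = locus_magnitude(
                    treated_ae_by_timepoint[tp].get(sample, {}), snp_ids
                )
                if m is not None:
                    by_tp[tp] = m
            records.append(
                TreatmentRecord(
                    locus_id, sample, mu, by_tp.get(final_timepoint), by_tp
                )
            )
        if records:
            out[locus_id] = records
    return out


# ---------------------------------------------------------------------------
# truth scoring

_IMPRINTED_CALLS = ("imprinted_paternal_expressed", "imprinted_maternal_expressed")


def _overlap(locus: Locus, truth_chrom: str, truth_start: int, truth_end: int) -> int:
    if locus.chrom != truth_chrom:
        return 0
    return max(0, min(locus.end, truth_end) - max(locus.start, truth_start) + 1)


def score_against_truth(result: DiscoveryResult, sim: Simulation) -> dict[str, float]:
    """Compare classified loci with the simulator's truth.

    Predicted loci are assigned to the truth locus they overlap most.
    Returns imprinted sensitivity and precision, the fraction of heritable
    loci miscalled imprinted, the fraction of detected heritable loci
    called heritable, and parental-origin accuracy among correctly
    detected imprinted loci.
    """
    truths = sim.loci
    assigned: dict[str, list] = defaultdict(list)  # truth locus id -> predictions
    for locus in result.classified_loci:
        best, best_ov = None, 0
        for t in truths:
            ov = _overlap(locus, t.chrom, t.start, t.end)
            if ov > best_ov:
                best, best_ov = t, ov
        if best is not None:
            assigned[best.locus_id].append(locus)

    true_imprinted = [t for t in truths if t.locus_class.startswith("imprinted")]
    true_heritable = [t for t in truths if t.locus_class == "heritable_cis"]

    detected_imprinted = 0
    origin_correct = 0
    origin_total = 0
    for t in true_imprinted:
        calls = [l.classification for l in assigned.get(t.locus_id, [])]
        if any(c in _IMPRINTED_CALLS for c in calls):
            detected_imprinted += 1
            origin_total += 1
            expected = (
                "imprinted_paternal_expressed"
                if t.locus_class == "imprinted_paternal"
                else "imprinted_maternal_expressed"
            )
            if expected in calls:
                origin_correct += 1

    # precision counts any parent-of-origin truth class (imprinted or
    # partial) as a correct imprinted detection: a partial locus whose noisy
    # means cross the extreme threshold is still genuinely imprinted
    parent_of_origin = ("imprinted_paternal", "imprinted_maternal", "partial")
    imprinted_predictions = [
        l for l in result.classified_loci if l.classification in _IMPRINTED_CALLS
    ]
    true_pos_predictions = 0
    for locus in imprinted_predictions:
        best, best_ov = None, 0
        for t in truths:
            ov = _overlap(locus, t.chrom, t.start, t.end)
            if ov > best_ov:
                best, best_ov = t, ov
        if best is not None and best.locus_class in parent_of_origin:
            true_pos_predictions += 1

    heritable_as_imprinted = sum(
        1
        for t in true_heritable
        if any(l.classification in _IMPRINTED_CALLS for l in assigned.get(t.locus_id, []))
    )
    heritable_detected = [t for t in true_heritable if assigned.get(t.locus_id)]
    heritable_called = sum(
        1
        for t in heritable_detected
        if any(l.classification == "heritable" for l in assigned.get(t.locus_id, []))
    )

    return {
        "n_true_imprinted": len(true_imprinted),
        "imprinted_sensitivity": detected_imprinted / len(true_imprinted)
        if true_imprinted
        else float("nan"),
        "imprinted_precision": true_pos_predictions / len(imprinted_predictions)
        if imprinted_predictions
        else float("nan"),
        "origin_accuracy": origin_correct / origin_total if origin_total else float("nan"),
        "heritable_as_imprinted": heritable_as_imprinted / len(true_heritable)
        if true_heritable
        else float("nan"),
        "n_heritable_detected": float(len(heritable_detected)),
        "heritable_called_heritable": heritable_called / len(heritable_detected)
        if heritable_detected
        else float("nan"),
        "n_imprinted_predictions": float(len(imprinted_predictions)),
    }
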