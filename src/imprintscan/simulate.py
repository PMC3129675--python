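"""Synthetic family-based allelic-expression panels with known truth.

The generator emulates the statistical structure the pipeline assumes:

* a panel of parent-offspring trios plus one three-generation family
  (grandparents, two parents, several children), founder haplotypes drawn
  under Hardy-Weinberg at a per-SNP minor-allele frequency, children
  receiving one intact parental haplotype per locus (no intra-locus
  recombination in one meiosis);
* loci of known class: classically imprinted (one parental haplotype
  silenced to a small residual fraction, ~8-fold allelic imbalance),
  partially imprinted (2-2.9-fold parental bias), cis-heritable (imbalance
  in regulatory-SNP heterozygotes, direction set by phase), random
  monoallelic (a per-individual random haplotype silenced, the clonal-LCL
  phenomenon), and biallelic;
* a two-channel intensity model: lognormal total intensity, observed beta
  equal to the true allelic fraction plus a quadratic intensity-dependent
  bias plus Gaussian noise, channels reconstructed as X = T*beta,
  Y = T*(1-beta) — the distortion the bin-median normalization removes;
* a demethylation-treatment model in which random-monoallelic loci move
  toward balanced expression by a configurable fraction per timepoint while
  imprinted and heritable loci only fluctuate with noise, plus a
  methyl-pulldown intensity panel losing signal at demethylated sites.

Every random draw flows from one seeded NumPy generator (PCG64), so a fixed
seed reproduces the panel exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io import IntensityRecord, Pedigree, PedigreeMember, SnpDef

__all__ = [
    "SimConfig",
    "LocusTruth",
    "Simulation",
    "MbdTruth",
    "simulate_pedigree_genotypes",
    "simulate_expression_signals",
    "simulate_treatment",
    "simulate_panel",
]

LOCUS_CLASSES = (
    "imprinted_paternal",
    "imprinted_maternal",
    "partial",
    "heritable_cis",
    "rme",
    "biallelic",
)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic panel."""

    n_trios: int = 9
    include_three_generation: bool = True
    n_family_children: int = 6
    n_loci: dict[str, int] = field(
        default_factory=lambda: {
            "imprinted_paternal": 10,
            "imprinted_maternal": 10,
            "partial": 6,
            "heritable_cis": 10,
            "rme": 10,
            "biallelic": 14,
        }
    )
    snps_per_locus: tuple[int, int] = (5, 12)
    maf_range: tuple[float, float] = (0.1, 0.5)
    silenced_allele_fraction: float = 1.0 / 9.0  # residual share of a silenced haplotype
    partial_fold_range: tuple[float, float] = (2.0, 2.9)
    heritable_fold_range: tuple[float, float] = (2.0, 6.0)
    bias_coefficients: tuple[float, float, float] = (-0.42, 0.19, -0.02)  # a, b1, b2
    intensity_log_mean: float = 3.5
    intensity_log_sd: float = 0.35
    beta_noise_sd: float = 0.02
    treatment_response: float = 0.5  # fraction of RME silencing reverted per timepoint
    mbd_n_sites: int = 2000
    mbd_affected_fraction: float = 0.8
    mbd_reduction: float = 0.5
    mbd_site_mean: float = 4000.0
    mbd_site_sd: float = 600.0
    mbd_noise_sd: float = 250.0
    n_chromosomes: int = 4
    locus_spacing_bp: int = 400_000
    snp_spacing_bp: int = 2_000
    rng_seed: int = 0

    def bias(self, log_total: np.ndarray | float) -> np.ndarray | float:
        a, b1, b2 = self.bias_coefficients
        return a + b1 * log_total + b2 * np.square(log_total)


@dataclass
class LocusTruth:
    locus_id: str
    locus_class: str
    chrom: str
    start: int
    end: int
    snp_ids: tuple[str, ...]
    expressed_parent: Optional[str] = None  # imprinted / partial classes
    fold: float = 1.0
    regulatory_snp: Optional[str] = None
    regulatory_high_allele: Optional[str] = None  # 'A' or 'B'
    rme_silenced_hap: dict[str, int] = field(default_factory=dict)  # ind -> 0 pat / 1 mat


@dataclass
class MbdTruth:
    untreated: np.ndarray
    treated: np.ndarray
    affected: np.ndarray  # boolean per site


@dataclass
class Simulation:
    """A generated panel plus the truth needed to score every pipeline call."""

    config: SimConfig
    pedigree: Pedigree
    snps: list[SnpDef]
    haplotypes: dict[str, np.ndarray]  # individual -> (2, n_snps) of 0(A)/1(B)
    loci: list[LocusTruth]
    transmissions: dict[tuple[str, str], tuple[int, int]]  # (child, locus) -> (from father, from mother)
    _rng: np.random.Generator = None  # type: ignore[assignment]

    @property
    def snp_index(self) -> dict[str, int]:
        return {s.snp_id: i for i, s in enumerate(self.snps)}

    def genotype(self, individual_id: str, snp_id: str) -> str:
        i = self.snp_index[snp_id]
        h = self.haplotypes[individual_id][:, i]
        return "".join(sorted("AB"[a] for a in h))

    def truth_by_id(self) -> dict[str, LocusTruth]:
        return {t.locus_id: t for t in self.loci}


def _founder_haplotypes(rng: np.random.Generator, mafs: np.ndarray) -> np.ndarray:
    return (rng.random((2, mafs.size)) < mafs).astype(np.int8)


def simulate_pedigree_genotypes(
    config: SimConfig | None = None, rng: Optional[np.random.Generator] = None
) -> Simulation:
    """Build the pedigree, SNP map, founder haplotypes and transmissions."""
    config = config or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)

    # SNP map: loci laid out round-robin over chromosomes, classes shuffled.
    classes = [c for c in LOCUS_CLASSES for _ in range(config.n_loci.get(c, 0))]
    classes = [classes[i] for i in rng.permutation(len(classes))]
    snps: list[SnpDef] = []
    loci: list[LocusTruth] = []
    mafs: list[float] = []
    per_chrom_count: dict[str, int] = {}
    lo, hi = config.snps_per_locus
    for locus_idx, cls in enumerate(classes):
        chrom = f"chr{locus_idx % config.n_chromosomes + 1}"
        slot = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = slot + 1
        n_snps = int(rng.integers(lo, hi + 1))
        start = 1_000_000 + slot * config.locus_spacing_bp
        ids = []
        for k in range(n_snps):
            snp_id = f"L{locus_idx:03d}_S{k:02d}"
            snps.append(SnpDef(chrom, start + k * config.snp_spacing_bp, snp_id))
            mafs.append(float(rng.uniform(*config.maf_range)))
            ids.append(snp_id)
        truth = LocusTruth(
            locus_id=f"L{locus_idx:03d}",
            locus_class=cls,
            chrom=chrom,
            start=start,
            end=start + (n_snps - 1) * config.snp_spacing_bp,
            snp_ids=tuple(ids),
        )
        if cls in ("imprinted_paternal", "imprinted_maternal"):
            truth.expressed_parent = "paternal" if cls == "imprinted_paternal" else "maternal"
            truth.fold = (1 - config.silenced_allele_fraction) / config.silenced_allele_fraction
        elif cls == "partial":
            truth.expressed_parent = "paternal" if rng.random() < 0.5 else "maternal"
            truth.fold = float(rng.uniform(*config.partial_fold_range))
        elif cls == "heritable_cis":
            truth.regulatory_snp = ids[n_snps // 2]
            truth.regulatory_high_allele = "A" if rng.random() < 0.5 else "B"
            truth.fold = float(rng.uniform(*config.heritable_fold_range))
        elif cls == "rme":
            truth.fold = (1 - config.silenced_allele_fraction) / config.silenced_allele_fraction
        loci.append(truth)
    maf_arr = np.array(mafs)

    members: list[PedigreeMember] = []
    haplotypes: dict[str, np.ndarray] = {}
    transmissions: dict[tuple[str, str], tuple[int, int]] = {}

    def add_founder(ind: str, fam: str, sex: str, generation: int) -> None:
        members.append(PedigreeMember(ind, fam, None, None, sex, generation))
        haplotypes[ind] = _founder_haplotypes(rng, maf_arr)

    def add_child(ind: str, fam: str, father: str, mother: str, sex: str, generation: int) -> None:
        members.append(PedigreeMember(ind, fam, father, mother, sex, generation))
        hap = np.empty((2, maf_arr.size), dtype=np.int8)
        for truth in loci:
            idx = [i for i, s in enumerate(snps) if s.snp_id in set(truth.snp_ids)]
            tf = int(rng.integers(0, 2))
            tm = int(rng.integers(0, 2))
            hap[0, idx] = haplotypes[father][tf, idx]
            hap[1, idx] = haplotypes[mother][tm, idx]
            transmissions[(ind, truth.locus_id)] = (tf, tm)
        haplotypes[ind] = hap

    for t in range(config.n_trios):
        fam = f"F{t + 1:02d}"
        add_founder(f"{fam}_fa", fam, "1", 1)
        add_founder(f"{fam}_mo", fam, "2", 1)
        add_child(f"{fam}_ch", fam, f"{fam}_fa", f"{fam}_mo", "1" if t % 2 else "2", 2)
    if config.include_three_generation:
        fam = "G01"
        for gp, sex in (("gpf_p", "1"), ("gmf_p", "2"), ("gpf_m", "1"), ("gmf_m", "2")):
            add_founder(f"{fam}_{gp}", fam, sex, 1)
        add_child(f"{fam}_fa", fam, f"{fam}_gpf_p", f"{fam}_gmf_p", "1", 2)
        add_child(f"{fam}_mo", fam, f"{fam}_gpf_m", f"{fam}_gmf_m", "2", 2)
        for c in range(config.n_family_children):
            add_child(
                f"{fam}_c{c + 1}", fam, f"{fam}_fa", f"{fam}_mo", "1" if c % 2 else "2", 3
            )

    sim = Simulation(
        config=config,
        pedigree=Pedigree(members),
        snps=snps,
        haplotypes=haplotypes,
        loci=loci,
        transmissions=transmissions,
        _rng=rng,
    )
    # assign per-individual silenced haplotypes for RME loci
    for truth in loci:
        if truth.locus_class == "rme":
            for ind in haplotypes:
                truth.rme_silenced_hap[ind] = int(rng.integers(0, 2))
    return sim


def _haplotype_shares(
    truth: LocusTruth, individual_id: str, hap: np.ndarray, snp_pos: Mapping[str, int],
    config: SimConfig, treatment_reverted: float = 0.0,
) -> tuple[float, float]:
    """Expression share (paternal, maternal) of one individual at one locus."""
    s = config.silenced_allele_fraction
    cls = truth.locus_class
    if cls in ("imprinted_paternal", "imprinted_maternal"):
        pat = 1 - s if truth.expressed_parent == "paternal" else s
        return pat, 1 - pat
    if cls == "partial":
        w = truth.fold / (1 + truth.fold)
        pat = w if truth.expressed_parent == "paternal" else 1 - w
        return pat, 1 - pat
    if cls == "heritable_cis":
        i = snp_pos[truth.regulatory_snp]
        high = 0 if truth.regulatory_high_allele == "A" else 1
        pat_high, mat_high = hap[0, i] == high, hap[1, i] == high
        if pat_high == mat_high:
            return 0.5, 0.5
        w = truth.fold / (1 + truth.fold)
        return (w, 1 - w) if pat_high else (1 - w, w)
    if cls == "rme":
        s_eff = s + treatment_reverted * (0.5 - s)
        silenced = truth.rme_silenced_hap[individual_id]
        return (s_eff, 1 - s_eff) if silenced == 0 else (1 - s_eff, s_eff)
    return 0.5, 0.5


def simulate_expression_signals(
    sim: Simulation,
    rng: Optional[np.random.Generator] = None,
    individuals: Optional[Sequence[str]] = None,
    treatment_reverted: float = 0.0,
    assays: Sequence[str] = ("gDNA", "cDNA"),
) -> list[IntensityRecord]:
    """Two-channel intensity records for the panel (gDNA and cDNA).

    gDNA carries the true allelic fraction of the genotype (0.5 at
    heterozygotes); cDNA carries the class-dependent haplotype expression
    shares.  Both receive the same quadratic intensity bias and beta noise.
    ``treatment_reverted`` moves random-monoallelic silencing toward 0.5
    (0 = untreated, 1 = fully reverted).
    """
    config = sim.config
    rng = rng if rng is not None else sim._rng
    individuals = list(individuals) if individuals is not None else list(sim.haplotypes)
    snp_pos = sim.snp_index
    records: list[IntensityRecord] = []
    for ind in individuals:
        hap = sim.haplotypes[ind]
        for truth in sim.loci:
            w_pat, w_mat = _haplotype_shares(
                truth, ind, hap, snp_pos, config, treatment_reverted
            )
            for snp_id in truth.snp_ids:
                i = snp_pos[snp_id]
                a_pat, a_mat = hap[0, i], hap[1, i]  # 0 = A, 1 = B
                genotype = "".join(sorted("AB"[a] for a in (a_pat, a_mat)))
                for assay in assays:
                    if assay == "gDNA":
                        p = ((a_pat == 0) + (a_mat == 0)) / 2.0
                    else:
                        p = w_pat * (a_pat == 0) + w_mat * (a_mat == 0)
                    total = 10.0 ** rng.normal(config.intensity_log_mean, config.intensity_log_sd)
                    beta = p + config.bias(math.log10(total)) + rng.normal(0, config.beta_noise_sd)
                    beta = min(1.0, max(0.0, beta))
                    records.append(
                        IntensityRecord(ind, snp_id, assay, total * beta, total * (1 - beta), genotype)
                    )
    return records


def simulate_treatment(
    sim: Simulation,
    rng: Optional[np.random.Generator] = None,
    individuals: Optional[Sequence[str]] = None,
    timepoints: Sequence[str] = ("5d", "10d"),
) -> tuple[dict[str, list[IntensityRecord]], MbdTruth]:
    """Treated cDNA panels per timepoint plus a methyl-pulldown comparison.

    The cumulative reverted fraction after timepoint k (1-based) is
    1 - (1 - treatment_response)**k, so random-monoallelic silencing decays
    monotonically toward balance while imprinted, heritable, partial and
    biallelic loci are redrawn with noise only.
    """
    config = sim.config
    rng = rng if rng is not None else sim._rng
    treated: dict[str, list[IntensityRecord]] = {}
    for k, tp in enumerate(timepoints, start=1):
        reverted = 1.0 - (1.0 - config.treatment_response) ** k
        treated[tp] = simulate_expression_signals(
            sim, rng=rng, individuals=individuals,
            treatment_reverted=reverted, assays=("cDNA",),
        )
    untr = rng.normal(config.mbd_site_mean, config.mbd_site_sd, config.mbd_n_sites)
    untr = np.clip(untr, 100.0, None)
    affected = rng.random(config.mbd_n_sites) < config.mbd_affected_fraction
    trt = untr.copy()
    trt[affected] *= 1.0 - config.mbd_reduction
    trt = trt + rng.normal(0, config.mbd_noise_sd, config.mbd_n_sites)
    return treated, MbdTruth(untreated=untr, treated=trt, affected=affected)


def simulate_panel(
    config: SimConfig | None = None, seed: Optional[int] = None
) -> tuple[Simulation, list[IntensityRecord]]:
    """Convenience wrapper: pedigree + genotypes + baseline intensity records."""
    config = config or SimConfig()
    if seed is not None:
        config.rng_seed = seed
    sim = simulate_pedigree_genotypes(config)
    records = simulate_expression_signals(sim)
    return sim, records
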