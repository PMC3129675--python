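"""Genome scan for allelic-expression windows and locus classification.

A window is a run of at least ``min_window_snps`` consecutive informative
SNPs (consecutive among informative sites, since homozygous or low-signal
SNPs carry no allelic information) whose per-child mean fold magnitude
clears the configured band in at least ``min_children`` children.  Extreme
mode (> 2.9-fold, open-ended) targets classical imprinting and monoallelic
expression; partial mode ([2.0, 2.9)-fold) targets moderate, partial
imprinting.  Reported windows are maximal: extending them by one SNP on
either side breaks the criteria.

Windows merge into loci; loci are classified from the parental origin of
the overexpressed allele across children (all-paternal or all-maternal is
imprinting-consistent) with a positive heritability mapping overriding any
imprinted call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .config import RunConfig
from .io import GeneModel, SnpDef
from .normalization import AEPoint
from .phasing import TransmissionObservation

__all__ = [
    "Window",
    "Locus",
    "SiteTransmission",
    "CLASSIFICATIONS",
    "scan_windows",
    "merge_windows_to_loci",
    "classify_transmission",
    "classify_locus",
    "detect_partial_imprinting",
    "annotate_extension",
]

CLASSIFICATIONS = (
    "imprinted_paternal_expressed",
    "imprinted_maternal_expressed",
    "partial_imprinting",
    "heritable",
    "non_transmitted",
    "inconsistent",
    "biallelic",
    "unclassified",
)


@dataclass(frozen=True)
class Window:
    chrom: str
    snp_ids: tuple[str, ...]
    start: int
    end: int
    per_child_magnitude: dict[str, float]
    qualifying_children: tuple[str, ...]
    mean_magnitude: float

    @property
    def n_informative_children(self) -> int:
        return len(self.qualifying_children)


@dataclass
class Locus:
    locus_id: str
    chrom: str
    start: int
    end: int
    snp_ids: tuple[str, ...]
    windows: tuple[Window, ...] = ()
    mean_magnitude: float = 1.0
    classification: str = "unclassified"
    transmissions: tuple[TransmissionObservation, ...] = ()
    gene_overlap: str = "beyond_extension"


@dataclass(frozen=True)
class SiteTransmission:
    """Per-SNP transmission record used for partial-imprinting evidence."""

    child_id: str
    snp_id: str
    origin: str  # 'paternal' | 'maternal' | 'unknown'
    overexpressed_allele: Optional[str]
    magnitude: float


def _mean_magnitudes(
    ae_by_child: Mapping[str, Mapping[str, AEPoint]],
    snp_ids: Sequence[str],
) -> dict[str, float]:
    """Per-child mean magnitude over the informative SNPs of a window."""
    means = {}
    for child, points in ae_by_child.items():
        mags = [
            points[s].magnitude
            for s in snp_ids
            if s in points and points[s].informative
        ]
        if mags:
            means[child] = sum(mags) / len(mags)
    return means


def scan_windows(
    ae_by_child: Mapping[str, Mapping[str, AEPoint]],
    snps: Sequence[SnpDef],
    config: RunConfig | None = None,
    fold_range: Optional[tuple[float, float]] = None,
) -> list[Window]:
    """Emit every maximal qualifying window.

    Parameters
    ----------
    ae_by_child:
        child id -> snp id -> AEPoint, for the children of the panel.
    snps:
        SNP definitions; scanned in (chrom, pos) order, runs never cross a
        chromosome boundary.
    fold_range:
        (low, high): a child qualifies when its mean magnitude over the
        window's informative SNPs is strictly above ``low`` and, if ``high``
        is finite, at or above ``low`` and strictly below ``high`` (the
        partial band is inclusive at its lower edge).  Defaults to the
        extreme-mode band (config.extreme_fold, inf).
    """
    config = config or RunConfig()
    if fold_range is None:
        fold_range = (config.extreme_fold, float("inf"))
    low, high = fold_range
    partial_mode = high != float("inf")

    def child_qualifies(mean: float) -> bool:
        if partial_mode:
            return low <= mean < high
        return mean > low

    ordered = sorted(snps, key=lambda s: (s.chrom, s.pos))
    windows: list[Window] = []
    by_chrom: dict[str, list[SnpDef]] = {}
    for s in ordered:
        by_chrom.setdefault(s.chrom, []).append(s)

    for chrom, chrom_snps in by_chrom.items():
        chrom_grid = [
            s
            for s in chrom_snps
            if any(
                s.snp_id in pts and pts[s.snp_id].informative
                for pts in ae_by_child.values()
            )
        ]
        # adjacent informative SNPs farther apart than window_gap_bp are not
        # "consecutive": the run breaks, as it does at chromosome ends
        segments: list[list[SnpDef]] = []
        for s in chrom_grid:
            if segments and s.pos - segments[-1][-1].pos <= config.window_gap_bp:
                segments[-1].append(s)
            else:
                segments.append([s])
        for grid in segments:
            windows.extend(
                _scan_segment(grid, chrom, ae_by_child, config, child_qualifies)
            )
    return windows


def _scan_segment(
    grid: Sequence[SnpDef],
    chrom: str,
    ae_by_child: Mapping[str, Mapping[str, AEPoint]],
    config: RunConfig,
    child_qualifies,
) -> list[Window]:
    windows: list[Window] = []
    n = len(grid)
    k = config.min_window_snps

    def qualifies(i: int, j: int) -> Optional[dict[str, float]]:
        """Means for a run grid[i..j] if it meets the criteria, else None."""
        ids = [s.snp_id for s in grid[i : j + 1]]
        means = _mean_magnitudes(ae_by_child, ids)
        passing = [c for c, m in means.items() if child_qualifies(m)]
        if len(passing) >= config.min_children:
            return means
        return None

    for i in range(n):
        for j in range(i + k - 1, n):
            means = qualifies(i, j)
            if means is None:
                continue
            if i > 0 and qualifies(i - 1, j) is not None:
                continue  # extendable left
            if j < n - 1 and qualifies(i, j + 1) is not None:
                continue  # extendable right
            passing = tuple(sorted(c for c, m in means.items() if child_qualifies(m)))
            mean_mag = sum(means[c] for c in passing) / len(passing)
            windows.append(
                Window(
                    chrom=chrom,
                    snp_ids=tuple(s.snp_id for s in grid[i : j + 1]),
                    start=grid[i].pos,
                    end=grid[j].pos,
                    per_child_magnitude=means,
                    qualifying_children=passing,
                    mean_magnitude=mean_mag,
                )
            )
    return windows


def merge_windows_to_loci(
    windows: Iterable[Window], config: RunConfig | None = None
) -> list[Locus]:
    """Merge windows closer than ``merge_gap_bp`` on a chromosome into loci."""
    config = config or RunConfig()
    ws = sorted(windows, key=lambda w: (w.chrom, w.start, w.end))
    loci: list[Locus] = []
    cluster: list[Window] = []

    def flush() -> None:
        if not cluster:
            return
        snp_ids = tuple(dict.fromkeys(s for w in cluster for s in w.snp_ids))
        start = min(w.start for w in cluster)
        end = max(w.end for w in cluster)
        mean_mag = sum(w.mean_magnitude for w in cluster) / len(cluster)
        loci.append(
            Locus(
                locus_id=f"{cluster[0].chrom}:{start}-{end}",
                chrom=cluster[0].chrom,
                start=start,
                end=end,
                snp_ids=snp_ids,
                windows=tuple(cluster),
                mean_magnitude=mean_mag,
            )
        )
        cluster.clear()

    for w in ws:
        if cluster and (
            w.chrom != cluster[-1].chrom
            or w.start > max(c.end for c in cluster) + config.merge_gap_bp
        ):
            flush()
        cluster.append(w)
    flush()
    return loci


def classify_transmission(
    transmissions: Iterable[TransmissionObservation], config: RunConfig | None = None
) -> str:
    """Parent-of-origin classification from per-child transmission calls."""
    config = config or RunConfig()
    known = [t for t in transmissions if t.origin_of_overexpressed != "unknown"]
    if len(known) < config.min_children:
        return "non_transmitted"
    origins = {t.origin_of_overexpressed for t in known}
    if origins == {"paternal"}:
        return "imprinted_paternal_expressed"
    if origins == {"maternal"}:
        return "imprinted_maternal_expressed"
    return "inconsistent"


def classify_locus(locus: Locus, transmission_class: str, mapped: bool) -> Locus:
    """Final locus call: a positive cis mapping overrides any imprinted call."""
    classification = "heritable" if mapped else transmission_class
    return replace(locus, classification=classification)


def _overlaps_or_near(locus: Locus, other: Locus, margin: int) -> bool:
    return locus.chrom == other.chrom and (
        locus.start <= other.end + margin and other.start <= locus.end + margin
    )


def detect_partial_imprinting(
    moderate_loci: Iterable[Locus],
    classic_loci: Iterable[Locus],
    mapped_by_locus: Mapping[str, bool],
    transmissions_by_locus: Mapping[str, Sequence[TransmissionObservation]],
    site_observations_by_locus: Mapping[str, Sequence[SiteTransmission]],
    config: RunConfig | None = None,
) -> list[Locus]:
    """Screen moderate (2-2.9-fold) loci for partial imprinting.

    Pipeline: (1) start from moderate loci; (2) drop any within the boundary
    extension of a classic imprinted locus (redundant signal); (3) drop loci
    with a positive heritability mapping; (4) require that all known-origin
    transmissions agree on one parent and that the overexpressed allele is
    not one fixed allele label across children and sites (expression must
    track the transmitting parent, not a particular allele — the signature
    of a non-genetic, parent-of-origin effect).
    """
    config = config or RunConfig()
    classics = list(classic_loci)
    out: list[Locus] = []
    for locus in moderate_loci:
        if any(
            _overlaps_or_near(locus, c, config.boundary_extension_bp) for c in classics
        ):
            continue
        if mapped_by_locus.get(locus.locus_id, False):
            continue
        transmissions = tuple(transmissions_by_locus.get(locus.locus_id, ()))
        t_class = classify_transmission(transmissions, config)
        if t_class not in ("imprinted_paternal_expressed", "imprinted_maternal_expressed"):
            continue
        site_obs = [
            o
            for o in site_observations_by_locus.get(locus.locus_id, ())
            if o.origin != "unknown" and o.overexpressed_allele is not None
        ]
        alleles = {o.overexpressed_allele for o in site_obs}
        if len(alleles) < 2:
            continue  # could be a fixed allele-linked effect
        out.append(
            replace(locus, classification="partial_imprinting", transmissions=transmissions)
        )
    return out


def annotate_extension(
    locus: Locus, gene_models: Iterable[GeneModel], config: RunConfig | None = None
) -> str:
    """Position of a locus relative to annotated gene models.

    'within_gene' when overlapping a model, 'within_extension' when within
    ``boundary_extension_bp`` of one (possible unannotated isoform or
    adjacent transcriptional unit), 'beyond_extension' otherwise.
    """
    config = config or RunConfig()
    best: Optional[int] = None
    for gm in gene_models:
        if gm.chrom != locus.chrom:
            continue
        if locus.start <= gm.end and gm.start <= locus.end:
            return "within_gene"
        dist = max(gm.start - locus.end, locus.start - gm.end)
        best = dist if best is None else min(best, dist)
    if best is not None and best <= config.boundary_extension_bp:
        return "within_extension"
    return "beyond_extension"
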