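"""Demethylation (5-aza-2'-deoxycytidine) response analysis.

Loci with allelic expression at baseline are scored for a treatment effect
against a change threshold derived from untreated biological controls: the
95th percentile of replicate-to-replicate allelic fold change (1.25-fold in
the reference panels).  A locus counts as affected when every informative
sample decreases by at least that threshold and at least one sample has a
two-fold or greater allelic magnitude untreated — a consistent, directional
loss of allelic imbalance rather than replicate noise.

A time-course variant flags strong responses (halving of the allelic
magnitude, measured on the log scale by default since magnitudes are ratios
bounded below by 1) and checks monotone time dependency (the 5-day effect
smaller than the 10-day effect).  The methyl-CpG pulldown comparison
summarizes whether probe intensities of methylation-enriched DNA
predominantly drop after treatment, the expected direction under global
demethylation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import RunConfig

__all__ = [
    "TreatmentRecord",
    "TreatmentCall",
    "MbdComparison",
    "control_change_threshold",
    "classify_treatment_effect",
    "strong_response_and_time",
    "mbd_signal_compare",
    "load_reference_treatment_panel",
]

MIN_CONTROL_PAIRS = 20


@dataclass(frozen=True)
class TreatmentRecord:
    """Untreated/treated allelic magnitudes for one locus in one sample."""

    locus_id: str
    sample_id: str
    magnitude_untreated: float
    magnitude_treated: Optional[float] = None
    magnitude_by_timepoint: Mapping[str, float] = None  # type: ignore[assignment]
    dose_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.magnitude_untreated < 1:
            raise ValueError("magnitudes are folds >= 1")


@dataclass(frozen=True)
class TreatmentCall:
    locus_id: str
    affected: bool
    qualifying_samples: int
    n_informative_samples: int
    strong_response: Optional[bool] = None
    time_consistent: Optional[bool] = None  # None = not applicable


@dataclass(frozen=True)
class MbdComparison:
    n_sites: int
    n_decreased: int
    n_increased: int
    n_unchanged: int
    fraction_decreased_among_changed: float
    low_confidence: bool
    directions: tuple[str, ...] = ()


def control_change_threshold(
    replicate_pairs: Sequence[tuple[float, float]],
    percentile: float = 95.0,
    min_pairs: int = MIN_CONTROL_PAIRS,
) -> float:
    """Allelic fold-change threshold from untreated biological controls.

    Takes (magnitude_rep1, magnitude_rep2) pairs, computes the symmetric
    fold change max(m1/m2, m2/m1) per pair, and returns its ``percentile``
    (linear interpolation).  Changes beyond this value are larger than
    essentially all replicate noise.
    """
    if len(replicate_pairs) < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} control replicate pairs, got {len(replicate_pairs)}"
        )
    folds = [max(m1 / m2, m2 / m1) for m1, m2 in replicate_pairs]
    return float(np.percentile(folds, percentile))


def classify_treatment_effect(
    records: Sequence[TreatmentRecord],
    threshold: Optional[float] = None,
    config: RunConfig | None = None,
) -> TreatmentCall:
    """Call one locus affected/unaffected by demethylation treatment.

    ``records`` are the untreated/treated magnitude pairs of one locus
    across treated samples; pairs missing either magnitude are ignored.
    Affected requires (a) every informative sample to decrease with an
    untreated/treated ratio of at least ``threshold`` and (b) at least one
    informative sample with untreated magnitude >= the baseline fold.
    """
    config = config or RunConfig()
    if threshold is None:
        threshold = config.treatment_change_fold
    locus_ids = {r.locus_id for r in records}
    if len(locus_ids) != 1:
        raise ValueError(f"records span {len(locus_ids)} loci; expected one")
    (locus_id,) = locus_ids
    pairs = [
        (r.magnitude_untreated, r.magnitude_treated)
        for r in records
        if r.magnitude_treated is not None
    ]
    if not pairs:
        return TreatmentCall(locus_id, False, 0, 0)
    qualifying = sum(
        1 for u, t in pairs if t < u and u / t >= threshold
    )
    all_decrease = qualifying == len(pairs)
    baseline_ok = any(u >= config.treatment_baseline_fold for u, _ in pairs)
    return TreatmentCall(
        locus_id=locus_id,
        affected=all_decrease and baseline_ok,
        qualifying_samples=qualifying,
        n_informative_samples=len(pairs),
    )


def strong_response_and_time(
    record: TreatmentRecord,
    config: RunConfig | None = None,
    early: str = "5d",
    late: str = "10d",
) -> tuple[bool, Optional[bool]]:
    """Strong-response and time-consistency flags for a time-course record.

    Strong response: the late-timepoint magnitude shows a 50% decrease
    relative to untreated — on the log scale (log m_late <= 0.5 * log m_0)
    by default, or linearly (m_late <= m_0 / 2) when
    ``config.response_scale == 'linear'``.  Time consistency: the magnitude
    decreases monotonically, with the early effect less marked
    (m_late <= m_early <= m_0).  Returns (strong, time_consistent); the
    latter is None when the early timepoint is missing.
    """
    config = config or RunConfig()
    tp = record.magnitude_by_timepoint or {}
    if late not in tp:
        raise ValueError(f"record lacks late timepoint {late!r}")
    m0 = record.magnitude_untreated
    if m0 < config.treatment_baseline_fold:
        raise ValueError("strong-response evaluation requires a >= baseline-fold locus")
    m_late = tp[late]
    if config.response_scale == "log":
        strong = math.log(m_late) <= 0.5 * math.log(m0)
    else:
        strong = m_late <= 0.5 * m0
    if early not in tp:
        return strong, None
    m_early = tp[early]
    return strong, m_late <= m_early <= m0


def mbd_signal_compare(
    treated: Sequence[float],
    untreated: Sequence[float],
    config: RunConfig | None = None,
    min_sites: int = 100,
) -> MbdComparison:
    """Per-site direction of methyl-pulldown signal change after treatment.

    A site is changed when |treated - untreated| exceeds
    ``mbd_sd_multiplier`` standard deviations of the across-site difference
    distribution; the summary is the decreased fraction among changed sites
    (values well above 0.5 indicate genuine demethylation rather than
    symmetric noise).
    """
    config = config or RunConfig()
    t = np.asarray(treated, dtype=float)
    u = np.asarray(untreated, dtype=float)
    if t.shape != u.shape:
        raise ValueError("treated/untreated site vectors must align")
    diff = t - u
    low_confidence = diff.size < min_sites
    if low_confidence:
        warnings.warn(
            f"only {diff.size} paired sites; direction summary is low-confidence",
            stacklevel=2,
        )
    sd = float(np.std(diff))
    cut = config.mbd_sd_multiplier * sd
    directions = tuple(
        "decreased" if d < -cut else "increased" if d > cut else "unchanged"
        for d in diff
    )
    n_dec = directions.count("decreased")
    n_inc = directions.count("increased")
    n_changed = n_dec + n_inc
    return MbdComparison(
        n_sites=diff.size,
        n_decreased=n_dec,
        n_increased=n_inc,
        n_unchanged=directions.count("unchanged"),
        fraction_decreased_among_changed=(n_dec / n_changed) if n_changed else float("nan"),
        low_confidence=low_confidence,
        directions=directions,
    )


def load_reference_treatment_panel() -> list[list[TreatmentRecord]]:
    """Load the bundled AZA reference panel of two treated LCLs.

    Returns one record list per locus (70 loci), each holding the
    untreated/treated allelic magnitudes measured in lymphoblastoid lines
    GM19099 and GM19141 after 3 days of 5 uM 5-aza-2'-deoxycytidine; the
    curated affected/unaffected status of each locus is available through
    :func:`load_reference_treatment_status`.
    """
    rows = _read_reference_rows()
    by_locus: dict[str, list[TreatmentRecord]] = {}
    for locus_id, _status, sample, untreated, treated in rows:
        by_locus.setdefault(locus_id, []).append(
            TreatmentRecord(locus_id, sample, untreated, treated, dose_um=5.0)
        )
    return list(by_locus.values())


def load_reference_treatment_status() -> dict[str, bool]:
    """locus id -> curated affected status for the bundled AZA panel."""
    return {locus_id: status for locus_id, status, *_ in _read_reference_rows()}


def _read_reference_rows() -> list[tuple[str, bool, str, float, float]]:
    from importlib.resources import files

    rows = []
    text = files("imprintscan.data").joinpath("aza_reference_panel.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        locus_id, status, sample, untreated, treated = line.split("\t")
        if untreated == "NA" or treated == "NA":
            continue
        rows.append(
            (locus_id, status == "affected", sample, float(untreated), float(treated))
        )
    return rows
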