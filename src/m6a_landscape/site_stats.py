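"""Replicate aggregation, site filtering/calling, differential sites,
isoform modification classes and the treatment-restoration analysis.

All thresholds in this module are strict inequalities (``>`` / ``<``),
matching how the cut-offs are stated: a site at exactly 50% stoichiometry or
exactly 10 reads is *not* called, a delta of exactly +0.10 is counted in
neither direction, and the medium isoform bin is the closed interval
[0.30, 0.70].

Deltas are differences of ``mean_level`` (the unweighted mean of per-replicate
modified-read fractions); the coverage-weighted ``agg_level`` is carried
alongside but never drives a threshold.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .data_model_io import ReadLevelRecord, SiteRecord
from .transcript_annotation import MotifClass, Region, SiteAnnotation

__all__ = [
    "SiteKey",
    "ConditionSiteSummary",
    "DifferentialSite",
    "ThresholdCounts",
    "IsoformClass",
    "IsoformModProfile",
    "RestorationResult",
    "FILTER_PRESETS",
    "aggregate_condition",
    "filter_sites",
    "call_m6a_sites",
    "differential_sites",
    "classify_isoforms",
    "restoration_analysis",
    "metagene_histogram",
]

SiteKey = tuple[str, int, str]  # (chrom, start, strand)

# Two circulating variants of the per-condition aggregated-coverage cut-off
# (">20" for methods-grade filtering, ">10" for figure-level filtering); both
# are exposed and the choice is recorded in output metadata.
FILTER_PRESETS: dict[str, dict[str, float]] = {
    "methods": {"min_agg_cov": 20, "min_level": 0.10},
    "figure": {"min_agg_cov": 10, "min_level": 0.10},
}


@dataclass(frozen=True)
class ConditionSiteSummary:
    """Per-condition aggregation of one site over replicates.

    ``mean_level`` is the unweighted mean of per-replicate fractions over
    replicates with ``valid_cov > 0`` (``None`` if there are none);
    ``agg_level`` is total modified reads over total valid coverage.
    """

    key: SiteKey
    condition: str
    n_replicates: int
    mean_level: float | None
    agg_cov: int
    agg_level: float | None


@dataclass(frozen=True)
class DifferentialSite:
    """One site passing the joint filter, with per-condition mean levels and
    their signed difference ``delta = level_a - level_b``."""

    key: SiteKey
    level_a: float
    level_b: float
    delta: float
    agg_level_a: float
    agg_level_b: float
    region: Region = Region.UNASSIGNED
    motif_class: MotifClass = MotifClass.UNDEFINED
    gene_id: str | None = None
    transcript_id: str | None = None
    metagene_x: float | None = None


@dataclass
class ThresholdCounts:
    """Counts of sites beyond the +/-10% and +/-20% delta thresholds (strict)."""

    n_up_10: int = 0
    n_dn_10: int = 0
    n_up_20: int = 0
    n_dn_20: int = 0
    n_total: int = 0

    def add(self, delta: float) -> None:
        self.n_total += 1
        if delta > 0.10:
            self.n_up_10 += 1
        if delta < -0.10:
            self.n_dn_10 += 1
        if delta > 0.20:
            self.n_up_20 += 1
        if delta < -0.20:
            self.n_dn_20 += 1


class IsoformClass(str, Enum):
    LOW = "LOW"
    MEDIUM = "MEDIUM"
    HIGH = "HIGH"


@dataclass(frozen=True)
class IsoformModProfile:
    transcript_id: str
    n_reads: int
    n_modified_reads: int
    level: float
    iso_class: IsoformClass


@dataclass(frozen=True)
class RestorationResult:
    restored: tuple[SiteKey, ...]
    n_restored: int
    n_eligible: int
    fraction: float


def aggregate_condition(records: Iterable[SiteRecord]) -> dict[SiteKey, ConditionSiteSummary]:
    """Aggregate per-replicate records of one condition into per-site summaries.

    A site absent from a replicate contributes nothing (it is not a zero);
    replicates with ``valid_cov = 0`` are excluded from the mean but their
    presence still counts toward ``n_replicates``.
    """
    by_key: dict[SiteKey, list[SiteRecord]] = defaultdict(list)
    conditions: set[str] = set()
    seen: set[tuple[str, SiteKey]] = set()
    for rec in records:
        conditions.add(rec.condition)
        dup_key = (rec.sample_id, rec.key)
        if dup_key in seen:
            raise ValueError(f"duplicate record for sample {rec.sample_id} at {rec.key}")
        seen.add(dup_key)
        by_key[rec.key].append(rec)
    if len(conditions) > 1:
        raise ValueError(f"records span multiple conditions: {sorted(conditions)}")
    condition = next(iter(conditions)) if conditions else ""

    out: dict[SiteKey, ConditionSiteSummary] = {}
    for key, recs in by_key.items():
        levels = [r.level for r in recs if r.valid_cov > 0]
        agg_cov = sum(r.valid_cov for r in recs)
        agg_mod = sum(r.n_mod for r in recs)
        out[key] = ConditionSiteSummary(
            key=key,
            condition=condition,
            n_replicates=len(recs),
            mean_level=(sum(levels) / len(levels)) if levels else None,
            agg_cov=agg_cov,
            agg_level=(agg_mod / agg_cov) if agg_cov > 0 else None,
        )
    return out


def filter_sites(
    summary_a: Mapping[SiteKey, ConditionSiteSummary],
    summary_b: Mapping[SiteKey, ConditionSiteSummary],
    min_agg_cov: float = 20,
    min_level: float = 0.10,
) -> set[SiteKey]:
    """Joint site filter: present in both conditions, aggregated coverage
    strictly above ``min_agg_cov`` in *each*, and mean level strictly above
    ``min_level`` in *at least one*."""
    if not (0.0 <= min_level <= 1.0):
        raise ValueError(f"min_level must be in [0,1], got {min_level}")
    kept: set[SiteKey] = set()
    for key in summary_a.keys() & summary_b.keys():
        a, b = summary_a[key], summary_b[key]
        if a.agg_cov <= min_agg_cov or b.agg_cov <= min_agg_cov:
            continue
        if a.mean_level is None or b.mean_level is None:
            continue
        if a.mean_level > min_level or b.mean_level > min_level:
            kept.add(key)
    return kept


def call_m6a_sites(
    summary: Mapping[SiteKey, ConditionSiteSummary],
    level_threshold: float = 0.5,
    min_reads: int = 10,
) -> set[SiteKey]:
    """Call modified sites: mean level strictly above ``level_threshold`` and
    aggregated coverage strictly above ``min_reads``.

    Apply to a single-replicate summary for per-replicate calls.
    """
    return {
        key
        for key, s in summary.items()
        if s.mean_level is not None
        and s.mean_level > level_threshold
        and s.agg_cov > min_reads
    }


def differential_sites(
    joint_keys: Iterable[SiteKey],
    summary_a: Mapping[SiteKey, ConditionSiteSummary],
    summary_b: Mapping[SiteKey, ConditionSiteSummary],
    annotations: Mapping[SiteKey, SiteAnnotation] | None = None,
) -> tuple[
    list[DifferentialSite],
    dict[tuple[Region, MotifClass], ThresholdCounts],
    ThresholdCounts,
]:
    """Per-site deltas plus threshold counts per (region, motif-class) stratum.

    Returns the differential sites (sorted by key), the stratified counts
    (unassigned sites excluded from strata) and the overall counts (all
    sites).  Counts are nested by construction: ``n_up_20 <= n_up_10``.
    """
    sites: list[DifferentialSite] = []
    strata: dict[tuple[Region, MotifClass], ThresholdCounts] = defaultdict(ThresholdCounts)
    overall = ThresholdCounts()
    for key in sorted(joint_keys):
        a, b = summary_a[key], summary_b[key]
        if a.mean_level is None or b.mean_level is None:
            raise ValueError(f"site {key} lacks coverage in a condition; filter first")
        ann = annotations.get(key) if annotations is not None else None
        site = DifferentialSite(
            key=key,
            level_a=a.mean_level,
            level_b=b.mean_level,
            delta=a.mean_level - b.mean_level,
            agg_level_a=a.agg_level if a.agg_level is not None else 0.0,
            agg_level_b=b.agg_level if b.agg_level is not None else 0.0,
            region=ann.region if ann else Region.UNASSIGNED,
            motif_class=ann.motif_class if ann else MotifClass.UNDEFINED,
            gene_id=ann.gene_id if ann else None,
            transcript_id=ann.transcript_id if ann else None,
            metagene_x=ann.metagene_x if ann else None,
        )
        sites.append(site)
        overall.add(site.delta)
        if site.region is not Region.UNASSIGNED:
            strata[(site.region, site.motif_class)].add(site.delta)
    return sites, dict(strata), overall


def classify_isoforms(
    read_records: Iterable[ReadLevelRecord],
    bins: tuple[float, float] = (0.30, 0.70),
    min_reads_per_isoform: int = 10,
) -> tuple[list[IsoformModProfile], dict[IsoformClass, float], int]:
    """Classify transcript isoforms by their fraction of modified reads.

    A read is modified iff it carries at least one modified call; reads with
    no queryable A (``n_called_A == 0``) are excluded from the denominator.
    Classes: LOW iff level < bins[0], HIGH iff level > bins[1], MEDIUM for the
    closed interval in between.  Transcripts with fewer informative reads than
    ``min_reads_per_isoform`` are excluded and tallied as unclassified.

    Returns (profiles, class proportions over classified isoforms, n_unclassified).
    """
    lo, hi = bins
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid bins {bins}")
    by_tid: dict[str, list[ReadLevelRecord]] = defaultdict(list)
    for rec in read_records:
        by_tid[rec.transcript_id].append(rec)

    profiles: list[IsoformModProfile] = []
    unclassified = 0
    for tid in sorted(by_tid):
        informative = [r for r in by_tid[tid] if r.n_called_A > 0]
        if len(informative) < min_reads_per_isoform:
            unclassified += 1
            continue
        n_modified = sum(1 for r in informative if r.n_mod >= 1)
        level = n_modified / len(informative)
        if level < lo:
            cls = IsoformClass.LOW
        elif level > hi:
            cls = IsoformClass.HIGH
        else:
            cls = IsoformClass.MEDIUM
        profiles.append(
            IsoformModProfile(
                transcript_id=tid,
                n_reads=len(informative),
                n_modified_reads=n_modified,
                level=level,
                iso_class=cls,
            )
        )
    proportions = {cls: 0.0 for cls in IsoformClass}
    if profiles:
        for p in profiles:
            proportions[p.iso_class] += 1
        for cls in proportions:
            proportions[cls] /= len(profiles)
    return profiles, proportions, unclassified


def restoration_analysis(
    hypo_sites: Iterable[SiteKey],
    treated_summary: Mapping[SiteKey, ConditionSiteSummary],
    untreated_summary: Mapping[SiteKey, ConditionSiteSummary],
    delta_min: float = 0.10,
    min_agg_cov: float = 20,
) -> RestorationResult:
    """Fraction of tumor-hypomethylated sites regaining methylation on treatment.

    A hypo site is *eligible* if both treated and untreated summaries cover it
    with aggregated coverage strictly above ``min_agg_cov``; it is *restored*
    iff ``mean_level(treated) - mean_level(untreated) > delta_min`` (strict).
    """
    eligible: list[SiteKey] = []
    restored: list[SiteKey] = []
    for key in sorted(set(hypo_sites)):
        t = treated_summary.get(key)
        u = untreated_summary.get(key)
        if t is None or u is None:
            continue
        if t.agg_cov <= min_agg_cov or u.agg_cov <= min_agg_cov:
            continue
        if t.mean_level is None or u.mean_level is None:
            continue
        eligible.append(key)
        if t.mean_level - u.mean_level > delta_min:
            restored.append(key)
    if not eligible:
        raise ValueError("no hypo sites with treated+untreated coverage; cannot form a fraction")
    return RestorationResult(
        restored=tuple(restored),
        n_restored=len(restored),
        n_eligible=len(eligible),
        fraction=len(restored) / len(eligible),
    )


def metagene_histogram(
    metagene_xs: Iterable[float],
    n_bins: int = 30,
) -> list[tuple[float, float, int]]:
    """Histogram of metagene coordinates over [0,3) with left-closed bins.

    Returns (bin_start, bin_end, count) triples; values outside [0,3) are
    ignored.
    """
    width = 3.0 / n_bins
    counts = [0] * n_bins
    for x in metagene_xs:
        if x is None or not (0.0 <= x < 3.0):
            continue
        counts[min(int(x / width), n_bins - 1)] += 1
    return [(i * width, (i + 1) * width, counts[i]) for i in range(n_bins)]
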