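"""Cross-dataset integration: differential-expression set intersections across
cell lines and overlap of called m6A sites with reader-binding intervals."""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .data_model_io import BindingInterval, DEResult
from .gene_level import hypergeometric_overlap
from .site_stats import SiteKey
from .transcript_annotation import SiteAnnotation

__all__ = [
    "CommonDESets",
    "BindingOverlapResult",
    "de_sets",
    "intersect_lines",
    "reader_binding_overlap",
]


@dataclass(frozen=True)
class CommonDESets:
    up_common: frozenset[str]
    down_common: frozenset[str]
    per_line_up: dict[str, frozenset[str]]
    per_line_down: dict[str, frozenset[str]]
    fdr_max: float
    fc_min: float


@dataclass(frozen=True)
class BindingOverlapResult:
    """Per-gene-set qualification against one binding-interval source."""

    source_label: str
    percentages: dict[str, float]
    qualifying: dict[str, frozenset[str]]
    set_sizes: dict[str, int]
    hypergeom: tuple[int, float, float] | None  # (k, expected, p) for 2 sets


def de_sets(
    de: Iterable[DEResult], fdr_max: float = 0.05, fc_min: float = 1.5
) -> tuple[set[str], set[str]]:
    """Significantly up- and down-regulated gene sets for one cell line.

    The fold-change cut-off is interpreted on the linear scale: up means
    ``log2fc > log2(fc_min)``, down means ``log2fc < -log2(fc_min)``, both
    with ``fdr < fdr_max``; all inequalities strict.
    """
    if fc_min <= 1.0:
        raise ValueError(f"fc_min must be > 1, got {fc_min}")
    bound = math.log2(fc_min)
    up: set[str] = set()
    down: set[str] = set()
    for r in de:
        if r.fdr >= fdr_max:
            continue
        if r.log2fc > bound:
            up.add(r.gene_id)
        elif r.log2fc < -bound:
            down.add(r.gene_id)
    return up, down


def intersect_lines(
    per_line: Mapping[str, tuple[set[str], set[str]]],
    fdr_max: float = 0.05,
    fc_min: float = 1.5,
) -> CommonDESets:
    """Intersect per-line (up, down) gene sets across >= 2 cell lines."""
    if len(per_line) < 2:
        raise ValueError("need at least two cell lines to intersect")
    ups = {line: frozenset(u) for line, (u, _) in per_line.items()}
    downs = {line: frozenset(d) for line, (_, d) in per_line.items()}
    up_common = frozenset.intersection(*ups.values())
    down_common = frozenset.intersection(*downs.values())
    return CommonDESets(
        up_common=up_common,
        down_common=down_common,
        per_line_up=ups,
        per_line_down=downs,
        fdr_max=fdr_max,
        fc_min=fc_min,
    )


def _check_chrom_namespace(site_chroms: set[str], interval_chroms: set[str]) -> None:
    if not site_chroms or not interval_chroms:
        return
    if site_chroms & interval_chroms:
        return
    raise ValueError(
        "chromosome namespaces of sites and binding intervals do not overlap "
        f"(sites e.g. {sorted(site_chroms)[:3]}, intervals e.g. "
        f"{sorted(interval_chroms)[:3]}); harmonise 'chr' prefixes before overlap"
    )


def reader_binding_overlap(
    gene_sets: Mapping[str, set[str]],
    called_sites: Iterable[SiteKey],
    binding: Iterable[BindingInterval],
    annotations: Mapping[SiteKey, SiteAnnotation],
) -> list[BindingOverlapResult]:
    """Fraction of each gene set with a called m6A site inside a binding interval.

    A gene qualifies iff at least one of its called sites lies within at least
    one interval (half-open containment; strand ignored when the interval
    strand is ".").  Interval sources (``source_label``) are analysed
    separately, never merged.  When exactly two gene sets are given, an
    upper-tail hypergeometric comparison of qualifying genes in the first set
    against the union universe is attached.
    """
    sites_by_gene: dict[str, list[SiteKey]] = defaultdict(list)
    site_chroms: set[str] = set()
    for key in called_sites:
        site_chroms.add(key[0])
        ann = annotations.get(key)
        if ann is not None and ann.gene_id is not None:
            sites_by_gene[ann.gene_id].append(key)

    by_source: dict[str, list[BindingInterval]] = defaultdict(list)
    interval_chroms: set[str] = set()
    for iv in binding:
        interval_chroms.add(iv.chrom)
        by_source[iv.source_label].append(iv)
    _check_chrom_namespace(site_chroms, interval_chroms)

    results: list[BindingOverlapResult] = []
    for source in sorted(by_source):
        intervals = by_source[source]
        by_chrom: dict[str, list[BindingInterval]] = defaultdict(list)
        for iv in intervals:
            by_chrom[iv.chrom].append(iv)

        def gene_qualifies(gene: str) -> bool:
            for chrom, pos, strand in sites_by_gene.get(gene, ()):
                for iv in by_chrom.get(chrom, ()):
                    if iv.start <= pos < iv.end and (
                        iv.strand == "." or iv.strand == strand
                    ):
                        return True
            return False

        qualifying = {
            name: frozenset(g for g in genes if gene_qualifies(g))
            for name, genes in gene_sets.items()
        }
        percentages = {
            name: (100.0 * len(qualifying[name]) / len(genes) if genes else 0.0)
            for name, genes in gene_sets.items()
        }
        hyper = None
        if len(gene_sets) == 2:
            names = sorted(gene_sets)
            universe = set(gene_sets[names[0]]) | set(gene_sets[names[1]])
            all_qual = (set(qualifying[names[0]]) | set(qualifying[names[1]])) & universe
            hyper = hypergeometric_overlap(
                all_qual, set(gene_sets[names[0]]), universe
            )
        results.append(
            BindingOverlapResult(
                source_label=source,
                percentages=percentages,
                qualifying=qualifying,
                set_sizes={name: len(genes) for name, genes in gene_sets.items()},
                hypergeom=hyper,
            )
        )
    return results
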