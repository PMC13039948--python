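"""Gene-level statistics on differential sites.

Implements per-gene average-delta ranking, the net methylation change
(#sites up minus #sites down), a native preranked enrichment statistic
(weighted running sum with a gene-label permutation null), upper-tail
hypergeometric overlap tests, and the top-net-gain differential-expression
composition rule.

Tie-breaking is deterministic everywhere: score descending, then gene id
lexicographic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model_io import DEResult
from .site_stats import DifferentialSite

__all__ = [
    "GeneRankRecord",
    "EnrichmentResult",
    "CompositionResult",
    "gene_average_delta",
    "net_m6a_change",
    "preranked_enrichment",
    "run_enrichment_suite",
    "hypergeometric_overlap",
    "top_net_gain_de_composition",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class GeneRankRecord:
    gene_id: str
    n_sites: int
    avg_delta: float
    net_change: int


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set_id: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    seed: int
    n_hits: int
    q_value: float | None = None


@dataclass(frozen=True)
class CompositionResult:
    n_down: int
    n_up: int
    genes: tuple[str, ...]
    n_missing_de: int
    truncated: bool  # True when fewer than top_n eligible genes existed


def net_m6a_change(deltas: Sequence[float], min_abs: float = 0.0) -> int:
    """#sites with delta > min_abs minus #sites with delta < -min_abs.

    The default ``min_abs = 0`` counts any increase/decrease; exact zeros
    count neither way.
    """
    if len(deltas) == 0:
        raise ValueError("need at least one delta")
    up = sum(1 for d in deltas if d > min_abs)
    dn = sum(1 for d in deltas if d < -min_abs)
    return up - dn


def gene_average_delta(
    diff_sites: Iterable[DifferentialSite],
    net_min_abs: float = 0.0,
) -> list[GeneRankRecord]:
    """One record per gene with >= 1 filtered site, ranked by average delta
    descending (ties broken by gene id).  Sites without a gene assignment are
    skipped."""
    by_gene: dict[str, list[float]] = {}
    for site in diff_sites:
        if site.gene_id is None:
            continue
        by_gene.setdefault(site.gene_id, []).append(site.delta)
    records = [
        GeneRankRecord(
            gene_id=gid,
            n_sites=len(ds),
            avg_delta=sum(ds) / len(ds),
            net_change=net_m6a_change(ds, min_abs=net_min_abs),
        )
        for gid, ds in by_gene.items()
    ]
    records.sort(key=lambda r: (-r.avg_delta, r.gene_id))
    return records


def _running_sum(
    scores: Sequence[float], is_hit: Sequence[bool], weight_exponent: float
) -> tuple[float, list[float]]:
    """Weighted running-sum walk over a ranked list.

    Hits increment by |score|^w normalised over the hits, misses decrement by
    1/(N - Nh).  Returns (maximum deviation from zero with its sign, the
    walk)."""
    n = len(scores)
    n_hits = sum(is_hit)
    n_miss = n - n_hits
    hit_weights = [abs(s) ** weight_exponent for s, h in zip(scores, is_hit) if h]
    total_w = sum(hit_weights)
    if total_w == 0.0:
        # All hit scores exactly zero: fall back to unweighted increments.
        hit_inc = 1.0 / n_hits
        increments = [hit_inc if h else -1.0 / n_miss for h in is_hit]
    else:
        increments = [
            (abs(s) ** weight_exponent / total_w) if h else -1.0 / n_miss
            for s, h in zip(scores, is_hit)
        ]
    walk: list[float] = []
    acc = 0.0
    es = 0.0
    for inc in increments:
        acc += inc
        walk.append(acc)
        if abs(acc) > abs(es):
            es = acc
    return es, walk


def preranked_enrichment(
    ranked: Sequence[GeneRankRecord],
    gene_set: set[str],
    weight_exponent: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked enrichment of ``gene_set`` in genes ranked by average delta.

    The statistic is the maximum deviation from zero of a running sum that
    increments hits by ``|avg_delta| ** weight_exponent`` (normalised over the
    hits) and decrements misses by ``1/(N - Nh)``.  The null permutes gene
    labels with scores fixed; ``p_perm = (1 + #{|es_perm| >= |es|}) /
    (n_perm + 1)`` and ``nes = es / mean(|es_perm| of the same sign)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ordered = sorted(ranked, key=lambda r: (-r.avg_delta, r.gene_id))
    genes = [r.gene_id for r in ordered]
    scores = [r.avg_delta for r in ordered]
    n = len(genes)
    hits = [g in gene_set for g in genes]
    n_hits = sum(hits)
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits >= n:
        raise ValueError("gene set covers the whole ranked universe (degenerate)")

    es, _ = _running_sum(scores, hits, weight_exponent)

    rng = np.random.default_rng(seed)
    abs_scores = np.abs(np.asarray(scores, dtype=float)) ** weight_exponent
    miss_dec = -1.0 / (n - n_hits)
    es_perm = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=n_hits, replace=False)
        total_w = abs_scores[idx].sum()
        inc = np.full(n, miss_dec)
        if total_w == 0.0:
            inc[idx] = 1.0 / n_hits
        else:
            inc[idx] = abs_scores[idx] / total_w
        walk = np.cumsum(inc)
        j = int(np.argmax(np.abs(walk)))
        es_perm[i] = walk[j]

    p = (1 + int(np.sum(np.abs(es_perm) >= abs(es)))) / (n_perm + 1)
    same_sign = es_perm[np.sign(es_perm) == np.sign(es)] if es != 0 else es_perm
    nes = es / float(np.mean(np.abs(same_sign))) if same_sign.size else float("nan")
    return EnrichmentResult(
        gene_set_id="",
        es=float(es),
        nes=float(nes),
        p_perm=p,
        n_perm=n_perm,
        seed=seed,
        n_hits=n_hits,
    )


def run_enrichment_suite(
    ranked: Sequence[GeneRankRecord],
    gene_sets: Mapping[str, set[str]],
    weight_exponent: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Run :func:`preranked_enrichment` for every gene set and attach
    Benjamini-Hochberg q-values across sets.  Each set gets a deterministic
    sub-seed derived from (seed, set index in sorted order)."""
    results: list[EnrichmentResult] = []
    for i, name in enumerate(sorted(gene_sets)):
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0])
        res = preranked_enrichment(
            ranked, gene_sets[name], weight_exponent, n_perm, sub_seed
        )
        results.append(
            EnrichmentResult(
                gene_set_id=name,
                es=res.es,
                nes=res.nes,
                p_perm=res.p_perm,
                n_perm=res.n_perm,
                seed=sub_seed,
                n_hits=res.n_hits,
            )
        )
    qs = benjamini_hochberg([r.p_perm for r in results])
    return [
        EnrichmentResult(
            gene_set_id=r.gene_set_id,
            es=r.es,
            nes=r.nes,
            p_perm=r.p_perm,
            n_perm=r.n_perm,
            seed=r.seed,
            n_hits=r.n_hits,
            q_value=q,
        )
        for r, q in zip(results, qs)
    ]


def benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values (q-values), order preserved."""
    m = len(pvals)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[i] * m / rank)
        q[i] = val
        prev = val
    return q


def hypergeometric_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[int, float, float]:
    """Upper-tail hypergeometric test of the overlap of two gene sets.

    Returns ``(k, expected, p)`` with ``k = |A & B|``, ``expected =
    |A| * |B| / |U|`` and ``p = P(X >= k)`` for X hypergeometric with
    population |U|, |A| successes and |B| draws.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    M, n, N = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = n * N / M
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    return k, expected, min(p, 1.0)


def top_net_gain_de_composition(
    records: Sequence[GeneRankRecord],
    de: Iterable[DEResult],
    top_n: int = 100,
    fdr_max: float = 0.01,
) -> CompositionResult:
    """Expression direction of the genes with the highest net methylation gain.

    Restricts to genes whose DE FDR is strictly below ``fdr_max`` (genes
    absent from the DE table are excluded and tallied), ranks by net change
    descending (ties: average delta descending, then gene id), takes the top
    ``top_n`` and counts down- (log2fc < 0) and up-regulated (log2fc > 0)
    genes among them.  If fewer than ``top_n`` genes are eligible, all are
    returned with ``truncated=True``.
    """
    de_by_gene = {r.gene_id: r for r in de}
    missing = sum(1 for r in records if r.gene_id not in de_by_gene)
    eligible = [
        r
        for r in records
        if r.gene_id in de_by_gene and de_by_gene[r.gene_id].fdr < fdr_max
    ]
    eligible.sort(key=lambda r: (-r.net_change, -r.avg_delta, r.gene_id))
    top = eligible[:top_n]
    n_down = sum(1 for r in top if de_by_gene[r.gene_id].log2fc < 0)
    n_up = sum(1 for r in top if de_by_gene[r.gene_id].log2fc > 0)
    return CompositionResult(
        n_down=n_down,
        n_up=n_up,
        genes=tuple(r.gene_id for r in top),
        n_missing_de=missing,
        truncated=len(eligible) < top_n,
    )
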