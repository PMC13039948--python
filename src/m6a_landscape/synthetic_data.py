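"""Deterministic synthetic corpus generator for the whole pipeline.

Generates, from explicit parameters and a master seed, every input the
analysis consumes: a toy genome + GTF annotation with planted DRACH and
non-DRACH adenosines, per-site modification pileups for four conditions
(``normal``, ``tumor``, ``tumor_untreated``, ``tumor_treated``) with binomial
count noise over a negative-binomial coverage model, read-level modification
tables, differential-expression tables for three synthetic cell lines, and
reader-binding intervals — plus a ground-truth table for recovery tests.

Design of the stoichiometry field: each planted site draws a baseline level
from a two-component mixture (near-zero mass + a Beta-distributed methylated
component); condition effects are applied on top (tumor gain at DRACH sites
of hyper genes, planted loss at methylated DRACH 3'UTR sites of a hypo gene
set, and partial treatment restoration of a fraction of the hypo sites), all
clamped to [0, 1].  Counts are binomial given the stoichiometry; replicate
variability enters only through counting noise and coverage.

Everything is a pure function of (config, seed): sub-seeds are derived
deterministically per stage / condition / replicate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .data_model_io import (
    BindingInterval,
    DEResult,
    ReadLevelRecord,
    SiteRecord,
    write_binding_bed,
    write_de_table,
    write_pileup,
    write_read_level_table,
)
from .transcript_annotation import (
    MotifClass,
    Region,
    TranscriptModel,
    assign_region,
    transcript_to_genome,
)

__all__ = [
    "SyntheticConfig",
    "SiteTruth",
    "SyntheticAnnotation",
    "CONDITIONS",
    "generate_annotation",
    "generate_site_counts",
    "generate_read_level",
    "simulate_read_level",
    "generate_de_and_binding",
    "generate_corpus",
    "mean_fraction_distribution",
    "crossing_probability",
]

CONDITIONS = ("normal", "tumor", "tumor_untreated", "tumor_treated")

_DRACH_5MER = "GGACT"
_NONDRACH_5MER = "CCACC"  # central A, D position fails -> NON_DRACH
_BACKGROUND = "CGT"  # no adenosines outside planted sites

# Stage codes for sub-seed derivation.
_STAGE_ANNOTATION = 1
_STAGE_COUNTS = 2
_STAGE_READS = 3
_STAGE_DE = 4


@dataclass
class SyntheticConfig:
    """All generator parameters.  Fractions are in [0,1]; deltas are clamped
    so stoichiometries stay in [0,1]; the same (config, seed) pair yields
    byte-identical outputs."""

    n_genes: int = 1000
    replicates: int = 2
    chrom: str = "chrSim"
    # transcript geometry (inclusive uniform ranges, nt)
    utr5_len: tuple[int, int] = (100, 300)
    cds_len: tuple[int, int] = (300, 1500)
    utr3_len: tuple[int, int] = (200, 800)
    intron_len: tuple[int, int] = (60, 400)
    gene_spacing: int = 500
    # site planting
    drach_per_kb: float = 6.0
    nondrach_a_per_kb: float = 3.0
    min_site_spacing: int = 5
    # baseline stoichiometry mixture
    p_methylated_drach: float = 0.5
    p_methylated_nondrach: float = 0.05
    meth_beta: tuple[float, float] = (2.0, 2.0)
    noise_level_max: float = 0.03
    # stop-codon proximity enrichment: fraction of methylated sites placed
    # within stop_window_nt downstream of the CDS end (inside the 3'UTR)
    stop_window_fraction: float = 0.5
    stop_window_nt: int = 50
    # condition effects
    hyper_gene_fraction: float = 0.2
    hyper_delta: float = 0.25
    hyper_regions: tuple[str, ...] = ("CDS", "THREE_UTR")
    hypo_gene_set_size: int = 100
    hypo_delta: float = 0.30
    restoration_fraction: float = 0.25
    restoration_delta: float = 0.30
    # coverage model: valid_cov ~ NegBin(mean, dispersion) per site/replicate
    coverage_mean: float = 30.0
    coverage_dispersion: float = 20.0
    # read-level model
    reads_per_transcript: int = 100
    read_level_condition: str = "tumor"
    # differential-expression model (three synthetic lines)
    de_lines: tuple[str, ...] = ("lineA", "lineB", "lineC")
    de_down_core_size: int = 30
    de_up_core_size: int = 40
    de_private_per_line: int = 30
    de_core_l2fc: float = 2.0
    de_l2fc_sd: float = 0.3
    hypo_de_down_prob: float = 0.0
    hypo_de_up_prob: float = 0.0
    # binding intervals
    binding_down_frac: float = 0.5
    binding_up_frac: float = 0.05
    binding_halfwidth: int = 25
    binding_source: str = "synthetic_reader"

    def __post_init__(self) -> None:
        for name in (
            "p_methylated_drach",
            "p_methylated_nondrach",
            "stop_window_fraction",
            "hyper_gene_fraction",
            "restoration_fraction",
            "binding_down_frac",
            "binding_up_frac",
            "hypo_de_down_prob",
            "hypo_de_up_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("utr5_len", "cds_len", "utr3_len"):
            lo, hi = getattr(self, name)
            if lo < 5:
                raise ValueError(f"{name} range must start at >= 5 nt, got {lo}")
            if hi < lo:
                raise ValueError(f"{name} range inverted")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        with open(path, "w") as out:
            yaml.safe_dump(data, out, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        kwargs = {}
        valid = {f.name: f for f in dataclasses.fields(cls)}
        for k, v in data.items():
            if k not in valid:
                raise ValueError(f"unknown synthetic config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)


@dataclass
class SiteTruth:
    """Ground truth for one planted site."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    gpos: int
    tpos: int
    region: Region
    motif: MotifClass
    methylated: bool
    base_level: float
    levels: dict[str, float]
    is_hyper: bool = False
    is_hypo: bool = False
    is_restored: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.gpos, self.strand)


@dataclass
class SyntheticAnnotation:
    transcripts: list[TranscriptModel]
    sites: list[SiteTruth]
    genome: dict[str, str]
    hyper_genes: set[str]
    hypo_genes: set[str]
    config: SyntheticConfig
    seed: int


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, stream)])


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    low: int,
    high: int,
    spacing: int,
    taken: list[int],
) -> list[int]:
    """Greedily sample up to n positions in [low, high) keeping all accepted
    positions >= spacing apart from each other and from ``taken``."""
    accepted: list[int] = []
    if high <= low:
        return accepted
    for _ in range(n):
        for _try in range(30):
            p = int(rng.integers(low, high))
            if all(abs(p - q) >= spacing for q in taken) and all(
                abs(p - q) >= spacing for q in accepted
            ):
                accepted.append(p)
                break
    return accepted


def generate_annotation(
    config: SyntheticConfig, seed: int, outdir=None
) -> SyntheticAnnotation:
    """Build transcripts, genome and ground-truth sites (with per-condition
    stoichiometries); writes ``annotation.gtf`` and ``genome.fa`` to
    ``outdir`` when given."""
    rng = _rng(seed, _STAGE_ANNOTATION)

    n_hyper = int(round(config.hyper_gene_fraction * config.n_genes))
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    perm = rng.permutation(config.n_genes)
    hyper_genes = {gene_ids[i] for i in perm[:n_hyper]}
    n_hypo = min(config.hypo_gene_set_size, config.n_genes - n_hyper)
    hypo_genes = {gene_ids[i] for i in perm[n_hyper : n_hyper + n_hypo]}
    hyper_regions = {Region(r) for r in config.hyper_regions}

    genome_parts: list[str] = []
    cursor = 0

    def background(n: int) -> str:
        return "".join(
            _BACKGROUND[i] for i in rng.integers(0, len(_BACKGROUND), size=n)
        )

    transcripts: list[TranscriptModel] = []
    sites: list[SiteTruth] = []

    for gi, gene_id in enumerate(gene_ids):
        u5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        cds = int(rng.integers(config.cds_len[0], config.cds_len[1] + 1))
        u3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        ilen = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
        L = u5 + cds + u3
        strand = "+" if gi % 2 == 0 else "-"
        tid = f"{gene_id}.t1"

        # --- plant sites on the transcript ---------------------------------
        n_drach = int(rng.poisson(config.drach_per_kb * L / 1000.0))
        n_nond = int(rng.poisson(config.nondrach_a_per_kb * L / 1000.0))
        stop_lo = u5 + cds
        stop_hi = min(u5 + cds + config.stop_window_nt, L - 3)

        planted: list[tuple[int, MotifClass, bool, float, bool]] = []
        taken: list[int] = []
        for motif, count, p_meth in (
            (MotifClass.DRACH, n_drach, config.p_methylated_drach),
            (MotifClass.NON_DRACH, n_nond, config.p_methylated_nondrach),
        ):
            for _ in range(count):
                methylated = bool(rng.random() < p_meth)
                if methylated:
                    level = float(rng.beta(*config.meth_beta))
                else:
                    level = float(rng.uniform(0.0, config.noise_level_max))
                in_stop = methylated and rng.random() < config.stop_window_fraction
                if in_stop and stop_hi > stop_lo:
                    pos = _sample_positions(rng, 1, stop_lo, stop_hi,
                                            config.min_site_spacing, taken)
                else:
                    pos = _sample_positions(rng, 1, 2, L - 2,
                                            config.min_site_spacing, taken)
                if not pos:
                    continue  # spacing conflict; site dropped
                taken.append(pos[0])
                planted.append((pos[0], motif, methylated, level, in_stop))

        # --- transcript sequence ------------------------------------------
        seq = list(background(L))
        for tpos, motif, _, _, _ in planted:
            mer = _DRACH_5MER if motif is MotifClass.DRACH else _NONDRACH_5MER
            seq[tpos - 2 : tpos + 3] = mer
        tseq = "".join(seq)

        # --- genomic layout: two exons, one intron ------------------------
        l1 = L // 2
        l2 = L - l1
        gap = background(config.gene_spacing)
        genome_parts.append(gap)
        cursor += config.gene_spacing
        if strand == "+":
            e1 = (cursor, cursor + l1)
            intron_start = e1[1]
            e2 = (intron_start + ilen, intron_start + ilen + l2)
            genome_parts.append(tseq[:l1])
            genome_parts.append(background(ilen))
            genome_parts.append(tseq[l1:])
            exons = (e1, e2)
            cursor = e2[1]
        else:
            eB = (cursor, cursor + l2)  # transcript tail
            intron_start = eB[1]
            eA = (intron_start + ilen, intron_start + ilen + l1)  # head
            genome_parts.append(_revcomp(tseq[l1:]))
            genome_parts.append(background(ilen))
            genome_parts.append(_revcomp(tseq[:l1]))
            exons = (eA, eB)
            cursor = eA[1]

        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=config.chrom,
            strand=strand,
            exons=exons,
            cds_start_t=u5,
            cds_end_t=u5 + cds,
            sequence=tseq,
        )
        transcripts.append(model)

        # --- per-condition stoichiometries --------------------------------
        is_hyper_gene = gene_id in hyper_genes
        is_hypo_gene = gene_id in hypo_genes
        for tpos, motif, methylated, base, _ in planted:
            region = assign_region(tpos, model, 0)
            gpos = transcript_to_genome(tpos, model)
            normal = base
            tumor = base
            is_hyper = (
                is_hyper_gene and motif is MotifClass.DRACH and region in hyper_regions
            )
            is_hypo = (
                is_hypo_gene
                and methylated
                and motif is MotifClass.DRACH
                and region is Region.THREE_UTR
            )
            if is_hyper:
                tumor = min(1.0, tumor + config.hyper_delta)
            if is_hypo:
                tumor = max(0.0, tumor - config.hypo_delta)
            treated = tumor
            is_restored = False
            if is_hypo and rng.random() < config.restoration_fraction:
                treated = min(1.0, tumor + config.restoration_delta)
                is_restored = True
            sites.append(
                SiteTruth(
                    gene_id=gene_id,
                    transcript_id=tid,
                    chrom=config.chrom,
                    strand=strand,
                    gpos=gpos,
                    tpos=tpos,
                    region=region,
                    motif=motif,
                    methylated=methylated,
                    base_level=base,
                    levels={
                        "normal": normal,
                        "tumor": tumor,
                        "tumor_untreated": tumor,
                        "tumor_treated": treated,
                    },
                    is_hyper=is_hyper,
                    is_hypo=is_hypo,
                    is_restored=is_restored,
                )
            )

    genome = {config.chrom: "".join(genome_parts)}
    ann = SyntheticAnnotation(
        transcripts=transcripts,
        sites=sites,
        genome=genome,
        hyper_genes=hyper_genes,
        hypo_genes=hypo_genes,
        config=config,
        seed=seed,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(transcripts, outdir / "annotation.gtf")
        write_fasta(genome, outdir / "genome.fa")
        write_ground_truth(ann, outdir / "ground_truth.tsv")
    return ann


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as out:
        for name in sorted(genome):
            out.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def _tx_to_genomic_blocks(
    t: TranscriptModel, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Genomic half-open blocks covered by transcript range [t_start, t_end)."""
    blocks = []
    offset = 0
    for s, e in t.exons:
        n = e - s
        a = max(t_start, offset)
        b = min(t_end, offset + n)
        if a < b:
            if t.strand == "+":
                blocks.append((s + (a - offset), s + (b - offset)))
            else:
                blocks.append((e - (b - offset), e - (a - offset)))
        offset += n
    return sorted(blocks)


def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write gene/transcript/exon/CDS features (GTF, 1-based inclusive)."""
    with open(path, "w") as out:
        for t in sorted(transcripts, key=lambda x: x.genomic_span()):
            gmin, gmax = t.genomic_span()
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            gattrs = f'gene_id "{t.gene_id}";'

            def row(feature: str, s: int, e: int, a: str) -> str:
                return (
                    f"{t.chrom}\tsynthetic\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\t{a}\n"
                )

            out.write(row("gene", gmin, gmax, gattrs))
            out.write(row("transcript", gmin, gmax, attrs))
            for s, e in sorted(t.exons):
                out.write(row("exon", s, e, attrs))
            if t.is_coding:
                for s, e in _tx_to_genomic_blocks(t, t.cds_start_t, t.cds_end_t):
                    out.write(row("CDS", s, e, attrs))


_TRUTH_HEADER = [
    "gene_id", "transcript_id", "chrom", "gpos", "strand", "tpos", "region",
    "motif", "methylated", "base_level", "level_normal", "level_tumor",
    "level_tumor_untreated", "level_tumor_treated", "is_hyper", "is_hypo",
    "is_restored",
]


def write_ground_truth(ann: SyntheticAnnotation, path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_TRUTH_HEADER) + "\n")
        for s in sorted(ann.sites, key=lambda x: (x.chrom, x.gpos, x.strand)):
            out.write(
                "\t".join(
                    [
                        s.gene_id, s.transcript_id, s.chrom, str(s.gpos), s.strand,
                        str(s.tpos), s.region.value, s.motif.value,
                        str(int(s.methylated)), f"{s.base_level:.6f}",
                        f"{s.levels['normal']:.6f}", f"{s.levels['tumor']:.6f}",
                        f"{s.levels['tumor_untreated']:.6f}",
                        f"{s.levels['tumor_treated']:.6f}",
                        str(int(s.is_hyper)), str(int(s.is_hypo)),
                        str(int(s.is_restored)),
                    ]
                )
                + "\n"
            )


def generate_site_counts(
    ann: SyntheticAnnotation,
    config: SyntheticConfig,
    seed: int,
    outdir=None,
    conditions: Sequence[str] = CONDITIONS,
) -> dict[str, list[list[SiteRecord]]]:
    """Draw per-replicate pileup records for each condition.

    Per site and replicate, ``valid_cov ~ NegBin(coverage_mean,
    coverage_dispersion)`` and ``n_mod ~ Binomial(valid_cov, level)``; files
    are emitted in the 18-column count dialect as
    ``pileup_<condition>_rep<k>.tsv``.
    """
    out: dict[str, list[list[SiteRecord]]] = {}
    p_nb = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)
    ordered_sites = sorted(ann.sites, key=lambda s: (s.chrom, s.gpos, s.strand))
    for ci, cond in enumerate(conditions):
        cond_idx = CONDITIONS.index(cond)
        out[cond] = []
        for rep in range(config.replicates):
            rng = _rng(seed, _STAGE_COUNTS, cond_idx, rep)
            levels = np.array([s.levels[cond] for s in ordered_sites])
            covs = rng.negative_binomial(config.coverage_dispersion, p_nb,
                                         size=len(ordered_sites))
            mods = rng.binomial(covs, levels)
            sample_id = f"{cond}_rep{rep + 1}"
            records = [
                SiteRecord(
                    chrom=s.chrom,
                    start=s.gpos,
                    end=s.gpos + 1,
                    strand=s.strand,
                    mod_code="a",
                    valid_cov=int(c),
                    n_mod=int(m),
                    sample_id=sample_id,
                    condition=cond,
                )
                for s, c, m in zip(ordered_sites, covs, mods)
            ]
            out[cond].append(records)
            if outdir is not None:
                outdir = Path(outdir)
                outdir.mkdir(parents=True, exist_ok=True)
                write_pileup(records, outdir / f"pileup_{cond}_rep{rep + 1}.tsv")
    return out


def simulate_read_level(
    site_levels: Sequence[float],
    n_reads: int,
    rng: np.random.Generator,
    transcript_id: str,
    read_prefix: str = "read",
) -> list[ReadLevelRecord]:
    """Draw reads for one transcript: each site modified independently on each
    read at its stoichiometry.  The expected modified-read fraction is
    ``1 - prod(1 - s_i)``."""
    levels = np.asarray(site_levels, dtype=float)
    n_sites = len(levels)
    if n_sites == 0:
        mods = np.zeros(n_reads, dtype=int)
    else:
        draws = rng.random((n_reads, n_sites)) < levels
        mods = draws.sum(axis=1)
    return [
        ReadLevelRecord(
            read_id=f"{read_prefix}_{transcript_id}_{i}",
            transcript_id=transcript_id,
            n_called_A=n_sites,
            n_mod=int(m),
        )
        for i, m in enumerate(mods)
    ]


def generate_read_level(
    ann: SyntheticAnnotation,
    config: SyntheticConfig,
    seed: int,
    outdir=None,
) -> list[ReadLevelRecord]:
    """Read-level records for every transcript at the configured condition's
    stoichiometries."""
    rng = _rng(seed, _STAGE_READS)
    by_tid: dict[str, list[float]] = {}
    for s in ann.sites:
        by_tid.setdefault(s.transcript_id, []).append(
            s.levels[config.read_level_condition]
        )
    records: list[ReadLevelRecord] = []
    for t in ann.transcripts:
        records.extend(
            simulate_read_level(
                by_tid.get(t.transcript_id, []),
                config.reads_per_transcript,
                rng,
                t.transcript_id,
            )
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_read_level_table(records, outdir / "read_level.tsv")
    return records


def generate_de_and_binding(
    ann: SyntheticAnnotation,
    config: SyntheticConfig,
    seed: int,
    outdir=None,
) -> tuple[dict[str, list[DEResult]], list[BindingInterval], dict]:
    """Differential-expression tables for the synthetic cell lines plus
    binding intervals.

    Common up/down cores are shared across lines (the down core is drawn from
    the hypo gene set when large enough); each line adds private significant
    genes.  Binding intervals are placed over the strongest methylated 3'UTR
    site of a configurable fraction of down-core (and up-core) genes.

    Returns (tables per line, intervals, ground-truth dict).
    """
    rng = _rng(seed, _STAGE_DE)
    gene_ids = sorted({t.gene_id for t in ann.transcripts})
    hypo_sorted = sorted(ann.hypo_genes)

    if len(hypo_sorted) >= config.de_down_core_size:
        down_core = set(
            np.array(hypo_sorted)[
                rng.choice(len(hypo_sorted), config.de_down_core_size, replace=False)
            ]
        )
    else:
        down_core = set(hypo_sorted)
    pool = [g for g in gene_ids if g not in down_core]
    n_up = min(config.de_up_core_size, len(pool))
    up_core = set(np.array(pool)[rng.choice(len(pool), n_up, replace=False)])

    def sig_fdr(r: np.random.Generator) -> float:
        return float(10.0 ** -r.uniform(3.0, 8.0))

    tables: dict[str, list[DEResult]] = {}
    private: dict[str, set[str]] = {}
    for li, line in enumerate(config.de_lines):
        line_rng = _rng(seed, _STAGE_DE, 10 + li)
        rest = [g for g in gene_ids if g not in down_core and g not in up_core]
        priv = set(
            np.array(rest)[
                line_rng.choice(len(rest), min(config.de_private_per_line, len(rest)),
                                replace=False)
            ]
        )
        private[line] = priv
        rows: list[DEResult] = []
        for g in gene_ids:
            if g in down_core:
                fc = -abs(line_rng.normal(config.de_core_l2fc, config.de_l2fc_sd))
                fdr = sig_fdr(line_rng)
            elif g in up_core:
                fc = abs(line_rng.normal(config.de_core_l2fc, config.de_l2fc_sd))
                fdr = sig_fdr(line_rng)
            elif g in priv:
                sign = 1.0 if line_rng.random() < 0.5 else -1.0
                fc = sign * abs(line_rng.normal(config.de_core_l2fc, config.de_l2fc_sd))
                fdr = sig_fdr(line_rng)
            elif (
                g in ann.hypo_genes
                and (config.hypo_de_down_prob > 0 or config.hypo_de_up_prob > 0)
            ):
                u = line_rng.random()
                if u < config.hypo_de_down_prob:
                    fc = -abs(line_rng.normal(1.5, config.de_l2fc_sd))
                elif u < config.hypo_de_down_prob + config.hypo_de_up_prob:
                    fc = abs(line_rng.normal(1.5, config.de_l2fc_sd))
                else:
                    fc = float(line_rng.normal(0.0, 0.1))
                fdr = float(line_rng.uniform(0.0, 0.009))
            else:
                fc = float(line_rng.normal(0.0, 0.2))
                fdr = float(line_rng.uniform(0.2, 1.0))
            rows.append(DEResult(gene_id=g, log2fc=fc, fdr=min(fdr, 1.0),
                                 cell_line=line))
        tables[line] = rows

    # binding intervals over methylated 3'UTR sites of core genes
    best_site: dict[str, SiteTruth] = {}
    for s in ann.sites:
        if s.region is Region.THREE_UTR and s.methylated:
            cur = best_site.get(s.gene_id)
            if cur is None or s.base_level > cur.base_level:
                best_site[s.gene_id] = s

    bind_rng = _rng(seed, _STAGE_DE, 99)
    intervals: list[BindingInterval] = []
    bound_genes: dict[str, list[str]] = {"down": [], "up": []}
    for direction, core, frac in (
        ("down", sorted(down_core), config.binding_down_frac),
        ("up", sorted(up_core), config.binding_up_frac),
    ):
        for g in core:
            if g in best_site and bind_rng.random() < frac:
                s = best_site[g]
                intervals.append(
                    BindingInterval(
                        chrom=s.chrom,
                        start=max(0, s.gpos - config.binding_halfwidth),
                        end=s.gpos + config.binding_halfwidth + 1,
                        strand=".",
                        source_label=config.binding_source,
                    )
                )
                bound_genes[direction].append(g)

    truth = {
        "down_core": sorted(down_core),
        "up_core": sorted(up_core),
        "private": {k: sorted(v) for k, v in private.items()},
        "bound_down_genes": bound_genes["down"],
        "bound_up_genes": bound_genes["up"],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for line, rows in tables.items():
            write_de_table(rows, outdir / f"de_{line}.tsv")
        write_binding_bed(intervals, outdir / "binding.bed")
        with open(outdir / "de_binding_truth.json", "w") as out:
            json.dump(truth, out, indent=2, sort_keys=True)
    return tables, intervals, truth


def generate_corpus(config: SyntheticConfig, seed: int, outdir) -> SyntheticAnnotation:
    """Generate and write the full corpus (annotation, pileups, read-level
    table, DE tables, binding BED, ground truth) under ``outdir``."""
    outdir = Path(outdir)
    ann = generate_annotation(config, seed, outdir)
    generate_site_counts(ann, config, seed, outdir)
    generate_read_level(ann, config, seed, outdir)
    generate_de_and_binding(ann, config, seed, outdir)
    config.to_yaml(outdir / "synthetic_config.yaml")
    return ann


# ---------------------------------------------------------------------------
# Analytic helpers for null calibration
# ---------------------------------------------------------------------------

def mean_fraction_distribution(
    level: float, covs: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the mean of per-replicate modified fractions for
    independent Binomial(cov_r, level) counts (replicates with zero coverage
    excluded, mirroring the aggregation rule).

    Returns (sorted values, probabilities).
    """
    from scipy.stats import binom

    covs = [c for c in covs if c > 0]
    if not covs:
        raise ValueError("no replicate with positive coverage")
    values = np.array([0.0])
    probs = np.array([1.0])
    for c in covs:
        ks = np.arange(c + 1)
        pk = binom.pmf(ks, c, level)
        values = (values[:, None] + (ks / c)[None, :]).ravel()
        probs = (probs[:, None] * pk[None, :]).ravel()
    values = values / len(covs)
    order = np.argsort(values)
    return values[order], probs[order]


def crossing_probability(
    level_a: float,
    covs_a: Sequence[int],
    level_b: float,
    covs_b: Sequence[int],
    threshold: float,
    two_sided: bool = True,
) -> float:
    """Exact P(delta-hat beyond the threshold) under the binomial count model,
    where delta-hat is the difference of per-condition means of replicate
    fractions.  Strict inequality, matching the threshold counters."""
    va, pa = mean_fraction_distribution(level_a, covs_a)
    vb, pb = mean_fraction_distribution(level_b, covs_b)
    cdf_b = np.cumsum(pb)

    eps = 1e-12
    # P(delta > t) = sum_a P(A=a) * P(B < a - t)
    idx_lt = np.searchsorted(vb, va - threshold - eps, side="left")
    p_up = float(np.sum(pa * np.where(idx_lt > 0, cdf_b[idx_lt - 1], 0.0)))
    if not two_sided:
        return p_up
    # P(delta < -t) = sum_a P(A=a) * P(B > a + t)
    idx_gt = np.searchsorted(vb, va + threshold + eps, side="right")
    tail_b = 1.0 - np.concatenate([[0.0], cdf_b])
    p_dn = float(np.sum(pa * tail_b[idx_gt]))
    return p_up + p_dn
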