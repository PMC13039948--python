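"""Map genomic sites onto transcripts: coordinates, regions, motifs, metagene.

Coordinate conventions: all genomic and transcript coordinates are 0-based;
genomic intervals are half-open.  Exons of a :class:`TranscriptModel` are
stored in transcript orientation (5'->3'), i.e. descending genomic order for
minus-strand transcripts.

Sites are annotated against a single representative transcript per gene
(longest CDS, deterministic tie-breaks); sites falling in no representative
transcript are retained as "unassigned" and excluded from region-stratified
outputs.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "Region",
    "MotifClass",
    "TranscriptModel",
    "SiteAnnotation",
    "SiteAnnotator",
    "genome_to_transcript",
    "transcript_to_genome",
    "assign_region",
    "classify_motif",
    "metagene_position",
    "choose_representative_transcript",
    "load_transcripts",
    "reverse_complement",
]


class Region(str, Enum):
    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    THREE_UTR = "THREE_UTR"
    THREE_UTR_EXT = "THREE_UTR_EXT"
    NONCODING = "NONCODING"
    UNASSIGNED = "UNASSIGNED"


class MotifClass(str, Enum):
    DRACH = "DRACH"
    NON_DRACH = "NON_DRACH"
    UNDEFINED = "UNDEFINED"


# D = A/G/U, R = A/G, central A, C, H = A/C/U (T treated as U).
_DRACH_RE = re.compile(r"^[AGT][AG]AC[ACT]$")

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript on a genome.

    ``exons`` are genomic half-open intervals ordered 5'->3' in transcript
    orientation.  ``cds_start_t``/``cds_end_t`` are transcript coordinates
    (half-open) of the coding region, ``None`` for noncoding transcripts.
    ``sequence`` (optional) is the spliced sequence in transcript orientation.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_t: int | None = None
    cds_end_t: int | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon interval ({s},{e})")
        ordered = sorted(self.exons, key=lambda x: x[0])
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if e1 > s2:
                raise ValueError("exons overlap")
        expected = ordered if self.strand == "+" else ordered[::-1]
        if tuple(expected) != tuple(self.exons):
            raise ValueError("exons not sorted 5'->3' in transcript orientation")
        if (self.cds_start_t is None) != (self.cds_end_t is None):
            raise ValueError("cds_start_t and cds_end_t must be set together")
        if self.cds_start_t is not None:
            if not (0 <= self.cds_start_t < self.cds_end_t <= self.length):
                raise ValueError("CDS coordinates out of range")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length != transcript length")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_t is not None

    @property
    def cds_length(self) -> int:
        if not self.is_coding:
            return 0
        return self.cds_end_t - self.cds_start_t  # type: ignore[operator]

    def genomic_span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


def genome_to_transcript(pos: int, strand: str, t: TranscriptModel) -> int | None:
    """Transcript-orientation offset of genomic base ``pos``, or ``None``.

    ``None`` for intronic/out-of-range positions and for strand mismatches;
    absence is a valid outcome, not an error.
    """
    if strand != t.strand:
        return None
    offset = 0
    for s, e in t.exons:
        if s <= pos < e:
            if t.strand == "+":
                return offset + (pos - s)
            return offset + (e - 1 - pos)
        offset += e - s
    return None


def transcript_to_genome(tpos: int, t: TranscriptModel) -> int:
    """Genomic position of transcript base ``tpos`` (inverse of
    :func:`genome_to_transcript` for exonic bases)."""
    if tpos < 0 or tpos >= t.length:
        raise ValueError(f"tpos {tpos} outside transcript of length {t.length}")
    offset = 0
    for s, e in t.exons:
        n = e - s
        if tpos < offset + n:
            within = tpos - offset
            if t.strand == "+":
                return s + within
            return e - 1 - within
        offset += n
    raise AssertionError("unreachable")


def assign_region(tpos: int, t: TranscriptModel, utr3_extension: int = 100) -> Region:
    """Region of a transcript coordinate; the stop-codon-adjacent boundary base
    (``tpos == cds_end_t``) belongs to the 3'UTR."""
    if not t.is_coding:
        if 0 <= tpos < t.length + utr3_extension:
            return Region.NONCODING
        raise ValueError(f"tpos {tpos} out of range")
    if tpos < 0 or tpos >= t.length + utr3_extension:
        raise ValueError(
            f"tpos {tpos} outside [0, {t.length + utr3_extension}) "
            f"(length {t.length} + extension {utr3_extension})"
        )
    if tpos < t.cds_start_t:  # type: ignore[operator]
        return Region.FIVE_UTR
    if tpos < t.cds_end_t:  # type: ignore[operator]
        return Region.CDS
    if tpos < t.length:
        return Region.THREE_UTR
    return Region.THREE_UTR_EXT


def classify_motif(t: TranscriptModel, tpos: int, window_seq: str | None = None) -> MotifClass:
    """DRACH / NON_DRACH / UNDEFINED for the 5-mer centred on ``tpos``.

    UNDEFINED iff the window is unavailable (sequence missing or truncated at
    the transcript ends) or the central base is not A.  ``window_seq`` may
    supply the 5-mer directly (used for extension sites classified from the
    genome).
    """
    if window_seq is None:
        if t.sequence is None:
            return MotifClass.UNDEFINED
        if tpos - 2 < 0 or tpos + 3 > len(t.sequence):
            return MotifClass.UNDEFINED
        window_seq = t.sequence[tpos - 2 : tpos + 3]
    if len(window_seq) != 5:
        return MotifClass.UNDEFINED
    window = window_seq.upper().replace("U", "T")
    if window[2] != "A":
        return MotifClass.UNDEFINED
    return MotifClass.DRACH if _DRACH_RE.match(window) else MotifClass.NON_DRACH


def metagene_position(tpos: int, t: TranscriptModel) -> float | None:
    """Unit-width metagene coordinate in [0,3): 5'UTR -> [0,1), CDS -> [1,2),
    3'UTR -> [2,3).  ``None`` for transcripts missing any region and for
    extension/noncoding positions."""
    if not t.is_coding:
        return None
    utr5_len = t.cds_start_t
    cds_len = t.cds_length
    utr3_len = t.length - t.cds_end_t  # type: ignore[operator]
    if utr5_len < 1 or cds_len < 1 or utr3_len < 1:
        return None
    if tpos < 0 or tpos >= t.length:
        return None
    if tpos < t.cds_start_t:  # type: ignore[operator]
        return (tpos - 0) / utr5_len
    if tpos < t.cds_end_t:  # type: ignore[operator]
        return 1.0 + (tpos - t.cds_start_t) / cds_len  # type: ignore[operator]
    return 2.0 + (tpos - t.cds_end_t) / utr3_len  # type: ignore[operator]


def choose_representative_transcript(
    transcripts: Sequence[TranscriptModel],
) -> TranscriptModel:
    """Deterministic representative: longest CDS, then longest transcript,
    then lexicographically smallest transcript_id."""
    if not transcripts:
        raise ValueError("empty transcript set")
    return min(
        transcripts,
        key=lambda t: (-t.cds_length, -t.length, t.transcript_id),
    )


@dataclass(frozen=True)
class SiteAnnotation:
    transcript_id: str | None
    gene_id: str | None
    tpos: int | None
    region: Region
    motif_class: MotifClass
    metagene_x: float | None


_UNASSIGNED = SiteAnnotation(
    transcript_id=None,
    gene_id=None,
    tpos=None,
    region=Region.UNASSIGNED,
    motif_class=MotifClass.UNDEFINED,
    metagene_x=None,
)


class SiteAnnotator:
    """Annotate genomic sites against one representative transcript per gene.

    Parameters
    ----------
    transcripts:
        All transcript models; one representative per gene is chosen with
        :func:`choose_representative_transcript`.
    utr3_extension:
        Number of nucleotides past the annotated transcript end still assigned
        to the gene (region ``THREE_UTR_EXT``).
    genome:
        Optional chrom -> sequence mapping, used to classify the motif of
        extension sites (exonic sites use the spliced transcript sequence).
    """

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel],
        utr3_extension: int = 100,
        genome: Mapping[str, str] | None = None,
    ) -> None:
        self.utr3_extension = utr3_extension
        self.genome = genome
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        self.representatives: dict[str, TranscriptModel] = {
            g: choose_representative_transcript(ts) for g, ts in by_gene.items()
        }
        # Per (chrom, strand): sorted interval index over exons and the
        # downstream extension window of each representative transcript.
        self._index: dict[tuple[str, str], list[tuple[int, int, TranscriptModel, bool]]] = {}
        self._maxlen: dict[tuple[str, str], int] = {}
        for t in self.representatives.values():
            key = (t.chrom, t.strand)
            entries = self._index.setdefault(key, [])
            for s, e in t.exons:
                entries.append((s, e, t, False))
            gmin, gmax = t.genomic_span()
            if utr3_extension > 0:
                if t.strand == "+":
                    entries.append((gmax, gmax + utr3_extension, t, True))
                else:
                    entries.append((max(0, gmin - utr3_extension), gmin, t, True))
        for key, entries in self._index.items():
            entries.sort(key=lambda x: x[0])
            self._maxlen[key] = max(e - s for s, e, _, _ in entries)
        self._starts = {
            key: [s for s, _, _, _ in entries] for key, entries in self._index.items()
        }

    def _lookup(self, chrom: str, pos: int, strand: str):
        key = (chrom, strand)
        entries = self._index.get(key)
        if not entries:
            return None
        starts = self._starts[key]
        i = bisect_right(starts, pos) - 1
        lo = pos - self._maxlen[key]
        exonic_hit = None
        ext_hit = None
        while i >= 0 and starts[i] > lo:
            s, e, t, is_ext = entries[i]
            if s <= pos < e:
                if is_ext and ext_hit is None:
                    ext_hit = t
                elif not is_ext and exonic_hit is None:
                    exonic_hit = t
            i -= 1
        return exonic_hit, ext_hit

    def annotate(self, chrom: str, pos: int, strand: str) -> SiteAnnotation:
        hit = self._lookup(chrom, pos, strand)
        if hit is None or (hit[0] is None and hit[1] is None):
            return _UNASSIGNED
        exonic_t, ext_t = hit
        if exonic_t is not None:
            t = exonic_t
            tpos = genome_to_transcript(pos, strand, t)
            assert tpos is not None
            region = assign_region(tpos, t, self.utr3_extension)
            motif = classify_motif(t, tpos)
            mx = metagene_position(tpos, t)
            return SiteAnnotation(t.transcript_id, t.gene_id, tpos, region, motif, mx)
        t = ext_t
        # Downstream extension window: contiguous in the genome, not spliced.
        gmin, gmax = t.genomic_span()
        if t.strand == "+":
            tpos = t.length + (pos - gmax)
        else:
            tpos = t.length + (gmin - 1 - pos)
        region = (
            assign_region(tpos, t, self.utr3_extension)
            if t.is_coding
            else Region.NONCODING
        )
        motif = MotifClass.UNDEFINED
        if self.genome is not None and chrom in self.genome:
            gseq = self.genome[chrom]
            if pos - 2 >= 0 and pos + 3 <= len(gseq):
                window = gseq[pos - 2 : pos + 3]
                if strand == "-":
                    window = reverse_complement(window)
                motif = classify_motif(t, tpos, window_seq=window)
        return SiteAnnotation(t.transcript_id, t.gene_id, tpos, region, motif, None)

    def annotate_key(self, key: tuple[str, int, str]) -> SiteAnnotation:
        chrom, pos, strand = key
        return self.annotate(chrom, pos, strand)


def _load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_transcripts(
    gtf_path,
    fasta_path=None,
    fasta_is_genome: bool = True,
) -> list[TranscriptModel]:
    """Build :class:`TranscriptModel` objects from a GTF (exon + CDS features,
    ``gene_id``/``transcript_id`` attributes).

    If ``fasta_path`` is given it is read as a genome FASTA and transcript
    sequences are spliced internally (set ``fasta_is_genome=False`` if the
    FASTA already holds transcript sequences keyed by transcript id).
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    seqs = _load_fasta(fasta_path) if fasta_path is not None else None

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        meta[tid] = (gid, feat.seqid, feat.strand)
        # GTF is 1-based inclusive -> 0-based half-open.
        iv = (feat.start - 1, feat.end)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    models: list[TranscriptModel] = []
    for tid, ivs in exons.items():
        gid, chrom, strand = meta[tid]
        ivs = sorted(ivs)
        ordered = tuple(ivs) if strand == "+" else tuple(ivs[::-1])
        seq = None
        if seqs is not None:
            if fasta_is_genome:
                if chrom not in seqs:
                    raise KeyError(f"chromosome {chrom!r} not in FASTA")
                parts = []
                for s, e in ordered:
                    chunk = seqs[chrom][s:e]
                    parts.append(chunk if strand == "+" else reverse_complement(chunk))
                seq = "".join(parts)
            else:
                seq = seqs.get(tid)
        cds_start_t = cds_end_t = None
        if tid in cds:
            model_nocds = TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=ordered,
            )
            tposs = []
            for s, e in cds[tid]:
                for gp in (s, e - 1):
                    tp = genome_to_transcript(gp, strand, model_nocds)
                    if tp is None:
                        raise ValueError(f"CDS block of {tid} outside its exons")
                    tposs.append(tp)
            cds_start_t, cds_end_t = min(tposs), max(tposs) + 1
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=ordered,
                cds_start_t=cds_start_t,
                cds_end_t=cds_end_t,
                sequence=seq,
            )
        )
    models.sort(key=lambda t: t.transcript_id)
    return models
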