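"""Promoter-isoform models from transcript annotation.

A *promoter-isoform* is the group of transcripts of a gene that share a
transcription start site (TSS).  Because full-length isoforms greatly
outnumber promoters, quantifying at promoter resolution from junction
reads is far more robust than full isoform deconvolution.  This module
builds promoter-isoform models from exon structures: it groups
transcripts by strand-aware TSS, ranks promoters 5'->3' in transcription
direction, derives the set of first-intron junctions that identify each
promoter, classifies identifiability (``unique`` / ``internal`` /
``single_exon_only``), and attaches promoter-proximal open-chromatin
regions (OCRs).

Coordinates are 0-based half-open throughout; GTF input is converted at
the reader boundary (:func:`promlink.io.read_gtf`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: window (bp) around the TSS used for promoter/OCR assignment
PROMOTER_WINDOW_BP = 1000

CLASS_UNIQUE = "unique"
CLASS_INTERNAL = "internal"
CLASS_SINGLE_EXON = "single_exon_only"


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript.

    Exons are 0-based half-open genomic intervals, sorted ascending by
    coordinate and non-overlapping, all on one chromosome and strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.transcript_id}: empty/inverted exon ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def tss(self) -> int:
        """Strand-aware TSS: interval start on ``+``, interval end on ``-``."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals (upstream exon end, downstream exon start)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    def first_intron(self) -> tuple[int, int] | None:
        """The intron adjacent to the first exon in transcription direction.

        Returned as a genomic ``(start, end)`` pair; ``None`` for
        single-exon transcripts.
        """
        if len(self.exons) < 2:
            return None
        introns = self.introns()
        return introns[0] if self.strand == "+" else introns[-1]

    def non_first_introns(self) -> list[tuple[int, int]]:
        introns = self.introns()
        if not introns:
            return []
        return introns[1:] if self.strand == "+" else introns[:-1]


@dataclass(frozen=True)
class PromoterIsoform:
    """A promoter: group of transcripts sharing a strand-aware TSS.

    ``rank`` is 1 for the gene's 5'-most promoter and increases in
    transcription direction.  ``first_intron_junctions`` holds the
    genomic (donor-side, acceptor-side) intron coordinates of the member
    transcripts' first introns — the reads spanning these junctions
    quantify the promoter.  ``label_transcript`` is the lexicographically
    smallest member, recorded as the promoter's representative.
    """

    promoter_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    rank: int
    member_transcripts: frozenset[str]
    first_intron_junctions: frozenset[tuple[int, int]]
    promoter_class: str = CLASS_UNIQUE

    @property
    def label_transcript(self) -> str:
        return min(self.member_transcripts)

    @property
    def is_quantifiable(self) -> bool:
        return self.promoter_class == CLASS_UNIQUE

    @property
    def is_five_prime(self) -> bool:
        return self.rank == 1


def build_promoters(
    transcripts: list[TranscriptModel],
) -> list[PromoterIsoform]:
    """Group transcripts into promoter-isoforms by strand-aware TSS.

    Within each gene, transcripts sharing the same TSS form one promoter.
    Promoters are ranked by TSS position in transcription direction
    (rank 1 = 5'-most) and given deterministic ids
    ``<gene_id>.P<zero-padded rank>``.  Promoters whose members are all
    single-exon get class ``single_exon_only`` (they carry no identifying
    junction); everything else starts as ``unique`` until
    :func:`classify_identifiability` refines it.

    Genes with transcripts on both strands are rejected with a warning
    and excluded entirely.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    promoters: list[PromoterIsoform] = []
    for gene_id in sorted(by_gene):
        members = by_gene[gene_id]
        strands = {t.strand for t in members}
        chroms = {t.chrom for t in members}
        if len(strands) > 1 or len(chroms) > 1:
            logger.warning(
                "gene %s has transcripts on multiple strands/chromosomes; rejected",
                gene_id,
            )
            continue
        strand = members[0].strand
        groups: dict[int, list[TranscriptModel]] = {}
        for t in members:
            groups.setdefault(t.tss, []).append(t)
        # rank 1 = 5'-most in transcription direction
        tss_order = sorted(groups, reverse=(strand == "-"))
        width = max(2, len(str(len(tss_order))))
        for rank, tss in enumerate(tss_order, start=1):
            grp = groups[tss]
            junctions = frozenset(
                fi for t in grp if (fi := t.first_intron()) is not None
            )
            cls = CLASS_SINGLE_EXON if not junctions else CLASS_UNIQUE
            promoters.append(
                PromoterIsoform(
                    promoter_id=f"{gene_id}.P{rank:0{width}d}",
                    gene_id=gene_id,
                    chrom=members[0].chrom,
                    strand=strand,
                    tss=tss,
                    rank=rank,
                    member_transcripts=frozenset(t.transcript_id for t in grp),
                    first_intron_junctions=junctions,
                    promoter_class=cls,
                )
            )
    return promoters


def classify_identifiability(
    promoters: list[PromoterIsoform],
    transcripts: list[TranscriptModel],
) -> list[PromoterIsoform]:
    """Flag promoters whose first-intron junctions are ambiguous.

    A promoter is ``internal`` when any edge (either coordinate) of any
    of its first-intron junctions coincides with an edge of a non-first
    intron of another transcript of the same gene: junction reads could
    then come from internal splicing of a different isoform, so the
    promoter cannot be quantified reliably.  Comparison is within-gene
    only.  ``single_exon_only`` promoters are left unchanged; remaining
    multi-exon promoters are ``unique``.
    """
    nonfirst_edges: dict[str, set[int]] = {}
    for t in transcripts:
        edges = nonfirst_edges.setdefault(t.gene_id, set())
        for start, end in t.non_first_introns():
            edges.add(start)
            edges.add(end)

    out: list[PromoterIsoform] = []
    for p in promoters:
        if p.promoter_class == CLASS_SINGLE_EXON:
            out.append(p)
            continue
        edges = nonfirst_edges.get(p.gene_id, set())
        internal = any(
            start in edges or end in edges for start, end in p.first_intron_junctions
        )
        out.append(
            replace(p, promoter_class=CLASS_INTERNAL if internal else CLASS_UNIQUE)
        )
    return out


def _tss_peak_distance(tss: int, start: int, end: int) -> int:
    """bp distance from a TSS to the nearest edge of peak [start, end)."""
    if start <= tss < end:
        return 0
    if tss < start:
        return start - tss
    return tss - end


def assign_promoter_ocrs(
    promoters: list[PromoterIsoform],
    peaks: pd.DataFrame,
    window_bp: int = PROMOTER_WINDOW_BP,
) -> pd.DataFrame:
    """Assign each promoter its nearest OCR within ``window_bp`` of the TSS.

    Parameters
    ----------
    peaks
        DataFrame with columns ``chrom``, ``start``, ``end``, ``ocr_id``
        (0-based half-open intervals).

    Returns
    -------
    One row per promoter: ``promoter_id``, ``ocr_id`` (NA when no peak
    overlaps the tss +/- window), ``distance_bp``.  Distance ties are
    broken by smaller peak start, then lexicographic ``ocr_id``.
    """
    known_chroms = {p.chrom for p in promoters}
    unknown = set(peaks["chrom"]) - known_chroms
    if unknown:
        logger.warning("peaks on chromosomes without promoters ignored: %s", sorted(unknown))

    by_chrom = {
        chrom: grp.sort_values(["start", "ocr_id"]).reset_index(drop=True)
        for chrom, grp in peaks.groupby("chrom")
    }
    rows = []
    for p in promoters:
        grp = by_chrom.get(p.chrom)
        best: tuple[int, int, str] | None = None
        if grp is not None:
            near = grp[(grp["start"] < p.tss + window_bp) & (grp["end"] > p.tss - window_bp)]
            for start, end, ocr_id in zip(near["start"], near["end"], near["ocr_id"]):
                cand = (_tss_peak_distance(p.tss, int(start), int(end)), int(start), str(ocr_id))
                if best is None or cand < best:
                    best = cand
        if best is None:
            rows.append((p.promoter_id, pd.NA, pd.NA))
        else:
            rows.append((p.promoter_id, best[2], best[0]))
    return pd.DataFrame(rows, columns=["promoter_id", "ocr_id", "distance_bp"])


def promoter_table(promoters: list[PromoterIsoform]) -> pd.DataFrame:
    """Tabular view of promoters (deterministic row and serialization order)."""
    rows = []
    for p in sorted(promoters, key=lambda q: q.promoter_id):
        rows.append(
            {
                "promoter_id": p.promoter_id,
                "gene_id": p.gene_id,
                "chrom": p.chrom,
                "strand": p.strand,
                "tss": p.tss,
                "rank": p.rank,
                "class": p.promoter_class,
                "members": ",".join(sorted(p.member_transcripts)),
                "junctions": ";".join(
                    f"{d}-{a}" for d, a in sorted(p.first_intron_junctions)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "promoter_id", "gene_id", "chrom", "strand", "tss",
            "rank", "class", "members", "junctions",
        ],
    )


def promoter_windows_bed(
    promoters: list[PromoterIsoform], window_bp: int = PROMOTER_WINDOW_BP
) -> pd.DataFrame:
    """BED6 promoter windows (tss +/- window), name = promoter_id."""
    rows = [
        {
            "chrom": p.chrom,
            "start": max(0, p.tss - window_bp),
            "end": p.tss + window_bp,
            "name": p.promoter_id,
            "score": 0,
            "strand": p.strand,
        }
        for p in sorted(promoters, key=lambda q: q.promoter_id)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
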