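"""Promoter model construction, ranking, classification, OCR assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promlink import annotation
from promlink.annotation import (
    CLASS_INTERNAL,
    CLASS_SINGLE_EXON,
    CLASS_UNIQUE,
    TranscriptModel,
    assign_promoter_ocrs,
    build_promoters,
    classify_identifiability,
    promoter_windows_bed,
)

from conftest import make_tx


# ------------------------------------------------------- TranscriptModel

def test_tss_plus_strand_is_first_exon_start():
    t = make_tx("t1", "g1", [(100, 200), (300, 400)], strand="+")
    assert t.tss == 100


def test_tss_minus_strand_is_last_exon_end():
    t = make_tx("t1", "g1", [(100, 200), (300, 400)], strand="-")
    assert t.tss == 400


def test_first_intron_plus_strand():
    t = make_tx("t1", "g1", [(0, 10), (20, 30), (40, 50)], strand="+")
    assert t.first_intron() == (10, 20)
    assert t.non_first_introns() == [(30, 40)]


def test_first_intron_minus_strand_is_last_genomic_intron():
    t = make_tx("t1", "g1", [(0, 10), (20, 30), (40, 50)], strand="-")
    assert t.first_intron() == (30, 40)
    assert t.non_first_introns() == [(10, 20)]


def test_single_exon_has_no_first_intron():
    assert make_tx("t1", "g1", [(0, 10)]).first_intron() is None


@pytest.mark.parametrize(
    "exons, strand",
    [
        ([], "+"),                      # no exons
        ([(10, 10)], "+"),              # empty exon
        ([(10, 5)], "+"),               # inverted exon
        ([(0, 20), (10, 30)], "+"),     # overlapping exons
        ([(0, 10)], "*"),               # invalid strand
    ],
)
def test_transcript_validation_errors(exons, strand):
    with pytest.raises(ValueError):
        make_tx("t1", "g1", exons, strand=strand)


# --------------------------------------------------------- build_promoters

def test_grouping_by_shared_tss():
    txs = [
        make_tx("tA", "g1", [(100, 200), (300, 400)]),
        make_tx("tB", "g1", [(100, 250), (300, 400)]),   # same TSS as tA
        make_tx("tC", "g1", [(500, 600), (700, 800)]),
    ]
    proms = build_promoters(txs)
    assert len(proms) == 2
    assert proms[0].member_transcripts == frozenset({"tA", "tB"})
    assert proms[0].rank == 1 and proms[1].rank == 2
    assert proms[0].promoter_id == "g1.P01"
    assert proms[1].promoter_id == "g1.P02"


def test_rank_one_is_five_prime_most_on_minus_strand():
    txs = [
        make_tx("tA", "g1", [(100, 200), (300, 400)], strand="-"),
        make_tx("tB", "g1", [(100, 200), (500, 600)], strand="-"),
    ]
    proms = build_promoters(txs)
    # on '-' the 5'-most TSS is the largest coordinate (600)
    assert proms[0].rank == 1 and proms[0].tss == 600
    assert proms[1].tss == 400


def test_label_transcript_is_lexicographic_min():
    txs = [
        make_tx("tB", "g1", [(0, 10), (20, 30)]),
        make_tx("tA", "g1", [(0, 15), (20, 30)]),
    ]
    (p,) = build_promoters(txs)
    assert p.label_transcript == "tA"


def test_multi_strand_gene_rejected():
    txs = [
        make_tx("tA", "g1", [(0, 10), (20, 30)], strand="+"),
        make_tx("tB", "g1", [(0, 10), (20, 30)], strand="-"),
        make_tx("tC", "g2", [(0, 10), (20, 30)], strand="+"),
    ]
    proms = build_promoters(txs)
    assert {p.gene_id for p in proms} == {"g2"}


def test_single_exon_only_class():
    txs = [make_tx("tA", "g1", [(0, 10)]), make_tx("tB", "g1", [(0, 20)])]
    (p,) = build_promoters(txs)
    assert p.promoter_class == CLASS_SINGLE_EXON
    assert not p.first_intron_junctions


def _random_transcripts(rng, n_genes=4):
    txs = []
    for g in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(1, 6))
        starts = rng.choice(np.arange(0, 50) * 1000, size=n_tx, replace=True)
        for k, s in enumerate(sorted(int(x) for x in starts)):
            n_ex = int(rng.integers(1, 4))
            exons = []
            pos = s
            for _ in range(n_ex):
                length = int(rng.integers(50, 200))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(100, 500))
            txs.append(
                make_tx(f"g{g}.t{k}", f"g{g}", exons, strand=strand)
            )
    return txs


def test_grouping_oracle_random_instances():
    """Brute-force partition by (gene, strand-aware TSS) on 120 instances."""
    rng = np.random.default_rng(2024)
    for _ in range(120):
        txs = _random_transcripts(rng)
        proms = build_promoters(txs)
        # oracle: dict (gene, tss) -> transcript set
        expected: dict[tuple[str, int], set[str]] = {}
        for t in txs:
            expected.setdefault((t.gene_id, t.tss), set()).add(t.transcript_id)
        got = {
            (p.gene_id, p.tss): set(p.member_transcripts) for p in proms
        }
        assert got == expected
        # oracle: rank order is 5'->3' in transcription direction
        by_gene: dict[str, list] = {}
        for p in proms:
            by_gene.setdefault(p.gene_id, []).append(p)
        for plist in by_gene.values():
            plist.sort(key=lambda p: p.rank)
            assert [p.rank for p in plist] == list(range(1, len(plist) + 1))
            tss_seq = [p.tss for p in plist]
            if plist[0].strand == "+":
                assert tss_seq == sorted(tss_seq)
            else:
                assert tss_seq == sorted(tss_seq, reverse=True)


def test_strand_reflection_preserves_ranks():
    """Mirroring coordinates and flipping strand preserves rank assignment."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        txs = _random_transcripts(rng, n_genes=2)
        lim = 10_000_000
        flipped = [
            make_tx(
                t.transcript_id, t.gene_id,
                sorted((lim - e, lim - s) for s, e in t.exons),
                strand="-" if t.strand == "+" else "+",
            )
            for t in txs
        ]
        ranks = {(p.gene_id, frozenset(p.member_transcripts)): p.rank
                 for p in build_promoters(txs)}
        ranks_f = {(p.gene_id, frozenset(p.member_transcripts)): p.rank
                   for p in build_promoters(flipped)}
        assert ranks == ranks_f


# ------------------------------------------------ classify_identifiability

def test_internal_when_first_intron_edge_matches_nonfirst_intron():
    txs = [
        # tA introns: (10,20) first, (30,40) non-first
        make_tx("tA", "g1", [(0, 10), (20, 30), (40, 50)]),
        # tB first intron (32, 40): its end coincides with tA's non-first
        # intron edge 40 -> internal
        make_tx("tB", "g1", [(30, 32), (40, 50)]),
    ]
    proms = classify_identifiability(build_promoters(txs), txs)
    by_id = {p.promoter_id: p for p in proms}
    assert by_id["g1.P01"].promoter_class == CLASS_UNIQUE
    assert by_id["g1.P02"].promoter_class == CLASS_INTERNAL


def test_internal_comparison_is_within_gene_only():
    txs = [
        make_tx("tA", "g1", [(0, 10), (20, 30), (40, 50)]),
        # same structure as the internal case above but in another gene
        make_tx("tB", "g2", [(30, 32), (40, 50)]),
    ]
    proms = classify_identifiability(build_promoters(txs), txs)
    assert all(p.promoter_class == CLASS_UNIQUE for p in proms)


def test_internal_oracle_random_instances():
    """Edge-set oracle over 120 random annotations."""
    rng = np.random.default_rng(99)
    for _ in range(120):
        txs = _random_transcripts(rng)
        proms = classify_identifiability(build_promoters(txs), txs)
        nonfirst: dict[str, set[int]] = {}
        for t in txs:
            s = nonfirst.setdefault(t.gene_id, set())
            for a, b in t.non_first_introns():
                s |= {a, b}
        for p in proms:
            if p.promoter_class == CLASS_SINGLE_EXON:
                assert not p.first_intron_junctions
                continue
            edges = nonfirst.get(p.gene_id, set())
            expect_internal = any(
                a in edges or b in edges for a, b in p.first_intron_junctions
            )
            assert (p.promoter_class == CLASS_INTERNAL) == expect_internal


# -------------------------------------------------- assign_promoter_ocrs

def _one_promoter(tss=5000, strand="+"):
    txs = [make_tx("t1", "g1", [(tss, tss + 100), (tss + 200, tss + 300)], strand)]
    return build_promoters(txs)


def test_ocr_zero_distance_inside_peak():
    proms = _one_promoter(tss=5000)
    peaks = pd.DataFrame(
        [{"ocr_id": "a", "chrom": "chr1", "start": 4900, "end": 5100}]
    )
    out = assign_promoter_ocrs(proms, peaks)
    assert out.loc[0, "ocr_id"] == "a" and out.loc[0, "distance_bp"] == 0


def test_ocr_distance_and_window_boundary():
    proms = _one_promoter(tss=5000)
    peaks = pd.DataFrame(
        [
            {"ocr_id": "near", "chrom": "chr1", "start": 5800, "end": 5900},
            # window is (tss - 1000, tss + 1000) exclusive at the edges:
            # a peak starting exactly at tss + 1000 does not qualify
            {"ocr_id": "edge", "chrom": "chr1", "start": 6000, "end": 6100},
        ]
    )
    out = assign_promoter_ocrs(proms, peaks)
    assert out.loc[0, "ocr_id"] == "near"
    assert out.loc[0, "distance_bp"] == 800
    out2 = assign_promoter_ocrs(proms, peaks.iloc[[1]])
    assert pd.isna(out2.loc[0, "ocr_id"])


def test_ocr_tie_breaks_by_start_then_id():
    proms = _one_promoter(tss=5000)
    peaks = pd.DataFrame(
        [
            {"ocr_id": "z", "chrom": "chr1", "start": 5100, "end": 5200},
            {"ocr_id": "a", "chrom": "chr1", "start": 4800, "end": 4900},
        ]
    )
    # both at distance 100; smaller start wins
    out = assign_promoter_ocrs(proms, peaks)
    assert out.loc[0, "ocr_id"] == "a"
    peaks_same_start = pd.DataFrame(
        [
            {"ocr_id": "z", "chrom": "chr1", "start": 5100, "end": 5200},
            {"ocr_id": "b", "chrom": "chr1", "start": 5100, "end": 5200},
        ]
    )
    out = assign_promoter_ocrs(proms, peaks_same_start)
    assert out.loc[0, "ocr_id"] == "b"


def test_ocr_oracle_random_instances():
    """Exhaustive nearest-peak oracle on 100 random instances."""
    rng = np.random.default_rng(5)

    def dist(tss, s, e):
        if s <= tss < e:
            return 0
        return s - tss if tss < s else tss - e

    for _ in range(100):
        tss = int(rng.integers(2000, 50_000))
        proms = _one_promoter(tss=tss)
        n_pk = int(rng.integers(0, 8))
        rows = []
        for k in range(n_pk):
            s = int(rng.integers(max(0, tss - 3000), tss + 3000))
            rows.append({"ocr_id": f"p{k}", "chrom": "chr1",
                         "start": s, "end": s + int(rng.integers(50, 400))})
        peaks = pd.DataFrame(rows, columns=["ocr_id", "chrom", "start", "end"])
        out = assign_promoter_ocrs(proms, peaks)
        cands = [
            (dist(tss, r["start"], r["end"]), r["start"], r["ocr_id"])
            for _, r in peaks.iterrows()
            if r["start"] < tss + 1000 and r["end"] > tss - 1000
        ]
        if not cands:
            assert pd.isna(out.loc[0, "ocr_id"])
        else:
            best = min(cands)
            assert out.loc[0, "ocr_id"] == best[2]
            assert out.loc[0, "distance_bp"] == best[0]


def test_promoter_windows_bed_clamps_at_zero():
    proms = _one_promoter(tss=300)
    bed = promoter_windows_bed(proms)
    assert bed.loc[0, "start"] == 0 and bed.loc[0, "end"] == 1300


@given(st.integers(min_value=0, max_value=10_000), st.integers(1, 500))
def test_promoter_window_width_property(tss, width):
    txs = [make_tx("t1", "g1", [(tss, tss + 10), (tss + 20, tss + 30)])]
    bed = promoter_windows_bed(build_promoters(txs), window_bp=width)
    start, end = bed.loc[0, "start"], bed.loc[0, "end"]
    assert end - start <= 2 * width
    assert end == tss + width and start == max(0, tss - width)
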