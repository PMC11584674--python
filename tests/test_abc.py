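"""Contact maps, power-law fallback, ABC scoring and link statistics."""

import numpy as np
import pandas as pd
import pytest

from promlink.abc_model import (
    ContactMap,
    abc_scores,
    call_active_promoters,
    collapse_gene_links,
    contact,
    element_activity,
    link_sharing,
)
from promlink.annotation import build_promoters, classify_identifiability
from promlink.quant import ExpressionMatrix

from conftest import make_counts, make_meta, make_tx

RES = 5000


# ------------------------------------------------------------- ContactMap

def test_contact_map_symmetric_access():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    cmap.set(10 * RES, 3 * RES, 7.0)
    assert cmap.get_bins(3, 10) == 7.0
    assert cmap.get_bins(10, 3) == 7.0
    assert cmap.get_bins(4, 10) is None


def test_contact_map_rejects_negative():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    with pytest.raises(ValueError):
        cmap.set(0, RES, -1.0)


def test_contact_map_triplet_round_trip():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    cmap.set(0, 4 * RES, 2.0)
    cmap.set(2 * RES, 2 * RES, 5.0)
    back = ContactMap.from_triplets(cmap.to_triplets(), RES, "chr1")
    assert back._data == cmap._data


# ------------------------------------------------------------ contact law

def test_fallback_pure_power_law_on_empty_map():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    d = 20 * RES
    # empty map: scale 1, contact = (d + res) ** -gamma exactly
    assert np.isclose(contact(cmap, 0, d, gamma=1.0), 1.0 / (d + RES))
    assert np.isclose(contact(cmap, 0, d, gamma=1.5), (d + RES) ** -1.5)


def test_fallback_distance_ratio_closed_form():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    d = 40 * RES
    r = contact(cmap, 0, 2 * d, gamma=1.0) / contact(cmap, 0, d, gamma=1.0)
    assert np.isclose(r, (d + RES) / (2 * d + RES))


def test_fallback_calibrated_to_reference_distance():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    # stored contacts at the 100 kb reference distance (20 bins at 5 kb)
    cmap.set(0, 20 * RES, 3.0)
    cmap.set(40 * RES, 60 * RES, 5.0)  # mean at reference = 4.0
    d = 10 * RES
    expected = 4.0 * (100_000 + RES) * (d + RES) ** -1.0
    assert np.isclose(contact(cmap, 100 * RES, 100 * RES + d), expected)
    # at the reference distance itself the fallback equals the mean count
    assert np.isclose(contact(cmap, 200 * RES, 220 * RES), 4.0)


def test_observed_counts_returned_directly():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    cmap.set(0, 20 * RES, 1.0)
    cmap.set(5 * RES, 8 * RES, 42.0)
    assert contact(cmap, 5 * RES + 10, 8 * RES + 4999) == 42.0


def test_self_contact_dominates_everything():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    cmap.set(0, 20 * RES, 1.0)
    cmap.set(5 * RES, 8 * RES, 42.0)
    self_c = contact(cmap, 3 * RES, 3 * RES + 100)
    assert self_c >= 42.0
    probe = [contact(cmap, 0, k * RES) for k in range(1, 60)]
    assert self_c >= max(probe)


def test_cross_chromosome_contact_is_zero():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    assert contact(cmap, 0, RES, chrom="chr2") == 0.0


def test_set_invalidates_fallback_cache():
    cmap = ContactMap(resolution=RES, chrom="chr1")
    before = contact(cmap, 0, 10 * RES)
    cmap.set(0, 20 * RES, 50.0)  # calibration changes the scale
    after = contact(cmap, 0, 10 * RES)
    assert after > before


# ------------------------------------------------------- active promoters

def _promoters():
    txs = [
        make_tx("tA", "g1", [(100_000, 100_100), (101_000, 101_100),
                             (140_000, 140_500)]),
        make_tx("tB", "g1", [(112_000, 112_100), (113_000, 113_100),
                             (140_000, 140_500)]),
    ]
    return classify_identifiability(build_promoters(txs), txs)


def _expr(cpm_rows, features, meta):
    samples = list(meta.index)
    return ExpressionMatrix(
        cpm=pd.DataFrame(np.asarray(cpm_rows, dtype=float), index=features,
                         columns=samples),
        meta=meta, feature_kind="promoter_isoform",
        norm_factors=pd.Series(1.0, index=samples),
        lib_sizes=pd.Series(1e6, index=samples),
    )


def test_call_active_promoters_requires_expression_and_ocr():
    meta = make_meta([f"s{i}" for i in range(5)], regions=["R1"] * 5)
    expr = _expr(
        [
            [5, 5, 5, 5, 5],       # expressed, has OCR -> active
            [5, 5, 5, 5, 5],       # expressed, no OCR -> inactive
            [1.0, 1.0, 0, 0, 0],   # CPM == 1 is not > 1 -> inactive
        ],
        ["g1.P01", "g1.P02", "g1.P03"], meta,
    )
    assign = pd.DataFrame(
        {
            "promoter_id": ["g1.P01", "g1.P02", "g1.P03"],
            "ocr_id": ["a", pd.NA, "c"],
            "distance_bp": [0, pd.NA, 10],
        }
    )
    assert call_active_promoters(expr, assign, "R1") == {"g1.P01"}


def test_call_active_promoters_fraction_boundary():
    meta = make_meta([f"s{i}" for i in range(5)], regions=["R1"] * 5)
    expr = _expr([[5, 0, 0, 0, 0]], ["g1.P01"], meta)  # 20% of samples
    assign = pd.DataFrame(
        {"promoter_id": ["g1.P01"], "ocr_id": ["a"], "distance_bp": [0]}
    )
    # exactly 20% satisfies the >= fraction rule
    assert call_active_promoters(expr, assign, "R1") == {"g1.P01"}
    with pytest.raises(ValueError):
        call_active_promoters(expr, assign, "R9")


# -------------------------------------------------------- element activity

def test_element_activity_kinds_and_cpm():
    proms = _promoters()  # TSSs at 100_000 and 112_000
    meta = make_meta(["s1", "s2"], regions=["R1", "R2"])
    peaks = pd.DataFrame(
        [
            {"ocr_id": "prox", "chrom": "chr1", "start": 100_500, "end": 100_900},
            {"ocr_id": "dist", "chrom": "chr1", "start": 150_000, "end": 150_400},
        ]
    )
    counts = make_counts([[100, 300], [900, 700]], ["prox", "dist"],
                         ["s1", "s2"], kind="ocr", meta=meta)
    out = element_activity(peaks, counts, "R1", proms).set_index("element_id")
    assert out.loc["prox", "kind"] == "promoter_proximal"
    assert out.loc["dist", "kind"] == "distal"
    # activity = CPM in the region's single sample s1 (library 1000)
    assert np.isclose(out.loc["prox", "activity"], 100 / 1000 * 1e6)
    assert np.isclose(out.loc["dist", "activity"], 900 / 1000 * 1e6)


def test_element_activity_window_edge_is_distal():
    proms = _promoters()
    meta = make_meta(["s1"], regions=["R1"])
    peaks = pd.DataFrame(
        [{"ocr_id": "edge", "chrom": "chr1", "start": 101_000, "end": 101_400}]
    )
    counts = make_counts([[10]], ["edge"], ["s1"], kind="ocr", meta=meta)
    # peak starts exactly at tss + 1000 -> no overlap with the open window
    out = element_activity(peaks, counts, "R1", proms)
    assert out.loc[0, "kind"] == "distal"


# -------------------------------------------------------------- abc_scores

def _scene(activities, positions, loop_to=None, loop_count=100.0):
    """One active promoter at 100_000 plus elements at given positions."""
    proms = _promoters()
    cmap = ContactMap(resolution=RES, chrom="chr1")
    cmap.set(0, 20 * RES, 1.0)  # calibration: fallback = power law with scale
    if loop_to is not None:
        cmap.set(loop_to, 100_000, loop_count)
    elements = pd.DataFrame(
        [
            {"element_id": f"e{k}", "chrom": "chr1", "start": pos - 200,
             "end": pos + 200, "kind": "distal", "activity": act}
            for k, (act, pos) in enumerate(zip(activities, positions))
        ]
    )
    return proms, elements, {"chr1": cmap}


def test_abc_scores_sum_to_one_unthresholded():
    proms, elements, cmaps = _scene([5.0, 2.0, 9.0],
                                    [150_000, 400_000, 2_000_000])
    links = abc_scores({"g1.P01"}, proms, elements, cmaps, "R1", threshold=0.0)
    assert np.isclose(links["abc"].sum(), 1.0, atol=1e-12)


def test_abc_scores_monotone_in_activity():
    proms, elements, cmaps = _scene([5.0, 5.0], [150_000, 150_800])
    links = abc_scores({"g1.P01"}, proms, elements, cmaps, "R1", threshold=0.0)
    base = links.set_index("element_id")["abc"]
    elements2 = elements.copy()
    elements2.loc[elements2["element_id"] == "e0", "activity"] = 10.0
    links2 = abc_scores({"g1.P01"}, proms, elements2, cmaps, "R1", threshold=0.0)
    boosted = links2.set_index("element_id")["abc"]
    assert boosted["e0"] > base["e0"]
    assert boosted["e1"] < base["e1"]


def test_abc_scores_loop_beats_distance():
    # a looped far element outranks a near element of equal activity
    proms, elements, cmaps = _scene(
        [5.0, 5.0], [150_000, 130_000], loop_to=150_000, loop_count=50.0
    )
    links = abc_scores({"g1.P01"}, proms, elements, cmaps, "R1",
                       threshold=0.0).set_index("element_id")
    assert links.loc["e0", "abc"] > links.loc["e1", "abc"]


def test_abc_scores_threshold_and_window():
    proms, elements, cmaps = _scene([5.0, 5.0], [150_000, 6_000_000])
    links = abc_scores({"g1.P01"}, proms, elements, cmaps, "R1")
    # the 6 Mb element is outside the 5 Mb window entirely
    assert set(links["element_id"]) == {"e0"}
    assert (links["abc"] >= 0.02).all()


def test_abc_scores_inactive_promoter_ignored():
    proms, elements, cmaps = _scene([5.0], [150_000])
    links = abc_scores(set(), proms, elements, cmaps, "R1", threshold=0.0)
    assert links.empty


def test_abc_scores_distance_and_metadata():
    proms, elements, cmaps = _scene([5.0], [150_000])
    links = abc_scores({"g1.P01"}, proms, elements, cmaps, "R1", threshold=0.0)
    row = links.iloc[0]
    assert row["gene_id"] == "g1" and row["region"] == "R1"
    assert row["distance_bp"] == abs(150_000 - 100_000)
    assert row["tss"] == 100_000


# ------------------------------------------------------------ aggregation

def test_collapse_gene_links_keeps_max_per_gene():
    links = pd.DataFrame(
        [
            {"region": "R1", "element_id": "e1", "gene_id": "g1",
             "promoter_id": "g1.P01", "abc": 0.1},
            {"region": "R1", "element_id": "e1", "gene_id": "g1",
             "promoter_id": "g1.P02", "abc": 0.4},
            {"region": "R1", "element_id": "e1", "gene_id": "g2",
             "promoter_id": "g2.P01", "abc": 0.2},
        ]
    )
    out = collapse_gene_links(links)
    assert len(out) == 2
    assert set(out["promoter_id"]) == {"g1.P02", "g2.P01"}


def _links_frame(region, rows):
    return pd.DataFrame(
        [{"region": region, "element_id": e, "promoter_id": p, "abc": a}
         for e, p, a in rows]
    )


def test_link_sharing_counts_and_unique_fraction():
    by_region = {
        "R1": _links_frame("R1", [("e1", "p1", 0.1), ("e2", "p1", 0.2),
                                  ("e3", "p2", 0.3)]),
        "R2": _links_frame("R2", [("e1", "p1", 0.15), ("e2", "p1", 0.1),
                                  ("e4", "p3", 0.5)]),
    }
    out = link_sharing(by_region)
    assert out["shared"].loc["R1", "R2"] == 2
    assert np.isclose(out["unique_fraction"]["R1"], 1 / 3)
    assert np.isclose(out["unique_fraction"]["R2"], 1 / 3)


def test_link_sharing_spearman_needs_three_common():
    by_region = {
        "R1": _links_frame("R1", [("e1", "p1", 0.1), ("e2", "p1", 0.2)]),
        "R2": _links_frame("R2", [("e1", "p1", 0.3), ("e2", "p1", 0.4)]),
    }
    out = link_sharing(by_region)
    assert np.isnan(out["correlation"].loc["R1", "R2"])
    by_region["R1"] = _links_frame(
        "R1", [("e1", "p1", 0.1), ("e2", "p1", 0.2), ("e3", "p1", 0.3)]
    )
    by_region["R2"] = _links_frame(
        "R2", [("e1", "p1", 0.2), ("e2", "p1", 0.3), ("e3", "p1", 0.5)]
    )
    out = link_sharing(by_region)
    assert np.isclose(out["correlation"].loc["R1", "R2"], 1.0)
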