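"""Activity-by-contact enhancer-promoter links at promoter-isoform resolution.

For each brain region, the ABC score of a candidate element e for a
promoter p is

    ABC(e, p) = activity(e) * contact(e, p) / sum over all candidate
                elements within the screening window of p

where activity is the element's mean chromatin accessibility (ATAC CPM)
in the region and contact comes from a Hi-C map, with a power-law
distance-decay fallback for bin pairs the map does not cover.  Links
with ABC >= 0.02 inside a 5 Mb window around the TSS are reported.
Promoters are *active* (eligible for links) when they are both
expressed (CPM > 1 in at least 20% of the region's samples) and have an
open-chromatin peak within 1 kb of the TSS; internal promoters are
included at this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import PROMOTER_WINDOW_BP, PromoterIsoform
from .quant import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

ABC_THRESHOLD = 0.02
ABC_WINDOW_BP = 5_000_000
REFERENCE_DISTANCE_BP = 100_000


@dataclass
class ContactMap:
    """Sparse symmetric Hi-C contact map for one chromosome.

    Entries are keyed by bin index pairs (``start // resolution``) with
    the smaller index first; the accessor is symmetric.  Queries for bin
    pairs absent from the map fall back to a power-law distance decay
    (see :func:`contact`).
    """

    resolution: int
    chrom: str
    _data: dict[tuple[int, int], float] = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_triplets(cls, df: pd.DataFrame, resolution: int, chrom: str) -> "ContactMap":
        """Build from (bin_a_start, bin_b_start, count) rows."""
        cmap = cls(resolution=resolution, chrom=chrom)
        for a, b, c in zip(df["bin_a_start"], df["bin_b_start"], df["count"]):
            cmap.set(int(a), int(b), float(c))
        return cmap

    def set(self, bin_a_start: int, bin_b_start: int, count: float) -> None:
        if count < 0:
            raise ValueError("negative contact count")
        i, j = sorted((bin_a_start // self.resolution, bin_b_start // self.resolution))
        self._data[(i, j)] = count
        self._cache.clear()

    def get_bins(self, i: int, j: int) -> float | None:
        key = (i, j) if i <= j else (j, i)
        return self._data.get(key)

    @property
    def n_entries(self) -> int:
        return len(self._data)

    def max_count(self) -> float:
        if "max" not in self._cache:
            self._cache["max"] = max(self._data.values(), default=0.0)
        return self._cache["max"]

    def mean_at_distance(self, distance_bp: int, rel_tol: float = 0.2) -> float | None:
        """Mean stored count among bin pairs near the given separation."""
        target = distance_bp / self.resolution
        vals = [
            c for (i, j), c in self._data.items()
            if abs(abs(j - i) - target) <= rel_tol * target
        ]
        return float(np.mean(vals)) if vals else None

    def to_triplets(self) -> pd.DataFrame:
        rows = [
            (i * self.resolution, j * self.resolution, c)
            for (i, j), c in sorted(self._data.items())
        ]
        return pd.DataFrame(rows, columns=["bin_a_start", "bin_b_start", "count"])


def _fallback_scale(cmap: ContactMap, gamma: float) -> float:
    """Scale the power-law fallback to the map's contact level.

    Chosen so the fallback at the 100 kb reference distance equals the
    map's mean contact at that distance; 1.0 for an empty map (pure
    power law).
    """
    key = ("scale", gamma)
    if key not in cmap._cache:
        ref = cmap.mean_at_distance(REFERENCE_DISTANCE_BP)
        if ref is None or ref <= 0:
            cmap._cache[key] = 1.0
        else:
            cmap._cache[key] = ref * (REFERENCE_DISTANCE_BP + cmap.resolution) ** gamma
    return cmap._cache[key]


def contact(
    cmap: ContactMap,
    pos_a: int,
    pos_b: int,
    gamma: float = 1.0,
    chrom: str | None = None,
) -> float:
    """Contact frequency between two positions on the map's chromosome.

    Observed bin-pair counts are returned directly; absent or zero
    pairs fall back to ``(|delta| + resolution) ** -gamma`` scaled to
    the map's mean contact at the 100 kb reference distance.  Same-bin
    queries return the self-contact convention value, which dominates
    every other contact the map can return.  Cross-chromosome queries
    return 0 with a warning (trans contacts unsupported).
    """
    if chrom is not None and chrom != cmap.chrom:
        logger.warning("cross-chromosome contact query (%s vs %s) -> 0", chrom, cmap.chrom)
        return 0.0
    res = cmap.resolution
    scale = _fallback_scale(cmap, gamma)
    i, j = pos_a // res, pos_b // res
    if i == j:
        return max(cmap.max_count(), scale * res ** -gamma)
    obs = cmap.get_bins(i, j)
    if obs is not None and obs > 0:
        return float(obs)
    d = abs(i - j) * res
    return scale * (d + res) ** -gamma


def call_active_promoters(
    expr: ExpressionMatrix,
    ocr_assignments: pd.DataFrame,
    region: str,
    min_cpm: float = 1.0,
    min_fraction: float = 0.20,
) -> set[str]:
    """Promoters eligible for enhancer-promoter links in one region.

    Active iff CPM > ``min_cpm`` in at least ``min_fraction`` of the
    region's samples AND the promoter has an assigned OCR within 1 kb
    of its TSS.  ``expr`` should include internal promoters.
    """
    samples = expr.meta.index[expr.meta["region"] == region]
    if len(samples) == 0:
        raise ValueError(f"no samples for region {region}")
    cpm = expr.cpm.loc[:, samples]
    expressed = (cpm > min_cpm).mean(axis=1) >= min_fraction
    with_ocr = set(ocr_assignments.loc[ocr_assignments["ocr_id"].notna(), "promoter_id"])
    return {pid for pid in expr.feature_ids[expressed] if pid in with_ocr}


def element_activity(
    peaks: pd.DataFrame,
    peak_counts: CountMatrix,
    region: str,
    promoters: list[PromoterIsoform],
    window_bp: int = PROMOTER_WINDOW_BP,
) -> pd.DataFrame:
    """Candidate elements with per-region activity.

    Activity is the mean depth-normalized accessibility (CPM) of the
    peak across the region's samples.  Elements overlapping any
    promoter window (TSS +/- 1 kb) are flagged ``promoter_proximal``,
    the rest ``distal``.

    Returns columns ``element_id, chrom, start, end, kind, activity``.
    """
    samples = peak_counts.meta.index[peak_counts.meta["region"] == region]
    mat = peak_counts.counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    cpm = pd.DataFrame(
        mat / lib * 1e6, index=peak_counts.feature_ids, columns=peak_counts.sample_ids
    )
    activity = cpm.loc[:, samples].mean(axis=1)

    proms_by_chrom: dict[str, list[int]] = {}
    for p in promoters:
        proms_by_chrom.setdefault(p.chrom, []).append(p.tss)
    rows = []
    for _, pk in peaks.iterrows():
        tss_list = proms_by_chrom.get(pk["chrom"], [])
        proximal = any(
            pk["start"] < t + window_bp and pk["end"] > t - window_bp for t in tss_list
        )
        rows.append(
            {
                "element_id": pk["ocr_id"],
                "chrom": pk["chrom"],
                "start": int(pk["start"]),
                "end": int(pk["end"]),
                "kind": "promoter_proximal" if proximal else "distal",
                "activity": float(activity.get(pk["ocr_id"], 0.0)),
            }
        )
    return pd.DataFrame(rows, columns=["element_id", "chrom", "start", "end", "kind", "activity"])


def abc_scores(
    active_promoters: set[str],
    promoters: list[PromoterIsoform],
    elements: pd.DataFrame,
    cmaps: dict[str, ContactMap],
    region: str,
    window_bp: int = ABC_WINDOW_BP,
    threshold: float = ABC_THRESHOLD,
    gamma: float = 1.0,
) -> pd.DataFrame:
    """ABC links for one region.

    For each active promoter, candidates are all elements within
    ``window_bp`` of its TSS on the same chromosome; the raw score is
    activity x contact(element midpoint, TSS) and ABC scores are raw
    scores normalized to sum 1 over all candidates (promoter-proximal
    elements included in the denominator).  Links at or above
    ``threshold`` are emitted, both distal and promoter-proximal,
    flagged by ``kind``.
    """
    prom_map = {p.promoter_id: p for p in promoters}
    el_by_chrom = {c: g.reset_index(drop=True) for c, g in elements.groupby("chrom")}
    rows = []
    n_zero = 0
    for pid in sorted(active_promoters):
        p = prom_map.get(pid)
        if p is None:
            continue
        cmap = cmaps.get(p.chrom)
        if cmap is None:
            logger.warning("no contact map for chromosome %s; promoter %s skipped", p.chrom, pid)
            continue
        els = el_by_chrom.get(p.chrom)
        if els is None:
            continue
        cand = els[(els["start"] < p.tss + window_bp) & (els["end"] > p.tss - window_bp)]
        if cand.empty:
            continue
        mids = ((cand["start"] + cand["end"]) // 2).to_numpy()
        contacts = np.array([contact(cmap, int(m), p.tss, gamma=gamma) for m in mids])
        raw = cand["activity"].to_numpy() * contacts
        total = raw.sum()
        if total <= 0:
            n_zero += 1
            continue
        abc = raw / total
        for k in range(len(cand)):
            if abc[k] >= threshold:
                row = cand.iloc[k]
                rows.append(
                    {
                        "region": region,
                        "element_id": row["element_id"],
                        "promoter_id": pid,
                        "gene_id": p.gene_id,
                        "chrom": p.chrom,
                        "e_start": int(row["start"]),
                        "e_end": int(row["end"]),
                        "tss": p.tss,
                        "activity": float(row["activity"]),
                        "contact": float(contacts[k]),
                        "abc": float(abc[k]),
                        "distance_bp": int(abs(int(mids[k]) - p.tss)),
                        "kind": row["kind"],
                    }
                )
    if n_zero:
        logger.info("%d promoters had zero total raw score", n_zero)
    return pd.DataFrame(
        rows,
        columns=[
            "region", "element_id", "promoter_id", "gene_id", "chrom",
            "e_start", "e_end", "tss", "activity", "contact", "abc",
            "distance_bp", "kind",
        ],
    )


def collapse_gene_links(links: pd.DataFrame) -> pd.DataFrame:
    """Gene-level links: per (element, gene, region), the max ABC promoter link."""
    if links.empty:
        return links.copy()
    idx = links.groupby(["region", "element_id", "gene_id"])["abc"].idxmax()
    return links.loc[idx].reset_index(drop=True)


def link_sharing(links_by_region: dict[str, pd.DataFrame]) -> dict:
    """Cross-region link statistics.

    Link identity is (element_id, promoter_id) on a shared element
    universe.  Returns pairwise shared counts, per-region unique link
    fractions, and a Spearman correlation matrix of ABC scores over
    links present in both regions of each pair (complete values only).
    """
    regions = sorted(links_by_region)
    keysets = {
        r: dict(zip(zip(df["element_id"], df["promoter_id"]), df["abc"]))
        for r, df in links_by_region.items()
    }
    shared = pd.DataFrame(0, index=regions, columns=regions, dtype=int)
    corr = pd.DataFrame(np.nan, index=regions, columns=regions)
    for r in regions:
        shared.loc[r, r] = len(keysets[r])
        corr.loc[r, r] = 1.0 if keysets[r] else np.nan
    for i, r in enumerate(regions):
        for q in regions[i + 1:]:
            common = sorted(set(keysets[r]) & set(keysets[q]))
            shared.loc[r, q] = shared.loc[q, r] = len(common)
            if len(common) >= 3:
                x = [keysets[r][k] for k in common]
                yv = [keysets[q][k] for k in common]
                rho = stats.spearmanr(x, yv).statistic
                corr.loc[r, q] = corr.loc[q, r] = rho
    unique_frac = {}
    for r in regions:
        others = set().union(*(keysets[q].keys() for q in regions if q != r)) if len(regions) > 1 else set()
        n = len(keysets[r])
        unique_frac[r] = (
            sum(1 for k in keysets[r] if k not in others) / n if n else np.nan
        )
    return {"shared": shared, "unique_fraction": pd.Series(unique_frac), "correlation": corr}
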