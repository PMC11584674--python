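"""Generic statistical validation operators.

One-tailed Fisher enrichment, one-tailed Wilcoxon comparisons (exact
for small samples), tie-aware Spearman correlation, basepair Jaccard
overlap of interval sets, and validation of enhancer-promoter links
against external reference sets (cis-eQTLs with LD proxies, or
correlated-enhancer catalogs) using flanked element intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25
FLANK_BP = 500
R2_MIN = 0.8


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: (in-set & in-annotation, in-set & not, not & in, not & not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")


def fisher_one_tailed(table: ContingencyTable2x2) -> tuple[float, float]:
    """Upper-tail Fisher's exact test for enrichment.

    Returns (odds ratio, p).  The odds ratio is the sample OR
    a*d / (b*c), infinite when b*c = 0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    return odds, p


def wilcoxon_one_tailed(
    x, y, paired: bool, zero_method: str = "wilcox"
) -> tuple[float, float]:
    """One-tailed rank test with alternative "x greater".

    Paired: Wilcoxon signed-rank, exact null for n <= 25 (after zero
    removal) else normal approximation with continuity and tie
    correction; all-zero differences are degenerate (p = 1).
    ``zero_method='pratt'`` keeps zero differences in the ranking.
    Unpaired: Wilcoxon rank-sum (Mann-Whitney), same exact/approximate
    policy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired mode requires equal lengths")
        diffs = x - y
        nz = int(np.count_nonzero(diffs))
        if nz == 0:
            logger.warning("all paired differences are zero; degenerate test")
            return 0.0, 1.0
        has_ties = len(np.unique(np.abs(diffs[diffs != 0]))) < nz
        method = "exact" if (nz <= EXACT_WILCOXON_MAX_N and not has_ties) else "approx"
        res = stats.wilcoxon(
            x, y, alternative="greater", zero_method=zero_method,
            correction=(method == "approx"), method=method,
        )
        return float(res.statistic), float(res.pvalue)
    n, m = len(x), len(y)
    method = "exact" if max(n, m) <= EXACT_WILCOXON_MAX_N else "asymptotic"
    if method == "exact" and (len(np.unique(np.concatenate([x, y]))) < n + m):
        method = "asymptotic"  # scipy's exact branch does not handle ties
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> float:
    """Tie-aware Spearman correlation (Pearson on mid-ranks).

    Pairwise-complete: rows with a NaN in either vector are dropped;
    needs >= 3 complete pairs and non-constant vectors, else NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spearman undefined (constant or too-short input)")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def jaccard(intervals_a, intervals_b) -> float:
    """Basepair Jaccard index between two interval sets (one chromosome).

    Intervals are merged first; empty union returns 0 by convention.
    """
    a = _merge_intervals(intervals_a)
    b = _merge_intervals(intervals_b)
    total_a = sum(e - s for s, e in a)
    total_b = sum(e - s for s, e in b)
    inter = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            inter += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    union = total_a + total_b - inter
    if union == 0:
        logger.warning("jaccard of empty interval sets; 0 by convention")
        return 0.0
    return inter / union


def expand_ld_proxies(
    reference: pd.DataFrame,
    ld_proxies: pd.DataFrame | None,
    r2_min: float = R2_MIN,
) -> pd.DataFrame:
    """Add LD-proxy positions to a reference variant table.

    ``reference`` rows: ``chrom, start, end, gene_id`` (SNPs as 1 bp
    intervals) plus optional ``variant_id``.  ``ld_proxies`` rows:
    ``lead_id, proxy_id, chrom, pos, r2`` — proxies with r2 > ``r2_min``
    inherit the lead variant's target gene.
    """
    if ld_proxies is None or ld_proxies.empty:
        return reference
    if "variant_id" not in reference.columns:
        raise ValueError("reference needs variant_id to expand LD proxies")
    lead_gene = reference.set_index("variant_id")["gene_id"].to_dict()
    extra = []
    for _, row in ld_proxies.iterrows():
        if row["r2"] > r2_min and row["lead_id"] in lead_gene:
            pos0 = int(row["pos"]) - 1
            extra.append(
                {
                    "chrom": row["chrom"],
                    "start": pos0,
                    "end": pos0 + 1,
                    "gene_id": lead_gene[row["lead_id"]],
                    "variant_id": row["proxy_id"],
                }
            )
    return pd.concat([reference, pd.DataFrame(extra)], ignore_index=True)


def validate_links(
    links: pd.DataFrame,
    reference: pd.DataFrame,
    promoter_ranks: dict[str, int],
    flank_bp: int = FLANK_BP,
    ld_proxies: pd.DataFrame | None = None,
    r2_min: float = R2_MIN,
) -> pd.DataFrame:
    """Validated proportion of links per region, 5' and non-5' separately.

    A link's element, flanked by ``flank_bp`` on both sides, enters the
    denominator when it intersects any reference position or interval,
    and the numerator when an intersected reference row targets the
    link's gene.  For each (region, promoter type) stratum a one-tailed
    Fisher's exact test asks whether that region's validated proportion
    exceeds the pooled other regions'.
    """
    if reference.empty:
        raise ValueError("empty reference set")
    ref = expand_ld_proxies(reference, ld_proxies, r2_min)
    ref_by_chrom = {c: g.reset_index(drop=True) for c, g in ref.groupby("chrom")}

    recs = []
    for _, ln in links.iterrows():
        grp = ref_by_chrom.get(ln["chrom"])
        if grp is None:
            continue
        s, e = ln["e_start"] - flank_bp, ln["e_end"] + flank_bp
        hit = grp[(grp["start"] < e) & (grp["end"] > s)]
        if hit.empty:
            continue
        ptype = "five_prime" if promoter_ranks.get(ln["promoter_id"]) == 1 else "non_five_prime"
        recs.append(
            {
                "region": ln["region"],
                "promoter_type": ptype,
                "validated": bool((hit["gene_id"] == ln["gene_id"]).any()),
            }
        )
    hits = pd.DataFrame(recs, columns=["region", "promoter_type", "validated"])
    rows = []
    for (region, ptype), grp in hits.groupby(["region", "promoter_type"], sort=True):
        others = hits[(hits["region"] != region) & (hits["promoter_type"] == ptype)]
        a = int(grp["validated"].sum())
        b = len(grp) - a
        c = int(others["validated"].sum())
        d = len(others) - c
        if a + b + c + d > 0:
            odds, p = fisher_one_tailed(ContingencyTable2x2(a, b, c, d))
        else:
            odds, p = np.nan, np.nan
        rows.append(
            {
                "region": region,
                "promoter_type": ptype,
                "n_intersected": len(grp),
                "n_validated": a,
                "proportion": a / len(grp) if len(grp) else np.nan,
                "fisher_or": odds,
                "fisher_p": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "promoter_type", "n_intersected", "n_validated",
            "proportion", "fisher_or", "fisher_p",
        ],
    )
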