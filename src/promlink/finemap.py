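"""ABC-Max assignment of fine-mapped GWAS variants to promoter-isoforms.

Fine-mapped variants (posterior inclusion probability, PIP > 1%) that
fall inside an ABC enhancer are assigned to the promoter-isoform (and
hence gene) with the maximal ABC score among the links whose element
contains the variant — the ABC-Max strategy.  The assigned promoter is
classified as 5' (rank 1) or non-5'; per-gene aggregation across
regions yields a 5' / non-5' / both class.  The naive closest-gene
baseline and 10 kb lead-SNP windows are also provided, plus summary
tables comparing externally supplied per-gene priority scores between
non-5' targets, 5' targets, and closest genes.

SNP positions are 1-based on input (VCF convention) and converted to
0-based internally; element intervals are half-open.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation import PromoterIsoform
from .validation import wilcoxon_one_tailed

logger = logging.getLogger(__name__)

PIP_MIN = 0.01
LEAD_FLANK_BP = 10_000


def overlap_snps(
    snps: pd.DataFrame,
    links: pd.DataFrame,
    pip_min: float = PIP_MIN,
    include_promoter_proximal: bool = False,
) -> pd.DataFrame:
    """Pair fine-mapped SNPs with ABC links whose element contains them.

    ``snps`` columns: ``rsid, chrom, pos`` (1-based), ``pip``.  Only
    SNPs with pip > ``pip_min`` are considered, and promoter-proximal
    elements are excluded by default (enhancer fine-mapping).  Rows
    with malformed positions are rejected and reported.
    """
    snps = snps.copy()
    bad = ~np.isfinite(snps["pos"]) | (snps["pos"] < 1)
    if bad.any():
        logger.warning("%d SNP rows with malformed positions rejected", int(bad.sum()))
        snps = snps[~bad]
    snps = snps[snps["pip"] > pip_min]
    use = links if include_promoter_proximal else links[links["kind"] == "distal"]
    rows = []
    for _, s in snps.iterrows():
        pos0 = int(s["pos"]) - 1
        hit = use[
            (use["chrom"] == s["chrom"]) & (use["e_start"] <= pos0) & (pos0 < use["e_end"])
        ]
        for _, ln in hit.iterrows():
            rows.append({"rsid": s["rsid"], "pip": float(s["pip"]), "pos0": pos0, **ln.to_dict()})
    cols = ["rsid", "pip", "pos0"] + list(links.columns)
    return pd.DataFrame(rows, columns=cols)


def abc_max(
    pairs: pd.DataFrame,
    promoters: list[PromoterIsoform],
    per_region: bool = True,
) -> pd.DataFrame:
    """Keep, per SNP (and region), the link with the maximal ABC score.

    Ties are broken toward the smaller TSS distance, then lexicographic
    promoter id.  With ``per_region=False`` a single global maximum per
    SNP is taken across regions.  The output adds ``promoter_type``
    (``five_prime`` / ``non_five_prime`` from promoter rank) and
    ``gene_promoter_class`` (``5'`` / ``non-5'`` / ``both``) aggregated
    per gene over all retained assignments.
    """
    if pairs.empty:
        out = pairs.copy()
        out["promoter_type"] = pd.Series(dtype=str)
        out["gene_promoter_class"] = pd.Series(dtype=str)
        return out
    rank = {p.promoter_id: p.rank for p in promoters}
    df = pairs.copy()
    df["_snp_dist"] = (df["pos0"] - df["tss"]).abs()
    group_cols = ["rsid", "region"] if per_region else ["rsid"]
    df = df.sort_values(
        by=group_cols + ["abc", "_snp_dist", "promoter_id"],
        ascending=[True] * len(group_cols) + [False, True, True],
        kind="mergesort",
    )
    best = df.groupby(group_cols, sort=True).head(1).drop(columns="_snp_dist")
    best = best.reset_index(drop=True)
    best["promoter_type"] = [
        "five_prime" if rank.get(pid) == 1 else "non_five_prime"
        for pid in best["promoter_id"]
    ]
    cls = {}
    for gene_id, grp in best.groupby("gene_id"):
        kinds = set(grp["promoter_type"])
        cls[gene_id] = (
            "both" if len(kinds) == 2 else ("5'" if "five_prime" in kinds else "non-5'")
        )
    best["gene_promoter_class"] = best["gene_id"].map(cls)
    return best


def closest_gene(snps: pd.DataFrame, promoters: list[PromoterIsoform]) -> pd.DataFrame:
    """Nearest-TSS gene(s) per SNP.

    Returns one row per (rsid, gene_id) — ties produce multiple rows in
    sorted gene order — with the TSS distance in bp.
    """
    if not promoters:
        raise ValueError("empty promoter annotation")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append((p.tss, p.gene_id))
    rows = []
    for _, s in snps.iterrows():
        pos0 = int(s["pos"]) - 1
        cands = by_chrom.get(s["chrom"], [])
        if not cands:
            continue
        dists: dict[str, int] = {}
        for tss, gene_id in cands:
            d = abs(tss - pos0)
            if gene_id not in dists or d < dists[gene_id]:
                dists[gene_id] = d
        dmin = min(dists.values())
        for gene_id in sorted(g for g, d in dists.items() if d == dmin):
            rows.append({"rsid": s["rsid"], "gene_id": gene_id, "distance_bp": dmin})
    return pd.DataFrame(rows, columns=["rsid", "gene_id", "distance_bp"])


def lead_snp_windows(hits: pd.DataFrame, flank_bp: int = LEAD_FLANK_BP) -> pd.DataFrame:
    """Merge +/- ``flank_bp`` windows around hits; report each window's lead.

    The lead SNP is the row with the lowest p-value in the merged
    window (ties toward the smaller position).

    ``hits`` columns: ``chrom, pos, p``.  Returns one row per merged
    window: ``chrom, start, end, lead_pos, lead_p``.
    """
    out = []
    for chrom, grp in hits.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos", "p"]).reset_index(drop=True)
        cur = None  # [start, end, lead_pos, lead_p]
        for _, row in grp.iterrows():
            start, end = int(row["pos"]) - flank_bp, int(row["pos"]) + flank_bp
            if cur is not None and start <= cur[1]:
                cur[1] = max(cur[1], end)
                if (row["p"], row["pos"]) < (cur[3], cur[2]):
                    cur[2], cur[3] = int(row["pos"]), float(row["p"])
            else:
                if cur is not None:
                    out.append([chrom] + cur)
                cur = [start, end, int(row["pos"]), float(row["p"])]
        if cur is not None:
            out.append([chrom] + cur)
    return pd.DataFrame(out, columns=["chrom", "start", "end", "lead_pos", "lead_p"])


def summarize_targets(
    assignments: pd.DataFrame,
    closest: pd.DataFrame,
    priority_scores: pd.DataFrame | None = None,
    paired: bool | None = None,
) -> dict:
    """Per-region target summaries and priority-score comparisons.

    Per region: the fraction of target genes reached only via non-5'
    links, the fraction whose gene is not the SNP's closest gene, and
    the fraction of genes unique to that region.  If ``priority_scores``
    (columns ``gene_id, score``) is given, one-tailed rank tests
    (alternative: non-5' targets greater) compare non-5' target scores
    against 5' target scores and against closest-gene scores;
    ``paired`` must then be passed explicitly because the compared gene
    sets generally differ in size (unpaired is the natural choice).
    """
    if assignments.empty:
        return {"per_region": pd.DataFrame(), "score_tests": {}}
    closest_by_snp = closest.groupby("rsid")["gene_id"].apply(set).to_dict()
    assignments = assignments.copy()
    assignments["is_closest_gene"] = [
        g in closest_by_snp.get(r, set())
        for r, g in zip(assignments["rsid"], assignments["gene_id"])
    ]
    genes_by_region = {
        r: set(g["gene_id"]) for r, g in assignments.groupby("region")
    }
    rows = []
    for region, grp in assignments.groupby("region", sort=True):
        genes = genes_by_region[region]
        non5_only = {
            g for g in genes
            if set(grp.loc[grp["gene_id"] == g, "promoter_type"]) == {"non_five_prime"}
        }
        not_closest = {
            g for g in genes
            if not grp.loc[grp["gene_id"] == g, "is_closest_gene"].any()
        }
        others = set().union(
            *(genes_by_region[q] for q in genes_by_region if q != region)
        ) if len(genes_by_region) > 1 else set()
        unique = {g for g in genes if g not in others}
        n = len(genes)
        rows.append(
            {
                "region": region,
                "n_genes": n,
                "frac_non5_only": len(non5_only) / n if n else np.nan,
                "frac_not_closest": len(not_closest) / n if n else np.nan,
                "frac_region_unique": len(unique) / n if n else np.nan,
            }
        )
    per_region = pd.DataFrame(rows)

    score_tests: dict = {}
    if priority_scores is not None and not priority_scores.empty:
        if paired is None:
            raise ValueError("score comparisons require an explicit paired= argument")
        scores = priority_scores.set_index("gene_id")["score"]
        pct = scores.rank(pct=True)
        def _scores(genes: set[str]) -> np.ndarray:
            return pct.loc[sorted(g for g in genes if g in pct.index)].to_numpy()
        non5 = _scores(
            set(assignments.loc[assignments["promoter_type"] == "non_five_prime", "gene_id"])
        )
        five = _scores(
            set(assignments.loc[assignments["promoter_type"] == "five_prime", "gene_id"])
        )
        closest_genes = _scores(set().union(*closest_by_snp.values()) if closest_by_snp else set())
        for label, other in (("non5_vs_5prime", five), ("non5_vs_closest", closest_genes)):
            if len(non5) >= 1 and len(other) >= 1:
                score_tests[label] = wilcoxon_one_tailed(non5, other, paired=paired)
    return {"per_region": per_region, "score_tests": score_tests, "assignments": assignments}
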