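"""End-to-end orchestration of the promoter-isoform analysis.

Chains the stages on an in-memory input bundle: promoter quantification
and normalization, pairwise differential statistics with global FDR,
broad-region specificity and isoform-specific DEG calls, per-region ABC
enhancer-promoter links, cross-region link statistics, and ABC-Max
fine-mapping of the supplied SNPs.  File-based runs (CLI) read standard
formats into the same bundle structure first.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import abc_model, annotation, diffstats, finemap, quant
from .annotation import CLASS_INTERNAL, CLASS_UNIQUE
from .synthdata import SimBundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Stage parameters; defaults are the analysis constants."""

    fdr_cut: float = 0.05
    gene_null_p: float = 0.1
    abc_threshold: float = abc_model.ABC_THRESHOLD
    abc_window_bp: int = abc_model.ABC_WINDOW_BP
    gamma: float = 1.0
    pip_min: float = finemap.PIP_MIN
    promoter_window_bp: int = annotation.PROMOTER_WINDOW_BP
    group_col: str = "broad_region"
    compute_pi1: bool = True
    include_ocr_de: bool = True


def pi1_matrix_from_de(de: pd.DataFrame) -> pd.DataFrame:
    """Assemble a pi1 dissimilarity matrix from an all-pairs DE table."""
    regions = sorted(set(de["group_a"]) | set(de["group_b"]))
    mat = pd.DataFrame(0.0, index=regions, columns=regions)
    for a, b in itertools.combinations(regions, 2):
        sub = de[(de["group_a"] == a) & (de["group_b"] == b)
                 | (de["group_a"] == b) & (de["group_b"] == a)]
        if sub.empty:
            continue
        pi1 = diffstats.storey_pi1(sub["p"].to_numpy())
        mat.loc[a, b] = mat.loc[b, a] = pi1
    return mat


def run_bundle(bundle: SimBundle, params: PipelineParams | None = None) -> dict:
    """Run every analysis stage on a bundle; returns an output dict."""
    par = params or PipelineParams()
    promoters = bundle.promoters
    prom_to_gene = {p.promoter_id: p.gene_id for p in promoters}
    regions = sorted(bundle.meta["region"].astype(str).unique())

    # --- promoter-isoform quantification (unique promoters only) ----
    qres = quant.quantify_promoters(bundle.junction_counts, promoters)
    iso_expr = quant.tmm_normalize(qres.counts)
    iso_expr_f = quant.filter_detected(iso_expr, *quant.PROMOTER_FILTER[:2],
                                       strict_gt_fraction=quant.PROMOTER_FILTER[2])
    gene_expr = quant.tmm_normalize(bundle.gene_counts)
    gene_expr_f = quant.filter_detected(gene_expr, *quant.GENE_FILTER[:2])

    # --- differential statistics ------------------------------------
    iso_de = diffstats.all_pairwise_de(iso_expr_f, group_col=par.group_col)
    gene_de = diffstats.all_pairwise_de(gene_expr_f, group_col=par.group_col)
    iso_specific = diffstats.isoform_specific_degs(
        iso_de, gene_de, prom_to_gene, fdr_cut=par.fdr_cut, gene_null_p=par.gene_null_p
    )
    specific_genes = diffstats.broad_region_specific(gene_de, fdr_cut=par.fdr_cut)
    specific_promoters = diffstats.broad_region_specific(iso_de, fdr_cut=par.fdr_cut)
    ocr_de = None
    specific_ocrs = None
    if par.include_ocr_de:
        ocr_expr = quant.tmm_normalize(bundle.peak_counts)
        ocr_expr_f = quant.filter_detected(ocr_expr, *quant.OCR_FILTER[:2])
        ocr_de = diffstats.all_pairwise_de(ocr_expr_f, group_col=par.group_col)
        specific_ocrs = diffstats.broad_region_specific(ocr_de, fdr_cut=par.fdr_cut)
    pi1 = pi1_matrix_from_de(gene_de) if par.compute_pi1 else None

    major = quant.call_major_promoters(iso_expr_f, promoters)

    # --- ABC links per region (internal promoters included) ---------
    ocr_assign = annotation.assign_promoter_ocrs(
        promoters, bundle.peaks, window_bp=par.promoter_window_bp
    )
    qres_abc = quant.quantify_promoters(
        bundle.junction_counts, promoters, classes=(CLASS_UNIQUE, CLASS_INTERNAL)
    )
    abc_expr = quant.tmm_normalize(qres_abc.counts)
    links_by_region: dict[str, pd.DataFrame] = {}
    for region in regions:
        active = abc_model.call_active_promoters(abc_expr, ocr_assign, region)
        elements = abc_model.element_activity(
            bundle.peaks, bundle.peak_counts, region, promoters,
            window_bp=par.promoter_window_bp,
        )
        links_by_region[region] = abc_model.abc_scores(
            active, promoters, elements, bundle.contact_maps[region], region,
            window_bp=par.abc_window_bp, threshold=par.abc_threshold, gamma=par.gamma,
        )
    all_links = pd.concat(links_by_region.values(), ignore_index=True) \
        if links_by_region else pd.DataFrame()
    sharing = abc_model.link_sharing(links_by_region) if len(regions) >= 2 else None

    # --- fine-mapping ------------------------------------------------
    pairs = finemap.overlap_snps(bundle.snps, all_links, pip_min=par.pip_min)
    assignments = finemap.abc_max(pairs, promoters, per_region=True)
    closest = finemap.closest_gene(bundle.snps, promoters)
    summaries = finemap.summarize_targets(
        assignments, closest, priority_scores=bundle.gene_scores, paired=False
    )

    return {
        "promoters": promoters,
        "iso_expr": iso_expr_f,
        "gene_expr": gene_expr_f,
        "iso_de": iso_de,
        "gene_de": gene_de,
        "ocr_de": ocr_de,
        "iso_specific": iso_specific,
        "specific_genes": specific_genes,
        "specific_promoters": specific_promoters,
        "specific_ocrs": specific_ocrs,
        "pi1": pi1,
        "major_promoters": major,
        "ocr_assignments": ocr_assign,
        "links_by_region": links_by_region,
        "links": all_links,
        "link_sharing": sharing,
        "snp_link_pairs": pairs,
        "assignments": assignments,
        "closest_gene": closest,
        "target_summaries": summaries,
    }


def truth_report(outputs: dict, bundle: SimBundle) -> dict:
    """Recovery metrics of the planted truth from pipeline outputs.

    Sensitivity/precision for switching promoter-isoforms, planted-loop
    link recovery (ABC >= threshold; rank-first among the promoter's
    distal links), causal-SNP gene assignment and promoter-type
    accuracy, and major-promoter call accuracy.  ``chance_loop_recovery``
    is the uniform-share expectation for a designated loop pair when no
    loop is planted (one of the gene's exchangeable enhancers).
    """
    truth = bundle.truth
    cfg = bundle.config
    report: dict = {}

    # switching promoter recovery
    iso_specific = outputs["iso_specific"]
    recovered = 0
    for _, row in truth.switching.iterrows():
        hits = iso_specific[iso_specific["promoter_id"] == row["promoter_id"]]
        ok = (
            ((hits["group_a"] == row["region"]) & (hits["iso_log2fc"] > 0))
            | ((hits["group_b"] == row["region"]) & (hits["iso_log2fc"] < 0))
        ).any()
        recovered += bool(ok)
    n_sw = len(truth.switching)
    report["switching_sensitivity"] = recovered / n_sw if n_sw else np.nan

    # a discovery is true when its contrast involves a gene's planted switch
    # region: the switched promoter moves up there and, because the gene
    # total is held constant, its sibling promoters move down
    sw_regions = set(zip(truth.switching["gene_id"], truth.switching["region"]))
    n_true = 0
    discovered = set()
    for _, row in iso_specific.iterrows():
        key = (row["promoter_id"], row["contrast"])
        if key in discovered:
            continue
        discovered.add(key)
        if (row["gene_id"], row["group_a"]) in sw_regions or (
            (row["gene_id"], row["group_b"]) in sw_regions
        ):
            n_true += 1
    report["switching_precision"] = n_true / len(discovered) if discovered else np.nan

    # planted-loop recovery
    links_by_region = outputs["links_by_region"]
    n_rec = n_first = 0
    for _, lp in truth.loops.iterrows():
        rec = first = False
        for region in lp["regions"].split(","):
            links = links_by_region.get(region)
            if links is None or links.empty:
                continue
            mine = links[
                (links["element_id"] == lp["element_id"])
                & (links["promoter_id"] == lp["promoter_id"])
            ]
            if not mine.empty:
                rec = True
                distal = links[
                    (links["promoter_id"] == lp["promoter_id"])
                    & (links["kind"] == "distal")
                ]
                if not distal.empty and (
                    distal.loc[distal["abc"].idxmax(), "element_id"] == lp["element_id"]
                ):
                    first = True
        n_rec += rec
        n_first += first
    n_loops = len(truth.loops)
    report["loop_recovery"] = n_rec / n_loops if n_loops else np.nan
    report["loop_rank_first"] = n_first / n_loops if n_loops else np.nan
    report["chance_loop_recovery"] = (
        1.0 / cfg.enhancers_per_gene if cfg is not None else np.nan
    )

    # causal SNP assignment (global max over regions per SNP)
    assignments = outputs["assignments"]
    n_gene_ok = n_type_ok = n_prom_ok = 0
    for _, row in truth.causal.iterrows():
        sub = assignments[assignments["rsid"] == row["rsid"]] if not assignments.empty \
            else assignments
        if sub.empty:
            continue
        best = sub.loc[sub["abc"].idxmax()]
        if best["gene_id"] == row["gene_id"]:
            n_gene_ok += 1
            true_rank = next(
                p.rank for p in bundle.promoters if p.promoter_id == row["promoter_id"]
            )
            true_type = "five_prime" if true_rank == 1 else "non_five_prime"
            n_type_ok += best["promoter_type"] == true_type
            n_prom_ok += best["promoter_id"] == row["promoter_id"]
    n_causal = len(truth.causal)
    report["causal_gene_accuracy"] = n_gene_ok / n_causal if n_causal else np.nan
    report["causal_promoter_type_accuracy"] = n_type_ok / n_causal if n_causal else np.nan
    report["causal_promoter_accuracy"] = n_prom_ok / n_causal if n_causal else np.nan

    # major-promoter calls
    major = outputs["major_promoters"].set_index("gene_id")["major_promoter_id"]
    tm = truth.major_promoters
    both = [g for g in tm["gene_id"] if g in major.index]
    if both:
        tm_idx = tm.set_index("gene_id")
        ok = sum(major[g] == tm_idx.loc[g, "promoter_id"] for g in both)
        report["major_promoter_accuracy"] = ok / len(both)
        non5 = [g for g in both if not tm_idx.loc[g, "is_5prime"]]
        report["nonmajor_5prime_accuracy"] = (
            sum(major[g] == tm_idx.loc[g, "promoter_id"] for g in non5) / len(non5)
            if non5 else np.nan
        )
    else:
        report["major_promoter_accuracy"] = np.nan
        report["nonmajor_5prime_accuracy"] = np.nan
    return report
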