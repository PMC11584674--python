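"""Seeded synthetic multi-region datasets with planted ground truth.

The generator emulates the structure of a multi-region, multi-donor
brain expression/accessibility study at desk scale: genes with one to
three promoters (some with a non-5' major promoter, some with an
internal promoter that cannot be quantified), junction-read counts with
negative-binomial noise and donor effects, open-chromatin peaks at
promoters and at distal enhancers, idealized Hi-C contact maps with
power-law distance decay and planted enhancer-promoter loops,
fine-mapped SNPs planted inside looped enhancers, and per-gene priority
scores inflated for causal genes.  Every planted effect is recorded in
a :class:`SyntheticTruth` so downstream recovery can be measured.

Counts are negative-binomial around promoter-level means; switching
genes receive a promoter-specific region effect of the configured
log2 fold change while the gene total is held constant, so the parent
gene stays null.  All outputs are byte-reproducible per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation
from .abc_model import ContactMap
from .annotation import CLASS_UNIQUE, PromoterIsoform, TranscriptModel
from .quant import CountMatrix, junction_key

logger = logging.getLogger(__name__)

CHROM = "chr1"
GENE_SPACING = 150_000
GENE_SPAN = 50_000
PROMOTER_OFFSET = 12_000


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe a 50-gene, 3-region, 4-donor neuronal design with
    2 samples per donor and region, promoter switching at log2 fold
    change 2 in 30% of genes, enhancer-promoter loops (contact x10) for
    half the genes, and fine-mapped SNPs of which 30% are causal
    (planted inside looped enhancers of score-inflated genes).
    """

    seed: int
    n_genes: int = 50
    promoter_probs: tuple[float, ...] = (0.2, 0.5, 0.3)  # P(1, 2, 3 promoters)
    internal_promoter_fraction: float = 0.1
    n_regions: int = 3
    n_donors: int = 4
    samples_per_donor_region: int = 2
    gene_mean_log: float = np.log(300.0)
    gene_mean_sd: float = 0.6
    dispersion: float = 0.1
    donor_sd: float = 0.25
    library_sd: float = 0.3
    nonmajor_5prime_fraction: float = 0.25
    switching_gene_fraction: float = 0.3
    switch_log2fc: float = 2.0
    region_shift_gene_fraction: float = 0.0
    region_shift_log2fc: float = 1.0
    enhancers_per_gene: int = 3
    n_background_peaks: int = 40
    enhancer_activity_log: float = np.log(8.0)
    enhancer_activity_sd: float = 0.5
    promoter_activity_log: float = np.log(20.0)
    promoter_activity_sd: float = 0.5
    atac_depth: float = 40.0  # mean counts per unit activity
    loop_fraction: float = 0.5
    loop_contact_multiplier: float = 10.0
    loop_region_specific_fraction: float = 0.3
    contact_resolution: int = 5_000
    gamma: float = 1.0
    n_snps: int = 40
    causal_snp_fraction: float = 0.3
    score_effect: float = 1.5

    def __post_init__(self) -> None:
        for name in (
            "internal_promoter_fraction", "nonmajor_5prime_fraction",
            "switching_gene_fraction", "region_shift_gene_fraction",
            "loop_fraction", "loop_region_specific_fraction", "causal_snp_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.promoter_probs) - 1.0) > 1e-9:
            raise ValueError("promoter_probs must sum to 1")

    @property
    def regions(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_regions)]

    @property
    def donors(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_donors)]


@dataclass
class SyntheticTruth:
    """Planted ground truth for a bundle."""

    major_promoters: pd.DataFrame  # gene_id, promoter_id (overall major), is_5prime
    major_by_region: pd.DataFrame  # gene_id, region, promoter_id
    switching: pd.DataFrame  # gene_id, promoter_id, region, log2fc
    loops: pd.DataFrame  # element_id, promoter_id, gene_id, regions, distance_bp
    causal: pd.DataFrame  # rsid, gene_id, promoter_id, element_id
    inflated_genes: list[str]
    internal_promoters: list[str]


@dataclass
class SimBundle:
    """In-memory dataset: every input the pipeline consumes.

    ``config`` and ``truth`` are present for generated bundles and
    ``None`` for bundles loaded from files.
    """

    transcripts: list[TranscriptModel]
    promoters: list[PromoterIsoform]
    meta: pd.DataFrame
    junction_counts: CountMatrix
    gene_counts: CountMatrix
    peaks: pd.DataFrame
    peak_counts: CountMatrix
    contact_maps: dict[str, dict[str, ContactMap]]  # region -> chrom -> map
    snps: pd.DataFrame
    gene_scores: pd.DataFrame
    truth: SyntheticTruth | None = None
    config: SimConfig | None = None


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws parameterized by mean and dispersion."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _build_gene(
    rng: np.random.Generator, gene_idx: int, cfg: SimConfig
) -> tuple[list[TranscriptModel], bool]:
    """Transcript models for one gene; returns (transcripts, has_internal)."""
    gene_id = f"G{gene_idx + 1:03d}"
    origin = 100_000 + gene_idx * GENE_SPACING
    n_prom = int(rng.choice(len(cfg.promoter_probs), p=cfg.promoter_probs)) + 1
    strand = "+" if rng.random() < 0.5 else "-"
    has_internal = rng.random() < cfg.internal_promoter_fraction

    def place(rel_exons: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
        if strand == "+":
            return tuple((origin + a, origin + b) for a, b in rel_exons)
        return tuple(
            sorted((origin + GENE_SPAN - b, origin + GENE_SPAN - a) for a, b in rel_exons)
        )

    transcripts = []
    last_exon = (45_000, 45_500)
    for r in range(1, n_prom + 1):
        t = (r - 1) * PROMOTER_OFFSET
        rel = [(t, t + 200), (t + 1400 + 200 * r, t + 1600 + 200 * r), last_exon]
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.T{r}", gene_id=gene_id, chrom=CHROM,
                strand=strand, exons=place(rel),
            )
        )
        if rng.random() < 0.3:
            # second member transcript at the same TSS with a longer first
            # exon: same promoter, a distinct identifying junction
            rel_b = [(t, t + 300), (t + 1400 + 200 * r, t + 1600 + 200 * r), last_exon]
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.T{r}b", gene_id=gene_id, chrom=CHROM,
                    strand=strand, exons=place(rel_b),
                )
            )
    if has_internal:
        t = n_prom * PROMOTER_OFFSET
        rel = [(t, t + 200), last_exon]  # first intron ends on a shared non-first edge
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.Tint", gene_id=gene_id, chrom=CHROM,
                strand=strand, exons=place(rel),
            )
        )
    return transcripts, has_internal


def simulate(config: SimConfig) -> SimBundle:
    """Generate a full synthetic bundle with planted truth (seeded)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- annotation -------------------------------------------------
    transcripts: list[TranscriptModel] = []
    internal_flags: dict[str, bool] = {}
    for g in range(cfg.n_genes):
        tx, has_internal = _build_gene(rng, g, cfg)
        transcripts.extend(tx)
        internal_flags[tx[0].gene_id] = has_internal
    promoters = annotation.classify_identifiability(
        annotation.build_promoters(transcripts), transcripts
    )
    proms_by_gene: dict[str, list[PromoterIsoform]] = {}
    for p in promoters:
        proms_by_gene.setdefault(p.gene_id, []).append(p)
    for plist in proms_by_gene.values():
        plist.sort(key=lambda p: p.rank)
    genes = sorted(proms_by_gene)
    internal_promoter_ids = [
        p.promoter_id for p in promoters if p.promoter_class == "internal"
    ]

    # --- sample design ---------------------------------------------
    meta_rows = []
    for region in cfg.regions:
        for donor in cfg.donors:
            for k in range(cfg.samples_per_donor_region):
                sid = f"{region}_{donor}_s{k + 1}"
                meta_rows.append(
                    {
                        "sample_id": sid, "donor": donor, "region": region,
                        "broad_region": region, "cell_type": "neuronal",
                    }
                )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    n_samples = len(meta)
    lib = np.exp(rng.normal(0.0, cfg.library_sd, n_samples))

    # --- expression program -----------------------------------------
    gene_mean = {
        g: float(np.exp(rng.normal(cfg.gene_mean_log, cfg.gene_mean_sd))) for g in genes
    }
    shares: dict[str, np.ndarray] = {}
    nonmajor_genes: list[str] = []
    for g in genes:
        plist = proms_by_gene[g]
        k = len(plist)
        sh = rng.dirichlet(np.full(k, 2.0))
        uniq_idx = [i for i, p in enumerate(plist) if p.promoter_class == CLASS_UNIQUE]
        if (
            len([i for i in uniq_idx if plist[i].rank > 1]) >= 1
            and 0 in [plist[i].rank - 1 for i in uniq_idx]  # rank-1 is quantifiable
            and rng.random() < cfg.nonmajor_5prime_fraction
        ):
            # plant a non-5' major promoter: give the largest share to a
            # random non-rank-1 unique promoter (clearly above the rest)
            target = int(rng.choice([i for i in uniq_idx if plist[i].rank > 1]))
            sh = np.sort(sh)[::-1]
            order = [target] + [i for i in range(k) if i != target]
            out = np.empty(k)
            for pos, i in enumerate(order):
                out[i] = sh[pos]
            if out[target] < 0.55:  # ensure an unambiguous major promoter
                rest = 1.0 - out[target]
                for i in range(k):
                    if i != target:
                        out[i] *= 0.45 / rest
                out[target] = 0.55
            sh = out / out.sum()
            nonmajor_genes.append(g)
        shares[g] = sh

    # region multipliers per (gene, promoter, region); start at 1
    region_mult = {
        g: np.ones((len(proms_by_gene[g]), cfg.n_regions)) for g in genes
    }

    # --- switching genes: promoter up in one region, total constant --
    switch_rows = []
    eligible = [
        g for g in genes
        if len(proms_by_gene[g]) >= 2
        and any(p.promoter_class == CLASS_UNIQUE for p in proms_by_gene[g])
    ]
    n_switch = int(round(cfg.switching_gene_fraction * len(eligible)))
    switch_genes = sorted(rng.choice(eligible, size=n_switch, replace=False))
    fold = 2.0 ** cfg.switch_log2fc
    for g in switch_genes:
        plist = proms_by_gene[g]
        sh = shares[g]
        uniq = [i for i, p in enumerate(plist) if p.promoter_class == CLASS_UNIQUE]
        i_star = min(uniq, key=lambda i: sh[i])
        # keep the switched promoter's share small enough that the other
        # promoters can absorb the increase while the gene total is constant
        cap = 1.0 / fold * 0.8
        if sh[i_star] > cap:
            rest = 1.0 - sh[i_star]
            sh = sh * ((1.0 - cap) / rest)
            sh[i_star] = cap
            shares[g] = sh / sh.sum()
            sh = shares[g]
        r_idx = int(rng.integers(cfg.n_regions))
        region = cfg.regions[r_idx]
        s = sh[i_star]
        comp = (1.0 - fold * s) / (1.0 - s)
        region_mult[g][:, r_idx] *= comp
        region_mult[g][i_star, r_idx] = fold
        switch_rows.append(
            {
                "gene_id": g, "promoter_id": plist[i_star].promoter_id,
                "region": region, "log2fc": cfg.switch_log2fc,
            }
        )
    switching = pd.DataFrame(
        switch_rows, columns=["gene_id", "promoter_id", "region", "log2fc"]
    )

    # optional gene-level regional shifts (off by default)
    if cfg.region_shift_gene_fraction > 0:
        n_shift = int(round(cfg.region_shift_gene_fraction * len(genes)))
        for g in rng.choice(genes, size=n_shift, replace=False):
            r_idx = int(rng.integers(cfg.n_regions))
            region_mult[g][:, r_idx] *= 2.0 ** cfg.region_shift_log2fc

    # --- counts ------------------------------------------------------
    donor_eff = {
        (g, d): float(np.exp(rng.normal(0.0, cfg.donor_sd)))
        for g in genes for d in cfg.donors
    }
    region_index = {r: i for i, r in enumerate(cfg.regions)}
    sample_region = meta["region"].to_numpy()
    sample_donor = meta["donor"].to_numpy()

    junc_ids: list[str] = []
    junc_means: list[np.ndarray] = []
    gene_mean_mat = np.zeros((len(genes), n_samples))
    for gi, g in enumerate(genes):
        plist = proms_by_gene[g]
        sh = shares[g]
        for pi, p in enumerate(plist):
            mult = region_mult[g][pi]
            base = gene_mean[g] * sh[pi]
            mean_per_sample = np.array(
                [
                    base * mult[region_index[r]] * donor_eff[(g, d)] * lib[s]
                    for s, (r, d) in enumerate(zip(sample_region, sample_donor))
                ]
            )
            gene_mean_mat[gi] += mean_per_sample
            juncs = sorted(p.first_intron_junctions)
            for donor_c, acceptor_c in juncs:
                junc_ids.append(junction_key(p.chrom, donor_c, acceptor_c, p.strand))
                junc_means.append(mean_per_sample / len(juncs))
    junc_mat = _nb(rng, np.array(junc_means), cfg.dispersion)
    junction_counts = CountMatrix(
        pd.DataFrame(junc_mat, index=junc_ids, columns=meta.index), meta, "junction"
    )
    gene_mat = _nb(rng, gene_mean_mat, cfg.dispersion)
    gene_counts = CountMatrix(
        pd.DataFrame(gene_mat, index=genes, columns=meta.index), meta, "gene"
    )

    # --- peaks and accessibility -------------------------------------
    chrom_length = cfg.n_genes * GENE_SPACING + 200_000
    peak_rows = []
    activity_mean: dict[str, float] = {}
    enh_by_gene: dict[str, list[str]] = {g: [] for g in genes}
    for g in genes:
        for p in proms_by_gene[g]:
            ocr_id = f"OCR_{p.promoter_id}"
            peak_rows.append(
                {"ocr_id": ocr_id, "chrom": CHROM,
                 "start": max(0, p.tss - 150), "end": p.tss + 150}
            )
            activity_mean[ocr_id] = float(
                np.exp(rng.normal(cfg.promoter_activity_log, cfg.promoter_activity_sd))
            )
        anchor = proms_by_gene[g][0].tss  # rank-1 TSS
        own_tss = [p.tss for p in proms_by_gene[g]]
        for e in range(cfg.enhancers_per_gene):
            while True:
                d = int(rng.integers(20_000, 75_000))
                side = 1 if rng.random() < 0.5 else -1
                mid = anchor + side * d
                # keep enhancers clear of promoter windows so they stay distal
                if all(abs(mid - t) > 2_500 for t in own_tss):
                    break
            ocr_id = f"OCR_{g}_E{e + 1}"
            peak_rows.append(
                {"ocr_id": ocr_id, "chrom": CHROM,
                 "start": max(0, mid - 200), "end": mid + 200}
            )
            activity_mean[ocr_id] = float(
                np.exp(rng.normal(cfg.enhancer_activity_log, cfg.enhancer_activity_sd))
            )
            enh_by_gene[g].append(ocr_id)
    tss_positions = np.array(sorted(p.tss for p in promoters))
    n_bg = 0
    while n_bg < cfg.n_background_peaks:
        mid = int(rng.integers(10_000, chrom_length - 10_000))
        if np.min(np.abs(tss_positions - mid)) < 3_000:
            continue
        ocr_id = f"OCR_bg{n_bg + 1}"
        peak_rows.append(
            {"ocr_id": ocr_id, "chrom": CHROM, "start": mid - 200, "end": mid + 200}
        )
        activity_mean[ocr_id] = float(
            np.exp(rng.normal(cfg.enhancer_activity_log, cfg.enhancer_activity_sd))
        )
        n_bg += 1
    peaks = pd.DataFrame(peak_rows, columns=["ocr_id", "chrom", "start", "end"])
    atac_lib = np.exp(rng.normal(0.0, cfg.library_sd, n_samples))
    peak_mean = np.array(
        [
            activity_mean[ocr] * cfg.atac_depth * atac_lib
            for ocr in peaks["ocr_id"]
        ]
    )
    peak_counts = CountMatrix(
        pd.DataFrame(
            _nb(rng, peak_mean, cfg.dispersion), index=list(peaks["ocr_id"]),
            columns=meta.index,
        ),
        meta, "ocr",
    )

    # --- loops and contact maps --------------------------------------
    res = cfg.contact_resolution
    scale0 = float((100_000 + res) ** cfg.gamma)  # baseline contact = 1 at 100 kb

    def baseline(d_bp: float) -> float:
        return scale0 * (d_bp + res) ** -cfg.gamma

    peak_mid = {
        row["ocr_id"]: (row["start"] + row["end"]) // 2 for _, row in peaks.iterrows()
    }
    loop_rows = []
    loop_genes = sorted(
        rng.choice(genes, size=int(round(cfg.loop_fraction * len(genes))), replace=False)
    )
    for g in loop_genes:
        if not enh_by_gene[g]:
            continue
        # pick an (enhancer, promoter) pair at least two bins apart so the
        # loop is resolvable against the promoter's self-contact bin
        choice = None
        for element_id in rng.permutation(sorted(enh_by_gene[g])):
            targets = [
                p for p in proms_by_gene[g]
                if abs(peak_mid[element_id] - p.tss) >= 2 * res
            ]
            if targets:
                choice = (str(element_id), targets[int(rng.integers(len(targets)))])
                break
        if choice is None:
            continue
        element_id, target = choice
        if rng.random() < cfg.loop_region_specific_fraction:
            loop_regions = [str(rng.choice(cfg.regions))]
        else:
            loop_regions = list(cfg.regions)
        loop_rows.append(
            {
                "element_id": element_id, "promoter_id": target.promoter_id,
                "gene_id": g, "regions": ",".join(loop_regions),
                "distance_bp": abs(peak_mid[element_id] - target.tss),
            }
        )
    loops = pd.DataFrame(
        loop_rows,
        columns=["element_id", "promoter_id", "gene_id", "regions", "distance_bp"],
    )

    prom_tss = {p.promoter_id: p.tss for p in promoters}
    anchor_bins = sorted(
        {t // res for t in prom_tss.values()} | {m // res for m in peak_mid.values()}
    )
    contact_maps: dict[str, dict[str, ContactMap]] = {}
    for region in cfg.regions:
        cmap = ContactMap(resolution=res, chrom=CHROM)
        for b in anchor_bins:
            cmap.set(b * res, b * res, baseline(0))
        for b in anchor_bins[:30]:  # calibration entries at the 100 kb reference
            cmap.set(b * res, (b + 20) * res, 1.0)
        if cfg.loop_contact_multiplier != 1.0:
            for _, lp in loops.iterrows():
                if region not in lp["regions"].split(","):
                    continue
                eb = peak_mid[lp["element_id"]] // res
                pb = prom_tss[lp["promoter_id"]] // res
                d = abs(eb - pb) * res
                cmap.set(eb * res, pb * res, baseline(d) * cfg.loop_contact_multiplier)
        contact_maps[region] = {CHROM: cmap}

    # --- fine-mapped SNPs and priority scores ------------------------
    n_causal = int(round(cfg.causal_snp_fraction * cfg.n_snps))
    if n_causal > len(loops):
        raise ValueError(
            f"infeasible config: {n_causal} causal SNPs but only {len(loops)} loops"
        )
    causal_loops = loops.iloc[
        sorted(rng.choice(len(loops), size=n_causal, replace=False))
    ] if n_causal else loops.iloc[:0]
    snp_rows = []
    causal_rows = []
    peaks_idx = peaks.set_index("ocr_id")
    for i, (_, lp) in enumerate(causal_loops.iterrows()):
        pk = peaks_idx.loc[lp["element_id"]]
        pos1 = int(rng.integers(pk["start"], pk["end"])) + 1  # 1-based
        rsid = f"rs{i + 1}"
        snp_rows.append(
            {"rsid": rsid, "chrom": CHROM, "pos": pos1,
             "pip": float(rng.uniform(0.05, 0.6))}
        )
        causal_rows.append(
            {
                "rsid": rsid, "gene_id": lp["gene_id"],
                "promoter_id": lp["promoter_id"], "element_id": lp["element_id"],
            }
        )
    element_ivs = [
        (row["start"], row["end"]) for _, row in peaks.iterrows()
    ]
    i = n_causal
    while i < cfg.n_snps:
        pos0 = int(rng.integers(10_000, chrom_length - 10_000))
        if any(s <= pos0 < e for s, e in element_ivs):
            continue
        pip = (
            float(rng.uniform(0.011, 0.3)) if (i % 2 == 0)
            else float(rng.uniform(0.001, 0.009))
        )
        snp_rows.append(
            {"rsid": f"rs{i + 1}", "chrom": CHROM, "pos": pos0 + 1, "pip": pip}
        )
        i += 1
    snps = pd.DataFrame(snp_rows, columns=["rsid", "chrom", "pos", "pip"])
    causal = pd.DataFrame(
        causal_rows, columns=["rsid", "gene_id", "promoter_id", "element_id"]
    )

    inflated = sorted(set(causal["gene_id"]))
    score = rng.normal(0.0, 1.0, len(genes))
    score += np.array([cfg.score_effect if g in inflated else 0.0 for g in genes])
    gene_scores = pd.DataFrame({"gene_id": genes, "score": score})

    # --- truth -------------------------------------------------------
    major_rows = []
    major_region_rows = []
    for g in genes:
        plist = proms_by_gene[g]
        uniq = [i for i, p in enumerate(plist) if p.promoter_class == CLASS_UNIQUE]
        if not uniq:
            continue
        sh = shares[g]
        overall = np.array(
            [sh[i] * region_mult[g][i].mean() for i in range(len(plist))]
        )
        i_best = max(uniq, key=lambda i: (overall[i], -plist[i].rank))
        major_rows.append(
            {
                "gene_id": g, "promoter_id": plist[i_best].promoter_id,
                "is_5prime": plist[i_best].rank == 1,
            }
        )
        for r_idx, region in enumerate(cfg.regions):
            vals = np.array([sh[i] * region_mult[g][i, r_idx] for i in range(len(plist))])
            i_r = max(uniq, key=lambda i: (vals[i], -plist[i].rank))
            major_region_rows.append(
                {"gene_id": g, "region": region, "promoter_id": plist[i_r].promoter_id}
            )
    truth = SyntheticTruth(
        major_promoters=pd.DataFrame(
            major_rows, columns=["gene_id", "promoter_id", "is_5prime"]
        ),
        major_by_region=pd.DataFrame(
            major_region_rows, columns=["gene_id", "region", "promoter_id"]
        ),
        switching=switching,
        loops=loops,
        causal=causal,
        inflated_genes=inflated,
        internal_promoters=internal_promoter_ids,
    )
    return SimBundle(
        config=cfg, transcripts=transcripts, promoters=promoters, meta=meta,
        junction_counts=junction_counts, gene_counts=gene_counts, peaks=peaks,
        peak_counts=peak_counts, contact_maps=contact_maps, snps=snps,
        gene_scores=gene_scores, truth=truth,
    )
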