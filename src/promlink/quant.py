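"""Promoter-isoform quantification and count normalization.

Promoter-isoform expression is measured as the number of RNA-seq reads
spanning the first-intron junctions of the promoter's member transcripts
— junctions that uniquely identify transcription from that promoter.
Count matrices (gene, promoter-isoform, or open-chromatin region) are
normalized with trimmed-mean-of-M-values (TMM) scaling factors and
expressed as counts per million (CPM), then passed through detection
filters before any statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import CLASS_UNIQUE, PromoterIsoform

logger = logging.getLogger(__name__)

# detection-filter presets: (min_cpm, min_fraction, strict_gt_fraction)
GENE_FILTER = (1.0, 0.20, False)
PROMOTER_FILTER = (2.0, 0.40, True)
OCR_FILTER = (1.0, 0.20, False)


def junction_key(chrom: str, donor: int, acceptor: int, strand: str) -> str:
    """Canonical string key for a splice junction (genomic intron coords)."""
    return f"{chrom}:{donor}-{acceptor}:{strand}"


@dataclass
class CountMatrix:
    """Raw counts, features x samples, with sample metadata.

    ``meta`` is indexed by sample id and carries at least ``donor``,
    ``region``, ``broad_region`` and ``cell_type`` columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    feature_kind: str

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids in count matrix")
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("count matrix columns do not match sample metadata")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[:, list(sample_ids)], self.meta.loc[list(sample_ids)],
            self.feature_kind,
        )


@dataclass
class ExpressionMatrix:
    """TMM/CPM-normalized expression with per-sample normalization factors."""

    cpm: pd.DataFrame
    meta: pd.DataFrame
    feature_kind: str
    norm_factors: pd.Series
    lib_sizes: pd.Series

    @property
    def feature_ids(self) -> pd.Index:
        return self.cpm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.cpm.columns

    def log2_cpm(self, pseudocount: float = 0.5) -> pd.DataFrame:
        """log2(CPM + pseudocount); the pseudocount is used only here."""
        return np.log2(self.cpm + pseudocount)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            self.cpm.loc[:, ids], self.meta.loc[ids], self.feature_kind,
            self.norm_factors.loc[ids], self.lib_sizes.loc[ids],
        )

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.cpm.loc[list(feature_ids)], self.meta, self.feature_kind,
            self.norm_factors, self.lib_sizes,
        )


@dataclass
class PromoterQuantResult:
    counts: CountMatrix
    ambiguous_junctions: list[str]
    unassigned: pd.Series  # per-sample tally of reads on unannotated junctions


def quantify_promoters(
    junction_counts: CountMatrix,
    promoters: list[PromoterIsoform],
    classes: tuple[str, ...] = (CLASS_UNIQUE,),
) -> PromoterQuantResult:
    """Sum junction reads over each promoter's first-intron junctions.

    Only promoters whose class is in ``classes`` are quantified (default:
    uniquely identifiable promoters only; pass
    ``("unique", "internal")`` to also quantify internal promoters, as is
    done when calling active promoters for enhancer-promoter linking).

    A junction claimed by two or more quantified promoters of the same
    gene is ambiguous: it is counted for none of them and reported.
    Junction rows matching no promoter are summed into a per-sample
    ``unassigned`` tally.
    """
    if junction_counts.feature_kind != "junction":
        raise ValueError("expected a junction count matrix")

    quantified = [p for p in promoters if p.promoter_class in classes]
    # map junction key -> claiming promoters, per gene
    claims: dict[str, list[PromoterIsoform]] = {}
    for p in quantified:
        for donor, acceptor in p.first_intron_junctions:
            key = junction_key(p.chrom, donor, acceptor, p.strand)
            claims.setdefault(key, []).append(p)

    ambiguous: set[str] = set()
    for key, claimants in claims.items():
        genes: dict[str, int] = {}
        for p in claimants:
            genes[p.gene_id] = genes.get(p.gene_id, 0) + 1
        if any(n > 1 for n in genes.values()):
            ambiguous.add(key)
    if ambiguous:
        logger.warning("%d junctions shared within a gene; excluded", len(ambiguous))

    counts = junction_counts.counts
    matched_keys = set(claims) & set(counts.index)
    unassigned_keys = [k for k in counts.index if k not in claims]
    unassigned = counts.loc[unassigned_keys].sum(axis=0)
    if unassigned_keys:
        logger.info("%d junction rows matched no quantified promoter", len(unassigned_keys))

    rows = []
    ids = []
    zero = np.zeros(counts.shape[1])
    for p in sorted(quantified, key=lambda q: q.promoter_id):
        total = zero.copy()
        for donor, acceptor in sorted(p.first_intron_junctions):
            key = junction_key(p.chrom, donor, acceptor, p.strand)
            if key in ambiguous or key not in matched_keys:
                continue
            total = total + counts.loc[key].to_numpy()
        ids.append(p.promoter_id)
        rows.append(total)
    mat = pd.DataFrame(np.array(rows), index=ids, columns=counts.columns)
    return PromoterQuantResult(
        counts=CountMatrix(mat, junction_counts.meta, "promoter_isoform"),
        ambiguous_junctions=sorted(ambiguous),
        unassigned=unassigned,
    )


def _tmm_factor_pair(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """One TMM scaling factor: weighted trimmed mean of M-values vs a reference."""
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse-binomial asymptotic variance weights
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
    m, a, w = m[finite], a[finite], w[finite]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    log_f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(log_f):
        return 1.0
    return float(2.0 ** log_f)


def tmm_normalize(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> ExpressionMatrix:
    """TMM scaling factors and CPM.

    The reference sample is the one whose upper-quartile fraction
    (75th percentile of counts / library size) is closest to the mean
    over samples.  Per sample, the factor is the weighted trimmed mean
    of M-values against the reference (trims ``trim_m`` on M,
    ``trim_a`` on A; inverse-binomial precision weights).  Factors are
    rescaled to geometric mean 1 and CPM is computed against
    factor-adjusted library sizes.
    """
    mat = counts.counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.sample_ids[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    f75 = np.array([np.quantile(mat[:, j], 0.75) / lib[j] for j in range(mat.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_factor_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff_lib = lib * factors
    cpm = pd.DataFrame(
        mat / eff_lib * 1e6, index=counts.feature_ids, columns=counts.sample_ids
    )
    return ExpressionMatrix(
        cpm=cpm,
        meta=counts.meta,
        feature_kind=counts.feature_kind,
        norm_factors=pd.Series(factors, index=counts.sample_ids, name="norm_factor"),
        lib_sizes=pd.Series(lib, index=counts.sample_ids, name="lib_size"),
    )


def filter_detected(
    expr: ExpressionMatrix,
    min_cpm: float,
    min_fraction: float,
    strict_gt_fraction: bool = False,
    sample_ids=None,
) -> ExpressionMatrix:
    """Keep features detected at ``min_cpm`` in enough samples.

    A feature passes when CPM >= ``min_cpm`` in at least (or, with
    ``strict_gt_fraction``, strictly more than) ``min_fraction`` of the
    samples.  Presets: genes/OCRs (1 CPM, 20%, >=); promoter-isoforms
    (2 CPM, 40%, strictly >).  ``sample_ids`` restricts the sample
    universe used for the fraction without subsetting the output.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    cpm = expr.cpm if sample_ids is None else expr.cpm.loc[:, list(sample_ids)]
    frac = (cpm >= min_cpm).mean(axis=1)
    keep = frac > min_fraction if strict_gt_fraction else frac >= min_fraction
    return expr.subset_features(expr.feature_ids[keep])


def call_major_promoters(
    expr: ExpressionMatrix,
    promoters: list[PromoterIsoform],
    sample_ids=None,
) -> pd.DataFrame:
    """Per gene, the promoter-isoform with highest mean CPM.

    Mean CPM is taken across all samples, or across ``sample_ids`` if
    given (e.g. one region's samples).  Ties go to the smaller rank so
    the 5' promoter wins exact ties.  Genes with no surviving promoter
    in ``expr`` are omitted.

    Returns columns ``gene_id``, ``major_promoter_id``, ``is_5prime``.
    """
    if expr.feature_kind != "promoter_isoform":
        raise ValueError("expected promoter-isoform expression")
    cpm = expr.cpm if sample_ids is None else expr.cpm.loc[:, list(sample_ids)]
    mean_cpm = cpm.mean(axis=1)
    info = {p.promoter_id: p for p in promoters}
    per_gene: dict[str, list[tuple[float, int, str]]] = {}
    for pid, mu in mean_cpm.items():
        p = info.get(pid)
        if p is None:
            continue
        per_gene.setdefault(p.gene_id, []).append((float(mu), p.rank, pid))
    rows = []
    for gene_id in sorted(per_gene):
        cands = per_gene[gene_id]
        # highest mean CPM; ties broken toward smaller rank
        best = max(cands, key=lambda c: (c[0], -c[1]))
        rows.append(
            {
                "gene_id": gene_id,
                "major_promoter_id": best[2],
                "is_5prime": info[best[2]].rank == 1,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "major_promoter_id", "is_5prime"])
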