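"""Pairwise differential statistics across brain regions.

Per feature and region pair, log2(CPM + 0.5) is modeled by weighted
least squares with the region indicator, donor as a fixed blocking
covariate, and optional extra covariates; precision weights come from a
LOWESS mean-variance trend (residual SD against mean log-CPM),
evaluated per observation at its fitted value.  Downstream statistics
consume only the group coefficient (log2 fold change), its two-sided
t-test p-value, and Benjamini-Hochberg FDR.

The module also provides Storey's pi1 (proportion of true non-null
tests) as a dissimilarity metric between regions, the broad-region
specificity rule (significantly higher in every pairwise comparison),
and the promoter-isoform-specific DEG classifier (isoform significant
while its parent gene is null or moves the opposite way).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .quant import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contrast:
    group_a: str
    group_b: str
    group_col: str = "region"  # or "broad_region"

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")

    @property
    def name(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are excluded from the ranking and propagate to the output.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _design_matrix(
    meta: pd.DataFrame, group_col: str, group_a: str, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + group indicator + covariate columns (donor dummies etc.).

    Covariate columns that are collinear with the group indicator (or
    with earlier columns) are dropped with a warning.
    """
    n = len(meta)
    cols = [np.ones(n), (meta[group_col] == group_a).to_numpy(dtype=float)]
    names = ["intercept", "group"]
    for cov in covariates:
        vals = meta[cov]
        if vals.dtype.kind in "if":
            cand = [(cov, vals.to_numpy(dtype=float))]
        else:
            levels = sorted(vals.astype(str).unique())[1:]  # first level absorbed
            cand = [(f"{cov}[{lv}]", (vals.astype(str) == lv).to_numpy(dtype=float))
                    for lv in levels]
        for name, col in cand:
            trial = np.column_stack(cols + [col])
            if np.linalg.matrix_rank(trial) > len(cols):
                cols.append(col)
                names.append(name)
            else:
                logger.warning("covariate column %s collinear with design; dropped", name)
    return np.column_stack(cols), names


def _variance_trend_weights(y: np.ndarray, fitted: np.ndarray, resid_sd: np.ndarray) -> np.ndarray:
    """Per-observation precision weights from a LOWESS SD-vs-mean trend."""
    mean_expr = y.mean(axis=1)
    order = np.argsort(mean_expr)
    trend = lowess(resid_sd[order], mean_expr[order], frac=0.6, return_sorted=True)
    xs, ys = trend[:, 0], np.maximum(trend[:, 1], 1e-4)
    sd_pred = np.interp(fitted, xs, ys)
    return 1.0 / sd_pred**2


def fit_pairwise_de(
    expr: ExpressionMatrix,
    contrast: Contrast,
    covariates: list[str] | None = None,
    use_weights: bool = True,
) -> pd.DataFrame:
    """Differential test for one region pair.

    Fits ``log2(CPM + 0.5) ~ group + donor + covariates`` per feature by
    (weighted) least squares and reports the group coefficient as log2
    fold change (group_a minus group_b) with a two-sided t-test p-value
    and BH-adjusted FDR within the contrast.  Features with zero
    variance get ``log2fc = 0, p = 1``.
    """
    covariates = list(covariates) if covariates else []
    if "donor" not in covariates:
        covariates = ["donor"] + covariates
    mask = expr.meta[contrast.group_col].isin([contrast.group_a, contrast.group_b])
    meta = expr.meta.loc[mask]
    for grp in (contrast.group_a, contrast.group_b):
        if (meta[contrast.group_col] == grp).sum() < 2:
            raise ValueError(f"need >=2 samples in group {grp}")
    sub = expr.subset_samples(meta.index)
    y = sub.log2_cpm().to_numpy()
    X, _ = _design_matrix(meta, contrast.group_col, contrast.group_a, covariates)
    n, p_cols = X.shape
    df_resid = n - p_cols
    if df_resid < 1:
        raise ValueError("design has no residual degrees of freedom")

    pinv = np.linalg.pinv(X)
    beta0 = y @ pinv.T  # features x p
    fitted0 = beta0 @ X.T
    resid0 = y - fitted0
    resid_sd = np.sqrt((resid0**2).sum(axis=1) / df_resid)

    log2fc = np.zeros(y.shape[0])
    pvals = np.ones(y.shape[0])
    nonzero = y.std(axis=1) > 1e-12

    if use_weights:
        w = _variance_trend_weights(y, fitted0, resid_sd)
    else:
        w = np.ones_like(y)

    for i in np.flatnonzero(nonzero):
        wi = w[i]
        sw = np.sqrt(wi)
        Xw = X * sw[:, None]
        yw = y[i] * sw
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        sigma2 = (resid @ resid) / df_resid
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
        se = np.sqrt(max(sigma2 * xtx_inv[1, 1], 1e-300))
        log2fc[i] = beta[1]
        pvals[i] = 2.0 * stats.t.sf(abs(beta[1]) / se, df_resid)

    out = pd.DataFrame(
        {
            "feature_id": sub.feature_ids,
            "contrast": contrast.name,
            "group_a": contrast.group_a,
            "group_b": contrast.group_b,
            "log2fc": log2fc,
            "p": pvals,
        }
    )
    out["fdr"] = bh_fdr(out["p"])
    return out


def all_pairwise_de(
    expr: ExpressionMatrix,
    group_col: str = "region",
    covariates: list[str] | None = None,
    global_fdr: bool = True,
) -> pd.DataFrame:
    """DE for every unordered pair of groups, optionally with pooled BH.

    With ``global_fdr`` the ``fdr`` column is recomputed by pooling
    p-values over all features x contrasts ("global FDR").
    """
    groups = sorted(expr.meta[group_col].astype(str).unique())
    tables = []
    for a, b in itertools.combinations(groups, 2):
        tables.append(fit_pairwise_de(expr, Contrast(a, b, group_col), covariates))
    de = pd.concat(tables, ignore_index=True)
    if global_fdr:
        de["fdr"] = bh_fdr(de["p"])
    return de


DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


def storey_pi1(pvalues, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Storey's estimate of the proportion of true non-null tests.

    pi0(lambda) = #{p > lambda} / ((1 - lambda) n) over the lambda grid
    is smoothed with a natural cubic smoothing spline and evaluated at
    the largest lambda; pi1 = 1 - pi0, clamped to [0, 1].  Falls back to
    the fixed lambda = 0.5 estimate when fewer than 5 grid points are
    usable.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if p.size < 100:
        logger.warning("pi1 estimated from only %d p-values; unstable", p.size)
    lam = np.asarray(sorted(set(float(x) for x in lambda_grid)))
    pi0_hat = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    usable = np.isfinite(pi0_hat)
    if usable.sum() < 5:
        pi0 = float((p > 0.5).mean() / 0.5)
    else:
        lam_u, pi0_u = lam[usable], pi0_hat[usable]
        try:
            spline = make_smoothing_spline(lam_u, pi0_u)
            pi0 = float(spline(lam_u[-1]))
        except Exception:  # ill-conditioned spline
            pi0 = float((p > 0.5).mean() / 0.5)
    pi0 = min(max(pi0, 0.0), 1.0)
    return 1.0 - pi0


def pairwise_dissimilarity(
    expr: ExpressionMatrix,
    group_col: str = "region",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """pi1 dissimilarity matrix over regions (diagonal 0, symmetric)."""
    counts = expr.meta[group_col].value_counts()
    groups = sorted(g for g in counts.index if counts[g] >= 2)
    dropped = sorted(set(counts.index) - set(groups))
    if dropped:
        logger.warning("regions with <2 samples excluded from pi1: %s", dropped)
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for a, b in itertools.combinations(groups, 2):
        de = fit_pairwise_de(expr, Contrast(a, b, group_col), covariates)
        pi1 = storey_pi1(de["p"].to_numpy())
        mat.loc[a, b] = pi1
        mat.loc[b, a] = pi1
    return mat


def broad_region_specific(
    de: pd.DataFrame,
    fdr_cut: float = 0.05,
    refit_global_fdr: bool = False,
) -> pd.DataFrame:
    """Label features specific to one broad region.

    A feature is specific to region R iff, for every other region Q,
    the R-vs-Q contrast is significant (fdr < ``fdr_cut``) with the
    fold change favoring R.  ``de`` must contain all pairwise contrasts
    (columns ``group_a``, ``group_b``, ``log2fc``, ``fdr``), with FDR
    already pooled across contrasts unless ``refit_global_fdr``.

    Returns columns ``feature_id``, ``region`` for labeled features.
    """
    de = de.copy()
    if refit_global_fdr:
        de["fdr"] = bh_fdr(de["p"])
    regions = sorted(set(de["group_a"]) | set(de["group_b"]))
    have = {frozenset(pair) for pair in zip(de["group_a"], de["group_b"])}
    for a, b in itertools.combinations(regions, 2):
        if frozenset((a, b)) not in have:
            raise ValueError(f"missing contrast between {a} and {b}")
    rows = []
    for feature_id, grp in de.groupby("feature_id", sort=True):
        for r in regions:
            ok = True
            for q in regions:
                if q == r:
                    continue
                sub = grp[
                    ((grp["group_a"] == r) & (grp["group_b"] == q))
                    | ((grp["group_a"] == q) & (grp["group_b"] == r))
                ]
                if sub.empty:
                    ok = False
                    break
                hit = False
                for _, row in sub.iterrows():
                    fc_toward_r = row["log2fc"] if row["group_a"] == r else -row["log2fc"]
                    if row["fdr"] < fdr_cut and fc_toward_r > 0:
                        hit = True
                if not hit:
                    ok = False
                    break
            if ok:
                rows.append({"feature_id": feature_id, "region": r})
    return pd.DataFrame(rows, columns=["feature_id", "region"])


def isoform_specific_degs(
    iso_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    promoter_to_gene: dict[str, str],
    fdr_cut: float = 0.05,
    gene_null_p: float = 0.1,
) -> pd.DataFrame:
    """Promoter-isoforms that change while their gene does not.

    For each contrast, a promoter-isoform is a *specific DEG* iff its
    FDR < ``fdr_cut`` and its parent gene is either non-significant
    (nominal p > ``gene_null_p``) or changes in the opposite direction
    (strict sign disagreement; a zero gene fold change counts as
    neither sign).  The ``reason`` column records which branch applied
    (``gene_null`` / ``opposite_sign``).  Isoforms whose gene lacks a DE
    row for the contrast are skipped and counted.
    """
    gene_idx = gene_de.set_index(["feature_id", "contrast"])
    rows = []
    skipped = 0
    sig = iso_de[iso_de["fdr"] < fdr_cut]
    for _, row in sig.iterrows():
        gene_id = promoter_to_gene.get(row["feature_id"])
        if gene_id is None or (gene_id, row["contrast"]) not in gene_idx.index:
            skipped += 1
            continue
        g = gene_idx.loc[(gene_id, row["contrast"])]
        if isinstance(g, pd.DataFrame):
            g = g.iloc[0]
        reason = None
        if g["p"] > gene_null_p:
            reason = "gene_null"
        elif np.sign(row["log2fc"]) != 0 and np.sign(g["log2fc"]) != 0 and (
            np.sign(row["log2fc"]) != np.sign(g["log2fc"])
        ):
            reason = "opposite_sign"
        if reason is not None:
            rows.append(
                {
                    "promoter_id": row["feature_id"],
                    "gene_id": gene_id,
                    "contrast": row["contrast"],
                    "group_a": row["group_a"],
                    "group_b": row["group_b"],
                    "iso_log2fc": row["log2fc"],
                    "iso_fdr": row["fdr"],
                    "gene_log2fc": g["log2fc"],
                    "gene_p": g["p"],
                    "reason": reason,
                }
            )
    if skipped:
        logger.info("%d significant isoforms lacked a parent-gene DE row", skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "promoter_id", "gene_id", "contrast", "group_a", "group_b",
            "iso_log2fc", "iso_fdr", "gene_log2fc", "gene_p", "reason",
        ],
    )
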