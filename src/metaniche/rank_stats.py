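"""Rank-based and pseudobulk differential-expression statistics.

Two testing routes live here. The per-cell route is the Wilcoxon rank-sum
marker test with a signed Z conversion (genes with Z above a cutoff,
default 3, are called markers). The per-sample route forms "mini-bulk"
(pseudobulk) counts by summing each gene over a sample's cells of one type
— samples contributing fewer than 10 cells are dropped — and fits a
negative-binomial GLM per gene with a Wald test on the group contrast, in
the style of bulk RNA-seq DE (median-of-ratios size factors, trend-shrunken
method-of-moments dispersions).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
import statsmodels.api as sm

from .core import NormalizedMatrix

logger = logging.getLogger(__name__)

EXACT_MAX_GROUP = 10  # exact rank-sum when both groups are at most this size

__all__ = [
    "benjamini_hochberg", "rank_sum_test", "wilcoxon_markers",
    "make_pseudobulk", "pseudobulk_de",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _asymptotic_ranksum(x_in: np.ndarray, x_out: np.ndarray):
    """Vectorized two-sided rank-sum with tie and continuity correction.

    ``x_in``/``x_out`` are (n_items, n1) and (n_items, n2); returns
    (signed_z, p) per item. Constant items give z = 0, p = 1.
    """
    n1, n2 = x_in.shape[1], x_out.shape[1]
    n = n1 + n2
    data = np.concatenate([x_in, x_out], axis=1)
    ranks = st.rankdata(data, axis=1)
    r_in = ranks[:, :n1].sum(axis=1)
    u = r_in - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # tie correction on the variance: sum(t^3 - t) over tied groups per item
    sorted_data = np.sort(data, axis=1)
    new_group = np.ones_like(sorted_data, dtype=bool)
    new_group[:, 1:] = sorted_data[:, 1:] != sorted_data[:, :-1]
    tie_term = np.zeros(data.shape[0])
    for i in range(data.shape[0]):
        counts = np.diff(np.append(np.flatnonzero(new_group[i]), n))
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    with np.errstate(divide="ignore", invalid="ignore"):
        z_abs = np.where(var > 0, np.maximum(np.abs(u - mu) - 0.5, 0.0) / np.sqrt(var), 0.0)
    p = np.where(var > 0, 2.0 * st.norm.sf(z_abs), 1.0)
    signed = np.sign(u - mu) * z_abs
    return signed, np.minimum(p, 1.0)


def rank_sum_test(x, y, exact: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; returns ``(signed_z, p)``.

    ``exact='auto'`` uses the exact null distribution when both groups have
    at most 10 observations and there are no ties across the pooled sample;
    otherwise the normal approximation with tie and continuity correction.
    The signed Z is the inverse-normal of the two-sided p, signed by the
    direction of the mean-rank difference of ``x`` versus ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    use_exact = (exact == "exact") or (
        exact == "auto" and no_ties
        and max(x.size, y.size) <= EXACT_MAX_GROUP)
    if use_exact:
        res = st.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        mu = x.size * y.size / 2.0
        sign = np.sign(res.statistic - mu)
        z = float(sign * st.norm.isf(min(p, 1.0) / 2.0)) if p < 1.0 else 0.0
        return z, p
    z, p = _asymptotic_ranksum(x[None, :], y[None, :])
    return float(z[0]), float(p[0])


def wilcoxon_markers(norm: NormalizedMatrix, labels, target) -> pd.DataFrame:
    """Marker statistics of one cluster against all remaining cells.

    Per gene: signed Z (positive = higher in the target cluster), raw and
    BH-adjusted two-sided p, fraction of target cells expressing, mean
    normalized expression inside/outside, and a log2 fold change on the
    de-logged means. Exact p for tiny groups (both <= 10, no ties),
    otherwise the tie/continuity-corrected normal approximation.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != norm.n_cells:
        raise ValueError("labels length does not match the number of cells")
    in_mask = labels == target
    n1, n2 = int(in_mask.sum()), int((~in_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("target cluster and its complement each need >= 2 cells")
    x_in = norm.values[:, in_mask]
    x_out = norm.values[:, ~in_mask]

    if max(n1, n2) <= EXACT_MAX_GROUP:
        z = np.empty(norm.n_genes)
        p = np.empty(norm.n_genes)
        for i in range(norm.n_genes):
            z[i], p[i] = rank_sum_test(x_in[i], x_out[i])
    else:
        z, p = _asymptotic_ranksum(x_in, x_out)

    mean_in = x_in.mean(axis=1)
    mean_out = x_out.mean(axis=1)
    eps = 1e-9
    if norm.log:
        lfc = np.log2((np.expm1(mean_in) + eps) / (np.expm1(mean_out) + eps))
    else:
        lfc = np.log2((mean_in + eps) / (mean_out + eps))
    constant = (x_in.min(axis=1) == x_in.max(axis=1)) & \
               (x_out.min(axis=1) == x_out.max(axis=1)) & \
               (x_in[:, 0] == x_out[:, 0])
    out = pd.DataFrame({
        "gene_id": norm.gene_ids,
        "symbol": norm.symbols,
        "z": z,
        "p": p,
        "p_adj": benjamini_hochberg(p),
        "frac_in": (x_in > 0).mean(axis=1),
        "frac_out": (x_out > 0).mean(axis=1),
        "mean_in": mean_in,
        "mean_out": mean_out,
        "log2_fc": lfc,
        "constant": constant,
    })
    return out


def make_pseudobulk(counts, cells: pd.DataFrame, cell_type: str,
                    min_cells: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum counts per sample over that sample's cells of one type.

    Samples contributing fewer than ``min_cells`` cells of the type are
    excluded (and listed in the returned audit table). Raises if every
    sample is excluded.
    """
    if cell_type not in set(cells["cell_type"].dropna()):
        raise KeyError(f"cell type {cell_type!r} not present in the cell table")
    mat = counts.tocsc() if sp.issparse(counts) else np.asarray(counts)
    mask = (cells["cell_type"] == cell_type).to_numpy()
    samples = sorted(cells["sample_id"].unique())
    columns, audit_rows = {}, []
    for s in samples:
        idx = np.flatnonzero(mask & (cells["sample_id"] == s).to_numpy())
        included = len(idx) >= min_cells
        audit_rows.append((s, len(idx), included))
        if included:
            sub = mat[:, idx]
            columns[s] = np.asarray(sub.sum(axis=1)).ravel().astype(np.int64)
    audit = pd.DataFrame(audit_rows, columns=["sample_id", "n_cells", "included"])
    if not columns:
        raise ValueError(
            f"no sample has >= {min_cells} cells of type {cell_type!r}")
    excluded = audit.loc[~audit["included"], "sample_id"].tolist()
    if excluded:
        logger.info("pseudobulk %s: excluded samples %s (< %d cells)",
                    cell_type, excluded, min_cells)
    pb = pd.DataFrame(columns)
    return pb, audit


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference)."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    usable = np.all(np.isfinite(logc), axis=1)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample; "
                         "cannot estimate size factors")
    log_geo = logc[usable].mean(axis=1)
    sf = np.exp(np.median(logc[usable] - log_geo[:, None], axis=0))
    return sf


def _dispersion_estimates(counts: np.ndarray, sf: np.ndarray,
                          groups: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion: method of moments, shrunk toward a mean trend.

    Gene-wise moments pool within-group variances of the size-factor
    normalized counts; the Poisson part of that variance is mu * mean(1/s_j)
    (not mu), so the excess ``v - mu * c`` isolates the overdispersion.
    The mean-dispersion trend ``alpha(mu) = a0 + a1/mu`` is fit to binned
    ratio estimates ``sum(excess) / sum(mu^2)`` — unbiased under the NB
    moment model, with no positivity selection on the noisy gene-wise
    values. Each gene's final dispersion is the log-space midpoint of the
    trend and its own estimate clipped to within 5x of the trend.
    """
    q = counts / sf
    mu = q.mean(axis=1)
    var = np.zeros(counts.shape[0])
    dof = 0
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() >= 2:
            var += q[:, sel].var(axis=1, ddof=1) * (sel.sum() - 1)
            dof += sel.sum() - 1
    var = var / max(dof, 1)
    c = float(np.mean(1.0 / sf))
    excess = var - mu * c

    order = np.argsort(mu)
    bin_mu, bin_alpha = [], []
    for b in np.array_split(order, min(10, max(1, len(mu) // 20))):
        denom = float((mu[b] ** 2).sum())
        if denom > 0:
            bin_mu.append(float(mu[b].mean()))
            bin_alpha.append(float(excess[b].sum() / denom))
    glob = max(float(excess.sum() / max((mu ** 2).sum(), 1e-300)), 1e-8)
    if len(bin_mu) >= 3:
        X = np.column_stack([np.ones(len(bin_mu)), 1.0 / np.asarray(bin_mu)])
        coef, *_ = np.linalg.lstsq(X, np.asarray(bin_alpha), rcond=None)
        a0, a1 = coef
        if a0 <= 0 and a1 <= 0:
            trend = np.full(len(mu), glob)
        else:
            with np.errstate(divide="ignore"):
                trend = np.clip(max(a0, 0.0) + max(a1, 0.0) / np.maximum(mu, 1e-12),
                                1e-8, 10.0)
    else:
        trend = np.full(len(mu), glob)

    with np.errstate(divide="ignore", invalid="ignore"):
        mom = excess / mu ** 2
    mom = np.clip(np.nan_to_num(mom, nan=glob, posinf=glob, neginf=glob),
                  trend / 5, trend * 5)
    mom = np.maximum(mom, 1e-8)
    alpha = np.exp(0.5 * (np.log(trend) + np.log(mom)))
    return np.clip(alpha, 1e-8, 10.0)


def pseudobulk_de(pseudobulk_a: pd.DataFrame, pseudobulk_b: pd.DataFrame,
                  min_samples: int = 2) -> pd.DataFrame:
    """Negative-binomial Wald differential expression on pseudobulk counts.

    Size factors by median-of-ratios over both groups jointly; per-gene NB
    GLM ``count ~ group`` with log size-factor offset and trend-shrunken
    dispersion; two-sided Wald p on the group coefficient; BH over tested
    genes. Genes with zero counts everywhere are reported untested.
    """
    if pseudobulk_a.shape[1] < min_samples or pseudobulk_b.shape[1] < min_samples:
        raise ValueError(f"need >= {min_samples} samples per group")
    if not pseudobulk_a.index.equals(pseudobulk_b.index):
        raise ValueError("pseudobulk tables must share the same gene index")
    counts = np.column_stack([pseudobulk_a.to_numpy(), pseudobulk_b.to_numpy()])
    # indicator 1 for group A: the Wald coefficient is log-FC of A over B
    groups = np.array([1] * pseudobulk_a.shape[1] + [0] * pseudobulk_b.shape[1])
    genes = pseudobulk_a.index.to_numpy()

    nonzero = counts.sum(axis=1) > 0
    sf = _size_factors(counts[nonzero])
    alpha = _dispersion_estimates(counts[nonzero], sf, groups)

    X = np.column_stack([np.ones(counts.shape[1]), groups.astype(float)])
    offset = np.log(sf)
    n_tested = int(nonzero.sum())
    beta = np.full(n_tested, np.nan)
    se = np.full(n_tested, np.nan)
    sub = counts[nonzero]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_tested):
            fam = sm.families.NegativeBinomial(alpha=float(alpha[i]))
            try:
                res = sm.GLM(sub[i], X, family=fam, offset=offset).fit(maxiter=100)
                beta[i], se[i] = res.params[1], res.bse[1]
            except Exception:  # non-convergence / separation stays NaN
                continue
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = beta / se
    p = np.where(np.isfinite(wald), 2.0 * st.norm.sf(np.abs(wald)), np.nan)
    p_adj = np.full(n_tested, np.nan)
    fin = np.isfinite(p)
    p_adj[fin] = benjamini_hochberg(p[fin])

    q = sub / sf
    out = pd.DataFrame({
        "gene_id": genes[nonzero],
        "base_mean": q.mean(axis=1),
        "log2_fc": beta / np.log(2),
        "wald": wald,
        "p": p,
        "p_adj": p_adj,
        "dispersion": alpha,
        "tested": True,
    })
    untested = pd.DataFrame({
        "gene_id": genes[~nonzero],
        "base_mean": 0.0, "log2_fc": np.nan, "wald": np.nan,
        "p": np.nan, "p_adj": np.nan, "dispersion": np.nan, "tested": False,
    })
    result = pd.concat([out, untested], ignore_index=True)
    result.attrs["samples_a"] = list(pseudobulk_a.columns)
    result.attrs["samples_b"] = list(pseudobulk_b.columns)
    return result
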