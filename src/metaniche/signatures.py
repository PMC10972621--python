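"""Gene-set signature scoring (plain average of normalized expression)."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .core import GeneSet, NormalizedMatrix
from .rank_stats import benjamini_hochberg, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = ["score_signature", "aggregate_scores_by_sample", "compare_signature"]


def score_signature(norm: NormalizedMatrix, gene_set: GeneSet) -> pd.DataFrame:
    """Per-cell signature score: unweighted mean normalized expression over
    the set members present in the matrix (resolved by symbol).

    Absent members are logged and reduce ``n_members_used``; an entirely
    absent set is an error naming the set.
    """
    rows, missing = norm.rows_for_symbols(gene_set.genes)
    if missing:
        logger.info("signature %s: %d member(s) absent from matrix: %s",
                    gene_set.name, len(missing), missing[:10])
    if rows.size == 0:
        raise KeyError(f"no member of gene set {gene_set.name!r} is present in the matrix")
    scores = norm.values[rows].mean(axis=0)
    return pd.DataFrame({
        "unit_id": norm.cell_ids,
        "score": scores,
        "n_members_used": rows.size,
    })


def aggregate_scores_by_sample(scores: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Mean per-cell score per sample: the per-sample scoring unit."""
    merged = scores.merge(cells[["cell_id", "sample_id"]],
                          left_on="unit_id", right_on="cell_id")
    agg = merged.groupby("sample_id", as_index=False)["score"].mean()
    agg = agg.rename(columns={"sample_id": "unit_id"})
    agg["n_members_used"] = scores["n_members_used"].iloc[0]
    return agg


def compare_signature(scores: pd.DataFrame, groups: pd.Series | dict,
                      comparisons: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Two-sided rank-sum comparison of signature scores between groups.

    ``groups`` maps unit id -> group label. ``comparisons`` lists the
    (group_a, group_b) pairs to test; by default every unordered pair of
    observed groups. P-values are BH-adjusted across the family when more
    than one comparison runs. Groups with fewer than 2 units are skipped
    with a warning.
    """
    g = pd.Series(groups)
    s = scores.set_index("unit_id")["score"]
    common = s.index.intersection(g.index)
    s, g = s.loc[common], g.loc[common]
    observed = sorted(g.dropna().unique())
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(observed)
                       for b in observed[i + 1:]]
    rows = []
    for a, b in comparisons:
        xa = s[g == a].to_numpy()
        xb = s[g == b].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"comparison {a} vs {b} skipped: a group has < 2 units")
            continue
        z, p = rank_sum_test(xa, xb)
        rows.append({
            "group_a": a, "group_b": b, "n_a": len(xa), "n_b": len(xb),
            "z": z, "p": p,
            "median_a": np.median(xa), "median_b": np.median(xb),
            "iqr_a": np.subtract(*np.percentile(xa, [75, 25])),
            "iqr_b": np.subtract(*np.percentile(xb, [75, 25])),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out
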