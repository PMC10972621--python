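"""Cell-level quality filtering and per-sample composition comparison.

QC keeps cells with at least 600 total UMIs and a doublet score of at most
0.4 (both thresholds configurable; the doublet score is an input, e.g. from
Scrublet). Composition compares per-sample cell-type proportions between
two condition arms with a two-sided Wilcoxon rank-sum test per cell type —
exact for the small per-arm sample counts typical of such cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import total_umis
from .rank_stats import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = ["filter_cells", "composition_test", "CompositionResult"]


def filter_cells(counts, cells: pd.DataFrame, min_umi: int = 600,
                 max_doublet: float = 0.4):
    """Drop cells with fewer than ``min_umi`` total UMIs or a doublet score
    above ``max_doublet``.

    Boundary semantics: a cell with exactly ``min_umi`` UMIs or exactly
    ``max_doublet`` doublet score is retained. Returns the filtered matrix
    and table plus a per-sample audit of removals per criterion.
    """
    if "doublet_score" not in cells.columns or cells["doublet_score"].isna().any():
        raise ValueError("every cell needs a doublet_score; refusing to treat "
                         "missing scores as passing")
    if "total_umis" in cells.columns and cells["total_umis"].notna().all():
        umis = cells["total_umis"].to_numpy()
    else:
        umis = total_umis(counts)
    scores = cells["doublet_score"].to_numpy(dtype=float)
    low_umi = umis < min_umi
    doublet = scores > max_doublet
    keep = ~(low_umi | doublet)

    audit = (pd.DataFrame({
        "sample_id": cells["sample_id"],
        "n_input": 1,
        "removed_low_umi": low_umi.astype(int),
        "removed_doublet": doublet.astype(int),
        "retained": keep.astype(int),
    }).groupby("sample_id", as_index=True).sum()
      if len(cells) else
      pd.DataFrame(columns=["n_input", "removed_low_umi", "removed_doublet",
                            "retained"]))

    idx = np.flatnonzero(keep)
    out_counts = counts[:, idx] if (sp.issparse(counts) or isinstance(counts, np.ndarray)) \
        else np.asarray(counts)[:, idx]
    out_cells = cells.iloc[idx].reset_index(drop=True).copy()
    out_cells["total_umis"] = umis[idx]
    return out_counts, out_cells, audit


@dataclass
class CompositionResult:
    """Per-sample cell-type proportions and per-type two-group rank tests."""

    proportions: pd.DataFrame   # samples x cell types, rows sum to 1
    tests: pd.DataFrame         # one row per cell type
    sample_cells: pd.DataFrame  # retained-cell counts per sample
    group_a: str
    group_b: str


def composition_test(cells: pd.DataFrame, group_a: str, group_b: str,
                     min_cells_per_sample: int = 40) -> CompositionResult:
    """Compare per-sample cell-type proportions between two condition arms.

    Samples with fewer than ``min_cells_per_sample`` cells are dropped
    first. For each cell type present in at least one sample, the two
    per-arm proportion vectors are compared with a two-sided Wilcoxon
    rank-sum test (exact when both arms have at most 10 samples and the
    proportions are tie-free; tie-corrected normal approximation
    otherwise).
    """
    sub = cells[cells["condition"].isin([group_a, group_b])]
    counts_per_sample = sub.groupby("sample_id").size()
    kept_samples = counts_per_sample[counts_per_sample >= min_cells_per_sample].index
    sub = sub[sub["sample_id"].isin(kept_samples)]
    if sub.empty:
        raise ValueError("no sample passes the minimum-cell rule")

    sample_cond = sub.groupby("sample_id")["condition"].first()
    for g in (group_a, group_b):
        if not (sample_cond == g).any():
            raise ValueError(f"no retained sample in group {g!r}")

    tab = pd.crosstab(sub["sample_id"], sub["cell_type"])
    empty_types = [t for t in tab.columns if tab[t].sum() == 0]
    if empty_types:
        warnings.warn(f"cell types absent from every sample excluded: {empty_types}")
        tab = tab.drop(columns=empty_types)
    props = tab.div(tab.sum(axis=1), axis=0)

    rows = []
    a_samples = sample_cond[sample_cond == group_a].index
    b_samples = sample_cond[sample_cond == group_b].index
    for ct in props.columns:
        a = props.loc[props.index.isin(a_samples), ct].to_numpy()
        b = props.loc[props.index.isin(b_samples), ct].to_numpy()
        z, p = rank_sum_test(a, b)
        rows.append({
            "cell_type": ct, "n_a": len(a), "n_b": len(b), "z": z, "p": p,
            "median_a": np.median(a), "median_b": np.median(b),
            "q1_a": np.percentile(a, 25), "q3_a": np.percentile(a, 75),
            "q1_b": np.percentile(b, 25), "q3_b": np.percentile(b, 75),
        })
    tests = pd.DataFrame(rows)
    sample_cells = counts_per_sample.rename("n_cells").to_frame()
    sample_cells["included"] = sample_cells.index.isin(kept_samples)
    return CompositionResult(proportions=props, tests=tests,
                             sample_cells=sample_cells.reset_index(),
                             group_a=group_a, group_b=group_b)
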