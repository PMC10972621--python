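"""Expression-based CNV profiling (simplified moving-average inference).

Evidence of chromosomal copy-number change is read out of log-normalized
expression: each gene is centered by its mean over a caller-supplied
reference population (e.g. immune cells), clipped at a few reference
standard deviations to tame outliers, smoothed by a moving average along
the chromosome-ordered gene index, and finally each cell's profile is
median-centered. Reference cells end up flat around zero; cells carrying a
gain (loss) show a coherent positive (negative) stretch over the segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NormalizedMatrix, order_genes_by_position

__all__ = ["infer_cnv", "CNVProfile", "segment_scores"]


@dataclass
class CNVProfile:
    """Smoothed reference-centered profile: cells x chromosome-ordered windows."""

    values: np.ndarray          # cells x windows
    cell_ids: pd.Index
    windows: pd.DataFrame       # window_id, chromosome, center gene, half-width used
    reference_cells: list[str]
    clip_sd: float
    window: int


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with symmetric shortened windows
    at the ends: position i averages ranks [i-k, i+k], k = min(h, i, n-1-i)."""
    n = x.shape[0]
    h = (window - 1) // 2
    cs = np.vstack([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    out = np.empty_like(x, dtype=float)
    for i in range(n):
        k = min(h, i, n - 1 - i)
        out[i] = (cs[i + k + 1] - cs[i - k]) / (2 * k + 1)
    return out


def infer_cnv(norm: NormalizedMatrix, genes: pd.DataFrame, reference_cells,
              window: int = 101, clip_sd: float = 3.0) -> CNVProfile:
    """Reference-centered, clipped, chromosome-wise smoothed expression profile.

    One window per retained gene position (centered moving average of odd
    length ``window``, shortened symmetrically at chromosome ends);
    chromosomes with fewer than 3 genes are excluded with a warning.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("reference cell list must be non-empty")
    ref_idx = norm.cell_ids.get_indexer(pd.Index(reference_cells))
    if (ref_idx < 0).any():
        raise KeyError("reference list contains unknown cell identifiers")

    ordered = order_genes_by_position(genes)
    sizes = ordered.groupby("chromosome").size()
    small = sizes[sizes < 3].index.tolist()
    if small:
        warnings.warn(f"chromosomes with < 3 genes excluded: {small}")
        ordered = ordered[~ordered["chromosome"].isin(small)]
    gene_rows = pd.Index(norm.gene_ids).get_indexer(ordered["gene_id"])
    present = gene_rows >= 0
    ordered = ordered[present].reset_index(drop=True)
    gene_rows = gene_rows[present]

    X = norm.values[gene_rows]                       # ordered genes x cells
    ref_mean = X[:, ref_idx].mean(axis=1)
    ref_sd = X[:, ref_idx].std(axis=1, ddof=1) if len(ref_idx) > 1 \
        else np.zeros(X.shape[0])
    centered = X - ref_mean[:, None]
    bound = clip_sd * ref_sd
    centered = np.clip(centered, -bound[:, None], bound[:, None])

    smoothed = np.empty_like(centered)
    win_rows = []
    for chrom, block in ordered.groupby("chromosome", sort=False):
        rows = block.index.to_numpy()
        smoothed[rows] = _moving_average(centered[rows], window)
        n = len(rows)
        h = (window - 1) // 2
        for j, r in enumerate(rows):
            win_rows.append((chrom, ordered.loc[r, "gene_id"],
                             min(h, j, n - 1 - j)))
    profile = smoothed.T                              # cells x windows
    profile = profile - np.median(profile, axis=1, keepdims=True)

    windows = pd.DataFrame(win_rows, columns=["chromosome", "center_gene", "half_width"])
    windows.insert(0, "window_id", np.arange(len(windows)))
    return CNVProfile(values=profile, cell_ids=norm.cell_ids, windows=windows,
                      reference_cells=reference_cells, clip_sd=clip_sd,
                      window=window)


def segment_scores(profile: CNVProfile, chromosome: str,
                   start_rank: int | None = None,
                   end_rank: int | None = None) -> pd.Series:
    """Per-cell mean profile value over the windows of one segment.

    Ranks are 0-based inclusive positions within the chromosome's window
    block; omitted bounds cover the whole chromosome. Used with a
    reference-derived threshold (e.g. mean ± 2 SD of the reference cells'
    segment scores) to call gains and losses per cell.
    """
    block = profile.windows[profile.windows["chromosome"] == chromosome]
    if block.empty:
        raise KeyError(f"no windows on chromosome {chromosome!r}")
    pos = np.arange(len(block))
    lo = 0 if start_rank is None else start_rank
    hi = len(block) - 1 if end_rank is None else end_rank
    sel = block.index.to_numpy()[(pos >= lo) & (pos <= hi)]
    return pd.Series(profile.values[:, sel].mean(axis=1),
                     index=profile.cell_ids, name=f"{chromosome}:{lo}-{hi}")
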