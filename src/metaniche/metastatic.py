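"""Metastatic tumor-cell signature derivation and score-based stratification.

The signature is the intersection of two Z-filtered marker comparisons:
genes upregulated in metastatic tumor cells versus primary tumor cells AND
versus non-malignant cells, each at a signed-Z cutoff (default 10). Bulk
cohorts are then stratified into high/low strata by the top and bottom
quantile (default 25%) of their per-patient signature score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneSet, NormalizedMatrix
from .rank_stats import wilcoxon_markers

__all__ = ["derive_signature", "stratify_by_score", "SignatureDerivation"]


@dataclass
class SignatureDerivation:
    """Provenance of a derived signature: both Z tables and per-gene passage."""

    vs_primary: pd.DataFrame       # metastatic tumor vs primary tumor marker table
    vs_normal: pd.DataFrame        # metastatic tumor vs non-malignant marker table
    z_cutoff: float
    provenance: pd.DataFrame       # gene_id, z in each comparison, pass flags
    signature: GeneSet | None      # None when the intersection is empty


def derive_signature(norm: NormalizedMatrix, cells: pd.DataFrame,
                     z_cutoff: float = 10.0, tumor_label: str = "tumor",
                     max_normal_fraction: float | None = None) -> SignatureDerivation:
    """Z-filtered two-comparison intersection defining the metastatic signature.

    Comparison A: metastatic tumor cells vs primary tumor cells. Comparison
    B: metastatic tumor cells vs all non-malignant cells. A gene enters the
    signature iff its signed Z exceeds ``z_cutoff`` in both. The optional
    ``max_normal_fraction`` additionally requires the gene expressed in
    fewer than that fraction of non-malignant cells (off by default).
    """
    is_tumor = (cells["cell_type"] == tumor_label).to_numpy()
    cond = cells["condition"].to_numpy()
    met_tumor = is_tumor & (cond == "metastatic")
    pri_tumor = is_tumor & (cond == "primary")
    normal = ~is_tumor
    for name, mask in (("metastatic tumor", met_tumor),
                       ("primary tumor", pri_tumor),
                       ("non-malignant", normal)):
        if mask.sum() < 2:
            raise ValueError(f"group {name!r} has fewer than 2 cells")

    ids = cells["cell_id"].to_numpy()
    sub_a = norm.subset_cells(np.asarray(met_tumor | pri_tumor))
    lab_a = np.where(met_tumor[met_tumor | pri_tumor], "met", "pri")
    vs_primary = wilcoxon_markers(sub_a, lab_a, "met")

    sub_b = norm.subset_cells(np.asarray(met_tumor | normal))
    lab_b = np.where(met_tumor[met_tumor | normal], "met", "normal")
    vs_normal = wilcoxon_markers(sub_b, lab_b, "met")

    prov = pd.DataFrame({
        "gene_id": vs_primary["gene_id"],
        "symbol": vs_primary["symbol"],
        "z_vs_primary": vs_primary["z"].to_numpy(),
        "z_vs_normal": vs_normal.set_index("gene_id").loc[
            vs_primary["gene_id"], "z"].to_numpy(),
        "frac_normal": vs_normal.set_index("gene_id").loc[
            vs_primary["gene_id"], "frac_out"].to_numpy(),
    })
    prov["pass_vs_primary"] = prov["z_vs_primary"] > z_cutoff
    prov["pass_vs_normal"] = prov["z_vs_normal"] > z_cutoff
    prov["in_signature"] = prov["pass_vs_primary"] & prov["pass_vs_normal"]
    if max_normal_fraction is not None:
        prov["in_signature"] &= prov["frac_normal"] < max_normal_fraction

    members = tuple(prov.loc[prov["in_signature"], "symbol"])
    if members:
        signature = GeneSet(name="metastatic_signature", genes=members,
                            description=f"Z > {z_cutoff} in both comparisons")
    else:
        warnings.warn("signature derivation produced an empty intersection")
        signature = None
    return SignatureDerivation(vs_primary=vs_primary, vs_normal=vs_normal,
                               z_cutoff=float(z_cutoff), provenance=prov,
                               signature=signature)


def stratify_by_score(scores: pd.Series | pd.DataFrame,
                      quantile: float = 0.25) -> pd.DataFrame:
    """Top/bottom-quantile stratification of patients by signature score.

    ``scores`` is a Series indexed by patient id (or a score_signature-style
    frame with unit_id/score columns). The bottom floor(q*n) patients form
    the low stratum, the top floor(q*n) the high stratum, the middle mass
    is excluded. Ties at a boundary break by stable patient-id order, the
    boundary patient staying with its stratum; an all-equal score vector is
    flagged with a warning but still stratified by that rule.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores.set_index("unit_id")["score"]
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 patients to stratify")
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must lie in (0, 0.5]")
    k = max(1, int(np.floor(quantile * n + 1e-9)))
    order = scores.reset_index()
    order.columns = ["patient_id", "score"]
    order = order.sort_values(["score", "patient_id"], kind="stable").reset_index(drop=True)
    stratum = np.array(["excluded"] * n, dtype=object)
    stratum[:k] = "low"
    stratum[n - k:] = "high"
    if scores.nunique() == 1:
        warnings.warn("all scores equal: stratification is degenerate "
                      "(assigned by stable patient-id order)")
    out = order.assign(stratum=stratum)
    out.attrs["quantile"] = quantile
    out.attrs["bounds"] = (float(order["score"].iloc[k - 1]),
                           float(order["score"].iloc[n - k]))
    return out
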