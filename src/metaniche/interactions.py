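"""Ligand-receptor interaction scoring with a shuffled-identity null.

A channel (pair, sender type, receiver type) is screened in when the ligand
is expressed in at least 10% of sender cells and the receptor in at least
10% of receiver cells. Its score is the product of the mean normalized
ligand expression over sender cells and the mean receptor expression over
receiver cells. Significance comes from globally shuffling cell-type labels
(one shuffle per permutation round, shared by every channel, preserving
type counts) and counting null scores at or above the observed one with an
add-one correction: p = (1 + #{null >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["screen_pairs", "score_pair", "permutation_test", "flag_exclusive_ligands"]


def _type_stats(values: np.ndarray, type_codes: np.ndarray, n_types: int):
    """Mean and expressed-fraction of each gene row per cell type."""
    sums = np.zeros((values.shape[0], n_types))
    fracs = np.zeros((values.shape[0], n_types))
    counts = np.bincount(type_codes, minlength=n_types).astype(float)
    for t in range(n_types):
        sel = type_codes == t
        if sel.any():
            sums[:, t] = values[:, sel].sum(axis=1)
            fracs[:, t] = (values[:, sel] > 0).mean(axis=1)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return means, fracs


def screen_pairs(norm: NormalizedMatrix, cells: pd.DataFrame, db: pd.DataFrame,
                 min_fraction: float = 0.10,
                 sender_types=None, receiver_types=None) -> pd.DataFrame:
    """Admissible (pair, sender, receiver) channels under the expressed-fraction screen.

    A channel passes iff the ligand has a positive normalized value in at
    least ``min_fraction`` of sender cells AND the receptor in at least
    ``min_fraction`` of receiver cells. Pairs whose genes are absent from
    the matrix are skipped with a log entry.
    """
    if cells["cell_type"].isna().any():
        raise ValueError("every cell needs a cell_type for interaction screening")
    types = sorted(cells["cell_type"].unique())
    type_codes = pd.Categorical(cells["cell_type"], categories=types).codes
    senders = types if sender_types is None else list(sender_types)
    receivers = types if receiver_types is None else list(receiver_types)

    symbols = pd.unique(pd.concat([db["ligand"], db["receptor"]]))
    rows, missing = norm.rows_for_symbols(symbols)
    present = {s: r for s, r in zip([s for s in symbols if s not in set(missing)], rows)}
    if missing:
        logger.info("LR screen: %d gene(s) absent from matrix, pairs skipped: %s",
                    len(missing), missing[:10])

    means, fracs = _type_stats(norm.values, np.asarray(type_codes), len(types))
    t_index = {t: i for i, t in enumerate(types)}
    out = []
    for _, rec in db.iterrows():
        if rec["ligand"] not in present or rec["receptor"] not in present:
            continue
        lrow, rrow = present[rec["ligand"]], present[rec["receptor"]]
        for s in senders:
            fl = fracs[lrow, t_index[s]]
            if fl < min_fraction:
                continue
            for r in receivers:
                fr = fracs[rrow, t_index[r]]
                if fr < min_fraction:
                    continue
                out.append({
                    "pair_id": rec["pair_id"], "ligand": rec["ligand"],
                    "receptor": rec["receptor"], "sender": s, "receiver": r,
                    "ligand_fraction": fl, "receptor_fraction": fr,
                    "score": means[lrow, t_index[s]] * means[rrow, t_index[r]],
                })
    return pd.DataFrame(out, columns=["pair_id", "ligand", "receptor", "sender",
                                      "receiver", "ligand_fraction",
                                      "receptor_fraction", "score"])


def score_pair(norm: NormalizedMatrix, cells: pd.DataFrame, ligand: str,
               receptor: str, sender: str, receiver: str) -> float:
    """Mean ligand expression over sender cells x mean receptor expression
    over receiver cells."""
    rows, missing = norm.rows_for_symbols([ligand, receptor])
    if missing:
        raise KeyError(f"gene(s) absent from matrix: {missing}")
    ct = cells["cell_type"].to_numpy()
    s_mask, r_mask = ct == sender, ct == receiver
    if not s_mask.any() or not r_mask.any():
        raise ValueError("sender and receiver types must both be non-empty")
    return float(norm.values[rows[0], s_mask].mean()
                 * norm.values[rows[1], r_mask].mean())


def _distinct_arrangements(codes: np.ndarray, limit: int = 200_000):
    """All distinct arrangements of the label multiset (tiny inputs only)."""
    from sympy.utilities.iterables import multiset_permutations
    out = []
    for arr in multiset_permutations(codes.tolist()):
        out.append(np.asarray(arr))
        if len(out) > limit:
            raise ValueError("too many distinct arrangements to enumerate")
    return out


def permutation_test(norm: NormalizedMatrix, cells: pd.DataFrame,
                     triples: pd.DataFrame, n_perm: int = 1000,
                     seed: int = 0, exhaustive: bool = False) -> pd.DataFrame:
    """Empirical p per admissible channel under globally shuffled identities.

    Each round draws ONE permutation of the cell-type labels (type counts
    preserved by construction) reused across every channel; p uses the
    add-one convention with ties counted against significance
    (``null >= observed``). With ``exhaustive=True`` every distinct label
    arrangement is evaluated exactly once instead of sampling (tiny inputs
    only) and ``n_perm`` is ignored.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if triples.empty:
        return triples.assign(p=pd.Series(dtype=float), n_perm=n_perm)
    types = sorted(cells["cell_type"].unique())
    t_index = {t: i for i, t in enumerate(types)}
    codes = np.asarray(pd.Categorical(cells["cell_type"], categories=types).codes)

    symbols = pd.unique(pd.concat([triples["ligand"], triples["receptor"]]))
    rows, missing = norm.rows_for_symbols(symbols)
    if missing:
        raise KeyError(f"triple gene(s) absent from matrix: {missing}")
    sub = norm.values[rows]                       # used genes x cells
    sub_row = {s: i for i, s in enumerate(symbols)}

    lig_rows = triples["ligand"].map(sub_row).to_numpy()
    rec_rows = triples["receptor"].map(sub_row).to_numpy()
    snd_cols = triples["sender"].map(t_index).to_numpy()
    rcv_cols = triples["receiver"].map(t_index).to_numpy()

    counts = np.bincount(codes, minlength=len(types)).astype(float)
    assert (counts[snd_cols] > 0).all() and (counts[rcv_cols] > 0).all()

    def channel_scores(perm_codes: np.ndarray) -> np.ndarray:
        onehot = np.zeros((norm.n_cells, len(types)))
        onehot[np.arange(norm.n_cells), perm_codes] = 1.0
        means = (sub @ onehot) / counts
        return means[lig_rows, snd_cols] * means[rec_rows, rcv_cols]

    observed = channel_scores(codes)
    exceed = np.zeros(len(triples))
    if exhaustive:
        arrangements = _distinct_arrangements(codes)
        n_perm = len(arrangements)
        for arr in arrangements:
            exceed += channel_scores(arr) >= observed
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            exceed += channel_scores(rng.permutation(codes)) >= observed
    out = triples.copy()
    out["score"] = observed
    out["p"] = (1.0 + exceed) / (1.0 + n_perm)
    out["n_perm"] = n_perm
    return out


def flag_exclusive_ligands(marker_results: pd.DataFrame, ligands,
                           z_cutoff: float = 3.0) -> pd.Series:
    """Flag each ligand exclusive iff its focal-type marker Z exceeds the cutoff.

    ``marker_results`` is a wilcoxon_markers table for the focal type (e.g.
    tumor cells). Ligands absent from the table flag False with a log entry.
    """
    z = marker_results.set_index("symbol")["z"]
    flags = {}
    for lig in ligands:
        if lig in z.index:
            flags[lig] = bool(z[lig] > z_cutoff)
        else:
            logger.info("ligand %s absent from marker table: flagged non-exclusive", lig)
            flags[lig] = False
    return pd.Series(flags, name="exclusive")
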