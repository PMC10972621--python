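"""Synthetic cohort generation with planted, recoverable structure.

The single-cell generator emulates the design of a two-arm bone-marrow
cohort (7 nonmetastatic + 8 metastatic samples by default, plus a small set
of primary-tumor samples): condition-shifted cell-type composition, tumor
cells present only in metastatic (and primary) samples, tumor-exclusive
genes upregulated only in metastatic tumor cells, multiplicative
chromosomal gain/loss segments in tumor cells, log-normal library sizes,
negative-binomial counts with a shared dispersion, and simulated doublets
with high doublet scores.

Every draw comes from a single ``numpy.random.default_rng`` stream, so a
config plus its seed reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import GeneSet, write_mtx_bundle

__all__ = [
    "SimConfig", "GroundTruth", "BulkGroundTruth",
    "generate_sc_cohort", "generate_bulk_cohort", "generate_lr_database",
    "write_cohort",
]


def _default_catalog(gene_ids: list[str], markers_per_type: int = 10,
                     marker_fold: float = 5.0):
    """Marker blocks at the start of the universe, one block per type."""
    names = ("tumor", "T", "myeloid", "B", "NK")
    catalog = []
    for i, name in enumerate(names):
        block = tuple(gene_ids[i * markers_per_type:(i + 1) * markers_per_type])
        catalog.append((name, block, marker_fold))
    return tuple(catalog)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic single-cell cohort.

    Defaults encode the study design this generator emulates: 7
    nonmetastatic + 8 metastatic bone-marrow samples plus 3 primary-tumor
    samples; 2,000 genes on 10 equal chromosomes; five cell types with
    10 marker genes each (fold 5); 30 metastatic-tumor-exclusive genes at
    fold 4; one full-chromosome gain (ratio 2) and one loss (ratio 0.5) in
    tumor cells; NB dispersion 0.3; log-normal library sizes with median
    ~2,000 UMIs; 5% doublets.
    """

    n_samples_per_condition: Mapping[str, int] | int = field(
        default_factory=lambda: {"nonmetastatic": 7, "metastatic": 8})
    n_primary_samples: int = 3
    cells_per_sample: tuple[int, int] = (150, 250)
    n_genes: int = 2000
    n_chromosomes: int = 10
    cell_type_catalog: tuple = None
    base_composition: Mapping[str, float] = field(
        default_factory=lambda: {"T": 8.0, "myeloid": 8.0, "B": 4.0, "NK": 4.0})
    composition_shift: Mapping[str, float] = field(
        default_factory=lambda: {"T": 0.7, "myeloid": 1.6, "B": 1.0, "NK": 0.8})
    tumor_fraction_metastatic: float = 0.35
    tumor_fraction_primary: float = 0.6
    planted_signature: tuple[str, ...] = None
    signature_fold: float = 4.0
    cnv_segments: tuple = None
    nb_dispersion: float = 0.3
    library_size_lognormal: tuple[float, float] = (7.6, 0.35)
    doublet_rate: float = 0.05
    seed: int = 0

    # -- derived structure ---------------------------------------------------

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def genes_per_chromosome(self) -> int:
        return self.n_genes // self.n_chromosomes

    def gene_table(self) -> pd.DataFrame:
        per = self.genes_per_chromosome()
        ids = self.gene_ids()
        chrom = [f"chr{i // per + 1}" if i // per < self.n_chromosomes
                 else f"chr{self.n_chromosomes}" for i in range(self.n_genes)]
        rank = []
        seen: dict[str, int] = {}
        for c in chrom:
            seen[c] = seen.get(c, 0) + 1
            rank.append(seen[c])
        return pd.DataFrame({
            "gene_id": ids,
            "symbol": ids,
            "chromosome": chrom,
            "start": [r * 1000 for r in rank],
            "chrom_rank": rank,
        })

    def resolved_catalog(self) -> tuple:
        if self.cell_type_catalog is not None:
            return tuple((n, tuple(m), float(f)) for n, m, f in self.cell_type_catalog)
        return _default_catalog(self.gene_ids())

    def resolved_signature(self) -> tuple[str, ...]:
        if self.planted_signature is not None:
            return tuple(self.planted_signature)
        per = self.genes_per_chromosome()
        if self.n_chromosomes >= 6 and per >= 30:
            start = 5 * per  # chr6 block, clear of marker blocks and CNV chromosomes
        else:
            start = max(0, self.n_genes - 30)
        return tuple(f"G{i:04d}" for i in range(start, min(start + 30, self.n_genes)))

    def resolved_segments(self) -> tuple:
        if self.cnv_segments is not None:
            return tuple((c, int(a), int(b), float(r)) for c, a, b, r in self.cnv_segments)
        per = self.genes_per_chromosome()
        if self.n_chromosomes >= 8:
            return (("chr3", 0, per - 1, 2.0), ("chr8", 0, per - 1, 0.5))
        return ()

    def samples(self) -> list[tuple[str, str]]:
        nsc = self.n_samples_per_condition
        if isinstance(nsc, int):
            nsc = {"nonmetastatic": nsc, "metastatic": nsc}
        out = [(f"NM{i + 1:02d}", "nonmetastatic") for i in range(nsc.get("nonmetastatic", 0))]
        out += [(f"MET{i + 1:02d}", "metastatic") for i in range(nsc.get("metastatic", 0))]
        out += [(f"PRI{i + 1:02d}", "primary") for i in range(self.n_primary_samples)]
        return out

    def validate(self) -> None:
        ids = set(self.gene_ids())
        if self.n_genes <= 0 or self.n_chromosomes <= 0:
            raise ValueError("n_genes and n_chromosomes must be positive")
        lo, hi = self.cells_per_sample
        if not (0 < lo <= hi):
            raise ValueError("cells_per_sample must be a positive (low, high) range")
        if not self.samples():
            raise ValueError("cohort has no samples")
        catalog = self.resolved_catalog()
        names = [n for n, _, _ in catalog]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names in catalog")
        for name, markers, fold in catalog:
            if not set(markers) <= ids:
                raise ValueError(f"markers of type {name!r} outside the gene universe")
            if fold <= 0:
                raise ValueError(f"marker fold of type {name!r} must be positive")
        nontumor = [n for n in names if n != "tumor"]
        for t in nontumor:
            conc = self.base_composition.get(t, 0.0)
            if not (np.isfinite(conc) and conc > 0):
                raise ValueError(
                    f"cell type {t!r} has non-positive composition concentration: "
                    "it would have zero expected cells in every sample")
            if self.composition_shift.get(t, 1.0) <= 0:
                raise ValueError(f"composition shift for {t!r} must be positive")
        for frac in (self.tumor_fraction_metastatic, self.tumor_fraction_primary):
            if not 0 <= frac <= 1:
                raise ValueError("tumor fractions must lie in [0, 1]")
        if not set(self.resolved_signature()) <= ids:
            raise ValueError("planted signature outside the gene universe")
        if self.signature_fold <= 0:
            raise ValueError("signature fold must be positive")
        per = self.genes_per_chromosome()
        gt = self.gene_table()
        sizes = gt.groupby("chromosome").size()
        for chrom, a, b, ratio in self.resolved_segments():
            if chrom not in sizes.index:
                raise ValueError(f"CNV segment on unknown chromosome {chrom!r}")
            if not (0 <= a <= b < sizes[chrom]):
                raise ValueError(f"CNV segment bounds [{a}, {b}] outside {chrom}")
            if ratio <= 0:
                raise ValueError("CNV copy ratio must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must lie in [0, 1)")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimConfig":
        """A no-effect cohort: type labels carry no expression signal.

        Marker folds are 1, no planted signature fold, no CNV segments, and
        no tumor cells unless a tumor fraction is passed explicitly (labels
        then exist but remain expression-free) — the exchangeable null for
        every downstream test.
        """
        overrides.setdefault("tumor_fraction_metastatic", 0.0)
        overrides.setdefault("tumor_fraction_primary", 0.0)
        base = cls(seed=seed, **overrides)
        catalog = tuple((n, m, 1.0) for n, m, _ in base.resolved_catalog())
        return replace(base, cell_type_catalog=catalog, signature_fold=1.0,
                       cnv_segments=())

    def to_json(self, path) -> None:
        d = asdict(self)
        d["cell_type_catalog"] = [list(x) for x in self.resolved_catalog()]
        d["planted_signature"] = list(self.resolved_signature())
        d["cnv_segments"] = [list(x) for x in self.resolved_segments()]
        Path(path).write_text(json.dumps(d, indent=2, default=str))


@dataclass
class GroundTruth:
    """Planted truth of a simulated single-cell cohort.

    ``cells`` records each cell's true type and doublet flag; ``genes``
    records every multiplicative effect actually applied (marker fold per
    type, metastatic-signature fold, CNV ratio); ``cnv_segments`` lists the
    planted segments (carried by every true tumor cell).
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    cnv_segments: pd.DataFrame
    config: SimConfig

    def de_genes(self, comparison: str) -> set[str]:
        """Genes whose applied fold differs between the two compared groups.

        Comparisons: ``met_tumor_vs_primary_tumor`` (only the planted
        metastatic signature differs) and ``met_tumor_vs_normal`` (tumor
        markers, other types' markers, signature genes and CNV genes all
        differ in applied fold).
        """
        g = self.genes
        if comparison == "met_tumor_vs_primary_tumor":
            return set(g.loc[g["signature_fold"] != 1.0, "gene_id"])
        if comparison == "met_tumor_vs_normal":
            mask = (
                (g["marker_of"].notna())
                | (g["signature_fold"] != 1.0)
                | (g["cnv_ratio"] != 1.0)
            )
            return set(g.loc[mask, "gene_id"])
        raise KeyError(f"unknown comparison {comparison!r}")

    @property
    def signature_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["signature_fold"] != 1.0, "gene_id"])

    @property
    def decoy_genes(self) -> set[str]:
        """Tumor markers: upregulated in BOTH tumor groups, so not metastatic-exclusive."""
        g = self.genes
        return set(g.loc[g["marker_of"] == "tumor", "gene_id"])


@dataclass
class BulkGroundTruth:
    """Latent per-patient signature burden driving the planted hazard."""

    patients: pd.DataFrame  # patient_id, burden
    hazard_ratio: float


def _expected_profiles(config: SimConfig, gene_table: pd.DataFrame,
                       baseline: np.ndarray):
    """Expected relative expression per (cell type, metastatic-tumor flag)."""
    ids = gene_table["gene_id"].to_numpy()
    idx = {g: i for i, g in enumerate(ids)}
    catalog = config.resolved_catalog()
    sig_rows = np.array([idx[g] for g in config.resolved_signature()], dtype=int)

    cnv_mult = np.ones(config.n_genes)
    for chrom, a, b, ratio in config.resolved_segments():
        rows = np.flatnonzero(
            (gene_table["chromosome"] == chrom).to_numpy()
            & (gene_table["chrom_rank"].to_numpy() - 1 >= a)
            & (gene_table["chrom_rank"].to_numpy() - 1 <= b))
        cnv_mult[rows] *= ratio

    profiles = {}
    for name, markers, fold in catalog:
        w = baseline.copy()
        rows = np.array([idx[g] for g in markers], dtype=int)
        if rows.size:
            w[rows] *= fold
        if name == "tumor":
            w = w * cnv_mult
            w_met = w.copy()
            if sig_rows.size:
                w_met[sig_rows] *= config.signature_fold
            profiles[("tumor", True)] = w_met
            profiles[("tumor", False)] = w
        else:
            profiles[(name, False)] = w
    return profiles, cnv_mult


def generate_sc_cohort(config: SimConfig):
    """Simulate the single-cell cohort.

    Returns ``(counts, cells, genes, truth)``: a genes x cells CSR count
    matrix, the cell table, the positional gene table and the
    :class:`GroundTruth`. Bit-reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_table = config.gene_table()
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    # marker and signature genes are detectably expressed by construction —
    # a curated marker or signature gene is never drawn from the dropout tail
    idx = {g: i for i, g in enumerate(gene_table["gene_id"])}
    planted_rows = sorted(
        {idx[g] for _, markers, fold in config.resolved_catalog() if fold != 1.0
         for g in markers}
        | ({idx[g] for g in config.resolved_signature()}
           if config.signature_fold != 1.0 else set()))
    if planted_rows:
        baseline[planted_rows] = rng.lognormal(mean=1.0, sigma=0.5,
                                               size=len(planted_rows))
    profiles, cnv_mult = _expected_profiles(config, gene_table, baseline)

    catalog = config.resolved_catalog()
    names = [n for n, _, _ in catalog]
    nontumor = [n for n in names if n != "tumor"]
    conc_base = np.array([config.base_composition[t] for t in nontumor])
    shift = np.array([config.composition_shift.get(t, 1.0) for t in nontumor])

    sample_rows = []
    lo, hi = config.cells_per_sample
    for sample_id, condition in config.samples():
        n_cells = int(rng.integers(lo, hi + 1))
        if condition == "metastatic":
            f_tumor = config.tumor_fraction_metastatic
            conc = conc_base * shift
        elif condition == "primary":
            f_tumor = config.tumor_fraction_primary
            conc = conc_base
        else:
            f_tumor = 0.0
            conc = conc_base
        props = rng.dirichlet(conc)
        p = np.concatenate([[f_tumor], (1 - f_tumor) * props])
        pool = ["tumor"] + nontumor
        types = rng.choice(pool, size=n_cells, p=p / p.sum())
        sample_rows.append((sample_id, condition, types))

    # expand to per-cell arrays
    cell_sample, cell_cond, cell_type = [], [], []
    for sample_id, condition, types in sample_rows:
        cell_sample += [sample_id] * len(types)
        cell_cond += [condition] * len(types)
        cell_type += list(types)
    n_total = len(cell_type)
    cell_sample = np.array(cell_sample)
    cell_cond = np.array(cell_cond)
    cell_type = np.array(cell_type)

    mu_log, sd_log = config.library_size_lognormal
    lib = rng.lognormal(mean=mu_log, sigma=sd_log, size=n_total)

    # per-cell expected profile (cells x genes), then NB via gamma-Poisson
    prof_keys = [(t, t == "tumor" and c == "metastatic")
                 for t, c in zip(cell_type, cell_cond)]
    key_list = sorted(set(prof_keys))
    key_index = {k: i for i, k in enumerate(key_list)}
    W = np.stack([profiles[k] / profiles[k].sum() for k in key_list])
    M = W[[key_index[k] for k in prof_keys]] * lib[:, None]
    disp = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / disp, scale=disp * M)
    counts = rng.poisson(lam).astype(np.int64)  # cells x genes

    # doublets: replace a random subset with binomial-thinned parent sums
    is_doublet = np.zeros(n_total, dtype=bool)
    n_doub = int(round(config.doublet_rate * n_total))
    if n_doub:
        doub_idx = rng.choice(n_total, size=n_doub, replace=False)
        is_doublet[doub_idx] = True
        for i in doub_idx:
            same = np.flatnonzero((cell_sample == cell_sample[i]) & ~is_doublet)
            if len(same) < 2:
                same = np.flatnonzero(~is_doublet)
            p1, p2 = rng.choice(same, size=2, replace=False)
            counts[i] = rng.binomial(counts[p1] + counts[p2], 0.5)
    doublet_score = np.where(
        is_doublet,
        rng.uniform(0.55, 0.95, size=n_total),
        rng.uniform(0.0, 0.25, size=n_total))

    counts_gc = sp.csr_matrix(counts.T)  # genes x cells
    cell_ids = np.array([f"{s}_C{i:04d}" for i, s in enumerate(cell_sample)])
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": cell_sample,
        "condition": cell_cond,
        "cell_type": cell_type,
        "doublet_score": doublet_score,
        "total_umis": counts.sum(axis=1),
    })

    sig = set(config.resolved_signature())
    marker_of = pd.Series(pd.NA, index=gene_table["gene_id"], dtype="object")
    marker_fold = pd.Series(1.0, index=gene_table["gene_id"])
    for name, markers, fold in catalog:
        if fold != 1.0:
            marker_of.loc[list(markers)] = name
            marker_fold.loc[list(markers)] = fold
    truth_genes = pd.DataFrame({
        "gene_id": gene_table["gene_id"],
        "marker_of": marker_of.to_numpy(),
        "marker_fold": marker_fold.to_numpy(),
        "signature_fold": [
            config.signature_fold if g in sig and config.signature_fold != 1.0 else 1.0
            for g in gene_table["gene_id"]],
        "cnv_ratio": cnv_mult,
    })
    truth = GroundTruth(
        cells=pd.DataFrame({"cell_id": cell_ids, "true_type": cell_type,
                            "is_doublet": is_doublet}),
        genes=truth_genes,
        cnv_segments=pd.DataFrame(
            [(c, a, b, r) for c, a, b, r in config.resolved_segments()],
            columns=["chromosome", "start_rank", "end_rank", "copy_ratio"]),
        config=config,
    )
    return counts_gc, cells, gene_table, truth


def generate_bulk_cohort(n_patients: int, signature: GeneSet, hazard_ratio: float,
                         seed: int, n_background: int = 200,
                         effect_size: float = 1.0, noise_sd: float = 0.5,
                         baseline_hazard: float = 0.08,
                         censor_horizon: float = 12.0):
    """Bulk expression cohort with survival driven by a latent signature burden.

    Each patient carries a standardized burden b ~ N(0, 1); signature genes
    read ``mu_g + effect_size * b + noise`` while background genes carry no
    burden signal. Event times are exponential with hazard
    ``baseline_hazard * hazard_ratio ** b``, censoring is uniform on
    (0, censor_horizon).
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if len(signature) == 0:
        raise ValueError("signature must be non-empty")
    rng = np.random.default_rng(seed)
    patients = [f"P{i + 1:04d}" for i in range(n_patients)]
    burden = rng.standard_normal(n_patients)

    sig_genes = list(signature.genes)
    bg_genes = [f"BG{i:04d}" for i in range(n_background)]
    all_genes = sig_genes + bg_genes
    mu = rng.normal(2.0, 0.5, size=len(all_genes))
    expr = mu[:, None] + rng.normal(0.0, noise_sd, size=(len(all_genes), n_patients))
    expr[:len(sig_genes)] += effect_size * burden[None, :]
    bulk = pd.DataFrame(expr, index=pd.Index(all_genes, name="gene"),
                        columns=patients)

    hazard = baseline_hazard * hazard_ratio ** burden
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, censor_horizon, size=n_patients)
    surv = pd.DataFrame({
        "patient_id": patients,
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
    })
    truth = BulkGroundTruth(
        patients=pd.DataFrame({"patient_id": patients, "burden": burden}),
        hazard_ratio=float(hazard_ratio))
    return bulk, surv, truth


def generate_lr_database(n_pairs: int, gene_universe, seed: int) -> pd.DataFrame:
    """Random unique (ligand, receptor) pairs drawn from the gene universe."""
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if isinstance(gene_universe, pd.DataFrame):
        universe = gene_universe.get("symbol", gene_universe["gene_id"]).tolist()
    else:
        universe = list(gene_universe)
    if len(set(universe)) < 2 * n_pairs:
        raise ValueError(
            f"gene universe of {len(set(universe))} cannot host {n_pairs} disjoint pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(sorted(set(universe)))[:2 * n_pairs]
    return pd.DataFrame({
        "pair_id": [f"LR{i:04d}" for i in range(n_pairs)],
        "ligand": chosen[0::2],
        "receptor": chosen[1::2],
    })


def write_cohort(outdir, counts, cells, genes, truth: GroundTruth) -> dict:
    """Write the triplet bundle plus ground-truth tables and the config JSON."""
    outdir = Path(outdir)
    paths = write_mtx_bundle(outdir, counts, genes, cells)
    truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.cnv_segments.to_csv(outdir / "truth_cnv_segments.tsv", sep="\t", index=False)
    truth.config.to_json(outdir / "sim_config.json")
    paths.update({
        "truth_cells": outdir / "truth_cells.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_cnv_segments": outdir / "truth_cnv_segments.tsv",
        "config": outdir / "sim_config.json",
    })
    return paths
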