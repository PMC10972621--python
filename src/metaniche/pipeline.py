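"""End-to-end orchestration of the analysis stages.

``PipelineConfig`` carries every stage threshold, defaulting to the study's
stated values (600-UMI and 0.4-doublet QC, 10-cell mini-bulk rule, 40-cell
sample rule, marker Z 3, signature Z 10, 10% ligand-receptor screen, 1,000
permutations, top/bottom-25% survival strata). ``run_pipeline`` executes the
enabled stages in dependency order on a simulated or loaded cohort and
writes one tab-delimited table per result plus a manifest with content
digests, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, qc, rank_stats, signatures, cnv, metastatic, survival as surv_mod
from . import interactions as lr
from .simulate import SimConfig, generate_sc_cohort, generate_bulk_cohort, \
    generate_lr_database, write_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "composition", "markers", "de", "cnv",
              "signature", "score", "survival", "interactions")


@dataclass
class PipelineConfig:
    """Resolved run configuration; numeric defaults are the study's values."""

    input_dir: str | None = None          # triplet bundle; None -> simulate
    output_dir: str = "metaniche_out"
    stages: tuple[str, ...] = ALL_STAGES
    min_umi: int = 600
    max_doublet: float = 0.4
    min_cells: int = 10                   # mini-bulk inclusion rule
    subset_min_cells: int = 40            # per-sample rule in composition subsets
    marker_z: float = 3.0
    signature_z: float = 10.0
    lr_fraction: float = 0.10
    n_perm: int = 1000
    quantile: float = 0.25
    normalize_scale: float = 1e4
    de_cell_type: str = "T"
    cnv_window: int = 101
    cnv_clip_sd: float = 3.0
    n_bulk_patients: int = 200
    bulk_hazard_ratio: float = 3.0
    n_lr_pairs: int = 100
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run manifest (also written).

    Stage dependencies are enforced by name: a stage whose upstream input is
    unavailable raises a dependency error naming the stage. Disabling QC
    while running downstream stages proceeds on unfiltered cells with a
    logged warning.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "resolved_config.json")
    manifest: dict = {"stages": {}, "config": dataclasses.asdict(config),
                      "versions": _versions()}
    outputs: dict[str, Path] = {}
    stages = set(config.stages)

    def record(stage: str, files: dict[str, Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(p) for k, p in files.items()},
            "sha256": {k: _digest(p) for k, p in files.items()},
            "seconds": round(time.perf_counter() - t0, 3),
        }
        outputs.update(files)

    # --- input -------------------------------------------------------------
    t0 = time.perf_counter()
    if config.input_dir is not None:
        d = Path(config.input_dir)
        counts, genes, cells = core.read_mtx_bundle(
            d / "matrix.mtx", d / "genes.tsv", d / "cells.tsv")
        truth = None
    else:
        if "simulate" not in stages:
            raise ValueError("stage 'simulate' disabled but no input_dir given")
        counts, cells, genes, truth = generate_sc_cohort(SimConfig(seed=config.seed))
        paths = write_cohort(out / "cohort", counts, cells, genes, truth)
        record("simulate", paths, t0)

    # --- qc ------------------------------------------------------------------
    if "qc" in stages:
        t0 = time.perf_counter()
        counts, cells, audit = qc.filter_cells(counts, cells, config.min_umi,
                                               config.max_doublet)
        record("qc", {"qc_audit": _write(audit.reset_index(), out / "qc_audit.tsv")}, t0)
    else:
        logger.warning("QC disabled: downstream stages run on unfiltered cells")

    norm = core.normalize(counts, genes, cells, scale=config.normalize_scale)
    bm = cells["condition"].isin(["metastatic", "nonmetastatic"]).to_numpy()

    # --- composition ---------------------------------------------------------
    if "composition" in stages:
        t0 = time.perf_counter()
        comp = qc.composition_test(cells, "metastatic", "nonmetastatic",
                                   min_cells_per_sample=config.subset_min_cells)
        record("composition", {
            "composition_tests": _write(comp.tests, out / "composition_tests.tsv"),
            "composition_proportions": _write(
                comp.proportions.reset_index(), out / "composition_proportions.tsv"),
        }, t0)

    # --- markers ---------------------------------------------------------------
    marker_tables: dict[str, pd.DataFrame] = {}
    if "markers" in stages:
        t0 = time.perf_counter()
        files = {}
        for ct in sorted(cells["cell_type"].dropna().unique()):
            if (cells["cell_type"] == ct).sum() < 2:
                continue
            tab = rank_stats.wilcoxon_markers(norm, cells["cell_type"].to_numpy(), ct)
            tab["is_marker"] = tab["z"] > config.marker_z
            marker_tables[ct] = tab
            files[f"markers_{ct}"] = _write(tab, out / f"markers_{ct}.tsv")
        record("markers", files, t0)

    # --- pseudobulk DE ----------------------------------------------------------
    if "de" in stages:
        t0 = time.perf_counter()
        ct = config.de_cell_type
        pb = {}
        for cond in ("metastatic", "nonmetastatic"):
            sel = np.flatnonzero((cells["condition"] == cond).to_numpy())
            pb[cond], _ = rank_stats.make_pseudobulk(
                counts[:, sel], cells.iloc[sel].reset_index(drop=True),
                ct, config.min_cells)
            pb[cond].index = pd.Index(genes["gene_id"])
        pb_a, pb_b = pb["metastatic"], pb["nonmetastatic"]
        de = rank_stats.pseudobulk_de(pb_a, pb_b)
        record("de", {"pseudobulk_de": _write(de, out / f"de_{ct}_met_vs_nonmet.tsv")}, t0)

    # --- CNV ---------------------------------------------------------------------
    if "cnv" in stages:
        t0 = time.perf_counter()
        ref_ids = cells.loc[bm & (cells["cell_type"] != "tumor"), "cell_id"].tolist()
        if not ref_ids:
            raise ValueError("stage 'cnv' has no non-tumor reference cells")
        profile = cnv.infer_cnv(norm, genes, ref_ids, window=config.cnv_window,
                                clip_sd=config.cnv_clip_sd)
        prof_df = pd.DataFrame(profile.values, index=profile.cell_ids,
                               columns=profile.windows["window_id"])
        record("cnv", {
            "cnv_profile": _write(prof_df.reset_index(names="cell_id"),
                                  out / "cnv_profile.tsv"),
            "cnv_windows": _write(profile.windows, out / "cnv_windows.tsv"),
        }, t0)

    # --- metastatic signature -------------------------------------------------------
    derivation = None
    if "signature" in stages:
        t0 = time.perf_counter()
        if not (cells["condition"] == "primary").any():
            raise ValueError("stage 'signature' requires primary-tumor cells")
        derivation = metastatic.derive_signature(norm, cells,
                                                 z_cutoff=config.signature_z)
        files = {"signature_provenance": _write(derivation.provenance,
                                                out / "signature_provenance.tsv")}
        if derivation.signature is not None:
            core.write_gmt(out / "metastatic_signature.gmt", [derivation.signature])
            files["signature_gmt"] = out / "metastatic_signature.gmt"
        record("signature", files, t0)

    # --- signature scoring ------------------------------------------------------------
    if "score" in stages:
        t0 = time.perf_counter()
        if derivation is None or derivation.signature is None:
            raise ValueError("stage 'score' requires a derived signature "
                             "(enable 'signature' or provide one)")
        sc = signatures.score_signature(norm, derivation.signature)
        groups = pd.Series(
            np.where(cells["cell_type"] == "tumor",
                     "tumor_" + cells["condition"], "non_malignant"),
            index=cells["cell_id"])
        comp = signatures.compare_signature(sc, groups)
        record("score", {
            "signature_scores": _write(sc, out / "signature_scores.tsv"),
            "signature_comparisons": _write(comp, out / "signature_comparisons.tsv"),
        }, t0)

    # --- bulk survival ---------------------------------------------------------------
    if "survival" in stages:
        t0 = time.perf_counter()
        if derivation is None or derivation.signature is None:
            raise ValueError("stage 'survival' requires a derived signature")
        bulk, surv, _ = generate_bulk_cohort(
            config.n_bulk_patients, derivation.signature,
            config.bulk_hazard_ratio, seed=config.seed + 1)
        members = [g for g in derivation.signature.genes if g in bulk.index]
        scores = bulk.loc[members].mean(axis=0)
        scores.index.name = "patient_id"
        strat = metastatic.stratify_by_score(scores, quantile=config.quantile)
        surv = surv.merge(strat[["patient_id", "stratum"]], on="patient_id")
        tested = surv[surv["stratum"].isin(["high", "low"])]
        stat, p = surv_mod.logrank_test(tested, "high", "low")
        km_high = surv_mod.km_estimate(tested, "high").table.assign(stratum="high")
        km_low = surv_mod.km_estimate(tested, "low").table.assign(stratum="low")
        summary = pd.DataFrame([{"statistic": stat, "p": p,
                                 "n_high": (strat["stratum"] == "high").sum(),
                                 "n_low": (strat["stratum"] == "low").sum()}])
        record("survival", {
            "survival_strata": _write(strat, out / "survival_strata.tsv"),
            "km_curves": _write(pd.concat([km_high, km_low]), out / "km_curves.tsv"),
            "logrank": _write(summary, out / "logrank.tsv"),
        }, t0)

    # --- ligand-receptor interactions ---------------------------------------------------
    if "interactions" in stages:
        t0 = time.perf_counter()
        db = generate_lr_database(config.n_lr_pairs, genes, seed=config.seed + 2)
        norm_bm = norm.subset_cells(bm)
        cells_bm = cells.loc[bm].reset_index(drop=True)
        triples = lr.screen_pairs(norm_bm, cells_bm, db,
                                  min_fraction=config.lr_fraction)
        res = lr.permutation_test(norm_bm, cells_bm, triples,
                                  n_perm=config.n_perm, seed=config.seed + 3)
        if "tumor" in marker_tables:
            flags = lr.flag_exclusive_ligands(marker_tables["tumor"],
                                              res["ligand"].unique(),
                                              z_cutoff=config.marker_z)
            res["ligand_exclusive"] = res["ligand"].map(flags)
        record("interactions", {
            "lr_database": _write(db, out / "lr_database.tsv"),
            "lr_results": _write(res, out / "lr_results.tsv"),
        }, t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _versions() -> dict:
    import scipy
    import statsmodels
    from . import __version__
    return {"metaniche": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__}
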