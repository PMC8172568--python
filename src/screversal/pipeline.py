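"""End-to-end orchestration: simulate/load -> QC -> normalize -> HVG -> PCA
-> SNN -> cluster -> assign types -> per-type DE contrasts -> reversal
statistics -> top reversed genes -> ORA -> signature scores -> consistency /
replication checks.

Every stage draws its randomness from a seed derived deterministically from
the master seed and the stage name, so a rerun with the same configuration
is byte-identical and single stages can be reproduced in isolation. A run
manifest (configuration echo, library versions, per-stage cell/gene counts)
is written alongside the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from .cluster import assign_cell_types, build_snn, cluster_modularity, pca_embed
from .config import PipelineConfig
from .enrichment import enrich_collection
from .hurdle import DEG_TABLE_SCHEMA, ContrastSpec, run_de_contrast
from .io import (
    CountMatrix,
    GeneSetCollection,
    read_gmt,
    read_mtx_bundle,
    read_table,
    write_gmt,
    write_mtx_bundle,
    write_table,
)
from .preprocess import compute_cell_qc, filter_cells, filter_genes, lognormalize, select_hvg
from .reversal import (
    pairwise_consistency,
    replication_check,
    reversal_statistics,
    select_top_reversed,
    union_significant,
)
from .signatures import compare_groups, module_score
from .simulate import simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_seed", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _float_fmt(x):
    return float(x) if np.isfinite(x) else None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of in-memory results.

    All outputs are also written under ``config.outdir``. Any stage failure
    raises :class:`PipelineError` naming the stage, after writing a
    partial-output marker file.
    """
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config": config.manifest_dict(),
        "versions": _versions(),
        "stages": {},
    }
    results: dict = {}
    stage = "init"
    try:
        # ---- stage: data -------------------------------------------------
        stage = "data"
        truth = None
        if config.simulation is not None:
            sim_cfg = config.simulation
            counts, meta, truth = simulate_dataset(sim_cfg)
            sim_dir = os.path.join(out, "sim")
            write_mtx_bundle(counts, sim_dir)
            write_table(meta, os.path.join(sim_dir, "metadata.tsv"))
            write_table(truth.to_frame(), os.path.join(sim_dir, "truth.tsv"))
            marker_gmt, signature_gmt = _truth_gene_sets(truth, sim_dir)
        else:
            paths = config.input
            counts = read_mtx_bundle(paths["matrix"], paths["genes"], paths["barcodes"])
            meta = read_table(
                paths["metadata"], {"barcode": str, "sample": str, "group": str}
            )
            marker_gmt = signature_gmt = None
        if list(meta["barcode"]) != list(counts.barcodes):
            raise ValueError("metadata barcodes do not match matrix barcodes")
        manifest["stages"]["data"] = {
            "n_genes": counts.n_genes,
            "n_cells": counts.n_cells,
            "groups": sorted(meta["group"].unique()),
        }

        # ---- stage: qc ---------------------------------------------------
        stage = "qc"
        gene_mask = filter_genes(counts, config.qc.min_cells_per_gene)
        counts = counts.subset(gene_mask=gene_mask)
        qc_stats = compute_cell_qc(counts, mito_prefix=config.mito_prefix)
        cell_mask = filter_cells(qc_stats, config.qc)
        write_table(qc_stats, os.path.join(out, "cell_qc.tsv"))
        counts = counts.subset(cell_mask=cell_mask)
        meta = meta.loc[cell_mask].reset_index(drop=True)
        manifest["stages"]["qc"] = {
            "genes_retained": int(gene_mask.sum()),
            "cells_retained": int(cell_mask.sum()),
        }

        # ---- stage: normalize / hvg -------------------------------------
        stage = "normalize"
        norm = lognormalize(counts)
        n_hvg = min(config.n_hvg, counts.n_genes)
        hvg = select_hvg(counts, n_hvg=n_hvg)
        manifest["stages"]["normalize"] = {"n_hvg": len(hvg)}

        # ---- stage: cluster ---------------------------------------------
        stage = "cluster"
        n_pcs = min(config.n_pcs, len(hvg) - 1, counts.n_cells - 1)
        emb = pca_embed(norm, hvg, n_pcs=n_pcs)
        graph = build_snn(emb, k=config.snn_k, prune=config.snn_prune)
        labels = cluster_modularity(
            graph, resolution=config.resolution, seed=stage_seed(config.seed, "cluster")
        )
        manifest["stages"]["cluster"] = {"n_clusters": labels.n_clusters}

        # ---- stage: assign types ----------------------------------------
        stage = "assign_types"
        marker_path = config.marker_gmt or marker_gmt
        if marker_path is None:
            raise ValueError("no marker GMT available (set marker_gmt)")
        marker_sets = read_gmt(marker_path)
        assignment, excluded, score_table = assign_cell_types(
            norm, labels, marker_sets, z_threshold=config.z_threshold
        )
        assigned_type = np.array(
            [assignment.get(int(c), "") for c in labels.labels], dtype=object
        )
        meta = meta.assign(cluster=labels.labels, assigned_type=assigned_type)
        if "cell_type" in meta.columns:
            meta = meta.rename(columns={"cell_type": "cell_type_true"})
        meta = meta.rename(columns={"assigned_type": "cell_type"})
        write_table(meta, os.path.join(out, "cell_annotations.tsv"))
        write_table(score_table, os.path.join(out, "cluster_marker_scores.tsv"))
        manifest["stages"]["assign_types"] = {
            "assignment": {str(k): v for k, v in assignment.items()},
            "excluded_clusters": {str(k): v for k, v in excluded.items()},
        }

        # ---- stage: de ---------------------------------------------------
        stage = "de"
        keep = meta["cell_type"] != ""
        meta_de = meta.loc[keep].reset_index(drop=True)
        norm_de = norm.subset_cells(keep.to_numpy())
        cell_types = sorted(meta_de["cell_type"].unique())
        has_vehicle = "vehicle" in set(meta_de["group"])
        contrast_defs = {"aging": ("aged", "young"), "treatment": ("treated", "aged")}
        if has_vehicle:
            contrast_defs["replicate"] = ("treated", "vehicle")
        de_dir = os.path.join(out, "de")
        os.makedirs(de_dir, exist_ok=True)
        deg: dict = {}
        for ct in cell_types:
            deg[ct] = {}
            for cname, (ga, gb) in contrast_defs.items():
                grp = meta_de.loc[meta_de["cell_type"] == ct, "group"]
                if not ({ga, gb} <= set(grp)):
                    logger.warning("cell type %s: missing group for %s contrast", ct, cname)
                    continue
                spec = ContrastSpec(
                    cell_type=ct,
                    group_A=ga,
                    group_B=gb,
                    covariates=config.de_covariates,
                    min_detection_fraction=config.min_detection_fraction,
                    min_abs_lnfc_prefilter=config.min_abs_lnfc_prefilter,
                    alpha=config.alpha,
                )
                table = run_de_contrast(norm_de, meta_de, spec)
                deg[ct][cname] = table
                write_table(
                    table, os.path.join(de_dir, f"{ct}_{cname}.tsv"), DEG_TABLE_SCHEMA
                )
        results["deg"] = deg
        manifest["stages"]["de"] = {
            ct: {
                c: {
                    "n_tested": len(t),
                    "n_significant": int((t["q_value"] < config.alpha).sum()),
                }
                for c, t in d.items()
            }
            for ct, d in deg.items()
        }

        # ---- stage: reversal --------------------------------------------
        stage = "reversal"
        rev_dir = os.path.join(out, "reversal")
        os.makedirs(rev_dir, exist_ok=True)
        reversal: dict = {}
        top_reversed: dict = {}
        for ct in cell_types:
            tables = deg.get(ct, {})
            if "aging" not in tables or "treatment" not in tables:
                continue
            try:
                genes = union_significant(
                    tables["aging"], tables["treatment"], alpha=config.alpha
                )
            except ValueError as exc:
                logger.warning("cell type %s: %s", ct, exc)
                continue
            res = reversal_statistics(tables["aging"], tables["treatment"], genes)
            reversal[ct] = res
            summary, gene_table = res.to_frames()
            write_table(summary, os.path.join(rev_dir, f"{ct}_summary.tsv"))
            write_table(gene_table, os.path.join(rev_dir, f"{ct}_genes.tsv"))
            top = select_top_reversed(
                tables["aging"],
                tables["treatment"],
                rank_limit=config.rank_limit,
                alpha=config.alpha,
            )
            top_reversed[ct] = top
            write_table(
                pd.DataFrame({"gene": top}), os.path.join(rev_dir, f"{ct}_top_reversed.tsv")
            )
        results["reversal"] = reversal
        results["top_reversed"] = top_reversed
        manifest["stages"]["reversal"] = {
            ct: {
                "n_union": r.n_union,
                "prop_reversed": r.prop_reversed,
                "slope": _float_fmt(r.slope),
                "r2": _float_fmt(r.r2),
                "n_top_reversed": len(top_reversed.get(ct, [])),
            }
            for ct, r in reversal.items()
        }

        # ---- stage: enrichment ------------------------------------------
        stage = "enrichment"
        if config.enrich_gmt:
            collection = read_gmt(config.enrich_gmt)
            enr_dir = os.path.join(out, "enrichment")
            os.makedirs(enr_dir, exist_ok=True)
            enrich: dict = {}
            for ct, top in top_reversed.items():
                if not top:
                    continue
                universe = sorted(
                    set(deg[ct]["aging"]["gene"]) & set(deg[ct]["treatment"]["gene"])
                )
                table = enrich_collection(top, collection, universe, alpha=config.alpha)
                enrich[ct] = table
                write_table(table, os.path.join(enr_dir, f"{ct}.tsv"))
            results["enrichment"] = enrich
            manifest["stages"]["enrichment"] = {
                ct: int(t["significant"].sum()) for ct, t in enrich.items()
            }

        # ---- stage: signature scores ------------------------------------
        stage = "signatures"
        sig_path = config.signature_gmt or signature_gmt
        if sig_path is not None:
            sig_sets = read_gmt(sig_path)
            sig_name = sig_sets.names()[0]
            score_ct = config.score_cell_type
            if score_ct is None:
                score_ct = _default_score_type(truth, cell_types)
            if score_ct in cell_types:
                mask = (meta_de["cell_type"] == score_ct).to_numpy()
                sub = norm_de.subset_cells(mask)
                sv = module_score(
                    sub,
                    sig_sets.genes(sig_name),
                    nbins=min(config.nbins, max(2, sub.n_genes // 2)),
                    nctrl=config.nctrl,
                    seed=stage_seed(config.seed, "signatures"),
                    name=sig_name,
                )
                groups = meta_de.loc[mask, "group"].to_numpy()
                comp = compare_groups(sv.scores, groups)
                results["signature_scores"] = sv
                results["signature_comparison"] = comp
                write_table(sv.to_frame(groups), os.path.join(out, "signature_scores.tsv"))
                with open(os.path.join(out, "signature_comparison.json"), "w") as fh:
                    json.dump(
                        {
                            "H": comp.H,
                            "df": comp.df,
                            "p_omnibus": comp.p_omnibus,
                            "group_medians": comp.group_medians,
                            "pairwise": comp.pairwise.to_dict(orient="records"),
                        },
                        fh,
                        indent=2,
                        sort_keys=True,
                    )
                manifest["stages"]["signatures"] = {
                    "cell_type": score_ct,
                    "p_omnibus": comp.p_omnibus,
                    "group_medians": comp.group_medians,
                }
            else:
                logger.warning("score cell type %r not among assigned types", score_ct)

        # ---- stage: consistency / replication ---------------------------
        stage = "consistency"
        aging_tables = {
            ct: t["aging"] for ct, t in deg.items() if "aging" in t and len(t["aging"])
        }
        if len(aging_tables) >= 2:
            cons = pairwise_consistency(aging_tables, alpha=config.alpha)
            results["consistency"] = cons
            write_table(cons, os.path.join(out, "consistency_aging.tsv"))
        if has_vehicle:
            rep_rows = []
            for ct, top in top_reversed.items():
                if not top or "replicate" not in deg.get(ct, {}):
                    continue
                try:
                    table, agree = replication_check(
                        top, deg[ct]["replicate"], deg[ct]["aging"]
                    )
                except ValueError as exc:
                    logger.warning("replication %s: %s", ct, exc)
                    continue
                table.insert(0, "cell_type", ct)
                rep_rows.append((table, agree))
            if rep_rows:
                rep_table = pd.concat([t for t, _ in rep_rows], ignore_index=True)
                write_table(rep_table, os.path.join(out, "replication.tsv"))
                manifest["stages"]["replication"] = {
                    t["cell_type"].iloc[0]: a for t, a in rep_rows
                }
                results["replication"] = rep_rows
    except Exception as exc:
        with open(os.path.join(out, "PARTIAL_OUTPUT"), "w") as fh:
            fh.write(f"pipeline aborted at stage {stage!r}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results


def _versions() -> dict:
    import igraph
    import scipy
    import sklearn
    import statsmodels

    return {
        "screversal": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
        "igraph": igraph.__version__,
    }


def _truth_gene_sets(truth, sim_dir):
    """Write marker + signature GMTs derived from the simulation truth."""
    marker_sets = {}
    for k, ct in enumerate(truth.cell_types):
        genes = [str(g) for g in truth.gene_ids[truth.is_marker[:, k]]]
        if genes:
            marker_sets[ct] = (f"planted markers of {ct}", genes)
    marker_path = os.path.join(sim_dir, "markers.gmt")
    write_gmt(GeneSetCollection(sets=marker_sets), marker_path)

    sig_genes = [str(g) for g in truth.gene_ids[truth.is_signature]]
    sig_path = None
    if sig_genes:
        sig_path = os.path.join(sim_dir, "signature.gmt")
        write_gmt(
            GeneSetCollection(
                sets={"disease_signature": ("planted disease-associated signature", sig_genes)}
            ),
            sig_path,
        )
    return marker_path, sig_path


def _default_score_type(truth, cell_types):
    if truth is not None:
        ct = truth.cell_types[truth.config.signature_cell_type]
        if ct in cell_types:
            return ct
    return cell_types[0] if cell_types else None
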