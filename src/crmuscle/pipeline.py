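"""End-to-end orchestration from a single YAML config.

Stages: preprocess -> per-gene LMM -> rank metric -> Monte-Carlo consensus
GSEA -> pathway scores -> delta mediation search, plus the transcript
branch (filter -> DTE/DTU on two quantifications -> intersection -> biotype
tally).  A JSON manifest records every threshold actually applied, the
seeds, and the row counts at each stage; re-running the same config
reproduces all outputs byte-identically.
"""
from __future__ import annotations

import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd

from . import io, lmm, mediation, preprocess, splicing
from .gsea import gsea_consensus
from .simulate import STRENGTH_VARS
from .types import DesignSpec

log = logging.getLogger("crmuscle")

DEFAULTS = {
    "dge_alpha": 0.05, "focus_alpha": 0.01, "cpm_prior": 1.0,
    "filter_scope": "subgroup",
    "gsea": {"alpha": 0.05, "freq_threshold": 0.8, "n_iter": 50, "nperm": 500,
             "min_size": 10, "max_size": 500},
    "mediation": {"k_max": 2, "threshold": 20.0},
    "splice_alpha": 0.01, "run_splice": True, "seed": 0,
}


def _merged(config: dict) -> dict:
    cfg = {**DEFAULTS, **(config or {})}
    for key in ("gsea", "mediation"):
        cfg[key] = {**DEFAULTS[key], **(config.get(key, {}) if config else {})}
    for a in ("dge_alpha", "focus_alpha", "splice_alpha"):
        if not 0 < cfg[a] < 1:
            raise ValueError(f"{a} must be in (0,1)")
    return cfg


def run_all(inputs: dict, config: dict | None = None,
            outdir: str | Path | None = None) -> dict:
    """Run every stage on an in-memory input bundle.

    ``inputs`` carries counts, meta, annotation, gene_sets, tpm_a/tpm_b,
    gene_map and phenotypes (the bundle ``simulate_dataset`` produces, or
    the same pieces loaded from disk via :func:`load_inputs`).  Returns the
    result bundle and writes TSV/JSON artifacts plus the manifest when
    ``outdir`` is given.
    """
    cfg = _merged(config)
    manifest: dict = {"parameters": cfg, "package_version": _pkg_version("crmuscle"),
                      "stages": {}}
    meta = inputs["meta"]

    log.info("preprocess: %d genes in", len(inputs["counts"]))
    counts = preprocess.filter_protein_coding(inputs["counts"], inputs["annotation"])
    counts = preprocess.filter_low_expression(counts, meta, scope=cfg["filter_scope"])
    factors = preprocess.tmm_factors(counts)
    expr = preprocess.log2_cpm(counts, factors, prior=cfg["cpm_prior"])
    manifest["stages"]["preprocess"] = {"genes_in": int(len(inputs["counts"])),
                                        "genes_out": int(len(expr))}

    dge = lmm.run_dge(expr, meta, DesignSpec())
    summary = lmm.significance_summary(dge, (cfg["dge_alpha"], cfg["focus_alpha"]))
    manifest["stages"]["dge"] = {"rows": int(len(dge)),
                                 "summary": summary.to_dict("records")}

    ranked = lmm.rank_genes(dge)
    g = cfg["gsea"]
    consensus = gsea_consensus(ranked, {"synthetic": inputs["gene_sets"]},
                               n_iter=g["n_iter"], alpha=g["alpha"],
                               freq_threshold=g["freq_threshold"],
                               nperm=g["nperm"], seed=cfg["seed"],
                               min_size=g["min_size"], max_size=g["max_size"])
    reported = consensus[consensus["reported"]]
    manifest["stages"]["gsea"] = {"pathways_tested": int(len(consensus)),
                                  "pathways_reported": int(len(reported))}

    results = {"expr": expr, "factors": factors, "dge": dge, "ranked": ranked,
               "consensus": consensus}

    if len(reported):
        leading = {r["pathway"]: r["leading_edge"] for _, r in reported.iterrows()}
        scores = mediation.pathway_scores(expr, leading)
        sample_meta = meta.set_index("sample_id")
        tidy = scores.copy()
        tidy["subject_id"] = sample_meta.loc[tidy.index, "subject_id"].to_numpy()
        tidy["visit"] = sample_meta.loc[tidy.index, "visit"].to_numpy()
        pheno = inputs["phenotypes"].copy()
        for v in STRENGTH_VARS:
            pheno[v] = (pheno[f"{v}_left"] + pheno[f"{v}_right"]) / 2.0
        merged = pheno.merge(tidy, on=["subject_id", "visit"], how="inner")
        value_cols = ["leg_lean_mass", *STRENGTH_VARS, *scores.columns]
        deltas = mediation.delta_scores(merged, value_cols)
        med = {}
        m = cfg["mediation"]
        for var in STRENGTH_VARS:
            med[var] = mediation.mediation_search(
                deltas, list(scores.columns), var,
                k_max=m["k_max"], threshold=m["threshold"])
        results["pathway_scores"] = scores
        results["mediation"] = med
        manifest["stages"]["mediation"] = {
            "pathways": int(scores.shape[1]), "subjects": int(len(deltas)),
            "flagged": {v: int(len(med[v]["records"])) for v in med}}

    if cfg["run_splice"]:
        gm = inputs["gene_map"]
        fa = splicing.filter_transcripts(inputs["tpm_a"], meta, gm)
        fb = splicing.filter_transcripts(inputs["tpm_b"], meta, gm)
        dte_a, dte_b = splicing.run_dte(fa, meta), splicing.run_dte(fb, meta)
        dtu_a = splicing.run_dtu(fa, meta, gm)
        dtu_b = splicing.run_dtu(fb, meta, gm)
        sets = splicing.shared_variant_sets(dte_a, dte_b, dtu_a, dtu_b,
                                            alpha=cfg["splice_alpha"])
        bio = splicing.classify_biotypes(sorted(sets["union"]), gm, dge,
                                         alpha=cfg["dge_alpha"]) \
            if sets["union"] else {"tally": {}}
        results["splice"] = {"dte_a": dte_a, "dte_b": dte_b, "dtu_a": dtu_a,
                             "dtu_b": dtu_b, "sets": sets, "biotypes": bio}
        manifest["stages"]["splice"] = {
            "transcripts_a": int(len(fa)), "transcripts_b": int(len(fb)),
            "shared_dte": len(sets["dte"]), "shared_dtu": len(sets["dtu"]),
            "shared_union": len(sets["union"]), "shared_both": len(sets["both"]),
            "biotype_tally": {k: int(v) for k, v in bio["tally"].items()}}

    results["manifest"] = manifest
    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_matrix(results["expr"], outdir / "log2cpm.tsv", "gene_id")
    io.write_table(results["dge"], outdir / "dge_results.tsv")
    cons = results["consensus"].copy()
    if len(cons):
        cons["leading_edge"] = [",".join(le) for le in cons["leading_edge"]]
    io.write_table(cons, outdir / "gsea_consensus.tsv")
    if "mediation" in results:
        recs = [m["records"] for m in results["mediation"].values()
                if len(m["records"])]
        table = pd.concat(recs, ignore_index=True) if recs else \
            next(iter(results["mediation"].values()))["records"]
        io.write_table(table, outdir / "mediation_records.tsv")
    if "splice" in results:
        for key in ("dte_a", "dte_b", "dtu_a", "dtu_b"):
            io.write_table(results["splice"][key], outdir / f"splice_{key}.tsv")
        io.write_json({k: sorted(v) for k, v in results["splice"]["sets"].items()},
                      outdir / "splice_shared_variants.json")
    io.write_json(results["manifest"], outdir / "manifest.json")


def load_inputs(paths: dict) -> dict:
    """Load an input bundle from the fixture files ``write_fixtures`` emits."""
    return {
        "counts": io.read_matrix(paths["counts"]),
        "meta": io.read_table(paths["meta"]),
        "annotation": io.read_table(paths["annotation"]),
        "gene_sets": io.read_gmt(paths["gene_sets"]),
        "tpm_a": io.read_matrix(paths["tpm_a"]),
        "tpm_b": io.read_matrix(paths["tpm_b"]),
        "gene_map": io.read_table(paths["gene_map"]),
        "phenotypes": io.read_table(paths["phenotypes"]),
    }
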