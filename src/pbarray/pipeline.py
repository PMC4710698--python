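"""End-to-end orchestration of the analysis stages.

Each stage is a file-to-file function (read TSV inputs, compute, write TSV
/JSON outputs); :func:`run_all` simply chains them, so running the stages
separately on the intermediate files produces byte-identical outputs to a
single ``run_all`` call.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .concordance import concordance_by_tissue
from .config import PipelineConfig
from .containers import SPECIES, TISSUES
from .crosscompare import (
    candidate_accounting,
    candidate_table,
    tissue_overlap,
    venn_partition,
)
from .enrichment import class_map_from_annotation, enrichment_table
from .errors import DataError, PbArrayError
from .io import (
    read_annotation,
    read_matrix,
    read_qpcr,
    read_table,
    write_json,
    write_matrix,
    write_table,
)
from .preprocess import (
    background_filter,
    de_test,
    median_center_probes,
    quartile_normalize,
    summarize_regulated,
)

log = logging.getLogger(__name__)


def stage_normalize(matrix_path, samples_path, out_matrix, out_samples,
                    mode: str = "upper_quartile") -> None:
    """Between-array quartile normalization (intensity scale preserved)."""
    m = read_matrix(matrix_path, samples_path)
    m = quartile_normalize(m, mode=mode)
    write_matrix(m, out_matrix, out_samples)
    log.info("normalize: %d probes x %d samples -> %s", m.n_probes, m.n_samples, out_matrix)


def stage_de(matrix_path, samples_path, annotation_path, out_path,
             background: float = 50.0, fdr_threshold: float = 0.1,
             log_base: float = 2.0) -> pd.DataFrame:
    """Background filter, per-probe median centering, then t-test/BH per
    species x tissue; one combined DE table.

    The background-retention rule runs on the between-array-normalized
    intensity scale (the floor is in intensity units); the per-probe median
    centering that follows rescales each probe by a constant, which cancels
    in both the t statistic and the fold-change ratio.
    """
    m = read_matrix(matrix_path, samples_path)
    ann = read_annotation(annotation_path)
    probe_to_gene = dict(zip(ann["probe_id"], ann["gene_id"]))
    centered = median_center_probes(m)
    tables = []
    for species in SPECIES:
        for tissue in TISSUES:
            if not m.sample_ids(species=species, tissue=tissue):
                continue
            retained = background_filter(m, background, species, tissue)
            de = de_test(
                centered, species, tissue,
                probes=retained, probe_to_gene=probe_to_gene,
                fdr_threshold=fdr_threshold, log_base=log_base,
            )
            log.info(
                "de: %s/%s %d probes retained, %d genes tested, %d regulated",
                species, tissue, len(retained), len(de), int(de["regulated"].sum()),
            )
            tables.append(de)
    combined = pd.concat(tables, ignore_index=True)
    write_table(combined, out_path)
    return combined


def _split_de(de: pd.DataFrame) -> dict:
    return {
        (sp, ti): sub.reset_index(drop=True)
        for (sp, ti), sub in de.groupby(["species", "tissue"], sort=True)
    }


def shared_universe(de_tol: pd.DataFrame, de_sen: pd.DataFrame):
    """Restrict both DE tables to genes tested in both species (the Venn universe)."""
    common = set(de_tol["gene_id"]) & set(de_sen["gene_id"])
    f = lambda de: de[de["gene_id"].isin(common)].reset_index(drop=True)
    return f(de_tol), f(de_sen)


def stage_compare(de_path, outdir, fc_hi=2.0, fc_lo=0.5, ratio_hi=2.0, ratio_lo=0.5) -> dict:
    """Venn partition + candidate cascade per tissue; writes venn.json,
    accounting.tsv, candidates.tsv, overlap.json."""
    outdir = Path(outdir)
    de = read_table(de_path)
    by_scope = _split_de(de)
    selections = {}
    venns = {}
    accounting = []
    candidates = []
    for tissue in TISSUES:
        key_t, key_s = ("tolerant", tissue), ("sensitive", tissue)
        if key_t not in by_scope or key_s not in by_scope:
            continue
        de_tol, de_sen = shared_universe(by_scope[key_t], by_scope[key_s])
        vp = venn_partition(de_tol, de_sen, tissue)
        sel = candidate_accounting(vp, de_tol, de_sen, fc_hi, fc_lo, ratio_hi, ratio_lo)
        venns[tissue] = vp.summary()
        accounting.append(sel.accounting())
        candidates.append(candidate_table(sel, de_tol, de_sen))
        selections[tissue] = sel
        log.info("compare: %s %d candidates (%d up / %d down)",
                 tissue, len(sel.candidates), sel.candidate_up, sel.candidate_down)
    write_json(venns, outdir / "venn.json")
    write_table(pd.concat(accounting, ignore_index=True), outdir / "accounting.tsv")
    write_table(pd.concat(candidates, ignore_index=True), outdir / "candidates.tsv")
    overlap = (
        sorted(tissue_overlap(selections["roots"], selections["shoots"]))
        if {"roots", "shoots"} <= set(selections)
        else []
    )
    write_json({"n_overlap": len(overlap), "genes": overlap}, outdir / "overlap.json")
    return selections


def stage_enrich(candidates_path, annotation_path, out_path,
                 B: int = 100, seed: int = 0, alpha: float = 0.05,
                 small_class_min: int = 5, bh_correct: bool = False) -> pd.DataFrame:
    """Normed-frequency enrichment of the candidate lists against the array annotation.

    One enrichment block per tissue x direction (up / down / all); the
    reference set is every classified gene on the array.
    """
    cand = read_table(candidates_path)
    ann = read_annotation(annotation_path)
    cmap = class_map_from_annotation(ann)
    reference = sorted(set(ann["gene_id"]))
    blocks = []
    if len(cand):
        for tissue, sub in cand.groupby("tissue", sort=True):
            groups = [("all", sub)]
            groups += [(d, s) for d, s in sub.groupby("direction", sort=True)]
            for direction, rows in groups:
                tbl = enrichment_table(
                    rows["gene_id"], cmap, reference,
                    B=B, seed=seed, alpha=alpha,
                    small_class_min=small_class_min, bh_correct=bh_correct,
                )
                tbl.insert(0, "direction", direction)
                tbl.insert(0, "tissue", tissue)
                blocks.append(tbl)
    if blocks:
        out = pd.concat(blocks, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["tissue", "direction", "class_label"])
    write_table(out, out_path)
    return out


def stage_concord(qpcr_path, out_path) -> pd.DataFrame:
    pairs = read_qpcr(qpcr_path)
    out = concordance_by_tissue(pairs)
    write_table(out, out_path)
    return out


def run_all(config: PipelineConfig) -> dict:
    """Execute preprocess -> crosscompare -> enrichment -> concordance.

    Reads the inputs named in ``config``, writes every stage artifact plus
    a run manifest under ``config.outdir``, and returns the in-memory
    result bundle.  Any stage error propagates with its stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not (config.matrix and config.samples and config.annotation):
        raise DataError("run_all requires matrix, samples and annotation paths")

    results: dict = {}
    counts: dict = {}
    stage = "normalize"
    try:
        norm_matrix = outdir / "normalized_matrix.tsv"
        norm_samples = outdir / "normalized_samples.tsv"
        stage_normalize(config.matrix, config.samples, norm_matrix, norm_samples,
                        mode=config.normalization_mode)

        stage = "de"
        de_path = outdir / "de.tsv"
        de = stage_de(norm_matrix, norm_samples, config.annotation, de_path,
                      background=config.background, fdr_threshold=config.fdr_threshold,
                      log_base=config.log_base)
        results["de"] = de
        counts["de_rows"] = len(de)
        summary = summarize_regulated(_split_de(de))
        write_table(summary, outdir / "regulated_summary.tsv")
        results["regulated_summary"] = summary

        stage = "compare"
        selections = stage_compare(de_path, outdir,
                                   fc_hi=config.fc_hi, fc_lo=config.fc_lo,
                                   ratio_hi=config.ratio_hi, ratio_lo=config.ratio_lo)
        results["selections"] = selections
        counts["candidates"] = {t: len(s.candidates) for t, s in selections.items()}

        stage = "enrich"
        enr = stage_enrich(outdir / "candidates.tsv", config.annotation,
                           outdir / "enrichment.tsv",
                           B=config.bootstrap_B, seed=config.seed, alpha=config.alpha,
                           small_class_min=config.small_class_min)
        results["enrichment"] = enr
        counts["enrichment_rows"] = len(enr)

        if config.qpcr:
            stage = "concord"
            conc = stage_concord(config.qpcr, outdir / "concordance.tsv")
            results["concordance"] = conc
            counts["concordance_rows"] = len(conc)
    except PbArrayError as e:
        raise type(e)(f"[stage: {stage}] {e}") from e

    import numpy, scipy, statsmodels

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "pbarray": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "row_counts": counts,
    }
    write_json(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    return results
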