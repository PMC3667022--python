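"""End-to-end orchestration: simulate -> count -> rpkm -> dge -> enrich -> ssr -> orf.

Each stage writes a headered TSV under the configured output directory
and the run ends with a JSON manifest recording the seed, the full
parameter set, per-stage row counts and a sha256 checksum per output
file. Reruns with the same configuration reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from denovotx import counting, dge, enrichment, expression, ssr, coding, synthetic
from denovotx.io import RunConfig, read_fasta, write_fasta, write_tsv, read_tsv

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_term_map(path) -> enrichment.TermMap:
    df = read_tsv(path)
    members: dict[str, set] = {}
    cats: dict[str, str] = {}
    for _, row in df.iterrows():
        members.setdefault(row["term_id"], set()).add(row["unigene_id"])
        if "category" in df.columns:
            cats[row["term_id"]] = row["category"]
    return enrichment.TermMap(members, categories=cats)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for path_attr in ("unigenes_fasta", "counts1_tsv", "counts2_tsv", "term_map_tsv"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured input {path_attr}={p} does not exist")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.to_dict(), "stages": {}}

    def record(stage: str, path: Path, n_rows: int):
        manifest["stages"][stage] = {
            "path": str(path),
            "n_rows": n_rows,
            "sha256": _sha256(path),
        }

    # --- simulate (or load) ---------------------------------------------
    truth = None
    term_map = None
    if config.unigenes_fasta:
        unigenes = read_fasta(config.unigenes_fasta)
        lengths = {u: len(s) for u, s in unigenes.items()}
    else:
        spec = synthetic.SyntheticSpec(
            n_unigenes=config.n_unigenes,
            library_sizes=tuple(config.library_sizes),
            de_fraction=config.de_fraction,
            de_log2fc=config.de_log2fc,
            dispersion=config.dispersion,
            planted_orf_fraction=0.3,
            seed=config.seed,
        )
        unigenes, truth = synthetic.generate_unigenes(spec)
        lengths = truth.lengths
        fasta_path = outdir / "unigenes.fasta"
        write_fasta(unigenes, fasta_path)
        record("simulate", fasta_path, len(unigenes))
        term_map = synthetic.generate_annotation(spec, truth)

    # --- counts (mapped reads or direct simulation) ---------------------
    if config.counts1_tsv and config.counts2_tsv:
        c1 = read_tsv(config.counts1_tsv, index_col=0)["count"]
        c2 = read_tsv(config.counts2_tsv, index_col=0)["count"]
        counts = pd.DataFrame({"lib1": c1, "lib2": c2})
    elif config.mean_read_depth > 0 and truth is not None:
        index = counting.build_index(unigenes, k=config.k)
        cols = {}
        L = pd.Series(lengths)
        for j, lib in enumerate(("lib1", "lib2")):
            expr = truth.expression[f"expr{j + 1}"]
            weight = L * expr
            depth = (config.mean_read_depth * len(unigenes) * weight / weight.sum()).to_dict()
            reads = synthetic.generate_reads(
                unigenes, depth=depth, read_length=config.read_length,
                error_rate=0.005, seed=config.seed * 2 + j,
            )
            cols[lib], _ = counting.count_reads(
                [(r.read_id, r.sequence) for r in reads], index,
                max_mismatch=config.max_mismatch,
            )
        counts = pd.DataFrame(cols)
    else:
        if truth is None:
            raise ValueError(
                "external unigenes require counts1_tsv/counts2_tsv or mean_read_depth > 0"
            )
        counts = synthetic.generate_counts(spec, unigenes, truth)
    counts_path = outdir / "counts.tsv"
    write_tsv(counts, counts_path)
    record("count", counts_path, len(counts))

    # --- rpkm -------------------------------------------------------------
    rpkm_frames = {
        lib: expression.rpkm_table(counts[lib], lengths) for lib in ("lib1", "lib2")
    }
    rpkm_path = outdir / "rpkm.tsv"
    merged = pd.DataFrame(
        {
            "length": rpkm_frames["lib1"]["length"],
            "count1": rpkm_frames["lib1"]["count"],
            "rpkm1": rpkm_frames["lib1"]["rpkm"],
            "count2": rpkm_frames["lib2"]["count"],
            "rpkm2": rpkm_frames["lib2"]["rpkm"],
        }
    )
    write_tsv(merged, rpkm_path)
    record("rpkm", rpkm_path, len(merged))

    # --- dge --------------------------------------------------------------
    table, summary = dge.dge_table(
        counts["lib1"], counts["lib2"], lengths,
        fdr_cutoff=config.fdr_cutoff, lfc_cutoff=config.lfc_cutoff,
    )
    dge_path = outdir / "dge.tsv"
    write_tsv(table, dge_path)
    record("dge", dge_path, len(table))
    manifest["dge_summary"] = summary

    # --- enrichment --------------------------------------------------------
    if config.term_map_tsv:
        term_map = _load_term_map(config.term_map_tsv)
    if term_map is not None:
        de_set = set(table.index[table["direction"] != dge.NOT_SIG]) & term_map.background
        enr = enrichment.enrich(
            de_set, term_map, correction=config.correction, alpha=config.alpha
        )
        enr_path = outdir / "enrichment.tsv"
        write_tsv(enr, enr_path)
        record("enrich", enr_path, len(enr))

    # --- ssr ----------------------------------------------------------------
    loci = []
    for uid, seq in unigenes.items():
        loci.extend(
            ssr.detect_ssrs(seq, min_repeats=config.min_repeats,
                            k_range=tuple(config.ssr_k_range), unigene_id=uid)
        )
    loci_df = pd.DataFrame(
        [(l.unigene_id, l.start, l.end, l.unit, l.canonical, l.n_repeats) for l in loci],
        columns=["unigene_id", "start", "end", "unit", "canonical", "n_repeats"],
    )
    ssr_path = outdir / "ssr_loci.tsv"
    write_tsv(loci_df, ssr_path, index=False)
    record("ssr", ssr_path, len(loci_df))

    total_bp = sum(len(s) - s.count("N") for s in unigenes.values())
    summary_df = ssr.summarize_ssrs(loci, total_bp)
    ssr_sum_path = outdir / "ssr_summary.tsv"
    write_tsv(summary_df, ssr_sum_path)
    record("ssr_summary", ssr_sum_path, len(summary_df))

    cands = ssr.select_marker_loci(
        loci, unigenes, min_flank_bp=config.min_flank_bp,
        min_product_bp=config.min_product_bp,
    )
    cand_df = pd.DataFrame(
        [
            (c.locus.unigene_id, c.locus.start, c.locus.end, c.locus.unit,
             c.left_flank_bp, c.right_flank_bp, c.unique, c.flank_repeat_free, c.eligible)
            for c in cands
        ],
        columns=["unigene_id", "start", "end", "unit", "left_flank_bp",
                 "right_flank_bp", "unique", "flank_repeat_free", "eligible"],
    )
    cand_path = outdir / "ssr_markers.tsv"
    write_tsv(cand_df, cand_path, index=False)
    record("ssr_select", cand_path, len(cand_df))

    # --- orf ------------------------------------------------------------------
    rows = []
    for uid, seq in unigenes.items():
        is_coding, best, direction = coding.classify_coding(seq, min_cds_bp=config.min_cds_bp)
        rows.append(
            (uid, is_coding, direction,
             best.start if best else -1, best.end if best else -1,
             best.length if best else 0, best.frame if best else 0)
        )
    orf_df = pd.DataFrame(
        rows, columns=["unigene_id", "coding", "direction", "start", "end", "length", "frame"]
    )
    orf_path = outdir / "orf_calls.tsv"
    write_tsv(orf_df, orf_path, index=False)
    record("orf", orf_path, len(orf_df))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", manifest_path)
    return manifest
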