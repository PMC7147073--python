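"""End-to-end orchestration: simulate -> collapse -> AS -> expression/DE ->
lncRNA, with a single config, deterministic seeding and an output manifest.

A single global seed is fanned out to per-stage substreams by stable hashing
of stage names, so adding a stage never perturbs the randomness of earlier
stages.
"""

from __future__ import annotations

import contextlib
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from gonadiso import collapse as collapse_mod
from gonadiso import expression as expr_mod
from gonadiso import lncrna as lnc_mod
from gonadiso import splicing as splice_mod
from gonadiso import synthetic as syn_mod
from gonadiso.core_io import SampleDesign, TranscriptSet, write_event_table, write_fasta

log = logging.getLogger("gonadiso")


@dataclass
class RunConfig:
    """All pipeline thresholds, defaulting to the published values."""

    identity: float = 0.99
    as_min_len: int = 1000
    as_min_gap: int = 100
    as_flank: int = 100
    as_max_overlap: int = 5
    min_hsp_score: float = 50.0
    fpkm_threshold: float = 0.1
    fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    lncrna_min_len: int = 200
    orf_aa_threshold: int = 100
    bootstrap_reps: int = 100
    seed: int = 0
    # synthetic-run parameters
    n_families: int = 30
    length_range: tuple[int, int] = (1200, 3000)
    isoforms_per_parent: int = 1
    gap_range: tuple[int, int] = (120, 400)
    flank_min: int = 150
    duplicate_identity: float = 0.995
    nb_dispersion: float = 0.1

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("length_range", "gap_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2**31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextlib.contextmanager
def _stage(name: str):
    log.info("stage=%s", name)
    try:
        yield
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig, outdir: str | Path,
                 design: SampleDesign | None = None) -> dict:
    """Run the synthetic happy path end to end; returns the manifest.

    Stages execute in dependency order; identical config implies identical
    outputs.  Each output file is listed in the manifest together with the
    config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                "outputs": {}, "metrics": {}}

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    if design is None:
        design = syn_mod.default_design()

    with _stage("simulate"):
        parents, truth = syn_mod.generate_transcript_set(
            config.n_families, config.length_range,
            seed=stage_seed(config.seed, "simulate"))
        ts, truth = syn_mod.plant_isoforms(
            parents, truth, k_per_parent=config.isoforms_per_parent,
            gap_range=config.gap_range, flank_min=config.flank_min,
            seed=stage_seed(config.seed, "isoforms"))
        ts, truth = syn_mod.plant_duplicates(
            ts, truth, q=config.duplicate_identity,
            seed=stage_seed(config.seed, "duplicates"),
            threshold=config.identity)
        syn_mod.plant_effects(truth, list(truth.records),
                              seed=stage_seed(config.seed, "effects"))
        counts = syn_mod.simulate_counts(
            truth, design, nb_dispersion=config.nb_dispersion,
            seed=stage_seed(config.seed, "counts"))
        fasta = outdir / "transcripts.fasta"
        write_fasta(ts, fasta)
        emit("transcripts", fasta)
        counts_path = outdir / "counts.tsv"
        counts.write(counts_path)
        emit("counts", counts_path)
        truth_path = outdir / "truth.tsv"
        truth.to_frame().to_csv(truth_path, sep="\t", index=False)
        emit("truth", truth_path)
        design_path = outdir / "design.tsv"
        design.write(design_path)
        emit("design", design_path)

    with _stage("collapse"):
        clusters, collapsed = collapse_mod.cluster_collapse(ts, config.identity)
        cluster_path = outdir / "clusters.tsv"
        collapse_mod.write_cluster_table(clusters, cluster_path)
        emit("clusters", cluster_path)
        manifest["metrics"]["n_input"] = len(ts)
        manifest["metrics"]["n_collapsed"] = len(collapsed)

    with _stage("as-detect"):
        events, iso_counts = splice_mod.as_catalog(
            collapsed, min_len=config.as_min_len, min_gap=config.as_min_gap,
            flank=config.as_flank, max_overlap=config.as_max_overlap,
            min_hsp_score=config.min_hsp_score)
        events_path = outdir / "as_events.tsv"
        write_event_table(events, events_path)
        emit("as_events", events_path)
        hist = splice_mod.isoform_histogram(iso_counts)
        manifest["metrics"]["n_as_events"] = len(events)
        manifest["metrics"]["isoform_histogram"] = hist

    with _stage("expression"):
        lengths = ts.lengths().reindex(counts.transcript_ids)
        fpkm = expr_mod.compute_fpkm(counts, lengths)
        fpkm_path = outdir / "fpkm.tsv"
        fpkm.to_csv(fpkm_path, sep="\t")
        emit("fpkm", fpkm_path)
        categories = expr_mod.classify_expression(fpkm, design, config.fpkm_threshold)
        cat_path = outdir / "expression_categories.tsv"
        categories.summary().to_csv(cat_path, sep="\t", index=False)
        emit("expression_categories", cat_path)

    with _stage("de"):
        de_stats = expr_mod.nb_de_test(counts, design)
        de = expr_mod.de_classify(de_stats, categories, design,
                                  config.fc_threshold, config.fdr_threshold)
        de_path = outdir / "de_results.tsv"
        de.table.to_csv(de_path, sep="\t")
        emit("de_results", de_path)
        manifest["metrics"]["n_de"] = len(de.de_ids)

    with _stage("lncrna"):
        coding_ts, coding_truth = syn_mod.generate_coding_noncoding(
            50, seed=stage_seed(config.seed, "coding"))
        train = TranscriptSet(list(coding_ts)[:25] + list(coding_ts)[50:75],
                              provenance="synthetic")
        coding_train = TranscriptSet([t for t in train if coding_truth[t.id].coding],
                                     provenance="synthetic")
        noncoding_train = TranscriptSet([t for t in train if not coding_truth[t.id].coding],
                                        provenance="synthetic")
        tables = lnc_mod.train_hexamer_tables(coding_train, noncoding_train)
        reports = lnc_mod.lncrna_screen(coding_ts, tables,
                                        min_len=config.lncrna_min_len,
                                        orf_aa_threshold=config.orf_aa_threshold)
        lnc_path = outdir / "lncrna_report.tsv"
        pd.DataFrame([
            {"transcript": r.transcript_id, "length": r.length,
             "orf_aa": r.longest_orf.protein_length if r.longest_orf else 0,
             "orf_verdict": r.orf_verdict, "fickett": r.fickett,
             "fickett_verdict": r.fickett_verdict, "hexamer": r.hexamer,
             "hexamer_verdict": r.hexamer_verdict, "final": r.final}
            for r in reports
        ]).to_csv(lnc_path, sep="\t", index=False)
        emit("lncrna_report", lnc_path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    emit_path = str(manifest_path)
    manifest["outputs"]["manifest"] = emit_path
    return manifest
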