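"""End-to-end orchestration: config, stage ordering, outputs, summary.

The pipeline runs the dual-omics analysis in its natural order: TPM
quantification and protein-coding filtering, per-layer differential
expression between two conditions, translation efficiency and dual-omics
classes, then (when UTR sequences and a motif compendium are supplied)
3'-UTR motif enrichment of the high-TE genes against the other expressed
genes, and CPE/PAS annotation. Every output table carries a provenance
line (package version + config hash) and the run ends with a
machine-readable JSON summary of gene counts at each filter stage.

All coordinates in outputs are 0-based, half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (config_hash, read_annotation, read_counts, read_sample_sheet,
                 read_utr_fasta, write_table)
from .quantify import counts_to_tpm, expressed_genes, filter_protein_coding
from .diffexpr import nb_wald_test, call_degs
from .te_class import classify_dual_omics, class_counts, compute_te, high_te_genes
from .motifs import (enrich, load_motif_compendium, normalize_and_filter,
                     occurrence_table, scan_utrs)
from .cpe_pas import annotate_gene_set

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts_transcriptome: str
    counts_translatome: str
    sample_sheet: str
    annotation: str
    condition_a: str
    condition_b: str
    out_dir: str = "tnt_results"
    utr_fasta: str | None = None
    motif_file: str | None = None
    tpm_threshold: float = 1.0
    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    log2_te_threshold: float = 1.0
    motif_pvalue_threshold: float = 1e-4
    normalized_score_threshold: float = 0.8
    enrich_lfc_threshold: float = 1.0
    enrich_p_threshold: float = 1e-5
    cpe_window: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.tpm_threshold <= 0:
            raise ValueError("tpm_threshold must be > 0")
        for name in ("p_threshold", "motif_pvalue_threshold", "enrich_p_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.normalized_score_threshold <= 1:
            raise ValueError("normalized_score_threshold must be in [0, 1]")
        if self.cpe_window < 0:
            raise ValueError("cpe_window must be >= 0")
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _layer_condition_columns(sheet: pd.DataFrame, layer: str, stage: str) -> list[str]:
    sel = sheet[(sheet["layer"] == layer) & (sheet["stage"] == stage)]
    sel = sel.sort_values("replicate")
    if sel.empty:
        raise ValueError(f"no {layer} samples with stage {stage!r} in sample sheet")
    return list(sel["sample_id"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the summary dict (also written to disk)."""
    config.validate()
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash of the analysis parameters (output location excluded)
    chash = config_hash({k: v for k, v in config.to_dict().items()
                         if k != "out_dir"})
    provenance = f"tntseq {__version__} config_hash={chash}"
    summary: dict = {"version": __version__, "config_hash": chash,
                     "config": config.to_dict(), "stages": {}}

    def stage(name):
        log.info("stage %-16s %6.1fs", name, time.time() - t0)

    try:
        annotation = read_annotation(config.annotation)
        sheet = read_sample_sheet(config.sample_sheet)
        counts = {"transcriptome": read_counts(config.counts_transcriptome),
                  "translatome": read_counts(config.counts_translatome)}
    except Exception as exc:
        raise RuntimeError(f"[input] {exc}") from exc

    tpm, de, cols = {}, {}, {}
    for layer in ("transcriptome", "translatome"):
        try:
            stage(f"quantify/{layer}")
            pc = filter_protein_coding(counts[layer], annotation)
            tpm[layer] = counts_to_tpm(pc, annotation)
            cols[layer] = {c: _layer_condition_columns(sheet, layer, cond)
                           for c, cond in (("A", config.condition_a),
                                           ("B", config.condition_b))}
            summary["stages"][f"expressed_{layer}"] = len(
                expressed_genes(tpm[layer], config.tpm_threshold))
        except Exception as exc:
            raise RuntimeError(f"[quantify/{layer}] {exc}") from exc
        try:
            stage(f"de/{layer}")
            de[layer] = nb_wald_test(pc[cols[layer]["A"]], pc[cols[layer]["B"]],
                                     annotation, min_tpm=config.tpm_threshold)
            up, down = call_degs(de[layer], config.p_threshold, config.lfc_threshold)
            summary["stages"][f"degs_up_{layer}"] = len(up)
            summary["stages"][f"degs_down_{layer}"] = len(down)
            header = (f"{provenance}; log2FC > 0 means higher in "
                      f"{config.condition_b} than {config.condition_a}")
            write_table(de[layer], out / f"de_{layer}.tsv", header)
        except Exception as exc:
            raise RuntimeError(f"[diffexpr/{layer}] {exc}") from exc
        write_table(tpm[layer], out / f"tpm_{layer}.tsv", provenance)

    try:
        stage("te")
        profiles = {}
        for c, cond in (("A", config.condition_a), ("B", config.condition_b)):
            profiles[cond] = compute_te(
                tpm["transcriptome"][cols["transcriptome"][c]],
                tpm["translatome"][cols["translatome"][c]],
                condition=cond, min_tpm=config.tpm_threshold)
            write_table(profiles[cond], out / f"te_{cond}.tsv", provenance)
            summary["stages"][f"te_defined_{cond}"] = int(len(profiles[cond]))
            summary["stages"][f"high_te_{cond}"] = len(
                high_te_genes(profiles[cond], config.log2_te_threshold))
    except Exception as exc:
        raise RuntimeError(f"[te] {exc}") from exc

    try:
        stage("classify")
        classes = classify_dual_omics(de["transcriptome"], de["translatome"],
                                      config.p_threshold, config.lfc_threshold)
        write_table(classes, out / "classes.tsv", provenance)
        summary["stages"]["classes"] = {k: int(v)
                                        for k, v in class_counts(classes).items()}
    except Exception as exc:
        raise RuntimeError(f"[te_class] {exc}") from exc

    if config.utr_fasta is not None:
        try:
            stage("utr")
            utrs = read_utr_fasta(config.utr_fasta)
            cpepas = annotate_gene_set(utrs, window=config.cpe_window)
            write_table(cpepas, out / "cpe_pas.tsv", provenance)
            summary["stages"]["cpe_pas_paired"] = int(cpepas["paired"].sum())
        except Exception as exc:
            raise RuntimeError(f"[cpe_pas] {exc}") from exc

        if config.motif_file is not None:
            try:
                stage("motifs")
                pwms = load_motif_compendium(config.motif_file)
                hits = scan_utrs(utrs, pwms,
                                 pvalue_threshold=config.motif_pvalue_threshold)
                retained = normalize_and_filter(
                    hits, config.normalized_score_threshold)
                write_table(retained, out / "motif_hits.tsv", provenance,
                            index=False)
                target = high_te_genes(profiles[config.condition_b],
                                       config.log2_te_threshold)
                background = (set(profiles[config.condition_b].index) - target)
                lengths = {g: len(s) for g, s in utrs.items()}
                target &= set(lengths)
                background &= set(lengths)
                summary["stages"]["motif_target_genes"] = len(target)
                if len(target) >= 2 and len(background) >= 2:
                    occ = occurrence_table(retained, target | background, lengths)
                    enr = enrich(target, background, occ,
                                 lfc_threshold=config.enrich_lfc_threshold,
                                 p_threshold=config.enrich_p_threshold)
                    write_table(enr, out / "motif_enrichment.tsv", provenance)
                    summary["stages"]["enriched_rbps"] = int(enr["significant"].sum())
                else:
                    log.warning("too few target/background genes with UTRs; "
                                "skipping enrichment")
            except Exception as exc:
                raise RuntimeError(f"[motif_enrichment] {exc}") from exc

    log.info("pipeline finished in %.1fs", time.time() - t0)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    stage("done")
    return summary
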