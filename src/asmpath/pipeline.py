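"""End-to-end orchestration: ingest -> score -> weight -> enrich -> report.

``run_pipeline`` executes the stages in order, writes all artifact
tables plus a JSON manifest of configuration, input checksums and stage
counts, and removes partial outputs on failure.  Identical config and
inputs produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import asm_weighting, enrichment, gene_scoring, io_formats, postprocess
from .errors import AsmPathError, ConfigError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    assoc_path: str = ""
    genes_path: str = ""
    asm_path: str = ""
    gmt_path: str = ""
    go_gmt_path: Optional[str] = None
    out_dir: str = "asmpath_out"
    window_bp: int = 5_000
    cis_alpha: float = 0.05
    trans_alpha: float = 0.05
    snp_alpha: float = 0.05
    gene_stat: str = "adjusted"
    score_perms: int = 10_000
    pathway_perms: int = 5_000
    min_size: int = 10
    max_size: int = 380
    fdr_threshold: float = 0.01
    gene_fraction: float = 0.2
    weighting: str = "both"
    seed: int = 0

    def validate(self) -> None:
        for name in ("cis_alpha", "trans_alpha", "snp_alpha", "fdr_threshold", "gene_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.window_bp < 0:
            raise ConfigError("window_bp must be >= 0")
        if self.min_size > self.max_size:
            raise ConfigError("min_size must be <= max_size")
        if self.weighting not in ("on", "off", "both"):
            raise ConfigError("weighting must be 'on', 'off' or 'both'")
        if self.gene_stat not in ("adjusted", "raw_chisq"):
            raise ConfigError("gene_stat must be 'adjusted' or 'raw_chisq'")
        for name in ("score_perms", "pathway_perms"):
            if getattr(self, name) < 100:
                raise ConfigError(f"{name} must be >= 100")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(AsmPathError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run all stages and return the manifest dict.

    Artifacts written to ``config.out_dir``: gene_table.tsv, weights.tsv,
    results.tsv, go_terms.tsv (when a GO GMT is configured),
    gene_report.tsv, manifest.json.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    manifest: Dict[str, object] = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {},
        "counts": {},
    }
    counts = manifest["counts"]
    stage = "setup"
    try:
        stage = "ingest-assoc"
        stats = io_formats.ReadStats()
        snps = io_formats.read_assoc(config.assoc_path, stats=stats)
        manifest["inputs"]["assoc"] = _sha256(config.assoc_path)
        counts["snps_read"] = stats.n_read
        counts["snps_dropped_na"] = stats.n_dropped_na
        counts["snps_dropped_nonautosomal"] = stats.n_dropped_nonautosomal
        counts["snps_analyzed"] = len(snps)
        log.info("stage %s: %d SNPs analyzed (%d NA, %d non-autosomal dropped)",
                 stage, len(snps), stats.n_dropped_na, stats.n_dropped_nonautosomal)

        stage = "ingest-genes"
        genes = io_formats.read_gene_table(config.genes_path)
        manifest["inputs"]["genes"] = _sha256(config.genes_path)
        counts["genes_total"] = len(genes)
        log.info("stage %s: %d genes", stage, len(genes))

        stage = "ingest-asm"
        pairs = io_formats.read_asm_pairs(config.asm_path)
        pairs_f = io_formats.filter_asm_pairs(pairs, config.cis_alpha, config.trans_alpha)
        manifest["inputs"]["asm"] = _sha256(config.asm_path)
        counts["asm_pairs_read"] = len(pairs)
        counts["asm_pairs_filtered"] = len(pairs_f)
        log.info("stage %s: %d pairs read, %d pass the cis/trans filter",
                 stage, len(pairs), len(pairs_f))

        stage = "ingest-gmt"
        pathways = io_formats.read_gmt(config.gmt_path)
        manifest["inputs"]["gmt"] = _sha256(config.gmt_path)
        counts["pathways_parsed"] = len(pathways)
        log.info("stage %s: %d pathways", stage, len(pathways))

        stage = "gene-scoring"
        assignments = gene_scoring.score_genes(
            snps, genes, pairs_f,
            window_bp=config.window_bp,
            snp_alpha=config.snp_alpha,
            score_perms=config.score_perms,
            seed=config.seed,
            gene_stat=config.gene_stat,
        )
        n_asm = sum(1 for a in assignments if a.is_asm)
        counts["genes_mapped"] = len(assignments)
        counts["asm_genes"] = n_asm
        counts["nonasm_genes"] = len(assignments) - n_asm
        p = out / "gene_table.tsv"
        gene_scoring.write_gene_table(p, assignments, genes)
        written.append(p)
        log.info("stage %s: %d mapped genes (%d ASM / %d non-ASM)",
                 stage, len(assignments), n_asm, len(assignments) - n_asm)

        stage = "enrichment"
        mapped_ids = [a.gene_id for a in assignments]
        tested = enrichment.filter_pathways_by_size(
            pathways, mapped_ids, config.min_size, config.max_size
        )
        counts["pathways_tested"] = len(tested)
        results = enrichment.analyze_pathways(
            assignments, tested,
            B=config.pathway_perms,
            seed=config.seed,
            weighting=config.weighting,
        )
        p = out / "weights.tsv"
        asm_weighting.write_weights_table(p, [r.weights for r in results])
        written.append(p)
        p = out / "results.tsv"
        io_formats.write_results(p, results)
        written.append(p)
        selected = enrichment.significant_pathways(results, config.fdr_threshold)
        counts["enriched_pathways"] = len(selected)
        log.info("stage %s: %d pathways tested, %d enriched at BH < %g",
                 stage, len(tested), len(selected), config.fdr_threshold)

        stage = "postprocess"
        by_name = {pw.name: pw for pw in pathways}
        enriched_pw = [by_name[r.pathway_name] for r, _ in selected]
        reports = postprocess.overrepresented_genes(
            enriched_pw, assignments,
            fraction=config.gene_fraction, snp_alpha=config.snp_alpha,
        )
        p = out / "gene_report.tsv"
        postprocess.write_gene_report(p, reports)
        written.append(p)
        counts["overrepresented_genes"] = len(reports)

        if config.go_gmt_path:
            go_sets = io_formats.read_gmt(config.go_gmt_path)
            manifest["inputs"]["go_gmt"] = _sha256(config.go_gmt_path)
            universe = set(mapped_ids)
            non_go = [pw for pw in enriched_pw if pw.source != "GO"]
            query = set().union(*(pw.gene_ids for pw in non_go)) & universe if non_go else set()
            go_results: List[postprocess.GoEnrichmentResult] = []
            if query:
                go_results = postprocess.go_overrepresentation(query, go_sets, universe)
            p = out / "go_terms.tsv"
            postprocess.write_go_table(p, go_results, universe_note="mapped genes")
            written.append(p)
            counts["go_terms_reported"] = len(go_results)

        stage = "manifest"
        p = out / "manifest.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise StageFailure(stage, exc) from exc
    return manifest
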