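"""Synthetic study bundles for end-to-end testing without real GWA data.

A study consists of a SNP association table, a gene coordinate table,
a SNP-CpG ASM pair list, a GMT pathway database and a truth table.  Null
SNP p-values are i.i.d. uniform(0,1); signal is injected at the SNP
level by drawing 1-df non-central chi-square statistics for a subset of
SNPs in genes belonging to the configured enriched pathways and
converting them to upper-tail p-values.  Within enriched ASM genes,
each injected SNP lands on an ASM-list SNP with probability
``asm_concentration``.

All randomness derives from a single master seed via fixed per-component
substreams, so an identical config yields a bit-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigError
from . import io_formats
from .io_formats import AsmPair, GeneRecord, Pathway, SnpRecord

# substream tags (fixed offsets from the master seed)
_S_LAYOUT, _S_PVALUES, _S_ASM, _S_PATHWAYS, _S_SIGNAL = 11, 12, 13, 14, 15

_GENE_GAP_BP = 20_001  # > 2 * default mapping window, keeps windows disjoint

#: fraction of ASM genes flagged only through a trans pair targeting their CpG
_TARGET_ONLY_PROB = 0.10
#: probability an ASM gene additionally carries a non-surviving decoy pair
_DECOY_PROB = 0.30
#: fraction of an enriched member gene's SNPs that carry injected signal
_SPIKE_FRACTION = 0.5


@dataclass(frozen=True)
class IntRangeDistribution:
    """Discrete distribution on [min, max] with a target mean.

    Sampled as ``min + Binomial(max - min, (mean - min)/(max - min))``.
    """

    min: int
    max: int
    mean: float

    def __post_init__(self) -> None:
        if not (1 <= self.min <= self.mean <= self.max):
            raise ConfigError(f"need 1 <= min <= mean <= max, got {self}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.max == self.min:
            return np.full(size, self.min, dtype=int)
        p = (self.mean - self.min) / (self.max - self.min)
        return self.min + rng.binomial(self.max - self.min, p, size=size)


@dataclass(frozen=True)
class EnrichedPathwaySpec:
    """Signal injection spec for one pathway (by index in the database)."""

    pathway_index: int
    noncentrality: float
    asm_concentration: float

    def __post_init__(self) -> None:
        if self.noncentrality < 0:
            raise ConfigError("noncentrality must be >= 0")
        if not (0.0 <= self.asm_concentration <= 1.0):
            raise ConfigError("asm_concentration must be in [0, 1]")


@dataclass
class SyntheticStudyConfig:
    n_genes: int = 2_000
    snps_per_gene: IntRangeDistribution = field(
        default_factory=lambda: IntRangeDistribution(2, 30, 10.0)
    )
    gene_length_bp: Tuple[int, int] = (5_000, 50_000)
    asm_gene_fraction: float = 0.13
    asm_snps_per_asm_gene: Tuple[int, int] = (1, 4)
    n_pathways: int = 60
    pathway_size: Tuple[int, int] = (10, 50)
    enriched_pathways: List[EnrichedPathwaySpec] = field(default_factory=list)
    background_alpha_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not (0.0 <= self.asm_gene_fraction <= 1.0):
            raise ConfigError("asm_gene_fraction must be in [0, 1]")
        if not (0.05 <= self.background_alpha_fraction < 1.0):
            raise ConfigError("background_alpha_fraction must be in [0.05, 1)")
        lo, hi = self.pathway_size
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigError("pathway_size range must lie within [1, n_genes]")
        lo, hi = self.asm_snps_per_asm_gene
        if not (1 <= lo <= hi):
            raise ConfigError("asm_snps_per_asm_gene range invalid")
        lo, hi = self.gene_length_bp
        if not (100 <= lo <= hi):
            raise ConfigError("gene_length_bp range invalid")
        for spec in self.enriched_pathways:
            if not (0 <= spec.pathway_index < self.n_pathways):
                raise ConfigError(f"enriched pathway index {spec.pathway_index} out of range")


@dataclass
class StudyBundle:
    snps: List[SnpRecord]
    genes: List[GeneRecord]
    asm_pairs: List[AsmPair]
    pathways: List[Pathway]
    gene_truth: pd.DataFrame
    pathway_truth: pd.DataFrame


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag])


def generate_study(config: SyntheticStudyConfig) -> StudyBundle:
    """Generate a complete synthetic study bundle from *config*."""
    config.validate()
    seed = config.seed

    # -- gene layout: non-overlapping intervals round-robin over chr 1..22
    layout_rng = _rng(seed, _S_LAYOUT)
    lengths = layout_rng.integers(config.gene_length_bp[0], config.gene_length_bp[1] + 1,
                                  size=config.n_genes)
    genes: List[GeneRecord] = []
    cursors = {c: 1 for c in range(1, 23)}
    for i in range(config.n_genes):
        chrom = (i % 22) + 1
        start = cursors[chrom]
        end = start + int(lengths[i]) - 1
        cursors[chrom] = end + _GENE_GAP_BP
        genes.append(GeneRecord(f"G{i:05d}", chrom, start, end))

    # -- SNPs: unique positions inside each gene body
    n_snps_per_gene = config.snps_per_gene.sample(layout_rng, config.n_genes)
    snps_raw: List[Tuple[str, int, int]] = []  # id, chrom, position
    snp_counter = 0
    gene_snp_indices: List[List[int]] = []
    for i, g in enumerate(genes):
        k = int(n_snps_per_gene[i])
        length = g.end - g.start + 1
        k = min(k, length)
        offsets = np.sort(layout_rng.choice(length, size=k, replace=False))
        idxs = []
        for off in offsets:
            snps_raw.append((f"rs{snp_counter}", g.chromosome, g.start + int(off)))
            idxs.append(snp_counter)
            snp_counter += 1
        gene_snp_indices.append(idxs)
    n_snps = snp_counter

    # -- null p-values, with optional background spiking above 5%
    pval_rng = _rng(seed, _S_PVALUES)
    pvals = pval_rng.uniform(0.0, 1.0, size=n_snps)
    bg = config.background_alpha_fraction
    if bg > 0.05:
        f = (bg - 0.05) / 0.95
        spike_mask = pval_rng.random(n_snps) < f
        pvals[spike_mask] = pval_rng.uniform(0.0, 0.05, size=int(spike_mask.sum()))

    # -- ASM genes: exact count, chosen at random
    asm_rng = _rng(seed, _S_ASM)
    n_asm = int(round(config.asm_gene_fraction * config.n_genes))
    asm_gene_idx = np.sort(asm_rng.choice(config.n_genes, size=n_asm, replace=False))
    asm_set = set(int(i) for i in asm_gene_idx)

    target_only = {
        int(i) for i in asm_gene_idx if asm_rng.random() < _TARGET_ONLY_PROB
    }
    donors = [i for i in asm_set if i not in target_only]
    if not donors:
        target_only = set()  # degenerate tiny configs: make every ASM gene cis
        donors = sorted(asm_set)

    asm_pairs: List[AsmPair] = []
    asm_snp_flags = np.zeros(n_snps, dtype=bool)
    lo_a, hi_a = config.asm_snps_per_asm_gene
    cis_genes = sorted(asm_set - target_only)
    cis_by_chrom: Dict[int, List[int]] = {}
    for i in cis_genes:
        cis_by_chrom.setdefault(genes[i].chromosome, []).append(i)
    for i in cis_genes:
        g = genes[i]
        idxs = gene_snp_indices[i]
        k = min(int(asm_rng.integers(lo_a, hi_a + 1)), len(idxs))
        chosen = sorted(asm_rng.choice(len(idxs), size=k, replace=False))
        # half the genes regulate a nearby ASM gene's CpG instead of their
        # own, so the pure "SNP in gene" membership route also occurs
        target = i
        if asm_rng.random() < 0.5:
            nearby = [
                j for j in cis_by_chrom[g.chromosome]
                if j != i and abs((genes[j].start + genes[j].end) // 2 - g.start) <= io_formats.CIS_WINDOW_BP - config.gene_length_bp[1]
            ]
            if nearby:
                target = nearby[int(asm_rng.integers(len(nearby)))]
        tg = genes[target]
        cpg_pos = (tg.start + tg.end) // 2
        for c in chosen:
            si = idxs[c]
            asm_snp_flags[si] = True
            snp_id, chrom, pos = snps_raw[si]
            asm_pairs.append(AsmPair(snp_id, chrom, pos, chrom, cpg_pos, tg.gene_id,
                                     "cis", float(asm_rng.uniform(0.0, 0.05))))
        if asm_rng.random() < _DECOY_PROB:
            # a pair that will not survive the p < 0.05 filter
            si = idxs[chosen[0]]
            snp_id, chrom, pos = snps_raw[si]
            asm_pairs.append(AsmPair(snp_id, chrom, pos, chrom, cpg_pos, tg.gene_id,
                                     "cis", float(asm_rng.uniform(0.05, 1.0))))
    for i in sorted(target_only):
        g = genes[i]
        # donor SNP from another ASM gene on a different chromosome -> trans
        candidates = [d for d in donors if genes[d].chromosome != g.chromosome]
        if not candidates:
            candidates = donors
        donor = candidates[int(asm_rng.integers(len(candidates)))]
        donor_snp_candidates = [si for si in gene_snp_indices[donor] if asm_snp_flags[si]]
        if not donor_snp_candidates:
            donor_snp_candidates = gene_snp_indices[donor]
        si = donor_snp_candidates[int(asm_rng.integers(len(donor_snp_candidates)))]
        snp_id, chrom, pos = snps_raw[si]
        asm_snp_flags[si] = True
        cpg_pos = (g.start + g.end) // 2
        asm_pairs.append(AsmPair(snp_id, chrom, pos, g.chromosome, cpg_pos, g.gene_id,
                                 "trans", float(asm_rng.uniform(0.0, 0.05))))

    # -- pathways
    pw_rng = _rng(seed, _S_PATHWAYS)
    lo_p, hi_p = config.pathway_size
    pathways: List[Pathway] = []
    pathway_members: List[np.ndarray] = []
    for j in range(config.n_pathways):
        size = int(pw_rng.integers(lo_p, hi_p + 1))
        members = np.sort(pw_rng.choice(config.n_genes, size=size, replace=False))
        pathway_members.append(members)
        source = "GO" if j % 2 == 0 else "KEGG"
        name = f"{source}_PW{j:04d}"
        pathways.append(Pathway(name=name, source=source,
                                gene_ids=frozenset(genes[int(i)].gene_id for i in members)))

    # -- signal injection
    sig_rng = _rng(seed, _S_SIGNAL)
    enriched_gene_idx: Dict[int, EnrichedPathwaySpec] = {}
    for spec in config.enriched_pathways:
        for gi in pathway_members[spec.pathway_index]:
            # first spec wins if pathways overlap
            enriched_gene_idx.setdefault(int(gi), spec)
    n_spiked_per_gene = np.zeros(config.n_genes, dtype=int)
    for gi in sorted(enriched_gene_idx):
        spec = enriched_gene_idx[gi]
        if spec.noncentrality == 0:
            continue
        idxs = gene_snp_indices[gi]
        n_spike = max(1, int(round(_SPIKE_FRACTION * len(idxs))))
        asm_idxs = [si for si in idxs if asm_snp_flags[si]]
        other_idxs = [si for si in idxs if not asm_snp_flags[si]]
        targets: List[int] = []
        if gi in asm_set and asm_idxs:
            n_on_asm = int(sig_rng.binomial(n_spike, spec.asm_concentration))
            n_on_asm = min(n_on_asm, len(asm_idxs))
            if n_on_asm:
                targets += [asm_idxs[t] for t in
                            sig_rng.choice(len(asm_idxs), size=n_on_asm, replace=False)]
            n_rest = min(n_spike - n_on_asm, len(other_idxs))
            if n_rest:
                targets += [other_idxs[t] for t in
                            sig_rng.choice(len(other_idxs), size=n_rest, replace=False)]
        else:
            n_spike = min(n_spike, len(idxs))
            targets = [idxs[t] for t in sig_rng.choice(len(idxs), size=n_spike, replace=False)]
        for si in sorted(targets):
            x = sig_rng.noncentral_chisquare(1.0, spec.noncentrality)
            pvals[si] = float(chi2.sf(x, df=1))
        n_spiked_per_gene[gi] = len(targets)

    pvals = np.clip(pvals, np.nextafter(0.0, 1.0), 1.0)

    chisq_all = chi2.isf(pvals, df=1)
    snps = [
        SnpRecord(snp_id, chrom, pos, float(pvals[k]), float(chisq_all[k]))
        for k, (snp_id, chrom, pos) in enumerate(snps_raw)
    ]

    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "is_asm": [i in asm_set for i in range(config.n_genes)],
            "is_target_only": [i in target_only for i in range(config.n_genes)],
            "is_enriched_member": [i in enriched_gene_idx for i in range(config.n_genes)],
            "n_spiked_snps": n_spiked_per_gene,
            "n_snps": [len(gene_snp_indices[i]) for i in range(config.n_genes)],
        }
    )
    enriched_by_index = {s.pathway_index: s for s in config.enriched_pathways}
    pathway_truth = pd.DataFrame(
        {
            "pathway": [p.name for p in pathways],
            "enriched": [j in enriched_by_index for j in range(config.n_pathways)],
            "noncentrality": [
                enriched_by_index[j].noncentrality if j in enriched_by_index else 0.0
                for j in range(config.n_pathways)
            ],
            "asm_concentration": [
                enriched_by_index[j].asm_concentration if j in enriched_by_index else 0.0
                for j in range(config.n_pathways)
            ],
        }
    )
    return StudyBundle(snps, genes, asm_pairs, pathways, gene_truth, pathway_truth)


def generate_null_scores(n_genes: int, seed: int) -> np.ndarray:
    """I.i.d. 1-df chi-square gene scores (unit-test shortcut)."""
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    return np.random.default_rng(seed).chisquare(df=1, size=n_genes)


def write_study(bundle: StudyBundle, outdir) -> Dict[str, str]:
    """Write a bundle to *outdir* in the formats the readers consume.

    Returns a dict of logical name -> path.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "assoc": str(out / "study.assoc"),
        "genes": str(out / "genes.bed"),
        "asm_pairs": str(out / "asm_pairs.tsv"),
        "gmt": str(out / "pathways.gmt"),
        "truth": str(out / "truth.tsv"),
        "truth_pathways": str(out / "truth_pathways.tsv"),
    }
    io_formats.write_assoc(paths["assoc"], bundle.snps)
    io_formats.write_gene_table(paths["genes"], bundle.genes)
    io_formats.write_asm_pairs(paths["asm_pairs"], bundle.asm_pairs)
    io_formats.write_gmt(paths["gmt"], bundle.pathways)
    bundle.gene_truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    bundle.pathway_truth.to_csv(paths["truth_pathways"], sep="\t", index=False, lineterminator="\n")
    return paths
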