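"""SNP-to-gene mapping, ASM gene-set construction and per-gene statistics.

A gene is represented by the smallest SNP p-value in its window
(*min-p*): for ASM genes only SNPs on the ASM list count, for non-ASM
genes all mapped SNPs count.  The min-p is then normalized for gene size
against a resampled null (B draws of ``n_snps`` p-values without
replacement from the study-wide pool, each reduced to its minimum) and
converted to a 1-df chi-square scale gene score.

"Informative" genes are those whose within-gene fraction of SNPs with
p < 0.05 strictly exceeds the genome-wide fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .errors import ContractError
from .io_formats import AsmPair, GeneRecord, SnpRecord

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 5_000
DEFAULT_SNP_ALPHA = 0.05
DEFAULT_SCORE_PERMS = 10_000

ROUTE_SNP = "asm_snp_in_gene"
ROUTE_CPG = "cpg_target"
ROUTE_BOTH = "both"
ROUTE_NONE = "none"


@dataclass
class GeneAssignment:
    """A mapped gene with its SNPs, ASM status and gene-level statistics."""

    gene_id: str
    snp_ids: List[str]
    asm_snp_ids: List[str]
    is_asm: bool
    asm_route: str
    n_snps: int
    n_significant_snps: int
    prop_significant: float
    min_p: float
    min_p_all: float
    representative_snp: str
    adjusted_p: Optional[float] = None
    gene_score: Optional[float] = None
    is_informative: bool = False


def map_snps_to_genes(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> Dict[str, List[SnpRecord]]:
    """Assign SNPs to genes within *window_bp* of both gene ends (inclusive).

    A SNP may map to several overlapping genes; genes with no mapped SNP
    are absent from the result.
    """
    if window_bp < 0:
        raise ContractError("window_bp must be >= 0")
    by_chrom: Dict[int, List[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chromosome, []).append(s)
    positions: Dict[int, np.ndarray] = {}
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda s: (s.position, s.snp_id))
        positions[chrom] = np.array([s.position for s in lst])

    mapping: Dict[str, List[SnpRecord]] = {}
    for g in genes:
        if g.chromosome not in positions:
            continue
        pos = positions[g.chromosome]
        lo = int(np.searchsorted(pos, g.start - window_bp, side="left"))
        hi = int(np.searchsorted(pos, g.end + window_bp, side="right"))
        if hi > lo:
            mapping[g.gene_id] = by_chrom[g.chromosome][lo:hi]
    return mapping


def build_asm_gene_sets(
    mapping: Mapping[str, Sequence[SnpRecord]],
    asm_pairs: Sequence[AsmPair],
) -> Tuple[Dict[str, str], Set[str]]:
    """Partition mapped genes into ASM (with route) and non-ASM.

    A gene is ASM iff it contains a mapped SNP on the ASM list
    (route ``asm_snp_in_gene``) or it is the target of an ASM pair's CpG
    (route ``cpg_target``); both conditions give route ``both``.  Pairs
    targeting genes absent from the mapping are ignored with a warning.
    Returns ``(asm_routes, non_asm_gene_ids)``.
    """
    asm_snp_ids = {p.snp_id for p in asm_pairs}
    target_ids = {p.target_gene_id for p in asm_pairs}
    unknown_targets = target_ids - set(mapping)
    if unknown_targets:
        log.warning(
            "build_asm_gene_sets: %d ASM pair target genes not in the mapped gene table; ignored",
            len(unknown_targets),
        )
    routes: Dict[str, str] = {}
    non_asm: Set[str] = set()
    for gene_id, gene_snps in mapping.items():
        has_snp = any(s.snp_id in asm_snp_ids for s in gene_snps)
        is_target = gene_id in target_ids
        if has_snp and is_target:
            routes[gene_id] = ROUTE_BOTH
        elif has_snp:
            routes[gene_id] = ROUTE_SNP
        elif is_target:
            routes[gene_id] = ROUTE_CPG
        else:
            non_asm.add(gene_id)
    return routes, non_asm


def gene_min_p(
    gene_snps: Sequence[SnpRecord],
    asm_snp_ids: Set[str],
    is_asm: bool,
) -> Tuple[float, str, float]:
    """Return (min_p, representative_snp, min_p_all) for one gene.

    ASM genes with at least one in-gene ASM SNP take the minimum over
    their ASM SNPs only; ASM genes flagged purely as CpG targets fall
    back to all mapped SNPs, as do non-ASM genes.  Ties go to the lowest
    position, then lexicographic SNP id.
    """
    if not gene_snps:
        raise ContractError("gene_min_p: gene has no mapped SNPs")

    def best(records: Iterable[SnpRecord]) -> SnpRecord:
        return min(records, key=lambda s: (s.p_value, s.position, s.snp_id))

    overall = best(gene_snps)
    in_gene_asm = [s for s in gene_snps if s.snp_id in asm_snp_ids]
    if is_asm and in_gene_asm:
        rep = best(in_gene_asm)
    else:
        rep = overall
    return rep.p_value, rep.snp_id, overall.p_value


def genomewide_significant_proportion(
    snps: Sequence[SnpRecord], alpha: float = DEFAULT_SNP_ALPHA
) -> float:
    """Fraction of all analyzed SNPs with p < *alpha* (strict)."""
    if not snps:
        raise ContractError("genomewide_significant_proportion: empty SNP list")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return sum(1 for s in snps if s.p_value < alpha) / len(snps)


def informative_flag(prop_significant: float, genomewide_prop: float) -> bool:
    """Strictly more significant SNPs than the genome-wide average."""
    return prop_significant > genomewide_prop


def chisq_from_p(p):
    """1-df chi-square value with upper-tail probability *p* (vectorized)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("chisq_from_p: p must be in (0, 1]")
    out = chi2.isf(arr, df=1)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# size-adjusted gene scores
# ---------------------------------------------------------------------------

def _min_rank_cdf(pool_size: int, n: int) -> np.ndarray:
    """CDF of the minimum rank of n indices drawn without replacement from
    ``0..pool_size-1``: entry j is P(min <= j) = 1 - C(S-1-j, n)/C(S, n)."""
    S = pool_size
    j = np.arange(S)
    top = S - 1 - j  # remaining indices strictly above j
    with np.errstate(invalid="ignore"):
        logtail = gammaln(top + 1) - gammaln(top - n + 1) - (gammaln(S + 1) - gammaln(S - n + 1))
    tail = np.where(top >= n, np.exp(logtail), 0.0)
    return 1.0 - tail


def _null_min_values(sorted_pool: np.ndarray, n: int, B: int, seed: int) -> np.ndarray:
    """B null replicates of min(n p-values sampled without replacement).

    Sampled exactly via the minimum-order-statistic rank distribution:
    draw u ~ U(0,1) and invert the min-rank CDF, then index the sorted
    pool.  The stream depends on (seed, n) only, so genes with the same
    SNP count share one null distribution.
    """
    rng = np.random.default_rng([seed, n])
    u = rng.random(B)
    cdf = _min_rank_cdf(len(sorted_pool), n)
    j = np.searchsorted(cdf, u, side="left")
    j = np.minimum(j, len(sorted_pool) - 1)
    return sorted_pool[j]


def adjusted_gene_score(
    min_p: float,
    n_snps: int,
    pool: Sequence[float],
    B: int = DEFAULT_SCORE_PERMS,
    seed: int = 0,
) -> Tuple[float, float]:
    """Gene-size-adjusted p and chi-square-scale score for one gene.

    ``adjusted_p = (1 + #{null min <= min_p}) / (1 + B)`` against B null
    minima of ``n_snps`` p-values resampled without replacement from
    *pool*; the score is the 1-df chi-square upper-tail quantile at
    ``adjusted_p``.
    """
    if B < 100:
        raise ContractError("adjusted_gene_score: B must be >= 100")
    pool_arr = np.sort(np.asarray(pool, dtype=float))
    if n_snps < 1 or n_snps > len(pool_arr):
        raise ContractError("adjusted_gene_score: need 1 <= n_snps <= pool size")
    null_min = _null_min_values(pool_arr, n_snps, B, seed)
    count = int(np.count_nonzero(null_min <= min_p))
    adj = (1 + count) / (1 + B)
    return adj, chisq_from_p(adj)


def adjusted_scores_batch(
    min_ps: Sequence[float],
    n_snps_list: Sequence[int],
    pool: Sequence[float],
    B: int = DEFAULT_SCORE_PERMS,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`adjusted_gene_score` over many genes.

    Genes sharing a SNP count reuse one null sample, and the per-count
    random stream matches the single-gene function exactly.
    """
    if B < 100:
        raise ContractError("adjusted_scores_batch: B must be >= 100")
    min_ps = np.asarray(min_ps, dtype=float)
    n_arr = np.asarray(n_snps_list, dtype=int)
    sorted_pool = np.sort(np.asarray(pool, dtype=float))
    if np.any(n_arr < 1) or np.any(n_arr > len(sorted_pool)):
        raise ContractError("adjusted_scores_batch: need 1 <= n_snps <= pool size")
    adj = np.empty(len(min_ps), dtype=float)
    for n in np.unique(n_arr):
        null_sorted = np.sort(_null_min_values(sorted_pool, int(n), B, seed))
        idx = np.nonzero(n_arr == n)[0]
        counts = np.searchsorted(null_sorted, min_ps[idx], side="right")
        adj[idx] = (1 + counts) / (1 + B)
    return adj, chi2.isf(adj, df=1)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def score_genes(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    asm_pairs: Sequence[AsmPair],
    window_bp: int = DEFAULT_WINDOW_BP,
    snp_alpha: float = DEFAULT_SNP_ALPHA,
    score_perms: int = DEFAULT_SCORE_PERMS,
    seed: int = 0,
    gene_stat: str = "adjusted",
) -> List[GeneAssignment]:
    """Full gene-level stage: map, partition, min-p, adjust, flag.

    *asm_pairs* must already be filtered.  ``gene_stat`` selects the
    statistic stored in ``gene_score``: the size-adjusted chi-square
    (``"adjusted"``, default) or the raw chi-square of the min-p SNP
    (``"raw_chisq"``).
    """
    if gene_stat not in ("adjusted", "raw_chisq"):
        raise ValueError(f"gene_stat must be 'adjusted' or 'raw_chisq', got {gene_stat!r}")
    mapping = map_snps_to_genes(snps, genes, window_bp)
    routes, _non_asm = build_asm_gene_sets(mapping, asm_pairs)
    asm_snp_ids = {p.snp_id for p in asm_pairs}
    gw_prop = genomewide_significant_proportion(snps, snp_alpha)

    assignments: List[GeneAssignment] = []
    for gene_id in sorted(mapping):
        gene_snps = mapping[gene_id]
        is_asm = gene_id in routes
        route = routes.get(gene_id, ROUTE_NONE)
        in_gene_asm = [s.snp_id for s in gene_snps if s.snp_id in asm_snp_ids]
        min_p, rep, min_p_all = gene_min_p(gene_snps, asm_snp_ids, is_asm)
        n_sig = sum(1 for s in gene_snps if s.p_value < snp_alpha)
        n = len(gene_snps)
        assignments.append(
            GeneAssignment(
                gene_id=gene_id,
                snp_ids=[s.snp_id for s in gene_snps],
                asm_snp_ids=in_gene_asm,
                is_asm=is_asm,
                asm_route=route,
                n_snps=n,
                n_significant_snps=n_sig,
                prop_significant=n_sig / n,
                min_p=min_p,
                min_p_all=min_p_all,
                representative_snp=rep,
                is_informative=informative_flag(n_sig / n, gw_prop),
            )
        )

    pool = np.array([s.p_value for s in snps])
    adj, score = adjusted_scores_batch(
        [a.min_p for a in assignments],
        [a.n_snps for a in assignments],
        pool,
        B=score_perms,
        seed=seed,
    )
    for a, ap, sc in zip(assignments, adj, score):
        a.adjusted_p = float(ap)
        a.gene_score = float(sc) if gene_stat == "adjusted" else chisq_from_p(a.min_p)
    return assignments


def write_gene_table(path, assignments: Sequence[GeneAssignment], genes: Sequence[GeneRecord]) -> None:
    """Write the intermediate gene-level table as TSV."""
    coords = {g.gene_id: g for g in genes}
    header = [
        "gene_id", "chrom", "start", "end", "n_snps", "is_asm", "asm_route",
        "min_p", "representative_snp", "adjusted_p", "gene_score",
        "prop_significant", "is_informative",
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for a in assignments:
            g = coords[a.gene_id]
            row = [
                a.gene_id, g.chromosome, g.start, g.end, a.n_snps, int(a.is_asm),
                a.asm_route, format(a.min_p, ".12g"), a.representative_snp,
                format(a.adjusted_p, ".12g"), format(a.gene_score, ".12g"),
                format(a.prop_significant, ".12g"), int(a.is_informative),
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")
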