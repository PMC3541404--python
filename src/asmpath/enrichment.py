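"""Pathway enrichment statistics with permutation p-values and BH FDR.

Three statistics per pathway, each in a weighted and an unweighted mode:

* ``gsea`` — competitive running-sum enrichment score over the global
  gene ranking (weight exponent 1, maximum positive deviation);
* ``sumst`` / ``sumsq`` — self-contained sum and sum-of-squares of the
  member gene scores.

The null is a gene-label permutation: each permutation jointly shuffles
the per-gene (score, informative) tuples across all mapped genes while
pathway membership and ASM labels stay fixed; subset weights are
recomputed from the shuffled informative flags.  Empirical p-values use
the add-one estimator (1 + r) / (1 + B), and the same permutation stream
is shared by all three methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .asm_weighting import PathwayWeights, pathway_weights
from .errors import ConfigError, ContractError
from .gene_scoring import GeneAssignment
from .io_formats import Pathway

METHODS = ("gsea", "sumst", "sumsq")
MODES = ("weighted", "unweighted")

DEFAULT_PATHWAY_PERMS = 5_000
DEFAULT_MIN_SIZE = 10
DEFAULT_MAX_SIZE = 380
DEFAULT_FDR = 0.01


@dataclass
class MethodStat:
    raw_stat: float
    empirical_p: Optional[float] = None
    bh_p: Optional[float] = None


@dataclass
class PathwayResult:
    """Per-pathway statistics for every method x mode combination."""

    pathway_name: str
    source: str
    total_genes: int
    genes_on_list: int
    pct_asm: float
    weights: PathwayWeights
    stats: Dict[Tuple[str, str], MethodStat] = field(default_factory=dict)


def filter_pathways_by_size(
    pathways: Sequence[Pathway],
    mapped_gene_ids: Iterable[str],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> List[Pathway]:
    """Keep pathways whose mapped ("on list") gene count is in [min, max]."""
    if min_size > max_size:
        raise ConfigError("min_size must be <= max_size")
    mapped = set(mapped_gene_ids)
    out = []
    for pw in pathways:
        k = len(pw.gene_ids & mapped)
        if min_size <= k <= max_size:
            out.append(pw)
    return out


def apply_weights(
    scores: Mapping[str, float],
    asm_labels: Mapping[str, bool],
    w: PathwayWeights,
) -> Dict[str, float]:
    """Multiply each member gene's score by its subset weight."""
    out = {}
    for gene, s in scores.items():
        if gene not in asm_labels:
            raise ContractError(f"apply_weights: gene {gene!r} has no ASM label")
        out[gene] = float(w.w_asm if asm_labels[gene] else w.w_nonasm) * s
    return out


def enrichment_score(
    pathway_members: Set[str],
    all_scores: Mapping[str, float],
    member_weighted_scores: Mapping[str, float],
) -> float:
    """Running-sum enrichment score of one pathway against the global ranking.

    Genes are ranked by score descending (ties by gene id); the running
    sum gains (weighted |score|)/N_R at members and loses 1/(N - N_H) at
    non-members; the ES is the maximum over all positions.  Returns 0 if
    the members' weighted mass N_R is zero.
    """
    n = len(all_scores)
    n_h = len(pathway_members)
    if not (n > n_h >= 1):
        raise ContractError("enrichment_score: need N > N_H >= 1")
    if not pathway_members <= set(all_scores):
        raise ContractError("enrichment_score: members must all be scored")
    order = sorted(all_scores, key=lambda g: (-all_scores[g], g))
    n_r = sum(abs(member_weighted_scores[g]) for g in pathway_members)
    if n_r == 0:
        return 0.0
    miss = 1.0 / (n - n_h)
    running = 0.0
    best = -np.inf
    for g in order:
        if g in pathway_members:
            running += abs(member_weighted_scores[g]) / n_r
        else:
            running -= miss
        best = max(best, running)
    return best


def sum_statistic(member_weighted_scores: Mapping[str, float]) -> float:
    """Sum of member gene scores."""
    if not member_weighted_scores:
        raise ContractError("sum_statistic: need at least one member")
    return float(sum(member_weighted_scores.values()))


def sum_square_statistic(member_weighted_scores: Mapping[str, float]) -> float:
    """Sum of squared member gene scores."""
    if not member_weighted_scores:
        raise ContractError("sum_square_statistic: need at least one member")
    return float(sum(v * v for v in member_weighted_scores.values()))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("bh_adjust: p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(ranked, 1.0)
    return out


def significant_pathways(
    results: Sequence[PathwayResult], fdr_threshold: float = DEFAULT_FDR
) -> List[Tuple[PathwayResult, List[Tuple[str, str]]]]:
    """Pathways with any BH p below *fdr_threshold*, with triggering cells."""
    if not (0.0 < fdr_threshold < 1.0):
        raise ConfigError("fdr_threshold must be in (0, 1)")
    selected = []
    for r in results:
        triggers = [
            key
            for key, s in sorted(r.stats.items())
            if s.bh_p is not None and s.bh_p < fdr_threshold
        ]
        if triggers:
            selected.append((r, triggers))
    return selected


# ---------------------------------------------------------------------------
# vectorized core
# ---------------------------------------------------------------------------

def _weights_float(
    n: np.ndarray, m: np.ndarray, k_n: np.ndarray, k_m: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized float replica of :func:`~asmpath.asm_weighting.pathway_weights`.

    Used inside the permutation loop where exact fractions would be
    needlessly slow; exhaustively tested against the exact version.
    """
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    k_n = np.asarray(k_n, dtype=float)
    k_m = np.asarray(k_m, dtype=float)
    w_a = np.ones_like(n)
    w_na = np.ones_like(n)
    both = (n > 0) & (m > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_n = np.where(n > 0, k_n / n, 0.0)
        r_m = np.where(m > 0, k_m / m, 0.0)
    binned = both & (k_m == 0) & (k_n > 0)
    if np.any(binned):
        cuts = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        w_a[binned] = 1 + np.searchsorted(cuts, r_n[binned], side="right")
    harmonic = both & ~binned & (r_n > r_m)
    if np.any(harmonic):
        h = 2 * r_n[harmonic] * r_m[harmonic] / (r_n[harmonic] + r_m[harmonic])
        w_a[harmonic] = r_n[harmonic] / h
        w_na[harmonic] = r_m[harmonic] / h
    return w_a, w_na


@dataclass
class _PathwayCtx:
    name: str
    member_idx: np.ndarray        # indices into the gene arrays
    asm_mask: np.ndarray          # bool over member_idx
    n: int
    m: int


def _pathway_stats(
    ctx: _PathwayCtx,
    scores: np.ndarray,
    ranks: np.ndarray,
    w_a: float,
    w_na: float,
    n_genes: int,
) -> Tuple[float, float, float]:
    """(es, sumst, sumsq) for one pathway given a global ranking."""
    sm = scores[ctx.member_idx]
    wm = np.where(ctx.asm_mask, w_a, w_na) * sm
    st = float(wm.sum())
    sq = float((wm * wm).sum())
    r = ranks[ctx.member_idx]
    o = np.argsort(r, kind="stable")
    rs = r[o]
    cw = np.cumsum(np.abs(wm[o]))
    n_r = cw[-1]
    if n_r == 0:
        es = 0.0
    else:
        hit = cw / n_r
        miss = (rs - np.arange(len(rs))) / (n_genes - len(rs))
        es = float(np.max(hit - miss))
    return es, st, sq


def analyze_pathways(
    assignments: Sequence[GeneAssignment],
    pathways: Sequence[Pathway],
    B: int = DEFAULT_PATHWAY_PERMS,
    seed: int = 0,
    weighting: str = "both",
) -> List[PathwayResult]:
    """Compute all pathway statistics, empirical p-values and BH p-values.

    *pathways* should already be size-filtered; *assignments* carry the
    gene scores, ASM labels and informative flags.  ``weighting`` is one
    of ``"on"``, ``"off"``, ``"both"``.
    """
    if weighting not in ("on", "off", "both"):
        raise ConfigError(f"weighting must be 'on', 'off' or 'both', got {weighting!r}")
    if B < 100:
        raise ConfigError("analyze_pathways: B must be >= 100")
    modes = {"on": ("weighted",), "off": ("unweighted",), "both": MODES}[weighting]

    assignments = sorted(assignments, key=lambda a: a.gene_id)
    gene_ids = np.array([a.gene_id for a in assignments])
    scores = np.array([a.gene_score for a in assignments], dtype=float)
    informative = np.array([a.is_informative for a in assignments], dtype=float)
    is_asm = np.array([a.is_asm for a in assignments], dtype=bool)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    G = len(gene_ids)

    ctxs: List[_PathwayCtx] = []
    results: List[PathwayResult] = []
    for pw in pathways:
        idx = np.array(sorted(gene_index[g] for g in pw.gene_ids if g in gene_index), dtype=int)
        if len(idx) == 0 or len(idx) >= G:
            raise ContractError(f"pathway {pw.name}: needs 1 <= mapped size < number of mapped genes")
        amask = is_asm[idx]
        n = int(amask.sum())
        m = int(len(idx) - n)
        ctxs.append(_PathwayCtx(pw.name, idx, amask, n, m))
        k_n = int(informative[idx][amask].sum())
        k_m = int(informative[idx][~amask].sum())
        w = pathway_weights(n, m, k_n, k_m, pathway_name=pw.name)
        results.append(
            PathwayResult(
                pathway_name=pw.name,
                source=pw.source,
                total_genes=len(pw.gene_ids),
                genes_on_list=len(idx),
                pct_asm=round(100.0 * n / len(idx), 1),
                weights=w,
            )
        )

    # observed statistics (global ranking with deterministic tie-break)
    order = np.lexsort((gene_ids, -scores))
    ranks = np.empty(G, dtype=int)
    ranks[order] = np.arange(G)
    observed: Dict[Tuple[int, str, str], float] = {}
    for pi, (ctx, res) in enumerate(zip(ctxs, results)):
        for mode in modes:
            if mode == "weighted":
                w_a, w_na = float(res.weights.w_asm), float(res.weights.w_nonasm)
            else:
                w_a = w_na = 1.0
            es, st, sq = _pathway_stats(ctx, scores, ranks, w_a, w_na, G)
            res.stats[("gsea", mode)] = MethodStat(es)
            res.stats[("sumst", mode)] = MethodStat(st)
            res.stats[("sumsq", mode)] = MethodStat(sq)
            observed[(pi, "gsea", mode)] = es
            observed[(pi, "sumst", mode)] = st
            observed[(pi, "sumsq", mode)] = sq

    # permutation null: shuffle (score, informative) jointly over genes
    exceed = {key: 0 for key in observed}
    rng = np.random.default_rng([seed, 21])
    n_vec = np.array([c.n for c in ctxs], dtype=float)
    m_vec = np.array([c.m for c in ctxs], dtype=float)
    for _ in range(B):
        perm = rng.permutation(G)
        s = scores[perm]
        f = informative[perm]
        p_order = np.argsort(-s, kind="stable")
        p_ranks = np.empty(G, dtype=int)
        p_ranks[p_order] = np.arange(G)
        if "weighted" in modes:
            k_n_vec = np.array([f[c.member_idx][c.asm_mask].sum() for c in ctxs])
            k_m_vec = np.array([f[c.member_idx][~c.asm_mask].sum() for c in ctxs])
            w_a_vec, w_na_vec = _weights_float(n_vec, m_vec, k_n_vec, k_m_vec)
        for pi, ctx in enumerate(ctxs):
            for mode in modes:
                if mode == "weighted":
                    w_a, w_na = float(w_a_vec[pi]), float(w_na_vec[pi])
                else:
                    w_a = w_na = 1.0
                es, st, sq = _pathway_stats(ctx, s, p_ranks, w_a, w_na, G)
                if es >= observed[(pi, "gsea", mode)]:
                    exceed[(pi, "gsea", mode)] += 1
                if st >= observed[(pi, "sumst", mode)]:
                    exceed[(pi, "sumst", mode)] += 1
                if sq >= observed[(pi, "sumsq", mode)]:
                    exceed[(pi, "sumsq", mode)] += 1

    for (pi, method, mode), r in exceed.items():
        results[pi].stats[(method, mode)].empirical_p = (1 + r) / (1 + B)

    # BH within each method x mode family
    for method in METHODS:
        for mode in modes:
            ps = [res.stats[(method, mode)].empirical_p for res in results]
            adj = bh_adjust(ps)
            for res, a in zip(results, adj):
                res.stats[(method, mode)].bh_p = float(a)
    return results


def permutation_pvalues(
    assignments: Sequence[GeneAssignment],
    pathways: Sequence[Pathway],
    B: int = DEFAULT_PATHWAY_PERMS,
    seed: int = 0,
    weighting: str = "both",
) -> Dict[Tuple[str, str, str], float]:
    """Empirical p-values keyed (pathway, method, mode).

    Thin wrapper over :func:`analyze_pathways` for callers that only
    need the permutation p-values.
    """
    results = analyze_pathways(assignments, pathways, B=B, seed=seed, weighting=weighting)
    out = {}
    for res in results:
        for (method, mode), s in res.stats.items():
            if s.empirical_p is not None:
                out[(res.pathway_name, method, mode)] = s.empirical_p
    return out
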