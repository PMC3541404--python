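"""Follow-up reporting on enriched pathways.

* GO-term over-representation of the genes belonging to enriched
  (non-GO) pathways, via a one-sided hypergeometric test over the
  mapped-gene universe (no multiple-testing correction; exploratory).
* The over-represented-gene report: genes present in more than a given
  fraction of all enriched pathways that carry at least one nominally
  significant SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

from scipy.stats import hypergeom

from .errors import ContractError
from .gene_scoring import GeneAssignment
from .io_formats import Pathway

log = logging.getLogger(__name__)

DEFAULT_TOP_K = 50
DEFAULT_GO_ALPHA = 0.05


@dataclass(frozen=True)
class GoEnrichmentResult:
    term_name: str
    term_size: int
    overlap: int
    pct_overlap: float
    p_value: float


@dataclass(frozen=True)
class GeneReport:
    gene_id: str
    set_label: str  # "ASM" | "non-ASM"
    n_pathways_containing: int
    n_snps: int
    pct_significant_snps: float
    smallest_p: float


def hypergeom_upper_tail(universe: int, term: int, query: int, overlap: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, term, query)."""
    return float(hypergeom.sf(overlap - 1, universe, term, query))


def go_overrepresentation(
    query_genes: Set[str],
    go_sets: Sequence[Pathway],
    universe: Set[str],
    top_k: int = DEFAULT_TOP_K,
    alpha: float = DEFAULT_GO_ALPHA,
) -> List[GoEnrichmentResult]:
    """One-sided hypergeometric over-representation of *query_genes*.

    Each GO set is restricted to *universe* before testing; terms
    disjoint from the universe are skipped with a warning.  Results with
    p < *alpha* are returned sorted by (p, name), truncated to *top_k*.
    """
    if not query_genes:
        raise ContractError("go_overrepresentation: empty query")
    if not query_genes <= universe:
        raise ContractError("go_overrepresentation: query must be a subset of the universe")
    n_universe = len(universe)
    n_query = len(query_genes)
    out: List[GoEnrichmentResult] = []
    for term in go_sets:
        term_genes = term.gene_ids & universe
        if not term_genes:
            log.warning("go_overrepresentation: term %s disjoint from universe; skipped", term.name)
            continue
        overlap = len(term_genes & query_genes)
        p = hypergeom_upper_tail(n_universe, len(term_genes), n_query, overlap)
        out.append(
            GoEnrichmentResult(
                term_name=term.name,
                term_size=len(term_genes),
                overlap=overlap,
                pct_overlap=round(100.0 * overlap / len(term_genes), 1),
                p_value=p,
            )
        )
    out = [r for r in out if r.p_value < alpha]
    out.sort(key=lambda r: (r.p_value, r.term_name))
    return out[:top_k]


def overrepresented_genes(
    enriched_pathways: Sequence[Pathway],
    assignments: Sequence[GeneAssignment],
    fraction: float = 0.2,
    snp_alpha: float = 0.05,
) -> List[GeneReport]:
    """Genes in more than ``fraction`` of all enriched pathways with >= 1
    SNP at p < *snp_alpha* (both thresholds strict).

    With zero enriched pathways the report is empty, not an error.
    """
    if not (0.0 < fraction < 1.0):
        raise ContractError("fraction must be in (0, 1)")
    if not enriched_pathways:
        return []
    by_gene: Dict[str, GeneAssignment] = {a.gene_id: a for a in assignments}
    counts: Dict[str, int] = {}
    for pw in enriched_pathways:
        for g in pw.gene_ids:
            if g in by_gene:
                counts[g] = counts.get(g, 0) + 1
    threshold = fraction * len(enriched_pathways)
    reports: List[GeneReport] = []
    for gene_id in sorted(counts):
        if counts[gene_id] <= threshold:
            continue
        a = by_gene[gene_id]
        if a.min_p_all >= snp_alpha:
            continue
        reports.append(
            GeneReport(
                gene_id=gene_id,
                set_label="ASM" if a.is_asm else "non-ASM",
                n_pathways_containing=counts[gene_id],
                n_snps=a.n_snps,
                pct_significant_snps=round(100.0 * a.prop_significant, 1),
                smallest_p=a.min_p_all,
            )
        )
    return reports


def write_go_table(path, results: Iterable[GoEnrichmentResult], universe_note: str = "") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if universe_note:
            fh.write(f"# universe: {universe_note}; exploratory, no multiple-testing correction\n")
        fh.write("term\tterm_size\toverlap\tpct_overlap\tp_value\n")
        for r in results:
            fh.write(
                f"{r.term_name}\t{r.term_size}\t{r.overlap}\t{r.pct_overlap}\t"
                f"{format(r.p_value, '.12g')}\n"
            )


def write_gene_report(path, reports: Iterable[GeneReport]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tset\tn_pathways\tn_snps\tpct_significant_snps\tsmallest_p\n")
        for r in reports:
            fh.write(
                f"{r.gene_id}\t{r.set_label}\t{r.n_pathways_containing}\t{r.n_snps}\t"
                f"{r.pct_significant_snps}\t{format(r.smallest_p, '.12g')}\n"
            )
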