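"""Readers and writers for the external formats touched by the pipeline.

Formats handled:

* PLINK ``.assoc``-style whitespace-delimited association tables
  (columns ``CHR SNP BP P`` and optionally ``CHISQ``);
* BED4 gene coordinate tables (0-based half-open on disk, converted to
  1-based inclusive at ingestion and never again);
* tab-delimited SNP-CpG regulatory-pair tables with cis/trans mode;
* GMT gene-set files (MSigDB convention);
* the tab-delimited pathway results table.

Chromosome labels ``"chr1"`` and ``"1"`` are both accepted and
normalized to bare integers; only autosomes 1..22 are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

AUTOSOMES = frozenset(range(1, 23))

#: inclusive distance bound (bp) between a cis-acting SNP and its CpG site
CIS_WINDOW_BP = 1_000_000

_NA_TOKENS = {"", "NA", "NAN", "N/A", "NONE", "."}


def normalize_chromosome(label: object) -> Optional[int]:
    """Normalize a chromosome label to an autosome integer, or ``None``.

    ``"chr7"``, ``"7"`` and ``7`` all map to ``7``; sex chromosomes,
    mitochondrial contigs and anything unparsable map to ``None``.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        c = int(s)
    except ValueError:
        return None
    return c if c in AUTOSOMES else None


def _check_p(p: float, what: str) -> None:
    if not (0.0 < p <= 1.0) or math.isnan(p):
        raise FormatError(f"{what} p-value must be in (0, 1], got {p!r}")


@dataclass(frozen=True)
class SnpRecord:
    """One SNP's single-marker association result."""

    snp_id: str
    chromosome: int
    position: int
    p_value: float
    chi_square: Optional[float] = None

    def __post_init__(self) -> None:
        if self.chromosome not in AUTOSOMES:
            raise FormatError(f"SNP {self.snp_id}: chromosome must be an autosome 1..22")
        if self.position < 1:
            raise FormatError(f"SNP {self.snp_id}: position must be >= 1")
        _check_p(self.p_value, f"SNP {self.snp_id}")
        if self.chi_square is not None and self.chi_square < 0:
            raise FormatError(f"SNP {self.snp_id}: chi-square must be >= 0")


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval, 1-based inclusive."""

    gene_id: str
    chromosome: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.chromosome not in AUTOSOMES:
            raise FormatError(f"Gene {self.gene_id}: chromosome must be an autosome 1..22")
        if not (1 <= self.start <= self.end):
            raise FormatError(f"Gene {self.gene_id}: need 1 <= start <= end")


@dataclass(frozen=True)
class AsmPair:
    """One SNP-CpG regulatory pair from the allele-specific-methylation list.

    ``mode == "cis"`` requires the SNP and CpG on the same chromosome
    within :data:`CIS_WINDOW_BP` (inclusive); ``trans`` is unconstrained.
    """

    snp_id: str
    snp_chromosome: int
    snp_position: int
    cpg_chromosome: int
    cpg_position: int
    target_gene_id: str
    mode: str
    p_value: float

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise FormatError(f"ASM pair {self.snp_id}: mode must be 'cis' or 'trans', got {self.mode!r}")
        for chrom, what in ((self.snp_chromosome, "SNP"), (self.cpg_chromosome, "CpG")):
            if chrom not in AUTOSOMES:
                raise FormatError(f"ASM pair {self.snp_id}: {what} chromosome must be an autosome")
        if self.snp_position < 1 or self.cpg_position < 1:
            raise FormatError(f"ASM pair {self.snp_id}: positions must be >= 1")
        _check_p(self.p_value, f"ASM pair {self.snp_id}")
        if self.mode == "cis":
            if self.snp_chromosome != self.cpg_chromosome:
                raise FormatError(f"ASM pair {self.snp_id}: cis pair on different chromosomes")
            if abs(self.snp_position - self.cpg_position) > CIS_WINDOW_BP:
                raise FormatError(
                    f"ASM pair {self.snp_id}: cis distance "
                    f"{abs(self.snp_position - self.cpg_position)} exceeds {CIS_WINDOW_BP} bp"
                )


@dataclass(frozen=True)
class Pathway:
    """A named gene set."""

    name: str
    source: str
    gene_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise FormatError(f"Pathway {self.name}: gene set must be non-empty")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ReadStats:
    """Row-drop accounting for a reader call."""

    n_read: int = 0
    n_dropped_na: int = 0
    n_dropped_nonautosomal: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_read - self.n_dropped_na - self.n_dropped_nonautosomal


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_assoc(path, stats: Optional[ReadStats] = None) -> list[SnpRecord]:
    """Read a PLINK ``.assoc``-style whitespace-delimited table.

    Requires header columns ``CHR``, ``SNP``, ``BP``, ``P``; ``CHISQ`` is
    optional.  Rows with ``P == NA`` and non-autosomal rows are dropped
    (counts logged, and recorded in *stats* when given).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    for col in ("CHR", "SNP", "BP", "P"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    has_chisq = "CHISQ" in df.columns

    records: list[SnpRecord] = []
    seen: set[str] = set()
    n_na = n_nonauto = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        p_raw = str(getattr(row, "P")).strip()
        if p_raw.upper() in _NA_TOKENS:
            n_na += 1
            continue
        try:
            p = float(p_raw)
        except ValueError:
            raise FormatError(f"{path}:{i}: unparsable P value {p_raw!r}") from None
        chrom = normalize_chromosome(getattr(row, "CHR"))
        if chrom is None:
            n_nonauto += 1
            continue
        snp_id = str(getattr(row, "SNP"))
        if snp_id in seen:
            raise FormatError(f"{path}:{i}: duplicate SNP id {snp_id!r}")
        seen.add(snp_id)
        chisq = None
        if has_chisq:
            c_raw = str(getattr(row, "CHISQ")).strip()
            if c_raw.upper() not in _NA_TOKENS:
                chisq = float(c_raw)
        try:
            bp = int(getattr(row, "BP"))
        except ValueError:
            raise FormatError(f"{path}:{i}: unparsable BP value") from None
        records.append(SnpRecord(snp_id, chrom, bp, p, chisq))

    if n_na:
        log.info("read_assoc(%s): dropped %d rows with P=NA", path, n_na)
    if n_nonauto:
        log.info("read_assoc(%s): dropped %d non-autosomal rows", path, n_nonauto)
    if stats is not None:
        stats.n_read = len(df)
        stats.n_dropped_na = n_na
        stats.n_dropped_nonautosomal = n_nonauto
    return records


def read_gene_table(path, stats: Optional[ReadStats] = None) -> list[GeneRecord]:
    """Read a headerless BED4 gene table (chrom, start, end, name).

    BED intervals are 0-based half-open; the returned records are 1-based
    inclusive (start+1, end).  Duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: BED4 requires 4 columns, found {df.shape[1]}")
    records: list[GeneRecord] = []
    seen: set[str] = set()
    n_nonauto = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        start, end = int(row[1]), int(row[2])
        name = str(row[3])
        if start >= end:
            raise FormatError(f"{path}:{i}: empty or inverted BED interval [{start}, {end}) for {name}")
        if name in seen:
            raise FormatError(f"{path}:{i}: duplicate gene id {name!r}")
        chrom = normalize_chromosome(row[0])
        if chrom is None:
            n_nonauto += 1
            continue
        seen.add(name)
        records.append(GeneRecord(name, chrom, start + 1, end))
    if n_nonauto:
        log.info("read_gene_table(%s): dropped %d non-autosomal rows", path, n_nonauto)
    if stats is not None:
        stats.n_read = len(df)
        stats.n_dropped_nonautosomal = n_nonauto
    return records


ASM_COLUMNS = (
    "snp_id",
    "snp_chromosome",
    "snp_position",
    "cpg_chromosome",
    "cpg_position",
    "target_gene_id",
    "mode",
    "p_value",
)


def read_asm_pairs(path, stats: Optional[ReadStats] = None) -> list[AsmPair]:
    """Read a tab-delimited SNP-CpG pair table.

    All :class:`AsmPair` invariants are enforced; a cis pair violating the
    1 Mb distance bound is a format error.  Non-autosomal pairs are
    dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ASM_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    pairs: list[AsmPair] = []
    n_nonauto = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        snp_chrom = normalize_chromosome(getattr(row, "snp_chromosome"))
        cpg_chrom = normalize_chromosome(getattr(row, "cpg_chromosome"))
        if snp_chrom is None or cpg_chrom is None:
            n_nonauto += 1
            continue
        try:
            pairs.append(
                AsmPair(
                    snp_id=str(getattr(row, "snp_id")),
                    snp_chromosome=snp_chrom,
                    snp_position=int(getattr(row, "snp_position")),
                    cpg_chromosome=cpg_chrom,
                    cpg_position=int(getattr(row, "cpg_position")),
                    target_gene_id=str(getattr(row, "target_gene_id")),
                    mode=str(getattr(row, "mode")).strip().lower(),
                    p_value=float(getattr(row, "p_value")),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from None
    if n_nonauto:
        log.info("read_asm_pairs(%s): dropped %d non-autosomal pairs", path, n_nonauto)
    if stats is not None:
        stats.n_read = len(df)
        stats.n_dropped_nonautosomal = n_nonauto
    return pairs


def filter_asm_pairs(
    pairs: Sequence[AsmPair], cis_alpha: float = 0.05, trans_alpha: float = 0.05
) -> list[AsmPair]:
    """Keep cis pairs with p < *cis_alpha* and trans pairs with p < *trans_alpha*.

    Both inequalities are strict; input order is preserved.  The filter is
    idempotent, so it is safe to apply to an already-filtered list.
    """
    for alpha, name in ((cis_alpha, "cis_alpha"), (trans_alpha, "trans_alpha")):
        if not (0.0 < alpha < 1.0):
            raise ValueError(f"{name} must be in (0, 1), got {alpha}")
    return [
        p
        for p in pairs
        if (p.mode == "cis" and p.p_value < cis_alpha)
        or (p.mode == "trans" and p.p_value < trans_alpha)
    ]


def read_gmt(path) -> list[Pathway]:
    """Read an MSigDB-style GMT file (name, description, genes...).

    Duplicate gene symbols within a line are deduplicated; pathway names
    are inferred sources when the name carries a known prefix (``GO_``,
    ``KEGG_``, ...), else the GMT description field is used.
    """
    pathways: list[Pathway] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{i}: GMT line needs >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in seen:
                raise FormatError(f"{path}:{i}: duplicate pathway name {name!r}")
            seen.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{i}: pathway {name!r} has an empty gene list")
            source = _infer_source(name, desc)
            pathways.append(Pathway(name=name, source=source, gene_ids=genes))
    return pathways


_SOURCE_PREFIXES = ("GO", "KEGG", "REACTOME", "BIOCARTA", "PID", "WP")


def _infer_source(name: str, desc: str) -> str:
    head = name.split("_", 1)[0].upper()
    if head in _SOURCE_PREFIXES:
        return head
    return desc if desc else "literature"


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(x: object) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return format(x, ".12g")
    return str(x)


def write_results(path, results: Sequence) -> None:
    """Write the pathway results table as TSV.

    One row per pathway; per-method (gsea/sumst/sumsq) and per-mode
    (weighted/unweighted) blocks of raw statistic, empirical p and BH p.
    Rows are ordered by ascending best BH p, ties broken by name.
    """
    if not results:
        raise ValueError("write_results: results must be non-empty")

    methods = ("gsea", "sumst", "sumsq")
    modes = ("weighted", "unweighted")
    header = ["pathway", "source", "total_genes", "genes_on_list", "pct_asm_genes"]
    for method in methods:
        for mode in modes:
            header += [f"{method}_{mode}_stat", f"{method}_{mode}_p", f"{method}_{mode}_bh"]

    def best_bh(r) -> float:
        vals = [s.bh_p for s in r.stats.values() if s.bh_p is not None]
        return min(vals) if vals else 2.0

    ordered = sorted(results, key=lambda r: (best_bh(r), r.pathway_name))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for r in ordered:
            row = [r.pathway_name, r.source, r.total_genes, r.genes_on_list, r.pct_asm]
            for method in methods:
                for mode in modes:
                    s = r.stats.get((method, mode))
                    if s is None:
                        row += [None, None, None]
                    else:
                        row += [s.raw_stat, s.empirical_p, s.bh_p]
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def write_assoc(path, snps: Iterable[SnpRecord]) -> None:
    """Write SNP records as a PLINK-style ``.assoc`` table."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("CHR SNP BP P CHISQ\n")
        for s in snps:
            fh.write(
                f"{s.chromosome} {s.snp_id} {s.position} {_fmt(s.p_value)} "
                f"{_fmt(s.chi_square)}\n"
            )


def write_gene_table(path, genes: Iterable[GeneRecord]) -> None:
    """Write gene records as BED4 (back to 0-based half-open)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(f"chr{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


def write_asm_pairs(path, pairs: Iterable[AsmPair]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ASM_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                "\t".join(
                    _fmt(x)
                    for x in (
                        p.snp_id,
                        p.snp_chromosome,
                        p.snp_position,
                        p.cpg_chromosome,
                        p.cpg_position,
                        p.target_gene_id,
                        p.mode,
                        p.p_value,
                    )
                )
                + "\n"
            )


def write_gmt(path, pathways: Iterable[Pathway]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pw in pathways:
            genes = "\t".join(sorted(pw.gene_ids))
            fh.write(f"{pw.name}\t{pw.source}\t{genes}\n")


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
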