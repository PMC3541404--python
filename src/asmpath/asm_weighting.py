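"""Per-pathway weights for the ASM and non-ASM gene subsets.

For each pathway, the proportions of "informative" genes in the ASM
subset (R_n = k_n/n) and non-ASM subset (R_m = k_m/m) are combined via
their harmonic average H = 2/(1/R_n + 1/R_m):

* if R_n > R_m (both positive), the subsets are weighted R_n/H and R_m/H;
* if the non-ASM subset has no informative gene while the ASM subset
  does, the ASM subset gets an integer weight 1..6 binned on R_n at
  cutoffs 0.1, 0.3, 0.5, 0.7, 0.9 and the non-ASM subset weight 1;
* otherwise both subsets get weight 1.

Pathways that are entirely ASM or entirely non-ASM carry no contrast and
also get equal weights (branch ``degenerate_equal``).

Proportions are kept as exact :class:`fractions.Fraction` values so H
and the weights are exact for small counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Real
from typing import Optional

from .errors import ContractError

BRANCH_HARMONIC = "harmonic"
BRANCH_BINNED = "binned_no_nonasm_informative"
BRANCH_EQUAL = "equal"
BRANCH_DEGENERATE = "degenerate_equal"

#: left-closed bin edges for the 1..6 integer weight
BIN_CUTOFFS = (Fraction(1, 10), Fraction(3, 10), Fraction(5, 10), Fraction(7, 10), Fraction(9, 10))


@dataclass(frozen=True)
class PathwayWeights:
    """Weights for one pathway's ASM/non-ASM gene subsets.

    ``R_n``, ``R_m`` and ``H`` are ``None`` where undefined (empty subset,
    or H when either proportion is zero).
    """

    pathway_name: str
    n: int
    m: int
    k_n: int
    k_m: int
    R_n: Optional[Fraction]
    R_m: Optional[Fraction]
    H: Optional[Fraction]
    w_asm: Fraction
    w_nonasm: Fraction
    rule_branch: str


def harmonic_average(r_n, r_m):
    """Harmonic average 2/(1/r_n + 1/r_m) of two positive proportions.

    Exact for :class:`~fractions.Fraction` inputs; lies between
    min(r_n, r_m) and max(r_n, r_m).
    """
    if not (r_n > 0 and r_m > 0):
        raise ValueError(f"harmonic_average requires positive arguments, got {r_n}, {r_m}")
    return 2 * r_n * r_m / (r_n + r_m)


def binned_weight(prop) -> int:
    """Integer weight 1..6 for an informative-gene proportion in (0, 1].

    Bins are left-closed on the printed cutoffs:
    [0, 0.1) -> 1, [0.1, 0.3) -> 2, [0.3, 0.5) -> 3,
    [0.5, 0.7) -> 4, [0.7, 0.9) -> 5, [0.9, 1] -> 6.
    """
    if not isinstance(prop, (Real, Fraction)) or not (0 < prop <= 1):
        raise ValueError(f"binned_weight requires prop in (0, 1], got {prop!r}")
    if isinstance(prop, float):
        # snap binary floats (0.3 -> 3/10) so decimal cutoffs compare exactly
        prop = Fraction(prop).limit_denominator(10**6)
    w = 1
    for cut in BIN_CUTOFFS:
        if prop >= cut:
            w += 1
    return w


def pathway_weights(n: int, m: int, k_n: int, k_m: int, pathway_name: str = "") -> PathwayWeights:
    """Compute subset weights from subset sizes and informative counts.

    Branch order: (i) one subset empty -> equal weights, flagged
    ``degenerate_equal``; (ii) no informative non-ASM gene but some
    informative ASM gene -> binned ASM weight; (iii) R_n > R_m ->
    harmonic weights (R_n/H, R_m/H); (iv) otherwise equal weights.
    """
    for label, k, total in (("k_n", k_n, n), ("k_m", k_m, m)):
        if not (0 <= k <= total):
            raise ContractError(f"pathway_weights: need 0 <= {label} <= subset size, got {k}/{total}")
    if n + m < 1:
        raise ContractError("pathway_weights: pathway has no genes")

    one = Fraction(1)
    if n == 0 or m == 0:
        r_n = Fraction(k_n, n) if n else None
        r_m = Fraction(k_m, m) if m else None
        return PathwayWeights(pathway_name, n, m, k_n, k_m, r_n, r_m, None, one, one, BRANCH_DEGENERATE)

    r_n = Fraction(k_n, n)
    r_m = Fraction(k_m, m)
    h = harmonic_average(r_n, r_m) if (k_n > 0 and k_m > 0) else None

    if k_m == 0 and k_n > 0:
        return PathwayWeights(
            pathway_name, n, m, k_n, k_m, r_n, r_m, None,
            Fraction(binned_weight(r_n)), one, BRANCH_BINNED,
        )
    if r_n > r_m:
        assert h is not None
        return PathwayWeights(pathway_name, n, m, k_n, k_m, r_n, r_m, h, r_n / h, r_m / h, BRANCH_HARMONIC)
    return PathwayWeights(pathway_name, n, m, k_n, k_m, r_n, r_m, h, one, one, BRANCH_EQUAL)


def write_weights_table(path, weights_list) -> None:
    """Write one row per pathway: counts, proportions, H, weights, branch."""

    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, Fraction):
            return format(float(x), ".12g")
        return str(x)

    header = ["pathway", "n", "m", "k_n", "k_m", "R_n", "R_m", "H", "w_asm", "w_nonasm", "branch"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for w in weights_list:
            row = [w.pathway_name, w.n, w.m, w.k_n, w.k_m, w.R_n, w.R_m, w.H, w.w_asm, w.w_nonasm, w.rule_branch]
            fh.write("\t".join(fmt(x) for x in row) + "\n")
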