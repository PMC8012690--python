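"""Per-drug activity scores from intrinsic clearance.

An allele's activity score is its CLint divided by the CLint of the *4
reference (so *4 scores exactly 1 and a score of 0.5 means a 50% reduction
in intrinsic clearance).  A diploid genotype's score (AS) is the sum of its
two allele scores: *4/*4 = 2 for every drug, and scores are substrate
specific because the CLint ratios are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

from .errors import MissingReferenceError, UnsupportedAlleleError
from .star_allele import (
    REFERENCE_ALLELE,
    Diplotype,
    allele_sort_key,
    canonical_label,
)

#: the ten diploid genotypes over {*4, *5, *6, *7}, canonical order
GENOTYPES = tuple(
    canonical_label(a, b)
    for a, b in combinations_with_replacement(("*4", "*5", "*6", "*7"), 2)
)


def round_half_up(x: float, decimals: int = 3) -> float:
    """Report-style rounding (half away from zero), e.g. 0.0625 -> 0.063."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def allele_activity_score(clint_allele: float, clint_ref: float) -> float:
    """CLint ratio to the *4 reference."""
    if clint_ref <= 0:
        raise MissingReferenceError("reference CLint must be > 0")
    return clint_allele / clint_ref


@dataclass
class ActivityScoreTable:
    """Allele scores (ratio to *4) and genotype scores (sum) for one drug."""

    drug: str
    allele_scores: dict = field(default_factory=dict)
    genotype_scores: dict = field(default_factory=dict)

    def __post_init__(self):
        ref = self.allele_scores.get(REFERENCE_ALLELE)
        if ref is None or abs(ref - 1.0) > 1e-12:
            raise MissingReferenceError(
                f"allele_scores[{REFERENCE_ALLELE}] must be exactly 1")

    def rounded(self, decimals: int = 3) -> dict:
        """Genotype scores rounded half-up for reports."""
        return {g: round_half_up(s, decimals)
                for g, s in self.genotype_scores.items()}


def genotype_activity_score(diplotype: Diplotype | str,
                            table: ActivityScoreTable) -> float:
    """Sum of both allele scores; symmetric in allele order."""
    label = diplotype if isinstance(diplotype, str) else diplotype.label
    a, b = label.split("/")
    missing = [x for x in (a, b) if x not in table.allele_scores]
    if missing:
        raise UnsupportedAlleleError(
            f"no kinetic data for allele(s) {', '.join(missing)} "
            f"({table.drug}); cannot score {canonical_label(a, b)}")
    return table.allele_scores[a] + table.allele_scores[b]


def build_score_table(clints: Mapping[str, float], drug: str,
                      alleles: Sequence[str] | None = None) -> ActivityScoreTable:
    """Build the full allele + genotype score table for one drug.

    ``clints`` maps allele name to mean CLint (per-replicate ratio means
    when raw data are available, printed means when rebuilding from a
    published table).  All unordered genotype pairs over the available
    alleles are scored; full precision is retained internally and
    :meth:`ActivityScoreTable.rounded` applies report rounding.
    """
    if REFERENCE_ALLELE not in clints:
        raise MissingReferenceError(
            f"CLint for the {REFERENCE_ALLELE} reference is required")
    ref = clints[REFERENCE_ALLELE]
    if ref <= 0:
        raise MissingReferenceError("reference CLint must be > 0")
    names = sorted(alleles if alleles is not None else clints,
                   key=allele_sort_key)
    missing = [a for a in names if a not in clints]
    if missing:
        raise UnsupportedAlleleError(
            f"no kinetic data for allele(s) {', '.join(missing)} ({drug})")
    allele_scores = {a: allele_activity_score(clints[a], ref) for a in names}
    genotype_scores = {
        canonical_label(a, b): allele_scores[a] + allele_scores[b]
        for a, b in combinations_with_replacement(names, 2)
    }
    return ActivityScoreTable(drug, allele_scores, genotype_scores)
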