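"""Worldwide acetylator-phenotype distributions from cohort genotype counts.

Combines per-population NAT2 genotype counts (e.g. a Japanese resequencing
cohort and the five 1000 Genomes super-populations) with per-drug
phenotype assignments to produce phenotype frequency tables, and
summarizes each phenotype's frequency range across drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .activity_score import round_half_up
from .errors import UnlabelledGenotypeError
from .phenotype_cluster import PHENOTYPE_ORDER, PhenotypeAssignment
from .star_allele import Diplotype, allele_sort_key

logger = logging.getLogger(__name__)


def _genotype_key(label: str) -> tuple:
    a, b = label.split("/")
    return (allele_sort_key(a), allele_sort_key(b))


@dataclass
class PopulationCohort:
    """Diplotype counts for one population."""

    population: str
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = {g: c for g, c in self.counts.items() if c < 0}
        if bad:
            raise ValueError(f"negative counts: {bad}")
        self.counts = {g: int(self.counts[g])
                       for g in sorted(self.counts, key=_genotype_key)}

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict:
        n = self.n
        return {g: c / n for g, c in self.counts.items()}

    @classmethod
    def from_diplotypes(cls, population: str,
                        diplotypes: Iterable[Diplotype]) -> "PopulationCohort":
        counts: dict = {}
        for d in diplotypes:
            counts[d.label] = counts.get(d.label, 0) + 1
        return cls(population, counts)


def tabulate_genotype_frequencies(
    source: Mapping[str, int] | Sequence[Diplotype],
    population: str = "cohort",
) -> PopulationCohort:
    """Build a cohort from genotype counts or a list of called diplotypes."""
    if isinstance(source, Mapping):
        if not source:
            raise ValueError("empty count table")
        return PopulationCohort(population, dict(source))
    diplotypes = list(source)
    if not diplotypes:
        raise ValueError("empty diplotype list")
    return PopulationCohort.from_diplotypes(population, diplotypes)


@dataclass
class PhenotypeDistribution:
    """Phenotype counts and proportions for one population x drug."""

    population: str
    drug: str
    counts: dict
    n: int

    @property
    def frequencies(self) -> dict:
        return {p: c / self.n for p, c in self.counts.items()}

    def percentages(self, decimals: int | None = 2) -> dict:
        """Phenotype percentages, rounded half-up at report time only."""
        pct = {p: 100.0 * c / self.n for p, c in self.counts.items()}
        if decimals is None:
            return pct
        return {p: round_half_up(x, decimals) for p, x in pct.items()}


def phenotype_frequencies(cohort: PopulationCohort,
                          assignment: PhenotypeAssignment,
                          ) -> PhenotypeDistribution:
    """Aggregate a cohort's genotype counts into phenotype proportions."""
    unlabelled = [g for g in cohort.counts if g not in assignment.labels]
    if unlabelled:
        raise UnlabelledGenotypeError(
            f"{cohort.population}/{assignment.drug}: no phenotype label for "
            f"genotype(s) {', '.join(unlabelled)}")
    counts = {p: 0 for p in PHENOTYPE_ORDER if p in assignment.labels.values()}
    for g, c in cohort.counts.items():
        counts[assignment.labels[g]] += c
    return PhenotypeDistribution(cohort.population, assignment.drug,
                                 counts, cohort.n)


def frequency_range_summary(distributions: Sequence[PhenotypeDistribution],
                            phenotype: str) -> dict:
    """(min%, max%) of one phenotype across drugs, per population.

    Populations where the phenotype never appears are omitted with a
    warning (an empty range).
    """
    if not distributions:
        raise ValueError("no distributions")
    per_pop: dict = {}
    for dist in distributions:
        pct = dist.percentages(decimals=None)
        if phenotype in pct:
            per_pop.setdefault(dist.population, []).append(pct[phenotype])
    missing = {d.population for d in distributions} - set(per_pop)
    if missing:
        logger.warning("phenotype %s absent for all drugs in population(s): %s",
                       phenotype, ", ".join(sorted(missing)))
    return {pop: (min(vals), max(vals)) for pop, vals in per_pop.items()}
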