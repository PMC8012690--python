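#!/usr/bin/env python
"""Worldwide distribution of substrate-specific NAT2 phenotypes.

Combines the cohort genotype counts with the per-drug phenotype
assignments (from 04) to tabulate phenotype percentages per population
and drug, plus each phenotype's range across the eight drugs.  Writes
``results/phenotype_distribution.tsv`` and
``results/phenotype_ranges.tsv``.
"""

from pathlib import Path

from nat2kit import data as refdata
from nat2kit.io import write_distributions
from nat2kit.kinetics import DRUGS
from nat2kit.phenotype_cluster import PHENOTYPE_ORDER, classify_scores
from nat2kit.population_distribution import (
    frequency_range_summary,
    phenotype_frequencies,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    scores, _ = refdata.load_reference_activity_scores()
    cohorts = refdata.load_genotype_counts()
    assignments = {d: classify_scores(scores[d], d)[1] for d in DRUGS}

    distributions = [phenotype_frequencies(cohorts[pop], assignments[drug])
                     for pop in refdata.POPULATIONS for drug in DRUGS]
    write_distributions(distributions, OUT / "phenotype_distribution.tsv")

    with open(OUT / "phenotype_ranges.tsv", "w") as fh:
        fh.write("population\tphenotype\tmin_percent\tmax_percent\n")
        for phen in PHENOTYPE_ORDER:
            ranges = frequency_range_summary(distributions, phen)
            for pop in refdata.POPULATIONS:
                if pop in ranges:
                    lo, hi = ranges[pop]
                    fh.write(f"{pop}\t{phen}\t{lo:.2f}\t{hi:.2f}\n")

    ra = frequency_range_summary(distributions, "RA")
    print("rapid acetylators across the 8 drugs: "
          f"Japanese {ra['Japanese'][0]:.2f}-{ra['Japanese'][1]:.2f}% vs "
          f"EUR {ra['EUR'][0]:.2f}-{ra['EUR'][1]:.2f}%")
    for pop in ("Japanese", "EAS", "AFR", "EUR"):
        usa = phenotype_frequencies(cohorts[pop],
                                    assignments["SMZ"]).percentages()["USA"]
        print(f"SMZ ultra-slow acetylators in {pop}: {usa:.2f}%")
    print("the USA burden for sulfamethazine is an order of magnitude "
          "higher outside East Asia")
    print(f"wrote {OUT / 'phenotype_distribution.tsv'}")
    print(f"wrote {OUT / 'phenotype_ranges.tsv'}")


if __name__ == "__main__":
    main()
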