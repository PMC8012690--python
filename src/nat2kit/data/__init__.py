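"""Published reference datasets shipped with the package.

Three small tab-separated tables transcribed from the source study's
printed results:

* ``genotype_counts.tsv`` — NAT2 diplotype counts for 990 Japanese
  individuals and the five 1000 Genomes super-populations (AFR, AMR,
  EAS, EUR, SAS).
* ``kinetic_parameters.tsv`` — per allele x drug Michaelis-Menten
  parameters (Km in uM, Vmax in relative peak area/min/mg protein,
  CLint = Vmax/Km), mean +/- SE of four independent experiments, with
  Tukey significance letters.
* ``activity_scores.tsv`` — the published per-drug genotype activity
  scores and predicted acetylator phenotypes (the reproduction surface
  for the clustering stage).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..population_distribution import PopulationCohort

#: populations in reporting order
POPULATIONS = ("Japanese", "AFR", "AMR", "EAS", "EUR", "SAS")


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_genotype_counts() -> dict:
    """Cohort genotype counts: population -> :class:`PopulationCohort`."""
    df = _read("genotype_counts.tsv")
    return {
        pop: PopulationCohort(pop, dict(zip(grp["genotype"], grp["count"])))
        for pop, grp in df.groupby("population", sort=False)
    }


def load_kinetic_params() -> pd.DataFrame:
    """Kinetic parameter table indexed by (drug, allele)."""
    df = _read("kinetic_parameters.tsv")
    return df.set_index(["drug", "allele"])


def kinetic_truth() -> dict:
    """(drug, allele) -> (Km, Vmax) means, e.g. for simulation truth."""
    df = load_kinetic_params()
    return {idx: (float(row["km_mean"]), float(row["vmax_mean"]))
            for idx, row in df.iterrows()}


def clint_means() -> dict:
    """drug -> {allele -> published mean CLint}."""
    df = load_kinetic_params()
    out: dict = {}
    for (drug, allele), row in df.iterrows():
        out.setdefault(drug, {})[allele] = float(row["clint_mean"])
    return out


def load_reference_activity_scores() -> tuple[dict, dict]:
    """Published per-drug genotype scores and phenotype labels.

    Returns ``(scores, phenotypes)``: both keyed drug -> genotype.
    """
    df = _read("activity_scores.tsv")
    scores: dict = {}
    phenotypes: dict = {}
    for _, row in df.iterrows():
        scores.setdefault(row["drug"], {})[row["genotype"]] = float(
            row["activity_score"])
        phenotypes.setdefault(row["drug"], {})[row["genotype"]] = row["phenotype"]
    return scores, phenotypes
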