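"""Readers, writers, configuration and the end-to-end pipeline.

All tabular files are tab-separated UTF-8 with one header row; genotype
labels use the canonical ``*a/*b`` form.  Reports carry rounded values;
a JSON companion carries full precision.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import data as _data
from .activity_score import ActivityScoreTable, build_score_table, round_half_up
from .errors import ConfigError, PipelineStageError, VCFFormatError
from .kinetics import DRUGS, fit_dataset, summarize_kinetics
from .phenotype_cluster import PhenotypeAssignment, classify_scores
from .population_distribution import (
    PhenotypeDistribution,
    PopulationCohort,
    phenotype_frequencies,
)
from .star_allele import (
    AlleleDefinitionSet,
    Diplotype,
    GenotypeCall,
    call_diplotype,
    em_haplotype_frequencies,
    load_allele_definitions,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- genotypes

def read_vcf(path: str | Path,
             definitions: AlleleDefinitionSet) -> list:
    """Read per-sample dosages at the signature sites from a VCF.

    Records are matched to signature variants by the ID column (rsID);
    dosage is the alt-allele count in the GT field (phase is ignored —
    the EM handles phasing).  Multi-allelic signature records are
    rejected; other sites are skipped with a count in the log.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VCFFormatError(f"{path}: no samples")
    dosages: dict = {s: {} for s in samples}
    wanted = set(definitions.sites)
    n_skipped = 0
    n_used = 0
    for record in vcf:
        rsid = record.ID
        if rsid not in wanted:
            n_skipped += 1
            continue
        if len(record.ALT) != 1:
            raise VCFFormatError(
                f"{path}: multi-allelic record at signature site {rsid}")
        n_used += 1
        for sample, gt in zip(samples, record.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles:
                continue  # missing genotype -> missing dosage
            dosages[sample][rsid] = sum(1 for a in alleles if a > 0)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-signature record(s)", n_skipped)
    if n_used == 0:
        raise VCFFormatError(f"{path}: no usable sites "
                             f"(expected IDs {', '.join(definitions.sites)})")
    return [GenotypeCall(s, dosages[s]) for s in samples]


def write_vcf(calls: Sequence[GenotypeCall],
              definitions: AlleleDefinitionSet, path: str | Path) -> None:
    """Write dosages as an unphased single-sample-per-column VCF."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    chroms = {v.chrom or "8" for v in definitions.variants}
    for c in sorted(chroms):
        lines.append(f"##contig=<ID={c}>")
    ids = [c.individual_id for c in calls]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids))
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    for i, v in enumerate(definitions.variants):
        row = [v.chrom or "8", str(v.pos or i + 1), v.rsid,
               v.ref_base, v.alt_base, ".", "PASS", ".", "GT"]
        row += [gt_of[c.dosages.get(v.rsid)] for c in calls]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dosage_tsv(path: str | Path) -> list:
    """Dosage matrix: rows = individuals, columns = rsIDs; blank = missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    calls = []
    for ind, row in df.iterrows():
        dosages = {r: int(d) for r, d in row.items() if pd.notna(d)}
        calls.append(GenotypeCall(str(ind), dosages))
    return calls


def write_dosage_tsv(calls: Sequence[GenotypeCall], path: str | Path) -> None:
    sites = sorted({r for c in calls for r in c.dosages})
    df = pd.DataFrame(
        [[c.dosages.get(s) for s in sites] for c in calls],
        index=pd.Index([c.individual_id for c in calls], name="individual_id"),
        columns=sites,
    )
    df.to_csv(path, sep="\t")


def write_diplotype_calls(diplotypes: Mapping[str, Diplotype],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tdiplotype\tambiguous\tposterior\n")
        for ind, d in diplotypes.items():
            fh.write(f"{ind}\t{d.label}\t{str(d.ambiguous).lower()}"
                     f"\t{d.posterior:.6g}\n")


def read_diplotype_calls(path: str | Path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["individual_id"]): Diplotype.from_label(
            r["diplotype"], ambiguous=bool(r["ambiguous"]),
            posterior=float(r["posterior"]))
        for _, r in df.iterrows()
    }


# ----------------------------------------------------------------- kinetics

def read_reactions_tsv(path: str | Path) -> pd.DataFrame:
    """Reaction table: drug, allele, replicate, conc_um, velocity."""
    df = pd.read_csv(path, sep="\t")
    required = {"drug", "allele", "replicate", "conc_um", "velocity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_reactions_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_kinetic_params_tsv(path: str | Path) -> pd.DataFrame:
    """Summary kinetic-parameter table as written by the fit stage."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"drug", "allele", "clint_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df.set_index(["drug", "allele"])


def write_kinetic_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- scores

def write_score_table(tables: Mapping[str, ActivityScoreTable],
                      path: str | Path, decimals: int = 3) -> None:
    """Wide genotype x drug table of rounded activity scores."""
    drugs = [d for d in DRUGS if d in tables] + [
        d for d in tables if d not in DRUGS]
    genotypes = list(next(iter(tables.values())).genotype_scores)
    with open(path, "w") as fh:
        fh.write("genotype\t" + "\t".join(drugs) + "\n")
        for g in genotypes:
            cells = [f"{tables[d].rounded(decimals)[g]:.{decimals}f}"
                     for d in drugs]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def read_score_table(path: str | Path) -> dict:
    """drug -> {genotype -> score} from a wide score table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {drug: {g: float(s) for g, s in df[drug].items()}
            for drug in df.columns}


def write_assignments(assignments: Mapping[str, PhenotypeAssignment],
                      scores: Mapping[str, Mapping[str, float]],
                      path: str | Path, decimals: int = 3) -> None:
    with open(path, "w") as fh:
        fh.write("drug\tgenotype\tactivity_score\tphenotype\tk\n")
        for drug, a in assignments.items():
            for g, label in a.labels.items():
                fh.write(f"{drug}\t{g}\t"
                         f"{round_half_up(scores[drug][g], decimals):.{decimals}f}"
                         f"\t{label}\t{a.k}\n")


def read_assignments(path: str | Path) -> dict:
    """drug -> :class:`PhenotypeAssignment` from an assignment table."""
    df = pd.read_csv(path, sep="\t")
    out: dict = {}
    for drug, grp in df.groupby("drug", sort=False):
        labels = dict(zip(grp["genotype"], grp["phenotype"]))
        out[drug] = PhenotypeAssignment(drug, int(grp["k"].iloc[0]), labels)
    return out


def write_distributions(distributions: Sequence[PhenotypeDistribution],
                        path: str | Path, decimals: int = 2) -> None:
    with open(path, "w") as fh:
        fh.write("population\tdrug\tphenotype\tcount\tpercent\n")
        for dist in distributions:
            pct = dist.percentages(decimals)
            for phen, count in dist.counts.items():
                fh.write(f"{dist.population}\t{dist.drug}\t{phen}\t{count}"
                         f"\t{pct[phen]:.{decimals}f}\n")


def read_cohort_counts_tsv(path: str | Path) -> dict:
    """population -> :class:`PopulationCohort` from a long count table."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "genotype", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return {
        pop: PopulationCohort(pop, dict(zip(grp["genotype"], grp["count"])))
        for pop, grp in df.groupby("population", sort=False)
    }


# ------------------------------------------------------------ configuration

_CONFIG_FIELDS = {
    "definition_set", "fitting_method", "k_candidates", "score_decimals",
    "percent_decimals", "seed", "genotypes_vcf", "dosages_tsv",
    "cohort_counts", "reactions_tsv", "kinetic_params", "out_dir",
}


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Genotypes come from exactly one of ``genotypes_vcf`` / ``dosages_tsv``
    / ``cohort_counts``; kinetics from one of ``reactions_tsv`` /
    ``kinetic_params``.  The string ``"builtin"`` selects the shipped
    reference tables for ``cohort_counts`` or ``kinetic_params``.
    """

    out_dir: str
    definition_set: str = "NAT2"
    fitting_method: str = "lineweaver_burk"
    k_candidates: tuple = (3, 4)
    score_decimals: int = 3
    percent_decimals: int = 2
    seed: int | None = None
    genotypes_vcf: str | None = None
    dosages_tsv: str | None = None
    cohort_counts: str | None = None
    reactions_tsv: str | None = None
    kinetic_params: str | None = None

    def __post_init__(self):
        problems = []
        if self.fitting_method not in ("lineweaver_burk", "nls"):
            problems.append(f"unknown fitting_method {self.fitting_method!r}")
        geno = [x for x in (self.genotypes_vcf, self.dosages_tsv,
                            self.cohort_counts) if x]
        if len(geno) != 1:
            problems.append(
                "exactly one of genotypes_vcf/dosages_tsv/cohort_counts "
                f"is required (got {len(geno)})")
        kin = [x for x in (self.reactions_tsv, self.kinetic_params) if x]
        if len(kin) != 1:
            problems.append(
                "exactly one of reactions_tsv/kinetic_params is required "
                f"(got {len(kin)})")
        self.k_candidates = tuple(int(k) for k in self.k_candidates)
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ConfigError(f"unknown key(s): {', '.join(sorted(unknown))}")
        if "out_dir" not in raw:
            raise ConfigError("missing required key: out_dir")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Everything the pipeline produced, plus where it was written."""

    cohorts: dict
    clints: dict
    score_tables: dict
    assignments: dict
    distributions: list
    paths: dict = field(default_factory=dict)
    diplotypes: dict | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """call -> fit -> score -> cluster -> distribute, writing all reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, str(exc)) from exc

    defs = stage("definitions", load_allele_definitions, config.definition_set)

    # --- genotypes -> cohorts
    diplotypes = None
    if config.cohort_counts:
        if config.cohort_counts == "builtin":
            cohorts = stage("cohorts", _data.load_genotype_counts)
        else:
            cohorts = stage("cohorts", read_cohort_counts_tsv,
                            config.cohort_counts)
    else:
        if config.genotypes_vcf:
            calls = stage("read_genotypes", read_vcf, config.genotypes_vcf, defs)
        else:
            calls = stage("read_genotypes", read_dosage_tsv, config.dosages_tsv)
        freqs = stage("em_frequencies", em_haplotype_frequencies, calls,
                      sites=defs.sites)
        diplotypes = {
            c.individual_id: stage("call_diplotypes", call_diplotype,
                                   c, freqs, defs)
            for c in calls if c.individual_id not in freqs.excluded
        }
        paths["calls"] = out / "diplotype_calls.tsv"
        write_diplotype_calls(diplotypes, paths["calls"])
        cohorts = {"cohort": PopulationCohort.from_diplotypes(
            "cohort", diplotypes.values())}

    # --- kinetics -> CLint means per drug x allele
    if config.reactions_tsv:
        reactions = stage("read_reactions", read_reactions_tsv,
                          config.reactions_tsv)
        fits = stage("fit_kinetics", fit_dataset, reactions,
                     method=config.fitting_method)
        summary = stage("summarize_kinetics", summarize_kinetics, fits)
        paths["kinetic_params"] = out / "kinetic_params.tsv"
        write_kinetic_summary(summary, paths["kinetic_params"])
        clints = {
            drug: dict(zip(grp["allele"], grp["clint_mean"]))
            for drug, grp in summary.groupby("drug", sort=False)
        }
    else:
        if config.kinetic_params == "builtin":
            clints = stage("kinetic_params", _data.clint_means)
        else:
            params = stage("kinetic_params", read_kinetic_params_tsv,
                           config.kinetic_params)
            clints = {}
            for (drug, allele), row in params.iterrows():
                clints.setdefault(drug, {})[allele] = float(row["clint_mean"])

    # --- scores
    score_tables = {
        drug: stage("score", build_score_table, clints[drug], drug)
        for drug in clints
    }
    paths["scores"] = out / "activity_scores.tsv"
    write_score_table(score_tables, paths["scores"], config.score_decimals)

    # --- clustering
    assignments: dict = {}
    dendro_lines = []
    for drug, table in score_tables.items():
        dendrogram, assignment = stage(
            "cluster", classify_scores, table.genotype_scores, drug,
            candidates=config.k_candidates)
        assignments[drug] = assignment
        dendro_lines.append(f"# {drug}\n{dendrogram.to_newick()}\n")
    paths["assignments"] = out / "phenotype_assignments.tsv"
    write_assignments(assignments,
                      {d: t.genotype_scores for d, t in score_tables.items()},
                      paths["assignments"], config.score_decimals)
    paths["dendrograms"] = out / "dendrograms.nwk"
    paths["dendrograms"].write_text("".join(dendro_lines))

    # --- distributions
    distributions = [
        stage("distribute", phenotype_frequencies, cohort, assignment)
        for cohort in cohorts.values()
        for assignment in assignments.values()
    ]
    paths["distributions"] = out / "phenotype_distribution.tsv"
    write_distributions(distributions, paths["distributions"],
                        config.percent_decimals)

    # --- full-precision JSON + run log
    payload = {
        "score_tables": {d: t.genotype_scores for d, t in score_tables.items()},
        "assignments": {d: {"k": a.k, "labels": a.labels}
                        for d, a in assignments.items()},
        "distributions": [
            {"population": d.population, "drug": d.drug,
             "frequencies": d.frequencies} for d in distributions
        ],
    }
    paths["results_json"] = out / "results.json"
    paths["results_json"].write_text(json.dumps(payload, indent=2))
    import nat2kit
    log = [
        f"timestamp\t{datetime.now(timezone.utc).isoformat()}",
        f"nat2kit\t{nat2kit.__version__}",
        f"python\t{platform.python_version()}",
        f"numpy\t{np.__version__}",
        f"pandas\t{pd.__version__}",
        f"seed\t{config.seed}",
        f"fitting_method\t{config.fitting_method}",
        f"k_candidates\t{','.join(map(str, config.k_candidates))}",
    ]
    paths["log"] = out / "run_log.tsv"
    paths["log"].write_text("\n".join(log) + "\n")

    return PipelineResult(cohorts, clints, score_tables, assignments,
                          distributions, paths, diplotypes)
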