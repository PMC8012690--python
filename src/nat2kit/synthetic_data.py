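"""Synthetic inputs for every pipeline stage.

Two generators make the whole pipeline testable without any downloads:

* :func:`simulate_cohort_hwe` draws diploid NAT2 genotypes under
  Hardy-Weinberg equilibrium at given star-allele frequencies, emitting
  both the true diplotypes and the implied signature-SNV dosage rows.
* :func:`simulate_kinetic_dataset` generates replicated Michaelis-Menten
  velocity data at given (Km, Vmax) truth over the study's per-drug
  concentration designs, with multiplicative lognormal noise (velocities
  are positive peak-area ratios, so noise scales with the signal; the
  noise factor has mean 1 and coefficient of variation ``cv_noise``).

Both are deterministic given their integer seed; no global random state
is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data as _data
from .star_allele import (
    AlleleDefinitionSet,
    Diplotype,
    GenotypeCall,
    allele_sort_key,
    load_allele_definitions,
)

#: substrate concentration series (uM) per drug, including the 0 blank
DEFAULT_CONCENTRATIONS = {
    "AGT": (0, 0.3, 1, 3, 10, 30, 100, 300, 1000),
    "DDP": (0, 0.1, 0.3, 1, 3, 10, 30, 100, 300),
    "HLZ": (0, 0.003, 0.01, 0.03, 0.1, 0.3, 1, 3, 10),
    "INH": (0, 0.3, 1, 3, 10, 30, 100, 300, 1000),
    "PZ": (0, 0.3, 1, 3, 10, 30, 100, 300, 1000),
    "PA": (0, 0.3, 1, 3, 10, 30, 100, 300, 1000),
    "SMZ": (0, 0.3, 1, 3, 10, 30, 100, 300, 1000),
    "SP": (0, 0.3, 1, 3, 10, 30, 100, 300, 1000),
}


@dataclass
class CohortSpec:
    """Allele frequencies + cohort size + seed for an HWE cohort draw."""

    allele_frequencies: dict
    n_individuals: int
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        freqs = self.allele_frequencies
        if any(f < 0 for f in freqs.values()):
            raise ValueError("allele frequencies must be >= 0")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total!r}, not 1")


@dataclass
class CohortSim:
    """True diplotypes plus the dosage rows a genotyping pipeline would see."""

    diplotypes: list
    calls: list
    spec: CohortSpec


def simulate_cohort_hwe(spec: CohortSpec,
                        definitions: AlleleDefinitionSet | None = None,
                        ) -> CohortSim:
    """Draw a cohort under Hardy-Weinberg equilibrium.

    Each individual draws two alleles i.i.d. from the frequency vector
    (random mating), so genotype *i*/*j* has expected frequency
    p_i . p_j . (2 - delta_ij).
    """
    defs = definitions or load_allele_definitions("NAT2")
    names = sorted(spec.allele_frequencies, key=allele_sort_key)
    unknown = [a for a in names if a not in defs.alleles]
    if unknown:
        raise ValueError(f"allele(s) not in the definition set: {unknown}")
    probs = np.array([spec.allele_frequencies[a] for a in names], dtype=float)
    probs = probs / probs.sum()
    patterns = {a: np.array(defs.allele_pattern(a)) for a in names}

    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(len(names), size=(spec.n_individuals, 2), p=probs)
    diplotypes, calls = [], []
    width = len(str(spec.n_individuals))
    for i, (ia, ib) in enumerate(draws):
        a, b = names[ia], names[ib]
        diplotypes.append(Diplotype(a, b))
        dosage_vec = patterns[a] + patterns[b]
        calls.append(GenotypeCall(
            individual_id=f"sim{i:0{width}d}",
            dosages={s: int(d) for s, d in zip(defs.sites, dosage_vec)},
        ))
    return CohortSim(diplotypes, calls, spec)


@dataclass
class KineticSimSpec:
    """Truth, design and noise level for a simulated kinetics experiment.

    Defaults reproduce the study conditions: the published (Km, Vmax) for
    every allele x drug as truth, the per-drug concentration series, four
    replicates, and 5% CV multiplicative noise.
    """

    true_params: dict = field(default_factory=_data.kinetic_truth)
    concentration_design: dict = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATIONS))
    cv_noise: float = 0.05
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for drug, concs in self.concentration_design.items():
            if any(c < 0 for c in concs):
                raise ValueError(f"negative concentration in design for {drug}")


def simulate_kinetic_dataset(spec: KineticSimSpec) -> pd.DataFrame:
    """Replicated velocity observations on the Michaelis-Menten curve.

    Returns a reaction table (columns ``drug, allele, replicate, conc_um,
    velocity``).  v = Vmax.[S]/(Km+[S]) times a lognormal factor with mean
    1 and CV ``cv_noise``; [S] = 0 blank rows carry velocity 0 exactly.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.cv_noise > 0:
        sigma = float(np.sqrt(np.log1p(spec.cv_noise ** 2)))
        mu = -sigma ** 2 / 2.0  # mean-one noise factor
    rows = []
    for (drug, allele) in sorted(spec.true_params,
                                 key=lambda da: (da[0], allele_sort_key(da[1]))):
        km, vmax = spec.true_params[(drug, allele)]
        concs = np.asarray(spec.concentration_design[drug], dtype=float)
        for rep in range(1, spec.n_replicates + 1):
            v = vmax * concs / (km + concs)
            v[concs == 0] = 0.0
            if spec.cv_noise > 0:
                factors = rng.lognormal(mu, sigma, size=concs.size)
                v = np.where(concs == 0, 0.0, v * factors)
            for c, vel in zip(concs, v):
                rows.append({"drug": drug, "allele": allele, "replicate": rep,
                             "conc_um": float(c), "velocity": float(vel)})
    return pd.DataFrame(rows)
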