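#!/usr/bin/env python
"""Michaelis-Menten parameter recovery under the study conditions.

Simulates four replicate velocity curves for every allele x drug at the
published (Km, Vmax) truth with 5% CV multiplicative noise over the
per-drug concentration designs, fits each replicate by nonlinear least
squares, and summarizes Km, Vmax and CLint (mean +/- SE across
replicates, Tukey letters vs preceding alleles).  Writes
``results/kinetic_params_recovered.tsv``.
"""

from pathlib import Path

from nat2kit import data as refdata
from nat2kit.kinetics import fit_dataset, summarize_kinetics
from nat2kit.synthetic_data import KineticSimSpec, simulate_kinetic_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20210318 % 2 ** 31


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = KineticSimSpec(seed=SEED)  # published truth, 5% CV, 4 replicates
    reactions = simulate_kinetic_dataset(spec)
    fits = fit_dataset(reactions, method="nls")
    summary = summarize_kinetics(fits)
    summary.to_csv(OUT / "kinetic_params_recovered.tsv", sep="\t",
                   index=False, float_format="%.4g")

    truth = refdata.kinetic_truth()
    worst = max(abs(row["km_mean"] - truth[(row["drug"], row["allele"])][0])
                / truth[(row["drug"], row["allele"])][0]
                for _, row in summary.iterrows())
    print(f"simulated {len(reactions)} velocity observations "
          f"({spec.n_replicates} replicates, {100 * spec.cv_noise:.0f}% CV)")
    print(f"worst replicate-averaged Km error across 32 curves: "
          f"{100 * worst:.1f}%")

    # CLint rank order *4 > *5 > *6 must survive the noise for every drug
    ranks_ok = 0
    for drug, grp in summary.groupby("drug"):
        cl = dict(zip(grp["allele"], grp["clint_mean"]))
        ranks_ok += cl["*4"] > cl["*5"] > cl["*6"]
    print(f"CLint rank *4 > *5 > *6 preserved for {ranks_ok}/8 drugs")
    print(f"wrote {OUT / 'kinetic_params_recovered.tsv'}")


if __name__ == "__main__":
    main()
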