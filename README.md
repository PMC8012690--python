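# nat2kit

Arylamine *N*-acetyltransferase 2 (NAT2) acetylates aromatic amines and
hydrazine drugs — isoniazid, hydralazine, sulfamethazine, dapsone and
others — and common *NAT2* star alleles change that capacity enough to
matter clinically (slow acetylators accumulate isoniazid metabolites and
carry a higher risk of drug-induced liver injury). `nat2kit` implements
the full genotype-to-phenotype chain for the four common alleles
(*4 reference; *5, *6, *7 reduced function) and eight substrate drugs
(AGT, DDP, HLZ, INH, PZ, PA, SMZ, SP), for pharmacogeneticists who want
substrate-specific acetylator categories rather than a single
one-size-fits-all classification:

1. **Diplotyping** — *NAT2* star alleles are defined by signature SNVs
   (c.341T>C / rs1801280 → \*5, c.590G>A / rs1799930 → \*6, c.857G>A /
   rs1799931 → \*7). Unphased dosages are resolved into diplotypes by
   enumerating phase configurations and scoring them with haplotype
   frequencies from a standard multilocus EM.
2. **Enzyme kinetics** — per allele × drug, velocity data are fit to
   *v* = *V*max·[S]/(*K*m+[S]) (Lineweaver–Burk or nonlinear least
   squares) and summarized as intrinsic clearance CLint = *V*max/*K*m.
3. **Activity scores** — allele score = CLint/CLint(\*4); a diplotype's
   score (AS) is the sum over its two alleles, so \*4/\*4 = 2 and a score
   of 0.5 means a 50% clearance reduction.
4. **Phenotype categories** — per drug, the ten genotype scores are
   clustered (Ward D2, Euclidean); the cluster count k ∈ {3, 4} is chosen
   by the Krzanowski–Lai index and clusters are labelled, by decreasing
   mean AS, rapid / intermediate / slow (/ ultra-slow) acetylator
   (RA/IA/SA/USA).
5. **Worldwide distribution** — phenotype frequencies per population,
   combining the assignments with shipped genotype counts for 990
   Japanese individuals and the five 1000 Genomes super-populations.

A synthetic-data module generates Hardy–Weinberg cohorts and noisy
kinetic datasets at the published truth, so every stage is testable
without downloads.

## Worked example

```python
>>> from nat2kit import data, classify_scores, phenotype_frequencies
>>> scores, _ = data.load_reference_activity_scores()
>>> dendrogram, smz = classify_scores(scores["SMZ"], "SMZ")
>>> smz.k
4
>>> smz.members("USA")
('*5/*5', '*5/*6', '*6/*6')
>>> cohorts = data.load_genotype_counts()
>>> phenotype_frequencies(cohorts["EUR"], smz).percentages()
{'RA': 6.76, 'IA': 35.59, 'SA': 3.38, 'USA': 54.27}
```

For sulfamethazine the clustering puts \*5/\*5, \*5/\*6 and \*6/\*6 into
an ultra-slow group, and combining that with the European genotype counts
says 54.27% of the EUR cohort are ultra-slow sulfamethazine acetylators —
versus 4.75% of the Japanese cohort (run
`analysis/05_worldwide_distribution.py` for the full table). The same
machinery shows the substrate specificity of \*7: for dapsone (DDP) the
\*7-bearing genotypes stay in the rapid cluster, while for most other
drugs they are slow.

The numbered scripts under `analysis/` walk the whole study in order
(cohort frequencies → kinetics recovery → activity scores → clustering →
worldwide distribution → synthetic round trip) and write their tables
under `results/`.

The `nat2kit` command exposes the same stages from a shell:

```sh
nat2kit score --out scores.tsv
nat2kit cluster --scores scores.tsv --k auto --out assignments.tsv
nat2kit distribute --assignments assignments.tsv --out distribution.tsv
```

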