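# edtool

Evolutionary-dependency (ED) analysis of cancer gene pairs from somatic
mutation calls.

For a pair of genes (A, B), the cohort is split into genomes with and
without non-silent mutations in the *context gene* A. The partner gene B's
dN/dS ratio is estimated separately in each arm — each with its own
synonymous-mutation calibration — and the two ratios are combined into a
**cdNS score**, `log2(dNdS_context+ / dNdS_context−)`. Positive scores mark
synergistic (SYN) pairs, negative scores antagonistic/redundant (ANT)
pairs. Significance comes from shuffling the context labels (with a
sample-size-corrected one-sided Fisher test for pan-cancer ANT pairs), and
calls are filtered by p-value, minimum mutation counts and the ED ratio.

The package also provides:

- per-gene, per-class (missense / truncating / indel) dN/dS estimation with
  uniform, 12-category base-substitution or 96/192-category trinucleotide
  rate models, and driver-gene selection by FDR-corrected Poisson tests;
- ΔVAF and ΔTMB contrasts of called pairs with gene-shuffled permutation
  baselines, and gene-set co-membership z-scores;
- knockout-viability and IC50 effect sizes from cell-line panels, with
  rescuing/compromising labels and the fourfold Res/Com × SYN/ANT
  categorisation;
- a synthetic-data module that generates MAF-format cohorts and cell-line
  panels with known ground truth (per-gene omega, programmed cdNS per pair,
  clonal/subclonal VAF structure, hypermutator fractions, programmed screen
  effects), so every pipeline stage is testable offline.

## CLI

All functionality is exposed through the `edtool` command:

```sh
# generate a synthetic cohort + panel from a YAML config
edtool simulate --config sim.yaml --out-dir sim/

# per-gene dN/dS
edtool dnds --maf sim/cohort.maf --cds sim/cds.fasta \
    --granularity uniform --out dnds.tsv

# score and call SYN/ANT pairs
edtool cdns --maf sim/cohort.maf --cds sim/cds.fasta \
    --context-genes G001,G002 --partner-genes G003,G004 \
    --mode pancancer --n-perm 1000 --seed 17 --out pairs.tsv

# ΔVAF / ΔTMB features for called pairs
edtool features --maf sim/cohort.maf --pairs pairs.tsv --seed 7 --out features.tsv

# cell-line effect sizes
edtool dependency --mutations sim/panel_mutations.tsv \
    --viability sim/panel_viability.tsv --pairs pairs.tsv --out dep.tsv
edtool pharm --mutations sim/panel_mutations.tsv --ic50 sim/panel_ic50.tsv \
    --drug-map drug_map.tsv --out pharm.tsv

# MAF plumbing
edtool convert --maf in.maf --out canonical.maf
edtool filter --maf in.maf --tumor-types LUAD,LUSC --min-cases 500 --out out.maf
```

A minimal simulation config:

```yaml
seed: 3
n_samples: 1000
n_genes: 20
length_codons: 250
mutation_rate: 0.0005
ed_pairs:
  - {gene_a: G001, gene_b: G002, impact_class: missense,
     cdns_true: 2.0, context_prevalence: 0.2}
```

## Notes on the estimator

The dN/dS estimator is a synonymous-calibrated Poisson model over explicitly
enumerated substitution opportunities; it does not reproduce covariate-based
rate shrinkage from third-party packages. Each context arm is calibrated on
its own synonymous mutations, which absorbs burden differences between
context-positive and context-negative genomes. Undefined scores (omega = 0
in either arm) are excluded from calling rather than imputed; an opt-in
pseudocount exists for exploratory work.
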