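# epiforge

Headless epitope selection for missense-mutation cancer vaccine design.

Given an oncogene protein sequence and a list of missense mutations
(`E542K`-style notation), epiforge:

1. builds the mutant sequences and enumerates every mutation-spanning
   peptide window (9/10-mers for MHC Class I, 15-mers for Class II);
2. collects predicted features per epitope/HLA pair — binding affinity
   (IC50, nM), immunogenicity, antigenicity, allergenicity, toxicity and
   IFN-γ release — through a pluggable backend (a deterministic mock and a
   precomputed-table replay ship in the box; nothing in the core touches
   the network);
3. labels binding strength (STRONG ≤ 50 nM < NORMAL ≤ 500 nM < WEAK ≤
   5000 nM < N/A) against the packaged 27-allele Class I and Class II HLA
   reference sets;
4. ranks pairs per point mutation with probabilistic logistic scoring
   functions, keeps the top 20, and filters the survivors on safety and
   stability (instability index < 40, N-end-rule half-life > 1 h,
   non-toxic, and IFN-γ-positive for Class II);
5. computes HLA population coverage, average epitope hit and PC90 under
   Hardy–Weinberg equilibrium, and reduces the final list to a minimum
   epitope subset with identical coverage (set-cover optimization).

It is aimed at immunoinformaticians who want the epitope-selection logic
of GUI vaccine-design tools as a tested, scriptable library.

## The scoring model

Each epitope/HLA pair is scored by the probability of eliciting a positive
T-cell response,

    π* = ln(π / (1 − π)) = β₀ + β₁α + β₂γ + β₃δ + β₄ε

where α, γ, δ are the normalized immunogenicity, antigenicity and
allergenicity (z-score then min–max to [0, 1]; allergenicity — and Class II
immunogenicity — inverted so that "safer" is closer to 1) and ε = ln of the
binding affinity in nM. Published fitted weights ship as named constant
models (`published-class1-logistic`: β = 2.311, 0.893, 0.197, −3.426, −0.479;
`published-class2-logistic`: β = 0.654, −0.010, 0.381, 0.831, −0.096), and both
logistic and linear families can be refit on training tables of T-cell
assay outcomes (`outcome` 0/1, or beta–binomial potentials
(responded + 1)/(tested + 2) for the linear family).

Population coverage treats each HLA locus as an independent Hardy–Weinberg
draw of two alleles; a genotype's "hits" are the distinct epitope/HLA
combinations it can present (homozygotes count an allele's epitopes once),
and the population hit distribution is the convolution across loci.
Coverage is P(≥ 1 hit), and PC90 is the interpolated minimum number of
combinations recognized by 90% of the population.

## Worked example

```python
import pandas as pd
from epiforge import PipelineConfig, run_pipeline
from epiforge.fixtures import (
    load_packaged_mutations, synthetic_protein, synthetic_frequency_table,
)

muts = load_packaged_mutations()          # 49 PIK3CA-study point mutations
protein = synthetic_protein(1, mutations=muts)   # synthetic stand-in sequence
freq = pd.concat([synthetic_frequency_table(2, ["World"], "I"),
                  synthetic_frequency_table(3, ["World"], "II")])
freq.to_csv("freqs.csv", index=False)

result = run_pipeline(PipelineConfig(
    protein=protein, mutations=muts, seed=1,
    frequency_table="freqs.csv", populations=("World",),
))
print(result.manifest["counts"])
print(result.coverage_optimized.round(2).to_string(index=False))
```

prints

```
{'mutations': 49, 'candidate_windows': 1666, 'predicted_pairs': 44982,
 'binder_pairs': 32809, 'scored_pairs': 32809, 'ranked_pairs': 1960,
 'filtered_pairs': 597, 'mutations_with_class_I_epitopes': 32,
 'mutations_with_class_II_epitopes': 25, 'excluded_unsupported_pairs': 117}
mhc_class population  coverage_pct  average_hit  pc90
        I      World         99.95         4.76  3.38
       II      World         90.21         1.84  1.01
```

Reading: the 49 mutations yield 1666 candidate windows and 44,982
epitope/HLA pairs under the mock predictor; 597 pairs survive ranking and
safety filtration, covering 32 mutations with Class I epitopes and 25 with
Class II. Optimization shrinks each class's list to a minimal subset with
*identical* population coverage (here 99.95% / 90.21% world coverage) while
the average number of recognized epitope/HLA combinations per individual
drops (49.6 → 4.8 for Class I). With a real predictor backend
(`TableBackend` over exported feature CSVs) the same pipeline runs on real
feature data. The same run is available from the shell:

```
epiforge fixtures --seed 1 --out demo/
epiforge run --fasta demo/protein.fasta --mutations demo/mutations.csv \
    --freq-table demo/frequencies.csv --seed 1 --out demo/out/
```

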