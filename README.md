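# brafscan

Why is BRAF V600E found in hundreds of thousands of tumours while other
substitutions that should activate the kinase just as well are rare or
absent? `brafscan` implements a quantitative answer for the hydrophobic
pocket surrounding the activation segment (AS) of the BRAF kinase domain,
combining four ingredients:

1. **Folding-energy post-processing.** Per-mutation ΔΔG values (kcal/mol,
   positive = destabilising) computed on active-like and inactive-like
   template structures are averaged per conformational state; a mutation is
   called destabilising when its state-averaged ΔΔG > 0.8 kcal/mol.
2. **Flexibility weighting.** Across an ensemble of kinase-domain crystal
   structures, each AS residue is resolved in only a fraction of entries
   (~70% for Val600). Inactive-state AS-loop energies are multiplied by this
   presence fraction: mutations in flexible, rarely ordered regions unfold
   the domain less than a rigid-lattice energy suggests.
3. **Mutational accessibility.** The minimum number of nucleotide
   substitutions separating the wild-type codon from the nearest codon of
   the mutant residue (V600E needs one base change from GTG; V600K/D need
   two; V600H three), plus the resulting change in codon-usage fraction.
4. **Phosphomimetic salt bridges.** Asp/Glu at Thr599, Lys601 or Ser602 can
   reach Arg575 and stabilise the active conformation; a favourable energy
   is credited to the active-state term there (never at position 600, which
   points away from Arg575).

Per mutation these combine into a composite **activation score**

    score = presence-corrected ΔΔG(inactive loop)
            − [ΔΔG(active) + salt-bridge credit]
            + ΔΔG_solvH(inactive)

and into a seven-feature vector whose contribution to observed cancer
mutation counts is quantified with a **balanced random-forest protocol**:
two sets of 100 regression forests (40 trees, 4 candidate variables per
split), trained on ~70% of mutations with zero-count and nonzero-count
strata sampled separately, the V600E row forced into the training set in one
set and out of it in the other. Feature importance is the total decrease in
node impurity (residual sum of squares) over all splits; per-run test-set
Pearson correlation, RMSD and their ratio (the performance indicator) are
recorded.

A synthetic-data module generates all inputs — correlated per-template
energy tables, PDB ensembles with presence-coupled B-factors, and Poisson
log-linear mutation counts — with known ground truth, so the entire pipeline
runs and is tested offline.

## Worked example

```python
from brafscan import (Codon, GeneticCode, min_nt_substitutions, run_pipeline)

code = GeneticCode()
for target in "EKDH":
    print(f"V600{target}: {min_nt_substitutions(Codon('GTG'), target, code)} base change(s)")

result = run_pipeline(seed=1)          # simulate -> profile -> features -> forests
print(f"presence(600) = {result.profile.presence(600):.3f}")
print(result.protocol.importance_table().round(1))
```

prints

```
V600E: 1 base change(s)
V600K: 2 base change(s)
V600D: 2 base change(s)
V600H: 3 base change(s)
presence(600) = 0.679
                          with_v600e  without_v600e
feature
inactive_destabilization         7.6            7.2
active_destabilization           9.1            9.6
loop_destabilization            52.3           51.9
nt_substitutions                 8.7            8.9
codon_usage_delta                3.9            3.9
salt_bridge                      6.3            7.7
hydrophobic_solvation           12.1           10.8
```

V600E is the only one-base route to a charged residue at position 600; the
28-structure synthetic ensemble resolves residue 600 in ~70% of entries
(binomial noise around the configured 0.70); and the corrected inactive-loop
destabilisation (`loop_destabilization`) dominates the forest importances in
both protocol sets, with near-identical values whether or not the V600E
analogue is in the training set.

A command-line interface exposes the stages individually; e.g.

```
brafscan simulate --seed 1 --out-dir synthetic
brafscan flexibility synthetic/pdb --out profile.tsv
brafscan summarize synthetic/energies.tsv --profile profile.tsv --out summary.tsv
brafscan accessibility
```

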