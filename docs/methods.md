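# Methods

## Scope and model

`brafscan` post-processes mutational-scan folding energies for the BRAF
kinase domain's hydrophobic pocket; it does not compute ΔΔG from coordinates
(a force-field's job) and does not model wet-lab readouts. The analysed
positions default to the 14 pocket/activation-segment residues
F468, L485, V487, A497, F498, L525, L597, A598, T599, V600, K601, S602,
R603, W604 — 14 × 20 substitutions (self-substitutions included as controls)
on 5 template structures (active-like 4MNE, 3OG7, 4MNF; inactive-like 4EHE,
3TV6) = 1400 models.

Per mutation the pipeline computes:

* state-averaged ΔΔG for the active and inactive conformations (arithmetic
  mean over the templates of each state);
* a destabilisation call at the strict threshold ΔΔG > 0.8 kcal/mol (about
  twice the force field's error SD; 0.80 itself is *not* destabilising);
* the inactive **loop energy**: the mean of the per-record `loop` term when
  the table provides a decomposition, else the total ΔΔG (for loop-position
  mutations the energy change is concentrated there anyway);
* the **presence correction**: loop energies of inactive templates at
  positions within the AS loop (597–615) are multiplied by the residue's
  presence fraction in the structure ensemble. The source analysis says the
  energies were "corrected by the frequency solved" without a formula;
  multiplication is the minimal monotone reading (never amplifies, vanishes
  for never-resolved residues) and is what this package implements. Active
  conformations are never corrected.
* the **salt-bridge credit**: a favourable constant (default −2.0 kcal/mol)
  added to the active-state term for Asp/Glu at positions {599, 601, 602}.
  The magnitude is a placeholder: the original calibration (phospho-Ser →
  Ser in PDB 1ATP) is not published as a number, so reproduction runs must
  set it explicitly. Position 600 is always exempt, and the possible
  Glu600–Lys507 interaction is fixed at zero (measured to be negligible,
  ΔΔG(E600A) ≈ 0.04 kcal/mol).
* the **activation score** = corrected loop energy − (active ΔΔG +
  salt-bridge credit) + hydrophobic-solvation term of the inactive state.
  The solvation term enters as the raw ΔG_solvH difference; a sign-adjusted
  "bulky-hydrophobic accommodation" penalty would be an alternative reading,
  not implemented.

## Flexibility profile

A residue counts as *resolved* in a structure iff it has an alpha-carbon
coordinate record; side-chain completeness is not required. One chain per
structure is used (configurable; default: the first chain covering the
residue range). B-factors are z-normalised per structure over the analysed
residue range — "normalised B-factor" has several dialects in the
literature; the per-structure z-score is this package's — then averaged per
residue across structures. A structure with zero B-factor variance
contributes zeros (warning); a structure resolving fewer than two residues
in the range contributes to presence counts but not to B-factor averages.
Author residue numbering is taken verbatim.

## Feature matrix and response

Seven predictors per mutation, in fixed order: (1) inactive ΔΔG, (2) active
ΔΔG, (3) presence-corrected inactive-loop energy, (4) minimum nucleotide
substitutions, (5) codon-usage delta, (6) salt-bridge credit, (7)
hydrophobic-solvation change. Assembly is an inner join over the energy,
accessibility and frequency inputs (drops logged), rows ordered by
(position, mutant residue).

The response is log10(count + 1) of the per-substitution cancer occurrence
count. Counts span four orders of magnitude; on the raw scale the single top
hotspot would dominate every residual-sum-of-squares computation. `raw` and
`binary` modes are available.

Codon bookkeeping uses the standard genetic code (via Biopython) and a
bundled human codon-usage table in fractions of synonymous usage. When
several mutant codons are equally close, the usage delta uses the
highest-usage one (the most accessible high-expression outcome) with an
alphabetical tie-break for determinism. Reference codons for the 14
positions are bundled: GTG at 600 and CTG at 597 are forced by the known
1/2/3-base distances of the hotspot substitutions; the remaining positions
default to the most frequent human codon of their wild-type residue, and a
user file can override all of them. Stop codons are excluded as targets
(missense scope).

## Forest protocol

Two sets of `n_runs` (default 100) regression forests, 40 trees each,
4 candidate features per split, bootstrap sampling within trees. Each run
draws ~70% of the zero-count stratum and ~70% of the nonzero-count stratum
into training (the strata boundary — zero vs nonzero — is configurable); in
one set the V600E row is forced into training (swap with a random training
member of its stratum if needed), in the other it is forced out. Evaluation
on the held-out rows: Pearson correlation of predicted vs observed response,
RMSD, and correlation/RMSD as the per-run performance indicator; runs with
constant predictions raise rather than contribute undefined correlations,
and RMSD = 0 yields an infinite-performance sentinel. No run filtering
precedes importance averaging.

Importance is the **total RSS node-impurity decrease**: for squared-error
trees the weighted impurity decrease of a split times the training-set size
is the split's residual-sum-of-squares reduction; summing over all splits of
all trees gives each feature's importance, averaged over runs and normalised
to percent per set (sums to 100 within 1e-9). This is deliberately not
permutation importance. The forest itself is scikit-learn's
`RandomForestRegressor`; ties at equal split gain follow its seeded
candidate ordering rather than a lowest-index rule — everything remains
bit-reproducible from the master seed, which spawns independent
`numpy.random.SeedSequence` streams per set and per run.

## Synthetic generator

The generator fixes the study conditions; its defaults are not tuning knobs.

* **Energy tables.** Each non-self mutation draws latent true energies
  (loop, inactive, active, solvation) around mutation-type means: charged
  residues in the pocket destabilise the inactive loop strongly
  (3.4 kcal/mol at loop positions) and, at core positions, both folded
  states (≈3 kcal/mol); bulky hydrophobics are attenuated (the flexible
  segment accommodates them) and gain favourable solvation; polar residues
  sit between; self-substitutions are exactly zero. Latent spread is
  0.8 kcal/mol (solvation 0.3). Template replicates add state-specific noise
  whose SD is set from the realised latent variance so that same-state
  templates correlate at the configured 0.85; active/inactive pairs
  correlate only through the shared mutation-type structure (empirically
  ≈0.35; an explicit cross-state coupling knob defaults to 0). Self
  substitutions get small replicate noise (SD 0.15 kcal/mol), matching the
  near-zero spread of remodelling an unchanged side chain.
* **Ensembles.** Minimal PDB files (CA-only, chain A, residues 580–620,
  written and read with gemmi). Loop residues are present independently with
  the configured probability — 0.70 at residue 600, decaying into the
  segment's middle — and B-factors rise linearly as presence falls
  (20 + 45·(1 − presence), SD 3), coupling the two flexibility proxies.
* **Counts.** count ~ Poisson(exp(α + Σᵢ wᵢ·zᵢ) · g^max(f4−1, 0)) with
  α = 1.0, standardised features zᵢ, true weights
  w = (−0.3, −0.4, **+1.5**, 0, +0.15, −0.3, +0.4) — destabilising either
  folded state or losing the salt bridge suppresses counts, loop release
  dominates — and accessibility gate g = 0.25 per extra required base
  (between the ~10× rarity of the two-base hotspot variants and a mild
  penalty; w₄ = 0 so accessibility acts only through the gate).

What the generator does **not** emulate: real force-field error structure
(heavy tails, position-specific covariance), trinucleotide mutational
signatures, tissue composition of tumour cohorts, multiple chains or
occupancy in crystals. Passing tests therefore show the pipeline's
statistical machinery is correct and recovers known ground truth, not that
the biological conclusions transfer to any particular new protein.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 280-mutation, 5-template,
28-structure cohort; the importance-recovery check repeats the complete
two-set, 100-run protocol on 20 independently seeded cohorts and requires
the loop feature to rank first in both sets in ≥95% of them; the binomial
presence check uses a 1000-structure ensemble. Degenerate inputs are
handled explicitly: constant responses yield zero importances (warning),
zero-variance correlations raise, never-resolved residues carry NaN B-factor
averages, and empty strata or empty joins are errors rather than silent
drops.

## Known limitations

* The salt-bridge magnitude is a single constant per (position, residue)
  rule; no geometry is evaluated.
* The loop-energy fallback (total ΔΔG when no decomposition is present)
  overstates loop energies for core-position mutations whose destabilisation
  is not loop-local; tables with a `loop` term avoid this.
* Presence fractions from small ensembles are noisy (binomial with n = 28);
  the correction inherits that noise.
* The forest protocol quantifies association, not causation; importances are
  RSS-based and therefore favour continuous, high-variance features over
  few-valued ones such as the substitution count.
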