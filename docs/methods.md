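# Methods

This note documents the models and procedures implemented in `hergsift`,
the defaults they use, the numerical choices behind them, and what the
synthetic test bed does and does not establish about real data.

## Problem setting

hERG (Kv11.1) is a homotetrameric potassium channel whose central cavity —
the region around F557, T623, S624, V625, G648, Y652 and F656 — binds a
remarkably diverse set of drugs, and whose blockade causes QT prolongation.
The package classifies compounds as hERG binders or nonbinders from two
structural predictors produced by an external docking engine: the docking
score (DS) of the top-ranked pose and the geometry of that pose, summarised
as a per-residue interaction fingerprint (IF).

## Data curation and labeling

Activity records pass, in order: activity type must be IC50; target
organism `Homo sapiens`; assay type `B` (direct binding); no
data-validity warning; parsable SMILES; molecular weight in [200, 600] Da
(computed from the structure when not supplied); and structural
deduplication. Duplicates are keyed on the canonical SMILES of the desalted
parent (largest organic fragment); among duplicates the record with the
lowest numeric IC50 is kept — the conservative choice for a toxicity
endpoint, since it preserves the strongest evidence of liability. Each
filter's removal count is returned as an audit trail.

Labels: binder iff IC50 ≤ 1 μM; nonbinder iff IC50 exceeds the inactivity
threshold (one of 1–80 μM, default 80) or the potency field carries the
"not a number" annotation (recognized case-insensitively); records between
the bounds are excluded. IC50s are carried in nM (the ChEMBL
`standard_value` convention for this target) and converted to μM at the
threshold comparison.

Internal diversity is the mean over all unordered pairs of one minus the
Tanimoto similarity of 2048-bit hashed Morgan fingerprints (radius 2),
computed exactly (no pair sampling) — quadratic cost is acceptable to about
10⁴ molecules. Representative binders are picked by k-means (k = 5,
Euclidean metric on the binary fingerprint vectors, fixed seed) followed by
the minimum-IC50 member of each cluster; when k equals the number of
compounds every compound is its own cluster. Because k-means on hashed
fingerprints is implementation-sensitive, the chosen fingerprint and metric
are recorded in the run manifest and exact recovery of any particular
reference selection is not claimed.

## Structures and poses

Receptors are PDB files; only standard amino-acid ATOM records are kept
(waters and ligand HETATMs dropped; altloc conflicts resolve to the
highest-occupancy conformer). Coordinates stay in the PDB frame — receptor
and poses must already share it, as they do for any docking output. Poses
are SDF V2000 records (scores from a configurable data tag or a sidecar
CSV); records without a score are skipped and counted, mirroring the
exclusion of undocked molecules. Score orientation (lower-is-better
kcal/mol vs higher-is-better fitness) is explicit configuration and never
inferred from the numbers. Pose hydrogens are collapsed onto their heavy
atoms at read time with the attached-H count retained per atom, so all
geometric rules operate heavy-atom-only. The package's own SDF writer pins
each atom's hydrogen count in the V2000 valence field, so synthetic poses
round-trip exactly.

## Interaction fingerprints

The binding site is every residue (as a monomer-collapsed
residue-number/name key) with a heavy atom within 9 Å of any heavy atom of
the best-scoring docked molecule. Each site residue then contributes nine
bits per pose:

| bit | meaning | criterion |
|---|---|---|
| contact | any contact | any heavy-atom pair ≤ 4.5 Å |
| backbone | backbone contact | contact via N/CA/C/O/OXT |
| sidechain | side-chain contact | contact via any other atom |
| polar | polar-residue contact | contact ∧ residue ∈ {SER,THR,ASN,GLN,CYS,TYR,HIS} |
| hydrophobic | hydrophobic-residue contact | contact ∧ residue ∈ {ALA,VAL,LEU,ILE,MET,PHE,TRP,PRO,TYR} |
| hbond_acceptor | site atom accepts from ligand donor | donor–acceptor heavy atoms ≤ 3.5 Å |
| hbond_donor | site atom donates to ligand acceptor | donor–acceptor heavy atoms ≤ 3.5 Å |
| aromatic | aromatic-residue contact | contact ∧ residue ∈ {PHE,TYR,TRP,HIS} |
| charged | charged-residue contact | contact ∧ residue ∈ {ASP,GLU,LYS,ARG,HIS} |

Class sets deliberately overlap (TYR is polar and hydrophobic and aromatic;
HIS is polar, aromatic and charged) and are configurable. Receptor
donor/acceptor roles come from a residue/atom table (backbone N donates
except in PRO, backbone O accepts, side-chain roles per residue type);
atoms missing from the table are treated as neither and logged. Ligand N/O
atoms donate when they carry a hydrogen (or a protonated nitrogen's formal
charge) and accept unless they are a fully substituted positive nitrogen.
The D–H⋯A angle criterion (≥ 120°) applies only where explicit hydrogen
coordinates exist (receptor PDBs with hydrogens); otherwise hydrogen bonds
are distance-only, the standard fallback for heavy-atom-only poses. Every
specific bit implies the contact bit by construction. The final fingerprint
is the elementwise OR over the (up to four) monomer copies of each residue:
a bit is on if the interaction occurs in at least one subunit. These exact
cutoffs are conventional rather than canonical; they are emitted in a JSON
manifest beside every fingerprint table, and numerical identity with other
fingerprint implementations is not claimed.

## Classifier

Feature vectors are DSst alone (score-only models) or DSst followed by the
fingerprint bits mapped 0/1 → −1/+1 (fused models), with rows aligned by
compound. The standardizer is fit on training scores only and applied to
external compounds — fitting it on pooled data would leak the external
distribution into training. Binder = +1, nonbinder = −1.

The L1-penalized linear SVM objective λ‖w‖₁ + mean loss is solved by
liblinear (squared hinge, primal, tolerance 1e-6, iteration cap 10⁴).
λ ∈ (0,1) is mapped to the liblinear cost by C = (1−λ)/(nλ), so the
effective L1 weight λ/(1−λ) sweeps the entire regularization path: λ → 0
approaches the unpenalized fit and λ → 1 yields the empty (all-zero)
model. λ is chosen from 20 logarithmically spaced values in (10⁻³, 0.99)
by minimum error on a stratified 20% tuning split (ties resolve to the
larger, sparser λ), then the model is refit on the full training set.
Prediction is sign(w·x + b); an exact zero margin is called nonbinder —
for an antitarget, flagging a borderline compound is the safer error.

## Evaluation

Per repeat (default 100): 50 + 50 external compounds are drawn without
replacement; the training set is the remainder with the majority class
undersampled to balance (unbalanced training would push a linear SVM
toward the majority class); the model is trained and scored on the
external set. ACC, SE, SP, NPV follow their standard confusion-matrix
definitions; an empty denominator yields not-available rather than an
error. AUC is the Mann–Whitney probability that a binder outscores a
nonbinder, ties counted half, computed from midranks. Per-repeat RNG
streams derive from (seed, repeat index), so runs are reproducible and
individual repeats are independent of protocol length.

Model comparisons use the two-sample KS test on per-repeat metric values
(exact p for min(n) ≤ 25, asymptotic otherwise; no multiple-testing
correction). Summaries report mean ± sd to two decimals.

The score threshold of a score-only model is found by scanning raw DS
across the observed range at step 0.01 and returning the midpoint of the
two grid points where the predicted label flips; for a linear model this
lies within half a step of the analytic crossing μ − σ·b/w. Thresholds are
computed per repeat and averaged, yielding mean ± sd in raw score units.

## Residue importance

For each fingerprint column, the IC50 distributions of compounds with and
without the bit are compared by a KS test, repeated over (default) 100
random subsamples of 80% of the compounds; the occurrence count is the
number of trials with p < 0.05. Direction (lower vs higher IC50) compares
group medians on the full data; since KS and medians are invariant under
the monotone log transform, raw and log-scale IC50 give identical results.
Output rows sort by occurrences descending, label ascending on ties, and
format as `557_aromatic[100]`.

A caveat documented here because it shapes the tests: trials subsample one
fixed dataset and are therefore strongly positively correlated. A null bit
on a dataset that happens to carry a chance association can reach high
occurrence counts, while most null bits score near zero — per-bit counts
are overdispersed relative to Binomial(100, 0.05). What is calibrated is
the marginal rate: across independent datasets the fraction of significant
(bit, trial) pairs under the null is the nominal 5%, and that is the form
the test suite verifies (many independent datasets with few trials each,
since correlated trials add pairs but not precision). Occurrence counts
should be read as a robustness ranking, not as p-values.

## Synthetic data generator

Two generators make the pipeline testable without downloads.

`make_toy_complex` builds a Cn-symmetric (default C4) receptor: each chain
is a vertical column of residues at a configurable ring radius with the
four backbone atoms and one representative side-chain atom per residue,
side chains pointing at the pore axis; the other chains are rotated
copies. The representative atom is chosen per residue type so every
detector is exercisable (e.g. SER→OG, ASP→OD1, LYS→NZ, PHE→CZ). Ligand
atoms are placed at exact requested distances from named receptor atoms,
displaced toward the axis; infeasible placements (beyond the opposite
wall) raise an error. The construction is its own oracle: a 3 Å approach
to a PHE ring carbon must light exactly the contact, side-chain,
hydrophobic and aromatic bits.

`make_dataset` draws docking scores from class-conditional Gaussians
(default binders −8.0, nonbinders −6.0, σ = 1.0, lower-is-better — a 2σ
separation giving closed-form AUC Φ(√2) ≈ 0.9214), fingerprint bits
Bernoulli per class, and IC50 log-normal with median 10 μM and geometric
sd 10, clipped to [1 nM, 1 mM] — the dynamic range typical of this assay —
with optional multiplicative effects tied to planted bits. Default class
sizes (400 + 400) keep the 50+50 resampling protocol comfortably feasible.
Ground-truth parameters are returned so recovery tests close the loop.

What passing on this test bed shows: the geometric detectors, the
statistics, the resampling machinery and the sparsity behaviour are
correct, and planted signal of known size is recovered at its theoretical
strength. What it does not show: performance on real docking output. Real
poses have correlated, geometry-driven bit patterns rather than
independent Bernoulli bits; real scores are not Gaussian and their
separation depends on the docking engine and the protein conformation
(conformations accounting for induced fit separate far better than
apo models); and real IC50s carry inter-assay noise. Published headline
figures at ChEMBL scale with commercial engines are therefore outside what
this package's tests can or do certify.

## Problem sizes and runtime

Default verification sizes were chosen to keep everything fast on one CPU
while leaving no estimate starved: 800 + 800 compounds for the resampled
recovery runs (the resampled mean converges to the dataset's empirical
value, so the dataset must be large enough that its empirical AUC sits
within a few thousandths of the population value); 100 randomized
complexes for the fingerprint oracle; 1000 random cases for the AUC
cross-check; 800 independent datasets × 25 trials for the null
calibration. The full test suite runs in about a minute and a half; the
acceptance script in about half a minute.

## Known limitations

- No π-stacking plane geometry and no salt-bridge-specific detector
  beyond the charged-contact bit; the nine-bit scheme does not include
  them.
- No MOL2 input; SDF bond orders are taken as given (no perception).
- No tautomer/protomer enumeration; multi-state ligands should be reduced
  to the best-scoring state per parent before fingerprinting.
- The λ ↔ sparsity correspondence is solver-parameterization specific;
  only the qualitative path behaviour (monotone sparsity, empty model at
  the top of the range) is asserted.
- k-means cluster assignments on hashed binary fingerprints can differ
  across implementations; representative selection is reproducible under
  a fixed seed but not guaranteed to match other toolkits compound for
  compound.
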