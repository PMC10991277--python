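# Methods

## The problem

Microbial proteins carry a compositional imprint of the temperature their
host organism grows at: thermophile proteomes are enriched in charged and
hydrophobic residues (E, L, V, Y among others) and depleted in several
polar ones (D, H, M, Q, S, T).  `ogtpred` exploits this imprint to regress
a protein's *optimal growth temperature* (OGT, °C) label directly from the
amino-acid sequence, and to screen metagenome-derived enzyme candidates
for thermostable variants before any wet-lab work.

## Corpus construction

Genomes are classed from their OGT using strict inequalities:
psychrophilic below 20 °C, mesophilic strictly between 30 and 40 °C,
thermophilic above 50 °C.  Boundary values and the bands [20, 30] and
[40, 50] are *excluded*: their proteins are kept in the corpus but carry
no regression label (they can still be scored by a trained model, e.g.
during mining).  Every labelled protein inherits its genome's OGT as the
target — a deliberately weak, noisy label: not every protein in a
thermophile is itself thermostable, which is one reason per-protein
correlations saturate well below 1 while genome-level averages correlate
much more strongly.

## Homology-aware cross-validation

Ortholog clusters (orthogroups) are the unit of splitting.  Clusters are
read from OrthoFinder-style `Orthogroups.tsv`; only clusters whose
members span at least two temperature classes enter the train/validation
pool (single-class clusters carry no cross-class signal); everything else
labelled forms the held-out test pool.  Clusters are shuffled with a
seeded generator after lexicographic ordering (platform-stable) and dealt
round-robin into k = 10 folds, so fold sizes differ by at most one
cluster and members of one cluster can never straddle a fold boundary.

Why cluster-level and not protein-level?  Homologs are near-duplicates;
with a protein-level split a flexible model can recognise the family of a
validation protein from training and fit family-specific corrections —
i.e. memorise rather than generalise.  The package ships a *leakage
audit* (`ogtpred.evaluation.leakage_audit`) that quantifies this: it
trains the same model once under the cluster split and once under a
deliberately protein-level split and reports the validation-r inflation.
The audit deliberately uses a leak-*sensitive* training configuration —
no dropout and a long early-stopping patience — because a strongly
regularised, early-stopped model may never enter the memorisation regime
at desk scale, which would mask the hazard the audit exists to measure.
Under the audit configuration the protein-level split consistently trains
far longer (it keeps "improving" its leaky validation loss by fitting
family structure) and ends with a higher validation r than the honest
cluster split.

## Encoding

Sequences are one-hot encoded into `L_max × 20` binary matrices with
channels in alphabetical residue order.  Non-standard residues
(B, J, O, U, Z, *, …) are normalised to a single unknown symbol at load
time and encode as an all-zero row (no 21st channel).  Longer sequences
are truncated at the C-terminus, shorter ones zero-padded; `L_max`
defaults to 1,000 residues and is configurable (pipelines typically pass
the corpus maximum).

## Model

A 1-D convolutional regressor, implemented in numpy (layers with explicit
forward/backward passes; no deep-learning framework is required):

    conv(kernel k, f filters, relu) → maxpool(2)
    → conv(k, f, relu) → maxpool(2) → flatten
    → dense(f, relu) → dropout(0.3)
    → dense(f, relu) → dropout(0.3) → dense(1, linear)

One width scalar `n_neurons` (= f) sets both the convolution filter count
and the dense widths; the tuned optimum on the full-scale corpus is
kernel 18 with 256 neurons, and both remain the config defaults.  Desk-
scale runs (tests, acceptance script) use 32 neurons: the synthetic
signal is compositional, so width mainly buys training speed, not
accuracy.  Training minimises MSE in °C with Adam (learning rate 1e-3,
AMSGRAD correction on), batch size 32, at most 100 epochs, early stopping
with patience 5 on validation loss, best-validation weights restored.
All stochasticity (init, shuffling, dropout) flows from the config seed;
a fixed seed reproduces training bit-for-bit on a fixed platform.
Labels are regressed in °C without normalisation (a z-scoring switch
exists but is off by default).

Pooling window 2 with stride 2, learning rate 1e-3 and patience 5 are
package defaults chosen as conventional values; they are exposed in
`ModelConfig` and recorded in every run snapshot.

`grid_search` trains one model per (kernel, neurons) pair on the same
seeded split, scores by validation Pearson r, records failures per pair,
and breaks exact ties toward the smaller kernel, then fewer neurons.

## Evaluation

`pearson_r` (product-moment, via scipy) and `mae` (°C) are the two
metrics.  Correlations of constant vectors are *undefined* and are
signalled as errors or missing values, never coerced to 0.  `evaluate_cv`
reports per-fold r/MAE with across-fold mean ± sd for train and
validation; the test pool is scored with the across-fold ensemble mean
(one r per run), with per-model scoring behind a flag.  `genome_average`
computes the unweighted arithmetic mean of member-protein predictions per
genome (`optTem_pre`) next to the genome's recorded OGT (`optTem_exp`).
`aa_frequency_correlation` correlates each residue's per-protein
frequency (unknown symbols excluded from numerator and denominator) with
the label; p-values are two-sided and deliberately uncorrected for
multiple testing, with undefined rows counted in the table metadata.
Frequencies are computed per protein by default (per-genome pooling is a
flag).

## Mining

The mining contract starts at a precomputed HMMER3 `hmmsearch --tblout`
file (e.g. the glycoside-hydrolase-18 chitinase domain PF00704 searched
against a metagenome gene catalogue).  Hits are deduplicated per protein
(best full-sequence E-value wins) and filtered at E ≤ 1e-5 by default — a
conventional domain-screen cutoff, logged prominently and configurable.
Candidates are ranked by predicted temperature (descending, ties broken
by ascending id) and binned with thresholds (20, 50) °C, echoing the
training-class boundaries; both thresholds are configurable.  The top
candidates are exported as FASTA (rank and predicted temperature in the
description) plus a ranked TSV.  hmmsearch itself is an external
prerequisite run by the user; the package neither re-implements nor
wraps profile-HMM search.

## Synthetic study conditions

The generator (`ogtpred.synthetic`) emulates the statistical skeleton of
an OGT-labelled corpus at desk scale.  Defaults: 6 genomes per class
(18 total) with OGT uniform in (5, 19) / (31, 39) / (51, 95) °C — the
excluded bands are never populated — 200 proteins per genome, 600
ortholog families spanning 2–4 genomes (probabilities 0.5/0.3/0.2),
sequence lengths uniform in 150–220 residues (typical bacterial protein
lengths), enrichment strength 0.8, per-protein label noise 3 °C,
per-family compositional effect 5 °C, and a 10% per-site substitution
rate within families.

The compositional signal is planted linearly: residue sampling weights
tilt hot-enriched residues {E, L, V, Y} up and cold-enriched
{D, H, M, Q, S, T} down in proportion to `(OGT − 50)/45`, scaled by the
enrichment strength.  The signal is composition-only — no positional
motif — so a small CNN learns it quickly on one CPU and the recovery
target is parameter recovery, not biological realism.

Families are built by copying one ancestor sequence (drawn at the
members' mean OGT plus the family effect) into each member genome with a
Binomial(L, 0.1) substitution budget.  Substitutions are
*composition-targeted*: surplus residues relative to the member's own
tilted background are converted into deficit residues, moving the copy's
composition toward its own genome's equilibrium with the fewest possible
changes, and leftover budget is spent on neutral churn.  This mirrors
long-term compositional adaptation of real homologs, and it decouples the
two quantities the tests care about: members stay ≈90% identical to the
ancestor (so homology leakage is detectable), while each member's overall
composition still tracks its own genome's OGT (so the signal generalises
to held-out families).

The per-family effect (a shared temperature offset applied to the
composition of every member, not to the label) models family-idiosyncratic
composition — e.g. function-driven residue usage independent of
temperature.  It is the confounder that makes homology-aware splitting
matter: for an unseen family the offset is irreducible prediction error,
while a protein-level split lets the model cancel it using same-family
training labels.  Unclustered proteins draw their own one-protein effect
so the test pool is statistically comparable.

What the generator does *not* emulate: phylogenetic tree structure,
positional/structural signal, codon-level evolution, realistic family
size distributions, database noise in OGT metadata, or mechanistic
hmmsearch scores (the mining fixture fabricates E-values ≤ 1e-10).
Passing tests therefore demonstrate that the pipeline machinery —
labelling, cluster-aware splitting, encoding, optimisation, evaluation,
ranking — recovers a planted signal under controlled conditions; they say
nothing about accuracy on real proteomes.

## Numerical choices and degenerate inputs

* Strict-inequality class boundaries; boundary OGTs are excluded.
* Undefined correlations are errors/missing values, never 0.
* Ranking ties break by ascending protein id; grid-search ties by smaller
  kernel then fewer neurons; cluster ordering is lexicographic before the
  seeded shuffle.
* Early stopping uses a 1e-7 minimum improvement; non-finite training
  loss aborts with diagnostics.
* Empty FASTA files, unresolvable protein/genome ids, duplicate cluster
  ids and proteins claimed by two clusters are hard errors that name the
  offending records.
* Checkpoints embed a schema tag and refuse to load across incompatible
  code versions.

## Problem sizes

Unit tests run on corpora of tens of proteins.  The end-to-end recovery
properties and the acceptance script use the generator defaults above
(3,600 proteins, ~500 retained families) and train a 32-neuron model for
one validation fold — a few minutes on one CPU.  The leakage audit trains
two such models under the leak-sensitive configuration.  Full-scale runs
(hundreds of genomes, 256 neurons, all ten folds) use the same code paths
through the CLI.

## Known limitations

* Full-scale corpora (hundreds of species, over a million proteins) and
  the metrics achievable on them are not reproducible at desk scale; the
  synthetic conditions validate machinery, not biology.
* A single trained fold is used for desk-scale evaluation; the CLI
  supports training all folds and ensemble test scoring.
* The regressor is composition-dominated at desk scale; nothing in the
  tests verifies that positional features are exploited.
* Mining fractions depend on the unspecified upstream hit-acceptance
  criterion of the screened catalogue; they are reported, not asserted.
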