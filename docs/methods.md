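# Methods

## Molecular representations

**BRICS sequence fragmentation.** A molecule's atoms are scanned left to
right in SMILES order (RDKit atom indices follow the input string). A
BRICS-breakable bond is cleaved exactly when the scan *enters a ring
system* through it, i.e. when the later-scanned atom of the bond is a ring
atom. This reading keeps acyclic linkers and terminal groups attached to
the fragment that precedes them (an ethoxy tail stays a fragment of its
own only when a ring follows it; a carboxylic acid stays on its ring
system), producing the characteristic 2–4 maximal fragments per drug-like
molecule rather than the much finer full BRICS decomposition. Cleaved
bonds are always single acyclic bonds, so reassembly is unambiguous.

Fragments are exposed in two forms. The interchange form carries bare
`*` attachment markers. The token form used by the sequence model labels
each fragment's dummy atoms directionally: atom map 1 on the dummy linking
back toward the root fragment, maps 2, 3, … on the dummies linking forward
to child fragments in scan order. Because the fragment sequence is a
depth-first linearization of the fragment tree (cut bonds are bridges), a
token sequence is reassembled right to left with a stack that exactly
inverts the scan; the exact round trip `reassemble(brics_fragment(m)) = m`
holds for every valid molecule and is asserted over the whole fixture
library.

**Junction trees.** Clusters are the smallest set of smallest rings
(SSSR), with rings sharing ≥ 3 atoms merged iteratively into bridged-ring
clusters, every non-ring bond, and a singleton cluster for any atom shared
by ≥ 3 clusters (the standard junction-atom construction; the cluster
graph is otherwise not guaranteed to reduce to a tree). Edges connect
intersecting clusters, weighted by shared-atom count with junction-atom
edges forced to dominate; Kruskal's algorithm with ties broken on sorted
node-id pairs yields a deterministic maximum spanning tree. Fused rings
sharing exactly one bond (naphthalene) remain separate clusters and both
contain the shared bond; bridged systems (norbornane) merge.

Cluster label SMILES are extracted from a kekulized copy of the parent so
partial aromatic systems export cleanly, then re-canonicalized. The
cluster vocabulary orders labels by (count desc, SMILES lex) into dense
ids.

**Preprocessing** deduplicates on canonical SMILES (RDKit default
aromatic canonical form, stereo preserved — the same function used by the
uniqueness/novelty metrics and vocabulary lookups) and removes molecules
with fewer than two fragments; unparseable entries are logged and
dropped. The operation is idempotent.

## Generative models

Both models are small variational autoencoders over token sequences,
implemented in numpy with hand-written gradients (no deep-learning
framework is required); the backward pass is verified against central
finite differences in the test suite, and all training is seeded and
bit-reproducible.

* **Encoder(s).** A one-hidden-layer tanh network over the molecule's
  token count vector produces the posterior mean and (clamped to ±10)
  log-variance. The junction-tree model uses the two-part latent
  z = [z_T, z_G]: the tree encoder reads cluster counts, the graph
  encoder a radius-2 Morgan fingerprint folded to 64–128 bits. Samples
  use the reparameterization trick with recorded noise.
* **Decoder.** A tanh recurrence conditioned on z (initial state
  tanh(W z)), teacher-forced during training. The fragment model's
  softmax output includes an end-of-sequence class; the tree decoder
  instead carries a separate logistic topology head ("does another node
  follow?") plus a label softmax, so its reconstruction splits into
  topology + label terms. Generation is greedy argmax, hence
  deterministic given parameters.
* **Graph decoding (junction-tree model).** Decoded cluster labels are
  attached sequentially: the first chemically acceptable atom pair (atoms
  with free valence, deterministic order) is bonded and the intermediate
  is sanitized; clusters with no acceptable attachment are skipped. Every
  accepted intermediate is a sane molecule, so decoding validity is 1.0
  structurally, for any sample budget — this is the property the reduced
  validity experiment measures. An empty decode falls back to the most
  frequent vocabulary cluster. The stereochemistry term of the tree
  reconstruction is exposed as a hook and disabled (0) in the reduced
  profile.
* **Property regularizer.** A two-layer tanh perceptron maps the full z
  to the three objectives, standardized to zero mean and unit variance
  over the current fit set. Its squared error joins the loss as
  `reconstruction + β·KL + α·SE` with a single-sample Monte-Carlo
  estimate of the expectations (the standard one-draw estimator).

Defaults follow the study settings: latent 64, β = 0.1, learning rate
1e-4 (Adam, gradient-norm clip 5), batch 32, 20 pretraining epochs and 10
fine-tuning epochs per generation with the learning rate annealed by
0.8^generation. The property weight α is not prescribed anywhere; the
default is 0.1, and the regularizer's effect (lower held-in prediction
error than α = 0) is asserted in the tests. The test suite and the
reduced experiments use a "tiny" profile (hidden 64, embedding 32, latent
16, learning rate 3e-3) so everything runs in seconds on one CPU.

## Objectives

SAS is the Ertl–Schuffenhauer synthetic accessibility score and logP the
Crippen atom-contribution estimate, both from the toolkit. BAS is the
best pose affinity from an AutoDock-Vina-compatible engine run as a
subprocess (seeded, exhaustiveness 8 by default; ligands are 3D-embedded
with seeded ETKDG, MMFF-relaxed and converted to PDBQT via Open Babel;
the cubic 60 Å search box is user-configurable). All three are minimized.
Molecules the engine cannot process score +inf, are excluded from the
first front, and are logged.

For engine-free operation the package ships a documented surrogate
affinity: `−(1.2·rings + 0.8·√heavy_atoms + 0.5·h)` clipped to
[−12, −2], where h ∈ [0, 1) is a stable hash of (canonical SMILES, seed).
It is deterministic, strictly favours additional ring systems, spans a
realistic score range, and is *not* an approximation of docking — it
exists so the evolutionary loop has a reproducible third objective.

## Evolutionary loop

Each generation: (1) individuals carry the encoder *mean* as their latent
(evolution operates on a deterministic embedding); (2) NSGA-II fast
non-dominated sort assigns Pareto ranks, crowding distances use the
normalized-gap convention with infinite boundary values; (3) binary
tournament selection returns the crowded-comparison winner with
probability 0.95; (4) per-coordinate uniform crossover (swap probability
0.5) and Gaussian mutation (rate 0.01, σ = 0.1 × the population's mean
per-dimension latent spread) produce offspring latents until one decode
attempt per population slot has been spent; (5) decoded offspring are
validity-filtered and deduplicated against the current population, the
training set, and each other; (6) the previous population and offspring
merge and the best `size_target` by (rank asc, crowding desc) survive —
plain elitist truncation, so the previous population contributes at most
half of the merged pool at the default settings; (7) the top 20% by the
same ordering fine-tune the model. Deduplication is scoped to the current
generation plus the training data, not all past generations.

The first population is a uniform sample without replacement from the
training data; known drug molecules can be appended via
`run_del(..., extra_initial=...)`.

## Metrics

Validity is reported over raw decode attempts when those counts are
available (the stored population only contains valid survivors).
Uniqueness divides distinct canonical SMILES by valid molecules. Novelty
divides the unique valid molecules absent from the training set by all
unique valid molecules (the "validly unique" denominator; some
benchmarks divide by all generated molecules instead, which yields
smaller values). W1 uses the exact piecewise-constant CDF integral, also
for unequal sample sizes. Hypervolume is computed exactly by recursive
slicing on the first coordinate (staircase formula in 2D); points must
weakly dominate the reference. The per-run reference point is fixed at
generation 0 as the componentwise maximum of the initial first front
scaled 10% away from zero, and is recorded with the run; front members
that fall outside the reference box in later generations are excluded
from the volume rather than moving the reference.

## Virtual screening

The first front of a ranked population is filtered with inclusive bounds
SAS ≤ 3, −0.4 ≤ logP ≤ 5.6 and BAS ≤ −6.6; the affinity bound is the
`calibrate_bas_threshold` maximum over reference-ligand scores. Note the
deliberate asymmetry followed here: evolution *minimizes* raw logP while
screening applies a drug-likeness *range*, so very hydrophilic optima can
be produced during search and rejected at screening. Hits are ordered
best (most negative) BAS first with a canonical-SMILES tie-break.

## Synthetic fixture library

Fixture molecules are scaffold–linker–scaffold compositions (18 ring
systems × 8 linkers × 18 ring systems, seeded shuffle, uniqueness and
≥ 2-fragment checks), giving valid, drug-like-sized molecules with > 2
logP units of spread. They emulate the combinatorial character of a small
screening library but not the property distribution, functional-group
diversity, or stereochemistry of real vendor catalogues — so passing
tests demonstrate the machinery's correctness and the claimed structural
guarantees, not chemical performance on real data.

## Problem sizes

The reduced experiments use a 200-molecule library, the tiny model
profile, populations of 60–100, 3–5 generations, and 1,000 prior samples
for the validity measurement; these sizes were chosen so the full suite
runs in well under a minute per experiment while still exercising every
stage of the pipeline. The full-scale configuration (population 20,000,
10 generations, 250K-molecule training set, real docking) is expressible
through the same configuration schema but is not part of the test
envelope.

## Known limitations

* The ring-entry reading of the fragmentation scan is one consistent
  interpretation of sequential BRICS cleavage; molecules without ring
  systems (or with all rings first) yield a single fragment and are
  removed by preprocessing.
* The junction-tree graph decoder is rule-based: it guarantees validity
  and determinism but cannot reproduce fused-ring attachments, so exact
  reconstruction through the tree route is limited; exact round trips are
  the fragment route's job.
* The tanh recurrence is a single layer; the configured
  `recurrent_layers` beyond 1 is accepted but not stacked.
* Surrogate affinity rewards molecular size/ring count, which drags the
  Pareto front toward large molecules in long surrogate runs — visible as
  growing front-mean SAS/logP even while the front only gains points.
* No conditional (lead-anchored) generation, no beam search, no
  graph-message-passing encoders; stereoisomer scoring is a disabled
  hook.
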