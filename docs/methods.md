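# Methods

`m6aflow` implements a three-part computational scheme for studying
N6-methyladenosine (m6A) regulation from MeRIP-seq compendia: single-base
site calling inside peak regions, network discovery of m6A-regulated gene
modules, and prioritization of m6A-associated diseases. Everything below
is exercised end-to-end on synthetic fixtures whose ground truth is known;
the final section states what those fixtures do and do not emulate.

## Single-base site calling

MeRIP-seq localizes m6A only to ~100-bp peaks. Within a peak, every DRACH
5-mer (D = A/G/U, R = A/G, H = A/C/U, center A) is a candidate site. A
candidate is described by the 101-nt window centered on its A and the
per-base immunoprecipitation (IP) read counts over that window:

    RC_norm[j] = ln( RC[j] / RC_total * 1e8 )

with `RC_total` the IP library size. Raw counts are floored at one read
before the log — the normalization is undefined at zero coverage, and a
one-read pseudo-count preserves monotonicity (the floor is a package
decision; peaks with literally zero IP coverage are rare in practice).
The sequence is one-hot encoded into a 4 x 101 matrix `M_s` (row order
A, U, C, G) and the classifier input is the coverage-weighted one-hot

    M_sr = M_s . diag(RC_norm),

so column j carries `RC_norm[j]` in the row of base j. The sequence-only
model variant is the same code path with the coverage weights forced to
one (`M_sr = M_s`); when IP replicates exist their `RC_norm` vectors are
averaged.

The classifier is a small convolutional network: conv(4x5 kernel, 32
filters, valid mode) → ReLU → 1x4 max-pool → dropout 0.25 → dense(12) →
ReLU → dropout 0.25 → 2-unit softmax, trained with categorical
cross-entropy and the Adadelta update rule (rho 0.95, eps 1e-6). Those
hyperparameters are the grid-search optimum for this architecture and are
the package defaults. The network, backpropagation and optimizer are
implemented in numpy inside the package, fully seeded so that
train-then-predict is bitwise reproducible on one machine (a single
BLAS-threaded CPU run; no GPU path exists).

Because validated positives are far outnumbered by clean negatives, the
negatives are split into `k` near-equal random subsets (default 7) and
one network is trained per subset on (all positives, that subset); the
reported probability of a site is the arithmetic mean over the members.
A site is called when its probability strictly exceeds 0.907, the
operating point at which the original 10-fold cross-validation reaches a
precision of 0.7. Training schedule (epochs, batch size) is not part of
the published description; the package defaults to 50 epochs and batch 64
for standalone training, no early stopping, everything seeded and
configurable.

Windows that would extend past a transcript end are dropped rather than
padded: padding would inject an artificial coverage shape into exactly
the region the model attends to. Training labels follow the exclusion
rule used for building miCLIP-based training sets: known single-base
positives are positive; candidates farther than 50 nt from every positive
and absent from an orthogonal-evidence exclusion list are negative; all
other candidates are ambiguous and dropped.

## Recurrence and methylation–expression correlation

To correlate methylation with expression across samples, a site must
recur. A two-sided Fisher-z power analysis — smallest n with

    n >= ((z_{1-alpha/2} + z_{power}) / atanh(rho))^2 + 3

— gives n = 12 for detecting rho = 0.8 at alpha = 0.05 and 90% power, so
sites called in at least 12 samples are retained (both the formula and
the cutoff are exposed; the cutoff is configuration). Per sample, the
methylation degree of a site is

    Methlevel = ln( mean_j exp(RC_norm[j]) / G_FPKM )

the window-averaged de-logged IP coverage over the host gene's FPKM. The
mean is taken over the 101 window positions (the averaging span is not
stated in the original description; the site window is the natural
choice). FPKM is floored at 1e-3 before logs; genes harboring called
peaks are expressed, so the floor is rarely binding.

The Pearson correlation r between `Methlevel` and `ln FPKM` — computed
over exactly the samples in which the site was called, so n varies by
site — is transformed with the second-order (Hotelling) correction of the
Fisher z:

    z  = 1/2 ln((1+r)/(1-r)),     z* = z - (3z + r) / (4n).

`|z*| < |z|` for every r ≠ 0: the correction shrinks toward zero, more so
at small n. A gene's heat is the largest |z*| over its sites (ties break
to the lowest site coordinate so the selection is deterministic); the
signed z* and the chosen site are retained for reporting.

## Hot-module discovery by insulated diffusion

Gene heats are diffused over a protein–protein interaction network with
the insulated heat-diffusion construction: with `W` the column-stochastic
degree-normalized walk matrix, the steady state of a process in which
each node retains a fraction `beta` of its heat per step is

    F = beta (I - (1 - beta) W)^(-1),

whose columns are nonnegative and sum to one (heat conservation — the
package asserts this to 1e-10, and cross-checks `F` against the 200-term
geometric series to 1e-8). The exchanged-heat matrix `E = F diag(h)`
gives the heat node i receives from source j; the directed graph with
edge j→i wherever `E[i,j] >= delta` is decomposed into strongly connected
components, and components of size >= 2 are the candidate modules.

`beta` is chosen from the topology: unit heat is diffused from a
high-betweenness source and, over a threshold grid, the number of direct
neighbors retaining influence above the threshold is tracked. That count
plateaus at the source degree and drops once the threshold passes the
weakest direct neighbor; the chosen `beta` maximizes this drop point —
the largest insulation that still heats the whole first shell. (The
criterion in the original description is pictorial; this operationalization
is the package's, and degenerate topologies — stars, cliques — fall back
to beta = 0.5 with a warning.) `delta` is calibrated on degree-preserving
random networks (double-edge-swap, 10x|E| swaps): for each random network
and each `L_max` in {5, 10, 15, 20}, the smallest delta keeping all
component sizes <= L_max is found by binary search over the distinct
entries of `E` (the component structure is a step function of delta with
breakpoints exactly there); the median over networks is the candidate
for that L_max. Among candidates, the one whose observed component sizes
are most significant is selected — the largest count of sizes k
(2 <= k <= 10; larger components are too rare for stable permutation
counts) with p(k) < 0.05 — with ties broken toward the smallest delta.

Significance of the component-size statistics X_k (number of components
of size >= k) comes from permuting the heat values across all network
genes, zeros included, and recomputing X_k (default 1000 permutations;
100 random networks for delta — both are configuration and are scaled
down in the test suite, which uses 10 random networks and 100–200
permutations at its 200-node fixture scale).

Runs on four reference networks are combined by consensus: every module
edge gets a weight equal to the number of networks reporting it;
consensus modules are the connected components of weight-4 edges;
extension attaches genes reachable through weight-3, then weight-2, then
weight-1 edges incident to a component (growth repeats to a fixed point
within each weight level, and components that come to overlap merge).
Genes of the extended components are the m6A-regulated genes; deleting
weight-1 edges and keeping components with >= 3 genes yields the
functional modules. The incident-edge growth rule is the package's
reading of "extend by adding edges of weight w"; a global rule would
re-merge everything through the weight-1 background.

## Disease prioritization

The gene layer (a PPI network), the disease layer (a semantic-similarity
matrix; edges below 0.3 are dropped to keep the layer sparse — a dense
similarity matrix makes the walk degenerate) and the bipartite
gene–disease relations form a heterogeneous network. The walk restarts
with probability gamma = 0.7 at the seed distribution (eta = 0.5 mass on
seed diseases, the rest on seed genes, each uniform); at a node with
cross-layer links it jumps layers with probability lambda = 0.5, split by
link weight. These three parameters are not given in the original
description, which delegates to the cited random-walk method; the
defaults follow that method's convention and are exposed in
configuration. The iteration `p <- (1-gamma) M p + gamma p0` runs to an
L1 residual below 1e-10 (mass is conserved exactly because `M` is
column-stochastic; the fixed point is also verified against a direct
linear solve in the tests).

The top 10 diseases by steady-state probability are candidates. Their
empirical p-value is the fraction of 100 degree-preserving random gene
networks — with the relations between seed genes and their diseases
removed, so the null holds no prior tie — in which the candidate is again
top-10. Candidates with p < 0.05 in every reference network are the
final m6A-associated diseases. Seed diseases may be included in or
excluded from the ranking via a flag; the package default includes them,
but the "no-direct-link" demonstration (a disease with no annotated
m6A gene surfacing through one-hop network topology) is only observable
among non-seed diseases, so that check ranks with seed exclusion.

## Synthetic fixtures

The generators are pure functions of (config, seed) and emit exactly the
formats the pipeline consumes.

* **Transcriptome**: uniform-random RNA with DRACH sites planted at
  least 120 nt apart (so negatives always respect the 50-nt exclusion)
  and at least 55 nt from transcript ends. Positives carry a
  probabilistic flanking consensus (35% per base over ten flank
  positions) — the learnable sequence signal — and, in coverage, a
  Gaussian enrichment bump (sd 10 nt, amplitude 60 on a Poisson
  background of 10) centered on the site. Defaults give 700 positives
  and 2,100 negatives (1:3 imbalance split over a 3-member ensemble in
  the tests).
* **Multi-sample matrices**: per gene, (Methlevel, ln FPKM) pairs drawn
  from a bivariate normal with planted correlation 0.8 on half the genes
  across 20 samples, with per-site occurrence masks of at least 12
  samples.
* **Networks**: 200-node Erdős–Rényi background (edge probability 0.04)
  plus a dense 8-gene module whose edges appear in all four derived
  networks while background edges are kept per network with probability
  0.7. Heat is sparse: module genes draw from U(1.5, 2.5), a quarter of
  background genes draw |N(0, 0.25)|, the rest are exactly 0 — mirroring
  a heat table that covers a minority of network genes.
* **Disease layer**: one planted disease annotating the module's genes,
  a block of seed-linked diseases with elevated mutual similarity, and
  decoys linked to background genes. The one-hop variant removes the
  planted disease's direct links and attaches it through bridge genes
  adjacent to the module plus similarity to the seed block.
* **End-to-end fixture**: one transcript per network gene with one
  positive site; IP enrichment amplitude proportional to
  exp(methylation) x FPKM, so computing the methylation degree from the
  realized coverage recovers the planted correlation through the real
  code path. Module genes are methylated in nearly every sample
  (constitutive targets); background occurrence straddles the recurrence
  cutoff so the filter is exercised. The training sample draws its
  amplitudes from the same enrichment model the study samples use. The
  pipeline default schedule is 30 epochs with a 3-member ensemble:
  Adadelta ramps slowly, and probability mass near the strict 0.907
  threshold is not yet saturated at shorter schedules.

What the fixtures do **not** emulate: read-level artifacts (fragment
length, GC bias, duplicates), isoforms and intron-aware genomic
coordinates, antibody batch effects, correlated nulls in expression, and
the scale-free topology of real PPI networks. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
signal under idealized noise — not expected performance on real
MeRIP-seq compendia, whose published headline numbers require the
original datasets.

## Numerical and scale choices

* Fixture scales (200-node networks, 500 genes, 20 samples, ~2,800
  training windows) keep the full suite in minutes on one CPU.
* Monte Carlo defaults (100 random networks, 1000 permutations, 100
  disease nulls) are configuration; the tests and the acceptance script
  run 10–20 random networks, 100–200 permutations and 50–100 disease
  nulls, which already give p-value granularity well below the 0.05
  decision threshold.
* All RNG flows from explicit seeds through `numpy.random.Generator`;
  per-stage seeds are derived by hashing (config seed, stage name), so
  stages are independently reproducible and a rerun is byte-identical.
* Ties: gene heat breaks toward the lowest site coordinate; disease
  ranking breaks by disease id; subnetworks are reported largest-first.
* Degenerate inputs: zero-variance correlation vectors are flagged and
  excluded; transcripts shorter than the window yield no candidates;
  graphs with isolated nodes are rejected by the diffusion (isolation is
  removed upstream); a recurrence cutoff above the sample count empties
  the gene table and the pipeline exits cleanly with a warning.
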