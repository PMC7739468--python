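# Methods

This note documents the models implemented in `regulonkit`, the parameters
that matter, the numerical choices made where the design was open, and what
the synthetic test data do and do not establish.

## Motif representation and transfer

A site collection (≥ 2 aligned sites over {A,C,G,T}) is summarized as a PSWM
with a background-distributed pseudocount:

    f[j,b] = (count[j,b] + c·bg[b]) / (n + c),   c = 0.5 by default.

The pseudocount keeps log-odds scores finite for small collections while
distorting frequencies by at most c/(n+c). The PSSM is the log2-odds of the
PSWM against the *target genome's* mononucleotide composition — per-species,
because score thresholds calibrated on one genome's oligomer composition do
not transfer to another. Information content is the Kullback–Leibler
divergence from that background, in bits.

When several reference collections exist, the motif assigned to a target
species is the convex mixture of reference PSWMs with weights
w_r ∝ 1/(d_r + ε), where d_r is the patristic distance on the TF tree from
the target's TF to reference r and ε = 0.01 substitutions/site. The floor
makes a target that coincides with a reference (d = 0) dominant without
silencing other references. Classic progressive-alignment weighting schemes
are tree-partition based; the inverse-distance rule used here preserves their
monotone behavior (closer references weigh more) with a closed form that is
trivially reproducible. Mixtures require equal motif widths; aligning or
trimming incompatible motifs is the user's responsibility.

## TF phylogeny

Pairwise distances between TF proteins come from global alignments (BLOSUM62,
gap open 10, extend 0.5) as Poisson-corrected p-distances d = −ln(1 − p),
with p capped at 0.95 so unrelated sequences receive a finite maximal
distance (≈ 3 substitutions/site). Argument order is canonicalized before
aligning so the distance is exactly symmetric even when co-optimal alignments
exist. Trees are built by neighbor joining (scikit-bio), negative branch
lengths clamped to zero, and midpoint-rooted — no outgroup is assumed, and
ancestral reconstruction needs a root. Internal nodes are renamed N1..Nk in a
canonical postorder so node ids are stable across runs.

TF orthologs in each target genome are reciprocal best hits of the reference
TF at e-value ≤ 1e−30. The bundled search backend aligns the query against
every candidate (Smith–Waterman, BLOSUM62, open 11/extend 1) and converts
scores to e-values with gapped Karlin–Altschul statistics (λ = 0.267,
K = 0.041); any object implementing the same query→ranked-hits contract can
replace it. Species without a TF ortholog are dropped with a warning, since
the workflow is undefined for them.

## Promoter model

The promoter region of an operon is [−250, +50] around the translation start
of its first gene, truncated at the nearest neighboring gene and at contig
edges. Windows containing ambiguous bases are skipped — draft genomes contain
gaps. Strand scores are combined as log2(2^f + 2^r); the combined score
exceeds both strand scores and equals f + 1 for perfect palindromes.

* Background model N(μ_G, σ_G²): sample mean/SD (ddof = 1) of combined
  scores over all promoter windows of the genome; if a (pathologically small)
  genome yields fewer than 100 windows, the fit widens to whole-contig
  windows.
* Motif model N(μ_M, σ_M²): computed analytically from the mixture PSWM
  under column independence, on single-strand scores. Mixture motifs have no
  physical site list, so an analytic expectation is the only well-defined
  choice; whether the upstream tooling fitted realized site scores instead is
  unknowable from outside, and the analytic route is exact for the stated
  normal approximation.
* α: sites_per_promoter (config, default 1) divided by the genome's average
  promoter length, measured as the mean intergenic distance between first
  genes of divergently transcribed directon pairs, falling back to 250 bp.
* P(R): known regulon size / operon count when a reference regulon size is
  configured; otherwise the information-content route
  m = n_windows·2^(−IC), P(R) = min(m/n_operons, 1−1e−6).

The posterior treats window scores as independent. This is formally false
for overlapping windows; it is the standard simplification for this model
class and is retained deliberately. All likelihood products are accumulated
in log space with log-sum-exp mixing, so underflow cannot occur; the
log-space and direct-arithmetic forms agree to ≥ 10 significant digits
wherever the direct form is computable.

## Operon prediction

Intergenic distance is start(downstream) − end(upstream) in 0-based
half-open coordinates; overlapping genes give negative distances and are
always co-operonic. The merge threshold is the arithmetic mean of intergenic
distances over all within-directon adjacent pairs (fallback 50 bp when a
genome has none), optionally scaled by a config multiplier (default 1.0).
Pairs at exactly the threshold stay together.

The rescue split uses a score threshold t chosen as the smallest score with
FPR(t) ≤ 2^(−IC), where FPR is the exact probability that an i.i.d.
background k-mer scores ≥ t on a single strand. The score distribution is
computed by dynamic programming over scores discretized to 0.01-bit bins —
the discretization error (≤ width·0.005 bits) is far below score differences
between adjacent k-mers at realistic widths. If no attainable score reaches
the target FPR (a weak motif), the maximum attainable score is returned with
a warning. The split scan evaluates the *untruncated* [−250, +50] window of
every gene with single-strand scores on both strands: truncating at the
upstream gene boundary would hide exactly the sites this step exists to
recover, and single-strand scoring is what the FPR definition refers to.
Every qualifying non-first gene starts a new operon; the operation is
idempotent because first genes are never tested. After splitting, only the
promoters of new first genes are scanned; the background fit is not redone,
since operon structure does not change the genome-wide score distribution
materially.

## Ortholog groups

Only genes in operons whose posterior exceeds the cutoff (default 0.5,
strict inequality) in at least one species enter the all-vs-all search.
Reciprocal best hits (e-value ≤ 1e−10; ties broken by score then
lexicographic locus tag) define an undirected graph; ortholog groups are its
maximal cliques. A gene can belong to several maximal cliques; groups are
committed greedily by decreasing clique size, ties by larger total edge
score, then lexicographic member ids, and leftover genes become singletons.
This assignment policy is the package's own choice — "cliques" alone do not
define a partition.

## Ancestral reconstruction

Regulation history is a three-state character on the TF tree: s0, s1, and sa
(absent). Treating absence as a third Markov state, rather than missing
data, follows the explicit state vocabulary of the workflow. Each bootstrap
replicate samples leaf states (s1 with probability equal to the species'
posterior; sa deterministically where the group lacks a member), estimates
the equal-rates transition rate by maximum likelihood — a 25-point log-grid
scan over [1e−3, 100] followed by bounded scalar refinement (xatol 1e−4),
because the likelihood plateaus at high rates and a pure local search can
stall there; rate 1.0 is used if the likelihood is degenerate — and computes
marginal state posteriors at every internal node by the pruning algorithm
with a uniform root prior. Marginals are averaged over replicates (default
100; the seed is recorded in the report). Distinct leaf-state patterns recur
across replicates, so reconstructions are cached per pattern; this changes
nothing numerically and makes thousands of replicates cheap.

## Synthetic clades (the test generator)

The generator emits minimal valid GenBank records so the production parser is
exercised. Default study conditions: 4 species, 60 shared gene families in
conserved order (family 0 is the TF), operon sizes drawn from
(0.4, 0.3, 0.2, 0.1) for sizes 1–4, within-operon gaps ~ N(15, 5²) bp,
between-operon gaps ~ N(150, 40²) bp, a 16-bp planting PSWM with dominant
base probability 0.9 (≈ 22 bits), 30% of operons regulated, 20 reference
sites, per-species protein divergence 8% per residue and TF divergence
0, 8, 16, 24% across the four species.

Two generator choices deserve emphasis:

* **Regulation is assigned per promoter unit.** Divergently transcribed
  adjacent operons share one bidirectional intergenic gap, and both promoters
  scan all of it; a site planted there is visible to both. Such pairs
  therefore share regulation status and one planted site — the biological
  situation for bidirectional promoters — rather than contaminating an
  "unregulated" neighbor with a true site.
* **Planted and reference sites are functional.** Draws from the PSWM are
  rejected until the site scores ≥ μ_M − σ_M (the upper ~84% of the motif's
  score distribution). An unconditioned draw occasionally carries only ~3
  bits, which no scanner could distinguish from background; real regulated
  sites are under selection and cluster in the motif's functional range.
  Sites are placed uniformly over the feasible part of [−250, −width] of the
  intergenic gap, fully outside coding sequence.

What the fixtures do **not** emulate: genome rearrangement, horizontal
transfer, paralogy, pseudogenes, codon bias, skewed base composition, operon
structure divergence between species, and TF-binding sites inside coding
regions. Passing the end-to-end recovery tests therefore shows internal
consistency of the whole pipeline under favorable but realistic signal/noise
conditions, not performance on real genomes.

## Problem sizes and determinism

The test suite runs the complete workflow on the 4-species/60-gene clade and
the oracle suites on widths ≤ 6 (exhaustive k-mer enumeration), trees ≤ 6
leaves (exhaustive ancestral-state summation), graphs ≤ 40 vertices
(Bron–Kerbosch enumeration), and 100 random gene layouts (brute-force operon
splitting); these sizes make every oracle exact while keeping the suite in
the seconds-to-minutes range. All randomness flows from explicit seeds; a
run with identical configuration and seed reproduces byte-identical outputs,
and the report manifest records a SHA-256 checksum per file.

## Known limitations

* The mixture-weight rule is monotone-equivalent to, not identical with, the
  progressive-alignment weighting it stands in for; with many unevenly
  related references the weights will differ in detail.
* μ_M > μ_G is assumed for informative motifs; for a motif close to the
  background the posterior is uninformative (as it should be), and the split
  rule degenerates with a warning.
* tBLASTX semantics (six-frame translated search) are approximated by
  protein-vs-protein search; on annotation-complete genomes the difference
  is immaterial, on poorly annotated ones a production backend should be
  plugged in.
* The Karlin–Altschul e-values of the bundled backend use fixed gapped
  parameters rather than sequence-composition-adjusted ones; they are
  calibrated enough for best-hit ranking, not for absolute significance.
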