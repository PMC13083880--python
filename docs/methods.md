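# Methods

`chromdyn` implements a chromatin-state dynamics analysis for a
two-genotype, two-time-point design (wild type and knockout, before and
after a proliferative stimulus), built from five stages: binarization of
binned ChIP-seq coverage, hidden-Markov chromatin-state segmentation,
cross-condition transition coding, integration with differential gene
expression, and model-based clustering of expression trajectories.  A
synthetic-data module generates all inputs with planted ground truth so
every stage can be validated end to end.

## Binarization

Coverage for each histone mark is summed in fixed 5 kb bins.  The
background model is uniform: the expected background count of mark *m*
in a full bin is

    lambda_m = library_size_m * bin_size / genome_length,

scaled by the length fraction for a shorter terminal bin.  A bin is
called *present* for a mark when both

1. `count >= fold_threshold * lambda_bin` (fold rule, default 2; the
   boundary is closed because counts are integers and `lambda` is not —
   a configurable choice), and
2. the upper-tail Poisson probability `P(X >= count)` under
   `Poisson(lambda_bin)` is at most `tail_alpha` (default `1e-4`;
   `tail_alpha = 1` disables the tail test and leaves the pure fold
   rule).

Both criteria mirror the semantics of the standard binarizer for
chromatin-state analysis, which applies a Poisson tail test alongside
its fold-enrichment option.  No local background, mappability or input
subtraction is modeled; duplicate marking and blacklisting are upstream
concerns.

Note that the background estimate includes signal bins, so dense marks
raise their own threshold.  With the default simulation (~40% of the
genome carrying at least one mark) the effective threshold stays well
between the background and signal count laws; a mark covering half the
genome would start to undercall, which is a property of the
signal-to-background definition itself.

## Chromatin-state HMM

States are latent labels per bin with independent Bernoulli emissions
per mark: state *k* emits observation `o` with probability
`prod_m e_km^o_m (1-e_km)^(1-o_m)`.  One K=4 model is trained **jointly
on all four conditions** (pooled sequences, one per chromosome per
condition; no transition crosses a chromosome boundary), then each
condition is decoded separately.  A shared model is what makes state
identities comparable across conditions, which the transition coding
requires.

Training is Baum–Welch EM with scaled forward–backward recursions,
capped at 300 iterations, stopping when the log-likelihood gain drops
below `1e-4`.  Initialization draws emissions uniformly in (0.1, 0.9)
and uses uniform transitions with self-transition weight 0.5.  Among
random restarts the fit with the highest final log-likelihood wins.
The default is 5 restarts: on default-size simulations roughly a
quarter of single restarts converge to a local optimum that merges the
two repressive states (its log-likelihood is clearly lower, so restart
selection rejects it); five restarts push the probability that *all*
restarts fail below 0.1%.  An emission floor of `1e-6` prevents
zero-probability lock-in.

Per-bin states are assigned by maximal posterior probability
(forward–backward), matching the segmentation semantics of the standard
tool; Viterbi decoding is provided as a testing aid.  Ties break toward
the lowest semantic state index.

### Semantic state labels

With marks ordered (H2AK119ub, H3K27me3, H3K27ac) and emissions
thresholded at 0.5, raw states map to:

* state 1 — H3K27ac high, both repressive marks low (active);
* state 2 — nothing high (unmarked);
* state 3 — exactly one repressive mark high;
* state 4 — both repressive marks high (doubly repressed).

If two raw states share a pattern class the deterministic fallback
orders states by repressive emission sum ascending (H3K27ac descending
on ties) and warns.  The fallback can mislabel a degenerate fit — on
very small inputs (a few hundred bins) EM may genuinely merge states,
and the warning is the signal to inspect the model; at the default
problem size (16,000 training bins) the pattern rule applies cleanly.

## Transition codes and delayed-remodeling bins

Each bin's states across the four conditions, in the fixed slot order
(WT t0, WT t1, KO t0, KO t1), form the code `#{a0}{a1}_{b0}{b1}`;
`#41_44` reads "4 → 1 in wild type vs 4 → 4 in knockout".
Delayed-remodeling bins are those coded `#41_44`, `#42_44` or `#43_44`:
they leave the doubly repressed state in the wild type but stay in it
in the knockout.  Flow tables (K×K bin counts for consecutive condition
pairs) summarize the global dynamics behind alluvial displays.

Bins are annotated against a BED6 gene model: a bin overlapping any
promoter window (TSS ± 3 kb by default, the usual annotation-tool
default) is *promoter*; otherwise overlapping any gene body, *genic*;
otherwise *distal intergenic*.  Any-overlap is used rather than
midpoint containment because 5 kb bins dwarf promoter windows and
midpoint tests would systematically undercall.  The nearest gene
minimizes |bin midpoint − TSS| (TSS = start on +, end on −), ties going
to the lower TSS then the lexicographically smaller gene id.

## Expression integration

Candidate genes are the intersection of three sets: (1) nearest genes
of the delayed-remodeling bins, (2) genes upregulated in the wild type
at t1 vs t0 (`log2FC > 0`, `padj < 0.05` by default), and (3) genes
downregulated in the knockout vs wild type at t1.  Differential
expression is consumed as input tables (gene, log2FC, adjusted p) —
refitting a published DE tool is not this package's contribution.  The
expressed-gene filter retains genes with mean TPM strictly greater than
0.1 in at least one condition (means over three replicates).

## Trajectory clustering

Per-gene condition-mean trajectories are z-scored per gene (sample
standard deviation, n−1 denominator) and clustered with a G-component
Gaussian mixture with diagonal, component-specific covariances — the
"VVI" parameterization (varying volume, varying shape, axis-aligned).
EM uses seeded k-means++ responsibilities for initialization, 10
restarts, a `1e-6` variance floor (a lightweight stand-in for a
conjugate prior), and reseeds an emptied component from the point with
the lowest maximum responsibility.  This initialization differs from
the reference implementation of model-based clustering, which seeds
from agglomerative hierarchical clustering; the seeded variant is fully
reproducible from an explicit integer seed.

BIC is reported on the convention `2·loglik − df·log(n)` with
`df = (G−1) + G·D + G·D` (weights, means, diagonal variances), larger
better.  The component grid defaults to 2..30 step 2.  Two selection
rules are computed on every scan, because the phrase commonly used to
describe stepwise BIC selection ("the first stepwise increase reducing
BIC") is ambiguous: **max** (argmax of BIC over the grid; the default)
and **first-drop** (the largest G before BIC first decreases).  Both
are written into the scan report.

On clean mixture data the two rules agree and recover the planted
component count.  On pipeline expression data, where within-cluster
gene-level offsets form a continuum around the templates, BIC keeps
improving with more components and "max" tends to choose a large G;
this mirrors the behavior of BIC on real transcriptome trajectories and
is why the selection-recovery claims are made on the explicit mixture
simulation, not on the pipeline surface.

## Synthetic data

The generator emulates the statistical structure of the study inputs at
desk scale; its defaults are the conditions under which all recovery
claims are tested.

**Chromatin.**  Two chromosomes of 10 Mb at 5 kb bins (4,000 bins),
four conditions.  Per condition, states follow a sticky Markov chain
(`A = 0.8·I + 0.2·1·piᵀ`) whose stationary distribution
`pi = (0.15, 0.60, 0.125, 0.125)` leaves most of the genome unmarked,
as in real chromatin; each condition draws an independent path.
Emission truth puts each mark at 0.9 where present and 0.05–0.10
elsewhere.  Counts are a two-component Poisson mixture per mark:
background rate 20 per full bin, multiplied by `fold_on = 6` when the
mark is "on" — the simplest law matching the binarizer's background
model, which makes its error rates analytically checkable.

**Delayed remodeling** is planted as 3-bin windows carved out of
wild-type state-4 runs (short remodeling domains rather than isolated
bins, which a posterior decoder would smooth over): the window moves to
a target state in {1, 2, 3} at the late wild-type time point and is
held at state 4 in both knockout conditions, covering
`delayed_fraction = 0.1` of state-4 bins.  Any *unplanted* bin whose
four-condition pattern happens to read as a delayed code is reset to
`#44_44`, so the planted set is exactly the coded set and truth-path
recovery can be asserted as equality.

**Expression.**  1,200 genes, three replicates per condition, log2-TPM
surfaces: per-gene baseline N(4, 1) (a 5% "silent" cohort at −6 stays
below the TPM filter), plus a cluster template, plus per-gene
per-condition offsets (sd 0.5, the within-cluster spread), plus
replicate noise (sd 0.4).  Cluster templates are random directions
scaled so the minimum pairwise distance is
`separation · sigma_within · sqrt(D)` (template 1 is the flat
trajectory).  Each delayed window anchors one gene at its center bin —
other genes are kept ≥ 2 bins away so the window's gene is provably its
bins' nearest TSS — and delayed genes carry the planted effect
(0, +3, 0, +0.6) in log2 over (WT t0, WT t1, KO t0, KO t1): a strong
wild-type induction attenuated to 20% in the knockout, with a tighter
condition offset (sd 0.25) reflecting a coherent cohort.

**DEG tables** are computed from the sampled replicates: log2FC is the
difference of condition means and p-values come from a moderated z-test
whose standard error uses the genome-wide median of per-gene pooled
variances, with Benjamini–Hochberg adjustment.  Dispersion sharing is
deliberate: the tables emulate the output of a dispersion-moderated DE
tool, and a per-gene t-test at three replicates cannot represent its
power (its df-4 tails make small adjusted p-values unreachable).

**Standalone trajectories** (`simulate_trajectories`) provide planted
Gaussian clusters for clustering studies: for G ≤ D the templates sit
on scaled coordinate axes and are exactly equidistant; points add
isotropic noise (sd 0.5).

All randomness flows from one seed through named substreams
(`zlib.crc32` of the stage name), so each stage is reproducible in
isolation and identical configurations produce byte-identical outputs.

**What the generator does not model:** read-level structure (fragment
lengths, GC, mappability), local background variation, realistic gene
architecture (bodies are fixed 2 kb), correlated replicate structure,
and count-based expression noise (log-normal instead of negative
binomial).  Passing tests therefore demonstrate the correctness of the
algorithms under the stated statistical model, not performance on real
sequencing data.

## Numerical choices

* Forward–backward uses per-step scaling; likelihood work in log space.
* Emission floor `1e-6`, transition floor `1e-12`, GMM variance floor
  `1e-6`.
* EM stopping: Baum–Welch `tol = 1e-4` on log-likelihood gain (cap 300
  iterations); GMM `tol = 1e-6` (cap 200).
* Ties: posterior and responsibility argmax break toward the lowest
  state/component index; nearest-gene ties toward the lower TSS, then
  the lexicographic gene id.
* Degenerate inputs: all-identical observations train to a
  one-effective-state model with a warning; constant trajectories are
  dropped from z-scoring with a warning; an emptied mixture component
  is reseeded from the worst-explained point.

## Problem sizes

Default analyses run at 4,000 bins × 4 conditions × 3 marks for the
chromatin chain and 1,200 genes × 4 conditions × 3 replicates for
expression; clustering studies use n = 1,200, D = 6, G* = 6.  These
sizes give recovery margins (binarization accuracy ≥ 0.95, decoding
accuracy ≥ 0.90, delayed-bin precision/recall ≥ 0.8, ARI ≥ 0.9) without
requiring long runtimes.

## Known limitations

* The four-state scheme is fixed; no state-number selection is offered.
* The semantic labeling fallback can misorder states on degenerate
  fits; it always warns.
* The uniform background makes binarization of very dense marks
  conservative.
* BIC model selection on continuous (non-mixture) trajectory data
  favors large G; interpret the chosen G on real data accordingly, and
  prefer the per-cluster mean trajectories over the raw count of
  clusters.
* DEG tables are inputs; the package neither models counts nor refits
  dispersion.
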