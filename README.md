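# chromdyn

Chromatin-state dynamics across conditions: find genomic loci whose
repressive chromatin fails to remodel in a mutant, and connect them to
delayed gene activation.

## The problem

After a strong proliferative stimulus (the motivating system is mouse
liver regeneration after partial hepatectomy), quiescent cells remodel
repressive chromatin — notably the Polycomb marks H2AK119ub and
H3K27me3 — before re-entering the cell cycle.  In a mutant that cannot
remove these marks on schedule, some loci that normally exit the
doubly-repressed state stay repressed, and nearby genes fail to induce
on time.  `chromdyn` provides the full computational chain for this
analysis:

1. **Binarize** binned coverage of three histone marks (H2AK119ub,
   H3K27me3, H3K27ac) against a Poisson background: a bin is "present"
   for a mark when its count is at least twice the background
   expectation and clears a Poisson upper-tail test.
2. **Segment** the genome into four chromatin states with a hidden
   Markov model with independent Bernoulli emissions per mark, trained
   jointly on all conditions (Baum–Welch, ≤ 300 iterations) and decoded
   per condition by maximal posterior.  States are labeled
   semantically: 1 active (H3K27ac alone), 2 unmarked, 3 one repressive
   mark, 4 both repressive marks.
3. **Code transitions** per 5 kb bin across the four conditions
   (WT t0, WT t1, KO t0, KO t1) as `#{a0}{a1}_{b0}{b1}` — e.g.
   `#41_44` means "4 → 1 in wild type vs 4 → 4 in knockout" — and
   select the delayed-remodeling bins (`#41_44`, `#42_44`, `#43_44`).
4. **Integrate with expression**: intersect the nearest genes of
   delayed bins with genes up in wild type over time and genes down in
   knockout vs wild type at the late time point.
5. **Cluster trajectories**: z-score per-gene condition means
   (TPM > 0.1 filter) and fit diagonal-covariance Gaussian mixtures
   ("VVI"), scanning G = 2..30 by BIC
   (`2·loglik − df·log n`, larger better).

A synthetic-data module simulates all inputs at desk scale with planted
ground truth (state paths, delayed windows, attenuated genes, cluster
labels), so the whole pipeline is testable without any sequencing data.

## Worked example

Run the full chain on a simulated study (seed 42, default sizes:
2 × 10 Mb chromosomes at 5 kb bins, 4 conditions, 1,200 genes):

```bash
echo '{"seed": 42}' > config.json
chromdyn run-all --config config.json --outdir run
```

which prints:

```
simulated 4000 bins x 4 conditions -> run/sim
binarized 4 conditions -> run/binarized
trained K=4 model, final log-likelihood -16727.47 -> run/model.json
segmented 4 conditions -> run/segments
31 delayed-remodeling bins -> run/dynamics
near=11 up=669 down=852 intersection=11
retained 1185 genes; chosen G=26 (max=26, first-drop=18)
pipeline complete -> run
```

Reading these numbers: the four-state model was trained jointly on all
conditions' binarized tracks; 31 bins carry a delayed-remodeling code
(state 4 lost in wild type, kept in knockout — this run planted 36 such
bins in 12 windows); their nearest genes (11) intersected with the 669
wild-type-induced and 852 knockout-reduced genes give 11 candidate
genes with delayed activation — here 11 of the 12 planted attenuated
genes, with no false positives.  The clustering stage retained 1,185 of
1,200 genes at the TPM > 0.1 filter and reports both BIC selection
rules for the trajectory mixture.

Every stage is also available as a library function
(`simulate_chromatin`, `binarize`, `baum_welch`, `posterior_decode`,
`transition_codes`, `select_delayed_bins`, `annotate_bins`,
`triple_intersection`, `zscore_rows`, `bic_scan`, ...) and as an
individual subcommand (`simulate`, `binarize`, `learn`, `segment`,
`dynamics`, `integrate`, `cluster`).  Identical configurations and
seeds produce byte-identical output trees.

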