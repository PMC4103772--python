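# Methods

## Model and assumptions

`stclust` treats a sample library — the multiset of primer- and
barcode-trimmed reads for one individual — as draws from a mixture of N
unknown allelic sequences plus error processes. Two standing assumptions
drive the design: most reads are error-free (≈82 % for pyrosequencing
chemistry, which also motivates the default dominance threshold), and
artifacts are minor deviations from the allele they derive from, so reads
group naturally into roughly N clouds, one per allele. Chimeras are the
exception — they recombine two alleles and are handled by a dedicated
post-hoc screen rather than by clustering.

The clustering itself is a quasi-Dirichlet ("Chinese restaurant")
sequential insertion process. Unlike a formal Dirichlet process, whether a
focal read joins an existing cluster is deterministic given the threshold
γ: it joins the most similar cluster label at or above γ, else founds a
new cluster. The only stochastic element is the insertion order, which is
integrated out by replicating each round (default 100×) and assigning
every sequence its modal cluster label. Reads with the same sequence
always co-cluster, so the process is implemented at the unique-sequence
level: sequences enter in an order drawn without replacement with
probability proportional to their remaining read counts, which is exactly
the order-of-first-appearance distribution of uniform read-level draws.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| γ schedule | percent similarity to join a cluster; rises each round | auto → 97, step 1 | start at the floor of the library's minimum pairwise similarity (one giant cluster), stop slightly below 100 so minor-error artifacts stay attached to their allele |
| θ | minimum cluster size as a fraction of the library | 1/22 | starting guidance is 1/(N_max·2); for six diploid loci N_max = 12 gives 1/24, tightened to 1/22 for the worked-example conditions |
| δ | minimum dominant/subdominant read ratio | 4.0–4.55 | 0.82/0.18 ≈ 4.55, the error-free/errored read ratio; a cluster whose second sequence is more than 1/4.55 of its first likely holds two alleles |
| replicates | insertion-order replicates per round | 100 | enough for a stable per-sequence mode; configurations rarely exceed 2–3 variants |
| ε | samples (other than the focal one) in which a sequence must label a good cluster to rescue a small cluster | 3 | guards against promoting artifacts that recur by chance |
| min dropped reads | minimum reads in a promotable small cluster | 3 | the reads need not share a sequence; single-read clusters are too easily contamination or barcode error |
| expected length | correct amplicon length in bp | 213 | the target amplicon; drives pair-type ordering, the split rule and the optional length screen |
| min length / min library / subsample cap | phase-1 filters | 200 bp / 80 reads / 1000 reads | ≈94 % of the amplicon; below ~80 reads genotypes are unreliable; capping deep libraries bounds the O(n²) pair scan |

Size comparisons use ≥ θ ("must contain at least this proportion"),
dominance uses > δ ("must be greater than"); single-sequence clusters have
infinite dominance ratio and pass.

## Alignment and numerical choices

Every similarity and difference profile comes from one fixed global
(end-to-end) aligner: match +1, mismatch −1, gap −2 per gap column, ties
broken toward fewer gap columns and then leftmost placement (implemented
by folding score and gap count into one lexicographic integer objective;
traceback prefers diagonal, then a gap in the second sequence). Percent
similarity is 100 × matches / alignment columns. Given the optimal
(score, gap-column) pair and the two lengths, the match, substitution and
per-side gap counts are uniquely determined, which makes pair types and
similarities reproducible to the bit. The aligner is written directly (a
numba-compiled Needleman–Wunsch) because the tie-break policy is part of
the method's contract; no installed aligner exposes it.

Other numerical conventions:

- Tie-breaks in clustering (equal similarity to two clusters, equal
  dominant counts) resolve toward the larger cluster read total, then the
  lexicographically smallest label — determinism under a fixed seed.
- The modal label is the most frequent across replicates; an exact tie
  takes the lexicographically smallest label. Modal labels are opaque
  group keys: no transitive merging.
- The θ denominator is the post-filter, post-subsampling library size,
  fixed across rounds.
- Ambiguous clusters from one round are pooled and re-clustered jointly
  at the next γ, not in isolation.
- The ambiguous split assigns round(total · d/(d+s)) reads to the
  dominant sub-cluster (d, s = top two correct-length member counts;
  wrong-length top sequences are skipped, so the third most frequent can
  serve as subdominant). Sub-cluster membership is notional — label plus
  read total — matching how the split is defined. A residual ambiguous
  cluster with fewer than two correct-length members is kept whole as
  small, with a warning.
- Seeding: one global seed; per-sample seeds by CRC32 of the sample id
  XOR the global seed (kept below 2³¹), per-round and per-replicate
  streams derived through `numpy` SeedSequences. Adding a sample never
  perturbs another sample's results.
- In phase 2, types are processed I → II → III → IV, recomputing pair
  profiles against the current library state between types; "more common"
  is strict, and a second member shared by several candidate pairs of one
  type goes to the most common first member (an exact tie skips the
  pair). A strict mode refuses shared second members entirely.
- Degenerate inputs: empty libraries yield empty cluster sets; an empty
  run yields empty genotypes; correlations with fewer than three points
  or zero variance are reported as absent, never fabricated.

## The simulator

The generator emulates one sequencing run over a pool of
divergence-constrained alleles (default 213 bp, pairwise similarity
≤ 90 %, plus designated 2-bp-apart pairs to exercise the similar-allele
problem). Each sample draws a diploid multi-locus genotype (two picks per
locus), then reads proportional to per-allele relative efficiencies;
libraries span 80–1000 reads. Per read, a homopolymer indel (expand or
contract a run of ≥ 2 by one base) occurs with probability 0.12 and a
substitution with probability 0.0682, calibrated so 82 % of reads are
error-free with indels dominant, as in pyrosequencing; 0.5 % of reads are
single-crossover chimeras of two co-amplified alleles at a uniform
breakpoint. Every read carries a provenance record (source allele, error
events, chimera parents), so recovery reports can distinguish *missing*
alleles (zero reads emitted — unrecoverable by any analysis) from
*dropped-and-lost* ones (reads present but no call).

What the simulator does not model: flowgram-level signal, position- or
motif-dependent substitution spectra, PCR-cycle error propagation
(artifact read counts are independent per read, so large correlated
artifact families are rarer than in real data), barcode cross-talk, and
quality-score structure (the method never reads qualities). Passing tests
therefore demonstrate correctness of the algorithmic machinery and
recovery under the stated error mix — not robustness to every artifact
family structure a real run can produce.

## Problem sizes used in the test and acceptance runs

The packaged studies use 6–32 samples of 200–600 reads over pools of 14–18
alleles: a zero-noise run (6 samples), a calibrated-mix recovery study (20
samples, 400–600 reads, six equal-efficiency alleles per sample), and an
efficiency-diagnostics study (32 samples × 600 reads with a four-allele
low-efficiency clade at relative efficiencies 0.10–0.14). These sizes give
stable per-allele drop-rate estimates while keeping a full run on one CPU
in the minutes range; the algorithms themselves have no size-dependent
switches.

## Known limitations

- **Absorption of similar rare alleles.** A low-frequency allele whose
  sequence is moderately similar to a much more abundant co-occurring
  allele can be absorbed into that allele's cluster: once every other
  allele has separated, the pair's dominance ratio may exceed δ and the
  cluster exits as good before γ rises enough to split it. The rare
  allele is then silently missing (not dropped, so phase 4 cannot rescue
  it). This is the inherent gray-zone trade-off of the dominance
  criterion; raising δ trades it against false ambiguity. Low-efficiency
  alleles in real data tend to be sequence-divergent, which is why the
  diagnostics simulation models them as a divergent clade.
- **Quadratic pair scan.** Phase 2 and the similarity matrix scale with
  the square of unique sequences; the subsample cap keeps this bounded.
- **Replicated-mode stability.** With few replicates, per-sequence modes
  of nearly 50/50 configurations can be noisy; 100 replicates and the
  deterministic tie-breaks keep runs reproducible, but the mode is still
  per-sequence, not a joint partition estimate.
- **Chimera screen scope.** Only single-crossover daughters of two
  same-sample parents are considered, with exact matching by default; a
  chimera that ever occurs without both parents is retained as a putative
  natural recombinant, by design.
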