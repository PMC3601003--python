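# Methods

## The model

`ltrhmm` models a family of long terminal repeats (LTRs) with a linear
nucleotide profile hidden Markov model: `M` match states, each with its own
emission distribution over A/C/G/T, flanked by insert states `I_0..I_M`
(emitting unaligned residues between conserved positions) and delete states
`D_1..D_M` (skipping conserved positions), plus begin and end anchors. All
nine transition types between consecutive match/insert/delete states are
legal. Alignment is global: an LTR is modelled end to end, from its 5'
short inverted repeat (SIR) to the 3' one, which is where integrase-driven
conservation concentrates. Locality for genome screening comes from
windowing, not from local-alignment wing states.

Scores are log-odds in bits: the Viterbi (maximum-probability) path log
probability minus the log probability of the same residues under a
background residue model, divided by ln 2. A score of 0 means the sequence
is no more probable under the profile than under background. `N` residues
are scored neutrally (probability 1/4 under both model and background).

## Numerics

All dynamic programming runs in natural-log space. Delete states form a
non-emitting chain inside each residue layer; both the forward/backward and
the Viterbi recursions evaluate that chain with a prefix scan
(`logaddexp.accumulate` / `maximum.accumulate` over the entry points of the
chain), so each sequence costs an O(L) Python loop of vectorised O(M)
numpy steps. The genome scanner batches equal-length windows into a single
(windows x states) lattice. Viterbi traceback recomputes local argmaxes
from the stored score matrices; ties prefer match over delete over insert,
which makes paths deterministic.

Training is Baum-Welch EM with a small additive pseudocount (default 1e-6,
also the probability floor), so the log-likelihood trace is monotone up to
a perturbation far below the reported tolerance. Initial emissions are
near-uniform with seeded relative jitter of 1e-2 to break symmetry;
initial transitions favour the match path (0.8/0.1/0.1), which anchors the
register of the match backbone on the sequence start and makes planted
motifs come out at their true offsets. EM stops when the total
log-likelihood changes by less than `tol` (default 1e-3) or at `max_iter`
(default 50). An empty sequence is legal at alignment time (all-delete
path) but a training set must contain at least two non-empty sequences.

## Model construction protocol

A family is split 80/20 into training and held-out sequences (seeded,
`|train| = round(0.8 n)`, both parts non-empty, minimum family size 5).
Noise regularisation augments the training split: each sequence
contributes one copy whose residues are independently substituted with
probability `z` to a uniformly chosen different residue, alongside the
untouched original. The held-out split is never perturbed and never seen
by EM (content hashes are asserted). One model is trained per `(M, z)`
grid cell and evaluated by the mean held-out log-odds score; the best cell
wins, ties toward smaller `M` — longer profiles merely promote variable
positions to quasi-random match states.

A design observation from the synthetic benchmarks: because the originals
are retained, even heavy noise (z = 0.5) acts as useful smoothing and
keeps EM off poor local optima, so held-out score is not maximised at the
smallest z; the benefit is non-monotone, and the fully scrambled extreme
z = 1 scores below intermediate z. The property suite asserts exactly
this shape (noise helps vs z = 0; z = 1 helps less than z = 0.5) rather
than a monotone preference for small z. "Removing" noise (subsampling or
denoising the training set) is deliberately not implemented.

## Consensus, information content and motifs

The consensus is the per-column argmax residue (alphabetical tie-break);
the degenerate consensus emits a single residue when its probability
reaches `major_threshold` (0.6), else the minimal IUPAC class covering all
residues at or above `minor_threshold` (0.25). Information content per
column is `2 - H2(p)` bits against a uniform background with no
small-sample correction, so a fully conserved column is exactly 2 bits and
a uniform one 0; a background-weighted (relative-entropy) variant is
available behind a flag. Motif scanning is IUPAC-class matching with
overlapping hits. The SIR report takes the degenerate consensus of the
first and last 7 match states (conservation extends roughly 7 bp into the
LTR) and reports the fraction of positions where the 3' letter's class
intersects the reverse complement of the 5' letter's class. Motifs are
reported on match-state consensus only; insert-state expected lengths are
available in the model JSON.

## Detection

Windows of 0.8x, 1.0x and 1.25x the model length advance by a stride
(default 10 bp) across both strands; each is Viterbi-scored in bits, and
windows with more than 50% N are skipped. Overlapping windows are merged
by non-maximum suppression (best-scoring representative per locus), so
counting is per element. The truth set is first cleaned by the fragment
filter: annotations shorter than 100 bp or ending more than 100 bp from
the 3' end of the family consensus are discarded. An annotation counts as
detected when a single hit covers at least 50% of it (no rule is inherited
from the original protocol; 50% coverage is the weakest rule that still
forces positional accuracy, and it is configurable); hits covering no
annotation at all are additional positives; sensitivity is
detected/(detected+missed) in percent. The threshold is chosen from the
merged-window score grid as the smallest value keeping additional
positives at or below a bound (default 100) and, among those, maximising
sensitivity; if no value qualifies, +inf is returned with a warning. The
report is optionally computed a second time over truth records outside
the training set (matched by `source_id`, falling back to family), since
training elements are found more easily.

## Phylogeny

Each family's profile yields a consensus; the consensus set trains one
general profile (noise level `z`), and Viterbi-aligning every consensus to
it places homologous match states in shared columns — the SuperViterbi
alignment. Insert runs are padded per run and written lowercase; ungapping
any row reproduces its input exactly. Distances are p-distances
(proportion of differing nucleotides) with pairwise deletion of gapped
columns by default — consensuses differ in length, and pairwise deletion
keeps the most signal; complete deletion is available. Trees are
neighbour-joining (Saitou-Nei, via scikit-bio) with negative branch
lengths clamped to zero. Column bootstrap resamples alignment columns with
replacement, rebuilds the NJ tree per replicate, and annotates each
internal edge of the point tree with the percentage of replicates
containing its bipartition; degenerate replicates (a pair with no
comparable columns) are skipped and counted. The mean bootstrap averages
over the internal edges of the point tree only, and the grid search over
consensus `M`, general `M` and `z` returns the tree maximising it. The
default replicate count is 1,000; the test suite and the acceptance
script use 100 to keep runtimes in seconds.

## Synthetic data

`LTRFamilySpec` plants, on a background that is depleted of C (like the
low-complexity U3 filler of real LTRs), the canonical conserved layout:
5' SIR `TGTTRNR` at position 0, `TATATA`, `AATAAA`, a GT-rich run, and the
complementary 3' SIR `YNYAACA` at the end. Degenerate letters are resolved
once at the ancestor, so the family is internally consistent at SIR
positions; when two planted patterns are mutually reverse-complementary
(the SIR pair), the second is realised as the reverse complement of the
first, so the ancestor's actual termini are complementary — as integrase
recognition of both LTR ends implies. Descendants accumulate i.i.d. substitutions (default rate 0.05
per site, matching a moderately diverged family) and indels (default rate
0.01 per site, geometric lengths with mean 3 bp) — the indel model is not
a claim about LTR evolution, it simply produces the length variation the
profile must absorb. Genomes are i.i.d. background at a chosen GC content
with implants placed at seeded random positions and strands, at least 1 kb
apart; fragmentary implants keep a uniform 30-70% of one end and record
consensus-relative coordinates so the fragment filter is exercisable.
`make_superfamily_system` evolves one root LTR into two clades of family
founders (between-clade divergence 0.4, within 0.02 in the benchmarks) and
then into per-family sequence sets, returning the true tree.

What the generators do not emulate: insertion-age structure and 5'/3' LTR
divergence, target-site duplications, nested repeats, compositional
heterogeneity along real chromosomes, and solo-LTR/full-element length
mixtures. Passing tests therefore demonstrate correctness of the
algorithms and recoverability of planted structure under realistic noise
levels, not detection performance on real genomes.

## Problem sizes

The benchmark sizes were chosen as the smallest at which the planted
structure is informative: families of 25 sequences with 100-120 bp cores
and profiles of matching length; a 50 kb genome with 5 full and 3
fragmentary implants; 20 seeds for motif-recovery rates; 20 random
additive trees (up to 8 taxa) for NJ exactness; 6 families in two clades
with 100 bootstrap replicates for the superfamily split. Real LTR families
(150-700 bp, chromosome-scale screening) run with the same code; cost
scales linearly in genome length and model length.

## Known limitations

- Scores are in bits under this package's background model and are not
  comparable to thresholds or test scores reported on other scales.
- The profile is single-hit and global; tandem or nested LTRs inside one
  window resolve to the single best-scoring locus.
- Model selection maximises mean held-out log-odds; it does not penalise
  model length beyond the tie-break, so grids should span sensible `M`.
- EM occasionally converges to an alignment register shifted by one
  position around descendant indels; at substitution rate 0.05 and indel
  rate 0.01 the chance that a trained consensus carries every planted
  motif at its exact offset is roughly 90-100% per family, not 100%.
- Bootstrap supports are conditioned on the SuperViterbi alignment; they
  do not propagate uncertainty in the alignment or in the consensuses.
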