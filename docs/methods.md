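# Methods

`crcpipe` implements core regulatory circuitry (CRC) discovery from a single
H3K27ac ChIP-seq sample's peak calls and signal: super-enhancer (SE)
identification, SE-to-TF-gene assignment, motif scanning of extended SE
regions, and enumeration and scoring of fully interconnected autoregulatory
TF circuits. A synthetic-epigenome generator plants a known circuit so that
every stage can be validated against ground truth without external data.

## Coordinate model and inputs

All intervals are 0-based half-open (BED convention); GTF input (1-based
inclusive) is converted on read and never seen downstream. Inputs are
narrowPeak/BED peaks, an optional 4-column bedGraph signal track, gene
models from GTF, a genome FASTA (soft-masking uppercased on read), a
plain-text TF symbol list restricting circuit nodes, and motifs in MEME
minimal format with alphabet A,C,G,T. bedGraph steps that overlap are
rejected rather than summed: overlapping-step dialects are ambiguous and we
surface them instead of guessing. Probability rows off by at most 1e-3 are
renormalised (MEME files printed at low precision routinely drift by that
much); larger deviations are errors.

## Enhancer stitching

Peaks whose midpoint lies within ±`tss_window` (default 2,500 bp) of any TSS
are removed first; `tss_window = 0` disables the filter, since it is not
certain that promoter exclusion belongs in every analysis. Remaining peaks
are merged transitively: two peaks share a stitched region iff a chain of
peaks connects them with successive gaps ≤ `stitch_distance` (default
12,500 bp, the ROSE convention). Overlapping input peaks are merged into one
constituent footprint before gap logic so signal is never double-counted.
Region signal is the bedGraph value integrated over constituent footprints
only (gaps contribute nothing); without a track, the sum of narrowPeak
signalValues is used. An optional control track is rescaled by the
total-mass ratio, subtracted, and floored at zero. The "unstitching" of
regions spanning multiple TSSs that some ROSE builds apply is deliberately
not implemented.

## Super-enhancer calling

Regions are sorted by ascending signal s_1 ≤ … ≤ s_n. With overall slope
m = (max − min)/n, each rank x defines a line of slope m through (x, s_x);
the cutoff rank x* is the one whose line leaves the fewest points on or
below it, ties resolved to the largest x (fewest, strongest SEs). A point j
counts as on or below the line iff its rank-adjusted signal s_j − m·j is at
most s_x − m·x; evaluating the comparison in rank-adjusted form keeps
knife-edge decisions consistent across candidate lines and reduces the
search to a single arg-min, which the exhaustive per-candidate count (the
reference formulation, kept as the test oracle) must and does match exactly.
The cutoff is y* = s_{x*}; regions with s > y* are super-enhancers. All
signals equal degenerates to x* = n and zero SEs; a single region cannot
define a curve and is flagged typical. The cutoff is scale-equivariant:
scaling all signals by c > 0 scales y* by c and leaves SE membership
unchanged.

Genes are assigned to an SE when their TSS lies inside it or within
`assign_window` (default 50,000 bp, ROSE gene-mapper convention) of its
boundary; overlap-only assignment is the `assign_window = 0` special case.
The primary gene minimises TSS distance (ties lexicographic). A TF is
SE-associated when at least one SE is assigned to it.

## Motif scanning

SE intervals are extended 500 bp on both sides (clipped at chromosome
bounds) before scanning. Scoring is log2-odds against a 0-order background
(uniform by default; optionally estimated from the scanned sequences) with a
background-proportional pseudocount (default 0.1):
entry(j,b) = log2((p_jb + 0.1·bg_b)/1.1/bg_b). Exact p-values follow the
standard discretized dynamic-programming construction: log-odds entries are
scaled so the achievable score range spans 1,000 integer bins, rounded, and
the distribution of window scores under the background is built by
position-wise convolution; the tail array gives P(score ≥ t). Hit calling
uses the same integer scores as the p-value lookup, so calling is internally
consistent; the real-valued bit score is reported alongside. Windows on both
strands with p ≤ 1e-4 (the FIMO-conventional default) are hits; overlapping
hits are all reported, with no greedy masking, and N bases contribute zero
score (background substitution). Both-strand and overlapping occurrences all
count toward edge support — the most literal reading of "binding motif
occurrences", and the one we document. Multiple motifs sharing a TF symbol
have their counts summed.

## Graph, circuitries and score

The node set is the SE-associated TFs from the supplied TF list. A directed
edge a→b exists when TF a's motif occurs at least `edge_min` (default 1)
times across the extended SEs assigned to TF b. A TF is autoregulated when
its own motif occurs strictly more than `self_threshold` = 2 times in its
own extended SEs; the strict "more than two" rule is kept verbatim and
exactly-two is excluded.

A circuitry is a set of autoregulated TFs in which every ordered pair is an
edge. Enumeration is downward-closed — every qualifying subset of size ≥
`min_size` (default 2) is emitted, not only maximal ones — implemented as
clique enumeration on the symmetrized graph (undirected edge iff both
directions present), which provably equals power-set filtering and is tested
against it. Above 25 autoregulated nodes an explicit `max_size` is required,
since the universe is exponential.

Each TF's occurrence count occ(t) is the number of enumerated circuitries
containing it, and score(C) = Σ_{t∈C} occ(t) / |C|: the total occurrence of
a circuitry's members across all possible circuitries divided by its size.
Occurrence counting over the full downward-closed universe is what makes
the score discriminate — it rewards TFs embedded in many interconnected
sub-circuits. Reported candidates are ranked with maximal circuitries first,
then by score descending, size descending, and lexicographic members. The
maximal-first rule reflects what a candidate core is: a non-maximal subset
is a fragment of a larger loop, not a competing circuit, yet it still
contributes occurrence statistics. Under pure score ordering a pair of
high-occurrence hub TFs would always outrank the full clique containing
them (the mean of the two largest occ values cannot be smaller than the mean
over a superset), so "top-scoring circuit" would degenerate to "top pair";
ranking maximal candidates by the occurrence score avoids that while keeping
the score's discrimination among genuinely competing (maximal) circuits. A
`maximal_only_occurrence` switch restricts occurrence counting to maximal
circuitries for sensitivity analysis.

## Synthetic epigenome

The generator emulates one sample's evidence around `n_tf_genes` = 20 TF
genes on 2 × 2.5 Mb chromosomes of i.i.d. bases at GC 0.41 (hg38-like).
Genes sit on a 120 kb grid so no neighbour TSS intrudes into another TF's
50 kb assignment window. A random `k_core` = 5 subset is the planted core:
each core TF receives a cluster of 5 peaks (300–500 bp wide, 600 bp gaps —
MACS2-narrow-like constituents) placed 4–8 kb from its TSS, with per-bp
signal drawn log-normally around median 50. Within the cluster footprint,
5 instances of every core TF's motif (including its own) are embedded at
recorded positions on random strands — a complete digraph with self-loops.
Instances are consensus-sampled (per column: consensus with probability 0.9,
else a draw from the column), so most but not all planted words are exact.

Motifs are width-8 PWMs with one dominant base per column at probability
0.95 and the remainder spread evenly; consensus sequences (and their reverse
complements) differ pairwise by ≥ 4. Two consequences are intended. First,
under a uniform background every specific 8-mer has probability 4⁻⁸ ≈
1.5e-5, and with evenly spread off-consensus probabilities all 24
single-mismatch words tie in score, so a 1e-4 exact-p-value threshold admits
essentially only the consensus word: the per-window false-positive rate is
~1.5e-5 and an extended ~5 kb SE accrues ~0.2 spurious hits per motif. At
that load the strict "more than two" rule and the full-interconnection
requirement genuinely discriminate; with wide (multi-kb × λ≈1) regions or
heterogeneous mismatch penalties the 1e-4 threshold floods the graph and no
occurrence score can rescue it — a real phenomenon worth knowing about when
applying the method to large SEs. Second, planting five copies per
(motif, host) pair keeps the detected self-count above two with near
certainty even though ~4% of sampled instances deviate from consensus and
are individually missed.

Decoys exercise the rules: three near-miss TFs receive intermediate-signal
clusters (median 8 per bp) carrying exactly 2 self-motif copies (fails the
strict rule) and pairwise cross-motifs with one ordered edge deliberately
missing (fails full interconnection); the remaining TFs get single low-signal
peaks near their TSSs; 150 low-signal background peaks (median 1 per bp) are
scattered genome-wide. Log-normal draws are clipped at ±2σ so the three
signal tiers cannot overlap, making the separation invariant (every planted
core SE outweighs every decoy cluster, which outweighs every background
region) hold by construction. Background and singleton peaks keep > 13 kb
from each other and planted clusters keep a 15 kb margin from everything, so
nothing stitches across tiers and planted SE footprints are exactly the
stitched regions the pipeline sees. All randomness flows from one seeded
generator and all writers are canonical, so identical config+seed yields
byte-identical files.

What the generator does not model: mappability and copy-number artifacts,
fragment-level read noise, nucleosome structure, correlated motif grammar,
input/control asymmetry, and the 10–50 kb SE widths of real chromatin.
Passing recovery tests therefore shows the inference machinery is correct
under clean, well-separated conditions — not that real patient data will
yield unambiguous circuits.

## Numerical and degenerate-input choices

* Discretization: 1,000 bins across the achievable score range; DP mass is
  checked to 1e-9. Exhaustive 4^w enumeration must match the DP exactly on
  integer scores (tested for w ≤ 6).
* Thresholds below the minimum achievable score give p = 1; above the
  maximum, p = 0; a sequence shorter than the motif yields no hits.
* Region sorting before ranking is by (signal, chromosome, start, end, id),
  so SE calling is invariant to input order and byte-deterministic.
* Circuitry tie-breaks (size descending, then lexicographic members) are a
  reproducibility convention, not a scientific claim.
* Empty peak files, empty circuitry universes and headers-only outputs are
  all defined, tested behaviours rather than errors.

## Problem sizes

Validation runs use the default synthetic conditions above (≈250 peaks,
20 motifs, ~5 Mb genome); a full simulate-plus-pipeline cycle takes well
under a second, and the bundled recovery check repeats it across 20 seeds.
Oracle-equivalence tests run 100 stitching instances (≤1,000 peaks), 100
ranked curves (≤10,000 points), 20 PWMs (width ≤ 6, exhaustively
enumerated) and 50 random digraphs (≤15 nodes, power-set filtered).

## Known limitations

* One sample per run; cross-sample consensus circuits are out of scope.
* No BAM/bigWig input; peaks and bedGraph come from the caller upstream.
* 0-order background only; no q-value correction across motifs.
* The ROSE "unstitch across TSSs" refinement is not implemented.
* Whether occurrence counting should include non-maximal circuitries and
  whether an edge needs more than one motif hit are genuinely open choices;
  both are exposed (`maximal_only_occurrence`, `edge_min`) with the defaults
  argued above.
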