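# Methods

This note documents the models, parameters and design choices behind
`mirtarget`, and what its synthetic corpus does and does not establish.

## Duplex alignment

Targets are scanned with windows of `|miRNA| + 10` nt at stride 1 (stride 1
cannot miss a site; overlap filtering removes the redundancy). The window
is reversed before alignment so that alignment columns correspond directly
to duplex base pairs (miRNA 5'→3' against target 3'→5'); reported
coordinates are mapped back to the forward strand, 0-based half-open.

The aligner is a three-state (Gotoh) local dynamic program with the
floor-at-zero convention. Column scores: Watson-Crick +5, G:U wobble +1,
mismatch −3. Gap runs are affine: the first column of a run scores −8,
each further column −2; switching the gapped strand opens a new run. Ties
in the traceback prefer a paired column over a gap in the target over a
gap in the miRNA, and a zero-score prefix is trimmed, so output is
deterministic. The suite checks the score against exhaustive enumeration
of all gapped local alignments for short pairs.

Alignments with fewer than 4 base-paired columns are discarded before
classification (mirroring the >4-mer seed-match floor used for the decoy
corpus). Among overlapping candidates the highest score survives; ties
break by leftmost start, then class priority (seed-only > dominant >
canonical).

## Site classes

The seed is miRNA positions 2-8 from the 5' end by default (2-9 via
configuration). Counts are attributed per column by the miRNA coordinate
it consumes; a gap-in-miRNA column inherits the last consumed position.
The class cascade (seed-only → dominant → canonical) is strict: the
numeric bounds overlap and the first satisfied rule wins. Thresholds are
read as bounds, not exact counts (a perfect seed also satisfies the
dominant bounds but is labelled seed-only). A gap column inside the seed
disqualifies seed-only and counts against the mismatch budget of the other
two classes — gaps are at least as disruptive as mismatches. An alignment
that does not cover every seed position is unclassifiable and dropped.

## Features

Sixteen features per classified site, in fixed order: seed and out-seed
complementarity scores (WC 5, G:U 2, other columns −3, summed per region);
WC/wobble/mismatch counts; largest-bulge length and bulge count (a bulge is
a maximal run of gap columns on one strand); site G+C fraction; folding
free energy of the site subsequence; duplex hybridization energy;
normalized free energy `(−ΔG)/ln(|site|·|miRNA|)` (natural log — the base
is a pure rescaling absorbed by input normalization); hybridization-energy
gap to the perfect (reverse-complement) target; position-weighted pair
score (WC 5, G:U 1, mismatch −3, gap column −1; seed columns weighted 2,
others 1); substitution-matrix score (WC 5, wobble 2, insert/delete −1,
symmetric mismatch such as A:A −3, other mismatch −2); and the deviations
of the matrix and positional scores from the same miRNA's perfect target.
Deviations are signed (perfect − observed), non-negative for gap-free
duplexes. The nucleotide-proportion feature is collapsed to the single
G+C fraction so that it occupies one network input; "insert" means a gap
in the miRNA row and "delete" a gap in the target row.

## Energy backends

The default **fallback** backend is a deliberately simple, self-contained
per-pair model: G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol. Folding maximises
total pair energy over non-crossing pairs with a minimum hairpin loop of
3 nt (Nussinov-style cubic DP, verified against full enumeration of
pairings at small length); duplex energy sums pair energies over the fixed
alignment. It is not a nearest-neighbor model: absolute values are on the
model's own scale, which is why the −17 kcal/mol site cutoff is only
enforced under the **external** backend (an RNAfold/RNAcofold subprocess
adapter that parses the trailing "structure (energy)" line). The external
backend never falls back silently; a missing executable raises. Folding is
applied to the site subsequence, not the whole transcript: a full-3'UTR
fold would swamp the per-site signal.

## Verifier networks

One 16-9-1 multilayer perceptron per target class. Both layers use tanh
(bipolar sigmoid) so outputs live in (−1, 1), matching the ±1 training
targets and the 0.98 decision threshold; a logistic-output variant with
0/1 recoded targets is available. Inputs are min-max normalized to [0, 1]
with statistics taken from the training split only (clamped at inference).

Training is online backpropagation on squared error with learning rate 0.2
and momentum 0.8, at most 500 epochs, examples visited in a freshly
shuffled order per epoch, weights initialised uniformly in [−0.5, 0.5]
from the seeded generator. 70% of the examples train the network; the
remaining 30% drive early stopping (patience 25 epochs, best-validation
weights returned). At this learning rate plain backprop saturates the
output unit within the first epoch and never recovers (the tanh derivative
vanishes); training therefore adds Fahlman's flat-spot constant (0.1) to
the activation derivative. This is an optimizer modification only — the
exact analytic gradient is kept separately and verified against central
finite differences to 1e-5 relative error.

Models serialize to a versioned JSON file carrying dimensions, weights,
normalization statistics, threshold, seed and a config hash. Evaluation
reports sensitivity, specificity and accuracy at the threshold plus a
threshold-swept ROC with trapezoid-rule area.

## Synthetic corpus

The generator replaces a curated corpus of experimentally supported sites
with seeded, label-sound constructions at the same scale: 150 positives
(52 seed-only / 58 dominant / 40 canonical) and 200 negatives (70/74/56
per class partition), a fresh test split of the same shape, and a scan
fixture of 60 UTRs (80-120 nt, uniform base composition) carrying 90
implanted sites from a pool of 25 miRNAs (18-24 nt), with some miRNAs
targeting several UTRs and some UTRs hosting sites of two miRNAs.

Positives invert the class rules: a seed composition (WC/G:U/mismatch
counts over the 7 seed positions) is sampled from the class's admissible
set and realised as a gap-free duplex; the 3' region carries the sampled
number of matches with at most one interleaved mismatch. The duplex covers
only the 5' prefix of the miRNA that its matches support — beyond the last
3' match a real site pairs by chance alone, and a local alignment would
trim such a tail anyway. Columns are arranged so every proper prefix and
suffix of the duplex scores positive under the alignment scheme, which
makes the intended register the alignment's optimum. Two canonical-rule
compositions admitted by the rules ((3,0,4) and (4,0,3)) are excluded from
the defaults: with only three paired seed positions the intended duplex
scores so low that the aligner prefers a shifted gapped arrangement of the
same site, and the implanted register is unrecoverable.

Negatives are seed-matched decoys, not random sequence (random negatives
are trivially rejected and teach the verifier nothing). Two families, half
and half: *short-tail* decoys with a >4-mer consecutive WC block in the
seed and almost no 3' pairing, and *large* decoys whose >4-mer seed run
leans on wobbles (WC ≤ 2 or G:U ≥ 4, so every class rule fails inside the
seed) attached to long, bulged, mismatch-bearing 3' regions. The large
family exists so the verifier sees what chance high-scoring alignments
look like; without it, bulge and mismatch features are constant across
training and the networks accept most spurious scan candidates.

Scan-fixture contexts are re-drawn until each implanted site is recovered
at the candidate stage exactly as constructed (same span and class, no gap
columns). Random flanks can otherwise let the aligner absorb neighbouring
bases into a higher-scoring gapped variant whose features match no
constructed duplex.

**What this corpus does not show.** It contains no conservation signal, no
expression data, no realistic 3'UTR composition (real UTRs are AU-rich and
repeat-laden), and its positives are cleaner than experimentally supported
duplexes. Passing the end-to-end benchmark demonstrates that the pipeline
is internally consistent — sites constructed by the class definitions are
found, classified, and separated from seed-matched decoys and from chance
alignments under these conditions — not that the trained networks transfer
to biological data.

## Problem sizes and runtime

Default study sizes: 350 training examples, 350 fresh test examples, 60
UTRs / 90 sites / ~90 scanned pairs. A full benchmark run (corpus,
training, held-out evaluation, scan, oracle cross-checks) takes about one
minute on one CPU. Oracle checks use 200 random alignment pairs of length
≤ 7 and 100 random fold sequences of length ≤ 12 — the largest sizes at
which exhaustive enumeration stays cheap.

## Known limitations

* The fallback energy model ranks duplex stability correctly but is not on
  a physical kcal/mol scale; absolute energies and the −17 cutoff are only
  meaningful with the external backend.
* Windows plus stride-1 scanning cannot represent one site pairing a miRNA
  twice (no multi-loop duplexes), and only the + strand is scanned.
* The rule cascade admits chance candidates in long random sequence at a
  rate that grows with target length; precision on real transcriptomes
  would require the conservation filtering this package does not implement.
* Verifier scores saturate near ±1 on separable data, so the 0.98
  threshold behaves nearly like a sign test there; on harder corpora the
  threshold and the per-class score distributions should be re-examined.
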