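# mirtarget

Prediction of animal microRNA target sites in mRNA / 3'UTR sequences, with
per-class neural-network verification.

Animal miRNAs repress transcripts by imperfect base-pairing, mostly within
3'UTRs; functional sites fall into three classes by where the pairing
strength lies — **5' seed-only** (perfect pairing across miRNA positions
2-8, little 3' pairing), **5' dominant** (strong seed plus some 3' pairing)
and **3' canonical** (weak seed compensated by extensive pairing to the
miRNA 3' end). Most seed-match tools only catch the first two;
`mirtarget` detects all three in one framework.

## Method

For each (miRNA, target) pair:

1. **Scan** — windows of length `|miRNA| + 10` slide over the target at
   stride 1. Each window is aligned to the miRNA with a local
   Smith-Waterman variant (Gotoh three-state, floor at zero) under a duplex
   scoring scheme: Watson-Crick pair +5, G:U wobble +1, mismatch −3, gap
   open −8, gap extend −2 — mismatches are preferred to gaps.
2. **Classify** — alignment columns are split by miRNA coordinate into seed
   (positions 2-8 from the 5' end; 2-9 configurable) and non-seed regions,
   and a strict rule cascade assigns a class:

   | class | seed WC | seed mismatch | seed G:U | non-seed matches |
   |---|---|---|---|---|
   | 5' seed-only | ≥ 6 | 0 | 0 | ≥ 4 |
   | 5' dominant | ≥ 5 | ≤ 1 | ≤ 2 | ≥ 5 |
   | 3' canonical | ≥ 3 | ≤ 4 | ≤ 3 | ≥ 7 |

   Candidates matching no rule are dropped; overlapping candidates are
   reduced to the best-scoring disjoint set.
3. **Featurize** — each surviving site gets a 16-dimensional vector:
   structural (seed/out-seed complementarity scores, WC/wobble/mismatch
   counts, bulge length and count, site G+C fraction), thermodynamic (site
   folding free energy, duplex hybridization energy, normalized free energy
   `NFE = −ΔG / ln(|site|·|miRNA|)`, hybridization-energy gap to the
   perfect duplex) and positional (position-weighted pair score,
   substitution-matrix score, and their deviations from the perfect
   target). Energies come from a pluggable backend: a self-contained
   per-pair fallback model, or RNAfold/RNAcofold via a subprocess adapter.
4. **Verify** — a 16-9-1 multilayer perceptron per class (tanh units, ±1
   targets, trained from scratch by online backpropagation with momentum
   0.8 and learning rate 0.2, early-stopped on a 30% held-out split) scores
   the vector; sites with output ≥ 0.98 are reported as targets. With the
   external energy backend an MFE cutoff (default −17 kcal/mol) is applied
   as well.

Because the curated corpora behind the original training data are not
redistributable, the package ships a seeded synthetic-data generator that
emulates them: class-structured positive duplexes (150 across the three
classes) and seed-matched decoy negatives (200), plus a scan fixture of 60
UTRs with 90 implanted sites and known ground truth. See
`docs/methods.md` for the model details and the generator's scope.

## Worked example

```sh
mirtarget simulate --seed 4 --out corpus
mirtarget train --features corpus/train_seed_only.tsv --target-class seed_only --seed 9 --out models/seed_only.json
mirtarget train --features corpus/train_dominant.tsv  --target-class dominant  --seed 9 --out models/dominant.json
mirtarget train --features corpus/train_canonical.tsv --target-class canonical --seed 9 --out models/canonical.json
mirtarget scan --mirna corpus/mirnas.fasta --targets corpus/targets.fasta \
    --models models --pairs corpus/pairs.tsv --out predictions
```

which prints

```
196 classified sites, 103 verified; wrote predictions.tsv, predictions.gff3, predictions.txt
```

196 window alignments passed the class rules; the per-class networks
accepted 103 of them as targets. `predictions.tsv` holds one row per site
with its span (0-based half-open), class, alignment score S, the 16
features, the network score and the verdict; `predictions.txt` renders each
duplex:

```
## scan-mir-0 -> scan-utr-18 [31,45) Class 1: 5' Seed-only S=62 ann=0.9998 verdict=yes
miRNA  5' GCCGCAGCCAAAUA 3'
          ||||||||| ||||
target 3' CGGCGUCGGGUUAU 5'
```

Here the site pairs every seed position of `scan-mir-0` by Watson-Crick
pairs (`|`; `:` marks G:U), scores S = 62 under the alignment scheme, and
the seed-only network accepts it at 0.9998 ≥ 0.98. The following record in
the same file (a chance canonical-rule candidate, `ann=-1.0`) is reported
with `verdict=no`. `predictions.gff3` carries the same sites as
`miRNA_target_site` features with 1-based inclusive coordinates.

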