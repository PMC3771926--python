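# Methods

## Model and assumptions

`conregid` treats a protein collection as a mixture of families, each
defined by one highly conserved sequence region (a domain or family
region), with individual sequences carrying zero, one, or several such
regions embedded in non-conserved context. The method assumes that

* region co-membership is detectable by local alignment significance
  between full sequences (loosely thresholded, so only very weak pairs are
  discarded);
* a shared region manifests as a *fully interconnected* subset of the
  similarity graph, so maximal cliques isolate regions even when
  multi-domain sequences connect otherwise unrelated families (the
  domain-chaining effect);
* within a clique's multiple alignment the shared region appears as a
  contiguous run of high-conservation columns;
* remote family members that fail pairwise significance are still
  recoverable by profile (PSSM) search against the region model.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `evalue_connectivity` | 0.01 | max e-value for a similarity-graph edge (inclusive) |
| `max_group` | 100 | components larger than this are randomly split before clique finding |
| `hamming_threshold` | 0.3 | fractional Hamming distance below which cliques count as redundant |
| `frame` | 50 | median-filter frame; the window holds `frame+1` = 51 values |
| `conservation_threshold` | 0.2 | per-column conservation score a conserved position must exceed (strict) |
| `min_region_length` | 20 | minimum alignment-column span of a region |
| `search_evalue` | 1e-5 | max e-value for a PSSM hit |
| `merge_evalue` | 0.01 | consensus–consensus alignment significance required to consider merging (strict) |
| `overlap_fraction` | 0.9 | aligned-span coverage of the shorter consensus required to merge |
| `align_matrix`, `gap_open`, `gap_extend` | BLOSUM50, 10, 2 | pairwise search scoring; a gap of length k costs `open + k·extend` |
| `score_matrix` | BLOSUM62 | matrix behind MSA scoring and conservation scores |
| `min_seq_length`, `max_seq_length` | 100, 10000 | outlier length filter on input sequences |
| `seed` | 0 | root of all randomness (decoy shuffling, group splitting) |

All file coordinates are 1-based inclusive; internal coordinates are
0-based half-open.

## E-value statistics

Local alignment scores of unrelated sequences follow an extreme-value law,
`E = K·m·N·e^(−λS)`. Rather than trusting published constants for every
scoring combination, λ and K are fitted by maximum likelihood (Gumbel) on
scores of decoy pairs drawn i.i.d. from the input's residue composition
(default 100 pairs of 200-mers); published gapped constants for
BLOSUM50/10/2 and BLOSUM62 ship as fallbacks. The same procedure calibrates
each PSSM before searching, using residue-shuffled input sequences as
decoys (default 60). Absolute agreement with any particular search tool's
e-values is not a goal; the pipeline only needs correct ranking and stable
thresholding, and the calibration test requires the fitted parameters to
recover a generating Gumbel within 10%.

## Conservation scoring

Row weights are proportional to each row's mean pairwise distance
(1 − fractional identity over mutually non-gap columns), so redundant rows
are down-weighted. The column score is the weighted sum of pairs

```
score(x) = Σ_{i<j} w_i w_j Mut(x_i, x_j) / Σ_{i<j} w_i w_j
```

with `Mut` the substitution matrix scaled Karlin-style,
`M(a,b)/sqrt(M(a,a)·M(b,b))`, clamped to [0, 1]. Identical pairs score
exactly 1 regardless of residue, dissimilar pairs score 0, and a random
ungapped column averages ≈ 0.1 — safely below the 0.2 threshold, which is
what lets the threshold separate conserved from background columns. Pairs
involving gaps or unknown residues contribute 0; an all-gap column scores
0. A plain min–max rescaling of the raw matrix was rejected because it
leaves identical-pair scores residue-dependent (0.53–1.0 for BLOSUM62) and
puts random columns at ≈ 0.23–0.29, above the threshold, which inflated
region boundaries ~30 residues into flanking sequence in planted-domain
experiments (residue precision 0.47 vs 0.997 with the clamped form).

## Median smoothing

The window at position p holds the value at p plus 25 neighbours per side
(51 values at the default frame of 50); out-of-range positions contribute
zeros; the output is the upper median (26th order statistic). Consequences,
verified by enumeration: an isolated perfectly conserved run survives
smoothing iff it spans ≥ 26 positions, and for surviving ideal runs the
recovered boundaries are exact (within ±3 columns once scores are noisy).
The filter is idempotent on constant tracks and monotone in the input.

## Multiple alignment

Cliques are aligned progressively: UPGMA guide tree over normalized edit
distances (an identity proxy), then profile–profile merges scored by
expected sum-of-pairs (`f₁ᵀ M f₂` per column pair) under affine gaps with
free terminal gaps. Free end gaps are deliberate: members share a region
but not their flank lengths, and penalized ends drag flanks into the
conserved block. Any external aligner can be substituted by supplying
aligned FASTA/Clustal files through `read_alignment`. The aligner makes no
refinement passes; determinism (fixed input order → byte-identical output)
is guaranteed.

## Region profiles, search and merging

Profiles store per-column counts over 20 residues + X + gap. Consensus
columns are those with < 50% gaps; consensus residues are the most frequent
standard residue (ties alphabetical). PSSM scores are
`log2((count + pc·bg) / ((N + pc)·bg))` with pseudocount weight 1 and
background = input composition. Search is one pass of local DP of the PSSM
against each sequence, best hit per (region, sequence), no profile
re-estimation.

Merging aligns consensus pairs all-against-all; significantly aligned pairs
(e < 0.01) merge when the aligned span covers the shorter consensus
entirely or > 90% of it. Pairs are processed in ascending e-value order and
the procedure repeats to a fixpoint, so the outcome is deterministic and
idempotent. The merged profile sums counts over aligned columns on the
longer profile's coordinate system; the longer profile's unaligned flanks
are carried through, the shorter's are dropped (dropping the longer's would
discard counts). Associations (hits) of merged regions are unions of the
originals, deduplicated per sequence by best e-value.

## Final clustering and evaluation

Two sequences cluster together iff they share at least one region
(connected components of the bipartite projection of the association
table). Evaluation against reference annotations therefore derives the
reference partition the same way: sequences sharing a reference label are
linked, and the partition is the connected components — multi-domain
sequences legitimately fuse the reference groups they bridge, exactly as
they fuse predicted clusters. Region↔label pairing for hit metrics is by
largest total residue overlap; hit precision only counts sequences with at
least one reference hit; residue metrics aggregate per-position TP/FN/FP
over all sequences.

## Synthetic data

The generator plants families of mutated domain copies (default: domain
length 60–120, point-substitution rate 0.08, indel rate 0.01 with 1–3
residue indels) in i.i.d. background flanks of 30–150 residues; a fraction
of sequences (default 10%) carries 2–3 domains from distinct families (the
chaining stressor), and a fraction per family (default 15%) mutates at
0.3 — remote homologs meant to strain pairwise significance while
remaining recoverable by profile search. All sequences respect the
100–10000 length window and generation is deterministic per seed.

What it does *not* emulate: phylogenetic correlation between members,
low-complexity/coiled-coil/transmembrane segments, signal peptides, tandem
repeats of a domain on one sequence, or real database domains. Passing
tests on this generator demonstrate the pipeline's mechanics (chaining
safety, split-family reunification, boundary recovery, remote-member
retrieval via profiles) — not performance on real proteomes, where
non-homologous similarity sources dominate the error budget.

## Problem sizes used by the test suite

The planted-recovery test runs the default generator conditions
(6 families × 30 members, 10% multi-domain, 15% remote; 180 sequences,
~52k residues, ~18 s end to end); the reunification test uses one
250-member family with a 100-residue domain so that group splitting at 100
is exercised (~26 s); oracle-equivalence tests use exhaustive enumeration
at n ≤ 10 vertices and brute-force window sorting on random tracks.

## Known limitations

* Clique enumeration is exponential in the worst case; the group-size cap
  bounds it, but a group whose similarity graph is dense-but-incomplete in
  an adversarial pattern can still produce very many maximal cliques.
* One best hit per (region, sequence): tandem repeats of a region on one
  sequence are counted once.
* E-values are calibrated, not tool-compatible; thresholds tuned for other
  search engines' e-values may need adjustment.
* Conservation scoring approximates the published sum-of-pairs family of
  scores; its exact gap-weighting internals are not reproduced (gap pairs
  simply score 0).
* Region boundaries inherit the smoothing floor: regions must survive a
  51-value median window, so true regions shorter than ~26 alignment
  columns are invisible by construction.
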