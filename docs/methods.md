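# Methods

## Scope and model

`lanthimine` identifies candidate lanthipeptide precursor ORFs near cyclase
gene clusters in bacterial genomes, classifies the synthetase combination
serving each cluster, predicts and encodes each peptide's thioether/labionin
bridging topology, and computes homology-calibration and leader/core
compositional statistics. It consumes externally produced profile-HMM domain
hits (HMMER3 `domtblout`); it does not build HMMs, run gene prediction with
coding-potential models, or do any phylogenetics.

## ORF calling (`seqio`)

A six-frame start-to-stop scan over linear genomes. Start codons default to
the bacterial set {ATG, GTG, TTG} (translation table 11); the initiator is
always translated as Met. Coordinates are 1-based inclusive on the forward
strand, the stop codon included in the span but not the peptide. For ORFs
sharing a stop codon only the longest is reported by default (`all_starts`
emits every start), mirroring standard ORF-caller behaviour. Codons
containing N are non-translatable and split ORFs; wrap-around ORFs on
circular genomes are out of scope. This scanner intentionally differs from
coding-potential gene finders, so ORF sets will not exactly match pipelines
built on such tools.

`domtblout` parsing keeps rows with independent (per-domain) E-value
≤ 0.01 (configurable) whose HMM name appears in the domain configuration, and
projects residue coordinates onto the genome through per-protein `loc=`
location tokens in the searched-protein FASTA.

## Mining rules (`mining`)

A precursor candidate is an ORF with peptide length L ≤ 100, ≥ 1 Cys,
#Ser + #Thr ≥ #Cys, and last Cys position strictly greater than ⌊2L/3⌋. The
"last third" boundary convention is strict so that L = 3 requires the Cys at
position 3.

Clusters are single-linkage chains of domain hits and candidates sorted by
genomic start; the chain breaks when the gap between closest interval edges
(overlap = 0) exceeds 10 kb — a gap of exactly 10 kb keeps the chain. Chains
without a cyclase hit are discarded. Distances use closest edges rather than
midpoints as the most direct reading of "distance between adjacent domains".

The 15-domain list ships as an editable mapping of HMM names to roles
(1 cyclase, 7 dehydratase-associated, 2 peptidase, 1 transporter,
4 two-component). The dehydratase class is defined by the class-defining
domain present (LanB-family → B, DUF4135 → D, lyase → L); the kinase that
always accompanies the lyase is configured as an accessory and does not set
the class by itself. The cyclase triad call is a motif heuristic, not an
alignment to reference triad columns: the last CHG (→ CCH) or CCG (→ CCC)
within the final 150 residues of the domain match, requiring an additional
upstream Cys; no match → Unk. The heuristic is fallible by design and Unk is
the fallback. Clusters mixing dehydratase classes resolve per precursor via
the nearest class-defining dehydratase; triads come from the nearest cyclase.
Nearest = minimal edge-to-edge gap, ties to the upstream (smaller start)
feature.

## Bridging predictor (`topology`)

Cysteines are processed from the C terminus toward the N terminus. At each
Cys *j*:

1. **Labionin:** if two free serines sit at i₂ and i₁ = i₂ − 3 with
   3 ≤ j − i₂ ≤ 6 and no Cys strictly inside (i₁, j) — the motif
   `S[^C]{2}S[^C]{2,5}C` — bind the unit, taking the match with maximal i₂
   (nearest serines), mirroring the nearest-partner logic of the Lan rule.
2. **Lan/MeLan:** otherwise bind the nearest free Ser/Thr at gap ≥ 3
   ("more than two residues away").
3. Otherwise the Cys is free.

`labionin_mode` defaults to `all_cys` (the geometry is tested at every Cys);
`first_cys_only` restricts it to the C-terminal-most Cys for the literal
reading of the rule, and `off` disables it. Labionin serines must be Ser by
default (labionin derives from a Cys and two dehydrated serines); variant
motifs such as the labionin-like `TxxSx{1,2}C` are expressed through the
configurable `LabioninPattern` geometry. Predictions run on the core peptide
when a leader split is known and requested (`on_core`), else on the whole
precursor.

Because every Cys takes the *nearest* available upstream partner, predicted
bridges may cross (arcs a<c<b<d) but can never nest (a<c<d<b); this is
verified exhaustively over all peptides on {A,S,T,C} up to length 10 and on
10⁴ random longer peptides. Disulphides, D-stereochemistry and dehydration of
unbridged Ser/Thr are not modelled.

**Codes.** `encode_topology` emits, N→C, `L` per labionin Ser, `S` per
bridged Ser/Thr, `C` per Cys; unbridged Ser/Thr are omitted (forced by the
seven-bridge geobacillin I code having exactly seven S letters).
`decode_topology` rebuilds an abstract bridge set on code indices: scanning C
letters right-to-left, a C consumes the two nearest unconsumed L letters if
any remain, else the nearest unconsumed S, else is free; residue spacing is
lost in codes so no minimum-gap rule applies. For crossing counts a labionin
unit (i₁, i₂, j) contributes the single arc (i₁, j), which makes
"no crossings involve labionin" checkable as stated.

**Round-trip scope.** decode(encode(predict(p))) reproduces the arc pattern
exactly (rank-isomorphic positions, identical crossing counts) whenever the
prediction contains no labionin unit — verified on tens of thousands of
random peptides — and for peptides generated from realizable codes. It does
*not* hold in general when cysteines follow a labionin unit: decode gives L
letters to the rightmost C while the predictor's window geometry binds them
to a nearby one. Decoded arbitrary codes are therefore abstract summaries,
not guaranteed predictor outputs (they may even nest, e.g. `LLSCC`).

`count_crossings` uses a Fenwick-tree straddle count; tests compare it
against a brute-force O(n²) pair scan. `bridge_space_size(n, k)` is the exact
falling factorial n!/(n−k)!, checked against explicit enumeration for n ≤ 7.
Novel-topology tallies flag codes absent from a user-supplied known-code list
and report which reach the support threshold (default 2 occurrences, to
reduce false positives).

## Homology calibration (`homology`)

Global (end-to-end) affine-gap alignment via Biopython's PairwiseAligner;
defaults BLOSUM62, gap open 10, gap extend 1 (a k-residue gap costs
open + k·extend), set in configuration rather than hard-coded. The traceback
tie order is the aligner's deterministic enumeration order; scores are
tie-independent and are validated against an independent quadratic-time Gotoh
implementation (exhaustively for all pairs up to length 3 over a four-letter
alphabet, plus 2 000 sampled pairs of lengths 4–6 — sizes chosen to keep the
pure-Python oracle fast).

Significance is empirical rather than an E-value model: each database entry
is shuffled *within* its leader and within its core segment (composition
preserved per segment, since composition bias is what inflates chance
matches; midpoint fallback when no boundary is annotated, taken from
`boundary=` keys in the database FASTA or from `split_leader_core`). Each
query's best score against the shuffled database forms its null maximum; the
threshold is the (1 − target) quantile of those maxima (conservative
`higher` interpolation) and the empirical false-match rate is reported. The
default target is 0.001 — one query in a thousand matching a randomized
sequence. All randomness flows through an explicit seeded generator.

Redundancy reduction is greedy longest-first clustering at 50% identity
(identical aligned positions / shorter length), CD-HIT style. Subfamilies are
connected components of the significant-similarity graph, largest first.

## Peptide statistics (`peptidestats`)

*Leader/core:* cleavage after the double-glycine-type `G[GA]` motif;
occurrences are enumerated non-overlapping left-to-right and the rightmost
occurrence leaving every Cys in the core wins (no compatible occurrence →
no split). *Positional correlation:* every residue of every peptide pools as
a point (fractional position, indicator or property value); Pearson r with
zero-variance cases flagged undefined. Pooling across peptides (rather than
averaging per-peptide correlations) is the implemented reading. *Charge:*
(#K + #R) − (#D + #E), His contributing 0 by default (a flag adds +0.1/His).
*Hydrophobicity:* mean Kyte–Doolittle. *Motif expectation:* per-peptide
Bernoulli-site model, Σᵢ [1 − (1 − Πₖ fᵢ(motifₖ))^(Lᵢ−k+1)] with fᵢ the
peptide's own residue frequencies. The model ignores site dependence and
composition depletion, giving a systematic few-percent bias for short or
motif-dense peptides; the Monte-Carlo cross-check in the tests therefore
allows a 10% relative model tolerance on top of sampling error.
*Dihistidine:* a peptide counts when an HH dimer starts strictly past
⌊L/2⌋. *G+C deviation:* GC fraction of gene vs background with N excluded
from numerator and denominator.

## Synthetic data (`synthdata`)

The generator emulates the study conditions: genomes carrying clusters
(cyclase + dehydratase + peptidase + transporter stubs, intra-cluster gaps
200–1500 bp) separated by 15 kb, two planted precursors per cluster whose
peptides realize configured topology codes, and decoy ORFs (six by default,
length-matched to the planted precursors, satisfying all composition rules)
placed > 10 kb from any cluster; `generate_negative_orfs` additionally makes
two length-matched rule-satisfying negatives per supplied candidate. Defaults: five clusters
covering the five literature synthetase types (B-CCH, D-CCH, D-CCC, L-CCH,
L-Unk), codes {SCSC, SSCC, LLC, SC, C} spanning uncrossed, crossed, labionin,
single-ring and single-free-Cys classes, 48-aa precursors, genome G+C 0.5
(hit within ±5% by G+C-weighted synonymous codon choice).

Peptides realizing a code lay special residues left-to-right — Thr for `S`
letters, Ser for `L`, Cys for `C` — with spacings that satisfy the predictor's
windows, front-padded with filler residues (never Ser/Thr/Cys, and no Gly so
no accidental `G[GA]` cleavage site) so cysteines stay in the C-terminal
third; trailing never-bridged serines top up composition when a code has more
C than S/L letters. Every generated peptide is verified by running the
predictor; unrealizable codes raise.

Domain detection is simulated by emitting `domtblout` rows for the stub
genes, exercising the real parsing/projection code path without HMMER.
Cyclase stubs carry a planted CHG/CCG triad motif; other stubs contain no Cys
so no spurious triad can arise.

So that recovery is exact *by construction*, the genome avoids chance
precursor candidates: intergenic DNA and stub/precursor codons are chosen to
exclude the Cys-codon trigrams (TGT/TGC and their reverse complements
ACA/GCA) everywhere except planted cysteine sites, so a chance ORF almost
never passes the ≥ 1 Cys filter; planted precursor genes are guarded by an
upstream in-frame stop so the scanner reports exactly the planted span; and a
bounded seeded cleanup pass disrupts any residual chance candidate near a
cluster (synonymous substitutions only, inside planted genes). What the
synthetic genomes do **not** emulate: realistic intergenic composition,
HMM score distributions, overlapping genes, split clusters across contigs —
so passing recovery tests demonstrates correctness of the pipeline logic,
not performance on real genomes.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run in minutes on one CPU:
exhaustive nesting checks cover all {A,S,T,C} peptides to length 10 (tests)
or 8 (script) plus 10⁴ random peptides to length 80; null calibration uses
1 000 query peptides × 5 database entries × 2 shuffles (10⁴ null scores) at
target rate 0.001; parameter recovery uses one five-cluster genome
(~115 kb). All stochastic steps take an explicit `numpy` Generator; the CLI
and the acceptance script derive every random stream from a single integer
seed, and fixed seeds give byte-identical synthetic outputs.

## Known limitations

- The cyclase triad motif heuristic can miscall divergent cyclases (Unk is
  the fallback), and parity with gene-caller-based ORF sets is not attempted.
- Decoded topology codes lose residue spacing; bridge/crossing counts for
  codes are exact for the abstract arc model but need the real sequence for
  geometric claims.
- The labionin rule's minimum-gap interaction with the inner serine spacing
  follows the printed motif geometry; alternative conventions are expressible
  only through `LabioninPattern`.
- The shuffled-null calibration controls the false-match rate on
  composition-matched nulls; it says nothing about sensitivity to remote
  homologs.
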