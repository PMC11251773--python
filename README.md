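# lanthimine

Genome mining for **lanthipeptides** — ribosomally synthesized peptides
cyclized by thioether (lanthionine/methyllanthionine) and labionin bridges —
with a rule-based predictor of each peptide's **bridging topology**.

The package is for microbiologists and natural-product bioinformaticians who
want to survey bacterial genomes for candidate lanthipeptide precursors beyond
what sequence similarity to known lantibiotics can reach, and to summarise the
likely ring architecture of each candidate.

## What it does

**Mining.** Candidate precursors are short ORFs (≤ 100 aa) satisfying
composition rules — at least one Cys, #Ser + #Thr ≥ #Cys, and the last Cys in
the C-terminal third of the peptide — that lie inside a gene cluster:
a single-linkage chain of ORFs matching 15 lanthipeptide-associated protein
domains (supplied as HMMER3 `domtblout` hits) in which adjacent members are
≤ 10 kb apart and at least one member matches the LanC-like **cyclase**
domain. Each precursor is assigned a synthetase combination
`dehydratase × cyclase triad`:

| | B (LanB) | D (DUF4135) | L (lyase + kinase) |
|---|---|---|---|
| **CCH** | B-CCH (Type I) | D-CCH (Type II) | L-CCH (Type IV) |
| **CCC** | B-CCC | D-CCC (Type IIa) | L-CCC |
| **Unk** | B-Unk | D-Unk | L-Unk (Type III) |

The cyclase triad is called from the CHG (→ CCH) vs CCG (→ CCC) motif near the
domain's C terminus; clusters mixing dehydratase classes resolve each
precursor to its chromosomally nearest dehydratase.

**Topology prediction.** Walking the cysteines from the C terminus: if a Cys
completes a labionin motif `S[^C]{2}S[^C]{2,5}C`, the three residues form a
labionin unit; otherwise the Cys bridges the nearest free Ser/Thr more than
two residues upstream; failing both it stays free. The structure is encoded
over `{S, C, L}` in N→C order (`S` bridged Ser/Thr, `C` Cys, `L` labionin Ser;
unbridged Ser/Thr omitted), e.g. `SCSC` for two tandem uncrossed rings and
`SSCC` for two overlapping ones. The greedy nearest-partner rule can produce
crossed bridges but provably never nested ones. Codes can also be decoded
back to abstract bridge sets, crossings counted, and novel codes tallied
against a known-code list. With *n* Ser/Thr and *k* Cys there are
*n!/(n−k)!* conceivable pairings (over 250 million for n=15, k=8); the
predictor picks the single one consistent with known lanthipeptide chemistry.

**Statistics.** Leader/core splitting at the double-glycine `G[GA]` cleavage
motif (all Cys must stay in the core), net charge and Kyte–Doolittle
hydrophobicity, pooled positional composition correlations, fixed-motif
expectation counts, second-half HH dihistidine enrichment, G+C deviation, and
a shuffled-null homology calibration: global alignment scores against
leader/core-segment-shuffled copies of known lanthipeptides set an empirical
score threshold at a chosen false-match rate (default 1 in 1000).

**Synthetic data.** `lanthimine synth` generates genomes with planted
clusters, precursors realizing requested topology codes, and length-matched
decoy ORFs outside clusters, plus the matching `domtblout` and truth tables —
so the entire pipeline is testable offline.

## Worked example

```python
from lanthimine import ProteinSequence, split_leader_core
from lanthimine import predict_bridges, encode_topology, count_bridges, count_crossings

pep = ProteinSequence(
    id="nisin_like",
    residues="MKTEKLQNLDVVEAGGASTVSLLSCTPGCKTGALMTCAIKTATCGCHFG",
)
split = split_leader_core(pep)
bridges = predict_bridges(split.core)
print(split.leader.residues)            # MKTEKLQNLDVVEAGG
print(split.core.residues)              # ASTVSLLSCTPGCKTGALMTCAIKTATCGCHFG
print(str(encode_topology(bridges, split.core)))  # LLCSCSCSSCC
print(count_bridges(bridges), count_crossings(bridges))  # 5 1
```

The leader is cleaved after the `GG` motif; the core's first Cys closes a
labionin unit on Ser2/Ser5, the remaining cysteines form four
(methyl)lanthionine rings of which one pair overlaps — summarised by the code
`LLCSCSCSSCC` with 5 bridges and 1 crossing.

From the shell, against a synthetic genome:

```bash
lanthimine synth --seed 42 --out demo
lanthimine mine --genome demo/genome.fasta --domtbl demo/hits.domtblout \
                --proteins demo/proteins.fasta --out demo/mine
lanthimine topology --peptides demo/precursors.fasta --out demo/topologies.tsv
lanthimine stats --peptides demo/precursors.fasta --out demo/stats
```

`demo/mine/summary.json` reports cluster and precursor counts per synthetase
label; `demo/topologies.tsv` lists per-peptide codes, bridge/crossing counts
and novelty flags.

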