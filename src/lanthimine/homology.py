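"""Global-alignment similarity with a composition-preserving shuffled null.

Homology of candidate precursors to known lanthipeptides is scored by global
(end-to-end, affine-gap) alignment. Significance is calibrated empirically:
each database entry is internally randomized within its leader and core
segments separately — preserving each segment's residue composition, which is
what drives spurious matches between compositionally biased peptides — and
the score threshold is set so that only a chosen fraction (default 1 in 1000)
of queries match any shuffled entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinSequence, read_fasta

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity: float  # identical aligned positions / shorter sequence length
    length: int  # alignment columns

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0 + 1e-9:
            raise ValueError("identity outside [0, 1]")


@dataclass
class NullCalibration:
    n_shuffles: int
    null_scores: list  # per-query maxima over the shuffled database
    threshold_score: float
    empirical_fdr: float


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _residues(seq) -> str:
    return seq if isinstance(seq, str) else seq.residues


def _check_alphabet(seq: str, matrix_alphabet: str) -> None:
    bad = set(seq) - set(matrix_alphabet)
    if bad:
        raise ValueError(f"residues not in substitution matrix alphabet: {sorted(bad)}")


def global_align(
    a,
    b,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of two peptides with affine gap penalties."""
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValueError("global_align: empty sequence")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    _check_alphabet(sa, alphabet)
    _check_alphabet(sb, alphabet)
    aln = aligner.align(sa, sb)[0]
    counts = aln.counts()
    identity = counts.identities / min(len(sa), len(sb))
    return AlignmentResult(score=float(aln.score), identity=identity, length=aln.length)


def align_score(
    a,
    b,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Score-only fast path of :func:`global_align`."""
    return float(_aligner(matrix, gap_open, gap_extend).score(_residues(a), _residues(b)))


# ---------------------------------------------------------------------------
# Shuffled null
# ---------------------------------------------------------------------------

def segment_shuffle(seq, boundary: int, rng: np.random.Generator):
    """Permute a sequence within [1..boundary] and (boundary..L] independently.

    A boundary of 0 or L shuffles the whole sequence. Per-segment residue
    multisets are preserved exactly.
    """
    s = _residues(seq)
    if not 0 <= boundary <= len(s):
        raise ValueError(f"boundary {boundary} out of range for length {len(s)}")
    left = list(s[:boundary])
    right = list(s[boundary:])
    rng.shuffle(left)
    rng.shuffle(right)
    shuffled = "".join(left) + "".join(right)
    if isinstance(seq, ProteinSequence):
        return ProteinSequence(id=f"{seq.id}|shuffled", residues=shuffled)
    return shuffled


def calibrate_null(
    queries: Sequence,
    db: Sequence[tuple],
    n_shuffles: int,
    target_rate: float = 0.001,
    rng: np.random.Generator | None = None,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> NullCalibration:
    """Calibrate a score threshold from segment-shuffled database copies.

    ``db`` entries are (sequence, leader/core boundary or None); an absent
    boundary falls back to the midpoint. Each query's best score against
    ``n_shuffles`` shuffled copies of every database entry forms its null
    maximum; the threshold is the (1 - target_rate) quantile of those maxima
    and the empirical FDR is the fraction of queries at or above it.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must be in (0, 1)")
    if not db:
        raise ValueError("calibrate_null: empty database")
    if rng is None:
        raise ValueError("calibrate_null requires a seeded random generator")

    shuffled_db = []
    for entry, boundary in db:
        s = _residues(entry)
        b = boundary if boundary is not None else len(s) // 2
        for _ in range(n_shuffles):
            shuffled_db.append(segment_shuffle(s, b, rng))

    maxima = np.array(
        [
            max(align_score(q, t, matrix, gap_open, gap_extend) for t in shuffled_db)
            for q in queries
        ]
    )
    threshold = float(np.quantile(maxima, 1.0 - target_rate, method="higher"))
    empirical_fdr = float(np.mean(maxima >= threshold))
    return NullCalibration(
        n_shuffles=n_shuffles,
        null_scores=maxima.tolist(),
        threshold_score=threshold,
        empirical_fdr=empirical_fdr,
    )


def read_reference_db(path) -> list[tuple[ProteinSequence, int | None]]:
    """Load a known-lanthipeptide FASTA with optional ``boundary=<int>`` keys."""
    out = []
    for rec in read_fasta(path, "protein"):
        boundary = None
        for token in (rec.description or "").split():
            if token.startswith("boundary="):
                boundary = int(token.split("=", 1)[1])
        out.append((rec, boundary))
    return out


# ---------------------------------------------------------------------------
# Redundancy reduction and subfamilies
# ---------------------------------------------------------------------------

def reduce_redundancy(
    seqs: Sequence[ProteinSequence],
    identity_cutoff: float = 0.5,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[list[ProteinSequence], dict[str, str]]:
    """Greedy longest-first identity clustering (CD-HIT style).

    Each sequence joins the first representative it matches at >= the
    identity cutoff (identical aligned positions / shorter length), else
    founds a new cluster. Returns representatives plus an id -> representative
    id membership map covering every input exactly once.
    """
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError("identity_cutoff must be in (0, 1]")
    ordered = sorted(seqs, key=lambda s: -len(s))
    reps: list[ProteinSequence] = []
    membership: dict[str, str] = {}
    for s in ordered:
        home = None
        for rep in reps:
            res = global_align(s, rep, matrix, gap_open, gap_extend)
            if res.identity >= identity_cutoff:
                home = rep
                break
        if home is None:
            reps.append(s)
            membership[s.id] = s.id
        else:
            membership[s.id] = home.id
    return reps, membership


def build_subfamilies(
    nodes: Iterable[str],
    edges: Iterable[tuple[str, str]],
) -> list[list[str]]:
    """Connected components of the significant-similarity graph, largest first."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps
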