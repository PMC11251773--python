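"""Leader/core splitting and compositional statistics of precursor peptides.

Leader peptides of lanthipeptide precursors are typically cleaved after a
double-glycine-type G[GA] motif by a C39 peptidase; all modifiable cysteines
must lie in the core. Compositional statistics cover positional residue
preferences (fractional position vs presence/absence), net charge and
Kyte-Doolittle hydrophobicity, expected fixed-motif counts under a per-peptide
composition model, dihistidine enrichment in the second half of precursors,
and G+C deviation of a gene from its genomic background.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .seqio import GenomeSequence, ProteinSequence

_GGA = re.compile("G[GA]")


@dataclass(frozen=True)
class LeaderCoreSplit:
    leader: ProteinSequence
    core: ProteinSequence
    cleavage_motif: str
    motif_end: int  # 1-based position of the motif's second residue

    def __post_init__(self):
        if "C" in self.leader.residues:
            raise ValueError("leader contains a cysteine")


@dataclass(frozen=True)
class PositionalCorrelation:
    amino_acid: str  # single letter, or "hydrophobicity" / "charge"
    r: float
    n: int  # pooled residue count

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def _residues(seq) -> str:
    return seq if isinstance(seq, str) else seq.residues


# ---------------------------------------------------------------------------
# Leader / core
# ---------------------------------------------------------------------------

def split_leader_core(precursor) -> LeaderCoreSplit | None:
    """Split a precursor at the rightmost G[GA] motif leaving all Cys in the core.

    Motif occurrences are enumerated non-overlapping left-to-right; the
    rightmost occurrence whose downstream segment contains every cysteine
    wins, and cleavage is immediately after the motif's second residue.
    Returns None when no compatible motif exists.
    """
    seq = _residues(precursor)
    if len(seq) < 3:
        raise ValueError("precursor shorter than 3 residues")
    last_cys = seq.rfind("C")
    pid = precursor.id if isinstance(precursor, ProteinSequence) else "peptide"
    for m in reversed(list(_GGA.finditer(seq))):
        end = m.end()  # 0-based exclusive = 1-based motif_end
        if end >= len(seq):
            continue  # nothing left for a core
        if last_cys != -1 and last_cys < end:
            continue
        if "C" in seq[:end]:
            continue  # a Cys would be stranded in the leader
        return LeaderCoreSplit(
            leader=ProteinSequence(id=f"{pid}|leader", residues=seq[:end]),
            core=ProteinSequence(id=f"{pid}|core", residues=seq[end:]),
            cleavage_motif=m.group(),
            motif_end=end,
        )
    return None


# ---------------------------------------------------------------------------
# Positional composition
# ---------------------------------------------------------------------------

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


def positional_correlation(peptides: Sequence, target: str) -> PositionalCorrelation:
    """Pearson correlation of fractional residue position with a residue property.

    Every residue of every peptide is pooled as one point: x = position /
    peptide length; y = presence (1/0) of the target amino acid, or the
    residue's Kyte-Doolittle value ("hydrophobicity") or unit charge
    ("charge"). Zero variance in either variable yields r = NaN (flagged via
    ``defined``).
    """
    xs, ys = [], []
    for pep in peptides:
        seq = _residues(pep)
        L = len(seq)
        for pos, aa in enumerate(seq, 1):
            xs.append(pos / L)
            if target == "hydrophobicity":
                ys.append(KYTE_DOOLITTLE.get(aa, 0.0))
            elif target == "charge":
                ys.append(_CHARGE.get(aa, 0.0))
            else:
                ys.append(1.0 if aa == target else 0.0)
    n = len(xs)
    if n < 2:
        raise ValueError("need at least 2 pooled residues")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PositionalCorrelation(amino_acid=target, r=float("nan"), n=n)
    r = float(stats.pearsonr(x, y).statistic)
    return PositionalCorrelation(amino_acid=target, r=r, n=n)


def net_charge(seq, his_charge: float = 0.0) -> float:
    """Net charge: (#K + #R) - (#D + #E); histidine contributes ``his_charge``
    per residue (0 by default)."""
    s = _residues(seq)
    if not s:
        raise ValueError("empty sequence")
    return (
        s.count("K") + s.count("R") - s.count("D") - s.count("E") + his_charge * s.count("H")
    )


def mean_hydrophobicity(seq) -> float:
    """Mean Kyte-Doolittle hydrophobicity over the sequence."""
    s = _residues(seq)
    if not s:
        raise ValueError("empty sequence")
    vals = [KYTE_DOOLITTLE[aa] for aa in s if aa in KYTE_DOOLITTLE]
    if not vals:
        raise ValueError("no scorable residues")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Motif expectation and enrichment
# ---------------------------------------------------------------------------

def motif_expected_count(peptides: Sequence, motif: str) -> tuple[int, float]:
    """Observed and expected number of peptides containing a fixed k-mer motif.

    The expectation uses each peptide's own residue frequencies under a
    Bernoulli-site approximation: a peptide of length L with per-site motif
    probability p contributes 1 - (1 - p)^(L - k + 1).
    """
    if not motif:
        raise ValueError("empty motif")
    k = len(motif)
    observed = 0
    expected = 0.0
    for pep in peptides:
        seq = _residues(pep)
        if motif in seq:
            observed += 1
        L = len(seq)
        n_sites = L - k + 1
        if n_sites <= 0 or L == 0:
            continue
        p_site = 1.0
        for ch in motif:
            p_site *= seq.count(ch) / L
        expected += 1.0 - (1.0 - p_site) ** n_sites
    return observed, expected


def has_second_half_dihistidine(seq) -> bool:
    """True when an HH dimer starts strictly past floor(L/2)."""
    s = _residues(seq)
    half = len(s) // 2
    pos = s.find("HH")
    while pos != -1:
        if pos + 1 > half:  # 1-based position of first H
            return True
        pos = s.find("HH", pos + 1)
    return False


def dihistidine_rate_ratio(
    group_a: Sequence,
    group_b: Sequence,
) -> tuple[float, float, float]:
    """Second-half HH dihistidine rates of two peptide groups and their ratio.

    The ratio is math.inf (flagged by the caller as such) when group B's rate
    is zero but group A's is not, and NaN when both are zero.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    rate_a = sum(has_second_half_dihistidine(p) for p in group_a) / len(group_a)
    rate_b = sum(has_second_half_dihistidine(p) for p in group_b) / len(group_b)
    if rate_b == 0:
        ratio = math.nan if rate_a == 0 else math.inf
    else:
        ratio = rate_a / rate_b
    return rate_a, rate_b, ratio


# ---------------------------------------------------------------------------
# G+C deviation
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    counted = [b for b in seq if b in "ACGT"]  # N excluded entirely
    if not counted:
        raise ValueError("no unambiguous bases")
    gc = sum(b in "GC" for b in counted)
    return gc / len(counted)


def gc_deviation(gene, background) -> tuple[float, float, float]:
    """G+C fraction of a gene, of its background, and their difference.

    A large deviation of a gene's G+C content from its genomic neighbourhood
    is one indicator of horizontal transfer.
    """
    gene_s = gene if isinstance(gene, str) else gene.residues
    back_s = background if isinstance(background, str) else background.residues
    gene_gc = _gc_fraction(gene_s)
    back_gc = _gc_fraction(back_s)
    return gene_gc, back_gc, gene_gc - back_gc
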