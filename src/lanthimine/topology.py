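"""Rule-based thioether bridging prediction and the topology-code algebra.

The predictor walks a peptide's cysteines from the C terminus toward the N
terminus. At each Cys it first tries to complete a labionin unit — two free
serines spaced exactly three apart, the second 3..6 residues upstream of the
Cys, with no intervening cysteine (the motif ``S[^C]{2}S[^C]{2,5}C``) — and
otherwise forms a (methyl)lanthionine bridge to the nearest free Ser/Thr more
than two residues upstream; failing both, the Cys is left free. Because every
Cys greedily takes the nearest available upstream partner, the procedure can
produce crossed (overlapping) bridges but never nested ones.

A predicted structure is summarised as a topology code over {S, C, L}: in
N-to-C order, ``L`` for each labionin serine, ``S`` for each bridged Ser/Thr
(the letter covers both residues), ``C`` for each cysteine; unbridged Ser/Thr
are omitted. ``decode_topology`` maps a code back to an abstract bridge set
on code indices (residue spacing is lost in codes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class LabioninPattern:
    """Geometry of the labionin motif, default ``S[^C]{2}S[^C]{2,5}C``.

    ``first_residues``/``second_residues`` are the allowed identities of the
    two ring serines; ``spacer`` is the fixed offset between them; the Cys
    must sit ``cys_gap_min..cys_gap_max`` residues after the second serine.
    Variant motifs (e.g. the labionin-like TxxSx{1,2}C) are expressed by
    changing these fields.
    """

    first_residues: frozenset = frozenset("S")
    second_residues: frozenset = frozenset("S")
    spacer: int = 3
    cys_gap_min: int = 3
    cys_gap_max: int = 6


DEFAULT_LABIONIN = LabioninPattern()


@dataclass
class BridgeSet:
    """Predicted bridging structure of one peptide.

    ``lan_bridges`` are (Ser/Thr, Cys) position pairs, ``labionin_units`` are
    (Ser, Ser, Cys) triples, ``free_cys`` are unbridged Cys positions; all
    positions 1-based.
    """

    peptide_length: int
    lan_bridges: list = field(default_factory=list)
    labionin_units: list = field(default_factory=list)
    free_cys: list = field(default_factory=list)

    def arcs(self) -> list[tuple[int, int]]:
        """All bridge arcs; a labionin (i1, i2, j) contributes the single arc (i1, j)."""
        return [tuple(a) for a in self.lan_bridges] + [
            (i1, j) for (i1, _i2, j) in self.labionin_units
        ]

    def positions_used(self) -> list[int]:
        out = []
        for i, j in self.lan_bridges:
            out += [i, j]
        for i1, i2, j in self.labionin_units:
            out += [i1, i2, j]
        out += list(self.free_cys)
        return out

    def validate(self) -> None:
        pos = self.positions_used()
        if len(pos) != len(set(pos)):
            raise ValueError("a residue position appears in two units")
        for i, j in self.lan_bridges:
            if not 1 <= i < j <= self.peptide_length:
                raise ValueError(f"bad lan bridge ({i},{j})")
        for i1, i2, j in self.labionin_units:
            if not 1 <= i1 < i2 < j <= self.peptide_length:
                raise ValueError(f"bad labionin unit ({i1},{i2},{j})")


@dataclass(frozen=True)
class TopologyCode:
    """String summary of a bridging structure over the alphabet {S, C, L}."""

    code: str

    def __post_init__(self):
        bad = set(self.code) - set("SCL")
        if bad:
            raise ValueError(f"topology code contains letters outside SCL: {bad}")
        if self.code.count("L") % 2:
            raise ValueError("topology code has an odd number of L letters")

    def __str__(self) -> str:
        return self.code


def _residues(peptide) -> str:
    return peptide if isinstance(peptide, str) else peptide.residues


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_bridges(
    peptide,
    labionin_mode: str = "all_cys",
    labionin_pattern: LabioninPattern = DEFAULT_LABIONIN,
    min_gap: int = 3,
) -> BridgeSet:
    """Predict the bridging structure of a (core) peptide.

    ``labionin_mode``: ``all_cys`` tests the labionin geometry at every Cys,
    ``first_cys_only`` only at the C-terminal-most Cys (the literal reading of
    the rule), ``off`` disables labionin detection. ``min_gap`` is the minimum
    Cys-to-partner offset for a lanthionine bridge ("more than two residues
    away" = 3).
    """
    if labionin_mode not in ("all_cys", "first_cys_only", "off"):
        raise ValueError(f"unknown labionin_mode {labionin_mode!r}")
    seq = _residues(peptide)
    if not seq:
        raise ValueError("empty peptide")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")

    n = len(seq)
    cys = [k + 1 for k in range(n) if seq[k] == "C"]
    bonded = bytearray(n + 1)
    pat = labionin_pattern

    lan: list[tuple[int, int]] = []
    lab: list[tuple[int, int, int]] = []
    free: list[int] = []

    first = True
    for j in reversed(cys):
        unit = None
        if labionin_mode == "all_cys" or (labionin_mode == "first_cys_only" and first):
            # maximal i2 wins (nearest serines to the Cys)
            for i2 in range(j - pat.cys_gap_min, j - pat.cys_gap_max - 1, -1):
                i1 = i2 - pat.spacer
                if i1 < 1:
                    break
                if bonded[i2] or seq[i2 - 1] not in pat.second_residues:
                    continue
                if bonded[i1] or seq[i1 - 1] not in pat.first_residues:
                    continue
                if "C" in seq[i1 : j - 1]:  # no Cys strictly inside (i1, j)
                    continue
                unit = (i1, i2, j)
                break
        first = False
        if unit is not None:
            i1, i2, _ = unit
            bonded[i1] = bonded[i2] = bonded[j] = 1
            lab.append(unit)
            continue
        partner = 0
        for i in range(j - min_gap, 0, -1):
            if not bonded[i] and seq[i - 1] in "ST":
                partner = i
                break
        if partner:
            bonded[partner] = bonded[j] = 1
            lan.append((partner, j))
        else:
            free.append(j)

    bs = BridgeSet(
        peptide_length=n,
        lan_bridges=sorted(lan),
        labionin_units=sorted(lab),
        free_cys=sorted(free),
    )
    bs.validate()
    return bs


def encode_topology(bridges: BridgeSet, peptide) -> TopologyCode:
    """Summarise a predicted bridge set as a topology code (unbridged Ser/Thr omitted)."""
    roles: dict[int, str] = {}
    for i, j in bridges.lan_bridges:
        roles[i] = "S"
        roles[j] = "C"
    for i1, i2, j in bridges.labionin_units:
        roles[i1] = "L"
        roles[i2] = "L"
        roles[j] = "C"
    for j in bridges.free_cys:
        roles[j] = "C"
    return TopologyCode("".join(roles[p] for p in sorted(roles)))


def decode_topology(code) -> BridgeSet:
    """Reconstruct the abstract bridge set of a topology code on code indices.

    Scans C letters right-to-left: a Cys takes the two nearest unconsumed L
    letters to its left as a labionin unit if any remain, else the nearest
    unconsumed S as a lanthionine arc, else it is free. No spacing rule
    applies (residue spacing is not represented in codes).
    """
    code_s = code.code if isinstance(code, TopologyCode) else code
    TopologyCode(code_s)  # validates alphabet and L parity
    n = len(code_s)
    ls = [k + 1 for k in range(n) if code_s[k] == "L"]
    ss = [k + 1 for k in range(n) if code_s[k] == "S"]
    cs = [k + 1 for k in range(n) if code_s[k] == "C"]
    free_l = list(ls)
    free_s = list(ss)
    lan, lab, free = [], [], []
    for j in reversed(cs):
        avail_l = [p for p in free_l if p < j]
        if avail_l:
            if len(avail_l) < 2:
                raise ValueError(f"code {code_s!r}: unpaired L letter before C at {j}")
            i2, i1 = avail_l[-1], avail_l[-2]
            free_l.remove(i1)
            free_l.remove(i2)
            lab.append((i1, i2, j))
            continue
        avail_s = [p for p in free_s if p < j]
        if avail_s:
            i = avail_s[-1]
            free_s.remove(i)
            lan.append((i, j))
        else:
            free.append(j)
    if free_l:
        raise ValueError(f"code {code_s!r}: L letters with no cysteine to their right")
    bs = BridgeSet(
        peptide_length=n,
        lan_bridges=sorted(lan),
        labionin_units=sorted(lab),
        free_cys=sorted(free),
    )
    bs.validate()
    return bs


# ---------------------------------------------------------------------------
# Bridge-set arithmetic
# ---------------------------------------------------------------------------

def count_bridges(bridges: BridgeSet) -> int:
    """Number of bridges; a labionin unit counts once."""
    return len(bridges.lan_bridges) + len(bridges.labionin_units)


def count_crossings(bridges: BridgeSet) -> int:
    """Number of crossing (overlapping) arc pairs (a,b),(c,d) with a<c<b<d.

    Counted with a Fenwick tree over arc endpoints (arcs in order of right
    endpoint; each new arc is crossed by exactly the already-seen arcs that
    straddle its left endpoint). Free cysteines contribute nothing.
    """
    arcs = sorted(bridges.arcs(), key=lambda a: a[1])
    if not arcs:
        return 0
    size = max(b for _, b in arcs) + 1
    tree = [0] * (size + 1)

    def add(pos: int, val: int) -> None:
        while pos <= size:
            tree[pos] += val
            pos += pos & -pos

    def prefix(pos: int) -> int:
        s = 0
        while pos > 0:
            s += tree[pos]
            pos -= pos & -pos
        return s

    total = 0
    for left, right in arcs:
        total += prefix(left - 1)  # earlier arcs with a < left < b (b < right)
        add(left, 1)
        add(right, -1)
    return total


def check_nesting(bridges: BridgeSet) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Arc pairs (a,b),(c,d) with a<c<d<b (one bridge fully inside another)."""
    arcs = sorted(bridges.arcs())
    nested = []
    for k, (a, b) in enumerate(arcs):
        for c, d in arcs[k + 1 :]:
            if a < c and d < b:
                nested.append(((a, b), (c, d)))
    return nested


def bridge_space_size(n_st: int, n_cys: int) -> int:
    """Number of ways to assign each of n_cys cysteines a distinct partner among
    n_st Ser/Thr residues: the falling factorial n_st!/(n_st-n_cys)!, exact."""
    if not (n_st >= n_cys >= 0):
        raise ValueError("require n_st >= n_cys >= 0")
    total = 1
    for k in range(n_cys):
        total *= n_st - k
    return total


def tally_topologies(
    codes: Iterable,
    known_codes: Iterable,
    min_support: int = 2,
) -> pd.DataFrame:
    """Tally distinct topology codes against a set of known codes.

    Returns a table with one row per distinct code: its count, whether it is
    absent from ``known_codes`` (``is_novel``), and whether it additionally
    reaches ``min_support`` occurrences (``novel_supported`` — the criterion
    for calling a bridging pattern suggestively new).
    """
    known = {str(c) for c in known_codes}
    counts: dict[str, int] = {}
    for c in codes:
        s = str(c)
        counts[s] = counts.get(s, 0) + 1
    rows = [
        {
            "code": c,
            "count": k,
            "is_novel": c not in known,
            "novel_supported": c not in known and k >= min_support,
        }
        for c, k in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["code", "count", "is_novel", "novel_supported"])
    if len(df):
        df = df.sort_values(["count", "code"], ascending=[False, True]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Motif counting
# ---------------------------------------------------------------------------

def motif_to_regex(pattern: str) -> str:
    """Translate a motif spec like ``SxxSx{2,5}C`` into a Python regex.

    ``x`` means any residue; bracketed residue classes (including ``[^C]``)
    and ``{m,n}`` repeats pass through unchanged; other letters are literal.
    """
    out = []
    k = 0
    while k < len(pattern):
        ch = pattern[k]
        if ch in ("x", "."):
            out.append("[A-Z]")
            k += 1
        elif ch == "[":
            end = pattern.index("]", k)
            out.append(pattern[k : end + 1])
            k = end + 1
        elif ch == "{":
            end = pattern.index("}", k)
            out.append(pattern[k : end + 1])
            k = end + 1
        else:
            out.append(re.escape(ch))
            k += 1
    return "".join(out)


def find_motif(peptide, pattern: str) -> list[int]:
    """All 1-based start positions of a motif in a peptide, overlapping allowed."""
    seq = _residues(peptide)
    rx = motif_to_regex(pattern)
    return [m.start() + 1 for m in re.finditer(f"(?=({rx}))", seq)]
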