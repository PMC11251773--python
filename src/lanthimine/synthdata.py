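"""Synthetic genomes with planted lanthipeptide clusters, precursors and decoys.

The generator emulates the study conditions every pipeline stage is tested
against: genomes carrying gene clusters (cyclase + dehydratase + accessory
domain genes within 10 kb of each other) with planted precursor ORFs whose
peptides decode to specified topology codes, plus length-matched negative
ORFs satisfying the precursor composition rules but placed more than 10 kb
from any cluster. Domain genes are sequence stubs whose detection is
simulated through emitted HMMER3 domtblout rows, so the pipeline's real
domain-consumption code path is exercised without running profile searches.

Everything is driven by a single integer seed; a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from Bio.Data import CodonTable
from Bio.Seq import Seq

from . import mining, topology
from .seqio import (
    GenomeSequence,
    GenomicInterval,
    ProteinSequence,
    format_location,
    scan_orfs,
)

# Fillers never include S/T/C (no accidental bridge partners) nor G (no
# accidental G[GA] cleavage motifs shifting the predicted core); L and Q are
# also excluded so every filler has a codon compatible with the Cys-free DNA
# discipline below.
FILLER_AA = "AVEKDN"
# Domain-gene stubs avoid C (at the protein level) so no spurious cyclase
# triad motif (CHG/CCG, both Cys-anchored) can arise outside planted ones.
DOMAIN_STUB_AA = "ADEFGIKLNPRSTVWY"

DEFAULT_LABELS = ["B-CCH", "D-CCH", "D-CCC", "L-CCH", "L-Unk"]
DEFAULT_CODES = ["SCSC", "SSCC", "LLC", "SC", "C"]

DOMAINS_FOR_CLASS = {
    "B": ["Lant_dehydr_N", "Lant_dehydr_C"],
    "D": ["DUF4135"],
    "L": ["Lyase", "Kinase"],
}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic genome."""

    seed: int = 0
    n_clusters: int = 5
    synthetase_labels: list = field(default_factory=lambda: list(DEFAULT_LABELS))
    domains_per_cluster: list | None = None  # override; else derived from labels
    precursors_per_cluster: int = 2
    precursor_codes: list = field(default_factory=lambda: list(DEFAULT_CODES))
    precursor_length: int = 48
    gap_distribution: tuple = (200, 1500)  # intra-cluster intergenic bp
    cluster_separation: int = 15_000  # bp between clusters (> 10 kb)
    n_decoy_orfs: int = 6
    genome_gc: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.gap_distribution, list):
            cfg.gap_distribution = tuple(cfg.gap_distribution)
        return cfg

    def to_yaml(self, path) -> None:
        data = dict(self.__dict__)
        data["gap_distribution"] = list(self.gap_distribution)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class TruthTable:
    """Planted ground truth: precursor, decoy and cluster tables."""

    precursors: pd.DataFrame  # id, start, end, strand, peptide, code, cluster, label
    decoys: pd.DataFrame  # id, start, end, strand, peptide
    clusters: pd.DataFrame  # cluster, label, start, end

    def to_tsv(self, path) -> None:
        pre = self.precursors.assign(kind="precursor")
        dec = self.decoys.assign(kind="decoy", code="", cluster="", label="")
        pd.concat([pre, dec], ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Peptides realizing a topology code
# ---------------------------------------------------------------------------

def _min_layout(code: str, pattern: topology.LabioninPattern) -> list[int]:
    """Distances between consecutive special residues realizing ``code``."""
    pairing = topology.decode_topology(code)
    lab_pairs = {(u[0], u[1]) for u in pairing.labionin_units}
    lab_cys = {u[2]: u[1] for u in pairing.labionin_units}  # code pos of C -> its i2
    dists = []
    for k in range(1, len(code)):
        prev_pos, pos = k, k + 1  # code positions
        if (prev_pos, pos) in lab_pairs:
            dists.append(pattern.spacer)
        elif code[k] == "C" and lab_cys.get(pos) == prev_pos:
            dists.append(pattern.cys_gap_min)
        else:
            dists.append(4)
    return dists


def generate_peptide_for_code(
    code: str,
    length: int,
    rng: np.random.Generator,
    labionin_mode: str = "all_cys",
    min_gap: int = 3,
    ensure_filter_compliant: bool = False,
) -> ProteinSequence:
    """Build a peptide whose predicted topology encodes exactly to ``code``.

    The special residues are laid out left to right — Thr for bridged 'S'
    letters, Ser for labionin 'L' letters, Cys for 'C' — padded at the front
    with filler residues (never S/T/C) to the requested length, so the
    cysteines stay in the C-terminal third. ``ensure_filter_compliant``
    appends trailing (never-bridged) serines when the code has fewer S/L
    letters than cysteines, so the peptide also passes the precursor
    composition filter. The result is verified by running the predictor; an
    unrealizable code or an infeasible length raises.
    """
    code_s = str(code)
    pattern = topology.DEFAULT_LABIONIN
    dists = _min_layout(code_s, pattern)
    letters = {"S": "T", "L": "S", "C": "C"}
    specials = [letters[c] for c in code_s]

    n_extra_ser = 0
    if ensure_filter_compliant:
        n_st = sum(c in "SL" for c in code_s)
        n_cys = code_s.count("C")
        n_extra_ser = max(0, n_cys - n_st)
        if n_cys == 0:
            raise ValueError("a precursor code needs at least one C")

    core_len = 1 + sum(dists) + n_extra_ser  # first special + gaps + trailing Ser
    min_len = core_len + 1  # leading Met
    if length < min_len:
        raise ValueError(
            f"code {code_s!r} infeasible at length {length}; minimum length {min_len}"
        )

    filler = lambda k: "".join(rng.choice(list(FILLER_AA), size=k))
    parts = ["M", filler(length - min_len)]
    parts.append(specials[0])
    for d, sp in zip(dists, specials[1:]):
        parts.append(filler(d - 1))
        parts.append(sp)
    parts.append("S" * n_extra_ser)
    pep = "".join(parts)
    assert len(pep) == length

    got = topology.encode_topology(
        topology.predict_bridges(pep, labionin_mode=labionin_mode, min_gap=min_gap), pep
    )
    if str(got) != code_s:
        raise ValueError(
            f"code {code_s!r} is not realizable by the bridging rules "
            f"(layout encodes to {got!s})"
        )
    return ProteinSequence(id=f"code_{code_s}", residues=pep)


def generate_negative_orfs(
    candidates: Sequence,
    rng: np.random.Generator,
) -> list[ProteinSequence]:
    """Two length-matched negatives per candidate, passing the composition rules."""
    out = []
    for cand in candidates:
        if hasattr(cand, "peptide"):  # PrecursorCandidate
            pep = cand.peptide.residues
        elif hasattr(cand, "residues"):  # ProteinSequence
            pep = cand.residues
        else:
            pep = str(cand)
        L = len(pep)
        for k in range(2):
            out.append(
                ProteinSequence(
                    id=f"neg_{len(out) + 1}",
                    residues=_random_compliant_peptide(L, rng),
                )
            )
    return out


def _random_compliant_peptide(length: int, rng: np.random.Generator) -> str:
    """A random peptide of given length satisfying the precursor rules."""
    if length < 4:
        raise ValueError("compliant peptides need length >= 4")
    body = ["M"] + list(rng.choice(list(FILLER_AA), size=length - 1))
    body[-1] = "C"  # single Cys, trivially in the last third
    body[rng.integers(1, length - 1)] = "S"
    return "".join(body)


# ---------------------------------------------------------------------------
# Reverse translation
# ---------------------------------------------------------------------------

def _codon_choices(genetic_code: int = 11) -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for v in by_aa.values():
        v.sort()
    return by_aa


_BY_AA = _codon_choices()


def reverse_translate(peptide: str, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Pick synonymous codons with weights biased toward the target G+C."""
    out = []
    for aa in peptide:
        codons = _BY_AA[aa]
        weights = np.array(
            [
                (gc ** sum(b in "GC" for b in c)) * ((1 - gc) ** sum(b in "AT" for b in c))
                for c in codons
            ]
        )
        out.append(codons[rng.choice(len(codons), p=weights / weights.sum())])
    return "".join(out)


# --- Cys-free DNA discipline ------------------------------------------------
#
# Cys codons are TGT/TGC; their reverse complements are ACA/GCA. DNA that
# avoids these four trigrams everywhere encodes no cysteine in any frame on
# either strand — so a chance ORF there can never pass the >=1 Cys precursor
# filter. Gene DNA is built from codons chosen so the forbidden trigrams occur
# only inside planted Cys codons, keeping spurious candidate ORFs to the rare
# frame-aligned overlap with a planted cysteine (removed by the cleanup pass).

_FORBIDDEN_TRIGRAMS = frozenset(("TGT", "TGC", "ACA", "GCA"))


def _internal_safe(codon: str) -> bool:
    return codon not in _FORBIDDEN_TRIGRAMS


_CODONS_SAFE: dict[str, list[str]] = {
    aa: ([c for c in codons if _internal_safe(c)] if aa != "C" else list(codons))
    for aa, codons in _BY_AA.items()
}
_CODONS_SAFE["*"] = ["TAA", "TAG", "TGA"]


def _junction_ok(tail: str, codon: str) -> bool:
    """No forbidden trigram spans the junction between ``tail`` and ``codon``."""
    t = tail[-2:]
    s = t + codon
    for k in range(len(t)):
        if s[k : k + 3] in _FORBIDDEN_TRIGRAMS:
            return False
    return True


def _gc_weight(codon: str, gc: float) -> float:
    w = 1.0
    for b in codon:
        w *= gc if b in "GC" else (1 - gc)
    return w


def _weighted_order(cands: list[str], rng: np.random.Generator, gc: float) -> list[str]:
    """Candidates in weighted random order (Efraimidis-Spirakis keys)."""
    keys = [rng.random() ** (1.0 / max(_gc_weight(c, gc), 1e-9)) for c in cands]
    return [c for _, c in sorted(zip(keys, cands), key=lambda t: t[0], reverse=True)]


def _encode_peptide_dna(peptide: str, rng: np.random.Generator, gc: float) -> str:
    """Guard stop + ATG + safe codons + stop for a fixed peptide (DFS backtracking)."""
    if peptide[0] != "M":
        raise ValueError("planted peptides must start with Met")
    targets = list(peptide[1:]) + ["*"]
    chosen: list[str] = []
    options: list[list[str]] = []
    while len(chosen) < len(targets):
        idx = len(chosen)
        tail = chosen[-1][1:] if chosen else "TG"  # after the ATG initiator
        if len(options) == idx:
            aa = targets[idx]
            cands = [c for c in _CODONS_SAFE[aa] if _junction_ok(tail, c)]
            options.append(_weighted_order(cands, rng, gc))
        if not options[idx]:
            options.pop()
            if not chosen:
                raise RuntimeError(f"cannot encode peptide {peptide!r} safely")
            chosen.pop()
            continue
        chosen.append(options[idx].pop(0))
    return "TAA" + "ATG" + "".join(chosen)


def _stub_gene_dna(
    triad: str | None,
    rng: np.random.Generator,
    gc: float,
    length: int = 180,
) -> tuple[str, str]:
    """(protein, coding DNA incl. ATG and stop) for a domain-gene stub.

    Free positions sample any non-Cys residue with a junction-safe codon;
    cyclase stubs carry a fixed upstream Cys plus a CHG/CCG triad motif —
    the only Cys trigrams in the gene.
    """
    fixed: dict[int, str] = {}
    if triad in ("CCH", "CCC"):
        fixed[39] = "C"
        motif = "CHG" if triad == "CCH" else "CCG"
        for k, ch in enumerate(motif):
            fixed[length - 20 + k] = ch
    codons = ["ATG"]
    aas = ["M"]
    free_pool = [
        (aa, c)
        for aa in DOMAIN_STUB_AA
        for c in _CODONS_SAFE[aa]
        if not c.endswith("TG")  # keeps every fixed follow-up reachable
    ]
    for pos in range(1, length):
        tail = codons[-1][1:]
        aa = fixed.get(pos)
        if aa is None:
            cands = [(a, c) for a, c in free_pool if _junction_ok(tail, c)]
        else:
            cands = [(aa, c) for c in _CODONS_SAFE[aa] if _junction_ok(tail, c)]
        if not cands:
            raise RuntimeError("stub codon selection stuck")  # pragma: no cover
        keys = [rng.random() ** (1.0 / max(_gc_weight(c, gc), 1e-9)) for _, c in cands]
        _, (a, c) = sorted(zip(keys, cands), key=lambda t: t[0], reverse=True)[0]
        codons.append(c)
        aas.append(a)
    stop = next(c for c in ("TAA", "TAG", "TGA") if _junction_ok(codons[-1][1:], c))
    return "".join(aas), "".join(codons) + stop


def _random_dna(
    length: int,
    rng: np.random.Generator,
    gc: float,
    tail: str = "",
    head: str = "",
) -> str:
    """Random intergenic DNA near the target G+C, free of Cys codons both strands.

    ``tail`` is the preceding sequence context and ``head`` the following
    one; the forbidden-trigram discipline is maintained across both
    junctions.
    """
    bases = "ATGC"
    weights = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    out: list[str] = []

    def allowed_at(ctx: str, also_head: bool) -> list[str]:
        opts = []
        for b in bases:
            if (ctx + b)[-3:] in _FORBIDDEN_TRIGRAMS:
                continue
            if also_head and head and not _junction_ok((ctx + b)[-2:], head[:3]):
                continue
            opts.append(b)
        return opts

    for k in range(length):
        ctx = (tail + "".join(out))[-2:]
        opts = allowed_at(ctx, also_head=(k == length - 1))
        if not opts:  # extremely rare corner; relax the head constraint
            opts = allowed_at(ctx, also_head=False)
        w = np.array([weights[b] for b in opts])
        out.append(opts[rng.choice(len(opts), p=w / w.sum())])
    return "".join(out)


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    gene_id: str
    protein: str
    start: int = 0
    end: int = 0
    strand: str = "+"
    kind: str = "domain"  # domain | precursor | decoy
    domain_name: str | None = None
    code: str | None = None
    cluster: str | None = None
    label: str | None = None
    coding_dna: str | None = None  # pre-rendered ATG..stop (domain stubs)


def generate_genome(
    config: SynthConfig,
) -> tuple[GenomeSequence, TruthTable, str, list[ProteinSequence]]:
    """Build a genome, its truth table, domtblout text and domain-gene proteins.

    Precursor genes are embedded as ATG..stop spans guarded by an upstream
    in-frame stop, so the six-frame scanner recovers exactly the planted
    peptide. After assembly, chance ORFs near clusters that would pass the
    composition filter are disrupted by seeded point mutations (synonymous
    ones inside planted genes), keeping recovery exact by construction.
    """
    rng = np.random.default_rng(config.seed)
    genome_id = f"synth_{config.seed}"
    gc = config.genome_gc

    labels = [
        config.synthetase_labels[k % len(config.synthetase_labels)]
        for k in range(config.n_clusters)
    ]
    codes = config.precursor_codes

    genes: list[_Gene] = []
    cluster_rows = []
    code_cursor = 0
    for ci, label in enumerate(labels, 1):
        deh_class, triad = label.split("-")
        cluster_id = f"truth_cluster_{ci}"
        members: list[_Gene] = []
        cyc_prot, cyc_dna = _stub_gene_dna(triad, rng, gc)
        members.append(
            _Gene(
                gene_id=f"g{ci}_cyclase",
                protein=cyc_prot,
                domain_name="LANC_like",
                coding_dna=cyc_dna,
            )
        )
        domain_names = (
            config.domains_per_cluster
            if config.domains_per_cluster is not None
            else DOMAINS_FOR_CLASS.get(deh_class, []) + ["Peptidase_C39", "ABC_membrane"]
        )
        for dname in domain_names:
            stub_prot, stub_dna = _stub_gene_dna(None, rng, gc)
            members.append(
                _Gene(
                    gene_id=f"g{ci}_{dname}",
                    protein=stub_prot,
                    domain_name=dname,
                    coding_dna=stub_dna,
                )
            )
        for pk in range(config.precursors_per_cluster):
            code = codes[code_cursor % len(codes)]
            code_cursor += 1
            pep = generate_peptide_for_code(
                code, config.precursor_length, rng, ensure_filter_compliant=True
            )
            members.append(
                _Gene(
                    gene_id=f"g{ci}_pre{pk + 1}",
                    protein=pep.residues,
                    kind="precursor",
                    code=code,
                    cluster=cluster_id,
                    label=label,
                )
            )
        for m in members:
            m.cluster = m.cluster or cluster_id
            m.label = m.label or label
        genes.append(("cluster", members))
        cluster_rows.append({"cluster": cluster_id, "label": label})

    # decoys: length-matched to the planted precursors, far from any cluster
    decoy_genes = [
        _Gene(
            gene_id=f"decoy_{k + 1}",
            protein=_random_compliant_peptide(config.precursor_length, rng),
            kind="decoy",
        )
        for k in range(config.n_decoy_orfs)
    ]

    # --- lay the genes onto a coordinate axis ----------------------------
    lo, hi = config.gap_distribution
    ordered: list[tuple[str, object]] = [("gap", 1500)]
    idx = 0
    for _, members in genes:
        for mi, gene in enumerate(members):
            if mi > 0:
                ordered.append(("gap", int(rng.integers(lo, hi + 1))))
            gene.strand = "+" if idx % 2 == 0 else "-"
            idx += 1
            ordered.append(("gene", gene))
        ordered.append(("gap", config.cluster_separation))
    for dk, gene in enumerate(decoy_genes):
        if dk > 0:
            ordered.append(("gap", 400))
        gene.strand = "+" if dk % 2 == 0 else "-"
        ordered.append(("gene", gene))
    ordered.append(("gap", 1500))

    rendered = {}  # id(_Gene) -> forward-strand DNA incl. guard stop
    for kind, item in ordered:
        if kind == "gene":
            rendered[id(item)] = _gene_dna(item, rng, gc)

    parts: list[str] = []
    pos = 1  # next free 1-based coordinate
    placed: list[_Gene] = []
    for k, (kind, item) in enumerate(ordered):
        if kind == "gap":
            tail = parts[-1][-2:] if parts else ""
            head = ""
            if k + 1 < len(ordered) and ordered[k + 1][0] == "gene":
                head = rendered[id(ordered[k + 1][1])][:3]
            seg = _random_dna(item, rng, gc, tail=tail, head=head)
        else:
            seg = rendered[id(item)]
            item.start = pos + 3  # coding span excludes the guard stop
            item.end = pos + len(seg) - 1
            if item.strand == "-":
                item.start, item.end = pos, pos + len(seg) - 4
            placed.append(item)
        parts.append(seg)
        pos += len(seg)

    residues = "".join(parts)
    residues = _disrupt_spurious_orfs(residues, genome_id, placed, config, rng)
    genome = GenomeSequence(id=genome_id, residues=residues, description="synthetic")

    # --- outputs ---------------------------------------------------------
    proteins = [
        ProteinSequence(
            id=g.gene_id,
            residues=g.protein,
            description=format_location(
                GenomicInterval(genome_id, g.start, g.end, g.strand)
            ),
        )
        for g in placed
        if g.kind == "domain"
    ]
    domtbl = _domtblout_text(
        [g for g in placed if g.kind == "domain"], genome_id
    )

    pre_rows, dec_rows = [], []
    for g in placed:
        if g.kind == "precursor":
            pre_rows.append(
                {
                    "id": g.gene_id,
                    "genome_id": genome_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "peptide": g.protein,
                    "code": g.code,
                    "cluster": g.cluster,
                    "label": g.label,
                }
            )
        elif g.kind == "decoy":
            dec_rows.append(
                {
                    "id": g.gene_id,
                    "genome_id": genome_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "peptide": g.protein,
                }
            )
    for row in cluster_rows:
        members = [g for g in placed if g.cluster == row["cluster"]]
        row["start"] = min(g.start for g in members)
        row["end"] = max(g.end for g in members)
    truth = TruthTable(
        precursors=pd.DataFrame(pre_rows),
        decoys=pd.DataFrame(dec_rows),
        clusters=pd.DataFrame(cluster_rows),
    )
    return genome, truth, domtbl, proteins


def _gene_dna(gene: _Gene, rng: np.random.Generator, gc: float) -> str:
    """Guard stop + ATG..coding..stop on the gene's strand (forward sequence).

    The upstream in-frame guard stop makes the six-frame scanner report this
    exact span; codons follow the Cys-free trigram discipline so the gene's
    other frames and strand cannot harbour chance precursor candidates.
    """
    if gene.coding_dna is not None:
        dna = "TAA" + gene.coding_dna
    else:
        dna = _encode_peptide_dna(gene.protein, rng, gc)
    if gene.strand == "-":
        dna = str(Seq(dna).reverse_complement())
    return dna


def _domtblout_text(domain_genes: Sequence[_Gene], genome_id: str) -> str:
    """HMMER3 per-domain tabular rows for the planted domain genes."""
    lines = [
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    for g in domain_genes:
        tlen = len(g.protein)
        lines.append(
            f"{g.gene_id:<21}-          {tlen:>5} {g.domain_name:<20} -          {tlen:>5}   1e-30  200.0   0.0   1   1     1e-30     1e-30  200.0   0.0     1 {tlen:>5}     1 {tlen:>5}     1 {tlen:>5} 0.99 synthetic domain stub"
        )
    lines.append("#")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Spurious-ORF cleanup
# ---------------------------------------------------------------------------

def _disrupt_spurious_orfs(
    residues: str,
    genome_id: str,
    placed: Sequence[_Gene],
    config: SynthConfig,
    rng: np.random.Generator,
    max_passes: int = 60,
) -> str:
    """Mutate away chance candidate ORFs that could be confused with planted ones.

    Only ORFs passing the composition filter within 10 kb of a cluster (or
    overlapping a decoy span) matter. Mutations avoid planted coding spans
    except at synonymous third-codon positions, so every planted peptide is
    untouched.
    """
    planted_spans = [(g.start, g.end, g) for g in placed]
    cluster_ranges = []
    for g in placed:
        if g.kind != "decoy":
            cluster_ranges.append((g.start - 11_000, g.end + 11_000))

    def spurious(seq: str) -> list:
        genome = GenomeSequence(id=genome_id, residues=seq)
        orfs = scan_orfs(genome, max_len_aa=100)
        cands = mining.filter_precursor_candidates(orfs, max_len_aa=100)
        out = []
        planted_keys = {
            (g.start, g.end, g.strand) for g in placed if g.kind in ("precursor", "decoy")
        }
        for c in cands:
            key = (c.orf.start, c.orf.end, c.orf.strand)
            if key in planted_keys:
                continue
            near_cluster = any(
                c.orf.start <= hi and c.orf.end >= lo for lo, hi in cluster_ranges
            )
            if near_cluster:
                out.append(c)
        return out

    seq = residues
    for _ in range(max_passes):
        bad = spurious(seq)
        if not bad:
            return seq
        seq_list = list(seq)
        for c in bad:
            site = _mutable_site(c.orf.start, c.orf.end, planted_spans, rng)
            if site is None:
                continue
            pos, gene = site
            if gene is None:
                current = seq_list[pos - 1]
                choices = [b for b in "ACGT" if b != current]
                seq_list[pos - 1] = choices[int(rng.integers(len(choices)))]
            else:
                _synonymous_mutate(seq_list, pos, gene, rng)
        seq = "".join(seq_list)
    raise RuntimeError("could not remove spurious candidate ORFs from synthetic genome")


def _mutable_site(start: int, end: int, planted_spans, rng) -> tuple[int, _Gene | None] | None:
    """A position inside [start, end] that is free, or a synonymous site of a planted gene."""
    positions = list(range(start, end + 1))
    rng.shuffle(positions)
    fallback = None
    for pos in positions:
        hit = next((g for (s, e, g) in planted_spans if s - 3 <= pos <= e + 3), None)
        if hit is None:
            return pos, None
        if fallback is None and hit.start <= pos <= hit.end:
            fallback = (pos, hit)
    return fallback


def _synonymous_mutate(seq_list: list, pos: int, gene: _Gene, rng) -> None:
    """Swap the codon covering ``pos`` for a synonymous one (peptide preserved)."""
    if gene.strand == "+":
        offset = pos - gene.start
        codon_idx = offset // 3
        codon_start = gene.start + 3 * codon_idx  # genomic, 1-based
        codon = "".join(seq_list[codon_start - 1 : codon_start + 2])
        aa_codon = codon
    else:
        offset = gene.end - pos
        codon_idx = offset // 3
        codon_start = gene.end - 3 * codon_idx - 2
        codon = "".join(seq_list[codon_start - 1 : codon_start + 2])
        aa_codon = str(Seq(codon).reverse_complement())
    table = CodonTable.unambiguous_dna_by_id[11]
    aa = table.forward_table.get(aa_codon)
    if aa is None:
        return  # stop or guard codon; leave alone
    options = [c for c in _BY_AA[aa] if c != aa_codon]
    if not options:
        return
    new = options[int(rng.integers(len(options)))]
    if gene.strand == "-":
        new = str(Seq(new).reverse_complement())
    seq_list[codon_start - 1 : codon_start + 2] = list(new)
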