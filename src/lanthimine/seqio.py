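"""Sequence I/O: FASTA, small-ORF calling, HMMER3 domtblout parsing, GFF3 output.

Coordinates are 1-based inclusive throughout (GFF3 convention); genomes are
treated as linear (no wrap-around ORFs). ORF calling is a plain six-frame
start-to-stop scan, not a coding-potential gene finder: every start codon
(ATG/GTG/TTG by default) to its in-frame stop is considered, and by default
only the longest ORF per (stop, frame, strand) is reported, mirroring standard
ORF-caller behaviour. Codons containing N are treated as non-translatable and
split ORFs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_LETTERS = set("ACGTN")
PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")

_LOC_RE = re.compile(r"loc=([^:\s]+):(\d+)\.\.(\d+):([+-])")


@dataclass(frozen=True)
class GenomeSequence:
    """A DNA sequence over {A,C,G,T,N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence over the 20 standard letters plus X."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive stranded genomic interval."""

    genome_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class OrfRecord:
    """A called open reading frame.

    ``start``/``end`` are forward-strand coordinates of the first codon base
    and the last stop-codon base; ``peptide`` excludes the stop. ``frame`` is
    the 0/1/2 offset on the ORF's own strand.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    peptide: ProteinSequence
    frame: int

    def __post_init__(self):
        span = self.end - self.start + 1
        if self.start > self.end:
            raise ValueError("ORF start > end")
        if span % 3:
            raise ValueError("ORF span not divisible by 3")
        if len(self.peptide) != span // 3 - 1:
            raise ValueError("peptide length inconsistent with ORF span")

    @property
    def orf_id(self) -> str:
        return f"{self.genome_id}|{self.start}-{self.end}({self.strand})"

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.genome_id, self.start, self.end, self.strand)


@dataclass
class DomainHit:
    """One profile-domain match on a protein/ORF target."""

    target_id: str
    domain_name: str
    ali_start: int
    ali_end: int
    score: float
    evalue: float
    genome_interval: GenomicInterval | None = None

    def __post_init__(self):
        if self.ali_start > self.ali_end:
            raise ValueError("alignment start > end")
        if self.evalue < 0:
            raise ValueError("negative E-value")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: str, strip_gaps: bool = True):
    """Read a FASTA file as GenomeSequence (dna) or ProteinSequence (protein) records.

    Terminal/internal '*' stop symbols and '-' gaps are stripped when
    ``strip_gaps`` is true. Illegal characters raise, naming the record and
    the 1-based position of the first offender.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    allowed = DNA_LETTERS if alphabet == "dna" else PROTEIN_LETTERS
    cls = GenomeSequence if alphabet == "dna" else ProteinSequence

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if strip_gaps:
            residues = residues.replace("*", "").replace("-", "")
        for pos, ch in enumerate(residues, 1):
            if ch not in allowed:
                raise ValueError(
                    f"record {rec.id!r}: illegal {alphabet} character {ch!r} at position {pos}"
                )
        records.append(cls(id=rec.id, residues=residues, description=rec.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def parse_location(description: str) -> GenomicInterval | None:
    """Parse a ``loc=<genome>:<start>..<end>:<strand>`` token from a FASTA description."""
    m = _LOC_RE.search(description or "")
    if not m:
        return None
    return GenomicInterval(m.group(1), int(m.group(2)), int(m.group(3)), m.group(4))


def format_location(interval: GenomicInterval) -> str:
    return f"loc={interval.genome_id}:{interval.start}..{interval.end}:{interval.strand}"


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def _codon_tables(genetic_code: int):
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    fwd = dict(table.forward_table)
    stops = set(table.stop_codons)
    return fwd, stops


def scan_orfs(
    genome: GenomeSequence,
    max_len_aa: int,
    min_len_aa: int = 1,
    genetic_code: int = 11,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    all_starts: bool = False,
) -> list[OrfRecord]:
    """Six-frame start-to-stop ORF scan.

    Returns every start-codon-to-in-frame-stop span on both strands whose
    peptide length lies in [min_len_aa, max_len_aa]. By default only the
    longest ORF per shared stop codon is emitted; ``all_starts`` emits every
    start. ORFs without a stop codon are never emitted. The initiator codon is
    translated as Met regardless of which start codon it is.
    """
    if not (max_len_aa >= min_len_aa >= 1):
        raise ValueError("require max_len_aa >= min_len_aa >= 1")
    seq = genome.residues
    n = len(seq)
    if n < 6:
        return []
    fwd_table, stop_codons = _codon_tables(genetic_code)
    starts = set(c.upper() for c in start_codons)
    rc = str(Seq(seq).reverse_complement())

    orfs: list[OrfRecord] = []
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            pending: list[int] = []  # 0-based codon start offsets
            for p in range(frame, n - 2, 3):
                codon = s[p : p + 3]
                if "N" in codon or any(ch not in "ACGT" for ch in codon):
                    pending.clear()  # non-translatable codon splits ORFs
                    continue
                if codon in stop_codons:
                    chosen = pending if all_starts else pending[:1]
                    for q in chosen:
                        aa_len = (p - q) // 3
                        if not (min_len_aa <= aa_len <= max_len_aa):
                            continue
                        pep = _translate_orf(s[q : p], fwd_table)
                        if strand == "+":
                            start, end = q + 1, p + 3
                        else:
                            start, end = n - (p + 3) + 1, n - q
                        orfs.append(
                            OrfRecord(
                                genome_id=genome.id,
                                start=start,
                                end=end,
                                strand=strand,
                                peptide=ProteinSequence(
                                    id=f"{genome.id}|{start}-{end}({strand})",
                                    residues=pep,
                                ),
                                frame=frame,
                            )
                        )
                    pending.clear()
                elif codon in starts:
                    pending.append(p)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def _translate_orf(coding: str, fwd_table) -> str:
    aas = [fwd_table[coding[i : i + 3]] for i in range(0, len(coding), 3)]
    aas[0] = "M"  # initiator codon
    return "".join(aas)


# ---------------------------------------------------------------------------
# HMMER3 domtblout
# ---------------------------------------------------------------------------

def parse_domtblout(
    path,
    domain_map: dict[str, str],
    max_evalue: float = 0.01,
) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output (domtblout).

    Keeps rows whose independent (per-domain) E-value is <= ``max_evalue`` and
    whose query (HMM) name is in ``domain_map``; drops the rest and logs the
    dropped count. ``domain_map`` maps HMM query names to canonical domain
    role names.
    """
    hits: list[DomainHit] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split(None, 22)
            if len(cols) < 23:
                raise ValueError(f"{path}: malformed domtblout row at line {lineno}")
            try:
                target = cols[0]
                query = cols[3]
                i_evalue = float(cols[12])
                score = float(cols[13])
                ali_from = int(cols[17])
                ali_to = int(cols[18])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed domtblout row at line {lineno}: {exc}"
                ) from None
            if i_evalue > max_evalue or query not in domain_map:
                dropped += 1
                continue
            hits.append(
                DomainHit(
                    target_id=target,
                    domain_name=domain_map[query],
                    ali_start=ali_from,
                    ali_end=ali_to,
                    score=score,
                    evalue=i_evalue,
                )
            )
    logger.info("parse_domtblout: kept %d hits, dropped %d rows", len(hits), dropped)
    return hits


def project_hits(
    hits: Iterable[DomainHit],
    gene_locations: dict[str, GenomicInterval],
) -> list[DomainHit]:
    """Attach genomic intervals to domain hits given their genes' locations.

    Residue coordinates on the protein are projected onto the gene's coding
    span; hits on targets with unknown location are returned unprojected.
    """
    projected = []
    for h in hits:
        gene = gene_locations.get(h.target_id)
        if gene is None:
            projected.append(h)
            continue
        if gene.strand == "+":
            gstart = gene.start + 3 * (h.ali_start - 1)
            gend = gene.start + 3 * h.ali_end - 1
        else:
            gend = gene.end - 3 * (h.ali_start - 1)
            gstart = gene.end - 3 * h.ali_end + 1
        projected.append(
            DomainHit(
                target_id=h.target_id,
                domain_name=h.domain_name,
                ali_start=h.ali_start,
                ali_end=h.ali_end,
                score=h.score,
                evalue=h.evalue,
                genome_interval=GenomicInterval(gene.genome_id, gstart, gend, gene.strand),
            )
        )
    return projected


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(rows: Iterable[tuple], path) -> None:
    """Write (seqid, source, type, start, end, score, strand, attributes) rows as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, score, strand, attrs in rows:
            score_s = "." if score is None else f"{score:g}"
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score_s}\t{strand}\t.\t{attrs}\n"
            )
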