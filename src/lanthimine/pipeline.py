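"""Pipeline orchestration: mine -> topology -> stats, plus synthetic data.

Each ``run_*`` function is deterministic given its inputs and writes plain
tabular/JSON outputs; the click CLI in :mod:`lanthimine.cli` is a thin wrapper
over these.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import mining, peptidestats, synthdata, topology
from .seqio import (
    GenomicInterval,
    ProteinSequence,
    parse_domtblout,
    parse_location,
    project_hits,
    read_fasta,
    scan_orfs,
    write_fasta,
    write_gff3,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PipelineConfig:
    max_gap: int = 10_000
    max_orf_aa: int = 100
    max_evalue: float = 0.01
    identity_cutoff: float = 0.5
    min_support: int = 2
    labionin_mode: str = "all_cys"
    min_gap: int = 3
    domain_config: dict = field(
        default_factory=lambda: dict(mining.DEFAULT_DOMAIN_CONFIG)
    )
    seed: int = 0


# ---------------------------------------------------------------------------
# mine
# ---------------------------------------------------------------------------

def run_mine(
    genome_path,
    domtbl_path,
    proteins_path,
    out_dir,
    config: PipelineConfig | None = None,
) -> dict:
    """Mine candidate lanthipeptide precursors near cyclase clusters.

    Reads a genome FASTA, externally produced HMMER3 domtblout hits, and the
    searched proteins FASTA (whose descriptions carry ``loc=`` genomic
    locations used to project domain hits). Writes ``precursors.tsv``,
    ``clusters.gff3`` and ``summary.json`` into ``out_dir`` and returns the
    summary dict.
    """
    cfg = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genomes = read_fasta(genome_path, "dna")
    proteins = read_fasta(proteins_path, "protein")
    locations = {}
    protein_by_id = {}
    for p in proteins:
        protein_by_id[p.id] = p
        loc = parse_location(p.description)
        if loc is not None:
            locations[p.id] = loc

    domain_map = {name: name for name in cfg.domain_config}
    hits = project_hits(
        parse_domtblout(domtbl_path, domain_map, cfg.max_evalue), locations
    )

    rows = []
    gff_rows = []
    label_counts: dict[str, int] = {}
    n_clusters_total = 0
    n_unclustered = 0
    for genome in genomes:
        orfs = scan_orfs(genome, max_len_aa=cfg.max_orf_aa)
        candidates = mining.filter_precursor_candidates(orfs, cfg.max_orf_aa)
        features = [
            mining.ClusterFeature(
                feature_id=h.target_id,
                interval=h.genome_interval,
                kind="domain",
                domain_name=h.domain_name,
            )
            for h in hits
            if h.genome_interval is not None
            and h.genome_interval.genome_id == genome.id
        ]
        clusters = mining.build_clusters(
            features, candidates, cfg.max_gap, cfg.domain_config,
            cluster_prefix=f"{genome.id}|cluster",
        )
        n_clusters_total += len(clusters)
        cluster_by_id = {c.cluster_id: c for c in clusters}

        triads = {}
        for c in clusters:
            for cyc in c.features_in_category("cyclase", cfg.domain_config):
                prot = protein_by_id.get(cyc.feature_id)
                if prot is None:
                    triads[cyc.feature_id] = "Unk"
                else:
                    hit = next(h for h in hits if h.target_id == cyc.feature_id)
                    region = prot.residues[hit.ali_start - 1 : hit.ali_end]
                    triads[cyc.feature_id], _ = mining.classify_triad(region)

        for cand in candidates:
            if cand.cluster_id is None:
                n_unclustered += 1
                continue
            cluster = cluster_by_id[cand.cluster_id]
            assignment, nearest_cyc, nearest_deh = mining.assign_synthetase_for_candidate(
                cand, cluster, triads, cfg.domain_config
            )
            label_counts[assignment.label] = label_counts.get(assignment.label, 0) + 1
            rows.append(
                {
                    "genome": genome.id,
                    "orf_id": cand.orf.orf_id,
                    "start": cand.orf.start,
                    "end": cand.orf.end,
                    "strand": cand.orf.strand,
                    "peptide": cand.peptide.residues,
                    "cluster": cand.cluster_id,
                    "synthetase_label": assignment.label,
                    "roman_type": assignment.roman_type or "",
                    "nearest_cyclase": nearest_cyc.feature_id,
                    "nearest_dehydratase": nearest_deh.feature_id if nearest_deh else "",
                }
            )
        for c in clusters:
            span = c.span
            gff_rows.append(
                (genome.id, "lanthimine", "cluster", span.start, span.end, None, "+",
                 f"ID={c.cluster_id}")
            )
            for m in c.members:
                ftype = "precursor" if m.kind == "precursor" else (
                    "cyclase"
                    if cfg.domain_config.get(m.domain_name) == "cyclase"
                    else "dehydratase"
                    if mining.DEHYDRATASE_CLASS_BY_CATEGORY.get(
                        cfg.domain_config.get(m.domain_name, "")
                    )
                    else "domain"
                )
                gff_rows.append(
                    (genome.id, "lanthimine", ftype, m.interval.start, m.interval.end,
                     None, m.interval.strand,
                     f"ID={m.feature_id};cluster_id={c.cluster_id}")
                )

    df = pd.DataFrame(
        rows,
        columns=[
            "genome", "orf_id", "start", "end", "strand", "peptide", "cluster",
            "synthetase_label", "roman_type", "nearest_cyclase", "nearest_dehydratase",
        ],
    )
    df.to_csv(out_dir / "precursors.tsv", sep="\t", index=False)
    write_gff3(gff_rows, out_dir / "clusters.gff3")
    summary = {
        "n_genomes": len(genomes),
        "n_clusters": n_clusters_total,
        "n_precursors": len(rows),
        "n_unclustered_candidates": n_unclustered,
        "synthetase_counts": dict(sorted(label_counts.items())),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def run_topology(
    peptides_path,
    out_path,
    known_codes_path=None,
    labionin_mode: str = "all_cys",
    min_gap: int = 3,
    min_support: int = 2,
    on_core: bool = False,
) -> pd.DataFrame:
    """Predict bridging topologies for a peptide FASTA and write a TSV.

    ``on_core`` predicts on the core peptide when a leader/core split is
    found, else on the whole precursor.
    """
    peptides = read_fasta(peptides_path, "protein")
    known: set[str] = set()
    if known_codes_path:
        with open(known_codes_path) as fh:
            known = {line.strip() for line in fh if line.strip()}

    rows = []
    codes = []
    for pep in peptides:
        target = pep
        if on_core:
            split = peptidestats.split_leader_core(pep)
            if split is not None:
                target = split.core
        bridges = topology.predict_bridges(
            target, labionin_mode=labionin_mode, min_gap=min_gap
        )
        code = str(topology.encode_topology(bridges, target))
        codes.append(code)
        rows.append(
            {
                "id": pep.id,
                "code": code,
                "n_bridges": topology.count_bridges(bridges),
                "n_labionin": len(bridges.labionin_units),
                "n_free_cys": len(bridges.free_cys),
                "n_crossings": topology.count_crossings(bridges),
                "novel_flag": code not in known,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_path, sep="\t", index=False)
    tally = topology.tally_topologies(codes, known, min_support=min_support)
    tally_path = Path(str(out_path)).with_suffix(".tally.tsv")
    tally.to_csv(tally_path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------

def run_stats(peptides_path, out_dir) -> dict:
    """Leader/core table, per-amino-acid positional correlations, enrichment report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    peptides = read_fasta(peptides_path, "protein")

    split_rows = []
    for pep in peptides:
        split = peptidestats.split_leader_core(pep)
        if split is None:
            split_rows.append(
                {"id": pep.id, "leader": "", "core": pep.residues,
                 "charge_leader": "", "charge_core": peptidestats.net_charge(pep),
                 "kd_leader": "", "kd_core": peptidestats.mean_hydrophobicity(pep)}
            )
        else:
            split_rows.append(
                {
                    "id": pep.id,
                    "leader": split.leader.residues,
                    "core": split.core.residues,
                    "charge_leader": peptidestats.net_charge(split.leader),
                    "charge_core": peptidestats.net_charge(split.core),
                    "kd_leader": peptidestats.mean_hydrophobicity(split.leader),
                    "kd_core": peptidestats.mean_hydrophobicity(split.core),
                }
            )
    pd.DataFrame(split_rows).to_csv(out_dir / "leader_core.tsv", sep="\t", index=False)

    corr_rows = []
    for target in list(AA20) + ["hydrophobicity", "charge"]:
        pc = peptidestats.positional_correlation(peptides, target)
        corr_rows.append({"target": target, "r": pc.r, "n": pc.n})
    pd.DataFrame(corr_rows).to_csv(
        out_dir / "positional_correlation.tsv", sep="\t", index=False
    )

    single = [p for p in peptides if p.residues.count("C") == 1]
    other = [p for p in peptides if p.residues.count("C") != 1]
    report: dict = {"n_peptides": len(peptides), "n_single_cysteine": len(single)}
    if single and other:
        rate_a, rate_b, ratio = peptidestats.dihistidine_rate_ratio(single, other)
        report["dihistidine"] = {
            "rate_single_cys": rate_a,
            "rate_other": rate_b,
            "ratio": None if ratio != ratio else ("inf" if ratio == float("inf") else ratio),
        }
    obs, exp = peptidestats.motif_expected_count(peptides, "CG")
    report["cg_motif"] = {"observed": obs, "expected": exp}
    with open(out_dir / "enrichment.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# synth
# ---------------------------------------------------------------------------

def run_synth(config: synthdata.SynthConfig, out_dir) -> synthdata.TruthTable:
    """Generate a synthetic genome bundle (FASTA, proteins, domtblout, truth, config)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, truth, domtbl, proteins = synthdata.generate_genome(config)
    write_fasta([genome], out_dir / "genome.fasta")
    write_fasta(proteins, out_dir / "proteins.fasta")
    (out_dir / "hits.domtblout").write_text(domtbl)
    truth.to_tsv(out_dir / "truth.tsv")
    config.to_yaml(out_dir / "config.yaml")
    precursors = [
        ProteinSequence(id=r["id"], residues=r["peptide"])
        for r in truth.precursors.to_dict("records")
    ]
    write_fasta(precursors, out_dir / "precursors.fasta")
    return truth
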