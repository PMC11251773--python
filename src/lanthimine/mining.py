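"""Precursor candidate filtering, gene-cluster assembly and synthetase classing.

A candidate precursor is a short ORF (<= 100 aa) with at least one Cys, at
least as many Ser+Thr as Cys, and its last Cys strictly inside the C-terminal
third of the peptide. Clusters are single-linkage chains of domain-bearing
features and candidates along the genome with inter-feature gaps of at most
10 kb, retained only when they contain a cyclase hit. A cluster's synthetase
is named by its dehydratase class (B = LanB-related, D = DUF4135, L =
lyase/kinase) crossed with its cyclase zinc-binding triad (CCH / CCC / Unk),
with the five literature combinations also carrying Roman type numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import DomainHit, GenomicInterval, OrfRecord, ProteinSequence

# Editable 15-domain configuration: HMM role name -> category. The categories
# drive clustering (cyclase requirement) and dehydratase classing; accessory
# domains extend clusters but decide nothing.
DEFAULT_DOMAIN_CONFIG: dict[str, str] = {
    "LANC_like": "cyclase",
    # dehydratase-associated
    "Lant_dehydr_N": "dehydratase_B",
    "Lant_dehydr_C": "dehydratase_B",
    "SpaB_C": "dehydratase_B",
    "DUF4135": "dehydratase_D",
    "Lyase": "dehydratase_L",
    "Kinase": "dehydratase_L_accessory",  # always accompanies the lyase
    "Flavoprotein": "dehydratase_accessory",
    # peptidases
    "Peptidase_C39": "peptidase",
    "Peptidase_S8": "peptidase",
    # transporter
    "ABC_membrane": "transporter",
    # two-component systems
    "HisKA": "two_component",
    "HATPase_c": "two_component",
    "Response_reg": "two_component",
    "Trans_reg_C": "two_component",
}

DEHYDRATASE_CLASS_BY_CATEGORY = {
    "dehydratase_B": "B",
    "dehydratase_D": "D",
    "dehydratase_L": "L",
}

ROMAN_TYPE = {
    ("B", "CCH"): "I",
    ("D", "CCH"): "II",
    ("D", "CCC"): "IIa",
    ("L", "Unk"): "III",
    ("L", "CCH"): "IV",
}


@dataclass
class PrecursorCandidate:
    orf: OrfRecord
    n_cys: int
    n_ser: int
    n_thr: int
    last_cys_pos: int
    cluster_id: str | None = None

    @property
    def peptide(self) -> ProteinSequence:
        return self.orf.peptide

    @property
    def interval(self) -> GenomicInterval:
        return self.orf.interval


@dataclass(frozen=True)
class ClusterFeature:
    """A located cluster member: a domain hit or a precursor candidate."""

    feature_id: str
    interval: GenomicInterval
    kind: str  # "domain" | "precursor"
    domain_name: str | None = None


@dataclass
class GeneCluster:
    cluster_id: str
    genome_id: str
    members: list = field(default_factory=list)  # ClusterFeature, ordered by start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.genome_id,
            min(m.interval.start for m in self.members),
            max(m.interval.end for m in self.members),
            "+",
        )

    def domain_features(self, config: dict[str, str] | None = None) -> list[ClusterFeature]:
        return [m for m in self.members if m.kind == "domain"]

    def features_in_category(self, category: str, config: dict[str, str]) -> list[ClusterFeature]:
        return [
            m
            for m in self.members
            if m.kind == "domain" and config.get(m.domain_name) == category
        ]

    def has_cyclase(self, config: dict[str, str]) -> bool:
        return bool(self.features_in_category("cyclase", config))

    def dehydratase_classes(self, config: dict[str, str]) -> set[str]:
        out = set()
        for m in self.members:
            if m.kind != "domain":
                continue
            cls = DEHYDRATASE_CLASS_BY_CATEGORY.get(config.get(m.domain_name, ""))
            if cls:
                out.add(cls)
        return out


@dataclass(frozen=True)
class SynthetaseAssignment:
    dehydratase_class: str  # B | D | L | none
    triad: str  # CCH | CCC | Unk
    label: str
    roman_type: str | None

    def __post_init__(self):
        if self.label != f"{self.dehydratase_class}-{self.triad}":
            raise ValueError("label inconsistent with class and triad")


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

def filter_precursor_candidates(
    orfs: Iterable[OrfRecord],
    max_len_aa: int = 100,
) -> list[PrecursorCandidate]:
    """Keep exactly the ORFs satisfying the precursor composition rules.

    Length <= max_len_aa; #Cys >= 1; #Ser + #Thr >= #Cys; and the last Cys
    strictly past floor(2L/3) (the C-terminal third, where the modifiable
    core is expected).
    """
    out = []
    for orf in orfs:
        pep = orf.peptide.residues
        L = len(pep)
        if L > max_len_aa:
            continue
        n_cys = pep.count("C")
        if n_cys < 1:
            continue
        n_ser, n_thr = pep.count("S"), pep.count("T")
        if n_ser + n_thr < n_cys:
            continue
        last_cys = pep.rfind("C") + 1
        if last_cys <= (2 * L) // 3:
            continue
        out.append(
            PrecursorCandidate(
                orf=orf,
                n_cys=n_cys,
                n_ser=n_ser,
                n_thr=n_thr,
                last_cys_pos=last_cys,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two intervals' closest edges; 0 when they overlap."""
    if a.end < b.start:
        return b.start - a.end - 1
    if b.end < a.start:
        return a.start - b.end - 1
    return 0


def build_clusters(
    features: Sequence[ClusterFeature],
    candidates: Sequence[PrecursorCandidate],
    max_gap: int = 10_000,
    domain_config: dict[str, str] | None = None,
    cluster_prefix: str = "cluster",
) -> list[GeneCluster]:
    """Single-linkage chaining of domain features and candidates along a genome.

    Members are sorted by start; a new chain begins whenever the gap to the
    previous member exceeds ``max_gap`` (a gap of exactly ``max_gap`` keeps
    the chain). Chains lacking a cyclase hit are discarded; candidates inside
    retained chains receive that chain's cluster_id.
    """
    config = DEFAULT_DOMAIN_CONFIG if domain_config is None else domain_config
    cand_features = {
        id(c): ClusterFeature(c.orf.orf_id, c.interval, "precursor") for c in candidates
    }
    all_feats = list(features) + list(cand_features.values())
    if not all_feats:
        return []
    genomes = {f.interval.genome_id for f in all_feats}
    if len(genomes) > 1:
        raise ValueError(f"features from mixed genomes: {sorted(genomes)}")
    genome_id = genomes.pop()

    all_feats.sort(key=lambda f: (f.interval.start, f.interval.end))
    chains: list[list[ClusterFeature]] = [[all_feats[0]]]
    chain_end = all_feats[0].interval.end
    for f in all_feats[1:]:
        gap = f.interval.start - chain_end - 1
        if gap > max_gap:
            chains.append([f])
            chain_end = f.interval.end
        else:
            chains[-1].append(f)
            chain_end = max(chain_end, f.interval.end)

    clusters = []
    n = 0
    feat_to_cluster: dict[str, str] = {}
    for chain in chains:
        cluster = GeneCluster(f"{cluster_prefix}_{n + 1}", genome_id, chain)
        if not cluster.has_cyclase(config):
            continue
        n += 1
        cluster.cluster_id = f"{cluster_prefix}_{n}"
        clusters.append(cluster)
        for m in chain:
            if m.kind == "precursor":
                feat_to_cluster[m.feature_id] = cluster.cluster_id
    for c in candidates:
        c.cluster_id = feat_to_cluster.get(c.orf.orf_id)
    return clusters


def assign_nearest(
    candidate_interval: GenomicInterval,
    features: Sequence[ClusterFeature],
) -> ClusterFeature:
    """The feature whose interval is genomically closest to the candidate.

    Distance is the gap between closest interval edges (0 when overlapping);
    ties go to the upstream feature (smaller start).
    """
    if not features:
        raise ValueError("assign_nearest: empty feature list")
    return min(
        features,
        key=lambda f: (_interval_gap(candidate_interval, f.interval), f.interval.start),
    )


# ---------------------------------------------------------------------------
# Synthetase classification
# ---------------------------------------------------------------------------

def classify_triad(
    cyclase_region,
    search_window: int = 150,
) -> tuple[str, int | None]:
    """Call the cyclase zinc-binding triad from its domain-match region.

    Looks for CHG (-> CCH triad) or CCG (-> CCC triad) within the final
    ``search_window`` residues, requiring at least one additional Cys
    upstream of the motif within the region; the last (most C-terminal) match
    wins. Returns (triad, 1-based motif position) or ("Unk", None).
    """
    seq = cyclase_region if isinstance(cyclase_region, str) else cyclase_region.residues
    window_start = max(0, len(seq) - search_window)
    best: tuple[str, int] | None = None
    for k in range(window_start, len(seq) - 2):
        tri = seq[k : k + 3]
        if tri == "CHG":
            triad = "CCH"
        elif tri == "CCG":
            triad = "CCC"
        else:
            continue
        if "C" not in seq[:k]:  # the triad needs another Cys upstream
            continue
        best = (triad, k + 1)
    if best is None:
        return "Unk", None
    return best


def classify_synthetase(dehydratase_class: str, triad: str) -> SynthetaseAssignment:
    """Name a synthetase combination (e.g. B-CCH = Type I)."""
    if dehydratase_class not in ("B", "D", "L", "none"):
        raise ValueError(f"unknown dehydratase class {dehydratase_class!r}")
    if triad not in ("CCH", "CCC", "Unk"):
        raise ValueError(f"unknown triad {triad!r}")
    return SynthetaseAssignment(
        dehydratase_class=dehydratase_class,
        triad=triad,
        label=f"{dehydratase_class}-{triad}",
        roman_type=ROMAN_TYPE.get((dehydratase_class, triad)),
    )


def assign_synthetase_for_candidate(
    candidate: PrecursorCandidate,
    cluster: GeneCluster,
    triads: dict[str, str],
    domain_config: dict[str, str] | None = None,
) -> tuple[SynthetaseAssignment, ClusterFeature | None, ClusterFeature | None]:
    """Resolve a candidate's synthetase label within its cluster.

    The triad comes from the chromosomally closest cyclase (``triads`` maps
    cyclase feature ids to triad calls); the dehydratase class from the
    cluster's domain content, resolved per-candidate via the nearest
    class-defining dehydratase when the cluster mixes classes. Returns the
    assignment plus the nearest cyclase and dehydratase features.
    """
    config = DEFAULT_DOMAIN_CONFIG if domain_config is None else domain_config
    cyclases = cluster.features_in_category("cyclase", config)
    nearest_cyc = assign_nearest(candidate.interval, cyclases)
    triad = triads.get(nearest_cyc.feature_id, "Unk")

    dehydratases = [
        m
        for m in cluster.members
        if m.kind == "domain"
        and DEHYDRATASE_CLASS_BY_CATEGORY.get(config.get(m.domain_name, ""))
    ]
    nearest_deh = None
    if not dehydratases:
        cls = "none"
    else:
        classes = cluster.dehydratase_classes(config)
        nearest_deh = assign_nearest(candidate.interval, dehydratases)
        if len(classes) == 1:
            cls = classes.pop()
        else:
            cls = DEHYDRATASE_CLASS_BY_CATEGORY[config[nearest_deh.domain_name]]
    return classify_synthetase(cls, triad), nearest_cyc, nearest_deh
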