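"""Precursor filtering, cluster chaining, triad and synthetase classification."""

import pytest

from lanthimine import mining
from lanthimine.seqio import GenomicInterval, OrfRecord, ProteinSequence


def orf(start, peptide, genome="g", strand="+"):
    end = start + 3 * (len(peptide) + 1) - 1
    return OrfRecord(
        genome_id=genome,
        start=start,
        end=end,
        strand=strand,
        peptide=ProteinSequence(id=f"{genome}|{start}", residues=peptide),
        frame=0,
    )


def feat(fid, start, end, domain=None, genome="g"):
    return mining.ClusterFeature(
        feature_id=fid,
        interval=GenomicInterval(genome, start, end, "+"),
        kind="domain" if domain else "precursor",
        domain_name=domain,
    )


# ---------------------------------------------------------------------------
# composition filter
# ---------------------------------------------------------------------------

class TestFilter:
    @pytest.mark.parametrize(
        "peptide, accepted",
        [
            ("MASTC", True),  # 2 S/T >= 1 C, last C at 5 > floor(10/3)
            ("MACAA", False),  # last C at 3 <= floor(10/3) = 3
            ("MASTA", False),  # no Cys
            ("MACTC", False),  # 1 S/T < 2 C
            ("MATCC", False),  # 1 S/T < 2 C
            ("MSTCC", True),  # 2 >= 2, last C at 5
            ("M" + "A" * 96 + "STC", True),  # length 100 boundary
            ("M" + "A" * 97 + "STC", False),  # length 101 rejected
        ],
    )
    def test_composition_rules(self, peptide, accepted):
        got = mining.filter_precursor_candidates([orf(1, peptide)])
        assert bool(got) == accepted

    def test_idempotent_and_order_preserving(self):
        orfs = [orf(1, "MASTC"), orf(100, "MSTCC"), orf(200, "MACAA")]
        first = mining.filter_precursor_candidates(orfs)
        again = mining.filter_precursor_candidates([c.orf for c in first])
        assert [c.orf.start for c in first] == [1, 100]
        assert [c.orf.start for c in again] == [1, 100]

    def test_candidate_fields(self):
        (c,) = mining.filter_precursor_candidates([orf(1, "MASTC")])
        assert (c.n_cys, c.n_ser, c.n_thr, c.last_cys_pos) == (1, 1, 1, 5)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClusters:
    def test_chain_breaks_beyond_max_gap_and_requires_cyclase(self):
        features = [
            feat("cyc", 1000, 2000, "LANC_like"),
            feat("lanb", 5000, 6000, "Lant_dehydr_N"),
            feat("tr", 20000, 21000, "ABC_membrane"),
        ]
        clusters = mining.build_clusters(features, [], max_gap=10_000)
        assert len(clusters) == 1
        assert {m.feature_id for m in clusters[0].members} == {"cyc", "lanb"}

    def test_gap_exactly_max_gap_is_inclusive(self):
        features = [
            feat("cyc", 1, 100, "LANC_like"),
            feat("lanb", 10_101, 10_200, "Lant_dehydr_N"),  # gap exactly 10000
        ]
        clusters = mining.build_clusters(features, [], max_gap=10_000)
        assert len(clusters) == 1 and len(clusters[0].members) == 2
        features[1] = feat("lanb", 10_102, 10_200, "Lant_dehydr_N")  # gap 10001
        clusters = mining.build_clusters(features, [], max_gap=10_000)
        assert len(clusters) == 1 and len(clusters[0].members) == 1

    def test_candidate_in_cluster_gets_cluster_id(self):
        features = [feat("cyc", 1000, 2000, "LANC_like")]
        cand = mining.filter_precursor_candidates([orf(5000, "MASTC")])
        clusters = mining.build_clusters(features, cand, max_gap=10_000)
        assert cand[0].cluster_id == clusters[0].cluster_id

    def test_candidate_outside_cluster_unassigned(self):
        features = [feat("cyc", 1000, 2000, "LANC_like")]
        cand = mining.filter_precursor_candidates([orf(50_000, "MASTC")])
        mining.build_clusters(features, cand, max_gap=10_000)
        assert cand[0].cluster_id is None

    def test_mixed_genomes_error(self):
        features = [
            feat("a", 1, 10, "LANC_like", genome="g1"),
            feat("b", 1, 10, "LANC_like", genome="g2"),
        ]
        with pytest.raises(ValueError, match="mixed genomes"):
            mining.build_clusters(features, [], max_gap=10_000)

    def test_gap_chain_respected_post_hoc(self):
        """Independent scan: consecutive members of a cluster never exceed max_gap."""
        features = [
            feat("cyc", 1000, 2000, "LANC_like"),
            feat("a", 4000, 4500, "Peptidase_C39"),
            feat("b", 9000, 9500, "ABC_membrane"),
        ]
        (cluster,) = mining.build_clusters(features, [], max_gap=10_000)
        members = sorted(cluster.members, key=lambda m: m.interval.start)
        for prev, nxt in zip(members, members[1:]):
            assert nxt.interval.start - prev.interval.end - 1 <= 10_000


# ---------------------------------------------------------------------------
# nearest-feature assignment
# ---------------------------------------------------------------------------

class TestAssignNearest:
    def test_picks_minimum_gap(self):
        cand = GenomicInterval("g", 100, 200, "+")
        a, b = feat("a", 300, 400, "X"), feat("b", 1000, 1100, "X")
        assert mining.assign_nearest(cand, [a, b]).feature_id == "a"

    def test_tie_goes_upstream(self):
        cand = GenomicInterval("g", 500, 600, "+")
        up, down = feat("up", 349, 449, "X"), feat("down", 651, 751, "X")
        assert mining.assign_nearest(cand, [down, up]).feature_id == "up"

    def test_overlap_is_distance_zero(self):
        cand = GenomicInterval("g", 500, 600, "+")
        over, near = feat("over", 550, 650, "X"), feat("near", 610, 620, "X")
        assert mining.assign_nearest(cand, [near, over]).feature_id == "over"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mining.assign_nearest(GenomicInterval("g", 1, 2, "+"), [])


# ---------------------------------------------------------------------------
# triad and synthetase labels
# ---------------------------------------------------------------------------

class TestTriad:
    def test_chg_motif_is_cch(self):
        triad, pos = mining.classify_triad("C" + "A" * 40 + "AACHGAA")
        assert triad == "CCH" and pos == 44

    def test_ccg_motif_is_ccc(self):
        triad, _ = mining.classify_triad("C" + "A" * 40 + "AACCGAA")
        assert triad == "CCC"

    def test_no_motif_is_unk(self):
        assert mining.classify_triad("AAAAAA") == ("Unk", None)

    def test_motif_without_upstream_cys_is_unk(self):
        assert mining.classify_triad("AAACHGAA")[0] == "Unk"

    def test_last_match_wins(self):
        triad, _ = mining.classify_triad("C" + "A" * 10 + "CHG" + "A" * 10 + "CCG")
        assert triad == "CCC"

    def test_motif_outside_window_ignored(self):
        seq = "C" + "ACHG" + "A" * 200
        assert mining.classify_triad(seq, search_window=150) == ("Unk", None)


class TestSynthetase:
    @pytest.mark.parametrize(
        "deh, triad, roman",
        [
            ("B", "CCH", "I"),
            ("D", "CCH", "II"),
            ("D", "CCC", "IIa"),
            ("L", "Unk", "III"),
            ("L", "CCH", "IV"),
            ("L", "CCC", None),
            ("B", "CCC", None),
            ("B", "Unk", None),
            ("D", "Unk", None),
        ],
    )
    def test_label_and_roman_type(self, deh, triad, roman):
        a = mining.classify_synthetase(deh, triad)
        assert a.label == f"{deh}-{triad}"
        assert a.roman_type == roman

    def test_mixed_dehydratase_cluster_resolved_by_nearest(self):
        features = [
            feat("cyc", 1000, 2000, "LANC_like"),
            feat("lanb", 3000, 4000, "Lant_dehydr_N"),
            feat("duf", 9000, 10_000, "DUF4135"),
        ]
        cands = mining.filter_precursor_candidates(
            [orf(4500, "MASTC"), orf(8500, "MASTC")]
        )
        (cluster,) = mining.build_clusters(features, cands, max_gap=10_000)
        triads = {"cyc": "CCH"}
        a1, _, deh1 = mining.assign_synthetase_for_candidate(cands[0], cluster, triads)
        a2, _, deh2 = mining.assign_synthetase_for_candidate(cands[1], cluster, triads)
        assert (a1.label, deh1.feature_id) == ("B-CCH", "lanb")
        assert (a2.label, deh2.feature_id) == ("D-CCH", "duf")

    def test_no_dehydratase_class_none(self):
        features = [feat("cyc", 1000, 2000, "LANC_like")]
        cands = mining.filter_precursor_candidates([orf(2500, "MASTC")])
        (cluster,) = mining.build_clusters(features, cands, max_gap=10_000)
        a, cyc, deh = mining.assign_synthetase_for_candidate(
            cands[0], cluster, {"cyc": "CCC"}
        )
        assert a.label == "none-CCC" and a.roman_type is None and deh is None
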