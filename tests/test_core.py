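"""SD network construction: parsing, region union, graph build, annotation."""

import networkx as nx
import numpy as np
import pytest

from sdupnet.core import (
    AlignmentRecord,
    build_duplicated_regions,
    build_network,
    cycle_census,
    detect_communities,
    flag_suspicious_edges,
    map_intervals_to_nodes,
    network_summary,
    parse_sd_annotation,
)

from conftest import make_records, net_from_rows

N_COLS = 27


def write_sd_table(path, rows):
    with open(path, "w") as fh:
        for ca, sa, ea, cb, sb, eb, ident in rows:
            cols = ["."] * N_COLS
            cols[0], cols[1], cols[2] = ca, str(sa), str(ea)
            cols[6], cols[7], cols[8] = cb, str(sb), str(eb)
            cols[26] = str(ident)
            fh.write("\t".join(cols) + "\n")


class TestParse:
    def test_valid_autosomal_rows(self, tmp_path):
        p = tmp_path / "sd.tsv"
        write_sd_table(
            p,
            [
                ("chr1", 0, 2000, "chr2", 0, 2000, 0.95),
                ("chr1", 5000, 7000, "chr1", 9000, 11000, 0.99),
                ("chr3", 100, 1200, "chr4", 100, 1200, 0.91),
            ],
        )
        records = parse_sd_annotation(p)
        assert len(records) == 3
        assert [r.id for r in records] == [0, 1, 2]
        assert records[1].identity == 0.99

    def test_sex_chromosomes_dropped(self, tmp_path):
        p = tmp_path / "sd.tsv"
        write_sd_table(
            p,
            [
                ("chrX", 0, 2000, "chr2", 0, 2000, 0.95),
                ("chr2", 0, 2000, "chrY", 0, 2000, 0.95),
                ("chr1", 0, 2000, "chr2", 0, 2000, 0.95),
            ],
        )
        assert len(parse_sd_annotation(p, drop_sex=True)) == 1
        assert len(parse_sd_annotation(p, drop_sex=False)) == 3

    def test_inverted_interval_errors_with_line(self, tmp_path):
        p = tmp_path / "sd.tsv"
        write_sd_table(p, [("chr1", 2000, 100, "chr2", 0, 2000, 0.95)])
        with pytest.raises(ValueError, match="line 1"):
            parse_sd_annotation(p)

    def test_unparseable_row_names_line(self, tmp_path):
        p = tmp_path / "sd.tsv"
        write_sd_table(p, [("chr1", 0, 2000, "chr2", 0, 2000, 0.95)])
        with open(p, "a") as fh:
            fh.write("garbage\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_sd_annotation(p)


class TestRegions:
    def test_overlapping_intervals_merge(self):
        records = make_records(
            [("chr1", 100, 2000, "chr9", 0, 1900, 0.95), ("chr1", 1500, 3000, "chr8", 0, 1500, 0.95)]
        )
        regions = build_duplicated_regions(records)
        chr1 = [r for r in regions if r.chrom == "chr1"]
        assert len(chr1) == 1
        assert (chr1[0].start, chr1[0].end) == (100, 3000)
        assert chr1[0].member_ids == {0, 1}

    def test_disjoint_and_bookended_stay_separate(self):
        records = make_records(
            [("chr1", 0, 1000, "chr9", 0, 1000, 0.95), ("chr1", 1000, 2000, "chr8", 0, 1000, 0.95)]
        )
        chr1 = [r for r in build_duplicated_regions(records) if r.chrom == "chr1"]
        assert len(chr1) == 2  # touching intervals are not merged

    def test_tandem_overlap_single_region(self):
        # overlapping copies of a tandem duplication collapse to one node
        records = make_records([("chr1", 0, 1500, "chr1", 1000, 2500, 0.98)])
        regions = build_duplicated_regions(records)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 2500)

    def test_union_invariants_random(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(120):
            s1, s2 = rng.integers(0, 50_000, size=2)
            rows.append(
                ("chr%d" % rng.integers(1, 4), int(s1), int(s1) + int(rng.integers(1000, 5000)),
                 "chr%d" % rng.integers(1, 4), int(s2), int(s2) + int(rng.integers(1000, 5000)), 0.95)
            )
        records = make_records(rows)
        regions = build_duplicated_regions(records)
        # union property: every member interval inside its region; maximality:
        # regions on a chromosome are disjoint and sorted
        ivals = []
        for rec in records:
            ivals.extend(rec.intervals())
        for reg in regions:
            covered = [iv for iv in ivals if iv[0] == reg.chrom and iv[1] < reg.end and iv[2] > reg.start]
            assert min(iv[1] for iv in covered) == reg.start
            assert max(iv[2] for iv in covered) == reg.end
        by_chrom = {}
        for reg in regions:
            by_chrom.setdefault(reg.chrom, []).append(reg)
        for regs in by_chrom.values():
            for a, b in zip(regs, regs[1:]):
                assert a.end <= b.start
        # idempotence: re-merging the region intervals reproduces the regions
        again = build_duplicated_regions(
            make_records([(r.chrom, r.start, r.end, r.chrom, r.start, r.end, 1.0) for r in regions])
        )
        assert [(r.chrom, r.start, r.end) for r in again] == [
            (r.chrom, r.start, r.end) for r in regions
        ]


class TestNetwork:
    def test_two_overlapping_duplications_three_nodes_three_edges(self):
        # two events; the second sources inside the first event's copy, so a
        # secondary alignment closes a triangle: 3 nodes, 3 edges
        net, regions, _ = net_from_rows(
            [
                ("chr1", 0, 2000, "chr1", 10_000, 12_000, 0.99),
                ("chr1", 10_000, 11_500, "chr2", 20_000, 21_500, 0.98),
                ("chr2", 20_000, 21_500, "chr1", 0, 1_500, 0.97),
            ]
        )
        assert net.number_of_nodes() == 3
        assert net.number_of_edges() == 3

    def test_self_loop_counted_not_edged(self):
        net, _, _ = net_from_rows([("chr1", 0, 1500, "chr1", 1000, 2500, 0.98)])
        assert net.number_of_nodes() == 1
        assert net.number_of_edges() == 0
        node = next(iter(net.nodes))
        assert net.nodes[node]["self_loop_count"] == 1

    def test_parallel_alignments_collapse(self):
        net, _, _ = net_from_rows(
            [
                ("chr1", 0, 2000, "chr2", 0, 2000, 0.95),
                ("chr1", 100, 1900, "chr2", 100, 1900, 0.99),
            ]
        )
        assert net.number_of_edges() == 1
        (u, v), = net.edges
        assert net.edges[u, v]["n_alignments"] == 2
        assert net.edges[u, v]["max_identity"] == 0.99
        assert net.nodes[u]["n_double_edges"] == 1
        assert net.nodes[v]["n_double_edges"] == 1

    def test_every_alignment_is_edge_or_self_loop(self, small_bundle):
        records = small_bundle.records()
        regions = build_duplicated_regions(records)
        net = build_network(regions, records)
        total = sum(d["n_alignments"] for _, _, d in net.edges(data=True))
        total += sum(net.nodes[n]["self_loop_count"] for n in net.nodes)
        assert total == len(records)

    def test_intrachromosomal_flag(self):
        net, _, _ = net_from_rows([("chr1", 0, 2000, "chr1", 9000, 11_000, 0.95)])
        (u, v), = net.edges
        assert net.edges[u, v]["intrachromosomal"]


class TestSummary:
    def test_two_disjoint_triangles(self):
        rows = []
        for base, chrom in ((0, "chr1"), (0, "chr2")):
            a, b, c = base, base + 10_000, base + 20_000
            rows += [
                (chrom, a, a + 1500, chrom, b, b + 1500, 0.95),
                (chrom, b, b + 1500, chrom, c, c + 1500, 0.95),
                (chrom, c, c + 1500, chrom, a, a + 1500, 0.95),
            ]
        net, _, _ = net_from_rows(rows)
        rep = network_summary(net)
        assert rep.n_nodes == 6 and rep.n_edges == 6 and rep.n_components == 2
        assert rep.giant_node_share == 50.0

    def test_single_node_report(self):
        net, _, _ = net_from_rows([("chr1", 0, 1500, "chr1", 1000, 2500, 0.98)])
        rep = network_summary(net)
        assert (rep.n_nodes, rep.n_edges, rep.n_components) == (1, 0, 1)

    def test_empty_network(self):
        rep = network_summary(nx.Graph())
        assert rep.n_nodes == 0 and rep.giant_node_share == 0.0

    def test_spanning_forest_edge_expectation(self, small_bundle):
        records = small_bundle.records()
        regions = build_duplicated_regions(records)
        net = build_network(regions, records)
        rep = network_summary(net)
        # forest size law: sum over components of (nodes - 1)
        assert rep.n_nodes - rep.n_components == sum(
            len(c) - 1 for c in nx.connected_components(net)
        )


class TestCommunities:
    def test_two_cliques_two_communities(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
        labels = detect_communities(g, seed=0)
        assert len(set(labels.values())) == 2

    def test_barbell_two_communities(self):
        # two K5s joined by one bridge edge: label propagation settles on the
        # two cliques (verified against the modular partition of this graph)
        g = nx.barbell_graph(5, 0)
        labels = detect_communities(g, seed=1)
        parts = {}
        for node, lab in labels.items():
            parts.setdefault(lab, set()).add(node)
        assert sorted(map(sorted, parts.values())) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]

    def test_relabeling_preserves_partition(self):
        g = nx.barbell_graph(5, 0)
        mapping = {i: 100 - i for i in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        lg = detect_communities(g, seed=2)
        lh = detect_communities(h, seed=2)
        parts_g = {frozenset(mapping[n] for n in g if lg[n] == lab) for lab in set(lg.values())}
        parts_h = {frozenset(n for n in h if lh[n] == lab) for lab in set(lh.values())}
        assert parts_g == parts_h

    def test_partition_covers_nodes_within_components(self, small_bundle):
        records = small_bundle.records()
        regions = build_duplicated_regions(records)
        net = build_network(regions, records)
        labels = detect_communities(net, seed=0)
        assert set(labels) == set(net.nodes)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(net)):
            for n in comp:
                comp_of[n] = ci
        for lab in set(labels.values()):
            comps = {comp_of[n] for n in labels if labels[n] == lab}
            assert len(comps) == 1  # communities never span components


class TestMapIntervals:
    def test_longest_overlap_wins(self):
        net, regions, _ = net_from_rows(
            [("chr1", 0, 1000, "chr1", 5000, 6000, 0.95)]
        )
        # interval overlapping first region by 300 bp, second by 800 bp
        got = map_intervals_to_nodes(net, [("chr1", 700, 5800)])
        a = [r for r in regions if r.start == 0][0]
        b = [r for r in regions if r.start == 5000][0]
        assert got[0]["node"] == b.id
        assert got[0]["overlap_bp"] == 800
        assert not got[0]["tie"]

    def test_no_overlap_unassigned(self):
        net, _, _ = net_from_rows([("chr1", 0, 1000, "chr1", 5000, 6000, 0.95)])
        got = map_intervals_to_nodes(net, [("chr2", 0, 1000)])
        assert got[0]["node"] is None

    def test_exact_tie_lowest_region(self):
        net, regions, _ = net_from_rows([("chr1", 0, 1000, "chr1", 5000, 6000, 0.95)])
        got = map_intervals_to_nodes(net, [("chr1", 800, 5200)])  # 200 bp each
        lowest = min(regions, key=lambda r: (r.chrom, r.start))
        assert got[0]["node"] == lowest.id
        assert got[0]["tie"]


class TestSuspicious:
    ROWS = [
        ("chr1", 0, 2000, "chr2", 50_000, 52_000, 0.95),
        ("chr1", 500, 2000, "chr3", 80_000, 81_500, 0.95),  # shares end=2000 on chr1
        ("chr1", 10_000, 12_000, "chr4", 1000, 3000, 0.95),
    ]

    def test_matching_breakpoint_flags_both_edges(self):
        net, _, records = net_from_rows(self.ROWS)
        flag_suspicious_edges(net, records, gaps=[])
        flags = {tuple(sorted(e)): net.edges[e]["suspicious"] for e in net.edges}
        assert sum(flags.values()) == 2  # the two edges sharing the breakpoint

    def test_gap_excuses_the_match(self):
        net, _, records = net_from_rows(self.ROWS)
        flag_suspicious_edges(net, records, gaps=[("chr1", 2000, 2100)], gap_pad_bp=50)
        assert not any(net.edges[e]["suspicious"] for e in net.edges)

    def test_tolerance_boundary(self):
        rows = [
            ("chr1", 0, 2000, "chr2", 50_000, 52_000, 0.95),
            ("chr1", 500, 2003, "chr3", 80_000, 81_503, 0.95),
        ]
        net, _, records = net_from_rows(rows)
        flag_suspicious_edges(net, records, tol_bp=2)
        assert not any(net.edges[e]["suspicious"] for e in net.edges)
        flag_suspicious_edges(net, records, tol_bp=3)
        assert all(net.edges[e]["suspicious"] for e in net.edges)


class TestCycleCensus:
    def test_triangle(self):
        g = nx.cycle_graph(3)
        rep = cycle_census(g)
        assert rep["cycles_by_length"][3] == 1
        assert all(v == 3 for v in rep["shortest_self_path"].values())

    def test_tree_has_no_cycles(self):
        g = nx.random_labeled_tree(12, seed=0)
        rep = cycle_census(g)
        assert sum(rep["cycles_by_length"].values()) == 0
        assert all(np.isinf(v) for v in rep["shortest_self_path"].values())

    def test_k4_chordless(self):
        # exhaustive: K4 has four 3-cycles and no chordless longer cycle
        rep = cycle_census(nx.complete_graph(4), max_len=6)
        assert rep["cycles_by_length"] == {3: 4, 4: 0, 5: 0, 6: 0}

    def test_max_len_validation(self):
        with pytest.raises(ValueError):
            cycle_census(nx.cycle_graph(3), max_len=2)
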