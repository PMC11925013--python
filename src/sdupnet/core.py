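"""Construction and annotation of the segmental-duplication (SD) network.

A segmental duplication is annotated as a pairwise alignment between two
genomic intervals (>= 1 kbp, >= 90% identity).  Overlapping alignment
intervals are merged into *duplicated regions*; the SD network is the simple
undirected graph with duplicated regions as nodes and an edge wherever at
least one alignment connects two regions.  Self-loops (both intervals of an
alignment inside one region) and parallel alignments are trimmed but their
multiplicities are retained as node/edge attributes, because they are
informative features of actively duplicating loci.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}

__all__ = [
    "AlignmentRecord",
    "DuplicatedRegion",
    "SummaryReport",
    "ColumnMap",
    "parse_sd_annotation",
    "build_duplicated_regions",
    "build_network",
    "network_summary",
    "detect_communities",
    "map_intervals_to_nodes",
    "flag_suspicious_edges",
    "cycle_census",
    "write_network_tables",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise SD alignment: two genomic intervals plus fraction identity."""

    id: int
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    identity: float

    def __post_init__(self) -> None:
        if self.end_a <= self.start_a or self.end_b <= self.start_b:
            raise ValueError(
                f"alignment {self.id}: inverted or empty interval "
                f"({self.chrom_a}:{self.start_a}-{self.end_a}, "
                f"{self.chrom_b}:{self.start_b}-{self.end_b})"
            )
        if self.start_a < 0 or self.start_b < 0:
            raise ValueError(f"alignment {self.id}: negative coordinate")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"alignment {self.id}: identity {self.identity} outside [0,1]")

    def intervals(self) -> tuple[tuple[str, int, int], tuple[str, int, int]]:
        return (self.chrom_a, self.start_a, self.end_a), (self.chrom_b, self.start_b, self.end_b)


@dataclass
class DuplicatedRegion:
    """Maximal union of mutually overlapping alignment intervals (one node)."""

    id: int
    chrom: str
    start: int
    end: int
    member_ids: set = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class SummaryReport:
    n_nodes: int
    n_edges: int
    n_components: int
    giant_nodes: int
    giant_edges: int
    giant_node_share: float
    giant_edge_share: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class ColumnMap:
    """0-based column indices into a tab-delimited SD annotation.

    Defaults follow the UCSC genomicSuperDups table exported without the
    leading ``bin`` column: chrom/chromStart/chromEnd in columns 0-2, the
    partner interval (otherChrom/otherStart/otherEnd) in columns 6-8 and
    fracMatch in column 26.
    """

    chrom_a: int = 0
    start_a: int = 1
    end_a: int = 2
    chrom_b: int = 6
    start_b: int = 7
    end_b: int = 8
    identity: int = 26


def parse_sd_annotation(
    path: str | Path,
    drop_sex: bool = True,
    colmap: ColumnMap | None = None,
) -> list[AlignmentRecord]:
    """Read a tab-delimited SD annotation into alignment records.

    Rows with either interval on a sex chromosome are removed when
    ``drop_sex`` is set (the network is built from autosomal duplications
    only).  Record ids are assigned by input order among the kept rows,
    so parsing is deterministic.
    """
    colmap = colmap or ColumnMap()
    records: list[AlignmentRecord] = []
    rid = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                chrom_a = parts[colmap.chrom_a]
                chrom_b = parts[colmap.chrom_b]
                start_a = int(parts[colmap.start_a])
                end_a = int(parts[colmap.end_a])
                start_b = int(parts[colmap.start_b])
                end_b = int(parts[colmap.end_b])
                identity = float(parts[colmap.identity])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: unparseable row at line {lineno}: {exc}") from exc
            if drop_sex and (chrom_a in SEX_CHROMS or chrom_b in SEX_CHROMS):
                continue
            try:
                rec = AlignmentRecord(rid, chrom_a, start_a, end_a, chrom_b, start_b, end_b, identity)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
            rid += 1
    return records


def build_duplicated_regions(records: Sequence[AlignmentRecord]) -> list[DuplicatedRegion]:
    """Merge all alignment intervals into maximal overlapping unions.

    Each record contributes both of its intervals.  Intervals overlapping by
    at least 1 bp are merged transitively; intervals that merely touch
    (bookended) are kept separate.  Output is sorted by (chrom, start) and
    region ids follow that order.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom_a, []).append((rec.start_a, rec.end_a, rec.id))
        by_chrom.setdefault(rec.chrom_b, []).append((rec.start_b, rec.end_b, rec.id))

    regions: list[DuplicatedRegion] = []
    for chrom in sorted(by_chrom):
        ivals = sorted(by_chrom[chrom])
        cur_start, cur_end, members = ivals[0][0], ivals[0][1], {ivals[0][2]}
        for start, end, rid in ivals[1:]:
            if start < cur_end:  # >=1 bp overlap; bookended intervals not merged
                cur_end = max(cur_end, end)
                members.add(rid)
            else:
                regions.append(DuplicatedRegion(-1, chrom, cur_start, cur_end, members))
                cur_start, cur_end, members = start, end, {rid}
        regions.append(DuplicatedRegion(-1, chrom, cur_start, cur_end, members))

    for i, reg in enumerate(regions):
        reg.id = i
    return regions


class _RegionIndex:
    """Per-chromosome sorted lookup from an interval to its covering region."""

    def __init__(self, regions: Sequence[DuplicatedRegion]):
        self.by_chrom: dict[str, tuple[list[int], list[int], list[DuplicatedRegion]]] = {}
        for reg in regions:
            self.by_chrom.setdefault(reg.chrom, ([], [], []))
        for reg in sorted(regions, key=lambda r: (r.chrom, r.start)):
            starts, ends, regs = self.by_chrom[reg.chrom]
            starts.append(reg.start)
            ends.append(reg.end)
            regs.append(reg)

    def find_containing(self, chrom: str, start: int, end: int) -> DuplicatedRegion:
        entry = self.by_chrom.get(chrom)
        if entry is not None:
            starts, ends, regs = entry
            i = bisect_right(starts, start) - 1
            if i >= 0 and ends[i] >= end:
                return regs[i]
        raise ValueError(
            f"internal inconsistency: interval {chrom}:{start}-{end} "
            "is not contained in any duplicated region"
        )

    def overlapping(self, chrom: str, start: int, end: int) -> list[DuplicatedRegion]:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, regs = entry
        lo = bisect_left(starts, start)
        # step back while previous regions may still reach into [start, end)
        while lo > 0 and ends[lo - 1] > start:
            lo -= 1
        out = []
        for i in range(lo, len(regs)):
            if starts[i] >= end:
                break
            if ends[i] > start:
                out.append(regs[i])
        return out


def build_network(
    regions: Sequence[DuplicatedRegion],
    records: Sequence[AlignmentRecord],
) -> nx.Graph:
    """Build the simple SD network over duplicated regions.

    An alignment with both intervals inside the same region becomes a
    self-loop count on that node (no edge).  Parallel alignments between the
    same pair of regions collapse to one edge carrying ``n_alignments``,
    ``max_identity`` and the list of contributing alignment ids.
    """
    index = _RegionIndex(regions)
    net = nx.Graph()
    for reg in regions:
        net.add_node(
            reg.id,
            region=reg,
            chrom=reg.chrom,
            start=reg.start,
            end=reg.end,
            self_loop_count=0,
            n_double_edges=0,
        )
    for rec in records:
        (ca, sa, ea), (cb, sb, eb) = rec.intervals()
        ra = index.find_containing(ca, sa, ea)
        rb = index.find_containing(cb, sb, eb)
        if ra.id == rb.id:
            net.nodes[ra.id]["self_loop_count"] += 1
            continue
        u, v = (ra.id, rb.id) if ra.id < rb.id else (rb.id, ra.id)
        if net.has_edge(u, v):
            data = net.edges[u, v]
            data["n_alignments"] += 1
            data["max_identity"] = max(data["max_identity"], rec.identity)
            data["alignment_ids"].append(rec.id)
        else:
            net.add_edge(
                u,
                v,
                n_alignments=1,
                max_identity=rec.identity,
                intrachromosomal=(ra.chrom == rb.chrom),
                suspicious=False,
                alignment_ids=[rec.id],
            )
    for u, v, data in net.edges(data=True):
        if data["n_alignments"] >= 2:
            net.nodes[u]["n_double_edges"] += 1
            net.nodes[v]["n_double_edges"] += 1
    return net


def network_summary(net: nx.Graph) -> SummaryReport:
    """Node/edge/component counts and the giant component's share of each."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        return SummaryReport(0, 0, 0, 0, 0, 0.0, 0.0)
    comps = list(nx.connected_components(net))
    giant = max(comps, key=len)
    ge = net.subgraph(giant).number_of_edges()
    return SummaryReport(
        n_nodes=n,
        n_edges=e,
        n_components=len(comps),
        giant_nodes=len(giant),
        giant_edges=ge,
        giant_node_share=round(100.0 * len(giant) / n, 1),
        giant_edge_share=round(100.0 * ge / e, 1) if e else 0.0,
    )


def detect_communities(net: nx.Graph, seed: int = 0) -> dict:
    """Label-propagation communities (asynchronous updates, seeded order).

    Labels are arbitrary integers; the partition is deterministic for a
    given seed.  Communities never span connected components.
    """
    labels: dict = {}
    for i, comm in enumerate(
        nx.community.asyn_lpa_communities(net, seed=seed)
    ):
        for node in comm:
            labels[node] = i
    return labels


def map_intervals_to_nodes(
    net: nx.Graph,
    intervals: Iterable[tuple[str, int, int]],
) -> list[dict]:
    """Assign each genomic interval to the region with the longest bp overlap.

    Returns one dict per interval with keys ``interval``, ``node`` (region id
    or None), ``overlap_bp`` and ``tie`` (True when several regions overlap
    equally long; the lowest (chrom, start) region is then reported).
    """
    regions = [net.nodes[n]["region"] for n in net.nodes]
    index = _RegionIndex(regions)
    out = []
    for chrom, start, end in intervals:
        hits = index.overlapping(chrom, start, end)
        best, best_ov, tie = None, 0, False
        for reg in sorted(hits, key=lambda r: (r.chrom, r.start)):
            ov = reg.overlap(start, end)
            if ov > best_ov:
                best, best_ov, tie = reg, ov, False
            elif ov == best_ov and best is not None and ov > 0:
                tie = True
        out.append(
            {
                "interval": (chrom, start, end),
                "node": best.id if best is not None else None,
                "overlap_bp": best_ov,
                "tie": tie,
            }
        )
    return out


def _near_gap(chrom: str, pos: int, gap_index: dict, pad: int) -> bool:
    # gap lists are short; a linear scan per lookup is fine
    for start, end in gap_index.get(chrom, ()):
        if start <= pos + pad and end >= pos - pad:
            return True
    return False


def flag_suspicious_edges(
    net: nx.Graph,
    records: Sequence[AlignmentRecord],
    gaps: Iterable[tuple[str, int, int]] = (),
    tol_bp: int = 0,
    gap_pad_bp: int = 50,
) -> nx.Graph:
    """Flag edges whose alignments share breakpoints with a sibling edge.

    Two independent duplications rarely start or end at the same basepair;
    matching coordinates of two alignments incident to the same region are a
    hallmark of a secondary alignment (one produced by overlap between
    duplications rather than by an event).  A match is excused when the
    shared breakpoint lies within ``gap_pad_bp`` of an assembly gap, since
    assembly gaps truncate alignments at identical coordinates for
    uninteresting reasons.  Flags are written in place (``suspicious`` edge
    attribute); the network is also returned.
    """
    rec_by_id = {rec.id: rec for rec in records}
    gap_index: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in sorted(gaps):
        gap_index.setdefault(chrom, []).append((start, end))

    for node in net.nodes:
        # alignment breakpoints landing inside this node's region, per edge
        per_edge: list[tuple[tuple, list[tuple[str, int]]]] = []
        region = net.nodes[node]["region"]
        for nbr in net.neighbors(node):
            edge = (node, nbr)
            bps: list[tuple[str, int]] = []
            for rid in net.edges[edge]["alignment_ids"]:
                rec = rec_by_id[rid]
                for chrom, start, end in rec.intervals():
                    if chrom == region.chrom and region.overlap(start, end) > 0:
                        bps.append((chrom, start))
                        bps.append((chrom, end))
            per_edge.append((edge, bps))
        for i in range(len(per_edge)):
            for j in range(i + 1, len(per_edge)):
                (e1, bps1), (e2, bps2) = per_edge[i], per_edge[j]
                for (c1, p1) in bps1:
                    for (c2, p2) in bps2:
                        if c1 == c2 and abs(p1 - p2) <= tol_bp:
                            if _near_gap(c1, p1, gap_index, gap_pad_bp) or _near_gap(
                                c2, p2, gap_index, gap_pad_bp
                            ):
                                continue
                            net.edges[e1]["suspicious"] = True
                            net.edges[e2]["suspicious"] = True
    return net


def cycle_census(net: nx.Graph, max_len: int = 6) -> dict:
    """Census of chordless cycles by length and shortest self-paths per node.

    The SD network is expected to be dominated by triangles: in a copying
    model a daughter can only close cycles of length three, so longer
    chordless cycles point at other processes (or artifacts).  Enumeration is
    exponential in ``max_len``; keep it small.

    Returns ``{"cycles_by_length": {length: count}, "shortest_self_path": {node: length or inf}}``.
    """
    if max_len < 3:
        raise ValueError("max_len must be >= 3")
    counts: dict[int, int] = {k: 0 for k in range(3, max_len + 1)}
    for cyc in nx.chordless_cycles(net, length_bound=max_len):
        counts[len(cyc)] += 1

    shortest: dict = {}
    for node in net.nodes:
        best = np.inf
        for nbr in list(net.neighbors(node)):
            data = net.edges[node, nbr]
            net.remove_edge(node, nbr)
            try:
                alt = nx.shortest_path_length(net, node, nbr)
                best = min(best, alt + 1)
            except nx.NetworkXNoPath:
                pass
            net.add_edge(node, nbr, **data)
        shortest[node] = best
    return {"cycles_by_length": counts, "shortest_self_path": shortest}


def write_network_tables(net: nx.Graph, out_dir: str | Path, seed: int = 0) -> None:
    """Write nodes/edges TSVs and a summary JSON for a built network."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comp_of = {}
    for ci, comp in enumerate(sorted(nx.connected_components(net), key=len, reverse=True)):
        for node in comp:
            comp_of[node] = ci
    communities = detect_communities(net, seed=seed)
    with open(out_dir / "nodes.tsv", "w") as fh:
        fh.write("id\tchrom\tstart\tend\tdegree\tself_loops\tn_double_edges\tcomponent\tcommunity\n")
        for node in sorted(net.nodes):
            d = net.nodes[node]
            fh.write(
                f"{node}\t{d['chrom']}\t{d['start']}\t{d['end']}\t{net.degree(node)}\t"
                f"{d['self_loop_count']}\t{d['n_double_edges']}\t{comp_of[node]}\t{communities[node]}\n"
            )
    with open(out_dir / "edges.tsv", "w") as fh:
        fh.write("node_a\tnode_b\tn_alignments\tmax_identity\tintrachromosomal\tsuspicious\n")
        for u, v, d in sorted(net.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{d['n_alignments']}\t{d['max_identity']:.4f}\t"
                f"{int(d['intrachromosomal'])}\t{int(d['suspicious'])}\n"
            )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(network_summary(net).to_dict(), fh, indent=2)
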