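"""Synthetic genomes with known duplication history, for end-to-end testing.

The generator forward-simulates duplication events on a coordinate genome:
each event copies a source interval to a fresh locus and emits one *primary*
alignment.  When the source overlaps the footprint of an earlier alignment,
the new copy is also homologous to that alignment's partner, so the implied
*secondary* alignment is emitted for the overlapped portion (this is the
mechanism that creates cycles in real SD networks).  The bundle carries the
full ground truth plus feature tracks with planted, tunable effects:
breakpoint repeat enrichment and a value track correlated with per-locus
duplication counts.

All emitted tables use the same dialects the analysis modules consume, so a
bundle can be written to disk and fed through the command-line interface
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .core import (
    AlignmentRecord,
    build_duplicated_regions,
    build_network,
)
from .evaluate import edges_match, variance_explained
from .reconstruct import assign_weights, minimum_spanning_forest

__all__ = ["FixtureParams", "FixtureBundle", "generate_fixture", "write_bundle", "roundtrip_check", "component_graph"]

MIN_ALIGN_BP = 1000  # segmental duplications are >= 1 kbp by definition


@dataclass(frozen=True)
class FixtureParams:
    n_chroms: int = 4
    chrom_length_bp: int = 4_000_000
    n_duplication_events: int = 120
    dup_length_min: int = 1_000
    dup_length_max: int = 20_000
    overlap_prob: float = 0.3
    breakpoint_repeat_enrichment: float = 4.0
    feature_rate_assoc: float = 0.5
    n_background_repeats_per_chrom: int = 150
    n_gaps_per_chrom: int = 2
    gap_length_bp: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dup_length_min < MIN_ALIGN_BP:
            raise ValueError(f"dup_length_min must be >= {MIN_ALIGN_BP}")
        if not 0.0 <= self.overlap_prob <= 1.0:
            raise ValueError("overlap_prob must be in [0, 1]")
        if self.n_duplication_events * self.dup_length_max > 0.25 * self.n_chroms * self.chrom_length_bp:
            raise ValueError("genome too small for the requested number of events")


@dataclass
class FixtureBundle:
    params: FixtureParams
    # alignment rows: (chrom_a, start_a, end_a, chrom_b, start_b, end_b, identity, is_primary, event)
    alignments: list = field(default_factory=list)
    truth_events: list = field(default_factory=list)  # (event, src_chrom, src_start, src_end, tgt_chrom, tgt_start, tgt_end)
    gaps: list = field(default_factory=list)
    repeats: dict = field(default_factory=dict)  # family -> [(chrom, start, end)]
    value_tracks: dict = field(default_factory=dict)  # name -> [(chrom, start, end, value)]
    chrom_sizes: dict = field(default_factory=dict)
    centromeres: dict = field(default_factory=dict)  # chrom -> (start, end)
    telomeres: dict = field(default_factory=dict)  # chrom -> [(start, end), (start, end)]

    def records(self) -> list[AlignmentRecord]:
        return [
            AlignmentRecord(i, ca, sa, ea, cb, sb, eb, ident)
            for i, (ca, sa, ea, cb, sb, eb, ident, _prim, _ev) in enumerate(self.alignments)
        ]

    def primary_flags(self) -> list[bool]:
        return [bool(row[7]) for row in self.alignments]


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


class _Occupancy:
    """Tracks placed intervals so fresh loci can be kept disjoint."""

    def __init__(self, margin: int = 10):
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}
        self.margin = margin

    def add(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((start, end))

    def clashes(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.by_chrom.get(chrom, ()):
            if _overlap(start - self.margin, end + self.margin, s, e) > 0:
                return True
        return False


def generate_fixture(params: FixtureParams) -> FixtureBundle:
    """Forward-simulate duplications; emit annotation, truth and tracks."""
    rng = np.random.default_rng(params.seed)
    chroms = [f"chr{i + 1}" for i in range(params.n_chroms)]
    L = params.chrom_length_bp
    bundle = FixtureBundle(params=params)
    bundle.chrom_sizes = {c: L for c in chroms}
    for c in chroms:
        mid = L // 2
        bundle.centromeres[c] = (mid - 50_000, mid + 50_000)
        bundle.telomeres[c] = [(0, 10_000), (L - 10_000, L)]

    # assembly gaps, kept away from chromosome ends
    for c in chroms:
        for _ in range(params.n_gaps_per_chrom):
            start = int(rng.integers(L // 10, L - L // 10))
            bundle.gaps.append((c, start, start + params.gap_length_bp))

    occupancy = _Occupancy()
    for c, s, e in bundle.gaps:
        occupancy.add(c, s, e)

    def place_fresh(length: int) -> tuple[str, int, int]:
        for _ in range(500):
            c = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(20_000, L - length - 20_000))
            if not occupancy.clashes(c, start, start + length):
                return c, start, start + length
        raise ValueError("genome too small: could not place a fresh locus")

    # alignment footprints placed so far, as (chrom, start, end, partner_row_index, side)
    align_rows = bundle.alignments
    n_ev = params.n_duplication_events
    for ev in range(n_ev):
        length = int(rng.integers(params.dup_length_min, params.dup_length_max + 1))
        prior = align_rows[:]
        if prior and rng.random() < params.overlap_prob:
            # source deliberately overlaps an earlier duplicated locus
            row = prior[rng.integers(len(prior))]
            side = rng.integers(2)
            pc, ps, pe = (row[0], row[1], row[2]) if side == 0 else (row[3], row[4], row[5])
            span = pe - ps
            # keep >= MIN_ALIGN_BP overlap with the prior footprint
            shift_max = max(1, span - MIN_ALIGN_BP)
            shift = int(rng.integers(0, shift_max))
            src = (pc, max(0, ps + shift), max(0, ps + shift) + length)
            if src[2] > L:
                src = (pc, L - length, L)
        else:
            src = place_fresh(length)
        tgt = place_fresh(length)
        # identity decreases with age: oldest events are most diverged
        identity = 0.9 + 0.1 * (ev + 1) / n_ev
        identity = min(identity, 1.0)

        # secondary alignments: new copy is homologous to partners of any
        # earlier alignment footprint the source overlaps
        secondaries = []
        for row in prior:
            for (ic, is_, ie), (jc, js, je) in (
                ((row[0], row[1], row[2]), (row[3], row[4], row[5])),
                ((row[3], row[4], row[5]), (row[0], row[1], row[2])),
            ):
                if ic != src[0]:
                    continue
                ov_s, ov_e = max(is_, src[1]), min(ie, src[2])
                if ov_e - ov_s < MIN_ALIGN_BP:
                    continue
                # map overlapped portion through src->tgt and I->J
                t_s = tgt[1] + (ov_s - src[1])
                t_e = tgt[1] + (ov_e - src[1])
                j_s = js + (ov_s - is_)
                j_e = js + (ov_e - is_)
                j_e = min(j_e, je)
                if j_e - j_s < MIN_ALIGN_BP:
                    continue
                sec_ident = min(identity, row[6])
                secondaries.append((tgt[0], t_s, t_e, jc, j_s, j_e, sec_ident, False, ev))
        align_rows.append((src[0], src[1], src[2], tgt[0], tgt[1], tgt[2], identity, True, ev))
        align_rows.extend(secondaries)
        bundle.truth_events.append((ev, src[0], src[1], src[2], tgt[0], tgt[1], tgt[2]))
        occupancy.add(*src)
        occupancy.add(*tgt)

    _plant_repeats(bundle, rng)
    _plant_value_tracks(bundle, rng)
    return bundle


def _plant_repeats(bundle: FixtureBundle, rng) -> None:
    params = bundle.params
    chroms = list(bundle.chrom_sizes)
    L = params.chrom_length_bp
    families = ["SatSyn", "LineSyn", "DnaSyn"]
    for fam in families:
        ivals = []
        for c in chroms:
            for _ in range(params.n_background_repeats_per_chrom):
                start = int(rng.integers(0, L - 300))
                ivals.append((c, start, start + 300))
        bundle.repeats[fam] = ivals
    # enriched family gets extra copies right at duplication breakpoints
    p_bp = min(1.0, 0.12 * params.breakpoint_repeat_enrichment)
    extra = []
    for row in bundle.alignments:
        for chrom, start, end in ((row[0], row[1], row[2]), (row[3], row[4], row[5])):
            for bp in (start, end):
                if rng.random() < p_bp:
                    extra.append((chrom, max(0, bp - 25), bp + 25))
    bundle.repeats["SatSyn"] = bundle.repeats["SatSyn"] + extra


def _plant_value_tracks(bundle: FixtureBundle, rng) -> None:
    """Value tracks in 50-kb bins; one is correlated with local event counts."""
    params = bundle.params
    bin_bp = 50_000
    # per-bin event footprint count
    counts: dict[tuple[str, int], int] = {}
    for _, sc, ss, se, tc, ts, te in bundle.truth_events:
        for chrom, start, end in ((sc, ss, se), (tc, ts, te)):
            for b in range(start // bin_bp, end // bin_bp + 1):
                counts[(chrom, b)] = counts.get((chrom, b), 0) + 1
    for name, assoc in (("rep_timing", 0.0), ("dup_assoc_track", params.feature_rate_assoc)):
        rows = []
        for chrom, size in bundle.chrom_sizes.items():
            for b in range(size // bin_bp):
                noise = rng.normal()
                val = assoc * counts.get((chrom, b), 0) + noise
                rows.append((chrom, b * bin_bp, (b + 1) * bin_bp, float(val)))
        bundle.value_tracks[name] = rows


# genomicSuperDups-style dialect: partner interval in cols 6-8, fracMatch col 26
_N_COLS = 27


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict:
    """Write the bundle in the on-disk dialects the CLI consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    sd_path = out_dir / "sd_annotation.tsv"
    with open(sd_path, "w") as fh:
        for ca, sa, ea, cb, sb, eb, ident, _p, _ev in bundle.alignments:
            row = ["."] * _N_COLS
            row[0], row[1], row[2] = ca, str(sa), str(ea)
            row[6], row[7], row[8] = cb, str(sb), str(eb)
            row[26] = f"{ident:.6f}"
            fh.write("\t".join(row) + "\n")
    paths["sd"] = sd_path

    truth_path = out_dir / "truth_events.tsv"
    with open(truth_path, "w") as fh:
        fh.write("event\tsrc_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\ttgt_end\n")
        for row in bundle.truth_events:
            fh.write("\t".join(str(x) for x in row) + "\n")
    truth_aln_path = out_dir / "truth_alignments.tsv"
    with open(truth_aln_path, "w") as fh:
        fh.write("alignment_id\tis_primary\tevent\n")
        for i, row in enumerate(bundle.alignments):
            fh.write(f"{i}\t{int(row[7])}\t{row[8]}\n")
    paths["truth"] = truth_path
    paths["truth_alignments"] = truth_aln_path

    gaps_path = out_dir / "gaps.bed"
    with open(gaps_path, "w") as fh:
        for c, s, e in sorted(bundle.gaps):
            fh.write(f"{c}\t{s}\t{e}\n")
    paths["gaps"] = gaps_path

    for fam, ivals in bundle.repeats.items():
        p = out_dir / f"repeats_{fam}.bed"
        with open(p, "w") as fh:
            for c, s, e in sorted(ivals):
                fh.write(f"{c}\t{s}\t{e}\n")
        paths[f"repeats_{fam}"] = p

    for name, rows in bundle.value_tracks.items():
        p = out_dir / f"{name}.bedgraph"
        with open(p, "w") as fh:
            for c, s, e, v in rows:
                fh.write(f"{c}\t{s}\t{e}\t{v:.6f}\n")
        paths[name] = p

    sizes_path = out_dir / "chrom_sizes.tsv"
    with open(sizes_path, "w") as fh:
        for c, size in bundle.chrom_sizes.items():
            fh.write(f"{c}\t{size}\n")
    paths["chrom_sizes"] = sizes_path

    cyto_path = out_dir / "centromeres_telomeres.tsv"
    with open(cyto_path, "w") as fh:
        fh.write("chrom\tkind\tstart\tend\n")
        for c, (s, e) in bundle.centromeres.items():
            fh.write(f"{c}\tcentromere\t{s}\t{e}\n")
        for c, pair in bundle.telomeres.items():
            for s, e in pair:
                fh.write(f"{c}\ttelomere\t{s}\t{e}\n")
    paths["cyto"] = cyto_path
    return paths


def truth_region_labels(bundle: FixtureBundle, regions, net: nx.Graph):
    """Map fixture truth onto the built network.

    Returns (primary_edge_set over region-id pairs, per-node true event
    counts).  A primary event whose source and target fall into the same
    region (tandem-style) contributes to counts but yields no edge.
    """
    from .core import _RegionIndex  # internal helper, same package

    index = _RegionIndex(regions)
    primary_edges = set()
    counts = {n: 0 for n in net.nodes}
    for _ev, sc, ss, se, tc, ts, te in bundle.truth_events:
        src_hits = index.overlapping(sc, ss, se)
        tgt_hits = index.overlapping(tc, ts, te)
        src = max(src_hits, key=lambda r: r.overlap(ss, se)) if src_hits else None
        tgt = max(tgt_hits, key=lambda r: r.overlap(ts, te)) if tgt_hits else None
        if src is not None:
            counts[src.id] += 1
        if tgt is not None:
            counts[tgt.id] += 1
        if src is not None and tgt is not None and src.id != tgt.id:
            primary_edges.add((min(src.id, tgt.id), max(src.id, tgt.id)))
    return primary_edges, counts


def roundtrip_check(bundle: FixtureBundle, seed: int = 0) -> dict:
    """Run network construction + reconstruction on a bundle; score vs truth."""
    records = bundle.records()
    regions = build_duplicated_regions(records)
    net = build_network(regions, records)
    assign_weights(net)
    forest = minimum_spanning_forest(net, seed=seed)
    primary_edges, counts = truth_region_labels(bundle, regions, net)
    nodes = list(net.nodes)
    pred = [forest.duplication_count[n] for n in nodes]
    truth = [counts[n] for n in nodes]
    # a no-overlap bundle gives every region exactly one event: r2 undefined
    r2 = (
        variance_explained(pred, truth)
        if len(set(truth)) > 1
        else float("nan")
    )
    return {
        "n_regions": len(regions),
        "n_edges": net.number_of_edges(),
        "edges_match": edges_match(forest, primary_edges),
        "r2": r2,
    }


def component_graph(n_nodes: int, n_components: int, seed: int = 0, mean_extra_edges: float = 1.5) -> nx.Graph:
    """Random weighted graph with an exact node and component count.

    Node counts per component are multinomially split; each component gets a
    random spanning tree plus a Poisson number of extra edges, and every
    edge a uniform random weight.  Useful for exercising the spanning-forest
    size law |forest| = n_nodes - n_components at any scale.
    """
    if n_components < 1 or n_nodes < n_components:
        raise ValueError("need 1 <= n_components <= n_nodes")
    rng = np.random.default_rng(seed)
    sizes = np.ones(n_components, dtype=int)
    remaining = n_nodes - n_components
    if remaining:
        sizes += rng.multinomial(remaining, np.ones(n_components) / n_components)
    g = nx.Graph()
    node = 0
    for size in sizes:
        members = list(range(node, node + size))
        g.add_nodes_from(members)
        for i in range(1, size):
            parent = members[rng.integers(0, i)]
            g.add_edge(parent, members[i], weight=float(rng.random()), suspicious=False)
        if size >= 3:
            for _ in range(rng.poisson(mean_extra_edges)):
                u, v = rng.choice(members, size=2, replace=False)
                if u != v and not g.has_edge(u, v):
                    g.add_edge(int(u), int(v), weight=float(rng.random()), suspicious=False)
        node += size
    return g
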