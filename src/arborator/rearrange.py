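"""Synteny blocks and rearrangement calls in gene-order space.

Blocks are maximal runs of syntenic ortholog pairs whose target indices step
by +1 (same orientation) or −1 (inverted).  A reciprocal translocation shows
up as two query chromosomes exchanging prefix/suffix blocks between two
target chromosomes; an inversion as an inverted block flanked by
same-orientation blocks.  Breakpoints are reported as intergenic intervals
in both genomes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .model import GeneModel, TRNAModel
from .orthology import GeneOrder, OrthologAssignment, SYNTENIC_CLASSES


@dataclass
class SyntenyBlock:
    query_chrom: str
    target_chrom: str
    query_gene_ids: list[str]
    target_gene_ids: list[str]
    q_start_idx: int
    q_end_idx: int              # inclusive
    t_start_idx: int            # index of the first pair's target
    t_end_idx: int              # index of the last pair's target
    orientation: str            # "same" | "inverted"

    @property
    def n_genes(self) -> int:
        return len(self.query_gene_ids)


@dataclass
class Breakpoint:
    genome: str                 # "query" | "target"
    chrom: str
    left_gene: str | None
    right_gene: str | None
    start: int
    end: int


@dataclass
class RearrangementEvent:
    type: str                   # "reciprocal_translocation" | "inversion" | "complex"
    chroms: list[str]
    breakpoints: list[Breakpoint] = field(default_factory=list)
    nearby_features: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------- blocks

def build_blocks(assignments: dict[str, OrthologAssignment],
                 query_order: GeneOrder, target_order: GeneOrder,
                 min_block_genes: int = 2) -> tuple[list[SyntenyBlock], int]:
    """Greedy left-to-right scan of query gene order into collinear blocks.

    Only syntenic-class assignments participate.  Returns (blocks, number of
    pairs discarded in blocks shorter than ``min_block_genes``).
    """
    blocks: list[SyntenyBlock] = []
    discarded = 0

    def close(cur: list[tuple[int, str, str, str, int]], orient: str | None):
        nonlocal discarded
        if not cur:
            return
        if len(cur) < min_block_genes:
            discarded += len(cur)
            return
        if orient is None:
            orient = "same"
        blocks.append(SyntenyBlock(
            query_chrom=qchrom, target_chrom=cur[0][2],
            query_gene_ids=[c[1] for c in cur],
            target_gene_ids=[c[3] for c in cur],
            q_start_idx=cur[0][0], q_end_idx=cur[-1][0],
            t_start_idx=cur[0][4], t_end_idx=cur[-1][4],
            orientation=orient))

    for qchrom, order in query_order.by_chrom.items():
        pairs = []
        for i, q in enumerate(order):
            a = assignments.get(q)
            if a is None or a.assignment_class not in SYNTENIC_CLASSES:
                continue
            tchrom, tidx = target_order.index[a.target_gene_id]
            pairs.append((i, q, tchrom, a.target_gene_id, tidx))
        cur: list[tuple[int, str, str, str, int]] = []
        orient: str | None = None
        for p in pairs:
            if not cur:
                cur, orient = [p], None
                continue
            step = p[4] - cur[-1][4]
            same_chrom = p[2] == cur[-1][2]
            if same_chrom and orient is None and step in (1, -1):
                orient = "same" if step == 1 else "inverted"
                cur.append(p)
            elif same_chrom and ((orient == "same" and step == 1) or
                                 (orient == "inverted" and step == -1)):
                cur.append(p)
            else:
                close(cur, orient)
                cur, orient = [p], None
        close(cur, orient)
    return blocks, discarded


# ---------------------------------------------------------------- breakpoints

def _intergenic(genes: dict[str, GeneModel], left: str | None, right: str | None,
                chrom: str, genome_label: str,
                chrom_len: int | None = None) -> Breakpoint:
    """Intergenic interval between two genes (order-normalized); open ends
    fall back to the chromosome boundary."""
    gl = genes.get(left) if left else None
    gr = genes.get(right) if right else None
    if gl is not None and gr is not None and gl.start > gr.start:
        gl, gr = gr, gl
        left, right = right, left
    start = gl.end if gl is not None else 0
    end = gr.start if gr is not None else (chrom_len if chrom_len else start + 1)
    if end < start:
        start, end = end, start
    return Breakpoint(genome_label, chrom, left, right, start, end)


def detect_translocations(blocks: list[SyntenyBlock],
                          query_genes: list[GeneModel],
                          target_genes: list[GeneModel],
                          ) -> list[RearrangementEvent]:
    """Reciprocal translocations: two query chromosomes whose block order is
    t1-then-t2 and t2-then-t1 over the same two target chromosomes, with
    complementary target index ranges."""
    qg = {g.gene_id: g for g in query_genes}
    tg = {g.gene_id: g for g in target_genes}
    by_q: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_q.setdefault(b.query_chrom, []).append(b)
    for bs in by_q.values():
        bs.sort(key=lambda b: b.q_start_idx)

    # collapse each query chromosome to its ordered distinct target chroms
    profile: dict[str, list[str]] = {}
    for qc, bs in by_q.items():
        seq: list[str] = []
        for b in bs:
            if not seq or seq[-1] != b.target_chrom:
                seq.append(b.target_chrom)
        profile[qc] = seq

    events: list[RearrangementEvent] = []
    multi = [qc for qc, seq in profile.items() if len(set(seq)) == 2]
    seen_pairs: set[frozenset] = set()
    for i, q1 in enumerate(multi):
        for q2 in multi[i + 1:]:
            key = frozenset((q1, q2))
            if key in seen_pairs:
                continue
            s1, s2 = profile[q1], profile[q2]
            if len(s1) != 2 or len(s2) != 2 or set(s1) != set(s2) or s1 == s2:
                continue
            t1, t2 = s1
            bp = []
            ok = True
            for qc, (pre, suf) in ((q1, (t1, t2)), (q2, (t2, t1))):
                bs = by_q[qc]
                pre_blocks = [b for b in bs if b.target_chrom == pre]
                suf_blocks = [b for b in bs if b.target_chrom == suf]
                if not pre_blocks or not suf_blocks:
                    ok = False
                    break
                last_pre = pre_blocks[-1]
                first_suf = suf_blocks[0]
                # query-side breakpoint between the two junction genes
                bp.append(_intergenic(qg, last_pre.query_gene_ids[-1],
                                      first_suf.query_gene_ids[0], qc, "query"))
            if not ok:
                continue
            # target-side breakpoints: junction between the part of t landing
            # on q1 and the part landing on q2
            for t in (t1, t2):
                parts = []
                for qc in (q1, q2):
                    for b in by_q[qc]:
                        if b.target_chrom == t:
                            parts.append(b)
                parts.sort(key=lambda b: min(b.t_start_idx, b.t_end_idx))
                qcs = [b.query_chrom for b in parts]
                split = next((k for k in range(1, len(parts))
                              if qcs[k] != qcs[k - 1]), None)
                if split is None:
                    ok = False
                    break
                bp.append(_intergenic(tg, parts[split - 1].target_gene_ids[-1]
                                      if parts[split - 1].orientation == "same"
                                      else parts[split - 1].target_gene_ids[0],
                                      parts[split].target_gene_ids[0]
                                      if parts[split].orientation == "same"
                                      else parts[split].target_gene_ids[-1],
                                      t, "target"))
            if ok:
                seen_pairs.add(key)
                events.append(RearrangementEvent(
                    "reciprocal_translocation", sorted({t1, t2}) + sorted(key),
                    breakpoints=bp))
    return events


def detect_inversions(blocks: list[SyntenyBlock],
                      query_genes: list[GeneModel],
                      target_genes: list[GeneModel],
                      ) -> list[RearrangementEvent]:
    """Inverted blocks flanked by same-orientation blocks on the same
    chromosome pair; whole-chromosome inverted blocks get chromosome-end
    breakpoints."""
    qg = {g.gene_id: g for g in query_genes}
    tg = {g.gene_id: g for g in target_genes}
    by_pair: dict[tuple[str, str], list[SyntenyBlock]] = {}
    for b in blocks:
        by_pair.setdefault((b.query_chrom, b.target_chrom), []).append(b)
    events = []
    for (qc, tc), bs in sorted(by_pair.items()):
        bs.sort(key=lambda b: b.q_start_idx)
        for i, b in enumerate(bs):
            if b.orientation != "inverted":
                continue
            prev = bs[i - 1] if i > 0 else None
            nxt = bs[i + 1] if i + 1 < len(bs) else None
            left_gene = prev.query_gene_ids[-1] if prev else None
            right_gene = nxt.query_gene_ids[0] if nxt else None
            bp_q_left = _intergenic(qg, left_gene, b.query_gene_ids[0], qc, "query")
            bp_q_right = _intergenic(qg, b.query_gene_ids[-1], right_gene, qc, "query")
            # target side: pick the segment's outermost genes by coordinate —
            # an inverted block's leftmost target gene pairs with its *last*
            # query gene
            t_left_flank = prev.target_gene_ids[-1] if prev else None
            t_right_flank = nxt.target_gene_ids[0] if nxt else None
            leftmost = min(b.target_gene_ids, key=lambda x: tg[x].start)
            rightmost = max(b.target_gene_ids, key=lambda x: tg[x].end)
            bp_t_left = _intergenic(tg, t_left_flank, leftmost, tc, "target")
            bp_t_right = _intergenic(tg, rightmost, t_right_flank, tc, "target")
            events.append(RearrangementEvent(
                "inversion", [qc, tc],
                breakpoints=[bp_q_left, bp_q_right, bp_t_left, bp_t_right]))
    return events


# ---------------------------------------------------------------- annotation

def annotate_breakpoint_features(event: RearrangementEvent,
                                 features: list[GeneModel | TRNAModel],
                                 max_dist: int = 1000) -> RearrangementEvent:
    """Attach features within ``max_dist`` of any target-side breakpoint
    interval (distance 0 when overlapping); symmetric, strand-independent."""
    found: list[tuple[str, int]] = []
    for bp in event.breakpoints:
        if bp.genome != "target":
            continue
        for f in features:
            if f.chrom_id != bp.chrom:
                continue
            s, e = f.span
            if e <= bp.start:
                dist = bp.start - e
            elif s >= bp.end:
                dist = s - bp.end
            else:
                dist = 0
            if dist <= max_dist:
                fid = getattr(f, "gene_id", None) or getattr(f, "trna_id")
                found.append((fid, dist))
    event.nearby_features = sorted(set(found), key=lambda x: (x[1], x[0]))
    return event


def dot_plot_points(assignments: dict[str, OrthologAssignment],
                    query_order: GeneOrder, target_order: GeneOrder
                    ) -> list[tuple[str, int, str, int]]:
    """(query_chrom, query_index, target_chrom, target_index) per syntenic
    pair, for external plotting."""
    pts = []
    for a in assignments.values():
        if a.assignment_class not in SYNTENIC_CLASSES:
            continue
        qc, qi = query_order.index[a.query_gene_id]
        tc, ti = target_order.index[a.target_gene_id]
        pts.append((qc, qi, tc, ti))
    return sorted(pts)
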