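"""Three-stage synteny-aware ortholog assignment.

Stage 1 (first pass): a query gene whose top hit, together with its two
chromosomal neighbours' top hits, lands on three consecutive target genes
(in either orientation) is a syntenic ortholog.
Stage 2 (iterative rescue): unassigned queries whose nearest assigned
neighbours bracket a target window are rescued when exactly one of their
top-ranked hits falls strictly inside that window; repeated to fixed point.
Stage 3 (fallback): remaining queries take their free rank-1 target as a
non-syntenic ortholog.

Also: the tRNA synteny rule, prediction classification, and the telomeric
decile enrichment test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .model import GeneModel, HitRecord, TRNAModel

SYNTENIC_CLASSES = ("syntenic_first_pass", "syntenic_rescued")


@dataclass
class OrthologAssignment:
    query_gene_id: str
    target_gene_id: str | None = None
    assignment_class: str = "unassigned"
    round_assigned: int = 0

    def __post_init__(self) -> None:
        if self.assignment_class in SYNTENIC_CLASSES + ("non_syntenic",) \
                and self.target_gene_id is None:
            raise ValueError("assigned class without a target gene")


class GeneOrder:
    """Per-chromosome gene order by start coordinate, with index lookup."""

    def __init__(self, genes: list[GeneModel]):
        self.by_chrom: dict[str, list[str]] = {}
        tmp: dict[str, list[GeneModel]] = {}
        for g in genes:
            tmp.setdefault(g.chrom_id, []).append(g)
        self.index: dict[str, tuple[str, int]] = {}
        for chrom, gs in tmp.items():
            gs.sort(key=lambda g: (g.start, g.gene_id))
            self.by_chrom[chrom] = [g.gene_id for g in gs]
            for i, g in enumerate(gs):
                self.index[g.gene_id] = (chrom, i)

    def neighbours(self, gene_id: str) -> tuple[str | None, str | None]:
        chrom, i = self.index[gene_id]
        order = self.by_chrom[chrom]
        return (order[i - 1] if i > 0 else None,
                order[i + 1] if i + 1 < len(order) else None)


# ---------------------------------------------------------------- hit mapping

def map_top_hits_to_genes(hits: list[HitRecord], target_genes: list[GeneModel]
                          ) -> dict[str, list[str | None]]:
    """Resolve each ranked hit to the target gene with the largest exonic
    overlap (ties: leftmost gene start, then gene id); None if no overlap."""
    trees: dict[str, IntervalTree] = {}
    by_id = {g.gene_id: g for g in target_genes}
    for g in target_genes:
        trees.setdefault(g.chrom_id, IntervalTree()).addi(g.start, g.end, g.gene_id)
    byq: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.rank is None:
            raise ValueError("hits must be ranked (use rank_hits)")
        byq.setdefault(h.query_id, []).append(h)
    out: dict[str, list[str | None]] = {}
    for q, hs in byq.items():
        resolved: list[str | None] = [None] * len(hs)
        for h in hs:
            best: tuple[int, int, str] | None = None
            for iv in trees.get(h.chrom_id, IntervalTree()).overlap(h.start, h.end):
                g = by_id[iv.data]
                ov = sum(max(0, min(e, h.end) - max(s, h.start)) for s, e in g.exons)
                if ov <= 0:
                    continue
                key = (-ov, g.start, g.gene_id)
                if best is None or key < best:
                    best = key
            resolved[h.rank - 1] = None if best is None else best[2]
        out[q] = resolved
    return out


def top_hit_gene(ranked: dict[str, list[str | None]]) -> dict[str, str | None]:
    return {q: (lst[0] if lst else None) for q, lst in ranked.items()}


# ---------------------------------------------------------------- first pass

def assign_first_pass(query_order: GeneOrder, top_hits: dict[str, str | None],
                      target_order: GeneOrder
                      ) -> dict[str, OrthologAssignment]:
    """Triplet synteny: three query neighbours hitting three consecutive
    target genes (ascending or descending) assign the middle gene."""
    proposals: dict[str, set[str]] = {}  # target -> middle queries claiming it
    for chrom, order in query_order.by_chrom.items():
        for i in range(1, len(order) - 1):
            trip = [top_hits.get(order[j]) for j in (i - 1, i, i + 1)]
            if any(t is None for t in trip):
                continue
            locs = [target_order.index.get(t) for t in trip]
            if any(l is None for l in locs):
                continue
            chroms = {c for c, _ in locs}
            if len(chroms) != 1:
                continue
            j = [x for _, x in locs]
            if (j[1] == j[0] + 1 and j[2] == j[1] + 1) or \
               (j[1] == j[0] - 1 and j[2] == j[1] - 1):
                proposals.setdefault(trip[1], set()).add(order[i])

    assignments = {q: OrthologAssignment(q)
                   for order in query_order.by_chrom.values() for q in order}
    for target, middles in proposals.items():
        if len(middles) == 1:  # conflicting claims void both (conservatism)
            q = next(iter(middles))
            assignments[q] = OrthologAssignment(q, target, "syntenic_first_pass")
    return assignments


# ---------------------------------------------------------------- rescue

def _window_candidates(q: str, assignments: dict[str, OrthologAssignment],
                       ranked_hits: dict[str, list[str | None]],
                       query_order: GeneOrder, target_order: GeneOrder,
                       claimed: set[str], max_rank: int,
                       rank_scores: dict[str, list[float]] | None = None,
                       ) -> tuple[int, int, float, list[str]] | None:
    """Anchor window and unclaimed in-window hit genes for one pending query.

    Returns (window span in genes, best candidate hit rank, best candidate
    score, candidates), or None when no two same-chromosome anchors exist.
    """
    chrom, i = query_order.index[q]
    order = query_order.by_chrom[chrom]
    left = next((j for j in range(i - 1, -1, -1)
                 if assignments[order[j]].target_gene_id is not None), None)
    right = next((j for j in range(i + 1, len(order))
                  if assignments[order[j]].target_gene_id is not None), None)
    if left is None or right is None:
        return None
    cl, il = target_order.index[assignments[order[left]].target_gene_id]
    cr, ir = target_order.index[assignments[order[right]].target_gene_id]
    if cl != cr:
        return None  # anchors on different target chromosomes
    lo, hi = min(il, ir), max(il, ir)
    cands = []
    best_rank = max_rank + 1
    best_score = float("-inf")
    scores = (rank_scores or {}).get(q, [])
    seen: set[str] = set()
    for r, t in enumerate(ranked_hits.get(q, [])[:max_rank], 1):
        if t is None or t in claimed or t in seen:
            continue
        seen.add(t)
        loc = target_order.index.get(t)
        if loc is not None and loc[0] == cl and lo < loc[1] < hi:
            cands.append(t)
            best_rank = min(best_rank, r)
            if r - 1 < len(scores):
                best_score = max(best_score, scores[r - 1])
    return hi - lo - 1, best_rank, best_score, cands


def pending_window_candidates(assignments: dict[str, OrthologAssignment],
                              ranked_hits: dict[str, list[str | None]],
                              query_order: GeneOrder, target_order: GeneOrder,
                              max_rank: int = 10) -> dict[str, list[str]]:
    """In-window candidate targets of every still-unassigned query."""
    claimed = {a.target_gene_id for a in assignments.values()
               if a.target_gene_id is not None}
    out: dict[str, list[str]] = {}
    for order in query_order.by_chrom.values():
        for q in order:
            if assignments[q].target_gene_id is not None:
                continue
            wc = _window_candidates(q, assignments, ranked_hits, query_order,
                                    target_order, claimed, max_rank)
            if wc is not None and wc[3]:
                out[q] = wc[3]
    return out


def rescue_iterative(assignments: dict[str, OrthologAssignment],
                     ranked_hits: dict[str, list[str | None]],
                     query_order: GeneOrder, target_order: GeneOrder,
                     max_rank: int = 10, max_rounds: int = 1000,
                     rank_scores: dict[str, list[float]] | None = None,
                     ) -> tuple[dict[str, OrthologAssignment], int]:
    """Iterative single-candidate rescue inside synteny anchor windows.

    ``rank_scores`` optionally gives each query's hit scores in rank order;
    they refine the within-round processing order only, never eligibility.
    Returns the updated assignments and the number of productive rounds.
    """
    claimed = {a.target_gene_id for a in assignments.values()
               if a.target_gene_id is not None}

    def window_and_cands(q):
        return _window_candidates(q, assignments, ranked_hits, query_order,
                                  target_order, claimed, max_rank, rank_scores)

    all_queries = [q for order in query_order.by_chrom.values() for q in order]
    rounds = 0
    while rounds < max_rounds:
        pending = [q for q in all_queries
                   if assignments[q].target_gene_id is None]
        # confident rescues first — tight windows, high-ranking and
        # high-scoring in-window hits — so true owners claim their targets
        # before a wide, ambiguous window elsewhere can grab them
        sized = []
        for q in pending:
            wc = window_and_cands(q)
            if wc is not None:
                sized.append((wc[0], -wc[2], wc[1], q))
        sized.sort()
        added = 0
        for _, _, _, q in sized:
            wc = window_and_cands(q)  # re-evaluate under current claims
            if wc is None:
                continue
            cands = wc[3]
            if len(cands) != 1:
                continue
            # a singleton-vs-singleton contest (another pending query whose
            # only in-window candidate is the same target) is undecidable by
            # synteny: at most one claimant can be right, so both are left
            # for the sequence-evidence fallback stage
            contested = any(
                q2 != q and assignments[q2].target_gene_id is None
                and (wc2 := window_and_cands(q2)) is not None
                and wc2[3] == cands
                for _, _, _, q2 in sized)
            if contested:
                continue
            assignments[q] = OrthologAssignment(
                q, cands[0], "syntenic_rescued", rounds + 1)
            claimed.add(cands[0])
            added += 1
        if added == 0:
            break
        rounds += 1
    return assignments, rounds


# ---------------------------------------------------------------- fallback

def assign_non_syntenic(assignments: dict[str, OrthologAssignment],
                        top_hits: dict[str, str | None],
                        target_genes: list[GeneModel],
                        reserved: set[str] | None = None,
                        top_scores: dict[str, float] | None = None,
                        ) -> dict[str, OrthologAssignment]:
    """Remaining queries take their free, non-overlapping rank-1 target.

    ``reserved`` targets (e.g. live synteny-rescue candidates) are treated
    as claimed: sequence-only evidence never outranks pending synteny
    evidence.  With ``top_scores`` queries are processed by ascending rank-1
    score (ties by id): moderate true matches claim their target before the
    anomalously high-scoring spurious best hits can steal it; without
    scores, plain gene-id order.  Either way deterministic.
    """
    by_id = {g.gene_id: g for g in target_genes}
    claimed = {a.target_gene_id for a in assignments.values()
               if a.target_gene_id is not None}
    trees: dict[str, IntervalTree] = {}
    for g in target_genes:
        trees.setdefault(g.chrom_id, IntervalTree()).addi(g.start, g.end, g.gene_id)
    if top_scores:
        queue = sorted(assignments, key=lambda q: (top_scores.get(q, 0.0), q))
    else:
        queue = sorted(assignments)
    for q in queue:
        a = assignments[q]
        if a.target_gene_id is not None:
            continue
        t = top_hits.get(q)
        if t is None or t in claimed or (reserved and t in reserved):
            continue
        g = by_id[t]
        overlaps_claimed = any(
            iv.data != t and iv.data in claimed
            for iv in trees[g.chrom_id].overlap(g.start, g.end))
        if overlaps_claimed:
            continue
        assignments[q] = OrthologAssignment(q, t, "non_syntenic")
        claimed.add(t)
    return assignments


def assign_orthologs(query_genes: list[GeneModel], target_genes: list[GeneModel],
                     hits: list[HitRecord], max_rank: int = 10,
                     max_outer_loops: int = 5,
                     ) -> tuple[dict[str, OrthologAssignment], int]:
    """Full three-stage pipeline; returns assignments and total rescue rounds.

    After the fallback stage the rescue loop is re-entered (and the fallback
    re-applied) until the assignment set stops growing: fallback assignments
    at chromosome ends and rearrangement junctions provide the anchors that
    pure synteny could not, letting stranded interior genes be rescued.
    """
    qorder, torder = GeneOrder(query_genes), GeneOrder(target_genes)
    ranked = map_top_hits_to_genes(hits, target_genes)
    tops = top_hit_gene(ranked)
    rank_scores: dict[str, list[float]] = {}
    for h in sorted(hits, key=lambda h: (h.query_id, h.rank)):
        rank_scores.setdefault(h.query_id, []).append(h.score)
    assignments = assign_first_pass(qorder, tops, torder)
    assignments, rounds = rescue_iterative(assignments, ranked, qorder, torder,
                                           max_rank=max_rank,
                                           rank_scores=rank_scores)
    top_scores = {q: s[0] for q, s in rank_scores.items() if s}
    for _ in range(max_outer_loops):
        before = sum(1 for a in assignments.values() if a.target_gene_id)
        live = pending_window_candidates(assignments, ranked, qorder, torder,
                                         max_rank)
        # reserve only uncontested candidates: a target wanted by several
        # pending queries cannot be resolved by synteny, so the fallback's
        # sequence evidence is allowed to break the tie
        want_count: dict[str, int] = {}
        for cands in live.values():
            for t in cands:
                want_count[t] = want_count.get(t, 0) + 1
        reserved = {t for t, n in want_count.items() if n == 1}
        assignments = assign_non_syntenic(assignments, tops, target_genes,
                                          reserved=reserved,
                                          top_scores=top_scores)
        assignments, r = rescue_iterative(assignments, ranked, qorder, torder,
                                          max_rank=max_rank,
                                          rank_scores=rank_scores)
        rounds += r
        if sum(1 for a in assignments.values() if a.target_gene_id) == before:
            break
    check_unique_targets(assignments)
    return assignments, rounds


def check_unique_targets(assignments: dict[str, OrthologAssignment]) -> None:
    seen: dict[str, str] = {}
    for a in assignments.values():
        if a.target_gene_id is None:
            continue
        if a.target_gene_id in seen:
            raise AssertionError(
                f"target {a.target_gene_id} claimed by {seen[a.target_gene_id]} "
                f"and {a.query_gene_id}")
        seen[a.target_gene_id] = a.query_gene_id


# ---------------------------------------------------------------- tRNA rule

def trna_synteny(query_trnas: list[TRNAModel], target_trnas: list[TRNAModel],
                 assignments: dict[str, OrthologAssignment],
                 query_genes: list[GeneModel], target_genes: list[GeneModel],
                 ) -> dict[str, str]:
    """A target tRNA is syntenic iff its flanking protein genes are syntenic
    assignments and a query tRNA lies between those genes' partners."""
    t_by_chrom: dict[str, list[GeneModel]] = {}
    for g in target_genes:
        t_by_chrom.setdefault(g.chrom_id, []).append(g)
    for gs in t_by_chrom.values():
        gs.sort(key=lambda g: g.start)
    q_by_id = {g.gene_id: g for g in query_genes}
    partner_of_target = {a.target_gene_id: a.query_gene_id
                         for a in assignments.values()
                         if a.target_gene_id is not None
                         and a.assignment_class in SYNTENIC_CLASSES}
    out: dict[str, str] = {}
    for t in target_trnas:
        genes = t_by_chrom.get(t.chrom_id, [])
        left = next((g for g in reversed(genes) if g.end <= t.start), None)
        right = next((g for g in genes if g.start >= t.end), None)
        label = "non_syntenic"
        if left is not None and right is not None:
            ql = partner_of_target.get(left.gene_id)
            qr = partner_of_target.get(right.gene_id)
            if ql is not None and qr is not None:
                gl, gr = q_by_id[ql], q_by_id[qr]
                if gl.chrom_id == gr.chrom_id:
                    lo = min(gl.end, gr.end)
                    hi = max(gl.start, gr.start)
                    for qt in query_trnas:
                        if qt.chrom_id == gl.chrom_id and lo <= qt.start and qt.end <= hi:
                            label = "syntenic"
                            break
        out[t.trna_id] = label
    return out


# ---------------------------------------------------------------- classification

def classify_predictions(assignments: dict[str, OrthologAssignment],
                         target_genes: list[GeneModel],
                         denovo_genes: list[GeneModel],
                         reference_hit: dict[str, bool]) -> dict[str, str]:
    """Partition target gene predictions into syntenic / non-syntenic homolog
    / no-reference-hit classes.  De novo predictions overlapping a
    homology-based prediction (>=1 bp, either strand) are dropped as
    redundant rather than classified twice."""
    syntenic_targets = {a.target_gene_id for a in assignments.values()
                       if a.assignment_class in SYNTENIC_CLASSES}
    trees: dict[str, IntervalTree] = {}
    for g in target_genes:
        t = trees.setdefault(g.chrom_id, IntervalTree())
        for s, e in g.exons:
            t.addi(s, e, g.gene_id)
    out: dict[str, str] = {}
    for g in target_genes:
        if g.gene_id in syntenic_targets:
            out[g.gene_id] = "syntenic"
        elif reference_hit.get(g.gene_id, False):
            out[g.gene_id] = "non_syntenic_homolog"
        else:
            out[g.gene_id] = "no_reference_hit"
    for g in denovo_genes:
        overlapping = any(
            trees.get(g.chrom_id, IntervalTree()).overlap(s, e)
            for s, e in g.exons)
        if overlapping:
            continue
        out[g.gene_id] = ("non_syntenic_homolog"
                          if reference_hit.get(g.gene_id, False)
                          else "no_reference_hit")
    return out


# ---------------------------------------------------------------- enrichment

FLAGGED_CLASSES = ("non_syntenic_homolog", "no_reference_hit")


def decile_enrichment(gene_classes: dict[str, str],
                      genes: list[GeneModel] | list[object],
                      chrom_lengths: dict[str, int],
                      decile_fraction: float = 0.1,
                      ) -> tuple[dict[str, np.ndarray], float]:
    """Bin genes by midpoint into 10 equal-length chromosome bins and test
    enrichment of non-syntenic/novel genes in the terminal bins.

    Returns per-class decile fractions (each row sums to 1) and the one-sided
    hypergeometric tail p-value for the terminal bins.
    """
    n_bins = int(round(1.0 / decile_fraction))
    for c, L in chrom_lengths.items():
        if L < 10:
            raise ValueError(f"chromosome {c} shorter than 10 bp")
    by_id = {g.gene_id: g for g in genes}
    decile_of: dict[str, int] = {}
    for gid in gene_classes:
        g = by_id[gid]
        L = chrom_lengths[g.chrom_id]
        d = min(int(g.midpoint() / L * n_bins), n_bins - 1)
        decile_of[gid] = d
    counts: dict[str, np.ndarray] = {}
    for gid, cls in gene_classes.items():
        counts.setdefault(cls, np.zeros(n_bins))[decile_of[gid]] += 1
    fractions = {cls: (v / v.sum() if v.sum() else v) for cls, v in counts.items()}

    N = len(gene_classes)
    K = sum(1 for c in gene_classes.values() if c in FLAGGED_CLASSES)
    terminal = {0, n_bins - 1}
    n_term = sum(1 for gid in gene_classes if decile_of[gid] in terminal)
    k_term = sum(1 for gid, c in gene_classes.items()
                 if decile_of[gid] in terminal and c in FLAGGED_CLASSES)
    # P(X >= k_term) drawing n_term genes from N with K flagged
    p = float(hypergeom.sf(k_term - 1, N, K, n_term))
    return fractions, p
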