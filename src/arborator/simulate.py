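"""Synthetic genome pairs with known ground truth.

Generates an ancestral gene-dense genome and evolves a descendant from it by
substitutions, gene losses, inversions, a reciprocal translocation, and
homopolymer-biased ±1 bp indels (the pyrosequencing error mode).  Everything
is recorded in a TruthTable so downstream stages can be scored exactly.

Also provides ranked noisy hit tables (aligner stand-in), depth tracks with
variant calls (read-mapping stand-in) and three-phase growth curves.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .model import GeneModel, GenomeSequence, HitRecord, TRNAModel, VariantCall, revcomp
from .io import rank_hits

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"


# ------------------------------------------------------------------ types

@dataclass
class EvolutionParams:
    sub_rate: float = 0.0
    hp_indel_rate: float = 0.0
    gene_loss_prob: float = 0.0
    n_inversions: int = 0
    n_translocations: int = 0
    a_bias: float = 1.0
    min_homopolymer_run: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "hp_indel_rate", "gene_loss_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_inversions < 0 or self.n_translocations < 0:
            raise ValueError("event counts must be >= 0")


@dataclass
class RearrangementTruth:
    type: str                      # "inversion" | "reciprocal_translocation"
    chroms: list[str]              # derived chromosome ids involved
    # per junction: (chrom, left_gene_id or None, right_gene_id or None),
    # gene ids in *derived* naming, flanking the breakpoint in derived order
    junctions: list[tuple[str, str | None, str | None]]


@dataclass
class PlantedIndel:
    chrom_id: str
    pos: int                       # position in the final derived genome
    delta: int                     # +1 insertion, -1 deletion
    base: str                      # homopolymer base (derived forward strand)
    run_len: int                   # run length before the edit
    run_start: int                 # run interval in the final derived genome
    run_end: int
    gene_id: str | None            # derived gene id if inside a gene


@dataclass
class TruthTable:
    ortholog_pairs: dict[str, str] = field(default_factory=dict)
    lost_genes: set[str] = field(default_factory=set)
    rearrangements: list[RearrangementTruth] = field(default_factory=list)
    planted_indels: list[PlantedIndel] = field(default_factory=list)
    n_substitutions: int = 0

    def to_json(self, path: str | Path) -> None:
        obj = {"ortholog_pairs": self.ortholog_pairs,
               "lost_genes": sorted(self.lost_genes),
               "rearrangements": [asdict(r) for r in self.rearrangements],
               "planted_indels": [asdict(i) for i in self.planted_indels],
               "n_substitutions": self.n_substitutions}
        Path(path).write_text(json.dumps(obj, indent=1))


# ------------------------------------------------------------------ ancestor

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    body = []
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice(list(BASES), 3))
            if codon not in STOPS:
                break
        body.append(codon)
    return "ATG" + "".join(body) + STOPS[rng.integers(3)]


def _spacer(rng: np.random.Generator, mean_len: int) -> str:
    """Intergenic spacer with 1-2 planted homopolymer runs (len 3-12)."""
    n = max(20, int(rng.poisson(mean_len)))
    seq = list(rng.choice(list(BASES), n))
    for _ in range(int(rng.integers(1, 3))):
        run_len = int(np.clip(3 + rng.geometric(0.35) - 1, 3, 12))
        if run_len + 2 >= n:
            continue
        start = int(rng.integers(1, n - run_len - 1))
        base = BASES[rng.integers(4)]
        seq[start:start + run_len] = base * run_len
    return "".join(seq)


def simulate_ancestor(n_chrom: int, genes_per_chrom: int,
                      intergenic_len_mean: int = 200, rng_seed: int = 0,
                      gene_len_codons: tuple[int, int] = (40, 120),
                      ) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Gene-dense ancestral genome: ATG..stop ORFs separated by spacers."""
    if n_chrom < 1 or genes_per_chrom < 3:
        raise ValueError("need >= 1 chromosome and >= 3 genes per chromosome")
    if intergenic_len_mean < 20 or gene_len_codons[0] < 3:
        raise ValueError("infeasible lengths")
    rng = np.random.default_rng(rng_seed)
    genome, genes = [], []
    for ci in range(n_chrom):
        chrom_id = f"chr{ci + 1}"
        parts = [_spacer(rng, intergenic_len_mean)]
        pos = len(parts[0])
        for gi in range(genes_per_chrom):
            n_codons = int(rng.integers(gene_len_codons[0], gene_len_codons[1] + 1))
            cds = _random_cds(rng, n_codons)
            strand = "+" if rng.random() < 0.5 else "-"
            gseq = cds if strand == "+" else revcomp(cds)
            genes.append(GeneModel(f"g{ci + 1}_{gi + 1}", chrom_id, strand,
                                   [(pos, pos + len(gseq))]))
            parts.append(gseq)
            pos += len(gseq)
            sp = _spacer(rng, intergenic_len_mean)
            parts.append(sp)
            pos += len(sp)
        genome.append(GenomeSequence(chrom_id, "".join(parts)))
    return genome, genes


# ------------------------------------------------------------------ evolution

@dataclass
class _Seg:
    kind: str                      # "gene" | "spacer"
    seq: str
    gene_id: str | None = None
    strand: str | None = None


def _segments(genome: list[GenomeSequence], genes: list[GeneModel]
              ) -> dict[str, list[_Seg]]:
    """Decompose each chromosome into alternating spacer/gene segments."""
    by_chrom: dict[str, list[GeneModel]] = {g.chrom_id: [] for g in genes}
    for g in genes:
        if g.has_intron:
            raise ValueError("evolve() supports single-exon genes only")
        by_chrom[g.chrom_id].append(g)
    segs: dict[str, list[_Seg]] = {}
    for rec in genome:
        out, pos = [], 0
        for g in sorted(by_chrom.get(rec.chrom_id, []), key=lambda g: g.start):
            out.append(_Seg("spacer", rec.seq[pos:g.start]))
            out.append(_Seg("gene", rec.seq[g.start:g.end], g.gene_id, g.strand))
            pos = g.end
        out.append(_Seg("spacer", rec.seq[pos:]))
        segs[rec.chrom_id] = out
    return segs


def _substitute_gene(rng: np.random.Generator, seg: _Seg, rate: float) -> int:
    """Substitutions inside a CDS, sparing start/stop codons and never
    creating an in-frame stop."""
    cds = list(seg.seq if seg.strand == "+" else revcomp(seg.seq))
    n = 0
    for i in range(3, len(cds) - 3):
        if rng.random() >= rate:
            continue
        codon_start = (i // 3) * 3
        old = cds[i]
        for b in rng.permutation(list(BASES)):
            if b == old:
                continue
            cds[i] = b
            codon = "".join(cds[codon_start:codon_start + 3])
            if codon not in STOPS:
                n += 1
                break
            cds[i] = old
    new = "".join(cds)
    seg.seq = new if seg.strand == "+" else revcomp(new)
    return n


def _substitute_spacer(rng: np.random.Generator, seg: _Seg, rate: float) -> int:
    seq = list(seg.seq)
    n = 0
    for i, c in enumerate(seq):
        if c != "N" and rng.random() < rate:
            choices = [b for b in BASES if b != c]
            seq[i] = choices[rng.integers(3)]
            n += 1
    seg.seq = "".join(seq)
    return n


def _gene_indices(segs: list[_Seg]) -> list[int]:
    return [i for i, s in enumerate(segs) if s.kind == "gene"]


def evolve(genome: list[GenomeSequence], genes: list[GeneModel],
           params: EvolutionParams
           ) -> tuple[list[GenomeSequence], list[GeneModel], TruthTable]:
    """Derive a descendant genome; record everything in a TruthTable.

    Order of events: gene loss -> substitutions -> inversions ->
    reciprocal translocations -> homopolymer indels.  Derived chromosomes
    are named ``d_<ancestral id>`` and derived genes ``t_<ancestral id>``.
    """
    rng = np.random.default_rng(params.rng_seed)
    truth = TruthTable()
    segs = _segments(genome, genes)
    chrom_ids = [r.chrom_id for r in genome]
    if params.n_translocations > len(chrom_ids) // 2:
        raise ValueError("n_translocations exceeds floor(n_chrom/2)")

    # --- gene loss
    for cid in chrom_ids:
        kept = []
        for s in segs[cid]:
            if s.kind == "gene" and rng.random() < params.gene_loss_prob:
                truth.lost_genes.add(s.gene_id)
                continue
            kept.append(s)
        # merge adjacent spacers left by excisions
        merged: list[_Seg] = []
        for s in kept:
            if merged and s.kind == "spacer" and merged[-1].kind == "spacer":
                merged[-1].seq += s.seq
            else:
                merged.append(s)
        segs[cid] = merged

    # --- substitutions
    if params.sub_rate > 0:
        for cid in chrom_ids:
            for s in segs[cid]:
                if s.kind == "gene":
                    truth.n_substitutions += _substitute_gene(rng, s, params.sub_rate)
                else:
                    truth.n_substitutions += _substitute_spacer(rng, s, params.sub_rate)

    # --- inversions (>=2 genes, intergenic-bounded)
    used: dict[str, set[int]] = {cid: set() for cid in chrom_ids}
    for _ in range(params.n_inversions):
        placed = False
        for _attempt in range(100):
            cid = chrom_ids[rng.integers(len(chrom_ids))]
            gidx = _gene_indices(segs[cid])
            if len(gidx) < 8:
                continue
            k = int(rng.integers(2, min(6, len(gidx) - 4)))
            # >= 2 flanking genes each side: a 1-gene fragment next to the
            # inverted segment would fall below the synteny-block threshold
            i0 = int(rng.integers(2, len(gidx) - k - 1))
            lo, hi = gidx[i0], gidx[i0 + k - 1]
            if set(range(lo - 3, hi + 4)) & used[cid]:
                continue
            used[cid] |= set(range(lo - 3, hi + 4))  # flanking gene + spacers
            block = segs[cid][lo:hi + 1]
            inv = []
            for s in reversed(block):
                ns = _Seg(s.kind, revcomp(s.seq), s.gene_id,
                          None if s.strand is None else ("+" if s.strand == "-" else "-"))
                inv.append(ns)
            segs[cid][lo:hi + 1] = inv
            left_flank = segs[cid][lo - 2].gene_id if lo >= 2 else None
            right_flank = segs[cid][hi + 2].gene_id if hi + 2 < len(segs[cid]) else None
            dcid = f"d_{cid}"
            truth.rearrangements.append(RearrangementTruth(
                "inversion", [dcid],
                [(dcid, _t(left_flank), _t(inv[0].gene_id)),
                 (dcid, _t(inv[-1].gene_id), _t(right_flank))]))
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place inversion after 100 attempts")

    # --- reciprocal translocations (suffix swap at intergenic breakpoints)
    free = [c for c in chrom_ids]
    for _ in range(params.n_translocations):
        placed = False
        for _attempt in range(100):
            if len(free) < 2:
                break
            ca, cb = (str(x) for x in rng.choice(free, size=2, replace=False))
            ga, gb = _gene_indices(segs[ca]), _gene_indices(segs[cb])
            if len(ga) < 4 or len(gb) < 4:
                continue
            # split inside an internal spacer, leaving >= 2 genes on every
            # arm (single-gene arms are invisible in gene-order space)
            ia = int(rng.integers(2, len(ga) - 1))   # break before gene ga[ia]
            ib = int(rng.integers(2, len(gb) - 1))
            spa, spb = ga[ia] - 1, gb[ib] - 1    # spacer segment indices
            if spa in used[ca] or spb in used[cb]:
                continue
            sa, sb = segs[ca][spa], segs[cb][spb]
            offa = int(rng.integers(1, len(sa.seq))) if len(sa.seq) > 1 else 0
            offb = int(rng.integers(1, len(sb.seq))) if len(sb.seq) > 1 else 0
            a_pre = segs[ca][:spa] + [_Seg("spacer", sa.seq[:offa])]
            a_suf = [_Seg("spacer", sa.seq[offa:])] + segs[ca][spa + 1:]
            b_pre = segs[cb][:spb] + [_Seg("spacer", sb.seq[:offb])]
            b_suf = [_Seg("spacer", sb.seq[offb:])] + segs[cb][spb + 1:]
            segs[ca] = a_pre + b_suf
            segs[cb] = b_pre + a_suf
            da, db = f"d_{ca}", f"d_{cb}"
            truth.rearrangements.append(RearrangementTruth(
                "reciprocal_translocation", [da, db],
                [(da, _t(segs[ca][spa - 1].gene_id), _t(segs[ca][spa + 2].gene_id)),
                 (db, _t(segs[cb][spb - 1].gene_id), _t(segs[cb][spb + 2].gene_id))]))
            free.remove(ca)
            free.remove(cb)
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place translocation after 100 attempts")

    # --- lay out derived genome and annotations
    derived_genome: list[GenomeSequence] = []
    derived_genes: list[GeneModel] = []
    for cid in chrom_ids:
        dcid = f"d_{cid}"
        pos, parts = 0, []
        for s in segs[cid]:
            if s.kind == "gene":
                did = _t(s.gene_id)
                derived_genes.append(GeneModel(did, dcid, s.strand,
                                               [(pos, pos + len(s.seq))]))
                truth.ortholog_pairs[s.gene_id] = did
            parts.append(s.seq)
            pos += len(s.seq)
        derived_genome.append(GenomeSequence(dcid, "".join(parts)))

    # junction chroms recorded at event time may be stale after a later
    # translocation moved the segment; fix them up from the final annotation
    chrom_of = {g.gene_id: g.chrom_id for g in derived_genes}
    for r in truth.rearrangements:
        r.junctions = [(chrom_of.get(lg) or chrom_of.get(rg) or ch, lg, rg)
                       for (ch, lg, rg) in r.junctions]
        r.chroms = sorted({ch for ch, _, _ in r.junctions})

    # --- homopolymer indels on the laid-out genome
    if params.hp_indel_rate > 0:
        derived_genome, derived_genes, planted = plant_homopolymer_indels(
            derived_genome, derived_genes, rate=params.hp_indel_rate,
            a_bias=params.a_bias, min_run=params.min_homopolymer_run, rng=rng)
        truth.planted_indels = planted
    return derived_genome, derived_genes, truth


def _t(gene_id: str | None) -> str | None:
    return None if gene_id is None else f"t_{gene_id}"


# ------------------------------------------------------------------ hp indels

_RUN_RE = re.compile(r"(A+|C+|G+|T+)")


def homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int, str]]:
    """Maximal single-base runs of length >= min_run as (start, end, base)."""
    return [(m.start(), m.end(), m.group(0)[0])
            for m in _RUN_RE.finditer(seq) if m.end() - m.start() >= min_run]


def plant_homopolymer_indels(genome: list[GenomeSequence], genes: list[GeneModel],
                             rate: float, a_bias: float, min_run: int,
                             rng: np.random.Generator,
                             n_exact: int | None = None,
                             ) -> tuple[list[GenomeSequence], list[GeneModel],
                                        list[PlantedIndel]]:
    """±1 bp miscount errors inside homopolymer runs.

    Per run of length >= min_run, an indel is planted with probability
    ``rate * a_bias`` for A/T runs and ``rate`` for C/G runs (clipped to 1).
    With ``n_exact`` set, exactly that many runs are edited instead (chosen
    with the same A/T bias as weights).
    """
    out_genome, out_genes, planted = [], [], []
    gene_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom_id, []).append(g)

    # choose runs; runs overlapping a gene boundary (±6 bp) are not edited so
    # that every genic error sits strictly inside its gene's reading frame
    chosen: dict[str, list[tuple[int, int, str, int]]] = {}
    all_runs = []
    margins: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        margins.setdefault(g.chrom_id, []).extend(
            [(g.start - 1, g.start + 6), (g.end - 6, g.end + 1)])
    for rec in genome:
        mg = margins.get(rec.chrom_id, [])
        for (s, e, b) in homopolymer_runs(rec.seq, min_run):
            if any(s < hi and lo < e for lo, hi in mg):
                continue
            all_runs.append((rec.chrom_id, s, e, b))
    if n_exact is not None:
        if n_exact > len(all_runs):
            raise ValueError(f"only {len(all_runs)} runs available for "
                             f"{n_exact} exact indels")
        w = np.array([a_bias if b in "AT" else 1.0 for _, _, _, b in all_runs])
        idx = rng.choice(len(all_runs), size=n_exact, replace=False, p=w / w.sum())
        picks = [all_runs[i] for i in idx]
    else:
        picks = [r for r in all_runs
                 if rng.random() < min(1.0, rate * (a_bias if r[3] in "AT" else 1.0))]
    for cid, s, e, b in picks:
        delta = 1 if rng.random() < 0.5 else -1
        chosen.setdefault(cid, []).append((s, e, b, delta))

    for rec in genome:
        edits = sorted(chosen.get(rec.chrom_id, []))
        seq = rec.seq
        cg = sorted(gene_by_chrom.get(rec.chrom_id, []), key=lambda g: g.start)
        shift = 0
        new_edits = []
        # apply left-to-right, tracking the cumulative shift
        chunks, last = [], 0
        for (s, e, b, delta) in edits:
            p = int((s + e) // 2)  # edit in the middle of the run
            chunks.append(seq[last:p])
            if delta == 1:
                chunks.append(b)   # duplicate one run base before p
                last = p
            else:
                last = p + 1       # drop the run base at p
            new_edits.append((p, s, e, b, delta, shift))
            shift += delta
        chunks.append(seq[last:])
        new_seq = "".join(chunks)

        # shift gene coordinates; indel inside a gene stretches/shrinks it
        shifted_genes = []
        for g in cg:
            gs, ge = g.start, g.end
            for (p, s, e, b, delta, _sh) in new_edits:
                if p < gs:
                    gs += delta
                    ge += delta
                elif p < ge:
                    ge += delta
            shifted_genes.append(GeneModel(g.gene_id, g.chrom_id, g.strand,
                                           [(gs, ge)], flags=set(g.flags)))
        # record final coordinates
        for (p, s, e, b, delta, sh) in new_edits:
            host = next((g.gene_id for g in cg if g.start <= p < g.end), None)
            planted.append(PlantedIndel(rec.chrom_id, p + sh, delta, b,
                                        e - s, s + sh, e + sh + delta, host))
        out_genome.append(GenomeSequence(rec.chrom_id, new_seq))
        out_genes.extend(shifted_genes)
    return out_genome, out_genes, planted


def plant_assembly_errors(genome: list[GenomeSequence], genes: list[GeneModel],
                          n_substitutions: int, n_indels: int,
                          min_run: int = 3, a_bias: float = 3.0,
                          rng_seed: int = 0,
                          ) -> tuple[list[GenomeSequence], list[GeneModel],
                                     TruthTable]:
    """Plant an exact number of base substitutions and homopolymer indels.

    Emulates raw pyrosequencing assembly errors on an otherwise-true genome;
    the return is the erroneous assembly plus the truth record.
    """
    rng = np.random.default_rng(rng_seed)
    truth = TruthTable(ortholog_pairs={g.gene_id: g.gene_id for g in genes})
    # substitutions first (positions away from any run edited later are
    # irrelevant; coordinates are still final since indels shift later)
    sub_genome = []
    n_left = n_substitutions
    lens = np.array([len(r.seq) for r in genome], dtype=float)
    per_chrom = rng.multinomial(n_substitutions, lens / lens.sum())
    for rec, k in zip(genome, per_chrom):
        seq = list(rec.seq)
        pos = rng.choice(len(seq), size=int(k), replace=False)
        for p in pos:
            old = seq[p]
            if old == "N":
                continue
            choices = [b for b in BASES if b != old]
            seq[p] = choices[rng.integers(3)]
            n_left -= 1
        sub_genome.append(GenomeSequence(rec.chrom_id, "".join(seq)))
    truth.n_substitutions = n_substitutions - max(n_left, 0)
    err_genome, err_genes, planted = plant_homopolymer_indels(
        sub_genome, genes, rate=0.0, a_bias=a_bias, min_run=min_run,
        rng=rng, n_exact=n_indels)
    truth.planted_indels = planted
    return err_genome, err_genes, truth


# ------------------------------------------------------------------ hit tables

def make_hit_table(query_genes: list[GeneModel], target_genes: list[GeneModel],
                   truth: TruthTable, decoy_prob: float = 0.0,
                   score_jitter: float = 2.0, rank_swap_prob: float = 0.0,
                   rng_seed: int = 0) -> list[HitRecord]:
    """Ranked noisy protein-to-genome hits.

    Every query with a surviving ortholog gets a hit at the true locus; with
    ``decoy_prob`` a *higher-scoring* decoy at another gene's locus is added,
    so the rank-1 hit is then not the true ortholog (rescue must recover it).
    """
    for p in (decoy_prob, rank_swap_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("noise probabilities must be in [0,1]")
    rng = np.random.default_rng(rng_seed)
    tg = {g.gene_id: g for g in target_genes}
    hits: list[HitRecord] = []
    for q in query_genes:
        partner = truth.ortholog_pairs.get(q.gene_id)
        if partner is not None and partner in tg:
            t = tg[partner]
            base = 100.0 + rng.normal(0, score_jitter)
            hits.append(HitRecord(q.gene_id, t.chrom_id, t.start, t.end,
                                  t.strand, round(base, 3)))
            if rng.random() < decoy_prob:
                d = target_genes[rng.integers(len(target_genes))]
                if d.gene_id != partner:
                    hits.append(HitRecord(q.gene_id, d.chrom_id, d.start, d.end,
                                          d.strand, round(base + 5.0 + rng.random(), 3)))
            n_extra = int(rng.integers(0, 4))
        else:
            base = 60.0
            n_extra = int(rng.integers(1, 4))
        for _ in range(n_extra):
            d = target_genes[rng.integers(len(target_genes))]
            hits.append(HitRecord(q.gene_id, d.chrom_id, d.start, d.end, d.strand,
                                  round(base - 20.0 - 10.0 * rng.random(), 3)))
    # optional adjacent-rank score swaps
    if rank_swap_prob > 0:
        byq: dict[str, list[HitRecord]] = {}
        for h in hits:
            byq.setdefault(h.query_id, []).append(h)
        for hs in byq.values():
            hs.sort(key=lambda h: -h.score)
            for i in range(1, len(hs)):
                if rng.random() < rank_swap_prob:
                    hs[i - 1].score, hs[i].score = hs[i].score, hs[i - 1].score
    return rank_hits(hits)


# ------------------------------------------------------------------ depth & calls

def diff_variants(assembly: list[GenomeSequence], true_genome: list[GenomeSequence],
                  support: float = 0.9) -> list[VariantCall]:
    """Exact variant calls (in assembly coordinates) restoring the true genome.

    Alignment-based: edlib global alignment per chromosome; mismatches become
    SNPs, assembly-only bases deletions, truth-only bases insertions.
    """
    tru = {r.chrom_id: r.seq for r in true_genome}
    calls: list[VariantCall] = []
    for rec in assembly:
        t = tru[rec.chrom_id]
        if rec.seq == t:
            continue
        res = edlib.align(rec.seq, t, mode="NW", task="path")
        qa = tt = 0
        for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
            n = int(n)
            if op == "=":
                qa += n
                tt += n
            elif op == "X":
                for k in range(n):
                    calls.append(VariantCall(rec.chrom_id, qa + k,
                                             rec.seq[qa + k], t[tt + k], support))
                qa += n
                tt += n
            elif op == "I":      # assembly has extra bases -> delete them
                calls.append(VariantCall(rec.chrom_id, qa, rec.seq[qa:qa + n],
                                         "", support))
                qa += n
            else:                # truth has extra bases -> insert before qa
                calls.append(VariantCall(rec.chrom_id, qa, "", t[tt:tt + n],
                                         support))
                tt += n
    return calls


def simulate_depth_and_variants(true_genome: list[GenomeSequence],
                                erroneous_genome: list[GenomeSequence],
                                mean_depth: float = 50.0,
                                error_frac: float = 0.0,
                                rng_seed: int = 0,
                                cn_regions: list[tuple[str, int, int, int]] | None = None,
                                ) -> tuple[dict[str, np.ndarray], list[VariantCall]]:
    """Per-base depth track plus variant calls against the erroneous assembly.

    True discrepancies get Beta-distributed support centred near 0.9; false
    calls are sprinkled at ``error_frac`` per base with support < 0.6.
    ``cn_regions`` (chrom, start, end, copies) raise local expected depth.
    """
    rng = np.random.default_rng(rng_seed)
    depth: dict[str, np.ndarray] = {}
    for rec in erroneous_genome:
        lam = np.full(len(rec.seq), float(mean_depth))
        for (c, s, e, copies) in cn_regions or []:
            if c == rec.chrom_id:
                lam[s:e] *= copies
        depth[rec.chrom_id] = rng.poisson(lam).astype(float)

    calls = diff_variants(erroneous_genome, true_genome)
    for c in calls:
        c.support = float(np.clip(rng.beta(27, 3), 0.0, 1.0))
    if error_frac > 0:
        for rec in erroneous_genome:
            n_false = rng.poisson(error_frac * len(rec.seq))
            for p in rng.choice(len(rec.seq), size=min(n_false, len(rec.seq)),
                                replace=False):
                ref = rec.seq[int(p)]
                if ref == "N":
                    continue
                alt = [b for b in BASES if b != ref][rng.integers(3)]
                calls.append(VariantCall(rec.chrom_id, int(p), ref, alt,
                                         float(rng.uniform(0.2, 0.59))))
    calls.sort(key=lambda c: (c.chrom_id, c.pos))
    return depth, calls


# ------------------------------------------------------------------ tRNAs

def plant_trnas(genome: list[GenomeSequence], genes: list[GeneModel],
                n_per_chrom: int = 3, rng_seed: int = 0) -> list[TRNAModel]:
    """Place tRNA annotations inside intergenic spacers (no sequence edit)."""
    rng = np.random.default_rng(rng_seed)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom_id, []).append(g)
    trnas = []
    k = 0
    for rec in genome:
        cg = sorted(by_chrom.get(rec.chrom_id, []), key=lambda g: g.start)
        gaps = [(a.end, b.start) for a, b in zip(cg, cg[1:]) if b.start - a.end >= 100]
        if not gaps:
            continue
        take = rng.choice(len(gaps), size=min(n_per_chrom, len(gaps)), replace=False)
        for gi in sorted(take):
            lo, hi = gaps[gi]
            length = int(rng.integers(60, 95))
            start = int(rng.integers(lo, hi - length))
            k += 1
            trnas.append(TRNAModel(f"trna{k}", rec.chrom_id,
                                   "+" if rng.random() < 0.5 else "-",
                                   start, start + length,
                                   isotype="ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]))
    return trnas


# ------------------------------------------------------------------ growth curves

def simulate_growth_curve(lag_min: float, doubling_min: float, efficiency_od: float,
                          noise_sd: float = 0.0, rng_seed: int = 0,
                          baseline_od: float = 0.05, interval_min: float = 20.0,
                          duration_min: float = 72 * 60.0) -> pd.DataFrame:
    """Three-phase growth curve sampled every 20 min for 72 h.

    Flat baseline until the lag ends, then exponential doubling, then a hard
    plateau at baseline + efficiency; optional Gaussian OD noise.
    """
    rng = np.random.default_rng(rng_seed)
    t = np.arange(0.0, duration_min + interval_min / 2, interval_min)
    od = np.where(t < lag_min, baseline_od,
                  baseline_od * np.power(2.0, (t - lag_min) / doubling_min))
    od = np.minimum(od, baseline_od + efficiency_od)
    if noise_sd > 0:
        od = np.maximum(od + rng.normal(0.0, noise_sd, od.shape), 1e-4)
    return pd.DataFrame({"time_min": t, "od": od})


# ------------------------------------------------------------------ run directory

def write_run(outdir: str | Path, ancestor: list[GenomeSequence],
              anc_genes: list[GeneModel], derived: list[GenomeSequence],
              der_genes: list[GeneModel], truth: TruthTable,
              hits: list[HitRecord] | None = None,
              calls: list[VariantCall] | None = None) -> None:
    """Write a complete synthetic run directory (FASTA/GFF3/TSV/JSON)."""
    from . import io as _io
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_fasta(ancestor, out / "ancestor.fa")
    _io.write_gff3(anc_genes, out / "ancestor.gff3")
    _io.write_fasta(derived, out / "derived.fa")
    _io.write_gff3(der_genes, out / "derived.gff3")
    truth.to_json(out / "truth.json")
    if hits is not None:
        _io.write_hits_tsv(hits, out / "hits.tsv")
    if calls is not None:
        _io.write_variants_tsv(calls, out / "variants.tsv")
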