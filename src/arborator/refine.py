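"""ORF boundary refinement and frameshift detection with homopolymer context.

Boundary fixes scan in-frame codon windows (default 9 codons) outside the
current prediction; frameshift events are alignment gaps of length not
divisible by 3 inside orthologous coding regions, attributed to the maximal
homopolymer run covering or abutting the gap in either species.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .model import GeneModel, revcomp
from .io import extract_cds
from .simulate import homopolymer_runs

STOPS = ("TAA", "TAG", "TGA")
_CIG = re.compile(r"(\d+)([=XID])")


@dataclass
class FrameshiftEvent:
    gene_id: str
    chrom_id: str
    pos: int                # target genomic coordinate of the gap
    indel_len: int          # target minus query bases; |len| % 3 != 0
    qpos: int = 0           # position in the query CDS (for context lookup)
    in_homopolymer: bool = False
    hp_base: str | None = None
    hp_len: int = 0


# ---------------------------------------------------------------- boundaries

def _downstream_codon(gene: GeneModel, seq: str, k: int) -> str | None:
    """k-th in-frame codon past the CDS 3' end (1-based), mRNA sense."""
    if gene.strand == "+":
        s = gene.end + 3 * (k - 1)
        return seq[s:s + 3] if s + 3 <= len(seq) else None
    s = gene.start - 3 * k
    return revcomp(seq[s:s + 3]) if s >= 0 else None


def _upstream_codon(gene: GeneModel, seq: str, k: int) -> str | None:
    """k-th in-frame codon before the CDS 5' start (1-based), mRNA sense."""
    if gene.strand == "+":
        s = gene.start - 3 * k
        return seq[s:s + 3] if s >= 0 else None
    s = gene.end + 3 * (k - 1)
    return revcomp(seq[s:s + 3]) if s + 3 <= len(seq) else None


def _shift(gene: GeneModel, five_prime: int = 0, three_prime: int = 0) -> GeneModel:
    """New single-exon gene with the 5'/3' boundary moved by N bases
    (positive = extension)."""
    s, e = gene.span
    if gene.strand == "+":
        s, e = s - five_prime, e + three_prime
    else:
        s, e = s - three_prime, e + five_prime
    return GeneModel(gene.gene_id, gene.chrom_id, gene.strand, [(s, e)],
                     flags=set(gene.flags) - {"missing_start" if five_prime else
                                              "missing_stop"})


def fix_stop(gene: GeneModel, genome: dict[str, str], window: int = 9
             ) -> tuple[GeneModel, str]:
    """Extend a stop-less CDS to the first in-frame stop within ``window``
    codons; statuses: corrected / uncorrectable / unchanged."""
    if gene.has_intron:
        return gene, "unchanged"
    seq = genome[gene.chrom_id]
    cds = extract_cds(gene, genome)
    if len(cds) >= 3 and cds[-3:] in STOPS:
        return gene, "unchanged"
    for k in range(1, window + 1):
        codon = _downstream_codon(gene, seq, k)
        if codon is None or len(codon) < 3:
            return gene, "uncorrectable"  # runs past the chromosome end
        if codon in STOPS:
            out = _shift(gene, three_prime=3 * k)
            out.flags.discard("missing_stop")
            return out, "corrected"
    return gene, "uncorrectable"


def fix_start(gene: GeneModel, genome: dict[str, str], window: int = 9
              ) -> tuple[GeneModel, str]:
    """Recover a missing ATG: extend upstream to the first ATG with no
    intervening in-frame stop, else truncate to a downstream ATG; statuses:
    corrected_extend / corrected_truncate / uncorrectable / unchanged."""
    if gene.has_intron:
        return gene, "unchanged"
    seq = genome[gene.chrom_id]
    cds = extract_cds(gene, genome)
    if cds[:3] == "ATG":
        return gene, "unchanged"
    saw_stop = False
    for k in range(1, window + 1):
        codon = _upstream_codon(gene, seq, k)
        if codon is None or len(codon) < 3:
            break
        if codon in STOPS:
            saw_stop = True
            break
        if codon == "ATG":
            out = _shift(gene, five_prime=3 * k)
            out.flags.discard("missing_start")
            return out, "corrected_extend"
    if saw_stop:
        for k in range(1, window + 1):
            if 3 * (k + 1) > len(cds):  # keep at least one codon
                break
            if cds[3 * k:3 * k + 3] == "ATG":
                out = _shift(gene, five_prime=-3 * k)
                out.flags.discard("missing_start")
                return out, "corrected_truncate"
    return gene, "uncorrectable"


# ---------------------------------------------------------------- frameshifts

def detect_frameshifts(query_cds: str, target_cds: str, gene_id: str = "",
                       chrom_id: str = "") -> list[FrameshiftEvent]:
    """Frame-breaking alignment gaps between orthologous coding sequences.

    Positions are coordinates in ``target_cds``; ``indel_len`` is the target
    gain (+) or loss (−).  Gaps touching either sequence's termini are
    boundary artifacts and are skipped.
    """
    res = edlib.align(query_cds, target_cds, mode="NW", task="path")
    ops = [(int(n), op) for n, op in _CIG.findall(res["cigar"])]
    events: list[FrameshiftEvent] = []
    qa = tt = 0
    for i, (n, op) in enumerate(ops):
        if op in "=X":
            qa += n
            tt += n
            continue
        internal = 0 < i < len(ops) - 1 and qa > 0 and tt > 0
        if op == "I":            # query-only bases: deletion in target
            if internal and n % 3:
                events.append(FrameshiftEvent(
                    gene_id, chrom_id, pos=min(tt, len(target_cds) - 1),
                    indel_len=-n, qpos=qa))
            qa += n
        else:                    # 'D': target-only bases: insertion in target
            if internal and n % 3:
                events.append(FrameshiftEvent(
                    gene_id, chrom_id, pos=tt, indel_len=n, qpos=qa))
            tt += n
    return events


def _best_run(seq: str, pos: int, min_len: int = 1) -> tuple[str, int] | None:
    """Longest maximal single-base run covering or abutting ``pos``."""
    best: tuple[int, str] | None = None
    for p in (pos - 1, pos, pos + 1):
        if not 0 <= p < len(seq):
            continue
        b = seq[p]
        lo = p
        while lo > 0 and seq[lo - 1] == b:
            lo -= 1
        hi = p
        while hi + 1 < len(seq) and seq[hi + 1] == b:
            hi += 1
        length = hi - lo + 1
        if length >= min_len and (best is None or length > best[0]):
            best = (length, b)
    return None if best is None else (best[1], best[0])


def homopolymer_context(event: FrameshiftEvent, target_seq: str,
                        query_cds: str | None = None,
                        cds_strand: str = "+",
                        min_run: int = 3) -> FrameshiftEvent:
    """Attribute an event to a homopolymer run (length >= min_run).

    The run is taken from the target sequence at the event position and, if
    longer, from the query CDS (miscounting changes run length between the
    two); the reported base is on the target's forward strand.  ``cds_strand``
    is the strand the CDS orientation corresponds to on the target genome,
    used to express a query-side run base on the target forward strand.
    """
    cand: list[tuple[int, str]] = []
    tr = _best_run(target_seq, event.pos)
    if tr is not None:
        cand.append((tr[1], tr[0]))
    if query_cds is not None:
        qr = _best_run(query_cds, event.qpos)
        if qr is not None:
            base = qr[0] if cds_strand == "+" else revcomp(qr[0])
            cand.append((qr[1], base))
    if cand:
        length, base = max(cand)
        if length >= min_run:
            event.in_homopolymer = True
            event.hp_base = base
            event.hp_len = length
            return event
    event.in_homopolymer = False
    event.hp_base = None
    event.hp_len = 0
    return event


def frameshifts_for_gene_pair(query_gene: GeneModel, query_genome: dict[str, str],
                              target_gene: GeneModel, target_genome: dict[str, str],
                              min_run: int = 3) -> list[FrameshiftEvent]:
    """Detect and annotate frameshifts for one ortholog pair.

    Event positions are mapped back to target genomic coordinates (forward
    strand), so they can be compared against genome-level error records.
    """
    qcds = extract_cds(query_gene, query_genome)
    tcds = extract_cds(target_gene, target_genome)
    events = detect_frameshifts(qcds, tcds, target_gene.gene_id,
                                target_gene.chrom_id)
    tseq = target_genome[target_gene.chrom_id]
    out = []
    for ev in events:
        cpos = ev.pos
        if target_gene.strand == "+":
            ev.pos = target_gene.start + cpos
        else:
            ev.pos = target_gene.end - 1 - cpos
        # context on the genomic forward strand of the target
        ev = homopolymer_context(ev, tseq, query_cds=qcds,
                                 cds_strand=target_gene.strand, min_run=min_run)
        out.append(ev)
    return out


def frameshift_census(pairs: list[tuple[GeneModel, GeneModel]],
                      query_genome: dict[str, str], target_genome: dict[str, str],
                      min_run: int = 3) -> list[FrameshiftEvent]:
    events: list[FrameshiftEvent] = []
    for qg, tg in pairs:
        events.extend(frameshifts_for_gene_pair(qg, query_genome, tg,
                                                target_genome, min_run))
    return events


def frameshift_report(events_by_version: dict[str, list[FrameshiftEvent]]
                      ) -> dict[str, dict]:
    """Per assembly version: ORFs with >=1 frameshift, event counts by
    homopolymer base and by run length (a gene counts once in the ORF total,
    every event counts in the histograms)."""
    report: dict[str, dict] = {}
    for version, events in events_by_version.items():
        by_base = {b: 0 for b in "ACGT"}
        by_len: dict[int, int] = {}
        for ev in events:
            if ev.in_homopolymer:
                by_base[ev.hp_base] += 1
                by_len[ev.hp_len] = by_len.get(ev.hp_len, 0) + 1
        report[version] = {
            "orfs_with_frameshifts": len({ev.gene_id for ev in events}),
            "n_events": len(events),
            "by_base": by_base,
            "by_hp_len": dict(sorted(by_len.items())),
        }
    return report
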