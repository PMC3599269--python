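"""Iterative variant-integration polishing, assembly metrics, coverage windows.

Each polishing round mirrors the two-pass design of hybrid error correction:
SNPs are called and integrated first, the caller is re-run, then indels are
integrated; rounds repeat until a fixed point.  Integrated variants must be
supported by at least 60% of the evidence (``min_support``).
"""
from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass

import numpy as np

from .model import GenomeSequence, VariantCall

log = logging.getLogger(__name__)


@dataclass
class PolishRound:
    round_index: int
    n_snps_applied: int
    n_indels_applied: int
    n_rejected_support: int


@dataclass
class AssemblyMetrics:
    n_contigs: int
    total_len: int
    mean_len: float
    max_len: int
    n50: int


class OscillationError(RuntimeError):
    """The genome state repeated across polishing rounds."""


# ---------------------------------------------------------------- variants

def apply_variants(genome: list[GenomeSequence], calls: list[VariantCall],
                   min_support: float = 0.6,
                   vtypes: tuple[str, ...] = ("SNP", "INS", "DEL"),
                   ) -> tuple[list[GenomeSequence], list[VariantCall]]:
    """Apply supported calls right-to-left per chromosome.

    Overlapping accepted calls: the higher-support one wins (ties by
    position).  A call whose ref allele does not match the assembly is
    rejected and logged, never silently applied.
    """
    eligible = [c for c in calls
                if c.support >= min_support and c.vtype in vtypes]
    by_chrom: dict[str, list[VariantCall]] = {}
    for c in eligible:
        by_chrom.setdefault(c.chrom_id, []).append(c)

    out: list[GenomeSequence] = []
    applied: list[VariantCall] = []
    for rec in genome:
        cs = sorted(by_chrom.get(rec.chrom_id, []),
                    key=lambda c: (-c.support, c.pos))
        accepted: list[VariantCall] = []
        taken: list[tuple[int, int]] = []
        for c in cs:  # greedy overlap resolution, best support first
            span = (c.pos, c.pos + max(len(c.ref), 1))
            if any(span[0] < e and s < span[1] for s, e in taken):
                continue
            accepted.append(c)
            taken.append(span)
        seq = rec.seq
        for c in sorted(accepted, key=lambda c: -c.pos):  # right-to-left
            if c.ref and seq[c.pos:c.pos + len(c.ref)] != c.ref:
                log.warning("%s:%d ref mismatch (%r != %r), call rejected",
                            c.chrom_id, c.pos, c.ref,
                            seq[c.pos:c.pos + len(c.ref)])
                continue
            seq = seq[:c.pos] + c.alt + seq[c.pos + len(c.ref):]
            applied.append(c)
        out.append(GenomeSequence(rec.chrom_id, seq))
    return out, applied


def polish_iterate(genome: list[GenomeSequence], caller,
                   max_rounds: int = 10, min_support: float = 0.6,
                   ) -> tuple[list[GenomeSequence], list[PolishRound]]:
    """SNP-then-indel polishing until no variant is integrated.

    ``caller`` maps a genome to a list of VariantCall.  Raises
    OscillationError if a previously seen genome state recurs.
    """
    seen = {_genome_hash(genome)}
    rounds: list[PolishRound] = []
    for r in range(1, max_rounds + 1):
        calls = caller(genome)
        n_rej = sum(1 for c in calls if c.support < min_support)
        genome, snps = apply_variants(genome, calls, min_support, ("SNP",))
        calls2 = caller(genome)
        n_rej += sum(1 for c in calls2 if c.support < min_support)
        genome, indels = apply_variants(genome, calls2, min_support,
                                        ("INS", "DEL"))
        rounds.append(PolishRound(r, len(snps), len(indels), n_rej))
        if not snps and not indels:
            break
        h = _genome_hash(genome)
        if h in seen:
            raise OscillationError(f"genome state repeated at round {r}")
        seen.add(h)
    return genome, rounds


def _genome_hash(genome: list[GenomeSequence]) -> str:
    h = hashlib.sha256()
    for rec in sorted(genome, key=lambda r: r.chrom_id):
        h.update(rec.chrom_id.encode())
        h.update(rec.seq.encode())
    return h.hexdigest()


# ---------------------------------------------------------------- metrics

def assembly_metrics(contig_lengths: list[int], min_len: int = 500) -> AssemblyMetrics:
    """Contig count/total/mean/max/N50 over contigs >= min_len.

    N50: the largest L such that contigs of length >= L together cover at
    least half the (filtered) total, found on the descending cumulative sum.
    """
    lens = sorted((l for l in contig_lengths if l >= min_len), reverse=True)
    if not lens:
        return AssemblyMetrics(0, 0, 0.0, 0, 0)
    total = sum(lens)
    csum = np.cumsum(lens)
    n50 = lens[int(np.searchsorted(csum, total / 2))]
    return AssemblyMetrics(len(lens), total, total / len(lens), lens[0], int(n50))


def gap_stats(scaffolds: list[GenomeSequence]
              ) -> tuple[int, float, int, int]:
    """(n_gaps, mean, min, max) over maximal 'N' runs across all scaffolds."""
    lengths = [m.end() - m.start()
               for rec in scaffolds for m in re.finditer(r"N+", rec.seq)]
    if not lengths:
        return 0, 0.0, 0, 0
    return len(lengths), float(np.mean(lengths)), min(lengths), max(lengths)


# ---------------------------------------------------------------- coverage

def coverage_windows(depth: dict[str, np.ndarray], window: int = 1000
                     ) -> list[tuple[str, int, int, float]]:
    """log2(window mean depth / genome-wide mean) in non-overlapping windows.

    A trailing window shorter than half the window size is merged into the
    previous one.
    """
    total = sum(float(d.sum()) for d in depth.values())
    n = sum(len(d) for d in depth.values())
    if n == 0:
        return []
    gmean = total / n
    out = []
    for chrom in sorted(depth):
        d = np.asarray(depth[chrom], dtype=float)
        edges = list(range(0, len(d), window))
        bounds = [(s, min(s + window, len(d))) for s in edges]
        if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < window / 2:
            last = bounds.pop()
            bounds[-1] = (bounds[-1][0], last[1])
        for s, e in bounds:
            ratio = d[s:e].mean() / gmean if gmean > 0 else np.nan
            out.append((chrom, s, e, float(np.log2(ratio)) if ratio > 0 else -np.inf))
    return out
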