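"""ORF boundary fixes (with an independent brute-force oracle) and
frameshift detection with homopolymer attribution."""
import numpy as np
import pytest

from arborator import refine, simulate as sim
from arborator.io import extract_cds
from arborator.model import GeneModel, genome_dict, revcomp

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"


# ---------------------------------------------------------------- oracles

def oracle_fix_stop(gene, genome, window=9):
    """Straight re-implementation on the mRNA-sense string."""
    seq = genome[gene.chrom_id]
    cds = extract_cds(gene, genome)
    if cds[-3:] in STOPS:
        return None, "unchanged"
    # mRNA-sense downstream context
    if gene.strand == "+":
        ctx = seq[gene.end:]
    else:
        ctx = revcomp(seq[:gene.start])
    for k in range(1, window + 1):
        codon = ctx[3 * (k - 1):3 * k]
        if len(codon) < 3:
            return None, "uncorrectable"
        if codon in STOPS:
            return 3 * k, "corrected"
    return None, "uncorrectable"


def oracle_fix_start(gene, genome, window=9):
    seq = genome[gene.chrom_id]
    cds = extract_cds(gene, genome)
    if cds[:3] == "ATG":
        return None, "unchanged"
    up = revcomp(seq[gene.end:]) if gene.strand == "-" else seq[:gene.start]
    # upstream codons nearest-first, in mRNA sense
    saw_stop = False
    for k in range(1, window + 1):
        lo = len(up) - 3 * k
        if lo < 0:
            break
        codon = up[lo:lo + 3] if gene.strand == "+" else \
            revcomp(seq[gene.end + 3 * (k - 1):gene.end + 3 * k])
        if gene.strand == "-":
            if gene.end + 3 * k > len(seq):
                break
        if codon in STOPS:
            saw_stop = True
            break
        if codon == "ATG":
            return 3 * k, "corrected_extend"
    if saw_stop:
        for k in range(1, window + 1):
            if 3 * (k + 1) > len(cds):
                break
            if cds[3 * k:3 * k + 3] == "ATG":
                return -3 * k, "corrected_truncate"
    return None, "uncorrectable"


def _random_gene(rng, chrom_len=400):
    seq = "".join(rng.choice(list(BASES), chrom_len))
    n_codons = int(rng.integers(4, 20))
    start = int(rng.integers(0, chrom_len - 3 * n_codons))
    strand = "+" if rng.random() < 0.5 else "-"
    g = GeneModel("g", "c", strand, [(start, start + 3 * n_codons)])
    return g, {"c": seq}


class TestFixStop:
    def test_extension_example(self):
        genome = {"c": "ATGAAACCC" + "GCTTAA" + "ACGT"}
        g = GeneModel("g", "c", "+", [(0, 9)], flags={"missing_stop"})
        g2, status = refine.fix_stop(g, genome)
        assert status == "corrected"
        assert g2.end == 15
        assert extract_cds(g2, genome)[-3:] == "TAA"

    def test_no_stop_within_window(self):
        genome = {"c": "ATGAAACCC" + "GCA" * 9 + "TAAACGT"}
        g = GeneModel("g", "c", "+", [(0, 9)])
        _, status = refine.fix_stop(g, genome)
        assert status == "uncorrectable"

    def test_already_has_stop(self):
        genome = {"c": "ATGGCTTAAACG"}
        g = GeneModel("g", "c", "+", [(0, 9)])
        assert refine.fix_stop(g, genome)[1] == "unchanged"

    def test_chromosome_end(self):
        genome = {"c": "ATGAAACCCGC"}
        g = GeneModel("g", "c", "+", [(0, 9)])
        assert refine.fix_stop(g, genome)[1] == "uncorrectable"

    def test_oracle_agreement_randomized(self, rng):
        statuses = {"corrected": 0, "uncorrectable": 0, "unchanged": 0}
        for _ in range(3000):
            g, genome = _random_gene(rng)
            g2, status = refine.fix_stop(g, genome)
            delta, ostatus = oracle_fix_stop(g, genome)
            assert status == ostatus, (g.strand, g.span)
            statuses[status] += 1
            if status == "corrected":
                assert g2.cds_len == g.cds_len + delta
                assert extract_cds(g2, genome)[-3:] in STOPS
                assert g2.strand == g.strand and g2.chrom_id == g.chrom_id
                assert g2.cds_len - g.cds_len <= 9 * 3
        assert statuses["corrected"] + statuses["uncorrectable"] + \
            statuses["unchanged"] == 3000


class TestFixStart:
    def test_extension_example(self):
        genome = {"c": "ATG" + "GCAGCAGCA"[3:] + "GCAAAACCCTAA"}
        genome = {"c": "ATGGCCGCA" + "AAACCCTAA"}
        g = GeneModel("g", "c", "+", [(9, 18)], flags={"missing_start"})
        g2, status = refine.fix_start(g, genome)
        assert status == "corrected_extend"
        assert g2.start == 0
        assert extract_cds(g2, genome)[:3] == "ATG"

    def test_truncation_when_upstream_stop(self):
        # upstream: stop codon immediately before; downstream ATG at codon 2
        genome = {"c": "TAA" + "GCAATGCCCAAATAA"}
        g = GeneModel("g", "c", "+", [(3, 18)])
        g2, status = refine.fix_start(g, genome)
        assert status == "corrected_truncate"
        assert extract_cds(g2, genome)[:3] == "ATG"
        assert g2.start == 6

    def test_oracle_agreement_randomized(self, rng):
        counts = {}
        for _ in range(3000):
            g, genome = _random_gene(rng)
            g2, status = refine.fix_start(g, genome)
            delta, ostatus = oracle_fix_start(g, genome)
            assert status == ostatus, (g.strand, g.span, status, ostatus)
            counts[status] = counts.get(status, 0) + 1
            if status.startswith("corrected"):
                assert extract_cds(g2, genome)[:3] == "ATG"
                assert abs(g2.cds_len - g.cds_len) <= 9 * 3
        assert sum(counts.values()) == 3000
        assert set(counts) >= {"corrected_extend", "uncorrectable"}


class TestDetectFrameshifts:
    def test_single_deletion(self):
        q = "ATGAAACCCGGGTTTTAA"
        t = q[:8] + q[9:]  # 1-bp deletion mid-CDS
        events = refine.detect_frameshifts(q, t)
        assert len(events) == 1
        assert events[0].indel_len == -1

    def test_in_frame_gap_ignored(self):
        q = "ATGAAACCCGGGTTTTAA"
        t = q[:9] + q[12:]  # 3-bp deletion
        assert refine.detect_frameshifts(q, t) == []

    def test_terminal_gap_ignored(self):
        q = "ATGAAACCCGGGTTTTAA"
        t = q[1:]
        assert refine.detect_frameshifts(q, t) == []

    def test_insertion_sign(self):
        q = "ATGAAACCCGGGTTTTAA"
        t = q[:10] + "G" + q[10:]
        events = refine.detect_frameshifts(q, t)
        assert len(events) == 1 and events[0].indel_len == 1


class TestHomopolymerContext:
    def test_inside_run(self):
        ev = refine.FrameshiftEvent("g", "c", pos=6, indel_len=1, qpos=6)
        ev = refine.homopolymer_context(ev, "GCGC" + "AAAAAA" + "GCGC")
        assert ev.in_homopolymer and ev.hp_base == "A" and ev.hp_len == 6

    def test_no_run(self):
        ev = refine.FrameshiftEvent("g", "c", pos=2, indel_len=1, qpos=2)
        ev = refine.homopolymer_context(ev, "ACGTACGT")
        assert not ev.in_homopolymer and ev.hp_base is None

    def test_longer_query_run_wins(self):
        # deletion shrank the target run below threshold; query run counts
        ev = refine.FrameshiftEvent("g", "c", pos=4, indel_len=-1, qpos=4)
        ev = refine.homopolymer_context(ev, "GCGC" + "AA" + "GCGC",
                                        query_cds="GCGC" + "AAA" + "GCGC")
        assert ev.in_homopolymer and ev.hp_len == 3


class TestCensusClosedLoop:
    def test_precision_recall_on_planted_indels(self):
        genome, genes = sim.simulate_ancestor(2, 80, 250, rng_seed=41)
        derived, dgenes, truth = sim.evolve(
            genome, genes,
            sim.EvolutionParams(hp_indel_rate=0.01, a_bias=3.0, rng_seed=42))
        genic = [pi for pi in truth.planted_indels if pi.gene_id is not None]
        assert genic, "generator planted no genic indels"
        qg, tg = genome_dict(genome), genome_dict(derived)
        dg_by = {g.gene_id: g for g in dgenes}
        pairs = [(q, dg_by[truth.ortholog_pairs[q.gene_id]]) for q in genes
                 if q.gene_id in truth.ortholog_pairs]
        events = refine.frameshift_census(pairs, qg, tg)
        matched, fp = set(), 0
        for ev in events:
            hit = next(((pi.chrom_id, pi.run_start) for pi in genic
                        if ev.chrom_id == pi.chrom_id
                        and pi.run_start - 2 <= ev.pos <= pi.run_end + 2), None)
            if hit is None:
                fp += 1
            else:
                matched.add(hit)
        assert fp == 0
        assert len(matched) == len(genic)
        assert all(ev.in_homopolymer for ev in events)


class TestReport:
    def test_empty(self):
        rep = refine.frameshift_report({"v1": []})
        assert rep["v1"]["orfs_with_frameshifts"] == 0
        assert sum(rep["v1"]["by_base"].values()) == 0

    def test_gene_counts_once_events_count_each(self):
        evs = [refine.FrameshiftEvent("g1", "c", 5, 1, in_homopolymer=True,
                                      hp_base="A", hp_len=4),
               refine.FrameshiftEvent("g1", "c", 50, -1, in_homopolymer=True,
                                      hp_base="T", hp_len=5)]
        rep = refine.frameshift_report({"v": evs})
        assert rep["v"]["orfs_with_frameshifts"] == 1
        assert rep["v"]["by_base"]["A"] == 1 and rep["v"]["by_base"]["T"] == 1
        assert rep["v"]["by_hp_len"] == {4: 1, 5: 1}
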