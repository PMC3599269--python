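"""Synteny ortholog assignment: hit mapping, triplet pass, rescue, fallback,
tRNA rule, classification and telomeric enrichment."""
import itertools

import numpy as np
import pytest
from scipy import stats

from arborator import orthology as orth
from arborator.io import rank_hits
from arborator.model import GeneModel, HitRecord, TRNAModel


def _gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, chrom, strand, [(start, end)])


def _linear_genes(chrom, n, gene_len=90, gap=30, prefix="g"):
    out, pos = [], gap
    for i in range(n):
        out.append(_gene(f"{prefix}{i + 1}", chrom, pos, pos + gene_len))
        pos += gene_len + gap
    return out


class TestMapHits:
    def test_exact_cover(self):
        genes = _linear_genes("t", 3, prefix="t")
        hits = rank_hits([HitRecord("q", "t", genes[1].start, genes[1].end, "+", 100)])
        assert orth.map_top_hits_to_genes(hits, genes)["q"] == ["t2"]

    def test_max_overlap_wins(self):
        g1 = _gene("t1", "t", 0, 100)
        g2 = _gene("t2", "t", 100, 200)
        hits = rank_hits([HitRecord("q", "t", 50, 110, "+", 100)])  # 50 vs 10 bp
        assert orth.map_top_hits_to_genes(hits, [g1, g2])["q"] == ["t1"]

    def test_no_overlap_is_none(self):
        genes = [_gene("t1", "t", 0, 50)]
        hits = rank_hits([HitRecord("q", "t", 500, 600, "+", 10)])
        assert orth.map_top_hits_to_genes(hits, genes)["q"] == [None]

    def test_resolution_independent_of_hit_order(self, rng):
        genes = _linear_genes("t", 10, prefix="t")
        raw = [HitRecord(f"q{i%4}", "t", int(rng.integers(0, 1000)),
                         int(rng.integers(1000, 1200)), "+",
                         float(rng.integers(10, 99)) + i * 1e-3)
               for i in range(30)]
        r1 = orth.map_top_hits_to_genes(rank_hits(list(raw)), genes)
        perm = [raw[i] for i in rng.permutation(len(raw))]
        r2 = orth.map_top_hits_to_genes(rank_hits(perm), genes)
        assert r1 == r2


class TestFirstPass:
    def _setup(self, target_perm):
        """3 query genes; their top hits land on 3 consecutive targets in
        the order given by target_perm (a permutation of (0, 1, 2))."""
        qgenes = _linear_genes("q", 3, prefix="q")
        tgenes = _linear_genes("t", 5, prefix="t")
        # targets t2, t3, t4 (indices 1..3) assigned per permutation
        tops = {f"q{i + 1}": f"t{target_perm[i] + 2}" for i in range(3)}
        return orth.GeneOrder(qgenes), tops, orth.GeneOrder(tgenes)

    def test_monotone_orientations_assign_middle(self):
        # exhaustive orientation oracle: of all 3! permutations only the two
        # monotone ones assign the middle gene
        for perm in itertools.permutations(range(3)):
            qo, tops, to = self._setup(perm)
            res = orth.assign_first_pass(qo, tops, to)
            assigned = res["q2"].assignment_class == "syntenic_first_pass"
            assert assigned == (perm in ((0, 1, 2), (2, 1, 0))), perm

    def test_conflicting_claims_void_both(self):
        qgenes = _linear_genes("q", 6, prefix="q")
        tgenes = _linear_genes("t", 3, prefix="t")
        tops = {"q1": "t1", "q2": "t2", "q3": "t3",
                "q4": "t1", "q5": "t2", "q6": "t3"}
        res = orth.assign_first_pass(orth.GeneOrder(qgenes), tops,
                                     orth.GeneOrder(tgenes))
        assert res["q2"].assignment_class == "unassigned"
        assert res["q5"].assignment_class == "unassigned"


class TestRescue:
    def test_rescue_uses_lower_rank_hit_in_window(self):
        qgenes = _linear_genes("q", 5, prefix="q")
        tgenes = _linear_genes("t", 5, prefix="t")
        qo, to = orth.GeneOrder(qgenes), orth.GeneOrder(tgenes)
        a = {g.gene_id: orth.OrthologAssignment(g.gene_id) for g in qgenes}
        for q, t in (("q1", "t1"), ("q2", "t2"), ("q4", "t4"), ("q5", "t5")):
            a[q] = orth.OrthologAssignment(q, t, "syntenic_first_pass")
        ranked = {"q3": ["t5", "t1", "t3"]}  # decoy-rank1 claimed; t3 in window
        a, rounds = orth.rescue_iterative(a, ranked, qo, to)
        assert a["q3"].assignment_class == "syntenic_rescued"
        assert a["q3"].target_gene_id == "t3"
        assert rounds == 1

    def test_two_candidates_stay_unassigned(self):
        qgenes = _linear_genes("q", 4, prefix="q")
        tgenes = _linear_genes("t", 5, prefix="t")
        qo, to = orth.GeneOrder(qgenes), orth.GeneOrder(tgenes)
        a = {g.gene_id: orth.OrthologAssignment(g.gene_id) for g in qgenes}
        a["q1"] = orth.OrthologAssignment("q1", "t1", "syntenic_first_pass")
        a["q4"] = orth.OrthologAssignment("q4", "t5", "syntenic_first_pass")
        ranked = {"q2": ["t2", "t3"], "q3": []}  # two unclaimed in-window hits
        a, _ = orth.rescue_iterative(a, ranked, qo, to)
        assert a["q2"].assignment_class == "unassigned"

    def test_monotone_growth_and_termination(self, rng):
        # random instances: assignment count never shrinks; <= 10 rounds
        for trial in range(100):
            n = int(rng.integers(6, 30))
            qgenes = _linear_genes("q", n, prefix="q")
            tgenes = _linear_genes("t", n, prefix="t")
            qo, to = orth.GeneOrder(qgenes), orth.GeneOrder(tgenes)
            a = {g.gene_id: orth.OrthologAssignment(g.gene_id) for g in qgenes}
            for i in rng.choice(n, size=max(2, n // 4), replace=False):
                a[f"q{i + 1}"] = orth.OrthologAssignment(
                    f"q{i + 1}", f"t{i + 1}", "syntenic_first_pass")
            before = sum(1 for x in a.values() if x.target_gene_id)
            ranked = {f"q{i + 1}": [f"t{int(rng.integers(1, n + 1))}"
                                    for _ in range(3)] + [f"t{i + 1}"]
                      for i in range(n)}
            a, rounds = orth.rescue_iterative(a, ranked, qo, to)
            after = sum(1 for x in a.values() if x.target_gene_id)
            assert after >= before
            assert rounds <= 10
            orth.check_unique_targets(a)


class TestFallback:
    def _base(self):
        qgenes = _linear_genes("q", 2, prefix="q")
        tgenes = _linear_genes("t", 3, prefix="t")
        a = {g.gene_id: orth.OrthologAssignment(g.gene_id) for g in qgenes}
        return a, tgenes

    def test_free_rank1_assigned(self):
        a, tgenes = self._base()
        a = orth.assign_non_syntenic(a, {"q1": "t1"}, tgenes)
        assert a["q1"].assignment_class == "non_syntenic"

    def test_claimed_rank1_skipped(self):
        a, tgenes = self._base()
        a["q2"] = orth.OrthologAssignment("q2", "t1", "syntenic_first_pass")
        a = orth.assign_non_syntenic(a, {"q1": "t1"}, tgenes)
        assert a["q1"].assignment_class == "unassigned"

    def test_reserved_target_skipped(self):
        a, tgenes = self._base()
        a = orth.assign_non_syntenic(a, {"q1": "t1"}, tgenes, reserved={"t1"})
        assert a["q1"].assignment_class == "unassigned"


class TestTRNASynteny:
    def _pairs(self):
        qgenes = _linear_genes("q", 2, prefix="q", gene_len=90, gap=200)
        tgenes = _linear_genes("t", 2, prefix="t", gene_len=90, gap=200)
        a = {"q1": orth.OrthologAssignment("q1", "t1", "syntenic_first_pass"),
             "q2": orth.OrthologAssignment("q2", "t2", "syntenic_rescued")}
        return qgenes, tgenes, a

    def test_syntenic_trna(self):
        qgenes, tgenes, a = self._pairs()
        qt = [TRNAModel("qt1", "q", "+", 320, 400)]
        tt = [TRNAModel("tt1", "t", "+", 330, 410)]
        res = orth.trna_synteny(qt, tt, a, qgenes, tgenes)
        assert res["tt1"] == "syntenic"

    def test_non_syntenic_flanker(self):
        qgenes, tgenes, a = self._pairs()
        a["q2"] = orth.OrthologAssignment("q2", "t2", "non_syntenic")
        tt = [TRNAModel("tt1", "t", "+", 330, 410)]
        res = orth.trna_synteny([TRNAModel("qt1", "q", "+", 320, 400)],
                                tt, a, qgenes, tgenes)
        assert res["tt1"] == "non_syntenic"

    def test_missing_query_trna(self):
        qgenes, tgenes, a = self._pairs()
        res = orth.trna_synteny([], [TRNAModel("tt1", "t", "+", 330, 410)],
                                a, qgenes, tgenes)
        assert res["tt1"] == "non_syntenic"


class TestClassification:
    def test_partition_sums(self):
        tgenes = _linear_genes("t", 4, prefix="t")
        denovo = [_gene("d1", "t", 5000, 5100), _gene("d2", "t", 10, 80)]
        a = {"q1": orth.OrthologAssignment("q1", "t1", "syntenic_first_pass")}
        flags = {"t2": True, "d1": False}
        res = orth.classify_predictions(a, tgenes, denovo, flags)
        # d2 overlaps t1 -> dropped as redundant
        assert "d2" not in res
        assert res["t1"] == "syntenic"
        assert res["t2"] == "non_syntenic_homolog"
        assert res["t3"] == "no_reference_hit"
        assert res["d1"] == "no_reference_hit"
        assert len(res) == 5


class TestDecileEnrichment:
    def test_closed_form_against_direct_summation(self):
        # all flagged genes terminal: p equals the hypergeometric tail
        genes = _linear_genes("c", 20, gene_len=10, gap=40)
        L = 1000
        classes = {}
        for g in genes:
            d = int(g.midpoint() / L * 10)
            classes[g.gene_id] = ("no_reference_hit" if d in (0, 9)
                                  else "syntenic")
        fr, p = orth.decile_enrichment(classes, genes, {"c": L})
        N = len(genes)
        K = sum(1 for c in classes.values() if c == "no_reference_hit")
        n = K  # all flagged genes are terminal and all terminal are flagged
        # direct summation oracle
        direct = sum(stats.hypergeom.pmf(k, N, K, n) for k in range(K, K + 1))
        assert p == pytest.approx(direct, abs=1e-12)
        for cls, v in fr.items():
            assert v.sum() == pytest.approx(1.0)

    def test_null_calibration(self, rng):
        # random flags: the test is calibrated.  The hypergeometric tail is
        # discrete, so raw p-values are super-uniform by construction; the
        # randomized probability integral transform u = P(X>k) + V*P(X=k)
        # is exactly uniform under the null and must pass a KS test, and the
        # reported p must never be anti-conservative relative to it.
        genes = _linear_genes("c", 400, gene_len=10, gap=15)
        L = genes[-1].end + 15
        n_bins = 10
        pit, pvals = [], []
        for _ in range(500):
            classes = {g.gene_id: ("no_reference_hit" if rng.random() < 0.25
                                   else "syntenic") for g in genes}
            _, p = orth.decile_enrichment(classes, genes, {"c": L})
            pvals.append(p)
            N = len(genes)
            K = sum(1 for c in classes.values() if c == "no_reference_hit")
            term = {0, n_bins - 1}
            deciles = {g.gene_id: min(int(g.midpoint() / L * n_bins), n_bins - 1)
                       for g in genes}
            n = sum(1 for g in genes if deciles[g.gene_id] in term)
            k = sum(1 for g in genes if deciles[g.gene_id] in term
                    and classes[g.gene_id] == "no_reference_hit")
            u = (stats.hypergeom.sf(k, N, K, n)
                 + rng.random() * stats.hypergeom.pmf(k, N, K, n))
            pit.append(u)
            assert p >= stats.hypergeom.sf(k, N, K, n)  # conservative tail
        assert stats.kstest(pit, "uniform").pvalue > 0.01
        # super-uniformity of the reported p-values at common levels
        for alpha in (0.01, 0.05, 0.1, 0.25):
            assert np.mean(np.array(pvals) <= alpha) <= alpha + 0.04

    def test_short_chromosome_rejected(self):
        g = _gene("g1", "c", 0, 5)
        with pytest.raises(ValueError):
            orth.decile_enrichment({"g1": "syntenic"}, [g], {"c": 5})


class TestPipelineInvariants:
    def test_classes_cover_all_queries_and_targets_unique(self, small_pair):
        from arborator import simulate as sim
        _, genes, _, dgenes, truth = small_pair
        hits = sim.make_hit_table(genes, dgenes, truth, decoy_prob=0.2,
                                  rng_seed=9)
        assign, _ = orth.assign_orthologs(genes, dgenes, hits)
        assert set(assign) == {g.gene_id for g in genes}
        orth.check_unique_targets(assign)
        valid = {"syntenic_first_pass", "syntenic_rescued", "non_syntenic",
                 "unassigned"}
        assert {a.assignment_class for a in assign.values()} <= valid

    def test_noise_free_pair_recovers_truth(self):
        from arborator import simulate as sim
        genome, genes = sim.simulate_ancestor(2, 40, 150, rng_seed=30)
        derived, dgenes, truth = sim.evolve(genome, genes,
                                            sim.EvolutionParams(rng_seed=31))
        hits = sim.make_hit_table(genes, dgenes, truth, decoy_prob=0.0,
                                  rng_seed=32)
        assign, _ = orth.assign_orthologs(genes, dgenes, hits)
        for q, t in truth.ortholog_pairs.items():
            assert assign[q].target_gene_id == t
        # interior genes are syntenic-class
        qo = orth.GeneOrder(genes)
        for chrom, order in qo.by_chrom.items():
            for q in order[2:-2]:
                assert assign[q].assignment_class in orth.SYNTENIC_CLASSES


class TestPlantedTrnaRecovery:
    def test_all_planted_trnas_syntenic_without_rearrangement(self):
        from arborator import simulate as sim
        from arborator.model import TRNAModel
        genome, genes = sim.simulate_ancestor(2, 30, 250, rng_seed=80)
        derived, dgenes, truth = sim.evolve(genome, genes,
                                            sim.EvolutionParams(rng_seed=81))
        qtrnas = sim.plant_trnas(genome, genes, n_per_chrom=3, rng_seed=82)
        # the derived genome is co-linear, so the same coordinates hold
        ttrnas = [TRNAModel("t_" + t.trna_id, "d_" + t.chrom_id, t.strand,
                            t.start, t.end, t.isotype) for t in qtrnas]
        assign = {q: orth.OrthologAssignment(q, t, "syntenic_first_pass")
                  for q, t in truth.ortholog_pairs.items()}
        res = orth.trna_synteny(qtrnas, ttrnas, assign, genes, dgenes)
        assert res and all(v == "syntenic" for v in res.values())
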