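"""Pruning likelihood kernel, branch-length optimization and placement."""
import itertools

import numpy as np
import pytest

from arborator.phylo import (AlignedFamily, PoissonModel, Tree,
                             concatenate, log_likelihood,
                             make_candidate_topologies, median_branch_lengths,
                             optimize_branch_lengths, place_species,
                             sample_gene_sets, simulate_alignment)


def brute_force_logl(aln, tree, model):
    """Exhaustive sum over ancestral state assignments."""
    idx = {c: i for i, c in enumerate(model.alphabet)}
    leaves = tree.leaves()
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    P = {v: model.transition(tree.length[v])
         for v in range(tree.n_nodes) if tree.parent[v] is not None}
    n_sites = len(next(iter(aln.values())))
    total = 0.0
    for site in range(n_sites):
        acc = 0.0
        leaf_state = {v: idx[aln[tree.name[v]][site]] for v in leaves}
        for combo in itertools.product(range(model.k), repeat=len(internals)):
            st = dict(zip(internals, combo))
            st.update(leaf_state)
            p = model.freqs[st[tree.root]]
            for v in range(tree.n_nodes):
                if tree.parent[v] is not None:
                    p *= P[v][st[tree.parent[v]], st[v]]
            acc += p
        total += np.log(acc)
    return total


class TestModel:
    def test_rate_matrix_rows_sum_to_zero(self):
        m = PoissonModel.nucleotide(np.array([0.1, 0.2, 0.3, 0.4]))
        q = m.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0.0)
        # detailed balance pi_a q_ab = pi_b q_ba
        for a in range(4):
            for b in range(4):
                assert m.freqs[a] * q[a, b] == pytest.approx(m.freqs[b] * q[b, a])

    def test_transition_rows_are_distributions(self):
        m = PoissonModel.amino_acid()
        p = m.transition(0.3)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p >= 0).all()


class TestLikelihood:
    @pytest.mark.parametrize("newick,n_sites", [
        ("((A:0.2,B:0.35):0.15,(C:0.4,D:0.1):0.05);", 3),
        ("(((A:0.1,B:0.2):0.1,C:0.3):0.05,(D:0.25,E:0.15):0.1);", 4),
    ])
    def test_pruning_equals_brute_force(self, newick, n_sites):
        model = PoissonModel.nucleotide(np.array([0.3, 0.2, 0.25, 0.25]))
        tree = Tree.from_newick(newick)
        aln = simulate_alignment(tree, model, n_sites, rng_seed=13)
        assert log_likelihood(aln, tree, model) == \
            pytest.approx(brute_force_logl(aln, tree, model), abs=1e-10)

    def test_single_site_closed_form(self):
        model = PoissonModel.nucleotide(np.array([0.3, 0.2, 0.25, 0.25]))
        tree = Tree.from_newick("(A:0.0,B:0.0);")
        ll = log_likelihood({"A": "C", "B": "C"}, tree, model)
        assert ll == pytest.approx(np.log(0.2), abs=1e-7)

    def test_gap_is_fully_ambiguous(self):
        model = PoissonModel.nucleotide()
        tree = Tree.from_newick("(A:0.1,B:0.1);")
        ll_gap = log_likelihood({"A": "C", "B": "-"}, tree, model)
        # marginalising B equals summing likelihood over B's states
        total = sum(np.exp(log_likelihood({"A": "C", "B": b}, tree, model))
                    for b in "ACGT")
        assert ll_gap == pytest.approx(np.log(total), abs=1e-10)

    def test_conflict_lowers_likelihood_on_short_branches(self):
        model = PoissonModel.nucleotide()
        tree = Tree.from_newick("(A:0.01,B:0.01);")
        same = log_likelihood({"A": "C", "B": "C"}, tree, model)
        diff = log_likelihood({"A": "C", "B": "G"}, tree, model)
        assert diff < same

    def test_zero_branch_conflict_is_finite(self):
        model = PoissonModel.nucleotide()
        tree = Tree.from_newick("(A:0.0,B:0.0);")
        ll = log_likelihood({"A": "C", "B": "G"}, tree, model)
        assert np.isfinite(ll)

    def test_site_permutation_invariance(self):
        model = PoissonModel.nucleotide()
        tree = Tree.from_newick("((A:0.2,B:0.3):0.1,C:0.2);")
        aln = simulate_alignment(tree, model, 50, rng_seed=5)
        perm = np.random.default_rng(1).permutation(50)
        aln2 = {sp: "".join(s[i] for i in perm) for sp, s in aln.items()}
        assert log_likelihood(aln, tree, model) == \
            pytest.approx(log_likelihood(aln2, tree, model), abs=1e-9)


class TestOptimization:
    def test_two_taxon_matches_closed_form(self):
        jc = PoissonModel.nucleotide()
        truth = Tree.from_newick("(A:0.15,B:0.15);")
        aln = simulate_alignment(truth, jc, 100000, rng_seed=4)
        p_dist = np.mean([a != b for a, b in zip(aln["A"], aln["B"])])
        opt, _ = optimize_branch_lengths(aln, Tree.from_newick("(A:0.05,B:0.05);"), jc)
        total = sum(opt.length[e] for e in opt.edges())
        assert total == pytest.approx(jc.ml_distance(p_dist), abs=1e-4)

    def test_logl_never_decreases(self):
        model = PoissonModel.amino_acid()
        tree = Tree.from_newick("((A:0.4,B:0.02):0.2,(C:0.05,D:0.6):0.1);")
        aln = simulate_alignment(tree, model, 400, rng_seed=6)
        start = Tree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        before = log_likelihood(aln, start, model)
        opt, after = optimize_branch_lengths(aln, start, model)
        assert after >= before
        assert after == pytest.approx(log_likelihood(aln, opt, model), abs=1e-6)

    def test_seven_taxon_length_recovery(self):
        model = PoissonModel.amino_acid()
        cands = make_candidate_topologies()
        gt = cands[1].tree.copy()
        for e in gt.edges():
            gt.length[e] = 0.35 if gt.name[e] == "Scas" else \
                (0.10 if gt.name[e] else 0.04)
        aln = simulate_alignment(gt, model, 100000, rng_seed=7)
        opt, _ = optimize_branch_lengths(aln, cands[1].tree, model)
        true_sp, est_sp = gt.split_lengths(), opt.split_lengths()
        for split, v in true_sp.items():
            assert abs(est_sp[split] - v) / v < 0.05


class TestFamilies:
    def _fams(self, n=8, species=("A", "B", "C")):
        rng = np.random.default_rng(3)
        out = []
        for i in range(n):
            L = int(rng.integers(5, 15))
            out.append(AlignedFamily(
                f"f{i}", {sp: "".join(rng.choice(list("ACDE"), L))
                          for sp in species}))
        return out

    def test_concatenate_lengths(self):
        fams = self._fams(2)
        cat = concatenate(fams)
        assert cat.length == fams[0].length + fams[1].length

    def test_concatenate_species_mismatch(self):
        fams = self._fams(1) + self._fams(1, species=("A", "B"))
        with pytest.raises(ValueError):
            concatenate(fams)

    def test_concatenation_order_does_not_change_likelihood(self):
        model = PoissonModel.amino_acid()
        tree = Tree.from_newick("((A:0.2,B:0.3):0.1,C:0.2);")
        fams = []
        for i in range(4):
            fams.append(AlignedFamily(
                f"f{i}", simulate_alignment(tree, model, 30, rng_seed=50 + i)))
        l1 = log_likelihood(concatenate(fams).sequences, tree, model)
        l2 = log_likelihood(concatenate(fams[::-1]).sequences, tree, model)
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_sampling_determinism_and_eligibility(self):
        fams = self._fams(10) + self._fams(3, species=("A", "B"))
        s1 = sample_gene_sets(fams, 4, 5, {"A", "B", "C"}, rng_seed=9)
        s2 = sample_gene_sets(fams, 4, 5, {"A", "B", "C"}, rng_seed=9)
        assert s1 == s2
        chosen = {f for s in s1 for f in s}
        eligible = {f.family_id for f in fams if {"A", "B", "C"} <= f.species}
        assert chosen <= eligible
        for s in s1:
            assert len(set(s)) == len(s)

    def test_sampling_uniformity(self):
        fams = self._fams(12)
        sets = sample_gene_sets(fams, 3, 4000, {"A", "B", "C"}, rng_seed=11)
        counts = {f.family_id: 0 for f in fams}
        for s in sets:
            for f in s:
                counts[f] += 1
        expect = 4000 * 3 / 12
        sd = np.sqrt(4000 * (3 / 12) * (1 - 3 / 12))
        for c in counts.values():
            assert abs(c - expect) < 3 * sd


class TestPlacement:
    def test_tie_broken_by_lowest_topo_id(self):
        model = PoissonModel.amino_acid()
        cands = make_candidate_topologies()
        dup = [cands[1], cands[1].__class__(4, cands[1].tree.copy())]
        gt = cands[1].tree.copy()
        for e in gt.edges():
            gt.length[e] = 0.1
        fams = [AlignedFamily(f"f{i}",
                              simulate_alignment(gt, model, 100, rng_seed=i))
                for i in range(3)]
        res = place_species(fams, dup, sample_count=1, genes_per_sample=2,
                            n_bootstrap=5, rng_seed=0, model=model)
        assert res.samples[0].best_topo_id == 2
        assert res.samples[0].tie

    def test_support_counts_sum(self):
        model = PoissonModel.amino_acid()
        cands = make_candidate_topologies()
        gt = cands[0].tree.copy()
        for e in gt.edges():
            gt.length[e] = 0.08
        fams = [AlignedFamily(f"f{i}",
                              simulate_alignment(gt, model, 120, rng_seed=20 + i))
                for i in range(6)]
        res = place_species(fams, cands, sample_count=4, genes_per_sample=3,
                            n_bootstrap=10, rng_seed=1, model=model)
        assert sum(res.support_counts.values()) == 4
        assert res.sample_count == 4

    def test_median_lengths_on_identical_families(self):
        model = PoissonModel.amino_acid()
        tree = Tree.from_newick("((A:0.2,B:0.3):0.1,C:0.2);")
        aln = simulate_alignment(tree, model, 500, rng_seed=8)
        fams = [AlignedFamily(f"f{i}", dict(aln)) for i in range(3)]
        med, failures = median_branch_lengths(fams, tree, model)
        single, _ = median_branch_lengths(fams[:1], tree, model)
        assert failures == 0
        for split, v in single.items():
            assert med[split] == pytest.approx(v, abs=1e-9)

    def test_median_invariant_to_family_order(self):
        model = PoissonModel.amino_acid()
        tree = Tree.from_newick("((A:0.2,B:0.3):0.1,C:0.2);")
        fams = [AlignedFamily(f"f{i}",
                              simulate_alignment(tree, model, 200, rng_seed=30 + i))
                for i in range(4)]
        m1, _ = median_branch_lengths(fams, tree, model)
        m2, _ = median_branch_lengths(fams[::-1], tree, model)
        for k, v in m1.items():
            assert m2[k] == pytest.approx(v, abs=1e-12)


class TestCandidates:
    def test_five_placements_share_leafset(self):
        cands = make_candidate_topologies()
        assert [c.topo_id for c in cands] == [1, 2, 3, 4, 5]
        leafsets = {frozenset(c.tree.leaf_names()) for c in cands}
        assert len(leafsets) == 1
        assert "Sarb" in next(iter(leafsets))
        # topologies pairwise distinct as unrooted split sets
        splits = [frozenset(c.tree.split_lengths()) for c in cands]
        assert len(set(splits)) == 5
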