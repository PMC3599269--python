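"""Topology placement by random gene-set concatenation and ML comparison.

The likelihood kernel is Felsenstein's pruning algorithm with site-pattern
compression.  The substitution process is an equal-exchangeability
(F81/Poisson-type) model — amino-acid or nucleotide — whose transition
probabilities have the closed form P(t) = e^{-bt} I + (1-e^{-bt}) 1 pi^T.
That form makes the likelihood along any single edge *linear* in
x = e^{-bt}, so per-edge branch-length optimization is an exact 1-D concave
maximization, cycled over edges to convergence.

Placement support is RELL-style: alignment columns are bootstrapped with
replacement and candidate log-likelihoods re-evaluated at the optimized
branch lengths.
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import brentq

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

# effective lower bound on branch lengths inside the likelihood kernel: keeps
# the likelihood finite when zero-length branches meet conflicting residues
MIN_BRANCH = 1e-9


# ---------------------------------------------------------------- model

@dataclass
class PoissonModel:
    """Equal-exchangeability reversible model with stationary frequencies.

    Rate matrix Q_ab = beta * pi_b (a != b), normalized to one expected
    substitution per unit branch length: beta = 1 / (1 - sum pi^2).
    """

    alphabet: str
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.freqs) != len(self.alphabet):
            raise ValueError("freqs/alphabet size mismatch")
        if abs(self.freqs.sum() - 1.0) > 1e-9 or (self.freqs <= 0).any():
            raise ValueError("freqs must be positive and sum to 1")
        self.beta = 1.0 / (1.0 - float(self.freqs @ self.freqs))

    @property
    def k(self) -> int:
        return len(self.alphabet)

    @classmethod
    def amino_acid(cls, freqs=None) -> "PoissonModel":
        if freqs is None:
            freqs = np.full(20, 1 / 20)
        return cls(AA_ALPHABET, freqs)

    @classmethod
    def nucleotide(cls, freqs=None) -> "PoissonModel":
        if freqs is None:
            freqs = np.full(4, 0.25)
        return cls(NT_ALPHABET, freqs)

    @classmethod
    def from_alignment(cls, alignment: dict[str, str], alphabet: str = AA_ALPHABET,
                       pseudocount: float = 1.0) -> "PoissonModel":
        """Empirical stationary frequencies estimated from the alignment."""
        counts = np.full(len(alphabet), pseudocount)
        idx = {c: i for i, c in enumerate(alphabet)}
        for seq in alignment.values():
            for c in seq:
                if c in idx:
                    counts[idx[c]] += 1
        return cls(alphabet, counts / counts.sum())

    def rate_matrix(self) -> np.ndarray:
        q = self.beta * np.tile(self.freqs, (self.k, 1))
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def transition(self, t: float) -> np.ndarray:
        x = np.exp(-self.beta * t)
        return x * np.eye(self.k) + (1.0 - x) * np.tile(self.freqs, (self.k, 1))

    def ml_distance(self, p_dist: float) -> float:
        """Closed-form ML distance from an observed proportion of differing
        sites between two sequences (the F81/JC inverse formula)."""
        e = 1.0 - float(self.freqs @ self.freqs)
        arg = 1.0 - p_dist / e
        if arg <= 0:
            return np.inf
        return -np.log(arg) / self.beta


# ---------------------------------------------------------------- trees

class Tree:
    """Rooted tree over named leaves with per-edge lengths (array-backed)."""

    def __init__(self) -> None:
        self.parent: list[int | None] = []
        self.children: list[list[int]] = []
        self.length: list[float] = []
        self.name: list[str | None] = []
        self.root = 0

    @classmethod
    def from_newick(cls, newick: str, default_length: float = 0.1) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        t = cls()
        index: dict[int, int] = {}
        for nd in dt.preorder_node_iter():
            i = len(t.parent)
            index[id(nd)] = i
            t.parent.append(index[id(nd.parent_node)] if nd.parent_node else None)
            t.children.append([])
            el = nd.edge.length
            t.length.append(float(el) if el is not None else default_length)
            t.name.append(nd.taxon.label if nd.taxon else None)
            if nd.parent_node:
                t.children[index[id(nd.parent_node)]].append(i)
        return t

    def copy(self) -> "Tree":
        t = Tree()
        t.parent = list(self.parent)
        t.children = [list(c) for c in self.children]
        t.length = list(self.length)
        t.name = list(self.name)
        t.root = self.root
        return t

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def leaf_names(self) -> list[str]:
        return [self.name[i] for i in self.leaves()]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def edges(self) -> list[int]:
        """Edges identified by their child node (every non-root node)."""
        return [i for i in range(self.n_nodes) if self.parent[i] is not None]

    def leafset_below(self) -> dict[int, frozenset]:
        below: dict[int, frozenset] = {}
        for v in self.postorder():
            if not self.children[v]:
                below[v] = frozenset([self.name[v]])
            else:
                below[v] = frozenset().union(*(below[c] for c in self.children[v]))
        return below

    def split_lengths(self) -> dict[frozenset, float]:
        """Branch lengths keyed by the (canonical) leaf-set split.

        The two edges meeting at a rooted tree's root describe the same
        unrooted edge; their lengths are summed.
        """
        all_taxa = frozenset(self.leaf_names())
        below = self.leafset_below()
        out: dict[frozenset, float] = {}
        for e in self.edges():
            side = below[e]
            other = all_taxa - side
            key = min(side, other, key=lambda s: (len(s), sorted(s)))
            out[key] = out.get(key, 0.0) + self.length[e]
        return out

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                label = self.name[v]
            else:
                label = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if self.parent[v] is None:
                return label
            return f"{label}:{self.length[v]:.6f}"
        return rec(self.root) + ";"


@dataclass
class CandidateTopology:
    topo_id: int
    tree: Tree


SENSU_STRICTO = ("Scer", "Spar", "Smik", "Skud", "Sbay")
FOCAL = "Sarb"
OUTGROUP = "Scas"

_PLACEMENTS = [
    "(((Sbay,Sarb),(Skud,(Smik,(Spar,Scer)))),Scas);",
    "((Sbay,(Sarb,(Skud,(Smik,(Spar,Scer))))),Scas);",   # published placement
    "((Sbay,((Skud,Sarb),(Smik,(Spar,Scer)))),Scas);",
    "((Sbay,(Skud,(Sarb,(Smik,(Spar,Scer))))),Scas);",
    "((Sbay,(Skud,((Smik,Sarb),(Spar,Scer)))),Scas);",
]


def make_candidate_topologies(default_length: float = 0.1) -> list[CandidateTopology]:
    """The five possible attachments of the focal species along the backbone
    from the most basal ingroup lineage to the crown, outgroup-rooted."""
    return [CandidateTopology(i + 1, Tree.from_newick(nw, default_length))
            for i, nw in enumerate(_PLACEMENTS)]


PUBLISHED_TOPO_ID = 2


# ---------------------------------------------------------------- alignments

@dataclass
class AlignedFamily:
    family_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.family_id}: unequal sequence lengths")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> set[str]:
        return set(self.sequences)


def concatenate(families: list[AlignedFamily]) -> AlignedFamily:
    """Per-species concatenation in list order; all families must share the
    full species set."""
    if not families:
        raise ValueError("nothing to concatenate")
    species = families[0].species
    for f in families:
        if f.species != species:
            raise ValueError(f"{f.family_id}: species set differs")
    return AlignedFamily(
        "concat", {sp: "".join(f.sequences[sp] for f in families)
                   for sp in sorted(species)})


def sample_gene_sets(families: list[AlignedFamily], k: int, n: int,
                     required_species: set[str], rng_seed: int = 0,
                     ) -> list[list[str]]:
    """n independent samples of k family ids, each drawn without replacement
    from the families covering all required species."""
    eligible = [f.family_id for f in families if required_species <= f.species]
    if len(eligible) < k:
        raise ValueError(f"only {len(eligible)} eligible families for k={k}")
    rng = np.random.default_rng(rng_seed)
    return [[eligible[i] for i in rng.choice(len(eligible), size=k, replace=False)]
            for _ in range(n)]


def encode_alignment(alignment: dict[str, str], model: PoissonModel
                     ) -> tuple[list[str], np.ndarray]:
    idx = {c: i for i, c in enumerate(model.alphabet)}
    species = sorted(alignment)
    mat = np.full((len(species), len(alignment[species[0]])), -1, dtype=np.int16)
    for r, sp in enumerate(species):
        mat[r] = [idx.get(c, -1) for c in alignment[sp]]
    return species, mat


def compress_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their counts."""
    pats, counts = np.unique(mat, axis=1, return_counts=True)
    return pats, counts.astype(float)


# ---------------------------------------------------------------- pruning

def _leaf_partial(codes: np.ndarray, k: int) -> np.ndarray:
    npat = codes.shape[0]
    part = np.zeros((npat, k))
    known = codes >= 0
    part[known, codes[known]] = 1.0
    part[~known] = 1.0  # gap / ambiguous: sums over all states
    return part


def _down_pass(tree: Tree, leaf_parts: dict[int, np.ndarray],
               model: PoissonModel) -> tuple[list, list]:
    """Post-order conditional likelihoods with per-pattern scaling."""
    pi = model.freqs
    down: list = [None] * tree.n_nodes
    scale: list = [None] * tree.n_nodes
    for v in tree.postorder():
        if not tree.children[v]:
            down[v] = leaf_parts[v]
            scale[v] = np.zeros(down[v].shape[0])
            continue
        acc = None
        sc = None
        for c in tree.children[v]:
            x = np.exp(-model.beta * max(tree.length[c], MIN_BRANCH))
            m = x * down[c] + (1.0 - x) * (down[c] @ pi)[:, None]
            acc = m if acc is None else acc * m
            sc = scale[c] if sc is None else sc + scale[c]
        mx = acc.max(axis=1)
        mx[mx == 0] = 1.0
        down[v] = acc / mx[:, None]
        scale[v] = sc + np.log(mx)
    return down, scale


def log_likelihood(alignment: dict[str, str], tree: Tree, model: PoissonModel
                   ) -> float:
    logls, counts = site_log_likelihoods(alignment, tree, model)
    return float(logls @ counts)


def _prepare(alignment: dict[str, str], model: PoissonModel
             ) -> tuple[list[str], np.ndarray, np.ndarray]:
    species, mat = encode_alignment(alignment, model)
    pats, counts = compress_patterns(mat)
    return species, pats, counts


def site_log_likelihoods(alignment: dict[str, str], tree: Tree,
                         model: PoissonModel,
                         prepared: tuple | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern log-likelihoods and pattern counts."""
    species, pats, counts = prepared or _prepare(alignment, model)
    leaf_of = {tree.name[i]: i for i in tree.leaves()}
    missing = set(species) ^ set(leaf_of)
    if missing:
        raise ValueError(f"alignment/tree species mismatch: {sorted(missing)}")
    leaf_parts = {leaf_of[sp]: _leaf_partial(pats[r], model.k)
                  for r, sp in enumerate(species)}
    down, scale = _down_pass(tree, leaf_parts, model)
    root_l = down[tree.root] @ model.freqs
    return np.log(root_l) + scale[tree.root], counts


# ---------------------------------------------------------------- optimization

def _edge_uv(tree: Tree, edge: int, down: list, scale: list,
             model: PoissonModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pattern (u, v, logscale) so that the likelihood across ``edge``
    equals exp(logscale) * (x*u + (1-x)*v) with x = exp(-beta * t_edge)."""
    pi = model.freqs
    npat = down[tree.root].shape[0]
    # outside partial at the parent of `edge`, looking away from it
    up = {tree.root: np.tile(pi, (npat, 1))}
    upscale = {tree.root: np.zeros(npat)}
    # walk from root to the edge's parent along the ancestor chain
    chain = []
    v = tree.parent[edge]
    while v is not None:
        chain.append(v)
        v = tree.parent[v]
    chain.reverse()  # root ... parent(edge)
    for node, nxt in zip(chain, chain[1:] + [edge]):
        raw = up[node].copy()
        sc = upscale[node].copy()
        for c in tree.children[node]:
            if c == nxt:
                continue
            x = np.exp(-model.beta * max(tree.length[c], MIN_BRANCH))
            raw *= x * down[c] + (1.0 - x) * (down[c] @ pi)[:, None]
            sc = sc + scale[c]
        if nxt == edge:
            up_e, upsc_e = raw, sc
            break
        # cross the edge into `nxt`: U'_b = x*U_b + (1-x)*pi_b*sum(U)
        x = np.exp(-model.beta * max(tree.length[nxt], MIN_BRANCH))
        crossed = x * raw + (1.0 - x) * np.outer(raw.sum(axis=1), pi)
        mx = crossed.max(axis=1)
        mx[mx == 0] = 1.0
        up[nxt] = crossed / mx[:, None]
        upscale[nxt] = sc + np.log(mx)
    else:  # edge hangs off the root
        up_e, upsc_e = up[tree.root], upscale[tree.root]
        sc = upsc_e.copy()
        raw = up_e.copy()
        for c in tree.children[tree.root]:
            if c == edge:
                continue
            x = np.exp(-model.beta * max(tree.length[c], MIN_BRANCH))
            raw = raw * (x * down[c] + (1.0 - x) * (down[c] @ pi)[:, None])
            sc = sc + scale[c]
        up_e, upsc_e = raw, sc

    d = down[edge]
    u = (up_e * d).sum(axis=1)
    v = up_e.sum(axis=1) * (d @ pi)
    return u, v, upsc_e + scale[edge]


def _optimize_edge(u: np.ndarray, v: np.ndarray, w: np.ndarray,
                   x_bounds: tuple[float, float]) -> float:
    """argmax_x sum w*log(x*u + (1-x)*v) on [x_lo, x_hi] (concave in x)."""
    lo, hi = x_bounds
    duv = u - v

    def deriv(x: float) -> float:
        return float((w * duv / (v + x * duv)).sum())

    dlo, dhi = deriv(lo), deriv(hi)
    if dlo <= 0:
        return lo
    if dhi >= 0:
        return hi
    return float(brentq(deriv, lo, hi, xtol=1e-12))


def _all_edge_uv(tree: Tree, down: list, scale: list, model: PoissonModel
                 ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-pattern (u, v) for every edge in one outside (preorder) pass."""
    pi = model.freqs
    npat = down[tree.root].shape[0]
    up_in: dict[int, np.ndarray] = {tree.root: np.tile(pi, (npat, 1))}
    up_scale: dict[int, np.ndarray] = {tree.root: np.zeros(npat)}
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for v in tree.postorder()[::-1]:  # preorder
        if not tree.children[v]:
            continue
        ms = {}
        for c in tree.children[v]:
            x = np.exp(-model.beta * max(tree.length[c], MIN_BRANCH))
            ms[c] = x * down[c] + (1.0 - x) * (down[c] @ pi)[:, None]
        for c in tree.children[v]:
            raw = up_in[v].copy()
            sc = up_scale[v].copy()
            for s in tree.children[v]:
                if s != c:
                    raw = raw * ms[s]
                    sc = sc + scale[s]
            u = (raw * down[c]).sum(axis=1)
            vv = raw.sum(axis=1) * (down[c] @ pi)
            out[c] = (u, vv)
            # cross edge c for its descendants
            x = np.exp(-model.beta * max(tree.length[c], MIN_BRANCH))
            crossed = x * raw + (1.0 - x) * np.outer(raw.sum(axis=1), pi)
            mx = crossed.max(axis=1)
            mx[mx == 0] = 1.0
            up_in[c] = crossed / mx[:, None]
            up_scale[c] = sc + np.log(mx)
    return out


def optimize_branch_lengths(alignment: dict[str, str], tree: Tree,
                            model: PoissonModel, tol: float = 1e-6,
                            max_sweeps: int = 50,
                            length_bounds: tuple[float, float] = (1e-8, 10.0),
                            prepared: tuple | None = None,
                            ) -> tuple[Tree, float]:
    """Cyclic per-edge ML branch-length optimization.

    Each edge update is an exact 1-D maximization (the per-edge likelihood is
    linear in e^{-beta t}).  Sweeps normally update all edges against the
    partials computed at the start of the sweep (two tree passes); whenever
    such a sweep fails to improve the log-likelihood, it is redone with
    exact per-edge recomputation, so the result never regresses.  Sweeps
    repeat until the gain drops below ``tol``.
    """
    tree = tree.copy()
    species, pats, counts = prepared or _prepare(alignment, model)
    leaf_of = {tree.name[i]: i for i in tree.leaves()}
    leaf_parts = {leaf_of[sp]: _leaf_partial(pats[r], model.k)
                  for r, sp in enumerate(species)}
    x_bounds = (np.exp(-model.beta * length_bounds[1]),
                np.exp(-model.beta * length_bounds[0]))

    def current_logl() -> float:
        down, scale = _down_pass(tree, leaf_parts, model)
        root_l = down[tree.root] @ model.freqs
        return float(counts @ (np.log(root_l) + scale[tree.root]))

    # the two edges meeting at the root are confounded (only their summed
    # length matters on the unrooted tree): park one at the lower bound and
    # let its sibling carry the full length, else parallel updates double-step
    skip = None
    if len(tree.children[tree.root]) == 2:
        skip = tree.children[tree.root][0]
        sib = tree.children[tree.root][1]
        tree.length[sib] = min(tree.length[sib] + tree.length[skip],
                               length_bounds[1])
        tree.length[skip] = length_bounds[0]

    def exact_sweep() -> None:
        for edge in tree.edges():
            if edge == skip:
                continue
            down, scale = _down_pass(tree, leaf_parts, model)
            u, v, _sc = _edge_uv(tree, edge, down, scale, model)
            x = _optimize_edge(u, v, counts, x_bounds)
            tree.length[edge] = float(-np.log(x) / model.beta)

    logl = current_logl()
    for _ in range(max_sweeps):
        saved = list(tree.length)
        down, scale = _down_pass(tree, leaf_parts, model)
        for edge, (u, v) in _all_edge_uv(tree, down, scale, model).items():
            if edge == skip:
                continue
            x = _optimize_edge(u, v, counts, x_bounds)
            tree.length[edge] = float(-np.log(x) / model.beta)
        new_logl = current_logl()
        if new_logl < logl:  # stale-partial sweep overshot: redo exactly
            tree.length = saved
            exact_sweep()
            new_logl = current_logl()
        if new_logl - logl < tol:
            logl = max(new_logl, logl)
            break
        logl = new_logl
    return tree, logl


# ---------------------------------------------------------------- simulation

def simulate_alignment(tree: Tree, model: PoissonModel, n_sites: int,
                       rng_seed: int = 0) -> dict[str, str]:
    """Evolve i.i.d. sites down the tree under the model."""
    rng = np.random.default_rng(rng_seed)
    k = model.k
    states: dict[int, np.ndarray] = {
        tree.root: rng.choice(k, size=n_sites, p=model.freqs)}
    for v in tree.postorder()[::-1]:  # preorder
        for c in tree.children[v]:
            x = np.exp(-model.beta * max(tree.length[c], MIN_BRANCH))
            keep = rng.random(n_sites) < x
            redraw = rng.choice(k, size=n_sites, p=model.freqs)
            states[c] = np.where(keep, states[v], redraw)
    return {tree.name[i]: "".join(model.alphabet[s] for s in states[i])
            for i in tree.leaves()}


# ---------------------------------------------------------------- placement

@dataclass
class SamplePlacement:
    best_topo_id: int
    log_likelihoods: dict[int, float]
    bootstrap_support: float
    tie: bool = False


@dataclass
class PlacementResult:
    samples: list[SamplePlacement]
    support_counts: dict[int, int]
    median_split_lengths: dict[frozenset, float]

    @property
    def sample_count(self) -> int:
        return len(self.samples)


def place_species(families: list[AlignedFamily],
                  candidates: list[CandidateTopology],
                  sample_count: int = 100, genes_per_sample: int = 50,
                  n_bootstrap: int = 100, rng_seed: int = 0,
                  model: PoissonModel | None = None) -> PlacementResult:
    """Repeated random concatenation, per-candidate ML, RELL bootstrap.

    Per sample: branch lengths optimized per candidate; the winner is the
    argmax log-likelihood (ties to the lowest topo_id).  Support is the
    fraction of column-bootstrap replicates, re-evaluated at the optimized
    lengths, in which the same candidate wins.
    """
    required = set(candidates[0].tree.leaf_names())
    sets = sample_gene_sets(families, genes_per_sample, sample_count,
                            required, rng_seed)
    fam_by_id = {f.family_id: f for f in families}
    rng = np.random.default_rng(rng_seed + 1)
    samples: list[SamplePlacement] = []
    counts: dict[int, int] = {c.topo_id: 0 for c in candidates}
    winner_trees: list[Tree] = []
    for ids in sets:
        concat = concatenate([
            AlignedFamily(i, {sp: fam_by_id[i].sequences[sp] for sp in required})
            for i in ids])
        m = model or PoissonModel.from_alignment(concat.sequences)
        prep = _prepare(concat.sequences, m)
        logls: dict[int, float] = {}
        per_site: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        opt_trees: dict[int, Tree] = {}
        for cand in candidates:
            t, ll = optimize_branch_lengths(concat.sequences, cand.tree, m,
                                            prepared=prep)
            logls[cand.topo_id] = ll
            opt_trees[cand.topo_id] = t
            per_site[cand.topo_id] = site_log_likelihoods(concat.sequences, t, m,
                                                          prepared=prep)
        best_ll = max(logls.values())
        winners = sorted(tid for tid, ll in logls.items() if ll == best_ll)
        best = winners[0]
        # RELL bootstrap: one column resampling shared across candidates
        _, pat_counts = per_site[best]
        n_sites = int(pat_counts.sum())
        probs = pat_counts / n_sites
        wins = 0
        for _ in range(n_bootstrap):
            w = rng.multinomial(n_sites, probs).astype(float)
            rep = {tid: float(per_site[tid][0] @ w) for tid in logls}
            rep_best = max(rep.values())
            rep_winners = sorted(t for t, ll in rep.items() if ll == rep_best)
            if rep_winners[0] == best:
                wins += 1
        counts[best] += 1
        samples.append(SamplePlacement(best, logls, wins / n_bootstrap,
                                       tie=len(winners) > 1))
        winner_trees.append(opt_trees[best])
    # per-edge medians over samples that chose the overall winner
    overall = max(counts, key=lambda t: (counts[t], -t))
    per_split: dict[frozenset, list[float]] = {}
    for sp, t in zip(samples, winner_trees):
        if sp.best_topo_id != overall:
            continue
        for split, ln in t.split_lengths().items():
            per_split.setdefault(split, []).append(ln)
    medians = {s: float(np.median(v)) for s, v in per_split.items()}
    return PlacementResult(samples, counts, medians)


def median_branch_lengths(families: list[AlignedFamily], topology: Tree,
                          model: PoissonModel | None = None,
                          ) -> tuple[dict[frozenset, float], int]:
    """Per-family ML branch lengths on a fixed topology; per-split medians.

    Families failing optimization (non-finite likelihood) are excluded and
    counted in the second return value.
    """
    per_split: dict[frozenset, list[float]] = {}
    failures = 0
    for fam in families:
        try:
            m = model or PoissonModel.from_alignment(fam.sequences)
            t, ll = optimize_branch_lengths(fam.sequences, topology, m)
            if not np.isfinite(ll):
                raise ValueError("non-finite likelihood")
        except (ValueError, KeyError):
            failures += 1
            continue
        for split, ln in t.split_lengths().items():
            per_split.setdefault(split, []).append(ln)
    return {s: float(np.median(v)) for s, v in per_split.items()}, failures
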