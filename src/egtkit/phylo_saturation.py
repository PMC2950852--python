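"""Saturation-aware distance phylogenetics plus parsimony utilities.

Multiple superimposed substitutions at fast sites erase signal and,
together with compositional convergence, drive long-branch attraction.
The filtering strategy implemented here sorts the residue pair observed
at each alignment column, for each pair of taxa, into "frequent"
(probable under an empirical substitution model, here LG) or "rare"
(likely saturated); rare pairs are discarded and Poisson-corrected
distances are computed from the remainder, then handed to conventional
neighbor joining.  The probability cutoff separating frequent from rare
is a free parameter, as it is meant to be explored.

Also here: parsimony-informative counting, Fitch small parsimony, an
exhaustive/NNI maximum-parsimony search, nonparametric bootstrap and
Robinson-Foulds distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .seq_io import ProteinAlignment

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # PAML residue order
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


# ---------------------------------------------------------------------------
# substitution model


@dataclass
class SubstitutionModel:
    """Empirical amino-acid model reduced to residue-pair probabilities.

    ``pair_prob[i, j]`` is the stationary probability of observing the
    unordered residue pair (i, j), computed from exchangeabilities s and
    frequencies pi as pi_i * s_ij * pi_j and normalised over the 190
    unordered pairs.  A differing pair is "frequent" when its probability
    is at least ``cutoff``, otherwise "rare" (treated as saturated).
    """

    name: str
    pair_prob: np.ndarray  # (20, 20) symmetric, zero diagonal
    cutoff: float

    def classify(self, res1: str, res2: str) -> str:
        return classify_pair_saturation(res1, res2, self)

    def with_cutoff(self, cutoff: float) -> "SubstitutionModel":
        return SubstitutionModel(name=self.name, pair_prob=self.pair_prob, cutoff=cutoff)

    @property
    def rare_mask(self) -> np.ndarray:
        """Boolean (20, 20): True where a differing pair counts as saturated."""
        mask = self.pair_prob < self.cutoff
        np.fill_diagonal(mask, False)
        return mask


def load_paml_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-layout rate file: 19 lower-triangle rows then frequencies."""
    text = Path(path).read_text()
    values = [float(x) for x in text.split()]
    if len(values) < 210:
        raise ValueError(f"expected 190 exchangeabilities + 20 frequencies, got {len(values)}")
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = values[k]
            k += 1
    freqs = np.array(values[k : k + 20])
    return s, freqs


def lg_model(cutoff: float | None = None) -> SubstitutionModel:
    """The LG model as pair probabilities.

    The default cutoff is the lower quartile of the 190 pair-type
    probabilities: "rare" means the improbable tail of substitution
    types, the ones most plausibly reflecting multiple superimposed
    changes rather than single events.
    """
    with resources.as_file(resources.files("egtkit.data") / "lg.paml") as p:
        s, freqs = load_paml_matrix(p)
    pair = np.outer(freqs, freqs) * s
    np.fill_diagonal(pair, 0.0)
    iu = np.triu_indices(20, k=1)
    pair /= pair[iu].sum()
    if cutoff is None:
        cutoff = float(np.quantile(pair[iu], 0.25))
    return SubstitutionModel(name="LG", pair_prob=pair, cutoff=cutoff)


def classify_pair_saturation(res1: str, res2: str, model: SubstitutionModel) -> str:
    """identical / frequent / rare for a residue pair; nonstandard → excluded."""
    res1, res2 = res1.upper(), res2.upper()
    if res1 not in AA_INDEX or res2 not in AA_INDEX:
        return "excluded"
    if res1 == res2:
        return "identical"
    p = model.pair_prob[AA_INDEX[res1], AA_INDEX[res2]]
    return "frequent" if p >= model.cutoff else "rare"


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    effective_sites: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")

    def get(self, t1: str, t2: str) -> float:
        return float(self.d[self.taxa.index(t1), self.taxa.index(t2)])


def _encode(rows: list[str]) -> np.ndarray:
    """Alignment rows as int codes; -1 marks gaps/nonstandard residues."""
    n, m = len(rows), len(rows[0]) if rows else 0
    enc = np.full((n, m), -1, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row.upper()):
            enc[i, j] = AA_INDEX.get(ch, -1)
    return enc


def saturation_filtered_distance(
    aln: ProteinAlignment, model: SubstitutionModel, use_mask: bool = True
) -> DistanceMatrix:
    """Poisson-corrected distances from saturation-filtered columns.

    Per pair of taxa, columns whose residue pair is rare under the model
    are excluded as saturated; p is the fraction of differing (frequent)
    pairs among the remaining effective sites and d = -ln(1 - p).
    Filtering is per-pair: each pair keeps its own column set, and the
    per-pair effective-site counts are reported.
    """
    if len(aln.ids) < 2:
        raise ValueError("need at least 2 taxa")
    rows = aln.masked_rows() if use_mask else aln.rows
    enc = _encode(rows)
    rare = model.rare_mask
    n = len(aln.ids)
    d = np.zeros((n, n))
    eff = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        a, b = enc[i], enc[j]
        valid = (a >= 0) & (b >= 0)
        av, bv = a[valid].astype(int), b[valid].astype(int)
        is_rare = rare[av, bv]
        keep = ~is_rare
        n_eff = int(keep.sum())
        if n_eff == 0:
            raise ValueError(
                f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) has zero effective sites"
            )
        n_diff = int(((av != bv) & keep).sum())
        p = n_diff / n_eff
        if p >= 1.0:
            # every effective site differs; cap at the resolution limit
            p = 1.0 - 1.0 / (2 * n_eff)
        d[i, j] = d[j, i] = -math.log(1.0 - p)
        eff[i, j] = eff[j, i] = n_eff
    return DistanceMatrix(
        taxa=list(aln.ids),
        d=d,
        effective_sites=eff,
        meta={"model": model.name, "cutoff": model.cutoff, "correction": "poisson"},
    )


def plain_distance(aln: ProteinAlignment, use_mask: bool = True) -> DistanceMatrix:
    """Unfiltered Poisson-corrected p-distance (cutoff-0 boundary case)."""
    model = lg_model(cutoff=0.0)
    dm = saturation_filtered_distance(aln, model, use_mask=use_mask)
    dm.meta["cutoff"] = 0.0
    return dm


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei agglomeration; exact on additive matrices.

    Deterministic: on tied Q values the lowest-index pair is joined.
    Negative branch-length estimates are clamped to zero at the end, as
    is conventional.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    ns = dendropy.TaxonNamespace(dm.taxa)
    nodes = []
    for label in dm.taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(label)
        nodes.append(node)
    d = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - row_sum[i] - row_sum[j]
                if best_q is None or q < best_q:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (row_sum[i] - row_sum[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[u, k] = d[k, u] = duk
        active = [k for k in active if k not in (i, j)] + [u]
    # final three-point join
    i, j, k = active
    root = dendropy.Node()
    for x, y, z in ((i, j, k), (j, i, k), (k, i, j)):
        root.add_child(nodes[x])
        nodes[x].edge.length = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# splits and Robinson-Foulds


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as leaf sets, normalised to exclude a reference
    taxon (so each bipartition appears once)."""
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    splits = set()
    for node in tree.preorder_internal_node_iter():
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = below if ref not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset(side))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds (symmetric difference of splits)."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValueError("trees have different leaf sets")
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns,
        preserve_underscores=True
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns,
        preserve_underscores=True
    )
    for t in (a, b):
        t.is_rooted = False
        t.update_bipartitions(suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=True)
    return int(treecompare.symmetric_difference(a, b))


# ---------------------------------------------------------------------------
# parsimony


def parsimony_informative_count(rows: list[str]) -> int:
    """Columns with >=2 states each present in >=2 taxa (gaps/X ignored)."""
    if not rows:
        return 0
    count = 0
    for j in range(len(rows[0])):
        tallies: dict[str, int] = {}
        for row in rows:
            ch = row[j].upper()
            if ch in AA_INDEX:
                tallies[ch] = tallies.get(ch, 0) + 1
        if sum(v >= 2 for v in tallies.values()) >= 2:
            count += 1
    return count


class _Utree:
    """Minimal unrooted leaf-labelled tree for parsimony search.

    Nodes are integers; leaves 0..n-1 carry taxon indices, internal nodes
    follow.  Edges are an adjacency map.
    """

    def __init__(self, n_leaves: int, adj: dict[int, set[int]]):
        self.n_leaves = n_leaves
        self.adj = adj

    @classmethod
    def star(cls, n_leaves_total: int = 3) -> "_Utree":
        """3-leaf star whose hub id sits beyond every eventual leaf id."""
        hub = n_leaves_total
        adj = {i: {hub} for i in range(3)}
        adj[hub] = {0, 1, 2}
        return cls(n_leaves_total, adj)

    def copy(self) -> "_Utree":
        return _Utree(self.n_leaves, {k: set(v) for k, v in self.adj.items()})

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def add_leaf(self, leaf: int, edge: tuple[int, int]) -> "_Utree":
        t = self.copy()
        u, v = edge
        mid = max(t.adj) + 1
        t.adj[u].discard(v)
        t.adj[v].discard(u)
        t.adj[u].add(mid)
        t.adj[v].add(mid)
        t.adj[mid] = {u, v, leaf}
        t.adj[leaf] = {mid}
        t.n_leaves = max(t.n_leaves, leaf + 1)
        return t

    def newick(self, taxa: list[str]) -> str:
        # root at the internal neighbor of leaf 0
        root = next(iter(self.adj[0]))

        def sub(node: int, parent: int) -> str:
            if node < self.n_leaves:
                return taxa[node]
            children = [sub(c, node) for c in self.adj[node] if c != parent]
            return "(" + ",".join(children) + ")"

        inner = [sub(c, root) for c in self.adj[root] if c != 0]
        return f"({taxa[0]},{','.join(inner)});"


def _enumerate_topologies(n_leaves: int):
    """All (2n-5)!! unrooted leaf-labelled topologies, by edge insertion."""
    trees = [_Utree.star(n_leaves)]
    for leaf in range(3, n_leaves):
        trees = [t.add_leaf(leaf, e) for t in trees for e in t.edges()]
    return trees


def _fitch_on_utree(tree: _Utree, leaf_masks: list[list[int]], weights: list[int]) -> int:
    """Fitch score via bitmask set operations, columns compressed to
    unique patterns with weights."""
    root = next(iter(tree.adj[0]))
    order: list[tuple[int, int]] = []  # (node, parent), leaves first via DFS postorder
    stack = [(root, 0)]
    seen = []
    while stack:
        node, parent = stack.pop()
        seen.append((node, parent))
        for c in tree.adj[node]:
            if c != parent:
                stack.append((c, node))
    order = list(reversed(seen))
    n_cols = len(weights)
    masks: dict[int, list[int]] = {}
    score = 0
    for node, parent in order:
        if node < tree.n_leaves:
            masks[node] = leaf_masks[node]
            continue
        children = [c for c in tree.adj[node] if c != parent]
        acc = masks[children[0]]
        out = list(acc)
        for c in children[1:]:
            cm = masks[c]
            for k in range(n_cols):
                inter = out[k] & cm[k]
                if inter:
                    out[k] = inter
                else:
                    out[k] |= cm[k]
                    score += weights[k]
        masks[node] = out
    # fold in the leaf the tree is rooted at
    lm = leaf_masks[0]
    rm = masks[root]
    for k in range(n_cols):
        if not (lm[k] & rm[k]):
            score += weights[k]
    return score


def _compress_columns(rows: list[str]) -> tuple[list[list[int]], list[int]]:
    """Unique column patterns as per-leaf state bitmasks, with counts.

    Gaps/nonstandard residues become the full state set (they never force
    a change), matching the usual missing-data convention.
    """
    n = len(rows)
    full = (1 << 20) - 1
    patterns: dict[tuple[int, ...], int] = {}
    for j in range(len(rows[0]) if rows else 0):
        col = tuple(
            (1 << AA_INDEX[rows[i][j].upper()]) if rows[i][j].upper() in AA_INDEX else full
            for i in range(n)
        )
        patterns[col] = patterns.get(col, 0) + 1
    cols = list(patterns)
    weights = [patterns[c] for c in cols]
    leaf_masks = [[col[i] for col in cols] for i in range(n)]
    return leaf_masks, weights


def fitch_score(tree: dendropy.Tree, aln: ProteinAlignment, use_mask: bool = True) -> int:
    """Minimum number of state changes on the tree (Fitch small parsimony)."""
    rows = aln.masked_rows() if use_mask else aln.rows
    if leaf_labels(tree) != set(aln.ids):
        raise ValueError("tree leaf set does not match alignment taxa")
    ut, taxa = _dendropy_to_utree(tree, aln.ids)
    order = {t: i for i, t in enumerate(taxa)}
    rows_by_taxon = [rows[aln.ids.index(t)] for t in taxa]
    leaf_masks, weights = _compress_columns(rows_by_taxon)
    return _fitch_on_utree(ut, leaf_masks, weights)


def _dendropy_to_utree(tree: dendropy.Tree, id_order: list[str]) -> tuple[_Utree, list[str]]:
    taxa = list(id_order)
    index = {t: i for i, t in enumerate(taxa)}
    t = tree.clone(depth=1)
    t.is_rooted = False
    # suppress the artificial degree-2 root dendropy may keep
    t.suppress_unifurcations()
    seed = t.seed_node
    if len(seed.child_nodes()) == 2:
        t.collapse_basal_bifurcation()
    next_id = len(taxa)
    node_ids: dict = {}
    adj: dict[int, set[int]] = {}
    for node in t.preorder_node_iter():
        if node.is_leaf():
            node_ids[node] = index[node.taxon.label]
        else:
            node_ids[node] = next_id
            next_id += 1
        adj.setdefault(node_ids[node], set())
    for node in t.preorder_node_iter():
        for child in node.child_nodes():
            adj[node_ids[node]].add(node_ids[child])
            adj[node_ids[child]].add(node_ids[node])
    return _Utree(len(taxa), adj), taxa


def _utree_to_dendropy(ut: _Utree, taxa: list[str]) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=ut.newick(taxa), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    return tree


def _nni_neighbors(ut: _Utree):
    """Both NNI rearrangements across every internal edge."""
    for u, v in ut.edges():
        if u < ut.n_leaves or v < ut.n_leaves:
            continue
        u_subs = [x for x in ut.adj[u] if x != v]
        v_subs = [x for x in ut.adj[v] if x != u]
        if len(u_subs) != 2 or len(v_subs) != 2:
            continue
        b = u_subs[1]
        for c in v_subs:
            t = ut.copy()
            t.adj[u].discard(b)
            t.adj[b].discard(u)
            t.adj[v].discard(c)
            t.adj[c].discard(v)
            t.adj[u].add(c)
            t.adj[c].add(u)
            t.adj[v].add(b)
            t.adj[b].add(v)
            yield t


def mp_search(
    aln: ProteinAlignment,
    exhaustive_limit: int = 8,
    use_mask: bool = True,
    start_tree: dendropy.Tree | None = None,
) -> tuple[list[dendropy.Tree], int]:
    """Maximum parsimony: exhaustive up to ``exhaustive_limit`` taxa
    (all co-optimal trees returned), else NNI hill-climbing from an NJ
    start tree.  Returns (best trees, best score)."""
    taxa = list(aln.ids)
    n = len(taxa)
    rows = aln.masked_rows() if use_mask else aln.rows
    leaf_masks, weights = _compress_columns(rows)
    if n < 4:
        ut = _Utree.star(n)
        return [_utree_to_dendropy(ut, taxa)], _fitch_on_utree(ut, leaf_masks, weights)
    if n <= exhaustive_limit:
        best_score, best = None, []
        for ut in _enumerate_topologies(n):
            s = _fitch_on_utree(ut, leaf_masks, weights)
            if best_score is None or s < best_score:
                best_score, best = s, [ut]
            elif s == best_score:
                best.append(ut)
        return [_utree_to_dendropy(u, taxa) for u in best], int(best_score)
    if start_tree is None:
        start_tree = neighbor_joining(plain_distance(aln, use_mask=use_mask))
    ut, order = _dendropy_to_utree(start_tree, taxa)
    rows_by_taxon = [rows[aln.ids.index(t)] for t in order]
    leaf_masks, weights = _compress_columns(rows_by_taxon)
    score = _fitch_on_utree(ut, leaf_masks, weights)
    improved = True
    while improved:
        improved = False
        for nb in _nni_neighbors(ut):
            s = _fitch_on_utree(nb, leaf_masks, weights)
            if s < score:
                ut, score, improved = nb, s, True
                break
    return [_utree_to_dendropy(ut, order)], int(score)


# ---------------------------------------------------------------------------
# bootstrap


def _resample_alignment(aln: ProteinAlignment, rng: np.random.Generator) -> ProteinAlignment:
    rows = aln.masked_rows()
    m = len(rows[0])
    idx = rng.integers(0, m, size=m)
    return ProteinAlignment(
        ids=list(aln.ids), rows=["".join(r[j] for j in idx) for r in rows]
    )


def bootstrap_support(
    aln: ProteinAlignment,
    builder,
    replicates: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """Attach column-resampling bootstrap supports to a point-estimate tree.

    ``builder`` maps a ProteinAlignment to a dendropy tree (e.g. NJ on
    filtered distances, or MP).  Support = % of replicate trees containing
    each split of the point tree, written as internal node labels.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = builder(aln)
    point_splits = tree_splits(point)
    counts = {s: 0 for s in point_splits}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        rep = builder(_resample_alignment(aln, rng))
        rep_splits = tree_splits(rep)
        for s in point_splits:
            if s in rep_splits:
                counts[s] += 1
    all_leaves = leaf_labels(point)
    ref = min(all_leaves)
    for node in point.preorder_internal_node_iter():
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = below if ref not in below else all_leaves - below
        key = frozenset(side)
        if key in counts:
            node.label = str(round(100.0 * counts[key] / replicates))
    return point


def nj_plain_builder(aln: ProteinAlignment) -> dendropy.Tree:
    return neighbor_joining(plain_distance(aln))


def nj_filtered_builder(model: SubstitutionModel | None = None):
    model = model or lg_model()

    def build(aln: ProteinAlignment) -> dendropy.Tree:
        return neighbor_joining(saturation_filtered_distance(aln, model))

    return build


def mp_builder(exhaustive_limit: int = 8):
    def build(aln: ProteinAlignment) -> dendropy.Tree:
        trees, _ = mp_search(aln, exhaustive_limit=exhaustive_limit)
        return trees[0]

    return build
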