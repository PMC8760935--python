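"""Per-window gene trees, topology classification, and quartet species trees.

Local trees are inferred by neighbor joining on Jukes-Cantor distances
with column-resampling bootstrap support; classification collapses a tree
to one leaf per population (after an outgroup rooting and monophyly
check) and matches it against enumerated reference topologies by exact
unrooted-bipartition equality.  Windows are then partitioned into
ancestry classes, and a quartet-score species-tree estimator (exhaustive
over unrooted topologies, <= 8 taxa) summarises whole or partitioned
genomes under the multispecies coalescent's quartet consistency.
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from mosaicscan.popio import PopulationMap, WindowAlignment, GenomicWindow

logger = logging.getLogger(__name__)

OTHER = "OTHER"
UNRESOLVED = "UNRESOLVED"
DEFAULT_MIN_SUPPORT = 60.0
JC_SATURATION_CAP = 0.74

__all__ = [
    "LocalTree",
    "TopologyClass",
    "TopologyDistribution",
    "jc_distance",
    "infer_local_tree",
    "classify_topology",
    "topology_distribution",
    "partition_by_ancestry",
    "quartet_species_tree",
    "OTHER",
    "UNRESOLVED",
]


@dataclass
class LocalTree:
    """A per-window gene tree with bootstrap support.

    ``tree`` is a dendropy Tree (unrooted unless rooted downstream);
    internal nodes carry ``support`` in [0, 100].
    """

    tree: "object"
    window: GenomicWindow | None = None
    mean_support: float = math.nan
    saturated: bool = False

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


@dataclass(frozen=True)
class TopologyClass:
    """One reference lineage-level topology (Newick on population labels)."""

    class_id: str
    newick: str
    description: str = ""


@dataclass
class TopologyDistribution:
    """Counts and fractions per topology class, plus OTHER and UNRESOLVED."""

    counts: dict[str, int]
    n_windows: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_windows == 0:
            return {k: math.nan for k in self.counts}
        return {k: v / self.n_windows for k, v in self.counts.items()}


# ---------------------------------------------------------------------------
# distances + NJ


def jc_distance(p_mismatch: float, cap: float = JC_SATURATION_CAP) -> tuple[float, bool]:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p).

    p is capped below 3/4 (default 0.74) to avoid infinities on saturated
    pairs; returns (distance, was_capped).
    """
    capped = p_mismatch > cap
    p = min(p_mismatch, cap)
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), capped


def _jc_matrix(mat: np.ndarray, cap: float) -> tuple[np.ndarray, bool]:
    """Pairwise JC distances from a uint8 sequence matrix (N = missing)."""
    n = mat.shape[0]
    n_code = ord("N")
    ok = mat != n_code
    dist = np.zeros((n, n))
    saturated = False
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            L = int(comp.sum())
            if L == 0:
                raise ValueError(f"all-N comparison between sequences {i} and {j}")
            p = float(((mat[i] != mat[j]) & comp).sum()) / L
            d, was_capped = jc_distance(p, cap)
            saturated |= was_capped
            dist[i, j] = dist[j, i] = d
    return dist, saturated


def _nj_tree(dist: np.ndarray, labels: Sequence[str]):
    """Neighbor joining via dendropy's PhylogeneticDistanceMatrix."""
    import dendropy

    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{x:.10f}" for x in dist[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    tree.is_rooted = False
    return tree


def _bipartitions(tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as frozensets of leaf-label frozensets."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset((side, other)))
    return out


def infer_local_tree(
    alignment: WindowAlignment,
    n_bootstrap: int = 100,
    seed: int = 0,
    saturation_cap: float = JC_SATURATION_CAP,
) -> LocalTree:
    """NJ tree on JC distances with column-resampling bootstrap support.

    Support of an internal bipartition = percentage of bootstrap replicates
    whose NJ tree contains it; ``mean_support`` averages over the internal
    bipartitions of the main tree.
    """
    if alignment.n_seqs < 4:
        raise ValueError(f"need >= 4 sequences, got {alignment.n_seqs}")
    if alignment.length == 0:
        raise ValueError("empty alignment")
    labels = alignment.samples()
    mat = alignment.matrix()
    dist, saturated = _jc_matrix(mat, saturation_cap)
    tree = _nj_tree(dist, labels)
    main_bips = _bipartitions(tree)

    counts = {b: 0 for b in main_bips}
    rng = np.random.default_rng(seed)
    n_sites = mat.shape[1]
    for _ in range(n_bootstrap):
        cols = rng.integers(0, n_sites, size=n_sites)
        b_dist, _ = _jc_matrix(mat[:, cols], saturation_cap)
        for b in _bipartitions(_nj_tree(b_dist, labels)):
            if b in counts:
                counts[b] += 1

    support: dict[frozenset, float] = {
        b: 100.0 * c / n_bootstrap if n_bootstrap else math.nan for b, c in counts.items()
    }
    all_leaves = frozenset(labels)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        key = frozenset((side, all_leaves - side))
        if key in support:
            nd.support = support[key]
            nd.label = f"{support[key]:.0f}"
    mean_support = float(np.mean(list(support.values()))) if support else math.nan
    return LocalTree(tree, alignment.window, mean_support, saturated)


def local_tree_from_newick(newick: str, window: GenomicWindow | None = None) -> LocalTree:
    """Wrap an externally inferred tree (e.g. per-window ML) for classification.

    Internal node labels that parse as numbers are taken as supports.
    """
    from mosaicscan.popio import read_newick

    tree = read_newick(newick)
    tree.is_rooted = False
    supports = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        label = nd.label or (nd.taxon.label if nd.taxon else None)
        try:
            nd.support = float(label)
            supports.append(nd.support)
        except (TypeError, ValueError):
            pass
    mean_support = float(np.mean(supports)) if supports else math.nan
    return LocalTree(tree, window, mean_support)


# ---------------------------------------------------------------------------
# classification


def _root_on_outgroup(tree, outgroup_samples: set[str]) -> tuple["object", bool]:
    """Root on the smallest clade containing all outgroup samples.

    If no clean edge separates the outgroup, root on the edge maximising
    outgroup purity and flag the tree.  Returns (rooted clone, pure)."""
    import dendropy

    t = tree.clone(depth=1)
    t.is_rooted = True
    all_leaves = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    missing = outgroup_samples - all_leaves
    if missing:
        raise KeyError(f"outgroup samples absent from tree: {sorted(missing)}")

    best_node, best_score, pure = None, -math.inf, False
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        for s in (side, all_leaves - side):
            og_in = len(outgroup_samples & s)
            others = len(s) - og_in
            score = og_in - others
            if og_in == len(outgroup_samples) and score > best_score:
                best_score = score
                best_node = nd if s == side else nd  # edge is the same either way
                pure = others == 0
    if best_node is None:  # degenerate: root stays
        return t, False
    edge = best_node.edge
    t.reroot_at_edge(edge, update_bipartitions=False)
    return t, pure


def _is_monophyletic(tree, labels: set[str]) -> bool:
    taxa = [lf.taxon for lf in tree.leaf_node_iter() if lf.taxon.label in labels]
    if len(taxa) != len(labels):
        return False
    if len(taxa) == 1:
        return True
    mrca = tree.mrca(taxa=taxa)
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == labels


def _collapsed_bipartitions(tree, leaf_to_pop: dict[str, str]) -> set[frozenset]:
    """Population-level unrooted bipartitions of a tree whose populations
    are each monophyletic (one representative leaf per population)."""
    reps: dict[str, str] = {}
    for leaf, pop in leaf_to_pop.items():
        reps.setdefault(pop, leaf)
    rep_leaves = set(reps.values())
    all_pops = frozenset(reps)
    out: set[frozenset] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side_pops = frozenset(
            leaf_to_pop[lf.taxon.label]
            for lf in nd.leaf_iter()
            if lf.taxon.label in rep_leaves
        )
        other = all_pops - side_pops
        if len(side_pops) >= 2 and len(other) >= 2:
            out.add(frozenset((side_pops, other)))
    return out


def _newick_bipartitions(newick: str) -> tuple[set[frozenset], frozenset]:
    from mosaicscan.popio import read_newick

    t = read_newick(newick)
    t.is_rooted = False
    leaves = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    return _bipartitions(t), leaves


def classify_topology(
    local_tree: LocalTree,
    pops: PopulationMap,
    classes: Sequence[TopologyClass],
    outgroup: str,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> str:
    """Assign a window tree to a reference topology class.

    The tree is rooted on the outgroup's smallest containing clade; each
    multi-sample focal population must be monophyletic (else OTHER); the
    population-collapsed tree is matched against the reference topologies
    by exact unrooted-bipartition equality.  Trees whose mean bootstrap is
    below ``min_support`` return UNRESOLVED.
    """
    if not math.isnan(local_tree.mean_support) and local_tree.mean_support < min_support:
        return UNRESOLVED

    leaf_labels = set(local_tree.leaf_labels())
    leaf_to_pop = {}
    for leaf in leaf_labels:
        if leaf not in pops:
            raise KeyError(f"sample {leaf!r} missing from population map")
        leaf_to_pop[leaf] = pops[leaf]
    present_pops = set(leaf_to_pop.values())
    if outgroup not in present_pops:
        raise KeyError(f"outgroup population {outgroup!r} absent from tree")

    og_samples = {s for s, p in leaf_to_pop.items() if p == outgroup}
    rooted, _pure = _root_on_outgroup(local_tree.tree, og_samples)

    for pop in sorted(present_pops):
        members = {s for s, p in leaf_to_pop.items() if p == pop}
        if len(members) > 1 and not _is_monophyletic(rooted, members):
            return OTHER

    observed = _collapsed_bipartitions(rooted, leaf_to_pop)
    for cls in classes:
        ref_bips, ref_leaves = _newick_bipartitions(cls.newick)
        if ref_leaves != frozenset(present_pops):
            continue
        if ref_bips == observed:
            return cls.class_id
    return OTHER


def topology_distribution(
    class_ids: Iterable[str], classes: Sequence[TopologyClass]
) -> TopologyDistribution:
    """Tally class assignments, always reporting every class plus
    OTHER/UNRESOLVED; fractions sum to 1 over all windows."""
    ids = list(class_ids)
    counts = {c.class_id: 0 for c in classes}
    counts[OTHER] = 0
    counts[UNRESOLVED] = 0
    for cid in ids:
        counts[cid] = counts.get(cid, 0) + 1
    return TopologyDistribution(counts, len(ids))


def partition_by_ancestry(
    table,
    rule: set[str],
    class_column: str = "topology_class",
    out_column: str = "ancestry",
):
    """Label windows 'in_set' / 'background' / 'unresolved' by topology class.

    ``rule`` is the set of class ids defining the in-set partition (for the
    hybrid-lineage analysis: the classes placing the focal lineage with its
    recent source).  Returns a copy of the table with ``out_column`` filled.
    """
    import pandas as pd

    if not rule:
        raise ValueError("empty ancestry rule set")
    out = table.copy()
    cls = out[class_column]
    labels = np.where(
        cls.isna() | (cls == UNRESOLVED), "unresolved", np.where(cls.isin(rule), "in_set", "background")
    )
    out[out_column] = labels
    n_in = int((labels == "in_set").sum())
    n_bg = int((labels == "background").sum())
    n_un = int((labels == "unresolved").sum())
    if n_in == 0 and n_bg == 0:
        logger.warning("partition_by_ancestry: all windows unresolved")
    logger.info("partition_by_ancestry: in_set=%d background=%d unresolved=%d", n_in, n_bg, n_un)
    return out


def collapse_to_populations(local_tree: LocalTree, pops: PopulationMap | dict[str, str]) -> "object":
    """Reduce a sample-level tree to one leaf per population.

    Keeps the lexicographically first sample of each population, prunes the
    rest, and relabels leaves with population names.  Intended for feeding
    :func:`quartet_species_tree`; meaningful when populations are
    (near-)monophyletic in the input trees.
    """
    get = pops.__getitem__ if not isinstance(pops, dict) else pops.__getitem__
    reps: dict[str, str] = {}
    for label in sorted(local_tree.leaf_labels()):
        reps.setdefault(get(label), label)
    t = local_tree.tree.clone(depth=1)
    t.retain_taxa_with_labels(list(reps.values()))
    back = {v: k for k, v in reps.items()}
    for lf in t.leaf_node_iter():
        lf.taxon.label = back[lf.taxon.label]
    return t


# ---------------------------------------------------------------------------
# quartet-score species tree


def _enumerate_unrooted(taxa: Sequence[str]) -> list[dict[int, list[int]]]:
    """All unrooted binary topologies on the taxa, as adjacency maps.

    Nodes 0..n-1 are leaves (taxa order); internal nodes number upward.
    """
    n = len(taxa)
    if n < 4:
        raise ValueError("need >= 4 taxa")
    base: dict[int, list[int]] = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    trees = [base]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for adj in trees:
            edges = {tuple(sorted((a, b))) for a, nbrs in adj.items() for b in nbrs}
            for a, b in sorted(edges):
                new = {k: list(v) for k, v in adj.items()}
                mid = max(new) + 1
                new[a].remove(b)
                new[b].remove(a)
                new[a].append(mid)
                new[b].append(mid)
                new[mid] = [a, b, leaf]
                new[leaf] = [mid]
                new_trees.append(new)
        trees = new_trees
    return trees


def _leaf_distances(adj: dict[int, list[int]], n_leaves: int) -> np.ndarray:
    nodes = sorted(adj)
    index = {v: i for i, v in enumerate(nodes)}
    size = len(nodes)
    dist = np.full((n_leaves, size), -1, dtype=np.int32)
    for leaf in range(n_leaves):
        dist[leaf, index[leaf]] = 0
        queue = [leaf]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if dist[leaf, index[v]] < 0:
                    dist[leaf, index[v]] = dist[leaf, index[u]] + 1
                    queue.append(v)
    return dist[:, [index[i] for i in range(n_leaves)]]


def _quartet_split(dist: np.ndarray, a: int, b: int, c: int, d: int) -> int | None:
    """0: ab|cd, 1: ac|bd, 2: ad|bc, None: unresolved tie."""
    sums = (dist[a, b] + dist[c, d], dist[a, c] + dist[b, d], dist[a, d] + dist[b, c])
    m = min(sums)
    if sums.count(m) != 1:
        return None
    return sums.index(m)


def _adjacency_to_newick(adj: dict[int, list[int]], taxa: Sequence[str]) -> str:
    """Canonical unrooted Newick: rooted at the internal node next to taxon 0,
    children sorted by smallest contained taxon."""

    def subtree(node: int, parent: int):
        nbrs = [x for x in adj[node] if x != parent]
        if not nbrs:
            return taxa[node], taxa[node]
        parts = [subtree(x, node) for x in nbrs]
        parts.sort(key=lambda p: p[1])
        return "(" + ",".join(p[0] for p in parts) + ")", min(p[1] for p in parts)

    anchor = adj[0][0]
    parts = [subtree(x, anchor) for x in adj[anchor] if x != 0]
    parts.sort(key=lambda p: p[1])
    return f"({taxa[0]}," + ",".join(p[0] for p in parts) + ");"


def quartet_species_tree(trees: Sequence[LocalTree | object], taxa: Sequence[str] | None = None):
    """Exhaustive quartet-score species-tree estimator (<= 8 taxa).

    Scores every unrooted topology by the total number of input-tree
    quartets it induces and returns the maximiser — the maximum-quartet-
    support species tree that is statistically consistent under the
    multispecies coalescent.  Ties are broken by lexicographic Newick
    order and reported.

    Returns a dict with 'newick', 'score', 'ties', and 'branch_support'
    (per internal bipartition: fraction of relevant input-tree quartet
    observations agreeing with it).
    """
    dtrees = [t.tree if isinstance(t, LocalTree) else t for t in trees]
    if not dtrees:
        raise ValueError("need >= 1 input tree")
    if taxa is None:
        labels: set[str] = set()
        for t in dtrees:
            labels |= {lf.taxon.label for lf in t.leaf_node_iter()}
        taxa = sorted(labels)
    n = len(taxa)
    if n > 8:
        raise ValueError(f"{n} taxa exceed the exhaustive enumeration limit of 8")
    tindex = {x: i for i, x in enumerate(taxa)}

    # tally observed quartet splits over input trees
    quartets = list(itertools.combinations(range(n), 4))
    counts = np.zeros((len(quartets), 3), dtype=np.int64)
    for t in dtrees:
        leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
        present = [x for x in leaves if x in tindex]
        # topological distances between present taxa
        idx = {x: i for i, x in enumerate(present)}
        dmat = np.zeros((len(present), len(present)), dtype=np.int32)
        _fill_topo_distances(t, present, dmat, idx)
        for qi, (a, b, c, d) in enumerate(quartets):
            names = [taxa[a], taxa[b], taxa[c], taxa[d]]
            if any(x not in idx for x in names):
                continue
            ia, ib, ic, id_ = (idx[x] for x in names)
            split = _quartet_split(dmat, ia, ib, ic, id_)
            if split is not None:
                counts[qi, split] += 1

    best_score = -1
    best: list[tuple[str, dict]] = []
    for adj in _enumerate_unrooted(taxa):
        dist = _leaf_distances(adj, n)
        score = 0
        induced = {}
        for qi, (a, b, c, d) in enumerate(quartets):
            split = _quartet_split(dist, a, b, c, d)
            induced[qi] = split
            if split is not None:
                score += int(counts[qi, split])
        if score > best_score:
            best_score = score
            best = [(_adjacency_to_newick(adj, taxa), {"adj": adj, "induced": induced})]
        elif score == best_score:
            best.append((_adjacency_to_newick(adj, taxa), {"adj": adj, "induced": induced}))

    best.sort(key=lambda x: x[0])
    newick, info = best[0]
    ties = [nwk for nwk, _ in best[1:]]
    if ties:
        logger.warning("quartet_species_tree: %d tied topologies; lexicographic winner kept", len(ties))

    # per-branch quartet support on the winning topology
    branch_support = _branch_quartet_support(info["adj"], taxa, quartets, counts)
    return {"newick": newick, "score": int(best_score), "ties": ties, "branch_support": branch_support}


def _fill_topo_distances(tree, present: list[str], dmat: np.ndarray, idx: dict[str, int]) -> None:
    """Pairwise path lengths (edge counts) between the named leaves,
    breadth-first over the (unrooted) node graph."""
    leaf_nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter() if lf.taxon.label in idx}

    def neighbours(nd):
        out = list(nd.child_nodes())
        if nd.parent_node is not None:
            out.append(nd.parent_node)
        return out

    for label, start in leaf_nodes.items():
        dist = {start: 0}
        queue = [start]
        while queue:
            u = queue.pop(0)
            for v in neighbours(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for other, nd in leaf_nodes.items():
            dmat[idx[label], idx[other]] = dist[nd]


def _branch_quartet_support(
    adj: dict[int, list[int]], taxa: Sequence[str], quartets, counts
) -> dict[str, float]:
    n = len(taxa)
    dist = _leaf_distances(adj, n)
    # leafsets on each side of every internal edge
    supports: dict[str, float] = {}
    edges = {tuple(sorted((a, b))) for a, nbrs in adj.items() for b in nbrs}
    for a, b in sorted(edges):
        if a < n or b < n:
            continue  # pendant edge
        side = _leaves_beyond(adj, a, b, n)
        if len(side) < 2 or n - len(side) < 2:
            continue
        other = [i for i in range(n) if i not in side]
        agree = 0
        total = 0
        for qi, (p, q, r, s) in enumerate(quartets):
            members = [p, q, r, s]
            in_side = [x for x in members if x in side]
            if len(in_side) != 2:
                continue
            x1, x2 = in_side
            y1, y2 = [x for x in members if x not in side]
            split = _quartet_split(dist, p, q, r, s)
            total += int(counts[qi].sum())
            if split is not None:
                agree += int(counts[qi, split])
        key = "{" + ",".join(sorted(taxa[i] for i in side)) + "}"
        supports[key] = agree / total if total else math.nan
    return supports


def _leaves_beyond(adj: dict[int, list[int]], start: int, blocked: int, n_leaves: int) -> set[int]:
    """Leaves reachable from ``start`` without crossing the edge to ``blocked``."""
    seen = {start}
    queue = [start]
    while queue:
        u = queue.pop(0)
        for v in adj[u]:
            if v == blocked and u == start:
                continue
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return {x for x in seen if x < n_leaves}
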