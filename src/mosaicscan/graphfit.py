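"""Admixture graphs: expected f-statistics and fixed-topology fitting.

An admixture graph is a rooted DAG in which ordinary nodes have one parent
(the connecting edge carries a drift length ``c >= 0`` in f2 units) and
admixture nodes have exactly two parents, receiving a fraction ``alpha``
of their ancestry from the first and ``1 - alpha`` from the second
(admixture edges carry no drift).  Leaves may be unsampled ("ghost"
lineages, e.g. extinct donors); only sampled leaves enter the fitting
basis.

Expected f-statistics follow the standard path algebra: a lineage sampled
at a leaf traverses edge ``e`` with total probability ``w(leaf, e)`` (sum
over root paths of the product of admixture weights chosen), and

    E[f4(A,B; C,D)] = sum_e c_e (w(A,e) - w(B,e)) (w(C,e) - w(D,e))

with f2/f3 as the corresponding quadratic forms.  Fitting minimises the
diagonal-weighted least squares of observed versus expected statistics
over the free drift lengths and admixture weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares, lsq_linear
from scipy.stats import qmc

logger = logging.getLogger(__name__)

__all__ = [
    "AdmixtureGraph",
    "GraphInvalidError",
    "GraphFitResult",
    "ObservedStat",
    "path_weights",
    "expected_f2",
    "expected_f3",
    "expected_f4",
    "f2_basis",
    "fit_graph",
]

FREE = None  # sentinel for a free parameter in graph files


class GraphInvalidError(ValueError):
    """The graph violates the admixture-graph invariants."""


@dataclass
class AdmixtureGraph:
    """Rooted DAG with drift-length edges and two-parent admixture nodes.

    ``edges`` maps (child, parent) -> drift length (or None = free).
    ``admixtures`` maps node -> (parent1, parent2, alpha-or-None); alpha is
    the weight on parent1.  ``ghosts`` lists unsampled leaves.
    """

    edges: dict[tuple[str, str], float | None] = field(default_factory=dict)
    admixtures: dict[str, tuple[str, str, float | None]] = field(default_factory=dict)
    ghosts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def nodes(self) -> list[str]:
        out: list[str] = []
        for child, parent in self.edges:
            for n in (child, parent):
                if n not in out:
                    out.append(n)
        for node, (p1, p2, _) in self.admixtures.items():
            for n in (node, p1, p2):
                if n not in out:
                    out.append(n)
        return out

    def parents(self, node: str) -> list[str]:
        if node in self.admixtures:
            return list(self.admixtures[node][:2])
        return [p for (c, p) in self.edges if c == node]

    def children(self, node: str) -> list[str]:
        out = [c for (c, p) in self.edges if p == node]
        out += [n for n, (p1, p2, _) in self.admixtures.items() if node in (p1, p2)]
        return out

    @property
    def root(self) -> str:
        roots = [n for n in self.nodes() if not self.parents(n)]
        if len(roots) != 1:
            raise GraphInvalidError(f"graph must have exactly one root, found {roots}")
        return roots[0]

    def leaves(self) -> list[str]:
        return [n for n in self.nodes() if not self.children(n)]

    def sampled_leaves(self) -> list[str]:
        return [n for n in self.leaves() if n not in self.ghosts]

    def topological_order(self) -> list[str]:
        """Root-first order; raises on cycles."""
        nodes = self.nodes()
        n_parents = {n: len(self.parents(n)) for n in nodes}
        queue = [n for n in nodes if n_parents[n] == 0]
        order: list[str] = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for c in self.children(n):
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    queue.append(c)
        if len(order) != len(nodes):
            raise GraphInvalidError("cycle detected in admixture graph")
        return order

    def validate(self) -> None:
        for node in self.admixtures:
            tree_parents = [p for (c, p) in self.edges if c == node]
            if tree_parents:
                raise GraphInvalidError(f"admixture node {node} also has tree edge(s) to {tree_parents}")
        for n in self.nodes():
            if n not in self.admixtures and len(self.parents(n)) > 1:
                raise GraphInvalidError(f"non-admixture node {n} has multiple parents")
        for (c, p), length in self.edges.items():
            if length is not None and length < 0:
                raise GraphInvalidError(f"negative drift on edge {c}<-{p}")
        for node, (_, _, alpha) in self.admixtures.items():
            if alpha is not None and not (0.0 <= alpha <= 1.0):
                raise GraphInvalidError(f"alpha of {node} outside [0,1]")
        self.topological_order()  # raises on cycles
        _ = self.root
        root = self.root
        for leaf in self.sampled_leaves():
            seen: set[str] = set()
            stack = [leaf]
            while stack:
                n = stack.pop()
                if n in seen:
                    continue
                seen.add(n)
                stack.extend(self.parents(n))
            if root not in seen:
                raise GraphInvalidError(f"sampled leaf {leaf} not reachable from root")

    # -- parameters --------------------------------------------------------

    def free_edges(self) -> list[tuple[str, str]]:
        return [e for e, v in self.edges.items() if v is None]

    def free_admixtures(self) -> list[str]:
        return [n for n, (_, _, a) in self.admixtures.items() if a is None]

    def with_parameters(
        self,
        lengths: dict[tuple[str, str], float] | None = None,
        alphas: dict[str, float] | None = None,
    ) -> "AdmixtureGraph":
        """Copy with free (or overridden) parameters bound to values."""
        edges = dict(self.edges)
        for e, v in (lengths or {}).items():
            if e not in edges:
                raise KeyError(f"unknown edge {e}")
            edges[e] = float(v)
        adm = dict(self.admixtures)
        for n, a in (alphas or {}).items():
            p1, p2, _ = adm[n]
            adm[n] = (p1, p2, float(a))
        return AdmixtureGraph(edges, adm, set(self.ghosts))

    def freed(self, edges: Iterable[tuple[str, str]] = (), admixtures: Iterable[str] = ()) -> "AdmixtureGraph":
        """Copy with the named parameters marked free."""
        e = dict(self.edges)
        for key in edges:
            e[key] = None
        adm = dict(self.admixtures)
        for n in admixtures:
            p1, p2, _ = adm[n]
            adm[n] = (p1, p2, None)
        return AdmixtureGraph(e, adm, set(self.ghosts))

    # -- text format -------------------------------------------------------

    @classmethod
    def from_text(cls, text_or_path: str | Path) -> "AdmixtureGraph":
        """Parse the one-record-per-line graph format::

            edge  <child> <parent> <length|free>
            admix <node> <parent1> <parent2> <alpha|free>
            ghost <leaf>
        """
        text = str(text_or_path)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        edges: dict[tuple[str, str], float | None] = {}
        adm: dict[str, tuple[str, str, float | None]] = {}
        ghosts: set[str] = set()
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            kind = parts[0]
            if kind == "edge" and len(parts) == 4:
                edges[(parts[1], parts[2])] = None if parts[3] == "free" else float(parts[3])
            elif kind == "admix" and len(parts) == 5:
                adm[parts[1]] = (parts[2], parts[3], None if parts[4] == "free" else float(parts[4]))
            elif kind == "ghost" and len(parts) == 2:
                ghosts.add(parts[1])
            else:
                raise GraphInvalidError(f"line {lineno}: cannot parse {raw!r}")
        return cls(edges, adm, ghosts)

    def to_text(self) -> str:
        lines = []
        for (c, p), v in self.edges.items():
            lines.append(f"edge {c} {p} {'free' if v is None else format(v, '.6g')}")
        for n, (p1, p2, a) in self.admixtures.items():
            lines.append(f"admix {n} {p1} {p2} {'free' if a is None else format(a, '.6g')}")
        for g in sorted(self.ghosts):
            lines.append(f"ghost {g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# path weights and expected f-statistics


def path_weights(graph: AdmixtureGraph, leaf: str) -> dict[tuple[str, str], float]:
    """Probability that a lineage sampled at ``leaf`` traverses each edge.

    Keys cover drift edges and admixture parent edges (the latter keyed
    (admixture-node, parent)).  At an admixture node the ancestry flow
    splits alpha / (1 - alpha) between the two parents.
    """
    if leaf in graph.ghosts:
        raise ValueError(f"leaf {leaf!r} is a ghost (unsampled)")
    if leaf not in graph.leaves():
        raise ValueError(f"{leaf!r} is not a leaf")
    node_w = {n: 0.0 for n in graph.nodes()}
    node_w[leaf] = 1.0
    weights: dict[tuple[str, str], float] = {}
    for n in reversed(graph.topological_order()):
        w = node_w[n]
        if w == 0.0:
            continue
        if n in graph.admixtures:
            p1, p2, alpha = graph.admixtures[n]
            if alpha is None:
                raise ValueError(f"alpha of {n} unbound; bind parameters first")
            weights[(n, p1)] = weights.get((n, p1), 0.0) + alpha * w
            weights[(n, p2)] = weights.get((n, p2), 0.0) + (1 - alpha) * w
            node_w[p1] += alpha * w
            node_w[p2] += (1 - alpha) * w
        else:
            for (c, p) in graph.edges:
                if c == n:
                    weights[(c, p)] = weights.get((c, p), 0.0) + w
                    node_w[p] += w
    return weights


def _drift_weights(graph: AdmixtureGraph, leaves: Sequence[str]) -> tuple[list[tuple[str, str]], np.ndarray]:
    edge_list = list(graph.edges)
    mat = np.zeros((len(leaves), len(edge_list)))
    for i, leaf in enumerate(leaves):
        w = path_weights(graph, leaf)
        for j, e in enumerate(edge_list):
            mat[i, j] = w.get(e, 0.0)
    return edge_list, mat


def expected_f4(graph: AdmixtureGraph, a: str, b: str, c: str, d: str) -> float:
    """E[f4(A,B; C,D)] under the graph (all parameters bound)."""
    edge_list, w = _drift_weights(graph, [a, b, c, d])
    lengths = np.array([graph.edges[e] for e in edge_list], dtype=float)
    if np.isnan(lengths).any():
        raise ValueError("graph has unbound drift lengths")
    return float(np.sum(lengths * (w[0] - w[1]) * (w[2] - w[3])))


def expected_f2(graph: AdmixtureGraph, a: str, b: str) -> float:
    return expected_f4(graph, a, b, a, b)


def expected_f3(graph: AdmixtureGraph, x: str, a: str, b: str) -> float:
    return expected_f4(graph, x, a, x, b)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ObservedStat:
    """One fitted f-statistic: kind in {'f2','f3','f4'}, its populations,
    the block-jackknife estimate and standard error."""

    kind: str
    populations: tuple[str, ...]
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if self.kind not in ("f2", "f3", "f4"):
            raise ValueError(f"unsupported statistic kind {self.kind!r}")
        if not (self.se > 0):
            raise ValueError("observed statistics need positive SEs")


def f2_basis(freqs, leaves: Sequence[str], n_blocks: int = 50) -> list[ObservedStat]:
    """All pairwise unbiased f2 statistics with jackknife SEs.

    The unbiased estimator subtracts the within-population sampling terms
    p(1-p)/(n-1) so expectations match the graph path algebra at small
    sample sizes.
    """
    from mosaicscan.fstats import block_jackknife

    out = []
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            r = block_jackknife(freqs, "f2", (a, b), n_blocks=n_blocks, unbiased=True)
            if r.se is None or r.se == 0:
                raise ValueError(f"f2({a},{b}) has no usable jackknife SE")
            out.append(ObservedStat("f2", (a, b), r.estimate, r.se))
    return out


@dataclass
class GraphFitResult:
    graph: AdmixtureGraph
    lengths: dict[tuple[str, str], float]
    alphas: dict[str, float]
    residual_z: dict[tuple[str, tuple[str, ...]], float]
    worst_abs_z: float
    objective: float
    converged: bool
    unidentifiable: list[str]
    n_restarts: int
    length_scale: float | None = None

    def adequate(self, z_threshold: float = 3.0) -> bool:
        return self.worst_abs_z < z_threshold

    def fitted_graph(self) -> AdmixtureGraph:
        lengths = dict(self.lengths)
        if self.length_scale is not None:
            for e, v in self.graph.edges.items():
                if v is not None:
                    lengths[e] = v * self.length_scale
        return self.graph.with_parameters(lengths, self.alphas)


_EXPECT = {"f2": expected_f2, "f3": expected_f3, "f4": expected_f4}


def _stat_edge_terms(
    graph_with_alphas: AdmixtureGraph,
    observed: Sequence[ObservedStat],
    edge_list: list[tuple[str, str]],
) -> np.ndarray:
    """Matrix T[s, e] with expected stat s = sum_e c_e T[s, e].

    Expected f-statistics are linear in the drift lengths once the
    admixture weights are bound; T holds the path-weight products.
    """
    leaves = sorted({p for s in observed for p in s.populations})
    w = {leaf: path_weights(graph_with_alphas, leaf) for leaf in leaves}

    def wvec(leaf: str) -> np.ndarray:
        return np.array([w[leaf].get(e, 0.0) for e in edge_list])

    rows = []
    for s in observed:
        if s.kind == "f2":
            a, b = s.populations
            rows.append((wvec(a) - wvec(b)) ** 2)
        elif s.kind == "f3":
            x, a, b = s.populations
            rows.append((wvec(x) - wvec(a)) * (wvec(x) - wvec(b)))
        else:
            a, b, c, d = s.populations
            rows.append((wvec(a) - wvec(b)) * (wvec(c) - wvec(d)))
    return np.vstack(rows)


def fit_graph(
    graph: AdmixtureGraph,
    observed: Sequence[ObservedStat],
    n_restarts: int = 20,
    seed: int = 0,
    length_scale: bool = False,
) -> GraphFitResult:
    """Least-squares fit of free drift lengths and admixture weights.

    Minimises ``sum(((obs - expected)/SE)**2)`` over ``c_e >= 0`` and
    ``alpha in [0,1]``.  Because expected f-statistics are linear in the
    drift lengths at fixed admixture weights, free lengths are profiled
    out exactly by bounded linear least squares; the outer optimisation
    runs only over the free admixture weights, multi-started from
    ``n_restarts`` Latin-hypercube draws under a fixed seed (plus the box
    centre), best objective winning with ties by first found.

    With ``length_scale=True`` the graph's *bound* drift lengths are
    treated as a pattern multiplied by one free non-negative scale factor
    (solved linearly) — useful when the proposal's lengths are in
    different units than the observed statistics (e.g. a simulator's
    variance coefficients versus f2 units).

    Residual Z-scores per statistic and the worst |Z| are reported
    (adequacy convention: worst |Z| < 3); parameters with vanishing
    sensitivity at the optimum are flagged unidentifiable, not fatal.
    """
    free_e = graph.free_edges()
    free_a = graph.free_admixtures()
    if not free_e and not free_a and not length_scale:
        raise ValueError("graph has no free parameters")
    sampled = set(graph.sampled_leaves())
    for stat in observed:
        missing = [p for p in stat.populations if p not in sampled]
        if missing:
            raise ValueError(f"observed {stat.kind}{stat.populations} uses non-sampled leaves {missing}")

    edge_list = list(graph.edges)
    fixed_idx = [i for i, e in enumerate(edge_list) if e not in free_e]
    free_idx = [i for i, e in enumerate(edge_list) if e in free_e]
    fixed_lengths = np.array([graph.edges[edge_list[i]] for i in fixed_idx], dtype=float)

    obs_vals = np.array([s.estimate for s in observed])
    obs_ses = np.array([s.se for s in observed])
    w_inv = 1.0 / obs_ses

    n_lin = len(free_idx) + (1 if length_scale else 0)

    def inner_solve(avec: np.ndarray):
        """Profile out the linear parameters at fixed admixture weights."""
        g = graph.with_parameters(alphas=dict(zip(free_a, avec)))
        terms = _stat_edge_terms(g, observed, edge_list)
        cols = []
        if free_idx:
            cols.append(terms[:, free_idx])
        if length_scale:
            cols.append((terms[:, fixed_idx] @ fixed_lengths)[:, None])
            offset = np.zeros(len(observed))
        else:
            offset = terms[:, fixed_idx] @ fixed_lengths if fixed_idx else np.zeros(len(observed))
        if cols:
            A = np.hstack(cols) * w_inv[:, None]
            y = (obs_vals - offset) * w_inv
            sol = lsq_linear(A, y, bounds=(0.0, np.inf))
            lin = sol.x
            resid = A @ lin - y  # weighted (expected - observed)/SE with sign flipped below
            return lin, -resid, A
        resid = (obs_vals - offset) * w_inv
        return np.zeros(0), resid, np.zeros((len(observed), 0))

    def outer_residuals(avec: np.ndarray) -> np.ndarray:
        _, resid, _ = inner_solve(avec)
        return resid

    if free_a:
        starts = [np.full(len(free_a), 0.5)]
        if n_restarts > 1:
            sampler = qmc.LatinHypercube(d=len(free_a), seed=seed)
            starts += list(sampler.random(n_restarts - 1))
        best_avec, best_obj, converged = None, math.inf, False
        for x0 in starts:
            sol = least_squares(
                outer_residuals, np.asarray(x0, dtype=float),
                bounds=(np.zeros(len(free_a)), np.ones(len(free_a))),
                method="trf", diff_step=1e-4,
            )
            obj = float(2 * sol.cost)
            if obj < best_obj - 1e-12:
                best_avec, best_obj, converged = sol.x, obj, bool(sol.success)
        n_starts = len(starts)
    else:
        best_avec, converged, n_starts = np.zeros(0), True, 1

    lin, resid, A = inner_solve(best_avec)
    best_obj = float(np.sum(resid**2))

    unident: list[str] = []
    col_norm = np.linalg.norm(A, axis=0) if A.size else np.zeros(A.shape[1])
    ref = float(np.max(col_norm)) if len(col_norm) else 0.0
    for j, e in enumerate(free_e):
        if col_norm[j] < 1e-10 * (ref + 1e-300):
            unident.append(f"edge {e}")
    if free_a:
        jac = np.empty((len(observed), len(free_a)))
        for k in range(len(free_a)):
            step = 1e-5
            up = np.clip(best_avec.copy(), 0, 1)
            up[k] = min(1.0, up[k] + step)
            dn = best_avec.copy()
            dn[k] = max(0.0, dn[k] - step)
            jac[:, k] = (outer_residuals(up) - outer_residuals(dn)) / (up[k] - dn[k])
        for k, name in enumerate(free_a):
            if np.linalg.norm(jac[:, k]) < 1e-8:
                unident.append(f"alpha {name}")
    if unident:
        logger.warning("fit_graph: parameters with zero sensitivity: %s", unident)

    lengths = {e: float(lin[j]) for j, e in enumerate(free_e)}
    scale = float(lin[len(free_e)]) if length_scale else None
    alphas = {n: float(a) for n, a in zip(free_a, best_avec)}
    residual_z = {(s.kind, s.populations): float(r) for s, r in zip(observed, resid)}
    return GraphFitResult(
        graph=graph,
        lengths=lengths,
        alphas=alphas,
        residual_z=residual_z,
        worst_abs_z=float(np.max(np.abs(resid))) if len(resid) else 0.0,
        objective=best_obj,
        converged=converged,
        unidentifiable=unident,
        n_restarts=n_starts,
        length_scale=scale,
    )
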