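"""Ground-truth synthetic data generators.

Two generators give every pipeline stage a harness with known truth:

* :func:`simulate_graph_drift` — population allele frequencies evolve by
  genetic drift along a user-specified admixture graph (normal
  approximation to Wright-Fisher, variance ``c p(1-p)`` per edge of drift
  length ``c``, absorbing at 0/1; admixture nodes mix their parents'
  frequencies ``alpha p1 + (1-alpha) p2``), then diploid genotypes are
  drawn binomially.  This emulates unlinked genome-wide SNVs shaped by a
  reticulate lineage history.

* :func:`simulate_msc_windows` — per-window gene trees follow a
  multispecies coalescent on a species network: lineages coalesce at rate
  1 per pair per coalescent unit within species branches, and at a hybrid
  node each entering lineage independently chooses a parental branch
  according to the inheritance probability gamma.  Sequences evolve by
  JC69 with branch lengths = coalescent units x mu.  This reproduces the
  window-to-window topology mosaic produced by hybridization on top of
  incomplete lineage sorting.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng`` (PCG64), so fixed seeds give bit-identical
output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mosaicscan.graphfit import AdmixtureGraph
from mosaicscan.popio import (
    GenomicWindow,
    GenotypeMatrix,
    PopulationMap,
    WindowAlignment,
    write_fasta,
    write_popmap,
    write_vcf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DriftSimConfig",
    "NetworkSimConfig",
    "simulate_graph_drift",
    "simulate_msc_windows",
    "emit_fixture_suite",
    "FIG3C_ANALOG_GRAPH",
    "QUARTET_GENE_FLOW_GRAPH",
]


# Six-lineage admixture graph patterned on the wall-lizard history: an
# outgroup (O), a ghost basal lineage (G0-G2, unsampled) that is sister to
# all ingroup lineages, SA basal among the extant ingroup, CI sister to the
# Western-Europe/Balkan clade, and a hybrid Southern-Italy lineage (SI)
# drawing 32% of its ancestry from the CI lineage and 68% from the ghost.
# The ghost also contributed 10% to the ancestor of all non-SA ingroup
# lineages.  Drift lengths are 0.01-0.05 per edge.
FIG3C_ANALOG_GRAPH = """\
# Six sampled ingroup lineages + outgroup, one ghost basal source.
edge  O    R    0.05
edge  X0   R    0.01
edge  G0   X0   0.01
edge  G1   G0   0.02
edge  G2   G1   0.02
edge  S0   X0   0.01
edge  SA   S0   0.03
edge  T1   S0   0.02
admix M    T1   G1   0.90
edge  CIa  M    0.02
edge  WB   M    0.02
edge  CIm  CIa  0.01
edge  CI   CIm  0.02
edge  WE   WB   0.03
edge  B    WB   0.02
edge  NB   B    0.02
edge  SB   B    0.02
admix H    CIm  G2   0.32
edge  SI   H    0.02
"""

# Four-population gene-flow scenario (((P1,P2),P3),O): P2 receives 20% of
# its ancestry from the P3 lineage.
QUARTET_GENE_FLOW_GRAPH = """\
edge  O    R    0.02
edge  X    R    0.02
edge  P3s  X    0.02
edge  A    X    0.02
edge  P1   A    0.02
edge  P2a  A    0.02
admix P2m  P2a  P3s  0.8
edge  P2   P2m  0.02
edge  P3   P3s  0.02
"""


# ---------------------------------------------------------------------------
# drift along an admixture graph


@dataclass
class DriftSimConfig:
    """Configuration for the admixture-graph drift simulator.

    graph must have every drift length and admixture weight bound.  The
    root allele frequency is drawn uniformly on ``root_freq_range`` per
    locus.  ``mode`` 'normal' uses the normal approximation to drift;
    'wf' runs explicit Wright-Fisher binomial generations (population size
    ``wf_n`` diploids, ``round(c * 2 * wf_n)`` generations per edge) for
    cross-checking.
    """

    graph: AdmixtureGraph
    n_loci: int
    samples_per_leaf: int = 3
    root_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    mode: str = "normal"
    wf_n: int = 500

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.mode not in ("normal", "wf"):
            raise ValueError("mode must be 'normal' or 'wf'")
        if self.graph.free_edges() or self.graph.free_admixtures():
            raise ValueError("all graph parameters must be concrete for simulation")


def _drift_step(p: np.ndarray, c: float, rng: np.random.Generator, mode: str, wf_n: int) -> np.ndarray:
    if c == 0:
        return p.copy()
    if mode == "normal":
        out = p + rng.normal(0.0, 1.0, size=p.shape) * np.sqrt(c * p * (1 - p))
        return np.clip(out, 0.0, 1.0)
    two_n = 2 * wf_n
    gens = max(1, round(c * two_n))
    out = p.copy()
    for _ in range(gens):
        out = rng.binomial(two_n, out) / two_n
    return out


def simulate_graph_drift(config: DriftSimConfig):
    """Simulate genotypes under drift along an admixture graph.

    Returns ``(GenotypeMatrix, PopulationMap, truth)`` where truth records
    the generating graph and the true per-population allele frequencies.
    """
    rng = np.random.default_rng(config.seed)
    graph = config.graph
    lo, hi = config.root_freq_range
    p_root = rng.uniform(lo, hi, size=config.n_loci)

    node_freq: dict[str, np.ndarray] = {}
    for node in graph.topological_order():
        parents = graph.parents(node)
        if not parents:
            node_freq[node] = p_root
        elif node in graph.admixtures:
            p1, p2, alpha = graph.admixtures[node]
            node_freq[node] = alpha * node_freq[p1] + (1 - alpha) * node_freq[p2]
        else:
            (parent,) = parents
            c = graph.edges[(node, parent)]
            node_freq[node] = _drift_step(node_freq[parent], c, rng, config.mode, config.wf_n)

    leaves = graph.sampled_leaves()
    samples: list[str] = []
    assignments: dict[str, str] = {}
    cols: list[np.ndarray] = []
    for leaf in leaves:
        p = node_freq[leaf]
        for k in range(config.samples_per_leaf):
            name = f"{leaf}_{k}"
            samples.append(name)
            assignments[name] = leaf
            cols.append(rng.binomial(2, p).astype(np.int8))

    n = config.n_loci
    geno = GenotypeMatrix(
        np.full(n, "1", dtype=object),
        np.arange(n, dtype=np.int64),
        np.full(n, "A", dtype=object),
        np.full(n, "T", dtype=object),
        np.column_stack(cols),
        samples,
    )
    pops = PopulationMap(assignments, list(leaves))
    truth = {
        "graph": graph,
        "leaf_frequencies": {leaf: node_freq[leaf] for leaf in leaves},
        "root_frequency": p_root,
        "seed": config.seed,
    }
    return geno, pops, truth


def true_frequency_table(truth: dict):
    """True population frequencies from a drift-sim truth record, as an
    AlleleFrequencyTable (no sampling noise; for calibration tests)."""
    from mosaicscan.popio import AlleleFrequencyTable

    leaves = list(truth["leaf_frequencies"])
    freq = np.column_stack([truth["leaf_frequencies"][x] for x in leaves])
    n = freq.shape[0]
    return AlleleFrequencyTable(
        np.full(n, "1", dtype=object), np.arange(n, dtype=np.int64), freq, leaves
    )


# ---------------------------------------------------------------------------
# multispecies coalescent with hybridization


@dataclass
class HybridEvent:
    """At the top of ``node``'s pendant branch, each entering lineage jumps
    into the branch above ``donor`` with probability ``gamma_donor`` (and
    otherwise follows the species tree)."""

    node: str
    donor: str
    gamma_donor: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma_donor <= 1.0):
            raise ValueError("gamma must lie in [0,1]")


@dataclass
class NetworkSimConfig:
    """Species network simulation settings.

    species_tree: ultrametric Newick with branch lengths in coalescent
    units.  hybrids: hybridization events grafted onto the tree.  mu:
    substitutions per site per coalescent unit.
    """

    species_tree: str
    hybrids: list[HybridEvent] = field(default_factory=list)
    samples_per_species: int | dict[str, int] = 2
    n_windows: int = 100
    sites_per_window: int = 1000
    mu: float = 0.01
    seed: int = 0
    window_length: int | None = None  # genomic footprint; defaults to sites_per_window

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.n_windows < 1 or self.sites_per_window < 1:
            raise ValueError("need >= 1 window and >= 1 site")


class _SpeciesNetwork:
    """Internal event-time representation of the species network."""

    def __init__(self, config: NetworkSimConfig):
        import dendropy

        tree = dendropy.Tree.get(data=config.species_tree, schema="newick")
        self.parent: dict[str, str | None] = {}
        self.time: dict[str, float] = {}
        self.children: dict[str, list[str]] = {}
        self.leaves: list[str] = []

        def label(nd) -> str:
            if nd.taxon is not None:
                return nd.taxon.label
            if nd.label:
                return nd.label
            nd.label = f"_n{id(nd) % 100000}"
            return nd.label

        # node ages from leaf depth (tree must be ultrametric)
        depths = {}
        for nd in tree.preorder_node_iter():
            depths[nd] = (depths[nd.parent_node] if nd.parent_node else 0.0) + (nd.edge.length or 0.0)
        max_depth = max(d for nd, d in depths.items() if nd.is_leaf())
        for nd in tree.preorder_node_iter():
            name = label(nd)
            self.time[name] = max_depth - depths[nd]
            self.parent[name] = label(nd.parent_node) if nd.parent_node else None
            self.children.setdefault(name, [])
            if nd.parent_node:
                self.children.setdefault(label(nd.parent_node), []).append(name)
            if nd.is_leaf():
                self.leaves.append(name)
                if abs(self.time[name]) > 1e-9:
                    raise ValueError("species tree must be ultrametric (all tips at time 0)")
        self.root = label(tree.seed_node)
        self.hybrids = {h.node: h for h in config.hybrids}
        for h in config.hybrids:
            if h.node not in self.time or h.donor not in self.time:
                raise ValueError(f"hybrid event references unknown node(s): {h.node}/{h.donor}")

    def branch_at(self, node: str, t: float) -> str:
        """The branch (named by its child node) on the path above ``node``
        whose time interval contains ``t``."""
        x = node
        while self.parent[x] is not None and self.time[self.parent[x]] <= t:
            x = self.parent[x]
        return x


def _n_samples(samples_per_species: int | dict[str, int], species: str) -> int:
    if isinstance(samples_per_species, dict):
        return samples_per_species.get(species, 0)
    return samples_per_species


def _sim_gene_tree(net: _SpeciesNetwork, samples_per_species, rng: np.random.Generator):
    """One gene tree under the network MSC.

    Returns (newick string with branch lengths in coalescent units,
    hybrid-choice record {species: [chose_donor per lineage]}).
    """
    next_id = [0]

    def new_node(name, t, children=None):
        return {"name": name, "time": t, "children": children or []}

    active: dict[str, list[dict]] = {}  # branch (child-node name) -> lineages
    for sp in net.leaves:
        active[sp] = [
            new_node(f"{sp}_{k}", 0.0) for k in range(_n_samples(samples_per_species, sp))
        ]
    choices: dict[str, list[bool]] = {}

    def coalesce_in(branch: str, t_start: float, t_end: float):
        lineages = active.get(branch, [])
        t = t_start
        while len(lineages) >= 2:
            rate = len(lineages) * (len(lineages) - 1) / 2.0
            t += rng.exponential(1.0 / rate)
            if t >= t_end:
                break
            i, j = rng.choice(len(lineages), size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            parent = new_node(f"c{next_id[0]}", t, [lineages[i], lineages[j]])
            next_id[0] += 1
            lineages = [x for k, x in enumerate(lineages) if k not in (i, j)] + [parent]
        active[branch] = lineages

    event_times = sorted({net.time[n] for n in net.time} - {0.0})
    t_prev = 0.0
    for t_ev in event_times:
        for branch in list(active):
            coalesce_in(branch, t_prev, t_ev)
        # species nodes reaching time t_ev absorb their children's branches,
        # applying any hybrid jump first
        for node in [n for n in net.time if abs(net.time[n] - t_ev) < 1e-12]:
            for child in net.children.get(node, []):
                movers = active.pop(child, [])
                if child in net.hybrids and movers:
                    ev = net.hybrids[child]
                    go_donor = rng.random(len(movers)) < ev.gamma_donor
                    choices.setdefault(child, []).extend(bool(g) for g in go_donor)
                    donor_branch = net.branch_at(ev.donor, t_ev)
                    active.setdefault(donor_branch, []).extend(
                        m for m, g in zip(movers, go_donor) if g
                    )
                    movers = [m for m, g in zip(movers, go_donor) if not g]
                active.setdefault(node, []).extend(movers)
        t_prev = t_ev

    # root branch: coalesce to one lineage
    root_lineages = active.get(net.root, [])
    t = t_prev
    while len(root_lineages) >= 2:
        rate = len(root_lineages) * (len(root_lineages) - 1) / 2.0
        t += rng.exponential(1.0 / rate)
        i, j = rng.choice(len(root_lineages), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = new_node(f"c{next_id[0]}", t, [root_lineages[i], root_lineages[j]])
        next_id[0] += 1
        root_lineages = [x for k, x in enumerate(root_lineages) if k not in (i, j)] + [parent]

    root = root_lineages[0]

    def to_newick(nd) -> str:
        if not nd["children"]:
            return nd["name"]
        inner = ",".join(
            f"{to_newick(c)}:{nd['time'] - c['time']:.8f}" for c in nd["children"]
        )
        return f"({inner})"

    return to_newick(root) + ";", choices, root


def _evolve_jc69(root_node: dict, n_sites: int, mu: float, rng: np.random.Generator) -> dict[str, str]:
    """JC69 sequences on a gene tree given as nested dicts with 'time'."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {}

    def recurse(nd, parent_seq: np.ndarray, blen_cu: float):
        b = blen_cu * mu
        seq = parent_seq
        if b > 0:
            p_resample = 1.0 - np.exp(-4.0 * b / 3.0)
            hit = rng.random(n_sites) < p_resample
            seq = parent_seq.copy()
            seq[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
        if not nd["children"]:
            seqs[nd["name"]] = seq
        for c in nd["children"]:
            recurse(c, seq, nd["time"] - c["time"])

    root_seq = bases[rng.integers(0, 4, size=n_sites)]
    recurse(root_node, root_seq, 0.0)
    return {name: s.tobytes().decode() for name, s in seqs.items()}


def simulate_msc_windows(config: NetworkSimConfig):
    """Simulate per-window alignments under the network MSC.

    Returns ``(alignments, truth)``: a list of WindowAlignment laid out
    consecutively on chromosome 'sim', and a truth dict with per-window
    gene-tree Newick strings (branch lengths in coalescent units) and the
    hybrid parental choice of every lineage that crossed a hybrid node.
    """
    rng = np.random.default_rng(config.seed)
    net = _SpeciesNetwork(config)
    span = config.window_length or config.sites_per_window
    alignments: list[WindowAlignment] = []
    gene_trees: list[str] = []
    all_choices: list[dict[str, list[bool]]] = []
    for w in range(config.n_windows):
        newick, choices, root = _sim_gene_tree(net, config.samples_per_species, rng)
        seqs = _evolve_jc69(root, config.sites_per_window, config.mu, rng)
        window = GenomicWindow("sim", w * span, (w + 1) * span, partial=config.sites_per_window < span)
        records = []
        for sp in net.leaves:
            for k in range(_n_samples(config.samples_per_species, sp)):
                name = f"{sp}_{k}"
                records.append((name, sp, seqs[name]))
        alignments.append(WindowAlignment(window, records))
        gene_trees.append(newick)
        all_choices.append(choices)
    truth = {
        "gene_trees": gene_trees,
        "hybrid_choices": all_choices,
        "species": list(net.leaves),
        "seed": config.seed,
    }
    return alignments, truth


# ---------------------------------------------------------------------------
# fixture suite


def emit_fixture_suite(out_dir: str | Path, scale: str = "tiny", seed: int = 1) -> dict:
    """Write a deterministic VCF/FASTA/Newick/popmap/graph fixture set.

    'tiny' regenerates in seconds (test-suite scale); 'standard' is the
    tutorial scale.  Returns the manifest (also written as JSON).
    """
    if scale not in ("tiny", "standard"):
        raise ValueError("scale must be 'tiny' or 'standard'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_loci = 5_000 if scale == "tiny" else 50_000
    n_windows = 24 if scale == "tiny" else 120
    sites = 500 if scale == "tiny" else 5_000

    graph = AdmixtureGraph.from_text(FIG3C_ANALOG_GRAPH)
    (out / "graph_fig3c_analog.txt").write_text(FIG3C_ANALOG_GRAPH)
    geno, pops, _ = simulate_graph_drift(
        DriftSimConfig(graph, n_loci=n_loci, samples_per_leaf=3, seed=seed)
    )
    write_vcf(geno, out / "drift.vcf")
    write_popmap(pops, out / "popmap.txt")

    # hybrid-lineage network: SI-analog sister to CI in the tree, drawing
    # 68% of its ancestry from an unsampled basal ghost branch (GH)
    net_tree = "(((((CI:1.0,SI:1.0):1.0,WB:2.0):1.0,SA:3.0):2.0,GH:5.0):1.0,OUT:6.0);"
    config = NetworkSimConfig(
        species_tree=net_tree,
        hybrids=[HybridEvent("SI", "GH", 0.68)],
        samples_per_species={"CI": 2, "SI": 2, "WB": 2, "SA": 2, "OUT": 2, "GH": 0},
        n_windows=n_windows,
        sites_per_window=sites,
        mu=0.01,
        seed=seed + 1,
    )
    alignments, truth = simulate_msc_windows(config)
    win_dir = out / "windows"
    win_dir.mkdir(exist_ok=True)
    for i, aln in enumerate(alignments):
        write_fasta(aln, win_dir / f"window_{i:04d}.fasta")
    with open(out / "gene_trees.nwk", "w") as fh:
        for nwk in truth["gene_trees"]:
            fh.write(nwk + "\n")

    manifest = {
        "scale": scale,
        "seed": seed,
        "drift": {"loci": n_loci, "samples_per_leaf": 3, "populations": pops.populations},
        "msc": {"windows": n_windows, "sites_per_window": sites, "samples_per_species": 2},
        "files": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("emit_fixture_suite: wrote %d files to %s", len(manifest["files"]), out)
    return manifest
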