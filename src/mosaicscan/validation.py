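"""Synthetic re-enactments of the headline hybrid-lineage inferences.

Each scenario generates data under a known truth with the package's own
simulators and pushes it through the corresponding estimator, so the
whole chain (simulation -> statistics -> inference) is exercised at
desk scale:

* :func:`hybrid_graph_weight_recovery` — genotypes drift along the
  six-lineage admixture graph with a ghost basal source and a hybrid
  Southern-Italy-analog lineage (32% recent-source / 68% ghost); the
  fixed-topology fitter re-estimates the recent-source admixture weight.
* :func:`gene_flow_z` — a four-population scenario with unidirectional
  gene flow P3 -> P2; Patterson's D with a 50-block jackknife is tested
  against the Z > 3.3 significance convention.
* :func:`ancestry_dxy_contrast` — a mosaic genome whose window classes
  differ in divergence time; the one-sided permutation contrast on
  windowed Dxy re-detects the ancestry-linked divergence difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mosaicscan.fstats import block_jackknife, dxy_alignment
from mosaicscan.graphfit import AdmixtureGraph, f2_basis, fit_graph
from mosaicscan.popio import allele_frequencies
from mosaicscan.resample import PermutationResult, permutation_contrast
from mosaicscan.simgen import (
    FIG3C_ANALOG_GRAPH,
    QUARTET_GENE_FLOW_GRAPH,
    DriftSimConfig,
    NetworkSimConfig,
    simulate_graph_drift,
    simulate_msc_windows,
)

__all__ = ["hybrid_graph_weight_recovery", "gene_flow_z", "ancestry_dxy_contrast"]


def hybrid_graph_weight_recovery(
    seeds: list[int],
    n_loci: int = 50_000,
    samples_per_leaf: int = 3,
    n_blocks: int = 50,
) -> dict:
    """Recover the recent-source admixture weight of the hybrid lineage.

    Simulates ``n_loci`` unlinked diploid loci per seed under the
    six-lineage graph (truth: 32% of the SI-analog's ancestry from the
    CI-analog source), then fits the same topology with the SI-node
    admixture weight free (drift lengths follow the proposal's pattern up
    to one freely fitted scale factor, which converts the simulator's
    variance units to f2 units).

    Returns the per-seed fitted weights, their mean/SD (as percentages),
    and the generating truth.
    """
    truth_graph = AdmixtureGraph.from_text(FIG3C_ANALOG_GRAPH)
    proposal = truth_graph.freed(admixtures=["H"])
    fitted = []
    for seed in seeds:
        geno, pops, _ = simulate_graph_drift(
            DriftSimConfig(truth_graph, n_loci=n_loci, samples_per_leaf=samples_per_leaf, seed=seed)
        )
        freqs = allele_frequencies(geno, pops)
        basis = f2_basis(freqs, truth_graph.sampled_leaves(), n_blocks=n_blocks)
        res = fit_graph(proposal, basis, seed=seed, length_scale=True)
        fitted.append(res.alphas["H"])
    arr = np.asarray(fitted)
    return {
        "alphas": fitted,
        "mean_percent": float(arr.mean() * 100.0),
        "sd_percent": float(arr.std(ddof=1) * 100.0) if len(arr) > 1 else float("nan"),
        "truth_percent": truth_graph.admixtures["H"][2] * 100.0,
        "n_loci": n_loci,
        "seeds": list(seeds),
    }


def gene_flow_z(
    seeds: list[int],
    n_loci: int = 100_000,
    samples_per_leaf: int = 3,
    n_blocks: int = 50,
    z_threshold: float = 3.3,
) -> dict:
    """Patterson's D with block-jackknife Z under P3 -> P2 gene flow.

    The generating graph is (((P1,P2),P3),O) with drift 0.02 per edge and
    an admixture edge giving P2 20% of its ancestry from the P3 lineage.
    D(P1,P2,P3,O) uses the allele-coding-invariant formula (the simulated
    outgroup is itself polymorphic).  Returns per-seed Z-scores and the
    fraction exceeding the significance threshold.
    """
    graph = AdmixtureGraph.from_text(QUARTET_GENE_FLOW_GRAPH)
    zs, ds = [], []
    for seed in seeds:
        geno, pops, _ = simulate_graph_drift(
            DriftSimConfig(graph, n_loci=n_loci, samples_per_leaf=samples_per_leaf, seed=seed)
        )
        freqs = allele_frequencies(geno, pops)
        r = block_jackknife(
            freqs, "D_general", ("P1", "P2", "P3", "O"), n_blocks=n_blocks,
            z_threshold=z_threshold,
        )
        zs.append(r.z)
        ds.append(r.estimate)
    zs_arr = np.asarray(zs)
    return {
        "z_scores": zs,
        "d_estimates": ds,
        "mean_z": float(zs_arr.mean()),
        "min_z": float(zs_arr.min()),
        "n_significant": int((zs_arr >= z_threshold).sum()),
        "n_replicates": len(seeds),
        "n_loci": n_loci,
        "seeds": list(seeds),
    }


def ancestry_dxy_contrast(
    seed: int,
    n_recent: int = 150,
    n_background: int = 350,
    tau_recent: float = 1.0,
    tau_background: float = 3.0,
    sites_per_window: int = 5_000,
    mu: float = 0.01,
    n_perm: int = 1_000,
) -> PermutationResult:
    """Permutation contrast of windowed Dxy on a synthetic mosaic genome.

    ``n_recent`` windows have the focal pair diverging ``tau_recent``
    coalescent units ago (recent-source ancestry) and ``n_background``
    windows ``tau_background`` units ago; windows are labelled by their
    generating class and the one-sided contrast (direction 'less') is
    evaluated with ``n_perm`` label permutations.
    """
    rows = []
    for tau, n, label, offset in (
        (tau_recent, n_recent, "in_set", 1),
        (tau_background, n_background, "background", 2),
    ):
        cfg = NetworkSimConfig(
            species_tree=f"(A:{tau},B:{tau});",
            samples_per_species=2,
            n_windows=n,
            sites_per_window=sites_per_window,
            mu=mu,
            seed=seed * 10 + offset,
        )
        alignments, _ = simulate_msc_windows(cfg)
        for aln in alignments:
            rows.append({"ancestry": label, "dxy": dxy_alignment(aln, "A", "B")})
    table = pd.DataFrame(rows)
    return permutation_contrast(
        table, "ancestry", "dxy", direction="less", n_perm=n_perm, seed=seed
    )
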