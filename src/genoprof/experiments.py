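"""Canned study designs: the end-to-end experiments the package exists to
run, with their study conditions fixed in one place.

* ``clustering_recovery``   — the planted-topology study: a 3-branch,
  3-leaves-per-branch tree whose between-branch separations put expected
  pairwise mutation counts well above 50; Ward clustering of the measured
  dG matrix is scored against the planted branch partition.
* ``monotone_signal``       — the dose-response study: independent
  two-leaf lineages spanning expected mutation counts 10-100; mean dG over
  replicate gel measurements is correlated (Spearman) with the true
  generational separation.
* ``normalization_residual``— reference calibration stress test under
  random affine gel distortions.
* ``rate_recovery``         — Poisson parameter recovery of mu_c from
  (generations, count) regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .config import RunConfig
from .insilico_gp import PreSpiddo
from .lineage_sim import (
    TreeSpec,
    build_lineage,
    random_genome,
    simulate_leaf_genomes,
)
from .mutation_model import estimate_rate_from_simulation
from .pass_distance import genomic_distance
from .pipeline import derive_seed, measure_genome, run_pipeline
from .spiddos import nominal_reference_points, normalize

__all__ = [
    "clustering_recovery",
    "monotone_signal",
    "normalization_residual",
    "rate_recovery",
]


@dataclass(frozen=True)
class ClusteringRecoveryResult:
    aris: tuple[float, ...]
    n_success: int  # runs with ARI >= 0.9

    @property
    def n_runs(self) -> int:
        return len(self.aris)


def clustering_recovery(seed: int, n_runs: int = 10) -> ClusteringRecoveryResult:
    """Repeat the full pipeline on freshly simulated trees and score how
    often Ward clustering recovers the planted branch partition.

    Uses the package defaults: 3 branches x 3 leaves, between-branch
    expected mutation counts ~235-460, per-gel affine distortion and
    0.005 jitter, 3-replicate mean spiddos.
    """
    cfg = RunConfig()
    aris = tuple(
        run_pipeline(cfg, seed=derive_seed(seed, 100, r)).recovery.ari
        for r in range(n_runs)
    )
    return ClusteringRecoveryResult(aris, sum(a >= 0.9 for a in aris))


@dataclass(frozen=True)
class MonotoneSignalResult:
    spearman_rho: float
    generations: tuple[int, ...]
    mean_dg: tuple[float, ...]
    expected_mutations: tuple[float, ...]


def monotone_signal(
    seed: int,
    n_roots: int = 3,
    n_separations: int = 25,
    n_replicates: int = 20,
) -> MonotoneSignalResult:
    """Dose-response of genomic distance to generational separation.

    For each of ``n_roots`` independent root genomes, simulate
    ``n_separations`` two-leaf lineages with separations log-spaced over
    2 000-20 000 generations (expected pairwise mutation counts 10-100 at
    the default mu_c * L), measure each leaf ``n_replicates`` times under
    fresh gel distortions, and pool all pairs into one Spearman
    correlation of mean dG against true separation.
    """
    base = RunConfig()
    mu, L, a = base.tree.mu_c, base.tree.genome_length_L, base.tree.unit_cell_length_a
    lo, hi = np.log10(2000), np.log10(20000)
    gens: list[int] = []
    dgs: list[float] = []
    for root_idx in range(n_roots):
        root = random_genome(L, derive_seed(seed, 200, root_idx))
        for k in range(n_separations):
            g = int(round(10 ** (lo + k / (n_separations - 1) * (hi - lo))))
            spec = TreeSpec(
                trunk_height=0.01,
                branch_attach_heights=(0.0,),
                leaves_per_branch=2,
                branch_length=g / 2 * a,
                genome_length_L=L,
                mu_c=mu,
            )
            cfg = RunConfig(tree=spec, pcr=base.pcr, tgge=base.tgge,
                            analysis=base.analysis)
            tree = build_lineage(spec)
            leaves = simulate_leaf_genomes(
                tree, root, mu, derive_seed(seed, 201, root_idx, k)
            )[:2]
            g_true = tree.path_generations(leaves[0].label, leaves[1].label)
            acc = 0.0
            for r in range(n_replicates):
                profs = [
                    measure_genome(
                        lf.sequence, cfg,
                        derive_seed(seed, 202, root_idx, k, i, r), lf.label,
                    )
                    for i, lf in enumerate(leaves)
                ]
                acc += genomic_distance(profs[0], profs[1])
            gens.append(g_true)
            dgs.append(acc / n_replicates)
    rho = float(spearmanr(gens, dgs).statistic)
    return MonotoneSignalResult(
        rho, tuple(gens), tuple(dgs), tuple(mu * L * g for g in gens)
    )


def normalization_residual(seed: int, n_distortions: int = 100) -> float:
    """Worst-case spiddo displacement after normalization over random
    positive-scale affine gel distortions (no jitter); exact calibration
    makes this float rounding error."""
    rng = np.random.default_rng(seed)
    (n1m, n1t), (n2m, n2t) = nominal_reference_points()
    truth = np.column_stack([rng.uniform(0.1, 0.9, 15),
                             rng.uniform(56.0, 64.0, 15)])
    base_raw = [PreSpiddo(n1m, n1t, True, "Ref1"),
                PreSpiddo(n2m, n2t, True, "Ref2")]
    base_raw += [PreSpiddo(m, t, False, f"p{i}")
                 for i, (m, t) in enumerate(truth)]
    expected = normalize(base_raw, "truth").spiddos
    worst = 0.0
    for _ in range(n_distortions):
        sm, st_ = rng.uniform(0.5, 2.0, 2)
        om = rng.uniform(-0.3, 0.3)
        ot = rng.uniform(-5.0, 5.0)
        raw = [
            PreSpiddo(sm * p.mobility_raw + om, st_ * p.temp_raw + ot,
                      p.is_reference, p.source)
            for p in base_raw
        ]
        got = normalize(raw, "distorted").spiddos
        worst = max(worst, float(np.abs(got - expected).max()))
    return worst


@dataclass(frozen=True)
class RateRecoveryResult:
    n_within_factor: int
    n_trials: int
    estimates: tuple[float, ...]

    @property
    def success_rate(self) -> float:
        return self.n_within_factor / self.n_trials


def rate_recovery(
    seed: int,
    n_trials: int = 200,
    mu_c: float = 1e-8,
    L: int = 10**6,
    factor: float = 1.5,
) -> RateRecoveryResult:
    """Recover mu_c from Poisson (generations, count) data: 50 pairs with
    g log-spaced over 1e3-1e5 per trial; success = estimate within
    ``factor`` of truth."""
    rng = np.random.default_rng(seed)
    gs = np.logspace(3, 5, 50)
    estimates = []
    for t in range(n_trials):
        counts = rng.poisson(mu_c * L * gs).astype(float)
        est = estimate_rate_from_simulation(
            list(zip(gs, counts)), L, n_boot=20,
            seed=derive_seed(seed, 300, t),
        )
        estimates.append(est.mu_c)
    ok = sum(mu_c / factor <= e <= mu_c * factor for e in estimates)
    return RateRecoveryResult(ok, n_trials, tuple(estimates))
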