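"""End-to-end orchestration: simulate -> measure -> normalize -> distance
-> cluster, all driven by one :class:`~genoprof.config.RunConfig` and one
master seed.

Stage seeds are spawned deterministically from the master seed, so a fixed
(config, seed) pair reproduces every intermediate byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Dendrogram, TopologyRecovery, topology_recovery, ward_cluster
from .config import RunConfig
from .insilico_gp import (
    PreSpiddo,
    enumerate_amplicons,
    find_binding_sites,
    profile_fragments,
    select_fragments,
)
from .lineage_sim import (
    LeafGenome,
    LineageTree,
    build_lineage,
    pairwise_generations,
    random_genome,
    simulate_leaf_genomes,
)
from .pass_distance import DistanceMatrix, average_profiles, distance_matrix
from .spiddos import GenomeProfile, normalize

__all__ = ["PipelineResult", "measure_genome", "measure_raw", "run_pipeline",
           "derive_seed"]


def derive_seed(master: int, *key: int) -> int:
    """Deterministic per-stage 31-bit seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def measure_raw(genome: str, cfg: RunConfig, seed: int) -> list[PreSpiddo]:
    """One simulated GP measurement of a genome: random PCR, band
    selection, and gel rendering with this run's distortion draw."""
    primer = cfg.pcr.primer_obj()
    sites = find_binding_sites(genome, primer, cfg.pcr.max_mismatch,
                               cfg.pcr.anchor3)
    frags = enumerate_amplicons(sites, genome, cfg.pcr.min_len, cfg.pcr.max_len)
    # n_bands None means every amplified product is scored as a band
    bands = frags if cfg.pcr.n_bands is None else select_fragments(frags, cfg.pcr.n_bands)
    return profile_fragments(
        bands,
        distortion=cfg.tgge.distortion(),
        seed=seed,
        tm_window=cfg.tgge.tm_window,
        tm_denaturant_offset=cfg.tgge.tm_denaturant_offset,
        mobility_model=cfg.tgge.mobility_model(),
    )


def measure_genome(
    genome: str, cfg: RunConfig, seed: int, sample_label: str = ""
) -> GenomeProfile:
    """Measure and normalize in one step."""
    raw = measure_raw(genome, cfg, seed)
    return normalize(raw, sample_label, mobility_model=cfg.tgge.mobility_model())


@dataclass
class PipelineResult:
    tree: LineageTree
    genomes: list[LeafGenome]
    generations: "object"  # labeled DataFrame of true pairwise generations
    profiles: list[GenomeProfile]
    dg: DistanceMatrix
    dendrogram: Dendrogram
    recovery: TopologyRecovery


def run_pipeline(cfg: RunConfig, seed: int | None = None) -> PipelineResult:
    """Run the full synthetic study.

    Each leaf is measured ``analysis.n_replicates`` times under fresh gel
    distortions; in ``mean`` replicate mode the replicate spiddos are
    averaged per sample before distances are computed.
    """
    master = cfg.seed if seed is None else seed
    tree = build_lineage(cfg.tree)
    root = random_genome(cfg.tree.genome_length_L, derive_seed(master, 0))
    genomes = simulate_leaf_genomes(tree, root, cfg.tree.mu_c,
                                    derive_seed(master, 1))
    gens = pairwise_generations(tree)

    n_rep = cfg.analysis.n_replicates if cfg.analysis.replicate_mode == "mean" else 1
    profiles: list[GenomeProfile] = []
    for gi, g in enumerate(genomes):
        reps = [
            measure_genome(g.sequence, cfg, derive_seed(master, 2, gi, r),
                           g.label)
            for r in range(n_rep)
        ]
        profiles.append(reps[0] if n_rep == 1 else average_profiles(reps))

    dg = distance_matrix(profiles)
    dend = ward_cluster(dg, cfg.analysis.ward_variant)
    recovery = topology_recovery(dend, tree.leaf_branch)
    return PipelineResult(tree, genomes, gens, profiles, dg, dend, recovery)
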