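"""In-silico genome profiling measurement.

Emulates the two experimental stages as a feature-point model:

1. *Random PCR* — a single short primer binds both genome strands under low
   stringency (Hamming mismatches tolerated, perfect 3' anchor required);
   every convergent pair of binding sites within a length window defines a
   candidate amplicon, and amplification bias is modelled by keeping the
   best-primed fragments.
2. *micro-TGGE* — each fragment becomes one raw feature point
   (pre-spiddo): a size-dependent gel mobility and the melting temperature
   of its lowest-melting domain.  Two internal reference fragments of known
   length and Tm (200 bp / 60.0 C and 900 bp / 61.4 C) are co-migrated, and
   a per-profile affine distortion plus Gaussian jitter models gel-to-gel
   irreproducibility.  Downstream normalization uses the references to
   cancel the affine part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Primer",
    "BindingSite",
    "Fragment",
    "ReferenceFragment",
    "PreSpiddo",
    "DistortionSpec",
    "MobilityModel",
    "REF1",
    "REF2",
    "find_binding_sites",
    "enumerate_amplicons",
    "select_fragments",
    "melting_temperature",
    "mobility",
    "profile_fragments",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


@dataclass(frozen=True)
class Primer:
    """Single random-PCR primer (typically a 12-mer, e.g. HUNT
    5'-TGCTGCTGCTGC-3')."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("primer sequence must be ACGT only")


HUNT = Primer("HUNT", "TGCTGCTGCTGC")
PFM12 = Primer("Pfm12", "AGAACGCGCCTG")


@dataclass(frozen=True)
class BindingSite:
    """Primer footprint on the genome, forward-strand coordinates.

    ``position`` is the 0-based start of the footprint; ``strand`` '+'
    means the primer extends rightward, '-' leftward; ``footprint`` is the
    primer length in bases.
    """

    position: int
    strand: str
    mismatches: int
    footprint: int = 12


@dataclass(frozen=True)
class Fragment:
    """Amplicon between a convergent pair of binding sites.

    ``score`` is the total mismatch count of its two priming sites; lower
    scores amplify better.
    """

    sequence: str
    start: int
    end: int
    score: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReferenceFragment:
    name: str
    length: int
    tm: float


REF1 = ReferenceFragment("Ref1", 200, 60.0)
REF2 = ReferenceFragment("Ref2", 900, 61.4)


@dataclass(frozen=True)
class PreSpiddo:
    """Raw gel coordinate of one band's melting transition."""

    mobility_raw: float
    temp_raw: float
    is_reference: bool
    source: str


@dataclass(frozen=True)
class DistortionSpec:
    """Per-gel measurement distortion: one affine transform per axis drawn
    from the given ranges (shared by every point on the gel, references
    included) plus i.i.d. Gaussian jitter per point."""

    mob_scale_range: tuple[float, float] = (0.9, 1.1)
    mob_offset_range: tuple[float, float] = (-0.05, 0.05)
    temp_scale_range: tuple[float, float] = (0.95, 1.05)
    temp_offset_range: tuple[float, float] = (-2.0, 2.0)
    sigma_mobility: float = 0.005
    sigma_temp: float = 0.005

    @classmethod
    def none(cls) -> "DistortionSpec":
        return cls((1.0, 1.0), (0.0, 0.0), (1.0, 1.0), (0.0, 0.0), 0.0, 0.0)


@dataclass(frozen=True)
class MobilityModel:
    """Log-size gel mobility: 1 at ``l_min``, 0 at ``l_max``."""

    l_min: int = 100
    l_max: int = 3000


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _window_mismatches(genome: np.ndarray, primer: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer against every genome window,
    shape (len(genome) - len(primer) + 1, len(primer)) boolean reduced."""
    w = np.lib.stride_tricks.sliding_window_view(genome, len(primer))
    return w != primer  # boolean (n_windows, m)


def find_binding_sites(
    genome: str, primer: Primer, max_mismatch: int = 4, anchor3: int = 3
) -> list[BindingSite]:
    """All footprints where the primer binds either strand with at most
    ``max_mismatch`` Hamming mismatches and a perfect ``anchor3``-base 3'
    end (polymerase extension requires a matched 3' terminus).

    Returned sorted by (position, strand).  A primer longer than the genome
    yields an empty list.
    """
    m = len(primer.sequence)
    if anchor3 > m:
        raise ValueError("anchor3 cannot exceed primer length")
    if len(genome) < m:
        return []
    g = _encode(genome.upper())
    sites: list[BindingSite] = []
    # + strand: primer 3' end is the rightmost anchor3 bases of the footprint
    mm = _window_mismatches(g, _encode(primer.sequence))
    total = mm.sum(axis=1)
    if anchor3 > 0:
        ok_anchor = ~mm[:, m - anchor3:].any(axis=1)
    else:
        ok_anchor = np.ones(len(total), dtype=bool)
    for pos in np.nonzero((total <= max_mismatch) & ok_anchor)[0]:
        sites.append(BindingSite(int(pos), "+", int(total[pos]), m))
    # - strand: footprint is the reverse complement of the primer; its 3'
    # end maps to the leftmost anchor3 bases in forward coordinates
    mm = _window_mismatches(g, _encode(_revcomp(primer.sequence)))
    total = mm.sum(axis=1)
    if anchor3 > 0:
        ok_anchor = ~mm[:, :anchor3].any(axis=1)
    else:
        ok_anchor = np.ones(len(total), dtype=bool)
    for pos in np.nonzero((total <= max_mismatch) & ok_anchor)[0]:
        sites.append(BindingSite(int(pos), "-", int(total[pos]), m))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def enumerate_amplicons(
    sites: list[BindingSite],
    genome: str,
    min_len: int = 200,
    max_len: int = 2000,
) -> list[Fragment]:
    """One fragment per convergent (+, -) site pair whose span lies in the
    length window.  The span runs from the + footprint start to the end of
    the - footprint; nested amplicons are all kept (band selection happens
    later)."""
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    if not plus or not minus:
        return []
    fw = len(genome)
    frags: list[Fragment] = []
    minus_pos = np.array([s.position for s in minus])
    for p in plus:
        for q_idx in np.nonzero(minus_pos >= p.position)[0]:
            q = minus[q_idx]
            end = q.position + q.footprint
            length = end - p.position
            if min_len <= length <= max_len and end <= fw:
                frags.append(
                    Fragment(genome[p.position:end], p.position, end,
                             p.mismatches + q.mismatches)
                )
    frags.sort(key=lambda f: (f.start, f.end))
    return frags


def select_fragments(fragments: list[Fragment], n_bands: int = 10) -> list[Fragment]:
    """Deterministic amplification-bias model: keep the ``n_bands``
    best-primed fragments, sorting by (mismatch score, length, start)."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    ordered = sorted(fragments, key=lambda f: (f.score, f.length, f.start))
    if len(ordered) < n_bands:
        logger.warning(
            "only %d fragments available for %d requested bands",
            len(ordered), n_bands,
        )
        return ordered
    return ordered[:n_bands]


def melting_temperature(
    seq: str, window: int = 500, denaturant_offset: float = 20.0
) -> float:
    """Tm of the lowest-melting domain: the minimum over all ``window``-bp
    subsequences of the GC-count formula ``64.9 + 41 * (nGC - 16.4) / w``,
    shifted down by ``denaturant_offset``.

    The melting transition observed on the gel initiates where the weakest
    domain opens, hence the windowed minimum rather than a global Tm.  The
    constant offset models the Tm depression by the 8 M urea these gels
    contain (roughly 2 C per molar), which places sample transitions in
    the same temperature range as the internal references; it cancels in
    any Tm difference.
    """
    if not seq:
        raise ValueError("empty sequence")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    if window < 1:
        raise ValueError("window must be >= 1")
    g = _encode(seq.upper())
    is_gc = ((g == ord("G")) | (g == ord("C"))).astype(np.float64)
    csum = np.concatenate(([0.0], np.cumsum(is_gc)))
    gc_counts = csum[window:] - csum[:-window]
    return float(
        np.min(64.9 + 41.0 * (gc_counts - 16.4) / window) - denaturant_offset
    )


def mobility(length: int, model: MobilityModel = MobilityModel()) -> float:
    """Dimensionless migration distance, strictly decreasing in fragment
    size: ``1 - log10(length / l_min) / log10(l_max / l_min)``, clipped to
    [0, 1]."""
    if length <= 0:
        raise ValueError("fragment length must be > 0")
    v = 1.0 - np.log10(length / model.l_min) / np.log10(model.l_max / model.l_min)
    return float(np.clip(v, 0.0, 1.0))


def profile_fragments(
    fragments: list[Fragment],
    refs: tuple[ReferenceFragment, ReferenceFragment] = (REF1, REF2),
    distortion: DistortionSpec = DistortionSpec(),
    seed: int = 0,
    *,
    tm_window: int = 500,
    tm_denaturant_offset: float = 20.0,
    mobility_model: MobilityModel = MobilityModel(),
) -> list[PreSpiddo]:
    """Render fragments plus the two internal references as raw gel
    feature points under a shared per-profile affine distortion and
    per-point Gaussian jitter."""
    if len(refs) != 2:
        raise ValueError("exactly two internal references are required")
    rng = np.random.default_rng(seed)
    s_mob = rng.uniform(*distortion.mob_scale_range)
    o_mob = rng.uniform(*distortion.mob_offset_range)
    s_tmp = rng.uniform(*distortion.temp_scale_range)
    o_tmp = rng.uniform(*distortion.temp_offset_range)

    points: list[PreSpiddo] = []

    def distort(mob: float, tmp: float) -> tuple[float, float]:
        mob = s_mob * mob + o_mob + rng.normal(0.0, distortion.sigma_mobility)
        tmp = s_tmp * tmp + o_tmp + rng.normal(0.0, distortion.sigma_temp)
        return mob, tmp

    for ref in refs:
        mob, tmp = distort(mobility(ref.length, mobility_model), ref.tm)
        points.append(PreSpiddo(mob, tmp, True, ref.name))
    for i, frag in enumerate(fragments):
        mob, tmp = distort(
            mobility(frag.length, mobility_model),
            melting_temperature(frag.sequence, tm_window, tm_denaturant_offset),
        )
        points.append(PreSpiddo(mob, tmp, False, f"frag{i}:{frag.start}-{frag.end}"))
    return points
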