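"""Internal-reference-mediated normalization of raw gel feature points.

Each gel run distorts both axes (mobility, temperature) by an unknown,
roughly affine transform.  Because the two internal reference fragments of
known size and Tm ride on the same gel, the per-axis linear map that sends
their *observed* coordinates back to their *nominal* coordinates undoes any
per-axis affine distortion exactly.  Applying that map to every sample
point and dropping the references yields the spiddos — the gel-invariant
genome fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .insilico_gp import REF1, REF2, MobilityModel, PreSpiddo, mobility

__all__ = ["GenomeProfile", "NormalizationError", "nominal_reference_points",
           "normalize"]


class NormalizationError(ValueError):
    """Raised when reference points cannot calibrate the profile."""


@dataclass
class GenomeProfile:
    """Normalized profile of one sample: an (n, 2) array of spiddos
    (mobility_norm, temp_norm) plus provenance metadata."""

    sample_label: str
    spiddos: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spiddos = np.asarray(self.spiddos, dtype=np.float64)
        if self.spiddos.ndim != 2 or self.spiddos.shape[1] != 2:
            raise ValueError("spiddos must be an (n, 2) array")
        if self.spiddos.shape[0] < 1:
            raise ValueError("a profile needs at least one spiddo")
        if not np.all(np.isfinite(self.spiddos)):
            raise ValueError("spiddo coordinates must be finite")

    @property
    def n(self) -> int:
        return self.spiddos.shape[0]


def nominal_reference_points(
    mobility_model: MobilityModel = MobilityModel(),
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Nominal (mobility, Tm) coordinates of Ref1 (200 bp, 60.0 C) and
    Ref2 (900 bp, 61.4 C) in the model's own frame, so simulated and
    normalized coordinates coincide."""
    return (
        (mobility(REF1.length, mobility_model), REF1.tm),
        (mobility(REF2.length, mobility_model), REF2.tm),
    )


def _axis_map(obs1: float, obs2: float, nom1: float, nom2: float, axis: str):
    if obs1 == obs2:
        raise NormalizationError(
            f"reference points coincide on the {axis} axis; calibration is "
            "degenerate"
        )
    a = (nom2 - nom1) / (obs2 - obs1)
    if a <= 0:
        raise NormalizationError(
            f"negative calibration scale on the {axis} axis (flipped gel?)"
        )
    b = nom1 - a * obs1
    return a, b


def normalize(
    raw: Sequence[PreSpiddo],
    sample_label: str = "",
    *,
    mobility_model: MobilityModel = MobilityModel(),
    metadata: dict | None = None,
) -> GenomeProfile:
    """Calibrate raw feature points against the two internal references.

    Per axis, the unique linear map sending the observed Ref1/Ref2
    coordinates to their nominal values is applied to every sample point;
    the reference points themselves are then dropped.  Exactly two
    reference points (sources ``Ref1`` and ``Ref2``) are required, and any
    per-axis affine distortion with positive scale that was applied jointly
    to samples and references cancels exactly.
    """
    refs = [p for p in raw if p.is_reference]
    samples = [p for p in raw if not p.is_reference]
    if len(refs) != 2:
        raise NormalizationError(
            f"expected exactly 2 reference points, got {len(refs)}"
        )
    by_name = {p.source: p for p in refs}
    if set(by_name) != {REF1.name, REF2.name}:
        raise NormalizationError(
            f"reference points must be named {REF1.name}/{REF2.name}, "
            f"got {sorted(by_name)}"
        )
    if not samples:
        raise NormalizationError("profile has no sample points")
    (nom1_m, nom1_t), (nom2_m, nom2_t) = nominal_reference_points(mobility_model)
    r1, r2 = by_name[REF1.name], by_name[REF2.name]
    a_m, b_m = _axis_map(r1.mobility_raw, r2.mobility_raw, nom1_m, nom2_m,
                         "mobility")
    a_t, b_t = _axis_map(r1.temp_raw, r2.temp_raw, nom1_t, nom2_t,
                         "temperature")
    pts = np.array(
        [(a_m * p.mobility_raw + b_m, a_t * p.temp_raw + b_t) for p in samples]
    )
    # exact duplicates can only arise in noiseless simulation; merge them
    pts = np.unique(pts, axis=0)
    meta = dict(metadata or {})
    meta.setdefault("n_raw_points", len(samples))
    return GenomeProfile(sample_label, pts, meta)
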