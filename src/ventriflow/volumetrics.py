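"""Ventricular volume curve and global function parameters.

Volumes come from voxel counting on the per-phase segmentation; the
derived global parameters follow the standard conventions: ED and ES are
the phases attaining the maximal and minimal cavity volume, stroke
volume SV = EDV - ESV, ejection fraction EF = 100 * SV / EDV, and
cardiac output CO = SV * HR. The sphericity index is the short-to-long
axis ratio (ventricular width / ventricular height) measured from the
axis-aligned bounding box of the mask at the ED and ES phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SegmentationMask


@dataclass
class VolumetricSummary:
    """EDV/ESV/SV in mL, EF in %, CO in L/min, dimensionless sphericity."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    co_l_min: float
    hr_bpm: float
    ed_phase: int
    es_phase: int
    sphericity_ed: float | None = None
    sphericity_es: float | None = None

    def as_rows(self) -> dict[str, float | None]:
        return {
            "EDV (mL)": self.edv_ml,
            "ESV (mL)": self.esv_ml,
            "SV (mL)": self.sv_ml,
            "EF (%)": self.ef_pct,
            "CO (L/min)": self.co_l_min,
            "HR (bpm)": self.hr_bpm,
            "Sphericity index diastole": self.sphericity_ed,
            "Sphericity index systole": self.sphericity_es,
        }


def volume_curve(mask: SegmentationMask) -> np.ndarray:
    """Per-phase chamber volume in mL: in-mask voxel count times dV."""
    counts = mask.m.sum(axis=(0, 1, 2))
    return counts * mask.grid.voxel_volume_ml


def summarize_volumes(curve, hr_bpm: float) -> VolumetricSummary:
    """Global function parameters from a volume curve (mL) and HR (bpm)."""
    v = np.asarray(curve, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume curve")
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    edv = float(v.max())
    esv = float(v.min())
    if edv <= 0:
        raise ValueError("all-phase zero volume: ejection fraction undefined")
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * hr_bpm / 1000.0  # mL/beat * beat/min -> L/min
    return VolumetricSummary(
        edv_ml=edv, esv_ml=esv, sv_ml=sv, ef_pct=ef, co_l_min=co, hr_bpm=hr_bpm,
        ed_phase=int(np.argmax(v)), es_phase=int(np.argmin(v)),
    )


def sphericity_index(mask: SegmentationMask, phase: int,
                     width_axis: int = 0, height_axis: int = 2) -> float:
    """Short-to-long axis ratio of the chamber at one phase.

    Extents are axis-aligned bounding-box lengths in mm (voxel span plus
    one voxel, so a single-voxel mask has extent = spacing). `width_axis`
    is the left-right in-plane axis, `height_axis` the base-apex long
    axis; both are configurable because orientation is acquisition-
    dependent.
    """
    m3 = mask.phase(phase)
    if not m3.any():
        raise ValueError(f"mask empty at phase {phase}")
    spacing = mask.grid.spacing_mm

    def extent(axis: int) -> float:
        proj = np.any(m3, axis=tuple(i for i in range(3) if i != axis))
        idx = np.nonzero(proj)[0]
        return (idx[-1] - idx[0] + 1) * spacing[axis]

    return extent(width_axis) / extent(height_axis)


def summarize_mask(mask: SegmentationMask, hr_bpm: float,
                   width_axis: int = 0, height_axis: int = 2) -> VolumetricSummary:
    """Full volumetric summary straight from a mask series."""
    summary = summarize_volumes(volume_curve(mask), hr_bpm)
    summary.sphericity_ed = sphericity_index(mask, summary.ed_phase, width_axis, height_axis)
    summary.sphericity_es = sphericity_index(mask, summary.es_phase, width_axis, height_axis)
    return summary
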