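"""Lumen radii profile: the 1-D radius-vs-length signal of an OCT pullback.

An intravascular OCT pullback yields one cross-sectional frame every
0.2 mm (5 frames/mm).  After lumen segmentation each frame reduces to an
effective lumen radius, so a vessel segment becomes an ordered sequence of
radii.  The interventional cardiologist annotates four frames: the start
and end of the analyzed vessel segment and the start and end of the
stenotic lesion.  All frame indices are 0-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class RadiiProfile:
    """Lumen radius signal along a vessel segment, with segment/lesion markers.

    Parameters
    ----------
    lesion_id : str
        Identifier of the lesion this profile belongs to.
    radii : ndarray of float
        Lumen radius (mm) for each frame, proximal to distal.
    frame_spacing : float
        Axial distance between consecutive frames (mm/frame).
    segment_start, segment_end : int
        Inclusive frame indices delimiting the analyzed vessel segment.
    lesion_start, lesion_end : int
        Inclusive frame indices delimiting the stenosis region; the radii at
        these frames are the proximal/distal reference radii of the lesion.
    """

    lesion_id: str
    radii: np.ndarray
    frame_spacing: float = 0.2
    segment_start: int = 0
    segment_end: int = field(default=-1)
    lesion_start: int = 0
    lesion_end: int = 0

    def __post_init__(self):
        radii = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "radii", radii)
        if self.segment_end == -1:
            object.__setattr__(self, "segment_end", len(radii) - 1)
        if radii.ndim != 1 or len(radii) == 0:
            raise ValueError("radii must be a non-empty 1-D sequence")
        if np.any(radii <= 0):
            raise ValueError("all radii must be positive")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")
        if not (0 <= self.segment_start <= self.lesion_start
                <= self.lesion_end <= self.segment_end < len(radii)):
            raise ValueError(
                "marker ordering violated: need segment_start <= lesion_start"
                " <= lesion_end <= segment_end within bounds, got "
                f"{self.segment_start}, {self.lesion_start}, "
                f"{self.lesion_end}, {self.segment_end} for {len(radii)} frames"
            )

    @property
    def segment_radii(self) -> np.ndarray:
        return self.radii[self.segment_start:self.segment_end + 1]

    @property
    def lesion_radii(self) -> np.ndarray:
        return self.radii[self.lesion_start:self.lesion_end + 1]

    @property
    def r_proximal(self) -> float:
        """Radius at the annotated proximal lesion boundary (mm)."""
        return float(self.radii[self.lesion_start])

    @property
    def r_distal(self) -> float:
        """Radius at the annotated distal lesion boundary (mm)."""
        return float(self.radii[self.lesion_end])

    @property
    def segment_length(self) -> float:
        """(segment_end - segment_start) * frame_spacing, in mm."""
        return (self.segment_end - self.segment_start) * self.frame_spacing

    @property
    def lesion_length(self) -> float:
        """Stenosis length lengthS = (lesion_end - lesion_start) * spacing, mm."""
        return (self.lesion_end - self.lesion_start) * self.frame_spacing

    def reversed(self) -> "RadiiProfile":
        """Profile traversed distal-to-proximal; markers remapped accordingly."""
        n = len(self.radii)
        return RadiiProfile(
            lesion_id=self.lesion_id,
            radii=self.radii[::-1].copy(),
            frame_spacing=self.frame_spacing,
            segment_start=n - 1 - self.segment_end,
            segment_end=n - 1 - self.segment_start,
            lesion_start=n - 1 - self.lesion_end,
            lesion_end=n - 1 - self.lesion_start,
        )
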