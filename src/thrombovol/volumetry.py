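"""Thrombus volume quantification from confocal z-stacks by optical thresholding.

A thrombus grown on the bottom wall of a microfluidic channel is imaged as an
ordered stack of 8-bit fluorescence planes spaced ``delta_z`` apart, the focal
(adhesion) plane first.  For an intensity threshold ``Thr`` the area covered by
thrombus in each plane is the count of pixels at or above ``Thr`` times the
pixel area ``f**2``; summing the per-plane areas and multiplying by the z-step
gives the optically-thresholded volume ``V_OT``.

The threshold itself is selected automatically: sweeping ``Thr`` from 0 to the
stack's maximum intensity yields a volume curve ``V_OT(Thr)`` and a maximum
height curve ``H_max(Thr)``.  Coming down from high thresholds the height curve
saturates at the stack height while the volume curve turns through an elbow;
the selected threshold is the saturation point of the height curve — the
largest threshold still reaching the full plateau height.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImagePlane",
    "ZStack",
    "ThresholdCurves",
    "VolumeEstimate",
    "thresholded_area",
    "volume_ot",
    "stack_height",
    "threshold_curves",
    "select_optimal_threshold",
    "volume_uncertainty",
    "sensitivity_analysis",
]

#: CCD magnification of the reference setup: 1 pixel = 0.33 µm.
DEFAULT_PIXEL_PITCH = 0.33
#: Axial step between consecutive confocal planes, µm.
DEFAULT_DELTA_Z = 0.5


def _coerce_u8(intensities: np.ndarray) -> np.ndarray:
    """Coerce an intensity array to 8-bit, rescaling wider dtypes to [0, 255]."""
    arr = np.asarray(intensities)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D intensity grid, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
        return arr.astype(np.uint8)
    # Non 8-bit input: rescale so the observed maximum maps to 255.
    warnings.warn(
        f"rescaling {arr.dtype} intensities to 8-bit (max -> 255)", stacklevel=3
    )
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


@dataclass(frozen=True)
class ImagePlane:
    """A single 8-bit grayscale plane with physical pixel pitch ``f`` (µm/px)."""

    intensities: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "intensities", _coerce_u8(self.intensities))

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class ZStack:
    """Ordered bottom-to-top stack of planes; index 0 is the focal plane.

    All planes share shape and pixel pitch; ``delta_z`` is the axial step in µm.
    """

    planes: tuple[ImagePlane, ...]
    delta_z: float = DEFAULT_DELTA_Z

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise ValueError("a z-stack needs at least one plane")
        if self.delta_z <= 0:
            raise ValueError("delta_z must be positive")
        shape = self.planes[0].shape
        pitch = self.planes[0].pixel_pitch
        for p in self.planes:
            if p.shape != shape or p.pixel_pitch != pitch:
                raise ValueError("all planes must share shape and pixel pitch")
        object.__setattr__(self, "planes", tuple(self.planes))

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        pixel_pitch: float = DEFAULT_PIXEL_PITCH,
        delta_z: float = DEFAULT_DELTA_Z,
    ) -> "ZStack":
        """Build a stack from an (N, rows, cols) array, bottom plane first."""
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError("expected an (N, rows, cols) array")
        return cls(
            planes=tuple(ImagePlane(p, pixel_pitch) for p in data), delta_z=delta_z
        )

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    @property
    def pixel_pitch(self) -> float:
        return self.planes[0].pixel_pitch

    @property
    def f_max(self) -> int:
        """Maximum fluorescence intensity over the whole stack."""
        return int(max(int(p.intensities.max()) for p in self.planes))

    def as_array(self) -> np.ndarray:
        return np.stack([p.intensities for p in self.planes])


@dataclass(frozen=True)
class ThresholdCurves:
    """V_OT and H_max as functions of the threshold, for Thr = 0 .. F_max."""

    thresholds: np.ndarray
    volume_curve: np.ndarray  # µm^3 per threshold
    height_curve: np.ndarray  # µm per threshold
    delta_z: float

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class VolumeEstimate:
    """A volume with its relative uncertainty and provenance tag.

    ``method`` is ``"OT"`` for optical thresholding or ``"IM"`` for the
    impedance inversion; ``threshold_used`` is set for OT only.
    """

    value: float
    relative_uncertainty: float
    method: str
    threshold_used: int | None = None

    def __post_init__(self) -> None:
        if self.value < 0 or self.relative_uncertainty < 0:
            raise ValueError("volume and uncertainty must be non-negative")
        if self.method not in ("OT", "IM"):
            raise ValueError("method must be 'OT' or 'IM'")


def _check_thr(thr: int) -> int:
    thr = int(thr)
    if not 0 <= thr <= 255:
        raise ValueError(f"threshold {thr} outside [0, 255]")
    return thr


def thresholded_area(plane: ImagePlane, thr: int) -> float:
    """Area (µm²) covered by pixels with intensity >= ``thr``."""
    thr = _check_thr(thr)
    count = int(np.count_nonzero(plane.intensities >= thr))
    return count * plane.pixel_pitch**2


def volume_ot(stack: ZStack, thr: int) -> float:
    """Optically-thresholded volume (µm³): z-step times the sum of plane areas."""
    thr = _check_thr(thr)
    return stack.delta_z * sum(thresholded_area(p, thr) for p in stack.planes)


def stack_height(n_planes: int, delta_z: float) -> float:
    """Physical height spanned by an N-plane stack: (N - 1) * delta_z (µm)."""
    if n_planes < 1:
        raise ValueError("a stack has at least one plane")
    return (n_planes - 1) * delta_z


def threshold_curves(stack: ZStack) -> ThresholdCurves:
    """Sweep Thr = 0 .. F_max, computing V_OT(Thr) and H_max(Thr).

    H_max(Thr) is ``i_max * delta_z`` with ``i_max`` the 0-based index of the
    topmost plane containing any surviving pixel, or 0 when nothing survives.
    Implemented with reverse-cumulative histograms so the sweep is a single
    pass over the stack.
    """
    f_max = stack.f_max
    thresholds = np.arange(f_max + 1)
    f2 = stack.pixel_pitch**2

    # survival[i, t] = number of pixels in plane i with intensity >= t
    n = stack.n_planes
    survival = np.empty((n, f_max + 1), dtype=np.int64)
    plane_max = np.empty(n, dtype=np.int64)
    for i, p in enumerate(stack.planes):
        hist = np.bincount(p.intensities.ravel(), minlength=f_max + 1)[: f_max + 1]
        survival[i] = hist[::-1].cumsum()[::-1]
        plane_max[i] = p.intensities.max()

    volume = stack.delta_z * f2 * survival.sum(axis=0)

    height = np.zeros(f_max + 1)
    for t in thresholds:
        alive = np.nonzero(plane_max >= t)[0]
        if alive.size:
            height[t] = alive[-1] * stack.delta_z
    return ThresholdCurves(
        thresholds=thresholds,
        volume_curve=volume.astype(np.float64),
        height_curve=height,
        delta_z=stack.delta_z,
    )


def select_optimal_threshold(curves: ThresholdCurves) -> int:
    """Saturation point of the height curve / elbow of the volume curve.

    Returns the largest threshold at which the height curve still attains its
    plateau (its maximum over thresholds >= 1; threshold 0 is excluded because
    every pixel trivially survives there).  Ties break toward the larger
    threshold.
    """
    if len(curves) < 2:
        raise ValueError("threshold curves must cover at least thresholds 0 and 1")
    h = curves.height_curve[1:]
    plateau = h.max()
    if plateau <= 0:
        raise ValueError(
            "height curve is identically zero above threshold 0: empty stack content"
        )
    return int(np.nonzero(h == plateau)[0][-1] + 1)


def volume_uncertainty(
    curves: ThresholdCurves, thr: int, delta_thr: int = 3
) -> float:
    """Relative uncertainty of V_OT from the threshold-identification error.

    Propagates u(Thr) = delta_thr / sqrt(3) (uniform distribution of half-width
    ``delta_thr`` threshold units) through the slope of the volume curve,
    estimated by a central finite difference on the integer threshold grid
    (one-sided at the curve ends).  Returned as a fraction of V_OT(thr).
    """
    v = curves.volume_curve
    if not 0 <= thr < len(v):
        raise ValueError("threshold outside the computed curve range")
    if thr == 0:
        slope = v[1] - v[0]
    elif thr == len(v) - 1:
        slope = v[-1] - v[-2]
    else:
        slope = (v[thr + 1] - v[thr - 1]) / 2.0
    u_thr = delta_thr / math.sqrt(3.0)
    if v[thr] == 0:
        raise ValueError("V_OT is zero at the requested threshold")
    return abs(slope) * u_thr / v[thr]


def sensitivity_analysis(
    stack: ZStack, thr: int, halfwidth: int = 10
) -> np.ndarray:
    """Percent volume change for threshold offsets -halfwidth .. +halfwidth.

    ``result[i + halfwidth] = 100 * (V(thr + i) - V(thr)) / V(thr)``; the entry
    at offset 0 is exactly 0.
    """
    if thr - halfwidth < 0:
        raise ValueError("thr - halfwidth must be >= 0")
    v0 = volume_ot(stack, thr)
    if v0 == 0:
        raise ValueError("V_OT is zero at the reference threshold")
    out = np.empty(2 * halfwidth + 1)
    for i in range(-halfwidth, halfwidth + 1):
        out[i + halfwidth] = (
            0.0 if i == 0 else 100.0 * (volume_ot(stack, min(thr + i, 255)) - v0) / v0
        )
    return out


def analyze_stack(
    stack: ZStack,
    thr: int | None = None,
    delta_thr: int = 3,
) -> tuple[VolumeEstimate, ThresholdCurves]:
    """Full optical pipeline: curves, automatic threshold, volume, uncertainty."""
    curves = threshold_curves(stack)
    if thr is None:
        thr = select_optimal_threshold(curves)
    else:
        thr = _check_thr(thr)
    value = float(curves.volume_curve[thr]) if thr < len(curves) else 0.0
    if value > 0:
        u = volume_uncertainty(curves, thr, delta_thr)
    else:
        u = 0.0
    est = VolumeEstimate(
        value=value, relative_uncertainty=u, method="OT", threshold_used=thr
    )
    return est, curves
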