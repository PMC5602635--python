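"""Scale-factor inversion: from a measured |Z| and a 2D image to a 3D thrombus.

The thrombus height at every pixel is assumed linearly proportional to the
fluorescence intensity, h(x, y) = k * I(x, y), with a single scale factor k
shared by all pixels.  The forward conduction model makes |Z| strictly
increasing in k (more insulating volume, higher impedance), so k is recovered
by bisection until the simulated impedance matches the measured one.  The
impedance-derived volume is then

    V_IM = f^2 * sum_pixels min(k * I(x, y), h_channel)

and the height field doubles as a watertight 3D surface reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conduction import ForwardModel
from .volumetry import ImagePlane

__all__ = [
    "InversionResult",
    "invert_scale_factor",
    "volume_im",
    "reconstruct_3d",
    "compare_volumes",
    "VolumeComparison",
]

#: Relative impedance-mismatch tolerance for a converged inversion.
RESIDUAL_TOL = 1e-3
#: Maximum bisection iterations.
MAX_ITER = 60
#: Measured |Z| may sit this fraction below baseline before being flagged
#: unphysical (measurement noise allowance).
BASELINE_NOISE_TOL = 0.02


@dataclass(frozen=True)
class InversionResult:
    """Outcome of the impedance inversion for one experiment."""

    scale_factor: float  # µm per intensity unit
    v_im: float  # µm^3
    relative_uncertainty: float
    iterations: int
    residual: float  # relative impedance mismatch at the solution
    saturated: bool = False  # measured |Z| above the occlusive-thrombus ceiling
    warnings: tuple[str, ...] = ()


def volume_im(image: ImagePlane, k: float, channel_height: float = 100.0) -> float:
    """Impedance-method volume (µm³) of the height field k * I, roof-clamped."""
    if k < 0:
        raise ValueError("scale factor must be non-negative")
    h = np.minimum(image.intensities.astype(np.float64) * k, channel_height)
    return float(image.pixel_pitch**2 * h.sum())


def invert_scale_factor(
    image: ImagePlane,
    z_measured: float,
    forward: ForwardModel,
    z_baseline: float | None = None,
    tol: float = RESIDUAL_TOL,
    max_iter: int = MAX_ITER,
    uncertainty: float = 0.10,
) -> InversionResult:
    """Bisection on k in [0, k_max] until |Z_sim(k) - z_measured| <= tol * z.

    ``k_max = h / max(1, I_max)`` is the scale at which the brightest pixel
    reaches the channel roof.  Guaranteed to converge by the strict
    monotonicity of the forward model in k.
    """
    warn: list[str] = []
    i_max = int(image.intensities.max())
    if i_max == 0:
        raise ValueError("image has no nonzero pixel; nothing to invert")
    if int(np.count_nonzero(image.intensities == 255)):
        frac = np.count_nonzero(image.intensities == 255) / image.intensities.size
        warn.append(
            f"saturated pixels: {frac:.2%} of the image at 255; "
            "intensity-height linearity is broken there"
        )
    if z_baseline is None:
        z_baseline = forward.baseline_impedance()
    if z_measured < z_baseline * (1.0 - BASELINE_NOISE_TOL):
        raise ValueError(
            "measured impedance below the thrombus-free baseline beyond noise "
            "tolerance: no physical solution (possible detachment or artifact)"
        )
    if z_measured <= z_baseline:
        return InversionResult(
            scale_factor=0.0, v_im=0.0, relative_uncertainty=uncertainty,
            iterations=0, residual=abs(z_measured - z_baseline) / z_measured,
            warnings=tuple(warn),
        )

    h = forward.geom.height
    k_max = h / max(1, i_max)
    z_hi = forward.impedance(image, k_max)
    if z_measured > z_hi:
        warn.append(
            "measured impedance above the roof-saturated forward value: "
            "occlusive thrombus; reporting k_max"
        )
        return InversionResult(
            scale_factor=k_max,
            v_im=volume_im(image, k_max, h),
            relative_uncertainty=uncertainty,
            iterations=0,
            residual=(z_measured - z_hi) / z_measured,
            saturated=True,
            warnings=tuple(warn),
        )

    lo, hi = 0.0, k_max
    k = 0.5 * (lo + hi)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        k = 0.5 * (lo + hi)
        z_sim = forward.impedance(image, k)
        residual = abs(z_sim - z_measured) / z_measured
        # stop once the scale factor itself is resolved to ~tol; this also
        # bounds the impedance residual wherever |Z|(k) has nonzero slope
        if (hi - lo) <= tol * max(k, 1e-12):
            break
        if z_sim < z_measured:
            lo = k
        else:
            hi = k
    if residual > tol:
        warn.append(
            f"impedance residual {residual:.2e} above tolerance {tol:.0e} "
            "(discretization floor of the forward model)"
        )
    return InversionResult(
        scale_factor=k,
        v_im=volume_im(image, k, h),
        relative_uncertainty=uncertainty,
        iterations=it,
        residual=residual,
        warnings=tuple(warn),
    )


# ---------------------------------------------------------------------------
# 3D reconstruction


def reconstruct_3d(image: ImagePlane, k: float, channel_height: float = 100.0):
    """Watertight step-surface mesh of the height field k * I(x, y).

    Each pixel becomes a rectangular column of its own height (piecewise
    constant surface), so the enclosed mesh volume equals ``volume_im``
    exactly; a flat (all-zero) image yields an empty mesh.  The surface is
    watertight whenever the occupied pixels do not touch purely diagonally.
    Returns a ``trimesh.Trimesh``.
    """
    import trimesh

    if k < 0:
        raise ValueError("scale factor must be non-negative")
    h = np.minimum(image.intensities.astype(np.float64) * k, channel_height)
    f = image.pixel_pitch
    nr, nc = h.shape

    # vertices on the (nr+1) x (nc+1) corner lattice, one layer per distinct
    # surface level would be wasteful; instead emit per-pixel top quads plus
    # vertical quads where neighbours differ, plus the base sheet.
    verts: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []

    def add_quad(p0, p1, p2, p3):
        """Two triangles for quad p0-p1-p2-p3 (counter-clockwise outward)."""
        base = len(verts)
        verts.extend([p0, p1, p2, p3])
        faces.append((base, base + 1, base + 2))
        faces.append((base, base + 2, base + 3))

    hp = np.pad(h, 1)  # neighbour heights, zero outside the image
    for i in range(nr):
        x0, x1 = i * f, (i + 1) * f
        for j in range(nc):
            y0, y1 = j * f, (j + 1) * f
            z = h[i, j]
            if z > 0:
                add_quad((x0, y0, z), (x1, y0, z), (x1, y1, z), (x0, y1, z))
            # vertical walls toward lower neighbours (or the outside)
            zn = hp[i, j + 1]  # neighbour at i-1
            if zn < z:
                add_quad((x0, y0, zn), (x0, y1, zn), (x0, y1, z), (x0, y0, z))
            zn = hp[i + 2, j + 1]  # i+1
            if zn < z:
                add_quad((x1, y1, zn), (x1, y0, zn), (x1, y0, z), (x1, y1, z))
            zn = hp[i + 1, j]  # j-1
            if zn < z:
                add_quad((x1, y0, zn), (x0, y0, zn), (x0, y0, z), (x1, y0, z))
            zn = hp[i + 1, j + 2]  # j+1
            if zn < z:
                add_quad((x0, y1, zn), (x1, y1, zn), (x1, y1, z), (x0, y1, z))
    # base sheet under occupied pixels only, tiled per pixel so edges match
    # the column walls exactly (a single large quad would leave T-junctions);
    # zero-height pixels are simply outside the solid
    for i in range(nr):
        x0, x1 = i * f, (i + 1) * f
        for j in range(nc):
            if h[i, j] > 0:
                y0, y1 = j * f, (j + 1) * f
                add_quad(
                    (x0, y0, 0.0), (x0, y1, 0.0), (x1, y1, 0.0), (x1, y0, 0.0)
                )

    if not faces:  # all-zero image: flat wall, empty solid
        return trimesh.Trimesh()
    mesh = trimesh.Trimesh(
        vertices=np.asarray(verts), faces=np.asarray(faces), process=True
    )
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# V_OT vs V_IM comparison

#: Relative uncertainties of the two volume methods.
U_REL_OT = 0.15
U_REL_IM = 0.10


@dataclass(frozen=True)
class VolumeComparison:
    """Pearson correlation and per-pair metrological compatibility."""

    pearson_r: float
    compatible: tuple[bool, ...]
    n_pairs: int

    @property
    def all_compatible(self) -> bool:
        return all(self.compatible)


def compare_volumes(
    pairs,
    u_ot: float = U_REL_OT,
    u_im: float = U_REL_IM,
    coverage: float = 2.0,
) -> VolumeComparison:
    """Correlate optical and impedance volumes and test their compatibility.

    Two measurements of the same volume are metrologically compatible when
    |V_OT - V_IM| <= coverage * sqrt((u_ot V_OT)^2 + (u_im V_IM)^2).
    """
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (V_OT, V_IM) pairs")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs to compute a correlation")
    v_ot, v_im = arr[:, 0], arr[:, 1]
    if np.std(v_ot) == 0 or np.std(v_im) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float(np.corrcoef(v_ot, v_im)[0, 1])
    tol = coverage * np.sqrt((u_ot * v_ot) ** 2 + (u_im * v_im) ** 2)
    compat = tuple(bool(c) for c in np.abs(v_ot - v_im) <= tol)
    return VolumeComparison(pearson_r=r, compatible=compat, n_pairs=arr.shape[0])
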