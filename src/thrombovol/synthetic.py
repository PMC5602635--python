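"""Seeded synthetic fixtures with exact ground truth.

Every estimator in the package can be exercised without any external data:
this module generates thrombus height fields with analytically known volume,
renders them as noisy confocal z-stacks and intensity-projection images, and
synthesizes ΔZ(%) impedance traces for the four behaviour groups, optionally
with injected detachment drops.  All generators are deterministic in the
seed.

The default rendering conditions emulate the reference acquisition: 512x512
8-bit planes at 0.33 µm/pixel, z-step 0.5 µm, traces at 1 Hz over 300 s.
Background noise (mean 8, sd 5 on the 0-255 scale) floods every plane,
including a few pure-background margin planes above the thrombus tips, so the
automatic threshold lands just above the noise floor — a small optimal
threshold, as on real stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .monitor import (
    BAND_EDGES,
    CROSSING_BOUNDS,
    ImpedanceSeries,
)
from .volumetry import DEFAULT_DELTA_Z, DEFAULT_PIXEL_PITCH, ImagePlane, ZStack

__all__ = [
    "SyntheticTruth",
    "make_thrombus_field",
    "render_zstack",
    "render_projection_image",
    "make_trace",
    "make_archetype_cohort",
    "make_paired_cohort",
    "PairedExperiment",
    "GROUP_FINAL_DZ",
    "GROUP_CROSSING",
]

#: Mean (sd) of the final ΔZ(%) per behaviour group.
GROUP_FINAL_DZ = {1: (7.55, 1.42), 2: (16.55, 1.88), 3: (31.15, 5.43), 4: (65.46, 20.12)}
#: Mean (sd) of the 10%-crossing time per group (s); group 1 never crosses.
GROUP_CROSSING = {2: (213.83, 15.76), 3: (159.32, 12.63), 4: (72.37, 29.81)}

IMAGE_SIZE = 512  # pixels per side of the optical field
CHANNEL_HEIGHT = 100.0  # µm


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth attached to a generated fixture."""

    true_volume: float  # analytic volume of the height field, µm^3
    rendered_volume: float | None = None  # voxelized volume of the z-stack, µm^3
    height_map: np.ndarray | None = None  # µm, pixel grid
    scale_factor: float | None = None  # µm per intensity unit
    group_label: int | None = None
    seed: int | None = None


def _pyramid(size: int, height: float) -> tuple[np.ndarray, float]:
    """Square pyramid height profile on a size x size pixel block + volume."""
    half = size / 2.0
    ax = (np.arange(size) + 0.5) - half
    r = np.maximum(np.abs(ax)[:, None], np.abs(ax)[None, :]) / half
    h = height * np.clip(1.0 - r, 0.0, None)
    base = size * DEFAULT_PIXEL_PITCH
    return h, base * base * height / 3.0


def _frustum(size: int, height: float, top_frac: float = 0.5) -> tuple[np.ndarray, float]:
    half = size / 2.0
    ax = (np.arange(size) + 0.5) - half
    r = np.maximum(np.abs(ax)[:, None], np.abs(ax)[None, :]) / half
    h = height * np.clip((1.0 - r) / (1.0 - top_frac), 0.0, 1.0)
    a1 = size * DEFAULT_PIXEL_PITCH
    a2 = top_frac * a1
    vol = height / 3.0 * (a1 * a1 + a2 * a2 + a1 * a2)
    return h, vol


def _dome(size: int, height: float) -> tuple[np.ndarray, float]:
    """Paraboloid dome inscribed in the size x size block (circular base)."""
    half = size / 2.0
    ax = (np.arange(size) + 0.5) - half
    r2 = (ax[:, None] ** 2 + ax[None, :] ** 2) / half**2
    h = height * np.clip(1.0 - r2, 0.0, None)
    radius = half * DEFAULT_PIXEL_PITCH
    return h, math.pi * radius**2 * height / 2.0


_SHAPES = {"pyramid": _pyramid, "frustum": _frustum, "dome": _dome}


def make_thrombus_field(
    n_thrombi: int,
    base_size: tuple[int, int] = (40, 90),
    height: tuple[float, float] = (8.0, 25.0),
    shapes: tuple[str, ...] = ("pyramid", "frustum", "dome"),
    seed: int = 0,
    image_size: int = IMAGE_SIZE,
    carpet_height: tuple[float, float] = (0.0, 0.0),
    carpet_smooth_px: float = 20.0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Pack non-overlapping solid height fields on the optical pixel grid.

    ``base_size`` is the footprint side in pixels, ``height`` the apex height
    range in µm (must fit inside the channel).  ``carpet_height`` (µm), when
    nonzero, adds a smoothed mural adhesion layer under the aggregates — the
    thin platelet carpet that forms on a collagen-coated wall before discrete
    aggregates tower.  The truth volume is the sum of the per-shape closed
    forms plus the carpet grid integral.  Raises if the packing is infeasible.
    """
    if height[1] > CHANNEL_HEIGHT:
        raise ValueError("thrombus height exceeds the channel height")
    rng = np.random.default_rng(seed)
    hmap = np.zeros((image_size, image_size))
    total = 0.0
    if carpet_height[1] > 0:
        from scipy.ndimage import gaussian_filter

        carpet = gaussian_filter(
            rng.uniform(carpet_height[0], carpet_height[1], (image_size, image_size)),
            carpet_smooth_px,
        )
        hmap += carpet
        total += float(carpet.sum()) * DEFAULT_PIXEL_PITCH**2
    if n_thrombi == 0:
        return hmap, SyntheticTruth(true_volume=total, height_map=hmap, seed=seed)
    # jittered-grid placement: one thrombus per grid cell guarantees
    # disjoint footprints even at high coverage, where rejection sampling jams
    n_side = math.ceil(math.sqrt(n_thrombi))
    cell = image_size // n_side
    if base_size[0] > cell:
        raise RuntimeError(
            f"cannot pack {n_thrombi} thrombi of base >= {base_size[0]} px "
            f"on a {image_size} px field (cell {cell} px)"
        )
    cells = rng.permutation(n_side * n_side)[:n_thrombi]
    for c in cells:
        size = int(rng.integers(base_size[0], min(base_size[1], cell) + 1))
        h_apex = float(rng.uniform(*height))
        shape = shapes[int(rng.integers(len(shapes)))]
        r0 = (int(c) // n_side) * cell + int(rng.integers(0, cell - size + 1))
        c0 = (int(c) % n_side) * cell + int(rng.integers(0, cell - size + 1))
        block, vol = _SHAPES[shape](size, h_apex)
        hmap[r0 : r0 + size, c0 : c0 + size] += block
        total += vol
    return hmap, SyntheticTruth(true_volume=total, height_map=hmap, seed=seed)


def render_zstack(
    height_map: np.ndarray,
    truth: SyntheticTruth | None = None,
    delta_z: float = DEFAULT_DELTA_Z,
    object_intensity: int = 200,
    background_mean: float = 8.0,
    background_sd: float = 5.0,
    signal_sd: float = 5.0,
    margin_planes: int = 4,
    seed: int = 0,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> tuple[ZStack, SyntheticTruth]:
    """Render a height field as an 8-bit confocal z-stack with Gaussian noise.

    Plane i (0-based, focal plane first) shows ``object_intensity`` plus
    signal noise wherever the local height exceeds ``i * delta_z``, and
    background noise elsewhere; ``margin_planes`` extra pure-background planes
    sit above the tips, as acquisition always overshoots the tallest
    aggregate slightly.  The recorded ``rendered_volume`` is the voxelized
    volume the thresholding method should recover exactly in the noiseless
    limit.
    """
    h = np.asarray(height_map, dtype=np.float64)
    if not 0 < background_mean < object_intensity <= 255:
        raise ValueError("need 0 < background_mean < object_intensity <= 255")
    rng = np.random.default_rng(seed)
    n_object = max(int(np.ceil(h.max() / delta_z)), 0)
    n = max(n_object, 1) + margin_planes
    f2 = pixel_pitch * pixel_pitch
    planes = np.empty((n,) + h.shape, dtype=np.uint8)
    voxels = 0
    for i in range(n):
        mask = h > i * delta_z
        voxels += int(mask.sum())
        bg = rng.normal(background_mean, background_sd, size=h.shape)
        if signal_sd > 0:
            obj = rng.normal(object_intensity, signal_sd, size=h.shape)
        else:
            obj = np.full(h.shape, float(object_intensity))
        plane = np.where(mask, obj, bg)
        planes[i] = np.clip(np.round(plane), 0, 255).astype(np.uint8)
    rendered = voxels * f2 * delta_z
    base = truth or SyntheticTruth(true_volume=rendered, height_map=h)
    return (
        ZStack.from_array(planes, pixel_pitch=pixel_pitch, delta_z=delta_z),
        replace(base, rendered_volume=rendered, seed=seed),
    )


def render_projection_image(
    height_map: np.ndarray,
    k_true: float,
    truth: SyntheticTruth | None = None,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> tuple[ImagePlane, SyntheticTruth]:
    """Project heights to an 8-bit intensity image: I = round(h / k), clip 255."""
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    h = np.asarray(height_map, dtype=np.float64)
    raw = np.round(h / k_true)
    if (raw > 255).any():
        import warnings

        warnings.warn(
            f"{int((raw > 255).sum())} pixels clipped at 255: intensity "
            "saturation, heights there are under-represented",
            stacklevel=2,
        )
    img = ImagePlane(np.clip(raw, 0, 255).astype(np.uint8), pixel_pitch)
    base = truth or SyntheticTruth(true_volume=float(h.sum() * pixel_pitch**2))
    return img, replace(base, scale_factor=k_true)


# ---------------------------------------------------------------------------
# impedance traces


def _logistic_dz(times: np.ndarray, final: float, t0: float, tau: float) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-(times - t0) / tau))
    s0 = 1.0 / (1.0 + np.exp(t0 / tau))
    s_end = 1.0 / (1.0 + np.exp(-(times[-1] - t0) / tau))
    return final * (s - s0) / (s_end - s0)


def make_trace(
    group: int,
    final_dz: float | None = None,
    crossing_time: float | None = None,
    noise_sd: float = 0.5,
    events: list[tuple[float, float, float]] | None = None,
    seed: int = 0,
    baseline_ohm: float = 1200.0,
    tau: float = 25.0,
    duration: float = 300.0,
    frequency: float = 150_000.0,
) -> tuple[ImpedanceSeries, SyntheticTruth]:
    """Synthesize a 1 Hz |Z| trace for one behaviour group.

    The clean ΔZ(%) trace is a logistic rise pinned to ΔZ(0) = 0, the target
    final value at the end, and the target 10%-crossing time (solved for the
    logistic midpoint by root finding).  Gaussian noise and optional
    ``events`` — (t1, t2, drop) linear falls — are superimposed, then the
    trace is converted to |Z| = baseline * (1 + ΔZ/100).
    """
    if group not in (1, 2, 3, 4):
        raise ValueError("group must be 1..4")
    if final_dz is None:
        final_dz = GROUP_FINAL_DZ[group][0]
    lo = ([0.0] + list(BAND_EDGES))[group - 1]
    hi = (list(BAND_EDGES) + [math.inf])[group - 1]
    if not lo <= final_dz < hi:
        raise ValueError(
            f"final ΔZ {final_dz}% outside group {group} band [{lo}, {hi})"
        )
    times = np.arange(0.0, duration + 0.5, 1.0)
    if group == 1:
        dz = _logistic_dz(times, final_dz, t0=150.0, tau=40.0)
    else:
        if crossing_time is None:
            crossing_time = GROUP_CROSSING[group][0]
        target = 10.0 / final_dz

        def miss(t0: float) -> float:
            s = 1.0 / (1.0 + math.exp(-(crossing_time - t0) / tau))
            s0 = 1.0 / (1.0 + math.exp(t0 / tau))
            s_end = 1.0 / (1.0 + math.exp(-(duration - t0) / tau))
            return (s - s0) / (s_end - s0) - target

        t0 = brentq(miss, -10.0 * tau, duration + 10.0 * tau, xtol=1e-6)
        dz = _logistic_dz(times, final_dz, t0=t0, tau=tau)
    for t1, t2, drop in events or ():
        if not t1 < t2:
            raise ValueError("event needs t1 < t2")
        dz = dz - drop * np.clip((times - t1) / (t2 - t1), 0.0, 1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dz = dz + rng.normal(0.0, noise_sd, size=times.shape)
    z = baseline_ohm * (1.0 + dz / 100.0)
    series = ImpedanceSeries(times=times, zmag=z, frequency=frequency)
    return series, SyntheticTruth(
        true_volume=math.nan, group_label=group, seed=seed
    )


def make_archetype_cohort(
    counts: dict[int, int],
    seed: int = 0,
    noise_sd: float = 0.5,
) -> list[tuple[ImpedanceSeries, SyntheticTruth]]:
    """Traces per group with final ΔZ and crossing time sampled around the
    group anchors, truncated so every trace satisfies its band and bound."""
    rng = np.random.default_rng(seed)
    out = []
    # keep sampled finals at least 5 noise-sd clear of the band edges so the
    # noisy end-of-perfusion sample cannot leak into a neighbouring band
    margin = max(1.0, 5.0 * noise_sd)
    for group, n in sorted(counts.items()):
        lo = ([0.0] + list(BAND_EDGES))[group - 1]
        hi = (list(BAND_EDGES) + [90.0])[group - 1]
        mean, sd = GROUP_FINAL_DZ[group]
        for _ in range(n):
            final = float(
                np.clip(rng.normal(mean, sd), lo + margin, hi - margin)
            )
            if group == 1:
                tc = None
            else:
                tmean, tsd = GROUP_CROSSING[group]
                bound = CROSSING_BOUNDS[group]
                # crossing inside (stronger-group bound, own bound): the trace
                # then satisfies its bound without qualifying for a stronger one
                t_lo = CROSSING_BOUNDS.get(group + 1, 15.0) + 10.0
                tc = float(np.clip(rng.normal(tmean, tsd), t_lo, bound - 5.0))
            trace, truth = make_trace(
                group,
                final_dz=final,
                crossing_time=tc,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
            out.append((trace, truth))
    return out


# ---------------------------------------------------------------------------
# paired optical/electrical cohort


@dataclass(frozen=True)
class PairedExperiment:
    """One synthetic perfusion: z-stack, projection image, measured |Z|, truth."""

    stack: ZStack
    image: ImagePlane
    z_measured: float
    z_baseline: float
    truth: SyntheticTruth


def make_paired_cohort(
    n: int,
    seed: int = 0,
    forward=None,
    k_true: float = 0.06,
    n_thrombi: tuple[int, int] = (2, 9),
    base_size: tuple[int, int] = (90, 160),
    height: tuple[float, float] = (3.0, 9.0),
    carpet_mean: tuple[float, float] = (0.3, 4.5),
    stack_noise_sd: float = 5.0,
    impedance_noise: float = 0.02,
) -> list[PairedExperiment]:
    """Generate paired optical + electrical experiments with shared truth.

    For each experiment a thrombus field is packed, rendered as a noisy
    z-stack and as the intensity projection seen by the fusion method, and
    the "measured" impedance is the forward-model value at the true scale
    factor perturbed by multiplicative Gaussian noise (default 2%).
    """
    if n < 3:
        raise ValueError("need at least 3 experiments for a cohort")
    from .conduction import ForwardModel

    fm = forward or ForwardModel()
    z0 = fm.baseline_impedance()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        s_field, s_stack, s_noise = (int(s) for s in rng.integers(2**31 - 1, size=3))
        nt = int(rng.integers(n_thrombi[0], n_thrombi[1] + 1))
        cm = float(rng.uniform(*carpet_mean))
        hmap, truth = make_thrombus_field(
            nt, base_size=base_size, height=height, seed=s_field,
            carpet_height=(0.6 * cm, 1.4 * cm),
        )
        stack, truth = render_zstack(
            hmap, truth, background_sd=stack_noise_sd, signal_sd=stack_noise_sd,
            seed=s_stack,
        )
        image, truth = render_projection_image(hmap, k_true, truth)
        z_clean = fm.impedance(image, k_true)
        noise = np.random.default_rng(s_noise).normal(0.0, impedance_noise)
        z_measured = z_clean * (1.0 + noise)
        out.append(
            PairedExperiment(
                stack=stack, image=image, z_measured=float(z_measured),
                z_baseline=z0, truth=truth,
            )
        )
    return out
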