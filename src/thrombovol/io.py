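"""File formats and run configuration.

Stacks are multi-page grayscale TIFFs (page order = z order, bottom plane
first) or a lexicographically sorted directory of single-plane images.
Impedance traces are CSVs with columns ``time_s, freq_hz, zmag_ohm``; a file
may hold several frequencies, of which only the configured working frequency
is kept.  The run configuration is a validated JSON/YAML document.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, PositiveFloat, PositiveInt

from .monitor import ImpedanceSeries
from .volumetry import DEFAULT_DELTA_Z, DEFAULT_PIXEL_PITCH, ImagePlane, ZStack

__all__ = ["RunConfig", "read_stack", "read_image", "read_trace", "write_trace"]

TRACE_COLUMNS = ("time_s", "freq_hz", "zmag_ohm")


class GeometryConfig(BaseModel):
    width_um: PositiveFloat = 500.0
    height_um: PositiveFloat = 100.0
    modeled_length_um: PositiveFloat = 840.0
    flow_rate_ul_min: PositiveFloat = 75.0


class ElectrodeConfig(BaseModel):
    window_um: PositiveFloat = 280.0
    outer_track_um: PositiveFloat = 30.0
    inner_track_um: PositiveFloat = 20.0
    inner_margin_um: PositiveFloat = 70.0


class ConductivityConfig(BaseModel):
    sigma_blood_s_m: PositiveFloat = 0.59
    sigma_thrombus_s_m: PositiveFloat = 0.59 / 8.0
    working_frequency_hz: PositiveFloat = 150_000.0
    drive_voltage_v: PositiveFloat = 0.1


class SolverConfig(BaseModel):
    voxel_xy_um: PositiveFloat = 10.0
    z_first_um: PositiveFloat = 2.0
    z_uniform_layers: PositiveInt = 8
    z_ratio: PositiveFloat = 1.5


class MonitorConfig(BaseModel):
    crossing_level_pct: PositiveFloat = 10.0
    min_drop_pct: PositiveFloat = 5.0
    max_window_s: PositiveFloat = 10.0
    baseline_window: PositiveInt = 1


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    pixel_pitch_um: PositiveFloat = DEFAULT_PIXEL_PITCH
    delta_z_um: PositiveFloat = DEFAULT_DELTA_Z
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    electrodes: ElectrodeConfig = Field(default_factory=ElectrodeConfig)
    conductivity: ConductivityConfig = Field(default_factory=ConductivityConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    monitor: MonitorConfig = Field(default_factory=MonitorConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data or {})

    def content_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:16]

    def forward_model(self):
        from .conduction import (
            ChannelGeometry,
            ConductivityModel,
            ElectrodeLayout,
            ForwardModel,
            VoxelGrid,
        )

        geom = ChannelGeometry(
            width=self.geometry.width_um,
            height=self.geometry.height_um,
            modeled_length=self.geometry.modeled_length_um,
            flow_rate_ul_min=self.geometry.flow_rate_ul_min,
        )
        layout = ElectrodeLayout(
            window=self.electrodes.window_um,
            outer_track=self.electrodes.outer_track_um,
            inner_track=self.electrodes.inner_track_um,
            inner_margin=self.electrodes.inner_margin_um,
        )
        model = ConductivityModel(
            sigma_blood=self.conductivity.sigma_blood_s_m,
            sigma_thrombus=self.conductivity.sigma_thrombus_s_m,
            working_frequency=self.conductivity.working_frequency_hz,
            drive_voltage=self.conductivity.drive_voltage_v,
        )
        grid = VoxelGrid.default(
            geom,
            layout,
            voxel_xy=self.solver.voxel_xy_um,
            z_first=self.solver.z_first_um,
            z_uniform=self.solver.z_uniform_layers,
            z_ratio=self.solver.z_ratio,
        )
        return ForwardModel(geom=geom, layout=layout, model=model, grid=grid)


def _load_plane(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A): grayscale content expected, take one channel
        arr = arr[..., 0]
    return arr


def read_stack(
    path: str | Path,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    delta_z: float = DEFAULT_DELTA_Z,
) -> ZStack:
    """Load a z-stack from a multi-page TIFF or a directory of plane images."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not files:
            raise FileNotFoundError(f"no plane images found in {path}")
        planes = [_load_plane(p) for p in files]
    elif path.is_file():
        import tifffile

        with tifffile.TiffFile(path) as tf:
            planes = [page.asarray() for page in tf.pages]
        if not planes:
            raise ValueError(f"{path} contains no pages")
    else:
        raise FileNotFoundError(path)
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise ValueError(f"planes have mixed shapes: {sorted(shapes)}")
    return ZStack(
        planes=tuple(ImagePlane(p, pixel_pitch) for p in planes), delta_z=delta_z
    )


def read_image(path: str | Path, pixel_pitch: float = DEFAULT_PIXEL_PITCH) -> ImagePlane:
    """Load a single 2D grayscale image."""
    return ImagePlane(_load_plane(Path(path)), pixel_pitch)


def read_trace(path: str | Path, frequency: float = 150_000.0) -> ImpedanceSeries:
    """Load an impedance CSV, keeping only rows at the working frequency."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns: {missing}")
    sel = df[np.isclose(df["freq_hz"], frequency)]
    if sel.empty:
        raise ValueError(f"no rows at working frequency {frequency} Hz")
    times = sel["time_s"].to_numpy(dtype=np.float64)
    if not (np.diff(times) > 0).all():
        raise ValueError("trace times are not strictly increasing")
    return ImpedanceSeries(
        times=times, zmag=sel["zmag_ohm"].to_numpy(dtype=np.float64),
        frequency=frequency,
    )


def write_trace(series: ImpedanceSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": series.times,
            "freq_hz": np.full(len(series), series.frequency),
            "zmag_ohm": series.zmag,
        }
    ).to_csv(path, index=False)
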