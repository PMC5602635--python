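"""Real-time impedance monitoring: ΔZ(%) traces, classification, events.

During a 300 s blood perfusion the impedance magnitude at the working
frequency rises as platelets adhere and aggregate between the electrodes.
Expressed as the relative increase over the thrombus-free initial value,
ΔZ(%), the traces fall into four physiological behaviours:

====== ==================== ========================== =====================
group  behaviour            final ΔZ at 300 s          10%-crossing bound
====== ==================== ========================== =====================
1      very low adhesion    < 10 %                     never crosses
2      regular adhesion     10–20 %                    within 240 s
3      strong aggregation   20–40 %                    within 180 s
4      occlusive towering   >= 40 %                    within 120 s
====== ==================== ========================== =====================

The final-ΔZ band is the primary key (the bands partition [0, inf) while the
crossing times do not); the crossing-time bound is kept as a consistency
flag.  Sudden monotone drops of ΔZ signal detachment (embolization) of formed
aggregates and are reported as timed events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImpedanceSeries",
    "DeltaZSeries",
    "ClassificationResult",
    "DetachmentEvent",
    "delta_z",
    "crossing_time",
    "classify",
    "predict_group",
    "detect_detachment",
    "plot_trace",
]

PERFUSION_SECONDS = 300.0
CROSSING_LEVEL = 10.0  # percent
#: final-ΔZ band edges: [0,10) -> G1, [10,20) -> G2, [20,40) -> G3, [40,inf) -> G4
BAND_EDGES = (10.0, 20.0, 40.0)
#: 10%-crossing bound per group (seconds); group 1 has no bound.
CROSSING_BOUNDS = {2: 240.0, 3: 180.0, 4: 120.0}


@dataclass(frozen=True)
class ImpedanceSeries:
    """Time-stamped |Z| samples at one working frequency."""

    times: np.ndarray  # s, strictly increasing
    zmag: np.ndarray  # ohm, positive
    frequency: float = 150_000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        z = np.asarray(self.zmag, dtype=np.float64)
        if t.shape != z.shape or t.ndim != 1:
            raise ValueError("times and zmag must be 1-D arrays of equal length")
        if len(t) >= 2 and not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (z <= 0).any():
            raise ValueError("|Z| must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "zmag", z)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class DeltaZSeries:
    """Relative impedance variation ΔZ(%) over the initial (baseline) value."""

    times: np.ndarray
    dz: np.ndarray  # percent
    baseline: float  # ohm

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ClassificationResult:
    group: int  # 1..4
    final_delta_z: float  # percent at end of perfusion
    crossing_time_10pct: float | None  # s, None if never crossed
    consistent: bool


@dataclass(frozen=True)
class DetachmentEvent:
    """A sudden monotone fall of ΔZ between t1 and t2."""

    t1: float
    t2: float
    drop: float  # percentage points, positive

    def __post_init__(self) -> None:
        if not (self.t1 < self.t2 and self.drop > 0):
            raise ValueError("need t1 < t2 and a positive drop")


def delta_z(series: ImpedanceSeries, baseline_window: int = 1) -> DeltaZSeries:
    """ΔZ(t) = 100 (|Z|(t) - Z0) / Z0 with Z0 the mean of the first samples.

    ``baseline_window`` = 1 (the default) uses the initial value alone; a wider
    window is available for noisy logs.
    """
    if len(series) < 2:
        raise ValueError("need at least two samples")
    z0 = float(series.zmag[: max(1, baseline_window)].mean())
    if z0 <= 0:
        raise ValueError("non-positive baseline impedance")
    dz = 100.0 * (series.zmag - z0) / z0
    return DeltaZSeries(times=series.times, dz=dz, baseline=z0)


def crossing_time(dz: DeltaZSeries, level: float = CROSSING_LEVEL) -> float | None:
    """First time ΔZ reaches ``level``, linearly interpolated; None if never."""
    above = dz.dz >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(dz.times[0])
    t0, t1 = dz.times[i - 1], dz.times[i]
    y0, y1 = dz.dz[i - 1], dz.dz[i]
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def _band(final: float) -> int:
    for grp, edge in enumerate(BAND_EDGES, start=1):
        if final < edge:
            return grp
    return 4


def classify(dz: DeltaZSeries) -> ClassificationResult:
    """Assign the 4-level behaviour group from the final ΔZ, with a
    crossing-time consistency flag.

    The trace should cover the full 300 s perfusion (tolerance one sample
    interval); shorter traces are classified on the available data with a
    truncation warning.
    """
    t_end = float(dz.times[-1])
    step = float(np.median(np.diff(dz.times))) if len(dz) > 1 else 1.0
    if t_end < PERFUSION_SECONDS - step - 1e-9:
        warnings.warn(
            f"trace ends at {t_end:.0f} s < {PERFUSION_SECONDS:.0f} s; "
            "classifying on available data",
            stacklevel=2,
        )
    final = float(dz.dz[-1])
    group = _band(final)
    tc = crossing_time(dz)
    if group == 1:
        consistent = True  # no crossing requirement
    else:
        bound = CROSSING_BOUNDS[group]
        consistent = tc is not None and tc <= bound
    return ClassificationResult(
        group=group, final_delta_z=final, crossing_time_10pct=tc,
        consistent=consistent,
    )


@dataclass(frozen=True)
class GroupPrediction:
    """Provisional group while the perfusion is still running."""

    group: int | None  # point prediction, None while undecided
    candidates: tuple[int, ...]
    t_now: float


def predict_group(dz: DeltaZSeries, t_now: float) -> GroupPrediction:
    """Earliest-decision rule from the 10%-crossing thresholds.

    Crossing by 120 s predicts group 4, by 180 s group 3, by 240 s group 2;
    with no crossing by 240 s the trace is group 1 or 2 until the final value
    at 300 s decides.
    """
    if t_now > PERFUSION_SECONDS:
        raise ValueError("t_now beyond the perfusion window")
    keep = dz.times <= t_now + 1e-9
    part = DeltaZSeries(times=dz.times[keep], dz=dz.dz[keep], baseline=dz.baseline)
    tc = crossing_time(part)
    if tc is not None:
        if tc <= 120.0:
            return GroupPrediction(group=4, candidates=(4,), t_now=t_now)
        if tc <= 180.0:
            return GroupPrediction(group=3, candidates=(3,), t_now=t_now)
        if tc <= 240.0:
            return GroupPrediction(group=2, candidates=(2,), t_now=t_now)
        # late crossing: final band will decide between 2 and above
        return GroupPrediction(group=None, candidates=(2, 3, 4), t_now=t_now)
    if t_now >= 240.0:
        return GroupPrediction(group=None, candidates=(1, 2), t_now=t_now)
    return GroupPrediction(group=None, candidates=(1, 2, 3, 4), t_now=t_now)


def plot_trace(dz: DeltaZSeries, events=None, classification=None, path=None):
    """Plot ΔZ(%) with the group bands and optional event markers.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(dz.times, dz.dz, lw=1.2, color="tab:blue")
    for edge in BAND_EDGES:
        ax.axhline(edge, color="0.7", lw=0.8, ls="--")
    ax.axhline(CROSSING_LEVEL, color="tab:red", lw=0.8, ls=":")
    for ev in events or ():
        ax.axvspan(ev.t1, ev.t2, color="tab:orange", alpha=0.3)
        ax.annotate(
            f"-{ev.drop:.1f}", xy=(ev.t2, dz.dz[np.searchsorted(dz.times, ev.t2)]),
            fontsize=8,
        )
    title = "ΔZ(%) during perfusion"
    if classification is not None:
        title += f" — group {classification.group}"
    ax.set(xlabel="time (s)", ylabel="ΔZ (%)", title=title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


#: A step may rise by this many points and still count as "monotone decrease".
MONOTONE_STEP_TOL = 0.2


def detect_detachment(
    dz: DeltaZSeries,
    min_drop: float = 5.0,
    max_window: float = 10.0,
) -> list[DetachmentEvent]:
    """Find sudden monotone falls of ΔZ: detachment/embolization events.

    An event is a maximal interval [t1, t2] with t2 - t1 <= ``max_window``
    over which every step changes by at most +MONOTONE_STEP_TOL (i.e. the
    trace is monotone decreasing up to tolerance), the total fall is at least
    ``min_drop`` percentage points, and the first and last steps are genuine
    falls (below -MONOTONE_STEP_TOL) so that flat noise floors do not stretch
    the reported endpoints.  Events are returned in time order.
    """
    t, y = dz.times, dz.dz
    n = len(t)
    steps = np.diff(y)
    ok = steps <= MONOTONE_STEP_TOL
    strict = steps < -MONOTONE_STEP_TOL
    candidates: list[tuple[int, int]] = []
    for i in range(n - 1):
        if not strict[i]:
            continue
        j = i + 1
        while j < n and t[j] - t[i] <= max_window and ok[j - 1]:
            if strict[j - 1] and y[i] - y[j] >= min_drop:
                candidates.append((i, j))
            j += 1
    # keep only intervals not contained in another candidate
    events = []
    for i, j in candidates:
        if any(
            (i2 <= i and j <= j2 and (i2, j2) != (i, j)) for i2, j2 in candidates
        ):
            continue
        events.append(
            DetachmentEvent(t1=float(t[i]), t2=float(t[j]), drop=float(y[i] - y[j]))
        )
    events.sort(key=lambda e: (e.t1, e.t2))
    return events
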