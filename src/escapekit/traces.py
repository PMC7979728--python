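"""Rule-based segmentation and classification of single-cell CDK2 activity traces.

A CDK2 translocation sensor reads out cell-cycle commitment in live-cell
movies: the cytoplasmic:nuclear ratio of the sensor is low in quiescent
(CDK2-low) cells and builds up as cells pass the restriction point and
progress toward mitosis.  The classification proceeds in three rule-based
steps per cell:

1. *Seed regions* — maximal runs of frames with CDK2 activity above a high
   threshold (default 0.9, roughly S-phase entry).  Near the end of the
   movie the threshold drops to 0.6 so that cells which have begun to
   re-enter the cycle but have not yet reached high activity are still
   caught.
2. *Phase annotation* — each seed region is extended backward to the
   restriction point (the closest earlier frame where the activity slope
   falls below a threshold, i.e. where the ramp starts) and forward to the
   mitosis point (the closest later frame with a locally maximal H2B
   nuclear intensity, which spikes at division).  Frames between the two
   are proliferative; everything else is quiescent.  Interior quiescent
   gaps shorter than a minimum duration (default 4 h) are relabelled
   proliferative, because the high seed threshold can otherwise split a
   single fast cycle in two.
3. *Escape classification* — a cell is an *escapee* if it spends at least
   one frame quiescent at or after drug addition and subsequently passes a
   restriction point (re-enters the cycle in drug); a cell that stays
   quiescent after entering the drug-induced CDK2-low state is a
   *non-escapee*.  Cells not tracked to the end of the movie are excluded.

Frames are 0-based and intervals half-open unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.ndimage import median_filter

__all__ = [
    "Trace",
    "TraceSet",
    "TraceConfig",
    "PhaseAnnotation",
    "EscapeCall",
    "find_seed_regions",
    "annotate_phases",
    "classify_escape",
    "classify_all",
    "order_traces",
    "cell_count_curve",
    "read_trace_csv",
    "write_trace_csv",
]

ESCAPEE = "escapee"
NON_ESCAPEE = "non-escapee"
EXCLUDED = "excluded"


@dataclass
class Trace:
    """One cell's CDK2 activity and H2B intensity time series.

    ``complete`` is False when the cell was lost before the end of the
    movie (e.g. apoptosis or tracking loss); such cells are excluded from
    escape classification.
    """

    cdk2: np.ndarray
    h2b: np.ndarray
    complete: bool = True

    def __post_init__(self) -> None:
        self.cdk2 = np.asarray(self.cdk2, dtype=float)
        self.h2b = np.asarray(self.h2b, dtype=float)
        if self.cdk2.ndim != 1 or self.h2b.ndim != 1:
            raise ValueError("cdk2 and h2b must be 1-D")
        if len(self.cdk2) != len(self.h2b):
            raise ValueError("cdk2 and h2b must have equal length")
        if len(self.cdk2) == 0:
            raise ValueError("empty trace")
        if not (np.isfinite(self.cdk2).all() and np.isfinite(self.h2b).all()):
            raise ValueError("activities must be finite")
        if (self.cdk2 < 0).any() or (self.h2b < 0).any():
            raise ValueError("activities must be >= 0")

    def __len__(self) -> int:
        return len(self.cdk2)


@dataclass
class TraceSet:
    """A collection of single-cell traces on a shared frame grid."""

    traces: list[Trace]
    frame_interval_h: float
    drug_add_frame: int | None = None
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i:04d}" for i in range(len(self.traces))]
        if len(self.cell_ids) != len(self.traces):
            raise ValueError("cell_ids and traces length mismatch")
        if self.drug_add_frame is not None:
            n_max = max((len(t) for t in self.traces), default=0)
            if not (0 <= self.drug_add_frame < n_max):
                raise ValueError("drug_add_frame outside frame range")

    def __len__(self) -> int:
        return len(self.traces)


@dataclass
class TraceConfig:
    """Thresholds for trace segmentation.

    seed_threshold : CDK2 activity above which frames anchor a
        proliferative interval (S-phase-entry level).
    tail_threshold : reduced threshold applied within the final
        ``tail_window_h`` hours, catching late cell-cycle re-entries that
        have not yet reached ``seed_threshold`` by movie end.
    slope_threshold : activity change per frame below which the ramp is
        considered not yet started (restriction-point rule).
    min_quiescence_h : interior quiescent gaps shorter than this are
        relabelled proliferative.
    h2b_peak_halfwidth : a frame is an H2B local maximum when strictly
        greater than all neighbours within this many frames.
    smoothing_window : width of an optional centered median filter applied
        to the CDK2 trace before all rules; 1 disables smoothing.
    """

    seed_threshold: float = 0.9
    tail_threshold: float = 0.6
    tail_window_h: float = 6.0
    slope_threshold: float = 0.01
    min_quiescence_h: float = 4.0
    h2b_peak_halfwidth: int = 2
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        if not self.tail_threshold < self.seed_threshold:
            raise ValueError("tail_threshold must be < seed_threshold")
        for name in ("seed_threshold", "tail_threshold", "tail_window_h",
                     "slope_threshold", "min_quiescence_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.h2b_peak_halfwidth < 1:
            raise ValueError("h2b_peak_halfwidth must be >= 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


@dataclass
class PhaseAnnotation:
    """Per-frame proliferative/quiescent labels plus anchor points.

    ``phase`` is True on proliferative frames.  Restriction and mitosis
    points are sorted, unique frame indices.
    """

    phase: np.ndarray
    restriction_points: list[int]
    mitosis_points: list[int]


@dataclass
class EscapeCall:
    label: str
    first_escape_frame: int | None
    n_mitoses_in_window: int


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as half-open intervals."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _smooth(cdk2: np.ndarray, cfg: TraceConfig) -> np.ndarray:
    if cfg.smoothing_window == 1:
        return cdk2
    return median_filter(cdk2, size=cfg.smoothing_window, mode="nearest")


def find_seed_regions(
    cdk2: np.ndarray, cfg: TraceConfig, frame_interval_h: float
) -> list[tuple[int, int]]:
    """Maximal runs of frames with CDK2 activity above the seed threshold.

    Within the final ``tail_window_h`` hours of the trace, frames above
    the lower ``tail_threshold`` also qualify.  Returns disjoint, sorted
    half-open ``[start, end)`` intervals.
    """
    cdk2 = np.asarray(cdk2, dtype=float)
    if cdk2.size == 0:
        raise ValueError("empty trace")
    mask = cdk2 > cfg.seed_threshold
    tail_frames = int(round(cfg.tail_window_h / frame_interval_h))
    if tail_frames > 0:
        tail_start = max(0, cdk2.size - tail_frames)
        mask[tail_start:] |= cdk2[tail_start:] > cfg.tail_threshold
    return _runs(mask)


def _h2b_local_maxima(h2b: np.ndarray, halfwidth: int) -> np.ndarray:
    """Frames strictly greater than every neighbour within +/- halfwidth."""
    n = h2b.size
    is_max = np.ones(n, dtype=bool)
    for off in range(1, halfwidth + 1):
        left = np.empty(n, dtype=bool)
        left[:off] = True
        left[off:] = h2b[off:] > h2b[:-off]
        right = np.empty(n, dtype=bool)
        right[n - off:] = True
        right[: n - off] = h2b[: n - off] > h2b[off:]
        is_max &= left & right
    return is_max


def annotate_phases(
    trace: Trace, cfg: TraceConfig, frame_interval_h: float
) -> PhaseAnnotation:
    """Assign each frame proliferative or quiescent via the three-rule scheme.

    For every seed region, scan backward for the first frame whose
    forward-difference slope drops below ``slope_threshold`` (restriction
    point; frame 0 if none is found) and forward for the first H2B local
    maximum (mitosis point; the trace runs proliferative through its end
    if none is found).  Frames from restriction to mitosis inclusive are
    proliferative; after taking the union over seed regions, interior
    quiescent runs shorter than ``min_quiescence_h`` are relabelled
    proliferative.
    """
    if cfg.min_quiescence_h < frame_interval_h:
        warnings.warn(
            "min_quiescence_h below the frame interval; the short-gap rule "
            "is inert", stacklevel=2,
        )
    x = _smooth(trace.cdk2, cfg)
    n = x.size
    slope = np.empty(n)
    if n > 1:
        slope[:-1] = np.diff(x)
        slope[-1] = slope[-2]
    else:
        slope[0] = 0.0
    regions = find_seed_regions(x, cfg, frame_interval_h)
    locmax = _h2b_local_maxima(trace.h2b, cfg.h2b_peak_halfwidth)

    phase = np.zeros(n, dtype=bool)
    restriction: list[int] = []
    mitosis: list[int] = []
    for start, end in regions:
        r = 0
        for t in range(start - 1, -1, -1):
            if slope[t] < cfg.slope_threshold:
                r = t
                break
        hits = np.flatnonzero(locmax[end:])
        if hits.size:
            m = end + int(hits[0])
            mitosis.append(m)
        else:
            m = n - 1  # proliferative through trace end
        phase[r: m + 1] = True
        restriction.append(r)

    # Relabel interior quiescent gaps shorter than the minimum duration.
    # Boundary runs are exempt: converting pre-ramp baseline at the trace
    # edges would misclassify it.
    min_frames = cfg.min_quiescence_h / frame_interval_h
    for start, end in _runs(~phase):
        if start == 0 or end == n:
            continue
        if (end - start) < min_frames:
            phase[start:end] = True

    return PhaseAnnotation(
        phase=phase,
        restriction_points=sorted(set(restriction)),
        mitosis_points=sorted(set(mitosis)),
    )


def classify_escape(
    annotation: PhaseAnnotation,
    trace: Trace,
    drug_add_frame: int | None,
    mitosis_window: tuple[int, int] | None = None,
) -> EscapeCall:
    """Call a cell escapee, non-escapee, or excluded.

    Escapee: at least one quiescent frame at/after drug addition is
    followed by a later restriction point (cell-cycle re-entry in drug).
    Incomplete traces are excluded.  ``n_mitoses_in_window`` counts
    mitosis points inside the half-open ``mitosis_window``, for
    quantifying continued cycling after classification.
    """
    if mitosis_window is not None:
        w0, w1 = mitosis_window
        n_mit = sum(w0 <= m < w1 for m in annotation.mitosis_points)
    else:
        n_mit = 0
    if not trace.complete:
        return EscapeCall(EXCLUDED, None, n_mit)
    if drug_add_frame is None:
        raise ValueError("drug_add_frame required for escape classification")
    quiescent = np.flatnonzero(~annotation.phase[drug_add_frame:])
    if quiescent.size:
        q0 = drug_add_frame + int(quiescent[0])
        for r in annotation.restriction_points:
            if r > q0:
                return EscapeCall(ESCAPEE, r, n_mit)
    return EscapeCall(NON_ESCAPEE, None, n_mit)


def classify_all(
    ts: TraceSet,
    cfg: TraceConfig | None = None,
    mitosis_window: tuple[int, int] | None = None,
) -> tuple[list[PhaseAnnotation], list[EscapeCall]]:
    """Annotate and classify every cell of a trace set."""
    cfg = cfg or TraceConfig()
    annotations = [annotate_phases(t, cfg, ts.frame_interval_h) for t in ts.traces]
    calls = [
        classify_escape(a, t, ts.drug_add_frame, mitosis_window)
        for a, t in zip(annotations, ts.traces)
    ]
    return annotations, calls


def order_traces(ts: TraceSet, calls: Sequence[EscapeCall]) -> np.ndarray:
    """Display permutation for heatmaps: escapees then non-escapees, each
    ordered by hierarchical clustering of their CDK2 activity vectors
    (Euclidean distance, average linkage); excluded cells follow in input
    order.  Deterministic given a fixed input order."""
    lengths = {len(t) for t, c in zip(ts.traces, calls)
               if c.label != EXCLUDED}
    if len(lengths) > 1:
        raise ValueError("order_traces requires an aligned frame grid")
    order: list[int] = []
    for label in (ESCAPEE, NON_ESCAPEE):
        idx = np.array([i for i, c in enumerate(calls) if c.label == label], dtype=int)
        if idx.size == 0:
            continue
        if idx.size < 3:
            order.extend(idx.tolist())
            continue
        mat = np.vstack([ts.traces[i].cdk2 for i in idx])
        leaf = leaves_list(linkage(mat, method="average", metric="euclidean"))
        order.extend(idx[leaf].tolist())
    order.extend(i for i, c in enumerate(calls) if c.label == EXCLUDED)
    return np.asarray(order, dtype=int)


def cell_count_curve(ts: TraceSet) -> np.ndarray:
    """Number of cells whose trace spans each frame.

    Mirrors counting nuclei in the field of view over time: truncated
    traces stop contributing at their truncation frame.
    """
    n_frames = max((len(t) for t in ts.traces), default=0)
    counts = np.zeros(n_frames, dtype=int)
    for t in ts.traces:
        counts[: len(t)] += 1
    return counts


def read_trace_csv(
    path,
    frame_interval_h: float | None = None,
    drug_add_frame: int | None = None,
    movie_frames: int | None = None,
) -> TraceSet:
    """Read long-format trace CSV (cell_id, frame, time_h, cdk2, h2b).

    Cells whose last frame falls short of ``movie_frames`` (default: the
    longest trace present) are flagged incomplete.
    """
    df = pd.read_csv(path)
    required = {"cell_id", "frame", "cdk2", "h2b"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(required)}")
    if frame_interval_h is None:
        if "time_h" not in df.columns:
            raise ValueError("frame_interval_h not given and no time_h column")
        sub = df[df.frame < 2].pivot_table(index="cell_id", columns="frame", values="time_h")
        if sub.shape[1] < 2:
            raise ValueError("cannot infer frame interval from a 1-frame file")
        frame_interval_h = float(sub.iloc[0, 1] - sub.iloc[0, 0])
    traces, ids = [], []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        traces.append(Trace(grp.cdk2.to_numpy(), grp.h2b.to_numpy()))
        ids.append(str(cid))
    n_full = movie_frames if movie_frames is not None else max(len(t) for t in traces)
    for t in traces:
        t.complete = len(t) == n_full
    return TraceSet(traces, frame_interval_h, drug_add_frame, ids)


def write_trace_csv(ts: TraceSet, path) -> None:
    rows = []
    for cid, t in zip(ts.cell_ids, ts.traces):
        frames = np.arange(len(t))
        rows.append(pd.DataFrame({
            "cell_id": cid,
            "frame": frames,
            "time_h": frames * ts.frame_interval_h,
            "cdk2": t.cdk2,
            "h2b": t.h2b,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
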