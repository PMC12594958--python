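"""Active/inactive classification of cells from calcium-imaging time series.

Per-cell mean-intensity traces are corrected for dye bleaching with an
iteratively clipped polynomial baseline, normalised to dF/F, low-pass
filtered, and screened for transients with a peak finder.  A cell is active
if it shows at least one qualifying transient and the variance of its
normalised trace exceeds a floor that rejects flat, noise-only cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "TraceMatrix",
    "DetectionThresholds",
    "ActivityTable",
    "PerformanceReport",
    "extract_traces",
    "fit_baseline",
    "normalize_and_filter",
    "detect_transients",
    "classify_active",
    "optimize_thresholds",
    "detection_performance",
    "compare_active_fractions",
]


@dataclass
class TraceMatrix:
    """Per-cell mean fluorescence over time (cells x frames)."""

    traces: np.ndarray
    frame_interval_s: float = 0.08
    cell_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not np.isfinite(self.traces).all():
            raise ValueError("traces contain missing frames")
        if self.cell_ids is None:
            self.cell_ids = list(range(self.traces.shape[0]))

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.frame_interval_s


@dataclass(frozen=True)
class DetectionThresholds:
    """Transient-detection criteria (dF/F units unless noted).

    min_width is in seconds (1.25 frames at the 80-ms frame interval);
    max_length is the event extent at its prominence base, in frames.
    """

    prominence: float = 0.023
    min_width_s: float = 0.1
    max_length_frames: float = 37.0
    min_variance: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("prominence", "min_width_s", "max_length_frames", "min_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ActivityTable:
    """Per-cell events/variance/active flags and the FOV active fraction."""

    cells: pd.DataFrame  # cell_id, n_events, variance, active
    events: pd.DataFrame  # cell_id, frame, prominence, width_frames

    @property
    def active_fraction(self) -> float:
        return float(self.cells["active"].mean()) if len(self.cells) else float("nan")


@dataclass
class PerformanceReport:
    """Sensitivity/specificity of the detector against reference labels."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sn(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def extract_traces(
    movie: np.ndarray, masks: np.ndarray, frame_interval_s: float = 0.08
) -> TraceMatrix:
    """Mean intensity within each labelled cell outline, per frame."""
    movie = np.asarray(movie, dtype=float)
    masks = np.asarray(masks)
    if movie.ndim != 3 or movie.shape[1:] != masks.shape:
        raise ValueError("movie frames must share the mask geometry")
    labels = [lab for lab in np.unique(masks) if lab > 0]
    traces, ids = [], []
    for lab in labels:
        sel = masks == lab
        if not sel.any():
            warnings.warn(f"label {lab} is empty; cell skipped")
            continue
        traces.append(movie[:, sel].mean(axis=1))
        ids.append(int(lab))
    return TraceMatrix(np.asarray(traces), frame_interval_s, cell_ids=ids)


def fit_baseline(
    trace: np.ndarray, degree: int = 3, max_iter: int = 100, tol: float = 1e-9
) -> np.ndarray:
    """Bleaching baseline via iteratively clipped polynomial fitting.

    A degree-``degree`` polynomial is fitted, the trace is clipped to the
    pointwise minimum of itself and the fit, and the fit repeats until the
    coefficients converge.  Positive transients are thereby excluded from the
    baseline, which tracks the slow multiplicative bleaching trend.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < degree + 1:
        raise ValueError("fewer frames than degree + 1")
    x = np.linspace(-1.0, 1.0, y.size)  # scaled support keeps the fit stable
    clipped = y.copy()
    coeffs = np.polyfit(x, clipped, degree)
    for _ in range(max_iter):
        base = np.polyval(coeffs, x)
        clipped = np.minimum(clipped, base)
        new = np.polyfit(x, clipped, degree)
        if np.abs(new - coeffs).max() < tol:
            coeffs = new
            break
        coeffs = new
    return np.polyval(coeffs, x)


def normalize_and_filter(
    trace: np.ndarray,
    baseline: np.ndarray,
    sampling_rate_hz: float = 12.5,
    butter_order: int = 3,
    cutoff_hz: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """dF/F normalisation followed by zero-phase Butterworth smoothing.

    Returns ``(dff_raw, dff_filtered)``; the raw normalised trace feeds the
    variance gate, the filtered one the peak finder.
    """
    trace = np.asarray(trace, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if (baseline <= 0).any():
        raise ValueError("baseline must be strictly positive")
    dff = trace / baseline - 1.0
    nyq = sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    b, a = signal.butter(butter_order, cutoff_hz / nyq)
    filtered = signal.filtfilt(b, a, dff)
    return dff, filtered


def detect_transients(
    dff_filtered: np.ndarray,
    thresholds: DetectionThresholds = DetectionThresholds(),
    frame_interval_s: float = 0.08,
) -> pd.DataFrame:
    """Find calcium transients in a filtered dF/F trace.

    Peaks must have prominence >= ``prominence`` and a half-prominence
    width between ``min_width_s`` (converted to frames) and
    ``max_length_frames``.  Both bounds act on the same contour: calcium
    transients at this sampling have a half-prominence extent of a few
    hundred milliseconds to ~2 s, whereas bleaching residues and slow
    drifts are far wider, so the 37-frame cap rejects them; the
    half-prominence level itself sits well above the noise floor, which
    keeps the measure stable.
    """
    min_width_frames = thresholds.min_width_s / frame_interval_s
    peaks, props = signal.find_peaks(
        dff_filtered,
        prominence=thresholds.prominence,
        width=min_width_frames,
    )
    if len(peaks) == 0:
        return pd.DataFrame(columns=["frame", "prominence", "width_frames"])
    lengths = props["widths"]
    keep = lengths <= thresholds.max_length_frames
    return pd.DataFrame(
        {
            "frame": peaks[keep],
            "prominence": props["prominences"][keep],
            "width_frames": props["widths"][keep],
        }
    )


def classify_active(
    events: pd.DataFrame,
    dff_raw: np.ndarray,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> bool:
    """Active = at least one qualifying transient AND variance above floor."""
    return bool(len(events) >= 1 and np.var(dff_raw) >= thresholds.min_variance)


def analyze_traces(
    tm: TraceMatrix, thresholds: DetectionThresholds = DetectionThresholds()
) -> ActivityTable:
    """Run the full per-cell pipeline over a trace matrix."""
    cell_rows, event_rows = [], []
    for cid, trace in zip(tm.cell_ids, tm.traces):
        baseline = fit_baseline(trace)
        dff, filt = normalize_and_filter(
            trace, baseline, sampling_rate_hz=tm.sampling_rate_hz
        )
        events = detect_transients(filt, thresholds, tm.frame_interval_s)
        active = classify_active(events, dff, thresholds)
        cell_rows.append((cid, len(events), float(np.var(dff)), active))
        for _, ev in events.iterrows():
            event_rows.append((cid, int(ev["frame"]), ev["prominence"], ev["width_frames"]))
    return ActivityTable(
        cells=pd.DataFrame(
            cell_rows, columns=["cell_id", "n_events", "variance", "active"]
        ),
        events=pd.DataFrame(
            event_rows, columns=["cell_id", "frame", "prominence", "width_frames"]
        ),
    )


def detection_performance(
    predicted: np.ndarray, truth: np.ndarray
) -> PerformanceReport:
    """Confusion counts of predicted vs reference active flags."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("flag arrays must share a shape")
    return PerformanceReport(
        tp=int((predicted & truth).sum()),
        fp=int((predicted & ~truth).sum()),
        tn=int((~predicted & ~truth).sum()),
        fn=int((~predicted & truth).sum()),
    )


def optimize_thresholds(
    tm: TraceMatrix,
    labels: np.ndarray,
    prominence_grid: tuple[float, ...] = (0.01, 0.023, 0.05, 0.1),
    variance_grid: tuple[float, ...] = (1e-5, 1e-4, 1e-3),
) -> DetectionThresholds:
    """Grid search maximising balanced accuracy (sn + sp)/2 against labels.

    Ties resolve to the more conservative candidate (higher prominence, then
    higher variance floor).
    """
    labels = np.asarray(labels, dtype=bool)
    best: tuple[float, float, float] | None = None
    best_thr = None
    for prom in prominence_grid:
        for var in variance_grid:
            thr = DetectionThresholds(prominence=prom, min_variance=var)
            table = analyze_traces(tm, thr)
            pred = table.cells["active"].to_numpy()
            rep = detection_performance(pred, labels)
            sn = rep.sn if np.isfinite(rep.sn) else 1.0
            sp = rep.sp if np.isfinite(rep.sp) else 1.0
            key = ((sn + sp) / 2.0, prom, var)
            if best is None or key > best:
                best = key
                best_thr = thr
    assert best_thr is not None
    return best_thr


def compare_active_fractions(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis across per-FOV active fractions + pairwise Tukey table.

    Delegates to scipy (Kruskal-Wallis H) and statsmodels (Tukey HSD).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    h, p = stats.kruskal(*samples)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(samples)
    labels = np.concatenate([[n] * len(s) for n, s in zip(names, samples)])
    tukey = pairwise_tukeyhsd(values, labels)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"H": float(h), "p": float(p), "pairwise": pairwise}
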