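"""Whole-cell patch-clamp feature extraction.

Covers the passive-membrane test (single exponential fit of the capacitive
transient evoked by a -5 mV pulse, yielding series resistance, membrane
resistance and capacitance), the voltage-step IV protocol (peak transient
inward sodium current, peak outward and late sustained delayed-rectifier
potassium currents, and their capacitance-normalised densities), action
potential detection in current-clamp traces, and F-I curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths

__all__ = [
    "SweepSet",
    "MembraneProperties",
    "fit_capacitive_transient",
    "extract_step_currents",
    "current_density",
    "detect_aps",
    "fi_curve",
    "classify_spontaneous",
]

#: liquid-junction potential correction applied to command voltages on ingest
JUNCTION_POTENTIAL_MV = -14.0


@dataclass
class SweepSet:
    """A stack of sweeps sharing a protocol.

    ``sweeps`` is (n_sweeps, n_samples): currents in pA for voltage clamp,
    membrane potential in mV for current clamp.  ``levels`` holds the command
    step per sweep (mV or pA).  The step occupies [step_start_s,
    step_start_s + step_dur_s).
    """

    time_s: np.ndarray
    sweeps: np.ndarray
    mode: str  # "vc" or "cc"
    holding: float
    levels: np.ndarray
    step_start_s: float
    step_dur_s: float
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.levels = np.asarray(self.levels, dtype=float)
        if self.sweeps.shape != (len(self.levels), len(self.time_s)):
            raise ValueError("sweeps must be (n_levels, n_samples)")


@dataclass
class MembraneProperties:
    """Passive properties from the capacitive transient."""

    tau_s: float
    rs_mohm: float
    rm_mohm: float
    cm_pf: float

    def __post_init__(self) -> None:
        if min(self.tau_s, self.rs_mohm, self.rm_mohm, self.cm_pf) <= 0:
            raise ValueError("membrane properties must be positive")


def fit_capacitive_transient(
    time_s: np.ndarray,
    current_pa: np.ndarray,
    delta_v_mv: float = -5.0,
) -> MembraneProperties:
    """Fit I(t) = I_ss + (I_0 - I_ss) exp(-t/tau) to a membrane-test sweep.

    The sweep must start at the voltage-step onset (t = 0 at the transient
    peak).  From the fit: Rs = dV/I_0, Rm = dV/I_ss - Rs and
    Cm = tau (Rs + Rm)/(Rs Rm).  Units: mV, pA -> GOhm internally, reported
    in MOhm/pF/s.
    """
    if delta_v_mv == 0:
        raise ValueError("delta_v_mv must be nonzero")
    t = np.asarray(time_s, dtype=float)
    i = np.asarray(current_pa, dtype=float)
    i_ss0 = float(np.mean(i[int(0.8 * len(i)) :]))
    i_00 = float(i[0])
    tau0 = max((t[-1] - t[0]) / 20.0, t[1] - t[0])

    def model(t, i_ss, i_0, tau):
        return i_ss + (i_0 - i_ss) * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            model, t, i, p0=(i_ss0, i_00, tau0), maxfev=10000
        )
    except RuntimeError as err:
        raise ValueError(f"capacitive transient fit failed: {err}") from err
    i_ss, i_0, tau = popt
    if tau <= 0 or i_0 == 0:
        raise ValueError("non-decaying transient; cell flagged")
    rs_gohm = (delta_v_mv * 1e-3) / (i_0 * 1e-12) * 1e-9  # GOhm
    rm_gohm = (delta_v_mv * 1e-3) / (i_ss * 1e-12) * 1e-9 - rs_gohm
    if rs_gohm <= 0 or rm_gohm <= 0:
        raise ValueError("non-physical resistances; cell flagged")
    cm_f = tau * (rs_gohm + rm_gohm) / (rs_gohm * rm_gohm) * 1e-9
    return MembraneProperties(
        tau_s=float(tau),
        rs_mohm=float(rs_gohm * 1e3),
        rm_mohm=float(rm_gohm * 1e3),
        cm_pf=float(cm_f * 1e12),
    )


def extract_step_currents(
    sweeps: SweepSet,
    na_window_s: float = 0.010,
    kdr_window_s: float = 0.050,
    cm_pf: float | None = None,
) -> pd.DataFrame:
    """Per-step sodium and potassium currents from the IV protocol.

    The pre-step holding current is subtracted per sweep; then
    I_Na = most negative current within ``na_window_s`` of step onset,
    I_K = largest outward current over the full step,
    I_Kdr = mean current over the final ``kdr_window_s`` of the step.
    If ``cm_pf`` is given, densities (pA/pF) are included.
    """
    t = sweeps.time_s
    on = sweeps.step_start_s
    off = on + sweeps.step_dur_s
    pre = t < on
    step = (t >= on) & (t < off)
    early = (t >= on) & (t < on + na_window_s)
    late = (t >= off - kdr_window_s) & (t < off)
    rows = []
    for level, sweep in zip(sweeps.levels, sweeps.sweeps):
        baseline = sweep[pre].mean() if pre.any() else 0.0
        s = sweep - baseline
        i_na = float(s[early].min()) if early.any() else np.nan
        i_k = float(s[step].max()) if step.any() else np.nan
        i_kdr = float(s[late].mean()) if late.any() else np.nan
        rows.append((level, i_na, i_k, i_kdr))
    table = pd.DataFrame(rows, columns=["voltage_mv", "i_na_pa", "i_k_pa", "i_kdr_pa"])
    if cm_pf is not None:
        for col in ("i_na_pa", "i_k_pa", "i_kdr_pa"):
            table[col.replace("_pa", "_density_pa_pf")] = current_density(
                table[col].to_numpy(), cm_pf
            )
    return table


def current_density(current_pa: np.ndarray | float, cm_pf: float) -> np.ndarray | float:
    """Current divided by membrane capacitance (pA/pF)."""
    if cm_pf <= 0:
        raise ValueError("cm_pf must be positive")
    return np.asarray(current_pa, dtype=float) / cm_pf if np.ndim(current_pa) else float(current_pa) / cm_pf


def detect_aps(
    time_s: np.ndarray,
    voltage_mv: np.ndarray,
    min_prominence_mv: float = 20.0,
    min_height_mv: float = 0.0,
    max_width_ms: float = 60.0,
    min_interval_ms: float = 20.0,
) -> pd.DataFrame:
    """Action potentials: prominent overshooting peaks with a bounded width.

    Criteria applied in order: prominence >= 20 mV, peak height >= 0 mV
    (full reversal), half-prominence width <= 60 ms, and a minimum inter-peak
    interval of 20 ms where the earlier peak is kept.
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(voltage_mv, dtype=float)
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    peaks, props = find_peaks(v, prominence=min_prominence_mv, height=min_height_mv)
    if len(peaks) == 0:
        return pd.DataFrame(columns=["peak_time_s", "peak_mv", "prominence_mv", "width_ms"])
    widths_ms = peak_widths(v, peaks, rel_height=0.5)[0] * dt * 1e3
    keep = widths_ms <= max_width_ms
    peaks, widths_ms = peaks[keep], widths_ms[keep]
    proms = props["prominences"][keep]
    kept_idx: list[int] = []
    last_t = -np.inf
    for k, p in enumerate(peaks):
        if (t[p] - last_t) * 1e3 >= min_interval_ms:
            kept_idx.append(k)
            last_t = t[p]
    kept = np.asarray(kept_idx, dtype=int)
    return pd.DataFrame(
        {
            "peak_time_s": t[peaks[kept]],
            "peak_mv": v[peaks[kept]],
            "prominence_mv": proms[kept],
            "width_ms": widths_ms[kept],
        }
    )


def fi_curve(sweeps: SweepSet, **ap_kwargs) -> pd.DataFrame:
    """AP frequency per current step: spike count / step duration."""
    if sweeps.mode != "cc":
        raise ValueError("F-I curves need current-clamp sweeps")
    on, dur = sweeps.step_start_s, sweeps.step_dur_s
    rows = []
    for level, sweep in zip(sweeps.levels, sweeps.sweeps):
        events = detect_aps(sweeps.time_s, sweep, **ap_kwargs)
        in_step = events[
            (events["peak_time_s"] >= on) & (events["peak_time_s"] < on + dur)
        ]
        rows.append((level, len(in_step), len(in_step) / dur))
    return pd.DataFrame(rows, columns=["injected_pa", "n_aps", "frequency_hz"])


def classify_spontaneous(time_s: np.ndarray, voltage_mv: np.ndarray, **ap_kwargs) -> bool:
    """Active if at least one action potential occurs in the gap-free trace."""
    return len(detect_aps(time_s, voltage_mv, **ap_kwargs)) >= 1
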