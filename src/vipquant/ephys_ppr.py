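"""Paired-pulse ratio measurement from evoked synaptic currents.

Workflow: average the sweeps of one recording, measure the two EPSC
amplitudes relative to baseline (the second one relative to the
extrapolated decay of the first, which removes summation), form
PPR = amp2/amp1, and classify presynaptic release probability:
facilitating synapses (PPR > 1) have low release probability,
depressing ones (PPR < 1) high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SweepSet",
    "PPRResult",
    "average_sweeps",
    "measure_amplitudes",
    "compute_ppr",
    "qc_recording",
    "ppr_from_sweeps",
]


@dataclass
class SweepSet:
    """A set of equal-length voltage-clamp sweeps from one recording."""

    time: np.ndarray            # seconds, shared across sweeps
    sweeps: np.ndarray          # (n_sweeps, n_samples), pA; inward negative
    sampling_rate: float        # Hz
    stim_times: tuple[float, float]
    holding_potential: float = -70.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a 2D (n_sweeps, n_samples) array")
        if self.sweeps.shape[1] != self.time.size:
            raise ValueError("ragged sweeps: every sweep must match the time base")
        t1, t2 = self.stim_times
        if not t2 > t1:
            raise ValueError("stim_times must be strictly increasing")
        if not (self.time[0] <= t1 and t2 <= self.time[-1]):
            raise ValueError("stimulus times outside the trace")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (sweep, time_s, current_pA) for CSV export."""
        n, m = self.sweeps.shape
        return pd.DataFrame({
            "sweep": np.repeat(np.arange(n), m),
            "time_s": np.tile(self.time, n),
            "current_pA": self.sweeps.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stim_times, holding_potential=-70.0) -> "SweepSet":
        sweeps = []
        time = None
        for _, g in df.groupby("sweep", sort=True):
            t = g["time_s"].to_numpy()
            if time is None:
                time = t
            elif t.size != time.size or not np.allclose(t, time):
                raise ValueError("ragged sweeps in table")
            sweeps.append(g["current_pA"].to_numpy())
        if time is None:
            raise ValueError("empty sweep table")
        rate = 1.0 / float(np.median(np.diff(time)))
        return cls(time=time, sweeps=np.vstack(sweeps), sampling_rate=rate,
                   stim_times=tuple(stim_times), holding_potential=holding_potential)


@dataclass
class PPRResult:
    """Amplitude pair (positive magnitudes, pA) and second/first ratio."""

    amp1: float
    amp2: float
    ppr: float
    release_class: str

    def __post_init__(self) -> None:
        if self.amp1 <= 0:
            raise ValueError("amp1 must be a positive magnitude")


def average_sweeps(sweeps: SweepSet) -> np.ndarray:
    """Pointwise mean trace across the sweeps of one recording."""
    return sweeps.sweeps.mean(axis=0)


class NoEvokedResponseError(ValueError):
    """The averaged trace contains no response above the noise floor."""


def _window(time: np.ndarray, start: float, stop: float) -> slice:
    """Half-sample-tolerant index window, so the same offset from either
    stimulus selects congruent samples despite float rounding."""
    dt = float(np.median(np.diff(time)))
    i0 = int(np.searchsorted(time, start - 0.5 * dt, side="left"))
    i1 = int(np.searchsorted(time, stop + 0.5 * dt, side="right"))
    return slice(i0, i1)


def _fit_exponential_decay(t: np.ndarray, y: np.ndarray):
    """Least-squares fit of y = A exp(-t/tau) in log space; y must be > 0."""
    ly = np.log(y)
    slope, intercept = np.polyfit(t, ly, 1)
    if slope >= 0:
        # no decay detectable; fall back to a flat extrapolation
        return float(np.exp(ly.mean())), np.inf
    return float(np.exp(intercept)), float(-1.0 / slope)


def measure_amplitudes(
    mean_trace: np.ndarray,
    time: np.ndarray,
    stim_times: tuple[float, float],
    baseline_window: float = 0.05,
    peak_window: tuple[float, float] = (0.001, 0.015),
    blank: float = 0.001,
    decay_fit_start: float = 0.006,
    summation_correction: bool = True,
    smooth_ms: float = 0.3,
    noise_floor_k: float = 3.0,
    min_amplitude: float = 1.0,
) -> tuple[float, float]:
    """Measure both evoked amplitudes (positive magnitudes, pA).

    ``amp1`` is the extremum within ``peak_window`` after the first
    stimulus relative to the pre-stimulus baseline.  With
    ``summation_correction`` (default), a mono-exponential is fitted to
    the first response's decay between the pulses (starting
    ``decay_fit_start`` seconds after stimulus 1) and subtracted before
    the second extremum is taken, so residual decay of the first response
    does not contaminate ``amp2``.  The first millisecond after each
    stimulus is blanked as artifact.  A light boxcar smoothing
    (``smooth_ms``) suppresses the upward bias of picking a peak in
    noise; it rescales both amplitudes identically, leaving their ratio
    unchanged.  Raises :class:`NoEvokedResponseError` if the first
    response does not exceed ``noise_floor_k`` baseline standard
    deviations (or ``min_amplitude`` pA, whichever is larger).
    """
    trace = np.asarray(mean_trace, dtype=float)
    time = np.asarray(time, dtype=float)
    t1, t2 = stim_times
    isi = t2 - t1
    dt = float(np.median(np.diff(time)))
    if smooth_ms > 0:
        width = max(1, int(round(smooth_ms * 1e-3 / dt)))
        trace = uniform_filter1d(trace, size=width, mode="nearest")

    base_sel = _window(time, t1 - baseline_window, t1 - dt)
    if base_sel.start >= base_sel.stop:
        raise ValueError("baseline window outside trace")
    baseline = trace[base_sel].mean()
    noise = trace[base_sel].std()

    w_lo, w_hi = peak_window
    w_lo = max(w_lo, blank)
    sel1 = _window(time, t1 + w_lo, t1 + min(w_hi, isi - blank))
    if sel1.start >= sel1.stop:
        raise ValueError("first peak window outside trace")
    dev1 = trace[sel1] - baseline
    i1 = np.argmax(np.abs(dev1))
    polarity = np.sign(dev1[i1]) or 1.0
    amp1 = abs(dev1[i1])
    if amp1 < max(noise_floor_k * noise, min_amplitude):
        raise NoEvokedResponseError(
            f"first response {amp1:.2f} pA below noise floor"
        )

    sel2 = _window(time, t2 + w_lo, t2 + w_hi)
    if sel2.start >= sel2.stop or sel2.stop > time.size:
        raise ValueError("second peak window outside trace")
    if summation_correction:
        fit_sel = _window(time, t1 + decay_fit_start, t2 - dt)
        y = polarity * (trace[fit_sel] - baseline)
        ok = y > max(noise, 1e-12)
        if ok.sum() >= 5:
            a, tau = _fit_exponential_decay(time[fit_sel][ok] - t1, y[ok])
            decay = a * np.exp(-(time - t1) / tau) if np.isfinite(tau) else np.full_like(time, a)
        else:
            decay = np.zeros_like(time)
        residual = polarity * (trace - baseline) - decay
        amp2 = float(residual[sel2].max())
        amp2 = abs(amp2)
    else:
        dev2 = trace[sel2] - baseline
        amp2 = abs(dev2[np.argmax(np.abs(dev2))])
    return float(amp1), float(amp2)


def compute_ppr(amp1: float, amp2: float, moderate_band: float = 0.1) -> PPRResult:
    """PPR = amp2/amp1 with release-probability class.

    Facilitation (PPR > 1) indicates low release probability, depression
    (PPR < 1) high; a band of ±``moderate_band`` around 1 is called
    moderate.
    """
    if amp1 <= 0:
        raise ValueError("amp1 must be positive")
    ppr = amp2 / amp1
    if abs(ppr - 1.0) <= moderate_band:
        cls = "moderate"
    elif ppr > 1.0:
        cls = "low"
    else:
        cls = "high"
    return PPRResult(amp1=float(amp1), amp2=float(amp2), ppr=float(ppr), release_class=cls)


def qc_recording(access_resistance: float, whole_cell_capacitance: float) -> bool:
    """Recording quality gate: fail (False) iff access resistance exceeds
    40 MΩ or whole-cell capacitance is below 4 pF."""
    for v in (access_resistance, whole_cell_capacitance):
        if v is None or not np.isfinite(v):
            raise ValueError("QC values must be present and finite")
    return not (access_resistance > 40.0 or whole_cell_capacitance < 4.0)


def ppr_from_sweeps(sweeps: SweepSet, summation_correction: bool = True,
                    moderate_band: float = 0.1, **kwargs) -> PPRResult:
    """Average the recording's sweeps, measure both amplitudes, and
    return the paired-pulse ratio."""
    trace = average_sweeps(sweeps)
    amp1, amp2 = measure_amplitudes(
        trace, sweeps.time, sweeps.stim_times,
        summation_correction=summation_correction, **kwargs,
    )
    return compute_ppr(amp1, amp2, moderate_band=moderate_band)
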