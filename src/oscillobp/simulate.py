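"""Forward simulation of cuff pressure oscillations during a deflation run.

The coupled model: arterial pressure follows a fixed Fourier waveform; the
artery segment volume responds instantaneously to transmural pressure
through the bi-exponential law; the sealed cuff converts the artery's
volume pulses into pressure oscillations through its Boyle's-law
compliance, superimposed on the steady bleed.  The cuff-pressure rate

    dP/dt = -r + (P0 + 760 - r*t)/V0 * dVa/dt

is integrated with the forward Euler method.  The transmural pressure that
drives the artery uses the smooth deflation ramp ``P0 - r*t``: the artery
"feels" the prevailing mean difference, and the small cuff oscillations it
generates are neglected in its own forcing.  With that closure the
right-hand side depends on time only, so the Euler recursion reduces to a
cumulative sum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .models import (
    ATM_MMHG,
    ArteryModel,
    CuffModel,
    PressureWaveform,
    artery_compliance,
    waveform_derivative,
    waveform_pressure,
)

__all__ = [
    "Recording",
    "Envelope",
    "simulate_run",
    "highpass_filter",
    "extract_envelope",
    "AMP_METHODS",
]

logger = logging.getLogger(__name__)

#: Supported per-beat amplitude definitions for :func:`extract_envelope`.
#:
#: ``"ptp"``        peak-to-trough of the filtered oscillation (default; the
#:                  max-minus-min per heartbeat definition).
#: ``"harmonic"``   peak-to-trough of the filtered oscillation after
#:                  projection onto harmonics of the beat frequency;
#:                  scale-equivariant, so semi-log slopes and the normalized
#:                  envelope are unchanged, but broadband noise is rejected.
#: ``"area"``       mean absolute filtered oscillation per beat (pulse-area
#:                  envelope, up to the fixed beat duration factor).
#: ``"cuff_range"`` max-minus-min of the *raw* cuff pressure per heartbeat,
#:                  which includes the deflation ramp's fall across the beat;
#:                  this is the figure-style envelope.
AMP_METHODS = ("ptp", "harmonic", "area", "cuff_range")


@dataclass
class Recording:
    """Uniformly sampled cuff-pressure record of one deflation run.

    ``osc`` is the high-pass-filtered oscillation signal; it is NaN within
    half a beat period of either end of the record (and everywhere until
    :func:`highpass_filter` has been applied).
    """

    t: np.ndarray
    P: np.ndarray
    osc: np.ndarray | None = None
    sample_rate: float = 2000.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.t.shape != self.P.shape or self.t.ndim != 1:
            raise ValueError("t and P must be 1-D arrays of equal length")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("t must be uniformly spaced at 1/sample_rate")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def beat_period(self) -> float:
        """Beat period from metadata; raises if the heart rate is unknown."""
        f = self.meta.get("f")
        if f is None:
            raise ValueError("recording metadata has no cardiac frequency 'f'")
        return 1.0 / float(f)

    def with_oscillations(self, osc: np.ndarray) -> "Recording":
        return replace(self, osc=np.asarray(osc, dtype=float))


@dataclass
class Envelope:
    """Beat-wise oscillation amplitude envelope.

    One row per complete, filter-valid heartbeat: a representative cuff
    pressure and the oscillation amplitude for that beat.  Pressures
    decrease monotonically across beats during deflation.
    """

    pressures: np.ndarray
    amplitudes: np.ndarray
    beat_indices: np.ndarray

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.beat_indices = np.asarray(self.beat_indices, dtype=int)
        if not (self.pressures.shape == self.amplitudes.shape == self.beat_indices.shape):
            raise ValueError("envelope arrays must have equal shape")

    def __len__(self) -> int:
        return self.pressures.size

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.amplitudes))

    @property
    def peak_amp(self) -> float:
        """Maximum oscillation amplitude (mmHg)."""
        return float(self.amplitudes[self.peak_index])

    @property
    def P_max(self) -> float:
        """Cuff pressure at the envelope peak (mmHg)."""
        return float(self.pressures[self.peak_index])

    def rising(self) -> tuple[np.ndarray, np.ndarray]:
        """(pressures, amplitudes) on the rising side, peak included."""
        i = self.peak_index
        return self.pressures[: i + 1], self.amplitudes[: i + 1]

    def falling(self) -> tuple[np.ndarray, np.ndarray]:
        """(pressures, amplitudes) on the falling side, peak included."""
        i = self.peak_index
        return self.pressures[i:], self.amplitudes[i:]


def simulate_run(
    artery: ArteryModel,
    cuff: CuffModel,
    waveform: PressureWaveform,
    duration: float = 40.0,
    dt: float = 5e-4,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Recording:
    """Integrate one cuff deflation run and return the pressure recording.

    Parameters
    ----------
    artery, cuff, waveform :
        Physiologic models.  ``artery.Va0 = 0`` removes the artery term and
        yields the exact deflation line ``P0 - r*t``.
    duration : float
        Run length in seconds (default 40 s, i.e. 150 mmHg down to 30 mmHg
        at 3 mmHg/s).
    dt : float
        Euler step, seconds.  Must resolve the beat: ``dt <= 1/(20*f)``.
    noise_sd : float
        Optional additive white Gaussian measurement noise (mmHg) applied
        to the stored pressure samples only, never to the dynamics.
    seed : int, optional
        Seed for the noise generator; identical seeds give identical
        recordings.

    Returns
    -------
    Recording
        With ``meta`` carrying every scenario parameter (including the
        deflation schedule, used downstream as the beat pressure
        coordinate).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0 or dt > 1.0 / (20.0 * waveform.f):
        raise ValueError(f"dt={dt} must lie in (0, 1/(20 f)] = (0, {1.0 / (20.0 * waveform.f):g}]")

    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt

    ramp = cuff.P0 - cuff.r * t
    Pa = waveform_pressure(t, waveform)
    dPa = waveform_derivative(t, waveform)
    Pt = Pa - ramp
    dVa = artery_compliance(Pt, artery) * (dPa + cuff.r)
    dPdt = -cuff.r + (cuff.P0 + ATM_MMHG - cuff.r * t) / cuff.V0 * dVa

    # forward Euler; the RHS is a pure function of t, so the recursion is a
    # cumulative sum with P(0) = P0
    P = cuff.P0 + np.concatenate(([0.0], np.cumsum(dPdt[:-1]) * dt))

    if not np.all(np.isfinite(P)):
        raise FloatingPointError("cuff pressure integration diverged (non-finite values)")
    neg = np.nonzero(P <= 0.0)[0]
    if neg.size:
        warnings.warn(
            f"cuff pressure reached zero at t={t[neg[0]]:.2f} s; run truncated",
            RuntimeWarning,
            stacklevel=2,
        )
        t, P = t[: neg[0]], P[: neg[0]]

    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        P = P + rng.normal(0.0, noise_sd, size=P.size)

    meta = {
        "a": artery.a,
        "b": artery.b,
        "Va0": artery.Va0,
        "V0": cuff.V0,
        "P0": cuff.P0,
        "r": cuff.r,
        "SBP": waveform.SBP,
        "DBP": waveform.DBP,
        "f": waveform.f,
        "duration": duration,
        "dt": dt,
        "noise_sd": noise_sd,
        "seed": seed,
        "schedule": "linear",
    }
    return Recording(t=t, P=P, sample_rate=1.0 / dt, meta=meta)


def highpass_filter(rec: Recording, beat_period: float | None = None) -> np.ndarray:
    """Extract oscillations by subtracting each sample from its beat-mean.

    ``osc(t) = mean(P over [t - dT/2, t + dT/2]) - P(t)`` for beat period
    ``dT``; a centered mean over exactly one beat period removes both the
    cardiogenic component's window-average and any linear trend, leaving
    (minus) the oscillation.  Samples within half a beat period of either
    end of the record are NaN.  The discrete mean is trapezoidal so that an
    exactly periodic signal averages to zero over its period.
    """
    if beat_period is None:
        beat_period = rec.beat_period()
    dts = rec.dt
    h = int(round(beat_period / (2.0 * dts)))
    n = rec.P.size
    if 2 * h + 1 > n:
        raise ValueError(
            f"filter window ({2 * h + 1} samples) exceeds record length ({n} samples)"
        )
    if abs(2 * h * dts - beat_period) > 0.5 * dts:
        logger.warning(
            "beat period %.4g s is not an even multiple of the sample interval; "
            "filter window truncated to %.4g s",
            beat_period,
            2 * h * dts,
        )

    P = rec.P
    cs = np.concatenate(([0.0], np.cumsum(P)))
    osc = np.full(n, np.nan)
    idx = np.arange(h, n - h)
    # trapezoidal sliding sum over the 2h+1 samples centered on each index
    sliding = cs[idx + h + 1] - cs[idx - h] - 0.5 * (P[idx - h] + P[idx + h])
    osc[idx] = sliding / (2.0 * h) - P[idx]
    return osc


def _harmonic_ptp(o: np.ndarray, n_harmonics: int) -> float:
    # keep DC..n_harmonics multiples of the beat fundamental (the window is
    # exactly one beat long, so the fundamental is FFT bin 1)
    spec = np.fft.rfft(o)
    spec[n_harmonics + 1 :] = 0.0
    rec = np.fft.irfft(spec, n=o.size)
    return float(rec.max() - rec.min())


def extract_envelope(
    rec: Recording,
    beat_period: float | None = None,
    amp_method: str = "ptp",
    n_harmonics: int = 8,
    pressure_axis: str = "auto",
    align: str = "auto",
) -> Envelope:
    """Segment a recording into beats and measure the amplitude envelope.

    Beats are consecutive non-overlapping windows of one beat period.  For
    simulated recordings the windows are aligned to the known waveform phase
    (``t = 0`` starts a beat); for external data the first oscillation
    zero-crossing anchors the grid (``align="zero_crossings"``), subject to
    a minimum separation of half a beat.  Beats containing filter-invalid
    (NaN) samples are dropped.

    Parameters
    ----------
    amp_method : str
        One of :data:`AMP_METHODS`.  Default ``"ptp"``: oscillation
        max-minus-min per heartbeat.
    pressure_axis : str
        Representative beat pressure: ``"schedule"`` uses the nominal
        deflation ramp at the beat's mid-time, ``"measured"`` the per-beat
        mean of the recorded pressure, ``"auto"`` (default) the schedule
        when the recording metadata carries one, else measured.  The
        constant-rate vent in the model lets the recorded pressure
        accumulate the artery's net refill volume (a few mmHg over a run) —
        an artifact a real regulated bleed valve does not show — so the
        schedule is the faithful coordinate for simulated runs.
    """
    if amp_method not in AMP_METHODS:
        raise ValueError(f"amp_method must be one of {AMP_METHODS}, got {amp_method!r}")
    if beat_period is None:
        beat_period = rec.beat_period()
    osc = rec.osc if rec.osc is not None else highpass_filter(rec, beat_period)

    t0 = float(rec.t[0])
    offset = 0.0
    if align == "zero_crossings" or (align == "auto" and "schedule" not in rec.meta):
        offset = _first_crossing_offset(rec.t, osc, beat_period)
    elif align not in ("auto", "phase"):
        raise ValueError(f"unknown align mode {align!r}")

    dts = rec.dt
    span = rec.t[-1] - t0 - offset
    n_beats = int(np.floor(span / beat_period + 1e-9))
    if n_beats < 3:
        raise ValueError(f"need at least 3 complete beats, record holds {max(n_beats, 0)}")

    use_schedule = pressure_axis == "schedule" or (
        pressure_axis == "auto" and "schedule" in rec.meta
    )
    if pressure_axis not in ("auto", "schedule", "measured"):
        raise ValueError(f"unknown pressure_axis {pressure_axis!r}")
    if use_schedule and "P0" not in rec.meta:
        raise ValueError("pressure_axis='schedule' needs P0 and r in recording metadata")

    pressures, amps, kept = [], [], []
    for k in range(n_beats):
        i0 = int(round((offset + k * beat_period) / dts))
        i1 = int(round((offset + (k + 1) * beat_period) / dts))
        o = osc[i0:i1]
        if o.size == 0 or np.any(np.isnan(o)):
            continue
        if amp_method == "ptp":
            amp = float(o.max() - o.min())
        elif amp_method == "harmonic":
            amp = _harmonic_ptp(o, n_harmonics)
        elif amp_method == "area":
            amp = float(np.mean(np.abs(o)))
        else:  # cuff_range
            seg = rec.P[i0:i1]
            amp = float(seg.max() - seg.min())
        if use_schedule:
            p_beat = rec.meta["P0"] - rec.meta["r"] * float(np.mean(rec.t[i0:i1]))
        else:
            p_beat = float(np.mean(rec.P[i0:i1]))
        pressures.append(p_beat)
        amps.append(amp)
        kept.append(k)

    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} usable beats after filtering; need at least 3")
    logger.info("envelope: %d beats kept of %d segmented", len(kept), n_beats)
    return Envelope(
        pressures=np.array(pressures),
        amplitudes=np.array(amps),
        beat_indices=np.array(kept),
    )


def _first_crossing_offset(t: np.ndarray, osc: np.ndarray, beat_period: float) -> float:
    """Offset (s) of the first upward oscillation zero-crossing.

    Crossings closer than half a beat to the previous accepted one are
    rejected as noise re-crossings; only the first anchor is needed since
    the beat grid is then laid out at the known period.
    """
    valid = np.nonzero(~np.isnan(osc))[0]
    if valid.size < 2:
        raise ValueError("no filtered samples available for zero-crossing alignment")
    o = osc[valid]
    up = np.nonzero((o[:-1] <= 0.0) & (o[1:] > 0.0))[0]
    if up.size == 0:
        raise ValueError("no oscillation zero-crossings found")
    i = valid[up[0]]
    return float(t[i] - t[0])
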