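"""Band power extraction: zero-phase band-pass filtering, Hilbert power
envelopes, per-interval mean power and relative power (ERD/ERS).

The pipeline filters the full-length record into the four analysis bands,
squares the magnitude of the analytic signal to obtain an instantaneous
band-power envelope, averages it inside each protocol interval, and expresses
each non-baseline condition as a percent change from the Rest1 baseline:

    RPW = 100 * (P_condition - P_Rest1) / P_Rest1

Negative RPW is event-related desynchronization, positive is synchronization.
Filtering and the Hilbert transform run on the whole record before
segmentation so interval means carry no per-segment edge transients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len
from scipy.signal import butter, hilbert, sosfiltfilt

from .core import BANDS, BASELINE, CONDITIONS, INTERVALS
from .io_seg import IntervalAnnotation, Recording

POWER_COLUMNS = ["subject_id", "electrode", "band", "interval", "power"]
RPW_COLUMNS = ["subject_id", "electrode", "band", "condition", "rpw"]


def bandpass(
    signal: np.ndarray, band: tuple[float, float], fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward filtering doubles the effective order and cancels phase,
    so envelope timing is unaffected by the filter.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band edges ({lo}, {hi})")
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def power_envelope(filtered: np.ndarray, mode: str = "power") -> np.ndarray:
    """Hilbert envelope of a band-limited signal, along the last axis.

    ``mode="power"`` (default) returns the squared magnitude of the analytic
    signal — instantaneous band power; ``mode="amplitude"`` returns the
    magnitude itself. The FFT is padded to a fast length and truncated back.
    """
    x = np.asarray(filtered, dtype=float)
    n = x.shape[-1]
    analytic = hilbert(x, N=next_fast_len(n), axis=-1)[..., :n]
    env = np.abs(analytic)
    if mode == "power":
        return env**2
    if mode == "amplitude":
        return env
    raise ValueError(f"unknown envelope mode {mode!r}")


def interval_mean_power(
    envelope: np.ndarray, interval: IntervalAnnotation
) -> np.ndarray:
    """Mean of the power envelope over [start_sample, end_sample)."""
    n = np.asarray(envelope).shape[-1]
    if interval.start_sample < 0 or interval.end_sample > n:
        raise ValueError(f"interval {interval.name} outside envelope bounds")
    seg = np.asarray(envelope)[..., interval.start_sample:interval.end_sample]
    if seg.shape[-1] == 0:
        raise ValueError(f"interval {interval.name} is empty")
    return seg.mean(axis=-1)


def compute_power_table(
    recordings: list[Recording] | Recording,
    bands: dict[str, tuple[float, float]] | None = None,
    order: int = 4,
    mode: str = "power",
) -> pd.DataFrame:
    """Mean band power per subject x electrode x band x interval.

    Returns a tidy frame with columns ``subject_id, electrode, band,
    interval, power`` (uV^2, or uV for amplitude mode), complete over the
    19 electrodes, the four bands and the eight intervals.
    """
    if isinstance(recordings, Recording):
        recordings = [recordings]
    bands = BANDS if bands is None else bands
    rows = []
    for rec in recordings:
        sig = rec.canonical().signal
        labels = list(rec.canonical().channel_labels)
        for band_name, edges in bands.items():
            filt = bandpass(sig, edges, rec.fs, order=order)
            env = power_envelope(filt, mode=mode)
            for ann in rec.annotations:
                means = interval_mean_power(env, ann)
                for ch, m in zip(labels, means):
                    rows.append((rec.subject_id, ch, band_name, ann.name, float(m)))
    df = pd.DataFrame(rows, columns=POWER_COLUMNS)
    return df


def compute_rpw(power: pd.DataFrame) -> pd.DataFrame:
    """Relative mean power: percent change of each condition vs. Rest1.

    Input is a tidy power table; output is tidy with columns ``subject_id,
    electrode, band, condition, rpw``, covering the seven non-baseline
    conditions. A nonpositive baseline cell is a hard error (it would make
    the percent change undefined).
    """
    missing = set(POWER_COLUMNS) - set(power.columns)
    if missing:
        raise ValueError(f"power table missing columns {sorted(missing)}")
    wide = power.pivot_table(
        index=["subject_id", "electrode", "band"], columns="interval",
        values="power", aggfunc="first",
    )
    absent = [i for i in INTERVALS if i not in wide.columns]
    if absent:
        raise ValueError(f"power table missing interval {absent[0]!r}")
    if wide.isna().any().any():
        raise ValueError("power table has missing cells")
    base = wide[BASELINE]
    bad = base[base <= 0]
    if len(bad):
        sid, ele, band = bad.index[0]
        raise ValueError(
            f"nonpositive baseline power for subject {sid}, electrode {ele}, "
            f"band {band}"
        )
    rel = wide[list(CONDITIONS)].sub(base, axis=0).div(base, axis=0) * 100.0
    out = (
        rel.reset_index()
        .melt(id_vars=["subject_id", "electrode", "band"],
              var_name="condition", value_name="rpw")
    )
    return out[RPW_COLUMNS]


def rpw_wide(rpw: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy RPW table to subjects x (electrode, band, condition)."""
    return rpw.pivot_table(
        index="subject_id", columns=["electrode", "band", "condition"],
        values="rpw", aggfunc="first",
    )
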