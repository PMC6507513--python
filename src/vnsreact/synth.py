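"""Synthetic labelled cohorts with the reactivity structure the analysis
assumes.

The generator emulates the qualitative group differences the method is built
to detect: responders keep (or increase) alpha power under photic
stimulation and hyperventilation and show gamma synchronization, while
non-responders desynchronize in both bands and stay desynchronized in the
closing rest periods; both groups share the Berger alpha blockade on eye
opening. Each planted effect is a mean RPW shift (percent) for one band x
condition, applied to a region or globally, with a per-subject random
effect controlling between-subject spread.

Two output modes:

* ``rpw_table`` — draw the RPW table directly: per cell, the sum of
  applicable effect means and subject random effects, plus i.i.d.
  cell-level noise, truncated at -100 %;
* ``raw_eeg`` — synthesize full-protocol 19-channel recordings: per channel,
  pink background noise plus one narrowband noise carrier per band whose
  amplitude in each interval is scaled by sqrt(1 + RPW_target/100) relative
  to Rest1, so the band-power pipeline recovers the planted targets. In raw
  mode cell-level measurement noise is not added to the targets — it arises
  naturally from envelope estimation on finite data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    BAND_NAMES,
    BANDS,
    CHANNELS,
    CONDITIONS,
    INTERVAL_DURATIONS_S,
    INTERVALS,
    NONRESPONDER,
    REGIONS,
    RESPONDER,
)
from .io_seg import IntervalAnnotation, Recording
from .spectral import RPW_COLUMNS


@dataclass(frozen=True)
class EffectSpec:
    """One planted band x condition RPW shift.

    ``region`` is an anatomical group name or "global" (all 19 electrodes);
    ``group`` is Responder, NonResponder or "both". ``mean`` is the shift in
    percent RPW; ``sd`` the between-subject standard deviation of the
    subject-level random effect riding on it.
    """

    band: str
    condition: str
    mean: float
    sd: float = 0.0
    region: str = "global"
    group: str = "both"

    def __post_init__(self):
        if self.band not in BAND_NAMES:
            raise ValueError(f"unknown band {self.band!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"effect condition must be a non-baseline condition, "
                f"got {self.condition!r}"
            )
        if self.sd < 0:
            raise ValueError("effect sd must be >= 0")
        if self.region != "global" and self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.group not in (RESPONDER, NONRESPONDER, "both"):
            raise ValueError(f"unknown group {self.group!r}")

    def electrodes(self) -> tuple[str, ...]:
        return CHANNELS if self.region == "global" else REGIONS[self.region]


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings. ``seed`` is mandatory."""

    seed: int
    n_responders: int = 35
    n_nonresponders: int = 25
    effects: list[EffectSpec] = field(default_factory=list)
    noise_sd: float = 10.0  # cell-level measurement noise, percent RPW
    baseline_power: dict[str, float] = field(
        default_factory=lambda: {"theta": 20.0, "alpha": 30.0,
                                 "beta": 10.0, "gamma": 5.0})  # uV^2
    background_rms: float = 2.0  # broadband pink-noise RMS, uV (raw mode)
    durations_s: dict[str, float] = field(
        default_factory=lambda: dict(INTERVAL_DURATIONS_S))
    fs: float = 128.0
    mode: str = "rpw_table"
    id_prefix: str = "S"

    def __post_init__(self):
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise ValueError("need at least 2 subjects per class")
        if self.mode not in ("rpw_table", "raw_eeg"):
            raise ValueError(f"unknown mode {self.mode!r}")


def default_config(seed: int, mode: str = "rpw_table") -> SyntheticConfig:
    """The reference study conditions: a 35/25 responder/non-responder cohort
    with the canonical protocol and the qualitative alpha/gamma reactivity
    pattern. Effect magnitudes are generator defaults, not measured values.
    """
    sd = 25.0
    effects = [
        # responders: preserved alpha under PS, strong alpha increase in HV,
        # gamma synchronization under both activations
        EffectSpec("alpha", "PS", 0.0, sd, group=RESPONDER),
        EffectSpec("alpha", "HV", 40.0, sd, group=RESPONDER),
        EffectSpec("gamma", "PS", 15.0, sd, group=RESPONDER),
        EffectSpec("gamma", "HV", 20.0, sd, group=RESPONDER),
        # non-responders: desynchronization during the activations that
        # persists into the final rest
        EffectSpec("alpha", "PS", -25.0, sd, group=NONRESPONDER),
        EffectSpec("alpha", "Rest4", -15.0, sd, group=NONRESPONDER),
        EffectSpec("gamma", "PS", -10.0, sd, group=NONRESPONDER),
        EffectSpec("gamma", "HV", -10.0, sd, group=NONRESPONDER),
        # Berger effect: alpha blockade on eye opening, equal in both groups
        EffectSpec("alpha", "OpenClose1", -50.0, sd, group="both"),
        EffectSpec("alpha", "OpenClose2", -50.0, sd, group="both"),
    ]
    return SyntheticConfig(seed=seed, effects=effects, mode=mode)


def null_config(seed: int, n_responders: int = 35, n_nonresponders: int = 25,
                mode: str = "rpw_table") -> SyntheticConfig:
    """A zero-effect cohort: labels carry no signal (global null)."""
    cfg = default_config(seed, mode=mode)
    return replace(cfg, effects=[], n_responders=n_responders,
                   n_nonresponders=n_nonresponders)


def planted_differential_cells(config: SyntheticConfig) -> set[tuple[str, str]]:
    """Band x condition cells where the two groups' planted means differ."""
    means: dict[tuple[str, str], dict[str, float]] = {}
    for eff in config.effects:
        groups = (RESPONDER, NONRESPONDER) if eff.group == "both" else (eff.group,)
        for g in groups:
            cell = means.setdefault((eff.band, eff.condition),
                                    {RESPONDER: 0.0, NONRESPONDER: 0.0})
            cell[g] += eff.mean
    return {cell for cell, m in means.items()
            if m[RESPONDER] != m[NONRESPONDER]}


def _subject_ids_and_labels(config: SyntheticConfig):
    ids, labels = [], {}
    for i in range(config.n_responders):
        sid = f"{config.id_prefix}R{i + 1:03d}"
        ids.append(sid)
        labels[sid] = RESPONDER
    for i in range(config.n_nonresponders):
        sid = f"{config.id_prefix}N{i + 1:03d}"
        ids.append(sid)
        labels[sid] = NONRESPONDER
    return ids, labels


_E_IDX = {e: i for i, e in enumerate(CHANNELS)}
_B_IDX = {b: i for i, b in enumerate(BAND_NAMES)}
_C_IDX = {c: i for i, c in enumerate(CONDITIONS)}


def _subject_target(config: SyntheticConfig, group: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Noiseless per-cell RPW targets (19 x 4 x 7) for one subject."""
    t = np.zeros((len(CHANNELS), len(BAND_NAMES), len(CONDITIONS)))
    for eff in config.effects:
        if eff.group != "both" and eff.group != group:
            continue
        u = rng.normal(0.0, eff.sd) if eff.sd > 0 else 0.0
        ei = [_E_IDX[e] for e in eff.electrodes()]
        t[ei, _B_IDX[eff.band], _C_IDX[eff.condition]] += eff.mean + u
    return t


def _targets_to_frame(sid: str, target: np.ndarray) -> pd.DataFrame:
    e, b, c = np.meshgrid(np.arange(len(CHANNELS)), np.arange(len(BAND_NAMES)),
                          np.arange(len(CONDITIONS)), indexing="ij")
    return pd.DataFrame({
        "subject_id": sid,
        "electrode": np.array(CHANNELS)[e.ravel()],
        "band": np.array(BAND_NAMES)[b.ravel()],
        "condition": np.array(CONDITIONS)[c.ravel()],
        "rpw": target.ravel(),
    })


def generate_rpw_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Draw a labelled RPW table directly from the effect model."""
    rng = np.random.default_rng(config.seed)
    ids, labels = _subject_ids_and_labels(config)
    frames = []
    for sid in ids:
        target = _subject_target(config, labels[sid], rng)
        target = target + rng.normal(0.0, config.noise_sd, size=target.shape)
        frames.append(_targets_to_frame(sid, np.maximum(target, -100.0)))
    rpw = pd.concat(frames, ignore_index=True)[RPW_COLUMNS]
    return rpw, labels


# ---------------------------------------------------------------------------
# raw-EEG mode


def _interval_slices(config: SyntheticConfig) -> list[tuple[str, int, int]]:
    fs = config.fs
    out, cursor = [], 0
    for name in INTERVALS:
        n = int(round(config.durations_s[name] * fs))
        out.append((name, cursor, cursor + n))
        cursor += n
    return out


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-power background noise (flat below 0.5 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(f, 0.5))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def generate_raw_cohort(
    config: SyntheticConfig,
    return_targets: bool = False,
):
    """Synthesize full-protocol recordings realizing the planted RPW targets.

    Each band's oscillator is white noise confined to the band in the
    frequency domain (so the Hilbert envelope is non-degenerate and nothing
    leaks into neighbouring analysis bands), RMS-normalized per interval,
    and amplitude-scaled by sqrt(1 + RPW_target/100) against Rest1. Targets
    are truncated at -99 % so every interval keeps nonzero oscillatory power.

    With ``return_targets=True`` also returns the realized per-subject RPW
    targets (tidy frame, same layout as the analyzer's RPW table) so
    parameter-recovery checks can compare against exactly what was planted,
    subject random effects included.
    """
    if config.mode != "raw_eeg":
        raise ValueError("generate_raw_cohort requires mode='raw_eeg'")
    rng = np.random.default_rng(config.seed)
    ids, labels = _subject_ids_and_labels(config)
    slices = _interval_slices(config)
    n_total = slices[-1][2]
    fs = config.fs
    freqs = np.fft.rfftfreq(n_total, d=1.0 / fs)
    band_mask = {b: (freqs >= BANDS[b][0]) & (freqs <= BANDS[b][1])
                 for b in BAND_NAMES}
    # narrowband carrier variance -> mean squared Hilbert envelope is 2 sigma^2
    sigma = {b: np.sqrt(config.baseline_power[b] / 2.0) for b in BAND_NAMES}

    recordings, target_frames = [], []
    for sid in ids:
        target = np.maximum(_subject_target(config, labels[sid], rng), -99.0)
        target_frames.append(_targets_to_frame(sid, target))
        signal = np.empty((len(CHANNELS), n_total))
        for ci in range(len(CHANNELS)):
            x = config.background_rms * _pink_noise(n_total, fs, rng)
            for bi, band in enumerate(BAND_NAMES):
                spec = np.fft.rfft(rng.standard_normal(n_total))
                carrier = np.fft.irfft(spec * band_mask[band], n=n_total)
                for name, s0, s1 in slices:
                    seg = carrier[s0:s1]
                    rms = seg.std()
                    if name == "Rest1":
                        amp = sigma[band]
                    else:
                        r = target[ci, bi, _C_IDX[name]]
                        amp = sigma[band] * np.sqrt(1.0 + r / 100.0)
                    x[s0:s1] += seg * (amp / max(rms, 1e-12))
            signal[ci] = x
        annotations = [IntervalAnnotation(name, s0, s1) for name, s0, s1 in slices]
        recordings.append(Recording(
            subject_id=sid, channel_labels=list(CHANNELS), fs=fs,
            signal=signal, annotations=annotations,
        ))
    if return_targets:
        targets = pd.concat(target_frames, ignore_index=True)[RPW_COLUMNS]
        return recordings, labels, targets
    return recordings, labels
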