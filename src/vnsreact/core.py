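"""Shared vocabulary of the recording protocol and montage.

The analysis operates on 20-minute routine pre-operative EEG sessions
recorded with the 19 scalp electrodes of the international 10-20 system,
segmented into eight fixed clinical conditions (rest, eyes opening/closing,
intermittent photic stimulation, hyperventilation). Everything downstream
indexes into the canonical orderings defined here.
"""

from __future__ import annotations

# The 19 canonical 10-20 scalp electrodes, in conventional anterior-to-posterior
# listing order. Extra channels of the acquisition system are ignored.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Modern 10-10 names mapped back to the classic 10-20 temporal labels.
CHANNEL_ALIASES: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

# The eight protocol intervals in recording order, with canonical durations
# in seconds: 2 min rest, 10 s eyes open/close, 10 s rest, 2.5 min photic
# stimulation, 4 min hyperventilation, 10 s eyes open/close, 10 s rest,
# 2 min rest.
INTERVALS: tuple[str, ...] = (
    "Rest1", "OpenClose1", "Rest2", "PS", "HV", "OpenClose2", "Rest3", "Rest4",
)
INTERVAL_DURATIONS_S: dict[str, float] = {
    "Rest1": 120.0,
    "OpenClose1": 10.0,
    "Rest2": 10.0,
    "PS": 150.0,
    "HV": 240.0,
    "OpenClose2": 10.0,
    "Rest3": 10.0,
    "Rest4": 120.0,
}

BASELINE = "Rest1"
# The seven non-baseline conditions for which relative power is computed.
CONDITIONS: tuple[str, ...] = tuple(i for i in INTERVALS if i != BASELINE)

# Analysis frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.5),
    "alpha": (8.0, 12.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 45.0),
}
BAND_NAMES: tuple[str, ...] = tuple(BANDS)

# Seven anatomical electrode groups used for the grouped feature space.
# Midline electrodes (Fz, Pz) deliberately belong to both hemispheric groups.
REGIONS: dict[str, tuple[str, ...]] = {
    "left_frontal": ("Fp1", "F3", "Fz"),
    "right_frontal": ("Fp2", "F4", "Fz"),
    "left_anterotemporal": ("F7", "T3"),
    "right_anterotemporal": ("F8", "T4"),
    "central": ("C3", "Cz", "C4"),
    "left_posterior": ("P3", "Pz", "T5", "O1"),
    "right_posterior": ("P4", "Pz", "T6", "O2"),
}
REGION_NAMES: tuple[str, ...] = tuple(REGIONS)

RESPONDER = "Responder"
NONRESPONDER = "NonResponder"
LABELS = (RESPONDER, NONRESPONDER)

CANONICAL_FS = 128.0
# Hard floor on the sampling rate: Nyquist for the 45 Hz upper band edge,
# with the same small headroom the canonical 128 Hz provides over 2 x 45.
MIN_FS = 91.0


def protocol_total_seconds() -> float:
    return sum(INTERVAL_DURATIONS_S.values())


def encode_labels(labels) -> "list[int]":
    """Map class labels to 1 (Responder, the positive class) / 0."""
    out = []
    for lab in labels:
        if lab not in LABELS:
            raise ValueError(f"unknown class label {lab!r}")
        out.append(1 if lab == RESPONDER else 0)
    return out
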