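"""Reading, validating and segmenting annotated protocol EEG recordings.

A :class:`Recording` is one subject's multichannel scalp EEG (microvolts)
plus the eight protocol interval annotations. Recordings are read from EDF
files via MNE; interval annotations come either from a sidecar TSV
(``subject_id, interval, onset_s, duration_s``) or from annotations embedded
in the file. Sample coordinates are 0-based half-open ``[start, end)``;
second-valued onsets are converted by rounding half-up, which avoids
cumulative float drift over a 20-minute record.

A minimal 16-bit EDF writer is included so synthetic fixture cohorts can be
round-tripped through the same reader used for real exports.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CHANNEL_ALIASES,
    CHANNELS,
    INTERVALS,
    LABELS,
    MIN_FS,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalAnnotation:
    """One protocol interval, in 0-based half-open sample coordinates."""

    name: str
    start_sample: int
    end_sample: int

    def __post_init__(self):
        if self.name not in INTERVALS:
            raise ValueError(f"unknown interval name {self.name!r}")
        if self.end_sample <= self.start_sample:
            raise ValueError(
                f"interval {self.name}: end_sample {self.end_sample} must exceed "
                f"start_sample {self.start_sample}"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class Recording:
    """One subject's annotated multichannel EEG.

    ``signal`` is channels x samples in microvolts, rows aligned with
    ``channel_labels``. All 19 canonical 10-20 electrodes must be present.
    """

    subject_id: str
    channel_labels: list[str]
    fs: float
    signal: np.ndarray
    annotations: list[IntervalAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("signal must be channels x samples, aligned with labels")
        missing = [ch for ch in CHANNELS if ch not in self.channel_labels]
        if missing:
            raise ValueError(f"missing channel {missing[0]}")
        if self.fs < MIN_FS:
            raise ValueError(
                f"sampling rate {self.fs} Hz below the {MIN_FS} Hz floor required "
                "for the 31-45 Hz band"
            )
        self._check_annotations()

    def _check_annotations(self):
        names = [a.name for a in self.annotations]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate interval annotation {dup!r}")
        if set(names) != set(INTERVALS):
            missing = sorted(set(INTERVALS) - set(names))
            raise ValueError(f"missing interval annotation {missing[0]!r}")
        ordered = sorted(self.annotations, key=lambda a: a.start_sample)
        if [a.name for a in ordered] != list(INTERVALS):
            raise ValueError("interval annotations not in protocol order")
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start_sample < prev.end_sample:
                raise ValueError(
                    f"annotations {prev.name} and {nxt.name} overlap"
                )
        if ordered[-1].end_sample > self.signal.shape[1]:
            raise ValueError("annotation extends past end of signal")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.signal[self.channel_labels.index(label)]

    def canonical(self) -> "Recording":
        """Return a copy restricted to the 19 canonical channels, in order."""
        idx = [self.channel_labels.index(ch) for ch in CHANNELS]
        return Recording(
            subject_id=self.subject_id,
            channel_labels=list(CHANNELS),
            fs=self.fs,
            signal=self.signal[idx],
            annotations=list(self.annotations),
        )


def _normalize_label(raw_label: str) -> str | None:
    """Map an as-recorded channel label onto a canonical 10-20 name."""
    name = raw_label.strip()
    # strip common "EEG Fp1-REF" style decoration
    if name.upper().startswith("EEG "):
        name = name[4:]
    name = name.split("-")[0].strip()
    by_lower = {ch.lower(): ch for ch in CHANNELS}
    by_lower.update({k.lower(): v for k, v in CHANNEL_ALIASES.items()})
    return by_lower.get(name.lower())


def seconds_to_samples(t: float, fs: float) -> int:
    """Convert seconds to a sample index, rounding half-up."""
    return int(np.floor(t * fs + 0.5))


def read_annotation_tsv(path: str | Path) -> dict[str, list[tuple[str, float, float]]]:
    """Read a sidecar annotation table; returns per-subject (name, onset_s, duration_s)."""
    out: dict[str, list[tuple[str, float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"subject_id", "interval", "onset_s", "duration_s"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"annotation TSV must have columns {sorted(required)}")
        for row in reader:
            out.setdefault(row["subject_id"], []).append(
                (row["interval"], float(row["onset_s"]), float(row["duration_s"]))
            )
    return out


def _annotations_from_spans(
    spans: list[tuple[str, float, float]], fs: float
) -> list[IntervalAnnotation]:
    anns = []
    for name, onset_s, duration_s in spans:
        start = seconds_to_samples(onset_s, fs)
        end = seconds_to_samples(onset_s + duration_s, fs)
        anns.append(IntervalAnnotation(name=name, start_sample=start, end_sample=end))
    return anns


def read_recording(
    path: str | Path,
    annotation_source: str | Path | list[tuple[str, float, float]] | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read an EDF recording and resolve its eight protocol annotations.

    ``annotation_source`` may be a sidecar TSV path, an explicit list of
    ``(interval, onset_s, duration_s)`` spans, or ``None`` to use annotations
    embedded in the file (EDF+). When both a sidecar and embedded annotations
    exist, the sidecar wins.
    """
    import mne

    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])

    labels, rows = [], []
    dropped = []
    data = raw.get_data() * 1e6  # MNE returns volts; the pipeline works in uV
    for i, ch in enumerate(raw.ch_names):
        canon = _normalize_label(ch)
        if canon is None or canon in labels:
            dropped.append(ch)
            continue
        labels.append(canon)
        rows.append(data[i])
    if dropped:
        logger.info("%s: dropped %d non-canonical channels: %s",
                    sid, len(dropped), dropped)
    missing = [ch for ch in CHANNELS if ch not in labels]
    if missing:
        raise ValueError(f"missing channel {missing[0]}")

    if annotation_source is None:
        spans = [
            (desc, float(onset), float(dur))
            for onset, dur, desc in zip(
                raw.annotations.onset, raw.annotations.duration,
                raw.annotations.description,
            )
            if desc in INTERVALS
        ]
        if not spans:
            raise ValueError(f"{path}: no protocol annotations found in file")
    elif isinstance(annotation_source, (str, Path)):
        table = read_annotation_tsv(annotation_source)
        if sid not in table:
            raise ValueError(f"annotation TSV has no rows for subject {sid!r}")
        spans = table[sid]
    else:
        spans = list(annotation_source)

    rec = Recording(
        subject_id=sid,
        channel_labels=labels,
        fs=fs,
        signal=np.asarray(rows),
        annotations=_annotations_from_spans(spans, fs),
    )
    if fs != 128.0:
        warnings.warn(
            f"{sid}: non-canonical sampling rate {fs} Hz (analysis is fs-agnostic; "
            "no resampling performed)", stacklevel=2,
        )
    return rec.canonical()


def segment(recording: Recording) -> dict[str, np.ndarray]:
    """Slice the signal into the eight annotated protocol intervals.

    Returns a mapping interval name -> channels x samples view. The entries
    partition the annotated spans: no sample belongs to two intervals.
    """
    out = {}
    for ann in recording.annotations:
        out[ann.name] = recording.signal[:, ann.start_sample:ann.end_sample]
    return {name: out[name] for name in INTERVALS}


# ---------------------------------------------------------------------------
# label tables and cohorts


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a subject_id -> {Responder, NonResponder} CSV."""
    df = pd.read_csv(path)
    if not {"subject_id", "label"} <= set(df.columns):
        raise ValueError("label CSV must have columns subject_id,label")
    table: dict[str, str] = {}
    for sid, lab in zip(df["subject_id"].astype(str), df["label"].astype(str)):
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r} for subject {sid}")
        if sid in table:
            raise ValueError(f"duplicate label row for subject {sid}")
        table[sid] = lab
    return table


def write_label_table(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "label"])
        for sid, lab in labels.items():
            w.writerow([sid, lab])


@dataclass
class CohortDataset:
    """A labelled cohort of recordings."""

    recordings: list[Recording]
    labels: dict[str, str]

    def __post_init__(self):
        ids = [r.subject_id for r in self.recordings]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate subject ids in cohort")
        unlabelled = [i for i in ids if i not in self.labels]
        if unlabelled or len(self.labels) != len(ids):
            raise ValueError("cohort size must equal label-table size, one label each")

    @property
    def n(self) -> int:
        return len(self.recordings)


# ---------------------------------------------------------------------------
# minimal EDF writer (16-bit, 1-second data records) for fixture cohorts


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as a plain 16-bit EDF file.

    Requires a whole number of seconds of signal (the canonical protocol is
    670 s exactly). Physical range is chosen per channel, so round-trip error
    is bounded by half a quantisation step of the channel's own range.
    """
    sig = np.asarray(recording.signal, dtype=float)
    n_ch, n_samp = sig.shape
    fs = recording.fs
    spr = int(round(fs))  # samples per 1 s record
    if abs(fs - spr) > 1e-9 or n_samp % spr != 0:
        raise ValueError("EDF writer needs integer fs and whole seconds of signal")
    n_rec = n_samp // spr

    # physical range is stored as ASCII with ~6 significant digits; digitize
    # against the value as written so reader and writer agree exactly
    raw_max = np.maximum(np.max(np.abs(sig), axis=1), 1e-6) * 1.001
    phys_max = np.array([float(f"{m:.6g}"[:8]) for m in raw_max])
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {recording.subject_id}"[:80], 80),
        pad("Startdate X X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        ("".join(pad(ch, 16).decode() for ch in recording.channel_labels), 16),
        ("".join(pad("AgAgCl electrode", 80).decode() for _ in range(n_ch)), 80),
        ("".join(pad("uV", 8).decode() for _ in range(n_ch)), 8),
        ("".join(pad(f"{-m:.6g}"[:8], 8).decode() for m in phys_max), 8),
        ("".join(pad(f"{m:.6g}"[:8], 8).decode() for m in phys_max), 8),
        ("".join(pad(str(dig_min), 8).decode() for _ in range(n_ch)), 8),
        ("".join(pad(str(dig_max), 8).decode() for _ in range(n_ch)), 8),
        ("".join(pad("", 80).decode() for _ in range(n_ch)), 80),
        ("".join(pad(str(spr), 8).decode() for _ in range(n_ch)), 8),
        ("".join(pad("", 32).decode() for _ in range(n_ch)), 32),
    ]
    header += b"".join(f[0].encode("ascii") for f in fields)
    assert len(header) == 256 * (n_ch + 1)

    # exact EDF affine map: physical = phys_min + (digital - dig_min) * step
    step = 2 * phys_max / (dig_max - dig_min)
    digital = np.rint((sig + phys_max[:, None]) / step[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records are contiguous per channel within each 1 s block
        blocks = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def write_annotation_tsv(
    recordings: list[Recording], path: str | Path
) -> None:
    """Write sidecar interval annotations for a list of recordings."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject_id", "interval", "onset_s", "duration_s"])
        for rec in recordings:
            for ann in sorted(rec.annotations, key=lambda a: a.start_sample):
                w.writerow([
                    rec.subject_id, ann.name,
                    ann.start_sample / rec.fs, ann.n_samples / rec.fs,
                ])
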