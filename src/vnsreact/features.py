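"""Classifier feature spaces built from the RPW table.

Two layouts are supported:

* grouped — the mean RPW over each of the seven anatomical electrode
  regions, giving 7 conditions x 4 bands x 7 regions = 196 columns;
* single-electrode — the raw per-electrode cells, 7 x 4 x 19 = 532 columns.

Column ordering is fixed (condition-major, then band, then region/electrode,
each in canonical order) so selection frequencies are comparable across runs
and index ties break deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BAND_NAMES, CHANNELS, CONDITIONS, REGIONS


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identifies one feature column: a source (region or electrode), a
    frequency band and a protocol condition."""

    source: str
    band: str
    condition: str

    def __str__(self) -> str:
        return f"{self.condition}|{self.band}|{self.source}"


class FeatureMatrix:
    """Subjects x features matrix of RPW-derived variables (percent units)."""

    def __init__(self, values: pd.DataFrame, descriptors: list[FeatureDescriptor]):
        if values.shape[1] != len(descriptors):
            raise ValueError("descriptor count must match column count")
        self.values = values
        self.descriptors = list(descriptors)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def restrict(self, indices) -> "FeatureMatrix":
        idx = sorted(int(i) for i in indices)
        return FeatureMatrix(self.values.iloc[:, idx],
                             [self.descriptors[i] for i in idx])

    def to_frame(self, labels: dict[str, str] | None = None) -> pd.DataFrame:
        df = self.values.copy()
        df.columns = [str(d) for d in self.descriptors]
        if labels is not None:
            df.insert(0, "label", [labels[s] for s in df.index])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        cols = [c for c in df.columns if c != "label"]
        descs = []
        for c in cols:
            cond, band, source = c.split("|")
            descs.append(FeatureDescriptor(source=source, band=band, condition=cond))
        return cls(df[cols], descs)


def _cube(rpw: pd.DataFrame, electrodes: tuple[str, ...]):
    """Pivot the tidy table to an (n_subjects, electrode, band, condition)
    array over the requested electrodes, preserving subject order."""
    wide = rpw.pivot_table(index="subject_id",
                           columns=["electrode", "band", "condition"],
                           values="rpw", aggfunc="first", sort=False)
    present = set(wide.columns.get_level_values("electrode"))
    missing = [e for e in electrodes if e not in present]
    if missing:
        raise ValueError(f"RPW table missing electrode {missing[0]!r}")
    full = pd.MultiIndex.from_product(
        [electrodes, BAND_NAMES, CONDITIONS],
        names=["electrode", "band", "condition"])
    wide = wide.reindex(columns=full)
    if wide.isna().any().any():
        raise ValueError("RPW table has missing cells")
    arr = wide.to_numpy().reshape(
        wide.shape[0], len(electrodes), len(BAND_NAMES), len(CONDITIONS))
    return arr, list(wide.index)


def build_grouped_features(
    rpw: pd.DataFrame, regions: dict[str, tuple[str, ...]] | None = None
) -> FeatureMatrix:
    """Mean RPW over each anatomical region, per band x condition.

    Midline electrodes contribute to both hemispheric regions exactly as the
    region table lists them, so left/right frontal features share Fz by
    construction.
    """
    regions = REGIONS if regions is None else regions
    needed = tuple(dict.fromkeys(e for members in regions.values()
                                 for e in members))
    bad = [e for e in needed if e not in CHANNELS]
    if bad:
        raise ValueError(f"region electrode {bad[0]!r} is not a canonical label")
    arr, subjects = _cube(rpw, needed)
    e_idx = {e: i for i, e in enumerate(needed)}
    n = arr.shape[0]
    out = np.empty((n, len(CONDITIONS) * len(BAND_NAMES) * len(regions)))
    descs, k = [], 0
    for ci in range(len(CONDITIONS)):
        for bi in range(len(BAND_NAMES)):
            for region, members in regions.items():
                idx = [e_idx[e] for e in members]
                out[:, k] = arr[:, idx, bi, ci].mean(axis=1)
                descs.append(FeatureDescriptor(region, BAND_NAMES[bi],
                                               CONDITIONS[ci]))
                k += 1
    values = pd.DataFrame(out, index=subjects)
    return FeatureMatrix(values, descs)


def build_single_electrode_features(rpw: pd.DataFrame) -> FeatureMatrix:
    """Identity mapping of RPW cells onto feature columns (19 electrodes)."""
    arr, subjects = _cube(rpw, CHANNELS)
    # (n, electrode, band, condition) -> condition-major, band, electrode
    out = arr.transpose(0, 3, 2, 1).reshape(arr.shape[0], -1)
    descs = [FeatureDescriptor(ele, band, cond)
             for cond in CONDITIONS for band in BAND_NAMES for ele in CHANNELS]
    values = pd.DataFrame(out, index=subjects)
    return FeatureMatrix(values, descs)
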