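"""Independent-cohort validation of a developed model.

Two approaches, both starting by restricting the external cohort's feature
matrix to the discriminative columns identified on the development cohort:

* single — one classifier trained on all n development subjects predicts
  each external subject;
* voting — n jackknife classifiers, each trained on a leave-one-out subset
  of the development cohort, vote on each external subject; the majority
  label wins, and an even split resolves to NonResponder (the conservative
  call for a treatment-benefit prediction; ties are logged).

Standardization parameters always come from the training data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NONRESPONDER, RESPONDER
from .features import FeatureMatrix
from .predictor import ClassifierSpec, PerformanceReport, _as_xy

logger = logging.getLogger(__name__)


@dataclass
class ValidationResult:
    """Per-subject external predictions, vote tallies (voting mode only) and
    performance metrics when true labels are supplied."""

    predictions: pd.Series  # subject_id -> predicted label
    votes: pd.DataFrame | None = None  # columns: votes_responder, votes_nonresponder
    report: PerformanceReport | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"predicted": self.predictions})
        if self.votes is not None:
            df = df.join(self.votes)
        return df


def reduce_external(
    features_ext: FeatureMatrix,
    selected: list[int],
    reference: FeatureMatrix | None = None,
) -> FeatureMatrix:
    """Restrict an external feature matrix to the selected development columns.

    When ``reference`` (the development matrix) is given, the external
    descriptors must match it column for column.
    """
    if reference is not None:
        if features_ext.descriptors != reference.descriptors:
            raise ValueError(
                "external feature descriptors do not match the development matrix"
            )
    if max(selected, default=-1) >= features_ext.n_features:
        raise ValueError("selected index outside external feature matrix")
    return features_ext.restrict(selected)


def _label(v: int) -> str:
    return RESPONDER if v == 1 else NONRESPONDER


def validate_single(
    train_features,
    train_labels,
    external: FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec(),
    true_labels: dict[str, str] | None = None,
    chance: float | None = None,
) -> ValidationResult:
    """One classifier trained on the full development cohort."""
    Xtr, ytr = _as_xy(train_features, train_labels)
    model = spec.build()
    model.fit(Xtr, ytr)
    pred = model.predict(external.to_array()).astype(int)
    predictions = pd.Series([_label(v) for v in pred],
                            index=external.subject_ids, name="predicted")
    report = None
    if true_labels is not None:
        yt = [true_labels[s] for s in external.subject_ids]
        report = PerformanceReport.from_predictions(yt, predictions, chance=chance)
    return ValidationResult(predictions=predictions, report=report)


def validate_voting(
    train_features,
    train_labels,
    external: FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec(),
    true_labels: dict[str, str] | None = None,
    chance: float | None = None,
) -> ValidationResult:
    """Majority voting of the n jackknife classifiers."""
    Xtr, ytr = _as_xy(train_features, train_labels)
    n = Xtr.shape[0]
    if n < 3:
        raise ValueError("jackknife voting needs at least 3 training subjects")
    Xext = external.to_array()
    votes = np.zeros((Xext.shape[0],), dtype=int)  # responder votes
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[:] = True
        mask[i] = False
        yfold = ytr[mask]
        if yfold.min() == yfold.max():
            raise ValueError("a jackknife fold lost one class entirely")
        model = spec.build()
        model.fit(Xtr[mask], yfold)
        votes += model.predict(Xext).astype(int)
    nonresp_votes = n - votes
    pred = votes > nonresp_votes  # even split -> NonResponder
    for sid, v in zip(external.subject_ids, votes):
        if v * 2 == n:
            logger.info("vote tie (%d/%d) for subject %s -> NonResponder",
                        v, n - v, sid)
    predictions = pd.Series([_label(int(v)) for v in pred],
                            index=external.subject_ids, name="predicted")
    votes_df = pd.DataFrame(
        {"votes_responder": votes, "votes_nonresponder": nonresp_votes},
        index=external.subject_ids,
    )
    report = None
    if true_labels is not None:
        yt = [true_labels[s] for s in external.subject_ids]
        report = PerformanceReport.from_predictions(yt, predictions, chance=chance)
    return ValidationResult(predictions=predictions, votes=votes_df, report=report)
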