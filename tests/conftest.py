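import dataclasses

import numpy as np
import pytest

import vnsreact as v


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect RPW cohort (8 responders / 6 non-responders)."""
    cfg = dataclasses.replace(v.default_config(42), n_responders=8,
                              n_nonresponders=6)
    rpw, labels = v.generate_rpw_cohort(cfg)
    return rpw, labels, cfg


@pytest.fixture(scope="session")
def raw_pair():
    """Two tiny raw-EEG subjects with the default planted effects."""
    cfg = dataclasses.replace(v.default_config(7, mode="raw_eeg"),
                              n_responders=2, n_nonresponders=2)
    recs, labels, targets = v.generate_raw_cohort(cfg, return_targets=True)
    return recs, labels, targets


@pytest.fixture(scope="session")
def edf_cohort(raw_pair, tmp_path_factory):
    """The raw cohort written out as EDF + sidecar annotation TSV + labels."""
    recs, labels, _ = raw_pair
    d = tmp_path_factory.mktemp("edf")
    paths = []
    for rec in recs:
        p = d / f"{rec.subject_id}.edf"
        v.write_edf(rec, p)
        paths.append(p)
    ann = d / "annotations.tsv"
    v.write_annotation_tsv(recs, ann)
    lab = d / "labels.csv"
    v.write_label_table(labels, lab)
    return paths, ann, lab, recs


def make_separable_features(n_per_class=5, n_noise=3, seed=0):
    """A linearly separable FeatureMatrix-like array plus labels."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(2 * n_per_class, 1 + n_noise))
    X[:n_per_class, 0] = rng.uniform(2, 3, n_per_class)
    X[n_per_class:, 0] = rng.uniform(-3, -2, n_per_class)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    return X, y
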