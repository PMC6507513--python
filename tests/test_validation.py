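import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import vnsreact as v
from vnsreact.experiments import derive_seed


def _dev_and_external(seed, n_dev=(8, 6), n_ext=(4, 4)):
    cfg = dataclasses.replace(v.default_config(seed),
                              n_responders=n_dev[0], n_nonresponders=n_dev[1])
    ext_cfg = dataclasses.replace(
        v.default_config(seed + 1), n_responders=n_ext[0],
        n_nonresponders=n_ext[1], id_prefix="X")
    rpw, labels = v.generate_rpw_cohort(cfg)
    ext_rpw, ext_labels = v.generate_rpw_cohort(ext_cfg)
    return (v.build_grouped_features(rpw), labels,
            v.build_grouped_features(ext_rpw), ext_labels)


class TestReduceExternal:
    def test_restriction_to_selected_columns(self, small_cohort):
        rpw, _, _ = small_cohort
        fm = v.build_grouped_features(rpw)
        reduced = v.reduce_external(fm, list(range(8)), reference=fm)
        assert reduced.n_features == 8
        identity = v.reduce_external(fm, list(range(196)))
        assert identity.n_features == 196

    def test_descriptor_mismatch_rejected(self, small_cohort):
        rpw, _, _ = small_cohort
        fm = v.build_grouped_features(rpw)
        fm_single = v.build_single_electrode_features(rpw)
        with pytest.raises(ValueError, match="descriptor"):
            v.reduce_external(fm_single, [0, 1], reference=fm)

    def test_out_of_range_selection_rejected(self, small_cohort):
        rpw, _, _ = small_cohort
        fm = v.build_grouped_features(rpw)
        with pytest.raises(ValueError, match="outside"):
            v.reduce_external(fm, [500])


class TestValidateSingle:
    def test_generator_matched_external_above_majority(self):
        fm, labels, fm_ext, ext_labels = _dev_and_external(10)
        sel = v.stepwise_logistic_select(fm, labels)
        res = v.validate_single(fm.restrict(sel), labels,
                                v.reduce_external(fm_ext, sel),
                                true_labels=ext_labels)
        majority = 100.0 * 4 / 8
        assert res.report.accuracy > majority

    def test_self_validation_of_separable_cohort_is_perfect(self):
        from .conftest import make_separable_features
        X, y = make_separable_features()
        fm = v.FeatureMatrix(
            pd.DataFrame(X, index=[f"s{i}" for i in range(len(y))]),
            [v.FeatureDescriptor(f"f{j}", "alpha", "HV")
             for j in range(X.shape[1])])
        labels = {f"s{i}": (v.RESPONDER if yi else v.NONRESPONDER)
                  for i, yi in enumerate(y)}
        res = v.validate_single(fm, labels, fm, true_labels=labels)
        assert res.report.accuracy == 100.0

    def test_without_true_labels_no_report(self):
        fm, labels, fm_ext, _ = _dev_and_external(11)
        res = v.validate_single(fm, labels, fm_ext)
        assert res.report is None
        assert set(res.predictions) <= {v.RESPONDER, v.NONRESPONDER}


class _ParityStub:
    """Deterministic stand-in classifier: votes Responder iff the training
    fold contains an even number of responders (forces a 2/2 vote tie when
    one responder or one non-responder is dropped from a 2+2 cohort)."""

    def fit(self, X, y):
        self._even = int(np.sum(y)) % 2 == 0
        return self

    def predict(self, X):
        return np.full(len(X), 1 if self._even else 0)


class _StubSpec:
    def build(self):
        return _ParityStub()


class TestValidateVoting:
    def test_unanimous_models_match_single_classifier(self):
        fm, labels, fm_ext, ext_labels = _dev_and_external(12)
        sel = v.stepwise_logistic_select(fm, labels)
        tr, ex = fm.restrict(sel), v.reduce_external(fm_ext, sel)
        voting = v.validate_voting(tr, labels, ex, true_labels=ext_labels)
        unanimous = (voting.votes.max(axis=1) == len(labels))
        single = v.validate_single(tr, labels, ex, true_labels=ext_labels)
        assert unanimous.any()
        agree = voting.predictions[unanimous] == single.predictions[unanimous]
        assert agree.all()

    def test_vote_tallies_sum_to_n(self):
        fm, labels, fm_ext, _ = _dev_and_external(13)
        res = v.validate_voting(fm, labels, fm_ext)
        assert (res.votes.sum(axis=1) == len(labels)).all()

    def test_even_split_resolves_to_nonresponder(self):
        fm, labels, fm_ext, _ = _dev_and_external(14, n_dev=(2, 2))
        res = v.validate_voting(fm, labels, fm_ext, spec=_StubSpec())
        assert (res.votes["votes_responder"] == 2).all()
        assert (res.predictions == v.NONRESPONDER).all()

    def test_clear_majority_wins(self):
        fm, labels, fm_ext, ext_labels = _dev_and_external(15)
        res = v.validate_voting(fm, labels, fm_ext, true_labels=ext_labels)
        for sid in res.predictions.index:
            vr = res.votes.loc[sid, "votes_responder"]
            vn = res.votes.loc[sid, "votes_nonresponder"]
            expect = v.RESPONDER if vr > vn else v.NONRESPONDER
            assert res.predictions[sid] == expect

    def test_voting_stability_vs_single(self):
        """Voting tracks the single classifier within 5 points on
        generator-matched external cohorts in nearly all replicates."""
        hits = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(50):
                cfg = v.default_config(derive_seed(50, i))
                ext_cfg = dataclasses.replace(
                    v.default_config(derive_seed(51, i)),
                    n_responders=12, n_nonresponders=10, id_prefix="X")
                rpw, labels = v.generate_rpw_cohort(cfg)
                ext_rpw, ext_labels = v.generate_rpw_cohort(ext_cfg)
                fm = v.build_grouped_features(rpw)
                fm_ext = v.build_grouped_features(ext_rpw)
                sel = v.stepwise_logistic_select(fm, labels)
                tr, ex = fm.restrict(sel), v.reduce_external(fm_ext, sel)
                vote = v.validate_voting(tr, labels, ex,
                                         true_labels=ext_labels)
                single = v.validate_single(tr, labels, ex,
                                           true_labels=ext_labels)
                hits.append(vote.report.accuracy
                            >= single.report.accuracy - 5.0)
        assert np.mean(hits) >= 0.9
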