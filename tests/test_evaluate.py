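"""Train/test protocol, confusion matrices and reports."""

import numpy as np
import pandas as pd
import pytest

from olivesort.evaluate import (
    ProtocolConfig,
    confusion_matrix,
    parse_report,
    report,
    run_protocol,
)
from olivesort.labeler import scheme_classes
from olivesort.synthetic import SceneSpec, generate_dataset


def small_dataset(scheme="simple", per=40, seed=0, **spec_kw):
    n = {c: per for c in scheme_classes(scheme)}
    defaults = SceneSpec(**spec_kw) if spec_kw else None
    return generate_dataset(n, scheme=scheme, seed=seed, spec_defaults=defaults)


class TestProtocolConfig:
    def test_curie_cannot_take_256_byte_vectors(self):
        with pytest.raises(ValueError):
            ProtocolConfig(network="curie", resolution=(16, 16))
        ProtocolConfig(network="curie", resolution=(11, 11))  # fits

    def test_positive_sizing_required(self):
        with pytest.raises(ValueError):
            ProtocolConfig(reps=0)

    def test_network_profile_uses_raster_length(self):
        cfg = ProtocolConfig(resolution=(11, 11))
        assert cfg.network_profile().vector_len == 121
        assert cfg.network_profile().max_neurons == 1024


class TestRunProtocol:
    def test_presentation_count_is_reps_times_test_per_case(self):
        ds = small_dataset(per=10)
        cfg = ProtocolConfig(resolution=(10, 10), train_cap=8, reps=10,
                             test_per_case=300, seed=1)
        res = run_protocol(ds, cfg)
        assert res.presented_per_case == 3000
        assert res.drew_with_replacement  # pool of 2 per class
        for m in res.confusions:
            assert (m.sum(axis=1) == 300).all()

    def test_memorization_scores_zero_error(self):
        ds = small_dataset(per=15, noise_sigma=0.0)
        # the whole pool trains, so the test pool falls back to the train set
        cfg = ProtocolConfig(resolution=(10, 10), train_cap=15, reps=2,
                             test_per_case=15, seed=2)
        res = run_protocol(ds, cfg)
        assert res.rep_errors == [0.0, 0.0]
        assert res.total_error == 0.0

    def test_fresh_network_commits_at_least_one_neuron_per_class(self):
        ds = small_dataset(per=30)
        res = run_protocol(ds, ProtocolConfig(train_cap=20, reps=2,
                                              test_per_case=10, seed=3))
        assert res.committed_neurons >= 3
        assert res.committed_neurons <= 1024

    def test_missing_class_is_named(self):
        ds = [s for s in small_dataset(per=10) if s.label != "boat"]
        with pytest.raises(ValueError, match="boat"):
            run_protocol(ds, ProtocolConfig(train_cap=5, reps=1, test_per_case=5))

    def test_deterministic_for_fixed_seed(self):
        ds = small_dataset(per=25)
        cfg = ProtocolConfig(train_cap=15, reps=3, test_per_case=20, seed=7)
        a, b = run_protocol(ds, cfg), run_protocol(ds, cfg)
        assert a.rep_errors == b.rep_errors
        assert a.committed_neurons == b.committed_neurons

    def test_diverted_cases_bypass_network_and_are_tallied(self):
        ds = small_dataset(per=25)
        n_div = {"double": 9, "small_part": 6}
        ds += generate_dataset(n_div, scheme="simple", seed=13)
        res = run_protocol(ds, ProtocolConfig(train_cap=15, reps=2,
                                              test_per_case=10, seed=1))
        assert res.diverted == {"double": 9, "small_part": 6}

    def test_finer_partition_is_no_easier_than_simple(self):
        """Splitting angles into 10-degree bins cannot beat 3-way sorting."""
        errs = {}
        for scheme, per in (("degrees", 30), ("simple", 30)):
            errors = []
            for seed in range(3):
                ds = small_dataset(scheme=scheme, per=per, seed=seed)
                cfg = ProtocolConfig(scheme=scheme, resolution=(11, 11),
                                     train_cap=20, reps=2, test_per_case=20,
                                     seed=seed)
                errors.append(run_protocol(ds, cfg).total_error)
            errs[scheme] = np.mean(errors)
        assert errs["degrees"] >= errs["simple"]


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        classes = ["a", "b", "c"]
        m = confusion_matrix(["a", "b", "c", "a"], ["a", "b", "c", "a"], classes)
        assert m.loc["a", "a"] == 2
        assert int(m.to_numpy().sum()) == 4
        off = m.to_numpy().sum() - np.trace(m.loc[classes, classes].to_numpy())
        assert off == 0

    def test_empty_inputs_give_zero_matrix(self):
        m = confusion_matrix([], [], ["a", "b"])
        assert (m.to_numpy() == 0).all()
        assert list(m.columns) == ["a", "b", "unknown", "uncertain"]

    def test_hand_built_six_item_case(self):
        truths = ["a", "a", "b", "b", "b", "a"]
        preds = ["a", "b", "b", "unknown", "uncertain", "a"]
        m = confusion_matrix(preds, truths, ["a", "b"])
        assert m.loc["a", "a"] == 2
        assert m.loc["a", "b"] == 1
        assert m.loc["b", "b"] == 1
        assert m.loc["b", "unknown"] == 1
        assert m.loc["b", "uncertain"] == 1
        assert m.sum(axis=1).tolist() == [3, 3]

    def test_labels_outside_scheme_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["x"], ["a"], ["a", "b"])
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["x"], ["a", "b"])


class TestReport:
    def _result(self, rep_errors):
        ds = small_dataset(per=10)
        cfg = ProtocolConfig(resolution=(10, 10), train_cap=8, reps=len(rep_errors),
                             test_per_case=5, seed=1)
        res = run_protocol(ds, cfg)
        res.rep_errors = rep_errors
        return res

    def test_totals_row_is_mean_of_repetitions(self):
        text, _ = report(self._result([0.0] * 10))
        assert "Totals  0.00%" in text
        reps = [0.01, 0.0, 0.0, 0.02, 0.01, 0.01, 0.0, 0.01, 0.01, 0.0]
        text, data = report(self._result(reps))
        assert "Totals  0.70%" in text
        assert data["total_error"] == pytest.approx(0.007)

    def test_machine_twin_round_trips(self):
        res = self._result([0.01, 0.03])
        _, data = report(res)
        back = parse_report(data)
        assert back.rep_errors == res.rep_errors
        assert back.total_error == pytest.approx(res.total_error)
        assert back.committed_neurons == res.committed_neurons
        assert back.config.scheme == res.config.scheme
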