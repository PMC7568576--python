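"""Elastic-net selection behavior and distribution summaries."""

import numpy as np
import pytest

from cardiowave import feature_select as fsel, synthetic as syn, timefreq as tf
from cardiowave.exceptions import (
    DegenerateLabelsError,
    InvalidArgumentError,
    MalformedFeatureNameError,
)


def _table(matrix, names=None, labels=None):
    n, p = matrix.shape
    return fsel.FeatureTable(
        matrix=matrix,
        feature_names=names or [f"F{j:04d}" for j in range(p)],
        subject_ids=[f"S{i:03d}" for i in range(n)],
        labels=labels or ["AS" if i % 2 else "NON_AS" for i in range(n)],
    )


class TestFeatureTable:
    def test_validation_errors(self, rng):
        x = rng.standard_normal((10, 4))
        with pytest.raises(InvalidArgumentError):
            _table(x, names=["a", "b", "c"])                    # count mismatch
        with pytest.raises(InvalidArgumentError):
            _table(x, names=["a", "a", "b", "c"])               # duplicates
        bad = x.copy()
        bad[0, 0] = np.nan
        with pytest.raises(InvalidArgumentError):
            _table(bad)

    def test_task_detection(self, rng):
        x = rng.standard_normal((12, 3))
        assert _table(x).task == "BINARY"
        labels = ["AS", "AS_MI", "AS_MS", "AS_TR"] * 3
        assert _table(x, labels=labels).task == "MULTICLASS"

    def test_channel_filter_keeps_matching_columns(self, rng):
        names = ["SCG_Z_MAX_5.00", "GCG_Y_MED_3.10", "SCG_Z_STD_1.00"]
        t = _table(rng.standard_normal((8, 3)), names=names)
        assert t.filter_channels(["SCG_Z"]).feature_names == [
            "SCG_Z_MAX_5.00", "SCG_Z_STD_1.00"]

    def test_frame_round_trip(self, rng):
        t = _table(rng.standard_normal((6, 3)))
        back = fsel.FeatureTable.from_frame(t.to_frame())
        assert back.feature_names == t.feature_names
        assert np.allclose(back.matrix, t.matrix)
        assert back.labels == t.labels


class TestElasticNetSelect:
    def test_recovers_planted_features(self, planted_table):
        table, planted = planted_table
        result = fsel.elastic_net_select(table, seed=3)
        recovered = len(set(result.selected_names) & set(planted))
        assert recovered >= 8
        assert result.n_original == table.n_features

    def test_null_labels_select_few_features(self, planted_table):
        table, _ = planted_table
        rng = np.random.default_rng(0)
        for perm_seed in range(3):
            labels = list(rng.permutation(table.labels))
            shuffled = fsel.FeatureTable(
                table.matrix, table.feature_names, table.subject_ids, labels)
            result = fsel.elastic_net_select(shuffled, seed=perm_seed)
            assert result.n_selected <= 0.05 * table.n_features

    def test_selection_invariant_to_column_order(self, planted_table):
        table, _ = planted_table
        rng = np.random.default_rng(7)
        perm = rng.permutation(table.n_features)
        shuffled = fsel.FeatureTable(
            table.matrix[:, perm],
            [table.feature_names[j] for j in perm],
            table.subject_ids, table.labels)
        a = set(fsel.elastic_net_select(table, seed=3).selected_names)
        b = set(fsel.elastic_net_select(shuffled, seed=3).selected_names)
        # allow boundary churn from solver tolerance, require essential identity
        assert len(a & b) >= 0.9 * max(len(a), len(b))

    def test_monotone_sparsity_along_penalty_path(self, planted_table):
        """Weaker penalties never shrink the active set (checked on the
        refit path the selector uses)."""
        from sklearn.linear_model import LogisticRegression

        table, _ = planted_table
        X = (table.matrix - table.matrix.mean(0)) / table.matrix.std(0)
        y = np.asarray([l == "AS" for l in table.labels], dtype=int)
        c0 = 0.5 / np.abs(X.T @ (y - y.mean())).max()
        nnz = []
        for c in c0 * np.logspace(0, 3, 8):
            m = LogisticRegression(solver="saga", l1_ratio=0.5, C=c,
                                   max_iter=3000, tol=1e-4, random_state=0).fit(X, y)
            nnz.append(int((m.coef_ != 0).sum()))
        assert all(b >= a - 1 for a, b in zip(nnz, nnz[1:]))   # tol-level slack

    def test_single_class_rejected(self, rng):
        t = _table(rng.standard_normal((20, 5)), labels=["AS"] * 20)
        with pytest.raises(DegenerateLabelsError):
            fsel.elastic_net_select(t)

    def test_constant_columns_dropped_with_warning(self, rng, caplog):
        x = rng.standard_normal((40, 6))
        x[:, 2] = 7.0
        x[::2, 0] += 3.0
        labels = ["AS" if i % 2 == 0 else "NON_AS" for i in range(40)]
        with caplog.at_level("WARNING"):
            result = fsel.elastic_net_select(_table(x, labels=labels), seed=0)
        assert "constant" in caplog.text
        assert "F0002" not in result.selected_names

    def test_multiclass_union_includes_each_class_signal(self, rng):
        # each class has its own informative feature block
        n_per, p = 40, 30
        rows, labels = [], []
        for k, label in enumerate(["AS", "AS_MI", "AS_MS", "AS_TR"]):
            x = rng.standard_normal((n_per, p))
            x[:, 3 * k: 3 * k + 3] += 2.5
            rows.append(x)
            labels += [label] * n_per
        t = _table(np.vstack(rows), labels=labels)
        result = fsel.elastic_net_select(t, seed=0)
        for k in range(4):
            block = {f"F{j:04d}" for j in range(3 * k, 3 * k + 3)}
            assert block & set(result.selected_names)

    def test_reduction_pct_is_computed_from_counts(self):
        result = fsel.SelectionResult(
            selected_names=[f"F{j}" for j in range(214)],
            coefficients={}, n_original=4764)
        assert result.reduction_pct == pytest.approx(100 * (1 - 214 / 4764))
        assert result.reduction_pct == pytest.approx(95.5, abs=0.1)


class TestSummaries:
    def test_hand_counted_example(self):
        result = fsel.SelectionResult(
            selected_names=["SCG_Z_MAX_5.00", "GCG_Y_MAX_12.00", "GCG_Y_MED_21.00"],
            coefficients={}, n_original=100)
        s = fsel.summarize_selection(result)
        assert s.frequency_bands == {"<10 Hz": 1, "10-20 Hz": 1, ">20 Hz": 1}
        assert s.statistic_counts["MAX"] == 2 and s.statistic_counts["MED"] == 1
        assert s.source_counts["GCG_Y"] == 2 and s.source_counts["SCG_Z"] == 1

    def test_counts_partition_selected_set(self):
        rng = np.random.default_rng(1)
        names = [tf.feature_name(rng.choice(syn.CHANNELS), rng.choice(tf.STATS),
                                 rng.uniform(1, 25)) for _ in range(50)]
        names = list(dict.fromkeys(names))
        result = fsel.SelectionResult(names, {}, 1000)
        s = fsel.summarize_selection(result)
        for counts in (s.frequency_bands, s.statistic_counts, s.source_counts):
            assert sum(counts.values()) == result.n_selected

    def test_pareto_nondecreasing_and_ends_at_100(self):
        result = fsel.SelectionResult(
            ["SCG_Z_MAX_5.00", "SCG_Z_MAX_6.00", "GCG_Y_MED_3.00"], {}, 10)
        s = fsel.summarize_selection(result)
        for family, curve in s.pareto.items():
            pcts = [p for _, p in curve]
            assert all(b >= a for a, b in zip(pcts, pcts[1:]))
            assert pcts[-1] == pytest.approx(100.0)

    def test_single_category_pareto(self):
        s = fsel.summarize_selection(
            fsel.SelectionResult(["SCG_Z_MAX_5.00"], {}, 10))
        assert s.pareto["statistic"][0] == ("MAX", pytest.approx(100.0))

    def test_malformed_name_rejected(self):
        with pytest.raises(MalformedFeatureNameError):
            fsel.summarize_selection(fsel.SelectionResult(["banana"], {}, 10))

    def test_summary_frame_layout(self):
        s = fsel.summarize_selection(
            fsel.SelectionResult(["SCG_Z_MAX_5.00", "GCG_Y_MED_3.00"], {}, 10))
        frame = fsel.summary_to_frame(s)
        assert set(frame["family"]) == {"frequency", "statistic", "source"}
        assert frame["count"].sum() == 6          # 2 per family


class TestPlantedProfileRecovery:
    def test_max_dominated_sub10hz_profile_is_recovered(self, rng):
        """When the ground-truth effects live in sub-10-Hz MAX features,
        the selected-feature histograms are majority <10 Hz and majority
        MAX — the qualitative profile the selection stage must expose."""
        grid = tf.build_grid(256.0, 4)
        names = [tf.feature_name(ch, stat, f)
                 for ch in ("SCG_Z", "GCG_Y")
                 for stat in tf.STATS
                 for f in grid.frequencies_hz]
        informative = [n for n in names
                       if "_MAX_" in n and tf.parse_feature_name(n)[2] < 10.0][:10]
        idx = [names.index(n) for n in informative]
        x = rng.standard_normal((160, len(names)))
        y = np.arange(160) % 2
        x[np.flatnonzero(y == 1)[:, None], idx] += 2.0
        t = fsel.FeatureTable(x, names, [f"S{i}" for i in range(160)],
                              ["AS" if v else "NON_AS" for v in y])
        result = fsel.elastic_net_select(t, seed=0)
        s = fsel.summarize_selection(result)
        assert s.frequency_bands["<10 Hz"] > result.n_selected / 2
        assert max(s.statistic_counts, key=s.statistic_counts.get) == "MAX"
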