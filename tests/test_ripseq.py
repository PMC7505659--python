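"""CPM normalization, IP enrichment scoring, and client classification."""

import numpy as np
import pandas as pd
import pytest

from xlrip import (
    CountMatrix,
    CountSimSpec,
    RunConfig,
    SampleSheet,
    client_set,
    cpm,
    enrichment_scores,
    floor_filter,
    simulate_counts,
    tmd_summary,
)
from xlrip.errors import ConfigError, DataError
from xlrip.ripseq import log2_display
from xlrip.synthetic import ClassEffect


def _matrix(counts: dict, genes=None):
    roles = {"f": "flag_ip", "c": "ctrl_ip", "i": "input"}
    sheet = SampleSheet(frame=pd.DataFrame({
        "sample_id": list(counts),
        "role": [roles[s[0]] for s in counts],
        "replicate": [int(s[1:]) for s in counts],
    }))
    n = len(next(iter(counts.values())))
    index = pd.Index(genes or [f"g{j}" for j in range(n)], name="gene_id")
    return CountMatrix(counts=pd.DataFrame(counts, index=index), sheet=sheet)


class TestCPM:
    def test_single_gene_gets_full_million(self):
        m = cpm(_matrix({"f1": [7], "c1": [3], "i1": [11]}))
        assert np.allclose(m.counts.values, 1e6, atol=1e-6)

    def test_two_gene_arithmetic(self):
        m = cpm(_matrix({"f1": [1, 3], "c1": [1, 3], "i1": [1, 3]}))
        assert list(m.counts["f1"]) == [250000.0, 750000.0]

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(1)
        m = cpm(_matrix({"f1": rng.integers(0, 50, 30), "c1": rng.integers(0, 50, 30),
                         "i1": rng.integers(1, 50, 30)}))
        assert np.allclose(m.counts.sum(axis=0), 1e6, atol=1e-6)

    def test_zero_sum_column_names_sample(self):
        with pytest.raises(DataError, match="c1"):
            cpm(_matrix({"f1": [1], "c1": [0], "i1": [1]}))


class TestEnrichmentScores:
    def test_printed_formula_arithmetic(self, cfg):
        """mean flag 10, ctrl 4, input 2 (CPM) -> (10-4)/2 = 3.0 exactly."""
        m = _matrix({"f1": [10.0, 1.0], "c1": [4.0, 7.0], "i1": [2.0, 5.0]})
        m.unit = "cpm"
        table = enrichment_scores(m, cfg)
        assert table.frame.loc[0, "enrichment"] == 3.0

    def test_equal_ip_means_give_zero(self, cfg):
        m = _matrix({"f1": [5.0, 2.0], "f2": [3.0, 2.0], "c1": [4.0, 1.0],
                     "c2": [4.0, 3.0], "i1": [2.0, 2.0]})
        m.unit = "cpm"
        table = enrichment_scores(m, cfg)
        assert table.frame.loc[0, "enrichment"] == 0.0  # (4-4)/2

    def test_replicate_means_on_cpm_scale(self, cfg):
        m = _matrix({"f1": [12.0], "f2": [8.0], "c1": [4.0], "i1": [2.0]})
        m.unit = "cpm"
        assert enrichment_scores(m, cfg).frame.loc[0, "enrichment"] == 3.0

    def test_zero_input_left_unscored(self, cfg):
        m = _matrix({"f1": [10.0, 10.0], "c1": [4.0, 4.0], "i1": [0.0, 2.0]})
        m.unit = "cpm"
        table = enrichment_scores(m, cfg)
        assert np.isnan(table.frame.loc[0, "enrichment"])
        assert np.isnan(table.frame.loc[0, "rank"])

    def test_missing_role_rejected(self, cfg):
        sheet = SampleSheet(frame=pd.DataFrame({
            "sample_id": ["f1", "c1"], "role": ["flag_ip", "ctrl_ip"],
            "replicate": [1, 1],
        }))
        m = CountMatrix(
            counts=pd.DataFrame({"f1": [1.0], "c1": [1.0]},
                                index=pd.Index(["g0"], name="gene_id")),
            sheet=sheet, unit="cpm",
        )
        with pytest.raises(ConfigError, match="input"):
            enrichment_scores(m, cfg)

    def test_depth_invariance(self, cfg):
        """Multiplying all counts in every sample by a constant changes no
        score: CPM cancels sequencing depth."""
        rng = np.random.default_rng(3)
        raw = {s: rng.integers(1, 200, 40) for s in ("f1", "f2", "c1", "c2", "i1")}
        t1 = enrichment_scores(cpm(_matrix(raw)), cfg)
        t2 = enrichment_scores(cpm(_matrix({s: v * 17 for s, v in raw.items()})), cfg)
        pd.testing.assert_series_equal(t1.frame["enrichment"], t2.frame["enrichment"])


class TestFloorFilter:
    def _table(self, cfg, cpms):
        m = _matrix({"f1": cpms, "c1": cpms, "i1": cpms})
        m.unit = "cpm"
        return enrichment_scores(m, cfg)

    def test_floor_is_strict(self, cfg):
        table = self._table(cfg, [0.5, 0.51, 0.49, 7.0])
        flags = list(table.frame["passes_floor"])
        assert flags == [False, True, False, True]  # 0.5 exactly is excluded
        filtered = floor_filter(table, cfg)
        assert list(filtered.frame["gene_id"]) == ["g1", "g3"]

    def test_all_failing_leaves_empty_table(self, cfg, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="xlrip"):
            filtered = floor_filter(self._table(cfg, [0.1, 0.2]), cfg)
        assert filtered.frame.empty
        assert "floor" in caplog.text


class TestClientSet:
    def _table(self, cfg):
        m = _matrix({"f1": [40.0, 30.0, 20.0, 10.0], "c1": [0.0] * 4,
                     "i1": [10.0] * 4})
        m.unit = "cpm"
        return enrichment_scores(m, cfg)

    def test_top_n(self, cfg):
        table = self._table(cfg)
        assert client_set(table, "top_n", 0) == []
        assert client_set(table, "top_n", 2) == ["g0", "g1"]

    def test_top_n_larger_than_table_returns_all(self, cfg):
        assert len(client_set(self._table(cfg), "top_n", 99)) == 4

    def test_score_threshold_at_max_keeps_argmax_only(self, cfg):
        table = self._table(cfg)
        scores = table.frame["enrichment"]
        just_below = float(scores.max()) - 1e-9
        assert client_set(table, "score_threshold", just_below) == ["g0"]

    def test_ties_break_by_gene_id(self, cfg):
        m = _matrix({"f1": [10.0, 10.0, 10.0], "c1": [0.0] * 3, "i1": [5.0] * 3},
                    genes=["g_c", "g_a", "g_b"])
        m.unit = "cpm"
        table = enrichment_scores(m, cfg)
        assert client_set(table, "top_n", 2) == ["g_a", "g_b"]


class TestTMDSummary:
    def _annotated_table(self, cfg, tmds):
        n = len(tmds)
        m = _matrix({"f1": [10.0] * n, "c1": [1.0] * n, "i1": [5.0] * n})
        m.unit = "cpm"
        annot = pd.DataFrame({
            "gene_id": [f"g{j}" for j in range(n)],
            "is_secretory_membrane": [t > 0 for t in tmds],
            "n_tmd": tmds,
            "category": ["transporter" if t >= 4 else "other" for t in tmds],
        })
        return enrichment_scores(m, cfg, annotation=annot)

    def test_uniform_class_fills_one_bin(self, cfg):
        table = self._annotated_table(cfg, [12] * 6)
        summary = tmd_summary([f"g{j}" for j in range(6)], table)
        assert summary.proportions.loc[12, "client"] == 1.0
        assert summary.multipass_fraction_client == 1.0

    def test_client_equal_background_gives_identical_distributions(self, cfg):
        tmds = [1, 2, 4, 7, 14, 0]
        table = self._annotated_table(cfg, tmds)
        summary = tmd_summary([f"g{j}" for j in range(len(tmds))], table)
        pd.testing.assert_series_equal(
            summary.proportions["client"], summary.proportions["background"],
            check_names=False,
        )

    def test_proportions_sum_to_one(self, cfg):
        table = self._annotated_table(cfg, [1, 2, 3, 4, 9, 15, 20])
        summary = tmd_summary([f"g{j}" for j in range(7)], table)
        assert summary.proportions["client"].sum() == pytest.approx(1.0, abs=1e-9)
        # counts beyond the last integer bin pool into "14+"
        assert summary.proportions.loc["14+", "client"] == pytest.approx(2 / 7)

    def test_category_tabulation(self, cfg):
        table = self._annotated_table(cfg, [4, 5, 1])
        summary = tmd_summary(["g0", "g1", "g2"], table)
        assert summary.category_counts["transporter"] == 2


class TestNullSimulation:
    def test_no_planted_effect_shows_no_class_excess(self, cfg):
        """Null generator: scores are sign-symmetric and the multi-pass
        fraction of a top-n client set matches the background within 3 SE."""
        effects = {
            "soluble": ClassEffect(0.4, 0.4, 0.5, (), ("soluble",)),
            "single": ClassEffect(0.4, 0.4, 0.3, (1,), ("other",)),
            "multi": ClassEffect(0.4, 0.4, 0.2, (4, 6, 8), ("transporter",)),
        }
        spec = CountSimSpec(n_genes=1200, effects=effects, rng_seed=42)
        matrix, _, annot = simulate_counts(spec)
        table = enrichment_scores(cpm(matrix), cfg, annotation=annot)
        frame = table.frame[table.frame["passes_floor"]]
        frac_pos = (frame["enrichment"] > 0).mean()
        assert abs(frac_pos - 0.5) <= 3 * np.sqrt(0.25 / len(frame))

        clients = client_set(table, "top_n", 300)
        summary = tmd_summary(clients, table)
        p_bg = summary.multipass_fraction_background
        se = np.sqrt(p_bg * (1 - p_bg) / 300)
        assert abs(summary.multipass_fraction_client - p_bg) <= 3 * se

    def test_planted_class_ordering_recovered_across_seeds(self, cfg):
        """Multi-pass mean enrichment exceeds single-pass in 20/20 runs."""
        for seed in range(20):
            matrix, _, annot = simulate_counts(
                CountSimSpec(n_genes=600, rng_seed=1000 + seed)
            )
            table = enrichment_scores(cpm(matrix), cfg, annotation=annot)
            by_class = table.frame.groupby("sim_class")["enrichment"].mean()
            assert by_class["multi_pass"] > by_class["few_pass"] > by_class["single_pass"]


class TestBatchCenter:
    def _batched(self, base):
        from xlrip.ripseq import batch_center
        sheet = SampleSheet(frame=pd.DataFrame({
            "sample_id": ["f1", "f2", "c1", "c2", "i1", "i2"],
            "role": ["flag_ip"] * 2 + ["ctrl_ip"] * 2 + ["input"] * 2,
            "replicate": [1, 2] * 3,
            "batch": ["x", "y"] * 3,
        }))
        m = CountMatrix(
            counts=pd.DataFrame(base, columns=sheet.sample_ids,
                                index=pd.Index([f"g{i}" for i in range(len(base))],
                                               name="gene_id")),
            sheet=sheet,
        )
        return batch_center(cpm(m))

    def test_removes_per_gene_batch_offsets(self):
        rng = np.random.default_rng(5)
        base = rng.integers(50, 500, (25, 6)).astype(float)
        centered = self._batched(base)
        log_cpm = np.log1p(centered.counts)
        batch_x = log_cpm[["f1", "c1", "i1"]].mean(axis=1)
        batch_y = log_cpm[["f2", "c2", "i2"]].mean(axis=1)
        assert np.allclose(batch_x, batch_y, atol=1e-9)

    def test_single_batch_passes_through(self, cfg):
        from xlrip.ripseq import batch_center
        m = _matrix({"f1": [5, 9], "c1": [4, 2], "i1": [3, 3]})
        assert batch_center(m) is m


def test_log2_display_transform_is_odd_and_labeled_display_only():
    x = np.array([-3.0, 0.0, 3.0])
    y = log2_display(x)
    assert y[1] == 0.0
    assert y[0] == -y[2] == -2.0
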