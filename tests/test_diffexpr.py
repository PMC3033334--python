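"""Detection calls and concordance differential expression."""

import numpy as np
import pandas as pd
import pytest

import stageset as ss
from stageset.diffexpr import DEConfig, required_concordant_count, marker_panel
from stageset.io import SampleSheet
from stageset.simulate import PlantedBlock, SyntheticSpec


def _tiny_sheet(n_cond=2, n_rep=3):
    conds = [c for c in ("G9", "G22", "S9", "S22")[:n_cond] for _ in range(n_rep)]
    reps = list(range(1, n_rep + 1)) * n_cond
    return SampleSheet(
        tuple(f"{c}_r{r}" for c, r in zip(conds, reps)), tuple(conds), tuple(reps)
    )


def _probe_matrix(values_by_gene, sheet, min_probes=1):
    """values_by_gene: {gene: (n_probes, n_samples) array}."""
    ids, probes, rows = [], [], []
    for g, v in values_by_gene.items():
        v = np.asarray(v, float)
        ids += [g] * v.shape[0]
        probes += list(range(1, v.shape[0] + 1))
        rows.append(v)
    return ss.ExpressionMatrix(
        feature_ids=np.array(ids, dtype=object),
        values=np.vstack(rows),
        samples=sheet,
        probe_index=np.array(probes),
        min_probes=min_probes,
    )


class TestSummarizeSignal:
    def test_median_of_probes(self):
        sheet = _tiny_sheet()
        v = np.tile(np.array([[1.0], [2.0], [3.0], [4.0], [100.0]]), (1, 6))
        m = _probe_matrix({"g": v}, sheet)
        sig = ss.summarize_signal(m, "median")
        assert (sig.loc["g"] == 3.0).all()

    def test_single_probe_identity(self):
        sheet = _tiny_sheet()
        m = _probe_matrix({"g": np.full((1, 6), 42.0)}, sheet)
        assert (ss.summarize_signal(m).loc["g"] == 42.0).all()

    def test_zero_noise_gene_recovers_baseline(self):
        spec = SyntheticSpec(
            n_genes=5,
            noise_sd_log2=0.0,
            gene_sd_log2=0.0,
            probe_affinity_sd_log2=0.0,
            absent_fraction=0.0,
            baseline_log2_mean=7.0,
            seed=0,
        )
        matrix, _, _ = ss.generate(spec)
        sig = ss.summarize_signal(matrix)
        np.testing.assert_allclose(sig.to_numpy(), 2.0**7.0, rtol=1e-12)

    def test_gene_level_passthrough(self):
        sheet = _tiny_sheet()
        m = ss.ExpressionMatrix(
            feature_ids=np.array(["a", "b"], dtype=object),
            values=np.arange(12.0).reshape(2, 6),
            samples=sheet,
        )
        np.testing.assert_array_equal(ss.summarize_signal(m).to_numpy(), m.values)


class TestDetectionCall:
    def test_probes_at_background_are_absent(self):
        sheet = _tiny_sheet()
        m = _probe_matrix({"g": np.full((11, 6), 16.0)}, sheet)
        det = ss.detection_call(m, 16.0)
        assert (det["status"] == "Absent").all()
        assert (det["detection_p"] == 1.0).all()

    def test_probes_far_above_background_reach_minimal_p(self):
        sheet = _tiny_sheet()
        m = _probe_matrix({"g": np.full((11, 6), 4096.0)}, sheet)
        det = ss.detection_call(m, 16.0)
        assert (det["status"] == "Present").all()
        # one-sided exact signed-rank floor at n = 11: 1 / 2**11
        assert det["detection_p"].unique() == pytest.approx(2.0**-11)

    def test_planted_absent_genes_called_absent(self):
        spec = SyntheticSpec(
            n_genes=200, noise_sd_log2=0.25, absent_fraction=0.5, seed=21
        )
        matrix, truth, _ = ss.generate(spec)
        det = ss.detection_call(matrix, spec.background_level)
        absent = det[det["feature_id"].isin(truth.absent_genes())]
        assert (absent["status"] == "Absent").mean() >= 0.95

    def test_too_few_probes_conservatively_absent(self):
        sheet = _tiny_sheet()
        m = _probe_matrix({"g": np.full((2, 6), 4096.0)}, sheet)
        det = ss.detection_call(m, 16.0)
        assert (det["status"] == "Absent").all()
        assert (det["detection_p"] == 1.0).all()


class TestPairwiseChangeCalls:
    def test_three_by_three_replicates_give_nine_calls(self, small_data):
        matrix, _, _ = small_data
        calls = ss.pairwise_change_calls(matrix, "G9", "G22")
        assert (calls.groupby("feature_id").size() == 9).all()

    def test_self_comparison_is_nochange(self):
        sheet = _tiny_sheet()
        rng = np.random.default_rng(0)
        v = np.tile(rng.gamma(3, 40, size=(11, 1)), (1, 6))  # identical samples
        m = _probe_matrix({"g": v}, sheet)
        calls = ss.pairwise_change_calls(m, "G9", "G22")
        assert (calls["direction"] == "NoChange").all()
        assert (calls["change_p"] == 1.0).all()

    def test_planted_fourfold_zero_noise_gives_nine_increases(self):
        spec = SyntheticSpec(
            n_genes=12,
            noise_sd_log2=0.0,
            planted_blocks=(PlantedBlock("G9_sel", ("G9",), 4, 2.0),),
            absent_fraction=0.0,
            seed=5,
        )
        matrix, truth, _ = ss.generate(spec)
        calls = ss.pairwise_change_calls(matrix, "G9", "S9")
        for gene in truth.selective_genes("G9"):
            sub = calls[calls["feature_id"] == gene]
            assert (sub["direction"] == "Increase").all() and len(sub) == 9

    def test_unknown_condition_label_raises(self, small_data):
        matrix, _, _ = small_data
        with pytest.raises(KeyError):
            ss.pairwise_change_calls(matrix, "G9", "Mars")

    def test_antisymmetry_of_swapped_comparison(self, small_data):
        matrix, _, _ = small_data
        fwd = ss.differential_expression(matrix, "G9", "S9").set_index("feature_id")
        rev = ss.differential_expression(matrix, "S9", "G9").set_index("feature_id")
        pd.testing.assert_series_equal(
            fwd["n_increase"], rev["n_decrease"], check_names=False
        )
        meaningful = fwd["fold_change"] * rev["fold_change"]
        # fold inverts wherever the denominator floor never engaged
        sig = ss.summarize_signal(matrix)
        ok = (sig.mean(axis=1) > 2.0).reindex(fwd.index)
        np.testing.assert_allclose(meaningful[ok], 1.0, rtol=1e-9)


class TestConcordanceSelect:
    def test_required_count_at_published_cutoff(self):
        assert required_concordant_count(9, 0.77) == 7
        assert required_concordant_count(9, 0.60) == 6
        assert required_concordant_count(4, 0.77) == 4

    def _records(self, n_inc, n_dec, fold):
        sheet = _tiny_sheet()
        directions = (
            ["Increase"] * n_inc + ["Decrease"] * n_dec + ["NoChange"] * (9 - n_inc - n_dec)
        )
        calls = pd.DataFrame(
            {
                "feature_id": ["g"] * 9,
                "exp_sample": [s for s in sheet.samples_of("G9") for _ in range(3)],
                "ref_sample": sheet.samples_of("G22") * 3,
                "direction": directions,
                "change_p": [0.01 if d != "NoChange" else 0.8 for d in directions],
            }
        )
        base = 100.0
        sig = pd.DataFrame(
            [[base * fold] * 3 + [base] * 3],
            index=["g"],
            columns=list(sheet.sample_ids),
        )
        return ss.concordance_select(calls, sig, "G9", "G22", sheet)

    def test_six_of_nine_not_selected(self):
        rec = self._records(6, 0, 3.1).iloc[0]
        assert rec["concordance"] == pytest.approx(6 / 9)
        assert not rec["selected"]

    def test_fold_change_filter_blocks_selection(self):
        rec = self._records(8, 0, 1.8).iloc[0]
        assert not rec["selected"] and rec["direction"] == "None"

    def test_seven_of_nine_with_twofold_selected(self):
        rec = self._records(7, 1, 2.4).iloc[0]
        assert rec["selected"] and rec["direction"] == "Up"
        assert rec["n_increase"] + rec["n_decrease"] + rec["n_nochange"] == rec["n_pairs"]

    def test_raising_thresholds_never_enlarges_selection(self, small_data):
        matrix, _, _ = small_data
        sel = {}
        for fc, cc in [(2.0, 0.77), (3.0, 0.77), (2.0, 0.89), (3.0, 0.89)]:
            cfg = DEConfig(fc_threshold=fc, concordance_cutoff=cc)
            rec = ss.differential_expression(matrix, "G9", "S9", cfg)
            sel[(fc, cc)] = frozenset(rec[rec["selected"]]["feature_id"])
        assert sel[(3.0, 0.77)] <= sel[(2.0, 0.77)]
        assert sel[(2.0, 0.89)] <= sel[(2.0, 0.77)]
        assert sel[(3.0, 0.89)] <= sel[(2.0, 0.77)]


class TestMarkerPanel:
    def test_marker_statuses_and_presence(self, small_data):
        matrix, truth, _ = small_data
        cfg = DEConfig()
        sig = ss.summarize_signal(matrix)
        det = ss.detection_call(matrix, 16.0, cfg)
        rec = ss.differential_expression(matrix, "G9", "S9", cfg, signals=sig)
        up_gene = sorted(truth.selective_genes("G9"))[0]
        down_gene = sorted(truth.selective_genes("S9"))[0]
        absent_gene = sorted(truth.absent_genes())[0]
        markers = ss.GeneSetCollection(
            sets={
                "panel": frozenset({up_gene, down_gene, absent_gene, "not_on_array"})
            }
        )
        rep = marker_panel(rec, det, markers, matrix.samples, "G9", "S9").set_index(
            "feature_id"
        )
        assert rep.loc[up_gene, "status"] == "Up"
        assert rep.loc[down_gene, "status"] == "Down"
        assert rep.loc["not_on_array", "status"] == "not represented"
        assert rep.loc[absent_gene, ["present_G9", "present_S9"]].sum() <= 1
        assert rep.loc[up_gene, "present_G9"] == 3
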