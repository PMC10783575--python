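"""Direct-substrate calling, subset reports, enrichment and occupancy ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ksubinfer as ks
from ksubinfer import refdata
from ksubinfer.motif import CAMK2_MOTIF
from ksubinfer.target_inference import (MODE_STRICT, MODE_TABLE,
                                        call_direct_targets,
                                        characterize_indirect,
                                        fisher_enrichment,
                                        invitro_phospho_ratio, subset_report)


class TestDirectCalls:
    def test_published_direct_targets_all_called(self):
        calls = call_direct_targets(refdata.camk2d_direct_targets(),
                                    CAMK2_MOTIF, mode=MODE_TABLE)
        assert calls["is_direct"].all()
        assert len(calls) == 35

    def test_positive_effect_never_direct(self):
        row = pd.DataFrame({"log2_effect": [0.5], "p_joint": [1e-6],
                            "sequence_13": ["VLHKSKSEEAHAE"]}, index=["x"])
        for mode in (MODE_STRICT, MODE_TABLE):
            calls = call_direct_targets(row, CAMK2_MOTIF, mode=mode)
            assert calls["passes_motif"].iloc[0]
            assert not calls["is_direct"].iloc[0]

    def test_excluded_or_underquantified_sites_ineligible(self):
        rows = pd.DataFrame({
            "log2_effect": [-0.5, -0.5, -0.5],
            "p_joint": [1e-5, 1e-5, 1e-5],
            "sequence_13": ["VLHKSKSEEAHAE"] * 3,
        }, index=["ok", "excl", "thin"])
        statuses = pd.Series({"ok": "down", "excl": "excluded_protein_change",
                              "thin": "insufficient_replicates"})
        calls = call_direct_targets(rows, CAMK2_MOTIF, statuses=statuses)
        assert calls.loc["ok", "is_direct"]
        assert not calls.loc["excl", "is_direct"]
        assert not calls.loc["thin", "is_direct"]

    def test_missing_sequence_reported_not_called(self):
        rows = pd.DataFrame({"log2_effect": [-0.6], "p_joint": [1e-5],
                             "sequence_13": [None]}, index=["s"])
        calls = call_direct_targets(rows, CAMK2_MOTIF)
        assert calls["passes_significance"].iloc[0]
        assert pd.isna(calls["passes_motif"].iloc[0])
        assert not calls["is_direct"].iloc[0]

    @pytest.mark.parametrize("alpha,effect", [(0.0005, 0.3), (0.0001, 0.3),
                                              (0.0005, 0.5), (0.0001, 0.5)])
    def test_tightening_thresholds_never_adds_calls(self, alpha, effect):
        table = refdata.camk2d_direct_targets()
        base = call_direct_targets(table, CAMK2_MOTIF, mode=MODE_TABLE)
        tighter = call_direct_targets(table, CAMK2_MOTIF, alpha_joint=alpha,
                                      effect_threshold=effect, mode=MODE_TABLE)
        assert tighter["is_direct"].sum() <= base["is_direct"].sum()
        assert set(tighter.index[tighter["is_direct"]]) <= \
            set(base.index[base["is_direct"]])

    def test_row_order_invariance(self):
        table = refdata.camk2d_kinase_sites()
        a = call_direct_targets(table, CAMK2_MOTIF, mode=MODE_TABLE)
        b = call_direct_targets(table.iloc[::-1], CAMK2_MOTIF, mode=MODE_TABLE)
        assert set(a.index[a["is_direct"]]) == set(b.index[b["is_direct"]])


class TestSubsetReport:
    def test_kinase_subset_has_single_direct_call(self):
        calls = call_direct_targets(refdata.camk2d_kinase_sites(),
                                    CAMK2_MOTIF, mode=MODE_TABLE)
        annotation = {g: "kinase" for g in calls["gene"]}
        report = subset_report(calls, annotation)
        assert len(report) == 19
        direct = report[report["is_direct"]]
        assert list(direct["gene"]) == ["Cdk18"]
        assert direct.iloc[0]["site"] == "S66"
        # Stk11 S31 passes the motif but misses the effect-size cut
        stk11 = report.loc["Stk11_S31"]
        assert stk11["passes_motif"] and not stk11["passes_significance"]

    def test_phosphatase_subset_has_no_direct_calls(self):
        calls = call_direct_targets(refdata.camk2d_phosphatase_sites(),
                                    CAMK2_MOTIF, mode=MODE_TABLE)
        report = subset_report(calls, {g: "phosphatase" for g in calls["gene"]})
        assert len(report) == 4 and not report["is_direct"].any()

    def test_empty_inputs_give_empty_report(self):
        calls = call_direct_targets(refdata.camk2d_kinase_sites(),
                                    CAMK2_MOTIF, mode=MODE_TABLE)
        assert subset_report(calls, {}).empty
        assert subset_report(calls.head(0), {"Cdk18": "kinase"}).empty


class TestFisherEnrichment:
    def test_query_equal_background_is_null(self):
        bg = {f"g{i}" for i in range(50)}
        ann = {"termA": {f"g{i}" for i in range(10)}}
        out = fisher_enrichment(bg, ann, bg)
        assert out.loc[0, "fold_enrichment"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_hypergeometric_tail_by_summation(self):
        # 4 hits in a query of 20, term of 10, background of 500
        bg = [f"g{i}" for i in range(500)]
        query = set(bg[:4]) | {f"g{i}" for i in range(100, 116)}
        term = set(bg[:10])
        out = fisher_enrichment(query, {"t": term}, bg)
        expected = sum(stats.hypergeom.pmf(k, 500, 10, 20) for k in range(4, 11))
        assert out.loc[0, "p_value"] == pytest.approx(expected, rel=1e-10)
        assert out.loc[0, "fold_enrichment"] == pytest.approx(
            (4 / 20) / (10 / 500))

    def test_zero_hit_term_never_flagged(self):
        bg = [f"g{i}" for i in range(100)]
        out = fisher_enrichment(set(bg[:10]), {"t": set(bg[50:60])}, bg)
        assert out.loc[0, "hits"] == 0
        assert out.loc[0, "fold_enrichment"] == 0.0
        assert not out.loc[0, "significant"]

    def test_query_outside_background_raises(self):
        with pytest.raises(ValueError, match="stranger"):
            fisher_enrichment({"stranger"}, {"t": {"a"}}, {"a", "b"})


class TestIndirectCharacterization:
    def test_planted_proline_sites_flagged(self):
        cfg = ks.SyntheticConfig(n_proteins=400, sites_per_protein=5,
                                 frac_direct=0.0, frac_indirect_up=0.05, seed=13)
        phospho, _, _, truth = ks.generate_experiment(cfg)
        up = truth.index[truth["class"] == "indirect_up"]
        table, summary = characterize_indirect(
            phospho.loc[up, "sequence_13"].tolist(),
            phospho["sequence_13"].tolist())
        assert summary["proline_plus1_enriched"]

    def test_foreground_equal_background_flags_nothing(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 13))
                for _ in range(60)]
        table, summary = characterize_indirect(seqs, list(seqs))
        assert not summary["proline_plus1_enriched"]
        assert not table["enriched"].any()

    def test_empty_up_set_is_not_an_error(self):
        table, summary = characterize_indirect([], ["AAAAAASAAAAAA"])
        assert table.empty and summary["n_up"] == 0


class TestInvitroRatios:
    def _table(self, groups):
        rows = []
        for dose, ratios in groups.items():
            for r in ratios:
                rows.append((dose, r * 1e6, 1e6))
        return pd.DataFrame(rows, columns=["dose", "phospho_intensity",
                                           "total_intensity"])

    def test_zero_phospho_gives_zero_ratio(self):
        table, _ = invitro_phospho_ratio(self._table(
            {0: [0.0, 0.0], 1: [0.5, 0.6]}))
        assert (table.loc[table["dose"] == 0, "ratio"] == 0.0).all()

    def test_identical_ratios_give_p_one(self):
        _, p = invitro_phospho_ratio(self._table({0: [0.4, 0.4, 0.4],
                                                  1: [0.4, 0.4, 0.4]}))
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_f_statistic(self):
        groups = {0: [0.0, 0.0, 0.0], 1: [0.4, 0.5, 0.45], 2: [0.8, 0.85, 0.9]}
        _, p = invitro_phospho_ratio(self._table(groups))
        data = [np.array(v) for v in groups.values()]
        grand = np.concatenate(data).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
        df_b, df_w = len(data) - 1, sum(len(g) for g in data) - len(data)
        f = (ss_between / df_b) / (ss_within / df_w)
        assert p == pytest.approx(stats.f.sf(f, df_b, df_w), abs=1e-10)

    def test_zero_total_flagged_and_dropped(self):
        table = self._table({0: [0.1, 0.2, 0.3], 1: [0.5, 0.6, 0.7]})
        table.loc[0, "total_intensity"] = 0.0
        out, p = invitro_phospho_ratio(table)
        assert out.loc[0, "flagged"] and np.isnan(out.loc[0, "ratio"])
        assert np.isfinite(p)

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 dose groups"):
            invitro_phospho_ratio(self._table({0: [0.1, 0.2, 0.3]}))
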