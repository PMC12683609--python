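import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gsemkit as gk
from gsemkit import presets
from gsemkit.ldblocks import build_ld_panels
from gsemkit.sumstats import (
    SchemaError,
    SumstatsTable,
    expected_chisq_tail,
    harmonize,
    merge_panel,
    qc_filter,
    read_sumstats,
    write_sumstats,
)
from gsemkit.synthetic import simulate_sumstats


def _table(rows, **kwargs):
    df = pd.DataFrame(rows, columns=["SNP", "A1", "A2", "Z", "N"])
    return SumstatsTable(data=df, **kwargs)


class TestReadSumstats:
    def test_basic_read(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("SNP\tA1\tA2\tZ\tN\nrs1\tA\tG\t1.0\t100\n"
                        "rs2\tA\tG\t-2.0\t100\nrs3\tA\tG\t0.5\t100\n")
        tab = read_sumstats(path)
        assert len(tab) == 3

    def test_nan_z_dropped_and_logged(self, tmp_path):
        lines = ["SNP\tA1\tA2\tZ\tN"]
        for i in range(10):
            z = "NA" if i == 4 else "1.0"
            lines.append(f"rs{i}\tA\tG\t{z}\t100")
        path = tmp_path / "ss.tsv"
        path.write_text("\n".join(lines) + "\n")
        tab = read_sumstats(path)
        assert len(tab) == 9
        assert tab.log["n_dropped_missing"] == 1

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("SNP\tA1\tA2\tN\nrs1\tA\tG\t100\n")
        with pytest.raises(SchemaError, match="Z"):
            read_sumstats(path)

    def test_duplicate_variant_id_rejected(self):
        with pytest.raises(SchemaError, match="rs1"):
            _table([("rs1", "A", "G", 1.0, 100), ("rs1", "A", "G", 2.0, 100)])

    def test_column_map(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("rsid\tEA\tOA\tzscore\tn\nrs1\tA\tG\t1.0\t100\n")
        tab = read_sumstats(path, column_map={
            "rsid": "SNP", "EA": "A1", "OA": "A2", "zscore": "Z", "n": "N"})
        assert len(tab) == 1

    def test_scramble_round_trip(self, tmp_path, small_design):
        sc = presets.overlap_pair_scenario(seed=2, design=small_design)
        tables, _ = simulate_sumstats(sc, scramble=True)
        tab = SumstatsTable(data=tables[0], trait="T1")
        write_sumstats(tab, tmp_path / "rt.tsv")
        back = read_sumstats(tmp_path / "rt.tsv")
        pd.testing.assert_frame_equal(
            back.data[["SNP", "A1", "A2", "N"]], tab.data[["SNP", "A1", "A2", "N"]])
        assert np.allclose(back.data["Z"], tab.data["Z"])


class TestHarmonize:
    REF = pd.DataFrame({"SNP": ["rs1"], "A1": ["A"], "A2": ["G"]})

    def test_swapped_alleles_negate_z(self):
        tab = _table([("rs1", "G", "A", 1.7, 100)])
        out = harmonize([tab], self.REF)[0]
        assert out.data.loc[0, "A1"] == "A"
        assert out.data.loc[0, "Z"] == pytest.approx(-1.7)

    def test_strand_flip_keeps_z(self):
        tab = _table([("rs1", "T", "C", 0.9, 100)])
        out = harmonize([tab], self.REF)[0]
        assert out.data.loc[0, "A1"] == "A"
        assert out.data.loc[0, "Z"] == pytest.approx(0.9)

    def test_strand_flip_and_swap_negates(self):
        tab = _table([("rs1", "C", "T", 0.9, 100)])
        out = harmonize([tab], self.REF)[0]
        assert out.data.loc[0, "Z"] == pytest.approx(-0.9)

    def test_ambiguous_and_irreconcilable_removed(self):
        ref = pd.DataFrame({"SNP": ["rs1", "rs2", "rs3"],
                            "A1": ["A", "A", "A"], "A2": ["G", "G", "G"]})
        tab = _table([("rs1", "A", "T", 1.0, 100),   # ambiguous
                      ("rs2", "C", "A", 1.0, 100),   # irreconcilable
                      ("rs3", "A", "G", 1.0, 100)])
        out = harmonize([tab], ref)[0]
        assert list(out.data["SNP"]) == ["rs3"]
        assert out.log["harmonize"]["strand_ambiguous"] == 1
        assert out.log["harmonize"]["irreconcilable"] == 1

    def test_idempotent(self, small_design):
        sc = presets.overlap_pair_scenario(seed=4, design=small_design)
        tables, _ = simulate_sumstats(sc, scramble=True)
        tabs = [SumstatsTable(data=t, trait=f"T{i}") for i, t in enumerate(tables)]
        ref = pd.DataFrame({"SNP": tabs[0].data["SNP"], "A1": "A", "A2": "G"})
        once = harmonize(tabs, ref)
        twice = harmonize(once, ref)
        for a, b in zip(once, twice):
            pd.testing.assert_frame_equal(a.data, b.data)

    def test_sign_consistency_invariant(self, small_design):
        """Negating all Z and swapping alleles of one input yields the
        same harmonized panel."""
        sc = presets.overlap_pair_scenario(seed=6, design=small_design)
        tables, _ = simulate_sumstats(sc)
        ref = pd.DataFrame({"SNP": tables[0]["SNP"], "A1": "A", "A2": "G"})
        flipped = tables[0].copy()
        flipped["A1"], flipped["A2"] = tables[0]["A2"], tables[0]["A1"]
        flipped["Z"] = -tables[0]["Z"]
        a = harmonize([SumstatsTable(data=tables[0])], ref)[0]
        b = harmonize([SumstatsTable(data=flipped)], ref)[0]
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_scrambled_harmonizes_back_to_clean(self, small_design):
        sc = presets.overlap_pair_scenario(seed=8, design=small_design)
        clean, _ = simulate_sumstats(sc)
        scrambled, _ = simulate_sumstats(sc, scramble=True)
        ref = pd.DataFrame({"SNP": clean[0]["SNP"], "A1": "A", "A2": "G"})
        out = harmonize([SumstatsTable(data=scrambled[0])], ref)[0]
        merged = out.data.merge(clean[0], on="SNP", suffixes=("", "_true"))
        assert np.allclose(merged["Z"], merged["Z_true"])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.sampled_from(["AG", "GA", "TC", "CT", "AT", "CG", "CA"]),
                    min_size=1, max_size=12))
    def test_harmonize_idempotent_property(self, alleles):
        rows = [(f"rs{i}", a[0], a[1], 1.0, 100) for i, a in enumerate(alleles)]
        ref = pd.DataFrame({"SNP": [f"rs{i}" for i in range(len(alleles))],
                            "A1": "A", "A2": "G"})
        once = harmonize([_table(rows)], ref)
        twice = harmonize(once, ref)
        pd.testing.assert_frame_equal(once[0].data, twice[0].data)


class TestQcFilter:
    def test_max_chisq_removes_large_z(self):
        tab = _table([("rs1", "A", "G", 10.0, 100), ("rs2", "A", "G", 1.0, 100)])
        out = qc_filter(tab, max_chisq=80)
        assert list(out.data["SNP"]) == ["rs2"]

    def test_missing_optional_columns_skipped_with_warning(self, caplog):
        tab = _table([("rs1", "A", "G", 1.0, 100)])
        with caplog.at_level("WARNING"):
            out = qc_filter(tab, max_chisq=30)
        assert len(out) == 1
        assert "maf filter skipped" in caplog.text.lower()

    @pytest.mark.parametrize("cutoff", [4.0, 30.0])
    def test_null_removal_fraction_matches_chi2_tail(self, cutoff, small_design):
        sc = presets.single_trait_scenario(seed=9, h2=1e-12,
                                           design=presets.default_design())
        tables, _ = simulate_sumstats(sc)
        tab = SumstatsTable(data=tables[0])
        out = qc_filter(tab, max_chisq=cutoff)
        frac = 1 - len(out) / len(tab)
        p = expected_chisq_tail(cutoff)
        mc_sd = np.sqrt(max(p * (1 - p), 1e-12) / len(tab))
        assert abs(frac - p) < max(3 * mc_sd, 2 / len(tab))


class TestMergePanel:
    def _two_tables_and_panels(self, small_design):
        sc = presets.overlap_pair_scenario(seed=3, design=small_design)
        tables, _ = simulate_sumstats(sc)
        tabs = [SumstatsTable(data=t, trait=f"T{i}", population="POP")
                for i, t in enumerate(tables)]
        p1, _, _ = build_ld_panels(small_design)
        return tabs, {"POP": p1}

    def test_intersection(self, small_design):
        tabs, panels = self._two_tables_and_panels(small_design)
        tabs[0].data.drop(index=range(2), inplace=True)
        panel = merge_panel(tabs, panels, n_blocks=10)
        assert panel.n_variants == small_design.M - 2

    def test_missing_context_error_names_pair(self, small_design):
        tabs, panels = self._two_tables_and_panels(small_design)
        tabs[1].population = "OTHER"
        with pytest.raises(KeyError, match="OTHER"):
            merge_panel(tabs, panels)

    def test_empty_intersection_error(self, small_design):
        tabs, panels = self._two_tables_and_panels(small_design)
        tabs[1].data["SNP"] = "x" + tabs[1].data["SNP"]
        with pytest.raises(ValueError, match="empty"):
            merge_panel(tabs, panels)

    def test_synthetic_panel_no_loss_and_matches_direct(self, small_design):
        sc = presets.overlap_pair_scenario(seed=12, design=small_design)
        tables, _ = simulate_sumstats(sc)
        tabs = [SumstatsTable(data=t, trait=tr, population="POP")
                for t, tr in zip(tables, sc.traits)]
        p1, _, _ = build_ld_panels(small_design)
        merged = merge_panel(tabs, {"POP": p1}, n_blocks=small_design.n_blocks)
        direct, _ = gk.simulate_panel(sc)
        assert merged.n_variants == small_design.M
        assert np.allclose(merged.z, direct.z)
        assert np.allclose(merged.ld["POP"], direct.ld["POP"])
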