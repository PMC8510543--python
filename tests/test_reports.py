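"""Report tables: gene subsets, CD-vs-HO comparisons, correlations,
tRNA decomposition, placement summary, BH family bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from oriconflict.features import assign_to_cds
from oriconflict.genome import orientation_table
from oriconflict.rates import frequency_per_cds
from oriconflict.reports import (
    GeneSubset,
    apply_bh_family,
    comparison_table,
    correlation_table,
    delta_ho_ci,
    delta_ho_percent,
    placement_summary,
    poisson_ratio_ci,
    run_report,
    select_highly_expressed,
    subset_all,
    subset_by_category,
    trna_decomposition,
)


def _freq_frame(cd_values, ho_values, metric="indel_per_cds"):
    n_cd, n_ho = len(cd_values), len(ho_values)
    ids = [f"c{i}" for i in range(n_cd)] + [f"h{i}" for i in range(n_ho)]
    freq = pd.DataFrame({metric: list(cd_values) + list(ho_values)},
                        index=pd.Index(ids, name="gene_id"))
    ori = pd.DataFrame({"orientation": ["CD"] * n_cd + ["HO"] * n_ho},
                       index=freq.index)
    return freq, ori


class TestSelectHighlyExpressed:
    def test_hand_computed_threshold(self):
        """5 genes, one phase: log10 TPMs 1,1,1,1,3 -> mean 1.4, SD ~0.894;
        only the log10=3 gene clears mean + 1 SD = 2.294."""
        tpm = pd.DataFrame(
            {"tpm_lag": [10.0, 10.0, 10.0, 10.0, 1000.0],
             "tpm_log": [0.0] * 5, "tpm_stat": [0.0] * 5},
            index=pd.Index(list("abcde"), name="gene_id"),
        )
        sel = select_highly_expressed(tpm)
        assert sel.gene_ids == frozenset({"e"})

    def test_zero_tpm_never_selected(self):
        tpm = pd.DataFrame(
            {"tpm_lag": [0.0, 10.0, 100.0, 1000.0, 10000.0],
             "tpm_log": [0.0] * 5, "tpm_stat": [0.0] * 5},
            index=pd.Index(list("abcde"), name="gene_id"),
        )
        sel = select_highly_expressed(tpm)
        assert "a" not in sel.gene_ids

    def test_all_phases_subset_of_any_phase(self):
        rng = np.random.default_rng(30)
        tpm = pd.DataFrame(
            {ph: 10 ** rng.normal(1, 0.5, 200) for ph in ("tpm_lag", "tpm_log", "tpm_stat")},
            index=pd.Index([f"g{i}" for i in range(200)], name="gene_id"),
        )
        any_ = select_highly_expressed(tpm, mode="any_phase")
        all_ = select_highly_expressed(tpm, mode="all_phases")
        assert all_.gene_ids <= any_.gene_ids
        assert len(any_.gene_ids) > 0

    def test_selected_fraction_matches_normal_tail(self):
        """On lognormal TPMs the per-phase selected fraction is ~P(Z>=1)
        ~ 15.9%; the union over 3 weakly dependent phases is larger."""
        rng = np.random.default_rng(31)
        n = 4000
        base = rng.normal(1, 0.5, n)
        tpm = pd.DataFrame(
            {ph: 10 ** (base + rng.normal(0, 0.15, n))
             for ph in ("tpm_lag", "tpm_log", "tpm_stat")},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )
        frac = len(select_highly_expressed(tpm).gene_ids) / n
        assert 0.13 < frac < 0.30

    def test_all_zero_rejected(self):
        tpm = pd.DataFrame({"tpm_lag": [0.0, 0.0], "tpm_log": [0.0, 0.0],
                            "tpm_stat": [0.0, 0.0]},
                           index=pd.Index(["a", "b"], name="gene_id"))
        with pytest.raises(ValueError):
            select_highly_expressed(tpm)


class TestComparisonTable:
    def test_essential_gene_worked_example(self):
        """15 indels across 252 CD genes vs 16 across 106 HO genes gives
        means 0.06 and 0.15 and an HO excess of ~154%."""
        cd = np.zeros(252); cd[:15] = 1
        ho = np.zeros(106); ho[:16] = 1
        freq, ori = _freq_frame(cd, ho)
        rows = comparison_table(freq, ori, metrics=("indel_per_cds",))
        r = rows.iloc[0]
        assert round(r.mean_cd, 2) == 0.06
        assert round(r.mean_ho, 2) == 0.15
        assert round(r.delta_ho) == 154
        # exact bookkeeping: mean * n recovers the integer counts
        assert r.mean_cd * r.n_cd == pytest.approx(15)
        assert r.mean_ho * r.n_ho == pytest.approx(16)

    def test_identical_groups_give_zero_delta_and_p_one(self):
        v = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        freq, ori = _freq_frame(v, v)
        r = comparison_table(freq, ori, metrics=("indel_per_cds",)).iloc[0]
        assert r.delta_ho == pytest.approx(0.0)
        assert r.p_t == pytest.approx(1.0)

    def test_empty_class_flagged_not_crashed(self):
        freq, ori = _freq_frame([1.0, 2.0], [])
        r = comparison_table(freq, ori, metrics=("indel_per_cds",)).iloc[0]
        assert "NA" in r.flag
        assert np.isnan(r.p_t)

    def test_delta_ho_undefined_when_cd_mean_zero(self):
        assert delta_ho_percent(0.0, 1.0) is None

    def test_delta_ho_ci_covers_truth_under_null(self):
        rng = np.random.default_rng(32)
        cover = 0
        for _ in range(200):
            cd = rng.poisson(3, 150).astype(float)
            ho = rng.poisson(3, 150).astype(float)
            d, lo, hi = delta_ho_ci(cd, ho)
            if lo <= 0 <= hi:
                cover += 1
        assert cover / 200 >= 0.90


class TestCorrelationTable:
    def test_length_proportional_counts_correlate_strongly(self):
        """Counts Poisson-proportional to CDS length at the per-nt scale of
        ~6 BPS per 900 nt give Pearson rho >= 0.8 over 4,000 genes."""
        rng = np.random.default_rng(33)
        n = 4000
        lengths = rng.uniform(100, 3000, n)
        counts = rng.poisson(lengths * (6.0 / 900.0)).astype(float)
        ids = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
        freq = pd.DataFrame({"bps_per_cds": counts}, index=ids)
        ori = pd.DataFrame(
            {"orientation": np.where(rng.random(n) < 0.55, "CD", "HO")}, index=ids
        )
        rows = correlation_table(freq, ori, "cds_length",
                                 pd.Series(lengths, index=ids),
                                 metrics=("bps_per_cds",))
        r_all = rows.loc[rows["class"] == "All"].iloc[0]
        assert r_all.rho_pearson >= 0.8
        assert r_all.p_pearson < 1e-6

    def test_independent_predictor_gives_null_rho(self):
        rng = np.random.default_rng(34)
        n = 1000
        ids = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
        freq = pd.DataFrame({"bps_per_cds": rng.poisson(6, n).astype(float)}, index=ids)
        ori = pd.DataFrame({"orientation": ["CD"] * n}, index=ids)
        rows = correlation_table(freq, ori, "tpm", pd.Series(rng.uniform(1, 100, n), index=ids),
                                 metrics=("bps_per_cds",), log_predictor=True)
        assert abs(rows.loc[rows["class"] == "All"].iloc[0].rho_pearson) < 0.1

    def test_constant_predictor_flagged(self):
        ids = pd.Index([f"g{i}" for i in range(10)], name="gene_id")
        freq = pd.DataFrame({"bps_per_cds": np.arange(10.0)}, index=ids)
        ori = pd.DataFrame({"orientation": ["CD"] * 10}, index=ids)
        rows = correlation_table(freq, ori, "x", pd.Series(5.0, index=ids),
                                 metrics=("bps_per_cds",))
        r = rows.loc[rows["class"] == "All"].iloc[0]
        assert np.isnan(r.rho_pearson)
        assert "variance" in r.flag


class TestBhFamily:
    def test_single_comparison_unchanged(self):
        df = pd.DataFrame({"p_t": [0.03], "p_mw": [np.nan]})
        n = apply_bh_family({"t": df})
        assert n == 1
        assert df["p_t_adj"].iloc[0] == pytest.approx(0.03)

    def test_family_spans_all_tables(self):
        df1 = pd.DataFrame({"p_t": [0.01, 0.04], "p_mw": [0.02, np.nan]})
        df2 = pd.DataFrame({"p_pearson": [0.03]})
        n = apply_bh_family({"a": df1, "b": df2})
        assert n == 4
        from oriconflict.stats import benjamini_hochberg
        expected = benjamini_hochberg([0.01, 0.04, 0.02, 0.03])
        got = [df1["p_t_adj"][0], df1["p_t_adj"][1], df1["p_mw_adj"][0],
               df2["p_pearson_adj"][0]]
        assert got == pytest.approx(list(expected))


class TestTrnaDecomposition:
    def _frame(self, counts, orients):
        ids = pd.Index([f"t{i}" for i in range(len(counts))], name="gene_id")
        freq = pd.DataFrame({"n_bps": 0, "n_indel": counts}, index=ids)
        ori = pd.DataFrame({"orientation": orients}, index=ids)
        return freq, ori, GeneSubset("tRNA", frozenset(ids))

    def test_homogeneous_hotspot_counts(self):
        """Per-gene indels 23, 29, 25, 23 sum to 100 and pass the
        chi-square homogeneity test."""
        freq, ori, sub = self._frame([23, 29, 25, 23], ["HO", "HO", "HO", "CD"])
        dec = trna_decomposition(freq, ori, sub, ["t0", "t1", "t2", "t3"])
        assert dec["total_indels"] == 100
        assert dec["hotspot_indels"] == 100
        assert dec["chi2_p"] > 0.05

    def test_hotspot_placement_inflates_naive_ratio(self):
        # 3 HO hotspots + 1 CD hotspot among quiet tRNAs, even CD/HO split
        counts = [25, 25, 25, 25] + [0] * 36
        orients = ["HO", "HO", "HO", "CD"] + ["CD"] * 19 + ["HO"] * 17
        freq, ori, sub = self._frame(counts, orients)
        dec = trna_decomposition(freq, ori, sub, ["t0", "t1", "t2", "t3"])
        assert dec["ho_cd_indel_ratio"] == pytest.approx(3.0)
        # removing the hotspot genes removes the apparent bias entirely
        assert not (dec["ho_cd_indel_ratio_minus_hotspots"] > 1.0)

    def test_empty_trna_set_no_crash(self):
        ids = pd.Index([], name="gene_id")
        freq = pd.DataFrame({"n_bps": [], "n_indel": []}, index=ids)
        ori = pd.DataFrame({"orientation": []}, index=ids)
        dec = trna_decomposition(freq, ori, GeneSubset("tRNA", frozenset()), [])
        assert dec["n_trna"] == 0


class TestPlacementSummary:
    def test_ratio_ci_basics(self):
        r, lo, hi = poisson_ratio_ci(200, 1000.0, 100, 1000.0)
        assert r == pytest.approx(2.0)
        assert lo < 2.0 < hi
        r1, _, _ = poisson_ratio_ci(100, 500.0, 100, 1000.0)
        assert r1 == pytest.approx(2.0)  # site normalization matters

    def test_orientation_split_equals_placement_relabeling(self, small_sim):
        """Within genes, counting the diagnostic base on/off the
        transcribed strand and relabeling through CD->LDST / HO->LGST must
        reproduce the placement classes exactly."""
        ass = assign_to_cds(small_sim.mutations, small_sim.genome)
        ps = placement_summary(small_sim.mutations, small_sim.genome, ass)
        per_gene = ps["per_gene"]
        from oriconflict.features import classify_transition_placement
        # recount placements restricted to uniquely-assigned transitions
        gene_ids = set(per_gene.index)
        expect = {"A_on_LGST": 0, "A_on_LDST": 0, "C_on_LGST": 0, "C_on_LDST": 0}
        for m in small_sim.mutations:
            if not (m.is_bps and m.bps_class().change_class == "transition"):
                continue
            for gid in ass.mutation_genes[m.mutation_id]:
                if gid in gene_ids:
                    expect[classify_transition_placement(m, small_sim.genome)] += 1
        cd = per_gene["orientation"] == "CD"
        # CD transcribed strand = LDST: "on transcribed" in CD genes = on LDST
        relabeled = {
            "A_on_LDST": int(per_gene.loc[cd, "at_ts_on_transcribed"].sum()
                             + per_gene.loc[~cd, "at_ts_off_transcribed"].sum()),
            "A_on_LGST": int(per_gene.loc[~cd, "at_ts_on_transcribed"].sum()
                             + per_gene.loc[cd, "at_ts_off_transcribed"].sum()),
            "C_on_LDST": int(per_gene.loc[cd, "gc_ts_on_transcribed"].sum()
                             + per_gene.loc[~cd, "gc_ts_off_transcribed"].sum()),
            "C_on_LGST": int(per_gene.loc[~cd, "gc_ts_on_transcribed"].sum()
                             + per_gene.loc[cd, "gc_ts_off_transcribed"].sum()),
        }
        assert relabeled == expect


class TestRunReport:
    def test_end_to_end_determinism(self, tmp_path, small_sim):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_report(small_sim.genome, small_sim.mutations, small_sim.experiments, out1, seed=1)
        run_report(small_sim.genome, small_sim.mutations, small_sim.experiments, out2, seed=1)
        files1 = sorted(p.name for p in out1.iterdir())
        assert files1 == sorted(p.name for p in out2.iterdir())
        for name in files1:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name

    def test_manifest_and_conservation(self, tmp_path, small_sim):
        rep = run_report(small_sim.genome, small_sim.mutations, small_sim.experiments,
                         tmp_path / "r", seed=1)
        man = rep["manifest"]
        assert man["n_mutations"] == len(small_sim.mutations)
        assert man["bh_family_size"] > 0
        comp = rep["tables"]["table3_comparisons"]
        row = comp.loc[(comp.subset_name == "all_genes") & (comp.metric == "bps_per_cds")].iloc[0]
        total_bps_in_genes = rep["assignment"].gene_counts["n_bps"].sum()
        assert row.mean_all * row.n_all == pytest.approx(total_bps_in_genes)
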