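"""Expression coupling: normalization, DE, correlation groups, 5hmC share."""

import numpy as np
import pandas as pd
import pytest

import hmcpipe as h


class TestQuantileNormalize:
    def test_forced_two_column_example(self):
        m = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]})
        out = h.quantile_normalize(m)
        assert np.allclose(out["s1"], [1.5, 3.5])
        assert np.allclose(out["s2"], [1.5, 3.5])

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        assert np.allclose(h.quantile_normalize(m), m)

    def test_ties_get_mean_of_quantile_values(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        out = h.quantile_normalize(m)
        # sorted means are [1, 1.5, 2.5]; the tied pair shares (1+1.5)/2
        assert np.allclose(out["a"], [1.25, 1.25, 2.5])

    def test_column_distributions_identical_after(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out = h.quantile_normalize(m)
        ref = np.sort(out["a"].to_numpy())
        for c in "bcd":
            assert np.allclose(np.sort(out[c].to_numpy()), ref)


def _sheet(n_mt=5, n_wt=5):
    return h.SampleSheet(
        pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n_mt + n_wt)],
             "cohort": ["MT"] * n_mt + ["WT"] * n_wt}
        )
    )


class TestDifferentialExpression:
    def test_identical_cohorts_select_nothing(self, rng):
        sheet = _sheet()
        half = rng.normal(7, 1, (30, 5))
        expr = pd.DataFrame(np.hstack([half, half]),
                            index=[f"g{i}" for i in range(30)],
                            columns=sheet.sample_ids)
        de = h.differential_expression(expr, sheet)
        assert de["selected"].sum() == 0

    def test_planted_gene_selected_up(self, rng):
        sheet = _sheet()
        expr = pd.DataFrame(rng.normal(7, 0.2, (50, 10)),
                            index=[f"g{i}" for i in range(50)],
                            columns=sheet.sample_ids)
        expr.iloc[0, :5] += 2.0  # fold change 4 in MT
        de = h.differential_expression(expr, sheet)
        assert de.loc["g0", "selected"]
        assert de.loc["g0", "direction"] == "UP_MT"
        assert de.loc["g0", "fold_change"] == pytest.approx(4, rel=0.3)

    def test_fold_change_alone_insufficient(self, rng):
        sheet = _sheet(3, 3)
        expr = pd.DataFrame(rng.normal(7, 0.1, (200, 6)),
                            index=[f"g{i}" for i in range(200)],
                            columns=sheet.sample_ids)
        # large shift but huge within-cohort spread -> p stays high
        noisy = np.array([4.0, 10.0, 7.0])
        expr.iloc[0, :3] = noisy + 1.8
        expr.iloc[0, 3:] = noisy
        de = h.differential_expression(expr, sheet)
        assert de.loc["g0", "fold_change"] > 2
        assert not de.loc["g0", "selected"]

    def test_label_swap_flips_direction_keeps_fc(self, dataset):
        sheet = dataset["sheet"]
        swapped = h.SampleSheet(
            sheet.table.assign(
                cohort=np.where(sheet.table["cohort"] == "MT", "WT", "MT")
            )
        )
        a = h.differential_expression(dataset["expr"], sheet)
        b = h.differential_expression(dataset["expr"], swapped)
        assert np.allclose(a["fold_change"], b["fold_change"])
        sel = a.index[a["selected"]]
        assert (
            a.loc[sel, "direction"].map({"UP_MT": "DOWN_MT", "DOWN_MT": "UP_MT"})
            == b.loc[sel, "direction"]
        ).all()


class TestTopExpressed:
    def test_counts_and_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(100, 4)),
                            index=[f"g{i:03d}" for i in range(100)])
        top = h.top_expressed_genes(expr, 0.2)
        assert len(top) == 20
        means = expr.mean(axis=1).sort_values(ascending=False)
        assert top == set(means.index[:20])

    def test_full_fraction_returns_all(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 2)),
                            index=[f"g{i}" for i in range(10)])
        assert h.top_expressed_genes(expr, 1.0) == set(expr.index)


class TestExpressionAssociation:
    def test_constructed_enrichment(self, dataset):
        ann = dataset["manifest"]
        genic = ann[ann["gene_symbol"].notna()]
        top = set(genic["gene_symbol"].unique()[:20])
        query = set(genic.loc[genic["gene_symbol"].isin(top), "probe_id"][:50])
        res = h.expression_association(
            query, ann, top, set(genic["gene_symbol"].unique())
        )
        assert res.odds_ratio > 1
        assert res.p_value < 0.01

    def test_empty_query_after_region_filter(self, dataset):
        ann = dataset["manifest"]
        genic = ann[ann["gene_region"] == "BODY"]
        query = set(genic["probe_id"][:10])
        with pytest.raises(ValueError, match="empty query"):
            h.expression_association(
                query, ann, {"GENE0001"},
                set(ann["gene_symbol"].dropna().unique()),
                region_filter={"TSS200"},
            )


class TestExtremeProbes:
    def test_boundary_inclusive_and_oracle(self, mc, dataset):
        sheet = dataset["sheet"]
        mask = sheet.cohort_mask("MT")
        means = mc.values.loc[:, mc.values.columns[mask]].mean(axis=1)
        high = h.methylation_extreme_probes(mc, mask, ("ge", 0.7))
        low = h.methylation_extreme_probes(mc, mask, ("le", 0.3))
        assert high == set(means.index[means >= 0.7])
        assert low == set(means.index[means <= 0.3])

    def test_midrange_matrix_empty_both_modes(self):
        bm = h.BetaMatrix(
            pd.DataFrame(0.5, index=["a", "b"], columns=["s1", "s2"]), "5mC"
        )
        mask = np.array([True, True])
        assert h.methylation_extreme_probes(bm, mask, ("ge", 0.7)) == set()
        assert h.methylation_extreme_probes(bm, mask, ("le", 0.3)) == set()


class TestSpearman:
    def test_monotone_perfect(self):
        x = np.arange(10.0)
        r, _ = h.spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)
        r2, _ = h.spearman(x, -np.exp(x))
        assert r2 == pytest.approx(-1.0)

    def test_tied_fixture_matches_hand_ranks(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 3.0, 2.0, 4.0])
        expect = np.corrcoef(rx, ry)[0, 1]
        r, _ = h.spearman(x, y)
        assert r == pytest.approx(expect)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            h.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="length"):
            h.spearman([1, 2, 3], [1, 2, 3])


class TestClassifyGroups:
    def test_planted_groups_recovered(self, dataset, hmc, mc):
        truth = dataset["truth"]
        de = h.differential_expression(dataset["expr"], dataset["sheet"])
        probes = {r["probe_id"] for r in truth.planted_coupled_probes}
        rec, table, p = h.classify_groups(
            hmc, mc, dataset["expr"], de, probes, dataset["manifest"]
        )
        rec = rec.set_index("probe_id")
        planted = pd.Series(
            {r["probe_id"]: r["group"] for r in truth.planted_coupled_probes}
        )
        agree = (rec.loc[planted.index, "group"] == planted).mean()
        assert agree >= 0.9
        assert table.to_numpy().sum() == (rec["group"] != "NONE").sum()
        assert p < 0.01

    def test_group_rules_on_constructed_pairs(self):
        sheet = _sheet(5, 5)
        samples = sheet.sample_ids
        idx = ["p_pos", "p_neg", "p_weak"]
        # probe signal high in the MT cohort (first five samples)
        u = np.array([0.6, 0.55, 0.5, 0.45, 0.4, 0.3, 0.25, 0.2, 0.15, 0.1])
        weak = np.random.default_rng(0).permutation(u)
        mt = np.r_[np.ones(5), np.zeros(5)]
        hmc = h.BetaMatrix(
            pd.DataFrame([u, u, weak], index=idx, columns=samples), "5hmC"
        )
        mcm = h.BetaMatrix(
            pd.DataFrame([weak, weak, weak], index=idx, columns=samples), "5mC"
        )
        expr = pd.DataFrame(
            [10 * u + 15 * mt,          # up in MT, tracks the probe: G1
             -10 * u + 25 * (1 - mt),   # down in MT, anti-tracks: G4
             10 * u + 15 * mt],
            index=["gU", "gD", "gW"], columns=samples,
        )
        de = h.differential_expression(expr, sheet)
        from hmcpipe.io import validate_annotation

        ann = validate_annotation(
            pd.DataFrame(
                {
                    "probe_id": idx, "chrom": "chr1", "pos": [100, 200, 300],
                    "cpg_feature": "OPEN_SEA", "gene_region": "BODY",
                    "gene_symbol": ["gU", "gD", "gW"],
                    "snp_flag": False, "sex_chrom_flag": False,
                }
            )
        )
        rec, _, _ = h.classify_groups(hmc, mcm, expr, de, set(idx), ann)
        rec = rec.set_index("probe_id")
        assert rec.loc["p_pos", "group"] == "G1"   # +r, UP_MT
        assert rec.loc["p_neg", "group"] == "G4"   # -r, DOWN_MT
        assert rec.loc["p_weak", "group"] == "NONE"


class TestGcimpContribution:
    def test_percentage_arithmetic_and_exclusion(self, dataset, hmc, mc):
        contrib = h.gcimp_contribution(
            hmc, mc,
            h.GeneSet("sig", frozenset(dataset["truth"].planted_gcimp_genes)),
            dataset["manifest"], sheet=dataset["sheet"],
        )
        kept = contrib[~contrib["excluded"]]
        assert ((kept["pct_5hmc"] >= 0) & (kept["pct_5hmc"] <= 100)).all()
        recompute = 100 * kept["mean_5hmc"] / (kept["mean_5hmc"] + kept["mean_5mc"])
        assert np.allclose(kept["pct_5hmc"], recompute)
        # exclusion rule is exactly total < 0.3
        totals = contrib["mean_5hmc"] + contrib["mean_5mc"]
        with_probes = contrib["unit"].notna()
        assert (
            contrib.loc[with_probes, "excluded"]
            == (totals[with_probes] < 0.3)
        ).all()

    def test_simple_numbers(self):
        samples = ["s1", "s2"]
        hmcm = h.BetaMatrix(
            pd.DataFrame([[0.1, 0.1]], index=["p1"], columns=samples), "5hmC"
        )
        mcm = h.BetaMatrix(
            pd.DataFrame([[0.3, 0.3]], index=["p1"], columns=samples), "5mC"
        )
        from hmcpipe.io import validate_annotation

        ann = validate_annotation(
            pd.DataFrame(
                {"probe_id": ["p1"], "chrom": "chr1", "pos": 100,
                 "cpg_feature": "ISLAND", "gene_region": "TSS200",
                 "gene_symbol": "G", "snp_flag": False, "sex_chrom_flag": False}
            )
        )
        out = h.gcimp_contribution(
            hmcm, mcm, h.GeneSet("s", frozenset({"G"})), ann, level="per_sample"
        )
        assert np.allclose(out["pct_5hmc"], 25.0)
        out2 = h.gcimp_contribution(
            hmcm, mcm, h.GeneSet("s", frozenset({"G"})), ann,
            min_total=0.5, level="per_sample",
        )
        assert out2["excluded"].all()


class TestNegativeCorrelationProportion:
    def test_perfect_anticorrelation(self):
        samples = [f"s{i}" for i in range(6)]
        vals = np.linspace(0.1, 0.6, 6)
        hmcm = h.BetaMatrix(
            pd.DataFrame([vals, vals * 0.5], index=["p1", "p2"], columns=samples),
            "5hmC",
        )
        mcm = h.BetaMatrix(
            pd.DataFrame([1 - vals, 1 - vals * 0.5], index=["p1", "p2"],
                         columns=samples),
            "5mC",
        )
        prop, n, excl = h.negative_correlation_proportion(hmcm, mcm, ["p1", "p2"])
        assert prop == 1.0 and n == 2 and excl == 0

    def test_zero_correlation_counts_nonnegative(self):
        samples = ["s1", "s2", "s3", "s4"]
        hmcm = h.BetaMatrix(
            pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["p"], columns=samples),
            "5hmC",
        )
        mcm = h.BetaMatrix(
            pd.DataFrame([[0.1, 0.3, 0.3, 0.1]], index=["p"], columns=samples),
            "5mC",
        )
        prop, n, _ = h.negative_correlation_proportion(hmcm, mcm, ["p"])
        assert prop == 0.0 and n == 1

    def test_independent_channels_near_half(self, rng):
        samples = [f"s{i}" for i in range(21)]
        idx = [f"p{i}" for i in range(300)]
        a = h.BetaMatrix(pd.DataFrame(rng.random((300, 21)), index=idx,
                                      columns=samples), "5hmC")
        b = h.BetaMatrix(pd.DataFrame(rng.random((300, 21)), index=idx,
                                      columns=samples), "5mC")
        prop, n, _ = h.negative_correlation_proportion(a, b, idx)
        assert abs(prop - 0.5) <= 3 * 0.5 / np.sqrt(n)
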