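"""The synthetic-data generator: determinism, layout constraints, planted
structure, and channel noise behavior."""

import numpy as np
import pytest
from scipy.stats import binom

import hmcpipe as h
from hmcpipe.simulate import gene_intervals


class TestDeterminism:
    def test_same_seed_identical_outputs(self, small_cfg):
        import dataclasses

        cfg2 = dataclasses.replace(small_cfg)
        d1 = h.generate_dataset(small_cfg, with_hmedip=True)
        d2 = h.generate_dataset(cfg2, with_hmedip=True)
        assert d1["manifest"].equals(d2["manifest"])
        assert d1["bs"].values.equals(d2["bs"].values)
        assert d1["oxbs"].values.equals(d2["oxbs"].values)
        assert d1["expr"].equals(d2["expr"])
        for sid in d1["reads"]:
            assert d1["reads"][sid].equals(d2["reads"][sid])

    def test_truth_json_round_trip(self, dataset, tmp_path):
        p = tmp_path / "truth.json"
        dataset["truth"].to_json(p)
        back = h.SyntheticTruth.from_json(p)
        assert back.planted_gcimp_genes == dataset["truth"].planted_gcimp_genes
        assert back.cluster_labels == dataset["truth"].cluster_labels
        assert back.planted_dhmrs == dataset["truth"].planted_dhmrs


class TestManifestLayout:
    def test_planted_regions_are_single_gap_clusters(self, dataset, small_cfg):
        clusters = h.cluster_probes(dataset["manifest"], small_cfg.max_gap)
        for region in dataset["truth"].planted_dhmrs:
            ids = clusters.loc[region["probe_ids"]]
            assert ids.nunique() == 1

    def test_every_gene_has_promoter_and_body_probes(self, dataset):
        ann = dataset["manifest"]
        genic = ann[ann["gene_symbol"].notna()]
        promoter = genic["gene_region"].isin(["TSS200", "TSS1500"])
        body = genic["gene_region"].isin(["BODY", "INTRON"])
        per_gene_prom = genic[promoter].groupby("gene_symbol").size()
        per_gene_body = genic[body].groupby("gene_symbol").size()
        genes = set(genic["gene_symbol"])
        assert set(per_gene_prom.index) == genes
        assert (per_gene_body >= 3).all() and set(per_gene_body.index) == genes

    def test_enhancer_fraction_within_binomial_bounds(self, dataset, small_cfg):
        ann = dataset["manifest"]
        n = len(ann)
        for src, frac in small_cfg.enhancer_fraction.items():
            k = int(ann[src].sum())
            lo, hi = binom.ppf([0.005, 0.995], n, frac)
            assert lo <= k <= hi

    def test_sex_chromosome_probes_flagged_and_intergenic(self, dataset):
        ann = dataset["manifest"]
        x = ann[ann["chrom"] == "chrX"]
        assert (x["sex_chrom_flag"]).all()
        assert (x["gene_region"] == "INTERGENIC").all()
        assert not ann.loc[ann["chrom"] != "chrX", "sex_chrom_flag"].any()

    def test_impossible_layout_rejected(self):
        cfg = h.SimulationConfig(n_probes=50, n_genes=40, n_planted_dhmrs=5,
                                 gcimp_gene_count=5, n_coupled_genes=5,
                                 n_de_extra=5)
        with pytest.raises(ValueError, match="layout impossible"):
            h.generate_manifest(cfg)
        with pytest.raises(ValueError, match="too small"):
            h.SimulationConfig(n_probes=40, n_planted_dhmrs=5)


class TestPairedBetas:
    def test_noise_free_run_has_no_artifact(self):
        cfg = h.SimulationConfig(
            n_probes=600, n_genes=40, n_planted_dhmrs=2, gcimp_gene_count=5,
            n_coupled_genes=5, n_de_extra=5, technical_noise_sd=0.0,
            biological_noise_sd=0.0, seed=3,
        )
        d = h.generate_dataset(cfg)
        delta = d["bs"].values.to_numpy() - d["oxbs"].values.to_numpy()
        assert (delta >= -1e-12).all()

    def test_symmetric_noise_artifact_fraction_half(self):
        cfg = h.SimulationConfig(
            n_probes=2000, n_genes=60, n_planted_dhmrs=2, gcimp_gene_count=5,
            n_coupled_genes=0, group_mix={"G1": 1.0}, n_de_extra=5,
            baseline_5hmc_level=0.0, dhmr_effect=0.0, gcimp_5mc_effect=0.0,
            technical_noise_sd=0.02, biological_noise_sd=0.0, seed=4,
        )
        d = h.generate_dataset(cfg)
        frac = (d["bs"].values.to_numpy() < d["oxbs"].values.to_numpy()).mean()
        n = d["bs"].values.size
        assert abs(frac - 0.5) <= 3 * 0.5 / np.sqrt(n)

    def test_all_betas_in_unit_interval(self, dataset):
        for key in ("bs", "oxbs"):
            v = dataset[key].values.to_numpy()
            assert v.min() >= 0 and v.max() <= 1

    def test_truth_ids_exist_in_manifest(self, dataset):
        ann = dataset["manifest"]
        truth = dataset["truth"]
        for r in truth.planted_dhmrs:
            assert set(r["probe_ids"]) <= set(ann.index)
        for r in truth.planted_coupled_probes:
            assert r["probe_id"] in ann.index
        genic = set(ann["gene_symbol"].dropna())
        assert set(truth.planted_gcimp_genes) <= genic


class TestExpression:
    def test_realized_fold_change_matches_construction(self, dataset, small_cfg):
        sheet, truth, expr = dataset["sheet"], dataset["truth"], dataset["expr"]
        mt = sheet.cohort_ids("MT")
        wt = sheet.cohort_ids("WT")
        target = np.log2(small_cfg.expression_fc)
        diffs = []
        for d in truth.planted_de_genes:
            sign = 1 if d["direction"] == "UP_MT" else -1
            diffs.append(sign * (expr.loc[d["gene"], mt].mean()
                                 - expr.loc[d["gene"], wt].mean()))
        assert np.mean(diffs) == pytest.approx(target, abs=0.15)

    def test_coupled_pairs_reach_strong_correlation(self):
        cfg = h.SimulationConfig(
            n_probes=1500, n_genes=80, n_planted_dhmrs=2, gcimp_gene_count=5,
            n_coupled_genes=16, n_de_extra=5, coupling_r=0.95, seed=6,
        )
        d = h.generate_dataset(cfg)
        hmc = h.compute_5hmc(d["bs"], d["oxbs"])
        strong = []
        for r in d["truth"].planted_coupled_probes:
            rs, _ = h.spearman(
                hmc.values.loc[r["probe_id"]].to_numpy(),
                d["expr"].loc[r["gene"]].to_numpy(),
            )
            strong.append(abs(rs) >= 0.5)
        assert np.mean(strong) >= 0.95

    def test_null_genes_have_equal_cohort_means(self):
        cfg = h.SimulationConfig(
            n_probes=600, n_genes=40, n_planted_dhmrs=2, gcimp_gene_count=5,
            n_coupled_genes=0, group_mix={"G1": 1.0}, n_de_extra=0,
            expression_noise_sd=1e-12, seed=8,
        )
        d = h.generate_dataset(cfg)
        mt = d["sheet"].cohort_ids("MT")
        wt = d["sheet"].cohort_ids("WT")
        diff = d["expr"][mt].mean(axis=1) - d["expr"][wt].mean(axis=1)
        assert np.abs(diff).max() < 1e-9


class TestHmedipReads:
    def test_zero_rates_give_empty_bed(self):
        cfg = h.SimulationConfig(
            n_probes=600, n_genes=40, n_planted_dhmrs=2, gcimp_gene_count=5,
            n_coupled_genes=5, n_de_extra=5, hmedip_rate_scale=0.0,
            hmedip_noise_rate=0.0, seed=9,
        )
        d = h.generate_dataset(cfg, with_hmedip=True)
        assert all(bed.empty for bed in d["reads"].values())

    def test_planted_windows_show_fold_change(self, dataset):
        counts = h.count_windows(dataset["reads"], dataset["chrom_sizes"])
        diff = h.differential_windows(counts, dataset["sheet"], min_mean=3)
        truth_spans = [
            (r["chrom"], r["start"], r["end"])
            for r in dataset["truth"].planted_dhmrs
        ]
        hits = 0
        for chrom, start, end in truth_spans:
            sel = diff[(diff["chrom"] == chrom) & (diff["start"] < end)
                       & (diff["end"] > start - 1)]
            if (sel["log_fc"] > 1).any():
                hits += 1
        assert hits >= 0.9 * len(truth_spans)

    def test_spike_factors_recorded_for_all_samples(self, dataset):
        spikes = dataset["spikes"]
        assert set(spikes) == set(dataset["sheet"].sample_ids)
        assert all(s > 0 for s in spikes.values())


def test_gene_intervals_cover_probes(dataset):
    gi = gene_intervals(dataset["manifest"]).set_index("gene")
    ann = dataset["manifest"]
    genic = ann[ann["gene_symbol"].notna()]
    for gene, grp in list(genic.groupby("gene_symbol"))[:20]:
        assert gi.loc[gene, "start"] == grp["pos"].min() - 1
        assert gi.loc[gene, "end"] == grp["pos"].max()
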