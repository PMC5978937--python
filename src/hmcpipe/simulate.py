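"""Synthetic study inputs with planted, recorded ground truth.

The generator emulates the statistical structure of a paired BS/OxBS
methylation-array study of two tumor cohorts (12 IDH1-mutant vs 9
wild-type by default) together with matched expression and hMeDIP read
data:

* probe-level 5mC drawn from bounded unimodal (beta) distributions per
  CpG-island feature class, low 5hmC baseline (~0.04), and independent
  clipped-Gaussian technical noise per channel so a fraction of probes
  shows the negative BS - OxBS artifact;
* planted differentially hydroxymethylated regions (DHMRs): contiguous
  gene-body probe runs whose MT-cohort 5hmC is raised by a fixed effect;
* planted promoter/island hypermethylation on a G-CIMP-style gene set;
* coupled genes whose body-probe 5hmC co-varies with their expression at
  a target correlation, crossed with the direction of differential
  expression to plant Group 1-4 probe-gene pairs;
* per-sample hMeDIP read intervals with Poisson rates proportional to
  true 5hmC and a recorded spike-in recovery factor per sample.

Every random draw flows from ``cfg.seed`` through per-stage child seeds,
so each artifact is reproducible independently of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BetaMatrix, Channel, Cohort, SampleSheet, validate_annotation

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "make_sample_sheet",
    "generate_manifest",
    "generate_paired_betas",
    "generate_expression",
    "generate_hmedip_reads",
    "generate_dataset",
]

_GROUP_SIGNS = {  # group -> (correlation sign, DE direction)
    "G1": (+1, "UP_MT"),
    "G2": (-1, "UP_MT"),
    "G3": (+1, "DOWN_MT"),
    "G4": (-1, "DOWN_MT"),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_probes: int = 20000
    n_genes: int = 1000
    n_mt: int = 12
    n_wt: int = 9

    # baseline methylation: per-feature (mean, concentration) of a beta law
    baseline_5mc_params: dict = field(
        default_factory=lambda: {
            "ISLAND": (0.15, 30.0),
            "SHORE": (0.35, 30.0),
            "SHELF": (0.55, 30.0),
            "OPEN_SEA": (0.70, 30.0),
        }
    )
    baseline_5hmc_level: float = 0.04
    technical_noise_sd: float = 0.02
    biological_noise_sd: float = 0.01

    # planted DHMRs
    n_planted_dhmrs: int = 20
    dhmr_effect: float = 0.15
    dhmr_effect_jitter: float = 0.4
    dhmr_min_probes: int = 10

    # planted promoter hypermethylation (G-CIMP-style signature)
    gcimp_gene_count: int = 50
    gcimp_5mc_effect: float = 0.25
    gcimp_effect_jitter: float = 0.4

    # 5hmC-expression coupling
    n_coupled_genes: int = 40
    coupled_probes_per_gene: int = 4
    coupling_r: float = 0.9
    coupled_hmc_base: float = 0.30
    coupled_hmc_amplitude: float = 0.12
    coupled_hmc_shift: float = 0.15
    coupled_5mc_mean: float = 0.35
    group_mix: dict = field(
        default_factory=lambda: {"G1": 0.625, "G2": 0.075, "G3": 0.075, "G4": 0.225}
    )

    # expression
    expression_fc: float = 3.0
    n_de_extra: int = 30
    expression_noise_sd: float = 0.5
    expression_baseline_mean: float = 7.0
    expression_baseline_sd: float = 1.5

    # sample-cluster structure (2 = cohorts; 3 adds an intermediate group)
    n_sample_clusters: int = 2

    # manifest layout
    max_gap: int = 1000
    block_gap: int = 5000
    min_within_gap: int = 50
    max_within_gap: int = 300
    enhancer_fraction: dict = field(
        default_factory=lambda: {"enhancer_fantom": 0.10, "enhancer_chmm": 0.05}
    )
    snp_fraction: float = 0.02
    chrx_intergenic_fraction: float = 0.05
    n_autosomes: int = 4

    # hMeDIP
    hmedip_rate_scale: float = 20.0
    hmedip_noise_rate: float = 0.02
    hmedip_read_length: int = 100
    hmedip_window: int = 100
    hmedip_spike_sd: float = 0.15

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < self.n_planted_dhmrs * self.dhmr_min_probes:
            raise ValueError("n_probes too small for the planted DHMRs")
        if not 0 < self.coupling_r < 1:
            raise ValueError("coupling_r must be in (0, 1)")
        if self.dhmr_min_probes < 7:
            raise ValueError("dhmr_min_probes must be >= 7")
        if self.coupled_probes_per_gene < 3:
            raise ValueError("coupled genes need >= 3 body probes")
        n_special = (
            self.n_planted_dhmrs + self.gcimp_gene_count + self.n_coupled_genes
        )
        if self.n_genes < n_special + self.n_de_extra:
            raise ValueError("n_genes too small for the planted gene classes")
        if abs(sum(self.group_mix.values()) - 1) > 1e-9:
            raise ValueError("group_mix must sum to 1")
        if self.max_within_gap > self.max_gap:
            raise ValueError("within-block gaps must not exceed max_gap")
        if self.block_gap <= self.max_gap:
            raise ValueError("block_gap must exceed max_gap")

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class SyntheticTruth:
    """Planted structure, recorded for recovery testing."""

    planted_dhmrs: list  # dicts: chrom, start, end, probe_ids, sign, gene
    planted_gcimp_genes: list
    planted_coupled_probes: list  # dicts: probe_id, gene, group
    planted_de_genes: list  # dicts: gene, direction, fold_change
    cluster_labels: dict  # sample_id -> int
    coupled_signal: pd.DataFrame | None = None  # gene x sample latent 5hmC signal
    spike_factors: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_dhmrs": self.planted_dhmrs,
            "planted_gcimp_genes": self.planted_gcimp_genes,
            "planted_coupled_probes": self.planted_coupled_probes,
            "planted_de_genes": self.planted_de_genes,
            "cluster_labels": self.cluster_labels,
            "spike_factors": self.spike_factors,
            "coupled_signal": None
            if self.coupled_signal is None
            else self.coupled_signal.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        sig = d.pop("coupled_signal")
        return cls(coupled_signal=None if sig is None else pd.DataFrame(sig), **d)


def scaled_config(n_probes: int, n_genes: int, seed: int = 0,
                  **overrides) -> SimulationConfig:
    """A config whose planted-class sizes shrink with the requested scale,
    keeping the default proportions; full-size defaults are unchanged."""
    params = dict(
        n_probes=n_probes,
        n_genes=n_genes,
        n_planted_dhmrs=min(20, max(2, n_genes // 6)),
        gcimp_gene_count=min(50, max(5, n_genes // 4)),
        n_coupled_genes=min(40, max(4, n_genes // 5)),
        n_de_extra=min(30, max(2, n_genes // 6)),
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def make_sample_sheet(cfg: SimulationConfig) -> SampleSheet:
    rng = cfg._rng(0)
    rows = []
    for i in range(cfg.n_mt):
        rows.append(
            {"sample_id": f"MT{i + 1:02d}", "cohort": "MT",
             "age_years": int(rng.integers(25, 70)), "who_grade": "III"}
        )
    for i in range(cfg.n_wt):
        rows.append(
            {"sample_id": f"WT{i + 1:02d}", "cohort": "WT",
             "age_years": int(rng.integers(25, 70)), "who_grade": "IV"}
        )
    return SampleSheet(pd.DataFrame(rows))


def planted_gene_classes(cfg: SimulationConfig) -> dict[str, list[str]]:
    """Deterministic partition of gene symbols into planted classes."""
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    i = 0
    out = {"dhmr": genes[i : i + cfg.n_planted_dhmrs]}
    i += cfg.n_planted_dhmrs
    out["gcimp"] = genes[i : i + cfg.gcimp_gene_count]
    i += cfg.gcimp_gene_count
    out["coupled"] = genes[i : i + cfg.n_coupled_genes]
    i += cfg.n_coupled_genes
    out["de_extra"] = genes[i : i + cfg.n_de_extra]
    out["all"] = genes
    return out


def coupled_gene_groups(cfg: SimulationConfig) -> dict[str, str]:
    """Assign each coupled gene a Group 1-4 label per the configured mix."""
    coupled = planted_gene_classes(cfg)["coupled"]
    counts = {
        g: int(round(frac * len(coupled))) for g, frac in cfg.group_mix.items()
    }
    # distribute rounding remainder to the largest class
    leftover = len(coupled) - sum(counts.values())
    counts[max(counts, key=counts.get)] += leftover
    labels = {}
    i = 0
    for group in ("G1", "G2", "G3", "G4"):
        for g in coupled[i : i + counts.get(group, 0)]:
            labels[g] = group
        i += counts.get(group, 0)
    return labels


def generate_manifest(cfg: SimulationConfig) -> pd.DataFrame:
    """Probe annotation table laid out in gap-separated blocks.

    Gene blocks (1-2 promoter probes + body probes) and intergenic blocks
    are placed on ``n_autosomes`` autosomes plus chrX (intergenic only,
    sex-flagged); within a block consecutive gaps are <= max_gap and
    blocks are separated by ``block_gap`` > max_gap, so gap-clustering
    recovers blocks exactly.
    """
    rng = cfg._rng(1)
    classes = planted_gene_classes(cfg)
    dhmr_set, coupled_set = set(classes["dhmr"]), set(classes["coupled"])
    gcimp_set = set(classes["gcimp"])

    blocks = []  # (kind, gene, [probe specs])
    n_gene_probes = 0
    for gene in classes["all"]:
        if gene in dhmr_set:
            n_body = cfg.dhmr_min_probes
        elif gene in coupled_set:
            n_body = cfg.coupled_probes_per_gene
        else:
            n_body = int(rng.integers(3, 7))
        specs = [("TSS200", gene)]
        if rng.random() < 0.5:
            specs.append(("TSS1500", gene))
        body_regions = rng.choice(["BODY", "INTRON"], size=n_body, p=[0.7, 0.3])
        specs.extend((r, gene) for r in body_regions)
        blocks.append(("gene", gene, specs))
        n_gene_probes += len(specs)
    remaining = cfg.n_probes - n_gene_probes
    if remaining < 0:
        raise ValueError("layout impossible: gene probes exceed n_probes")
    while remaining > 0:
        size = int(min(remaining, rng.integers(1, 4)))
        blocks.append(("intergenic", None, [("INTERGENIC", None)] * size))
        remaining -= size

    gene_blocks = [b for b in blocks if b[0] == "gene"]
    inter_blocks = [b for b in blocks if b[0] == "intergenic"]
    n_x = int(len(inter_blocks) * cfg.chrx_intergenic_fraction)
    x_blocks = inter_blocks[:n_x]
    auto_blocks = gene_blocks + inter_blocks[n_x:]
    order = rng.permutation(len(auto_blocks))
    autosomes = [f"chr{i + 1}" for i in range(cfg.n_autosomes)]
    per_chrom: dict[str, list] = {c: [] for c in autosomes}
    for j, idx in enumerate(order):
        per_chrom[autosomes[j % cfg.n_autosomes]].append(auto_blocks[idx])
    per_chrom["chrX"] = x_blocks

    rows = []
    feature_p = {
        "promoter": (["ISLAND", "SHORE"], [0.7, 0.3]),
        "body": (["SHORE", "SHELF", "OPEN_SEA"], [0.25, 0.25, 0.5]),
        "intergenic": (["SHELF", "OPEN_SEA"], [0.2, 0.8]),
    }
    probe_no = 0
    for chrom, chrom_blocks in per_chrom.items():
        cursor = 10_000
        for kind, gene, specs in chrom_blocks:
            gaps = rng.integers(
                cfg.min_within_gap, cfg.max_within_gap + 1, size=max(len(specs) - 1, 0)
            )
            pos = cursor + np.concatenate([[0], np.cumsum(gaps)])
            for (region, sym), p in zip(specs, pos):
                probe_no += 1
                if region in ("TSS200", "TSS1500"):
                    cls = "promoter"
                elif region == "INTERGENIC":
                    cls = "intergenic"
                else:
                    cls = "body"
                if sym in gcimp_set and cls == "promoter":
                    feature = "ISLAND"
                else:
                    opts, probs = feature_p[cls]
                    feature = str(rng.choice(opts, p=probs))
                special = sym in dhmr_set or sym in coupled_set or sym in gcimp_set
                row = {
                    "probe_id": f"cg{probe_no:08d}",
                    "chrom": chrom,
                    "pos": int(p),
                    "cpg_feature": feature,
                    "gene_region": region,
                    "gene_symbol": sym,
                    "snp_flag": bool(rng.random() < cfg.snp_fraction) and not special,
                    "sex_chrom_flag": chrom == "chrX",
                }
                for src, frac in cfg.enhancer_fraction.items():
                    row[src] = bool(rng.random() < frac)
                rows.append(row)
            cursor = int(pos[-1]) + cfg.block_gap
    ann = pd.DataFrame(rows)
    cols = ["probe_id", "chrom", "pos", "cpg_feature", "gene_region", "gene_symbol"]
    cols += list(cfg.enhancer_fraction) + ["snp_flag", "sex_chrom_flag"]
    return validate_annotation(ann[cols])


def gene_intervals(ann: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open genomic span of each gene's probes."""
    genic = ann[ann["gene_symbol"].notna()]
    grp = genic.groupby("gene_symbol", sort=True)
    return pd.DataFrame(
        {
            "gene": grp.size().index,
            "chrom": grp["chrom"].first().to_numpy(),
            "start": (grp["pos"].min() - 1).to_numpy(),
            "end": grp["pos"].max().to_numpy(),
        }
    ).reset_index(drop=True)


def _beta_draw(rng, mean: float, conc: float, size) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    if mean >= 1:
        return np.ones(size)
    a = mean * conc
    b = (1 - mean) * conc
    return rng.beta(a, b, size=size)


def _cluster_labels(cfg: SimulationConfig, sheet: SampleSheet) -> dict[str, int]:
    mt_ids = sheet.cohort_ids(Cohort.MT)
    wt_ids = sheet.cohort_ids(Cohort.WT)
    if cfg.n_sample_clusters == 2:
        return {**{s: 1 for s in mt_ids}, **{s: 2 for s in wt_ids}}
    if cfg.n_sample_clusters == 3:
        n_int_mt = max(len(mt_ids) // 3, 1)
        n_int_wt = max(len(wt_ids) // 3, 1)
        inter = set(mt_ids[-n_int_mt:]) | set(wt_ids[-n_int_wt:])
        labels = {}
        for s in mt_ids:
            labels[s] = 2 if s in inter else 1
        for s in wt_ids:
            labels[s] = 2 if s in inter else 3
        return labels
    raise ValueError("n_sample_clusters must be 2 or 3")


def generate_paired_betas(
    manifest: pd.DataFrame, sheet: SampleSheet, cfg: SimulationConfig
) -> tuple[BetaMatrix, BetaMatrix, SyntheticTruth]:
    """Draw true 5mC/5hmC, plant all effects, and emit noisy BS/OxBS.

    OxBS = clip(5mC + noise); BS = clip(5mC + 5hmC + noise) with channel
    noise independent, so BS < OxBS occurs at low-5hmC probes.
    """
    rng = cfg._rng(2)
    classes = planted_gene_classes(cfg)
    groups = coupled_gene_groups(cfg)
    samples = sheet.sample_ids
    n_s = len(samples)
    n_p = len(manifest)
    mt_mask = sheet.cohort_mask(Cohort.MT)
    labels = _cluster_labels(cfg, sheet)
    lab = np.array([labels[s] for s in samples])

    # per-probe baseline means
    mu_m = np.empty(n_p)
    for feat, (mean, conc) in cfg.baseline_5mc_params.items():
        m = (manifest["cpg_feature"] == feat).to_numpy()
        mu_m[m] = _beta_draw(rng, mean, conc, m.sum())
    mu_h = _beta_draw(rng, cfg.baseline_5hmc_level, 60.0, n_p)

    # coupled probes carry high 5hmC, so their 5mC must leave headroom
    # (total methylation is bounded by 1)
    symbol_arr = manifest["gene_symbol"].to_numpy()
    body_arr = manifest["gene_region"].isin(["BODY", "INTRON"]).to_numpy()
    coupled_idx_all = np.flatnonzero(
        np.isin(symbol_arr, classes["coupled"]) & body_arr
    )
    mu_m[coupled_idx_all] = _beta_draw(
        rng, cfg.coupled_5mc_mean, 30.0, coupled_idx_all.size
    )

    true_m = np.clip(
        mu_m[:, None] + rng.normal(0, cfg.biological_noise_sd, (n_p, n_s)), 0, 1
    )
    true_h = np.clip(
        mu_h[:, None] + rng.normal(0, cfg.biological_noise_sd / 2, (n_p, n_s)), 0, 1
    )

    probe_pos = manifest["pos"]
    symbol = manifest["gene_symbol"]
    region = manifest["gene_region"]
    body = region.isin(["BODY", "INTRON"]).to_numpy()
    promoter = region.isin(["TSS200", "TSS1500"]).to_numpy()
    probe_index = {p: i for i, p in enumerate(manifest.index)}

    planted_dhmrs = []
    # per-region effect magnitudes vary around the nominal effect so the
    # gained profile is a regional pattern, as in real DHMR sets
    region_effects = cfg.dhmr_effect * rng.uniform(
        1 - cfg.dhmr_effect_jitter, 1 + cfg.dhmr_effect_jitter,
        len(classes["dhmr"]),
    )
    for i_region, gene in enumerate(classes["dhmr"]):
        sel = ((symbol == gene).to_numpy()) & body
        idx = np.flatnonzero(sel)
        if cfg.n_sample_clusters == 2:
            mult = mt_mask.astype(float)
        else:
            # intermediate cluster carries the gain in only half the
            # regions, so each cluster has a distinct regional pattern
            inter_gain = 1.0 if i_region % 2 == 0 else 0.0
            mult = np.where(lab == 1, 1.0, np.where(lab == 2, inter_gain, 0.0))
        true_h[np.ix_(idx, np.arange(n_s))] += region_effects[i_region] * mult[None, :]
        probes = manifest.index[idx].tolist()
        planted_dhmrs.append(
            {
                "chrom": str(manifest["chrom"].iloc[idx[0]]),
                "start": int(probe_pos.iloc[idx].min()),
                "end": int(probe_pos.iloc[idx].max()),
                "probe_ids": probes,
                "sign": 1,
                "gene": gene,
            }
        )

    gcimp_effects = cfg.gcimp_5mc_effect * rng.uniform(
        1 - cfg.gcimp_effect_jitter, 1 + cfg.gcimp_effect_jitter,
        len(classes["gcimp"]),
    )
    for i_gene, gene in enumerate(classes["gcimp"]):
        sel = ((symbol == gene).to_numpy()) & promoter
        idx = np.flatnonzero(sel)
        true_m[np.ix_(idx, np.flatnonzero(mt_mask))] += gcimp_effects[i_gene]

    planted_coupled = []
    signal = {}
    for gene in classes["coupled"]:
        group = groups[gene]
        c_sign, direction = _GROUP_SIGNS[group]
        d_sign = 1 if direction == "UP_MT" else -1
        sel = ((symbol == gene).to_numpy()) & body
        idx = np.flatnonzero(sel)[: cfg.coupled_probes_per_gene]
        z = rng.normal(0, 1, n_s)
        shift = c_sign * d_sign * cfg.coupled_hmc_shift
        gene_h = (
            cfg.coupled_hmc_base
            + cfg.coupled_hmc_amplitude * z
            + shift * mt_mask
        )
        true_h[idx, :] = np.clip(
            gene_h[None, :] + rng.normal(0, cfg.biological_noise_sd / 2, (len(idx), n_s)),
            0,
            1,
        )
        signal[gene] = gene_h
        for p in manifest.index[idx]:
            planted_coupled.append({"probe_id": p, "gene": gene, "group": group})

    # keep total methylation within [0, 1]
    true_m = np.clip(true_m, 0, 1)
    true_h = np.clip(true_h, 0, 1 - true_m)

    oxbs_v = np.clip(true_m + rng.normal(0, cfg.technical_noise_sd, (n_p, n_s)), 0, 1)
    bs_v = np.clip(
        true_m + true_h + rng.normal(0, cfg.technical_noise_sd, (n_p, n_s)), 0, 1
    )

    de_genes = [
        {"gene": g, "direction": _GROUP_SIGNS[groups[g]][1], "fold_change": cfg.expression_fc}
        for g in classes["coupled"]
    ]
    half = len(classes["de_extra"]) // 2
    for i, g in enumerate(classes["de_extra"]):
        de_genes.append(
            {
                "gene": g,
                "direction": "UP_MT" if i < half else "DOWN_MT",
                "fold_change": cfg.expression_fc,
            }
        )

    truth = SyntheticTruth(
        planted_dhmrs=planted_dhmrs,
        planted_gcimp_genes=classes["gcimp"],
        planted_coupled_probes=planted_coupled,
        planted_de_genes=de_genes,
        cluster_labels=labels,
        coupled_signal=pd.DataFrame(signal, index=samples).T,
    )
    idx = manifest.index
    bs = BetaMatrix(pd.DataFrame(bs_v, index=idx, columns=samples), Channel.BS)
    oxbs = BetaMatrix(pd.DataFrame(oxbs_v, index=idx, columns=samples), Channel.OXBS)
    return bs, oxbs, truth


def generate_expression(
    manifest: pd.DataFrame,
    truth: SyntheticTruth,
    cfg: SimulationConfig,
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Gene x sample log2 expression with planted DE and 5hmC coupling.

    Coupled genes receive sigma * (sign * r * z + sqrt(1 - r^2) * eps)
    where z is the gene's within-cohort-standardized body 5hmC signal, so
    the realized 5hmC-expression correlation magnitude tracks
    ``coupling_r``; the cohort shift log2(fold_change) is added separately
    so the realized fold change matches the planted one.
    """
    rng = cfg._rng(3)
    classes = planted_gene_classes(cfg)
    groups = coupled_gene_groups(cfg)
    samples = sheet.sample_ids
    mt = sheet.cohort_mask(Cohort.MT).astype(float)
    n_s = len(samples)
    log_fc = np.log2(cfg.expression_fc)

    de_dir = {d["gene"]: d["direction"] for d in truth.planted_de_genes}
    values = np.empty((cfg.n_genes, n_s))
    for i, gene in enumerate(classes["all"]):
        base = rng.normal(cfg.expression_baseline_mean, cfg.expression_baseline_sd)
        eps = rng.normal(0, 1, n_s)
        if gene in groups:
            c_sign, direction = _GROUP_SIGNS[groups[gene]]
            sig = truth.coupled_signal.loc[gene].to_numpy(dtype=float)
            # remove cohort means so z carries only within-cohort variation
            z = sig.copy()
            for mask in (mt.astype(bool), ~mt.astype(bool)):
                z[mask] -= z[mask].mean()
            sd = z.std()
            z = z / sd if sd > 0 else z
            noise = cfg.coupling_r * c_sign * z + np.sqrt(1 - cfg.coupling_r**2) * eps
            d_sign = 1 if direction == "UP_MT" else -1
            values[i] = base + d_sign * log_fc * mt + cfg.expression_noise_sd * noise
        elif gene in de_dir:
            d_sign = 1 if de_dir[gene] == "UP_MT" else -1
            values[i] = base + d_sign * log_fc * mt + cfg.expression_noise_sd * eps
        else:
            values[i] = base + cfg.expression_noise_sd * eps
    return pd.DataFrame(values, index=classes["all"], columns=samples)


def generate_hmedip_reads(
    manifest: pd.DataFrame,
    truth: SyntheticTruth,
    cfg: SimulationConfig,
    sheet: SampleSheet,
) -> tuple[dict[str, pd.DataFrame], dict[str, float], dict[str, int]]:
    """Per-sample read intervals with Poisson window rates proportional to
    true 5hmC, elevated in planted MT regions for MT samples.

    Returns (reads per sample, spike-in recovery factor per sample,
    chromosome sizes).
    """
    rng = cfg._rng(4)
    ws = cfg.hmedip_window
    chrom_sizes = {
        str(c): int(manifest.loc[manifest["chrom"] == c, "pos"].max()) + cfg.block_gap
        for c in manifest["chrom"].unique()
    }
    # per-chromosome window rate profiles (per unit spike factor)
    base_rate = cfg.hmedip_rate_scale * cfg.baseline_5hmc_level
    region_rate = cfg.hmedip_rate_scale * (cfg.baseline_5hmc_level + cfg.dhmr_effect)
    profiles = {}
    for chrom, size in chrom_sizes.items():
        n_win = int(np.ceil(size / ws))
        rate = np.full(n_win, cfg.hmedip_noise_rate)
        sub = manifest[manifest["chrom"] == chrom]
        win_idx = np.unique((sub["pos"].to_numpy() - 1) // ws)
        rate[win_idx] = base_rate
        # keep the chromosome tail read-free so downstream fragment
        # extension cannot cross the chromosome end
        tail = int(np.ceil((cfg.hmedip_read_length + 300) / ws))
        rate[-tail:] = 0.0
        rate[:tail] = 0.0
        profiles[chrom] = rate
    mt_windows = []  # (chrom, window indices) of planted regions
    for r in truth.planted_dhmrs:
        lo = (r["start"] - 1) // ws
        hi = (r["end"] - 1) // ws
        mt_windows.append((r["chrom"], np.arange(lo, hi + 1)))

    mt_ids = set(sheet.cohort_ids(Cohort.MT))
    reads: dict[str, pd.DataFrame] = {}
    spikes: dict[str, float] = {}
    for sid in sheet.sample_ids:
        spike = float(np.exp(rng.normal(0, cfg.hmedip_spike_sd)))
        spikes[sid] = spike
        frames = []
        for chrom, rate in profiles.items():
            lam = rate.copy()
            if sid in mt_ids:
                for rc, widx in mt_windows:
                    if rc == chrom:
                        lam[widx] = region_rate
            counts = rng.poisson(lam * spike)
            widx = np.repeat(np.arange(len(lam)), counts)
            if widx.size == 0:
                continue
            offset = rng.integers(0, ws, size=widx.size)
            start = widx * ws + offset
            strand = rng.choice(["+", "-"], size=widx.size)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + cfg.hmedip_read_length,
                        "strand": strand,
                    }
                )
            )
        reads[sid] = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        )
    truth.spike_factors = spikes
    return reads, spikes, chrom_sizes


def generate_dataset(cfg: SimulationConfig, with_hmedip: bool = False):
    """One-call convenience wrapper: sheet, manifest, BS/OxBS, expression,
    truth (and optionally hMeDIP reads)."""
    sheet = make_sample_sheet(cfg)
    manifest = generate_manifest(cfg)
    bs, oxbs, truth = generate_paired_betas(manifest, sheet, cfg)
    expr = generate_expression(manifest, truth, cfg, sheet)
    out = {
        "sheet": sheet,
        "manifest": manifest,
        "bs": bs,
        "oxbs": oxbs,
        "expr": expr,
        "truth": truth,
    }
    if with_hmedip:
        reads, spikes, chrom_sizes = generate_hmedip_reads(manifest, truth, cfg, sheet)
        out.update({"reads": reads, "spikes": spikes, "chrom_sizes": chrom_sizes})
    return out
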