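"""Coupling of methylation channels to gene expression.

Covers differential expression on a log2 matrix (pooled-t per gene with BH
adjustment and a fold-change filter), the association of probe sets with
highly expressed genes, probe-gene Spearman correlation records with
Group 1-4 classification (sign of the 5hmC-expression correlation crossed
with the direction of differential expression), the per-gene share of
total methylation carried by 5hmC, and the proportion of probes whose
5hmC and 5mC channels anticorrelate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import BetaMatrix, Cohort, GeneSet, SampleSheet
from .stats import (
    EnrichmentResult,
    Table2x2,
    bh_adjust,
    chi_square_2xk,
    fisher_exact,
    odds_ratio_ci,
    two_proportion_z,
)

__all__ = [
    "quantile_normalize",
    "differential_expression",
    "top_expressed_genes",
    "expression_association",
    "methylation_extreme_probes",
    "spearman",
    "classify_groups",
    "gcimp_contribution",
    "negative_correlation_proportion",
    "compare_negative_proportions",
]


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every column (sample) onto the mean of the sorted columns.

    Tied values within a column receive the mean of the quantile values
    their positions would have taken.
    """
    if expr.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    arr = expr.to_numpy(dtype=float)
    sorted_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = sorted_means
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def differential_expression(
    expr: pd.DataFrame,
    sheet: SampleSheet,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-group contrast on log2 expression (pooled t = one-way
    ANOVA with two groups), BH adjustment, and the joint selection rule
    adj_p < alpha AND fold_change > fc_threshold.

    Zero-variance genes are flagged and excluded from adjustment/selection.
    """
    sheet.require_two_per_cohort()
    e = expr.loc[:, sheet.sample_ids]
    mt = sheet.cohort_mask(Cohort.MT)
    v = e.to_numpy(dtype=float)
    x, y = v[:, mt], v[:, ~mt]
    diff = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(x, y, axis=1, equal_var=True)
    flagged = ~np.isfinite(p)
    adj = np.full_like(diff, np.nan)
    ok = ~flagged
    if ok.any():
        adj[ok] = bh_adjust(p[ok])
    fc = 2.0 ** np.abs(diff)
    out = pd.DataFrame(
        {
            "gene": e.index,
            "log2_diff": diff,
            "fold_change": fc,
            "direction": np.where(diff >= 0, "UP_MT", "DOWN_MT"),
            "t_stat": t,
            "p": p,
            "adj_p": adj,
            "flagged": flagged,
        }
    ).set_index("gene", drop=False)
    out["selected"] = (~flagged) & (out["adj_p"] < alpha) & (fc > fc_threshold)
    return out


def top_expressed_genes(expr: pd.DataFrame, fraction: float = 0.2) -> set[str]:
    """Top ceil(fraction * n) genes by mean log2 expression over all
    samples; boundary ties broken by symbol order."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    means = expr.mean(axis=1)
    order = sorted(zip(-means.to_numpy(), means.index), key=lambda t: (t[0], t[1]))
    n_keep = int(np.ceil(fraction * len(order)))
    return {g for _, g in order[:n_keep]}


def expression_association(
    probes: set[str],
    ann: pd.DataFrame,
    top_genes: set[str],
    all_genes: set[str],
    region_filter: set[str] | None = None,
) -> EnrichmentResult:
    """2x2 association between membership in the probe set and the probe's
    target gene being highly expressed, optionally restricted to a subset
    of gene regions (e.g. promoter or gene body)."""
    sub = ann[ann["gene_symbol"].isin(all_genes)]
    if region_filter is not None:
        sub = sub[sub["gene_region"].isin(region_filter)]
    in_query = sub["probe_id"].isin(probes)
    if not in_query.any():
        raise ValueError("empty query: no probes left after region filter")
    in_top = sub["gene_symbol"].isin(top_genes)
    t = Table2x2(
        int((in_query & in_top).sum()),
        int((in_query & ~in_top).sum()),
        int((~in_query & in_top).sum()),
        int((~in_query & ~in_top).sum()),
    )
    return odds_ratio_ci(t)


def methylation_extreme_probes(
    mc: BetaMatrix, mask: np.ndarray, mode: tuple[str, float]
) -> set[str]:
    """Probes whose cohort-mean 5mC beta satisfies an inclusive threshold,
    mode ('ge', 0.7) or ('le', 0.3)."""
    op, thr = mode
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("mask selects no samples")
    means = mc.values.loc[:, mc.values.columns[mask]].mean(axis=1)
    if op == "ge":
        keep = means >= thr
    elif op == "le":
        keep = means <= thr
    else:
        raise ValueError(f"mode must be 'ge' or 'le', got {op!r}")
    return set(means.index[keep])


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and the t
    approximation (n - 2 df) for the p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("constant vector: Spearman undefined")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


_GROUPS = {("+", "UP_MT"): "G1", ("-", "UP_MT"): "G2",
           ("+", "DOWN_MT"): "G3", ("-", "DOWN_MT"): "G4"}


def classify_groups(
    hmc: BetaMatrix,
    mc: BetaMatrix,
    expr: pd.DataFrame,
    de: pd.DataFrame,
    probes: set[str] | list[str],
    ann: pd.DataFrame,
    rs_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Correlate each probe's 5hmC and 5mC with its target gene's
    expression; retain |r_5hmC| >= threshold and assign Groups 1-4.

    Returns (records, 2x2 sign-by-direction table, association p: Fisher
    when any cell is small, chi-square otherwise).  Only samples present in
    both the beta matrices and the expression matrix are used.
    """
    samples = [s for s in hmc.sample_ids if s in set(expr.columns)]
    if len(samples) < 4:
        raise ValueError("need >= 4 shared samples for correlations")
    de_sel = de[de["selected"]]
    records = []
    for probe in sorted(probes):
        if probe not in ann.index:
            continue
        gene = ann.loc[probe, "gene_symbol"]
        if gene is None or gene not in de_sel.index or gene not in expr.index:
            continue
        ev = expr.loc[gene, samples].to_numpy(dtype=float)
        hv = hmc.values.loc[probe, samples].to_numpy(dtype=float)
        mv = mc.values.loc[probe, samples].to_numpy(dtype=float)
        try:
            r_h, p_h = spearman(hv, ev)
            r_m, p_m = spearman(mv, ev)
        except ValueError:
            continue
        direction = de_sel.loc[gene, "direction"]
        if abs(r_h) >= rs_threshold:
            group = _GROUPS[("+" if r_h > 0 else "-", direction)]
        else:
            group = "NONE"
        records.append(
            {
                "probe_id": probe, "gene": gene,
                "r_5hmc": r_h, "p_5hmc": p_h,
                "r_5mc": r_m, "p_5mc": p_m,
                "gene_direction": direction, "group": group,
                "gene_region": ann.loc[probe, "gene_region"],
            }
        )
    rec = pd.DataFrame(
        records,
        columns=["probe_id", "gene", "r_5hmc", "p_5hmc", "r_5mc", "p_5mc",
                 "gene_direction", "group", "gene_region"],
    )
    kept = rec[rec["group"] != "NONE"]
    table = pd.DataFrame(
        [
            [int((kept["group"] == "G1").sum()), int((kept["group"] == "G2").sum())],
            [int((kept["group"] == "G3").sum()), int((kept["group"] == "G4").sum())],
        ],
        index=["UP_MT", "DOWN_MT"],
        columns=["positive_rs", "negative_rs"],
    )
    cells = table.to_numpy()
    if cells.sum() == 0:
        p_assoc = float("nan")
    elif (cells < 5).any():
        p_assoc = fisher_exact(
            Table2x2(cells[0, 0], cells[0, 1], cells[1, 0], cells[1, 1])
        )
    else:
        _, p_assoc = chi_square_2xk(cells)
    return rec, table, p_assoc


def gcimp_contribution(
    hmc: BetaMatrix,
    mc: BetaMatrix,
    genes: GeneSet,
    ann: pd.DataFrame,
    min_total: float = 0.3,
    level: str = "per_cohort",
    sheet: SampleSheet | None = None,
) -> pd.DataFrame:
    """Per-gene 5hmC share of total methylation, pct = 100 * 5hmC /
    (5hmC + 5mC), computed over the gene's probes.

    ``level`` is ``per_cohort`` (one row per gene x cohort; requires a
    sample sheet), ``per_sample``, or ``per_gene`` (pooled over all
    samples).  Genes whose total methylation falls
    below ``min_total`` are flagged ``excluded`` and should be left out of
    percentage summaries.
    """
    gene_probes = {
        g: ann.index[(ann["gene_symbol"] == g)].tolist() for g in sorted(genes.symbols)
    }
    rows = []
    if level == "per_cohort":
        if sheet is None:
            raise ValueError("per_cohort level needs a sample sheet")
        units = [(c.value, sheet.cohort_ids(c)) for c in Cohort]
    elif level == "per_sample":
        units = [(s, [s]) for s in hmc.sample_ids]
    elif level == "per_gene":
        units = [("ALL", hmc.sample_ids)]
    else:
        raise ValueError("level must be per_cohort, per_sample or per_gene")
    for gene, probes in gene_probes.items():
        probes = [p for p in probes if p in hmc.values.index]
        if not probes:
            rows.append({"gene": gene, "unit": None, "mean_5hmc": np.nan,
                         "mean_5mc": np.nan, "pct_5hmc": np.nan,
                         "excluded": True, "reason": "no probes"})
            continue
        for unit, sample_ids in units:
            mh = float(hmc.values.loc[probes, sample_ids].to_numpy().mean())
            mm = float(mc.values.loc[probes, sample_ids].to_numpy().mean())
            total = mh + mm
            excluded = total < min_total
            rows.append({
                "gene": gene, "unit": unit, "mean_5hmc": mh, "mean_5mc": mm,
                "pct_5hmc": 100.0 * mh / total if total > 0 else np.nan,
                "excluded": excluded,
                "reason": "total methylation below threshold" if excluded else "",
            })
    return pd.DataFrame(rows)


def negative_correlation_proportion(
    hmc: BetaMatrix, mc: BetaMatrix, probes: set[str] | list[str]
) -> tuple[float, int, int]:
    """Fraction of probes whose 5hmC-5mC Spearman correlation across
    samples is strictly negative.

    Returns (proportion, n_used, n_excluded); zero-variance probes are
    excluded and counted.  Compare two probe sets with
    :func:`hmcpipe.stats.two_proportion_z` on the returned counts.
    """
    n_neg = n_used = n_excl = 0
    for probe in probes:
        hv = hmc.values.loc[probe].to_numpy(dtype=float)
        mv = mc.values.loc[probe].to_numpy(dtype=float)
        try:
            r, _ = spearman(hv, mv)
        except ValueError:
            n_excl += 1
            continue
        n_used += 1
        n_neg += r < 0
    if n_used == 0:
        raise ValueError("no probes with usable variance")
    return n_neg / n_used, n_used, n_excl


def compare_negative_proportions(
    result_a: tuple[float, int, int], result_b: tuple[float, int, int]
) -> tuple[float, float]:
    """Two-proportion z comparison of two negative-correlation proportions."""
    pa, na, _ = result_a
    pb, nb, _ = result_b
    return two_proportion_z(round(pa * na), na, round(pb * nb), nb)
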