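"""5hmC/5mC quantification from paired BS/OxBS beta values.

The BS channel measures 5mC + 5hmC jointly and the OxBS channel 5mC alone,
so the per-probe difference BS - OxBS estimates the 5hmC beta value.
Negative differences are a technical artifact of the paired measurement and
are clamped to 1e-7 (strictly negative values only; exact zeros are kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .io import BetaMatrix, Channel, Cohort, SampleSheet
from .stats import bh_adjust

__all__ = [
    "CLAMP_VALUE",
    "TopProbeSet",
    "compute_5hmc",
    "compute_5mc",
    "top_fraction_probes",
    "volcano_stats",
    "stratify_counts",
    "fit_f_dist_prior",
]

CLAMP_VALUE = 1e-7


@dataclass(frozen=True)
class TopProbeSet:
    """Probes in the top ``fraction`` of cohort-mean beta values.

    Boundary ties are broken by probe_id lexical order; ``threshold_value``
    is the smallest selected mean.
    """

    cohort: str
    fraction: float
    probe_ids: tuple[str, ...]
    threshold_value: float

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in set(self.probe_ids)


def _check_aligned(bs: BetaMatrix, oxbs: BetaMatrix) -> None:
    if bs.probe_ids != oxbs.probe_ids:
        raise ValueError("BS and OxBS probe sets/order differ")
    if bs.sample_ids != oxbs.sample_ids:
        raise ValueError("BS and OxBS sample sets/order differ")


def compute_5hmc(
    bs: BetaMatrix, oxbs: BetaMatrix, clamp_value: float = CLAMP_VALUE
) -> BetaMatrix:
    """5hmC beta = BS - OxBS, with strictly negative differences clamped."""
    if bs.channel is not Channel.BS:
        raise ValueError(f"first argument must be BS channel, got {bs.channel}")
    if oxbs.channel is not Channel.OXBS:
        raise ValueError(f"second argument must be OxBS channel, got {oxbs.channel}")
    _check_aligned(bs, oxbs)
    delta = bs.values.to_numpy() - oxbs.values.to_numpy()
    clamped = np.where(delta < 0, clamp_value, delta)
    return BetaMatrix(
        pd.DataFrame(clamped, index=bs.values.index, columns=bs.values.columns),
        Channel.FIVE_HMC,
    )


def compute_5mc(oxbs: BetaMatrix) -> BetaMatrix:
    """Relabel the OxBS channel as the 5mC estimate (values unchanged)."""
    if oxbs.channel is not Channel.OXBS:
        raise ValueError(f"expected OxBS channel, got {oxbs.channel}")
    return BetaMatrix(oxbs.values.copy(), Channel.FIVE_MC)


def top_fraction_probes(
    beta: BetaMatrix,
    mask: np.ndarray | None = None,
    fraction: float = 0.01,
    cohort: str = "ALL",
) -> TopProbeSet:
    """Rank probes by mean beta over the masked samples; keep the top
    ceil(fraction * n_probes)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    values = beta.values
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < 1:
            raise ValueError("mask selects no samples")
        values = values.loc[:, values.columns[mask]]
    means = values.mean(axis=1)
    order = sorted(zip(-means.to_numpy(), means.index), key=lambda t: (t[0], t[1]))
    n_keep = int(np.ceil(fraction * len(order)))
    chosen = [pid for _, pid in order[:n_keep]]
    threshold = float(means.loc[chosen].min())
    return TopProbeSet(cohort, fraction, tuple(chosen), threshold)


def fit_f_dist_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the scaled-F prior (d0, s0^2) for residual variances by moment
    matching on log s^2 (digamma/trigamma scale).

    Returns (d0, s0sq); d0 = inf when the observed spread of log-variances
    is no larger than expected from the chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to fit prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    target = e_var - special.polygamma(1, df / 2)
    if target <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = target by Newton on x = d0/2
    x = 0.5 + 1.0 / target
    for _ in range(60):
        tri = special.polygamma(1, x)
        step = tri * (target - tri) / (target * special.polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    d0 = 2 * x
    s0sq = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    return float(d0), s0sq


def volcano_stats(
    hmc: BetaMatrix,
    sheet: SampleSheet,
    prior_df_mode: str | float = "moment",
) -> pd.DataFrame:
    """Per-probe moderated-t contrast of cohort means (MT - WT).

    ``prior_df_mode`` is ``"moment"`` for the empirical-Bayes moment fit or
    a fixed nonnegative prior df (0 gives the ordinary pooled two-sample t).
    Zero-variance probes with no prior are flagged (``flagged=True``,
    NaN p) and excluded from the BH adjustment.
    """
    sheet.require_two_per_cohort()
    bm = hmc.reorder_samples(sheet.sample_ids)
    v = bm.values.to_numpy()
    mt = sheet.cohort_mask(Cohort.MT)
    wt = sheet.cohort_mask(Cohort.WT)
    n1, n2 = int(mt.sum()), int(wt.sum())
    mean_mt = v[:, mt].mean(axis=1)
    mean_wt = v[:, wt].mean(axis=1)
    delta = mean_mt - mean_wt
    ss = ((v[:, mt] - mean_mt[:, None]) ** 2).sum(axis=1) + (
        (v[:, wt] - mean_wt[:, None]) ** 2
    ).sum(axis=1)
    dg = n1 + n2 - 2
    s2 = ss / dg

    if prior_df_mode == "moment":
        d0, s0sq = fit_f_dist_prior(s2, dg)
    else:
        d0 = float(prior_df_mode)
        if d0 < 0:
            raise ValueError("fixed prior df must be >= 0")
        s0sq = 0.0

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    scale = np.sqrt(1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / (np.sqrt(s2_tilde) * scale)
    flagged = ~np.isfinite(t)
    t = np.where(flagged, np.nan, t)
    if np.isinf(df_total):
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = 2 * sps.t.sf(np.abs(t), df_total)
    adj = np.full_like(p, np.nan)
    ok = ~flagged
    if ok.any():
        adj[ok] = bh_adjust(p[ok])
    return pd.DataFrame(
        {
            "probe_id": bm.values.index,
            "delta_beta": delta,
            "t_stat": t,
            "p_value": p,
            "adj_p": adj,
            "flagged": flagged,
        }
    ).set_index("probe_id", drop=False)


def stratify_counts(
    probes, ann: pd.DataFrame, by: str = "cpg_feature"
) -> pd.DataFrame:
    """Counts and proportions of a probe set per annotation category."""
    if by not in ("cpg_feature", "gene_region"):
        raise ValueError("stratify by cpg_feature or gene_region")
    probe_ids = list(probes.probe_ids) if isinstance(probes, TopProbeSet) else list(probes)
    missing = set(probe_ids) - set(ann.index)
    if missing:
        raise ValueError(f"probes missing from annotation: {sorted(missing)[:10]}")
    counts = ann.loc[probe_ids, by].value_counts()
    out = counts.rename("count").to_frame()
    out["proportion"] = out["count"] / out["count"].sum()
    return out
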