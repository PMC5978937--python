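"""hMeDIP validation arithmetic: windowed read counting, differential
window filtering, window-gene intersection, and spike-in-normalized qPCR
enrichment.

Windows tile each chromosome from 0 in fixed steps (default 100 bp); a
read increments every window it overlaps by at least one base after being
extended to the library fragment length from its 5' end.  Differential
windows are kept when the raw read count averaged over all samples is at
least ``min_mean`` and the log2 fold change of CPM-normalized cohort means
(with a pseudocount) exceeds ``logfc_cut`` in magnitude.  qPCR enrichment
is normalized by the recovery of an exogenous spiked-in 5hmC control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort, SampleSheet
from .stats import EnrichmentMethod, EnrichmentResult, Table2x2, hypergeom_tail

__all__ = [
    "SpikeEnrichment",
    "count_windows",
    "differential_windows",
    "windows_to_genes",
    "spike_normalized_enrichment",
    "overlap_with_array_genes",
]


@dataclass(frozen=True)
class SpikeEnrichment:
    sample_id: str
    target_name: str
    raw_target: float
    raw_spike: float

    @property
    def normalized(self) -> float:
        return self.raw_target / self.raw_spike


def _extend_reads(reads: pd.DataFrame, extend: int, chrom_len: int) -> pd.DataFrame:
    start = reads["start"].to_numpy(dtype=np.int64).copy()
    end = reads["end"].to_numpy(dtype=np.int64).copy()
    length = end - start
    grow = np.maximum(length, extend)
    if "strand" in reads.columns:
        minus = (reads["strand"] == "-").to_numpy()
        end = np.where(minus, end, start + grow)
        start = np.where(minus, end - grow, start)
    else:
        end = start + grow
    if (start < 0).any() or (end > chrom_len).any():
        warnings.warn("read interval beyond chromosome bounds; clipping")
        start = np.clip(start, 0, chrom_len)
        end = np.clip(end, 0, chrom_len)
    return pd.DataFrame({"start": start, "end": end})


def count_windows(
    reads: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    ws: int = 100,
    extend: int = 300,
    dedup: bool = False,
) -> pd.DataFrame:
    """Count reads per tiling window per sample.

    ``reads`` maps sample id to a BED-like frame (chrom, start, end
    [, strand], 0-based half-open).  ``dedup`` drops exact duplicate
    intervals within a sample before counting.  Windows with no reads in
    any sample are omitted from the output.
    """
    if ws <= 0:
        raise ValueError("ws must be positive")
    sample_ids = list(reads)
    n_win = {c: int(np.ceil(L / ws)) for c, L in chrom_sizes.items()}
    counts = {
        c: np.zeros((n_win[c], len(sample_ids)), dtype=np.int64) for c in chrom_sizes
    }
    for j, sid in enumerate(sample_ids):
        bed = reads[sid]
        if bed.empty:
            continue
        if dedup:
            bed = bed.drop_duplicates(subset=["chrom", "start", "end"])
        for chrom, grp in bed.groupby("chrom"):
            if chrom not in chrom_sizes:
                raise ValueError(f"read on unknown chromosome {chrom!r}")
            ext = _extend_reads(grp, extend, chrom_sizes[chrom])
            first = ext["start"].to_numpy() // ws
            last = (ext["end"].to_numpy() - 1) // ws
            keep = ext["end"].to_numpy() > ext["start"].to_numpy()
            for f, l in zip(first[keep], last[keep]):
                counts[chrom][f : l + 1, j] += 1
    frames = []
    for chrom in chrom_sizes:
        arr = counts[chrom]
        nonzero = np.flatnonzero(arr.sum(axis=1) > 0)
        if nonzero.size == 0:
            continue
        frame = pd.DataFrame(arr[nonzero], columns=sample_ids)
        frame.insert(0, "chrom", chrom)
        frame.insert(1, "start", nonzero * ws)
        frame.insert(2, "end", (nonzero + 1) * ws)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", *sample_ids])
    return pd.concat(frames, ignore_index=True)


def differential_windows(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    min_mean: float = 3.0,
    logfc_cut: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Filter windows on mean raw coverage and CPM-normalized log2 fold
    change between cohorts; only passing windows are returned."""
    sample_ids = [s for s in sheet.sample_ids if s in counts.columns]
    if not sample_ids:
        raise ValueError("no sample sheet samples in count table")
    mt_ids = [s for s in sample_ids if s in set(sheet.cohort_ids(Cohort.MT))]
    wt_ids = [s for s in sample_ids if s in set(sheet.cohort_ids(Cohort.WT))]
    if not mt_ids or not wt_ids:
        raise ValueError("need >= 1 sample per cohort")
    raw = counts[sample_ids].to_numpy(dtype=float)
    lib = raw.sum(axis=0)
    cpm = raw / np.where(lib > 0, lib, 1.0) * 1e6
    cpm_df = pd.DataFrame(cpm, columns=sample_ids)
    mean_reads = raw.mean(axis=1)
    mean_mt = cpm_df[mt_ids].mean(axis=1).to_numpy()
    mean_wt = cpm_df[wt_ids].mean(axis=1).to_numpy()
    log_fc = np.log2((mean_mt + pseudocount) / (mean_wt + pseudocount))
    out = counts[["chrom", "start", "end"]].copy()
    out["mean_reads"] = mean_reads
    out["log_fc"] = log_fc
    out["passes"] = (mean_reads >= min_mean) & (np.abs(log_fc) > logfc_cut)
    return out[out["passes"]].reset_index(drop=True)


def windows_to_genes(
    windows: pd.DataFrame, gene_intervals: pd.DataFrame
) -> dict[str, set[str]]:
    """Genes overlapping >= 1 passing window, split by fold-change sign.

    ``gene_intervals`` needs columns gene, chrom, start, end (0-based
    half-open).
    """
    out = {"up": set(), "down": set()}
    if windows.empty:
        return out
    for chrom, gw in windows.groupby("chrom"):
        genes = gene_intervals[gene_intervals["chrom"] == chrom]
        if genes.empty:
            continue
        ws_, we_ = gw["start"].to_numpy(), gw["end"].to_numpy()
        lfc = gw["log_fc"].to_numpy()
        gs, ge = genes["start"].to_numpy(), genes["end"].to_numpy()
        for g, s, e in zip(genes["gene"], gs, ge):
            overlap = (ws_ < e) & (we_ > s)
            if overlap.any():
                signs = lfc[overlap]
                if (signs > 0).any():
                    out["up"].add(g)
                if (signs < 0).any():
                    out["down"].add(g)
    return out


def spike_normalized_enrichment(
    raw_target: float, raw_spike: float, sample_id: str = "", target_name: str = ""
) -> SpikeEnrichment:
    """Spike-in normalized enrichment = target enrichment / spike-in
    (exogenous control) enrichment."""
    if raw_spike <= 0:
        raise ValueError("spike-in enrichment must be positive")
    if raw_target <= 0:
        raise ValueError("target enrichment must be positive")
    return SpikeEnrichment(sample_id, target_name, float(raw_target), float(raw_spike))


def overlap_with_array_genes(
    hmedip_genes: set[str],
    array_genes: set[str],
    universe_size: int = 20345,
) -> EnrichmentResult:
    """Hypergeometric upper-tail significance of the overlap between
    hMeDIP-derived genes and array-derived genes in a genome of
    ``universe_size`` protein-coding genes."""
    k = len(hmedip_genes & array_genes)
    K, n = len(array_genes), len(hmedip_genes)
    if k > min(K, n):
        raise ValueError("overlap exceeds set sizes")
    p = hypergeom_tail(universe_size, K, n, k)
    table = Table2x2(k, n - k, K - k, universe_size - n - K + k)
    return EnrichmentResult(
        float("nan"), float("nan"), float("nan"), p,
        EnrichmentMethod.HYPERGEOM, (table,),
    )
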