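"""Readers, writers and probe filtering for the on-disk study artifacts.

All tabular artifacts are plain text: CSV for the sample sheet, TSV for
beta-value matrices and the probe annotation, one-symbol-per-line files for
gene sets, and BED (0-based half-open) for detected regions.  Annotations
are held 1-based internally; conversion to BED coordinates happens only on
output.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "Cohort",
    "SampleSheet",
    "BetaMatrix",
    "GeneSet",
    "ANNOTATION_COLUMNS",
    "CPG_FEATURES",
    "GENE_REGIONS",
    "read_sample_sheet",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_annotation",
    "validate_annotation",
    "enhancer_sources",
    "read_gene_set",
    "write_gene_set",
    "filter_probes",
    "write_regions_bed",
]


class Channel(str, enum.Enum):
    """Which molecular signal a beta matrix carries."""

    BS = "BS"            # bisulfite: 5mC + 5hmC jointly
    OXBS = "OxBS"        # oxidative bisulfite: 5mC alone
    FIVE_MC = "5mC"
    FIVE_HMC = "5hmC"


class Cohort(str, enum.Enum):
    MT = "MT"
    WT = "WT"


CPG_FEATURES = ("ISLAND", "SHORE", "SHELF", "OPEN_SEA")
GENE_REGIONS = (
    "TSS200",
    "TSS1500",
    "FIRST_EXON",
    "FIVE_UTR",
    "BODY",
    "INTRON",
    "THREE_UTR",
    "INTERGENIC",
)

#: Fixed leading columns of the probe annotation table.  Any number of
#: ``enhancer_*`` boolean columns may sit between ``gene_symbol`` and
#: ``snp_flag``.
ANNOTATION_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "cpg_feature",
    "gene_region",
    "gene_symbol",
    "snp_flag",
    "sex_chrom_flag",
)


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: cohort label plus optional clinical covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.empty:
            raise ValueError("no samples in sample sheet")
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        bad = ~t["cohort"].isin([c.value for c in Cohort])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unknown cohort token {t['cohort'].iloc[row]!r} in row {row + 2}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def cohort_mask(self, cohort: Cohort | str) -> np.ndarray:
        """Boolean mask over samples, in sheet order."""
        label = Cohort(cohort).value
        return (self.table["cohort"] == label).to_numpy()

    def cohort_ids(self, cohort: Cohort | str) -> list[str]:
        return self.table.loc[self.cohort_mask(cohort), "sample_id"].tolist()

    def counts(self) -> dict[str, int]:
        return {c.value: int(self.cohort_mask(c).sum()) for c in Cohort}

    def require_two_per_cohort(self) -> None:
        counts = self.counts()
        for label, n in counts.items():
            if n < 2:
                raise ValueError(
                    f"two-group statistics need >= 2 samples per cohort, "
                    f"got {n} in {label}"
                )


@dataclass
class BetaMatrix:
    """Probe x sample matrix of beta values in [0, 1] with a channel tag.

    ``values`` is indexed by probe_id with one column per sample_id; both
    axes are unique and ordered.
    """

    values: pd.DataFrame
    channel: Channel

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy()
        if arr.size and (not np.isfinite(arr).all() or arr.min() < 0 or arr.max() > 1):
            raise ValueError("beta values must be finite and in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def reorder_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise ValueError(f"samples absent from matrix: {sorted(missing)}")
        return BetaMatrix(self.values.loc[:, list(sample_ids)], self.channel)

    def restrict_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)], self.channel)


@dataclass(frozen=True)
class GeneSet:
    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV sample sheet (sample_id, cohort[, age_years, who_grade, histology]).

    Cohort tokens are normalized case-insensitively to MT/WT.
    """
    t = pd.read_csv(path, dtype={"sample_id": str})
    if t.empty:
        raise ValueError(f"no samples in {path}")
    required = {"sample_id", "cohort"}
    if not required.issubset(t.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    t = t.copy()
    t["cohort"] = t["cohort"].astype(str).str.strip().str.upper()
    if "age_years" in t.columns and (t["age_years"].dropna() < 0).any():
        raise ValueError("negative age_years")
    return SampleSheet(t.reset_index(drop=True))


def read_beta_matrix(
    path: str | Path,
    channel: Channel | str,
    sheet: SampleSheet | None = None,
) -> BetaMatrix:
    """Read a TSV beta matrix (first column probe_id, one column per sample).

    If a sample sheet is given the columns are re-ordered to sheet order so
    downstream cohort masks are positional; missing samples are an error.
    """
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index = t.index.astype(str)
    arr = t.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for col in t.columns:
            coerced = pd.to_numeric(t[col], errors="coerce")
            bad = coerced.isna() & t[col].notna()
            if bad.any():
                probe = t.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric value at probe {probe!r}, sample {col!r} in {path}"
                )
        t = t.apply(pd.to_numeric)
        arr = t.to_numpy()
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"missing beta value at probe {t.index[r]!r}, sample {t.columns[c]!r}"
        )
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        r, c = np.argwhere((arr < 0) | (arr > 1))[0]
        raise ValueError(
            f"beta value {arr[r, c]} outside [0, 1] at probe {t.index[r]!r}, "
            f"sample {t.columns[c]!r}"
        )
    bm = BetaMatrix(t, Channel(channel))
    if sheet is not None:
        bm = bm.reorder_samples(sheet.sample_ids)
    return bm


def write_beta_matrix(path: str | Path, beta: BetaMatrix) -> None:
    beta.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.12g")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe annotation table and normalize its dtypes."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    ann = ann.copy()
    ann["probe_id"] = ann["probe_id"].astype(str)
    if ann["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_id in annotation")
    if (ann["pos"] < 1).any():
        raise ValueError("annotation positions are 1-based; pos must be >= 1")
    if not ann["cpg_feature"].isin(CPG_FEATURES).all():
        bad = sorted(set(ann["cpg_feature"]) - set(CPG_FEATURES))
        raise ValueError(f"unknown cpg_feature values {bad}")
    if not ann["gene_region"].isin(GENE_REGIONS).all():
        bad = sorted(set(ann["gene_region"]) - set(GENE_REGIONS))
        raise ValueError(f"unknown gene_region values {bad}")
    sym = ann["gene_symbol"]
    ann["gene_symbol"] = sym.where(sym.notna() & (sym != ""), None)
    inter = ann["gene_region"] == "INTERGENIC"
    if (inter & ann["gene_symbol"].notna()).any():
        raise ValueError("INTERGENIC probes must not carry a gene_symbol")
    for col in list(ann.columns):
        if col.startswith("enhancer_") or col in ("snp_flag", "sex_chrom_flag"):
            ann[col] = ann[col].astype(bool)
    return ann.set_index("probe_id", drop=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    return validate_annotation(ann)


def enhancer_sources(ann: pd.DataFrame) -> list[str]:
    return [c for c in ann.columns if c.startswith("enhancer_")]


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    symbols = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GeneSet(name or Path(path).stem, frozenset(symbols))


def write_gene_set(path: str | Path, genes: GeneSet) -> None:
    Path(path).write_text("\n".join(sorted(genes.symbols)) + "\n")


def filter_probes(
    beta: BetaMatrix,
    ann: pd.DataFrame,
    drop_snp: bool = True,
    drop_sex: bool = True,
) -> BetaMatrix:
    """Drop SNP-overlapping and/or sex-chromosome probes, preserving order."""
    probes = beta.values.index
    unknown = probes.difference(ann.index)
    if len(unknown):
        raise ValueError(f"probes missing from annotation: {sorted(unknown)[:10]}")
    sub = ann.loc[probes]
    keep = pd.Series(True, index=probes)
    if drop_snp:
        keep &= ~sub["snp_flag"]
    if drop_sex:
        keep &= ~sub["sex_chrom_flag"]
    return BetaMatrix(beta.values.loc[keep.to_numpy()], beta.channel)


def write_regions_bed(path: str | Path, regions: Iterable) -> None:
    """Write detected regions as BED plus a sidecar ``<path>.stats.tsv``.

    BED score is -log10(adjusted p) capped at 1000.  Internal coordinates are
    1-based inclusive; BED output is 0-based half-open.
    """
    path = Path(path)
    regions = list(regions)
    lines = ["#chrom\tstart\tend\tname\tscore"]
    rows = []
    for r in regions:
        if r.start > r.end:
            raise ValueError(f"region {r.region_id}: start > end")
        score = 1000.0 if r.adj_p <= 0 else min(1000.0, -math.log10(r.adj_p))
        lines.append(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\t{score:.4g}")
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_probes": r.n_probes,
                "value": r.value,
                "area": r.area,
                "p_value": r.p_value,
                "adj_p": r.adj_p,
                "probe_ids": ",".join(r.probe_ids),
            }
        )
    path.write_text("\n".join(lines) + "\n")
    pd.DataFrame(
        rows,
        columns=[
            "region_id", "chrom", "start", "end", "n_probes",
            "value", "area", "p_value", "adj_p", "probe_ids",
        ],
    ).to_csv(path.with_suffix(path.suffix + ".stats.tsv"), sep="\t", index=False)
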