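"""TSV input/output for trait and covariate matrices, cis pairing and
MAF filtering.

The interchange format is tab-separated text: one header row of sample
identifiers, first column feature/covariate identifiers, numeric cells
("NA" or empty for missing).  Coordinates are 1-based inclusive;
variant-to-feature distances are measured to the nearest edge of the
feature interval (0 inside it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidArgumentError

logger = logging.getLogger(__name__)

COVARIATE_KINDS = ("discrete", "dosage", "binary", "continuous")


@dataclass
class TraitMatrix:
    """Features x samples trait matrix with optional feature coordinates
    (chromosome, start, end; 1-based inclusive)."""

    data: pd.DataFrame
    coords: pd.DataFrame | None = None


@dataclass
class CovariateTable:
    """Covariates x samples matrix with optional per-covariate kind,
    variant coordinates (chromosome, position) and MAF."""

    data: pd.DataFrame
    kinds: pd.Series | None = None
    coords: pd.DataFrame | None = None
    maf: pd.Series | None = None

    def computed_maf(self) -> pd.Series:
        """Per-covariate MAF: supplied values where present, otherwise
        min(m, 1-m) with m = row mean / 2 (discrete or dosage rows)."""
        if self.maf is not None:
            return self.maf
        m = self.data.mean(axis=1) / 2.0
        return pd.Series(np.minimum(m, 1.0 - m), index=self.data.index,
                         name="maf")


def _read_matrix(path, what: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = [h for h in header if header.count(h) > 1]
    if dups:
        raise FormatError(
            f"duplicate sample identifier(s): {sorted(set(dups))}")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     na_values=["NA", ""], keep_default_na=False)
    dup_rows = df.index[df.index.duplicated()].unique()
    if len(dup_rows):
        raise FormatError(f"duplicate {what} identifier(s): {list(dup_rows)}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            addr = f"row {bad[0]!r}, column {col!r}" if len(bad) else f"column {col!r}"
            raise FormatError(f"non-numeric cell at {addr}")
    n_missing = int(df.isna().sum().sum())
    logger.info("read %s: %d rows x %d samples (%d missing values)",
                what, df.shape[0], df.shape[1], n_missing)
    return df.astype(float)


def read_trait_matrix(path, coords_path=None) -> TraitMatrix:
    coords = None
    if coords_path is not None:
        coords = pd.read_csv(coords_path, sep="\t", index_col=0)
    return TraitMatrix(data=_read_matrix(path, "trait"), coords=coords)


def read_covariate_table(path, coords_path=None) -> CovariateTable:
    coords = None
    if coords_path is not None:
        coords = pd.read_csv(coords_path, sep="\t", index_col=0)
    return CovariateTable(data=_read_matrix(path, "covariate"), coords=coords)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def make_cis_pairs(trait_coords: pd.DataFrame, cov_coords: pd.DataFrame,
                   window: int) -> pd.DataFrame:
    """All (trait, covariate) pairs on the same chromosome within
    ``window`` bases of each other.

    ``trait_coords`` needs columns chrom/start/end, ``cov_coords`` needs
    chrom/pos (1-based inclusive).  The distance from a variant to a
    feature is 0 inside [start, end] and the distance to the nearest
    edge otherwise; pairs with distance <= window are kept.
    """
    for df, cols in ((trait_coords, ("chrom", "start", "end")),
                     (cov_coords, ("chrom", "pos"))):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"missing coordinate columns: {missing}")
        bad = df.index[df[list(cols)].isna().any(axis=1)]
        if len(bad):
            raise InvalidArgumentError(
                f"missing coordinates for: {list(bad)}")
    rows = []
    for chrom, tsub in trait_coords.groupby("chrom"):
        csub = cov_coords[cov_coords.chrom == chrom]
        if csub.empty:
            continue
        pos = csub.pos.to_numpy(dtype=float)
        for tid, t in tsub.iterrows():
            dist = np.where(
                pos < t.start, t.start - pos,
                np.where(pos > t.end, pos - t.end, 0.0))
            keep = dist <= window
            for cid, d in zip(csub.index[keep], dist[keep]):
                rows.append({"trait_id": tid, "covariate_id": cid,
                             "distance": int(d)})
    return pd.DataFrame(rows, columns=["trait_id", "covariate_id", "distance"])


def filter_maf(covariates: CovariateTable, min_maf: float) -> CovariateTable:
    """Drop covariates with minor allele frequency below ``min_maf``."""
    maf = covariates.computed_maf()
    keep = maf >= min_maf
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_maf: removed %d covariates below MAF %g",
                    n_drop, min_maf)

    def _sub(obj):
        return obj.loc[keep[keep].index] if obj is not None else None

    return CovariateTable(
        data=covariates.data.loc[keep],
        kinds=_sub(covariates.kinds),
        coords=_sub(covariates.coords),
        maf=maf[keep],
    )


def align_samples(traits: TraitMatrix, covariates: CovariateTable,
                  ) -> tuple[TraitMatrix, CovariateTable]:
    """Inner-join the sample columns of a trait matrix and covariate table."""
    common = [s for s in traits.data.columns if s in set(covariates.data.columns)]
    if not common:
        raise InvalidArgumentError("no samples shared between traits and covariates")
    return (TraitMatrix(traits.data[common], traits.coords),
            CovariateTable(covariates.data[common], covariates.kinds,
                           covariates.coords, covariates.maf))
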