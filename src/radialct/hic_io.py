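"""Reading, writing and normalizing binned Hi-C contact matrices.

The central container is :class:`HicMatrix`: a dense square symmetric
matrix of contact counts (raw) or balanced contact strengths (after ICE),
annotated with a :class:`BinTable` mapping matrix rows to genomic bins.
Matrices are expected at a fixed resolution (2.5 Mb for human data is the
tested operating point); the last bin of each chromosome may be shorter.

Accepted on-disk dialects:

``dense``
    whitespace/TAB separated square numeric text, one matrix row per line.
``triplet``
    TSV with three columns ``bin1  bin2  count`` (0-based bin indices);
    symmetrized on read.
``cooler``
    a cooler container, available only when the optional :mod:`cooler`
    package is installed.

Bin tables are BED-like TSV: ``chrom  start  end`` plus an optional
fourth 0/1 ``mappable`` column. Chromosome property tables are TSV with
columns ``chrom  gene_density  length_bp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CHROMS",
    "BinTable",
    "HicMatrix",
    "ChromProperties",
    "HicFormatError",
    "read_bins",
    "write_bins",
    "read_matrix",
    "write_matrix",
    "filter_bins",
    "ice_normalize",
    "read_properties",
    "write_properties",
]

#: Canonical chromosome order used throughout: 22 autosomes then chrX.
#: chrY is never part of an analysis-ready matrix.
CHROMS: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

_SYMMETRY_RTOL = 1e-8


class HicFormatError(ValueError):
    """Raised when an input file violates the matrix/bin-table contract."""


@dataclass(frozen=True)
class BinTable:
    """Genomic bins backing the rows/columns of a contact matrix.

    Coordinates are 0-based half-open; bins within a chromosome are
    contiguous and sorted; row ``i`` of the matrix is bin ``i``.
    """

    df: pd.DataFrame  # columns: chrom, start, end, mappable

    def __post_init__(self):
        required = {"chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise HicFormatError(f"bin table needs columns {sorted(required)}")
        if "mappable" not in self.df.columns:
            self.df["mappable"] = True
        if (self.df["end"] <= self.df["start"]).any():
            raise HicFormatError("bin table has end <= start")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in first-appearance order."""
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_indices(self) -> dict[str, np.ndarray]:
        """Map each chromosome to the array of its bin indices."""
        labels = self.chrom
        return {c: np.flatnonzero(labels == c) for c in self.chromosomes}

    def subset(self, keep: np.ndarray) -> "BinTable":
        return BinTable(self.df.iloc[keep].reset_index(drop=True).copy())


@dataclass
class HicMatrix:
    """Square symmetric contact matrix with bin annotations."""

    values: np.ndarray
    bins: BinTable
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise HicFormatError("contact matrix must be square")
        if self.values.shape[0] != len(self.bins):
            raise HicFormatError(
                f"matrix dimension {self.values.shape[0]} does not match "
                f"bin table length {len(self.bins)}"
            )
        if (self.values < 0).any():
            raise HicFormatError("contact matrix has negative entries")
        scale = max(1.0, float(np.abs(self.values).max()))
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_RTOL * scale):
            raise HicFormatError("contact matrix is not symmetric")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "HicMatrix":
        return HicMatrix(self.values.copy(), self.bins, self.normalized)


@dataclass(frozen=True)
class ChromProperties:
    """Per-chromosome gene density (genes per sequenced Mb) and length (bp)."""

    df: pd.DataFrame  # columns: chrom, gene_density, length_bp

    def __post_init__(self):
        required = {"chrom", "gene_density", "length_bp"}
        if not required.issubset(self.df.columns):
            raise HicFormatError(f"property table needs columns {sorted(required)}")
        if (self.df["gene_density"] <= 0).any() or (self.df["length_bp"] <= 0).any():
            raise HicFormatError("gene_density and length_bp must be positive")

    def reindex(self, chroms) -> "ChromProperties":
        """Return properties restricted to and ordered by ``chroms``."""
        df = self.df.set_index("chrom")
        missing = [c for c in chroms if c not in df.index]
        if missing:
            raise HicFormatError(f"properties missing chromosomes: {missing}")
        return ChromProperties(df.loc[list(chroms)].reset_index())

    @property
    def gene_density(self) -> np.ndarray:
        return self.df["gene_density"].to_numpy(dtype=float)

    @property
    def length_bp(self) -> np.ndarray:
        return self.df["length_bp"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# bin tables and property tables


def read_bins(path) -> BinTable:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "mappable"],
    )
    if df["mappable"].isna().all():
        df["mappable"] = True
    else:
        df["mappable"] = df["mappable"].fillna(1).astype(bool)
    return BinTable(df)


def write_bins(bins: BinTable, path) -> None:
    out = bins.df[["chrom", "start", "end"]].copy()
    out["mappable"] = bins.df["mappable"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_properties(path) -> ChromProperties:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "chrom" not in df.columns:  # headerless fallback
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "gene_density", "length_bp"],
        )
    return ChromProperties(df[["chrom", "gene_density", "length_bp"]])


def write_properties(props: ChromProperties, path) -> None:
    props.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path, bins: BinTable | str, dialect: str = "dense") -> HicMatrix:
    """Read a contact matrix in one of the accepted dialects.

    ``bins`` may be a :class:`BinTable` or a path to one (ignored for the
    cooler dialect, which carries its own bin table). The returned matrix
    is raw (``normalized=False``); triplet input is symmetrized so each
    off-diagonal record populates both (i, j) and (j, i).
    """
    if isinstance(bins, (str,)) or hasattr(bins, "__fspath__"):
        bins = read_bins(bins)
    if dialect == "dense":
        values = np.loadtxt(path, dtype=float)
        values = np.atleast_2d(values)
        return HicMatrix(values, bins)
    if dialect == "triplet":
        trip = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["bin1", "bin2", "count"],
        )
        m = len(bins)
        b1 = trip["bin1"].to_numpy(dtype=int)
        b2 = trip["bin2"].to_numpy(dtype=int)
        if len(b1) and (b1.min() < 0 or b2.min() < 0 or b1.max() >= m or b2.max() >= m):
            raise HicFormatError(
                f"triplet bin index outside 0..{m - 1} (bin table has {m} bins)"
            )
        values = np.zeros((m, m), dtype=float)
        np.add.at(values, (b1, b2), trip["count"].to_numpy(dtype=float))
        off = b1 != b2
        np.add.at(values, (b2[off], b1[off]), trip["count"].to_numpy(dtype=float)[off])
        return HicMatrix(values, bins)
    if dialect == "cooler":
        try:
            import cooler  # noqa: F401
        except ImportError as exc:
            raise HicFormatError(
                "cooler dialect requires the optional 'cooler' package"
            ) from exc
        clr = cooler.Cooler(str(path))
        values = clr.matrix(balance=False)[:]
        bdf = clr.bins()[:][["chrom", "start", "end"]].copy()
        bdf["chrom"] = bdf["chrom"].astype(str)
        return HicMatrix(np.nan_to_num(values, nan=0.0), BinTable(bdf))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_matrix(H: HicMatrix, path, dialect: str = "dense") -> None:
    if dialect == "dense":
        np.savetxt(path, H.values, delimiter="\t", fmt="%.10g")
        return
    if dialect == "triplet":
        iu = np.triu_indices(H.m)
        vals = H.values[iu]
        nz = vals != 0
        df = pd.DataFrame({"bin1": iu[0][nz], "bin2": iu[1][nz], "count": vals[nz]})
        df.to_csv(path, sep="\t", header=False, index=False)
        return
    raise ValueError(f"unsupported write dialect {dialect!r}")


def filter_bins(
    H: HicMatrix,
    drop_chroms: tuple[str, ...] = ("chrY",),
    auto_flag_unmappable: bool = True,
) -> HicMatrix:
    """Drop chrY and unmappable bins; re-index the matrix contiguously.

    A bin with an all-zero row is treated as unmappable when
    ``auto_flag_unmappable`` is on (an operational proxy for repetitive,
    alignment-poor regions which accumulate no valid read pairs). Values
    of retained bins are never altered.
    """
    keep = ~np.isin(H.bins.chrom, drop_chroms)
    keep &= H.bins.df["mappable"].to_numpy(dtype=bool)
    if auto_flag_unmappable:
        keep &= H.values.sum(axis=1) > 0
    before = set(H.bins.chromosomes) - set(drop_chroms)
    idx = np.flatnonzero(keep)
    out = HicMatrix(H.values[np.ix_(idx, idx)], H.bins.subset(idx), H.normalized)
    lost = before - set(out.bins.chromosomes)
    if lost:
        warnings.warn(f"all bins removed for chromosome(s): {sorted(lost)}")
    return out


def ice_normalize(H: HicMatrix, max_iter: int = 200, tol: float = 1e-6) -> HicMatrix:
    """Iterative correction (ICE) to uniform bin coverage.

    Row/column balancing is iterated until the coefficient of variation
    of the row sums drops below ``tol``; the result is rescaled so its
    total equals the input total, preserving the read count. Bins with a
    zero row sum must be filtered beforehand.
    """
    if H.normalized:
        warnings.warn("input already flagged normalized; re-balancing anyway")
    values = H.values.astype(float).copy()
    rowsum = values.sum(axis=1)
    if (rowsum == 0).any():
        raise ValueError(
            "zero-coverage bin present; run filter_bins before ice_normalize"
        )
    total = values.sum()
    cv = np.inf
    for _ in range(max_iter):
        rowsum = values.sum(axis=1)
        cv = rowsum.std() / rowsum.mean()
        if cv < tol:
            break
        b = rowsum / rowsum.mean()
        values /= np.outer(b, b)
    else:
        rowsum = values.sum(axis=1)
        cv = rowsum.std() / rowsum.mean()
        if cv >= tol:
            warnings.warn(
                f"ICE did not reach row-sum CV < {tol:g} in {max_iter} iterations "
                f"(achieved {cv:.3g})"
            )
    values *= total / values.sum()
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return HicMatrix(values, H.bins, normalized=True)
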