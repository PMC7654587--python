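"""Chromosome-property tuning of consensus radial distances.

The selected model cluster D' (t models x 23 territories) gives a mean
radial profile M. A second, complementary summary P comes from PCA on
the 23x23 chromosome-chromosome correlation matrix of D': PC1 captures
the dominant axis along which territories separate across models. M and
P are combined into C by weights W1, W2 proportional to the variance
fractions of PC1 and PC2:

    C = W1 * M + W2 * P,   W1 = v1 / (v1 + v2),   W2 = v2 / (v1 + v2)

A property reference vector R mixes normalized gene density (as
exp(1 - GD), so gene-poor chromosomes push outward) and normalized
length with the same weights, the larger weight W1 on the component
matching the inferred organization type:

    R = W1 * exp(1 - GD) + W2 * LN    (gene-density organization)
    R = W2 * exp(1 - GD) + W1 * LN    (length organization)

Finally C is loess-smoothed against R; the fitted values are the tuned
radial distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hic_io import ChromProperties
from .pca_ordering import _pca_rows

__all__ = [
    "TunedProfile",
    "cluster_pc1",
    "combine_weighted",
    "property_reference",
    "loess_tune",
    "tune_profile",
]


@dataclass
class TunedProfile:
    chrom_order: list[str]
    M: np.ndarray          # mean CT distance over the selected cluster
    P: np.ndarray          # PC1 of the chromosome correlation matrix, [0,1]
    W1: float
    W2: float
    C: np.ndarray          # combined consensus
    R: np.ndarray          # property reference
    tuned: np.ndarray      # loess-smoothed output


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def cluster_pc1(Dprime: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PC1 of the chromosome-chromosome correlation matrix of D'.

    Returns the chromosome projections on PC1 (oriented so the
    correlation with the cluster mean profile M is non-negative, then
    min-max normalized to [0, 1] so it is commensurate with M) and the
    variance fractions of all PCs.
    """
    Dprime = np.asarray(Dprime, dtype=float)
    if Dprime.shape[0] < 5:
        raise ValueError("selected cluster must contain at least 5 models")
    sd = Dprime.std(axis=0)
    if (sd == 0).any():
        warnings.warn("constant chromosome column(s); correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(Dprime.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    scores, var_frac = _pca_rows(corr)
    P = scores[:, 0]
    M = Dprime.mean(axis=0)
    if np.std(P) > 0 and np.std(M) > 0 and np.corrcoef(P, M)[0, 1] < 0:
        P = -P
    return _minmax(P), var_frac


def combine_weighted(
    M: np.ndarray, P: np.ndarray, var_fractions: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Weighted average of M and P by PC1/PC2 variance fractions."""
    v1, v2 = float(var_fractions[0]), float(var_fractions[1])
    if v1 + v2 == 0:
        raise ValueError("PC1 and PC2 explain zero variance")
    W1 = v1 / (v1 + v2)
    W2 = v2 / (v1 + v2)
    return W1 * np.asarray(M, float) + W2 * np.asarray(P, float), W1, W2


def property_reference(
    props: ChromProperties,
    inferred_type: str,
    W1: float,
    W2: float,
    chrom_order: list[str],
) -> np.ndarray:
    """Property reference vector from normalized gene density and length.

    Gene density enters as exp(1 - GD) of its min-max-normalized values
    (gene-poor chromosomes get large values, i.e. are referenced toward
    the periphery); length enters min-max normalized directly. The
    higher weight W1 multiplies the component matching the inferred
    organization type.
    """
    props = props.reindex(chrom_order)
    gd = _minmax(props.gene_density)
    ln = _minmax(props.length_bp)
    if inferred_type == "gene_density":
        return W1 * np.exp(1.0 - gd) + W2 * ln
    if inferred_type == "length":
        return W2 * np.exp(1.0 - gd) + W1 * ln
    raise ValueError("inferred_type must be 'gene_density' or 'length'")


def loess_tune(
    C: np.ndarray, R: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Loess regression of C on R, evaluated at the observed R.

    Local weighted polynomial fit with tricube weights over the span
    fraction of nearest neighbors. Fitted values are returned in the
    input (chromosome) order. Duplicate R values share a neighborhood
    and pose no problem; a span too small to support the polynomial
    degree raises.
    """
    C = np.asarray(C, dtype=float)
    R = np.asarray(R, dtype=float)
    n = len(R)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    q = max(int(np.ceil(span * n)), 2)
    if q < degree + 2:
        raise ValueError(
            f"span {span} gives {q} local points; need at least {degree + 2} "
            f"for degree {degree}"
        )
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(R - R[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:  # all neighbors at the same R
            fitted[i] = C[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        if w.sum() == 0:
            w[:] = 1.0
        # weighted polynomial fit, centered for conditioning
        x = R[idx] - R[i]
        V = np.vander(x, degree + 1, increasing=True)
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * W[:, None], C[idx] * W, rcond=None)
        fitted[i] = coef[0]
    return fitted


def tune_profile(
    Dprime: np.ndarray,
    props: ChromProperties,
    inferred_type: str,
    chrom_order: list[str],
    span: float = 0.75,
    degree: int = 2,
) -> TunedProfile:
    """Full tuning stage: M, P, weights, C, R, loess -> TunedProfile."""
    Dprime = np.asarray(Dprime, dtype=float)
    M = Dprime.mean(axis=0)
    P, var_frac = cluster_pc1(Dprime)
    C, W1, W2 = combine_weighted(M, P, var_frac)
    R = property_reference(props, inferred_type, W1, W2, chrom_order)
    tuned = loess_tune(C, R, span=span, degree=degree)
    return TunedProfile(list(chrom_order), M, P, W1, W2, C, R, tuned)
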