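"""Random-ligation Hi-C simulation by matched matrix shuffling.

A random-ligation control matrix is produced from a real raw contact
matrix by permuting its upper-triangle entries (diagonal included) over
upper-triangle positions and mirroring the result, so the control has
exactly the same total read count and dynamic range of values but no
chromosome-specific structure. The shuffled matrix is then ICE-balanced,
mirroring the pre-processing of the real matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic_io import HicMatrix, ice_normalize

__all__ = ["ShuffleSpec", "simulate_random_ligation", "shuffle_matrix"]


@dataclass(frozen=True)
class ShuffleSpec:
    n_shuffles: int = 5
    seed: int = 0
    mode: str = "values"  # "values" | "labels"

    def __post_init__(self):
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.mode not in ("values", "labels"):
            raise ValueError("mode must be 'values' or 'labels'")


def shuffle_matrix(values: np.ndarray, rng: np.random.Generator,
                   n_shuffles: int = 5, mode: str = "values") -> np.ndarray:
    """Shuffle a symmetric matrix n_shuffles times, preserving symmetry.

    ``values`` mode permutes upper-triangle entries (with diagonal) over
    upper-triangle positions; ``labels`` mode applies a random
    simultaneous row/column permutation.
    """
    m = values.shape[0]
    out = values.copy()
    for _ in range(n_shuffles):
        if mode == "values":
            iu = np.triu_indices(m)
            flat = out[iu]
            rng.shuffle(flat)
            out = np.zeros_like(out)
            out[iu] = flat
            out = out + np.triu(out, 1).T
        else:
            perm = rng.permutation(m)
            out = out[np.ix_(perm, perm)]
    return out


def simulate_random_ligation(H_raw: HicMatrix, spec: ShuffleSpec | None = None,
                             normalize: bool = True) -> HicMatrix:
    """Matched random-ligation control for a raw (unnormalized) matrix.

    Raises if the input is already balanced: the shuffle must act on raw
    read counts so that real and control matrices share a total read
    count before their separate ICE passes.
    """
    if H_raw.normalized:
        raise ValueError("random ligation must be simulated from a raw matrix")
    spec = spec or ShuffleSpec()
    rng = np.random.default_rng(spec.seed)
    shuffled = shuffle_matrix(H_raw.values, rng, spec.n_shuffles, spec.mode)
    out = HicMatrix(shuffled, H_raw.bins, normalized=False)
    if normalize:
        # a shuffle can strand a bin with zero coverage; such bins would
        # break balancing, so guard (vanishingly rare at realistic depth)
        if (out.values.sum(axis=1) == 0).any():
            raise ValueError("shuffle produced a zero-coverage bin; re-seed")
        out = ice_normalize(out)
    return out
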