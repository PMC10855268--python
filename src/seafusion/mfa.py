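"""Multiple Factor Analysis over omics blocks.

MFA is a block-weighted PCA: each variable block is rescaled by the
inverse of the first eigenvalue of its own PCA, so that every block's
first-axis inertia equals 1 and no block dominates the global solution by
scale alone. A single categorical "classes" variable can participate as
an additional block through its scaled indicator encoding (the standard
treatment of qualitative variables in MFA); by default it is active in
the solution, with a switch for supplementary-only projection.

Outputs are the global dimensions: eigenvalues, sample scores, and block
and variable contributions (percent of each dimension's inertia).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CLASS_BLOCK = "classes"


class MFAError(ValueError):
    pass


def pca(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based PCA of a column-centered matrix.

    Returns ``(eigenvalues, scores, loadings)`` with eigenvalues
    ``s**2 / (n - 1)`` in non-increasing order; ``scores @ loadings.T``
    reconstructs the input.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise MFAError("PCA needs at least 2 samples")
    x = x - x.mean(axis=0)  # idempotent on centered input
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s ** 2 / (x.shape[0] - 1)
    scores = u * s
    return eigvals, scores, vt.T


def block_weight(block: pd.DataFrame | np.ndarray) -> float:
    """MFA weight of a block: the inverse of its first PCA eigenvalue.

    After multiplying the block by ``sqrt(weight)``, its first eigenvalue
    is 1. The block is expected to be autoscaled already.
    """
    x = np.asarray(block, dtype=float)
    lam1 = float(pca(x)[0][0])
    if lam1 <= 1e-12:
        raise MFAError("degenerate block: first eigenvalue is 0")
    return 1.0 / lam1


def encode_qualitative(labels: Sequence[str]) -> pd.DataFrame:
    """Indicator encoding of a categorical variable for MFA.

    Each level's indicator column is divided by the square root of the
    level proportion, then column-centered, so the encoded block behaves
    like the correspondence-analysis treatment of a qualitative variable.
    """
    labels = pd.Series(list(labels))
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise MFAError("qualitative variable needs >= 2 levels")
    n = len(labels)
    cols = {}
    for lev in levels:
        ind = (labels == lev).to_numpy(dtype=float)
        n_lev = ind.sum()
        if n_lev == 0:
            raise MFAError(f"level {lev!r} has no samples")
        col = ind / np.sqrt(n_lev / n)
        cols[f"{CLASS_BLOCK}={lev}"] = col - col.mean()
    return pd.DataFrame(cols, index=labels.index)


@dataclass
class MFAResult:
    eigenvalues: pd.Series  # per dimension
    variance_explained: pd.Series  # percent
    scores: pd.DataFrame  # samples x dimensions
    block_weights: dict[str, float]
    block_contributions: pd.DataFrame  # blocks x dimensions, percent
    variable_contributions: pd.DataFrame  # features x dimensions, percent
    loadings: pd.DataFrame  # features x dimensions (weighted space)
    block_index: pd.Series  # feature -> block

    def top_contributors(self, dim: str, k: int = 100) -> pd.DataFrame:
        """Variables sorted by descending contribution on one dimension."""
        out = self.variable_contributions[[dim]].sort_values(
            dim, ascending=False)
        return out.head(k)


def mfa_fit(blocks: Mapping[str, pd.DataFrame],
            classes: Sequence[str] | None = None,
            n_dims: int = 5,
            class_active: bool = True) -> MFAResult:
    """Fit an MFA on preprocessed (pair-centered, autoscaled) blocks.

    ``classes`` optionally adds the qualitative class variable; when
    ``class_active`` it contributes to the solution like any block,
    otherwise it is projected afterwards and reported with zero
    contribution.
    """
    if not blocks:
        raise MFAError("no blocks given")
    names = list(blocks)
    index = next(iter(blocks.values())).index
    for name, b in blocks.items():
        if not b.index.equals(index):
            raise MFAError(f"block {name!r} has mismatched samples")

    weights: dict[str, float] = {}
    weighted: list[pd.DataFrame] = []
    feat_block: list[tuple[str, str]] = []
    parts: dict[str, pd.DataFrame] = {n: blocks[n] for n in names}
    qual = None
    if classes is not None:
        qual = encode_qualitative(list(classes))
        qual.index = index
        if class_active:
            parts[CLASS_BLOCK] = qual
    for name, data in parts.items():
        w = block_weight(data)
        weights[name] = w
        weighted.append(data * np.sqrt(w))
        feat_block.extend((str(c), name) for c in data.columns)

    xw = pd.concat(weighted, axis=1)
    eigvals, scores, loadings = pca(xw.to_numpy())
    rank = int((eigvals > 1e-12 * max(eigvals[0], 1.0)).sum())
    if n_dims > rank:
        warnings.warn(f"n_dims={n_dims} exceeds rank {rank}; truncating",
                      stacklevel=2)
        n_dims = rank
    eigvals, scores, loadings = (eigvals[:n_dims], scores[:, :n_dims],
                                 loadings[:, :n_dims])
    # reproducible sign: the largest-magnitude loading of each dimension
    # is positive
    for s in range(n_dims):
        j = int(np.argmax(np.abs(loadings[:, s])))
        if loadings[j, s] < 0:
            loadings[:, s] *= -1
            scores[:, s] *= -1

    dims = [f"Dim{s + 1}" for s in range(n_dims)]
    block_of = pd.Series(dict(feat_block), name="block").reindex(xw.columns)
    var_ctr = pd.DataFrame(100.0 * loadings ** 2, index=xw.columns,
                           columns=dims)
    blk_ctr = var_ctr.groupby(block_of).sum().reindex(
        [n for n in parts], fill_value=0.0)
    ve = pd.Series(100.0 * eigvals / pca(xw.to_numpy())[0].sum(), index=dims)
    return MFAResult(
        eigenvalues=pd.Series(eigvals, index=dims),
        variance_explained=ve,
        scores=pd.DataFrame(scores, index=index, columns=dims),
        block_weights=weights,
        block_contributions=blk_ctr,
        variable_contributions=var_ctr,
        loadings=pd.DataFrame(loadings, index=xw.columns, columns=dims),
        block_index=block_of,
    )
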