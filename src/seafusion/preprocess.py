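"""Paired day-centering, autoscaling, and low-level fusion.

The measurements are coupled comparisons: one control and one treated fish
per day. Subtracting each day-pair's mean from both of its samples removes
the additive day batch effect exactly, and is fold-safe for paired
cross-validation (it uses no class labels beyond the pairing itself).
Autoscaling (column mean 0, unit variance with the n-1 denominator) then
puts all features of all platforms on a common scale; low-level fusion is
a column-wise concatenation of the blocks with provenance bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import day_pairs

log = logging.getLogger(__name__)

#: deterministic fusion order; unknown blocks follow alphabetically
BLOCK_ORDER = ("lipidomics", "metabolomics", "proteomics")


class PreprocessError(ValueError):
    pass


class PairingError(PreprocessError):
    pass


@dataclass
class OmicsBlock:
    """One platform's samples x features intensity matrix."""

    name: str
    data: pd.DataFrame  # index = sample_id, columns = feature ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise PreprocessError(f"block {self.name!r}: duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise PreprocessError(f"block {self.name!r}: duplicate feature ids")
        if self.data.isna().to_numpy().any():
            bad = self.data.columns[self.data.isna().any(axis=0)][:5]
            raise PreprocessError(
                f"block {self.name!r} contains missing values "
                f"(e.g. features {list(bad)}); missing intensities are not "
                "supported")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ScalingRecord:
    """Per-feature mean/sd used for autoscaling; supports exact inversion."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)

    def inverse(self, scaled: pd.DataFrame) -> pd.DataFrame:
        """Back-transform autoscaled data (dropped columns stay absent)."""
        return scaled * self.sd[scaled.columns] + self.mean[scaled.columns]


@dataclass
class FusedDataset:
    """Low-level fused matrix with feature-to-block provenance."""

    data: pd.DataFrame
    block_index: pd.Series  # feature id -> block name
    pairing: dict[int, tuple[str, str]]
    scaling: ScalingRecord | None = None

    def block_of(self, feature: str) -> str:
        return str(self.block_index[feature])


def pair_center(block: OmicsBlock, design: pd.DataFrame) -> OmicsBlock:
    """Subtract each day-pair's mean from both of its samples.

    After centering, the two rows of every day-pair sum to the zero
    vector, so any additive per-day effect shared by the pair is removed.
    """
    sub = design[design["sample_id"].isin(block.data.index)]
    if set(sub["sample_id"]) != set(block.data.index):
        missing = set(block.data.index) - set(sub["sample_id"])
        raise PairingError(f"samples absent from design: {sorted(missing)[:5]}")
    pairs = day_pairs(sub)
    out = block.data.copy()
    for day, (ctrl, trt) in pairs.items():
        pair_mean = (out.loc[ctrl] + out.loc[trt]) / 2.0
        out.loc[ctrl] = out.loc[ctrl] - pair_mean
        out.loc[trt] = out.loc[trt] - pair_mean
    return OmicsBlock(name=block.name, data=out)


def autoscale(data: pd.DataFrame,
              tol: float = 1e-12) -> tuple[pd.DataFrame, ScalingRecord]:
    """Center each column to mean 0 and scale to unit sample variance.

    Constant columns (sd below ``tol``) carry no discriminant information
    and would break unit-variance scaling; they are dropped and logged.
    """
    if len(data) < 2:
        raise PreprocessError("autoscaling needs at least 2 samples")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    dropped = list(data.columns[sd.to_numpy() <= tol])
    if dropped:
        log.warning("autoscale: dropping %d constant feature(s), e.g. %s",
                    len(dropped), dropped[:5])
    keep = [c for c in data.columns if c not in set(dropped)]
    if not keep:
        raise PreprocessError("all features are constant; nothing to scale")
    scaled = (data[keep] - mean[keep]) / sd[keep]
    return scaled, ScalingRecord(mean=mean, sd=sd, dropped=dropped)


def fuse(blocks: Sequence[OmicsBlock] | Mapping[str, OmicsBlock],
         design: pd.DataFrame) -> FusedDataset:
    """Concatenate blocks column-wise in the deterministic fusion order.

    All blocks must cover the same sample set; rows are aligned to the
    first block's order. Values are preserved bit-exactly.
    """
    if isinstance(blocks, Mapping):
        blocks = list(blocks.values())
    if not blocks:
        raise PreprocessError("no blocks to fuse")
    order = {name: i for i, name in enumerate(BLOCK_ORDER)}
    blocks = sorted(blocks, key=lambda b: (order.get(b.name, len(order)),
                                           b.name))
    ref = blocks[0]
    ref_ids = set(ref.data.index)
    for b in blocks[1:]:
        ids = set(b.data.index)
        if ids != ref_ids:
            diff = sorted(ids.symmetric_difference(ref_ids))
            raise PreprocessError(
                f"blocks {ref.name!r} and {b.name!r} disagree on samples: "
                f"{diff[:10]}")
    # canonical row order comes from the design, so shuffled block input
    # fuses identically
    row_order = [s for s in design["sample_id"] if s in ref_ids]
    if len(row_order) != len(ref_ids):
        missing = sorted(ref_ids - set(row_order))
        raise PreprocessError(f"samples absent from design: {missing[:10]}")
    aligned = [b.data.reindex(row_order) for b in blocks]
    seen: set[str] = set()
    for b in blocks:
        clash = seen.intersection(b.data.columns)
        if clash:
            raise PreprocessError(
                f"feature ids shared across blocks: {sorted(clash)[:5]}")
        seen.update(b.data.columns)
    fused = pd.concat(aligned, axis=1)
    block_index = pd.Series(
        np.concatenate([[b.name] * b.data.shape[1] for b in blocks]),
        index=fused.columns, name="block")
    sub = design[design["sample_id"].isin(fused.index)]
    pairing = day_pairs(sub)
    return FusedDataset(data=fused, block_index=block_index, pairing=pairing)


def preprocess_blocks(blocks: Mapping[str, OmicsBlock],
                      design: pd.DataFrame,
                      scale: bool = True,
                      ) -> tuple[dict[str, pd.DataFrame],
                                 dict[str, ScalingRecord]]:
    """Pair-center each block, then (optionally) autoscale it.

    Convenience for the MFA path, which needs per-block autoscaled
    matrices over the full analysis set.
    """
    out: dict[str, pd.DataFrame] = {}
    records: dict[str, ScalingRecord] = {}
    for name, block in blocks.items():
        centered = pair_center(block, design)
        if scale:
            scaled, rec = autoscale(centered.data)
            out[name] = scaled
            records[name] = rec
        else:
            out[name] = centered.data
    return out, records
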