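"""Jaccard trait dissimilarity at vessel and site level.

Trait records are aggregated upward by presence-OR (a site shows a trait if
any of its vessels does) and compared with the Jaccard dissimilarity,
``d(i, j) = 1 − |A∩B| / |A∪B|`` on the presence sets, per trait block
(decoration, morphology, technology, use) or combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import DistanceMatrix, TraitMatrix, VALID_BLOCKS, logger


@dataclass(frozen=True)
class JaccardOptions:
    """Options for Jaccard matrix construction.

    ``drop_empty_rows`` removes rows with no present trait in the selected
    blocks; otherwise a pair of all-empty rows gets distance 0 (they are
    indistinguishable) — a convention, logged when it fires.
    """

    blocks: tuple[str, ...] = VALID_BLOCKS
    drop_empty_rows: bool = False

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block must be selected")


def aggregate(
    matrix: TraitMatrix,
    level: str,
    row_to_group: Mapping[str, str] | None = None,
) -> TraitMatrix:
    """Aggregate trait rows to a coarser level by presence-OR.

    ``row_to_group`` maps each row id to its vessel/site; when omitted, row
    ids of the form ``site:vessel`` (or ``site:vessel:sample``) are split on
    ``:``, keeping the first component for site level and the first two for
    vessel level.
    """
    if level == matrix.level:
        return matrix
    if level not in ("vessel", "site"):
        raise ValueError(f"unknown aggregation level {level!r}")
    if matrix.level == "site" and level == "vessel":
        raise ValueError("cannot disaggregate site-level traits to vessels")

    def default_group(rid: str) -> str:
        parts = rid.split(":")
        return parts[0] if level == "site" else ":".join(parts[:2])

    groups = []
    for rid in matrix.row_ids:
        if row_to_group is not None:
            if rid not in row_to_group:
                raise KeyError(f"row {rid!r} has no {level} mapping")
            groups.append(str(row_to_group[rid]))
        else:
            groups.append(default_group(rid))
    order = list(dict.fromkeys(groups))  # first-appearance order
    idx = {g: i for i, g in enumerate(order)}
    out = np.zeros((len(order), matrix.shape[1]), dtype=np.int8)
    for g, row in zip(groups, matrix.values):
        out[idx[g]] |= row
    return TraitMatrix(order, matrix.trait_ids, matrix.blocks, out, level=level)


def jaccard_matrix(
    matrix: TraitMatrix, opts: JaccardOptions = JaccardOptions()
) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity over the selected trait blocks."""
    sub = matrix.select_blocks(opts.blocks)
    X = sub.values.astype(np.int64)
    row_ids = sub.row_ids
    sizes = X.sum(axis=1)
    if opts.drop_empty_rows:
        keep = sizes > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("jaccard: dropping %d all-empty rows", n_drop)
        X, sizes = X[keep], sizes[keep]
        row_ids = [r for r, k in zip(row_ids, keep) if k]
    if len(row_ids) < 2:
        raise ValueError("need at least 2 rows for a distance matrix")
    inter = X @ X.T
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    both_empty = union == 0
    if both_empty.sum() > len(row_ids):  # off-diagonal occurrences
        logger.info("jaccard: %d empty-vs-empty pairs set to distance 0",
                    int((both_empty.sum() - len(row_ids)) // 2))
    d[both_empty] = 0.0
    np.fill_diagonal(d, 0.0)
    name = "jaccard[" + "+".join(b for b in VALID_BLOCKS if b in opts.blocks) + "]"
    return DistanceMatrix(row_ids, d, name)


def block_summary(matrices: Mapping[str, DistanceMatrix]) -> pd.DataFrame:
    """Mean, s.d. and pair count of off-diagonal distances per trait block."""
    labels = None
    rows = []
    for block, dm in matrices.items():
        if labels is None:
            labels = dm.labels
        elif dm.labels != labels:
            raise ValueError(f"block {block!r}: label mismatch across matrices")
        v = dm.condensed()
        rows.append({"block": block, "mean": float(v.mean()),
                     "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                     "n_pairs": int(v.size)})
    return pd.DataFrame(rows)


def merge_trait_matrices(a: TraitMatrix, b: TraitMatrix) -> TraitMatrix:
    """Column-concatenate two trait matrices on the union of rows (absent = 0).

    Used to join ceramic production traits with biomolecular use traits before
    the combined Jaccard analysis.
    """
    if a.level != b.level:
        raise ValueError("matrices at different aggregation levels")
    rows = list(dict.fromkeys(a.row_ids + b.row_ids))
    out = np.zeros((len(rows), a.shape[1] + b.shape[1]), dtype=np.int8)
    pos = {r: i for i, r in enumerate(rows)}
    for rid, row in zip(a.row_ids, a.values):
        out[pos[rid], : a.shape[1]] = row
    for rid, row in zip(b.row_ids, b.values):
        out[pos[rid], a.shape[1]:] = row
    return TraitMatrix(rows, a.trait_ids + b.trait_ids, a.blocks + b.blocks, out, level=a.level)
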