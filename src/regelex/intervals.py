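"""Genomic interval utilities.

All element/exon intervals are BED-style: 0-based, half-open ``[start, end)``.
Variant positions follow the VCF convention and are 1-based.  The conversion
between the two systems lives here and nowhere else: a 1-based position ``p``
intersects ``[start, end)`` iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "validate_intervals",
    "variant_pos_to_bed",
    "intersect_positions",
    "intersect_positions_brute",
]


def validate_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Check a BED-like frame (columns chrom, start, end) for malformed rows.

    Raises ``ValueError`` on any interval with ``end <= start``.
    """
    required = {"chrom", "start", "end"}
    missing = required - set(intervals.columns)
    if missing:
        raise ValueError(f"interval table missing columns: {sorted(missing)}")
    bad = intervals["end"] <= intervals["start"]
    if bad.any():
        rows = intervals.index[bad].tolist()[:5]
        raise ValueError(f"malformed intervals (end <= start) at rows {rows}")
    return intervals


def variant_pos_to_bed(pos: np.ndarray) -> np.ndarray:
    """Convert 1-based variant positions to 0-based BED offsets."""
    return np.asarray(pos, dtype=np.int64) - 1


def intersect_positions(
    variants: pd.DataFrame,
    elements: pd.DataFrame,
    *,
    element_id_col: str = "element_id",
) -> dict:
    """Map each variant to the element intervals containing it.

    Parameters
    ----------
    variants
        Frame with columns ``variant_id``, ``chrom``, ``pos`` (1-based).
    elements
        BED-like frame with ``chrom``, ``start``, ``end`` (0-based half-open)
        and an id column.

    Returns
    -------
    dict mapping variant_id -> sorted list of overlapping element ids.

    Notes
    -----
    Uses a sorted-endpoint sweep per chromosome; equivalent to the
    brute-force all-pairs scan (see :func:`intersect_positions_brute`).
    """
    validate_intervals(elements)
    out: dict = {vid: [] for vid in variants["variant_id"]}
    for chrom, vchunk in variants.groupby("chrom", sort=False):
        echunk = elements[elements["chrom"] == chrom]
        if echunk.empty:
            continue
        starts = echunk["start"].to_numpy(dtype=np.int64)
        ends = echunk["end"].to_numpy(dtype=np.int64)
        ids = echunk[element_id_col].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends, ids = starts[order], ends[order], ids[order]
        offsets = variant_pos_to_bed(vchunk["pos"].to_numpy())
        # candidate window: all intervals with start <= offset; filter by end
        hi = np.searchsorted(starts, offsets, side="right")
        for vid, off, h in zip(vchunk["variant_id"], offsets, hi):
            hit = ids[:h][ends[:h] > off]
            out[vid] = sorted(hit.tolist())
    return out


def intersect_positions_brute(variants: pd.DataFrame, elements: pd.DataFrame, *, element_id_col: str = "element_id") -> dict:
    """All-pairs reference implementation of :func:`intersect_positions`:
    every (variant, element) pair is tested directly, with no sorting or
    search structure."""
    validate_intervals(elements)
    off = variant_pos_to_bed(variants["pos"].to_numpy())[:, None]
    vchrom = variants["chrom"].to_numpy()[:, None]
    starts = elements["start"].to_numpy(dtype=np.int64)[None, :]
    ends = elements["end"].to_numpy(dtype=np.int64)[None, :]
    echrom = elements["chrom"].to_numpy()[None, :]
    ids = elements[element_id_col].to_numpy()
    hit = (vchrom == echrom) & (starts <= off) & (off < ends)
    return {
        vid: sorted(ids[hit[i]].tolist())
        for i, vid in enumerate(variants["variant_id"])
    }
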