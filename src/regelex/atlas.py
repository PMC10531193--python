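"""Regulatory-element atlas operations.

Elements are genomic intervals (BED 0-based half-open) carrying a
per-biosample activity Z-score.  An element is called *active* in an
analysis if its Z exceeds 1.64 (one-sided 5% of a standard normal) in at
least a minimum number of datasets — the inequality is strict.  On top of
the activity calls, this module provides variant-to-element intersection,
the set algebra over T-cell-receptor (TCR) stimulation responses across
CD4+/CD8+ lineages, and per-locus TCR-response classification.
"""

from __future__ import annotations

import pandas as pd

from .intervals import intersect_positions

__all__ = [
    "threshold_active_elements",
    "select_top_k_elements",
    "intersect_variants_elements",
    "tcr_response_sets",
    "classify_locus_tcr",
]

DEFAULT_Z_CUT = 1.64
DEFAULT_MIN_DATASETS = 3
LOCUS_TCR_CLASSES = (
    "up_only",
    "down_only",
    "both",
    "tcell_nonresponsive",
    "no_tcell_element",
)


def threshold_active_elements(
    zscores: pd.DataFrame,
    z_cut: float = DEFAULT_Z_CUT,
    min_datasets: int = DEFAULT_MIN_DATASETS,
) -> set[str]:
    """Element ids with Z strictly above ``z_cut`` in >= ``min_datasets``
    columns."""
    if zscores.size == 0:
        raise ValueError("empty Z-score matrix")
    if min_datasets < 1:
        raise ValueError("min_datasets must be >= 1")
    n_exceed = (zscores.to_numpy() > z_cut).sum(axis=1)
    return set(zscores.index[n_exceed >= min_datasets])


def select_top_k_elements(signal: pd.Series, k: int) -> list[str]:
    """The ``k`` elements with the largest signal; ties at the cut broken by
    element id ascending; all elements if ``k >= n``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = signal.to_frame("signal").reset_index(names="element_id")
    ordered = ordered.sort_values(
        ["signal", "element_id"], ascending=[False, True], kind="stable"
    )
    return ordered["element_id"].head(k).tolist()


def intersect_variants_elements(
    variants: pd.DataFrame, elements: pd.DataFrame
) -> dict:
    """Per-variant sorted list of containing element ids (1-based variant
    positions against 0-based half-open intervals)."""
    return intersect_positions(variants, elements)


def tcr_response_sets(
    per_lineage_diff: dict[str, pd.DataFrame],
    lineage_groups: dict[str, str],
    q_cut: float = 0.05,
) -> dict[str, set[str]]:
    """Set algebra over per-lineage TCR-stimulation differential calls.

    Parameters
    ----------
    per_lineage_diff
        Mapping lineage -> frame indexed by element id with columns
        ``log2fc`` and ``q``.  An element is *up* in a lineage if
        ``q < q_cut`` and ``log2fc > 0``; *down* if ``q < q_cut`` and
        ``log2fc < 0``.
    lineage_groups
        Mapping lineage -> ``"CD4"`` or ``"CD8"``.

    Returns
    -------
    dict with keys ``up_union``, ``down_union`` (responsive in any lineage),
    ``cd4_union``, ``cd8_union``, ``shared_cd4_cd8``, ``cd4_only``,
    ``cd8_only`` (unions of responsive-either-direction elements per group),
    and ``discordant`` (up in >=1 lineage and down in >=1 lineage).
    """
    for lin in per_lineage_diff:
        if lineage_groups.get(lin) not in ("CD4", "CD8"):
            raise ValueError(f"lineage {lin!r} has unknown group {lineage_groups.get(lin)!r}")
    up_by_group: dict[str, set] = {"CD4": set(), "CD8": set()}
    down_by_group: dict[str, set] = {"CD4": set(), "CD8": set()}
    for lin, df in per_lineage_diff.items():
        g = lineage_groups[lin]
        sig = df["q"] < q_cut
        up_by_group[g] |= set(df.index[sig & (df["log2fc"] > 0)])
        down_by_group[g] |= set(df.index[sig & (df["log2fc"] < 0)])
    up_union = up_by_group["CD4"] | up_by_group["CD8"]
    down_union = down_by_group["CD4"] | down_by_group["CD8"]
    cd4 = up_by_group["CD4"] | down_by_group["CD4"]
    cd8 = up_by_group["CD8"] | down_by_group["CD8"]
    return {
        "up_union": up_union,
        "down_union": down_union,
        "cd4_union": cd4,
        "cd8_union": cd8,
        "shared_cd4_cd8": cd4 & cd8,
        "cd4_only": cd4 - cd8,
        "cd8_only": cd8 - cd4,
        "discordant": up_union & down_union,
    }


def classify_locus_tcr(
    locus_variants: pd.DataFrame,
    elements: pd.DataFrame,
    tcell_element_ids: set[str],
    up_ids: set[str],
    down_ids: set[str],
) -> str:
    """Classify a locus by the TCR responsiveness of the T-cell elements its
    credible variants hit.

    Classes: ``both`` (hits up- and down-regulated elements), ``up_only``,
    ``down_only``, ``tcell_nonresponsive`` (hits T-cell elements, none
    responsive), ``no_tcell_element``.
    """
    if not up_ids <= tcell_element_ids or not down_ids <= tcell_element_ids:
        raise ValueError("responsive element ids must be a subset of T-cell element ids")
    hits = intersect_positions(locus_variants, elements)
    hit_ids = set().union(*hits.values()) if hits else set()
    tcell_hits = hit_ids & tcell_element_ids
    if not tcell_hits:
        return "no_tcell_element"
    has_up = bool(tcell_hits & up_ids)
    has_down = bool(tcell_hits & down_ids)
    if has_up and has_down:
        return "both"
    if has_up:
        return "up_only"
    if has_down:
        return "down_only"
    return "tcell_nonresponsive"
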