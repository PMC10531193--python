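"""Permutation test for enrichment of risk SNPs within an element set.

The observed statistic is the number of risk SNPs falling inside the element
intervals.  The null is built by repeatedly drawing equally many SNPs
without replacement from a background universe (optionally within matched
minor-allele-frequency bins) and recounting.  The empirical p uses the
standard add-one correction, ``p = (1 + #{perm >= obs}) / (1 + n_perm)``, so
it can never be zero.  For the unmatched scheme the null is exactly
hypergeometric, and :func:`exact_overlap_p` provides the closed-form tail as
an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import intersect_positions

__all__ = ["OverlapTest", "permutation_overlap_test", "exact_overlap_p"]


@dataclass
class OverlapTest:
    observed: int
    n_perm: int
    perm_counts: np.ndarray
    p_value: float
    scheme: str
    seed: int

    def histogram(self) -> pd.Series:
        vals, counts = np.unique(self.perm_counts, return_counts=True)
        return pd.Series(counts, index=vals, name="n_permutations")


def _overlap_flags(universe: pd.DataFrame, elements: pd.DataFrame) -> np.ndarray:
    hits = intersect_positions(universe, elements)
    return np.array([bool(hits[v]) for v in universe["variant_id"]])


def permutation_overlap_test(
    risk_snps: set[str],
    universe: pd.DataFrame,
    elements: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    maf_bins: pd.Series | None = None,
) -> OverlapTest:
    """Permutation enrichment of ``risk_snps`` within ``elements``.

    Parameters
    ----------
    risk_snps
        Variant ids; must be a subset of the universe.
    universe
        Frame with ``variant_id``, ``chrom``, ``pos`` (1-based) of all
        eligible SNPs.
    elements
        BED-like interval frame.
    maf_bins
        Optional per-variant bin labels (indexed by variant id); when given,
        each permutation draws the same number of SNPs per bin as the risk
        set contains.
    """
    if seed is None:
        raise ValueError("seed is required")
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    ids = universe["variant_id"].to_numpy()
    if not set(risk_snps) <= set(ids):
        raise ValueError("risk SNPs must be a subset of the universe")
    if len(risk_snps) > len(ids):
        raise ValueError("more risk SNPs than universe SNPs")
    rng = np.random.default_rng(int(seed))

    in_element = _overlap_flags(universe, elements)
    flag = dict(zip(ids, in_element))
    observed = sum(flag[v] for v in risk_snps)
    n_draw = len(risk_snps)

    if maf_bins is None:
        scheme = "unmatched_snp_permutation"
        perm = np.array(
            [in_element[rng.choice(len(ids), size=n_draw, replace=False)].sum() for _ in range(n_perm)]
        )
    else:
        scheme = "maf_matched_snp_permutation"
        bins = maf_bins.reindex(ids)
        if bins.isna().any():
            missing = bins.index[bins.isna()].tolist()[:5]
            raise ValueError(f"universe SNPs missing a MAF bin: {missing}")
        need = pd.Series([bins.loc[v] for v in risk_snps]).value_counts()
        pools = {b: np.flatnonzero((bins == b).to_numpy()) for b in need.index}
        for b, cnt in need.items():
            if len(pools[b]) < cnt:
                raise ValueError(f"MAF bin {b!r} smaller than its required draw ({cnt})")
        perm = np.empty(n_perm, dtype=int)
        for t in range(n_perm):
            tot = 0
            for b, cnt in need.items():
                tot += in_element[rng.choice(pools[b], size=cnt, replace=False)].sum()
            perm[t] = tot
    p = (1 + int((perm >= observed).sum())) / (1 + n_perm)
    return OverlapTest(int(observed), int(n_perm), perm, float(p), scheme, int(seed))


def exact_overlap_p(
    universe_size: int, n_overlapping: int, n_draws: int, observed: int
) -> float:
    """Exact hypergeometric upper tail P(X >= observed).

    X counts element-overlapping SNPs among ``n_draws`` drawn without
    replacement from a universe with ``n_overlapping`` overlapping SNPs.
    """
    if not (0 <= n_overlapping <= universe_size and 0 <= n_draws <= universe_size):
        raise ValueError("inconsistent counts")
    if observed > min(n_draws, n_overlapping):
        raise ValueError("observed exceeds the possible maximum")
    if observed <= 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, universe_size, n_overlapping, n_draws))
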