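"""Differential chromatin accessibility on element count matrices.

The workflow mirrors a standard two-condition ATAC-seq comparison:

1. **Trended (loess) normalization** — for each sample, the log-ratio
   ``M = log2(CPM_sample / geometric-mean CPM)`` is regressed on the average
   abundance ``A`` with a loess smoother; the fitted trend becomes a
   per-element, per-sample log2 offset.  This removes both global
   library-composition shifts and abundance-dependent efficiency biases.
2. **Negative-binomial likelihood-ratio test** — per element, group means
   are fitted by maximum likelihood on the NB2 model (``var = mu + alpha
   mu^2``) with the normalization offsets held fixed, the dispersion
   ``alpha`` estimated per element and shrunk toward a global
   maximum-likelihood value (empirical-Bayes style), and the group effect
   tested by a 1-df likelihood-ratio chi-square.  This is a deliberate
   simplification of quasi-likelihood frameworks such as csaw/edgeR: same
   analysis design, plainer machinery.

Also provided: a two-sample Kolmogorov-Smirnov shift test for comparing
log2FC distributions, Fisher-exact motif enrichment with BH correction, and
a rule-based chromatin-state transition caller (active / poised / inactive
from histone-mark Z-scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "loess_normalize",
    "NegativeBinomialDifferentialTest",
    "test_differential",
    "ks_shift_test",
    "motif_enrichment",
    "state_transitions",
]


# ---------------------------------------------------------------------------
# normalization


def loess_normalize(counts: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Per-element, per-sample log2 normalization offsets from an MA-trend
    loess fit.

    For sample ``s``: ``M_s = log2(count_s) - mean_t log2(count_t)`` is
    smoothed against the average abundance ``A = mean_t log2(count_t)``; the
    fitted value at each element is sample ``s``'s offset.  Working on raw
    log counts (not CPM) means the offsets absorb library-size differences
    as well as abundance-dependent trends, so they are the complete
    normalization term for the downstream model.  Offsets are re-centered
    across samples so each element's offsets sum to zero (only relative
    scaling is identifiable).

    A 0.5-count prior is added before taking logs so all-zero-per-sample
    elements stay finite; an entirely zero matrix raises.
    """
    X = counts.to_numpy(dtype=float)
    if X.sum() == 0:
        raise ValueError("all-zero count matrix")
    log2c = np.log2(X + 0.5)
    A = log2c.mean(axis=1)
    offsets = np.empty_like(log2c)
    for s in range(X.shape[1]):
        M = log2c[:, s] - A
        fit = lowess(M, A, frac=span, it=1, return_sorted=False)
        offsets[:, s] = fit
    offsets -= offsets.mean(axis=1, keepdims=True)
    return pd.DataFrame(offsets, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# NB fitting machinery (vectorized across elements)


def _nb_loglik(y, mu, alpha):
    """NB2 log-likelihood, elementwise; alpha broadcastable over rows."""
    size = 1.0 / alpha
    return (
        special.gammaln(y + size)
        - special.gammaln(size)
        - special.gammaln(y + 1)
        + size * np.log(size / (size + mu))
        + y * np.log(mu / (size + mu))
    )


def _fit_group_mean(y, s, alpha, n_iter=50, tol=1e-10):
    """ML estimate of m in mu_ij = m_i * s_ij for NB2 with known alpha.

    Solves the 1-D score equation sum_j (y - m s)/(1 + alpha m s) * s/(1 +
    ...) per element by damped Newton on log m; vectorized over elements
    (rows).  ``y``, ``s`` are (n_el, n_samp); ``alpha`` is (n_el,) or
    scalar.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    tot = y.sum(axis=1)
    # start at the offset-weighted mean; elements with zero totals get a floor
    m = np.maximum(tot / s.sum(axis=1), 1e-8)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), m.shape)
    eta = np.log(m)
    for _ in range(n_iter):
        mu = np.exp(eta)[:, None] * s
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        # negative derivative of score wrt eta (Fisher-style, positive)
        info = ((mu * (1.0 + alpha[:, None] * y)) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        eta = eta + step
        if np.max(np.abs(step)) < tol:
            break
    return np.exp(eta)


def _profile_dispersion(y, s, m1, m2, g1, g2, grid):
    """Per-element dispersion over a log-spaced grid, given group means.

    Uses the Cox-Reid adjusted profile likelihood (subtracting half the
    log-determinant of the per-group Fisher information for the means) to
    correct the downward bias of plain ML with estimated means.
    """
    mu = np.empty_like(y, dtype=float)
    mu[:, g1] = m1[:, None] * s[:, g1]
    mu[:, g2] = m2[:, None] * s[:, g2]
    best_ll = np.full(y.shape[0], -np.inf)
    best_a = np.full(y.shape[0], grid[0])
    total_adj_ll = np.empty(len(grid))
    for i, a in enumerate(grid):
        ll = _nb_loglik(y, mu, a).sum(axis=1)
        w = mu / (1.0 + a * mu)
        cr = 0.5 * (np.log(w[:, g1].sum(axis=1)) + np.log(w[:, g2].sum(axis=1)))
        ll = ll - cr
        total_adj_ll[i] = ll.sum()
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_a[better] = a
    alpha_global = float(grid[np.argmax(total_adj_ll)])
    return best_a, alpha_global, mu


class NegativeBinomialDifferentialTest(BaseEstimator):
    """Two-group differential test on NB counts with fixed offsets.

    scikit-learn-style estimator: construct with hyperparameters, call
    :meth:`fit` with a count matrix, sample groups and (optionally)
    normalization offsets; fitted results land in ``results_``.

    Parameters
    ----------
    shrink_df : float
        Prior degrees of freedom pulling per-element log-dispersion toward
        the global value; larger = stronger shrinkage.
    min_total : int
        Elements with total count below this are reported untested.

    Attributes
    ----------
    results_ : pd.DataFrame
        Per-element ``A`` (average log2 CPM), ``log2fc`` (group2 over
        group1, normalized), ``p``, ``q`` (BH), ``tested`` flag.
    global_dispersion_ : float
    dispersion_ : np.ndarray  (shrunk per-element alpha)
    """

    def __init__(self, shrink_df: float = 20.0, min_total: int = 1):
        self.shrink_df = shrink_df
        self.min_total = min_total

    def fit(self, counts: pd.DataFrame, groups, offsets: pd.DataFrame | None = None):
        groups = np.asarray(groups)
        levels = np.sort(pd.unique(groups))  # log2fc is second level over first
        if len(levels) != 2:
            raise ValueError("exactly two groups are required")
        g1 = groups == levels[0]
        g2 = groups == levels[1]
        if g1.sum() < 2 or g2.sum() < 2:
            raise ValueError("each group needs at least 2 samples")

        y_all = counts.to_numpy(dtype=float)
        if offsets is None:
            offsets = loess_normalize(counts)
        o = offsets.to_numpy(dtype=float)
        # offsets already absorb library size; exposure is their exponential
        s_all = 2.0**o

        tested = y_all.sum(axis=1) >= self.min_total
        y, s = y_all[tested], s_all[tested]
        n_el = y.shape[0]

        grid = np.exp(np.linspace(np.log(1e-4), np.log(5.0), 40))
        # pass 1: crude means with a moderate dispersion to profile alpha
        m1 = _fit_group_mean(y[:, g1], s[:, g1], 0.1)
        m2 = _fit_group_mean(y[:, g2], s[:, g2], 0.1)
        alpha_el, alpha_global, mu = _profile_dispersion(y, s, m1, m2, g1, g2, grid)
        # empirical-Bayes shrink on the log scale
        n_samp = y.shape[1]
        w = n_samp / (n_samp + self.shrink_df)
        alpha_shrunk = np.exp(
            w * np.log(alpha_el) + (1 - w) * np.log(alpha_global)
        )

        # pass 2: final fits and LRT with shrunk dispersion
        m1 = _fit_group_mean(y[:, g1], s[:, g1], alpha_shrunk)
        m2 = _fit_group_mean(y[:, g2], s[:, g2], alpha_shrunk)
        m0 = _fit_group_mean(y, s, alpha_shrunk)
        mu_alt = np.empty_like(y)
        mu_alt[:, g1] = m1[:, None] * s[:, g1]
        mu_alt[:, g2] = m2[:, None] * s[:, g2]
        mu_null = m0[:, None] * s
        ll_alt = _nb_loglik(y, mu_alt, alpha_shrunk[:, None]).sum(axis=1)
        ll_null = _nb_loglik(y, mu_null, alpha_shrunk[:, None]).sum(axis=1)
        lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
        p = stats.chi2.sf(lrt, df=1)
        q = multipletests(p, method="fdr_bh")[1]

        res = pd.DataFrame(index=counts.index)
        res["A"] = np.log2((y_all + 0.5) / s_all).mean(axis=1)
        res["log2fc"] = np.nan
        res["p"] = np.nan
        res["q"] = np.nan
        res["tested"] = tested
        res.loc[tested, "log2fc"] = np.log2(m2 / m1)
        res.loc[tested, "p"] = p
        res.loc[tested, "q"] = q
        self.results_ = res
        self.global_dispersion_ = alpha_global
        self.dispersion_ = alpha_shrunk
        self.groups_ = levels
        self.offsets_ = offsets
        return self


def test_differential(
    counts: pd.DataFrame,
    offsets: pd.DataFrame | None,
    groups,
    shrink_df: float = 20.0,
) -> pd.DataFrame:
    """Functional wrapper over :class:`NegativeBinomialDifferentialTest`."""
    est = NegativeBinomialDifferentialTest(shrink_df=shrink_df)
    est.fit(counts, groups, offsets=offsets)
    return est.results_


# ---------------------------------------------------------------------------
# shift test, motif enrichment, chromatin states


def ks_shift_test(query_values, background_values) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p).

    Used to ask whether a query set of stimulation log2 fold changes is
    shifted relative to a background distribution.
    """
    q = np.asarray(query_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if q.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(q, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def motif_enrichment(
    diff_elements: set,
    background_elements: set,
    motif_hits: dict,
) -> pd.DataFrame:
    """Per-motif Fisher-exact enrichment of differential vs background
    elements.

    ``motif_hits`` maps element id -> iterable of motif ids.  Odds ratio is
    the plain cross-product ratio (no Haldane correction): a zero cell gives
    OR of 0 or inf, with the exact p still defined.  Motifs absent from both
    sets get an undefined OR and are excluded from BH correction.
    Returns columns ``motif, n_diff, n_bg, odds_ratio, p, q, log2_or,
    neglog10_q`` (volcano coordinates).
    """
    diff_elements = set(diff_elements)
    background_elements = set(background_elements)
    if diff_elements & background_elements:
        raise ValueError("diff and background element sets must be disjoint")
    all_motifs = sorted({m for el in (diff_elements | background_elements) for m in motif_hits.get(el, ())})
    n_d, n_b = len(diff_elements), len(background_elements)
    rows = []
    for m in all_motifs:
        with_m_d = sum(1 for el in diff_elements if m in motif_hits.get(el, ()))
        with_m_b = sum(1 for el in background_elements if m in motif_hits.get(el, ()))
        table = [[with_m_d, n_d - with_m_d], [with_m_b, n_b - with_m_b]]
        if with_m_d + with_m_b == 0:
            rows.append({"motif": m, "n_diff": 0, "n_bg": 0, "odds_ratio": np.nan, "p": np.nan})
            continue
        num = with_m_d * (n_b - with_m_b)
        den = (n_d - with_m_d) * with_m_b
        odds = np.inf if den == 0 else num / den
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        rows.append({"motif": m, "n_diff": with_m_d, "n_bg": with_m_b, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    defined = out["p"].notna()
    if defined.any():
        out.loc[defined, "q"] = multipletests(out.loc[defined, "p"], method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        out["log2_or"] = np.log2(out["odds_ratio"])
        out["neglog10_q"] = -np.log10(out["q"])
    return out


CHROMATIN_STATES = ("active", "poised", "inactive")


def _call_states(marks: pd.DataFrame, active_mark: str, poised_mark: str, z_cut: float) -> pd.Series:
    for col in (active_mark, poised_mark):
        if col not in marks.columns:
            raise ValueError(f"missing mark column {col!r}")
    state = np.where(
        marks[active_mark] > z_cut,
        "active",
        np.where(marks[poised_mark] > z_cut, "poised", "inactive"),
    )
    return pd.Series(state, index=marks.index, name="state")


def state_transitions(
    pre_marks: pd.DataFrame,
    post_marks: pd.DataFrame,
    active_mark: str = "H3K27ac",
    poised_mark: str = "H3K4me1",
    z_cut: float = 1.64,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enhancer chromatin-state calls before/after stimulation and the
    transition count table.

    State rule per element: ``active`` if the active-enhancer mark
    (H3K27ac) exceeds ``z_cut``; else ``poised`` if the priming mark
    (H3K4me1) exceeds it; else ``inactive``.  The transition table's row
    sums equal the pre-stimulation state counts.
    """
    pre = _call_states(pre_marks, active_mark, poised_mark, z_cut)
    post = _call_states(post_marks.loc[pre_marks.index], active_mark, poised_mark, z_cut)
    per_element = pd.DataFrame({"state_pre": pre, "state_post": post})
    table = pd.crosstab(pre, post).reindex(
        index=CHROMATIN_STATES, columns=CHROMATIN_STATES, fill_value=0
    )
    table.index.name = "state_pre"
    table.columns.name = "state_post"
    return per_element, table
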