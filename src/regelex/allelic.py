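"""Allele-specific chromatin accessibility from per-SNP allele read counts.

Procedure, per dataset:

1. infer each individual's genotype at each SNP from its reference /
   alternative read depths (>= 5 reads required; heterozygote iff both
   alleles observed, homozygote iff only one; lower-depth individuals
   excluded);
2. pool reads across heterozygotes per SNP to a (k = reference reads,
   n = total reads) pair;
3. fit one global beta-binomial null (mean mu, overdispersion rho) to all
   pooled pairs by maximum likelihood — the overdispersion absorbs
   SNP-to-SNP technical variability that a plain binomial would mistake for
   allelic imbalance;
4. test each SNP against that null with a two-sided exact minimum-likelihood
   p-value;
5. optionally intersect results across datasets, keeping SNPs significant in
   at least two with concordant direction.

Counts are assumed to be already filtered for reference mapping bias
upstream; note that genotypes and tests use the same reads, so extreme
imbalance can mask heterozygosity — a known, uncorrected selection effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "infer_genotype",
    "add_genotypes",
    "pool_het_counts",
    "BetaBinomialModel",
    "fit_beta_binomial",
    "beta_binomial_logpmf",
    "test_allelic_imbalance",
    "test_table",
    "concordance",
]

DEFAULT_MIN_DEPTH = 5
_TIE_SLACK = 1.0 + 1e-7


def infer_genotype(ref_reads: int, alt_reads: int, min_depth: int = DEFAULT_MIN_DEPTH) -> str:
    """Genotype call from allele read depths.

    ``excluded`` below ``min_depth`` total reads; ``het`` iff both alleles
    observed at least once; else homozygote for the observed allele.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    if ref_reads + alt_reads < min_depth:
        return "excluded"
    if ref_reads >= 1 and alt_reads >= 1:
        return "het"
    return "hom_ref" if ref_reads >= 1 else "hom_alt"


def add_genotypes(table: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Vectorized genotype column for an allele count table."""
    ref = table["ref_reads"].to_numpy()
    alt = table["alt_reads"].to_numpy()
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    geno = np.where(
        ref + alt < min_depth,
        "excluded",
        np.where((ref >= 1) & (alt >= 1), "het", np.where(ref >= 1, "hom_ref", "hom_alt")),
    )
    out = table.copy()
    out["genotype"] = geno
    return out


def pool_het_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP pooled heterozygote counts.

    Sums reference (k) and total (n) reads across heterozygous individuals
    only; SNPs with no heterozygotes are absent from the output.
    """
    if "genotype" not in table.columns:
        raise ValueError("run add_genotypes first")
    hets = table[table["genotype"] == "het"]
    grouped = hets.groupby("snp_id", sort=True)
    out = grouped.agg(
        k=("ref_reads", "sum"),
        alt=("alt_reads", "sum"),
        n_hets=("ref_reads", "size"),
    ).reset_index()
    out["n"] = out["k"] + out["alt"]
    out["ref_fraction"] = out["k"] / out["n"]
    return out[["snp_id", "k", "n", "n_hets", "ref_fraction"]]


# ---------------------------------------------------------------------------
# beta-binomial model


def beta_binomial_logpmf(k, n, mu: float, rho: float):
    """Log pmf of the (mu, rho)-parameterized beta-binomial.

    ``alpha = mu (1-rho)/rho``, ``beta = (1-mu)(1-rho)/rho``; the ``rho = 0``
    limit is the plain binomial.  Below rho = 1e-6 the binomial is used
    directly: the variance inflation lost is at most (n-1)e-6, while the
    gammaln differences above would lose precision for alpha, beta ~ 1/rho
    and leave the likelihood numerically non-smooth for the optimizer.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if rho < 1e-6:
        return stats.binom.logpmf(k, n, mu)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + special.betaln(k + a, n - k + b)
        - special.betaln(a, b)
    )


class BetaBinomialModel(BaseEstimator):
    """Global beta-binomial null for pooled heterozygote reference counts.

    scikit-learn-style estimator.  :meth:`fit` takes arrays ``k`` (reference
    reads) and ``n`` (total reads), one pair per SNP, and maximizes the
    joint beta-binomial likelihood over mean ``mu`` in (0,1) and
    overdispersion ``rho`` in [0, 0.99].  Initialization is by method of
    moments; optimization is bounded L-BFGS-B on the log-likelihood.

    Attributes
    ----------
    mu_, rho_ : float
    loglik_ : float
    n_snps_ : int
    converged_ : bool
    degenerate_ : bool
        Set when ``mu_`` was pinned at a boundary (e.g. all k == n).
    """

    def __init__(self, min_snps: int = 10, rho_max: float = 0.99):
        self.min_snps = min_snps
        self.rho_max = rho_max

    def fit(self, k, n):
        k = np.asarray(k, dtype=float)
        n = np.asarray(n, dtype=float)
        if np.any(k > n) or np.any(k < 0):
            raise ValueError("need 0 <= k <= n")
        keep = n >= 1
        k, n = k[keep], n[keep]
        if len(k) < self.min_snps:
            raise ValueError(f"need at least {self.min_snps} SNPs with reads (got {len(k)})")

        # method-of-moments start
        frac = k / n
        mu0 = float(np.clip(frac.mean(), 1e-3, 1 - 1e-3))
        var_f = float(frac.var())
        nbar = float(n.mean())
        binom_var = mu0 * (1 - mu0) / nbar
        rho0 = 0.0
        if var_f > binom_var and nbar > 1:
            rho0 = float(
                np.clip((var_f - binom_var) / (mu0 * (1 - mu0) * (1 - 1 / nbar)), 0.0, 0.5)
            )

        def nll(params):
            mu, rho = params
            return -float(beta_binomial_logpmf(k, n, mu, rho).sum())

        eps = 1e-6
        bounds = [(eps, 1 - eps), (0.0, self.rho_max)]
        best = None
        for start in ((mu0, max(rho0, 1e-4)), (mu0, 0.05)):
            res = optimize.minimize(
                nll, x0=np.asarray(start), method="L-BFGS-B", bounds=bounds
            )
            if best is None or res.fun < best.fun:
                best = res
        if not best.success:
            # L-BFGS-B line searches can stall at the rho=0 boundary with
            # finite-difference gradients; a simplex polish settles it
            res = optimize.minimize(nll, x0=best.x, method="Nelder-Mead", bounds=bounds)
            if res.fun <= best.fun or res.success:
                best = res
        self.mu_ = float(best.x[0])
        self.rho_ = float(best.x[1])
        self.loglik_ = -float(best.fun)
        self.n_snps_ = int(len(k))
        self.converged_ = bool(best.success)
        self.degenerate_ = bool(self.mu_ <= 2 * eps or self.mu_ >= 1 - 2 * eps)
        if not self.converged_ and not self.degenerate_:
            raise RuntimeError(f"beta-binomial fit did not converge: {best.message}")
        return self

    def logpmf(self, k, n):
        return beta_binomial_logpmf(k, n, self.mu_, self.rho_)

    def pvalue(self, k: int, n: int) -> float:
        """Two-sided exact minimum-likelihood p for one pooled (k, n)."""
        return test_allelic_imbalance(k, n, self)


def fit_beta_binomial(pooled, min_snps: int = 10) -> BetaBinomialModel:
    """Fit the global null from a pooled-counts frame (columns ``k``, ``n``)
    or a list of (k, n) pairs."""
    if isinstance(pooled, pd.DataFrame):
        k, n = pooled["k"].to_numpy(), pooled["n"].to_numpy()
    else:
        arr = np.asarray(list(pooled), dtype=float)
        k, n = arr[:, 0], arr[:, 1]
    return BetaBinomialModel(min_snps=min_snps).fit(k, n)


def test_allelic_imbalance(k: int, n: int, model: BetaBinomialModel) -> float:
    """Two-sided exact p by the minimum-likelihood method.

    Sums the probability of every outcome ``k'`` in 0..n whose pmf does not
    exceed that of the observed ``k`` (with a tiny multiplicative slack so
    exact floating-point ties on the other tail are included).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n < 1:
        raise ValueError("need n >= 1")
    ks = np.arange(n + 1)
    pmf = np.exp(beta_binomial_logpmf(ks, n, model.mu_, model.rho_))
    p_obs = pmf[int(k)]
    p = float(pmf[pmf <= p_obs * _TIE_SLACK].sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


def test_table(pooled: pd.DataFrame, model: BetaBinomialModel, add_bh: bool = True) -> pd.DataFrame:
    """Per-SNP imbalance test over a pooled-counts frame.

    Adds ``p``, ``direction`` (``ref`` if the pooled reference fraction
    exceeds the fitted mean, ``alt`` if below, ``tie`` at equality) and
    optionally a BH ``q`` column alongside the nominal p-values.
    """
    ps = np.array([test_allelic_imbalance(int(r.k), int(r.n), model) for r in pooled.itertuples()])
    out = pooled.copy()
    out["p"] = ps
    frac = out["k"] / out["n"]
    out["direction"] = np.where(frac > model.mu_, "ref", np.where(frac < model.mu_, "alt", "tie"))
    if add_bh:
        out["q"] = multipletests(ps, method="fdr_bh")[1]
    return out


def concordance(results: dict[str, pd.DataFrame], p_cut: float = 0.05) -> pd.DataFrame:
    """SNPs significant in >= 2 datasets with identical direction.

    ``results`` maps dataset name -> tested frame (columns ``snp_id``,
    ``p``, ``direction``).  Ties in direction never count toward
    concordance.
    """
    sig = []
    for ds, df in results.items():
        hit = df[(df["p"] < p_cut) & (df["direction"] != "tie")]
        sig.append(hit.assign(dataset=ds)[["snp_id", "dataset", "direction", "p"]])
    if not sig:
        return pd.DataFrame(columns=["snp_id", "direction", "n_datasets", "datasets"])
    allsig = pd.concat(sig, ignore_index=True)
    rows = []
    for (snp, direction), grp in allsig.groupby(["snp_id", "direction"]):
        if grp["dataset"].nunique() >= 2:
            rows.append(
                {
                    "snp_id": snp,
                    "direction": direction,
                    "n_datasets": grp["dataset"].nunique(),
                    "datasets": ",".join(sorted(grp["dataset"].unique())),
                }
            )
    return pd.DataFrame(rows, columns=["snp_id", "direction", "n_datasets", "datasets"])
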