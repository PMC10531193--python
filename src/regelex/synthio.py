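"""Synthetic input generators for the regulatory-variant analysis pipeline.

Every generator is a pure function of its arguments, including a mandatory
integer seed; the same call always returns bit-identical output.  Each
simulated quantity with a hidden true value (SNP effects, element fold
changes, allelic imbalance) is recorded in a truth table so that downstream
estimators can be checked for parameter recovery.

What is emulated, at toy scale:

* a haplotype reference panel with block LD structure (founder-haplotype
  model: within a block every haplotype descends from one of a few founders,
  plus per-site mutation noise);
* GWAS summary statistics drawn from the LD-aware polygenic model
  ``z = sqrt(N) R beta + eps``, ``eps ~ N(0, R)``, with per-SNP effect
  variance set by binary annotations;
* negative-binomial ATAC fragment counts over elements with per-sample
  library-size factors and a spiked subset of truly differential elements;
* beta-binomial allele-specific read counts at heterozygous SNPs;
* a regulatory-element atlas: disjoint intervals with per-biosample activity
  Z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HaplotypePanel",
    "simulate_haplotype_panel",
    "simulate_gwas_summary",
    "simulate_atac_counts",
    "simulate_allele_counts",
    "simulate_element_atlas",
    "write_panel",
    "read_panel",
]


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("seed is required: simulators must be deterministic")
    return np.random.default_rng(int(seed))


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (rows) over SNPs (columns).

    ``haplotypes`` is ``(2 * n_individuals, n_snps)`` with 0 = reference
    allele, 1 = alternative.  ``snp_meta`` has one row per SNP with columns
    ``variant_id``, ``chrom``, ``pos`` (1-based), ``ref``, ``alt``,
    ``block``.
    """

    haplotypes: np.ndarray
    snp_meta: pd.DataFrame
    n_dropped_monomorphic: int = 0

    def __post_init__(self):
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (diploid panel)")
        if self.haplotypes.shape[1] != len(self.snp_meta):
            raise ValueError("snp_meta length does not match haplotype columns")
        freqs = self.haplotypes.mean(axis=0)
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError("panel contains monomorphic SNPs")
        for _, grp in self.snp_meta.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def index_of(self, variant_id: str) -> int:
        idx = self.snp_meta.index[self.snp_meta["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(idx[0])


_BASES = np.array(list("ACGT"))


def simulate_haplotype_panel(
    n_individuals: int,
    n_blocks: int,
    snps_per_block: int,
    n_founders_per_block: int = 4,
    mutation_rate: float = 0.01,
    seed: int | None = None,
    chrom: str = "chrS",
    block_spacing_bp: int = 100_000,
    snp_spacing_bp: int = 1_000,
) -> HaplotypePanel:
    """Simulate a phased panel with block LD via a founder-haplotype model.

    Each LD block has ``n_founders_per_block`` random founder haplotypes;
    every sampled haplotype copies one founder and flips each site
    independently with probability ``mutation_rate``.  SNPs that end up
    monomorphic are dropped (count reported on the panel).  Blocks are
    mutually independent, giving near-zero cross-block r^2.
    """
    rng = _require_seed(seed)
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if n_founders_per_block < 2:
        raise ValueError("need at least 2 founders per block")
    if min(n_blocks, snps_per_block) < 1:
        raise ValueError("counts must be >= 1")
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must be a probability")

    n_hap = 2 * n_individuals
    cols, meta_rows = [], []
    n_dropped = 0
    pos_cursor = 1
    for b in range(n_blocks):
        founders = rng.integers(0, 2, size=(n_founders_per_block, snps_per_block))
        assign = rng.integers(0, n_founders_per_block, size=n_hap)
        block = founders[assign]
        if mutation_rate > 0:
            flips = rng.random(block.shape) < mutation_rate
            block = np.where(flips, 1 - block, block)
        freqs = block.mean(axis=0)
        keep = (freqs > 0) & (freqs < 1)
        n_dropped += int((~keep).sum())
        block = block[:, keep]
        refalt = rng.integers(0, 4, size=(block.shape[1], 2))
        # ensure ref != alt per SNP
        refalt[:, 1] = (refalt[:, 0] + 1 + refalt[:, 1] % 3) % 4
        for j in range(block.shape[1]):
            meta_rows.append(
                {
                    "variant_id": f"rs{b}_{j}",
                    "chrom": chrom,
                    "pos": pos_cursor + j * snp_spacing_bp,
                    "ref": _BASES[refalt[j, 0]],
                    "alt": _BASES[refalt[j, 1]],
                    "block": b,
                }
            )
        pos_cursor += snps_per_block * snp_spacing_bp + block_spacing_bp
        cols.append(block)

    haplotypes = np.concatenate(cols, axis=1).astype(np.int8)
    meta = pd.DataFrame(meta_rows)
    return HaplotypePanel(haplotypes, meta, n_dropped_monomorphic=n_dropped)


def _block_correlation(panel: HaplotypePanel, block_idx: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the haplotype columns in one block."""
    X = panel.haplotypes[:, block_idx].astype(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return (X.T @ X) / X.shape[0]


def simulate_gwas_summary(
    panel: HaplotypePanel,
    annotations: np.ndarray,
    tau: np.ndarray,
    N: float,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw GWAS summary statistics from the annotation-weighted polygenic model.

    Per-SNP true effects are ``beta_j ~ Normal(0, sum_C tau_C a_jC)``; within
    each LD block with SNP correlation matrix ``R`` the observed z-scores are
    ``z = sqrt(N) R beta + eps`` with ``eps ~ Normal(0, R)``.  Implied
    effect/SE columns use the standard ``se = 1/sqrt(N)``, ``betahat = z*se``
    parameterisation of a standardized-genotype GWAS.

    Returns ``(summary, truth)`` frames; ``truth`` records the drawn
    ``beta_j`` and per-SNP variance.
    """
    rng = _require_seed(seed)
    annotations = np.atleast_2d(np.asarray(annotations))
    if annotations.shape[0] != panel.n_snps:
        raise ValueError("annotation matrix must have one row per SNP")
    tau = np.asarray(tau, dtype=float)
    var_per_snp = annotations @ tau
    if np.any(var_per_snp < 0):
        bad = np.flatnonzero(var_per_snp < 0)[:10]
        ids = panel.snp_meta["variant_id"].iloc[bad].tolist()
        raise ValueError(f"negative per-SNP effect variance for SNPs {ids}")

    beta = rng.normal(0.0, np.sqrt(var_per_snp))
    z = np.empty(panel.n_snps)
    blocks = panel.snp_meta["block"].to_numpy()
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        R = _block_correlation(panel, idx)
        # small jitter keeps the Cholesky stable for near-duplicate SNPs
        L = np.linalg.cholesky(R + 1e-8 * np.eye(len(idx)))
        eps = L @ rng.standard_normal(len(idx))
        z[idx] = np.sqrt(N) * (R @ beta[idx]) + eps if N > 0 else eps

    se = np.full(panel.n_snps, 1.0 / np.sqrt(N) if N > 0 else 1.0)
    betahat = z * se
    pvals = stats.chi2.sf(z**2, df=1)
    summary = panel.snp_meta[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    summary["beta"] = betahat
    summary["se"] = se
    summary["z"] = z
    summary["chi2"] = z**2
    summary["p"] = np.clip(pvals, np.finfo(float).tiny, 1.0)
    summary["n"] = N
    truth = pd.DataFrame(
        {
            "variant_id": panel.snp_meta["variant_id"],
            "true_beta": beta,
            "true_var": var_per_snp,
        }
    )
    return summary, truth


def simulate_atac_counts(
    n_elements: int,
    group_sizes: tuple[int, int] = (10, 11),
    baseline_logmean_range: tuple[float, float] = (3.0, 8.0),
    dispersion: float = 0.1,
    spike_fraction: float = 0.05,
    spike_log2fc: float = 2.0,
    libsize_sd: float = 0.2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial element-by-sample ATAC count matrix with spike-ins.

    A random ``spike_fraction`` of elements have their group-2 mean shifted
    by ``spike_log2fc`` (in log2 units).  Per-sample library-size factors are
    drawn log-normally with log2-scale SD ``libsize_sd`` and recorded in the
    sample table.  ``dispersion`` is the NB2 alpha: ``var = mu + alpha mu^2``.

    Group sizes of 10 and 11 mirror a patient-versus-control cohort design.

    Returns ``(counts, samples, truth)``.
    """
    rng = _require_seed(seed)
    if min(group_sizes) < 1:
        raise ValueError("both groups need at least one sample")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if not 0 <= spike_fraction <= 1:
        raise ValueError("spike_fraction must be in [0, 1]")

    n1, n2 = group_sizes
    n_samples = n1 + n2
    groups = np.array(["g1"] * n1 + ["g2"] * n2)
    sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    log2_libfac = rng.normal(0.0, libsize_sd, size=n_samples)

    base_log2mean = rng.uniform(*baseline_logmean_range, size=n_elements)
    n_spiked = int(round(spike_fraction * n_elements))
    spiked = np.zeros(n_elements, dtype=bool)
    spiked[rng.choice(n_elements, size=n_spiked, replace=False)] = True
    log2fc = np.where(spiked, spike_log2fc, 0.0)

    mu = 2.0 ** (
        base_log2mean[:, None]
        + np.where(groups == "g2", log2fc[:, None], 0.0)
        + log2_libfac[None, :]
    )
    size = 1.0 / dispersion  # NB "number of failures" parameter
    counts = rng.negative_binomial(size, size / (size + mu))
    counts_df = pd.DataFrame(
        counts, index=[f"el{i:05d}" for i in range(n_elements)], columns=sample_ids
    )
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "log2_libsize_factor": log2_libfac}
    )
    truth = pd.DataFrame(
        {
            "element_id": counts_df.index,
            "true_log2fc": log2fc,
            "is_differential": spiked,
            "base_log2mean": base_log2mean,
        }
    )
    return counts_df, samples, truth


def simulate_allele_counts(
    n_snps: int,
    n_individuals: int,
    depth_mean: float = 30.0,
    theta: float | np.ndarray = 0.5,
    rho: float = 0.05,
    het_rate: float = 0.5,
    imbalanced_fraction: float = 0.0,
    imbalanced_theta: float = 0.6,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(SNP, individual) allele read depths with beta-binomial het counts.

    Each pair gets a genotype (heterozygote with probability ``het_rate``,
    otherwise homozygote for either allele) and a Poisson read depth.  At
    heterozygotes the reference read count is beta-binomial with mean
    ``theta`` and overdispersion ``rho``; homozygote reads are all one
    allele.  ``theta`` may be scalar or per-SNP; alternatively set
    ``imbalanced_fraction``/``imbalanced_theta`` to spike a random subset of
    SNPs to a non-0.5 truth.

    Returns ``(table, truth)`` where the table has columns
    ``snp_id, individual_id, ref_reads, alt_reads``.
    """
    rng = _require_seed(seed)
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    theta_arr = np.broadcast_to(np.asarray(theta, dtype=float), (n_snps,)).copy()
    if np.any((theta_arr <= 0) | (theta_arr >= 1)):
        raise ValueError("theta must be strictly inside (0, 1)")
    if imbalanced_fraction > 0:
        n_spiked = int(round(imbalanced_fraction * n_snps))
        spiked_idx = rng.choice(n_snps, size=n_spiked, replace=False)
        theta_arr[spiked_idx] = imbalanced_theta

    snp_ids = np.array([f"snp{j:05d}" for j in range(n_snps)])
    rows = []
    for j in range(n_snps):
        for i in range(n_individuals):
            depth = rng.poisson(depth_mean)
            u = rng.random()
            if u < het_rate:
                if rho > 0:
                    a = theta_arr[j] * (1 - rho) / rho
                    b = (1 - theta_arr[j]) * (1 - rho) / rho
                    p = rng.beta(a, b)
                else:
                    p = theta_arr[j]
                ref = rng.binomial(depth, p) if depth > 0 else 0
                alt = depth - ref
            elif u < het_rate + (1 - het_rate) / 2:
                ref, alt = depth, 0
            else:
                ref, alt = 0, depth
            rows.append((snp_ids[j], f"ind{i:03d}", ref, alt))
    table = pd.DataFrame(rows, columns=["snp_id", "individual_id", "ref_reads", "alt_reads"])
    truth = pd.DataFrame(
        {"snp_id": snp_ids, "true_theta": theta_arr, "true_rho": rho}
    )
    return table, truth


def simulate_element_atlas(
    n_elements: int,
    biosamples: list[str],
    active_fraction: float = 0.3,
    element_width: int = 300,
    gap: int = 700,
    chrom: str = "chrS",
    z_cut: float = 1.64,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint element intervals plus per-biosample activity Z-scores.

    Per (element, biosample), with probability ``active_fraction`` the
    Z-score is drawn above ``z_cut`` (shifted exponential tail), otherwise
    from a standard normal truncated below ``z_cut``; the realized active
    fraction therefore matches the target in expectation exactly.

    Returns ``(elements, zscores)``: a BED-like frame (0-based half-open)
    and an element-by-biosample Z matrix.
    """
    rng = _require_seed(seed)
    if n_elements < 1:
        raise ValueError("need at least one element")
    if not 0 < active_fraction <= 1:
        raise ValueError("active_fraction must be in (0, 1]")
    starts = np.arange(n_elements, dtype=np.int64) * (element_width + gap)
    elements = pd.DataFrame(
        {
            "element_id": [f"el{i:05d}" for i in range(n_elements)],
            "chrom": chrom,
            "start": starts,
            "end": starts + element_width,
        }
    )
    Z = np.empty((n_elements, len(biosamples)))
    for k in range(len(biosamples)):
        active = rng.random(n_elements) < active_fraction
        hi = z_cut + rng.exponential(1.0, size=n_elements)
        lo = stats.truncnorm.ppf(
            rng.random(n_elements), a=-np.inf, b=z_cut, loc=0.0, scale=1.0
        )
        Z[:, k] = np.where(active, hi, lo)
    zscores = pd.DataFrame(Z, index=elements["element_id"], columns=list(biosamples))
    return elements, zscores


# ---------------------------------------------------------------------------
# fixture I/O: VCF-like variant table + binary haplotype sidecar, TSV matrices


def write_panel(panel: HaplotypePanel, prefix: str) -> None:
    """Write a panel as ``<prefix>.variants.tsv`` (1-based, VCF-like columns)
    and ``<prefix>.haplotypes.tsv`` (0/1 matrix, one row per haplotype)."""
    meta = panel.snp_meta.copy()
    meta.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    np.savetxt(f"{prefix}.haplotypes.tsv", panel.haplotypes, fmt="%d", delimiter="\t")


def read_panel(prefix: str) -> HaplotypePanel:
    meta = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
    hap = np.loadtxt(f"{prefix}.haplotypes.tsv", dtype=np.int8, delimiter="\t", ndmin=2)
    return HaplotypePanel(hap, meta)
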