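"""Motif delta scoring, eQTL-based gene support, and pipeline orchestration.

* **PWM scoring** — log2-odds of a sequence under a position weight matrix
  against background base frequencies; both-strand scanning takes the max of
  the forward score and the reverse-complement score.
* **Allele delta scoring** — the predicted change in transcription-factor
  binding when a variant swaps the base at one motif position: with the
  alignment held fixed the full-window score difference collapses to the
  single-column log-ratio ``log2(P(alt)/P(ref))``; a negative delta predicts
  decreased binding for the alternative (risk) allele.
* **Gene-support classification** — a differentially-expressed-gene tier
  (FDR < 10%, < 20%, or none) combined with two independent lines of
  support through the gene's eQTLs: GWAS support (an eQTL SNP with GWAS
  p below a cutoff) and ATAC support (an eQTL SNP inside a differentially
  accessible element).  Non-differential genes with both supports are
  flagged as candidate risk genes.
* **run_pipeline** — end-to-end orchestration over synthetic inputs with a
  single seed, emitting a machine-readable JSON summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic, atlas, diffacc, ldcred, permenrich, sldsc, synthio
from .intervals import intersect_positions

__all__ = [
    "PWM",
    "pwm_score",
    "pwm_delta_score",
    "classify_gene_support",
    "run_pipeline",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
DEFAULT_PSEUDOCOUNT = 0.001


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities (A, C, G, T).

    Columns (positions) must each sum to 1 within 1e-6 before the
    pseudocount; the stored matrix has the pseudocount applied and is
    renormalized, so probabilities are strictly positive.
    """

    motif_id: str
    probs: np.ndarray  # (L, 4)
    background: np.ndarray = None
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be (L, 4)")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("each PWM position must sum to 1")
        self.probs = self.probs + self.pseudocount
        self.probs /= self.probs.sum(axis=1, keepdims=True)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()])
    except KeyError as e:
        raise ValueError(f"ambiguous or invalid base {e.args[0]!r} in sequence") from None


def pwm_score(seq: str, pwm: PWM, both_strands: bool = False) -> float:
    """Log2-odds score of ``seq`` (length L) under the PWM:
    ``sum_i log2(P_i(seq_i) / bg(seq_i))``.

    With ``both_strands``, the reverse complement is scored too and the max
    is returned.
    """
    if len(seq) != pwm.length:
        raise ValueError(f"sequence length {len(seq)} != motif length {pwm.length}")
    idx = _encode(seq)
    fwd = float(
        np.log2(pwm.probs[np.arange(pwm.length), idx] / pwm.background[idx]).sum()
    )
    if not both_strands:
        return fwd
    rc = seq.upper().translate(_COMPLEMENT)[::-1]
    idx_rc = _encode(rc)
    rev = float(
        np.log2(pwm.probs[np.arange(pwm.length), idx_rc] / pwm.background[idx_rc]).sum()
    )
    return max(fwd, rev)


def pwm_delta_score(ref_window: str, alt_allele: str, offset: int, pwm: PWM) -> float:
    """Predicted binding change when the base at ``offset`` flips to
    ``alt_allele``; negative = decreased binding for the alternative allele.

    With the motif alignment held fixed the delta equals the single-column
    log-ratio ``log2(P_offset(alt) / P_offset(ref))``.
    """
    if not 0 <= offset < pwm.length:
        raise ValueError("offset outside the motif window")
    ref_base = ref_window[offset].upper()
    alt_allele = alt_allele.upper()
    if alt_allele == ref_base:
        raise ValueError("alt allele equals the reference base at the offset")
    alt_window = ref_window[:offset] + alt_allele + ref_window[offset + 1 :]
    return pwm_score(alt_window, pwm) - pwm_score(ref_window, pwm)


# ---------------------------------------------------------------------------
# gene support


def classify_gene_support(
    diff_genes: pd.DataFrame,
    eqtls: pd.DataFrame,
    gwas_p: dict,
    diff_elements: pd.DataFrame,
    fdr_tiers: tuple[float, float] = (0.10, 0.20),
    gwas_p_cut: float = 1e-6,
    element_p_cut: float = 0.01,
) -> pd.DataFrame:
    """Per-gene differential tier plus GWAS / ATAC support flags.

    Parameters
    ----------
    diff_genes
        Frame indexed by gene id with columns ``log2fc``, ``q`` (expression
        FDR).
    eqtls
        Frame with columns ``gene_id``, ``variant_id``, ``chrom``, ``pos``
        (1-based), ``p`` (eQTL significance, taken as given).
    gwas_p
        Mapping variant id -> GWAS p-value.
    diff_elements
        BED-like frame with a per-element differential ``p`` column.

    Rules: GWAS support iff some eQTL SNP of the gene has GWAS
    ``p < gwas_p_cut``; ATAC support iff some eQTL SNP lies inside an
    element with differential ``p < element_p_cut``.  Tier ``fdr10`` if
    gene ``q < 0.10``, ``fdr20`` if ``q < 0.20``, else ``none``.  The
    candidate-risk flag marks non-differential genes with both supports.
    """
    t10, t20 = fdr_tiers
    sig_elements = diff_elements[diff_elements["p"] < element_p_cut]
    eqtl_hits = intersect_positions(
        eqtls.rename(columns={"variant_id": "variant_id"})[
            ["variant_id", "chrom", "pos"]
        ].drop_duplicates("variant_id"),
        sig_elements,
    ) if len(sig_elements) else {}
    rows = []
    for gene, grp in eqtls.groupby("gene_id"):
        gsup = any(gwas_p.get(v, 1.0) < gwas_p_cut for v in grp["variant_id"])
        asup = any(bool(eqtl_hits.get(v)) for v in grp["variant_id"])
        rows.append({"gene_id": gene, "gwas_support": gsup, "atac_support": asup})
    support = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["gwas_support", "atac_support"]
    )
    out = diff_genes.copy()
    out["tier"] = np.where(out["q"] < t10, "fdr10", np.where(out["q"] < t20, "fdr20", "none"))
    out = out.join(support, how="left")
    out[["gwas_support", "atac_support"]] = out[["gwas_support", "atac_support"]].fillna(False)
    out["candidate_risk_gene"] = (
        (out["tier"] == "none") & out["gwas_support"] & out["atac_support"]
    )
    return out


# ---------------------------------------------------------------------------
# pipeline


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


DEFAULT_CONFIG = {
    "seed": 1,
    "stages": ["simulate", "credible", "atlas", "diff", "allelic", "ldsc", "permtest"],
    "panel": {"n_individuals": 200, "n_blocks": 20, "snps_per_block": 25},
    "gwas": {"N": 5000, "h2": 0.02, "annot_fraction": 0.1, "annot_h2_share": 0.5},
    "atac": {"n_elements": 500, "group_sizes": [10, 11], "spike_fraction": 0.05, "spike_log2fc": 2.0},
    "allelic": {"n_snps": 200, "n_individuals": 20, "depth_mean": 30, "rho": 0.05},
    "atlas": {"n_elements": 500, "biosamples": ["Th1", "Th2", "Th17", "Treg", "Teff"], "active_fraction": 0.3},
    "permtest": {"n_perm": 2000},
    "ldsc": {"n_blocks": 20},
    "credible": {"coverage": 0.95, "min_pp": 0.01, "r2_threshold": 0.7},
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic analysis end to end; returns the JSON summary.

    ``config`` is a dict or a path to a YAML file; unknown keys raise before
    any computation.  Outputs (when ``out_dir`` is given) go to a
    config-hashed subdirectory so a rerun with the same config lands in the
    same place and is bit-identical.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **config}
    for key, val in DEFAULT_CONFIG.items():
        if isinstance(val, dict):
            bad = set(cfg[key]) - set(val)
            if bad:
                raise ValueError(f"unknown keys in config section {key!r}: {sorted(bad)}")
            cfg[key] = {**val, **cfg[key]}
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    summary: dict = {"config_hash": _config_hash(cfg), "seed": seed, "stages": {}}

    # --- simulate ---------------------------------------------------------
    pc = cfg["panel"]
    panel = synthio.simulate_haplotype_panel(
        pc["n_individuals"], pc["n_blocks"], pc["snps_per_block"], seed=seed
    )
    gc = cfg["gwas"]
    M = panel.n_snps
    annot = np.zeros((M, 2))
    annot[:, 0] = 1.0
    rng = np.random.default_rng(seed + 1)
    in_annot = rng.random(M) < gc["annot_fraction"]
    annot[in_annot, 1] = 1.0
    h2 = gc["h2"]
    share = gc["annot_h2_share"]
    n_in = max(int(in_annot.sum()), 1)
    tau = np.array(
        [(1 - share) * h2 / max(M - n_in, 1), share * h2 / n_in - (1 - share) * h2 / max(M - n_in, 1)]
    )
    gwas, gwas_truth = synthio.simulate_gwas_summary(panel, annot, tau, gc["N"], seed=seed + 2)
    summary["stages"]["simulate"] = {
        "n_snps": int(M),
        "n_dropped_monomorphic": panel.n_dropped_monomorphic,
        "mean_chi2": float(gwas["chi2"].mean()),
    }

    # --- credible sets ----------------------------------------------------
    if "credible" in stages:
        cc = cfg["credible"]
        lead = gwas.loc[gwas["chi2"].idxmax(), "variant_id"]
        ld_set = ldcred.ld_expand(lead, panel, threshold=cc["r2_threshold"])
        lead_block = panel.snp_meta.loc[panel.index_of(lead), "block"]
        locus_stats = gwas[panel.snp_meta["block"].to_numpy() == lead_block]
        pps = ldcred.single_causal_posteriors(locus_stats)
        cred = ldcred.build_credible_set(pps, coverage=cc["coverage"], min_pp=cc["min_pp"])
        members = ldcred.combine_sources(ld_set, cred)
        summary["stages"]["credible"] = {
            "lead": str(lead),
            "n_ld_set": int(len(ld_set)),
            "n_finemap_set": int(len(cred)),
            "n_shared": int((members["source"] == "both").sum()),
        }

    # --- atlas ------------------------------------------------------------
    if "atlas" in stages:
        ac = cfg["atlas"]
        elements, zscores = synthio.simulate_element_atlas(
            ac["n_elements"], ac["biosamples"], ac["active_fraction"], seed=seed + 3
        )
        active = atlas.threshold_active_elements(zscores)
        summary["stages"]["atlas"] = {
            "n_elements": int(len(elements)),
            "n_active": int(len(active)),
        }

    # --- differential accessibility ---------------------------------------
    if "diff" in stages:
        dc = cfg["atac"]
        counts, samples, atac_truth = synthio.simulate_atac_counts(
            dc["n_elements"],
            tuple(dc["group_sizes"]),
            spike_fraction=dc["spike_fraction"],
            spike_log2fc=dc["spike_log2fc"],
            seed=seed + 4,
        )
        offsets = diffacc.loess_normalize(counts)
        diff = diffacc.test_differential(counts, offsets, samples["group"])
        called = diff["q"] < 0.05
        truly = atac_truth.set_index("element_id")["is_differential"]
        summary["stages"]["diff"] = {
            "n_tested": int(diff["tested"].sum()),
            "n_called_q05": int(called.sum()),
            "n_true_spiked": int(truly.sum()),
            "recall_q05": float((called & truly).sum() / max(int(truly.sum()), 1)),
        }

    # --- allelic ----------------------------------------------------------
    if "allelic" in stages:
        lc = cfg["allelic"]
        table, al_truth = synthio.simulate_allele_counts(
            lc["n_snps"], lc["n_individuals"], depth_mean=lc["depth_mean"],
            rho=lc["rho"], imbalanced_fraction=0.05, seed=seed + 5,
        )
        pooled = allelic.pool_het_counts(allelic.add_genotypes(table))
        model = allelic.fit_beta_binomial(pooled)
        tested = allelic.test_table(pooled, model)
        summary["stages"]["allelic"] = {
            "n_snps_tested": int(len(tested)),
            "mu_hat": model.mu_,
            "rho_hat": model.rho_,
            "n_significant_p05": int((tested["p"] < 0.05).sum()),
        }

    # --- ldsc -------------------------------------------------------------
    if "ldsc" in stages:
        ld_scores = sldsc.compute_ld_scores(panel, annot)
        reg = sldsc.regress_partitioned(
            gwas["chi2"].to_numpy(),
            ld_scores.drop(columns="variant_id").to_numpy(),
            gc["N"],
            n_blocks=cfg["ldsc"]["n_blocks"],
        )
        enr = sldsc.enrichment_estimates(reg, annot)
        summary["stages"]["ldsc"] = {
            "intercept": reg.intercept_,
            "tau": reg.tau_.tolist(),
            "enrichment_annot1": float(enr["enrichment"].iloc[1]),
        }

    # --- permutation enrichment -------------------------------------------
    if "permtest" in stages and "atlas" in stages and "credible" in stages:
        universe = gwas[["variant_id", "chrom", "pos"]].copy()
        # place elements on the GWAS chromosome so overlap is possible
        span = int(universe["pos"].max())
        n_el = max(len(universe) // 20, 5)
        el_rng = np.random.default_rng(seed + 6)
        starts = np.sort(el_rng.choice(span, size=n_el, replace=False))
        perm_elements = pd.DataFrame(
            {
                "element_id": [f"pe{i}" for i in range(n_el)],
                "chrom": universe["chrom"].iloc[0],
                "start": starts,
                "end": starts + 2000,
            }
        )
        risk = set(members["variant_id"])
        test = permenrich.permutation_overlap_test(
            risk, universe, perm_elements, n_perm=cfg["permtest"]["n_perm"], seed=seed + 7
        )
        summary["stages"]["permtest"] = {
            "observed_overlap": test.observed,
            "p_value": test.p_value,
            "scheme": test.scheme,
        }

    if out_dir is not None:
        out = Path(out_dir) / summary["config_hash"]
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
    return summary
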