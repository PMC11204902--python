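"""Sample- and variant-level genotype quality control.

Filters follow standard array-QC practice for case-control panels:

* samples: call rate >= 0.95; genome-wide heterozygosity within +/- 3 SD
  of the panel mean;
* variants: call rate >= 0.98; Hardy-Weinberg exact-test p >= 1e-4
  (computed on hard-called genotypes, all samples pooled by default).

The HWE test is the exact conditional test: conditioning on the observed
allele counts, the p-value sums the probabilities of every heterozygote
count (same parity, same allele totals) whose conditional probability does
not exceed that of the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from prscad.data_io import GenotypePanel


@dataclass
class QCReport:
    samples_removed: list[tuple[str, str]] = field(default_factory=list)
    variants_removed: list[tuple[str, str]] = field(default_factory=list)
    thresholds_used: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("entity\tkey\treason\n")
            for sid, reason in self.samples_removed:
                fh.write(f"sample\t{sid}\t{reason}\n")
            for key, reason in self.variants_removed:
                fh.write(f"variant\t{key}\t{reason}\n")


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

def sample_call_rate(panel: GenotypePanel) -> np.ndarray:
    """Fraction of non-missing genotypes per sample."""
    if panel.n_variants == 0:
        raise ValueError("sample_call_rate: panel has zero variants")
    return 1.0 - panel.missing_mask.mean(axis=1)


def heterozygosity_rate(panel: GenotypePanel) -> np.ndarray:
    """Per-sample fraction of called genotypes that are heterozygous.

    Dosages are hard-called (rounded, ties-to-even) for counting only.
    Samples with no called genotypes get rate NaN.
    """
    hard = panel.hard_calls()
    called = hard >= 0
    n_called = called.sum(axis=1)
    n_het = ((hard == 1) & called).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)


def heterozygosity_filter(panel: GenotypePanel, k_sd: float = 3.0,
                          report: QCReport | None = None):
    """Remove samples whose het rate deviates more than ``k_sd`` SDs from the mean.

    With zero spread (SD = 0) no sample can deviate, so none are removed.
    """
    if panel.n_samples < 3:
        raise ValueError("heterozygosity_filter: need >= 3 samples")
    rate = heterozygosity_rate(panel)
    mean = np.nanmean(rate)
    sd = np.nanstd(rate)
    if sd == 0:
        keep = np.ones(panel.n_samples, dtype=bool)
    else:
        keep = np.abs(rate - mean) <= k_sd * sd
    keep &= ~np.isnan(rate)
    if report is not None:
        for i in np.flatnonzero(~keep):
            report.samples_removed.append((panel.sample_ids[i], "heterozygosity"))
        report.thresholds_used["het_k_sd"] = k_sd
    return panel.subset_samples(keep)


def sample_qc(panel: GenotypePanel, call_rate_min: float = 0.95,
              het_k_sd: float = 3.0) -> tuple[GenotypePanel, QCReport]:
    """Apply call-rate then heterozygosity sample filters."""
    report = QCReport(thresholds_used={"sample_call_rate": call_rate_min})
    cr = sample_call_rate(panel)
    keep = cr >= call_rate_min
    for i in np.flatnonzero(~keep):
        report.samples_removed.append((panel.sample_ids[i], "call_rate"))
    panel = panel.subset_samples(keep)
    panel = heterozygosity_filter(panel, k_sd=het_k_sd, report=report)
    return panel, report


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditional on the observed allele counts (n_A copies of A, n_a of a in
    n diploids), the heterozygote count n_Aa has distribution

        P(n_Aa) = C * 2^{n_Aa} * n! / (n_AA! n_Aa! n_aa!)

    over all n_Aa with the same parity as n_A.  The p-value sums P over all
    heterozygote counts whose probability is <= that of the observed count.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("hwe_exact_test: all counts zero")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = (max(n_A, n_a) - hets) // 2
    logp = (hets * np.log(2.0) + gammaln(n + 1)
            - gammaln(hets + 1) - gammaln(homs_rare + 1) - gammaln(homs_common + 1))
    logp -= np.logaddexp.reduce(logp)  # normalize
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size != 1:  # impossible given consistent counts
        raise ValueError("observed heterozygote count inconsistent with allele totals")
    p_obs = logp[obs[0]]
    # tolerance guards against ties broken by rounding
    mask = logp <= p_obs + 1e-12
    p = float(np.exp(np.logaddexp.reduce(logp[mask])))
    return min(p, 1.0)


def hwe_pvalues(panel: GenotypePanel, controls_only: bool = False,
                case_status: np.ndarray | None = None) -> np.ndarray:
    """Per-variant HWE p-values from hard calls (monomorphic -> p = 1)."""
    hard = panel.hard_calls()
    if controls_only:
        if case_status is None:
            raise ValueError("controls_only requires case_status")
        hard = hard[np.asarray(case_status) == 0]
    p = np.ones(panel.n_variants)
    for j in range(panel.n_variants):
        col = hard[:, j]
        col = col[col >= 0]
        if col.size == 0:
            continue
        n_aa0 = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_aa2 = int((col == 2).sum())
        p[j] = hwe_exact_test(n_aa2, n_het, n_aa0)
    return p


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def variant_call_rate(panel: GenotypePanel) -> np.ndarray:
    return 1.0 - panel.missing_mask.mean(axis=0)


def variant_qc(panel: GenotypePanel, hwe_alpha: float = 1e-4,
               call_rate_min: float = 0.98, controls_only: bool = False,
               case_status: np.ndarray | None = None
               ) -> tuple[GenotypePanel, QCReport]:
    """Retain variants with call rate >= ``call_rate_min`` and HWE p >= ``hwe_alpha``.

    Call rate is the primary removal reason when both criteria fail.
    """
    report = QCReport(thresholds_used={
        "variant_call_rate": call_rate_min, "hwe_alpha": hwe_alpha,
    })
    cr = variant_call_rate(panel)
    hwe_p = hwe_pvalues(panel, controls_only=controls_only, case_status=case_status)
    keep = np.ones(panel.n_variants, dtype=bool)
    for j in range(panel.n_variants):
        key = f"{panel.variant_meta['chrom'][j]}:{panel.variant_meta['pos'][j]}"
        if cr[j] < call_rate_min:
            keep[j] = False
            report.variants_removed.append((key, "call_rate"))
        elif hwe_p[j] < hwe_alpha:
            keep[j] = False
            report.variants_removed.append((key, "hwe"))
    return panel.subset_variants(keep), report
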