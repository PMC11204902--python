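"""Additive dosage-weighted polygenic score computation.

For individual i the score is the unnormalized weighted sum

    PRS_i = sum_j w_j * G_ij

over the harmonized (panel-oriented) weights w_j and ALT dosages
G_ij in [0, 2].  Missing dosages are mean-imputed by default so that a
sporadically missing variant shifts every affected sample by the same
constant and leaves between-sample contrasts untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from prscad.data_io import GenotypePanel
from prscad.harmonize import HarmonizedScore


@dataclass
class PRSVector:
    pgs_id: str
    sample_ids: list[str]
    values: np.ndarray
    n_variants_used: int
    missing_policy: str = "mean"
    is_standardized: bool = False
    raw_values: np.ndarray | None = None

    def __post_init__(self):
        if len(self.sample_ids) != len(self.values):
            raise ValueError("one value per sample required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite PRS values")

    def to_tsv(self, path) -> None:
        std = self.values if self.is_standardized else None
        raw = self.raw_values if self.raw_values is not None else self.values
        with open(path, "w") as fh:
            fh.write("sample_id\tprs_raw\tprs_z\tn_variants_used\n")
            for i, sid in enumerate(self.sample_ids):
                z = "" if std is None else repr(float(std[i]))
                fh.write(f"{sid}\t{float(raw[i])!r}\t{z}\t{self.n_variants_used}\n")


def compute_prs(harmonized: HarmonizedScore, panel: GenotypePanel,
                missing_policy: str = "mean") -> PRSVector:
    """Evaluate the harmonized score on every panel sample.

    ``missing_policy`` is one of ``mean`` (impute the variant's mean dosage
    over non-missing samples), ``zero`` (missing contributes nothing), or
    ``drop_variant`` (any variant with missingness is excluded).
    """
    if missing_policy not in ("mean", "zero", "drop_variant"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    used = harmonized.used()
    if not used:
        raise ValueError(f"{harmonized.pgs_id}: empty score (zero used variants)")
    pos_idx = panel.position_index()
    cols, weights = [], []
    for sv, outcome in used:
        col = pos_idx.get(outcome.panel_variant_key)
        if col is None:
            raise ValueError(
                f"{harmonized.pgs_id}: harmonized entry {outcome.panel_variant_key} "
                "does not resolve to a panel variant")
        cols.append(col)
        weights.append(outcome.aligned_weight)
    cols = np.asarray(cols, dtype=int)
    w = np.asarray(weights, dtype=float)

    G = panel.dosage[:, cols].astype(float).copy()
    miss = panel.missing_mask[:, cols]
    if missing_policy == "drop_variant":
        keep = ~miss.any(axis=0)
        if not keep.any():
            raise ValueError(f"{harmonized.pgs_id}: empty score (zero used variants)")
        G, miss, w = G[:, keep], miss[:, keep], w[keep]
    elif missing_policy == "mean":
        n_obs = (~miss).sum(axis=0)
        col_sum = np.where(miss, 0.0, G).sum(axis=0)
        with np.errstate(invalid="ignore"):
            col_mean = np.where(n_obs > 0, col_sum / np.maximum(n_obs, 1), 0.0)
        G = np.where(miss, col_mean[None, :], G)
    else:  # zero
        G = np.where(miss, 0.0, G)

    values = G @ w
    return PRSVector(
        pgs_id=harmonized.pgs_id,
        sample_ids=list(panel.sample_ids),
        values=values,
        n_variants_used=int(w.size),
        missing_policy=missing_policy,
    )


def standardize_prs(prs: PRSVector) -> PRSVector:
    """Z-score the PRS (population SD); keeps the raw values alongside.

    Enables per-SD odds ratios: a logistic coefficient on the z-scored
    score exponentiates to the odds ratio per score SD.
    """
    if len(prs.values) < 2:
        raise ValueError("standardize_prs: need >= 2 samples")
    raw = prs.raw_values if prs.raw_values is not None else prs.values
    sd = raw.std()
    if sd == 0:
        raise ValueError(f"{prs.pgs_id}: degenerate score (zero SD)")
    z = (raw - raw.mean()) / sd
    return PRSVector(
        pgs_id=prs.pgs_id,
        sample_ids=list(prs.sample_ids),
        values=z,
        n_variants_used=prs.n_variants_used,
        missing_policy=prs.missing_policy,
        is_standardized=True,
        raw_values=raw.copy(),
    )
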