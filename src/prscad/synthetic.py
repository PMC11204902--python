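"""Seeded synthetic data with the structure the replication pipeline assumes.

The generator emulates a THISEAS-like case-control panel: ~900 samples with
~40% cases, biallelic SNP dosages in Hardy-Weinberg proportions within each
of (by default) two subpopulations whose allele frequencies follow a
Balding-Nichols beta model at a target Fst, local LD from a block-copy
haplotype model, Table-1-calibrated clinical covariates, and a logistic
disease model with a planted per-SD PRS effect.  Corrupted scoring files
(allele switches, strand flips, variants dropped in favour of planted
r2 = 1 proxies) exercise the harmonization logic; every corruption is
recorded in a ground-truth ledger.

All randomness flows from ``SimulationConfig.seed`` via numpy SeedSequence
spawning: identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from prscad.data_io import GenotypePanel, PhenotypeTable, ScoreSet, ScoreVariant, write_score_file

# ordered (ref, alt) pairs excluding strand-ambiguous (palindromic) pairs
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]

# Covariate distributions calibrated to the THISEAS descriptive table:
# age 57.7 +/- 12.4 y, 63.9% male, SBP 132.6 +/- 19.7 mmHg, total
# cholesterol 200.7 +/- 44.6 mg/dl, 23.5% T2DM, 65.0% smokers.  Body weight
# is not tabulated (only BMI 28.3 +/- 4.4 kg/m2); 78 +/- 14 kg matches that
# BMI at typical stature.
DEFAULT_COVARIATE_PARAMS = {
    "age": (57.7, 12.4),
    "male_fraction": 0.639,
    "sbp": (132.6, 19.7),
    "total_chol": (200.7, 44.6),
    "t2dm_prevalence": 0.235,
    "smoking_prevalence": 0.65,
    "weight": (78.0, 14.0),
}

# plausible fixed covariate log-odds for the disease model; ground truth for
# recovery tests is whatever the config says
DEFAULT_COVARIATE_EFFECTS = {"age": 0.03, "sex": 0.5, "t2dm": 0.4, "smoking": 0.3}


@dataclass
class SimulationConfig:
    n_samples: int = 924
    n_variants: int = 1000
    case_fraction: float = 390 / 924
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.01
    n_subpops: int = 2
    ld_block_size: int = 10
    ld_decay: float = 0.9
    n_causal: int = 20
    true_weights: np.ndarray | None = None
    per_sd_or: float = 1.5
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    dosage_jitter_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.fst < 0 or self.ld_decay < 0 or self.ld_decay >= 1:
            raise ValueError("fst >= 0 and ld_decay in [0, 1) required")
        if self.n_subpops < 1 or self.n_samples < 2 or self.n_variants < 1:
            raise ValueError("invalid panel dimensions")
        if self.per_sd_or <= 0:
            raise ValueError("per_sd_or must be positive")


@dataclass
class SimulationTruth:
    causal_keys: list[tuple[str, int]]
    causal_weights: np.ndarray
    per_sd_log_or: float
    subpop_labels: np.ndarray
    true_prs_z: np.ndarray | None = None
    proxy_pairs: list[tuple[tuple[str, int], tuple[str, int], float]] = field(default_factory=list)
    corruption_ledger: list[tuple[str, str]] = field(default_factory=list)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_haplotypes(rng, freqs: np.ndarray, n_haps: int,
                         block_size: int, ld_decay: float) -> np.ndarray:
    """Block-copy haplotypes: within a block each site either copies the
    previous site's latent uniform (probability ``ld_decay``) or redraws it,
    so adjacent-site allele correlation ~ ld_decay and blocks are
    independent.  ``freqs`` is (n_haps, m) row-specific (per-subpopulation)
    allele frequencies."""
    n, m = freqs.shape
    assert n == n_haps
    U = rng.random((n_haps, m))
    K = rng.random((n_haps, m)) < ld_decay
    u = np.empty_like(U)
    for j in range(m):
        if j % block_size == 0:
            u[:, j] = U[:, j]
        else:
            u[:, j] = np.where(K[:, j], u[:, j - 1], U[:, j])
    return (u < freqs).astype(np.int8)


def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, SimulationTruth]:
    """Generate a structured, LD-patterned dosage panel plus ground truth."""
    rng_freq, rng_hap, rng_meta, rng_jit, rng_miss, rng_w = _rngs(config.seed, 6)
    m = config.n_variants
    n = config.n_samples
    # ancestral frequencies drawn per LD block with small per-site jitter:
    # the block-copy model only produces high adjacent-site r2 when
    # neighbouring frequencies are similar
    lo, hi = config.maf_range
    n_blocks = -(-m // config.ld_block_size)
    p_block = rng_freq.uniform(lo, hi, size=n_blocks)
    p_anc = np.repeat(p_block, config.ld_block_size)[:m]
    if config.ld_block_size > 1:
        p_anc = np.clip(p_anc + rng_freq.normal(0.0, 0.03, size=m), lo, hi)

    if config.n_subpops > 1 and config.fst > 0:
        F = config.fst
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        sub_freqs = np.stack([
            np.clip(rng_freq.beta(a, b), 1e-3, 1 - 1e-3)
            for _ in range(config.n_subpops)
        ])
    else:
        sub_freqs = np.tile(p_anc, (config.n_subpops, 1))

    labels = np.arange(n) % config.n_subpops
    hap_freqs = sub_freqs[np.repeat(labels, 2)]
    haps = _simulate_haplotypes(rng_hap, hap_freqs, 2 * n,
                                config.ld_block_size, config.ld_decay)
    dosage = (haps[0::2] + haps[1::2]).astype(float)

    if config.dosage_jitter_sd > 0:
        dosage = np.clip(dosage + rng_jit.normal(0, config.dosage_jitter_sd, dosage.shape),
                         0.0, 2.0)
    missing = np.zeros_like(dosage, dtype=bool)
    if config.missing_rate > 0:
        missing = rng_miss.random(dosage.shape) < config.missing_rate
        dosage[missing] = 0.0

    pair_idx = rng_meta.integers(0, len(_ALLELE_PAIRS), size=m)
    pos = 10_000 + 2_000 * np.arange(m)
    meta = pd.DataFrame({
        "id": [f"rs{j+1}" for j in range(m)],
        "chrom": "1",
        "pos": pos,
        "ref": [_ALLELE_PAIRS[k][0] for k in pair_idx],
        "alt": [_ALLELE_PAIRS[k][1] for k in pair_idx],
    })
    panel = GenotypePanel(
        sample_ids=[f"S{i+1:05d}" for i in range(n)],
        variant_meta=meta, dosage=dosage, missing_mask=missing,
    )

    n_causal = min(config.n_causal, m)
    causal_cols = np.sort(rng_w.choice(m, size=n_causal, replace=False))
    if config.true_weights is not None:
        w = np.asarray(config.true_weights, dtype=float)
        if w.size != n_causal:
            raise ValueError("true_weights length must equal n_causal")
    else:
        w = rng_w.normal(0.0, 0.15, size=n_causal)
        w[w == 0] = 0.15
    raw = np.zeros(n)
    for c, wj in zip(causal_cols, w):
        col = dosage[:, c].copy()
        if missing[:, c].any():
            mean = col[~missing[:, c]].mean()
            col[missing[:, c]] = mean
        raw += wj * col
    sd = raw.std()
    true_z = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)

    truth = SimulationTruth(
        causal_keys=[("1", int(pos[c])) for c in causal_cols],
        causal_weights=w,
        per_sd_log_or=float(np.log(config.per_sd_or)),
        subpop_labels=labels,
        true_prs_z=true_z,
    )
    return panel, truth


def simulate_phenotypes(panel: GenotypePanel, truth: SimulationTruth,
                        config: SimulationConfig) -> PhenotypeTable:
    """Draw Table-1-calibrated covariates and logistic case status.

    The linear predictor is alpha + log(per_sd_or) * zPRS_true + covariate
    effects on centered covariates; alpha is solved numerically so the
    expected case fraction matches the configured target.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[6])
    n = panel.n_samples
    cp = config.covariate_params
    age = rng.normal(*cp["age"], size=n)
    age = np.clip(age, 18.0, None)  # age > 0 invariant, adult cohort
    sex = (rng.random(n) < cp["male_fraction"]).astype(int)
    weight = np.clip(rng.normal(*cp["weight"], size=n), 35.0, None)
    t2dm = (rng.random(n) < cp["t2dm_prevalence"]).astype(int)
    smoking = (rng.random(n) < cp["smoking_prevalence"]).astype(int)
    sbp = np.clip(rng.normal(*cp["sbp"], size=n), 70.0, None)
    chol = np.clip(rng.normal(*cp["total_chol"], size=n), 80.0, None)

    eff = config.covariate_effects
    z = truth.true_prs_z if truth.true_prs_z is not None else np.zeros(n)
    eta = truth.per_sd_log_or * z
    covs = {"age": age, "sex": sex, "weight": weight, "t2dm": t2dm,
            "smoking": smoking, "sbp": sbp, "total_chol": chol}
    for name, beta in eff.items():
        x = covs[name].astype(float)
        eta = eta + beta * (x - x.mean())

    target = config.case_fraction
    lo, hi = -30.0, 30.0
    f = lambda a: expit(a + eta).mean() - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("unattainable case fraction")
    alpha = brentq(f, lo, hi, xtol=1e-12)
    case = (rng.random(n) < expit(alpha + eta)).astype(int)

    df = pd.DataFrame({
        "sample_id": panel.sample_ids,
        "case_status": case,
        "sex": sex,
        "age": age,
        "weight": weight,
        "t2dm": t2dm,
        "smoking": smoking,
        "sbp": sbp,
        "total_chol": chol,
    })
    return PhenotypeTable(df=df)


def emit_score_file(truth: SimulationTruth, panel: GenotypePanel,
                    corruption: dict | None = None, seed: int = 0,
                    path=None, pgs_id: str = "SIM000001"
                    ) -> tuple[ScoreSet, GenotypePanel]:
    """Write a scoring file for the true causal variants, optionally corrupted.

    ``corruption`` maps fraction names to values in [0, 1] summing to <= 1:

    * ``allele_switch`` — effect/other swapped with the weight re-expressed
      for the swapped effect allele (negated), so harmonization must reverse
      it to recover truth;
    * ``strand_flip`` — both alleles complemented, weight unchanged;
    * ``drop_with_proxy`` — the variant is deleted from the panel and an
      r2 = 1 duplicate dosage column is planted 1 kb away as its proxy.

    Returns the emitted ScoreSet and the (possibly modified) panel; the
    truth ledger records every action and planted proxy pair.
    """
    corruption = dict(corruption or {})
    fracs = {k: float(corruption.get(k, 0.0))
             for k in ("allele_switch", "strand_flip", "drop_with_proxy")}
    if sum(fracs.values()) > 1 + 1e-12:
        raise ValueError("corruption fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n_causal = len(truth.causal_keys)
    order = rng.permutation(n_causal)
    n_switch = int(round(fracs["allele_switch"] * n_causal))
    n_flip = int(round(fracs["strand_flip"] * n_causal))
    n_drop = int(round(fracs["drop_with_proxy"] * n_causal))
    switch_set = set(order[:n_switch])
    flip_set = set(order[n_switch:n_switch + n_flip])
    drop_set = set(order[n_switch + n_flip:n_switch + n_flip + n_drop])

    from prscad.harmonize import COMPLEMENT

    pos_idx = panel.position_index()
    meta = panel.variant_meta
    variants = []
    drop_cols = []
    proxy_rows = []
    for i, (key, w) in enumerate(zip(truth.causal_keys, truth.causal_weights)):
        col = pos_idx[key]
        row = meta.iloc[col]
        ref, alt = row["ref"], row["alt"]
        effect, other, weight = alt, ref, float(w)
        if i in switch_set:
            effect, other, weight = ref, alt, -float(w)
            truth.corruption_ledger.append((f"{key[0]}:{key[1]}", "allele_switch"))
        elif i in flip_set:
            effect, other = COMPLEMENT[alt], COMPLEMENT[ref]
            truth.corruption_ledger.append((f"{key[0]}:{key[1]}", "strand_flip"))
        elif i in drop_set:
            drop_cols.append(col)
            proxy_rows.append((col, key))
            truth.corruption_ledger.append((f"{key[0]}:{key[1]}", "drop_with_proxy"))
        variants.append(ScoreVariant(
            variant_id=f"{row['id']}",
            chrom=key[0], pos=key[1],
            effect_allele=effect, other_allele=other, weight=weight,
        ))

    if drop_cols:
        keep = np.ones(panel.n_variants, dtype=bool)
        keep[drop_cols] = False
        new_meta_rows = []
        new_dosage = []
        new_missing = []
        for col, key in proxy_rows:
            row = meta.iloc[col]
            proxy_pos = int(row["pos"]) + 1_000
            new_meta_rows.append((f"{row['id']}_proxy", row["chrom"], proxy_pos,
                                  row["ref"], row["alt"]))
            new_dosage.append(panel.dosage[:, col].copy())
            new_missing.append(panel.missing_mask[:, col].copy())
            truth.proxy_pairs.append((key, (str(row["chrom"]), proxy_pos), 1.0))
        meta_kept = meta.loc[keep].reset_index(drop=True)
        meta_new = pd.DataFrame(new_meta_rows, columns=["id", "chrom", "pos", "ref", "alt"])
        panel = GenotypePanel(
            sample_ids=list(panel.sample_ids),
            variant_meta=pd.concat([meta_kept, meta_new], ignore_index=True),
            dosage=np.column_stack([panel.dosage[:, keep]] + new_dosage),
            missing_mask=np.column_stack([panel.missing_mask[:, keep]] + new_missing),
        )

    scoreset = ScoreSet(pgs_id=pgs_id, variants=variants)
    if path is not None:
        write_score_file(scoreset, path)
    return scoreset, panel


def write_ld_tsv(truth: SimulationTruth, path) -> None:
    """Write the planted proxy pairs as an external LD reference TSV
    (chrom_a, pos_a, chrom_b, pos_b, r2), the format the pipeline accepts."""
    with open(path, "w") as fh:
        fh.write("chrom_a\tpos_a\tchrom_b\tpos_b\tr2\n")
        for (ca, pa), (cb, pb), r2 in truth.proxy_pairs:
            fh.write(f"{ca}\t{pa}\t{cb}\t{pb}\t{r2!r}\n")


def ld_reference_from_truth(truth: SimulationTruth, window_bp: int = 500_000):
    """LDReference over the planted proxy pairs (ground-truth linkage)."""
    from prscad.harmonize import LDReference
    pairs = {(tuple(a), tuple(b)): float(r2) for a, b, r2 in truth.proxy_pairs}
    return LDReference(pairs=pairs, window_bp=window_bp)


def emit_null_score_file(panel: GenotypePanel, truth: SimulationTruth,
                         n_variants: int = 20, seed: int = 0, path=None,
                         pgs_id: str = "SIMNULL01") -> ScoreSet:
    """A score over random non-causal panel variants with random weights.

    Used to emulate published scores unrelated to the planted disease
    signal; variants are drawn away from causal LD blocks.
    """
    rng = np.random.default_rng(seed)
    causal_pos = {k[1] for k in truth.causal_keys}
    meta = panel.variant_meta
    eligible = [j for j in range(panel.n_variants)
                if all(abs(int(meta["pos"][j]) - cp) > 20_000 for cp in causal_pos)]
    if len(eligible) < n_variants:
        raise ValueError("not enough non-causal variants for a null score")
    cols = np.sort(rng.choice(eligible, size=n_variants, replace=False))
    variants = []
    for j in cols:
        row = meta.iloc[int(j)]
        variants.append(ScoreVariant(
            variant_id=str(row["id"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            effect_allele=row["alt"], other_allele=row["ref"],
            weight=float(rng.normal(0, 0.15)),
        ))
    scoreset = ScoreSet(pgs_id=pgs_id, variants=variants)
    if path is not None:
        write_score_file(scoreset, path)
    return scoreset
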