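"""Genotype PCA and Tracy-Widom selection of significant components.

Genotypes are normalized per variant by the estimated allele frequency
(center by 2*p_hat, scale by sqrt(p_hat*(1-p_hat))), the standard
eigenanalysis normalization under which, absent structure, the leading
eigenvalue of the sample covariance follows a Tracy-Widom (GOE, TW1) law
after moment-based standardization.  Components are declared significant
one at a time: the leading remaining eigenvalue is standardized using an
effective-marker-count estimator and compared with the TW1 (1 - alpha)
quantile; testing stops at the first non-significant eigenvalue.

The TW1 distribution is evaluated from an embedded CDF table (computed
numerically from the Painleve II representation of the Tracy-Widom laws)
with monotone linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from prscad.data_io import GenotypePanel

# TW1 (GOE) CDF on a uniform grid, from the Painleve II / Hastings-McLeod
# representation: F1(s) = exp(-(I(s) + J(s))/2) with I = int_s^inf q,
# J = int_s^inf (x - s) q^2, q'' = s q + 2 q^3, q ~ Ai at +inf.
TW1_S = np.arange(-6.0, 4.51, 0.1)
TW1_CDF = np.array([
    2.70304404e-06, 4.59335046e-06, 7.68485272e-06, 1.26617398e-05, 2.05504122e-05, 3.28648009e-05,
    5.18007872e-05, 8.04908376e-05, 1.23330325e-04, 1.86386459e-04, 2.77898977e-04, 4.08878440e-04,
    5.93802922e-04, 8.51406953e-04, 1.20554782e-03, 1.68612403e-03, 2.33000944e-03, 3.18195496e-03,
    4.29539889e-03, 5.73311816e-03, 7.56764674e-03, 9.88138617e-03, 1.27663369e-02, 1.63233888e-02,
    2.06611250e-02, 2.58941148e-02, 3.21406980e-02, 3.95202916e-02, 4.81502830e-02, 5.81426017e-02,
    6.96000898e-02, 8.26128148e-02, 9.72544778e-02, 1.13579082e-01, 1.31618018e-01, 1.51377705e-01,
    1.72837924e-01, 1.95950912e-01, 2.20641296e-01, 2.46806866e-01, 2.74320179e-01, 3.03030921e-01,
    3.32768947e-01, 3.63347862e-01, 3.94569024e-01, 4.26225788e-01, 4.58107863e-01, 4.90005605e-01,
    5.21714119e-01, 5.53037039e-01, 5.83789886e-01, 6.13802926e-01, 6.42923470e-01, 6.71017601e-01,
    6.97971304e-01, 7.23691045e-01, 7.48103815e-01, 7.71156694e-01, 7.92816009e-01, 8.13066142e-01,
    8.31908062e-01, 8.49357667e-01, 8.65443979e-01, 8.80207289e-01, 8.93697277e-01, 9.05971181e-01,
    9.17092045e-01, 9.27127074e-01, 9.36146139e-01, 9.44220421e-01, 9.51421236e-01, 9.57819007e-01,
    9.63482417e-01, 9.68477715e-01, 9.72868167e-01, 9.76713648e-01, 9.80070359e-01, 9.82990650e-01,
    9.85522938e-01, 9.87711707e-01, 9.89597571e-01, 9.91217395e-01, 9.92604453e-01, 9.93788616e-01,
    9.94796566e-01, 9.95652023e-01, 9.96375968e-01, 9.96986886e-01, 9.97500982e-01, 9.97932410e-01,
    9.98293480e-01, 9.98594857e-01, 9.98845745e-01, 9.99054055e-01, 9.99226569e-01, 9.99369073e-01,
    9.99486492e-01, 9.99583001e-01, 9.99662129e-01, 9.99726848e-01, 9.99779656e-01, 9.99822641e-01,
    9.99857548e-01, 9.99885830e-01, 9.99908692e-01, 9.99927129e-01,
])


def tw1_cdf(x) -> np.ndarray:
    """TW1 cumulative distribution, interpolated from the embedded table."""
    return np.interp(x, TW1_S, TW1_CDF, left=0.0, right=1.0)


def tw1_quantile(p: float) -> float:
    """Inverse TW1 CDF by interpolation (valid for p within table coverage)."""
    if not 0 < p < 1:
        raise ValueError("quantile level must be in (0, 1)")
    return float(np.interp(p, TW1_CDF, TW1_S))


def tw1_sf(x) -> np.ndarray:
    return 1.0 - tw1_cdf(x)


@dataclass
class PCResult:
    eigenvalues: np.ndarray          # descending, length k
    pc_coords: np.ndarray            # samples x k, eigenvector * sqrt(eigenvalue)
    tw_stats: np.ndarray             # standardized TW1 statistic per eigenvalue
    n_significant: int
    alpha: float

    def coords_tsv(self, sample_ids, path) -> None:
        k = self.pc_coords.shape[1]
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(f"PC{j+1}" for j in range(k)) + "\n")
            for i, sid in enumerate(sample_ids):
                fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in self.pc_coords[i]) + "\n")


def normalize_genotypes(panel: GenotypePanel) -> np.ndarray:
    """Frequency-normalize the dosage matrix for eigenanalysis.

    Missing cells are mean-imputed; each column is centered by 2*p_hat and
    scaled by its binomial genotype SD sqrt(2*p_hat*(1-p_hat)) with
    p_hat = mean dosage / 2, giving unit variance per column under
    Hardy-Weinberg proportions.  Monomorphic columns (p_hat in {0, 1}) are
    removed.  (The haploid-SD convention differs only by a global factor
    and leaves PC directions and Tracy-Widom statistics unchanged.)
    """
    G = panel.dosage.astype(float).copy()
    miss = panel.missing_mask
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("normalize_genotypes: fully-missing variant column")
    col_mean = np.where(miss, 0.0, G).sum(axis=0) / n_obs
    G = np.where(miss, col_mean[None, :], G)
    p_hat = col_mean / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if not poly.any():
        raise ValueError("normalize_genotypes: all columns monomorphic")
    G = G[:, poly]
    p = p_hat[poly]
    return (G - 2 * p) / np.sqrt(2 * p * (1 - p))


def compute_pcs(X: np.ndarray, k_max: int) -> PCResult:
    """Top-``k_max`` eigenpairs of the samples-by-samples covariance of ``X``.

    Coordinates follow the eigenvector * sqrt(eigenvalue) convention; each
    component's sign is fixed so its largest-magnitude loading is positive.
    Tracy-Widom statistics and the significant count are filled in by
    :func:`tracy_widom_select` (here initialized with all eigenvalues and
    n_significant = 0 at alpha = NaN).
    """
    n, m = X.shape
    if n < 3:
        raise ValueError("compute_pcs: need >= 3 samples")
    if not 1 <= k_max < min(n, m):
        raise ValueError("compute_pcs: require 1 <= k_max < min(n_samples, n_variants)")
    C = (X @ X.T) / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    if not np.all(np.isfinite(evals)):
        raise np.linalg.LinAlgError(
            f"eigendecomposition failed; cond ~ {np.linalg.cond(C):.3e}")
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    top = evals[:k_max]
    V = evecs[:, :k_max]
    for j in range(k_max):
        i_max = np.argmax(np.abs(V[:, j]))
        if V[i_max, j] < 0:
            V[:, j] = -V[:, j]
    coords = V * np.sqrt(top)[None, :]
    return PCResult(eigenvalues=evals, pc_coords=coords,
                    tw_stats=np.full(evals.shape, np.nan),
                    n_significant=0, alpha=float("nan"))


def tracy_widom_statistics(eigenvalues: np.ndarray) -> np.ndarray:
    """Standardized TW1 statistic for each leading eigenvalue in turn.

    For the i-th test the tail eigenvalues lambda_i..lambda_{M} (positive
    part) play the role of an M_i-dimensional white Wishart spectrum; the
    effective number of independent markers is estimated by moment matching
    of the first two Wishart spectral moments (E[tr A] = M*p and
    E[tr A^2] = M*p*(M + p + 1) for A ~ W_p(M)),

        n_eff = (M + 1) * S1^2 / (M * S2 - S1^2),

    with S1, S2 the tail sum and sum of squares, and the leading tail
    eigenvalue is location-scale standardized by the Johnstone constants.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 1:
        raise ValueError("need at least one eigenvalue")
    tol = 1e-10 * max(ev.max(), 1.0)
    ev = ev[ev > tol]
    stats = np.full(len(ev), np.nan)
    for i in range(len(ev)):
        tail = ev[i:]
        M = tail.size
        if M < 3:
            break
        S1 = tail.sum()
        S2 = (tail ** 2).sum()
        denom = M * S2 - S1 ** 2
        if denom <= 0:
            break
        n_eff = (M + 1) * S1 ** 2 / denom
        if n_eff <= 1:
            break
        ell = M * tail[0] / S1
        a, b = np.sqrt(n_eff - 1), np.sqrt(M)
        mu = (a + b) ** 2 / n_eff
        sigma = (a + b) / n_eff * (1 / a + 1 / b) ** (1 / 3)
        stats[i] = (ell - mu) / sigma
    return stats


def tracy_widom_select(eigenvalues: np.ndarray, n_samples: int, n_variants: int,
                       alpha: float = 0.05, k_cap: int = 15) -> tuple[int, np.ndarray]:
    """Count significant PCs by sequential Tracy-Widom testing.

    Tests the leading remaining eigenvalue against the TW1 (1 - alpha)
    quantile and stops at the first non-significant one; the count is capped
    at ``k_cap`` (15 by default, the conventional covariate budget).
    Returns (n_significant, tw_stats).
    """
    if n_samples <= 1 or n_variants <= 1:
        raise ValueError("need n_samples > 1 and n_variants > 1")
    stats = tracy_widom_statistics(eigenvalues)
    threshold = tw1_quantile(1.0 - alpha)
    n_sig = 0
    for s in stats:
        if not np.isfinite(s) or s <= threshold:
            break
        n_sig += 1
        if n_sig >= k_cap:
            break
    return n_sig, stats


def pca_with_tw(panel: GenotypePanel, k_max: int = 20, alpha: float = 0.05,
                k_cap: int = 15) -> PCResult:
    """Normalize, decompose, and select significant PCs in one call."""
    X = normalize_genotypes(panel)
    k_max = min(k_max, min(X.shape) - 1)
    res = compute_pcs(X, k_max)
    n_sig, stats = tracy_widom_select(res.eigenvalues, X.shape[0], X.shape[1],
                                      alpha=alpha, k_cap=k_cap)
    return PCResult(eigenvalues=res.eigenvalues, pc_coords=res.pc_coords,
                    tw_stats=stats, n_significant=n_sig, alpha=alpha)
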