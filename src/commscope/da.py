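"""Two-group differential abundance on read-count tables.

Per-feature testing of treatment vs control replicates under a
negative-binomial model with a common dispersion: library-composition
normalization by trimmed mean of M-values (TMM), an exact conditional
test on group pseudo-count sums, and Benjamini-Hochberg FDR control.
This is a from-scratch TMM + common-dispersion exact test; a precomputed
(feature, logFC, p, q) table can be injected instead wherever the
pipeline consumes DA output, so results from other DA tools can be used
verbatim.

Model
-----
Counts for feature f in sample j are NB with mean mu_fj proportional to
the effective library size and variance mu + phi * mu^2 (phi = common
dispersion).  After normalizing samples to a common effective library
size, the group sums (y_A, y_B) are compared conditional on their total:
under the null of equal means the probability of each split is the
product of two NB masses, and the p-value sums the probabilities of all
splits at most as likely as the observed one.
"""

from __future__ import annotations

import logging
import os
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountTable, UNASSIGNED

logger = logging.getLogger(__name__)

DA_COLUMNS = ["feature", "log2_fold_change", "p_value", "q_value", "direction", "significant"]


def tmm_factors(
    table: CountTable | pd.DataFrame,
    *,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference is the sample whose library size is closest to the mean
    library size.  For each sample, M (log-ratio) and A (log-abundance)
    values are computed over features positive in both the sample and the
    reference; the most extreme 30% of M and 5% of A are trimmed and the
    remaining M-values averaged with inverse delta-method-variance
    weights.
    """
    mat = table.matrix if isinstance(table, CountTable) else table
    mat = mat[mat.index != UNASSIGNED]
    counts = mat.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = counts.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"all-zero sample(s): {list(mat.columns[zero])}")
    ref = int(np.argmin(np.abs(lib - lib.mean())))
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref], lib[j], lib[ref], logratio_trim, sum_trim
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, sum_trim) -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    obs, ref = obs[ok], ref[ok]
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M (delta method on two binomial proportions)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.allclose(m, m[0]):
        return float(2.0 ** m[0])
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def estimate_common_dispersion(pseudo: np.ndarray, groups: list[np.ndarray]) -> float:
    """Pooled method-of-moments NB dispersion across features.

    Within-group sample means and variances are combined over all
    features by regression through the origin of the excess variance
    (s^2 - m) on m^2, which is unbiased under variance = m + phi * m^2
    and robust to features with low means.
    """
    num = den = 0.0
    for idx in groups:
        sub = pseudo[:, idx]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += np.sum(s2 - m)
        den += np.sum(m**2)
    if den <= 0:
        return 0.0
    return float(max(0.0, num / den))


def _nb_exact_pvalue(ya: int, yb: int, na: int, nb: int, phi: float) -> float:
    """Exact conditional two-sided p for group sums under a common-phi NB."""
    t = ya + yb
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(k, t, na / (na + nb))
    else:
        mu = t / (na + nb)  # per-sample mean under the null
        ra, rb = na / phi, nb / phi
        pa = ra / (ra + na * mu)
        pb = rb / (rb + nb * mu)
        logp = stats.nbinom.logpmf(k, ra, pa) + stats.nbinom.logpmf(t - k, rb, pb)
    logp -= np.max(logp)
    p = np.exp(logp)
    p /= p.sum()
    obs = p[ya]
    return float(min(1.0, p[p <= obs * (1 + 1e-10)].sum()))


def exact_nb_test(
    table: CountTable,
    group_a: str,
    group_b: str,
    *,
    dispersion: Literal["auto"] | float = "auto",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact NB test of ``group_a`` vs ``group_b`` per feature, with BH FDR.

    Requires >= 2 replicates per group (no dispersion is estimable
    otherwise).  Counts are converted to pseudo-counts at a common
    effective library size (TMM-normalized), group sums are tested
    exactly, and q-values come from Benjamini-Hochberg.  Positive
    log2 fold changes mean enrichment in ``group_a``; when one group sum
    is zero a pseudo-count of 0.5 enters the fold-change ratio only.
    """
    sa = table.samples_of(group_a)
    sb = table.samples_of(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"each group needs >=2 replicates (got {group_a}: {len(sa)}, {group_b}: {len(sb)})"
        )
    mat = table.matrix[mat_cols := sa + sb]
    mat = mat[mat.index != UNASSIGNED]
    mat = mat[mat.sum(axis=1) > 0]
    factors = tmm_factors(CountTable(table.key_scheme, table.matrix[mat_cols], table.design))
    lib = table.matrix[mat_cols].drop(index=UNASSIGNED, errors="ignore").sum(axis=0).to_numpy(float)
    eff = lib * factors.to_numpy()
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = mat.to_numpy(float) * (common / eff)

    na, nb = len(sa), len(sb)
    ia, ib = np.arange(na), np.arange(na, na + nb)
    if dispersion == "auto":
        phi = estimate_common_dispersion(pseudo, [ia, ib])
        logger.info("common dispersion (method of moments): %.4g", phi)
    else:
        phi = float(dispersion)

    sum_a = np.rint(pseudo[:, ia].sum(axis=1)).astype(int)
    sum_b = np.rint(pseudo[:, ib].sum(axis=1)).astype(int)
    pvals = np.array(
        [_nb_exact_pvalue(ya, yb, na, nb, phi) for ya, yb in zip(sum_a, sum_b)]
    )
    mean_a = pseudo[:, ia].sum(axis=1) / na
    mean_b = pseudo[:, ib].sum(axis=1) / nb
    prior = np.where((mean_a == 0) | (mean_b == 0), 0.5, 0.0)
    lfc = np.log2((mean_a + prior) / (mean_b + prior))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "feature": mat.index,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "q_value": qvals,
            "direction": np.where(lfc >= 0, "treatment-enriched", "control-enriched"),
            "significant": qvals <= alpha,
        }
    )
    return out.sort_values(["q_value", "p_value"], ignore_index=True)


def significant_features(results: pd.DataFrame) -> set[str]:
    return set(results.loc[results["significant"], "feature"])


def read_precomputed(path: str | os.PathLike, alpha: float = 0.05) -> pd.DataFrame:
    """Load an externally produced DA table (feature, logFC, p, q)."""
    df = pd.read_csv(path, sep="\t")
    rename = {"logFC": "log2_fold_change", "p": "p_value", "q": "q_value",
              "PValue": "p_value", "FDR": "q_value"}
    df = df.rename(columns=rename)
    for col in ("feature", "log2_fold_change", "p_value", "q_value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    df["direction"] = np.where(
        df["log2_fold_change"] >= 0, "treatment-enriched", "control-enriched"
    )
    df["significant"] = df["q_value"] <= alpha
    return df[DA_COLUMNS]
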