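"""Poly(A)-site-level differential abundance.

Treats each poly(A) site as the counting unit and tests depleted vs
control with a conditional negative-binomial exact test on group sums,
after trimmed-mean-of-M-values (TMM) library normalization and a pooled
method-of-moments dispersion estimate.  Sites are called differential at
FDR <= 0.05 with |log2FC| > 1 (both thresholds adjustable).

The exact test conditions on the per-site total after equalizing
effective library sizes: at dispersion phi = 0 the conditional law is
exactly binomial in the group-1 share; at phi > 0 the conditional
probabilities are products of negative-binomial mass functions for the
two group sums, renormalized over all splits of the total.  Two-sided
p-values sum the probability of every split at most as likely as the one
observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .pasquant import PASCountMatrix


def tmm_factors(
    matrix: PASCountMatrix | pd.DataFrame,
    ref: str | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed mean of M-values normalization factors.

    M-values (log2 relative abundance vs the reference sample) are
    trimmed by 30% on each side, A-values (mean log2 abundance) by 5%,
    and the surviving M-values averaged with inverse-variance (binomial
    precision) weights.  The reference defaults to the sample whose
    upper-quartile count fraction is closest to the mean upper quartile.
    Factors are anchored so their geometric mean is 1.
    """
    counts = matrix.counts if isinstance(matrix, PASCountMatrix) else matrix
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    if ref is None:
        expressed = counts.loc[(counts > 0).any(axis=1)]
        uq = expressed.div(lib, axis=1).quantile(0.75)
        ref = (uq - uq.mean()).abs().idxmin()

    y_r = counts[ref].to_numpy(float)
    n_r = float(lib[ref])
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        y_k = counts[s].to_numpy(float)
        n_k = float(lib[s])
        use = (y_k > 0) & (y_r > 0)
        yk, yr = y_k[use], y_r[use]
        m = np.log2((yk / n_k) / (yr / n_r))
        a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
        w = (n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr)
        if len(m) == 0:
            factors[s] = 1.0
            continue
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            factors[s] = 1.0
        else:
            factors[s] = float(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.mean(np.log(f)))  # geometric-mean anchor
    return f


def effective_lib_sizes(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    return counts.sum(axis=0).astype(float) * factors


def estimate_dispersion(
    matrix: PASCountMatrix | pd.DataFrame, groups: pd.Series | dict
) -> float:
    """Pooled method-of-moments NB dispersion on normalized counts.

    Within each group with >= 2 replicates, per-site sample mean m and
    variance v satisfy E[v] ~ m + phi*m^2 under the NB model; phi is
    estimated as sum(v - m) / sum(m^2) pooled over sites and groups,
    floored at 0.
    """
    counts = matrix.counts if isinstance(matrix, PASCountMatrix) else matrix
    groups = pd.Series(groups)
    factors = tmm_factors(counts)
    eff = effective_lib_sizes(counts, factors)
    scale = eff / eff.mean()
    norm = counts.div(scale, axis=1)

    num = den = 0.0
    replicated = False
    for g in groups.unique():
        cols = groups.index[groups == g]
        if len(cols) < 2:
            continue
        replicated = True
        sub = norm[cols].to_numpy(float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        use = m > 0
        num += float(np.sum(v[use] - m[use]))
        den += float(np.sum(m[use] ** 2))
    if not replicated:
        raise ValueError("no group has >= 2 replicates")
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_log_pmf(total: int, mu1: float, mu2: float, r1: float, r2: float):
    """log P(Y1 = x | Y1 + Y2 = total) for x = 0..total, NB group sums."""
    x = np.arange(total + 1)
    if np.isfinite(r1):  # NB mass (unnormalized, common terms dropped later)
        lp1 = gammaln(x + r1) - gammaln(x + 1) + x * np.log(mu1 / (mu1 + r1))
        lp2 = (
            gammaln(total - x + r2)
            - gammaln(total - x + 1)
            + (total - x) * np.log(mu2 / (mu2 + r2))
        )
    else:  # Poisson limit
        lp1 = x * np.log(mu1) - gammaln(x + 1)
        lp2 = (total - x) * np.log(mu2) - gammaln(total - x + 1)
    lp = lp1 + lp2
    return lp - logsumexp(lp)


def nb_exact_test(
    counts1: np.ndarray,
    counts2: np.ndarray,
    phi: float,
    eff_lib1: np.ndarray,
    eff_lib2: np.ndarray,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Two-sided conditional exact test on group sums for one site.

    Returns (log2FC of group 2 vs group 1 from normalized means, p).
    At phi = 0 this is the exact binomial split test conditioning on the
    total, with success probability the group-2 share of effective
    library size.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    y1, y2 = float(np.sum(counts1)), float(np.sum(counts2))
    N1, N2 = float(np.sum(eff_lib1)), float(np.sum(eff_lib2))
    mean_lib = (N1 + N2) / (len(eff_lib1) + len(eff_lib2))
    m1 = np.mean(np.asarray(counts1, float) / np.asarray(eff_lib1, float)) * mean_lib
    m2 = np.mean(np.asarray(counts2, float) / np.asarray(eff_lib2, float)) * mean_lib
    log2fc = float(np.log2((m2 + pseudocount) / (m1 + pseudocount)))

    total = int(round(y1 + y2))
    if total == 0:
        return 0.0, 1.0
    lam = total / (N1 + N2)
    mu1, mu2 = lam * N1, lam * N2
    n1, n2 = len(np.atleast_1d(counts1)), len(np.atleast_1d(counts2))
    r1 = n1 / phi if phi > 0 else np.inf
    r2 = n2 / phi if phi > 0 else np.inf
    lp = _conditional_log_pmf(total, mu1, mu2, r1, r2)
    obs = int(round(y1))
    # two-sided: total mass of outcomes no more likely than the observed one
    p = float(np.exp(logsumexp(lp[lp <= lp[obs] + 1e-12])))
    return log2fc, min(1.0, p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, capped at 1."""
    p = np.asarray(pvalues, float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # index pas_id: log2FC, pvalue, fdr, call (+ class)
    factors: pd.Series
    lib_sizes: pd.Series

    def n_called(self) -> int:
        return int((self.table["call"] != "ns").sum())


def call_differential(
    matrix: PASCountMatrix,
    contrast: tuple[str, str],
    fdr: float = 0.05,
    lfc: float = 1.0,
    phi: float | None = None,
    condition_col: str = "condition",
) -> DifferentialResult:
    """Full differential pipeline: TMM -> dispersion -> exact test -> BH.

    ``contrast`` is (control, depleted); log2FC is depleted over control.
    ``call`` is 'up' when FDR <= fdr and log2FC > lfc, 'down' when
    FDR <= fdr and log2FC < -lfc, else 'ns'.
    """
    ctrl, depl = contrast
    meta = matrix.samples
    for level in contrast:
        if level not in set(meta[condition_col]):
            raise ValueError(f"unknown contrast level {level!r}")
    cols1 = meta.index[meta[condition_col] == ctrl]
    cols2 = meta.index[meta[condition_col] == depl]
    counts = matrix.counts[list(cols1) + list(cols2)]
    factors = tmm_factors(counts)
    eff = effective_lib_sizes(counts, factors)
    if phi is None:
        grp = pd.Series(
            [ctrl] * len(cols1) + [depl] * len(cols2), index=counts.columns
        )
        phi = estimate_dispersion(counts, grp)

    e1 = eff[cols1].to_numpy()
    e2 = eff[cols2].to_numpy()
    c1 = matrix.counts[cols1].to_numpy()
    c2 = matrix.counts[cols2].to_numpy()
    res = [
        nb_exact_test(c1[i], c2[i], phi, e1, e2) for i in range(len(counts))
    ]
    log2fc = np.array([r[0] for r in res])
    pvals = np.array([r[1] for r in res])
    fdrs = bh_adjust(pvals)
    call = np.where(
        (fdrs <= fdr) & (log2fc > lfc),
        "up",
        np.where((fdrs <= fdr) & (log2fc < -lfc), "down", "ns"),
    )
    table = pd.DataFrame(
        {"log2FC": log2fc, "pvalue": pvals, "fdr": fdrs, "call": call},
        index=matrix.counts.index,
    )
    if matrix.site_info is not None and "pas_class" in matrix.site_info:
        table.insert(0, "pas_class", matrix.site_info["pas_class"])
    return DifferentialResult(table, factors, counts.sum(axis=0))
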