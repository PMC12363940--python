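"""Class-level nucleus/cytoplasm statistics.

Summarises depletion responses per poly(A)-site class (terminal, IPA,
PROMPT) and per compartment: per-site log2 fold changes on normalized
means, Mann-Whitney comparisons of the cytoplasmic vs nuclear response
distributions, cytoplasm/nucleus abundance ratios, and delta-delta-Ct
quantification for reporter qPCR.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import effective_lib_sizes, tmm_factors
from .pasquant import PASCountMatrix

EXACT_MAX_N = 16  # enumerate the U distribution up to C(16,8)=12870 splits


def _norm_means(
    matrix: PASCountMatrix, cols: pd.Index, all_cols: pd.Index
) -> pd.Series:
    factors = tmm_factors(matrix.counts[list(all_cols)])
    eff = effective_lib_sizes(matrix.counts[list(all_cols)], factors)
    scale = eff / eff.mean()
    return matrix.counts[list(cols)].div(scale[list(cols)], axis=1).mean(axis=1)


def compute_log2fc(
    matrix: PASCountMatrix,
    contrast: tuple[str, str],
    pseudocount: float = 0.5,
    condition_col: str = "condition",
    compartment_col: str = "compartment",
) -> pd.DataFrame:
    """Per-site log2FC (depleted vs control) within each compartment.

    Counts are TMM-normalized within the compartment; per-condition means
    get a pseudocount before the log ratio so zero counts stay finite.
    Returns a long table: pas_id, pas_class, compartment, log2FC.
    """
    ctrl, depl = contrast
    meta = matrix.samples
    rows = []
    for comp in meta[compartment_col].unique():
        sub = meta.index[meta[compartment_col] == comp]
        c_ctrl = sub[meta.loc[sub, condition_col] == ctrl]
        c_depl = sub[meta.loc[sub, condition_col] == depl]
        if len(c_ctrl) == 0 or len(c_depl) == 0:
            continue  # compartment lacks one condition; skipped
        m_ctrl = _norm_means(matrix, c_ctrl, sub)
        m_depl = _norm_means(matrix, c_depl, sub)
        lfc = np.log2((m_depl + pseudocount) / (m_ctrl + pseudocount))
        classes = (
            matrix.site_info["pas_class"]
            if matrix.site_info is not None
            else pd.Series("other", index=matrix.counts.index)
        )
        for pid, v in lfc.items():
            rows.append(
                dict(pas_id=pid, pas_class=classes[pid], compartment=comp,
                     log2FC=float(v))
            )
    return pd.DataFrame(rows)


def _u_statistic(ranks_x: np.ndarray, n: int, m: int) -> float:
    return float(ranks_x.sum() - n * (n + 1) / 2)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (of x) with a two-sided p-value.

    For n + m <= 16 the permutation distribution of U is enumerated
    exactly over all C(n+m, n) splits of the pooled mid-ranks, so ties
    are handled without approximation.  Larger samples use the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n], n, m)

    if n + m <= EXACT_MAX_N:
        mu = n * m / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = comb(n + m, n)
        for idx in combinations(range(n + m), n):
            u = float(ranks[list(idx)].sum() - n * (n + 1) / 2)
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return u_obs, hits / total

    mu = n * m / 2.0
    tie_counts = np.unique(pooled, return_counts=True)[1]
    nm = n + m
    tie_term = np.sum(tie_counts**3 - tie_counts) / (nm * (nm - 1))
    sigma2 = n * m / 12.0 * (nm + 1 - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return u_obs, float(2 * stats.norm.sf(z))


def class_compartment_tests(
    lfc_table: pd.DataFrame,
    classes: tuple[str, ...] = ("terminal", "IPA", "PROMPT"),
    nucleus: str = "nucleus",
    cytoplasm: str = "cytoplasm",
) -> pd.DataFrame:
    """Per class: median log2FC per compartment and the Mann-Whitney
    p-value comparing cytoplasmic vs nuclear per-site responses."""
    rows = []
    for cls in classes:
        sub = lfc_table[lfc_table["pas_class"] == cls]
        nuc = sub.loc[sub["compartment"] == nucleus, "log2FC"].to_numpy()
        cyt = sub.loc[sub["compartment"] == cytoplasm, "log2FC"].to_numpy()
        if len(nuc) == 0 or len(cyt) == 0:
            continue
        _, p = mann_whitney(cyt, nuc)
        rows.append(
            dict(
                pas_class=cls,
                n_sites=len(sub["pas_id"].unique()),
                median_lfc_nucleus=float(np.median(nuc)),
                median_lfc_cytoplasm=float(np.median(cyt)),
                mw_pvalue=p,
            )
        )
    return pd.DataFrame(rows).set_index("pas_class")


def cyto_nuc_ratio(
    cyto_norm: float, nuc_norm: float, pseudocount: float = 0.5
) -> tuple[float, float]:
    """Cytoplasm/nucleus abundance ratio and its log2, pseudocount-guarded."""
    ratio = (cyto_norm + pseudocount) / (nuc_norm + pseudocount)
    return float(ratio), float(np.log2(ratio))


def cyto_nuc_ratios(
    matrix: PASCountMatrix,
    condition: str,
    pseudocount: float = 0.5,
    nucleus: str = "nucleus",
    cytoplasm: str = "cytoplasm",
) -> pd.DataFrame:
    """Per-site cytoplasm/nucleus ratios within one condition."""
    meta = matrix.samples
    sub = meta.index[meta["condition"] == condition]
    c_nuc = sub[meta.loc[sub, "compartment"] == nucleus]
    c_cyt = sub[meta.loc[sub, "compartment"] == cytoplasm]
    m_nuc = _norm_means(matrix, c_nuc, sub)
    m_cyt = _norm_means(matrix, c_cyt, sub)
    ratio = (m_cyt + pseudocount) / (m_nuc + pseudocount)
    out = pd.DataFrame(
        {"ratio": ratio, "log2_ratio": np.log2(ratio)}, index=matrix.counts.index
    )
    if matrix.site_info is not None:
        out.insert(0, "pas_class", matrix.site_info["pas_class"])
    return out


def delta_delta_ct(
    ct_target_a: float, ct_ref_a: float, ct_target_b: float, ct_ref_b: float
) -> float:
    """Relative abundance of condition b vs a by the delta-delta-Ct rule:
    2^-((Ct_target_b - Ct_ref_b) - (Ct_target_a - Ct_ref_a))."""
    vals = (ct_target_a, ct_ref_a, ct_target_b, ct_ref_b)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_b - ct_ref_b) - (ct_target_a - ct_ref_a)
    return float(2.0**-ddct)
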