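"""CRISPR-screen and mass-spec hit selection and overlap.

Consumes a MAGeCK-style gene summary (gene + FDR + enrichment score) and
mass-spec percent-coverage tables, applies the hit filters (top-n genes
by FDR; fold enrichment of coverage >= threshold, optionally required in
every replicate), and intersects the resulting gene sets.  Symbols are
matched exactly after uppercasing and whitespace stripping; no alias or
ortholog mapping is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)


def normalize_symbol(sym: str) -> str:
    return str(sym).strip().upper()


def read_screen_table(
    path, gene_col: str = "id", fdr_col: str = "pos|fdr", score_col: str = "pos|score"
) -> pd.DataFrame:
    """Read a MAGeCK gene_summary-style TSV into gene/fdr/score columns."""
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(
        {
            "gene": df[gene_col].map(normalize_symbol),
            "fdr": df[fdr_col].astype(float),
            "score": df[score_col].astype(float) if score_col in df else 0.0,
        }
    )
    if ((out["fdr"] < 0) | (out["fdr"] > 1)).any():
        raise ValueError("FDR values outside [0, 1]")
    return out


def select_top_hits(table: pd.DataFrame, n: int = 200) -> set[str]:
    """The n genes with smallest FDR.

    Boundary ties on FDR are broken by enrichment score (higher first)
    then symbol order, with a warning, so the set is deterministic.
    """
    if table.empty:
        raise ValueError("empty screen table")
    df = table.copy()
    df["gene"] = df["gene"].map(normalize_symbol)
    if n > len(df):
        warnings.warn(f"requested top {n} of {len(df)} genes; returning all")
        return set(df["gene"])
    score = df["score"] if "score" in df else pd.Series(0.0, index=df.index)
    df = df.assign(_score=-score).sort_values(["fdr", "_score", "gene"])
    cut_fdr = df["fdr"].iloc[n - 1]
    if n < len(df) and df["fdr"].iloc[n] == cut_fdr:
        warnings.warn(f"FDR tie at the top-{n} boundary (FDR={cut_fdr}); "
                      "broken by score then symbol")
    return set(df["gene"].iloc[:n])


def fold_enrichment(
    ms: pd.DataFrame,
    num_cond: str | list[str],
    den_cond: str | list[str],
    pseudocount: float = 1.0,
    gene_col: str = "gene",
) -> pd.DataFrame:
    """Per-protein coverage fold enrichment, per replicate when present.

    ``num_cond``/``den_cond`` name coverage columns (one per replicate;
    paired by position when lists).  Proteins absent in a condition count
    as coverage 0; the pseudocount (percentage points) keeps zero
    denominators finite.
    """
    num_cols = [num_cond] if isinstance(num_cond, str) else list(num_cond)
    den_cols = [den_cond] if isinstance(den_cond, str) else list(den_cond)
    if len(num_cols) != len(den_cols):
        raise ValueError("condition column lists must pair up")
    df = ms.copy()
    df[gene_col] = df[gene_col].map(normalize_symbol)
    out = pd.DataFrame({"gene": df[gene_col]})
    for i, (nc, dc) in enumerate(zip(num_cols, den_cols), 1):
        num = df[nc].fillna(0.0).astype(float)
        den = df[dc].fillna(0.0).astype(float)
        out[f"FE_rep{i}" if len(num_cols) > 1 else "FE"] = (num + pseudocount) / (
            den + pseudocount
        )
    return out


def filter_enriched(
    fe: pd.DataFrame, threshold: float = 1.5, mode: str = "all-replicates"
) -> set[str]:
    """Proteins whose fold enrichment passes the threshold (inclusive).

    mode 'all-replicates': FE >= threshold in every replicate column;
    mode 'any': in at least one.
    """
    fe_cols = [c for c in fe.columns if c.startswith("FE")]
    if not fe_cols:
        return set()
    passing = fe[fe_cols] >= threshold
    if mode == "all-replicates":
        keep = passing.all(axis=1)
    elif mode == "any":
        keep = passing.any(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return set(fe.loc[keep, "gene"].map(normalize_symbol))


@dataclass
class OverlapReport:
    shared: set[str]
    only_a: set[str]
    only_b: set[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [("shared", g) for g in sorted(self.shared)]
        rows += [("only_a", g) for g in sorted(self.only_a)]
        rows += [("only_b", g) for g in sorted(self.only_b)]
        return pd.DataFrame(rows, columns=["region", "gene"])


def intersect_sets(a: set[str], b: set[str]) -> OverlapReport:
    """Exact symbol intersection after normalization, with a Venn report."""
    a = {normalize_symbol(g) for g in a}
    b = {normalize_symbol(g) for g in b}
    return OverlapReport(shared=a & b, only_a=a - b, only_b=b - a)
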