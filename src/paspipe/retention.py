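"""Intron retention from junction counts.

Retention of an intron is summarised as PSI, the fraction of transcripts
keeping the intron, estimated from the two exon-intron boundary counts
(I1, I2) and the spliced exon-exon junction count (S):

    PSI = ((I1 + I2) / 2) / ((I1 + I2) / 2 + S)

Nucleus-vs-cytoplasm shifts are tested per intron with Fisher's exact
test on pooled replicate counts, and positional bias of significant
introns (the last-intron enrichment seen when nuclear retention is lost)
with an exact binomial test against the background last-intron fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

ORDINALS = ("first", "middle", "last")


@dataclass
class JunctionCountTable:
    """Long-format junction counts: one row per intron x sample."""

    counts: pd.DataFrame  # intron_id, gene_id, ordinal, sample, I1, I2, S
    samples: pd.DataFrame  # index sample; condition/compartment/replicate

    def __post_init__(self):
        req = {"intron_id", "gene_id", "ordinal", "sample", "I1", "I2", "S"}
        missing = req - set(self.counts.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.counts[["I1", "I2", "S"]].values < 0).any():
            raise ValueError("negative junction counts")
        bad = set(self.counts["ordinal"]) - set(ORDINALS)
        if bad:
            raise ValueError(f"unknown ordinals: {sorted(bad)}")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def intron_psi(i1: float, i2: float, s: float) -> float:
    """Inclusion level from boundary and spliced-junction counts."""
    if min(i1, i2, s) < 0:
        raise ValueError("negative counts")
    inc = (i1 + i2) / 2.0
    if inc + s == 0:
        return float("nan")
    return inc / (inc + s)


def psi_per_sample(table: JunctionCountTable) -> pd.DataFrame:
    """Wide PSI matrix, introns x samples (NaN where uncovered)."""
    df = table.counts.copy()
    inc = (df["I1"] + df["I2"]) / 2.0
    with np.errstate(invalid="ignore"):
        df["psi"] = np.where(inc + df["S"] > 0, inc / (inc + df["S"]), np.nan)
    return df.pivot(index="intron_id", columns="sample", values="psi")


def delta_psi_test(
    cyto: tuple[float, float], nuc: tuple[float, float]
) -> tuple[float, float]:
    """Compartment PSI shift for one intron on pooled counts.

    ``cyto`` and ``nuc`` are (inclusion, spliced) sums with inclusion
    already averaged over the two boundaries.  Returns
    (delta PSI = PSI_cyto - PSI_nuc, two-sided Fisher p on the 2x2 table
    [[I_cyto, S_cyto], [I_nuc, S_nuc]] with inclusion rounded to int).
    """
    (ic, sc), (inn, sn) = cyto, nuc
    if ic + sc <= 0 or inn + sn <= 0:
        return float("nan"), float("nan")
    dpsi = ic / (ic + sc) - inn / (inn + sn)
    table = [[int(round(ic)), int(round(sc))], [int(round(inn)), int(round(sn))]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(dpsi), float(p)


def compartment_shift(
    table: JunctionCountTable,
    condition: str,
    nucleus: str = "nucleus",
    cytoplasm: str = "cytoplasm",
    dpsi_min: float = 0.1,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-intron cytoplasm-vs-nucleus retention shift within a condition.

    Replicates are pooled per compartment before Fisher's test; BH FDR is
    computed over all testable introns.  ``significant`` marks introns
    with delta PSI > dpsi_min and FDR <= fdr.
    """
    meta = table.samples
    want = meta.index[meta["condition"] == condition]
    df = table.counts[table.counts["sample"].isin(want)].copy()
    df["compartment"] = meta.loc[df["sample"], "compartment"].to_numpy()
    df["inc"] = (df["I1"] + df["I2"]) / 2.0
    pooled = (
        df.groupby(["intron_id", "ordinal", "compartment"])[["inc", "S"]]
        .sum()
        .reset_index()
        .pivot(index=["intron_id", "ordinal"], columns="compartment")
    )
    rows = []
    for (intron_id, ordinal), r in pooled.iterrows():
        cy = (r[("inc", cytoplasm)], r[("S", cytoplasm)])
        nu = (r[("inc", nucleus)], r[("S", nucleus)])
        dpsi, p = delta_psi_test(cy, nu)
        rows.append(
            dict(intron_id=intron_id, ordinal=ordinal, delta_psi=dpsi, pvalue=p)
        )
    out = pd.DataFrame(rows).set_index("intron_id")
    ok = out["pvalue"].notna()
    out["fdr"] = np.nan
    out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "pvalue"].to_numpy())
    out["significant"] = (out["delta_psi"] > dpsi_min) & (out["fdr"] <= fdr)
    return out


def intron_position_enrichment(
    significant_ordinals: Sequence[str], all_ordinals: Sequence[str]
) -> tuple[float, float, float]:
    """Last-intron enrichment among significant introns.

    Exact two-sided binomial test of the number of 'last' introns in the
    significant set against the background last-intron fraction among all
    tested introns.  Returns (observed fraction, expected fraction, p).
    """
    sig = list(significant_ordinals)
    allo = list(all_ordinals)
    if not sig or not allo:
        raise ValueError("both intron sets must be non-empty")
    k = sum(o == "last" for o in sig)
    n = len(sig)
    p0 = sum(o == "last" for o in allo) / len(allo)
    if p0 in (0.0, 1.0):
        return k / n, p0, 1.0
    p = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
    return k / n, p0, float(p)
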