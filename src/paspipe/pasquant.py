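"""Poly(A)-site quantification from aligned 3'-end tags.

Covers the strand-aware 3'-end extraction, the A-rich internal-priming
filter (a tag is discarded when the 10 nt immediately downstream of its
3' end, read in transcribed sense, contain six consecutive adenosines or
seven adenosines in total), assignment of surviving ends to a master
annotation of known poly(A) sites, count-matrix construction, and
positional classification of sites as terminal, intronic (IPA) or
promoter-upstream antisense (PROMPT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .readproc import AlignedTag
from .simulate import GenomeAnnotation, PASite, revcomp


@dataclass
class PASCountMatrix:
    """Integer counts per PAS x sample plus sample and site metadata."""

    counts: pd.DataFrame  # index: pas_id, columns: sample ids
    samples: pd.DataFrame  # index: sample id; condition/compartment/replicate
    site_info: Optional[pd.DataFrame] = None  # index: pas_id; pas_class etc.

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")

    def subset_samples(self, sample_ids: Sequence[str]) -> "PASCountMatrix":
        return PASCountMatrix(
            self.counts[list(sample_ids)], self.samples.loc[list(sample_ids)],
            self.site_info,
        )

    def to_tsv(self, counts_path, samples_path) -> None:
        out = self.counts.copy()
        if self.site_info is not None:
            out.insert(0, "pas_class", self.site_info["pas_class"])
        out.to_csv(counts_path, sep="\t", index_label="pas_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "PASCountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col="pas_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        site_info = None
        if "pas_class" in df.columns:
            site_info = df[["pas_class"]].copy()
            df = df.drop(columns=["pas_class"])
        return cls(df.astype(int), samples, site_info)


def downstream_window(
    tag: AlignedTag, contigs: dict[str, str], width: int = 10
) -> str:
    """The ``width`` bases immediately downstream of the tag's 3' end.

    Reported in transcribed sense: genomic [p+1, p+1+width) on '+',
    reverse complement of [p-width, p) on '-'.  Positions beyond the
    contig are padded with N.
    """
    seq = contigs[tag.contig]
    p = tag.three_prime
    if tag.strand == "+":
        lo, hi = p + 1, p + 1 + width
        raw = seq[max(lo, 0) : min(hi, len(seq))]
        return raw + "N" * (width - len(raw))
    lo, hi = p - width, p
    raw = seq[max(lo, 0) : min(hi, len(seq))]
    pad = "N" * (width - len(raw))
    return revcomp(raw) + pad


def is_internal_priming(window: str) -> bool:
    """True iff the downstream window looks like an oligo-dT priming site.

    Rule: a run of >= 6 consecutive A, or >= 7 A in total, within the
    10-nt window.  N never counts as A (and breaks runs).
    """
    if len(window) != 10:
        raise ValueError(f"window must be 10 bases, got {len(window)}")
    return "AAAAAA" in window or window.count("A") >= 7


def is_internal_priming_batch(windows: np.ndarray) -> np.ndarray:
    """Vectorised priming rule over an (n, 10) boolean array of A-flags."""
    if windows.ndim != 2 or windows.shape[1] != 10:
        raise ValueError("expected an (n, 10) array")
    a = windows.astype(bool)
    total7 = a.sum(axis=1) >= 7
    run6 = np.zeros(len(a), dtype=bool)
    for i in range(5):
        run6 |= a[:, i : i + 6].all(axis=1)
    return run6 | total7


def filter_internal_priming(
    tags: Iterable[AlignedTag], contigs: dict[str, str], width: int = 10
) -> tuple[list[AlignedTag], list[AlignedTag]]:
    """Split tags into (kept, discarded-as-artifact) by the A-rich rule."""
    kept, dropped = [], []
    for tag in tags:
        if is_internal_priming(downstream_window(tag, contigs, width)):
            dropped.append(tag)
        else:
            kept.append(tag)
    return kept, dropped


def assign_pas(
    tag: AlignedTag, pas_sites: Sequence[PASite], flank: int = 24
) -> Optional[str]:
    """Assign a filtered tag to the nearest same-strand PAS within +-flank.

    Ties by distance are broken in favour of the upstream site (smaller
    coordinate on '+', larger on '-').  Returns the PAS id or None.
    """
    p = tag.three_prime
    best: Optional[tuple[int, int, str]] = None
    for site in pas_sites:
        if site.contig != tag.contig or site.strand != tag.strand:
            continue
        d = abs(site.position - p)
        if d > flank:
            continue
        # upstream key: smaller position upstream on '+', larger on '-'
        upkey = site.position if tag.strand == "+" else -site.position
        cand = (d, upkey, site.pas_id)
        if best is None or cand < best:
            best = cand
    return best[2] if best else None


class _PASIndex:
    """Per (contig, strand) sorted position index for fast assignment."""

    def __init__(self, pas_sites: Sequence[PASite]):
        self.by_key: dict[tuple[str, str], tuple[np.ndarray, list[PASite]]] = {}
        grouped: dict[tuple[str, str], list[PASite]] = {}
        for s in pas_sites:
            grouped.setdefault((s.contig, s.strand), []).append(s)
        for key, sites in grouped.items():
            sites.sort(key=lambda s: s.position)
            self.by_key[key] = (np.array([s.position for s in sites]), sites)

    def assign(self, tag: AlignedTag, flank: int) -> Optional[str]:
        entry = self.by_key.get((tag.contig, tag.strand))
        if entry is None:
            return None
        positions, sites = entry
        p = tag.three_prime
        lo = int(np.searchsorted(positions, p - flank, "left"))
        hi = int(np.searchsorted(positions, p + flank, "right"))
        if lo == hi:
            return None
        return assign_pas(tag, sites[lo:hi], flank)


def assign_all(
    tags: Iterable[AlignedTag], pas_sites: Sequence[PASite], flank: int = 24
) -> tuple[list[tuple[AlignedTag, str]], list[AlignedTag]]:
    """Assign many tags; returns (assigned pairs, unassigned tags)."""
    index = _PASIndex(pas_sites)
    assigned, unassigned = [], []
    for tag in tags:
        pid = index.assign(tag, flank)
        if pid is None:
            unassigned.append(tag)
        else:
            assigned.append((tag, pid))
    return assigned, unassigned


def build_count_matrix(
    assignments: dict[str, list[str]],
    pas_sites: Sequence[PASite],
    samples: pd.DataFrame,
) -> PASCountMatrix:
    """Tally assigned tags into a PAS x sample matrix.

    ``assignments`` maps sample id -> list of assigned PAS ids.  Sites
    with zero tags everywhere are retained with zero rows.
    """
    unknown = set(assignments) - set(samples.index)
    if unknown:
        raise ValueError(f"unknown sample ids: {sorted(unknown)}")
    site_ids = [s.pas_id for s in pas_sites]
    counts = pd.DataFrame(0, index=site_ids, columns=samples.index, dtype=int)
    for sample, ids in assignments.items():
        if ids:
            vc = pd.Series(ids).value_counts()
            counts.loc[vc.index, sample] += vc.astype(int)
    site_info = pd.DataFrame(
        {
            "pas_class": [s.pas_class for s in pas_sites],
            "gene_id": [s.gene_id for s in pas_sites],
        },
        index=site_ids,
    )
    return PASCountMatrix(counts, samples.copy(), site_info)


def classify_pas(
    contig: str,
    strand: str,
    position: int,
    genes,
    prompt_window: int = 3000,
) -> str:
    """Positional PAS class: IPA > terminal > PROMPT > other.

    IPA: inside an intron of a same-strand gene.  Terminal: within the
    terminal exon of a same-strand gene.  PROMPT: within ``prompt_window``
    nt upstream of a TSS on the antisense strand and not inside any
    same-strand gene.
    """
    inside_same_strand_gene = False
    is_ipa = is_terminal = False
    for gene in genes:
        if gene.contig != contig:
            continue
        if gene.strand == strand and gene.start <= position < gene.end:
            inside_same_strand_gene = True
            for intr in gene.introns:
                if intr.start <= position < intr.end:
                    is_ipa = True
            term_exon = gene.exons[-1] if gene.strand == "+" else gene.exons[0]
            if term_exon[0] <= position < term_exon[1]:
                is_terminal = True
    if is_ipa:
        return "IPA"
    if is_terminal:
        return "terminal"
    if not inside_same_strand_gene:
        for gene in genes:
            if gene.contig != contig or gene.strand == strand:
                continue
            # antisense of the gene: upstream window relative to the gene TSS
            if gene.strand == "+" and gene.tss - prompt_window <= position < gene.tss:
                return "PROMPT"
            if gene.strand == "-" and gene.tss < position <= gene.tss + prompt_window:
                return "PROMPT"
    return "other"


def quantify(
    tags: Iterable[AlignedTag],
    sample_of_read: dict[str, str],
    ann: GenomeAnnotation,
    samples: pd.DataFrame,
    flank: int = 24,
    window_width: int = 10,
):
    """Filter, assign and count aligned tags end-to-end.

    Returns (PASCountMatrix, stats dict with tag bookkeeping).
    """
    kept, dropped = filter_internal_priming(tags, ann.contigs, window_width)
    assigned, unassigned = assign_all(kept, ann.pas_sites, flank)
    per_sample: dict[str, list[str]] = {s: [] for s in samples.index}
    for tag, pid in assigned:
        per_sample[sample_of_read[tag.read_id]].append(pid)
    mat = build_count_matrix(per_sample, ann.pas_sites, samples)
    stats = {
        "filtered_artifact": len(dropped),
        "assigned": len(assigned),
        "unassigned": len(unassigned),
    }
    return mat, stats
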