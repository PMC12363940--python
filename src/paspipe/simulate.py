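"""Synthetic PAS-seq data generator.

Builds toy genomes with gene models, a master annotation of poly(A) sites
(terminal, intronic/IPA, and promoter-upstream antisense/PROMPT classes),
negative-binomial count matrices over a condition x compartment x replicate
design, junction-count tables for intron retention, and FASTQ reads with
poly(A) tails, a ligated linker, and internal-priming artifacts at planted
A-rich tracts.  Every output carries a ground-truth record so each
downstream stage of the pipeline can be scored against what was simulated.

The depletion effects (IPA accumulation, PROMPT stabilisation, cytoplasmic
leakage of normally nucleus-restricted transcripts) mirror what acute loss
of a nuclear-retention factor does to a transcriptome: transcripts that are
normally degraded or retained accumulate, and accumulate preferentially in
the cytoplasm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# rng stream tags so each stage has an independent deterministic stream
_STREAM_ANNOTATION = 1
_STREAM_COUNTS = 2
_STREAM_READS = 3
_STREAM_JUNCTIONS = 4


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study.

    The defaults describe a small degron-depletion experiment: two
    conditions (vehicle ``DMSO`` vs degrader ``dTAG``), two compartments
    (nucleus, cytoplasm), three replicates each.  Effects are expressed as
    log2 fold changes applied to the depleted condition.
    """

    seed: int = 0
    n_genes: int = 50
    introns_per_gene: tuple[int, int] = (1, 4)
    frac_genes_with_ipa: float = 0.2
    frac_genes_with_prompt: float = 0.2
    lib_size: Optional[int] = None  # expected reads/sample; None -> n_sites * base_mean
    nb_dispersion: float = 0.05  # phi in var = mu + phi*mu^2
    base_mean: float = 100.0
    # baseline abundance of the repressed classes relative to terminal PAS:
    # IPA isoforms are minor and PROMPTs are near-undetectable at steady
    # state, so most library mass stays on terminal sites
    ipa_abundance: float = 0.15
    prompt_abundance: float = 0.05
    effect_ipa_log2fc: float = 0.0
    effect_leak_log2fc: float = 0.0
    effect_prompt_log2fc: float = 0.0
    internal_priming_rate: float = 0.0
    tail_len_range: tuple[int, int] = (8, 30)
    linker_seq: str = "CTGTAG"
    replicates: int = 3
    # layout / sequence-level knobs
    read_len: int = 75
    min_insert: int = 20
    exon_len_range: tuple[int, int] = (150, 300)
    intron_len_range: tuple[int, int] = (250, 450)
    intergenic_gap: int = 3500
    prompt_offset_range: tuple[int, int] = (300, 1500)
    frac_introns_with_decoy: float = 0.5
    baseline_sigma: float = 0.5  # lognormal spread of per-site baselines
    # junction-count knobs
    junction_depth: int = 100
    base_psi: float = 0.1
    psi_spike: float = 0.3
    frac_introns_spiked: float = 0.2
    last_intron_bias: float = 0.8
    # labels
    cond_control: str = "DMSO"
    cond_depleted: str = "dTAG"
    compartments: tuple[str, str] = ("nucleus", "cytoplasm")

    def validate(self) -> None:
        for name in (
            "frac_genes_with_ipa",
            "frac_genes_with_prompt",
            "internal_priming_rate",
            "frac_introns_with_decoy",
            "base_psi",
            "frac_introns_spiked",
            "last_intron_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if len(self.linker_seq) != 6:
            raise ValueError("linker_seq must be 6 bases")
        if set(self.linker_seq) - set("ACGT"):
            raise ValueError("linker_seq must be ACGT only")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.junction_depth <= 0:
            raise ValueError("junction_depth must be > 0")
        if not np.isfinite(self.base_mean) or self.base_mean <= 0:
            raise ValueError("base_mean must be a positive finite number")
        if self.ipa_abundance <= 0 or self.prompt_abundance <= 0:
            raise ValueError("class abundance factors must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class Intron:
    start: int
    end: int
    ordinal: str  # first / middle / last


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]
    introns: list[Intron]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class PASite:
    pas_id: str
    contig: str
    strand: str
    position: int  # 0-based coordinate of the last transcribed base
    gene_id: Optional[str]
    pas_class: str  # terminal / IPA / PROMPT / other


@dataclass
class GenomeAnnotation:
    contigs: dict[str, str]
    genes: list[Gene]
    pas_sites: list[PASite]
    # artifact anchors: (contig, strand, position); the 10 nt downstream of
    # position in transcribed sense is an A-rich tract
    decoys: list[tuple[str, str, int]] = field(default_factory=list)

    def gene_by_id(self, gene_id: str) -> Gene:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def pas_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(p) for p in self.pas_sites]
        ).set_index("pas_id")


@dataclass
class SimulationTruth:
    expected_means: Optional[pd.DataFrame] = None  # sites x samples
    read_origins: Optional[pd.DataFrame] = None  # read_id -> origin, sample
    true_psi: Optional[pd.DataFrame] = None  # introns x samples


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


def _a_rich(window: str) -> bool:
    return "AAAAAA" in window or window.count("A") >= 7


def _decode(codes: np.ndarray) -> str:
    return _BASE_CODES[codes].tobytes().decode()


def _sanitize_window(seq: np.ndarray, lo: int, hi: int, strand: str, rng) -> None:
    """Resample genome bases so the transcribed-sense window is not A-rich."""
    for _ in range(100):
        win = _decode(seq[lo:hi])
        sense = win if strand == "+" else revcomp(win)
        if not _a_rich(sense):
            return
        seq[lo:hi] = rng.integers(0, 4, hi - lo, dtype=np.uint8)
    raise RuntimeError("failed to sanitize PAS downstream window")


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Build a toy genome plus gene models and a master PAS annotation.

    Genes are laid left-to-right on one contig with alternating strands and
    wide intergenic gaps so promoter-upstream antisense windows never
    overlap a neighbouring gene.  Each gene gets exactly one terminal PAS
    at its 3' end; a configured fraction additionally get one intronic PAS
    and/or one PROMPT PAS in the antisense window upstream of the TSS.
    A-rich decoy tracts (6-8 consecutive A in transcribed sense) are
    planted in a fraction of introns, at least 30 nt away from any true
    PAS, so internal-priming artifacts can be simulated and the filter's
    sensitivity/specificity measured cleanly.
    """
    config.validate()
    rng = config.rng(_STREAM_ANNOTATION)

    genes: list[Gene] = []
    pas_sites: list[PASite] = []
    decoys: list[tuple[str, str, int]] = []

    lo_i, hi_i = config.introns_per_gene
    n_introns = rng.integers(lo_i, hi_i + 1, size=config.n_genes)
    # the configured fractions force exact class counts
    ipa_genes = np.zeros(config.n_genes, bool)
    ipa_genes[
        rng.choice(
            config.n_genes,
            size=int(round(config.frac_genes_with_ipa * config.n_genes)),
            replace=False,
        )
    ] = True
    prompt_genes = np.zeros(config.n_genes, bool)
    prompt_genes[
        rng.choice(
            config.n_genes,
            size=int(round(config.frac_genes_with_prompt * config.n_genes)),
            replace=False,
        )
    ] = True

    # first pass: gene structures and total length
    structures = []
    cursor = config.intergenic_gap
    for gi in range(config.n_genes):
        k = int(n_introns[gi])
        exon_lens = rng.integers(*config.exon_len_range, size=k + 1, endpoint=True)
        intron_lens = rng.integers(*config.intron_len_range, size=k, endpoint=True)
        exons, introns = [], []
        pos = cursor
        for j in range(k + 1):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < k:
                introns.append((pos, pos + int(intron_lens[j])))
                pos += int(intron_lens[j])
        structures.append((exons, introns))
        cursor = pos + config.intergenic_gap
    genome_len = cursor + config.intergenic_gap
    seq = rng.integers(0, 4, genome_len, dtype=np.uint8)

    for gi, (exons, introns) in enumerate(structures):
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"gene{gi:04d}"
        k = len(introns)
        ordinals = []
        for j in range(k):
            # genomic order; flip for minus strand so "first" is 5'-most
            tx_j = j if strand == "+" else k - 1 - j
            if k == 1:
                ordinals.append("last")
            elif tx_j == 0:
                ordinals.append("first")
            elif tx_j == k - 1:
                ordinals.append("last")
            else:
                ordinals.append("middle")
        intron_objs = [Intron(s, e, o) for (s, e), o in zip(introns, ordinals)]
        gstart, gend = exons[0][0], exons[-1][1]
        tss = gstart if strand == "+" else gend - 1
        gene = Gene(gene_id, "chr1", strand, tss, exons, intron_objs)
        genes.append(gene)

        # terminal PAS at the 3'-most transcribed base
        tpos = gend - 1 if strand == "+" else gstart
        pas_sites.append(
            PASite(f"{gene_id}:terminal", "chr1", strand, tpos, gene_id, "terminal")
        )

        if ipa_genes[gi] and k > 0:
            intr = intron_objs[int(rng.integers(k))]
            mid = (intr.start + intr.end) // 2
            pas_sites.append(
                PASite(f"{gene_id}:IPA", "chr1", strand, mid, gene_id, "IPA")
            )

        if prompt_genes[gi]:
            off = int(rng.integers(*config.prompt_offset_range, endpoint=True))
            if strand == "+":
                ppos, pstrand = tss - off, "-"
            else:
                ppos, pstrand = tss + off, "+"
            pas_sites.append(
                PASite(f"{gene_id}:PROMPT", "chr1", pstrand, ppos, gene_id, "PROMPT")
            )

    # keep every true PAS clean: non-A at the site itself (so poly(A)
    # trimming stops exactly at the 3' end) and a non-A-rich 10-nt
    # downstream window (so the priming filter never removes true reads)
    for p in pas_sites:
        seq[p.position] = _C if p.strand == "+" else _G  # 'G' revcomps to C, not A
        if p.strand == "+":
            lo, hi = p.position + 1, min(p.position + 11, genome_len)
        else:
            lo, hi = max(p.position - 10, 0), p.position
        _sanitize_window(seq, lo, hi, p.strand, rng)

    # plant decoy A-tracts inside introns, away from true PAS
    pas_positions = np.array([p.position for p in pas_sites])
    for gene in genes:
        for intr in gene.introns:
            if rng.random() >= config.frac_introns_with_decoy:
                continue
            run = int(rng.integers(6, 9))
            for _ in range(20):
                anchor = int(rng.integers(intr.start + 15, intr.end - 15))
                if np.min(np.abs(pas_positions - anchor)) < 30:
                    continue
                if gene.strand == "+":
                    if anchor + 1 + run > genome_len:
                        continue
                    seq[anchor] = _C
                    seq[anchor + 1 : anchor + 1 + run] = _A
                else:
                    if anchor - run < 0:
                        continue
                    seq[anchor] = _A  # revcomps to T: read won't end in A
                    seq[anchor - run : anchor] = _T
                decoys.append(("chr1", gene.strand, anchor))
                break

    return GenomeAnnotation({"chr1": _decode(seq)}, genes, pas_sites, decoys)


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata: condition x compartment x replicate."""
    rows = []
    for cond in (config.cond_control, config.cond_depleted):
        for comp in config.compartments:
            for r in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample": f"{cond}_{comp}_rep{r}",
                        "condition": cond,
                        "compartment": comp,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def _effect_multiplier(pas_class: str, cond: str, comp: str, config: SimulationConfig) -> float:
    if cond != config.cond_depleted:
        return 1.0
    if pas_class == "IPA":
        lfc = config.effect_ipa_log2fc
    elif pas_class == "PROMPT":
        lfc = config.effect_prompt_log2fc
    else:
        return 1.0
    if comp == config.compartments[1]:  # cytoplasm: retention loss adds leakage
        lfc += config.effect_leak_log2fc
    return float(2.0**lfc)


def simulate_pas_counts(ann: GenomeAnnotation, config: SimulationConfig):
    """Draw an NB count matrix over PAS x sample.

    Per-site baselines are lognormal around ``base_mean``; the depletion
    effects multiply the mean of IPA/PROMPT sites in the depleted
    condition, with the leakage effect applied on top in the depleted
    cytoplasm.  var = mu + phi*mu^2; phi = 0 falls back to Poisson.

    Returns (PASCountMatrix, SimulationTruth).
    """
    from .pasquant import PASCountMatrix

    config.validate()
    rng = config.rng(_STREAM_COUNTS)
    samples = sample_sheet(config)
    site_ids = [p.pas_id for p in ann.pas_sites]
    classes = {p.pas_id: p.pas_class for p in ann.pas_sites}
    n = len(site_ids)

    sigma = config.baseline_sigma
    class_level = {"IPA": config.ipa_abundance, "PROMPT": config.prompt_abundance}
    baselines = (
        config.base_mean
        * np.array([class_level.get(classes[s], 1.0) for s in site_ids])
        * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))
    )
    depth_scale = 1.0
    if config.lib_size is not None:
        depth_scale = config.lib_size / (n * config.base_mean)

    means = np.empty((n, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        mult = np.array(
            [
                _effect_multiplier(classes[s], row["condition"], row["compartment"], config)
                for s in site_ids
            ]
        )
        means[:, j] = baselines * mult * depth_scale
    if not np.all(np.isfinite(means)):
        raise ValueError("non-finite expected mean; check effect sizes")

    phi = config.nb_dispersion
    if phi == 0:
        counts = rng.poisson(means)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + means))

    mat = PASCountMatrix(
        counts=pd.DataFrame(counts, index=site_ids, columns=samples.index),
        samples=samples.copy(),
        site_info=ann.pas_table()[["pas_class", "gene_id", "contig", "strand", "position"]],
    )
    truth = SimulationTruth(
        expected_means=pd.DataFrame(means, index=site_ids, columns=samples.index)
    )
    return mat, truth


def _make_read(contig_seq: str, strand: str, pos: int, insert_len: int, tail: int, linker: str):
    """Sequence a single 3'-end tag; returns (read, start, end) or None."""
    if strand == "+":
        start, end = pos - insert_len + 1, pos + 1
        if start < 0:
            return None
        insert = contig_seq[start:end]
    else:
        start, end = pos, pos + insert_len
        if end > len(contig_seq):
            return None
        insert = revcomp(contig_seq[start:end])
    return insert + "A" * tail + linker, start, end


def emit_reads(ann: GenomeAnnotation, counts, config: SimulationConfig):
    """Emit FASTQ reads for every counted tag.

    Read layout: [genomic insert ending at the PAS][poly(A) tail][6-nt
    linker], reported on the sense strand of transcription and padded to a
    fixed pre-trim read length.  A fraction ``internal_priming_rate`` of
    reads is re-anchored to a planted A-rich decoy instead of its true
    PAS, emulating oligo-dT priming on genomic A tracts.

    Returns (reads_by_sample, truth) where reads_by_sample maps sample id
    to a list of (read_id, sequence) and truth.read_origins records, per
    read, the intended alignment interval and origin ('<pas_id>' or
    'artifact').  Inserts shorter than the minimum or running off the
    contig are skipped and counted in truth via origin 'skipped'.
    """
    config.validate()
    rng = config.rng(_STREAM_READS)
    pas_by_id = {p.pas_id: p for p in ann.pas_sites}
    decoys = ann.decoys
    linker = config.linker_seq
    tlo, thi = config.tail_len_range

    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    origin_rows = []
    ridx = 0
    for sample in counts.counts.columns:
        out = []
        col = counts.counts[sample]
        for pas_id, c in col.items():
            c = int(c)
            if c == 0:
                continue
            site = pas_by_id[pas_id]
            contig_seq = ann.contigs[site.contig]
            tails = rng.integers(tlo, thi + 1, size=c)
            artifact = (
                rng.random(c) < config.internal_priming_rate
                if decoys and config.internal_priming_rate > 0
                else np.zeros(c, bool)
            )
            decoy_pick = rng.integers(len(decoys), size=c) if decoys else None
            for i in range(c):
                tail = int(tails[i])
                insert_len = config.read_len - len(linker) - tail
                if artifact[i]:
                    dcontig, dstrand, dpos = decoys[int(decoy_pick[i])]
                    made = _make_read(
                        ann.contigs[dcontig], dstrand, dpos, insert_len, tail, linker
                    )
                    origin, strand = "artifact", dstrand
                else:
                    made = _make_read(
                        contig_seq, site.strand, site.position, insert_len, tail, linker
                    )
                    origin, strand = pas_id, site.strand
                rid = f"read{ridx:08d}"
                ridx += 1
                if insert_len < config.min_insert or made is None:
                    origin_rows.append(
                        dict(read_id=rid, sample=sample, origin="skipped",
                             contig="", start=-1, end=-1, strand=strand)
                    )
                    continue
                seqread, start, end = made
                out.append((rid, seqread))
                origin_rows.append(
                    dict(read_id=rid, sample=sample, origin=origin,
                         contig=site.contig if origin != "artifact" else dcontig,
                         start=start, end=end, strand=strand)
                )
        reads_by_sample[sample] = out
    truth = SimulationTruth(
        read_origins=pd.DataFrame(origin_rows).set_index("read_id")
        if origin_rows
        else pd.DataFrame(
            columns=["sample", "origin", "contig", "start", "end", "strand"]
        )
    )
    return reads_by_sample, truth


def simulate_junction_counts(ann: GenomeAnnotation, config: SimulationConfig):
    """Simulate per-intron junction counts for intron-retention analysis.

    For each intron and sample, ``depth`` pre-mRNA molecules are observed;
    retained molecules (binomial with the intron's true inclusion level
    PSI) support both exon-intron boundaries (I1, I2) while spliced
    molecules support the exon-exon junction (S).  A configured fraction
    of introns - biased toward last introns with probability
    ``last_intron_bias`` - has its cytoplasmic PSI raised by ``psi_spike``
    in the depleted condition, emulating leakage of intron-retained
    transcripts upon loss of nuclear retention.

    Returns (JunctionCountTable, SimulationTruth with true_psi).
    """
    from .retention import JunctionCountTable

    config.validate()
    rng = config.rng(_STREAM_JUNCTIONS)
    samples = sample_sheet(config)

    introns = []
    for gene in ann.genes:
        for j, intr in enumerate(gene.introns):
            introns.append((f"{gene.gene_id}:intron{j + 1}", gene.gene_id, intr.ordinal))
    if not introns:
        raise ValueError("annotation has no introns")
    n = len(introns)

    n_spike = int(round(config.frac_introns_spiked * n))
    last_idx = [i for i, t in enumerate(introns) if t[2] == "last"]
    other_idx = [i for i, t in enumerate(introns) if t[2] != "last"]
    n_last = min(int(round(config.last_intron_bias * n_spike)), len(last_idx))
    n_other = min(n_spike - n_last, len(other_idx))
    spiked = set(rng.choice(last_idx, size=n_last, replace=False)) | set(
        rng.choice(other_idx, size=n_other, replace=False)
    )

    rows, psi_rows = [], []
    depth = config.junction_depth
    for i, (intron_id, gene_id, ordinal) in enumerate(introns):
        psi_per_sample = {}
        for sid, meta in samples.iterrows():
            psi = config.base_psi
            if (
                i in spiked
                and meta["condition"] == config.cond_depleted
                and meta["compartment"] == config.compartments[1]
            ):
                psi = min(1.0, psi + config.psi_spike)
            k = int(rng.binomial(depth, psi))
            rows.append(
                dict(intron_id=intron_id, gene_id=gene_id, ordinal=ordinal,
                     sample=sid, I1=k, I2=k, S=depth - k)
            )
            psi_per_sample[sid] = psi
        psi_rows.append(dict(intron_id=intron_id, spiked=i in spiked, **psi_per_sample))

    table = JunctionCountTable(
        counts=pd.DataFrame(rows), samples=samples.copy()
    )
    truth = SimulationTruth(true_psi=pd.DataFrame(psi_rows).set_index("intron_id"))
    return table, truth
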