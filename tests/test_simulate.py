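"""Generator contracts: determinism, annotation geometry, NB count moments,
read construction, and junction-count sampling bounds."""

import hashlib
from collections import Counter

import numpy as np
import pytest

from paspipe.simulate import (
    SimulationConfig,
    emit_reads,
    generate_annotation,
    revcomp,
    sample_sheet,
    simulate_junction_counts,
    simulate_pas_counts,
)


def test_annotation_class_counts_forced_by_config():
    cfg = SimulationConfig(seed=1, n_genes=10, frac_genes_with_ipa=0.5,
                           frac_genes_with_prompt=0.2)
    ann = generate_annotation(cfg)
    classes = Counter(p.pas_class for p in ann.pas_sites)
    assert classes["terminal"] == 10
    assert classes["IPA"] == 5
    assert classes["PROMPT"] == 2


def test_annotation_no_ipa_when_fraction_zero():
    cfg = SimulationConfig(seed=1, n_genes=8, frac_genes_with_ipa=0.0)
    ann = generate_annotation(cfg)
    assert all(p.pas_class != "IPA" for p in ann.pas_sites)


def test_annotation_deterministic_under_seed():
    cfg = SimulationConfig(seed=5, n_genes=6)
    a, b = generate_annotation(cfg), generate_annotation(cfg)
    assert a.contigs == b.contigs
    assert a.pas_table().equals(b.pas_table())
    assert a.decoys == b.decoys


def test_annotation_geometry(small_annotation):
    ann = small_annotation
    glen = len(ann.contigs["chr1"])
    gene_by_id = {g.gene_id: g for g in ann.genes}
    for g in ann.genes:
        for s, e in g.exons:
            assert 0 <= s < e <= glen
        # introns strictly between consecutive exons
        for i, intr in enumerate(g.introns):
            assert intr.start == g.exons[i][1]
            assert intr.end == g.exons[i + 1][0]
    for p in ann.pas_sites:
        assert 0 <= p.position < glen
        g = gene_by_id[p.gene_id]
        if p.pas_class == "IPA":
            assert any(i.start <= p.position < i.end for i in g.introns)
            assert p.strand == g.strand
        elif p.pas_class == "terminal":
            term = g.exons[-1] if g.strand == "+" else g.exons[0]
            assert term[0] <= p.position < term[1]
        elif p.pas_class == "PROMPT":
            assert p.strand != g.strand
            off = p.position - g.tss if g.strand == "-" else g.tss - p.position
            assert 0 < off <= 3000


def test_decoys_inside_introns_and_away_from_pas(small_annotation):
    ann = small_annotation
    pas_pos = np.array([p.position for p in ann.pas_sites])
    intron_iv = [
        (i.start, i.end) for g in ann.genes for i in g.introns
    ]
    for _, strand, pos in ann.decoys:
        assert np.min(np.abs(pas_pos - pos)) >= 10
        assert any(s <= pos < e for s, e in intron_iv)
        # downstream window in transcribed sense really is A-rich
        seq = ann.contigs["chr1"]
        win = seq[pos + 1 : pos + 11] if strand == "+" else revcomp(seq[pos - 10 : pos])
        assert "AAAAAA" in win or win.count("A") >= 7


def test_null_counts_have_no_condition_effect(small_annotation, small_config):
    mat, truth = simulate_pas_counts(small_annotation, small_config)
    meta = mat.samples
    ctrl = meta.index[meta.condition == "DMSO"]
    depl = meta.index[meta.condition == "dTAG"]
    # expected means identical between conditions under the null config
    assert np.allclose(
        truth.expected_means[ctrl].to_numpy(),
        truth.expected_means[depl].to_numpy(),
    )
    m_c = mat.counts[ctrl].to_numpy().mean()
    m_d = mat.counts[depl].to_numpy().mean()
    assert abs(np.log2(m_d / m_c)) < 0.15


def test_ipa_effect_mean_ratio_matches_nb_moments():
    # 200 IPA sites at base mean 100 and a +2 log2FC: the mean of the
    # per-site depleted/control count ratios should sit within 3 SE of 4.
    cfg = SimulationConfig(seed=3, n_genes=200, frac_genes_with_ipa=1.0,
                           frac_genes_with_prompt=0.0, effect_ipa_log2fc=2.0,
                           base_mean=100.0, ipa_abundance=1.0, baseline_sigma=0.0)
    ann = generate_annotation(cfg)
    mat, truth = simulate_pas_counts(ann, cfg)
    meta = mat.samples
    nuc = meta.index[meta.compartment == "nucleus"]
    c = mat.counts[nuc[meta.loc[nuc].condition == "DMSO"]].mean(axis=1)
    d = mat.counts[nuc[meta.loc[nuc].condition == "dTAG"]].mean(axis=1)
    ipa = [p.pas_id for p in ann.pas_sites if p.pas_class == "IPA"]
    ratios = (d[ipa] / c[ipa]).to_numpy()
    # delta method on the ratio of NB group means (3 reps each):
    # Var(R) ~ Var(dbar)/mu_c^2 + (mu_d/mu_c^2)^2 Var(cbar), plus the
    # second-order ratio bias 4*Var(cbar)/mu_c^2
    phi, mu_c, mu_d, reps = cfg.nb_dispersion, 100.0, 400.0, cfg.replicates
    var_c = (mu_c + phi * mu_c**2) / reps
    var_d = (mu_d + phi * mu_d**2) / reps
    var_r = var_d / mu_c**2 + (mu_d / mu_c**2) ** 2 * var_c
    bias = 4.0 * var_c / mu_c**2
    se = np.sqrt(var_r / len(ipa))
    assert len(ipa) == 200
    assert abs(ratios.mean() - 4.0) < bias + 3 * se


def test_poisson_limit_variance_equals_mean():
    cfg = SimulationConfig(seed=4, n_genes=500, frac_genes_with_ipa=1.0,
                           frac_genes_with_prompt=0.0, nb_dispersion=0.0,
                           baseline_sigma=0.0, ipa_abundance=1.0, replicates=3)
    ann = generate_annotation(cfg)
    mat, _ = simulate_pas_counts(ann, cfg)
    x = mat.counts.to_numpy(float)  # >1,000 sites x 12 null samples
    m, v = x.mean(), x.var(ddof=1)
    assert abs(v / m - 1.0) < 0.05


def test_read_construction_rule():
    cfg = SimulationConfig(seed=9, n_genes=2, frac_genes_with_prompt=0.0,
                           tail_len_range=(8, 8), linker_seq="CTGTAG")
    ann = generate_annotation(cfg)
    mat, _ = simulate_pas_counts(ann, cfg)
    reads, truth = emit_reads(ann, mat, cfg)
    some = next(rs for rs in reads.values() if rs)
    rid, seq = some[0]
    assert seq.endswith("AAAAAAAA" + "CTGTAG")
    assert len(seq) == cfg.read_len
    origin = truth.read_origins.loc[rid]
    iv = ann.contigs[origin.contig][origin.start : origin.end]
    insert = seq[: -(8 + 6)]
    assert insert == (iv if origin.strand == "+" else revcomp(iv))


def test_zero_priming_rate_means_no_artifact_reads(small_annotation, small_config):
    mat, _ = simulate_pas_counts(small_annotation, small_config)
    _, truth = emit_reads(small_annotation, mat, small_config)
    origins = truth.read_origins.origin
    assert not (origins == "artifact").any()


def test_artifact_fraction_within_binomial_bound(small_annotation, small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, internal_priming_rate=0.2)
    mat, _ = simulate_pas_counts(small_annotation, cfg)
    _, truth = emit_reads(small_annotation, mat, cfg)
    ro = truth.read_origins[truth.read_origins.origin != "skipped"]
    n = len(ro)
    assert n > 3000
    frac = (ro.origin == "artifact").mean()
    half = 2.58 * np.sqrt(0.2 * 0.8 / n)  # 99% binomial interval
    assert abs(frac - 0.2) < half + 0.01


def test_read_count_conservation(small_annotation, small_config):
    mat, _ = simulate_pas_counts(small_annotation, small_config)
    reads, truth = emit_reads(small_annotation, mat, small_config)
    emitted = sum(len(v) for v in reads.values())
    skipped = (truth.read_origins.origin == "skipped").sum()
    assert emitted + skipped == int(mat.counts.values.sum())


def test_fastq_and_counts_hash_identical_across_runs(small_config):
    def digest():
        ann = generate_annotation(small_config)
        mat, _ = simulate_pas_counts(ann, small_config)
        reads, _ = emit_reads(ann, mat, small_config)
        h = hashlib.sha256()
        h.update(ann.contigs["chr1"].encode())
        h.update(mat.counts.to_csv().encode())
        for s in sorted(reads):
            for rid, seq in reads[s]:
                h.update(f"{rid}:{seq}".encode())
        return h.hexdigest()

    assert digest() == digest()


def test_junction_counts_zero_psi_gives_zero_inclusion(small_annotation, small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, base_psi=0.0, frac_introns_spiked=0.0)
    jt, _ = simulate_junction_counts(small_annotation, cfg)
    assert (jt.counts[["I1", "I2"]].to_numpy() == 0).all()
    assert (jt.counts["S"] == cfg.junction_depth).all()


def test_junction_counts_binomial_bound(small_annotation, small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, base_psi=0.25, junction_depth=1000,
                              frac_introns_spiked=0.0)
    jt, truth = simulate_junction_counts(small_annotation, cfg)
    psi_hat = (jt.counts.I1 + jt.counts.I2) / 2 / (
        (jt.counts.I1 + jt.counts.I2) / 2 + jt.counts.S
    )
    se = np.sqrt(0.25 * 0.75 / 1000)
    # per-observation bound wide enough for the multiplicity across introns
    assert (np.abs(psi_hat - 0.25) < 5 * se).all()
    assert abs(psi_hat.mean() - 0.25) < 3 * se / np.sqrt(len(psi_hat))


def test_full_last_intron_bias_spikes_only_last(small_annotation, small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, last_intron_bias=1.0,
                              frac_introns_spiked=0.3)
    jt, truth = simulate_junction_counts(small_annotation, cfg)
    spiked = truth.true_psi[truth.true_psi.spiked].index
    ords = jt.counts.drop_duplicates("intron_id").set_index("intron_id")["ordinal"]
    assert (ords[spiked] == "last").all()


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimulationConfig(frac_genes_with_ipa=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(nb_dispersion=-0.1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(linker_seq="CTGTAGA").validate()
    with pytest.raises(ValueError):
        SimulationConfig(junction_depth=0).validate()


def test_sample_sheet_layout(small_config):
    sheet = sample_sheet(small_config)
    assert len(sheet) == 2 * 2 * small_config.replicates
    assert set(sheet.condition) == {"DMSO", "dTAG"}
    assert set(sheet.compartment) == {"nucleus", "cytoplasm"}
    assert not sheet.index.has_duplicates
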