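"""3'-end windows, the A-rich internal-priming rule, PAS assignment,
count-matrix construction and positional classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paspipe.pasquant import (
    PASCountMatrix,
    assign_all,
    assign_pas,
    build_count_matrix,
    classify_pas,
    downstream_window,
    filter_internal_priming,
    is_internal_priming,
    is_internal_priming_batch,
)
from paspipe.readproc import AlignedTag
from paspipe.simulate import Gene, Intron, PASite


def tag(contig="chr1", start=90, end=100, strand="+", rid="r"):
    return AlignedTag(rid, contig, start, end, strand)


class TestDownstreamWindow:
    def test_plus_strand_window(self):
        contig = "G" * 100 + "AAAAAACGTT" + "G" * 50
        t = tag(start=80, end=100, strand="+")  # three_prime = 99
        assert downstream_window(t, {"chr1": contig}) == "AAAAAACGTT"

    def test_minus_strand_window_is_revcomp(self):
        contig = "G" * 40 + "TTTTTTTTGC" + "G" * 100
        t = tag(start=50, end=70, strand="-")  # three_prime = 50
        assert downstream_window(t, {"chr1": contig}) == "GCAAAAAAAA"

    def test_contig_end_pads_with_n(self):
        contig = "G" * 100
        t = tag(start=80, end=100, strand="+")
        assert downstream_window(t, {"chr1": contig}) == "N" * 10

    def test_contig_start_pads_minus_strand(self):
        contig = "G" * 100
        t = tag(start=4, end=30, strand="-")  # only 4 bases upstream exist
        win = downstream_window(t, {"chr1": contig})
        assert len(win) == 10 and win.endswith("NNNNNN")


def _oracle_a_rich(window: str) -> bool:
    """Character-walk oracle: longest A run and total A count."""
    longest = run = total = 0
    for ch in window:
        if ch == "A":
            run += 1
            total += 1
            longest = max(longest, run)
        else:
            run = 0
    return longest >= 6 or total >= 7


class TestInternalPriming:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("AAAAAACGTT", True),  # run of 6
            ("AAAAACAAAC", True),  # 8 A total, no run of 6
            ("AAAAACGTCG", False),  # run 5, total 5
            ("AANAAANAAA", True),  # 8 A with N breaks
            ("AAAAANACGT", False),  # N breaks the run; total 6
            ("NNNNNNNNNN", False),
        ],
    )
    def test_rule_examples(self, window, expected):
        assert is_internal_priming(window) is expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            is_internal_priming("AAAAAA")

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.text(alphabet="ACGTN", min_size=10, max_size=10))
    def test_matches_character_walk_oracle(self, window):
        assert is_internal_priming(window) == _oracle_a_rich(window)

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        wins = rng.choice(list("ACGT"), size=(2000, 10))
        flags = is_internal_priming_batch(wins == "A")
        scalars = [is_internal_priming("".join(w)) for w in wins]
        assert list(flags) == scalars


class TestAssign:
    SITES = [
        PASite("p495", "chr1", "+", 495, "g", "terminal"),
        PASite("p505", "chr1", "+", 505, "g", "IPA"),
        PASite("m505", "chr1", "-", 505, "g", "terminal"),
    ]

    def test_within_flank_assigned(self):
        t = tag(start=480, end=501, strand="+")  # three_prime 500
        assert assign_pas(t, [self.SITES[1]], flank=24) == "p505"

    def test_strand_mismatch_unassigned(self):
        t = tag(start=480, end=501, strand="+")
        assert assign_pas(t, [self.SITES[2]], flank=24) is None

    def test_out_of_flank_unassigned(self):
        t = tag(start=380, end=401, strand="+")
        assert assign_pas(t, self.SITES, flank=24) is None

    def test_distance_tie_broken_upstream(self):
        t = tag(start=480, end=501, strand="+")  # 500: ties 495 vs 505
        assert assign_pas(t, self.SITES, flank=24) == "p495"

    def test_minus_strand_tie_prefers_larger_coordinate(self):
        sites = [
            PASite("a", "chr1", "-", 495, "g", "terminal"),
            PASite("b", "chr1", "-", 505, "g", "terminal"),
        ]
        t = tag(start=500, end=530, strand="-")  # three_prime 500
        assert assign_pas(t, sites, flank=24) == "b"

    def test_assignment_order_invariant(self):
        rng = np.random.default_rng(3)
        sites = [
            PASite(f"p{i}", "chr1", "+", int(p), "g", "terminal")
            for i, p in enumerate(np.sort(rng.choice(10000, 50, replace=False)))
        ]
        tags = [
            tag(start=int(p), end=int(p) + 25, rid=f"r{i}")
            for i, p in enumerate(rng.integers(0, 9900, 200))
        ]
        a1, _ = assign_all(tags, sites)
        perm = list(np.array(tags, dtype=object)[rng.permutation(len(tags))])
        a2, _ = assign_all(perm, sites)
        assert dict((t.read_id, p) for t, p in a1) == dict(
            (t.read_id, p) for t, p in a2
        )


class TestCountMatrix:
    SITES = [
        PASite("S", "chr1", "+", 100, "g", "terminal"),
        PASite("T", "chr1", "+", 500, "g", "IPA"),
    ]
    SAMPLES = pd.DataFrame(
        {"condition": ["DMSO", "dTAG"], "compartment": ["nucleus"] * 2,
         "replicate": [1, 1]},
        index=pd.Index(["A", "B"], name="sample"),
    )

    def test_counting(self):
        mat = build_count_matrix({"A": ["S", "S", "S"], "B": ["T"]},
                                 self.SITES, self.SAMPLES)
        assert mat.counts.loc["S", "A"] == 3
        assert mat.counts.loc["T", "B"] == 1
        assert int(mat.counts.values.sum()) == 4

    def test_zero_sites_retained(self):
        mat = build_count_matrix({"A": [], "B": []}, self.SITES, self.SAMPLES)
        assert list(mat.counts.index) == ["S", "T"]
        assert (mat.counts.values == 0).all()

    def test_unknown_sample_errors(self):
        with pytest.raises(ValueError):
            build_count_matrix({"Z": ["S"]}, self.SITES, self.SAMPLES)

    def test_tsv_round_trip(self, tmp_path):
        mat = build_count_matrix({"A": ["S"], "B": ["T", "T"]},
                                 self.SITES, self.SAMPLES)
        mat.to_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = PASCountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        assert back.counts.equals(mat.counts)
        assert list(back.site_info["pas_class"]) == ["terminal", "IPA"]


class TestClassify:
    GENES = [
        Gene("G", "chr1", "+", 5000,
             exons=[(5000, 5200), (5500, 5700), (6000, 6300)],
             introns=[Intron(5200, 5500, "first"), Intron(5700, 6000, "last")]),
    ]

    def test_intronic_position_is_ipa(self):
        assert classify_pas("chr1", "+", 5800, self.GENES) == "IPA"

    def test_terminal_exon_position(self):
        assert classify_pas("chr1", "+", 6299, self.GENES) == "terminal"

    def test_prompt_upstream_antisense(self):
        assert classify_pas("chr1", "-", 3800, self.GENES, 3000) == "PROMPT"
        # 1,200 nt upstream but beyond a narrow window
        assert classify_pas("chr1", "-", 3800, self.GENES, 1000) == "other"

    def test_sense_upstream_is_not_prompt(self):
        assert classify_pas("chr1", "+", 4800, self.GENES, 3000) == "other"

    def test_intergenic_is_other(self):
        assert classify_pas("chr1", "+", 50000, self.GENES) == "other"

    def test_ipa_precedence_over_terminal(self):
        # overlapping genes: intron of one over terminal exon of another
        genes = self.GENES + [
            Gene("H", "chr1", "+", 5600, exons=[(5600, 5900)], introns=[]),
        ]
        assert classify_pas("chr1", "+", 5800, genes) == "IPA"


def test_filter_sensitivity_and_specificity_on_simulation():
    """Planted decoys are removed and true-PAS tags survive the filter."""
    from paspipe.readproc import process_reads
    from paspipe.simulate import (
        SimulationConfig,
        emit_reads,
        generate_annotation,
        simulate_pas_counts,
    )

    cfg = SimulationConfig(seed=13, n_genes=15, base_mean=15.0,
                           internal_priming_rate=0.25)
    ann = generate_annotation(cfg)
    mat, _ = simulate_pas_counts(ann, cfg)
    reads, truth = emit_reads(ann, mat, cfg)
    ro = truth.read_origins
    n_art = n_art_drop = n_true = n_true_drop = 0
    for sample, rs in reads.items():
        tags, _ = process_reads(rs, ann.contigs, linker=cfg.linker_seq)
        kept, dropped = filter_internal_priming(tags, ann.contigs)
        for t in dropped:
            if ro.loc[t.read_id].origin == "artifact":
                n_art_drop += 1
            else:
                n_true_drop += 1
        for group in (kept, dropped):
            for t in group:
                if ro.loc[t.read_id].origin == "artifact":
                    n_art += 1
                else:
                    n_true += 1
    assert n_art > 200 and n_true > 1000
    assert n_art_drop / n_art >= 0.95
    assert n_true_drop / n_true <= 0.01
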