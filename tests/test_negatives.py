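from collections import Counter

import numpy as np
import pytest
from scipy.stats import binomtest, chisquare

from promoterbench.negatives import (
    BaseFrequencies,
    Gene,
    GenomeAnnotation,
    build_mixed,
    classify_intergenic,
    extract_coding_windows,
    extract_intergenic_windows,
    generate_random_negatives,
    mixed_share_sizes,
    read_annotation_tsv,
    write_annotation_tsv,
)

from conftest import make_set, random_window


class TestBaseFrequencies:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            BaseFrequencies({"A": 0.5, "C": 0.5, "G": 0.5, "T": 0.5})

    def test_all_bases_required(self):
        with pytest.raises(ValueError):
            BaseFrequencies({"A": 0.5, "C": 0.5})


class TestRandomNegatives:
    def test_zero_request_gives_empty_set(self):
        assert len(generate_random_negatives(0, seed=1)) == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            generate_random_negatives(-1, seed=1)

    def test_degenerate_distribution_gives_homopolymer(self):
        freqs = BaseFrequencies({"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0})
        sset = generate_random_negatives(3, freqs=freqs, source_length=500, seed=2)
        assert all(r.residues == "A" * 81 for r in sset)

    def test_pooled_frequencies_match_background(self):
        # chi-square goodness of fit on ~810k pooled bases at alpha = 0.01
        sset = generate_random_negatives(10_000, seed=5)
        counts = Counter("".join(sset.sequences()))
        total = sum(counts.values())
        expected_p = {"T": 0.28, "G": 0.22, "C": 0.22, "A": 0.28}
        for base, p in expected_p.items():
            assert abs(counts[base] / total - p) < 0.01
        observed = [counts[b] for b in "ACGT"]
        expected = [expected_p[b] * total for b in "ACGT"]
        assert chisquare(observed, expected).pvalue > 0.01

    def test_seed_determinism_bit_exact(self):
        a = generate_random_negatives(50, source_length=10_000, seed=9)
        b = generate_random_negatives(50, source_length=10_000, seed=9)
        assert a.sequences() == b.sequences()
        assert [r.id for r in a] == [r.id for r in b]

    def test_window_length_and_alphabet(self):
        sset = generate_random_negatives(20, source_length=5000, window=33, seed=0)
        assert all(len(r) == 33 and set(r.residues) <= set("ACGT") for r in sset)


def _toy_genome(genes, length=600, seed=0):
    rng = np.random.default_rng(seed)
    return GenomeAnnotation(sequence=random_window(rng, length), genes=genes)


class TestGenomeAnnotation:
    def test_gene_containment_rejected(self):
        with pytest.raises(ValueError, match="contained"):
            _toy_genome([Gene("a", 10, 100, "+"), Gene("b", 20, 50, "-")])

    def test_overlap_flagged_not_fatal(self):
        ann = _toy_genome([Gene("a", 10, 100, "+"), Gene("b", 90, 150, "-")])
        assert ann.overlapping_pairs == [("a", "b")]

    def test_tsv_round_trip(self, tmp_path, rng):
        ann = _toy_genome([Gene("a", 10, 100, "+"), Gene("b", 200, 300, "-")])
        p = write_annotation_tsv(ann, tmp_path / "ann.tsv")
        back = read_annotation_tsv(p, ann.sequence)
        assert [(g.id, g.start, g.end, g.strand) for g in back.genes] == [
            ("a", 10, 100, "+"), ("b", 200, 300, "-")
        ]


class TestCodingWindows:
    def test_single_exact_length_gene_forces_placement(self):
        ann = _toy_genome([Gene("g", 101, 181, "+")], length=400)
        sset = extract_coding_windows(ann, 3, window=81, seed=1)
        gene_seq = ann.sequence[100:181]
        assert all(r.residues == gene_seq for r in sset)

    def test_windows_contained_in_gene_bodies(self):
        genes = [Gene("a", 51, 250, "+"), Gene("b", 301, 460, "-")]
        ann = _toy_genome(genes, length=600)
        sset = extract_coding_windows(ann, 40, window=81, seed=3)
        spans = [(g.start - 1, g.end) for g in genes]
        for rec in sset:
            start = int(rec.id.rsplit("_", 1)[1])
            assert any(s <= start and start + 81 <= e for s, e in spans)

    def test_gene_choice_proportional_to_valid_offsets(self):
        # genes of length 181 and 81 offer 101 and 1 valid starts: ~101:1
        ann = _toy_genome([Gene("a", 1, 181, "+"), Gene("b", 301, 381, "+")],
                          length=500)
        sset = extract_coding_windows(ann, 3000, window=81, seed=7)
        n_b = sum(1 for r in sset if int(r.id.rsplit("_", 1)[1]) >= 300)
        assert binomtest(n_b, 3000, p=1 / 102).pvalue > 0.01

    def test_no_long_enough_gene_raises(self):
        ann = _toy_genome([Gene("tiny", 10, 50, "+")], length=200)
        with pytest.raises(ValueError, match="no interval"):
            extract_coding_windows(ann, 1, window=81, seed=0)


class TestClassifyIntergenic:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ("+", "-", "convergent"),
            ("-", "+", "divergent"),
            ("+", "+", "codirectional_pos"),
            ("-", "-", "codirectional_neg"),
        ],
    )
    def test_strand_pair_truth_table(self, s1, s2, expected):
        ann = _toy_genome([Gene("a", 1, 100, s1), Gene("b", 201, 300, s2)])
        assert classify_intergenic(ann) == [(101, 200, expected)]

    def test_zero_gap_pair_skipped(self):
        ann = _toy_genome([Gene("a", 1, 100, "+"), Gene("b", 101, 200, "-")])
        assert classify_intergenic(ann) == []

    def test_every_positive_gap_covered_exactly_once(self):
        genes = [Gene(f"g{i}", 1 + 120 * i, 100 + 120 * i, "+-"[i % 2])
                 for i in range(5)]
        ann = _toy_genome(genes, length=700)
        regions = classify_intergenic(ann)
        assert len(regions) == 4
        starts = [s for s, _, _ in regions]
        assert starts == sorted(starts)

    def test_requires_two_genes(self):
        with pytest.raises(ValueError):
            classify_intergenic(_toy_genome([Gene("a", 1, 50, "+")]))


class TestIntergenicWindows:
    def test_single_81nt_region_forces_identical_windows(self):
        ann = _toy_genome([Gene("a", 1, 100, "+"), Gene("b", 182, 300, "-")],
                          length=400)
        sset = extract_intergenic_windows(ann, "convergent", 2, window=81, seed=1)
        region_seq = ann.sequence[100:181]
        assert sset.sequences() == [region_seq, region_seq]
        assert all(r.source == "convergent" for r in sset)

    def test_windows_never_overlap_gene_bodies(self):
        genes = [Gene("a", 1, 150, "+"), Gene("b", 351, 500, "-"),
                 Gene("c", 701, 850, "+")]
        ann = _toy_genome(genes, length=1000)
        sset = extract_intergenic_windows(ann, "convergent", 50, window=81, seed=2)
        gene_spans = [(g.start - 1, g.end) for g in genes]
        for rec in sset:
            start = int(rec.id.rsplit("_", 1)[1])
            w = (start, start + 81)
            assert all(w[1] <= s or w[0] >= e for s, e in gene_spans)

    def test_missing_category_error_names_it(self):
        ann = _toy_genome([Gene("a", 1, 100, "+"), Gene("b", 201, 300, "-")])
        with pytest.raises(ValueError, match="divergent"):
            extract_intergenic_windows(ann, "divergent", 1, seed=0)

    def test_unknown_category_rejected(self):
        ann = _toy_genome([Gene("a", 1, 100, "+"), Gene("b", 201, 300, "-")])
        with pytest.raises(ValueError, match="unknown category"):
            extract_intergenic_windows(ann, "antisense", 1, seed=0)


class TestBuildMixed:
    def _sources(self, rng, n=120):
        names = ["random", "coding", "convergent", "divergent", "copos", "coneg"]
        return [
            make_set([random_window(rng) for _ in range(n)], name=nm, source=nm)
            for nm in names
        ]

    def test_exact_division_takes_one_each(self, rng):
        out = build_mixed(self._sources(rng), n_total=6, seed=0)
        assert sorted(out.source_counts().values()) == [1] * 6

    def test_579_allocation(self):
        assert mixed_share_sizes(579) == [97, 97, 97, 96, 96, 96]

    def test_histogram_matches_allocation(self, rng):
        sources = self._sources(rng, n=110)
        out = build_mixed(sources, n_total=579, seed=3)
        counts = out.source_counts()
        expected = dict(zip(
            ["random", "coding", "convergent", "divergent", "copos", "coneg"],
            [97, 97, 97, 96, 96, 96],
        ))
        assert counts == expected
        assert len(out) == 579

    def test_insufficient_source_raises(self, rng):
        sources = self._sources(rng, n=2)
        with pytest.raises(ValueError, match="needs"):
            build_mixed(sources, n_total=30, seed=0)

    def test_seed_determinism(self, rng):
        sources = self._sources(rng, n=50)
        a = build_mixed(sources, 30, seed=11)
        b = build_mixed(sources, 30, seed=11)
        assert a.sequences() == b.sequences()
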