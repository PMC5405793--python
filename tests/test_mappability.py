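import numpy as np
import pytest

from dangertrack.mappability import (
    MISSING_AS_ZERO,
    MISSING_EXCLUDED,
    kmer_mappability,
    read_mappability,
    window_uniqueness,
    write_mappability_bedgraph,
)
from dangertrack.windows import GenomeLayout, make_windows


def brute_force_occurrences(sequences: dict[str, str], kmer: str) -> int:
    """Independent oracle: overlapping occurrence count via str.find."""
    n = 0
    for s in sequences.values():
        i = s.find(kmer)
        while i != -1:
            n += 1
            i = s.find(kmer, i + 1)
    return n


class TestReadMappability:
    def test_bedgraph_interval(self, tmp_path):
        layout = GenomeLayout(("chrA",), (200,))
        p = tmp_path / "m.bedgraph"
        p.write_text("chrA\t0\t100\t1.0\n")
        t = read_mappability(p, layout)
        v = t.values_at("chrA")
        assert (v[:100] == 1.0).all() and np.isnan(v[100:]).all()

    def test_fixedstep_wiggle_one_based_shift(self, tmp_path):
        layout = GenomeLayout(("chrA",), (10,))
        p = tmp_path / "m.wig"
        p.write_text("fixedStep chrom=chrA start=1 step=1\n1.0\n0.5\n0.25\n")
        v = read_mappability(p, layout).values_at("chrA")
        assert v[0] == 1.0 and v[1] == 0.5 and v[2] == 0.25 and np.isnan(v[3])

    def test_variablestep_wiggle(self, tmp_path):
        layout = GenomeLayout(("chrA",), (10,))
        p = tmp_path / "m.wig"
        p.write_text("variableStep chrom=chrA\n5\t0.5\n7\t1.0\n")
        v = read_mappability(p, layout).values_at("chrA")
        assert v[4] == 0.5 and v[6] == 1.0 and np.isnan(v[5])

    def test_value_out_of_range_rejected(self, tmp_path):
        layout = GenomeLayout(("chrA",), (200,))
        p = tmp_path / "bad.bedgraph"
        p.write_text("chrA\t0\t100\t1.5\n")
        with pytest.raises(ValueError, match="outside"):
            read_mappability(p, layout)

    def test_overlapping_intervals_rejected(self, tmp_path):
        layout = GenomeLayout(("chrA",), (200,))
        p = tmp_path / "ov.bedgraph"
        p.write_text("chrA\t0\t100\t1.0\nchrA\t50\t150\t0.5\n")
        with pytest.raises(ValueError, match="overlap"):
            read_mappability(p, layout)

    def test_unknown_chrom_skipped(self, tmp_path):
        layout = GenomeLayout(("chrA",), (200,))
        p = tmp_path / "m.bedgraph"
        p.write_text("chrZ\t0\t10\t1.0\nchrA\t0\t10\t1.0\n")
        t = read_mappability(p, layout)
        assert set(t.intervals) == {"chrA"}

    def test_write_read_round_trip_bit_exact(self, tmp_path, rng):
        layout = GenomeLayout(("chrA",), (500,))
        p = tmp_path / "m.bedgraph"
        vals = rng.uniform(0, 1, 10)
        p.write_text("".join(f"chrA\t{i * 50}\t{i * 50 + 40}\t{float(v)!r}\n" for i, v in enumerate(vals)))
        t = read_mappability(p, layout)
        q = tmp_path / "m2.bedgraph"
        write_mappability_bedgraph(t, q)
        t2 = read_mappability(q, layout)
        for (s1, e1, v1), (s2, e2, v2) in zip(zip(*t.intervals["chrA"]), zip(*t2.intervals["chrA"])):
            assert (s1, e1) == (s2, e2) and v1 == v2  # bit-exact


class TestWindowUniqueness:
    @pytest.fixture
    def layout(self):
        return GenomeLayout(("chrA",), (5000,))

    def test_fully_unique_window_scores_zero(self, tmp_path, layout):
        p = tmp_path / "m.bedgraph"
        p.write_text("chrA\t0\t5000\t1.0\n")
        grid = make_windows(layout, 5000)
        u = window_uniqueness(read_mappability(p, layout), grid)
        assert u.values.tolist() == [0.0]

    def test_constant_half_mappability(self, tmp_path, layout):
        p = tmp_path / "m.bedgraph"
        p.write_text("chrA\t0\t5000\t0.5\n")
        grid = make_windows(layout, 5000)
        u = window_uniqueness(read_mappability(p, layout), grid)
        assert u.values.tolist() == [0.5]

    def test_partial_coverage_missing_as_zero(self, tmp_path, layout):
        """2000 of 5000 bases at m=1, rest undefined -> u = 1 - 2000/5000."""
        p = tmp_path / "m.bedgraph"
        p.write_text("chrA\t0\t2000\t1.0\n")
        grid = make_windows(layout, 5000)
        u = window_uniqueness(read_mappability(p, layout), grid, MISSING_AS_ZERO)
        np.testing.assert_allclose(u.values, [0.6])

    def test_partial_coverage_missing_excluded(self, tmp_path, layout):
        p = tmp_path / "m.bedgraph"
        p.write_text("chrA\t0\t2000\t1.0\n")
        grid = make_windows(layout, 5000)
        u = window_uniqueness(read_mappability(p, layout), grid, MISSING_EXCLUDED)
        assert u.values.tolist() == [0.0]

    def test_uncovered_window_missing_excluded_is_one(self, tmp_path):
        layout = GenomeLayout(("chrA",), (10000,))
        p = tmp_path / "m.bedgraph"
        p.write_text("chrA\t0\t5000\t1.0\n")
        grid = make_windows(layout, 5000)
        u = window_uniqueness(read_mappability(p, layout), grid, MISSING_EXCLUDED)
        assert u.values.tolist() == [0.0, 1.0]

    def test_unknown_policy_rejected(self, tmp_path, layout):
        p = tmp_path / "m.bedgraph"
        p.write_text("chrA\t0\t10\t1.0\n")
        with pytest.raises(ValueError):
            window_uniqueness(read_mappability(p, layout), make_windows(layout, 5000), "bogus")

    @pytest.mark.parametrize("policy", [MISSING_AS_ZERO, MISSING_EXCLUDED])
    def test_interval_aggregation_matches_per_base_expansion(self, tmp_path, rng, policy):
        """Interval-wise window means equal a naive per-base expansion."""
        layout = GenomeLayout(("c1", "c2"), (3777, 2100))
        grid = make_windows(layout, 500)
        lines = []
        for chrom, n in layout.items():
            pos = 0
            while pos < n:
                length = int(rng.integers(1, 400))
                end = min(pos + length, n)
                if rng.random() < 0.7:  # leave gaps
                    lines.append(f"{chrom}\t{pos}\t{end}\t{rng.uniform():.6f}")
                pos = end
        p = tmp_path / "r.bedgraph"
        p.write_text("\n".join(lines) + "\n")
        track = read_mappability(p, layout)
        u = window_uniqueness(track, grid, policy)
        expected = []
        for chrom, n in layout.items():
            v = track.values_at(chrom)
            for s in range(0, n, 500):
                w = v[s : min(s + 500, n)]
                if policy == MISSING_AS_ZERO:
                    expected.append(1 - np.nan_to_num(w).mean())
                else:
                    expected.append(1 - np.nanmean(w) if np.isfinite(w).any() else 1.0)
        np.testing.assert_allclose(u.values, expected, atol=1e-12)


class TestKmerMappability:
    def test_repeated_four_mer(self):
        """ACGT occurs at 0 and 4 of ACGTACGTAA -> m = 0.5 at both."""
        t = kmer_mappability({"c": "ACGTACGTAA"}, k=4)
        v = t.values_at("c", 10)
        assert v[0] == 0.5 and v[4] == 0.5
        assert np.isnan(v[7:]).all()  # no full 4-mer starts after position 6

    def test_all_unique_genome_scores_one(self, rng):
        # draw until no repeated 50-mer (overwhelmingly likely first try)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        kmers = {seq[i : i + 50] for i in range(951)}
        if len(kmers) == 951:
            v = kmer_mappability({"c": seq}, 50).values_at("c", 1000)
            assert (v[:951] == 1.0).all()

    def test_tandem_duplication_halves_mappability(self, rng):
        x = "".join(rng.choice(list("ACGT"), 300))
        t = kmer_mappability({"c": x + x}, k=50)
        v = t.values_at("c", 600)
        # k-mers fully inside either copy occur >= twice
        assert (v[:251] <= 0.5).all() and (v[300:551] <= 0.5).all()

    def test_matches_brute_force_counter(self, rng):
        seqs = {
            "c1": "".join(rng.choice(list("ACGT"), 400)),
            "c2": "".join(rng.choice(list("ACGT"), 250)),
        }
        seqs["c2"] = seqs["c2"][:100] + seqs["c1"][50:120] + seqs["c2"][170:]
        for k in (5, 21):
            t = kmer_mappability(seqs, k)
            for chrom, s in seqs.items():
                v = t.values_at(chrom, len(s))
                for i in range(len(s) - k + 1):
                    assert v[i] == 1.0 / brute_force_occurrences(seqs, s[i : i + k])

    def test_values_are_reciprocals_of_integers(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 500))
        v = kmer_mappability({"c": seq + seq[:100]}, 10).values_at("c", 600)
        defined = v[np.isfinite(v)]
        inv = 1.0 / defined
        np.testing.assert_allclose(inv, np.round(inv))
        assert (inv >= 1).all()

    def test_chromosome_order_invariance(self, rng):
        a = "".join(rng.choice(list("ACGT"), 200))
        b = "".join(rng.choice(list("ACGT"), 150))
        t1 = kmer_mappability({"x": a, "y": b}, 8)
        t2 = kmer_mappability({"y": b, "x": a}, 8)
        np.testing.assert_array_equal(t1.values_at("x", 200), t2.values_at("x", 200))

    def test_non_acgt_positions_undefined(self):
        t = kmer_mappability({"c": "ACGTNACGTACGT"}, 4)
        v = t.values_at("c", 13)
        assert np.isnan(v[1:5]).all()  # any 4-mer touching the N
        assert np.isfinite(v[5])

    def test_reverse_complement_counting(self):
        # GATC is its own reverse complement: no double counting
        t = kmer_mappability({"c": "GATCAAATTTCCC"}, 4, count_reverse_complement=True)
        assert t.values_at("c", 13)[0] == 1.0
        # ACGT's RC present elsewhere
        t2 = kmer_mappability({"c": "AACGTTTTACGTTT"}, 5, count_reverse_complement=False)
        v_f = t2.values_at("c", 14)
        t3 = kmer_mappability({"c": "AACGTTTTACGTTT"}, 5, count_reverse_complement=True)
        v_rc = t3.values_at("c", 14)
        assert np.all(v_rc[np.isfinite(v_rc)] <= v_f[np.isfinite(v_f)])

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kmer_mappability({"c": "ACGT"}, 0)
        with pytest.raises(ValueError):
            kmer_mappability({"c": "ACGT"}, 5)

    def test_uniqueness_zero_iff_no_repeats(self, rng):
        """Self-consistency, both directions on tiny genomes."""
        unique = {"c": "ACGTTGCAAC"}  # all 3-mers distinct
        t = kmer_mappability(unique, 3)
        grid = make_windows(GenomeLayout(("c",), (10,)), 10)
        u = window_uniqueness(t, grid, MISSING_EXCLUDED)
        assert u.values[0] == 0.0
        repeated = {"c": "ACGACGTTTT"}  # ACG twice
        u2 = window_uniqueness(
            kmer_mappability(repeated, 3), make_windows(GenomeLayout(("c",), (10,)), 10),
            MISSING_EXCLUDED,
        )
        assert u2.values[0] > 0.0

    def test_k50_and_k100_uniqueness_positively_correlated(self, reference_bundle):
        """Short- and long-k uniqueness agree on where repeats are."""
        from scipy.stats import pearsonr

        from dangertrack.windows import read_genome_layout
        from dangertrack.mappability import read_mappability

        spec, paths = reference_bundle
        layout = read_genome_layout(paths["chrom_sizes"])
        grid = make_windows(layout, spec.window_size)
        u = {}
        for k in (50, 100):
            track = read_mappability(paths[f"mappability_k{k}"], layout, k=k)
            u[k] = window_uniqueness(track, grid).values
        assert pearsonr(u[50], u[100]).statistic > 0
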