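"""Trinucleotide context collapse, frequency matrices, and rate normalization."""
from itertools import product

import numpy as np
import pytest

from nucperiod import (
    DyadPosition,
    GenomeSequence,
    MutationRecord,
    NucperiodError,
    build_context_frequencies,
    estimate_context_rates,
    normalize_counts,
    trinucleotide_context,
)
from nucperiod.counting import DyadRelativeCounts, map_mutations_to_dyads
from nucperiod.fixtures import generate_dyad_map, generate_periodic_mutations, generate_toy_genome, PeriodicIntensityModel
from nucperiod.normalization import (
    PYRIMIDINE_CONTEXTS,
    collapse_trinucleotide,
    reverse_complement,
)


class TestContextCollapse:
    def test_purine_center_reverse_complemented(self):
        g = GenomeSequence({"chr1": "ACGTA"})
        assert trinucleotide_context(g, "chr1", 2) == "ACG"  # CGT -> rc

    def test_pyrimidine_center_unchanged(self):
        g = GenomeSequence({"chr1": "ACTTA"})
        assert trinucleotide_context(g, "chr1", 2) == "CTT"

    def test_edge_positions_are_boundary_errors(self):
        g = GenomeSequence({"chr1": "ACGTA"})
        for pos in (0, 4):
            with pytest.raises(ValueError):
                trinucleotide_context(g, "chr1", pos)

    def test_n_in_triplet_is_invalid(self):
        g = GenomeSequence({"chr1": "ANCTA"})
        assert trinucleotide_context(g, "chr1", 2) == "invalid"

    def test_all_64_raw_trimers_collapse_two_to_one(self):
        collapsed = {}
        for tri in map("".join, product("ACGT", repeat=3)):
            collapsed.setdefault(collapse_trinucleotide(tri), []).append(tri)
        assert set(collapsed) == set(PYRIMIDINE_CONTEXTS)
        for ctx, members in collapsed.items():
            assert len(members) == 2
            assert ctx in members or reverse_complement(ctx) in members


class TestContextFrequencies:
    def test_single_dyad_radius_one(self):
        g = GenomeSequence({"chr1": "GACTC"})  # window ACT with flanks G,C
        m = build_context_frequencies(g, [DyadPosition("chr1", 2)], radius=1)
        assert m.freq.sum() == 3
        # offset -1: GAC -> rc GTC; offset 0: ACT; offset +1: CTC
        assert m.freq[PYRIMIDINE_CONTEXTS.index("GTC"), 0] == 1
        assert m.freq[PYRIMIDINE_CONTEXTS.index("ACT"), 1] == 1
        assert m.freq[PYRIMIDINE_CONTEXTS.index("CTC"), 2] == 1

    def test_duplicated_window_doubles_matrix(self):
        g = GenomeSequence({"chr1": "GACTCAAGACTCAA"})
        one = build_context_frequencies(g, [DyadPosition("chr1", 2)], radius=1)
        two = build_context_frequencies(
            g, [DyadPosition("chr1", 2), DyadPosition("chr1", 9)], radius=1
        )
        assert np.array_equal(two.freq, 2 * one.freq)

    def test_matches_per_position_recount(self, small_genome_dyads):
        genome, dyads = small_genome_dyads
        radius = 20
        m = build_context_frequencies(genome, dyads, radius)
        oracle = np.zeros_like(m.freq)
        for d in dyads:
            for j, p in enumerate(range(d.pos - radius, d.pos + radius + 1)):
                ctx = trinucleotide_context(genome, d.chrom, p)
                if ctx != "invalid":
                    oracle[PYRIMIDINE_CONTEXTS.index(ctx), j] += 1
        assert np.array_equal(m.freq, oracle)

    def test_column_sums_equal_dyads_minus_invalid(self, small_genome_dyads):
        genome, dyads = small_genome_dyads
        m = build_context_frequencies(genome, dyads, 30)
        assert np.array_equal(m.freq.sum(axis=0) + m.n_invalid, np.full(61, m.n_dyads))


class TestContextRates:
    def test_direct_ratio(self):
        freq = np.zeros((32, 3), dtype=np.int64)
        i = PYRIMIDINE_CONTEXTS.index("ACA")
        freq[i, :] = [400, 300, 300]  # 1000 occurrences total
        from nucperiod.normalization import ContextFrequencyMatrix

        m = ContextFrequencyMatrix(1, freq, 1000, np.zeros(3, dtype=np.int64))
        muts = [MutationRecord("chr1", 0, context="ACA") for _ in range(10)]
        rates = estimate_context_rates(muts, m)
        assert rates["ACA"] == pytest.approx(0.01)
        assert rates["CCC"] == 0.0  # never mutated

    def test_no_valid_context_mutations_is_error(self):
        from nucperiod.normalization import ContextFrequencyMatrix

        m = ContextFrequencyMatrix(1, np.ones((32, 3), dtype=np.int64), 1, np.zeros(3, int))
        with pytest.raises(NucperiodError):
            estimate_context_rates([MutationRecord("chr1", 0, context="invalid")], m)

    def test_uniform_process_gives_equal_rates_within_noise(self):
        genome = generate_toy_genome(1, 30_000, 0.5, seed=31)
        dyads = generate_dyad_map(genome, 160, 80, seed=31)
        model = PeriodicIntensityModel(period=10.2, amplitude=0.0, window_radius=73)
        muts = generate_periodic_mutations(genome, dyads, model, 50_000, seed=32)
        freqs = build_context_frequencies(genome, dyads, 73)
        rates = estimate_context_rates(muts, freqs, genome)
        vals = np.array([rates[c] for c in PYRIMIDINE_CONTEXTS])
        totals = freqs.context_totals
        # a context-blind process mutates every occurrence at the same rate
        overall = 50_000 / totals.sum()
        sds = np.sqrt(overall / totals)  # Poisson approximation per context
        assert np.all(np.abs(vals - overall) < 4 * sds)

    def test_strand_collapse_invariance_under_reverse_complement(self):
        genome = generate_toy_genome(1, 5000, 0.45, seed=33)
        dyads = generate_dyad_map(genome, 160, 80, seed=33)
        model = PeriodicIntensityModel(period=10.2, amplitude=0.4, window_radius=73)
        muts = generate_periodic_mutations(genome, dyads, model, 2000, seed=34)
        freqs = build_context_frequencies(genome, dyads, 73)
        rates = estimate_context_rates(muts, freqs, genome)

        length = genome.chrom_length("chr1")
        rc_genome = GenomeSequence(
            {"chr1": reverse_complement(genome.fetch("chr1", 0, length))}
        )
        rc_dyads = sorted(DyadPosition("chr1", length - 1 - d.pos) for d in dyads)
        rc_muts = sorted(
            MutationRecord("chr1", length - 1 - m.pos) for m in muts
        )
        rc_freqs = build_context_frequencies(rc_genome, rc_dyads, 73)
        rc_rates = estimate_context_rates(rc_muts, rc_freqs, rc_genome)
        assert np.array_equal(rc_freqs.freq, freqs.freq[:, ::-1])
        for ctx in PYRIMIDINE_CONTEXTS:
            assert rc_rates[ctx] == pytest.approx(rates[ctx])


class TestNormalizeCounts:
    def _matrix(self, freq):
        from nucperiod.normalization import ContextFrequencyMatrix

        return ContextFrequencyMatrix(
            (freq.shape[1] - 1) // 2, freq, int(freq.sum(axis=0).max()),
            np.zeros(freq.shape[1], dtype=np.int64),
        )

    def test_flat_identity(self):
        freq = np.zeros((32, 5), dtype=np.int64)
        freq[:4, :] = 25  # uniform composition over four contexts
        rates = {c: 0.02 for c in PYRIMIDINE_CONTEXTS}
        obs = DyadRelativeCounts(2, np.full(5, 7, dtype=np.int64), 100, 35, 35)
        norm = normalize_counts(obs, self._matrix(freq), rates)
        assert np.allclose(norm.normalized, 1.0)

    def test_designed_composition_gradient_normalizes_flat(self):
        # two contexts with a 2-fold abundance gradient and 4-fold rate gap;
        # observed built as the exact expectation must normalize to exactly 1
        freq = np.zeros((32, 3), dtype=np.int64)
        ia, ib = PYRIMIDINE_CONTEXTS.index("ACA"), PYRIMIDINE_CONTEXTS.index("GCG")
        freq[ia] = [100, 150, 200]
        freq[ib] = [200, 150, 100]
        rates = dict.fromkeys(PYRIMIDINE_CONTEXTS, 0.0)
        rates["ACA"], rates["GCG"] = 0.04, 0.02  # integer-valued expectation
        expected = 0.04 * freq[ia] + 0.02 * freq[ib]
        assert np.allclose(expected, np.round(expected))
        obs = DyadRelativeCounts(
            1, expected.astype(np.int64), 300, int(expected.sum()), int(expected.sum())
        )
        assert obs.counts[0] != obs.counts[2]  # observed gradient is real
        norm = normalize_counts(obs, self._matrix(freq), rates)
        assert np.allclose(norm.normalized, 1.0, atol=1e-12)

    def test_background_self_normalization_is_one(self):
        rng = np.random.default_rng(40)
        c = rng.integers(1, 500, 147)
        obs = DyadRelativeCounts(73, c, 10, int(c.sum()), int(c.sum()))
        norm = normalize_counts(obs, background=obs)
        assert np.allclose(norm.normalized, 1.0)

    def test_mass_conservation(self, small_genome_dyads):
        genome, dyads = small_genome_dyads
        model = PeriodicIntensityModel(period=10.2, amplitude=0.6, window_radius=73)
        muts = generate_periodic_mutations(genome, dyads, model, 20_000, seed=41)
        counts = map_mutations_to_dyads(muts, dyads, 73, genome)
        freqs = build_context_frequencies(genome, dyads, 73)
        rates = estimate_context_rates(muts, freqs, genome)
        norm = normalize_counts(counts, freqs, rates)
        assert norm.expected.sum() == pytest.approx(counts.counts.sum(), rel=1e-9)
        assert np.all(norm.normalized[norm.defined] >= 0)

    def test_zero_expected_position_flagged_undefined(self):
        freq = np.zeros((32, 3), dtype=np.int64)
        i = PYRIMIDINE_CONTEXTS.index("ACA")
        freq[i] = [10, 0, 10]
        rates = dict.fromkeys(PYRIMIDINE_CONTEXTS, 0.0)
        rates["ACA"] = 0.1
        obs = DyadRelativeCounts(1, np.array([3, 2, 3]), 10, 8, 8)
        norm = normalize_counts(obs, self._matrix(freq), rates)
        assert np.isnan(norm.normalized[1]) and norm.defined.sum() == 2

    def test_requires_exactly_one_mode(self):
        obs = DyadRelativeCounts(1, np.array([1, 1, 1]), 1, 3, 3)
        with pytest.raises(ValueError):
            normalize_counts(obs)
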