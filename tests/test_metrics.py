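import itertools
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from tcrdyn.metrics import (
    convergence_frequency,
    percent_decline,
    pielou_evenness,
    rarefy,
    shannon_diversity,
    unique_clone_count,
)
from tcrdyn.model import Clonotype, RepertoireSample
from tcrdyn.simulate import sample_repertoire, synonymous_variants

from conftest import brute_force_convergent_classes


class TestShannonAndEvenness:
    def test_uniform_reaches_log_s(self):
        for s in (2, 4, 10):
            freqs = np.full(s, 1.0 / s)
            assert shannon_diversity(freqs) == pytest.approx(math.log(s), abs=1e-12)
            assert pielou_evenness(freqs) == pytest.approx(1.0, abs=1e-12)

    def test_single_clone(self):
        assert shannon_diversity([1.0]) == 0.0
        assert math.isnan(pielou_evenness([1.0]))

    def test_skewed_example(self):
        assert shannon_diversity([0.5, 0.25, 0.25]) == pytest.approx(1.039721, abs=1e-6)
        assert pielou_evenness([0.5, 0.25, 0.25]) == pytest.approx(0.946395, abs=1e-6)

    @pytest.mark.parametrize("bad", [[0.5, 0.5, 0.0], [0.6, 0.6], [-0.1, 1.1], []])
    def test_invalid_frequency_vectors_rejected(self, bad):
        with pytest.raises(ValueError):
            shannon_diversity(bad)

    def test_entropy_bounded_by_log_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = int(rng.integers(2, 50))
            freqs = rng.dirichlet(np.ones(s))
            freqs = freqs[freqs > 0]
            freqs /= freqs.sum()
            h = shannon_diversity(freqs)
            assert 0.0 <= h <= math.log(freqs.size) + 1e-12

    def test_evenness_invariant_under_permutation(self):
        rng = np.random.default_rng(1)
        freqs = rng.dirichlet(np.ones(12))
        j = pielou_evenness(freqs)
        for _ in range(5):
            assert pielou_evenness(rng.permutation(freqs)) == pytest.approx(j, abs=1e-12)


class TestPercentDecline:
    @pytest.mark.parametrize(
        "pre,post,rounded,unrounded",
        [
            (2248, 1335, 41, 40.6),
            (3318, 2790, 16, 15.9),
            (100, 100, 0, 0.0),
        ],
    )
    def test_worked_examples(self, pre, post, rounded, unrounded):
        value = percent_decline(pre, post)
        assert round(value) == rounded
        assert value == pytest.approx(unrounded, abs=0.05)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_decline(0, 5)


class TestRarefaction:
    def _sample(self, counts):
        nts = synonymous_variants("CASSIRSSYEQYF", len(counts), seed=5)
        return RepertoireSample(
            clonotypes=[
                Clonotype(nt, "CASSIRSSYEQYF", f"TRBV{i}", "TRBJ2-1", c)
                for i, (nt, c) in enumerate(zip(nts, counts))
            ]
        )

    def test_full_depth_is_identity(self):
        s = self._sample([5, 3, 2])
        r = rarefy(s, 10, seed=0)
        assert [c.count for c in r.clonotypes] == [5, 3, 2]

    def test_depth_beyond_sample_rejected(self):
        with pytest.raises(ValueError):
            rarefy(self._sample([5, 3]), 100, seed=0)

    @pytest.mark.parametrize("depth", [0, -3])
    def test_nonpositive_depth_rejected(self, depth):
        with pytest.raises(ValueError):
            rarefy(self._sample([5, 3]), depth, seed=0)

    def test_deterministic_given_seed_and_bounded_by_original(self):
        s = self._sample([40, 25, 10, 5])
        a = rarefy(s, 30, seed=42)
        b = rarefy(s, 30, seed=42)
        assert [c.count for c in a.clonotypes] == [c.count for c in b.clonotypes]
        assert a.depth == 30
        orig = {c.key: c.count for c in s.clonotypes}
        assert all(c.count <= orig[c.key] for c in a.clonotypes)

    def test_matches_read_level_subsampling_oracle(self):
        """Drawn counts follow the exact distribution of shuffling the read
        pool and taking the first `depth` reads (computed by enumeration)."""
        counts = (5, 3, 2)
        depth = 5
        s = self._sample(list(counts))
        # exact oracle: enumerate all C(10,5) read subsets
        reads = [i for i, c in enumerate(counts) for _ in range(c)]
        outcomes = {}
        for subset in itertools.combinations(range(len(reads)), depth):
            key = tuple(sum(1 for r in subset if reads[r] == i) for i in range(3))
            outcomes[key] = outcomes.get(key, 0) + 1
        total = sum(outcomes.values())
        keys = sorted(outcomes)
        expected_p = np.array([outcomes[k] / total for k in keys])

        rng = np.random.default_rng(123)
        observed = {k: 0 for k in keys}
        n_rep = 1000
        for _ in range(n_rep):
            r = rarefy(s, depth, seed=rng)
            drawn = {c.key: c.count for c in r.clonotypes}
            key = tuple(drawn.get(c.key, 0) for c in s.clonotypes)
            observed[key] += 1
        obs = np.array([observed[k] for k in keys])
        _, p = chisquare(obs, f_exp=expected_p * n_rep)
        assert p > 0.01

    def test_expected_counts_proportional_to_original(self):
        s = self._sample([60, 30, 10])
        depth = 50
        rng = np.random.default_rng(7)
        totals = np.zeros(3)
        n_rep = 500
        for _ in range(n_rep):
            r = rarefy(s, depth, seed=rng)
            drawn = {c.key: c.count for c in r.clonotypes}
            totals += [drawn.get(c.key, 0) for c in s.clonotypes]
        expected = np.array([60, 30, 10]) * depth / 100
        assert np.allclose(totals / n_rep, expected, atol=0.5)


class TestConvergenceFrequency:
    def test_toy_example(self, convergent_toy_sample):
        assert convergence_frequency(convergent_toy_sample) == pytest.approx(0.70)

    def test_no_groups_gives_zero(self):
        s = RepertoireSample(
            clonotypes=[
                Clonotype("TGTGCCAGCAGC", "CASS", "TRBV5-1", "TRBJ2-1", 5),
                Clonotype("TGTGCCAGCTTC", "CASF", "TRBV5-1", "TRBJ2-1", 5),
            ]
        )
        assert convergence_frequency(s) == 0.0

    def test_matches_brute_force_grouping(self):
        sample = sample_repertoire(
            n_clones=120, abundance_shape=1.0, depth=3000,
            convergence_injection=0.12, seed=21,
        )
        oracle = brute_force_convergent_classes(sample)
        expected = sum(count for _, count in oracle.values()) / sample.depth
        assert convergence_frequency(sample) == pytest.approx(expected, abs=1e-12)

    def test_adding_synonymous_variant_never_decreases(self):
        base = sample_repertoire(
            n_clones=80, abundance_shape=1.0, depth=1500,
            convergence_injection=0.1, seed=2,
        )
        before = convergence_frequency(base)
        target = base.clonotypes[0]
        variants = synonymous_variants(target.cdr3_aa, 5, seed=3)
        new_nt = next(v for v in variants if v != target.cdr3_nt)
        extended = RepertoireSample(
            clonotypes=base.clonotypes
            + [Clonotype(new_nt, target.cdr3_aa, target.v_gene, target.j_gene, 10)]
        )
        assert convergence_frequency(extended) >= before


class TestUniqueCloneCount:
    def test_distinct_keys(self, convergent_toy_sample):
        assert unique_clone_count(convergent_toy_sample) == 3

    def test_empty(self):
        assert unique_clone_count(RepertoireSample(clonotypes=[])) == 0

    def test_matches_hash_set_oracle(self):
        sample = sample_repertoire(
            n_clones=300, abundance_shape=1.0, depth=5000,
            convergence_injection=0.05, seed=4,
        )
        oracle = len({(c.cdr3_nt, c.v_gene, c.j_gene) for c in sample.clonotypes})
        assert unique_clone_count(sample) == oracle
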