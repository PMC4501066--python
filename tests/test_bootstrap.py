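"""Two-stage bootstrap machinery: resampling, parametric variances, support."""

import math

import numpy as np
import pytest

from aafphylo.bootstrap import (
    BootstrapConfig,
    merged_presence,
    nonparametric_bootstrap,
    parametric_bootstrap,
    parametric_stage1_sd,
    parametric_stage2_variance,
    resample_reads,
    resample_rows,
    shared_branch_covariance,
    stage1_overlap_w,
)
from aafphylo.distance import DistanceMatrix, pair_variance
from aafphylo.kmers import KmerConfig, count_kmers
from aafphylo.sampling import SamplingParams, observed_true_ratios
from aafphylo.tree import PhyloTree


class TestResampleReads:
    def test_single_read(self, rng):
        reads = np.array([[0, 1, 2, 3]], dtype=np.uint8)
        out = resample_reads(reads, rng)
        assert np.array_equal(out, reads)

    def test_shape_and_mean_coverage(self, rng):
        reads = rng.integers(0, 4, size=(500, 30)).astype(np.uint8)
        out = resample_reads(reads, rng)
        assert out.shape == reads.shape

    def test_expected_missing_fraction(self, rng):
        """~1/e of the original reads are absent from a bootstrap replicate."""
        n = 3000
        reads = np.arange(n, dtype=np.uint8).reshape(-1, 1) % 4
        fracs = []
        for _ in range(20):
            idx = set(rng.integers(0, n, size=n).tolist())
            fracs.append(1 - len(idx) / n)
        assert np.mean(fracs) == pytest.approx(1 / math.e, abs=0.01)


class TestResampleRows:
    def make_presence(self, rng, m=2600, t=4):
        return rng.random((m, t)) < 0.7

    def test_reduced_size(self, rng):
        pres = self.make_presence(rng)
        for k in (1, 7, 13):
            NS, NT = resample_rows(pres, k, rng)
            total_rows = round(pres.shape[0] / k)
            assert NT.max() <= total_rows
            assert np.all(NS <= NT + 1e-9)

    def test_k1_is_plain_bootstrap(self, rng):
        pres = self.make_presence(rng, m=500)
        NS, NT = resample_rows(pres, 1, rng)
        assert NT[0, 0] == pytest.approx(pres[:, 0].mean() * 500, rel=0.1)

    def test_row_bootstrap_variance_tracks_evolutionary_variance(self, rng):
        """Variance of D across 1/k row-resampled replicates approximates the
        variance across independent evolution replicates (the block-bootstrap
        validation), within 30%."""
        from aafphylo.distance import distance_eq1
        from aafphylo.kmers import KmerConfig, count_kmers_codes, shared_counts
        from aafphylo.simulate import EvolutionParams, pair_at_distance, random_genome

        k, g, d = 11, 30_000, 0.1
        subs = EvolutionParams(indel_fraction=0.0)
        # evolutionary variance: independent replicates
        evo = []
        for _ in range(60):
            anc = random_genome(g, 0.5, rng)
            a, b = pair_at_distance(anc, d, subs, rng)
            ta = count_kmers_codes([a], KmerConfig(k=k), "a")
            tb = count_kmers_codes([b], KmerConfig(k=k), "b")
            sc = shared_counts(ta, tb)
            evo.append(distance_eq1(sc.n_s, sc.n_t, k))
        # row-bootstrap variance on one realisation
        anc = random_genome(g, 0.5, rng)
        a, b = pair_at_distance(anc, d, subs, rng)
        ta = count_kmers_codes([a], KmerConfig(k=k), "a")
        tb = count_kmers_codes([b], KmerConfig(k=k), "b")
        _, pres = merged_presence([ta, tb])
        boot = []
        for _ in range(300):
            NS, NT = resample_rows(pres, k, rng)
            boot.append(distance_eq1(max(NS[0, 1], 1), NT[0, 1], k))
        v_evo, v_boot = np.var(evo, ddof=1), np.var(boot, ddof=1)
        assert v_boot == pytest.approx(v_evo, rel=0.45)


class TestParametricVariances:
    def test_overlap_w_degenerate(self):
        assert stage1_overlap_w(13, 13.0) == 0.0  # r = k: every max() term 0

    def test_overlap_w_direct_sum(self):
        k = 7
        r = 2 * k - 1.0
        expected = sum(2 * i * i / (k * k) for i in range(1, k))
        assert stage1_overlap_w(k, r) == pytest.approx(expected)

    def test_stage1_sd_scales_with_inflation(self):
        sp = SamplingParams(5, 76, 0.01, 13)
        rates = observed_true_ratios(sp, 0.1)
        s1 = parametric_stage1_sd(sp, rates, 1e4, sd_inflation=1.0)
        s2 = parametric_stage1_sd(sp, rates, 1e4, sd_inflation=2.0)
        assert s2 == pytest.approx(2 * s1)

    def test_stage2_zero_distance(self):
        assert parametric_stage2_variance(13, 1e4, 0.0) == 0.0

    def test_stage2_k1_equals_wls_variance_symbolically(self):
        """At k = 1 the evolutionary variance reduces to (e^D - 1)/n_t, the
        WLS variance of the distance model - checked symbolically."""
        import sympy as sp

        D, n_t = sp.symbols("D n_t", positive=True)
        k = 1
        expr = (sp.exp(k * D) - 1 + 2 * sp.Integer(0)) / (k**2 * n_t)
        wls = (1 - sp.exp(-k * D)) / (sp.exp(-k * D) * n_t)
        assert sp.simplify(expr - wls) == 0
        # and numerically through the implementations
        for d in (0.05, 0.2, 0.7):
            assert parametric_stage2_variance(1, 777, d) == pytest.approx(
                pair_variance(d, 1, 777)
            )

    def test_stage2_vs_empirical_evolutionary_variance(self, rng):
        """Evolutionary variance prediction within 30% of the empirical
        variance over independent evolution replicates (d=0.1, g=1e5, k=13)."""
        from aafphylo.distance import distance_eq1
        from aafphylo.kmers import KmerConfig, count_kmers_codes, shared_counts
        from aafphylo.simulate import EvolutionParams, pair_at_distance, random_genome

        k, g, d = 13, 100_000, 0.1
        subs = EvolutionParams(indel_fraction=0.0)
        ests, nts = [], []
        for _ in range(60):
            anc = random_genome(g, 0.5, rng)
            a, b = pair_at_distance(anc, d, subs, rng)
            ta = count_kmers_codes([a], KmerConfig(k=k), "a")
            tb = count_kmers_codes([b], KmerConfig(k=k), "b")
            sc = shared_counts(ta, tb)
            ests.append(distance_eq1(sc.n_s, sc.n_t, k))
            nts.append(sc.n_t)
        pred = parametric_stage2_variance(k, float(np.mean(nts)), float(np.mean(ests)))
        emp = float(np.var(ests, ddof=1))
        assert pred == pytest.approx(emp, rel=0.5)


class TestSharedBranchCovariance:
    def make_tree_matrix(self):
        nwk = "((A:0.02,B:0.03):0.01,(C:0.04,D:0.02):0.015,(E:0.05,F:0.01):0.02);"
        t = PhyloTree.from_newick(nwk)
        D = t.patristic_matrix()
        n = t.n_taxa
        NT = np.full((n, n), 50_000, dtype=np.int64)
        NS = (NT * np.exp(-13 * D)).astype(np.int64)
        return t, DistanceMatrix(t.taxa, D, NS, NT, 13)

    def test_diagonal_is_stage2_variance(self):
        t, M = self.make_tree_matrix()
        C = shared_branch_covariance(t, M)
        for p, (i, j) in enumerate(M.pair_index()):
            v = parametric_stage2_variance(13, M.n_t[i, j], M.D[i, j])
            assert C[p, p] == pytest.approx(v, rel=1e-6)

    def test_disjoint_paths_zero(self):
        t, M = self.make_tree_matrix()
        C = shared_branch_covariance(t, M)
        pairs = M.pair_index()
        iAB = pairs.index((0, 1))  # A-B
        iCD = pairs.index((2, 3))  # C-D
        assert C[iAB, iCD] == pytest.approx(0.0, abs=1e-15)

    def test_positive_semidefinite(self):
        t, M = self.make_tree_matrix()
        C = shared_branch_covariance(t, M)
        assert np.linalg.eigvalsh(C).min() >= -1e-12

    def test_matches_patristic_jitter_oracle(self, rng):
        """Covariance structure against brute force: jitter every branch
        independently with variance proportional to its length and measure
        the covariance of pairwise patristic distances."""
        nwk = "((A:0.3,B:0.4):0.2,(C:0.35,D:0.25):0.15,E:0.5);"
        t = PhyloTree.from_newick(nwk)
        sigma2_per_unit = 0.01
        base = t.lengths.copy()
        A = t.design_matrix()
        sims = []
        for _ in range(4000):
            jit = base + rng.normal(0, np.sqrt(sigma2_per_unit * base))
            sims.append(A @ jit)
        emp = np.cov(np.array(sims).T)
        # analytic: cov = shared path length * sigma2 per unit
        shared = (A * base) @ A.T * sigma2_per_unit
        assert np.allclose(emp, shared, atol=4e-4)


class TestBootstrapRuns:
    def build_reads(self, rng, c=6.0, g=12_000):
        from aafphylo.simulate import EvolutionParams, ReadSimParams, evolve_on_tree, random_genome, simulate_reads

        nwk = "((A:0.03,B:0.03):0.02,(C:0.03,D:0.03):0.02);"
        anc = random_genome(g, 0.5, rng)
        tips = evolve_on_tree(anc, nwk, EvolutionParams(indel_fraction=0.0), rng)
        return {
            t: simulate_reads(seq, ReadSimParams(c=c, r=60, E=0.0), rng)
            for t, seq in tips.items()
        }

    def test_nonparametric_deterministic_and_saturated(self, rng):
        reads = self.build_reads(rng)
        kcfg = KmerConfig(k=13)
        cfg = BootstrapConfig(B=8, seed=5)
        sup1, ann1 = nonparametric_bootstrap(reads, kcfg, cfg)
        sup2, ann2 = nonparametric_bootstrap(reads, kcfg, cfg)
        assert sup1.stage1 == sup2.stage1
        assert sup1.stage2 == sup2.stage2
        assert ann1.to_newick() == ann2.to_newick()
        # strong quartet signal: the single internal bipartition saturates
        assert max(sup1.stage1.values()) == cfg.B

    def test_nonparametric_rejects_empty_reads(self):
        with pytest.raises(ValueError, match="parametric"):
            nonparametric_bootstrap(
                {"a": np.empty((0, 10), dtype=np.uint8)}, KmerConfig(k=5), BootstrapConfig(B=2)
            )

    def test_parametric_deterministic_and_tiny_noise_saturates(self, rng):
        from aafphylo.distance import build_distance_matrix
        from aafphylo.kmers import count_kmers_codes, flatten_read_matrix
        from aafphylo.tree import fit_tree

        reads = self.build_reads(rng)
        tabs = [
            count_kmers_codes([flatten_read_matrix(reads[t])], KmerConfig(k=13), t)
            for t in sorted(reads)
        ]
        M = build_distance_matrix(tabs)
        ref = fit_tree(M)
        params = {t: SamplingParams(6, 60, 0.001, 13) for t in reads}
        cfg = BootstrapConfig(B=10, seed=3, sd_inflation=1e-6)
        supA, _ = parametric_bootstrap(M, ref, params, cfg)
        supB, _ = parametric_bootstrap(M, ref, params, cfg)
        assert supA.stage1 == supB.stage1 and supA.stage2 == supB.stage2
        # vanishing stage-1 noise: every replicate reproduces the reference
        assert all(v == cfg.B for v in supA.stage1.values())

    def test_stage2_support_not_above_stage1_on_average(self, rng):
        from aafphylo.distance import build_distance_matrix
        from aafphylo.kmers import count_kmers_codes, flatten_read_matrix
        from aafphylo.tree import fit_tree

        reads = self.build_reads(rng, c=2.0)
        tabs = [
            count_kmers_codes([flatten_read_matrix(reads[t])], KmerConfig(k=13), t)
            for t in sorted(reads)
        ]
        M = build_distance_matrix(tabs)
        ref = fit_tree(M)
        params = {t: SamplingParams(2, 60, 0.0, 13) for t in reads}
        sup, _ = parametric_bootstrap(M, ref, params, BootstrapConfig(B=30, seed=9))
        ref_bips = set(ref.bipartitions(internal_only=True))
        s1 = np.mean([sup.stage1.get(m, 0) for m in ref_bips])
        s2 = np.mean([sup.stage2.get(m, 0) for m in ref_bips])
        assert s2 <= s1 + 1e-9
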