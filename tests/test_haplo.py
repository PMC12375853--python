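"""Tests of LD-block construction, RR-BLUP, local GEBVs, haplotype
cataloguing, effect tests and stacking."""

import numpy as np
import pytest
from scipy import stats

from magicpop.haplo import (
    block_variance,
    build_ld_blocks,
    catalog_haplotypes,
    fit_rrblup,
    haplotype_gebvs,
    local_gebv,
    stack_haplotypes,
    haplotype_anova,
)
from magicpop.sim import MarkerMap


def _map_for(n, chrom=None, spacing=1000):
    chrom = np.ones(n) if chrom is None else np.asarray(chrom)
    bp = []
    for c in np.unique(chrom):
        k = (chrom == c).sum()
        bp.extend(np.arange(1, k + 1) * spacing)
    return MarkerMap([f"m{i}" for i in range(n)], chrom, bp, np.zeros(n))


def _crafted_dosage(rng, n=400):
    """8 markers with a designed r^2 pattern: 1-4 tight, 5 independent,
    6-8 tight; groups mutually near-independent."""

    def group(base, k, flip=0.04):
        cols = []
        for _ in range(k):
            c = base.copy()
            mask = rng.random(n) < flip
            c[mask] = rng.integers(0, 3, mask.sum())
            cols.append(c)
        return cols

    base_a = rng.integers(0, 3, n).astype(float)
    base_b = rng.integers(0, 3, n).astype(float)
    lone = rng.integers(0, 3, n).astype(float)
    cols = group(base_a, 4) + [lone] + group(base_b, 3)
    return np.column_stack(cols)


class TestBuildLdBlocks:
    def test_all_identical_single_block(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 100).astype(float)
        d = np.tile(a[:, None], (1, 6))
        blocks = build_ld_blocks(d, _map_for(6))
        assert len(blocks.blocks) == 1
        assert len(blocks.blocks[0]) == 6

    def test_independent_markers_all_singletons(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(2000, 10)).astype(float)
        blocks = build_ld_blocks(d, _map_for(10))
        assert all(len(b) == 1 for b in blocks.blocks)

    def test_crafted_pattern_matches_hand_trace(self):
        """Hand-traced scan: blocks {1-4}, {5}, {6-8} (1-based)."""
        rng = np.random.default_rng(2)
        d = _crafted_dosage(rng)
        r2 = np.corrcoef(d, rowvar=False) ** 2
        # verify the construction delivers the designed r^2 pattern
        assert r2[:4, :4][np.triu_indices(4, 1)].min() >= 0.6
        assert r2[5:, 5:][np.triu_indices(3, 1)].min() >= 0.6
        assert r2[4, list(range(4)) + [5, 6, 7]].max() < 0.5
        assert r2[np.ix_(range(4), range(5, 8))].max() < 0.5
        blocks = build_ld_blocks(d, _map_for(8), r2_threshold=0.5, t=3)
        got = [b.tolist() for b in blocks.blocks]
        assert got == [[0, 1, 2, 3], [4], [5, 6, 7]]

    def test_partition_property_random_inputs(self, small_pop):
        d = small_pop.dosage.astype(float)
        keep = d.std(axis=0) > 0
        d = d[:, keep]
        mmap = MarkerMap(
            small_pop.map.marker_id[keep],
            small_pop.map.chromosome[keep],
            small_pop.map.position_bp[keep],
            small_pop.map.position_cM[keep],
        )
        blocks = build_ld_blocks(d, mmap)
        covered = np.concatenate(blocks.blocks)
        assert len(covered) == mmap.n_markers
        assert len(np.unique(covered)) == mmap.n_markers
        for b in blocks.blocks:  # contiguity in map order
            assert (np.diff(b) == 1).all()
            assert len(np.unique(mmap.chromosome[b])) == 1

    def test_mirror_image_on_reversed_input(self):
        rng = np.random.default_rng(3)
        d = _crafted_dosage(rng)
        fwd = build_ld_blocks(d, _map_for(8))
        rev = build_ld_blocks(d[:, ::-1], _map_for(8))
        m = 8
        mirrored = sorted(sorted(m - 1 - i for i in b) for b in rev.blocks)
        assert mirrored == sorted(b.tolist() for b in fwd.blocks)

    def test_tolerance_bridges_short_gaps(self):
        """A single failing marker inside a tight group is absorbed when a
        passing marker follows within t."""
        rng = np.random.default_rng(4)
        n = 500
        base = rng.integers(0, 3, n).astype(float)
        lone = rng.integers(0, 3, n).astype(float)

        def noisy():
            c = base.copy()
            mask = rng.random(n) < 0.04
            c[mask] = rng.integers(0, 3, mask.sum())
            return c

        d = np.column_stack([noisy(), noisy(), lone, noisy(), noisy()])
        blocks = build_ld_blocks(d, _map_for(5), r2_threshold=0.5, t=3)
        assert [b.tolist() for b in blocks.blocks] == [[0, 1, 2, 3, 4]]
        # with t = 0 the gap closes the block instead
        blocks0 = build_ld_blocks(d, _map_for(5), r2_threshold=0.5, t=0)
        assert blocks0.blocks[0].tolist() == [0, 1]


class TestFitRrblup:
    def test_toy_matches_closed_form(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(6, 4)).astype(float)
        y = rng.normal(size=6)
        lam = 2.0
        model = fit_rrblup(X, y, lam=lam)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        expected = np.linalg.inv(Xc.T @ Xc + lam * np.eye(4)) @ Xc.T @ yc
        np.testing.assert_allclose(model.effects, expected, atol=1e-8)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, size=(30, 10)).astype(float)
        y = rng.normal(10.0, 1.0, size=30)
        model = fit_rrblup(X, y, lam=1e12)
        assert np.abs(model.effects).max() < 1e-8
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-6)

    @pytest.mark.parametrize("n,m", [(20, 50), (50, 20)])
    def test_primal_dual_equivalence(self, n, m):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(n, m))
        y = rng.normal(size=n)
        lam = 3.7
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        primal = np.linalg.solve(Xc.T @ Xc + lam * np.eye(m), Xc.T @ yc)
        dual = Xc.T @ np.linalg.solve(Xc @ Xc.T + lam * np.eye(n), yc)
        np.testing.assert_allclose(primal, dual, atol=1e-8)
        model = fit_rrblup(X, y, lam=lam)
        np.testing.assert_allclose(model.effects, primal, atol=1e-8)

    def test_effect_recovery_under_low_noise(self, small_pop):
        rng = np.random.default_rng(8)
        X = small_pop.dosage.astype(float)
        keep = X.std(axis=0) > 0.2
        X = X[:, keep]
        qtl = rng.choice(X.shape[1], 20, replace=False)
        true = np.zeros(X.shape[1])
        true[qtl] = rng.normal(0, 1, 20)
        g = X @ true
        train = slice(0, 250)
        test = slice(250, 300)
        model = fit_rrblup(X[train], g[train])
        r_eff = np.corrcoef(model.effects[qtl], true[qtl])[0, 1]
        assert r_eff > 0.8
        r_pred = np.corrcoef(model.predict(X[test]), g[test])[0, 1]
        assert r_pred > 0.9


class TestLocalGebv:
    def test_conservation_sums_to_total(self, small_pop):
        rng = np.random.default_rng(9)
        X = small_pop.dosage.astype(float)
        keep = X.std(axis=0) > 0
        X = X[:, keep]
        mmap = _map_for(X.shape[1], chrom=np.repeat([1, 2], [X.shape[1] // 2, X.shape[1] - X.shape[1] // 2]))
        y = rng.normal(size=X.shape[0])
        model = fit_rrblup(X, y)
        blocks = build_ld_blocks(X, mmap)
        gebvs = local_gebv(model, blocks, X)
        np.testing.assert_allclose(
            gebvs.total(), model.genomic_values(X), rtol=0, atol=1e-10
        )

    def test_hand_computed_block_value(self):
        from magicpop.haplo import LDBlockSet, RidgeModel

        mmap = _map_for(2)
        blocks = LDBlockSet(blocks=[np.array([0, 1])], map=mmap)
        model = RidgeModel(
            intercept=0.0,
            effects=np.array([0.5, -0.2]),
            lam=1.0,
            sigma2_u=1.0,
            sigma2_e=1.0,
            marker_means=np.zeros(2),
        )
        gebvs = local_gebv(model, blocks, np.array([[2.0, 0.0]]))
        assert gebvs.values[0, 0] == pytest.approx(1.0)

    def test_zero_effect_block_zero_gebv(self):
        from magicpop.haplo import LDBlockSet, RidgeModel

        mmap = _map_for(3)
        blocks = LDBlockSet(blocks=[np.array([0, 1]), np.array([2])], map=mmap)
        model = RidgeModel(0.0, np.array([0.0, 0.0, 1.0]), 1.0, 1.0, 1.0, np.zeros(3))
        gebvs = local_gebv(model, blocks, np.array([[2.0, 1.0, 1.0]]))
        assert gebvs.values[0, 0] == 0.0


class TestCatalog:
    def test_counts_sum_to_lines(self, small_pop):
        X = small_pop.dosage.astype(float)[:, :100]
        mmap = _map_for(100)
        blocks = build_ld_blocks(X, mmap)
        cat = catalog_haplotypes(blocks, X)
        for cnt in cat.counts:
            assert cnt.sum() == small_pop.n_lines

    def test_frequency_class_boundaries_strict(self):
        """Counts 71/11 are high/medium; 70/10 fall to medium/rare."""
        counts = [71, 70, 11, 10]
        # two-marker block, four distinct strings with those multiplicities
        strings = [(0, 0), (0, 2), (2, 0), (2, 2)]
        rows = []
        for s, c in zip(strings, counts):
            rows.extend([s] * c)
        d = np.array(rows, dtype=float)
        mmap = _map_for(2)
        from magicpop.haplo import LDBlockSet

        blocks = LDBlockSet(blocks=[np.array([0, 1])], map=mmap)
        cat = catalog_haplotypes(blocks, d)
        by_string = {
            tuple(int(x) for x in h): cat.frequency_class(0, i)
            for i, h in enumerate(cat.haplotypes[0])
        }
        assert by_string[(0, 0)] == "high"
        assert by_string[(0, 2)] == "medium"
        assert by_string[(2, 0)] == "medium"
        assert by_string[(2, 2)] == "rare"

    def test_uniform_block_single_haplotype(self):
        d = np.tile([1.0, 2.0], (80, 1))
        from magicpop.haplo import LDBlockSet

        blocks = LDBlockSet(blocks=[np.array([0, 1])], map=_map_for(2))
        cat = catalog_haplotypes(blocks, d)
        assert len(cat.haplotypes[0]) == 1
        assert cat.frequency_class(0, 0) == "high"


class TestBlockVariance:
    def _setup(self, values, counts):
        """One 1-marker block with prescribed per-line dosages."""
        rows = []
        for v, c in zip(values, counts):
            rows.extend([v] * c)
        d = np.array(rows, dtype=float)[:, None]
        from magicpop.haplo import LDBlockSet, RidgeModel

        mmap = _map_for(1)
        blocks = LDBlockSet(blocks=[np.array([0])], map=mmap)
        model = RidgeModel(0.0, np.array([1.0]), 1.0, 1.0, 1.0, np.zeros(1))
        cat = catalog_haplotypes(blocks, d)
        gebvs = local_gebv(model, blocks, d)
        return d, blocks, model, cat, gebvs

    def test_single_haplotype_zero_variance(self):
        _, _, model, cat, gebvs = self._setup([1.0], [50])
        vt = block_variance(gebvs, cat, model)
        assert vt.variance.iloc[0] == 0.0

    def test_two_haplotypes_symmetric(self):
        # effects +2 and -2 around their mean: population variance = a^2 = 4
        _, _, model, cat, gebvs = self._setup([0.0, 4.0], [10, 10])
        vt = block_variance(gebvs, cat, model)
        assert vt.variance.iloc[0] == pytest.approx(4.0)

    def test_weighted_option_uses_counts(self):
        _, _, model, cat, gebvs = self._setup([0.0, 4.0], [30, 10])
        unw = block_variance(gebvs, cat, model, weighted=False).variance.iloc[0]
        wtd = block_variance(gebvs, cat, model, weighted=True).variance.iloc[0]
        assert unw == pytest.approx(4.0)
        assert wtd == pytest.approx(3.0)  # 0.75*0.25*16

    def test_planted_qtl_block_ranks_high(self, small_pop):
        rng = np.random.default_rng(12)
        X = small_pop.dosage.astype(float)
        keep = X.std(axis=0) > 0.3
        X = X[:, keep]
        mmap = MarkerMap(
            small_pop.map.marker_id[keep],
            small_pop.map.chromosome[keep],
            small_pop.map.position_bp[keep],
            small_pop.map.position_cM[keep],
        )
        j = X.shape[1] // 3
        y = 3.0 * X[:, j] + rng.normal(0, 1.0, X.shape[0])
        model = fit_rrblup(X, y)
        blocks = build_ld_blocks(X, mmap)
        cat = catalog_haplotypes(blocks, X)
        gebvs = local_gebv(model, blocks, X)
        vt = block_variance(gebvs, cat, model)
        target = blocks.marker_to_block()[j]
        target_id = blocks.block_ids[target]
        rank = int(vt.loc[vt.block_id == target_id, "rank"].iloc[0])
        assert rank <= 10


class TestHaplotypeEffects:
    def test_group_means_match_direct_computation(self):
        rng = np.random.default_rng(13)
        d = np.repeat([0.0, 1.0, 2.0], 40)[:, None]
        from magicpop.haplo import LDBlockSet

        blocks = LDBlockSet(blocks=[np.array([0])], map=_map_for(1))
        cat = catalog_haplotypes(blocks, d)
        y = rng.normal(size=120)
        res = haplotype_anova(cat, 0, y)
        for h, m in res["means"].items():
            mask = cat.line_haplotype[:, 0] == h
            assert m == pytest.approx(y[mask].mean())

    def test_shifted_haplotype_detected(self):
        rng = np.random.default_rng(14)
        d = np.repeat([0.0, 2.0], 40)[:, None]
        from magicpop.haplo import LDBlockSet

        blocks = LDBlockSet(blocks=[np.array([0])], map=_map_for(1))
        cat = catalog_haplotypes(blocks, d)
        detected = 0
        for _ in range(20):
            y = rng.normal(0, 1.0, 80)
            y[40:] += 2.0
            res = haplotype_anova(cat, 0, y)
            detected += res["p"] < 0.05
        assert detected >= 18

    def test_permutation_null_calibrated(self):
        rng = np.random.default_rng(15)
        d = np.repeat([0.0, 1.0, 2.0], 30)[:, None]
        from magicpop.haplo import LDBlockSet

        blocks = LDBlockSet(blocks=[np.array([0])], map=_map_for(1))
        cat = catalog_haplotypes(blocks, d)
        y = rng.normal(size=90)
        rejected = 0
        n_perm = 400
        for _ in range(n_perm):
            res = haplotype_anova(cat, 0, rng.permutation(y))
            rejected += res["p"] < 0.05
        rate = rejected / n_perm
        se = np.sqrt(0.05 * 0.95 / n_perm)
        assert abs(rate - 0.05) < 3 * se + 0.01

    def test_single_haplotype_not_testable(self):
        d = np.zeros((20, 1))
        from magicpop.haplo import LDBlockSet

        blocks = LDBlockSet(blocks=[np.array([0])], map=_map_for(1))
        cat = catalog_haplotypes(blocks, d)
        res = haplotype_anova(cat, 0, np.random.default_rng(0).normal(size=20))
        assert not res["testable"]


class TestStacking:
    def _machinery(self, rng, n=200, m=30):
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        mmap = _map_for(m)
        blocks = build_ld_blocks(d, mmap)
        cat = catalog_haplotypes(blocks, d)
        return d, blocks, cat

    def test_counts_bounded(self):
        rng = np.random.default_rng(16)
        d, blocks, cat = self._machinery(rng)
        y = rng.normal(size=200)
        model = fit_rrblup(d, y)
        gebvs = local_gebv(model, blocks, d)
        vt = block_variance(gebvs, cat, model)
        res = stack_haplotypes(cat, vt, model, y, direction="negative", top_k=10)
        assert res.counts.min() >= 0 and res.counts.max() <= 10

    def test_all_undesirable_sign_zero_counts(self):
        rng = np.random.default_rng(17)
        d, blocks, cat = self._machinery(rng, m=5)
        from magicpop.haplo import RidgeModel

        model = RidgeModel(0.0, np.full(5, 1.0), 1.0, 1.0, 1.0, np.zeros(5))
        gebvs = local_gebv(model, blocks, d)
        vt = block_variance(gebvs, cat, model)
        y = rng.normal(size=200)
        # all effects positive, dosages non-negative: no negative local GEBVs
        res = stack_haplotypes(cat, vt, model, y, direction="negative", top_k=5)
        assert (res.counts == 0).all()
        assert not res.trend_defined

    def test_top_k_truncated_with_warning(self):
        rng = np.random.default_rng(18)
        d, blocks, cat = self._machinery(rng, m=4)
        y = rng.normal(size=200)
        model = fit_rrblup(d, y)
        gebvs = local_gebv(model, blocks, d)
        vt = block_variance(gebvs, cat, model)
        with pytest.warns(UserWarning, match="truncating"):
            res = stack_haplotypes(cat, vt, model, y, top_k=99)
        assert len(res.top_blocks) == len(blocks.blocks)

    def test_additive_architecture_negative_trend(self, small_pop):
        """More stacked negative-effect haplotypes -> earlier flowering."""
        rng = np.random.default_rng(19)
        X = small_pop.dosage.astype(float)
        keep = X.std(axis=0) > 0.2
        X = X[:, keep]
        mmap = MarkerMap(
            small_pop.map.marker_id[keep],
            small_pop.map.chromosome[keep],
            small_pop.map.position_bp[keep],
            small_pop.map.position_cM[keep],
        )
        qtl = rng.choice(X.shape[1], 10, replace=False)
        eff = rng.normal(0, 1, 10)
        g = X[:, qtl] @ eff
        y = 50 + g + rng.normal(0, g.std(), X.shape[0])
        model = fit_rrblup(X, y)
        blocks = build_ld_blocks(X, mmap)
        cat = catalog_haplotypes(blocks, X)
        gebvs = local_gebv(model, blocks, X)
        vt = block_variance(gebvs, cat, model)
        res = stack_haplotypes(cat, vt, model, y, direction="negative", top_k=10)
        assert res.trend_defined
        assert res.slope < 0
        assert stats.pearsonr(res.counts, y).statistic < 0


def test_haplotype_gebvs_align_with_line_values(small_pop):
    rng = np.random.default_rng(20)
    X = small_pop.dosage.astype(float)[:, :60]
    mmap = _map_for(60)
    y = rng.normal(size=X.shape[0])
    model = fit_rrblup(X, y)
    blocks = build_ld_blocks(X, mmap)
    cat = catalog_haplotypes(blocks, X)
    gebvs = local_gebv(model, blocks, X)
    hv = haplotype_gebvs(model, cat)
    for b in range(len(blocks.blocks)):
        np.testing.assert_allclose(
            gebvs.values[:, b], hv[b][cat.line_haplotype[:, b]], atol=1e-10
        )
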