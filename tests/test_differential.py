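"""Matrix construction, per-position tests, BH FDR, perfect differences, DMRs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methpore.differential import (
    MethylationMatrix,
    bh_adjust,
    build_matrix,
    find_perfect_differences,
    genomewide_means,
    merge_regions,
    pca,
    per_site_tests,
)
from methpore.errors import DataError, ParameterError, UndefinedStatisticError
from methpore.formats import SampleEntry, SampleSheet

from conftest import make_site


def sheet_4v4():
    entries = [SampleEntry(f"apo{i}", "", "apo") for i in range(1, 5)]
    entries += [SampleEntry(f"sym{i}", "", "sym") for i in range(1, 5)]
    return SampleSheet(entries=tuple(entries))


def matrix_from(freqs, groups=("apo", "apo", "apo", "apo", "sym", "sym", "sym", "sym"),
                starts=None):
    freqs = np.asarray(freqs, dtype=float)
    n, s = freqs.shape
    starts = starts if starts is not None else 100 * (1 + np.arange(n))
    positions = pd.DataFrame(
        {"contig": "tig1", "start": starts, "end": starts, "n_motifs": 1}
    )
    samples = [f"s{j}" for j in range(s)]
    return MethylationMatrix(
        positions=positions,
        samples=samples,
        groups={f"s{j}": groups[j] for j in range(s)},
        frequencies=freqs,
        coverages=np.full((n, s), 10, dtype=int),
    )


class TestBuildMatrix:
    def _tables(self, coverage_by_sample, start=100):
        return {
            sample: [make_site(start=start, called_reads=cov, meth_reads=min(1, cov))]
            for sample, cov in coverage_by_sample.items()
        }

    def test_position_dropped_if_any_sample_below_threshold(self):
        sheet = sheet_4v4()
        cov = {s: 5 for s in sheet.samples}
        cov["sym4"] = 2
        matrix = build_matrix(self._tables(cov), sheet, min_called=3)
        assert matrix.n_positions == 0

    def test_position_retained_with_full_coverage(self):
        sheet = sheet_4v4()
        matrix = build_matrix(self._tables({s: 3 for s in sheet.samples}), sheet,
                              min_called=3)
        assert matrix.n_positions == 1
        assert matrix.frequencies.shape == (1, 8)

    def test_missing_sample_table_rejected(self):
        sheet = sheet_4v4()
        tables = self._tables({s: 5 for s in sheet.samples[:-1]})
        with pytest.raises(DataError, match="sym4"):
            build_matrix(tables, sheet)

    def test_empty_intersection_gives_empty_matrix(self):
        sheet = sheet_4v4()
        tables = {
            s: [make_site(start=100 + 10 * j, called_reads=5, meth_reads=1)]
            for j, s in enumerate(sheet.samples)
        }
        assert build_matrix(tables, sheet).n_positions == 0


class TestGenomewide:
    def test_identical_group_means_give_p_one(self):
        freqs = np.tile([[0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]], (5, 1))
        res = genomewide_means(matrix_from(freqs))
        assert (res.t_statistic, res.p_value) == (0.0, 1.0)

    def test_zero_variance_with_different_means_flagged(self):
        freqs = np.tile([[0.1] * 4 + [0.2] * 4], (5, 1))
        res = genomewide_means(matrix_from(freqs))
        assert res.perfect_separation
        assert np.isnan(res.p_value)

    def test_matches_scipy_on_sample_means(self, rng):
        freqs = rng.uniform(0, 1, size=(50, 8))
        res = genomewide_means(matrix_from(freqs))
        a = freqs[:, :4].mean(axis=0)
        b = freqs[:, 4:].mean(axis=0)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert res.t_statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        res = pca(matrix_from(rng.uniform(0, 1, size=(40, 8))))
        assert res.variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_identical_samples_get_equal_scores(self, rng):
        col = rng.uniform(0, 1, size=40)
        freqs = np.column_stack([col, col] + [rng.uniform(0, 1, 40) for _ in range(6)])
        res = pca(matrix_from(freqs))
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1], atol=1e-10)

    def test_scores_invariant_under_sample_reordering(self, rng):
        freqs = rng.uniform(0, 1, size=(40, 8))
        res1 = pca(matrix_from(freqs))
        order = rng.permutation(8)
        groups = tuple(np.array(["apo"] * 4 + ["sym"] * 4)[order])
        m2 = matrix_from(freqs[:, order], groups=groups)
        m2.samples = [f"s{j}" for j in order]
        m2.groups = {f"s{j}": g for j, g in zip(order, groups)}
        res2 = pca(m2)
        for sample in res1.scores.index:
            assert np.allclose(
                res1.scores.loc[sample], res2.scores.loc[sample], atol=1e-8
            )

    def test_strong_group_effect_separates_groups_in_sign(self, rng):
        base = rng.uniform(0.2, 0.4, size=(60, 8))
        base[:30, 4:] += 0.5  # group effect >> noise
        res = pca(matrix_from(base))
        pc1 = res.scores["PC1"]
        assert len(set(np.sign(pc1[:4]))) == 1
        assert set(np.sign(pc1[:4])) != set(np.sign(pc1[4:]))

    def test_constant_matrix_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pca(matrix_from(np.full((10, 8), 0.5)))


class TestPerSiteTests:
    def test_perfect_difference_has_undefined_t(self):
        freqs = [[0, 0, 0, 0, 1, 1, 1, 1]]
        res = per_site_tests(matrix_from(freqs))
        assert bool(res["perfect"][0])
        assert np.isnan(res["p"][0])

    def test_constant_equal_groups_give_p_one(self):
        res = per_site_tests(matrix_from([[0.5] * 8]))
        assert not res["perfect"][0]
        assert (res["t"][0], res["p"][0]) == (0.0, 1.0)

    def test_identical_group_samples_give_p_one_pooled(self):
        freqs = [[0.1, 0.2, 0.1, 0.2, 0.1, 0.2, 0.1, 0.2]]
        res = per_site_tests(matrix_from(freqs), flavor="pooled")
        assert res["p"][0] == pytest.approx(1.0)

    @pytest.mark.parametrize("flavor, equal_var", [("welch", False), ("pooled", True)])
    def test_matches_scipy_reference(self, rng, flavor, equal_var):
        freqs = rng.uniform(0, 1, size=(200, 8))
        res = per_site_tests(matrix_from(freqs), flavor=flavor)
        t_ref, p_ref = stats.ttest_ind(
            freqs[:, :4], freqs[:, 4:], axis=1, equal_var=equal_var
        )
        assert np.allclose(res["t"], t_ref, atol=1e-10)
        assert np.allclose(res["p"], p_ref, atol=1e-10)

    def test_unknown_flavor_rejected(self, rng):
        with pytest.raises(ParameterError):
            per_site_tests(matrix_from(rng.uniform(0, 1, (5, 8))), flavor="paired")


def brute_force_bh(p, alpha):
    """Literal step-up definition evaluated by exhaustive minimisation."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[order[j - 1]] / j for j in range(rank, m + 1)), 1.0
        )
    return q, [qi <= alpha for qi in q]


class TestBH:
    def test_step_up_arithmetic(self):
        q, sig = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert sig.all()

    def test_single_p_identity(self):
        q, _ = bh_adjust([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_all_ones(self):
        q, sig = bh_adjust([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not sig.any()

    def test_q_never_below_p(self, rng):
        p = rng.uniform(1e-6, 1, 500)
        q, _ = bh_adjust(p)
        assert (q >= p - 1e-15).all()

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(1e-8, 1, int(rng.integers(1, 60)))
            q, sig = bh_adjust(p, alpha=0.05)
            q_bf, sig_bf = brute_force_bh(list(p), 0.05)
            assert np.allclose(q, q_bf, atol=1e-12)
            assert list(sig) == sig_bf
            sm_sig, sm_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose(q, sm_q, atol=1e-12)
            assert (sig == sm_sig).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [0.5, float("nan")]])
    def test_invalid_p_values_rejected(self, bad):
        with pytest.raises(DataError):
            bh_adjust(bad)


class TestPerfectDifferences:
    @pytest.mark.parametrize(
        "row, flagged",
        [
            ([0, 0, 0, 0, 1, 1, 1, 1], True),
            ([0, 0, 0, 0, 0, 0, 0, 0], False),  # no difference
            ([0, 0, 0, 0.01, 1, 1, 1, 1], False),  # nonzero variance in group A
        ],
    )
    def test_definition(self, row, flagged):
        idx = find_perfect_differences(matrix_from([row]))
        assert (len(idx) == 1) is flagged

    def test_no_false_flags_under_jitter(self, rng):
        freqs = np.clip(0.3 + rng.normal(0, 0.01, size=(20_000, 8)), 0, 1)
        assert len(find_perfect_differences(matrix_from(freqs))) == 0


class TestMergeRegions:
    def _matrix(self, starts):
        n = len(starts)
        freqs = np.tile([0.0] * 4 + [1.0] * 4, (n, 1))
        return matrix_from(freqs, starts=np.asarray(starts))

    def test_gap_rule(self):
        m = self._matrix([100, 600, 12_000])
        regions = merge_regions(m, [0, 1, 2], max_gap=1000)
        assert [(r.start, r.end, r.n_positions) for r in regions] == [
            (100, 600, 2), (12_000, 12_000, 1),
        ]

    def test_no_flagged_positions(self, rng):
        m = self._matrix([100])
        assert merge_regions(m, []) == []

    def test_regions_report_group_means(self):
        m = self._matrix([100, 200])
        (region,) = merge_regions(m, [0, 1], max_gap=1000)
        assert region.group_means == {"apo": 0.0, "sym": 1.0}

    def test_unsorted_flags_rejected(self):
        m = self._matrix([100, 600])
        with pytest.raises(DataError, match="sorted"):
            merge_regions(m, [1, 0])

    def test_different_contigs_never_merge(self):
        n = 2
        freqs = np.tile([0.0] * 4 + [1.0] * 4, (n, 1))
        m = matrix_from(freqs, starts=np.array([100, 150]))
        m.positions.loc[1, "contig"] = "tig2"
        assert len(merge_regions(m, [0, 1], max_gap=1000)) == 2
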