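"""Tests for per-probe testing, candidate filtering, region assembly,
Fisher combination and FDR adjustment."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epicase import (
    FilterConfig,
    MValueMatrix,
    call_regions,
    control_titration,
    fdr_adjust,
    filter_candidates,
    fisher_combine,
)
from epicase.regions import test_probes as probe_tests

from conftest import make_dataset


def _scores_with_moments(mean, sd, n, rng=None):
    """n values with exactly the requested sample mean and SD."""
    rng = rng or np.random.default_rng(0)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def _probe_frame(rows):
    """rows: list of (probe_id, chrom, pos, p, control_mean_m, delta_beta)."""
    df = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "p_one_tailed",
                       "control_mean_m", "delta_beta"]
    ).set_index("probe_id")
    df["t"] = -1.0
    df["df"] = 9
    df["delta_m"] = np.where(df["delta_beta"] < 0, -1.0, 1.0)
    df["effective_n"] = 10
    return df


class TestTestProbes:
    def test_worked_example_transplanted_to_one_probe(self):
        ctrl = _scores_with_moments(0.5, 0.1, 10)
        m = pd.DataFrame(
            [np.concatenate([[0.4], ctrl])],
            index=["probe1"],
            columns=["case"] + [f"c{i}" for i in range(10)],
        )
        ds = make_dataset(m.clip(0, 1))  # beta placeholder; M supplied directly
        res = probe_tests(ds, MValueMatrix(m))
        assert abs(res.loc["probe1", "t"]) == pytest.approx(0.9535, abs=1e-3)
        assert res.loc["probe1", "df"] == 9
        assert res.loc["probe1", "effective_n"] == 10

    def test_case_equal_to_mean_gives_half(self):
        ctrl = _scores_with_moments(0.0, 0.5, 8)
        m = pd.DataFrame([np.concatenate([[0.0], ctrl])], index=["p1"],
                         columns=["case"] + [f"c{i}" for i in range(8)])
        ds = make_dataset(m_to_beta_df(m))
        res = probe_tests(ds, MValueMatrix(m))
        assert res.loc["p1", "p_one_tailed"] == pytest.approx(0.5)

    def test_null_simulation_rejects_at_nominal_rate(self):
        rng = np.random.default_rng(21)
        n_probes, n_ctrl = 500, 15
        m = pd.DataFrame(
            rng.normal(0, 0.3, (n_probes, n_ctrl + 1)),
            index=[f"p{i}" for i in range(n_probes)],
            columns=["case"] + [f"c{i}" for i in range(n_ctrl)],
        )
        ds = make_dataset(m_to_beta_df(m))
        res = probe_tests(ds, MValueMatrix(m))
        rate = (res["p_one_tailed"] < 0.05).mean()
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_probes)

    def test_os_direction_matches_hypomethylation_tail(self):
        """For a clearly hypomethylated case, all three methods must put the
        signal into p_one_tailed."""
        ctrl = _scores_with_moments(0.0, 0.2, 12)
        m = pd.DataFrame([np.concatenate([[-2.0], ctrl])], index=["p1"],
                         columns=["case"] + [f"c{i}" for i in range(12)])
        ds = make_dataset(m_to_beta_df(m))
        for method in ("CH", "OS", "WB"):
            res = probe_tests(ds, MValueMatrix(m), method)
            assert res.loc["p1", "p_one_tailed"] < 0.01


def m_to_beta_df(m):
    from epicase import m_to_beta

    return pd.DataFrame(m_to_beta(m.to_numpy()), index=m.index, columns=m.columns)


class TestFilterCandidates:
    def test_enumerated_fixture(self):
        rows = [
            ("a", "chr1", 100, 1e-3, 0.0, -0.2),   # qualifies
            ("b", "chr1", 200, 1e-9, 2.5, -0.2),   # fully methylated -> out
            ("c", "chr1", 300, 0.2, 0.0, -0.2),    # p too big -> out
            ("d", "chr1", 400, 1e-3, 0.0, +0.2),   # hypermethylated -> out
            ("e", "chr1", 500, 0.01, -0.5, -0.1),  # qualifies
            ("f", "chr1", 600, 0.04, 0.9, -0.3),   # qualifies
            ("g", "chr1", 700, 0.04, -1.5, -0.3),  # below hemi band -> out
            ("h", "chr1", 800, 0.04, 1.5, -0.3),   # above hemi band -> out
            ("i", "chr2", 100, 1e-4, 0.3, -0.05),  # qualifies
            ("j", "chr2", 200, 0.06, 0.3, -0.05),  # p too big -> out
        ]
        out = filter_candidates(_probe_frame(rows), FilterConfig())
        assert sorted(out.index) == ["a", "e", "f", "i"]

    def test_stringent_mode_uses_fdr(self):
        rows = [(f"p{i}", "chr1", 100 * i, 1e-9, 0.0, -0.2) for i in range(5)]
        rows += [(f"q{i}", "chr1", 1000 + 100 * i, 0.04, 0.0, -0.2) for i in range(5)]
        df = _probe_frame(rows)
        out = filter_candidates(df, FilterConfig(stringent=True))
        assert sorted(out.index) == [f"p{i}" for i in range(5)]

    def test_hypermethylation_flag(self):
        rows = [("a", "chr1", 100, 1e-3, 0.0, -0.2), ("b", "chr1", 200, 1e-3, 0.0, 0.2)]
        out = filter_candidates(
            _probe_frame(rows), FilterConfig(call_hypermethylation=True)
        )
        assert list(out.index) == ["b"]


class TestCallRegions:
    def _cfg(self, **kw):
        return FilterConfig(**kw)

    def test_two_adjacent_candidates_insufficient(self):
        rows = [("a", "chr1", 100, 0.01, 0.0, -0.2), ("b", "chr1", 200, 0.01, 0.0, -0.2)]
        df = _probe_frame(rows)
        assert call_regions(df, df, self._cfg()) == []

    def test_gap_rule_splits_runs(self):
        rows = [(p, "chr1", pos, 0.01, 0.0, -0.2)
                for p, pos in zip("abcde", [100, 600, 1100, 9000, 9400])]
        df = _probe_frame(rows)
        regions = call_regions(df, df, self._cfg())
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 1100)
        assert regions[0].k == 3

    def test_intervening_noncandidate_breaks_run(self):
        rows = [(p, "chr1", pos, 0.01, 0.0, -0.2)
                for p, pos in zip("abcdef", [100, 300, 500, 700, 900, 1100])]
        df = _probe_frame(rows)
        # probe "c" stays retained + hemimethylated but is not a candidate
        cand = df.drop(index="c")
        regions = call_regions(cand, df, self._cfg())
        assert len(regions) == 1  # d,e,f; a,b alone are too short
        assert regions[0].probe_ids == ("d", "e", "f")

    def test_nonhemimethylated_interloper_ignored_by_default_scope(self):
        rows = [(p, "chr1", pos, 0.01, 0.0, -0.2)
                for p, pos in zip("abc", [100, 300, 500])]
        rows.append(("x", "chr1", 200, 0.5, 3.0, 0.0))  # methylated, non-hemi
        df = _probe_frame(rows)
        cand = df.drop(index="x")
        regions = call_regions(cand, df, self._cfg())
        assert len(regions) == 1 and regions[0].k == 3
        # with scope widened to all retained probes, the run is broken
        regions2 = call_regions(cand, df, self._cfg(consecutive_scope="all_retained"))
        assert regions2 == []

    def test_region_members_all_pass_filters_and_order_invariance(self):
        rng = np.random.default_rng(13)
        df = _random_probe_frame(rng, 120)
        cfg = self._cfg()
        cand = filter_candidates(df, cfg)
        regions = call_regions(cand, df, cfg)
        for r in regions:
            assert set(r.probe_ids) <= set(cand.index)
            assert r.fisher_df == 2 * r.k
        shuffled = df.sample(frac=1, random_state=1)
        regions2 = call_regions(filter_candidates(shuffled, cfg), shuffled, cfg)
        assert {r.probe_ids for r in regions} == {r.probe_ids for r in regions2}

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = _random_probe_frame(rng, 200)
        cfg = self._cfg()
        cand = filter_candidates(df, cfg)
        got = {r.probe_ids for r in call_regions(cand, df, cfg)}
        expect = _bruteforce_regions(cand, df, cfg)
        assert got == expect


def _random_probe_frame(rng, n):
    chroms = rng.choice(["chr1", "chr2", "chr3"], size=n)
    pos = rng.integers(1, 50_000, size=n)
    rows = [
        (
            f"p{i:03d}", chroms[i], int(pos[i]),
            float(rng.uniform(0, 0.15)),
            float(rng.normal(0, 1.2)),
            float(rng.uniform(-0.3, 0.1)),
        )
        for i in range(n)
    ]
    return _probe_frame(rows)


def _bruteforce_regions(cand, all_retained, cfg):
    """Independent O(n^2) enumeration of maximal valid candidate windows."""
    scope = all_retained[
        all_retained["control_mean_m"].between(cfg.control_m_low, cfg.control_m_high)
    ]
    out = set()
    for chrom in scope["chrom"].unique():
        sub = scope[scope["chrom"] == chrom]
        sub = sub.assign(_pid=sub.index).sort_values(["pos", "_pid"], kind="stable")
        ids = list(sub.index)
        is_cand = [pid in set(cand.index) for pid in ids]
        positions = list(sub["pos"])
        n = len(ids)

        def valid(i, j):
            for k in range(i, j + 1):
                if not is_cand[k]:
                    return False
            for k in range(i, j):
                if positions[k + 1] - positions[k] > cfg.max_gap_nt:
                    return False
            return True

        for i in range(n):
            for j in range(i + cfg.min_probes - 1, n):
                if not valid(i, j):
                    continue
                left_ext = i > 0 and valid(i - 1, j)
                right_ext = j < n - 1 and valid(i, j + 1)
                if not left_ext and not right_ext:
                    out.add(tuple(ids[i: j + 1]))
    return out


class TestFisherCombine:
    def test_k1_identity(self):
        for p in (0.01, 0.2, 0.9):
            chi2, df, log10_p, p_disp = fisher_combine([p])
            assert df == 2
            assert p_disp == pytest.approx(p, rel=1e-10)

    def test_k2_against_chisquare_oracle(self):
        chi2, df, log10_p, p_disp = fisher_combine([0.05, 0.05])
        assert chi2 == pytest.approx(-2 * 2 * math.log(0.05), rel=1e-12)
        assert chi2 == pytest.approx(11.9829, abs=1e-4)
        assert df == 4
        assert p_disp == pytest.approx(stats.chi2.sf(chi2, 4), rel=1e-10)
        assert p_disp == pytest.approx(0.0175, abs=5e-4)

    def test_underflow_contract(self):
        chi2, df, log10_p, p_disp = fisher_combine([1e-12] * 40)
        assert p_disp == 0.0
        assert math.isfinite(log10_p) and log10_p < -350

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            chi2, *_ = fisher_combine([0.0, 0.5])
        assert math.isfinite(chi2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])


class TestFdrAdjust:
    def test_hand_example(self):
        out = fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.07])[0] == pytest.approx(0.07)

    def test_all_equal_stay_equal(self):
        out = fdr_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        out = fdr_adjust(p)
        assert (out >= p - 1e-12).all() and (out <= 1).all()
        order = np.argsort(p)
        assert (np.diff(out[order]) >= -1e-12).all()


class TestControlTitration:
    def test_determinism_and_skip(self, sim_dataset):
        from epicase.preprocess import preprocess_pipeline

        ds, truth = sim_dataset
        ds2, m = preprocess_pipeline(ds)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            rep1 = control_titration(ds2, m, sizes=(5, 10, 999), replicates=2, seed=4)
            rep2 = control_titration(ds2, m, sizes=(5, 10, 999), replicates=2, seed=4)
        assert any("skipped" in str(x.message) for x in w)
        pd.testing.assert_frame_equal(rep1, rep2)
        assert set(rep1["size"]) == {5, 10}

    def test_truth_overlap_reported(self, sim_dataset):
        from epicase.preprocess import preprocess_pipeline

        ds, truth = sim_dataset
        ds2, m = preprocess_pipeline(ds)
        rep = control_titration(
            ds2, m, sizes=(10,), replicates=2, seed=5,
            truth_regions=truth.dmr_spans(),
        )
        assert {"sensitivity", "truth_mean_z_cc", "truth_mean_ci_width"} <= set(rep.columns)
        assert (rep["sensitivity"] <= 1).all()
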