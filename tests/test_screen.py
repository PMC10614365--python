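from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from hrrscan.screen import (
    CountMatrix,
    control_size_factors,
    guide_lfc,
    normalize,
    remove_low_count,
    rra_enhancer,
    rra_rho,
)
from hrrscan.simulate import ScreenConfig, SimConfig, gen_screen_counts, toy_library


def _cm(counts: dict, membership, timepoints=None):
    df = pd.DataFrame(counts)
    samples = pd.DataFrame(
        [
            {
                "sample": s,
                "timepoint": (timepoints or {}).get(s, s.split("_")[0]),
                "replicate": int(s.rsplit("r", 1)[1]) if "r" in s else 1,
            }
            for s in df.columns
        ]
    ).set_index("sample")
    return CountMatrix(df, samples, membership)


class TestRemoveLowCount:
    def _matrix(self, n=300):
        rng = np.random.default_rng(0)
        counts = {
            "day0_r1": rng.integers(100, 1000, n),
            "day21_r1": rng.integers(100, 1000, n),
        }
        df = {k: pd.Series(v, index=[f"g{i}" for i in range(n)]) for k, v in counts.items()}
        membership = {f"g{i}": ("E1" if i else None) for i in range(n)}
        membership["g0"] = None
        return _cm(df, membership)

    def test_at_least_ceil_fraction_flagged_per_sample(self):
        cm = self._matrix(300)
        filtered, dropped = remove_low_count(cm, 0.01)
        assert len(dropped) >= 3  # ceil(0.01 * 300) per sample, union
        assert filtered.counts.shape[0] == 300 - len(dropped)

    def test_fraction_zero_is_identity(self):
        cm = self._matrix(50)
        filtered, dropped = remove_low_count(cm, 0.0)
        assert dropped == [] and filtered.counts.equals(cm.counts)

    def test_guide_lowest_in_one_sample_dropped_globally(self):
        membership = {"a": "E1", "b": "E1", "c": None, "d": None, "e": "E1"}
        cm = _cm(
            {
                "day0_r1": pd.Series([1, 500, 500, 500, 500], index=list("abcde")),
                "day21_r1": pd.Series([500, 500, 500, 500, 2], index=list("abcde")),
            },
            membership,
        )
        _, dropped = remove_low_count(cm, 0.2)
        assert set(dropped) == {"a", "e"}

    def test_ties_at_cutoff_all_flagged(self):
        membership = {g: "E1" for g in "abcd"}
        membership["z"] = None
        cm = _cm(
            {"day0_r1": pd.Series([5, 5, 5, 100, 100], index=list("abcdz"))},
            membership,
        )
        _, dropped = remove_low_count(cm, 0.2)  # ceil(.2*5)=1 but ties extend
        assert set(dropped) == {"a", "b", "c"}


class TestControlSizeFactors:
    def test_median_of_ratios_worked_example(self):
        cm = _cm(
            {
                "A": pd.Series([10, 10], index=["c1", "c2"]),
                "B": pd.Series([20, 20], index=["c1", "c2"]),
            },
            {"c1": None, "c2": None},
        )
        f = control_size_factors(cm)
        assert f["A"] == pytest.approx(1 / np.sqrt(2), abs=1e-6)
        assert f["B"] == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_identical_samples_give_unit_factors(self):
        cm = _cm(
            {
                "A": pd.Series([10, 30], index=["c1", "c2"]),
                "B": pd.Series([10, 30], index=["c1", "c2"]),
            },
            {"c1": None, "c2": None},
        )
        assert np.allclose(control_size_factors(cm), 1.0)

    def test_scaling_one_sample_scales_only_its_factor(self):
        base = {
            "A": pd.Series([10, 30, 50], index=["c1", "c2", "c3"]),
            "B": pd.Series([12, 28, 55], index=["c1", "c2", "c3"]),
        }
        membership = {c: None for c in ("c1", "c2", "c3")}
        f1 = control_size_factors(_cm(dict(base), membership))
        doubled = dict(base)
        doubled["B"] = base["B"] * 2
        f2 = control_size_factors(_cm(doubled, membership))
        # ratios computed against the geometric mean across samples: doubling
        # B multiplies its factor by 2/sqrt(2) and divides A's by sqrt(2)
        assert f2["B"] / f1["B"] == pytest.approx(np.sqrt(2), rel=1e-9)
        assert f2["A"] / f1["A"] == pytest.approx(1 / np.sqrt(2), rel=1e-9)

    def test_controls_with_zeros_excluded(self):
        cm = _cm(
            {
                "A": pd.Series([0, 10], index=["c1", "c2"]),
                "B": pd.Series([100, 10], index=["c1", "c2"]),
            },
            {"c1": None, "c2": None},
        )
        assert np.allclose(control_size_factors(cm), 1.0)


class TestGuideLfc:
    def _norm(self):
        membership = {"g1": "E1", "g2": None}
        cm = _cm(
            {
                "day0_r1": pd.Series([15, 100], index=["g1", "g2"]),
                "day21_r1": pd.Series([63, 100], index=["g1", "g2"]),
            },
            membership,
        )
        return cm

    def test_worked_example(self):
        cm = self._norm()
        lfc = guide_lfc(cm.counts.astype(float), cm.samples)
        assert lfc.loc["g1", "score"] == pytest.approx(2.0)
        assert lfc.loc["g2", "score"] == 0.0

    def test_swapping_timepoints_negates(self):
        cm = self._norm()
        fwd = guide_lfc(cm.counts.astype(float), cm.samples, "day0", "day21")
        rev = guide_lfc(cm.counts.astype(float), cm.samples, "day21", "day0")
        assert np.allclose(fwd["score"], -rev["score"])

    def test_missing_replicate_pairing_rejected(self):
        membership = {"g1": None}
        cm = _cm({"day0_r1": pd.Series([5], index=["g1"])}, membership)
        with pytest.raises(ValueError, match="replicate"):
            guide_lfc(cm.counts.astype(float), cm.samples)


class TestRraRho:
    def test_single_guide_rho_is_u(self):
        assert rra_rho(np.array([0.07]), alpha=0.25) == (0.07, 1)

    def test_two_guide_worked_example(self):
        rho, j = rra_rho(np.array([0.1, 0.4]), alpha=0.5)
        assert j == 2
        assert rho == pytest.approx(0.16)

    def test_no_guide_below_alpha_gives_one(self):
        assert rra_rho(np.array([0.5, 0.9]), alpha=0.25) == (1.0, 0)


class TestRraEnhancer:
    def _scores(self, values, membership):
        return pd.Series(values), membership

    def test_exact_enumeration_matches_independent_oracle(self):
        # 6 targeting guides, one enhancer of 2: all C(6,2)=15 assignments
        scores = pd.Series(
            [5.0, 3.0, 2.0, 1.0, 0.5, 0.1],
            index=[f"g{i}" for i in range(6)],
        )
        membership = {f"g{i}": ("E1" if i < 2 else "other") for i in range(6)}
        membership = {f"g{i}": ("E1" if i < 2 else f"X{i}") for i in range(6)}
        res = rra_enhancer(scores, membership, "positive", alpha=0.5, exact=True)
        target = next(r for r in res if r.enhancer_id == "E1")
        # oracle: enumerate subsets of the 6 normalized ranks
        u = (np.arange(1, 7)) / 6.0
        obs = target.rho

        def rho_of(subset):
            ss = np.sort(np.array(subset))
            from scipy.stats import beta as beta_dist

            j = np.searchsorted(ss, 0.5, side="right")
            if j == 0:
                return 1.0
            k = np.arange(1, j + 1)
            return float(beta_dist.cdf(ss[:j], k, len(ss) - k + 1).min())

        hits = sum(rho_of(s) <= obs for s in combinations(u, 2))
        assert target.p == pytest.approx(hits / 15)

    def test_rho_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(0, 1, 40), index=[f"g{i}" for i in range(40)])
        membership = {f"g{i}": f"E{i % 8}" for i in range(40)}
        a = rra_enhancer(scores, membership, "positive", n_perm=200, seed=1)
        b = rra_enhancer(np.exp(scores * 3), membership, "positive", n_perm=200, seed=1)
        assert [r.rho for r in a] == [r.rho for r in b]
        assert [r.p for r in a] == [r.p for r in b]

    def test_p_at_least_add_one_floor(self):
        rng = np.random.default_rng(9)
        scores = pd.Series(rng.normal(0, 1, 30), index=[f"g{i}" for i in range(30)])
        membership = {f"g{i}": f"E{i % 5}" for i in range(30)}
        res = rra_enhancer(scores, membership, "positive", n_perm=99, seed=0)
        assert all(r.p >= 1 / 100 for r in res)

    def test_null_pvalues_roughly_uniform(self):
        """Global-null enhancer p-values pass KS uniformity at the library's
        guide multiplicity (~10 guides/enhancer; at much smaller m the
        alpha-RRA atom at rho=1 makes p discrete near 1 by construction)."""
        from scipy.stats import kstest

        failures = 0
        for seed in range(8):
            cfg = SimConfig(
                seed=700 + seed,
                chrom_lengths={"chr1": 50_000},
                screen=ScreenConfig(
                    n_enhancers=60, guides_per_enhancer=10, n_controls=200, depth=300
                ),
            )
            lib = toy_library(cfg)
            cm, _ = gen_screen_counts(cfg, lib)
            norm = normalize(cm)
            lfc = guide_lfc(norm, cm.samples)
            res = rra_enhancer(
                lfc["score"], cm.membership, "positive", n_perm=400, seed=seed
            )
            p = np.array([r.p for r in res])
            if kstest(p, "uniform").pvalue < 0.01:
                failures += 1
        assert failures <= 1


class TestPlantedRecovery:
    def test_planted_enhancers_recovered_with_few_false_positives(self):
        effects = {f"E_{i + 1:03d}": 1.5 for i in range(10)}
        cfg = SimConfig(
            seed=77,
            chrom_lengths={"chr1": 50_000},
            screen=ScreenConfig(
                n_enhancers=60,
                guides_per_enhancer=10,
                n_controls=300,
                depth=500,
                dispersion=0.05,
                planted_effects=effects,
            ),
        )
        lib = toy_library(cfg)
        cm, _ = gen_screen_counts(cfg, lib)
        norm = normalize(cm)
        lfc = guide_lfc(norm, cm.samples)
        res = rra_enhancer(lfc["score"], cm.membership, "positive", n_perm=1000, seed=7)
        hits = {r.enhancer_id for r in res if r.q < 0.05}
        assert len(hits & set(effects)) >= 9
        assert len(hits - set(effects)) <= 1
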