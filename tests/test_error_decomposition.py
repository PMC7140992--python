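import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoerr.error_decomposition import (pairwise_error, procrustes_anova,
                                           repeatability)
from morphoerr.landmark_io import (DatasetError, LandmarkConfiguration,
                                   LandmarkDataset)
from morphoerr.synthetic_data import StudySpec, simulate_study


def dataset_from_array(arr, prefix="s"):
    return LandmarkDataset([LandmarkConfiguration(f"{prefix}{i}", a)
                            for i, a in enumerate(arr)])


class TestRepeatability:
    def test_equal_mean_squares_gives_zero(self):
        assert repeatability(2.0, 2.0, 2).r == 0.0

    def test_no_within_variation_gives_one(self):
        assert repeatability(3.0, 0.0, 2).r == 1.0

    def test_hand_computed_case(self):
        res = repeatability(3.0, 1.0, 2)
        assert res.s2_among == pytest.approx(1.0)
        assert res.r == pytest.approx(0.5)

    def test_negative_component_clamped(self):
        res = repeatability(0.5, 1.0, 2)
        assert res.s2_among == 0.0 and res.r == 0.0

    def test_degenerate_case_is_nan_not_zero(self):
        assert math.isnan(repeatability(0.0, 0.0, 2).r)

    def test_monotone_decreasing_in_within_ms(self):
        rs = [repeatability(3.0, w, 2).r for w in (0.0, 0.5, 1.0, 2.0, 3.0)]
        assert all(a >= b for a, b in zip(rs, rs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            repeatability(1.0, 1.0, 1)
        with pytest.raises(ValueError):
            repeatability(-1.0, 1.0, 2)


class TestProcrustesAnovaOracle:
    def test_one_way_matches_classical_anova_on_scalar_data(self, rng):
        """Sequential decomposition on 1-D data is textbook one-way ANOVA."""
        groups = np.repeat(["a", "b", "c"], [8, 10, 12])
        y = rng.normal(size=(30, 1)) + (groups == "b")[:, None] * 0.7
        table = procrustes_anova(y, pd.DataFrame({"g": groups}), ["g"],
                                 nperm=99, seed=1)
        # direct, independent computation
        grand = y.mean()
        ss_b = sum(len(y[groups == g]) * (y[groups == g].mean() - grand) ** 2
                   for g in "abc")
        ss_w = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
                   for g in "abc")
        f_direct = (ss_b / 2) / (ss_w / 27)
        row = table[table.effect == "g"].iloc[0]
        assert row.SS == pytest.approx(ss_b, abs=1e-10)
        assert row.df == 2
        assert row.F == pytest.approx(f_direct, abs=1e-10)
        resid = table[table.effect == "Residual"].iloc[0]
        assert resid.SS == pytest.approx(ss_w, abs=1e-10)
        # scipy agrees too
        f_scipy, _ = stats.f_oneway(*(y[groups == g].ravel() for g in "abc"))
        assert row.F == pytest.approx(f_scipy, rel=1e-10)

    def test_r2_sums_to_one(self, rng):
        groups = np.repeat(["a", "b", "c", "d"], 6)
        reps = np.tile(["r1", "r2", "r3"], 8)
        y = rng.normal(size=(24, 10))
        table = procrustes_anova(y, pd.DataFrame({"g": groups, "r": reps}),
                                 ["g", "r"], nperm=9, seed=0)
        assert table.R2.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nested_balanced_df_bookkeeping(self, rng):
        """Eight-replicate nested design follows the balanced df algebra."""
        spec = StudySpec(seed=5, n_species=3, n_per_species=6, k=8,
                         unknown_mixture=(0.5, 0.25, 0.25))
        sim = simulate_study(spec)
        names = [n for n in sim.datasets if not sim.datasets[n].label.tilted]
        rows, stacks = [], []
        for n in names:
            d = sim.datasets[n]
            stacks.append(d.coords_array())
            lab = d.label
            for sid, sp in zip(d.specimen_ids, d.species):
                rows.append({"species": sp, "individual": sid, "device": lab.device,
                             "observer": lab.observer, "trial": f"T{lab.trial}"})
        y = np.concatenate(stacks)
        table = procrustes_anova(y, pd.DataFrame(rows),
                                 ["species", "individual", "device", "observer", "trial"],
                                 nperm=5, seed=0)
        n_ind = 18
        expect = {"species": 3 - 1, "individual": n_ind - 3,
                  "device": n_ind * (2 - 1), "observer": n_ind * 2 * (2 - 1),
                  "trial": n_ind * 2 * 2 * (2 - 1)}
        got = dict(zip(table.effect, table.df))
        assert got == expect
        assert table.df.sum() == 8 * n_ind - 1  # total df

    def test_permutation_pvalues_bounded_and_reproducible(self, rng):
        groups = np.repeat(["a", "b"], 10)
        y = rng.normal(size=(20, 4))
        t1 = procrustes_anova(y, pd.DataFrame({"g": groups}), ["g"], nperm=49, seed=7)
        t2 = procrustes_anova(y, pd.DataFrame({"g": groups}), ["g"], nperm=49, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        p = t1[t1.effect == "g"].p.iloc[0]
        assert 1 / 50 <= p <= 1.0

    def test_planted_effect_detected(self, rng):
        groups = np.repeat(["a", "b"], 15)
        y = rng.normal(size=(30, 6))
        y[groups == "b"] += 2.0
        table = procrustes_anova(y, pd.DataFrame({"g": groups}), ["g"],
                                 nperm=199, seed=3)
        assert table[table.effect == "g"].p.iloc[0] == pytest.approx(1 / 200)

    def test_single_level_factor_rejected(self, rng):
        y = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="degrees of freedom"):
            procrustes_anova(y, pd.DataFrame({"g": ["a"] * 10}), ["g"], nperm=1)


class TestPairwiseError:
    def test_identical_datasets_have_zero_replicate_variance(self, rng):
        arr = rng.normal(size=(12, 9, 2))
        a = dataset_from_array(arr)
        b = dataset_from_array(arr.copy())
        table, rep = pairwise_error(a, b, nperm=9, seed=0)
        r2 = table[table.effect == "replicate"].R2.iloc[0]
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert rep.r == pytest.approx(1.0, abs=1e-9)

    def test_noise_dominated_pair_has_low_repeatability(self, rng):
        base = rng.normal(size=(20, 10, 2)) * 0.01  # tiny individual signal
        shape = np.tile(np.stack([np.cos(np.linspace(0, 2 * np.pi, 10, endpoint=False)),
                                  np.sin(np.linspace(0, 2 * np.pi, 10, endpoint=False))],
                                 axis=1), (20, 1, 1))
        a = dataset_from_array(shape + base + rng.normal(scale=0.1, size=(20, 10, 2)))
        b_arr = shape + base + rng.normal(scale=0.1, size=(20, 10, 2))
        b = dataset_from_array(b_arr)
        _, rep = pairwise_error(a, b, nperm=9, seed=0)
        assert rep.r < 0.1

    def test_specimen_mismatch_lists_difference(self, rng):
        a = dataset_from_array(rng.normal(size=(4, 5, 2)))
        b = dataset_from_array(rng.normal(size=(4, 5, 2)), prefix="t")
        with pytest.raises(DatasetError, match="s0"):
            pairwise_error(a, b, nperm=1)

    def test_nested_r2_ordering_recovered_on_small_replicates(self):
        """Planted error ordering (interobs > session > device) shows in R2."""
        hits = 0
        for seed in range(8):
            sim = simulate_study(StudySpec(seed=seed, n_per_species=12))
            names = [n for n in sim.datasets if not sim.datasets[n].label.tilted]
            rows, stacks = [], []
            for n in names:
                d = sim.datasets[n]
                stacks.append(d.coords_array())
                lab = d.label
                for sid, sp in zip(d.specimen_ids, d.species):
                    rows.append({"species": sp, "individual": sid,
                                 "device": lab.device, "observer": lab.observer,
                                 "trial": f"T{lab.trial}"})
            from morphoerr.gpa_core import gpa
            aligned = gpa(np.concatenate(stacks))
            table = procrustes_anova(
                aligned.shapes, pd.DataFrame(rows),
                ["species", "individual", "device", "observer", "trial"],
                nperm=1, seed=0)
            r2 = dict(zip(table.effect, table.R2))
            hits += (r2["individual"] > r2["observer"] > r2["trial"] > r2["device"])
        assert hits >= 7
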