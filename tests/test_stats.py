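import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ligcect.io import ValidationError
from ligcect.stats import (
    correlation_screen,
    spearman_correlation,
    wilcoxon_exact_p,
    wilcoxon_signed_rank,
)

HSETTINGS = settings(max_examples=25, deadline=None, derandomize=True)


def brute_force_wilcoxon(diffs):
    """Enumeration over all 2^n sign assignments (the independent oracle)."""
    diffs = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ws = np.array(
        [
            sum(r for bit, r in zip(bits, ranks) if bit)
            for bits in itertools.product((0, 1), repeat=len(diffs))
        ]
    )
    p_lo = np.mean(ws <= w_obs + 1e-9)
    p_hi = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2.0 * min(p_lo, p_hi))


def brute_force_spearman(x, y):
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    rhos = np.array(
        [np.corrcoef(rx, np.array(p))[0, 1] for p in itertools.permutations(ry)]
    )
    return rho, float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


class TestWilcoxon:
    def test_six_positive_differences(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5, 6]))
        assert res.p_value == pytest.approx(2 / 64)
        assert res.n == 6 and not res.underpowered

    def test_antisymmetric_pairs_p_one(self):
        res = wilcoxon_signed_rank(np.array([1.0, -1.0, 2.5, -2.5, 0.4, -0.4]))
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        d = np.round(rng.normal(0, 1, n), 1)  # rounding induces ties/zeros
        if np.all(d == 0):
            d[0] = 0.5
        w_fast, p_fast = wilcoxon_exact_p(d[d != 0])
        w_oracle, p_oracle = brute_force_wilcoxon(d)
        assert w_fast == pytest.approx(w_oracle)
        assert p_fast == pytest.approx(p_oracle, abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            wilcoxon_signed_rank(np.zeros(6))

    def test_small_n_flagged_underpowered(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0]))
        assert res.underpowered

    def test_paired_signature_matches_differences(self):
        x = np.array([5.0, 6, 7, 8, 9, 10])
        y = np.array([4.0, 5, 9, 6, 7, 8])
        assert (
            wilcoxon_signed_rank(x, y).p_value
            == wilcoxon_signed_rank(x - y).p_value
        )


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman_correlation(x, x**3).rho == pytest.approx(1.0)
        assert spearman_correlation(x, -np.exp(x)).rho == pytest.approx(-1.0)

    def test_exact_p_matches_full_permutation_oracle(self):
        x = np.array([3.0, 1, 4, 1, 5, 9, 2])
        y = np.array([2.0, 7, 1, 8, 2, 8, 1])
        res = spearman_correlation(x, y)
        rho, p = brute_force_spearman(x, y)
        assert res.rho == pytest.approx(rho, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman_correlation(np.ones(5), np.arange(5.0))

    @given(
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 10),
        cube=st.booleans(),
    )
    @HSETTINGS
    def test_invariant_to_monotone_transforms(self, shift, scale, cube):
        x = np.array([0.3, 1.2, -0.7, 2.4, 0.9, -1.5, 3.1])
        y = np.array([1.0, 0.2, 0.5, 2.2, -0.3, 0.8, 1.9])
        base = spearman_correlation(x, y)
        xt = scale * x + shift
        if cube:
            xt = xt**3
        res = spearman_correlation(xt, y)
        assert res.rho == pytest.approx(base.rho, abs=1e-12)
        assert res.p_value == pytest.approx(base.p_value, abs=1e-12)


class TestCorrelationScreen:
    @staticmethod
    def _tables(link=True, seed=0):
        rng = np.random.default_rng(seed)
        rows_b, rows_c = [], []
        for i in range(11):
            lig = f"L{i:02d}"
            phase = rng.normal(4.0, 0.6)
            for group in ("control", "damaged"):
                pmax = (2.0 - 0.3 * phase if link else rng.normal(1.0, 0.2))
                pmax += rng.normal(0, 0.01)
                rows_b.append(
                    {
                        "ligament_id": lig, "group": group,
                        "gamma_0.1Hz": phase + rng.normal(0, 0.01),
                        "E": rng.normal(70, 25),
                        "D_sigma": 0.8 + rng.normal(0, 0.05)
                        if group == "damaged" else np.nan,
                    }
                )
                rows_c.append(
                    {
                        "ligament_id": lig, "group": group, "agent": "iodixanol",
                        "Pmax": pmax, "tau_h": rng.normal(0.8, 0.2),
                    }
                )
        return pd.DataFrame(rows_b), pd.DataFrame(rows_c)

    def test_engineered_link_detected(self):
        biomech, cect = self._tables(link=True)
        out = correlation_screen(biomech, cect)
        row = out[(out["parameter"] == "gamma_0.1Hz") & (out["uptake"] == "Pmax")]
        assert bool(row["significant"].iloc[0])
        assert row["rho"].iloc[0] < -0.9

    def test_null_cells_mostly_insignificant(self):
        ps = []
        for seed in range(6):
            biomech, cect = self._tables(link=False, seed=seed)
            out = correlation_screen(biomech, cect)
            ps.extend(out[out["parameter"] == "E"]["p_value"].tolist())
        assert np.mean(ps) > 0.2

    def test_damage_parameters_use_damaged_group_only(self):
        biomech, cect = self._tables()
        out = correlation_screen(biomech, cect)
        dmg = out[out["parameter"] == "D_sigma"]
        assert set(dmg["pooling"]) == {"damaged-only"}
        assert (dmg["n"] == 11).all()
        pooled = out[out["parameter"] == "gamma_0.1Hz"]
        assert set(pooled["pooling"]) == {"pooled"}
        assert (pooled["n"] == 22).all()

    def test_empty_cect_table_rejected(self):
        biomech, _ = self._tables()
        empty = pd.DataFrame(columns=["ligament_id", "group", "agent", "Pmax", "tau_h"])
        with pytest.raises(ValidationError, match="key"):
            correlation_screen(biomech, empty)


class TestNullCalibration:
    def test_type_one_error_controlled_quick(self):
        # smaller replicate count than the dedicated acceptance run
        rng = np.random.default_rng(7)
        rejections = sum(
            wilcoxon_signed_rank(rng.normal(0, 1, 11)).p_value < 0.05
            for _ in range(1500)
        )
        assert rejections / 1500 <= 0.065
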