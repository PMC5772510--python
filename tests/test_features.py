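"""Feature derivation, V0 assembly, and best-subset selection."""

import itertools
import logging
import math

import numpy as np
import pandas as pd
import pytest

from ifpwv.features import (
    ClinicalRecord,
    V0_NAMES,
    V_NAMES,
    assemble_v0,
    best_subset_select,
    derive_frequency_features,
    derive_shape_features,
)
from ifpwv.intrinsic_frequency import IFResult
from ifpwv.preprocess import CardiacCycle


def _ifres(**kw):
    base = dict(
        a1=-0.4, b1=0.1, a2=-0.5, b2=-0.2, omega1=2 * np.pi, omega2=4.0,
        p_bar=0.5, T0=0.25, T=1.0, objective=0.0,
    )
    base.update(kw)
    return IFResult(**base)


def _clin(**kw):
    base = dict(Age=45.0, Ps=120.0, Pd=70.0, SSN=540.0, AIx=9.0, RWAT=135.0)
    base.update(kw)
    return ClinicalRecord(**base)


class TestFrequencyFeatures:
    def test_direct_arithmetic(self):
        f = derive_frequency_features(_ifres(omega1=2 * np.pi, T0=0.25, T=1.0))
        assert f["omega_bar1"] == pytest.approx(np.pi / 2)
        assert f["omega1c"] == pytest.approx(np.pi)  # w1 * sqrt(T0), units 1/sqrt(s)
        assert f["omega1n"] == pytest.approx(2 * np.pi)
        assert f["inv_systole"] == pytest.approx(4.0)
        assert f["inv_diastole"] == pytest.approx(1.0 / 0.75)

    def test_omega1c_scales_with_sqrt_of_systole_duration(self):
        # doubling T0 must scale omega1c by sqrt(2), not 2 (1/sqrt(s) units)
        f1 = derive_frequency_features(_ifres(T0=0.2))
        f2 = derive_frequency_features(_ifres(T0=0.4))
        assert f2["omega1c"] / f1["omega1c"] == pytest.approx(math.sqrt(2))

    def test_degenerate_notch_time_raises(self):
        with pytest.raises(ValueError):
            derive_frequency_features(_ifres(T0=1.0, T=1.0))


class TestShapeFeatures:
    @staticmethod
    def _cycle(samples, fs=1000.0):
        s = np.asarray(samples, dtype=float)
        return CardiacCycle(samples=s, fs=fs, T=len(s) / fs, T0=0.25)

    def test_rho_endpoints(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        hump = np.sin(np.pi * t)  # min at ends, max mid-cycle
        low = self._cycle(hump)  # s(T0=0.25) partway up
        feats = derive_shape_features(low, _ifres())
        assert 0.0 < feats["rho"] < 1.0
        # cycle whose value at the notch equals the minimum -> rho = 0
        v = hump.copy()
        v[250] = v.min()
        assert derive_shape_features(self._cycle(v), _ifres())["rho"] == pytest.approx(0.0)
        # ... and equal to the maximum -> rho = 1
        v[250] = v.max()
        assert derive_shape_features(self._cycle(v), _ifres())["rho"] == pytest.approx(1.0)

    def test_half_sine_mcsf_matches_quadrature(self):
        from scipy.integrate import quad

        T = 0.8
        fs = 10000.0
        t = np.arange(int(T * fs)) / fs
        cyc = self._cycle(np.sin(np.pi * t / T), fs=fs)
        mcsf = derive_shape_features(cyc, _ifres())["MCSF"]
        mean_oracle = quad(lambda u: np.sin(np.pi * u / T), 0, T)[0] / T
        assert mcsf == pytest.approx(mean_oracle, abs=1e-3)
        assert mcsf == pytest.approx(2 / np.pi, abs=1e-3)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        s = np.abs(np.cumsum(rng.normal(size=500))) + 1.0
        base = derive_shape_features(self._cycle(s), _ifres())
        # affine waveform rescale with jointly scaled envelope coefficients
        scaled_if = _ifres(
            a1=3 * -0.4, b1=3 * 0.1, a2=3 * -0.5, b2=3 * -0.2, p_bar=3 * 0.5 + 7
        )
        shifted = derive_shape_features(self._cycle(3 * s + 7), scaled_if)
        for key in ("rho", "MCSF", "Er"):
            assert shifted[key] == pytest.approx(base[key], rel=1e-9)

    def test_zero_diastolic_envelope_raises(self):
        t = np.linspace(0, 1, 500)
        with pytest.raises(ValueError, match="Er"):
            derive_shape_features(self._cycle(np.sin(np.pi * t)), _ifres(a2=0.0, b2=0.0))

    def test_flat_cycle_raises(self):
        with pytest.raises(ValueError, match="flat"):
            derive_shape_features(self._cycle(np.ones(500)), _ifres())

    def test_bounded_shape_fractions(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            s = rng.normal(size=400).cumsum()
            if np.ptp(s) == 0:
                continue
            feats = derive_shape_features(self._cycle(s), _ifres())
            assert 0.0 <= feats["rho"] <= 1.0
            assert 0.0 <= feats["Cr"] <= 1.0
            assert 0.0 <= feats["MCSF"] <= 1.0


class TestAssembleV0:
    @staticmethod
    def _parts():
        freq = derive_frequency_features(_ifres())
        t = np.linspace(0, 1, 1000, endpoint=False)
        cyc = CardiacCycle(samples=np.sin(np.pi * t), fs=1000.0, T=1.0, T0=0.25)
        shape = derive_shape_features(cyc, _ifres())
        return freq, shape

    def test_complete_inputs_give_21_feature_row(self):
        freq, shape = self._parts()
        table, excluded = assemble_v0([(freq, shape, _clin(subject_id="a"))])
        assert excluded == []
        assert list(table.columns[1:]) == list(V0_NAMES)
        assert len(V0_NAMES) == 21
        assert len(table) == 1

    def test_missing_covariate_excludes_record(self):
        freq, shape = self._parts()
        table, excluded = assemble_v0(
            [
                (freq, shape, _clin(subject_id="ok")),
                (freq, shape, _clin(subject_id="noAIx", AIx=None)),
            ]
        )
        assert len(table) == 1
        assert excluded == [("noAIx", "missing AIx")]

    def test_external_mcsf_takes_precedence_with_notice(self, caplog):
        freq, shape = self._parts()
        with caplog.at_level(logging.INFO, logger="ifpwv.features"):
            table, _ = assemble_v0([(freq, shape, _clin(MCSF=0.77))])
        assert table["MCSF"].iloc[0] == pytest.approx(0.77)
        assert any("overrides" in r.message for r in caplog.records)

    def test_v_subset_columns_in_fixed_order(self):
        freq, shape = self._parts()
        table, _ = assemble_v0([(freq, shape, _clin())])
        v = table[list(V_NAMES)]
        assert list(v.columns) == list(V_NAMES)
        assert len(V_NAMES) == 12

    def test_clinical_record_validation(self):
        with pytest.raises(ValueError):
            _clin(Ps=60.0, Pd=70.0)
        with pytest.raises(ValueError):
            _clin(Age=-1.0)


class TestBestSubset:
    def test_single_candidate_selected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 1))
        y = 2 * x[:, 0] + rng.normal(0, 0.1, 100)
        assert best_subset_select(x, y) == ["x0"]

    def test_duplicate_column_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 5))
        X = np.column_stack([X, X[:, 0]])  # duplicate of x0 appended
        y = 3 * X[:, 0] + rng.normal(0, 0.1, 200)
        assert best_subset_select(X, y) == ["x0"]

    def test_named_columns_returned(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("abcd"))
        y = 1.5 * df["b"] - df["d"] + rng.normal(0, 0.1, 150)
        assert best_subset_select(df, y) == ["b", "d"]

    def test_matches_independent_exhaustive_oracle(self):
        """Exhaustive statsmodels-scored enumeration agrees with the selector."""
        import statsmodels.api as sm

        for rep in range(3):
            rng = np.random.default_rng(100 + rep)
            p, n = 8, 300
            X = rng.normal(size=(n, p))
            y = 2 * X[:, 0] - X[:, 2] + 0.5 * X[:, 6] + rng.normal(0, 0.1, n)
            best = (np.inf, None)
            for k in range(1, p + 1):
                for S in itertools.combinations(range(p), k):
                    fit = sm.OLS(y, sm.add_constant(X[:, S])).fit()
                    # same scoring family as the selector: BIC + EBIC term
                    score = fit.bic + 2.0 * math.log(math.comb(p, k))
                    if score < best[0]:
                        best = (score, S)
            oracle = [f"x{j}" for j in best[1]]
            assert best_subset_select(X, y) == oracle

    def test_branch_and_bound_equals_exhaustive_above_cutoff(self):
        rng = np.random.default_rng(9)
        p, n = 9, 250
        X = rng.normal(size=(n, p))
        y = X[:, 1] - 2 * X[:, 4] + rng.normal(0, 0.2, n)
        exhaustive = best_subset_select(X, y, max_exhaustive=15)
        bnb = best_subset_select(X, y, max_exhaustive=5)  # force the BnB path
        assert bnb == exhaustive

    def test_more_candidates_than_rows_raises(self):
        with pytest.raises(ValueError):
            best_subset_select(np.ones((5, 6)), np.ones(5))
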