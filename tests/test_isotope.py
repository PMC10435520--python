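"""Natural-abundance correction and isotopologue bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcatrace.isotope import (
    CorrectionSettings,
    FormulaError,
    MetaboliteDef,
    MIDVector,
    correct_natural_abundance,
    correct_table,
    default_registry,
    load_registry,
    mid_from_intensities,
    na_correction_matrix,
    parse_formula,
)

from conftest import random_mid


class TestParseFormula:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("C5H9NO4", {"C": 5, "H": 9, "N": 1, "O": 4}),
            ("C10H17N3O6S", {"C": 10, "H": 17, "N": 3, "O": 6, "S": 1}),
        ],
    )
    def test_valid(self, formula, expected):
        assert parse_formula(formula) == expected

    @pytest.mark.parametrize("bad", ["C0", "Xx3", "", "C6h12", "C6 H12"])
    def test_invalid(self, bad):
        with pytest.raises((FormulaError, ValueError)):
            parse_formula(bad)


class TestMetaboliteDef:
    def test_formula_carbon_mismatch_rejected(self):
        with pytest.raises(ValueError, match="carbons"):
            MetaboliteDef("glutamate", 4, "C5H9NO4")

    def test_zero_carbons_rejected(self):
        with pytest.raises(ValueError):
            MetaboliteDef("x", 0)


class TestCorrectionMatrix:
    def test_p_zero_is_identity(self):
        m = na_correction_matrix(2, CorrectionSettings(p13c=0.0))
        np.testing.assert_allclose(m, np.eye(3))

    def test_one_carbon_binomial(self):
        m = na_correction_matrix(1, CorrectionSettings(p13c=0.0107))
        np.testing.assert_allclose(m, [[0.9893, 0.0], [0.0107, 1.0]])

    @pytest.mark.parametrize("n", range(1, 21))
    def test_columns_sum_to_one(self, n):
        m = na_correction_matrix(n, CorrectionSettings(p13c=0.0107))
        np.testing.assert_allclose(m.sum(axis=0), np.ones(n + 1), atol=1e-12)

    def test_upper_triangle_zero(self):
        m = na_correction_matrix(4, CorrectionSettings(p13c=0.05))
        assert np.all(m[np.triu_indices(5, k=1)] == 0)

    def test_purity_columns_still_stochastic(self):
        m = na_correction_matrix(
            3, CorrectionSettings(p13c=0.0107, tracer_purity=0.99)
        )
        np.testing.assert_allclose(m.sum(axis=0), np.ones(4), atol=1e-12)

    def test_purity_moves_label_down(self):
        # an impure tracer leaks m+n molecules down to lighter masses
        pure = na_correction_matrix(3, CorrectionSettings(p13c=0.0))
        impure = na_correction_matrix(
            3, CorrectionSettings(p13c=0.0, tracer_purity=0.9)
        )
        assert pure[3, 3] == 1.0
        assert impure[3, 3] == pytest.approx(0.9**3)
        assert impure[2, 3] > 0

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            na_correction_matrix(0)


class TestCorrection:
    def test_roundtrip_known_mid(self):
        md = MetaboliteDef("x", 3)
        true = np.array([0.2, 0.0, 0.0, 0.8])
        settings = CorrectionSettings(p13c=0.0107)
        convolved = na_correction_matrix(3, settings) @ true
        rec = correct_natural_abundance(convolved, md, settings)
        np.testing.assert_allclose(rec.fractions, true, atol=1e-6)

    def test_p_zero_identity(self):
        md = MetaboliteDef("x", 4)
        mid = np.array([0.1, 0.2, 0.3, 0.2, 0.2])
        rec = correct_natural_abundance(mid, md, CorrectionSettings(p13c=0.0))
        np.testing.assert_allclose(rec.fractions, mid, atol=1e-12)

    def test_unlabelled_input_recovers_pure_m0(self):
        settings = CorrectionSettings(p13c=0.0107)
        md = MetaboliteDef("x", 5)
        col0 = na_correction_matrix(5, settings)[:, 0]
        rec = correct_natural_abundance(col0, md, settings)
        expected = np.zeros(6)
        expected[0] = 1.0
        np.testing.assert_allclose(rec.fractions, expected, atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            correct_natural_abundance(np.zeros(4), MetaboliteDef("x", 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            correct_natural_abundance(np.ones(3) / 3, MetaboliteDef("x", 3))

    def test_raw_intensities_accepted(self):
        # correction is scale-invariant: raw peak areas need no prior
        # normalisation
        md = MetaboliteDef("x", 2)
        settings = CorrectionSettings(p13c=0.0107)
        true = np.array([0.5, 0.0, 0.5])
        raw = 1e6 * (na_correction_matrix(2, settings) @ true)
        rec = correct_natural_abundance(raw, md, settings)
        np.testing.assert_allclose(rec.fractions, true, atol=1e-9)

    def test_noisy_input_never_negative(self, rng):
        # noise pushing m+1 below its natural-abundance share must not
        # produce negative fractions under the non-negative solve
        md = MetaboliteDef("x", 4)
        settings = CorrectionSettings(p13c=0.05)
        for _ in range(50):
            true = random_mid(rng, 4)
            noisy = (na_correction_matrix(4, settings) @ true) * rng.lognormal(
                0, 0.3, 5
            )
            rec = correct_natural_abundance(noisy, md, settings)
            assert np.all(rec.fractions >= 0)
            assert rec.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    @given(
        n=st.integers(1, 10),
        p=st.sampled_from([0.0, 0.0107, 0.05]),
        seed=st.integers(0, 10_000),
    )
    def test_roundtrip_property(self, n, p, seed):
        """correct(convolve(mid)) == mid for random MIDs (matrix oracle)."""
        mid = random_mid(np.random.default_rng(seed), n)
        md = MetaboliteDef("x", n)
        settings = CorrectionSettings(p13c=p)
        convolved = na_correction_matrix(n, settings) @ mid
        rec = correct_natural_abundance(convolved, md, settings)
        np.testing.assert_allclose(rec.fractions, mid, atol=1e-6)


class TestMidFromIntensities:
    def test_normalisation(self):
        md = MetaboliteDef("x", 2)
        mid = mid_from_intensities({0: 100.0, 1: 0.0, 2: 300.0}, md)
        np.testing.assert_allclose(mid.fractions, [0.25, 0.0, 0.75])

    def test_missing_indices_zero_filled_with_warning(self):
        md = MetaboliteDef("x", 2)
        with pytest.warns(UserWarning, match="missing"):
            mid = mid_from_intensities({0: 5.0}, md)
        np.testing.assert_allclose(mid.fractions, [1.0, 0.0, 0.0])

    def test_all_zero_rejected(self):
        md = MetaboliteDef("x", 2)
        with pytest.raises(ValueError, match="no signal"):
            mid_from_intensities({0: 0.0, 1: 0.0, 2: 0.0}, md)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError, match="iso_index"):
            mid_from_intensities({5: 1.0}, MetaboliteDef("x", 2))


class TestRegistry:
    def test_default_panel_carbon_counts(self, registry):
        assert registry["citrate"].n_carbons == 6
        assert registry["glutamate"].n_carbons == 5
        assert registry["aspartate"].n_carbons == 4
        assert registry["glycine"].n_carbons == 2
        assert registry["glutathione"].n_carbons == 10

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "reg.yaml"
        path.write_text(
            "citrate: 6\nserine:\n  n_carbons: 3\n  formula: C3H7NO3\n"
        )
        reg = load_registry(path)
        assert reg["citrate"].n_carbons == 6
        assert reg["serine"].formula == "C3H7NO3"


class TestCorrectTable:
    def test_roundtrip_and_order(self, registry, tmp_path):
        settings = CorrectionSettings(p13c=0.0107)
        rows = []
        true = {"citrate": random_mid(np.random.default_rng(0), 6),
                "malate": random_mid(np.random.default_rng(1), 4)}
        for sample in ("S2", "S1"):
            for met, mid in true.items():
                conv = na_correction_matrix(
                    registry[met].n_carbons, settings) @ mid
                for i, area in enumerate(conv * 1e6):
                    rows.append((sample, met, i, area))
        df = pd.DataFrame(
            rows, columns=["sample_id", "metabolite", "iso_index", "peak_area"]
        )
        out = correct_table(df, registry, settings)
        # deterministic (sample, metabolite, iso_index) ordering
        assert out["sample_id"].is_monotonic_increasing or (
            out.groupby("sample_id").ngroup().is_monotonic_increasing
        )
        for (sample, met), grp in out.groupby(["sample_id", "metabolite"]):
            np.testing.assert_allclose(
                grp.sort_values("iso_index")["fraction_corrected"].to_numpy(),
                true[met],
                atol=1e-9,
            )

    def test_unknown_metabolite_rejected(self, registry):
        df = pd.DataFrame(
            {"sample_id": ["S1"], "metabolite": ["unobtainium"],
             "iso_index": [0], "peak_area": [1.0]}
        )
        with pytest.raises(ValueError, match="unobtainium"):
            correct_table(df, registry)
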