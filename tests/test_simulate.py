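"""Ground-truth TCA labelling simulator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcatrace.enrichment import (
    carbon_pool_contribution,
    fraction_enrichment,
    pc_activity,
    pc_pdh_ratio,
)
from tcatrace.isotope import (
    CorrectionSettings,
    correct_table,
    default_registry,
    na_correction_matrix,
)
from tcatrace.simulate import (
    FluxScenario,
    MEASURED_METABOLITES,
    carbon_loss,
    generate_cohort,
    observe,
    simulate_mids,
)

from oracles import closed_form_glucose


scenario_fields = st.fixed_dictionaries(
    {
        "g_label": st.floats(0, 1),
        "f_pdh": st.floats(0, 0.6),
        "f_fao": st.floats(0, 0.4),
        "f_pc": st.floats(0, 1),
        "f_gln": st.floats(0, 1),
        "d_exch": st.floats(0, 1),
        "tracer": st.sampled_from(["glucose", "glutamine", "palmitate"]),
    }
)


class TestSimulateMids:
    def test_full_labelling_condensation(self):
        """f_pc = f_pdh = g = 1, no dilution: citrate is pure m+5 and one
        uniform carbon loss sends AKG to m+4 w.p. 5/6, m+5 w.p. 1/6."""
        sc = FluxScenario(g_label=1, f_pdh=1, f_fao=0, f_pc=1, d_exch=0,
                          noise_cv=0)
        mids = simulate_mids(sc)
        np.testing.assert_allclose(
            mids["citrate"].fractions, [0, 0, 0, 0, 0, 1, 0]
        )
        np.testing.assert_allclose(
            mids["alpha-ketoglutarate"].fractions,
            [0, 0, 0, 0, 5 / 6, 1 / 6],
        )

    def test_no_tracer_all_m0(self):
        mids = simulate_mids(FluxScenario(g_label=0, noise_cv=0))
        for met, mid in mids.items():
            assert mid[0] == pytest.approx(1.0), met

    def test_pc_knockout_abolishes_m3_and_m5(self):
        """f_pc = 0: citrate carries only {m0, m2} — the condensation
        product of labelled acetyl-CoA with unlabelled oxaloacetate."""
        mids = simulate_mids(FluxScenario(f_pc=0.0, noise_cv=0))
        cit = mids["citrate"].fractions
        assert cit[3] == 0.0 and cit[5] == 0.0
        assert cit[2] > 0
        assert set(np.nonzero(cit)[0]) <= {0, 2}
        # AKG m+5 (PC-m+3 x PDH-m+2 condensation product) vanishes too
        assert mids["alpha-ketoglutarate"][5] == 0.0

    def test_glutamine_tracer_seeds_akg(self):
        sc = FluxScenario(tracer="glutamine", f_gln=0.6, d_exch=0.0)
        mids = simulate_mids(sc)
        assert mids["alpha-ketoglutarate"][5] == pytest.approx(0.6)
        assert mids["pyruvate"][0] == 1.0

    def test_palmitate_tracer_labels_acetyl_only(self):
        sc = FluxScenario(tracer="palmitate", f_fao=0.3)
        mids = simulate_mids(sc)
        assert mids["citrate"][2] == pytest.approx(0.3)
        assert mids["citrate"][3] == 0.0
        assert mids["pyruvate"][0] == 1.0

    @given(fields=scenario_fields)
    def test_all_mids_normalised(self, fields):
        """Convolution and carbon loss preserve normalisation for every
        admissible scenario."""
        mids = simulate_mids(FluxScenario(**fields))
        for met, mid in mids.items():
            assert mid.fractions.sum() == pytest.approx(1.0, abs=1e-9), met
            assert np.all(mid.fractions >= -1e-12)

    def test_carbon_loss_preserves_mass_balance(self, rng):
        for n in (2, 4, 6):
            mid = rng.dirichlet(np.ones(n + 1))
            out = carbon_loss(mid)
            assert out.sum() == pytest.approx(1.0, abs=1e-12)
            # mean label drops by exactly the uniform-loss factor (n-1)/n
            mean_in = np.dot(np.arange(n + 1), mid)
            mean_out = np.dot(np.arange(n), out)
            assert mean_out == pytest.approx(mean_in * (n - 1) / n)

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(ValueError, match="f_pdh"):
            FluxScenario(f_pdh=0.8, f_fao=0.5)
        with pytest.raises(ValueError, match="g_label"):
            FluxScenario(g_label=1.2)


class TestObserve:
    def test_noise_free_no_na_recovers_truth(self):
        sc = FluxScenario(noise_cv=0.0)
        mids = simulate_mids(sc)
        df = observe(mids, sc, settings=CorrectionSettings(p13c=0.0))
        for met, grp in df.groupby("metabolite"):
            fr = grp.sort_values("iso_index")["peak_area"].to_numpy()
            np.testing.assert_allclose(
                fr / fr.sum(), mids[met].fractions, atol=1e-12
            )

    def test_noise_free_equals_matrix_product(self):
        sc = FluxScenario(noise_cv=0.0)
        settings = CorrectionSettings(p13c=0.0107)
        mids = simulate_mids(sc)
        df = observe(mids, sc, settings=settings)
        for met, grp in df.groupby("metabolite"):
            fr = grp.sort_values("iso_index")["peak_area"].to_numpy()
            n = default_registry()[met].n_carbons
            expected = na_correction_matrix(n, settings) @ mids[met].fractions
            np.testing.assert_allclose(fr / fr.sum(), expected, atol=1e-12)

    def test_same_seed_identical(self):
        sc = FluxScenario(noise_cv=0.2, seed=42)
        mids = simulate_mids(sc)
        a = observe(mids, sc)
        b = observe(mids, sc)
        pd.testing.assert_frame_equal(a, b)

    def test_emits_full_measured_panel(self):
        sc = FluxScenario()
        df = observe(simulate_mids(sc), sc)
        assert set(df["metabolite"]) == set(MEASURED_METABOLITES)


class TestPipelineRecovery:
    def test_closed_form_recovery_noise_free(self, registry):
        """observe -> correction -> enrichment reproduces the hand-derived
        closed-form statistics of the single-turn model to 1e-9."""
        settings = CorrectionSettings(p13c=0.0107)
        for f_pc, f_pdh, g in [(0.2, 0.5, 0.7), (0.5, 0.3, 0.9),
                               (0.1, 0.6, 0.4)]:
            sc = FluxScenario(g_label=g, f_pdh=f_pdh, f_pc=f_pc, f_fao=0.2,
                              noise_cv=0.0)
            df = observe(simulate_mids(sc), sc, settings=settings)
            corrected = correct_table(df, registry, settings)
            mids = {}
            for met, grp in corrected.groupby("metabolite"):
                fr = grp.sort_values("iso_index")["fraction_corrected"]
                mids[met] = fr.to_numpy()
            from tcatrace.isotope import MIDVector

            cit = MIDVector(registry["citrate"], mids["citrate"])
            asp = MIDVector(registry["aspartate"], mids["aspartate"])
            truth = closed_form_glucose(f_pc, f_pdh, g)
            assert fraction_enrichment(cit) == pytest.approx(
                truth["fraction_enrichment_citrate"], abs=1e-9)
            assert pc_pdh_ratio(cit) == pytest.approx(
                truth["pc_pdh_ratio_citrate"], abs=1e-9)
            assert carbon_pool_contribution(cit) == pytest.approx(
                truth["carbon_pool_contribution_citrate"], abs=1e-9)
            assert pc_activity(asp) == pytest.approx(
                truth["pc_activity_aspartate"], abs=1e-9)


class TestGenerateCohort:
    def test_paired_structure(self):
        ds = generate_cohort(n_pairs=3, seed=11)
        meta = ds.metadata
        assert meta["sample_id"].is_unique
        assert set(meta["condition"]) == {"control", "treated"}
        assert meta.groupby("pair_id").size().eq(6).all()  # 2 arms x 3 tracers
        assert set(meta["tracer"]) == {"glucose", "glutamine", "palmitate"}

    def test_determinism_bit_identical(self):
        a = generate_cohort(n_pairs=3, seed=5)
        b = generate_cohort(n_pairs=3, seed=5)
        pd.testing.assert_frame_equal(a.measured, b.measured)
        pd.testing.assert_frame_equal(a.medium, b.medium)
        assert a.true_mids == b.true_mids

    def test_seed_changes_data(self):
        a = generate_cohort(n_pairs=2, seed=1)
        b = generate_cohort(n_pairs=2, seed=2)
        assert not a.measured["peak_area"].equals(b.measured["peak_area"])

    def test_null_effect_same_truth_per_pair(self):
        ds = generate_cohort(n_pairs=2, effect={}, seed=3)
        for pair in ("P01", "P02"):
            ctl = ds.true_mids[f"{pair}_control_glc"]
            trt = ds.true_mids[f"{pair}_treated_glc"]
            assert ctl == trt

    def test_effect_reduces_pdh_not_pc(self):
        ds = generate_cohort(n_pairs=2, seed=3)
        for sid, sc in ds.scenarios.items():
            pair, cond = sid.split("_")[0], sid.split("_")[1]
            ctl = ds.scenarios[f"{pair}_control_glc"]
            if cond == "treated":
                assert sc.f_pdh == pytest.approx(ctl.f_pdh * 0.6)
                assert sc.f_pc == pytest.approx(ctl.f_pc)

    def test_medium_reflects_consumption(self):
        ds = generate_cohort(n_pairs=2, seed=3)
        med = ds.medium.set_index(["sample_id", "metabolite"])
        for pair in ("P01", "P02"):
            g_ctl = med.loc[(f"{pair}_control", "glucose")]
            g_trt = med.loc[(f"{pair}_treated", "glucose")]
            # treated consumes less glucose (lower g_label) -> more remains
            assert g_trt["conc_spent"] >= g_ctl["conc_spent"]
            assert g_ctl["conc_spent"] < g_ctl["conc_cellfree"]

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            generate_cohort(n_pairs=1)
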