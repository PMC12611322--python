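import numpy as np
import pandas as pd
import pytest

from mkptools.containers import BEAD_LABEL
from mkptools.differential import nb_wald_test, pseudobulk_aggregate
from mkptools.normalize import clr_normalize_matrix
from mkptools.simulate import (
    PlantedEffect,
    SimConfig,
    default_adt_modes,
    generate_flow_sample,
    generate_multimodal,
    generate_wells,
)


class TestSimConfig:
    def test_invalid_fractions_rejected(self):
        config = SimConfig(
            conditions=("old",), subtype_fractions={"old": {"cMkP": 0.5, "ncMkP": 0.4}}
        )
        with pytest.raises(ValueError):
            config.validate()

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(nb_dispersion=0.0).validate()

    def test_yaml_roundtrip(self, tmp_path):
        config = SimConfig(
            n_cells=50,
            n_genes=40,
            planted_degs=(PlantedEffect("Gene0001", ("young", "old"), 2.0),),
            seed=5,
        )
        path = tmp_path / "sim.yaml"
        config.to_yaml(path)
        loaded = SimConfig.from_yaml(path)
        assert loaded.n_cells == 50
        assert loaded.planted_degs[0].gene == "Gene0001"
        assert loaded.planted_degs[0].contrast == ("young", "old")


class TestGenerateMultimodal:
    def test_seed_determinism(self):
        a = generate_multimodal(SimConfig(n_cells=300, n_genes=60, seed=42))
        b = generate_multimodal(SimConfig(n_cells=300, n_genes=60, seed=42))
        np.testing.assert_array_equal(a.rna_counts, b.rna_counts)
        np.testing.assert_array_equal(a.adt_counts, b.adt_counts)
        assert a.cell_meta.equals(b.cell_meta)

    def test_subtype_fraction_within_binomial_tolerance(self):
        config = SimConfig(
            n_cells=1000,
            n_genes=40,
            conditions=("old",),
            subtype_fractions={"old": {"cMkP": 0.8, "ncMkP": 0.2}},
            adt_modes=default_adt_modes(("cMkP", "ncMkP")),
            seed=21,
        )
        ds = generate_multimodal(config)
        frac = (ds.cell_meta["subtype"] == "ncMkP").mean()
        sd = np.sqrt(0.2 * 0.8 / 1000)
        assert abs(frac - 0.2) <= 3 * sd

    def test_blocklist_genes_always_present(self, small_dataset):
        cats = small_dataset.gene_meta["blocklist_category"]
        assert set(cats.unique()) == {"none", "mito", "ribo", "malat1"}
        assert cats.loc["Malat1"] == "malat1"

    def test_adt_clr_modes_match_configuration(self, small_dataset, small_clr):
        subtype = small_dataset.cell_meta["subtype"]
        hi = small_clr.loc[(subtype == "cMkP").to_numpy(), "CD48"]
        lo = small_clr.loc[(subtype == "ncMkP").to_numpy(), "CD48"]
        assert hi.mean() == pytest.approx(1.9, abs=0.05)
        assert lo.mean() == pytest.approx(0.3, abs=0.05)

    def test_reporter_concordance_controls_label_noise(self):
        config = SimConfig(n_cells=1500, n_genes=30, reporter_concordance=1.0, seed=2)
        ds = generate_multimodal(config)
        mkp = ds.cell_meta[ds.cell_meta["subtype"].isin(["cMkP", "ncMkP"])]
        agree = (
            (mkp["subtype"] == "cMkP") & (mkp["reporter"] == "GFP")
            | (mkp["subtype"] == "ncMkP") & (mkp["reporter"] == "Tom")
        ).mean()
        assert agree == 1.0

    def test_null_pseudobulk_lfc_centered_at_zero(self):
        config = SimConfig(n_cells=1200, n_genes=150, seed=17)
        ds = generate_multimodal(config)
        counts, sample_meta = pseudobulk_aggregate(
            ds.rna_frame(), ds.cell_meta, ("biosample", "condition")
        )
        res = nb_wald_test(counts, sample_meta["condition"])
        informative = res[res["baseMean"] > 1]
        assert abs(informative["log2FC"].median()) < 0.1

    def test_planted_effect_recovered_by_de(self):
        planted = tuple(
            PlantedEffect(f"Gene{i + 1:04d}", ("young", "old"), 2.0) for i in range(10)
        )
        config = SimConfig(n_cells=2000, n_genes=150, planted_degs=planted, seed=19)
        ds = generate_multimodal(config)
        counts, sample_meta = pseudobulk_aggregate(
            ds.rna_frame(), ds.cell_meta, ("biosample", "condition")
        )
        res = nb_wald_test(counts, sample_meta["condition"], reference="young")
        genes = [p.gene for p in planted]
        assert res.loc[genes, "log2FC"].mean() == pytest.approx(2.0, abs=0.4)


class TestGenerateWells:
    def test_strict_wells_are_pure(self):
        wells = generate_wells("strict_restriction", 0.5, 6, 200, seed=0)
        assert all(w.n_cmkp == 0 or w.n_ncmkp == 0 for w in wells)

    def test_independent_mixed_fraction_matches_analytic(self):
        wells = generate_wells("independent", 0.3, 4, 10000, seed=1)
        mixed = np.mean([0 < w.n_ncmkp < w.n_mkp for w in wells])
        expected = 1 - 0.3**4 - 0.7**4
        se = np.sqrt(expected * (1 - expected) / 10000)
        assert abs(mixed - expected) <= 3 * se

    @pytest.mark.parametrize("model", ["strict_restriction", "independent"])
    def test_p_zero_gives_cmkp_only(self, model):
        wells = generate_wells(model, 0.0, 5, 100, seed=2)
        assert all(w.n_ncmkp == 0 for w in wells)

    def test_generation_rate_yields_empty_wells(self):
        wells = generate_wells(
            "independent", 0.3, 5, 400, seed=3, mkp_generation_rate=0.4
        )
        frac = np.mean([w.n_mkp > 0 for w in wells])
        assert frac == pytest.approx(0.4, abs=0.08)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_wells("other", 0.3, 5, 10)
        with pytest.raises(ValueError):
            generate_wells("independent", 1.5, 5, 10)


class TestGenerateFlowSample:
    def test_exact_event_counts(self):
        table = generate_flow_sample(
            {"A": {"n_events": 5000, "channels": {"PE": (100.0, 0.3)}}},
            n_bead_events=500,
            beads_added=10000,
            seed=0,
        )
        assert table.n_events("A") == 5000
        assert table.n_bead_events == 500
        assert table.beads_added == 10000

    def test_lognormal_median_near_target(self):
        table = generate_flow_sample(
            {"A": {"n_events": 10000, "channels": {"PE": (250.0, 0.5)}}},
            n_bead_events=100,
            beads_added=1000,
            seed=4,
        )
        med = table.population_events("A")["PE"].median()
        assert med == pytest.approx(250.0, rel=0.05)

    def test_zero_event_population_allowed(self):
        table = generate_flow_sample(
            {
                "A": {"n_events": 0, "channels": {"PE": (100.0, 0.3)}},
                "B": {"n_events": 10, "channels": {"PE": (100.0, 0.3)}},
            },
            n_bead_events=5,
            beads_added=100,
            seed=5,
        )
        assert table.n_events("A") == 0
        assert table.n_events("B") == 10

    def test_reserved_bead_label_rejected(self):
        with pytest.raises(ValueError):
            generate_flow_sample(
                {BEAD_LABEL: {"n_events": 1, "channels": {}}},
                n_bead_events=1,
                beads_added=10,
            )
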