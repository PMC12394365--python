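"""Generator contracts: design shape, moments, determinism, table I/O."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from constind import (
    ConfigurationError,
    GeneratorConfig,
    PhosphorusTraitParams,
    TableFormatError,
    TraitModel,
    generate_experiment,
    make_config,
    maritime_pine_preset,
    read_table,
    write_table,
)
from conftest import make_single_trait_config


class TestDesignShape:
    def test_default_preset_emits_full_factorial(self):
        table = generate_experiment(maritime_pine_preset())
        assert len(table) == 33 * 2 * 2 * 4 == 528
        assert set(table.columns) == {
            "seedling_id", "family_id", "block", "phosphorus", "induction",
            "stem_resin", "needle_phenolics",
        }

    def test_degenerate_design_single_row(self):
        cfg = make_single_trait_config(n_families=1, n_blocks=1)
        cfg = cfg.model_copy(update={"induction_levels": ("control",)})
        assert len(generate_experiment(cfg)) == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n_fam=st.integers(1, 5),
        n_blocks=st.integers(1, 3),
        n_phos=st.integers(1, 2),
        n_ind=st.integers(1, 2),
        seed=st.integers(0, 10),
    )
    def test_design_balance_one_record_per_cell(self, n_fam, n_blocks, n_phos, n_ind, seed):
        cfg = make_single_trait_config(
            n_families=n_fam,
            n_blocks=n_blocks,
            seed=seed,
            phosphorus_levels=("low", "high")[:n_phos],
        )
        cfg = cfg.model_copy(
            update={"induction_levels": ("control", "JA")[:n_ind]}
        )
        table = generate_experiment(cfg)
        counts = table.groupby(
            ["family_id", "block", "phosphorus", "induction"]
        ).size()
        assert len(table) == n_fam * n_blocks * n_phos * n_ind
        assert (counts == 1).all()


class TestGenerativeMoments:
    def test_noiseless_generator_exact_cell_means(self):
        cfg = make_single_trait_config(n_families=3, n_blocks=2, seed=7)
        table = generate_experiment(cfg)
        control = table.loc[table.induction == "control", "resin"]
        ja = table.loc[table.induction == "JA", "resin"]
        assert (control == 10.0).all()
        assert (ja == 13.0).all()

    def test_family_effect_correlation_recovered(self):
        # seed-averaged sample corr of latent (C, D) within +-0.05 of rho
        rho = -0.6
        corrs = []
        for seed in range(20):
            cfg = make_single_trait_config(
                n_families=500,
                n_blocks=1,
                seed=seed,
                sigma_family_constitutive=8.0,
                sigma_family_inducibility=5.0,
                rho_tradeoff=rho,
            )
            _, truth = generate_experiment(cfg, return_truth=True)
            corrs.append(
                np.corrcoef(truth.constitutive_true, truth.inducibility_true)[0, 1]
            )
        assert abs(np.mean(corrs) - rho) < 0.05

    def test_truncate_at_zero_clamps(self):
        kwargs = dict(
            n_families=50, n_blocks=2, seed=3,
            grand_constitutive_mean=1.0, sigma_family_constitutive=5.0,
        )
        raw = generate_experiment(make_single_trait_config(**kwargs))
        assert (raw.resin < 0).any()
        cfg = make_single_trait_config(**kwargs).model_copy(
            update={"truncate_at_zero": True}
        )
        assert (generate_experiment(cfg).resin >= 0).all()

    def test_missing_fraction_drops_rows(self):
        cfg = make_single_trait_config(n_families=30, n_blocks=4).model_copy(
            update={"missing_fraction": 0.2}
        )
        table = generate_experiment(cfg)
        assert len(table) < 240
        assert len(table) == len(generate_experiment(cfg))  # deterministic

    def test_same_seed_byte_identical(self):
        cfg = maritime_pine_preset(seed=11)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_table(generate_experiment(cfg), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]


class TestConfigValidation:
    def test_invalid_correlation_rejected(self):
        with pytest.raises((ConfigurationError, ValueError)):
            PhosphorusTraitParams(
                grand_constitutive_mean=10, sigma_family_constitutive=1,
                mean_inducibility=1, sigma_family_inducibility=1,
                rho_tradeoff=1.5,
            )

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            make_config(
                n_families=0,
                traits=maritime_pine_preset().traits,
            )

    def test_trait_must_cover_all_phosphorus_levels(self):
        trait = TraitModel(
            trait_name="resin",
            per_phosphorus={
                "low": PhosphorusTraitParams(
                    grand_constitutive_mean=10, sigma_family_constitutive=0,
                    mean_inducibility=1, sigma_family_inducibility=0,
                    rho_tradeoff=0,
                )
            },
        )
        with pytest.raises(ConfigurationError):
            make_config(phosphorus_levels=("low", "high"), traits=(trait,))

    def test_induced_correlation_converter_round_trips(self):
        # corr(C, C + D) computed from the converted (sigma_D, rho_CD)
        # must equal the requested constitutive-induced correlation
        for rho_ci in (-0.9, -0.5, 0.0, 0.4):
            p = PhosphorusTraitParams.from_induced_correlation(
                grand_constitutive_mean=100, mean_inducibility=10,
                sigma_family_constitutive=10, sigma_family_induced=14,
                rho_constitutive_induced=rho_ci,
            )
            s_c, s_d = p.sigma_family_constitutive, p.sigma_family_inducibility
            cov_ci = s_c**2 + p.rho_tradeoff * s_c * s_d
            var_i = s_c**2 + s_d**2 + 2 * p.rho_tradeoff * s_c * s_d
            assert cov_ci / (s_c * np.sqrt(var_i)) == pytest.approx(rho_ci, abs=1e-9)


class TestPreset:
    def test_preset_low_phosphorus_strong_tradeoff(self):
        cfg = maritime_pine_preset()
        for trait in cfg.traits:
            assert trait.per_phosphorus["low"].rho_tradeoff <= -0.7

    def test_preset_high_phosphorus_null(self):
        cfg = maritime_pine_preset()
        for trait in cfg.traits:
            assert trait.per_phosphorus["high"].rho_tradeoff == 0.0

    def test_preset_concentrations_realistic(self):
        cfg = maritime_pine_preset()
        for trait in cfg.traits:
            for par in trait.per_phosphorus.values():
                assert 0 < par.grand_constitutive_mean <= 200.0


class TestTableIO:
    def test_written_file_line_count(self, tmp_path):
        path = tmp_path / "t.csv"
        write_table(generate_experiment(maritime_pine_preset()), path)
        assert len(path.read_text().splitlines()) == 529  # header + 528 rows

    def test_round_trip_identity(self, tmp_path):
        table = generate_experiment(maritime_pine_preset(seed=2))
        path = tmp_path / "t.csv"
        write_table(table, path)
        back = read_table(path)
        pd.testing.assert_frame_equal(back, table.reset_index(drop=True))

    def test_strict_labels_reject_trailing_space(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "seedling_id,family_id,block,phosphorus,induction,resin\n"
            "S1,F1,B1,low,control,10.0\n"
            "S2,F1,B1,low,ja ,13.0\n"
        )
        with pytest.raises(TableFormatError, match="ja "):
            read_table(path)

    def test_duplicate_seedling_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "seedling_id,family_id,block,phosphorus,induction,resin\n"
            "S1,F1,B1,low,control,10.0\n"
            "S1,F1,B2,low,control,11.0\n"
        )
        with pytest.raises(TableFormatError, match="duplicate"):
            read_table(path)

    def test_unparseable_value_names_row_and_column(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text(
            "seedling_id,family_id,block,phosphorus,induction,resin\n"
            "S1,F1,B1,low,control,10.0\n"
            "S2,F1,B2,low,control,oops\n"
        )
        with pytest.raises(TableFormatError) as err:
            read_table(path)
        assert "resin" in str(err.value) and "row 2" in str(err.value)

    def test_missing_values_round_trip_as_empty(self, tmp_path):
        table = generate_experiment(make_single_trait_config(seed=5))
        table.loc[2, "resin"] = np.nan
        path = tmp_path / "miss.csv"
        write_table(table, path)
        back = read_table(path)
        assert np.isnan(back.loc[2, "resin"])

    def test_unknown_column_rejected_when_traits_specified(self, tmp_path):
        path = tmp_path / "extra.csv"
        write_table(generate_experiment(make_single_trait_config()), path)
        with pytest.raises(TableFormatError, match="unknown"):
            read_table(path, trait_names=["other_trait"])
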