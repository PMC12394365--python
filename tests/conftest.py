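import itertools

import numpy as np
import pandas as pd
import pytest

from constind import GeneratorConfig, PhosphorusTraitParams, TraitModel


def make_single_trait_config(
    n_families=4,
    n_blocks=3,
    seed=0,
    trait_name="resin",
    phosphorus_levels=("low",),
    **params,
):
    """GeneratorConfig with one trait and identical params at every P level."""
    defaults = dict(
        grand_constitutive_mean=10.0,
        sigma_family_constitutive=0.0,
        mean_inducibility=3.0,
        sigma_family_inducibility=0.0,
        rho_tradeoff=0.0,
    )
    defaults.update(params)
    p = PhosphorusTraitParams(**defaults)
    trait = TraitModel(
        trait_name=trait_name,
        per_phosphorus={lvl: p for lvl in phosphorus_levels},
    )
    return GeneratorConfig(
        n_families=n_families,
        n_blocks=n_blocks,
        phosphorus_levels=tuple(phosphorus_levels),
        traits=(trait,),
        seed=seed,
    )


def balanced_table(
    control_by_family,
    ja_by_family,
    n_blocks=4,
    phosphorus="low",
    trait_name="resin",
    noise_sd=0.0,
    block_effects=None,
    seed=0,
):
    """Hand-built balanced one-trait table with known cell means."""
    rng = np.random.default_rng(seed)
    families = sorted(control_by_family)
    rows = []
    sid = 0
    for fam, ind, blk in itertools.product(
        families, ("control", "JA"), range(n_blocks)
    ):
        base = control_by_family[fam] if ind == "control" else ja_by_family[fam]
        if block_effects is not None:
            base += block_effects[blk]
        sid += 1
        rows.append(
            {
                "seedling_id": f"S{sid:04d}",
                "family_id": fam,
                "block": f"B{blk + 1}",
                "phosphorus": phosphorus,
                "induction": ind,
                trait_name: base + noise_sd * rng.standard_normal(),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def single_trait_config():
    return make_single_trait_config


@pytest.fixture
def table_builder():
    return balanced_table
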