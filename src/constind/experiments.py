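"""Validation experiments: calibration, power, oracle checks, preset pattern.

These are first-class, reproducible computational experiments that
characterise the pipeline's statistical behaviour on synthetic data with a
known ground truth.  They are used both by the test suite and by
``scripts/acceptance.py``.

Study conditions
----------------
* *Calibration* runs the full generator -> least-square means -> Monte Carlo
  pipeline under the null hypothesis of the spurious-correlation test —
  true constitutive and true induced family levels independent
  (``rho_constitutive_induced = 0``) — with sampling error of the family
  mean equal to the between-family SD.  A calibrated test rejects at the
  nominal 5% rate; the naive Pearson test on the same replicates rejects
  far more often, which is the artefact the Monte Carlo null exists to fix.
* *Power* uses a strong true trade-off (``rho_constitutive_induced = -0.9``,
  equivalently a constitutive/inducibility correlation of about -0.97) with
  between-family SD twice the sampling SD and 33 families, the design size
  of the emulated trial.
* *Null-centre* checks the closed form: with no sampling noise and equal
  between-family variances, corr(C, I - C) for independent C, I has
  expectation -sqrt(VarC / (VarC + VarI)) = -1/sqrt(2).
* *Oracle* checks compare the least-square-mean path against an independent
  normal-equations solver built on a different design-matrix codepath, and
  the Pearson r against the direct summation formula.
"""

from __future__ import annotations

import itertools
from typing import Optional

import numpy as np
import pandas as pd

from .means import MeansModelSpec, fit_family_means
from .simulate import (
    GeneratorConfig,
    PhosphorusTraitParams,
    TraitModel,
    generate_experiment,
    maritime_pine_preset,
)
from .tradeoff import (
    TradeoffInput,
    build_tradeoff_input,
    classify_tradeoff,
    monte_carlo_null,
    pearson_correlation,
)

__all__ = [
    "single_trait_config",
    "analyze_dataset",
    "null_center_experiment",
    "calibration_experiment",
    "conservativeness_experiment",
    "power_experiment",
    "preset_pattern_experiment",
    "normal_equations_lsmeans",
    "lsmeans_oracle_discrepancy",
    "pearson_oracle_discrepancy",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic 32-bit child seeds for replicate runs."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


def single_trait_config(
    params: PhosphorusTraitParams,
    seed: int,
    n_families: int = 33,
    n_blocks: int = 4,
    trait_name: str = "stem_resin",
) -> GeneratorConfig:
    """One-trait, one-phosphorus-level design (the unit of a replicate run)."""
    return GeneratorConfig(
        n_families=n_families,
        n_blocks=n_blocks,
        phosphorus_levels=("low",),
        traits=(TraitModel(trait_name=trait_name, per_phosphorus={"low": params}),),
        seed=seed,
    )


def analyze_dataset(
    table: pd.DataFrame,
    trait_name: str,
    phosphorus: str,
    n_sims: int,
    seed: int,
    alpha: float = 0.05,
):
    """Means -> trade-off input -> Pearson + Monte Carlo + verdict for one panel."""
    spec = MeansModelSpec(trait_name=trait_name, phosphorus=phosphorus)
    means = fit_family_means(table, spec)
    ti = build_tradeoff_input(means, trait_name, phosphorus)
    pearson = pearson_correlation(ti.constitutive, ti.inducibility)
    mc = monte_carlo_null(ti, n_sims=n_sims, seed=seed)
    verdict = classify_tradeoff(pearson, mc, alpha=alpha)
    return pearson, mc, verdict


def null_center_experiment(
    n_families: int = 200,
    n_sims: int = 2000,
    seed: int = 0,
    sigma_family: float = 10.0,
) -> float:
    """Monte Carlo null mean of r with zero sampling variance, equal variances.

    Builds a :class:`TradeoffInput` whose constitutive and induced values
    are independent draws with equal between-family SD and zero sampling
    variance, then returns the simulated ``null_mean_r`` (expected
    -1/sqrt(2)).
    """
    rng = np.random.default_rng(seed)
    c = 100.0 + sigma_family * rng.standard_normal(n_families)
    i = 115.0 + sigma_family * rng.standard_normal(n_families)
    ti = TradeoffInput(
        trait_name="stem_resin",
        phosphorus="low",
        family_ids=tuple(f"F{k}" for k in range(n_families)),
        constitutive=c,
        inducibility=i - c,
        var_control=np.zeros(n_families),
        var_induced=np.zeros(n_families),
    )
    mc = monte_carlo_null(ti, n_sims=n_sims, seed=int(_child_seeds(seed, 1)[0]))
    return mc.null_mean_r


def calibration_experiment(
    n_reps: int = 500,
    n_sims: int = 2000,
    seed: int = 0,
    n_families: int = 33,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the Monte Carlo test vs the naive Pearson test.

    Data are generated under the test's null (independent constitutive and
    induced family levels, sigma_C = sigma_I = 10) with the sampling SD of a
    four-block family mean equal to the between-family SD
    (sigma_residual = 20, so SE = 20/sqrt(4) = 10).
    """
    params = PhosphorusTraitParams.from_induced_correlation(
        grand_constitutive_mean=100.0,
        mean_inducibility=15.0,
        sigma_family_constitutive=10.0,
        sigma_family_induced=10.0,
        rho_constitutive_induced=0.0,
        sigma_residual=20.0,
    )
    seeds = _child_seeds(seed, 2 * n_reps)
    mc_reject = 0
    pearson_reject = 0
    for k in range(n_reps):
        cfg = single_trait_config(params, seed=int(seeds[2 * k]), n_families=n_families)
        table = generate_experiment(cfg)
        pearson, mc, _ = analyze_dataset(
            table, "stem_resin", "low", n_sims=n_sims, seed=int(seeds[2 * k + 1]),
            alpha=alpha,
        )
        mc_reject += mc.p_mc < alpha
        pearson_reject += pearson.p_two_sided < alpha
    return {
        "mc_rejection_rate": mc_reject / n_reps,
        "pearson_rejection_rate": pearson_reject / n_reps,
        "n_reps": n_reps,
    }


def conservativeness_experiment(
    n_reps: int = 200,
    n_sims: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rate when constitutive level and *inducibility* are independent.

    With corr(C, D) = 0 the induced level I = C + D is positively correlated
    with C, which is farther from a trade-off than the test's null of
    independent C and I; the Monte Carlo test should reject at most alpha.
    """
    params = PhosphorusTraitParams(
        grand_constitutive_mean=100.0,
        sigma_family_constitutive=10.0,
        mean_inducibility=15.0,
        sigma_family_inducibility=10.0,
        rho_tradeoff=0.0,
        sigma_residual=20.0,
    )
    seeds = _child_seeds(seed, 2 * n_reps)
    mc_reject = 0
    for k in range(n_reps):
        cfg = single_trait_config(params, seed=int(seeds[2 * k]))
        table = generate_experiment(cfg)
        _, mc, _ = analyze_dataset(
            table, "stem_resin", "low", n_sims=n_sims, seed=int(seeds[2 * k + 1]),
            alpha=alpha,
        )
        mc_reject += mc.p_mc < alpha
    return {"mc_rejection_rate": mc_reject / n_reps, "n_reps": n_reps}


def power_experiment(
    n_reps: int = 200,
    n_sims: int = 2000,
    seed: int = 0,
    n_families: int = 33,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of replicates classified ``true_tradeoff`` under a strong trade-off.

    sigma_C = sigma_I = 10, twice the sampling SD of the family mean
    (sigma_residual = 10, four blocks -> SE = 5), with
    corr(C, I) = -0.9 (constitutive/inducibility correlation about -0.97).
    """
    params = PhosphorusTraitParams.from_induced_correlation(
        grand_constitutive_mean=100.0,
        mean_inducibility=15.0,
        sigma_family_constitutive=10.0,
        sigma_family_induced=10.0,
        rho_constitutive_induced=-0.9,
        sigma_residual=10.0,
    )
    seeds = _child_seeds(seed, 2 * n_reps)
    hits = 0
    for k in range(n_reps):
        cfg = single_trait_config(params, seed=int(seeds[2 * k]), n_families=n_families)
        table = generate_experiment(cfg)
        _, _, verdict = analyze_dataset(
            table, "stem_resin", "low", n_sims=n_sims, seed=int(seeds[2 * k + 1]),
            alpha=alpha,
        )
        hits += verdict.category == "true_tradeoff"
    return {"true_tradeoff_rate": hits / n_reps, "n_reps": n_reps}


def preset_pattern_experiment(
    n_reps: int = 50,
    n_sims: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Qualitative four-panel pattern of the default preset.

    Success per replicate: both traits classified ``true_tradeoff`` at low
    phosphorus AND neither classified ``true_tradeoff`` at high phosphorus.
    """
    seeds = _child_seeds(seed, n_reps * 5)
    pattern_hits = 0
    panel_hits: dict[tuple[str, str], int] = {}
    base = maritime_pine_preset()
    traits = [t.trait_name for t in base.traits]
    for k in range(n_reps):
        cfg = maritime_pine_preset(seed=int(seeds[5 * k]))
        table = generate_experiment(cfg)
        verdicts: dict[tuple[str, str], str] = {}
        for j, (trait, phos) in enumerate(itertools.product(traits, ("low", "high"))):
            _, _, verdict = analyze_dataset(
                table, trait, phos, n_sims=n_sims, seed=int(seeds[5 * k + 1 + j]),
                alpha=alpha,
            )
            verdicts[(trait, phos)] = verdict.category
            ok = (
                verdict.category == "true_tradeoff"
                if phos == "low"
                else verdict.category != "true_tradeoff"
            )
            panel_hits[(trait, phos)] = panel_hits.get((trait, phos), 0) + ok
        if all(verdicts[(t, "low")] == "true_tradeoff" for t in traits) and all(
            verdicts[(t, "high")] != "true_tradeoff" for t in traits
        ):
            pattern_hits += 1
    out: dict[str, float] = {
        "pattern_rate": pattern_hits / n_reps,
        "n_reps": n_reps,
    }
    for (trait, phos), hits in panel_hits.items():
        out[f"{trait}_{phos}_ok_rate"] = hits / n_reps
    return out


# ---------------------------------------------------------------------------
# independent oracles


def normal_equations_lsmeans(
    table: pd.DataFrame,
    trait_name: str,
    phosphorus: str,
) -> dict[tuple[str, str], float]:
    """LS means via an explicit dummy design matrix and pseudo-inverse.

    Independent of the patsy/statsmodels codepath used by
    :func:`constind.means.fit_family_means`: the design matrix is built with
    ``pandas.get_dummies`` (full one-hot, no reference coding) and solved by
    ``numpy.linalg.pinv`` normal equations; each (family, induction) LS mean
    is the fitted value averaged with equal weight over all blocks.
    """
    sub = table.loc[
        (table["phosphorus"] == phosphorus) & table[trait_name].notna()
    ].copy()
    y = sub[trait_name].to_numpy(dtype=float)

    def one_hot(frame: pd.DataFrame) -> np.ndarray:
        parts = [np.ones((len(frame), 1))]
        for col in ("block", "family_id", "induction"):
            parts.append(pd.get_dummies(frame[col], dtype=float).to_numpy())
        inter = pd.get_dummies(
            frame["family_id"].astype(str) + "\x00" + frame["induction"].astype(str),
            dtype=float,
        )
        parts.append(inter.to_numpy())
        return np.hstack(parts)

    # shared dummy-column layout: fit rows and prediction rows concatenated
    families = sorted(sub["family_id"].unique())
    inductions = sorted(sub["induction"].unique())
    blocks = sorted(sub["block"].unique())
    pred = pd.DataFrame(
        [(b, f, i) for f in families for i in inductions for b in blocks],
        columns=["block", "family_id", "induction"],
    )
    combined = pd.concat(
        [sub[["block", "family_id", "induction"]], pred], ignore_index=True
    )
    design = one_hot(combined)
    X = design[: len(sub)]
    P = design[len(sub):]

    beta = np.linalg.pinv(X) @ y
    fitted = P @ beta
    out: dict[tuple[str, str], float] = {}
    row = 0
    for f in families:
        for i in inductions:
            out[(f, i)] = float(fitted[row : row + len(blocks)].mean())
            row += len(blocks)
    return out


def lsmeans_oracle_discrepancy(seed: int = 0, drop_rows: int = 3) -> float:
    """Max |LS mean - oracle| over all cells of an unbalanced toy table."""
    params = PhosphorusTraitParams(
        grand_constitutive_mean=50.0,
        sigma_family_constitutive=8.0,
        mean_inducibility=10.0,
        sigma_family_inducibility=6.0,
        rho_tradeoff=-0.4,
        sigma_block=4.0,
        sigma_residual=5.0,
    )
    cfg = single_trait_config(params, seed=seed, n_families=6, n_blocks=3)
    table = generate_experiment(cfg)
    rng = np.random.default_rng(seed + 1)
    # delete rows but never empty a (family, induction) cell
    for _ in range(drop_rows):
        for cand in rng.permutation(len(table)):
            r = table.iloc[cand]
            cell = table[
                (table["family_id"] == r["family_id"])
                & (table["induction"] == r["induction"])
            ]
            if len(cell) > 1:
                table = table.drop(table.index[cand]).reset_index(drop=True)
                break
    means = fit_family_means(
        table, MeansModelSpec(trait_name="stem_resin", phosphorus="low")
    )
    oracle = normal_equations_lsmeans(table, "stem_resin", "low")
    return max(abs(m.estimate - oracle[(m.family_id, m.induction)]) for m in means)


def pearson_oracle_discrepancy(seed: int = 0, n: int = 25) -> float:
    """|r - direct summation oracle| on a random dataset."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 0.3 * x + rng.normal(size=n)
    r_impl = pearson_correlation(x, y).r
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    r_oracle = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return float(abs(r_impl - r_oracle))
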