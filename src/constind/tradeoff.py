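"""Constitutive vs inducibility correlation and its Monte Carlo spurious-correlation null.

The scientific question is whether half-sib families with high constitutive
defence have low inducibility — a genetic trade-off.  The natural statistic
is the family-level Pearson correlation between the constitutive estimate
``x_f`` (control-cell least-square mean) and the inducibility estimate
``y_f = i_f - x_f`` (induced minus control mean).  That statistic is biased
toward negative values even when nothing is traded off, because the
sampling error of ``x_f`` enters both axes with opposite sign (the classic
part-whole artefact).

The Monte Carlo null quantifies exactly how negative the correlation would
be if true constitutive and true *induced* levels were independent, given
the observed means, between-family variances and per-family sampling
variances.  Each simulation:

1. draws a true constitutive value per family from
   ``Normal(mean(x), max(S2_x - mean(var_control), 0))`` and, independently,
   a true induced value from
   ``Normal(mean(i), max(S2_i - mean(var_induced), 0))`` — the between-family
   variances deflated by the average sampling variance so that the *noisy*
   simulated values reproduce the observed marginal variances;
2. adds per-family sampling noise ``Normal(0, var_control_f)`` and
   ``Normal(0, var_induced_f)``;
3. forms simulated inducibility = noisy induced - noisy constitutive and
   records the Pearson r against the noisy constitutive values.

The lower-tail Monte Carlo P-value, with an add-one correction,
``p_mc = (1 + #{r_sim <= r_obs}) / (n_sims + 1)``, is the probability of a
spurious correlation at least as negative as the one observed.  An observed
negative correlation is declared a *true* trade-off only when both the
ordinary Pearson P and the Monte Carlo P fall below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InferenceError
from .means import FamilyCellMean

__all__ = [
    "TradeoffInput",
    "PearsonResult",
    "MonteCarloResult",
    "TradeoffVerdict",
    "build_tradeoff_input",
    "pearson_correlation",
    "monte_carlo_null",
    "mc_p_value",
    "classify_tradeoff",
]

logger = logging.getLogger(__name__)

_MAX_REDRAW_ROUNDS = 100


@dataclass(frozen=True)
class TradeoffInput:
    """Aligned per-family estimates for one trait x phosphorus combination.

    ``constitutive`` is the control-cell estimate, ``inducibility`` the
    induced-minus-control difference; ``var_control`` / ``var_induced`` are
    the squared standard errors of the two cell means.
    """

    trait_name: str
    phosphorus: str
    family_ids: tuple[str, ...]
    constitutive: np.ndarray
    inducibility: np.ndarray
    var_control: np.ndarray
    var_induced: np.ndarray

    def __post_init__(self) -> None:
        for name in ("constitutive", "inducibility", "var_control", "var_induced"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(self.family_ids),):
                raise InferenceError(f"{name} not aligned with family_ids")
        if len(self.family_ids) < 3:
            raise InferenceError(
                f"need >= 3 families, got {len(self.family_ids)} for "
                f"{self.trait_name}/{self.phosphorus}"
            )
        if (self.var_control < 0).any() or (self.var_induced < 0).any():
            raise InferenceError("sampling variances must be >= 0")

    @property
    def induced(self) -> np.ndarray:
        """Induced-cell estimates (constitutive + inducibility)."""
        return self.constitutive + self.inducibility

    @property
    def n_families(self) -> int:
        return len(self.family_ids)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_two_sided: float
    n: int


@dataclass(frozen=True)
class MonteCarloResult:
    observed_r: float
    n_sims: int
    seed: int
    p_mc: float
    tail: str
    null_mean_r: float
    null_quantiles: dict[str, float]
    null_histogram: tuple[np.ndarray, np.ndarray] = field(repr=False)
    n_redraws: int = 0


@dataclass(frozen=True)
class TradeoffVerdict:
    category: Literal["true_tradeoff", "spurious_only", "no_tradeoff"]
    alpha: float


def build_tradeoff_input(
    means: Iterable[FamilyCellMean],
    trait_name: str,
    phosphorus: str,
    control_label: str = "control",
    induced_label: str = "JA",
) -> TradeoffInput:
    """Pair control and induced family means into a :class:`TradeoffInput`.

    Families missing either cell, or whose standard error is unavailable,
    are dropped with a logged warning; fewer than 3 complete families is an
    :class:`InferenceError`.
    """
    control: dict[str, FamilyCellMean] = {}
    induced: dict[str, FamilyCellMean] = {}
    for m in means:
        if m.trait_name != trait_name or m.phosphorus != phosphorus:
            continue
        if m.induction == control_label:
            control[m.family_id] = m
        elif m.induction == induced_label:
            induced[m.family_id] = m
    all_families = sorted(set(control) | set(induced))
    if not all_families:
        raise InferenceError(
            f"no means found for trait {trait_name!r}, phosphorus {phosphorus!r} "
            f"with induction labels {control_label!r}/{induced_label!r}"
        )

    kept: list[str] = []
    for fam in all_families:
        c, i = control.get(fam), induced.get(fam)
        if c is None or i is None:
            missing = induced_label if i is None else control_label
            logger.warning(
                "family %s dropped: missing %s cell (%s/%s)",
                fam, missing, trait_name, phosphorus,
            )
            continue
        if c.std_error is None or i.std_error is None:
            logger.warning(
                "family %s dropped: standard error unavailable (%s/%s)",
                fam, trait_name, phosphorus,
            )
            continue
        kept.append(fam)
    if len(kept) < 3:
        raise InferenceError(
            f"only {len(kept)} complete families for {trait_name}/{phosphorus}; "
            "need >= 3"
        )
    c_est = np.array([control[f].estimate for f in kept])
    i_est = np.array([induced[f].estimate for f in kept])
    return TradeoffInput(
        trait_name=trait_name,
        phosphorus=phosphorus,
        family_ids=tuple(kept),
        constitutive=c_est,
        inducibility=i_est - c_est,
        var_control=np.array([control[f].std_error ** 2 for f in kept]),
        var_induced=np.array([induced[f].std_error ** 2 for f in kept]),
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with the two-sided t-transform P-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InferenceError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise InferenceError(f"need >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InferenceError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p_two_sided=float(res.pvalue), n=n)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def mc_p_value(observed_r: float, null_r: np.ndarray, tail: str = "lower") -> float:
    """Add-one-corrected Monte Carlo P-value against a sample of null statistics.

    ``lower``: probability of a simulated r at least as negative as observed.
    ``two_sided``: doubled smaller tail, capped at 1.
    """
    null_r = np.asarray(null_r, dtype=float)
    n = null_r.size
    lower = (1 + int((null_r <= observed_r).sum())) / (n + 1)
    if tail == "lower":
        return lower
    if tail == "two_sided":
        upper = (1 + int((null_r >= observed_r).sum())) / (n + 1)
        return min(1.0, 2.0 * min(lower, upper))
    raise InferenceError(f"unknown tail {tail!r}")


def monte_carlo_null(
    tradeoff_input: TradeoffInput,
    n_sims: int = 10_000,
    seed: int = 0,
    tail: str = "lower",
    deflate_sampling_variance: bool = True,
    n_bins: int = 40,
) -> MonteCarloResult:
    """Simulate the null distribution of spurious constitutive-inducibility correlations.

    See the module docstring for the generative scheme.  Deterministic given
    ``seed``; all ``n_sims`` simulations are drawn from a single seeded
    generator in a fixed order.  Simulations that produce a constant vector
    (possible only when the corresponding variances are all zero on one
    axis) are re-drawn and counted in ``n_redraws``.

    ``deflate_sampling_variance=False`` uses the raw between-family
    variances of the observed estimates instead of subtracting the mean
    sampling variance (for sensitivity analysis).
    """
    ti = tradeoff_input
    if n_sims < 100:
        raise InferenceError(f"n_sims must be >= 100, got {n_sims}")
    x = ti.constitutive
    i_obs = ti.induced
    n_fam = ti.n_families

    obs = pearson_correlation(x, ti.inducibility)
    observed_r = obs.r

    mean_c, mean_i = float(x.mean()), float(i_obs.mean())
    s2_c = float(np.var(x, ddof=1))
    s2_i = float(np.var(i_obs, ddof=1))
    if deflate_sampling_variance:
        tau2_c = max(s2_c - float(ti.var_control.mean()), 0.0)
        tau2_i = max(s2_i - float(ti.var_induced.mean()), 0.0)
    else:
        tau2_c, tau2_i = s2_c, s2_i

    sd_noise_c = np.sqrt(ti.var_control)
    sd_noise_i = np.sqrt(ti.var_induced)
    x_varies = tau2_c > 0 or bool((ti.var_control > 0).any())
    y_varies = x_varies or tau2_i > 0 or bool((ti.var_induced > 0).any())
    if not (x_varies and y_varies):
        raise InferenceError(
            "degenerate null: all between-family and sampling variances are zero"
        )

    rng = np.random.default_rng(seed)

    def draw(count: int) -> np.ndarray:
        c_true = mean_c + np.sqrt(tau2_c) * rng.standard_normal((count, n_fam))
        i_true = mean_i + np.sqrt(tau2_i) * rng.standard_normal((count, n_fam))
        x_sim = c_true + sd_noise_c * rng.standard_normal((count, n_fam))
        i_sim = i_true + sd_noise_i * rng.standard_normal((count, n_fam))
        return _rowwise_pearson(x_sim, i_sim - x_sim)

    r_sims = draw(n_sims)
    n_redraws = 0
    rounds = 0
    while np.isnan(r_sims).any():
        bad = int(np.isnan(r_sims).sum())
        n_redraws += bad
        rounds += 1
        if rounds > _MAX_REDRAW_ROUNDS:
            raise InferenceError("degenerate null: simulations keep producing constants")
        logger.warning("re-drawing %d degenerate simulation(s)", bad)
        r_sims[np.isnan(r_sims)] = draw(bad)

    p = mc_p_value(observed_r, r_sims, tail=tail)
    q = np.quantile(r_sims, [0.025, 0.5, 0.975])
    counts, edges = np.histogram(r_sims, bins=np.linspace(-1.0, 1.0, n_bins + 1))
    return MonteCarloResult(
        observed_r=observed_r,
        n_sims=n_sims,
        seed=seed,
        p_mc=float(p),
        tail=tail,
        null_mean_r=float(r_sims.mean()),
        null_quantiles={"q025": float(q[0]), "q500": float(q[1]), "q975": float(q[2])},
        null_histogram=(edges, counts),
        n_redraws=n_redraws,
    )


def classify_tradeoff(
    pearson: PearsonResult,
    mc: MonteCarloResult,
    alpha: float = 0.05,
) -> TradeoffVerdict:
    """Categorical verdict from the naive and Monte Carlo tests.

    * ``true_tradeoff``: r < 0, Pearson p < alpha and Monte Carlo p < alpha;
    * ``spurious_only``: r < 0, Pearson p < alpha but Monte Carlo p >= alpha
      (the negative correlation is within what shared sampling error
      produces on its own);
    * ``no_tradeoff`` otherwise.
    """
    if not 0.0 < alpha < 1.0:
        raise InferenceError(f"alpha must be in (0, 1), got {alpha}")
    if pearson.r < 0 and pearson.p_two_sided < alpha:
        category = "true_tradeoff" if mc.p_mc < alpha else "spurious_only"
    else:
        category = "no_tradeoff"
    return TradeoffVerdict(category=category, alpha=alpha)
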