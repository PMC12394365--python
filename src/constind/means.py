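"""Per-family least-square means within each phosphorus stratum.

The estimands are the family x induction marginal means of a trait,
averaged with equal weight over blocks — the quantities that downstream
trade-off inference treats as "constitutive level" (control cell) and, by
difference, "inducibility" (induced cell minus control cell).

Two estimators are provided:

``ols_lsmeans``
    Fit an ordinary-least-squares model with blocks, families, induction and
    the family x induction interaction as fixed effects on the data of one
    phosphorus level, then evaluate each (family, induction) marginal mean as
    an estimable function averaged over blocks.  Robust to moderate
    imbalance (missing seedlings); standard errors come from the residual
    variance and the contrast vector.

``cell_means``
    Arithmetic mean of the (family, induction) cell over blocks, with a
    residual-pooled standard error.  On fully balanced data the two
    estimators give identical estimates; the cell-means SE additionally
    pools block-to-block variation into the residual.

Families are treated as fixed effects: the goal is family-level means with
correct sampling variances, not variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
import patsy
from pydantic import BaseModel, field_validator

from .errors import EstimationError
from .simulate import DESIGN_COLUMNS

__all__ = [
    "FamilyCellMean",
    "MeansModelSpec",
    "fit_family_means",
    "summarize_variances",
    "means_to_frame",
    "frame_to_means",
    "write_means",
    "read_means",
]

_TERM_FORMULAS = {
    "block": "C(block)",
    "family": "C(family_id)",
    "induction": "C(induction)",
    "family:induction": "C(family_id):C(induction)",
}


@dataclass(frozen=True)
class FamilyCellMean:
    """Least-square mean of one family x phosphorus x induction cell."""

    family_id: str
    phosphorus: str
    induction: str
    trait_name: str
    estimate: float
    std_error: Optional[float]  # None when residual degrees of freedom = 0
    n_obs: int


class MeansModelSpec(BaseModel):
    """Model specification for one trait within one phosphorus level."""

    model_config = {"frozen": True}

    trait_name: str
    phosphorus: str
    fixed_terms: tuple[str, ...] = ("block", "family", "induction", "family:induction")
    estimator: Literal["ols_lsmeans", "cell_means"] = "ols_lsmeans"

    @field_validator("fixed_terms")
    @classmethod
    def _terms_ok(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        unknown = [t for t in v if t not in _TERM_FORMULAS]
        if unknown:
            raise ValueError(f"unknown model term(s) {unknown}")
        if "family:induction" not in v:
            raise ValueError(
                "the family:induction term is required (it defines the estimands)"
            )
        return v


def _subset_for_fit(table: pd.DataFrame, spec: MeansModelSpec) -> pd.DataFrame:
    if spec.trait_name not in table.columns or spec.trait_name in DESIGN_COLUMNS:
        raise EstimationError(f"trait {spec.trait_name!r} not present in table")
    sub = table.loc[
        (table["phosphorus"] == spec.phosphorus) & table[spec.trait_name].notna()
    ].copy()
    if sub.empty:
        raise EstimationError(
            f"no observations at phosphorus level {spec.phosphorus!r}"
        )
    families = sorted(sub["family_id"].unique())
    inductions = sorted(sub["induction"].unique())
    counts = sub.groupby(["family_id", "induction"], sort=True).size()
    for fam in families:
        for ind in inductions:
            if (fam, ind) not in counts.index:
                raise EstimationError(
                    f"empty cell: family {fam!r}, induction {ind!r} at "
                    f"phosphorus {spec.phosphorus!r}"
                )
    return sub


def _fit_ols_lsmeans(sub: pd.DataFrame, spec: MeansModelSpec) -> list[FamilyCellMean]:
    rhs = " + ".join(_TERM_FORMULAS[t] for t in spec.fixed_terms)
    y = sub[spec.trait_name].to_numpy(dtype=float)
    X = patsy.dmatrix("1 + " + rhs, sub, return_type="matrix")
    design_info = X.design_info
    X = np.asarray(X)

    XtX = X.T @ X
    ncov = np.linalg.pinv(XtX, rcond=1e-12)
    beta = ncov @ (X.T @ y)
    resid = y - X @ beta
    rank = int(np.linalg.matrix_rank(X))
    df_resid = len(y) - rank
    sigma2 = float(resid @ resid) / df_resid if df_resid > 0 else None

    # row-space projector for estimability checks on rank-deficient designs
    projector = None
    if rank < X.shape[1]:
        projector = np.linalg.pinv(X) @ X

    families = sorted(sub["family_id"].unique())
    inductions = sorted(sub["induction"].unique())
    blocks = sorted(sub["block"].unique())
    counts = sub.groupby(["family_id", "induction"], sort=True).size()

    # design rows for every cell x block; LS mean averages over blocks
    pred = pd.DataFrame(
        [(f, i, b) for f in families for i in inductions for b in blocks],
        columns=["family_id", "induction", "block"],
    )
    (pred_X,) = patsy.build_design_matrices([design_info], pred)
    pred_X = np.asarray(pred_X)
    n_blocks = len(blocks)

    out: list[FamilyCellMean] = []
    row = 0
    for fam in families:
        for ind in inductions:
            L = pred_X[row : row + n_blocks].mean(axis=0)
            row += n_blocks
            if projector is not None:
                if np.linalg.norm(L @ projector - L) > 1e-8 * max(1.0, np.linalg.norm(L)):
                    warnings.warn(
                        f"non-estimable LS mean for family {fam!r}, induction "
                        f"{ind!r} at phosphorus {spec.phosphorus!r}; cell dropped",
                        stacklevel=3,
                    )
                    continue
            est = float(L @ beta)
            if sigma2 is None:
                se: Optional[float] = None
            else:
                se = float(np.sqrt(max(sigma2 * (L @ ncov @ L), 0.0)))
            out.append(
                FamilyCellMean(
                    family_id=fam,
                    phosphorus=spec.phosphorus,
                    induction=ind,
                    trait_name=spec.trait_name,
                    estimate=est,
                    std_error=se,
                    n_obs=int(counts[(fam, ind)]),
                )
            )
    return out


def _fit_cell_means(sub: pd.DataFrame, spec: MeansModelSpec) -> list[FamilyCellMean]:
    grouped = sub.groupby(["family_id", "induction"], sort=True)[spec.trait_name]
    stats = grouped.agg(["mean", "count"])
    # residual variance pooled over cells: sum of within-cell SS / sum of (n-1)
    ss = grouped.apply(lambda v: float(((v - v.mean()) ** 2).sum()))
    df = int((stats["count"] - 1).sum())
    sigma2 = float(ss.sum()) / df if df > 0 else None

    out: list[FamilyCellMean] = []
    for (fam, ind), r in stats.iterrows():
        n_c = int(r["count"])
        se = float(np.sqrt(sigma2 / n_c)) if sigma2 is not None else None
        out.append(
            FamilyCellMean(
                family_id=fam,
                phosphorus=spec.phosphorus,
                induction=ind,
                trait_name=spec.trait_name,
                estimate=float(r["mean"]),
                std_error=se,
                n_obs=n_c,
            )
        )
    return out


def fit_family_means(table: pd.DataFrame, spec: MeansModelSpec) -> list[FamilyCellMean]:
    """Estimate family x induction least-square means at one phosphorus level.

    Raises :class:`EstimationError` if any (family, induction) cell has no
    observations.  When the residual degrees of freedom are zero the
    estimates are returned with ``std_error=None``.
    """
    sub = _subset_for_fit(table, spec)
    if spec.estimator == "cell_means":
        return _fit_cell_means(sub, spec)
    return _fit_ols_lsmeans(sub, spec)


def summarize_variances(
    means: Iterable[FamilyCellMean],
) -> dict[tuple[str, str, str], dict[str, float]]:
    """Between-family variance of estimates and mean sampling variance.

    Returns, per ``(trait_name, phosphorus, induction)``::

        {"between_family_variance": ..., "mean_squared_std_error": ...,
         "n_families": ...}

    These are the moments that parameterize the Monte Carlo null.
    """
    groups: dict[tuple[str, str, str], list[FamilyCellMean]] = {}
    for m in means:
        groups.setdefault((m.trait_name, m.phosphorus, m.induction), []).append(m)
    if not groups:
        raise EstimationError("no family means supplied")
    out: dict[tuple[str, str, str], dict[str, float]] = {}
    for key, cells in groups.items():
        if len(cells) < 2:
            raise EstimationError(f"fewer than 2 families for {key}")
        if any(c.std_error is None for c in cells):
            raise EstimationError(
                f"standard errors unavailable for {key} (zero residual df)"
            )
        est = np.array([c.estimate for c in cells], dtype=float)
        se2 = np.array([c.std_error**2 for c in cells], dtype=float)
        out[key] = {
            "between_family_variance": float(np.var(est, ddof=1)),
            "mean_squared_std_error": float(se2.mean()),
            "n_families": float(len(cells)),
        }
    return out


# ---------------------------------------------------------------------------
# means table I/O

_MEANS_COLUMNS = [
    "family_id",
    "phosphorus",
    "induction",
    "trait_name",
    "estimate",
    "std_error",
    "n_obs",
]


def means_to_frame(means: Iterable[FamilyCellMean]) -> pd.DataFrame:
    rows = [
        {
            "family_id": m.family_id,
            "phosphorus": m.phosphorus,
            "induction": m.induction,
            "trait_name": m.trait_name,
            "estimate": m.estimate,
            "std_error": np.nan if m.std_error is None else m.std_error,
            "n_obs": m.n_obs,
        }
        for m in means
    ]
    return pd.DataFrame(rows, columns=_MEANS_COLUMNS)


def frame_to_means(frame: pd.DataFrame) -> list[FamilyCellMean]:
    missing = [c for c in _MEANS_COLUMNS if c not in frame.columns]
    if missing:
        raise EstimationError(f"means table missing column(s) {missing}")
    return [
        FamilyCellMean(
            family_id=str(r.family_id),
            phosphorus=str(r.phosphorus),
            induction=str(r.induction),
            trait_name=str(r.trait_name),
            estimate=float(r.estimate),
            std_error=None if pd.isna(r.std_error) else float(r.std_error),
            n_obs=int(r.n_obs),
        )
        for r in frame.itertuples()
    ]


def write_means(means: Iterable[FamilyCellMean], path) -> None:
    means_to_frame(means).to_csv(path, index=False)


def read_means(path) -> list[FamilyCellMean]:
    return frame_to_means(pd.read_csv(path))
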