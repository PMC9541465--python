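"""Stage-1 modelling: per-trait fixed-effects adjustment with fractional
polynomials, standardization of the residuals, and the rank-based inverse
normal transformation used for sensitivity analysis.

The mixed model downstream is fitted to *standardized residuals*: each trait
is regressed on its fixed effects (demographics, batch, principal
components, ...), continuous covariates entering through fractional
polynomials selected by the Royston-Altman closed test, and the residual is
scaled to unit variance.  Principal components always enter linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import chi2, rankdata

from mrnm.errors import DegenerateTraitError, ParameterError, ValidationError

FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def _fp_shift(x: np.ndarray) -> float:
    """Origin shift making x strictly positive (smallest-increment rule)."""
    xmin = np.min(x)
    if xmin > 0:
        return 0.0
    ux = np.unique(x)
    delta = np.min(np.diff(ux)) if ux.size > 1 else 1.0
    return float(-xmin + delta)


def _fp_basis(x: np.ndarray, powers: tuple[float, ...], shift: float) -> np.ndarray:
    """Columns of the fractional-polynomial basis for the given powers.

    Power 0 means ln(x); a repeated power (p, p) contributes x^p and
    x^p ln(x).
    """
    xs = x + shift
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        base = np.log(xs) if p == 0.0 else xs ** p
        if p in seen:
            cols.append(cols[seen[p]] * np.log(xs))
        else:
            seen[p] = len(cols)
            cols.append(base)
    return np.column_stack(cols)


@dataclass
class FixedEffectsModel:
    """A fitted stage-1 linear model for one trait.

    ``selected`` maps each FP-eligible column to its chosen power tuple
    (``()`` if the closed test dropped the term, ``(1.0,)`` if linear).
    """

    outcome: str
    design_columns: list[str]
    fp_columns: list[str]
    selected: dict[str, tuple[float, ...]]
    shifts: dict[str, float]
    coefficients: np.ndarray
    r_squared: float
    n_used: int
    sample_ids: list[str]
    fitted_values: np.ndarray
    _design_frame: pd.DataFrame | None = field(default=None, repr=False)

    def design_matrix(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))]
        for name in self.design_columns:
            x = data[name].to_numpy(dtype=float)
            if name in self.fp_columns:
                powers = self.selected[name]
                if len(powers) == 0:
                    continue
                cols.append(_fp_basis(x, powers, self.shifts[name]))
            else:
                cols.append(x[:, None])
        return np.column_stack(cols)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.design_matrix(data) @ self.coefficients


@dataclass
class AdjustedTrait:
    """Standardized residual of a trait after fixed-effects adjustment."""

    sample_ids: list[str]
    values: np.ndarray
    source: str = ""
    group_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != self.values.size:
            raise ValidationError("id/value length mismatch in AdjustedTrait")

    @property
    def n(self) -> int:
        return self.values.size

    def subset(self, ids: list[str]) -> "AdjustedTrait":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return AdjustedTrait(
            sample_ids=list(ids),
            values=self.values[rows],
            source=self.source,
            group_id=self.group_id,
        )


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares fit returning (coefficients, residual sum of squares)."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _deviance(rss: float, n: int) -> float:
    return n * np.log(rss / n)


def fit_fixed_effects_fp(
    trait: np.ndarray | pd.Series,
    design: pd.DataFrame,
    fp_columns: list[str] | None = None,
    alpha: float = 0.05,
    powers: tuple[float, ...] = FP_POWERS,
    outcome_name: str = "trait",
    max_cycles: int = 5,
) -> FixedEffectsModel:
    """Fit a fixed-effects model with fractional-polynomial terms.

    For each column in ``fp_columns`` the Royston-Altman closed test (RA2)
    chooses between dropping the term, a linear term, the best one-power FP
    (FP1) and the best two-power FP (FP2), at significance level ``alpha``:
    FP2 vs null on 4 df, FP2 vs linear on 3 df, FP2 vs FP1 on 2 df.  All
    other design columns enter linearly and are always retained.  With
    several FP-eligible columns the selection cycles until stable.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if design.shape[0] != n:
        raise ValidationError("trait and design have different lengths")
    design_columns = list(design.columns)
    fp_columns = list(fp_columns or [])
    for c in fp_columns:
        if c not in design_columns:
            raise ValidationError(f"FP column {c!r} not in design")

    # demote near-constant columns: an FP needs enough distinct values
    eligible = []
    for c in fp_columns:
        if design[c].nunique() <= 3:
            warnings.warn(
                f"column {c!r} has <=3 distinct values; demoted to linear",
                stacklevel=2,
            )
        else:
            eligible.append(c)
    linear_always = [c for c in design_columns if c not in eligible]

    shifts = {c: _fp_shift(design[c].to_numpy(dtype=float)) for c in eligible}
    selected: dict[str, tuple[float, ...]] = {c: (1.0,) for c in eligible}
    for c in fp_columns:
        if c not in eligible:
            selected[c] = (1.0,)

    def build(sel_override: dict[str, tuple[float, ...]]) -> np.ndarray:
        cols = [np.ones(n)]
        for name in design_columns:
            x = design[name].to_numpy(dtype=float)
            if name in eligible:
                pw = sel_override[name]
                if len(pw) == 0:
                    continue
                cols.append(_fp_basis(x, pw, shifts[name]))
            else:
                cols.append(x[:, None])
        return np.column_stack(cols)

    fp1_cands = [(p,) for p in powers]
    fp2_cands = list(combinations_with_replacement(powers, 2))

    for _ in range(max_cycles):
        changed = False
        for c in eligible:
            others = dict(selected)

            def rss_for(pw: tuple[float, ...]) -> float:
                others[c] = pw
                _, rss = _ols(y, build(others))
                return rss

            rss_null = rss_for(())
            rss_lin = rss_for((1.0,))
            best_fp1 = min(fp1_cands, key=rss_for)
            rss_fp1 = rss_for(best_fp1)
            best_fp2 = min(fp2_cands, key=rss_for)
            rss_fp2 = rss_for(best_fp2)

            dev = lambda rss: _deviance(rss, n)
            choice: tuple[float, ...]
            if chi2.sf(dev(rss_null) - dev(rss_fp2), 4) > alpha:
                choice = ()
            elif chi2.sf(dev(rss_lin) - dev(rss_fp2), 3) > alpha:
                choice = (1.0,)
            elif chi2.sf(dev(rss_fp1) - dev(rss_fp2), 2) > alpha:
                choice = best_fp1
            else:
                choice = best_fp2
            if choice != selected[c]:
                selected[c] = choice
                changed = True
        if not changed:
            break

    X = build(selected)
    beta, rss = _ols(y, X)
    tss = float(((y - y.mean()) ** 2).sum())
    fitted = X @ beta
    model = FixedEffectsModel(
        outcome=outcome_name,
        design_columns=design_columns,
        fp_columns=eligible,
        selected=selected,
        shifts=shifts,
        coefficients=beta,
        r_squared=1.0 - rss / tss if tss > 0 else 0.0,
        n_used=n,
        sample_ids=[str(i) for i in design.index],
        fitted_values=fitted,
        _design_frame=design,
    )
    return model


def adjust_and_standardize(
    trait: np.ndarray | pd.Series,
    model: FixedEffectsModel,
    group_id: str = "",
) -> AdjustedTrait:
    """Residualize a trait on its fitted fixed-effects model and scale to
    mean zero, unit variance."""
    y = np.asarray(trait, dtype=float)
    if y.size != model.n_used:
        raise ValidationError("trait length differs from the model's fit sample")
    resid = y - model.fitted_values
    sd = resid.std(ddof=0)
    scale = max(1.0, float(np.abs(y).max()))
    if not np.isfinite(sd) or sd <= 1e-10 * scale:
        raise DegenerateTraitError("zero residual variance after adjustment")
    values = (resid - resid.mean()) / sd
    return AdjustedTrait(
        sample_ids=model.sample_ids,
        values=values,
        source=model.outcome,
        group_id=group_id,
    )


def transform_biomarker(values: np.ndarray, rule: str = "identity") -> np.ndarray:
    """Pre-adjustment biomarker transform: identity or natural log."""
    values = np.asarray(values, dtype=float)
    if rule == "identity":
        return values
    if rule == "log":
        nonpos = np.flatnonzero(values <= 0)
        if nonpos.size:
            raise ValidationError(
                f"log transform on non-positive values at rows {nonpos[:10].tolist()}"
            )
        return np.log(values)
    raise ParameterError(f"unknown transform rule {rule!r}")


def rint(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transformation (Blom variant).

    A value with (average, for ties) rank r maps to the standard-normal
    quantile of (r - offset) / (n + 1 - 2*offset).
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise DegenerateTraitError("RINT needs at least two distinct values")
    r = rankdata(values, method="average")
    n = values.size
    return ndtri((r - offset) / (n + 1.0 - 2.0 * offset))
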