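"""Hypothesis testing and aggregation across subgroups.

The full (interaction) and null (bivariate GREML) models are compared by a
likelihood ratio test; because the variance components are estimated
unconstrained, the reference distribution is a plain chi-square on the
added-parameter count (no boundary mixture).  Per-subgroup p-values are
combined by Fisher's method, variance components by fixed-effect
inverse-variance meta-analysis, and multiplicity is handled by Bonferroni
correction with a strict-inequality threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from mrnm.core import MRNMFit
from mrnm.errors import ParameterError


@dataclass
class InteractionResult:
    """Everything reported for one outcome-covariate analysis."""

    covariate: str
    subgroup_stats: list = field(default_factory=list)
    subgroup_p: list = field(default_factory=list)
    combined_stat: float = np.nan
    combined_p: float = np.nan
    significant: bool = False
    threshold: float = np.nan
    gxc_pct: float = np.nan
    gxc_se: float = np.nan
    gxc_ci: tuple = (np.nan, np.nan)
    rxc_pct: float = np.nan
    rxc_se: float = np.nan
    rxc_ci: tuple = (np.nan, np.nan)
    rint_combined_p: float = np.nan
    rint_signal_retained: bool | None = None
    original_scale: dict | None = None
    fits: list = field(default_factory=list)
    warnings_: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "subgroup_lrt_stats": list(map(float, self.subgroup_stats)),
            "subgroup_p": list(map(float, self.subgroup_p)),
            "combined_stat": float(self.combined_stat),
            "combined_p": float(self.combined_p),
            "significant": bool(self.significant),
            "threshold": float(self.threshold),
            "gxc_pct": float(self.gxc_pct),
            "gxc_se": float(self.gxc_se),
            "gxc_ci": [float(v) for v in self.gxc_ci],
            "rxc_pct": float(self.rxc_pct),
            "rxc_se": float(self.rxc_se),
            "rxc_ci": [float(v) for v in self.rxc_ci],
            "rint_combined_p": float(self.rint_combined_p),
            "rint_signal_retained": self.rint_signal_retained,
            "original_scale": self.original_scale,
            "warnings": self.warnings_,
            "fits": [f.to_dict() for f in self.fits],
        }


def lrt(full: MRNMFit, null: MRNMFit, df: int | None = None
        ) -> tuple[float, float, bool]:
    """Full-vs-null likelihood ratio test.

    Returns (statistic, p, reliable).  The statistic is clamped at zero;
    df defaults to the difference in free-parameter counts of the two
    fits.  ``reliable`` is False when either fit failed to converge (the
    p-value is still computed).
    """
    if df is None:
        df = len(full.param_names) - len(null.param_names)
    if df < 1:
        raise ParameterError("models are not nested or df < 1")
    stat = 2.0 * (full.loglik - null.loglik)
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    reliable = full.converged and null.converged
    return stat, p, reliable


def fisher_combine(pvals) -> tuple[float, float]:
    """Fisher's method: X^2 = -2 sum(ln p) ~ chi-square on 2k df."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ParameterError("no p-values to combine")
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise ParameterError("p-values outside [0, 1]")
    if np.any(p == 0.0):
        warnings.warn("zero p-value floored at the smallest positive float",
                      stacklevel=2)
        p = np.maximum(p, np.nextafter(0.0, 1.0))
    stat = -2.0 * float(np.sum(np.log(p)))
    return stat, float(chi2.sf(stat, 2 * p.size))


def meta_variance_components(
    estimates, ses, z: float = 1.959963984540054
) -> tuple[float, float, tuple[float, float]]:
    """Fixed-effect inverse-variance meta-analysis of one component.

    Subgroups with a missing/invalid SE are excluded with a warning.
    Returns (estimate, SE, 95% CI).
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    ok = np.isfinite(est) & np.isfinite(se) & (se > 0)
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} subgroup(s) with missing SE "
            "from the meta-analysis",
            stacklevel=2,
        )
    if not ok.any():
        return np.nan, np.nan, (np.nan, np.nan)
    w = 1.0 / se[ok] ** 2
    m = float(np.sum(w * est[ok]) / np.sum(w))
    s = float(np.sum(w) ** -0.5)
    return m, s, (m - z * s, m + z * s)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ParameterError("n_tests must be at least 1")
    return alpha / n_tests


def flag_significant(pvals, threshold: float) -> np.ndarray:
    """Strict inequality: p exactly at the threshold is not significant."""
    return np.asarray(pvals, dtype=float) < threshold


def rescale_to_outcome_scale(
    proportion: float, se: float, variance_ratio: float
) -> tuple[float, float]:
    """Rescale a variance proportion from the residualised to the original
    outcome scale.

    ``variance_ratio`` is Var(residual after the full adjustment) over
    Var(outcome after the reduced adjustment — age, sex, batch, PCs only);
    both the proportion and its SE scale linearly.
    """
    if variance_ratio <= 0:
        raise ParameterError("variance ratio must be positive")
    return proportion * variance_ratio, se * variance_ratio


def rint_sensitivity(
    subgroup_data: list,
    threshold: float,
    fit_kwargs: dict | None = None,
) -> tuple[float, list, bool]:
    """Refit full/null models with a rank-normalised outcome.

    ``subgroup_data`` is a list of (K, Y, C) per subgroup (GRM and
    AdjustedTraits).  The outcome is replaced by its rank-based inverse
    normal transform; the combined p is recomputed.  Variance components
    remain those of the untransformed analysis — a loss of signal under
    RINT marks the untransformed interaction as potentially spurious.
    Returns (combined_p, per-subgroup p, signal_retained).
    """
    from mrnm.core import fit_mrnm
    from mrnm.covariate_prep import AdjustedTrait, rint

    fit_kwargs = dict(fit_kwargs or {})
    pvals = []
    for K, Y, C in subgroup_data:
        y_r = rint(Y.values if isinstance(Y, AdjustedTrait) else np.asarray(Y))
        y_r = (y_r - y_r.mean()) / y_r.std(ddof=0)
        Yr = AdjustedTrait(
            sample_ids=Y.sample_ids if isinstance(Y, AdjustedTrait)
            else [str(i) for i in range(len(y_r))],
            values=y_r,
            source="rint",
        )
        full = fit_mrnm(K, Yr, C, model="full", **fit_kwargs)
        null = fit_mrnm(K, Yr, C, model="null", **fit_kwargs)
        _, p, _ = lrt(full, null)
        pvals.append(p)
    _, combined = fisher_combine(pvals)
    return combined, pvals, combined < threshold
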