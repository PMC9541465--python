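"""Forward simulation of the reaction norm model.

Generates genotypes in Hardy-Weinberg and linkage equilibrium and a
bivariate (outcome, covariate) trait pair with exactly the covariance
structure the MRNM assumes: the covariate trait C carries a polygenic
intercept beta0 and residual eps0; the outcome Y carries a polygenic
intercept alpha0, a polygenic slope alpha1 on the standardized adjusted
covariate gradient c, and residual intercept/slope tau0, tau1:

    C = fixed_C + g_b0 + e0,      c = standardize(C - fixed_C)
    Y = fixed_Y + g_a0 + c*g_a1 + t0 + c*t1      (optional skew last)

Genetic values are generated per-SNP on standardized genotypes
(infinitesimal model), so a GRM computed downstream is an *estimate* of the
kernel that produced them, as with real data; a direct MVN(0, Sigma (x) K)
mode is available for exact-kernel oracle tests.  With the four outcome
components summing to one and a standardized gradient, the marginal
variance of Y is one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import skew as sample_skewness

from mrnm.errors import ParameterError
from mrnm.io_formats import GenotypeMatrix, TraitTable


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(
    n: int, m: int, maf_range: tuple[float, float] = (0.05, 0.5), seed=0
) -> GenotypeMatrix:
    """HWE hard-call genotypes at per-SNP MAFs drawn uniform on a range.

    Dosages are Binomial(2, p) independently across SNPs (linkage
    equilibrium) and individuals.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError(f"maf_range {maf_range} not within (0, 0.5]")
    if n < 1 or m < 1:
        raise ParameterError("n and m must be at least 1")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return GenotypeMatrix(
        sample_ids=[f"ind{i:06d}" for i in range(n)],
        snp_ids=[f"snp{k:06d}" for k in range(m)],
        chromosomes=np.ones(m, dtype=object),
        positions=np.arange(1, m + 1) * 1000,
        allele1=["A"] * m,
        allele2=["G"] * m,
        dosages=dosages,
    )


@dataclass
class FixedEffectSim:
    """One simulated confounder column with its true effect functions."""

    name: str
    sampler: Callable[[np.random.Generator, int], np.ndarray]
    effect_y: Callable[[np.ndarray], np.ndarray] = lambda x: 0.0 * x
    effect_c: Callable[[np.ndarray], np.ndarray] = lambda x: 0.0 * x


@dataclass
class SimulationSpec:
    """Generative parameters for one simulated study.

    ``sigma_g`` / ``sigma_e`` are 3x3 covariance matrices over the genetic
    effects (alpha0, alpha1, beta0) and residual effects (tau0, tau1, eps0).
    On the standardized scale the four outcome components
    (sigma_g[0,0], sigma_g[1,1], sigma_e[0,0], sigma_e[1,1]) should sum to
    one for a unit-variance outcome.
    """

    sigma_g: np.ndarray
    sigma_e: np.ndarray
    fixed_effects: list[FixedEffectSim] = field(default_factory=list)
    skew_method: str = "none"
    skew_params: dict = field(default_factory=dict)
    mode: str = "snp_effects"  # or "direct_mvn"
    seed: int = 0

    def __post_init__(self) -> None:
        self.sigma_g = np.asarray(self.sigma_g, dtype=float)
        self.sigma_e = np.asarray(self.sigma_e, dtype=float)
        for mat, tag in ((self.sigma_g, "sigma_g"), (self.sigma_e, "sigma_e")):
            if mat.shape != (3, 3):
                raise ParameterError(f"{tag} must be 3x3")
            if not np.allclose(mat, mat.T, atol=1e-12):
                raise ParameterError(f"{tag} must be symmetric")
        if self.mode not in ("snp_effects", "direct_mvn"):
            raise ParameterError(f"unknown generation mode {self.mode!r}")

    @classmethod
    def from_components(
        cls,
        var_a0: float,
        var_a1: float,
        var_t0: float,
        var_t1: float,
        var_b0: float = 0.3,
        var_e0: float = 0.7,
        cov_a0a1: float = 0.0,
        cov_a0b0: float = 0.0,
        cov_a1b0: float = 0.0,
        cov_t0t1: float = 0.0,
        cov_t0e0: float = 0.0,
        cov_t1e0: float = 0.0,
        **kwargs,
    ) -> "SimulationSpec":
        sigma_g = np.array(
            [
                [var_a0, cov_a0a1, cov_a0b0],
                [cov_a0a1, var_a1, cov_a1b0],
                [cov_a0b0, cov_a1b0, var_b0],
            ]
        )
        sigma_e = np.array(
            [
                [var_t0, cov_t0t1, cov_t0e0],
                [cov_t0t1, var_t1, cov_t1e0],
                [cov_t0e0, cov_t1e0, var_e0],
            ]
        )
        return cls(sigma_g=sigma_g, sigma_e=sigma_e, **kwargs)


@dataclass
class TruthRecord:
    """Everything needed to rebuild Y and C exactly from the stored draws."""

    sigma_g: np.ndarray
    sigma_e: np.ndarray
    genetic_values: np.ndarray   # n x 3 columns (g_a0, g_a1, g_b0)
    residual_values: np.ndarray  # n x 3 columns (t0, t1, e0)
    fixed_y: np.ndarray
    fixed_c: np.ndarray
    gradient: np.ndarray         # standardized adjusted covariate c
    y_pre_skew: np.ndarray
    snp_effects: np.ndarray | None = None
    fixed_coefficients: dict = field(default_factory=dict)

    def rebuild(self) -> tuple[np.ndarray, np.ndarray]:
        g = self.genetic_values
        e = self.residual_values
        c = self.gradient
        C = self.fixed_c + g[:, 2] + e[:, 2]
        Y = self.fixed_y + g[:, 0] + c * g[:, 1] + e[:, 0] + c * e[:, 1]
        return Y, C


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    traits: TraitTable
    truth: TruthRecord


def _chol_psd(mat: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerating PSD matrices (zero components)."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(mat)
        if np.min(w) < -1e-8:
            raise ParameterError("covariance matrix has negative eigenvalues")
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _standardized_dosages(genotypes: GenotypeMatrix) -> np.ndarray:
    from mrnm.io_formats import MISSING

    x = genotypes.dosages.astype(float)
    missing = genotypes.dosages == MISSING
    x[missing] = np.nan
    p = genotypes.allele_frequencies()
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z[missing] = 0.0
    return z


def simulate_bivariate_traits(
    genotypes: GenotypeMatrix, spec: SimulationSpec
) -> SimulatedStudy:
    """Draw one study (Y, C, confounders) under the reaction norm model."""
    rng = _rng(spec.seed)
    n, m = genotypes.n_individuals, genotypes.n_snps
    Lg = _chol_psd(spec.sigma_g)
    Le = _chol_psd(spec.sigma_e)

    snp_effects = None
    if spec.mode == "snp_effects":
        z = _standardized_dosages(genotypes)
        snp_effects = (rng.standard_normal((m, 3)) @ Lg.T) / np.sqrt(m)
        gvals = z @ snp_effects
    else:
        from mrnm.grm import compute_grm

        K = compute_grm(genotypes).matrix
        Lk = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        gvals = Lk @ (rng.standard_normal((n, 3)) @ Lg.T)

    evals = rng.standard_normal((n, 3)) @ Le.T

    fixed_y = np.zeros(n)
    fixed_c = np.zeros(n)
    columns: dict[str, np.ndarray] = {}
    for fe in spec.fixed_effects:
        x = fe.sampler(rng, n)
        columns[fe.name] = x
        fixed_y = fixed_y + fe.effect_y(x)
        fixed_c = fixed_c + fe.effect_c(x)

    c_adj = gvals[:, 2] + evals[:, 2]
    c = (c_adj - c_adj.mean()) / c_adj.std(ddof=0)
    C = fixed_c + gvals[:, 2] + evals[:, 2]
    y_core = gvals[:, 0] + c * gvals[:, 1] + evals[:, 0] + c * evals[:, 1]
    y_pre_skew = fixed_y + y_core
    if spec.skew_method != "none":
        Y = apply_skew(y_pre_skew, spec.skew_method, spec.skew_params)
    else:
        Y = y_pre_skew

    frame = pd.DataFrame({"Y": Y, "C": C, **columns},
                         index=pd.Index(genotypes.sample_ids, name="id"))
    traits = TraitTable(
        data=frame,
        outcome="Y",
        covariates=["C"],
        fixed_effects=list(columns),
    )
    truth = TruthRecord(
        sigma_g=spec.sigma_g,
        sigma_e=spec.sigma_e,
        genetic_values=gvals,
        residual_values=evals,
        fixed_y=fixed_y,
        fixed_c=fixed_c,
        gradient=c,
        y_pre_skew=y_pre_skew,
        snp_effects=snp_effects,
    )
    return SimulatedStudy(genotypes=genotypes, traits=traits, truth=truth)


# ---------------------------------------------------------------------------
# Skew transforms (emulating the positive skew of a depressive-symptom score)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def apply_skew(values: np.ndarray, method: str = "none", params: dict | None = None
               ) -> np.ndarray:
    """Monotone skewing transform, re-standardized afterwards.

    ``sinh-arcsinh`` uses z -> sinh(asinh(z) + epsilon); epsilon may be
    given directly or tuned by bisection to hit ``target_skewness`` (e.g.
    0.47, the positive skew typical of questionnaire symptom scores).
    ``exponential`` uses z -> exp(rate * z).
    """
    params = dict(params or {})
    z = _standardize(np.asarray(values, dtype=float))
    if method == "none":
        return z
    if method == "sinh-arcsinh":
        if "epsilon" in params:
            eps = float(params["epsilon"])
        else:
            target = float(params.get("target_skewness", 0.47))
            eps = tune_sinh_arcsinh(z, target)
        return _standardize(np.sinh(np.arcsinh(z) + eps))
    if method == "exponential":
        rate = float(params.get("rate", 0.5))
        return _standardize(np.exp(rate * z))
    raise ParameterError(f"unknown skew method {method!r}")


def tune_sinh_arcsinh(z: np.ndarray, target_skewness: float,
                      lo: float = -3.0, hi: float = 3.0, tol: float = 1e-10
                      ) -> float:
    """Bisection on the sinh-arcsinh shift so the sample skewness of the
    transformed values matches ``target_skewness`` (skewness is monotone
    increasing in the shift)."""
    def skew_at(eps: float) -> float:
        return float(sample_skewness(np.sinh(np.arcsinh(z) + eps)))

    f_lo, f_hi = skew_at(lo) - target_skewness, skew_at(hi) - target_skewness
    if f_lo > 0 or f_hi < 0:
        raise ParameterError(
            f"target skewness {target_skewness} not reachable in [{lo}, {hi}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if skew_at(mid) < target_skewness:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
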