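"""Config-driven end-to-end interaction analysis.

For each covariate trait: stage-1 fixed-effects adjustment of outcome and
covariate on the full analysis group, standardization, GRM construction and
per-subgroup subsetting, null and full MRNM fits per random subgroup, the
full-vs-null LRT, Fisher combination across subgroups, Bonferroni flagging,
inverse-variance meta-analysis of the interaction variance components, and
a rank-normalisation sensitivity rerun.  Every fit's diagnostics and all
seeds go into a run manifest so a rerun with the same config is
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from mrnm import io_formats
from mrnm.covariate_prep import (
    adjust_and_standardize,
    fit_fixed_effects_fp,
    transform_biomarker,
)
from mrnm.core import fit_mrnm, variance_proportions
from mrnm.errors import ParameterError, SchemaError
from mrnm.grm import compute_grm, qc_filter_snps
from mrnm.interaction import (
    InteractionResult,
    bonferroni_threshold,
    fisher_combine,
    lrt,
    meta_variance_components,
    rint_sensitivity,
)

logger = logging.getLogger("mrnm.pipeline")


@dataclass
class CovariateSpec:
    name: str
    transform: str = "identity"

    @classmethod
    def parse(cls, entry) -> "CovariateSpec":
        if isinstance(entry, str):
            return cls(name=entry)
        return cls(**entry)


@dataclass
class PipelineConfig:
    """Inputs, modelling choices and seeds for one analysis run."""

    trait_path: str | Path | None = None
    genotype_prefix: str | Path | None = None
    grm_prefix: str | Path | None = None
    outcome: str = "Y"
    covariates: list = field(default_factory=list)
    fixed_effects: list[str] = field(default_factory=list)
    reduced_fixed_effects: list[str] | None = None
    fp_columns: list[str] = field(default_factory=list)
    fp_alpha: float = 0.05
    id_column: str = "id"
    maf_min: float = 0.01
    completeness_min: float = 0.95
    k_subgroups: int = 3
    alpha: float = 0.05
    n_tests: int | None = None
    seed: int = 0
    min_n: int = 100
    fit_tol: float = 1e-6
    fit_max_iter: int = 50
    run_rint: bool = True
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        self.covariates = [CovariateSpec.parse(c) for c in self.covariates]
        if self.k_subgroups < 1:
            raise ParameterError("k_subgroups must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        payload = {
            k: str(v) for k, v in sorted(self.__dict__.items())
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def split_subgroups(ids: list[str], k: int, seed: int) -> list[list[str]]:
    """Random partition into k groups with sizes differing by at most one.

    Ids are canonicalised (sorted) before the seeded shuffle, so the
    partition depends on the id *set* and the seed, never on input order.
    """
    n = len(ids)
    if k > n:
        raise ParameterError(f"k = {k} exceeds n = {n}")
    ordered = sorted(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [[ordered[i] for i in part] for part in np.array_split(order, k)]


def _validate_columns(traits: io_formats.TraitTable, config: PipelineConfig) -> None:
    need = [config.outcome, *[c.name for c in config.covariates],
            *config.fixed_effects]
    if config.reduced_fixed_effects:
        need += list(config.reduced_fixed_effects)
    for col in need:
        if col not in traits.data.columns:
            raise SchemaError(f"config references missing column {col!r}")


def run_analysis(
    config: PipelineConfig,
    traits: io_formats.TraitTable | None = None,
    genotypes: io_formats.GenotypeMatrix | None = None,
    grm=None,
) -> list[InteractionResult]:
    """Run the full interaction analysis for every configured covariate.

    Inputs may be passed pre-loaded (for testing and scripted use) or read
    from the paths in the config.  A non-convergent covariate is flagged
    and reported partially; it never aborts the batch.
    """
    if traits is None:
        traits = io_formats.read_trait_table(
            config.trait_path,
            {
                "id": config.id_column,
                "outcome": config.outcome,
                "covariates": [c.name for c in config.covariates],
                "fixed_effects": config.fixed_effects,
            },
        )
    _validate_columns(traits, config)
    if grm is None and genotypes is None:
        if config.grm_prefix is not None:
            grm = io_formats.read_grm_gcta(config.grm_prefix)
        elif config.genotype_prefix is not None:
            genotypes = io_formats.read_plink(config.genotype_prefix)
        else:
            raise ParameterError("no genotype or GRM input configured")

    n_tests = config.n_tests or max(len(config.covariates), 1)
    threshold = bonferroni_threshold(config.alpha, n_tests)
    fit_kwargs = {
        "max_iter": config.fit_max_iter,
        "tol": config.fit_tol,
        "min_n": config.min_n,
    }

    results: list[InteractionResult] = []
    for cov in config.covariates:
        result = InteractionResult(covariate=cov.name, threshold=threshold)
        try:
            results.append(
                _analyse_one(
                    cov, traits, genotypes, grm, config, threshold,
                    fit_kwargs, result,
                )
            )
        except Exception as exc:  # noqa: BLE001 - failure isolation per covariate
            logger.exception("covariate %s failed", cov.name)
            result.warnings_.append(f"failed: {exc}")
            results.append(result)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_results(results, out / "interaction_results.tsv")
        manifest = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "k_subgroups": config.k_subgroups,
            "threshold": threshold,
            "n_tests": n_tests,
            "covariates": [c.name for c in config.covariates],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _analyse_one(cov, traits, genotypes, grm, config, threshold,
                 fit_kwargs, result: InteractionResult) -> InteractionResult:
    data = traits.data
    needed = [config.outcome, cov.name, *config.fixed_effects]
    complete = ~data[needed].isna().any(axis=1)
    group = data.loc[complete].copy()
    group_ids = [str(i) for i in group.index]
    logger.info("covariate %s: analysis group n=%d", cov.name, len(group))

    # stage 1: fixed-effects adjustment on the full analysis group
    cov_values = transform_biomarker(group[cov.name].to_numpy(float), cov.transform)
    if config.fixed_effects:
        design = group[config.fixed_effects]
        fp_cols = [c for c in config.fp_columns if c in design.columns]
        m_y = fit_fixed_effects_fp(
            group[config.outcome].to_numpy(float), design,
            fp_columns=fp_cols, alpha=config.fp_alpha,
            outcome_name=config.outcome,
        )
        m_c = fit_fixed_effects_fp(
            cov_values, design, fp_columns=fp_cols, alpha=config.fp_alpha,
            outcome_name=cov.name,
        )
        Y = adjust_and_standardize(group[config.outcome].to_numpy(float), m_y)
        C = adjust_and_standardize(cov_values, m_c)
    else:
        from mrnm.covariate_prep import AdjustedTrait

        y = group[config.outcome].to_numpy(float)
        Y = AdjustedTrait(group_ids, (y - y.mean()) / y.std(ddof=0),
                          source=config.outcome)
        C = AdjustedTrait(group_ids, (cov_values - cov_values.mean())
                          / cov_values.std(ddof=0), source=cov.name)

    # one GRM per analysis group, subset per subgroup
    if grm is not None:
        K_group = grm.subset(group_ids)
    else:
        g_sub = genotypes.subset_individuals(group_ids)
        g_qc, report = qc_filter_snps(
            g_sub, config.maf_min, config.completeness_min
        )
        logger.info("covariate %s: SNP QC %s", cov.name, report)
        K_group = compute_grm(g_qc)

    parts = split_subgroups(group_ids, config.k_subgroups, config.seed)
    subgroup_data = []
    full_fits, null_fits = [], []
    for si, ids in enumerate(parts):
        Ks, Ys, Cs = K_group.subset(ids), Y.subset(ids), C.subset(ids)
        subgroup_data.append((Ks, Ys, Cs))
        full = fit_mrnm(Ks, Ys, Cs, model="full", subgroup=str(si), **fit_kwargs)
        null = fit_mrnm(Ks, Ys, Cs, model="null", subgroup=str(si), **fit_kwargs)
        if not (full.converged and null.converged):
            result.warnings_.append(f"subgroup {si}: non-convergence")
        stat, p, reliable = lrt(full, null)
        result.subgroup_stats.append(stat)
        result.subgroup_p.append(p)
        full_fits.append(full)
        null_fits.append(null)
    result.fits = full_fits + null_fits

    result.combined_stat, result.combined_p = fisher_combine(result.subgroup_p)
    result.significant = result.combined_p < threshold

    props = [variance_proportions(f) for f in full_fits]
    g_est, g_se, g_ci = meta_variance_components(
        [p["var_a1"]["pct"] for p in props], [p["var_a1"]["se"] for p in props]
    )
    r_est, r_se, r_ci = meta_variance_components(
        [p["var_t1"]["pct"] for p in props], [p["var_t1"]["se"] for p in props]
    )
    result.gxc_pct, result.gxc_se, result.gxc_ci = g_est, g_se, g_ci
    result.rxc_pct, result.rxc_se, result.rxc_ci = r_est, r_se, r_ci

    if config.run_rint:
        combined_r, pvals_r, retained = rint_sensitivity(
            subgroup_data, threshold, fit_kwargs
        )
        result.rint_combined_p = combined_r
        result.rint_signal_retained = retained

    if config.reduced_fixed_effects is not None and config.fixed_effects:
        reduced = group[config.reduced_fixed_effects]
        m_red = fit_fixed_effects_fp(
            group[config.outcome].to_numpy(float), reduced,
            fp_columns=[], alpha=config.fp_alpha, outcome_name=config.outcome,
        )
        resid_full = group[config.outcome].to_numpy(float) - m_y.fitted_values
        resid_red = group[config.outcome].to_numpy(float) - m_red.fitted_values
        ratio = float(resid_full.var(ddof=0) / resid_red.var(ddof=0))
        from mrnm.interaction import rescale_to_outcome_scale

        g_orig, g_orig_se = rescale_to_outcome_scale(g_est, g_se, ratio)
        r_orig, r_orig_se = rescale_to_outcome_scale(r_est, r_se, ratio)
        result.original_scale = {
            "variance_ratio": ratio,
            "gxc_pct": g_orig,
            "gxc_se": g_orig_se,
            "rxc_pct": r_orig,
            "rxc_se": r_orig_se,
        }
    return result
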