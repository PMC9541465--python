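"""Shared cohort definition for the numbered analysis scripts.

One synthetic cohort emulating the real study design: a quantitative
depressive-symptom-like outcome with positive skew, one covariate trait
carrying true polygenic and residual interactions (a sleep-duration
analogue), one null log-scale biomarker (a CRP analogue), and age/sex
confounders with nonlinear effects.  Interaction variance components are
scaled up relative to the ~1-3% seen in biobank data so they are
recoverable at this cohort size.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import mrnm
from mrnm.synthetic import FixedEffectSim, SimulationSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

N_INDIVIDUALS = 1200
N_SNPS = 400
SEED = 2024

TRUE_COMPONENTS = dict(var_a0=0.20, var_a1=0.10, var_t0=0.50, var_t1=0.10,
                       cov_a0b0=0.05, cov_t0e0=0.10)


def _fixed_effects():
    return [
        FixedEffectSim(
            name="age",
            sampler=lambda rng, n: rng.uniform(40.0, 70.0, size=n),
            effect_y=lambda x: 0.003 * (x - 55.0) ** 2,
            effect_c=lambda x: -0.015 * (x - 55.0),
        ),
        FixedEffectSim(
            name="sex",
            sampler=lambda rng, n: rng.integers(0, 2, size=n).astype(float),
            effect_y=lambda x: 0.15 * x,
            effect_c=lambda x: 0.05 * x,
        ),
    ]


def build_cohort():
    """Genotypes plus a trait table with outcome, two covariates and
    confounders; returns (genotypes, trait_table, truth)."""
    genotypes = mrnm.simulate_genotypes(N_INDIVIDUALS, N_SNPS,
                                        maf_range=(0.05, 0.5), seed=SEED)
    spec = SimulationSpec.from_components(
        **TRUE_COMPONENTS,
        fixed_effects=_fixed_effects(),
        skew_method="sinh-arcsinh",
        skew_params={"target_skewness": 0.47},
        seed=SEED + 1,
    )
    study = mrnm.simulate_bivariate_traits(genotypes, spec)

    # an independent polygenic trait from the same genotypes serves as a
    # no-interaction biomarker; stored on its natural (exponential) scale
    null_spec = SimulationSpec.from_components(
        var_a0=0.0, var_a1=0.0, var_t0=1.0, var_t1=0.0,
        var_b0=0.2, var_e0=0.8, seed=SEED + 2,
    )
    null_study = mrnm.simulate_bivariate_traits(genotypes, null_spec)
    crp = np.exp(0.5 * null_study.traits.data["C"].to_numpy())

    frame = study.traits.data.rename(columns={"Y": "depsympt", "C": "sleepdur"})
    frame["crp"] = crp
    table = mrnm.io_formats.TraitTable(
        data=frame,
        outcome="depsympt",
        covariates=["sleepdur", "crp"],
        fixed_effects=["age", "sex"],
    )
    return genotypes, table, study.truth


def pipeline_config(**overrides):
    base = dict(
        outcome="depsympt",
        covariates=[{"name": "sleepdur", "transform": "identity"},
                    {"name": "crp", "transform": "log"}],
        fixed_effects=["age", "sex"],
        fp_columns=["age"],
        k_subgroups=2,
        alpha=0.05,
        n_tests=2,
        seed=SEED,
        min_n=100,
        out_dir=RESULTS / "interactions",
    )
    base.update(overrides)
    return mrnm.PipelineConfig(**base)
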