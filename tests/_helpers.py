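"""Shared helpers for the test suite."""

import numpy as np

import mrnm
from mrnm.covariate_prep import AdjustedTrait


def standardize(v):
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std(ddof=0)


def simulate_and_fit(n, m, components, seed, model="both", fit_kwargs=None,
                     skew_method="none", skew_params=None, rint_outcome=False):
    """One simulated study and its MRNM fit(s), used across tests."""
    fit_kwargs = dict(fit_kwargs or {})
    genotypes = mrnm.simulate_genotypes(n, m, seed=seed)
    spec = mrnm.SimulationSpec.from_components(
        **components, seed=seed + 7_000_000, skew_method=skew_method,
        skew_params=skew_params or {},
    )
    study = mrnm.simulate_bivariate_traits(genotypes, spec)
    grm = mrnm.compute_grm(genotypes)
    y = study.traits.data["Y"].to_numpy()
    if rint_outcome:
        y = mrnm.rint(y)
    Y = AdjustedTrait(genotypes.sample_ids, standardize(y), source="Y")
    C = AdjustedTrait(genotypes.sample_ids, study.truth.gradient, source="C")
    fits = {}
    if model in ("full", "both"):
        fits["full"] = mrnm.fit_mrnm(grm, Y, C, model="full", **fit_kwargs)
    if model in ("null", "both"):
        fits["null"] = mrnm.fit_mrnm(grm, Y, C, model="null", **fit_kwargs)
    return study, grm, Y, C, fits
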