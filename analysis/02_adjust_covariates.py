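"""Stage-1 fixed-effects adjustment with fractional polynomials.

Regresses the outcome and each covariate trait on age and sex, letting age
enter through a fractional polynomial chosen by the Royston-Altman closed
test, then standardizes the residuals.  The age effect on the outcome was
generated as a centred quadratic, so the selected transform should be
nonlinear for the outcome and the table reports which powers won.
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from mrnm import adjust_and_standardize, fit_fixed_effects_fp, transform_biomarker
from common import RESULTS, build_cohort


def main():
    _, table, _ = build_cohort()
    design = table.data[["age", "sex"]]
    out_dir = RESULTS / "adjustment"
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    adjusted = {}
    for trait, transform in [("depsympt", "identity"),
                             ("sleepdur", "identity"), ("crp", "log")]:
        values = transform_biomarker(table.data[trait].to_numpy(float),
                                     transform)
        model = fit_fixed_effects_fp(values, design, fp_columns=["age"],
                                     outcome_name=trait)
        adj = adjust_and_standardize(values, model)
        adjusted[trait] = adj.values
        rows.append({
            "trait": trait,
            "transform": transform,
            "age_fp_powers": str(model.selected["age"]),
            "r_squared": round(model.r_squared, 4),
            "n": model.n_used,
        })
        print(f"{trait:10s} transform={transform:8s} "
              f"age FP powers {model.selected['age']} "
              f"R^2 {model.r_squared:.4f}")

    pd.DataFrame(rows).to_csv(out_dir / "fp_selection.tsv", sep="\t",
                              index=False)
    pd.DataFrame(adjusted, index=table.data.index).to_csv(
        out_dir / "adjusted_traits.tsv", sep="\t", index_label="id")
    print(f"wrote {out_dir}/fp_selection.tsv and adjusted_traits.tsv")


if __name__ == "__main__":
    main()
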