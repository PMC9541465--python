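"""SNP QC and genetic relationship matrix construction.

Filters the panel at MAF >= 0.01 and completeness >= 95%, builds the
GCTA-form GRM and writes it in the GCTA binary convention (scratch/, it is
binary).  For HWE genotypes the diagonal mean should be close to 1 and the
off-diagonal mean close to 0.
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent))

import json

import numpy as np

import mrnm
from common import RESULTS, SCRATCH, build_cohort


def main():
    genotypes, _, _ = build_cohort()
    filtered, report = mrnm.qc_filter_snps(genotypes, maf_min=0.01,
                                           completeness_min=0.95)
    grm = mrnm.compute_grm(filtered)
    SCRATCH.mkdir(exist_ok=True)
    mrnm.write_grm_gcta(grm, SCRATCH / "cohort")

    diag = np.diag(grm.matrix)
    off = grm.matrix[np.triu_indices(grm.n, k=1)]
    summary = {
        **report,
        "diagonal_mean": float(diag.mean()),
        "offdiagonal_mean": float(off.mean()),
        "offdiagonal_sd": float(off.std()),
    }
    out = RESULTS / "grm_summary.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(summary, indent=2))
    print(f"QC: {report['n_input']} SNPs -> {report['n_kept']} kept "
          f"({report['n_removed_maf']} failed MAF, "
          f"{report['n_removed_completeness']} failed completeness)")
    print(f"GRM: diag mean {diag.mean():.4f}, off-diag mean "
          f"{off.mean():+.5f}, off-diag sd {off.std():.4f}")
    print(f"wrote {SCRATCH / 'cohort'}.grm.bin/.grm.N.bin/.grm.id and {out}")


if __name__ == "__main__":
    main()
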