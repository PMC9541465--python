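"""SNP quality control and genetic relationship matrix construction.

The GRM is the GCTA/Yang estimator on standardized dosages:
``K_ij = (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k))``
with allele frequencies computed in-sample and missing dosages mean-imputed
(a missing call contributes zero after centring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mrnm.errors import AlignmentError, EmptyPanelError, ParameterError
from mrnm.io_formats import MISSING, GenotypeMatrix


@dataclass
class GRM:
    """Symmetric genetic-relationship matrix with sample identifiers."""

    sample_ids: list[str]
    matrix: np.ndarray
    n_snps_used: int = 0
    pair_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise AlignmentError(
                f"GRM is {self.matrix.shape} for {n} sample ids"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ParameterError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids: list[str]) -> "GRM":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = np.array([index[s] for s in ids])
        except KeyError as exc:
            raise AlignmentError(f"unknown sample id {exc.args[0]!r}") from exc
        sub = self.matrix[np.ix_(rows, rows)]
        return GRM(
            sample_ids=list(ids),
            matrix=sub,
            n_snps_used=self.n_snps_used,
            pair_counts=self.pair_counts[np.ix_(rows, rows)]
            if self.pair_counts is not None
            else None,
        )


def qc_filter_snps(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    completeness_min: float = 0.95,
) -> tuple[GenotypeMatrix, dict]:
    """Drop SNPs failing minor-allele-frequency or completeness thresholds.

    Returns the filtered panel and a report of removals per criterion.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ParameterError(f"maf_min {maf_min} outside [0, 0.5]")
    if not 0.0 <= completeness_min <= 1.0:
        raise ParameterError(f"completeness_min {completeness_min} outside [0, 1]")

    freq = genotypes.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    comp = genotypes.completeness()
    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_comp = comp < completeness_min
    keep = ~(fail_maf | fail_comp)
    if not keep.any():
        raise EmptyPanelError("all SNPs removed by QC")
    report = {
        "n_input": genotypes.n_snps,
        "n_removed_maf": int(fail_maf.sum()),
        "n_removed_completeness": int(fail_comp.sum()),
        "n_kept": int(keep.sum()),
    }
    return genotypes.subset_snps(keep), report


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    """GCTA-form GRM from hard-call dosages.

    Monomorphic SNPs (in-sample p of 0 or 1) are dropped with a warning
    rather than dividing by zero.  The divisor is the common SNP count m,
    not per-pair non-missing counts.
    """
    freq = genotypes.allele_frequencies()
    poly = ~np.isnan(freq) & (freq > 0.0) & (freq < 1.0)
    if not poly.all():
        warnings.warn(
            f"dropping {int((~poly).sum())} monomorphic/all-missing SNPs "
            "before GRM construction",
            stacklevel=2,
        )
        genotypes = genotypes.subset_snps(poly)
        freq = freq[poly]

    x = genotypes.dosages.astype(float)
    missing = genotypes.dosages == MISSING
    # mean-impute: x - 2p becomes 0 for missing calls
    x[missing] = np.nan
    z = (x - 2.0 * freq) / np.sqrt(2.0 * freq * (1.0 - freq))
    z[missing] = 0.0
    m = genotypes.n_snps
    matrix = (z @ z.T) / m
    return GRM(sample_ids=genotypes.sample_ids, matrix=matrix, n_snps_used=m)
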