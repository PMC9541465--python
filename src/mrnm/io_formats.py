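"""Readers and writers for the standard interchange formats of GREML-family
tooling: PLINK1 binary genotypes, the GCTA three-file GRM, tab-separated
phenotype tables, and the package's own results tables.

All joins downstream are by sample identifier, never by file position, so
every container here carries its ids.  Missing hard-call dosages use the
sentinel ``MISSING`` (never silently imputed at read time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mrnm.errors import FormatError, SchemaError, ValidationError

MISSING: int = -1
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK1 magic + SNP-major flag


@dataclass
class GenotypeMatrix:
    """Hard-call dosages (individuals x SNPs) with identifiers.

    ``dosages[i, k]`` counts copies of the A1 allele of SNP ``k`` carried by
    individual ``i`` and is one of {0, 1, 2, MISSING}.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    allele1: list[str]
    allele2: list[str]
    dosages: np.ndarray  # int8, shape (n, m)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.snp_ids) != m:
            raise ValidationError(f"{len(self.snp_ids)} snp ids for {m} dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("duplicate SNP ids")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError(f"{bad.sum()} dosage values outside {{0,1,2,missing}}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP A1 allele frequency from non-missing calls (NaN if all missing)."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def completeness(self) -> np.ndarray:
        """Per-SNP proportion of non-missing calls."""
        return (self.dosages != MISSING).mean(axis=0)

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from exc
        return GenotypeMatrix(
            sample_ids=list(ids),
            snp_ids=self.snp_ids,
            chromosomes=self.chromosomes,
            positions=self.positions,
            allele1=self.allele1,
            allele2=self.allele2,
            dosages=self.dosages[rows, :],
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            snp_ids=[self.snp_ids[j] for j in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.snp_ids[j] for j in keep],
            chromosomes=self.chromosomes[keep],
            positions=self.positions[keep],
            allele1=[a for a, k in zip(self.allele1, keep) if k]
            if keep.dtype == bool
            else [self.allele1[j] for j in keep],
            allele2=[a for a, k in zip(self.allele2, keep) if k]
            if keep.dtype == bool
            else [self.allele2[j] for j in keep],
            dosages=self.dosages[:, keep],
        )


@dataclass
class TraitTable:
    """Per-individual phenotype/covariate table keyed by sample id."""

    data: pd.DataFrame  # indexed by sample id
    outcome: str
    covariates: list[str]
    fixed_effects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in trait table")
        for col in [self.outcome, *self.covariates, *self.fixed_effects]:
            if col not in self.data.columns:
                raise SchemaError(f"declared column {col!r} not in table")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def missing_mask(self, columns: list[str]) -> pd.Series:
        """True where any of the given columns is missing."""
        return self.data[columns].isna().any(axis=1)


# ---------------------------------------------------------------------------
# PLINK1 binary triplet

# 2-bit genotype codes in a .bed byte, LSB-first: 00 hom A1 (dosage 2),
# 01 missing, 10 het, 11 hom A2 (dosage 0).
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK1 ``.bed/.bim/.fam`` triplet (SNP-major) into memory."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    sample_ids = fam["iid"].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate individual ids in .fam")
    n, m = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"bad .bed magic bytes {raw[:3]!r}; expected PLINK1 SNP-major"
        )
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * m:
        raise FormatError(
            f".bed body has {body.size} bytes, expected {bytes_per_snp * m}"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, LSB first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=bim["snp"].tolist(),
        chromosomes=bim["chrom"].to_numpy(),
        positions=bim["pos"].to_numpy(),
        allele1=bim["a1"].tolist(),
        allele2=bim["a2"].tolist(),
        dosages=dosages,
    )


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK1 ``.bed/.bim/.fam`` triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genotypes.dosages.shape

    fam = pd.DataFrame(
        {
            "fid": genotypes.sample_ids,
            "iid": genotypes.sample_ids,
            "pid": "0",
            "mid": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": genotypes.chromosomes,
            "snp": genotypes.snp_ids,
            "cm": 0,
            "pos": genotypes.positions,
            "a1": genotypes.allele1,
            "a2": genotypes.allele2,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    code_lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        code_lut[dosage % 4] = code  # MISSING==-1 maps to index 3 via % 4
    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 0, dtype=np.int8)
    padded[:, :n] = genotypes.dosages.T
    codes = code_lut[padded % 4].reshape(m, bytes_per_snp, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# GCTA GRM binary (grm.bin lower triangle incl. diagonal, float32)


def read_grm_gcta(prefix: str | Path):
    """Read a GCTA three-file GRM (``.grm.bin``, ``.grm.N.bin``, ``.grm.id``)."""
    from mrnm.grm import GRM  # local import to avoid a cycle

    prefix = Path(prefix)
    ids = pd.read_csv(
        Path(str(prefix) + ".grm.id"), sep=r"\s+", header=None, names=["fid", "iid"],
        dtype=str,
    )
    n = len(ids)
    n_pairs = n * (n + 1) // 2
    values = np.fromfile(Path(str(prefix) + ".grm.bin"), dtype=np.float32)
    if values.size != n_pairs:
        raise FormatError(
            f".grm.bin holds {values.size} float32 values; "
            f"{n} ids imply {n_pairs}"
        )
    matrix = np.zeros((n, n))
    iu = np.tril_indices(n)
    matrix[iu] = values
    matrix = matrix + matrix.T - np.diag(np.diag(matrix))

    n_file = Path(str(prefix) + ".grm.N.bin")
    pair_counts = None
    if n_file.exists():
        counts = np.fromfile(n_file, dtype=np.float32)
        if counts.size not in (1, n_pairs):
            raise FormatError(
                f".grm.N.bin holds {counts.size} values; expected 1 or {n_pairs}"
            )
        if counts.size == n_pairs:
            pair_counts = np.zeros((n, n))
            pair_counts[iu] = counts
            pair_counts = pair_counts + pair_counts.T - np.diag(np.diag(pair_counts))
        else:
            pair_counts = np.full((n, n), float(counts[0]))

    return GRM(
        sample_ids=ids["iid"].tolist(),
        matrix=matrix,
        n_snps_used=int(pair_counts.max()) if pair_counts is not None else 0,
        pair_counts=pair_counts,
    )


def write_grm_gcta(grm, prefix: str | Path) -> None:
    """Write a GRM in the GCTA three-file binary convention."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = len(grm.sample_ids)
    iu = np.tril_indices(n)
    np.asarray(grm.matrix[iu], dtype=np.float32).tofile(
        Path(str(prefix) + ".grm.bin")
    )
    counts = (
        grm.pair_counts
        if grm.pair_counts is not None
        else np.full((n, n), float(grm.n_snps_used))
    )
    np.asarray(counts[iu], dtype=np.float32).tofile(Path(str(prefix) + ".grm.N.bin"))
    pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids}).to_csv(
        Path(str(prefix) + ".grm.id"), sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Phenotype tables and results


def read_trait_table(path: str | Path, schema: dict) -> TraitTable:
    """Read a TSV phenotype table.

    ``schema`` names the roles: ``{"id": col, "outcome": col,
    "covariates": [cols], "fixed_effects": [cols]}``.  Rows with missing
    values are retained; missingness is handled per analysis group later.
    """
    df = pd.read_csv(path, sep="\t")
    id_col = schema.get("id", "id")
    declared = [id_col, schema["outcome"], *schema.get("covariates", []),
                *schema.get("fixed_effects", [])]
    for col in declared:
        if col not in df.columns:
            raise SchemaError(f"declared column {col!r} missing from {path}")
    df[id_col] = df[id_col].astype(str)
    df = df.set_index(id_col)
    return TraitTable(
        data=df,
        outcome=schema["outcome"],
        covariates=list(schema.get("covariates", [])),
        fixed_effects=list(schema.get("fixed_effects", [])),
    )


def results_to_frame(results: list) -> pd.DataFrame:
    """Flatten InteractionResults into a one-row-per-covariate table."""
    rows = []
    for r in results:
        rows.append(
            {
                "covariate": r.covariate,
                "p_value": r.combined_p,
                "significant": r.significant,
                "gxc_pct": r.gxc_pct,
                "gxc_ci_low": r.gxc_ci[0],
                "gxc_ci_high": r.gxc_ci[1],
                "rxc_pct": r.rxc_pct,
                "rxc_ci_low": r.rxc_ci[0],
                "rxc_ci_high": r.rxc_ci[1],
                "rint_p": r.rint_combined_p,
                "rint_signal_retained": r.rint_signal_retained,
                "n_subgroups": len(r.subgroup_p),
            }
        )
    return pd.DataFrame(rows)


def write_results(results: list, path: str | Path) -> None:
    """Write interaction results as TSV plus a JSON sidecar with full detail."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = results_to_frame(results)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    detail = [r.to_dict() for r in results]
    path.with_suffix(".json").write_text(json.dumps(detail, indent=2))


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
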