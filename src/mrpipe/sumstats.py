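"""Reading, validating and writing GWAS summary statistics and LD tables.

The canonical in-memory container is a :class:`SumstatsTable`: a pandas
DataFrame with one row per SNP and fixed column names, plus trait metadata
(name, continuous/binary, case fraction for binary traits).  Files from
different consortia use different column spellings; a *dialect* is a mapping
from canonical names to file column names, so e.g. FinnGen-style files
(``rsids``, ``#chrom``, ``sebeta`` ...) and MiBioGen-style files
(``rsID``, ``bp``, ``eff.allele`` ...) parse to identical records.

Linkage disequilibrium is consumed as a precomputed pairwise r-squared
table (:class:`LdTable`), not computed from genotypes: clumping only ever
needs symmetric r2 lookups, and a three-column TSV keeps the package free
of reference-panel downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

__all__ = [
    "CANONICAL_COLUMNS",
    "SumstatsTable",
    "LdTable",
    "read_sumstats",
    "write_sumstats",
    "read_ld",
    "write_ld",
    "register_dialect",
    "load_dialect_yaml",
]

#: Canonical column order of the interchange TSV.
CANONICAL_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")

_VALID_ALLELES = frozenset("ACGT")

#: Columns that every dialect must map; ``eaf`` and ``n`` may be absent from
#: a file (eaf becomes missing; n may be supplied through trait metadata).
_MANDATORY = ("snp", "chr", "pos", "ea", "oa", "beta", "se", "pval")

_DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    "mibiogen-like": {
        "snp": "rsID",
        "chr": "chr",
        "pos": "bp",
        "ea": "eff.allele",
        "oa": "ref.allele",
        "eaf": "EAF",
        "beta": "beta",
        "se": "SE",
        "pval": "P.weightedSumZ",
        "n": "N",
    },
    "finngen-like": {
        "snp": "rsids",
        "chr": "#chrom",
        "pos": "pos",
        "ea": "alt",
        "oa": "ref",
        "eaf": "af_alt",
        "beta": "beta",
        "se": "sebeta",
        "pval": "pval",
    },
}


def register_dialect(name: str, mapping: Mapping[str, str]) -> None:
    """Register a column-name dialect. ``mapping`` maps canonical names
    (see :data:`CANONICAL_COLUMNS`) to the column names used in files."""
    missing = [c for c in _MANDATORY if c not in mapping]
    if missing:
        raise FormatError(f"dialect {name!r} does not map mandatory columns: {missing}")
    _DIALECTS[name] = dict(mapping)


def load_dialect_yaml(path: str | Path) -> None:
    """Register one or more dialects from a YAML file of
    ``{dialect_name: {canonical: file_column, ...}, ...}``."""
    with open(path) as fh:
        dialects = yaml.safe_load(fh)
    for name, mapping in dialects.items():
        register_dialect(name, mapping)


@dataclass(frozen=True)
class SumstatsTable:
    """Per-SNP GWAS association records for a single trait.

    Parameters
    ----------
    trait_name
        Label of the trait (e.g. a bacterial genus, or the outcome phenotype).
    trait_type
        ``"continuous"`` (standardized abundance) or ``"binary"``
        (log-odds effect sizes).
    records
        DataFrame with the canonical columns; ``eaf`` may contain NaN.
    case_fraction
        Proportion of cases; required exactly when the trait is binary.
    """

    trait_name: str
    trait_type: str
    records: pd.DataFrame
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.case_fraction is None or not 0.0 < self.case_fraction < 1.0:
                raise ValidationError(
                    "binary trait requires case_fraction in (0, 1), "
                    f"got {self.case_fraction!r}"
                )
        elif self.case_fraction is not None:
            raise ValidationError("case_fraction only applies to binary traits")
        df = _coerce_records(self.records)
        _validate_records(df)
        object.__setattr__(self, "records", df)

    def __len__(self) -> int:
        return len(self.records)

    def with_records(self, records: pd.DataFrame) -> "SumstatsTable":
        """Copy of this table with a different record set (same trait metadata)."""
        return replace(self, records=records.reset_index(drop=True))

    def equals(self, other: "SumstatsTable") -> bool:
        return (
            self.trait_name == other.trait_name
            and self.trait_type == other.trait_type
            and (
                self.case_fraction == other.case_fraction
                or (self.case_fraction is None and other.case_fraction is None)
            )
            and self.records.equals(other.records)
        )


def _coerce_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    out = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True).copy()
    out["snp"] = out["snp"].astype(str)
    out["chr"] = out["chr"].astype(str)
    for col, kind in (("pos", np.int64), ("n", np.int64)):
        try:
            out[col] = out[col].astype(kind)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"column {col!r} is not integral: {exc}") from exc
    for col in ("eaf", "beta", "se", "pval"):
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
    for col in ("ea", "oa"):
        out[col] = out[col].astype(str).str.upper()
    return out


def _validate_records(df: pd.DataFrame) -> None:
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.ea not in _VALID_ALLELES or row.oa not in _VALID_ALLELES:
            problems.append(f"row {i}: alleles must be single A/C/G/T bases "
                            f"(got {row.ea!r}/{row.oa!r})")
            continue
        if row.ea == row.oa:
            problems.append(f"row {i}: effect and other allele are identical ({row.ea})")
        if not row.se > 0:
            problems.append(f"row {i}: se must be > 0 (got {row.se!r})")
        if not 0.0 < row.pval <= 1.0:
            problems.append(f"row {i}: pval must be in (0, 1] (got {row.pval!r})")
        if not math.isnan(row.eaf) and not 0.0 <= row.eaf <= 1.0:
            problems.append(f"row {i}: eaf must be in [0, 1] (got {row.eaf!r})")
        if row.pos <= 0:
            problems.append(f"row {i}: pos must be a positive 1-based coordinate")
        if row.n <= 0:
            problems.append(f"row {i}: n must be a positive sample size")
    dup = df["snp"][df["snp"].duplicated()].unique()
    if len(dup):
        problems.append(f"duplicate snp_id(s): {', '.join(dup[:5])}")
    if problems:
        raise ValidationError("; ".join(problems))


def read_sumstats(
    path: str | Path,
    dialect: str = "canonical",
    *,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    case_fraction: float | None = None,
    n_default: int | None = None,
) -> SumstatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``dialect`` selects the registered column-name map.  ``n_default`` fills
    the per-SNP sample size when the file carries no N column (FinnGen-style
    files do not).
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; registered: {sorted(_DIALECTS)}")
    mapping = _DIALECTS[dialect]
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""],
                          keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [mapping[c] for c in _MANDATORY if mapping[c] not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    df = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        col = mapping.get(canon)
        if col is not None and col in raw.columns:
            df[canon] = raw[col]
        elif canon == "eaf":
            df[canon] = np.nan
        elif canon == "n":
            if n_default is None:
                raise FormatError(
                    f"{path}: no sample-size column ({col!r}) and no n_default given")
            df[canon] = n_default
        else:
            raise FormatError(f"{path}: missing mandatory column(s): {col}")
    for col in ("pos", "n"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: row {bad[0]}: unparseable {col!r} value {df[col][bad[0]]!r}")
        df[col] = numeric
    for col in ("eaf", "beta", "se", "pval"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: row {bad[0]}: unparseable {col!r} value {df[col][bad[0]]!r}")
        # exact decimal-to-binary rounding so write -> read is bit-identical
        df[col] = np.array([float(v) if isinstance(v, str) else v
                            for v in df[col]], dtype=float)
    return SumstatsTable(
        trait_name=trait_name if trait_name is not None else path.stem,
        trait_type=trait_type,
        records=df,
        case_fraction=case_fraction,
    )


def write_sumstats(table: SumstatsTable, path: str | Path,
                   dialect: str = "canonical") -> Path:
    """Write a table as a TSV in the given dialect.

    Floats are serialized with 17 significant digits so that
    ``read_sumstats(write_sumstats(t))`` reproduces ``t`` bit-exactly.
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    mapping = _DIALECTS[dialect]
    df = table.records
    out = pd.DataFrame(index=df.index)
    for canon in CANONICAL_COLUMNS:
        col = mapping.get(canon)
        if col is None:
            continue
        if canon in ("pos", "n"):
            out[col] = df[canon].map("{:d}".format)
        elif canon in ("eaf", "beta", "se", "pval"):
            out[col] = df[canon].map(
                lambda x: "NA" if pd.isna(x) else f"{x:.17g}")
        else:
            out[col] = df[canon]
    path = Path(path)
    out.to_csv(path, sep="\t", index=False)
    return path


class LdTable:
    """Symmetric pairwise r-squared lookup.

    Stores unordered SNP pairs; ``r2(a, a)`` is 1 by definition and any
    pair not stored is treated as unlinked (r2 = 0).
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), r2 in entries.items():
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValidationError(f"r2 must be in [0, 1], got {r2!r} for ({a}, {b})")
        if a == b:
            return  # self-pairs are implicit (r2 = 1), never stored
        self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def items(self):
        return self._r2.items()


def read_ld(path: str | Path) -> LdTable:
    """Read a three-column (snp_a, snp_b, r2) TSV into an :class:`LdTable`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns (snp_a, snp_b, r2)")
    table = LdTable()
    for i, row in enumerate(df.itertuples(index=False)):
        r2 = float(row[2])
        if not 0.0 <= r2 <= 1.0:
            raise ValidationError(f"{path}: row {i}: r2 outside [0, 1]: {r2}")
        table.add(str(row[0]), str(row[1]), r2)
    return table


def write_ld(table: LdTable, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"snp_a": a, "snp_b": b, "r2": f"{r2:.17g}"}
            for (a, b), r2 in sorted(table.items())]
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
        path, sep="\t", index=False)
    return path
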