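"""GWAS summary-statistics tables and linkage-disequilibrium references.

This module is the contract layer for the rest of the package: every
analysis consumes :class:`SumStatTable` objects (one per trait) and an
:class:`LDReference` for clumping and proxy lookup.

The on-disk dialect is deliberately strict: tab-separated, UTF-8, ``NA``
for missing values, and a fixed canonical header.  ``column_map`` on
:func:`read_sumstats` adapts other dialects at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_case", "n_control",
]
MANDATORY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]
VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_FLOAT_COLS = ["eaf", "beta", "se", "pval"]
_INT_COLS = ["pos", "n", "n_case", "n_control"]


class SumStatFormatError(ValueError):
    """The file or table violates the summary-statistics contract."""


@dataclass
class SumStatRecord:
    """One variant's association summary for a single trait.

    ``beta`` is the per-effect-allele estimate: a log odds ratio for binary
    traits, standardized units for continuous traits.  ``eaf`` is the
    effect-allele frequency; it may be absent (``None``) and downstream
    steps that need it (palindrome adjudication, variance explained) flag
    or reject such records.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n: Optional[int] = None
    n_case: Optional[int] = None
    n_control: Optional[int] = None

    def problems(self) -> list[str]:
        """Return invariant violations (empty list when valid)."""
        msgs = []
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            msgs.append("alleles must be single bases in {A,C,G,T} (SNPs only)")
        elif ea == oa:
            msgs.append("effect_allele must differ from other_allele")
        if not (self.se > 0):
            msgs.append("se must be > 0")
        if not (0 < self.pval <= 1):
            msgs.append("pval must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            msgs.append("eaf must be in [0, 1]")
        if (
            self.n is not None
            and self.n_case is not None
            and self.n_control is not None
            and self.n_case + self.n_control != self.n
        ):
            msgs.append("n_case + n_control must equal n")
        return msgs

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class SumStatTable:
    """An ordered collection of per-SNP summary records for one trait."""

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    data: pd.DataFrame
    diagnostics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary/continuous, got {self.trait_type!r}")
        self.data = _canonicalize_frame(self.data)
        dup = self.data["snp_id"][self.data["snp_id"].duplicated()]
        if len(dup):
            raise SumStatFormatError(
                "duplicate snp_id entries: " + ", ".join(sorted(set(dup)))
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def _index(self) -> dict:
        # tables are treated as immutable once built; cache the id lookup
        idx = getattr(self, "_index_cache", None)
        if idx is None or len(idx) != len(self.data):
            idx = {s: i for i, s in enumerate(self.data["snp_id"])}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> SumStatRecord:
        i = self._index.get(snp_id)
        if i is None:
            raise KeyError(snp_id)
        return _row_to_record(self.data.iloc[i])

    def records(self) -> Iterator[SumStatRecord]:
        for _, row in self.data.iterrows():
            yield _row_to_record(row)

    def subset(self, snp_ids: Sequence[str]) -> "SumStatTable":
        """Rows restricted to ``snp_ids``, original order preserved."""
        keep = self.data[self.data["snp_id"].isin(set(snp_ids))].reset_index(drop=True)
        return SumStatTable(self.trait_name, self.trait_type, keep,
                            diagnostics=list(self.diagnostics))


def _canonicalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[CANONICAL_COLUMNS]
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype("string")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    def _exact_float(v):
        # python float() is round-trip exact; pandas' fast parser is not
        if pd.isna(v):
            return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    for col in _FLOAT_COLS:
        df[col] = df[col].map(_exact_float).astype(float)
    for col in _INT_COLS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df.reset_index(drop=True)


def _row_to_record(row: pd.Series) -> SumStatRecord:
    def _opt(v):
        return None if pd.isna(v) else v

    return SumStatRecord(
        snp_id=row["snp_id"],
        effect_allele=row["effect_allele"],
        other_allele=row["other_allele"],
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=float(row["pval"]),
        chrom=_opt(row["chrom"]),
        pos=None if pd.isna(row["pos"]) else int(row["pos"]),
        eaf=_opt(row["eaf"]),
        n=None if pd.isna(row["n"]) else int(row["n"]),
        n_case=None if pd.isna(row["n_case"]) else int(row["n_case"]),
        n_control=None if pd.isna(row["n_control"]) else int(row["n_control"]),
    )


def read_sumstats(
    path,
    trait_type: str,
    column_map: Optional[Mapping[str, str]] = None,
    trait_name: Optional[str] = None,
) -> SumStatTable:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps file column names to canonical names, e.g.
    ``{"SNP": "snp_id", "A1": "effect_allele"}``.  Rows violating record
    invariants (non-positive se, invalid alleles, indels, p outside (0,1])
    are rejected; a row-numbered diagnostic is kept on the returned table.

    Raises
    ------
    SumStatFormatError
        When a mandatory column is missing or snp_ids are duplicated.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                      keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SumStatFormatError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )

    diagnostics: list[str] = []
    keep_rows = []
    for i, row in raw.iterrows():
        rowno = i + 2  # 1-based, counting the header line
        msgs = []
        for col in ("beta", "se", "pval"):
            val = row.get(col)
            if pd.isna(val):
                msgs.append(f"{col} missing")
            else:
                try:
                    float(val)
                except (TypeError, ValueError):
                    msgs.append(f"{col} is not numeric: {val!r}")
        if msgs:
            diagnostics.append(f"row {rowno}: " + "; ".join(msgs))
            continue
        rec_df = _canonicalize_frame(row.to_frame().T)
        rec = _row_to_record(rec_df.iloc[0])
        problems = rec.problems()
        if problems:
            diagnostics.append(f"row {rowno} ({rec.snp_id}): " + "; ".join(problems))
            continue
        keep_rows.append(rec_df)

    if keep_rows:
        df = pd.concat(keep_rows, ignore_index=True)
    else:
        df = _canonicalize_frame(pd.DataFrame(columns=CANONICAL_COLUMNS))

    table = SumStatTable(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        data=df,
        diagnostics=diagnostics,
    )
    if trait_type == "binary" and table.data["n_case"].isna().all() and len(table):
        table.diagnostics.append("trait declared binary but no case/control counts present")
    if table.data["eaf"].isna().any():
        table.diagnostics.append("eaf absent for some records; palindrome adjudication "
                                 "and frequency-based R2 unavailable for those SNPs")
    return table


def write_sumstats(table: SumStatTable, path) -> Path:
    """Write a table in the canonical tab-delimited dialect.

    ``read_sumstats(write_sumstats(t))`` reproduces ``t`` field for field,
    and a file already in the canonical dialect round-trips byte-identically.
    """
    path = Path(path)
    # shortest round-trip float repr so write -> read is the identity
    table.data.to_csv(path, sep="\t", index=False, na_rep="NA",
                      float_format=lambda v: repr(float(v)))
    return path


class LDReference:
    """Symmetric pairwise r-squared lookup between variants.

    Absent pairs are treated as r2 = 0 (independent), which is the
    conservative convention for clumping decisions.  Positions are kept
    only for clump windows and proxy tie-breaks.
    """

    def __init__(
        self,
        pairs: Optional[Mapping[tuple, float]] = None,
        positions: Optional[Mapping[str, tuple]] = None,
    ):
        self._pairs: dict[tuple, float] = {}
        self._adjacency: dict[str, dict[str, float]] = {}
        self.positions: dict[str, tuple] = dict(positions or {})
        for (a, b), r2 in (pairs or {}).items():
            self.add_pair(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple:
        return (a, b) if a <= b else (b, a)

    def add_pair(self, a: str, b: str, r2: float) -> None:
        if a == b:
            if not math.isclose(r2, 1.0, abs_tol=1e-8):
                raise ValueError(f"self-pair r2 for {a} must be 1, got {r2}")
            return
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a in self.positions and b in self.positions:
            if self.positions[a][0] != self.positions[b][0]:
                raise ValueError(
                    f"r2 stored for cross-chromosome pair ({a}, {b})"
                )
        key = self._key(a, b)
        prev = self._pairs.get(key)
        if prev is not None and not math.isclose(prev, r2, abs_tol=1e-8):
            raise ValueError(f"conflicting r2 entries for pair {key}: {prev} vs {r2}")
        self._pairs[key] = r2
        self._adjacency.setdefault(a, {})[b] = r2
        self._adjacency.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b), 0.0)

    def partners(self, snp_id: str) -> dict[str, float]:
        """All variants with a stored (non-zero-by-default) r2 to ``snp_id``."""
        return dict(self._adjacency.get(snp_id, {}))

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_matrix(
        cls,
        matrix,
        snp_ids: Sequence[str],
        positions: Optional[Mapping[str, tuple]] = None,
    ) -> "LDReference":
        """Build from a dense square r2 matrix with a matching id list."""
        mat = np.asarray(matrix, dtype=float)
        k = len(snp_ids)
        if mat.shape != (k, k):
            raise ValueError(f"matrix shape {mat.shape} does not match {k} ids")
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValueError("dense LD matrix is not symmetric (tolerance 1e-8)")
        if np.any(mat < -1e-12) or np.any(mat > 1 + 1e-12):
            raise ValueError("r2 values outside [0, 1] in dense LD matrix")
        ref = cls(positions=positions)
        for i in range(k):
            for j in range(i + 1, k):
                if mat[i, j] > 0:
                    ref.add_pair(snp_ids[i], snp_ids[j], float(mat[i, j]))
        return ref


def load_ld_reference(path) -> LDReference:
    """Load a whitespace-delimited pair list with header ``SNP_A SNP_B R2``.

    Optional ``CHR_A BP_A CHR_B BP_B`` columns populate positions; other
    columns are ignored.  This matches the pair-list dialect emitted by
    common LD tools.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise SumStatFormatError(f"{path.name}: LD pair list missing column {col}")
    positions = {}
    has_pos = {"CHR_A", "BP_A", "CHR_B", "BP_B"}.issubset(df.columns)
    if has_pos:
        for _, row in df.iterrows():
            positions[str(row["SNP_A"])] = (str(row["CHR_A"]), int(row["BP_A"]))
            positions[str(row["SNP_B"])] = (str(row["CHR_B"]), int(row["BP_B"]))
    ref = LDReference(positions=positions)
    for _, row in df.iterrows():
        ref.add_pair(str(row["SNP_A"]), str(row["SNP_B"]), float(row["R2"]))
    return ref


def write_ld_reference(ref: LDReference, path) -> Path:
    """Write the pair list (with positions when known)."""
    path = Path(path)
    rows = []
    has_pos = bool(ref.positions)
    for (a, b), r2 in sorted(ref._pairs.items()):
        row = {"SNP_A": a, "SNP_B": b, "R2": r2}
        if has_pos and a in ref.positions and b in ref.positions:
            row.update(CHR_A=ref.positions[a][0], BP_A=ref.positions[a][1],
                       CHR_B=ref.positions[b][0], BP_B=ref.positions[b][1])
        rows.append(row)
    cols = ["SNP_A", "SNP_B", "R2"]
    if has_pos:
        cols = ["SNP_A", "SNP_B", "R2", "CHR_A", "BP_A", "CHR_B", "BP_B"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path
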