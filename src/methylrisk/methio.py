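"""Data model and file I/O for methylation-array analyses.

Central containers: :class:`BetaMatrix` (CpG x sample methylation
fractions), :class:`SampleSheet` (per-sample phenotypes and covariates),
:class:`CpGAnnotation` (CpG -> gene map), :class:`GeneSetCollection`
(named gene sets, GMT dialect) and :class:`Signature` (sparse CpG ->
coefficient risk signature with its standardization metadata).

All file dialects are plain text: beta matrices are tab-separated with a
leading ``cpg_id`` column and ``NA`` for missing values; sample sheets
and annotations are CSV; gene sets use the standard GMT format;
signatures are CSV with a ``# key: value`` metadata header block.
Readers validate invariants (unique ids, betas in [0, 1)) and raise
:class:`ParseError` naming the offending row/column rather than coercing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "BetaMatrix",
    "SampleSheet",
    "CpGAnnotation",
    "GeneSetCollection",
    "Signature",
    "beta_from_intensities",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "read_gene_sets",
    "write_gene_sets",
    "read_signature",
    "write_signature",
]

#: fixed offset in the intensity-ratio beta formula (array-platform convention)
BETA_OFFSET = 100.0

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless enough for round-trips


class ParseError(ValueError):
    """A file violated its declared dialect or a container invariant."""


# ---------------------------------------------------------------------------
# beta computation


def beta_from_intensities(M, U):
    """Methylation fraction from methylated/unmethylated signal intensities.

    beta = Max(M, 0) / (Max(M, 0) + Max(U, 0) + 100); negative intensities
    are clamped to zero and the +100 offset keeps the ratio in [0, 1) and
    stabilises low-intensity probes.  Works element-wise on arrays.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise ValueError("intensities must be finite")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    out = m / (m + u + BETA_OFFSET)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# containers


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()[:5]
        raise ParseError(f"duplicate {what}: {dup}")


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation fractions in [0, 1).

    ``values`` is a DataFrame indexed by CpG id with sample-id columns.
    Missing values are NaN; everything else must lie in [0, 1).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "cpg_id")
        _check_unique(self.values.columns, "sample_id")
        arr = self.values.to_numpy(dtype=float)
        bad = ~(np.isnan(arr) | ((arr >= 0.0) & (arr < 1.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"beta out of [0,1) at cpg {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {arr[i, j]!r}"
            )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_cpgs(self, cpg_ids) -> "BetaMatrix":
        keep = self.values.index.intersection(pd.Index(cpg_ids))
        return BetaMatrix(self.values.loc[keep])


_SHEET_CORE = ("group", "age", "batch", "cancer_status")
_SHEET_SURV = ("followup_time", "event")


@dataclass
class SampleSheet:
    """Per-sample phenotype table indexed by sample id.

    Core columns: ``group`` (0/1: wildtype/carrier or control/case),
    ``age`` (years), ``batch`` (categorical), ``cancer_status`` (0/1).
    Optional survival columns ``followup_time`` (years) and ``event``
    (0/1); any further columns are treated as epidemiological factors.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample_id")
        missing = [c for c in _SHEET_CORE if c not in self.data.columns]
        if missing:
            raise ParseError(f"sample sheet missing required columns: {missing}")
        if "event" in self.data.columns and "followup_time" not in self.data.columns:
            raise ParseError("column 'event' requires 'followup_time'")
        if "followup_time" in self.data.columns:
            ft = self.data["followup_time"].to_numpy(dtype=float)
            if np.any(ft[~np.isnan(ft)] < 0):
                raise ParseError("followup_time must be >= 0")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def group(self) -> np.ndarray:
        return self.data["group"].to_numpy(dtype=int)

    @property
    def factor_columns(self) -> list[str]:
        known = set(_SHEET_CORE) | set(_SHEET_SURV)
        return [c for c in self.data.columns if c not in known]


@dataclass
class CpGAnnotation:
    """One gene symbol per CpG row (multi-mapping = repeated cpg rows)."""

    data: pd.DataFrame  # columns: cpg_id (index), gene_symbol

    def __post_init__(self) -> None:
        if "gene_symbol" not in self.data.columns:
            raise ParseError("annotation needs a 'gene_symbol' column")
        _check_unique(self.data.index, "cpg_id")

    def genes_for(self, cpg_ids) -> set[str]:
        idx = self.data.index.intersection(pd.Index(cpg_ids))
        return set(self.data.loc[idx, "gene_symbol"])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. polycomb-target collections)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ParseError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class Signature:
    """Sparse linear risk signature over CpGs.

    ``coefficients`` maps CpG id -> log-odds weight per standardized beta
    (all non-zero).  ``means``/``scales`` store the training-cohort
    per-CpG standardization so that scoring a new cohort is
    self-contained.  ``metadata`` records how the signature was derived
    (elastic-net mixing alpha, number of base classifiers, seed, the
    candidate FDR threshold, ...).
    """

    coefficients: pd.Series
    means: pd.Series
    scales: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.coefficients.index, "cpg_id")
        if (self.coefficients == 0).any() or self.coefficients.isna().any():
            raise ParseError("signature coefficients must be non-zero and finite")
        for s, nm in ((self.means, "means"), (self.scales, "scales")):
            if not s.index.equals(self.coefficients.index):
                raise ParseError(f"signature {nm} index mismatch")

    def __len__(self) -> int:
        return len(self.coefficients)

    @property
    def cpg_ids(self) -> pd.Index:
        return self.coefficients.index


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str})
    if df.columns[0] != "cpg_id":
        raise ParseError(f"{path}: first column must be 'cpg_id', got {df.columns[0]!r}")
    df = df.set_index("cpg_id")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric beta value ({e})") from None
    try:
        return BetaMatrix(df)
    except ParseError as e:
        raise ParseError(f"{path}: {e}") from None


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT,
                         index_label="cpg_id")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    try:
        return SampleSheet(df)
    except ParseError as e:
        raise ParseError(f"{path}: {e}") from None


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index_label="sample_id", float_format=_FLOAT_FMT)


def read_annotation(path) -> CpGAnnotation:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["cpg_id", "gene_symbol"]:
        raise ParseError(f"{path}: expected columns cpg_id,gene_symbol")
    return CpGAnnotation(df.set_index("cpg_id"))


def write_annotation(ann: CpGAnnotation, path) -> None:
    ann.data.to_csv(path, index_label="cpg_id")


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description "
                                 f"and >=1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def _fmt_meta(value) -> str:
    if isinstance(value, float):
        return _FLOAT_FMT % value
    return str(value)


def write_signature(sig: Signature, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(sig.metadata):
            fh.write(f"# {key}: {_fmt_meta(sig.metadata[key])}\n")
        fh.write("cpg_id,coefficient,mean,scale\n")
        for cpg in sig.cpg_ids:
            fh.write(
                f"{cpg},{_FLOAT_FMT % sig.coefficients[cpg]},"
                f"{_FLOAT_FMT % sig.means[cpg]},{_FLOAT_FMT % sig.scales[cpg]}\n"
            )


def _parse_meta_value(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def read_signature(path) -> Signature:
    metadata: dict = {}
    rows: list[tuple[str, float, float, float]] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, raw = line.lstrip("# ").partition(":")
                metadata[key.strip()] = _parse_meta_value(raw.strip())
                continue
            if not header_seen:
                if line.split(",")[:2] != ["cpg_id", "coefficient"]:
                    raise ParseError(f"{path}:{lineno}: bad signature header")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            cpg, coef, mean, scale = parts
            coef = float(coef)
            if coef == 0.0:
                raise ParseError(f"{path}:{lineno}: zero coefficient for {cpg!r}")
            rows.append((cpg, coef, float(mean), float(scale)))
    if not rows:
        raise ParseError(f"{path}: empty signature")
    cpgs = [r[0] for r in rows]
    idx = pd.Index(cpgs, name="cpg_id")
    return Signature(
        coefficients=pd.Series([r[1] for r in rows], index=idx),
        means=pd.Series([r[2] for r in rows], index=idx),
        scales=pd.Series([r[3] for r in rows], index=idx),
        metadata=metadata,
    )
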