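"""Domain types and file I/O for multi-omics phase analysis.

The package works with four kinds of objects:

* :class:`OmicsMatrix` — a features × subjects numeric matrix (gene
  expression or CpG methylation) together with its measurement scale,
* subject metadata tables (plain :class:`pandas.DataFrame`),
* :class:`GeneSetCollection` — named gene lists with GMT round-trip,
* :class:`ClockModel` — a linear molecular-age clock.

All tabular formats are tab-separated UTF-8 with a mandatory header row
and no quoting, matching common omics matrix exports.  Feature and
subject identifiers are matched by exact string equality; identifier
translation is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("agingphases")

EXPRESSION = "expression"
METHYLATION = "methylation"
KINDS = frozenset({EXPRESSION, METHYLATION})

RAW_TPM = "raw_tpm"
LOG2_TPM = "log2_tpm"
BETA = "beta"
M_VALUE = "m_value"
SCALES = frozenset({RAW_TPM, LOG2_TPM, BETA, M_VALUE})


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class OmicsMatrix:
    """A features × subjects omics data matrix.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and subject ids as columns.
    kind
        ``"expression"`` or ``"methylation"``.
    scale
        One of ``raw_tpm``, ``log2_tpm``, ``beta``, ``m_value``.  Beta
        values must lie in [0, 1].
    batch
        Optional subject → batch label mapping (Series indexed by
        subject id).
    """

    values: pd.DataFrame
    kind: str
    scale: str
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown omics kind {self.kind!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("matrix body must be numeric")
        if arr.size and np.isnan(arr.astype(float)).any():
            raise ValueError("matrix contains missing values")
        if self.scale == BETA and arr.size:
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValueError("beta values must lie in [0, 1]")
        if self.batch is not None:
            self.batch = self.batch.reindex(cols)
            if self.batch.isna().any():
                missing = self.batch.index[self.batch.isna()].tolist()
                raise ValueError(f"batch labels missing for subjects {missing[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "OmicsMatrix":
        """Return a copy carrying new values (and optionally a new scale)."""
        batch = None if self.batch is None else self.batch.copy()
        return OmicsMatrix(values=values, kind=self.kind,
                           scale=self.scale if scale is None else scale,
                           batch=batch)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    def __init__(self, sets: list[GeneSet] | None = None) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets or []:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return list(self) == list(other)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self:
            out.update(s.genes)
        return out

    def subset(self, names: list[str]) -> "GeneSetCollection":
        return GeneSetCollection([self._sets[n] for n in names])


@dataclass
class ClockModel:
    """A linear molecular-age clock: age = intercept + Σ w_f · x_f."""

    intercept: float
    coefficients: pd.Series
    input_scale: str

    def __post_init__(self) -> None:
        if self.input_scale not in (M_VALUE, LOG2_TPM):
            raise ValueError(f"unsupported clock input scale {self.input_scale!r}")
        if self.coefficients.index.has_duplicates:
            raise ValueError("duplicate clock feature ids")
        if len(self.coefficients) == 0:
            raise ValueError("clock must have at least one coefficient")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a Broad-style GMT file.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Lines
    with fewer than three fields raise :class:`FormatError` naming the
    line; duplicate genes within a line are collapsed with a warning;
    duplicate set names are an error.  File order is preserved.
    """
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("gene set %r: %d duplicate gene(s) collapsed",
                               name, len(genes) - len(deduped))
            collection.add(GeneSet(name, description, tuple(deduped)))
    return collection


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    """Write a collection in GMT format (inverse of :func:`read_gene_sets`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def load_omics_matrix(path, kind: str, scale: str, impute_missing: bool = False) -> OmicsMatrix:
    """Load a TSV matrix (first column feature ids, header subject ids).

    Non-numeric cells raise an error with their coordinates.  Missing
    values are rejected unless ``impute_missing`` is set, in which case
    each feature's missing entries are replaced by that feature's
    median across subjects.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: matrix body is empty")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature ids {dups[:5]}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate subject ids in header")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at feature "
            f"{df.index[r]!r}, subject {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        if not impute_missing:
            n_missing = int(numeric.isna().to_numpy().sum())
            raise FormatError(f"{path}: {n_missing} missing value(s); "
                              "pass impute_missing=True to median-impute per feature")
        medians = numeric.median(axis=1)
        numeric = numeric.apply(lambda row: row.fillna(medians[row.name]), axis=1)
        logger.warning("%s: missing values median-imputed per feature", path)
    try:
        return OmicsMatrix(values=numeric.astype(float), kind=kind, scale=scale)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_omics_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path) -> pd.DataFrame:
    """Read a subject metadata table (subject_id, chron_age, batch, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("subject_id", "chron_age"):
        if col not in df.columns:
            raise FormatError(f"metadata lacks required column {col!r}")
    if (df["chron_age"] <= 0).any():
        raise FormatError("chronological ages must be positive")
    tp = df["timepoint"] if "timepoint" in df.columns else pd.Series(1, index=df.index)
    if df.groupby(tp)["subject_id"].apply(lambda s: s.duplicated().any()).any():
        raise FormatError("duplicate subject ids within a timepoint")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_clock(path, input_scale: str) -> ClockModel:
    """Read a linear clock from a two-column TSV (feature, coefficient).

    The intercept is stored under the reserved feature id
    ``(Intercept)``; a missing intercept row defaults to zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={"feature": str})
    if list(df.columns[:2]) != ["feature", "coefficient"]:
        raise FormatError(f"{path}: expected columns feature, coefficient")
    coef = pd.Series(df["coefficient"].to_numpy(float), index=df["feature"])
    intercept = float(coef.pop("(Intercept)")) if "(Intercept)" in coef.index else 0.0
    return ClockModel(intercept=intercept, coefficients=coef, input_scale=input_scale)


def write_clock(clock: ClockModel, path) -> None:
    rows = [("(Intercept)", clock.intercept)]
    rows += list(clock.coefficients.items())
    pd.DataFrame(rows, columns=["feature", "coefficient"]).to_csv(path, sep="\t", index=False)


def intersect_features(a: OmicsMatrix, b: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict two same-kind matrices to their (sorted) common features.

    Used to make platforms comparable, e.g. reducing a larger CpG array
    to the probes shared with a smaller one.  Subject columns are
    unchanged; an empty intersection is an error.
    """
    if a.kind != b.kind or a.scale != b.scale:
        raise ValueError("matrices must share kind and scale to intersect features")
    common = sorted(set(a.feature_ids) & set(b.feature_ids))
    if not common:
        raise ValueError("feature intersection is empty")
    return a.with_values(a.values.loc[common]), b.with_values(b.values.loc[common])
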