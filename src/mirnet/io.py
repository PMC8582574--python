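"""Expression matrices, sample annotations and gene-set collections.

All pipeline inputs are plain text: expression matrices are TSV files with a
header row of sample identifiers and feature identifiers in the first column;
clinical annotations are TSV with fixed column names; gene sets use the GMT
dialect (name, description, genes, tab-separated).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ValueKind",
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSetCollection",
    "ParseError",
    "ValidationError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_sample_annotations",
    "write_sample_annotations",
    "filter_by_purity",
    "align_samples",
]

ANNOTATION_COLUMNS = (
    "sample_id",
    "purity",
    "group",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
)


class ParseError(ValueError):
    """A file could not be parsed into the declared structure."""


class ValidationError(ValueError):
    """Structurally parseable input violates a domain invariant."""


class ValueKind(str, Enum):
    """What the numbers in an expression matrix mean.

    RPM and FPKM are library-size-normalized abundances (small RNA and mRNA
    respectively), RAW_COUNTS are unnormalized non-negative counts, and
    LOG2_NORM marks a matrix that has been size-factor normalized and
    log2-transformed (the only kind allowed to contain negative values).
    """

    RPM = "RPM"
    FPKM = "FPKM"
    RAW_COUNTS = "RAW_COUNTS"
    LOG2_NORM = "LOG2_NORM"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A feature-by-sample numeric matrix with a declared value kind.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique row and column identifiers, in matrix order.
    values
        Array of shape ``(n_features, n_samples)``. Finite everywhere;
        non-negative unless ``value_kind`` is :attr:`ValueKind.LOG2_NORM`.
    value_kind
        Declared by the caller, never inferred from the data.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: ValueKind

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.value_kind = ValueKind(self.value_kind)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.value_kind is not ValueKind.LOG2_NORM and np.any(self.values < 0):
            raise ValidationError(
                f"negative values are not allowed for value_kind={self.value_kind.value}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value_kind: ValueKind) -> "ExpressionMatrix":
        return cls(
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            value_kind=value_kind,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given samples, in the given order."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample identifiers: {missing}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols],
            value_kind=self.value_kind,
        )

    def row(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise ValidationError(f"feature {feature_id!r} not in matrix") from None
        return self.values[i]


@dataclass
class SampleAnnotation:
    """Per-sample clinical annotation.

    ``purity`` is the tumor-content fraction in [0, 1] (``None`` when not
    assessed); ``group`` is a free-form response label such as ``benefit`` /
    ``no_benefit``; time fields are in days with a boolean event flag that
    must be present whenever the matching time is present.
    """

    sample_id: str
    purity: float | None = None
    group: str | None = None
    pfs_time: float | None = None
    pfs_event: bool | None = None
    os_time: float | None = None
    os_event: bool | None = None

    def __post_init__(self) -> None:
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id}: purity {self.purity} outside [0, 1]"
            )
        for time_field, event_field in (("pfs_time", "pfs_event"), ("os_time", "os_event")):
            t = getattr(self, time_field)
            e = getattr(self, event_field)
            if t is not None:
                if t < 0:
                    raise ValidationError(
                        f"sample {self.sample_id}: {time_field} must be non-negative"
                    )
                if e is None:
                    raise ValidationError(
                        f"sample {self.sample_id}: {event_field} required when "
                        f"{time_field} is present"
                    )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. a hallmark collection) from a GMT file."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


def read_expression_matrix(path: str | Path, value_kind: ValueKind) -> ExpressionMatrix:
    """Read a TSV expression matrix (features x samples).

    The first row holds sample identifiers, the first column feature
    identifiers. Every cell must be numeric; the first offending cell is
    named in the error. Duplicate identifiers are rejected.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, comment="#"
    )
    feature_ids = [str(i) for i in raw.index]
    sample_ids = [str(c) for c in raw.columns]
    _check_unique(feature_ids, "feature")
    _check_unique(sample_ids, "sample")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at feature "
            f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=numeric.to_numpy(dtype=float),
        value_kind=value_kind,
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a matrix as TSV with full float precision (round-trips to 1e-12)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.to_frame().to_csv(fh, sep="\t", float_format="%.17g", index_label="")


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    The description column is discarded and duplicate genes within a set are
    de-duplicated preserving first occurrence.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_bool(v) -> bool | None:
    f = _opt_float(v)
    return None if f is None else bool(int(f))


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a clinical annotation TSV with the fixed column set.

    Expected columns: ``sample_id, purity, group, pfs_time, pfs_event,
    os_time, os_event``. All but ``sample_id`` may be absent or empty.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str}, comment="#")
    if "sample_id" not in frame.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    annotations = []
    for rec in frame.to_dict(orient="records"):
        group = rec.get("group")
        if isinstance(group, float) and np.isnan(group):
            group = None
        annotations.append(
            SampleAnnotation(
                sample_id=str(rec["sample_id"]),
                purity=_opt_float(rec.get("purity")),
                group=group,
                pfs_time=_opt_float(rec.get("pfs_time")),
                pfs_event=_opt_bool(rec.get("pfs_event")),
                os_time=_opt_float(rec.get("os_time")),
                os_event=_opt_bool(rec.get("os_event")),
            )
        )
    _check_unique([a.sample_id for a in annotations], "sample")
    return annotations


def write_sample_annotations(
    annotations: Iterable[SampleAnnotation], path: str | Path
) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "sample_id": a.sample_id,
                "purity": a.purity,
                "group": a.group,
                "pfs_time": a.pfs_time,
                "pfs_event": None if a.pfs_event is None else int(a.pfs_event),
                "os_time": a.os_time,
                "os_event": None if a.os_event is None else int(a.os_event),
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def filter_by_purity(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    min_purity: float = 0.80,
) -> ExpressionMatrix:
    """Keep samples whose tumor purity is at least ``min_purity``.

    Samples with missing purity are dropped: the filter is a guarantee of
    tumor content, and an unassessed sample provides no such guarantee.
    Every matrix sample must be annotated. Idempotent.
    """
    purity = {a.sample_id: a.purity for a in annotations}
    missing = [s for s in matrix.sample_ids if s not in purity]
    if missing:
        raise ValidationError(f"samples without annotation: {missing}")
    kept = [
        s for s in matrix.sample_ids if purity[s] is not None and purity[s] >= min_purity
    ]
    if not kept:
        log.warning(
            "purity filter at %.2f removed all %d samples", min_purity, matrix.n_samples
        )
    else:
        log.info(
            "purity filter at %.2f kept %d/%d samples",
            min_purity,
            len(kept),
            matrix.n_samples,
        )
    return matrix.subset_samples(kept)


def align_samples(
    mirna: ExpressionMatrix, mrna: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared samples in sorted order.

    The canonical (lexicographic) order makes every downstream statistic
    independent of the column order of the inputs. Fewer than three shared
    samples is an error: a rank correlation on n < 3 points carries no
    information.
    """
    shared = sorted(set(mirna.sample_ids) & set(mrna.sample_ids))
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared samples between matrices; need >= 3"
        )
    return mirna.subset_samples(shared), mrna.subset_samples(shared)
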