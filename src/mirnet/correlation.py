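"""Spearman rank correlation and inverse-correlation edge filtering.

The regulatory proxy used throughout the pipeline is monotone
anti-association between a miRNA's abundance and an mRNA's abundance across
samples, measured by Spearman's rho. Ties receive midranks and rho is the
Pearson correlation of the rank vectors, which is algebraically identical to
the tie-corrected Spearman formula. Edges are the miRNA-mRNA pairs whose
rho falls strictly below a negative threshold (default -0.4 for tumor data,
-0.6 for cell lines, where correlations run stronger).

No p-values are attached to edges and no multiple-testing correction is
applied at the edge level: the screen filters on effect size (rho) alone.
The resulting per-pair false-positive rate at a given threshold is a
property of the sample size and is characterized in the package docs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ParseError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "midrank",
    "spearman_rho",
    "correlate_all",
    "filter_inverse",
    "CorrelationEdge",
    "CorrelationEdgeSet",
    "read_edge_set",
]


def midrank(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Midranks of a 1-D vector: tied values share the mean of their ranks.

    Ranks are 1-based and always sum to ``n * (n + 1) / 2``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValidationError("midrank expects a non-empty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValidationError("midrank requires finite values")
    n = v.size
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    # boundaries of tie blocks in the sorted vector
    block_start = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
    block_end = np.r_[block_start[1:], n]
    block_rank = 0.5 * (block_start + block_end - 1) + 1.0
    block_of = np.cumsum(np.r_[True, sv[1:] != sv[:-1]]) - 1
    ranks = np.empty(n, dtype=float)
    ranks[order] = block_rank[block_of]
    return ranks


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.vstack([midrank(row) for row in values])


def spearman_rho(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Spearman correlation of two vectors (NaN when either is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValidationError("spearman_rho requires 1-D vectors of length >= 3")
    rx = midrank(x) - (x.size + 1) / 2.0
    ry = midrank(y) - (y.size + 1) / 2.0
    nx = np.sqrt(np.sum(rx * rx))
    ny = np.sqrt(np.sum(ry * ry))
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(np.dot(rx, ry) / (nx * ny))


def correlate_all(mirna: ExpressionMatrix, mrna: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Spearman correlation between miRNA and mRNA features.

    Both matrices must already be sample-aligned (identical ``sample_ids``
    in identical order; see :func:`mirnet.io.align_samples`). Ranks are
    computed once per feature, so the cost is O(F * n log n) ranking plus a
    single matrix product for the F_mi x F_m correlation table.

    Returns a DataFrame indexed by miRNA id with mRNA ids as columns.
    Constant features yield NaN entries (undefined rho); their count is
    logged. The sample count is stored in ``result.attrs["n_samples"]``.
    """
    if mirna.sample_ids != mrna.sample_ids:
        raise ValidationError(
            "matrices are not sample-aligned; apply align_samples first"
        )
    n = mirna.n_samples
    if n < 3:
        raise ValidationError("correlation requires >= 3 samples")

    def standardized_ranks(values: np.ndarray) -> np.ndarray:
        r = _rank_rows(values) - (n + 1) / 2.0
        norms = np.sqrt(np.sum(r * r, axis=1))
        constant = norms == 0.0
        norms[constant] = 1.0
        r /= norms[:, None]
        r[constant] = np.nan
        return r

    rm = standardized_ranks(mirna.values)
    rg = standardized_ranks(mrna.values)
    n_const = int(np.isnan(rm[:, 0]).sum() + np.isnan(rg[:, 0]).sum())
    if n_const:
        log.info("correlate_all: %d constant feature(s) yield undefined rho", n_const)
    rho = pd.DataFrame(
        rm @ rg.T, index=list(mirna.feature_ids), columns=list(mrna.feature_ids)
    )
    rho.attrs["n_samples"] = n
    return rho


@dataclass(frozen=True)
class CorrelationEdge:
    """A single miRNA-mRNA inverse-correlation association."""

    mirna_id: str
    mrna_id: str
    rho: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError(f"|rho| > 1 for edge {self.mirna_id}-{self.mrna_id}")
        if self.n < 3:
            raise ValidationError("edge sample count must be >= 3")


@dataclass
class CorrelationEdgeSet:
    """The edges surviving the inverse-correlation filter at ``rho_max``."""

    edges: list[CorrelationEdge]
    rho_max: float

    def __post_init__(self) -> None:
        pairs = set()
        for e in self.edges:
            key = (e.mirna_id, e.mrna_id)
            if key in pairs:
                raise ValidationError(f"duplicate edge {key}")
            pairs.add(key)
            if not e.rho < self.rho_max:
                raise ValidationError(
                    f"edge {key} has rho {e.rho} >= threshold {self.rho_max}"
                )

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def mirna_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.mirna_id, None)
        return list(seen)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(e.mirna_id, e.mrna_id) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.mirna_id, e.mrna_id, e.rho, e.n) for e in self.edges],
            columns=["mirna_id", "mrna_id", "rho", "n"],
        )

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_edge_set(path: str | Path, rho_max: float | None = None) -> CorrelationEdgeSet:
    """Read an edge TSV written by :meth:`CorrelationEdgeSet.write_tsv`.

    When ``rho_max`` is not given it is recovered from a ``# rho_max=...``
    header comment if present, otherwise set just above the largest stored
    rho (the loosest threshold consistent with the file).
    """
    path = Path(path)
    if rho_max is None:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for token in line[1:].replace("|", " ").split():
                    if token.startswith("rho_max="):
                        rho_max = float(token.split("=", 1)[1])
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"mirna_id", "mrna_id", "rho", "n"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    edges = [
        CorrelationEdge(str(r.mirna_id), str(r.mrna_id), float(r.rho), int(r.n))
        for r in frame.itertuples(index=False)
    ]
    if rho_max is None:
        rho_max = max((e.rho for e in edges), default=-1.0) + 1e-9
    return CorrelationEdgeSet(edges=edges, rho_max=rho_max)


def filter_inverse(
    rho: pd.DataFrame, rho_max: float, n_samples: int | None = None
) -> CorrelationEdgeSet:
    """Retain miRNA-mRNA pairs with rho strictly below ``rho_max`` (< 0).

    NaN (undefined) correlations never pass. Edge order is row-major in the
    input table, so results are deterministic for a given rho table.
    """
    if not rho_max < 0:
        raise ValidationError("rho_max must be negative (inverse-correlation contract)")
    if n_samples is None:
        n_samples = rho.attrs.get("n_samples")
    if n_samples is None:
        raise ValidationError(
            "n_samples not available; pass explicitly or use correlate_all output"
        )
    values = rho.to_numpy()
    mask = values < rho_max  # NaN compares False
    edges = []
    mirna_ids = list(rho.index)
    mrna_ids = list(rho.columns)
    for i, j in np.argwhere(mask):
        edges.append(
            CorrelationEdge(
                mirna_id=mirna_ids[i],
                mrna_id=mrna_ids[j],
                rho=float(values[i, j]),
                n=int(n_samples),
            )
        )
    log.info(
        "filter_inverse: %d/%d pairs below rho_max=%g",
        len(edges),
        values.size,
        rho_max,
    )
    return CorrelationEdgeSet(edges=edges, rho_max=rho_max)
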