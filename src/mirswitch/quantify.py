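"""Normalization and detection filtering applied before differential expression.

CPM = count / library_size * 1e6; RPKM = count / (library_size/1e6) /
(length/1e3).  Detection keeps features reaching a threshold (default 30,
inclusive) in at least one sample; an ``all``-samples rule is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import CountMatrix, SampleSheet, ValidationError

__all__ = ["ExpressionMatrix", "cpm", "rpkm", "filter_expressed"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression values (features x samples) tagged with a unit."""

    values: pd.DataFrame
    samples: SampleSheet
    unit: str  # "CPM" | "RPKM"

    def __post_init__(self) -> None:
        if self.unit not in ("CPM", "RPKM"):
            raise ValidationError(f"unit must be 'CPM' or 'RPKM', got {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million mapped reads.

    Computed on the full unfiltered matrix each sample column sums to 1e6
    (to floating tolerance) whenever the library size equals the column total.
    """
    libs = pd.Series(counts.samples.library_sizes, index=list(counts.samples.sample_ids), dtype=float)
    values = counts.counts / libs * 1e6
    return ExpressionMatrix(values, counts.samples, "CPM")


def rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads."""
    if counts.feature_lengths is None:
        raise ValidationError("RPKM requires feature lengths")
    if (counts.feature_lengths <= 0).any():
        raise ValidationError("RPKM requires positive feature lengths")
    c = cpm(counts)
    values = c.values.div(counts.feature_lengths / 1e3, axis=0)
    return ExpressionMatrix(values, counts.samples, "RPKM")


def filter_expressed(
    expr: ExpressionMatrix, threshold: float = 30.0, rule: str = "any"
) -> set[str]:
    """Feature ids meeting the detection threshold (inclusive, >=).

    ``rule='any'`` (default): threshold reached in at least one sample, the
    per-library detection reading of the study design; ``rule='all'``: in
    every sample.
    """
    if threshold < 0:
        raise ValidationError("detection threshold must be >= 0")
    if rule not in ("any", "all"):
        raise ValidationError(f"rule must be 'any' or 'all', got {rule!r}")
    mask = expr.values >= threshold
    keep = mask.any(axis=1) if rule == "any" else mask.all(axis=1)
    return set(expr.values.index[keep])
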