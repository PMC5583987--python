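"""Shared domain types and readers/writers for the pipeline's file formats.

Conventions
-----------
* All genomic coordinates are 0-based, half-open (BED-style); the length of a
  window is always ``end - start``.  The only 1-based frame in the package is
  miRNA position numbering (counted from the mature 5' end), which is confined
  to the seed-rule logic in :mod:`mirswitch.seedscan`.
* Sequences are normalized to the uppercase RNA alphabet ``{A, C, G, U}`` on
  input; DNA ``T`` is silently mapped to ``U`` because mature-miRNA databases
  and genomic PCR templates mix the two alphabets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "DEFAULT_STAGES",
    "MirswitchError",
    "ParseError",
    "ValidationError",
    "SampleSheet",
    "CountMatrix",
    "SequenceRecord",
    "GenomicWindow",
    "read_fasta",
    "write_fasta",
    "read_sample_sheet",
    "read_counts",
    "write_counts",
    "write_sites",
    "read_sites",
    "write_edges",
    "read_edges",
    "to_one_based",
]

#: Developmental stages of the study design, ordered: embryonic day 18 and 20,
#: then posthatch day 0 (pre-feeding), 1 and 3.
DEFAULT_STAGES: tuple[str, ...] = ("E18", "E20", "D0", "D1", "D3")

_RNA_ALPHABET = frozenset("ACGU")


class MirswitchError(Exception):
    """Base class for all pipeline errors."""


class ParseError(MirswitchError):
    """Malformed input file."""


class ValidationError(MirswitchError):
    """Input violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: id, developmental stage, replicate, library size.

    ``stage_order`` declares the ordered stage list; every sample's stage must
    be one of them.  Library size is the total number of mapped reads and must
    be positive (it is the CPM/RPKM denominator).
    """

    sample_ids: tuple[str, ...]
    stages: tuple[str, ...]
    replicates: tuple[int, ...]
    library_sizes: tuple[int, ...]
    stage_order: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.stages) == len(self.replicates) == len(self.library_sizes) == n):
            raise ValidationError("sample sheet columns have unequal lengths")
        if n == 0:
            raise ValidationError("sample sheet is empty")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in sample sheet")
        for s, stage in zip(self.sample_ids, self.stages):
            if stage not in self.stage_order:
                raise ValidationError(
                    f"sample {s!r} has stage {stage!r} not in declared order {self.stage_order}"
                )
        for s, rep in zip(self.sample_ids, self.replicates):
            if rep < 1:
                raise ValidationError(f"sample {s!r} has non-positive replicate {rep}")
        for s, lib in zip(self.sample_ids, self.library_sizes):
            if lib <= 0:
                raise ValidationError(f"sample {s!r} has non-positive library size {lib}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def samples_for_stage(self, stage: str) -> list[str]:
        if stage not in self.stage_order:
            raise ValidationError(f"unknown stage {stage!r}")
        return [s for s, st in zip(self.sample_ids, self.stages) if st == stage]

    @property
    def library_size_by_sample(self) -> dict[str, int]:
        return dict(zip(self.sample_ids, self.library_sizes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "stage": self.stages,
                "replicate": self.replicates,
                "library_size": self.library_sizes,
            }
        )


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts, features x samples.

    ``counts`` is a pandas DataFrame indexed by feature id with one column per
    sample, in the sample sheet's order.  mRNA matrices additionally carry
    per-feature transcript lengths (nucleotides), required for RPKM.
    """

    counts: pd.DataFrame
    samples: SampleSheet
    feature_kind: str  # "mirna" | "mrna"
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in ("mirna", "mrna"):
            raise ValidationError(f"feature_kind must be 'mirna' or 'mrna', got {self.feature_kind!r}")
        if list(self.counts.columns) != list(self.samples.sample_ids):
            raise ValidationError("count matrix columns do not match the sample sheet")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        vals = self.counts.to_numpy()
        if vals.size and ((vals < 0).any() or (vals != vals.astype(int)).any()):
            raise ValidationError("counts must be non-negative integers")
        if self.feature_kind == "mrna":
            if self.feature_lengths is None:
                raise ValidationError("mRNA count matrix requires feature lengths (for RPKM)")
            if not self.feature_lengths.index.equals(self.counts.index):
                raise ValidationError("feature_lengths index does not match counts")
            if (self.feature_lengths <= 0).any():
                raise ValidationError("feature lengths must be positive")
        elif self.feature_lengths is not None:
            raise ValidationError("feature_lengths only apply to mRNA matrices")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = [i for i, s in enumerate(self.samples.sample_ids) if s in set(sample_ids)]
        sheet = SampleSheet(
            tuple(self.samples.sample_ids[i] for i in keep),
            tuple(self.samples.stages[i] for i in keep),
            tuple(self.samples.replicates[i] for i in keep),
            tuple(self.samples.library_sizes[i] for i in keep),
            self.samples.stage_order,
        )
        return CountMatrix(
            self.counts[list(sheet.sample_ids)], sheet, self.feature_kind, self.feature_lengths
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "CountMatrix":
        idx = [f for f in self.counts.index if f in set(feature_ids)]
        lengths = self.feature_lengths.loc[idx] if self.feature_lengths is not None else None
        return CountMatrix(self.counts.loc[idx], self.samples, self.feature_kind, lengths)


@dataclass(frozen=True)
class SequenceRecord:
    """An RNA sequence: a mature miRNA or a 3'UTR, normalized to ACGU."""

    id: str
    sequence: str
    kind: str  # "mature_mirna" | "utr3"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.sequence:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains non-ACGTU symbol(s): {sorted(bad)}"
            )
        if self.kind not in ("mature_mirna", "utr3"):
            raise ValidationError(f"unknown sequence kind {self.kind!r}")
        if self.kind == "mature_mirna" and not (18 <= len(self.sequence) <= 26):
            raise ValidationError(
                f"mature miRNA {self.id!r} length {len(self.sequence)} outside 18-26 nt"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """A 0-based half-open interval on a 3'UTR sequence."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid window [{self.start}, {self.end}) on {self.transcript_id!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicWindow") -> bool:
        return (
            self.transcript_id == other.transcript_id
            and self.start < other.end
            and other.start < self.end
        )


def to_one_based(window: GenomicWindow) -> tuple[int, int]:
    """Convert a 0-based half-open window to 1-based inclusive coordinates."""
    return window.start + 1, window.end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def normalize_rna(seq: str, record_id: str = "?") -> str:
    """Uppercase and map T->U; reject anything outside ACGTU."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValidationError(f"record {record_id!r} contains non-ACGTU symbol(s): {sorted(bad)}")
    return s


def read_fasta(path: str | Path, kind: str) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    DNA input is accepted (T mapped to U).  Order is preserved.  An empty file
    yields an empty list; an empty sequence or a symbol outside ACGTU raises.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise ParseError(f"{path}: FASTA record with empty header")
            seq = str(rec.seq)
            if not seq:
                raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
            records.append(SequenceRecord(rec.id, normalize_rna(seq, rec.id), kind))
    except ValueError as err:  # Biopython's malformed-FASTA error
        raise ParseError(f"{path}: {err}") from err
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Count tables + sample sheets
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path, stage_order: Sequence[str] = DEFAULT_STAGES) -> SampleSheet:
    """Read a tab-separated sample sheet: sample_id, stage, replicate, library_size."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    required = {"sample_id", "stage", "replicate", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing column(s) {sorted(missing)}")
    return SampleSheet(
        tuple(df["sample_id"]),
        tuple(df["stage"]),
        tuple(int(r) for r in df["replicate"]),
        tuple(int(l) for l in df["library_size"]),
        tuple(stage_order),
    )


def read_counts(
    path: str | Path,
    sample_sheet_path: str | Path,
    feature_kind: str,
    stage_order: Sequence[str] = DEFAULT_STAGES,
) -> CountMatrix:
    """Read a tab-separated count table against its sample sheet.

    First column is the feature id; a ``length`` column is required for mRNA
    tables and forbidden for miRNA tables; remaining columns must exactly
    cover the sheet's sample ids.
    """
    samples = read_sample_sheet(sample_sheet_path, stage_order)
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if "length" in df.columns:
        lengths = df["length"].astype(int)
        df = df.drop(columns=["length"])
    elif feature_kind == "mrna":
        raise ValidationError(f"{path}: mRNA count table lacks a 'length' column")
    got, want = set(df.columns), set(samples.sample_ids)
    if got != want:
        raise ValidationError(
            f"{path}: sample mismatch vs sheet (missing {sorted(want - got)}, extra {sorted(got - want)})"
        )
    df = df[list(samples.sample_ids)]
    arr = df.to_numpy()
    if arr.size and ((arr < 0).any() or (arr != arr.astype(int)).any()):
        raise ValidationError(f"{path}: counts must be non-negative integers")
    if feature_kind == "mirna":
        lengths = None
    return CountMatrix(df.astype(int), samples, feature_kind, lengths)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    if matrix.feature_lengths is not None:
        df.insert(0, "length", matrix.feature_lengths)
    df.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Site and edge tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["transcript", "start", "end", "mirna", "score", "energy", "seed_class"]
_EDGE_COLUMNS = [
    "mirna_id",
    "gene_id",
    "comparison",
    "mirna_log2fc",
    "gene_log2fc",
    "n_sites",
    "best_energy",
    "best_score",
    "rank_score",
]


def write_sites(sites: Sequence, path: str | Path, header_comment: str | None = None) -> None:
    """Write target sites as a BED-like 7-column tab-separated table.

    Coordinates are 0-based half-open.  ``sites`` are
    :class:`mirswitch.seedscan.TargetSite` objects (duck-typed here to avoid a
    circular import).  Round-trips losslessly through :func:`read_sites`.
    """
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for s in sites:
            # repr round-trips floats exactly
            fh.write(
                f"{s.transcript_id}\t{s.window.start}\t{s.window.end}\t{s.mirna_id}\t"
                f"{s.score!r}\t{s.energy!r}\t{s.seed_class}\n"
            )


def read_sites(path: str | Path) -> list:
    from .seedscan import TargetSite  # local import: seedscan depends on core_io

    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != _SITE_COLUMNS:
        raise ParseError(f"{path}: unexpected site table columns {list(df.columns)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TargetSite(
                mirna_id=str(row.mirna),
                transcript_id=str(row.transcript),
                window=GenomicWindow(str(row.transcript), int(row.start), int(row.end)),
                score=float(row.score),
                energy=float(row.energy),
                seed_class=str(row.seed_class),
            )
        )
    return out


def write_edges(edges: Sequence, path: str | Path) -> None:
    """Write reciprocal-expression edges as a tab-separated table with header."""
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_COLUMNS) + "\n")
        for e in edges:
            comparison = f"{e.comparison[0]}:{e.comparison[1]}"
            fh.write(
                f"{e.mirna_id}\t{e.gene_id}\t{comparison}\t{e.mirna_log2fc!r}\t"
                f"{e.gene_log2fc!r}\t{e.n_sites}\t{e.best_energy!r}\t"
                f"{e.best_score!r}\t{e.rank_score!r}\n"
            )


def read_edges(path: str | Path) -> list:
    from .integrate import ReciprocalEdge

    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _EDGE_COLUMNS:
        raise ParseError(f"{path}: unexpected edge table columns {list(df.columns)}")
    out = []
    for row in df.itertuples(index=False):
        a, b = str(row.comparison).split(":")
        out.append(
            ReciprocalEdge(
                mirna_id=str(row.mirna_id),
                gene_id=str(row.gene_id),
                comparison=(a, b),
                mirna_log2fc=float(row.mirna_log2fc),
                gene_log2fc=float(row.gene_log2fc),
                n_sites=int(row.n_sites),
                best_energy=float(row.best_energy),
                best_score=float(row.best_score),
                rank_score=float(row.rank_score),
            )
        )
    return out


def write_json_summary(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
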