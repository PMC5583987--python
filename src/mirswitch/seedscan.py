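"""miRNA target-site prediction in 3'UTRs.

The scan combines three gates, applied conjunctively:

1. a miRanda-style local complementarity alignment score (strictly > 130 by
   default) under the scheme WC +5, G:U +2, mismatch -3, gap open -9, gap
   extend -4, with pair scores at miRNA positions 2-8 scaled x4;
2. a nearest-neighbor duplex free energy (strictly < -16 kcal/mol by default);
3. a high-stringency seed rule — class A: miRNA nucleotides 2-8 all
   Watson-Crick paired, contiguous and gap-free; class B: nucleotides 2-7 AND
   13-16 paired, G:U wobbles tolerated, contiguous and gap-free in each span.

miRNA positions are numbered 1-based from the mature 5' end (the only 1-based
frame in the package).  The duplex is antiparallel: along an alignment the
miRNA position increases while the UTR position decreases, so a target site
read 5'->3' on the mRNA is the reverse complement of the miRNA region it
pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import _stacks
from .core_io import GenomicWindow, MirswitchError, SequenceRecord, ValidationError

__all__ = [
    "PairClass",
    "AlignParams",
    "AlignedColumn",
    "DuplexAlignment",
    "TargetSite",
    "align_duplex",
    "duplex_energy",
    "seed_rule_class",
    "scan_utr",
    "count_predicted_targets",
]


class PairClass:
    """Pair categories of one alignment column."""

    WC = "WC"
    GU = "GU"
    MISMATCH = "MISMATCH"
    GAP_MIRNA = "GAP_MIRNA"  # miRNA strand gapped; target base bulged
    GAP_TARGET = "GAP_TARGET"  # target strand gapped; miRNA base bulged


_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_pair(mirna_base: str, utr_base: str) -> str:
    if _COMPLEMENT[mirna_base] == utr_base:
        return PairClass.WC
    if (mirna_base, utr_base) in (("G", "U"), ("U", "G")):
        return PairClass.GU
    return PairClass.MISMATCH


@dataclass(frozen=True)
class AlignParams:
    """miRanda v3.3-style complementarity scoring parameters.

    Pair scores at miRNA positions within ``seed_span`` (1-based, inclusive)
    are multiplied by ``seed_scale``; gap penalties are not scaled.
    """

    wc: float = 5.0
    gu: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    seed_span: tuple[int, int] = (2, 8)

    def position_scale(self, mirna_pos: int) -> float:
        lo, hi = self.seed_span
        return self.seed_scale if lo <= mirna_pos <= hi else 1.0

    def pair_score(self, mirna_pos: int, mirna_base: str, utr_base: str) -> float:
        cls = classify_pair(mirna_base, utr_base)
        base = {PairClass.WC: self.wc, PairClass.GU: self.gu, PairClass.MISMATCH: self.mismatch}[cls]
        return base * self.position_scale(mirna_pos)

    def gap_cost(self, length: int) -> float:
        if length <= 0:
            return 0.0
        return self.gap_open + self.gap_extend * (length - 1)


@dataclass(frozen=True)
class AlignedColumn:
    """One column of a duplex alignment (positions are None in gap columns)."""

    mirna_pos: int | None  # 1-based from the mature 5' end
    utr_pos: int | None  # 0-based on the UTR
    pair_class: str
    mirna_base: str | None
    utr_base: str | None


@dataclass(frozen=True)
class DuplexAlignment:
    """Best local antiparallel duplex between a miRNA and a UTR window."""

    mirna_id: str
    window: GenomicWindow
    columns: tuple[AlignedColumn, ...]
    score: float

    def __post_init__(self) -> None:
        m_prev, u_prev = None, None
        for col in self.columns:
            if col.mirna_pos is not None:
                if m_prev is not None and col.mirna_pos <= m_prev:
                    raise ValidationError("miRNA positions not strictly increasing")
                m_prev = col.mirna_pos
            if col.utr_pos is not None:
                if u_prev is not None and col.utr_pos >= u_prev:
                    raise ValidationError("UTR positions not strictly decreasing (antiparallel)")
                u_prev = col.utr_pos
        utr_positions = [c.utr_pos for c in self.columns if c.utr_pos is not None]
        if utr_positions:
            if self.window.start != min(utr_positions) or self.window.end != max(utr_positions) + 1:
                raise ValidationError("window does not cover exactly the aligned UTR positions")

    @property
    def n_gaps(self) -> int:
        return sum(
            1 for c in self.columns if c.pair_class in (PairClass.GAP_MIRNA, PairClass.GAP_TARGET)
        )

    def paired_columns(self) -> list[AlignedColumn]:
        return [c for c in self.columns if c.pair_class in (PairClass.WC, PairClass.GU)]


@dataclass(frozen=True)
class TargetSite:
    """A located, threshold-passing, seed-classified binding site."""

    mirna_id: str
    transcript_id: str
    window: GenomicWindow
    score: float
    energy: float
    seed_class: str

    def __post_init__(self) -> None:
        if self.seed_class not in ("A", "B"):
            raise ValidationError(f"target site with seed class {self.seed_class!r}")


# ---------------------------------------------------------------------------
# Local duplex alignment (Gotoh affine-gap DP on the reversed target)
# ---------------------------------------------------------------------------

_NEG = -math.inf


def align_duplex(
    mirna: SequenceRecord | str,
    utr_window: str,
    params: AlignParams = AlignParams(),
    mirna_id: str = "mirna",
    transcript_id: str = "window",
    window_offset: int = 0,
) -> DuplexAlignment | None:
    """Best local antiparallel complementarity alignment of a miRNA vs a window.

    Returns None when no positive-scoring pairing exists.  Ties on score are
    broken deterministically: prefer the smaller UTR start, then fewer gaps
    (traceback prefers pair columns over gaps).
    """
    if isinstance(mirna, SequenceRecord):
        m_seq, mirna_id = mirna.sequence, mirna.id
    else:
        m_seq = mirna
    if not m_seq or not utr_window:
        raise ValidationError("align_duplex requires non-empty sequences")

    M, N = len(m_seq), len(utr_window)
    rev = utr_window[::-1]  # rev[j-1] is UTR base at original position N-j

    # H/E/F Gotoh matrices, (M+1) x (N+1); local alignment (floor at 0 in H)
    H = [[0.0] * (N + 1) for _ in range(M + 1)]
    E = [[_NEG] * (N + 1) for _ in range(M + 1)]  # gap in target (miRNA bulge)
    F = [[_NEG] * (N + 1) for _ in range(M + 1)]  # gap in miRNA (target bulge)
    ptr = [[0] * (N + 1) for _ in range(M + 1)]  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = [[0] * (N + 1) for _ in range(M + 1)]  # 1 open-from-H, 2 extend
    ptrF = [[0] * (N + 1) for _ in range(M + 1)]

    go, ge = params.gap_open, params.gap_extend
    best, best_cells = 0.0, []
    for i in range(1, M + 1):
        mi = m_seq[i - 1]
        row_ps = params.position_scale(i)
        for j in range(1, N + 1):
            e_open, e_ext = H[i - 1][j] + go, E[i - 1][j] + ge
            if e_open >= e_ext:
                E[i][j], ptrE[i][j] = e_open, 1
            else:
                E[i][j], ptrE[i][j] = e_ext, 2
            f_open, f_ext = H[i][j - 1] + go, F[i][j - 1] + ge
            if f_open >= f_ext:
                F[i][j], ptrF[i][j] = f_open, 1
            else:
                F[i][j], ptrF[i][j] = f_ext, 2
            uj = rev[j - 1]
            cls = classify_pair(mi, uj)
            base = params.wc if cls == PairClass.WC else params.gu if cls == PairClass.GU else params.mismatch
            diag = H[i - 1][j - 1] + base * row_ps
            h, p = 0.0, 0
            if diag > h:
                h, p = diag, 1
            if E[i][j] > h:
                h, p = E[i][j], 2
            if F[i][j] > h:
                h, p = F[i][j], 3
            H[i][j], ptr[i][j] = h, p
            if h > best + 1e-12:
                best, best_cells = h, [(i, j)]
            elif best > 0 and abs(h - best) <= 1e-12:
                best_cells.append((i, j))

    if best <= 0:
        return None

    # tie-break 1: smaller original-UTR start == larger reversed index j at the
    # alignment end; among those, smaller i (shorter miRNA extent, fewer gaps
    # downstream); traceback itself prefers pairs over gaps (fewer gaps).
    best_cells.sort(key=lambda c: (-c[1], c[0]))
    i, j = best_cells[0]

    cols_rev: list[AlignedColumn] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptr[i][j]
            if p == 0:
                break
            if p == 1:
                mb, ub = m_seq[i - 1], rev[j - 1]
                cols_rev.append(
                    AlignedColumn(i, N - j + window_offset, classify_pair(mb, ub), mb, ub)
                )
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols_rev.append(AlignedColumn(i, None, PairClass.GAP_TARGET, m_seq[i - 1], None))
            if ptrE[i][j] == 1:
                state = "H"
            i -= 1
        else:  # F
            cols_rev.append(AlignedColumn(None, N - j + window_offset, PairClass.GAP_MIRNA, None, rev[j - 1]))
            if ptrF[i][j] == 1:
                state = "H"
            j -= 1

    columns = tuple(reversed(cols_rev))
    utr_positions = [c.utr_pos for c in columns if c.utr_pos is not None]
    window = GenomicWindow(transcript_id, min(utr_positions), max(utr_positions) + 1)
    return DuplexAlignment(mirna_id, window, columns, best)


# ---------------------------------------------------------------------------
# Duplex free energy
# ---------------------------------------------------------------------------


def _is_terminal_penalized(col: AlignedColumn) -> bool:
    return (col.mirna_base, col.utr_base) not in (("G", "C"), ("C", "G"))


def duplex_energy(alignment: DuplexAlignment) -> float:
    """Nearest-neighbor free energy (kcal/mol) of an aligned duplex.

    Sum of stacking terms over maximal runs of consecutive paired columns
    (WC or G:U), plus duplex initiation (+4.09), a terminal penalty (+0.45)
    per helix end closed by an A:U or G:U pair, and a fixed destabilization
    (+3.0) per internal interruption (each maximal mismatch/gap run between
    two helix segments).  More negative is more stable.
    """
    cols = alignment.columns
    paired_flags = [c.pair_class in (PairClass.WC, PairClass.GU) for c in cols]
    if not any(paired_flags):
        raise MirswitchError("alignment has no paired positions")

    dg = _stacks.INITIATION
    # helix segments: maximal runs of paired columns
    segments: list[list[AlignedColumn]] = []
    run: list[AlignedColumn] = []
    for col, flag in zip(cols, paired_flags):
        if flag:
            run.append(col)
        elif run:
            segments.append(run)
            run = []
    if run:
        segments.append(run)

    for seg in segments:
        for a, b in zip(seg, seg[1:]):
            dg += _stacks.stack_energy((a.mirna_base, a.utr_base), (b.mirna_base, b.utr_base))
        if _is_terminal_penalized(seg[0]):
            dg += _stacks.TERMINAL_AU_GU
        if _is_terminal_penalized(seg[-1]):
            dg += _stacks.TERMINAL_AU_GU

    # interruptions: maximal non-paired runs strictly between helix segments
    first = paired_flags.index(True)
    last = len(cols) - 1 - paired_flags[::-1].index(True)
    in_gap = False
    for flag in paired_flags[first : last + 1]:
        if not flag and not in_gap:
            dg += _stacks.INTERRUPTION
            in_gap = True
        elif flag:
            in_gap = False
    return dg


# ---------------------------------------------------------------------------
# Seed rules
# ---------------------------------------------------------------------------


def _span_ok(
    by_pos: dict[int, AlignedColumn], lo: int, hi: int, allowed: tuple[str, ...]
) -> bool:
    """Positions lo..hi all paired with allowed classes, contiguous, gap-free."""
    prev_utr = None
    for pos in range(lo, hi + 1):
        col = by_pos.get(pos)
        if col is None or col.pair_class not in allowed or col.utr_pos is None:
            return False
        if prev_utr is not None and col.utr_pos != prev_utr - 1:
            return False  # a bulged target base interrupts the span
        prev_utr = col.utr_pos
    return True


def seed_rule_class(
    alignment: DuplexAlignment, mirna: SequenceRecord | None = None, wobble_scope: str = "both"
) -> str:
    """Classify an alignment under the high-stringency seed rules.

    Class A: miRNA nt 2-8 all WC-paired, contiguous, no gaps.  Class B: nt 2-7
    and nt 13-16 all paired with WC or G:U, contiguous, no gaps in either
    span.  A takes precedence.  ``wobble_scope='3p'`` restricts rule-B wobble
    tolerance to the nt 13-16 span (nt 2-7 then WC-only); the default 'both'
    allows G:U in both spans.
    """
    if wobble_scope not in ("both", "3p"):
        raise ValidationError(f"wobble_scope must be 'both' or '3p', got {wobble_scope!r}")
    by_pos = {c.mirna_pos: c for c in alignment.columns if c.mirna_pos is not None}
    if _span_ok(by_pos, 2, 8, (PairClass.WC,)):
        return "A"
    seed_allowed = (PairClass.WC, PairClass.GU) if wobble_scope == "both" else (PairClass.WC,)
    if _span_ok(by_pos, 2, 7, seed_allowed) and _span_ok(by_pos, 13, 16, (PairClass.WC, PairClass.GU)):
        return "B"
    return "NONE"


# ---------------------------------------------------------------------------
# UTR scanning
# ---------------------------------------------------------------------------

#: extra UTR bases on each side of a seed anchor when extending to a full window
_ANCHOR_SLACK = 8


def _pairs_with(mirna_base: str, utr_base: str, allow_gu: bool) -> bool:
    cls = classify_pair(mirna_base, utr_base)
    return cls == PairClass.WC or (allow_gu and cls == PairClass.GU)


def _anchor_starts(m_seq: str, utr_seq: str, allow_gu: bool) -> list[int]:
    """UTR start positions whose 6-mer pairs miRNA nt 2-7 antiparallel.

    In an antiparallel duplex the UTR base at anchor offset k pairs miRNA
    position 7-k, i.e. the anchor read 5'->3' is the (reverse) complement of
    the seed.  Every class-A or class-B site contains such an anchor, so
    anchor enumeration cannot miss a reportable site.
    """
    out = []
    for p in range(len(utr_seq) - 5):
        if all(_pairs_with(m_seq[7 - k - 1], utr_seq[p + k], allow_gu) for k in range(6)):
            out.append(p)
    return out


def scan_utr(
    mirna: SequenceRecord,
    utr: SequenceRecord,
    score_threshold: float = 130.0,
    energy_threshold: float = -16.0,
    wobble_scope: str = "both",
    params: AlignParams = AlignParams(),
) -> list[TargetSite]:
    """Predict target sites of one miRNA in one 3'UTR.

    Candidate regions are located by seed anchors, each is aligned with the
    full local DP, and candidates must pass score (strictly >), free energy
    (strictly <) and carry seed class A or B.  Overlapping candidates are
    resolved greedily by descending score; the result is sorted by window
    start.
    """
    if len(utr.sequence) < 7:
        return []
    m_seq, u_seq = mirna.sequence, utr.sequence
    allow_gu = wobble_scope == "both"
    L = len(m_seq)

    candidates: list[tuple[TargetSite, DuplexAlignment]] = []
    seen_windows: set[tuple[int, int]] = set()
    for p in _anchor_starts(m_seq, u_seq, allow_gu):
        w_start = max(0, p - (L + _ANCHOR_SLACK))
        w_end = min(len(u_seq), p + 6 + 1 + _ANCHOR_SLACK)
        aln = align_duplex(
            m_seq,
            u_seq[w_start:w_end],
            params,
            mirna_id=mirna.id,
            transcript_id=utr.id,
            window_offset=w_start,
        )
        if aln is None:
            continue
        key = (aln.window.start, aln.window.end)
        if key in seen_windows:
            continue
        seen_windows.add(key)
        cls = seed_rule_class(aln, mirna, wobble_scope)
        if cls == "NONE":
            continue
        energy = duplex_energy(aln)
        if aln.score > score_threshold and energy < energy_threshold:
            site = TargetSite(mirna.id, utr.id, aln.window, aln.score, energy, cls)
            candidates.append((site, aln))

    # greedy non-overlap selection by descending score, then alignment tie-break
    candidates.sort(key=lambda ca: (-ca[0].score, ca[0].window.start, ca[1].n_gaps))
    chosen: list[TargetSite] = []
    for site, _ in candidates:
        if not any(site.window.overlaps(s.window) for s in chosen):
            chosen.append(site)
    chosen.sort(key=lambda s: s.window.start)
    return chosen


def count_predicted_targets(
    mirnas: Sequence[SequenceRecord],
    utrs: Sequence[SequenceRecord],
    annotation: Mapping[str, Iterable[str]],
    transcript_to_gene: Mapping[str, str] | None = None,
    **scan_kwargs,
) -> pd.DataFrame:
    """Count distinct predicted target genes per (miRNA, function category).

    ``annotation`` maps gene ids to zero or more category labels; a gene with
    sites counts once in every category it belongs to.  Returns a DataFrame
    indexed by miRNA id with one column per category (all annotation
    categories appear, zero-filled).
    """
    categories = sorted({c for cats in annotation.values() for c in cats})
    genes_hit: dict[str, set[str]] = {m.id: set() for m in mirnas}
    for m in mirnas:
        for u in utrs:
            if scan_utr(m, u, **scan_kwargs):
                gene = transcript_to_gene.get(u.id, u.id) if transcript_to_gene else u.id
                genes_hit[m.id].add(gene)
    table = pd.DataFrame(0, index=[m.id for m in mirnas], columns=categories, dtype=int)
    for mid, genes in genes_hit.items():
        for g in genes:
            for cat in annotation.get(g, ()):
                table.loc[mid, cat] += 1
    table.index.name = "mirna"
    return table
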