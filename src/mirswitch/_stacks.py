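"""Nearest-neighbor RNA/RNA stacking free energies (ΔG°37, kcal/mol).

Watson-Crick/Watson-Crick stacks use the standard 10-parameter table
(Xia et al. 1998, as adopted in the Turner 2004 rule set).  Stacks involving
G:U wobble pairs use a deliberately simplified 3-level approximation keyed on
the strength of the neighbouring pair; the duplex model in this package is a
helix-stack sum without loop thermodynamics, so wobble stacks only need to be
qualitatively right (weaker than WC, still stabilizing, tandem wobbles
weakest).  See docs/methods.md for the discussion of this approximation.

A stack is keyed by its two base pairs read 5'->3' along the miRNA strand:
``((m1, t1), (m2, t2))`` for the duplex fragment::

    5'-m1 m2-3'   (miRNA)
    3'-t1 t2-5'   (target)
"""

from __future__ import annotations

#: duplex initiation ΔG°37 (kcal/mol)
INITIATION = 4.09

#: penalty per helix end closed by an A:U or G:U pair
TERMINAL_AU_GU = 0.45

#: destabilization per internal interruption (mismatch/bulge run) of a helix
INTERRUPTION = 3.0

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}

# 5'XY3'/3'WZ5' entries as (X, Y, W, Z): pairs X:W and Y:Z.
_WC_TABLE = [
    ("A", "A", "U", "U", -0.93),
    ("A", "U", "U", "A", -1.10),
    ("U", "A", "A", "U", -1.33),
    ("C", "U", "G", "A", -2.08),
    ("C", "A", "G", "U", -2.11),
    ("G", "U", "C", "A", -2.24),
    ("G", "A", "C", "U", -2.35),
    ("C", "G", "G", "C", -2.36),
    ("G", "G", "C", "C", -3.26),
    ("G", "C", "C", "G", -3.42),
]


def _build_wc_stacks() -> dict:
    stacks: dict[tuple, float] = {}
    for x, y, w, z, dg in _WC_TABLE:
        stacks[((x, w), (y, z))] = dg
        # same physical stack read from the opposite strand
        stacks[((z, y), (w, x))] = dg
    return stacks


WC_STACKS = _build_wc_stacks()


def is_wc(pair: tuple[str, str]) -> bool:
    return pair in _WC_PAIRS


def is_gu(pair: tuple[str, str]) -> bool:
    return pair in _GU_PAIRS


def stack_energy(pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
    """ΔG°37 of stacking ``pair2`` on ``pair1`` (5'->3' on the miRNA strand)."""
    key = (pair1, pair2)
    if key in WC_STACKS:
        return WC_STACKS[key]
    gu1, gu2 = is_gu(pair1), is_gu(pair2)
    if not (gu1 or gu2):
        raise ValueError(f"not a stackable pair combination: {pair1}, {pair2}")
    if gu1 and gu2:
        return -0.5
    other = pair2 if gu1 else pair1
    if other in (("G", "C"), ("C", "G")):
        return -1.5
    return -1.0
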