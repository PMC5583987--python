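"""Reciprocal-expression regulatory networks and reporter-assay helpers.

A regulatory edge miRNA -> gene requires, within one stage comparison:
both features significantly differentially expressed, opposite-direction
log2 fold changes, and at least one predicted target site.  Candidate edges
are ranked by a weighted combination of the selection criteria used for
validation: duplex thermodynamics, inverse-expression magnitude, site count,
and a binary metabolic-function annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import MirswitchError, ValidationError, write_edges, write_json_summary
from .diffexp import DEResult
from .seedscan import TargetSite

__all__ = [
    "ReciprocalEdge",
    "ReporterMeasurement",
    "reciprocal_pairs",
    "rank_targets",
    "normalized_luciferase",
    "repression_test",
    "export_network",
]


@dataclass(frozen=True)
class ReciprocalEdge:
    """miRNA -> gene edge supported by opposite DE plus >= 1 predicted site."""

    mirna_id: str
    gene_id: str
    comparison: tuple[str, str]
    mirna_log2fc: float
    gene_log2fc: float
    n_sites: int
    best_energy: float
    best_score: float
    rank_score: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("edge requires at least one predicted site")
        if self.mirna_log2fc * self.gene_log2fc >= 0:
            raise ValidationError("edge requires opposite-direction fold changes")


@dataclass(frozen=True)
class ReporterMeasurement:
    """One dual-luciferase well: Renilla (targeted) over firefly (control)."""

    construct_id: str
    condition: str  # "mirna" | "scrambled_control"
    renilla: float
    firefly: float

    def __post_init__(self) -> None:
        if self.condition not in ("mirna", "scrambled_control"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.firefly <= 0:
            raise ValidationError("firefly signal must be > 0")

    @property
    def normalized(self) -> float:
        return self.renilla / self.firefly


def reciprocal_pairs(
    de_mirna: Sequence[DEResult],
    de_mrna: Sequence[DEResult],
    sites: Sequence[TargetSite],
    comparison: tuple[str, str],
    transcript_to_gene: Mapping[str, str] | None = None,
) -> list[ReciprocalEdge]:
    """Build reciprocal-expression edges for one stage comparison.

    One edge per (miRNA, gene) with both features significant in the
    comparison, opposite log2FC signs, and >= 1 predicted site; ``n_sites``
    counts the passing sites across all of the gene's transcripts.
    """
    comparison = tuple(comparison)
    for r in list(de_mirna) + list(de_mrna):
        if tuple(r.comparison) != comparison:
            raise MirswitchError(
                f"DE result for {r.feature_id} has comparison {r.comparison}, expected {comparison}"
            )
    tx2gene = dict(transcript_to_gene) if transcript_to_gene else {}
    sig_mirna = {r.feature_id: r for r in de_mirna if r.significant}
    sig_gene = {r.feature_id: r for r in de_mrna if r.significant}

    by_pair: dict[tuple[str, str], list[TargetSite]] = {}
    for s in sites:
        gene = tx2gene.get(s.transcript_id, s.transcript_id)
        by_pair.setdefault((s.mirna_id, gene), []).append(s)

    edges = []
    for (mirna_id, gene_id), pair_sites in sorted(by_pair.items()):
        rm = sig_mirna.get(mirna_id)
        rg = sig_gene.get(gene_id)
        if rm is None or rg is None:
            continue
        if rm.log2fc * rg.log2fc >= 0:
            continue
        edges.append(
            ReciprocalEdge(
                mirna_id=mirna_id,
                gene_id=gene_id,
                comparison=comparison,
                mirna_log2fc=rm.log2fc,
                gene_log2fc=rg.log2fc,
                n_sites=len(pair_sites),
                best_energy=min(s.energy for s in pair_sites),
                best_score=max(s.score for s in pair_sites),
            )
        )
    return edges


def rank_targets(
    edges: Sequence[ReciprocalEdge],
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    metabolic_genes: Iterable[str] | None = None,
) -> list[ReciprocalEdge]:
    """Rank candidate edges by the weighted selection criteria.

    rank_score = w1 * minmax(-best_energy) + w2 * |gene_log2fc| +
    w3 * n_sites + w4 * metabolic-annotation flag.  Stable descending sort;
    ties broken by gene id.  The weighted combination itself is a pipeline
    convention (the selection criteria are qualitative); weights default to 1
    and are recorded on the returned edges.
    """
    if not edges:
        raise MirswitchError("rank_targets requires at least one edge")
    if any(w < 0 for w in weights):
        raise ValidationError("rank weights must be non-negative")
    metabolic = set(metabolic_genes) if metabolic_genes else set()
    stability = np.array([-e.best_energy for e in edges], dtype=float)
    lo, hi = stability.min(), stability.max()
    scaled = (stability - lo) / (hi - lo) if hi > lo else np.zeros_like(stability)
    w1, w2, w3, w4 = weights
    ranked = [
        ReciprocalEdge(
            e.mirna_id, e.gene_id, e.comparison, e.mirna_log2fc, e.gene_log2fc,
            e.n_sites, e.best_energy, e.best_score,
            rank_score=float(
                w1 * scaled[i]
                + w2 * abs(e.gene_log2fc)
                + w3 * e.n_sites
                + w4 * (e.gene_id in metabolic)
            ),
        )
        for i, e in enumerate(edges)
    ]
    # stable: equal (-rank_score, gene_id) keys preserve input order
    return sorted(ranked, key=lambda e: (-e.rank_score, e.gene_id))


def normalized_luciferase(renilla: float, firefly: float) -> float:
    """Renilla/firefly signal ratio (firefly normalizes transfection)."""
    if firefly <= 0:
        raise ValidationError("firefly signal must be > 0")
    return renilla / firefly


def repression_test(
    mirna_ratios: Sequence[float],
    control_ratios: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """One-way ANOVA (two groups) on normalized reporter ratios.

    Repression is called iff p < alpha AND the miRNA-condition mean is below
    the scrambled-control mean (direction gate).
    """
    m = np.asarray(mirna_ratios, dtype=float)
    c = np.asarray(control_ratios, dtype=float)
    if len(m) < 2 or len(c) < 2:
        raise MirswitchError("repression_test requires >= 2 replicates per condition")
    if np.allclose(m.mean(), c.mean()) and np.allclose(m.var(), c.var()):
        return 1.0, False
    f, p = stats.f_oneway(m, c)
    if np.isnan(p):
        p = 1.0
    repressed = bool(p < alpha and m.mean() < c.mean())
    return float(p), repressed


def export_network(edges: Sequence[ReciprocalEdge], path, summary_path=None) -> dict:
    """Write the edge list (TSV) and a JSON summary; return the summary.

    Every exported edge is re-checked against the sign and site invariants
    (they are enforced at construction; this is the last line of defense
    before data leaves the pipeline).
    """
    for e in edges:
        assert e.n_sites >= 1 and e.mirna_log2fc * e.gene_log2fc < 0
    write_edges(edges, path)
    per_mirna: dict[str, int] = {}
    for e in edges:
        per_mirna[e.mirna_id] = per_mirna.get(e.mirna_id, 0) + 1
    summary = {
        "n_edges": len(edges),
        "n_mirnas": len({e.mirna_id for e in edges}),
        "n_genes": len({e.gene_id for e in edges}),
        "targets_per_mirna": dict(sorted(per_mirna.items())),
    }
    if summary_path is not None:
        write_json_summary(summary, summary_path)
    return summary
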