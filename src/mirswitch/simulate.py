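"""Synthetic-data generator with known ground truth.

Emulates the study design: five developmental stages (E18, E20, D0, D1, D3),
four mRNA replicate libraries per stage, one pooled miRNA library per stage,
negative-binomial counts (Var = mu + phi*mu^2) with planted fold changes on a
log2 grid spanning ~2-fold to ~700-fold, and random-uniform 3'UTR sequences
with planted binding sites of both high-stringency seed classes.

All outputs are pure functions of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_STAGES,
    CountMatrix,
    GenomicWindow,
    SampleSheet,
    SequenceRecord,
    ValidationError,
)
from .seedscan import reverse_complement

__all__ = [
    "PlantedEffect",
    "PlantedSiteSpec",
    "PlantedSite",
    "SimulationDesign",
    "SimulationTruth",
    "LET7C",
    "default_mirnas",
    "simulate_counts",
    "simulate_utrs",
    "demo_design",
    "DEFAULT_LOG2FC_GRID",
]

#: mature gga-let-7c, the reference miRNA of the worked examples
LET7C = "UGAGGUAGUAGGUUGUAUGGUU"

#: default planted effect-size grid (log2 fold changes); spans 2-fold to
#: ~700-fold, the range of the hepatic switch (FASN 182x, SCD 665x, FADS2 >700x)
DEFAULT_LOG2FC_GRID: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.45)


@dataclass(frozen=True)
class PlantedEffect:
    """A planted differential-expression effect between two stages."""

    feature_id: str
    stage_a: str
    stage_b: str
    log2fc: float  # b over a


@dataclass(frozen=True)
class PlantedSiteSpec:
    """Request to plant ``count`` binding sites of one miRNA in one UTR."""

    mirna_id: str
    transcript_id: str
    seed_class: str  # "A" | "B"
    count: int = 1
    n_wobble: int = 1  # G:U pairs placed in the nt 13-16 span of class-B sites

    def __post_init__(self) -> None:
        if self.seed_class not in ("A", "B"):
            raise ValidationError(f"seed_class must be 'A' or 'B', got {self.seed_class!r}")
        if self.count < 0:
            raise ValidationError("count must be >= 0")


@dataclass(frozen=True)
class PlantedSite:
    """Registry entry for one planted site (exact window, known class)."""

    transcript_id: str
    mirna_id: str
    seed_class: str
    window: GenomicWindow


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of a synthetic study.

    ``baseline_range`` is in CPM-like units (expected count at a library of
    1e6 reads), drawn log-uniform; the default [30, 5000] keeps features above
    the detection thresholds so tests exercise the DE logic rather than
    detection edge cases.  ``dispersion`` is the NB overdispersion phi per
    feature kind (Var = mu + phi*mu^2); phi=0 gives Poisson counts.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates: Mapping[str, int] = field(default_factory=lambda: {"mrna": 4, "mirna": 1})
    n_features: Mapping[str, int] = field(default_factory=lambda: {"mrna": 2000, "mirna": 100})
    baseline_range: tuple[float, float] = (30.0, 5000.0)
    dispersion: Mapping[str, float] = field(default_factory=lambda: {"mrna": 0.1, "mirna": 0.02})
    library_size: Mapping[str, int] = field(
        default_factory=lambda: {"mrna": 1_000_000, "mirna": 1_400_000}
    )
    length_range: tuple[int, int] = (500, 3000)
    utr_length: int = 500
    planted_de: tuple[PlantedEffect, ...] = ()
    planted_sites: tuple[PlantedSiteSpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for kind, phi in self.dispersion.items():
            if phi < 0:
                raise ValidationError(f"dispersion for {kind} must be >= 0, got {phi}")
        for kind, lib in self.library_size.items():
            if lib <= 0:
                raise ValidationError(f"library size for {kind} must be > 0")
        for eff in self.planted_de:
            for st in (eff.stage_a, eff.stage_b):
                if st not in self.stages:
                    raise ValidationError(f"planted effect references unknown stage {st!r}")

    def feature_ids(self, kind: str) -> list[str]:
        prefix = "gene" if kind == "mrna" else "mir-syn"
        return [f"{prefix}{i:04d}" for i in range(self.n_features[kind])]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study."""

    stage_means: dict[str, pd.DataFrame]  # kind -> features x stages, CPM units
    planted_de: tuple[PlantedEffect, ...]
    planted_sites: list[PlantedSite] = field(default_factory=list)

    def de_features(self, kind_features: Sequence[str], stage_a: str, stage_b: str) -> set[str]:
        """Planted-DE feature ids among ``kind_features`` for one comparison."""
        pool = set(kind_features)
        return {
            e.feature_id
            for e in self.planted_de
            if e.feature_id in pool and {e.stage_a, e.stage_b} == {stage_a, stage_b}
        }


def default_mirnas(design: SimulationDesign, rng: np.random.Generator) -> list[SequenceRecord]:
    """Mature miRNA panel: gga-let-7c plus random 22-nt synthetic miRNAs."""
    ids = _mirna_feature_ids(design)  # first panel member is gga-let-7c
    records = [SequenceRecord(ids[0], LET7C, "mature_mirna")] if ids else []
    for fid in ids[1:]:
        seq = "".join(rng.choice(list("ACGU"), size=22))
        records.append(SequenceRecord(fid, seq, "mature_mirna"))
    return records


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _stage_mean_table(
    design: SimulationDesign, features: Sequence[str], baselines: np.ndarray
) -> pd.DataFrame:
    """Per-feature per-stage expected CPM, applying planted fold changes.

    A planted effect (a, b, lfc) anchors the feature's baseline at whichever
    of the two stages is the more highly expressed and places the other at
    baseline / 2^|lfc|, with geometric interpolation at stages in between —
    a smooth developmental trajectory.  Anchoring the high side keeps
    absolute abundances inside the baseline range however large the fold
    change (the switch genes go from barely detectable to high, not from
    typical to astronomically high).
    """
    means = pd.DataFrame(
        np.tile(baselines[:, None], (1, len(design.stages))),
        index=list(features),
        columns=list(design.stages),
    )
    stage_idx = {s: i for i, s in enumerate(design.stages)}
    for eff in design.planted_de:
        if eff.feature_id not in means.index:
            continue
        ia, ib = stage_idx[eff.stage_a], stage_idx[eff.stage_b]
        lfc = eff.log2fc
        if ia > ib:
            ia, ib = ib, ia
            lfc = -lfc
        base = means.at[eff.feature_id, design.stages[ia]]
        # mean at the earlier stage so that the higher of the two equals base
        start = base if lfc <= 0 else base / 2.0**lfc
        for j, stage in enumerate(design.stages):
            if j <= ia:
                frac = 0.0
            elif j >= ib:
                frac = 1.0
            else:
                frac = (j - ia) / (ib - ia)
            means.at[eff.feature_id, stage] = start * 2.0 ** (lfc * frac)
    return means


def _draw_nb(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def _mirna_feature_ids(design: SimulationDesign) -> list[str]:
    ids = design.feature_ids("mirna")
    if ids:
        ids[0] = "gga-let-7c"
    return ids


def simulate_counts(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[dict[str, CountMatrix], SimulationTruth]:
    """Draw NB count matrices for both feature kinds, with known truth.

    Counts for a sample at stage s are NB with mean = stage_mean_cpm *
    library_size/1e6 and the kind's dispersion.  Identical (design, seed)
    yields identical output.
    """
    if rng is None:
        rng = np.random.default_rng(design.rng_seed)
    lo, hi = design.baseline_range
    matrices: dict[str, CountMatrix] = {}
    stage_means: dict[str, pd.DataFrame] = {}
    for kind in ("mrna", "mirna"):
        n = design.n_features[kind]
        features = design.feature_ids(kind) if kind == "mrna" else _mirna_feature_ids(design)
        baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        # planted features get a floor so they stay comfortably detected;
        # planted miRNAs sit higher: the study's validated regulators are
        # abundant hepatic miRNAs, and pooled n=1 libraries need the counts
        planted = {e.feature_id for e in design.planted_de}
        floor = 100.0 if kind == "mrna" else 500.0
        for i, fid in enumerate(features):
            if fid in planted:
                baselines[i] = max(baselines[i], floor)
        means = _stage_mean_table(design, features, baselines)
        stage_means[kind] = means

        reps = design.replicates[kind]
        lib = design.library_size[kind]
        sample_ids, stages_col, rep_col, lib_col, cols = [], [], [], [], []
        for stage in design.stages:
            for r in range(1, reps + 1):
                sid = f"{kind}_{stage}_r{r}"
                sample_ids.append(sid)
                stages_col.append(stage)
                rep_col.append(r)
                lib_col.append(lib)
                mu = means[stage].to_numpy() * (lib / 1e6)
                cols.append(_draw_nb(rng, mu, design.dispersion[kind]))
        counts = pd.DataFrame(
            np.column_stack(cols), index=features, columns=sample_ids, dtype=int
        )
        sheet = SampleSheet(
            tuple(sample_ids), tuple(stages_col), tuple(rep_col), tuple(lib_col), design.stages
        )
        lengths = None
        if kind == "mrna":
            llo, lhi = design.length_range
            lengths = pd.Series(
                np.exp(rng.uniform(np.log(llo), np.log(lhi), size=n)).astype(int),
                index=features,
                name="length",
            )
        matrices[kind] = CountMatrix(counts, sheet, kind, lengths)
    truth = SimulationTruth(stage_means, design.planted_de)
    return matrices, truth


# ---------------------------------------------------------------------------
# UTRs with planted sites
# ---------------------------------------------------------------------------

_GU_PARTNER = {"G": "U", "U": "G"}
_ALPHABET = ("A", "C", "G", "U")


_WC_PARTNER = {"A": "U", "C": "G", "G": "C", "U": "A"}


def _non_pairing_bases(mirna_base: str) -> list[str]:
    return [
        b
        for b in _ALPHABET
        if b != _WC_PARTNER[mirna_base] and b != _GU_PARTNER.get(mirna_base)
    ]


def _site_sequence(
    mirna_seq: str, seed_class: str, n_wobble: int, rng: np.random.Generator
) -> str:
    """Target-site sequence (mRNA sense, 5'->3') for one planted site.

    Class A: exact reverse complement of the full miRNA.  Class B: reverse
    complement with the pairing of miRNA nt 8 broken (so rule A fails) and up
    to ``n_wobble`` G:U wobbles substituted in the nt 13-16 span.  Site index
    L-k holds the base opposite miRNA position k.

    Class-B candidates are verified against the aligner before they are
    accepted: a naively broken position 8 can be rescued by a shifted,
    slipped register (helped by sequence self-similarity around the seed
    junction) whose best alignment interrupts a required span and classifies
    NONE.  The preferred break is therefore a G:U wobble at position 8 —
    full pairing is kept, so no alternative register can outscore it — with
    mismatch breaks (progressively insulated against slippage by also
    de-pairing the bases opposite nt 9 and 10, which rule B leaves free)
    as the fallback for miRNAs whose position 8 is A or C.
    """
    from .seedscan import align_duplex, duplex_energy, seed_rule_class

    L = len(mirna_seq)
    template = list(reverse_complement(mirna_seq))
    if seed_class == "A":
        return "".join(template)

    wobble_positions = [k for k in range(13, min(16, L) + 1) if mirna_seq[k - 1] in _GU_PARTNER]
    rng.shuffle(wobble_positions)
    for k in wobble_positions[:n_wobble]:
        template[L - k] = _GU_PARTNER[mirna_seq[k - 1]]

    def candidates():
        m8 = mirna_seq[7]
        if m8 in _GU_PARTNER:  # wobble break: not class A, nothing to slip
            site = list(template)
            site[L - 8] = _GU_PARTNER[m8]
            yield site
        breaks = _non_pairing_bases(m8)
        # prefer break bases that cannot pair the neighbours either
        neigh = {mirna_seq[6], m8, mirna_seq[8]}
        breaks.sort(key=lambda b: sum(b in (_WC_PARTNER[x], _GU_PARTNER.get(x)) for x in neigh))
        for b in breaks:
            site = list(template)
            site[L - 8] = b
            yield site
        # insulate against register slippage: de-pair nt 9 (and then 10) too
        for depth in (1, 2):
            for b in breaks:
                site = list(template)
                site[L - 8] = b
                ok = True
                for k in range(9, 9 + depth):
                    near = {mirna_seq[k - 2], mirna_seq[k - 1], mirna_seq[k]}
                    free = [
                        c for c in _ALPHABET
                        if all(c != _WC_PARTNER[x] and c != _GU_PARTNER.get(x) for x in near)
                    ]
                    if not free:
                        ok = False
                        break
                    site[L - k] = free[int(rng.integers(len(free)))]
                if ok:
                    yield site

    for site in candidates():
        seq = "".join(site)
        aln = align_duplex(mirna_seq, seq)
        if (
            aln is not None
            and seed_rule_class(aln) == "B"
            and aln.score > 130.0
            and duplex_energy(aln) < -16.0
        ):
            return seq
    raise ValidationError(
        f"could not construct a class-B site for miRNA sequence {mirna_seq}"
    )


def simulate_utrs(
    mirnas: Sequence[SequenceRecord],
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
    transcript_ids: Sequence[str] | None = None,
    scrub_chance_sites: bool = True,
) -> tuple[list[SequenceRecord], list[PlantedSite]]:
    """Generate random-uniform 3'UTRs and plant the designed binding sites.

    Background composition is uniform over {A,C,G,U}, so the chance null rate
    of a class-A seed occurrence is 4^-7 per position.  Planted sites are
    inserted at non-overlapping uniform positions; the registry records their
    exact windows.  Raises if a requested site does not fit the UTR.

    With ``scrub_chance_sites`` (the default, a no-op when nothing is
    planted), a UTR whose random background happens to contain a
    threshold-passing site for one of the *planted* miRNAs is redrawn, so the
    registry is the complete ground truth for those miRNAs — without this the
    "known truth" of a clean simulation would be incomplete at a rate of
    roughly utr_length * 4^-7 chance seeds per miRNA-UTR pair.  Designs that
    plant nothing (e.g. null-rate studies) are never scrubbed.
    """
    from .seedscan import scan_utr  # deferred: seedscan does not import simulate

    if rng is None:
        rng = np.random.default_rng(design.rng_seed + 1)
    by_id = {m.id: m for m in mirnas}
    if transcript_ids is None:
        wanted = [s.transcript_id for s in design.planted_sites]
        transcript_ids = list(dict.fromkeys(wanted))
    specs_by_tx: dict[str, list[PlantedSiteSpec]] = {t: [] for t in transcript_ids}
    for spec in design.planted_sites:
        if spec.transcript_id not in specs_by_tx:
            raise ValidationError(
                f"planted site references transcript {spec.transcript_id!r} not in the UTR set"
            )
        if spec.mirna_id not in by_id:
            raise ValidationError(f"planted site references unknown miRNA {spec.mirna_id!r}")
        specs_by_tx[spec.transcript_id].append(spec)

    planted_mirnas = [by_id[mid] for mid in dict.fromkeys(s.mirna_id for s in design.planted_sites)]

    def build_one(tx: str) -> tuple[SequenceRecord, list[PlantedSite]]:
        seq = list(rng.choice(_ALPHABET, size=design.utr_length))
        occupied: list[tuple[int, int]] = []
        placed: list[PlantedSite] = []
        for spec in specs_by_tx[tx]:
            mirna = by_id[spec.mirna_id]
            for _ in range(spec.count):
                site = _site_sequence(mirna.sequence, spec.seed_class, spec.n_wobble, rng)
                if len(site) > design.utr_length:
                    raise ValidationError(
                        f"site of {spec.mirna_id} ({len(site)} nt) exceeds UTR length "
                        f"{design.utr_length}"
                    )
                for _attempt in range(200):
                    start = int(rng.integers(0, design.utr_length - len(site) + 1))
                    end = start + len(site)
                    if all(end <= s or start >= e for s, e in occupied):
                        break
                else:  # pragma: no cover - pathological overfull UTR
                    raise ValidationError(f"could not place site of {spec.mirna_id} in {tx}")
                seq[start:end] = list(site)
                occupied.append((start, end))
                placed.append(
                    PlantedSite(tx, spec.mirna_id, spec.seed_class, GenomicWindow(tx, start, end))
                )
        return SequenceRecord(tx, "".join(seq), "utr3"), placed

    def only_planted_sites(utr: SequenceRecord, placed: list[PlantedSite]) -> bool:
        for m in planted_mirnas:
            windows = [p.window for p in placed if p.mirna_id == m.id]
            for found in scan_utr(m, utr):
                if not any(found.window.overlaps(w) for w in windows):
                    return False
        return True

    utrs: list[SequenceRecord] = []
    registry: list[PlantedSite] = []
    for tx in transcript_ids:
        for _redraw in range(50):
            utr, placed = build_one(tx)
            if not (scrub_chance_sites and planted_mirnas) or only_planted_sites(utr, placed):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ValidationError(f"could not generate a chance-site-free UTR for {tx}")
        utrs.append(utr)
        registry.extend(placed)
    return utrs, registry


# ---------------------------------------------------------------------------
# Bundled end-to-end demo design
# ---------------------------------------------------------------------------


def demo_design(
    seed: int = 0,
    n_regulations: int = 10,
    n_mrna: int = 400,
    n_mirna: int = 40,
    n_utr: int = 80,
) -> tuple[SimulationDesign, list[str]]:
    """The bundled synthetic study: planted miRNA->gene regulations.

    Each regulation pairs a miRNA down-regulated >=4-fold between E18 and D3
    with a gene up-regulated >=4-fold over the same comparison and a planted
    class-A site of that miRNA in the gene's 3'UTR.  The planted regulations
    are the only DE truth (clean data): every non-edge the pipeline reports
    would be a genuine false positive.  Non-DE background genes still carry
    scanned (random) UTRs, so the site gate is exercised against chance
    matches.  Returns the design and the list of transcripts carrying UTRs.
    """
    gene_ids = [f"gene{i:04d}" for i in range(n_mrna)]
    mirna_ids = ["gga-let-7c"] + [f"mir-syn{i:04d}" for i in range(1, n_mirna)]
    reg_mirnas = mirna_ids[:n_regulations]
    reg_genes = gene_ids[:n_regulations]

    planted_de = []
    gene_lfcs = (2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 9.45)
    for i, (m, g) in enumerate(zip(reg_mirnas, reg_genes)):
        planted_de.append(PlantedEffect(m, "E18", "D3", -2.0 - (i % 3)))  # miRNA down
        planted_de.append(PlantedEffect(g, "E18", "D3", gene_lfcs[i % len(gene_lfcs)]))

    planted_sites = tuple(
        PlantedSiteSpec(m, g, "A", count=1) for m, g in zip(reg_mirnas, reg_genes)
    )
    design = SimulationDesign(
        n_features={"mrna": n_mrna, "mirna": n_mirna},
        planted_de=tuple(planted_de),
        planted_sites=planted_sites,
        rng_seed=seed,
    )
    utr_transcripts = gene_ids[:n_utr]
    return design, utr_transcripts
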