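"""End-to-end pipeline runs: config, orchestration, reproducible outputs.

``run_all`` executes simulate -> quantify -> differential expression ->
target scan -> network integration and writes every intermediate table, a
JSON run summary (with the effective config, its hash and the seed) and the
final edge list into a run directory.  Identical config + seed produce
byte-identical tables; no stage mutates another stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .core_io import (
    DEFAULT_STAGES,
    MirswitchError,
    ValidationError,
    read_counts,
    read_fasta,
    write_counts,
    write_fasta,
    write_json_summary,
    write_sites,
)
from .diffexp import de_results_frame, run_pairwise_de
from .integrate import export_network, rank_targets, reciprocal_pairs
from .quantify import cpm, filter_expressed, rpkm
from .seedscan import scan_utr
from .simulate import default_mirnas, demo_design, simulate_counts, simulate_utrs

logger = logging.getLogger("mirswitch")

DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("E18", "E20"), ("E20", "D0"), ("D0", "D1"), ("D1", "D3"), ("E18", "D3"),
)


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    All printed thresholds of the analysis live here: detection 30 (CPM for
    miRNA, RPKM for mRNA), fold-change cutoff 2, FDR 0.05, alignment score
    130, duplex energy -16 kcal/mol.  Unreplicated miRNA comparisons require
    ``mirna_fixed_dispersion``.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    network_comparison: tuple[str, str] = ("E18", "D3")
    detection_threshold: float = 30.0
    detection_rule: str = "any"
    fold_cutoff: float = 2.0
    fdr: float = 0.05
    score_threshold: float = 130.0
    energy_threshold: float = -16.0
    wobble_scope: str = "both"
    mirna_fixed_dispersion: float | None = 0.05
    rng_seed: int = 0
    simulate: bool = True
    n_regulations: int = 10
    n_mrna: int = 400
    n_mirna: int = 40
    n_utr: int = 80
    inputs: dict = field(default_factory=dict)  # paths when simulate=False

    def validate(self) -> None:
        if len(self.stages) < 2 or len(set(self.stages)) != len(self.stages):
            raise ValidationError("stages must be >= 2 distinct names")
        for a, b in self.comparisons:
            if a not in self.stages or b not in self.stages:
                raise ValidationError(f"comparison ({a}, {b}) references an undeclared stage")
        a, b = self.network_comparison
        if (a, b) not in {tuple(c) for c in self.comparisons}:
            raise ValidationError("network_comparison must be one of the comparisons")
        if self.detection_threshold < 0:
            raise ValidationError("detection threshold must be >= 0")
        if self.fold_cutoff < 1:
            raise ValidationError("fold cutoff must be >= 1")
        if not (0 < self.fdr < 1):
            raise ValidationError("fdr must lie in (0, 1)")
        if self.detection_rule not in ("any", "all"):
            raise ValidationError("detection_rule must be 'any' or 'all'")
        if self.wobble_scope not in ("both", "3p"):
            raise ValidationError("wobble_scope must be 'both' or '3p'")
        if not self.simulate:
            required = {"mirna_counts", "mirna_samples", "mrna_counts", "mrna_samples",
                        "mirna_fasta", "utr_fasta"}
            missing = required - set(self.inputs)
            if missing:
                raise ValidationError(f"inputs missing {sorted(missing)} (simulate=false)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "comparisons" in d:
            d["comparisons"] = tuple(tuple(c) for c in d["comparisons"])
        if "network_comparison" in d:
            d["network_comparison"] = tuple(d["network_comparison"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a key-value mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline into ``outdir``; return the run summary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run config hash %s, seed %d", config.config_hash(), config.rng_seed)

    stage = "simulate"
    try:
        if config.simulate:
            design, utr_transcripts = demo_design(
                seed=config.rng_seed,
                n_regulations=config.n_regulations,
                n_mrna=config.n_mrna,
                n_mirna=config.n_mirna,
                n_utr=config.n_utr,
            )
            rng = np.random.default_rng(config.rng_seed)
            matrices, truth = simulate_counts(design, rng)
            mirnas = default_mirnas(design, rng)
            utrs, registry = simulate_utrs(mirnas, design, rng, utr_transcripts)
            truth.planted_sites = registry
            for kind in ("mirna", "mrna"):
                write_counts(matrices[kind], outdir / f"{kind}_counts.tsv")
                matrices[kind].samples.to_frame().to_csv(
                    outdir / f"{kind}_samples.tsv", sep="\t", index=False
                )
            write_fasta(mirnas, outdir / "mirnas.fa")
            write_fasta(utrs, outdir / "utrs.fa")
            write_json_summary(
                {
                    "planted_de": [asdict(e) for e in design.planted_de],
                    "planted_sites": [
                        {
                            "transcript_id": s.transcript_id,
                            "mirna_id": s.mirna_id,
                            "seed_class": s.seed_class,
                            "start": s.window.start,
                            "end": s.window.end,
                        }
                        for s in registry
                    ],
                },
                outdir / "truth.json",
            )
        else:
            inp = config.inputs
            matrices = {
                "mirna": read_counts(inp["mirna_counts"], inp["mirna_samples"], "mirna", config.stages),
                "mrna": read_counts(inp["mrna_counts"], inp["mrna_samples"], "mrna", config.stages),
            }
            mirnas = read_fasta(inp["mirna_fasta"], "mature_mirna")
            utrs = read_fasta(inp["utr_fasta"], "utr3")
        logger.info("inputs ready: %d miRNAs, %d mRNAs, %d UTRs",
                    len(matrices["mirna"].feature_ids), len(matrices["mrna"].feature_ids), len(utrs))

        stage = "quantify"
        mirna_cpm = cpm(matrices["mirna"])
        mrna_rpkm = rpkm(matrices["mrna"])
        mirna_cpm.values.to_csv(outdir / "mirna_cpm.tsv", sep="\t", index_label="feature_id")
        mrna_rpkm.values.to_csv(outdir / "mrna_rpkm.tsv", sep="\t", index_label="feature_id")
        detected = {
            "mirna": filter_expressed(mirna_cpm, config.detection_threshold, config.detection_rule),
            "mrna": filter_expressed(mrna_rpkm, config.detection_threshold, config.detection_rule),
        }
        logger.info("detected: %d miRNAs (CPM >= %g), %d mRNAs (RPKM >= %g)",
                    len(detected["mirna"]), config.detection_threshold,
                    len(detected["mrna"]), config.detection_threshold)

        stage = "de"
        de = {}
        for kind in ("mirna", "mrna"):
            fixed = config.mirna_fixed_dispersion if kind == "mirna" else None
            replicated = max(
                len(matrices[kind].samples.samples_for_stage(s)) for s in config.stages
            ) >= 2
            if kind == "mirna" and not replicated and fixed is None:
                raise MirswitchError(
                    "miRNA libraries are unreplicated; set mirna_fixed_dispersion"
                )
            de[kind] = run_pairwise_de(
                matrices[kind],
                config.comparisons,
                fold_cutoff=config.fold_cutoff,
                fdr=config.fdr,
                fixed_dispersion=fixed if kind == "mirna" else None,
                detected_features=detected[kind],
            )
            frame = de_results_frame(de[kind])
            if kind == "mirna" and fixed is not None:
                frame["fixed_dispersion"] = fixed  # flag the assumption in the output
            frame.to_csv(outdir / f"de_{kind}.tsv", sep="\t", index=False)

        stage = "scan"
        sites = []
        for m in mirnas:
            for u in utrs:
                sites.extend(
                    scan_utr(
                        m, u,
                        score_threshold=config.score_threshold,
                        energy_threshold=config.energy_threshold,
                        wobble_scope=config.wobble_scope,
                    )
                )
        write_sites(
            sites,
            outdir / "sites.tsv",
            header_comment=(
                f"mirswitch {__version__}; score>{config.score_threshold:g}; "
                f"energy<{config.energy_threshold:g} kcal/mol; seed rules A,B; "
                f"wobble_scope={config.wobble_scope}"
            ),
        )
        logger.info("scan: %d passing sites", len(sites))

        stage = "integrate"
        comp = tuple(config.network_comparison)
        edges = reciprocal_pairs(de["mirna"][comp], de["mrna"][comp], sites, comp)
        if edges:
            edges = rank_targets(edges)
        summary_net = export_network(edges, outdir / "edges.tsv", outdir / "network_summary.json")
        logger.info("network: %d edges", summary_net["n_edges"])

        summary = {
            "version": __version__,
            "seed": config.rng_seed,
            "config_hash": config.config_hash(),
            "config": {k: v for k, v in asdict(config).items()},
            "n_detected": {k: len(v) for k, v in detected.items()},
            "n_sites": len(sites),
            "network": summary_net,
        }
        write_json_summary(summary, outdir / "run_summary.json")
        return summary
    except MirswitchError as err:
        raise MirswitchError(f"stage {stage!r} failed: {err}") from err
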