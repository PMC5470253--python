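"""End-to-end orchestration: simulate -> quantify -> call -> interpret.

A :class:`RunConfig` fully determines a run; identical configs (same
seed) produce byte-identical output tables.  Every table is written with
a '#'-prefixed provenance header recording the seed, package version, and
thresholds, and a run manifest lists all artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .gene_models import FIXTURE_NAMES, build_fixture, load_gene_model
from .simulate import (
    IndelAllele,
    IndelSpectrum,
    SimConfig,
    isoform_weights_for_psi,
    random_genome,
    simulate_amplicon_reads,
    simulate_junction_reads,
)
from .junctions import (
    compute_psi,
    count_junction_reads,
    inclusion_counts,
    write_junction_tsv,
)
from .splicing import Thresholds, call_events, events_to_frame
from .consequence import frame_report, interpret_deletion, predict_amplicon_size
from .indels import call_indels, classify_sgrna

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "quantify", "events", "indels", "consequence")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    seed: int = 1
    fixture: Optional[str] = "kras"
    gene_model: Optional[str] = None  # GTF path, alternative to fixture
    gene_id: Optional[str] = None
    out_dir: str = "exonskip_run"
    stages: tuple[str, ...] = ALL_STAGES
    # junction-read simulation
    depth: int = 2000
    read_length: int = 75
    error_rate: float = 0.001
    min_overhang: int = 6
    # duplicate removal saturates at high per-gene depth on single-end
    # simulated reads (few distinct placements), so it is opt-in
    dedup: bool = False
    psi_parent: float = 1.0
    psi_clone: float = 0.64
    # amplicon simulation / indel calling
    amplicon_depth: int = 5000
    indel_fraction: float = 0.65
    insertion_base: str = "T"
    min_allele_frequency: float = 0.005
    sgrna_threshold: float = 0.20
    # event calling
    delta_min: float = 0.2
    reads_min: int = 10
    bf_min: float = 10.0

    def validate(self) -> None:
        if self.fixture is None and self.gene_model is None:
            raise ConfigError("either a fixture name or a gene model is required")
        if self.fixture is not None and self.fixture not in FIXTURE_NAMES:
            raise ConfigError(f"unknown fixture {self.fixture!r}")
        if self.gene_model is not None and self.gene_id is None:
            raise ConfigError("gene_id is required with a gene model file")
        for name in self.stages:
            if name not in ALL_STAGES:
                raise ConfigError(f"unknown stage {name!r}")
        if self.depth <= 0 or self.amplicon_depth <= 0:
            raise ConfigError("depths must be positive")
        if self.reads_min < 0:
            raise ConfigError("reads_min must be non-negative")
        if not (0.0 <= self.delta_min <= 1.0):
            raise ConfigError("delta_min must lie in [0, 1]")
        if self.bf_min < 0:
            raise ConfigError("bf_min must be non-negative")
        if not (0.0 <= self.psi_parent <= 1.0 and 0.0 <= self.psi_clone <= 1.0):
            raise ConfigError("PSI values must lie in [0, 1]")
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise ConfigError("indel_fraction must lie in [0, 1]")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ConfigError("error_rate must lie in [0, 0.1]")
        if not (0.0 <= self.sgrna_threshold <= 1.0):
            raise ConfigError("sgrna_threshold must lie in [0, 1]")
        if not (0.0 <= self.min_allele_frequency <= 1.0):
            raise ConfigError("min_allele_frequency must lie in [0, 1]")

    def thresholds(self) -> Thresholds:
        return Thresholds(self.delta_min, self.reads_min, self.bf_min)


def _provenance(config: RunConfig) -> dict:
    return {
        "seed": config.seed,
        "version": __version__,
        "thresholds": f"delta_min={config.delta_min},"
        f"reads_min={config.reads_min},bf_min={config.bf_min}",
    }


def _write_table(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _provenance(config)

    if config.fixture is not None:
        gene, primers, fmeta = build_fixture(config.fixture)
    else:
        gene = load_gene_model(config.gene_model, config.gene_id)
        primers, fmeta = None, {}
    labels = gene.labels
    cassette = fmeta.get("cassette") if fmeta else None
    if cassette is None:
        if len(labels) < 3:
            raise ConfigError("gene model needs at least 3 exons")
        cassette = (labels[0], labels[1], labels[2])

    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31)) for name in
             ("genome", "parent", "clone", "amplicon")}
    genome = random_genome(gene.end + 200, seeds["genome"])
    artifacts: dict[str, str] = {}
    results: dict = {}
    stages = [s for s in ALL_STAGES if s in config.stages]

    sam_paths = {"parent": out / "parent.sam", "clone": out / "clone.sam"}
    if "simulate" in stages:
        try:
            for sample, psi in (("parent", config.psi_parent),
                                ("clone", config.psi_clone)):
                cfg = SimConfig(
                    seed=seeds[sample],
                    depth=config.depth,
                    read_length=config.read_length,
                    error_rate=config.error_rate,
                )
                mix = isoform_weights_for_psi(
                    gene, cassette, psi, cfg, config.min_overhang
                )
                simulate_junction_reads(
                    mix, cfg, sam_paths[sample],
                    min_overhang=config.min_overhang,
                    genome=genome, target_psi=psi,
                )
                artifacts[f"{sample}_sam"] = str(sam_paths[sample])
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("simulate", exc) from exc

    counts = {}
    if "quantify" in stages:
        try:
            psi_rows = []
            for sample in ("parent", "clone"):
                jc = count_junction_reads(
                    sam_paths[sample], gene,
                    min_overhang=config.min_overhang,
                    dedup=config.dedup, sample_id=sample,
                )
                counts[sample] = jc
                jpath = out / f"junctions_{sample}.tsv"
                write_junction_tsv(jc, jpath, meta)
                artifacts[f"junctions_{sample}"] = str(jpath)
                x, m = inclusion_counts(jc, cassette)
                psi_rows.append(
                    {
                        "sample": sample,
                        "gene": gene.gene_id,
                        "cassette": "-".join(map(str, cassette)),
                        "x_inclusion": x,
                        "m_total": m,
                        "psi": compute_psi(jc, cassette) if m else float("nan"),
                    }
                )
            psi_df = pd.DataFrame(psi_rows)
            ppath = out / "psi_report.tsv"
            _write_table(psi_df, ppath, meta)
            artifacts["psi_report"] = str(ppath)
            results["psi"] = {
                r["sample"]: r["psi"] for r in psi_rows
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("quantify", exc) from exc

    if "events" in stages and counts:
        try:
            clone_c = {cassette: inclusion_counts(counts["clone"], cassette)}
            parent_c = {cassette: inclusion_counts(counts["parent"], cassette)}
            events = call_events(
                clone_c, parent_c, gene=gene.gene_id,
                thresholds=config.thresholds(),
            )
            epath = out / "events.tsv"
            _write_table(events_to_frame(events), epath, meta)
            artifacts["events"] = str(epath)
            results["events"] = [
                {"cassette": ev.cassette, "delta_psi": ev.delta_psi,
                 "bayes_factor": ev.bayes_factor, "passes": ev.passes}
                for ev in events
            ]
        except Exception as exc:
            raise StageError("events", exc) from exc

    cut = (fmeta or {}).get("cut_site")
    if "indels" in stages and cut is not None:
        try:
            # amplicon: 120 nt each side of the genomic cut position
            g = cut["genomic"]
            lo, hi = max(1, g - 120), min(len(genome), g + 120)
            ref = genome[lo - 1 : hi]
            cut_local = g - lo + 1
            spectrum = IndelSpectrum(
                target=("amplicon", cut_local),
                alleles=(
                    IndelAllele("ins", config.insertion_base,
                                config.indel_fraction),
                    IndelAllele("ref", None, 1.0 - config.indel_fraction),
                ),
            )
            cfg = SimConfig(
                seed=seeds["amplicon"], depth=config.amplicon_depth,
                read_length=config.read_length,
                error_rate=config.error_rate,
            )
            amp_sam = out / "amplicon.sam"
            simulate_amplicon_reads(spectrum, ref, cfg, out_sam=amp_sam)
            artifacts["amplicon_sam"] = str(amp_sam)
            table = call_indels(
                amp_sam, ref,
                window=(cut_local - 20, cut_local + 20),
                min_frequency=config.min_allele_frequency,
                target=("amplicon", cut_local),
            )
            ipath = out / "indels.tsv"
            _write_table(table.rows, ipath, {
                **meta,
                "n_reads": table.n_reads,
                "edited_fraction": f"{table.edited_fraction:.6f}",
                "sgrna_class": classify_sgrna(
                    table.edited_fraction, config.sgrna_threshold
                ),
            })
            artifacts["indels"] = str(ipath)
            results["edited_fraction"] = table.edited_fraction
        except Exception as exc:
            raise StageError("indels", exc) from exc

    if "consequence" in stages:
        try:
            rows = []
            mid = cassette[1]
            report = frame_report(gene, [mid], genome=genome)
            rows.append(
                {
                    "item": f"skip_exon_{mid}",
                    "value": f"len={report.skipped_length},"
                    f"in_frame={report.in_frame}",
                }
            )
            if primers is not None:
                full = predict_amplicon_size(gene, list(labels), primers)
                skip = predict_amplicon_size(
                    gene, [l for l in labels if l != mid], primers
                )
                rows.append({"item": "rt_pcr_full_bp", "value": full})
                rows.append({"item": "rt_pcr_skip_bp", "value": skip})
                results["rt_pcr"] = {"full": full, "skip": skip}
            if (fmeta or {}).get("deletion_allele"):
                s, e = fmeta["deletion_allele"]
                allele = interpret_deletion(gene, s, e)
                rows.append(
                    {
                        "item": "deletion_allele",
                        "value": f"len={allele.length},"
                        f"removed={','.join(map(str, allele.removed_exons))};"
                        f"{allele.description}",
                    }
                )
                results["deletion_length"] = allele.length
            cpath = out / "consequence.tsv"
            _write_table(pd.DataFrame(rows), cpath, meta)
            artifacts["consequence"] = str(cpath)
        except Exception as exc:
            raise StageError("consequence", exc) from exc

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "fixture": config.fixture,
        "gene": gene.gene_id,
        "stages": stages,
        "artifacts": artifacts,
        "results": results,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    artifacts["manifest"] = str(out / "manifest.json")
    return manifest
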