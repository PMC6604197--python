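"""End-to-end pipeline: simulate -> coverage -> peaks -> differential
binding -> clustering -> pausing -> expression -> summary report.

One global seed expands into per-stage seeds through named SeedSequence
salts, so every stage is independently reproducible; each stage writes its
artifacts plus a manifest line (stage, parameters, input hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as pc
from . import coverage as cov
from . import diffbind as db
from . import expression as xp
from . import pausing as pz
from . import peaks as pk
from .simulate import (
    FragmentSet,
    SimulationConfig,
    make_annotation,
    assign_classes,
    simulate_chip,
    simulate_expression,
    simulate_polii,
)

logger = logging.getLogger(__name__)

RUN_MODES = ("simulate", "analyze", "full")


@dataclass
class PipelineConfig:
    outdir: str = "betshift_run"
    seed: int = 0
    mode: str = "full"
    models: tuple = ("sensitive", "resistant")
    bin_size: int = 50
    extension: int = 300
    flank: int = 1000
    profile_flank: int = 4000
    fdr: float = 0.05
    min_count: float = 10.0
    k: int = 4
    n_restarts: int = 25
    peak_p_cutoff: float = 1e-3
    peak_max_gap: int = 500
    tr_dose: float = 500.0
    gain_threshold: float = 2.0
    simulation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in RUN_MODES:
            raise ValueError(f"mode must be one of {RUN_MODES}")
        self.models = tuple(self.models)  # YAML deserializes sequences as lists

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class PipelineRun:
    """Stateful run directory: executes stages in dependency order and
    records a manifest entry per artifact."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.jsonl"
        self.summary: dict = {}
        # in-memory state shared between stages
        self.annotation = None
        self.classes = None
        self.truths: dict = {}
        self.chip: dict = {}
        self.windows = None
        self.db_results: dict = {}
        self.assignments: dict = {}
        self.de_results: dict = {}

    def _record(self, stage: str, params: dict, artifacts: list) -> None:
        entry = {
            "stage": stage, "params": params,
            "artifacts": {str(p): _hash_file(Path(p)) for p in artifacts},
        }
        with open(self.manifest_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")
        logger.info("stage %s done: %s", stage, params)

    # ----------------------------------------------------------------- stages

    def stage_simulate(self) -> None:
        sim = self.config.sim_config()
        self.annotation = make_annotation(sim)
        self.classes = assign_classes(sim, self.annotation)
        artifacts = []
        gene_path = self.outdir / "genes.tsv"
        from .genome import write_gene_table
        write_gene_table(self.annotation.genes, gene_path)
        artifacts.append(gene_path)
        for model in self.config.models:
            samples, truth = simulate_chip(sim, model, self.annotation, self.classes)
            self.chip[model] = samples
            self.truths[model] = truth
            tpath = self.outdir / f"truth_{model}.tsv"
            truth.to_frame().to_csv(tpath, sep="\t", index=False)
            artifacts.append(tpath)
        self._record("simulate", {"seed": sim.seed, "n_tss": sim.n_tss,
                                  "models": list(self.config.models)}, artifacts)

    def stage_coverage(self) -> None:
        """RPGC-normalized, input-subtracted TSS metaprofile per model at
        vehicle, with mode detection."""
        c = self.config
        anchors = [(g.chrom, g.tss, g.strand) for g in self.annotation.genes]
        artifacts = []
        for model, samples in self.chip.items():
            inp = next(s for s in samples if s.is_input)
            inp_track = cov.rpgc_normalize(cov.extend_and_bin(
                inp, self.annotation.chrom_sizes, c.bin_size, c.extension))
            veh = [s for s in samples if not s.is_input and s.dose == 0]
            merged = FragmentSet(model=model, track="BRD4", dose=0.0, replicate=0,
                                 is_input=False,
                                 fragments=[f for s in veh for f in s.fragments])
            track = cov.subtract_input(
                cov.rpgc_normalize(cov.extend_and_bin(
                    merged, self.annotation.chrom_sizes, c.bin_size, c.extension)),
                inp_track)
            profile = cov.metaprofile(track, anchors, flank=c.profile_flank)
            modes = cov.profile_modes(profile)
            ppath = self.outdir / f"metaprofile_{model}.tsv"
            cov.export_metaprofile(profile, ppath)
            artifacts.append(ppath)
            self.summary[f"profile_{model}"] = modes
        self._record("coverage", {"bin": c.bin_size, "extend": c.extension}, artifacts)

    def stage_peaks(self) -> None:
        """Consensus peaks per model and dose; count trend in the summary."""
        c = self.config
        artifacts = []
        for model, samples in self.chip.items():
            inp = next(s for s in samples if s.is_input)
            counts = {}
            for dose in sorted({s.dose for s in samples if not s.is_input}):
                reps = [s for s in samples if not s.is_input and s.dose == dose]
                peaks = pk.consensus_pipeline(
                    reps[0], reps[1], inp, self.annotation.chrom_sizes,
                    blacklist=self.annotation.blacklist,
                    seed=self.config.seed + int(dose),
                    p_cutoff=c.peak_p_cutoff, bin_size=c.bin_size,
                    extension=c.extension, max_gap=c.peak_max_gap)
                path = self.outdir / f"peaks_{model}_{dose:g}.bed"
                pk.write_peaks(peaks, path)
                artifacts.append(path)
                counts[f"{dose:g}"] = len(peaks)
            self.summary[f"peak_counts_{model}"] = counts
        self._record("peaks", {"p_cutoff": c.peak_p_cutoff}, artifacts)

    def stage_diffbind(self) -> None:
        from .genome import tss_windows
        c = self.config
        self.windows = tss_windows(self.annotation, flank=c.flank)
        sim = self.config.sim_config()
        artifacts = []
        for model, samples in self.chip.items():
            cols = {
                f"dose{s.dose:g}_rep{s.replicate}": s
                for s in samples if not s.is_input
            }
            matrix = db.count_in_windows(cols, self.windows)
            info = pd.DataFrame(
                {"dose": [s.dose for s in samples if not s.is_input]},
                index=list(cols),
            )
            res = db.run_contrasts(matrix, info, sim.doses, min_count=c.min_count)
            self.db_results[model] = res
            table = db.affected_tss_table(res, fdr=c.fdr, n_total=sim.n_tss)
            tpath = self.outdir / f"affected_tss_{model}.tsv"
            table.to_csv(tpath, sep="\t")
            artifacts.append(tpath)
            mpath = self.outdir / f"window_counts_{model}.tsv"
            matrix.to_csv(mpath, sep="\t")
            artifacts.append(mpath)
            self.summary[f"affected_{model}"] = table.to_dict()
        self._record("diffbind", {"fdr": c.fdr, "min_count": c.min_count}, artifacts)

    def stage_cluster(self) -> None:
        c = self.config
        artifacts = []
        for model, res in self.db_results.items():
            matrix = pc.build_lfc_matrix(res, fdr=c.fdr)
            if len(matrix) < c.k:
                logger.warning("model %s: %d affected TSSs < k; skipping clustering",
                               model, len(matrix))
                continue
            assignment = pc.name_clusters(
                pc.cluster_tss(matrix, k=c.k, seed=self.config.seed,
                               n_restarts=c.n_restarts))
            self.assignments[model] = assignment
            path = self.outdir / f"clusters_{model}.tsv"
            assignment.to_frame().to_csv(path, sep="\t")
            artifacts.append(path)
            self.summary[f"cluster_sizes_{model}"] = (
                assignment.labeled().value_counts().to_dict())
        if len(self.assignments) == 2:
            a, b = (self.assignments[m] for m in self.config.models)
            tid_to_gid = {g.transcript_id: g.gene_id for g in self.annotation.genes}
            overlap = pc.cluster_overlap(a, b, tid_to_gid, tid_to_gid)
            opath = self.outdir / "cluster_overlap.tsv"
            overlap.to_csv(opath, sep="\t")
            artifacts.append(opath)
        self._record("cluster", {"k": c.k}, artifacts)

    def stage_pausing(self) -> None:
        c = self.config
        sim = self.config.sim_config()
        model = self.config.models[0]
        truth = self.truths[model]
        track0 = simulate_polii(sim, truth, self.annotation, dose=0.0)
        track1 = simulate_polii(sim, truth, self.annotation, dose=c.tr_dose)
        folds = {}
        for g in self.annotation.genes:
            r0 = pz.traveling_ratio(track0, g, "vehicle")
            r1 = pz.traveling_ratio(track1, g, f"{c.tr_dose:g}")
            if r0.valid and r1.valid:
                folds[g.transcript_id] = pz.tr_shift(r0, r1, c.gain_threshold)[0]
        path = self.outdir / f"tr_fold_{model}.tsv"
        pd.Series(folds, name="tr_fold").rename_axis("transcript_id").to_csv(path, sep="\t")
        if model in self.assignments:
            groups = self.assignments[model].labeled().to_dict()
            fractions = pz.gained_fraction_by_group(folds, groups, c.gain_threshold)
            self.summary["tr_gained_by_cluster"] = {
                g: {"gained": k, "total": n} for g, (k, n) in fractions.items()}
            from .simulate import CLASS_HIGHLY_PAUSE, CLASS_HIGHLY_CORE
            if CLASS_HIGHLY_PAUSE in fractions and CLASS_HIGHLY_CORE in fractions:
                k1, n1 = fractions[CLASS_HIGHLY_PAUSE]
                k2, n2 = fractions[CLASS_HIGHLY_CORE]
                self.summary["tr_gain_proportion_p"] = pz.proportion_test(k1, n1, k2, n2)
        self._record("pausing", {"dose": c.tr_dose, "gain_threshold": c.gain_threshold},
                     [path])

    def stage_expression(self) -> None:
        c = self.config
        sim = self.config.sim_config()
        artifacts = []
        tid_to_gid = {g.transcript_id: g.gene_id for g in self.annotation.genes}
        for model in self.config.models:
            truth = self.truths[model]
            counts, _ = simulate_expression(sim, truth, self.annotation,
                                            seed_salt=f"expression_{model}")
            vehicle = [col for col in counts if col.startswith("dose0_")]
            per_dose = {}
            for dose in sim.doses:
                if dose == 0:
                    continue
                treated = [col for col in counts if col.startswith(f"dose{dose:g}_")]
                per_dose[dose] = xp.differential_expression(
                    counts, treated, vehicle, fdr=c.fdr)
            self.de_results[model] = per_dose
            top_dose = max(per_dose)
            de = per_dose[top_dose]
            path = self.outdir / f"de_{model}.tsv"
            de.to_csv(path, sep="\t")
            artifacts.append(path)
            if model in self.db_results:
                affected = db.affected_transcripts(self.db_results[model], fdr=c.fdr)
                n_ov, n_de, pct = xp.db_de_overlap(
                    affected, de, transcript_to_gene=tid_to_gid)
                self.summary[f"db_de_overlap_{model}"] = {
                    "n_overlap": n_ov, "n_down": n_de, "pct": pct}
        if len(self.de_results) == 2 and self.config.models[0] in self.assignments:
            m_a, m_b = self.config.models
            top = max(self.de_results[m_a])
            comp = xp.cluster_expression_compare(
                self.assignments[m_a].labeled(),
                self.de_results[m_a][top], self.de_results[m_b][top],
                transcript_to_gene=tid_to_gid)
            cpath = self.outdir / "cluster_expression_compare.tsv"
            comp.to_csv(cpath, sep="\t")
            artifacts.append(cpath)
        self._record("expression", {"fdr": c.fdr}, artifacts)

    def stage_report(self) -> None:
        path = self.outdir / "summary.json"
        with open(path, "w") as fh:
            json.dump(self.summary, fh, indent=2, default=str, sort_keys=True)
        self._record("report", {}, [path])

    def run(self) -> dict:
        stages = [self.stage_simulate]
        if self.config.mode in ("analyze", "full"):
            stages += [self.stage_coverage, self.stage_peaks, self.stage_diffbind,
                       self.stage_cluster, self.stage_pausing, self.stage_expression]
        stages.append(self.stage_report)
        for stage in stages:
            try:
                stage()
            except Exception as exc:
                raise RuntimeError(f"stage {stage.__name__} failed: {exc}") from exc
        return self.summary


def run_pipeline(config: PipelineConfig) -> dict:
    return PipelineRun(config).run()
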