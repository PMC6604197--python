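"""Synthetic-data generator with known ground truth.

Emulates the study design: two cell models (one drug-sensitive, one
resistant), four bromodomain-inhibitor doses (vehicle, 50, 500, 5000 nM),
two ChIP replicates per condition, bimodal fragment occupancy around each
TSS (an upstream mode near -300 bp and a stronger downstream mode near
+165 bp), per-TSS sensitivity classes whose occupancy is displaced
dose-dependently and independently at the core-promoter and pause-site
windows, Pol II coverage whose promoter/body ratio rises as pause-site
occupancy is lost, negative-binomial expression counts downregulated in
proportion to pause-site displacement, and efficiency-corrected qPCR Ct
tables.

Displacement follows a Hill law: the fraction of occupancy remaining at
dose d is r = 1 / (1 + (d/EC50)^h). Overdispersion is injected as a
Gamma-Poisson mixture so negative-binomial test assumptions are exercised
honestly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeAnnotation, Interval, write_bed

# canonical sensitivity classes (cluster names used throughout)
CLASS_SENSITIVE_BOTH = "sensitive-both"
CLASS_HIGHLY_BOTH = "highly-sensitive-both"
CLASS_HIGHLY_PAUSE = "highly-sensitive-pause"
CLASS_HIGHLY_CORE = "highly-sensitive-core"
CLASS_UNAFFECTED = "unaffected"

SENSITIVITY_CLASSES = (
    CLASS_SENSITIVE_BOTH,
    CLASS_HIGHLY_BOTH,
    CLASS_HIGHLY_PAUSE,
    CLASS_HIGHLY_CORE,
    CLASS_UNAFFECTED,
)

_NO_DISPLACEMENT = math.inf  # EC50 sentinel: window never displaced


def displacement_fraction(dose: float, ec50: float, hill: float = 1.0):
    """Remaining-occupancy fraction r = 1/(1 + (dose/ec50)^hill).

    r(0) = 1 and r decreases strictly with dose; an infinite EC50 encodes a
    window that the compound never displaces.
    """
    if np.any(np.asarray(ec50) <= 0):
        raise ValueError("ec50 must be positive")
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    if np.isinf(ec50):
        return np.ones_like(dose)[()] if dose.ndim else 1.0
    with np.errstate(divide="ignore"):
        r = 1.0 / (1.0 + (dose / ec50) ** hill)
    return r[()] if dose.ndim == 0 else r


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults encode the study conditions: 4 doses x 2 replicates, bimodal
    TSS occupancy with the downstream mode at +165 bp (centre of the
    reported 150-180 bp range) and the upstream mode at -300 bp, the
    downstream mode twice as strong as the upstream one in the sensitive
    model, and a resistant model with ~50-fold higher EC50s and a flatter
    downstream/upstream ratio.
    """

    seed: int = 0
    n_tss: int = 2000
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    doses: tuple = (0.0, 50.0, 500.0, 5000.0)
    n_replicates: int = 2
    class_proportions: dict = field(
        default_factory=lambda: {
            CLASS_SENSITIVE_BOTH: 0.06,
            CLASS_HIGHLY_BOTH: 0.04,
            CLASS_HIGHLY_PAUSE: 0.06,
            CLASS_HIGHLY_CORE: 0.05,
            CLASS_UNAFFECTED: 0.79,
        }
    )
    upstream_offset: int = -300
    downstream_offset: int = 165
    peak_sd: float = 40.0
    amp_up: float = 60.0      # expected fragments per core-promoter window, vehicle
    amp_down: float = 90.0    # expected fragments per pause-site window, vehicle
    # per-class EC50 (nM) at each window; inf = never displaced
    ec50_core: dict = field(
        default_factory=lambda: {
            CLASS_SENSITIVE_BOTH: 2000.0,
            CLASS_HIGHLY_BOTH: 100.0,
            CLASS_HIGHLY_PAUSE: _NO_DISPLACEMENT,
            CLASS_HIGHLY_CORE: 100.0,
            CLASS_UNAFFECTED: _NO_DISPLACEMENT,
        }
    )
    ec50_pause: dict = field(
        default_factory=lambda: {
            CLASS_SENSITIVE_BOTH: 2000.0,
            CLASS_HIGHLY_BOTH: 100.0,
            CLASS_HIGHLY_PAUSE: 100.0,
            CLASS_HIGHLY_CORE: _NO_DISPLACEMENT,
            CLASS_UNAFFECTED: _NO_DISPLACEMENT,
        }
    )
    hill: float = 1.0
    frag_len: int = 300
    noise_dispersion: float = 0.05   # NB dispersion of per-window fragment counts
    n_background: int = 40_000       # uniform background fragments per ChIP sample
    n_input: int = 200_000           # fragments in the matched input sample
    expr_mean_range: tuple = (50.0, 2000.0)
    coupling_beta: float = 2.0       # expression log2FC per unit pause-site displacement
    tr_coupling: float = 1.0         # promoter Pol II gain per unit pause-site displacement
    tr_body_floor: float = 0.1       # residual body density when pausing is complete
    # resistant-model modifiers
    resistant_ec50_factor: float = 50.0
    resistant_amp_down: float = 66.0
    resistant_amp_up: float = 60.0

    def __post_init__(self):
        props = np.array(list(self.class_proportions.values()), dtype=float)
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must be >= 0 and sum to 1")
        if not (self.upstream_offset < 0 < self.downstream_offset):
            raise ValueError("need upstream_offset < 0 < downstream_offset")
        if self.hill <= 0:
            raise ValueError("hill exponent must be positive")
        for name in ("ec50_core", "ec50_pause"):
            for v in getattr(self, name).values():
                if v <= 0:
                    raise ValueError(f"{name} values must be positive")

    def for_model(self, model: str) -> "SimulationConfig":
        """Specialise the config to one cell model.

        The resistant model has ~50-fold higher EC50s (globally weaker drug
        response) and weaker, flatter TSS binding, mirroring a cell line in
        which BET binding is globally weaker and displacement needs far
        higher compound doses.
        """
        if model == "sensitive":
            return self
        if model != "resistant":
            raise ValueError(f"unknown cell model {model!r}")
        f = self.resistant_ec50_factor
        scale = lambda d: {k: (v * f if np.isfinite(v) else v) for k, v in d.items()}
        return replace(
            self,
            ec50_core=scale(self.ec50_core),
            ec50_pause=scale(self.ec50_pause),
            amp_up=self.resistant_amp_up,
            amp_down=self.resistant_amp_down,
        )


@dataclass
class FragmentSet:
    """Sequenced fragments of one sample plus its metadata."""

    model: str
    track: str            # e.g. "BRD4", "input", "pol2"
    dose: float
    replicate: int
    is_input: bool
    fragments: list  # list[Interval]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def write_bed(self, path: str | Path) -> None:
        write_bed(self.fragments, path)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    ``remaining`` maps (transcript_id, dose, window) -> remaining-occupancy
    fraction r in [0, 1]; ``classes`` maps transcript_id -> sensitivity
    class; ``expression_lfc`` maps (gene_id, dose) -> true log2 fold change.
    """

    classes: dict
    remaining: dict
    expression_lfc: dict

    def r(self, transcript_id: str, dose: float, window: str) -> float:
        return self.remaining[(transcript_id, dose, window)]

    def class_series(self) -> pd.Series:
        return pd.Series(self.classes, name="class")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"transcript_id": t, "dose": d, "window": w, "remaining": r}
            for (t, d, w), r in self.remaining.items()
        ]
        df = pd.DataFrame(rows)
        df["class"] = df["transcript_id"].map(self.classes)
        return df


def _derive_seed(seed: int, *salts) -> np.random.Generator:
    """Expand the global seed plus stage-name salts into an independent
    generator (stable across processes, unlike the builtin hash)."""
    import zlib

    salted = [zlib.crc32(str(s).encode()) & 0x7FFFFFFF for s in salts]
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, *salted])
    return np.random.default_rng(ss)


def make_annotation(config: SimulationConfig, seed_salt: str = "annotation") -> GenomeAnnotation:
    """Place n_tss gene models quasi-uniformly (jittered grid) on the
    synthetic genome, random strand, gene lengths 3-8 kb, ~10% noncoding."""
    rng = _derive_seed(config.seed, seed_salt)
    chroms = list(config.chrom_sizes.items())
    total = sum(s for _, s in chroms)
    margin = 10_000
    genes = []
    idx = 0
    for chrom, size in chroms:
        n_here = round(config.n_tss * size / total)
        if chrom == chroms[-1][0]:
            n_here = config.n_tss - idx
        usable = size - 2 * margin
        if usable <= 0 or n_here * 2000 > usable:
            raise ValueError("chromosomes too small for requested n_tss")
        spacing = usable / max(n_here, 1)
        for i in range(n_here):
            pos = int(margin + i * spacing + rng.uniform(0.1, 0.9) * min(spacing, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.uniform(3000, 8000))
            if strand == "+":
                tes = min(pos + glen, size - 1)
            else:
                tes = max(pos - glen, 1)
            biotype = "noncoding" if rng.random() < 0.1 else "coding"
            genes.append(
                GeneModel(
                    gene_id=f"G{idx:05d}", transcript_id=f"T{idx:05d}",
                    chrom=chrom, strand=strand, tss=pos, tes=tes, biotype=biotype,
                )
            )
            idx += 1
    return GenomeAnnotation(chrom_sizes=dict(config.chrom_sizes), genes=genes)


def assign_classes(config: SimulationConfig, annotation: GenomeAnnotation,
                   seed_salt: str = "classes") -> dict:
    """Deterministic per-TSS sensitivity-class assignment at the configured
    proportions (shared across cell models so cluster overlap is meaningful)."""
    rng = _derive_seed(config.seed, seed_salt)
    names = list(config.class_proportions)
    props = np.array([config.class_proportions[n] for n in names])
    tids = [g.transcript_id for g in annotation.genes]
    draws = rng.choice(len(names), size=len(tids), p=props)
    return {t: names[d] for t, d in zip(tids, draws)}


def _ground_truth(config: SimulationConfig, annotation: GenomeAnnotation,
                  classes: dict) -> GroundTruth:
    remaining = {}
    for g in annotation.genes:
        cls = classes[g.transcript_id]
        for dose in config.doses:
            remaining[(g.transcript_id, dose, "core")] = float(
                displacement_fraction(dose, config.ec50_core[cls], config.hill)
            )
            remaining[(g.transcript_id, dose, "pause")] = float(
                displacement_fraction(dose, config.ec50_pause[cls], config.hill)
            )
    expression_lfc = {}
    for g in annotation.genes:
        for dose in config.doses:
            r_pause = remaining[(g.transcript_id, dose, "pause")]
            expression_lfc[(g.gene_id, dose)] = -config.coupling_beta * (1.0 - r_pause)
    return GroundTruth(classes=classes, remaining=remaining, expression_lfc=expression_lfc)


def _draw_window_fragments(rng, gene: GeneModel, mode_offset: int, lam: float,
                           config: SimulationConfig, chrom_len: int) -> np.ndarray:
    """Fragment start positions for one TSS window: Gamma-Poisson count,
    Gaussian positions around the strand-oriented mode."""
    disp = config.noise_dispersion
    if lam <= 0:
        return np.empty(0, dtype=np.int64)
    lam_i = rng.gamma(1.0 / disp, disp * lam) if disp > 0 else lam
    n = rng.poisson(lam_i)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    sign = 1 if gene.strand == "+" else -1
    centers = gene.tss + sign * (mode_offset + rng.normal(0.0, config.peak_sd, n))
    starts = np.rint(centers).astype(np.int64) - config.frag_len // 2
    return np.clip(starts, 0, chrom_len - config.frag_len)


def simulate_chip(config: SimulationConfig, model: str = "sensitive",
                  annotation: GenomeAnnotation | None = None,
                  classes: dict | None = None) -> tuple[list, GroundTruth]:
    """Simulate the full ChIP arm for one cell model.

    Returns one FragmentSet per (dose, replicate) plus one input sample,
    and the GroundTruth. Expected fragments per window are
    amp_up * r_core(dose) and amp_down * r_pause(dose), Gamma-Poisson
    sampled per replicate, with positions Gaussian around the two modes and
    a uniform background.
    """
    mconf = config.for_model(model)
    if annotation is None:
        annotation = make_annotation(config)
    if classes is None:
        classes = assign_classes(config, annotation)
    truth = _ground_truth(mconf, annotation, classes)

    chrom_names = list(config.chrom_sizes)
    chrom_len = dict(config.chrom_sizes)
    cum = np.cumsum([chrom_len[c] for c in chrom_names])
    total = int(cum[-1])

    samples = []
    for dose in mconf.doses:
        for rep in range(1, mconf.n_replicates + 1):
            rng = _derive_seed(config.seed, "chip", model, f"{dose:g}", rep)
            frags: list[Interval] = []
            for g in annotation.genes:
                clen = chrom_len[g.chrom]
                r_core = truth.r(g.transcript_id, dose, "core")
                r_pause = truth.r(g.transcript_id, dose, "pause")
                up = _draw_window_fragments(
                    rng, g, mconf.upstream_offset, mconf.amp_up * r_core, mconf, clen)
                down = _draw_window_fragments(
                    rng, g, mconf.downstream_offset, mconf.amp_down * r_pause, mconf, clen)
                for s in np.concatenate([up, down]):
                    frags.append(Interval(g.chrom, int(s), int(s) + mconf.frag_len, g.strand))
            # uniform background over the genome
            pos = rng.integers(0, total - mconf.frag_len, size=mconf.n_background)
            for p in np.sort(pos):
                ci = int(np.searchsorted(cum, p, side="right"))
                off = int(p - (cum[ci - 1] if ci else 0))
                off = min(off, chrom_len[chrom_names[ci]] - mconf.frag_len)
                frags.append(Interval(chrom_names[ci], off, off + mconf.frag_len, "."))
            samples.append(FragmentSet(model=model, track="BRD4", dose=dose,
                                       replicate=rep, is_input=False, fragments=frags))
    # matched input: uniform
    rng = _derive_seed(config.seed, "input", model)
    pos = rng.integers(0, total - config.frag_len, size=config.n_input)
    frags = []
    for p in np.sort(pos):
        ci = int(np.searchsorted(cum, p, side="right"))
        off = int(p - (cum[ci - 1] if ci else 0))
        off = min(off, chrom_len[chrom_names[ci]] - config.frag_len)
        frags.append(Interval(chrom_names[ci], off, off + config.frag_len, "."))
    samples.append(FragmentSet(model=model, track="input", dose=0.0,
                               replicate=1, is_input=True, fragments=frags))
    return samples, truth


def simulate_polii(config: SimulationConfig, truth: GroundTruth,
                   annotation: GenomeAnnotation, dose: float,
                   base_density: float = 1.0, noise_sd: float = 0.0,
                   seed_salt: str = "polii"):
    """Noiseless (by default) Pol II coverage at 1-bp resolution for one dose.

    Per gene, promoter density over [TSS-100, TSS+301) scales with
    (1 + tr_coupling * (1 - r_pause)) and body density over [TSS+301, TES)
    scales with max(r_pause, tr_body_floor): losing pause-site occupancy
    piles polymerase at the promoter and empties the body, so the true
    traveling-ratio fold change is computable from the ground truth.
    """
    from .coverage import CoverageTrack

    values = {c: np.zeros(n, dtype=np.float64) for c, n in config.chrom_sizes.items()}
    rng = _derive_seed(config.seed, seed_salt, f"{dose:g}")
    for g in annotation.genes:
        r_pause = truth.r(g.transcript_id, dose, "pause")
        prom_d = base_density * (1.0 + config.tr_coupling * (1.0 - r_pause))
        body_d = base_density * max(r_pause, config.tr_body_floor)
        arr = values[g.chrom]
        sign = 1 if g.strand == "+" else -1
        if g.strand == "+":
            prom = (g.tss - 100, g.tss + 301)
            body = (g.tss + 301, g.tes)
        else:
            prom = (g.tss - 300, g.tss + 101)
            body = (g.tes, g.tss - 300)
        p0, p1 = max(0, prom[0]), min(len(arr), prom[1])
        b0, b1 = max(0, body[0]), min(len(arr), body[1])
        if p1 > p0:
            arr[p0:p1] += prom_d
        if b1 > b0:
            arr[b0:b1] += body_d
        if noise_sd > 0:
            lo = min(p0, b0) if b1 > b0 else p0
            hi = max(p1, b1) if b1 > b0 else p1
            arr[lo:hi] += rng.normal(0.0, noise_sd, hi - lo).astype(np.float32)
    return CoverageTrack(bin_size=1, values=values, normalization="raw",
                         effective_genome_size=sum(config.chrom_sizes.values()))


def true_tr_fold_change(config: SimulationConfig, r_pause: float) -> float:
    """Coupling-law traveling-ratio fold change implied by a remaining
    pause-site fraction: (1 + c*(1-r)) / max(r, floor)."""
    return (1.0 + config.tr_coupling * (1.0 - r_pause)) / max(r_pause, config.tr_body_floor)


def simulate_expression(config: SimulationConfig, truth: GroundTruth,
                        annotation: GenomeAnnotation,
                        seed_salt: str = "expression") -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB expression counts (genes x samples) for all doses.

    Mean mu_g * 2^(true LFC at the sample's dose); vehicle replicates share
    mu_g; dispersion = noise_dispersion via Gamma-Poisson.
    """
    rng = _derive_seed(config.seed, seed_salt)
    genes = [g.gene_id for g in annotation.genes]
    lo, hi = config.expr_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), len(genes)))
    disp = config.noise_dispersion
    cols, data = [], []
    for dose in config.doses:
        lfc = np.array([truth.expression_lfc[(g, dose)] for g in genes])
        mean = mu * np.power(2.0, lfc)
        for rep in range(1, config.n_replicates + 1):
            lam = rng.gamma(1.0 / disp, disp * mean) if disp > 0 else mean
            counts = rng.poisson(lam)
            cols.append(f"dose{dose:g}_rep{rep}")
            data.append(counts)
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    counts.index.name = "gene_id"
    lfc_rows = [
        {"gene_id": g, "dose": d, "true_lfc": truth.expression_lfc[(g, d)]}
        for g in genes for d in config.doses if d > 0
    ]
    return counts, pd.DataFrame(lfc_rows)


def simulate_qpcr(fold_changes: dict, eff_target: float = 1.0, eff_ref: float = 1.0,
                  ct_ref: float = 20.0, ct_target_base: float = 24.0,
                  n_replicates: int = 4, noise_sd: float = 0.05,
                  seed: int = 0) -> pd.DataFrame:
    """Ct tables for target transcripts under vehicle and treatment.

    Inverts the efficiency-corrected relative-abundance equation
    X = (1+EffR)^CtR / (1+EffX)^CtX: treatment changes target abundance by
    the given fold change, so CtX shifts by -log(fold)/log(1+EffX); Gaussian
    Ct noise of sd ``noise_sd`` is added per replicate.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    rows = []
    for target, fold in fold_changes.items():
        if fold <= 0:
            raise ValueError("fold change must be positive")
        shift = -math.log(fold) / math.log(1.0 + eff_target)
        for cond, ct_x in (("DMSO", ct_target_base), ("treated", ct_target_base + shift)):
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "sample": f"{target}_{cond}_{rep}", "target": target,
                    "condition": cond, "replicate": rep,
                    "ct_target": ct_x + rng.normal(0.0, noise_sd),
                    "ct_ref": ct_ref + rng.normal(0.0, noise_sd),
                    "eff_target": eff_target, "eff_ref": eff_ref,
                })
    return pd.DataFrame(rows)
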