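"""Seeded synthetic-data generators for every pipeline input.

Forward models mirror the measurement models the analysis inverts:

* a random genome with non-overlapping regions and PWM-sampled motif
  instances planted into a known subset of regions;
* two-condition negative-binomial region counts (Var = mu + alpha*mu^2)
  where motif-bearing regions shift accessibility in treatment, with
  per-sample depth factors, against a common control;
* per-cell FRET sensor traces with rest / treatment / chelation /
  saturation phases, emitting raw donor/acceptor channel intensities whose
  background-corrected ratio equals the Hill-model ratio plus Gaussian
  noise (chelation and saturation are emitted at the apo and saturated
  limits R_min and R_max, which is what an in-situ calibration assumes);
* qPCR plates with input dilution series (1, 1:10, 1:100, 1:1,000), +Ab and
  -Ab immunoprecipitations and no-template controls, following the
  log-linear amplification model Ct = intercept + slope*log10(quantity).

A single global seed fans out to fixed per-generator child seeds, so each
stage is independently reproducible; identical configs give byte-identical
outputs. Every generator records a machine-readable truth table.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffacc import CountMatrix
from .intervals import GenomicInterval, RegionSet
from .motifs import BASES, PWM
from .qpcr import Volumes

__all__ = [
    "SynthConfig",
    "FretSimParams",
    "QpcrSimParams",
    "child_rng",
    "make_genome",
    "make_motifs",
    "plant_motifs",
    "simulate_counts",
    "simulate_fret",
    "simulate_qpcr",
    "write_fasta",
    "generate_all",
]

# fixed stage keys for seed fan-out
_STAGE_KEYS = {
    "genome": 1,
    "motifs": 2,
    "plant": 3,
    "counts": 4,
    "fret": 5,
    "qpcr": 6,
    "genes": 7,
    "chip": 8,
}

_LOG10_2 = math.log10(2.0)


@dataclass(frozen=True)
class FretSimParams:
    """Forward-model parameters for the nuclear Zn2+ FRET sensor traces.

    Defaults emulate the study conditions: resting labile Zn2+ of 150 pM
    rising to 75 nM under ZnCl2 treatment, sensor K_d = 5.3 nM and Hill
    n = 0.29, dynamic range r_min=1 to r_max=3.
    """

    zn_rest_nM: float = 0.15
    zn_treatment_nM: float = 75.0
    kd_nM: float = 5.3
    hill_n: float = 0.29
    r_min: float = 1.0
    r_max: float = 3.0
    noise_sd: float = 0.02
    n_cells: int = 50
    frames_per_phase: int = 20
    frame_interval_s: float = 30.0
    donor_level: float = 1000.0
    donor_bg: float = 100.0
    acceptor_bg: float = 100.0

    def __post_init__(self) -> None:
        if self.r_max <= self.r_min:
            raise ValueError("r_max must exceed r_min")
        if min(self.zn_rest_nM, self.zn_treatment_nM) <= 0:
            raise ValueError("phase Zn2+ concentrations must be > 0")

    def ratio_for(self, zn_nM: float) -> float:
        """Forward Hill model: R = (r_min + r_max*u)/(1+u), u = (Zn/Kd)^n."""
        u = (zn_nM / self.kd_nM) ** self.hill_n
        return (self.r_min + self.r_max * u) / (1.0 + u)


def _default_bound_fractions() -> dict[tuple[str, str], float]:
    """+Ab bound fractions per (target, condition).

    EGR1 values are parameterized so the true signal-to-noise (over the flat
    -Ab background of 0.002) reproduces the reported pattern of a low-SNR
    target responsive to zinc elevation; CDKN1A plays the strong positive
    control and NEG_CTRL sits at the background.
    """
    return {
        ("CDKN1A", "control"): 0.0240,
        ("CDKN1A", "tpa"): 0.0160,
        ("CDKN1A", "zncl2"): 0.0300,
        ("EGR1", "control"): 0.00648,
        ("EGR1", "tpa"): 0.00704,
        ("EGR1", "zncl2"): 0.01582,
        ("SFN", "control"): 0.0120,
        ("SFN", "tpa"): 0.0180,
        ("SFN", "zncl2"): 0.0140,
        ("NEG_CTRL", "control"): 0.002,
        ("NEG_CTRL", "tpa"): 0.002,
        ("NEG_CTRL", "zncl2"): 0.002,
    }


@dataclass(frozen=True)
class QpcrSimParams:
    """Forward model for ChIP-qPCR plates.

    ct_slope defaults to -1/log10(2) (perfect doubling chemistry, one
    dilution decade adds ~3.3219 cycles). bound_fraction maps
    (target, condition) to the +Ab immunoprecipitated fraction of input
    chromatin; minus_ab_fraction is the beads-only background.
    """

    conditions: tuple[str, ...] = ("control", "tpa", "zncl2")
    bound_fraction: dict = field(default_factory=_default_bound_fractions)
    minus_ab_fraction: float = 0.002
    ct_intercept: float = 24.0
    ct_slope: float = -1.0 / _LOG10_2
    ct_noise_sd: float = 0.15
    n_bio_replicates: int = 6
    n_tech_replicates: int = 2
    dilution_factors: tuple[int, ...] = (1, 10, 100, 1000)
    volumes: Volumes = field(default_factory=Volumes)

    def __post_init__(self) -> None:
        if self.ct_slope >= 0:
            raise ValueError("ct_slope must be negative")
        for key, frac in self.bound_fraction.items():
            if not (0 < frac <= 1):
                raise ValueError(f"bound_fraction {key} must be in (0, 1]")

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(t for t, _ in self.bound_fraction))


@dataclass(frozen=True)
class SynthConfig:
    """All generator parameters; defaults are the study-scale conditions.

    2,000 regions, a planted motif in 30% of them with a +1 log2
    accessibility effect in treatment, 5 replicates per condition at an
    expected control count of 200 with NB dispersion 0.05, and 20 decoy
    motifs alongside the planted one.
    """

    seed: int = 0
    genome_length: int = 20_000_000
    gc_fraction: float = 0.45
    n_regions: int = 2000
    region_length: int = 200
    n_motifs: int = 21
    motif_width: int = 14
    planted_motif_id: str = "motif_000"
    plant_fraction: float = 0.3
    effect_log2fc: float = 1.0
    nb_mean: float = 200.0
    nb_dispersion: float = 0.05
    n_replicates: int = 5
    baseline_sigma: float = 0.25  # lognormal spread of per-region baselines
    depth_sigma: float = 0.1  # lognormal spread of per-sample depth factors
    fret: FretSimParams = field(default_factory=FretSimParams)
    qpcr: QpcrSimParams = field(default_factory=QpcrSimParams)

    def __post_init__(self) -> None:
        if not (0 <= self.gc_fraction <= 1):
            raise ValueError("gc_fraction must be in [0, 1]")
        if not (0 <= self.plant_fraction <= 1):
            raise ValueError("plant_fraction must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.nb_mean < 0:
            raise ValueError("nb_mean must be >= 0")
        if self.region_length < self.motif_width:
            raise ValueError("region_length must be >= motif_width")
        if self.genome_length < self.n_regions * self.region_length:
            raise ValueError("genome too short for the requested regions")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["qpcr"]["bound_fraction"] = {
            f"{t}/{c}": v for (t, c), v in self.qpcr.bound_fraction.items()
        }
        data["qpcr"]["volumes"] = asdict(self.qpcr.volumes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fret" in data:
            data["fret"] = FretSimParams(**data["fret"])
        if "qpcr" in data:
            q = dict(data["qpcr"])
            if "bound_fraction" in q:
                q["bound_fraction"] = {
                    tuple(k.split("/")): v for k, v in q["bound_fraction"].items()
                }
            if "volumes" in q:
                q["volumes"] = Volumes(**q["volumes"])
            if "conditions" in q:
                q["conditions"] = tuple(q["conditions"])
            if "dilution_factors" in q:
                q["dilution_factors"] = tuple(q["dilution_factors"])
            data["qpcr"] = QpcrSimParams(**q)
        return cls(**data)


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Fixed seed fan-out: one global seed, one fixed child stream per stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STAGE_KEYS[stage]])
    )


# ---------------------------------------------------------------------------
# Genome, motifs, planting


def make_genome(cfg: SynthConfig) -> tuple[dict[str, str], RegionSet]:
    """I.i.d. genome at the configured GC fraction with non-overlapping regions.

    Regions are placed uniformly at random among all non-overlapping
    configurations (sorted-gap construction) on a single chromosome and
    recorded 0-based half-open.
    """
    rng = child_rng(cfg.seed, "genome")
    gc = cfg.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=cfg.genome_length, p=probs)
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    genome = {"chr1": lut[codes].tobytes().decode("ascii")}
    free = cfg.genome_length - cfg.n_regions * cfg.region_length
    gaps = np.sort(rng.integers(0, free + 1, size=cfg.n_regions))
    starts = gaps + np.arange(cfg.n_regions) * cfg.region_length
    width = len(str(cfg.n_regions - 1))
    regions = RegionSet(
        [
            GenomicInterval(
                "chr1",
                int(s),
                int(s) + cfg.region_length,
                f"region_{i:0{width}d}",
            )
            for i, s in enumerate(starts)
        ]
    )
    return genome, regions


def make_motifs(cfg: SynthConfig) -> list[PWM]:
    """Random near-consensus PWMs: 0.97 on the consensus base, 0.01 elsewhere.

    The first motif carries ``cfg.planted_motif_id``; the rest are decoys.
    """
    rng = child_rng(cfg.seed, "motifs")
    width_ids = max(3, len(str(cfg.n_motifs - 1)))
    pwms = []
    for m in range(cfg.n_motifs):
        consensus = rng.integers(0, 4, size=cfg.motif_width)
        mat = np.full((cfg.motif_width, 4), 0.01)
        mat[np.arange(cfg.motif_width), consensus] = 0.97
        motif_id = (
            cfg.planted_motif_id if m == 0 else f"motif_{m:0{width_ids}d}"
        )
        pwms.append(PWM(motif_id, mat))
    return pwms


def plant_motifs(
    genome: dict[str, str],
    regions: RegionSet,
    pwm: PWM,
    plant_fraction: float,
    rng: np.random.Generator | int,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant one PWM-sampled site into a random ceil(f*n) subset of regions.

    Each planted site replaces bases at a random offset within the region,
    on a random strand; the truth table records (region_id, chrom,
    genome_start, offset, strand, site). plant_fraction=0 leaves the genome
    unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if pwm.width > min((len(r) for r in regions), default=pwm.width):
        raise ValueError("motif wider than the narrowest region")
    n_plant = math.ceil(plant_fraction * len(regions))
    chosen = sorted(rng.choice(len(regions), size=n_plant, replace=False))
    arrays = {c: bytearray(s, "ascii") for c, s in genome.items()}
    rows = []
    from .motifs import reverse_complement

    for i in chosen:
        iv = regions[i]
        offset = int(rng.integers(0, len(iv) - pwm.width + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = pwm.sample_site(rng)
        inserted = site if strand == "+" else reverse_complement(site)
        start = iv.start + offset
        arrays[iv.chrom][start : start + pwm.width] = inserted.encode("ascii")
        rows.append((iv.name, iv.chrom, start, offset, strand, site))
    truth = pd.DataFrame(
        rows,
        columns=["region_id", "chrom", "genome_start", "offset", "strand", "site"],
    )
    return {c: a.decode("ascii") for c, a in arrays.items()}, truth


def make_genes(
    cfg: SynthConfig,
    regions: RegionSet,
    promoter_fraction: float = 0.35,
    genic_fraction: float = 0.25,
    promoter_length: int = 1000,
    rng: np.random.Generator | None = None,
):
    """Synthetic gene annotation giving regions a promoter/genic/nongenic mix.

    A random ``promoter_fraction`` of regions receive a downstream gene whose
    TSS places the region inside the promoter window; a further
    ``genic_fraction`` receive a gene body spanning them; the rest stay
    nongenic. Returns a list of GeneAnnotation.
    """
    from .intervals import GeneAnnotation

    rng = rng or child_rng(cfg.seed, "genes")
    n = len(regions)
    order = rng.permutation(n)
    n_prom = int(promoter_fraction * n)
    n_genic = int(genic_fraction * n)
    genes = []
    for j, i in enumerate(order[:n_prom]):
        iv = regions[int(i)]
        tss = iv.end + int(rng.integers(0, max(1, promoter_length - len(iv))))
        genes.append(
            GeneAnnotation(f"geneP_{j:04d}", iv.chrom, tss, tss + 5000, "+")
        )
    for j, i in enumerate(order[n_prom : n_prom + n_genic]):
        iv = regions[int(i)]
        start = max(0, iv.start - 2000)
        genes.append(
            GeneAnnotation(f"geneB_{j:04d}", iv.chrom, start, iv.end + 2000, "+")
        )
    return genes


def simulate_chip_candidates(
    cfg: SynthConfig,
    n_chip: int = 100,
    n_transcribed: int = 40,
    n_differential: int = 10,
    peak_length: int = 500,
    conditions: tuple[str, ...] = ("tpa", "zncl2"),
    rng: np.random.Generator | None = None,
) -> dict:
    """Synthetic candidate-selection scenario: ChIP peaks, transcription, counts.

    ``n_chip`` non-overlapping ChIP peaks; ``n_transcribed`` of them overlap
    a transcribed region for 80% of their length (the rest overlap 20% or
    not at all, failing a 50% filter); ``n_differential`` of the transcribed
    ones get the configured accessibility effect in the first listed
    perturbation. Counts cover all ChIP peaks for control plus each
    perturbation at ``cfg.n_replicates`` each.
    """
    rng = rng or child_rng(cfg.seed, "chip")
    span = n_chip * peak_length * 20
    free = span - n_chip * peak_length
    gaps = np.sort(rng.integers(0, free + 1, size=n_chip))
    starts = gaps + np.arange(n_chip) * peak_length
    chip = RegionSet(
        [
            GenomicInterval("chrC", int(s), int(s) + peak_length, f"chip_{i:03d}")
            for i, s in enumerate(starts)
        ]
    )
    order = rng.permutation(n_chip)
    transcribed_idx = np.sort(order[:n_transcribed])
    weak_idx = np.sort(order[n_transcribed : n_transcribed + n_chip // 4])
    tx = []
    for i in transcribed_idx:
        iv = chip[int(i)]
        tx.append(
            GenomicInterval(
                "chrC", iv.start, iv.start + int(0.8 * peak_length), f"tx_{i:03d}"
            )
        )
    for i in weak_idx:  # sub-threshold overlaps exercise the filter
        iv = chip[int(i)]
        tx.append(
            GenomicInterval(
                "chrC", iv.start, iv.start + int(0.2 * peak_length), f"txw_{i:03d}"
            )
        )
    transcription = RegionSet(tx)
    da_idx = np.sort(rng.choice(transcribed_idx, size=n_differential, replace=False))
    da_names = {chip[int(i)].name for i in da_idx}
    truth = pd.DataFrame(
        {
            "region_id": [iv.name for iv in chip],
            "transcribed": [
                i in set(transcribed_idx.tolist()) for i in range(n_chip)
            ],
            "differential": [iv.name in da_names for iv in chip],
        }
    )
    pseudo_plant = truth.loc[truth["differential"], ["region_id"]]
    chip_cfg = replace(cfg, n_regions=n_chip, region_length=peak_length)
    cond_effects = {c: 0.0 for c in conditions}
    cond_effects[conditions[0]] = cfg.effect_log2fc
    cm, counts_truth = simulate_counts(
        chip, pseudo_plant, chip_cfg, conditions=cond_effects, rng=rng
    )
    return {
        "chip_peaks": chip,
        "transcription": transcription,
        "count_matrix": cm,
        "truth": truth,
        "counts_truth": counts_truth,
    }


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    regions: RegionSet,
    truth: pd.DataFrame,
    cfg: SynthConfig,
    conditions: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, dict]:
    """NB counts per region x sample against a common control.

    ``conditions`` maps each treatment condition to the log2 accessibility
    shift applied to motif-bearing regions (default: one "treatment" at
    ``cfg.effect_log2fc``). Per-region lognormal baselines and per-sample
    lognormal depth factors are drawn and recorded in the returned truth
    dict. Counts follow NB with Var = mu + alpha*mu^2 (Poisson at alpha=0).
    """
    if cfg.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if cfg.nb_mean < 0:
        raise ValueError("nb_mean must be >= 0")
    rng = rng or child_rng(cfg.seed, "counts")
    conditions = conditions if conditions is not None else {
        "treatment": cfg.effect_log2fc
    }
    names = [r.name for r in regions]
    planted = pd.Index(names).isin(truth["region_id"])
    baselines = cfg.nb_mean * np.exp(
        rng.normal(0.0, cfg.baseline_sigma, size=len(names))
    )
    sample_ids, cond_labels, cols = [], [], []
    all_conditions = {"control": 0.0, **conditions}
    for cond, effect in all_conditions.items():
        mu_cond = baselines * np.where(planted, 2.0**effect, 1.0)
        for r in range(cfg.n_replicates):
            depth = float(np.exp(rng.normal(0.0, cfg.depth_sigma)))
            mu = mu_cond * depth
            if cfg.nb_dispersion > 0:
                size = 1.0 / cfg.nb_dispersion
                k = rng.negative_binomial(size, size / (size + mu))
            else:
                k = rng.poisson(mu)
            sid = f"{cond}_{r + 1}"
            sample_ids.append(sid)
            cond_labels.append(cond)
            cols.append((k, depth))
    counts = pd.DataFrame(
        {sid: k for sid, (k, _) in zip(sample_ids, cols)},
        index=pd.Index(names, name="region_id"),
    )
    cm = CountMatrix(counts, pd.Series(cond_labels, index=sample_ids))
    truth_out = {
        "baselines": pd.Series(baselines, index=names, name="baseline_mean"),
        "depth_factors": pd.Series(
            [d for _, d in cols], index=sample_ids, name="depth_factor"
        ),
        "motif_bearing": pd.Series(planted, index=names, name="motif_bearing"),
        "effects": all_conditions,
    }
    return cm, truth_out


# ---------------------------------------------------------------------------
# FRET traces


def simulate_fret(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell four-phase sensor traces plus a per-cell/phase truth table.

    Rest and treatment ratios follow the forward Hill model at the
    configured true concentrations; chelation and saturation are emitted at
    the sensor limits r_min and r_max. Channel intensities are emitted (not
    ratios): the background-corrected acceptor/donor ratio equals the phase
    ratio plus N(0, noise_sd) per frame.
    """
    p = cfg.fret
    rng = rng or child_rng(cfg.seed, "fret")
    phase_truth = {
        "rest": (p.zn_rest_nM, p.ratio_for(p.zn_rest_nM)),
        "treatment": (p.zn_treatment_nM, p.ratio_for(p.zn_treatment_nM)),
        "chelation": (np.nan, p.r_min),
        "saturation": (np.nan, p.r_max),
    }
    rows, truth_rows = [], []
    for cell in range(p.n_cells):
        cell_id = f"cell_{cell:03d}"
        t = 0.0
        for phase, (zn, r_true) in phase_truth.items():
            noise = rng.normal(0.0, p.noise_sd, size=p.frames_per_phase)
            for f in range(p.frames_per_phase):
                donor_corr = p.donor_level
                acceptor_corr = (r_true + noise[f]) * donor_corr
                rows.append(
                    (
                        cell_id,
                        round(t, 3),
                        phase,
                        donor_corr + p.donor_bg,
                        acceptor_corr + p.acceptor_bg,
                        p.donor_bg,
                        p.acceptor_bg,
                    )
                )
                t += p.frame_interval_s
            truth_rows.append((cell_id, phase, zn, r_true))
    traces = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "time_s", "phase", "donor", "acceptor",
            "donor_bg", "acceptor_bg",
        ],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "phase", "true_zn_nM", "true_ratio"]
    )
    return traces, truth


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ChIP-qPCR plates for all targets, conditions and replicates.

    Wells: input dilutions (1, 1:10, 1:100, 1:1,000), +Ab IP, -Ab IP, and a
    no-template control per target/condition/replicate, each in technical
    duplicate. Ct = intercept + slope*log10(quantity) + noise; the relative
    quantity of the IP eluate follows from the bound fraction and the
    volume bookkeeping, so the true %IP equals 100 x bound fraction.
    """
    q = cfg.qpcr
    rng = rng or child_rng(cfg.seed, "qpcr")
    v = q.volumes
    ip_scale = (v.chromatin_for_chip / v.chip_eluate) / (
        v.chromatin_as_input / v.input_eluate
    )
    rows, truth_rows = [], []
    well = 0
    for rep in range(1, q.n_bio_replicates + 1):
        for target in q.targets:
            for cond in q.conditions:
                bound = q.bound_fraction[(target, cond)]
                specs = [
                    ("input_dilution", d, 1.0 / d) for d in q.dilution_factors
                ]
                specs.append(("ip_plus_ab", 1, bound * ip_scale))
                specs.append(("ip_minus_ab", 1, q.minus_ab_fraction * ip_scale))
                specs.append(("ntc", 1, None))
                for sample_class, dilution, quantity in specs:
                    for tech in range(1, q.n_tech_replicates + 1):
                        well += 1
                        if quantity is None:
                            ct = np.nan
                        else:
                            ct = (
                                q.ct_intercept
                                + q.ct_slope * math.log10(quantity)
                                + rng.normal(0.0, q.ct_noise_sd)
                            )
                        rows.append(
                            (
                                f"W{well:05d}", target, sample_class, cond,
                                rep, dilution, tech, ct,
                            )
                        )
                truth_rows.append(
                    (
                        target, cond, rep, bound, 100.0 * bound,
                        bound / q.minus_ab_fraction,
                    )
                )
    plate = pd.DataFrame(
        rows,
        columns=[
            "well", "target", "sample_class", "condition", "replicate",
            "dilution_factor", "tech_rep", "ct",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "target", "condition", "replicate", "bound_fraction",
            "true_percent_ip", "true_snr",
        ],
    )
    return plate, truth


# ---------------------------------------------------------------------------
# Orchestration and file output


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_all(cfg: SynthConfig, outdir: str | Path) -> dict:
    """Run every generator and write all inputs plus truth files to ``outdir``.

    Returns the in-memory bundle (genome, regions, pwms, plant truth, count
    matrix and truth, FRET traces and truth, qPCR plate and truth) together
    with the written file paths.
    """
    from .intervals import write_bed
    from .motifs import write_meme

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, regions = make_genome(cfg)
    pwms = make_motifs(cfg)
    genome, plant_truth = plant_motifs(
        genome, regions, pwms[0], cfg.plant_fraction, child_rng(cfg.seed, "plant")
    )
    cm, counts_truth = simulate_counts(regions, plant_truth, cfg)
    traces, fret_truth = simulate_fret(cfg)
    plate, qpcr_truth = simulate_qpcr(cfg)

    paths = {
        "config": outdir / "config.yaml",
        "genome": outdir / "genome.fa",
        "regions": outdir / "regions.bed",
        "motifs": outdir / "motifs.meme",
        "plant_truth": outdir / "truth_planted_sites.tsv",
        "counts": outdir / "counts.tsv",
        "counts_truth": outdir / "truth_counts.tsv",
        "fret_traces": outdir / "fret_traces.tsv",
        "fret_truth": outdir / "truth_fret.tsv",
        "qpcr_plate": outdir / "qpcr_plate.tsv",
        "qpcr_truth": outdir / "truth_qpcr.tsv",
    }
    cfg.to_yaml(paths["config"])
    write_fasta(genome, paths["genome"])
    write_bed(regions, paths["regions"])
    write_meme(pwms, paths["motifs"])
    plant_truth.to_csv(paths["plant_truth"], sep="\t", index=False)
    cm.to_tsv(paths["counts"])
    counts_truth_df = pd.DataFrame(
        {
            "region_id": counts_truth["baselines"].index,
            "baseline_mean": counts_truth["baselines"].to_numpy(),
            "motif_bearing": counts_truth["motif_bearing"].to_numpy(),
        }
    )
    counts_truth_df.to_csv(paths["counts_truth"], sep="\t", index=False)
    traces.to_csv(paths["fret_traces"], sep="\t", index=False)
    fret_truth.to_csv(paths["fret_truth"], sep="\t", index=False)
    plate.to_csv(paths["qpcr_plate"], sep="\t", index=False)
    qpcr_truth.to_csv(paths["qpcr_truth"], sep="\t", index=False)

    return {
        "cfg": cfg,
        "genome": genome,
        "regions": regions,
        "pwms": pwms,
        "plant_truth": plant_truth,
        "count_matrix": cm,
        "counts_truth": counts_truth,
        "fret_traces": traces,
        "fret_truth": fret_truth,
        "qpcr_plate": plate,
        "qpcr_truth": qpcr_truth,
        "paths": paths,
    }
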