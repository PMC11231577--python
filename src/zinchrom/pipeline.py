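"""End-to-end orchestration and candidate-site selection.

``run_all`` executes the whole analysis on synthetic inputs — simulate,
annotate, scan, differential test, enrichment, zinc quantification, qPCR,
candidate selection — writing every output plus a manifest of input
parameters, seeds and output hashes. Reruns with the same config reproduce
identical hashes.

``select_candidates`` assembles the ChIP-site filter: ChIP peaks retained at
>= 50% overlap with transcribed regions, differential accessibility per
perturbation against the common control, BH adjustment, and the selection
criteria flags: (1) differentially accessible (padj <= cutoff) in at least
one perturbation, (2) overlaps a ChIP peak, (3) overlaps a transcribed
region at the required fraction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffacc, enrich, intervals, motifs, qpcr, synth, zinc
from .config import AnalysisConfig

__all__ = ["select_candidates", "run_all", "demo_synth_config"]

log = logging.getLogger("zinchrom")


def select_candidates(
    chip_peaks: intervals.RegionSet,
    transcription_regions: intervals.RegionSet,
    counts: diffacc.CountMatrix,
    cfg: AnalysisConfig | None = None,
    control: str = "control",
) -> pd.DataFrame:
    """Candidate binding sites from ChIP peaks, transcription and counts.

    Returns one row per retained ChIP peak with padj/log2FC per
    perturbation, the criteria flags and a ``selected`` conjunction, sorted
    by the minimum padj across perturbations. An empty post-filter set
    yields an empty frame (with a log message), not an error.
    """
    cfg = cfg or AnalysisConfig()
    retained = intervals.intersect_fraction(
        chip_peaks, transcription_regions, cfg.min_overlap_fraction
    )
    if len(retained) == 0:
        log.warning("no ChIP peaks pass the %.0f%% overlap filter",
                    100 * cfg.min_overlap_fraction)
        return pd.DataFrame(
            columns=["region_id", "chrom", "start", "end", "selected"]
        )
    names = [iv.name for iv in retained]
    sub = diffacc.CountMatrix(counts.counts.loc[names], counts.conditions)
    # Size factors come from the full ChIP-peak matrix: the retained subset
    # can be small and enriched for shifted regions, which would bias
    # median-of-ratios normalization.
    full_factors = diffacc.size_factors(counts.counts)
    perturbations = [
        c for c in dict.fromkeys(counts.conditions) if c != control
    ]
    out = retained.to_dataframe().rename(columns={"name": "region_id"})
    out = out[["region_id", "chrom", "start", "end"]].set_index("region_id")
    padj_cols = []
    for pert in perturbations:
        pair = counts.samples_for(control) + counts.samples_for(pert)
        res = diffacc.nb_wald_test(
            sub, control=control, treatment=pert, factors=full_factors[pair]
        )
        out[f"log2fc_{pert}"] = res["log2FoldChange"]
        out[f"padj_{pert}"] = res["padj"]
        padj_cols.append(f"padj_{pert}")
    out["criterion_differential"] = (
        (out[padj_cols] <= cfg.padj_cutoff).any(axis=1)
        if padj_cols
        else False
    )
    out["criterion_chip_overlap"] = True  # retained peaks are ChIP peaks
    out["criterion_transcribed"] = True  # enforced by the overlap filter
    out["selected"] = (
        out["criterion_differential"]
        & out["criterion_chip_overlap"]
        & out["criterion_transcribed"]
    )
    out["min_padj"] = out[padj_cols].min(axis=1) if padj_cols else np.nan
    return out.sort_values("min_padj", kind="mergesort").reset_index()


def demo_synth_config(seed: int = 0) -> synth.SynthConfig:
    """A reduced-scale configuration for quick end-to-end demonstration runs."""
    return synth.SynthConfig(
        seed=seed,
        genome_length=3_000_000,
        n_regions=300,
        n_motifs=6,
        fret=synth.FretSimParams(n_cells=25),
        qpcr=replace(synth.QpcrSimParams(), n_bio_replicates=3),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""


def run_all(
    synth_cfg: synth.SynthConfig,
    analysis_cfg: AnalysisConfig | None = None,
    outdir: str | Path = "zinchrom_run",
) -> dict:
    """Execute every stage on synthetic inputs and write a run manifest.

    Stages: simulate -> annotate -> diff -> scan -> enrichment -> zinc ->
    qpcr -> candidates. Any stage failure raises :class:`StageError` naming
    the stage. Returns the result bundle including the manifest dict.
    """
    analysis_cfg = analysis_cfg or AnalysisConfig(seed=synth_cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    t_all = time.perf_counter()

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %-10s done in %.1fs", name, time.perf_counter() - t0)
        return result

    sim = stage("simulate", lambda: synth.generate_all(synth_cfg, outdir / "inputs"))
    bundle["sim"] = sim

    genes = stage("annotate", lambda: synth.make_genes(synth_cfg, sim["regions"]))
    labels = intervals.annotate_regions(
        sim["regions"], genes, analysis_cfg.promoter_length
    )
    labels_path = outdir / "region_labels.tsv"
    labels.rename_axis("region_id").to_frame().to_csv(labels_path, sep="\t")

    diff = stage(
        "diff",
        lambda: diffacc.nb_wald_test(sim["count_matrix"]),
    )
    diff_path = outdir / "diff_results.tsv"
    diff.rename_axis("region_id").to_csv(diff_path, sep="\t")

    hits, hit_table = stage(
        "scan",
        lambda: motifs.scan_regions(
            sim["genome"],
            sim["regions"],
            [p.with_background(motifs.estimate_background(sim["genome"]))
             for p in sim["pwms"]],
            analysis_cfg,
        ),
    )
    hits_path = outdir / "motif_hits.tsv"
    hits.to_csv(hits_path, sep="\t", index=False)

    enr = stage(
        "enrichment",
        lambda: enrich.run_enrichment(diff, labels, hit_table, analysis_cfg),
    )
    enr_path = outdir / "enrichment_results.tsv"
    enr.to_csv(enr_path, sep="\t", index=False)

    zn = stage(
        "zinc",
        lambda: zinc.quantify_cells(
            sim["fret_traces"],
            zinc.CalibrationParams(
                kd_nM=synth_cfg.fret.kd_nM, hill_n=synth_cfg.fret.hill_n
            ),
        ),
    )
    zn_path = outdir / "zinc_estimates.tsv"
    zn.to_csv(zn_path, sep="\t", index=False)

    qp = stage(
        "qpcr",
        lambda: qpcr.analyze_plate(
            sim["qpcr_plate"],
            synth_cfg.qpcr.volumes,
            snr_reference=analysis_cfg.snr_reference,
        ),
    )
    qp_path = outdir / "qpcr_results.tsv"
    qp.to_csv(qp_path, sep="\t", index=False)

    chip = stage("candidates_sim", lambda: synth.simulate_chip_candidates(synth_cfg))
    cands = stage(
        "candidates",
        lambda: select_candidates(
            chip["chip_peaks"],
            chip["transcription"],
            chip["count_matrix"],
            analysis_cfg,
        ),
    )
    cands_path = outdir / "candidates.tsv"
    cands.to_csv(cands_path, sep="\t", index=False)

    outputs = {
        "region_labels": labels_path,
        "diff_results": diff_path,
        "motif_hits": hits_path,
        "enrichment_results": enr_path,
        "zinc_estimates": zn_path,
        "qpcr_results": qp_path,
        "candidates": cands_path,
        **{f"input_{k}": v for k, v in sim["paths"].items()},
    }
    import zinchrom

    manifest = {
        "seed": synth_cfg.seed,
        "elapsed_s": round(time.perf_counter() - t_all, 2),
        "versions": {
            "zinchrom": zinchrom.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": {k: _sha256(Path(p)) for k, p in sorted(outputs.items())},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle.update(
        {
            "labels": labels,
            "diff": diff,
            "hits": hits,
            "hit_table": hit_table,
            "enrichment": enr,
            "zinc": zn,
            "qpcr": qp,
            "chip": chip,
            "candidates": cands,
            "manifest": manifest,
            "outputs": outputs,
            "manifest_path": manifest_path,
        }
    )
    return bundle
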