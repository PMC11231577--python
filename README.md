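# zinchrom

Analysis toolkit for studying how perturbations of the labile nuclear Zn²⁺
pool reshape chromatin accessibility and transcription-factor (TF) binding.
It covers the full arc of such an experiment:

1. **Nuclear Zn²⁺ quantification** from FRET-sensor intensity traces: the
   background-corrected ratio R = (acceptor − bg) / (donor − bg) is
   calibrated per cell (chelation → R_min, saturation → R_max) and inverted
   through the Hill equation

   [Zn²⁺] = K_d · ((R − R_min) / (R_max − R))^(1/n)

   with K_d = 5.3 nM and Hill coefficient n = 0.29 for the NLS-ZapCV2-class
   sensor, censoring estimates below the ~1 pM quantification floor.
2. **Differential accessibility** from ATAC-style region × sample count
   matrices: median-of-ratios size factors, a negative-binomial Wald-type
   test (Var = μ + αμ²) with Benjamini–Hochberg correction, producing a
   signed ranking statistic sign(log₂FC)·(−log₁₀ p) per region.
3. **Rank-based motif enrichment**: FIMO-style PWM scanning (exact DP
   p-values, both strands, ±1,500 bp windows around region centers,
   p ≤ 10⁻⁵) followed by a Mann–Whitney-type enrichment score
   E = 1 − 2·mean((r_h − ½)/N) over the ranked region list, with a
   permutation null, per-stratum BH correction (all / promoter / nongenic),
   and quartile barcode summaries.
4. **Candidate-site selection**: ChIP peaks retained at ≥ 50% overlap with
   transcribed regions, tested for differential accessibility per
   perturbation against a common control (P_adj ≤ 0.1).
5. **ChIP-qPCR quantification**: input dilution standard curves
   (Ct = b + m·log₁₀ q), percent input with eluate/chromatin volume
   accounting, signal-to-noise (+Ab vs −Ab), fold enrichment vs control,
   and Tukey-IQR outlier flags.

Because the underlying sequencing and imaging data live in external
repositories, the package ships a first-class **synthetic-data generator**
(`zinchrom.synth`) whose forward models mirror each measurement model —
planted PWM sites in a random genome, NB counts with motif-linked
accessibility shifts, four-phase sensor traces, log-linear qPCR plates —
so every stage is testable end-to-end against known truth.

## Worked example

Quantify nuclear Zn²⁺ from synthetic sensor traces generated at the default
study conditions (resting 150 pM, elevated 75 nM, ratio noise sd 0.02):

```python
import numpy as np
from zinchrom import synth, zinc

cfg = synth.SynthConfig(seed=1)          # study-scale defaults
traces, truth = synth.simulate_fret(cfg) # 50 cells, 4 phases, noisy channels
est = zinc.quantify_cells(traces)        # per-cell calibration + inversion

for phase in ("rest", "treatment"):
    q = est[(est.phase == phase) & (est.censor == "quantified")]
    print(f"{phase:9s} median [Zn2+] = {np.median(q.zn_nM):8.3f} nM  (n={len(q)})")
```

prints

```
rest      median [Zn2+] =    0.147 nM  (n=50)
treatment median [Zn2+] =   74.769 nM  (n=50)
```

i.e., the per-cell calibration recovers the true resting (0.15 nM) and
elevated (75 nM) concentrations to within a few percent despite frame-level
ratio noise. The same pattern holds across the package: generators plant a
known truth, the analysis recovers it, and the tests assert the tolerances.

A full seeded run of every stage (simulate → annotate → differential test →
scan → enrichment → zinc → qPCR → candidates), with a manifest of output
hashes, is available from the command line:

```sh
zinchrom -v run-all --seed 1 --out demo_run
```

## Layout

| module | contents |
|---|---|
| `zinchrom.intervals` | half-open genomic intervals, BED I/O, merge / blacklist / fractional-overlap / promoter annotation |
| `zinchrom.motifs` | PWMs (MEME-minimal + TSV), log-odds scoring, exact DP p-values, window scanning |
| `zinchrom.diffacc` | count matrices, size factors, NB Wald-type test, BH |
| `zinchrom.enrich` | ranked lists, E-score, permutation null, barcodes, stratified assembly |
| `zinchrom.zinc` | FRET ratios, per-cell calibration, Hill inversion with censoring |
| `zinchrom.qpcr` | standard curves, %IP, SNR, fold enrichment, outliers |
| `zinchrom.synth` | seeded forward-model generators and truth tables |
| `zinchrom.pipeline` / `zinchrom.cli` | candidate selection, `run-all`, subcommands |

See `docs/methods.md` for the statistical models, parameter defaults, and
the design decisions behind them.
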