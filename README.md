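# domphoto

Analysis pipeline for coupled **photochemical–biological degradation of
dissolved organic matter (DOM)** in lakes, built for studies that pair
UV-exposure experiments with dark microbial incubations across a gradient
of lakes. It is aimed at aquatic biogeochemists who have:

* FT-ICR MS peak lists (negative ESI, centroided) per lake × treatment,
* UV-Vis absorbance spectra and fluorescence excitation–emission matrices,
* a sample table with DOC/DON and headspace CO₂ measured on days 0/7/28.

From these it computes, per lake:

1. **Molecular composition** — every S/N > 4 peak is assigned a unique
   CHONS formula (treated as [M−H]⁻; exhaustive enumeration within a ppm
   tolerance, 0.3 < H/C < 2.2, O/C < 1.2, 100–800 Da, least-heteroatom
   disambiguation), then indexed:
   DBE = 1 + (2C−H+N)/2, NOSC = 4 − (4C+H−3N−2O−2S)/C, and the modified
   aromaticity index AI_mod = (1 + C − O/2 − S − (N+H)/2)/(C − O/2 − N − S),
   with the four-class taxonomy CA (AI_mod > 0.66), Pol (0.50 < AI_mod ≤
   0.66), Uns (AI_mod ≤ 0.50, H/C < 1.5), Ali (1.5 ≤ H/C ≤ 2.0).
2. **Optical indices** — a₃₀₀ = 2.303·A(300)/path, SUVA₂₅₄, spectral slopes
   S₂₇₅₋₂₉₅ and S₃₅₀₋₄₀₀ (log-linear OLS) and their ratio S_R, BIX, HIX.
3. **Photo-produced / photo-degraded / bio-degraded compounds** — paired
   sample comparison by the dual 20% intensity-change rule (raw and
   total-normalised), cross-validated by a presence/absence method.
4. **The respiration link** — blank-corrected CO₂ production, response
   ratios RR = ln(light/dark), DOM content as PC1 of z-scored DOC and DON,
   and standardised regression coefficients (= Pearson r) relating CO₂-RR
   to the chemistry of the photo-produced pool, plus factorial ANOVA and
   rank-sum utilities with BH-FDR correction.

A first-class synthetic study generator (`domphoto.synthetic_data`)
emulates the whole design — 10 lakes × light/dark × 2 temperatures × 3
replicates — with exact ground truth, so every stage has a recovery test
without any external data. See `docs/methods.md` for the model and its
assumptions.

## Worked example

One command simulates a small study and runs every stage:

```bash
domphoto run-all --seed 1 --n-lakes 4 --formulas-per-lake 200 --out demo
```

which logs

```
INFO domphoto: DOM PC1 explains 99.6% of DOC/DON variance
INFO domphoto: CO2-RR ~ AI_mod(produced): coef=0.993 R2=0.987 p=0.006753 (n=4)
```

and writes `demo/lakes_summary.csv`:

```
lake_id  dom_pc1  co2_rr  n_produced  n_degraded  mean_ai_mod_produced  rr_a300_per_m  rr_suva254
    L01   -1.625  -0.556          26          25                 0.305         -0.163      -0.117
    L02   -0.596  -0.133          28          25                 0.322         -0.163      -0.121
    L03    0.605   0.301          30          27                 0.355         -0.163      -0.126
    L04    1.616   0.675          36          26                 0.375         -0.163      -0.130
```

Read: along the DOM gradient (`dom_pc1`), light exposure produces more and
more aromatic compounds (`mean_ai_mod_produced` rises), and the microbial
respiration response to light (`co2_rr`, the ln light/dark ratio of
blank-corrected CO₂ production) flips from inhibition (−0.556) to
stimulation (+0.675). The standardised coefficient of CO₂-RR on the mean
AI_mod of photo-produced compounds (0.993, p = 0.007 here) quantifies that
coupling; the generator built it in (β = 4 on the produced aromatic share),
and the pipeline recovers it from the raw peak lists. The negative optical
RRs reflect photobleaching of CDOM in the light treatment.

Individual stages are also subcommands (`simulate`, `assign`, `indices`,
`optics`, `diff`, `respond`) operating on plain CSV files, and everything
is importable as a library:

```python
from domphoto import (GeneratorConfig, synthesize_study, assign_peaklist,
                      compare_threshold, lake_co2_response, standardized_coef)

study = synthesize_study(GeneratorConfig(seed=1))
dark = assign_peaklist(study.pairs[0].dark)      # AnnotatedSample
light = assign_peaklist(study.pairs[0].light)
diff = compare_threshold(dark, light)            # produced/degraded/unchanged
```

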