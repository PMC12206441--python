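# kirquant

Quantification pipelines for loss-of-function studies of inward-rectifier
potassium (Kir) channels — built around the workflow used to characterise a
trafficking-deficient Kir4.2 variant, but applicable to any Kir-channel
wild-type/mutant comparison in a heterologous expression system.

The package covers the three quantitative arms such a study rests on, plus a
synthetic-data generator that makes every stage testable against exact
ground truth:

1. **Electrophysiology** (`kirquant.ephys`): paired voltage-ramp recordings
   (400 ms, +150 → −150 mV, holding 0 mV) under control conditions and in
   200 µM Ba²⁺. The Ba²⁺-sensitive current is the control-minus-Ba²⁺
   difference *I*(V); from it the pipeline computes the current density at
   −150 mV, CD = *I*(−150 mV)/*C*ₘ in pA/pF, the reversal potential *V*rev
   (zero crossing, near the K⁺ Nernst potential ≈ −5 mV for a 115/140 mM K⁺
   gradient at 22 °C), and the chord conductance

   &nbsp;&nbsp;&nbsp;&nbsp;*G*(V) = *I*Ba²⁺-sensitive(V) / (V − *V*rev)

   evaluated between −140 and −20 mV.
2. **Western-blot densitometry** (`kirquant.densitometry`): lane profiles,
   rolling-minimum background subtraction, detection and integration of the
   mature (~45 kDa) and immature (~43 kDa) glycoform bands plus an
   α-tubulin loading control, loading-normalised expression, upper/lower
   band ratios, and fold changes against a reference condition.
3. **Membrane-trafficking imaging** (`kirquant.image_quant`): the
   nucleus → cytoplasm → membrane segmentation procedure for three-channel
   fields (nuclear stain, Na⁺/K⁺-ATPase membrane marker, tagged channel):
   nucleoli-tolerant nucleus segmentation, median-cell-size-constrained
   cytoplasm expansion, marker-defined membrane ring, and per-cell metrics —
   membrane signal per ring area and membrane fraction of total signal.

Group comparisons (equal-variance unpaired *t* test, one-way ANOVA, star
annotation at *p* < 0.05/0.01/0.001/0.0001, no multiple-testing correction)
live in `kirquant.stats`; `kirquant.report` assembles the per-arm CSV
tables.

The synthetic generators (`kirquant.synthetic`) are first-class, tested
code. Their default presets are calibrated so that the true group values
equal the study's reference numbers: Ba²⁺-sensitive current densities of
−147.7 ± 23.1 pA/pF (WT, N = 5), −8.4 ± 2.3 (mutant, N = 7) and
−19.1 ± 3.2 (co-expression, N = 5); a mutant lane at 0.40× wild-type
abundance; untreated band ratios > 2 collapsing below 0.5 after enzymatic
deglycosylation; and cell fields with controllable expression level and
membrane-localised fraction.

## Worked example

Simulate the three recording groups at their default presets and run the
full ramp-analysis pipeline:

```python
from kirquant import ephys as ep
from kirquant.synthetic import ephys_preset, simulate_ramp_pair
from kirquant.stats import anova_oneway

summaries, groups = [], {}
for name in ("WT", "MT", "WT+MT"):
    pairs, _ = simulate_ramp_pair(ephys_preset(name, seed=1))
    cells = [ep.analyze_pair(ctrl, ba) for ctrl, ba in pairs]
    summaries.extend(cells)
    groups[name] = [c.cd_pa_per_pf for c in cells]

print(ep.summarize_groups(summaries).to_string(index=False))
cmp = anova_oneway(groups)
print(f"one-way ANOVA: F = {cmp.statistic:.1f}, p = {cmp.p_value:.2e} ({cmp.stars})")
```

which prints

```
group  n  mean_cd_pa_per_pf  sd_cd_pa_per_pf
   WT  5        -155.151905        13.923190
   MT  7          -8.669503         1.868382
WT+MT  5         -20.197352         1.977017
one-way ANOVA: F = 614.1, p = 2.31e-14 (****)
```

Five wild-type cells carry large inward Ba²⁺-sensitive currents (sample
mean −155.2 pA/pF, within sampling error of the −147.7 calibration target),
the homomeric mutant is essentially silent, the equimolar co-expression is
suppressed far below half of wild-type (a dominant-negative pattern), and
the three groups separate decisively (****).

The same flow is available from the shell:

```sh
kirquant simulate ephys --preset WT --seed 1 --out wt/
kirquant ephys analyze --pairs wt/pairs.csv --out out/
kirquant simulate blot --preset WT --preset MT --seed 1 --out blot/
kirquant blot quantify --stack blot/lanes.tif --meta blot/lanes_meta.csv \
    --ladder blot/ladder.csv --out out/
kirquant simulate cells --preset WT --seed 1 --out cells/
kirquant cells quantify --images cells/ --group WT --out out/
kirquant report build --in out/ --out report/
```

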