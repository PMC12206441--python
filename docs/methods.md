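# Methods

This note documents the models behind the synthetic generators, the
numerical choices in each analysis stage, and what the test suite does and
does not demonstrate about real data.

## Electrophysiology

### Current model of the generator

Whole-cell membrane current during the ramp is modelled as a rectified Kir
conductance plus an ohmic leak, both expressed as conductance densities so
the whole-cell current scales with capacitance:

    i(V) = [ g_kir · r(V) · (V − E_rev) + g_leak · V ] · C_m + ε,
    r(V) = 1 / (1 + exp((V − V_h) / k)),

with ε i.i.d. Gaussian per sample. The Boltzmann factor r(V) is not a
mechanistic gating model — the recording protocol constrains only the
stimulus, not the current shape — it is simply a smooth, monotone,
two-parameter inward-rectifying envelope (defaults V_h = −10 mV,
k = 25 mV) that exercises the analysis. Ba²⁺ multiplies g_kir by
(1 − ba_block_frac), default block 0.95 at 200 µM, and leaves the leak
untouched, so control-minus-Ba²⁺ subtraction isolates exactly the blocked
component. The leak reverses at 0 mV, consistent with a near-symmetrical
K⁺ gradient; the Kir component reverses at E_rev = −5 mV, the Nernst
potential for 115 mM external / 140 mM internal K⁺ at 22 °C.

The protocol is a 400 ms linear ramp from +150 to −150 mV between 50 ms
holds at 0 mV, sampled at 10 kHz. Sweep noise defaults to 10 pA SD;
capacitance defaults to 12 pF with ±10 % uniform jitter per cell, typical
of HEK293T cells.

### Calibration and variability placement

The per-cell ground-truth readout is the Ba²⁺-sensitive current density at
−150 mV,

    CD = g_kir · ba_block_frac · r(−150) · (−150 − E_rev)   [pA/pF].

Group presets are calibrated by inverting this relation so that the *true*
group mean equals the reference value (−147.7, −8.4 and −19.1 pA/pF for
WT, mutant, and equimolar co-expression) and the *between-cell* SD of CD
equals the reference SD (23.1, 2.3, 3.2 pA/pF). All biological variability
is placed between cells, on g_kir (normal, clipped at 0); within-cell
variability is additive trace noise only. This is a generator choice:
nothing in the calibration targets distinguishes between- from within-cell
spread, and placing it between cells makes the group SD directly
interpretable. Consequently the co-expression group is represented purely
by its aggregate conductance — no subunit-stoichiometry model is implied.

Because group sizes are small (5–7 cells), a recovered group mean wanders
around its target with SE = SD/√N (≈10 pA/pF for the WT group); recovery
tests therefore check agreement within 2 SEM, the same band a replication
at the study's N would use.

### Analysis choices

* The ramp segment is located from the command-voltage slope (longest
  monotonically falling run spanning ≥ 100 mV), not fixed sample indices,
  so CSV exports from different acquisition systems are handled alike.
* The −150 mV readout is the median of the difference current over
  ±1 mV — robust to single-sample noise without biasing the estimate.
  Since −150 mV is the ramp end, the window is effectively one-sided and
  reads ≈ −149.5 mV, a ~0.4 % underestimate of the magnitude; this is far
  below the between-cell spread and is accepted.
* V_rev is the zero crossing of the boxcar-smoothed (21-sample) difference
  current, refined by linear interpolation; with multiple crossings the one
  nearest the K⁺ Nernst prior (−5 mV) is taken. A trace with no sign
  change raises an error rather than extrapolating.
* Chord conductance is evaluated on a 2 mV grid restricted to
  [−140, −20] mV, excluding grid points within 5 mV of V_rev to avoid 0/0
  amplification near the reversal.
* No leak subtraction other than the Ba²⁺ subtraction, and no
  series-resistance or capacitance-compensation modelling (assumed handled
  at acquisition).
* Readers accept CSV traces (`time_s, v_mV, i_pA`) with a sidecar pairs
  table; no proprietary acquisition formats are parsed.

## Western-blot densitometry

### Generator

A lane is a 2-D patch with three Gaussian bands on a tilted baseline: the
mature (~45 kDa) and immature (~43 kDa) glycoforms splitting the target
abundance by `upper_frac`, plus an α-tubulin loading control (~50 kDa).
Band positions come from a ladder calibration linear in log(MW) over
10–250 kDa across a 900 px lane — the standard SDS-PAGE migration model —
which puts the 43/45 kDa pair ≈ 12.7 px apart. The default band width is
σ = 1.5 px so the pair is cleanly resolvable (centres 8.5 σ apart; the
generator refuses designs with centres closer than 3 σ). Lane-to-lane
biological/loading variability is a 8 % CV on the target and loading
amounts. Defaults: wild-type abundance 300 a.u. with `upper_frac` 0.70
(true ratio 2.33), mutant abundance 120 a.u. (0.40× wild-type), PNGase-like
deglycosylation preset `upper_frac` 0.05, Endo H-like preset 0.25.

### Analysis choices

* Lane profiles are column-wise means across the lane width.
* Background: a rolling-minimum (grey-opening) baseline with window
  8 × band σ. Under the bands themselves the opening is unreliable — on a
  rising baseline it hugs the left band tail — so the baseline is linearly
  interpolated across band regions (residual above 3× the robust noise SD,
  dilated by a 3 σ guard) from the flanking band-free anchors. The
  corrected profile is clipped at zero. The window and the guard are
  configuration, not magic numbers; with the defaults, noiseless band
  integrals are recovered to 0.1 % even on steeply tilted backgrounds.
* Band detection: local maxima above a detection floor of 3× the robust
  noise SD (high-frequency MAD estimator), each peak attributed to the
  *nearest* expected band so a neighbouring glycoform on the edge of
  another band's ±2 kDa window is never double-counted. Intensities are
  sums over centre ± 3 σ. An absent band reports 0 with an `absent` flag;
  an undetectable lower band makes the ratio NaN with a flag, never
  infinity.
* Normalisation: `norm_expression` = (upper + lower)/loading per lane;
  fold changes divide by the mean of the reference condition
  (non-transfected lanes never enter the reference), making them invariant
  to global exposure.
* Pre-integrated band tables (CSV) are accepted in place of images so the
  normalisation and statistics stages can be validated independently of
  peak detection.

Not modelled: gel warp, lane smile, saturation, multi-channel bleed-through.

## Membrane-trafficking imaging

### Generator

Each field (512² px default) contains non-overlapping disk cells: a bright
ring of configurable width (3 px) at the boundary (the membrane marker), an
elliptical nucleus strictly inside the interior with dark nucleoli spots,
and a target channel carrying `membrane_fraction` of each cell's total
intensity uniformly on the ring and the remainder uniformly in the
interior. Placement is rejection sampling with a minimum centre distance;
infeasible packings raise an error after a bounded number of attempts.
Per-cell totals have 15 % CV; noise is additive Gaussian with optional
Poisson shot-noise scaling. Defaults emulate the study contrast: wild-type
fields at full expression with membrane fraction 0.6, mutant-like fields at
0.4× expression with membrane fraction 0.4.

Ground truth records the nucleus/cell/ring label masks and per-cell
fractions, so segmentation accuracy is scored by IoU against exact masks
rather than by eye.

### Segmentation choices

* Nuclei: Gaussian smoothing (σ = 2 px) → Otsu threshold → hole filling
  (removes nucleoli) → watershed seeded at distance-transform maxima
  (splits touching nuclei) → [min, max] area filter. A blank channel is a
  valid empty result.
* Cells: the median cell radius is estimated from the combined
  marker+target foreground (area per contained nucleus per component);
  each nucleus seeds a watershed on the inverted smoothed intensity, masked
  to the hole-filled foreground and capped at 1.5× the median radius from
  the nucleus centroid (cells stay connected to their seed). With no usable
  cytoplasmic foreground the cells collapse to capped expansions of their
  nuclei and the field is flagged `low_foreground`.
* Membrane: the candidate band is the outer `membrane_width + slack`
  (3 + 3 px) of each cell label — the slack absorbs pixel-scale boundary
  error — intersected with marker-positive pixels, by default above half
  the peak smoothed marker intensity. Interior pixels are excluded by
  construction, which is how out-of-plane membrane signal contaminating
  the cytoplasm in confocal sections is kept out of the membrane estimate.
  Border-touching cells are retained but flagged `border_partial`.
* Quantification: the target channel is corrected by the image's robust
  background (median over non-cell pixels, clipped at zero); per cell,
  `mem_signal_per_area` = ring sum / ring area and `mem_fraction_of_total`
  = ring sum / whole-cell sum ∈ [0, 1]. Membrane area is normalised per
  cell (not per image); both metrics are reported so either convention can
  be aggregated. Cells with zero total signal report NaN with a flag.
* Aggregation applies a configurable positivity threshold on total target
  signal, mirroring the restriction to positively transfected cells; the
  exact criterion is a free parameter of any such analysis, so it is
  exposed rather than fixed.

The analysis is strictly 2-D: no 3-D reconstruction, deconvolution or
learned segmentation. Pixel-correlation colocalisation coefficients are
deliberately not used — membrane localisation is operationalised as signal
within the marker-defined ring, matching the two normalisations above.

### What passing tests show — and do not

On the generator's fixtures, segmentation recovers exact cell counts
(1–20 cells), compartment IoU ≥ 0.8–0.9, and membrane fractions within
±0.05 with perfect rank ordering across the 0.1–0.9 grid. Real confocal
fields are harder in ways the generator intentionally omits: irregular cell
shapes, contact between cells, intensity gradients, uneven marker
decoration, debris, and genuine 3-D structure. Passing the oracle suite
validates the *pipeline logic and normalisations*, not field-readiness on
arbitrary microscopy data; on real images the exposed thresholds and radii
will need tuning per dataset.

## Statistics

Equal-variance Student *t* (two-sided, unpaired) is the default to match
the study's naming; Welch is available by flag. One-way ANOVA is computed
from between/within mean squares with the natural degenerate conventions
(all observations identical → F = 0, p = 1; distinct means with zero
within-group scatter → F = ∞, p = 0); on two groups it satisfies F = t²
to numerical precision. Stars follow the strict-inequality convention
(p < 0.05 *, < 0.01 **, < 0.001 ***, < 0.0001 ****); p exactly at a cutoff
annotates at the weaker level. **No multiple-testing correction is applied
anywhere** — chord-conductance curves compared per voltage report raw
p-values (a two-factor group × voltage ANOVA is offered as an
alternative; neither is privileged). Cells are treated as independent
units; nesting of cells within images/replicates is not modelled.

## Determinism and problem sizes

Every generator consumes an explicit integer seed through NumPy's
`default_rng`; a fixed seed reproduces traces, lane stacks, fields and
ground truth bit for bit, and report CSVs are byte-identical across reruns.
Default problem sizes are those of the study design itself — 5/7/5 cells
for the recording groups, 3 replicate lanes per blot condition, fields of
~12 cells — so the full synthetic study, analysis and reporting complete in
seconds.
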