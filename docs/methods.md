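# Methods

## The assay model

Cells are encapsulated at Poisson occupancy (default λ = 0.3, configurable in
0.2–0.5) in 50 pL droplets packed as a monolayer in a 2-D observation chamber
and imaged as a stitched tile array (default 10×10) over 6 frames at 10-min
intervals (a 5-frame / 12-min variant is a config choice). Four channels are
modeled: a violet cell stain, a lactate probe, an intracellular ROS probe and
the oxidation-sensitive A647 channel that doubles as the IgG immunoassay
readout.

### NOX activity

The per-droplet statistic is the percent signal loss
`x = 100·(s(t₁) − s(lowest))/s(t₁)` with the minimum taken over frames 2…T.
Negative losses (rising signal) are retained unclamped; they can only classify
negative and keep the control distribution honest. The threshold is
`median(x) + 3·SD(x)` over probe-only control droplets, using the sample
(n−1) SD; the fixed default operating point is 10.3 %. Classification is a
strict inequality: a droplet exactly at the threshold is negative.

### Secretion and ROS

- IgG: relocation = beadline mean / droplet mean, inverted through the
  saturating exponential `R(c) = baseline + span·(1 − e^(−c/c₀))`
  (default baseline 1.0, span 4.0, c₀ 15 nM, giving ≈4.4× relocation near the
  top of the quantitative range). Molecules = c·V·N_A (1 pM in 50 pL ≈ 30.1
  molecules); the rate is the mean per-interval Δmolecules/Δt. Per-interval
  negatives are kept (noise); only the final mean clamps at 0. Gates:
  ≥ 9 IgG/s → secreting cell (boundary included), ≥ 285 IgG/s → above range.
  The upper bound is printed in two variants in the assay's source material
  (258 and 285 IgG/s); 285 is the default and 258 a config option — the
  package does not silently resolve the discrepancy.
- Lactate: linear calibration (default intercept 50 a.u., slope 2 a.u./µM),
  amounts in amol via the droplet volume; quantitative range 0.1–0.8 amol/s,
  rates ≥ 0.8 flagged above-range; droplets with ≠ 1 cell are excluded.
- ROS: per-interval increases of the cell signal averaged up to the frame of
  the signal maximum, rescaled to a 600 s window; maximum at the first frame
  gives slope 0.
- Droplets classified NOX-active in the same run get no IgG rate
  (`igg_uninterpretable`): the decaying A647 probe is the assay reagent.
- The human visual verification step of the original droplet curation is
  replaced by automated per-droplet flags (non-monotone relocation,
  calibration clamping).

### Transcriptomic gating

Subset assignment is argmax of the mean log2FC over each subset's marker
genes; exact ties and all-nonpositive scores give "unassigned". NOX_mRNA
status is positive iff **any** gene of the NOX set (NOX1-4, DUOX1-2, NOXO1,
NOXA1, CYBA, CYBB, NCF1/2/4, DUOXA1/2) has log2FC > 0 — chosen because cells
expressing a single isoform count as positive; a mean-aggregate mode is
available behind a switch. DEGs use a two-sided Mann-Whitney rank-sum test
(the upstream analysis tool is unspecified in the assay's source material)
with raw p-values and the 0.05 filter applied downstream; a BH column is
provided. Pathway modulation is the signed mean log2FC of the pathway's DEGs.
The housekeeping control (ATF1/2/4/6/7, BTF3, E2F4, JUND, HPRT, RPL3) passes
when all |mean log2FC| < 0.25 and no gene rejects a signed-rank test against 0
after BH across the control genes. Bundled marker and pathway YAMLs are
generic literature-style defaults meant to be replaced per study.

## The synthetic generator

The generator is the forward model of everything above, with planted ground
truth:

- A647 in a NOX-active droplet decays exponentially,
  `S(t) = S₀·e^(−kt)`, k set so the first-to-last-frame loss equals the
  planted terminal loss. The true decay kinetics are not established;
  exponential decay is this package's modeling choice, and the classifier
  statistic only depends on the terminal loss, which is controlled exactly.
- IgG/lactate channels apply the forward calibrations to the accumulated
  concentration `rate·t / V`; ROS cell signal rises linearly.
- Noise is additive iid Gaussian per frame and per measured mean (clipped at
  0). The "realistic" preset uses SD 4 a.u. on the 200 a.u. A647 baseline
  (2 %) and 2 a.u. elsewhere; with this noise the control-derived
  median+3·SD threshold lands near 10 %, i.e. in the regime of the published
  fixed operating point.
- Condition presets select phenotype sampling distributions only (no
  biology): the ROS-scavenger (NAC) preset forces terminal loss 0 everywhere;
  immunization-day presets set the NOX-active fraction (0.12 / 0.31 / 0.12 /
  0.59 for days 0/3/7/14).
- Image rendering: 16-bit stitched frames, droplets as filled disks on a
  jittered hexagonal-ish grid (static across frames), cells as Gaussian blobs
  (cell stain) or small flat disks (ROS), the beadline as a bright 2×radius
  segment at droplet center. Background pixels inside each disk are
  compensated so the disk mean equals the trace value to within quantization.
  Droplets within a radius of a tile boundary or the chamber border are
  flagged as edge in the ground truth; tile lines are only applied when a
  tile is at least four droplet radii wide (tiny test chambers have no
  meaningful stitch geometry).
- Default day-0 B-cell composition plants a 0.34 germinal-center fraction,
  with DZ/LZ split 61/39 and plasma-cell states 37/38/15/10
  (mature/apoptotic/immature/plasmablast).

What the generator does **not** emulate: optics (PSF, illumination fields),
droplet shrinkage/coalescence or motion, registration errors between tiles,
photobleaching, biological correlation structure between phenotypes, and
count-based single-cell noise (the expression model is Gaussian around
planted shifts). Passing tests therefore demonstrate correctness of the
estimators and gates against the stated forward model, not robustness to
every artifact of real microscopy or sequencing data.

## Image analysis choices

Segmentation is threshold + connected components + circularity filter
(4πA/P² ≥ 0.6, radius within [5, 30] px by default); the acceptance surface
is ground-truth recovery on renders, not the specific algorithm. Tracking is
greedy nearest-centroid with a displacement gate of 0.5·radius; unmatched or
ambiguous (two tracks, one region) droplets are flagged `tracking_failed`,
border/tile droplets `edge`/`stitch_suspect`, and no flagged droplet enters
downstream statistics. An exact positional swap of two identical droplets is
geometrically undetectable; the tracker guarantees only that any displacement
beyond the gate, or any ambiguous claim, is flagged rather than silently
matched. Cell counting takes local intensity maxima above threshold inside
the droplet mask, maximized over frames (conservative multi-cell exclusion).
Beadline extraction takes the compact cluster of pixels > 1.3× the droplet
mean; when relocation is absent it falls back to the mean of the top 2 %
intensity quantile and flags `beadline_fallback`.

## Statistics

Two-group comparisons use Welch's t-test; more than two groups use the Welch
ANOVA with the Brown-Forsythe adjusted F reported alongside; distribution
comparisons use the two-sample Kolmogorov-Smirnov test. Stars: * p<0.05,
** p<0.01, *** p<0.001, **** p<0.0001 (strict inequalities). Single-replicate
groups yield descriptive output only.

## Problem sizes and tolerances

The bundled demo runs 2,000 droplets × 6 frames × 3 synthetic mice for each
of two conditions at trace level (image rendering is a config toggle,
exercised separately in the imaging tests at 120–2,000 droplets), and
completes in well under five minutes on one CPU. Parameter-recovery suites
use 500 single-cell droplets with rates uniform over the quantitative ranges;
null-specificity suites use 10 chambers of 600 cell-droplets with the
threshold fit on an independent 5,000-droplet control set. RNA suites use up
to 5,000 cells × ~2,000 genes. Numerical tolerances: noiseless round trips
are exact to 1e-9 (traces) or one intensity quantum (renders); noisy recovery
is asserted at the 15 % median-relative-error level; calibration fits recover
exact-model parameters to 1e-6 relative.

## Known limitations

- The imaging stage assumes a static chamber; real drift would need
  registration, which is out of scope.
- The beadline detector is a heuristic stand-in for unpublished particle
  detection; its fallback path is flagged so downstream users can filter.
- The lactate assay's enzymatic kinetics and the NADPH competition between
  the lactate and NOX assays are not modeled.
- Pathway gene sets are static config files, not live database queries.
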