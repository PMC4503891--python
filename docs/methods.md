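# Methods

## Scope and model

The package implements two quantitative analyses for cardiac myofilament
regulatory proteins, each paired with a synthetic-data generator that carries a
known ground truth:

1. **Label-free mass-balance quantification** of site-specific phosphorylation
   of troponin I (Ser23/24) and alpha-tropomyosin (Ser283), and of C-terminal
   TnI truncation, from extracted-ion-chromatogram (XIC) peak areas of paired
   untreated / alkaline-phosphatase-treated tryptic digests.
2. **In vitro motility analysis**: per-filament sliding velocities from
   centroid tracks, the fraction of filaments moving, the motility index
   (their product), and Hill fitting of the velocity–pCa relation.

## Peptide mass arithmetic

All arithmetic is monoisotopic: residue masses to 5 decimals, water
18.010565 Da, proton 1.007276 Da, phospho +79.966331 Da, methionine sulfoxide
+15.994915 Da, sulfone +31.989829 Da. An ion's m/z is `(M + z·m_p)/z`.
Tryptic digestion cleaves C-terminal to K/R except before proline; missed
cleavages are enumerated by skipping up to k internal sites. b/y fragment
ladders place each modification with its residue; the z=1 complementarity
identity is `b_i + y_(n−i) = M + 2·m_p` (the peptide's single water lives in
the y ion).

Reported ion m/z values for these peptides are instrument readouts, so the
last printed digit carries readout ambiguity: the package's comparison
convention is agreement to one unit in the last printed place (0.01),
with a separate round-half-even helper for display. Charge states are explicit
inputs, never inferred; the packaged fixture records the assignment under
which each computed value matches its reported counterpart (z=1 for KLQLK and
ETLDLR, z=2 for all others).

## Synthetic LC-MS model

Each run draws a lognormal loading factor (median 1, sigma 0.2 by default,
shared by every species in the run). A species' expected area is
`protein amount × molar fraction × response factor × loading`; molar fractions
come from the group's occupancies (mono/bis TnI phosphorylation, Tm
phosphorylation split over three Met-oxidation states, C-terminal truncation
and oxidation). Multiplicative lognormal noise with CV 0.10 (mean-one, so
areas are unbiased) is applied to the integrated abundance; the trace is a
Gaussian elution peak at a fixed fixture retention time (sigma 0.05 min,
non-overlapping by construction) whose integral equals the realized area.

Phosphatase treatment is species reassignment, not chemistry: with
completeness 1.0 (default) every phospho species' molar share moves to its
dephosphorylated analog. Because dephosphorylation precedes digestion, both
the mis-cleaved mono- and bis-phosphopeptides collapse onto the properly
cleaved SSANYR analog. Reference peptides are emitted by every molecule and
respond only to loading.

Default occupancies (control mono 0.15, bis 0.05, Tm 0.10; zero truncation)
were fixed once so that the generated relative abundances equal the study's
reported values (mono 0.27/0.19 and bis 4.2/2.8 for IR2/IDNR) while total
phosphorylation rises only in IR2. A C-terminal relative abundance above 1
(e.g. 1.09) is expressed by assigning the *control* group a truncated
fraction of `1 − 1/ratio`, since truncating the experimental group can only
lower the ratio.

What the generator does **not** emulate: chromatographic baselines and peak
overlap, retention-time drift, isotope envelopes, ionization suppression,
incomplete digestion beyond the fixed phospho-induced mis-cleavage pattern,
and inter-animal biological variance. Passing recovery tests therefore
demonstrate that the estimator chain is unbiased under multiplicative area
noise and arbitrary loading — not that real chromatograms are this clean.

## Quantification

XIC areas are trapezoidal over fixed windows of ±5 peak widths (the excluded
~1e-6 tail fraction is identical for every species and cancels in all
normalized quantities); no baseline model. Each target is normalized by each
of the five same-protein reference peptides within the run; the per-reference
ratios are the replicate unit (5 per run), with replicate runs pooled flat —
mirroring significance testing on individual reference-peptide measurements.

* fraction phosphorylated: `f_r = 1 − untreated_r/treated_r` per reference,
  untreated/treated runs paired by replicate index; clamped to [0, 1] with a
  warning (negative raw values arise from noise).
* relative abundance: experimental per-reference ratio divided by the mean
  control ratio for that reference.
* truncation ratio: relative abundance of the summed C-terminal forms
  (unoxidized + sulfoxide); the two forms share one response factor so the
  sum is invariant to oxidation redistribution.
* Student's t: classical pooled-variance two-sample test on the per-reference
  normalized abundances; zero pooled variance gives p = 1 (equal means) or
  p = 0 (unequal). No multiple-testing correction is applied.

With mean-one lognormal area noise the ratio estimators carry a small
(~1–2 % at CV 0.10) positive bias from reference-denominator convexity; the
recovery experiments quantify it directly.

## Motility

Moving filaments advance along a persistent random direction at a lognormal
per-filament speed (CV 0.10); all centroids carry isotropic Gaussian
localization noise (0.05 um per coordinate per frame). Velocity is the mean
frame-to-frame displacement over the frame interval, unsmoothed (an optional
smoothing choice was considered and rejected as the simplest estimator is
transparent about its noise bias). Localization noise biases apparent speed
upward; for a stalled filament the floor is `sigma·sqrt(pi)/dt` (~0.89 um/s at
defaults), which **exceeds** the 0.25 um/s velocity threshold — the
classification therefore rests on the straightness criterion (net
displacement / path length ≥ 0.5), which separates directed motion from
random-walk jitter essentially perfectly at these settings (≥95 % accuracy on
labelled tracks). Both thresholds are configurable.

The Hill relation is implemented as `V = Vmax / (1 + 10^(n·(pCa − pCa50)))`
with n > 0, so velocity falls as calcium is withdrawn. The printed form with
the opposite exponent sign would rise with pCa, contradicting the observed
velocity–pCa data; the sign is treated as a typo and regression-tested.
Fitting is nonlinear least squares (1/SEM² weights when SEMs are available),
initialized at Vmax0 = max V, pCa50_0 = interpolated half-max, n0 = 2, with
bounds Vmax ∈ (0, 10·maxV], pCa50 ∈ data range ± 1, n ∈ (0, 20]; standard
errors come from the local curvature and non-convergence is flagged, never
silent.

Velocity–pCa recovery experiments sample 8 pCa values from 7.5 to 4.0 with
denser coverage of the activation transition (7.5, 7.0, 6.75, 6.5, 6.25, 6.0,
5.0, 4.0): with evenly spaced points at 0.5-unit intervals the steep portion
of a high-n curve falls between samples and the fitted n becomes noisy and
right-skewed, a design any motility study avoids by concentrating calcium
levels around the transition.

Group comparisons use Kruskal–Wallis (tie-corrected, chi-square p) by default
for velocities, with one-way ANOVA + Tukey HSD (studentized range, via
statsmodels) available.

## Reproducibility and problem sizes

A single master seed drives everything; per-stage and per-run seeds are
derived by SHA-256 over `"{seed}:{label}"` (kept below 2^31) and logged in the
report's provenance block, so identical config + seed yields byte-identical
reports. The recovery experiments use 200 independent repeats (100 for the
track simulations) at the study's design sizes — 3 replicates × 5 reference
peptides for LC-MS, 50 filaments per group at 10 frames/s for 30 s for
motility — which hold the Monte Carlo error of every reported mean well below
the comparison tolerance.

## Known limitations

* The quantifier assumes complete dephosphorylation, as the mass-balance
  method itself does; the simulator's completeness knob exists to probe the
  assumption, not to correct for it.
* Absolute percent-phosphorylation recovery targets are limited to what the
  generator defines, because only relative abundances are externally reported.
* The simulators are statistical emulators, not physical models (no spectra,
  no images); conclusions about real instruments require real data.
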