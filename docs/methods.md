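# Methods

## Data model and premise

All spectra are unit-mass: a scanning quadrupole acquiring m/z 50–350 at
12 scans/s produces nominal-mass data, so centroided or profile input is
binned to the nearest integer m/z on read. Times are minutes everywhere.
The total ion current (TIC) is always recomputed from the scans, never
cached.

A target compound carries its reference spectrum, its main (base-peak) ion,
and 2–5 qualifier ions whose expected relative abundances *Rᵢ* are, by
construction, the reference intensity at that m/z divided by the main-ion
intensity. When a library record does not name its qualifiers (the usual
case for MSP files), the three most intense ions after the base peak are
taken, capped at five.

## The identification criterion

Four tests form one conjunction, evaluated on the longest stretch of
consecutive scans in a retention-time window (default ±0.2 min) in which
every qualifier's reduced intensity Iᵢ = Aᵢ/(Rᵢ·A_main) stays within
`max_ion_deviation` (default 0.20) of 1 and the mean pairwise deviation
ΔI = Σᵢ<ⱼ|Iᵢ−Iⱼ|/(N(N−1)/2) satisfies ΔI ≤ K + Δ₀/A_main:

* stretch length ≥ `min_consecutive_scans` (default 5);
* min over the stretch of ΔE = ΔI·log₁₀(A_main) ≤ `delta_e_max` (default 7);
* Q-value ≥ `q_value_min` (default 95%);
* Q-ratio deviation ≤ `q_ratio_tol` (default ±20%).

Design points that were genuinely open:

* **Reduced-intensity denominator.** Iᵢ = Aᵢ/(Rᵢ·A_main) is the convention
  that makes a perfectly matching scan flat at 1, which is what the
  histogram view expects (flatter = better).
* **Logarithm base in ΔE.** Base 10: with abundances of 10³–10⁶ counts and
  ΔI up to ~2 this makes the ceiling of 7 a meaningful bound; a natural log
  would rescale the same information.
* **Q-value aggregation.** The mean (not the sum) of per-scan, per-qualifier
  percent deviations |Rᵢ−rᵢ(t)|/Rᵢ×100, clamped to [0, 100]; a sum would
  routinely exceed 100 and could not behave as a "closer to 100 is better"
  score. The main ion is excluded (its deviation is identically zero and
  would only dilute the statistic). Scans with a zero main ion are skipped.
* **Q-ratio.** Deviation of the *peak-mean* observed ratio per qualifier,
  so single-scan noise does not fail a peak; the per-scan rule is already
  enforced by criterion 1.
* **Δ₀** defaults to 0 in a bare `MatchCriteria` and to 3× the baseline MAD
  when tied to a run's noise model (`with_noise`).

The cross-scan narrative of scan-to-scan variance (scan 1 against scans
2…n, etc.) is exposed as a diagnostic pairwise spectral-distance matrix
(`scan_distance_matrix`); the acceptance path uses the ΔE formula.

## Peak detection and noise

The baseline noise model is estimated from the TIC: the noise sd comes from
the scan-to-scan first differences with the top decile trimmed (removing
peak flanks) and a truncated-normal rms correction; the level is the TIC
median (peaks occupy a minority of scans). `background threshold` =
level + 3×MAD throughout.

Peaks are apexes of the Savitzky–Golay-smoothed TIC (window 9, order 3,
nearest-edge padding) above the threshold, with bounds extended to the
baseline or the valley between apexes. Adjacent regions whose shared valley
exceeds 0.20 of the lower apex (baseline-corrected) are fused: two equal
Gaussians 5σ apart give a ratio of ~0.05 (resolved, keep split), while
members of an unresolved cluster give ≥ ~0.3 even when a weak compound sits
at the valley.

## Deconvolution

Per region the engine loops: evaluate all library targets whose retention
falls inside the region and subtract the passing ones (best Q-value first,
ties by larger main-ion area then id); then select the 3–5 consecutive
scans with the smallest mean pairwise spectral distance (all pairwise
1−cosine ≤ 0.05), average them, strip averaged ions below 1% of the base
peak (baseline cells), drop ions whose elution profile does not track the
anchor ion (Pearson r < 0.9; only ions strong enough to judge are subject
to removal), identify the candidate against reference libraries (weighted
cosine ≥ 0.80) or issue a numeric unknown id, and subtract it. Subtraction
scales the component spectrum by the scan's anchor-ion intensity; negative
residuals clip to zero with the pre-clip mass balance recorded exactly.
The loop ends when the residual falls below the background threshold, when
an iteration extracts nothing, or after 20 iterations.

**Profile refinement.** Sequential anchor-scaled subtraction misallocates
signal when coeluters share ions or sit closer than about one peak width.
After the loop, the region is therefore refit from scratch: every
significant m/z channel's apex position is found on its smoothed profile;
apex positions are clustered at the modes of their energy-weighted kernel
density (bandwidth 1 scan — narrow enough that a weak neighbour's mode is
not swallowed; modes closer than 3 scans fuse to absorb apex jitter); each
cluster's model profile is the pointwise *median* of its members'
max-normalised profiles, which suppresses the second hump that a shared
channel would contribute. Channels are then decomposed over the model
profiles plus a flat background column by non-negative least squares; two
alternating passes (profiles from spectra, spectra from profiles) sharpen
the median-based initialisation; while the unexplained residual exceeds 1%
of the signal energy, the residual is clustered again for missed
components. Components whose reconstructed peak stays within the noise band
are baseline artifacts and are dropped. Identities found by the subtraction
loop transfer to the best-matching refined spectrum (cosine ≥ 0.7); the
rest become fresh unknowns. Each component's abundance is its fitted
main-ion area, and the returned residual reflects the refined fit.

Under the study conditions (2–4 coeluters, apex separations 0.5–2σ, SNR
30–300, random 5–25-ion spectra), this recovers every planted component at
spectrum cosine ≥ 0.95 and abundance error ≤ 10% in ~99% of seeded trials;
the residual claim (≈ background) holds for the seven-compound cluster.
Genuinely inseparable cases remain out of reach by construction: two
compounds planted at the *same* retention time are one mixed component.

## Library building

Heartcuts (1-min half-open windows, non-overlapping) are processed in
order. Each cut is deconvolved against the cumulative library, so
components transferred from the previous cut are recognised as known
targets rather than re-registered. A new component is merged into an
existing entry when its spectrum cosine is ≥ 0.95 and its retention index
is within 10 units (retention time within 0.1 min when no alkane
calibration is supplied), keeping the spectrum of the higher-abundance
occurrence. Unknown ids are issued monotonically. Thresholds (0.80
tentative identification, 0.95 dedup, 30-unit RI match window, 10-unit
dedup window) are config-exposed defaults chosen from common GC/MS
practice. Reference-standard availability is an input flag per compound
(`classify_identification`): tentative + standard = positive.

Retention indices use van den Dool–Kratz linear interpolation between
bracketing n-alkanes (C7–C30); no extrapolation outside the ladder.

## Quantitation and comparison

Abundance = (deconvolved main-ion area ÷ internal-standard main-ion area) ×
10⁶ (nominal response scale, so values land in instrument-like magnitudes).
The internal standard is a d8-naphthalene-like target (main ion m/z 136); a
run in which it fails the identification criterion is an error, not a zero.
Targets failing the criterion report 0.

Detection defaults to "nonzero = present". The published tables this
package ships as its comparison fixture contain printed values below the
instrument's 5000-unit detection rule (e.g. 4983), so that rule evidently
applies upstream of the tables; 5000 remains available via the threshold
argument. Venn regions assign each compound to the exact subset of samples
where it is present; fold changes are unrounded ratios with a
nearest-integer (half away from zero) display fold; a zero denominator with
a positive numerator routes the compound to the "unique" tables rather than
the fold lists; a compound absent from both samples is omitted with a
warning.

One published count does not reproduce from the printed 72-row survivor
table under any direction or rounding convention enumerated (the claimed 65
compounds at ≥2-fold in one green-to-roast direction; strict arithmetic
gives 58). The computation is exposed but that number is not asserted.

## Synthetic data

The simulator emulates the target acquisition: Gaussian peaks (an
exponentially-modified-Gaussian option exists for tailing-robustness
checks), spectra distributed over scans by a discretised unit-sum peak
shape and over m/z by the unit-sum spectrum, so a compound's integrated TIC
equals its planted total abundance; additive per-cell baseline plus
Gaussian noise clipped at zero (a heteroscedastic mode is out of scope);
an optional internal standard; and contiguous 1-min heartcuts where a
seeded fraction of compounds (default probability 0.1) reappears in the
adjacent cut at a configurable carryover fraction (default 0.3). Every
generator is a pure function of its seed. Defaults: 12 scans/s, m/z
50–350, peak σ = 0.01 min (≈ 1.4 s FWHM, a realistic capillary-GC width),
per-cell noise sd 3 counts in the canonical scenarios, trial SNR defined as
apex TIC height over the TIC noise sd.

What the simulations do *not* emulate — and hence what passing tests do not
show about real data: retention-time drift between runs, detector
saturation and column overload, isotope patterns and real fragmentation
correlations between co-occurring compounds, heteroscedastic shot noise,
and matrix-dependent extraction efficiency. The packaged abundance table is
a transcription of published values and carries their original rounding.

## Numerical conventions

Base-peak ties break toward lower m/z. MSP normalisation scales the base
peak to 999 and is idempotent. Run I/O round-trips bit-stably for integer
m/z and to 1e-6 relative for intensities (mzML stores 64-bit floats
uncompressed). Subtraction mass balance (pre-clipping) is exact to float
summation order. The deconvolution engine is deterministic; all
stochasticity lives in the seeded generators. Problem sizes in the test
suite (0.5–0.75-min runs, 50-trial recovery studies, 3–5-cut campaigns)
are chosen to exercise the full engine at desk scale.
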