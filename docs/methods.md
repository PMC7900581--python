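# Methods

## Mass conventions

All masses are computed from elemental compositions with embedded IUPAC
monoisotopic atomic masses (C = 12 exactly; H 1.0078250, N 14.0030740,
O 15.9949146, P 30.9737616, plus S/Na/K/Cl/Br). Protonation and deprotonation
shift by the proton mass 1.007276 Da; intrinsic cations (quaternary ammonium
species carrying their own charge) subtract one electron mass (0.000549 Da).
For z > 1 the shift applies z times and the result divides by z. These
conventions reproduce the conventional two-decimal values of every diagnostic
fragment (227.20, 267.23, 208.07, 184.07, 335.26, 73.09). Isotope envelopes
and fine structure are out of scope; an optional type-I ¹³C correction
(divide by (1 − 0.0107)^nC) is available and off by default, since at a
resolution of 280,000 the monoisotopic peak is cleanly separated and ratios
against the internal standard largely cancel the envelope factor.

## Sum-composition formulas

The paperwork of lipid chemistry is backbone arithmetic. A diacyl PC with C
radyl carbons and D double bonds is C(C+8) H(2C−2D+16) N O8 P (validated
against standard lipid masses, e.g. PC 32:0 = C40H80NO8P = 733.5622,
PC 31:1 = C39H76NO8P = 717.5309). Ether (plasmanyl) classes exchange one
ester oxygen for two hydrogens; lyso classes drop one chain
(LPC = C(C+8)H(2C−2D+18)NO7P, ether lyso −O +H2 again); SM assumes a
dihydroxy sphingoid base, C(C+5)H(2C−2D+13)N2O6P, with the base double bond
counted in D (the conventional d18:1 reading). Every propargyl class is its
choline parent plus exactly C2 (propargyl replaces an N-methyl), a +24.000 Da
shift. Click products add the reporter's full composition (cycloaddition
conserves all atoms). We deliberately compute clicked masses from composition
rather than from any nominal shift: azidopalmitate adds C16H31N3O2 =
+297.2416 Da to the neutral.

The C171 reporter's exact structure is published elsewhere; the package
carries an overridable default (intrinsic cation C8H19N4⁺, 171.1604 Da,
nominal +171) whose neutral loss C4H11N reproduces the diagnostic 73.09 Da.
Only the NL enters identification, so the default composition affects
precursor placement, not the rule.

## Acquisition model and identification

A run models the direct-infusion scheme: MS1 survey scans over fixed 100-m/z
windows and DIA MS2 scans in 1-m/z isolation windows (950–1300 m/z negative,
250–1200 / 200–1200 positive). The DIA grid is half-open [k, k+1) with
centers at k + 0.5, so the windows partition the precursor axis; a boundary
precursor belongs to the window starting there. Repeated scans per window are
averaged before lookup: pooled peaks are clustered greedily along m/z,
breaking where consecutive peaks are further apart than the clustering
tolerance; cluster intensity is the mean over scans and m/z the
intensity-weighted mean. The clustering tolerance follows the lookup
tolerance of the level being averaged — an averaging tolerance smaller than
the instrument's mass scatter would split a peak's intensity across
fragments, which shows up directly as quantification noise.

Default tolerances are 5 ppm (MS1/precursor) and 10 ppm (MS2 fragments),
reflecting R = 280,000; both are configurable, and should be kept at ≥3× the
expected mass-error SD. Peak lookup returns the most intense peak within
tolerance, ties broken by closeness; absence is a value, not an error.

Identification requires the neutral-loss fragment at (precursor − NL) in the
precursor's own DIA window — the NL is the defining evidence and is never
optional — plus, by default (`require_ms1`), a precursor peak in averaged
MS1. Subspecies are resolved inside the same window via the FA carboxylate
fragments. Within one species the chain pairs are in bijection with their
observable FA fragments, because the partner chain is fixed by the sum
constraint; this is property-tested against brute-force enumeration.
Heteroacyl hits with one missing FA peak are kept with zero partner intensity
and flagged `single_fragment` (a strict both-peaks mode is a flag). For ether
and sphingo species only the sn-2 / amide acyl yields a carboxylate, so one
fragment is expected; sn-positions and double-bond positions are not
assigned. Candidates whose expected precursors collide within tolerance are
all reported, flagged `ambiguous_precursor`, with no automatic winner.

## Quantification

Species amounts come from NL-fragment intensities against the internal
standard (default 240 pmol pPC 31:1, chains 14:0/17:1):
pmol = I_NL/I_NL,IS × pmol_IS. Subspecies amounts use the summed FA-fragment
intensities with the per-chain response factor RF = (I_IS,1 + I_IS,2)/(2
pmol_IS); the homoacyl single peak carries both chains (divide by 2), so
heteroacyl and homoacyl estimators are unbiased under equal per-chain release
probability. Both routes are scale-invariant by construction. Species-level
(NL) and summed-subspecies (FA) totals are kept as separate columns — they
estimate the same quantity through different fragments and need not agree,
notably for PUFA chains (below).

## Simulator

The synthetic-data generator emulates the stated acquisition (100-m/z MS1
windows, 1-m/z DIA tiling, one polarity per run) and the fragmentation
chemistry: each clicked precursor deposits a residual precursor peak
(fraction 0.2), the NL fragment (fraction 0.5) and per observable chain an FA
carboxylate (fraction 0.25) into its window; intensity is pmol × response
factor (1000 per pmol) with equal response across species. PUFA chains lose
CO2 with probability 1 − (1 − q)^(d−1) for d ≥ 2; the lost share appears as
a distinct satellite at FA − 43.9898, which default identification ignores
— so FA-based quantification of PUFA chains is biased low while the NL route
is untouched, reproducing the direction of the reduced FA-signal recovery
seen for di-PUFA species. Noise is multiplicative log-normal per peak,
Normal ppm jitter on m/z, and a homogeneous-Poisson noise floor with
exponential intensities; a seed fixes the run byte-for-byte.

What the simulator does not emulate: peak shapes and profile data (it emits
centroids; the reader can centroid profile input by 3-point parabolic local
maxima), isotope envelopes, adduct heterogeneity, ion suppression between
co-sprayed analytes, chromatography, and real response-factor spread between
lipid classes. Passing recovery tests therefore shows the pipeline's
arithmetic and rule logic are correct under the model's assumptions — not
that any instrument achieves these figures.

## Calibration, LOD and LOQ

The calibration fit is ordinary least squares over the nonzero levels of a
dilution series (repeated levels are replicates); the linear range is
log10(highest/lowest level). LOD and LOQ use the ICH-style estimators
3.3σ/slope and 10σ/slope with σ the replicate SD at the blank (or, absent a
blank, the lowest level). Published instrument limits (≈1 and 4 pmol on the
original setup) depend on hardware and spray conditions and are not
desk-computable; the estimator itself is validated by parameter recovery, and
the simulated series (1–1000 pmol, 10% per-scan noise averaged over 5 scans
per window, 5 replicates) reproduces linearity with R² > 0.99 across three
orders of magnitude.

## Problem sizes and defaults

Default search space: species C 28–44, D 0–8 (both parities), acyl chains
c 12–26, d 0–6 — covering every reported labeled-cell species with margin.
Test mixtures use 20 species with one chain pair each at the amounts of the
bundled reference pool plus the internal standard; stochastic properties use
20 replicate runs at 10% log-normal noise and 5 ppm jitter. The bundled
reference tables (see `clicklipid.refdata`) are per-45,000-cell means over
seven replicates of LpPC-labeled bEND3 cells; report-layer outputs render
pmol and percent to one decimal while retaining full precision internally.

## Known limitations

No retention-time or mobility evidence, no FDR model (rule-based
identification), no plasmenyl/plasmanyl discrimination, no endogenous
(unlabeled) lipidome identification — endogenous class totals enter the
reports as external tables. Charge states above 2 and adducts other than
±H / intrinsic cations are out of scope.
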