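# Methods

This note records the models implemented, the defaults and why, what the
synthetic generators do and do not emulate, and the numerical choices made
where the conventions of the field leave room.

## Quenching and binding analysis

F₀/F ratios are read from the titration spectra at the wavelength of the
zero-quencher maximum (`mode="fixed"`, the default). Because a static
quencher attenuates the band without shifting it, per-spectrum peak
(`"peak"`), band-area (`"integrated"`) and user-wavelength modes agree on
such data; the default is documented rather than asserted as universal.
[Q] is the *total added* ligand concentration — no free-ligand iteration —
which is the convention under which the linear Stern–Volmer and double-log
models are normally fitted and reported.

Both regressions are unweighted ordinary least squares, matching the
standard linear plots. τ₀ is stored in ns and converted to seconds only
inside the K_q computation, which removes the classic 10⁹ unit slip.

The mechanism call is made deterministic: three criteria (K_SV trend with
temperature, K_q against the 2×10¹⁰ L mol⁻¹ s⁻¹ diffusion ceiling,
mean-lifetime invariance) each cast one vote, criteria without data are
skipped, and a label is issued only when at least two votes agree with
none opposing; everything else is "inconclusive". The K_SV trend uses a 1%
relative tolerance per step so fit noise cannot fake or mask monotonicity.

**Noise sensitivity.** On the study's concentration ladder
(4–24 µM, lg[Q] ∈ [−5.4, −4.6]), the double-log intercept extrapolates
about five decades to lg[Q] = 0. Slope noise is therefore amplified ~×5
into lg K_a: at 1% multiplicative intensity noise, K_SV is recovered with
≈1% median error, but K_a carries tens of percent and n a few percent.
This is a property of the estimator on this design, not of the
implementation; K_a values from single noisy titrations should be read
with that in mind.

## Van't Hoff thermodynamics

ln K_a is regressed on 1/T (unweighted by default; a weighted variant
accepts per-point uncertainties). R = 8.314 J mol⁻¹ K⁻¹ exactly. K_a
enters the logarithm carrying L/mol units — formally ln(K_a/c°) with
c° = 1 mol/L — the near-universal convention in binding papers, noted here
as a caveat rather than hidden. The ΔG map is computed from the
*unrounded* ΔH and ΔS: rounding the parameters first before forming
ΔH − TΔS can move ΔG by ~0.01 kJ/mol at physiological temperatures, which
matters at the two-decimal precision these tables are printed at. ΔH = 0
or ΔS = 0 makes the sign-rule force classification undefined and raises an
error rather than guessing.

## Lifetime fitting

Tail fitting only: the model Σᵢ cᵢ·exp(−t/τᵢ) starts at the count maximum,
so no instrument-response convolution is modelled, and the synthetic
decays are generated the same way so generator and fit model agree by
construction. Weights are Poisson (residuals divided by √max(count, 1));
the reduced χ² uses dof = n_window − 2k and should sit near 1 for a
correctly specified model, the usual goodness criterion for TCSPC fits.
The default window runs from the peak channel to the last channel with
≥ 10 counts. Initial lifetimes are log-spaced across the window span with
equal amplitudes; on non-convergence the fit restarts up to three times
from deterministically perturbed initials. Fitted amplitudes are
renormalised to fractions summing to one and sorted by descending
amplitude.

Mean lifetime is Σ αᵢτᵢ with the amplitudes *as given* — externally
supplied component sets (e.g. instrument printouts in percent, which may
sum to 99.99% after rounding) are deliberately not renormalised, so the
computed τ_ave reproduces the instrument's own arithmetic; the validation
tolerance on the amplitude sum is 0.5% for such inputs. Model-order
selection, when requested, takes the smallest order with reduced χ² < 1.3.

## Spectral probes

Synchronous-scan maxima are located by three-point parabolic interpolation
around the grid argmax, resolving sub-grid drifts; the shift verdict
compares the last scan with the zero-quencher scan against a 2 nm
tolerance (under half the usual 5 nm EEM step; synchronous grids are
finer). EEM fluorophore peaks are strict 8-neighbourhood local maxima at
≥ 5% of the global maximum, with a ±10 nm first-order Rayleigh diagonal
mask (second-order em ≈ 2·ex masking available, off by default); the
brightest in-band cell is reported as the Rayleigh record. CD handling is
deliberately qualitative — extremum positions and signs of a
window-3-smoothed curve — with no secondary-structure deconvolution.

## Enzyme activity

Pure arithmetic on OD₆₆₀ readings: inhibition (%) =
(OD_blank − OD_sample)/OD_blank × 100 and relative activity =
OD_sample/OD_blank, related by relative = 1 − inhibition/100 row-wise.
Negative inhibition (activation) is reported as-is, since ligands can
enhance an enzyme. Replicate rows are averaged with their SD carried
along.

## Trajectory observables

Superposition is Kabsch via SVD (`scipy`'s `align_vectors`) with the
proper-rotation constraint, so mirror images cannot alias; the RMSD is
recomputed from the aligned coordinates because the optimiser's residual
loses half its digits to cancellation on near-exact matches. Default RMSD
and RMSF selection is Cα. RMSF aligns the window's frames to their mean in
two passes, then averages per-atom RMS displacements within residues.
Ligand–residue distance is the closest-atom-pair distance (the natural
reading of "distance between ligand and residue" in contact analyses; a
centre-of-mass variant can be had by pre-reducing the selections).
Hydrogen bonds use a geometric criterion — H⋯acceptor ≤ 3.5 Å and
D–H⋯A ≥ 120°, both tunable — with donor hydrogens attached by covalent
proximity (≤ 1.25 Å in frame 0); a donor without a hydrogen is an error,
not a silent zero. Atomic masses come from a standard table keyed by
element; unknown elements fall back to 12 u with a warning. Residue
identity is (chain, residue number).

## Synthetic data: what it emulates, what it does not

The generators reproduce the study conditions: protein 1.6×10⁻⁵ mol/L,
quencher ladder 0–24 µM in 4 µM steps, a single Gaussian tryptophan band
near 345 nm, tri-exponential decays with a dominant ~5.7 ns component,
200–400 nm EEM grids at 5 nm steps with a first-order scatter ridge.
Titrations come in two laws: the Stern–Volmer form F = F₀/(1 + K_SV[Q])
and the double-log form F = F₀/(1 + K_a[Q]ⁿ), which coincide when n = 1;
each stage is validated against the law it estimates. Noise is
multiplicative Gaussian for steady-state spectra (a shot/gain proxy) and
Poisson for photon counts. All generators are bit-reproducible under a
fixed seed.

Not emulated: inner-filter effects (none are corrected for in the
analysis either), wavelength-dependent instrument response, IRF
convolution in decays, combined static+dynamic quenching, Raman scatter,
and real conformational dynamics in trajectories (frames are base + iid
jitter, optionally rigidly moved). Passing round-trip tests therefore
demonstrates estimator correctness under the stated models, not robustness
to these real-world artefacts.

Toy trajectories default to a helix-like base structure; collinear bases
are avoided because they leave the superposition rotation about the axis
undetermined. The intensity scale of simulated spectra (f0_peak) is
arbitrary units — absolute radiometric scale carries no information for
any ratio-based quantity computed here.

## Problem sizes used in the automated checks

Lifetime-fit calibration uses 10⁶ peak counts over 1024 channels of
25 ps, 50 seeds; titration recovery uses the 7-point ladder over 100
seeds; RMSF convergence uses 2000 frames of 120 atoms. These sizes give
sampling error comfortably below the asserted tolerances while keeping the
whole suite fast.

## Known limitations

- Single-temperature K_SV/K_a pairs cannot separate static from dynamic
  contributions; the mechanism vote needs ≥ 2 temperatures.
- The Van't Hoff ΔH/ΔS assume temperature-independent enthalpy over the
  range (no ΔCp term).
- Only multi-model PDB trajectories are read; binding energies, docking
  scores and per-residue secondary structure are out of scope.
- CD output is descriptive; no fraction-of-structure estimation.
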