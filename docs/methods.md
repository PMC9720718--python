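# Methods

## The reconstruction model

The package treats an absorption spectrum as the conformer average of
broadened vertical transitions (the nuclear-ensemble approach):

    A(E) = (1/N_p) * sum_{k=1..N_p} sum_{L=1..N_s(k)}
           f_IL(R_k) * g(E; dE_IL(R_k), delta)

with g a *unit-area* Gaussian of FWHM delta. The assumptions this encodes:

* the band is built from vertical (fixed-nuclei) transitions only — no
  vibronic / Franck–Condon structure, no Herzberg–Teller intensity borrowing,
  no lifetime (Lorentzian) broadening;
* the sampled geometries are equally weighted, i.e. they are treated as an
  unbiased, uncorrelated draw from the thermal ensemble — correctness of the
  weights is the sampler's job, not the reconstruction's;
* each transition's intensity is its oscillator strength; no conversion to
  molar absorptivity is attempted, so intensities are in arbitrary units and
  only ratios and peak positions are meaningful.

The conformer average uses a 1/N_p prefactor and a plain sum over states.
This choice makes a single optimised geometry exactly the N_p = 1 case, so
static ("opt") and ensemble ("conf") spectra are directly comparable, and it
gives the sum rule used as a standing numerical check: for an unclipped
reconstruction, ∫A dE equals the ensemble-mean total oscillator strength
(each lineshape has unit area). The absolute prefactor affects no reported
quantity except absolute intensity.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| broadening FWHM delta | 0.2 | eV | standard phenomenological width for room-temperature bands built from vertical transitions; sigma = delta/(2*sqrt(2 ln 2)) |
| energy grid | 1.0–5.0, step 0.001 | eV | covers near-IR to near-UV; step is FWHM/200, far below any feature width (the constructor rejects steps above FWHM/10) |
| hc | 1239.841984 | eV·nm | pinned so eV↔nm conversions are bit-stable; parsed (E, lambda) pairs must agree with it within 0.5 nm·eV (log-file rounding) |
| save interval / duration | 4 / 5000 | ps | a 5 ns production run saved every 4 ps: 1250 post-initial frames |
| decimation stride | 10 | – | every 10th saved frame goes to the excited-state stage |
| histogram bin width | 1 | deg | degree-level granularity for torsional mode positions; mode uncertainty is reported as ± half a bin |
| mode min_separation / prominence | 10 deg / 0.10 | – | peaks closer than 10° are one conformer basin; peaks under 10% of the maximum are noise. Both configurable. |

Frame-count convention: the trajectory is modelled as 1251 frames — the
t = 0 configuration plus 1250 saves — and every-10th decimation over indices
0..1250 yields 126 conformers. This is the one simple convention under which
both protocol counts (1250 saved, 126 extracted "starting from the first one
saved") are simultaneously exact.

## lambda_max and shifts

Spectra are convolved and stored in the energy domain; the wavelength view
is the pointwise map lambda = hc/E without Jacobian reweighting, and
lambda_max is hc/E_peak. The grid argmax is refined by a three-point
parabolic fit (a 1 meV grid alone would alias nm-level comparisons); exact
ties break toward lower energy, i.e. longer wavelength. The opt→conf shift
is reported in energy, delta_E = hc*(1/lambda_opt − 1/lambda_conf), signed
so that an ensemble red-shift is positive; solvent shifts are plain nm
differences, solution − gas. When published integer-nm wavelength pairs are
fed back through shift_ev, the result can differ from a shift computed on
unrounded maxima by up to ~0.003 eV; comparisons against such printed values
therefore use a ±0.005 eV slack.

## Circular statistics

Angles live in (−180, +180] with −180 mapped to +180. Histograms tile the
circle (a value of exactly +180 joins the last bin, so ±180 is one circular
point) and are normalised to unit circular integral. Mode detection works on
a 5-bin circular moving average of the density — with ~10^3–10^4 samples in
1° bins, raw bin counts carry few-percent Poisson noise, which would jitter a
bare argmax by several degrees — then refines each accepted peak as the
density-weighted circular mean of the raw bins within min_separation and
snaps the result to the nearest bin center. Final centers are re-checked
against min_separation (refinement can pull two candidates together),
keeping the denser mode. Torsion signs follow the standard two-plane atan2
construction: looking down the B→C bond, counter-clockwise rotation of the
far bond relative to the near bond is positive; the convention is fixed by
test geometries built by explicit rotation about B–C. The torsion is
invariant under rigid motion and under reversing the atom quadruple.

## The synthetic generator

The generator emulates the two expensive engines' *outputs* with the
statistical structure the analysis is sensitive to:

* torsional populations are i.i.d. draws from a von Mises mixture (wrapped,
  multimodal). No temporal autocorrelation is generated: the decimated
  configurations entering the average are treated as uncorrelated anyway, so
  dynamics would add nothing the pipeline can detect;
* the bright excitation follows a cosine coupling to one key dihedral,
  E_k = E_ref − a·(1 − cos(delta_k − delta_0)) + N(0, noise_sd): the
  simplest periodic law anchored at a reference torsion. Conformers away
  from delta_0 absorb lower, so the ensemble red-shifts against the static
  record — the mechanism the opt/conf comparison exists to expose. Sign and
  amplitude are configurable; the law is phenomenological, not a model of
  any real chromophore;
* each record carries a fixed template of weak higher-lying states so state
  stacks, bright-state selection and parsers see realistic inputs.

Default scenarios: **gas** — modes −113°/−76° (κ = 50), weights 0.75/0.25
with the off-minimum mode dominant, reference −76°, E_ref = 2.65 eV,
a = 1.2 eV, noise 0.02 eV, giving an opt→conf shift of ≈ 0.2 eV;
**solution** — modes −115°/−64° (κ = 150; solvent damps torsional mobility,
hence the narrower distribution), reference −64°, E_ref = 2.30 eV
(solvatochromic red-shift of the reference), a = 0.35 eV, noise 0.02 eV,
giving ≈ 0.1 eV. The amplitudes were calibrated once against those target
shifts and then frozen; because the peak position of a bimodal band is a
non-linear functional of the mixture, a single amplitude cannot land both
phases' targets, so the amplitude is per-scenario. What passing tests on
these data do **not** show: correctness of any force field or functional,
real torsion–energy surfaces (the cosine law is an ansatz), or behaviour
under autocorrelated sampling.

## Numerical choices and degenerate inputs

* Reconstruction is a vectorised grid × transition evaluation, verified in
  tests against the literal double loop at 1e-12.
* Transitions further than 5 sigma outside the grid trigger a clipping
  warning; the area sum-rule check stands down for clipped spectra.
* Parsing: the log dialect is anchored on the literal tokens
  "Excited State" and "f="; re-printed state blocks supersede earlier ones;
  malformed numeric fields raise line-numbered errors. State tables
  round-trip float64 exactly (%.17g out, round_trip parsing in).
* Ensembles reject mixed functional/phase tags; heterogeneous state counts
  only warn (a conformer occasionally needs extra states to cover the
  band).
* Degenerate geometry (collinear torsion triples), empty series/windows,
  flat spectra and non-positive energies all raise typed errors rather than
  returning NaN.
* All randomness flows through integer seeds; scenario runs derive child
  seeds (below 2^31) for the angle draws and the excitation noise from one
  master seed.

## Known limitations

* The wavelength view has no Jacobian factor; peak *positions* are exact
  under the map, but band *shapes* in nm are not what a spectrometer records
  against wavelength.
* lambda_max carries no finite-N_p statistical uncertainty estimate.
* Windowed spectra require every conformer id to appear in the angle series;
  there is no fuzzy matching of frame indexing schemes.
* The XYZ reader accepts the common "count / comment with t= / label x y z"
  dialect only; no element-symbol normalisation, PBC unwrapping or alignment
  is performed (frames are assumed whole-molecule, solute-only).
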