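# Methods

## Background and scope

Growing root tips commonly circumnutate: the tip sweeps a helical path
characterised by an amplitude (radial extent, mm) and a frequency
(oscillations per unit penetration length, cm⁻¹). `circumpen` analyses a
root-analogue experiment in which a cone penetrometer (cone base radius
`rc`, semi-opening angle `βc`, on a slender shaft of length `ls` and
bending stiffness `k`) penetrates a soil sample that performs an orbital
motion of radius `r_o`. The package covers the analysis chain only — probe
kinematics, force decomposition, CT structure metrics, statistics — plus a
synthetic generator standing in for the physical rig, load cells, camera
and scanner.

## Probe deflection kinematics (`circumpen.probe`)

The projected deflection angle of the shaft to the vertical is measured on
time-lapse images (degrees; all module interfaces keep degrees, radians
appear only inside trig calls). With `Δαᵢ` the max–min projected angle
within oscillation `i` and `R` oscillations in total,

    δc = (ls / R) Σᵢ sin(Δαᵢ / 2)                 horizontal cone deflection, mm
    amplitude = r_o − δc                          circumnutation amplitude, mm
    Fa = Fz / [ (1/R) Σᵢ cos(Δαᵢ / 2) ]           deflection-corrected axial force
    erel = (Fa − Fz) / Fz × 100                   relative force error, %

Design choices: `Δαᵢ` is the raw within-window range, not a fitted
sinusoid amplitude; oscillation windows are derived from the nominal rig
frequency and penetration speed (the rig imposes the period — signal-based
detection would only add failure modes); stationary runs carry `δc = 0`
and an undefined (NaN) amplitude, because amplitude is meaningless without
orbital motion. Windows are assumed aligned with the penetration start.

## Cavity-expansion force decomposition (`circumpen.cavity`)

The axial force on the cone splits into a cavity-expansion part and an
interfacial friction part. For a stationary sample with radial stress
`σr,s` on the cone:

    Fr,s = π rc² cot βc · σr,s
    Fc,s = Fr,s tan βc = π rc² σr,s
    Fz   = Fc,s (1 + μ cot βc),      Ff,s = Fz − Fc,s

`σr,s` is calibrated by inverting the last identity at the mean stationary
force. Orbital motion adds a unidirectional radial force `Fro = δc·k` from
the bent shaft, so the radial load around the circumference is
`F*r(γ) = Fr,s + Fro cos γ` (admissible while `Fro ≤ Fr,s`). Assuming the
net cavity size is unchanged by the motion (`Fc,m = Fc,s`), the frictional
force of a moving treatment is `Ff,m = Fz − Fc,s`; a negative value is
returned with a warning rather than clipped, as it flags a violated
assumption. Forces rescale to another friction coefficient `μ′` by
`Fz′ = Fz (1 + μ′ cot βc)/(1 + μ cot βc)`. The asymmetry and intensity
indices are

    Iasym = Fro / Fr,s ∈ [0, 1],      CI = Iasym · f / fmax.

Numerical choices: `cot βc = 1/tan(βc)` with `βc` validated in (0°, 90°);
`fmax` defaults to 10 cm⁻¹ (largest frequency tested) and is
configurable. For moving treatments `Fc,s` is inherited from the mean
stationary decomposition of the same shaft material.

## CT pore-space analysis (`circumpen.ct`)

Volumes are (depth, y, x) voxel grids with physical voxel edge; the
analysis domain is the in-cylinder region minus a 0.6 mm radial rim
(sampling artefacts). Greyscale volumes are binarised with one global
threshold.

Imprint isolation: (1) downscale ×0.5 (block majority); (2) 5³ binary
median filter, implemented as a box-mean majority vote (identical result,
much faster than a rank filter); (3) Euclidean-distance-transform
watershed with markers from h-maxima of the distance map (h = 2 voxels);
(4) two iterations of cross-erosion then cross-dilation restricted to the
pore space (volume-preserving pairing); (5) keep the largest basin (lowest
label on ties); (6) upscale; (7) repeat the split once at full resolution
on the pore neighbourhood of the coarse core. The full-resolution pass is
deliberately local: a granular pore space can percolate at native
resolution, so "the connected component containing the cone" may span the
whole sample, whereas the coarse pass has already located the imprint.
Connectivity conventions: 26-neighbourhood for pore labelling,
6-neighbourhood (radius-1 cross) for erosion/dilation, both exposed.

Radial profiles: shell `j` is the band between `j−1` and `j` dilations of
the imprint by 5 iterations of the cross element (60 µm at 12 µm voxels),
computed equivalently via the city-block distance transform. Per shell,
visible porosity `ε′vis` and compactness change `Δc = 1 − ε′vis/εvis`
(reference `εvis` = mean visible porosity of unpenetrated samples). Local
total-porosity and bulk-density estimates:

    ε′ = (1 − ρb/ρp) − (εvis − ε′vis),      ρ′b = (1 − ε′) ρp

with `ρb = 1.4 g cm⁻³`, `ρp = 2.56 g cm⁻³`. Total porosity before
penetration is computed as `1 − ρb/ρp = 0.453125` (not a rounded 0.45) so
that a zero visible change recovers `ρb` exactly. Sub-resolution porosity
changes are neglected by construction. "Mean pore diameter" is the
volume-weighted mean equivalent-sphere diameter of labelled pore clusters
(a local-thickness alternative was considered and left out; the equivalent
sphere is deterministic and cheap). Analysis regions: the domain
cross-section below the imprint tip and the nearest-shell region around
it, clipped to 1000 and 2000 mm³ scaled by the ratio of the domain volume
to the full-size scan domain (π·8.4²·24 mm³).

## Synthetic data (`circumpen.synthetic`)

The generator encodes the study conditions: penetration at 1 cm h⁻¹ to
10 mm, force sampled at 1 Hz, frequencies {0, 1, 5, 10} cm⁻¹, two shaft
materials (steel k = 6.96 N mm⁻¹, brass k = 2.96 N mm⁻¹), five replicates.

*Force traces.* Table mode draws Gaussian noise (sd 0.02 MPa per sample,
optional AR(1) with ρ = 0.9) around per-treatment mean resistances
(defaults: stationary 0.79 MPa both materials, steel 0.71 MPa at f = 1
and 5, brass 0.79 MPa there, both 0.67 MPa at f = 10). Mechanistic mode
derives the means from the cavity-expansion algebra with the frictional
force attenuated as `Ff,m = Ff,s (1 − a·CI)`; the attenuation coefficient
defaults to `a = 2.0`, a calibration chosen so the strongest treatment
(steel at f = 10, CI ≈ 0.10) loses ≈20% of its friction — a resistance
drop of the same order as the measured ~15%. The noise level is a
modelling choice: the measured traces are smooth with small standard
errors but no noise statistics are reported.

*Deflection series.* `α(t) = (Δα/2) cos(2π t/T)` sampled once per minute,
with `Δα = 2 arcsin(δc/ls)` so the deflection equation returns the
configured `δc` exactly, plus Gaussian angle noise (default sd 0.01°,
i.e. sub-pixel line placement at the camera's 10.8 µm pixel pitch over the
45 mm shaft). The cosine phase puts sampled extrema on true extrema, so
noise-free series round-trip `δc` to 10⁻⁶ mm. Default per-treatment
deflections (steel 0.19/0.22/0.30 mm at f = 1/5/10; brass 0.30 mm
throughout) are calibrations consistent with the measured amplitude
ranges, not per-treatment measurements.

*CT phantom.* A cylindrical domain (default 6 mm × 8 mm at 24 µm voxels —
a reduced desk-scale geometry; all lengths are physical, so 12 µm
generation works unchanged) containing a cone void (base radius 1 mm, 15°
half-angle, ≈3.9 mm³ — the 40 mm³ full-scale imprint scaled to the
domain), a Boolean random-sphere pore background, and a compaction halo.
Grains default to 100 µm diameter, consistent with most of the soil's
pore network lying below 120 µm. The Boolean intensity is calibrated
against the discretised ball volume so the expected visible porosity hits
the target (0.17 by default) exactly; near the cone, sphere centres are
thinned so the expected porosity follows
`εvis(d) = ε_bg (1 − A e^(−d/λ))` with `A = 0.55`, `λ = 0.6 mm`.
The halo distance `d` is defined in the city-block metric — the same
metric as the dilation-based profiling — making the configured decay
length directly commensurate with fitted profile decays. The greyscale
variant maps pore/matrix to two modes (60/180), blurs and adds noise.

What the phantom does *not* emulate: real grain shapes and pore
connectivity, partial-volume and beam-hardening artefacts, grey-value
drift between scans, cracks, or any mechanical response — passing
recovery tests shows the analysis chain is self-consistent at realistic
porosities and geometries, not that it is robust to every scanning
artefact of real data.

All generators consume a single integer seed and emit a machine-readable
ground-truth record; identical configurations reproduce identical outputs.

## Statistics (`circumpen.stats`)

Per-replicate resistance is the trace mean over 0–10 mm divided by the
cone base area; treatments are summarised as mean ± SE (SE missing for a
single replicate). The ANCOVA fits `Q ~ f + material + f:material` by
least squares with type-II F-tests (the design is balanced, so the
sums-of-squares type is immaterial; type II is used and documented). LSD
comparisons use pooled residual variance over the one-way layout of all
treatment cells; the compact letter display uses the insert-and-absorb
construction, assigning letters in descending mean order, and is exact
for any overlap pattern. LSD operates on per-replicate means. Simple
regressions report slope, intercept, R² and the two-sided slope t-test.

## Problem sizes and validation protocol

Tests and the acceptance script run the experiment at its native size
(8 treatments × 5 replicates × 3600 samples) and the phantom at the
reduced default geometry (~2×10⁷ voxels, a few seconds per stage).
Decay-length validation fits `Δc(d) = A e^(−d/λ)` excluding shells within
one grain diameter plus two voxels of the imprint surface: within that
zone the watershed annexes whole touching grains into the imprint, which
depresses the measured shell porosity for reasons unrelated to the halo.
ANCOVA calibration uses 1000 simulated null experiments and a KS test for
uniformity of the frequency-term p-values.

## Known limitations

- The deflection model treats the projected angle as capturing the orbit;
  a single camera view cannot resolve the full 3D path, and the equations
  are applied as defined for the projection.
- `Fc,m = Fc,s` is an assumption, supported in the original experiment by
  unchanged imprint volumes and compaction profiles across treatments; the
  decomposition inherits it rather than testing it.
- The friction-attenuation coefficient and per-treatment deflections in
  the mechanistic generator are calibrations; recovery tests assert signs
  and conserved quantities, not their particular values.
- Imprint isolation parameters (median kernel, h-maxima depth, opening
  iterations) are documented defaults of this implementation, not claims
  about the original processing pipeline.
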