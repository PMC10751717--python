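# Methods

## Physics model

The engine transports photons only, between 1 keV (absorption cut-off,
configurable upward) and 1.4 MeV. Interactions:

- **Photoelectric absorption** terminates the track and deposits the full
  photon energy locally. Characteristic X-rays and Auger electrons are not
  re-emitted: in low-Z media (water, air, tissue, bone) all relaxation
  quanta fall below the cut-off; in the steel capsule and any shield this
  slightly overestimates local absorption and underestimates kerma behind
  high-Z material (K X-rays of iron are 6–7 keV and travel far less than a
  voxel; for iridium ~65 keV K X-rays the bias is visible only in the
  capsule's self-filtration, at the sub-percent level of the scored
  quantities).
- **Compton scattering** uses the free-electron Klein–Nishina cross
  section. Binding and Doppler corrections modify water kerma at ¹⁹²Ir
  energies well below the package's tolerances; the simplification is
  recorded in every run log.
- **Rayleigh scattering** is elastic; the angle is sampled from the
  Thomson cross section modulated by a squared molecular form factor built
  as an independent-atom sum of screened (Thomas–Fermi-type) atomic form
  factors, `F(x, Z) = Z (1 + (4π a_TF x)²)^{-3/2}` with
  `a_TF = 0.4685 Z^{-1/3}` Å. Only the angular *shape* comes from this
  model; the Rayleigh interaction *rate* comes from the shipped tables.
- **Pair production** is omitted: the ¹⁹²Ir spectrum barely exceeds the
  1022 keV threshold, with negligible yield there.

Collisional kerma equals absorbed dose only under charged-particle
equilibrium; for ¹⁹²Ir this holds to ~1% beyond 2 mm from a source.
Rather than masking near-source voxels, dose grids expose a
`cpe_flag(source_positions)` marking voxels within 2 mm, and the
benchmark metrics mask voxels overlapping the capsule solids.

## Interaction data

Coefficient tables (`src/brachymc/data/*.txt`, regenerable with
`scripts/build_physics_tables.py`) live on a 141-point log-uniform energy
grid over 1–1400 keV and are interpolated log-log (exact at nodes,
monotone between them). Construction, per material:

- **Total attenuation** `μ/ρ`: anchor values transcribed from the
  standard published photon mass-attenuation tabulations for water, dry
  air, cortical bone, iron, lead, hydrogen and oxygen, interpolated
  log-log onto the grid. K edges below 10 keV and L-shell structure are
  smoothed; the lead K edge at 88 keV is kept as a two-point step.
- **Channel partition**: incoherent = Klein–Nishina per gram times an
  empirical low-energy screening factor `E²/(E² + (1.4 Z_eff)²)`;
  coherent = a `Z_eff^1.5` per-electron power law (`E^-1.7`, flattened
  below 25 keV) anchored at the water coherent value at 100 keV;
  photoelectric = the remainder, floored at a tiny positive value. The
  partials therefore sum to the shipped total exactly.
- **Energy absorption** `μ_en/ρ` is the energy-transfer coefficient *of
  the model itself*: photoelectric (times a fluorescence-escape factor
  above metal K edges) plus Klein–Nishina mean Compton transfer. This
  choice makes the track-length and analogue estimators estimate exactly
  the same quantity — the estimator-equivalence test would fail by ~2%
  systematically with externally tabulated `μ_en/ρ`, which mixes bound
  incoherent corrections the transport does not sample. The model values
  agree with the published energy-absorption tabulations to ≤1% above
  150 keV for water and air (asserted in the test suite against
  independently transcribed anchors).
- **Stainless steel 316L** uses elemental iron coefficients (constituents
  are neighbouring-Z; the capsule wall is ~0.12 g/cm², so the few-percent
  per-gram difference moves scored quantities by <0.2%). **Iridium** is
  Z-scaled from lead (photoelectric ~Z^4.6/A, incoherent ~Z/A, coherent
  ~Z^2.5/A) with the K edge moved to 76.1 keV. Which photoelectric
  renormalization variant underlies any particular published tabulation is
  not resolved by these anchors; the data-file headers record the
  construction.

The ¹⁹²Ir emission spectrum ships as a plain-text line list (gammas plus
Os/Pt K X-rays, ≥0.01% per decay; total yield 2.299 photons/decay,
intensity-weighted mean 354.8 keV). L X-rays are omitted — they cannot
escape the source core.

## Estimators and uncertainty

A *history* is one primary photon (or one phase-space record with all its
split clones) and all its descendants. Both tallies accumulate
history-by-history: contributions of one history pool in a tagged buffer
and flush into Σx and Σx² when the next history touches the voxel, so
correlated contributions (multiple crossings, splitting progeny) form one
statistical unit. Per voxel: mean `x̄ = Σx/N`, standard error `s/√N` with
`s² = (Σx² − (Σx)²/N)/(N−1)`, relative Type A uncertainty `s/(√N x̄)`
reported at k=1 with k=2 available. A batch-free history-by-history
estimator was chosen over batching because it is unbiased at any history
count and keeps split progeny grouped by construction.

TLKE contributions are `w·l·E·(μ_en/ρ)(E, voxel material)/V` in eV/g per
history; the analogue scorer deposits `w·E_transferred/(ρV)` at the
interaction voxel (full `E` for photoelectric, `E−E'` for Compton, zero
for Rayleigh — local deposition, since electrons are not transported).
Conversions: 1 eV/g = 1.602×10⁻¹⁶ Gy.

## Transport mechanics

- **Woodcock (delta) tracking** against a per-energy majorant
  `Σ_maj(E) = 1.001 · max over voxels of ρ·(μ/ρ)(material, E)`
  (the 0.1% margin covers interpolation of the majorant curve; a real
  attenuation exceeding the majorant raises a consistency error).
  Virtual collisions keep direction and energy, so every straight
  flight leg is scored by exact Siddon traversal of the scoring grid.
- **Voxel conventions**: right-handed coordinates in cm; voxel (i,j,k)
  owns the half-open box `[origin + i·spacing, origin + (i+1)·spacing)`;
  a traversal crossing exactly on a shared plane attributes by that
  half-open rule, and corner grazes produce zero-length segments that are
  dropped.
- **Capsule**: photons are born uniformly in the active core with
  isotropic direction and spectrum-sampled energy, then delta-tracked
  through core/capsule/cable solids in the capsule frame. Once a photon
  leaves the capsule bounding cylinder the capsule solids are not
  re-entered: in voxel scenes the capsule acts at emission only. The
  re-entrant solid angle from 1 cm is ~10⁻⁴ and capsule voxels are
  masked from all metrics; this mirrors phase-space-based clinical
  practice, where the capsule is absent from the patient grid.
- **RNG**: PCG32 inside the kernels; the (state, stream) pairs derive
  from the run seed through numpy `SeedSequence`, so runs are
  bit-reproducible for a given seed and decomposing a run into batches
  cannot change results.

## TG-43 characterization

`S_k`: source in vacuum, air collisional kerma scored in a cell of 0.1 cm
radial width ("width" read as radial extent, the only reading consistent
with a cell *located at* r = 10 cm) and 0.1 cm height at 10 cm on the
transverse axis; `S_k = K̇_air·d²` in U (1 U = 1 μGy·m²·h⁻¹ =
1 cGy·cm²·h⁻¹). `Λ`: the source centered in a 40 cm-radius water sphere,
water kerma scored in a cell 0.5 mm thick and 1 mm high at 1 cm;
`Λ = Ḋ(1 cm)/S_k` in cGy·h⁻¹·U⁻¹. Both cells are extended azimuthally
into full rings: by the cylindrical symmetry of the geometries this is an
exact variance reduction, not an approximation. With photon-only
transport and vacuum surroundings, no free-air-chamber-style electron
filtering or scatter correction applies to the `S_k` run. Per-decay
normalization multiplies per-photon scores by the spectrum yield; the
normalization constant cancels in `Λ`.

The uncertainty budget combines components in quadrature within Type A
and Type B separately, then across types; k=2 doubles the k=1 total. The
shipped default component sets for the generic HDR source give Type B
totals of 0.22% (dose rate at 1 cm; dominated by 0.20% tally volume
averaging) and 0.09% (`S_k`).

## Source models and plans

Capsule dimensions enter only through editable YAML configurations. The
shipped `generic_hdr` model is a pure-iridium core 0.60 mm in diameter
and 3.5 mm long inside an AISI-316L-like capsule of 0.90 mm outer
diameter with ~0.2 mm end caps and a short stranded-steel cable stub;
`microselectron_v2` is the analogous clinical-afterloader geometry
(0.65 mm × 3.6 mm core). These are nominal published dimensions for the
source classes, not vendor drawings; `S_k` and `Λ` computed from them
land within the 2% commissioning tolerance of the consensus values — the
appropriate check for a simplified capsule model.

Phase-space files store capsule-exit records (energy, weight, position,
direction; little-endian float32, versioned JSON header; lossless round
trip). The dwell-plan source replays records with particle splitting:
each record emits `split_factor` clones of weight `1/split`, each
independently assigned a dwell position with probability proportional to
dwell time and rigidly transformed by that dwell's orientation; all
clones of a record share one history. When the record stream is
exhausted it restarts (recorded in run metadata), the deterministic dwell
transforms continuing from the run's RNG stream. Catheter orientations
come from central differences of neighbouring dwell positions (one-sided
at the ends) with a minimal-rotation convention (rotation about the axis
normal to capsule axis and tangent), which removes the roll ambiguity a
cylindrically symmetric source leaves open.

Absolute normalization offers two routes: scaling the per-history grid so
the prescription point receives the prescription dose (an exact
arithmetic identity, the default), or the TG-43-style air-kerma bridge
`N_hist = TRAK / S_k^{per history}` when a plan carries a total reference
air kerma.

## Synthetic data

The generator produces the two clinical-scale scenarios end to end:

- **Prostate-like**: a 19.2×19.2×20.8 cm pelvis (3–4 mm voxels at the
  default reduced scale) with elliptical body, 4×4×3.5 cm ellipsoidal
  target, tubular urethra and rectum, bladder, and two high-intensity
  bone columns present only in the image (no bone contour — exercising
  intensity-range segmentation); 17 catheters with 111 dwells prescribed
  15 Gy, peripheral and end dwells weighted longer as a planner would.
- **Lung-like**: a 35×35×20.4 cm thorax with two air lungs and a
  bronchus; a single 19-dwell catheter curving through the bronchus into
  the left lung, prescribed 5 Gy at 1 cm. Rectum, lungs and bronchus are
  assigned air — the worst-case material scheme.

All geometry is deterministic in the seed (byte-identical files on
repeat). What these fixtures do *not* emulate: real CT texture and
HU-to-density calibration, irregular patient contours, DICOM encoding,
metal artifacts, and vendor applicators. Tests passing on them therefore
demonstrate the correctness of the pipeline mechanics (segmentation
precedence, scatter saturation, DVH arithmetic, splitting invariance) —
not agreement with any patient dataset.

## Problem sizes

The test and acceptance runs are sized for a single desk CPU: the
water-cube efficiency scene uses a 24 cm water cube with a 4.1 cm / 1 mm³
scoring mesh at 1.5–4×10⁶ histories (the published full-size setup is a
51.1 cm cube, 20.1 cm mesh and 5×10¹⁰ histories); `S_k` uses 8–10×10⁶
vacuum histories and `Λ` 2–4×10⁶ sphere histories (Type A ≲0.6% k=1);
clinical demonstrations run 1–2×10⁵ histories on 3–5 mm grids. At this
scale the analogue/TLKE uncertainty ratio near 1 cm converges to ~12
(the full-size figure is ~10); the ratio grows slightly as the scene
shrinks because the local fluence spectrum hardens.

## Known limitations

- No electron transport: kerma ≠ dose within ~2 mm of sources and near
  high-Z interfaces (flagged, not corrected).
- Free-electron Compton and a screened-analytic form factor: sub-percent
  biases in water at ¹⁹²Ir energies, larger in high-Z shields.
- Iridium and steel coefficient tables are analytic reconstructions
  (Z-scaled / elemental-iron); their few-percent uncertainty propagates
  to ~1% in `S_k` through core self-absorption.
- The detailed shielded-applicator benchmark geometry is represented
  only by a configurable cylindrical shield stand-in.
- No comparison datasets ship with the package; the metric suite reads
  any congruent external grid.
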