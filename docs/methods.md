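# Model and methods

## The model

`ebtip` simulates a single growing microtubule plus-end at the resolution of
individual tubulin dimers and individual EB1 molecules, renders the result
into TIRF-like two-channel images by model convolution, and quantifies EB1
tip tracking the way the corresponding experiments are quantified.

### Lattice

The microtubule is a 2D index sheet of 13 protofilaments of 8 nm dimers with
a circular seam (protofilament 13 bonds laterally to protofilament 1; no
helical offset — the offset is irrelevant to every measured output). Each
dimer carries a nucleotide state (GTP/GDP) and two lateral-bond flags. The
first 25 dimers of every protofilament form a stabilized seed — the
in-silico analogue of a GMPCPP seed — that never hydrolyzes and never
depolymerizes. There is no explicit mechanics: "flaring" is a classification
rule only (see below), and the model tracks no 3D geometry.

EB1 binds a pocket formed by up to four dimers at a protofilament interface:
two longitudinally adjacent dimers on each side. A pocket with all four
members is a **closed-lattice site**; with two or three members (at a
protofilament tip, along an exposed protofilament side, or at a lattice
opening) it is a **protofilament-edge site**; below two members the pocket
does not exist and any EB1 on it is force-released. The pocket's nucleotide
class is GDP as soon as either of its two minus-end-ward member dimers has
hydrolyzed. Neighbouring pockets share dimers; occupancy exclusion is
per-pocket only.

### Kinetics

Every candidate event is a Poisson process; a candidate's waiting time is
`-log(u)/k`. One event executes per step (the first-reaction minimum), then
a single hydrolysis time is drawn from the aggregate rate
`k_hydrolysis x (non-seed GTP dimers)` and, if shorter than the executed
event's time, one uniformly random non-seed GTP dimer converts to GDP. The
production kernel samples this law in aggregate form (`dt ~ Exp(R_total)`,
event chosen proportionally to rate), which is the exact joint distribution
of the per-candidate minimum; the literal per-candidate implementation in
`ebtip.reference` is held equivalent by tests against the closed-form
equilibrium occupancy on frozen lattices.

Rates (defaults; all exposed in `KineticParameters` and the YAML loader):

| parameter | default | note |
|---|---|---|
| tubulin on-rate | 0.654 uM^-1 s^-1 per pf | 13 x 0.654 x 10 uM ~ 85 s^-1 total |
| tubulin off (GTP; 0/1/2 lateral bonds) | 4.0 / 0.5 / 0.067 s^-1 | tip dimer only |
| tubulin off (GDP) | 40 / 12 / 5 s^-1 | hydrolyzed tips shed |
| lateral bond formation | 0.5 s^-1 per formable bond | |
| lateral bond breakage | 0.1 / pi_break s^-1 per bond | pi_break 10 (6 in split preset) |
| hydrolysis | 0.55 s^-1 per GTP dimer | slow variant 0.05 |
| catastrophe boost | 100x | applied to tubulin off + bond breakage |
| taper threshold | 75 dimers (600 nm) | longest minus second-shortest pf |
| EB1 concentration | 50 nM | |
| EB1 on, edge / closed | 4.7e-3 / 9.4e-5 nM^-1 site^-1 s^-1 | 50:1, nucleotide-independent |
| EB1 off, closed GTP / GDP | 0.11/12 / 0.11 s^-1 | 12:1 GDP:GTP |
| EB1 off, edge GTP / GDP | 0.11/12 / 0.05 s^-1 | |

The two dimensionless ratios that control tip tracking — the edge:closed
on-rate ratio (50–100:1) and the closed-lattice GDP:GTP off-rate ratio
(6–12:1) — are the experimentally measured bands; the defaults sit at 50:1
and 12:1. The absolute scales are not published, so they were calibrated
here, once, against the model's own quantitative anchors: total tubulin
arrival ~85 s^-1 at 10 uM with growth in the 10–30 nm/s band, a fitted tip
standard deviation near 191 nm, a comet peak ~130 nm behind the microtubule
end, a ~2x lattice-intensity gain at 0.05 s^-1 hydrolysis, and a ~25% Tip
Specificity loss at half the edge on-rate. Two calibration choices deserve
comment:

- **Absolute EB1 off-rates are low** (closed GDP 0.11 s^-1). The comet in
  this model is a flux population: EB1 lands on edge pockets at the tip, is
  locked into a closed GTP pocket by the next tubulin arrival, converts to
  GDP with the site, and then unbinds. Its spatial trail behind the tip is
  `growth rate / k_off_closed_GDP`; a ~130 nm peak offset at ~18 nm/s
  requires second-scale retention, i.e. off-rates well below the per-site
  hydrolysis conversion rate. This is also what makes "monomer mode" (all
  EB1 off-rates x4) cost roughly threefold in tip signal.
- **GDP tubulin sheds from bonded tips** (12 and 5 s^-1 at 1–2 bonds, above
  the per-protofilament arrival rate of 6.5 s^-1). A protofilament whose tip
  hydrolyzes therefore digs down until it re-enters the GTP-rich zone and
  recovers, producing transiently lagging protofilaments. This is the
  geometry that gives the observed tip taper and places the EB1 peak behind
  the microtubule end; with GDP off-rates scaled uniformly from the GTP
  column, tips stay too coherent and the comet sits on the end.

### Catastrophe and rescue

After every event the taper rule is evaluated: if the longest protofilament
exceeds the second-shortest by more than 600 nm (75 dimers; ~400 dimers in
the split-comet preset), tubulin off-rates and the bond breakage rate are
multiplied by 100x and the end shortens rapidly. Rescue is implicit: the
boost clears when the taper falls back under threshold (or the seed is
reached). There is no explicit rescue rate. Catastrophe times are recorded
at boost trips following at least 1 um of net growth from the seed.
Catastrophe–rescue cycles leave a "scar" of fresh GTP mid-lattice; growth
events whose lattice was scarred before the analysis frame are excluded
from intensity measurements.

## Imaging (model convolution)

15% of dimers carry a red fluorophore (drawn once per run, so label identity
persists across frames); every bound EB1 carries a green one. Point sources
are deposited with bilinear interpolation on a 64 nm pixel grid (all 13
protofilaments on the axis row — the 25 nm tube is unresolvable under the
PSF), convolved with an isotropic Gaussian PSF (sigma 130 nm, typical of a
1.49-NA TIRF objective at ~510 nm emission; the kernel is normalized to
unit sum so summed intensity counts fluorophores), and uniform noise on
[0, A] is added last (A defaults to 10% of a single fluorophore's peak).
No photobleaching, camera gain statistics, or TIRF axial decay are modeled.

## Quantification

- **Line scans** average a 5-pixel transverse band. Ensembles are
  registered at each profile's EB1 peak (searched near the red end so dim
  comets are not out-registered by noise), averaged over >= 5 growth
  events, and zeroed where the red channel crosses halfway between its
  maximum and minimum — the microtubule end. Positions increase toward the
  minus end.
- **Peak EB1 position**: distance from the end to the green maximum
  (parabolic sub-pixel refinement).
- **Tip:lattice ratio**: green maximum within +-512 nm of the end over the
  median green 768–1024 nm behind it.
- **Tip standard deviation**: least-squares fit of
  `A/2 erfc((x-mu)/(sigma sqrt(2))) + B` to the red profile around the end;
  sigma convolves the protofilament-length spread with the PSF, so a blunt
  tip recovers the PSF sigma.
- **Tip Specificity** `S = (I_tip - I_bg)/(I_lattice - I_bg)` from summed
  4x4-pixel boxes; automated picking uses the brightest green pixel near
  the end, a lattice box 1 um behind along the axis, and a background box
  offset transversely. Per growth event, five frames aligned at the comet
  are averaged first; single frames are shot-noise dominated in the lattice
  box. S is invariant under affine intensity rescaling.
- **Split comets**: frames are classified single/split by peak detection
  near the end (>= 720 nm separation, seed region excluded); the brightest
  split frame is paired with the brightest *preceding* single frame within
  40 s, green intensity is summed over the smallest region covering all
  comets in both frames, and a seed-only frame supplies the background.
- **Sweeps** vary one parameter over 1/16–16x (2-fold steps, explicit lists
  accepted since the published ranges differ between figure and video
  captions) with replicate growth events per point; profiles are scored by
  the sum of absolute errors against a reference profile over a window
  around the comet (-512 to +1536 nm), so the score reflects comet shape
  rather than far-lattice noise.
- **Coverage fraction** (damaged-lattice binding assays): Otsu threshold on
  the red channel defines the microtubule mask; green is binarized at an
  explicit threshold; the green-covered fraction of the mask is returned.

## Ensemble protocol and problem sizes

A growth event is one seeded run from the seed to its first catastrophe
(cap 400 s). The analysis frame is the first snapshot where every
protofilament exceeds 235 dimers, so the 768–1024 nm lattice window clears
the (EB1-avid, all-GTP) seed by several PSF widths. Binding-origin censuses
count events from when the mean length reaches 1 um ("steady growth").
Default ensemble sizes are 10–12 growth events per condition and 5–6 per
sweep point — reduced from the original 97-event ensembles; published means
are reproduced but ensemble SEMs here are correspondingly larger.

## Known limitations

- The constant-rate lateral-bond model (a single formation rate and a
  single breakage rate with `pi_break` as a divisor) produces continuous
  tip tapers rather than discrete lagging protofilament clusters. Frank
  two-puncta comet splits are therefore rare, and the paired split-comet
  intensity gain measures ~20–25% rather than ~40%; the sweep responses of
  tip intensity to the edge on-rate are near-linear (no strong saturation).
  An energy-based bond model with cooperative breakage would be required to
  recover those regimes.
- The census of bound EB1 by class runs about 1.3:1 closed-GTP : all
  edge-bound during steady growth (about 2:1 against GTP edge-bound only);
  partially saturated GDP edge pockets on exposed sides hold the balance.
- Free EB1 and tubulin form a well-mixed reservoir at fixed concentration;
  there is no diffusion, no EB1 effect on tubulin kinetics, and no explicit
  GTP-cap "maturation" intermediate.
- Simulated-image tests show what the *pipeline* measures on this model's
  output; they do not validate the model against real micrographs beyond
  the published summary statistics.
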