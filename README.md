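# ebtip

Stochastic simulation of EB1 tip tracking on growing microtubule plus-ends,
with model-convolution imaging and comet quantification.

EB1 marks growing microtubule ends as a moving "comet" and recruits much of
the +TIP machinery there. The usual explanation — EB1 prefers GTP-tubulin in
the unhydrolyzed cap over GDP-tubulin in the lattice — accounts for *where*
extra affinity lies but struggles to explain how efficiently the comet forms.
`ebtip` implements a molecular-scale model in which a second ingredient does
that work: EB1 arrives 50–100x faster at *protofilament-edge* sites (partial
binding pockets of 2–3 tubulin dimers at protofilament tips, exposed sides
and lattice openings) than at closed four-dimer pockets, and newly arriving
tubulin then "locks" edge-bound EB1 into closed GTP pockets at the tip.

The package is aimed at cytoskeleton biophysicists who want to interrogate
that mechanism quantitatively: every rate is explicit, every published
readout (peak comet position, tip taper, Tip Specificity, split-comet
intensity, on-rate sweeps) is a reproducible pipeline, and the simulated
output is rendered into TIRF-like images so that simulation and experiment
are measured with the same rulers.

## The model in brief

A 13-protofilament lattice of 8 nm dimers grows by single-dimer arrivals
(`k_on [tubulin]` per protofilament), loses tip dimers at rates set by their
nucleotide and lateral-bond state, forms and breaks lateral bonds
stochastically, and hydrolyzes GTP-tubulin at 0.55 s^-1 per dimer. Each
step executes the single event with the shortest exponential waiting time
(`t = -ln(u)/k`, first-reaction selection), followed by a hydrolysis
sub-step. When the tip taper (longest minus second-shortest protofilament)
exceeds 600 nm, off- and bond-breakage rates jump 100x: a catastrophe.

EB1 binds any pocket at rate `k_on^edge [EB1]` or `k_on^closed [EB1]`
depending only on the pocket's structural class (edge : closed = 50:1), and
unbinds at rates set by the pocket's hydrolysis state (closed GDP : GTP =
12:1). Occupied snapshots are rendered by model convolution — 15% red-labeled
dimers, green EB1, 130 nm Gaussian PSF, uniform noise — and quantified with
registered line scans, erfc tip fits, and Tip Specificity
`S = (I_tip - I_bg) / (I_lattice - I_bg)`.

See `docs/methods.md` for the full parameter table and the calibration
rationale.

## Worked example

```python
from ebtip import KineticParameters
from ebtip.workflows import measure_ensemble

res = measure_ensemble(KineticParameters(), n_events=6, base_seed=0)
print(f"mean growth rate       : {res['mean_growth_rate_nm_s']:.1f} nm/s")
print(f"peak EB1 position      : {res['peak_eb1_position_nm']:.0f} nm behind the end")
print(f"tip standard deviation : {res['mean_sigma_tip_nm']:.0f} +- {res['sem_sigma_tip_nm']:.0f} nm (mean +- SEM)")
print(f"tip:lattice ratio      : {res['tip_lattice_ratio']:.1f}")
print(f"edge binding fraction  : {100*res['mean_edge_binding_fraction']:.0f}%")
```

prints

```
mean growth rate       : 18.2 nm/s
peak EB1 position      : 140 nm behind the end
tip standard deviation : 197 +- 12 nm (mean +- SEM)
tip:lattice ratio      : 5.0
edge binding fraction  : 53%
```

Six baseline growth events were simulated to their first catastrophe,
model-convolved, line-scanned, registered at the EB1 peak and averaged. The
microtubule grows in the 10–30 nm/s regime the model is calibrated for; the
EB1 comet peaks ~140 nm behind the microtubule end (the red channel's
half-max position) even though nothing in the model singles out that
location — it emerges from edge-site binding across the tapered tip plus
the retention of locked-in EB1; the erfc fit of the red edge gives a
~200 nm tip standard deviation (protofilament-length spread convolved with
the PSF); the comet is ~5x brighter than the GDP lattice; and about half of
all EB1 binding events land on protofilament-edge sites.

The same machinery is scriptable from the shell:

```bash
ebtip simulate --out runs/ --seed 1 --n-steps 200000
ebtip render runs/trajectory_seed1.h5 --out runs/frames --pixel-size 64
ebtip analyze runs/frames/frame_*.tif --what linescan
ebtip preset slow_hydrolysis --out runs/slow --replicates 8
ebtip sweep k_on_edge --out sweep.csv --replicates 5
```

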