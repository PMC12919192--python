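# cellstretch

Multiscale viscoelastic simulation of a cell stretched on a flexible
membrane, for mechanobiology groups that condition cultured cells (for
example mesenchymal stem cells) with cyclic substrate stretch and want to
know what actually reaches the nucleus and the chromatin.

Experiments routinely assume the cell experiences the substrate strain. This
package quantifies that assumption with a three-compartment continuum model:

* **Geometry** — a half-ellipsoid cell (z ≥ 0, elliptical attachment at the
  basal plane) with an embedded ellipsoidal nucleus; x is the cell's long
  axis, y the short in-plane axis.
* **Mechanics** — cytoplasm and nucleus are Kelvin-Voigt viscoelastic solids,
  σ = C(E, ν) : ε + (η/E) · C(E, ν) : ε̇, with literature-based moduli
  (cytoplasm 4 kPa / 5.43 kPa·s, nucleus 2.01 kPa / 0.97 kPa·s); the plasma
  membrane (2.98 kPa / 4.01 kPa·s, 10 nm) is a viscoelastic shell on the
  outer surface. The quasi-static balance K u + D u̇ = f is advanced
  implicitly over cycles of applied strain, with the basal plane following
  the substrate affinely (perfect coupling).
* **Loading** — sine (raised cosine, 0 → ε_max → 0) or a brachial-artery
  distension pulse, at 0.1 or 1 Hz, ε_max from 2.5 to 17.5 %; equibiaxial by
  default, with an anisotropic mode (u_y = r · ε · y) for exploring
  long/short-axis strain partition.
* **Chromatin** — the volume-averaged nuclear stress σ(t) drives a
  Kelvin-Voigt chromosome, ε̇_c = −(E/η) ε_c + σ(t)/η (interphase
  E = 3.82 Pa, η = 68.81; mitotic E = 611.63 Pa, η = 733.95), and each cycle
  is classified by its fold extension 1 + ε_c: below 2× native length
  sub-threshold, 2–3× mechanical unfolding, ≥ 3× damaging. Because all of
  the averaged stress is applied to one chromosome, this is an upper-bound
  estimate.

The meshing (graded Delaunay tetrahedralization of the convex half-ellipsoid
domain), the P1 viscoelastic finite elements and the plain-text VTU/Gmsh
exporters are implemented here directly on numpy/scipy.

## Worked example

Run one loading condition (7.5 % sine at 0.1 Hz, 10 cycles, desk-scale mesh)
and summarize it:

```bash
cellstretch run --only "waveform=sine,freq=0.1,eps=0.075" --output-dir demo
cellstretch report demo
```

```
Chromatin regimes (final cycle):
phase                          interphase  mitotic
waveform frequency_hz eps_max
sine     0.1          0.075         36.91    1.389

Final-cycle X/Y nuclear strain ratios:
waveform  frequency_hz  eps_max  xy_ratio
    sine           0.1    0.075     1.213
```

Reading this: under equibiaxial coupling the nucleus follows the substrate
almost completely (final-cycle mean nuclear strain peaks ε_xx ≈ 0.076,
ε_yy ≈ 0.062, so the X/Y ratio is near 1.2), the mean nuclear σ_xx peaks
near 270 Pa, and the upper-bound interphase chromatin estimate saturates at
a 36.9-fold extension by cycle 10 — far beyond the damage threshold —
while the ~160× stiffer mitotic chromatin stays sub-threshold at 1.39-fold.
Per-run CSV time series (`nuclear_series.csv`, `cycle_summary.csv`,
`chromatin_trace_*.csv`) land in `demo/sine_f0.1_eps0.075/`.

The full sweep (`cellstretch run`, no filter) covers sine and brachial
waveforms × {0.1, 1} Hz × {2.5 … 17.5 %} in one command (~2 min at the
desk-scale profile; `--profile fidelity` uses the reference mesh sizing,
h_max 0.99 µm refined to 0.159 µm near interfaces, and is much heavier).

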