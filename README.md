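# flydense

Analysis pipeline for *Drosophila melanogaster* flight assays in
variable-density atmospheres.

When a culture bottle of fruit flies is flushed with helium or nitrogen and
ambient air is allowed to diffuse back in, the flies pass through a sequence
of behavior stages as oxygen and gas density recover: immobile (**A**),
walking (**B**), climbing the walls (**C**), ballistic jumps (**D**),
wing-assisted jumps (**E**), and finally sustained powered flight (**F**).
Because N₂ barely changes the gas density while He lowers it drastically, the
pair of conditions decouples *oxygen availability* from *atmospheric density*
as the limiting factor for flight: the O₂ partial pressure at which flight
first reappears differs strongly between the two gases, and the
corresponding mixture density identifies the minimum density that supports
active flight.

`flydense` implements the full analysis chain for such assays, plus a
synthetic-data generator so the chain can be exercised and validated without
terabytes of raw video:

* **gas** — mixture density from the measured O₂ partial pressure and
  conversion of a density to a standard-atmosphere flight ceiling,
* **simulate** — a two-pinhole-camera scene generator: flush/recovery O₂
  series, stage-gated fly trajectories in a box-shaped bottle, pixel noise,
  detector dropout, false positives, camera desynchronization, and periodic
  shake windows,
* **stereo** — timestamp-based frame pairing, shake-frame rejection, and
  exhaustive detection-vs-detection triangulation with reprojection-error
  gating and one-to-one conflict resolution,
* **tracking** — two-pass linking: slow crawling tracks first, then the
  fast airborne remainder,
* **behavior** — wall-state segmentation, ballistic least-squares fits
  `z(t) = z₀ + v_z t − ½ g_eff t²`, and stage labeling (a good parabolic fit
  with `g_eff ≈ g` is a jump, `g_eff` well below `g` an assisted jump, and a
  strongly non-parabolic fast trajectory powered flight),
* **experiment** — joining events with the O₂ sensor series and summarizing
  each run as the minimal pO₂ (and density) of first activity, climbing, and
  flight.

## The core quantities

With air mole fraction `f = pO₂ / pO₂_ambient` (ambient 210 mbar), the
chamber density is the blend of ideal-gas component densities at 273.15 K and
1013.25 hPa:

```
ρ(pO₂) = f·ρ_air + (1 − f)·ρ_flush,   ρ_x = P·M_x / (R·T)
```

The minimal flight-supporting density maps to an equivalent altitude through
the troposphere branch of the International Standard Atmosphere,

```
ρ(h) = ρ₀ (1 − L·h/T₀)^(g/(R_s·L) − 1)
```

inverted in closed form.

## Worked example

```
$ flydense density --gas He --po2 142
0.9316 kg/m^3 (72% of ambient air)

$ flydense ceiling --rho 0.93
2779 m (2.8 km)
```

A He-flushed chamber with 142 mbar of O₂ has a density of 0.93 kg/m³ — 72%
of sea-level air — and air only gets that thin at about 3 km altitude, which
is therefore the equivalent flight ceiling for an insect that needs at least
that density to fly.

Running the whole pipeline on a simulated helium experiment (4 flies,
180 s at 30 fps, flight-density gate 0.93 kg/m³):

```
$ flydense run-all --gas He --seed 1 --out out/he1
experiment gas  first_activity_pO2  ...  first_flight_pO2  first_flight_density
      He_1  He           33.496843  ...        141.875376              0.930957
```

The pipeline reconstructs the flies in 3D from the two noisy detection
tables, links and classifies their tracks, and recovers both gates it was
given: activity reappears at ≈33 mbar of O₂ (the configured hypoxia gate)
and the first powered flight occurs at ≈142 mbar, i.e. at a recovered
density of 0.931 kg/m³ against the configured 0.93 kg/m³ gate.  In an N₂ run
the density never drops much below ambient, so flies go straight from
climbing to flight and the jump stages D/E never appear — the behavioral
signature that separates density limitation from oxygen limitation.

## Layout

```
src/flydense/     gas.py geometry.py simulate.py stereo.py
                  tracking.py behavior.py experiment.py io.py cli.py
tests/            unit, property and end-to-end suites
docs/methods.md   model assumptions, parameter choices, limitations
```
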