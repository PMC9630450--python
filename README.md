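# astromigrate

Quantitative analysis of astrocyte-progenitor migration in the developing
cerebral cortex, for researchers doing time-lapse imaging of brain slices.

During late cortical development, astrocyte progenitors leave the
ventricular zone and spread through the cortical plate using two unusual
migration modes: *erratic* migration — fast, frequently turning movement
with a net drift toward the brain surface — and *blood vessel-guided*
migration, in which cells crawl along the abluminal surface of cortical
vessels, attaching and detaching as they go.  Quantifying these behaviours
requires a small zoo of measurements that this package implements as a
tested, reusable library:

* **Trajectory statistics** — per-frame speeds with a strict gate
  (> 10 um/h), signed turning angles between consecutive gated frames
  (positive = rightward turn in the right hemisphere, leftward in the
  left), signed angles to the radial axis (lateral positive, medial
  negative), net-displacement polar summaries, and a motility filter
  (> 20 um displacement in 24 h).
* **Vessel association** — voxelized vessel reconstruction from the
  endothelial channel (threshold, small-object removal, medial-axis
  skeleton, 6-connectivity surface), centre-to-surface nearest distances in
  physical um, edge exclusion (15 um at the Z faces, 20 um at the XY
  borders), the < 5 um association fraction with its histogram, per-frame
  on/off-vessel track labels, the ≥ 5 h on-vessel persistence selection,
  and per-field off/on ratios for endothelial-tube co-cultures (tracks
  traceable ≥ 10 h).
* **Cortical depth distribution** — double-positive cell detection by
  channel product, 26-connected components, local maxima and a strict
  > 6,000 um³ size filter; relative depth between the upper and lower
  cortical-plate borders; four-bin depth histograms; per-brain Dunnett or
  Tukey comparisons of bin fractions.
* **Statistics** — Student/Welch t (with an F-test variance gate),
  Mann-Whitney, Dunnett (deterministic multivariate-t quadrature), Tukey
  HSD, and Kruskal-Wallis-gated Dunn comparisons, all with box-plot
  descriptives (whiskers at 1.5× IQR) and the *, **, ***, **** star
  convention at 0.05, 0.01, 0.001, 0.0001.
* **A synthetic slice simulator** — seeded, parameterized generators for
  radially biased capsule vessel networks, trajectories of the three
  migration classes (with ground-truth contact flags), uniform nuclei
  reference clouds, and rasterized multi-channel volumes — so every
  analysis stage is verifiable end to end without external data.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

```python
from astromigrate import AnalysisConfig, SimulationConfig
from astromigrate import synthetic
from astromigrate.trajectory import compare_speed_distributions, frame_steps
from astromigrate.vessels import (association_fraction, build_vessel_mask,
                                  nearest_vessel_distance)

sim = SimulationConfig(seed=1)          # one 300 x 300 x 50 um field, 24 h at 15 min
ana = AnalysisConfig()                  # 10 um/h gate, 5 um association, 15/20 um margins

vessels = synthetic.generate_vessel_network(sim)
tracks = synthetic.generate_tracks(sim, vessels)

erratic = [s for t in tracks if t.true_mode == "erratic" for s in frame_steps(t, ana)]
radial = [s for t in tracks if t.true_mode == "radial" for s in frame_steps(t, ana)]
rep = compare_speed_distributions(erratic, radial)
e, r = rep.group_summaries
print(f"erratic: {e['n']} gated frames, {e['mean']:.1f} +/- {e['sd']:.1f} um/h")
print(f"radial:  {r['n']} gated frames, {r['mean']:.1f} +/- {r['sd']:.1f} um/h")
print(f"Welch t = {rep.statistic:.1f}, p = {rep.p_two_sided:.3g} ({rep.stars()})")

stack = synthetic.rasterize(vessels, tracks, frame_index=0, config=sim)
mask = build_vessel_mask(stack, "vessels", sim.channel_amplitude / 2, ana)
nuclei = synthetic.generate_nuclei(sim, 5000)
frac, hist = association_fraction(nearest_vessel_distance(nuclei, mask), ana)
print(f"nuclei within 5 um of a vessel: {100 * frac:.1f}%"
      f" (analytic null {100 * vessels.volume_fraction(sim.field_size_um, dilate_um=5.0):.1f}%)")
```

Output:

```
erratic: 948 gated frames, 29.6 +/- 10.4 um/h
radial:  475 gated frames, 13.8 +/- 3.3 um/h
Welch t = 42.7, p = 1.49e-247 (****)
nuclei within 5 um of a vessel: 7.2% (analytic null 8.4%)
```

The first three lines are the speed comparison between the two
vessel-independent migration modes: erratic cells move at ~30 um/h per
gated frame versus ~14 um/h for radially migrating cells, and Welch's test
separates the distributions decisively.  The last line is the association
null model: uniformly placed nuclei fall within 5 um of a vessel about as
often as the analytic volume fraction of the 5-um-dilated vessel network
predicts — the baseline against which a perivascular accumulation of real
cells would be judged.

## Command line

The same stages run from a shell, one output directory per run, with a
manifest recording the resolved config, seeds and content hashes:

```sh
astromigrate all --seed 1 --out-dir runs/demo
astromigrate simulate --config myconfig.json --out-dir runs/exp1
astromigrate vessel-dist --out-dir runs/exp1     # reuses simulate outputs
```

Stages: `simulate`, `track-stats`, `vessel-dist`, `classify`,
`distribution`, `report`, `all`.  Config files are JSON with `simulation`
and `analysis` sections; unknown keys are rejected.  Tracks can also be
supplied as TrackMate-dialect XML (physical units required) via
`astromigrate.io.read_trackmate_xml`.

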