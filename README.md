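# inclusiontools

Quantitative image and flow-cytometry analysis of polyglutamine-expanded
Huntingtin exon 1 (Httex1) inclusion bodies.

Mutant Httex1 with a polyQ tract beyond ~35 repeats forms intracellular
inclusions. A tetracysteine-tagged biosensor (TC9-Httex1) distinguishes the
age of an inclusion: the biarsenical dye FlAsH binds the disordered
conformers enriched in newly formed inclusions and loses binding upon
amyloid conversion, so the FlAsH:Cerulean fluorescence ratio inside an
inclusion reports its maturity. `inclusiontools` implements the analysis
pipeline built around that biosensor, for cell biologists quantifying
inclusion assembly from multi-channel TIFF microscopy and per-event
cytometry CSV exports:

- **Maturity classification** — per-inclusion FlAsH:Cerulean ratio *R*,
  classified against per-experiment population thresholds: HBR (Highly
  Biarsenical-Reactive, early-formed) if *R* > mean + SEM, PBR (Poorly
  Biarsenical-Reactive, mature) if *R* < mean − SEM, INTERMEDIATE inside
  the band.
- **Zone enrichment** — radial core / middle / outer-ring partition of each
  inclusion (outer ring from the 110%-scaled boundary) quantifying
  co-recruitment of HaloTag-TMR-labelled proteins and EU/AF647-labelled RNA,
  plus OLS regression of compartment intensity on maturity ratio with 95%
  confidence bands.
- **FRAP mobility** — background-corrected relative recovery
  r(t) = (B(t) − bg(t)) / (U(t) − bg(t)) of a half-bleached inclusion, with
  a single-exponential mobile-fraction/halftime fit.
- **Antibody penetration** — porosity of inclusions as the difference of
  mean centroid-to-boundary distances between the 110%-scaled external
  boundary (cerulean) and the internal boundary of the anti-GFP-unstained
  core (inverted-threshold).
- **Pulse-shape cytometry** — PulSA-style gating of inclusion-bearing cells
  by a calibrated linear discriminant on pulse-shape features, and the
  20 logarithmic expression bins × 4 modifier categories inclusion-fraction
  surface.
- **Stall reporter** — per-event mCherry:GFP ratios of GFP–test–mCherry
  cassettes; ribosome stalling lowers the ratio below one.
- **Synthetic scenes** — a seeded generator of images, FRAP series and event
  tables with known ground truth (radial channel profiles, logistic
  inclusion probability, pulse-shape shifts), so every stage is testable
  without raw microscopy data.

## Worked example

Classify five synthetic inclusions whose true FlAsH:Cerulean ratios are
0.10, 0.15, 0.21, 0.30 and 0.45:

```python
import inclusiontools as it

ratios = []
for i, target in enumerate([0.10, 0.15, 0.21, 0.30, 0.45]):
    image, truth = it.render_scene(
        it.maturity_scene_spec(target, noise_sigma=2.0, seed=i))
    roi = it.largest_component(it.auto_threshold(image["cerulean"]))
    ratios.append(it.flash_cerulean_ratio(
        it.mean_intensity(image["flash"], roi),
        it.mean_intensity(image["cerulean"], roi)))

thr = it.population_thresholds(ratios)
print(f"mean {thr.population_mean:.4f}  sem {thr.population_sem:.4f}")
for r in ratios:
    print(round(r, 4), it.classify(r, thr).value)
```

prints

```
mean 0.2421  sem 0.0617
0.1001 PBR
0.1501 PBR
0.2106 INTERMEDIATE
0.3001 INTERMEDIATE
0.4496 HBR
```

The measured ratios match the generating targets to the noise level; the two
low-ratio inclusions fall more than one SEM below the population mean and are
classified as mature (PBR), the high-ratio one more than one SEM above as
early-formed (HBR), and the two inside the ±SEM band are reported explicitly
as INTERMEDIATE rather than silently dropped.

The same analyses run from the shell. An immobile-inclusion FRAP experiment
end to end:

```sh
$ inclusiontools simulate --kind frap --seed 7 --out sim
$ inclusiontools frap --fusion-series sim/frap_mcherry.tif \
      --flash-series sim/frap_flash.tif --out frap_out
$ cat frap_out/frap_summary.json
{
  "end_recovery": 0.2,
  "delta_recovery": 0.0,
  "mobile_fraction_estimate": 0.0005931972335073038,
  ...
}
```

The bleached half stays at its immediate post-bleach level for the whole
21-minute series (`delta_recovery` 0, mobile fraction ≈ 0) — the
no-recovery phenotype of rigid inclusions. Subcommands `simulate`,
`segment`, `maturity`, `zones`, `frap`, `penetration`, `cytometry` and
`stall` all accept `--seed`, `--config` (YAML) and `--out`, write
schema-validated CSVs plus a JSON run report, and are byte-for-byte
reproducible for a fixed configuration.

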