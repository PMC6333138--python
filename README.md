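# tldose

Organ dose estimation for chest CT phantom studies with thermoluminescent
dosimeters (TLDs), plus the protocol-comparison and method-agreement
statistics built on top of it.

The measurement chain implemented here:

1. **Calibration** — fit a straight line mapping reader TL integrals to air
   kerma (free or forced-zero intercept, optional inverse-variance weights),
   with parameter standard errors.
2. **Background subtraction** — subtract the mean TL of a control group kept
   outside the exposure room.
3. **Slice kerma** — for each phantom slice, combine the three-chip TLD
   groups by an inverse-variance weighted mean (weights from the group's
   chip-to-chip scatter; a configurable variance floor handles zero-scatter
   groups).
4. **Slice dose** — convert slice air kerma to organ dose with the tabulated
   organ-to-air mass-energy absorption coefficient ratio for the run's tube
   voltage.
5. **Organ dose** — sum slice doses weighted by the organ mass fraction in
   each slice; uncertainties are first-order Gaussian, reported at k=1.

On top of the pipeline:

- **Protocol metrics** (`tldose.protocol`): mAs / effective mAs, dose per
  (effective) mAs, percent dose reductions, scout-scan dose fractions, and
  CTDIvol-coefficient organ dose estimates with relative differences.
- **Method agreement** (`tldose.comparison`): percent differences against
  simulated reference doses and Bland–Altman bias / 95% limits of agreement,
  with an optional plot.
- **Synthetic data** (`tldose.synth`): seeded generators that invert the
  dose chain to produce TL readings, calibration sets, and qualitative
  longitudinal tube-current-modulation profiles, so the full pipeline is
  testable without measurement data.

Packaged fixtures (`tldose/data/`) transcribe the study's layout, protocol,
coefficient and dose tables: adult (40 TLD groups over slices 11–19) and
pediatric (36 groups: 4 thyroid + 32 lung) phantom layouts, 10 acquisition
protocols plus the scout scan, mass-energy absorption coefficients at 80 and
120 kV, and the measured/simulated organ dose tables.

## CLI

The `tldose` entry point has five subcommands:

```sh
# generate a synthetic scenario (readings, background, calibration, layout)
tldose synth --layout adult_rando --protocols adult --protocol STD \
    --dose 14.30 --seed 1 --out-dir scratch/demo

# fit a calibration curve from a points CSV
tldose calibrate --calibration scratch/demo/calibration.csv --out curve.json

# run the full organ-dose pipeline
tldose dose --readings scratch/demo/readings.csv \
    --background scratch/demo/background.csv \
    --calibration scratch/demo/calibration.csv \
    --layout adult_rando --voltage 120 --out-dir scratch/demo/out

# protocol comparison (reductions + dose/mAs tables)
tldose compare --doses doses.csv --protocols adult --reference STD --out-dir out

# Bland–Altman agreement against simulated reference doses
tldose agreement --pairs pairs.csv --band 20 --out-dir out
```

Input formats: readings CSV (`chip_id,group_id,slice,organ,tl_value`),
calibration CSV (`tl_value,kerma_mGy,kerma_sigma_mGy`), layout JSON
(`{phantom_id, organs: [{organ, rows: [{slice, f, n_groups}]}]}`), pairs CSV
(`label,d_exp_mGy,d_exp_sigma,d_sim_mGy`).

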