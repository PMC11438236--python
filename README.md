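# hullmass

Body-mass estimation for quadrupedal tetrapods by two routes — whole-body
**minimum convex hull (MCH) volumetrics** and **stylopodial (limb-bone)
scaling** — together with the machinery to compare their accuracy and
precision, study limb-bone robustness allometry, and quantify
centre-of-mass (CoM) position from segmented body models.  It is written
for comparative biomechanists and paleobiologists who need reproducible
mass and CoM estimates from skeletal meshes or limb-bone measurements.

## The models

**Volumetric route.**  Each skeletal body segment (skull, neck, trunk,
tail, and the stylopod/zeugopod/autopod of every limb) is wrapped in its
minimum convex hull; hull volumes are computed exactly by signed-tetrahedron
summation over outward-oriented faces.  Segment volumes sum to whole-body
volume *V*, and the calibrated predictive equation is

    log10(M) = 0.968 · log10(V · ρ) + 0.215

with mass *M* in kg, *V* in m³ and density ρ = 1000 kg/m³ by default.

**Stylopodial route.**  From humerus and femur minimum midshaft
circumferences (mm):

    log10(M) = 2.716 · log10(C_humerus + C_femur) − 4.078

Both are ordinary least squares fits in log10–log10 space; `calibrate`
refits them on any specimen table.  Accuracy and precision are measured by
percent prediction error, PPE = 100·|obs − pred|/pred per specimen, with
group means and t-based 95% CIs (plus without-replacement subsampling to
put unequal sample sizes on the same footing).  Limb-bone *robustness*
(circumference/length) is analysed by log–log allometry with CI-versus-null
calls (isometry null slope 1 for circumference~length, 0 for
robustness~mass).  CoM position is the mass-weighted mean of segment
centroids, summarised as %C(AG) (percent cranial along the
acetabulum→glenoid transect) and DCA/FL (distance cranial of the
acetabulum over femur length), optionally under per-segment expansion
factors (MEF/SEF) or trunk deflation.

A synthetic-data module generates convex-primitive bodies with closed-form
volumes/centroids and specimen populations under the laws above, so every
stage is testable without the original CT meshes.

## Worked example

```python
>>> from hullmass import predict_mass_mch, predict_mass_ss, published_fossil_rows
>>> predict_mass_mch(1.0, density=1000.0)   # a 1 m^3 animal at water density
1315.2248321922377
>>> predict_mass_ss(48.0, 52.0)             # combined circumference 100 mm
22.59435770220978
>>> row = published_fossil_rows()[0]
>>> row.species, row.mch_kg, row.ss_kg, round(row.ratio_ss_mch, 1)
('Dinodontosaurus', 301.0, 1042.0, 3.5)
```

The first number says a 1 m³ hull at water density is predicted at about
1315 kg (slightly sub-isometric in hull volume); the second, that an
animal with 100 mm of combined stylopod circumference is predicted at
about 22.6 kg.  The last line reproduces the largest published
volumetric/stylopodial disagreement: for the dicynodont *Dinodontosaurus*
the limb-bone route predicts 3.5× the hull-based mass, because
Permo-Triassic tetrapods carry far more robust stylopodia than the extant
calibration sample.

From a shell, the same pipeline runs via the `hullmass` CLI
(`hull`, `calibrate`, `estimate`, `accuracy`, `robustness`, `com`,
`simulate`); e.g.

```sh
hullmass simulate --preset noiseless --n 50 --seed 7 --out extant.csv
hullmass calibrate --table extant.csv --out fits.json
# -> mch: slope 0.968 intercept 0.215 (r2 1.000, n 50)
# -> ss:  slope 2.716 intercept -4.078 (r2 1.000, n 50)
```

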