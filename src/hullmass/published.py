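"""Published reference values used as inputs and cross-checks.

These constants come from the published comparative study of volumetric
(minimum-convex-hull) versus stylopodial-scaling body-mass estimation in
quadrupedal tetrapods: the two predictive scaling equations fitted on the
extant calibration samples, the per-group mean percent prediction errors,
the limb-bone robustness regressions, and the body-mass estimates for the
twelve Permo-Triassic fossil taxa.  They are treated as literature inputs —
re-deriving them requires the original specimen tables and CT meshes.
"""

from __future__ import annotations

# --- Predictive scaling equations (log10 body mass in kg) -------------------

#: log10(mass) = 0.968 * log10(MCH volume [m^3] * density [kg/m^3]) + 0.215,
#: fitted on 33 extant specimens (25 species), r^2 = 0.993.
MCH_SLOPE = 0.968
MCH_INTERCEPT = 0.215
MCH_N = 33

#: log10(mass) = 2.716 * log10(humerus + femur circumference [mm]) - 4.078,
#: fitted on 266 extant amniotes.
SS_SLOPE = 2.716
SS_INTERCEPT = -4.078
SS_N = 266

# --- Precision: mean absolute PPE (%) with 95% CI halfwidths ----------------

MEAN_PPE = {
    # group: {method: (mean %, ci95 halfwidth %)}
    "total": {"mch": (19.3, 7.4), "ss": (28.8, 3.1)},
    "mammal": {"mch": (21.2, 11.6), "ss": (26.4, 3.1)},
    "crocodylian": {"mch": (16.1, 5.8), "ss": (29.0, 12.5)},
}

# --- Stylopod robustness: log10 circumference ~ log10 length ----------------
# (slope, slope 95% CI, intercept, intercept 95% CI); combined humerus+femur.

ROBUSTNESS_LENGTH_FITS = {
    "mammal": (1.038, (1.007, 1.069), -0.605, (-0.676, -0.534)),
    "reptile": (1.179, (1.077, 1.281), -0.840, (-1.043, -0.637)),
    "crocodylian": (0.985, (0.896, 1.074), -0.347, (-0.541, -0.153)),
    "fossil": (1.319, (1.106, 1.533), -1.053, (-1.563, -0.542)),
}

# log10 robustness (circumference/length) ~ log10 MCH-predicted mass;
# isometry null slope is 0.
ROBUSTNESS_MASS_FITS = {
    "mammal": (0.013, (-0.016, 0.042)),
    "crocodylian": (-0.004, (-0.034, 0.026)),
    "fossil": (0.092, (0.034, 0.150)),
}

# --- Fossil body-mass estimates ---------------------------------------------
# (species, log10 MCH mass, MCH mass kg, log10 SS mass, SS mass kg, SS/MCH),
# in the published descending-ratio order.

FOSSIL_MASS_TABLE = [
    ("Dinodontosaurus", 2.5, 301.0, 3.0, 1042.0, 3.5),
    ("Bradysaurus", 3.0, 906.0, 3.4, 2673.0, 3.0),
    ("Diadectes", 2.2, 160.0, 2.6, 415.0, 2.6),
    ("Eryops", 2.0, 104.0, 2.3, 217.0, 2.1),
    ("Orobates", 0.7, 5.5, 1.0, 11.0, 2.0),
    ("Scaloposaurus", -0.7, 0.2, -0.4, 0.4, 2.0),
    ("Tapinocaninus", 3.0, 1023.0, 3.2, 1663.0, 1.6),
    ("Lisowicia", 3.8, 6152.0, 4.0, 9332.0, 1.5),
    ("Procynosuchus", 0.7, 4.5, 0.7, 5.4, 1.2),
    ("Ophiacodon", 1.4, 27.0, 1.5, 30.0, 1.1),
    ("Dimetrodon", 1.7, 52.0, 1.6, 41.0, 0.8),
    ("Edaphosaurus", 2.1, 124.0, 1.7, 55.0, 0.4),
]

#: Regression of log10 SS-estimated on log10 MCH-estimated fossil mass.
DISCREPANCY_SLOPE = 1.020
DISCREPANCY_INTERCEPT = 0.163

# --- Physical defaults -------------------------------------------------------

#: Whole-body density used throughout, kg/m^3 (fresh water).
DEFAULT_DENSITY = 1000.0

#: Measured whole-body density range across extant taxa (horse .. crocodylian);
#: positional CoM metrics are exactly invariant to any uniform density in it.
DENSITY_RANGE = (893.0, 1080.0)
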