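"""Published group means for the *Brachypodium distachyon* species complex.

Steady-state gas exchange, stomatal density/size and anatomical g_smax means
for the diploids *B. distachyon* and *B. stacei* and the allotetraploid
*B. hybridum*, as printed in the literature.  They are bundled solely as
inputs for cross-checking the package's normalization conventions (per-stoma
scaling, operational opening, length/width ratio) against printed table
values — they are not defaults of any estimator.

Units: gsw mol m⁻² s⁻¹; A µmol m⁻² s⁻¹; iWUE µmol mol⁻¹; density mm⁻²;
lengths/widths µm; g_smax mol m⁻² s⁻¹.
"""

SPECIES = ("B. distachyon", "B. stacei", "B. hybridum")

#: per-leaf-area steady-state means by variable -> phase -> species
LEAF_AREA_MEANS = {
    "gsw": {
        "high_light_1": {"B. distachyon": 0.273, "B. stacei": 0.170, "B. hybridum": 0.304},
        "low_light": {"B. distachyon": 0.082, "B. stacei": 0.069, "B. hybridum": 0.097},
        "high_light_2": {"B. distachyon": 0.252, "B. stacei": 0.163, "B. hybridum": 0.261},
        "darkness": {"B. distachyon": 0.018, "B. stacei": 0.043, "B. hybridum": 0.032},
    },
    "A": {
        "high_light_1": {"B. distachyon": 18.66, "B. stacei": 7.09, "B. hybridum": 18.45},
        "low_light": {"B. distachyon": 2.93, "B. stacei": 1.45, "B. hybridum": 3.21},
        "high_light_2": {"B. distachyon": 18.39, "B. stacei": 7.63, "B. hybridum": 17.55},
    },
    "iwue": {
        "high_light_1": {"B. distachyon": 69.89, "B. stacei": 40.91, "B. hybridum": 61.58},
        "low_light": {"B. distachyon": 36.04, "B. stacei": 20.52, "B. hybridum": 34.38},
        "high_light_2": {"B. distachyon": 74.21, "B. stacei": 46.52, "B. hybridum": 70.15},
    },
}

STOMATAL_DENSITY = {"B. distachyon": 100.3, "B. stacei": 102.7, "B. hybridum": 59.6}
STOMATAL_LENGTH = {"B. distachyon": 24.1, "B. stacei": 25.8, "B. hybridum": 33.1}
STOMATAL_WIDTH = {"B. distachyon": 6.4, "B. stacei": 6.5, "B. hybridum": 7.3}
LENGTH_WIDTH_RATIO = {"B. distachyon": 3.8, "B. stacei": 4.0, "B. hybridum": 4.6}

ANATOMICAL_GSMAX = {"B. distachyon": 0.378, "B. stacei": 0.422, "B. hybridum": 0.333}
OPERATIONAL_OPENING_PCT = {"B. distachyon": 67, "B. stacei": 39, "B. hybridum": 78}

#: printed per-stoma means (÷density ×10³ convention) for the cases used as
#: exact cross-checks of the normalization
PER_STOMA_GSW_HIGH_LIGHT_1 = {"B. distachyon": 2.72, "B. hybridum": 5.10}
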