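"""Design constants of the Alta Floresta small-mammal survey.

These are the field-study quantities the rest of the package takes as
inputs or defaults: the sampling effort subtotals, the species tally,
the forest-dependency classification threshold, and the fitted
community-FD–area projection coefficients. They describe the study
design, not values this package estimates.
"""

from __future__ import annotations

#: Trap-nights accumulated inside forest patches and continuous-forest sites.
FOREST_TRAP_NIGHTS = 15_868
#: Trap-nights accumulated in matrix (open-habitat) strata adjacent to patches.
MATRIX_TRAP_NIGHTS = 5_700
#: Total sampling effort across all 22 surveyed sites.
TOTAL_TRAP_NIGHTS = 21_568

#: Species recorded across the whole survey, and the subset seen in the matrix.
N_SPECIES = 20
N_MATRIX_SPECIES = 5
#: Species counts per forest-dependency class (forest-dependent,
#: matrix-tolerant, open-habitat).
ARCHETYPE_COUNTS = (12, 5, 3)

#: Survey layout: forest patches plus continuous-forest reference sites.
N_PATCHES = 19
N_CONTINUOUS = 3
#: Patch areas span four orders of magnitude (ha).
AREA_RANGE_HA = (1.4, 14_480.5)

#: Surrogate covariates assigned to continuous-forest sites: area one order of
#: magnitude above the largest patch, circular shape, saturated proximity,
#: full cover, maximal matrix complexity.
CF_AREA_HA = 144_800.0
CF_SHAPE = 1.0
CF_PROX = 1.0e9
CF_COVER = 100.0
CF_MATRIX_COMPLEXITY = 10

#: Maximum forest-dependency index among matrix-recorded species; the
#: classification threshold between matrix-tolerant and forest-dependent.
FD_THRESHOLD = 1.82

#: Range of observed community-averaged FD across survey sites.
COMMUNITY_FD_RANGE = (1.61, 3.04)

#: Patches excluded as outliers from the community-FD regressions.
OUTLIER_PATCHES = (9, 12, 17)

#: Community-average FD as a function of patch area (log10 ha):
#: cfd = B1 * log10(area) + B2 * log10(area)^2, no intercept.
PROJECTION_B1 = 0.35
PROJECTION_B2 = -0.04

#: Years of the deforestation chronosequence analysed at 5-year intervals.
CHRONOSEQUENCE_YEARS = (1985, 1990, 1995, 2000, 2005, 2010, 2015)
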