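# Emerald ash borer (Agrilus planipennis) default model parameters.
# One key = value pair per line; '#' starts a comment.
# Temperatures in degrees C, durations and offsets in degree-days C.

# Lower developmental thresholds (C)
eggLDT = 12.2
larvaeLDT = 12.2
pupaeLDT = 12.2
adultLDT = 12.2

# Upper developmental thresholds (C)
eggUDT = 36.0
larvaeUDT = 36.0
pupaeUDT = 36.0
adultUDT = 36.0

# Stage durations (degree-days C)
eggDD = 172
larvaeDD = 700
pupDD = 135
adultDD = 145

# Phenological event offsets (degree-days C)
# OWEventDD varies per cohort and is derived from the cohort distribution.
eggEventDD = 172
larvaeEventDD = 700
pupaeEventDD = 135
adultEventDD = 72

# Cold stress
coldstress_threshold = -31
coldstress_units_max1 = 80
coldstress_units_max2 = 160

# Heat stress
heatstress_threshold = 38
heatstress_units_max1 = 75
heatstress_units_max2 = 150

# Overwintering cohort distribution (degree-days C to complete J-larval
# development; lognormal truncated to [xdist1, xdist2])
distro_mean = 200
distro_var = 15000
xdist1 = 60
xdist2 = 350
distro_shape = lognormal
n_cohorts = 7

# Other
stgorder = OL, P, A, E, L
obligate_diapause = 1
calctype = triangle
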