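"""Shared conventions: column names, date handling, missing tokens, rate ordering.

Everything that must agree between the simulator, the readers and the model
lives here so there is exactly one place to change a convention.
"""

# Missing-value token used in every CSV this package reads or writes.
MISSING_TOKEN = "NA"

# Dates are ISO 8601 (YYYY-MM-DD) everywhere.
DATE_FORMAT = "%Y-%m-%d"

# Standard deviations use the population convention (ddof=0) everywhere, so
# standardized regressions are internally consistent.
SD_DDOF = 0

# Sexes, age classes and the four age-sex groups of the capture-recapture model.
SEXES = ("f", "m")
AGE_CLASSES = ("juvenile", "adult")
# Group order is fixed: juvenile female, juvenile male, adult female, adult male.
GROUPS = ("juv_f", "juv_m", "ad_f", "ad_m")

# Order of the seven vital-rate series whose temporal residuals are jointly
# multivariate normal: juvenile survival (f, m), adult survival (f, m),
# fecundity, expected immigrants (f, m).
RATES = ("phi_j_f", "phi_j_m", "phi_ad_f", "phi_ad_m", "rho", "iota_f", "iota_m")
N_RATES = len(RATES)
SURVIVAL_RATES = RATES[:4]

# Annual-cycle windows (month, day) used to summarize daily weather records.
# The winter window spans the year boundary: 01 Nov of year y through 31 Mar of
# year y+1, and is indexed to the survival interval starting at breeding
# season t = y.
SEASON_WINDOWS = {
    "winter": ((11, 1), (3, 31)),
    "prebreeding": ((4, 15), (5, 19)),
    "breeding": ((5, 20), (7, 31)),
    "postbreeding": ((8, 15), (9, 30)),
}

# Canonical covariate column names.
COVARIATES = (
    "winter_temp",
    "winter_prcp",
    "prebreeding_temp",
    "prebreeding_prcp",
    "breeding_temp",
    "breeding_prcp",
    "postbreeding_temp",
    "postbreeding_prcp",
    "breeding_density",
    "breeding_density_detrended",
    "winter_density",
)
BREEDING_WEATHER = (
    "prebreeding_temp",
    "prebreeding_prcp",
    "breeding_temp",
    "breeding_prcp",
    "postbreeding_temp",
    "postbreeding_prcp",
)
WINTER_WEATHER = ("winter_temp", "winter_prcp")
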