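"""Shared vocabulary: cohort labels, period names, event types, rule constants."""

# Cohorts
PPD = "PPD"
NONPPD = "NONPPD"
COHORTS = (PPD, NONPPD)

# Pregnancy periods, in chronological order
PREPREGNANCY = "prepregnancy"
PREGNANCY = "pregnancy"
POSTPARTUM = "postpartum"
PPD_PERIOD = "ppd"
PERIODS = (PREPREGNANCY, PREGNANCY, POSTPARTUM, PPD_PERIOD)

# Clinical event types
EV_PREGNANCY_START = "pregnancy_start"
EV_DELIVERY = "delivery"
EV_PPD_DIAGNOSIS = "ppd_diagnosis"
EV_DEPRESSION_DIAGNOSIS = "depression_diagnosis"
EV_ANTIDEPRESSANT = "antidepressant_exposure"
EVENT_TYPES = (
    EV_PREGNANCY_START,
    EV_DELIVERY,
    EV_PPD_DIAGNOSIS,
    EV_DEPRESSION_DIAGNOSIS,
    EV_ANTIDEPRESSANT,
)
PPD_QUALIFYING_EVENTS = (EV_PPD_DIAGNOSIS, EV_DEPRESSION_DIAGNOSIS, EV_ANTIDEPRESSANT)

# Calendar-rule constants: month-based phrasings are fixed to day counts so
# results do not depend on locale-specific calendar arithmetic.
DAYS_LOOKBACK = 730          # "2 years" before the index date
DAYS_QUALIFYING_WINDOW = 730  # "24 months" after delivery
DAYS_PREGNANCY_FALLBACK = 270  # "9 months" standard pregnancy length
NONPPD_INDEX_OFFSET_DAYS = 58  # median delivery-to-diagnosis delay
PPD_WINDOW_PRE_DAYS = 14      # symptom lead before the index date
PPD_WINDOW_POST_DAYS = 30     # antidepressant onset lag after the index date

# Strict ("valid day") wear rule
STRICT_MIN_HOURS = 10         # inclusive
STRICT_MIN_STEPS = 100        # exclusive lower bound
STRICT_MAX_STEPS = 45_000     # exclusive upper bound

# The ten annual-income survey levels
INCOME_LEVELS = (
    "<10k",
    "10k-25k",
    "25k-35k",
    "35k-50k",
    "50k-75k",
    "75k-100k",
    "100k-150k",
    "150k-200k",
    ">200k",
    "prefer_not_to_answer",
)
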