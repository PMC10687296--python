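# Survey-cohort composition fixture: two national cross-sectional waves
# (2013, 2019) with the published marginal counts, plus per-disease overall
# prevalence by year.  Stratum cell counts are derived from these marginals
# by largest-remainder apportionment (see annl36.cohort.StratumParams).
#
# Where the source document prints conflicting values for the same quantity,
# the region-panel table value is used here; the alternates are kept in
# data/prevalence_variants.csv.
total: 27801
years:
  2013: 14623
  2019: 13178
gender:                 # pooled over both waves
  male: 13190
  female: 14611
regions:                # pooled over both waves
  Belgrade: 6760
  Vojvodina: 5925
  Sumadija-West: 8659
  East-South: 6457
age_groups:             # pooled over both waves
  15-24: 3241
  25-34: 3590
  35-44: 4140
  45-54: 4317
  55-64: 5268
  65-74: 4252
  75-84: 2510
  85+: 483
# Per-disease marginal prevalence (percent) by survey year.
disease_prevalence_pct:
  Asthma:                  {2013: 3.7,  2019: 3.6}
  Chronic lung diseases:   {2013: 4.7,  2019: 3.7}
  Myocardial infarction:   {2013: 2.8,  2019: 2.0}
  Coronary heart disease:  {2013: 11.6, 2019: 9.8}
  Hypertension:            {2013: 34.0, 2019: 32.3}
  Stroke:                  {2013: 2.2,  2019: 1.4}
  Arthrosis:               {2013: 10.4, 2019: 7.8}
  Lower back diseases:     {2013: 20.5, 2019: 18.4}
  Cervical spine diseases: {2013: 13.2, 2019: 13.0}
  Diabetes mellitus:       {2013: 8.4,  2019: 8.8}
  Allergies:               {2013: 8.8,  2019: 7.0}
  Liver cirrhosis:         {2013: 0.3,  2019: 0.3}
  Urinary track diseases:  {2013: 4.6,  2019: 3.9}
  Kidney diseases:         {2013: 6.1,  2019: 4.2}
  Depression:              {2013: 6.7,  2019: 4.8}
  High Cholesterol:        {2013: 13.9, 2019: 11.2}
  Cancer:                  {2013: 1.6,  2019: 2.0}
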