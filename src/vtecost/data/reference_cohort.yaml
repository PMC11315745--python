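# Age-stratified D-dimer summaries (median with IQR, mg/L FEU) of a published
# 526-patient oncology cohort with suspected VTE: 152 adjudicated VTE
# (83 PE / 69 DVT) and 374 without VTE.  n_below_05 / n_below_10 are the
# published counts of values below 0.5 / 1.0 mg/L.  Rows with n = 1 print no
# IQR; q25/q75 are left null and sigma falls back to the arm's typical spread.
seed: 0
n_pe: 83
n_dvt: 69
control_ctpa_fraction: 0.5
enforce_zero_fn_rules: [m1, m2, m3]
vte_groups:
  - {age_lo: 18, age_hi: 24, n: 1, median: 4.1, q25: null, q75: null, n_below_05: 0, n_below_10: 0}
  - {age_lo: 25, age_hi: 35, n: 5, median: 4.5, q25: 3.9, q75: 6.1, n_below_05: 0, n_below_10: 0}
  - {age_lo: 36, age_hi: 45, n: 10, median: 6.2, q25: 3.1, q75: 10.5, n_below_05: 0, n_below_10: 1}
  - {age_lo: 46, age_hi: 55, n: 25, median: 4.6, q25: 2.3, q75: 9.0, n_below_05: 0, n_below_10: 0}
  - {age_lo: 56, age_hi: 65, n: 35, median: 7.8, q25: 4.7, q75: 14.3, n_below_05: 0, n_below_10: 2}
  - {age_lo: 66, age_hi: 75, n: 29, median: 5.8, q25: 3.6, q75: 10.1, n_below_05: 0, n_below_10: 1}
  - {age_lo: 76, age_hi: 85, n: 41, median: 7.9, q25: 4.6, q75: 11.5, n_below_05: 0, n_below_10: 2}
  - {age_lo: 86, age_hi: 100, n: 6, median: 10.3, q25: 6.9, q75: 13.1, n_below_05: 0, n_below_10: 0}
control_groups:
  - {age_lo: 25, age_hi: 35, n: 1, median: 0.4, q25: null, q75: null, n_below_05: 1}
  - {age_lo: 36, age_hi: 45, n: 28, median: 0.3, q25: 0.2, q75: 0.7, n_below_05: 19}
  - {age_lo: 46, age_hi: 55, n: 65, median: 0.5, q25: 0.2, q75: 0.9, n_below_05: 37}
  - {age_lo: 56, age_hi: 65, n: 95, median: 0.3, q25: 0.2, q75: 0.7, n_below_05: 59}
  - {age_lo: 66, age_hi: 75, n: 93, median: 0.3, q25: 0.2, q75: 1.0, n_below_05: 54}
  - {age_lo: 76, age_hi: 85, n: 76, median: 0.4, q25: 0.2, q75: 1.3, n_below_05: 41}
  - {age_lo: 86, age_hi: 100, n: 16, median: 0.5, q25: 0.3, q75: 0.7, n_below_05: 8}
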