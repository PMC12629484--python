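# Published reference values that the pipeline's summary tables are compared
# against (regression targets for reproduce_tables; never used as inputs to
# any computation).
table1_ap_biomarkers:   # BCL 1000 ms, right-atrial cell, G490R mixture
  columns: [APA_mV, MUV_V_per_s, RMP_mV, APD90_ms]
  rows:
    0.0: [99.2, 192.0, -75.6, 247.4]
    0.2: [99.6, 194.8, -75.8, 234.6]
    0.4: [100.0, 197.4, -76.1, 223.1]
    0.5: [100.1, 198.4, -76.1, 192.4]
    0.6: [100.6, 201.3, -76.8, 113.4]
    0.8: [101.0, 205.2, -77.8, 58.3]
    1.0: [101.1, 206.9, -78.3, 41.7]
table2_critical_si:     # WT and G490R-graded strand
  columns: [critical_SI_ms, EXT_pA_per_pF]
  rows:
    0.0: [282, 425]
    0.2: [267, 449]
    0.4: [248, 449]
    0.5: [233, 406]
    0.6: [206, 421]
    0.8: [130, 421]
    1.0: [99, 420]
table3_reentry:         # 2D sheet, 8 s
  columns: [DF_Hz, meander_area_cm2]
  rows:
    0.0: [3.8, 14.9]
    0.2: [3.9, 23.9]
    0.4: [4.2, 59.6]
    0.5: [4.9, 34.8]
    0.6: [5.2, 9.3]
    0.8: [6.1, 5.7]
    1.0: [7.1, 4.1]
strand_bcl1000:         # CV (cm/s) and WL (mm) at BCL 1000 ms
  columns: [CV_cm_per_s, WL_mm]
  rows:
    0.0: [71.1, 202.8]
    0.5: [null, 167.8]
    1.0: [70.8, 64.4]
vulnerable_window_ms:
  columns: [CT_PM, LA_PV]
  rows:
    0.0: [5.8, 9.3]
    0.5: [3.1, 19.4]
    1.0: [13.2, 43.7]
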