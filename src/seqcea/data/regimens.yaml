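# Dosing schedules per treatment, reconstructed from the drug labels and
# the source trials' regimens (the study itself does not print them).
# Each drug line: dose rule (fixed_mg | per_m2 | auc), administration
# interval in days, maximum number of doses (null = until progression),
# and an optional market-share weight (with the complement drug carrying
# the remaining share).
#
# Chemotherapy backbones run at most 4-6 cycles; immune checkpoint
# inhibitors run to progression or 35 doses.

first_line:
  chemo:
    immunotherapy: false
    drugs:
      - {drug: paclitaxel, per_m2: 175, interval_days: 21, max_doses: 6, share: paclitaxel}
      - {drug: nab_paclitaxel, per_m2: 260, interval_days: 21, max_doses: 6, share_complement: paclitaxel}
      - {drug: carboplatin, auc: 5, interval_days: 21, max_doses: 6, share: carboplatin}
      - {drug: cisplatin, per_m2: 75, interval_days: 21, max_doses: 6, share_complement: carboplatin}
  N+C:
    immunotherapy: false
    drugs:
      - {drug: nedaplatin, per_m2: 100, interval_days: 21, max_doses: 6}
      - {drug: docetaxel, per_m2: 75, interval_days: 21, max_doses: 6}
  P+C:
    immunotherapy: true
    drugs:
      - {drug: pembrolizumab, fixed_mg: 200, interval_days: 21, max_doses: 35}
      - {drug: paclitaxel, per_m2: 175, interval_days: 21, max_doses: 4, share: paclitaxel}
      - {drug: nab_paclitaxel, per_m2: 260, interval_days: 21, max_doses: 4, share_complement: paclitaxel}
      - {drug: carboplatin, auc: 5, interval_days: 21, max_doses: 4, share: carboplatin}
      - {drug: cisplatin, per_m2: 75, interval_days: 21, max_doses: 4, share_complement: carboplatin}
  T+C:
    immunotherapy: true
    drugs:
      - {drug: tislelizumab, fixed_mg: 200, interval_days: 21, max_doses: 35}
      - {drug: paclitaxel, per_m2: 175, interval_days: 21, max_doses: 6, share: paclitaxel}
      - {drug: nab_paclitaxel, per_m2: 260, interval_days: 21, max_doses: 6, share_complement: paclitaxel}
      - {drug: carboplatin, auc: 5, interval_days: 21, max_doses: 6, share: carboplatin}
      - {drug: cisplatin, per_m2: 75, interval_days: 21, max_doses: 6, share_complement: carboplatin}
  CA+C:
    immunotherapy: true
    drugs:
      - {drug: camrelizumab, fixed_mg: 200, interval_days: 21, max_doses: 35}
      - {drug: paclitaxel, per_m2: 175, interval_days: 21, max_doses: 6, share: paclitaxel}
      - {drug: nab_paclitaxel, per_m2: 260, interval_days: 21, max_doses: 6, share_complement: paclitaxel}
      - {drug: carboplatin, auc: 5, interval_days: 21, max_doses: 6, share: carboplatin}
      - {drug: cisplatin, per_m2: 75, interval_days: 21, max_doses: 6, share_complement: carboplatin}
  SI+C:
    immunotherapy: true
    drugs:
      - {drug: sintilimab, fixed_mg: 200, interval_days: 21, max_doses: 35}
      # gemcitabine d1 + d8 each cycle
      - {drug: gemcitabine, per_m2: 1250, interval_days: 21, max_doses: 6, doses_per_cycle: 2}
      - {drug: carboplatin, auc: 5, interval_days: 21, max_doses: 6, share: carboplatin}
      - {drug: cisplatin, per_m2: 75, interval_days: 21, max_doses: 6, share_complement: carboplatin}
  SU+C:
    immunotherapy: true
    drugs:
      - {drug: sugemalimab, fixed_mg: 1200, interval_days: 21, max_doses: 35}
      - {drug: paclitaxel, per_m2: 175, interval_days: 21, max_doses: 4, share: paclitaxel}
      - {drug: nab_paclitaxel, per_m2: 260, interval_days: 21, max_doses: 4, share_complement: paclitaxel}
      - {drug: carboplatin, auc: 5, interval_days: 21, max_doses: 4, share: carboplatin}
      - {drug: cisplatin, per_m2: 75, interval_days: 21, max_doses: 4, share_complement: carboplatin}

second_line:
  docetaxel:
    immunotherapy: false
    drugs:
      - {drug: docetaxel, per_m2: 75, interval_days: 21, max_doses: null}
  tislelizumab:
    immunotherapy: true
    drugs:
      - {drug: tislelizumab, fixed_mg: 200, interval_days: 21, max_doses: 35}
  nivolumab:
    immunotherapy: true
    drugs:
      - {drug: nivolumab, per_kg: 3, interval_days: 14, max_doses: 35}

# follow-up / monitoring while on active treatment (lines 1 and 2):
# labs and administration every cycle, imaging every 2 cycles
monitoring:
  per_cycle: [biochemistry, blood_test, urinalysis, diagnosis, injection, nursing, bed]
  every_two_cycles: [ct_scan]
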