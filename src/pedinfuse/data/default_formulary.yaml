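# Default formulary: 6 continuous-infusion drugs and 19 direct-IV bolus drugs.
#
# Dopamine, norepinephrine and the two epinephrine strengths use
# literature-standard presentations (dopamine 200 mg / 5 ml vials,
# norepinephrine 1 mg / 1 ml vials, epinephrine 1:10,000 = 100 ug/ml and
# 1:1,000 = 1,000 ug/ml).  The remaining entries are documented placeholders
# with plausible hospital presentations; override any strength by editing a
# copy of this file and passing it via --formulary / load_formulary(path).
#
# shann_scale: ug/kg/min delivered per 1 ml/h under the rate-table
# preparation (mass diluted = 3 x scale x weight mg in 50 ml).
drugs:
  # --- continuous infusion -------------------------------------------------
  - name: dopamine
    mode: continuous
    stock_concentration_ug_per_ml: 40000
    vial_volume_ml: 5.0
    dose_rate_min: 5.0
    dose_rate_max: 20.0
    shann_scale: 1.0
  - name: dobutamine
    mode: continuous
    stock_concentration_ug_per_ml: 12500
    vial_volume_ml: 20.0
    dose_rate_min: 5.0
    dose_rate_max: 20.0
    shann_scale: 1.0
  - name: norepinephrine
    mode: continuous
    stock_concentration_ug_per_ml: 1000
    vial_volume_ml: 1.0
    dose_rate_min: 0.01
    dose_rate_max: 1.0
    shann_scale: 0.1
  - name: epinephrine-infusion
    mode: continuous
    stock_concentration_ug_per_ml: 1000
    vial_volume_ml: 1.0
    dose_rate_min: 0.01
    dose_rate_max: 1.0
    shann_scale: 0.1
  - name: milrinone
    mode: continuous
    stock_concentration_ug_per_ml: 1000
    vial_volume_ml: 10.0
    dose_rate_min: 0.25
    dose_rate_max: 0.75
    shann_scale: 0.1
  - name: midazolam-infusion
    mode: continuous
    stock_concentration_ug_per_ml: 5000
    vial_volume_ml: 3.0
    dose_rate_min: 1.0
    dose_rate_max: 6.0
    shann_scale: 1.0
  # --- direct IV bolus -----------------------------------------------------
  - name: epinephrine  # 1:10,000
    mode: bolus
    stock_concentration_ug_per_ml: 100
    vial_volume_ml: 10.0
    bolus_dose_mg_per_kg: 0.01
  - name: epinephrine-1-1000
    mode: bolus
    stock_concentration_ug_per_ml: 1000
    vial_volume_ml: 1.0
    bolus_dose_mg_per_kg: 0.01
  - name: atropine
    mode: bolus
    stock_concentration_ug_per_ml: 100
    vial_volume_ml: 10.0
    bolus_dose_mg_per_kg: 0.02
  - name: adenosine
    mode: bolus
    stock_concentration_ug_per_ml: 3000
    vial_volume_ml: 2.0
    bolus_dose_mg_per_kg: 0.1
  - name: amiodarone
    mode: bolus
    stock_concentration_ug_per_ml: 50000
    vial_volume_ml: 3.0
    bolus_dose_mg_per_kg: 5.0
  - name: ketamine
    mode: bolus
    stock_concentration_ug_per_ml: 10000
    vial_volume_ml: 5.0
    bolus_dose_mg_per_kg: 1.0
  - name: fentanyl
    mode: bolus
    stock_concentration_ug_per_ml: 50
    vial_volume_ml: 2.0
    bolus_dose_mg_per_kg: 0.001
  - name: midazolam
    mode: bolus
    stock_concentration_ug_per_ml: 1000
    vial_volume_ml: 5.0
    bolus_dose_mg_per_kg: 0.1
  - name: lorazepam
    mode: bolus
    stock_concentration_ug_per_ml: 2000
    vial_volume_ml: 1.0
    bolus_dose_mg_per_kg: 0.1
  - name: naloxone
    mode: bolus
    stock_concentration_ug_per_ml: 400
    vial_volume_ml: 1.0
    bolus_dose_mg_per_kg: 0.01
  - name: rocuronium
    mode: bolus
    stock_concentration_ug_per_ml: 10000
    vial_volume_ml: 5.0
    bolus_dose_mg_per_kg: 1.0
  - name: succinylcholine
    mode: bolus
    stock_concentration_ug_per_ml: 50000
    vial_volume_ml: 2.0
    bolus_dose_mg_per_kg: 1.5
  - name: etomidate
    mode: bolus
    stock_concentration_ug_per_ml: 2000
    vial_volume_ml: 10.0
    bolus_dose_mg_per_kg: 0.3
  - name: propofol
    mode: bolus
    stock_concentration_ug_per_ml: 10000
    vial_volume_ml: 20.0
    bolus_dose_mg_per_kg: 2.0
  - name: sodium-bicarbonate  # 8.4%, 1 mEq/ml
    mode: bolus
    stock_concentration_ug_per_ml: 84000
    vial_volume_ml: 50.0
    bolus_dose_mg_per_kg: 84.0
  - name: calcium-gluconate  # 10%
    mode: bolus
    stock_concentration_ug_per_ml: 100000
    vial_volume_ml: 10.0
    bolus_dose_mg_per_kg: 60.0
  - name: magnesium-sulfate  # 50%
    mode: bolus
    stock_concentration_ug_per_ml: 500000
    vial_volume_ml: 2.0
    bolus_dose_mg_per_kg: 50.0
  - name: dextrose-10pct
    mode: bolus
    stock_concentration_ug_per_ml: 100000
    vial_volume_ml: 50.0
    bolus_dose_mg_per_kg: 500.0
  - name: furosemide
    mode: bolus
    stock_concentration_ug_per_ml: 10000
    vial_volume_ml: 2.0
    bolus_dose_mg_per_kg: 1.0
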