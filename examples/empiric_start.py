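"""Guideline empiric starting doses: weight-based for children, model-based
for neonates, with the Schwartz eGFR renal gate."""
from vancomipd import CovariateRecord, empiric_starting_dose, schwartz_egfr

child = CovariateRecord(weight_kg=19.1, serum_creatinine_mg_dl=0.4,
                        chronological_age_days=6 * 365.25, height_cm=105.0)
egfr = schwartz_egfr(child.height_cm, child.serum_creatinine_mg_dl)
start = empiric_starting_dose(child, "le_pediatric")
print(f"6-year-old, 19.1 kg, eGFR {egfr:.0f} ml/min/1.73m^2: "
      f"{start.regimen.dose_mg:.0f} mg q{start.regimen.interval_h:.0f}h "
      f"({start.basis})")
print("  15 mg/kg rounded to the 25 mg grid; q6h because age < 12 years.")

impaired = CovariateRecord(weight_kg=19.1, serum_creatinine_mg_dl=1.0,
                           chronological_age_days=6 * 365.25, height_cm=105.0)
start = empiric_starting_dose(impaired, "le_pediatric")
print(f"\nSame child with creatinine 1.0 mg/dL "
      f"(eGFR {schwartz_egfr(105.0, 1.0):.0f}): "
      f"{start.regimen.dose_mg:.0f} mg q{start.regimen.interval_h:.0f}h")
for f in start.flags:
    print(f"  flag: {f}")

neonate = CovariateRecord(weight_kg=2.9, serum_creatinine_mg_dl=0.4,
                          chronological_age_days=30.0,
                          postmenstrual_age_weeks=34.8)
start = empiric_starting_dose(neonate, "frymoyer_neonatal")
print(f"\nNeonate 2.9 kg, PMA 34.8 wk: {start.regimen.dose_mg:.0f} mg "
      f"q{start.regimen.interval_h:.0f}h ({start.basis})")
print("  Chosen by searching the dose grid against the AUC24/MIC 400-600 "
      "band under the neonatal population prior (no TDM yet).")
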