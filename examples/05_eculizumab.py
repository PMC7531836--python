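"""Anti-C5 therapy: in-vitro inhibition and in-vivo treatment.

Scans eculizumab concentrations in the acidified-serum PNH lysis assay,
then simulates the clinical regimen (600 mg weekly x4, then 900 mg every
two weeks) in a PNH type-3 patient.
"""

import numpy as np

from altcomp.pharmacology import Regimen
from altcomp.scenarios import (ScenarioConfig, pnh_inhibition_assay,
                               run_hemolytic_assay, run_treatment)

print("in-vitro PNH lysis under eculizumab:")
concs = [0.0, 1e-7, 2e-7, 3e-7, 5e-7, 1e-6]
lysis = [run_hemolytic_assay(pnh_inhibition_assay(c)) for c in concs]
for c, h in zip(concs, lysis):
    print(f"  {c * 1e6:5.2f} uM -> {h:5.2f}% lysis")
half = lysis[0] / 2
ic50 = float(np.interp(-half, -np.asarray(lysis), concs))
print(f"  IC50 ~ {ic50 * 1e6:.2f} uM (stoichiometric C5 neutralization)\n")

print("in-vivo treatment of PNH type 3 (15 months):")
cfg = ScenarioConfig(context="in_vivo", cell_type="pnh3",
                     regimen=Regimen.clinical_default(15.0))
frame, _ = run_treatment(cfg, months=15.0, n_times=60)
for m in (0, 1, 3, 6, 12, 15):
    row = frame.iloc[(frame.time_days - m * 30.44).abs().idxmin()]
    print(f"  month {m:2d}:  Hb {row.hemoglobin_g_dl:5.2f} g/dL   "
          f"LDH {row.ldh_u_l:6.0f} U/L")
print("\nHemoglobin recovers monotonically and plateaus within about a "
      "year; the residual deficit reflects free-C5 escape between doses.")
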