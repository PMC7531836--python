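"""In-vitro hemolytic assays: rabbit cells, serum titration, knockouts.

Simulates the standard rabbit-erythrocyte assay (20% serum, 1e11 cells/L,
30 min), a serum dilution series, and single regulator knockouts on human
erythrocytes.
"""

import dataclasses

from altcomp.scenarios import (human_regulation_assay, run_hemolytic_assay,
                               standard_rabbit_assay)

h = run_hemolytic_assay(standard_rabbit_assay())
print(f"rabbit erythrocytes, 20% serum, 30 min:  {h:.1f}% lysis")
print("(unprotected foreign cells are destroyed almost completely)\n")

print("serum titration (rabbit cells):")
for f in (0.02, 0.05, 0.1, 0.2):
    h = run_hemolytic_assay(standard_rabbit_assay(serum_fraction=f))
    print(f"  {f * 100:4.0f}% serum -> {h:5.1f}% lysis")
print("(hemolysis rises monotonically with serum concentration)\n")

print("human erythrocytes, single regulator suppressed (30 min):")
base = human_regulation_assay()
for ko in [(), ("DAF",), ("CD59",), ("FH_surface",), ("FI",), ("P",)]:
    cfg = dataclasses.replace(base, knockouts=frozenset(ko))
    h = run_hemolytic_assay(cfg)
    print(f"  {'+'.join(ko) or 'intact regulation':<18} -> {h:5.1f}% lysis")
print("(membrane and fluid regulators protect self cells; losing the "
      "protease FI or CD59 exposes them, losing DAF alone does not)")
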