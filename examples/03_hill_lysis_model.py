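"""The pore-density to lysis dose-response.

Loads the packaged (synthetic) lysis-versus-MAC-density curve, fits the
Hill model and evaluates it at a few densities.
"""

from altcomp.fixtures import packaged_lysis_curve
from altcomp.hemolysis import fit_hill, percent_hemolysis

df = packaged_lysis_curve()
fit = fit_hill(df.values)
print(f"fitted Hill model: gamma = {fit.gamma:.2f}, "
      f"MAC50 = {fit.mac50:.2f} pores/cell")
print("(about one complete membrane-attack pore per cell suffices for "
      "half-maximal lysis)\n")

for mac in (0.25, 1.15, 2.30, 10.0):
    print(f"  {mac:5.2f} MAC/cell -> {percent_hemolysis(mac, fit):5.1f}% lysis")
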