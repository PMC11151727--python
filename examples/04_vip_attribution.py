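"""Which wavenumbers drive the PAH reference? PLSR + VIP attribution.

Simulates a small study, regresses the pseudo-GC-MS PAH sum on the corrected
spectra with NIPALS PLS1, and reports the wavenumber intervals whose
variable-importance-in-projection score exceeds 1.
"""

import numpy as np

from ftirfg import analyze_study
from ftirfg.synthetic import generate_study

study = generate_study(n=24, seed=5)
result = analyze_study(study.samples, study.blanks, study.meta,
                       study.references, seed=5, vip_components=3)

vr = result.vip["pah_sum"]
print(f"sum(VIP^2) / p = {float((vr.vip ** 2).sum()) / vr.vip.size:.6f} "
      "(the VIP normalization identity)")
print("\ninfluential intervals (VIP > 1) and their band assignments:")
for row in result.vip_reports["pah_sum"]:
    bands = ", ".join(row["bands"])
    print(f"  {row['interval_lo']:7.0f}-{row['interval_hi']:5.0f} cm-1 : {bands}")

oop = (vr.wavenumbers >= 740) & (vr.wavenumbers <= 760)
print(f"\nmax VIP in the 750 cm-1 region: {vr.vip[oop].max():.2f}")
print("The aromatic CH out-of-plane band carries the PAH signal, so its")
print("region should (and does) stand out as influential.")
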