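"""Baseline-correct a synthetic filter spectrum and subtract a matched blank.

Generates one kerosene-emission sample and a small blank library, removes the
smooth scattering/elemental-carbon baseline with an anchored smoothing
spline, picks the blank whose PTFE peak best matches, and subtracts a scaled
version of it.
"""

import numpy as np

from ftirfg import fit_baseline, generate_blank, generate_sample, select_blank, subtract_blank
from ftirfg.preprocess import ACID_SENSITIVE_ANCHOR, DEFAULT_ANCHOR_REGIONS
from ftirfg.synthetic import ARCHETYPES

raw, truth = generate_sample(ARCHETYPES["kerosene"], seed=42)
blanks = [fit_baseline(generate_blank(s)).corrected for s in (101, 102, 103)]

# the 2750-2500 anchor sits on the broad acid OH, so leave it out here
anchors = [r for r in DEFAULT_ANCHOR_REGIONS if r != tuple(sorted(ACID_SENSITIVE_ANCHOR))]
bl = fit_baseline(raw, anchors)
chosen = {b.id: b for b in blanks}[select_blank(bl.corrected, blanks)]
corrected, match = subtract_blank(bl.corrected, chosen)

print(f"baseline at 4000 cm-1 : {bl.baseline_at_4000:.4f} AU "
      f"(truth {truth.baseline_at_4000:.4f}) - an elemental-carbon proxy")
print(f"matched blank         : {match.blank_id}, scale {match.scale:.3f}")
print(f"PTFE residual RMS     : {match.residual_norm:.5f} AU over 1300-1000 cm-1")
print(f"negative points       : {100 * corrected.negative_fraction:.1f}% of the grid "
      "(negatives are kept, never clipped)")
print("\nThe corrected spectrum now holds only organic band absorption; the")
print("scattering/EC baseline and the PTFE membrane interference are gone.")
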