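"""Case-to-normal ratios and pathway activation on a small worked example.

CNR divides a tumor sample's (normalized) expression by the mean of the
tissue-matched controls; PAL is 100 x the role-weighted mean of log10(CNR)
over a pathway's members (+1 activator, -1 inhibitor, 0 ignored).
"""

import pandas as pd

from tertscape import PathwayLibrary, cnr, normalize, pal_matrix

counts = pd.DataFrame(
    {"tumor1": [80, 10, 40], "ctrl1": [20, 20, 40], "ctrl2": [20, 20, 40]},
    index=["GROWTH", "BRAKE", "HOUSE"],
)
samples = pd.DataFrame(
    {"tumor_type": ["lung"] * 3, "role": ["tumor", "control", "control"],
     "tert_stratum": ["unset"] * 3, "mutation_status": ["unknown"] * 3},
    index=pd.Index(["tumor1", "ctrl1", "ctrl2"], name="sample_id"),
)

norm = normalize(counts)
ratios = cnr(norm, samples, pseudocount=1.0)
print("CNR (tumor vs control mean):")
print(ratios.round(3))

# GROWTH activates the pathway, BRAKE inhibits it, HOUSE is ambiguous
lib = PathwayLibrary({"proliferation": {"GROWTH": 1, "BRAKE": -1, "HOUSE": 0}})
pal, coverage = pal_matrix(ratios, lib)
print("\nPAL (positive = pathway upregulated versus normal tissue):")
print(pal.round(2))
# GROWTH is up ~3x and the inhibitor BRAKE is down ~2x, so both terms push
# the activation score up: the pathway reads as strongly upregulated.
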