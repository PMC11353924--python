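"""Internal-standard quantification and OAV key-compound scoring.

Builds a tiny two-stage peak-area experiment, converts areas to absolute
contents (μg/kg) with the internal-standard equation, then scores each
compound's odor activity value (OAV = content / odor threshold) and keeps
the key contributors (max OAV >= 1 in some stage).
"""

import pandas as pd

import fermflavor as ff

design = ff.StageDesign(stages=("early", "late"), replicates_per_stage=2)

# peak areas for three volatiles in four samples; the internal standard
# (1 μL at 0.1 μg/μL into 3.00 g of sample) has area 1e5 everywhere
samples = design.sample_ids()
area = pd.DataFrame(
    {
        samples[0]: [2.0e5, 4.0e4, 0.0],
        samples[1]: [2.2e5, 3.8e4, 0.0],
        samples[2]: [6.0e5, 1.0e4, 9.0e3],
        samples[3]: [5.8e5, 1.2e4, 1.1e4],
    },
    index=["hexanal", "1-octen-3-ol", "hexanoic acid"],
)
peaks = ff.PeakTable(area=area, is_area=pd.Series(1.0e5, index=samples))
params = ff.QuantParams(c1=0.1, v=1.0, m=3.0)  # -> μg/kg via unit_factor 1000

content = ff.compute_absolute_content(peaks, params, design)
print("absolute content (μg/kg), replicate means per stage:")
print(content.values.round(2), "\n")

records = [
    ff.CompoundRecord("hexanal", "aldehyde", threshold=7.5),
    ff.CompoundRecord("1-octen-3-ol", "alcohol", threshold=2.0),
    ff.CompoundRecord("hexanoic acid", "acid", threshold=200.0),
]
oav = ff.compute_oav(content, records)
print("OAV = content / odor threshold:")
print(oav.values.round(2), "\n")

keys = ff.select_key_compounds(oav)
print("key compounds (max OAV >= 1 in some stage), strongest first:")
print(keys.table)
print(
    "\nA key compound's aroma contribution scales with its OAV; "
    "hexanoic acid stays below threshold everywhere, so it is not key."
)
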