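"""Extract the 16 windowed irregularity features from one RR record.

Generates a short two-state rhythm record, extracts per-beat features,
and contrasts dispersion features between AF and sinus beats.
"""

import numpy as np

from afdetect import SyntheticConfig, extract_features, gen_record

record = gen_record(SyntheticConfig(n_beats=4000, seed=42), signal_id="demo")
fm = extract_features(record)

print(f"record: {len(record)} beats, {np.sum(record.label == 'AF')} labeled AF")
print(f"valid beats with a complete 21-beat window: {fm.n_valid} "
      f"({(~fm.valid_mask).sum()} boundary beats masked)")

df = fm.to_frame().loc[fm.valid_mask]
df["label"] = fm.label
means = df.groupby("label")[["rmssd", "sd1", "di_yeh", "stv_zug", "sti_haan"]].mean()
print("\nmean dispersion features by rhythm state:")
print(means.round(3).to_string())
print("\nAF windows show far larger beat-to-beat dispersion (RMSSD in ms, "
      "SD1 in ms, the Yeh/Zugaib indices dimensionless, de Haan in degrees) — "
      "this contrast is what the classifier exploits.")
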