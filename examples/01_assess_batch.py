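"""Per-batch QC: CV/ICC filtering and the multi-sample SNR.

Simulates one laboratory batch of the four Quartet reference materials
(D5, D6, F7, M8 in triplicate), filters metabolites on replicate CV and
ICC reliability, and scores group discriminability with the SNR.
"""

import numpy as np

from quartetqc import FilterCriteria, SimConfig, filter_metabolites, simulate, snr

coll, _ = simulate(SimConfig(n_metabolites=150, n_labs=1, seed=1))
batch = coll.batches[0]

detected = batch.detected_any()
criteria = FilterCriteria(cv_max=0.30, icc_min=0.4, mode="cv_and_icc")
kept = filter_metabolites(batch, criteria)
result = snr(batch)
filtered = snr(batch, criteria=criteria)

print(f"detected metabolites:            {len(detected)}")
print(f"pass CV<30% and ICC>0.4:         {len(kept)} "
      f"({100 * len(kept) / len(detected):.0f}%)")
print(f"SNR (all complete cases):        {result.snr_db:.1f} dB "
      f"on {result.n_metabolites_used} metabolites")
print(f"SNR (after filtering):           {filtered.snr_db:.1f} dB "
      f"on {filtered.n_metabolites_used} metabolites")
print()
print("Higher SNR means the four sample groups separate more clearly from")
print("replicate noise on the first two principal components; values above")
print("~12 dB indicate profiling that resolves the Quartet's biology.")
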