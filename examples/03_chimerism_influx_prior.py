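"""Estimate the influx into a memory subset from donor-replacement data.

Generates a donor-chimerism timecourse that saturates at 0.7 under a
naive-pool source of 0.8 (the central-memory pattern), fits the
first-order replacement model, and ranks candidate precursor populations
by how well their chimerism matches the inferred chimerism of the influx.
"""

import numpy as np

from memkin import (fit_replacement, generate_chimerism_dataset,
                    normalized_chimerism, rank_precursors)

curve = generate_chimerism_dataset(phi=0.02, asymptote=0.7 / 0.8,
                                   chi_source=0.8, logit_sd=0.15,
                                   population="TCM", seed=2)
est = fit_replacement(curve, precursor_chimerism=0.8, model="scaled",
                      seed=1)

print(est.summary().round(4).to_string())
phi_lo, phi_med, phi_hi = np.quantile(est.phi, [0.025, 0.5, 0.975])
print(f"\nper-capita replacement rate: {phi_med:.4f}/d "
      f"(95% CrI {phi_lo:.4f}-{phi_hi:.4f}) -> a few percent of the pool "
      "is replaced by new cells each day")
fd = est.f_d_at(400.0)
print(f"influx donor fraction at day 400: {np.median(fd):.3f} "
      "(the 'chimerism of the influx', the prior fed to the labelling fits)")

candidates = {"DP1 thymocytes": np.full(8, 0.93),
              "naive CD4": np.full(8, 0.80),
              "central memory": np.full(8, 0.55)}
print("\ncandidate precursor ranking (smallest distance first):")
print(rank_precursors(est, candidates).round(3).to_string(index=False))
print("\nThe influx chimerism matches the naive pool, not the thymus: "
      "new central-memory cells come from naive CD4 T cells in bulk.")
print(f"\nraw chimerism of 70 donor / 30 host cells: "
      f"{normalized_chimerism(70, 30):.2f}")
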