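"""Noise-corrected inter-animal consistency under different mappings.

Two simulated animals observe the same latent signal through different
mixing matrices. A flexible linear map (ridge or PLS) can align the two
populations, so the noise-corrected consistency approaches 1; the strict
one-to-one map cannot pool units, so it stays well below the ceiling.
"""

import interanimal as ia

recs, _ = ia.generate_cohort(n_animals=2, n_units=60, n_stimuli=118,
                             n_trials=50, seed=0)
half = ia.SplitHalfPlan(n_bootstraps=20, seed=1)
split = ia.StimulusSplitPlan(n_splits=5, seed=2)

for kind in ("one_to_one", "ridge", "pls"):
    res = ia.noise_corrected_pairwise_consistency(
        recs[0], recs[1], ia.MappingSpec(kind=kind), half, split)
    print(f"{kind:>10}: median {res.median:.3f} +/- {res.sem:.3f} "
          f"({int(res.kept_mask.sum())} units)")

print("A value of ~1 means the mapping transfers all of the target's "
      "reliable signal; the gap below 1 for one-to-one reflects mapping "
      "mismatch, not trial noise (which the denominator removes).")
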