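"""Correlate empirical RDMs with the three model RDM families.

Simulates 4 subjects with a face-binding effect in region 0, decodes all 66
condition pairs, builds the Fisher-z Spearman maps for the face- and
tool-specific one-vs-rest models, and runs the group t-test with FDR. The
face map should be significant only in region 0 within 140-170 ms; its onset
is reported.
"""

import numpy as np

import regionrsa as rr
from regionrsa.synth import simulate_subject, simulation_parcellation

effect = rr.EffectSpec(
    kind="category_binding", target_regions=(0,), window_ms=(140.0, 170.0),
    amplitude=3.0, category="face",
)
config = rr.SimulationConfig(
    n_subjects=4, n_regions=3, vertices_per_region=6,
    n_trials_per_condition=50, effects=(effect,), seed=19,
)
parcellation = simulation_parcellation(config)

# model RDM structure: counts of dissimilar / similar / excluded cells
for name in ("recognizer", "face_vs_nonsense", "face_specific"):
    model = rr.build_model_rdm(rr.MODEL_NAMES[name])
    vals, valid = model.upper_cells()
    print(f"{name:>16}: {valid.sum()} valid cells "
          f"({int((vals[valid] == 1).sum())} dissimilar, "
          f"{int((vals[valid] == 0).sum())} similar, {66 - int(valid.sum())} excluded)")

z_subjects = []
for s in range(config.n_subjects):
    epochs = simulate_subject(config, s, parcellation)
    comp = rr.extract_region_components(epochs, parcellation)
    decoding = rr.decode_all_pairs(comp, n_randomizations=20, seed=s)
    z, names = rr.rsa_zmaps(decoding, ["face_specific", "tool_specific"])
    z_subjects.append(z)
z = np.stack(z_subjects)  # (subjects, regions, times, models)

time_ms = comp.time_ms
for m, name in enumerate(names):
    t, p = rr.region_time_ttest(z[..., m])
    sig = rr.fdr_mask(p, q=0.05, time_ms=time_ms, t=t)
    print(f"{name}: {sig.mask.sum()} significant region-time cells, "
          f"onsets {sig.onsets or 'none'}")
print("(expected: face_specific onset at 140 ms in region 0 only; "
      "tool_specific should stay empty)")
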