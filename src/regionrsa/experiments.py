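"""Self-contained validation experiments on synthetic data.

Each driver simulates its own dataset under known ground truth, runs the
full pipeline on it and reduces the outcome to a few scalar metrics:

* :func:`structural_constants` — design bookkeeping recomputed from the
  package's primitives (time grid, region counts, CV fold sizes, ...).
* :func:`null_decoding_experiment` — no injected effects: mean pairwise
  decoding accuracy should sit at chance.
* :func:`null_fdr_calibration` — repeated miniature null pipelines: the
  fraction of FDR-rejected region-time cells should not exceed q.
* :func:`recovery_experiment` — injected category-binding effects: the
  one-vs-rest maps should flag the injected region-window cells, recover
  onsets on the 10 ms grid, and stay quiet elsewhere.
* :func:`repetition_sign_experiment` — injected repetition trends of
  opposite sign: the fitted pooled slopes must match in sign.

The problem sizes default to what a laptop runs in minutes; they are
deliberately smaller than the study design the generator defaults encode
(22 subjects, 82 regions, 100 randomizations).
"""

from __future__ import annotations

import numpy as np

from . import design
from ._rng import child_seed
from .atlas import load_region_table
from .decode import (
    TEST_SIZE,
    TRAIN_SIZE,
    decode_all_pairs,
    extract_region_components,
)
from .pipeline import DEFAULT_Q
from .rdm import rsa_zmaps
from .repetition import repetition_regression, repetition_series
from .stats import fdr_mask, manova_model_specificity, region_time_ttest
from .synth import EffectSpec, SimulationConfig, simulate_subject, simulation_parcellation

__all__ = [
    "structural_constants",
    "null_decoding_experiment",
    "null_fdr_calibration",
    "recovery_experiment",
    "repetition_sign_experiment",
]


def structural_constants() -> dict:
    """Design constants recomputed from the package's own primitives."""
    table = load_region_table()
    time_ms = SimulationConfig().time_ms
    sizes_73 = design.segment_sizes(73)
    return {
        "n_time_bins": int(time_ms.size),
        "n_atlas_regions": len(table),
        "n_atlas_areas": len(table.aliases),
        "train_size": TRAIN_SIZE,
        "test_size": TEST_SIZE,
        "n_pseudo_trials": design.N_PSEUDO_TRIALS,
        "n_rsa_entries": design.N_ENTRIES,
        "n_entry_pairs": len(design.ENTRY_PAIRS),
        "pseudo_trial_sizes_73": [int(s) for s in sizes_73],
        "repetition_df2_22_subjects": repetition_regression(
            np.ones((22, 10)) + np.arange(10) * 0.1
        ).df[1],
        "manova_df_41_areas": manova_model_specificity(
            np.random.default_rng(0).standard_normal((22, 41, 3))
        )[1],
    }


def _zmaps_for(config: SimulationConfig, models, n_randomizations: int, seed: int):
    """Simulate + decode + RSA for every subject; returns (z, decodings, comps)."""
    parc = simulation_parcellation(config)
    zs, decs, comps = [], [], []
    for s in range(config.n_subjects):
        epochs = simulate_subject(config, s, parc)
        comp = extract_region_components(epochs, parc)
        dec = decode_all_pairs(
            comp, n_randomizations=n_randomizations, seed=child_seed(seed, "decode", s)
        )
        z, _ = rsa_zmaps(dec, list(models))
        zs.append(z)
        decs.append(dec)
        comps.append(comp)
    return np.stack(zs), decs, comps


def null_decoding_experiment(
    n_subjects: int = 8,
    n_regions: int = 20,
    n_trials_per_condition: int = 50,
    n_randomizations: int = 20,
    seed: int = 0,
) -> dict:
    """Global null: no effects, unit noise. Mean accuracy must be ~0.5."""
    config = SimulationConfig(
        n_subjects=n_subjects,
        n_regions=n_regions,
        vertices_per_region=5,
        n_trials_per_condition=n_trials_per_condition,
        noise_sd=1.0,
        seed=child_seed(seed, "null-sim"),
    )
    models = ["recognizer", "face_specific"]
    z, decs, _ = _zmaps_for(config, models, n_randomizations, seed)
    acc = np.concatenate([d.accuracy.ravel() for d in decs])
    return {
        "mean_accuracy": float(np.nanmean(acc)),
        "z": z,
        "models": models,
        "time_ms": decs[0].time_ms,
    }


def null_fdr_calibration(
    n_replicates: int = 100,
    n_subjects: int = 8,
    n_regions: int = 4,
    n_trials_per_condition: int = 50,
    n_randomizations: int = 10,
    epoch_ms: tuple[float, float] = (-100.0, 100.0),
    models: tuple[str, ...] = ("recognizer", "face_specific"),
    seed: int = 0,
) -> dict:
    """Repeated miniature null pipelines; realized FDR cell fractions.

    Each replicate runs simulate -> decode -> RSA -> t-test -> BH end to end
    with no injected effects, at the model family's default q. Returns the
    per-model mean fraction of rejected cells across replicates; under the
    global null its expectation is bounded by q.
    """
    fractions = {m: [] for m in models}
    for rep in range(n_replicates):
        config = SimulationConfig(
            n_subjects=n_subjects,
            n_regions=n_regions,
            vertices_per_region=5,
            n_trials_per_condition=n_trials_per_condition,
            epoch_ms=epoch_ms,
            noise_sd=1.0,
            seed=child_seed(seed, "fdr-null", rep),
        )
        z, decs, _ = _zmaps_for(config, models, n_randomizations, child_seed(seed, "fdr-dec", rep))
        for m, model in enumerate(models):
            t, p = region_time_ttest(z[..., m])
            sig = fdr_mask(p, q=DEFAULT_Q[model], time_ms=decs[0].time_ms, t=t)
            fractions[model].append(sig.mask.mean())
    return {
        "fp_fraction": {m: float(np.mean(v)) for m, v in fractions.items()},
        "q": {m: DEFAULT_Q[m] for m in models},
        "n_replicates": n_replicates,
    }


def recovery_experiment(
    n_replicates: int = 20,
    n_subjects: int = 6,
    n_regions: int = 20,
    amplitude: float = 3.0,
    n_trials_per_condition: int = 50,
    n_randomizations: int = 10,
    seed: int = 0,
) -> dict:
    """Inject face binding (140-170 ms, regions 0-1) and tool binding
    (210-220 ms, region 2) at high SNR; check the one-vs-rest maps.

    Per replicate the face- and tool-specific maps are FDR-thresholded at
    q = 0.05. Reported: the rate of replicates recovering every target
    region's onset within one 10 ms bin of the window start, the mean
    fraction of injected region-window cells flagged, and the mean
    fraction of flagged cells among clean null cells (cells of neither
    effect, in either map).

    The 20-region grid matters beyond realism: the onset of a region is its
    *first* significant post-stimulus bin, so a single Benjamini-Hochberg
    false positive landing pre-window in a target region spoils that
    replicate's onset. The realized BH threshold scales as q * k / m with k
    the rejection count and m the grid size, so a larger (mostly null) grid
    keeps that event at the ~1% level per replicate.
    """
    face_window, tool_window = (140.0, 170.0), (210.0, 220.0)
    face_regions, tool_region = (0, 1), 2
    effects = (
        EffectSpec("category_binding", face_regions, face_window, amplitude, category="face"),
        EffectSpec("category_binding", (tool_region,), tool_window, amplitude, category="tool"),
    )
    models = ("face_specific", "tool_specific")
    q = DEFAULT_Q["face_specific"]
    onset_hits, injected_rates, fp_rates = [], [], []
    for rep in range(n_replicates):
        config = SimulationConfig(
            n_subjects=n_subjects,
            n_regions=n_regions,
            vertices_per_region=6,
            n_trials_per_condition=n_trials_per_condition,
            noise_sd=1.0,
            effects=effects,
            seed=child_seed(seed, "recovery", rep),
        )
        z, decs, _ = _zmaps_for(config, models, n_randomizations, child_seed(seed, "rec-dec", rep))
        time_ms = decs[0].time_ms
        in_face = (time_ms >= face_window[0]) & (time_ms <= face_window[1])
        in_tool = (time_ms >= tool_window[0]) & (time_ms <= tool_window[1])
        target_cells = {
            "face_specific": [(r, in_face) for r in face_regions],
            "tool_specific": [(tool_region, in_tool)],
        }
        # cells touched by either effect are excluded from the null count in
        # both maps (the other category's effect is not a clean null there)
        touched = np.zeros((n_regions, time_ms.size), dtype=bool)
        for r in face_regions:
            touched[r, in_face] = True
        touched[tool_region, in_tool] = True

        hit, inj_flagged, inj_total, fp, fp_total = True, 0, 0, 0, 0
        for m, model in enumerate(models):
            t, p = region_time_ttest(z[..., m])
            sig = fdr_mask(p, q=q, time_ms=time_ms, t=t)
            for region, window in target_cells[model]:
                onset = sig.onsets.get(region)
                start = time_ms[window][0]
                if onset is None or abs(onset - start) > 10.0:
                    hit = False
                inj_flagged += int(sig.mask[region, window].sum())
                inj_total += int(window.sum())
            fp += int(sig.mask[~touched].sum())
            fp_total += int((~touched).sum())
        onset_hits.append(hit)
        injected_rates.append(inj_flagged / inj_total)
        fp_rates.append(fp / fp_total)
    return {
        "onset_hit_rate": float(np.mean(onset_hits)),
        "injected_cell_rate": float(np.mean(injected_rates)),
        "false_positive_fraction": float(np.mean(fp_rates)),
        "q": q,
        "n_replicates": n_replicates,
    }


def repetition_sign_experiment(
    n_replicates: int = 20,
    n_subjects: int = 4,
    base_amplitude: float = 3.0,
    trend_slope: float = 0.3,
    n_trials_per_condition: int = 60,
    n_randomizations: int = 20,
    seed: int = 0,
) -> dict:
    """Opposite repetition trends: +slope on a face region, -slope on a tool
    region. The fitted pooled slopes must recover the signs, and df2 must be
    10 * n_subjects - 2 in every replicate.
    """
    face_window, tool_window = (140.0, 170.0), (210.0, 220.0)
    effects = (
        EffectSpec("repetition_trend", (0,), face_window, base_amplitude,
                   category="face", trend_slope=trend_slope),
        EffectSpec("repetition_trend", (1,), tool_window, base_amplitude,
                   category="tool", trend_slope=-trend_slope / 2),
    )
    face_ok, tool_ok, df_ok = [], [], []
    face_k, tool_k = [], []
    for rep in range(n_replicates):
        config = SimulationConfig(
            n_subjects=n_subjects,
            n_regions=3,
            vertices_per_region=6,
            n_trials_per_condition=n_trials_per_condition,
            noise_sd=1.0,
            effects=effects,
            seed=child_seed(seed, "reptrend", rep),
        )
        parc = simulation_parcellation(config)
        comps, decs = [], []
        for s in range(config.n_subjects):
            epochs = simulate_subject(config, s, parc)
            comp = extract_region_components(epochs, parc)
            decs.append(
                decode_all_pairs(
                    comp, n_randomizations=n_randomizations,
                    seed=child_seed(seed, "rep-dec", rep, s),
                )
            )
            comps.append(comp)
        fit_face = repetition_regression(
            repetition_series(comps, decs, region=0, category="face",
                              window_ms=face_window).amplitudes
        )
        fit_tool = repetition_regression(
            repetition_series(comps, decs, region=1, category="tool",
                              window_ms=tool_window).amplitudes
        )
        face_ok.append(fit_face.k > 0)
        tool_ok.append(fit_tool.k < 0)
        df_ok.append(fit_face.df == (1, 10 * n_subjects - 2) == fit_tool.df)
        face_k.append(fit_face.k)
        tool_k.append(fit_tool.k)
    return {
        "face_sign_rate": float(np.mean(face_ok)),
        "tool_sign_rate": float(np.mean(tool_ok)),
        "df2_always_correct": bool(all(df_ok)),
        "df2": 10 * n_subjects - 2,
        "mean_face_k": float(np.mean(face_k)),
        "mean_tool_k": float(np.mean(tool_k)),
        "n_replicates": n_replicates,
    }
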