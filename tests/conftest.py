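import pytest

import regionrsa as rr
from regionrsa.synth import simulate_subject, simulation_parcellation


@pytest.fixture(scope="session")
def null_subject():
    """One subject of pure-noise data: 4 regions, 12 conditions x 20 trials."""
    cfg = rr.SimulationConfig(
        n_subjects=1, n_regions=4, vertices_per_region=5,
        n_trials_per_condition=20, noise_sd=1.0, seed=11,
    )
    parc = simulation_parcellation(cfg)
    epochs = simulate_subject(cfg, 0, parc)
    comp = rr.extract_region_components(epochs, parc)
    return cfg, parc, epochs, comp


@pytest.fixture(scope="session")
def face_effect_run():
    """4 subjects, 3 regions, a strong face-binding effect in region 0,
    decoded with all pairs. Shared by RSA/repetition integration tests."""
    eff = rr.EffectSpec(
        kind="category_binding", target_regions=(0,), window_ms=(140.0, 170.0),
        amplitude=3.0, category="face",
    )
    cfg = rr.SimulationConfig(
        n_subjects=4, n_regions=3, vertices_per_region=6,
        n_trials_per_condition=50, noise_sd=1.0, effects=(eff,), seed=21,
    )
    parc = simulation_parcellation(cfg)
    comps, decs = [], []
    for s in range(cfg.n_subjects):
        epochs = simulate_subject(cfg, s, parc)
        comp = rr.extract_region_components(epochs, parc)
        decs.append(rr.decode_all_pairs(comp, n_randomizations=15, seed=100 + s))
        comps.append(comp)
    return cfg, parc, comps, decs
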