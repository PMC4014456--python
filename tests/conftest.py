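import pytest

import histolink as hl


@pytest.fixture(scope="session")
def small_config():
    """Tiny study for I/O and plumbing tests."""
    return hl.SimulationConfig(seed=7, n_genes=60, n_chroms=2,
                               probes_per_promoter=6, probes_per_cds=2,
                               embryos_per_male=1)


@pytest.fixture(scope="session")
def small_study(small_config):
    return hl.simulate_study(small_config)


@pytest.fixture(scope="session")
def recovery_study():
    """Default-condition study with strong sperm->embryo linkage, shared
    by the enrichment-recovery and concordance tests."""
    cfg = hl.SimulationConfig(seed=1, n_genes=2000, p_link=0.8,
                              de_effect=2.0)
    return hl.simulate_study(cfg)


@pytest.fixture(scope="session")
def recovery_calls(recovery_study):
    """Differential histone calls on the recovery study."""
    study = recovery_study
    track = hl.ProbeTrack(probes=study.probes, values=study.intensities)
    ratio = hl.input_subtract(hl.normalize_probes(track))
    model = hl.TilingDifferential(ratio, study.genome,
                                  study.perturbed_males,
                                  study.control_males)
    return model.fit()
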