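import numpy as np
import pytest

from dlnmkit.cluster import cluster_sandwich
from dlnmkit.negbin import build_design, fit_negbin
from dlnmkit.simulate import (SimConfig, generate_counts,
                              generate_prevalence_panel)


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic panel (288 strata) with its truth."""
    cfg = SimConfig(seed=42, n_countries=3, registries_per_country=2)
    panel = generate_prevalence_panel(cfg)
    sim = generate_counts(cfg, panel)
    return cfg, panel, sim


@pytest.fixture(scope="session")
def medium_sim():
    """Larger panel (2016 strata) for estimation-accuracy checks."""
    cfg = SimConfig(seed=7, n_countries=7, registries_per_country=6)
    panel = generate_prevalence_panel(cfg)
    sim = generate_counts(cfg, panel)
    return cfg, panel, sim


@pytest.fixture(scope="session")
def small_fit(small_sim):
    _, _, sim = small_sim
    design = build_design(sim.records, sim.cross_basis)
    fit = fit_negbin(design)
    return sim, design, fit


@pytest.fixture(scope="session")
def medium_fit(medium_sim):
    _, _, sim = medium_sim
    design = build_design(sim.records, sim.cross_basis)
    fit = fit_negbin(design)
    robust = cluster_sandwich(fit, design)
    return sim, design, fit, robust


def simulate_panel(seed, n_countries=6, registries_per_country=1, **kw):
    """One-call generator used by replicate-based tests."""
    cfg = SimConfig(seed=seed, n_countries=n_countries,
                    registries_per_country=registries_per_country, **kw)
    panel = generate_prevalence_panel(cfg)
    return cfg, generate_counts(cfg, panel)
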