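import dataclasses

import pytest

from embryosplice.simulate import SimConfig, Simulator


def small_config(**overrides) -> SimConfig:
    """A fast-to-generate world that keeps every planted signal recoverable."""
    base = dict(
        seed=11,
        n_genes=300,
        n_pathways=20,
        genes_per_pathway=10,
        n_timepoints_pre=8,
        n_timepoints_post=12,
        n_events=300,
        n_sf=80,
        n_csf=20,
        n_driver_csf=3,
        n_neg_reg=4,
        n_mut_csf=3,
        n_mut_neg=3,
        n_tumor=40,
        n_normal=20,
        n_decoy_tfs=8,
        n_kd_csf=5,
        n_kd_ncsf=8,
        n_decoy_domains=4,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def simulator(sim_config) -> Simulator:
    return Simulator(sim_config)


@pytest.fixture(scope="session")
def dev_data(simulator):
    return simulator.development()


@pytest.fixture(scope="session")
def world(sim_config):
    """Development + cancer + annotation + regulatory from one generator."""
    sim = Simulator(sim_config)
    dev = sim.development()
    can = sim.cancer(dev.truth)
    ann = sim.annotation(dev.truth)
    reg = sim.regulatory(dev.truth)
    return dev, can, ann, reg


def replace_config(cfg: SimConfig, **kw) -> SimConfig:
    return dataclasses.replace(cfg, **kw)
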