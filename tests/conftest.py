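"""Shared fixtures: synthetic fields generated once per session."""

import numpy as np
import pytest

import septachain as sc

# study conditions for the noisy benchmark field: >= 20 chains carrying
# >= 200 septa at the generator's default noise (SNR ~ 10)
FIELD_PARAMS = dict(n_chains=25, seed=42, cells_per_chain=(8, 12))


@pytest.fixture(scope="session")
def default_field():
    return sc.generate_chain_field(sc.FixtureParams(**FIELD_PARAMS))


@pytest.fixture(scope="session")
def clean_field():
    return sc.generate_chain_field(
        sc.FixtureParams(**{**FIELD_PARAMS, "noise_sigma": 0.0}))


@pytest.fixture(scope="session")
def default_run(default_field):
    img, truth = default_field
    return sc.run_chaintracer(sc.RunConfig(seed=42), image_set=img), truth


@pytest.fixture(scope="session")
def default_nuc_run(default_field):
    img, truth = default_field
    return sc.run_nuctracer(sc.RunConfig(seed=42), image_set=img), truth


@pytest.fixture(scope="session")
def cocci_field():
    return sc.generate_cocci_field(sc.FixtureParams(seed=5), n_cells=500)


@pytest.fixture(scope="session")
def single_chain_clean():
    """One horizontal 4-cell chain, no read noise."""
    return sc.generate_chain_field(
        sc.FixtureParams(n_chains=1, seed=9, cells_per_chain=4, noise_sigma=0.0),
        orientation_deg=0)


def traced_chain(img):
    ch = sc.segment_chains(img["phase"], img.pixel_size)[0]
    sc.trace_chain_axis(ch)
    return ch


def exact_axis_chain(row, c0, n_cols, px=0.066):
    """Chain whose axis runs exactly along pixel row ``row`` with one
    station per pixel center — bilinear sampling then hits exact pixels."""
    from septachain.chain_detection import ChainObject

    ch = ChainObject(chain_id=1, mask=np.ones((1, 1), bool), offset=(0, 0),
                     pixel_size=px)
    ch.axis = np.array([[(c0 - 0.5) * px, row * px],
                        [(c0 - 0.5 + n_cols) * px, row * px]])
    ch.axis_length = n_cols * px
    return ch


@pytest.fixture(scope="session")
def single_chain_straightened(single_chain_clean):
    img, truth = single_chain_clean
    ch = traced_chain(img)
    return sc.straighten(img, ch), ch, truth
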