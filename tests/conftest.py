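import numpy as np
import pytest

import passaggio as pg


@pytest.fixture(scope="session")
def abrupt_phonation():
    """One fully analysed abrupt-transition phonation, shared across tests."""
    spec = pg.GlideSpec(strategy="abrupt", oq_start=0.6, oq_end=0.75,
                        noise_sd=0.02, seed=2)
    egg, _ = pg.synth_egg(spec)
    gaw, fld, truth = pg.synth_gaw_field(spec, n_positions=32)
    res = pg.analyze_phonation(egg, gaw, fld)
    assert res.error is None
    return dict(spec=spec, egg=egg, gaw=gaw, field=fld, truth=truth, result=res)


@pytest.fixture(scope="session")
def centred_windows(abrupt_phonation):
    """A WindowSet centred mid-phonation with no missing windows."""
    ws = abrupt_phonation["result"].windows
    assert not ws.missing.any()
    return ws


def make_segmentation(boundaries, fs, **kw):
    return pg.CycleSegmentation(np.asarray(boundaries, dtype=float), fs, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
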