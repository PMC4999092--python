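import numpy as np
import pytest

import petkin as pk


@pytest.fixture(scope="session")
def fdg_schedule():
    return pk.build_frame_schedule(pk.FRAMING["FDG"])


@pytest.fixture(scope="session")
def fdg_inputs(fdg_schedule):
    blood = pk.generate_aif(pk.AIFModel(), fdg_schedule)
    return pk.make_input_set("FDG", blood)


@pytest.fixture(scope="session")
def fet_schedule():
    return pk.build_frame_schedule(pk.FRAMING["FET"])


@pytest.fixture(scope="session")
def fet_inputs(fet_schedule):
    blood = pk.generate_aif(pk.AIFModel(), fet_schedule)
    return pk.make_input_set("FET", blood)


@pytest.fixture(scope="session")
def irreversible_2c_spec():
    return pk.ModelSpec("2C1i", fixed={"k4": 0.0})


@pytest.fixture(scope="session")
def fdg_gb_params():
    """Group-mean FDG micro-parameters of the glioblastoma group."""
    return pk.KineticParams(K1=0.16, k2=0.19, k3=0.07)


@pytest.fixture(scope="session")
def fdg_rn_params():
    """Group-mean FDG micro-parameters of the radiation-necrosis group."""
    return pk.KineticParams(K1=0.17, k2=0.28, k3=0.04)


@pytest.fixture(scope="session")
def long_schedule():
    """Extended 120-min framing (short bolus frames, then 5-min frames)
    for reversible-tracer equilibration."""
    return pk.build_frame_schedule("12x10s/6x20s/6x1min/10x2min/18x5min")


@pytest.fixture(scope="session")
def long_inputs(long_schedule):
    blood = pk.generate_aif(pk.AIFModel(), long_schedule)
    return pk.InputFunctionSet(blood.time, blood.activity, blood.activity)
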