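import numpy as np
import pytest

from csmtsim.phantom import (ProtocolSpec, default_vendors,
                             make_digital_phantom, make_field_maps,
                             simulate_acquisition)
from csmtsim.signal_models import TwoPoolTissue

TR, TE = 7.0, 3.5


def single_pool_params():
    """Phantom tissue table with the bound pool switched off everywhere."""
    return {
        1: TwoPoolTissue(t1_f=1100.0, t2_f=45.0, m0_f=0.7, bound_fraction=0.0, k_f=0.0),
        2: TwoPoolTissue(t1_f=1600.0, t2_f=70.0, m0_f=0.8, bound_fraction=0.0, k_f=0.0),
        3: TwoPoolTissue(t1_f=4000.0, t2_f=1800.0, m0_f=1.0, bound_fraction=0.0, k_f=0.0),
    }


def protocol_meta(tr=TR, te=TE):
    """Metadata of the full 8-volume protocol (4 SPGR + 3 bSSFP@180 + 1 @0)."""
    meta = [{"sequence": "spgr", "fa": f, "tr": tr, "te": te,
             "phase_increment": None} for f in (3.0, 7.0, 11.0, 15.0)]
    meta += [{"sequence": "bssfp", "fa": f, "tr": tr, "te": te,
              "phase_increment": 180.0} for f in (5.0, 25.0, 45.0)]
    meta += [{"sequence": "bssfp", "fa": 45.0, "tr": tr, "te": te,
              "phase_increment": 0.0}]
    return meta


@pytest.fixture(scope="session")
def sp_phantom32():
    return make_digital_phantom((32, 32, 32), seed=5,
                                tissue_params=single_pool_params())


@pytest.fixture(scope="session")
def fields32():
    return make_field_maps((32, 32, 32), seed=6)


@pytest.fixture(scope="session")
def sp_acq32(sp_phantom32, fields32):
    """Noiseless single-pool acquisition (ideal spoiling) at 32³."""
    vendor = default_vendors()[1]
    prot = ProtocolSpec(csmt=False, rf_spoiling_mode="harmonized")
    return simulate_acquisition(sp_phantom32, fields32, vendor, prot,
                                noise_sd=0.0, seed=11,
                                spoiling_imperfection=False)
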