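import numpy as np
import pytest

from mmclock.io_formats import mutations_to_frame, segments_to_frame
from mmclock.synthetic import SimProfile, simulate_patient
from mmclock.synthetic_signatures import synthetic_signature_reference


@pytest.fixture(scope="session")
def signatures():
    return synthetic_signature_reference()


@pytest.fixture(scope="session")
def sim_patient():
    """One moderately sized simulated patient with gains, subclone and SVs."""
    profile = SimProfile(
        group="progressive", n_patients=1,
        age_range=(60.0, 60.0), purity_range=(0.85, 0.85),
        gain_time_range=(0.4, 0.4), clock_yield=40.0, coverage=50.0,
        exposures={"SBS1": 0.2, "SBS5": 0.6, "SBS2": 0.08, "SBS13": 0.06,
                   "SBS9": 0.06},
        n_gains_range=(3, 3), cnloh_prob=1.0, tetrasomy_prob=1.0,
        second_gain_prob=0.0,
        sv_menu={"single": 3, "chromothripsis": 1, "templated_insertion": 1,
                 "chromoplexy": 1})
    rng = np.random.default_rng(12345)
    muts, segs, svs, meta, truth = simulate_patient(profile, rng, "PT001")
    return {"mutations": muts, "segments": segs, "svs": svs, "meta": meta,
            "truth": truth, "profile": profile}


@pytest.fixture(scope="session")
def sim_frames(sim_patient):
    return (mutations_to_frame(sim_patient["mutations"]),
            segments_to_frame(sim_patient["segments"]))
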