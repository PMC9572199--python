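import numpy as np
import pytest

import gaginter as gi


@pytest.fixture(scope="session")
def params():
    return gi.AnalysisParams()


def make_planted(seed=0, sigma=0.0, n_per_type=2, n_frames=40, n_waters=120,
                 cation="Na", isomer="CS4", validate=True, **overrides):
    """Desk-scale fixture with a random planted-event schedule."""
    rng = np.random.default_rng(seed)
    events = gi.schedule_events(
        {t: n_per_type for t in
         ("HBo", "HP", "ionic", "water_bridge", "ionic_bridge")},
        n_frames, rng, min_len=max(5, n_frames // 3), max_len=n_frames,
    )
    spec = gi.FixtureSpec.desk_scale(
        n_frames=n_frames, n_waters=n_waters, planted_events=events,
        rng_seed=seed, jitter_sigma=sigma, cation_species=cation,
        ligand_isomer=isomer, **overrides,
    )
    return gi.generate_trajectory(spec, validate=validate)


@pytest.fixture(scope="session")
def planted_traj():
    """Shared noiseless planted fixture (Ca solution for bridge labels)."""
    return make_planted(seed=7, cation="Ca")


def detected_sets(frame, system, frame_index=0):
    """Detector outputs of one frame as key sets, per event type."""
    return {
        "HBo": {
            (r.receptor_atom, r.ligand_atom)
            for r in gi.detect_hbonds(frame, system,
                                      ("receptor", "ligand"), None, frame_index)
        },
        "HP": {
            (r.receptor_atom, r.ligand_atom)
            for r in gi.detect_hydrophobic(frame, system, None,
                                           frame_index=frame_index)
        },
        "ionic": {
            (r.receptor_atom, r.ligand_atom)
            for r in gi.detect_ionic(frame, system, None,
                                     frame_index=frame_index)
        },
        "water_bridge": {
            (r.receptor_endpoint, r.ligand_endpoint)
            for r in gi.detect_water_bridges(frame, system, None, frame_index)
        },
        "ionic_bridge": {
            (r.receptor_endpoint, r.ligand_endpoint)
            for r in gi.detect_ionic_bridges(frame, system, None, frame_index)
        },
    }
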