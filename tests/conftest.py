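import numpy as np
import pytest

import cgmem
from cgmem.fixtures import FixtureSpec, generate


@pytest.fixture(scope="session")
def flat_bilayer():
    """Flat protein-free bilayer, 64 lipids/leaflet, 37 Å phosphate planes."""
    spec = FixtureSpec(lipids_per_leaflet=64, water=False, seed=7)
    frames, truth = generate(spec)
    return frames[0], truth


@pytest.fixture(scope="session")
def gpcr_fixture():
    """The documented GPCR-like 7-TM bundle worked example (seed 1)."""
    return generate(FixtureSpec.gpcr_default(seed=1))


@pytest.fixture(scope="session")
def gpcr_analysis(gpcr_fixture):
    """Shared downstream products for the bundle fixture."""
    frames, truth = gpcr_fixture
    last = frames[-1]
    assignment = cgmem.assign_leaflets(last)
    surfaces = cgmem.leaflet_surfaces(last, assignment)
    profile = cgmem.count_contacts(frames)
    depth = cgmem.local_thickness_per_residue(last, surfaces)
    return {
        "frames": frames,
        "truth": truth,
        "last": last,
        "assignment": assignment,
        "surfaces": surfaces,
        "profile": profile,
        "depth": depth,
    }


def merge_beads(base, extra_coords, bead_names, residue_names, residue_indices):
    """New frame = base frame plus extra beads (used to plant protein/probes)."""
    from cgmem.frames import frame_from_arrays

    n = len(extra_coords)
    return frame_from_arrays(
        coordinates=np.vstack([base.coordinates, np.asarray(extra_coords, float)]),
        bead_names=np.concatenate([base.bead_name, np.asarray(bead_names, object)]),
        residue_names=np.concatenate(
            [base.residue_name, np.asarray(residue_names, object)]
        ),
        residue_indices=np.concatenate(
            [base.residue_index, np.asarray(residue_indices, int)]
        ),
        chain_ids=np.concatenate([base.chain_id, np.full(n, "A", object)]),
        box=base.box,
        frame_time=base.frame_time,
    )
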