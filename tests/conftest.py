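import numpy as np
import pytest

from sarcosim import BundleState, Params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(params: Params, plus_pos, sigma, lengths=None, clusters=None,
               my_center=None, my_bound=None, my_offset=None) -> BundleState:
    """Hand-build a BundleState: explicit filament arrays, optional cluster
    groupings (list of sets of filament ids; the rest stay free) and myosins."""
    state = BundleState(params)
    state.plus_pos[:] = np.asarray(plus_pos, dtype=float)
    state.sigma[:] = np.asarray(sigma, dtype=np.int8)
    if lengths is not None:
        state.length[:] = np.asarray(lengths, dtype=float)
    if clusters:
        for members in clusters:
            members = set(members)
            z = float(state.plus_pos[next(iter(members))])
            state.new_cluster(z, members)
    if my_center is not None:
        state.my_center[:] = np.asarray(my_center, dtype=float)
    if my_bound is not None:
        state.my_bound[:] = np.asarray(my_bound, dtype=np.int64)
    if my_offset is not None:
        state.my_offset[:] = np.asarray(my_offset, dtype=float)
    from sarcosim.kinetics import make_streams

    state.streams = make_streams(params.seed)
    return state
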