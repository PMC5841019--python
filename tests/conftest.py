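import numpy as np
import pytest

from eegrsn.forward import (HeadModel, SourceSpace, build_source_grid,
                            compute_leadfield)
from eegrsn.synthdata import make_montage


@pytest.fixture(scope="session")
def head4():
    return HeadModel.four_shell()


@pytest.fixture(scope="session")
def montage64(head4):
    return make_montage(64, head_radius=head4.scalp_radius)


@pytest.fixture(scope="session")
def small_space(head4):
    """Coarse ribbon grid (~500 sources) for operator-level tests."""
    return build_source_grid(head4, spacing=0.014)


@pytest.fixture(scope="session")
def leadfield64(montage64, head4, small_space):
    return compute_leadfield(montage64, head4, small_space)


@pytest.fixture(scope="session")
def cube_space():
    """Dense 7x7x7 cubic lattice (no clipping) for cluster-statistics tests."""
    m = 3
    axis = np.arange(-m, m + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    return SourceSpace(positions=ijk * 0.006, spacing=0.006,
                       inner_radius=0.0, outer_radius=1.0,
                       grid_ijk=ijk + m, vol_shape=(2 * m + 1,) * 3)
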