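import numpy as np
import pytest

from thrombovol.conduction import (
    ChannelGeometry,
    ElectrodeLayout,
    ForwardModel,
    VoxelGrid,
)


@pytest.fixture(scope="session")
def device():
    """Default full-size forward model (shared; construction is cheap but the
    electrode masks and grid are reused by many tests)."""
    return ForwardModel()


@pytest.fixture(scope="session")
def small_device():
    """Scaled-down channel/electrode model whose grid stays under 10^3 cells,
    so dense-matrix oracles and exact direct solves are affordable."""
    geom = ChannelGeometry(width=150.0, height=40.0, modeled_length=210.0)
    layout = ElectrodeLayout(
        window=70.0, outer_track=10.0, inner_track=10.0, inner_margin=20.0
    )
    grid = VoxelGrid.default(
        geom, layout, voxel_xy=10.0, z_first=2.0, z_uniform=4, z_ratio=2.0,
        n_ext=2, n_margin=2,
    )
    fm = ForwardModel(geom=geom, layout=layout, grid=grid)
    assert grid.n_cells <= 1000
    return fm


def dense_nodal_impedance(field, masks, drive_voltage=0.1):
    """Independent dense nodal-analysis oracle for the conduction solve.

    Assembles the full resistor network with explicit Python loops (series
    half-cell conductances on every face, half-cell coupling from wall-adjacent
    cells to the two electrode potentials) and solves it with a dense LAPACK
    factorization.  Shares no code with the sparse finite-volume path.
    """
    um = 1e-6
    g = field.grid
    nx, ny, nz = g.shape
    sig = field.sigma
    n = nx * ny * nz

    def lin(i, j, k):
        return (i * ny + j) * nz + k

    A = np.zeros((n, n))
    b = np.zeros(n)
    dx, dy, dz = g.dx, g.dy, g.dz

    def couple(p, q, gf):
        A[p, p] += gf
        A[q, q] += gf
        A[p, q] -= gf
        A[q, p] -= gf

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = lin(i, j, k)
                if i + 1 < nx:
                    area = dy[j] * dz[k]
                    gf = area * um / (
                        dx[i] / (2 * sig[i, j, k]) + dx[i + 1] / (2 * sig[i + 1, j, k])
                    )
                    couple(p, lin(i + 1, j, k), gf)
                if j + 1 < ny:
                    area = dx[i] * dz[k]
                    gf = area * um / (
                        dy[j] / (2 * sig[i, j, k]) + dy[j + 1] / (2 * sig[i, j + 1, k])
                    )
                    couple(p, lin(i, j + 1, k), gf)
                if k + 1 < nz:
                    area = dx[i] * dy[j]
                    gf = area * um / (
                        dz[k] / (2 * sig[i, j, k]) + dz[k + 1] / (2 * sig[i, j, k + 1])
                    )
                    couple(p, lin(i, j, k + 1), gf)

    mo, mi = masks
    v = drive_voltage / 2.0
    g_outer = np.zeros((nx, ny))
    g_inner = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            ge = sig[i, j, 0] * dx[i] * dy[j] * um / (dz[0] / 2.0)
            p = lin(i, j, 0)
            if mo[i, j]:
                g_outer[i, j] = ge
                A[p, p] += ge
                b[p] += ge * v
            if mi[i, j]:
                g_inner[i, j] = ge
                A[p, p] += ge
                b[p] -= ge * v

    phi = np.linalg.solve(A, b)
    i_outer = 0.0
    for i in range(nx):
        for j in range(ny):
            if g_outer[i, j]:
                i_outer += g_outer[i, j] * (v - phi[lin(i, j, 0)])
    return drive_voltage / abs(i_outer)
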