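"""Axisymmetric (r, z) triangulation of the fluid region.

The fluid domain is the (r, z) rectangle [0, R] x [0, L) minus the RBC
envelopes.  Because every RBC is radially centred, the inner fluid boundary
at each axial station is a single radius s(z) (0 on the open axis, the cell
silhouette inside a cell), so a boundary-fitted mesh is obtained by mapping
a structured grid: node (i, j) sits at radius s(z_j) + (R - s(z_j)) * i/n_r.
The axial direction wraps periodically; quads are split into two triangles
with a fixed diagonal, which keeps the mesh deterministic.

Boundary tags follow the usual convention: ``wall`` (r = R), ``axis``
(r = 0), ``rbc`` (nodes on a cell envelope), plus ``inlet``/``outlet``
markers on the j = 0 column retained for export when the periodic seam is
of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RBCAgent, VesselGeometry


@dataclass
class Mesh:
    """Triangle mesh of the axisymmetric fluid region (lengths in nm).

    The axial seam is meshed with a duplicated column of nodes at z = L;
    ``owner`` maps every node to its periodic master (itself except for
    the seam slaves), which is how the solver folds the periodic dofs.
    """

    nodes: np.ndarray          # (n_nodes, 2) columns r, z
    elements: np.ndarray       # (n_elems, 3) node indices, CCW
    owner: np.ndarray          # (n_nodes,) periodic master node of each node
    wall_nodes: np.ndarray     # node indices on r = R
    axis_nodes: np.ndarray     # node indices on r = 0
    rbc_nodes: np.ndarray      # node indices on an RBC envelope
    n_r: int
    n_z: int
    geom: VesselGeometry

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_areas(self) -> np.ndarray:
        """Signed triangle areas (positive for CCW elements), nm^2."""
        p = self.nodes
        a, b, c = (p[self.elements[:, k]] for k in range(3))
        return 0.5 * (
            (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
            - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
        )

    def element_centroids(self) -> np.ndarray:
        p = self.nodes
        return (
            p[self.elements[:, 0]] + p[self.elements[:, 1]] + p[self.elements[:, 2]]
        ) / 3.0


def combined_silhouette(rbcs: list[RBCAgent], z: np.ndarray,
                        length: float, periodic: bool = True) -> np.ndarray:
    """Inner fluid radius s(z): the max of all cell silhouettes at z (nm).

    With a periodic axis, each cell is also evaluated at z +/- L so cells
    straddling the seam are seen on both sides.
    """
    z = np.asarray(z, dtype=float)
    s = np.zeros_like(z)
    for cell in rbcs:
        s = np.maximum(s, cell.silhouette_radius(z))
        if periodic:
            s = np.maximum(s, cell.silhouette_radius(z + length))
            s = np.maximum(s, cell.silhouette_radius(z - length))
    return s


def build_mesh(
    geom: VesselGeometry,
    rbcs: list[RBCAgent] | None = None,
    n_r: int = 24,
    n_z: int = 250,
) -> Mesh:
    """Build the mapped structured mesh of the fluid region.

    Parameters
    ----------
    n_r : int
        Number of radial elements between the inner boundary and the wall.
    n_z : int
        Number of axial columns (element size L / n_z).
    """
    if n_r < 4 or n_z < 8:
        raise ValueError("mesh too coarse: need n_r >= 4 and n_z >= 8")
    if not geom.periodic_axial:
        raise ValueError("only periodic axial meshes are supported")
    rbcs = rbcs or []

    # n_z + 1 columns: the last duplicates the first at z = L (seam slaves)
    z_cols = np.arange(n_z + 1) * (geom.length / n_z)
    s = combined_silhouette(rbcs, z_cols, geom.length, periodic=True)
    s[-1] = s[0]
    if np.any(s >= geom.radius):
        raise ValueError("an RBC envelope reaches the vessel wall")

    frac = np.arange(n_r + 1) / n_r
    # nodes (i, j): r = s_j + (R - s_j) * i/n_r, node id = j*(n_r+1) + i
    r = s[None, :] + (geom.radius - s[None, :]) * frac[:, None]  # (n_r+1, n_z+1)
    z = np.broadcast_to(z_cols[None, :], r.shape)
    nodes = np.column_stack([r.T.ravel(), z.T.ravel()])          # j-major

    nid = np.arange((n_z + 1) * (n_r + 1)).reshape(n_z + 1, n_r + 1)
    owner = np.arange(nodes.shape[0])
    owner[nid[-1]] = nid[0]

    a = nid[:-1, :-1]          # (j,   i)
    b = nid[1:, :-1]           # (j+1, i)
    c = nid[1:, 1:]            # (j+1, i+1)
    d = nid[:-1, 1:]           # (j,   i+1)
    # CCW in the (r, z) plane
    tri1 = np.stack([a, c, b], axis=-1).reshape(-1, 3)
    tri2 = np.stack([a, d, c], axis=-1).reshape(-1, 3)
    elements = np.concatenate([tri1, tri2], axis=0)

    inner = nid[:, 0]
    on_rbc = s > 0.0
    mesh = Mesh(
        nodes=nodes,
        elements=elements,
        owner=owner,
        wall_nodes=nid[:, -1].ravel(),
        axis_nodes=inner[~on_rbc],
        rbc_nodes=inner[on_rbc],
        n_r=n_r,
        n_z=n_z,
        geom=geom,
    )
    areas = mesh.element_areas()
    if np.any(areas <= 0.0):
        raise ValueError("mesh contains inverted or degenerate elements")
    return mesh
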