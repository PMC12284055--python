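"""2D finite-element forward model of a circular saline/agar tank.

Solves the continuum conduction equation ``div(sigma grad u) = 0`` on a
triangulated disk with point current injection at boundary electrode nodes
(point-electrode model; the phantoms are purely resistive so the DC
solution stands in for the 50 kHz envelope).  Linear (P1) elements, a
zero-mean potential gauge, and the adjoint method for the conductivity
sensitivity Jacobian.

Coordinates are in meters with the tank center at the origin; electrode 1
sits at angle 0 and indices run counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .acquisition import ElectrodeLayout, InjectionPattern

__all__ = [
    "DiskMesh",
    "ConductivityField",
    "SensitivityMatrix",
    "ForwardOperator",
    "build_disk_mesh",
    "solve_forward",
    "protocol_voltages",
    "protocol_voltages_signed",
    "jacobian",
    "element_areas",
    "element_centroids",
    "save_mesh",
    "load_mesh",
]


@dataclass(frozen=True)
class DiskMesh:
    """Triangulated disk with electrode nodes on the boundary ring."""

    nodes: np.ndarray  # (n_nodes, 2) meters
    triangles: np.ndarray  # (n_elements, 3) node indices, CCW
    boundary_nodes: np.ndarray  # boundary ring in angular order
    electrode_nodes: np.ndarray  # node index per electrode
    radius: float

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]


@dataclass(frozen=True)
class ConductivityField:
    """Per-element conductivity in S/m."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("conductivities must be a 1-D array of positive finites")
        object.__setattr__(self, "values", v)

    @classmethod
    def homogeneous(cls, mesh: DiskMesh, sigma: float) -> "ConductivityField":
        return cls(values=np.full(mesh.n_elements, float(sigma)))


@dataclass(frozen=True)
class SensitivityMatrix:
    """d(measurement)/d(element conductivity), one row per measurement."""

    matrix: np.ndarray  # (n_measurements, n_elements)


# ---------------------------------------------------------------------------
# mesh generation


def _stitch_rings(
    inner: np.ndarray, inner_ang: np.ndarray, outer: np.ndarray, outer_ang: np.ndarray
) -> list[tuple[int, int, int]]:
    """Triangulate the annulus between two node rings sorted by angle."""
    p, q = len(inner), len(outer)
    tris = []
    i = j = 0
    ci = cj = 0  # steps taken on each ring

    def nxt(ang, pos, count, size):
        return ang[(pos + 1) % size] + 2 * np.pi * ((pos + 1) // size)

    while ci < p or cj < q:
        adv_inner = cj >= q or (
            ci < p
            and nxt(inner_ang, i, ci, p) <= nxt(outer_ang, j, cj, q)
        )
        if adv_inner:
            tris.append((inner[i % p], outer[j % q], inner[(i + 1) % p]))
            i += 1
            ci += 1
        else:
            tris.append((inner[i % p], outer[j % q], outer[(j + 1) % q]))
            j += 1
            cj += 1
    return tris


def build_disk_mesh(
    radius: float, target_elements: int, layout: ElectrodeLayout
) -> DiskMesh:
    """Quasi-uniform triangulation of the disk with on-boundary electrodes.

    Nodes are laid out on concentric rings (ring ``i`` of ``R`` at radius
    ``r*i/R``) with per-ring counts proportional to circumference, and the
    annuli are stitched into triangles.  The boundary ring count is a
    multiple of the electrode count so each equispaced electrode angle is a
    node; a general layout is snapped to the nearest boundary node, which
    must lie within half an edge length.  The achieved element count lands
    within roughly 30% of ``target_elements``.
    """
    if target_elements < 64:
        raise ValueError("target_elements must be >= 64")
    if radius <= 0:
        raise ValueError("radius must be positive")
    n_elec = layout.n_electrodes
    n_rings = max(2, round(np.sqrt(target_elements / (2 * np.pi))))
    n_outer = n_elec * max(2, round(2 * np.pi * n_rings / n_elec))
    offset = layout.angles[0]

    nodes = [(0.0, 0.0)]
    ring_idx: list[np.ndarray] = []
    ring_ang: list[np.ndarray] = []
    for i in range(1, n_rings + 1):
        n_i = n_outer if i == n_rings else max(5, round(n_outer * i / n_rings))
        ang = offset + 2 * np.pi * np.arange(n_i) / n_i
        r_i = radius * i / n_rings
        start = len(nodes)
        nodes.extend(zip(r_i * np.cos(ang), r_i * np.sin(ang)))
        ring_idx.append(np.arange(start, start + n_i))
        ring_ang.append(np.mod(ang - offset, 2 * np.pi))

    tris: list[tuple[int, int, int]] = []
    first = ring_idx[0]
    for t in range(len(first)):
        tris.append((0, first[t], first[(t + 1) % len(first)]))
    for i in range(n_rings - 1):
        tris.extend(
            _stitch_rings(ring_idx[i], ring_ang[i], ring_idx[i + 1], ring_ang[i + 1])
        )

    nodes_arr = np.asarray(nodes, dtype=float)
    tris_arr = np.asarray(tris, dtype=np.int64)
    # enforce CCW orientation
    p = nodes_arr[tris_arr]
    cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = cross < 0
    tris_arr[flip] = tris_arr[flip][:, [0, 2, 1]]
    if np.any(np.abs(cross) <= 0):
        raise ValueError("degenerate triangle produced; infeasible target")

    boundary = ring_idx[-1]
    boundary_ang = ring_ang[-1] + offset
    gap = 2 * np.pi / n_outer
    elec_nodes = []
    for a in layout.angles:
        d = np.angle(np.exp(1j * (boundary_ang - a)))
        k = int(np.argmin(np.abs(d)))
        if abs(d[k]) > gap / 2 + 1e-12:
            raise ValueError("electrode angle farther than half an edge from a node")
        elec_nodes.append(boundary[k])
    return DiskMesh(
        nodes=nodes_arr,
        triangles=tris_arr,
        boundary_nodes=boundary,
        electrode_nodes=np.asarray(elec_nodes, dtype=np.int64),
        radius=float(radius),
    )


def _geometry(mesh: DiskMesh) -> tuple[np.ndarray, np.ndarray]:
    """Element areas (M,) and P1 basis gradients (M, 3, 2)."""
    p = mesh.nodes[mesh.triangles]
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    areas = 0.5 * det
    grads = np.empty((mesh.n_elements, 3, 2))
    # grad of basis k is perpendicular to the opposite edge / (2A)
    for k in range(3):
        a = p[:, (k + 1) % 3]
        b = p[:, (k + 2) % 3]
        grads[:, k, 0] = (a[:, 1] - b[:, 1]) / det
        grads[:, k, 1] = (b[:, 0] - a[:, 0]) / det
    return areas, grads


def element_areas(mesh: DiskMesh) -> np.ndarray:
    return _geometry(mesh)[0]


def element_centroids(mesh: DiskMesh) -> np.ndarray:
    return mesh.nodes[mesh.triangles].mean(axis=1)


class ForwardOperator:
    """Assembled and factorized forward problem for one (mesh, field) pair.

    The stiffness matrix is grounded at one node for factorization; returned
    potentials are shifted to the zero-mean gauge.  Reusable across drives,
    which is what makes the 8-drive protocol and the adjoint Jacobian cheap.
    """

    def __init__(self, mesh: DiskMesh, field: ConductivityField):
        if field.values.size != mesh.n_elements:
            raise ValueError("field size does not match mesh element count")
        self.mesh = mesh
        self.field = field
        self.areas, self.grads = _geometry(mesh)
        scaled = field.values * self.areas  # (M,)
        rows, cols, vals = [], [], []
        for a in range(3):
            for b in range(3):
                rows.append(mesh.triangles[:, a])
                cols.append(mesh.triangles[:, b])
                vals.append(scaled * np.einsum("md,md->m", self.grads[:, a], self.grads[:, b]))
        k_mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(mesh.n_nodes, mesh.n_nodes),
        ).tocsc()
        try:
            self._lu = spla.splu(k_mat[1:, 1:])
        except RuntimeError as exc:  # pragma: no cover - needs a broken mesh
            raise ValueError(f"singular forward system (disconnected mesh?): {exc}")

    def solve(self, drive: tuple[int, int], current: float) -> np.ndarray:
        """Zero-mean node potentials for +I at electrode ``drive[0]``, -I at ``drive[1]``."""
        if current <= 0:
            raise ValueError("current must be positive")
        src, snk = (self.mesh.electrode_nodes[e] for e in drive)
        b = np.zeros(self.mesh.n_nodes)
        b[src] += current
        b[snk] -= current
        u = np.empty(self.mesh.n_nodes)
        u[0] = 0.0
        u[1:] = self._lu.solve(b[1:])
        if not np.all(np.isfinite(u)):
            raise ValueError("forward solve produced non-finite potentials")
        return u - u.mean()

    def pair_potentials(self, pairs: list[tuple[int, int]]) -> dict[tuple[int, int], np.ndarray]:
        """Unit-current potentials for each unordered electrode pair."""
        out = {}
        for pair in pairs:
            key = (min(pair), max(pair))
            if key not in out:
                out[key] = self.solve(key, 1.0)
        return out


def solve_forward(
    mesh: DiskMesh,
    field: ConductivityField,
    drive: tuple[int, int],
    current: float,
) -> np.ndarray:
    """Node potentials (volts) for one drive pair; see ``ForwardOperator``."""
    return ForwardOperator(mesh, field).solve(drive, current)


def _signed_from_pairs(
    op: ForwardOperator, pattern: InjectionPattern, current: float
) -> tuple[np.ndarray, list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Signed measurements u[q]-u[p] and the (drive, measure) slot list."""
    all_pairs = [drive for drive, _ in pattern.entries]
    for _, measures in pattern.entries:
        all_pairs.extend(measures)
    pots = op.pair_potentials(all_pairs)

    def pot(pair):
        key = (min(pair), max(pair))
        sgn = 1.0 if pair[0] == key[0] else -1.0
        return sgn * pots[key]

    signed = []
    slots = []
    elec = op.mesh.electrode_nodes
    for drive, measures in pattern.entries:
        u = current * pot(drive)
        for p, q in measures:
            signed.append(u[elec[q]] - u[elec[p]])
            slots.append((drive, (p, q)))
    return np.asarray(signed), slots


def protocol_voltages_signed(
    mesh: DiskMesh,
    field: ConductivityField,
    pattern: InjectionPattern,
    current: float = 1.0,
) -> np.ndarray:
    """Signed differential voltages ``u[q] - u[p]``, flattened row-major."""
    op = ForwardOperator(mesh, field)
    return _signed_from_pairs(op, pattern, current)[0]


def protocol_voltages(
    mesh: DiskMesh,
    field: ConductivityField,
    pattern: InjectionPattern,
    current: float = 1.0,
) -> np.ndarray:
    """Measurement-vector magnitudes as the RMS demodulator reports them.

    One value per (drive, measure) slot in row-major order; the DC FEM
    solution stands in for the sinusoidal envelope, and the demodulator
    only ever sees magnitudes.
    """
    return np.abs(protocol_voltages_signed(mesh, field, pattern, current))


def jacobian(
    mesh: DiskMesh,
    field: ConductivityField,
    pattern: InjectionPattern,
    current: float = 1.0,
) -> SensitivityMatrix:
    """Adjoint-method sensitivity of ``protocol_voltages`` to element conductivity.

    For a signed measurement ``V = u_d[q] - u_d[p]`` the adjoint identity
    gives ``dV/dsigma_e = -A_e * grad(u_d)|_e . grad(w)|_e`` with ``w`` the
    unit-current field of the measurement pair; the sign of the background
    measurement converts this to the magnitude convention of the
    demodulated voltages.
    """
    op = ForwardOperator(mesh, field)
    signed, slots = _signed_from_pairs(op, pattern, current)
    pots = op.pair_potentials([pair for drive, meas in slots for pair in (drive, meas)])

    def pot(pair):
        key = (min(pair), max(pair))
        return (1.0 if pair[0] == key[0] else -1.0) * pots[key]

    tri = mesh.triangles
    grad_cache: dict[tuple[int, int], np.ndarray] = {}

    def grad_of(pair):
        key = (min(pair), max(pair))
        if key not in grad_cache:
            u = pots[key]
            grad_cache[key] = np.einsum("mk,mkd->md", u[tri], op.grads)
        return (1.0 if pair[0] == key[0] else -1.0) * grad_cache[key]

    rows = np.empty((len(slots), mesh.n_elements))
    for m, (drive, meas) in enumerate(slots):
        gu = current * grad_of(drive)
        gw = grad_of((meas[1], meas[0]))  # adjoint source +1 at the q electrode
        rows[m] = -op.areas * np.einsum("md,md->m", gu, gw)
    sign = np.where(signed >= 0, 1.0, -1.0)
    return SensitivityMatrix(matrix=sign[:, None] * rows)


# ---------------------------------------------------------------------------
# plain-text mesh serialization


def save_mesh(mesh: DiskMesh, path: str | Path) -> None:
    """Write the mesh in a simple line-oriented text format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# eitpsoc disk mesh\nradius {mesh.radius:.17g}\n")
        fh.write(f"nodes {mesh.n_nodes}\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.17g} {y:.17g}\n")
        fh.write(f"triangles {mesh.n_elements}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"{a} {b} {c}\n")
        fh.write("boundary " + " ".join(map(str, mesh.boundary_nodes)) + "\n")
        fh.write("electrodes " + " ".join(map(str, mesh.electrode_nodes)) + "\n")


def load_mesh(path: str | Path) -> DiskMesh:
    lines = [ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")]
    it = iter(lines)
    radius = float(next(it).split()[1])
    n_nodes = int(next(it).split()[1])
    nodes = np.array([[float(t) for t in next(it).split()] for _ in range(n_nodes)])
    n_tris = int(next(it).split()[1])
    tris = np.array(
        [[int(t) for t in next(it).split()] for _ in range(n_tris)], dtype=np.int64
    )
    boundary = np.array([int(t) for t in next(it).split()[1:]], dtype=np.int64)
    electrodes = np.array([int(t) for t in next(it).split()[1:]], dtype=np.int64)
    return DiskMesh(
        nodes=nodes,
        triangles=tris,
        boundary_nodes=boundary,
        electrode_nodes=electrodes,
        radius=radius,
    )
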