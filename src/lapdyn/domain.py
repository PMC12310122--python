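"""Spatial domains and Laplacian eigenfunction bases.

Two kinds of domain are supported:

* triangulated 2D geometries (:class:`TriangleMesh`), on which the Laplacian
  is discretized with linear (P1) finite elements under no-flux (Neumann)
  boundary conditions, and
* weighted graphs (:class:`GraphDomain`), e.g. region-by-region brain
  connectomes, on which the combinatorial graph Laplacian ``L = D - W`` plays
  the role of the (negative) Laplace operator.

Both yield a :class:`SpectralBasis`: the lowest generalized eigenpairs of the
Laplacian, orthonormal under the domain's natural inner product (the FEM mass
matrix for meshes, Euclidean for graphs).  These eigenfunctions are the
spatial modes in which all downstream dynamics are expressed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "GraphDomain",
    "FemMatrices",
    "SpectralBasis",
    "load_mesh",
    "write_off",
    "unit_square_mesh",
    "brain_slice_mesh",
    "assemble_fem",
    "build_graph_domain",
    "synthetic_connectome",
    "compute_basis",
    "save_basis",
    "load_basis",
    "DomainValidationError",
]


class DomainValidationError(ValueError):
    """Raised when a mesh or graph violates a structural invariant."""


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """A conforming triangulation of a planar domain.

    Parameters
    ----------
    node_coords : (n_nodes, 2) float array
        Vertex coordinates.
    triangles : (n_tri, 3) int array
        Vertex index triples, counter-clockwise or clockwise (orientation is
        irrelevant for the symmetric forms assembled here).
    """

    node_coords: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 2:
            raise DomainValidationError("node_coords must be (n, 2)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise DomainValidationError("triangles must be (m, 3)")
        n = self.n_nodes
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= n:
            raise DomainValidationError(
                f"triangle index out of range [0, {n})"
            )
        areas = self.triangle_areas()
        bad = np.flatnonzero(areas <= 1e-14)
        if bad.size:
            raise DomainValidationError(
                f"degenerate (zero-area) triangle(s) at indices {bad[:5].tolist()}"
            )
        if not self._connected():
            raise DomainValidationError("mesh is not connected")

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.node_coords
        t = self.triangles
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def _connected(self) -> bool:
        i = np.concatenate([self.triangles[:, k] for k in (0, 1, 2)])
        j = np.concatenate([self.triangles[:, k] for k in (1, 2, 0)])
        adj = sp.coo_matrix(
            (np.ones_like(i, dtype=float), (i, j)),
            shape=(self.n_nodes, self.n_nodes),
        )
        ncomp, _ = csgraph.connected_components(adj, directed=False)
        return ncomp == 1


def unit_square_mesh(nx: int = 20) -> TriangleMesh:
    """Structured triangulation of the unit square with ``nx`` cells per side.

    Mesh size is ``h = 1/nx``; each grid cell is split into two triangles.
    """
    xs = np.linspace(0.0, 1.0, nx + 1)
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    coords = np.column_stack([X.ravel(), Y.ravel()])
    tris = []
    for row in range(nx):
        for col in range(nx):
            v00 = row * (nx + 1) + col
            v10 = v00 + 1
            v01 = v00 + (nx + 1)
            v11 = v01 + 1
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    return TriangleMesh(coords, np.array(tris))


def brain_slice_mesh(n_rings: int = 10, n_theta: int = 28) -> TriangleMesh:
    """A smooth, asymmetric 'brain-slice'-like 2D blob, triangulated in polar
    rings.  Purely synthetic: the boundary is a low-harmonic perturbation of a
    circle, giving an irregular convex-ish domain for mesh-based tests."""

    def radius(theta: np.ndarray) -> np.ndarray:
        return 1.0 + 0.18 * np.cos(2 * theta) + 0.08 * np.sin(3 * theta) \
            - 0.05 * np.cos(5 * theta)

    coords = [(0.0, 0.0)]
    ring_start = [0]
    for r in range(1, n_rings + 1):
        frac = r / n_rings
        m = max(6, int(round(n_theta * frac)))
        ring_start.append(len(coords))
        theta = 2 * np.pi * np.arange(m) / m
        rad = frac * radius(theta)
        # mild anisotropic squash to break symmetry
        coords.extend(zip(rad * np.cos(theta), 0.85 * rad * np.sin(theta)))
    ring_start.append(len(coords))
    coords = np.array(coords)

    tris: list[tuple[int, int, int]] = []
    # innermost fan
    m1 = ring_start[2] - ring_start[1]
    for k in range(m1):
        tris.append((0, ring_start[1] + k, ring_start[1] + (k + 1) % m1))
    # ring-to-ring strips: connect each outer node to nearest inner nodes
    for r in range(1, n_rings):
        i0, i1 = ring_start[r], ring_start[r + 1]
        o0, o1 = ring_start[r + 1], ring_start[r + 2]
        mi, mo = i1 - i0, o1 - o0
        for k in range(mo):
            a = o0 + k
            b = o0 + (k + 1) % mo
            ia = i0 + int(round(k * mi / mo)) % mi
            ib = i0 + int(round((k + 1) * mi / mo)) % mi
            tris.append((a, b, ib))
            if ia != ib:
                tris.append((a, ib, ia))
    return TriangleMesh(coords, np.array(tris))


# --- mesh file I/O ---------------------------------------------------------

def load_mesh(path: str) -> TriangleMesh:
    """Read a triangle mesh from Gmsh MSH (ASCII v2/v4.1) or OFF format.

    Format is chosen by sniffing the header, not the extension.
    """
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    try:
        if stripped.startswith("OFF"):
            return _parse_off(text)
        if stripped.startswith("$MeshFormat"):
            return _parse_msh(text)
    except DomainValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap parser faults
        raise DomainValidationError(f"failed to parse mesh file {path}: {exc}") from exc
    raise DomainValidationError(f"unrecognized mesh format in {path}")


def _parse_off(text: str) -> TriangleMesh:
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.extend(line.split())
    if tokens[0] != "OFF":
        raise DomainValidationError("missing OFF header")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4  # skip edge count
    coords = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    tris = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise DomainValidationError("OFF faces must be triangles")
        tris.append([int(tokens[pos + 1]), int(tokens[pos + 2]), int(tokens[pos + 3])])
        pos += 4
    return TriangleMesh(coords[:, :2], np.array(tris))


def _parse_msh(text: str) -> TriangleMesh:
    lines = [ln.strip() for ln in text.splitlines()]
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(lines):
        if lines[i].startswith("$") and not lines[i].startswith("$End"):
            name = lines[i][1:]
            j = i + 1
            body: list[str] = []
            while j < len(lines) and not lines[j].startswith("$End"):
                body.append(lines[j])
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1
    version = float(sections["MeshFormat"][0].split()[0])
    if version < 3.0:
        return _parse_msh2(sections)
    return _parse_msh4(sections)


def _parse_msh2(sections: dict[str, list[str]]) -> TriangleMesh:
    node_lines = sections["Nodes"]
    n = int(node_lines[0])
    tags, coords = [], []
    for ln in node_lines[1 : 1 + n]:
        parts = ln.split()
        tags.append(int(parts[0]))
        coords.append([float(parts[1]), float(parts[2])])
    remap = {t: k for k, t in enumerate(tags)}
    elem_lines = sections["Elements"]
    ne = int(elem_lines[0])
    tris = []
    for ln in elem_lines[1 : 1 + ne]:
        parts = ln.split()
        etype, ntags = int(parts[1]), int(parts[2])
        if etype == 2:  # 3-node triangle
            vs = parts[3 + ntags : 6 + ntags]
            tris.append([remap[int(v)] for v in vs])
    if not tris:
        raise DomainValidationError("MSH file contains no triangles")
    return TriangleMesh(np.array(coords), np.array(tris))


def _parse_msh4(sections: dict[str, list[str]]) -> TriangleMesh:
    node_lines = sections["Nodes"]
    header = node_lines[0].split()
    n_blocks = int(header[0])
    tags: list[int] = []
    coords: list[list[float]] = []
    pos = 1
    for _ in range(n_blocks):
        blk = node_lines[pos].split()
        n_in_block = int(blk[3])
        pos += 1
        blk_tags = [int(node_lines[pos + k]) for k in range(n_in_block)]
        pos += n_in_block
        for k in range(n_in_block):
            parts = node_lines[pos + k].split()
            coords.append([float(parts[0]), float(parts[1])])
        pos += n_in_block
        tags.extend(blk_tags)
    remap = {t: k for k, t in enumerate(tags)}

    elem_lines = sections["Elements"]
    n_blocks = int(elem_lines[0].split()[0])
    pos = 1
    tris = []
    for _ in range(n_blocks):
        blk = elem_lines[pos].split()
        etype, n_in_block = int(blk[2]), int(blk[3])
        pos += 1
        for k in range(n_in_block):
            parts = elem_lines[pos + k].split()
            if etype == 2:
                tris.append([remap[int(v)] for v in parts[1:4]])
        pos += n_in_block
    if not tris:
        raise DomainValidationError("MSH file contains no triangles")
    return TriangleMesh(np.array(coords), np.array(tris))


def write_off(mesh: TriangleMesh, path: str) -> None:
    """Write a mesh in ASCII OFF (z coordinate written as 0)."""
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_nodes} {mesh.n_triangles} 0\n")
        for x, y in mesh.node_coords:
            fh.write(f"{x:.10g} {y:.10g} 0\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")


# --------------------------------------------------------------------------
# FEM assembly
# --------------------------------------------------------------------------

@dataclass
class FemMatrices:
    """P1 stiffness (``int grad u . grad v``) and mass (``int u v``) matrices.

    No boundary terms are assembled, which is exactly the natural (no-flux
    Neumann) condition of the weak form: constants lie in the stiffness
    kernel and total mass is conserved under pure diffusion.
    """

    stiffness: sp.csr_matrix
    mass: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.stiffness.shape[0]


def assemble_fem(mesh: TriangleMesh) -> FemMatrices:
    """Assemble P1 finite-element matrices on a triangle mesh."""
    p, t = mesh.node_coords, mesh.triangles
    n = mesh.n_nodes
    rows, cols, kv, mv = [], [], [], []
    local_mass = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    for ti, (a, b, c) in enumerate(t):
        xa, xb, xc = p[a], p[b], p[c]
        # gradients of barycentric coordinates
        B = np.array([xb - xa, xc - xa]).T  # 2x2
        detB = B[0, 0] * B[1, 1] - B[0, 1] * B[1, 0]
        area = 0.5 * abs(detB)
        if area <= 1e-14:
            raise DomainValidationError(f"degenerate triangle {ti} in assembly")
        Binv = np.array([[B[1, 1], -B[0, 1]], [-B[1, 0], B[0, 0]]]) / detB
        g_ref = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # ref gradients
        grads = g_ref @ Binv  # 3x2 physical gradients
        Kloc = area * grads @ grads.T
        Mloc = area * local_mass
        for ii, vi in enumerate((a, b, c)):
            for jj, vj in enumerate((a, b, c)):
                rows.append(vi)
                cols.append(vj)
                kv.append(Kloc[ii, jj])
                mv.append(Mloc[ii, jj])
    K = sp.coo_matrix((kv, (rows, cols)), shape=(n, n)).tocsr()
    M = sp.coo_matrix((mv, (rows, cols)), shape=(n, n)).tocsr()
    return FemMatrices(stiffness=K, mass=M)


# --------------------------------------------------------------------------
# graphs
# --------------------------------------------------------------------------

@dataclass
class GraphDomain:
    """Weighted undirected graph with its combinatorial Laplacian L = D - W."""

    W: np.ndarray
    region_labels: list[str] | None = None
    L: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise DomainValidationError("W must be square")
        if np.any(W < 0):
            raise DomainValidationError("negative connection weights are not allowed")
        if not np.allclose(W, W.T, rtol=0, atol=1e-12):
            logger.warning("adjacency matrix not symmetric; symmetrizing by (W + W.T)/2")
            W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        self.W = W
        deg = W.sum(axis=1)
        self.L = np.diag(deg) - W
        if self.region_labels is not None and len(self.region_labels) != W.shape[0]:
            raise DomainValidationError("region_labels length mismatch")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return self.W.sum(axis=1)


def build_graph_domain(
    W: np.ndarray,
    region_labels: list[str] | None = None,
    allow_disconnected: bool = False,
) -> GraphDomain:
    """Validate a connectivity matrix and build its graph Laplacian."""
    dom = GraphDomain(W=np.asarray(W, dtype=float), region_labels=region_labels)
    ncomp, _ = csgraph.connected_components(sp.csr_matrix(dom.W), directed=False)
    if ncomp != 1:
        msg = f"graph has {ncomp} connected components"
        if allow_disconnected:
            logger.warning(msg)
        else:
            raise DomainValidationError(msg)
    return dom


def synthetic_connectome(n: int = 68, seed: int = 0, sigma: float = 0.6,
                         sparsity: float = 0.35) -> GraphDomain:
    """Random distance-kernel connectome standing in for a tractography matrix.

    Synthetic: ``n`` pseudo-regions are placed on a unit sphere, connection
    strength decays as a Gaussian in chord distance, and the weakest
    ``sparsity`` fraction of edges is pruned (keeping the graph connected).
    Weights are rescaled so the mean degree is 1, which keeps graph-Laplacian
    eigenvalues O(1) and diffusion rates interpretable per year.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    W = np.exp(-d2 / (2 * sigma**2))
    np.fill_diagonal(W, 0.0)
    thr = np.quantile(W[np.triu_indices(n, 1)], sparsity)
    W = np.where(W >= thr, W, 0.0)
    W = 0.5 * (W + W.T)
    ncomp, labels = csgraph.connected_components(sp.csr_matrix(W), directed=False)
    if ncomp > 1:  # reconnect stragglers to their nearest neighbor
        for comp in range(1, ncomp):
            i = int(np.flatnonzero(labels == comp)[0])
            order = np.argsort(d2[i])
            j = next(int(k) for k in order if labels[k] == 0)
            W[i, j] = W[j, i] = np.exp(-d2[i, j] / (2 * sigma**2))
    W *= n / W.sum()
    return build_graph_domain(W)


# --------------------------------------------------------------------------
# spectral basis
# --------------------------------------------------------------------------

@dataclass
class SpectralBasis:
    """Lowest-P Laplacian eigenpairs of a domain.

    ``vectors[:, i]`` is the nodal representation of the i-th eigenfunction;
    eigenvalues are ascending with ``eigenvalues[0] == 0`` for connected
    domains.  ``mass`` is the inner-product matrix (None means Euclidean).
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    mass: sp.csr_matrix | None = None
    domain_hash: str = ""

    @property
    def P(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    def apply_mass(self, u: np.ndarray) -> np.ndarray:
        return u if self.mass is None else self.mass @ u

    def gram(self) -> np.ndarray:
        """Phi^T M Phi; identity to tolerance for a valid basis."""
        return self.vectors.T @ self.apply_mass(self.vectors)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for i in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, i])))
        if out[j, i] < 0:
            out[:, i] = -out[:, i]
    return out


def _domain_hash(arrays: list[np.ndarray]) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def compute_basis(domain: FemMatrices | GraphDomain, P: int) -> SpectralBasis:
    """Smallest-P Laplacian eigenpairs, mass-orthonormal and sign-fixed.

    Dense solvers are used for small problems; large sparse problems fall
    back to shift-inverted Lanczos.
    """
    if isinstance(domain, GraphDomain):
        n = domain.n
        if P < 1 or P > n:
            raise DomainValidationError(f"P must be in [1, {n}]")
        if n <= 800:
            vals, vecs = scipy.linalg.eigh(domain.L)
            vals, vecs = vals[:P], vecs[:, :P]
        else:
            vals, vecs = _sparse_eig(sp.csr_matrix(domain.L), None, P)
        mass = None
        dh = _domain_hash([domain.W])
    elif isinstance(domain, FemMatrices):
        n = domain.n
        if P < 1 or P > n:
            raise DomainValidationError(f"P must be in [1, {n}]")
        if n <= 1500:
            vals, vecs = scipy.linalg.eigh(
                domain.stiffness.toarray(), domain.mass.toarray()
            )
            vals, vecs = vals[:P], vecs[:, :P]
        else:
            vals, vecs = _sparse_eig(domain.stiffness, domain.mass, P)
        mass = domain.mass
        dh = _domain_hash([domain.stiffness.toarray(), domain.mass.toarray()])
    else:
        raise TypeError(f"unsupported domain type {type(domain)!r}")

    vals = np.where(np.abs(vals) < 1e-10, 0.0, vals)
    order = np.argsort(vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    vecs = _fix_signs(vecs)
    return SpectralBasis(eigenvalues=vals, vectors=vecs, mass=mass, domain_hash=dh)


def _sparse_eig(A: sp.spmatrix, M: sp.spmatrix | None, P: int):
    try:
        vals, vecs = spla.eigsh(A, k=P, M=M, sigma=-1e-3, which="LM")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(
            "sparse eigensolver failed to converge; try a different "
            "shift-invert target or a dense solve"
        ) from exc
    order = np.argsort(vals)
    return vals[order], vecs[:, order]


def save_basis(basis: SpectralBasis, path: str) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("basis")
        g.create_dataset("eigenvalues", data=basis.eigenvalues, track_times=False)
        g.create_dataset("eigenvectors", data=basis.vectors, track_times=False)
        g.attrs["P"] = basis.P
        g.attrs["domain_hash"] = basis.domain_hash
        if basis.mass is not None:
            m = basis.mass.tocoo()
            g.create_dataset("mass_row", data=m.row, track_times=False)
            g.create_dataset("mass_col", data=m.col, track_times=False)
            g.create_dataset("mass_data", data=m.data, track_times=False)


def load_basis(path: str) -> SpectralBasis:
    with h5py.File(path, "r") as fh:
        g = fh["basis"]
        vals = g["eigenvalues"][()]
        vecs = g["eigenvectors"][()]
        dh = g.attrs.get("domain_hash", "")
        mass = None
        if "mass_data" in g:
            n = vecs.shape[0]
            mass = sp.coo_matrix(
                (g["mass_data"][()], (g["mass_row"][()], g["mass_col"][()])),
                shape=(n, n),
            ).tocsr()
    return SpectralBasis(eigenvalues=vals, vectors=vecs, mass=mass, domain_hash=str(dh))
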