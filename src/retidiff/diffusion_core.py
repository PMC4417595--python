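"""Coarse-grained diffusion maps: node pooling, kernel, Markov chain, embedding.

The machinery here turns a (masked) volume into a sparse affinity graph and
embeds it spectrally:

1. voxels are pooled into rectangular blocks, one graph node per block,
   carrying the block's mean intensity as its feature and the block centroid
   as its position (coarse graining shrinks the eigenproblem);
2. a joint Gaussian kernel combines feature and geometric distances,
   truncated to zero beyond a neighbourhood radius ``r`` so the affinity
   matrix stays sparse;
3. degree normalisation turns the kernel into the transition matrix ``P`` of
   a reversible Markov chain, ``P(x, y) = k(x, y) / s(x)`` with
   ``s(x) = sum_y k(x, y)``;
4. the eigenpairs of ``P`` give the diffusion map after ``tau`` steps,
   ``Psi_tau(i) = (lambda_1^tau psi_1(i), ..., lambda_omega^tau psi_omega(i))``,
   where the trivial stationary pair (``lambda = 1``, constant eigenvector)
   is dropped;
5. k-means in the embedding space yields the clustering.

Numerically, the eigenproblem is solved on the symmetric conjugate
``D^{-1/2} K D^{-1/2}``, which shares the spectrum of ``P``; eigenvectors
convert back via ``psi = D^{-1/2} v``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .errors import (
    DegenerateScaleError,
    IsolatedNodeError,
    ValidationError,
)
from .io_volume import Volume

__all__ = [
    "NodeSet",
    "DiffusionConfig",
    "SparseKernel",
    "TransitionMatrix",
    "Embedding",
    "build_nodes",
    "estimate_scale",
    "compute_kernel",
    "markov_normalize",
    "diffusion_embed",
    "cluster_embedding",
]


@dataclass
class NodeSet:
    """Graph nodes obtained by pooling voxels into blocks.

    ``node_map`` assigns each voxel its node index (−1 outside the mask); it
    is the inverse of the node→voxel-block mapping and is used to project
    cluster labels back onto voxels.
    """

    positions: np.ndarray  # (n, 3) voxel-unit centroids
    features: np.ndarray  # (n,) mean intensities
    block_shape: tuple[int, int, int]
    node_map: np.ndarray  # int array, volume-shaped, -1 = unpooled

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.features):
            raise ValidationError("positions and features disagree in length")
        if len(self.features) < 2:
            raise ValidationError("need at least 2 nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.features)

    def node_to_voxels(self, i: int) -> np.ndarray:
        """Return the (m, 3) voxel indices pooled into node ``i``."""
        return np.argwhere(self.node_map == i)


@dataclass
class DiffusionConfig:
    """Parameters of the diffusion-map pipeline.

    ``sigma_feature`` / ``sigma_geo`` may be ``"auto"``, in which case each
    scale is set to 0.15 × the range of the corresponding pairwise distances
    (estimated on a seeded subsample of node pairs when the graph is large).
    ``radius`` may be ``"auto"``: 1.5 × the largest block edge, enough to
    connect neighbouring blocks along every axis.
    """

    sigma_feature: Union[float, str] = "auto"
    sigma_geo: Union[float, str] = "auto"
    radius: Union[float, str] = "auto"
    omega: int = 3
    tau: int = 1
    n_clusters: int = 3
    seed: int = 0
    block_shape: tuple[int, int, int] = (4, 4, 1)
    normalize_embedding: bool = True

    def __post_init__(self) -> None:
        if self.omega < 1:
            raise ValidationError("omega must be >= 1")
        if self.tau < 1:
            raise ValidationError("tau must be >= 1")
        if isinstance(self.radius, (int, float)) and self.radius <= 0:
            raise ValidationError("radius must be > 0")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if any(int(b) < 1 for b in self.block_shape):
            raise ValidationError("block_shape entries must be >= 1")

    def resolved_radius(self) -> float:
        if self.radius == "auto":
            return 1.5 * max(self.block_shape)
        return float(self.radius)


@dataclass
class SparseKernel:
    """Sparse symmetric nonnegative affinity matrix ``k(i, j)``."""

    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1]:
            raise ValidationError("kernel must be square")
        if m.nnz and m.data.min() < 0:
            raise ValidationError("kernel must be nonnegative")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class TransitionMatrix:
    """Row-stochastic Markov matrix ``P`` with node degrees ``s``."""

    P: sp.csr_matrix
    degrees: np.ndarray

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class Embedding:
    """Retained eigenpairs of ``P`` and the diffusion coordinates.

    ``eigenvalues`` are sorted by decreasing magnitude with the stationary
    pair (``lambda = 1``, constant eigenvector) already excluded;
    ``eigenvectors`` holds the matching ``psi_i`` columns.
    """

    eigenvalues: np.ndarray  # (omega,)
    eigenvectors: np.ndarray  # (n, omega)
    tau: int = 1

    @property
    def coordinates(self) -> np.ndarray:
        """Diffusion coordinates ``Psi_tau``, shape ``(n, omega)``."""
        return self.eigenvectors * (self.eigenvalues[None, :] ** self.tau)


# ---------------------------------------------------------------------------
# Node pooling
# ---------------------------------------------------------------------------


def build_nodes(
    volume: Volume,
    block_shape: tuple[int, int, int],
    mask: Optional[np.ndarray] = None,
) -> NodeSet:
    """Pool voxels into rectangular blocks; one graph node per block.

    Each node's feature is the mean intensity of the block's in-mask voxels
    and its position the centroid of those voxels.  Blocks with no in-mask
    voxel produce no node; every in-mask voxel belongs to exactly one node.
    """
    arr = volume.intensities
    nx, ny, nz = arr.shape
    bx, by, bz = (int(b) for b in block_shape)
    if bx > nx or by > ny or bz > nz:
        raise ValidationError(
            f"block_shape {block_shape} exceeds volume shape {arr.shape}"
        )
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise ValidationError("mask shape must match volume shape")
    if not mask.any():
        raise ValidationError("mask selects no voxels")

    gx = -(-nx // bx)  # ceil division: trailing partial blocks are kept
    gy = -(-ny // by)
    gz = -(-nz // bz)

    ix, iy, iz = np.indices(arr.shape, sparse=True)
    block_id = (ix // bx) * (gy * gz) + (iy // by) * gz + (iz // bz)
    block_id = np.broadcast_to(block_id, arr.shape)

    flat_ids = block_id[mask]
    n_blocks = gx * gy * gz
    counts = np.bincount(flat_ids, minlength=n_blocks)
    occupied = np.nonzero(counts)[0]
    remap = np.full(n_blocks, -1, dtype=np.int64)
    remap[occupied] = np.arange(len(occupied))

    feat_sum = np.bincount(flat_ids, weights=arr[mask], minlength=n_blocks)
    xs, ys, zs = np.nonzero(mask)
    pos_sum = np.stack(
        [
            np.bincount(flat_ids, weights=xs, minlength=n_blocks),
            np.bincount(flat_ids, weights=ys, minlength=n_blocks),
            np.bincount(flat_ids, weights=zs, minlength=n_blocks),
        ],
        axis=1,
    )

    cnt = counts[occupied].astype(np.float64)
    features = feat_sum[occupied] / cnt
    positions = pos_sum[occupied] / cnt[:, None]

    node_map = np.full(arr.shape, -1, dtype=np.int64)
    node_map[mask] = remap[flat_ids]

    return NodeSet(
        positions=positions,
        features=features,
        block_shape=(bx, by, bz),
        node_map=node_map,
    )


# ---------------------------------------------------------------------------
# Kernel scale
# ---------------------------------------------------------------------------


def estimate_scale(distances: np.ndarray) -> float:
    """Kernel scale from a pairwise-distance matrix: 0.15 × its range.

    The range is taken over finite off-diagonal entries; a zero range admits
    no scale and raises :class:`DegenerateScaleError`.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distances must be a square matrix")
    off = ~np.eye(d.shape[0], dtype=bool)
    vals = d[off]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("no finite off-diagonal distances")
    rng = float(vals.max() - vals.min())
    if rng == 0.0:
        raise DegenerateScaleError("all pairwise distances equal: zero range")
    return 0.15 * rng


def _scale_from_samples(values: np.ndarray, seed: int, max_pairs: int = 2000) -> float:
    """0.15 × distance range over a seeded subsample of node pairs.

    ``values`` is ``(n, d)``; for small ``n`` all pairs are used, otherwise a
    uniform random sample of ``max_pairs`` pairs.
    """
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    n = values.shape[0]
    n_all_pairs = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    if n_all_pairs <= max_pairs:
        from scipy.spatial.distance import pdist

        d = pdist(values)
    else:
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n, size=max_pairs)
        keep = i != j
        d = np.linalg.norm(values[i[keep]] - values[j[keep]], axis=1)
    dmin, dmax = float(d.min()), float(d.max())
    if dmax == dmin:
        raise DegenerateScaleError("sampled pairwise distances have zero range")
    return 0.15 * (dmax - dmin)


# ---------------------------------------------------------------------------
# Kernel, Markov chain, embedding, clustering
# ---------------------------------------------------------------------------


def compute_kernel(nodes: NodeSet, cfg: DiffusionConfig) -> SparseKernel:
    """Joint feature/geometric Gaussian kernel truncated at radius ``r``.

    ``k(i, j) = exp(-|F_i - F_j|^2 / 2 sigma_f^2) ·
    exp(-|X_i - X_j|^2 / 2 sigma_g^2)`` when the geometric distance is
    strictly below ``r``, else 0; the diagonal is 1.  A node with no
    neighbour within ``r`` is an error (the graph would disconnect it).
    """
    r = cfg.resolved_radius()
    sigma_f = (
        _scale_from_samples(nodes.features[:, None], cfg.seed)
        if cfg.sigma_feature == "auto"
        else float(cfg.sigma_feature)
    )
    sigma_g = (
        _scale_from_samples(nodes.positions, cfg.seed + 1)
        if cfg.sigma_geo == "auto"
        else float(cfg.sigma_geo)
    )
    if sigma_f <= 0 or sigma_g <= 0:
        raise ValidationError("kernel scales must be positive")

    tree = cKDTree(nodes.positions)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        dgeo2 = np.sum((nodes.positions[i] - nodes.positions[j]) ** 2, axis=1)
        strict = dgeo2 < r * r  # query_pairs includes distance == r
        i, j, dgeo2 = i[strict], j[strict], dgeo2[strict]
        dfeat2 = (nodes.features[i] - nodes.features[j]) ** 2
        vals = np.exp(-dfeat2 / (2 * sigma_f**2)) * np.exp(-dgeo2 / (2 * sigma_g**2))
    else:
        i = j = np.array([], dtype=int)
        vals = np.array([])

    n = nodes.n_nodes
    neighbour_count = np.bincount(i, minlength=n) + np.bincount(j, minlength=n)
    if (neighbour_count == 0).any():
        k_bad = int(np.argmin(neighbour_count))
        raise IsolatedNodeError(
            f"node {k_bad} has no neighbour within r={r:g}; increase the radius"
        )

    rows = np.concatenate([i, j, np.arange(n)])
    cols = np.concatenate([j, i, np.arange(n)])
    data = np.concatenate([vals, vals, np.ones(n)])
    k = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return SparseKernel(matrix=k)


def markov_normalize(kernel: SparseKernel) -> TransitionMatrix:
    """Degree-normalise the kernel into a row-stochastic transition matrix.

    ``s(x) = sum_y k(x, y)``; ``P(x, y) = k(x, y) / s(x)``.  Every row of
    ``P`` sums to 1; a zero degree is an error.
    """
    s = np.asarray(kernel.matrix.sum(axis=1)).ravel()
    if (s <= 0).any():
        raise ValidationError("zero row sum: node with no affinity mass")
    P = sp.diags(1.0 / s) @ kernel.matrix
    return TransitionMatrix(P=P.tocsr(), degrees=s)


_DENSE_EIG_THRESHOLD = 600


def diffusion_embed(P: TransitionMatrix, cfg: DiffusionConfig) -> Embedding:
    """Spectral embedding of the Markov chain after ``tau`` time steps.

    Solves the symmetric conjugate eigenproblem ``D^{-1/2} K D^{-1/2} v =
    lambda v`` (same spectrum as ``P``), converts ``psi = D^{-1/2} v``, drops
    the stationary pair and keeps the next ``omega`` pairs by decreasing
    eigenvalue magnitude.
    """
    n = P.n
    omega = cfg.omega
    if omega >= n:
        raise ValidationError(f"omega={omega} must be < n={n}")

    d_isqrt = 1.0 / np.sqrt(P.degrees)
    # M = D^{1/2} P D^{-1/2} = D^{-1/2} K D^{-1/2}
    M = sp.diags(np.sqrt(P.degrees)) @ P.P @ sp.diags(d_isqrt)
    M = (M + M.T) * 0.5  # symmetrise away roundoff

    k_want = min(omega + 1, n - 1)
    if n <= _DENSE_EIG_THRESHOLD or k_want >= n - 1:
        w, v = scipy.linalg.eigh(M.toarray())
    else:
        try:
            # modest tolerance: eigenvalues cluster near 1 on strongly
            # layered graphs and machine-precision ARPACK stalls there;
            # the starting vector is seeded or ARPACK draws it from the
            # global RNG and reruns stop being reproducible
            v0 = np.random.default_rng(cfg.seed).standard_normal(n)
            w, v = sp.linalg.eigsh(
                M, k=k_want, which="LM", tol=1e-7, v0=v0,
                ncv=min(n - 1, max(4 * k_want + 1, 40)),
                maxiter=n * 50,
            )
        except sp.linalg.ArpackNoConvergence as exc:
            raise ValidationError(f"eigen-solver did not converge: {exc}") from exc

    # drop the stationary pair: the single largest (real) eigenvalue
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w, v = w[1:], v[:, 1:]

    # remaining pairs by decreasing magnitude
    order = np.argsort(np.abs(w))[::-1][:omega]
    w, v = w[order], v[:, order]

    if np.abs(w).max(initial=0.0) > 1 + 1e-9:
        raise ValidationError("spectral bound violated: |lambda| > 1")

    psi = v * d_isqrt[:, None]
    # fixed sign convention so reruns are bitwise stable
    signs = np.sign(psi[np.argmax(np.abs(psi), axis=0), np.arange(psi.shape[1])])
    signs[signs == 0] = 1.0
    psi = psi * signs[None, :]
    return Embedding(eigenvalues=w, eigenvectors=psi, tau=cfg.tau)


def cluster_embedding(
    embedding: Embedding, n_clusters: int, seed: int, normalize_rows: bool = True
) -> np.ndarray:
    """k-means partition of the diffusion coordinates; deterministic per seed.

    By default each node's coordinate vector is projected onto the unit
    sphere first (as in Ng–Jordan–Weiss spectral clustering): per-node
    embedding mass varies with node degree, and without the projection
    k-means spends clusters on a few high-norm nodes instead of separating
    the tight, near-origin groups.
    """
    coords = embedding.coordinates
    n = coords.shape[0]
    if n_clusters > n:
        raise ValidationError(f"n_clusters={n_clusters} exceeds n={n}")
    if n_clusters == 1:
        return np.zeros(n, dtype=int)
    if normalize_rows and coords.shape[1] >= 2:
        # the sphere projection is information-destroying for scalar
        # coordinates (everything maps to ±1), so 1-D embeddings stay raw
        norms = np.linalg.norm(coords, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        coords = coords / norms
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(coords)
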