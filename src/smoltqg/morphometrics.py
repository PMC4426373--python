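"""Geometric morphometrics of 13-landmark body shapes.

Pipeline: generalized Procrustes superimposition (translation, unit
centroid-size scaling, optimal rotation to an iterated consensus), thin
plate spline partial-warp scores (non-uniform principal warps plus the
two-dimensional uniform/affine component, 2k-4 scores per fish for k
landmarks), and relative warps — the principal components of the
partial-warp scores (weight alpha = 0), reported x1000 with percent
variance explained.  For the study's k = 13 landmarks this yields the 22
relative warps used as shape traits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np


@dataclass
class LandmarkSet:
    """One fish's ordered 2D landmark configuration."""

    individual_id: str
    coordinates: np.ndarray  # (k, 2)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be (k, 2)")


@dataclass
class ShapeDecomposition:
    """GPA consensus, aligned shapes, and warp scores for a sample."""

    ids: list
    consensus: np.ndarray            # (k, 2), centred, unit centroid size
    aligned: np.ndarray              # (n, k, 2)
    centroid_size: np.ndarray        # (n,)
    partial_warp_scores: np.ndarray = None   # (n, 2k-4)
    relative_warp_scores: np.ndarray = None  # (n, 2k-4), x1000
    pve: np.ndarray = None                   # percent variance per warp
    warp_labels: list = None

    @property
    def k(self) -> int:
        return self.consensus.shape[0]


def centroid_size(coords) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    X = np.asarray(coords, dtype=float)
    c = X.mean(axis=0)
    cs = float(np.sqrt(((X - c) ** 2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _align_to(X, ref):
    """Optimal rotation of centred unit-size X onto ref (ordinary Procrustes)."""
    U, _, Vt = np.linalg.svd(X.T @ ref)
    R = U @ Vt
    if np.linalg.det(R) < 0:  # no reflections
        U[:, -1] *= -1
        R = U @ Vt
    return X @ R


def generalized_procrustes(
    shapes, tol: float = 1e-10, max_iter: int = 100
) -> ShapeDecomposition:
    """Generalized least-squares Procrustes superimposition.

    Each configuration is centred, scaled to unit centroid size, and
    rotated to the iteratively updated consensus; iteration stops when the
    consensus moves less than ``tol`` (RMS).
    """
    shapes = list(shapes)
    if len(shapes) < 2:
        raise ValueError("GPA needs at least two configurations")
    ks = {s.coordinates.shape[0] for s in shapes}
    if len(ks) != 1:
        raise ValueError("all configurations must share the landmark count")
    ids = [s.individual_id for s in shapes]
    cs = np.array([centroid_size(s.coordinates) for s in shapes])
    X = np.stack(
        [
            (s.coordinates - s.coordinates.mean(axis=0)) / c
            for s, c in zip(shapes, cs)
        ]
    )
    consensus = X[0].copy()
    for _ in range(max_iter):
        X = np.stack([_align_to(x, consensus) for x in X])
        new = X.mean(axis=0)
        new -= new.mean(axis=0)
        new /= np.sqrt((new**2).sum())
        if np.sqrt(((new - consensus) ** 2).mean()) < tol:
            consensus = new
            break
        consensus = new
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (tol={tol})"
        )
    X = np.stack([_align_to(x, consensus) for x in X])
    return ShapeDecomposition(
        ids=ids, consensus=consensus, aligned=X, centroid_size=cs
    )


def _bending_energy(consensus: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix of the consensus (k x k)."""
    k = consensus.shape[0]
    d2 = ((consensus[:, None, :] - consensus[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.column_stack([np.ones(k), consensus])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as e:  # collinear consensus
        raise ValueError("singular bending-energy computation") from e
    return Linv[:k, :k]


def tangent_basis(consensus: np.ndarray):
    """Orthonormal partial-warp basis of the shape tangent space.

    Returns ``(B, n_uniform)`` where ``B`` is (2k, 2k-4): the first
    2(k-3) columns are the non-uniform principal-warp directions (x then y
    copies of each bending-energy eigenvector, ordered by decreasing
    bending energy) and the last two columns span the uniform (affine)
    component, obtained as the orthogonal complement of the similarity +
    non-uniform space.
    """
    k = consensus.shape[0]
    Be = _bending_energy(consensus)
    evals, evecs = np.linalg.eigh(Be)
    keep = evals > 1e-10 * evals.max()
    if keep.sum() != k - 3:
        raise ValueError("singular bending-energy computation (collinear consensus)")
    # order principal warps by decreasing bending energy
    order = np.argsort(evals[keep])[::-1]
    pw = evecs[:, keep][:, order]  # (k, k-3), orthonormal, _|_ {1, x, y}
    nonuni = np.zeros((2 * k, 2 * (k - 3)))
    for m in range(k - 3):
        nonuni[0::2, 2 * m] = pw[:, m]   # x-copy
        nonuni[1::2, 2 * m + 1] = pw[:, m]  # y-copy
    # similarity space: translations, scale, rotation at the consensus
    sim = np.zeros((2 * k, 4))
    sim[0::2, 0] = 1.0
    sim[1::2, 1] = 1.0
    sim[0::2, 2] = consensus[:, 0]
    sim[1::2, 2] = consensus[:, 1]
    sim[0::2, 3] = -consensus[:, 1]
    sim[1::2, 3] = consensus[:, 0]
    span = np.hstack([sim, nonuni])
    # uniform component = orthogonal complement of span within R^{2k}
    U, s, _ = np.linalg.svd(span, full_matrices=True)
    null = U[:, span.shape[1]:]
    assert null.shape[1] == 2
    B = np.hstack([nonuni, null])
    return B, 2


def partial_warps(dec: ShapeDecomposition) -> ShapeDecomposition:
    """Project aligned deviations from the consensus onto the warp basis.

    Fills ``partial_warp_scores`` with 2k-4 scores per individual: the
    non-uniform principal-warp scores plus the two uniform scores.
    """
    B, _ = tangent_basis(dec.consensus)
    dev = (dec.aligned - dec.consensus).reshape(len(dec.ids), -1)
    dec.partial_warp_scores = dev @ B
    return dec


def relative_warps(dec: ShapeDecomposition, scale: float = 1000.0) -> ShapeDecomposition:
    """Relative warps: PCA of partial-warp scores (alpha = 0).

    Scores are multiplied by ``scale`` (the study convention is x1000);
    per-axis percent variance explained sums to 100.  Axis signs are fixed
    so the largest-magnitude loading is positive (the original signs are
    arbitrary).
    """
    S = dec.partial_warp_scores
    if S is None:
        dec = partial_warps(dec)
        S = dec.partial_warp_scores
    n = S.shape[0]
    if n < 2:
        raise ValueError("relative warps need at least two individuals")
    C = S - S.mean(axis=0)
    U, sv, Vt = np.linalg.svd(C, full_matrices=False)
    # keep all 2k-4 axes even when n-1 < 2k-4 (trailing axes are zero)
    p = S.shape[1]
    scores = np.zeros((n, p))
    var = np.zeros(p)
    m = min(n - 1, p, len(sv))
    axes = Vt[:m]
    for a in range(m):
        j = np.argmax(np.abs(axes[a]))
        if axes[a, j] < 0:
            axes[a] = -axes[a]
    scores[:, :m] = C @ axes.T
    var[:m] = (sv[:m] ** 2) / n
    total = var.sum()
    pve = 100.0 * var / total if total > 0 else np.full(p, np.nan)
    dec.relative_warp_scores = scores * scale
    dec.pve = pve
    dec.warp_labels = [f"RelW{i + 1}" for i in range(p)]
    return dec


def exclude_warps(dec: ShapeDecomposition, indices) -> tuple[np.ndarray, list]:
    """Drop named relative warps (1-based labels) from downstream tables.

    Retained warps keep their original labels (RelW2 stays RelW2 when
    RelW1 — the anesthesia-artifact axis in the study — is excluded).
    Returns ``(scores, labels)``.
    """
    if dec.relative_warp_scores is None:
        raise ValueError("run relative_warps first")
    p = dec.relative_warp_scores.shape[1]
    idx = sorted(set(int(i) for i in indices))
    for i in idx:
        if not 1 <= i <= p:
            raise IndexError(f"warp index {i} out of range 1..{p}")
    keep = [j for j in range(p) if (j + 1) not in idx]
    if not keep:
        raise ValueError("cannot exclude all warps: no shape variables remain")
    return dec.relative_warp_scores[:, keep], [dec.warp_labels[j] for j in keep]


def decompose_shapes(shapes, exclude=()) -> ShapeDecomposition:
    """Full pipeline: GPA -> partial warps -> relative warps."""
    dec = generalized_procrustes(shapes)
    dec = partial_warps(dec)
    dec = relative_warps(dec)
    if exclude:
        exclude_warps(dec, exclude)  # validates; callers slice as needed
    return dec


# ---------------------------------------------------------------------------
# TPS landmark dialect


def read_tps(path) -> list[LandmarkSet]:
    """Read a TPS landmark file (LM=, coordinate lines, ID=, optional SCALE=)."""
    shapes = []
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln.strip() for ln in text.replace("\r\n", "\n").split("\n")]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if not ln:
            i += 1
            continue
        m = re.match(r"^LM\s*=\s*(\d+)$", ln, re.IGNORECASE)
        if not m:
            raise ValueError(f"expected LM= record at line {i + 1}, got {ln!r}")
        k = int(m.group(1))
        coords = []
        i += 1
        while len(coords) < k:
            if i >= len(lines):
                raise ValueError("truncated TPS record")
            if lines[i]:
                x, y = lines[i].split()
                coords.append((float(x), float(y)))
            i += 1
        iid, scale = None, None
        while i < len(lines) and lines[i] and not lines[i].upper().startswith("LM"):
            key, _, val = lines[i].partition("=")
            if key.strip().upper() == "ID":
                iid = val.strip()
            elif key.strip().upper() == "SCALE":
                scale = float(val)
            i += 1
        coords = np.array(coords)
        if scale is not None:
            coords = coords * scale
        shapes.append(LandmarkSet(individual_id=iid or f"shape{len(shapes)}", coordinates=coords))
    return shapes


def write_tps(shapes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in shapes:
            fh.write(f"LM={s.coordinates.shape[0]}\n")
            for x, y in s.coordinates:
                fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"ID={s.individual_id}\n")
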