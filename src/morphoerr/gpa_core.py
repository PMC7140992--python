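"""Generalized Procrustes superimposition and basic shape geometry.

Configurations are translated to the origin, scaled to unit centroid size,
and iteratively rotated (generalized least squares) onto a running consensus
until the consensus stabilises.  Rotations are proper (determinant +1) by
default; reflections can be allowed explicitly.  No tangent-space projection
is applied by default — downstream statistics run on the Procrustes-aligned
coordinates, with :func:`tangent_project` available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .landmark_io import LandmarkConfiguration, LandmarkDataset

__all__ = [
    "centroid_size",
    "opa_align",
    "OpaResult",
    "gpa",
    "AlignedDataset",
    "procrustes_distance",
    "procrustes_variance",
    "tangent_project",
    "GpaConvergenceWarning",
]


class GpaConvergenceWarning(UserWarning):
    """Raised (as a warning) when GPA hits max_iter without converging."""


def centroid_size(config) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _center_and_scale(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    size = np.sqrt((centered**2).sum())
    if size == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return centered / size


class OpaResult(NamedTuple):
    aligned: np.ndarray
    rotation: np.ndarray
    distance: float


def opa_align(target, reference, allow_reflection: bool = False) -> OpaResult:
    """Optimally rotate ``target`` onto ``reference`` (ordinary Procrustes).

    Both shapes are expected centered and unit-size with the same landmark
    count.  The rotation minimising the summed squared landmark distances is
    obtained from the SVD of the cross-product matrix; the returned distance
    is the root summed squared difference after alignment.
    """
    target = np.asarray(target, float)
    reference = np.asarray(reference, float)
    if target.shape != reference.shape:
        raise ValueError(f"shape mismatch: {target.shape} vs {reference.shape}")
    rotation = _optimal_rotations(target[None], reference, allow_reflection)[0]
    aligned = target @ rotation
    distance = float(np.linalg.norm(aligned - reference))
    return OpaResult(aligned, rotation, distance)


def _optimal_rotations(shapes: np.ndarray, reference: np.ndarray,
                       allow_reflection: bool) -> np.ndarray:
    """Batched optimal rotation of each ``shapes[i]`` onto ``reference``."""
    m = np.einsum("nkj,kl->njl", shapes, reference)  # (n, 2, 2) cross-products
    u, _, vt = np.linalg.svd(m)
    rot = u @ vt
    if not allow_reflection:
        neg = np.linalg.det(rot) < 0
        if np.any(neg):
            u = u.copy()
            u[neg, :, -1] *= -1.0
            rot = u @ vt
    return rot


@dataclass
class AlignedDataset:
    """GPA output: unit-size shapes centered at the origin plus consensus."""

    shapes: np.ndarray            # (n, k, 2)
    consensus: np.ndarray         # (k, 2), unit centroid size
    iterations: int
    converged: bool
    specimen_ids: list[str] | None = None
    species: list[str] | None = None
    ss_history: list[float] = field(default_factory=list, repr=False)

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    def flat(self) -> np.ndarray:
        """Shapes flattened to an ``(n, 2k)`` coordinate matrix."""
        return self.shapes.reshape(self.n, -1)


def gpa(data, tol: float = 1e-8, max_iter: int = 100,
        allow_reflection: bool = False) -> AlignedDataset:
    """Generalized Procrustes analysis of a landmark dataset.

    Parameters
    ----------
    data
        A :class:`LandmarkDataset` or an ``(n, k, 2)`` array.
    tol
        Convergence threshold on the Procrustes distance between successive
        consensus shapes.
    max_iter
        Iteration cap; non-convergence is flagged (``converged=False``) with
        a :class:`GpaConvergenceWarning`, not an exception.

    The first configuration (after centering/scaling) initialises the
    consensus, making the result deterministic for a given input order.  The
    consensus is rescaled to unit centroid size after each update to fix the
    scale gauge.
    """
    ids = species = None
    if isinstance(data, LandmarkDataset):
        ids = data.specimen_ids
        species = data.species
        arr = data.coords_array()
    else:
        arr = np.asarray(data, float)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError(f"expected (n, k, 2) coordinates, got {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("GPA needs at least 2 configurations")

    shapes = np.stack([_center_and_scale(s) for s in arr])
    consensus = shapes[0].copy()
    converged = False
    iterations = 0
    ss_history: list[float] = []
    for iterations in range(1, max_iter + 1):
        rot = _optimal_rotations(shapes, consensus, allow_reflection)
        shapes = np.einsum("nkj,njl->nkl", shapes, rot)
        mean = shapes.mean(axis=0)
        ss_history.append(float(((shapes - mean) ** 2).sum()))
        new_consensus = mean / np.sqrt((mean**2).sum())
        delta = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last delta above tol)",
            GpaConvergenceWarning,
        )
    return AlignedDataset(shapes=shapes, consensus=consensus, iterations=iterations,
                          converged=converged, specimen_ids=ids, species=species,
                          ss_history=ss_history)


def procrustes_distance(a, b) -> float:
    """Root summed squared inter-landmark distance between aligned shapes."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def procrustes_variance(aligned: AlignedDataset) -> float:
    """Mean squared Procrustes distance of the aligned shapes to the consensus."""
    dev = aligned.shapes - aligned.consensus
    return float((dev**2).sum() / aligned.n)


def tangent_project(aligned: AlignedDataset) -> np.ndarray:
    """Orthogonally project aligned shapes onto the tangent space at the consensus.

    Removes the component of each shape along the (unit) consensus direction,
    then restores the consensus, returning an ``(n, 2k)`` matrix.  For small
    shape variation this is numerically close to the raw aligned coordinates.
    """
    c = aligned.consensus.reshape(-1)
    x = aligned.flat()
    coeff = x @ c  # consensus has unit norm
    return x - np.outer(coeff - 1.0, c)
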