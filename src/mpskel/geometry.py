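"""Neurite traces and arc-length projection.

A neurite is represented by a polyline (:class:`NeuriteTrace`).  Every 1D
analysis in this package — density profiles, autocorrelation, Fourier period
detection — lives in the trace's arc-length coordinate ``s`` (nm), obtained by
projecting each localization onto its nearest point on the polyline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["NeuriteTrace", "make_trace", "project_onto_trace", "ProjectionResult"]


@dataclass(frozen=True)
class NeuriteTrace:
    """Polyline neurite axis with arc-length parameterization.

    Parameters
    ----------
    vertices
        ``(n, 3)`` array of x/y/z coordinates in nm, ordered proximal to
        distal.  At least two vertices; consecutive vertices must be distinct.
    """

    vertices: np.ndarray
    arc_length: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
            raise InvalidArgumentError("trace needs an (n>=2, 3) vertex array")
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("trace vertices must be finite")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg <= 0):
            raise InvalidArgumentError("consecutive trace vertices must be distinct")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "arc_length", np.concatenate([[0.0], np.cumsum(seg)]))

    @property
    def length_nm(self) -> float:
        """Total arc length of the polyline in nm."""
        return float(self.arc_length[-1])

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def point_at(self, s: np.ndarray | float) -> np.ndarray:
        """Interpolate 3D position(s) at arc-length coordinate(s) ``s`` (nm)."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length_nm)
        idx = np.clip(np.searchsorted(self.arc_length, s, side="right") - 1, 0,
                      self.n_vertices - 2)
        s0 = self.arc_length[idx]
        seg_len = self.arc_length[idx + 1] - s0
        frac = (s - s0) / seg_len
        return self.vertices[idx] + frac[:, None] * (self.vertices[idx + 1] - self.vertices[idx])

    def frames_at(self, s: np.ndarray | float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Tangent and two transported normals at arc-length ``s``.

        The normal pair is parallel-transported along the polyline (a discrete
        Bishop frame), so it varies smoothly and does not flip on straight
        runs.  Used to place ring localizations in the plane normal to the
        axis.
        """
        t, n1, n2 = _vertex_frames(self.vertices)
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length_nm)
        idx = np.clip(np.searchsorted(self.arc_length, s, side="right") - 1, 0,
                      self.n_vertices - 2)
        return t[idx], n1[idx], n2[idx]


def _vertex_frames(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment unit tangents plus parallel-transported normal pairs."""
    tangents = np.diff(vertices, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n_seg = tangents.shape[0]
    n1 = np.empty_like(tangents)
    n2 = np.empty_like(tangents)
    # seed frame: any unit vector not parallel to the first tangent
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, tangents[0])) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    n1[0] = ref - np.dot(ref, tangents[0]) * tangents[0]
    n1[0] /= np.linalg.norm(n1[0])
    n2[0] = np.cross(tangents[0], n1[0])
    for i in range(1, n_seg):
        axis = np.cross(tangents[i - 1], tangents[i])
        sin_a = np.linalg.norm(axis)
        cos_a = float(np.dot(tangents[i - 1], tangents[i]))
        if sin_a < 1e-12:
            n1[i], n2[i] = n1[i - 1], n2[i - 1]
            continue
        axis = axis / sin_a
        n1[i] = _rotate(n1[i - 1], axis, cos_a, sin_a)
        n2[i] = np.cross(tangents[i], n1[i])
    return tangents, n1, n2


def _rotate(v: np.ndarray, axis: np.ndarray, cos_a: float, sin_a: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis``."""
    return (v * cos_a + np.cross(axis, v) * sin_a
            + axis * np.dot(axis, v) * (1.0 - cos_a))


def make_trace(
    length_um: float,
    curvature: float = 0.0,
    seed: int | None = None,
    *,
    step_nm: float = 100.0,
    wobble_deg_per_um: float = 0.0,
) -> NeuriteTrace:
    """Construct a planar neurite trace of a given arc length.

    Parameters
    ----------
    length_um
        Total arc length in µm (> 0).
    curvature
        Constant curvature in rad/µm; 0 gives a straight segment along +x
        starting at the origin.
    seed
        Seeds the optional heading wobble; ignored when ``wobble_deg_per_um``
        is 0 so default traces are fully deterministic.
    step_nm
        Vertex spacing; every chord has exactly this length, so the polyline
        arc length equals ``length_um`` exactly (up to one shorter final step).
    wobble_deg_per_um
        Standard deviation of a random-walk perturbation of the heading, per
        µm of arc — a crude model of meandering neurites.
    """
    if not length_um > 0:
        raise InvalidArgumentError(f"length_um must be positive, got {length_um}")
    if step_nm <= 0:
        raise InvalidArgumentError("step_nm must be positive")
    length_nm = length_um * 1000.0
    n_full = int(length_nm // step_nm)
    steps = np.full(n_full, step_nm)
    rem = length_nm - n_full * step_nm
    if rem > 1e-9:
        steps = np.append(steps, rem)
    mid_s_um = (np.cumsum(steps) - steps / 2.0) / 1000.0  # midpoint arc length, µm
    theta = curvature * mid_s_um
    if wobble_deg_per_um > 0:
        rng = np.random.default_rng(seed)
        incr = rng.normal(0.0, np.deg2rad(wobble_deg_per_um), size=steps.size)
        theta = theta + np.cumsum(incr * steps / 1000.0)
    dxy = np.column_stack([np.cos(theta), np.sin(theta)]) * steps[:, None]
    xy = np.vstack([[0.0, 0.0], np.cumsum(dxy, axis=0)])
    vertices = np.column_stack([xy, np.zeros(xy.shape[0])])
    return NeuriteTrace(vertices)


@dataclass(frozen=True)
class ProjectionResult:
    """Arc-length projection of localizations onto a trace.

    ``s_nm``/``lateral_nm`` cover only the kept localizations; ``kept_index``
    maps them back to rows of the input table. ``n_total = len(kept) +
    n_excluded`` always holds.
    """

    s_nm: np.ndarray
    lateral_nm: np.ndarray
    kept_index: np.ndarray
    n_total: int
    n_excluded: int


def project_onto_trace(locs, trace: NeuriteTrace, max_lateral_nm: float = 400.0) -> ProjectionResult:
    """Assign each localization the arc length of its nearest polyline point.

    Localizations farther than ``max_lateral_nm`` from the axis are excluded
    (background rejection).  ``locs`` may be a LocalizationTable or an (n, 3)
    coordinate array.
    """
    if not max_lateral_nm > 0:
        raise InvalidArgumentError("max_lateral_nm must be positive")
    pts = np.asarray(getattr(locs, "xyz", locs), dtype=float)
    if pts.size == 0:
        empty = np.empty(0)
        return ProjectionResult(empty, empty, np.empty(0, dtype=int), 0, 0)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError("expected an (n, 3) coordinate array")
    a = trace.vertices[:-1]
    d = np.diff(trace.vertices, axis=0)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    best_d2 = np.full(pts.shape[0], np.inf)
    best_s = np.zeros(pts.shape[0])
    # loop over segments (few hundred), vectorized over localizations
    for i in range(a.shape[0]):
        w = pts - a[i]
        t = np.clip(w @ d[i] / seg_len2[i], 0.0, 1.0)
        diff = w - t[:, None] * d[i]
        d2 = np.einsum("ij,ij->i", diff, diff)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_s[closer] = trace.arc_length[i] + t[closer] * np.sqrt(seg_len2[i])
    lateral = np.sqrt(best_d2)
    keep = lateral <= max_lateral_nm
    return ProjectionResult(
        s_nm=best_s[keep],
        lateral_nm=lateral[keep],
        kept_index=np.flatnonzero(keep),
        n_total=pts.shape[0],
        n_excluded=int(np.sum(~keep)),
    )
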