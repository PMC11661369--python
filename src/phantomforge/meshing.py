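"""Watertight prism meshes for slab phantoms with vertical inclusions.

All phantom geometries in this package are vertical prisms: an outer slab
whose cross-section may carry polygonal holes over sub-ranges of z (the
inclusion voids), and the inclusions themselves (boxes and cylinders).
This module triangulates polygons-with-holes by hole bridging plus ear
clipping and assembles closed, consistently oriented surface meshes, with
STL output in binary or ASCII form.

Triangle soups are ``float`` arrays of shape (n, 3, 3); outward normals
follow counter-clockwise winding.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, Polygon

from phantomforge.errors import MeshingError

__all__ = [
    "circle_ring",
    "rect_ring",
    "triangulate_polygon",
    "prism_mesh",
    "mesh_volume",
    "is_watertight",
    "write_stl",
]

_EPS = 1e-12


def circle_ring(center: tuple[float, float], diameter: float, n: int = 64) -> np.ndarray:
    """CCW polygonal approximation of a circle."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + 0.5 * diameter * np.cos(t), center[1] + 0.5 * diameter * np.sin(t)]
    )


def rect_ring(origin: tuple[float, float], size: tuple[float, float]) -> np.ndarray:
    """CCW rectangle from min-corner and (width, height)."""
    x0, y0 = origin
    w, h = size
    return np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h]], float)


def _signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _ensure_ccw(ring: np.ndarray) -> np.ndarray:
    return ring if _signed_area(ring) > 0 else ring[::-1]


def _segments_properly_cross(p, q, u, v) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p, q, u), orient(p, q, v)
    d3, d4 = orient(u, v, p), orient(u, v, q)
    return (d1 * d2 < -_EPS) and (d3 * d4 < -_EPS)


def _merge_hole(outer: list[np.ndarray], hole: np.ndarray, shape: Polygon) -> list[np.ndarray]:
    """Bridge one hole into the outer boundary, producing a simple polygon.

    The bridge must lie inside the polygon-with-holes AND avoid crossing
    edges of the already-merged boundary (which includes earlier bridges
    that the shapely cover test knows nothing about).
    """
    hole_cw = hole[::-1]  # traversed clockwise inside a CCW outer
    hi = int(np.argmax(hole_cw[:, 0]))
    hv = hole_cw[hi]

    def _orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    def _in_wedge(prev_v, v, next_v, target) -> bool:
        # does the ray v -> target point into the polygon interior at this
        # boundary instance?  (CCW boundary: interior on the left)
        if _orient(prev_v, v, next_v) >= -_EPS:  # convex corner
            return (
                _orient(prev_v, v, target) > _EPS
                and _orient(v, next_v, target) > _EPS
            )
        return (
            _orient(prev_v, v, target) > _EPS
            or _orient(v, next_v, target) > _EPS
        )

    order = np.argsort([np.hypot(p[0] - hv[0], p[1] - hv[1]) for p in outer])
    n = len(outer)
    for oi in order:
        ov = outer[oi]
        # the bridge must leave through this instance's interior wedge —
        # duplicated bridge anchors otherwise tangle the merged boundary
        if not _in_wedge(outer[(oi - 1) % n], ov, outer[(oi + 1) % n], hv):
            continue
        bridge = LineString([tuple(hv), tuple(ov)])
        if not shape.covers(bridge):
            continue
        crossing = False
        for j in range(n):
            u, v = outer[j], outer[(j + 1) % n]
            if _segments_properly_cross(hv, ov, u, v):
                crossing = True
                break
        if crossing:
            continue
        rolled = np.roll(hole_cw, -hi, axis=0)
        merged = (
            outer[: oi + 1]
            + [p for p in rolled]
            + [rolled[0]]
            + outer[oi:]
        )
        return merged
    raise MeshingError("could not bridge hole into outer boundary")


def _strictly_in_triangle(pts: np.ndarray, a, b, c) -> np.ndarray:
    d1 = (pts[:, 0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (pts[:, 1] - b[1])
    d2 = (pts[:, 0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (pts[:, 1] - c[1])
    d3 = (pts[:, 0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (pts[:, 1] - a[1])
    return ((d1 < -_EPS) & (d2 < -_EPS) & (d3 < -_EPS)) | (
        (d1 > _EPS) & (d2 > _EPS) & (d3 > _EPS)
    )


def _interior_of_segment(pts: np.ndarray, a, c) -> np.ndarray:
    """Points lying strictly inside segment a-c (collinear, between endpoints)."""
    ac = np.asarray(c) - np.asarray(a)
    ap = pts - np.asarray(a)
    cross = np.abs(ap[:, 0] * ac[1] - ap[:, 1] * ac[0])
    norm2 = float(ac[0] ** 2 + ac[1] ** 2)
    t = (ap[:, 0] * ac[0] + ap[:, 1] * ac[1]) / norm2
    tol = 1e-9 * max(np.sqrt(norm2), 1.0)
    return (cross <= tol) & (t > 1e-9) & (t < 1.0 - 1e-9)


def _ear_clip(poly: list[np.ndarray]) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    pts = [np.asarray(p, float) for p in poly]
    all_pts = np.array(pts)
    idx = list(range(len(pts)))
    tris: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    def _splits(u: np.ndarray, v: np.ndarray) -> list[np.ndarray]:
        inside = all_pts[_interior_of_segment(all_pts, u, v)]
        if not len(inside):
            return []
        uniq = np.unique(np.round(inside, 9), axis=0)
        uv = v - u
        t = (uniq - u) @ uv / float(uv @ uv)
        return [uniq[j] for j in np.argsort(t)]

    def _emit(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> None:
        # Every triangle edge is subdivided at original vertices lying in
        # its interior, so both sides of any collinear seam produce the
        # same primitive edges and the final surface stays edge-manifold.
        sab, sbc, sca = _splits(a, b), _splits(b, c), _splits(c, a)
        if not (sab or sbc or sca):
            tris.append((a, b, c))
            return
        # fan from a corner whose adjacent edges carry no splits; if none
        # exists, fan from the centroid (a Steiner point off every edge)
        corners = [a, b, c]
        chains = [sab, sbc, sca]  # edge i runs corner i -> corner (i+1)%3
        apex = None
        for i in range(3):
            if not chains[i] and not chains[(i + 2) % 3]:
                apex = i
                break
        loop: list[np.ndarray] = []
        for i in range(3):
            loop.append(corners[i])
            loop.extend(chains[i])
        if apex is not None:
            j = next(k for k, p in enumerate(loop) if p is corners[apex])
            ordered = loop[j:] + loop[:j]
            for i in range(1, len(ordered) - 1):
                tris.append((ordered[0], ordered[i], ordered[i + 1]))
        else:
            g = (a + b + c) / 3.0
            for p, q in zip(loop, loop[1:] + [loop[0]]):
                tris.append((g, p, q))

    while len(idx) > 3:
        n = len(idx)
        clipped = False
        for k in range(n):
            i0, i1, i2 = idx[(k - 1) % n], idx[k], idx[(k + 1) % n]
            a, b, c = pts[i0], pts[i1], pts[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if abs(cross) <= _EPS:
                # Degenerate corner.  A spike (a == c) or a vertex lying
                # between its neighbors may be dropped — subdivision at
                # original vertices keeps both sides of the merged edge
                # paired.  A backtracking corner (doubled bridge edge) must
                # be preserved or the polygon's topology would be cut.
                ac = c - a
                denom = float(ac @ ac)
                if denom <= _EPS:
                    del idx[k]  # spike
                    clipped = True
                    break
                t = float((b - a) @ ac) / denom
                if 0.0 <= t <= 1.0:
                    del idx[k]  # collinear, strictly between neighbors
                    clipped = True
                    break
                continue
            if cross < 0:
                continue  # reflex corner
            # an original vertex (clipped or not) strictly inside blocks the ear
            corner = (
                np.all(np.isclose(all_pts, a), axis=1)
                | np.all(np.isclose(all_pts, b), axis=1)
                | np.all(np.isclose(all_pts, c), axis=1)
            )
            others = all_pts[~corner]
            if others.size and np.any(_strictly_in_triangle(others, a, b, c)):
                continue
            _emit(a, b, c)
            del idx[k]
            clipped = True
            break
        if not clipped:
            raise MeshingError("ear clipping stalled on a degenerate polygon")
    if len(idx) == 3:
        a, b, c = (pts[i] for i in idx)
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(cross) > _EPS:
            _emit(a, b, c)
    return tris


def triangulate_polygon(
    outer: np.ndarray, holes: list[np.ndarray] | None = None
) -> np.ndarray:
    """Triangulate a CCW polygon with disjoint CCW holes.

    Returns an (n, 3, 2) array of CCW triangles covering outer minus holes.
    """
    outer = _ensure_ccw(np.asarray(outer, float))
    holes = [_ensure_ccw(np.asarray(h, float)) for h in (holes or [])]
    shape = Polygon(outer, [h[::-1] for h in holes])
    if not shape.is_valid:
        raise MeshingError("invalid polygon (overlapping or touching holes?)")
    poly = [p for p in outer]
    # bridge holes right-to-left so earlier bridges cannot block later ones
    for hole in sorted(holes, key=lambda h: -float(h[:, 0].max())):
        poly = _merge_hole(poly, hole, shape)
    tris = _ear_clip(poly)
    if not tris:
        raise MeshingError("triangulation produced no triangles")
    arr = np.array(tris)
    got = float(np.sum(np.abs([_signed_area(t) for t in arr])))
    want = shape.area
    if abs(got - want) > 1e-6 * max(want, 1.0):
        raise MeshingError(
            f"triangulation area mismatch: {got:.6f} vs polygon {want:.6f}"
        )
    return arr


def _cap(tris2d: np.ndarray, z: float, up: bool) -> np.ndarray:
    n = len(tris2d)
    out = np.empty((n, 3, 3))
    order = tris2d if up else tris2d[:, ::-1, :]
    out[:, :, :2] = order
    out[:, :, 2] = z
    return out


def _walls(ring: np.ndarray, z0: float, z1: float, outward: bool) -> np.ndarray:
    """Extrude a ring into side-wall triangles between two heights."""
    ring = np.asarray(ring, float)
    p = ring
    q = np.roll(ring, -1, axis=0)
    n = len(ring)
    tris = np.empty((2 * n, 3, 3))
    for i in range(n):
        a = (*p[i], z0)
        b = (*q[i], z0)
        c = (*q[i], z1)
        d = (*p[i], z1)
        if outward:
            tris[2 * i] = (a, b, c)
            tris[2 * i + 1] = (a, c, d)
        else:
            tris[2 * i] = (a, c, b)
            tris[2 * i + 1] = (a, d, c)
    return tris


def prism_mesh(
    outer: np.ndarray,
    z_breaks: list[float],
    holes_per_interval: list[list[np.ndarray]] | None = None,
) -> np.ndarray:
    """Closed mesh of a vertical prism whose holes vary between z-intervals.

    ``z_breaks`` has one more entry than intervals; ``holes_per_interval[i]``
    lists the CCW hole rings present between ``z_breaks[i]`` and
    ``z_breaks[i+1]``.  Hole rings must be identical arrays wherever the same
    hole spans several intervals, so internal caps pair up exactly.
    """
    outer = _ensure_ccw(np.asarray(outer, float))
    n_int = len(z_breaks) - 1
    if n_int < 1:
        raise ValueError("need at least one z interval")
    holes_per_interval = holes_per_interval or [[] for _ in range(n_int)]
    if len(holes_per_interval) != n_int:
        raise ValueError("holes_per_interval length must match intervals")
    holes_per_interval = [
        [_ensure_ccw(np.asarray(h, float)) for h in hs] for hs in holes_per_interval
    ]

    parts: list[np.ndarray] = []
    # bottom and top caps
    parts.append(
        _cap(triangulate_polygon(outer, holes_per_interval[0]), z_breaks[0], up=False)
    )
    parts.append(
        _cap(triangulate_polygon(outer, holes_per_interval[-1]), z_breaks[-1], up=True)
    )
    # outer walls span the full height
    parts.append(_walls(outer, z_breaks[0], z_breaks[-1], outward=True))

    def _key(h: np.ndarray) -> bytes:
        return np.round(h, 9).tobytes()

    for i in range(n_int):
        for h in holes_per_interval[i]:
            parts.append(_walls(h, z_breaks[i], z_breaks[i + 1], outward=False))
    # internal caps where hole sets change between intervals
    for i in range(1, n_int):
        below = {_key(h): h for h in holes_per_interval[i - 1]}
        above = {_key(h): h for h in holes_per_interval[i]}
        for k, h in below.items():
            if k not in above:  # void below, solid above: face points down
                parts.append(_cap(triangulate_polygon(h), z_breaks[i], up=False))
        for k, h in above.items():
            if k not in below:  # solid below, void above: face points up
                parts.append(_cap(triangulate_polygon(h), z_breaks[i], up=True))

    return np.concatenate(parts, axis=0)


def mesh_volume(tris: np.ndarray) -> float:
    """Signed volume via the divergence theorem (positive for outward CCW)."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    return float(np.sum(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0)


def is_watertight(tris: np.ndarray) -> bool:
    """Closed and edge-manifold: every edge shared by exactly two opposite halves."""
    verts = np.round(tris.reshape(-1, 3), 7)
    uniq, inv = np.unique(verts, axis=0, return_inverse=True)
    faces = inv.reshape(-1, 3)
    edges: dict[tuple[int, int], int] = {}
    for f in faces:
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if u == v:
                return False
            edges[(u, v)] = edges.get((u, v), 0) + 1
    for (u, v), cnt in edges.items():
        if cnt != 1 or edges.get((v, u), 0) != 1:
            return False
    return True


def write_stl(path, tris: np.ndarray, name: str = "phantomforge", binary: bool = True) -> None:
    path = Path(path)
    tris = np.asarray(tris, dtype=np.float64)
    ab = tris[:, 1] - tris[:, 0]
    ac = tris[:, 2] - tris[:, 0]
    normals = np.cross(ab, ac)
    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    normals = normals / lens
    if binary:
        with open(path, "wb") as fh:
            fh.write(name.encode()[:80].ljust(80, b"\0"))
            fh.write(struct.pack("<I", len(tris)))
            for nrm, tri in zip(normals, tris):
                fh.write(struct.pack("<3f", *nrm))
                for v in tri:
                    fh.write(struct.pack("<3f", *v))
                fh.write(b"\0\0")
    else:
        with open(path, "w") as fh:
            fh.write(f"solid {name}\n")
            for nrm, tri in zip(normals, tris):
                fh.write(f"  facet normal {nrm[0]:e} {nrm[1]:e} {nrm[2]:e}\n")
                fh.write("    outer loop\n")
                for v in tri:
                    fh.write(f"      vertex {v[0]:e} {v[1]:e} {v[2]:e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write(f"endsolid {name}\n")
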