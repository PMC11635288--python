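"""Ground-truth vacuole models for FRAP simulation.

A vacuole is modelled as a set of luminal compartments (2D pixel masks in a
single optical plane, one volume each) joined by exchange edges.  The graph
component structure is the ground truth for connectivity: compartments in the
same component as the bleach target can re-equilibrate after photobleaching,
compartments in other components cannot.

Three morphology styles mirror the phenotypes a microscopist encounters:

* ``tubular`` — one thin tube split into segments with fast exchange between
  neighbors (a fully connected network).
* ``constricted`` — a chain of lobes connected through low-conductance
  bottlenecks (connected, but recovery is slow).
* ``fragmented`` — isolated blobs with no exchange at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series_io import CircleRoi, RoiSet

__all__ = [
    "Compartment",
    "Edge",
    "CompartmentNetwork",
    "PlacementError",
    "build_network",
    "default_rois",
    "rate_for_half_time",
]


class PlacementError(RuntimeError):
    """Requested geometry cannot be placed without mask overlap."""


@dataclass
class Compartment:
    id: int
    mask: np.ndarray  # bool, H x W
    cell_label: int = 0

    @property
    def volume(self) -> int:
        """Voxel (pixel) count of the compartment lumen."""
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass(frozen=True)
class Edge:
    """Exchange edge with conductance ``rate`` (amount / (concentration s))."""

    i: int
    j: int
    rate: float


@dataclass
class CompartmentNetwork:
    compartments: list[Compartment]
    edges: list[Edge]
    image_shape: tuple[int, int] = (512, 512)
    initial_concentration: float = 1000.0

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate compartment ids")
        for c in self.compartments:
            if c.volume <= 0:
                raise ValueError(f"compartment {c.id} has empty mask")
        for e in self.edges:
            if e.rate < 0:
                raise ValueError(f"edge ({e.i},{e.j}) has negative rate")
            if e.i == e.j:
                raise ValueError("self-edges are not allowed")
            if e.i not in ids or e.j not in ids:
                raise ValueError(f"edge ({e.i},{e.j}) references unknown compartment")
        total = np.zeros(self.image_shape, dtype=np.int32)
        for c in self.compartments:
            if c.mask.shape != self.image_shape:
                raise ValueError("mask shape does not match image_shape")
            total += c.mask
        if np.any(total > 1):
            raise ValueError("compartment masks overlap")

    @property
    def n(self) -> int:
        return len(self.compartments)

    def index_of(self, comp_id: int) -> int:
        for k, c in enumerate(self.compartments):
            if c.id == comp_id:
                return k
        raise KeyError(f"no compartment with id {comp_id}")

    def volumes(self) -> np.ndarray:
        return np.array([c.volume for c in self.compartments], dtype=float)

    def components(self) -> list[set[int]]:
        """Connected components of the exchange graph (by compartment id).

        Edges with zero rate do not connect: they exchange nothing.
        """
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(c.id for c in self.compartments)
        g.add_edges_from((e.i, e.j) for e in self.edges if e.rate > 0)
        return [set(comp) for comp in nx.connected_components(g)]

    def component_of(self, comp_id: int) -> set[int]:
        for comp in self.components():
            if comp_id in comp:
                return comp
        raise KeyError(f"no compartment with id {comp_id}")

    def connected_to(self, comp_id: int) -> np.ndarray:
        """Boolean vector (network order): same graph component as comp_id."""
        comp = self.component_of(comp_id)
        return np.array([c.id in comp for c in self.compartments])


def rate_for_half_time(half_time_s: float, v_i: float, v_j: float) -> float:
    """Conductance giving a pairwise relaxation half-time ``half_time_s``.

    For two compartments the deviation from the common mean decays at
    lambda = k (1/V_i + 1/V_j); inverting t_half = ln2 / lambda gives k.
    """
    if half_time_s <= 0:
        raise ValueError("half_time_s must be > 0")
    return np.log(2) / (half_time_s * (1.0 / v_i + 1.0 / v_j))


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------

_DEFAULT_GEOMETRY = {
    "tubular": {"tube_half_width": 4, "edge_half_time_s": 0.02},
    "constricted": {"lobe_radius": 18, "edge_half_time_s": 3.0},
    "fragmented": {"blob_radius": 18},
}


def build_network(
    style: str,
    n_compartments: int,
    geometry_params: dict | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = (512, 512),
    with_neighbor: bool = False,
) -> CompartmentNetwork:
    """Build a deterministic ground-truth vacuole network.

    Parameters
    ----------
    style : {"tubular", "constricted", "fragmented"}
        Morphology class.  ``tubular`` gives one connected thin tube split
        into ``n_compartments`` segments with fast exchange, ``constricted``
        a connected chain of lobes joined by low-rate bottleneck edges, and
        ``fragmented`` isolated blobs with no edges.
    geometry_params : dict, optional
        Style-specific overrides.  ``edge_rate`` (conductance, passed through
        verbatim) or ``edge_half_time_s`` (pairwise relaxation half-time used
        to derive the conductance) control exchange; ``tube_half_width``,
        ``lobe_radius``, ``blob_radius`` control mask geometry.
    with_neighbor : bool
        Add one extra compartment with ``cell_label=1`` and no edges,
        standing in for the vacuole of a neighboring cell (the CI control
        area "c").
    """
    if style not in _DEFAULT_GEOMETRY:
        raise ValueError(f"unknown style {style!r}")
    if n_compartments < 1:
        raise ValueError("n_compartments must be >= 1")
    params = dict(_DEFAULT_GEOMETRY[style])
    params.update(geometry_params or {})
    rng = np.random.default_rng(seed)
    h, w = image_size

    if style == "tubular":
        comps = _tubular_masks(n_compartments, params, rng, image_size)
    elif style == "constricted":
        comps = _lobe_masks(n_compartments, params["lobe_radius"], rng, image_size)
    else:
        comps = _scattered_masks(n_compartments, params["blob_radius"], rng, image_size)

    edges: list[Edge] = []
    if style in ("tubular", "constricted"):
        for i in range(n_compartments - 1):
            if "edge_rate" in params:
                k = float(params["edge_rate"])
            else:
                k = rate_for_half_time(
                    params["edge_half_time_s"], comps[i].volume, comps[i + 1].volume
                )
            edges.append(Edge(i, i + 1, k))

    if with_neighbor:
        comps.append(_neighbor_mask(len(comps), comps, rng, image_size))

    return CompartmentNetwork(
        compartments=comps, edges=edges, image_shape=image_size
    )


def _tubular_masks(n, params, rng, image_size) -> list[Compartment]:
    h, w = image_size
    half_width = int(params["tube_half_width"])
    margin = 24
    seg_len = (w - 2 * margin) // n
    if seg_len < 4:
        raise PlacementError(f"{n} tube segments do not fit a width-{w} image")
    row = int(rng.integers(h // 3, 2 * h // 3))
    comps = []
    for i in range(n):
        mask = np.zeros(image_size, dtype=bool)
        c0 = margin + i * seg_len
        mask[row - half_width : row + half_width + 1, c0 : c0 + seg_len] = True
        comps.append(Compartment(id=i, mask=mask, cell_label=0))
    return comps


def _lobe_masks(n, radius, rng, image_size) -> list[Compartment]:
    h, w = image_size
    margin = radius + 8
    gap = 6  # pixels between adjacent lobes (the constriction)
    pitch = 2 * radius + gap
    if margin + (n - 1) * pitch + radius >= w - 8:
        raise PlacementError(f"{n} lobes of radius {radius} do not fit the image")
    row = int(rng.integers(h // 3, 2 * h // 3))
    rr, cc = np.mgrid[0:h, 0:w]
    comps = []
    for i in range(n):
        col = margin + i * pitch
        mask = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
        comps.append(Compartment(id=i, mask=mask, cell_label=0))
    return comps


def _scattered_masks(n, radius, rng, image_size) -> list[Compartment]:
    h, w = image_size
    margin = radius + 8
    rr, cc = np.mgrid[0:h, 0:w]
    centers: list[tuple[int, int]] = []
    comps = []
    for i in range(n):
        for _attempt in range(200):
            r = int(rng.integers(margin, h - margin))
            c = int(rng.integers(margin, w - margin))
            if all((r - r0) ** 2 + (c - c0) ** 2 > (2 * radius + 6) ** 2 for r0, c0 in centers):
                centers.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place blob {i} of radius {radius} without overlap"
            )
        mask = (rr - centers[-1][0]) ** 2 + (cc - centers[-1][1]) ** 2 <= radius**2
        comps.append(Compartment(id=i, mask=mask, cell_label=0))
    return comps


def _neighbor_mask(comp_id, existing, rng, image_size) -> Compartment:
    h, w = image_size
    radius = 16
    rr, cc = np.mgrid[0:h, 0:w]
    occupied = np.zeros(image_size, dtype=bool)
    for c in existing:
        occupied |= c.mask
    corners = [(radius + 8, radius + 8), (radius + 8, w - radius - 8),
               (h - radius - 8, radius + 8), (h - radius - 8, w - radius - 8)]
    for r0, c0 in corners:
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        if not np.any(mask & occupied):
            return Compartment(id=comp_id, mask=mask, cell_label=1)
    raise PlacementError("no free corner for the neighbor-cell compartment")


# ---------------------------------------------------------------------------
# ROI placement from ground truth
# ---------------------------------------------------------------------------


def default_rois(
    network: CompartmentNetwork, bleach_target: int, radius: float = 8.0
) -> RoiSet:
    """Place the CI measurement circles from the ground-truth masks.

    * ``a`` — inside the bleach-target compartment,
    * ``b`` — inside the same-cell compartment farthest from the target
      (or, for a single-compartment vacuole, at the far end of the target),
    * ``c`` — inside a compartment of another cell (requires a network built
      with ``with_neighbor=True``).

    Each circle is centered at the deepest interior point of its mask and its
    radius is shrunk to fit the mask if necessary.
    """
    from scipy import ndimage

    target = network.compartments[network.index_of(bleach_target)]
    rois: dict[str, CircleRoi] = {"a": _interior_circle(target.mask, radius, ndimage)}

    same_cell = [
        c
        for c in network.compartments
        if c.cell_label == target.cell_label and c.id != target.id
    ]
    if same_cell:
        t_cen = np.array(target.centroid)
        far = max(
            same_cell,
            key=lambda c: float(np.linalg.norm(np.array(c.centroid) - t_cen)),
        )
        rois["b"] = _interior_circle(far.mask, radius, ndimage)
    else:
        # single-compartment vacuole: area "b" at the far end of the target
        rois["b"] = _far_end_circle(target.mask, rois["a"], radius, ndimage)

    other_cell = [c for c in network.compartments if c.cell_label != target.cell_label]
    if not other_cell:
        raise ValueError(
            "no neighbor-cell compartment for area 'c'; build the network "
            "with with_neighbor=True"
        )
    rois["c"] = _interior_circle(other_cell[0].mask, radius, ndimage)
    return RoiSet(rois)


def _interior_circle(mask, radius, ndimage) -> CircleRoi:
    dist = ndimage.distance_transform_edt(mask)
    r, c = np.unravel_index(int(np.argmax(dist)), mask.shape)
    rad = min(radius, max(float(dist[r, c]) - 1.0, 0.5))
    return CircleRoi(center=(float(r), float(c)), radius=rad)


def _far_end_circle(mask, avoid: CircleRoi, radius, ndimage) -> CircleRoi:
    dist = ndimage.distance_transform_edt(mask)
    rr, cc = np.nonzero(dist >= min(2.0, dist.max()))
    d2 = (rr - avoid.center[0]) ** 2 + (cc - avoid.center[1]) ** 2
    k = int(np.argmax(d2))
    r, c = int(rr[k]), int(cc[k])
    rad = min(radius, max(float(dist[r, c]) - 1.0, 0.5))
    return CircleRoi(center=(float(r), float(c)), radius=rad)
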