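"""Process tracing and per-cell morphology.

The foreground mask is topologically skeletonized; skeleton pixels are
assigned to the soma they reach through the mask (geodesic connectivity) and
analysed as a weighted pixel graph (unit steps ``pixel_size``, diagonal steps
``sqrt(2) * pixel_size``).  Terminal spurs shorter than a pruning length --
skeletonization artifacts of blob boundaries -- are removed before counting.

Per cell the eight published parameters are computed: number of primary
branches (distinct skeleton crossings of the soma boundary), number of branch
points (clusters of skeleton pixels of degree >= 3 outside the soma), total
branch length, cell radius (furthest skeleton point from the soma centroid),
cell area (foreground area assigned to the cell), soma area and soma
eccentricity; cell density is a per-field quantity.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .segmentation import SomaDetection

__all__ = [
    "ProcessSkeleton",
    "CellMorphology",
    "FieldSummary",
    "trace_processes",
    "count_primary_branches",
    "count_branch_points",
    "total_branch_length",
    "cell_radius",
    "cell_area",
    "field_density",
    "measure_cells",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

# 8-neighbourhood offsets with step weights (in pixels)
_STEPS = [(-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
          (-1, -1, math.sqrt(2)), (-1, 1, math.sqrt(2)),
          (1, -1, math.sqrt(2)), (1, 1, math.sqrt(2))]


@dataclass
class ProcessSkeleton:
    """Rooted skeleton of one cell's processes.

    ``graph`` holds skeleton pixels (row, col) outside the soma with geodesic
    edge weights in pixels; ``anchors`` are skeleton pixels touching the soma
    region; ``ambiguous`` marks cells whose foreground component contained
    more than one soma and was split geodesically.
    """

    cell_label: int
    graph: nx.Graph
    anchors: frozenset[tuple[int, int]]
    soma_centroid_um: tuple[float, float]
    pixel_size: float
    ambiguous: bool = False

    def _clusters(self, pixels: set[tuple[int, int]]) -> list[set[tuple[int, int]]]:
        """8-connected clusters within an arbitrary pixel set."""
        pixels = set(pixels)
        clusters = []
        while pixels:
            seed = pixels.pop()
            comp = {seed}
            queue = deque([seed])
            while queue:
                r, c = queue.popleft()
                for dr, dc, _ in _STEPS:
                    q = (r + dr, c + dc)
                    if q in pixels:
                        pixels.remove(q)
                        comp.add(q)
                        queue.append(q)
            clusters.append(comp)
        return clusters

    def anchor_clusters(self) -> list[set[tuple[int, int]]]:
        """Soma-boundary crossing sites: clusters of anchor pixels that carry
        at least one skeleton edge leaving the cluster."""
        out = []
        for cl in self._clusters(set(self.anchors) & set(self.graph)):
            if any(nb not in cl for px in cl for nb in self.graph[px]):
                out.append(cl)
        return out

    def junction_clusters(self) -> list[set[tuple[int, int]]]:
        """Branch points: clusters of degree >= 3 skeleton pixels."""
        junction_px = {n for n in self.graph if self.graph.degree(n) >= 3}
        return self._clusters(junction_px)


@dataclass(frozen=True)
class CellMorphology:
    """The eight per-cell parameters (density is reported at field level)."""

    cell_label: int
    centroid_um: tuple[float, float]
    n_primary_branches: int
    n_branch_points: int
    total_branch_length_um: float
    cell_radius_um: float
    cell_area_um2: float
    soma_area_um2: float
    soma_eccentricity: float
    process_free: bool = False
    ambiguous: bool = False
    touches_border: bool = False

    def __post_init__(self) -> None:
        if self.cell_area_um2 + 1e-9 < self.soma_area_um2:
            raise ValueError("cell_area must be >= soma_area")


@dataclass(frozen=True)
class FieldSummary:
    region_label: str
    n_cells: int
    field_area_mm2: float

    @property
    def density_cells_per_mm2(self) -> float:
        return field_density(self.n_cells, self.field_area_mm2)


def field_density(n_cells: int, field_area_mm2: float) -> float:
    """Cells per square millimetre."""
    if field_area_mm2 <= 0:
        raise ValueError("field area must be positive")
    return n_cells / field_area_mm2


# ---------------------------------------------------------------------------
# skeleton graph machinery


def _pixel_graph(pixels: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton with sqrt(2) diagonal weights.

    A diagonal edge is dropped when the two pixels share a 4-connected
    skeleton neighbour, so staircase corners are not double-counted.
    """
    pset = {tuple(p) for p in pixels}
    g = nx.Graph()
    g.add_nodes_from(pset)
    for r, c in pset:
        for dr, dc, w in _STEPS:
            q = (r + dr, c + dc)
            if q not in pset or (r, c) > q:
                continue
            if w > 1.0 and ((r, c + dc) in pset or (r + dr, c) in pset):
                continue  # corner triangle: the rectilinear detour already counts
            g.add_edge((r, c), q, weight=w)
    return g


def _prune_spurs(g: nx.Graph, anchors: frozenset[tuple[int, int]],
                 prune_len_px: float) -> None:
    """Iteratively remove endpoint-terminated paths shorter than the pruning
    length.  Anchor pixels are protected terminals, like junctions."""
    if prune_len_px <= 0:
        return
    changed = True
    while changed:
        changed = False
        endpoints = [n for n in g.nodes if g.degree(n) <= 1 and n not in anchors]
        for ep in endpoints:
            if ep not in g:
                continue
            if g.degree(ep) == 0:
                g.remove_node(ep)
                changed = True
                continue
            path = [ep]
            acc = 0.0
            prev, cur = None, ep
            while True:
                nbrs = [n for n in g[cur] if n != prev]
                if cur != ep and (g.degree(cur) != 2 or cur in anchors):
                    break  # reached a junction, an anchor, or another endpoint
                if not nbrs:
                    break
                nxt = nbrs[0]
                acc += g[cur][nxt]["weight"]
                prev, cur = cur, nxt
                path.append(cur)
                if acc >= prune_len_px:
                    break
            if acc < prune_len_px and len(path) > 1:
                g.remove_nodes_from(path[:-1])
                changed = True


def _assign_mask_to_somata(mask: np.ndarray, soma_labels: np.ndarray
                           ) -> tuple[np.ndarray, set[int]]:
    """Geodesic assignment of every mask pixel to its nearest soma.

    Multi-source breadth-first search through the mask seeded by the soma
    regions; ties go to the lower soma label (deterministic).  Returns the
    assignment image (0 where unreachable) and the set of soma labels whose
    foreground component contained more than one soma.
    """
    comp_labels, _ = ndimage.label(mask, structure=_STRUCT8)
    somata_per_comp: dict[int, set[int]] = {}
    for lab in np.unique(soma_labels[soma_labels > 0]):
        comps = np.unique(comp_labels[(soma_labels == lab) & mask])
        for comp in comps[comps > 0]:
            somata_per_comp.setdefault(int(comp), set()).add(int(lab))
    ambiguous = {lab for s in somata_per_comp.values() if len(s) > 1 for lab in s}

    assign = np.where(mask, soma_labels, 0).astype(np.int32)
    h, w = mask.shape
    queue: deque[tuple[int, int]] = deque()
    seeds = np.argwhere((soma_labels > 0) & mask)
    for r, c in seeds[np.lexsort((seeds[:, 1], seeds[:, 0]))]:
        queue.append((int(r), int(c)))
    while queue:
        r, c = queue.popleft()
        lab = assign[r, c]
        for dr, dc, _ in _STEPS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and assign[rr, cc] == 0:
                assign[rr, cc] = lab
                queue.append((rr, cc))
    return assign, ambiguous


def trace_processes(mask: np.ndarray, somata: list[SomaDetection],
                    pixel_size: float, prune_len_um: float = 2.0,
                    ) -> list[ProcessSkeleton]:
    """Skeletonize the foreground and root each cell's processes at its soma.

    ``mask`` is the (cleaned) foreground mask; soma regions are forced into
    it so every detection is reachable.  Foreground components holding no
    soma are ignored; components holding several are split geodesically and
    all involved cells flagged ambiguous.
    """
    mask = mask.copy()
    soma_labels = np.zeros(mask.shape, dtype=np.int32)
    for det in somata:
        sl = det.slices
        soma_labels[sl][det.mask] = det.label
    mask |= soma_labels > 0

    assign, ambiguous = _assign_mask_to_somata(mask, soma_labels)
    skel = skeletonize(mask)

    skeletons = []
    for det in somata:
        cell_px = np.argwhere(skel & (assign == det.label) & (soma_labels == 0))
        g = _pixel_graph(cell_px)
        soma_set = {tuple(p) for p in np.argwhere(soma_labels == det.label)}
        anchors = frozenset(
            (r, c) for r, c in map(tuple, cell_px)
            if any((r + dr, c + dc) in soma_set for dr, dc, _ in _STEPS))
        _prune_spurs(g, anchors, prune_len_um / pixel_size)
        skeletons.append(ProcessSkeleton(
            cell_label=det.label, graph=g, anchors=anchors,
            soma_centroid_um=det.centroid_um, pixel_size=pixel_size,
            ambiguous=det.label in ambiguous))
    return skeletons


# ---------------------------------------------------------------------------
# per-cell parameters


def count_primary_branches(skel: ProcessSkeleton) -> int:
    """Distinct skeleton crossings of the soma-region boundary."""
    return len(skel.anchor_clusters())


def count_branch_points(skel: ProcessSkeleton) -> int:
    """Junction clusters (degree >= 3) in the pruned skeleton, outside the soma."""
    return len(skel.junction_clusters())


def total_branch_length(skel: ProcessSkeleton) -> float:
    """Sum of geodesic edge lengths outside the soma, in micrometres."""
    w = sum(d["weight"] for _, _, d in skel.graph.edges(data=True))
    return float(w * skel.pixel_size)


def cell_radius(skel: ProcessSkeleton, soma_centroid_um: tuple[float, float] | None = None,
                ) -> float:
    """Maximum Euclidean distance from the soma centroid to any skeleton
    point, in micrometres.  Returns 0 for a process-free cell (the caller
    substitutes the soma's own radius)."""
    cx, cy = soma_centroid_um or skel.soma_centroid_um
    ps = skel.pixel_size
    best = 0.0
    for r, c in skel.graph.nodes:
        d = math.hypot((c + 0.5) * ps - cx, (r + 0.5) * ps - cy)
        best = max(best, d)
    return best


def cell_area(n_assigned_px: int, pixel_size: float) -> float:
    """Foreground area assigned to one cell (soma plus processes), um^2."""
    return n_assigned_px * pixel_size**2


def measure_cells(mask: np.ndarray, somata: list[SomaDetection],
                  pixel_size: float, prune_len_um: float = 2.0,
                  radius_from: str = "skeleton") -> list[CellMorphology]:
    """Full per-cell morphology for every detected soma.

    ``radius_from`` selects the cell-radius definition: the furthest traced
    skeleton point from the soma centroid (default) or, as a hull-style
    alternative, the furthest foreground pixel assigned to the cell.
    """
    if radius_from not in ("skeleton", "mask"):
        raise ValueError("radius_from must be 'skeleton' or 'mask'")
    mask = mask.copy()
    soma_labels = np.zeros(mask.shape, dtype=np.int32)
    for det in somata:
        sl = det.slices
        soma_labels[sl][det.mask] = det.label
    mask |= soma_labels > 0
    assign, _ = _assign_mask_to_somata(mask, soma_labels)
    skeletons = trace_processes(mask, somata, pixel_size, prune_len_um)

    out = []
    for det, skel in zip(somata, skeletons):
        n_px = int((assign == det.label).sum())
        process_free = skel.graph.number_of_nodes() == 0
        if process_free or radius_from == "mask":
            coords = (det.pixel_coords() if process_free
                      else np.argwhere(assign == det.label))
            cx, cy = det.centroid_um
            d = np.hypot((coords[:, 1] + 0.5) * pixel_size - cx,
                         (coords[:, 0] + 0.5) * pixel_size - cy)
            radius = float(d.max()) if d.size else 0.0
        else:
            radius = cell_radius(skel)
        out.append(CellMorphology(
            cell_label=det.label,
            centroid_um=det.centroid_um,
            n_primary_branches=count_primary_branches(skel),
            n_branch_points=count_branch_points(skel),
            total_branch_length_um=total_branch_length(skel),
            cell_radius_um=radius,
            cell_area_um2=max(cell_area(n_px, pixel_size), det.area_um2),
            soma_area_um2=det.area_um2,
            soma_eccentricity=det.eccentricity,
            process_free=process_free,
            ambiguous=skel.ambiguous,
            touches_border=det.touches_border))
    return out
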