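"""Mitochondrial skeleton alignment analysis and morphometrics.

Skeletons are node/edge centerline graphs (one per mitochondrion) plus a
designated *primary axis* skeleton tracing the cone center line as a function
of z.  Alignment is quantified layer by layer: the z axis is discretized into
slabs (default 0.5 um), and within each slab the deviation angle between the
local primary-axis direction and every mitochondrial branch crossing that slab
is collected into a histogram.  The fraction of branch mass deviating by less
than a threshold (default 15 deg) summarizes bundle order: a tightly aligned
bundle concentrates nearly all mass below 15 deg, a disordered one does not.

Skeleton files use the KNOSSOS XML dialect (``<things>`` containing ``<thing>``
elements with ``<nodes>``/``<edges>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree

__all__ = [
    "Skeleton",
    "SkeletonSet",
    "AlignmentHistogram",
    "read_skeletons",
    "write_skeletons",
    "layer_deviation_histogram",
    "fraction_below",
    "mito_morphometrics",
]

PRIMARY_AXIS_NAME = "primary_axis"


@dataclass
class Skeleton:
    """A node/edge centerline graph in micrometers.

    ``edges`` holds integer index pairs into ``nodes`` (not raw file node ids).
    """

    nodes: np.ndarray  # (N, 3) float, um
    edges: np.ndarray  # (M, 2) int indices into nodes
    name: str = ""

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size and self.edges.max() >= len(self.nodes):
            raise ValueError("edge references a nonexistent node")

    def segments(self) -> np.ndarray:
        """Return (M, 2, 3) array of edge endpoint coordinates."""
        return self.nodes[self.edges]

    def transformed(self, rotation: np.ndarray, offset: np.ndarray | None = None) -> "Skeleton":
        nodes = self.nodes @ np.asarray(rotation).T
        if offset is not None:
            nodes = nodes + np.asarray(offset)
        return Skeleton(nodes, self.edges.copy(), self.name)


@dataclass
class SkeletonSet:
    """All mitochondrial skeletons of one cone plus its primary-axis skeleton."""

    skeletons: list[Skeleton]
    primary_axis: Skeleton | None = None

    def __post_init__(self) -> None:
        if self.primary_axis is not None:
            _check_primary(self.primary_axis)

    def transformed(self, rotation: np.ndarray, offset: np.ndarray | None = None) -> "SkeletonSet":
        prim = None if self.primary_axis is None else self.primary_axis.transformed(rotation, offset)
        return SkeletonSet([s.transformed(rotation, offset) for s in self.skeletons], prim)

    def branch_angles_to(self, axis: np.ndarray = (0.0, 0.0, 1.0)) -> np.ndarray:
        """Deviation angle (deg, folded into [0, 90]) of every edge vs a fixed axis."""
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        out = []
        for sk in self.skeletons:
            seg = sk.segments()
            if not len(seg):
                continue
            v = seg[:, 1] - seg[:, 0]
            norm = np.linalg.norm(v, axis=1)
            v = v[norm > 0] / norm[norm > 0, None]
            out.append(np.degrees(np.arccos(np.clip(np.abs(v @ axis), 0.0, 1.0))))
        return np.concatenate(out) if out else np.empty(0)


def _check_primary(skel: Skeleton) -> None:
    """Primary axis must be a single strand with strictly monotone z."""
    if len(skel.nodes) < 2:
        raise ValueError("primary axis skeleton needs at least 2 nodes")
    z = skel.nodes[:, 2]
    if not (np.all(np.diff(z) > 0) or np.all(np.diff(z) < 0)):
        raise ValueError("primary axis skeleton must be monotone in z")


@dataclass
class AlignmentHistogram:
    """Per-layer deviation-angle histograms plus their cross-layer aggregate."""

    layer_edges: np.ndarray       # (L+1,) z in um
    angle_bins: np.ndarray        # (B+1,) degrees, spanning [0, 90]
    per_layer: np.ndarray         # (L, B) rows normalized to 1 (empty rows all-nan)
    aggregate: np.ndarray = field(init=False)
    aggregate_sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        valid = self.per_layer[~np.isnan(self.per_layer).any(axis=1)]
        if len(valid) == 0:
            raise ValueError("no layer contained any branch")
        self.aggregate = valid.mean(axis=0)
        self.aggregate_sd = valid.std(axis=0, ddof=0)

    @property
    def n_layers(self) -> int:
        return len(self.layer_edges) - 1


def read_skeletons(xml_path, primary_name: str = PRIMARY_AXIS_NAME,
                   primary_id: int | None = None) -> SkeletonSet:
    """Parse a KNOSSOS-style skeleton XML file.

    Node coordinates are multiplied by the per-axis ``<scale>`` from the file's
    ``<parameters>`` block (KNOSSOS stores voxel indices plus a nm-per-voxel
    scale; this module stores um).  The primary-axis skeleton is identified by
    its comment/name attribute, or by ``primary_id`` (1-based thing id).
    """
    tree = etree.parse(str(xml_path))
    root = tree.getroot()
    scale = np.ones(3)
    scale_el = root.find("parameters/scale")
    if scale_el is not None:
        scale = np.array([float(scale_el.get(k, 1.0)) for k in ("x", "y", "z")])

    skeletons: list[Skeleton] = []
    primary: Skeleton | None = None
    for thing in root.iter("thing"):
        name = thing.get("comment", thing.get("name", ""))
        id_map: dict[int, int] = {}
        coords = []
        for node in thing.iter("node"):
            nid = int(node.get("id"))
            if nid in id_map:
                raise ValueError(f"duplicate node id {nid} in thing {thing.get('id')}")
            id_map[nid] = len(coords)
            coords.append([float(node.get(k)) for k in ("x", "y", "z")])
        edges = []
        for edge in thing.iter("edge"):
            src, tgt = int(edge.get("source")), int(edge.get("target"))
            if src not in id_map or tgt not in id_map:
                raise ValueError(
                    f"dangling edge {src}->{tgt} in thing id={thing.get('id')}")
            edges.append((id_map[src], id_map[tgt]))
        skel = Skeleton(np.asarray(coords).reshape(-1, 3) * scale,
                        np.asarray(edges, int).reshape(-1, 2), name=name)
        is_primary = (name == primary_name) or (
            primary_id is not None and int(thing.get("id", -1)) == primary_id)
        if is_primary:
            primary = skel
        else:
            skeletons.append(skel)
    if primary is None:
        raise ValueError(
            f"no skeleton named {primary_name!r} found and no primary_id given")
    return SkeletonSet(skeletons, primary)


def write_skeletons(skels: SkeletonSet, xml_path, scale_um: float = 1.0) -> None:
    """Write a SkeletonSet as KNOSSOS-style XML (coordinates in units of ``scale_um``)."""
    root = etree.Element("things")
    params = etree.SubElement(root, "parameters")
    etree.SubElement(params, "scale",
                     x=repr(float(scale_um)), y=repr(float(scale_um)), z=repr(float(scale_um)))
    all_things = list(skels.skeletons)
    names = [s.name or f"mito_{i:03d}" for i, s in enumerate(all_things)]
    if skels.primary_axis is not None:
        all_things.append(skels.primary_axis)
        names.append(PRIMARY_AXIS_NAME)
    for tid, (skel, name) in enumerate(zip(all_things, names), start=1):
        thing = etree.SubElement(root, "thing", id=str(tid), comment=name)
        nodes_el = etree.SubElement(thing, "nodes")
        for nid, p in enumerate(skel.nodes, start=1):
            etree.SubElement(nodes_el, "node", id=str(nid),
                             x=repr(float(p[0] / scale_um)),
                             y=repr(float(p[1] / scale_um)),
                             z=repr(float(p[2] / scale_um)), radius="1.0")
        edges_el = etree.SubElement(thing, "edges")
        for a, b in skel.edges:
            etree.SubElement(edges_el, "edge",
                             source=str(a + 1), target=str(b + 1))
    etree.ElementTree(root).write(str(xml_path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


def _primary_direction_at(primary: Skeleton, z: float) -> np.ndarray:
    """Unit direction of the primary-axis segment containing height z.

    Heights outside the skeleton's span use the nearest end segment.
    """
    nodes = primary.nodes
    if nodes[0, 2] > nodes[-1, 2]:
        nodes = nodes[::-1]
    zs = nodes[:, 2]
    i = int(np.clip(np.searchsorted(zs, z) - 1, 0, len(zs) - 2))
    v = nodes[i + 1] - nodes[i]
    return v / np.linalg.norm(v)


def layer_deviation_histogram(skels: SkeletonSet, dz: float = 0.5,
                              bin_width: float = 5.0) -> AlignmentHistogram:
    """Per-layer histograms of branch deviation angles from the local primary axis.

    A branch (edge) contributes to every 0.5-um layer its z-extent intersects;
    a mitochondrion crossing a layer several times contributes once per
    crossing branch.  The branch direction is the whole edge's unit vector,
    sign-folded into [0 deg, 90 deg].  Layers containing no branch are recorded
    as all-NaN rows and excluded from the aggregate.
    """
    if skels.primary_axis is None:
        raise ValueError("SkeletonSet has no primary axis skeleton")
    segs = [sk.segments() for sk in skels.skeletons if len(sk.edges)]
    if not segs:
        raise ValueError("no mitochondrial branches to analyze")
    seg = np.concatenate(segs, axis=0)              # (M, 2, 3)
    zlo = np.minimum(seg[:, 0, 2], seg[:, 1, 2])
    zhi = np.maximum(seg[:, 0, 2], seg[:, 1, 2])
    v = seg[:, 1] - seg[:, 0]
    norms = np.linalg.norm(v, axis=1)
    keep = norms > 0
    seg, zlo, zhi, v, norms = seg[keep], zlo[keep], zhi[keep], v[keep], norms[keep]
    v = v / norms[:, None]

    z0 = float(min(zlo.min(), skels.primary_axis.nodes[:, 2].min()))
    z1 = float(max(zhi.max(), skels.primary_axis.nodes[:, 2].max()))
    n_layers = max(1, int(np.ceil((z1 - z0) / dz - 1e-9)))
    layer_edges = z0 + dz * np.arange(n_layers + 1)
    n_bins = int(round(90.0 / bin_width))
    angle_bins = np.linspace(0.0, 90.0, n_bins + 1)

    per_layer = np.full((n_layers, n_bins), np.nan)
    for li in range(n_layers):
        a, b = layer_edges[li], layer_edges[li + 1]
        in_layer = (zlo < b) & (zhi >= a)
        if not in_layer.any():
            continue
        axis = _primary_direction_at(skels.primary_axis, 0.5 * (a + b))
        ang = np.degrees(np.arccos(np.clip(np.abs(v[in_layer] @ axis), 0.0, 1.0)))
        hist, _ = np.histogram(ang, bins=angle_bins)
        per_layer[li] = hist / hist.sum()
    return AlignmentHistogram(layer_edges, angle_bins, per_layer)


def fraction_below(hist: AlignmentHistogram, threshold: float = 15.0) -> float:
    """Aggregate probability mass at deviation angles below ``threshold`` degrees.

    Partial bins are counted by linear interpolation within the bin.
    """
    if not 0.0 <= threshold <= 90.0:
        raise ValueError("threshold must lie in [0, 90] degrees")
    lo, hi = hist.angle_bins[:-1], hist.angle_bins[1:]
    w = np.clip((threshold - lo) / (hi - lo), 0.0, 1.0)
    return float(np.sum(hist.aggregate * w))


def mito_morphometrics(model) -> dict:
    """Counts and divergence-theorem volumes of a cone's mitochondria.

    Accepts a ConeModel or a plain list of meshes.
    """
    from .synthetic_geometry import mesh_volume

    meshes = getattr(model, "mitochondria", model)
    volumes = np.array([mesh_volume(m) for m in meshes])
    return {
        "count": len(volumes),
        "volumes_um3": volumes,
        "total_volume_um3": float(volumes.sum()) if len(volumes) else 0.0,
        "mean_volume_um3": float(volumes.mean()) if len(volumes) else float("nan"),
        "sd_volume_um3": float(volumes.std(ddof=0)) if len(volumes) else float("nan"),
    }
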