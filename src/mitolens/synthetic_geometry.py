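"""Synthetic cone inner-segment geometry.

The cone ellipsoid region — the distal inner segment (IS) packed with
mitochondria — is modeled as a solid of revolution (the envelope) containing a
bundle of mitochondrion bodies.  Four bundle configurations are supported:

* ``elongated``  — axially aligned capsules, the organized bundle of a cone in
  the active state;
* ``disordered`` — shorter capsules with broadly spread orientations, emulating
  the shrunken, disorganized bundle of the hibernating state;
* ``spheres``    — volume-matched near-spherical bodies;
* ``mega``       — a single volume-matched megamitochondrion.

Branch orientations are drawn from a von Mises-Fisher distribution about +Z,
whose concentration ``kappa`` controls alignment.  The default presets are
calibrated so that ~75% of active-like branches and ~30% of hibernating-like
branches deviate by less than 15 degrees from the cone axis, and so that the
hibernating-like bundle carries 70% of the active-like total volume.

Every generated bundle returns its generative centerline skeletons
(:class:`~mitolens.alignment_morphometry.SkeletonSet`) as ground truth for the
alignment analysis.  All lengths are micrometers; +Z is the proximal-to-distal
direction of light travel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .alignment_morphometry import Skeleton, SkeletonSet

__all__ = [
    "BundleSpec",
    "CohortSpec",
    "ConeModel",
    "PackingError",
    "KAPPA_ACTIVE",
    "KAPPA_HIBERNATING",
    "ellipsoid_taper",
    "make_cone_envelope",
    "make_mito_bundle",
    "make_cristae_spec",
    "mesh_volume",
    "make_cohort",
    "bundle_preset",
    "sample_vmf",
    "vmf_fraction_below",
    "write_model",
    "read_model",
]

# von Mises-Fisher concentrations solving P(theta < 15 deg) = 0.75 and 0.30:
# P(theta < t) = 1 - exp(-kappa (1 - cos t)) for kappa >> 1.
_C15 = 1.0 - np.cos(np.radians(15.0))
KAPPA_ACTIVE = float(np.log(4.0) / _C15)        # ~40.7
KAPPA_HIBERNATING = float(np.log(1.0 / 0.7) / _C15)  # ~10.5

CLEARANCE_UM = 0.02  # minimum gap between bodies and to the envelope wall


class PackingError(RuntimeError):
    """Raised when a mitochondrial bundle cannot be packed into the envelope."""


@dataclass
class BundleSpec:
    """Parameters of one mitochondrial bundle configuration."""

    configuration: str            # elongated | spheres | mega | disordered
    n_mito: int
    target_volume: float          # um^3, total over all bodies
    disorder_kappa: float | None = None   # vMF concentration; None -> preset default
    capsule_length: float | None = None   # um, cylinder-section length; None -> preset
    planar: bool = False          # place body centers on the y = 0 plane (2D studies)
    z_range: tuple = (0.3, 1.0)   # bundle zone as fractions of envelope height:
    #                               mitochondria pack the distal ellipsoid, not
    #                               the proximal myoid region
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.configuration not in ("elongated", "spheres", "mega", "disordered"):
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.target_volume <= 0:
            raise ValueError("target_volume must be positive")
        if self.configuration == "mega":
            self.n_mito = 1
        if self.n_mito < 0:
            raise ValueError("n_mito must be >= 0")
        if self.disorder_kappa is None:
            self.disorder_kappa = (
                KAPPA_HIBERNATING if self.configuration == "disordered" else KAPPA_ACTIVE)


@dataclass
class CohortSpec:
    """Two-group cone cohort with animal-level and cone-level variability."""

    n_animals_per_group: int = 4
    cones_per_animal: tuple = (15, 15, 15, 15)
    group_means: tuple = (4.44, 3.65)   # OSR concentration factors, active vs hibernating
    between_animal_sd: float = 0.25
    within_animal_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1 or any(c < 1 for c in self.cones_per_animal):
            raise ValueError("counts must be >= 1")
        if self.between_animal_sd < 0 or self.within_animal_sd < 0:
            raise ValueError("SDs must be >= 0")
        if len(self.cones_per_animal) != self.n_animals_per_group:
            raise ValueError("need one cone count per animal")


@dataclass
class ConeModel:
    """Envelope + mitochondria + generative skeletons of one cone."""

    envelope: trimesh.Trimesh
    mitochondria: list
    skeletons: SkeletonSet | None = None
    anatomical_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    distal_tip: np.ndarray = None
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        self.anatomical_axis = np.asarray(self.anatomical_axis, float)
        n = np.linalg.norm(self.anatomical_axis)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("anatomical_axis must be a unit vector")
        if self.distal_tip is None:
            self.distal_tip = np.array([0.0, 0.0, self.envelope.bounds[1, 2]])
        self.distal_tip = np.asarray(self.distal_tip, float)

    @property
    def distal_tip_z(self) -> float:
        return float(self.distal_tip[2])

    def all_meshes(self) -> list:
        return [self.envelope, *self.mitochondria]

    def tilted(self, angle_deg: float) -> "ConeModel":
        """Rotate the whole model about the Y axis through the envelope centroid."""
        pivot = self.envelope.centroid
        R = trimesh.transformations.rotation_matrix(
            np.radians(angle_deg), [0.0, 1.0, 0.0], pivot)
        rot = R[:3, :3]

        def _rot(mesh):
            m = mesh.copy()
            m.apply_transform(R)
            return m

        skels = None
        if self.skeletons is not None:
            skels = self.skeletons.transformed(rot, R[:3, 3])
        return ConeModel(
            envelope=_rot(self.envelope),
            mitochondria=[_rot(m) for m in self.mitochondria],
            skeletons=skels,
            anatomical_axis=rot @ self.anatomical_axis,
            distal_tip=rot @ self.distal_tip + R[:3, 3],
            tilt_deg=self.tilt_deg + angle_deg,
        )


# ---------------------------------------------------------------------------
# envelope


def ellipsoid_taper(n: int = 33, bulge: float = 0.0) -> np.ndarray:
    """Default generatrix: ellipse-arc radius profile, widest at ``bulge`` (fraction
    of length from the base) and tapering to an apex at the distal end.

    Returns (n, 2) array of (z_fraction, r_fraction) in [0, 1].
    """
    zf = np.linspace(0.0, 1.0, n)
    a = 1.0 - bulge
    rf = np.sqrt(np.clip(1.0 - ((zf - bulge) / a) ** 2, 0.0, 1.0))
    if bulge > 0:
        rf[zf < bulge] = 1.0  # cylindrical below the bulge
    return np.column_stack([zf, rf])


def make_cone_envelope(length_um: float, max_diameter_um: float,
                       taper_profile: np.ndarray | None = None,
                       sections: int = 48, n_z: int = 65) -> trimesh.Trimesh:
    """Closed mesh of revolution for the IS envelope.

    ``taper_profile`` is a (k >= 8, 2) array of (z_fraction, radius_fraction)
    samples of the generatrix; the default is an ellipse-arc taper.  The base
    sits at z = 0 and the apex (distal tip) at z = ``length_um``.
    """
    if length_um <= 0 or max_diameter_um <= 0:
        raise ValueError("length and diameter must be positive")
    if taper_profile is None:
        taper_profile = ellipsoid_taper()
    prof = np.asarray(taper_profile, float)
    if prof.ndim != 2 or prof.shape[1] != 2 or len(prof) < 8:
        raise ValueError("taper_profile must be (k >= 8, 2) of (z_frac, r_frac)")
    if np.any(np.diff(prof[:, 0]) <= 0):
        raise ValueError("taper_profile z samples must be strictly increasing")

    rmax = max_diameter_um / 2.0
    z = np.linspace(0.0, 1.0, n_z) * length_um
    r = np.interp(z / length_um, prof[:, 0], prof[:, 1]) * rmax
    mesh = _revolve(z, r, sections)
    mesh.metadata["label"] = "envelope"
    mesh.metadata["generatrix"] = np.column_stack([z, r])
    return mesh


def _revolve(z: np.ndarray, r: np.ndarray, sections: int) -> trimesh.Trimesh:
    """Closed surface of revolution about +Z; outward winding (positive volume)."""
    theta = np.linspace(0.0, 2 * np.pi, sections, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    verts, rings = [], []
    eps = 1e-9 * max(z[-1] - z[0], 1.0)
    for zi, ri in zip(z, r):
        if ri <= eps:
            verts.append([0.0, 0.0, zi])
            rings.append(("point", len(verts) - 1))
        else:
            start = len(verts)
            verts.extend(np.column_stack([ri * ct, ri * st, np.full_like(ct, zi)]))
            rings.append(("ring", start))
    faces = []
    for (ka, ia), (kb, ib) in zip(rings[:-1], rings[1:]):
        if ka == "ring" and kb == "ring":
            for s in range(sections):
                s2 = (s + 1) % sections
                faces.append([ia + s, ia + s2, ib + s])
                faces.append([ia + s2, ib + s2, ib + s])
        elif ka == "ring" and kb == "point":
            for s in range(sections):
                faces.append([ia + s, ia + (s + 1) % sections, ib])
        elif ka == "point" and kb == "ring":
            for s in range(sections):
                faces.append([ia, ib + (s + 1) % sections, ib + s])
        # point-point: degenerate, skip
    # caps for open ends
    if rings[0][0] == "ring":
        verts.append([0.0, 0.0, z[0]])
        c = len(verts) - 1
        ia = rings[0][1]
        for s in range(sections):
            faces.append([ia + (s + 1) % sections, ia + s, c])
    if rings[-1][0] == "ring":
        verts.append([0.0, 0.0, z[-1]])
        c = len(verts) - 1
        ia = rings[-1][1]
        for s in range(sections):
            faces.append([ia + s, ia + (s + 1) % sections, c])
    mesh = trimesh.Trimesh(vertices=np.asarray(verts, float),
                           faces=np.asarray(faces, int), process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# mensuration


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Divergence-theorem volume of a closed, outward-wound mesh (um^3)."""
    if not mesh.is_watertight:
        raise ValueError("mesh is not watertight; volume undefined")
    v = float(mesh.volume)
    if v <= 0:
        raise ValueError("mesh winding is inward (negative signed volume)")
    return v


# ---------------------------------------------------------------------------
# orientation sampling


def sample_vmf(rng: np.random.Generator, kappa: float, n: int = 1) -> np.ndarray:
    """Draw unit vectors from a von Mises-Fisher distribution with mean +Z."""
    if np.isinf(kappa):
        return np.tile([0.0, 0.0, 1.0], (n, 1))
    u = rng.random(n)
    if kappa < 1e-12:
        w = 2.0 * u - 1.0
    else:
        # inverse-CDF of cos(theta) under vMF, numerically stable for large kappa
        w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.random(n) * 2 * np.pi
    s = np.sqrt(np.clip(1.0 - w ** 2, 0.0, 1.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), w])


def vmf_fraction_below(kappa: float, threshold_deg: float = 15.0) -> float:
    """Analytic P(theta < threshold) for a vMF deviation angle about its mean."""
    c = np.cos(np.radians(threshold_deg))
    if np.isinf(kappa):
        return 1.0
    if kappa < 1e-12:
        return float((1.0 - c) / 2.0)
    return float((np.exp(kappa) - np.exp(kappa * c)) / (np.exp(kappa) - np.exp(-kappa)))


# ---------------------------------------------------------------------------
# bundle packing



def _profile_radius(generatrix: np.ndarray, z):
    z_arr, r_arr = generatrix[:, 0], generatrix[:, 1]
    return np.interp(z, z_arr, r_arr, left=0.0, right=0.0)


def _inside_envelope(generatrix: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                     radius: float, clearance: float, n_check: int = 9) -> bool:
    """Check that a capsule axis segment + radius stays inside the revolution solid."""
    t = np.linspace(0.0, 1.0, n_check)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    # extend by hemispherical caps along the axis
    axis = (p1 - p0)
    L = np.linalg.norm(axis)
    if L > 0:
        axis = axis / L
    else:
        axis = np.array([0.0, 0.0, 1.0])
    pts = np.vstack([p0 - axis * radius * 0.999, pts, p1 + axis * radius * 0.999])
    zlo, zhi = generatrix[0, 0], generatrix[-1, 0]
    if np.any(pts[:, 2] < zlo + clearance) or np.any(pts[:, 2] > zhi - clearance):
        return False
    rad = np.hypot(pts[:, 0], pts[:, 1])
    allowed = _profile_radius(generatrix, pts[:, 2]) - radius - clearance
    return bool(np.all(rad <= allowed))



def _rot_z_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +Z to ``direction``."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(z @ d)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def make_mito_bundle(spec: BundleSpec, envelope: trimesh.Trimesh
                     ) -> tuple[list, SkeletonSet]:
    """Pack a mitochondrial bundle into the envelope.

    Returns the body meshes and the generative centerline skeletons (including
    the envelope primary-axis skeleton).  Orientations are drawn once per body;
    packing retries only resample positions, so the branch-angle distribution
    of the returned skeletons is exactly the requested von Mises-Fisher law.
    """
    gen = envelope.metadata.get("generatrix")
    if gen is None:
        raise ValueError("envelope has no generatrix metadata; "
                         "build it with make_cone_envelope")
    env_vol = mesh_volume(envelope)
    if spec.target_volume > 0.8 * env_vol:
        raise PackingError(
            f"target volume {spec.target_volume:.2f} exceeds 80% of the "
            f"envelope volume {env_vol:.2f}")
    rng = np.random.default_rng(spec.seed)
    length = float(gen[-1, 0] - gen[0, 0])
    gen_full = gen
    gen = _crop_generatrix(gen, spec.z_range)

    if spec.configuration == "mega":
        meshes, skels = _make_mega(spec, gen)
    elif spec.configuration == "spheres":
        meshes, skels = _pack_spheres(spec, gen, rng)
    else:  # elongated | disordered: segmented tube chains, differing in kappa
        seg_len = spec.capsule_length
        if seg_len is None:
            seg_len = 0.8 if spec.configuration == "elongated" else 0.5
        meshes, skels = _pack_chains(spec, gen, rng, seg_len)

    primary = _primary_axis_skeleton(gen_full)
    for m in meshes:
        m.metadata["label"] = "mitochondrion"
    return meshes, SkeletonSet(skels, primary)


def _crop_generatrix(gen: np.ndarray, z_range: tuple) -> np.ndarray:
    """Restrict the packing profile to the bundle zone (fractions of height)."""
    f0, f1 = z_range
    if not 0.0 <= f0 < f1 <= 1.0:
        raise ValueError("z_range fractions must satisfy 0 <= f0 < f1 <= 1")
    if f0 == 0.0 and f1 == 1.0:
        return gen
    zlo, zhi = gen[0, 0], gen[-1, 0]
    za, zb = zlo + f0 * (zhi - zlo), zlo + f1 * (zhi - zlo)
    z = np.linspace(za, zb, 129)
    return np.column_stack([z, _profile_radius(gen, z)])


def _primary_axis_skeleton(gen: np.ndarray, dz: float = 0.5) -> Skeleton:
    z = np.arange(gen[0, 0], gen[-1, 0] + 1e-9, dz)
    nodes = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    edges = np.column_stack([np.arange(len(z) - 1), np.arange(1, len(z))])
    return Skeleton(nodes, edges, name="primary_axis")




def _hex_lattice(n: int) -> np.ndarray:
    """First n unit-spacing hexagonal lattice points, sorted by radius."""
    pts = []
    for row in range(-8, 9):
        for col in range(-8, 9):
            pts.append((col + 0.5 * (row % 2), row * np.sqrt(3.0) / 2.0))
    pts = np.array(pts)
    return pts[np.argsort(np.linalg.norm(pts, axis=1), kind="stable")][:n]


def _vmf_polar(rng: np.random.Generator, kappa: float, n: int = 1) -> np.ndarray:
    """Polar deviation angles (rad) of vMF draws about the +Z mean."""
    d = sample_vmf(rng, kappa, n)
    return np.arccos(np.clip(np.abs(d[:, 2]), 0.0, 1.0))


_CHAIN_AMP_UM = 0.02   # lateral wobble amplitude of a chain about its site axis
_CHAIN_R_MIN = 0.08    # um, thinnest tube radius kept at the tapering tip
_CHAIN_AMP_DISORDERED_UM = 0.10  # wobble band of disordered (hibernating) chains


def _pack_chains(spec, gen, rng, seg_len):
    """Tightly packed aligned bundle: segmented, tapering tube 'chains' on
    concentric ring sites.

    Each mitochondrion is a tube swept along a polyline running the height of
    the envelope at its site.  Every segment's polar angle is an independent
    von Mises-Fisher draw (concentration ``spec.disorder_kappa``), so the
    branch-angle law of the returned skeletons is exactly vMF; azimuths are
    steered so the chain wobbles within a bounded tube about its site.  Tube
    radii shrink where the envelope tapers (as real mitochondria conform to
    the ellipsoid wall), which is what lets the bundle pack densely all the
    way to the distal tip.  A common radius rescale at the end hits the
    target volume to < 1%.  ``spec.n_mito`` caps the number of chains; the
    concentric layout decides how many fit.
    """
    # disordered (hibernating-like) bundles wobble in a much wider band:
    # the distortion is bundle-scale, not just segment-scale
    amp = _CHAIN_AMP_UM if spec.configuration == "elongated" else _CHAIN_AMP_DISORDERED_UM
    configs = []
    for r_cap in (0.7, 0.6, 0.5, 0.42, 0.35, 0.28, 0.22):
        sites = _ring_sites(gen, r_cap, amp, spec.planar, spec.n_mito,
                            np.random.default_rng(spec.seed))
        if not sites:
            continue
        vol = 0.0
        for (sx, sy, r_i) in sites:
            band = _chain_band(gen, np.hypot(sx, sy), r_i, amp)
            if band is None:
                continue
            zs, ravail, z0, z1 = band
            sel = (zs >= z0) & (zs <= z1)
            vol += np.pi * np.trapezoid(np.minimum(ravail[sel], r_i) ** 2,
                                        zs[sel])
        configs.append((r_cap, vol, sites))
    if not configs:
        raise PackingError("no chain arrangement fits this envelope")
    # prefer the finest tubes (most numerous, most realistic) whose estimated
    # capacity still clears the target with ~10% headroom for mesh deficits
    feasible = [c for c in configs if c[1] >= 1.10 * spec.target_volume]
    if feasible:
        r_cap, vol_max, sites = min(feasible, key=lambda c: c[0])
    else:
        r_cap, vol_max, sites = max(configs, key=lambda c: c[1])
    if vol_max < spec.target_volume:
        raise PackingError(
            f"target volume {spec.target_volume:.1f} um^3 exceeds the packable "
            f"~{vol_max:.1f} um^3; lower the volume or widen the envelope")

    chains, radii_per_chain = [], []
    for (sx, sy, r_i) in sites:
        band = _chain_band(gen, np.hypot(sx, sy), r_i, amp)
        if band is None:
            continue
        zs_b, ravail_b, za, zb = band
        if zb - za < max(0.3, 1.5 * r_i):
            continue
        nodes = [np.array([sx, sy, za])]
        ox = oy = 0.0
        z = za
        while z < zb - 1e-9:
            theta = float(_vmf_polar(rng, spec.disorder_kappa)[0])
            st, ct = np.sin(theta), max(np.cos(theta), 0.2)
            L = min(seg_len, (zb - z) / ct)
            if st > 1e-9:
                L = min(L, 2.0 * amp / st)  # bounce within the wobble tube
            L = max(L, 0.05)
            if spec.planar:
                # zigzag in the XZ plane so the central slice sees the chain
                sign = -np.sign(ox) if abs(ox) > 0.3 * amp else (
                    1.0 if rng.random() < 0.5 else -1.0)
                step = np.array([sign * st * L, 0.0])
            else:
                if np.hypot(ox, oy) > 0.3 * amp:
                    phi = np.arctan2(-oy, -ox) + (rng.random() - 0.5) * np.pi / 2
                else:
                    phi = rng.random() * 2 * np.pi
                step = st * L * np.array([np.cos(phi), np.sin(phi)])
            onew = np.hypot(ox + step[0], oy + step[1])
            if onew > amp:  # shrink this segment to stay inside the wobble band
                L *= max(0.2, 0.95 * amp / onew)
                step = step * max(0.2, 0.95 * amp / onew)
                if np.hypot(ox + step[0], oy + step[1]) > amp:
                    # point the (shortened) step straight back at the axis
                    inward = -np.array([ox, oy])
                    nrm = np.linalg.norm(inward)
                    if nrm > 0:
                        step = inward / nrm * min(np.linalg.norm(step), nrm)
            ox, oy = ox + step[0], oy + step[1]
            z = min(z + ct * L, zb)
            nodes.append(np.array([sx + ox, sy + oy, z]))
        nodes = np.array(nodes)
        # erode the available-radius profile so tilted rings near the steep
        # taper cannot poke outside: take the running minimum over a window
        # of half the local tube radius
        from scipy.ndimage import minimum_filter1d
        dz_grid = zs_b[1] - zs_b[0] if len(zs_b) > 1 else 1.0
        win = max(1, int(1.0 * min(r_i, ravail_b.max()) / dz_grid))
        eroded = minimum_filter1d(ravail_b, size=2 * win + 1, mode="nearest")
        r_nodes = np.minimum(r_i, np.interp(nodes[:, 2], zs_b, eroded))
        chains.append(nodes)
        radii_per_chain.append(np.maximum(r_nodes, 0.5 * _CHAIN_R_MIN))

    # true capacity: build at full radii once, then rescale toward the target
    full = [_tube_mesh(c, np.maximum(r, 0.5 * _CHAIN_R_MIN))
            for c, r in zip(chains, radii_per_chain)]
    vol_build = sum(abs(m.volume) for m in full)
    if vol_build < spec.target_volume:
        raise PackingError(
            f"target volume {spec.target_volume:.1f} um^3 exceeds the packable "
            f"~{vol_build:.1f} um^3; lower the volume or widen the envelope")
    # common radius scale hitting the target volume: tube volume ~ scale^2
    scale = np.sqrt(spec.target_volume / vol_build)
    meshes = None
    for _ in range(4):
        meshes = [_tube_mesh(c, np.maximum(r * scale, 0.5 * _CHAIN_R_MIN))
                  for c, r in zip(chains, radii_per_chain)]
        total = sum(abs(m.volume) for m in meshes)
        err = abs(total - spec.target_volume) / spec.target_volume
        if err < 0.005:
            break
        scale = scale * np.sqrt(spec.target_volume / total)
        if scale > 1.0 + 1e-6:
            raise PackingError("chains cannot reach the target volume")
    skels = []
    for i, c in enumerate(chains):
        edges = np.column_stack([np.arange(len(c) - 1), np.arange(1, len(c))])
        skels.append(Skeleton(c, edges, name=f"mito_{i:03d}"))
    return meshes, skels


def _ring_sites(gen, r_cap, amp, planar, n_max, rng):
    """Hexagonal lattice (or planar row) sites with per-site tube radii.

    Interior sites take the full cap radius; edge sites shrink to whatever
    still fits against the envelope's widest cross-section, mirroring the
    thick-core / thin-periphery build of real bundles.  The lattice
    orientation is randomized per seed.
    """
    wob = amp + 0.01  # wobble band plus miter-joint allowance
    R_out = gen[:, 1].max() - wob - CLEARANCE_UM
    s = 2 * (r_cap + wob) + CLEARANCE_UM
    sites = []
    if planar:
        k = 0
        while len(sites) < n_max:
            added = False
            for x in ([0.0] if k == 0 else [k * s, -k * s]):
                r_i = min(r_cap, R_out - abs(x))
                if r_i >= _CHAIN_R_MIN and len(sites) < n_max:
                    sites.append((x, 0.0, r_i))
                    added = True
            if not added:
                break
            k += 1
        return sites
    th = rng.random() * 2 * np.pi  # seed-dependent lattice orientation
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    for p in _hex_lattice(max(4 * n_max, 64)) @ R.T * s:
        rad = float(np.hypot(p[0], p[1]))
        r_i = min(r_cap, R_out - rad)
        if r_i < _CHAIN_R_MIN:
            continue  # later (outer) sites may still fit after rotation jitter
        sites.append((float(p[0]), float(p[1]), float(r_i)))
        if len(sites) >= n_max:
            break
    return sites


def _chain_band(gen, site_radius, r_i, amp):
    """Vertical band and available tube radius profile at one site.

    Returns (z samples, available radius at each z), where available =
    envelope profile minus the site's lateral position and margins, capped at
    the site's nominal radius; the band is where at least the minimum tube
    radius fits.
    """
    zlo, zhi = gen[0, 0], gen[-1, 0]
    zs = np.linspace(zlo, zhi, 257)
    ravail = np.clip(
        _profile_radius(gen, zs) - site_radius - amp - 0.01 - CLEARANCE_UM,
        0.0, None)
    ok = ravail >= _CHAIN_R_MIN
    if not ok.any():
        return None
    i0, i1 = np.argmax(ok), len(ok) - np.argmax(ok[::-1]) - 1
    # shrink ends by the local tube radius so caps stay inside
    z0 = zs[i0] + min(r_i, max(ravail[i0], _CHAIN_R_MIN)) + CLEARANCE_UM
    z1 = zs[i1] - min(r_i, max(ravail[i1], _CHAIN_R_MIN)) - CLEARANCE_UM
    if z1 <= z0:
        return None
    # full-range arrays: the radius erosion must see the profile collapsing
    # beyond the band ends (tilted rings near the tip extend past their node)
    return zs, np.minimum(ravail, r_i), z0, z1


def _tube_mesh(nodes: np.ndarray, radius, sections: int = 16) -> trimesh.Trimesh:
    """Watertight tube swept along a polyline, with flat end caps.

    ``radius`` may be a scalar or a per-node array (tapering tube).  Ring
    frames are parallel-transported along the path to avoid twist; at
    interior nodes the ring is perpendicular to the average of the adjacent
    segment directions (miter joint).
    """
    nodes = np.asarray(nodes, float)
    radii = np.broadcast_to(np.asarray(radius, float), (len(nodes),))
    segs = np.diff(nodes, axis=0)
    seg_dirs = segs / np.linalg.norm(segs, axis=1, keepdims=True)
    m = len(nodes)
    # node directions (miter at interior nodes); end rings horizontal so caps
    # never extend beyond the end nodes' z planes
    ndirs = np.empty_like(nodes)
    ndirs[0] = [0.0, 0.0, np.sign(seg_dirs[0, 2]) or 1.0]
    ndirs[-1] = [0.0, 0.0, np.sign(seg_dirs[-1, 2]) or 1.0]
    for i in range(1, m - 1):
        v = seg_dirs[i - 1] + seg_dirs[i]
        ndirs[i] = v / np.linalg.norm(v)
    # parallel-transported frame
    u = np.cross(ndirs[0], [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(ndirs[0], [0.0, 1.0, 0.0])
    u = u / np.linalg.norm(u)
    theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    verts = []
    for i in range(m):
        if i > 0:
            # rotate u from previous direction to current
            a, b = ndirs[i - 1], ndirs[i]
            v = np.cross(a, b)
            c = float(a @ b)
            if np.linalg.norm(v) > 1e-12 and c > -0.999:
                vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
                R = np.eye(3) + vx + vx @ vx / (1.0 + c)
                u = R @ u
            u = u - (u @ ndirs[i]) * ndirs[i]
            u = u / np.linalg.norm(u)
        w = np.cross(ndirs[i], u)
        ring = (nodes[i][None, :] + radii[i] * (np.outer(np.cos(theta), u)
                                                + np.outer(np.sin(theta), w)))
        verts.append(ring)
    verts = np.vstack(verts)
    faces = []
    for i in range(m - 1):
        a0, b0 = i * sections, (i + 1) * sections
        for s in range(sections):
            s2 = (s + 1) % sections
            faces.append([a0 + s, a0 + s2, b0 + s])
            faces.append([a0 + s2, b0 + s2, b0 + s])
    verts = np.vstack([verts, nodes[0], nodes[-1]])
    c0, c1 = len(verts) - 2, len(verts) - 1
    for s in range(sections):
        s2 = (s + 1) % sections
        faces.append([s2, s, c0])
        faces.append([(m - 1) * sections + s, (m - 1) * sections + s2, c1])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces, int), process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh



def _pack_spheres(spec, gen, rng):
    """Volume-matched equal spheres on a hexagonal-close-packed lattice.

    Random sequential placement cannot reach the density of a volume-matched
    configuration, so spheres sit on an HCP lattice clipped to the envelope;
    the ``n_mito`` most central lattice sites are kept, giving exactly
    ``n_mito`` equal bodies whose radius follows from the target volume.
    """
    n = spec.n_mito
    if n < 1:
        raise PackingError("spheres configuration needs n_mito >= 1")
    r = (3.0 * spec.target_volume / (4.0 * np.pi * n)) ** (1.0 / 3.0)
    zlo, zhi = gen[0, 0], gen[-1, 0]
    s = 2.0 * r + CLEARANCE_UM
    dz = s * np.sqrt(2.0 / 3.0)
    sites = []  # (center, radius): wall sites shrink to fit
    layer = 0
    z = zlo + 0.4 * r + CLEARANCE_UM
    while z <= zhi - 0.4 * r + 1e-9:
        # hexagonal layer with alternating A/B offsets
        off = np.array([0.5, np.sqrt(3) / 6]) * s if layer % 2 else np.zeros(2)
        for row in range(-6, 7):
            for col in range(-6, 7):
                if spec.planar and row != 0:
                    continue
                xy = (np.array([col + 0.5 * (row % 2), row * np.sqrt(3) / 2])
                      * s + off)
                c = np.array([xy[0], 0.0 if spec.planar else xy[1], z])
                # largest radius <= r fitting the envelope at this site
                for r_i in r * np.array([1.0, 0.85, 0.7, 0.55, 0.4]):
                    if _inside_envelope(gen, c, c, r_i, CLEARANCE_UM, n_check=1):
                        sites.append((c, float(r_i)))
                        break
        layer += 1
        z += dz
    if len(sites) < n:
        raise PackingError(
            f"only {len(sites)} HCP sites fit {n} spheres near radius {r:.2f} "
            "um; lower the target volume or n_mito")
    sites = sorted(sites, key=lambda cr: (-cr[1], np.hypot(cr[0][0], cr[0][1]),
                                          abs(cr[0][2] - 0.5 * (zlo + zhi))))[:n]
    total = sum(4.0 * np.pi * r_i ** 3 / 3.0 for _, r_i in sites)
    scale = (spec.target_volume / total) ** (1.0 / 3.0)
    if scale > 1.0 + 1e-9:
        raise PackingError(
            f"HCP sphere sites hold only {total:.1f} um^3 of the "
            f"{spec.target_volume:.1f} um^3 target; lower the volume or n_mito")
    meshes, skels = [], []
    for i, (c, r_i) in enumerate(sites):
        r_s = r_i * scale
        m = trimesh.creation.icosphere(subdivisions=3, radius=r_s)
        m.apply_scale((4.0 * np.pi * r_s ** 3 / 3.0 / m.volume) ** (1.0 / 3.0))
        m.apply_translation(c)
        meshes.append(m)
        skels.append(Skeleton(
            np.vstack([c - [0, 0, 0.5 * r_s], c + [0, 0, 0.5 * r_s]]),
            [[0, 1]], name=f"mito_{i:03d}"))
    return meshes, skels


def _make_mega(spec, gen):
    """Single lofted body: radially shrunk copy of the envelope profile."""
    zlo, zhi = gen[0, 0], gen[-1, 0]
    length = zhi - zlo
    z = np.linspace(zlo + 0.04 * length, zlo + 0.90 * length, 49)
    r_env = _profile_radius(gen, z)
    # smooth taper of both ends so the solid closes
    tf = np.sin(np.linspace(0.0, np.pi, len(z))) ** 0.25
    base = r_env * tf
    integral = np.pi * np.trapezoid(base ** 2, z)
    c = np.sqrt(spec.target_volume / integral)
    r = np.minimum(base * c, np.maximum(r_env - 2 * CLEARANCE_UM, 0.0))
    mesh = _revolve(z, r, 48)
    # correct the discrete + clipping volume error by one radial rescale
    s = np.sqrt(spec.target_volume / mesh.volume)
    mesh = _revolve(z, np.minimum(r * s, np.maximum(r_env - CLEARANCE_UM, 0.0)), 48)
    if abs(mesh.volume - spec.target_volume) / spec.target_volume > 0.01:
        raise PackingError("megamitochondrion cannot reach the target volume "
                           "inside this envelope")
    nodes = np.column_stack([np.zeros(9), np.zeros(9),
                             np.linspace(z[0], z[-1], 9)])
    edges = np.column_stack([np.arange(8), np.arange(1, 9)])
    return [mesh], [Skeleton(nodes, edges, name="mito_000")]


def bundle_preset(name: str, envelope: trimesh.Trimesh, seed: int = 0,
                  fill_fraction: float = 0.30, n_mito: int | None = None) -> BundleSpec:
    """Study presets.

    ``active``: elongated aligned bundle filling ``fill_fraction`` of the
    envelope; ``hibernating``: disordered bundle at 70% of the active volume
    (the hibernation-associated volume loss).  ``spheres`` and ``mega`` are the
    volume-matched alternative configurations.
    """
    v_active = fill_fraction * mesh_volume(envelope)
    defaults = {"active": 25, "hibernating": 25, "spheres": 28, "mega": 1}
    if name not in defaults:
        raise ValueError(f"unknown preset {name!r}")
    n = defaults[name] if n_mito is None else n_mito
    presets = {
        "active": dict(configuration="elongated", n_mito=n,
                       target_volume=v_active, disorder_kappa=KAPPA_ACTIVE),
        "hibernating": dict(configuration="disordered", n_mito=n,
                            target_volume=0.70 * v_active,
                            disorder_kappa=KAPPA_HIBERNATING),
        "spheres": dict(configuration="spheres", n_mito=n,
                        target_volume=v_active),
        "mega": dict(configuration="mega", n_mito=1, target_volume=v_active),
    }
    return BundleSpec(seed=seed, **presets[name])


# ---------------------------------------------------------------------------
# cristae spectrum


def make_cristae_spec(n_terms: int, freq_range_per_um=(1.5, 4.0), seed: int = 0,
                      membrane_halfwidth_um: float = 0.005):
    """Random cristae field specification: a sum of 3D cosines with isotropic
    frequency directions, random phases, and random amplitudes.

    Deterministic for a fixed seed.  The field partitions a mitochondrion's
    interior into matrix (f > 0), intramembrane space (f < 0), and an internal
    membrane band where |f| / ||grad f|| falls below the membrane halfwidth.
    """
    from .dielectric_grid import CristaeSpec

    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    lo, hi = freq_range_per_um
    if lo < 0 or hi <= 0 or hi < lo:
        raise ValueError("freq_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_terms, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    mags = lo + (hi - lo) * rng.random(n_terms)
    freqs = dirs * mags[:, None]
    phases = rng.random(n_terms) * 2 * np.pi
    amps = 0.5 + 0.5 * rng.random(n_terms)
    return CristaeSpec(frequencies=freqs, phases=phases, amplitudes=amps,
                       membrane_halfwidth_um=membrane_halfwidth_um, seed=seed)


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(spec: CohortSpec):
    """Two grouped OSR-concentration value sets: group -> {animal -> values}.

    value = group mean + animal effect (SD between) + cone noise (SD within).
    """
    rng = np.random.default_rng(spec.seed)
    groups = []
    for g, mean in enumerate(spec.group_means):
        animals = {}
        for a in range(spec.n_animals_per_group):
            effect = rng.normal(0.0, spec.between_animal_sd) if spec.between_animal_sd else 0.0
            n = spec.cones_per_animal[a]
            noise = rng.normal(0.0, spec.within_animal_sd, n) if spec.within_animal_sd else np.zeros(n)
            animals[f"g{g}a{a}"] = mean + effect + noise
        groups.append(animals)
    return tuple(groups)


# ---------------------------------------------------------------------------
# model I/O


def write_model(model: ConeModel, out_dir, fmt: str = "obj") -> None:
    """Write a ConeModel as mesh files (+ JSON metadata + skeleton XML).

    ``fmt`` is any extension trimesh can export (obj, ply, stl, ...).
    """
    from .alignment_morphometry import write_skeletons

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.envelope.export(out / f"envelope.{fmt}")
    for i, m in enumerate(model.mitochondria):
        m.export(out / f"mito_{i:03d}.{fmt}")
    meta = {
        "n_mitochondria": len(model.mitochondria),
        "format": fmt,
        "anatomical_axis": model.anatomical_axis.tolist(),
        "distal_tip": model.distal_tip.tolist(),
        "tilt_deg": model.tilt_deg,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    if model.skeletons is not None:
        write_skeletons(model.skeletons, out / "skeletons.xml")


def read_model(model_dir) -> ConeModel:
    from .alignment_morphometry import read_skeletons

    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    fmt = meta.get("format", "obj")
    envelope = trimesh.load(d / f"envelope.{fmt}", force="mesh")
    envelope.metadata["label"] = "envelope"
    mitos = []
    for i in range(meta["n_mitochondria"]):
        m = trimesh.load(d / f"mito_{i:03d}.{fmt}", force="mesh")
        m.metadata["label"] = "mitochondrion"
        mitos.append(m)
    skels = None
    if (d / "skeletons.xml").exists():
        skels = read_skeletons(d / "skeletons.xml")
    return ConeModel(envelope=envelope, mitochondria=mitos, skeletons=skels,
                     anatomical_axis=np.asarray(meta["anatomical_axis"]),
                     distal_tip=np.asarray(meta["distal_tip"]),
                     tilt_deg=meta["tilt_deg"])
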