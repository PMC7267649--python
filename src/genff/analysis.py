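"""Structure/trajectory analysis and the built-in molecule fixtures.

Provides optimal rigid superposition (Kabsch, SVD with proper-rotation
correction), distance/angle distributions over trajectories, mean absolute
deviation, and a deterministic generator of small idealized molecules used
throughout the test-suite and documentation (geometries assembled from
textbook equilibrium bond lengths and angles).
"""

from __future__ import annotations

import math

import numpy as np

from .errors import AlignmentError, InsufficientSamplingError
from .io import Molecule

DEG = math.pi / 180.0


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch_rmsd(a: Molecule, b: Molecule, heavy_only: bool = False):
    """Minimum RMSD (Angstrom) after optimal rigid superposition of b on a.

    Atom ordering must agree; no correspondence search is attempted.
    Returns (rmsd, rotation, translation) with x_b @ rotation + translation
    approximating x_a for the selected atoms.
    """
    if a.n_atoms != b.n_atoms or np.any(a.atomic_numbers != b.atomic_numbers):
        raise AlignmentError("atom count or element sequence mismatch")
    sel = np.ones(a.n_atoms, bool)
    if heavy_only:
        sel = a.atomic_numbers != 1
        if not np.any(sel):
            raise AlignmentError("no heavy atoms to align")
    pa = a.coords[sel]
    pb = b.coords[sel]
    ca = pa.mean(0)
    cb = pb.mean(0)
    qa = pa - ca
    qb = pb - cb
    h = qb.T @ qa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    diff = qb @ rot - qa
    rmsd = float(np.sqrt((diff**2).sum() / sel.sum()))
    trans = ca - cb @ rot
    return rmsd, rot, trans


def mad(values, refs) -> float:
    """Mean absolute deviation between two equal-length value lists."""
    v = np.asarray(values, float)
    r = np.asarray(refs, float)
    if v.shape != r.shape or v.ndim != 1 or len(v) < 1:
        raise ValueError("mad needs two equal-length 1-D lists")
    return float(np.abs(v - r).mean())


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


class Distribution:
    """Normalized histogram with bin edges and mode location."""

    def __init__(self, samples: np.ndarray, bins=None):
        samples = np.asarray(samples, float)
        if bins is None:
            # Freedman-Diaconis, with a sane fallback for degenerate spread
            q75, q25 = np.percentile(samples, [75, 25])
            iqr = q75 - q25
            if iqr > 1e-12:
                width = 2.0 * iqr / len(samples) ** (1.0 / 3.0)
                nbins = max(int(np.ceil((samples.max() - samples.min()) / width)), 1)
                bins = min(nbins, 1000)
            else:
                center = float(samples.mean())
                bins = np.linspace(center - 0.5, center + 0.5, 11)
        density, edges = np.histogram(samples, bins=bins, density=True)
        self.bin_edges = edges
        self.density = density
        self.mode_location = self._mode(density, edges)

    @staticmethod
    def _mode(density, edges) -> float:
        """Peak location: moving-average smoothing against bin noise, then
        three-point parabolic interpolation around the maximum bin."""
        centers = 0.5 * (edges[:-1] + edges[1:])
        if len(density) < 5:
            return float(centers[int(np.argmax(density))])
        width = max(5, (len(density) // 8) | 1)
        kernel = np.ones(width) / width
        smooth = np.convolve(density, kernel, mode="same")
        peaks = np.flatnonzero(smooth == smooth.max())
        k = int(peaks[len(peaks) // 2])  # middle of a tied plateau
        if 0 < k < len(smooth) - 1:
            y0, y1, y2 = smooth[k - 1], smooth[k], smooth[k + 1]
            denom = y0 - 2.0 * y1 + y2
            if abs(denom) > 1e-300:
                shift = 0.5 * (y0 - y2) / denom
                shift = float(np.clip(shift, -1.0, 1.0))
                return float(centers[k] + shift * (centers[1] - centers[0]))
        return float(centers[k])

    def integral(self) -> float:
        return float((self.density * np.diff(self.bin_edges)).sum())


def distance_angle_distributions(traj, r_pair, xi_triple, bins=None):
    """P(r) over an interatomic distance and P(xi) over an angle (degrees),
    sampled across all trajectory frames."""
    from .constants import ANGSTROM_PER_BOHR

    frames = traj.frames
    if len(frames) < 10:
        raise InsufficientSamplingError(
            f"{len(frames)} frames; at least 10 required"
        )
    i, j = r_pair
    a, b, c = xi_triple
    rs, xis = [], []
    for fr in frames:
        xyz = np.asarray(fr.coords_bohr) * ANGSTROM_PER_BOHR
        rs.append(np.linalg.norm(xyz[i] - xyz[j]))
        u = xyz[a] - xyz[b]
        v = xyz[c] - xyz[b]
        cosx = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        xis.append(math.degrees(math.acos(np.clip(cosx, -1.0, 1.0))))
    return Distribution(np.array(rs), bins), Distribution(np.array(xis), bins)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _rot2(v, ang):
    c, s = math.cos(ang), math.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _butadiene() -> tuple:
    # s-trans 1,3-butadiene, planar; C=C 1.338 A, C-C 1.454 A, CCC 123.6 deg
    r_cc = [1.338, 1.454, 1.338]
    turn = (180.0 - 123.6) * DEG
    pos = [np.zeros(2)]
    d = np.array([1.0, 0.0])
    sign = 1.0
    for k in range(3):
        pos.append(pos[-1] + r_cc[k] * d)
        d = _rot2(d, sign * turn)
        sign = -sign
    carbons = [np.array([p[0], p[1], 0.0]) for p in pos]
    zs = [6, 6, 6, 6]
    xyz = list(carbons)
    r_ch = 1.09
    for k, c in enumerate(carbons):
        neigh = [carbons[m] for m in (k - 1, k + 1) if 0 <= m <= 3]
        units = [(n - c) / np.linalg.norm(n - c) for n in neigh]
        if len(units) == 2:  # inner carbon: one in-plane H
            h_dir = -(units[0] + units[1])
            h_dir /= np.linalg.norm(h_dir)
            xyz.append(c + r_ch * h_dir)
            zs.append(1)
        else:  # terminal carbon: two in-plane H at +-120 deg from the C-C bond
            u2 = units[0][:2]
            for ang in (120.0 * DEG, -120.0 * DEG):
                h2 = _rot2(u2, ang)
                xyz.append(c + r_ch * np.array([h2[0], h2[1], 0.0]))
                zs.append(1)
    return zs, np.array(xyz)


def _glycine_dipeptide() -> tuple:
    """Glycylglycine H2N-CH2-C(=O)-NH-CH2-COOH, idealized near-planar
    backbone with out-of-plane methylene hydrogens."""
    # backbone zig-zag in the xy plane, 114 deg turns
    lengths = [1.45, 1.52, 1.33, 1.45, 1.52, 1.36]  # N-C, C-C', C'-N, N-C, C-C', C-O
    pos = [np.zeros(2)]
    d = np.array([1.0, 0.0])
    sign = 1.0
    turn = (180.0 - 114.0) * DEG
    for ln in lengths:
        pos.append(pos[-1] + ln * d)
        d = _rot2(d, sign * turn)
        sign = -sign
    n1, c2, c3, n5, c6, c7, o9 = [np.array([p[0], p[1], 0.0]) for p in pos]

    def unit(a, b):
        v = b - a
        return v / np.linalg.norm(v)

    def in_plane_sub(center, n_a, n_b, r):
        w = -(unit(center, n_a) + unit(center, n_b))
        w /= np.linalg.norm(w)
        return center + r * w

    def out_of_plane_pair(center, n_a, n_b, r, half_angle=54.0 * DEG):
        bis = -(unit(center, n_a) + unit(center, n_b))
        bis /= np.linalg.norm(bis)
        zax = np.array([0.0, 0.0, 1.0])
        out = []
        for s in (1.0, -1.0):
            w = math.cos(half_angle) * bis + s * math.sin(half_angle) * zax
            out.append(center + r * w)
        return out

    zs, xyz = [], []

    def add(z, p):
        zs.append(z)
        xyz.append(p)

    add(7, n1)
    # terminal NH2: two in-plane-ish hydrogens
    u12 = unit(n1, c2)
    for ang in (118.0 * DEG, -118.0 * DEG):
        h2 = _rot2(u12[:2], ang)
        add(1, n1 + 1.01 * np.array([h2[0], h2[1], 0.0]))
    add(6, c2)
    for h in out_of_plane_pair(c2, n1, c3, 1.09):
        add(1, h)
    add(6, c3)
    # carbonyl O opposite the backbone continuation
    add(8, in_plane_sub(c3, c2, n5, 1.23))
    add(7, n5)
    add(1, in_plane_sub(n5, c3, c6, 1.01))
    add(6, c6)
    for h in out_of_plane_pair(c6, n5, c7, 1.09):
        add(1, h)
    add(6, c7)
    add(8, in_plane_sub(c7, c6, o9, 1.23))  # carbonyl O of the acid
    add(8, o9)
    u_oh = _rot2(unit(o9, c7)[:2], 111.0 * DEG)
    add(1, o9 + 0.97 * np.array([u_oh[0], u_oh[1], 0.0]))
    return zs, np.array(xyz)


def _water(origin=np.zeros(3)):
    return (
        [8, 1, 1],
        np.array(
            [
                [0.0, 0.0, 0.0],
                [0.9572, 0.0, 0.0],
                [
                    0.9572 * math.cos(104.52 * DEG),
                    0.9572 * math.sin(104.52 * DEG),
                    0.0,
                ],
            ]
        )
        + origin,
    )


def _fixture_registry():
    reg = {}

    def water():
        return _water()

    def ammonia():
        # r(NH) = 1.0116 A, HNH = 106.7 deg
        rho, h = 0.93718, 0.38080
        xyz = [[0.0, 0.0, 0.0]]
        for k in range(3):
            ang = k * 120.0 * DEG
            xyz.append([rho * math.cos(ang), rho * math.sin(ang), -h])
        return [7, 1, 1, 1], np.array(xyz)

    def methane():
        a = 1.089 / math.sqrt(3.0)
        return [6, 1, 1, 1, 1], np.array(
            [
                [0, 0, 0],
                [a, a, a],
                [a, -a, -a],
                [-a, a, -a],
                [-a, -a, a],
            ],
            dtype=float,
        )

    def ethane():
        # staggered; C-C 1.536, C-H 1.091, HCC 111.2 deg
        zc = 0.768
        rho = 1.091 * math.sin(68.8 * DEG)
        zh = zc + 1.091 * math.cos(68.8 * DEG)
        zs = [6, 6]
        xyz = [[0, 0, zc], [0, 0, -zc]]
        for k in range(3):
            ang = k * 120.0 * DEG
            xyz.append([rho * math.cos(ang), rho * math.sin(ang), zh])
            zs.append(1)
        for k in range(3):
            ang = (60.0 + k * 120.0) * DEG
            xyz.append([rho * math.cos(ang), rho * math.sin(ang), -zh])
            zs.append(1)
        return zs, np.array(xyz)

    def ethylene():
        # planar; C=C 1.339, C-H 1.087, HCC 121.3 deg
        xc = 1.339 / 2.0
        hx = xc + 1.087 * math.cos(58.7 * DEG)
        hy = 1.087 * math.sin(58.7 * DEG)
        return [6, 6, 1, 1, 1, 1], np.array(
            [
                [xc, 0, 0],
                [-xc, 0, 0],
                [hx, hy, 0],
                [hx, -hy, 0],
                [-hx, hy, 0],
                [-hx, -hy, 0],
            ]
        )

    def butadiene():
        return _butadiene()

    def benzene():
        # D6h; C-C 1.391 A -> ring radius 1.391, C-H 1.080
        zs, xyz = [], []
        for k in range(6):
            ang = k * 60.0 * DEG
            zs.append(6)
            xyz.append([1.391 * math.cos(ang), 1.391 * math.sin(ang), 0.0])
        for k in range(6):
            ang = k * 60.0 * DEG
            zs.append(1)
            xyz.append([2.471 * math.cos(ang), 2.471 * math.sin(ang), 0.0])
        return zs, np.array(xyz)

    def water_dimer():
        # near-linear O-H...O hydrogen bond, O...O = 2.976 A
        zs_a = [8, 1, 1]
        tilt = 125.0 * DEG
        half = 104.52 / 2.0 * DEG
        # acceptor water: O at origin; its bisector makes ~125 deg with the
        # O...O axis and its molecular plane is perpendicular to the dimer
        # plane, so both hydrogens point well away from the incoming H
        bis = np.array([math.cos(tilt), 0.0, math.sin(tilt)])
        perp = np.array([0.0, 1.0, 0.0])
        xyz_a = [[0.0, 0.0, 0.0]]
        for s in (1.0, -1.0):
            d = math.cos(half) * bis + s * math.sin(half) * perp
            xyz_a.append((0.9572 * d).tolist())
        od = np.array([2.976, 0.0, 0.0])
        hd1 = od + np.array([-0.9572, 0.0, 0.0])  # donor H on the O-O line
        d2 = np.array(
            [math.cos(75.48 * DEG), math.sin(75.48 * DEG), 0.0]
        )
        hd2 = od + 0.9572 * d2
        return zs_a + [8, 1, 1], np.array(xyz_a + [od, hd1, hd2])

    def hf_dimer():
        # F...F = 2.72 A, donor H on the axis, acceptor tilted ~110 deg
        f2 = np.array([2.72, 0.0, 0.0])
        h2 = f2 + 0.9169 * np.array(
            [math.cos(110.0 * DEG), math.sin(110.0 * DEG), 0.0]
        )
        return [9, 1, 9, 1], np.array(
            [[0.0, 0.0, 0.0], [0.9169, 0.0, 0.0], f2, h2]
        )

    def nacl():
        return [11, 17], np.array([[0.0, 0.0, 0.0], [2.3609, 0.0, 0.0]])

    def helium_dimer():
        return [2, 2], np.array([[0.0, 0.0, 0.0], [2.97, 0.0, 0.0]])

    def glycine_dipeptide():
        return _glycine_dipeptide()

    for fn in (
        water,
        ammonia,
        methane,
        ethane,
        ethylene,
        butadiene,
        benzene,
        water_dimer,
        hf_dimer,
        nacl,
        helium_dimer,
        glycine_dipeptide,
    ):
        reg[fn.__name__] = fn
    return reg


_REGISTRY = _fixture_registry()

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def generate_fixture(name: str) -> Molecule:
    """Deterministic idealized geometry for one of the built-in molecules."""
    try:
        fn = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    zs, xyz = fn()
    return Molecule(np.array(zs), np.array(xyz, float), 0, name)
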