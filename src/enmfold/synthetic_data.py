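"""Deterministic synthetic structures for exercising every pipeline stage.

Real crystal structures are large and cannot be shipped with the test
suite, so each analysis stage is validated on generated models with
known, controllable properties:

* ``make_path_chain`` — collinear CA trace whose GNM is the path-graph
  Laplacian with a closed-form spectrum.
* ``make_helix`` — ideal alpha-helical CA spiral; in full-atom mode the
  backbone (N, CA, C, O, amide H) is built from ideal internal
  coordinates so the i -> i+4 hydrogen-bond ladder is present.
* ``make_globule`` / ``make_dumbbell`` — protein-density random globules
  (rejection-sampled, connectivity asserted) and two dense lattice cores
  joined by a thin arched linker: the canonical weakest-link test bed.
* ``make_sheet_hairpin`` — two antiparallel extended CA strands.
* ``make_charged_pair`` — Asp and Lys side chains posed at a requested
  closest O-N distance for salt-bridge threshold tests.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .structure_io import CaModel, Residue, write_pdb

__all__ = [
    "make_path_chain",
    "make_helix",
    "make_sheet_hairpin",
    "make_globule",
    "make_dumbbell",
    "make_charged_pair",
    "emit_fixture",
]

# Mean volume per residue in folded proteins (A^3); sets globule density
# so that the 7 A contact shell holds a protein-like 6-8 neighbors.
RESIDUE_VOLUME = 115.0
MIN_PAIR_DISTANCE = 3.5


def _ca_model(coords, source_id, names=None, chain_breaks=(), bfactors=None,
              start_number=1):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or ["ALA"] * n
    bfactors = bfactors if bfactors is not None else np.zeros(n)
    residues = [
        Residue(
            chain_id="A",
            seq_number=start_number + i,
            insertion_code="",
            name=names[i],
            ca_coord=coords[i],
            bfactor_exp=float(bfactors[i]),
        )
        for i in range(n)
    ]
    return CaModel(residues=residues, source_id=source_id,
                   chain_breaks=set(chain_breaks))


def make_path_chain(n: int, spacing: float = 3.8) -> CaModel:
    """Collinear CA trace along +x.

    With ``spacing`` above half the GNM cutoff only nearest neighbors
    are in contact, so the Kirchhoff matrix is the path-graph Laplacian
    with eigenvalues 4 sin^2(k pi / 2n).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    return _ca_model(coords, f"path_chain_n{n}")


# Ideal backbone internal coordinates (lengths A, angles deg).
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_N_H = 1.010
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5
# Dihedrals in the alpha-helical basin chosen so the ideal backbone
# realizes the canonical i -> i+4 ladder at ~2.86 A N..O.
_HELIX_PHI = -62.0
_HELIX_PSI = -47.0
_OMEGA = 180.0


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF: position of d given chain a-b-c and internal coordinates of c-d."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(n, phi, psi, omega=_OMEGA):
    """Backbone N/CA/C positions for n residues at fixed (phi, psi)."""
    ncac = []
    # bootstrap first residue in an arbitrary frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    ncac.append((n0, ca0, c0))
    for _ in range(1, n):
        n_prev, ca_prev, c_prev = ncac[-1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_i = _place_atom(ca_prev, c_prev, n_i, _BOND_N_CA, _ANGLE_C_N_CA, omega)
        c_i = _place_atom(c_prev, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        ncac.append((n_i, ca_i, c_i))
    return ncac


def make_helix(
    n: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    full_atom: bool = False,
) -> CaModel:
    """Ideal alpha-helix.

    CA-only mode places CA atoms on a spiral with the given rise, twist
    and radius.  Full-atom mode instead builds the backbone from ideal
    internal coordinates at (phi, psi) = (-62, -47), which realizes the
    canonical i -> i+4 hydrogen-bond ladder, and adds the carbonyl O and
    amide H needed by the hydrogen-bond detector.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not full_atom:
        t = np.deg2rad(twist) * np.arange(n)
        coords = np.stack(
            [radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)], axis=1
        )
        return _ca_model(coords, f"helix_n{n}")
    ncac = _build_backbone(n, _HELIX_PHI, _HELIX_PSI)
    residues = []
    for i, (n_i, ca_i, c_i) in enumerate(ncac):
        atoms = [("N", "N", n_i), ("CA", "C", ca_i), ("C", "C", c_i)]
        # carbonyl O in the peptide plane, anti to the next N
        if i + 1 < n:
            n_next = ncac[i + 1][0]
            o_i = _place_atom(n_next, ca_i, c_i, _BOND_C_O, _ANGLE_CA_C_O, 180.0)
        else:
            o_i = _place_atom(n_i, ca_i, c_i, _BOND_C_O, _ANGLE_CA_C_O,
                              _HELIX_PSI + 180.0)
        atoms.append(("O", "O", o_i))
        # amide H along the bisector of (N-C_prev, N-CA), i.e. trans-planar
        if i > 0:
            c_prev = ncac[i - 1][2]
            u = (n_i - c_prev) / np.linalg.norm(n_i - c_prev)
            v = (n_i - ca_i) / np.linalg.norm(n_i - ca_i)
            h = u + v
            h /= np.linalg.norm(h)
            atoms.append(("H", "H", n_i + _BOND_N_H * h))
        residues.append(
            Residue(
                chain_id="A",
                seq_number=i + 1,
                insertion_code="",
                name="ALA",
                ca_coord=np.asarray(ca_i, dtype=float),
                bfactor_exp=0.0,
                atoms=tuple(
                    (nm, el, np.asarray(xyz, dtype=float)) for nm, el, xyz in atoms
                ),
            )
        )
    return CaModel(residues=residues, source_id=f"helix_fa_n{n}")


def make_sheet_hairpin(n_strand: int = 6, strand_sep: float = 4.8,
                       spacing: float = 3.4) -> CaModel:
    """Two antiparallel extended CA strands joined by a two-residue turn."""
    up = np.stack(
        [spacing * np.arange(n_strand), np.zeros(n_strand), np.zeros(n_strand)],
        axis=1,
    )
    turn = np.array(
        [
            [spacing * n_strand, strand_sep * 0.35, 0.0],
            [spacing * n_strand, strand_sep * 0.65, 0.0],
        ]
    )
    down = np.stack(
        [
            spacing * np.arange(n_strand - 1, -1, -1),
            np.full(n_strand, strand_sep),
            np.zeros(n_strand),
        ],
        axis=1,
    )
    coords = np.vstack([up, turn, down])
    return _ca_model(coords, f"hairpin_n{len(coords)}")


def _is_connected(coords, cutoff=7.0):
    d = squareform(pdist(coords))
    adj = (d <= cutoff).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def _sample_globule_points(n, rng):
    radius = (3.0 * n * RESIDUE_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
    points = []
    attempts = 0
    while len(points) < n:
        attempts += 1
        if attempts > 200000:
            raise RuntimeError("globule sampling failed; relax density")
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) > radius:
            continue
        if points and np.min(
            np.linalg.norm(np.asarray(points) - p, axis=1)
        ) < MIN_PAIR_DISTANCE:
            continue
        points.append(p)
    return np.asarray(points)


def _greedy_chain_order(points, start_at=None, end_at=None):
    """Order points by a greedy nearest-neighbor walk (chain-like path).

    The walk begins at ``start_at`` (default: the +x extreme); with
    ``end_at`` it instead begins there and the order is reversed, so the
    returned path terminates at that point.
    """
    n = len(points)
    if end_at is not None:
        start = end_at
    elif start_at is not None:
        start = start_at
    else:
        start = int(np.argmax(points[:, 0]))
    remaining = set(range(n)) - {start}
    order = [start]
    while remaining:
        last = points[order[-1]]
        nxt = min(remaining, key=lambda k: float(np.linalg.norm(points[k] - last)))
        order.append(nxt)
        remaining.remove(nxt)
    if end_at is not None:
        order.reverse()
    return order


def make_globule(n: int, seed: int = 0) -> CaModel:
    """Random protein-density globule with a connected 7 A GNM network.

    Points are rejection-sampled in a sphere at folded-protein density
    with a 3.5 A minimum pair distance (mean contact degree ~6-8 at the
    7 A cutoff), then chained by a greedy nearest-neighbor walk.
    Resampled with a derived seed until connected.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for attempt in range(50):
        rng = np.random.default_rng((seed, attempt))
        pts = _sample_globule_points(n, rng)
        if _is_connected(pts):
            order = _greedy_chain_order(pts)
            return _ca_model(pts[order], f"globule_n{n}_s{seed}")
    raise RuntimeError("could not generate a connected globule")


def _lattice_core(n, spacing=3.8):
    """The n cubic-lattice points closest to the origin: a stiff dense blob."""
    r = np.arange(-3, 4)
    pts = np.array([[x, y, z] for x in r for y in r for z in r], float) * spacing
    idx = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")[:n]
    return pts[idx]


def make_dumbbell(n_core: int = 15, n_linker: int = 2, seed: int = 0) -> CaModel:
    """Two dense clusters joined by a thin linker.

    The cores are compact lattice blobs (uniformly high contact degree,
    so even the chain termini are well anchored); the chain runs from
    the center of core A out to its surface, across a short gently
    arched 3.8 A-spaced linker, and back into the center of core B.
    The linker has no internal non-covalent contacts and only a couple
    of junction contacts onto the cluster surfaces; those junction
    contacts are, by construction, the most weakly supported part of
    the network and carry the largest distance fluctuations — the
    weakest-link test bed for the unfolding simulator.  The arch gives
    the core-about-linker torsion a small positive stiffness so the ANM
    has exactly six zero modes; a seeded 0.05 A jitter breaks lattice
    symmetry degeneracies without altering the contact topology.
    """
    if n_core < 8 or n_linker < 2:
        raise ValueError("need n_core >= 8 and n_linker >= 2")
    # chain A starts at the core center (anchored terminus) and its
    # greedy walk ends at a peripheral point: the linker junction
    a = _lattice_core(n_core)
    start_a = int(np.argmin(np.linalg.norm(a - a.mean(axis=0), axis=1)))
    a = a[_greedy_chain_order(a, start_at=start_a)]
    u = a[-1] - a.mean(axis=0)
    u /= np.linalg.norm(u)
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    karc = np.arange(1, n_linker + 1)
    linker = (
        a[-1]
        + 3.8 * u * karc[:, None]
        + 1.0 * np.sin(np.pi * karc / (n_linker + 1))[:, None] * perp
    )
    # chain B starts at its junction and ends at its core center, so
    # both free termini of the full chain are buried in the cores
    b = _lattice_core(n_core)
    start_b = int(np.argmin(np.linalg.norm(b - b.mean(axis=0), axis=1)))
    b = b[_greedy_chain_order(b, end_at=start_b)]
    v = b.mean(axis=0) - b[0]
    v /= np.linalg.norm(v)
    rot, _ = Rotation.align_vectors(u[None, :], v[None, :])
    b = (b - b[0]) @ rot.as_matrix().T + linker[-1] + 3.8 * u
    coords = np.vstack([a, linker, b])
    rng = np.random.default_rng((seed, 7))
    coords = coords + rng.uniform(-0.05, 0.05, size=coords.shape)
    if not _is_connected(coords):
        raise RuntimeError("dumbbell construction produced a disconnected network")
    return _ca_model(coords, f"dumbbell_c{n_core}_l{n_linker}_s{seed}")


def dumbbell_segments(n_core: int, n_linker: int):
    """0-based index ranges (core_a, linker, core_b) of a dumbbell model."""
    return (
        list(range(n_core)),
        list(range(n_core, n_core + n_linker)),
        list(range(n_core + n_linker, 2 * n_core + n_linker)),
    )


def make_charged_pair(distance: float = 3.2) -> CaModel:
    """Asp and Lys with side chains posed at a given closest O-N distance.

    Minimal atom sets (backbone + the charged-group atoms) are used;
    the carboxylate OD1 faces the ammonium NZ along +x at exactly
    ``distance`` A.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")

    def res(name, seq, origin, atoms):
        return Residue(
            chain_id="A",
            seq_number=seq,
            insertion_code="",
            name=name,
            ca_coord=np.asarray(origin, dtype=float),
            bfactor_exp=0.0,
            atoms=tuple(
                (nm, el, np.asarray(origin, dtype=float) + np.asarray(off, float))
                for nm, el, off in atoms
            ),
        )

    asp = res(
        "ASP", 1, [0.0, 0.0, 0.0],
        [
            ("N", "N", [-1.46, 0.0, 0.0]),
            ("CA", "C", [0.0, 0.0, 0.0]),
            ("C", "C", [0.9, 1.2, 0.0]),
            ("O", "O", [0.4, 2.3, 0.0]),
            ("CB", "C", [0.8, -1.2, 0.3]),
            ("CG", "C", [2.2, -1.1, 0.3]),
            ("OD1", "O", [3.0, -1.1, 1.3]),
            ("OD2", "O", [2.8, -1.1, -0.8]),
        ],
    )
    nz_x = 3.0 + distance  # OD1 x + requested separation, same y/z
    lys = res(
        "LYS", 2, [nz_x + 5.0, -1.1, 1.3],
        [
            ("N", "N", [-1.46, 0.0, 0.0]),
            ("CA", "C", [0.0, 0.0, 0.0]),
            ("C", "C", [0.9, 1.2, 0.0]),
            ("O", "O", [0.4, 2.3, 0.0]),
            ("CB", "C", [-0.9, -1.2, 0.0]),
            ("CG", "C", [-2.2, -1.1, 0.0]),
            ("CD", "C", [-3.1, -2.3, 0.0]),
            ("CE", "C", [-4.2, -2.6, 0.6]),
            ("NZ", "N", [-5.0, 0.0, 0.0]),
        ],
    )
    model = CaModel(residues=[asp, lys], source_id=f"charged_pair_{distance:.2f}")
    model.chain_breaks = {0}
    # exact closest O-N distance by construction
    assert abs(np.linalg.norm(
        lys.atom_coord("NZ") - asp.atom_coord("OD1")) - distance) < 1e-12
    return model


def emit_fixture(model: CaModel, path) -> None:
    """Write a fixture model to a PDB file (round-trips through the parser)."""
    text = write_pdb(model)
    with open(path, "w") as fh:
        fh.write(text)
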