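"""Structural thermostability descriptors.

The descriptor panel used to compare a thermostable protein with a
mesophilic homolog: solvent-accessible surface area split by residue
class, hydrogen bonds (3.0 A / 150 deg), salt bridges (3.5 A), glycine
phi+/phi- classification, per-domain proline census, buried-hydrophilic
hydrogen-bond accounting, per-domain contact density (NCPR), and
kinetically hot/warm residues from the fastest GNM modes.

Geometric conventions
---------------------
* H-bond: donor/acceptor heavy atoms are N and O; heavy-atom distance
  <= 3.0 A and donor-H-acceptor angle >= 150 deg.  Backbone amide H is
  placed by ideal geometry when absent; side-chain donors without an
  explicit H fall back to an antecedent-donor-acceptor angle >= 120 deg
  surrogate.  Each donor atom forms at most one bond (nearest valid
  acceptor); bifurcation is not counted.
* Salt bridge: Asp/Glu carboxylate O within 3.5 A of Lys NZ, Arg
  NH1/NH2/NE or His ND1/NE2; counted once per residue pair.
* Hot spot: square fluctuation over the 10 fastest GNM modes, on a
  scale calibrated against experimental B-factors, above 0.03 A^2
  (warm: 0.01-0.03 A^2).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.PDB.SASA import ShrakeRupley
from scipy.spatial import cKDTree

from .enm_core import ModeSpectrum, mode_fluctuations
from .structure_io import (
    CaModel,
    DomainMap,
    Residue,
    assign_domains,
    write_pdb,
)

__all__ = [
    "ResidueClassScheme",
    "SasaResult",
    "HBond",
    "SaltBridge",
    "SpotReport",
    "sasa",
    "count_hbonds",
    "count_salt_bridges",
    "classify_glycines",
    "residue_census",
    "buried_hydrophilic_report",
    "ncpr",
    "hot_spots",
    "dihedral",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}

HBOND_DISTANCE_CUTOFF = 3.0      # donor-acceptor heavy atoms, A
HBOND_ANGLE_CUTOFF = 150.0       # donor-H-acceptor, deg
HBOND_SURROGATE_ANGLE = 120.0    # antecedent-donor-acceptor fallback, deg
SALT_BRIDGE_CUTOFF = 3.5         # carboxylate O to basic N, A
HOT_SPOT_SF = 0.03               # A^2 over the fastest modes
WARM_SPOT_SF = 0.01

# Side-chain donor atoms: donor -> antecedent heavy atom (for ideal-H or
# surrogate-angle geometry).  Sulfur donors/acceptors are excluded: the
# descriptor counts are defined on N and O atoms.
SIDECHAIN_DONORS = {
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "TRP": {"NE1": "CD1"},
}

SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

ACIDIC_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
BASIC_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
    "HIS": {"ND1", "NE2"},
}

# Maximum hydrogen bonds a buried hydrophilic side chain can form
# (donor H count + acceptor lone-pair sites, conventional capacities).
HBOND_CAPACITY = {
    "ASP": 4, "GLU": 4, "ASN": 4, "GLN": 4, "LYS": 3, "ARG": 5, "HIS": 2,
}

# Heavy-atom counts of complete standard residues (for completeness checks).
HEAVY_ATOM_COUNTS = {
    "ALA": 5, "ARG": 11, "ASN": 8, "ASP": 8, "CYS": 6, "GLN": 9, "GLU": 9,
    "GLY": 4, "HIS": 10, "ILE": 8, "LEU": 8, "LYS": 9, "MET": 8, "PHE": 11,
    "PRO": 7, "SER": 6, "THR": 7, "TRP": 14, "TYR": 12, "VAL": 7,
}


@dataclass(frozen=True)
class ResidueClassScheme:
    """Three-way residue partition used for the SASA split.

    The hydrophilic set is fixed by the descriptor definition
    (Asp, Asn, Glu, Gln, Lys, Arg, His); the hydrophobic set is
    configurable; everything else is "other".
    """

    hydrophilic: frozenset = frozenset(
        {"ASP", "ASN", "GLU", "GLN", "LYS", "ARG", "HIS"}
    )
    hydrophobic: frozenset = frozenset(
        {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP"}
    )

    def classify(self, resname: str) -> str:
        if resname in self.hydrophilic:
            return "hydrophilic"
        if resname in self.hydrophobic:
            return "hydrophobic"
        return "other"


@dataclass
class SasaResult:
    total: float
    by_class: dict           # class -> (area, fraction of total)
    per_residue: np.ndarray  # residue SASA, model order, A^2
    per_residue_sidechain: np.ndarray
    incomplete_residues: list  # (seq_number, name, n_heavy, expected)


def _to_biopdb(model: CaModel):
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        return parser.get_structure("m", io.StringIO(write_pdb(model)))


def sasa(
    model: CaModel,
    probe_radius: float = 1.4,
    scheme: ResidueClassScheme | None = None,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area of a full-atom model.

    Rolls a probe sphere (default water, 1.4 A) over the van der Waals
    surface; per-atom areas are aggregated per residue and per residue
    class.  Hydrogens, if present, are ignored.  Residues with missing
    heavy atoms are reported (their area is still computed) with a
    warning.
    """
    scheme = scheme or ResidueClassScheme()
    if not any(r.atoms for r in model.residues):
        raise ValueError("sasa requires a full-atom model")
    structure = _to_biopdb(model)
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(structure, level="A")
    per_res = np.zeros(len(model))
    per_side = np.zeros(len(model))
    by_class = {"hydrophilic": 0.0, "hydrophobic": 0.0, "other": 0.0}
    bp_residues = [r for r in structure.get_residues()]
    if len(bp_residues) != len(model):
        raise ValueError("round-trip residue count mismatch")
    incomplete = []
    for i, (res, bp_res) in enumerate(zip(model.residues, bp_residues)):
        area = 0.0
        side = 0.0
        n_heavy = 0
        for atom in bp_res:
            if (atom.element or "").strip() == "H":
                continue
            n_heavy += 1
            area += atom.sasa
            if atom.get_name() not in BACKBONE_ATOMS:
                side += atom.sasa
        per_res[i] = area
        per_side[i] = side
        by_class[scheme.classify(res.name)] += area
        expected = HEAVY_ATOM_COUNTS.get(res.name)
        if expected is not None and n_heavy < expected:
            incomplete.append((res.seq_number, res.name, n_heavy, expected))
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} residues are missing heavy atoms; "
            "their SASA is underestimated",
            stacklevel=2,
        )
    total = float(per_res.sum())
    return SasaResult(
        total=total,
        by_class={
            k: (v, v / total if total > 0 else 0.0) for k, v in by_class.items()
        },
        per_residue=per_res,
        per_residue_sidechain=per_side,
        incomplete_residues=incomplete,
    )


@dataclass(frozen=True)
class HBond:
    donor_index: int          # model residue index
    donor_atom: str
    acceptor_index: int
    acceptor_atom: str
    distance: float           # heavy-atom D..A, A
    angle: float              # D-H-A (or surrogate), deg
    kind: str                 # "backbone-backbone" | "sidechain-involving"


def _angle(a, b, c):
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in (-180, 180] degrees.

    Standard convention (IUPAC): positive when, looking down p1->p2,
    the far bond rotates clockwise from the near bond.
    """
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def _backbone_amide_h(model: CaModel, i: int):
    """Ideal-geometry amide H of residue i, or None (PRO, chain start)."""
    res = model.residues[i]
    if res.name == "PRO":
        return None
    h = res.atom_coord("H")
    if h is not None:
        return h
    if i == 0 or (i - 1) in model.chain_breaks:
        return None
    n = res.atom_coord("N")
    ca = res.atom_coord("CA")
    c_prev = model.residues[i - 1].atom_coord("C")
    if n is None or ca is None or c_prev is None:
        return None
    u = n - c_prev
    u /= np.linalg.norm(u)
    v = n - ca
    v /= np.linalg.norm(v)
    w = u + v
    w /= np.linalg.norm(w)
    return n + 1.01 * w


def _collect_donors(model: CaModel):
    """(residue_index, donor_atom, donor_coord, h_coord_or_None, antecedent_coord)."""
    donors = []
    for i, res in enumerate(model.residues):
        n = res.atom_coord("N")
        if n is not None and res.name != "PRO":
            h = _backbone_amide_h(model, i)
            ca = res.atom_coord("CA")
            if h is not None:
                donors.append((i, "N", n, h, ca))
        for datom, antecedent in SIDECHAIN_DONORS.get(res.name, {}).items():
            d = res.atom_coord(datom)
            if d is None:
                continue
            ant = res.atom_coord(antecedent)
            if ant is None:
                continue
            h = res.atom_coord("H" + datom[1:])  # explicit H if deposited
            donors.append((i, datom, d, h, ant))
    return donors


def _collect_acceptors(model: CaModel):
    acceptors = []
    for i, res in enumerate(model.residues):
        for aname in ("O", "OXT"):
            a = res.atom_coord(aname)
            if a is not None:
                acceptors.append((i, aname, a))
        for aname in SIDECHAIN_ACCEPTORS.get(res.name, set()):
            a = res.atom_coord(aname)
            if a is not None:
                acceptors.append((i, aname, a))
    return acceptors


def count_hbonds(model: CaModel, use_spatial_index: bool = True):
    """Detect hydrogen bonds; returns (total, backbone_backbone, sidechain_involving, bonds).

    Candidate donor-acceptor pairs within 3.0 A (heavy atoms, different
    residues) are screened by the 150 deg donor-H-acceptor criterion
    (ideal-geometry backbone H; surrogate antecedent angle >= 120 deg
    for H-less side-chain donors).  Each donor atom keeps only its
    nearest valid acceptor.  ``use_spatial_index=False`` forces the
    all-pairs scan (the oracle the k-d tree path is tested against).
    """
    if not any(r.atoms for r in model.residues):
        raise ValueError("count_hbonds requires a full-atom model")
    donors = _collect_donors(model)
    acceptors = _collect_acceptors(model)
    if not donors or not acceptors:
        return 0, 0, 0, []
    acc_coords = np.array([a[2] for a in acceptors])
    bonds = []
    if use_spatial_index:
        tree = cKDTree(acc_coords)
    for di, datom, dcoord, hcoord, antecedent in donors:
        if use_spatial_index:
            cand = tree.query_ball_point(dcoord, HBOND_DISTANCE_CUTOFF)
        else:
            dist_all = np.linalg.norm(acc_coords - dcoord, axis=1)
            cand = np.nonzero(dist_all <= HBOND_DISTANCE_CUTOFF)[0].tolist()
        best = None
        for k in sorted(cand):
            ai, aatom, acoord = acceptors[k]
            if ai == di:
                continue
            dist = float(np.linalg.norm(acoord - dcoord))
            if dist > HBOND_DISTANCE_CUTOFF:
                continue
            if hcoord is not None:
                ang = _angle(dcoord, hcoord, acoord)
                if ang < HBOND_ANGLE_CUTOFF:
                    continue
            else:
                ang = _angle(antecedent, dcoord, acoord)
                if ang < HBOND_SURROGATE_ANGLE:
                    continue
            if best is None or dist < best[0]:
                best = (dist, ai, aatom, ang)
        if best is not None:
            dist, ai, aatom, ang = best
            kind = (
                "backbone-backbone"
                if datom == "N" and aatom in ("O", "OXT")
                else "sidechain-involving"
            )
            bonds.append(
                HBond(
                    donor_index=di,
                    donor_atom=datom,
                    acceptor_index=ai,
                    acceptor_atom=aatom,
                    distance=dist,
                    angle=ang,
                    kind=kind,
                )
            )
    bb = sum(1 for b in bonds if b.kind == "backbone-backbone")
    return len(bonds), bb, len(bonds) - bb, bonds


@dataclass(frozen=True)
class SaltBridge:
    acidic_index: int
    basic_index: int
    min_distance: float


def count_salt_bridges(model: CaModel, use_spatial_index: bool = True):
    """Salt bridges: carboxylate O within 3.5 A of a basic side-chain N.

    Counted once per (acidic residue, basic residue) pair regardless of
    how many atom pairs qualify.  Returns (count, bridges).
    """
    if not any(r.atoms for r in model.residues):
        raise ValueError("count_salt_bridges requires a full-atom model")
    acidic = []
    basic = []
    for i, res in enumerate(model.residues):
        for aname in ACIDIC_ATOMS.get(res.name, ()):  # carboxylate oxygens
            c = res.atom_coord(aname)
            if c is not None:
                acidic.append((i, c))
        for bname in BASIC_ATOMS.get(res.name, ()):
            c = res.atom_coord(bname)
            if c is not None:
                basic.append((i, c))
    if not acidic or not basic:
        return 0, []
    bcoords = np.array([b[1] for b in basic])
    pair_best: dict = {}
    tree = cKDTree(bcoords) if use_spatial_index else None
    for ai, acoord in acidic:
        if tree is not None:
            cand = tree.query_ball_point(acoord, SALT_BRIDGE_CUTOFF)
        else:
            cand = np.nonzero(
                np.linalg.norm(bcoords - acoord, axis=1) <= SALT_BRIDGE_CUTOFF
            )[0].tolist()
        for k in cand:
            bi, bcoord = basic[k]
            if bi == ai:
                continue
            dist = float(np.linalg.norm(bcoord - acoord))
            if dist > SALT_BRIDGE_CUTOFF:
                continue
            key = (ai, bi)
            if key not in pair_best or dist < pair_best[key]:
                pair_best[key] = dist
    bridges = [
        SaltBridge(acidic_index=a, basic_index=b, min_distance=d)
        for (a, b), d in sorted(pair_best.items())
    ]
    return len(bridges), bridges


def classify_glycines(model: CaModel):
    """Backbone (phi, psi) and phi-sign class of every glycine.

    Returns a DataFrame with columns seq_number, phi, psi, cls where cls
    is "phi+" (phi >= 0), "phi-" or "undefined" for chain-terminal
    glycines lacking a flanking backbone atom.  phi uses the standard
    C(i-1)-N-CA-C convention in (-180, 180]; phi exactly 0 is "phi+".
    """
    rows = []
    for i, res in enumerate(model.residues):
        if res.name != "GLY":
            continue
        n = res.atom_coord("N")
        ca = res.atom_coord("CA")
        c = res.atom_coord("C")
        c_prev = (
            model.residues[i - 1].atom_coord("C")
            if i > 0 and (i - 1) not in model.chain_breaks
            else None
        )
        n_next = (
            model.residues[i + 1].atom_coord("N")
            if i + 1 < len(model) and i not in model.chain_breaks
            else None
        )
        phi = psi = np.nan
        cls = "undefined"
        if c_prev is not None and all(x is not None for x in (n, ca, c)):
            phi = dihedral(c_prev, n, ca, c)
            cls = "phi+" if phi >= 0 else "phi-"
        if n_next is not None and all(x is not None for x in (n, ca, c)):
            psi = dihedral(n, ca, c, n_next)
        rows.append(
            {"seq_number": res.seq_number, "phi": phi, "psi": psi, "cls": cls}
        )
    return pd.DataFrame(rows, columns=["seq_number", "phi", "psi", "cls"])


def residue_census(model: CaModel, domain_map: DomainMap, residue_name: str):
    """Per-composite-domain count of a residue type (Table-style census).

    Returns (DataFrame[domain, length, count, fraction], total_count,
    total_fraction).  Fractions are relative to the domain length (or
    the full model for the total).
    """
    labels = assign_domains(model, domain_map)
    comp = [domain_map.composite_label(l) for l in labels]
    rows = []
    for d in sorted(set(comp)):
        idx = [i for i, c in enumerate(comp) if c == d]
        count = sum(1 for i in idx if model.residues[i].name == residue_name)
        rows.append(
            {
                "domain": d,
                "length": len(idx),
                "count": count,
                "fraction": count / len(idx) if idx else 0.0,
            }
        )
    total = sum(r["count"] for r in rows)
    return (
        pd.DataFrame(rows, columns=["domain", "length", "count", "fraction"]),
        total,
        total / len(model),
    )


def buried_hydrophilic_report(
    model: CaModel,
    sasa_result: SasaResult,
    hbond_list,
    burial_threshold: float = 0.10,
    scheme: ResidueClassScheme | None = None,
    probe_radius: float = 1.4,
):
    """Hydrogen-bond satisfaction of buried hydrophilic residues.

    A hydrophilic residue is buried when its side-chain SASA relative to
    the same residue extracted in isolation falls below
    ``burial_threshold`` (default 10%).  Capacity comes from a fixed
    per-type table; "actual" counts H-bonds in ``hbond_list`` involving
    the residue's side-chain atoms.  Returns a dict with n_buried,
    max_capacity, actual_hbonds, ratio and the buried residue list.
    """
    scheme = scheme or ResidueClassScheme()
    buried = []
    for i, res in enumerate(model.residues):
        if scheme.classify(res.name) != "hydrophilic":
            continue
        iso = CaModel(residues=[res], source_id="iso")
        ref = sasa(iso, probe_radius=probe_radius).per_residue_sidechain[0]
        if ref <= 0:
            continue
        rel = sasa_result.per_residue_sidechain[i] / ref
        if rel < burial_threshold:
            buried.append((i, rel))
    buried_idx = {i for i, _ in buried}
    actual = 0
    for b in hbond_list:
        # a bond satisfies each buried side chain it touches
        if b.donor_index in buried_idx and b.donor_atom not in BACKBONE_ATOMS:
            actual += 1
        if (
            b.acceptor_index in buried_idx
            and b.acceptor_atom not in BACKBONE_ATOMS
        ):
            actual += 1
    capacity = sum(
        HBOND_CAPACITY.get(model.residues[i].name, 0) for i in buried_idx
    )
    return {
        "n_buried": len(buried),
        "max_capacity": capacity,
        "actual_hbonds": actual,
        "ratio": actual / capacity if capacity else 0.0,
        "buried": [
            (model.residues[i].seq_number, model.residues[i].name, rel)
            for i, rel in buried
        ],
    }


def ncpr(model: CaModel, domain_map: DomainMap, cutoff: float = 7.0):
    """Number of contacts per residue, per composite domain.

    A contact is a CA pair with both residues in the domain, sequence
    separation |i-j| >= 2 and distance <= ``cutoff``.  Returns a
    DataFrame with columns domain, contacts, residues, ncpr (2 d.p.).
    """
    labels = assign_domains(model, domain_map)
    comp = [domain_map.composite_label(l) for l in labels]
    coords = model.coords
    rows = []
    for d in sorted(set(comp)):
        idx = [i for i, c in enumerate(comp) if c == d]
        count = 0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if abs(i - j) < 2:
                    continue
                if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                    count += 1
        rows.append(
            {
                "domain": d,
                "contacts": count,
                "residues": len(idx),
                "ncpr": round(count / len(idx), 2) if idx else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["domain", "contacts", "residues", "ncpr"])


@dataclass
class SpotReport:
    sf: np.ndarray            # calibrated square fluctuations, A^2
    classes: list             # "hot" | "warm" | "none" per residue
    hot: list                 # residue seq numbers
    warm: list
    scale: float              # calibration factor applied to unit-gamma SF


def hot_spots(
    model: CaModel,
    gnm_spectrum: ModeSpectrum,
    calibration_scale: float,
    n_fast: int = 10,
) -> SpotReport:
    """Kinetically hot/warm residues from the fastest GNM modes.

    ``calibration_scale`` is the B-factor fit scale returned by
    :func:`enmfold.enm_core.fit_gamma` (it maps unit-gamma fluctuations
    onto the experimental A^2 scale); the absolute 0.03/0.01 A^2
    thresholds are meaningless without it.
    """
    if calibration_scale is None or calibration_scale <= 0:
        raise ValueError(
            "hot_spots requires a calibrated scale: fit gamma against "
            "experimental B-factors first (enm_core.fit_gamma)"
        )
    n_modes = gnm_spectrum.n_nonzero
    if n_fast > n_modes:
        raise ValueError("n_fast exceeds the number of nonzero modes")
    fast = range(n_modes - n_fast, n_modes)
    sf = calibration_scale * mode_fluctuations(gnm_spectrum, fast)
    classes = [
        "hot" if v > HOT_SPOT_SF else ("warm" if v > WARM_SPOT_SF else "none")
        for v in sf
    ]
    seq = model.seq_numbers
    return SpotReport(
        sf=sf,
        classes=classes,
        hot=[int(seq[i]) for i, c in enumerate(classes) if c == "hot"],
        warm=[int(seq[i]) for i, c in enumerate(classes) if c == "warm"],
        scale=float(calibration_scale),
    )
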