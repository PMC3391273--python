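"""Reading, writing and superposing protein structures.

This module turns PDB-format text into the coarse-grained and full-atom
models used by the elastic-network and descriptor machinery:

* :class:`CaModel` — an ordered C-alpha trace with author numbering,
  experimental B-factors and (optionally) the full atom list per residue.
* :class:`DomainMap` — named residue-number intervals describing the
  domain architecture (for amylosucrases: N, A1/A2/A3, B, B', C).
* Rigid-body superposition (Kabsch) and an iterative structure-based
  alignment of two homologs that alternates superposition with
  order-preserving re-pairing of nearest residues.

Author residue numbering (the PDB field) is the coordinate system for
domain maps and all reports; internal 0-based indices never appear in
output.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial.transform import Rotation

__all__ = [
    "Residue",
    "CaModel",
    "DomainMap",
    "AlignmentResult",
    "MalformedPDBError",
    "DegenerateGeometryError",
    "parse_pdb",
    "write_pdb",
    "strip_residue_range",
    "assign_domains",
    "kabsch_superpose",
    "iterative_fit",
    "THREE_TO_ONE",
]

# Distance between consecutive CA atoms above which the peptide bond is
# considered absent (trans CA-CA is ~3.8 A, cis ~2.9 A).
CHAIN_BREAK_CA_DISTANCE = 4.5

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Composite-domain grouping used throughout the reports: the catalytic
# (beta/alpha)8 barrel is split into three parts by the two insertion
# domains, but lengths and censuses are reported for the union.
COMPOSITE_DOMAINS = {"A1": "A", "A2": "A", "A3": "A"}


class MalformedPDBError(ValueError):
    """Raised when PDB text cannot be resolved into a unique residue list."""


class DegenerateGeometryError(ValueError):
    """Raised when a superposition problem is numerically degenerate."""


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue of a model.

    ``atoms`` is a list of ``(atom_name, element, coord)`` tuples and is
    empty in CA-only mode.  ``bfactor_exp`` is the experimental B-factor
    of the CA atom in A^2.
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    name: str
    ca_coord: np.ndarray
    bfactor_exp: float
    atoms: tuple = ()

    @property
    def key(self):
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_RESIDUES

    def atom_coord(self, atom_name: str):
        for name, _elem, coord in self.atoms:
            if name == atom_name:
                return np.asarray(coord, dtype=float)
        return None


@dataclass
class CaModel:
    """Ordered CA trace of a single chain (or several, concatenated).

    ``chain_breaks`` holds 0-based indices ``i`` meaning residues ``i``
    and ``i+1`` are not peptide-bonded.
    """

    residues: list
    source_id: str = ""
    chain_breaks: set = field(default_factory=set)

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("a model needs at least one residue")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise MalformedPDBError(
                f"{self.source_id}: duplicate residue key after altloc resolution"
            )

    def __len__(self):
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.ca_coord for r in self.residues], dtype=float)

    @property
    def bfactors(self) -> np.ndarray:
        return np.array([r.bfactor_exp for r in self.residues], dtype=float)

    @property
    def seq_numbers(self) -> np.ndarray:
        return np.array([r.seq_number for r in self.residues], dtype=int)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def covalent_pairs(self):
        """Chain-adjacent 0-based index pairs, excluding chain breaks."""
        return [
            (i, i + 1)
            for i in range(len(self.residues) - 1)
            if i not in self.chain_breaks
        ]


def _detect_chain_breaks(residues) -> set:
    breaks = set()
    for i in range(len(residues) - 1):
        a, b = residues[i], residues[i + 1]
        if a.chain_id != b.chain_id:
            breaks.add(i)
            continue
        if np.linalg.norm(a.ca_coord - b.ca_coord) > CHAIN_BREAK_CA_DISTANCE:
            breaks.add(i)
    return breaks


def parse_pdb(
    pdb_text: str,
    mode: str = "ca_only",
    chain: str | None = None,
    source_id: str = "",
) -> CaModel:
    """Parse PDB text into a :class:`CaModel`.

    One residue is produced per ``(chain, seq_number, icode)`` that has a
    CA atom; HETATM records and waters are excluded; alternate locations
    are resolved to the highest-occupancy conformer (ties: first listed).
    ``chain`` restricts parsing to one chain id; by default the first
    protein chain is used, matching single-chain analyses.

    Parameters
    ----------
    mode:
        ``"ca_only"`` keeps only the CA coordinate; ``"full_atom"``
        additionally stores every atom of each residue.
    """
    if mode not in ("ca_only", "full_atom"):
        raise ValueError(f"unknown mode {mode!r}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(source_id or "model", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise MalformedPDBError("no model in PDB text")
    residues = []
    chains = list(models[0])
    if chain is None:
        # first chain containing a CA atom
        selected = None
        for ch in chains:
            if any("CA" in res for res in ch if res.id[0] == " "):
                selected = [ch]
                break
        if selected is None:
            raise MalformedPDBError("no CA atoms found in any chain")
        chains = selected
    else:
        chains = [ch for ch in chains if ch.id == chain]
        if not chains:
            raise MalformedPDBError(f"chain {chain!r} not present")
    for ch in chains:
        for res in ch:
            hetflag, seqnum, icode = res.id
            if hetflag != " ":
                continue  # HETATM / water
            if res.is_disordered() == 2:
                raise MalformedPDBError(
                    f"residue {ch.id}{seqnum}{icode.strip()} has conflicting identities"
                )
            if "CA" not in res:
                continue
            ca = res["CA"]
            if ca.is_disordered():
                ca = ca.selected_child  # highest occupancy, first-listed on ties
            atoms = ()
            if mode == "full_atom":
                collected = []
                for atom in res:
                    if atom.is_disordered():
                        atom = atom.selected_child
                    collected.append(
                        (atom.get_name(), (atom.element or "").strip(),
                         np.asarray(atom.coord, dtype=float))
                    )
                atoms = tuple(collected)
            residues.append(
                Residue(
                    chain_id=ch.id,
                    seq_number=int(seqnum),
                    insertion_code=icode.strip(),
                    name=res.get_resname().strip(),
                    ca_coord=np.asarray(ca.coord, dtype=float),
                    bfactor_exp=float(ca.get_bfactor()),
                    atoms=atoms,
                )
            )
    if not residues:
        raise MalformedPDBError("no CA atoms found")
    model = CaModel(residues=residues, source_id=source_id)
    model.chain_breaks = _detect_chain_breaks(residues)
    return model


def write_pdb(model: CaModel) -> str:
    """Serialize a model to PDB-format text.

    Full-atom residues emit every stored atom; CA-only residues emit the
    CA record.  A TER record is written at every chain break and at the
    end of each chain.  Round-trips through :func:`parse_pdb` preserve
    residues and coordinates to the PDB's 3-decimal precision.
    """
    lines = []
    serial = 1
    n = len(model.residues)
    for i, res in enumerate(model.residues):
        atoms = res.atoms if res.atoms else (("CA", "C", res.ca_coord),)
        for name, elem, coord in atoms:
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = (float(c) for c in coord)
            lines.append(
                f"ATOM  {serial:>5d} {pad_name}{'':1s}{res.name:>3s} "
                f"{res.chain_id:1s}{res.seq_number:>4d}{res.insertion_code or '':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{res.bfactor_exp:6.2f}"
                f"          {elem:>2s}"
            )
            serial += 1
        if i in model.chain_breaks or i == n - 1:
            lines.append(f"TER   {serial:>5d}      {res.name:>3s} "
                         f"{res.chain_id:1s}{res.seq_number:>4d}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def strip_residue_range(model: CaModel, keep) -> CaModel:
    """Return a model restricted to author-numbered intervals.

    ``keep`` is a list of inclusive ``(start, end)`` residue-number
    intervals; residues outside every interval are dropped (e.g. removal
    of a residual expression tag before analysis).
    """
    intervals = [(int(a), int(b)) for a, b in keep]
    kept = [
        r for r in model.residues
        if any(a <= r.seq_number <= b for a, b in intervals)
    ]
    if not kept:
        raise ValueError("strip_residue_range would leave an empty model")
    out = CaModel(residues=kept, source_id=model.source_id)
    out.chain_breaks = _detect_chain_breaks(kept)
    return out


@dataclass
class DomainMap:
    """Domain label -> list of inclusive author-numbered intervals."""

    ranges: dict

    @classmethod
    def from_config(cls, text: str) -> "DomainMap":
        """Parse a simple config: one ``label: start-end[, start-end]`` per line.

        Lines starting with ``#`` are comments.  YAML mappings with the
        same value syntax are accepted too.
        """
        ranges: dict = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            label, _, spec_part = line.partition(":")
            label = label.strip().strip("\"'")
            intervals = []
            for chunk in spec_part.replace("[", "").replace("]", "").split(","):
                chunk = chunk.strip().strip("\"'")
                if not chunk:
                    continue
                start, _, end = chunk.partition("-")
                intervals.append((int(start), int(end)))
            if not intervals:
                raise ValueError(f"domain line without intervals: {raw!r}")
            ranges.setdefault(label, []).extend(intervals)
        return cls(ranges)

    def composite_label(self, label: str) -> str:
        return COMPOSITE_DOMAINS.get(label, label)

    @property
    def composite_labels(self):
        return sorted({self.composite_label(lbl) for lbl in self.ranges})


def assign_domains(model: CaModel, domain_map: DomainMap) -> list:
    """Per-residue domain labels (in model order).

    Every residue must be covered by exactly one interval; overlapping or
    incomplete maps raise a configuration error.  Composite parts (A1,
    A2, A3) keep their own label here; use
    :meth:`DomainMap.composite_label` to collapse them.
    """
    labels = [None] * len(model)
    for label, intervals in domain_map.ranges.items():
        for start, end in intervals:
            for i, res in enumerate(model.residues):
                if start <= res.seq_number <= end:
                    if labels[i] is not None:
                        raise ValueError(
                            f"residue {res.seq_number} covered by both "
                            f"{labels[i]!r} and {label!r}"
                        )
                    labels[i] = label
    missing = [model.residues[i].seq_number for i, l in enumerate(labels) if l is None]
    if missing:
        raise ValueError(f"domain map does not cover residues {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    return labels


@dataclass
class AlignmentResult:
    pairs: list          # [(index in A, index in B)] strictly increasing in both
    identity_fraction: float
    rmsd: float
    rotation: np.ndarray      # applied to B to superpose onto A
    translation: np.ndarray
    rounds: int = 0


def kabsch_superpose(coords_a, coords_b, pairs=None):
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` with
    ``a ~ rotation @ b + translation`` over the matched pairs.  The
    rotation is proper (det +1); reflections are never returned.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if pairs is not None:
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        a, b = a[ia], b[ib]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    if len(a) < 3:
        raise DegenerateGeometryError("need at least 3 pairs to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    s = np.linalg.svd(ac.T @ bc, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1e-300):
        raise DegenerateGeometryError("collinear or coincident points")
    rot, _rssd = Rotation.align_vectors(ac, bc)
    rotation = rot.as_matrix()
    translation = ca - rotation @ cb
    fitted = b @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((a - fitted) ** 2, axis=1))))
    return rotation, translation, rmsd


def _sequence_seed_alignment(model_a: CaModel, model_b: CaModel):
    """Global sequence alignment (BLOSUM62) as the starting pair set."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    seq_a = model_a.sequence.replace("X", "A")
    seq_b = model_b.sequence.replace("X", "A")
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def _monotone_repair(coords_a, coords_b_fit, cutoff):
    """Order-preserving re-pairing of nearest residues within ``cutoff``.

    Dynamic program maximizing the summed score ``cutoff - d_ij`` over
    monotone pair sets (gaps are free), i.e. a structure alignment that
    pairs as many close residues as possible, preferring nearer ones.
    """
    na, nb = len(coords_a), len(coords_b_fit)
    d = np.linalg.norm(coords_a[:, None, :] - coords_b_fit[None, :, :], axis=2)
    score = np.where(d <= cutoff, cutoff - d, -np.inf)
    dp = np.zeros((na + 1, nb + 1))
    # 0 = gap-a, 1 = gap-b, 2 = pair
    move = np.zeros((na + 1, nb + 1), dtype=np.int8)
    for i in range(1, na + 1):
        prev = dp[i - 1]
        cur = dp[i]
        cur[0] = prev[0]
        mrow = move[i]
        for j in range(1, nb + 1):
            pair_score = prev[j - 1] + score[i - 1, j - 1]
            gap_a = prev[j]
            gap_b = cur[j - 1]
            if pair_score >= gap_a and pair_score >= gap_b:
                cur[j] = pair_score
                mrow[j] = 2
            elif gap_a >= gap_b:
                cur[j] = gap_a
                mrow[j] = 0
            else:
                cur[j] = gap_b
                mrow[j] = 1
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        m = move[i, j]
        if m == 2:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif m == 0:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def iterative_fit(
    model_a: CaModel,
    model_b: CaModel,
    seed_alignment=None,
    prune_cutoff: float = 3.0,
    max_rounds: int = 50,
) -> AlignmentResult:
    """Iterative structure-based superposition and alignment of homologs.

    Starting from a seed correspondence (by default a global BLOSUM62
    sequence alignment), alternate (1) Kabsch superposition on the
    current pairs and (2) order-preserving re-pairing of residues whose
    fitted CA atoms lie within ``prune_cutoff``; stop at a fixed point
    of the pair set or after ``max_rounds``.  Identity is reported over
    the final matched pairs; RMSD over the retained pairs.
    """
    if seed_alignment is None:
        seed_alignment = _sequence_seed_alignment(model_a, model_b)
    pairs = list(seed_alignment)
    if len(pairs) < 3:
        raise DegenerateGeometryError("seed alignment has fewer than 3 pairs")
    ca_a, ca_b = model_a.coords, model_b.coords
    rotation = np.eye(3)
    translation = np.zeros(3)
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        rotation, translation, _ = kabsch_superpose(ca_a, ca_b, pairs)
        b_fit = ca_b @ rotation.T + translation
        dists = np.array(
            [np.linalg.norm(ca_a[i] - b_fit[j]) for i, j in pairs]
        )
        if int((dists <= prune_cutoff).sum()) < 3:
            # the fit straddles rigid sub-bodies and no pair is close
            # yet: trim the farthest 10% (correspondence kept) and
            # refit, locking progressively onto the dominant body
            if len(pairs) <= 3:
                raise DegenerateGeometryError("fit collapsed below 3 pairs")
            keep_n = max(3, int(0.9 * len(pairs)))
            order = sorted(np.argsort(dists)[:keep_n])
            pairs = [pairs[k] for k in order]
            continue
        new_pairs = _monotone_repair(ca_a, b_fit, prune_cutoff)
        if len(new_pairs) < 3:
            raise DegenerateGeometryError("fit collapsed below 3 pairs")
        if new_pairs == pairs:
            break
        pairs = new_pairs
    rotation, translation, rmsd = kabsch_superpose(ca_a, ca_b, pairs)
    matches = sum(
        model_a.residues[i].name == model_b.residues[j].name for i, j in pairs
    )
    identity = matches / len(pairs) if pairs else 0.0
    return AlignmentResult(
        pairs=pairs,
        identity_fraction=float(identity),
        rmsd=float(rmsd),
        rotation=rotation,
        translation=translation,
        rounds=rounds,
    )
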