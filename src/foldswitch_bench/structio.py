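"""Single-chain macromolecular structure I/O and residue-level editing.

Structures are held in a deliberately small container (ordered residues of
one chain, author numbering, per-atom B-factors) because every downstream
computation — regional TM-scores, backbone RMSD, contact maps, template
preparation — operates on exactly that view. Parsing of PDB and mmCIF is
delegated to gemmi; only the first model is kept, waters are dropped, and
alternate locations are resolved to the highest-occupancy conformer.

Predicted models store per-residue pLDDT (0-100) in the B-factor column;
``plddt_profile`` reads it from the CA atom of each residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "RegionSpec",
    "StructureError",
    "read_structure",
    "extract_region",
    "plddt_profile",
    "strip_sidechains",
    "add_glycine_cb",
    "standardize_residues",
    "truncate_to_common",
    "write_structure",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
TEMPLATE_ATOMS = frozenset({"N", "CA", "C", "O", "CB"})

# ideal CB internal coordinates (L-amino-acid chirality)
CB_BOND_LENGTH = 1.521  # Angstrom, CA-CB
CB_BOND_ANGLE = 110.4  # degrees, N-CA-CB

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}


class StructureError(ValueError):
    """Raised for unparseable files, unknown chains, or contract violations."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise StructureError(f"non-finite coordinates on atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class Residue:
    name: str
    number: int
    icode: str = ""
    atoms: tuple[Atom, ...] = ()

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise StructureError(
                f"duplicate atom names in residue {self.name}{self.number}"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass(frozen=True)
class Structure:
    id: str
    chain: str
    residues: tuple[Residue, ...] = ()

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise StructureError(
                f"residues of {self.id} not strictly ordered by (number, icode)"
            )

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self, atom_names: Sequence[str] = ("CA",)) -> np.ndarray:
        """Stacked coordinates of the named atoms, residues missing them skipped."""
        pts = [
            a.xyz
            for r in self.residues
            for name in atom_names
            if (a := r.atom(name)) is not None
        ]
        if not pts:
            return np.zeros((0, 3))
        return np.vstack(pts)


@dataclass(frozen=True)
class RegionSpec:
    """Inclusive author-numbered residue range on one chain (1-based)."""

    start: int
    end: int
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise StructureError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, text: str, chain: str = "A") -> "RegionSpec":
        start, _, end = text.partition("-")
        return cls(int(start), int(end), chain)

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations to the highest-occupancy conformer per atom name."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def read_structure(path: str | Path, chain: str) -> Structure:
    """Read one chain of a PDB or mmCIF file (first model, waters excluded)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"unparseable structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]
    gchain = model.find_chain(chain)
    if gchain is None:
        available = [c.name for c in model]
        raise StructureError(
            f"chain {chain!r} not found in {path} (available: {available})"
        )
    residues = []
    for gres in gchain:
        if gres.name == "HOH":
            continue
        atoms = tuple(
            Atom(
                name=a.name,
                element=a.element.name,
                coords=(a.pos.x, a.pos.y, a.pos.z),
                bfactor=a.b_iso,
            )
            for a in _pick_altlocs(gres)
        )
        icode = gres.seqid.icode.strip()
        residues.append(
            Residue(name=gres.name, number=gres.seqid.num, icode=icode, atoms=atoms)
        )
    return Structure(id=path.stem, chain=chain, residues=tuple(residues))


def extract_region(s: Structure, r: RegionSpec) -> Structure:
    """Contiguous sub-structure covering ``r.start <= number <= r.end``.

    Internally unresolved residues simply shorten the result; residue numbers
    requested but absent are available via :func:`region_gap_report`.
    """
    sub = tuple(x for x in s.residues if r.start <= x.number <= r.end)
    present = {x.number for x in sub}
    if r.start not in present or r.end not in present:
        missing = sorted(set(range(r.start, r.end + 1)) - present)
        raise StructureError(
            f"region {r} extends outside structure {s.id}; missing residues {missing}"
        )
    return Structure(id=s.id, chain=s.chain, residues=sub)


def region_gap_report(s: Structure, r: RegionSpec) -> list[tuple[int, str]]:
    """(residue number, reason) rows for residues of ``r`` absent from ``s``."""
    present = {x.number for x in s.residues}
    return [(n, "unresolved") for n in range(r.start, r.end + 1) if n not in present]


def plddt_profile(s: Structure) -> list[float]:
    """Per-residue pLDDT read from the CA B-factor; errors outside [0, 100]."""
    profile = []
    for res in s.residues:
        ca = res.atom("CA")
        if ca is None:
            raise StructureError(f"residue {res.name}{res.number} has no CA atom")
        if not 0.0 <= ca.bfactor <= 100.0:
            raise StructureError(
                f"B-factor {ca.bfactor} of residue {res.number} outside [0, 100]; "
                "not a pLDDT-annotated model"
            )
        profile.append(float(ca.bfactor))
    return profile


def strip_sidechains(s: Structure) -> Structure:
    """Keep only N, CA, C, O, CB in every residue (masks residue identity)."""
    residues = tuple(
        replace(r, atoms=tuple(a for a in r.atoms if a.name in TEMPLATE_ATOMS))
        for r in s.residues
    )
    return replace(s, residues=residues)


def _place_internal(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom D from A-B-C frame with bond |CD|, angle BCD, dihedral ABCD (NeRF)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB position from backbone N, CA, C (standard L chirality).

    Constructed as the tetrahedral direction bisecting the N and C arms,
    scaled to the canonical CA-CB bond; this realizes the usual
    ~1.521 A / 110.4 degree internal coordinates without an explicit
    dihedral convention.
    """
    u = n - ca
    u /= np.linalg.norm(u)
    v = c - ca
    v /= np.linalg.norm(v)
    bisector = -(u + v)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(v, u)
    perp /= np.linalg.norm(perp)
    # rotate away from the backbone plane so the N-CA-CB angle hits the target
    angle_nb = math.acos(np.clip(np.dot(u, bisector), -1, 1))
    tilt = math.acos(
        np.clip(math.cos(math.radians(CB_BOND_ANGLE)) / math.cos(angle_nb), -1, 1)
    )
    direction = bisector * math.cos(tilt) + perp * math.sin(tilt)
    return ca + CB_BOND_LENGTH * direction


def add_glycine_cb(s: Structure) -> Structure:
    """Add an ideal-geometry CB to every glycine lacking one (idempotent)."""
    out = []
    for res in s.residues:
        if res.name != "GLY" or res.atom("CB") is not None:
            out.append(res)
            continue
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        if n is None or ca is None or c is None:
            raise StructureError(
                f"glycine {res.number}{res.icode} missing a backbone atom"
            )
        cb = place_cb(n.xyz, ca.xyz, c.xyz)
        out.append(
            replace(res, atoms=res.atoms + (Atom("CB", "C", tuple(cb), ca.bfactor),))
        )
    return replace(s, residues=tuple(out))


_STANDARDIZE = {"MSE": ("MET", {"SE": "SD"}), "SEC": ("CYS", {"SE": "SG"})}


def standardize_residues(s: Structure) -> Structure:
    """Replace seleno residues with their standard analogs (MSE->MET, SEC->CYS)."""
    out = []
    for res in s.residues:
        if res.name not in _STANDARDIZE:
            out.append(res)
            continue
        new_name, atom_map = _STANDARDIZE[res.name]
        atoms = tuple(
            replace(a, name=atom_map[a.name], element="S") if a.name in atom_map else a
            for a in res.atoms
        )
        out.append(replace(res, name=new_name, atoms=atoms))
    return replace(s, residues=tuple(out))


def _longest_common_block(a: str, b: str) -> tuple[int, int, int]:
    """(start_a, start_b, length) of the longest common contiguous substring."""
    best = (0, 0, 0)
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best[2]:
                    best = (i - cur[j], j - cur[j], cur[j])
        prev = cur
    return best


def truncate_to_common(
    a: Structure, b: Structure, min_length: int = 10
) -> tuple[Structure, Structure, dict[str, int]]:
    """Trim both structures to their longest common contiguous sequence block.

    Returns the trimmed structures and a report of residues removed from each,
    so the same sequence is compared (extraneous purification tags dropped).
    """
    ia, ib, n = _longest_common_block(a.sequence, b.sequence)
    if n < min_length:
        raise StructureError(
            f"no common sequence block of length >= {min_length} "
            f"between {a.id} and {b.id} (best {n})"
        )
    ta = replace(a, residues=a.residues[ia : ia + n])
    tb = replace(b, residues=b.residues[ib : ib + n])
    report = {"trimmed_a": len(a) - n, "trimmed_b": len(b) - n, "common_length": n}
    return ta, tb, report


def write_structure(s: Structure, path: str | Path) -> Path:
    """Write a single-chain Structure as PDB text (coordinates to 3 decimals)."""
    if len(s) == 0:
        raise StructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    gchain = gemmi.Chain(s.chain)
    for res in s.residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.b_iso = atom.bfactor
            ga.occ = 1.0
            gres.add_atom(ga)
        gchain.add_residue(gres)
    model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


def structures_allclose(a: Structure, b: Structure, atol: float = 1e-3) -> bool:
    """Same residues/atom names and coordinates within ``atol`` (round-trip check)."""
    if len(a) != len(b):
        return False
    for ra, rb in zip(a.residues, b.residues):
        if (ra.name, ra.number, ra.icode) != (rb.name, rb.number, rb.icode):
            return False
        if [x.name for x in ra.atoms] != [x.name for x in rb.atoms]:
            return False
        for xa, xb in zip(ra.atoms, rb.atoms):
            if not np.allclose(xa.xyz, xb.xyz, atol=atol):
                return False
    return True
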