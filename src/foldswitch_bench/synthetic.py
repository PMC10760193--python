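"""Synthetic benchmark inputs with known ground truth.

Real fold switchers are pairs of experimentally determined structures that
share a sequence but disagree over a region of secondary structure, plus
large ensembles of predicted models of varying accuracy and confidence.
This module fabricates format-identical stand-ins at desk scale:

* ideal-geometry backbones (helix, strand, random coil) built from internal
  coordinates,
* paired conformations whose designated region is helical in one partner
  and extended in the other while the flanks are shared,
* "prediction" ensembles drawn from a controlled mixture of noisy copies of
  either conformation or of an unrelated coil,
* per-residue pLDDT profiles with an exact confident-residue fraction,
* toy MSAs at a stated identity and gap rate.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .structio import (
    Atom,
    RegionSpec,
    Residue,
    Structure,
    StructureError,
    place_cb,
)
from .speach import MSA

__all__ = [
    "ScenarioSpec",
    "PLDDTSpec",
    "SyntheticProtein",
    "Scenario",
    "build_helix",
    "build_strand",
    "build_coil",
    "build_backbone",
    "make_pair",
    "perturb",
    "synth_plddt",
    "synth_msa",
    "scenario",
]

# ideal peptide internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _extend(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of the next atom from three predecessors."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    sequence: str,
    phi: list[float] | np.ndarray,
    psi: list[float] | np.ndarray,
    *,
    structure_id: str = "synthetic",
    chain: str = "A",
    start_number: int = 1,
    bfactor: float = 0.0,
) -> Structure:
    """Build an ideal backbone (N, CA, C, O, CB except GLY) from phi/psi angles.

    ``phi[0]`` and ``psi[-1]`` are undefined for a real chain and ignored.
    """
    L = len(sequence)
    if L == 0:
        raise StructureError("empty sequence")
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise StructureError(f"invalid residue letter {letter!r}")
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if len(phi) != L or len(psi) != L:
        raise StructureError("phi/psi length must match sequence length")

    # first residue seeded explicitly
    n_xyz = [np.array([0.0, 0.0, 0.0])]
    ca_xyz = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    c_xyz = [ca_xyz[0] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, L):
        n_next = _extend(n_xyz[-1], ca_xyz[-1], c_xyz[-1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_next = _extend(ca_xyz[-1], c_xyz[-1], n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = _extend(c_xyz[-1], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        n_xyz.append(n_next)
        ca_xyz.append(ca_next)
        c_xyz.append(c_next)

    residues = []
    for i, letter in enumerate(sequence):
        atoms = [
            Atom("N", "N", tuple(n_xyz[i]), bfactor),
            Atom("CA", "C", tuple(ca_xyz[i]), bfactor),
            Atom("C", "C", tuple(c_xyz[i]), bfactor),
        ]
        # carbonyl O in the peptide plane, trans to the next N
        if i + 1 < L:
            o = _extend(n_xyz[i + 1], ca_xyz[i], c_xyz[i], BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            o = _extend(n_xyz[i], ca_xyz[i], c_xyz[i], BOND_C_O, ANGLE_CA_C_O, psi[i] if L > 1 else 0.0)
        atoms.append(Atom("O", "O", tuple(o), bfactor))
        if letter != "G":
            cb = place_cb(n_xyz[i], ca_xyz[i], c_xyz[i])
            atoms.append(Atom("CB", "C", tuple(cb), bfactor))
        residues.append(
            Residue(
                name=ONE_TO_THREE[letter],
                number=start_number + i,
                atoms=tuple(atoms),
            )
        )
    return Structure(id=structure_id, chain=chain, residues=tuple(residues))


def build_helix(sequence: str, **kwargs) -> Structure:
    """Ideal alpha-helix (phi, psi = -57, -47)."""
    L = len(sequence)
    return build_backbone(sequence, [HELIX_PHI_PSI[0]] * L, [HELIX_PHI_PSI[1]] * L, **kwargs)


def build_strand(sequence: str, **kwargs) -> Structure:
    """Ideal extended beta-strand (phi, psi = -139, 135)."""
    L = len(sequence)
    return build_backbone(sequence, [STRAND_PHI_PSI[0]] * L, [STRAND_PHI_PSI[1]] * L, **kwargs)


def build_coil(sequence: str, rng: np.random.Generator, **kwargs) -> Structure:
    """Random coil: per-residue phi/psi drawn from broad alpha or beta basins.

    Alternating basin membership per residue breaks any regular secondary
    structure, so the coil resembles neither an ideal helix nor an ideal
    strand over more than a few residues.
    """
    L = len(sequence)
    phi = np.empty(L)
    psi = np.empty(L)
    in_alpha = rng.random(L) < 0.5
    phi[in_alpha] = rng.uniform(-100.0, -45.0, in_alpha.sum())
    psi[in_alpha] = rng.uniform(-60.0, -20.0, in_alpha.sum())
    beta = ~in_alpha
    phi[beta] = rng.uniform(-160.0, -90.0, beta.sum())
    psi[beta] = rng.uniform(90.0, 175.0, beta.sum())
    return build_backbone(sequence, phi, psi, **kwargs)


def build_hairpin(
    sequence: str, turn_start: int | None = None, **kwargs
) -> Structure:
    """Strand-turn-strand hairpin with packed antiparallel strands.

    The two-residue turn dihedrals were chosen so the returning strand runs
    back alongside the first with heavy-atom contacts under 4 A across the
    full strand length — the long-range contact pattern window masking needs.
    """
    L = len(sequence)
    if L < 8:
        raise StructureError("hairpin needs at least 8 residues")
    mid = turn_start if turn_start is not None else L // 2 - 1
    phi = np.full(L, STRAND_PHI_PSI[0])
    psi = np.full(L, STRAND_PHI_PSI[1])
    phi[mid], psi[mid] = 60.0, -120.0
    phi[mid + 1], psi[mid + 1] = -90.0, 0.0
    return build_backbone(sequence, phi, psi, **kwargs)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@dataclass(frozen=True)
class FoldSwitchPairSpec:
    sequence: str
    region: RegionSpec


def make_pair(sequence: str, region: RegionSpec, seed: int = 0):
    """A synthetic fold-switch pair: helical region in A, extended in B.

    Flanks are helical with identical dihedrals in both conformations, so the
    two partners share sequence everywhere and differ structurally only over
    the region — the operational definition of a fold switcher.
    """
    from .benchmark import FoldSwitchPair  # local import to avoid a cycle

    L = len(sequence)
    if not (1 <= region.start <= region.end <= L):
        raise StructureError(f"region {region} outside sequence of length {L}")
    if region.length < 12:
        raise StructureError(f"region {region} shorter than 12 residues")
    phi_a = np.full(L, HELIX_PHI_PSI[0])
    psi_a = np.full(L, HELIX_PHI_PSI[1])
    phi_b = phi_a.copy()
    psi_b = psi_a.copy()
    lo, hi = region.start - 1, region.end  # 0-based slice of the region
    phi_b[lo:hi] = STRAND_PHI_PSI[0]
    psi_b[lo:hi] = STRAND_PHI_PSI[1]
    conf_a = build_backbone(sequence, phi_a, psi_a, structure_id="conf_a")
    conf_b = build_backbone(sequence, phi_b, psi_b, structure_id="conf_b")
    return FoldSwitchPair(
        id=f"synthetic_pair_{seed}",
        conf_a=conf_a,
        conf_b=conf_b,
        region_a=region,
        region_b=region,
        ground_state="A",
    )


def perturb(s: Structure, sigma: float, seed: int = 0) -> Structure:
    """Add iid zero-mean Gaussian noise (sd ``sigma`` A) to every atom."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    residues = []
    for res in s.residues:
        atoms = tuple(
            replace(a, coords=tuple(a.xyz + rng.normal(0.0, sigma, 3)))
            for a in res.atoms
        )
        residues.append(replace(res, atoms=atoms))
    return replace(s, residues=tuple(residues))


def synth_plddt(
    s: Structure,
    target_fraction: float,
    high_value: float = 90.0,
    low_value: float = 50.0,
    seed: int = 0,
) -> list[float]:
    """Profile with exactly round(target_fraction * L) residues at ``high_value``."""
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    L = len(s)
    n_high = round(target_fraction * L)
    rng = np.random.default_rng(seed)
    profile = np.full(L, low_value, dtype=float)
    idx = rng.choice(L, size=n_high, replace=False)
    profile[idx] = high_value
    return profile.tolist()


def set_bfactors(s: Structure, profile: list[float]) -> Structure:
    """Copy a per-residue profile into every atom's B-factor column."""
    if len(profile) != len(s):
        raise ValueError("profile length must match residue count")
    residues = tuple(
        replace(r, atoms=tuple(replace(a, bfactor=v) for a in r.atoms))
        for r, v in zip(s.residues, profile)
    )
    return replace(s, residues=residues)


def synth_msa(
    query: str,
    n_rows: int,
    identity: float = 0.8,
    gap_rate: float = 0.05,
    seed: int = 0,
) -> MSA:
    """Toy alignment: rows mutate each query column with prob (1 - identity)
    and open a gap with prob ``gap_rate``; row 0 is the query itself."""
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must lie in (0, 1]")
    if not 0.0 <= gap_rate < 1.0:
        raise ValueError("gap_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = [query]
    ids = ["query"]
    alphabet = list(AMINO_ACIDS)
    for i in range(n_rows):
        chars = []
        for c in query:
            if rng.random() < gap_rate:
                chars.append("-")
            elif rng.random() < 1.0 - identity:
                chars.append(str(rng.choice(alphabet)))
            else:
                chars.append(c)
        rows.append("".join(chars))
        ids.append(f"homolog_{i}")
    return MSA(ids=tuple(ids), rows=tuple(rows))


@dataclass(frozen=True)
class PLDDTSpec:
    """Mean/sd of the confident-residue fraction drawn per label."""

    mean: float
    sd: float


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for one synthetic benchmark run.

    Defaults: 30-residue fold-switching region in a 60-residue chain, sub-A
    coordinate noise on correct models, and confidence profiles in which
    models matching the dominant fold (or no fold) tend to score higher
    than models matching the alternative fold — the regime in which
    confidence-based reranking depletes the alternative conformation.
    """

    n_proteins: int = 5
    seq_length: int = 60
    region: RegionSpec = field(default_factory=lambda: RegionSpec(16, 45))
    mixture: tuple[float, float, float] = (0.6, 0.3, 0.1)
    noise_sigma: float = 0.4
    plddt_spec: dict[str, PLDDTSpec] = field(
        default_factory=lambda: {
            "Fold1": PLDDTSpec(0.85, 0.08),
            "Fold2": PLDDTSpec(0.55, 0.15),
            "Other": PLDDTSpec(0.80, 0.10),
        }
    )
    n_models: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class SyntheticProtein:
    pair: object  # FoldSwitchPair
    predictions: tuple  # tuple[PredictionRecord, ...]
    true_labels: tuple[str, ...]


@dataclass(frozen=True)
class Scenario:
    spec: ScenarioSpec
    proteins: tuple[SyntheticProtein, ...]


def scenario(spec: ScenarioSpec):
    """Full benchmark fixture: pairs, mixed prediction ensembles, pLDDT."""
    from .benchmark import PredictionRecord

    rng = np.random.default_rng(spec.seed)
    labels = ("Fold1", "Fold2", "Other")
    proteins = []
    for p in range(spec.n_proteins):
        seq = random_sequence(spec.seq_length, rng)
        pair = make_pair(seq, spec.region, seed=spec.seed * 1000 + p)
        pair = replace(pair, id=f"prot{p:03d}")
        preds = []
        truth = []
        drawn = rng.choice(3, size=spec.n_models, p=list(spec.mixture))
        for m, which in enumerate(drawn):
            label = labels[which]
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if label == "Fold1":
                structure = perturb(pair.conf_a, spec.noise_sigma, seed=sub_seed)
            elif label == "Fold2":
                structure = perturb(pair.conf_b, spec.noise_sigma, seed=sub_seed)
            else:
                structure = build_coil(seq, np.random.default_rng(sub_seed))
            ps = spec.plddt_spec[label]
            frac = float(np.clip(rng.normal(ps.mean, ps.sd), 0.0, 1.0))
            profile = synth_plddt(structure, frac, seed=sub_seed)
            structure = set_bfactors(
                replace(structure, id=f"prot{p:03d}_model{m:04d}"), profile
            )
            preds.append(
                PredictionRecord(
                    model_id=f"prot{p:03d}_model{m:04d}",
                    method="synthetic",
                    seed=sub_seed,
                    structure=structure,
                    plddt=tuple(profile),
                )
            )
            truth.append(label)
        proteins.append(
            SyntheticProtein(pair=pair, predictions=tuple(preds), true_labels=tuple(truth))
        )
    return Scenario(spec=spec, proteins=tuple(proteins))
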