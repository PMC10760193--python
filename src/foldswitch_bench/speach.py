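"""Alanine-masked MSA generation (modified SPEACH-style protocol).

An 11-residue window slides by one residue across the fold-switching region.
For each window, every residue with a heavy atom within 4 A of any heavy
atom of a window residue — excluding residues within 4 sequence positions of
the window, and the window residues themselves — has its MSA column mutated
to alanine in every row except the query. Masking contacts is meant to erase
the coevolutionary signal stabilizing one conformation so a predictor can
sample alternatives; generating the masked alignments is in scope here,
running the predictor on them is not.

MSAs are held in a minimal a3m-aware container: uppercase letters and '-'
are match columns, lowercase letters are unaligned insertions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .structio import RegionSpec, Structure, StructureError

__all__ = [
    "MSA",
    "Window",
    "MaskPlan",
    "read_a3m",
    "write_a3m",
    "windows",
    "contact_set",
    "mask_msa",
    "generate_all",
]

WINDOW_LENGTH = 11
CONTACT_CUTOFF = 4.0  # Angstrom, heavy-atom
SEQ_EXCLUSION = 4  # residues of primary sequence around the window


def _match_columns(row: str) -> str:
    """Match-state characters of an a3m row (lowercase insertions removed)."""
    return "".join(c for c in row if not c.islower())


@dataclass(frozen=True)
class MSA:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("one id per row required")
        if not self.rows:
            raise ValueError("MSA needs at least the query row")
        n = len(_match_columns(self.rows[0]))
        for i, row in enumerate(self.rows):
            if len(_match_columns(row)) != n:
                raise ValueError(
                    f"row {self.ids[i]} has {len(_match_columns(row))} match columns, "
                    f"query has {n}"
                )

    @property
    def query(self) -> str:
        return self.rows[0]

    @property
    def n_columns(self) -> int:
        return len(_match_columns(self.rows[0]))

    def __len__(self) -> int:
        return len(self.rows)


def read_a3m(path: str | Path) -> MSA:
    ids, rows = [], []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                ids.append(line[1:].split()[0] if line[1:].strip() else f"row{len(ids)}")
                current.append("")
            elif line and current:
                current[-1] += line.strip()
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return MSA(ids=tuple(ids), rows=tuple(current))


def write_a3m(msa: MSA, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")
    return path


@dataclass(frozen=True)
class Window:
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MaskPlan:
    window: Window
    masked_positions: frozenset[int]


def windows(region: RegionSpec, w: int = WINDOW_LENGTH, step: int = 1) -> list[Window]:
    """All w-residue windows sliding by ``step`` over the region (inclusive)."""
    if region.length < w:
        raise ValueError(f"region {region} shorter than window length {w}")
    return [
        Window(start, start + w - 1)
        for start in range(region.start, region.end - w + 2, step)
    ]


def _heavy_coords(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """(coords, residue numbers) over all non-hydrogen atoms."""
    pts, nums = [], []
    for res in s.residues:
        for atom in res.atoms:
            if atom.element != "H":
                pts.append(atom.xyz)
                nums.append(res.number)
    return np.vstack(pts), np.asarray(nums)


def contact_set(
    s: Structure,
    win: Window,
    cutoff: float = CONTACT_CUTOFF,
    seq_excl: int = SEQ_EXCLUSION,
) -> set[int]:
    """Residues with any heavy atom within ``cutoff`` of the window's heavy
    atoms, excluding window residues and residues within ``seq_excl``
    sequence positions of the window."""
    numbers = {r.number for r in s.residues}
    if not set(range(win.start, win.end + 1)) <= numbers:
        raise StructureError(f"window {win.start}-{win.end} not resolvable in {s.id}")
    coords, nums = _heavy_coords(s)
    in_win = (nums >= win.start) & (nums <= win.end)
    if not in_win.any():
        return set()
    d = cdist(coords[~in_win], coords[in_win])
    close = (d <= cutoff).any(axis=1)
    candidates = set(nums[~in_win][close].tolist())
    return {
        n
        for n in candidates
        if min(abs(n - win.start), abs(n - win.end)) > seq_excl
        # separation measured to the nearest window residue; numbers inside
        # the window were already excluded via ~in_win only if no atom of the
        # residue falls in the window — guard explicitly:
        and not (win.start <= n <= win.end)
    }


def _column_map(msa: MSA, s: Structure) -> dict[int, int]:
    """Residue number -> match-column index, requiring exact sequence match."""
    query_match = _match_columns(msa.query).replace("-", "")
    if query_match != s.sequence:
        raise ValueError(
            "query sequence does not match structure sequence: "
            f"{query_match} vs {s.sequence}"
        )
    mapping = {}
    col = 0
    res_iter = iter(s.residues)
    for c in _match_columns(msa.query):
        if c != "-":
            mapping[next(res_iter).number] = col
        col += 1
    return mapping


def mask_msa(msa: MSA, columns: Iterable[int]) -> MSA:
    """Alanine-substitute the given match columns in every row but the query.

    Gaps are preserved and lowercase insertion characters are untouched; the
    query row is returned byte-identical.
    """
    cols = set(columns)
    if cols and (min(cols) < 0 or max(cols) >= msa.n_columns):
        raise ValueError(f"mask column outside alignment of width {msa.n_columns}")
    new_rows = [msa.query]
    for row in msa.rows[1:]:
        out = []
        match_idx = 0
        for ch in row:
            if ch.islower():
                out.append(ch)
                continue
            if match_idx in cols and ch != "-":
                out.append("A")
            else:
                out.append(ch)
            match_idx += 1
        new_rows.append("".join(out))
    return MSA(ids=msa.ids, rows=tuple(new_rows))


def mask_positions(msa: MSA, s: Structure, positions: Iterable[int]) -> MSA:
    """Mask MSA columns corresponding to the given residue numbers of ``s``."""
    cmap = _column_map(msa, s)
    cols = []
    for p in positions:
        if p not in cmap:
            raise ValueError(f"residue {p} has no match column in the alignment")
        cols.append(cmap[p])
    return mask_msa(msa, cols)


def generate_all(
    s: Structure,
    msa: MSA,
    region: RegionSpec,
    out_dir: str | Path,
    *,
    window_length: int = WINDOW_LENGTH,
    cutoff: float = CONTACT_CUTOFF,
    seq_excl: int = SEQ_EXCLUSION,
    models_per_window: int = 15,
) -> list[dict]:
    """One alanine-masked MSA per window, plus a TSV manifest.

    The manifest records each window, the residues masked, the output path,
    and the downstream expectation of 15 models per window (3 predictor
    seeds x 5 models; model generation itself happens elsewhere).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for win in windows(region, w=window_length):
        positions = sorted(contact_set(s, win, cutoff=cutoff, seq_excl=seq_excl))
        masked = mask_positions(msa, s, positions)
        name = f"masked_w{win.start:04d}-{win.end:04d}.a3m"
        write_a3m(masked, out_dir / name)
        manifest.append(
            {
                "window_start": win.start,
                "window_end": win.end,
                "n_masked": len(positions),
                "masked_positions": ",".join(map(str, positions)),
                "expected_models": models_per_window,
                "output_path": name,
            }
        )
    with open(out_dir / "manifest.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0].keys()), delimiter="\t")
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
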