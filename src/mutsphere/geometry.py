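"""Protein structure geometry: PDB reading, Cα coordinates, residue neighborhoods.

Each residue is represented by the spatial position of its α-carbon, so a
"sphere of radius ``r``" around a residue is the closed Euclidean ball of
radius ``r`` (Å) centered on that residue's Cα atom.  Only one chain and one
conformation (model) of a structure are analyzed at a time; when several are
present the first one appearing in the file is the default, mirroring common
practice for crystallographic ensembles.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Common chemically modified residues accepted when ``include_modified`` is on.
MODIFIED_AA_3TO1 = {
    "MSE": "M",  # selenomethionine
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "CSO": "C",  # S-hydroxycysteine
    "HYP": "P",  # hydroxyproline
}


class StructureError(ValueError):
    """Base class for structure-loading problems."""


class StructureEmptyError(StructureError):
    """No α-carbon bearing amino-acid residues were found."""


class ChainNotFoundError(StructureError):
    def __init__(self, chain: str, available: Sequence[str]):
        super().__init__(
            f"chain {chain!r} not found; available chains: {sorted(available)}"
        )
        self.available = list(available)


class ConformationNotFoundError(StructureError):
    def __init__(self, conformation: int, n_models: int):
        super().__init__(
            f"conformation {conformation} not found; file has {n_models} model(s)"
        )
        self.n_models = n_models


@dataclass(frozen=True)
class ResiduePoint:
    """A single residue reduced to its α-carbon position.

    ``structure_position`` is the author-assigned residue label from the
    coordinate file (sequence number plus any insertion code, e.g. ``"100A"``);
    ``canonical_position`` is the 1-based index in the protein's canonical
    numbering once reconciliation has assigned one (``None`` before that).
    """

    structure_position: str
    coord: tuple[float, float, float]
    amino_acid: str
    canonical_position: int | None = None

    def __post_init__(self):
        if len(self.coord) != 3 or not all(np.isfinite(self.coord)):
            raise ValueError(f"coord must have 3 finite components, got {self.coord}")
        if self.amino_acid not in STANDARD_AA and self.amino_acid != "X":
            raise ValueError(f"unknown amino-acid letter {self.amino_acid!r}")


@dataclass
class StructureModel:
    """Ordered residues of one chain / one conformation, with Cα coordinates."""

    residues: list[ResiduePoint]
    chain_id: str
    conformation_index: int = 1
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)
    _dmat: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.residues:
            raise StructureEmptyError("a structure model needs at least one residue")
        labels = [r.structure_position for r in self.residues]
        if len(set(labels)) != len(labels):
            raise ValueError("structure_position labels must be unique within a model")

    @property
    def N(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in Å."""
        if self._coords is None:
            self._coords = np.array([r.coord for r in self.residues], dtype=float)
        return self._coords

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def distance_matrix(self) -> np.ndarray:
        """(N, N) matrix of pairwise Cα–Cα Euclidean distances, Å."""
        if self._dmat is None:
            x = self.coords
            d = x[:, None, :] - x[None, :, :]
            self._dmat = np.sqrt((d * d).sum(axis=2))
        return self._dmat

    def neighbor_matrix(self, r: float) -> np.ndarray:
        """Boolean (N, N) closed-ball membership: entry [i, j] iff d(i, j) <= r."""
        return self.distance_matrix <= r

    def neighborhood(self, center: int, r: float) -> frozenset[int]:
        """Residues (1-based indices) within the closed ball of radius ``r`` Å
        around ``center``; always contains ``center`` itself."""
        if not 1 <= center <= self.N:
            raise IndexError(f"center {center} out of range 1..{self.N}")
        if r <= 0:
            raise ValueError("radius must be positive")
        mask = self.distance_matrix[center - 1] <= r
        return frozenset(int(i) + 1 for i in np.nonzero(mask)[0])

    def author_number_index(self) -> dict[int, int]:
        """Map author residue number (insertion-code-free) -> 1-based model index.

        Residues carrying an insertion code are skipped: a bare integer
        canonical position cannot address them unambiguously.  On (rare)
        duplicate author numbers the first is kept.
        """
        out: dict[int, int] = {}
        for i, res in enumerate(self.residues, start=1):
            label = res.structure_position
            if label.lstrip("-").isdigit():
                num = int(label)
                out.setdefault(num, i)
        return out


def distance(a: ResiduePoint, b: ResiduePoint) -> float:
    """Euclidean Cα–Cα distance in Å."""
    pa, pb = np.asarray(a.coord), np.asarray(b.coord)
    return float(np.linalg.norm(pa - pb))


def _residue_letter(resname: str, include_modified: bool) -> str | None:
    letter = seq1(resname, custom_map=MODIFIED_AA_3TO1 if include_modified else None)
    if letter in STANDARD_AA:
        return letter
    return None


def _first_altloc(atom):
    # Bio.PDB's default child access prefers the highest-occupancy altloc;
    # we want a deterministic "first" instead, and altloc ids are listed in
    # alphabetical order in well-formed files, so the lowest id is kept.
    if atom.is_disordered():
        children = sorted(atom.disordered_get_list(), key=lambda a: a.get_altloc())
        return children[0]
    return atom


def load_structure(
    pdb_source: str | Path | IO[str],
    chain: str = "auto",
    conformation: int = 1,
    include_modified: bool = False,
) -> StructureModel:
    """Read a PDB-format file and return one chain / one conformation.

    Parameters
    ----------
    pdb_source:
        Path to a PDB file, raw PDB text, or an open text handle.
    chain:
        Chain identifier to extract, or ``"auto"`` to take the first chain in
        the file that contains α-carbon-bearing amino-acid residues.
    conformation:
        1-based model index for multi-model (e.g. NMR) files; default is the
        first conformation listed.
    include_modified:
        Also accept common chemically modified residues recorded as HETATM
        (selenomethionine and friends), translated to their parent letter.

    Residues without an α-carbon are skipped; alternate locations are resolved
    by keeping the first (lowest altloc id).
    """
    if isinstance(pdb_source, Path):
        handle: IO[str] = open(pdb_source)
    elif isinstance(pdb_source, str):
        if "\n" in pdb_source or not Path(pdb_source).exists():
            handle = io.StringIO(pdb_source)
        else:
            handle = open(pdb_source)
    else:
        handle = pdb_source

    parser = PDBParser(QUIET=True)
    with handle:
        structure = parser.get_structure("model", handle)

    models = list(structure)
    if not models:
        raise StructureEmptyError("no models / ATOM records in input")
    if not 1 <= conformation <= len(models):
        raise ConformationNotFoundError(conformation, len(models))
    model = models[conformation - 1]

    def chain_residues(ch) -> list[ResiduePoint]:
        points = []
        for res in ch:
            hetflag, resseq, icode = res.id
            if hetflag != " " and not (
                include_modified and res.resname in MODIFIED_AA_3TO1
            ):
                continue
            letter = _residue_letter(res.resname, include_modified)
            if letter is None:
                continue
            if "CA" not in res:
                continue
            ca = _first_altloc(res["CA"])
            label = f"{resseq}{icode.strip()}"
            points.append(
                ResiduePoint(
                    structure_position=label,
                    coord=tuple(float(v) for v in ca.coord),
                    amino_acid=letter,
                )
            )
        return points

    available = []
    for ch in model:
        pts = chain_residues(ch)
        if not pts:
            continue
        available.append(ch.id)
        if chain == "auto" or ch.id == chain:
            logger.debug(
                "selected chain %s, conformation %d, %d residues",
                ch.id, conformation, len(pts),
            )
            return StructureModel(
                residues=pts, chain_id=ch.id, conformation_index=conformation
            )
    if not available:
        raise StructureEmptyError("no α-carbon amino-acid residues in input")
    raise ChainNotFoundError(chain, available)


_ATOM_FMT = (
    "ATOM  {serial:>5d}  CA  {resname:<3s} {chain}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
)

_AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


def write_pdb(
    sequence: str,
    coords: Iterable[Sequence[float]],
    chain_id: str = "A",
    start_number: int = 1,
) -> str:
    """Emit minimal valid PDB text: one CA ATOM record per residue.

    Intended for synthetic fixtures; coordinates are written at the format's
    native 3-decimal precision, occupancy 1.00, B-factor 0.00.
    """
    lines = []
    for i, (aa, xyz) in enumerate(zip(sequence, coords, strict=True)):
        lines.append(
            _ATOM_FMT.format(
                serial=i + 1,
                resname=_AA_1TO3.get(aa, "UNK"),
                chain=chain_id,
                resseq=start_number + i,
                x=xyz[0], y=xyz[1], z=xyz[2],
            )
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
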