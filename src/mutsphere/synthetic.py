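"""Synthetic structures and mutation tables with known ground truth.

Desk-scale fixtures for the whole pipeline: idealized protein backbones
(straight chain, α-helix, self-avoiding random coil) written as valid PDB
text, and per-sample mutation tables with optional planted hotspots on top of
a uniform background.  With zero hotspots the generator draws mutation
positions i.i.d. uniformly over residues — exactly the null law the
simulation engine assumes — which is the basis of the calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, mutmap
from .geometry import StructureModel

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical Cα–Cα distance along a protein backbone, Å.
BACKBONE_SPACING = 3.8


@dataclass(frozen=True)
class Hotspot:
    """``count`` mutations spread uniformly over the ``span`` residues
    centered on ``center`` (span should be odd)."""

    center: int
    span: int = 3
    count: int = 0

    def positions(self, n_residues: int) -> list[int]:
        half = self.span // 2
        lo, hi = self.center - half, self.center + half
        if lo < 1 or hi > n_residues:
            raise ValueError(f"hotspot span {lo}..{hi} outside 1..{n_residues}")
        return list(range(lo, hi + 1))


@dataclass
class FixtureSpec:
    geometry: str = "linear"  # linear | helix | random_coil
    N: int = 100
    spacing: float = BACKBONE_SPACING
    hotspots: list[Hotspot] = field(default_factory=list)
    background: int = 0
    samples: int = 5
    gene: str = "SYNTH1"
    seed: int = 0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.background < 0 or any(h.count < 0 for h in self.hotspots):
            raise ValueError("mutation counts must be >= 0")
        if self.geometry not in {"linear", "helix", "random_coil"}:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        for h in self.hotspots:
            h.positions(self.N)  # validates span


def _helix_coords(n: int) -> np.ndarray:
    """Ideal α-helix: radius 2.3 Å, rise 1.5 Å and 100° turn per residue
    (consecutive Cα–Cα distance ≈ 3.8 Å)."""
    i = np.arange(n)
    theta = np.deg2rad(100.0 * i)
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _coil_coords(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random chain: steps of length spacing ± 0.1 Å in random
    directions, rejecting placements within 4 Å of any earlier non-adjacent
    residue."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(1000):
            v = rng.normal(size=3)
            v *= (spacing + rng.uniform(-0.1, 0.1)) / np.linalg.norm(v)
            candidate = coords[i - 1] + v
            if i < 2:
                break
            d = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
            if (d >= 4.0).all():
                break
        else:
            raise RuntimeError("self-avoiding chain generation failed")
        coords[i] = candidate
    return coords


def make_structure(spec: FixtureSpec) -> tuple[StructureModel, str]:
    """Generate the backbone and its PDB text (round-trippable through
    :func:`mutsphere.geometry.load_structure`)."""
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "linear":
        coords = np.column_stack(
            [spec.spacing * np.arange(spec.N), np.zeros(spec.N), np.zeros(spec.N)]
        )
    elif spec.geometry == "helix":
        coords = _helix_coords(spec.N)
    else:
        coords = _coil_coords(spec.N, spec.spacing, rng)
    sequence = "".join(rng.choice(list(AA_LETTERS), size=spec.N))
    pdb_text = geometry.write_pdb(sequence, np.round(coords, 3))
    model = geometry.load_structure(pdb_text)
    return model, pdb_text


def make_mutations(spec: FixtureSpec, model: StructureModel) -> list[mutmap.MutationRecord]:
    """Generate sample-level missense mutation records.

    Hotspot mutations are placed uniformly within each hotspot span and
    background mutations uniformly over all residues; sample ids are assigned
    round-robin.  All records carry an accepted somatic status and a
    whole-genome screen type, so the inclusion filter is a no-op on fixtures.
    """
    rng = np.random.default_rng(spec.seed + 1)
    positions: list[int] = []
    for h in spec.hotspots:
        span = h.positions(spec.N)
        positions.extend(int(p) for p in rng.choice(span, size=h.count))
    positions.extend(int(p) for p in rng.integers(1, spec.N + 1, size=spec.background))

    records = []
    occurrence: dict[tuple[str, int], int] = {}
    for i, pos in enumerate(positions):
        wt = model.residues[pos - 1].amino_acid
        sample = f"S{i % spec.samples + 1:03d}"
        # cycle through alternative residues so repeated hits of the same
        # (sample, position) stay distinct records: the dedupe filter must be
        # a no-op on generated tables
        alternatives = [a for a in AA_LETTERS if a != wt]
        k = occurrence.get((sample, pos), 0)
        occurrence[(sample, pos)] = k + 1
        if k >= len(alternatives):
            raise ValueError(
                "too many mutations per (sample, position); increase samples"
            )
        mut = alternatives[k]
        records.append(
            mutmap.MutationRecord(
                gene=spec.gene,
                sample_id=sample,
                position=pos,
                wt_aa=wt,
                mut_aa=mut,
                mutation_type="missense",
                somatic_status="Confirmed somatic variant",
                screen_type="whole_genome",
            )
        )
    return records


def write_fasta(sequence: str, dest: Path, name: str = "synthetic"):
    lines = [f">{name}"]
    for i in range(0, len(sequence), 60):
        lines.append(sequence[i : i + 60])
    dest.write_text("\n".join(lines) + "\n")


def make_study_dir(
    out_dir: str | Path,
    specs: list[FixtureSpec] | None = None,
    seed: int = 0,
) -> Path:
    """Materialize a ready-to-run study directory (PDBs, mutation TSVs,
    FASTAs, manifest.tsv).

    The default demo study has two structures with planted hotspots and three
    background-only structures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if specs is None:
        specs = default_demo_specs(seed)

    manifest_rows = []
    for i, spec in enumerate(specs, start=1):
        stem = f"structure_{i:02d}"
        model, pdb_text = make_structure(spec)
        (out_dir / f"{stem}.pdb").write_text(pdb_text)
        records = make_mutations(spec, model)
        mutmap.write_mutation_table(records, out_dir / f"{stem}.mutations.tsv")
        write_fasta(model.sequence, out_dir / f"{stem}.fasta", name=spec.gene)
        manifest_rows.append(
            "\t".join(
                [
                    f"{stem}.pdb",
                    "auto",
                    "1",
                    spec.gene,
                    f"{stem}.mutations.tsv",
                    f"{stem}.fasta",
                    "alignment",
                ]
            )
        )
    header = "\t".join(
        [
            "structure_path",
            "chain",
            "conformation",
            "gene",
            "mutation_table_path",
            "fasta_path",
            "reconciliation_mode",
        ]
    )
    (out_dir / "manifest.tsv").write_text("\n".join([header] + manifest_rows) + "\n")
    return out_dir / "manifest.tsv"


def default_demo_specs(seed: int = 0) -> list[FixtureSpec]:
    """Two planted-hotspot structures plus three background-only ones."""
    specs = [
        FixtureSpec(
            geometry="helix", N=150, hotspots=[Hotspot(60, 3, 40)], background=10,
            gene="HOTGENE1", seed=seed + 11,
        ),
        FixtureSpec(
            geometry="random_coil", N=120,
            hotspots=[Hotspot(30, 3, 25), Hotspot(90, 3, 20)], background=8,
            gene="HOTGENE2", seed=seed + 22,
        ),
    ]
    for j in range(3):
        specs.append(
            FixtureSpec(
                geometry="random_coil", N=100, background=25,
                gene=f"NULLGENE{j + 1}", seed=seed + 33 + j,
            )
        )
    return specs
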