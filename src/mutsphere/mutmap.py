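"""Mutation tables: filtering, canonical/structure reconciliation, tallies.

Somatic mutation catalogues report protein positions in the canonical
(database) numbering of a gene, while coordinate files carry the author's own
residue numbering.  This module ingests a per-sample mutation table, applies
the inclusion filters appropriate for testing spatial uniformity (missense
only, somatic, unbiased screens, deduplicated), maps canonical positions onto
structure residues either through the author numbering or through a global
pairwise sequence alignment, and aggregates per-residue mutation counts over
all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .geometry import STANDARD_AA, StructureModel

logger = logging.getLogger(__name__)

#: Somatic status strings accepted by the inclusion filter (compared
#: case-insensitively after whitespace trimming).
ACCEPTED_SOMATIC_STATUS = frozenset(
    {
        "confirmed somatic variant",
        "reported in another cancer sample as somatic",
    }
)

ACCEPTED_SCREENS = frozenset({"whole_gene", "whole_genome"})

MUTATION_TYPES = frozenset({"missense", "nonsense", "synonymous", "indel", "other"})

TABLE_COLUMNS = [
    "gene",
    "sample_id",
    "position",
    "wt_aa",
    "mut_aa",
    "mutation_type",
    "somatic_status",
    "screen_type",
]


class MutationTableError(ValueError):
    """Malformed rows in a mutation table; message lists offending row numbers."""


class ReconciliationError(ValueError):
    """Canonical sequence could not be reliably mapped onto the structure."""


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    sample_id: str
    position: int  # 1-based canonical residue index
    wt_aa: str
    mut_aa: str
    mutation_type: str = "missense"
    somatic_status: str = "confirmed somatic variant"
    screen_type: str = "whole_genome"


@dataclass
class ResidueMapping:
    """Canonical position -> 1-based structure residue index (or unmapped)."""

    pairs: dict[int, int]
    mode: Literal["structure_numbering", "alignment"]
    alignment_identity: float | None = None

    def __post_init__(self):
        targets = list(self.pairs.values())
        if len(set(targets)) != len(targets):
            raise ValueError("residue mapping must be injective")


@dataclass
class MutationTally:
    """Per-residue aggregated mutation occurrences, mapped onto a structure.

    ``counts`` is keyed by canonical position (mapped positions only);
    ``structure_counts`` is the same information as a length-N vector over the
    structure's residue indices — the form the sphere-cover kernel consumes.
    """

    counts: dict[int, int]
    structure_counts: np.ndarray
    dropped_unmapped: int = 0

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def mapped_positions(self) -> frozenset[int]:
        return frozenset(self.counts)


def read_mutation_table(source: str | Path | IO[str]) -> list[MutationRecord]:
    """Read the tab-separated mutation table contract.

    Expected header: gene, sample_id, position, wt_aa, mut_aa, mutation_type,
    somatic_status, screen_type.  Positions are 1-based.  Raises
    :class:`MutationTableError` listing the (1-based, header-exclusive) row
    numbers of malformed records.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MutationTableError(f"mutation table missing columns: {missing}")

    records, bad = [], []
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pos = int(getattr(row, "position"))
        except ValueError:
            bad.append((rownum, "non-integer position"))
            continue
        wt = getattr(row, "wt_aa").strip().upper()
        mut = getattr(row, "mut_aa").strip().upper()
        mtype = getattr(row, "mutation_type").strip().lower()
        problems = []
        if pos < 1:
            problems.append("position < 1")
        if wt not in STANDARD_AA | {"X"}:
            problems.append(f"unknown wt_aa {wt!r}")
        if mut not in STANDARD_AA | {"X", "*"}:
            problems.append(f"unknown mut_aa {mut!r}")
        if mtype == "missense" and wt == mut:
            problems.append("missense with wt_aa == mut_aa")
        if problems:
            bad.append((rownum, "; ".join(problems)))
            continue
        records.append(
            MutationRecord(
                gene=getattr(row, "gene").strip(),
                sample_id=getattr(row, "sample_id").strip(),
                position=pos,
                wt_aa=wt,
                mut_aa=mut,
                mutation_type=mtype,
                somatic_status=getattr(row, "somatic_status").strip(),
                screen_type=getattr(row, "screen_type").strip().lower(),
            )
        )
    if bad:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in bad)
        raise MutationTableError(f"malformed mutation records: {detail}")
    return records


def write_mutation_table(records: Iterable[MutationRecord], dest: str | Path | IO[str]):
    df = pd.DataFrame([r.__dict__ for r in records], columns=TABLE_COLUMNS)
    df.to_csv(dest, sep="\t", index=False)


def filter_mutations(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Apply the inclusion filters and deduplicate.

    Keeps records that are (i) missense, (ii) carry one of the accepted
    somatic-status strings, (iii) come from whole-gene or whole-genome screens
    (targeted screens would bias the spatial null).  Exact duplicates on
    (gene, sample_id, position, wt_aa, mut_aa) are then removed, keeping the
    first occurrence, so one sample never contributes the same substitution
    twice.
    """
    kept: list[MutationRecord] = []
    seen: set[tuple] = set()
    for rec in records:
        if rec.mutation_type != "missense":
            continue
        if rec.somatic_status.strip().lower() not in ACCEPTED_SOMATIC_STATUS:
            continue
        if rec.screen_type not in ACCEPTED_SCREENS:
            continue
        key = (rec.gene, rec.sample_id, rec.position, rec.wt_aa, rec.mut_aa)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    logger.info("mutation filter: %d of %d records kept", len(kept), len(records))
    return kept


def read_fasta_sequence(source: str | Path | IO[str]) -> str:
    """First record of a FASTA file, as an upper-case amino-acid string."""
    for rec in SeqIO.parse(source, "fasta"):
        return str(rec.seq).upper()
    raise ValueError("no FASTA records in input")


def _default_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def reconcile(
    canonical_seq: str | None,
    model: StructureModel,
    mode: Literal["structure_numbering", "alignment"] = "alignment",
    identity_floor: float = 0.90,
    aligner: PairwiseAligner | None = None,
) -> ResidueMapping:
    """Map canonical residue positions onto structure residue indices.

    ``structure_numbering`` trusts the author numbering in the coordinate
    file: canonical position p maps to the residue whose author number equals
    p.  ``alignment`` performs a global pairwise alignment (BLOSUM62, gap open
    10 / extend 0.5) between the canonical sequence and the structure-derived
    sequence, and maps positions through aligned non-gap columns; an identity
    fraction below ``identity_floor`` raises :class:`ReconciliationError`
    rather than returning a probably-wrong mapping.
    """
    if mode == "structure_numbering":
        index = model.author_number_index()
        return ResidueMapping(pairs=dict(sorted(index.items())), mode=mode)

    if mode != "alignment":
        raise ValueError(f"unknown reconciliation mode {mode!r}")
    if not canonical_seq:
        raise ReconciliationError("alignment mode requires a canonical sequence")

    canonical_seq = canonical_seq.upper()
    struct_seq = model.sequence
    aln = (aligner or _default_aligner()).align(canonical_seq, struct_seq)[0]

    pairs: dict[int, int] = {}
    matches = aligned_cols = 0
    for (c0, c1), (s0, s1) in zip(*aln.aligned):
        for k in range(c1 - c0):
            cpos, spos = c0 + k, s0 + k
            pairs[cpos + 1] = spos + 1
            aligned_cols += 1
            if canonical_seq[cpos] == struct_seq[spos]:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < identity_floor:
        raise ReconciliationError(
            f"alignment identity {identity:.3f} below floor {identity_floor:.2f}"
        )
    logger.info(
        "alignment reconciliation: %d/%d structure residues mapped, identity %.3f",
        len(pairs), model.N, identity,
    )
    return ResidueMapping(pairs=pairs, mode="alignment", alignment_identity=identity)


def check_wildtype(
    records: Sequence[MutationRecord], canonical_seq: str
) -> list[MutationRecord]:
    """Warn (don't fail) about records whose wt_aa disagrees with the sequence.

    Isoform drift between mutation databases and canonical sequences makes a
    hard failure too brittle; mismatches are returned for inspection.
    """
    mismatched = [
        r
        for r in records
        if r.position <= len(canonical_seq) and canonical_seq[r.position - 1] != r.wt_aa
    ]
    if mismatched:
        logger.warning(
            "%d mutation record(s) disagree with the canonical sequence at their "
            "position (isoform drift?)", len(mismatched),
        )
    return mismatched


def tally(
    records: Sequence[MutationRecord],
    mapping: ResidueMapping,
    model: StructureModel,
) -> MutationTally:
    """Aggregate mapped mutation occurrences per residue (sample-level).

    Two samples mutating the same residue contribute two occurrences.
    Records at canonical positions without structure coordinates are dropped
    (counted in ``dropped_unmapped``).
    """
    counts: dict[int, int] = {}
    structure_counts = np.zeros(model.N, dtype=np.int64)
    dropped = 0
    for rec in records:
        target = mapping.pairs.get(rec.position)
        if target is None:
            dropped += 1
            continue
        counts[rec.position] = counts.get(rec.position, 0) + 1
        structure_counts[target - 1] += 1
    if dropped:
        logger.info("tally: %d mutation occurrence(s) without tertiary data dropped", dropped)
    return MutationTally(
        counts=dict(sorted(counts.items())),
        structure_counts=structure_counts,
        dropped_unmapped=dropped,
    )


def is_blank(t: MutationTally) -> bool:
    """A structure with fewer than two mapped mutation occurrences is "blank":
    no spatial clustering is assessable and it is excluded from analysis."""
    return t.total < 2


def mapping_report(mapping: ResidueMapping, model: StructureModel) -> pd.DataFrame:
    """Tidy per-position report of the reconciliation outcome."""
    rows = []
    for cpos, spos in mapping.pairs.items():
        rows.append(
            {
                "canonical_position": cpos,
                "structure_position": model.residues[spos - 1].structure_position,
                "status": "mapped",
            }
        )
    return pd.DataFrame(rows, columns=["canonical_position", "structure_position", "status"])
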