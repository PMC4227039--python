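"""Multi-structure studies: per-structure analysis plus a rough-FDR threshold.

A study analyzes many structure/mutation pairs; each non-blank structure
yields one Monte-Carlo p-value.  Because many structures can belong to one
protein the tests are positively correlated, so a Bonferroni bound is overly
conservative; the rough false-discovery-rate cutoff

    rFDR = alpha * (k + 1) / (2 k)

(k = number of analyzed structures) is applied instead, optionally rounded
down for a conservative published threshold.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import geometry, mutmap, nullsim
from .nullsim import DEFAULT_RADII, DEFAULT_SPHERE_COUNTS, DEFAULT_T, HotspotResult

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "structure_path",
    "chain",
    "conformation",
    "gene",
    "mutation_table_path",
    "fasta_path",
    "reconciliation_mode",
]


@dataclass
class RunConfig:
    """Effective analysis configuration (embedded in every result file)."""

    radii: tuple[float, ...] = DEFAULT_RADII
    max_spheres: int = 3
    simulations: int = DEFAULT_T
    seed: int = 0
    alpha: float = 0.05
    reconciliation_mode: str = "alignment"
    chain: str = "auto"
    conformation: int = 1
    identity_floor: float = 0.90
    threshold_precision: int = 3

    def __post_init__(self):
        radii = tuple(float(r) for r in self.radii)
        if not radii or any(r <= 0 for r in radii) or list(radii) != sorted(set(radii)):
            raise ValueError("radii must be positive and strictly increasing")
        self.radii = radii
        if self.simulations < 1:
            raise ValueError("simulations (T) must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_spheres < 1:
            raise ValueError("max_spheres must be >= 1")

    @property
    def grid(self) -> list[tuple[int, float]]:
        counts = tuple(range(1, self.max_spheres + 1))
        return nullsim.default_grid(radii=self.radii, sphere_counts=counts)

    def to_dict(self) -> dict:
        return {
            "radii": list(self.radii),
            "max_spheres": self.max_spheres,
            "simulations": self.simulations,
            "seed": self.seed,
            "alpha": self.alpha,
            "reconciliation_mode": self.reconciliation_mode,
            "chain": self.chain,
            "conformation": self.conformation,
            "identity_floor": self.identity_floor,
            "threshold_precision": self.threshold_precision,
        }


@dataclass(frozen=True)
class ManifestEntry:
    structure_id: str
    structure_path: Path
    gene: str
    mutation_table_path: Path
    chain: str = "auto"
    conformation: int = 1
    fasta_path: Path | None = None
    reconciliation_mode: str = "alignment"


@dataclass
class StructureRow:
    structure_id: str
    gene: str
    status: str  # analyzed | blank | error
    p_value: float | None = None
    p_floor: bool = False
    p_text: str = ""
    significant: bool = False
    n_mapped: int = 0
    n_dropped: int = 0
    result: HotspotResult | None = None
    error: str = ""


@dataclass
class StudyResult:
    k: int
    alpha: float
    rfdr: float
    effective_threshold: float
    rows: list[StructureRow]
    per_gene: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            recs.append(
                {
                    "structure_id": row.structure_id,
                    "gene": row.gene,
                    "status": row.status,
                    "p_value": row.p_value,
                    "p_text": row.p_text,
                    "significant": row.significant,
                    "n_mapped": row.n_mapped,
                    "n_dropped": row.n_dropped,
                    "error": row.error,
                }
            )
        return pd.DataFrame(recs)


def rfdr_threshold(alpha: float, k: int) -> float:
    """Rough-FDR significance cutoff alpha * (k + 1) / (2 k) for k tests.

    Decreases from alpha at k = 1 toward alpha / 2 as k grows; a good
    approximation to standard FDR control for many positively correlated or
    independent tests.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha * (k + 1) / (2 * k)


def round_down(value: float, precision: int) -> float:
    """Round a threshold DOWN at ``precision`` decimals (conservative)."""
    scale = 10**precision
    return math.floor(value * scale) / scale


def derive_seed(master_seed: int, structure_id: str) -> int:
    """Stable per-structure sub-seed, independent of manifest row order."""
    digest = hashlib.sha256(f"{master_seed}:{structure_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a study manifest (TSV); relative paths resolve against its folder."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    base = path.parent
    entries = []
    for row in df.itertuples(index=False):
        spath = base / getattr(row, "structure_path")
        fasta = getattr(row, "fasta_path").strip()
        entries.append(
            ManifestEntry(
                structure_id=spath.stem,
                structure_path=spath,
                gene=getattr(row, "gene"),
                mutation_table_path=base / getattr(row, "mutation_table_path"),
                chain=getattr(row, "chain") or "auto",
                conformation=int(getattr(row, "conformation") or 1),
                fasta_path=base / fasta if fasta else None,
                reconciliation_mode=getattr(row, "reconciliation_mode") or "alignment",
            )
        )
    if not entries:
        raise ValueError("manifest is empty")
    return entries


def analyze_entry(entry: ManifestEntry, config: RunConfig) -> StructureRow:
    """Run the full single-structure pipeline for one manifest entry."""
    row = StructureRow(structure_id=entry.structure_id, gene=entry.gene, status="error")
    try:
        model = geometry.load_structure(
            entry.structure_path, chain=entry.chain, conformation=entry.conformation
        )
        records = mutmap.filter_mutations(
            mutmap.read_mutation_table(entry.mutation_table_path)
        )
        canonical = (
            mutmap.read_fasta_sequence(entry.fasta_path) if entry.fasta_path else None
        )
        mapping = mutmap.reconcile(
            canonical,
            model,
            mode=entry.reconciliation_mode,
            identity_floor=config.identity_floor,
        )
        tally = mutmap.tally(records, mapping, model)
        row.n_mapped = tally.total
        row.n_dropped = tally.dropped_unmapped
        logger.info(
            "%s: %d mutation occurrences mapped, %d dropped",
            entry.structure_id, tally.total, tally.dropped_unmapped,
        )
        if mutmap.is_blank(tally):
            row.status = "blank"
            return row
        result = nullsim.analyze(
            model,
            tally,
            grid=config.grid,
            T=config.simulations,
            seed=derive_seed(config.seed, entry.structure_id),
        )
        row.status = "analyzed"
        row.p_value = result.p_value
        row.p_floor = result.p_floor
        row.p_text = result.p_text
        row.result = result
    except Exception as exc:  # per-structure failures must not abort the study
        row.error = f"{type(exc).__name__}: {exc}"
        logger.error("%s failed: %s", entry.structure_id, row.error)
    return row


def comparable_p(row: StructureRow) -> float:
    """p-value used for thresholding: floor results ("< 1/T") compare as
    1/(2T), strictly below any achievable non-floor value."""
    assert row.p_value is not None
    if row.p_floor:
        return 1.0 / (2 * (row.result.T if row.result else DEFAULT_T))
    return row.p_value


def run_study(manifest: list[ManifestEntry], config: RunConfig) -> StudyResult:
    """Analyze every manifest entry and apply the rough-FDR threshold.

    Blank structures and per-structure failures are recorded but excluded
    before k is counted.  Each structure gets an independent sub-seed derived
    from (master seed, structure id), so results do not depend on manifest
    row order.
    """
    rows = [analyze_entry(entry, config) for entry in manifest]
    analyzed = [r for r in rows if r.status == "analyzed"]
    k = len(analyzed)
    if k == 0:
        return StudyResult(
            k=0, alpha=config.alpha, rfdr=float("nan"),
            effective_threshold=float("nan"), rows=rows,
        )
    rfdr = rfdr_threshold(config.alpha, k)
    threshold = round_down(rfdr, config.threshold_precision)
    per_gene: dict[str, float] = {}
    for row in analyzed:
        p = comparable_p(row)
        row.significant = p <= threshold
        per_gene[row.gene] = min(per_gene.get(row.gene, 1.0), p)
    return StudyResult(
        k=k,
        alpha=config.alpha,
        rfdr=rfdr,
        effective_threshold=threshold,
        rows=rows,
        per_gene=per_gene,
    )
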