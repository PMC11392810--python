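"""Domain types and readers/writers shared by the SHM-seq pipeline.

The data model mirrors the assay: a barcoded capture array (:class:`ArrayLayout`),
spatially barcoded read pairs (:class:`SpatialRead`), a taxonomic reference
(:class:`TaxonomyTree` + :class:`ReferenceSet`) and UMI-collapsed count matrices
(:class:`TaxaCountMatrix`) annotated by morphological region
(:class:`SpotAnnotation`).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import io as spio
from scipy import sparse

BARCODE_LEN = 18
UMI_LEN = 7
GRID_NX = 35  # columns (x: 1..35)
GRID_NY = 33  # rows (y: 1..33)
SPOT_PITCH_UM = 200.0
SPOT_DIAMETER_UM = 100.0
N_DEFAULT_SPOTS = 1007

#: Rank order from root to leaf used throughout.
RANKS = ("root", "phylum", "class", "order", "family", "genus", "species")
RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

#: Morphological region-of-interest vocabulary (16 tags).
MROI_TAGS = (
    "E", "ALL", "EMMSUB", "EMM", "MSUB", "BASE", "MEI", "ME",
    "MI", "MMI", "MUPE", "MID", "APEXMU", "UPPERMID", "PP", "PE",
)

CONDITIONS = ("SPF", "GF", "ASF")

DNA = "ACGT"


class FormatError(ValueError):
    """Raised on malformed input files or inconsistent in-memory objects."""


# ---------------------------------------------------------------------------
# Array layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spot:
    spot_id: str
    barcode: str
    grid_x: int
    grid_y: int


@dataclass
class ArrayLayout:
    """Barcoded capture-spot geometry.

    Grid coordinates are 1-based indices into a ``GRID_NX`` x ``GRID_NY``
    frame; the physical position of a spot is ``(grid_x * pitch, grid_y *
    pitch)`` with a 200-um pitch and 100-um spot diameter.
    """

    spots: list[Spot]
    reserved_positions: set[tuple[int, int]] = field(default_factory=set)
    pitch_um: float = SPOT_PITCH_UM
    diameter_um: float = SPOT_DIAMETER_UM

    def __post_init__(self) -> None:
        barcodes = [s.barcode for s in self.spots]
        if len(set(barcodes)) != len(barcodes):
            raise FormatError("duplicate barcodes in layout")
        for s in self.spots:
            if not (1 <= s.grid_x <= GRID_NX and 1 <= s.grid_y <= GRID_NY):
                raise FormatError(
                    f"spot {s.spot_id!r}: coordinate ({s.grid_x}, {s.grid_y}) "
                    f"outside the {GRID_NX}x{GRID_NY} grid"
                )
            if len(s.barcode) != BARCODE_LEN:
                raise FormatError(
                    f"spot {s.spot_id!r}: barcode length {len(s.barcode)} != {BARCODE_LEN}"
                )
        occupied = {(s.grid_x, s.grid_y) for s in self.spots}
        if len(occupied) != len(self.spots):
            raise FormatError("two spots share a grid position")
        if occupied & self.reserved_positions:
            raise FormatError("a spot sits on a reserved position")

    @property
    def barcodes(self) -> list[str]:
        return [s.barcode for s in self.spots]

    def barcode_to_spot(self) -> dict[str, Spot]:
        return {s.barcode: s for s in self.spots}

    def positions(self) -> np.ndarray:
        """(n_spots, 2) array of grid coordinates in spot order."""
        return np.array([(s.grid_x, s.grid_y) for s in self.spots], dtype=int)

    def __len__(self) -> int:
        return len(self.spots)


def _default_reserved_positions() -> set[tuple[int, int]]:
    """148 grid positions left unprinted in the default frame.

    The frame prints 35 x 33 = 1,155 addressable positions but only 1,007
    barcoded spots.  Which 148 positions are blank is a convention of this
    package: the outer border ring (132 positions, used as a fiducial frame)
    plus a 4x4 registration block in the top-left interior corner
    (x in 2..5, y in 2..5; 16 positions).
    """
    reserved: set[tuple[int, int]] = set()
    for x in range(1, GRID_NX + 1):
        reserved.add((x, 1))
        reserved.add((x, GRID_NY))
    for y in range(1, GRID_NY + 1):
        reserved.add((1, y))
        reserved.add((GRID_NX, y))
    for x in range(2, 6):
        for y in range(2, 6):
            reserved.add((x, y))
    assert len(reserved) == GRID_NX * GRID_NY - N_DEFAULT_SPOTS
    return reserved


def _generate_barcodes(n: int, rng: np.random.Generator, min_dist: int = 5) -> list[str]:
    """Deterministically generate ``n`` 18-nt barcodes pairwise Hamming >= min_dist."""
    picked: list[np.ndarray] = []
    while len(picked) < n:
        cand = rng.integers(0, 4, size=BARCODE_LEN)
        ok = True
        for other in picked:
            if int(np.sum(cand != other)) < min_dist:
                ok = False
                break
        if ok:
            picked.append(cand)
    return ["".join(DNA[b] for b in bc) for bc in picked]


@functools.lru_cache(maxsize=4)
def default_layout(seed: int = 90210) -> ArrayLayout:
    """The bundled default array: 1,007 barcoded spots on a 35x33 frame.

    Barcodes are generated deterministically from ``seed`` with pairwise
    Hamming distance >= 5, so demultiplexing at <= 2 mismatches is
    unambiguous by construction.
    """
    reserved = _default_reserved_positions()
    coords = [
        (x, y)
        for y in range(1, GRID_NY + 1)
        for x in range(1, GRID_NX + 1)
        if (x, y) not in reserved
    ]
    rng = np.random.default_rng(seed)
    barcodes = _generate_barcodes(len(coords), rng)
    spots = [
        Spot(spot_id=f"spot_{i:04d}", barcode=bc, grid_x=x, grid_y=y)
        for i, ((x, y), bc) in enumerate(zip(coords, barcodes))
    ]
    return ArrayLayout(spots=spots, reserved_positions=reserved)


def load_layout(path: str | Path) -> ArrayLayout:
    """Read a layout TSV with columns spot_id, barcode, x, y."""
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "barcode": str})
    required = {"spot_id", "barcode", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(f"layout file missing columns {sorted(required - set(df.columns))}")
    dup = df["barcode"].duplicated()
    if dup.any():
        raise FormatError(f"duplicate barcode at row {int(np.flatnonzero(dup)[0])}")
    spots = []
    for i, row in enumerate(df.itertuples(index=False)):
        x, y = int(row.x), int(row.y)
        if not (1 <= x <= GRID_NX and 1 <= y <= GRID_NY):
            raise FormatError(f"row {i} ({row.spot_id}): coordinate ({x}, {y}) outside grid")
        spots.append(Spot(spot_id=str(row.spot_id), barcode=str(row.barcode), grid_x=x, grid_y=y))
    return ArrayLayout(spots=spots)


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    pd.DataFrame(
        {
            "spot_id": [s.spot_id for s in layout.spots],
            "barcode": [s.barcode for s in layout.spots],
            "x": [s.grid_x for s in layout.spots],
            "y": [s.grid_y for s in layout.spots],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class SpatialRead:
    """A read pair after positional parsing of R1.

    R1 carries the 18-nt spatial barcode (positions 1-18) followed by the
    7-nt UMI (positions 19-25); R2 carries the captured 16S fragment.
    """

    read_id: str
    barcode_obs: str
    umi: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.barcode_obs) != BARCODE_LEN:
            raise FormatError(f"{self.read_id}: barcode length != {BARCODE_LEN}")
        if len(self.umi) != UMI_LEN:
            raise FormatError(f"{self.read_id}: UMI length != {UMI_LEN}")


@dataclass
class FastqPairSummary:
    n_pairs: int = 0
    n_valid: int = 0
    n_invalid_r1: int = 0


class ReadPairStream:
    """Iterator over :class:`SpatialRead` from a FASTQ pair, with a summary.

    R1 records shorter than 25 nt are counted in ``summary.n_invalid_r1`` and
    skipped; mismatched record counts between the two files raise.
    """

    def __init__(self, r1_path: str | Path, r2_path: str | Path) -> None:
        self.r1_path = Path(r1_path)
        self.r2_path = Path(r2_path)
        self.summary = FastqPairSummary()

    def __iter__(self) -> Iterator[SpatialRead]:
        with open(self.r1_path) as h1, open(self.r2_path) as h2:
            it1 = FastqGeneralIterator(h1)
            it2 = FastqGeneralIterator(h2)
            while True:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
                if rec1 is None and rec2 is None:
                    return
                if (rec1 is None) != (rec2 is None):
                    raise FormatError("R1 and R2 have different record counts")
                title1, seq1, _ = rec1
                title2, seq2, qual2 = rec2
                self.summary.n_pairs += 1
                if len(seq1) < BARCODE_LEN + UMI_LEN:
                    self.summary.n_invalid_r1 += 1
                    continue
                self.summary.n_valid += 1
                yield SpatialRead(
                    read_id=title1.split()[0],
                    barcode_obs=seq1[:BARCODE_LEN],
                    umi=seq1[BARCODE_LEN : BARCODE_LEN + UMI_LEN],
                    sequence=seq2,
                    qualities=qual2,
                )


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> ReadPairStream:
    """Stream :class:`SpatialRead` records from a paired FASTQ."""
    return ReadPairStream(r1_path, r2_path)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (read_id, sequence, quality) triples as Sanger FASTQ."""
    with open(path, "w") as handle:
        for read_id, seq, qual in records:
            handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    name: str
    rank: str
    parent_id: Optional[str]


class TaxonomyTree:
    """A rank-ordered taxonomy with a single root.

    Ranks follow :data:`RANKS`; ranks must strictly increase along any
    root-to-leaf path (levels may be skipped, e.g. root -> family).
    """

    def __init__(self, nodes: Iterable[TaxonNode]) -> None:
        self.nodes: dict[str, TaxonNode] = {}
        for n in nodes:
            if n.taxon_id in self.nodes:
                raise FormatError(f"duplicate taxon id {n.taxon_id!r}")
            self.nodes[n.taxon_id] = n
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise FormatError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root_id = roots[0].taxon_id
        for n in self.nodes.values():
            if n.parent_id is not None:
                parent = self.nodes.get(n.parent_id)
                if parent is None:
                    raise FormatError(f"{n.taxon_id}: unknown parent {n.parent_id!r}")
                if RANK_INDEX[n.rank] <= RANK_INDEX[parent.rank]:
                    raise FormatError(
                        f"{n.taxon_id}: rank {n.rank} not below parent rank {parent.rank}"
                    )
        for n in self.nodes.values():
            if n.rank == "species" and self.ancestor_at_rank(n.taxon_id, "genus") is None:
                raise FormatError(f"species {n.taxon_id} has no genus ancestor")

    def path_to_root(self, taxon_id: str) -> list[str]:
        path = [taxon_id]
        while self.nodes[path[-1]].parent_id is not None:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Optional[str]:
        for tid in self.path_to_root(taxon_id):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def genus_of(self, taxon_id: str) -> Optional[str]:
        return self.ancestor_at_rank(taxon_id, "genus")

    def lca(self, taxon_ids: Sequence[str]) -> str:
        if not taxon_ids:
            raise ValueError("lca of empty set")
        common = None
        for tid in taxon_ids:
            path = self.path_to_root(tid)
            common = set(path) if common is None else common & set(path)
        # deepest common ancestor = the one with the longest path to root
        return max(common, key=lambda t: len(self.path_to_root(t)))

    def children(self, taxon_id: str) -> list[str]:
        return [t for t, n in self.nodes.items() if n.parent_id == taxon_id]

    @property
    def species_ids(self) -> list[str]:
        return sorted(t for t, n in self.nodes.items() if n.rank == "species")

    @property
    def genus_ids(self) -> list[str]:
        return sorted(t for t, n in self.nodes.items() if n.rank == "genus")

    def rank_of(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].rank


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

@dataclass
class RefRecord:
    species_id: str
    lineage: tuple[str, ...]  # taxon ids from root to species
    sequence: str
    capture_site: Optional[tuple[int, int]] = None  # 0-based half-open

    def __post_init__(self) -> None:
        if self.capture_site is not None:
            a, b = self.capture_site
            if not (0 <= a < b <= len(self.sequence)):
                raise FormatError(
                    f"{self.species_id}: capture site {self.capture_site} outside sequence"
                )


@dataclass
class ReferenceSet:
    records: list[RefRecord]
    tree: TaxonomyTree

    def __post_init__(self) -> None:
        for rec in self.records:
            for tid in rec.lineage:
                if tid not in self.tree.nodes:
                    raise FormatError(f"{rec.species_id}: lineage node {tid!r} not in taxonomy")

    def __iter__(self) -> Iterator[RefRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_species(self) -> dict[str, RefRecord]:
        return {r.species_id: r for r in self.records}

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for rec in self.records:
                site = "" if rec.capture_site is None else f" capture={rec.capture_site[0]}-{rec.capture_site[1]}"
                handle.write(f">{rec.species_id} lineage={';'.join(rec.lineage)}{site}\n")
                for i in range(0, len(rec.sequence), 80):
                    handle.write(rec.sequence[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class TaxaCountMatrix:
    """Nonnegative integer counts, taxa (or genes) x spatial barcodes."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise FormatError("counts shape does not match labels")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise FormatError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise FormatError("duplicate column labels")
        if self.counts.size and (self.counts < 0).any():
            raise FormatError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxaCountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxaCountMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.counts, other.counts)
        )


def write_matrix(matrix: TaxaCountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix as TSV or MatrixMarket (with sidecar label files)."""
    path = Path(path)
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t", index_label="")
    elif format == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(matrix.counts.astype(np.int64).reshape(
            len(matrix.row_labels), len(matrix.col_labels))))
        path.with_suffix(".rows.txt").write_text("".join(l + "\n" for l in matrix.row_labels))
        path.with_suffix(".cols.txt").write_text("".join(l + "\n" for l in matrix.col_labels))
    else:
        raise FormatError(f"unknown matrix format {format!r}")


def read_matrix(path: str | Path, format: str = "tsv") -> TaxaCountMatrix:
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = [str(c) for c in df.columns]
        return TaxaCountMatrix.from_frame(df.astype(np.int64) if df.size else df)
    if format == "mtx":
        counts = np.asarray(spio.mmread(str(path)).todense()).astype(np.int64)
        rows = path.with_suffix(".rows.txt").read_text().splitlines()
        cols = path.with_suffix(".cols.txt").read_text().splitlines()
        return TaxaCountMatrix(rows, cols, counts)
    raise FormatError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# Spot annotations
# ---------------------------------------------------------------------------

@dataclass
class SpotAnnotation:
    """Per-barcode morphological region tags plus study design covariates."""

    table: pd.DataFrame  # columns: barcode, mroi, section_id, condition, animal_id

    REQUIRED = ("barcode", "mroi", "section_id", "condition", "animal_id")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation table missing columns {sorted(missing)}")
        bad = set(self.table["mroi"]) - set(MROI_TAGS)
        if bad:
            raise FormatError(f"unknown MROI tags {sorted(bad)}")
        bad_cond = set(self.table["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise FormatError(f"unknown conditions {sorted(bad_cond)}")

    def validate_against(self, layout: ArrayLayout) -> None:
        known = set(layout.barcodes)
        unknown = set(self.table["barcode"]) - known
        if unknown:
            raise FormatError(f"{len(unknown)} annotated barcodes not in layout")

    @classmethod
    def load(cls, path: str | Path) -> "SpotAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
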