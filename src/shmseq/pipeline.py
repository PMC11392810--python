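"""End-to-end spatial bacterial read processing.

Stage order: adapter trimming -> quality filter -> length filter -> barcode
demultiplexing -> optional host screen -> two-stage taxonomic classification
(k-mer LCA first, deep classifier fallback) -> UMI collapsing -> taxa-by-
barcode matrix.  Every stage reports exact kept/removed counts in the QC
report, so reads are conserved at each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    UMI_LEN,
    ArrayLayout,
    SpatialRead,
    TaxaCountMatrix,
    read_fastq_pairs,
)
from .deep_taxa import GenusClassifier, predict_genus
from .kmer_lca import KmerIndex, classify_batch, iter_kmers

logger = logging.getLogger(__name__)

DEMUX_KMER = 6
DEMUX_MAX_MISMATCH = 2
MIN_READ_LEN = 100
MIN_MEAN_QUALITY = 20.0


# ---------------------------------------------------------------------------
# Read-level filters
# ---------------------------------------------------------------------------

def trim_adapters(
    reads: Sequence[SpatialRead],
    adapters: Sequence[str],
    min_overlap: int = 8,
    max_mismatch: int = 1,
) -> list[SpatialRead]:
    """Remove 3' adapter contamination by suffix/prefix matching.

    For each read the longest suffix matching an adapter prefix with at least
    ``min_overlap`` overlap and at most ``max_mismatch`` mismatches is
    removed (qualities trimmed in step).
    """
    if not adapters:
        raise ValueError("adapter list must be nonempty")
    out = []
    for read in reads:
        seq = read.sequence
        cut = len(seq)
        for adapter in adapters:
            # longest overlap first
            for ov in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
                suffix = seq[len(seq) - ov :]
                prefix = adapter[:ov]
                mismatches = sum(a != b for a, b in zip(suffix, prefix))
                if mismatches <= max_mismatch:
                    cut = min(cut, len(seq) - ov)
                    break
        if cut < len(seq):
            read = SpatialRead(read.read_id, read.barcode_obs, read.umi,
                               read.sequence[:cut], read.qualities[:cut])
        out.append(read)
    return out


def mean_quality(qualities: str) -> float:
    if not qualities:
        return 0.0
    return float(np.mean([ord(c) - 33 for c in qualities]))


def quality_filter(reads: Sequence[SpatialRead],
                   min_mean_q: float = MIN_MEAN_QUALITY) -> list[SpatialRead]:
    """Keep reads whose mean base quality is at least ``min_mean_q``."""
    return [r for r in reads if mean_quality(r.qualities) >= min_mean_q]


def length_filter(reads: Sequence[SpatialRead],
                  min_len: int = MIN_READ_LEN) -> list[SpatialRead]:
    """Keep reads strictly longer than ``min_len`` nt."""
    return [r for r in reads if len(r.sequence) > min_len]


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

@dataclass
class DemuxResult:
    """Per-read barcode assignment with edit distance and candidate count."""

    table: pd.DataFrame  # read_id, barcode (or NA), distance, n_candidates, reason

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["barcode"].notna()]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class BarcodeBank:
    """k-mer indexed barcode bank for candidate retrieval."""

    def __init__(self, barcodes: Sequence[str], k: int = DEMUX_KMER) -> None:
        self.barcodes = list(barcodes)
        self.k = k
        self.kmer_map: dict[str, set[int]] = {}
        for i, bc in enumerate(self.barcodes):
            for p in range(len(bc) - k + 1):
                self.kmer_map.setdefault(bc[p : p + k], set()).add(i)

    def candidates(self, observed: str) -> set[int]:
        cand: set[int] = set()
        for p in range(len(observed) - self.k + 1):
            cand |= self.kmer_map.get(observed[p : p + self.k], set())
        return cand


def demux(
    reads: Sequence[SpatialRead],
    layout: ArrayLayout,
    index_k: int = DEMUX_KMER,
    max_mismatch: int = DEMUX_MAX_MISMATCH,
) -> DemuxResult:
    """Assign each observed barcode to the unique bank barcode within 2 mismatches.

    Candidates are retrieved through shared 6-mers; among candidates the read
    is assigned to a bank barcode at Hamming distance <= ``max_mismatch``,
    unassigned on ties at the minimum distance, and unassigned when the
    observed barcode carries N at more than ``max_mismatch`` positions.
    """
    bank = BarcodeBank(layout.barcodes, k=index_k)
    min_dists = [_hamming(a, b) for i, a in enumerate(layout.barcodes[:50])
                 for b in layout.barcodes[:50][i + 1 :]]
    if min_dists and min(min_dists) <= 2 * max_mismatch:
        logger.warning("layout barcodes closer than 2*max_mismatch; "
                       "demultiplexing may be ambiguous")
    rows = []
    for read in reads:
        obs = read.barcode_obs
        if obs.count("N") > max_mismatch:
            rows.append((read.read_id, None, -1, 0, "too_many_N"))
            continue
        cand = bank.candidates(obs)
        if not cand:
            rows.append((read.read_id, None, -1, 0, "no_candidates"))
            continue
        dists = [(idx, _hamming(obs, bank.barcodes[idx])) for idx in sorted(cand)]
        best = min(d for _, d in dists)
        hits = [idx for idx, d in dists if d == best]
        if best > max_mismatch:
            rows.append((read.read_id, None, best, len(cand), "too_distant"))
        elif len(hits) > 1:
            rows.append((read.read_id, None, best, len(cand), "ambiguous"))
        else:
            rows.append((read.read_id, bank.barcodes[hits[0]], best,
                         len(cand), None))
    table = pd.DataFrame(
        rows, columns=["read_id", "barcode", "distance", "n_candidates", "reason"]
    )
    return DemuxResult(table=table)


# ---------------------------------------------------------------------------
# Host screen
# ---------------------------------------------------------------------------

def host_screen(
    reads: Sequence[SpatialRead],
    host_kmer_set: set[str],
    k: int = 31,
    hit_fraction: float = 0.5,
) -> tuple[list[SpatialRead], list[SpatialRead]]:
    """Partition reads into (non_host, host) by shared-k-mer fraction.

    A read is flagged host when at least ``hit_fraction`` of its canonical
    k-mers occur in the host k-mer set.  An empty set is a no-op.
    """
    if not host_kmer_set:
        return list(reads), []
    non_host, host = [], []
    for read in reads:
        kmers = list(iter_kmers(read.sequence, k))
        if kmers:
            frac = sum(km in host_kmer_set for km in kmers) / len(kmers)
        else:
            frac = 0.0
        (host if frac >= hit_fraction else non_host).append(read)
    return non_host, host


def build_host_kmer_set(sequences: Iterable[str], k: int = 31) -> set[str]:
    out: set[str] = set()
    for seq in sequences:
        out.update(iter_kmers(seq, k))
    return out


# ---------------------------------------------------------------------------
# Two-stage classification
# ---------------------------------------------------------------------------

def classify_two_stage(
    reads: Sequence[SpatialRead],
    kmer_index: KmerIndex,
    deep_model: Optional[GenusClassifier],
    confidence: float = 0.01,
    max_deep_len: int = 150,
) -> pd.DataFrame:
    """First-pass k-mer LCA calls; unresolved reads go to the deep classifier.

    Returns read_id, genus (or NA), stage ('kmer', 'deep' or NA) and the
    stage's confidence/probability.  Both classifiers must share the genus
    vocabulary.
    """
    if deep_model is not None:
        vocab = set(deep_model.classes or [])
        tree_genera = set(kmer_index.tree.genus_ids)
        if not vocab.issubset(tree_genera):
            raise ValueError("deep model and k-mer index genus vocabularies differ")
    table, _ = classify_batch([(r.read_id, r.sequence) for r in reads],
                              kmer_index, confidence)
    table = table.set_index("read_id")
    genera = {}
    stages = {}
    scores = {}
    fallback = []
    for read in reads:
        row = table.loc[read.read_id]
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        if row["taxon"] is not None and not pd.isna(row["taxon"]):
            genera[read.read_id] = row["taxon"]
            stages[read.read_id] = "kmer"
            scores[read.read_id] = float(row["confidence"])
        else:
            fallback.append(read)
    if deep_model is not None and fallback:
        seqs = [r.sequence[-max_deep_len:] for r in fallback]
        preds = predict_genus(deep_model, seqs)
        for read, (_, pred) in zip(fallback, preds.iterrows()):
            genera[read.read_id] = pred["genus"]
            stages[read.read_id] = "deep"
            scores[read.read_id] = float(pred["probability"])
    rows = [(r.read_id, genera.get(r.read_id), stages.get(r.read_id),
             scores.get(r.read_id, np.nan)) for r in reads]
    return pd.DataFrame(rows, columns=["read_id", "genus", "stage", "score"])


# ---------------------------------------------------------------------------
# UMI collapsing
# ---------------------------------------------------------------------------

@dataclass
class MoleculeTable:
    """Collapsed molecules per (barcode, genus): one row per UMI component."""

    table: pd.DataFrame  # barcode, genus, representative_umi, n_reads

    def __len__(self) -> int:
        return len(self.table)


def _umi_components(umis: list[str]) -> list[list[int]]:
    """Connected components of the Hamming-distance-<=1 UMI graph."""
    n = len(umis)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if _hamming(umis[i], umis[j]) <= 1:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def collapse_umis(assignments: pd.DataFrame) -> MoleculeTable:
    """Collapse UMIs within each (barcode, genus) group.

    ``assignments`` needs columns barcode, genus, umi (one row per read).
    UMIs at Hamming distance <= 1 are joined transitively; each connected
    component is one molecule, represented by the most frequent UMI
    (lexicographic tie-break).
    """
    for col in ("barcode", "genus", "umi"):
        if col not in assignments.columns:
            raise ValueError(f"assignments missing column {col!r}")
    if assignments.empty:
        return MoleculeTable(table=pd.DataFrame(
            columns=["barcode", "genus", "representative_umi", "n_reads"]))
    bad = assignments["umi"].str.len() != UMI_LEN
    if bad.any():
        raise ValueError(f"{int(bad.sum())} UMIs are not {UMI_LEN} nt")
    rows = []
    for (barcode, genus), grp in assignments.groupby(["barcode", "genus"],
                                                     sort=True):
        counts = grp["umi"].value_counts()
        unique = sorted(counts.index)
        for comp in _umi_components(unique):
            members = [unique[i] for i in comp]
            n_reads = int(counts[members].sum())
            rep = max(members, key=lambda u: (counts[u], u))
            rows.append((barcode, genus, rep, n_reads))
    return MoleculeTable(
        table=pd.DataFrame(rows, columns=["barcode", "genus",
                                          "representative_umi", "n_reads"])
    )


def to_taxa_matrix(molecules: MoleculeTable, layout: ArrayLayout,
                   genera: Optional[Sequence[str]] = None) -> TaxaCountMatrix:
    """Molecule counts per (genus, barcode) over the full layout."""
    known = set(layout.barcodes)
    unknown = set(molecules.table["barcode"]) - known
    if unknown:
        raise ValueError(f"{len(unknown)} molecule barcodes not in layout")
    if genera is None:
        genera = sorted(molecules.table["genus"].unique())
    g_idx = {g: i for i, g in enumerate(genera)}
    b_idx = {b: i for i, b in enumerate(layout.barcodes)}
    counts = np.zeros((len(genera), len(layout.barcodes)), dtype=np.int64)
    for row in molecules.table.itertuples(index=False):
        counts[g_idx[row.genus], b_idx[row.barcode]] += 1
    return TaxaCountMatrix(list(genera), list(layout.barcodes), counts)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    adapters: tuple[str, ...] = ()
    min_mean_quality: float = MIN_MEAN_QUALITY
    min_read_len: int = MIN_READ_LEN
    demux_kmer: int = DEMUX_KMER
    demux_max_mismatch: int = DEMUX_MAX_MISMATCH
    host_kmer_set: Optional[set[str]] = None
    host_k: int = 31
    host_hit_fraction: float = 0.5
    kmer_confidence: float = 0.01


@dataclass
class PipelineResult:
    matrix: TaxaCountMatrix
    molecules: MoleculeTable
    assignments: pd.DataFrame
    qc: dict


def run_pipeline(
    r1_path,
    r2_path,
    layout: ArrayLayout,
    kmer_index: KmerIndex,
    deep_model: Optional[GenusClassifier] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run trim -> quality -> length -> demux -> host screen -> classify ->
    collapse -> matrix, with per-stage read accounting."""
    if config is None:
        config = PipelineConfig()
    qc: dict = {"stages": {}}

    stream = read_fastq_pairs(r1_path, r2_path)
    reads = list(stream)
    qc["stages"]["input"] = {
        "pairs": stream.summary.n_pairs,
        "kept": stream.summary.n_valid,
        "removed": stream.summary.n_invalid_r1,
    }

    if config.adapters:
        reads = trim_adapters(reads, config.adapters)
    n0 = len(reads)
    reads = quality_filter(reads, config.min_mean_quality)
    qc["stages"]["quality_filter"] = {"kept": len(reads), "removed": n0 - len(reads)}

    n0 = len(reads)
    reads = length_filter(reads, config.min_read_len)
    qc["stages"]["length_filter"] = {"kept": len(reads), "removed": n0 - len(reads)}

    demux_result = demux(reads, layout, config.demux_kmer,
                         config.demux_max_mismatch)
    bc_map = dict(zip(demux_result.table["read_id"],
                      demux_result.table["barcode"]))
    n0 = len(reads)
    reads = [r for r in reads if bc_map.get(r.read_id) is not None]
    qc["stages"]["demux"] = {"kept": len(reads), "removed": n0 - len(reads)}

    if config.host_kmer_set:
        n0 = len(reads)
        reads, host_reads = host_screen(reads, config.host_kmer_set,
                                        config.host_k,
                                        config.host_hit_fraction)
        qc["stages"]["host_screen"] = {"kept": len(reads),
                                       "removed": n0 - len(reads)}
    else:
        qc["stages"]["host_screen"] = {"kept": len(reads), "removed": 0}

    calls = classify_two_stage(reads, kmer_index, deep_model,
                               config.kmer_confidence)
    classified = calls[calls["genus"].notna()]
    qc["stages"]["classify"] = {
        "kept": len(classified),
        "removed": len(calls) - len(classified),
        "stage1_fraction": float((calls["stage"] == "kmer").mean()) if len(calls) else 0.0,
        "classified_fraction": float(calls["genus"].notna().mean()) if len(calls) else 0.0,
    }

    umi_map = {r.read_id: r.umi for r in reads}
    assignments = classified.assign(
        barcode=[bc_map[rid] for rid in classified["read_id"]],
        umi=[umi_map[rid] for rid in classified["read_id"]],
    )
    molecules = collapse_umis(assignments)
    qc["stages"]["collapse"] = {
        "molecules": len(molecules),
        "reads_in": len(assignments),
    }
    genera = sorted(kmer_index.tree.genus_ids)
    matrix = to_taxa_matrix(molecules, layout, genera=genera)
    qc["total_molecules"] = int(matrix.counts.sum())
    return PipelineResult(matrix=matrix, molecules=molecules,
                          assignments=assignments, qc=qc)
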