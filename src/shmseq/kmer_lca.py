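"""First-pass taxonomic classification: exact k-mer index with LCA labels.

Each canonical k-mer in the reference set maps to the lowest common ancestor
of all species whose reference contains it.  Reads are scored by summed
clade support along root-to-leaf paths; a confidence threshold moves calls
toward the root until supported, and the final call is reported at genus
rank.  This is the classic k-mer/LCA scheme at desk scale: exact 31-mers, no
minimizers, no low-complexity masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core_io import ReferenceSet, TaxonomyTree

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_K = 31
DEFAULT_CONFIDENCE = 0.01


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def iter_kmers(sequence: str, k: int) -> Iterable[str]:
    """Canonical k-mers of a sequence; k-mers containing non-ACGT are skipped."""
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if all(c in "ACGT" for c in kmer):
            yield canonical_kmer(kmer)


@dataclass
class KmerIndex:
    k: int
    lca_map: dict[str, str]  # canonical k-mer -> taxon id
    tree: TaxonomyTree

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not (15 <= self.k <= 35):
            raise ValueError("k must be odd and in [15, 35]")

    def __len__(self) -> int:
        return len(self.lca_map)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as h:
            h.write(f"#k={self.k}\tn_kmers={len(self.lca_map)}\n")
            for kmer in sorted(self.lca_map):
                h.write(f"{kmer}\t{self.lca_map[kmer]}\n")

    @classmethod
    def load(cls, path: str | Path, tree: TaxonomyTree) -> "KmerIndex":
        with open(path) as h:
            header = h.readline()
            k = int(header.split("#k=")[1].split("\t")[0])
            lca_map = {}
            for line in h:
                kmer, taxon = line.rstrip("\n").split("\t")
                lca_map[kmer] = taxon
        return cls(k=k, lca_map=lca_map, tree=tree)


def build_index(references: ReferenceSet, k: int = DEFAULT_K) -> KmerIndex:
    """Map every canonical reference k-mer to the LCA of the species carrying it."""
    if len(references) == 0:
        raise ValueError("empty reference set")
    tree = references.tree
    holders: dict[str, set[str]] = {}
    for rec in references:
        for kmer in set(iter_kmers(rec.sequence, k)):
            holders.setdefault(kmer, set()).add(rec.species_id)
    lca_map = {kmer: tree.lca(sorted(sp)) for kmer, sp in holders.items()}
    return KmerIndex(k=k, lca_map=lca_map, tree=tree)


@dataclass
class Assignment:
    read_id: str
    taxon: Optional[str]  # genus-rank taxon id, or None if unclassified
    rank: Optional[str]
    confidence: float
    reason: Optional[str] = None  # set when unclassified


def _clade_supports(hits: dict[str, int], tree: TaxonomyTree) -> dict[str, int]:
    """Summed k-mer hits in the clade rooted at each taxon on a hit path."""
    support: dict[str, int] = {}
    for taxon, count in hits.items():
        for anc in tree.path_to_root(taxon):
            support[anc] = support.get(anc, 0) + count
    return support


def classify_read(
    read_id: str,
    sequence: str,
    index: KmerIndex,
    confidence: float = DEFAULT_CONFIDENCE,
) -> Assignment:
    """Classify one read at genus rank via clade-support path scoring.

    Each k-mer hit votes for a taxon; every root-to-leaf path is scored by
    the summed hits inside the candidate clade.  The deepest taxon maximizing
    clade support is chosen (ties between siblings resolve to their LCA), and
    the call climbs toward the root until the supporting k-mer fraction
    reaches the confidence threshold.  Calls at or above family rank are
    unclassified.
    """
    tree = index.tree
    n_kmers = len(sequence) - index.k + 1
    if n_kmers < 1:
        return Assignment(read_id, None, None, 0.0, reason="too_short")
    hits: dict[str, int] = {}
    total = 0
    for kmer in iter_kmers(sequence, index.k):
        total += 1
        taxon = index.lca_map.get(kmer)
        if taxon is not None:
            hits[taxon] = hits.get(taxon, 0) + 1
    if not hits or total == 0:
        return Assignment(read_id, None, None, 0.0, reason="no_hits")

    support = _clade_supports(hits, tree)
    # deepest taxon with maximal clade support; sibling ties -> their LCA
    max_support = max(support.values())
    best = [t for t, s in support.items() if s == max_support]
    deepest_depth = max(len(tree.path_to_root(t)) for t in best)
    deepest = sorted(t for t in best
                     if len(tree.path_to_root(t)) == deepest_depth)
    current = deepest[0] if len(deepest) == 1 else tree.lca(deepest)

    while True:
        conf = support.get(current, 0) / total
        if conf >= confidence or tree.nodes[current].parent_id is None:
            break
        current = tree.nodes[current].parent_id

    genus = tree.ancestor_at_rank(current, "genus")
    conf = support.get(current, 0) / total
    if genus is None:
        return Assignment(read_id, None, tree.rank_of(current), conf,
                          reason="above_genus")
    return Assignment(read_id, genus, "genus", conf)


def classify_batch(
    reads: Sequence[tuple[str, str]],
    index: KmerIndex,
    confidence: float = DEFAULT_CONFIDENCE,
) -> tuple[pd.DataFrame, dict]:
    """Classify (read_id, sequence) pairs; returns (table, summary).

    Results are per-read deterministic, hence independent of input order.
    """
    assignments = [classify_read(rid, seq, index, confidence)
                   for rid, seq in reads]
    table = pd.DataFrame(
        {
            "read_id": [a.read_id for a in assignments],
            "taxon": [a.taxon for a in assignments],
            "rank": [a.rank for a in assignments],
            "confidence": [a.confidence for a in assignments],
            "reason": [a.reason for a in assignments],
        }
    )
    n = len(assignments)
    n_classified = int(table["taxon"].notna().sum())
    summary = {
        "n_reads": n,
        "n_classified": n_classified,
        "classified_fraction": (n_classified / n) if n else 0.0,
    }
    return table, summary
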