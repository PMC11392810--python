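"""Deterministic synthetic data: taxonomies, 16S-like references and
MROI-structured spatial counts with known generative parameters.

Everything here is a pure function of an explicit configuration and seed, so
every downstream stage (classification, demultiplexing, spatial modeling) can
be tested against known ground truth without any downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DNA,
    MROI_TAGS,
    ArrayLayout,
    RefRecord,
    ReferenceSet,
    SpotAnnotation,
    TaxaCountMatrix,
    TaxonNode,
    TaxonomyTree,
)

#: Degenerate recognition segment of the 16S surface capture probe (the
#: poly(A) attachment handle is not part of the recognition site).
PROBE_RECOGNITION = "GGATTAGATACCCBDGTAGTCGAGATNB"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def canonical_probe_site() -> str:
    """The fixed expansion of the probe embedded in synthetic references."""
    return "".join(IUPAC[c][0] for c in PROBE_RECOGNITION)


@dataclass
class FixtureConfig:
    """Shape and divergence of the synthetic reference set.

    The default shape mirrors the SPF-like reference: 65 species spread
    unevenly over 39 genera.  ``branch_substitution_rate`` is the per-site
    substitution probability applied on each branch of the taxonomy
    (Jukes-Cantor-style uniform substitutions); the variable region
    immediately upstream of the probe site receives extra genus-level
    substitutions so genera are discriminable from short fragments.
    """

    seed: int = 0
    n_genera: int = 39
    species_per_genus: int = 2
    n_species: Optional[int] = 65
    ref_length: int = 1500
    variable_region_span: int = 250
    branch_substitution_rate: float = 0.02
    variable_region_boost: float = 4.0
    probe_site_position: int = 900
    genera_per_family: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.branch_substitution_rate <= 1.0):
            raise ValueError("branch_substitution_rate must be in [0, 1]")
        if self.ref_length <= self.variable_region_span:
            raise ValueError("ref_length must exceed variable_region_span")
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")


def _species_counts(config: FixtureConfig) -> list[int]:
    """Species per genus; uneven assignment when n_species is given."""
    if config.n_species is None:
        return [config.species_per_genus] * config.n_genera
    if config.n_species < config.n_genera:
        raise ValueError("n_species must be >= n_genera")
    base, extra = divmod(config.n_species, config.n_genera)
    return [base + (1 if g < extra else 0) for g in range(config.n_genera)]


def make_taxonomy(config: FixtureConfig) -> TaxonomyTree:
    """A balanced root -> family -> genus -> species taxonomy."""
    nodes = [TaxonNode("root", "root", "root", None)]
    n_families = max(1, math.ceil(config.n_genera / config.genera_per_family))
    for f in range(n_families):
        nodes.append(TaxonNode(f"f{f:02d}", f"Family{f:02d}", "family", "root"))
    counts = _species_counts(config)
    s_idx = 0
    for g in range(config.n_genera):
        fam = f"f{g // config.genera_per_family:02d}"
        gid = f"g{g:02d}"
        nodes.append(TaxonNode(gid, f"Genus{g:02d}", "genus", fam))
        for _ in range(counts[g]):
            sid = f"s{s_idx:03d}"
            nodes.append(TaxonNode(sid, f"Species{s_idx:03d}", "species", gid))
            s_idx += 1
    return TaxonomyTree(nodes)


def _mutate_positions(seq: np.ndarray, rate: float, protected: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Substitute each unprotected site independently with probability rate."""
    out = seq.copy()
    hit = (rng.random(seq.size) < rate) & ~protected
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift by 1..3 mod 4 guarantees a different base
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return out


def _to_str(arr: np.ndarray) -> str:
    return "".join(DNA[b] for b in arr)


def make_references(tree: TaxonomyTree, config: FixtureConfig) -> ReferenceSet:
    """One 16S-like sequence per species.

    An ancestral template of ``ref_length`` bases carries the canonical probe
    expansion at ``probe_site_position``; the template is then mutated along
    the family -> genus -> species branches.  The probe site is
    substitution-free in every species (the conserved flank the capture probe
    targets) and the variable region upstream of it receives boosted
    substitutions on genus branches.
    """
    site = canonical_probe_site()
    start = config.probe_site_position
    end = start + len(site)
    if end > config.ref_length:
        raise ValueError("probe site extends past reference end")
    var_start = start - config.variable_region_span
    if var_start < 0:
        raise ValueError("variable region extends past reference start")
    # variable region sits strictly upstream of the site, so no overlap by
    # construction; guard anyway for exotic configurations
    if var_start < 0 or config.variable_region_span < 0:
        raise ValueError("variable region overlaps probe site")

    rng = np.random.default_rng(config.seed)
    base_to_int = {b: i for i, b in enumerate(DNA)}
    template = rng.integers(0, 4, size=config.ref_length)
    template[start:end] = [base_to_int[b] for b in site]

    protected = np.zeros(config.ref_length, dtype=bool)
    protected[start:end] = True
    in_var = np.zeros(config.ref_length, dtype=bool)
    in_var[var_start:start] = True

    rate = config.branch_substitution_rate
    records: list[RefRecord] = []
    for fam in sorted(t for t, n in tree.nodes.items() if n.rank == "family"):
        fam_seq = _mutate_positions(template, rate, protected, rng)
        for gid in sorted(tree.children(fam)):
            gen_seq = _mutate_positions(fam_seq, rate, protected, rng)
            # genus-discriminative substitutions in the variable region
            boost_rate = min(1.0, rate * config.variable_region_boost)
            gen_seq = _mutate_positions(
                gen_seq, boost_rate, protected | ~in_var, rng
            )
            for sid in sorted(tree.children(gid)):
                sp_seq = _mutate_positions(gen_seq, rate / 4.0, protected, rng)
                records.append(
                    RefRecord(
                        species_id=sid,
                        lineage=tuple(reversed(tree.path_to_root(sid))),
                        sequence=_to_str(sp_seq),
                        capture_site=(start, end),
                    )
                )
    return ReferenceSet(records=records, tree=tree)


# ---------------------------------------------------------------------------
# Spatial annotations
# ---------------------------------------------------------------------------

def make_annotations(
    layout: ArrayLayout,
    mrois: Sequence[str] = ("BASE", "MID", "APEXMU", "MUPE", "PE"),
    sections: Sequence[tuple[str, str, str]] = (("sec0", "SPF", "m0"),),
    max_spots_per_section: Optional[int] = None,
    seed: int = 0,
) -> SpotAnnotation:
    """Assign contiguous horizontal bands of the array to MROIs.

    ``sections`` is a list of (section_id, condition, animal_id).  Spots are
    optionally subsampled to ``max_spots_per_section`` contiguous rows per
    section so small fixtures stay small.  Bands are contiguous in grid y, so
    every MROI forms a connected region (no isolated spots in the rook
    adjacency, matching real annotations of tissue layers).
    """
    for m in mrois:
        if m not in MROI_TAGS:
            raise ValueError(f"unknown MROI tag {m!r}")
    rng = np.random.default_rng(seed)
    spots = sorted(layout.spots, key=lambda s: (s.grid_y, s.grid_x))
    rows = []
    for section_id, condition, animal_id in sections:
        chosen = spots
        if max_spots_per_section is not None and max_spots_per_section < len(spots):
            start = int(rng.integers(0, len(spots) - max_spots_per_section + 1))
            chosen = spots[start : start + max_spots_per_section]
        n = len(chosen)
        # equal-size contiguous bands in array order
        bounds = np.linspace(0, n, len(mrois) + 1).astype(int)
        for b, mroi in enumerate(mrois):
            for s in chosen[bounds[b] : bounds[b + 1]]:
                rows.append((s.barcode, mroi, section_id, condition, animal_id))
    table = pd.DataFrame(rows, columns=list(SpotAnnotation.REQUIRED))
    ann = SpotAnnotation(table)
    ann.validate_against(layout)
    return ann


# ---------------------------------------------------------------------------
# Spatial counts with known parameters
# ---------------------------------------------------------------------------

@dataclass
class SpatialModelParams:
    """Ground-truth parameters of the generative spatial model.

    ``beta`` maps (condition, animal_id, mroi) -> characteristic log rate per
    taxon (array of length n_taxa).  ``theta`` is the per-taxon dropout
    probability; ``alpha``/``tau`` the CAR autocorrelation and precision;
    ``sigma`` the iid spot-noise standard deviation.
    """

    taxa: list[str]
    beta: dict[tuple[str, str, str], np.ndarray]
    theta: np.ndarray
    alpha: float = 0.9
    tau: float = 1.0
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (len(self.taxa),):
            raise ValueError("theta must have one entry per taxon")


@dataclass
class SyntheticTissue:
    """A generated spatial dataset with all latents stored for recovery tests."""

    layout: ArrayLayout
    annotations: SpotAnnotation
    params: SpatialModelParams
    counts: dict[str, TaxaCountMatrix]          # section -> taxa x barcode
    size_factors: dict[str, np.ndarray]         # section -> per-spot s
    psi: dict[tuple[str, str], np.ndarray]      # (taxon, section) -> per-spot psi
    eps: dict[tuple[str, str], np.ndarray]      # (taxon, section) -> per-spot eps
    log_rate: dict[tuple[str, str], np.ndarray]  # (taxon, section) -> B+psi+eps

    def section_barcodes(self, section_id: str) -> list[str]:
        t = self.annotations.table
        return list(t.loc[t["section_id"] == section_id, "barcode"])


def grid_adjacency(positions: np.ndarray) -> np.ndarray:
    """Rook (4-nearest-neighbor) adjacency among grid positions."""
    n = len(positions)
    W = np.zeros((n, n), dtype=float)
    index = {tuple(p): i for i, p in enumerate(map(tuple, positions))}
    for (x, y), i in index.items():
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            j = index.get((x + dx, y + dy))
            if j is not None:
                W[i, j] = 1.0
    return W


def _car_sample(W: np.ndarray, alpha: float, tau: float,
                rng: np.random.Generator) -> np.ndarray:
    """Draw from the CAR prior N(0, (tau (K - alpha W))^-1).

    Isolated spots (no neighbors) get unit diagonal in K so the precision
    stays proper; their field value then reverts to the prior mean.
    """
    K = W.sum(axis=1)
    Kd = np.where(K > 0, K, 1.0)
    Q = tau * (np.diag(Kd) - alpha * W)
    L = np.linalg.cholesky(Q)
    z = rng.standard_normal(len(W))
    # solve L^T psi = z  =>  psi ~ N(0, Q^-1)
    return np.linalg.solve(L.T, z)


def make_spatial_dataset(
    layout: ArrayLayout,
    annotations: SpotAnnotation,
    params: SpatialModelParams,
    seed: int = 0,
    size_factors: Optional[dict[str, np.ndarray]] = None,
) -> SyntheticTissue:
    """Sample counts from the hierarchical ZIP spatial model.

    Per taxon and section: psi from the CAR prior on the section's rook
    adjacency, eps iid normal, log rate = B + psi + eps with B the MROI
    characteristic expression for the section's (condition, animal), and
    counts ~ ZIP(s * lambda, theta).  All latents are stored.
    """
    annotations.validate_against(layout)
    rng = np.random.default_rng(seed)
    bc2spot = layout.barcode_to_spot()
    tbl = annotations.table
    taxa = params.taxa

    counts: dict[str, TaxaCountMatrix] = {}
    sfs: dict[str, np.ndarray] = {}
    psi_store: dict[tuple[str, str], np.ndarray] = {}
    eps_store: dict[tuple[str, str], np.ndarray] = {}
    lograte_store: dict[tuple[str, str], np.ndarray] = {}

    for section_id, sec in tbl.groupby("section_id", sort=True):
        barcodes = list(sec["barcode"])
        mrois = list(sec["mroi"])
        condition = sec["condition"].iloc[0]
        animal = sec["animal_id"].iloc[0]
        pos = np.array([(bc2spot[b].grid_x, bc2spot[b].grid_y) for b in barcodes])
        W = grid_adjacency(pos)
        n = len(barcodes)
        s = (np.ones(n) if size_factors is None else
             np.asarray(size_factors[section_id], dtype=float))
        if s.shape != (n,) or (s <= 0).any():
            raise ValueError(f"bad size factors for section {section_id}")
        sfs[section_id] = s

        mat = np.zeros((len(taxa), n), dtype=np.int64)
        for t_i, taxon in enumerate(taxa):
            B = np.array([
                params.beta[(condition, animal, m)][t_i] for m in mrois
            ])
            psi = _car_sample(W, params.alpha, params.tau, rng)
            eps = rng.normal(0.0, params.sigma, size=n)
            log_rate = B + psi + eps
            lam = np.exp(log_rate)
            y = rng.poisson(s * lam)
            drop = rng.random(n) < params.theta[t_i]
            y[drop] = 0
            mat[t_i] = y
            psi_store[(taxon, section_id)] = psi
            eps_store[(taxon, section_id)] = eps
            lograte_store[(taxon, section_id)] = log_rate
        counts[section_id] = TaxaCountMatrix(list(taxa), barcodes, mat)

    return SyntheticTissue(
        layout=layout,
        annotations=annotations,
        params=params,
        counts=counts,
        size_factors=sfs,
        psi=psi_store,
        eps=eps_store,
        log_rate=lograte_store,
    )


# ---------------------------------------------------------------------------
# snRNA-seq style cell-type signatures
# ---------------------------------------------------------------------------

def make_celltype_signatures(
    n_celltypes: int = 30,
    n_genes: int = 300,
    n_markers_per_type: int = 5,
    n_cells_per_type: int = 20,
    marker_mean: float = 20.0,
    background_mean: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Block-structured mean-expression signatures plus sampled cell profiles.

    Returns (signatures genes x cell-types, cells genes x cells, labels per
    cell).  Each cell type has ``n_markers_per_type`` marker genes whose mean
    is maximal in that type; sampled cells multiply the type mean by
    lognormal noise.
    """
    if n_celltypes < 2:
        raise ValueError("n_celltypes must be >= 2")
    if n_genes < n_celltypes * n_markers_per_type:
        raise ValueError("not enough genes for the requested marker blocks")
    rng = np.random.default_rng(seed)
    genes = [f"gene{g:04d}" for g in range(n_genes)]
    types = [f"ct{t:02d}" for t in range(n_celltypes)]
    means = np.full((n_genes, n_celltypes), background_mean)
    for t in range(n_celltypes):
        block = slice(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        means[block, t] = marker_mean
    signatures = pd.DataFrame(means, index=genes, columns=types)

    cells = []
    labels = []
    for t, tname in enumerate(types):
        for c in range(n_cells_per_type):
            noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=n_genes)
            cells.append(means[:, t] * noise)
            labels.append(tname)
    cell_ids = [f"cell{t}" for t in range(len(cells))]
    cells_df = pd.DataFrame(np.array(cells).T, index=genes, columns=cell_ids)
    return signatures, cells_df, pd.Series(labels, index=cell_ids, name="cell_type")
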