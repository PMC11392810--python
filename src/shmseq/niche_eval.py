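"""Downstream niche analysis and classification benchmarking.

Covers the spatial co-expression module/submodule workflow (standardized
cell-to-spot similarity, hierarchical gene modules, cell-type and gene-set
enrichment), snRNA-seq preprocessing utilities (TP10K, CV-residual variable
gene selection, nucleus filtering) and the evaluation metrics used to
benchmark taxonomic classification (Bray-Curtis, accuracy/F1/FPR, spot-wise
abundance agreement, region-matched resampling correlation).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, spearmanr, wilcoxon
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Standardization and similarity
# ---------------------------------------------------------------------------

def standardize(matrix: pd.DataFrame, axis: int = 1) -> pd.DataFrame:
    """Z-score each row (axis=1) or column (axis=0) using sample (n-1) sd.

    Zero-variance vectors are dropped with a warning; an all-constant matrix
    raises.
    """
    df = matrix.astype(float)
    if axis == 0:
        return standardize(df.T, axis=1).T
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all rows have zero variance")
    if (~keep).any():
        logger.warning("dropping %d zero-variance rows", int((~keep).sum()))
        df = df.loc[keep]
        mean, sd = mean[keep], sd[keep]
    return df.sub(mean, axis=0).div(sd, axis=0)


def cell_spot_similarity(
    cell_matrix: pd.DataFrame, spot_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between standardized cell and spot expression vectors.

    Both matrices are genes x observations; only common genes are used
    (at least 3 required).  Returns cells x spots.
    """
    common = cell_matrix.index.intersection(spot_matrix.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common genes; need >= 3")
    X = standardize(cell_matrix.loc[common], axis=0)   # per cell over genes
    L = standardize(spot_matrix.loc[common], axis=0)   # per spot over genes
    common = X.index.intersection(L.index)
    X, L = X.loc[common], L.loc[common]
    n = len(common)
    # columns are z-scored, so Pearson r is the scaled dot product
    r = X.T.to_numpy() @ L.to_numpy() / (n - 1)
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=cell_matrix.columns,
                        columns=spot_matrix.columns)


# ---------------------------------------------------------------------------
# Modules and submodules
# ---------------------------------------------------------------------------

def cluster_modules(standardized: pd.DataFrame, n_modules: int = 28
                    ) -> pd.Series:
    """Hierarchical gene modules: average linkage, Manhattan distance.

    ``standardized`` is genes x spots; the tree is cut to exactly
    ``n_modules`` flat clusters.  Module ids are relabeled by first gene
    appearance so the result is stable under gene input order.
    """
    if n_modules > len(standardized):
        raise ValueError("n_modules exceeds the number of genes")
    order = standardized.index.argsort()
    df = standardized.iloc[order]
    Z = linkage(df.to_numpy(), method="average", metric="cityblock")
    raw = fcluster(Z, t=n_modules, criterion="maxclust")
    labels = pd.Series(raw, index=df.index).loc[standardized.index]
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    return labels.map(relabel).rename("module")


def scale_celltype_means(
    cell_profiles: pd.DataFrame,
    cluster_labels: pd.Series,
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """Per-cluster gene means scaled by each gene's row maximum.

    Genes whose mean expression across clusters stays below ``min_mean``
    before scaling are removed (``min_mean=None`` keeps the literal reading:
    remove genes with average *scaled* expression below 1, which max-scaling
    makes nearly universal, so the pre-scaling rule is the default).
    """
    means = cell_profiles.T.groupby(cluster_labels).mean().T
    row_max = means.max(axis=1)
    keep = row_max > 0
    means = means.loc[keep]
    row_max = row_max[keep]
    if min_mean is not None:
        keep2 = means.mean(axis=1) >= min_mean
        means = means.loc[keep2]
        row_max = row_max[keep2]
    return means.div(row_max, axis=0)


def partition_submodules(
    scaled: pd.DataFrame, cutoff_frac: float = 0.4
) -> pd.Series:
    """Submodules within a module: cosine distance, average linkage, flat cut
    at ``cutoff_frac`` times the maximum linkage height."""
    if len(scaled) == 1:
        return pd.Series([1], index=scaled.index, name="submodule")
    order = scaled.index.argsort()
    df = scaled.iloc[order]
    X = df.to_numpy()
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm gene rows cannot use cosine distance")
    Z = linkage(X, method="average", metric="cosine")
    max_h = Z[:, 2].max()
    if max_h < 1e-10:  # all rows effectively identical
        return pd.Series(1, index=scaled.index, name="submodule")
    raw = fcluster(Z, t=cutoff_frac * max_h, criterion="distance")
    labels = pd.Series(raw, index=df.index).loc[scaled.index]
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    return labels.map(relabel).rename("submodule")


def enrich_celltypes(
    submodule_genes: Sequence[str],
    scaled: pd.DataFrame,
    min_genes: int = 5,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon signed-rank test per cell type, BH-corrected.

    For each cell type, the scaled expression of the submodule's genes in
    that type is compared against their mean scaled expression in the
    remaining types (paired by gene, two-sided).  Submodules below
    ``min_genes`` genes are reported untested (p = NaN).
    """
    genes = [g for g in submodule_genes if g in scaled.index]
    rows = []
    for ct in scaled.columns:
        if len(genes) < min_genes:
            rows.append({"cell_type": ct, "statistic": np.nan, "p": np.nan,
                         "tested": False})
            continue
        own = scaled.loc[genes, ct].to_numpy()
        rest = scaled.loc[genes, scaled.columns != ct].mean(axis=1).to_numpy()
        diff = own - rest
        if np.allclose(diff, 0):
            rows.append({"cell_type": ct, "statistic": 0.0, "p": 1.0,
                         "tested": True})
            continue
        stat, p = wilcoxon(own, rest, zero_method="wilcox",
                           alternative="two-sided")
        rows.append({"cell_type": ct, "statistic": float(stat),
                     "p": float(p), "tested": True})
    out = pd.DataFrame(rows)
    tested = out["tested"] & out["p"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"],
                                               method="fdr_bh")[1]
    return out


def enrich_genesets(
    submodule_genes: Sequence[str],
    gene_sets: dict[str, Sequence[str]],
    universe: Sequence[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-tailed Fisher (hypergeometric upper tail) per gene set, BH-corrected.

    Returns one row per set with odds ratio, p, FDR and a ``significant``
    flag at ``fdr_threshold``; sets empty after intersection with the
    universe are skipped.
    """
    uni = set(universe)
    sub = set(submodule_genes) & uni
    if not sub <= uni:
        raise ValueError("submodule genes must be inside the universe")
    N = len(uni)
    n = len(sub)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & uni)
        if K == 0:
            continue
        k = len(sub & set(members))
        # upper tail: P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] < fdr_threshold
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as h:
        for line in h:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# snRNA-seq preprocessing
# ---------------------------------------------------------------------------

def tp10k_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each cell (column) to a total of 10,000; zero-total cells dropped."""
    totals = counts.sum(axis=0)
    keep = totals > 0
    if (~keep).any():
        logger.warning("dropping %d zero-total cells", int((~keep).sum()))
    df = counts.loc[:, keep]
    return df.div(df.sum(axis=0), axis=1) * 1e4


def select_variable_genes(
    normalized: pd.DataFrame,
    n_bins: int = 20,
    n_top: int = 1500,
    lowess_frac: float = 0.5,
) -> list[str]:
    """Highly variable genes by binned CV-vs-mean LOESS residuals.

    Genes are binned into ``n_bins`` equal-frequency bins by mean expression;
    a LOESS fit of log CV on log mean yields residuals, and the ``n_top``
    genes with the largest residuals are selected equally across bins
    (largest residuals within each bin first).
    """
    if n_top > len(normalized):
        raise ValueError("n_top exceeds the number of genes")
    mean = normalized.mean(axis=1)
    sd = normalized.std(axis=1, ddof=1)
    ok = (mean > 0) & (sd > 0)
    mean, sd = mean[ok], sd[ok]
    cv = sd / mean
    log_mean = np.log(mean)
    log_cv = np.log(cv)
    fit = lowess(log_cv.to_numpy(), log_mean.to_numpy(), frac=lowess_frac,
                 return_sorted=False)
    resid = pd.Series(log_cv.to_numpy() - fit, index=mean.index)
    bins = pd.qcut(mean.rank(method="first"), q=n_bins, labels=False)
    per_bin = int(np.ceil(n_top / n_bins))
    chosen: list[str] = []
    for b in range(n_bins):
        in_bin = resid[bins == b].sort_values(ascending=False)
        chosen.extend(in_bin.index[:per_bin])
    # trim to exactly n_top by global residual rank among the chosen
    chosen_sorted = resid[chosen].sort_values(ascending=False).index[:n_top]
    return [g for g in normalized.index if g in set(chosen_sorted)]


def consensus_variable_genes(per_sample_lists: Sequence[Sequence[str]],
                             n_top: int = 1500) -> list[str]:
    """Combine per-sample variable-gene runs by recovery rate."""
    counts: dict[str, int] = {}
    for lst in per_sample_lists:
        for g in lst:
            counts[g] = counts.get(g, 0) + 1
    ranked = sorted(counts, key=lambda g: (-counts[g], g))
    return ranked[:n_top]


def filter_nuclei(
    counts: pd.DataFrame,
    flagged_genes: Sequence[str],
    min_genes: int = 800,
    min_cells_per_gene: int = 10,
    max_flagged_frac: float = 0.30,
) -> pd.DataFrame:
    """Quality filters for nucleus profiles (genes x cells).

    Keeps cells with strictly more than ``min_genes`` detected genes and a
    mitochondrial/rRNA signature fraction below ``max_flagged_frac``; keeps
    genes detected in at least ``min_cells_per_gene`` cells.
    """
    flagged = counts.index.intersection(flagged_genes)
    detected = (counts > 0).sum(axis=0)
    frac = counts.loc[flagged].sum(axis=0) / counts.sum(axis=0).replace(0, np.nan)
    keep_cells = (detected > min_genes) & (frac.fillna(0) < max_flagged_frac)
    df = counts.loc[:, keep_cells]
    keep_genes = (df > 0).sum(axis=1) >= min_cells_per_gene
    df = df.loc[keep_genes]
    if df.empty:
        raise ValueError("no cells or genes survive filtering")
    return df


# ---------------------------------------------------------------------------
# Benchmarking metrics
# ---------------------------------------------------------------------------

def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """1 - 2 sum(min(u, v)) / (sum(u) + sum(v)) on nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if (u < 0).any() or (v < 0).any():
        raise ValueError("inputs must be nonnegative")
    denom = u.sum() + v.sum()
    if denom == 0:
        raise ValueError("inputs must not both be all-zero")
    return float(1.0 - 2.0 * np.minimum(u, v).sum() / denom)


def classification_report(
    truth: Sequence[str], predicted: Sequence[Optional[str]]
) -> dict:
    """Pooled (bulk-like) accuracy, macro F1, false-positive rate, per-genus table.

    Unclassified predictions (None/NaN) count against accuracy but not FPR:
    FPR = misassigned classified reads / total classified reads.
    """
    if len(truth) == 0:
        raise ValueError("empty input")
    if len(truth) != len(predicted):
        raise ValueError("length mismatch")
    t = pd.Series(truth, dtype=object)
    p = pd.Series(predicted, dtype=object)
    classified = p.notna()
    correct = classified & (p == t)
    accuracy = float(correct.mean())
    n_classified = int(classified.sum())
    fpr = float((classified & (p != t)).sum() / n_classified) if n_classified else 0.0
    labels = sorted(set(t) | set(p.dropna()))
    f1s = []
    per_genus = []
    for lab in labels:
        tp = int(((p == lab) & (t == lab)).sum())
        fp = int(((p == lab) & (t != lab)).sum())
        fn = int(((p != lab) & (t == lab)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        f1s.append(f1)
        per_genus.append({"genus": lab, "tp": tp, "fp": fp, "fn": fn,
                          "precision": prec, "recall": rec, "f1": f1})
    return {
        "accuracy": accuracy,
        "macro_f1": float(np.mean(f1s)),
        "fpr": fpr,
        "classified_fraction": float(classified.mean()),
        "per_genus": pd.DataFrame(per_genus),
    }


def spotwise_abundance_agreement(
    truth_genus: Sequence[str],
    predicted_genus: Sequence[Optional[str]],
    spots: Sequence[str],
    group_size: int = 1000,
    metric: str = "pearson",
    seed: int = 0,
) -> float:
    """Mean agreement of relative genus abundances over random spot groups.

    Spots are randomly partitioned into groups of ``group_size``; per group
    the relative abundances from truth and prediction are compared with
    Pearson r or Bray-Curtis, and the mean over groups is returned.
    """
    df = pd.DataFrame({"truth": truth_genus, "pred": predicted_genus,
                       "spot": spots})
    uniq = sorted(df["spot"].unique())
    if len(uniq) < group_size:
        logger.warning("fewer spots (%d) than group_size; using one group",
                       len(uniq))
        group_size = len(uniq)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    spot_group = {uniq[i]: order_i // group_size
                  for order_i, i in enumerate(order)}
    df["group"] = df["spot"].map(spot_group)
    genera = sorted(set(df["truth"]) | set(df["pred"].dropna()))
    values = []
    for _, grp in df.groupby("group"):
        tv = grp["truth"].value_counts().reindex(genera, fill_value=0).to_numpy(float)
        pv = grp["pred"].dropna().value_counts().reindex(genera, fill_value=0).to_numpy(float)
        tv = tv / tv.sum() if tv.sum() else tv
        pv = pv / pv.sum() if pv.sum() else pv
        if metric == "pearson":
            if tv.std() == 0 or pv.std() == 0:
                continue
            values.append(float(np.corrcoef(tv, pv)[0, 1]))
        elif metric == "bray_curtis":
            values.append(bray_curtis(tv, pv))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return float(np.mean(values)) if values else float("nan")


def region_resampling_correlation(
    signal_a: pd.DataFrame,
    signal_b: pd.DataFrame,
    max_per_region: int = 3,
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Mean Spearman rho between two per-spot signals under region-matched
    resampling.

    Both inputs need columns (sample, region, value), one row per spatial
    coordinate.  Per repetition at most ``max_per_region`` coordinates per
    (sample, region) are drawn from each signal, values are min-max scaled
    within sample, pairs are matched by region, and Spearman rho is computed;
    the mean over repetitions is returned.  Regions present in only one
    signal are excluded.
    """
    for df, name in ((signal_a, "signal_a"), (signal_b, "signal_b")):
        if not {"sample", "region", "value"}.issubset(df.columns):
            raise ValueError(f"{name} needs columns sample, region, value")
    shared = sorted(set(signal_a["region"]) & set(signal_b["region"]))
    a = signal_a[signal_a["region"].isin(shared)]
    b = signal_b[signal_b["region"].isin(shared)]
    rng = np.random.default_rng(seed)

    def scale_within_sample(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for s, grp in df.groupby("sample"):
            lo, hi = grp["value"].min(), grp["value"].max()
            rngv = hi - lo
            out.loc[grp.index, "value"] = ((grp["value"] - lo) / rngv
                                           if rngv > 0 else 0.0)
        return out

    groups_a = {k: np.asarray(v) for k, v in
                a.groupby(["sample", "region"]).groups.items()}
    groups_b = {k: np.asarray(v) for k, v in
                b.groupby(["sample", "region"]).groups.items()}
    rhos = []
    for _ in range(n_reps):
        picks = []
        for df, groups in ((a, groups_a), (b, groups_b)):
            idx = np.concatenate([
                rng.permutation(members)[:max_per_region]
                for members in groups.values()
            ])
            picks.append(scale_within_sample(df.loc[idx]))
        pa, pb = picks
        # match by region: mean scaled value per region in each signal
        ma = pa.groupby("region")["value"].mean().reindex(shared)
        mb = pb.groupby("region")["value"].mean().reindex(shared)
        if ma.std() == 0 or mb.std() == 0:
            continue
        rho = spearmanr(ma, mb).statistic
        if np.isfinite(rho):
            rhos.append(float(rho))
    return float(np.mean(rhos)) if rhos else float("nan")
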