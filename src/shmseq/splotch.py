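"""Hierarchical Bayesian spatial model for taxa/gene counts on barcoded arrays.

Observed counts y[spot] for one taxon (or gene) at a time follow a
zero-inflated Poisson with rate s * lambda, where log(lambda) = B + psi + eps:

* B is the characteristic expression of the spot's morphological region
  (MROI), drawn from a two-level hierarchy over study conditions (level 1)
  and animals (level 2);
* psi is a conditional-autoregressive (CAR) Gaussian Markov random field on
  the section's 4-nearest-neighbor spot adjacency;
* eps is iid spot-level noise;
* s is the spot size factor (spot UMI total / median spot total).

Priors: beta_l1 ~ N(0, 2^2); beta_l2 ~ N(beta_l1, sigma_l2^2) with
sigma_l2 ~ halfN(0,1); theta ~ Beta(1,2) (dropout); alpha ~ U(0,1) and
tau ~ InvGamma(1,1) (CAR); sigma_eps ~ halfN(0, 0.3^2).

Inference is gradient-based MCMC: a hand-written HMC sampler with analytic
gradients of the joint log posterior, dual-averaging step-size adaptation and
a diagonal mass matrix estimated during warmup.  Differential calls use the
Savage-Dickey density ratio on contrast draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln
from scipy.stats import gaussian_kde

from .core_io import ArrayLayout, SpotAnnotation, TaxaCountMatrix
from .fixtures import grid_adjacency

logger = logging.getLogger(__name__)

SIGMA_L1 = 2.0          # fixed level-1 prior scale
SIGMA_EPS_SCALE = 0.3   # half-normal scale for spot noise sd
DE_LOG10_BF = 0.5       # strict threshold for differential calls
DETECT_MIN_SHARE = 0.02


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def compute_size_factors(totals: np.ndarray) -> np.ndarray:
    """Spot totals divided by the median spot total (over nonzero spots).

    All-zero spots are excluded from the median and get a size factor of 0;
    callers should drop them before fitting (a warning is emitted).
    """
    totals = np.asarray(totals, dtype=float)
    nonzero = totals > 0
    if not nonzero.any():
        raise ValueError("no spot with nonzero total")
    if (~nonzero).any():
        logger.warning("%d all-zero spots excluded from size factors",
                       int((~nonzero).sum()))
    med = float(np.median(totals[nonzero]))
    s = np.zeros_like(totals)
    s[nonzero] = totals[nonzero] / med
    return s


def build_adjacency(layout: ArrayLayout, barcodes: Sequence[str]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rook adjacency W and neighbor-count diagonal K for annotated spots."""
    bc2spot = layout.barcode_to_spot()
    pos = np.array([(bc2spot[b].grid_x, bc2spot[b].grid_y) for b in barcodes])
    W = grid_adjacency(pos)
    K = W.sum(axis=1)
    return W, np.diag(K)


def zip_logpmf(y: np.ndarray, rate: np.ndarray, theta: float) -> np.ndarray:
    """Zero-inflated Poisson log-pmf.

    P(y=0) = theta + (1-theta) exp(-rate); P(y>0) = (1-theta) Pois(y; rate).
    """
    y = np.asarray(y)
    rate = np.broadcast_to(np.asarray(rate, dtype=float), y.shape)
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must be in [0, 1]")
    if (rate <= 0).any():
        raise ValueError("rate must be > 0")
    out = np.empty(y.shape, dtype=float)
    zero = y == 0
    out[zero] = np.log(theta + (1.0 - theta) * np.exp(-rate[zero]))
    yz = y[~zero]
    rz = rate[~zero]
    with np.errstate(divide="ignore"):
        out[~zero] = (np.log1p(-theta) + yz * np.log(rz) - rz
                      - gammaln(yz + 1.0))
    return out


def car_precision(K: np.ndarray, W: np.ndarray, alpha: float, tau: float
                  ) -> np.ndarray:
    """CAR precision Q = tau (K - alpha W); positive definite for alpha in (0,1)."""
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T):
        raise ValueError("adjacency must be symmetric")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return tau * (np.asarray(K, dtype=float) - alpha * W)


# ---------------------------------------------------------------------------
# Input bundle
# ---------------------------------------------------------------------------

@dataclass
class SplotchInput:
    """Counts, design and adjacency for a set of annotated sections.

    Spots are ordered section-major; the design maps each spot to its MROI
    column and its level-1 (condition) and level-2 (animal) groups.
    """

    taxa: list[str]
    counts: np.ndarray             # (n_taxa, n_spots)
    size_factors: np.ndarray       # (n_spots,)
    spot_table: pd.DataFrame       # barcode, section_id, mroi, condition, animal_id
    mrois: list[str]
    l1_groups: list[str]           # conditions
    l2_groups: list[tuple[str, str]]  # (condition, animal)
    spot_mroi: np.ndarray          # index into mrois per spot
    spot_l1: np.ndarray
    spot_l2: np.ndarray
    W: sparse.csr_matrix           # block-diagonal over sections
    K: np.ndarray                  # neighbor counts per spot
    car_eigs: np.ndarray           # eigvals of Khat^-1/2 W Khat^-1/2 (all sections)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    @property
    def two_level(self) -> bool:
        # a second level only exists when some condition has several animals
        return len(self.l2_groups) > len(self.l1_groups)

    @property
    def K_hat(self) -> np.ndarray:
        """Neighbor counts with isolated spots given unit diagonal weight."""
        return np.where(self.K > 0, self.K, 1.0)


def build_splotch_input(
    counts: dict[str, TaxaCountMatrix],
    annotations: SpotAnnotation,
    layout: ArrayLayout,
    size_factors: Optional[dict[str, np.ndarray]] = None,
) -> SplotchInput:
    """Assemble per-section count matrices into a model-ready bundle.

    Spots with zero totals are dropped (with a warning).  Size factors
    default to spot totals over the median total pooled across all sections.
    """
    annotations.validate_against(layout)
    tbl = annotations.table
    sections = sorted(counts)
    taxa = counts[sections[0]].row_labels
    rows = []
    y_cols = []
    sf_cols = []
    blocks = []
    K_all = []
    eigs = []
    for section_id in sections:
        mat = counts[section_id]
        if mat.row_labels != taxa:
            raise ValueError(f"section {section_id}: row labels differ")
        sec = tbl[tbl["section_id"] == section_id]
        ann = dict(zip(sec["barcode"], zip(sec["mroi"], sec["condition"],
                                           sec["animal_id"])))
        keep = [i for i, b in enumerate(mat.col_labels) if b in ann]
        barcodes = [mat.col_labels[i] for i in keep]
        y = mat.counts[:, keep]
        totals = y.sum(axis=0)
        nz = totals > 0
        if (~nz).any():
            logger.warning("section %s: dropping %d all-zero spots",
                           section_id, int((~nz).sum()))
        barcodes = [b for b, ok in zip(barcodes, nz) if ok]
        y = y[:, nz]
        if size_factors is not None:
            sf = np.asarray(size_factors[section_id], dtype=float)[keep][nz]
        else:
            sf = totals[nz].astype(float)  # normalized below
        W, K = build_adjacency(layout, barcodes)
        Kv = K.diagonal()
        blocks.append(sparse.csr_matrix(W))
        K_all.append(Kv)
        Khat = np.where(Kv > 0, Kv, 1.0)
        D = 1.0 / np.sqrt(Khat)
        eigs.append(np.linalg.eigvalsh(D[:, None] * W * D[None, :]))
        for b, (m, c, a) in ((b, ann[b]) for b in barcodes):
            rows.append((b, section_id, m, c, a))
        y_cols.append(y)
        sf_cols.append(sf)

    spot_table = pd.DataFrame(
        rows, columns=["barcode", "section_id", "mroi", "condition", "animal_id"]
    )
    ymat = np.concatenate(y_cols, axis=1)
    if size_factors is None:
        sf = compute_size_factors(np.concatenate(sf_cols))
    else:
        sf = np.concatenate(sf_cols)
    mrois = sorted(spot_table["mroi"].unique())
    l1_groups = sorted(spot_table["condition"].unique())
    l2_groups = sorted(set(zip(spot_table["condition"],
                               spot_table["animal_id"])))
    m_idx = {m: i for i, m in enumerate(mrois)}
    l1_idx = {c: i for i, c in enumerate(l1_groups)}
    l2_idx = {g: i for i, g in enumerate(l2_groups)}
    return SplotchInput(
        taxa=list(taxa),
        counts=ymat,
        size_factors=sf,
        spot_table=spot_table,
        mrois=mrois,
        l1_groups=l1_groups,
        l2_groups=l2_groups,
        spot_mroi=spot_table["mroi"].map(m_idx).to_numpy(),
        spot_l1=spot_table["condition"].map(l1_idx).to_numpy(),
        spot_l2=np.array([l2_idx[g] for g in
                          zip(spot_table["condition"], spot_table["animal_id"])]),
        W=sparse.block_diag(blocks, format="csr"),
        K=np.concatenate(K_all),
        car_eigs=np.concatenate(eigs),
    )


# ---------------------------------------------------------------------------
# Posterior (one taxon at a time)
# ---------------------------------------------------------------------------

class _Posterior:
    """Joint log posterior and gradient in unconstrained coordinates.

    Layout of the parameter vector:
    [beta_l1 (L1*M), beta_l2_raw (L2*M, two-level only), u_sig_l2 (two-level),
     psi (N), eps_raw (N), u_sig_eps, t_theta, a_alpha, v_tau]
    with sigma = exp(u), theta = sigmoid(t), alpha = sigmoid(a), tau = exp(v).
    The level-2 coefficients and the spot noise are non-centered
    (beta_l2 = beta_l1[parent] + sigma_l2 * raw; eps = sigma_eps * raw) to
    avoid funnel geometry in the hierarchy.
    """

    def __init__(self, inp: SplotchInput, y: np.ndarray) -> None:
        self.inp = inp
        self.y = np.asarray(y, dtype=np.int64)
        self.zero = self.y == 0
        self.log_s = np.log(inp.size_factors)
        self.N = inp.n_spots
        self.M = len(inp.mrois)
        self.L1 = len(inp.l1_groups)
        self.L2 = len(inp.l2_groups)
        self.two_level = inp.two_level
        self.l2_parent = np.array(
            [inp.l1_groups.index(c) for c, _ in inp.l2_groups]
        )
        # per-spot index into the flattened beta matrix used for B
        if self.two_level:
            self.spot_cell = inp.spot_l2 * self.M + inp.spot_mroi
        else:
            self.spot_cell = inp.spot_l1 * self.M + inp.spot_mroi
        i = 0
        self.sl_b1 = slice(i, i + self.L1 * self.M); i += self.L1 * self.M
        if self.two_level:
            self.sl_b2 = slice(i, i + self.L2 * self.M); i += self.L2 * self.M
            self.i_usig2 = i; i += 1
        self.sl_psi = slice(i, i + self.N); i += self.N
        self.sl_eps = slice(i, i + self.N); i += self.N
        self.i_usige = i; i += 1
        self.i_t = i; i += 1
        self.i_a = i; i += 1
        self.i_v = i; i += 1
        self.dim = i

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        """Empirical init: beta cells at stratified log mean rates."""
        q = np.zeros(self.dim)
        y, s = self.y, self.inp.size_factors
        b1 = np.zeros((self.L1, self.M))
        for l1 in range(self.L1):
            for m in range(self.M):
                sel = (self.inp.spot_l1 == l1) & (self.inp.spot_mroi == m)
                if sel.any():
                    b1[l1, m] = np.log((y[sel].sum() + 0.5) / (s[sel].sum() + 0.5))
        q[self.sl_b1] = b1.ravel()
        if self.two_level:
            q[self.i_usig2] = np.log(0.3)
        q[self.i_usige] = np.log(0.1)
        q[self.i_t] = math.log(0.1 / 0.9)       # theta ~ 0.1
        q[self.i_a] = 0.0                       # alpha = 0.5
        q[self.i_v] = 0.0                       # tau = 1
        q += 0.05 * rng.standard_normal(self.dim)
        return q

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        inp = self.inp
        g = np.zeros_like(q)
        # reject wildly out-of-range unconstrained scalars before they
        # overflow the transforms; HMC treats -inf as a divergence
        scalars = [q[self.i_usige], q[self.i_t], q[self.i_a], q[self.i_v]]
        if self.two_level:
            scalars.append(q[self.i_usig2])
        if not np.all(np.isfinite(q)) or max(abs(v) for v in scalars) > 30.0:
            return -math.inf, g
        b1 = q[self.sl_b1].reshape(self.L1, self.M)
        psi = q[self.sl_psi]
        eps_raw = q[self.sl_eps]
        sig_e = math.exp(q[self.i_usige])
        theta = 1.0 / (1.0 + math.exp(-q[self.i_t]))
        alpha = 1.0 / (1.0 + math.exp(-q[self.i_a]))
        tau = math.exp(q[self.i_v])
        eps = sig_e * eps_raw

        if self.two_level:
            sig2 = math.exp(q[self.i_usig2])
            b2_raw = q[self.sl_b2].reshape(self.L2, self.M)
            b2 = b1[self.l2_parent] + sig2 * b2_raw
            beta_active = b2
        else:
            beta_active = b1
        B = beta_active.ravel()[self.spot_cell]

        eta = self.log_s + B + psi + eps
        eta = np.clip(eta, -50.0, 50.0)
        mu = np.exp(eta)

        # --- ZIP likelihood ---
        zero = self.zero
        e_neg = np.exp(-mu[zero])
        p0 = theta + (1.0 - theta) * e_neg
        lp = float(np.sum(np.log(p0)))
        yz = self.y[~zero]
        lp += float(np.sum(math.log1p(-theta) + yz * eta[~zero] - mu[~zero]
                           - gammaln(yz + 1.0)))
        deta = np.empty(self.N)
        w0 = (1.0 - theta) * e_neg / p0
        deta[zero] = -mu[zero] * w0
        deta[~zero] = yz - mu[~zero]
        dtheta = float(np.sum((1.0 - e_neg) / p0)) - (~zero).sum() / (1.0 - theta)

        # --- beta hierarchy (level 2 non-centered) ---
        lp += float(-0.5 * np.sum(b1**2) / SIGMA_L1**2)
        db1 = -b1 / SIGMA_L1**2
        if self.two_level:
            lp += float(-0.5 * np.sum(b2_raw**2))
            dB_cells = np.zeros(self.L2 * self.M)
            np.add.at(dB_cells, self.spot_cell, deta)
            dB_cells = dB_cells.reshape(self.L2, self.M)
            np.add.at(db1, self.l2_parent, dB_cells)
            g[self.sl_b2] = (-b2_raw + sig2 * dB_cells).ravel()
            # sigma_l2 ~ halfN(0,1), in log coords
            lp += -0.5 * sig2**2 + q[self.i_usig2]
            g[self.i_usig2] = (sig2 * float(np.sum(b2_raw * dB_cells))
                               - sig2**2 + 1.0)
        else:
            dB_cells = np.zeros(self.L1 * self.M)
            np.add.at(dB_cells, self.spot_cell, deta)
            db1 += dB_cells.reshape(self.L1, self.M)
        g[self.sl_b1] = db1.ravel()

        # --- CAR prior on psi ---
        Khat = inp.K_hat
        Wpsi = inp.W.dot(psi)
        quad_K = float(np.sum(Khat * psi**2))
        quad_W = float(psi @ Wpsi)
        one_m = 1.0 - alpha * inp.car_eigs
        lp += 0.5 * (self.N * math.log(tau) + float(np.sum(np.log(Khat)))
                     + float(np.sum(np.log(one_m))))
        lp += -0.5 * tau * (quad_K - alpha * quad_W)
        dpsi = -tau * (Khat * psi - alpha * Wpsi) + deta
        g[self.sl_psi] = dpsi
        dalpha = -0.5 * float(np.sum(inp.car_eigs / one_m)) + 0.5 * tau * quad_W
        # alpha ~ U(0,1): logistic jacobian log(alpha(1-alpha))
        lp += math.log(alpha) + math.log1p(-alpha)
        g[self.i_a] = dalpha * alpha * (1.0 - alpha) + (1.0 - 2.0 * alpha)
        dtau = 0.5 * self.N / tau - 0.5 * (quad_K - alpha * quad_W)
        # tau ~ InvGamma(1,1) in log coords: -v - exp(-v)
        lp += -q[self.i_v] - 1.0 / tau
        g[self.i_v] = dtau * tau - 1.0 + 1.0 / tau

        # --- spot noise (non-centered) ---
        lp += float(-0.5 * np.sum(eps_raw**2))
        g[self.sl_eps] = -eps_raw + sig_e * deta
        lp += -0.5 * sig_e**2 / SIGMA_EPS_SCALE**2 + q[self.i_usige]
        g[self.i_usige] = (sig_e * float(np.sum(eps_raw * deta))
                           - sig_e**2 / SIGMA_EPS_SCALE**2 + 1.0)

        # --- dropout gate: theta ~ Beta(1,2), logistic jacobian ---
        lp += math.log(theta) + 2.0 * math.log1p(-theta)
        g[self.i_t] = dtheta * theta * (1.0 - theta) + (1.0 - 3.0 * theta)

        return lp, g


# ---------------------------------------------------------------------------
# HMC
# ---------------------------------------------------------------------------

def _hmc_chain(post: _Posterior, iterations: int, warmup: int,
               rng: np.random.Generator, target_accept: float = 0.8,
               max_leapfrog: int = 32) -> tuple[np.ndarray, dict]:
    q = post.initial(rng)
    lp, grad = post.logp_grad(q)
    inv_mass = np.ones(post.dim)
    eps_step = 0.1
    # dual averaging state
    mu_da = math.log(10 * eps_step)
    log_eps_bar = 0.0
    H_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    draws = np.empty((iterations - warmup, post.dim))
    n_div = 0
    n_acc = 0
    window: list[np.ndarray] = []

    for it in range(iterations):
        p = rng.standard_normal(post.dim) / np.sqrt(inv_mass)
        H0 = -lp + 0.5 * float(np.sum(p**2 * inv_mass))
        L = int(rng.integers(max_leapfrog // 2, max_leapfrog + 1))
        qn, lpn, gn = q, lp, grad
        pn = p + 0.5 * eps_step * gn
        diverged = False
        for step in range(L):
            qn = qn + eps_step * inv_mass * pn
            lpn, gn = post.logp_grad(qn)
            if not np.isfinite(lpn):
                diverged = True
                break
            pn = pn + (eps_step if step < L - 1 else 0.5 * eps_step) * gn
        if diverged:
            accept_prob = 0.0
        else:
            H1 = -lpn + 0.5 * float(np.sum(pn**2 * inv_mass))
            dH = H0 - H1
            if not np.isfinite(dH) or dH < -1000.0:
                diverged = True
                accept_prob = 0.0
            else:
                accept_prob = min(1.0, math.exp(min(0.0, dH)))
        if diverged and it >= warmup:
            n_div += 1
        if rng.random() < accept_prob:
            q, lp, grad = qn, lpn, gn
            if it >= warmup:
                n_acc += 1

        if it < warmup:
            # dual averaging on the acceptance statistic
            m = it + 1
            H_bar = (1 - 1 / (m + t0)) * H_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu_da - math.sqrt(m) / gamma * H_bar
            eta = m ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps_step = math.exp(log_eps)
            if warmup // 4 <= it < 3 * warmup // 4:
                window.append(q.copy())
            if it == 3 * warmup // 4 and len(window) > 10:
                var = np.var(np.array(window), axis=0)
                inv_mass = np.clip(var, 1e-4, 1e4)
            if it == warmup - 1:
                eps_step = math.exp(log_eps_bar)
        else:
            draws[it - warmup] = q
    info = {
        "accept_rate": n_acc / max(1, iterations - warmup),
        "divergences": n_div,
        "step_size": eps_step,
    }
    return draws, info


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ for one scalar; chains: (n_chains, n_draws)."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    if half < 2:
        return float("nan")
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    B = n * np.var(means, ddof=1)
    Wv = float(np.mean(np.var(segs, axis=1, ddof=1)))
    if Wv == 0:
        return 1.0
    var_plus = (n - 1) / n * Wv + B / n
    return float(np.sqrt(var_plus / Wv))


# ---------------------------------------------------------------------------
# Fit object and public API
# ---------------------------------------------------------------------------

@dataclass
class SplotchFit:
    """Posterior draws for one taxon/gene plus chain diagnostics."""

    taxon: str
    input: SplotchInput
    beta_l1: np.ndarray            # (draws, L1, M)
    beta_l2: Optional[np.ndarray]  # (draws, L2, M) or None
    psi: np.ndarray                # (draws, N)
    eps: np.ndarray
    theta: np.ndarray              # (draws,)
    alpha: np.ndarray
    tau: np.ndarray
    sigma: np.ndarray              # spot-noise sd
    sigma_l2: Optional[np.ndarray]
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return self.beta_l1.shape[0]

    def rate(self) -> np.ndarray:
        """lambda draws per spot: exp(B + psi + eps); shape (draws, N)."""
        inp = self.input
        M = len(inp.mrois)
        if self.beta_l2 is not None:
            cells = self.beta_l2.reshape(self.n_draws, -1)
            idx = inp.spot_l2 * M + inp.spot_mroi
        else:
            cells = self.beta_l1.reshape(self.n_draws, -1)
            idx = inp.spot_l1 * M + inp.spot_mroi
        B = cells[:, idx]
        return np.exp(B + self.psi + self.eps)

    def beta_summary(self) -> pd.DataFrame:
        rows = []
        inp = self.input
        for l1, cond in enumerate(inp.l1_groups):
            for m, mroi in enumerate(inp.mrois):
                d = self.beta_l1[:, l1, m]
                rows.append({
                    "level": "l1", "group": cond, "mroi": mroi,
                    "mean": d.mean(), "sd": d.std(ddof=1),
                    "q05": np.quantile(d, 0.05), "q95": np.quantile(d, 0.95),
                })
        if self.beta_l2 is not None:
            for l2, (cond, animal) in enumerate(inp.l2_groups):
                for m, mroi in enumerate(inp.mrois):
                    d = self.beta_l2[:, l2, m]
                    rows.append({
                        "level": "l2", "group": f"{cond}/{animal}", "mroi": mroi,
                        "mean": d.mean(), "sd": d.std(ddof=1),
                        "q05": np.quantile(d, 0.05), "q95": np.quantile(d, 0.95),
                    })
        return pd.DataFrame(rows)


def fit(
    inp: SplotchInput,
    taxon: str,
    chains: int = 4,
    iterations: int = 200,
    warmup: int = 100,
    seed: int = 0,
) -> SplotchFit:
    """Sample the posterior for one taxon with HMC.

    ``iterations`` is the total per chain (warmup + kept draws), matching the
    4 x 200 (100 warmup + 100 sampling) default schedule.  Two-level
    hierarchy is used when the design has several level-2 groups; one-level
    otherwise.  More than 10% divergent transitions is flagged in the
    diagnostics, not fatal.
    """
    if taxon not in inp.taxa:
        raise ValueError(f"unknown taxon {taxon!r}")
    y = inp.counts[inp.taxa.index(taxon)]
    post = _Posterior(inp, y)
    kept = iterations - warmup
    if kept < 2:
        raise ValueError("iterations must exceed warmup by at least 2")
    all_draws = np.empty((chains, kept, post.dim))
    infos = []
    for c in range(chains):
        rng = np.random.default_rng(seed * 1_000_003 % (2**31) + c)
        draws, info = _hmc_chain(post, iterations, warmup, rng)
        all_draws[c] = draws
        infos.append(info)

    flat = all_draws.reshape(chains * kept, post.dim)
    L1, L2, M, N = post.L1, post.L2, post.M, post.N
    beta_l1 = flat[:, post.sl_b1].reshape(-1, L1, M)
    sigma_eps = np.exp(flat[:, post.i_usige])
    if post.two_level:
        sigma_l2 = np.exp(flat[:, post.i_usig2])
        b2_raw = flat[:, post.sl_b2].reshape(-1, L2, M)
        beta_l2 = beta_l1[:, post.l2_parent, :] + sigma_l2[:, None, None] * b2_raw
    else:
        sigma_l2 = None
        beta_l2 = None
    # split-Rhat on the beta_l1 cells and the scalars
    rhats = {}
    for l1 in range(L1):
        for m in range(M):
            col = post.sl_b1.start + l1 * M + m
            rhats[f"beta_l1[{inp.l1_groups[l1]},{inp.mrois[m]}]"] = _split_rhat(
                all_draws[:, :, col]
            )
    for name, col in (("theta", post.i_t), ("alpha", post.i_a),
                      ("tau", post.i_v), ("sigma", post.i_usige)):
        rhats[name] = _split_rhat(all_draws[:, :, col])
    n_div = sum(i["divergences"] for i in infos)
    divergence_rate = n_div / max(1, chains * kept)
    diagnostics = {
        "rhat": rhats,
        "max_rhat": float(np.nanmax(list(rhats.values()))),
        "divergences": n_div,
        "divergence_rate": divergence_rate,
        "divergence_flag": divergence_rate > 0.10,
        "accept_rates": [i["accept_rate"] for i in infos],
        "step_sizes": [i["step_size"] for i in infos],
        "chains": chains,
        "kept_draws_per_chain": kept,
    }
    if diagnostics["divergence_flag"]:
        logger.warning("taxon %s: %.1f%% divergent transitions", taxon,
                       100 * divergence_rate)
    return SplotchFit(
        taxon=taxon,
        input=inp,
        beta_l1=beta_l1,
        beta_l2=beta_l2,
        psi=flat[:, post.sl_psi],
        eps=sigma_eps[:, None] * flat[:, post.sl_eps],
        theta=1.0 / (1.0 + np.exp(-flat[:, post.i_t])),
        alpha=1.0 / (1.0 + np.exp(-flat[:, post.i_a])),
        tau=np.exp(flat[:, post.i_v]),
        sigma=sigma_eps,
        sigma_l2=sigma_l2,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Savage-Dickey Bayes factors and calls
# ---------------------------------------------------------------------------

@dataclass
class BFResult:
    """Savage-Dickey Bayes factor for a contrast of two beta_l1 cells."""

    taxon: str
    cell_a: tuple[str, str]   # (condition, mroi)
    cell_b: tuple[str, str]
    delta_draws: np.ndarray
    bf: float
    log10_bf: float
    direction: int            # sign of the posterior mean difference
    prior_sd: float
    infinite: bool = False


def _normal_pdf(x: float, mean: float, sd: float) -> float:
    return math.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))


def savage_dickey_bf(
    fit_result: SplotchFit,
    cell_a: tuple[str, str],
    cell_b: tuple[str, str],
    method: str = "normal",
) -> BFResult:
    """BF = p(delta=0) / p(delta=0 | data) for delta = beta_a - beta_b.

    Both cells are level-1 (condition, MROI) coefficients with independent
    N(0, SIGMA_L1^2) priors, so the prior of the difference is
    N(0, 2 SIGMA_L1^2) in closed form.  The posterior density at zero uses a
    normal approximation of the draws by default (``method="kde"`` switches
    to a Gaussian kernel density estimate).
    """
    inp = fit_result.input
    if cell_a == cell_b:
        raise ValueError("contrast cells must differ")

    def cell_draws(cell: tuple[str, str]) -> np.ndarray:
        cond, mroi = cell
        return fit_result.beta_l1[:, inp.l1_groups.index(cond),
                                  inp.mrois.index(mroi)]

    delta = cell_draws(cell_a) - cell_draws(cell_b)
    prior_sd = math.sqrt(2.0) * SIGMA_L1
    prior_at_0 = _normal_pdf(0.0, 0.0, prior_sd)
    mean = float(delta.mean())
    sd = float(delta.std(ddof=1))
    infinite = False
    if sd == 0.0:
        post_at_0 = 0.0
    elif method == "kde":
        post_at_0 = float(gaussian_kde(delta)(0.0)[0])
    elif method == "normal":
        post_at_0 = _normal_pdf(0.0, mean, sd)
    else:
        raise ValueError(f"unknown density method {method!r}")
    if post_at_0 == 0.0:
        bf = math.inf
        infinite = True
    else:
        bf = prior_at_0 / post_at_0
    return BFResult(
        taxon=fit_result.taxon,
        cell_a=cell_a,
        cell_b=cell_b,
        delta_draws=delta,
        bf=bf,
        log10_bf=math.log10(bf) if bf > 0 else -math.inf,
        direction=int(np.sign(mean)) if mean != 0 else 0,
        prior_sd=prior_sd,
        infinite=infinite,
    )


def call_de(bf_results: Sequence[BFResult],
            threshold: float = DE_LOG10_BF) -> pd.DataFrame:
    """Differential table: flagged iff mean delta > 0 and log10 BF > threshold."""
    rows = []
    for r in bf_results:
        mean = float(r.delta_draws.mean())
        rows.append({
            "taxon": r.taxon,
            "cell_a": "/".join(r.cell_a),
            "cell_b": "/".join(r.cell_b),
            "delta_mean": mean,
            "bf": r.bf,
            "log10_bf": r.log10_bf,
            "significant": bool(mean > 0 and r.log10_bf > threshold),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bacteria detection rule
# ---------------------------------------------------------------------------

def region_weighted_means(fit_result: SplotchFit) -> pd.Series:
    """Posterior-mean rate averaged over each MROI's spots.

    Pooling spots across sections weights each section by its spot count in
    the region.
    """
    lam = fit_result.rate().mean(axis=0)
    inp = fit_result.input
    out = {}
    for m, mroi in enumerate(inp.mrois):
        sel = inp.spot_mroi == m
        out[mroi] = float(lam[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, name=fit_result.taxon)


def detect_taxa(
    spf_means: pd.DataFrame,
    gf_means: pd.DataFrame,
    spf_region_counts: pd.DataFrame,
    min_share: float = DETECT_MIN_SHARE,
) -> list[tuple[str, str]]:
    """(taxon, MROI) pairs detected in SPF tissue.

    A pair is detected iff the SPF weighted mean count in the region exceeds
    the maximum GF weighted mean over all regions for that taxon, and the
    region's raw count exceeds ``min_share`` of the taxon's total count.
    Taxa absent from the GF table use a GF maximum of 0.
    """
    detected = []
    for taxon in spf_means.index:
        gf_max = (float(np.nanmax(gf_means.loc[taxon].to_numpy()))
                  if taxon in gf_means.index else 0.0)
        total = float(spf_region_counts.loc[taxon].sum())
        for mroi in spf_means.columns:
            wm = spf_means.loc[taxon, mroi]
            if np.isnan(wm) or wm <= gf_max:
                continue
            share = (spf_region_counts.loc[taxon, mroi] / total
                     if total > 0 else 0.0)
            if share > min_share:
                detected.append((taxon, mroi))
    return detected
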