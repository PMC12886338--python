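"""Causal disease-aware alignment: stratified MMD, contrastive supervision,
Gaussian-KL invariance with running statistics, counterfactual consistency,
and the total objective.

All distributional terms operate on the disease code ``z_d``. The RBF kernel
bandwidth follows the median heuristic on the current batch; stratum or
(class, stratum) cells with fewer than two samples are skipped (and logged)
so no degenerate covariance or empty mean ever enters a loss. Each stratum
pair is weighted by the harmonic mean of the two cell sizes divided by the
batch size, which downweights tiny cells and is bounded above by 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .autodiff import Tensor, as_tensor, grad_reverse, logdet
from .errors import ValidationError
from .losses import LossWeights, loss_cls, sq_norm_rows

logger = logging.getLogger(__name__)

MIN_CELL = 2          # smallest usable subgroup for distributional terms
COV_FLOOR = 1e-6      # epsilon added to the shrinkage target's scale


# --------------------------------------------------------------------------
# Running class / cell statistics
# --------------------------------------------------------------------------

@dataclass
class ClassStats:
    """EMA centers and running Gaussian statistics per class and per cell."""

    n_classes: int
    n_strata: int
    dim: int
    ema_decay: float = 0.9
    shrink_alpha: float = 0.1
    centers: np.ndarray = field(default=None)
    center_init: np.ndarray = field(default=None)
    class_mean: np.ndarray = field(default=None)
    class_cov: np.ndarray = field(default=None)
    class_count: np.ndarray = field(default=None)
    cell_mean: np.ndarray = field(default=None)
    cell_cov: np.ndarray = field(default=None)
    cell_count: np.ndarray = field(default=None)

    def __post_init__(self):
        k, s, d = self.n_classes, self.n_strata, self.dim
        if self.centers is None:
            self.centers = np.zeros((k, d))
            self.center_init = np.zeros(k, dtype=bool)
            self.class_mean = np.zeros((k, d))
            self.class_cov = np.zeros((k, d, d))
            self.class_count = np.zeros(k)
            self.cell_mean = np.zeros((k, s, d))
            self.cell_cov = np.zeros((k, s, d, d))
            self.cell_count = np.zeros((k, s))

    def to_h5(self, grp) -> None:
        for name in ("centers", "center_init", "class_mean", "class_cov",
                     "class_count", "cell_mean", "cell_cov", "cell_count"):
            grp.create_dataset(name, data=getattr(self, name))
        grp.attrs["n_classes"] = self.n_classes
        grp.attrs["n_strata"] = self.n_strata
        grp.attrs["dim"] = self.dim
        grp.attrs["ema_decay"] = self.ema_decay
        grp.attrs["shrink_alpha"] = self.shrink_alpha

    @classmethod
    def from_h5(cls, grp) -> "ClassStats":
        out = cls(n_classes=int(grp.attrs["n_classes"]),
                  n_strata=int(grp.attrs["n_strata"]),
                  dim=int(grp.attrs["dim"]),
                  ema_decay=float(grp.attrs["ema_decay"]),
                  shrink_alpha=float(grp.attrs["shrink_alpha"]))
        for name in ("centers", "class_mean", "class_cov", "class_count",
                     "cell_mean", "cell_cov", "cell_count"):
            setattr(out, name, grp[name][...])
        out.center_init = grp["center_init"][...].astype(bool)
        return out


def _as_data(z) -> np.ndarray:
    return z.data if isinstance(z, Tensor) else np.asarray(z, dtype=float)


def update_centers(z_d, y, stats: ClassStats) -> ClassStats:
    """EMA update of per-class centers (outside the gradient path)."""
    z = _as_data(z_d)
    y = np.asarray(y, dtype=np.intp)
    decay = stats.ema_decay
    for k in np.unique(y):
        m = z[y == k].mean(axis=0)
        if stats.center_init[k]:
            stats.centers[k] = decay * stats.centers[k] + (1 - decay) * m
        else:
            stats.centers[k] = m
            stats.center_init[k] = True
    return stats


def _shrink(cov: np.ndarray, alpha: float, d: int) -> np.ndarray:
    target = (np.trace(cov) / d + COV_FLOOR) * np.eye(d)
    return (1 - alpha) * cov + alpha * target


def update_gaussian_stats(z_d, y, strata, stats: ClassStats) -> ClassStats:
    """EMA means/covariances per class and per (class, stratum) cell.

    Covariances are shrunk toward a scaled identity (with a small floor) after
    every update, so they stay positive-definite for any shrink_alpha > 0.
    """
    z = _as_data(z_d)
    y = np.asarray(y, dtype=np.intp)
    s = np.asarray(strata, dtype=np.intp)
    decay, alpha, d = stats.ema_decay, stats.shrink_alpha, stats.dim

    def batch_moments(sel):
        zs = z[sel]
        m = zs.mean(axis=0)
        c = (zs - m).T @ (zs - m) / len(zs)
        return m, c

    for k in range(stats.n_classes):
        sel_k = y == k
        if sel_k.sum() >= MIN_CELL:
            m, c = batch_moments(sel_k)
            if stats.class_count[k] > 0:
                m = decay * stats.class_mean[k] + (1 - decay) * m
                c = decay * stats.class_cov[k] + (1 - decay) * c
            stats.class_mean[k] = m
            stats.class_cov[k] = _shrink(c, alpha, d)
            stats.class_count[k] += sel_k.sum()
        for st in range(stats.n_strata):
            sel = sel_k & (s == st)
            if sel.sum() >= MIN_CELL:
                m, c = batch_moments(sel)
                if stats.cell_count[k, st] > 0:
                    m = decay * stats.cell_mean[k, st] + (1 - decay) * m
                    c = decay * stats.cell_cov[k, st] + (1 - decay) * c
                stats.cell_mean[k, st] = m
                stats.cell_cov[k, st] = _shrink(c, alpha, d)
                stats.cell_count[k, st] += sel.sum()
    return stats


# --------------------------------------------------------------------------
# Kernel machinery
# --------------------------------------------------------------------------

def median_bandwidth(embeddings) -> float:
    """Median pairwise Euclidean distance (the median heuristic)."""
    z = _as_data(embeddings)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValidationError("need >= 2 embeddings")
    med = float(np.median(pdist(z)))
    if med <= 0:
        logger.warning("all embeddings coincide; bandwidth falls back to 1.0")
        return 1.0
    return med


def _sq_dists(a: Tensor, b: Tensor) -> Tensor:
    """Differentiable pairwise squared Euclidean distances."""
    aa = sq_norm_rows(a).reshape(-1, 1)
    bb = sq_norm_rows(b).reshape(1, -1)
    return aa + bb - 2.0 * (a @ b.T)


def mmd2(sample_p, sample_q, bandwidth: float, kernel: str = "rbf",
         unbiased: bool = False) -> Tensor:
    """Squared MMD under an RBF or linear kernel.

    The default is the biased V-statistic (always >= 0), used as the training
    loss. With ``unbiased=True`` the within-sample diagonals are excluded
    (U-statistic): zero in expectation for identical distributions, so it is
    the right estimator for *measuring* residual discrepancy, at the price of
    occasionally negative values.
    """
    p, q = as_tensor(sample_p), as_tensor(sample_q)
    if p.ndim != 2 or q.ndim != 2 or p.shape[0] == 0 or q.shape[0] == 0:
        raise ValidationError("samples must be non-empty 2-D arrays")
    if p.shape[1] != q.shape[1]:
        raise ValidationError("sample dims differ")
    if kernel == "linear":
        d = p.mean(axis=0) - q.mean(axis=0)
        return (d * d).sum()
    if kernel != "rbf":
        raise ValidationError(f"unknown kernel {kernel!r}")
    scale = -1.0 / (2.0 * bandwidth ** 2)
    n, m = p.shape[0], q.shape[0]
    kpp = (_sq_dists(p, p) * scale).exp()
    kqq = (_sq_dists(q, q) * scale).exp()
    kpq = (_sq_dists(p, q) * scale).exp().mean()
    if unbiased and n > 1 and m > 1:
        off_p = 1.0 - np.eye(n)
        off_q = 1.0 - np.eye(m)
        return ((kpp * off_p).sum() * (1.0 / (n * (n - 1)))
                + (kqq * off_q).sum() * (1.0 / (m * (m - 1))) - 2.0 * kpq)
    return kpp.mean() + kqq.mean() - 2.0 * kpq


def _pair_weight(n1: int, n2: int, n_batch: int) -> float:
    return (2.0 * n1 * n2 / (n1 + n2)) / n_batch


def loss_mmd_strata(z_d, strata, kernel: str = "rbf") -> Tensor:
    """Marginal alignment: pairwise MMD^2 across strata, size-reweighted."""
    z = as_tensor(z_d)
    s = np.asarray(strata, dtype=np.intp)
    groups = {st: np.flatnonzero(s == st) for st in np.unique(s)}
    usable = [st for st, idx in groups.items() if len(idx) >= MIN_CELL]
    if len(usable) < 2:
        logger.info("loss_mmd_strata skipped: fewer than 2 usable strata")
        return Tensor(0.0)
    h = median_bandwidth(z.data) if kernel == "rbf" else 1.0
    n = z.shape[0]
    total = Tensor(0.0)
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            ia, ib = groups[usable[a]], groups[usable[b]]
            w = _pair_weight(len(ia), len(ib), n)
            total = total + w * mmd2(z.take_rows(ia), z.take_rows(ib), h,
                                     kernel)
    return total


def loss_cond_align(z_d, y, strata, kernel: str = "rbf") -> Tensor:
    """Class-conditional alignment: per-class pairwise subgroup MMD^2."""
    z = as_tensor(z_d)
    y = np.asarray(y, dtype=np.intp)
    s = np.asarray(strata, dtype=np.intp)
    n = z.shape[0]
    h = median_bandwidth(z.data) if (kernel == "rbf" and n >= 2) else 1.0
    total = Tensor(0.0)
    any_used = False
    for k in np.unique(y):
        sel_k = y == k
        groups = {st: np.flatnonzero(sel_k & (s == st))
                  for st in np.unique(s[sel_k])}
        usable = [st for st, idx in groups.items() if len(idx) >= MIN_CELL]
        for a in range(len(usable)):
            for b in range(a + 1, len(usable)):
                ia, ib = groups[usable[a]], groups[usable[b]]
                w = _pair_weight(len(ia), len(ib), n)
                total = total + w * mmd2(z.take_rows(ia), z.take_rows(ib),
                                         h, kernel)
                any_used = True
    if not any_used:
        logger.info("loss_cond_align skipped: no class with 2 usable cells")
    return total


# --------------------------------------------------------------------------
# Contrastive family
# --------------------------------------------------------------------------

def _normalize_rows(z: Tensor) -> Tensor:
    norms = (sq_norm_rows(z) + 1e-12).sqrt().reshape(-1, 1)
    return z / norms


def loss_supcon(z_d, y, tau: float) -> Tensor:
    """Supervised contrastive loss over all (anchor, positive) pairs."""
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    z = as_tensor(z_d)
    y = np.asarray(y, dtype=np.intp)
    n = z.shape[0]
    if n < 2:
        raise ValidationError("batch must have >= 2 samples")
    zn = _normalize_rows(z)
    sim = (zn @ zn.T) * (1.0 / tau)
    off_diag = 1.0 - np.eye(n)
    # stable log-sum-exp over A(i) = batch \ {i}
    shift = np.where(off_diag > 0, sim.data, -np.inf).max(axis=1,
                                                          keepdims=True)
    exps = (sim - shift).exp() * off_diag
    log_den = exps.sum(axis=1, keepdims=True).log() + shift
    pos = (y[:, None] == y[None, :]).astype(float) * off_diag
    n_pairs = pos.sum()
    if n_pairs == 0:
        logger.info("loss_supcon: no positive pairs in batch")
        return Tensor(0.0)
    return ((log_den - sim) * pos).sum() * (1.0 / n_pairs)


def loss_stability(z_d, sigma_stab: float, seed=None) -> Tensor:
    """Perturbation anchoring: mean ||z - (detach(z) + eps)||^2.

    The perturbed copy is treated as a constant target, so the gradient
    flows only through the model's own embedding.
    """
    if sigma_stab < 0:
        raise ValidationError("sigma_stab must be >= 0")
    z = as_tensor(z_d)
    if sigma_stab == 0:
        return Tensor(0.0)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma_stab, size=z.shape)
    target = z.data + eps
    return sq_norm_rows(z - target).mean()


def loss_hard_contrastive(z_d, y, tau: float, hard_k: int) -> Tensor:
    """Hardness-aware contrastive loss (hardest positive vs top-k negatives).

    Averaged over anchors that have at least one positive and one negative.
    """
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    z = as_tensor(z_d)
    y = np.asarray(y, dtype=np.intp)
    n = z.shape[0]
    zn = _normalize_rows(z)
    sim = zn @ zn.T
    sim_data = sim.data
    flat = sim.reshape(-1)

    terms = []
    n_valid = 0
    for i in range(n):
        pos = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        neg = np.flatnonzero(y != y[i])
        if len(pos) == 0 or len(neg) == 0:
            continue
        n_valid += 1
        j_star = pos[np.argmin(sim_data[i, pos])]          # hardest positive
        order = neg[np.argsort(sim_data[i, neg])[::-1]]     # hardest first
        hard = order[:hard_k] if hard_k > 0 else order
        idx = np.concatenate([[i * n + j_star], i * n + hard])
        vals = flat.take_rows(idx) * (1.0 / tau)
        shift = float(vals.data.max())
        e = (vals - shift).exp()
        num = e.take_rows([0])
        den = e.sum()
        terms.append(-(num.sum().log() - den.log()))
    if not terms:
        return Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / n_valid)


def loss_center(z_d, y, stats: ClassStats) -> Tensor:
    """Mean squared distance of each embedding to its class EMA center."""
    z = as_tensor(z_d)
    y = np.asarray(y, dtype=np.intp)
    for k in np.unique(y):
        if not stats.center_init[k]:
            stats.centers[k] = z.data[y == k].mean(axis=0)
            stats.center_init[k] = True
            logger.info("loss_center: lazily initialized center %d", k)
    mu = stats.centers[y]
    return sq_norm_rows(z - mu).mean()


def contrastive_total(con, stab, hard, center, w: LossWeights) -> Tensor:
    """Weighted contrastive bundle: con + stab + hard + center."""
    return (as_tensor(con) + w.lambda_stab * as_tensor(stab)
            + w.lambda_hard * as_tensor(hard)
            + w.lambda_center * as_tensor(center))


# --------------------------------------------------------------------------
# Gaussian-KL invariance
# --------------------------------------------------------------------------

def _gauss_kl(m0, c0, m1, c1) -> float:
    """KL( N(m0, c0) || N(m1, c1) ), closed form, plain numpy."""
    d = len(m0)
    c1_inv = np.linalg.inv(c1)
    diff = m1 - m0
    _, ld1 = np.linalg.slogdet(c1)
    _, ld0 = np.linalg.slogdet(c0)
    return 0.5 * (np.trace(c1_inv @ c0) + diff @ c1_inv @ diff - d
                  + ld1 - ld0)


def loss_invariance(stats: ClassStats, min_count: int = MIN_CELL) -> float:
    """Sum of KL(cell Gaussian || class Gaussian) over populated cells."""
    total = 0.0
    for k in range(stats.n_classes):
        if stats.class_count[k] < min_count:
            continue
        for s in range(stats.n_strata):
            if stats.cell_count[k, s] < min_count:
                continue
            total += _gauss_kl(stats.cell_mean[k, s], stats.cell_cov[k, s],
                               stats.class_mean[k], stats.class_cov[k])
    return float(total)


def loss_invariance_batch(z_d, y, strata, stats: ClassStats) -> Tensor:
    """Differentiable invariance term: within-batch cell Gaussians against
    the (detached) EMA class Gaussians, same closed form as loss_invariance.
    """
    z = as_tensor(z_d)
    y = np.asarray(y, dtype=np.intp)
    s = np.asarray(strata, dtype=np.intp)
    d = stats.dim
    eye = np.eye(d)
    alpha = stats.shrink_alpha
    total = Tensor(0.0)
    used = False
    for k in range(stats.n_classes):
        if stats.class_count[k] < MIN_CELL:
            continue
        c_inv = np.linalg.inv(stats.class_cov[k])
        _, ld_class = np.linalg.slogdet(stats.class_cov[k])
        mu_k = stats.class_mean[k]
        for st in np.unique(s[y == k]):
            idx = np.flatnonzero((y == k) & (s == st))
            if len(idx) < MIN_CELL:
                continue
            zc = z.take_rows(idx)
            m = zc.mean(axis=0)
            ctr = zc - m.reshape(1, -1)
            cov = (ctr.T @ ctr) * (1.0 / len(idx))
            tr = (cov * eye).sum()
            cov = (1 - alpha) * cov + (alpha * (tr * (1.0 / d) + COV_FLOOR)) \
                * eye
            diff = m - mu_k
            quad = (diff.reshape(1, -1) @ c_inv @ diff.reshape(-1, 1)).sum()
            trace_term = (cov * c_inv.T).sum()
            kl = 0.5 * (trace_term + quad - d + ld_class - logdet(cov))
            total = total + kl
            used = True
    if not used:
        logger.info("loss_invariance_batch skipped: no warm cells")
    return total


# --------------------------------------------------------------------------
# Counterfactual consistency and domain confusion
# --------------------------------------------------------------------------

def loss_counterfactual(cf_images, target_images) -> Tensor:
    """Mean over counterfactuals of the min squared distance to any target."""
    cf = as_tensor(cf_images)
    if cf.ndim == 3:
        cf = cf.reshape(cf.shape[0], -1)
    tgt = np.asarray(_as_data(target_images), dtype=float)
    if tgt.ndim == 3:
        tgt = tgt.reshape(tgt.shape[0], -1)
    if tgt.shape[0] == 0:
        logger.info("loss_counterfactual skipped: empty target set")
        return Tensor(0.0)
    d2 = _sq_dists(cf, Tensor(tgt))
    nearest = d2.data.argmin(axis=1)
    n = cf.shape[0]
    flat = d2.reshape(-1)
    picked = flat.take_rows(np.arange(n) * tgt.shape[0] + nearest)
    return picked.mean()


def domain_confusion_loss(domain_head, z_d, strata,
                          reversal_strength: float) -> Tensor:
    """Stratum cross-entropy on z_d with gradient reversal to the encoder."""
    if domain_head is None:
        raise ValidationError("domain-confusion branch is not enabled")
    from .model import softmax  # local import avoids a cycle

    z = as_tensor(z_d)
    probs = softmax(domain_head(grad_reverse(z, reversal_strength)))
    return loss_cls(probs, strata)


# --------------------------------------------------------------------------
# Total objective
# --------------------------------------------------------------------------

def total_cdaa(terms: dict, w: LossWeights) -> Tensor:
    """Alignment-augmented total loss.

    Expects keys: task, mmd, cond, contrastive, inv, cf.
    """
    needed = ["task", "mmd", "cond", "contrastive", "inv", "cf"]
    missing = [k for k in needed if k not in terms]
    if missing:
        raise ValidationError(f"missing loss terms: {missing}")
    return (as_tensor(terms["task"])
            + w.lambda1 * w.lambda_m * as_tensor(terms["mmd"])
            + w.lambda2 * w.lambda_c * as_tensor(terms["cond"])
            + w.lambda3 * as_tensor(terms["contrastive"])
            + w.lambda4 * as_tensor(terms["inv"])
            + w.lambda5 * as_tensor(terms["cf"]))
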