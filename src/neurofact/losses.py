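"""Reconstruction- and supervision-side loss terms.

Reduction convention, used everywhere: sum of squares over pixels / latent
dims inside each norm, mean over the batch; the temporal term is divided by
the number of contributing visit pairs. The Gaussian likelihood variance
``sigma2`` enters only the base reconstruction term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .errors import ValidationError


@dataclass
class LossWeights:
    """Every coefficient of the composite objective (all config-exposed).

    ``lambda1..lambda5`` weight the alignment terms of the total objective
    (MMD, conditional alignment, contrastive bundle, invariance,
    counterfactual); ``lambda_m``/``lambda_c`` are the inner marginal/
    conditional trade-off knobs and compose multiplicatively with
    ``lambda1``/``lambda2``.
    """

    sigma2: float = 25.0
    lambda_a: float = 0.005
    lambda_d: float = 0.005
    w_kl: float = 0.05
    kl_ratio_a: float = 4.0    # extra compression on the anatomy branch
    w_add: float = 0.5
    w_decorr: float = 0.001
    w_cls: float = 2.0
    w_age: float = 0.3
    w_smooth: float = 0.1
    w_xcov: float = 0.5
    w_sep_age: float = 10.0
    w_sep_cls: float = 5.0
    lambda_m: float = 1.0
    lambda_c: float = 1.0
    tau: float = 0.1
    sigma_stab: float = 0.1
    lambda_stab: float = 1.0
    lambda_hard: float = 0.5
    lambda_center: float = 0.1
    lambda1: float = 0.1
    lambda2: float = 0.1
    lambda3: float = 0.5
    lambda4: float = 0.1
    lambda5: float = 0.01
    gamma: float = 1.0
    smooth_mode: str = "adjacent"
    ema_decay: float = 0.9
    shrink_alpha: float = 0.1
    hard_k: int = 5
    reversal_strength: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")
        if self.sigma2 <= 0:
            raise ValidationError("sigma2 must be > 0")
        if not (0.0 <= self.ema_decay < 1.0):
            raise ValidationError("ema_decay must be in [0, 1)")
        if not (0.0 <= self.shrink_alpha <= 1.0):
            raise ValidationError("shrink_alpha must be in [0, 1]")
        if self.smooth_mode not in ("adjacent", "exp_decay"):
            raise ValidationError(f"unknown smooth_mode {self.smooth_mode!r}")
        for name in ("lambda_a", "lambda_d", "w_kl", "w_add", "w_decorr",
                     "w_cls", "w_age", "w_smooth", "lambda_m", "lambda_c",
                     "sigma_stab", "lambda_stab", "lambda_hard",
                     "lambda_center", "lambda1", "lambda2", "lambda3",
                     "lambda4", "lambda5", "gamma", "reversal_strength",
                     "kl_ratio_a", "w_xcov", "w_sep_age", "w_sep_cls"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _flat(t) -> Tensor:
    """Flatten image batches to (n, pixels)."""
    t = as_tensor(t)
    if t.ndim == 3:
        return t.reshape(t.shape[0], -1)
    if t.ndim == 1:
        return t.reshape(1, -1)
    return t


def _check_same_shape(*tensors) -> list[Tensor]:
    flats = [_flat(t) for t in tensors]
    if len({f.shape for f in flats}) != 1:
        raise ValidationError("image shapes do not match")
    return flats


def sq_norm_rows(t: Tensor) -> Tensor:
    """Per-row sum of squares."""
    return (t * t).sum(axis=1)


# --------------------------------------------------------------------------

def loss_recon(x, x_hat, sigma2: float) -> Tensor:
    """Negative Gaussian log-likelihood up to a constant: ||x-x^||^2/(2s^2)."""
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be > 0")
    x, x_hat = _check_same_shape(x, x_hat)
    return sq_norm_rows(x - x_hat).mean() * (1.0 / (2.0 * sigma2))


def _branch_kl(mu, lv) -> Tensor:
    mu, lv = as_tensor(mu), as_tensor(lv)
    if not (np.all(np.isfinite(mu.data)) and np.all(np.isfinite(lv.data))):
        raise ValidationError("non-finite posterior parameters")
    return ((lv.exp() + mu * mu - 1.0 - lv) * 0.5).sum(axis=1).mean()


def loss_kl(latent) -> Tensor:
    """Diagonal-Gaussian KL to N(0, I), summed over both branches."""
    return (_branch_kl(latent.mu_a, latent.logvar_a)
            + _branch_kl(latent.mu_d, latent.logvar_d))


def loss_kl_branches(latent) -> tuple[Tensor, Tensor]:
    """The two branch KLs separately (their sum is loss_kl)."""
    return (_branch_kl(latent.mu_a, latent.logvar_a),
            _branch_kl(latent.mu_d, latent.logvar_d))


def loss_additive(x_hat, x_hat_a, x_hat_d) -> Tensor:
    """Deviation of the full reconstruction from the pathway sum."""
    x_hat, x_hat_a, x_hat_d = _check_same_shape(x_hat, x_hat_a, x_hat_d)
    return sq_norm_rows(x_hat - x_hat_a - x_hat_d).mean()


def loss_rec_aug(x, x_hat, x_hat_a, x_hat_d,
                 lambda_a: float, lambda_d: float) -> Tensor:
    """Full + pathway-specific reconstruction errors, weighted."""
    if lambda_a < 0 or lambda_d < 0:
        raise ValidationError("lambda_a and lambda_d must be >= 0")
    x, x_hat, x_hat_a, x_hat_d = _check_same_shape(x, x_hat, x_hat_a, x_hat_d)
    out = sq_norm_rows(x - x_hat).mean()
    out = out + lambda_a * sq_norm_rows(x - x_hat_a).mean()
    return out + lambda_d * sq_norm_rows(x - x_hat_d).mean()


def loss_decorr(x_hat_a, x_hat_d) -> Tensor:
    """Squared pixel-space inner product of the two partial reconstructions."""
    x_hat_a, x_hat_d = _check_same_shape(x_hat_a, x_hat_d)
    inner = (x_hat_a * x_hat_d).sum(axis=1)
    return (inner * inner).mean()


def loss_cls(probs, y) -> Tensor:
    """Cross-entropy from predicted class probabilities."""
    probs = as_tensor(probs)
    y = np.asarray(y, dtype=np.intp)
    n, k = probs.shape
    if y.shape != (n,):
        raise ValidationError("labels must be one per row of probs")
    if np.any(y < 0) or np.any(y >= k):
        raise ValidationError("label out of range")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    p_true = (probs * onehot).sum(axis=1)
    return -(p_true.log().mean())


def loss_age(pred, t) -> Tensor:
    pred, t = as_tensor(pred), as_tensor(t)
    if pred.shape != t.shape:
        raise ValidationError("prediction/target lengths differ")
    d = pred - t
    return (d * d).mean()


def loss_smooth(z_a, z_d, subject_ids, times, mode: str = "adjacent",
                gamma: float = 1.0) -> Tensor:
    """Temporal coherence of within-subject latent trajectories.

    ``adjacent`` penalizes consecutive-visit differences; ``exp_decay``
    weights all within-subject pairs by exp(-gamma |t - t'|). Both are
    normalized by the number of contributing pairs.
    """
    if mode not in ("adjacent", "exp_decay"):
        raise ValidationError(f"unknown mode {mode!r}")
    z_a, z_d = as_tensor(z_a), as_tensor(z_d)
    subject_ids = np.asarray(subject_ids)
    times = np.asarray(times, dtype=float)
    ii, jj, ww = [], [], []
    for sid in np.unique(subject_ids):
        idx = np.flatnonzero(subject_ids == sid)
        idx = idx[np.argsort(times[idx], kind="stable")]
        if len(idx) < 2:
            continue
        if mode == "adjacent":
            for a, b in zip(idx[:-1], idx[1:]):
                ii.append(a), jj.append(b), ww.append(1.0)
        else:
            for p in range(len(idx)):
                for q in range(p + 1, len(idx)):
                    a, b = idx[p], idx[q]
                    ii.append(a), jj.append(b)
                    ww.append(np.exp(-gamma * abs(times[b] - times[a])))
    if not ii:
        return Tensor(0.0)
    w = np.asarray(ww)
    da = z_a.take_rows(ii) - z_a.take_rows(jj)
    dd = z_d.take_rows(ii) - z_d.take_rows(jj)
    per_pair = sq_norm_rows(da) + sq_norm_rows(dd)
    return (per_pair * w).sum() * (1.0 / len(ii))


def loss_latent_xcov(z_a, z_d) -> Tensor:
    """Elementwise L1 norm of the batch cross-covariance of the codes.

    Realizes the latent-independence assumption (z_a independent of z_d): any
    factor redundantly encoded in both branches shows up as cross-covariance
    between some pair of dimensions and is penalized, decoupling the two
    codes' functional roles.
    """
    z_a, z_d = as_tensor(z_a), as_tensor(z_d)
    if z_a.shape[0] != z_d.shape[0]:
        raise ValidationError("batch sizes differ")
    n = z_a.shape[0]
    if n < 2:
        return Tensor(0.0)
    ca = z_a - z_a.mean(axis=0, keepdims=True)
    cd = z_d - z_d.mean(axis=0, keepdims=True)
    xc = (ca.T @ cd) * (1.0 / n)
    return ((xc * xc) + 1e-12).sqrt().sum()


def loss_nuisance_r2(z, target, ridge_frac: float = 0.05) -> Tensor:
    """Separability penalty: linear readability of a nuisance from a code.

    Computes the (ridge-regularized) multivariate R^2 of the best linear
    predictor of `target` from `z` within the batch — exactly the quantity a
    linear/ridge probe on the code measures — and is minimized to remove
    every linearly readable trace of the nuisance. `target` is a vector
    (standardized internally) or an integer label vector (one-hot encoded);
    for labels the value is the summed R^2 over class indicators.
    """
    from .autodiff import inv

    z = as_tensor(z)
    n = z.shape[0]
    if n < 2:
        return Tensor(0.0)
    tgt = np.asarray(target)
    if tgt.ndim == 1 and np.issubdtype(tgt.dtype, np.integer):
        k = int(tgt.max()) + 1
        tgt = np.eye(k)[tgt]
    else:
        tgt = tgt.reshape(n, -1).astype(float)
    tgt = tgt - tgt.mean(axis=0)
    sd = tgt.std(axis=0)
    tgt = tgt / np.where(sd > 0, sd, 1.0)
    zc = z - z.mean(axis=0, keepdims=True)
    d = zc.shape[1]
    cov_zz = (zc.T @ zc) * (1.0 / n)
    lam = ridge_frac * float(np.trace(cov_zz.data)) / d + 1e-8
    cov_zt = (zc.T @ tgt) * (1.0 / n)
    s_inv = inv(cov_zz + lam * np.eye(d))
    return (cov_zt * (s_inv @ cov_zt)).sum()


def task_total(terms: dict, w: LossWeights) -> Tensor:
    """Weighted sum of the reconstruction/supervision bundle.

    Expects keys: recon, rec_a, rec_d, kl, additive, decorr, cls, age, smooth
    (recon is the sigma2-scaled base term; rec_a/rec_d the raw pathway
    errors).
    """
    needed = ["recon", "rec_a", "rec_d", "kl", "additive", "decorr",
              "cls", "age", "smooth"]
    missing = [k for k in needed if k not in terms]
    if missing:
        raise ValidationError(f"missing task terms: {missing}")
    t = terms
    if "kl_a" in t and "kl_d" in t:
        kl_term = w.kl_ratio_a * as_tensor(t["kl_a"]) + as_tensor(t["kl_d"])
    else:
        kl_term = as_tensor(t["kl"])
    return (as_tensor(t["recon"])
            + w.lambda_a * as_tensor(t["rec_a"])
            + w.lambda_d * as_tensor(t["rec_d"])
            + w.w_kl * kl_term
            + w.w_add * as_tensor(t["additive"])
            + w.w_decorr * as_tensor(t["decorr"])
            + w.w_cls * as_tensor(t["cls"])
            + w.w_age * as_tensor(t["age"])
            + w.w_smooth * as_tensor(t["smooth"])
            + w.w_xcov * as_tensor(t.get("xcov", 0.0)))
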