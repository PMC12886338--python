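"""Stratified batching, the optimization loop, and the evaluation harness.

Training executes the full alignment-augmented objective on phantom cohorts:
subject-level 70/15/15 train/validation/test splits, per-step logging of every
loss term, best-validation checkpoint selection, and deterministic seeding of
every stochastic component (batching, reparameterization, perturbations).
Evaluation probes the frozen latents with linear/ridge models to measure what
information each pathway carries, never touching model weights.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import (balanced_accuracy_score, f1_score,
                             roc_auc_score)

from . import alignment as al
from . import losses as ls
from .autodiff import Tensor
from .errors import ValidationError
from .losses import LossWeights
from .model import ModelConfig, NeuroFactNet
from .nn import Adam, clip_grad_norm
from .phantom import PhantomDataset

logger = logging.getLogger(__name__)


@dataclass
class OptimConfig:
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    clip_norm: float = 5.0
    penalty_ramp_epochs: int = 0   # 0 = decoupling penalties on from step 1

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")


@dataclass
class Batch:
    images: np.ndarray       # (n, H, W)
    y: np.ndarray
    ages: np.ndarray
    strata: np.ndarray
    subject_ids: np.ndarray
    visit_indices: np.ndarray


_UNDEFINED = "undefined"


@dataclass
class EvalReport:
    """Disentanglement / invariance / counterfactual metrics on one split."""

    age_pearson_r: float | str = _UNDEFINED
    class_accuracy: float | str = _UNDEFINED
    auc: float | str = _UNDEFINED
    f1: float | str = _UNDEFINED
    sensitivity: float | str = _UNDEFINED
    specificity: float | str = _UNDEFINED
    leakage_age_from_zd: float | str = _UNDEFINED
    leakage_class_from_za: float | str = _UNDEFINED
    site_mmd2: float | str = _UNDEFINED
    stratum_probe_accuracy: float | str = _UNDEFINED
    counterfactual_success_rate: float | str = _UNDEFINED
    mean_adjacent_displacement: float | str = _UNDEFINED
    n_scans: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls(**json.loads(text))


# --------------------------------------------------------------------------
# Splitting and batching
# --------------------------------------------------------------------------

def subject_split(ds: PhantomDataset, seed: int,
                  fractions=(0.70, 0.15, 0.15)) -> dict[str, np.ndarray]:
    """Subject-level stratified train/val/test split (scan-index arrays)."""
    rng = np.random.default_rng(seed)
    subj = ds.meta.groupby("subject_id")["diagnosis"].first()
    train_ids, val_ids, test_ids = [], [], []
    for _, grp in subj.groupby(subj):
        ids = grp.index.to_numpy()
        rng.shuffle(ids)
        n = len(ids)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        train_ids += list(ids[:n_tr])
        val_ids += list(ids[n_tr:n_tr + n_va])
        test_ids += list(ids[n_tr + n_va:])
    sid = ds.meta["subject_id"].to_numpy()
    return {name: np.flatnonzero(np.isin(sid, ids))
            for name, ids in (("train", train_ids), ("val", val_ids),
                              ("test", test_ids))}


def _subset(ds: PhantomDataset, idx: np.ndarray) -> Batch:
    m = ds.meta.iloc[idx]
    return Batch(images=ds.images[idx],
                 y=m["diagnosis"].to_numpy(),
                 ages=m["age"].to_numpy(float),
                 strata=m["site"].to_numpy(),
                 subject_ids=m["subject_id"].to_numpy(),
                 visit_indices=m["visit_index"].to_numpy())


def make_batches(ds: PhantomDataset, batch_size: int, seed: int,
                 indices: np.ndarray | None = None) -> list[Batch]:
    """Stratified batches: subjects kept whole (co-batching within-subject
    visit pairs) and interleaved across (class, site) cells so every batch
    spans multiple classes and strata whenever the data does.
    """
    if batch_size < 8:
        raise ValidationError("batch_size must be >= 8")
    if indices is None:
        indices = np.arange(ds.n_scans)
    meta = ds.meta.iloc[indices]
    if len(meta) == 0:
        return []
    rng = np.random.default_rng(seed)
    if batch_size > len(meta):
        logger.warning("batch_size exceeds dataset; using one full batch")

    # group scan indices by subject, note each subject's (class, site) cell
    subjects = {}
    for pos, sid in zip(indices, meta["subject_id"]):
        subjects.setdefault(sid, []).append(pos)
    cells: dict[tuple, list] = {}
    for sid, scans in subjects.items():
        row = ds.meta.iloc[scans[0]]
        cells.setdefault((row["diagnosis"], row["site"]), []).append(sid)
    for lst in cells.values():
        rng.shuffle(lst)
    cell_keys = sorted(cells.keys())
    rng.shuffle(cell_keys)

    # round-robin over cells so consecutive subjects cycle through all cells
    order = []
    queues = {k: list(cells[k]) for k in cell_keys}
    while any(queues.values()):
        for k in cell_keys:
            if queues[k]:
                order.append(queues[k].pop())

    batches, current = [], []
    for sid in order:
        current += subjects[sid]
        if len(current) >= batch_size:
            batches.append(np.asarray(current[:]))
            current = []
    if current:
        # fold a short remainder into the last batch rather than emitting a
        # degenerate batch with too few samples for the pairwise terms
        if batches and len(current) < max(8, batch_size // 4):
            batches[-1] = np.concatenate([batches[-1], current])
        else:
            batches.append(np.asarray(current))
    return [_subset(ds, idx) for idx in batches]


# --------------------------------------------------------------------------
# One optimization step
# --------------------------------------------------------------------------

def _age_bands(ages: np.ndarray, n_bands: int) -> np.ndarray:
    """Within-batch age quantile bins, used as a second stratum axis."""
    qs = np.quantile(ages, np.linspace(0, 1, n_bands + 1)[1:-1])
    return np.searchsorted(qs, ages).astype(np.intp)

def compute_all_terms(model: NeuroFactNet, batch: Batch, w: LossWeights,
                      stats: al.ClassStats, rng: np.random.Generator,
                      sample: bool = True) -> dict[str, Tensor]:
    """Forward pass and every loss term of the composite objective."""
    lat = model.encode(batch.images, sample=sample, seed=rng)
    x = Tensor(batch.images.reshape(len(batch.y), -1))
    x_hat = model.decode(lat.z_a, lat.z_d)
    x_hat_a = model.decode_pathway(lat.z_a, "anatomy")
    x_hat_d = model.decode_pathway(lat.z_d, "disease")
    probs = model.classify(lat.z_d)
    age_pred = model.predict_age(lat.z_a)

    diff_a, diff_d = x - x_hat_a, x - x_hat_d
    kl_a, kl_d = ls.loss_kl_branches(lat)
    terms: dict[str, Tensor] = {
        "recon": ls.loss_recon(x, x_hat, w.sigma2),
        "rec_a": ls.sq_norm_rows(diff_a).mean(),
        "rec_d": ls.sq_norm_rows(diff_d).mean(),
        "kl": kl_a + kl_d,
        "kl_a": kl_a,
        "kl_d": kl_d,
        "additive": ls.loss_additive(x_hat, x_hat_a, x_hat_d),
        "decorr": ls.loss_decorr(x_hat_a, x_hat_d),
        "cls": ls.loss_cls(probs, batch.y),
        "age": ls.loss_age(age_pred, Tensor(batch.ages)),
        "smooth": ls.loss_smooth(lat.z_a, lat.z_d, batch.subject_ids,
                                 batch.ages, w.smooth_mode, w.gamma),
        "xcov": ls.loss_latent_xcov(lat.z_a, lat.z_d),
    }
    terms["task"] = ls.task_total(terms, w)

    # stratum axes for alignment: acquisition site, plus age bands (the
    # anatomy factor is itself a non-causal stratum for the disease code)
    age_bands = _age_bands(batch.ages, model.config.n_age_bands)
    terms["mmd"] = (al.loss_mmd_strata(lat.z_d, batch.strata)
                    + al.loss_mmd_strata(lat.z_d, age_bands)) \
        if w.lambda1 > 0 else Tensor(0.0)
    terms["cond"] = (al.loss_cond_align(lat.z_d, batch.y, batch.strata)
                     + al.loss_cond_align(lat.z_d, batch.y, age_bands)) \
        if w.lambda2 > 0 else Tensor(0.0)

    con = al.loss_supcon(lat.z_d, batch.y, w.tau)
    stab = al.loss_stability(lat.z_d, w.sigma_stab, rng)
    hard = al.loss_hard_contrastive(lat.z_d, batch.y, w.tau, w.hard_k)
    center = al.loss_center(lat.z_d, batch.y, stats)
    terms.update(con=con, stab=stab, hard=hard, center=center)
    terms["contrastive"] = al.contrastive_total(con, stab, hard, center, w)

    terms["inv"] = al.loss_invariance_batch(lat.z_d, batch.y, batch.strata,
                                            stats) \
        if w.lambda4 > 0 else Tensor(0.0)

    # within-batch counterfactual consistency: shift controls toward the
    # first disease class whose center is warm and that is present in batch
    terms["cf"] = Tensor(0.0)
    if w.lambda5 > 0:
        src = np.flatnonzero(batch.y == 0)
        for tgt_class in range(1, model.config.n_classes):
            tgt = np.flatnonzero(batch.y == tgt_class)
            if (len(src) > 0 and len(tgt) > 0 and stats.center_init[0]
                    and stats.center_init[tgt_class]):
                delta = stats.centers[tgt_class] - stats.centers[0]
                cf = model.counterfactual_decode(
                    lat.z_a.take_rows(src), lat.z_d.take_rows(src), delta)
                terms["cf"] = al.loss_counterfactual(
                    cf, batch.images[tgt].reshape(len(tgt), -1))
                break

    # separability penalties read the posterior means: the sampled codes'
    # reparameterization noise would attenuate the measured correlation and
    # leave residual nuisance signal in the means
    if w.w_sep_age > 0 or w.w_sep_cls > 0:
        terms["sep_age"] = ls.loss_nuisance_r2(lat.mu_d, batch.ages)
        terms["sep_cls"] = ls.loss_nuisance_r2(
            lat.mu_a, batch.y.astype(np.intp))
        terms["task"] = (terms["task"] + w.w_sep_age * terms["sep_age"]
                         + w.w_sep_cls * terms["sep_cls"])

    if model.domain_head is not None and w.reversal_strength > 0:
        terms["domain"] = al.domain_confusion_loss(
            model.domain_head, lat.z_d, batch.strata, w.reversal_strength)
        terms["task"] = terms["task"] + terms["domain"]

    terms["total"] = al.total_cdaa(terms, w)
    terms["_latent"] = lat
    return terms


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------

def train(ds: PhantomDataset, model_config: ModelConfig,
          loss_weights: LossWeights, optim_config: OptimConfig,
          seed: int = 0):
    """Train on the 70% subject split; returns (model, stats, history, split).

    The returned model carries the weights of the epoch with the lowest
    validation total loss. `history` is a tidy per-step table of every term.
    """
    ss = np.random.SeedSequence(seed)
    s_init, s_batch, s_reparam, s_split = ss.spawn(4)
    model = NeuroFactNet(model_config, seed=np.random.default_rng(s_init))
    stats = al.ClassStats(model_config.n_classes, model_config.n_strata,
                          model_config.d_d,
                          ema_decay=loss_weights.ema_decay,
                          shrink_alpha=loss_weights.shrink_alpha)
    split = subject_split(ds, seed=int(s_split.generate_state(1)[0] % 2**31))
    # center the age head on the training ages so the regression term starts
    # at the age variance rather than the squared mean
    train_ages = ds.meta["age"].to_numpy(float)[split["train"]]
    if len(train_ages):
        model.age_head.b.data[...] = train_ages.mean()
    opt = Adam(model.parameters(), lr=optim_config.learning_rate)
    reparam_rng = np.random.default_rng(s_reparam)
    batch_seeds = np.random.default_rng(s_batch).integers(
        0, 2**31, size=optim_config.epochs)

    rows = []
    best = (np.inf, model.get_state(), copy.deepcopy(stats))
    step = 0
    val_batch = _subset(ds, split["val"]) if len(split["val"]) else None
    for epoch in range(optim_config.epochs):
        # ramp the decoupling penalties in over the first epochs so the
        # supervised/reconstruction structure forms before being constrained
        ramp = 1.0 if optim_config.penalty_ramp_epochs <= 0 else \
            min(1.0, (epoch + 1) / optim_config.penalty_ramp_epochs)
        w_epoch = replace(loss_weights,
                          w_xcov=ramp * loss_weights.w_xcov,
                          w_sep_age=ramp * loss_weights.w_sep_age,
                          w_sep_cls=ramp * loss_weights.w_sep_cls)
        for batch in make_batches(ds, optim_config.batch_size,
                                  int(batch_seeds[epoch]),
                                  indices=split["train"]):
            terms = compute_all_terms(model, batch, w_epoch, stats,
                                      reparam_rng)
            total = terms["total"]
            if not np.isfinite(total.data):
                bad = [k for k, v in terms.items()
                       if isinstance(v, Tensor) and not
                       np.all(np.isfinite(v.data))]
                raise ArithmeticError(f"non-finite loss in terms {bad}")
            opt.zero_grad()
            total.backward()
            clip_grad_norm(model.parameters(), optim_config.clip_norm)
            opt.step()
            lat = terms.pop("_latent")
            al.update_centers(lat.z_d, batch.y, stats)
            al.update_gaussian_stats(lat.z_d, batch.y, batch.strata, stats)
            for name, val in terms.items():
                rows.append({"step": step, "epoch": epoch, "term": name,
                             "value": float(np.asarray(val.data))})
            step += 1
        if val_batch is not None:
            vterms = compute_all_terms(model, val_batch, loss_weights, stats,
                                       np.random.default_rng(0), sample=False)
            vtotal = float(vterms["total"].data)
            rows.append({"step": step, "epoch": epoch, "term": "val_total",
                         "value": vtotal})
            if vtotal < best[0]:
                # snapshot the running class statistics with the weights so
                # the restored checkpoint's centers match its encoder
                best = (vtotal, model.get_state(), copy.deepcopy(stats))
    if val_batch is not None and best[1] is not None:
        model.set_state(best[1])
        stats = best[2]
    history = pd.DataFrame(rows)
    return model, stats, history, split


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def _encode_means(model: NeuroFactNet, images: np.ndarray):
    lat = model.encode(images, sample=False)
    return lat.mu_a.data, lat.mu_d.data


def evaluate(model: NeuroFactNet, ds: PhantomDataset, idx: np.ndarray,
             stats: al.ClassStats | None = None, seed: int = 0,
             cf_target_class: int = 1) -> EvalReport:
    """All EvalReport metrics on the scans `idx` (posterior means only)."""
    batch = _subset(ds, idx)
    z_a, z_d = _encode_means(model, batch.images)
    rep = EvalReport(n_scans=len(idx))

    # age regression head
    pred_age = model.predict_age(z_a).data
    if np.std(pred_age) > 0 and np.std(batch.ages) > 0:
        rep.age_pearson_r = float(pearsonr(pred_age, batch.ages)[0])

    # classification head
    probs = model.classify(z_d).data
    y_hat = probs.argmax(axis=1)
    classes = np.unique(batch.y)
    if len(classes) >= 2:
        rep.class_accuracy = float(np.mean(y_hat == batch.y))
        rep.f1 = float(f1_score(batch.y, y_hat, average="macro"))
        try:
            if probs.shape[1] == 2:
                rep.auc = float(roc_auc_score(batch.y, probs[:, 1]))
            else:
                rep.auc = float(roc_auc_score(
                    batch.y, probs, multi_class="ovr", average="macro",
                    labels=np.arange(probs.shape[1])))
        except ValueError:
            pass
        disease_true = batch.y > 0
        disease_pred = y_hat > 0
        if disease_true.any() and (~disease_true).any():
            rep.sensitivity = float(disease_pred[disease_true].mean())
            rep.specificity = float((~disease_pred[~disease_true]).mean())

    # leakage and stratum probes: fit on one half, score on the other
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(idx))
    half = len(idx) // 2
    tr, te = perm[:half], perm[half:]
    if half >= 4:
        ridge = Ridge(alpha=1.0).fit(z_d[tr], batch.ages[tr])
        p = ridge.predict(z_d[te])
        if np.std(p) > 0 and np.std(batch.ages[te]) > 0:
            rep.leakage_age_from_zd = float(pearsonr(p, batch.ages[te])[0])
        if len(np.unique(batch.y[tr])) >= 2:
            probe = LogisticRegression(max_iter=1000).fit(z_a[tr],
                                                          batch.y[tr])
            rep.leakage_class_from_za = float(balanced_accuracy_score(
                batch.y[te], probe.predict(z_a[te])))
        if len(np.unique(batch.strata[tr])) >= 2:
            sprobe = LogisticRegression(max_iter=1000).fit(z_d[tr],
                                                           batch.strata[tr])
            rep.stratum_probe_accuracy = float(balanced_accuracy_score(
                batch.strata[te], sprobe.predict(z_d[te])))

    # site MMD^2 on z_d with the median-heuristic bandwidth
    sites = np.unique(batch.strata)
    if len(sites) >= 2:
        h = al.median_bandwidth(z_d)
        vals = []
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                a, b = z_d[batch.strata == sites[i]], \
                    z_d[batch.strata == sites[j]]
                if len(a) >= 2 and len(b) >= 2:
                    vals.append(float(al.mmd2(a, b, h,
                                              unbiased=True).data))
        if vals:
            rep.site_mmd2 = float(np.mean(vals))

    # counterfactual success (control -> target disease class)
    if (stats is not None and cf_target_class in classes and 0 in classes
            and stats.center_init[0] and stats.center_init[cf_target_class]):
        rep.counterfactual_success_rate = run_counterfactual_eval(
            model, ds, idx, stats, 0, cf_target_class)

    # temporal displacement between adjacent visits
    disp = []
    for sid in np.unique(batch.subject_ids):
        rows = np.flatnonzero(batch.subject_ids == sid)
        rows = rows[np.argsort(batch.ages[rows])]
        for a, b in zip(rows[:-1], rows[1:]):
            disp.append(np.sum((z_d[b] - z_d[a]) ** 2)
                        + np.sum((z_a[b] - z_a[a]) ** 2))
    if disp:
        rep.mean_adjacent_displacement = float(np.mean(disp))
    return rep


def run_counterfactual_eval(model: NeuroFactNet, ds: PhantomDataset,
                            idx: np.ndarray, stats: al.ClassStats,
                            source_class: int, target_class: int) -> float:
    """Fraction of source-class scans whose delta-shifted decoding lands
    closer to the target-class mean image than to the source-class mean.

    Reference mean images are computed over the full cohort within the
    subject's own site and age tertile (falling back to the plain class mean
    for thin cells), so the comparison isolates the disease shift instead of
    incidental age/site composition differences between the class cohorts.
    """
    batch = _subset(ds, idx)
    if source_class not in batch.y or target_class not in batch.y:
        raise ValidationError("source or target class missing from split")
    if not (stats.center_init[source_class]
            and stats.center_init[target_class]):
        raise ValidationError("class centers are not initialized")
    z_a, z_d = _encode_means(model, batch.images)
    delta = stats.centers[target_class] - stats.centers[source_class]
    src = np.flatnonzero(batch.y == source_class)
    cf = model.counterfactual_decode(z_a[src], z_d[src], delta).data

    imgs = ds.images.reshape(ds.n_scans, -1)
    y_all = ds.meta["diagnosis"].to_numpy()
    site_all = ds.meta["site"].to_numpy()
    age_all = ds.meta["age"].to_numpy(float)
    qs = np.quantile(age_all, [1 / 3, 2 / 3])
    band_all = np.searchsorted(qs, age_all)

    def reference(k, site, band):
        sel = (y_all == k) & (site_all == site) & (band_all == band)
        if sel.sum() < 5:
            sel = y_all == k
        return imgs[sel].mean(axis=0)

    wins = []
    for row, i in zip(cf, src):
        site = batch.strata[i]
        band = int(np.searchsorted(qs, batch.ages[i]))
        m_tgt = reference(target_class, site, band)
        m_src = reference(source_class, site, band)
        wins.append(np.sum((row - m_tgt) ** 2) < np.sum((row - m_src) ** 2))
    return float(np.mean(wins))
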