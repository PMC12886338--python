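"""Synthetic longitudinal brain-phantom cohorts with known generative factors.

Each scan is an additive composition

    x = T + a(t) * A + d(t) * D_y + S_s + noise,

where ``T`` is a fixed anatomical template, ``A`` a spatial aging pattern
scaled by the subject's age score ``a(t)``, ``D_y`` a class-specific disease
pattern scaled by a positive, non-decreasing severity trajectory ``d(t)``,
``S_s`` a per-site acquisition pattern, and the noise is i.i.d. Gaussian per
pixel. Age scores and severities evolve smoothly along each subject's visits
via Gaussian-process residuals, and a class/age confound dial couples
diagnosis to age through a Gaussian copula. All spatial patterns are smooth
random Gaussian-bump fields, so the ground truth behind every downstream claim
(disentanglement, alignment, counterfactuals) is known exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.special import ndtr  # standard normal CDF
from scipy.stats import pearsonr

from .errors import FormatError, ValidationError

META_COLUMNS = ["subject_id", "visit_index", "age", "diagnosis", "site"]

# amplitude (intensity units) of the aging pattern per unit age score; the
# reference scale against which disease/site effect sizes are expressed
AGE_PATTERN_AMPLITUDE = 1.0


@dataclass
class PhantomConfig:
    """Generative settings for a synthetic cohort.

    Defaults define the "standard phantom": 300 subjects, 3 diagnostic classes
    (class 0 = control), 2 acquisition sites, 16x16 images, 1-4 visits per
    subject over ages 55-85.
    """

    n_subjects: int = 300
    image_size: int = 16
    n_classes: int = 3
    n_strata: int = 2              # number of acquisition sites
    visits_min: int = 1
    visits_max: int = 4
    age_lo: float = 55.0
    age_hi: float = 85.0
    gp_lengthscale: float = 8.0    # years
    gp_variance: float = 0.1
    disease_effect_size: float = 1.0
    site_effect_size: float = 0.5
    noise_sd: float = 0.1
    age_disease_confound: float = 0.0
    sex_axis: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.n_strata < 2:
            raise ValidationError("n_strata must be >= 2")
        if self.image_size < 8:
            raise ValidationError("image_size must be >= 8")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 <= self.age_disease_confound < 1.0):
            raise ValidationError("age_disease_confound must be in [0, 1)")
        if self.visits_min < 1 or self.visits_max < self.visits_min:
            raise ValidationError("visit range is empty")
        if self.age_hi <= self.age_lo:
            raise ValidationError("age_range is empty")
        if self.gp_lengthscale <= 0 or self.gp_variance < 0:
            raise ValidationError("invalid GP hyperparameters")


@dataclass
class PhantomDataset:
    """Images, observable metadata, and the hidden generative truth."""

    images: np.ndarray          # (n_scans, H, W)
    meta: pd.DataFrame          # META_COLUMNS (+ sex)
    truth: dict = field(default_factory=dict)
    config: PhantomConfig | None = None

    def __post_init__(self):
        if self.images.shape[0] != len(self.meta):
            raise ValidationError("images and meta row counts differ")
        for sid, grp in self.meta.groupby("subject_id"):
            ages = grp.sort_values("visit_index")["age"].to_numpy()
            if len(ages) < 1:
                raise ValidationError(f"subject {sid} has no visits")
            if np.any(np.diff(ages) <= 0):
                raise ValidationError(
                    f"ages must strictly increase within subject {sid}")
            if grp["diagnosis"].nunique() != 1:
                raise ValidationError(
                    f"diagnosis not constant within subject {sid}")

    @property
    def n_scans(self) -> int:
        return self.images.shape[0]

    def equals(self, other: "PhantomDataset") -> bool:
        if not np.array_equal(self.images, other.images):
            return False
        if not self.meta.reset_index(drop=True).equals(
                other.meta.reset_index(drop=True)):
            return False
        if set(self.truth) != set(other.truth):
            return False
        return all(np.array_equal(self.truth[k], other.truth[k])
                   for k in self.truth)


# --------------------------------------------------------------------------
# Gaussian-process trajectories
# --------------------------------------------------------------------------

def sample_gp_trajectory(times, lengthscale: float, variance: float,
                         seed=None) -> np.ndarray:
    """One draw from a zero-mean GP with squared-exponential kernel.

    `seed` may be an int or a numpy Generator.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a non-empty 1-D vector")
    if not np.all(np.isfinite(t)):
        raise ValidationError("times must be finite")
    if np.any(np.diff(t) < 0):
        raise ValidationError("times must be sorted ascending")
    if lengthscale <= 0:
        raise ValidationError("lengthscale must be > 0")
    if variance < 0:
        raise ValidationError("variance must be >= 0")
    if variance == 0:
        return np.zeros_like(t)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    d2 = (t[:, None] - t[None, :]) ** 2
    cov = variance * np.exp(-d2 / (2.0 * lengthscale ** 2))
    cov[np.diag_indices_from(cov)] += 1e-10 * max(variance, 1.0)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(t.size)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def render_scan(template, age_pattern, disease_pattern, site_pattern,
                age_score: float, disease_severity: float,
                site_indicator: float, noise_sd: float,
                seed=None) -> np.ndarray:
    """Compose one scan additively from its factors plus pixel noise."""
    arrs = [np.asarray(a, dtype=float)
            for a in (template, age_pattern, disease_pattern, site_pattern)]
    if len({a.shape for a in arrs}) != 1:
        raise ValidationError("all patterns must share the image shape")
    template, age_pattern, disease_pattern, site_pattern = arrs
    img = (template
           + age_score * age_pattern
           + disease_severity * disease_pattern
           + site_indicator * site_pattern)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


def _bump_field(shape, rng: np.random.Generator, n_bumps: int = 4,
                width_frac=(0.15, 0.35)) -> np.ndarray:
    """Smooth random field: a sum of signed Gaussian bumps, unit RMS."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.zeros(shape, dtype=float)
    for _ in range(n_bumps):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        s = rng.uniform(*width_frac) * h
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
        out += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s ** 2))
    rms = np.sqrt(np.mean(out ** 2))
    return out / max(rms, 1e-12)


def _make_patterns(cfg: PhantomConfig, rng: np.random.Generator) -> dict:
    """Template, age, per-class disease and per-site patterns.

    Disease patterns are resampled until their spatial correlation with the
    age pattern is below 0.3, keeping factor recovery identifiable.
    """
    shape = (cfg.image_size, cfg.image_size)
    template = 1.0 + 0.5 * _bump_field(shape, rng, n_bumps=6)
    age_pattern = AGE_PATTERN_AMPLITUDE * _bump_field(shape, rng)
    disease = np.zeros((cfg.n_classes, *shape))
    flat_age = age_pattern.ravel()
    for k in range(1, cfg.n_classes):
        for _ in range(200):
            cand = _bump_field(shape, rng, n_bumps=3)
            ok = abs(pearsonr(cand.ravel(), flat_age)[0]) < 0.3
            ok = ok and all(
                abs(pearsonr(cand.ravel(), disease[j].ravel())[0]) < 0.3
                for j in range(1, k))
            if ok:
                disease[k] = cfg.disease_effect_size * cand
                break
        else:  # pragma: no cover - 200 draws essentially always suffice
            raise RuntimeError("could not decorrelate disease patterns")
    site = np.stack([cfg.site_effect_size * _bump_field(shape, rng)
                     for _ in range(cfg.n_strata)])
    sex = np.stack([0.5 * cfg.site_effect_size * _bump_field(shape, rng)
                    for _ in range(2)]) if cfg.sex_axis else None
    out = {"template": template, "age_pattern": age_pattern,
           "disease_patterns": disease, "site_patterns": site}
    if sex is not None:
        out["sex_patterns"] = sex
    return out


# --------------------------------------------------------------------------
# Cohort sampling
# --------------------------------------------------------------------------

def sample_cohort(cfg: PhantomConfig) -> PhantomDataset:
    """Draw a full longitudinal cohort; deterministic given `cfg.seed`."""
    ss = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ["patterns", "subjects", "trajectories", "noise"], ss.spawn(4))}

    patterns = _make_patterns(cfg, streams["patterns"])
    rng = streams["subjects"]
    traj_rng = streams["trajectories"]
    noise_rng = streams["noise"]

    rho = cfg.age_disease_confound
    n = cfg.n_subjects
    g_age = rng.standard_normal(n)
    g_cls = rho * g_age + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    n_visits = rng.integers(cfg.visits_min, cfg.visits_max + 1, size=n)
    sites = rng.integers(0, cfg.n_strata, size=n)
    sexes = rng.integers(0, 2, size=n) if cfg.sex_axis else None

    # diagnosis via the copula: large g_cls -> disease, so rho > 0 makes
    # older subjects more likely to carry a disease label
    p_control = 1.0 / cfg.n_classes
    is_disease = ndtr(g_cls) > p_control
    disease_class = rng.integers(1, cfg.n_classes, size=n)
    diagnosis = np.where(is_disease, disease_class, 0)

    # first-visit age via the same copula margin; later visits ~1-1.5y apart
    span_needed = 1.5 * (cfg.visits_max - 1)
    base_age = cfg.age_lo + (cfg.age_hi - cfg.age_lo - span_needed) \
        * ndtr(g_age)

    rows, ages_all, subj_slices = [], [], []
    start = 0
    for i in range(n):
        gaps = rng.uniform(0.8, 1.5, size=n_visits[i] - 1)
        ages = base_age[i] + np.concatenate([[0.0], np.cumsum(gaps)])
        for j, a in enumerate(ages):
            row = {"subject_id": i, "visit_index": j, "age": a,
                   "diagnosis": int(diagnosis[i]), "site": int(sites[i])}
            if cfg.sex_axis:
                row["sex"] = int(sexes[i])
            rows.append(row)
        ages_all.append(ages)
        subj_slices.append(slice(start, start + n_visits[i]))
        start += n_visits[i]

    meta = pd.DataFrame(rows)
    all_ages = meta["age"].to_numpy()
    mu_age, sd_age = all_ages.mean(), max(all_ages.std(), 1e-9)

    n_scans = len(meta)
    shape = (cfg.image_size, cfg.image_size)
    images = np.zeros((n_scans, *shape))
    age_score = np.zeros(n_scans)
    severity = np.zeros(n_scans)

    for i in range(n):
        sl = subj_slices[i]
        ages = ages_all[i]
        age_score[sl] = (ages - mu_age) / sd_age + sample_gp_trajectory(
            ages, cfg.gp_lengthscale, cfg.gp_variance, traj_rng)
        if diagnosis[i] > 0:
            base = traj_rng.normal(0.5, 0.5)
            slope = traj_rng.uniform(0.05, 0.2)
            raw = base + slope * (ages - ages[0]) + sample_gp_trajectory(
                ages, cfg.gp_lengthscale, cfg.gp_variance, traj_rng)
            sev = np.logaddexp(0.0, raw)           # softplus -> positive
            severity[sl] = np.maximum.accumulate(sev)  # non-decreasing

    for idx in range(n_scans):
        i = int(meta["subject_id"].iloc[idx])
        extra = 0.0
        if cfg.sex_axis:
            extra = patterns["sex_patterns"][int(meta["sex"].iloc[idx])]
        images[idx] = render_scan(
            patterns["template"] + extra, patterns["age_pattern"],
            patterns["disease_patterns"][int(meta["diagnosis"].iloc[idx])],
            patterns["site_patterns"][int(meta["site"].iloc[idx])],
            age_score[idx], severity[idx], 1.0, cfg.noise_sd, noise_rng)

    truth = dict(patterns)
    truth["age_score"] = age_score
    truth["disease_severity"] = severity
    return PhantomDataset(images=images, meta=meta, truth=truth, config=cfg)


# --------------------------------------------------------------------------
# I/O: HDF5 tensor archive + sibling CSV metadata
# --------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.csv") if path.suffix != ".h5" \
        else path.with_suffix(".meta.csv")


def write_dataset(ds: PhantomDataset, path) -> Path:
    """Write images/truth to HDF5 and metadata to a sibling CSV."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=ds.images)
        grp = f.create_group("truth")
        for key, val in ds.truth.items():
            grp.create_dataset(key, data=np.asarray(val))
        if ds.config is not None:
            f.attrs["config"] = json.dumps(asdict(ds.config))
    # %.17g round-trips float64 exactly through text
    ds.meta.to_csv(_meta_path(path), index=False, float_format="%.17g")
    return path


def read_dataset(path) -> PhantomDataset:
    path = Path(path)
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise FormatError(f"missing metadata table {meta_path.name}")
    if not path.exists():
        raise FormatError(f"missing archive {path.name}")
    with h5py.File(path, "r") as f:
        if "images" not in f:
            raise FormatError("archive member 'images' is missing")
        if "truth" not in f:
            raise FormatError("archive member 'truth' is missing")
        images = f["images"][...]
        truth = {k: f["truth"][k][...] for k in f["truth"]}
        cfg = None
        if "config" in f.attrs:
            cfg = PhantomConfig(**json.loads(f.attrs["config"]))
    meta = pd.read_csv(meta_path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata table lacks columns {missing}")
    return PhantomDataset(images=images, meta=meta, truth=truth, config=cfg)
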