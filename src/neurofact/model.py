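"""NeuroFact-Net: a dual-pathway variational encoder-decoder.

A shared encoder trunk maps an image to two Gaussian posteriors — an anatomy
(aging) code ``z_a`` and a disease code ``z_d`` — sampled with the
reparameterization trick. A shared decoder reconstructs the image from the
concatenated codes; silencing one branch (feeding the zero vector) yields
pathway-isolated reconstructions. An auxiliary classifier reads only ``z_d``
and an age regressor reads only ``z_a``, so pathway supervision is structural:
the age head cannot see disease information and vice versa. Counterfactual
images are decoded after shifting ``z_d`` by a class-center difference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .errors import FormatError, ValidationError
from .nn import MLP, Linear

LOGVAR_CLAMP = 6.0  # soft clamp half-width for posterior log-variances


@dataclass
class ModelConfig:
    d_a: int = 8
    d_d: int = 8
    image_size: int = 16
    n_classes: int = 3
    enc_hidden: tuple = (128,)
    dec_hidden: tuple = (128,)
    activation: str = "tanh"
    decoder_bias: bool = True
    domain_head: bool = False       # gradient-reversal site classifier
    n_strata: int = 2
    n_age_bands: int = 4            # age-band stratum axis for alignment
    split_trunk: bool = False       # optionally bifurcate at the input

    def __post_init__(self):
        if self.d_a < 1 or self.d_d < 1:
            raise ValidationError("latent dims must be >= 1")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        self.enc_hidden = tuple(self.enc_hidden)
        self.dec_hidden = tuple(self.dec_hidden)

    @property
    def n_pixels(self) -> int:
        return self.image_size ** 2


@dataclass
class LatentCode:
    """Posterior parameters and reparameterized samples for both pathways."""

    mu_a: Tensor
    logvar_a: Tensor
    mu_d: Tensor
    logvar_d: Tensor
    z_a: Tensor
    z_d: Tensor
    eps_a: np.ndarray
    eps_d: np.ndarray


def softmax(logits: Tensor) -> Tensor:
    shift = logits.data.max(axis=-1, keepdims=True)  # detached stabilizer
    e = (logits - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


class NeuroFactNet:
    """Encoder/decoder plus classification, age, and optional domain heads."""

    def __init__(self, config: ModelConfig, seed=0):
        self.config = config
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        c = config
        trunk_out = c.enc_hidden[-1] if c.enc_hidden else c.n_pixels
        def make_trunk():
            return MLP(c.n_pixels, c.enc_hidden[:-1], trunk_out, rng,
                       c.activation) if c.enc_hidden else None
        self.enc_trunk = make_trunk()
        # with split_trunk the encoder bifurcates at the input: each branch
        # owns its feature stack, so disease-side features are shaped only
        # by disease-side gradients (and vice versa)
        self.enc_trunk_d = make_trunk() if c.split_trunk else None
        self.head_mu_a = Linear(trunk_out, c.d_a, rng)
        self.head_lv_a = Linear(trunk_out, c.d_a, rng)
        self.head_mu_d = Linear(trunk_out, c.d_d, rng)
        self.head_lv_d = Linear(trunk_out, c.d_d, rng)
        # start posteriors tight (sigma ~ e^-2) so early supervision is not
        # drowned in reparameterization noise
        self.head_lv_a.b.data[...] = -4.0
        self.head_lv_d.b.data[...] = -4.0
        self.decoder = MLP(c.d_a + c.d_d, c.dec_hidden, c.n_pixels, rng,
                           c.activation, bias=c.decoder_bias)
        self.classifier = Linear(c.d_d, c.n_classes, rng)
        self.age_head = Linear(c.d_a, 1, rng)
        self.domain_head = Linear(c.d_d, c.n_strata, rng) \
            if c.domain_head else None

    # ------------------------------------------------------------------ api
    def parameters(self) -> list[Tensor]:
        mods = [self.head_mu_a, self.head_lv_a, self.head_mu_d,
                self.head_lv_d, self.decoder, self.classifier, self.age_head]
        if self.enc_trunk is not None:
            mods.insert(0, self.enc_trunk)
        if self.enc_trunk_d is not None:
            mods.insert(1, self.enc_trunk_d)
        if self.domain_head is not None:
            mods.append(self.domain_head)
        return [p for m in mods for p in m.parameters()]

    def named_parameters(self) -> dict[str, Tensor]:
        names = {"head_mu_a": self.head_mu_a, "head_lv_a": self.head_lv_a,
                 "head_mu_d": self.head_mu_d, "head_lv_d": self.head_lv_d,
                 "decoder": self.decoder, "classifier": self.classifier,
                 "age_head": self.age_head}
        if self.enc_trunk is not None:
            names["enc_trunk"] = self.enc_trunk
        if self.enc_trunk_d is not None:
            names["enc_trunk_d"] = self.enc_trunk_d
        if self.domain_head is not None:
            names["domain_head"] = self.domain_head
        out = {}
        for name, mod in names.items():
            for i, p in enumerate(mod.parameters()):
                out[f"{name}.{i}"] = p
        return out

    def _flatten(self, x) -> Tensor:
        x = as_tensor(x)
        if x.ndim == 3:
            n, h, w = x.shape
            if h * w != self.config.n_pixels:
                raise ValidationError(
                    f"expected {self.config.image_size}^2 pixels, got {h}x{w}")
            x = x.reshape(n, h * w)
        elif x.ndim != 2 or x.shape[1] != self.config.n_pixels:
            raise ValidationError("input does not match configured image size")
        return x

    def encode(self, x, sample: bool = True, seed=None) -> LatentCode:
        """Posterior parameters and (optionally) sampled codes for a batch."""
        x = self._flatten(x)

        def activate(v):
            if not self.config.enc_hidden:
                return v
            return v.tanh() if self.config.activation == "tanh" else v.relu()

        h_a = activate(self.enc_trunk(x)) if self.enc_trunk is not None else x
        h_d = activate(self.enc_trunk_d(x)) \
            if self.enc_trunk_d is not None else h_a
        mu_a, mu_d = self.head_mu_a(h_a), self.head_mu_d(h_d)
        # soft-clamp log-variances for numerical stability
        lv_a = self.head_lv_a(h_a) * (1.0 / LOGVAR_CLAMP)
        lv_a = lv_a.tanh() * LOGVAR_CLAMP
        lv_d = self.head_lv_d(h_d) * (1.0 / LOGVAR_CLAMP)
        lv_d = lv_d.tanh() * LOGVAR_CLAMP
        n = x.shape[0]
        if sample:
            rng = seed if isinstance(seed, np.random.Generator) \
                else np.random.default_rng(seed)
            eps_a = rng.standard_normal((n, self.config.d_a))
            eps_d = rng.standard_normal((n, self.config.d_d))
        else:
            eps_a = np.zeros((n, self.config.d_a))
            eps_d = np.zeros((n, self.config.d_d))
        z_a = mu_a + (lv_a * 0.5).exp() * eps_a
        z_d = mu_d + (lv_d * 0.5).exp() * eps_d
        return LatentCode(mu_a, lv_a, mu_d, lv_d, z_a, z_d, eps_a, eps_d)

    def decode(self, z_a, z_d) -> Tensor:
        z_a, z_d = as_tensor(z_a), as_tensor(z_d)
        if z_a.shape[-1] != self.config.d_a or z_d.shape[-1] != self.config.d_d:
            raise ValidationError("latent dims do not match config")
        return self.decoder(concat([z_a, z_d], axis=1))

    def decode_pathway(self, z, pathway: str) -> Tensor:
        z = as_tensor(z)
        n = z.shape[0]
        if pathway == "anatomy":
            if z.shape[-1] != self.config.d_a:
                raise ValidationError("z does not have anatomy dim")
            return self.decode(z, np.zeros((n, self.config.d_d)))
        if pathway == "disease":
            if z.shape[-1] != self.config.d_d:
                raise ValidationError("z does not have disease dim")
            return self.decode(np.zeros((n, self.config.d_a)), z)
        raise ValidationError(f"unknown pathway {pathway!r}")

    def classify(self, z_d) -> Tensor:
        z_d = as_tensor(z_d)
        if z_d.shape[-1] != self.config.d_d:
            raise ValidationError("z_d dim does not match config")
        return softmax(self.classifier(z_d))

    def predict_age(self, z_a) -> Tensor:
        z_a = as_tensor(z_a)
        if z_a.shape[-1] != self.config.d_a:
            raise ValidationError("z_a dim does not match config")
        return self.age_head(z_a).reshape(-1)

    def counterfactual_decode(self, z_a, z_d, delta) -> Tensor:
        z_d = as_tensor(z_d)
        delta = np.asarray(delta, dtype=float)
        if delta.shape[-1] != self.config.d_d:
            raise ValidationError("delta dim does not match d_d")
        return self.decode(z_a, z_d + delta)

    # ------------------------------------------------------------ state I/O
    def get_state(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for k, p in params.items():
            if k not in state:
                raise FormatError(f"checkpoint lacks parameter {k}")
            p.data[...] = state[k]


def save_checkpoint(path, model: NeuroFactNet, loss_weights=None,
                    class_stats=None, step: int = 0, seed: int = 0) -> Path:
    """Single HDF5 archive: weights, configs, running class stats, step, seed."""
    from .alignment import ClassStats  # local import avoids a cycle

    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("weights")
        for k, v in model.get_state().items():
            g.create_dataset(k, data=v)
        f.attrs["model_config"] = json.dumps(asdict(model.config))
        f.attrs["step"] = step
        f.attrs["seed"] = seed
        if loss_weights is not None:
            f.attrs["loss_weights"] = json.dumps(asdict(loss_weights))
        if class_stats is not None:
            class_stats.to_h5(f.create_group("class_stats"))
    return path


def load_checkpoint(path):
    """Returns (model, loss_weights | None, class_stats | None, step, seed)."""
    from .alignment import ClassStats
    from .losses import LossWeights

    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing checkpoint {path}")
    with h5py.File(path, "r") as f:
        if "weights" not in f:
            raise FormatError("checkpoint member 'weights' is missing")
        cfg = ModelConfig(**json.loads(f.attrs["model_config"]))
        model = NeuroFactNet(cfg, seed=0)
        model.set_state({k: f["weights"][k][...] for k in f["weights"]})
        weights = None
        if "loss_weights" in f.attrs:
            weights = LossWeights(**json.loads(f.attrs["loss_weights"]))
        stats = ClassStats.from_h5(f["class_stats"]) \
            if "class_stats" in f else None
        step = int(f.attrs["step"])
        seed = int(f.attrs["seed"])
    return model, weights, stats, step, seed
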