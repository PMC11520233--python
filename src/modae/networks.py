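"""The five trainable networks and the latent partition.

Encoder E, decoder D, Wasserstein critic C, survival head A and drug head B
are SELU multilayer perceptrons built on the autodiff engine.  Hidden layers
use SELU activations with dropout after every layer except output layers and
the encoder bottleneck; output layers are linear.  Weights are initialized
with the self-normalizing-network convention (normal, variance 1/fan-in).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor, astensor, concatenate, matmul, mul, selu

__all__ = [
    "LatentPartition",
    "NetworkConfig",
    "MLP",
    "ModuleSet",
    "latent_mask",
    "extract_shared",
    "forward_autoencode",
    "predict_risk",
    "predict_drugs",
    "default_partition",
    "build_modules",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class LatentPartition:
    """Disjoint index sets over the latent vector: shared U, patient-private V,
    cell-line-private W (0-based indices)."""

    p: int
    U: tuple
    V: tuple
    W: tuple

    def __post_init__(self):
        u, v, w = set(self.U), set(self.V), set(self.W)
        if len(u) + len(v) + len(w) != len(self.U) + len(self.V) + len(self.W):
            raise ValueError("partition index sets contain duplicates")
        if (u & v) or (u & w) or (v & w):
            raise ValueError("U, V, W must be pairwise disjoint")
        if u | v | w != set(range(self.p)):
            raise ValueError("U ∪ V ∪ W must cover exactly {0..p-1}")
        if not u:
            raise ValueError("shared set U must be non-empty")

    @property
    def q(self) -> int:
        return len(self.U)

    def mask_for(self, s: np.ndarray) -> np.ndarray:
        """Multiplicative (n, p) mask for domain indicators ``s``."""
        s = np.atleast_1d(np.asarray(s))
        n = s.shape[0]
        mask = np.zeros((n, self.p))
        mask[:, list(self.U)] = 1.0
        if self.V:
            mask[:, list(self.V)] = (s == 0)[:, None]
        if self.W:
            mask[:, list(self.W)] = (s == 1)[:, None]
        return mask


def default_partition(p: int, q: int | None = None) -> LatentPartition:
    """q = ceil(p/2) shared, remainder split between V (first) and W."""
    if q is None:
        q = -(-p // 2)
    if not (1 <= q <= p):
        raise ValueError("need 1 <= q <= p")
    rest = p - q
    n_w = rest // 2
    n_v = rest - n_w
    return LatentPartition(
        p=p,
        U=tuple(range(q)),
        V=tuple(range(q, q + n_v)),
        W=tuple(range(q + n_v, p)),
    )


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    input_dim: int
    latent_dim: int = 16
    shared_dim: int | None = None  # default: ceil(latent_dim / 2)
    encoder_hidden: tuple = (256, 256)
    decoder_hidden: tuple = (256, 256)
    critic_hidden: tuple = (64, 64)
    survival_hidden: tuple = (64, 64)
    drug_hidden: tuple = (64, 64)
    dropout: float = 0.1
    l2: float = 1e-4
    n_drugs: int = 0
    n_covariates: int = 0

    def __post_init__(self):
        q = self.shared_dim
        if q is not None and not (1 <= q <= self.latent_dim):
            raise ValueError("shared_dim must satisfy 1 <= q <= latent_dim")
        for widths in (
            self.encoder_hidden,
            self.decoder_hidden,
            self.critic_hidden,
            self.survival_hidden,
            self.drug_hidden,
        ):
            if any(w < 1 for w in widths):
                raise ValueError("all hidden widths must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


class MLP:
    """SELU multilayer perceptron with linear output.

    Dropout (alpha-preserving plain inverted dropout) follows every hidden
    layer; the output layer is linear with no dropout.
    """

    def __init__(self, in_dim, hidden, out_dim, dropout, rng: np.random.Generator):
        dims = [in_dim, *hidden, out_dim]
        self.dropout = float(dropout)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for a, b in zip(dims[:-1], dims[1:]):
            w = rng.standard_normal((a, b)) / np.sqrt(a)
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(b), requires_grad=True))

    @property
    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def __call__(self, x, train: bool = False, rng: np.random.Generator | None = None):
        h = astensor(x)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = matmul(h, w) + b
            if i != last:
                h = selu(h)
                if train and self.dropout > 0:
                    if rng is None:
                        raise ValueError("training forward pass needs an rng for dropout")
                    keep = 1.0 - self.dropout
                    mask = rng.random(h.shape) < keep
                    h = mul(h, Tensor(mask / keep))
        return h


@dataclasses.dataclass
class ModuleSet:
    encoder: MLP
    decoder: MLP
    critic: MLP
    survival: MLP
    drug: MLP
    partition: LatentPartition
    config: NetworkConfig

    def named_modules(self):
        return {
            "encoder": self.encoder,
            "decoder": self.decoder,
            "critic": self.critic,
            "survival": self.survival,
            "drug": self.drug,
        }

    def parameters(self, exclude: tuple = ()) -> list[Tensor]:
        out = []
        for name, mod in self.named_modules().items():
            if name not in exclude:
                out.extend(mod.parameters)
        return out


def build_modules(config: NetworkConfig, seed: int = 0) -> ModuleSet:
    rng = np.random.default_rng(seed)
    p = config.latent_dim
    part = default_partition(p, config.shared_dim)
    q = part.q
    enc = MLP(config.input_dim, config.encoder_hidden, p, config.dropout, rng)
    dec = MLP(p, config.decoder_hidden, config.input_dim, config.dropout, rng)
    critic = MLP(q, config.critic_hidden, 1, config.dropout, rng)
    surv = MLP(q + config.n_covariates, config.survival_hidden, 1, config.dropout, rng)
    drug = MLP(q, config.drug_hidden, max(config.n_drugs, 1), config.dropout, rng)
    return ModuleSet(enc, dec, critic, surv, drug, part, config)


# -- latent-space operations --------------------------------------------


def latent_mask(z, s, partition: LatentPartition):
    """Zero the private coordinates that do not belong to each sample's domain.

    Shared indices U always pass; V passes only for patients (s = 0); W only
    for cell-lines (s = 1).  Accepts numpy arrays or Tensors, vectors or
    batches.
    """
    is_tensor = isinstance(z, Tensor)
    zt = astensor(z)
    single = zt.ndim == 1
    zb = zt.reshape(1, -1) if single else zt
    if zb.shape[1] != partition.p:
        raise ValueError(
            f"latent vector has length {zb.shape[1]}, partition expects {partition.p}"
        )
    mask = partition.mask_for(s)
    if mask.shape[0] != zb.shape[0]:
        raise ValueError("domain indicator length does not match batch size")
    out = mul(zb, Tensor(mask))
    if single:
        out = out.reshape(partition.p)
    return out if is_tensor else out.data


def extract_shared(z, partition: LatentPartition):
    """Subvector of z at the shared indices U (in U's order)."""
    is_tensor = isinstance(z, Tensor)
    zt = astensor(z)
    idx = list(partition.U)
    out = zt[idx] if zt.ndim == 1 else zt[:, idx]
    return out if is_tensor else out.data


def forward_autoencode(
    x,
    s,
    modules: ModuleSet,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Returns (z, z_shared, x_hat): encode, mask by domain, decode."""
    xt = astensor(x)
    if xt.shape[-1] != modules.config.input_dim:
        raise ValueError(
            f"input has {xt.shape[-1]} features, encoder expects {modules.config.input_dim}"
        )
    z = modules.encoder(xt, train=train, rng=rng)
    z_masked = latent_mask(z, s, modules.partition)
    x_hat = modules.decoder(z_masked, train=train, rng=rng)
    z_shared = extract_shared(z, modules.partition)
    return z, z_shared, x_hat


def predict_risk(
    x,
    covariates,
    modules: ModuleSet,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Log-risk g(x) = A([shared(E(x)); covariates]); hazard ∝ exp(g)."""
    xt = astensor(x)
    z = modules.encoder(xt, train=train, rng=rng)
    zs = extract_shared(z, modules.partition)
    if covariates is not None and np.size(getattr(covariates, "data", covariates)):
        k = astensor(covariates)
        feats = concatenate([zs, k], axis=1)
    else:
        feats = zs
    expected = modules.partition.q + modules.config.n_covariates
    if feats.shape[1] != expected:
        raise ValueError(
            f"survival head expects {expected} inputs, got {feats.shape[1]}"
        )
    g = modules.survival(feats, train=train, rng=rng)
    return g.reshape(g.shape[0])


def predict_drugs(
    x,
    modules: ModuleSet,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Predicted sensitivity for every drug (linear outputs, unclipped)."""
    xt = astensor(x)
    z = modules.encoder(xt, train=train, rng=rng)
    zs = extract_shared(z, modules.partition)
    return modules.drug(zs, train=train, rng=rng)


# -- checkpoints ---------------------------------------------------------


def save_checkpoint(modules: ModuleSet, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name, mod in modules.named_modules().items():
        for i, (w, b) in enumerate(zip(mod.weights, mod.biases)):
            arrays[f"{name}.w{i}"] = w.data
            arrays[f"{name}.b{i}"] = b.data
    np.savez(out / "weights.npz", **arrays)
    meta = {
        "network_config": dataclasses.asdict(modules.config),
        "partition": {
            "p": modules.partition.p,
            "U": list(modules.partition.U),
            "V": list(modules.partition.V),
            "W": list(modules.partition.W),
        },
    }
    (out / "config.json").write_text(json.dumps(meta, indent=2))
    return out


def load_checkpoint(indir) -> ModuleSet:
    indir = Path(indir)
    meta = json.loads((indir / "config.json").read_text())
    cfg_dict = meta["network_config"]
    for key in ("encoder_hidden", "decoder_hidden", "critic_hidden",
                "survival_hidden", "drug_hidden"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = NetworkConfig(**cfg_dict)
    part = LatentPartition(
        p=meta["partition"]["p"],
        U=tuple(meta["partition"]["U"]),
        V=tuple(meta["partition"]["V"]),
        W=tuple(meta["partition"]["W"]),
    )
    modules = build_modules(config, seed=0)
    modules = dataclasses.replace(modules, partition=part)
    with np.load(indir / "weights.npz") as npz:
        for name, mod in modules.named_modules().items():
            for i in range(len(mod.weights)):
                wkey, bkey = f"{name}.w{i}", f"{name}.b{i}"
                if wkey not in npz.files:
                    raise ValueError(
                        f"checkpoint at {indir} does not match configuration: missing {wkey}"
                    )
                if npz[wkey].shape != mod.weights[i].data.shape:
                    raise ValueError(
                        f"checkpoint weight {wkey} has shape {npz[wkey].shape}, "
                        f"expected {mod.weights[i].data.shape}"
                    )
                mod.weights[i].data = npz[wkey].astype(np.float64)
                mod.biases[i].data = npz[bkey].astype(np.float64)
    return modules
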