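"""The pan-specific binding-prediction network.

Architecture, in three stages:

(i)  Two sequence encoders. The peptide encoder maps the one-hot
     ``1 x 9 x 20`` peptide tensor through two blocks of convolution +
     batch norm + leaky rectifier to a ``1 x 9 x 10`` feature tensor. The
     HLA encoder maps the ``1 x 372 x 21`` aligned-sequence tensor through
     a VGG-style stack of convolution blocks with width-reducing pools,
     then an adaptive average pool to width 9 and a 1x1 convolution, also
     yielding ``1 x 9 x 10``. The two outputs are concatenated along the
     channel axis into a ``1 x 9 x 20`` feature tensor.

(ii) A binding-context extractor built from locally-connected blocks
     (position-specific kernels, no weight sharing across width — a
     feature at peptide position 1 may mean something different than the
     same feature at position 7). Valid padding shrinks the width 9→7→5;
     flattening the final ``5 x 512`` map gives the 2560-dimensional
     binding context vector.

(iii) Two small dense heads reading the same context vector: a linear
     regression head predicting logIC50 and a sigmoid classification head
     predicting the binding probability. The dual output is the model's
     multi-task signal: both heads must agree with the measured affinity
     through their respective losses.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .alphabet import AMINO_ACIDS, HLA_WIDTH, N_RESIDUES, PEPTIDE_LENGTH
from .data import Dataset, inverse_transform
from .errors import ConstructionError, NetworkShapeError, UnknownAlleleError
from .encoding import encode_hla, encode_peptide
from .nn import (
    AdaptiveAvgPool1d,
    BatchNorm,
    Conv1d,
    Dense,
    Flatten,
    Layer,
    LeakyReLU,
    LocallyConnected1d,
    MaxPool1d,
    Sequential,
)

__all__ = [
    "ConvBlockSpec",
    "LCBlockSpec",
    "NetworkConfig",
    "PredictionPair",
    "PredictionRow",
    "Network",
    "build_network",
    "locally_connected_apply",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

#: Required width/channel shape of each encoder's output.
ENCODER_OUT = (PEPTIDE_LENGTH, 10)
#: Required length of the binding context vector.
CONTEXT_LENGTH = 2560

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolution block: conv -> (batch norm) -> leaky rectifier -> (pool)."""

    filters: int
    kernel: int = 3
    padding: str = "same"
    batch_norm: bool = True
    pool: int = 0  # max-pool width after the block; 0 = none


@dataclass(frozen=True)
class LCBlockSpec:
    """One locally-connected block: LC (valid padding) -> (batch norm) -> leaky."""

    filters: int
    kernel: int = 3
    batch_norm: bool = True


@dataclass(frozen=True)
class NetworkConfig:
    """Full architecture description; ``default()`` is the reference model,
    ``reduced()`` a lighter variant for CPU-scale experiments."""

    peptide_encoder: tuple[ConvBlockSpec, ...]
    hla_encoder: tuple[ConvBlockSpec, ...]
    extractor: tuple[LCBlockSpec, ...]
    head_hidden_units: int = 64
    leaky_slope: float = 0.3
    seed: int = 0

    @staticmethod
    def default(seed: int = 0) -> "NetworkConfig":
        return NetworkConfig(
            peptide_encoder=(ConvBlockSpec(32), ConvBlockSpec(10)),
            hla_encoder=(
                ConvBlockSpec(32, pool=2),
                ConvBlockSpec(64, pool=2),
                ConvBlockSpec(128, pool=2),
            ),
            extractor=(LCBlockSpec(128), LCBlockSpec(512)),
            seed=seed,
        )

    @staticmethod
    def reduced(seed: int = 0) -> "NetworkConfig":
        """Lighter encoders for CPU-scale runs; same contracts as the
        reference model (9x10 encodings, 2560-length context)."""
        return NetworkConfig(
            peptide_encoder=(ConvBlockSpec(32), ConvBlockSpec(10)),
            hla_encoder=(ConvBlockSpec(32, pool=4), ConvBlockSpec(64, pool=2)),
            extractor=(LCBlockSpec(256), LCBlockSpec(512)),
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peptide_encoder"] = [asdict(b) for b in self.peptide_encoder]
        d["hla_encoder"] = [asdict(b) for b in self.hla_encoder]
        d["extractor"] = [asdict(b) for b in self.extractor]
        return d

    @staticmethod
    def from_dict(d: dict) -> "NetworkConfig":
        return NetworkConfig(
            peptide_encoder=tuple(ConvBlockSpec(**b) for b in d["peptide_encoder"]),
            hla_encoder=tuple(ConvBlockSpec(**b) for b in d["hla_encoder"]),
            extractor=tuple(LCBlockSpec(**b) for b in d["extractor"]),
            head_hidden_units=d.get("head_hidden_units", 64),
            leaky_slope=d.get("leaky_slope", 0.3),
            seed=d.get("seed", 0),
        )


@dataclass(frozen=True)
class PredictionPair:
    """The network's dual output for one peptide–HLA pair."""

    log_ic50_pred: float
    binding_prob: float

    @property
    def ic50_pred(self) -> float:
        return inverse_transform(self.log_ic50_pred)


@dataclass(frozen=True)
class PredictionRow:
    """One batch-inference result, keeping the originating sample."""

    sample: object
    ic50_pred: float
    binding_prob: float
    log_ic50_pred: float


def _conv_stack(blocks, c_in: int, slope: float, rng) -> tuple[Sequential, int]:
    layers: list[Layer] = []
    c = c_in
    for b in blocks:
        layers.append(Conv1d(c, b.filters, b.kernel, b.padding, rng))
        if b.batch_norm:
            layers.append(BatchNorm(b.filters))
        layers.append(LeakyReLU(slope))
        if b.pool:
            layers.append(MaxPool1d(b.pool))
        c = b.filters
    return Sequential(layers), c


def _trace_width(seq: Sequential, w: int) -> int:
    for layer in seq.layers:
        w = layer.out_width(w)
    return w


class Network:
    """All trainable parameters plus the forward/backward machinery.

    Built by :func:`build_network`; deterministic given the config seed.
    Inference (``train=False``) uses frozen batch-norm statistics and is a
    pure function of the parameters and inputs.
    """

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        slope = config.leaky_slope

        self.peptide_encoder, c_pep = _conv_stack(
            config.peptide_encoder, N_RESIDUES, slope, rng)
        w_pep = _trace_width(self.peptide_encoder, PEPTIDE_LENGTH)
        if (w_pep, c_pep) != ENCODER_OUT:
            raise ConstructionError(
                f"peptide encoder must yield 1x{ENCODER_OUT[0]}x{ENCODER_OUT[1]}, "
                f"config yields 1x{w_pep}x{c_pep}")

        hla_stack, c_hla = _conv_stack(config.hla_encoder, N_RESIDUES + 1, slope, rng)
        w_hla = _trace_width(hla_stack, HLA_WIDTH)
        # adaptive pool to width 9, then a 1x1 projection to 10 channels
        tail = [AdaptiveAvgPool1d(PEPTIDE_LENGTH),
                Conv1d(c_hla, ENCODER_OUT[1], 1, "valid", rng),
                BatchNorm(ENCODER_OUT[1]),
                LeakyReLU(slope)]
        if w_hla < PEPTIDE_LENGTH:
            raise ConstructionError(
                f"HLA encoder width collapsed below {PEPTIDE_LENGTH} (got {w_hla})")
        self.hla_encoder = Sequential(hla_stack.layers + tail)

        ext_layers: list[Layer] = []
        w, c = PEPTIDE_LENGTH, 2 * ENCODER_OUT[1]
        for b in config.extractor:
            if b.kernel > w:
                raise ConstructionError(f"extractor kernel {b.kernel} wider than {w}")
            ext_layers.append(LocallyConnected1d(w, c, b.filters, b.kernel, rng))
            if b.batch_norm:
                ext_layers.append(BatchNorm(b.filters))
            ext_layers.append(LeakyReLU(slope))
            w, c = w - b.kernel + 1, b.filters
        ext_layers.append(Flatten())
        self.extractor = Sequential(ext_layers)
        flat = w * c
        if flat != CONTEXT_LENGTH:
            raise ConstructionError(
                f"extractor must flatten to {CONTEXT_LENGTH}, config yields {flat} "
                f"({w} positions x {c} filters)")

        h = config.head_hidden_units
        self.head_affinity = Sequential(
            [Dense(CONTEXT_LENGTH, h, rng), LeakyReLU(slope), Dense(h, 1, rng)])
        self.head_binding = Sequential(
            [Dense(CONTEXT_LENGTH, h, rng), LeakyReLU(slope), Dense(h, 1, rng)])
        # start regression output at the 500 nM boundary of the label scale
        self.head_affinity.layers[-1].params["b"][:] = math.log(500.0)

        self._branches = {
            "peptide_encoder": self.peptide_encoder,
            "hla_encoder": self.hla_encoder,
            "extractor": self.extractor,
            "head_affinity": self.head_affinity,
            "head_binding": self.head_binding,
        }

    # ---- forward / backward -------------------------------------------------

    def forward_batch(self, peptides: np.ndarray, hlas: np.ndarray,
                      train: bool = False) -> dict[str, np.ndarray]:
        """Run a batch: peptides ``(B, 9, 20)``, HLAs ``(B, 372, 21)``.

        Returns log-IC50 predictions, classification logits, binding
        probabilities and the 2560-length context vectors.
        """
        if peptides.ndim != 3 or peptides.shape[1:] != (PEPTIDE_LENGTH, N_RESIDUES):
            raise NetworkShapeError(f"peptide batch must be (B, 9, 20), got {peptides.shape}")
        if hlas.ndim != 3 or hlas.shape[1:] != (HLA_WIDTH, N_RESIDUES + 1):
            raise NetworkShapeError(f"HLA batch must be (B, 372, 21), got {hlas.shape}")
        fp = self.peptide_encoder.forward(peptides.astype(np.float32), train=train)
        fh = self.hla_encoder.forward(hlas.astype(np.float32), train=train)
        feat = np.concatenate([fp, fh], axis=2)  # (B, 9, 20) along channels
        context = self.extractor.forward(feat, train=train)
        log_ic50 = self.head_affinity.forward(context, train=train)[:, 0]
        logit = self.head_binding.forward(context, train=train)[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        return {"log_ic50": log_ic50, "logit": logit, "prob": prob, "context": context}

    def forward_batch_grouped(self, peptides: np.ndarray, hla_bank: np.ndarray,
                              rows: np.ndarray, train: bool = False,
                              ) -> dict[str, np.ndarray]:
        """Like :meth:`forward_batch`, but HLAs are given as a bank of
        distinct allele tensors plus a per-sample row index.

        The HLA encoder runs once per distinct allele in the batch and its
        output is gathered per sample — datasets hold thousands of peptides
        but only tens of alleles, so this dominates the training speed. In
        training mode the HLA branch's batch-norm statistics are therefore
        computed over distinct alleles rather than samples.
        """
        uniq, inv = np.unique(rows, return_inverse=True)
        fp = self.peptide_encoder.forward(peptides.astype(np.float32), train=train)
        fh_u = self.hla_encoder.forward(hla_bank[uniq].astype(np.float32), train=train)
        fh = fh_u[inv]
        self._grouped = (len(uniq), inv)
        feat = np.concatenate([fp, fh], axis=2)
        context = self.extractor.forward(feat, train=train)
        log_ic50 = self.head_affinity.forward(context, train=train)[:, 0]
        logit = self.head_binding.forward(context, train=train)[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        return {"log_ic50": log_ic50, "logit": logit, "prob": prob, "context": context}

    def backward_batch_grouped(self, g_log_ic50: np.ndarray, g_logit: np.ndarray) -> None:
        g_ctx = self.head_affinity.backward(g_log_ic50[:, None].astype(np.float32))
        g_ctx = g_ctx + self.head_binding.backward(g_logit[:, None].astype(np.float32))
        g_feat = self.extractor.backward(g_ctx)
        n = ENCODER_OUT[1]
        self.peptide_encoder.backward(g_feat[:, :, :n])
        n_uniq, inv = self._grouped
        g_fh = np.ascontiguousarray(g_feat[:, :, n:])
        # scatter-add sample gradients back onto their distinct allele rows
        onehot = np.zeros((n_uniq, len(inv)), dtype=np.float32)
        onehot[inv, np.arange(len(inv))] = 1.0
        g_fh_u = (onehot @ g_fh.reshape(len(inv), -1)).reshape((n_uniq,) + g_fh.shape[1:])
        self.hla_encoder.backward(g_fh_u)

    def backward_batch(self, g_log_ic50: np.ndarray, g_logit: np.ndarray) -> None:
        g_ctx = self.head_affinity.backward(g_log_ic50[:, None].astype(np.float32))
        g_ctx = g_ctx + self.head_binding.backward(g_logit[:, None].astype(np.float32))
        g_feat = self.extractor.backward(g_ctx)
        n = ENCODER_OUT[1]
        self.peptide_encoder.backward(g_feat[:, :, :n])
        self.hla_encoder.backward(np.ascontiguousarray(g_feat[:, :, n:]))

    def forward(self, peptide_tensor: np.ndarray, hla_tensor: np.ndarray,
                ) -> tuple[PredictionPair, np.ndarray]:
        """Inference on a single encoded pair (accepts the ``1 x W x C`` tensors)."""
        p = np.asarray(peptide_tensor).reshape(1, PEPTIDE_LENGTH, N_RESIDUES)
        h = np.asarray(hla_tensor).reshape(1, HLA_WIDTH, N_RESIDUES + 1)
        out = self.forward_batch(p, h, train=False)
        pair = PredictionPair(float(out["log_ic50"][0]), float(out["prob"][0]))
        return pair, out["context"][0]

    # ---- parameter access ---------------------------------------------------

    def iter_layers(self):
        for branch in self._branches.values():
            yield from branch.iter_layers()

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, branch in self._branches.items():
            for i, layer in enumerate(branch.iter_layers()):
                for key, val in layer.params.items():
                    state[f"{name}.{i}.{key}"] = val.copy()
                if isinstance(layer, BatchNorm):
                    state[f"{name}.{i}.running_mean"] = layer.running_mean.copy()
                    state[f"{name}.{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, branch in self._branches.items():
            for i, layer in enumerate(branch.iter_layers()):
                for key in layer.params:
                    layer.params[key] = state[f"{name}.{i}.{key}"].copy()
                if isinstance(layer, BatchNorm):
                    layer.running_mean = state[f"{name}.{i}.running_mean"].copy()
                    layer.running_var = state[f"{name}.{i}.running_var"].copy()


def build_network(config: NetworkConfig) -> Network:
    """Construct a network with deterministically seeded parameters.

    Shape contracts (9x10 encoder outputs, 2560 context length) are
    validated at construction; a config whose stages cannot compose raises
    :class:`ConstructionError`.
    """
    return Network(config)


def locally_connected_apply(weights: np.ndarray, x: np.ndarray,
                            bias: np.ndarray | None = None) -> np.ndarray:
    """Apply position-specific kernels to ``x`` of shape ``(1, W, C)``.

    ``weights`` has shape ``(W', k*C, C')`` with ``W' = W - k + 1``: one
    independent ``(k*C, C')`` block per output position. Output position i
    depends only on ``x[:, i:i+k, :]`` and block i.
    """
    from .nn import _patches  # shared patch extraction

    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise NetworkShapeError(f"input must be (1, W, C), got shape {x.shape}")
    w_out, kc, _ = weights.shape
    c = x.shape[2]
    if kc % c:
        raise NetworkShapeError(f"weight block size {kc} not a multiple of {c} channels")
    k = kc // c
    if k > x.shape[1]:
        raise NetworkShapeError(f"kernel width {k} exceeds input width {x.shape[1]}")
    if w_out != x.shape[1] - k + 1:
        raise NetworkShapeError(
            f"expected {x.shape[1] - k + 1} weight blocks, got {w_out}")
    out = np.einsum("bwf,wfo->bwo", _patches(x, k), np.asarray(weights, dtype=np.float32))
    if bias is not None:
        out = out + bias
    return out


def encode_dataset(dataset: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute tensors for batch inference/training over a dataset.

    Returns ``(peptide_batch, allele_tensor_bank, allele_row_per_sample)``;
    the HLA bank holds each distinct allele once since datasets contain few
    alleles but many peptides.
    """
    pep_cache: dict[str, np.ndarray] = {}
    peptides = np.empty((len(dataset), PEPTIDE_LENGTH, N_RESIDUES), dtype=np.float32)
    for i, s in enumerate(dataset.samples):
        t = pep_cache.get(s.peptide)
        if t is None:
            t = encode_peptide(s.peptide)[0]
            pep_cache[s.peptide] = t
        peptides[i] = t

    allele_order: dict[str, int] = {}
    rows = np.empty(len(dataset), dtype=np.int64)
    bank_list: list[np.ndarray] = []
    for i, s in enumerate(dataset.samples):
        if s.allele not in allele_order:
            if s.allele not in dataset.allele_index:
                raise UnknownAlleleError(s.allele)
            allele_order[s.allele] = len(bank_list)
            bank_list.append(encode_hla(dataset.allele_index[s.allele])[0])
        rows[i] = allele_order[s.allele]
    bank = (np.stack(bank_list) if bank_list
            else np.empty((0, HLA_WIDTH, N_RESIDUES + 1), dtype=np.float32))
    return peptides, bank, rows


def predict(network: Network, dataset: Dataset, batch_size: int = 256,
            ) -> list[PredictionRow]:
    """Batch inference over a dataset, preserving sample order.

    Predicted logIC50 is mapped back to nM via the inverse log transform
    (clamped to [0, 80000]).
    """
    if len(dataset) == 0:
        return []
    peptides, bank, rows = encode_dataset(dataset)
    out_rows: list[PredictionRow] = []
    for start in range(0, len(dataset), batch_size):
        sl = slice(start, start + batch_size)
        out = network.forward_batch_grouped(peptides[sl], bank, rows[sl], train=False)
        for j, s in enumerate(dataset.samples[sl]):
            log_pred = float(out["log_ic50"][j])
            out_rows.append(PredictionRow(
                sample=s,
                ic50_pred=inverse_transform(log_pred),
                binding_prob=float(out["prob"][j]),
                log_ic50_pred=log_pred,
            ))
    return out_rows


def save_checkpoint(network: Network, path) -> None:
    """Persist weights + config + alphabet ordering; round-trips exactly."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "alphabet": AMINO_ACIDS,
        "config": network.config.to_dict(),
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **network.state_dict())


def load_checkpoint(path) -> Network:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
        if meta.get("alphabet") != AMINO_ACIDS:
            raise ValueError("checkpoint was written with a different alphabet ordering")
        net = Network(NetworkConfig.from_dict(meta["config"]))
        net.load_state_dict({k: npz[k] for k in npz.files if k != "__meta__"})
    return net
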