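"""The three coding/non-coding sequence classifier architectures.

All three consume the k-mer embedding matrix of a transcript and output a
two-class probability vector (noncoding, coding):

* ``cnn`` -- embedding, three blocks of (1-D convolution, 128 filters of
  width 5; max-pooling of 5), masked global max pooling, dense 128, softmax.
* ``lstm`` -- embedding, two such conv/pool blocks, a bidirectional LSTM
  (final states), dense 128, softmax.
* ``transformer`` -- embedding plus sinusoidal positional encoding, one
  transformer block (single-head self-attention, feed-forward, layer
  normalization), masked global average pooling, dropout, dense 64, softmax.

The networks are small enough that a numpy implementation (BLAS GEMM
convolutions, a fused token-table kernel for the first convolution,
hand-written backprop, Adam) trains them in minutes on one CPU.  The k-mer
embedding table is frozen by default; set ``embedding_trainable=True`` to
fine-tune it with the rest of the parameters.

Every source of randomness (initialization, batch order, dropout) derives
from the handle's seed, so two handles built alike produce identical
parameters, predictions and training trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from ._kernels import token_conv_bwd, token_conv_fwd
from .encoding import KmerEmbeddingTable
from .training import Batch, EncodedDataset

FAMILIES = ("cnn", "lstm", "transformer")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of one classifier family.

    ``conv_blocks`` and ``dense_units`` default per family (cnn: 3 blocks /
    128 units; lstm: 2 blocks / 128; transformer: 0 blocks / 64).  Dropout
    defaults to 0.3, the midpoint of the commonly searched range.
    """

    family: str
    conv_blocks: int | None = None
    conv_filters: int = 128
    conv_kernel: int = 5
    pool_size: int = 5
    dense_units: int | None = None
    lstm_units: int = 128
    lstm_bidirectional: bool = True
    attention_heads: int = 1
    ff_dim: int = 128
    dropout: float = 0.3
    embedding_trainable: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.conv_blocks is None:
            object.__setattr__(
                self, "conv_blocks", {"cnn": 3, "lstm": 2, "transformer": 0}[self.family]
            )
        if self.dense_units is None:
            object.__setattr__(
                self, "dense_units", 64 if self.family == "transformer" else 128
            )
        if self.family in ("cnn", "lstm") and self.conv_blocks < 1:
            raise ValueError("cnn/lstm require at least one conv block")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.attention_heads != 1:
            raise ValueError("only single-head attention is supported")

    @property
    def min_tokens(self) -> int:
        """Smallest token count the conv/pool stack can reduce to one position."""
        m = 1
        for _ in range(self.conv_blocks or 0):
            m = m * self.pool_size + (self.conv_kernel - 1)
        return m

    def with_(self, **kw) -> "ArchitectureSpec":
        return replace(self, **kw)


class SequenceClassifier:
    """Common machinery: parameters, optimizer, batching, fit/predict."""

    def __init__(
        self,
        spec: ArchitectureSpec,
        table: KmerEmbeddingTable,
        seed: int = 0,
        dtype=nn.DTYPE,
    ):
        self.spec = spec
        self.table = table
        self.dtype = np.dtype(dtype)
        self.k = table.k
        self.dim = table.dim
        self.vocab = 4**table.k + 2  # k-mers + unknown + padding
        self.pad_id = 4**table.k + 1
        emb = np.vstack([table.matrix(), np.zeros((1, table.dim), dtype=np.float32)])
        self._emb_const = emb.astype(self.dtype)
        self.reset(seed)

    # -- lifecycle ---------------------------------------------------------

    def reset(self, seed: int | None = None) -> None:
        """Re-initialize all parameters and optimizer state."""
        if seed is not None:
            self.seed = seed
        rng = np.random.default_rng(self.seed)
        self.params = self._init_params(rng)
        if self.spec.embedding_trainable:
            self.params["emb"] = self._emb_const.copy()
        self._opt = None
        self._rng = np.random.default_rng([self.seed, 0x5EED])

    def _emb(self) -> np.ndarray:
        return self.params.get("emb", self._emb_const)

    @property
    def min_tokens(self) -> int:
        return self.spec.min_tokens

    def n_parameters(self) -> int:
        return sum(int(np.prod(v.shape)) for v in self.params.values())

    # -- training / inference ---------------------------------------------

    def fit_epoch(
        self,
        data: EncodedDataset,
        class_weight,
        batch_size: int = 64,
        lr: float = 1e-3,
    ) -> float:
        """One epoch of Adam over shuffled length-bucketed minibatches.

        Returns the weighted mean training loss over the epoch.
        """
        class_weight = np.asarray(class_weight, dtype=float)
        groups = data.step_groups(batch_size, self.min_tokens)
        if self._opt is None:
            self._opt = nn.Adam(self.params, lr=lr)
        self._opt.lr = lr
        order = self._rng.permutation(len(groups))
        total, count = 0.0, 0
        for gi in order:
            # one optimizer step over a class-stratified group; the loss is
            # the weighted mean across all of the group's sub-batches, so
            # the update equals that of one mixed batch
            subs = groups[gi]
            fwd = []
            for batch in subs:
                y = data.labels[batch.idx].astype(np.int64)
                logits, caches = self._forward(batch, train=True)
                fwd.append((logits, caches, y))
            all_logits = np.concatenate([f[0] for f in fwd])
            all_y = np.concatenate([f[2] for f in fwd])
            all_w = class_weight[all_y]
            loss, _, dlogits = nn.softmax_xent_fwd(all_logits, all_y, all_w)
            grads: dict = {}
            pos = 0
            for logits, caches, y in fwd:
                g = self._backward(dlogits[pos : pos + len(y)], caches)
                pos += len(y)
                for k, v in g.items():
                    if k in grads:
                        grads[k] += v
                    else:
                        grads[k] = v
            self._opt.step(grads)
            total += loss * len(all_y)
            count += len(all_y)
        return total / max(count, 1)

    def predict_proba(self, data: EncodedDataset, batch_size: int = 64) -> np.ndarray:
        """Inference-mode class probabilities, (N, 2), in dataset order.

        The default batch size matches training so the cached length-bucketed
        batch partition is reused.
        """
        out = np.empty((len(data), 2))
        for batch in data.batches(batch_size, self.min_tokens):
            logits, _ = self._forward(batch, train=False)
            out[batch.idx] = nn.softmax(logits.astype(np.float64), axis=1)
        return out

    # -- shared embedding + conv stack -------------------------------------

    def _init_conv_stack(self, rng, params) -> None:
        K, F, D = self.spec.conv_kernel, self.spec.conv_filters, self.dim
        cin = D
        for i in range(self.spec.conv_blocks or 0):
            params[f"conv{i}_W"] = nn.glorot_uniform(
                rng, (K, cin, F), K * cin, F, self.dtype
            )
            params[f"conv{i}_b"] = np.zeros(F, dtype=self.dtype)
            cin = F

    def _conv_stack_fwd(self, batch: Batch, train: bool = True):
        """Embedding + (conv, relu, maxpool) blocks, first conv fused.

        With ``train=False`` the backward-pass bookkeeping is skipped.
        """
        spec = self.spec
        emb = self._emb()
        W0 = self.params["conv0_W"]
        G = np.einsum("vd,kdf->vkf", emb, W0, optimize=True)
        x = token_conv_fwd(batch.tok, batch.lengths, G)
        x += self.params["conv0_b"]
        lengths = nn.conv_out_lengths(batch.lengths, spec.conv_kernel)
        caches = [("conv0", (batch, G.shape))]
        # relu and non-overlapping max pooling commute (relu is monotone),
        # so relu runs on the pooled (pool_size x smaller) array
        x, lengths, pc = nn.maxpool_fwd(x, lengths, spec.pool_size, want_grad=train)
        caches.append(("pool", pc))
        x, mask = nn.relu_fwd(x, inplace=True)
        caches.append(("relu", mask))
        for i in range(1, spec.conv_blocks or 0):
            x, cc = nn.conv1d_fwd(x, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"])
            lengths = nn.conv_out_lengths(lengths, spec.conv_kernel)
            caches.append((f"conv{i}", cc if train else None))
            x, lengths, pc = nn.maxpool_fwd(x, lengths, spec.pool_size, want_grad=train)
            caches.append(("pool", pc))
            x, mask = nn.relu_fwd(x, inplace=True)
            caches.append(("relu", mask))
        return x, lengths, caches

    def _conv_stack_bwd(self, dx, caches, grads) -> None:
        for name, cache in reversed(caches):
            if name == "pool":
                dx = nn.maxpool_bwd(dx, cache)
            elif name == "relu":
                dx = nn.relu_bwd(dx, cache)
            elif name == "conv0":
                batch, gshape = cache
                dG = token_conv_bwd(batch.tok, batch.lengths, dx, gshape[0], gshape[1])
                emb = self._emb()
                W0 = self.params["conv0_W"]
                grads["conv0_W"] = np.einsum("vd,vkf->kdf", emb, dG, optimize=True)
                grads["conv0_b"] = dx.sum(axis=(0, 1))
                if self.spec.embedding_trainable:
                    demb = np.einsum("vkf,kdf->vd", dG, W0, optimize=True)
                    demb[self.pad_id] = 0.0
                    grads["emb"] = demb
            else:
                dx, dW, db = nn.conv1d_bwd(dx, cache)
                grads[f"{name}_W"] = dW
                grads[f"{name}_b"] = db

    # -- dense head shared by cnn and lstm ---------------------------------

    def _init_head(self, rng, params, cin: int) -> None:
        U = self.spec.dense_units
        params["dense_W"] = nn.glorot_uniform(rng, (cin, U), cin, U, self.dtype)
        params["dense_b"] = np.zeros(U, dtype=self.dtype)
        params["out_W"] = nn.glorot_uniform(rng, (U, 2), U, 2, self.dtype)
        params["out_b"] = np.zeros(2, dtype=self.dtype)

    def _head_fwd(self, g, train: bool):
        h, dc = nn.dense_fwd(g, self.params["dense_W"], self.params["dense_b"])
        h, mask = nn.relu_fwd(h)
        h, keep = nn.dropout_fwd(h, self.spec.dropout, self._rng, train)
        logits, oc = nn.dense_fwd(h, self.params["out_W"], self.params["out_b"])
        return logits, (dc, mask, keep, oc)

    def _head_bwd(self, dlogits, cache, grads):
        dc, mask, keep, oc = cache
        dh, grads["out_W"], grads["out_b"] = nn.dense_bwd(dlogits, oc)
        dh = nn.dropout_bwd(dh, keep)
        dh = nn.relu_bwd(dh, mask)
        dg, grads["dense_W"], grads["dense_b"] = nn.dense_bwd(dh, dc)
        return dg

    # -- subclass surface ---------------------------------------------------

    def _init_params(self, rng) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError

    def _forward(self, batch: Batch, train: bool):  # pragma: no cover - abstract
        raise NotImplementedError

    def _backward(self, dlogits, caches) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError


class CNNClassifier(SequenceClassifier):
    """Three conv/pool blocks, global max pooling, dense head."""

    def _init_params(self, rng):
        params: dict = {}
        self._init_conv_stack(rng, params)
        self._init_head(rng, params, self.spec.conv_filters)
        return params

    def _forward(self, batch, train):
        x, lengths, conv_caches = self._conv_stack_fwd(batch, train)
        g, gc = nn.global_maxpool_fwd(x, lengths)
        logits, head = self._head_fwd(g, train)
        return logits, (conv_caches, gc, head)

    def _backward(self, dlogits, caches):
        conv_caches, gc, head = caches
        grads: dict = {}
        dg = self._head_bwd(dlogits, head, grads)
        dx = nn.global_maxpool_bwd(dg, gc)
        self._conv_stack_bwd(dx, conv_caches, grads)
        return grads


class LSTMClassifier(SequenceClassifier):
    """Two conv/pool blocks feeding a bidirectional LSTM's final states."""

    def _init_params(self, rng):
        params: dict = {}
        self._init_conv_stack(rng, params)
        F, H = self.spec.conv_filters, self.spec.lstm_units
        dirs = ("f", "b") if self.spec.lstm_bidirectional else ("f",)
        for d in dirs:
            params[f"lstm_{d}_Wx"] = nn.glorot_uniform(rng, (F, 4 * H), F, 4 * H, self.dtype)
            params[f"lstm_{d}_Wh"] = nn.glorot_uniform(rng, (H, 4 * H), H, 4 * H, self.dtype)
            b = np.zeros(4 * H, dtype=self.dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias
            params[f"lstm_{d}_b"] = b
        self._init_head(rng, params, H * len(dirs))
        return params

    def _forward(self, batch, train):
        p = self.params
        x, lengths, conv_caches = self._conv_stack_fwd(batch, train)
        hf, cf = nn.lstm_fwd(x, lengths, p["lstm_f_Wx"], p["lstm_f_Wh"], p["lstm_f_b"])
        if self.spec.lstm_bidirectional:
            xr = nn.reverse_padded(x, lengths)
            hb, cb = nn.lstm_fwd(xr, lengths, p["lstm_b_Wx"], p["lstm_b_Wh"], p["lstm_b_b"])
            g = np.concatenate([hf, hb], axis=1)
        else:
            hb, cb = None, None
            g = hf
        logits, head = self._head_fwd(g, train)
        return logits, (conv_caches, lengths, cf, cb, head)

    def _backward(self, dlogits, caches):
        conv_caches, lengths, cf, cb, head = caches
        p = self.params
        grads: dict = {}
        dg = self._head_bwd(dlogits, head, grads)
        H = self.spec.lstm_units
        dxf, grads["lstm_f_Wx"], grads["lstm_f_Wh"], grads["lstm_f_b"] = nn.lstm_bwd(
            dg[:, :H], cf
        )
        dx = dxf
        if self.spec.lstm_bidirectional:
            dxb, grads["lstm_b_Wx"], grads["lstm_b_Wh"], grads["lstm_b_b"] = nn.lstm_bwd(
                dg[:, H:], cb
            )
            dx = dxf + nn.reverse_padded(dxb, lengths)
        self._conv_stack_bwd(dx, conv_caches, grads)
        return grads


class TransformerClassifier(SequenceClassifier):
    """Positional encoding, one attention block, masked mean pooling."""

    def _init_params(self, rng):
        D, FF = self.dim, self.spec.ff_dim
        params: dict = {}
        for name in ("att_Wq", "att_Wk", "att_Wv", "att_Wo"):
            params[name] = nn.glorot_uniform(rng, (D, D), D, D, self.dtype)
            params[name.replace("W", "b")] = np.zeros(D, dtype=self.dtype)
        params["ln1_g"] = np.ones(D, dtype=self.dtype)
        params["ln1_b"] = np.zeros(D, dtype=self.dtype)
        params["ff1_W"] = nn.glorot_uniform(rng, (D, FF), D, FF, self.dtype)
        params["ff1_b"] = np.zeros(FF, dtype=self.dtype)
        params["ff2_W"] = nn.glorot_uniform(rng, (FF, D), FF, D, self.dtype)
        params["ff2_b"] = np.zeros(D, dtype=self.dtype)
        params["ln2_g"] = np.ones(D, dtype=self.dtype)
        params["ln2_b"] = np.zeros(D, dtype=self.dtype)
        self._init_head(rng, params, D)
        return params

    def _forward(self, batch, train):
        p = self.params
        tok = batch.tok
        lengths = batch.lengths
        x = self._emb()[tok]
        pe = nn.positional_encoding(tok.shape[1], self.dim, self.dtype)
        x = x + pe[None, :, :]
        attn, ac = nn.attention_fwd(
            x, lengths,
            p["att_Wq"], p["att_bq"], p["att_Wk"], p["att_bk"],
            p["att_Wv"], p["att_bv"], p["att_Wo"], p["att_bo"],
        )
        a1 = x + attn
        h1, l1 = nn.layernorm_fwd(a1, p["ln1_g"], p["ln1_b"])
        f, fc1 = nn.dense_fwd(h1, p["ff1_W"], p["ff1_b"])
        f, fmask = nn.relu_fwd(f)
        f, fc2 = nn.dense_fwd(f, p["ff2_W"], p["ff2_b"])
        h2, l2 = nn.layernorm_fwd(h1 + f, p["ln2_g"], p["ln2_b"])
        g, gc = nn.global_avgpool_fwd(h2, lengths)
        g, keep = nn.dropout_fwd(g, self.spec.dropout, self._rng, train)
        d, dc = nn.dense_fwd(g, p["dense_W"], p["dense_b"])
        d, dmask = nn.relu_fwd(d)
        logits, oc = nn.dense_fwd(d, p["out_W"], p["out_b"])
        return logits, (batch, ac, l1, fc1, fmask, fc2, l2, gc, keep, dc, dmask, oc)

    def _backward(self, dlogits, caches):
        batch, ac, l1, fc1, fmask, fc2, l2, gc, keep, dc, dmask, oc = caches
        grads: dict = {}
        dd, grads["out_W"], grads["out_b"] = nn.dense_bwd(dlogits, oc)
        dd = nn.relu_bwd(dd, dmask)
        dg, grads["dense_W"], grads["dense_b"] = nn.dense_bwd(dd, dc)
        dg = nn.dropout_bwd(dg, keep)
        dh2 = nn.global_avgpool_bwd(dg, gc)
        dh1f, grads["ln2_g"], grads["ln2_b"] = nn.layernorm_bwd(dh2, l2)
        df, grads["ff2_W"], grads["ff2_b"] = nn.dense_bwd(dh1f, fc2)
        df = nn.relu_bwd(df, fmask)
        dh1, grads["ff1_W"], grads["ff1_b"] = nn.dense_bwd(df, fc1)
        dh1 = dh1 + dh1f
        da1, grads["ln1_g"], grads["ln1_b"] = nn.layernorm_bwd(dh1, l1)
        (dx_att, grads["att_Wq"], grads["att_bq"], grads["att_Wk"], grads["att_bk"],
         grads["att_Wv"], grads["att_bv"], grads["att_Wo"], grads["att_bo"]) = (
            nn.attention_bwd(da1, ac)
        )
        dx = da1 + dx_att
        if self.spec.embedding_trainable:
            demb = np.zeros_like(self.params["emb"])
            valid = nn.length_mask(batch.lengths, batch.tok.shape[1])
            np.add.at(demb, batch.tok[valid], dx[valid])
            demb[self.pad_id] = 0.0
            grads["emb"] = demb
        return grads


_CLASSES = {
    "cnn": CNNClassifier,
    "lstm": LSTMClassifier,
    "transformer": TransformerClassifier,
}


def build_classifier(
    spec: ArchitectureSpec | str,
    table: KmerEmbeddingTable,
    seed: int = 0,
    dtype=nn.DTYPE,
) -> SequenceClassifier:
    """Construct a classifier handle for the given architecture spec.

    A bare family name is accepted and expanded to the family defaults.
    """
    if isinstance(spec, str):
        spec = ArchitectureSpec(family=spec)
    try:
        cls = _CLASSES[spec.family]
    except KeyError:
        raise ValueError(f"unknown family {spec.family!r}") from None
    return cls(spec, table, seed=seed, dtype=dtype)
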