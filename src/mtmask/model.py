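"""Temporal-token transformer with per-session stitching and prompt tokens.

The architecture follows the neural-data-transformer family: each 20 ms time
bin of population activity is one token.  A per-session linear projection
("stitching") maps that session's neuron dimension into the shared model
width, a learned session embedding identifies the recording, and a learnable
per-masking-scheme prompt token is prepended so one network can switch
between reconstruction modes at train and test time.  The head maps each
time token back through a per-session output projection to strictly positive
Poisson rates.

Two details matter for the masking objectives:

* the token for bin ``t`` is built from the *zero-filled* counts concatenated
  with the binary context mask for that bin, so the model can distinguish a
  hidden entry from an observed zero;
* attention is bidirectional for every scheme — causality is imposed by the
  input mask, not by attention masking — so a single set of weights serves
  all schemes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import gammaln

from ._autograd import Tensor, concat
from .masking import TRAINING_SCHEMES, MaskScheme

__all__ = [
    "ModelConfig",
    "TokenSequence",
    "PopulationTransformer",
    "poisson_nll",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    d_model: int = 128
    n_layers: int = 4
    n_heads: int = 4
    ffn_dim: int = 512
    dropout: float = 0.0
    max_bins: int = 200
    rate_link: str = "softplus"  # or "exp"
    prompt_enabled: bool = True
    rate_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.rate_link not in ("softplus", "exp"):
            raise ValueError("rate_link must be 'softplus' or 'exp'")


@dataclass
class TokenSequence:
    """Per-trial token block consumed by the transformer."""

    tokens: Tensor  # (batch, T or T+1, d_model)
    n_bins: int
    session_id: str
    has_prompt: bool = False
    scheme: MaskScheme | None = None


def _softplus_inverse(y: np.ndarray) -> np.ndarray:
    y = np.maximum(y, 1e-4)
    return np.where(y > 30, y, np.log(np.expm1(y)))


class PopulationTransformer:
    """NDT1-style encoder with session stitching, prompts, and a Poisson head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.training = False
        D, F = config.d_model, config.ffn_dim
        init = lambda *s: Tensor(0.02 * self.rng.standard_normal(s), requires_grad=True)
        zeros = lambda *s: Tensor(np.zeros(s), requires_grad=True)
        ones = lambda *s: Tensor(np.ones(s), requires_grad=True)
        self.pos_emb = init(config.max_bins, D)
        self.prompts: dict[MaskScheme, Tensor] = {s: init(D) for s in TRAINING_SCHEMES}
        self.layers = []
        for _ in range(config.n_layers):
            self.layers.append(
                {
                    "ln1_g": ones(D), "ln1_b": zeros(D),
                    "wq": init(D, D), "bq": zeros(D),
                    "wk": init(D, D), "bk": zeros(D),
                    "wv": init(D, D), "bv": zeros(D),
                    "wo": init(D, D), "bo": zeros(D),
                    "ln2_g": ones(D), "ln2_b": zeros(D),
                    "w1": init(D, F), "b1": zeros(F),
                    "w2": init(F, D), "b2": zeros(D),
                }
            )
        self.ln_f_g, self.ln_f_b = ones(D), zeros(D)
        # stitcher registry: session_id -> dict of per-session parameters
        self.stitcher: dict[str, dict[str, Tensor]] = {}

    # -- session stitching -------------------------------------------------

    def register_session(
        self, session_id: str, n_neurons: int, mean_rates: np.ndarray | None = None
    ) -> None:
        """Create the per-session projections and context embedding.

        ``mean_rates`` (per-neuron mean count per bin, typically from the
        training split) warm-starts the output bias so an untrained model
        reproduces the per-neuron mean-rate null model.
        """
        if session_id in self.stitcher:
            raise ValueError(f"session {session_id!r} already registered")
        D = self.config.d_model
        init = lambda *s: Tensor(0.02 * self.rng.standard_normal(s), requires_grad=True)
        if mean_rates is None:
            b_out = np.full(n_neurons, _softplus_inverse(np.asarray([0.1]))[0])
        elif np.asarray(mean_rates).shape != (n_neurons,):
            raise ValueError("mean_rates must have one entry per neuron")
        else:
            m = np.asarray(mean_rates, dtype=float)
            b_out = _softplus_inverse(m) if self.config.rate_link == "softplus" else np.log(np.maximum(m, 1e-4))
        self.stitcher[session_id] = {
            "w_in": init(2 * n_neurons, D),
            "b_in": Tensor(np.zeros(D), requires_grad=True),
            "sess_emb": init(D),
            "w_out": init(D, n_neurons),
            "b_out": Tensor(b_out, requires_grad=True),
        }

    def session_neuron_count(self, session_id: str) -> int:
        return self.stitcher[session_id]["w_out"].shape[1]

    # -- forward pieces ----------------------------------------------------

    def tokenize(
        self, masked_counts: np.ndarray, context_mask: np.ndarray, session_id: str
    ) -> TokenSequence:
        """Embed zero-filled counts plus the context mask into time tokens.

        ``masked_counts``: (batch, T, N) with hidden entries zeroed;
        ``context_mask``: (T, N) or (batch, T, N) booleans, True = visible.
        """
        if session_id not in self.stitcher:
            raise KeyError(f"session {session_id!r} not registered with the stitcher")
        st = self.stitcher[session_id]
        masked_counts = np.asarray(masked_counts, dtype=np.float32)
        if masked_counts.ndim != 3:
            raise ValueError("masked_counts must be (batch, time, neuron)")
        B, T, N = masked_counts.shape
        if 2 * N != st["w_in"].shape[0]:
            raise ValueError(
                f"session {session_id!r} registered with "
                f"{st['w_in'].shape[0] // 2} neurons, got {N}"
            )
        if T > self.config.max_bins:
            raise ValueError(f"{T} bins exceeds max_bins={self.config.max_bins}")
        cm = np.broadcast_to(np.asarray(context_mask, dtype=np.float32), (B, T, N))
        x = Tensor(np.concatenate([masked_counts * cm, cm], axis=-1))
        tok = x @ st["w_in"] + st["b_in"] + st["sess_emb"] + self.pos_emb[:T]
        return TokenSequence(tokens=tok, n_bins=T, session_id=session_id)

    def prepend_prompt(self, seq: TokenSequence, scheme: MaskScheme) -> TokenSequence:
        """Prepend the scheme's learnable prompt token (identity if disabled)."""
        if not self.config.prompt_enabled:
            return TokenSequence(seq.tokens, seq.n_bins, seq.session_id, False, scheme)
        if scheme not in self.prompts:
            raise ValueError(f"no prompt for scheme {scheme!r} (baseline schemes have none)")
        B = seq.tokens.shape[0]
        D = self.config.d_model
        p = self.prompts[scheme].reshape(1, 1, D)
        ptile = p * Tensor(np.ones((B, 1, 1), dtype=np.float32))  # broadcast over batch
        toks = concat([ptile, seq.tokens], axis=1)
        return TokenSequence(toks, seq.n_bins, seq.session_id, True, scheme)

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0.0:
            return x
        keep = (self.rng.random(x.shape, dtype=np.float32) >= p).astype(np.float32) / np.float32(1.0 - p)
        return x * Tensor(keep)

    def _attention(self, x: Tensor, layer: dict[str, Tensor]) -> Tensor:
        B, L, D = x.shape
        H = self.config.n_heads
        dh = D // H
        q = (x @ layer["wq"] + layer["bq"]).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        k = (x @ layer["wk"] + layer["bk"]).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        v = (x @ layer["wv"] + layer["bv"]).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = scores.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return out @ layer["wo"] + layer["bo"]

    def encode(self, seq: TokenSequence) -> Tensor:
        """Run the bidirectional encoder; returns (batch, len, d_model)."""
        x = seq.tokens
        for layer in self.layers:
            h = x.layernorm() * layer["ln1_g"] + layer["ln1_b"]
            x = x + self._dropout(self._attention(h, layer))
            h = x.layernorm() * layer["ln2_g"] + layer["ln2_b"]
            h = (h @ layer["w1"] + layer["b1"]).gelu() @ layer["w2"] + layer["b2"]
            x = x + self._dropout(h)
        return x.layernorm() * self.ln_f_g + self.ln_f_b

    def forward_rates(self, seq: TokenSequence, session_id: str | None = None) -> Tensor:
        """Map a token sequence to strictly positive rates (batch, T, N).

        The prompt token's output position, if present, is discarded before
        the per-session output projection and the rate link.
        """
        session_id = session_id or seq.session_id
        st = self.stitcher[session_id]
        enc = self.encode(seq)
        if seq.has_prompt:
            enc = enc[:, 1:, :]
        z = enc @ st["w_out"] + st["b_out"]
        if self.config.rate_link == "softplus":
            rates = z.softplus() + self.config.rate_floor
        else:
            rates = z.exp() + self.config.rate_floor
        if not np.isfinite(rates.data).all():
            raise FloatingPointError("non-finite rates; inspect learning rate / inputs")
        return rates

    def predict_rates(
        self,
        counts: np.ndarray,
        context_mask: np.ndarray,
        session_id: str,
        scheme: MaskScheme | None = None,
    ) -> np.ndarray:
        """Inference convenience: mask, tokenize, prompt, and return rates."""
        was_training = self.training
        self.training = False
        try:
            masked = np.where(np.asarray(context_mask, dtype=bool), counts, 0)
            seq = self.tokenize(masked, context_mask, session_id)
            if scheme is not None and self.config.prompt_enabled:
                seq = self.prepend_prompt(seq, scheme)
            return self.forward_rates(seq).data
        finally:
            self.training = was_training

    # -- parameters --------------------------------------------------------

    def shared_parameters(self) -> list[Tensor]:
        ps: list[Tensor] = [self.pos_emb, self.ln_f_g, self.ln_f_b]
        ps.extend(self.prompts[s] for s in TRAINING_SCHEMES)
        for layer in self.layers:
            ps.extend(layer.values())
        return ps

    def session_parameters(self, session_ids=None) -> list[Tensor]:
        ids = list(self.stitcher) if session_ids is None else list(session_ids)
        return [t for sid in ids for t in self.stitcher[sid].values()]

    def parameters(self) -> list[Tensor]:
        return self.shared_parameters() + self.session_parameters()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of every parameter (for checkpoints)."""
        out: dict[str, np.ndarray] = {"pos_emb": self.pos_emb.data, "ln_f_g": self.ln_f_g.data, "ln_f_b": self.ln_f_b.data}
        for s, p in self.prompts.items():
            out[f"prompt/{s.value}"] = p.data
        for i, layer in enumerate(self.layers):
            for k, v in layer.items():
                out[f"layer{i}/{k}"] = v.data
        for sid, st in self.stitcher.items():
            for k, v in st.items():
                out[f"stitch/{sid}/{k}"] = v.data
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self._named_tensors().items():
            if name in state:
                t.data = np.asarray(state[name], dtype=np.float32).copy()

    def _named_tensors(self) -> dict[str, Tensor]:
        out = {"pos_emb": self.pos_emb, "ln_f_g": self.ln_f_g, "ln_f_b": self.ln_f_b}
        for s, p in self.prompts.items():
            out[f"prompt/{s.value}"] = p
        for i, layer in enumerate(self.layers):
            for k, v in layer.items():
                out[f"layer{i}/{k}"] = v
        for sid, st in self.stitcher.items():
            for k, v in st.items():
                out[f"stitch/{sid}/{k}"] = v
        return out


def poisson_nll(rates: Tensor, counts: np.ndarray, target_mask: np.ndarray) -> Tensor:
    """Masked Poisson negative log-likelihood, averaged over target entries.

    Per scored entry the contribution is ``lambda - x*log(lambda) + log(x!)``;
    entries outside ``target_mask`` contribute exactly zero.  The ``log(x!)``
    term is a data constant and is added outside the tape.
    """
    counts = np.asarray(counts, dtype=np.float32)
    w = np.broadcast_to(np.asarray(target_mask, dtype=bool), counts.shape)
    n_target = float(w.sum())
    if n_target == 0:
        raise ValueError("target mask selects no entries")
    lam = rates[w]  # 1-D tensor of scored rates only
    if np.any(lam.data <= 0):
        raise ValueError("non-positive rate at a scored entry")
    x = counts[w]
    nll = (lam - Tensor(x) * lam.log()).sum() * (1.0 / n_target)
    const = float(gammaln(x + 1.0).sum() / n_target)
    return nll + const


def save_checkpoint(path, model: PopulationTransformer, extra: dict | None = None) -> None:
    """Persist weights + config + stitcher registry (npz with a JSON header)."""
    meta = {
        "config": asdict(model.config),
        "sessions": {sid: model.session_neuron_count(sid) for sid in model.stitcher},
        "extra": extra or {},
    }
    arrays = {k.replace("/", "::"): v for k, v in model.state_arrays().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> PopulationTransformer:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = PopulationTransformer(ModelConfig(**meta["config"]))
        for sid, n in meta["sessions"].items():
            model.register_session(sid, int(n))
        state = {k.replace("::", "/"): z[k] for k in z.files if k != "__meta__"}
        model.load_state_arrays(state)
    return model
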