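"""Fusion Attention Module (FAM): quality-aware softmax attention over
modality latents, weighted-sum fusion, classification head, and the
multi-objective loss.

Each modality latent h_i (projected to a common dimension d_f) receives a
scalar score z_i = w_i . [h_i ; variance(h_i) ; entropy(h_i)] / temperature;
attention weights are the softmax of the scores over the *available*
modalities, so masking a modality renormalizes the remaining weights.  The
fused representation is the attention-weighted sum of the h_i, classified
by BatchNorm -> Dropout(0.3) -> Dense(64)+ReLU -> Dense(C) -> softmax.

The training objective is
    L_total = L_CE + lambda_fuse * L_fuse + lambda_att * L_sparsity,
where L_fuse is the mean KL divergence between each modality head's
distribution and the fused distribution, and L_sparsity is the L1 norm of
the pre-softmax attention scores (the softmax weights themselves always sum
to one, so an L1 penalty on them would be constant; penalizing the scores
is the reading that can actually promote sparsity).

Quality indicators are treated as constants (stop-gradient) in the score:
they describe the latent's reliability, not a path for learning signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "FusionConfig", "LossConfig", "LAMBDA_GRID", "QualityIndicators",
    "ModalityFeature", "AttentionState", "PredictionOutput",
    "quality_indicators", "attention_weights", "fuse", "total_loss",
    "FusionHead",
]

MODALITIES = ("text", "image", "signal")
N_ENTROPY_BINS = 16

#: Grid from which the loss mixture weights are selected.
LAMBDA_GRID = (0.1, 0.01, 0.001)


@dataclass(frozen=True)
class FusionConfig:
    d_f: int = 256
    heads: int = 1              # 4-head variant partitions d_f into blocks
    temperature: float = 0.5
    dropout: float = 0.3
    n_classes: int = 2
    seed: int = 0


@dataclass(frozen=True)
class LossConfig:
    lambda_fuse: float = 0.01
    lambda_att: float = 0.001


@dataclass
class QualityIndicators:
    variance: float
    entropy: float


@dataclass
class ModalityFeature:
    modality: str
    h: np.ndarray
    available: bool = True


@dataclass
class AttentionState:
    modalities: list[str]
    logits: dict[str, float]
    alpha: dict[str, float]
    temperature: float
    mask: dict[str, bool]


@dataclass
class PredictionOutput:
    fused_logits: np.ndarray
    per_modality_logits: dict[str, np.ndarray]
    probabilities: np.ndarray
    L_CE: float = 0.0
    L_fuse: float = 0.0
    L_sparsity: float = 0.0
    L_total: float = 0.0


def quality_indicators(h: np.ndarray) -> QualityIndicators:
    """Unbiased sample variance and 16-bin histogram Shannon entropy
    (natural log) of a latent vector's entries."""
    h = np.asarray(h, dtype=np.float64).ravel()
    if h.size < 2:
        raise ValueError(f"need at least 2 entries, got {h.size}")
    variance = float(np.var(h, ddof=1))
    counts, _ = np.histogram(h, bins=N_ENTROPY_BINS)
    p = counts[counts > 0] / h.size
    entropy = float(-(p * np.log(p)).sum())
    return QualityIndicators(variance=variance, entropy=entropy)


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_weights(
    features: list[ModalityFeature],
    params: dict[str, np.ndarray],
    temperature: float = 0.5,
) -> AttentionState:
    """Quality-aware attention over available modalities.

    ``params[modality]`` is the scoring vector w_i over [h_i ; var ; ent].
    Masked modalities get weight exactly 0; the softmax runs over the
    available scores only (with max-subtraction for stability).
    """
    avail = [f for f in features if f.available]
    if not avail:
        raise ValueError("no available modality")
    logits: dict[str, float] = {}
    for f in avail:
        q = quality_indicators(f.h)
        ext = np.concatenate([f.h, [q.variance, q.entropy]])
        logits[f.modality] = float(params[f.modality] @ ext) / temperature
    z = np.array([logits[f.modality] for f in avail])
    a = _softmax(z)
    alpha = {f.modality: 0.0 for f in features}
    for f, ai in zip(avail, a):
        alpha[f.modality] = float(ai)
    return AttentionState(
        modalities=[f.modality for f in features],
        logits=logits,
        alpha=alpha,
        temperature=temperature,
        mask={f.modality: f.available for f in features},
    )


def fuse(features: list[ModalityFeature], state: AttentionState) -> np.ndarray:
    """Weighted sum of available modality latents under the attention state."""
    avail = [f for f in features if f.available]
    dims = {f.h.shape[-1] for f in avail}
    if len(dims) != 1:
        raise ValueError(f"latent dimensions differ across modalities: {dims}")
    out = np.zeros(dims.pop())
    for f in avail:
        out += state.alpha[f.modality] * f.h
    return out


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def total_loss(
    fused_logits: np.ndarray,
    per_modality_logits: dict[str, np.ndarray],
    y: np.ndarray,
    attention_logits: np.ndarray,
    cfg: LossConfig,
) -> PredictionOutput:
    """Multi-objective loss components for a batch.

    L_CE = mean -log p_fused(y); L_fuse = mean over samples of the average
    KL(p_i || p_fused) across available modality heads; L_sparsity = mean
    sum_i |z_i| over the pre-softmax attention scores.
    """
    fused_logits = np.atleast_2d(fused_logits)
    y = np.atleast_1d(y)
    B = fused_logits.shape[0]
    logp_f = _log_softmax(fused_logits)
    p_f = np.exp(logp_f)
    L_ce = float(-np.log(np.maximum(p_f[np.arange(B), y], 1e-12)).mean())

    L_fuse = 0.0
    if per_modality_logits:
        for logits_i in per_modality_logits.values():
            logp_i = _log_softmax(np.atleast_2d(logits_i))
            p_i = np.exp(logp_i)
            L_fuse += float((p_i * (logp_i - logp_f)).sum(axis=1).mean())
        L_fuse /= len(per_modality_logits)

    z = np.atleast_2d(attention_logits)
    L_sp = float(np.abs(z).sum(axis=1).mean())

    L_total = L_ce + cfg.lambda_fuse * L_fuse + cfg.lambda_att * L_sp
    return PredictionOutput(
        fused_logits=fused_logits,
        per_modality_logits=per_modality_logits,
        probabilities=p_f,
        L_CE=L_ce, L_fuse=L_fuse, L_sparsity=L_sp, L_total=L_total,
    )


def _batch_quality(H: np.ndarray) -> np.ndarray:
    """Per-row (variance, entropy) of a (B, d) latent batch; vectorized
    16-equal-width-bin histogram entropy per row."""
    B, d = H.shape
    var = H.var(axis=1, ddof=1)
    lo = H.min(axis=1, keepdims=True)
    rng = H.max(axis=1, keepdims=True) - lo
    rng[rng == 0] = 1.0
    idx = np.minimum((H - lo) / rng * N_ENTROPY_BINS, N_ENTROPY_BINS - 1).astype(int)
    flat = idx + np.arange(B)[:, None] * N_ENTROPY_BINS
    counts = np.bincount(flat.ravel(), minlength=B * N_ENTROPY_BINS)
    p = counts.reshape(B, N_ENTROPY_BINS) / d
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return np.stack([var, -terms.sum(axis=1)], axis=1)


class FusionHead:
    """The trainable shared head: per-modality linear projections to d_f,
    FAM scoring vectors, per-modality logit heads, and the classifier.

    This is the parameter block theta shared across the federation; the
    modality encoders stay private to their clients.
    """

    def __init__(self, cfg: FusionConfig, in_dims: dict[str, int]):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.rng = np.random.default_rng(cfg.seed + 1)   # dropout stream
        if cfg.d_f % cfg.heads != 0:
            raise ValueError("d_f must be divisible by heads")
        self.block = cfg.d_f // cfg.heads
        self.proj = {m: nn.Dense(in_dims[m], cfg.d_f, rng) for m in MODALITIES}
        # one scoring vector per modality per head, over [h_block ; var ; ent];
        # zero init => uniform attention at the start of training
        self.scores = {
            m: nn.Param(np.zeros((cfg.heads, self.block + 2)))
            for m in MODALITIES
        }
        self.mod_heads = {m: nn.Dense(cfg.d_f, cfg.n_classes, rng) for m in MODALITIES}
        self.bn = nn.BatchNorm1D(cfg.d_f)
        self.drop = nn.Dropout(cfg.dropout, self.rng)
        self.fc1 = nn.Dense(cfg.d_f, 64, rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Dense(64, cfg.n_classes, rng)

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for m in MODALITIES:
            ps += self.proj[m].params()
        for m in MODALITIES:
            ps.append(self.scores[m])
        for m in MODALITIES:
            ps += self.mod_heads[m].params()
        ps += self.bn.params() + self.fc1.params() + self.fc2.params()
        return ps

    def param_blocks(self) -> list[str]:
        """Block label of every entry of params(), in order: which role
        trains which parameters (used for role-aware aggregation)."""
        labels: list[str] = []
        for m in MODALITIES:
            labels += [f"proj_{m}"] * len(self.proj[m].params())
        for m in MODALITIES:
            labels.append(f"score_{m}")
        for m in MODALITIES:
            labels += [f"head_{m}"] * len(self.mod_heads[m].params())
        labels += ["classifier"] * len(
            self.bn.params() + self.fc1.params() + self.fc2.params()
        )
        return labels

    def single_modality_params(self, modality: str) -> list[nn.Param]:
        """Parameters a single-modality client trains: its projection plus
        the shared classifier (attention is degenerate at weight 1)."""
        return (self.proj[modality].params() + self.bn.params()
                + self.fc1.params() + self.fc2.params())

    def get_theta(self) -> np.ndarray:
        return nn.params_to_vector(self.params())

    def set_theta(self, theta: np.ndarray) -> None:
        nn.vector_to_params(theta, self.params())

    #: parameters of the "dense layer" carrying the extra L2 penalty
    def dense_params(self) -> list[nn.Param]:
        return self.fc1.params()

    # -- forward pieces -----------------------------------------------------

    def _classifier_forward(self, F: np.ndarray, train: bool) -> np.ndarray:
        out = self.bn.forward(F, train=train)
        out = self.drop.forward(out, train=train)
        out = self.relu.forward(self.fc1.forward(out, train=train), train=train)
        return self.fc2.forward(out, train=train)

    def _classifier_backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.fc2.backward(dlogits)
        d = self.fc1.backward(self.relu.backward(d))
        return self.bn.backward(self.drop.backward(d))

    def forward(
        self,
        latents: dict[str, np.ndarray],
        mask: dict[str, bool] | None = None,
        train: bool = False,
    ):
        """Full fused forward pass for a batch.

        Returns (fused_logits, per_modality_logits, alpha (B, M), z (B, M, heads),
        cache) where alpha columns follow MODALITIES order; masked modalities
        have alpha identically 0.
        """
        mask = {m: True for m in MODALITIES} if mask is None else mask
        avail = [m for m in MODALITIES if mask.get(m, False) and m in latents]
        if not avail:
            raise ValueError("no available modality")
        B = next(iter(latents.values())).shape[0]
        Hs = {m: self.proj[m].forward(latents[m], train=train) for m in avail}
        Q = {m: _batch_quality(Hs[m]) for m in avail}

        heads, block = self.cfg.heads, self.block
        z = np.full((B, len(MODALITIES), heads), -np.inf)
        for mi, m in enumerate(MODALITIES):
            if m not in avail:
                continue
            for k in range(heads):
                hk = Hs[m][:, k * block:(k + 1) * block]
                ext = np.concatenate([hk, Q[m]], axis=1)
                z[:, mi, k] = (ext @ self.scores[m].value[k]) / self.cfg.temperature
        alpha = _softmax(z, axis=1)          # softmax over modalities per head
        alpha[np.isnan(alpha)] = 0.0

        F = np.zeros((B, self.cfg.d_f))
        for mi, m in enumerate(MODALITIES):
            if m not in avail:
                continue
            Hm = Hs[m].reshape(B, heads, block)
            F += (alpha[:, mi, :, None] * Hm).reshape(B, self.cfg.d_f)

        fused_logits = self._classifier_forward(F, train=train)
        per_mod_logits = {m: self.mod_heads[m].forward(Hs[m], train=train) for m in avail}
        cache = (latents, Hs, Q, z, alpha, F, avail)
        return fused_logits, per_mod_logits, alpha, z, cache

    def predict_proba(
        self, latents: dict[str, np.ndarray], mask: dict[str, bool] | None = None
    ) -> np.ndarray:
        fused_logits, _, _, _, _ = self.forward(latents, mask=mask, train=False)
        return _softmax(fused_logits)

    # -- single-modality path (clients 1-9: attention degenerate at 1) ------

    def forward_single(self, modality: str, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.proj[modality].forward(x, train=train)
        self._single_cache = modality
        return self._classifier_forward(h, train=train)

    def backward_single(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self._classifier_backward(dlogits)
        return self.proj[self._single_cache].backward(dh)

    # -- fused loss + backward ----------------------------------------------

    def loss_and_grad(
        self,
        latents: dict[str, np.ndarray],
        y: np.ndarray,
        loss_cfg: LossConfig,
        mask: dict[str, bool] | None = None,
        train: bool = True,
        backward: bool = True,
    ) -> PredictionOutput:
        """Compute the multi-objective loss and (optionally) accumulate
        gradients for all head parameters."""
        fused_logits, per_mod_logits, alpha, z, cache = self.forward(
            latents, mask=mask, train=train
        )
        latents, Hs, Q, _, _, F, avail = cache
        zA = z[:, [MODALITIES.index(m) for m in avail], :]
        out = total_loss(fused_logits, per_mod_logits, y,
                         zA.reshape(zA.shape[0], -1), loss_cfg)
        if not backward:
            return out
        B = fused_logits.shape[0]
        M = len(avail)
        heads, block = self.cfg.heads, self.block
        y = np.atleast_1d(y)
        p_f = out.probabilities
        onehot = np.zeros_like(p_f)
        onehot[np.arange(B), y] = 1.0

        p_i = {m: _softmax(per_mod_logits[m]) for m in avail}

        # fused-logit gradient: CE + KL flow through p_fused
        dlogits_f = (p_f - onehot) / B
        for m in avail:
            dlogits_f += loss_cfg.lambda_fuse / (B * M) * (p_f - p_i[m])
        dF = self._classifier_backward(dlogits_f)

        dH = {m: np.zeros_like(Hs[m]) for m in avail}

        # per-modality heads: KL w.r.t. modality logits
        logp_f = np.log(np.maximum(p_f, 1e-12))
        for m in avail:
            logp_i = np.log(np.maximum(p_i[m], 1e-12))
            g = logp_i - logp_f
            dlog_i = p_i[m] * (g - (p_i[m] * g).sum(axis=1, keepdims=True))
            dH[m] += self.mod_heads[m].backward(
                loss_cfg.lambda_fuse / (B * M) * dlog_i
            )

        # attention backward, per head block
        dF3 = dF.reshape(B, heads, block)
        idx = [MODALITIES.index(m) for m in avail]
        aA = alpha[:, idx, :]                                # (B, M, heads)
        HA = np.stack([Hs[m].reshape(B, heads, block) for m in avail], axis=1)
        # d alpha_{b,i,k} = dF3_{b,k,:} . H_{b,i,k,:}
        dalpha = np.einsum("bkd,bikd->bik", dF3, HA)
        # softmax over modalities: dz = alpha * (dalpha - sum_j alpha_j dalpha_j)
        dz = aA * (dalpha - (aA * dalpha).sum(axis=1, keepdims=True))
        dz += loss_cfg.lambda_att / B * np.sign(zA)
        da = dz / self.cfg.temperature                       # (B, M, heads)

        for i, m in enumerate(avail):
            Hm = Hs[m].reshape(B, heads, block)
            for k in range(heads):
                ext = np.concatenate([Hm[:, k], Q[m]], axis=1)
                self.scores[m].grad[k] += da[:, i, k] @ ext
                dH_k = da[:, i, k, None] * self.scores[m].value[k][:block]
                dH[m][:, k * block:(k + 1) * block] += dH_k
            # weighted-sum path: dh_i += alpha_i * dF (per head block)
            dH[m] += (aA[:, i, :, None] * dF3).reshape(B, self.cfg.d_f)

        dlat = {m: self.proj[m].backward(dH[m]) for m in avail}
        out.dlatents = dlat  # type: ignore[attr-defined]
        return out

    # -- convenience trainer (used standalone and by the integration node) --

    def fit(
        self,
        latents: dict[str, np.ndarray],
        y: np.ndarray,
        loss_cfg: LossConfig = LossConfig(),
        epochs: int = 20,
        batch_size: int = 32,
        lr: float = 1e-3,
        weight_decay: float = 1e-5,
        seed: int = 0,
    ) -> list[float]:
        """Train the head alone on fixed latents; returns per-epoch mean loss."""
        opt = nn.Adam(self.params(), lr=lr, weight_decay=weight_decay)
        rng = np.random.default_rng(seed)
        n = len(y)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                if len(idx) < 2:
                    continue
                opt.zero_grad()
                out = self.loss_and_grad(
                    {m: X[idx] for m, X in latents.items()}, y[idx], loss_cfg
                )
                opt.step()
                losses.append(out.L_total)
            history.append(float(np.mean(losses)))
        return history
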