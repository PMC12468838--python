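"""Ten-client vertical federation: stratified split, local training
rounds, DP + secure aggregation, and the global update rule.

Clients 1-3 hold text, 4-6 images, 7-9 signals; client 10 is the
integration node.  The *shared* parameter block theta is the fusion head
(projections, attention scores, per-modality logit heads, classifier);
modality encoders are private to their clients and never transmitted.
Labels are part of the shared entity alignment, so every client can train
the shared head against its own modality (attention degenerate at weight
1), while client 10 trains the full quality-aware fusion objective on the
encoded features it receives.

Each round, every client copies theta, runs E local epochs of Adam with a
cosine-annealed learning rate, and transmits its clipped, noised (and,
when enabled, Paillier-encrypted) parameter delta theta_before -
theta_after; the ring-aggregated sum G feeds the global rule
theta <- theta - eta * G.  Clients run sequentially in-process; the
federation is logical, not networked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .encoders import EncoderConfig, ImageEncoder, SignalEncoder, TextEncoder
from .evaluation import (MetricsReport, auc_score, classification_metrics,
                         confidence_stats, rank_clients)
from .features import (SGConfig, fit_zscore, preprocess_image, sg_filter,
                       smote_tomek, zscore)
from .fusion import MODALITIES, FusionConfig, FusionHead, LossConfig, _softmax
from .privacy import PrivacyConfig, encrypt_vector, generate_keypair, \
    privatize_update
from .synthdata import DEFAULT_ROLES, SynthConfig, generate_cohort
from .textproc import build_corpus_stats, embed_text, tokenize, train_word2vec

__all__ = [
    "FedConfig", "GlobalState", "RoundRecord", "ClientState",
    "stratified_split", "local_round", "global_update", "run_federation",
    "FederationRun",
]

@dataclass(frozen=True)
class FedConfig:
    K: int = 10
    T: int = 50                    # global rounds
    E: int = 5                     # local epochs per round
    eta: float = 0.1               # global rate on the aggregated update
    local_lr: float = 1e-4
    lr_min: float = 1e-6
    batch: int = 32
    adam_betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-5
    dense_l2: float = 1e-4         # extra L2 on the classifier dense layer
    split_fraction: float = 0.8
    aggregation: str = "sum"       # "sum", "mean" (/K), or "role"
    smote: bool = True
    w2v_epochs: int = 25
    seed: int = 0


@dataclass
class RoundRecord:
    round: int
    per_client_loss: dict[int, float]    # mean local loss during adaptation
    mean_loss: float
    global_loss: float                   # loss of the broadcast theta_t
    aggregate_norm: float


@dataclass
class GlobalState:
    theta: np.ndarray
    round: int = 0
    history: list[RoundRecord] = field(default_factory=list)


@dataclass
class ClientState:
    client_id: int
    modality: str | None
    encoder: object | None
    head: FusionHead
    X_train: np.ndarray | None
    y_train: np.ndarray | None
    X_test: np.ndarray | None
    y_test: np.ndarray
    enc_opt: nn.Adam | None = None


def stratified_split(
    labels: np.ndarray, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per class, floor(fraction * n_class) indices go to train (shuffled
    within class); the rest to test.  Disjoint and exhaustive."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        rng.shuffle(idx)
        n_train = int(np.floor(fraction * len(idx) + 1e-9))
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def global_update(state: GlobalState, aggregate: np.ndarray, eta: float) -> GlobalState:
    """theta_{t+1} = theta_t - eta * G; increments the round counter."""
    aggregate = np.asarray(aggregate, dtype=np.float64)
    if aggregate.shape != state.theta.shape:
        raise ValueError(
            f"aggregate shape {aggregate.shape} != theta shape {state.theta.shape}"
        )
    state.theta = state.theta - eta * aggregate
    state.round += 1
    return state


def _ce_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    p = _softmax(logits)
    B = len(y)
    loss = float(-np.log(np.maximum(p[np.arange(B), y], 1e-12)).mean())
    onehot = np.zeros_like(p)
    onehot[np.arange(B), y] = 1.0
    return loss, (p - onehot) / B


def _global_loss(client: ClientState, theta, loss_cfg, fusion_latents=None) -> float:
    """Loss of the broadcast parameters on a client's training data before
    local adaptation -- the global convergence measure.

    Uses full-batch batch-norm statistics (dropout off); the head's running
    statistics and dropout rate are restored afterwards, so the measurement
    does not perturb training.  Evaluated on a fixed subsample of at most
    256 training records per client to keep the per-round cost small.
    """
    head = client.head
    head.set_theta(theta)
    bn_state = (head.bn.running_mean.copy(), head.bn.running_var.copy())
    p_drop = head.drop.p
    head.drop.p = 0.0
    sub = slice(0, 256)
    try:
        if client.modality is None:
            out = head.loss_and_grad(
                {m: X[sub] for m, X in fusion_latents.items()},
                client.y_train[sub], loss_cfg, train=True, backward=False)
            return out.L_total
        latent = client.encoder.forward(client.X_train[sub], train=False)
        logits = head.forward_single(client.modality, latent, train=True)
        return _ce_loss_and_grad(logits, client.y_train[sub])[0]
    finally:
        head.bn.running_mean, head.bn.running_var = bn_state
        head.drop.p = p_drop


def local_round(
    client: ClientState,
    theta: np.ndarray,
    privacy_cfg: PrivacyConfig,
    fed_cfg: FedConfig,
    round_t: int,
    loss_cfg: LossConfig,
    fusion_latents: dict[str, np.ndarray] | None = None,
    public_key=None,
):
    """One client's local phase: E epochs of minibatch Adam starting from
    the broadcast theta; returns the (privatized, optionally encrypted)
    update direction theta_before - theta_after and the mean local loss.

    Clients 1-9 minimize cross-entropy of the shared head on their single
    projected modality; the integration node minimizes the full
    multi-objective fusion loss on the encoded features it received.
    """
    head = client.head
    head.set_theta(theta)
    lr_t = nn.cosine_lr(fed_cfg.local_lr, round_t, fed_cfg.T, fed_cfg.lr_min)
    trainable = (head.params() if client.modality is None
                 else head.single_modality_params(client.modality))
    opt = nn.Adam(trainable, lr=lr_t, betas=fed_cfg.adam_betas,
                  weight_decay=fed_cfg.weight_decay)
    rng = np.random.default_rng([fed_cfg.seed, round_t, client.client_id])

    if client.modality is None:
        X_dict, y = fusion_latents, client.y_train
        n = len(y)
    else:
        X_dict, y = None, client.y_train
        n = len(y)
    if n == 0:
        raise ValueError(f"client {client.client_id} has no local data")

    losses = []
    for _ in range(fed_cfg.E):
        order = rng.permutation(n)
        for start in range(0, n, fed_cfg.batch):
            idx = order[start:start + fed_cfg.batch]
            if len(idx) < 2:
                continue
            opt.zero_grad()
            if client.enc_opt is not None:
                client.enc_opt.zero_grad()
            if client.modality is None:
                out = head.loss_and_grad(
                    {m: X[idx] for m, X in X_dict.items()}, y[idx], loss_cfg,
                    train=True,
                )
                losses.append(out.L_total)
            else:
                latent = client.encoder.forward(client.X_train[idx], train=True)
                logits = head.forward_single(client.modality, latent, train=True)
                loss, dlogits = _ce_loss_and_grad(logits, y[idx])
                dlatent = head.backward_single(dlogits)
                client.encoder.backward(dlatent)
                losses.append(loss)
            for p in head.dense_params():
                p.grad += fed_cfg.dense_l2 * p.value
            opt.step()
            if client.enc_opt is not None:
                client.enc_opt.step(lr=lr_t)

    if not losses:   # E = 0: report the loss of the broadcast parameters
        if client.modality is None:
            out = head.loss_and_grad(X_dict, y, loss_cfg, train=False, backward=False)
            losses = [out.L_total]
        else:
            latent = client.encoder.forward(client.X_train, train=False)
            logits = head.forward_single(client.modality, latent, train=False)
            losses = [_ce_loss_and_grad(logits, y)[0]]

    delta = theta - head.get_theta()
    noise_seed = int(rng.integers(2**31))
    update = privatize_update(delta, privacy_cfg, noise_seed)
    if privacy_cfg.encrypt:
        if public_key is None:
            raise ValueError("encryption requested but no public key provided")
        payload = encrypt_vector(update.g_tilde, public_key, privacy_cfg.scale,
                                 np.random.default_rng(noise_seed + 1))
    else:
        payload = update.g_tilde
    return payload, float(np.mean(losses))


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class FederationRun:
    """Everything the evaluation and ablation stages need from a run."""

    global_state: GlobalState
    report: MetricsReport
    head: FusionHead                      # integration node's head, final theta
    test_latents: dict[str, np.ndarray]
    y_test: np.ndarray
    fused_probabilities: np.ndarray
    auc: float
    clients: dict[int, ClientState]


def _prepare_modality_features(
    cohort, train_idx, test_idx, enc_cfg: EncoderConfig, fed_cfg: FedConfig,
    sg_cfg: SGConfig,
):
    """Per-modality preprocessing fitted on the training split only."""
    notes = [r.note for r in cohort]
    docs = [tokenize(t) for t in notes]
    train_docs = [docs[i] for i in train_idx]
    w2v = train_word2vec(train_docs, dim=enc_cfg.text_in,
                         epochs=fed_cfg.w2v_epochs, seed=fed_cfg.seed)
    stats = build_corpus_stats(train_docs)
    X_text = np.array([embed_text(t, stats, w2v) for t in notes])
    norm_t = fit_zscore(X_text[train_idx])
    X_text = zscore(X_text, norm_t)

    # CLAHE at the native render resolution (8x8 tile grid), then resize to
    # the encoder's input side -- equalizing after downsampling to a very
    # small raster would flatten the regional disc/cup brightness cues
    from skimage.transform import resize as _resize
    native = cohort[0].image.shape[0]
    X_img = np.array([preprocess_image(r.image, target_size=native) for r in cohort])
    if native != enc_cfg.image_size:
        X_img = np.array([
            _resize(im, (enc_cfg.image_size, enc_cfg.image_size, 3),
                    anti_aliasing=True) for im in X_img
        ])

    X_sig = np.array([sg_filter(r.signal, sg_cfg) for r in cohort])
    norm_s = fit_zscore(X_sig[train_idx])
    X_sig = zscore(X_sig, norm_s)
    return {"text": X_text, "image": X_img, "signal": X_sig}


def _client_latents(clients, X_by_mod, idx, train=False):
    """Encoded features received by the integration node: for each
    modality, the mean latent over all clients holding that modality
    (their encoders stay aligned through the shared projection they are
    jointly trained against, so averaging acts as an encoder ensemble)."""
    out = {}
    for m in MODALITIES:
        holders = [c for c in clients.values() if c.modality == m]
        X = X_by_mod[m][idx]
        acc = None
        for holder in holders:
            chunks = [holder.encoder.forward(X[s:s + 128], train=train)
                      for s in range(0, len(X), 128)]
            lat = np.vstack(chunks)
            acc = lat if acc is None else acc + lat
        out[m] = acc / len(holders)
    return out


def run_federation(
    fed_cfg: FedConfig,
    privacy_cfg: PrivacyConfig,
    synth_cfg: SynthConfig | None = None,
    cohort=None,
    enc_cfg: EncoderConfig = EncoderConfig(),
    fusion_cfg: FusionConfig = FusionConfig(),
    loss_cfg: LossConfig = LossConfig(),
    sg_cfg: SGConfig = SGConfig(),
) -> FederationRun:
    """Generate/load data, train T federated rounds, evaluate per client.

    Returns a :class:`FederationRun`; its ``report`` has the per-client
    metric/rank table and its ``head``/``test_latents`` feed the
    missing-modality ablation.
    """
    if cohort is None:
        if synth_cfg is None:
            raise ValueError("provide either a cohort or a SynthConfig")
        cohort = generate_cohort(synth_cfg)
    labels = np.array([r.label for r in cohort], dtype=int)
    train_idx, test_idx = stratified_split(labels, fed_cfg.split_fraction, fed_cfg.seed)

    X_by_mod = _prepare_modality_features(cohort, train_idx, test_idx, enc_cfg,
                                          fed_cfg, sg_cfg)

    in_dims = {"text": enc_cfg.text_out, "image": enc_cfg.image_out,
               "signal": enc_cfg.signal_out}
    encoder_types = {"text": TextEncoder, "image": ImageEncoder, "signal": SignalEncoder}

    clients: dict[int, ClientState] = {}
    for cid, modality in DEFAULT_ROLES.items():
        head = FusionHead(fusion_cfg, in_dims)
        if modality is None:
            clients[cid] = ClientState(
                client_id=cid, modality=None, encoder=None, head=head,
                X_train=None, y_train=labels[train_idx],
                X_test=None, y_test=labels[test_idx],
            )
            continue
        enc = encoder_types[modality](replace(enc_cfg, seed=fed_cfg.seed * 1000 + cid))
        X = X_by_mod[modality]
        X_tr, y_tr = X[train_idx], labels[train_idx]
        if fed_cfg.smote:
            flat = X_tr.reshape(len(X_tr), -1)
            flat_rs, y_rs = smote_tomek(flat, y_tr, seed=fed_cfg.seed * 100 + cid)
            X_tr = flat_rs.reshape((-1,) + X.shape[1:])
            y_tr = y_rs
        clients[cid] = ClientState(
            client_id=cid, modality=modality, encoder=enc, head=head,
            X_train=X_tr, y_train=y_tr,
            X_test=X[test_idx], y_test=labels[test_idx],
            enc_opt=nn.Adam(enc.params(), lr=fed_cfg.local_lr,
                            betas=fed_cfg.adam_betas,
                            weight_decay=fed_cfg.weight_decay),
        )

    ref_head = FusionHead(fusion_cfg, in_dims)
    theta0 = ref_head.get_theta()
    state = GlobalState(theta=theta0)

    # role-aware averaging: each parameter block's summed delta is divided
    # by the number of clients whose role trains that block (vertical
    # parameter sparsity: only the integration node trains the attention)
    mod_counts = {m: sum(1 for v in DEFAULT_ROLES.values() if v == m)
                  for m in MODALITIES}
    block_count = {"classifier": fed_cfg.K}
    for m in MODALITIES:
        block_count[f"proj_{m}"] = mod_counts[m] + 1
        block_count[f"score_{m}"] = 1
        block_count[f"head_{m}"] = 1
    role_counts = np.concatenate([
        np.full(p.value.size, block_count[label], dtype=np.float64)
        for label, p in zip(ref_head.param_blocks(), ref_head.params())
    ])

    keys = None
    if privacy_cfg.encrypt:
        keys = generate_keypair(privacy_cfg.key_bits, seed=fed_cfg.seed)

    for t in range(fed_cfg.T):
        fusion_latents = _client_latents(clients, X_by_mod, train_idx, train=False)
        g_losses = [
            _global_loss(clients[cid], state.theta, loss_cfg,
                         fusion_latents if clients[cid].modality is None else None)
            for cid in sorted(clients)
        ]
        updates, losses = [], {}
        for cid in sorted(clients):
            payload, loss = local_round(
                clients[cid], state.theta, privacy_cfg, fed_cfg, t, loss_cfg,
                fusion_latents=fusion_latents if clients[cid].modality is None else None,
                public_key=keys.public if keys else None,
            )
            updates.append(payload)
            losses[cid] = loss
        if privacy_cfg.encrypt:
            from .privacy import AggregationServer, add_cipher_vectors
            running = updates[0]
            for enc_up in updates[1:]:
                running = add_cipher_vectors(running, enc_up, keys.public)
            aggregate = AggregationServer(keys).decrypt_aggregate(running)
        else:
            aggregate = np.sum(updates, axis=0)
        if fed_cfg.aggregation == "mean":
            aggregate = aggregate / fed_cfg.K
        elif fed_cfg.aggregation == "role":
            aggregate = aggregate / role_counts
        state = global_update(state, aggregate, fed_cfg.eta)
        state.history.append(RoundRecord(
            round=t + 1, per_client_loss=losses,
            mean_loss=float(np.mean(list(losses.values()))),
            global_loss=float(np.mean(g_losses)),
            aggregate_norm=float(np.linalg.norm(aggregate)),
        ))

    # ---- final evaluation on the held-out test split ----
    rows = []
    for cid in sorted(clients):
        c = clients[cid]
        c.head.set_theta(state.theta)
        if c.modality is None:
            continue
        latent = c.encoder.forward(c.X_test, train=False)
        logits = c.head.forward_single(c.modality, latent, train=False)
        proba = _softmax(logits)
        y_pred = proba.argmax(axis=1)
        acc, prec, rec, f1 = classification_metrics(c.y_test, y_pred)
        loss = float(-np.log(np.maximum(
            proba[np.arange(len(c.y_test)), c.y_test], 1e-12)).mean())
        mu, sd = confidence_stats(proba)
        rows.append({"client": cid, "modality": c.modality, "accuracy": acc,
                     "precision": prec, "recall": rec, "f1": f1, "loss": loss,
                     "conf_mu": mu, "conf_sigma": sd})

    integration = clients[10]
    integration.head.set_theta(state.theta)
    test_latents = _client_latents(clients, X_by_mod, test_idx, train=False)
    proba = integration.head.predict_proba(test_latents)
    y_pred = proba.argmax(axis=1)
    acc, prec, rec, f1 = classification_metrics(integration.y_test, y_pred)
    loss = float(-np.log(np.maximum(
        proba[np.arange(len(integration.y_test)), integration.y_test], 1e-12)).mean())
    mu, sd = confidence_stats(proba)
    rows.append({"client": 10, "modality": "fusion", "accuracy": acc,
                 "precision": prec, "recall": rec, "f1": f1, "loss": loss,
                 "conf_mu": mu, "conf_sigma": sd})

    report = rank_clients(pd.DataFrame(rows))
    auc = auc_score(integration.y_test, proba[:, 1])
    return FederationRun(
        global_state=state, report=report, head=integration.head,
        test_latents=test_latents, y_test=integration.y_test,
        fused_probabilities=proba, auc=auc, clients=clients,
    )
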