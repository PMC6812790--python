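"""Context-adaptive convolutional detector.

A main convolutional branch turns a 150 ms time-frequency clip into a
64-dimensional embedding z(t, n); an auxiliary branch turns the active
long-term context slice mu(t, q, f) (9 quantiles x 32 bands) into a
64-dimensional embedding z_aux(t, n). Four merge formulations combine them
into a probability of event presence y(t):

* ``baseline`` —  y = sigma(b + w . z)                  (static dense layer)
* ``aw``       —  y = sigma(b + z_aux . z)              (adaptive weights)
* ``at``       —  y = sigma(w_aux . z_aux + w . z)      (adaptive threshold)
* ``moe``      —  y = sigma(b + sum_k g_k(z_aux) e_k(z)) (mixture of experts)

where for MoE the 64 nodes are reshaped into M=16 mixture indices x K=4
experts via n = K*m + k, the gate g = softmax over experts of
alpha(k) = b_aux(k) + sum_m w_aux~(m,k) z_aux~(m,k), and
e_k = sum_m w~(m,k) z~(m,k).

Every formulation contains the static baseline as a special case, so
context adaptation can only enlarge the model family.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .frontend import PcenParams, StftConfig

#: Clip geometry: 150 ms at hop 32 / 22,050 Hz spans 104 spectrogram frames.
CLIP_FRAMES = 104
CLIP_BANDS = 128
EMBEDDING_DIM = 64
N_EXPERTS = 4
AUX_QUANTILES = 9
AUX_BANDS = 32
FORMULATIONS = ("baseline", "aw", "at", "moe")
L2_DENSE = 1e-3


@dataclass
class ClipBatch:
    """A batch of training/evaluation clips with aligned context slices."""

    clips: np.ndarray                    # (B, 104, 128)
    labels: np.ndarray                   # (B,), binary
    context: np.ndarray | None = None    # (B, 9, 32) or None
    sensor_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.clips = np.asarray(self.clips)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.clips.ndim != 3 or self.clips.shape[1:] != (CLIP_FRAMES, CLIP_BANDS):
            raise ValueError(f"clips must be (B, {CLIP_FRAMES}, {CLIP_BANDS})")
        if not np.isin(self.labels, (0.0, 1.0)).all():
            raise ValueError("labels must be binary")
        if self.context is not None:
            self.context = np.asarray(self.context)
            if self.context.shape != (len(self.labels), AUX_QUANTILES, AUX_BANDS):
                raise ValueError("context must be (B, 9, 32)")

    def __len__(self):
        return len(self.labels)

    def take(self, idx) -> "ClipBatch":
        ctx = None if self.context is None else self.context[idx]
        sids = [self.sensor_ids[i] for i in idx] if self.sensor_ids else []
        return ClipBatch(self.clips[idx], self.labels[idx], ctx, sids)


class ContextAdaptiveDetector:
    """The detector model: parameters, forward/backward passes, persistence.

    Parameters are float32 by default; tests that probe gradients use
    ``dtype=np.float64``. Inputs are standardized with scalar statistics
    (``feature_mean/std``, ``context_mean/std``) fitted on the training set
    and stored with the model, so a checkpoint is self-contained.
    """

    def __init__(self, formulation: str = "baseline", seed: int = 0,
                 dtype=np.float32, representation: str = "pcen",
                 pcen_params: PcenParams | None = None,
                 stft_config: StftConfig | None = None):
        if formulation not in FORMULATIONS:
            raise ValueError(f"unknown formulation {formulation!r}")
        self.formulation = formulation
        self.dtype = np.dtype(dtype)
        self.representation = representation
        self.pcen_params = pcen_params or PcenParams.outdoor()
        self.stft_config = stft_config or StftConfig()
        self.feature_mean, self.feature_std = 0.0, 1.0
        self.context_mean, self.context_std = 0.0, 1.0
        self.params = self._init_params(np.random.default_rng(seed))

    # -- initialization -----------------------------------------------------

    def _init_params(self, rng) -> dict:
        d = self.dtype
        g = nn.glorot_uniform
        p = {
            "c1_W": g(rng, (5, 5, 1, 24), 25, 24 * 25, d),
            "c1_b": np.zeros(24, d),
            "c2_W": g(rng, (5, 5, 24, 24), 24 * 25, 24 * 25, d),
            "c2_b": np.zeros(24, d),
            "c3_W": g(rng, (5, 5, 24, 48), 24 * 25, 48 * 25, d),
            "c3_b": np.zeros(48, d),
            "d1_W": g(rng, (1200, 64), 1200, 64, d),
            "d1_b": np.zeros(64, d),
        }
        if self.uses_context:
            p.update({
                "a1_W": g(rng, (8, 32), 32, 8, d),
                "a1_b": np.zeros(8, d),
                "a2_W": g(rng, (72, 64), 72, 64, d),
                "a2_b": np.zeros(64, d),
            })
        f = self.formulation
        if f == "baseline":
            p["w"] = g(rng, (64,), 64, 1, d)
            p["b"] = np.zeros(1, d)
        elif f == "aw":
            p["b"] = np.zeros(1, d)
        elif f == "at":
            p["w"] = g(rng, (64,), 64, 1, d)
            p["w_aux"] = g(rng, (64,), 64, 1, d)
        elif f == "moe":
            p["w"] = g(rng, (64,), 64, 1, d)
            p["b"] = np.zeros(1, d)
            p["w_aux_m"] = g(rng, (16, 4), 16, 4, d)
            p["b_aux"] = np.zeros(4, d)
        return p

    @property
    def uses_context(self) -> bool:
        return self.formulation != "baseline"

    # -- forward ------------------------------------------------------------

    def forward_main(self, clips: np.ndarray):
        """(B, 104, 128) clips -> (z (B, 64), cache)."""
        if clips.ndim == 2:
            clips = clips[None]
        if clips.shape[1:] != (CLIP_FRAMES, CLIP_BANDS):
            raise ValueError("clip must be 104 frames x 128 bands")
        p = self.params
        x = clips.astype(self.dtype)                     # copy: mutated below
        x -= self.dtype.type(self.feature_mean)
        x /= self.dtype.type(self.feature_std)
        x = x.reshape(*x.shape, 1)                       # (B,104,128,1) NHWC
        h1, c1 = nn.conv2d_forward(x, p["c1_W"], p["c1_b"])
        p1, q1 = nn.relu_pool_forward(h1, 4, 2)
        h2, c2 = nn.conv2d_forward(p1, p["c2_W"], p["c2_b"])
        p2, q2 = nn.relu_pool_forward(h2, 4, 2)
        h3, c3 = nn.conv2d_forward(p2, p["c3_W"], p["c3_b"])
        r3, m3 = nn.relu_forward(h3)
        flat = r3.reshape(r3.shape[0], -1)               # (B, 1200)
        h4, c4 = nn.dense_forward(flat, p["d1_W"], p["d1_b"])
        z, m4 = nn.relu_forward(h4)
        cache = (c1, q1, c2, q2, c3, m3, r3.shape, c4, m4)
        return z, cache

    def backward_main(self, dz, cache):
        p = self.params
        c1, q1, c2, q2, c3, m3, r3_shape, c4, m4 = cache
        g = {}
        dh4 = nn.relu_backward(dz, m4)
        dflat, g["d1_W"], g["d1_b"] = nn.dense_backward(dh4, p["d1_W"], c4)
        g["d1_W"] += 2 * L2_DENSE * p["d1_W"]
        dr3 = dflat.reshape(r3_shape)
        dh3 = nn.relu_backward(dr3, m3)
        dp2, g["c3_W"], g["c3_b"] = nn.conv2d_backward(dh3, p["c3_W"], c3)
        dh2 = nn.relu_pool_backward(dp2, q2)
        dp1, g["c2_W"], g["c2_b"] = nn.conv2d_backward(dh2, p["c2_W"], c2)
        dh1 = nn.relu_pool_backward(dp1, q1)
        _, g["c1_W"], g["c1_b"] = nn.conv2d_backward(dh1, p["c1_W"], c1,
                                                     need_dx=False)
        return g

    def forward_aux(self, context: np.ndarray):
        """(B, 9, 32) context slices -> (z_aux (B, 64), cache).

        The conv stage applies 8 kernels of size 1x32 (one full-band
        template per kernel, shared across the 9 quantile rows), yielding
        9 x 8 = 72 activations, followed by a 72 -> 64 dense layer.
        """
        if context.ndim == 2:
            context = context[None]
        if context.shape[1:] != (AUX_QUANTILES, AUX_BANDS):
            raise ValueError("context slice must be 9 x 32")
        p = self.params
        x = ((context - self.context_mean) / self.context_std).astype(self.dtype)
        h1 = np.einsum("bqf,kf->bqk", x, p["a1_W"]) + p["a1_b"]
        r1, m1 = nn.relu_forward(h1)
        flat = r1.reshape(r1.shape[0], -1)               # (B, 72)
        h2, c2 = nn.dense_forward(flat, p["a2_W"], p["a2_b"])
        z_aux, m2 = nn.relu_forward(h2)
        cache = (x, m1, r1.shape, c2, m2)
        return z_aux, cache

    def backward_aux(self, dz_aux, cache):
        p = self.params
        x, m1, r1_shape, c2, m2 = cache
        g = {}
        dh2 = nn.relu_backward(dz_aux, m2)
        dflat, g["a2_W"], g["a2_b"] = nn.dense_backward(dh2, p["a2_W"], c2)
        dr1 = dflat.reshape(r1_shape)
        dh1 = nn.relu_backward(dr1, m1)
        g["a1_W"] = np.einsum("bqk,bqf->kf", dh1, x)
        g["a1_b"] = dh1.sum(axis=(0, 1))
        return g

    # -- merge --------------------------------------------------------------

    def merge(self, z: np.ndarray, z_aux: np.ndarray | None):
        """Combine branch embeddings into (y, logit a, cache)."""
        p, f = self.params, self.formulation
        if f == "baseline":
            a = p["b"][0] + z @ p["w"]
            cache = (z, None)
        elif f == "aw":
            a = p["b"][0] + np.sum(z_aux * z, axis=1)
            cache = (z, z_aux)
        elif f == "at":
            a = z_aux @ p["w_aux"] + z @ p["w"]
            cache = (z, z_aux)
        elif f == "moe":
            B = z.shape[0]
            zt = z.reshape(B, 16, 4)
            zat = z_aux.reshape(B, 16, 4)
            alpha = p["b_aux"] + np.einsum("bmk,mk->bk", zat, p["w_aux_m"])
            gate = nn.softmax(alpha, axis=1)
            wt = p["w"].reshape(16, 4)
            e = np.einsum("bmk,mk->bk", zt, wt)
            a = p["b"][0] + np.sum(gate * e, axis=1)
            cache = (z, z_aux, gate, e)
        y = nn.sigmoid(a)
        return y, a, cache

    def backward_merge(self, da, cache):
        """da = dL/d(logit). Returns (param grads, dz, dz_aux)."""
        p, f = self.params, self.formulation
        g = {}
        if f == "baseline":
            z, _ = cache
            g["w"] = z.T @ da
            g["b"] = np.array([da.sum()], dtype=self.dtype)
            return g, da[:, None] * p["w"], None
        if f == "aw":
            z, z_aux = cache
            g["b"] = np.array([da.sum()], dtype=self.dtype)
            return g, da[:, None] * z_aux, da[:, None] * z
        if f == "at":
            z, z_aux = cache
            g["w"] = z.T @ da
            g["w_aux"] = z_aux.T @ da
            return g, da[:, None] * p["w"], da[:, None] * p["w_aux"]
        # moe
        z, z_aux, gate, e = cache
        B = z.shape[0]
        zt, zat = z.reshape(B, 16, 4), z_aux.reshape(B, 16, 4)
        wt = p["w"].reshape(16, 4)
        g["b"] = np.array([da.sum()], dtype=self.dtype)
        dgate = da[:, None] * e
        de = da[:, None] * gate
        dalpha = gate * (dgate - np.sum(dgate * gate, axis=1, keepdims=True))
        g["b_aux"] = dalpha.sum(axis=0)
        g["w_aux_m"] = np.einsum("bmk,bk->mk", zat, dalpha)
        dzat = dalpha[:, None, :] * p["w_aux_m"][None]
        g["w"] = np.einsum("bmk,bk->mk", zt, de).reshape(64)
        dzt = de[:, None, :] * wt[None]
        return g, dzt.reshape(B, 64), dzat.reshape(B, 64)

    # -- end-to-end ---------------------------------------------------------

    def forward(self, clips: np.ndarray, context: np.ndarray | None = None):
        z, main_cache = self.forward_main(clips)
        if self.uses_context:
            if context is None:
                raise ValueError(f"{self.formulation} model requires context")
            z_aux, aux_cache = self.forward_aux(context)
        else:
            z_aux, aux_cache = None, None
        y, a, merge_cache = self.merge(z, z_aux)
        return y, (main_cache, aux_cache, merge_cache)

    def predict(self, clips, context=None, batch_size: int = 256) -> np.ndarray:
        """Probabilities of presence, computed in minibatches."""
        outs = []
        for i in range(0, len(clips), batch_size):
            ctx = None if context is None else context[i:i + batch_size]
            y, _ = self.forward(clips[i:i + batch_size], ctx)
            outs.append(y)
        return np.concatenate(outs)

    def backward(self, da, caches) -> dict:
        main_cache, aux_cache, merge_cache = caches
        grads, dz, dz_aux = self.backward_merge(da.astype(self.dtype),
                                                merge_cache)
        grads.update(self.backward_main(dz, main_cache))
        if self.uses_context:
            grads.update(self.backward_aux(dz_aux, aux_cache))
        return grads

    def loss(self, y, labels) -> tuple[float, np.ndarray]:
        data_loss, da = nn.bce_loss(y, labels)
        reg = L2_DENSE * float(np.sum(self.params["d1_W"].astype(np.float64) ** 2))
        return data_loss + reg, da

    # -- adaptive-threshold reading ------------------------------------------

    def adaptive_threshold_view(self, tau: float,
                                context: np.ndarray) -> np.ndarray:
        """Time-varying threshold equivalent to thresholding an AT model.

        For the AT formulation, [y(t) > tau] is equivalent to comparing the
        static detection function sigma(w . z(t)) with the slowly varying
        threshold sigma(sigma^-1(tau) - w_aux . z_aux(t)) returned here,
        one value per context slice.
        """
        if self.formulation != "at":
            raise ValueError("adaptive_threshold_view requires an AT model")
        if not (0.0 < tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        z_aux, _ = self.forward_aux(context)
        proj = z_aux @ self.params["w_aux"]
        logit_tau = np.log(tau / (1.0 - tau))
        return nn.sigmoid(logit_tau - proj)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Single-file archive: parameters + merge/frontend configuration."""
        config = {
            "formulation": self.formulation,
            "dtype": self.dtype.name,
            "representation": self.representation,
            "pcen_params": asdict(self.pcen_params),
            "stft_config": asdict(self.stft_config),
            "feature_mean": self.feature_mean,
            "feature_std": self.feature_std,
            "context_mean": self.context_mean,
            "context_std": self.context_std,
        }
        buf = io.BytesIO()
        np.savez(buf, **self.params)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(config, indent=2))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ContextAdaptiveDetector":
        with zipfile.ZipFile(path) as zf:
            config = json.loads(zf.read("config.json"))
            with zf.open("params.npz") as fh:
                npz = np.load(io.BytesIO(fh.read()))
                params = {k: npz[k] for k in npz.files}
        model = cls(formulation=config["formulation"],
                    dtype=np.dtype(config["dtype"]),
                    representation=config["representation"],
                    pcen_params=PcenParams(**config["pcen_params"]),
                    stft_config=StftConfig(**config["stft_config"]))
        model.params = params
        model.feature_mean = config["feature_mean"]
        model.feature_std = config["feature_std"]
        model.context_mean = config["context_mean"]
        model.context_std = config["context_std"]
        return model


def classification_accuracy(y_pred, y_true) -> float:
    """Fraction of clips with |y - y_true| strictly below 0.5."""
    y_pred = np.asarray(y_pred, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    if y_pred.shape != y_true.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(y_pred - y_true) < 0.5))


def train(model: ContextAdaptiveDetector, train_batch: ClipBatch,
          val_batch: ClipBatch | None = None, epochs: int = 100,
          batch_size: int = 32, lr: float = 1e-3, patience: int = 20,
          seed: int = 0, standardize: bool = True) -> dict:
    """Minimize binary cross-entropy with Adam; early stop on val accuracy.

    Enforces the leave-one-sensor-out contract: training and validation
    sensors must be disjoint. Deterministic under a fixed seed on a fixed
    platform. Returns a history dict with per-epoch train/val loss and
    accuracy; the model is left at the parameters of the best validation
    epoch (or the last epoch when no validation set is given).
    """
    if len(train_batch) == 0:
        raise ValueError("empty training split")
    if val_batch is not None and train_batch.sensor_ids and val_batch.sensor_ids:
        overlap = set(train_batch.sensor_ids) & set(val_batch.sensor_ids)
        if overlap:
            raise ValueError(f"validation sensors intersect training "
                             f"sensors: {sorted(overlap)}")
    if standardize:
        model.feature_mean = float(train_batch.clips.mean())
        model.feature_std = float(train_batch.clips.std()) or 1.0
        if model.uses_context and train_batch.context is not None:
            model.context_mean = float(train_batch.context.mean())
            model.context_std = float(train_batch.context.std()) or 1.0

    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.params, lr=lr)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_acc, best_params, since_best = -1.0, None, 0
    n = len(train_batch)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, n, batch_size):
            sub = train_batch.take(order[i:i + batch_size])
            y, caches = model.forward(sub.clips, sub.context)
            loss, da = model.loss(y, sub.labels)
            grads = model.backward(da, caches)
            opt.step(model.params, grads)
            epoch_loss += loss * len(sub)
            epoch_correct += int(np.sum(np.abs(y - sub.labels) < 0.5))
        history["train_loss"].append(epoch_loss / n)
        history["train_acc"].append(epoch_correct / n)
        if val_batch is not None:
            yv = model.predict(val_batch.clips, val_batch.context)
            vloss, _ = nn.bce_loss(yv, val_batch.labels)
            vacc = classification_accuracy(yv, val_batch.labels)
            history["val_loss"].append(vloss)
            history["val_acc"].append(vacc)
            if vacc > best_acc:
                best_acc, since_best = vacc, 0
                best_params = {k: v.copy() for k, v in model.params.items()}
            else:
                since_best += 1
                if since_best >= patience:
                    break
    if best_params is not None:
        model.params = best_params
    return history
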