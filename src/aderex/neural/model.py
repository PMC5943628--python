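"""Batched LSTM/BiLSTM(+attention) network with hand-written backprop.

Architecture per candidate pair: each entity's context window (the L tokens
ending at the mention's head token, left-padded at document start) is
embedded, passed through a shared linear projection to the hidden size, and
encoded by that entity's own LSTM (one extra LSTM per direction when
bidirectional; outputs concatenated positionwise to width 2k).  Global
attention optionally refines the final output into the entity
representation; the two representations (plus embedded distance/type
features in the augmented variant) are composed by a tanh MLP whose output
feeds a softmax over relation types.

Everything is float64 numpy; gradients are computed by explicit
backpropagation through time and verified against numerical differentiation
in the test suite.
"""
from __future__ import annotations

import numpy as np

from ..types import ENTITY_TYPES
from .config import N_DISTANCE_BUCKETS, NeuralConfig

PAD_ID = 0
UNK_ID = 1

_SIDES = ("l", "r")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class TrainingDivergedError(RuntimeError):
    pass


class NeuralNetwork:
    """Parameters + forward/backward passes; optimizer-agnostic."""

    def __init__(
        self,
        config: NeuralConfig,
        n_labels: int,
        embedding_matrix: np.ndarray,
    ) -> None:
        self.config = config
        self.n_labels = n_labels
        self.E = np.asarray(embedding_matrix, dtype=float)
        if self.E.shape[1] != config.embedding_dim:
            raise ValueError(
                f"embedding matrix dim {self.E.shape[1]} != config {config.embedding_dim}"
            )
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(config.seed))

    # ------------------------------------------------------------------ init
    def _glorot(self, rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
        s = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return rng.uniform(-s, s, size=shape)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        k, d = cfg.hidden_size, cfg.embedding_dim
        H = cfg.output_width
        p = self.params
        p["proj_W"] = self._glorot(rng, (k, d))
        p["proj_b"] = np.zeros(k)
        p["unk"] = 0.01 * rng.standard_normal(d)
        dirs = ("f", "b") if cfg.bidirectional else ("f",)
        for s in _SIDES:
            for direction in dirs:
                p[f"lstm_{s}{direction}_Wx"] = self._glorot(rng, (4 * k, k))
                p[f"lstm_{s}{direction}_Wh"] = self._glorot(rng, (4 * k, k))
                b = np.zeros(4 * k)
                b[2 * k : 3 * k] = 1.0  # forget-gate bias opens the memory path
                p[f"lstm_{s}{direction}_b"] = b
            if cfg.attention:
                for i in (1, 2, 3, 4):
                    p[f"att_{s}_W{i}"] = self._glorot(rng, (H, H))
                p[f"att_{s}_w"] = self._glorot(rng, (H, 1))[:, 0]
        mlp_in = 2 * H + (4 * cfg.aug_embedding_dim if cfg.augmented else 0)
        p["mlp_W"] = self._glorot(rng, (self.n_labels, mlp_in))
        p["mlp_b"] = np.zeros(self.n_labels)
        if cfg.augmented:
            e = cfg.aug_embedding_dim
            p["emb_tdist"] = 0.1 * rng.standard_normal((N_DISTANCE_BUCKETS, e))
            p["emb_mdist"] = 0.1 * rng.standard_normal((N_DISTANCE_BUCKETS, e))
            p["emb_type"] = 0.1 * rng.standard_normal((len(ENTITY_TYPES), e))
        if cfg.finetune_embeddings:
            p["E"] = self.E  # shared reference; PAD/UNK rows masked in backward

    def _decay_keys(self) -> list[str]:
        return [
            k
            for k, v in self.params.items()
            if v.ndim == 2 and not k.startswith("emb_") and k != "E"
        ]

    # --------------------------------------------------------------- forward
    def _embed(self, ids: np.ndarray) -> np.ndarray:
        E = self.params.get("E", self.E)
        x = E[ids]
        x[ids == UNK_ID] = self.params["unk"]
        return x

    def _lstm_forward(self, key: str, x: np.ndarray) -> tuple[np.ndarray, list]:
        """x: (B, L, k) -> outputs (B, L, k) and per-step cache."""
        Wx, Wh, b = (self.params[f"{key}_Wx"], self.params[f"{key}_Wh"], self.params[f"{key}_b"])
        B, L, k = x.shape
        h = np.zeros((B, k))
        c = np.zeros((B, k))
        outputs = np.empty((B, L, k))
        cache = []
        for t in range(L):
            z = x[:, t] @ Wx.T + h @ Wh.T + b
            i = _sigmoid(z[:, :k])
            g = np.tanh(z[:, k : 2 * k])
            f = _sigmoid(z[:, 2 * k : 3 * k])
            o = _sigmoid(z[:, 3 * k :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x[:, t], h, c, i, g, f, o, tc))
            h, c = h_new, c_new
            outputs[:, t] = h
        return outputs, cache

    def _lstm_backward(
        self, key: str, dH: np.ndarray, cache: list, grads: dict[str, np.ndarray]
    ) -> np.ndarray:
        Wx, Wh = self.params[f"{key}_Wx"], self.params[f"{key}_Wh"]
        B, L, k = dH.shape
        gWx = grads.setdefault(f"{key}_Wx", np.zeros_like(Wx))
        gWh = grads.setdefault(f"{key}_Wh", np.zeros_like(Wh))
        gb = grads.setdefault(f"{key}_b", np.zeros_like(self.params[f"{key}_b"]))
        dx = np.empty((B, L, k))
        dh_next = np.zeros((B, k))
        dc_next = np.zeros((B, k))
        for t in reversed(range(L)):
            x_t, h_prev, c_prev, i, g, f, o, tc = cache[t]
            dh = dH[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), dg * (1 - g**2), df * f * (1 - f), do * o * (1 - o)],
                axis=1,
            )
            gWx += dz.T @ x_t
            gWh += dz.T @ h_prev
            gb += dz.sum(axis=0)
            dx[:, t] = dz @ Wx
            dh_next = dz @ Wh
        return dx

    def _encoder_forward(
        self,
        side: str,
        ids: np.ndarray,
        train: bool,
        rng: np.random.Generator | None,
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Returns (h_repr (B,H), S (B,L,H) post-dropout outputs, cache)."""
        cfg = self.config
        x_emb = self._embed(ids)
        x = x_emb @ self.params["proj_W"].T + self.params["proj_b"]
        in_mask = None
        if train and cfg.input_dropout > 0:
            in_mask = (rng.random(x.shape) >= cfg.input_dropout) / (1 - cfg.input_dropout)
            x = x * in_mask
        Hf, cache_f = self._lstm_forward(f"lstm_{side}f", x)
        cache = {"ids": ids, "x_emb": x_emb, "in_mask": in_mask, "cache_f": cache_f}
        if cfg.bidirectional:
            Hb_rev, cache_b = self._lstm_forward(f"lstm_{side}b", x[:, ::-1])
            cache["cache_b"] = cache_b
            H = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
        else:
            H = Hf
        h_last = H[:, -1]
        if not cfg.attention:
            cache["att"] = None
            return h_last, H, cache
        p = self.params
        W1, W2, W3, W4, w = (
            p[f"att_{side}_W1"], p[f"att_{side}_W2"], p[f"att_{side}_W3"],
            p[f"att_{side}_W4"], p[f"att_{side}_w"],
        )
        M_pre = H @ W1.T + (h_last @ W2.T)[:, None, :]
        M = np.tanh(M_pre)
        scores = M @ w
        a = _softmax(scores)
        z = (a[:, :, None] * H).sum(axis=1)
        hp_pre = z @ W3.T + h_last @ W4.T
        h_repr = np.tanh(hp_pre)
        cache["att"] = {"M": M, "a": a, "z": z, "h_repr": h_repr, "h_last": h_last}
        return h_repr, H, cache

    def _encoder_backward(
        self,
        side: str,
        d_repr: np.ndarray,
        S: np.ndarray,
        cache: dict,
        grads: dict[str, np.ndarray],
    ) -> None:
        cfg = self.config
        p = self.params
        if cfg.attention:
            at = cache["att"]
            W1, W2, W3, W4, w = (
                p[f"att_{side}_W1"], p[f"att_{side}_W2"], p[f"att_{side}_W3"],
                p[f"att_{side}_W4"], p[f"att_{side}_w"],
            )
            M, a, z, h_repr, h_last = at["M"], at["a"], at["z"], at["h_repr"], at["h_last"]
            dhp = d_repr * (1.0 - h_repr**2)
            grads[f"att_{side}_W3"] = grads.get(f"att_{side}_W3", 0) + dhp.T @ z
            grads[f"att_{side}_W4"] = grads.get(f"att_{side}_W4", 0) + dhp.T @ h_last
            dz = dhp @ W3
            dh_last = dhp @ W4
            da = (dz[:, None, :] * S).sum(axis=2)
            dS = a[:, :, None] * dz[:, None, :]
            dscores = a * (da - (da * a).sum(axis=1, keepdims=True))
            grads[f"att_{side}_w"] = grads.get(f"att_{side}_w", 0) + (
                M * dscores[:, :, None]
            ).sum(axis=(0, 1))
            dM = dscores[:, :, None] * w[None, None, :]
            dM_pre = dM * (1.0 - M**2)
            grads[f"att_{side}_W1"] = grads.get(f"att_{side}_W1", 0) + np.einsum(
                "blh,blg->hg", dM_pre, S
            )
            dS = dS + dM_pre @ W1
            dh2 = dM_pre.sum(axis=1)
            grads[f"att_{side}_W2"] = grads.get(f"att_{side}_W2", 0) + dh2.T @ h_last
            dh_last = dh_last + dh2 @ W2
            dS[:, -1] += dh_last
        else:
            dS = np.zeros_like(S)
            dS[:, -1] = d_repr

        k = cfg.hidden_size
        if cfg.bidirectional:
            dx = self._lstm_backward(f"lstm_{side}f", dS[..., :k], cache["cache_f"], grads)
            dx_b = self._lstm_backward(
                f"lstm_{side}b", dS[..., k:][:, ::-1], cache["cache_b"], grads
            )
            dx = dx + dx_b[:, ::-1]
        else:
            dx = self._lstm_backward(f"lstm_{side}f", dS, cache["cache_f"], grads)
        if cache["in_mask"] is not None:
            dx = dx * cache["in_mask"]
        x_emb = cache["x_emb"]
        grads["proj_W"] = grads.get("proj_W", 0) + np.einsum("blk,bld->kd", dx, x_emb)
        grads["proj_b"] = grads.get("proj_b", 0) + dx.sum(axis=(0, 1))
        dx_emb = dx @ self.params["proj_W"]
        ids = cache["ids"]
        unk_mask = ids == UNK_ID
        if unk_mask.any():
            grads["unk"] = grads.get("unk", 0) + dx_emb[unk_mask].sum(axis=0)
        if cfg.finetune_embeddings:
            gE = grads.setdefault("E", np.zeros_like(self.E))
            np.add.at(gE, ids, dx_emb)
            gE[PAD_ID] = 0.0
            gE[UNK_ID] = 0.0

    def _aug_vectors(self, aug: np.ndarray) -> np.ndarray:
        p = self.params
        return np.concatenate(
            [
                p["emb_tdist"][aug[:, 0]],
                p["emb_mdist"][aug[:, 1]],
                p["emb_type"][aug[:, 2]],
                p["emb_type"][aug[:, 3]],
            ],
            axis=1,
        )

    def forward(
        self,
        ids_l: np.ndarray,
        ids_r: np.ndarray,
        aug: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Class probabilities (B, |Y|) and the cache for backward."""
        hl, Sl, cl = self._encoder_forward("l", ids_l, train, rng)
        hr, Sr, cr = self._encoder_forward("r", ids_r, train, rng)
        # output dropout on the entity representations fed to the classifier
        out_masks = [None, None]
        if train and self.config.output_dropout > 0:
            p = self.config.output_dropout
            out_masks = [(rng.random(h.shape) >= p) / (1 - p) for h in (hl, hr)]
            hl = hl * out_masks[0]
            hr = hr * out_masks[1]
        parts = [hl, hr]
        if self.config.augmented:
            if aug is None:
                raise ValueError("augmented model requires aug feature indices")
            parts.append(self._aug_vectors(aug))
        u = np.concatenate(parts, axis=1)
        pre = u @ self.params["mlp_W"].T + self.params["mlp_b"]
        r = np.tanh(pre)
        probs = _softmax(r)
        cache = {"u": u, "r": r, "probs": probs, "Sl": Sl, "Sr": Sr,
                 "cl": cl, "cr": cr, "aug": aug, "out_masks": out_masks}
        return probs, cache

    def loss_and_grads(
        self,
        ids_l: np.ndarray,
        ids_r: np.ndarray,
        labels: np.ndarray,
        aug: np.ndarray | None = None,
        train: bool = True,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy + l2 penalty, and gradients for every parameter."""
        cfg = self.config
        B = ids_l.shape[0]
        probs, cache = self.forward(ids_l, ids_r, aug, train=train, rng=rng)
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(B), labels] + eps)))
        grads: dict[str, np.ndarray] = {}

        dr = probs.copy()
        dr[np.arange(B), labels] -= 1.0
        dr /= B
        r = cache["r"]
        dpre = dr * (1.0 - r**2)
        u = cache["u"]
        grads["mlp_W"] = dpre.T @ u
        grads["mlp_b"] = dpre.sum(axis=0)
        du = dpre @ self.params["mlp_W"]

        H = cfg.output_width
        du_l, du_r = du[:, :H], du[:, H : 2 * H]
        if cache["out_masks"][0] is not None:
            du_l = du_l * cache["out_masks"][0]
            du_r = du_r * cache["out_masks"][1]
        self._encoder_backward("l", du_l, cache["Sl"], cache["cl"], grads)
        self._encoder_backward("r", du_r, cache["Sr"], cache["cr"], grads)
        if cfg.augmented:
            e = cfg.aug_embedding_dim
            d_aug = du[:, 2 * H :]
            aug_idx = cache["aug"]
            g_td = grads.setdefault("emb_tdist", np.zeros_like(self.params["emb_tdist"]))
            g_md = grads.setdefault("emb_mdist", np.zeros_like(self.params["emb_mdist"]))
            g_ty = grads.setdefault("emb_type", np.zeros_like(self.params["emb_type"]))
            np.add.at(g_td, aug_idx[:, 0], d_aug[:, :e])
            np.add.at(g_md, aug_idx[:, 1], d_aug[:, e : 2 * e])
            np.add.at(g_ty, aug_idx[:, 2], d_aug[:, 2 * e : 3 * e])
            np.add.at(g_ty, aug_idx[:, 3], d_aug[:, 3 * e :])

        if cfg.l2 > 0:
            for key in self._decay_keys():
                W = self.params[key]
                loss += 0.5 * cfg.l2 * float(np.sum(W * W))
                grads[key] = grads.get(key, 0) + cfg.l2 * W
        for key in self.params:
            grads.setdefault(key, np.zeros_like(self.params[key]))
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"non-finite loss: {loss}")
        return loss, grads

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}
        if "E" in self.params:
            self.E = self.params["E"]
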