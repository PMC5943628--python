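"""Training loop, prediction and persistence for the neural relation models."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..candidates import CandidateExample
from ..evaluation import score
from ..resources import EmbeddingTable
from ..types import ENTITY_TYPES, NONE_LABEL, AnnotatedDocument, mentions_between, token_distance
from .config import NeuralConfig, distance_bucket
from .model import PAD_ID, UNK_ID, NeuralNetwork, TrainingDivergedError

log = logging.getLogger(__name__)

__all__ = [
    "EncodedDataset", "NeuralModel", "TrainingDivergedError",
    "encode_examples", "train_neural", "predict_neural",
    "save_neural", "load_neural",
]

_TYPE_INDEX = {t: i for i, t in enumerate(ENTITY_TYPES)}


def build_vocab(embeddings: EmbeddingTable) -> tuple[dict[str, int], np.ndarray]:
    """Vocabulary (PAD=0, UNK=1) and the aligned embedding matrix."""
    vocab = {"<pad>": PAD_ID, "<unk>": UNK_ID}
    rows = [np.zeros(embeddings.dimension), np.zeros(embeddings.dimension)]
    for word in embeddings.vocabulary:
        vocab[word] = len(rows)
        rows.append(embeddings.entries[word])
    return vocab, np.stack(rows)


def window_ids(
    doc: AnnotatedDocument, head_token: int, window: int, vocab: dict[str, int]
) -> list[int]:
    """Ids of the ``window`` tokens ending at the head, left-padded."""
    start = head_token - window + 1
    ids = [PAD_ID] * max(0, -start)
    for i in range(max(0, start), head_token + 1):
        ids.append(vocab.get(doc.tokens[i].surface.lower(), UNK_ID))
    return ids


@dataclass
class EncodedDataset:
    ids_l: np.ndarray  # (N, L)
    ids_r: np.ndarray
    aug: np.ndarray  # (N, 4): distance bucket, mention-distance bucket, types
    labels: np.ndarray  # (N,)
    gold: list[str]

    def __len__(self) -> int:
        return self.ids_l.shape[0]


def encode_examples(
    examples: list[CandidateExample],
    docs: dict[str, AnnotatedDocument],
    vocab: dict[str, int],
    label_list: list[str],
    window: int,
) -> EncodedDataset:
    label_index = {lab: i for i, lab in enumerate(label_list)}
    n = len(examples)
    ids_l = np.zeros((n, window), dtype=np.int64)
    ids_r = np.zeros((n, window), dtype=np.int64)
    aug = np.zeros((n, 4), dtype=np.int64)
    labels = np.zeros(n, dtype=np.int64)
    gold = []
    for i, ex in enumerate(examples):
        doc = docs[ex.doc_id]
        left, right = doc.mention(ex.left_id), doc.mention(ex.right_id)
        ids_l[i] = window_ids(doc, left.last, window, vocab)
        ids_r[i] = window_ids(doc, right.last, window, vocab)
        aug[i, 0] = distance_bucket(min(token_distance(doc, left, right), 100))
        aug[i, 1] = distance_bucket(min(mentions_between(doc, left, right), 100))
        aug[i, 2] = _TYPE_INDEX[left.etype]
        aug[i, 3] = _TYPE_INDEX[right.etype]
        labels[i] = label_index.get(ex.label, -1)
        gold.append(ex.label)
    if (labels < 0).any():
        bad = {g for g, li in zip(gold, labels) if li < 0}
        raise ValueError(f"labels outside the model's label set: {bad}")
    return EncodedDataset(ids_l=ids_l, ids_r=ids_r, aug=aug, labels=labels, gold=gold)


class Adam:
    def __init__(self, config: NeuralConfig) -> None:
        self.lr = config.learning_rate
        self.b1, self.b2, self.eps = config.adam_beta1, config.adam_beta2, config.adam_eps
        self.grad_clip = config.grad_clip
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        if self.grad_clip:
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if norm > self.grad_clip:
                scale = self.grad_clip / norm
                grads = {k: g * scale for k, g in grads.items()}
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(params[key])
                self.v[key] = np.zeros_like(params[key])
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            m_hat = self.m[key] / (1 - self.b1**self.t)
            v_hat = self.v[key] / (1 - self.b2**self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class NeuralModel:
    network: NeuralNetwork
    vocab: dict[str, int]
    label_list: list[str]
    config: NeuralConfig
    trace: list[dict]  # epoch, train_loss, dev_macro_f1
    best_epoch: int

    def predict(
        self,
        examples: list[CandidateExample],
        docs: dict[str, AnnotatedDocument],
        batch_size: int = 256,
    ) -> list[str]:
        if not examples:
            return []
        data = encode_examples_for_prediction(examples, docs, self.vocab,
                                              self.label_list, self.config.window)
        return self._predict_encoded(data, batch_size)

    def _predict_encoded(self, data: EncodedDataset, batch_size: int = 256) -> list[str]:
        out: list[str] = []
        for lo in range(0, len(data), batch_size):
            sl = slice(lo, lo + batch_size)
            probs, _ = self.network.forward(
                data.ids_l[sl], data.ids_r[sl],
                data.aug[sl] if self.config.augmented else None,
                train=False,
            )
            out.extend(self.label_list[int(i)] for i in probs.argmax(axis=1))
        return out


def encode_examples_for_prediction(
    examples: list[CandidateExample],
    docs: dict[str, AnnotatedDocument],
    vocab: dict[str, int],
    label_list: list[str],
    window: int,
) -> EncodedDataset:
    """Like :func:`encode_examples` but tolerates labels outside the model set."""
    known = set(label_list)
    placeholder = label_list[0]
    safe = [
        ex if ex.label in known else CandidateExample(
            ex.doc_id, ex.left_id, ex.right_id, placeholder, ex.provenance, ex.source_key
        )
        for ex in examples
    ]
    data = encode_examples(safe, docs, vocab, label_list, window)
    data.gold = [ex.label for ex in examples]
    return data


def train_neural(
    config: NeuralConfig,
    train_examples: list[CandidateExample],
    dev_examples: list[CandidateExample],
    docs: dict[str, AnnotatedDocument],
    embeddings: EmbeddingTable,
) -> NeuralModel:
    """ADAM training with per-epoch dev macro-F1 model selection.

    Dropout is active during training only; the returned model carries the
    parameters of the epoch with the highest dev macro-F1.
    """
    if not train_examples or not dev_examples:
        raise ValueError("train and dev sets must be non-empty")
    vocab, E = build_vocab(embeddings)
    cfg = NeuralConfig(**{**config.to_dict(), "embedding_dim": embeddings.dimension})
    label_list = sorted({ex.label for ex in train_examples})
    train_data = encode_examples(train_examples, docs, vocab, label_list, cfg.window)
    dev_data = encode_examples_for_prediction(dev_examples, docs, vocab, label_list, cfg.window)
    dev_positives = sorted({g for g in dev_data.gold if g != NONE_LABEL})

    net = NeuralNetwork(cfg, n_labels=len(label_list), embedding_matrix=E)
    opt = Adam(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # shuffling + dropout stream
    model = NeuralModel(
        network=net, vocab=vocab, label_list=label_list, config=cfg, trace=[], best_epoch=-1
    )

    n = len(train_data)
    best_f1, best_params, best_epoch = -1.0, None, -1
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss, n_batches = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            loss, grads = net.loss_and_grads(
                train_data.ids_l[idx],
                train_data.ids_r[idx],
                train_data.labels[idx],
                train_data.aug[idx] if cfg.augmented else None,
                train=True,
                rng=rng,
            )
            opt.step(net.params, grads)
            total_loss += loss
            n_batches += 1
        train_loss = total_loss / n_batches
        dev_pred = model._predict_encoded(dev_data)
        dev_f1 = score(dev_data.gold, dev_pred, dev_positives).macro_f1
        model.trace.append({"epoch": epoch, "train_loss": train_loss, "dev_macro_f1": dev_f1})
        log.info("epoch %d: train loss %.4f, dev macro-F1 %.2f", epoch, train_loss, dev_f1)
        if dev_f1 > best_f1:
            best_f1, best_params, best_epoch = dev_f1, net.clone_params(), epoch
    net.set_params(best_params)
    model.best_epoch = best_epoch
    return model


def predict_neural(
    model: NeuralModel,
    examples: list[CandidateExample],
    docs: dict[str, AnnotatedDocument],
) -> list[str]:
    """Argmax of the class probabilities; no stochastic layers at inference."""
    return model.predict(examples, docs)


def save_neural(model: NeuralModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.network.params)
    np.save(directory / "embeddings.npy", model.network.E)
    meta = {
        "config": model.config.to_dict(),
        "vocab": model.vocab,
        "label_list": model.label_list,
        "trace": model.trace,
        "best_epoch": model.best_epoch,
    }
    (directory / "model.json").write_text(json.dumps(meta))


def load_neural(directory: str | Path) -> NeuralModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    cfg = NeuralConfig.from_dict(meta["config"])
    E = np.load(directory / "embeddings.npy")
    net = NeuralNetwork(cfg, n_labels=len(meta["label_list"]), embedding_matrix=E)
    with np.load(directory / "weights.npz") as data:
        net.set_params({k: data[k] for k in data.files})
    return NeuralModel(
        network=net,
        vocab={str(k): int(v) for k, v in meta["vocab"].items()},
        label_list=list(meta["label_list"]),
        config=cfg,
        trace=list(meta["trace"]),
        best_epoch=int(meta["best_epoch"]),
    )
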