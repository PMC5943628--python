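"""Neural model configuration."""
from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class NeuralConfig:
    """Hyperparameters of the LSTM/BiLSTM(+attention) relation classifiers.

    Defaults follow the reference configuration: hidden size 100, context
    window 30, 300-dim word embeddings, 20% input / 30% output dropout,
    l2 strength 1e-3, ADAM with default moments, 30 epochs unidirectional /
    60 for bidirectional or attentional variants.
    """

    hidden_size: int = 100
    window: int = 30
    embedding_dim: int = 300
    bidirectional: bool = False
    attention: bool = False
    augmented: bool = False
    input_dropout: float = 0.20
    output_dropout: float = 0.30
    l2: float = 1e-3
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    grad_clip: float = 5.0  # global gradient-norm ceiling; 0 disables
    max_epochs: int | None = None  # None -> 30 uni / 60 bi-or-attention
    batch_size: int = 32
    aug_embedding_dim: int = 8
    finetune_embeddings: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_size, self.window, self.embedding_dim) < 1:
            raise ValueError("hidden_size, window and embedding_dim must be positive")
        for name in ("input_dropout", "output_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")

    @property
    def epochs(self) -> int:
        if self.max_epochs is not None:
            return self.max_epochs
        return 60 if (self.bidirectional or self.attention) else 30

    @property
    def output_width(self) -> int:
        """Width of the encoder outputs: 2k bidirectional, else k."""
        return self.hidden_size * (2 if self.bidirectional else 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuralConfig":
        return cls(**d)


#: Bucket upper bounds for embedded distance features (last bucket open).
DISTANCE_BUCKETS = (0, 1, 2, 4, 8, 16, 32, 100)


def distance_bucket(d: int) -> int:
    """Bucket index for a (token or mention) distance; 9 buckets total."""
    for i, upper in enumerate(DISTANCE_BUCKETS):
        if d <= upper:
            return i
    return len(DISTANCE_BUCKETS)


N_DISTANCE_BUCKETS = len(DISTANCE_BUCKETS) + 1
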