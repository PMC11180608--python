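"""Match/gap scoring heads.

Two independent convolutional stacks M and G map each sequence's residue
embeddings H (length x d) to transformed embeddings of the same shape; the
pairwise score matrices are then

    mu  = softplus( M(H_X) M(H_Y)^T )   > 0   (match log-odds)
    g   = logsigmoid( G(H_X) G(H_Y)^T ) < 0   (gap log-odds)

The softplus / log-sigmoid activations guarantee the sign constraints for
arbitrary parameters, which penalizes gaps, rewards matches and keeps the
alignment model identifiable.  The reference-scale configuration is eight
convolutional layers of width 1,024 on d = 1,024 inputs; the desk-scale
default used in tests is two layers of width 32 on d = 16.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .diffdp import ScoreMatrices
from .embedder import ResidueEmbeddings

__all__ = ["ScoringHeadConfig", "ScoringHeads", "compute_scores"]


@dataclass(frozen=True)
class ScoringHeadConfig:
    """Architecture of one head stack (M and G share it, not parameters).

    n_layers -- convolutional layers per stack (reference 8, toy 2)
    width -- internal channel width (reference 1024, toy 32)
    d -- residue-embedding dimension in and out (reference 1024, toy 16)
    kernel_size -- receptive field of each convolution (odd; default 5)
    seed -- parameter-initialization seed
    """

    n_layers: int = 2
    width: int = 32
    d: int = 16
    kernel_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_layers, self.width, self.d, self.kernel_size) < 1:
            raise ValueError("all architecture sizes must be positive")


class _ConvStack(nn.Module):
    def __init__(self, config: ScoringHeadConfig, rng: np.random.Generator):
        dims = (
            [config.d]
            + [config.width] * max(0, config.n_layers - 1)
            + [config.d]
        )
        if config.n_layers == 1:
            dims = [config.d, config.d]
        self.convs = [
            nn.Conv1d(dims[i], dims[i + 1], config.kernel_size, rng)
            for i in range(len(dims) - 1)
        ]

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for i, conv in enumerate(self.convs):
            x = conv(x)
            if i < len(self.convs) - 1:
                x = nn.relu(x)
        return x


class ScoringHeads(nn.Module):
    """Trainable M (match) and G (gap) heads with reproducible initialization."""

    def __init__(self, config: ScoringHeadConfig = ScoringHeadConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.match_head = _ConvStack(config, rng)
        self.gap_head = _ConvStack(config, rng)

    def score_tensors(self, hx: np.ndarray, hy: np.ndarray) -> tuple[nn.Tensor, nn.Tensor]:
        """Differentiable (mu, gap) tensors for a pair of embedding matrices."""
        hx = np.asarray(hx, dtype=np.float64)
        hy = np.asarray(hy, dtype=np.float64)
        if hx.ndim != 2 or hy.ndim != 2 or hx.shape[1] != hy.shape[1]:
            raise ValueError("embedding matrices must be 2-D with equal d")
        if hx.shape[1] != self.config.d:
            raise ValueError(
                f"embedding dimension {hx.shape[1]} != model d {self.config.d}"
            )
        tx, ty = nn.constant(hx), nn.constant(hy)
        # pre-activations are clipped to +-30 log-odds so softplus /
        # log-sigmoid never underflow to an exact 0 in double precision and
        # the strict sign guarantees survive arbitrary parameters
        pre_mu = nn.clamp(nn.matmul(self.match_head(tx), self.match_head(ty).T), -30.0, 30.0)
        pre_gap = nn.clamp(nn.matmul(self.gap_head(tx), self.gap_head(ty).T), -30.0, 30.0)
        return nn.softplus(pre_mu), nn.logsigmoid(pre_gap)


def compute_scores(
    hx: ResidueEmbeddings, hy: ResidueEmbeddings, heads: ScoringHeads
) -> ScoreMatrices:
    """Score a pair of sequences: strictly positive mu, strictly negative gap."""
    mu, gap = heads.score_tensors(hx.vectors, hy.vectors)
    return ScoreMatrices(mu=mu.data, gap=gap.data)
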