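"""Negative-instance construction from a promoter-trained Markov background.

The negative side of every balanced dataset follows a fixed recipe: fit an
order-3 Markov chain on promoter sequences, emit 5 kb pseudo-promoters from
it, tile them into non-overlapping windows of the TF's average site length,
and draw equal-size negative samples from the resulting pool to pair with the
TF's verified sites — ten balanced sets per TF, sharing the positives and
differing in the negative draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import decode_dna, encode_dna
from .containers import Instance, InstanceSet

__all__ = [
    "MarkovModel",
    "fit_markov",
    "generate_pseudo_sequence",
    "build_negative_pool",
    "assemble_instance_sets",
    "average_site_length",
]


@dataclass
class MarkovModel:
    """Order-k Markov chain over ACGT.

    ``transition`` has shape (4**order, 4): P(next base | context), context
    encoded base-4 with the oldest base most significant. ``initial`` is the
    observed distribution over order-mers used to seed generation.
    """

    order: int
    transition: np.ndarray
    initial: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        k = 4**self.order
        if self.transition.shape != (k, 4):
            raise ValueError("transition matrix shape inconsistent with order")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")

    def mononucleotide_frequencies(self) -> np.ndarray:
        """Stationary-ish base frequencies, from the initial k-mer distribution."""
        k = self.order
        ctx = self.initial
        freqs = np.zeros(4)
        for pos in range(k):
            digits = (np.arange(4**k) // 4 ** (k - 1 - pos)) % 4
            for b in range(4):
                freqs[b] += ctx[digits == b].sum()
        return freqs / k


def fit_markov(
    promoters: list[str], order: int = 3, pseudocount: float = 1.0
) -> MarkovModel:
    """Fit an order-k chain by transition counting with add-``pseudocount``
    smoothing; the initial distribution is the observed k-mer frequency.

    With ``pseudocount=0`` an unseen context falls back to a uniform draw
    (such contexts are effectively unreachable during generation).
    """
    if not promoters:
        raise ValueError("empty promoter training set")
    n_ctx = 4**order
    counts = np.zeros((n_ctx, 4))
    initial = np.zeros(n_ctx)
    total_len = 0
    weights = 4 ** np.arange(order - 1, -1, -1)
    for seq in promoters:
        idx = encode_dna(seq.upper())
        total_len += len(idx)
        if len(idx) < order + 1:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(idx, order)
        ctx_codes = windows @ weights
        np.add.at(initial, ctx_codes, 1)
        np.add.at(counts, (ctx_codes[:-1], idx[order:]), 1)
    if total_len <= order:
        raise ValueError("total promoter length must exceed the model order")
    if initial.sum() == 0:
        raise ValueError("no context of the requested order observed in training data")
    smoothed = counts + pseudocount
    row_sums = smoothed.sum(axis=1)
    empty = row_sums == 0  # only possible when pseudocount == 0
    smoothed[empty] = 0.25
    row_sums[empty] = 1.0
    return MarkovModel(
        order=order,
        transition=smoothed / row_sums[:, None],
        initial=initial / initial.sum(),
        pseudocount=pseudocount,
    )


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_pseudo_sequence(
    model: MarkovModel, length: int = 5000, seed: int | np.random.Generator | None = None
) -> str:
    """Emit one pseudo-promoter of exactly ``length`` nt from the chain."""
    rng = _as_rng(seed)
    if length <= 0:
        raise ValueError("length must be positive")
    k = model.order
    out = np.empty(length, dtype=np.int8)
    init_cum = model.initial.cumsum()
    trans_cum = model.transition.cumsum(axis=1)
    ctx_code = int(np.searchsorted(init_cum, rng.random() * init_cum[-1], side="right"))
    ctx_code = min(ctx_code, len(init_cum) - 1)
    # spell out the initial context
    first = [(ctx_code // 4 ** (k - 1 - i)) % 4 for i in range(k)]
    n_first = min(k, length)
    out[:n_first] = first[:n_first]
    draws = rng.random(max(0, length - k))
    mask = 4 ** (k - 1)
    for t in range(length - k):
        row = trans_cum[ctx_code]
        b = int(np.searchsorted(row, draws[t] * row[-1], side="right"))
        b = min(b, 3)
        out[k + t] = b
        ctx_code = (ctx_code % mask) * 4 + b
    return decode_dna(out[:length])


def build_negative_pool(
    model: MarkovModel,
    window: int,
    n_sequences: int,
    seed: int | np.random.Generator | None = None,
    sequence_length: int = 5000,
) -> list[str]:
    """Tile pseudo-promoters into non-overlapping ``window``-nt segments.

    The trailing remainder of each pseudo-sequence is discarded; pool order
    is deterministic under the seed.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > sequence_length:
        raise ValueError(
            f"window ({window}) exceeds pseudo-sequence length ({sequence_length})"
        )
    rng = _as_rng(seed)
    pool: list[str] = []
    for _ in range(n_sequences):
        seq = generate_pseudo_sequence(model, sequence_length, rng)
        for start in range(0, sequence_length - window + 1, window):
            pool.append(seq[start : start + window])
    return pool


def average_site_length(positives: list[str]) -> int:
    """Window size for the negative pool: mean positive length, nearest int."""
    if not positives:
        raise ValueError("no positive instances")
    return int(round(float(np.mean([len(p) for p in positives]))))


def assemble_instance_sets(
    positives: list[str],
    pool: list[str],
    n_sets: int = 10,
    seed: int | np.random.Generator | None = None,
    tf_id: str = "TF",
) -> list[InstanceSet]:
    """Build ``n_sets`` balanced sets: all positives plus an equal-size random
    draw from the negative pool.

    Negatives are drawn without replacement within a set and independently
    (with replacement) across sets; positives are identical in every set.
    """
    if not positives:
        raise ValueError("no positive instances")
    if len(pool) < len(positives):
        raise ValueError(
            f"negative pool of size {len(pool)} is smaller than the "
            f"{len(positives)} positives; need at least {len(positives)}"
        )
    rng = _as_rng(seed)
    streams = rng.spawn(n_sets)
    sets = []
    for s, sub_rng in enumerate(streams, start=1):
        chosen = sub_rng.choice(len(pool), size=len(positives), replace=False)
        instances = [
            Instance(f"{tf_id}_pos_{i}", seq, 1) for i, seq in enumerate(positives)
        ] + [
            Instance(f"{tf_id}_set{s}_neg_{i}", pool[int(j)], 0)
            for i, j in enumerate(chosen)
        ]
        sets.append(InstanceSet(f"{tf_id}_set{s}", instances))
    return sets
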