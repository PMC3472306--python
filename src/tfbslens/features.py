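"""The three per-segment features of a TF binding site.

A candidate site is characterized by

* a **sequence feature** — similarity of the segment to the TF's position
  weight matrix (PWM), computed as ``sum_j f(b_j, j) * C_j`` where ``f`` is the
  PWM frequency of the observed base and ``C_j`` the per-position information
  content ``sum_i f_ij log2(f_ij / P_i)``; both strands are scored and the
  larger value kept;
* a **structure feature vector** — for each of 38 conformational and
  physicochemical dinucleotide attributes, the mean attribute value over the
  ``n-1`` overlapping dinucleotides of the segment;
* an **evolution feature** — the maximal conservation score among catalog
  motifs whose best ungapped similarity to the segment reaches the catalog
  threshold (default 0.95), or 0 when no motif matches.

Together these give the canonical 40-column feature block (39 when no PWM is
available for the TF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import (
    DNA_BASES,
    IUPAC_COMPAT,
    encode_dna,
    encode_iupac,
    revcomp_indices,
    reverse_complement,
)
from .containers import InstanceSet

SEQUENCE_COLUMN = "seq_score"
EVOLUTION_COLUMN = "evo_score"

__all__ = [
    "PWM",
    "DinucleotidePropertyTable",
    "MotifCatalog",
    "information_content",
    "sequence_score",
    "match_similarity_score",
    "structure_score",
    "structure_vector",
    "motif_similarity",
    "evolution_score",
    "featurize",
    "SEQUENCE_COLUMN",
    "EVOLUTION_COLUMN",
]


@dataclass
class PWM:
    """Position frequency matrix with background probabilities.

    ``freqs`` has shape (n, 4) in base order A, C, G, T; each row sums to 1.
    ``background`` is the base distribution of the genomic background, uniform
    by default (it may be replaced by the mononucleotide frequencies of the
    background model used to build negative instances).
    """

    freqs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("PWM frequencies must have shape (n, 4)")
        if self.freqs.shape[0] == 0:
            raise ValueError("PWM must have at least one position")
        if (self.freqs < 0).any():
            raise ValueError("PWM frequencies must be non-negative")
        sums = self.freqs.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError("PWM has a position with zero total frequency")
        self.freqs = self.freqs / sums[:, None]
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background probabilities must sum to 1")

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def consensus(self) -> str:
        return "".join(DNA_BASES[i] for i in self.freqs.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        return information_content(self)


class DinucleotidePropertyTable:
    """Named dinucleotide attribute scales.

    ``values`` is (n_attributes, 16); dinucleotide column order is
    AA AC AG AT CA ... TT, i.e. index ``4*first + second`` with A=0..T=3.
    """

    DINUCS = [a + b for a in DNA_BASES for b in DNA_BASES]

    def __init__(self, attributes: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(attributes), 16):
            raise ValueError("property table must be (n_attributes, 16)")
        if len(set(attributes)) != len(attributes):
            raise ValueError("duplicate attribute names in property table")
        if np.isnan(values).any():
            raise ValueError("property table contains missing values")
        self.attributes = list(attributes)
        self.values = values
        self._index = {name: i for i, name in enumerate(self.attributes)}

    def __len__(self) -> int:
        return len(self.attributes)

    def row(self, attribute: str) -> np.ndarray:
        try:
            return self.values[self._index[attribute]]
        except KeyError:
            raise KeyError(f"unknown attribute {attribute!r}") from None

    def value(self, attribute: str, dinucleotide: str) -> float:
        j = self.DINUCS.index(dinucleotide)
        return float(self.row(attribute)[j])


class MotifCatalog:
    """Conserved regulatory motifs, each with a conservation score.

    A segment is compared to every motif by ungapped sliding of the shorter
    string along the longer on both strands; a motif whose best similarity
    reaches ``similarity_threshold`` contributes its conservation score.
    """

    def __init__(
        self,
        motifs: list[tuple[str, float]],
        similarity_threshold: float = 0.95,
    ):
        if not 0 < similarity_threshold <= 1:
            raise ValueError("similarity threshold must be in (0, 1]")
        self.motifs: list[tuple[str, float]] = []
        self._encoded: list[np.ndarray] = []
        for consensus, score in motifs:
            consensus = consensus.upper()
            enc = encode_iupac(consensus)  # raises on non-IUPAC
            if float(score) < 0:
                raise ValueError(f"motif {consensus!r}: negative conservation score")
            self.motifs.append((consensus, float(score)))
            self._encoded.append(enc)
        self.similarity_threshold = similarity_threshold

    def __len__(self) -> int:
        return len(self.motifs)


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content C_j = sum_i f_ij log2(f_ij / P_i).

    The 0*log(0) = 0 convention applies to zero-frequency bases. A zero
    background probability facing a positive frequency is a domain error.
    """
    f = pwm.freqs
    p = pwm.background
    if ((p == 0) & (f > 0).any(axis=0)).any():
        raise ValueError("zero background probability for a base with positive frequency")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0) / p), 0.0)
    return terms.sum(axis=1)


def _strand_scores(indices: np.ndarray, pwm: PWM) -> float:
    c = information_content(pwm)
    return float((pwm.freqs[np.arange(len(pwm)), indices] * c).sum())


def sequence_score(segment: str, pwm: PWM) -> float:
    """Raw PWM similarity ``sum_j f(b_j, j) * C_j``, max over the two strands."""
    if len(segment) != len(pwm):
        raise ValueError(
            f"segment length {len(segment)} != PWM length {len(pwm)}"
        )
    idx = encode_dna(segment.upper())
    watson = _strand_scores(idx, pwm)
    crick = _strand_scores(revcomp_indices(idx), pwm)
    return max(watson, crick)


def match_similarity_score(segment: str, pwm: PWM) -> float:
    """Min-max-normalized PWM similarity in [0, 1] (Match-style score).

    ``(Current - Min) / (Max - Min)`` with Current the raw information-weighted
    sum of the observed bases and Min/Max its extremes over all segments;
    double-strand maximum as in :func:`sequence_score`. Returns 1.0 for a
    completely uninformative matrix (Max == Min).
    """
    if len(segment) != len(pwm):
        raise ValueError(
            f"segment length {len(segment)} != PWM length {len(pwm)}"
        )
    c = information_content(pwm)
    lo = float((c * pwm.freqs.min(axis=1)).sum())
    hi = float((c * pwm.freqs.max(axis=1)).sum())
    if hi == lo:
        return 1.0
    current = sequence_score(segment, pwm)
    return (current - lo) / (hi - lo)


def structure_score(
    segment: str, table: DinucleotidePropertyTable, attribute: str
) -> float:
    """Mean attribute value over the n-1 overlapping dinucleotides.

    Computed on the segment as given; no strand flip (the attribute scales
    are defined on the written strand).
    """
    if len(segment) < 2:
        raise ValueError("structure feature needs a segment of length >= 2")
    idx = encode_dna(segment.upper())
    dinuc_idx = idx[:-1] * 4 + idx[1:]
    return float(table.row(attribute)[dinuc_idx].mean())


def structure_vector(segment: str, table: DinucleotidePropertyTable) -> np.ndarray:
    """All attribute scores for one segment, in the table's attribute order."""
    if len(segment) < 2:
        raise ValueError("structure feature needs a segment of length >= 2")
    idx = encode_dna(segment.upper())
    dinuc_idx = idx[:-1] * 4 + idx[1:]
    return table.values[:, dinuc_idx].mean(axis=1)


def _structure_matrix(sequences: list[str], table: DinucleotidePropertyTable) -> np.ndarray:
    """(n_segments, n_attributes) structure block; segments may differ in length."""
    out = np.empty((len(sequences), len(table)))
    for i, seq in enumerate(sequences):
        out[i] = structure_vector(seq, table)
    return out


def motif_similarity(segment: str, consensus: str) -> float:
    """Best ungapped similarity of segment and IUPAC consensus, in [0, 1].

    The shorter string slides along the longer (all full-containment offsets);
    both strands of the segment are considered; similarity is the fraction of
    positions of the shorter string whose segment base is compatible with the
    IUPAC code at that position.
    """
    seg_idx = encode_dna(segment.upper())
    cons_idx = encode_iupac(consensus.upper())
    best = 0.0
    for strand in (seg_idx, revcomp_indices(seg_idx)):
        best = max(best, _best_offset_similarity(strand, cons_idx))
    return best


def _best_offset_similarity(seg_idx: np.ndarray, cons_idx: np.ndarray) -> float:
    ns, nm = len(seg_idx), len(cons_idx)
    if ns >= nm:
        short = nm
        best = 0
        for off in range(ns - nm + 1):
            window = seg_idx[off : off + nm]
            best = max(best, int(IUPAC_COMPAT[cons_idx, window].sum()))
    else:
        short = ns
        best = 0
        for off in range(nm - ns + 1):
            codes = cons_idx[off : off + ns]
            best = max(best, int(IUPAC_COMPAT[codes, seg_idx].sum()))
    return best / short


def evolution_score(segment: str, catalog: MotifCatalog) -> float:
    """Maximal conservation score of catalog motifs similar to the segment.

    0 when no motif reaches the catalog's similarity threshold (in particular
    for an empty catalog).
    """
    best = 0.0
    for consensus, score in catalog.motifs:
        if score <= best:
            continue
        if motif_similarity(segment, consensus) >= catalog.similarity_threshold:
            best = score
    return best


def evolution_scores(sequences: list[str], catalog: MotifCatalog) -> np.ndarray:
    """Vectorized :func:`evolution_score` over many segments.

    Groups segments by length and slides every motif over every segment of a
    group at once. Equivalent to the scalar routine (composition oracle in the
    test suite).
    """
    out = np.zeros(len(sequences))
    if len(catalog) == 0 or not sequences:
        return out
    by_len: dict[int, list[int]] = {}
    for i, seq in enumerate(sequences):
        by_len.setdefault(len(seq), []).append(i)
    # motifs sorted by descending score: once a segment is matched it is final
    order = sorted(range(len(catalog)), key=lambda k: -catalog.motifs[k][1])
    for length, idx_list in by_len.items():
        enc = np.stack([encode_dna(sequences[i].upper()) for i in idx_list])
        rc = np.stack([revcomp_indices(row) for row in enc])
        scores = np.zeros(len(idx_list))
        unmatched = np.ones(len(idx_list), dtype=bool)
        for k in order:
            if not unmatched.any():
                break
            consensus, mscore = catalog.motifs[k]
            cons_idx = catalog._encoded[k]
            hit = _batch_motif_hits(
                enc[unmatched], rc[unmatched], cons_idx, catalog.similarity_threshold
            )
            if hit.any():
                rows = np.flatnonzero(unmatched)[hit]
                scores[rows] = mscore
                unmatched[rows] = False
        out[[idx_list[j] for j in range(len(idx_list))]] = scores
    return out


def _batch_motif_hits(
    enc: np.ndarray, rc: np.ndarray, cons_idx: np.ndarray, threshold: float
) -> np.ndarray:
    n, ns = enc.shape
    nm = len(cons_idx)
    short = min(ns, nm)
    need = int(np.ceil(threshold * short - 1e-9))
    hits = np.zeros(n, dtype=bool)
    for strand in (enc, rc):
        if ns >= nm:
            for off in range(ns - nm + 1):
                compat = IUPAC_COMPAT[cons_idx[None, :], strand[:, off : off + nm]]
                hits |= compat.sum(axis=1) >= need
        else:
            for off in range(nm - ns + 1):
                compat = IUPAC_COMPAT[cons_idx[None, off : off + ns], strand]
                hits |= compat.sum(axis=1) >= need
    return hits


def best_window_sequence_score(segment: str, pwm: PWM) -> float:
    """Sequence feature for a segment whose length may exceed the PWM length.

    The segment is scanned and the best-scoring window (double-strand max per
    window) is used; for a segment of exactly the PWM length this is
    :func:`sequence_score`.
    """
    n = len(pwm)
    if len(segment) < n:
        raise ValueError(
            f"segment length {len(segment)} shorter than PWM length {n}"
        )
    idx = encode_dna(segment.upper())
    c = information_content(pwm)
    pos = np.arange(n)
    best = -np.inf
    for off in range(len(segment) - n + 1):
        window = idx[off : off + n]
        w = float((pwm.freqs[pos, window] * c).sum())
        rcw = revcomp_indices(window)
        cr = float((pwm.freqs[pos, rcw] * c).sum())
        best = max(best, w, cr)
    return best


def featurize(
    instances: InstanceSet,
    table: DinucleotidePropertyTable,
    catalog: MotifCatalog,
    pwm: PWM | None = None,
) -> InstanceSet:
    """Attach the canonical feature block to an instance set.

    Column order: sequence score (only when a PWM is available), the 38
    structure attributes in table order, evolution score. Returns the same
    set with ``features`` populated.
    """
    seqs = instances.sequences
    for inst in instances.instances:
        if len(inst.sequence) < 2:
            raise ValueError(f"instance {inst.id!r} shorter than 2 nt")
    columns: dict[str, np.ndarray] = {}
    if pwm is not None:
        columns[SEQUENCE_COLUMN] = np.array(
            [best_window_sequence_score(s, pwm) for s in seqs]
        )
    struct = _structure_matrix(seqs, table)
    for j, name in enumerate(table.attributes):
        columns[name] = struct[:, j]
    columns[EVOLUTION_COLUMN] = evolution_scores(seqs, catalog)
    instances.features = pd.DataFrame(columns, index=[i.id for i in instances.instances])
    return instances
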