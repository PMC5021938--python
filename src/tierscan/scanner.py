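"""Motif scanning with exact p-values under a zero-order background.

Column log-odds scores are discretized to an integer lattice and the exact
distribution of the window score under the background model is obtained by
dynamic programming (position-wise convolution), in the style of FIMO.  The
survival function of that distribution converts any window score into an
exact p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .alphabet import (
    UNIFORM_BACKGROUND,
    encode,
    normalize_background,
    reverse_complement,
)
from .motif_models import MotifModel, reverse_complement_model

__all__ = [
    "MotifHit",
    "ScoreDistribution",
    "exact_score_distribution",
    "pvalue_to_score_threshold",
    "scan",
    "NO_THRESHOLD",
]

#: Sentinel returned when no window can reach the requested p-value.
NO_THRESHOLD = float("inf")


@dataclass(frozen=True)
class MotifHit:
    """A located, scored, stranded motif occurrence."""

    sequence_id: str
    start: int            # 0-based inclusive
    end: int              # exclusive; end - start == model width
    strand: str           # '+' or '-'
    score: float          # discretized log-odds score, bits
    p_value: float
    matched_seq: str      # as read on the hit strand
    model_name: str

    def sort_key(self):
        return (self.sequence_id, self.start, self.strand)


class ScoreDistribution:
    """Exact distribution of a model's window score under its background.

    Scores live on an integer lattice ``s_int`` with real value
    ``s_int * granularity``; ``atoms`` maps each attainable discretized
    score to its probability and ``survival`` to ``P(S >= s)``.
    """

    def __init__(
        self,
        model_name: str,
        granularity: float,
        int_lo: np.ndarray,
        offset: int,
        atom_probs: np.ndarray,
    ):
        self.model_name = model_name
        self.granularity = granularity
        self.int_lo = int_lo          # (W, 4) integer column scores
        self.offset = offset          # minimum attainable integer score
        self.atom_probs = atom_probs  # probability per lattice point
        # survival[k] = P(S_int >= offset + k)
        self.survival_arr = atom_probs[::-1].cumsum()[::-1]

    @property
    def scores(self) -> np.ndarray:
        """Real-valued lattice scores aligned with :attr:`atom_probs`."""
        return (self.offset + np.arange(len(self.atom_probs))) * self.granularity

    @property
    def atoms(self) -> dict:
        return {
            float(s): float(p)
            for s, p in zip(self.scores, self.atom_probs)
            if p > 0
        }

    @property
    def survival(self) -> dict:
        return {
            float(s): float(v)
            for s, p, v in zip(self.scores, self.atom_probs, self.survival_arr)
            if p > 0
        }

    def pvalue_of_int(self, s_int) -> np.ndarray:
        """Exact p-value(s) for integer lattice score(s)."""
        k = np.clip(np.asarray(s_int) - self.offset, 0, len(self.atom_probs) - 1)
        p = self.survival_arr[k]
        return np.where(np.asarray(s_int) < self.offset, 1.0, p)

    def min_pvalue(self) -> float:
        nz = np.nonzero(self.atom_probs)[0]
        return float(self.survival_arr[nz[-1]])


def _discretize(model: MotifModel, granularity: float | None):
    """Map column log-odds to integers; returns (granularity, int_lo)."""
    lo = model.log_odds
    ranges = lo.max(axis=1) - lo.min(axis=1)
    if granularity is None:
        widest = float(ranges.max())
        granularity = widest / 1000.0 if widest > 0 else 1.0
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    int_lo = np.rint(lo / granularity).astype(np.int64)
    collapsed = [
        i
        for i in range(model.width)
        if ranges[i] > 0 and len(set(int_lo[i])) == 1
    ]
    if collapsed:
        warnings.warn(
            f"granularity {granularity:.3g} collapses all column scores at "
            f"positions {collapsed}; p-values will be coarse",
            RuntimeWarning,
            stacklevel=3,
        )
    return granularity, int_lo


def exact_score_distribution(
    model: MotifModel, granularity: float | None = None
) -> ScoreDistribution:
    """Exact window-score distribution by position-wise convolution.

    Default granularity resolves the widest column score range into 1000
    steps (finer for narrower columns).
    """
    granularity, int_lo = _discretize(model, granularity)
    bg = model.background
    cur = np.array([1.0])
    offset = 0
    for i in range(model.width):
        col = int_lo[i]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(len(cur) + (cmax - cmin))
        for b in range(4):
            sh = int(col[b]) - cmin
            new[sh : sh + len(cur)] += cur * bg[b]
        cur = new
        offset += cmin
    return ScoreDistribution(model.name, granularity, int_lo, offset, cur)


def pvalue_to_score_threshold(dist: ScoreDistribution, p: float) -> float:
    """Smallest discretized score whose survival is <= p.

    Returns :data:`NO_THRESHOLD` when even the best attainable score has a
    p-value above *p* (no window can pass).
    """
    if not (0 < p <= 1):
        raise ValueError(f"p must be in (0, 1], got {p}")
    s_int = _int_threshold(dist, p)
    if s_int is None:
        return NO_THRESHOLD
    return s_int * dist.granularity


def _int_threshold(dist: ScoreDistribution, p: float):
    ok = np.nonzero(dist.survival_arr <= p)[0]
    if len(ok) == 0:
        return None
    return int(dist.offset + ok[0])


def _resolve_background(sequences, background):
    if isinstance(background, str):
        if background == "uniform":
            return UNIFORM_BACKGROUND.copy()
        if background == "auto":
            counts = np.zeros(4)
            for _, seq in sequences:
                enc = encode(seq)
                counts += np.bincount(enc[enc < 4], minlength=4)
            if counts.sum() == 0:
                return UNIFORM_BACKGROUND.copy()
            counts = np.clip(counts, 1.0, None)   # keep frequencies positive
            return counts / counts.sum()
        raise ValueError(f"unknown background spec {background!r}")
    return normalize_background(background)


def _as_pairs(sequences) -> list:
    if isinstance(sequences, Mapping):
        return list(sequences.items())
    return list(sequences)


def scan(
    sequences: Mapping[str, str] | Iterable[tuple],
    model: MotifModel,
    p_threshold: float,
    background="auto",
    granularity: float | None = None,
    dist: ScoreDistribution | None = None,
) -> list:
    """Scan sequences on both strands, reporting hits with p <= threshold.

    Windows containing non-ACGT letters are skipped.  For models that equal
    their own reverse complement the minus strand is not scanned (each site
    would otherwise be reported twice); the plus-strand record is kept.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    pairs = _as_pairs(sequences)
    bg = _resolve_background(pairs, background)
    if not np.allclose(bg, model.background):
        model = MotifModel(
            name=model.name,
            probs=model.probs,
            background=bg,
            informative_mask=model.informative_mask,
        )
    if dist is None:
        dist = exact_score_distribution(model, granularity)
    thr = _int_threshold(dist, p_threshold)
    hits: list[MotifHit] = []
    if thr is None:
        return hits
    W = model.width
    palindromic = model.is_palindromic()
    for seq_id, seq in pairs:
        L = len(seq)
        if L < W:
            continue
        enc = encode(seq)
        valid_base = enc < 4
        enc_safe = np.where(valid_base, enc, 0)
        n_win = L - W + 1
        # window is valid iff it contains no ambiguous base
        ok = np.ones(n_win, dtype=bool)
        fwd = np.zeros(n_win, dtype=np.int64)
        rev = np.zeros(n_win, dtype=np.int64)
        for i in range(W):
            col = enc_safe[i : i + n_win]
            ok &= valid_base[i : i + n_win]
            fwd += dist.int_lo[i][col]
            # minus strand: model read off the reverse complement window
            rev += dist.int_lo[W - 1 - i][3 - col]
        for strand, scores in (("+", fwd), ("-", rev)):
            if strand == "-" and palindromic:
                continue
            sel = np.nonzero(ok & (scores >= thr))[0]
            if len(sel) == 0:
                continue
            pvals = dist.pvalue_of_int(scores[sel])
            for start, s_int, p in zip(sel, scores[sel], np.atleast_1d(pvals)):
                start = int(start)
                window = seq[start : start + W].upper()
                if strand == "-":
                    window = reverse_complement(window)
                hits.append(
                    MotifHit(
                        sequence_id=seq_id,
                        start=start,
                        end=start + W,
                        strand=strand,
                        score=float(s_int * dist.granularity),
                        p_value=float(p),
                        matched_seq=window,
                        model_name=model.name,
                    )
                )
    hits.sort(key=MotifHit.sort_key)
    return hits
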