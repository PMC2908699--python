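"""Position weight matrices and sequence scoring.

Submotif clusters are encoded as PWMs whose log-odds scores are min-max
normalized into [0, 1]: the consensus sequence of a PWM scores exactly 1
and the worst achievable sequence scores exactly 0.  Normalized scores are
what the voting multi-classifier thresholds and what the fuzzy-rule stage
reads as fuzzy-set memberships.

The encoder is deliberately pluggable: anything implementing
:class:`SubmotifEncoder` can stand in for :func:`build_pwm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .errors import EmptyInputError, LengthMismatchError, ValidationError
from .seqio import ALPHABET, BASE_INDEX, SiteCollection, reverse_complement

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class PWMModel:
    """4 x L matrix of base probabilities with a normalized-score threshold.

    Rows are ordered A, C, G, T.  ``threshold`` is the cutoff on the
    normalized score used when this PWM acts as a voter or is scanned
    against a region.
    """

    freqs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.0
    threshold: float = 0.5
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[0] != 4:
            raise ValidationError("PWM frequency matrix must be 4 x L")
        colsums = self.freqs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValidationError("PWM columns must sum to 1")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValidationError("threshold must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.freqs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.freqs.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """4 x L log2(f / background); -inf where f = 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.freqs) - np.log2(self.background[:, None])


class SubmotifEncoder(Protocol):
    """Anything that turns a cluster of sites into a PWM."""

    def __call__(self, members: SiteCollection, name: str = ...) -> PWMModel: ...


def build_pwm(
    members: SiteCollection,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    name: str = "pwm",
) -> PWMModel:
    """Estimate a PWM from aligned member sequences.

    Per column, ``f[b] = (count_b + pseudocount * background_b) / (n +
    pseudocount)`` — the pseudocount mass is spread according to the
    background composition.
    """
    if len(members) == 0:
        raise EmptyInputError("cannot build a PWM from zero sites")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    L = members.length
    counts = np.zeros((4, L))
    for site in members:
        for p, base in enumerate(site.sequence):
            counts[BASE_INDEX[base], p] += 1.0
    n = len(members)
    freqs = (counts + pseudocount * bg[:, None]) / (n + pseudocount)
    freqs /= freqs.sum(axis=0, keepdims=True)
    return PWMModel(freqs=freqs, background=bg, pseudocount=pseudocount, name=name)


def information_content(pwm: PWMModel) -> tuple[np.ndarray, float]:
    """Per-position information in bits and the total over positions.

    Uses the background-uniform convention ``2 + sum_b f log2 f``; fully
    conserved columns give 2 bits, uniform columns 0.
    """
    f = pwm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    per_pos = 2.0 + plogp.sum(axis=0)
    return per_pos, float(per_pos.sum())


def score_sequence(pwm: PWMModel, seq: str) -> float:
    """Min-max normalized log-odds score in [0, 1].

    The normalization endpoints are the best and worst *achievable*
    log-odds sums of the PWM, so the consensus scores 1 and the
    anti-consensus scores 0 regardless of background.
    """
    if len(seq) != pwm.length:
        raise LengthMismatchError(
            f"sequence length {len(seq)} != PWM length {pwm.length}"
        )
    lo = pwm.log_odds()
    idx = [BASE_INDEX[b] for b in seq.upper()]
    raw = float(lo[idx, np.arange(pwm.length)].sum())
    return _normalize(raw, lo)


def _normalize(raw: float, log_odds: np.ndarray) -> float:
    best = log_odds.max(axis=0).sum()
    worst = log_odds.min(axis=0).sum()
    if best == worst:  # completely uninformative PWM
        return 1.0
    if np.isneginf(raw):
        return 0.0
    return float((raw - worst) / (best - worst))


@dataclass
class ScoredHit:
    """One above-threshold placement of a PWM inside a scanned region."""

    score: float
    position: int  # forward-strand offset of the match start
    strand: str
    submotif: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0 + 1e-12):
            raise ValidationError(f"hit score {self.score} outside [0, 1]")


def score_all_offsets(pwm: PWMModel, region: str) -> tuple[np.ndarray, np.ndarray]:
    """Normalized scores of every placement on + and - strands.

    Returns two arrays of length ``len(region) - L + 1``; the reverse-strand
    score at index ``i`` is for the reverse complement of
    ``region[i:i+L]`` and is reported at forward coordinate ``i``.
    """
    L = pwm.length
    region = region.upper()
    n = len(region) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    lo = pwm.log_odds()
    best = lo.max(axis=0).sum()
    worst = lo.min(axis=0).sum()
    span = best - worst
    idx = np.array([BASE_INDEX.get(b, -1) for b in region])
    if (idx < 0).any():
        # treat ambiguous bases as worst-scoring
        pass
    fwd = np.empty(n)
    rev = np.empty(n)
    # complement index: A<->T (0<->3), C<->G (1<->2)
    comp = np.where(idx >= 0, 3 - idx, -1)
    for i in range(n):
        w = idx[i : i + L]
        if (w < 0).any():
            fwd[i] = 0.0
        else:
            raw = lo[w, np.arange(L)].sum()
            fwd[i] = 0.0 if np.isneginf(raw) else (raw - worst) / span if span else 1.0
        wc = comp[i : i + L][::-1]
        if (wc < 0).any():
            rev[i] = 0.0
        else:
            raw = lo[wc, np.arange(L)].sum()
            rev[i] = 0.0 if np.isneginf(raw) else (raw - worst) / span if span else 1.0
    return fwd, rev


def scan_window(
    pwm: PWMModel, region: str, strands: str = "both"
) -> list[ScoredHit]:
    """All above-threshold placements of ``pwm`` in ``region``.

    Both strands are scanned by default; reverse-strand hits are reported
    at their forward-strand start coordinate.  Hits are sorted by
    descending score.
    """
    if len(region) < pwm.length:
        warnings.warn(
            f"region shorter than PWM length {pwm.length}; no placements",
            stacklevel=2,
        )
        return []
    fwd, rev = score_all_offsets(pwm, region)
    hits = []
    if strands in ("both", "+"):
        for i in np.flatnonzero(fwd >= pwm.threshold):
            hits.append(ScoredHit(float(fwd[i]), int(i), "+", pwm.name))
    if strands in ("both", "-"):
        for i in np.flatnonzero(rev >= pwm.threshold):
            hits.append(ScoredHit(float(rev[i]), int(i), "-", pwm.name))
    hits.sort(key=lambda h: (-h.score, h.position, h.strand))
    return hits


def write_hits_bed(hits, chromosome: str, length: int, path) -> None:
    """Hits as BED6 with scores scaled to 0-1000."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{chromosome}\t{h.position}\t{h.position + length}\t"
                f"{h.submotif}\t{int(round(h.score * 1000))}\t{h.strand}\n"
            )
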