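"""The "Combine" phase: OR-voting multi-classifier over submotif PWMs.

Every active voter (a PWM with its own learned threshold) scores a query
sequence; a single positive vote suffices to call the sequence a binding
site.  Performance is summarized by the correlation coefficient CC and its
standardized variant SCC, which rescales the negative-class counts to the
positive-class magnitude so that strongly unbalanced datasets do not
swamp the statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encode import PWMModel, scan_window, score_sequence
from .errors import ConfigurationError, EmptyInputError, ValidationError
from .seqio import SiteCollection


@dataclass
class Voter:
    pwm: PWMModel
    threshold: float = 0.5
    active: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValidationError("voter threshold must lie in [0, 1]")


@dataclass
class MultiClassifier:
    """Set of thresholded PWM voters combined by OR."""

    voters: list[Voter]
    tree_ref: object | None = None

    def __post_init__(self) -> None:
        if not self.voters:
            raise ConfigurationError("multi-classifier needs at least one voter")

    @property
    def active_voters(self) -> list[Voter]:
        return [v for v in self.voters if v.active]

    def predict(self, seq: str) -> tuple[bool, dict[str, float]]:
        """Classify one sequence; returns (is_site, per-voter scores).

        A voter fires when its normalized score is >= its threshold
        (inclusive boundary); the prediction is positive iff any active
        voter fires.
        """
        active = self.active_voters
        if not active:
            raise ConfigurationError("no active voters")
        votes = {v.pwm.name: score_sequence(v.pwm, seq) for v in active}
        fired = any(
            votes[v.pwm.name] >= v.threshold for v in active
        )
        return fired, votes

    def score_matrix(self, collection: SiteCollection) -> np.ndarray:
        """(n_sites, n_voters) normalized scores over *all* voters.

        Precomputing this matrix once makes threshold optimization cheap:
        fitness evaluation reduces to comparisons against it.
        """
        return np.array(
            [
                [score_sequence(v.pwm, s) for v in self.voters]
                for s in collection.sequences
            ]
        )

    def to_json(self) -> str:
        payload = [
            {
                "name": v.pwm.name,
                "threshold": v.threshold,
                "active": v.active,
                "freqs": v.pwm.freqs.tolist(),
                "background": v.pwm.background.tolist(),
            }
            for v in self.voters
        ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MultiClassifier":
        payload = json.loads(text)
        voters = [
            Voter(
                pwm=PWMModel(
                    freqs=np.array(d["freqs"]),
                    background=np.array(d["background"]),
                    name=d["name"],
                    threshold=d["threshold"],
                ),
                threshold=d["threshold"],
                active=d["active"],
            )
            for d in payload
        ]
        return cls(voters=voters)


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN with the P/N marginals."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP


def evaluate(
    mc: MultiClassifier,
    positives: SiteCollection,
    negatives: SiteCollection,
) -> ConfusionCounts:
    """Confusion counts of the classifier over labelled example sets."""
    if len(positives) == 0 or len(negatives) == 0:
        raise EmptyInputError("both example sets must be non-empty")
    overlap = set(positives.site_ids) & set(negatives.site_ids)
    if overlap:
        raise ValidationError(
            f"ids present in both positives and negatives: {sorted(overlap)}"
        )
    tp = sum(1 for s in positives.sequences if mc.predict(s)[0])
    fp = sum(1 for s in negatives.sequences if mc.predict(s)[0])
    return ConfusionCounts(
        TP=tp, FN=len(positives) - tp, FP=fp, TN=len(negatives) - fp
    )


def cc(counts: ConfusionCounts) -> float:
    """Correlation coefficient between predicted and true labels.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; a zero
    denominator yields 0 by convention.
    """
    if counts.P == 0 or counts.N == 0:
        raise ValidationError("CC requires P > 0 and N > 0")
    return _cc_raw(counts.TP, counts.FP, counts.TN, counts.FN)


def _cc_raw(tp: float, fp: float, tn: float, fn: float) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom <= 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def scc(counts: ConfusionCounts) -> float:
    """Standardized CC for unbalanced example sets.

    The negative-class counts are rescaled to the magnitude of the
    positive class (``FP' = FP * P/N``, ``TN' = TN * P/N``) before
    applying the CC formula, so false positives among a large negative
    set carry weight proportional to the positive-set size.  Reduces to
    CC exactly when P = N.
    """
    if counts.P == 0 or counts.N == 0:
        raise ValidationError("SCC requires P > 0 and N > 0")
    r = counts.P / counts.N
    return _cc_raw(counts.TP, counts.FP * r, counts.TN * r, counts.FN)


def empirical_fdr(mc: MultiClassifier, null_regions: list[str]) -> float:
    """Fraction of site-free regions with at least one positive scan hit."""
    if not null_regions:
        raise EmptyInputError("no null regions given")
    flagged = 0
    for region in null_regions:
        hit = False
        for v in mc.active_voters:
            pwm = v.pwm
            old = pwm.threshold
            pwm.threshold = v.threshold
            try:
                if scan_window(pwm, region):
                    hit = True
            finally:
                pwm.threshold = old
            if hit:
                break
        flagged += hit
    return flagged / len(null_regions)


def write_evaluation_tsv(
    mc: MultiClassifier,
    positives: SiteCollection,
    negatives: SiteCollection,
    path,
) -> None:
    """Per-example vote report plus summary metrics (TSV)."""
    counts = evaluate(mc, positives, negatives)
    with open(path, "w") as fh:
        fh.write("# CC=%.6f SCC=%.6f TP=%d FP=%d TN=%d FN=%d\n" % (
            cc(counts), scc(counts),
            counts.TP, counts.FP, counts.TN, counts.FN,
        ))
        names = [v.pwm.name for v in mc.voters]
        fh.write("site_id\tlabel\tpredicted\t" + "\t".join(names) + "\n")
        for label, coll in (("positive", positives), ("negative", negatives)):
            for s in coll:
                pred, votes = mc.predict(s.sequence)
                row = "\t".join(f"{votes.get(n, float('nan')):.4f}" for n in names)
                fh.write(f"{s.site_id}\t{label}\t{int(pred)}\t{row}\n")
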