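"""The "Fuse" phase: fuzzy IF-THEN rules over submotifs and TF-RNAP distance.

Two kinds of fuzzy sets are joined in rule antecedents: submotif sets,
whose membership function is the normalized PWM score, and distance sets,
triangles fitted to the histogram of signed binding-site offsets from the
transcription start site.  A rule fires when the product (fuzzy AND) of
its two antecedent memberships reaches the rule's activation threshold;
fired rules combine by maximum, and a sequence is called a site when at
least one rule fires.

Rule mining takes the Cartesian product of submotif and distance sets,
hard-thresholds both memberships at 0.5 and keeps the pairs whose overlap
is hypergeometrically significant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .divide import hypergeom_overlap
from .encode import PWMModel, score_sequence
from .errors import ConfigurationError, DegenerateFitError, EmptyInputError
from .optimize import Chromosome, FitnessConfig, GAResult, ga_run
from .seqio import SiteCollection

DEFAULT_WINDOW = (-90, 10)  # promoter window around the TSS, bp
DISTANCE_LABELS = ("close", "medium", "far")


@dataclass
class FuzzySet:
    """Either a PWM-backed score set or a triangular set on the distance axis.

    Triangles are general (a <= b <= c): membership rises linearly from
    the left foot ``a`` to 1 at the apex ``b`` and falls to 0 at the right
    foot ``c``.
    """

    label: str
    kind: str  # {"score_set", "triangular"}
    pwm: PWMModel | None = None
    a: float | None = None
    b: float | None = None
    c: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "triangular":
            if self.a is None or self.b is None or self.c is None:
                raise ConfigurationError("triangular set needs a, b, c")
            if not (self.a <= self.b <= self.c):
                raise ConfigurationError(
                    f"triangle must satisfy a <= b <= c, got {(self.a, self.b, self.c)}"
                )
        elif self.kind == "score_set":
            if self.pwm is None:
                raise ConfigurationError("score set needs a PWM")
        else:
            raise ConfigurationError(f"unknown fuzzy-set kind {self.kind!r}")


def membership(fset: FuzzySet, x) -> float:
    """Degree of membership of ``x`` (a sequence or a distance) in [0, 1]."""
    if fset.kind == "score_set":
        return score_sequence(fset.pwm, x)
    return _triangle(float(x), fset.a, fset.b, fset.c)


def _triangle(x: float, a: float, b: float, c: float) -> float:
    if x <= a or x >= c:
        # apex exactly on a foot (degenerate triangle) still scores 1 at b
        return 1.0 if x == b else 0.0
    if x == b:
        return 1.0
    if x < b:
        return (x - a) / (b - a)
    return (c - x) / (c - b)


def _kmeans_1d(values: np.ndarray, k: int, iters: int = 100) -> np.ndarray:
    """Deterministic 1-D k-means (quantile init); returns labels."""
    centers = np.quantile(values, (np.arange(k) + 0.5) / k)
    for _ in range(iters):
        labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [values[labels == i].mean() if (labels == i).any() else centers[i]
             for i in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)


def fit_distance_fuzzy_sets(
    distances,
    k: int = 3,
    bin_width: float = 2.0,
    window: tuple[float, float] = DEFAULT_WINDOW,
    labels: tuple[str, ...] | None = None,
) -> list[FuzzySet]:
    """Fit ``k`` triangular sets to the histogram of TSS distances.

    The distances are split into ``k`` modes (1-D k-means, quantile
    seeded, deterministic), each mode is histogrammed at ``bin_width`` bp
    resolution and a triangle is fitted to the peak-normalized histogram
    by least squares.  Sets are returned ordered by apex from least to
    most negative, matching the close/medium/far naming.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise EmptyInputError("no distances")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if np.unique(d).size < k:
        raise DegenerateFitError(
            f"only {np.unique(d).size} distinct distances for k={k} sets"
        )
    lo, hi = window
    inside = (d >= lo) & (d <= hi)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} distance(s) outside window {window}; dropped",
            stacklevel=2,
        )
        d = d[inside]
    lab = _kmeans_1d(d, k)
    triangles = [_fit_triangle(d[lab == i], bin_width) for i in range(k)]
    # one reassignment pass: overlapping modes pull the k-means boundary,
    # so points are re-attributed to the nearest fitted apex and refit
    apexes = np.array([t[1] for t in triangles])
    lab2 = np.argmin(np.abs(d[:, None] - apexes[None, :]), axis=1)
    if (lab2 != lab).any() and all((lab2 == i).sum() >= 2 for i in range(k)):
        triangles = [_fit_triangle(d[lab2 == i], bin_width) for i in range(k)]
    triangles.sort(key=lambda t: -t[1])  # closest to TSS (least negative) first
    if labels is None:
        labels = DISTANCE_LABELS if k == 3 else tuple(f"d{i + 1}" for i in range(k))
    return [
        FuzzySet(label=labels[i], kind="triangular", a=a, b=b, c=c)
        for i, (a, b, c) in enumerate(triangles)
    ]


def _fit_triangle(values: np.ndarray, bin_width: float) -> tuple[float, float, float]:
    """Least-squares triangle fit to the peak-normalized mode histogram."""
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return (vmin, vmin, vmin)
    edges = np.arange(vmin - bin_width / 2, vmax + bin_width, bin_width)
    hist, edges = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    y = hist / hist.max()
    b0 = centers[int(np.argmax(hist))]
    a0 = vmin - bin_width / 2
    c0 = vmax + bin_width / 2

    def resid(params):
        a, b, c = params
        a, c = min(a, b), max(c, b)
        mu = np.array([_triangle(x, a, b, c) for x in centers])
        return mu - y

    # overlapping neighbour modes skew the tails, so the apex is kept
    # within one bin of the empirical histogram peak during the fit
    sol = least_squares(
        resid,
        x0=[a0, b0, c0],
        method="trf",
        bounds=(
            [a0 - 3 * bin_width, b0 - bin_width, b0],
            [b0, b0 + bin_width, c0 + 3 * bin_width],
        ),
    )
    a, b, c = sol.x
    a, c = min(a, b), max(c, b)
    return (float(a), float(b), float(c))


@dataclass
class FuzzyRule:
    """IF submotif-set AND distance-set THEN binding site."""

    submotif: FuzzySet
    distance: FuzzySet
    th: float = 0.25
    consequent: float = 1.0
    pi: float = float("nan")  # mining significance, informational

    def __post_init__(self) -> None:
        if not (0.0 <= self.th <= 1.0):
            raise ConfigurationError("rule threshold must lie in [0, 1]")

    @property
    def name(self) -> str:
        return f"{self.submotif.label}&{self.distance.label}"

    def activation(self, seq: str, dist: float) -> float:
        return membership(self.submotif, seq) * membership(self.distance, dist)


@dataclass
class RuleBase:
    """Rule collection with the fixed product-AND / maximum-combine operators."""

    rules: list[FuzzyRule]
    and_operator: str = "product"
    combine_operator: str = "maximum"

    def active_rules(self) -> list[FuzzyRule]:
        return self.rules

    def to_json(self) -> str:
        payload = [
            {
                "submotif": r.submotif.label,
                "distance": r.distance.label,
                "triangle": [r.distance.a, r.distance.b, r.distance.c],
                "th": r.th,
                "pi": r.pi,
            }
            for r in self.rules
        ]
        return json.dumps(payload, indent=2)


def generate_rules(
    submotif_sets: list[FuzzySet],
    distance_sets: list[FuzzySet],
    training_sites: SiteCollection,
    alpha: float = 1e-4,
    membership_cut: float = 0.5,
    default_th: float = 0.25,
) -> RuleBase:
    """Mine significant (submotif, distance) pairs from training sites.

    For each pair in the Cartesian product, the sites whose submotif
    membership and distance membership both reach ``membership_cut`` are
    intersected; pairs whose overlap has hypergeometric tail probability
    below ``alpha`` become rules.
    """
    sites = [s for s in training_sites if s.tss_offset is not None]
    if not sites:
        raise EmptyInputError("training sites carry no tss_offset distances")
    g = len(sites)
    sub_members = {
        ss.label: {
            s.site_id for s in sites if membership(ss, s.sequence) >= membership_cut
        }
        for ss in submotif_sets
    }
    dist_members = {
        ds.label: {
            s.site_id
            for s in sites
            if membership(ds, s.tss_offset) >= membership_cut
        }
        for ds in distance_sets
    }
    rules = []
    for ss in submotif_sets:
        h = len(sub_members[ss.label])
        for ds in distance_sets:
            n = len(dist_members[ds.label])
            p = len(sub_members[ss.label] & dist_members[ds.label])
            if h == 0 or n == 0:
                continue
            pi = hypergeom_overlap(p, h, n, g)
            if pi < alpha:
                rules.append(
                    FuzzyRule(submotif=ss, distance=ds, th=default_th, pi=pi)
                )
    if not rules:
        warnings.warn("no significant rules at the given alpha", stacklevel=2)
    return RuleBase(rules=rules)


def infer(
    rulebase: RuleBase, seq: str, distance: float
) -> tuple[bool, float, list[tuple[str, float]]]:
    """Run the rule base on one (sequence, distance) query.

    Returns (positive, overall degree, fired rules with activations).
    Activation is the product of the two antecedent memberships; a rule
    fires at activation >= its threshold; the overall degree is the
    maximum over fired rules (0 when none fire).
    """
    if not rulebase.rules:
        raise ConfigurationError("empty rule base")
    fired = []
    for r in rulebase.rules:
        act = r.activation(seq, distance)
        if act >= r.th:
            fired.append((r.name, act))
    degree = max((a for _, a in fired), default=0.0)
    return bool(fired), degree, fired


def ga_optimize_rules(
    rulebase: RuleBase,
    positives: SiteCollection,
    negatives_with_dist: list[tuple[str, float]],
    config: FitnessConfig | None = None,
) -> tuple[RuleBase, GAResult]:
    """GA over (presence, threshold) pairs, one per rule.

    ``negatives_with_dist`` supplies (sequence, distance) for negative
    examples, since negatives have no annotated TSS offset of their own.
    Returns the optimized rule base (inactive rules dropped) plus the full
    GA result with its Pareto front over (measure, rule count).
    """
    if not rulebase.rules:
        raise ConfigurationError("empty rule base")
    config = config or FitnessConfig()
    pos = [
        (s.sequence, float(s.tss_offset))
        for s in positives
        if s.tss_offset is not None
    ]
    if not pos:
        raise EmptyInputError("positives carry no distances")
    # precompute activation matrices: examples x rules
    act_pos = np.array(
        [[r.activation(seq, d) for r in rulebase.rules] for seq, d in pos]
    )
    act_neg = np.array(
        [[r.activation(seq, d) for r in rulebase.rules]
         for seq, d in negatives_with_dist]
    )
    P, N = act_pos.shape[0], act_neg.shape[0]

    def evaluate_full(chrom: Chromosome):
        active = chrom.active
        n_active = int(active.sum())
        if n_active == 0:
            return -(config.w1 + config.w2 + 1.0), -1.0, 0
        thr = chrom.thresholds[active]
        tp = int((act_pos[:, active] >= thr).any(axis=1).sum())
        fp = int((act_neg[:, active] >= thr).any(axis=1).sum())
        from .classify import _cc_raw

        if config.objective == "cc":
            meas = _cc_raw(tp, fp, N - fp, P - tp)
        else:
            r = P / N
            meas = _cc_raw(tp, fp * r, (N - fp) * r, P - tp)
        fit = config.w1 * meas - config.w2 * (n_active / len(rulebase.rules))
        return fit, meas, n_active

    result = ga_run(evaluate_full, len(rulebase.rules), config)
    best = result.best
    optimized = [
        FuzzyRule(
            submotif=r.submotif,
            distance=r.distance,
            th=float(best.thresholds[i]),
            pi=r.pi,
        )
        for i, r in enumerate(rulebase.rules)
        if best.active[i]
    ]
    return RuleBase(rules=optimized), result
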