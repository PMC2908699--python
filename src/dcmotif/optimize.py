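"""The "Optimize" phase: genetic-algorithm tuning of the multi-classifier.

A chromosome carries one (presence, threshold) pair per candidate submotif;
a submotif is active when its presence gene exceeds 0.5.  Fitness trades
classification quality (CC or SCC) against model complexity (fraction of
submotifs used), so the search surfaces a whole front of optimal
configurations rather than a single winner.

The engine is generic over the scoring closure, which lets the fuzzy-rule
stage reuse it unchanged for (presence, rule-threshold) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classify import ConfusionCounts, MultiClassifier, Voter, _cc_raw
from .encode import PWMModel, score_sequence
from .errors import ConfigurationError
from .seqio import SiteCollection


@dataclass
class Chromosome:
    """(presence, threshold) pairs, both in [0, 1], one per candidate."""

    alleles: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=float)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != 2:
            raise ConfigurationError("alleles must have shape (n, 2)")
        if ((self.alleles < 0) | (self.alleles > 1)).any():
            raise ConfigurationError("allele entries must lie in [0, 1]")

    @property
    def active(self) -> np.ndarray:
        return self.alleles[:, 0] > 0.5

    @property
    def thresholds(self) -> np.ndarray:
        return self.alleles[:, 1]

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def copy(self) -> "Chromosome":
        return Chromosome(self.alleles.copy())


@dataclass
class FitnessConfig:
    """GA hyperparameters and the accuracy/complexity trade-off weights."""

    objective: str = "scc"  # {"cc", "scc"}
    w1: float = 1.0
    w2: float = 1.0
    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    elitism: int = 1
    tournament: int = 2
    p_on_off: float = 0.05
    p_off_on: float = 0.005
    threshold_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        if self.w1 < 0 or self.w2 < 0:
            raise ConfigurationError("objective weights must be >= 0")
        if self.objective not in ("cc", "scc"):
            raise ConfigurationError(f"unknown objective {self.objective!r}")


def measure_from_scores(
    chrom: Chromosome,
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    objective: str,
) -> float:
    """CC/SCC of the OR-voting classifier induced by a chromosome.

    Operates on precomputed (examples x submotifs) normalized-score
    matrices, so each evaluation is a handful of vectorized comparisons.
    """
    active = chrom.active
    if not active.any():
        return -1.0
    thr = chrom.thresholds[active]
    tp = int((pos_scores[:, active] >= thr).any(axis=1).sum())
    fp = int((neg_scores[:, active] >= thr).any(axis=1).sum())
    P, N = pos_scores.shape[0], neg_scores.shape[0]
    if objective == "cc":
        return _cc_raw(tp, fp, N - fp, P - tp)
    r = P / N
    return _cc_raw(tp, fp * r, (N - fp) * r, P - tp)


def fitness(
    chrom: Chromosome,
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    config: FitnessConfig,
) -> float:
    """w1 * measure - w2 * complexity; no active submotif scores worst."""
    n_total = chrom.alleles.shape[0]
    if chrom.n_active == 0:
        return -(config.w1 + config.w2 + 1.0)
    m = measure_from_scores(chrom, pos_scores, neg_scores, config.objective)
    return config.w1 * m - config.w2 * (chrom.n_active / n_total)


def crossover_maxmin(
    parent1: Chromosome, parent2: Chromosome, a: float, scorer
) -> Chromosome:
    """Max-min arithmetical crossover: four offspring, fittest survives.

    Offspring are the two a-weighted arithmetic mixtures of the parents
    plus their component-wise minimum and maximum.
    """
    if parent1.alleles.shape != parent2.alleles.shape:
        raise ConfigurationError("parents must have equal allele counts")
    if not (0.0 <= a <= 1.0):
        raise ConfigurationError("mixing parameter a must lie in [0, 1]")
    x, y = parent1.alleles, parent2.alleles
    candidates = [
        Chromosome(a * x + (1.0 - a) * y),
        Chromosome(a * y + (1.0 - a) * x),
        Chromosome(np.minimum(x, y)),
        Chromosome(np.maximum(x, y)),
    ]
    scores = [scorer(c) for c in candidates]
    return candidates[int(np.argmax(scores))]


def mutate(
    chrom: Chromosome,
    rng,
    p_on_off: float = 0.05,
    p_off_on: float = 0.005,
    threshold_jitter: float = 0.10,
) -> Chromosome:
    """Asymmetric presence flips plus multiplicative threshold jitter.

    Active submotifs switch off with probability ``p_on_off`` and inactive
    ones switch on with ``p_off_on``; every threshold is scaled by a
    uniform factor within +/- ``threshold_jitter`` of itself and clipped
    to [0, 1].
    """
    alleles = chrom.alleles.copy()
    for i in range(alleles.shape[0]):
        r = rng.random()
        on = alleles[i, 0] > 0.5
        if (on and r < p_on_off) or (not on and r < p_off_on):
            alleles[i, 0] = 1.0 - alleles[i, 0]
        factor = 1.0 + threshold_jitter * (2.0 * rng.random() - 1.0)
        alleles[i, 1] = min(1.0, max(0.0, alleles[i, 1] * factor))
    return Chromosome(alleles)


@dataclass
class ParetoEntry:
    n_active: int
    measure: float
    chromosome: Chromosome


@dataclass
class GAResult:
    best: Chromosome
    best_fitness: float
    history: list[float] = field(default_factory=list)
    pareto: list[ParetoEntry] = field(default_factory=list)


def _pareto_filter(entries: dict[int, ParetoEntry]) -> list[ParetoEntry]:
    """Mutually non-dominated set over (measure up, complexity down)."""
    out = []
    for e in entries.values():
        dominated = any(
            (o.measure >= e.measure and o.n_active < e.n_active)
            or (o.measure > e.measure and o.n_active <= e.n_active)
            for o in entries.values()
        )
        if not dominated:
            out.append(e)
    return sorted(out, key=lambda e: e.n_active)


def ga_run(evaluate_full, n_alleles: int, config: FitnessConfig) -> GAResult:
    """Generic seeded generational GA over (presence, value) chromosomes.

    ``evaluate_full(chrom) -> (fitness, measure, n_active)``.  Elitism
    guarantees a non-decreasing best fitness; the per-complexity-level
    best-measure table over every individual ever evaluated becomes the
    Pareto front.
    """
    rng = np.random.default_rng(config.seed)
    per_complexity: dict[int, ParetoEntry] = {}

    def record(chrom, fit):
        _, measure, n_active = fit
        if n_active > 0:
            cur = per_complexity.get(n_active)
            if cur is None or measure > cur.measure:
                per_complexity[n_active] = ParetoEntry(n_active, measure, chrom.copy())

    pop = [Chromosome(rng.random((n_alleles, 2))) for _ in range(config.population - 1)]
    all_on = np.column_stack(
        [np.ones(n_alleles), rng.random(n_alleles)]
    )
    pop.append(Chromosome(all_on))  # one all-active individual in the seed pool
    fits = [evaluate_full(c) for c in pop]
    for c, f in zip(pop, fits):
        record(c, f)
    scorer = lambda c: evaluate_full(c)[0]  # noqa: E731
    history = []
    for _ in range(config.generations):
        order = np.argsort([-f[0] for f in fits], kind="stable")
        history.append(fits[order[0]][0])
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < config.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population, size=config.tournament)
                best_i = max(contenders, key=lambda i: fits[i][0])
                parents.append(pop[best_i])
            if rng.random() < config.crossover_rate:
                child = crossover_maxmin(
                    parents[0], parents[1], a=float(rng.random()), scorer=scorer
                )
            else:
                child = max(parents, key=lambda p: evaluate_full(p)[0]).copy()
            child = mutate(
                child,
                rng,
                p_on_off=config.p_on_off,
                p_off_on=config.p_off_on,
                threshold_jitter=config.threshold_jitter,
            )
            new_pop.append(child)
        pop = new_pop
        fits = [evaluate_full(c) for c in pop]
        for c, f in zip(pop, fits):
            record(c, f)
    best_i = int(np.argmax([f[0] for f in fits]))
    history.append(fits[best_i][0])
    return GAResult(
        best=pop[best_i].copy(),
        best_fitness=fits[best_i][0],
        history=history,
        pareto=_pareto_filter(per_complexity),
    )


def ga_optimize(
    submotifs: list[PWMModel],
    positives: SiteCollection,
    negatives: SiteCollection,
    config: FitnessConfig | None = None,
) -> GAResult:
    """Optimize which submotifs vote and at what thresholds."""
    if not submotifs:
        raise ConfigurationError("need at least one candidate submotif")
    if len(positives) == 0 or len(negatives) == 0:
        raise ConfigurationError("training data must be non-empty")
    config = config or FitnessConfig()
    pos_scores = np.array(
        [[score_sequence(p, s) for p in submotifs] for s in positives.sequences]
    )
    neg_scores = np.array(
        [[score_sequence(p, s) for p in submotifs] for s in negatives.sequences]
    )

    def evaluate_full(chrom: Chromosome):
        fit = fitness(chrom, pos_scores, neg_scores, config)
        meas = measure_from_scores(chrom, pos_scores, neg_scores, config.objective)
        return fit, meas, chrom.n_active

    return ga_run(evaluate_full, len(submotifs), config)


def apply_chromosome(
    submotifs: list[PWMModel], chrom: Chromosome
) -> MultiClassifier:
    """Materialize a chromosome as a voting multi-classifier."""
    voters = [
        Voter(
            pwm=replace_threshold(pwm, float(chrom.thresholds[i])),
            threshold=float(chrom.thresholds[i]),
            active=bool(chrom.active[i]),
        )
        for i, pwm in enumerate(submotifs)
    ]
    return MultiClassifier(voters=voters)


def replace_threshold(pwm: PWMModel, threshold: float) -> PWMModel:
    return replace(pwm, threshold=threshold)


def leave_one_out(
    submotifs: list[PWMModel],
    thresholds: np.ndarray,
    positives: SiteCollection,
) -> dict[str, dict[str, int]]:
    """Recovery table for the leave-one-submotif-out analysis.

    For each submotif: how many positives it recovers alone, and how many
    of those are still recovered when it is withheld from the ensemble.
    """
    scores = np.array(
        [[score_sequence(p, s) for p in submotifs] for s in positives.sequences]
    )
    hits = scores >= np.asarray(thresholds)
    out = {}
    for i, pwm in enumerate(submotifs):
        own = hits[:, i]
        others = np.delete(hits, i, axis=1).any(axis=1)
        out[pwm.name] = {
            "recovered": int(own.sum()),
            "recovered_by_others": int((own & others).sum()),
            "lost_without": int((own & ~others).sum()),
        }
    return out


def write_pareto_tsv(result: GAResult, names: list[str], path) -> None:
    """Pareto table: objective value, submotif count, flags, min threshold."""
    with open(path, "w") as fh:
        fh.write("measure\tn_submotifs\t" + "\t".join(names) + "\tmin_threshold\n")
        for e in result.pareto:
            flags = "\t".join(str(int(x)) for x in e.chromosome.active)
            act = e.chromosome.active
            min_thr = (
                float(e.chromosome.thresholds[act].min()) if act.any() else float("nan")
            )
            fh.write(f"{e.measure:.6f}\t{e.n_active}\t{flags}\t{min_thr:.4f}\n")
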