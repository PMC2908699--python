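"""Rate-of-evolution profiles for binding-site positions.

The Halpern-Bruno model re-weights a position-independent background
mutation matrix Q by the fixation probability implied by a PWM column, so
that positions with sharply preferred bases accumulate substitutions more
slowly than background.  Expected per-position distances K (rate x time,
substitutions per site) are compared between the motif model and the
HKY85 background via the mean square difference (MSD).

Because time is assumed equal for all sites within one species, Q is
fitted directly on the *distance* scale; K values are substitutions per
site over the background alignment depth, not instantaneous rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .encode import PWMModel, information_content
from .errors import ConfigurationError, LengthMismatchError, ValidationError
from .seqio import ALPHABET, BASE_INDEX, BindingSite, SiteCollection

# transitions under the ACGT ordering: A<->G (0,2), C<->T (1,3)
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}


@dataclass
class SubstitutionModel:
    """HKY85 background model on the distance scale.

    ``Q`` is the rate matrix scaled so that branch length is absorbed
    into it (``scale`` is the fitted pairwise distance).
    """

    kappa: float
    pi: np.ndarray
    scale: float = 1.0
    kind: str = "HKY85"
    method: str = "ml-pairwise"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,) or not np.isclose(self.pi.sum(), 1.0):
            raise ValidationError("pi must be a 4-vector summing to 1")
        if self.kappa <= 0 or self.scale < 0:
            raise ValidationError("kappa must be > 0 and scale >= 0")

    @property
    def Q(self) -> np.ndarray:
        """Scaled rate matrix: rows sum to 0, off-diagonals >= 0."""
        Q = np.zeros((4, 4))
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                Q[a, b] = self.pi[b] * (
                    self.kappa if (a, b) in _TRANSITIONS else 1.0
                )
        # normalize to one expected substitution per unit time, then scale
        Q /= np.sum(self.pi[:, None] * Q)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q * self.scale

    def transition_matrix(self, t: float = 1.0) -> np.ndarray:
        return expm(self.Q * t)


def estimate_hky85(background: list[str] | SiteCollection) -> SubstitutionModel:
    """Fit an HKY85 model to aligned background sequences.

    Equilibrium frequencies come from observed base counts; kappa and the
    distance scale maximize the likelihood of the aggregate substitution
    count matrix over consecutive sequence pairs.  Deterministic given
    the input.
    """
    seqs = (
        background.sequences
        if isinstance(background, SiteCollection)
        else list(background)
    )
    if len(seqs) < 2:
        raise ConfigurationError("need at least 2 aligned sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise LengthMismatchError("background sequences must be aligned")
    if any("-" in s for s in seqs):
        raise ValidationError("gapped alignments are not supported")
    arr = np.array([[BASE_INDEX[b] for b in s.upper()] for s in seqs])
    counts = np.bincount(arr.ravel(), minlength=4).astype(float)
    pi = counts / counts.sum()
    pi = np.maximum(pi, 1e-6)
    pi /= pi.sum()
    # aggregate pair counts over consecutive pairs
    N = np.zeros((4, 4))
    for i in range(0, len(seqs) - 1, 2):
        x, y = arr[i], arr[i + 1]
        np.add.at(N, (x, y), 1.0)

    def negloglik(params):
        kappa, t = np.exp(params)
        model = SubstitutionModel(kappa=kappa, pi=pi, scale=1.0)
        P = expm(model.Q * t)
        P = np.maximum(P, 1e-300)
        return -float(np.sum(N * np.log(pi[:, None] * P)))

    res = minimize(negloglik, x0=np.log([2.0, 0.3]), method="Nelder-Mead")
    kappa, t = np.exp(res.x)
    return SubstitutionModel(kappa=float(kappa), pi=pi, scale=float(t))


def hb_rate(Q: np.ndarray, f: np.ndarray, a: int | str, b: int | str) -> float:
    """Halpern-Bruno substitution rate from base ``a`` to ``b``.

    ``R_ab = Q_ab * ln(x) / (1 - 1/x)`` with ``x = (f_b Q_ba)/(f_a Q_ab)``,
    the ratio of fixation fluxes.  The factor is 1 when the flux ratio is
    1 (neutral limit) and drives the rate to 0 as f_b -> 0.
    """
    a = BASE_INDEX[a] if isinstance(a, str) else a
    b = BASE_INDEX[b] if isinstance(b, str) else b
    if a == b:
        raise ValidationError("hb_rate requires a != b")
    f = np.asarray(f, dtype=float)
    if (f <= 0).any():
        raise ValidationError("PWM column must be strictly positive (pseudocount)")
    qab, qba = float(Q[a, b]), float(Q[b, a])
    if qab == 0.0:
        return 0.0
    x = (f[b] * qba) / (f[a] * qab)
    if np.isclose(x, 1.0):
        return qab
    return qab * np.log(x) / (1.0 - 1.0 / x)


def hb_rate_matrix(Q: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Full 4x4 HB matrix for one PWM column, diagonal re-derived."""
    R = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            if a != b:
                R[a, b] = hb_rate(Q, f, a, b)
    np.fill_diagonal(R, -R.sum(axis=1))
    return R


@dataclass
class RateProfile:
    """Per-position expected distances under the motif and background models."""

    K_model: np.ndarray
    K_background: np.ndarray
    ic: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        if not (len(self.K_model) == len(self.K_background) == len(self.ic)):
            raise LengthMismatchError("profile fields must share one length")
        if (self.K_model < -1e-12).any() or (self.K_background < -1e-12).any():
            raise ValidationError("expected distances must be non-negative")

    def __len__(self) -> int:
        return len(self.K_model)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tK_model\tK_background\tic\n")
            for p in range(len(self)):
                fh.write(
                    f"{p}\t{self.K_model[p]:.6f}\t{self.K_background[p]:.6f}"
                    f"\t{self.ic[p]:.6f}\n"
                )


def expected_distance_profile(
    pwm: PWMModel, model: SubstitutionModel
) -> RateProfile:
    """Expected distance K per position under HB and under the background.

    ``K_model(p) = sum_a f_a(p) sum_{b != a} R_ab(p)`` with R the HB
    matrix of column p; ``K_background = sum_a pi_a sum_{b != a} Q_ab``
    (constant across positions).
    """
    Q = model.Q
    k_bg = float(np.sum(model.pi * (-np.diag(Q))))
    K_model = np.zeros(pwm.length)
    for p in range(pwm.length):
        f = pwm.freqs[:, p].copy()
        f = np.maximum(f, 1e-9)
        f /= f.sum()
        R = hb_rate_matrix(Q, f)
        K_model[p] = float(np.sum(f * (-np.diag(R))))
    ic, _ = information_content(pwm)
    return RateProfile(
        K_model=K_model,
        K_background=np.full(pwm.length, k_bg),
        ic=ic,
        name=pwm.name,
    )


def msd(profile1: RateProfile, profile2: RateProfile, field: str = "K_model") -> float:
    """Mean square difference of one field between two profiles."""
    if len(profile1) != len(profile2):
        raise LengthMismatchError("profiles differ in length")
    x = getattr(profile1, field)
    y = getattr(profile2, field)
    return float(np.mean((np.asarray(x) - np.asarray(y)) ** 2))


def msd_to_background(profile: RateProfile) -> float:
    """MSD between a profile's motif and background distance tracks."""
    return float(np.mean((profile.K_model - profile.K_background) ** 2))


def simulate_site_evolution(
    sites: SiteCollection,
    pwm: PWMModel,
    model: SubstitutionModel,
    time: float,
    seed: int = 0,
) -> SiteCollection:
    """Evolve each site under the position-specific HB process for ``time``.

    Substitutions are sampled from the matrix exponential of the HB rate
    matrix of each column; seeded and deterministic.
    """
    if time < 0:
        raise ConfigurationError("time must be >= 0")
    if sites.length != pwm.length:
        raise LengthMismatchError("site length differs from PWM length")
    rng = np.random.default_rng(seed)
    Q = model.Q
    P_by_pos = []
    for p in range(pwm.length):
        f = np.maximum(pwm.freqs[:, p], 1e-9)
        f /= f.sum()
        P_by_pos.append(expm(hb_rate_matrix(Q, f) * time))
    evolved = []
    for site in sites:
        new = []
        for p, base in enumerate(site.sequence):
            probs = P_by_pos[p][BASE_INDEX[base]]
            probs = np.maximum(probs, 0.0)
            probs /= probs.sum()
            new.append(ALPHABET[rng.choice(4, p=probs)])
        evolved.append(
            BindingSite(
                sequence="".join(new),
                site_id=site.site_id,
                gene=site.gene,
                genome=site.genome,
                tss_offset=site.tss_offset,
                strand=site.strand,
            )
        )
    return SiteCollection(evolved)
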