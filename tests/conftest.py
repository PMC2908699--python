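"""Shared fixtures: planted mixtures with controlled separation."""

from __future__ import annotations

import numpy as np
import pytest

from dcmotif.encode import PWMModel
from dcmotif.seqio import ALPHABET, BindingSite, SiteCollection


def mutate_consensus(cons, p_mut, rng):
    seq = np.array(list(cons))
    mask = rng.random(len(seq)) < p_mut
    for j in np.flatnonzero(mask):
        seq[j] = rng.choice([b for b in ALPHABET if b != seq[j]])
    return "".join(seq)


def tight_mixture(seed, k=3, n_per=20, L=19, p_mut=0.05):
    """k tight Hamming-separated groups around random consensi.

    Returns (SiteCollection, integer labels).
    """
    rng = np.random.default_rng(seed)
    sites, labels = [], []
    for g in range(k):
        cons = "".join(rng.choice(list(ALPHABET), size=L))
        for i in range(n_per):
            sites.append(
                BindingSite(
                    sequence=mutate_consensus(cons, p_mut, rng),
                    site_id=f"g{g}s{i}",
                )
            )
            labels.append(g)
    return SiteCollection(sites), np.array(labels)


def nested_mixture(seed, H=14, fine=4, p_mut=0.02, n_per=15, L=19):
    """2 coarse groups, each split into 2 fine variants (deterministic geometry)."""
    rng = np.random.default_rng(seed)
    base0 = ["A"] * L
    base1 = ["A"] * L
    for j in range(H):
        base1[j] = "C"
    cons = {(0, 0): base0[:], (1, 0): base1[:]}
    cons[(0, 1)] = base0[:]
    cons[(1, 1)] = base1[:]
    for j in range(L - fine, L):
        cons[(0, 1)][j] = "G"
        cons[(1, 1)][j] = "T"
    sites, coarse_labels, fine_labels = [], [], []
    for (c, f), cn in sorted(cons.items()):
        for i in range(n_per):
            sites.append(
                BindingSite(
                    sequence=mutate_consensus("".join(cn), p_mut, rng),
                    site_id=f"c{c}f{f}s{i}",
                )
            )
            coarse_labels.append(c)
            fine_labels.append(2 * c + f)
    return SiteCollection(sites), np.array(coarse_labels), np.array(fine_labels)


def consensus_pwm(rng, L=19, p=0.95, name="pwm"):
    """Fully conserved random-consensus PWM."""
    cons = rng.choice(4, size=L)
    f = np.full((4, L), (1 - p) / 3)
    f[cons, np.arange(L)] = p
    return PWMModel(freqs=f, name=name)


@pytest.fixture
def small_collection():
    return SiteCollection(
        [
            BindingSite("ACGTACGTACGTACGTACG", "s1", gene="gA", genome="spA"),
            BindingSite("ACGTACGTACGTACGTACC", "s2", gene="gB", genome="spB"),
            BindingSite("TTGTACGTACGTACGTACG", "s3", gene="gC", genome="spA"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
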