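"""Replication/bypass simulator: synthetic-data stage 1.

Stands in for the wet-lab replication step (in a polymerase reaction or in
cells).  Each lesion-strand template is independently replicated past the
lesion with probability ``beta`` (the ground-truth bypass probability,
relative to the unmodified control); conditional on bypass, the base
incorporated opposite the lesion is drawn from the incorporation
distribution ``pi`` over {A, C, G, T}.  The progeny duplex then carries the
complement of the incorporated base at the lesion position on its
regenerated top strand.  Blocked templates yield no full-length product at
all; truncated species are not tracked because the assay reads only
full-length digestion products.  The complement (COM20) strand of every
template replicates regardless and its progeny are never PstI-cleavable.

PCR is modeled downstream as a linear, unbiased readout of this template
composition: the assay quantifies end-point band ratios against an
identically amplified control, so any common amplification gain cancels.

An optional indel channel (default off, matching the observed absence of
insertions/deletions) produces one-base insertion/deletion species at the
lesion so the 24-mer length check is exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import csv

import numpy as np

from .constructs import Construct, INTACT
from .seq_core import ParameterError, complement_base

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class LesionParams:
    """Ground-truth bypass/incorporation parameters for one scenario.

    beta
        Probability that a lesion-strand template is replicated past the
        lesion, relative to the STD control; in [0, 1].
    pi
        Distribution over the base incorporated opposite the lesion;
        non-negative entries for A/C/G/T summing to 1.
    indel_prob
        Probability (conditional on bypass) of a one-base insertion or
        deletion at the lesion instead of a normal incorporation.
    """

    beta: float
    pi: Mapping[str, float]
    indel_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ParameterError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.indel_prob <= 1.0:
            raise ParameterError(f"indel_prob must be in [0, 1], got {self.indel_prob}")
        pi = {b: float(self.pi.get(b, 0.0)) for b in BASES}
        extra = set(self.pi) - set(BASES)
        if extra:
            raise ParameterError(f"pi has non-base keys: {sorted(extra)}")
        if any(v < 0 for v in pi.values()):
            raise ParameterError(f"pi entries must be >= 0, got {pi}")
        if abs(sum(pi.values()) - 1.0) > 1e-9:
            raise ParameterError(f"pi must sum to 1 within 1e-9, got {sum(pi.values())}")
        object.__setattr__(self, "pi", pi)

    def pi_vector(self) -> np.ndarray:
        return np.array([self.pi[b] for b in BASES], dtype=float)


@dataclass(frozen=True)
class ProgenyPool:
    """Per-species progeny counts for one construct.

    ``counts`` is keyed by the progeny-strand base at the lesion position
    (plus ``"ins"``/``"del"`` for indel species and ``"intact"`` for the
    control product).  ``com20`` counts complement-strand progeny, one per
    template.  Counts are integers for sampled pools and may be fractional
    for expected (deterministic) pools.
    """

    construct: Construct
    counts: Mapping[str, float]
    blocked: float
    com20: float
    n_templates: int

    @property
    def name(self) -> str:
        return self.construct.name

    @property
    def total_progeny(self) -> float:
        return float(sum(self.counts.values()))


def replicate(
    c: Construct, p: LesionParams, n_templates: int, seed: int
) -> ProgenyPool:
    """Simulate replication of ``n_templates`` copies of one construct.

    The STD control is treated as beta = 1 with a point mass on the correct
    base: every template yields a site-restored product.  Reproducible under
    a fixed seed.
    """
    if n_templates < 1:
        raise ParameterError(f"n_templates must be >= 1, got {n_templates}")
    if c.is_control:
        return ProgenyPool(
            construct=c,
            counts={INTACT: n_templates},
            blocked=0,
            com20=n_templates,
            n_templates=n_templates,
        )
    rng = np.random.default_rng(seed)
    n_bypass = int(rng.binomial(n_templates, p.beta)) if p.beta > 0 else 0
    n_indel = int(rng.binomial(n_bypass, p.indel_prob)) if p.indel_prob > 0 else 0
    n_ins = int(rng.binomial(n_indel, 0.5)) if n_indel else 0
    incorporated = rng.multinomial(n_bypass - n_indel, p.pi_vector())
    counts: dict[str, int] = {}
    for b, k in zip(BASES, incorporated):
        if k:
            counts[complement_base(b)] = int(k)  # progeny base = complement
    if n_ins:
        counts["ins"] = n_ins
    if n_indel - n_ins:
        counts["del"] = n_indel - n_ins
    return ProgenyPool(
        construct=c,
        counts=counts,
        blocked=n_templates - n_bypass,
        com20=n_templates,
        n_templates=n_templates,
    )


def expected_pool(c: Construct, p: LesionParams, n_templates: int) -> ProgenyPool:
    """Deterministic pool carrying the exact expected species composition.

    Replaces the binomial/multinomial draws of :func:`replicate` by their
    means (fractional counts allowed).  This is the noise-free limit of the
    generator: feeding it through a zero-noise gel makes estimator recovery
    exact to floating precision, which pins the estimator algebra down
    independently of Monte-Carlo error.
    """
    if n_templates < 1:
        raise ParameterError(f"n_templates must be >= 1, got {n_templates}")
    if c.is_control:
        return ProgenyPool(
            construct=c,
            counts={INTACT: float(n_templates)},
            blocked=0.0,
            com20=float(n_templates),
            n_templates=n_templates,
        )
    n_bypass = n_templates * p.beta
    n_indel = n_bypass * p.indel_prob
    counts: dict[str, float] = {}
    for b in BASES:
        mean = (n_bypass - n_indel) * p.pi[b]
        if mean > 0:
            counts[complement_base(b)] = mean
    if n_indel > 0:
        counts["ins"] = counts["del"] = n_indel / 2
    return ProgenyPool(
        construct=c,
        counts=counts,
        blocked=n_templates - n_bypass,
        com20=float(n_templates),
        n_templates=n_templates,
    )


def expected_band_fractions(c: Construct, p: LesionParams) -> float:
    """Noise-free expected 20-mer signal fraction relative to the control.

    beta * pi[detected incorporation] for a lesion construct (scaled further
    by (1 - indel_prob) when the indel channel is open), 1.0 for the control.
    This is the analytic mean the simulator converges to and the quantity the
    estimator recovers.
    """
    if c.is_control:
        return 1.0
    assert c.detected_incorporation is not None
    return p.beta * (1.0 - p.indel_prob) * p.pi[c.detected_incorporation]


MANIFEST_COLUMNS = (
    "construct",
    "beta",
    "pi_A",
    "pi_C",
    "pi_G",
    "pi_T",
    "indel_prob",
    "seed",
    "n_templates",
)


def write_manifest(
    path: str | Path, rows: list[tuple[Construct, LesionParams, int, int]]
) -> None:
    """Ground-truth manifest (construct, beta, pi, seed, n) for recovery tests."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MANIFEST_COLUMNS)
        for c, p, seed, n in rows:
            if c.is_control:
                w.writerow([c.name, 1.0, "", "", "", "", 0.0, seed, n])
            else:
                w.writerow(
                    [c.name, p.beta]
                    + [p.pi[b] for b in BASES]
                    + [p.indel_prob, seed, n]
                )
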