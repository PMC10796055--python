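"""Randomness indices for response sequences.

The four behavioral indices — repetitions, adjacencies, turning points and
mean transition distance — plus the Shape statistic and the reshuffle null.
Repetitions are computed on the full sequence; the transition-geometry
indices (adjacencies, turning points, distances) are computed after
collapsing runs of consecutive identical responses, so they reflect
transition patterns rather than repetition frequency.  The Shape statistic
is computed on the full sequence.

Statistics that are undefined for a sequence (e.g. turning points of a
stripped sequence shorter than three) propagate as NaN, never silently as
zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from .domains import TargetDistribution

__all__ = [
    "Sequence",
    "SummaryVector",
    "NullExpectation",
    "FEATURE_NAMES",
    "repetitions",
    "strip_repeats",
    "adjacencies",
    "turning_points",
    "central_turning_points",
    "distances",
    "shape",
    "reshuffle_null",
    "summarize",
    "expected_central_turns_line7",
    "expected_reshuffled_repetitions",
]

#: Summary features fed to model-comparison inference (turning points enter
#: through their central-region restriction, which is the diagnostic one).
FEATURE_NAMES = ("repetitions", "adjacencies", "central_turning_points",
                 "distances", "shape")

ADJACENCY_TOL = 1e-9


@dataclass
class Sequence:
    """One participant-condition response series.

    ``responses`` are grid values: integer centimetres for height domains,
    item ids (1-based) for layouts.  ``raw`` optionally holds the sampler's
    pre-rounding continuous states.
    """

    responses: np.ndarray
    domain: TargetDistribution | None = None
    meta: dict = field(default_factory=dict)
    raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        if self.responses.size < 2:
            raise ValueError("a sequence needs at least 2 responses")

    def __len__(self) -> int:
        return self.responses.size

    @property
    def positions(self) -> np.ndarray:
        """(n, d) coordinates of the responses."""
        if self.domain is not None:
            return self.domain.positions_of(self.responses)
        return np.asarray(self.responses, dtype=float)[:, None]


@dataclass
class SummaryVector:
    """The statistics fed to inference, NaN where undefined."""

    repetitions: float
    adjacencies: float
    turning_points: float
    central_turning_points: float
    distances: float
    shape: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_array(self, feature_names=FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, name) for name in feature_names])

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.to_array(
            tuple(f.name for f in fields(self))))))


@dataclass
class NullExpectation:
    """Mean index values over uniform reshuffles of a sequence.

    Shape is permutation-invariant, so it is not part of the null.
    """

    expected: SummaryVector
    n_reshuffles: int
    seed: object = None


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _resp(seq) -> np.ndarray:
    return seq.responses if isinstance(seq, Sequence) else np.asarray(seq)


def _domain(seq, domain):
    if domain is not None:
        return domain
    return seq.domain if isinstance(seq, Sequence) else None


def _pos(responses: np.ndarray, domain) -> np.ndarray:
    if domain is not None:
        return domain.positions_of(responses)
    return np.asarray(responses, dtype=float)[:, None]


def _strip_mask(responses: np.ndarray) -> np.ndarray:
    keep = np.ones(responses.size, dtype=bool)
    keep[1:] = responses[1:] != responses[:-1]
    return keep


def _turn_flags(pos: np.ndarray) -> np.ndarray:
    """Turn indicator per interior transition of a stripped position path.

    1D: the step sign reverses.  2D: the angle between consecutive
    displacement vectors exceeds 90 degrees (negative dot product; exactly
    90 degrees is not a turn).
    """
    v = np.diff(pos, axis=0)
    if pos.shape[1] == 1:
        s = np.sign(v[:, 0])
        return s[1:] != s[:-1]
    return (v[1:] * v[:-1]).sum(axis=1) < 0.0


# --------------------------------------------------------------------------
# indices
# --------------------------------------------------------------------------

def repetitions(seq) -> float:
    """Proportion of transitions that repeat the previous item."""
    x = _resp(seq)
    return float(np.mean(x[1:] == x[:-1]))


def strip_repeats(seq):
    """Collapse runs of consecutive identical responses to a single item."""
    if isinstance(seq, Sequence):
        keep = _strip_mask(seq.responses)
        out = Sequence.__new__(Sequence)  # bypass the length-2 check: a
        out.responses = seq.responses[keep]  # stripped series may be length 1
        out.domain = seq.domain
        out.meta = dict(seq.meta)
        out.raw = None
        return out
    x = np.asarray(seq)
    return x[_strip_mask(x)]


def adjacencies(seq_stripped, unit: float = 1.0, domain=None) -> float:
    """Proportion of (repeat-stripped) transitions of exactly one unit
    distance; NaN if fewer than one transition remains."""
    x = _resp(seq_stripped)
    if x.size < 2:
        return math.nan
    pos = _pos(x, _domain(seq_stripped, domain))
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(np.mean(np.abs(step - unit) < ADJACENCY_TOL))


def turning_points(seq_stripped, domain=None) -> float:
    """Proportion of direction reversals among transitions with a defined
    previous direction; NaN if the stripped series is shorter than 3."""
    x = _resp(seq_stripped)
    if x.size < 3:
        return math.nan
    return float(np.mean(_turn_flags(_pos(x, _domain(seq_stripped, domain)))))


def central_turning_points(seq_stripped, domain=None, empirical: bool = False) -> float:
    """Turning-point proportion restricted to transitions whose origin (the
    middle item of the triple) lies in the central region.

    Continuous targets use the 37.5-62.5 percentile window of the target
    distribution (or, with ``empirical=True``, of the sequence itself); the
    7-item line uses items {3, 4, 5}; the hex grid its centre item.  NaN if
    no transition qualifies.
    """
    dom = _domain(seq_stripped, domain)
    x = _resp(seq_stripped)
    if x.size < 3:
        return math.nan
    turns = _turn_flags(_pos(x, dom))
    if dom is None or empirical:
        lo, hi = np.percentile(x, [37.5, 62.5])
        central = (x >= lo) & (x <= hi)
    else:
        central = dom.in_center(x)
    mask = central[1:-1]
    if not mask.any():
        return math.nan
    return float(np.mean(turns[mask]))


def distances(seq_stripped, domain=None) -> float:
    """Mean Euclidean step length over repeat-stripped transitions."""
    x = _resp(seq_stripped)
    if x.size < 2:
        return math.nan
    pos = _pos(x, _domain(seq_stripped, domain))
    return float(np.mean(np.linalg.norm(np.diff(pos, axis=0), axis=1)))


def shape(seq) -> float:
    """Shape statistic S: how much more Gaussian than uniform a sequence is.

    S = (1/N) sum_n [lpdf_G(x_n) - lpdf_U(x_n)], where the Gaussian is the
    maximum-likelihood fit (sample mean, population sd) and the uniform is
    the maximum-likelihood fit (support [min, max]) to the sequence itself.
    Positive S: the Gaussian describes the sequence better.  Repeats are
    not removed.
    """
    x = np.asarray(_resp(seq), dtype=float)
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("Shape is undefined for a constant sequence (degenerate fits)")
    mu = x.mean()
    sd = x.std()  # population (1/N) variance: the Gaussian MLE
    lpdf_g = -0.5 * ((x - mu) / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))
    lpdf_u = -math.log(hi - lo)
    return float(np.mean(lpdf_g) - lpdf_u)


def summarize(seq, domain=None) -> SummaryVector:
    """All six indices with the stated repeat-stripping conventions."""
    dom = _domain(seq, domain)
    x = _resp(seq)
    stripped = x[_strip_mask(x)]
    try:
        s = shape(seq)
    except ValueError:
        s = math.nan
    return SummaryVector(
        repetitions=repetitions(x),
        adjacencies=adjacencies(stripped, domain=dom),
        turning_points=turning_points(stripped, domain=dom),
        central_turning_points=central_turning_points(stripped, domain=dom),
        distances=distances(stripped, domain=dom),
        shape=s,
    )


def reshuffle_null(seq, n: int = 10_000, seed=None, rng=None, domain=None) -> NullExpectation:
    """Expected index values under uniform random permutations.

    Repetitions are computed on each permuted sequence as-is; the
    transition-geometry indices are computed after stripping the permuted
    sequence.  Means are taken over permutations where the index is
    defined.  Shape is permutation-invariant and therefore omitted (NaN).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    dom = _domain(seq, domain)
    x = _resp(seq)
    acc = np.zeros((n, 5))
    for i in range(n):
        perm = rng.permutation(x)
        stripped = perm[_strip_mask(perm)]
        acc[i] = (
            repetitions(perm),
            adjacencies(stripped, domain=dom),
            turning_points(stripped, domain=dom),
            central_turning_points(stripped, domain=dom),
            distances(stripped, domain=dom),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns stay NaN
        means = np.nanmean(acc, axis=0)
    expected = SummaryVector(*means, shape=math.nan)
    return NullExpectation(expected=expected, n_reshuffles=n, seed=seed)


# --------------------------------------------------------------------------
# exact expectations (enumeration oracles)
# --------------------------------------------------------------------------

def expected_central_turns_line7(n_items: int = 7, center=(3, 4, 5)) -> float:
    """Exact central turning-point expectation for no-repeat iid sampling on
    an ordered item line.

    Enumerates triples (a, b, c) with the origin b restricted to the
    central items and a, c uniform over the items different from b, and
    returns the probability that the a->b and b->c directions differ.
    """
    turns = 0
    total = 0
    items = range(1, n_items + 1)
    for b in center:
        for a in items:
            if a == b:
                continue
            for c in items:
                if c == b:
                    continue
                total += 1
                if np.sign(b - a) != np.sign(c - b):
                    turns += 1
    return turns / total


def expected_reshuffled_repetitions(x) -> float:
    """Closed-form reshuffle-null repetition rate: sum c_i(c_i - 1) / (N(N-1))
    for item counts c_i."""
    x = np.asarray(x)
    n = x.size
    _, counts = np.unique(x, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))
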