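"""Target distributions and response layouts for random-generation tasks.

A :class:`TargetDistribution` is the density a participant (or a sampling
algorithm standing in for one) is asked to reproduce: the Gaussian
distribution of adult heights, a scaled Beta over a bounded height range, or
a uniform distribution over a small set of spatially arranged items.  It
bundles the continuous density used by the samplers (log-density and its
gradient) with the response grid (integer centimetres, or item positions)
onto which continuous states are rounded before being "uttered".

Discrete item sets carry a :class:`Layout`: the 7-item line, or the 7-hex
grid arranged as rows of two, three and two hexagons, with all touching
hexes exactly one unit apart.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from scipy.special import betaln

__all__ = [
    "Layout",
    "TargetDistribution",
    "get_layout",
    "make_domain",
    "NEG_INF",
]

NEG_INF = float("-inf")

_SQ3_2 = math.sqrt(3.0) / 2.0

# Item coordinates, row-major from the top.  Line: items 1..7 on the x-axis.
_LINE7_POS = np.array([[float(i), 0.0] for i in range(1, 8)])
# Hex grid: rows of 2, 3, 2 pointy-top hexagons; touching centres at unit
# distance; item 4 is the centre.
_HEX7_POS = np.array(
    [
        [-0.5, _SQ3_2],
        [0.5, _SQ3_2],
        [-1.0, 0.0],
        [0.0, 0.0],
        [1.0, 0.0],
        [-0.5, -_SQ3_2],
        [0.5, -_SQ3_2],
    ]
)

# Convex hull of the hex centres: a regular hexagon with circumradius 1.
# Outward edge normals (unit vectors at 30 + 60k degrees) and offsets.
_HEX_HULL_NORMALS = np.array(
    [
        [math.cos(math.radians(30 + 60 * k)), math.sin(math.radians(30 + 60 * k))]
        for k in range(6)
    ]
)
_HEX_HULL_OFFSET = _SQ3_2  # apothem of the hull hexagon


@dataclass(frozen=True)
class Layout:
    """Geometry of a discrete response set.

    ``positions`` holds one 2D coordinate per item (items are numbered from
    1); ``center_items`` are the items whose outgoing transitions count for
    the central turning-point analysis.
    """

    kind: str
    positions: np.ndarray = field(repr=False)
    center_items: tuple[int, ...]

    @property
    def n_items(self) -> int:
        return self.positions.shape[0]

    @property
    def adjacency(self) -> list[tuple[int, int]]:
        """Pairs of items at unit distance (1-based, i < j)."""
        pairs = []
        n = self.n_items
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(self.positions[i] - self.positions[j])
                if abs(d - 1.0) < 1e-9:
                    pairs.append((i + 1, j + 1))
        return pairs


_LAYOUTS = {
    "line7": Layout(kind="line7", positions=_LINE7_POS, center_items=(3, 4, 5)),
    "hex7": Layout(kind="hex7", positions=_HEX7_POS, center_items=(4,)),
}


def get_layout(name: str) -> Layout:
    try:
        return _LAYOUTS[name]
    except KeyError:
        raise ValueError(f"unknown layout {name!r}; available: {sorted(_LAYOUTS)}")


# Family codes shared with the compiled sampler kernels.
FAM_GAUSSIAN = 0
FAM_SCALED_BETA = 1
FAM_FLAT_1D = 2
FAM_FLAT_HEX = 3


@dataclass(frozen=True)
class TargetDistribution:
    """A target density plus the response grid used to utter from it.

    Parameters are family-specific: ``gaussian`` uses ``mean``/``sd`` (cm),
    ``scaled_beta`` uses ``alpha``/``beta`` on the interval ``[lo, hi]``
    (cm), and ``discrete_uniform`` uses an item count ``k`` with a named
    ``layout``.  Continuous sampling for a discrete layout runs on the
    convex hull of the item coordinates under a flat density; responses are
    produced by nearest-item rounding.
    """

    family: str
    params: dict[str, Any] = field(repr=True)
    grid_step: float = 1.0
    layout: Layout | None = None
    #: Explicit bounded response range (lo, hi) for generators that need one
    #: on an unbounded target (the schema model); defaults to the grid range
    #: for bounded families and mean +/- 3.5 sd for the Gaussian.
    response_range: tuple[float, float] | None = None

    # ------------------------------------------------------------------ geometry
    @property
    def ndim(self) -> int:
        return 2 if (self.layout is not None and self.layout.kind == "hex7") else 1

    @property
    def support(self) -> tuple[float, float]:
        """Closed interval of the continuous support (1D families).

        For the hex layout the support is the hull polygon; the returned
        interval is the bounding range on x and should not be used for
        membership tests there.
        """
        if self.family == "gaussian":
            return (NEG_INF, math.inf)
        if self.family == "scaled_beta":
            return (self.params["lo"], self.params["hi"])
        if self.layout is not None and self.layout.kind == "line7":
            return (1.0, float(self.layout.n_items))
        return (-1.0, 1.0)

    @property
    def width(self) -> float:
        """Characteristic width of the support, used to scale sampler priors.

        Bounded families use the support length; the unbounded Gaussian uses
        six standard deviations; the hex hull uses its diameter.
        """
        if self.family == "gaussian":
            return 6.0 * self.params["sd"]
        if self.ndim == 2:
            return 2.0
        lo, hi = self.support
        return hi - lo

    @property
    def grid_values(self) -> np.ndarray:
        """All representable responses (finite families only)."""
        if self.family == "discrete_uniform":
            return np.arange(1, self.layout.n_items + 1)
        if self.family == "scaled_beta":
            lo, hi = self.support
            return np.arange(math.ceil(lo), math.floor(hi) + 1)
        raise ValueError("gaussian support has no finite response grid")

    @property
    def schema_grid(self) -> np.ndarray:
        """Integer response range available to the schema generator."""
        if self.response_range is not None:
            lo, hi = self.response_range
            return np.arange(math.ceil(lo), math.floor(hi) + 1)
        if self.family == "gaussian":
            mu, sd = self.params["mean"], self.params["sd"]
            return np.arange(round(mu - 3.5 * sd), round(mu + 3.5 * sd) + 1)
        return self.grid_values

    def in_support(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.ndim == 2:
            proj = x @ _HEX_HULL_NORMALS.T
            return np.all(proj <= _HEX_HULL_OFFSET + 1e-12, axis=-1)
        lo, hi = self.support
        return (x >= lo) & (x <= hi)

    # ------------------------------------------------------------------ density
    def log_density(self, x):
        """Normalized log density; ``-inf`` outside the support."""
        x = np.asarray(x, dtype=float)
        if self.family == "gaussian":
            mu, sd = self.params["mean"], self.params["sd"]
            return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))
        if self.family == "scaled_beta":
            a, b = self.params["alpha"], self.params["beta"]
            lo, hi = self.support
            w = hi - lo
            z = (x - lo) / w
            with np.errstate(divide="ignore", invalid="ignore"):
                lp = np.where(
                    (z > 0) & (z < 1),
                    (a - 1) * np.log(z) + (b - 1) * np.log1p(-z),
                    NEG_INF,
                )
            # interior endpoints of Beta(1,1) are fine: 0*log(0) handled above
            lp = np.where((z == 0) | (z == 1), NEG_INF, lp)
            return lp - betaln(a, b) - math.log(w)
        # flat families
        if self.ndim == 2:
            area = 3.0 * math.sqrt(3.0) / 2.0  # regular hexagon, R = 1
            return np.where(self.in_support(x), -math.log(area), NEG_INF)
        lo, hi = self.support
        return np.where((x >= lo) & (x <= hi), -math.log(hi - lo), NEG_INF)

    def grad_log_density(self, x):
        """Analytic gradient of the log density at interior points.

        Raises at or beyond the support boundary for bounded families;
        samplers are expected to reflect positions inside before calling.
        """
        x = np.asarray(x, dtype=float)
        if self.family == "gaussian":
            mu, sd = self.params["mean"], self.params["sd"]
            return (mu - x) / sd**2
        if self.family == "scaled_beta":
            a, b = self.params["alpha"], self.params["beta"]
            lo, hi = self.support
            w = hi - lo
            z = (x - lo) / w
            if np.any((z <= 0) | (z >= 1)):
                raise ValueError("gradient requested at or beyond the support boundary")
            return ((a - 1) / z - (b - 1) / (1 - z)) / w
        if self.ndim == 2:
            if not np.all(self.in_support(x)):
                raise ValueError("gradient requested outside the hex hull")
            return np.zeros_like(x)
        lo, hi = self.support
        if np.any((x < lo) | (x > hi)):
            raise ValueError("gradient requested outside the support")
        return np.zeros_like(x)

    # ------------------------------------------------------------------ grid
    def round_to_grid(self, x):
        """Map continuous states to responses.

        1D: nearest grid value, ties toward the smaller value.  Hex: nearest
        item centre by Euclidean distance (ties to the lower item number).
        """
        x = np.asarray(x, dtype=float)
        if self.ndim == 2:
            pts = np.atleast_2d(x)
            d2 = ((pts[:, None, :] - self.layout.positions[None, :, :]) ** 2).sum(-1)
            ids = np.argmin(d2, axis=1) + 1
            return ids if x.ndim == 2 else int(ids[0])
        vals = np.ceil(x / self.grid_step - 0.5) * self.grid_step
        if self.family != "gaussian":
            lo, hi = self.support
            gmin, gmax = math.ceil(lo), math.floor(hi)
            vals = np.clip(vals, gmin, gmax)
        if self.grid_step == 1.0:
            vals = vals.astype(int) if vals.ndim else int(vals)
        return vals

    # ------------------------------------------------------------------ quantiles
    def percentile(self, q: float) -> float:
        """Quantile of the target (continuous families only); q in [0, 100]."""
        if self.family == "gaussian":
            return float(stats.norm.ppf(q / 100, self.params["mean"], self.params["sd"]))
        if self.family == "scaled_beta":
            a, b = self.params["alpha"], self.params["beta"]
            lo, hi = self.support
            return float(lo + (hi - lo) * stats.beta.ppf(q / 100, a, b))
        raise ValueError("percentiles are defined for continuous families only")

    def center_window(self, lo_pct: float = 37.5, hi_pct: float = 62.5) -> tuple[float, float]:
        return (self.percentile(lo_pct), self.percentile(hi_pct))

    def in_center(self, responses) -> np.ndarray:
        """Whether each response lies in the central region.

        Continuous targets: the 37.5-62.5 percentile window of the target.
        Line layout: the three central items; hex layout: the centre item.
        """
        responses = np.asarray(responses)
        if self.layout is not None:
            return np.isin(responses, self.layout.center_items)
        lo, hi = self.center_window()
        return (responses >= lo) & (responses <= hi)

    # ------------------------------------------------------------------ positions
    def positions_of(self, responses) -> np.ndarray:
        """Coordinates of responses as an (n, d) float array."""
        responses = np.asarray(responses)
        if self.ndim == 2:
            return self.layout.positions[responses.astype(int) - 1]
        return np.asarray(responses, dtype=float)[:, None]

    # ------------------------------------------------------------------ kernels
    def kernel_spec(self) -> tuple[int, float, float, float, float]:
        """(family code, a, b, lo, hi) consumed by the compiled samplers."""
        if self.family == "gaussian":
            return (FAM_GAUSSIAN, self.params["mean"], self.params["sd"], NEG_INF, math.inf)
        if self.family == "scaled_beta":
            lo, hi = self.support
            return (FAM_SCALED_BETA, self.params["alpha"], self.params["beta"], lo, hi)
        if self.ndim == 2:
            return (FAM_FLAT_HEX, 0.0, 0.0, -1.0, 1.0)
        lo, hi = self.support
        return (FAM_FLAT_1D, 0.0, 0.0, lo, hi)

    # ------------------------------------------------------------------ serialization
    def to_json(self) -> str:
        d: dict[str, Any] = {"family": self.family, "grid": self.grid_step}
        d.update(self.params)
        if self.layout is not None:
            d["layout"] = self.layout.kind
        if self.response_range is not None:
            d["response_range"] = list(self.response_range)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "TargetDistribution":
        d = json.loads(s)
        family = d.pop("family")
        grid = d.pop("grid", 1.0)
        return make_domain(family, grid_step=grid, **d)


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid parameter {field_name!r}: {msg}")


def make_domain(family: str, grid_step: float = 1.0, **params) -> TargetDistribution:
    """Build a validated :class:`TargetDistribution`.

    Examples
    --------
    >>> make_domain("gaussian", mean=176.4, sd=12)
    >>> make_domain("scaled_beta", alpha=1.27, beta=1.43, lo=122, hi=219)
    >>> make_domain("discrete_uniform", k=7, layout="hex7")
    """
    rr = params.pop("response_range", None)
    if rr is not None:
        rr = (float(rr[0]), float(rr[1]))
    if family == "gaussian":
        _require("mean" in params, "mean", "missing")
        _require("sd" in params and params["sd"] > 0, "sd", "must be > 0")
        p = {"mean": float(params["mean"]), "sd": float(params["sd"])}
        return TargetDistribution("gaussian", p, grid_step, response_range=rr)
    if family == "scaled_beta":
        for k in ("alpha", "beta", "lo", "hi"):
            _require(k in params, k, "missing")
        _require(params["alpha"] > 0, "alpha", "must be > 0")
        _require(params["beta"] > 0, "beta", "must be > 0")
        _require(params["lo"] < params["hi"], "lo", "must satisfy lo < hi")
        p = {k: float(params[k]) for k in ("alpha", "beta", "lo", "hi")}
        return TargetDistribution("scaled_beta", p, grid_step, response_range=rr)
    if family == "discrete_uniform":
        k = params.get("k", params.get("K"))
        _require(k is not None and k >= 2, "k", "must be an integer >= 2")
        layout_name = params.get("layout", "line7")
        layout = get_layout(layout_name)
        _require(k == layout.n_items, "k", f"must match layout {layout_name} ({layout.n_items} items)")
        return TargetDistribution("discrete_uniform", {"k": int(k), "layout": layout_name},
                                  grid_step, layout=layout)
    raise ValueError(f"invalid parameter 'family': unknown family {family!r}")


def heights_gaussian() -> TargetDistribution:
    """Experiment-1 Gaussian condition: UK adult heights, N(176.4, 12) cm.

    The response range available to the schema generator is the study's
    average of participants' stated minimum and maximum heights, 131-213 cm.
    """
    return make_domain("gaussian", mean=176.4, sd=12.0, response_range=(131, 213))


def heights_uniform() -> TargetDistribution:
    """Experiment-1 Uniform condition: Beta(1.27, 1.43) scaled to 122-219 cm."""
    return make_domain("scaled_beta", alpha=1.27, beta=1.43, lo=122.0, hi=219.0)


def syllables(layout: str = "line7") -> TargetDistribution:
    """Experiment-2 domains: a uniform target over 7 items on a line or hex grid."""
    return make_domain("discrete_uniform", k=7, layout=layout)
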