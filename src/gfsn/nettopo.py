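"""Global topology statistics and degree-distribution model fitting.

The summary statistics follow the Cytoscape NetworkAnalyzer conventions
(the standard instrument for these network report tables):

* cluster coefficient: mean of nodal clustering coefficients, nodes of
  degree < 2 contributing 0;
* characteristic path length: mean shortest-path length over ordered
  reachable node pairs; ``n_shortest_paths`` counts those pairs;
* centralization: (n/(n-2)) * (max_degree/(n-1) - density);
* heterogeneity: coefficient of variation of the degree sequence.

Path-based metrics are computed on the largest connected component when
the network is disconnected (logged).

Degree histograms (node count versus degree, zero-degree nodes set
aside) are fitted by nonlinear least squares under four parametric
models — Gaussian, power law, log-normal and exponential — and ranked
by the coefficient of determination R².
"""

from __future__ import annotations

import dataclasses
import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "TopologySummary",
    "DistributionFit",
    "MODEL_NAMES",
    "topology_summary",
    "degree_histogram",
    "fit_degree_distribution",
    "best_fit",
]

MODEL_NAMES = ("gaussian", "power_law", "log_normal", "exponential")


@dataclasses.dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    cluster_coefficient: float
    diameter: int
    radius: int
    centralization: float
    n_shortest_paths: int
    characteristic_path_length: float
    avg_neighbors: float
    density: float
    heterogeneity: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class DistributionFit:
    model: str
    params: dict[str, float]
    r_squared: float | None
    converged: bool

    @property
    def n_params(self) -> int:
        return len(_MODELS[self.model][1])

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "r_squared": self.r_squared,
            "converged": self.converged,
        }


def topology_summary(net: nx.Graph) -> TopologySummary:
    """Table-1 style statistics; edge weights are ignored."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    m = net.number_of_edges()
    degrees = np.array([d for _, d in net.degree], dtype=float)
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    avg_neighbors = float(degrees.mean())
    mean_deg = degrees.mean()
    heterogeneity = float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else 0.0
    if n > 2:
        centralization = (n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density)
    else:
        centralization = 0.0
    clustering = nx.clustering(net)  # degree<2 nodes get 0
    cc = float(np.mean(list(clustering.values())))

    work = net
    if not nx.is_connected(net):
        comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
        work = net.subgraph(comps[0])
        logger.info(
            "network disconnected (%d components); path metrics on largest (%d nodes)",
            len(comps), work.number_of_nodes(),
        )
    total, count, diameter = 0, 0, 0
    eccentricities = []
    for src, lengths in nx.all_pairs_shortest_path_length(work):
        ecc = 0
        for dst, d in lengths.items():
            if dst == src:
                continue
            total += d
            count += 1
            ecc = max(ecc, d)
        eccentricities.append(ecc)
    diameter = max(eccentricities) if eccentricities else 0
    radius = min(eccentricities) if eccentricities else 0
    cpl = total / count if count else 0.0
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        cluster_coefficient=cc,
        diameter=int(diameter),
        radius=int(radius),
        centralization=float(centralization),
        n_shortest_paths=count,
        characteristic_path_length=float(cpl),
        avg_neighbors=avg_neighbors,
        density=float(density),
        heterogeneity=heterogeneity,
    )


def degree_histogram(net: nx.Graph) -> pd.DataFrame:
    """Node count per observed degree k >= 1.

    Zero-degree nodes are excluded from the table (log-scale models are
    undefined at k = 0) and reported in ``frame.attrs["n_zero_degree"]``.
    """
    degs = [d for _, d in net.degree]
    n_zero = sum(1 for d in degs if d == 0)
    counts: dict[int, int] = {}
    for d in degs:
        if d >= 1:
            counts[d] = counts.get(d, 0) + 1
    frame = pd.DataFrame(
        {"degree": sorted(counts), "count": [counts[k] for k in sorted(counts)]}
    )
    frame.attrs["n_zero_degree"] = n_zero
    return frame


# ---------------------------------------------------------------------------
# model forms (Origin-style parametrisations)

def _gaussian(x, y0, xc, w, A):
    return y0 + (A / (w * np.sqrt(np.pi / 2.0))) * np.exp(-2.0 * ((x - xc) / w) ** 2)


def _power_law(x, a, b):
    return a * np.power(x, b)


def _log_normal(x, y0, xc, w, A):
    return y0 + (A / (w * x * np.sqrt(2.0 * np.pi))) * np.exp(
        -(np.log(x / xc) ** 2) / (2.0 * w**2)
    )


def _exponential(x, y0, A1, t1):
    return y0 + A1 * np.exp(x / t1)


_MODELS = {
    "gaussian": (_gaussian, ("y0", "x_c", "w", "A")),
    "power_law": (_power_law, ("a", "b")),
    "log_normal": (_log_normal, ("y0", "x_c", "w", "A")),
    "exponential": (_exponential, ("y0", "A1", "t1")),
}


def _bounds(model: str, x: np.ndarray) -> tuple[list[float], list[float]]:
    """Parameter bounds keeping peaked models in their interpretable regime.

    The Gaussian and log-normal location x_c is confined to the observed
    degree range and the width to positive values; otherwise the peak can
    collapse below the smallest degree, where the curve degenerates into a
    monotone power-law mimic with no distributional reading.
    """
    inf = np.inf
    lo, hi = float(x.min()), float(x.max())
    if model in ("gaussian", "log_normal"):
        return ([-inf, lo, 1e-12, -inf], [inf, hi, inf, inf])
    return ([-inf] * {"power_law": 2, "exponential": 3}[model], [inf] * {"power_law": 2, "exponential": 3}[model])


def _starts(model: str, x: np.ndarray, y: np.ndarray) -> list[list[float]]:
    """Multi-start initial guesses seeded from the data."""
    ymin, ymax = float(y.min()), float(y.max())
    if model == "power_law":
        # log-log linear regression seed
        b, loga = np.polyfit(np.log(x), np.log(np.maximum(y, 1e-12)), 1)
        return [[math.exp(loga), b], [ymax, -1.0]]
    if model == "gaussian":
        wsum = y.sum()
        mu = float((x * y).sum() / wsum)
        sd = float(np.sqrt(((x - mu) ** 2 * y).sum() / wsum)) or 1.0
        starts = []
        for y0 in (0.0, ymin):
            starts.append([y0, mu, 2.0 * sd, (ymax - y0) * sd * math.sqrt(2.0 * math.pi)])
        starts.append([0.0, float(x[np.argmax(y)]), 2.0 * sd, ymax * sd])
        return starts
    if model == "log_normal":
        wsum = y.sum()
        mu = float((np.log(x) * y).sum() / wsum)
        sd = float(np.sqrt(((np.log(x) - mu) ** 2 * y).sum() / wsum)) or 0.5
        starts = []
        for y0 in (0.0, ymin):
            starts.append([y0, math.exp(mu), sd, (ymax - y0) * sd * math.sqrt(2.0 * math.pi)])
        starts.append([0.0, float(x[np.argmax(y)]), max(sd, 0.3), ymax])
        return starts
    if model == "exponential":
        span = float(x.max() - x.min()) or 1.0
        starts = []
        for y0 in (0.0, ymin):
            for t1 in (-span / 3.0, span / 3.0, -span, span):
                a1 = (ymax - y0) / math.exp(x.min() / t1) if t1 != 0 else ymax
                starts.append([y0, a1, t1])
        return starts
    raise ValueError(model)


def fit_degree_distribution(hist: pd.DataFrame, model: str) -> DistributionFit:
    """Nonlinear least-squares fit of node count against degree.

    Fitting is on the raw (degree, count) scatter, unbinned and
    unweighted.  Multiple data-driven starts are tried; the best
    converged solution (lowest residual sum of squares) is kept.
    Returns ``converged=False`` (with ``r_squared=None``) rather than
    garbage when no start converges.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    func, names = _MODELS[model]
    x = np.asarray(hist["degree"], dtype=float)
    y = np.asarray(hist["count"], dtype=float)
    if len(np.unique(x)) < len(names) + 1:
        raise ValueError(
            f"need at least {len(names) + 1} distinct degrees to fit {model} ({len(x)} given)"
        )
    best_popt, best_rss = None, np.inf
    lower, upper = _bounds(model, x)
    for p0 in _starts(model, x, y):
        p0 = [min(max(p, lo), up) for p, lo, up in zip(p0, lower, upper)]
        try:
            with np.errstate(all="ignore"):
                popt, _ = curve_fit(func, x, y, p0=p0, bounds=(lower, upper),
                                    maxfev=10000, xtol=1e-10, ftol=1e-10)
                resid = y - func(x, *popt)
            rss = float(np.sum(resid**2))
        except (RuntimeError, ValueError, FloatingPointError):
            continue
        if np.isfinite(rss) and rss < best_rss:
            best_popt, best_rss = popt, rss
    if best_popt is None:
        return DistributionFit(model=model, params={}, r_squared=None, converged=False)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_rss / ss_tot if ss_tot > 0 else (1.0 if best_rss == 0 else 0.0)
    params = {name: float(v) for name, v in zip(names, best_popt)}
    return DistributionFit(model=model, params=params, r_squared=float(r2), converged=True)


def best_fit(hist: pd.DataFrame) -> list[DistributionFit]:
    """Fit all four models and rank by R² (ties: fewer parameters first).

    Per-model failures (too few points, no convergence) are kept at the
    bottom of the ranking instead of aborting the comparison.
    """
    fits: list[DistributionFit] = []
    for model in MODEL_NAMES:
        try:
            fits.append(fit_degree_distribution(hist, model))
        except ValueError as exc:
            logger.warning("model %s not fitted: %s", model, exc)
            fits.append(DistributionFit(model=model, params={}, r_squared=None, converged=False))
    fits.sort(key=lambda f: (-(f.r_squared if f.converged else -np.inf), f.n_params))
    return fits
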