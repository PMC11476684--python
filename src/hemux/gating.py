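"""Marker gating and tile-level co-occurrence analysis.

Continuous per-tile marker z-scores are binarized into positive/negative
calls by fitting a two-component Gaussian mixture per marker and slide: the
lower-mean component models background, the higher-mean component positive
tiles, and the decision threshold is the smallest value whose posterior
probability of the positive component reaches 1/2. Calls are by
construction threshold-monotone (``value >= threshold``).

Co-occurrence classes are named marker subsets (e.g. PD1+/PDL1+): a tile
belongs to a class when all its markers are called positive, which at tile
resolution is read as evidence of cell–cell interaction. Predicted-vs-
measured class agreement is reported as a column-normalized confusion
matrix whose diagonal is per-class precision, and enrichment of a context
marker in interacting tiles is tested with a one-sided paired (by slide)
t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .panel import MarkerPanel

logger = logging.getLogger(__name__)


class GmmGate(BaseEstimator):
    """Two-component Gaussian-mixture gate for one marker on one slide.

    Parameters mirror the EM configuration: ``n_init`` k-means++ restarts,
    convergence tolerance, iteration cap and seed. After ``fit``:
    ``means_`` (low, high), ``sds_``, ``weights_``, ``threshold_`` and
    ``degenerate_`` (set when the fitted means are closer than
    ``min_separation`` pooled standard deviations — then every tile is
    called negative).
    """

    MIN_VALUES = 50

    def __init__(
        self,
        n_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        min_separation: float = 0.1,
        random_state: int = 0,
    ):
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.min_separation = min_separation
        self.random_state = random_state

    def fit(self, values) -> "GmmGate":
        v = np.asarray(values, dtype=float).ravel()
        v = v[np.isfinite(v)]
        if v.size < self.MIN_VALUES:
            raise ValueError(
                f"need >= {self.MIN_VALUES} finite values to fit a gate, got {v.size}"
            )
        if np.std(v) < 1e-12:
            self.means_ = np.array([v[0], v[0]])
            self.sds_ = np.array([0.0, 0.0])
            self.weights_ = np.array([1.0, 0.0])
            self.degenerate_ = True
            self.threshold_ = np.inf
            return self
        gm = GaussianMixture(
            n_components=2,
            covariance_type="spherical",
            n_init=self.n_init,
            init_params="k-means++",
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(v[:, None])
        order = np.argsort(gm.means_.ravel())
        mu = gm.means_.ravel()[order]
        sd = np.sqrt(gm.covariances_.ravel()[order])
        pi = gm.weights_.ravel()[order]
        self.means_ = mu
        self.sds_ = sd
        self.weights_ = pi
        pooled_sd = np.sqrt(pi[0] * sd[0] ** 2 + pi[1] * sd[1] ** 2)
        if mu[1] - mu[0] < self.min_separation * max(pooled_sd, 1e-12):
            self.degenerate_ = True
            self.threshold_ = np.inf
            return self
        self.degenerate_ = False
        self.threshold_ = self._posterior_crossing(v)
        return self

    def _posterior(self, x: np.ndarray) -> np.ndarray:
        mu, sd, pi = self.means_, np.maximum(self.sds_, 1e-12), self.weights_
        log0 = np.log(max(pi[0], 1e-300)) + stats.norm.logpdf(x, mu[0], sd[0])
        log1 = np.log(max(pi[1], 1e-300)) + stats.norm.logpdf(x, mu[1], sd[1])
        m = np.maximum(log0, log1)
        return np.exp(log1 - m) / (np.exp(log0 - m) + np.exp(log1 - m))

    def _posterior_crossing(self, v: np.ndarray) -> float:
        """Smallest value between the means where P(positive | x) >= 1/2.

        The search is restricted to [mu0, mu1]: with unequal variances the
        broad component can also dominate the far-left tail, and a crossing
        there would call every tile positive.
        """
        lo, hi = float(self.means_[0]), float(self.means_[1])
        grid = np.linspace(lo, hi, 4097)
        post = self._posterior(grid)
        above = np.nonzero(post >= 0.5)[0]
        if above.size == 0:
            return np.inf
        first = above[0]
        if first == 0:
            return lo
        a, b = grid[first - 1], grid[first]
        for _ in range(60):  # bisect the first crossing
            midp = 0.5 * (a + b)
            if self._posterior(np.array([midp]))[0] >= 0.5:
                b = midp
            else:
                a = midp
        return float(b)

    def predict(self, values) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("GmmGate is not fitted")
        return np.asarray(values, dtype=float) >= self.threshold_


def fit_gate(values, seed: int = 0, **kwargs) -> GmmGate:
    return GmmGate(random_state=seed, **kwargs).fit(values)


def fit_gates(
    tiles: pd.DataFrame,
    panel: MarkerPanel,
    seed: int = 0,
    column: str = "z",
    **kwargs,
) -> dict[tuple[str, str], GmmGate]:
    """Fit one gate per (slide, marker) on the tile table's z columns."""
    gates: dict[tuple[str, str], GmmGate] = {}
    for slide_id, sub in tiles.groupby("slide_id"):
        for name in panel.names:
            vals = sub[f"{name}_{column}"].to_numpy(dtype=float)
            gates[(str(slide_id), name)] = fit_gate(vals, seed=seed, **kwargs)
    return gates


def call_markers(
    tiles: pd.DataFrame,
    gates: dict[tuple[str, str], GmmGate],
    panel: MarkerPanel,
    column: str = "z",
) -> pd.DataFrame:
    """Apply fitted gates; returns a boolean call table aligned with tiles."""
    calls = pd.DataFrame(index=tiles.index)
    calls["slide_id"] = tiles["slide_id"]
    for name in panel.names:
        col = np.zeros(len(tiles), dtype=bool)
        for slide_id, idx in tiles.groupby("slide_id").groups.items():
            key = (str(slide_id), name)
            if key not in gates:
                raise KeyError(f"no gate fitted for slide={slide_id!r} marker={name!r}")
            loc = tiles.index.get_indexer(idx)
            vals = tiles.loc[idx, f"{name}_{column}"].to_numpy(dtype=float)
            col[loc] = gates[key].predict(vals)
        calls[name] = col
    return calls


# ---------------------------------------------------------------------------
# Co-occurrence classes


@dataclass(frozen=True)
class CooccurrenceClass:
    """A named subset of markers; a tile matches when all are positive."""

    name: str
    markers: tuple[str, ...]

    def member_mask(self, calls: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(calls), dtype=bool)
        for m in self.markers:
            mask &= calls[m].to_numpy(dtype=bool)
        return mask


DEFAULT_CLASSES = (
    CooccurrenceClass("CD45+", ("CD45",)),
    CooccurrenceClass("CD4+/FOXP3+/CD8a+", ("CD4", "FOXP3", "CD8a")),
    CooccurrenceClass("PDL1+", ("PDL1",)),
    CooccurrenceClass("PD1+/PDL1+", ("PD1", "PDL1")),
    CooccurrenceClass("CD68+/PDL1+/CD8a+/PD1+", ("CD68", "PDL1", "CD8a", "PD1")),
)

NONE_CLASS = "none"


def assign_classes(
    calls: pd.DataFrame, classes: tuple[CooccurrenceClass, ...]
) -> np.ndarray:
    """Exclusive class label per tile: the largest matching class wins.

    A tile whose positive markers satisfy several listed classes is counted
    under the one with the most markers (earlier in the list on ties);
    tiles matching none are labeled "none".
    """
    order = sorted(
        range(len(classes)), key=lambda i: (-len(classes[i].markers), i)
    )
    labels = np.full(len(calls), NONE_CLASS, dtype=object)
    unassigned = np.ones(len(calls), dtype=bool)
    for i in order:
        mask = classes[i].member_mask(calls) & unassigned
        labels[mask] = classes[i].name
        unassigned &= ~mask
    return labels


def confusion_by_class(
    true_calls: pd.DataFrame,
    pred_calls: pd.DataFrame,
    classes: tuple[CooccurrenceClass, ...] = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Column-normalized confusion matrix over co-occurrence classes.

    Columns index the class *predicted* for a tile, rows the measured class;
    each defined column sums to 1, so the diagonal entry is the class's
    precision (true positive calls over predicted positive calls). Columns
    with no predicted tiles are NaN.
    """
    if len(true_calls) != len(pred_calls):
        raise ValueError("call tables must be aligned")
    names = [c.name for c in classes] + [NONE_CLASS]
    t = assign_classes(true_calls, classes)
    p = assign_classes(pred_calls, classes)
    counts = pd.DataFrame(0.0, index=names, columns=names)
    for ti, pi in zip(t, p):
        counts.loc[ti, pi] += 1.0
    col_sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = counts / col_sums.replace(0.0, np.nan)
    return norm


def class_precision(
    true_calls: pd.DataFrame,
    pred_calls: pd.DataFrame,
    cls: CooccurrenceClass,
) -> float:
    """Precision of one class treated as a binary call (all markers +)."""
    t = cls.member_mask(true_calls)
    p = cls.member_mask(pred_calls)
    if p.sum() == 0:
        return float("nan")
    return float((t & p).sum() / p.sum())


# ---------------------------------------------------------------------------
# Interaction enrichment


@dataclass
class EnrichmentResult:
    context_marker: str
    direction: str
    t: float | None
    df: int
    p: float | None
    per_slide_interacting: dict[str, float]
    per_slide_non_interacting: dict[str, float]
    degenerate: bool = False


def interaction_enrichment(
    calls: pd.DataFrame,
    marker_pair: tuple[str, str],
    context_markers: tuple[str, ...],
    direction: str = "enrichment",
    min_slides: int = 3,
) -> dict[str, EnrichmentResult]:
    """Test whether interacting tiles are enriched for a context marker.

    A tile "interacts" when both pair markers are called positive in it.
    For each slide the fraction of context-positive tiles is computed among
    interacting and among non-interacting tiles; the per-slide differences
    feed a one-sided paired t-test (``direction='enrichment'`` tests
    interacting > non-interacting, ``'depletion'`` the reverse). Slides
    without both tile kinds are dropped with a warning; fewer than
    ``min_slides`` usable slides is an error.
    """
    if direction not in {"enrichment", "depletion"}:
        raise ValueError(f"direction must be enrichment|depletion, got {direction!r}")
    a, b = marker_pair
    inter = calls[a].to_numpy(dtype=bool) & calls[b].to_numpy(dtype=bool)
    results: dict[str, EnrichmentResult] = {}
    for ctx in context_markers:
        p_int: dict[str, float] = {}
        p_non: dict[str, float] = {}
        for slide_id, idx in calls.groupby("slide_id").groups.items():
            loc = calls.index.get_indexer(idx)
            m_int = inter[loc]
            if m_int.sum() == 0 or (~m_int).sum() == 0:
                logger.warning(
                    "enrichment: slide %s lacks interacting or non-interacting "
                    "tiles; dropped",
                    slide_id,
                )
                continue
            ctx_pos = calls[ctx].to_numpy(dtype=bool)[loc]
            p_int[str(slide_id)] = float(ctx_pos[m_int].mean())
            p_non[str(slide_id)] = float(ctx_pos[~m_int].mean())
        n = len(p_int)
        if n < min_slides:
            raise ValueError(
                f"need >= {min_slides} slides with interacting tiles, have {n}"
            )
        diffs = np.array([p_int[s] - p_non[s] for s in p_int])
        if np.std(diffs) < 1e-15:
            results[ctx] = EnrichmentResult(
                ctx, direction, None, n - 1, None, p_int, p_non, degenerate=True
            )
            continue
        alt = "greater" if direction == "enrichment" else "less"
        res = stats.ttest_1samp(diffs, 0.0, alternative=alt)
        results[ctx] = EnrichmentResult(
            ctx, direction, float(res.statistic), n - 1, float(res.pvalue),
            p_int, p_non,
        )
    return results
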