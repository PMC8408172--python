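"""Pedigree relatedness statistics and the Close Relationship Estimator.

COR (coefficient of relatedness) is twice the kinship coefficient computed
by the standard recursive algorithm on the pedigree truncated at a maximum
ancestral depth (default 3 generations, i.e. great-grandparents), with
founders treated as unrelated and non-inbred.  Reference SPLoSH
distributions per relationship group feed (a) an ordinary least-squares
regression of SPLoSH on COR, invertible into a COR estimate for a query
pair, and (b) the Close Relationship Estimator: an empirical sliding-window
table converting a SPLoSH value into relative probabilities of the COR
classes 0.5 (FSIB), 0.25 (HSIB), 0.125 (HAAM) and 0.0625 (OSGP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .formats_io import Pedigree, RelationshipCatalog

logger = logging.getLogger(__name__)

LABEL_COR = {"FSIB": 0.5, "HSIB": 0.25, "GPGC": 0.25, "HAAM": 0.125, "OSGP": 0.0625, "NKCR": 0.0}

__all__ = [
    "CORValue",
    "LABEL_COR",
    "compute_cor",
    "build_reference_distributions",
    "ReferenceDistributions",
    "fit_splosh_cor_regression",
    "estimate_cor_from_splosh",
    "CRETable",
    "build_cre",
]


@dataclass(frozen=True)
class CORValue:
    id_a: str
    id_b: str
    cor: float
    max_depth: int


def _truncate(ped: Pedigree, targets: tuple[str, str], max_depth: int) -> dict[str, tuple[str | None, str | None]]:
    """Parent map keeping ancestors within ``max_depth`` generations of the
    two target individuals; deeper ancestors become founders."""
    keep: dict[str, int] = {}
    frontier = [(t, 0) for t in targets]
    while frontier:
        ind, d = frontier.pop()
        if ind in keep and keep[ind] <= d:
            continue
        keep[ind] = d
        if d < max_depth:
            for p in ped.parents(ind):
                if p is not None:
                    frontier.append((p, d + 1))
    out: dict[str, tuple[str | None, str | None]] = {}
    for ind, d in keep.items():
        if d < max_depth:
            p1, p2 = ped.parents(ind)
            out[ind] = (
                p1 if p1 is not None and p1 in keep else None,
                p2 if p2 is not None and p2 in keep else None,
            )
        else:
            out[ind] = (None, None)
    return out


def _kinship(parents: dict[str, tuple[str | None, str | None]]):
    @lru_cache(maxsize=None)
    def phi(i: str | None, j: str | None) -> float:
        if i is None or j is None:
            return 0.0
        if i == j:
            f1, f2 = parents.get(i, (None, None))
            return 0.5 * (1.0 + phi(f1, f2))
        # recurse on the individual appearing later in a topological order;
        # with an acyclic pedigree, recursing on either is safe if we always
        # expand the one that is not an ancestor of the other.  Standard
        # trick: order by generation number.
        if _gen(i) < _gen(j):
            i, j = j, i
        p1, p2 = parents.get(i, (None, None))
        return 0.5 * (phi(p1, j) + phi(p2, j))

    @lru_cache(maxsize=None)
    def _gen(i: str) -> int:
        p1, p2 = parents.get(i, (None, None))
        gens = [_gen(p) + 1 for p in (p1, p2) if p is not None]
        return max(gens, default=0)

    return phi


def compute_cor(ped: Pedigree, a: str, b: str, max_depth: int = 3) -> CORValue:
    """COR = 2 x kinship on the depth-truncated pedigree.

    Parent-offspring and full-sibs give 0.5; half-sibs and
    grandparent-grandchild 0.25; half-avuncular 0.125; one shared
    grandparent (half first cousins) 0.0625.
    """
    for ind in (a, b):
        if ind not in ped:
            raise KeyError(f"{ind!r} not in pedigree")
    parents = _truncate(ped, (a, b), max_depth)
    phi = _kinship(parents)
    return CORValue(a, b, 2.0 * phi(a, b), max_depth)


# ---------------------------------------------------------------------------
# Reference distributions
# ---------------------------------------------------------------------------


@dataclass
class ReferenceDistributions:
    """Per (relationship label, threshold): vector of SPLoSH values."""

    values: dict[tuple[str, float], np.ndarray]
    summary: pd.DataFrame  # label, threshold_cM, n, mean, min, max

    def get(self, label: str, threshold: float) -> np.ndarray:
        return self.values.get((label, float(threshold)), np.array([]))

    def density_export(self, threshold: float, grid_points: int = 200) -> pd.DataFrame:
        """Histogram-density table on a shared value grid, one column per
        label — ready for external plotting of the reference curves."""
        vecs = {l: v for (l, t), v in self.values.items() if t == float(threshold) and v.size}
        if not vecs:
            return pd.DataFrame()
        lo = min(v.min() for v in vecs.values())
        hi = max(v.max() for v in vecs.values())
        edges = np.linspace(lo, hi, grid_points + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        out = {"splosh_cM": mids}
        for label, v in vecs.items():
            dens, _ = np.histogram(v, bins=edges, density=True)
            out[label] = dens
        return pd.DataFrame(out)


def build_reference_distributions(
    splosh: pd.DataFrame, catalog: RelationshipCatalog, thresholds=None
) -> ReferenceDistributions:
    """Group pairwise SPLoSH values by relationship label.

    ``splosh`` is a table from :func:`haploshare.splosh.compute_splosh`.
    Pairs are matched regardless of ordering within the pair.
    """
    if thresholds is None:
        thresholds = sorted(splosh["threshold_cM"].unique())
    key = {}
    for _, r in splosh.iterrows():
        key[(r["id_a"], r["id_b"], r["threshold_cM"])] = r["splosh_cM"]
        key[(r["id_b"], r["id_a"], r["threshold_cM"])] = r["splosh_cM"]
    values: dict[tuple[str, float], np.ndarray] = {}
    rows = []
    for label in catalog.labels:
        pairs = catalog.by_label(label)
        for t in thresholds:
            vals = []
            for a, b in pairs:
                if (a, b, t) not in key:
                    raise KeyError(f"pair ({a!r}, {b!r}) at threshold {t} missing from SPLoSH table")
                vals.append(key[(a, b, t)])
            v = np.asarray(vals, dtype=float)
            if v.size == 0:
                logger.warning("relationship group %s has no pairs", label)
            values[(label, float(t))] = v
            rows.append(
                (label, float(t), v.size, v.mean() if v.size else np.nan, v.min() if v.size else np.nan, v.max() if v.size else np.nan)
            )
    summary = pd.DataFrame(rows, columns=["label", "threshold_cM", "n", "mean", "min", "max"])
    return ReferenceDistributions(values=values, summary=summary)


# ---------------------------------------------------------------------------
# SPLoSH ~ COR regression
# ---------------------------------------------------------------------------


def fit_splosh_cor_regression(splosh: pd.DataFrame, cors: list[CORValue]) -> pd.DataFrame:
    """OLS of SPLoSH on COR, per (threshold, phasing_type).

    Returns a table with slope, intercept, r2, residual standard error and n.
    Requires at least 2 distinct COR levels (3+ recommended).
    """
    cor_map = {}
    for c in cors:
        cor_map[(c.id_a, c.id_b)] = c.cor
        cor_map[(c.id_b, c.id_a)] = c.cor
    rows = []
    for (t, mode), sub in splosh.groupby(["threshold_cM", "phasing_type"]):
        y = sub["splosh_cM"].to_numpy(dtype=float)
        x = np.array([cor_map[(a, b)] for a, b in zip(sub["id_a"], sub["id_b"])])
        if len(np.unique(x)) < 2:
            raise ValueError("COR values are constant; regression is degenerate")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        rse = float(np.sqrt(model.mse_resid)) if model.df_resid > 0 else np.nan
        rows.append((float(t), mode, float(model.params[1]), float(model.params[0]), float(model.rsquared), rse, len(y)))
    return pd.DataFrame(
        rows, columns=["threshold_cM", "phasing_type", "slope", "intercept", "r2", "resid_se", "n"]
    )


def estimate_cor_from_splosh(
    fit: pd.DataFrame, splosh_value: float, threshold: float, phasing_type: str
) -> float:
    """Inverse prediction (value - intercept) / slope, clamped to [0, 1]."""
    sub = fit[(fit["threshold_cM"] == float(threshold)) & (fit["phasing_type"] == phasing_type)]
    if sub.empty:
        raise KeyError(f"no fit for threshold {threshold}, phasing {phasing_type!r}")
    slope = float(sub["slope"].iloc[0])
    intercept = float(sub["intercept"].iloc[0])
    if slope <= 0:
        raise ValueError("non-positive slope; COR cannot be inverted")
    return float(np.clip((splosh_value - intercept) / slope, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Close Relationship Estimator
# ---------------------------------------------------------------------------

CRE_LABELS = ("FSIB", "HSIB", "HAAM", "OSGP")


@dataclass
class CRETable:
    """Empirical SPLoSH -> P(COR class) estimator.

    ``pools`` hold, per relationship label, the concatenation of repeated
    random subsamples of the reference values (equal loading across labels).
    A query counts pooled values within +/- ``window`` cM of the query and
    normalises across labels.
    """

    pools: dict[str, np.ndarray]
    window: float
    threshold: float
    subsample_n: int
    iterations: int

    def query(self, splosh_value: float) -> dict[str, float] | None:
        """Probabilities per label, or None when no pooled value falls in
        the window (undefined row)."""
        counts = {
            label: int(np.sum(np.abs(pool - splosh_value) <= self.window))
            for label, pool in self.pools.items()
        }
        total = sum(counts.values())
        if total == 0:
            return None
        return {label: c / total for label, c in counts.items()}

    def to_frame(self, grid: np.ndarray | None = None, step: float = 5.0) -> pd.DataFrame:
        """Query-able table over a SPLoSH value grid (CSV/Excel exportable).

        Undefined rows carry NaN probabilities and defined=False.
        """
        if grid is None:
            lo = min(p.min() for p in self.pools.values())
            hi = max(p.max() for p in self.pools.values())
            grid = np.arange(np.floor(lo), np.ceil(hi) + step, step)
        rows = []
        for s in grid:
            probs = self.query(float(s))
            if probs is None:
                rows.append([float(s), False] + [np.nan] * len(self.pools))
            else:
                rows.append([float(s), True] + [probs[l] for l in self.pools])
        return pd.DataFrame(rows, columns=["splosh_cM", "defined"] + [f"P_{l}" for l in self.pools])


def build_cre(
    refs: ReferenceDistributions,
    threshold: float = 40.0,
    subsample_n: int | None = None,
    iterations: int = 10,
    window: float = 20.0,
    seed: int | np.random.Generator = 0,
    labels=CRE_LABELS,
) -> CRETable:
    """Build the Close Relationship Estimator.

    Per relationship label, ``iterations`` random subsamples of size
    ``subsample_n`` (without replacement within an iteration) are drawn from
    the reference vector and concatenated; by default ``subsample_n`` is the
    smallest group size so every label contributes equally.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vecs = {l: refs.get(l, threshold) for l in labels}
    for l, v in vecs.items():
        if v.size == 0:
            raise ValueError(f"reference vector for {l} at threshold {threshold} is empty")
    min_n = min(v.size for v in vecs.values())
    if subsample_n is None:
        subsample_n = min_n
    if subsample_n > min_n:
        raise ValueError(f"subsample_n={subsample_n} exceeds smallest group size {min_n}")
    pools = {
        l: np.concatenate([rng.choice(v, size=subsample_n, replace=False) for _ in range(iterations)])
        for l, v in vecs.items()
    }
    return CRETable(pools=pools, window=window, threshold=threshold, subsample_n=subsample_n, iterations=iterations)
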