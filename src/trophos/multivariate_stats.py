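"""Permutation multivariate statistics on dissimilarity matrices.

Implements the distance-based analysis-of-variance toolkit used for the
diet and isotope comparisons:

* Bray–Curtis and Euclidean resemblance matrices,
* one-way PERMANOVA (unrestricted permutation of raw data),
* two-factor mixed-model PERMANOVA with a random factor nested in a fixed
  one (permutation of residuals under a reduced model),
* pairwise comparisons,
* PERMDISP (homogeneity of multivariate dispersions, distance to group
  centroid in principal-coordinate space),
* SIMPER (per-taxon decomposition of average between-group dissimilarity),
* CAP (canonical analysis of principal coordinates with leave-one-out
  choice of the number of retained axes).

The sums of squares are partitioned directly on the Gower-centered matrix
``G = -(1/2) J D^2 J`` (McArdle–Anderson), so a one-way analysis with a
Euclidean matrix of univariate data reproduces the classical ANOVA F
exactly.  All permutation p-values use the ``(b + 1) / (m + 1)`` convention
and are therefore never exactly zero; ties with the observed statistic
count as exceedances (conservative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateDesignError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "braycurtis_matrix",
    "euclidean_matrix",
    "PermanovaResult",
    "permanova_oneway",
    "permanova_nested",
    "pairwise_permanova",
    "DispersionResult",
    "permdisp",
    "SimperResult",
    "simper",
    "CapResult",
    "cap",
]

_TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# distance matrices


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities among labelled samples."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise DomainError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise DomainError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise DomainError("distance matrix diagonal must be zero")
        if np.any(v < -1e-12):
            raise DomainError("dissimilarities must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def subset(self, mask: np.ndarray) -> "DistanceMatrix":
        idx = np.flatnonzero(mask)
        return DistanceMatrix(
            labels=tuple(self.labels[i] for i in idx),
            values=self.values[np.ix_(idx, idx)],
            metric=self.metric,
        )


def braycurtis_matrix(
    biomass: pd.DataFrame, log_transform: bool = True
) -> DistanceMatrix:
    """Bray–Curtis resemblance matrix of a samples x taxa biomass table.

    Biomasses are log(x + 1)-transformed by default before computing
    ``d_ij = sum_k |y_ik - y_jk| / sum_k (y_ik + y_jk)``.  Samples whose
    row is entirely zero have no defined dissimilarity and are dropped with
    a warning.
    """
    x = biomass.to_numpy(dtype=float)
    if np.any(x < 0):
        raise DomainError("biomasses must be non-negative")
    zero = x.sum(axis=1) == 0
    if zero.any():
        dropped = list(biomass.index[zero])
        warnings.warn(
            f"dropping {len(dropped)} all-zero sample(s) with undefined "
            f"Bray-Curtis dissimilarity: {dropped}",
            stacklevel=2,
        )
        biomass = biomass.loc[~zero]
        x = x[~zero]
    if len(biomass) < 2:
        raise DomainError("need at least two non-empty samples")
    y = np.log1p(x) if log_transform else x
    d = squareform(pdist(y, metric="braycurtis"))
    return DistanceMatrix(
        labels=tuple(str(i) for i in biomass.index), values=d, metric="bray_curtis"
    )


def euclidean_matrix(values, labels=None) -> DistanceMatrix:
    """Euclidean resemblance matrix of untransformed values (1-D or 2-D)."""
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if labels is None:
        labels = [str(i) for i in range(len(x))]
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(labels=tuple(str(l) for l in labels), values=d, metric="euclidean")


# ---------------------------------------------------------------------------
# PERMANOVA machinery


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()

def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(set(labels.tolist()))
    x = np.zeros((len(labels), len(levels)))
    for j, lev in enumerate(levels):
        x[np.asarray(labels) == lev, j] = 1.0
    return x, levels


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


@dataclass(frozen=True)
class PermanovaResult:
    """ANOVA-style term table of a distance-based permutation test."""

    table: pd.DataFrame
    n_perm: int
    permutation_scheme: str
    seed: int | None = None

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_perm"])

    def pseudo_f(self, term: str) -> float:
        return float(self.table.loc[term, "pseudoF"])


def _safe_f(num_ss: float, num_df: int, den_ss: float, den_df: int) -> float:
    if num_df <= 0 or den_df <= 0:
        return np.nan
    den = den_ss / den_df
    if den <= _TIE_TOL:
        return np.nan if num_ss / num_df <= _TIE_TOL else np.inf
    return (num_ss / num_df) / den


def _perm_p(f_obs: float, f_perm: np.ndarray, n_perm: int) -> float:
    if not np.isfinite(f_obs):
        return 1.0
    exceed = np.sum(f_perm >= f_obs - _TIE_TOL)
    return float((exceed + 1) / (n_perm + 1))


def permanova_oneway(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA with unrestricted permutation of raw data.

    Pseudo-F is computed from the partition of the Gower-centered matrix:
    ``SS_among = tr(H G)`` with ``H`` the hat matrix of the group design.

    Raises
    ------
    DegenerateDesignError
        With fewer than two groups, or any group of size one.
    """
    labels = np.asarray(list(groups))
    if len(labels) != dm.n:
        raise DomainError("group labels do not match distance matrix size")
    x, levels = _one_hot(labels)
    sizes = x.sum(axis=0)
    if len(levels) < 2:
        raise DegenerateDesignError("need at least two groups")
    if np.any(sizes < 2):
        small = [l for l, s in zip(levels, sizes) if s < 2]
        raise DegenerateDesignError(f"group(s) of size one: {small}")

    n = dm.n
    a = len(levels)
    g = _gower_center(dm.values)
    h = _hat(x)
    ss_total = float(np.trace(g))
    ss_among = float((h * g).sum())
    ss_resid = ss_total - ss_among
    df_among, df_resid = a - 1, n - a
    f_obs = _safe_f(ss_among, df_among, ss_resid, df_resid)

    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(n)
        gp = g[np.ix_(idx, idx)]
        ss_a = float((h * gp).sum())
        f_perm[b] = _safe_f(ss_a, df_among, ss_total - ss_a, df_resid)
    p = _perm_p(f_obs, f_perm, n_perm)

    table = pd.DataFrame(
        {
            "df": [df_among, df_resid, n - 1],
            "SS": [ss_among, ss_resid, ss_total],
            "MS": [ss_among / df_among, ss_resid / df_resid, np.nan],
            "pseudoF": [f_obs, np.nan, np.nan],
            "p_perm": [p, np.nan, np.nan],
        },
        index=pd.Index(["factor", "Residual", "Total"], name="term"),
    )
    return PermanovaResult(table=table, n_perm=n_perm, permutation_scheme="raw", seed=seed)


def permanova_nested(
    dm: DistanceMatrix,
    fixed,
    nested,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """Two-factor mixed-model PERMANOVA: random ``nested`` within fixed.

    The fixed factor (species) is tested against the mean square of the
    nested random factor (area within species), per the expected mean
    squares of the mixed model; the nested factor is tested against the
    residual.  Sums of squares are sequential (fixed, then cells) on the
    Gower-centered matrix, which handles unbalanced designs.

    Permutations: the fixed term uses unrestricted permutation of the raw
    data (its reduced model is the intercept alone, under which residuals
    coincide with the centered data); the nested term permutes
    Freedman–Lane residuals of the reduced (fixed-factor-only) model.
    """
    fixed = np.asarray(list(fixed))
    nested = np.asarray(list(nested))
    if len(fixed) != dm.n or len(nested) != dm.n:
        raise DomainError("factor labels do not match distance matrix size")

    cells = np.array([f"{f}||{a}" for f, a in zip(fixed, nested)])
    # nesting validation: every cell label belongs to exactly one fixed level
    cell_to_fixed: dict[str, str] = {}
    for c, f in zip(cells, fixed):
        if cell_to_fixed.setdefault(c, f) != f:
            raise DegenerateDesignError("non-nested labelling")
    n_cells_per_fixed = pd.Series(
        [c.split("||")[0] for c in set(cells)]
    ).value_counts()
    if (n_cells_per_fixed < 1).any() or len(n_cells_per_fixed) < 2:
        raise DegenerateDesignError("need >= 2 fixed levels")
    if not (n_cells_per_fixed >= 2).any():
        raise DegenerateDesignError(
            "no fixed level holds >= 2 nested levels; nested term untestable"
        )

    n = dm.n
    x1, lv_fixed = _one_hot(fixed)
    x2, lv_cells = _one_hot(cells)
    h1, h2 = _hat(x1), _hat(x2)
    a = len(lv_fixed)
    n_cells = len(lv_cells)
    df_fixed = a - 1
    df_nested = n_cells - a
    df_resid = n - n_cells
    if df_resid <= 0:
        raise DegenerateDesignError("no residual degrees of freedom")

    g = _gower_center(dm.values)
    ss_total = float(np.trace(g))
    t1 = float((h1 * g).sum())
    t2 = float((h2 * g).sum())
    ss_fixed, ss_nested, ss_resid = t1, t2 - t1, ss_total - t2
    f_fixed = _safe_f(ss_fixed, df_fixed, ss_nested, df_nested)
    f_nested = _safe_f(ss_nested, df_nested, ss_resid, df_resid)

    rng = np.random.default_rng(seed)
    f_fixed_perm = np.empty(n_perm)
    f_nested_perm = np.empty(n_perm)
    resid_proj = np.eye(n) - h1
    r1 = resid_proj @ g @ resid_proj  # Freedman-Lane residual kernel
    fit1 = h1 @ g @ h1
    cross = h1 @ g @ resid_proj
    for b in range(n_perm):
        idx = rng.permutation(n)
        # fixed term: unrestricted raw permutation, denominator recomputed
        gp = g[np.ix_(idx, idx)]
        t1p = float((h1 * gp).sum())
        t2p = float((h2 * gp).sum())
        f_fixed_perm[b] = _safe_f(t1p, df_fixed, t2p - t1p, df_nested)
        # nested term: permute residuals of the reduced (fixed-only) model,
        # G* = M G M' with M = H1 + P (I - H1), expanded into its four
        # precomputable blocks (P acts as a row permutation)
        gs = fit1 + cross[:, idx] + cross[:, idx].T + r1[np.ix_(idx, idx)]
        t1s = float((h1 * gs).sum())
        t2s = float((h2 * gs).sum())
        tot = float(np.trace(gs))
        f_nested_perm[b] = _safe_f(t2s - t1s, df_nested, tot - t2s, df_resid)
    p_fixed = _perm_p(f_fixed, f_fixed_perm, n_perm)
    p_nested = _perm_p(f_nested, f_nested_perm, n_perm)

    table = pd.DataFrame(
        {
            "df": [df_fixed, df_nested, df_resid, n - 1],
            "SS": [ss_fixed, ss_nested, ss_resid, ss_total],
            "MS": [
                ss_fixed / df_fixed,
                ss_nested / df_nested,
                ss_resid / df_resid,
                np.nan,
            ],
            "pseudoF": [f_fixed, f_nested, np.nan, np.nan],
            "p_perm": [p_fixed, p_nested, np.nan, np.nan],
        },
        index=pd.Index(["fixed", "nested", "Residual", "Total"], name="term"),
    )
    return PermanovaResult(
        table=table,
        n_perm=n_perm,
        permutation_scheme="residuals_reduced",
        seed=seed,
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def pairwise_permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
    correction: str | None = None,
) -> pd.DataFrame:
    """All pairwise one-way PERMANOVAs between group levels.

    Uses the same unrestricted raw-data permutation scheme restricted to
    each pair of levels.  No multiplicity correction is applied by default
    (matching common permutational-ANOVA practice); pass
    ``correction="holm"`` for Holm-adjusted p-values.
    """
    labels = np.asarray(list(groups))
    levels = sorted(set(labels.tolist()))
    rng = np.random.default_rng(seed)
    rows = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            mask = (labels == la) | (labels == lb)
            sub = dm.subset(mask)
            try:
                res = permanova_oneway(
                    sub, labels[mask], n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                )
            except DegenerateDesignError:
                rows.append({"group_a": la, "group_b": lb, "pseudoF": np.nan,
                             "p_perm": np.nan, "n": int(mask.sum())})
                continue
            rows.append(
                {
                    "group_a": la,
                    "group_b": lb,
                    "pseudoF": res.pseudo_f("factor"),
                    "p_perm": res.p_value("factor"),
                    "n": int(mask.sum()),
                }
            )
    out = pd.DataFrame(rows)
    if correction == "holm" and len(out):
        ok = out["p_perm"].notna()
        adj = np.full(len(out), np.nan)
        adj[ok.to_numpy()] = _holm(out.loc[ok, "p_perm"].to_numpy())
        out["p_holm"] = adj
    return out


# ---------------------------------------------------------------------------
# PERMDISP


@dataclass(frozen=True)
class DispersionResult:
    """Homogeneity-of-dispersions test output."""

    group_means: pd.Series
    f_stat: float
    p_perm: float
    pairwise: pd.DataFrame
    distances: pd.Series
    n_perm: int
    tested: bool = True


def _pcoa_coords(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates split into real and imaginary parts.

    Negative eigenvalues of the Gower matrix (possible for semimetric
    dissimilarities like Bray–Curtis) yield imaginary axes whose squared
    distances are *subtracted* in the corrected distance formula.
    """
    g = _gower_center(d)
    w, v = np.linalg.eigh((g + g.T) / 2)
    tol = max(abs(w).max(), 1.0) * 1e-10
    pos = w > tol
    neg = w < -tol
    real = v[:, pos] * np.sqrt(w[pos])
    imag = v[:, neg] * np.sqrt(-w[neg])
    return real, imag


def _anova_f(d: np.ndarray, x: np.ndarray, sizes: np.ndarray) -> float:
    means = (x.T @ d) / sizes
    grand = d.mean()
    ss_b = float(sizes @ (means - grand) ** 2)
    ss_w = float(((d - x @ means) ** 2).sum())
    a, n = len(sizes), len(d)
    return _safe_f(ss_b, a - 1, ss_w, n - a)


def permdisp(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
) -> DispersionResult:
    """PERMDISP: permutation test of multivariate dispersion homogeneity.

    Each sample's distance to its group centroid is measured in
    principal-coordinate space with the negative-eigenvalue correction
    ``d^2 = sum_real (u - c)^2 - sum_imag (u - c)^2`` (clamped at zero),
    then compared between groups with an ANOVA F whose null distribution
    comes from permuting group membership of the distances.  Group mean
    dispersion reads as diet generalism (large) vs specialism (small).
    """
    labels = np.asarray(list(groups))
    if len(labels) != dm.n:
        raise DomainError("group labels do not match distance matrix size")
    x, levels = _one_hot(labels)
    sizes = x.sum(axis=0)
    if len(levels) < 2 or np.any(sizes < 2):
        raise DegenerateDesignError("PERMDISP needs >= 2 groups with >= 2 members")

    real, imag = _pcoa_coords(dm.values)
    d2 = np.zeros(dm.n)
    for j, lev in enumerate(levels):
        mask = labels == lev
        cr = real[mask].mean(axis=0) if real.size else np.zeros(0)
        ci = imag[mask].mean(axis=0) if imag.size else np.zeros(0)
        contrib = np.zeros(int(mask.sum()))
        if real.size:
            contrib += ((real[mask] - cr) ** 2).sum(axis=1)
        if imag.size:
            contrib -= ((imag[mask] - ci) ** 2).sum(axis=1)
        d2[mask] = contrib
    dist = np.sqrt(np.clip(d2, 0.0, None))
    distances = pd.Series(dist, index=list(dm.labels), name="dist_to_centroid")
    group_means = pd.Series(
        {lev: dist[labels == lev].mean() for lev in levels}, name="mean_dispersion"
    )

    if dist.max() - dist.min() <= 1e-12:
        # all dispersions coincide (e.g. duplicated points): nothing to test
        return DispersionResult(
            group_means=group_means, f_stat=np.nan, p_perm=np.nan,
            pairwise=pd.DataFrame(), distances=distances, n_perm=0, tested=False,
        )

    f_obs = _anova_f(dist, x, sizes)
    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        f_perm[b] = _anova_f(dist[rng.permutation(dm.n)], x, sizes)
    p = _perm_p(f_obs, f_perm, n_perm)

    rows = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            mask = (labels == la) | (labels == lb)
            sub_d = dist[mask]
            sub_x, _ = _one_hot(labels[mask])
            sub_sizes = sub_x.sum(axis=0)
            f_pair = _anova_f(sub_d, sub_x, sub_sizes)
            fp = np.empty(n_perm)
            m = int(mask.sum())
            for b in range(n_perm):
                fp[b] = _anova_f(sub_d[rng.permutation(m)], sub_x, sub_sizes)
            rows.append(
                {"group_a": la, "group_b": lb, "F": f_pair,
                 "p_perm": _perm_p(f_pair, fp, n_perm)}
            )
    return DispersionResult(
        group_means=group_means,
        f_stat=f_obs,
        p_perm=p,
        pairwise=pd.DataFrame(rows),
        distances=distances,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# SIMPER


@dataclass(frozen=True)
class SimperResult:
    """Per-taxon decomposition of average between-group dissimilarity."""

    group_a: str
    group_b: str
    average_dissimilarity: float  # percent
    table: pd.DataFrame  # full, sorted by descending contribution
    cutoff: float

    @property
    def truncated(self) -> pd.DataFrame:
        """Rows up to (and including) the one crossing the cumulative cutoff."""
        cum = self.table["cumulative_pct"].to_numpy()
        if len(cum) == 0:
            return self.table
        k = int(np.searchsorted(cum, self.cutoff - 1e-9)) + 1
        return self.table.iloc[:k]


def simper(
    biomass: pd.DataFrame,
    groups,
    cutoff: float = 60.0,
    log_transform: bool = True,
) -> list[SimperResult]:
    """SIMPER analysis on a samples x taxa biomass table.

    For every pair of groups, the average Bray–Curtis dissimilarity
    (percent) is decomposed into additive per-taxon contributions
    ``delta_ijk = 100 |y_ik - y_jk| / sum_k (y_ik + y_jk)`` averaged over
    all cross-group sample pairs.  Contributions are reported sorted in
    descending order with the cumulative percentage and the listing cutoff
    (default 60%).  Values are log(x + 1)-transformed by default,
    consistent with the resemblance matrix used for the diet tests.
    """
    labels = np.asarray(list(groups))
    if len(labels) != len(biomass):
        raise DomainError("group labels do not match biomass rows")
    y = np.log1p(biomass.to_numpy(dtype=float)) if log_transform else (
        biomass.to_numpy(dtype=float)
    )
    levels = sorted(set(labels.tolist()))
    if len(levels) < 2:
        raise DegenerateDesignError("SIMPER needs >= 2 groups")
    for lev in levels:
        if not np.any(labels == lev):
            raise DegenerateDesignError(f"empty group {lev!r}")

    results = []
    taxa = list(biomass.columns)
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            y1 = y[labels == la]
            y2 = y[labels == lb]
            # (n1, n2, k) per-pair per-taxon absolute differences
            diff = np.abs(y1[:, None, :] - y2[None, :, :])
            denom = (y1[:, None, :] + y2[None, :, :]).sum(axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                contrib = np.where(denom[:, :, None] > 0,
                                   diff / denom[:, :, None], 0.0)
            per_taxon = 100.0 * contrib.mean(axis=(0, 1))
            avg = float(per_taxon.sum())
            order = np.argsort(-per_taxon, kind="stable")
            tab = pd.DataFrame(
                {
                    "avg_contribution": per_taxon[order],
                    "contribution_pct": (
                        100.0 * per_taxon[order] / avg if avg > 0
                        else np.zeros(len(order))
                    ),
                },
                index=pd.Index([taxa[k] for k in order], name="taxon"),
            )
            tab["cumulative_pct"] = tab["contribution_pct"].cumsum()
            results.append(
                SimperResult(
                    group_a=la, group_b=lb, average_dissimilarity=avg,
                    table=tab, cutoff=cutoff,
                )
            )
    return results


# ---------------------------------------------------------------------------
# CAP


@dataclass(frozen=True)
class CapResult:
    """Canonical analysis of principal coordinates."""

    m: int
    axes: pd.DataFrame  # canonical scores, one row per sample
    allocation_success: float  # overall leave-one-out success, percent
    per_group_success: pd.Series
    m_search: pd.DataFrame = field(repr=False)


def cap(
    dm: DistanceMatrix,
    groups,
    m: int | None = None,
    max_m: int = 15,
) -> CapResult:
    """CAP: constrained ordination maximizing group separation.

    Samples are embedded by principal-coordinate analysis (positive axes);
    a linear discriminant analysis on the first ``m`` axes provides the
    canonical axes.  Unless ``m`` is given, it is chosen to maximize the
    leave-one-out allocation success, scanning 1..min(rank, n - g, max_m).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(list(groups))
    levels = sorted(set(labels.tolist()))
    n, ngroups = dm.n, len(levels)
    if ngroups < 2:
        raise DegenerateDesignError("CAP needs >= 2 groups")
    if n <= ngroups:
        raise DegenerateDesignError("CAP needs more samples than groups")

    real, _ = _pcoa_coords(dm.values)
    rank = real.shape[1]
    if rank == 0:
        raise DegenerateDesignError("embedding has no positive axes")
    m_cap = min(rank, n - ngroups, max_m)

    def loo_success(mm: int) -> float:
        q = real[:, :mm]
        hits = 0
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            if len(set(labels[mask].tolist())) < ngroups:
                continue
            lda = LinearDiscriminantAnalysis()
            lda.fit(q[mask], labels[mask])
            hits += int(lda.predict(q[i:i + 1])[0] == labels[i])
        return 100.0 * hits / n

    if m is None:
        search = [(mm, loo_success(mm)) for mm in range(1, m_cap + 1)]
        m_best, _ = max(search, key=lambda t: (t[1], -t[0]))
    else:
        if not (1 <= m <= m_cap):
            raise DomainError(f"m must be in 1..{m_cap}")
        search = [(m, loo_success(m))]
        m_best = m
    m_search = pd.DataFrame(search, columns=["m", "loo_success_pct"])

    q = real[:, :m_best]
    lda = LinearDiscriminantAnalysis()
    lda.fit(q, labels)
    scores = lda.transform(q)
    pred_loo = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        ld = LinearDiscriminantAnalysis()
        ld.fit(q[mask], labels[mask])
        pred_loo.append(ld.predict(q[i:i + 1])[0])
    pred_loo = np.asarray(pred_loo)
    overall = 100.0 * float((pred_loo == labels).mean())
    per_group = pd.Series(
        {lev: 100.0 * float((pred_loo[labels == lev] == lev).mean())
         for lev in levels},
        name="allocation_success_pct",
    )
    axes = pd.DataFrame(
        scores,
        index=pd.Index(list(dm.labels), name="sample"),
        columns=[f"CAP{j + 1}" for j in range(scores.shape[1])],
    )
    axes.insert(0, "group", labels)
    return CapResult(
        m=m_best,
        axes=axes,
        allocation_success=overall,
        per_group_success=per_group,
        m_search=m_search,
    )
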