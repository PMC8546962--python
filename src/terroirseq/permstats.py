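"""Permutation-based community statistics built from their definitions.

ANOSIM, PERMANOVA (single grouping factor) and the Mantel test are
implemented directly on the distance matrix, with label permutations
vectorized across the permutation axis.  Sampled permutation p-values use
p = (b + 1) / (m + 1), where b counts permuted statistics >= the observed
one, so p can never be 0.  ``exact=True`` enumerates every relabeling
(feasible for small n) and reports the exact permutation p-value.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof
from statsmodels.stats.multitest import multipletests

from .datamodel import DistanceMatrix, ValidationError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
_TIE_EPS = 1e-12


@dataclass
class PermTestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    effect_partition: dict = field(default_factory=dict)
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "effect_partition": self.effect_partition,
            "note": self.note,
        }


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool


def _as_group_array(groups) -> np.ndarray:
    arr = np.asarray(pd.Series(groups).astype(str))
    return arr


def _check_groups(labels: np.ndarray) -> list[str]:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    small = uniq[counts < 2]
    if len(small):
        raise ValidationError(f"group(s) with fewer than 2 samples: {list(small)}")
    return list(uniq)


def _perm_indices(
    n: int, n_perm: int, seed: int | None, exact: bool
) -> tuple[np.ndarray, bool]:
    """Permutation index matrix (m, n); exact mode enumerates all n!."""
    if exact:
        if n > 8:
            raise ValidationError("exact enumeration limited to n <= 8 samples")
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        return perms, True
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.intp)
    for i in range(n_perm):
        perms[i] = rng.permutation(n)
    return perms, False


def _perm_p(perm_stats: np.ndarray, observed: float, exact: bool) -> float:
    b = int(np.sum(perm_stats >= observed - _TIE_EPS))
    if exact:
        # observed relabeling is in the enumeration (identity permutation)
        return b / len(perm_stats)
    return (b + 1) / (len(perm_stats) + 1)


def anosim(
    d: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
    exact: bool = False,
) -> PermTestResult:
    """Analysis of similarities (Clarke's R) with a label-permutation test.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks taken over all pairwise distances with average ranks for ties.
    R is 1 when every between-group distance exceeds every within-group
    distance and ~0 under exchangeability.
    """
    labels = _as_group_array(groups)
    n = d.n
    if len(labels) != n:
        raise ValidationError("group labels must match distance matrix samples")
    _check_groups(labels)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d.condensed())
    denom = n * (n - 1) / 4.0

    def stat(lab_rows: np.ndarray) -> np.ndarray:
        within = lab_rows[:, iu] == lab_rows[:, ju]
        n_within = within.sum(axis=1)
        sum_within = (ranks[None, :] * within).sum(axis=1)
        n_between = within.shape[1] - n_within
        sum_between = ranks.sum() - sum_within
        return (sum_between / n_between - sum_within / n_within) / denom

    observed = float(stat(labels[None, :])[0])
    perms, exact_flag = _perm_indices(n, n_perm, seed, exact)
    perm_stats = stat(labels[perms])
    p = _perm_p(perm_stats, observed, exact_flag)
    return PermTestResult(
        method="anosim",
        statistic=observed,
        p_value=p,
        n_permutations=len(perms),
        seed=seed,
    )


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
    exact: bool = False,
) -> PermTestResult:
    """Single-factor PERMANOVA (pseudo-F on squared distances).

    SS_total = (1/N) sum_{i<j} d_ij^2;
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2;
    pseudo-F = ((SS_T - SS_W)/(a-1)) / (SS_W/(N-a)).
    Degenerate SS_W = 0 yields an infinite-F flag; the permutation p-value
    is still well defined.
    """
    labels = _as_group_array(groups)
    n = d.n
    if len(labels) != n:
        raise ValidationError("group labels must match distance matrix samples")
    uniq = _check_groups(labels)
    a = len(uniq)
    iu, ju = np.triu_indices(n, k=1)
    d2 = d.condensed() ** 2
    ss_total = d2.sum() / n
    group_sizes = {g: int((labels == g).sum()) for g in uniq}

    def ss_within(lab_rows: np.ndarray) -> np.ndarray:
        ssw = np.zeros(lab_rows.shape[0])
        for g in uniq:
            in_g = lab_rows == g
            mask = in_g[:, iu] & in_g[:, ju]
            ssw += (mask * d2[None, :]).sum(axis=1) / group_sizes[g]
        return ssw

    def pseudo_f(ssw: np.ndarray) -> np.ndarray:
        ss_among = ss_total - ssw
        with np.errstate(divide="ignore"):
            return np.where(
                ssw > 0,
                (ss_among / (a - 1)) / (ssw / (n - a)),
                np.inf,
            )

    ssw_obs = float(ss_within(labels[None, :])[0])
    f_obs = float(pseudo_f(np.array([ssw_obs]))[0])
    r2 = (ss_total - ssw_obs) / ss_total if ss_total > 0 else 0.0
    perms, exact_flag = _perm_indices(n, n_perm, seed, exact)
    perm_stats = pseudo_f(ss_within(labels[perms]))
    p = _perm_p(perm_stats, f_obs, exact_flag)
    return PermTestResult(
        method="permanova",
        statistic=f_obs,
        p_value=p,
        n_permutations=len(perms),
        seed=seed,
        effect_partition={"R2": float(r2)},
        note="SS_within = 0; maximal-F flag" if not np.isfinite(f_obs) else None,
    )


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int | None = None,
    exact: bool = False,
) -> PermTestResult:
    """Mantel test between two distance matrices over the same samples.

    The statistic is the (Spearman by default) correlation of the two
    strictly-lower-triangle vectors; the null distribution jointly permutes
    rows and columns of the second matrix.  Missing entries are dropped
    pairwise.  A constant matrix leaves the correlation undefined: a
    flagged result (statistic NaN, p 1) is returned rather than NaNs
    propagating.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if d1.ids != d2.ids:
        if set(d1.ids) == set(d2.ids):
            d2 = d2.reorder(d1.ids)
        else:
            raise ValidationError("Mantel requires the same samples in both matrices")
    n = d1.n
    iu, ju = np.triu_indices(n, k=1)
    v1 = d1.values[iu, ju]
    m2 = d2.values
    v2 = m2[iu, ju]
    finite = np.isfinite(v1) & np.isfinite(v2)
    has_missing = not finite.all()

    def corr(x: np.ndarray, y: np.ndarray) -> float:
        if method == "spearman":
            x, y = rankdata(x), rankdata(y)
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    observed = corr(v1[finite], v2[finite])
    if not np.isfinite(observed):
        return PermTestResult(
            method=f"mantel-{method}",
            statistic=float("nan"),
            p_value=1.0,
            n_permutations=0,
            seed=seed,
            note="correlation undefined (constant distance matrix)",
        )
    perms, exact_flag = _perm_indices(n, n_perm, seed, exact)
    if has_missing or method == "pearson":
        perm_stats = np.array(
            [
                corr(
                    v1[np.isfinite(v1) & np.isfinite(m2[p[iu], p[ju]])],
                    m2[p[iu], p[ju]][np.isfinite(v1) & np.isfinite(m2[p[iu], p[ju]])],
                )
                for p in perms
            ]
        )
    else:
        # relabeling permutes the condensed multiset, so ranks can be
        # precomputed once on the full matrix and gathered per permutation
        r1 = rankdata(v1)
        rank_sq = np.zeros_like(m2)
        rank_sq[iu, ju] = rankdata(v2)
        rank_sq += rank_sq.T
        gathered = rank_sq[perms[:, iu], perms[:, ju]]
        r1c = r1 - r1.mean()
        gc = gathered - gathered.mean(axis=1, keepdims=True)
        denom = np.sqrt((r1c**2).sum() * (gc**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            perm_stats = (gc @ r1c) / denom
    perm_stats = perm_stats[np.isfinite(perm_stats)]
    p = _perm_p(perm_stats, observed, exact_flag)
    return PermTestResult(
        method=f"mantel-{method}",
        statistic=observed,
        p_value=p,
        n_permutations=len(perms),
        seed=seed,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    The conventional reporting threshold downstream is an adjusted p of
    0.1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_stress(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against target dissimilarities.

    Disparities are the isotonic (monotone) regression of embedded
    distances on the rank order of the target dissimilarities.
    """
    iu, ju = np.triu_indices(d.shape[0], k=1)
    target = d[iu, ju]
    emb = np.sqrt(((coords[iu] - coords[ju]) ** 2).sum(axis=1))
    order = np.argsort(target, kind="stable")
    disparities = np.empty_like(emb)
    disparities[order] = IsotonicRegression().fit_transform(
        np.arange(len(order)), emb[order]
    )
    denom = (emb**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((emb - disparities) ** 2).sum() / denom))


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric multidimensional scaling (best of ``n_restarts`` SMACOF
    runs), reporting Kruskal stress-1.

    Samples at exactly zero dissimilarity are collapsed before embedding
    and share coordinates afterwards.  Coordinates are centered and
    rotated to principal axes with a deterministic sign convention, so the
    configuration is orientation-stable across runs.
    """
    n = d.n
    if n < k + 1:
        raise ValidationError(f"NMDS with k={k} requires at least {k + 1} samples")
    # collapse exact duplicates (zero dissimilarity implies identity)
    rep: dict[int, int] = {}
    keep: list[int] = []
    for i in range(n):
        for j in keep:
            if d.values[i, j] == 0:
                rep[i] = j
                break
        else:
            rep[i] = i
            keep.append(i)
    sub = d.values[np.ix_(keep, keep)]
    if len(keep) < k + 1:
        raise ValidationError("too few distinct samples for the requested k")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords_sub, _, n_iter = smacof(
            sub,
            metric=False,
            n_components=k,
            n_init=n_restarts,
            max_iter=max_iter,
            eps=tol,
            random_state=np.random.default_rng(seed).integers(2**31 - 1),
            normalized_stress=False,
            return_n_iter=True,
        )
    coords = np.empty((n, k))
    pos_of = {orig: idx for idx, orig in enumerate(keep)}
    for i in range(n):
        coords[i] = coords_sub[pos_of[rep[i]]]
    # center + principal-axis rotation + deterministic signs
    coords -= coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    stress = kruskal_stress(d.values, coords)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=d.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
        ),
        stress=stress,
        converged=bool(n_iter < max_iter),
    )


def haversine_matrix(lat_lon, ids=None) -> DistanceMatrix:
    """Great-circle distance matrix (km) from (latitude, longitude) pairs
    in decimal degrees, Earth radius 6371.0088 km."""
    if isinstance(lat_lon, pd.DataFrame):
        if ids is None:
            ids = list(lat_lon.index)
        lat_lon = lat_lon.to_numpy()
    pts = np.asarray(lat_lon, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("expected an n x 2 array of (lat, lon) degrees")
    lat, lon = pts[:, 0], pts[:, 1]
    if np.any(np.abs(lat) > 90):
        raise ValidationError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise ValidationError("longitude out of range [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (
        np.sin(dphi / 2) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    )
    dist = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    if ids is None:
        ids = [str(i) for i in range(len(lat))]
    return DistanceMatrix(list(ids), dist, metric_name="haversine_km")


def scale_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize columns to mean 0, sd 1 (n-1 denominator).

    Constant columns cannot be scaled and are dropped with a warning.
    """
    frame = pd.DataFrame(matrix).astype(float)
    sd = frame.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        logger.warning("scale_center dropping constant column(s): %s", list(constant))
        frame = frame.drop(columns=list(constant))
        sd = sd.drop(list(constant))
    return (frame - frame.mean()) / sd
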