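"""Community-ecology analyses for phytate-hydrolysis gene and taxon tables.

Covers the ordination and diversity toolkit used on sample × taxon abundance
matrices — Bray–Curtis dissimilarities, principal coordinates analysis
(with Lingoes correction for negative eigenvalues), α-richness with rank-sum
group comparisons, transformation-based redundancy analysis (Hellinger
transform + constrained least squares), distance–decay regression against
log10 geographic distance — plus the normalized stochasticity ratio (NST),
a null-model statistic in [0, 100%] that reads community assembly as
predominantly stochastic above 50% and deterministic below it.

The NST null model preserves each sample's richness and its abundance-value
distribution while reassigning taxon identities with probability
proportional to regional occupancy frequency. Per sample pair the observed
dissimilarity D is compared with the null expectation E: the stochasticity
ratio is D/E when selection makes communities more similar than the null
(D < E), and (1−D)/(1−E) when they are more dissimilar; the ratio is then
normalized by the null model's own expected ratio so that data drawn from
the null itself scores ≈100%.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "PCoAResult",
    "RDAResult",
    "DistanceDecayFit",
    "NSTResult",
    "bray_curtis_matrix",
    "pcoa",
    "alpha_richness",
    "hellinger",
    "tb_rda",
    "haversine_km",
    "distance_decay",
    "nst",
    "permanova_test",
]


@dataclass
class CommunityMatrix:
    """Samples × taxa abundances with optional group labels and coordinates."""

    abundance: pd.DataFrame
    groups: pd.Series | None = None
    coordinates: pd.DataFrame | None = None  # columns: lat, lon

    def __post_init__(self) -> None:
        if (self.abundance.values < 0).any():
            raise ValueError("community matrix has negative entries")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.abundance.index)
            if self.groups.isna().any():
                missing = list(self.groups[self.groups.isna()].index)
                raise ValueError(f"samples without group labels: {missing}")
        if self.coordinates is not None:
            self.coordinates = self.coordinates.reindex(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.index)


def _as_frame(m: "CommunityMatrix | pd.DataFrame") -> pd.DataFrame:
    frame = m.abundance if isinstance(m, CommunityMatrix) else m
    if (frame.values < 0).any():
        raise ValueError("community matrix has negative entries")
    return frame


def bray_curtis_matrix(m: "CommunityMatrix | pd.DataFrame") -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities, Σ|x−y| / Σ(x+y), in [0, 1]."""
    frame = _as_frame(m)
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero_rows = frame.index[frame.sum(axis=1) == 0]
    if len(zero_rows):
        raise ValueError(f"all-zero sample rows: {list(zero_rows)}")
    d = squareform(pdist(frame.values.astype(float), metric="braycurtis"))
    return pd.DataFrame(d, index=frame.index, columns=frame.index)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    correction: str = "none"


def pcoa(d: pd.DataFrame, n_axes: int | None = None) -> PCoAResult:
    """Principal coordinates analysis of a dissimilarity matrix.

    Gower double-centering followed by eigendecomposition; if negative
    eigenvalues arise (non-Euclidean input), the Lingoes correction (adding
    2c to squared off-diagonal dissimilarities) is applied and reported.
    Variance fractions are computed on the corrected, positive eigenvalues.
    """
    dm = np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(dm), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    ids = list(d.index) if isinstance(d, pd.DataFrame) else list(range(dm.shape[0]))
    n = dm.shape[0]

    def _decompose(mat: np.ndarray):
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (mat**2) @ j
        evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
        order = np.argsort(evals)[::-1]
        return evals[order], evecs[:, order]

    evals, evecs = _decompose(dm)
    correction = "none"
    tol = 1e-8 * max(1.0, float(np.abs(evals).max()))
    if evals.min() < -tol:
        c = -float(evals.min())
        d2 = dm**2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        evals, evecs = _decompose(np.sqrt(d2))
        correction = "lingoes"
    keep = evals > tol
    evals_pos = evals[keep]
    coords = evecs[:, keep] * np.sqrt(evals_pos)
    if n_axes is not None:
        coords = coords[:, :n_axes]
    prop = evals_pos / evals_pos.sum() if evals_pos.size else evals_pos
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=evals_pos,
        proportion_explained=prop[: coords.shape[1]],
        correction=correction,
    )


def alpha_richness(
    m: "CommunityMatrix | pd.DataFrame",
    groups: pd.Series | Mapping[str, str] | None = None,
) -> pd.Series | tuple[pd.Series, pd.DataFrame]:
    """Per-sample taxon richness; with groups, also pairwise rank-sum p-values."""
    frame = _as_frame(m)
    richness = (frame > 0).sum(axis=1).astype(int)
    richness.name = "richness"
    if groups is None and isinstance(m, CommunityMatrix):
        groups = m.groups
    if groups is None:
        return richness
    groups = pd.Series(groups).reindex(frame.index)
    labels = sorted(groups.dropna().unique())
    pmat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            stat = stats.ranksums(
                richness[groups == a], richness[groups == b], alternative="two-sided"
            )
            pmat.loc[a, b] = pmat.loc[b, a] = stat.pvalue
    return richness, pmat


def hellinger(frame: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: square root of row-relative abundances."""
    totals = frame.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero sample rows cannot be Hellinger-transformed")
    return np.sqrt(frame.div(totals, axis=0))


@dataclass
class RDAResult:
    site_scores: pd.DataFrame
    constraint_scores: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray  # per constrained axis, of total inertia
    constrained_fraction: float


def _encode_design(constraints: pd.DataFrame) -> pd.DataFrame:
    cols = []
    for name in constraints.columns:
        col = constraints[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(col.astype(float).to_frame())
    return pd.concat(cols, axis=1)


def tb_rda(
    m: "CommunityMatrix | pd.DataFrame",
    constraints: pd.DataFrame,
) -> RDAResult:
    """Transformation-based redundancy analysis (Hellinger + RDA).

    The community table is Hellinger-transformed and column-centered, the
    design matrix is encoded (categoricals one-hot, first level dropped) and
    centered, and the fitted values of the least-squares projection are
    eigendecomposed. Axis variance fractions are relative to total inertia
    and sum to the constrained-inertia share.
    """
    frame = _as_frame(m)
    constraints = constraints.reindex(frame.index)
    x = _encode_design(constraints)
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc.values)
    if rank < xc.shape[1]:
        _, r = np.linalg.qr(xc.values)
        bad = [xc.columns[i] for i in range(xc.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    y = hellinger(frame)
    yc = y - y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(xc.values, yc.values, rcond=None)
    yhat = xc.values @ beta
    n = frame.shape[0]
    total_inertia = float((yc.values**2).sum()) / (n - 1)
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > 1e-12 * max(total_inertia, 1.0)
    eig, u, s = eig[keep], u[:, keep], s[keep]
    site = u * s
    axes = [f"RDA{i + 1}" for i in range(site.shape[1])]
    site_scores = pd.DataFrame(site, index=frame.index, columns=axes)
    # constraint (biplot) scores: correlations of design columns with site axes
    cs = np.zeros((xc.shape[1], site.shape[1]))
    for i in range(xc.shape[1]):
        for j in range(site.shape[1]):
            sd = xc.values[:, i].std() * site[:, j].std()
            cs[i, j] = 0.0 if sd == 0 else np.corrcoef(xc.values[:, i], site[:, j])[0, 1]
    return RDAResult(
        site_scores=site_scores,
        constraint_scores=pd.DataFrame(cs, index=xc.columns, columns=axes),
        eigenvalues=eig,
        proportion_explained=eig / total_inertia if total_inertia > 0 else eig,
        constrained_fraction=float(eig.sum() / total_inertia) if total_inertia > 0 else 0.0,
    )


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres."""
    r = 6371.0088
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * r * np.arcsin(np.sqrt(a)))


@dataclass
class DistanceDecayFit:
    slope: float
    intercept: float
    r_value: float
    p_value: float
    ci95: tuple[float, float]
    log10_distance: bool = True


def distance_decay(
    similarity: Sequence[float],
    geographic_distance: Sequence[float],
    log10_distance: bool = True,
) -> DistanceDecayFit:
    """OLS regression of pairwise community similarity on (log10) distance."""
    sim = np.asarray(similarity, dtype=float)
    dist = np.asarray(geographic_distance, dtype=float)
    if sim.shape != dist.shape:
        raise ValueError("similarity and distance vectors differ in length")
    if sim.size < 3:
        raise ValueError("need at least 3 pairs")
    if log10_distance:
        if (dist <= 0).any():
            raise ValueError("non-positive distances are invalid on a log scale")
        dist = np.log10(dist)
    if np.ptp(sim) == 0:  # constant similarity: slope exactly 0
        return DistanceDecayFit(0.0, float(sim[0]), 0.0, 1.0, (0.0, 0.0), log10_distance)
    fit = stats.linregress(dist, sim)
    tcrit = stats.t.ppf(0.975, sim.size - 2)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return DistanceDecayFit(
        float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue),
        ci, log10_distance,
    )


@dataclass
class NSTResult:
    group: str
    nst_percent: float
    classification: str
    pair_ratios: pd.Series = field(repr=False, default=None)
    null_reps: int = 0
    seed: int | None = None
    null_model: str = "PF"
    metric: str = "ruzicka"


def _dissim_matrix(x: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise dissimilarities of rows of x (vectorized; n is small)."""
    if metric == "ruzicka":
        mins = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=-1)
        maxs = np.maximum(x[:, None, :], x[None, :, :]).sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - np.where(maxs > 0, mins / np.where(maxs == 0, 1, maxs), 1.0)
        return d
    if metric == "bray":
        sums = x[:, None, :] + x[None, :, :]
        diffs = np.abs(x[:, None, :] - x[None, :, :])
        tot = sums.sum(axis=-1)
        return np.where(tot > 0, diffs.sum(axis=-1) / np.where(tot == 0, 1, tot), 0.0)
    if metric == "jaccard":
        b = x > 0
        inter = (b[:, None, :] & b[None, :, :]).sum(axis=-1)
        union = (b[:, None, :] | b[None, :, :]).sum(axis=-1)
        return 1.0 - np.where(union > 0, inter / np.where(union == 0, 1, union), 1.0)
    raise ValueError(f"unknown dissimilarity metric {metric!r}")


def _null_sample(
    values: np.ndarray,
    pool_size: int,
    pool_freq: np.ndarray,
    rng: np.random.Generator,
    incidence: bool,
) -> np.ndarray:
    """One null community: observed abundance values on reshuffled taxa."""
    out = np.zeros(pool_size)
    k = values.size
    taxa = rng.choice(pool_size, size=k, replace=False, p=pool_freq)
    vals = np.ones(k) if incidence else rng.permutation(values)
    out[taxa] = vals
    return out


def _stochasticity_ratio(d: np.ndarray, e: np.ndarray, dmax: float = 1.0) -> np.ndarray:
    """Pairwise stochasticity ratio in [0, 1]; 1 when observed equals the null."""
    d, e = np.broadcast_arrays(np.asarray(d, dtype=float), np.asarray(e, dtype=float))
    ratio = np.ones(d.shape)
    lower = (d < e) & (e > 0)
    ratio[lower] = d[lower] / e[lower]
    upper = (d > e) & (e < dmax)
    ratio[upper] = (dmax - d[upper]) / (dmax - e[upper])
    ratio[(d > e) & (e >= dmax)] = 0.0
    ratio[(d < e) & (e <= 0)] = 0.0
    return np.clip(ratio, 0.0, 1.0)


def nst(
    m: "CommunityMatrix | pd.DataFrame",
    groups: pd.Series | Mapping[str, str] | None = None,
    null_model: str = "PF",
    reps: int = 1000,
    seed: int | None = None,
    metric: str = "ruzicka",
) -> list[NSTResult]:
    """Normalized stochasticity ratio per sample group.

    The taxon pool and occupancy frequencies come from the full matrix (the
    regional species pool); the null model ("PF": occupancy proportional to
    frequency, per-sample richness and abundance-value distribution fixed)
    is evaluated ``reps`` times. Groups with fewer than 3 samples are
    skipped. Deterministic given ``seed``; invariant to sample and taxon
    order (per-sample random streams are keyed by sample id).

    Groups are labelled stochastic above 50%, deterministic below.
    """
    if null_model != "PF":
        raise ValueError(f"unknown null model {null_model!r}")
    if reps < 100:
        raise ValueError("reps must be at least 100")
    if seed is None:
        raise ValueError("a seed is required for the null model")
    if metric == "jaccard":
        incidence = True
    elif metric in ("ruzicka", "bray"):
        incidence = False
    else:
        raise ValueError(f"unknown dissimilarity metric {metric!r}")
    frame = _as_frame(m)
    if groups is None:
        groups = m.groups if isinstance(m, CommunityMatrix) and m.groups is not None else None
    if groups is None:
        groups = pd.Series("all", index=frame.index)
    groups = pd.Series(groups).reindex(frame.index)

    # canonical taxon order so results do not depend on column order
    frame = frame[sorted(frame.columns)]
    occupied = (frame > 0).sum(axis=0)
    pool_cols = occupied[occupied > 0].index
    pool = frame[pool_cols]
    freq = occupied[pool_cols].to_numpy(dtype=float)
    freq = freq / freq.sum()
    pool_size = len(pool_cols)

    results: list[NSTResult] = []
    for label in sorted(groups.dropna().unique()):
        sample_ids = sorted(groups.index[groups == label])
        if len(sample_ids) < 3:
            logger.warning("group %r has <3 samples; skipped", label)
            continue
        x = pool.loc[sample_ids].to_numpy(dtype=float)
        if incidence:
            x = (x > 0).astype(float)
        n = len(sample_ids)
        iu = np.triu_indices(n, k=1)
        d_obs = _dissim_matrix(x, metric)[iu]
        nonzero_vals = [row[row > 0] for row in x]
        null_d = np.empty((reps, iu[0].size))
        for k in range(reps):
            null_x = np.empty((n, pool_size))
            for si, sid in enumerate(sample_ids):
                rng = np.random.default_rng(
                    [seed, k, zlib.crc32(str(sid).encode()) & 0x7FFFFFFF]
                )
                null_x[si] = _null_sample(
                    nonzero_vals[si], pool_size, freq, rng, incidence
                )
            null_d[k] = _dissim_matrix(null_x, metric)[iu]
        e = null_d.mean(axis=0)
        st_obs = _stochasticity_ratio(d_obs, e)
        st_null = _stochasticity_ratio(null_d, e[None, :]).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            nst_pair = np.where(st_null > 0, st_obs / st_null, np.where(st_obs > 0, 1.0, 1.0))
        nst_pair = np.clip(nst_pair, 0.0, 1.0)
        pct = float(100.0 * nst_pair.mean())
        classification = "stochastic" if pct > 50 else "deterministic" if pct < 50 else "boundary"
        pair_index = pd.MultiIndex.from_arrays(
            [np.array(sample_ids)[iu[0]], np.array(sample_ids)[iu[1]]]
        )
        results.append(
            NSTResult(
                group=str(label),
                nst_percent=pct,
                classification=classification,
                pair_ratios=pd.Series(100.0 * nst_pair, index=pair_index),
                null_reps=reps,
                seed=seed,
                null_model=null_model,
                metric=metric,
            )
        )
    return results


def permanova_test(
    d: pd.DataFrame,
    groups: pd.Series | Mapping[str, str],
    permutations: int = 999,
    seed: int = 42,
):
    """PERMANOVA on a dissimilarity matrix (supporting output for ordinations)."""
    from skbio import DistanceMatrix
    from skbio.stats.distance import permanova

    ids = list(d.index)
    dm = DistanceMatrix(np.asarray(d, dtype=float), ids=ids)
    grouping = pd.Series(groups).reindex(ids)
    return permanova(dm, grouping.values, permutations=permutations, seed=seed)
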