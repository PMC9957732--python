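"""Mantel tests, partial Mantel tests and Mantel correlograms.

The Mantel statistic is the Pearson product–moment correlation between the
off-diagonal entries of two labelled distance matrices.  Significance comes
from joint row/column permutations of one matrix (which preserves the
exchangeability structure of distances), and confidence intervals from a
bootstrap over site labels.  The partial Mantel statistic correlates the
residuals of both matrices after linear regression on a control matrix
(typically geographic distance).  Correlograms profile spatial
autocorrelation by testing trait distance against membership indicators of
fixed-width geographic distance classes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import DistanceMatrix

DEFAULT_N_PERM = 999
#: bootstrap resample count used for confidence intervals
DEFAULT_N_BOOT = 500
#: geographic distance-class width for correlograms, km
DEFAULT_CLASS_WIDTH_KM = 213.0


@dataclass
class MantelResult:
    """Mantel correlation with permutation p-value and bootstrap CI."""

    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n_perm: int
    n_boot: int
    n: int
    degenerate: bool = False


@dataclass
class Correlogram:
    """Per-distance-class Mantel statistics (positive r = within-class similarity)."""

    class_edges_km: np.ndarray      # len k+1
    r: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class_low_km": self.class_edges_km[:-1],
            "class_high_km": self.class_edges_km[1:],
            "class_mid_km": 0.5 * (self.class_edges_km[:-1] + self.class_edges_km[1:]),
            "r": self.r, "p": self.p,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_pairs": self.n_pairs,
        })


def _check_aligned(*mats: DistanceMatrix) -> list[DistanceMatrix]:
    base = mats[0]
    out = [base]
    for m in mats[1:]:
        out.append(m if m.labels == base.labels else m.align_to(base.labels))
    if base.n < 4:
        raise ValueError("Mantel tests need at least 4 labels")
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _perm_iter(n: int, n_perm: int, rng: np.random.Generator, exact: bool):
    if exact:
        # skip the identity; every non-trivial relabelling once
        return (np.asarray(p) for p in itertools.permutations(range(n))
                if p != tuple(range(n)))
    return (rng.permutation(n) for _ in range(n_perm))


def _p_value(r_obs: float, r_perm: np.ndarray, alternative: str) -> float:
    r_perm = r_perm[~np.isnan(r_perm)]
    m = r_perm.size
    if alternative == "two-sided":
        count = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    elif alternative == "greater":
        count = int(np.sum(r_perm >= r_obs - 1e-12))
    else:
        count = int(np.sum(r_perm <= r_obs + 1e-12))
    return (count + 1) / (m + 1)


def _bootstrap_ci(
    stat_fn, n: int, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Percentile bootstrap over site labels.

    Pairs formed by two copies of the same original site are excluded from the
    resampled statistic (their distance is a structural zero in every matrix).
    """
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        iu = np.triu_indices(n, k=1)
        keep = idx[iu[0]] != idx[iu[1]]
        if keep.sum() < 3:
            continue
        s = stat_fn(idx, iu, keep)
        if not math.isnan(s):
            stats.append(s)
    if len(stats) < 10:
        return (np.nan, np.nan)
    return tuple(np.percentile(stats, [2.5, 97.5]))


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = DEFAULT_N_PERM,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    alternative: str = "two-sided",
    exact: bool = False,
) -> MantelResult:
    """Mantel test between two labelled distance matrices.

    ``exact=True`` enumerates all label permutations (feasible for n ≤ 8)
    instead of Monte-Carlo sampling.  The permutation p-value is
    ``(count ≥ observed + 1) / (n_perm + 1)``, two-sided on \\|r\\| by default.
    """
    d1, d2 = _check_aligned(d1, d2)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1, v2 = d1.values[iu], d2.values[iu]
    r_obs = _pearson(v1, v2)
    if math.isnan(r_obs):
        return MantelResult(np.nan, 1.0, np.nan, np.nan, 0, 0, n, degenerate=True)
    rng = np.random.default_rng(seed)
    A = d1.values
    r_perm = np.array([
        _pearson(A[np.ix_(p, p)][iu], v2) for p in _perm_iter(n, n_perm, rng, exact)
    ])
    p = _p_value(r_obs, r_perm, alternative)

    def boot_stat(idx, iu_, keep):
        return _pearson(d1.values[np.ix_(idx, idx)][iu_][keep],
                        d2.values[np.ix_(idx, idx)][iu_][keep])

    lo, hi = _bootstrap_ci(boot_stat, n, n_boot, rng)
    return MantelResult(r_obs, p, lo, hi, int(r_perm.size), n_boot, n)


def _residualize(v: np.ndarray, vc: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(vc), vc])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d_control: DistanceMatrix,
    n_perm: int = DEFAULT_N_PERM,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> MantelResult:
    """Partial Mantel test of d1 vs d2 holding d_control constant.

    Both matrices are residualized on the control by ordinary least squares on
    the vectorized off-diagonals; the permutation scheme relabels d1 and
    re-residualizes (raw-matrix permutation, Legendre's method).
    """
    d1, d2, dc = _check_aligned(d1, d2, d_control)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1, v2, vc = d1.values[iu], d2.values[iu], dc.values[iu]
    if vc.std() == 0:
        raise ValueError("constant control matrix")
    r1, r2 = _residualize(v1, vc), _residualize(v2, vc)
    if np.allclose(r1, 0) or np.allclose(r2, 0):
        # d1 or d2 collinear with the control: partial correlation undefined
        return MantelResult(0.0, 1.0, np.nan, np.nan, 0, 0, n, degenerate=True)
    r_obs = _pearson(r1, r2)
    rng = np.random.default_rng(seed)
    r_perm = np.array([
        _pearson(_residualize(d1.values[np.ix_(p, p)][iu], vc), r2)
        for p in _perm_iter(n, n_perm, rng, False)
    ])
    p = _p_value(r_obs, r_perm, alternative)

    def boot_stat(idx, iu_, keep):
        b1 = d1.values[np.ix_(idx, idx)][iu_][keep]
        b2 = d2.values[np.ix_(idx, idx)][iu_][keep]
        bc = dc.values[np.ix_(idx, idx)][iu_][keep]
        if bc.std() == 0:
            return np.nan
        return _pearson(_residualize(b1, bc), _residualize(b2, bc))

    lo, hi = _bootstrap_ci(boot_stat, n, n_boot, rng)
    return MantelResult(r_obs, p, lo, hi, n_perm, n_boot, n)


def mantel_correlogram(
    d_trait: DistanceMatrix,
    d_geo_km: DistanceMatrix,
    class_width_km: float = DEFAULT_CLASS_WIDTH_KM,
    n_perm: int = DEFAULT_N_PERM,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> Correlogram:
    """Mantel correlogram with fixed-width geographic distance classes.

    For class *k* with membership indicator ``I_k(i,j)``, the reported
    statistic is ``r_k = −mantel(d_trait, I_k).r``: the sign is flipped so
    that positive values mean *similarity* within the class (pairs in the
    class have smaller trait distance than average).  Classes with fewer than
    2 pairs are dropped from the top of the range; a class whose indicator is
    constant over all pairs yields r = 0, p = 1.
    """
    if class_width_km <= 0:
        raise ValueError("class width must be positive")
    d_trait, d_geo = _check_aligned(d_trait, d_geo_km)
    n = d_trait.n
    iu = np.triu_indices(n, k=1)
    vt, vg = d_trait.values[iu], d_geo.values[iu]
    n_classes = int(np.ceil(vg.max() / class_width_km)) if vg.max() > 0 else 1
    edges = np.arange(n_classes + 1) * class_width_km
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]

    rs, ps, los, his, counts, kept_edges = [], [], [], [], [], [edges[0]]
    for k in range(n_classes):
        in_class = (vg >= edges[k]) & (vg < edges[k + 1])
        if k == n_classes - 1:
            in_class |= vg == edges[k + 1]
        n_pairs = int(in_class.sum())
        if n_pairs < 2:
            break  # beyond the informative range
        ind = in_class.astype(float)
        r_obs = _pearson(vt, ind)
        if math.isnan(r_obs):  # constant indicator: every pair in this class
            rs.append(0.0); ps.append(1.0); los.append(np.nan); his.append(np.nan)
        else:
            I = np.zeros((n, n))
            I[iu] = ind
            I = I + I.T
            r_perm = np.array([_pearson(vt, I[np.ix_(p, p)][iu]) for p in perms])
            ps.append(_p_value(r_obs, r_perm, "two-sided"))
            rs.append(-r_obs)

            def boot_stat(idx, iu_, keep, _I=I):
                return _pearson(d_trait.values[np.ix_(idx, idx)][iu_][keep],
                                _I[np.ix_(idx, idx)][iu_][keep])

            lo, hi = _bootstrap_ci(boot_stat, n, n_boot, rng)
            los.append(-hi); his.append(-lo)  # sign flip swaps the bounds
        counts.append(n_pairs)
        kept_edges.append(edges[k + 1])
    return Correlogram(
        np.asarray(kept_edges), np.asarray(rs), np.asarray(ps),
        np.asarray(los), np.asarray(his), np.asarray(counts),
    )


def mantel_table(
    pairs: dict[str, tuple[DistanceMatrix, DistanceMatrix]],
    control: DistanceMatrix | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Batch of (partial) Mantel tests, one row per named matrix pair."""
    rows = []
    for name, (a, b) in pairs.items():
        res = (partial_mantel(a, b, control, **kwargs) if control is not None
               else mantel(a, b, **kwargs))
        rows.append({"comparison": name, "r": res.r, "p": res.p_value,
                     "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n})
    return pd.DataFrame(rows)
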