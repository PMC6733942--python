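"""Variance-collapse detection along the drainage-area axis.

Synoptic snapshots of a stream network show high among-site variability in
solute concentration among small headwater subcatchments that *collapses*
toward zero once drainage areas exceed the characteristic patch size of the
landscape sources and sinks: downstream mixing averages the patches out.  The
drainage area at which the collapse happens is therefore an estimate of that
patch scale.

The detector orders the z-scored concentrations of one watershed x season x
solute by drainage area and fits a single change point in *variance*: for a
split after ``k`` sites the Gaussian log-likelihood-ratio against the
no-change model is

    LR(k) = n log s2_all - k log s2_left - (n - k) log s2_right

with maximum-likelihood (ddof=0) variances about each segment's own mean.
The split maximising LR over ``k in [min_segment, n - min_segment]`` is the
candidate change point; its significance comes from a permutation test that
shuffles the site order and recomputes the max-LR statistic.  The reported
threshold area is the geometric mean of the two drainage areas bracketing the
split (areas span orders of magnitude, so the log midpoint is the natural
interpolant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, ZeroVarianceError

#: floor applied to segment variances so the log stays finite on (near-)
#: constant segments; any real collapse hits this floor and yields a huge LR
VAR_FLOOR = 1e-12


@dataclass
class ScaledSeries:
    """Area-ordered z-scores for one watershed x season x solute."""

    areas: np.ndarray
    z: np.ndarray
    site_ids: list[str] = field(default_factory=list)
    watershed_id: str = ""
    season: str = ""
    solute: str = ""

    @property
    def n(self) -> int:
        return len(self.z)


def scale_concentrations(
    values,
    site_ids=None,
    **meta,
) -> ScaledSeries:
    """Z-score concentrations and order them by drainage area.

    ``values`` is a sequence of ``(area, concentration)`` pairs.  Scaling uses
    the sample standard deviation (n - 1).  Ties in area are broken by
    ``site_ids`` lexicographically so the ordering is deterministic.
    """
    values = list(values)
    n = len(values)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 sites to scale (got {n})")
    if site_ids is None:
        site_ids = [f"s{i}" for i in range(n)]
    if len(site_ids) != n:
        raise ValueError("site_ids length does not match values")

    order = sorted(range(n), key=lambda i: (values[i][0], site_ids[i]))
    areas = np.array([values[i][0] for i in order], dtype=float)
    conc = np.array([values[i][1] for i in order], dtype=float)
    sd = conc.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError(
            "concentrations are constant across sites; z-scores undefined"
        )
    z = (conc - conc.mean()) / sd
    return ScaledSeries(
        areas=areas, z=z, site_ids=[site_ids[i] for i in order], **meta
    )


def _max_lr(z: np.ndarray, min_segment: int) -> tuple[int, float]:
    """Exhaustive single-change-point LR maximisation (smallest-k tie-break).

    Returns ``(k, LR)`` where ``k`` is the size of the left segment.
    """
    n = len(z)
    c1 = np.cumsum(z)
    c2 = np.cumsum(z * z)
    k = np.arange(min_segment, n - min_segment + 1)
    nl, nr = k, n - k
    s1l = c1[k - 1]
    s2l = c2[k - 1]
    vl = np.maximum(s2l / nl - (s1l / nl) ** 2, VAR_FLOOR)
    vr = np.maximum((c2[-1] - s2l) / nr - ((c1[-1] - s1l) / nr) ** 2, VAR_FLOOR)
    vall = max(c2[-1] / n - (c1[-1] / n) ** 2, VAR_FLOOR)
    lr = n * np.log(vall) - nl * np.log(vl) - nr * np.log(vr)
    i = int(np.argmax(lr))
    return int(k[i]), float(lr[i])


def _max_lr_batch(Z: np.ndarray, min_segment: int) -> np.ndarray:
    """Max-LR statistic for each row of ``Z`` (vectorised over permutations)."""
    m, n = Z.shape
    c1 = np.cumsum(Z, axis=1)
    c2 = np.cumsum(Z * Z, axis=1)
    k = np.arange(min_segment, n - min_segment + 1)
    nl = k.astype(float)
    nr = (n - k).astype(float)
    s1l = c1[:, k - 1]
    s2l = c2[:, k - 1]
    vl = np.maximum(s2l / nl - (s1l / nl) ** 2, VAR_FLOOR)
    vr = np.maximum(
        (c2[:, -1:] - s2l) / nr - ((c1[:, -1:] - s1l) / nr) ** 2, VAR_FLOOR
    )
    vall = np.maximum(c2[:, -1] / n - (c1[:, -1] / n) ** 2, VAR_FLOOR)
    lr = n * np.log(vall)[:, None] - nl * np.log(vl) - nr * np.log(vr)
    return lr.max(axis=1)


@dataclass
class CollapseResult:
    """Fitted variance-collapse change point for one series.

    ``changepoint_index`` is the number of sites left of the split (1-based
    rank of the last small-catchment site); it and ``threshold_area_km2`` are
    ``None`` when the permutation p-value exceeds ``alpha`` — no significant
    variance collapse, as happens for solutes whose in-stream processing
    erases the terrestrial patch signal.
    """

    changepoint_index: int | None
    threshold_area_km2: float | None
    lr_statistic: float
    p_value: float
    n_permutations: int
    variance_profile: list[tuple[float, float]]
    n: int
    alpha: float
    watershed_id: str = ""
    season: str = ""
    solute: str = ""

    @property
    def significant(self) -> bool:
        return self.changepoint_index is not None

    def summary(self) -> str:
        lines = [
            "Variance collapse change point",
            "==============================",
            f"series            {self.watershed_id} {self.season} {self.solute}".rstrip(),
            f"n sites           {self.n}",
            f"max LR statistic  {self.lr_statistic:.4g}",
            f"permutation p     {self.p_value:.4g}  ({self.n_permutations} permutations)",
        ]
        if self.significant:
            lines += [
                f"split index       {self.changepoint_index}",
                f"threshold area    {self.threshold_area_km2:.4g} km2",
            ]
        else:
            lines.append(f"no significant variance collapse at alpha = {self.alpha}")
        return "\n".join(lines)


class VarianceCollapseModel:
    """Single change point in spatial variance along the area axis.

    Parameters
    ----------
    series
        A :class:`ScaledSeries` (already z-scored, area-ordered).  Use
        :meth:`from_concentrations` to build one from raw values.
    """

    def __init__(self, series: ScaledSeries):
        self.series = series

    @classmethod
    def from_concentrations(cls, values, site_ids=None, **meta):
        return cls(scale_concentrations(values, site_ids=site_ids, **meta))

    def fit(
        self,
        alpha: float = 0.05,
        n_perm: int = 999,
        min_segment: int = 5,
        seed: int | None = None,
        window: int = 10,
    ) -> CollapseResult:
        s = self.series
        n = s.n
        if n < 2 * min_segment:
            raise InsufficientDataError(
                f"need at least {2 * min_segment} sites for a change point "
                f"with min_segment={min_segment} (got {n})"
            )
        k, lr = _max_lr(s.z, min_segment)

        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(s.z, (n_perm, 1)), axis=1)
        perm_lr = _max_lr_batch(perms, min_segment)
        p = (1.0 + np.count_nonzero(perm_lr >= lr - 1e-12)) / (n_perm + 1.0)

        if p <= alpha:
            idx: int | None = k
            thr: float | None = float(np.sqrt(s.areas[k - 1] * s.areas[k]))
        else:
            idx, thr = None, None

        profile = (
            variance_profile(s, window=min(window, n)) if n >= 2 else []
        )
        return CollapseResult(
            changepoint_index=idx,
            threshold_area_km2=thr,
            lr_statistic=lr,
            p_value=float(p),
            n_permutations=n_perm,
            variance_profile=profile,
            n=n,
            alpha=alpha,
            watershed_id=s.watershed_id,
            season=s.season,
            solute=s.solute,
        )


def detect_variance_collapse(
    series: ScaledSeries,
    alpha: float = 0.05,
    n_perm: int = 999,
    min_segment: int = 5,
    seed: int | None = None,
) -> CollapseResult:
    """Functional wrapper: fit :class:`VarianceCollapseModel` on ``series``."""
    return VarianceCollapseModel(series).fit(
        alpha=alpha, n_perm=n_perm, min_segment=min_segment, seed=seed
    )


def variance_profile(series: ScaledSeries, window: int = 10) -> list[tuple[float, float]]:
    """Sliding-window sample variance of z over area-ordered sites.

    Each window is summarised by the geometric mean of its member areas and
    the sample (n - 1) variance of its z-scores; the profile has
    ``n - window + 1`` points and is the quantity plotted against area when
    visualising the collapse.
    """
    n = series.n
    if window < 2:
        raise ValueError("window must be >= 2")
    if n < window:
        raise InsufficientDataError(
            f"need at least window={window} sites for a profile (got {n})"
        )
    zw = np.lib.stride_tricks.sliding_window_view(series.z, window)
    aw = np.lib.stride_tricks.sliding_window_view(series.areas, window)
    variances = zw.var(axis=1, ddof=1)
    centers = np.exp(np.log(aw).mean(axis=1))
    return list(zip(centers.tolist(), variances.tolist()))
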