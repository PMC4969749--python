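"""Robust bivariate statistics linking cell-mean axial strain to death time.

The central object is :class:`StrainDeathModel`: given per-cell pairs
(⟨E_c⟩, t_d) — mean compressive axial strain and time of cell death in
hours — ``fit()`` runs the FAST-MCD robust estimator and returns a
:class:`StrainDeathResults` carrying the robust centroid and scatter, the
95% confidence ellipse of the fitted bivariate normal, and the death-time
law read off the ellipse's major axis:

    t_d = s (c − ⟨E_c⟩)

with s the slope magnitude (hours per unit strain) and c the strain at
which the predicted death time reaches zero.  The module also provides
cohort-level summaries (death percentages normalised by control viability,
bleb prevalence and fold change), the scaled inverse-CDF used for the
bleb shear-threshold analysis, and a Welch t-test wrapper.

Internally all bivariate quantities are ordered (strain, time); I/O columns
are explicitly named to keep the convention visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .robust import MCDFit, default_h, fast_mcd

__all__ = [
    "InjuryRecord",
    "BlebStrainSample",
    "ConfidenceEllipse",
    "DeathTimeRelation",
    "CohortSummary",
    "StrainDeathModel",
    "StrainDeathResults",
    "confidence_ellipse",
    "major_axis_relation",
    "predict_death_time",
    "bivariate_density_grid",
    "scaled_inverse_cdf",
    "cohort_summary",
    "welch_ttest",
]

CHI2_2_95 = float(stats.chi2.ppf(0.95, df=2))  # ≈ 5.991


@dataclass(frozen=True)
class InjuryRecord:
    """One cell's strain exposure and injury outcome.

    ``death_time_hr`` is ``None`` for cells that survived the observation
    window; such cells are excluded from the bivariate fit but counted in
    cohort percentages.  Strains are compressive magnitudes
    (dimensionless); bleb positions are arc lengths in µm.
    """

    cell_id: str
    rate_group: str
    mean_Ec: float
    mean_Es: float
    death_time_hr: float | None = None
    bleb_formed: bool = False
    bleb_positions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.death_time_hr is not None and self.death_time_hr <= 0:
            raise ValueError("death time must be positive when present")
        if self.mean_Es < 0:
            raise ValueError("mean shear strain must be non-negative")

    @property
    def died(self) -> bool:
        return self.death_time_hr is not None


@dataclass(frozen=True)
class BlebStrainSample:
    """Local strain extrema at one bleb site."""

    cell_id: str
    Ec_max: float
    Es_max: float

    def __post_init__(self) -> None:
        if self.Es_max < 0:
            raise ValueError("shear maximum must be non-negative")


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Confidence isocontour of a fitted bivariate normal.

    ``centroid`` is (strain, hours); ``a1`` and ``a2`` are the major and
    minor half-axis vectors (|a1| >= |a2|, mutually orthogonal in the raw
    (strain, hours) plane).  ``eccentricity`` is computed from raw
    half-axis lengths by default; ``eccentricity_standardized`` rescales
    each coordinate by its fitted standard deviation first (the two differ
    whenever the axes mix units).
    """

    centroid: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    level: float
    eccentricity: float
    eccentricity_standardized: float

    def axis_lengths(self) -> tuple[float, float]:
        return float(np.linalg.norm(self.a1)), float(np.linalg.norm(self.a2))

    def boundary(self, n: int = 200) -> np.ndarray:
        """(n, 2) polyline tracing the ellipse boundary."""
        theta = np.linspace(0, 2 * np.pi, n)
        return (
            self.centroid
            + np.outer(np.cos(theta), self.a1)
            + np.outer(np.sin(theta), self.a2)
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        pts = np.atleast_2d(points) - self.centroid
        u1 = self.a1 / np.linalg.norm(self.a1)
        u2 = self.a2 / np.linalg.norm(self.a2)
        x = pts @ u1 / np.linalg.norm(self.a1)
        y = pts @ u2 / np.linalg.norm(self.a2)
        return x**2 + y**2 <= 1.0


@dataclass(frozen=True)
class DeathTimeRelation:
    """Death-time law t_d = slope_mag × (strain_intercept − ⟨E_c⟩)."""

    slope_mag: float
    strain_intercept: float

    def __post_init__(self) -> None:
        if self.slope_mag <= 0:
            raise ValueError("slope magnitude must be positive")

    def predict(self, mean_Ec: float | np.ndarray) -> np.ndarray | float:
        return predict_death_time(self, mean_Ec)


def confidence_ellipse(
    fit: MCDFit | tuple[np.ndarray, np.ndarray], level: float = 0.95
) -> ConfidenceEllipse:
    """Confidence ellipse of the bivariate normal defined by a fit.

    Half-axis lengths are sqrt(eigenvalue × χ²₂(level)) along the
    covariance eigenvectors.
    """
    if isinstance(fit, MCDFit):
        mu, cov = fit.location, fit.covariance
    else:
        mu, cov = fit
    mu = np.asarray(mu, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("confidence ellipse requires a 2x2 covariance")
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 0:
        raise ValueError("covariance must be positive definite")
    q = float(stats.chi2.ppf(level, df=2))
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    a1 = eigvecs[:, 0] * np.sqrt(eigvals[0] * q)
    a2 = eigvecs[:, 1] * np.sqrt(eigvals[1] * q)
    ecc = float(np.sqrt(1.0 - eigvals[1] / eigvals[0]))

    sd = np.sqrt(np.diag(cov))
    cov_std = cov / np.outer(sd, sd)
    ev_std = np.linalg.eigvalsh(cov_std)
    ecc_std = float(np.sqrt(1.0 - ev_std[0] / ev_std[1]))

    return ConfidenceEllipse(
        centroid=mu, a1=a1, a2=a2, level=level,
        eccentricity=ecc, eccentricity_standardized=ecc_std,
    )


def major_axis_relation(
    ellipse: ConfidenceEllipse, min_strain_component: float = 1e-6
) -> DeathTimeRelation:
    """Death-time law along the major axis of the confidence ellipse.

    The major axis is a line through the centroid; expressed in the
    (strain, time) plane it gives t_d = slope_mag (strain_intercept − E)
    with slope_mag = |Δt / Δstrain| along the axis.  A major axis (nearly)
    parallel to the time axis carries no strain information and raises.
    """
    d_strain, d_time = ellipse.a1
    if abs(d_strain) <= min_strain_component * max(1.0, abs(d_time)):
        raise ValueError(
            "major axis is parallel to the time axis; death-time relation "
            "is degenerate"
        )
    slope_mag = abs(d_time / d_strain)
    mu_strain, mu_time = ellipse.centroid
    intercept = mu_strain + mu_time / slope_mag
    return DeathTimeRelation(slope_mag=slope_mag, strain_intercept=intercept)


def predict_death_time(
    relation: DeathTimeRelation, mean_Ec: float | np.ndarray
) -> float | np.ndarray:
    """Predicted hours to death at a given mean compressive axial strain.

    Strains beyond the intercept predict negative times; these are clamped
    to zero with a warning.
    """
    e = np.asarray(mean_Ec, dtype=float)
    t = relation.slope_mag * (relation.strain_intercept - e)
    if np.any(t < 0):
        warnings.warn(
            "strain exceeds the zero-death-time intercept; clamping to 0",
            stacklevel=2,
        )
        t = np.maximum(t, 0.0)
    return float(t) if np.isscalar(mean_Ec) else t


def bivariate_density_grid(
    fit: MCDFit | tuple[np.ndarray, np.ndarray],
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    resolution: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bivariate normal pdf of a fit on a regular grid.

    Returns (strain_axis, time_axis, density) with density indexed
    [strain, time]. Default bounds are centroid ± 5 SD per axis.
    """
    if isinstance(fit, MCDFit):
        mu, cov = fit.location, fit.covariance
    else:
        mu, cov = fit
    mu = np.asarray(mu, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if bounds is None:
        sd = np.sqrt(np.diag(cov))
        bounds = tuple((mu[k] - 5 * sd[k], mu[k] + 5 * sd[k]) for k in range(2))
    x = np.linspace(*bounds[0], resolution)
    y = np.linspace(*bounds[1], resolution)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    density = stats.multivariate_normal(mean=mu, cov=cov).pdf(
        np.stack([xx, yy], axis=-1)
    )
    return x, y, density


def scaled_inverse_cdf(
    samples: np.ndarray | list[BlebStrainSample],
    scale: float = 1.0,
    attr: str = "Es_max",
    n_bins: int = 10,
) -> dict[str, pd.DataFrame | float]:
    """Scaled complementary empirical CDF of per-bleb strain values.

    The probability of finding a bleb with strain >= x, multiplied by
    ``scale`` (e.g. the fraction of dead cells that formed blebs).  Returns
    a dict with the tabulated step curve (columns ``strain``,
    ``probability``), a count-normalised histogram, and the sample mean.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be a probability in (0, 1]")
    if len(samples) == 0:
        raise ValueError("at least one bleb sample is required")
    if isinstance(samples[0], BlebStrainSample):
        values = np.array([getattr(s, attr) for s in samples], dtype=float)
    else:
        values = np.asarray(samples, dtype=float)
    order = np.sort(values)
    n = len(order)
    uniq, first_idx = np.unique(order, return_index=True)
    # P(X >= x) evaluated at each unique value
    ccdf = scale * (n - first_idx) / n
    curve = pd.DataFrame({"strain": uniq, "probability": ccdf})
    counts, edges = np.histogram(values, bins=n_bins)
    hist = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "fraction": counts / n,
        }
    )
    return {"curve": curve, "histogram": hist, "mean": float(values.mean())}


@dataclass(frozen=True)
class CohortSummary:
    """Per-rate-group injury prevalence table plus bleb fold change."""

    table: pd.DataFrame
    bleb_fold_change: float | None

    def __post_init__(self) -> None:
        if self.bleb_fold_change is not None and self.bleb_fold_change <= 0:
            raise ValueError("fold change must be positive")


def cohort_summary(
    records: list[InjuryRecord],
    viability_by_group: dict[str, float] | float = 1.0,
    fold_change_groups: tuple[str, str] | None = None,
) -> CohortSummary:
    """Death and bleb percentages per strain-rate group.

    Death percentage is (dead / total) / viability × 100, normalising by
    the control viability of age-matched unloaded cultures (capped at
    100).  The bleb percentage is taken among dead cells.  Fold change is
    the ratio of bleb percentages between the two groups given in
    ``fold_change_groups`` (higher-rate first) or, by default, between the
    two groups with the largest bleb percentages, reported to one decimal.
    """
    if not records:
        raise ValueError("no records")
    groups: dict[str, list[InjuryRecord]] = {}
    for r in records:
        groups.setdefault(r.rate_group, []).append(r)

    rows = []
    for g, recs in groups.items():
        viability = (
            viability_by_group.get(g, 1.0)
            if isinstance(viability_by_group, dict)
            else viability_by_group
        )
        if not 0 < viability <= 1:
            raise ValueError(f"viability for group {g!r} must be in (0, 1]")
        dead = [r for r in recs if r.died]
        pct_death = min(100.0, len(dead) / len(recs) / viability * 100.0)
        pct_bleb = (
            100.0 * sum(r.bleb_formed for r in dead) / len(dead) if dead else np.nan
        )
        rows.append(
            {
                "rate_group": g,
                "n_cells": len(recs),
                "n_dead": len(dead),
                "pct_death": pct_death,
                "pct_bleb_of_dead": pct_bleb,
            }
        )
    table = pd.DataFrame(rows).set_index("rate_group")

    fold = None
    pb = table["pct_bleb_of_dead"].dropna()
    if fold_change_groups is not None:
        hi, lo = fold_change_groups
        if table.loc[lo, "pct_bleb_of_dead"] > 0:
            fold = round(
                table.loc[hi, "pct_bleb_of_dead"]
                / table.loc[lo, "pct_bleb_of_dead"],
                1,
            )
    elif len(pb) >= 2:
        top = pb.sort_values()
        if top.iloc[-2] > 0:
            fold = round(top.iloc[-1] / top.iloc[-2], 1)
    return CohortSummary(table=table, bleb_fold_change=fold)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test.

    Returns (t statistic, p).  Two zero-variance samples with equal means
    yield (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


class StrainDeathModel:
    """Robust bivariate model of cell-mean axial strain versus death time.

    Parameters
    ----------
    mean_Ec : array-like
        Per-cell mean compressive axial strain magnitudes (dimensionless).
    death_time_hr : array-like
        Matching times of cell death (hours).

    Cells that survived carry no death time and cannot enter the fit; use
    :meth:`from_records` or :meth:`from_dataframe` to filter a cohort.

    Examples
    --------
    >>> model = StrainDeathModel.from_dataframe(cohort_df)
    >>> res = model.fit(seed=7)
    >>> res.death_time_relation.predict(0.07)
    """

    def __init__(self, mean_Ec, death_time_hr) -> None:
        ec = np.asarray(mean_Ec, dtype=float)
        td = np.asarray(death_time_hr, dtype=float)
        if ec.shape != td.shape or ec.ndim != 1:
            raise ValueError("mean_Ec and death_time_hr must be equal-length 1D")
        if np.any(~np.isfinite(ec)) or np.any(~np.isfinite(td)):
            raise ValueError("model data must be finite (drop survivors first)")
        self.endog = np.column_stack([ec, td])  # (strain, time)
        self.nobs = len(ec)

    @classmethod
    def from_records(cls, records: list[InjuryRecord]) -> "StrainDeathModel":
        dead = [r for r in records if r.died]
        return cls(
            [r.mean_Ec for r in dead], [r.death_time_hr for r in dead]
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        strain_col: str = "mean_Ec",
        time_col: str = "death_time_hr",
    ) -> "StrainDeathModel":
        sub = df[[strain_col, time_col]].dropna()
        return cls(sub[strain_col].to_numpy(), sub[time_col].to_numpy())

    def fit(
        self,
        h_fraction: float | None = None,
        seed: int | None = 0,
        n_starts: int = 500,
        level: float = 0.95,
    ) -> "StrainDeathResults":
        """Fit by FAST-MCD and derive ellipse and death-time law."""
        mcd = fast_mcd(
            self.endog, h_fraction=h_fraction, seed=seed, n_starts=n_starts
        )
        return StrainDeathResults(self, mcd, level=level)


class StrainDeathResults:
    """Fit products of :class:`StrainDeathModel`.

    Attributes
    ----------
    mcd : MCDFit
        Robust location/scatter estimate.
    ellipse : ConfidenceEllipse
        Confidence isocontour of the fitted bivariate normal.
    death_time_relation : DeathTimeRelation
        Major-axis law t_d = s (c − ⟨E_c⟩).
    """

    def __init__(self, model: StrainDeathModel, mcd: MCDFit, level: float = 0.95):
        self.model = model
        self.mcd = mcd
        self.level = level
        self.ellipse = confidence_ellipse(mcd, level=level)
        self.death_time_relation = major_axis_relation(self.ellipse)

    @property
    def centroid_strain(self) -> float:
        return float(self.mcd.location[0])

    @property
    def centroid_time_hr(self) -> float:
        return float(self.mcd.location[1])

    @property
    def slope_mag(self) -> float:
        return self.death_time_relation.slope_mag

    @property
    def strain_intercept(self) -> float:
        return self.death_time_relation.strain_intercept

    def predict(self, mean_Ec) -> float | np.ndarray:
        """Predicted death time (hours) at given mean axial strain."""
        return self.death_time_relation.predict(mean_Ec)

    def density_grid(self, bounds=None, resolution: int = 200):
        return bivariate_density_grid(self.mcd, bounds, resolution)

    def inlier_fraction(self) -> float:
        """Fraction of the data inside the confidence ellipse."""
        return float(np.mean(self.ellipse.contains(self.model.endog)))

    def to_dict(self) -> dict:
        """JSON-serialisable fit report."""
        e = self.ellipse
        return {
            "n": int(self.mcd.n),
            "h": int(self.mcd.h),
            "seed": self.mcd.seed,
            "level": self.level,
            "centroid": {
                "mean_Ec": self.centroid_strain,
                "death_time_hr": self.centroid_time_hr,
            },
            "covariance": self.mcd.covariance.tolist(),
            "a1": e.a1.tolist(),
            "a2": e.a2.tolist(),
            "eccentricity": e.eccentricity,
            "eccentricity_standardized": e.eccentricity_standardized,
            "slope_hr_per_strain": self.slope_mag,
            "strain_intercept": self.strain_intercept,
        }

    def summary(self) -> str:
        """Human-readable fit summary table."""
        e = self.ellipse
        l1, l2 = e.axis_lengths()
        rel = self.death_time_relation
        lines = [
            "Strain–death-time robust bivariate fit (FAST-MCD)",
            "=" * 52,
            f"n obs                 {self.mcd.n:>10d}",
            f"h (subset size)       {self.mcd.h:>10d}",
            f"confidence level      {self.level:>10.2f}",
            "-" * 52,
            f"centroid <Ec>         {self.centroid_strain:>10.4f}",
            f"centroid t_d [hr]     {self.centroid_time_hr:>10.3f}",
            f"major half-axis a1    ({e.a1[0]:+.4f} strain, {e.a1[1]:+.3f} hr)"
            f"  |a1| = {l1:.3f}",
            f"minor half-axis a2    ({e.a2[0]:+.4f} strain, {e.a2[1]:+.3f} hr)"
            f"  |a2| = {l2:.3f}",
            f"eccentricity (raw)    {e.eccentricity:>10.3f}",
            f"eccentricity (std)    {e.eccentricity_standardized:>10.3f}",
            "-" * 52,
            "death-time law: t_d = s (c − <Ec>)",
            f"  slope s [hr/strain] {rel.slope_mag:>10.2f}",
            f"  intercept c         {rel.strain_intercept:>10.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, show_density: bool = False):
        """Scatter of the data with the confidence ellipse and major axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.model.endog
        ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.6, label="cells")
        boundary = self.ellipse.boundary()
        ax.plot(boundary[:, 0], boundary[:, 1], "g-", label=f"{self.level:.0%} ellipse")
        mu = self.ellipse.centroid
        ax.plot(*mu, "k+", markersize=10)
        span = np.linspace(-1, 1, 2)
        axis_line = mu + np.outer(span, self.ellipse.a1)
        ax.plot(axis_line[:, 0], axis_line[:, 1], "k--", lw=1, label="major axis")
        if show_density:
            x, y, dens = self.density_grid(resolution=100)
            ax.contour(x, y, dens.T, levels=6, alpha=0.4)
        ax.set_xlabel("mean compressive axial strain ⟨E_c⟩")
        ax.set_ylabel("time of cell death t_d [hr]")
        ax.legend(frameon=False)
        return ax
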