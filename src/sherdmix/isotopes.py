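"""Δ13C offsets and confidence-ellipse classification in (δ16:0, δ18:0) space.

Reference fats of each food class are summarised as a bivariate Gaussian
population-coverage ellipse: the density contour whose squared
Mahalanobis radius is the χ²(2 df) quantile at the chosen level (0.68 by
default). A sherd belongs to every class whose ellipse contains its
(δ13C_16:0, δ13C_18:0) point — overlap between classes is real and is
reported, not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import SherdRecord, ValidationError


class DegenerateInputError(ValueError):
    """Raised when ellipse fitting receives too few or collinear points."""


def delta_offset(d18: float | None, d16: float | None) -> float | None:
    """Δ13C_18:0–16:0 = δ13C_18:0 − δ13C_16:0 (‰); None if either is absent."""
    if d18 is None or d16 is None:
        return None
    return d18 - d16


@dataclass
class EllipseModel:
    """Bivariate Gaussian coverage ellipse of one reference class."""

    class_name: str
    center: np.ndarray
    covariance: np.ndarray
    level: float
    radius2: float = field(init=False)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        cov = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValidationError(f"{self.class_name}: covariance not symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if np.min(eigvals) <= 1e-12 * max(1.0, np.max(eigvals)):
            raise DegenerateInputError(
                f"{self.class_name}: covariance is singular (collinear points?)"
            )
        self.covariance = cov
        if not (0 < self.level < 1):
            raise ValidationError(f"{self.class_name}: level must be in (0, 1)")
        self.radius2 = float(stats.chi2.ppf(self.level, df=2))

    def mahalanobis2(self, point) -> float:
        d = np.asarray(point, dtype=float).reshape(2) - self.center
        return float(d @ np.linalg.solve(self.covariance, d))


def fit_confidence_ellipse(points, level: float = 0.68, class_name: str = "") -> EllipseModel:
    """Fit the coverage ellipse of a reference class from its scatter points.

    Centre is the sample mean, covariance the unbiased sample covariance;
    fewer than 3 points or a singular covariance raise
    :class:`DegenerateInputError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise DegenerateInputError(
            f"{class_name or 'ellipse'}: need >= 3 points, got {pts.shape[0]}"
        )
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    return EllipseModel(class_name=class_name, center=center, covariance=cov, level=level)


def ellipse_contains(ellipse: EllipseModel, point) -> bool:
    """Boundary-inclusive membership by squared Mahalanobis distance."""
    m2 = ellipse.mahalanobis2(point)
    return m2 <= ellipse.radius2 * (1.0 + 1e-12) + 1e-12


def fit_reference_ellipses(
    reference_points: pd.DataFrame, level: float = 0.68, suess_correction: float = 0.0
) -> dict[str, EllipseModel]:
    """Fit one ellipse per class from a reference-points table.

    ``suess_correction`` (‰) is added to both δ axes of every reference
    point before fitting, to shift modern reference fats for the
    fossil-fuel depletion of atmospheric δ13C when comparing with
    archaeological samples (default 0: raw modern values).
    """
    ellipses: dict[str, EllipseModel] = {}
    for name, group in reference_points.groupby("class", sort=True):
        pts = group[["d13c_16_0", "d13c_18_0"]].to_numpy(dtype=float) + suess_correction
        ellipses[str(name)] = fit_confidence_ellipse(pts, level=level, class_name=str(name))
    return ellipses


def classify_against_references(
    record: SherdRecord, ellipses: dict[str, EllipseModel]
) -> set[str] | None:
    """All reference classes whose ellipse contains the sherd's (δ16:0, δ18:0).

    Returns None when either proxy is missing; an empty set means the point
    lies outside every reference region; several names mean genuine overlap.
    """
    d16 = record.proxy_value("C16:0")
    d18 = record.proxy_value("C18:0")
    if d16 is None or d18 is None:
        return None
    point = (d16, d18)
    return {name for name, e in ellipses.items() if ellipse_contains(e, point)}
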