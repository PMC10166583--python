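"""Isotype background correction of imputed marker signals.

An isotype control is an antibody of the same class as a marker antibody but
with no specific target, so its imputed signal estimates the nonspecific
(Fc-receptor / stickiness) background shared by markers of that class. For
each marker m assigned an isotype column iso, an ordinary least-squares fit

    m = alpha + beta * iso + eps

is made across pooled events; the corrected value is ``m - max(beta, 0) * iso``.
The intercept is retained so the marker's location is preserved, and the
slope is clamped at zero — an isotype cannot remove negative background.
Unassigned markers pass through bitwise-untouched. Correction operates on
the regression (transformed) scale, where imputation happened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["IsotypeAssignment", "BackgroundFit", "correct_background"]


@dataclass(frozen=True)
class IsotypeAssignment:
    """Pairs a marker with the isotype-control column of its class."""

    marker_name: str
    isotype_marker_name: str
    group: str = ""


@dataclass
class BackgroundFit:
    """OLS fit report for one marker's background correction."""

    marker_name: str
    isotype_marker_name: str
    alpha: float
    beta: float  # clamped slope actually subtracted
    beta_raw: float  # unclamped OLS slope
    r_squared: float
    clamped: bool
    skipped: bool = False


def correct_background(
    imputed: np.ndarray,
    marker_names: list[str],
    assignments: list[IsotypeAssignment],
) -> tuple[np.ndarray, list[BackgroundFit]]:
    """Subtract fitted isotype background from assigned markers.

    Parameters
    ----------
    imputed
        Events x markers matrix on the regression scale.
    marker_names
        Column names of ``imputed``.
    assignments
        Marker -> isotype column pairings (markers sharing an isotype group
        all point at that group's control column).

    Returns
    -------
    corrected, fits
        A copy of ``imputed`` with assigned markers corrected, and one
        :class:`BackgroundFit` per assignment.
    """
    X = np.asarray(imputed, dtype=np.float64)
    if X.shape[0] < 10:
        raise ValueError(f"need at least 10 events for background fits, got {X.shape[0]}")
    if X.shape[1] != len(marker_names):
        raise ValueError("marker_names length must match imputed columns")
    col = {n: i for i, n in enumerate(marker_names)}
    corrected = X.copy()
    fits: list[BackgroundFit] = []
    for a in assignments:
        for needed in (a.marker_name, a.isotype_marker_name):
            if needed not in col:
                raise KeyError(
                    f"background correction: column {needed!r} not found "
                    f"(have {marker_names})"
                )
        m = X[:, col[a.marker_name]]
        iso = X[:, col[a.isotype_marker_name]]
        if np.ptp(iso) == 0:
            warnings.warn(
                f"isotype column {a.isotype_marker_name!r} has zero variance; "
                f"skipping correction of {a.marker_name!r}",
                stacklevel=2,
            )
            fits.append(
                BackgroundFit(a.marker_name, a.isotype_marker_name,
                              alpha=float(m.mean()), beta=0.0, beta_raw=0.0,
                              r_squared=0.0, clamped=False, skipped=True)
            )
            continue
        res = stats.linregress(iso, m)
        beta = float(res.slope)
        clamped = beta < 0
        if clamped:
            warnings.warn(
                f"negative isotype slope {beta:.3g} for {a.marker_name!r} "
                "clamped to 0",
                stacklevel=2,
            )
        beta_used = max(beta, 0.0)
        corrected[:, col[a.marker_name]] = m - beta_used * iso
        fits.append(
            BackgroundFit(
                a.marker_name,
                a.isotype_marker_name,
                alpha=float(res.intercept),
                beta=beta_used,
                beta_raw=beta,
                r_squared=float(res.rvalue**2),
                clamped=clamped,
            )
        )
    return corrected, fits
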