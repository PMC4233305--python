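"""Apical-ballooning quantification.

The A:B index is the ratio of the maximal mean endocardial radius over
a band of apical slices to the minimal mean endocardial radius over a
band of basal slices, evaluated at end systole (minimum cavity volume):

    A:B = max_{apical slices} r_e / min_{basal slices} r_e

In the slice surrogate every cross-section is a circle, so the mean
endocardial distance to the cavity centre is the slice radius itself.
An index of at least 1.3 is deemed significant apical ballooning;
typical human imaging of the syndrome gives roughly 1.35-2.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ventricle import CycleResult

__all__ = [
    "AB_SIGNIFICANT",
    "BallooningResult",
    "ab_index",
    "ejection_fraction",
    "ab_timecourse",
    "band_slice_sets",
    "select_results",
]

#: Significance threshold on the end-systolic A:B index.
AB_SIGNIFICANT = 1.3

#: Default apex-base coordinate bands defining the apical and basal
#: slice sets (the apical cap and the valve-plane slice are excluded).
APICAL_BAND = (0.1, 0.4)
BASAL_BAND = (0.7, 0.95)


@dataclass(frozen=True)
class BallooningResult:
    """A:B summary of one beat."""

    ab_end_systole: float
    ab_peak: float  # max over ejection onset .. end systole
    ab_series: np.ndarray = field(repr=False)
    ef: float  # percent
    significant: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "significant", bool(self.ab_end_systole >= AB_SIGNIFICANT)
        )


def ab_index(r_e, apical_set, basal_set) -> float:
    """Apical-to-basal radius ratio at one instant.

    Parameters
    ----------
    r_e:
        Mean endocardial radius per slice.
    apical_set, basal_set:
        Disjoint, non-empty slice index collections.
    """
    r_e = np.asarray(r_e, dtype=float)
    apical = list(apical_set)
    basal = list(basal_set)
    if not apical or not basal:
        raise ValueError("apical and basal slice sets must be non-empty")
    if set(apical) & set(basal):
        raise ValueError("apical and basal slice sets must be disjoint")
    return float(np.max(r_e[apical]) / np.min(r_e[basal]))


def ejection_fraction(edv: float, esv: float) -> float:
    """Ejection fraction in percent: ``100 (EDV - ESV) / EDV``."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    if not 0 <= esv <= edv:
        raise ValueError("ESV must lie in [0, EDV]")
    return 100.0 * (edv - esv) / edv


def band_slice_sets(
    slice_z,
    apical_band: tuple[float, float] = APICAL_BAND,
    basal_band: tuple[float, float] = BASAL_BAND,
) -> tuple[list[int], list[int]]:
    """Slice index sets whose z coordinates fall in the two bands."""
    z = np.asarray(slice_z, dtype=float)
    apical = [int(j) for j in np.nonzero((z >= apical_band[0]) & (z <= apical_band[1]))[0]]
    basal = [int(j) for j in np.nonzero((z >= basal_band[0]) & (z <= basal_band[1]))[0]]
    return apical, basal


def ab_timecourse(
    result: CycleResult,
    apical_set=None,
    basal_set=None,
) -> BallooningResult:
    """A:B at every stored instant, its end-systolic value and its peak
    between ejection onset and end systole."""
    if apical_set is None or basal_set is None:
        default_ap, default_ba = band_slice_sets(result.slice_z)
        apical_set = apical_set if apical_set is not None else default_ap
        basal_set = basal_set if basal_set is not None else default_ba
    apical = list(apical_set)
    basal = list(basal_set)
    series = np.max(result.r_i[:, apical], axis=1) / np.min(
        result.r_i[:, basal], axis=1
    )
    i_es = int(np.argmin(result.volume))
    try:
        i_ej = result.phase.index("ejection")
    except ValueError:
        i_ej = i_es  # never ejected: peak window collapses to end systole
    i_lo, i_hi = min(i_ej, i_es), i_es
    ab_peak = float(np.max(series[i_lo : i_hi + 1]))
    return BallooningResult(
        ab_end_systole=float(series[i_es]),
        ab_peak=ab_peak,
        ab_series=series,
        ef=result.ef,
    )


def select_results(rows, ef_window: tuple[float, float] = (30.0, 60.0)):
    """Rows with EF inside the closed window, sorted by descending
    end-systolic A:B (ties broken by config id for stability).

    Accepts a pandas DataFrame with ``ef``, ``ab_end_systole`` and
    ``config_id`` columns and returns the filtered, sorted frame.
    """
    if len(rows) == 0:
        return rows
    lo, hi = ef_window
    mask = (rows["ef"] >= lo) & (rows["ef"] <= hi)
    out = rows.loc[mask].sort_values(
        ["ab_end_systole", "config_id"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
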