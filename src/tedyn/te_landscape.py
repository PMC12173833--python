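"""TE insertion-time landscapes.

Each annotated TE copy carries a percent divergence D from its family
consensus.  Correcting D for multiple hits gives K, and dividing by twice
the per-site substitution rate gives the copy's age:

    K = -(300/4) * ln(1 - 4 D / 300)      (percent scale)
    T = (K / 100) / (2 r)                 (million years, r in subs/site/My)

Binning total copy length by T per family yields the landscape whose peaks
mark historical insertion bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .io_formats import PhyloTree, TECopyRecord

__all__ = [
    "kimura_correct",
    "kimura_forward",
    "insertion_time",
    "substitution_rate",
    "build_landscape",
    "landscape_summary",
    "detect_burst_peaks",
    "dominant_families",
    "TELandscape",
    "LandscapeSummary",
]


def kimura_correct(D):
    """Multiple-hit-corrected divergence K (percent) from raw percent divergence D.

    K = -(300/4) * ln(1 - 4D/300).  Defined on 0 <= D < 75; K >= D and K is
    strictly increasing in D.
    """
    D = np.asarray(D, dtype=float)
    if np.any((D < 0) | (D >= 75)):
        raise ValueError("percent divergence must lie in [0, 75)")
    K = -75.0 * np.log1p(-D / 75.0)
    return K if K.ndim else float(K)


def kimura_forward(K):
    """Exact inverse of :func:`kimura_correct`: D = 75 (1 - exp(-K/75))."""
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("corrected divergence must be non-negative")
    D = 75.0 * -np.expm1(-K / 75.0)
    return D if D.ndim else float(D)


def insertion_time(K, r: float):
    """Insertion age T (My) from corrected divergence K (percent): T = (K/100)/(2r)."""
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("corrected divergence must be non-negative")
    T = (K / 100.0) / (2.0 * r)
    return T if T.ndim else float(T)


def age_from_divergence(D, r: float):
    """Convenience composition: raw percent divergence -> age in My."""
    return insertion_time(kimura_correct(D), r)


def substitution_rate(
    tree: PhyloTree, calibration_tip: str, divergence_time: float
) -> float:
    """Per-site per-My substitution rate from a calibrated root-to-tip path.

    ``r = (root-to-tip branch length of calibration_tip) / divergence_time``,
    with branch lengths in substitutions/site and the calibration in My.
    """
    if divergence_time <= 0:
        raise ValueError("divergence_time must be positive")
    path = tree.root_to_tip(calibration_tip)  # KeyError if absent
    if path == 0:
        warnings.warn(
            f"root-to-tip path for {calibration_tip!r} has zero length; r = 0",
            stacklevel=2,
        )
    return path / divergence_time


@dataclass
class TELandscape:
    """Per-family TE length binned by estimated insertion age.

    ``matrix`` is indexed by family name with one column per age bin;
    cells hold total copy length in bases.  ``bin_edges`` (My) has one
    more entry than there are columns.
    """

    species: str
    bin_edges: np.ndarray
    matrix: pd.DataFrame
    rate_r: float
    ages: np.ndarray = field(repr=False, default=None)
    lengths: np.ndarray = field(repr=False, default=None)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def total_profile(self) -> np.ndarray:
        """Total TE length per bin, summed over families (bases)."""
        return self.matrix.to_numpy().sum(axis=0)

    @property
    def total_mass(self) -> float:
        return float(self.matrix.to_numpy().sum())

    def to_mb(self) -> pd.DataFrame:
        return self.matrix / 1e6


@dataclass
class LandscapeSummary:
    window_fractions: dict[tuple[float, float], float]
    peak_intervals: list[tuple[float, float]]
    dominant_families: pd.DataFrame | None = None


def build_landscape(
    records: list[TECopyRecord],
    r: float,
    bin_width: float = 1.0,
    species: str = "",
    n_bins: int | None = None,
) -> TELandscape:
    """Date every copy and accumulate copy length into uniform age bins.

    The grand total of the landscape equals the summed copy length of the
    input records exactly (mass conservation).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not records:
        warnings.warn("no TE copies supplied; landscape is empty", stacklevel=2)
        edges = np.array([0.0, bin_width])
        return TELandscape(
            species, edges, pd.DataFrame(np.zeros((0, 1))), r,
            ages=np.array([]), lengths=np.array([]),
        )
    D = np.array([rec.perc_div for rec in records])
    lengths = np.array([rec.copy_length for rec in records], dtype=float)
    families = np.array([rec.family_name for rec in records])
    ages = age_from_divergence(D, r)
    if n_bins is None:
        n_bins = int(np.floor(ages.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((ages // bin_width).astype(int), n_bins - 1)
    fam_names = sorted(set(families))
    mat = np.zeros((len(fam_names), n_bins))
    fam_pos = {f: i for i, f in enumerate(fam_names)}
    np.add.at(mat, ([fam_pos[f] for f in families], idx), lengths)
    matrix = pd.DataFrame(mat, index=fam_names, columns=edges[:-1])
    return TELandscape(species, edges, matrix, r, ages=ages, lengths=lengths)


def landscape_summary(
    landscape: TELandscape,
    windows: list[tuple[float, float]] = ((10.0, 30.0), (0.0, 5.0)),
) -> LandscapeSummary:
    """Fractions of total TE length whose estimated age falls in each window.

    Windows are closed on both ends and evaluated on the per-copy point
    ages kept by :func:`build_landscape`, not on bin membership.
    """
    if landscape.ages is None or landscape.total_mass == 0:
        raise ValueError("landscape has no dated mass; fractions are undefined")
    total = landscape.lengths.sum()
    fractions = {}
    for lo, hi in windows:
        mask = (landscape.ages >= lo) & (landscape.ages <= hi)
        fractions[(lo, hi)] = float(landscape.lengths[mask].sum() / total)
    return LandscapeSummary(window_fractions=fractions, peak_intervals=[])


def detect_burst_peaks(
    landscape: TELandscape,
    smoothing_window: int = 3,
    min_prominence: float = 0.1,
) -> list[tuple[float, float]]:
    """Locate insertion-burst peaks in the total landscape profile.

    The profile is smoothed with a centred moving average, local maxima with
    prominence >= ``min_prominence`` of the global maximum are kept, and each
    peak is reported as the maximal contiguous run of bins at or above half
    its smoothed height, as a closed interval in My rounded to bin edges.
    Peaks are sorted by contained mass, descending.
    """
    y = landscape.total_profile.astype(float)
    if y.size < 3 or y.max() == 0:
        return []
    kernel = np.ones(smoothing_window) / smoothing_window
    smooth = np.convolve(y, kernel, mode="same")
    # pad so maxima at the array ends are detectable
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = _signal.find_peaks(padded, prominence=min_prominence * smooth.max())
    peaks = peaks - 1
    intervals: list[tuple[float, float, float]] = []
    for p in peaks:
        half = smooth[p] / 2.0
        lo = p
        while lo > 0 and smooth[lo - 1] >= half:
            lo -= 1
        hi = p
        while hi < len(smooth) - 1 and smooth[hi + 1] >= half:
            hi += 1
        start = float(landscape.bin_edges[lo])
        end = float(landscape.bin_edges[hi + 1])
        mass = float(y[lo : hi + 1].sum())
        intervals.append((start, end, mass))
    # merge duplicates (two maxima can share a half-height run)
    seen: dict[tuple[float, float], float] = {}
    for start, end, mass in intervals:
        seen[(start, end)] = max(seen.get((start, end), 0.0), mass)
    ordered = sorted(seen.items(), key=lambda kv: -kv[1])
    return [iv for iv, _ in ordered]


def dominant_families(
    records: list[TECopyRecord], threshold: float = 0.50
) -> pd.DataFrame:
    """Minimal set of classified TE families covering > ``threshold`` of
    classified TE length.

    Families are ranked by total copy length (descending, ``Unknown`` class
    excluded from both numerator and denominator); the returned frame holds
    the shortest prefix whose cumulative share exceeds the threshold, with
    ties at the boundary all included.
    """
    classified = [r for r in records if r.te_class != "Unknown"]
    if not classified:
        raise ValueError("no classified (non-Unknown) TE families present")
    lengths = pd.Series(
        [r.copy_length for r in classified],
        index=[r.family_name for r in classified],
        dtype=float,
    )
    totals = lengths.groupby(level=0).sum().sort_values(ascending=False)
    share = totals / totals.sum()
    cum = share.cumsum()
    n_keep = int(np.searchsorted(cum.to_numpy(), threshold, side="left")) + 1
    n_keep = min(n_keep, len(cum))
    # include families tied with the last kept one
    last_total = totals.iloc[n_keep - 1]
    while n_keep < len(totals) and totals.iloc[n_keep] == last_total:
        n_keep += 1
    out = pd.DataFrame(
        {
            "family": totals.index[:n_keep],
            "total_length": totals.to_numpy()[:n_keep],
            "share": share.to_numpy()[:n_keep],
            "cumulative_share": cum.to_numpy()[:n_keep],
        }
    )
    return out
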