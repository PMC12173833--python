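"""Interval analytics: TE proximity to gene sets, TE/CRM overlap
configuration classification, and genome-window density profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from .io_formats import IntervalRecord, intervals_to_frame

__all__ = [
    "OverlapReport",
    "te_near_genes",
    "normalize_te_length",
    "classify_overlap",
    "overlap_report",
    "window_density",
]

CONFIGURATIONS = ("te_within_crm", "crm_within_te", "partial")


@dataclass
class OverlapReport:
    """Counts and percentages of TE/CRM overlap configurations.

    Percentages are over overlapping TEs (one configuration attributed per
    TE: containment beats partial, then leftmost CRM); ``pair_counts``
    additionally reports every overlapping pair.
    """

    counts: dict[str, int]
    percentages: dict[str, float]
    pair_counts: dict[str, int]
    n_te: int
    n_overlapping: int
    fraction_overlapping: float


def normalize_te_length(
    copy_length: float, consensus_length: float, cap: float | None = None
) -> float:
    """TE copy length as a percent of its family consensus length.

    May exceed 100 for tandem expansions; pass ``cap`` to clip.
    """
    if consensus_length <= 0:
        raise ValueError("consensus_length must be positive")
    pct = 100.0 * copy_length / consensus_length
    return min(pct, cap) if cap is not None else pct


def te_near_genes(
    te_intervals: list[IntervalRecord],
    gene_intervals: list[IntervalRecord],
    window: int = 1000,
    gene_categories: dict[str, str] | None = None,
    consensus_lengths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assign TEs to genes within ``window`` bp (boundary inclusive).

    A TE is assigned to every gene whose minimum gap to it is <= window
    (overlap counts as distance 0), so one TE may appear in several rows.
    Returns a frame with gene, te, distance, raw_length and, when lookup
    tables are given, the gene's selection category and the TE length as a
    percent of its family consensus.
    """
    if not te_intervals or not gene_intervals:
        return _empty_proximity_frame()
    te_scaf = {r.scaffold for r in te_intervals}
    gene_scaf = {r.scaffold for r in gene_intervals}
    if not te_scaf & gene_scaf:
        warnings.warn(
            "TE and gene files share no scaffolds; nothing can match",
            stacklevel=2,
        )
        return _empty_proximity_frame()
    tes = pr.PyRanges(intervals_to_frame(te_intervals))
    genes = pr.PyRanges(intervals_to_frame(gene_intervals))
    joined = tes.join(genes, slack=window + 1, suffix="_gene").df
    if joined.empty:
        return _empty_proximity_frame()
    gap = np.maximum(
        joined["Start_gene"] - joined["End"], joined["Start"] - joined["End_gene"]
    ).clip(lower=0)
    joined = joined.assign(distance=gap)
    joined = joined[joined["distance"] <= window]
    out = pd.DataFrame(
        {
            "gene": joined["Name_gene"].to_numpy(),
            "te": joined["Name"].to_numpy(),
            "distance": joined["distance"].to_numpy(),
            "raw_length": (joined["End"] - joined["Start"]).to_numpy(),
        }
    )
    if gene_categories is not None:
        out["category"] = out["gene"].map(gene_categories)
    if consensus_lengths is not None:
        out["normalized_length"] = [
            normalize_te_length(l, consensus_lengths[t])
            if t in consensus_lengths
            else np.nan
            for t, l in zip(out["te"], out["raw_length"])
        ]
    return out.sort_values(["gene", "te"], kind="stable").reset_index(drop=True)


def _empty_proximity_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene", "te", "distance", "raw_length"])


def classify_overlap(te: IntervalRecord, crm: IntervalRecord) -> str:
    """Configuration of a TE/CRM interval pair.

    ``te_within_crm`` if the CRM contains the TE (identical intervals
    included), ``crm_within_te`` for the reverse strict containment,
    ``partial`` for intersection without containment, else ``none``.
    """
    if te.scaffold != crm.scaffold:
        return "none"
    if crm.start <= te.start and te.end <= crm.end:
        return "te_within_crm"
    if te.start <= crm.start and crm.end <= te.end:
        return "crm_within_te"
    if te.start < crm.end and crm.start < te.end:
        return "partial"
    return "none"


def overlap_report(
    te_set: list[IntervalRecord], crm_set: list[IntervalRecord]
) -> OverlapReport:
    """Classify every TE against the CRM set.

    Each overlapping TE contributes one configuration (containment in
    either direction beats partial; ties broken by leftmost CRM, then by
    name); ``pair_counts`` tallies all overlapping pairs without the
    per-TE attribution.
    """
    if not te_set:
        raise ValueError("TE set is empty")
    counts = dict.fromkeys(CONFIGURATIONS, 0)
    pair_counts = dict.fromkeys(CONFIGURATIONS, 0)
    n_overlapping = 0
    rank = {"te_within_crm": 0, "crm_within_te": 0, "partial": 1}
    for te in te_set:
        hits = []
        for crm in crm_set:
            config = classify_overlap(te, crm)
            if config != "none":
                hits.append((config, crm))
                pair_counts[config] += 1
        if not hits:
            continue
        n_overlapping += 1
        best = min(
            hits, key=lambda h: (rank[h[0]], h[1].start, h[1].end, h[1].name)
        )
        counts[best[0]] += 1
    percentages = {
        c: (100.0 * counts[c] / n_overlapping if n_overlapping else 0.0)
        for c in CONFIGURATIONS
    }
    return OverlapReport(
        counts=counts,
        percentages=percentages,
        pair_counts=pair_counts,
        n_te=len(te_set),
        n_overlapping=n_overlapping,
        fraction_overlapping=n_overlapping / len(te_set),
    )


def window_density(
    track_a: list[IntervalRecord],
    track_b: list[IntervalRecord] | None,
    scaffold_lengths: dict[str, int],
    window_size: int,
) -> tuple[pd.DataFrame, float | None]:
    """Midpoint counts of two interval tracks in non-overlapping windows.

    Returns the per-window frame (scaffold, window start, count_a,
    count_b) over every declared scaffold, and the Spearman rank
    correlation between the tracks (None when fewer than three windows or
    a single track).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    for rec in (track_a or []) + (track_b or []):
        if rec.scaffold not in scaffold_lengths:
            raise ValueError(f"interval on undeclared scaffold {rec.scaffold!r}")
        if rec.end > scaffold_lengths[rec.scaffold]:
            raise ValueError(
                f"interval {rec.scaffold}:[{rec.start},{rec.end}) beyond "
                f"declared scaffold length {scaffold_lengths[rec.scaffold]}"
            )
    frames = []
    for scaffold, length in scaffold_lengths.items():
        n_win = int(np.ceil(length / window_size))
        counts = {}
        for key, track in (("count_a", track_a), ("count_b", track_b)):
            c = np.zeros(n_win, dtype=int)
            for rec in track or []:
                if rec.scaffold == scaffold:
                    c[min(int(rec.midpoint // window_size), n_win - 1)] += 1
            counts[key] = c
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "window_start": np.arange(n_win) * window_size,
                    **counts,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    rho = None
    if track_b is not None and len(table) >= 3:
        if table["count_a"].nunique() > 1 and table["count_b"].nunique() > 1:
            rho = float(stats.spearmanr(table["count_a"], table["count_b"])[0])
    return table, rho
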