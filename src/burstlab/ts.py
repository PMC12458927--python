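"""Transcription-site calling, burst-size estimation and population summaries.

A transcription site (TS) is a nuclear intron spot colocalized with a
nuclear exon spot of the same cell within a Euclidean distance of 5 px
(nascent transcripts retain introns, so an intron focus marks the site of
active transcription; the exon signal there measures the nascent RNA load).
Burst size at a TS is its exon intensity divided by the median intensity of
that cell's cytoplasmic exon spots — single mRNAs that calibrate the
single-molecule intensity — and is only defined for cells with at least 5
such spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptionSite",
    "call_transcription_sites",
    "burst_size",
    "cell_summaries",
    "population_summaries",
    "MIN_CYTO_SPOTS",
    "MAX_PAIR_DIST",
]

MAX_PAIR_DIST = 5.0  # px, inclusive
MIN_CYTO_SPOTS = 5  # cytoplasmic exon spots required for burst-size calibration


@dataclass
class TranscriptionSite:
    """A matched intron-exon nuclear spot pair.

    Position is the intron spot's (it marks the nascent RNA); intensity is
    the exon member's.  ``nascent_count`` is filled by :func:`burst_size`.
    """

    cell_id: int
    x: float
    y: float
    exon_intensity: float
    pair_distance: float
    intron_intensity: float
    nascent_count: float | None = None


def _require_assigned(spots: pd.DataFrame):
    for col in ("cell_id", "compartment"):
        if col not in spots.columns:
            raise ValueError(f"spot table lacks {col!r}; run compartment assignment first")


def call_transcription_sites(
    spots: pd.DataFrame, max_dist: float = MAX_PAIR_DIST
) -> list[TranscriptionSite]:
    """Match nuclear intron and exon spots into transcription sites.

    Within each cell, candidate pairs are all (intron, exon) nuclear spot
    pairs at Euclidean distance <= ``max_dist``; pairs are accepted greedily
    in order of increasing distance, each spot used at most once.  Exact
    distance ties are broken by higher intron intensity, then input order.
    The matching is symmetric in the two channels.
    """
    if len(spots) == 0:
        return []
    _require_assigned(spots)
    nuclear = spots[(spots["compartment"] == "nuclear") & (spots["cell_id"].astype(float) > 0)]
    sites: list[TranscriptionSite] = []
    for cell_id, sub in nuclear.groupby("cell_id"):
        introns = sub[sub["channel"] == "intron"].reset_index(drop=True)
        exons = sub[sub["channel"] == "exon"].reset_index(drop=True)
        if len(introns) == 0 or len(exons) == 0:
            continue
        pairs = []
        for i, irow in introns.iterrows():
            for j, erow in exons.iterrows():
                d = float(np.hypot(irow["x"] - erow["x"], irow["y"] - erow["y"]))
                if d <= max_dist:
                    pairs.append((d, -float(irow["intensity"]), i, j))
        pairs.sort()
        used_i, used_j = set(), set()
        for d, neg_int, i, j in pairs:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            irow, erow = introns.loc[i], exons.loc[j]
            sites.append(
                TranscriptionSite(
                    cell_id=int(cell_id),
                    x=float(irow["x"]),
                    y=float(irow["y"]),
                    exon_intensity=float(erow["intensity"]),
                    pair_distance=d,
                    intron_intensity=float(irow["intensity"]),
                )
            )
    sites.sort(key=lambda s: (s.cell_id, s.x, s.y))
    return sites


def _cyto_median_by_cell(spots: pd.DataFrame) -> dict[int, tuple[int, float]]:
    """Per cell: (count, median intensity) of cytoplasmic exon spots."""
    cyto = spots[(spots["channel"] == "exon") & (spots["compartment"] == "cytoplasmic")]
    out = {}
    for cell_id, sub in cyto.groupby("cell_id"):
        vals = sub["intensity"].to_numpy(dtype=float)
        out[int(cell_id)] = (len(vals), float(np.median(vals)))
    return out


def burst_size(
    sites: list[TranscriptionSite],
    spots: pd.DataFrame,
    min_cyto_spots: int = MIN_CYTO_SPOTS,
) -> list[TranscriptionSite]:
    """Fill ``nascent_count`` on each TS by single-molecule normalization.

    nascent_count = exon intensity of the TS / median intensity of the same
    cell's cytoplasmic exon spots.  Cells with fewer than ``min_cyto_spots``
    cytoplasmic exon spots give ``nascent_count = None`` (undefined, never
    zero): too few single molecules to calibrate the denominator.
    """
    _require_assigned(spots)
    calib = _cyto_median_by_cell(spots)
    for ts in sites:
        n, med = calib.get(ts.cell_id, (0, np.nan))
        ts.nascent_count = ts.exon_intensity / med if n >= min_cyto_spots else None
    return sites


def cell_summaries(
    spots: pd.DataFrame,
    sites: list[TranscriptionSite],
    min_cyto_spots: int = MIN_CYTO_SPOTS,
) -> pd.DataFrame:
    """Per-cell table: TS count, cytoplasmic spot count, transcribing flag, burst sizes.

    Every cell present in the spot table (cell_id > 0) is summarized, also
    cells without any TS.  ``burst_sizes`` is a list of nascent counts or
    None when the cell fails the calibration filter.
    """
    _require_assigned(spots)
    cells = sorted(
        {int(c) for c in spots["cell_id"].dropna().astype(int) if c > 0}
        | {ts.cell_id for ts in sites}
    )
    calib = _cyto_median_by_cell(spots)
    by_cell: dict[int, list] = {c: [] for c in cells}
    for ts in sites:
        by_cell[ts.cell_id].append(ts)
    rows = []
    for c in cells:
        n_cyto = calib.get(c, (0, np.nan))[0]
        ts_list = by_cell[c]
        eligible = n_cyto >= min_cyto_spots
        bursts = [t.nascent_count for t in ts_list if t.nascent_count is not None] if eligible else None
        rows.append(
            {
                "cell_id": c,
                "n_ts": len(ts_list),
                "n_cyto_exon": n_cyto,
                "transcribing": len(ts_list) >= 1,
                "burst_sizes": bursts,
            }
        )
    return pd.DataFrame(rows)


def population_summaries(cells: pd.DataFrame, max_ts_bin: int = 5) -> dict:
    """Population-level observables from a per-cell summary table.

    Returns percent_transcribing (0-100), the TS-per-cell histogram as
    fractions over bins 0, 1, ..., max_ts_bin-1 and "max_ts_bin+" (sums to
    1), pooled burst sizes with their median, and per-cell burst-size
    medians.
    """
    if len(cells) == 0:
        raise ValueError("no cells: percent transcribing is undefined")
    n = len(cells)
    n_trans = int(cells["transcribing"].sum())
    counts = cells["n_ts"].to_numpy(dtype=int)
    hist = {}
    for b in range(max_ts_bin):
        hist[str(b)] = float(np.mean(counts == b))
    hist[f"{max_ts_bin}+"] = float(np.mean(counts >= max_ts_bin))
    pooled = []
    per_cell_medians = []
    for bs in cells["burst_sizes"]:
        if bs:
            pooled.extend(bs)
            per_cell_medians.append(float(np.median(bs)))
    return {
        "n_cells": n,
        "percent_transcribing": 100.0 * n_trans / n,
        "ts_count_histogram": hist,
        "burst_sizes": pooled,
        "median_burst_size": float(np.median(pooled)) if pooled else None,
        "per_cell_median_burst_size": per_cell_medians,
    }
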