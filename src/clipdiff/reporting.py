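"""Region merging and UCSC-ready output files.

Adjacent bins decoded to the same state are concatenated into continuous
state regions within each cluster (never across clusters). Outputs per
run: a BED6 file of state regions, a per-bin TSV with every intermediate
quantity, and exactly eight bedGraph tracks — {total, mutant} tag counts x
{condition 1, 2} x {+, -} strand — all in 0-based half-open UCSC
coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import Tracks

REGION_COLUMNS = [
    "cluster_id", "chrom", "strand", "start", "end", "state",
    "n_bins", "mean_x1", "mean_x2", "mean_m_adj",
]

TXT_COLUMNS = [
    "cluster_id", "bin_index", "chrom", "start", "end", "strand",
    "x1", "x2", "m1", "m2", "M_raw", "A", "M_adj", "state",
]


def merge_state_runs(bins: pd.DataFrame) -> pd.DataFrame:
    """Merge maximal same-state runs of adjacent bins into regions.

    ``bins`` must carry a ``state`` column and be ordered by
    (cluster_id, bin_index). Region coordinates run from the first member
    bin's start to the last member's end; summary columns average over
    member bins. Runs never cross cluster boundaries, so regions tile each
    cluster and adjacent regions within a cluster differ in state.
    """
    if "state" not in bins:
        raise ValueError("bins must be decoded (state column) before merging")
    rows = []
    for _, grp in bins.groupby("cluster_id", sort=True):
        states = grp["state"].to_numpy()
        breaks = np.flatnonzero(np.diff(states) != 0) + 1
        for lo, hi in zip(np.concatenate(([0], breaks)),
                          np.concatenate((breaks, [len(grp)]))):
            run = grp.iloc[lo:hi]
            rows.append((
                run["cluster_id"].iat[0], run["chrom"].iat[0], run["strand"].iat[0],
                int(run["start"].iat[0]), int(run["end"].iat[-1]), int(states[lo]),
                int(hi - lo), float(run["x1"].mean()), float(run["x2"].mean()),
                float(run["M_adj"].mean()),
            ))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def filter_regions(regions: pd.DataFrame, state: int,
                   min_mean_intensity: float, which_condition: int) -> pd.DataFrame:
    """Screen regions: keep those in ``state`` whose mean tag intensity in
    the designated condition is at least ``min_mean_intensity``.

    This supports screens such as "regions with stronger binding and an
    average tag intensity of at least 30 in condition 1".
    """
    if which_condition not in (1, 2):
        raise ValueError("which_condition must be 1 or 2")
    col = "mean_x1" if which_condition == 1 else "mean_x2"
    mask = (regions["state"] == state) & (regions[col] >= min_mean_intensity)
    return regions.loc[mask].reset_index(drop=True)


def _bed_score(mean_m_adj: float) -> int:
    return min(1000, int(round(200.0 * abs(mean_m_adj))))


def write_regions_bed(regions: pd.DataFrame, path: str) -> None:
    """BED6: name cluster<j>_state<s>, score 200*|mean adjusted M| capped
    at the UCSC limit of 1000."""
    with open(path, "w") as out:
        out.write('track name="state_regions" description="differential binding state regions"\n')
        for r in regions.itertuples(index=False):
            out.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tcluster{r.cluster_id}_state{r.state}\t"
                f"{_bed_score(r.mean_m_adj)}\t{r.strand}\n"
            )


def write_bins_txt(bins: pd.DataFrame, path: str) -> None:
    """Per-bin inference table, tab-separated with a header row."""
    bins.loc[:, TXT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def _track_runs(arr: np.ndarray):
    """Yield (start, end, value) runs of equal non-zero value."""
    if arr.size == 0:
        return
    edges = np.flatnonzero(np.diff(arr) != 0) + 1
    bounds = np.concatenate(([0], edges, [arr.size]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        v = arr[lo]
        if v != 0:
            yield int(lo), int(hi), int(v)


def write_bedgraph(tracks: Tracks, cond: int, strand: str, path: str, name: str) -> None:
    """One bedGraph: zero intervals omitted, equal-value runs merged,
    UCSC track line included."""
    with open(path, "w") as out:
        out.write(f'track type=bedGraph name="{name}"\n')
        chroms = sorted(c for (c, s, k) in tracks if s == strand and k == cond)
        for chrom in chroms:
            for lo, hi, v in _track_runs(tracks[(chrom, strand, cond)]):
                out.write(f"{chrom}\t{lo}\t{hi}\t{v}\n")


def write_outputs(
    regions: pd.DataFrame,
    bins: pd.DataFrame,
    total_tracks: Tracks,
    mutant_tracks: Tracks,
    out_prefix: str,
) -> list[str]:
    """Write the full output file set; returns the paths written.

    Files: <prefix>.regions.bed, <prefix>.bins.txt and the eight
    <prefix>.{total,mutant}.cond{1,2}.{plus,minus}.bedGraph tracks. For
    iCLIP runs the mutant tracks are valid but contain no intervals.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    bed = f"{prefix}.regions.bed"
    write_regions_bed(regions, bed)
    paths.append(bed)
    txt = f"{prefix}.bins.txt"
    write_bins_txt(bins, txt)
    paths.append(txt)
    for kind, tracks in (("total", total_tracks), ("mutant", mutant_tracks)):
        for cond in (1, 2):
            for strand, sname in (("+", "plus"), ("-", "minus")):
                path = f"{prefix}.{kind}.cond{cond}.{sname}.bedGraph"
                write_bedgraph(tracks, cond, strand, path,
                               name=f"{kind}_cond{cond}_{sname}")
                paths.append(path)
    return paths
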