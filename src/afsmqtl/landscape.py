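"""Methylation landscape statistics: metaprofiles, bin levels, context proportions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import FULL_CMCGG, FULL_MCCGG, HEMI, METHYLATED_STATES
from .core import GeneModel, logger


@dataclass
class BinMethylationLevel:
    """Read-weighted methylation level of a genomic bin.

    numerator   = sum over methylated CCGG sites of reads from methylated
                  fragments; denominator = sum over all CCGG sites of all
    reads.  ``level`` is None when the bin has no covered sites.
    """

    scaffold: str
    start: int
    end: int
    numerator: float
    denominator: float

    @property
    def level(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator


def methylation_level(
    scaffold: str,
    start: int,
    end: int,
    positions: Sequence[int],
    methylated: Sequence[bool],
    reads_methylated: Sequence[int],
    reads_total: Sequence[int],
) -> BinMethylationLevel:
    """Methylation level of one bin from per-site read tallies.

    ``positions`` are CCGG site coordinates; sites outside [start, end)
    are ignored.  ``reads_methylated`` counts reads from methylated
    fragments at each site, ``reads_total`` all reads at the site.
    """
    if end <= start:
        raise ValueError("bin must be non-empty")
    pos = np.asarray(positions)
    meth = np.asarray(methylated, dtype=bool)
    rm = np.asarray(reads_methylated, dtype=float)
    rt = np.asarray(reads_total, dtype=float)
    inside = (pos >= start) & (pos < end)
    num = float(rm[inside & meth].sum())
    den = float(rt[inside].sum())
    return BinMethylationLevel(scaffold, start, end, num, den)


@dataclass
class MetaProfile:
    """Windowed average-depth profile over a set of regions (5'->3')."""

    n_windows: int
    values: np.ndarray
    region_set: str = "gene_body_with_flanks"
    n_regions: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_windows:
            raise ValueError("values length must equal n_windows")


def _window_means(depth: np.ndarray, n_windows: int) -> np.ndarray:
    """Split an interval's depth vector into n equal windows of mean depth."""
    edges = np.linspace(0, len(depth), n_windows + 1)
    out = np.empty(n_windows)
    for i in range(n_windows):
        lo, hi = int(round(edges[i])), int(round(edges[i + 1]))
        out[i] = depth[lo:hi].mean() if hi > lo else np.nan
    return out


def metaprofile(
    regions: Sequence[GeneModel],
    depth: Mapping[str, np.ndarray],
    n_windows: int = 80,
    flank: int = 2000,
    region_set: str = "gene_body_with_flanks",
) -> MetaProfile:
    """Average depth metaprofile across gene bodies with flanks.

    Each region contributes ``n_windows`` window means: when ``flank > 0``
    a quarter of the windows cover each flank at fixed width and the
    remaining half cover the body proportionally; with ``flank = 0`` all
    windows divide the body equally.  Minus-strand regions are reversed
    so the profile always reads 5'->3'.  Regions whose body is shorter
    than its window count are skipped with a warning.  Windows that fall
    off a scaffold edge are ignored in the cross-region average.
    """
    if flank > 0:
        n_flank = n_windows // 4
        n_body = n_windows - 2 * n_flank
    else:
        n_flank = 0
        n_body = n_windows

    profiles = []
    for g in regions:
        d = depth.get(g.scaffold_id)
        if d is None:
            logger.warning("no depth for scaffold %s; region %s skipped",
                           g.scaffold_id, g.gene_id)
            continue
        if g.end - g.start < n_body:
            logger.warning("region %s shorter than %d windows; skipped",
                           g.gene_id, n_body)
            continue
        body = _window_means(np.asarray(d[g.start : g.end], dtype=float), n_body)
        if n_flank > 0:
            up_lo = g.start - flank
            up = np.full(n_flank, np.nan)
            if up_lo >= 0:
                up = _window_means(np.asarray(d[up_lo : g.start], dtype=float), n_flank)
            down = np.full(n_flank, np.nan)
            if g.end + flank <= len(d):
                down = _window_means(
                    np.asarray(d[g.end : g.end + flank], dtype=float), n_flank
                )
            prof = np.concatenate([up, body, down])
        else:
            prof = body
        if g.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)

    if not profiles:
        return MetaProfile(n_windows, np.full(n_windows, np.nan), region_set, 0)
    stacked = np.vstack(profiles)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return MetaProfile(n_windows, mean, region_set, len(profiles))


def depth_from_calls(
    calls: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    states: frozenset[str] = METHYLATED_STATES,
) -> dict[str, np.ndarray]:
    """Per-base depth tracks counting calls in ``states`` at each CCGG position."""
    depth = {s: np.zeros(n, dtype=float) for s, n in scaffold_lengths.items()}
    sel = calls[calls["state"].isin(states)]
    for scaf, group in sel.groupby("scaffold"):
        if scaf not in depth:
            continue
        np.add.at(depth[scaf], group["position"].to_numpy(), 1.0)
    return depth


def context_proportions(
    calls: pd.DataFrame,
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Proportions of the three methylated states among methylated calls.

    Returns a frame indexed by region scope ("all", and "genic" when gene
    models are given — sites in gene bodies or 2-kb promoters) with
    columns full_CmCGG, hemi_mCCGG, full_mCCGG summing to 1.
    """
    meth = calls[calls["state"].isin(METHYLATED_STATES)]
    if meth.empty:
        raise ValueError("no methylated calls")

    def _props(df: pd.DataFrame) -> dict[str, float]:
        n = len(df)
        return {
            FULL_CMCGG: (df["state"] == FULL_CMCGG).sum() / n,
            HEMI: (df["state"] == HEMI).sum() / n,
            FULL_MCCGG: (df["state"] == FULL_MCCGG).sum() / n,
        }

    rows = {"all": _props(meth)}
    if genes is not None:
        mask = np.zeros(len(meth), dtype=bool)
        pos = meth["position"].to_numpy()
        scaf = meth["scaffold"].to_numpy()
        for g in genes:
            p_lo, p_hi = g.promoter
            in_gene = (scaf == g.scaffold_id) & (
                ((pos >= g.start) & (pos < g.end)) | ((pos >= p_lo) & (pos < p_hi))
            )
            mask |= in_gene
        genic = meth[mask]
        if len(genic):
            rows["genic"] = _props(genic)
    return pd.DataFrame(rows).T[[FULL_CMCGG, HEMI, FULL_MCCGG]]
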