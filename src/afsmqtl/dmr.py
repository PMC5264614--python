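"""Differentially methylated region (DMR) scan and DMR-DEG intersection.

Two call sets (samples or tissues) are compared on a shared CCGG site
universe.  The genome is tiled into fixed windows; a window is a DMR
when at least ``dmr_min_diff`` (default 5) sites change binary
methylated/unmethylated status between the two call sets and a 2x2
chi-squared test on (methylated, unmethylated) x (a, b) gives
p <= ``dmr_alpha`` (default 0.05).  Expected counts below 5 fall back to
Fisher's exact test.  Hemi- and fully methylated states are pooled into
one "methylated" status for differencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import METHYLATED_STATES, NO_CALL, UNMETHYLATED
from .core import GeneModel, RunConfig

DMR_COLUMNS = [
    "scaffold", "start", "end", "n_sites", "n_diff",
    "meth_a", "unmeth_a", "meth_b", "unmeth_b", "chi2", "p", "significant",
]


@dataclass(frozen=True)
class DmrRecord:
    scaffold: str
    start: int
    end: int
    n_sites: int
    n_diff: int
    counts_a: tuple[int, int]  # (methylated, unmethylated)
    counts_b: tuple[int, int]
    chi2: float
    p: float
    significant: bool


def _window_test(ma: int, ua: int, mb: int, ub: int) -> tuple[float, float]:
    """2x2 test on (methylated, unmethylated) x (set a, set b).

    Chi-squared without Yates correction; Fisher's exact probability when
    any expected count is < 5.  Degenerate tables (a zero margin) give
    p = 1.
    """
    table = np.array([[ma, ua], [mb, ub]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, 1.0
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        return np.nan, float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def scan_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Scan for DMRs between two per-site call sets.

    ``calls_a``/``calls_b`` have columns scaffold, position, state and
    must cover the same site universe (sites missing from one set are
    treated as no_call and excluded).  Returns one row per significant
    window (columns ``DMR_COLUMNS``).  The four tissue comparisons of a
    two-parent leaf/root design are simply four invocations.
    """
    cfg = cfg or RunConfig()
    a = calls_a.rename(columns={"state": "state_a"})[["scaffold", "position", "state_a"]]
    b = calls_b.rename(columns={"state": "state_b"})[["scaffold", "position", "state_b"]]
    merged = a.merge(b, on=["scaffold", "position"], how="inner")
    callable_ = merged[
        (merged["state_a"] != NO_CALL) & (merged["state_b"] != NO_CALL)
    ].copy()
    if callable_.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)

    callable_["meth_a"] = callable_["state_a"].isin(METHYLATED_STATES)
    callable_["meth_b"] = callable_["state_b"].isin(METHYLATED_STATES)
    callable_["widx"] = callable_["position"] // cfg.dmr_window_bp

    rows = []
    for (scaf, widx), grp in callable_.groupby(["scaffold", "widx"]):
        n_diff = int((grp["meth_a"] != grp["meth_b"]).sum())
        if n_diff < cfg.dmr_min_diff:
            continue
        ma = int(grp["meth_a"].sum())
        ua = len(grp) - ma
        mb = int(grp["meth_b"].sum())
        ub = len(grp) - mb
        chi2, p = _window_test(ma, ua, mb, ub)
        if p > cfg.dmr_alpha:
            continue
        rows.append(
            {
                "scaffold": scaf,
                "start": int(widx) * cfg.dmr_window_bp,
                "end": (int(widx) + 1) * cfg.dmr_window_bp,
                "n_sites": len(grp),
                "n_diff": n_diff,
                "meth_a": ma,
                "unmeth_a": ua,
                "meth_b": mb,
                "unmeth_b": ub,
                "chi2": chi2,
                "p": p,
                "significant": True,
            }
        )
    out = pd.DataFrame(rows, columns=DMR_COLUMNS)
    return out.sort_values(["scaffold", "start"]).reset_index(drop=True)


def intersect_dmr_deg(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    de_table: pd.DataFrame,
) -> pd.DataFrame:
    """Intersect DMRs with genes and keep only differentially expressed ones.

    A DMR maps to a gene when its window overlaps the gene body or the
    2000-bp upstream promoter; it is reported only when the gene passes
    the expression FDR gate (``fdr_pass`` column, FDR < 0.001 upstream).
    ``location`` is "body" when the window overlaps the body (promoter
    overlap alone gives "promoter").
    """
    required = {"gene_id", "fdr_pass"}
    if not required <= set(de_table.columns):
        raise ValueError(f"de_table needs columns {sorted(required)}")
    de = de_table.set_index("gene_id")

    rows = []
    for dmr in dmrs.itertuples():
        for g in genes:
            if g.scaffold_id != dmr.scaffold:
                continue
            body = _overlaps(dmr.start, dmr.end, g.start, g.end)
            p_lo, p_hi = g.promoter
            prom = _overlaps(dmr.start, dmr.end, p_lo, p_hi)
            if not (body or prom):
                continue
            if g.gene_id not in de.index or not bool(de.loc[g.gene_id, "fdr_pass"]):
                continue
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "scaffold": dmr.scaffold,
                    "dmr_start": dmr.start,
                    "dmr_end": dmr.end,
                    "location": "body" if body else "promoter",
                    "dmr_p": dmr.p,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "scaffold", "dmr_start", "dmr_end", "location", "dmr_p"]
    )


def _overlaps(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> bool:
    return a_lo < b_hi and b_lo < a_hi
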