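"""Trait index computation for the cold-tolerance / yield phenotyping design.

Trait families (trailing digits number independent trials):

* CTIG, CTIF1-5 — cold-tolerance indices (greenhouse / field), from
  per-plant injury levels 0-4.
* LFIF1-3 — leaf-fall index, 100 x fallen / total leaves.
* RIG, RIF1-2 — recovery indices after chilling; greenhouse levels run
  1-4, field levels 0-4.
* rSRY1-2 — storage-root yield at a test site relative to a reference
  site.
* SRY1-5, NSR1-3 — storage-root yield and root number (pass-through
  measurements).
* DW1-4 — storage-root dry-weight percentage from a 200-g fresh aliquot.
* FSC1-2 — fresh-root starch content; measured on a dry basis and
  converted to fresh basis via DW%.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

#: Allowed level range per level-count kind.
KIND_RANGES: dict[str, tuple[int, int]] = {
    "CTLG": (0, 4),  # cold-tolerance level, greenhouse
    "CTLF": (0, 4),  # cold-tolerance level, field
    "RLG": (1, 4),   # recovery level, greenhouse
    "RLF": (0, 4),   # recovery level, field
}


def level_index(counts: Mapping[int, int], kind: str = "CTLG") -> float:
    """Weighted-mean level index on a 0-100 scale.

    ``counts`` maps a level to the number of plants scored at it.  The
    index is 100 x sum(level_i x n_i) / (max_level x sum n_i); for kinds
    whose levels start at 1 (greenhouse recovery) levels are shifted so
    the index still spans the full [0, 100] range.
    """
    if kind not in KIND_RANGES:
        raise ValueError(f"unknown level kind {kind!r}; expected one of {sorted(KIND_RANGES)}")
    lo, hi = KIND_RANGES[kind]
    if not counts or sum(counts.values()) <= 0:
        raise ValueError("level counts must contain at least one plant")
    for level, n in counts.items():
        if not (lo <= level <= hi):
            raise ValueError(f"level {level} outside {kind} range [{lo}, {hi}]")
        if n < 0:
            raise ValueError("plant counts must be non-negative")
    total = sum(counts.values())
    weighted = sum((level - lo) * n for level, n in counts.items())
    return 100.0 * weighted / ((hi - lo) * total)


def leaf_fall_index(n_leaves_fallen: int, n_leaves: int) -> float:
    """LFIF = 100 x fallen / total leaves (recorded via leaf scars)."""
    if n_leaves <= 0:
        raise ValueError("total leaf count must be > 0")
    if not (0 <= n_leaves_fallen <= n_leaves):
        raise ValueError("fallen leaves must be in [0, total leaves]")
    return 100.0 * n_leaves_fallen / n_leaves


def dry_weight_percent(w_dry: float, w_fresh: float = 200.0) -> float:
    """DW% = 100 x dry weight / fresh weight (200-g fresh aliquot by design)."""
    if w_fresh <= 0:
        raise ValueError("fresh weight must be > 0")
    if not (0 <= w_dry <= w_fresh):
        raise ValueError("dry weight must be in [0, fresh weight]")
    return 100.0 * w_dry / w_fresh


def relative_yield(yield_site: float, yield_reference: float) -> float:
    """rSRY = test-site root yield / reference-site root yield."""
    if yield_reference <= 0:
        raise ValueError("reference yield must be > 0")
    if yield_site < 0:
        raise ValueError("yield must be >= 0")
    return yield_site / yield_reference


def starch_fresh_basis(starch_dry_pct: float, dw_pct: float) -> float:
    """Convert starch content from dry-weight basis to fresh-weight basis."""
    if not (0 <= starch_dry_pct <= 100 and 0 <= dw_pct <= 100):
        raise ValueError("percentages must be in [0, 100]")
    return starch_dry_pct * dw_pct / 100.0


def trait_family(trait_code: str) -> str:
    """Strip the trial number: CTIF3 -> CTIF, rSRY1 -> rSRY, DW-2 -> DW."""
    return trait_code.rstrip("0123456789").rstrip("-_")


def level_index_table(df: pd.DataFrame) -> pd.DataFrame:
    """Compute level indices from a long table.

    Columns: clone_id, trait_code, kind, level, n.  Returns one row per
    (clone_id, trait_code) with the 0-100 index.
    """
    required = {"clone_id", "trait_code", "kind", "level", "n"}
    if not required <= set(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    rows = []
    for (clone, trait), grp in df.groupby(["clone_id", "trait_code"]):
        kinds = grp["kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"{clone}/{trait}: mixed level kinds {kinds}")
        counts = dict(zip(grp["level"].astype(int), grp["n"].astype(int)))
        rows.append(
            {"clone_id": clone, "trait_code": trait,
             "value": level_index(counts, kinds[0])}
        )
    return pd.DataFrame(rows, columns=["clone_id", "trait_code", "value"])


def build_trait_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pivot long (clone_id, trait_code, value) rows into a clone x trait matrix."""
    return values.pivot_table(
        index="clone_id", columns="trait_code", values="value", aggfunc="mean"
    )
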