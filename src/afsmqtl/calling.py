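"""CCGG methylation-state calling and population-level classification.

The dual-digest logic: HpaII cuts C^CGG only when the site is fully
unmethylated on both strands (it tolerates hemi-methylation of the outer
C on one strand's complement in the classic MSAP reading used here as
condition (1)); MspI cuts C^CGG regardless of internal-C methylation but
not when the outer C is methylated.  Per sample and site, four read
categories are tallied — HpaII cleavage, MspI cleavage, HpaII body,
MspI body — and the pattern maps onto one of three methylated states:

=================  =========================================  ==============
pattern            reads present                              state
=================  =========================================  ==============
condition (1)      HpaII cleavage + MspI body, no MspI cut    hemi_mCCGG
condition (2)      MspI cleavage + HpaII body, no HpaII cut   full_CmCGG
condition (3)      body in both digests, no cuts              full_mCCGG
both digests cut   HpaII cleavage + MspI cleavage             unmethylated
=================  =========================================  ==============

A site needs >= 4 reads total with >= 2 per enzyme library to be
callable; any other pattern is conservatively ``no_call``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import RunConfig, logger

# The five call states.
UNMETHYLATED = "unmethylated"
HEMI = "hemi_mCCGG"
FULL_CMCGG = "full_CmCGG"
FULL_MCCGG = "full_mCCGG"
NO_CALL = "no_call"

STATES = (UNMETHYLATED, HEMI, FULL_CMCGG, FULL_MCCGG, NO_CALL)
METHYLATED_STATES = frozenset({HEMI, FULL_CMCGG, FULL_MCCGG})
FULL_STATES = frozenset({FULL_CMCGG, FULL_MCCGG})


def call_site_state(
    h_cleave: int, m_cleave: int, h_body: int, m_body: int,
    cfg: RunConfig | None = None,
) -> str:
    """Call the methylation state of one site in one sample.

    Raises ``ValueError`` on negative counts.
    """
    cfg = cfg or RunConfig()
    counts = (h_cleave, m_cleave, h_body, m_body)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative read counts: {counts}")
    k = cfg.min_reads_per_enzyme
    total = h_cleave + m_cleave + h_body + m_body
    if total < cfg.min_total_reads:
        return NO_CALL
    if h_cleave + h_body < k or m_cleave + m_body < k:
        return NO_CALL
    if h_cleave >= k and m_body >= k and m_cleave == 0:
        return HEMI
    if m_cleave >= k and h_body >= k and h_cleave == 0:
        return FULL_CMCGG
    if h_body >= k and m_body >= k and h_cleave == 0 and m_cleave == 0:
        return FULL_MCCGG
    if h_cleave >= k and m_cleave >= k:
        return UNMETHYLATED
    return NO_CALL


def call_states(evidence: pd.DataFrame, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Vectorised calling over an evidence table.

    Input columns: sample_id, scaffold, position, h_cleave, m_cleave,
    h_body, m_body.  Returns the same keys plus a ``state`` column.
    """
    cfg = cfg or RunConfig()
    hc = evidence["h_cleave"].to_numpy()
    mc = evidence["m_cleave"].to_numpy()
    hb = evidence["h_body"].to_numpy()
    mb = evidence["m_body"].to_numpy()
    if (hc < 0).any() or (mc < 0).any() or (hb < 0).any() or (mb < 0).any():
        raise ValueError("negative read counts in evidence table")
    k = cfg.min_reads_per_enzyme
    callable_ = (
        (hc + mc + hb + mb >= cfg.min_total_reads)
        & (hc + hb >= k)
        & (mc + mb >= k)
    )
    state = np.select(
        [
            callable_ & (hc >= k) & (mb >= k) & (mc == 0),
            callable_ & (mc >= k) & (hb >= k) & (hc == 0),
            callable_ & (hb >= k) & (mb >= k) & (hc == 0) & (mc == 0),
            callable_ & (hc >= k) & (mc >= k),
        ],
        [HEMI, FULL_CMCGG, FULL_MCCGG, UNMETHYLATED],
        default=NO_CALL,
    )
    out = evidence[["sample_id", "scaffold", "position"]].copy()
    out["state"] = state
    return out


def calls_to_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-form calls into a (scaffold, position) x sample matrix."""
    mat = calls.pivot_table(
        index=["scaffold", "position"],
        columns="sample_id",
        values="state",
        aggfunc="first",
    )
    return mat.fillna(NO_CALL)


# ---------------------------------------------------------------------------
# Population summary
# ---------------------------------------------------------------------------


def summarize_population(
    matrix: pd.DataFrame,
    cfg: RunConfig | None = None,
    require_identical: bool = True,
) -> pd.DataFrame:
    """Per-site population summary with the >2/3 hemi/full classification.

    ``matrix`` is a (scaffold, position)-indexed site x sample state
    matrix.  Sites are retained only when methylated in at least
    ``cfg.min_methylated_samples`` samples — by default in the strict
    sense of the *identical* methylated state recurring
    (``require_identical=True``); pass ``False`` to accept any
    combination of methylated states.

    site_class is ``hemi`` when hemi calls exceed the 2/3 majority of
    methylated calls, ``full`` when full calls (both full states pooled)
    do, otherwise ``mixed``.  A site is ``monomorphic`` when every called
    sample shares one state, ``polymorphic`` otherwise.
    """
    cfg = cfg or RunConfig()
    if matrix.shape[1] < 2:
        raise ValueError("population summary needs >= 2 samples")

    vals = matrix.to_numpy()
    n_called = (vals != NO_CALL).sum(axis=1)
    n_hemi = (vals == HEMI).sum(axis=1)
    n_full_c = (vals == FULL_CMCGG).sum(axis=1)
    n_full_m = (vals == FULL_MCCGG).sum(axis=1)
    n_full = n_full_c + n_full_m
    n_methylated = n_hemi + n_full

    if require_identical:
        max_same = np.maximum(n_hemi, np.maximum(n_full_c, n_full_m))
        keep = max_same >= cfg.min_methylated_samples
    else:
        keep = n_methylated >= cfg.min_methylated_samples
    dropped_empty = int((n_called == 0).sum())
    if dropped_empty:
        logger.info("dropping %d sites with zero called samples", dropped_empty)

    with np.errstate(invalid="ignore", divide="ignore"):
        hemi_fraction = np.where(n_methylated > 0, n_hemi / np.maximum(n_methylated, 1), np.nan)
        full_fraction = np.where(n_methylated > 0, n_full / np.maximum(n_methylated, 1), np.nan)

    site_class = np.select(
        [hemi_fraction > cfg.majority_fraction, full_fraction > cfg.majority_fraction],
        ["hemi", "full"],
        default="mixed",
    )

    # monomorphic: every called sample shares one state
    mono = np.zeros(len(matrix), dtype=bool)
    for state in (UNMETHYLATED, HEMI, FULL_CMCGG, FULL_MCCGG):
        mono |= (vals == state).sum(axis=1) == n_called
    mono &= n_called > 0

    out = pd.DataFrame(
        {
            "n_called": n_called,
            "n_methylated": n_methylated,
            "n_hemi": n_hemi,
            "n_full": n_full,
            "hemi_fraction": hemi_fraction,
            "full_fraction": full_fraction,
            "site_class": site_class,
            "monomorphic": mono,
            "polymorphic": ~mono,
        },
        index=matrix.index,
    )
    return out[keep]


# ---------------------------------------------------------------------------
# Inheritance classes
# ---------------------------------------------------------------------------

#: Keys describing the parental pattern at a site.
PARENT_SAME_HEMI = "same_hemi"
PARENT_SAME_FULL = "same_full"
PARENT_BOTH_UNMETH = "both_unmethylated"
PARENT_DISPARATE = "disparate"

#: Keys describing the F1 pattern.
F1_UNIFORM = "uniform_parental"
F1_SEG = "segregating"
F1_SEG_NOVEL = "segregating_novel"
F1_NOVEL = "novel"
F1_HEMI = "methylated_hemi"   # only used when parents are both unmethylated
F1_FULL = "methylated_full"

#: Default 12-class heritability table.  Parents sharing one methylated
#: state with a uniform parental F1 are class A (A1 hemi, A2 full);
#: same-state parents with a segregating or novel F1 are class B; parents
#: both unmethylated with methylated F1 offspring are class C (C1 hemi,
#: C2 full); parents with disparate states are class D (D1 uniform
#: parental, D2 segregating parental-only, D3 segregating including a
#: novel methylated state, D4 uniform novel).
DEFAULT_CLASS_TABLE: dict[tuple[str, str], str] = {
    (PARENT_SAME_HEMI, F1_UNIFORM): "A1",
    (PARENT_SAME_FULL, F1_UNIFORM): "A2",
    (PARENT_SAME_HEMI, F1_SEG): "B1",
    (PARENT_SAME_HEMI, F1_SEG_NOVEL): "B1",
    (PARENT_SAME_HEMI, F1_NOVEL): "B2",
    (PARENT_SAME_FULL, F1_SEG): "B3",
    (PARENT_SAME_FULL, F1_SEG_NOVEL): "B3",
    (PARENT_SAME_FULL, F1_NOVEL): "B4",
    (PARENT_BOTH_UNMETH, F1_HEMI): "C1",
    (PARENT_BOTH_UNMETH, F1_FULL): "C2",
    (PARENT_DISPARATE, F1_UNIFORM): "D1",
    (PARENT_DISPARATE, F1_SEG): "D2",
    (PARENT_DISPARATE, F1_SEG_NOVEL): "D3",
    (PARENT_DISPARATE, F1_NOVEL): "D4",
}

CLASS_LABELS = ("A1", "A2", "B1", "B2", "B3", "B4", "C1", "C2", "D1", "D2", "D3", "D4")


@dataclass(frozen=True)
class InheritanceClass:
    parent_pattern: tuple[str, str]
    f1_pattern: str
    class_label: str


def _parent_key(pa: str, pb: str) -> str:
    if pa == pb:
        if pa == UNMETHYLATED:
            return PARENT_BOTH_UNMETH
        return PARENT_SAME_HEMI if pa == HEMI else PARENT_SAME_FULL
    return PARENT_DISPARATE


def classify_inheritance(
    parent_a: str,
    parent_b: str,
    f1_states: Sequence[str],
    class_table: Mapping[tuple[str, str], str] | None = None,
    majority_fraction: float = 2.0 / 3.0,
) -> InheritanceClass | None:
    """Assign a site to one of the twelve heritability classes.

    ``parent_a``/``parent_b`` are the two parental calls (neither may be
    ``no_call``; the site is skipped upstream otherwise).  F1 ``no_call``
    entries are ignored.  "Novel" means a *methylated* state absent from
    both parents — an unmethylated F1 plant is a loss, not a novel state.
    The result depends only on the multiset of F1 states.

    Returns ``None`` for patterns outside the class system (no methylation
    anywhere, or all F1 reverting to unmethylated at a same-state
    methylated parental site).
    """
    table = dict(class_table) if class_table is not None else DEFAULT_CLASS_TABLE
    if parent_a == NO_CALL or parent_b == NO_CALL:
        raise ValueError("parent calls must not be no_call")
    called = [s for s in f1_states if s != NO_CALL]
    if not called:
        return None

    pkey = _parent_key(parent_a, parent_b)
    parental = {parent_a, parent_b}
    distinct = set(called)
    novel_states = (distinct & METHYLATED_STATES) - parental

    if pkey == PARENT_BOTH_UNMETH:
        meth = [s for s in called if s in METHYLATED_STATES]
        if not meth:
            return None  # nothing methylated anywhere
        hemi_frac = sum(s == HEMI for s in meth) / len(meth)
        fkey = F1_HEMI if hemi_frac > majority_fraction else F1_FULL
    elif len(distinct) >= 2:
        fkey = F1_SEG_NOVEL if novel_states else F1_SEG
    else:
        (only,) = distinct
        if only in parental:
            fkey = F1_UNIFORM
        elif only in METHYLATED_STATES:
            fkey = F1_NOVEL
        else:
            return None  # uniform loss of methylation: outside the table

    label = table.get((pkey, fkey))
    if label is None:
        return None
    return InheritanceClass((parent_a, parent_b), fkey, label)


def classify_population(
    matrix: pd.DataFrame,
    parent_ids: tuple[str, str],
    class_table: Mapping[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Classify every site of a call matrix; parent no_call sites are skipped."""
    pa_col, pb_col = parent_ids
    f1_cols = [c for c in matrix.columns if c not in parent_ids]
    rows = []
    for idx, row in matrix.iterrows():
        pa, pb = row[pa_col], row[pb_col]
        if pa == NO_CALL or pb == NO_CALL:
            continue
        res = classify_inheritance(pa, pb, [row[c] for c in f1_cols], class_table)
        if res is None:
            continue
        rows.append(
            {
                "scaffold": idx[0],
                "position": idx[1],
                "parent_a": pa,
                "parent_b": pb,
                "f1_pattern": res.f1_pattern,
                "class_label": res.class_label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["scaffold", "position", "parent_a", "parent_b", "f1_pattern", "class_label"],
    )
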