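"""Association scans: epiQTL (methylation x phenotype), marker segregation
filtering, two-point linkage statistics, and the single-marker
Kruskal-Wallis QTL scan.

The epiQTL scan scores each polymorphic CCGG site per sample on the
additive scale a = 1: fully methylated -> 1, hemi-methylated -> 2/3,
unmethylated -> 0 (Pearson correlation is scale invariant, so any a > 0
is equivalent).  For each (site, trait) pair with N >= 20
pairwise-complete samples, r is tested with t = r sqrt((N-2)/(1-r^2))
against Student's t with N-2 degrees of freedom, two tailed, at
alpha = 0.01.

Markers from the outbred F1 (CP) cross are typed lm x ll (segregating
from the female parent, expected 1:1), nn x np (male parent, 1:1) or
hk x hk (both parents, 3:1 dominant scoring), filtered on read support,
call rate and a segregation chi-squared goodness-of-fit at p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import FULL_STATES, HEMI, NO_CALL, UNMETHYLATED
from .core import RunConfig, logger
from .phenotypes import trait_family

#: Methylation genotype scores on the unit additive scale.
SCORE_FULL = 1.0
SCORE_HEMI = 2.0 / 3.0
SCORE_NONE = 0.0


def score_methylation(states: Sequence[str]) -> np.ndarray:
    """Map call states to {1, 2/3, 0, nan} methylation genotype scores."""
    out = np.full(len(states), np.nan)
    for i, s in enumerate(states):
        if s in FULL_STATES:
            out[i] = SCORE_FULL
        elif s == HEMI:
            out[i] = SCORE_HEMI
        elif s == UNMETHYLATED:
            out[i] = SCORE_NONE
        elif s != NO_CALL:
            raise ValueError(f"unknown state {s!r}")
    return out


def score_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Score a site x sample state matrix into a numeric score matrix."""
    return pd.DataFrame(
        np.vstack([score_methylation(row) for row in matrix.to_numpy()]),
        index=matrix.index,
        columns=matrix.columns,
    )


@dataclass
class AssociationResult:
    feature_id: str
    trait_code: str
    n_overlap: int
    r: float
    t: float
    p: float
    significant: bool
    reason: str = ""  # non-empty when the pair is non-evaluable


def associate(
    scores: Sequence[float],
    trait: Sequence[float],
    cfg: RunConfig | None = None,
    feature_id: str = "",
    trait_code: str = "",
) -> AssociationResult:
    """Pearson association between one site's scores and one trait.

    Pairwise-complete samples define N; pairs with N below
    ``cfg.epiqtl_min_overlap`` (default 20) or with zero variance in
    either vector are returned non-evaluable with an explicit reason.
    p = 2 x (1 - T_cdf(|t|, N-2)).
    """
    cfg = cfg or RunConfig()
    x = np.asarray(scores, dtype=float)
    y = np.asarray(trait, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < cfg.epiqtl_min_overlap:
        return AssociationResult(
            feature_id, trait_code, n, np.nan, np.nan, np.nan, False,
            f"overlap {n} < {cfg.epiqtl_min_overlap}",
        )
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(
            feature_id, trait_code, n, np.nan, np.nan, np.nan, False,
            "zero variance",
        )
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t, p = np.inf * np.sign(r), 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    significant = bool(p < cfg.epiqtl_alpha)
    return AssociationResult(feature_id, trait_code, n, r, float(t), float(p), significant)


def _pearson_columns(X: np.ndarray, y: np.ndarray, min_n: int):
    """Vectorised pairwise-complete Pearson r of every row of X against y.

    Returns (n, r, t, p) arrays; rows with n < min_n or zero variance get
    nan statistics.
    """
    valid = ~np.isnan(X) & ~np.isnan(y)[None, :]
    n = valid.sum(axis=1).astype(float)
    Xz = np.where(valid, X, 0.0)
    Yz = np.where(valid, y[None, :], 0.0)
    sx = Xz.sum(axis=1)
    sy = Yz.sum(axis=1)
    sxx = (Xz * Xz).sum(axis=1)
    syy = (Yz * Yz).sum(axis=1)
    sxy = (Xz * Yz).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(varx * vary)
    r = np.clip(r, -1.0, 1.0)
    bad = (n < min_n) | (varx <= 0) | (vary <= 0)
    r[bad] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.isnan(r), np.nan,
                 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1)))
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    return n.astype(int), r, t, p


def scan_qtl_epi(
    scores: pd.DataFrame,
    traits: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Genome-wide epiQTL scan of every polymorphic site against every trait.

    ``scores``: site x sample numeric score matrix (nan = missing), rows
    restricted to polymorphic sites upstream.  ``traits``: sample x trait
    frame.  Returns one row per (site, trait) with n, r, t, p, a
    significance flag (p < alpha and N >= the overlap floor), and a
    ``repeatable`` flag marking sites significant in >= 2 independent
    trials of the same trait family (the reCT / reQY notion).
    """
    cfg = cfg or RunConfig()
    common = [s for s in scores.columns if s in traits.index]
    if len(common) < scores.shape[1]:
        logger.info("restricting scan to %d samples shared with the trait table",
                    len(common))
    X = scores[common].to_numpy(dtype=float)
    frames = []
    for trait_code in traits.columns:
        y = traits.loc[common, trait_code].to_numpy(dtype=float)
        if np.isnan(y).all():
            logger.warning("trait %s has no data; skipped", trait_code)
            continue
        n, r, t, p = _pearson_columns(X, y, cfg.epiqtl_min_overlap)
        frames.append(
            pd.DataFrame(
                {
                    "site": [f"{s}:{p_}" for s, p_ in scores.index],
                    "trait_code": trait_code,
                    "n": n,
                    "r": r,
                    "t": t,
                    "p": p,
                    "significant": (p < cfg.epiqtl_alpha) & (n >= cfg.epiqtl_min_overlap),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["site", "trait_code", "n", "r", "t", "p", "significant", "repeatable"]
        )
    out = pd.concat(frames, ignore_index=True)
    out = out[out["n"] > 0].reset_index(drop=True)  # all-missing sites yield no rows
    out["family"] = out["trait_code"].map(trait_family)
    sig = out[out["significant"]]
    hits = sig.groupby(["site", "family"])["trait_code"].nunique()
    repeatable_keys = set(hits[hits >= 2].index)
    out["repeatable"] = [
        (s, f) in repeatable_keys for s, f in zip(out["site"], out["family"])
    ]
    return out.drop(columns=["family"])


# ---------------------------------------------------------------------------
# Marker segregation typing and filtering
# ---------------------------------------------------------------------------

MARKER_TYPES = ("lm_ll", "nn_np", "hk_hk")

#: Expected (present, absent) segregation per marker type.
EXPECTED_RATIOS = {"lm_ll": (1, 1), "nn_np": (1, 1), "hk_hk": (3, 1)}


@dataclass
class MarkerRecord:
    """One dominant AFSM marker in the CP cross.

    ``progeny`` holds per-sample calls: 1.0 present, 0.0 absent, nan
    missing (heterozygous-ambiguous calls are recorded as missing).
    """

    marker_id: str
    in_female: bool
    in_male: bool
    progeny: np.ndarray
    read_support: int = 2

    @property
    def marker_type(self) -> str | None:
        if self.in_female and self.in_male:
            return "hk_hk"
        if self.in_female:
            return "lm_ll"
        if self.in_male:
            return "nn_np"
        return None


def segregation_test(marker: MarkerRecord) -> tuple[float, float]:
    """Chi-squared goodness of fit of progeny presence to the expected ratio."""
    mtype = marker.marker_type
    if mtype is None:
        raise ValueError(f"{marker.marker_id}: marker absent in both parents")
    calls = marker.progeny
    present = int(np.nansum(calls == 1.0))
    absent = int(np.nansum(calls == 0.0))
    n = present + absent
    if n == 0:
        return np.nan, np.nan
    rp, ra = EXPECTED_RATIOS[mtype]
    expected = [n * rp / (rp + ra), n * ra / (rp + ra)]
    chi2, p = stats.chisquare([present, absent], expected)
    return float(chi2), float(p)


def classify_and_filter_markers(
    markers: Sequence[MarkerRecord],
    cfg: RunConfig | None = None,
    min_read_support: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type and filter markers for map construction.

    Retention requires, in order: presence in at least one parent
    (progeny-only markers are inconsistent and removed), read support of
    at least ``min_read_support``, a call rate above
    ``cfg.marker_presence_fraction`` of the individuals, and a
    segregation chi-squared goodness of fit with p >= ``cfg.seg_alpha``
    against the type's Mendelian ratio (1:1 or 3:1).

    Returns (retained, dropped) frames with marker_type, call_rate,
    seg_chi2, seg_p, and a drop reason.
    """
    cfg = cfg or RunConfig()
    kept, dropped = [], []
    for m in markers:
        row = {"marker_id": m.marker_id, "marker_type": m.marker_type,
               "read_support": m.read_support}
        n_total = len(m.progeny)
        n_called = int(np.sum(~np.isnan(m.progeny)))
        row["call_rate"] = n_called / n_total if n_total else 0.0
        if m.marker_type is None:
            row |= {"seg_chi2": np.nan, "seg_p": np.nan,
                    "reason": "absent in both parents"}
            dropped.append(row)
            continue
        if m.read_support < min_read_support:
            row |= {"seg_chi2": np.nan, "seg_p": np.nan, "reason": "read support"}
            dropped.append(row)
            continue
        if row["call_rate"] <= cfg.marker_presence_fraction:
            row |= {"seg_chi2": np.nan, "seg_p": np.nan, "reason": "call rate"}
            dropped.append(row)
            continue
        chi2, p = segregation_test(m)
        row |= {"seg_chi2": chi2, "seg_p": p}
        if not np.isnan(p) and p < cfg.seg_alpha:
            row["reason"] = "segregation distortion"
            dropped.append(row)
            continue
        row["reason"] = ""
        kept.append(row)
    cols = ["marker_id", "marker_type", "read_support", "call_rate",
            "seg_chi2", "seg_p", "reason"]
    return (
        pd.DataFrame(kept, columns=cols),
        pd.DataFrame(dropped, columns=cols),
    )


# ---------------------------------------------------------------------------
# Two-point linkage
# ---------------------------------------------------------------------------


@dataclass
class LinkagePairStat:
    marker_a: str
    marker_b: str
    n_informative: int
    rf: float
    lod: float
    groupable: bool
    reason: str = ""


def pairwise_linkage(
    a: MarkerRecord,
    b: MarkerRecord,
    cfg: RunConfig | None = None,
    min_informative: int = 10,
) -> LinkagePairStat:
    """Two-point recombination fraction and LOD for two same-phase markers.

    rf = recombinants / informative progeny (mismatching presence calls,
    capped at 0.5); LOD = n_nonrec log10(2(1-rf)) + n_rec log10(2 rf).
    The grouping predicate requires rf < 0.4 and LOD above the
    configured threshold (default 1.0).  Pairs of differing parental
    phase type or with < 10 shared informative progeny are
    non-evaluable.
    """
    cfg = cfg or RunConfig()
    if a.marker_type != b.marker_type:
        return LinkagePairStat(a.marker_id, b.marker_id, 0, np.nan, np.nan,
                               False, "phase type mismatch")
    both = ~np.isnan(a.progeny) & ~np.isnan(b.progeny)
    n = int(both.sum())
    if n < min_informative:
        return LinkagePairStat(a.marker_id, b.marker_id, n, np.nan, np.nan,
                               False, f"informative progeny {n} < {min_informative}")
    n_rec = int((a.progeny[both] != b.progeny[both]).sum())
    rf = min(n_rec / n, 0.5)
    n_nonrec = n - n_rec
    lod = 0.0
    if n_nonrec:
        lod += n_nonrec * np.log10(2.0 * (1.0 - rf))
    if n_rec:
        lod += n_rec * np.log10(2.0 * rf)
    groupable = rf < cfg.max_grouping_rf and lod > cfg.lod_threshold
    return LinkagePairStat(a.marker_id, b.marker_id, n, rf, float(lod), bool(groupable))


# ---------------------------------------------------------------------------
# Single-marker Kruskal-Wallis QTL scan
# ---------------------------------------------------------------------------


def kruskal_marker(
    genotypes: Sequence[float],
    trait: Sequence[float],
    min_class_size: int = 2,
) -> tuple[float, float]:
    """Kruskal-Wallis H and p for one marker against one raw trait.

    Genotype classes are the distinct non-missing genotype values; H is
    tie-corrected and referred to chi-squared with k-1 degrees of
    freedom.  Requires >= 2 classes each with >= ``min_class_size``
    observations; otherwise returns (nan, nan).  All-tied trait values
    give H = 0, p = 1.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    mask = ~(np.isnan(g) | np.isnan(y))
    g, y = g[mask], y[mask]
    groups = [y[g == val] for val in np.unique(g)]
    groups = [grp for grp in groups if len(grp) >= min_class_size]
    if len(groups) < 2:
        return np.nan, np.nan
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kw_scan(
    genotypes: pd.DataFrame,
    traits: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Single-marker Kruskal-Wallis scan on raw phenotypes.

    ``genotypes``: marker x sample frame ({1, 0, nan});
    ``traits``: sample x trait frame.  Significance at alpha = 0.001.
    """
    cfg = cfg or RunConfig()
    common = [s for s in genotypes.columns if s in traits.index]
    rows = []
    for marker_id, geno in genotypes[common].iterrows():
        for trait_code in traits.columns:
            h, p = kruskal_marker(geno.to_numpy(), traits.loc[common, trait_code].to_numpy())
            rows.append(
                {
                    "marker_id": marker_id,
                    "trait_code": trait_code,
                    "H": h,
                    "p": p,
                    "significant": bool(p < cfg.kw_alpha) if not np.isnan(p) else False,
                }
            )
    return pd.DataFrame(rows, columns=["marker_id", "trait_code", "H", "p", "significant"])
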