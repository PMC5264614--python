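"""Synthetic F1 (CP) population generator.

Emulates the study design every other module consumes: two heterozygous,
non-inbred parents crossed to give 186 F1 clones; CCGG sites planted on
toy scaffolds; per-site, per-sample dual-digest read evidence; dominant
markers segregating 1:1 (parent-specific) or 3:1 (shared); and
phenotypes built from planted additive site effects plus Gaussian noise.

The per-class inheritance rules are the generating counterparts of the
classification table in :mod:`afsmqtl.calling` — a single source of
truth, so a noiseless round trip through evidence simulation, state
calling and inheritance classification recovers every generating class.

Defaults mirror the study conditions: 186 F1 clones, an average
sequencing depth of 5 reads per enzyme library (floor-guarded at the
2-read callability minimum), and class frequencies concentrated on the
A and D classes (the B and C classes were not observed in the cassava
population this design emulates, but all twelve can be generated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import (
    CLASS_LABELS,
    FULL_CMCGG,
    FULL_MCCGG,
    HEMI,
    UNMETHYLATED,
)
from .core import GeneModel, GenomicSite, write_fasta, write_gene_models_gff3
from .association import score_methylation

#: Default class frequencies: mass on A and D only, D2-4 heaviest.
DEFAULT_CLASS_FREQUENCIES: dict[str, float] = {
    "A1": 0.07, "A2": 0.13,
    "B1": 0.0, "B2": 0.0, "B3": 0.0, "B4": 0.0,
    "C1": 0.0, "C2": 0.0,
    "D1": 0.12, "D2": 0.28, "D3": 0.22, "D4": 0.18,
}

#: Fraction of markers of each segregation type.
DEFAULT_MARKER_TYPE_PROBS: dict[str, float] = {
    "lm_ll": 0.4, "nn_np": 0.4, "hk_hk": 0.2,
}


@dataclass
class SimConfig:
    n_f1: int = 186
    n_sites: int = 1000
    n_markers: int = 500
    scaffold_lengths: dict[str, int] = field(
        default_factory=lambda: {"scaffold_1": 60000, "scaffold_2": 60000}
    )
    class_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQUENCIES)
    )
    read_depth_mean: float = 5.0
    min_library_depth: int = 2  # floor on per-library read counts
    evidence_noise_rate: float = 0.0  # per-read cleave<->body flip probability
    effect_sites: list[tuple[int, str, float]] = field(default_factory=list)
    trait_noise_sd: float = 1.0
    marker_type_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_TYPE_PROBS)
    )
    marker_missing_rate: float = 0.0
    parent_ids: tuple[str, str] = ("KU50", "SC124")
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_frequencies) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        total = sum(self.class_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_frequencies must sum to 1, got {total}")
        for name in ("evidence_noise_rate", "marker_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_f1 < 2 or self.n_sites < 1:
            raise ValueError("need n_f1 >= 2 and n_sites >= 1")
        capacity = sum(n // _SITE_SPACING for n in self.scaffold_lengths.values())
        if self.n_sites > capacity:
            raise ValueError(
                f"{self.n_sites} sites exceed scaffold capacity {capacity}"
            )


_SITE_SPACING = 50  # bp between planted CCGG sites

_FULLS = (FULL_CMCGG, FULL_MCCGG)


def _mix(rng: np.random.Generator, n: int, s1: str, s2: str) -> np.ndarray:
    """n draws from {s1, s2} with both states guaranteed present."""
    arr = np.where(rng.random(n) < 0.5, s1, s2).astype(object)
    arr[0], arr[1] = s1, s2
    return arr


def _uniform(n: int, s: str) -> np.ndarray:
    return np.full(n, s, dtype=object)


def _make_generators() -> dict[str, Callable]:
    """Per-class (parent_a, parent_b, F1 states) generating rules."""

    def a1(rng, n):
        return HEMI, HEMI, _uniform(n, HEMI)

    def a2(rng, n):
        f = rng.choice(_FULLS)
        return f, f, _uniform(n, f)

    def b1(rng, n):  # same hemi parents, F1 segregating (parental + loss)
        return HEMI, HEMI, _mix(rng, n, HEMI, UNMETHYLATED)

    def b2(rng, n):  # same hemi parents, F1 uniform novel full state
        return HEMI, HEMI, _uniform(n, FULL_MCCGG)

    def b3(rng, n):
        f = rng.choice(_FULLS)
        return f, f, _mix(rng, n, f, UNMETHYLATED)

    def b4(rng, n):  # full parents, F1 uniform novel hemi
        f = rng.choice(_FULLS)
        return f, f, _uniform(n, HEMI)

    def c1(rng, n):  # unmethylated parents, hemi gains in F1
        return UNMETHYLATED, UNMETHYLATED, _mix(rng, n, HEMI, UNMETHYLATED)

    def c2(rng, n):
        f = rng.choice(_FULLS)
        return UNMETHYLATED, UNMETHYLATED, _mix(rng, n, f, UNMETHYLATED)

    def _disparate_parents(rng):
        f = rng.choice(_FULLS)
        if rng.random() < 0.5:
            return f, UNMETHYLATED, f
        return UNMETHYLATED, f, f

    def d1(rng, n):
        pa, pb, f = _disparate_parents(rng)
        return pa, pb, _uniform(n, f)

    def d2(rng, n):
        pa, pb, f = _disparate_parents(rng)
        return pa, pb, _mix(rng, n, f, UNMETHYLATED)

    def d3(rng, n):  # segregating including a novel methylated state
        pa, pb, f = _disparate_parents(rng)
        return pa, pb, _mix(rng, n, f, HEMI)

    def d4(rng, n):  # uniform novel
        pa, pb, _ = _disparate_parents(rng)
        return pa, pb, _uniform(n, HEMI)

    return {
        "A1": a1, "A2": a2, "B1": b1, "B2": b2, "B3": b3, "B4": b4,
        "C1": c1, "C2": c2, "D1": d1, "D2": d2, "D3": d3, "D4": d4,
    }


CLASS_GENERATORS = _make_generators()


@dataclass
class TruthBundle:
    """Everything the simulator knows; the ground truth for every stage."""

    config: SimConfig
    sequences: dict[str, str]
    sites: list[GenomicSite]
    site_classes: list[str]
    parent_states: pd.DataFrame      # site x 2 parents
    f1_states: pd.DataFrame          # site x n_f1
    genes: list[GeneModel]
    marker_meta: pd.DataFrame        # marker_id, marker_type, in_female, in_male, read_support
    marker_calls: pd.DataFrame       # marker x sample, {1, 0, nan}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.parent_states.columns) + list(self.f1_states.columns)

    @property
    def states(self) -> pd.DataFrame:
        """Site x sample state matrix, parents first."""
        return pd.concat([self.parent_states, self.f1_states], axis=1)

    def site_scores(self) -> pd.DataFrame:
        """True methylation genotype scores ({1, 2/3, 0}) per site x F1."""
        mat = self.f1_states
        return pd.DataFrame(
            np.vstack([score_methylation(row) for row in mat.to_numpy()]),
            index=mat.index,
            columns=mat.columns,
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "reference.fa")
        write_gene_models_gff3(self.genes, outdir / "genes.gff3")
        self.states.to_csv(outdir / "true_states.tsv", sep="\t")
        self.marker_meta.to_csv(outdir / "marker_meta.tsv", sep="\t", index=False)
        self.marker_calls.to_csv(outdir / "marker_calls.tsv", sep="\t")
        truth = {
            "seed": self.config.seed,
            "n_f1": self.config.n_f1,
            "sites": [[s.scaffold_id, s.position] for s in self.sites],
            "site_classes": self.site_classes,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _scrub_and_plant(rng: np.random.Generator, length: int,
                     positions: Sequence[int]) -> str:
    """Random DNA with CCGG occurring exactly at the planted positions."""
    seq = rng.choice(list("ACGT"), size=length)
    s = "".join(seq)
    # plant first, then scrub spurious occurrences (a spurious CCGG can
    # never overlap a planted one, so mutating its final G is safe)
    chars = list(s)
    for p in positions:
        chars[p : p + 4] = "CCGG"
    s = "".join(chars)
    planted = set(positions)
    i = s.find("CCGG")
    while i != -1:
        if i not in planted:
            chars[i + 3] = "A"
        i = s.find("CCGG", i + 1)
    return "".join(chars)


def _tile_genes(scaffold_lengths: Mapping[str, int]) -> list[GeneModel]:
    """Alternating-strand 3-kb genes every 6 kb, leaving 2-kb flanks."""
    genes = []
    k = 0
    for scaf in sorted(scaffold_lengths):
        length = scaffold_lengths[scaf]
        start = 2000
        while start + 3000 + 2000 <= length:
            genes.append(
                GeneModel(f"gene_{k:04d}", scaf, start, start + 3000,
                          "+" if k % 2 == 0 else "-")
            )
            k += 1
            start += 6000
    return genes


def simulate_cross(cfg: SimConfig) -> TruthBundle:
    """Draw the full ground truth for one synthetic KS-style population.

    Per site a heritability class is drawn from ``class_frequencies``;
    parental states and the F1 state vector follow that class's
    generating rule.  Markers segregate Bernoulli(1/2) (lm x ll, nn x np)
    or Bernoulli(3/4) (hk x hk).  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    f1_ids = [f"F1_{i + 1:03d}" for i in range(cfg.n_f1)]
    pa_id, pb_id = cfg.parent_ids

    # --- site coordinates and reference sequences
    per_scaffold: dict[str, list[int]] = {s: [] for s in cfg.scaffold_lengths}
    names = sorted(cfg.scaffold_lengths)
    counts = {s: cfg.scaffold_lengths[s] // _SITE_SPACING for s in names}
    remaining = cfg.n_sites
    sites: list[GenomicSite] = []
    for scaf in names:
        take = min(remaining, counts[scaf])
        positions = [10 + i * _SITE_SPACING for i in range(take)]
        per_scaffold[scaf] = positions
        sites.extend(GenomicSite(scaf, p) for p in positions)
        remaining -= take
    sequences = {
        scaf: _scrub_and_plant(rng, cfg.scaffold_lengths[scaf], per_scaffold[scaf])
        for scaf in names
    }

    # --- methylation truth
    labels = [l for l in CLASS_LABELS if cfg.class_frequencies.get(l, 0.0) > 0]
    probs = np.array([cfg.class_frequencies[l] for l in labels])
    probs = probs / probs.sum()
    site_classes = [str(c) for c in rng.choice(labels, size=cfg.n_sites, p=probs)]
    parent_rows, f1_rows = [], []
    for label in site_classes:
        pa, pb, f1 = CLASS_GENERATORS[label](rng, cfg.n_f1)
        parent_rows.append((pa, pb))
        f1_rows.append(f1)
    index = pd.MultiIndex.from_tuples(
        [(s.scaffold_id, s.position) for s in sites], names=["scaffold", "position"]
    )
    parent_states = pd.DataFrame(parent_rows, index=index, columns=[pa_id, pb_id])
    f1_states = pd.DataFrame(np.vstack(f1_rows), index=index, columns=f1_ids)

    # --- markers
    mtypes = list(cfg.marker_type_probs)
    mprobs = np.array([cfg.marker_type_probs[t] for t in mtypes])
    mprobs = mprobs / mprobs.sum()
    marker_types = rng.choice(mtypes, size=cfg.n_markers, p=mprobs)
    meta_rows, call_rows = [], []
    for i, mtype in enumerate(marker_types):
        p_present = 0.75 if mtype == "hk_hk" else 0.5
        calls = (rng.random(cfg.n_f1) < p_present).astype(float)
        if cfg.marker_missing_rate > 0:
            calls[rng.random(cfg.n_f1) < cfg.marker_missing_rate] = np.nan
        meta_rows.append(
            {
                "marker_id": f"M{i + 1:05d}",
                "marker_type": mtype,
                "in_female": mtype in ("lm_ll", "hk_hk"),
                "in_male": mtype in ("nn_np", "hk_hk"),
                "read_support": 2 + int(rng.poisson(cfg.read_depth_mean)),
            }
        )
        call_rows.append(calls)
    marker_meta = pd.DataFrame(
        meta_rows,
        columns=["marker_id", "marker_type", "in_female", "in_male", "read_support"],
    )
    marker_calls = pd.DataFrame(
        np.vstack(call_rows) if call_rows else np.empty((0, cfg.n_f1)),
        index=marker_meta["marker_id"],
        columns=f1_ids,
    )

    return TruthBundle(
        config=cfg,
        sequences=sequences,
        sites=sites,
        site_classes=site_classes,
        parent_states=parent_states,
        f1_states=f1_states,
        genes=_tile_genes(cfg.scaffold_lengths),
        marker_meta=marker_meta,
        marker_calls=marker_calls,
    )


def simulate_evidence(
    truth: TruthBundle,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw dual-digest read evidence consistent with the true states.

    Per (sample, site), each enzyme library's read count is
    Poisson(read_depth_mean) floored at ``min_library_depth``; reads land
    in the category dictated by the true state (the noiseless expectation
    satisfies exactly one calling condition), then each read flips
    between its library's cleavage and body category with probability
    ``evidence_noise_rate``.
    """
    cfg = cfg or truth.config
    rng = rng or np.random.default_rng(cfg.seed + 1)
    states = truth.states
    n_sites, n_samples = states.shape
    vals = states.to_numpy()

    ch = np.maximum(rng.poisson(cfg.read_depth_mean, size=vals.shape),
                    cfg.min_library_depth)
    cm = np.maximum(rng.poisson(cfg.read_depth_mean, size=vals.shape),
                    cfg.min_library_depth)

    h_cleave = np.zeros(vals.shape, dtype=np.int64)
    h_body = np.zeros(vals.shape, dtype=np.int64)
    m_cleave = np.zeros(vals.shape, dtype=np.int64)
    m_body = np.zeros(vals.shape, dtype=np.int64)

    hemi = vals == HEMI
    full_c = vals == FULL_CMCGG
    full_m = vals == FULL_MCCGG
    unmeth = vals == UNMETHYLATED
    h_cleave[hemi | unmeth] = ch[hemi | unmeth]
    h_body[full_c | full_m] = ch[full_c | full_m]
    m_cleave[full_c | unmeth] = cm[full_c | unmeth]
    m_body[hemi | full_m] = cm[hemi | full_m]

    if cfg.evidence_noise_rate > 0:
        p = cfg.evidence_noise_rate
        flip_hc = rng.binomial(h_cleave, p)
        flip_hb = rng.binomial(h_body, p)
        flip_mc = rng.binomial(m_cleave, p)
        flip_mb = rng.binomial(m_body, p)
        h_cleave = h_cleave - flip_hc + flip_hb
        h_body = h_body - flip_hb + flip_hc
        m_cleave = m_cleave - flip_mc + flip_mb
        m_body = m_body - flip_mb + flip_mc

    scaffolds = states.index.get_level_values("scaffold")
    positions = states.index.get_level_values("position")
    frames = []
    for j, sample in enumerate(states.columns):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "scaffold": scaffolds,
                    "position": positions,
                    "h_cleave": h_cleave[:, j],
                    "m_cleave": m_cleave[:, j],
                    "h_body": h_body[:, j],
                    "m_body": m_body[:, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_phenotypes(
    truth: TruthBundle,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    extra_null_traits: Sequence[str] = (),
) -> pd.DataFrame:
    """F1 trait table with planted additive site effects.

    Each trait named in ``cfg.effect_sites`` is the sum of
    beta x score(site) over its effect sites plus Normal(0,
    trait_noise_sd) noise; ``extra_null_traits`` are pure noise.  Raises
    on effect sites outside the simulated site range.
    """
    cfg = cfg or truth.config
    rng = rng or np.random.default_rng(cfg.seed + 2)
    scores = truth.site_scores().to_numpy()
    n_sites, n_f1 = scores.shape

    traits: dict[str, np.ndarray] = {}
    for site_idx, trait_code, beta in cfg.effect_sites:
        if not (0 <= site_idx < n_sites):
            raise ValueError(f"effect site index {site_idx} out of range")
        traits.setdefault(trait_code, np.zeros(n_f1))
        traits[trait_code] = traits[trait_code] + beta * scores[site_idx]
    for trait_code in extra_null_traits:
        traits.setdefault(trait_code, np.zeros(n_f1))
    for trait_code in traits:
        traits[trait_code] = traits[trait_code] + rng.normal(
            0.0, cfg.trait_noise_sd, size=n_f1
        )
    return pd.DataFrame(traits, index=truth.f1_states.columns)


def discretize_levels(values: Sequence[float], n_levels: int = 5) -> np.ndarray:
    """Quantile-bin continuous values onto ordinal levels 0..n_levels-1.

    Used to turn simulated continuous liabilities into the 0-4 plant
    scores the level-index traits are built from.
    """
    v = np.asarray(values, dtype=float)
    qs = np.quantile(v, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.searchsorted(qs, v, side="right")
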