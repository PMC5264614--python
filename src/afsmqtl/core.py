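"""Core domain types, configuration and genomic plumbing.

The pipeline works on CCGG restriction sites assayed with the
methylation-sensitive isoschizomers HpaII and MspI.  Both enzymes
recognise 5'-CCGG-3' but differ in methylation sensitivity, so the
pattern of cleavage vs. protected ("body") reads across the two digests
encodes the methylation state of the site.

Coordinate conventions: everything internal is 0-based half-open.
``GenomicSite.position`` is the first C of CCGG on the forward strand;
the enzymes cut between the two Cs, i.e. at coordinate ``position + 1``.
Emitted BED is 0-based half-open; emitted GFF3 is 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("afsmqtl")

#: IUPAC nucleotide codes accepted in reference sequences.
IUPAC_DNA = set("ACGTRYSWKMBDHVN")

#: Columns of the tabular site-evidence interchange format (TSV).
EVIDENCE_COLUMNS = [
    "sample_id",
    "scaffold",
    "position",
    "h_cleave",
    "m_cleave",
    "h_body",
    "m_body",
]


def configure_logging(level: str = "INFO") -> None:
    """Set up the package logger for CLI / script use."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A CCGG site; ``position`` is the first C on the forward strand."""

    scaffold_id: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.scaffold_id:
            raise ValueError("scaffold_id must be non-empty")
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def cut_position(self) -> int:
        """The C^CGG cut coordinate (between the two Cs)."""
        return self.position + 1


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with a strand-aware upstream promoter span."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    promoter_span: int = 2000

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def promoter(self) -> tuple[int, int]:
        """Promoter interval (0-based half-open), upstream of the TSS."""
        if self.strand == "+":
            return (max(0, self.start - self.promoter_span), self.start)
        return (self.end, self.end + self.promoter_span)


@dataclass
class RunConfig:
    """Thresholds governing every pipeline stage.

    Defaults reflect the analysis this package implements: a methylated
    CCGG call needs >= 4 reads with >= 2 per enzyme library; population
    site classes use a 2/3 majority; sites must be identically methylated
    in >= 2 samples; DMR windows need >= 5 methylated differences at
    chi-squared p <= 0.05; epiQTL associations need >= 20 overlapping
    samples at p < 0.01; markers need > 50% call rate and a segregation
    goodness-of-fit p >= 0.01; the single-marker Kruskal-Wallis scan uses
    alpha = 0.001.
    """

    min_total_reads: int = 4
    min_reads_per_enzyme: int = 2
    majority_fraction: float = 2.0 / 3.0
    min_methylated_samples: int = 2
    dmr_window_bp: int = 1000
    dmr_min_diff: int = 5
    dmr_alpha: float = 0.05
    epiqtl_alpha: float = 0.01
    epiqtl_min_overlap: int = 20
    marker_presence_fraction: float = 0.5
    seg_alpha: float = 0.01
    kw_alpha: float = 0.001
    lod_threshold: float = 1.0
    max_grouping_rf: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_total_reads",
            "min_reads_per_enzyme",
            "min_methylated_samples",
            "dmr_window_bp",
            "dmr_min_diff",
            "epiqtl_min_overlap",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "majority_fraction",
            "dmr_alpha",
            "epiqtl_alpha",
            "marker_presence_fraction",
            "seg_alpha",
            "kw_alpha",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        import json

        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# CCGG site discovery
# ---------------------------------------------------------------------------

_NON_IUPAC = re.compile(r"[^ACGTRYSWKMBDHVN]")


def _as_sequence_mapping(reference) -> Mapping[str, str]:
    """Accept a FASTA path, a pyfaidx.Fasta, or a plain name->sequence mapping."""
    if isinstance(reference, (str, Path)):
        from pyfaidx import Fasta

        fasta = Fasta(str(reference), as_raw=True, sequence_always_upper=True)
        return {name: str(fasta[name][:]) for name in fasta.keys()}
    if hasattr(reference, "keys"):
        return {name: str(reference[name]).upper() for name in reference.keys()}
    raise TypeError(f"unsupported reference type: {type(reference)!r}")


def find_ccgg_sites(reference) -> list[GenomicSite]:
    """Locate every CCGG occurrence in a reference sequence set.

    CCGG is its own reverse complement, so a single forward-strand record
    per occurrence covers both strands.  Returns sites sorted by
    (scaffold, position).  Non-IUPAC characters raise ``ValueError``.
    """
    seqs = _as_sequence_mapping(reference)
    sites: list[GenomicSite] = []
    for name in sorted(seqs):
        seq = seqs[name].upper()
        bad = _NON_IUPAC.search(seq)
        if bad:
            raise ValueError(
                f"non-DNA character {bad.group()!r} in {name} at offset {bad.start()}"
            )
        start = seq.find("CCGG")
        while start != -1:
            sites.append(GenomicSite(name, start))
            start = seq.find("CCGG", start + 1)
    sites.sort()
    return sites


# ---------------------------------------------------------------------------
# Evidence extraction from alignments
# ---------------------------------------------------------------------------

ENZYMES = ("HpaII", "MspI")


def extract_evidence(
    alignments,
    sites: Sequence[GenomicSite],
    sample_id: str,
    enzyme: str,
) -> pd.DataFrame:
    """Count cleavage vs. body reads per CCGG site for one enzyme library.

    A read is CLEAVAGE evidence when its alignment starts or ends exactly
    at the C^CGG cut coordinate (``position + 1``), and BODY evidence when
    its aligned span covers the whole CCGG 4-mer internally.  Unmapped
    reads are ignored; reads on scaffolds absent from ``sites`` are
    skipped with a warning.

    Parameters
    ----------
    alignments : path to SAM/BAM or an open ``pysam.AlignmentFile``.
    enzyme : ``"HpaII"`` or ``"MspI"``.

    Returns a DataFrame with one row per site and the two count columns
    of this enzyme filled (the other enzyme's columns are 0).
    """
    import pysam

    if enzyme not in ENZYMES:
        raise ValueError(f"enzyme must be one of {ENZYMES}, got {enzyme!r}")
    cleave_col = "h_cleave" if enzyme == "HpaII" else "m_cleave"
    body_col = "h_body" if enzyme == "HpaII" else "m_body"

    by_scaffold: dict[str, np.ndarray] = {}
    for scaf, group in _sites_frame(sites).groupby("scaffold"):
        by_scaffold[scaf] = group["position"].to_numpy()

    cleave: dict[tuple[str, int], int] = {}
    body: dict[tuple[str, int], int] = {}
    unknown_scaffolds: set[str] = set()

    own_handle = isinstance(alignments, (str, Path))
    af = pysam.AlignmentFile(str(alignments)) if own_handle else alignments
    try:
        for read in af:
            if read.is_unmapped:
                continue
            scaf = read.reference_name
            positions = by_scaffold.get(scaf)
            if positions is None:
                unknown_scaffolds.add(scaf)
                continue
            rstart, rend = read.reference_start, read.reference_end
            # cut-coincident ends: cut = position + 1
            for cut in (rstart, rend):
                pos = cut - 1
                i = np.searchsorted(positions, pos)
                if i < len(positions) and positions[i] == pos:
                    key = (scaf, pos)
                    cleave[key] = cleave.get(key, 0) + 1
            # internally spanned sites: position >= rstart and position+4 <= rend,
            # excluding the cut-coincident ones counted above (a fully spanned
            # site can never have the read end at its cut coordinate).
            lo = np.searchsorted(positions, rstart)
            hi = np.searchsorted(positions, rend - 4, side="right")
            for pos in positions[lo:hi]:
                key = (scaf, int(pos))
                body[key] = body.get(key, 0) + 1
    finally:
        if own_handle:
            af.close()

    for scaf in sorted(unknown_scaffolds):
        logger.warning("reads on unknown scaffold %s skipped", scaf)

    out = _sites_frame(sites)
    out.insert(0, "sample_id", sample_id)
    for col in ("h_cleave", "m_cleave", "h_body", "m_body"):
        out[col] = 0
    keys = list(zip(out["scaffold"], out["position"]))
    out[cleave_col] = [cleave.get(k, 0) for k in keys]
    out[body_col] = [body.get(k, 0) for k in keys]
    return out[EVIDENCE_COLUMNS]


def combine_evidence(frames: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-enzyme evidence frames into one table per (sample, site).

    A sample with only one library present simply keeps zeros in the other
    enzyme's columns, which downstream calling turns into ``no_call``.
    """
    merged = pd.concat(list(frames), ignore_index=True)
    out = (
        merged.groupby(["sample_id", "scaffold", "position"], as_index=False)[
            ["h_cleave", "m_cleave", "h_body", "m_body"]
        ]
        .sum()
    )
    return out[EVIDENCE_COLUMNS]


def _sites_frame(sites: Sequence[GenomicSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": [s.scaffold_id for s in sites],
            "position": [s.position for s in sites],
        }
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read a TSV evidence table; validates columns and non-negative counts."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    counts = df[["h_cleave", "m_cleave", "h_body", "m_body"]]
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts in evidence table")
    return df[EVIDENCE_COLUMNS]


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    df[EVIDENCE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path, promoter_span: int = 2000) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open) or GFF3 (1-based)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=range(6),
            names=["scaffold", "start", "end", "gene_id", "score", "strand"],
        )
        return [
            GeneModel(r.gene_id, r.scaffold, int(r.start), int(r.end), r.strand,
                      promoter_span)
            for r in df.itertuples()
        ]
    if path.suffix.lower() in (".gff", ".gff3"):
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = []
        for feat in db.features_of_type("gene"):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            genes.append(
                GeneModel(
                    gene_id,
                    feat.seqid,
                    feat.start - 1,  # GFF3 is 1-based inclusive
                    feat.end,
                    feat.strand if feat.strand in ("+", "-") else "+",
                    promoter_span,
                )
            )
        return genes
    raise ValueError(f"unsupported gene-model format: {path.suffix}")


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold_id}\tafsmqtl\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sites_to_bed(sites: Sequence[GenomicSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": [s.scaffold_id for s in sites],
            "start": [s.position for s in sites],
            "end": [s.position + 4 for s in sites],
            "name": [f"CCGG_{s.scaffold_id}_{s.position}" for s in sites],
            "score": 0,
            "strand": [s.strand for s in sites],
        }
    )
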