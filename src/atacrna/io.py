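"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). GTF input,
which is 1-based inclusive, is converted at the boundary and converted back on
write. Every reader validates strictly and raises :class:`FormatError` with a
line number on malformed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: GENCODE biotypes recognised by the pipeline. The six non-coding classes
#: together form the "lncRNA" group used in coding/non-coding splits.
LNCRNA_BIOTYPES = frozenset(
    {
        "lincRNA",
        "antisense",
        "sense_intronic",
        "processed_transcript",
        "sense_overlapping",
        "TEC",
    }
)
KNOWN_BIOTYPES = frozenset({"protein_coding"}) | LNCRNA_BIOTYPES


class FormatError(ValueError):
    """A file violated its format contract."""


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted, overlapping/adjacent merged."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class GeneModel:
    """A gene with coordinates, strand, biotype and optional lncRNA target.

    Coordinates are 0-based half-open. ``tss`` is strand-aware: ``start`` on
    the plus strand, ``end`` on the minus strand. ``length_bp`` is the summed
    length of merged exons.
    """

    gene_id: str
    name: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    target_gene_id: str | None = None
    biotype_known: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand == ".":
            logger.warning("%s: strand '.' treated as '+' for TSS math", self.gene_id)
            self.strand = "+"
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = merge_intervals(self.exons) if self.exons else [(self.start, self.end)]
        if self.biotype not in KNOWN_BIOTYPES:
            self.biotype_known = False

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcript end site (the TTS), strand-aware."""
        return self.end if self.strand == "+" else self.start

    @property
    def length_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_lncrna(self) -> bool:
        return self.biotype in LNCRNA_BIOTYPES


@dataclass
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start >= self.end:
            raise ValueError(f"start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PWM:
    """Position probability matrix in A,C,G,T column order."""

    motif_id: str
    tf_name: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: probs must be L x 4 with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with per-sample metadata.

    ``meta`` is indexed by sample id and carries at least ``timepoint``,
    ``replicate`` and ``batch`` columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        self.meta = self.meta.loc[list(self.counts.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_at(self, timepoint: str) -> list[str]:
        return list(self.meta.index[self.meta["timepoint"] == timepoint])


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a 9-column GTF into one :class:`GeneModel` per gene_id.

    ``gene`` features define the span; ``exon`` features are aggregated and
    merged. GTF's 1-based inclusive coordinates become 0-based half-open.
    Unknown biotypes are retained but flagged via ``biotype_known``.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            chrom, _, feature, start, end, _, strand, _, attr_field = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            attrs = _parse_gtf_attrs(attr_field)
            if "gene_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            rec = genes.setdefault(
                gid,
                {
                    "name": attrs.get("gene_name", gid),
                    "chrom": chrom,
                    "strand": strand,
                    "start": None,
                    "end": None,
                    "biotype": attrs.get("gene_type", "unknown"),
                    "exons": [],
                    "target": attrs.get("target_gene_id"),
                },
            )
            s0, e0 = start_i - 1, end_i  # GTF 1-based inclusive -> half-open
            if feature == "gene":
                rec["start"], rec["end"] = s0, e0
                rec["biotype"] = attrs.get("gene_type", rec["biotype"])
                if attrs.get("target_gene_id"):
                    rec["target"] = attrs["target_gene_id"]
            elif feature == "exon":
                rec["exons"].append((s0, e0))
            rec["start"] = s0 if rec["start"] is None else min(rec["start"], s0)
            rec["end"] = e0 if rec["end"] is None else max(rec["end"], e0)
    out = []
    for gid, rec in genes.items():
        out.append(
            GeneModel(
                gene_id=gid,
                name=rec["name"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=rec["start"],
                end=rec["end"],
                biotype=rec["biotype"],
                exons=rec["exons"],
                target_gene_id=rec["target"],
            )
        )
    return out


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene and exon GTF records (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}"; gene_type "{g.biotype}";'
            if g.target_gene_id:
                attrs += f' target_gene_id "{g.target_gene_id}";'
            fh.write(
                f"{g.chrom}\tatacrna\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tatacrna\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED / narrowPeak

_NARROWPEAK_EXTRA = ("signalValue", "pValue", "qValue", "summit")


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak. Records with start >= end are dropped
    (counted in the log); narrowPeak columns 7-10 land in ``attrs``."""
    out: list[GenomicInterval] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                rejected += 1
                continue
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            attrs = {}
            if len(parts) >= 10:  # narrowPeak
                for key, val in zip(_NARROWPEAK_EXTRA, parts[6:10]):
                    attrs[key] = float(val) if key != "summit" else int(val)
            out.append(GenomicInterval(chrom, start, end, name, score, strand, attrs))
    if rejected:
        logger.warning("%s: rejected %d records with start >= end", path, rejected)
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols += [
                    iv.name or ".",
                    "." if iv.score is None else f"{iv.score:g}",
                    iv.strand or ".",
                ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# MEME motif format


def read_pwms(path: str | Path) -> list[PWM]:
    """Parse a (minimal) MEME motif file with an ACGT alphabet.

    Probability rows summing within 1e-3 of 1 are renormalised; anything
    further off is a format error. The file-level background line, when
    present, is attached to every motif.
    """
    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    motif_id: str | None = None
    tf_name = ""
    rows: list[list[float]] = []
    expect_bg = False
    in_matrix = False

    def flush() -> None:
        nonlocal motif_id, rows, in_matrix
        if motif_id is not None:
            if not rows:
                raise FormatError(f"{path}: motif {motif_id} has no probability matrix")
            pwms.append(PWM(motif_id, tf_name or motif_id, np.array(rows), background.copy()))
        motif_id, rows, in_matrix = None, [], False

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if expect_bg and stripped:
                toks = stripped.split()
                freqs = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks), 2)}
                background = np.array([freqs.get(b, 0.25) for b in "ACGT"])
                expect_bg = False
                continue
            if stripped.startswith("Background letter frequencies"):
                expect_bg = True
                continue
            if stripped.startswith("ALPHABET=") and "ACGT" not in stripped:
                raise FormatError(f"{path}:{lineno}: alphabet must be ACGT")
            if stripped.startswith("MOTIF"):
                flush()
                toks = stripped.split()
                motif_id = toks[1]
                tf_name = toks[2] if len(toks) > 2 else toks[1]
                continue
            if stripped.startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                if not stripped or stripped.startswith("URL"):
                    in_matrix = False
                    continue
                vals = [float(x) for x in stripped.split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 probabilities")
                total = sum(vals)
                if abs(total - 1.0) > 1e-3:
                    raise FormatError(
                        f"{path}:{lineno}: probability row sums to {total:.6f}"
                    )
                rows.append([v / total for v in vals])
    flush()
    return pwms


def write_pwms(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id} {p.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(p)} nsites= 20 E= 0\n"
            )
            for row in p.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT lines need >= 3 fields")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gene_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Count tables


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV and its sample metadata table.

    Counts must be non-negative integers; every sample in the header must
    appear in the metadata.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"{counts_path}: non-integer counts")
        df = df.round().astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{counts_path}: negative counts")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    missing = set(df.columns) - set(meta.index)
    if missing:
        raise FormatError(f"{counts_path}: samples missing metadata: {sorted(missing)}")
    return CountMatrix(df, meta)


def write_counts(cm: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# FASTA (promoter sequences)


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
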