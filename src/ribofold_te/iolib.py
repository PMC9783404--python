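"""Readers and writers for every external artifact of the pipeline.

All on-disk formats are plain text: FASTA for transcript sequences, and
tab-delimited tables for region annotations, per-nucleotide reactivity
tracks, read counts, feature matrices and result tables.

Conventions
-----------
* Transcript coordinates are 0-based half-open; a transcript is the
  concatenation 5'UTR + CDS + 3'UTR.
* Sequences are canonicalized to the DNA alphabet on read (U -> T).
* ``NA`` (case-insensitive) is the only missing-value token in reactivity
  tracks; in memory, missing values are ``numpy.nan``.
* Invariant violations are rejected per record (and logged); structural
  file problems (missing columns, id mismatches between paired inputs)
  are hard errors.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ribofold_te")

VALID_ALPHABET = frozenset("ACGTN")
CONDITIONS = ("vivo", "vitro")

#: order in which region scopes appear everywhere downstream
REGIONS = ("utr5", "cds", "utr3")


class ValidationError(ValueError):
    """Raised when an input file or record violates a format contract."""


def canonical_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and map U to T (DNA alphabet)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_ALPHABET
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript sequence with its three-region annotation.

    Regions are contiguous and ordered 5'UTR -> CDS -> 3'UTR;
    ``len_utr5 + len_cds + len_utr3`` must equal the sequence length and
    the CDS length must be a multiple of 3 (when non-zero).
    """

    transcript_id: str
    sequence: str
    len_utr5: int
    len_cds: int
    len_utr3: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", canonical_sequence(self.sequence))
        for name in ("len_utr5", "len_cds", "len_utr3"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{self.transcript_id}: {name} must be a non-negative integer, got {v!r}")
        total = self.len_utr5 + self.len_cds + self.len_utr3
        if total != len(self.sequence):
            raise ValidationError(
                f"{self.transcript_id}: region lengths sum to {total} but sequence has {len(self.sequence)} nt"
            )
        if self.len_cds > 0 and self.len_cds % 3 != 0:
            raise ValidationError(f"{self.transcript_id}: CDS length {self.len_cds} is not a multiple of 3")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def region_bounds(self, region: str) -> tuple[int, int]:
        """Half-open [start, end) bounds of ``utr5``/``cds``/``utr3``/``whole``."""
        if region == "whole":
            return 0, self.length
        if region == "utr5":
            return 0, self.len_utr5
        if region == "cds":
            return self.len_utr5, self.len_utr5 + self.len_cds
        if region == "utr3":
            return self.len_utr5 + self.len_cds, self.length
        raise ValueError(f"unknown region {region!r}")

    def region_seq(self, region: str) -> str:
        a, b = self.region_bounds(region)
        return self.sequence[a:b]

    @property
    def cds(self) -> str:
        return self.region_seq("cds")


@dataclass(frozen=True)
class ReactivityTrack:
    """Per-nucleotide probing reactivities for one transcript and condition.

    ``values`` is a float array, one entry per nucleotide 5'->3', with
    ``nan`` marking missing nucleotides; non-missing values are >= 0.
    """

    transcript_id: str
    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValidationError(f"{self.transcript_id}: reactivity track must be a non-empty 1-D array")
        if np.any(v[~np.isnan(v)] < 0):
            raise ValidationError(f"{self.transcript_id}: negative reactivity value")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CountRecord:
    """Ribo-seq and RNA-seq read counts for one transcript."""

    transcript_id: str
    ribo_count: int
    rna_count: int

    def __post_init__(self) -> None:
        for name in ("ribo_count", "rna_count"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"{self.transcript_id}: {name} must be a non-negative integer, got {v!r}")


# ---------------------------------------------------------------------------
# transcripts: FASTA + region table
# ---------------------------------------------------------------------------

def read_transcripts(fasta_path: str | Path, regions_path: str | Path) -> list[TranscriptModel]:
    """Read transcript sequences (FASTA) and their region table (TSV).

    The region table is tab-delimited with header
    ``transcript_id, len_utr5, len_cds, len_utr3``. Ids present in only one
    of the two inputs are a hard error; records violating the
    :class:`TranscriptModel` invariants are rejected individually with a
    logged reason.
    """
    fasta_path, regions_path = Path(fasta_path), Path(regions_path)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValidationError(f"{fasta_path}: no FASTA records")
    regions = pd.read_csv(regions_path, sep="\t", dtype={"transcript_id": str})
    required = ["transcript_id", "len_utr5", "len_cds", "len_utr3"]
    missing_cols = [c for c in required if c not in regions.columns]
    if missing_cols:
        raise ValidationError(f"{regions_path}: missing columns {missing_cols}")

    fasta_ids = set(seqs)
    table_ids = set(regions["transcript_id"])
    only_fasta = sorted(fasta_ids - table_ids)
    only_table = sorted(table_ids - fasta_ids)
    if only_fasta or only_table:
        raise ValidationError(
            f"id mismatch between {fasta_path.name} and {regions_path.name}: "
            f"FASTA-only={only_fasta[:10]} table-only={only_table[:10]}"
        )

    out: list[TranscriptModel] = []
    n_rejected = 0
    for row in regions.itertuples(index=False):
        tid = row.transcript_id
        try:
            out.append(
                TranscriptModel(tid, seqs[tid], int(row.len_utr5), int(row.len_cds), int(row.len_utr3))
            )
        except (ValidationError, ValueError) as exc:
            n_rejected += 1
            logger.warning("rejecting transcript %s: %s", tid, exc)
    if n_rejected:
        logger.warning("rejected %d/%d transcripts", n_rejected, len(regions))
    return out


def write_transcripts(
    transcripts: Sequence[TranscriptModel], fasta_path: str | Path, regions_path: str | Path
) -> None:
    records = [SeqRecord(Seq(t.sequence), id=t.transcript_id, description="") for t in transcripts]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "len_utr5": [t.len_utr5 for t in transcripts],
            "len_cds": [t.len_cds for t in transcripts],
            "len_utr3": [t.len_utr3 for t in transcripts],
        }
    ).to_csv(regions_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reactivity tracks
# ---------------------------------------------------------------------------

def read_reactivity(track_path: str | Path, condition: str) -> list[ReactivityTrack]:
    """Read a reactivity track file.

    Format: one transcript per line, ``transcript_id TAB v1,v2,...`` with
    the token ``NA`` for a missing nucleotide. Negative values and empty
    tracks are hard errors; a length mismatch against the transcript is
    detected downstream where transcripts are available.
    """
    tracks: list[ReactivityTrack] = []
    with open(track_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{track_path}:{lineno}: expected 2 tab-separated fields")
            tid, payload = parts
            if payload == "":
                raise ValidationError(f"{track_path}:{lineno}: empty reactivity track for {tid}")
            values = np.array(
                [math.nan if tok.upper() == "NA" else float(tok) for tok in payload.split(",")]
            )
            tracks.append(ReactivityTrack(tid, condition, values))
    return tracks


def write_reactivity(tracks: Sequence[ReactivityTrack], track_path: str | Path) -> None:
    with open(track_path, "w") as fh:
        for tr in tracks:
            toks = ["NA" if math.isnan(v) else format(v, ".6g") for v in tr.values]
            fh.write(f"{tr.transcript_id}\t{','.join(toks)}\n")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

_TOTALS_RE = re.compile(r"#\s*ribo_total\s*=\s*(\d+)\s+rna_total\s*=\s*(\d+)")


def read_counts(
    counts_path: str | Path,
    ribo_total: int | None = None,
    rna_total: int | None = None,
) -> tuple[list[CountRecord], int, int]:
    """Read a per-transcript count table; returns records and library sizes.

    The file is tab-delimited with header ``transcript_id, ribo_count,
    rna_count`` and may carry library sizes in a comment line
    ``#ribo_total=<int> rna_total=<int>``. Explicit arguments win over the
    header comment. Totals must be positive; counts must be non-negative
    integers.
    """
    header_totals: tuple[int, int] | None = None
    with open(counts_path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = _TOTALS_RE.match(line.strip())
                if m:
                    header_totals = (int(m.group(1)), int(m.group(2)))
            else:
                break
    if ribo_total is None:
        ribo_total = header_totals[0] if header_totals else None
    if rna_total is None:
        rna_total = header_totals[1] if header_totals else None
    if ribo_total is None or rna_total is None:
        raise ValidationError(f"{counts_path}: library totals missing (no header comment and no flags)")
    if ribo_total <= 0 or rna_total <= 0:
        raise ValidationError(f"{counts_path}: library totals must be > 0, got {ribo_total}, {rna_total}")

    df = pd.read_csv(counts_path, sep="\t", comment="#", dtype={"transcript_id": str})
    for col in ("transcript_id", "ribo_count", "rna_count"):
        if col not in df.columns:
            raise ValidationError(f"{counts_path}: missing column {col}")
    records: list[CountRecord] = []
    for row in df.itertuples(index=False):
        for v in (row.ribo_count, row.rna_count):
            if float(v) != int(v) or v < 0:
                raise ValidationError(
                    f"{counts_path}: count for {row.transcript_id} must be a non-negative integer, got {v!r}"
                )
        records.append(CountRecord(row.transcript_id, int(row.ribo_count), int(row.rna_count)))
    return records, int(ribo_total), int(rna_total)


def write_counts(
    records: Sequence[CountRecord], counts_path: str | Path, ribo_total: int, rna_total: int
) -> None:
    with open(counts_path, "w") as fh:
        fh.write(f"#ribo_total={ribo_total} rna_total={rna_total}\n")
        fh.write("transcript_id\tribo_count\trna_count\n")
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.ribo_count}\t{r.rna_count}\n")


# ---------------------------------------------------------------------------
# feature matrices and generic tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write any result table as a TSV with header."""
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a transcripts-x-features TSV (index column ``transcript_id``)."""
    return pd.read_csv(path, sep="\t", index_col="transcript_id", na_values=["NA"])


def feature_groups(names: Iterable[str]) -> dict[str, str]:
    """Assign every feature name to its group by naming convention.

    ``seq_*`` -> sequence, ``vivo_*`` -> vivo, ``vitro_*`` -> vitro,
    ``insilico_*`` -> insilico. Unrecognized names are an error: the group
    registry is closed.
    """
    groups: dict[str, str] = {}
    for name in names:
        prefix = name.split("_", 1)[0]
        if prefix == "seq":
            groups[name] = "sequence"
        elif prefix in ("vivo", "vitro", "insilico"):
            groups[name] = prefix
        else:
            raise ValidationError(f"feature {name!r} does not belong to a registered group")
    return groups
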