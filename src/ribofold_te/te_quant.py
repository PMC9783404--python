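"""Translation-efficiency quantification and high/low class definition.

TE of a transcript is the log2 ratio of its ribosome-footprint abundance
(Ribo-seq RPKM) to its mRNA abundance (RNA-seq RPKM). Lowly expressed
transcripts (RNA-seq RPKM not above a threshold, default 1) are excluded
to avoid extreme TE values; the top and bottom quantiles (default 25%)
of the remaining TE distribution become the high/low classes for the
classification problem, and intermediate transcripts are dropped from
modeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .iolib import CountRecord, TranscriptModel

TE_CLASSES = ("high", "low", "intermediate", "excluded")


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    rpkm_ribo: float
    rpkm_rna: float
    te: float  # nan when undefined
    te_class: str = "excluded"

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"invalid te_class {self.te_class!r}")


def compute_rpkm(count: int, transcript_length: int, library_total: int) -> float:
    """Reads per kilobase per million: count * 1e9 / (length * total)."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be > 0")
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count * 1e9 / (transcript_length * library_total)


def compute_te(rpkm_ribo: float, rpkm_rna: float) -> float:
    """log2(rpkm_ribo / rpkm_rna); both arguments must be positive."""
    if rpkm_ribo <= 0 or rpkm_rna <= 0:
        raise ValueError("TE requires positive RPKM in both libraries")
    return math.log2(rpkm_ribo / rpkm_rna)


def quantify(
    counts: Sequence[CountRecord],
    transcripts: Sequence[TranscriptModel] | Mapping[str, int],
    ribo_total: int,
    rna_total: int,
    length_mode: str = "transcript",
) -> list[ExpressionRecord]:
    """Compute per-transcript RPKMs and TE.

    ``length_mode`` selects the RPKM length denominator: the full
    transcript length (default) or the CDS length. Transcripts with zero
    ribosome counts get no TE (class stays ``excluded``; a -inf TE would
    poison downstream features).
    """
    if length_mode not in ("transcript", "cds"):
        raise ValueError(f"length_mode must be 'transcript' or 'cds', got {length_mode!r}")
    if isinstance(transcripts, Mapping):
        lengths = dict(transcripts)
    else:
        lengths = {
            t.transcript_id: (t.length if length_mode == "transcript" else t.len_cds)
            for t in transcripts
        }
    records = []
    for c in counts:
        if c.transcript_id not in lengths:
            raise KeyError(f"no transcript length for {c.transcript_id}")
        length = lengths[c.transcript_id]
        rpkm_ribo = compute_rpkm(c.ribo_count, length, ribo_total)
        rpkm_rna = compute_rpkm(c.rna_count, length, rna_total) if c.rna_count else 0.0
        te = (
            compute_te(rpkm_ribo, rpkm_rna)
            if rpkm_ribo > 0 and rpkm_rna > 0
            else math.nan
        )
        records.append(ExpressionRecord(c.transcript_id, rpkm_ribo, rpkm_rna, te))
    return records


def filter_expressed(
    records: Sequence[ExpressionRecord], threshold: float = 1.0
) -> list[ExpressionRecord]:
    """Mark the expression filter: retain rpkm_rna strictly above ``threshold``.

    Retained records (which also need a defined TE, i.e. non-zero ribosome
    signal) are provisionally labeled ``intermediate``; everything else is
    ``excluded``. Class assignment within the retained set is done by
    :func:`select_te_groups`.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = []
    for r in records:
        keep = r.rpkm_rna > threshold and not math.isnan(r.te)
        out.append(replace(r, te_class="intermediate" if keep else "excluded"))
    return out


def select_te_groups(
    records: Sequence[ExpressionRecord], q: float = 0.25
) -> list[ExpressionRecord]:
    """Label the top/bottom TE quantiles as the high/low classes.

    Among the N records with a defined TE that passed the expression
    filter, exactly ``floor(q*N)`` with the highest TE become ``high`` and
    ``floor(q*N)`` with the lowest become ``low``; the rest stay
    ``intermediate`` (removed from modeling). Ties at the quantile
    boundary are broken by lexicographic transcript_id so the labeling is
    deterministic.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    eligible = [r for r in records if r.te_class != "excluded" and not math.isnan(r.te)]
    n = len(eligible)
    if n < 4:
        raise ValueError(f"need at least 4 records with defined TE to form both classes, got {n}")
    k = int(q * n)  # floor for positive q*n
    ranked = sorted(eligible, key=lambda r: (r.te, r.transcript_id))
    low_ids = {r.transcript_id for r in ranked[:k]}
    high_ids = {r.transcript_id for r in ranked[n - k:]}
    out = []
    for r in records:
        if r.transcript_id in high_ids:
            out.append(replace(r, te_class="high"))
        elif r.transcript_id in low_ids:
            out.append(replace(r, te_class="low"))
        else:
            out.append(r)
    return out
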