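"""Sequence-derived features of a transcript.

The default registry covers nucleotide frequency and GC content in four
scopes (whole transcript, 5'UTR, CDS, 3'UTR), in-frame codon and amino
acid frequencies, codon/amino-acid repetitive rates, and the region
lengths — 111 named features in total, all in the ``sequence`` group.

Registry format: mapping family name -> list of scopes (for scoped
families) or ``True`` (for CDS-bound and length families). Extraction is
a pure function of (transcript, registry); missing features (empty
scopes, too-short CDS) are ``nan`` and imputed downstream inside each
train/test split.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .iolib import TranscriptModel

NUCLEOTIDES = "ACGT"
SCOPES = ("whole", "utr5", "cds", "utr3")
CODONS = tuple("".join(c) for c in product(NUCLEOTIDES, repeat=3))
#: the 20 amino acids plus stop ('*') as the 21st symbol
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)

DEFAULT_REGISTRY: dict[str, object] = {
    "nucleotide_frequency": list(SCOPES),
    "gc_content": list(SCOPES),
    "codon_frequency": True,
    "amino_acid_frequency": True,
    "codon_repetitive_rate": True,
    "amino_acid_repetitive_rate": True,
    "lengths": True,
}

_KNOWN_FAMILIES = set(DEFAULT_REGISTRY)


def nucleotide_frequency(seq: str, scope_name: str = "whole") -> dict[str, float]:
    """Fraction of A/C/G/T in a scope; N bases are excluded entirely."""
    counts = {b: seq.count(b) for b in NUCLEOTIDES}
    denom = sum(counts.values())
    return {
        f"seq_nucfreq_{scope_name}_{b}": (counts[b] / denom if denom else math.nan)
        for b in NUCLEOTIDES
    }


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); nan on an empty (or all-N) scope."""
    denom = sum(seq.count(b) for b in NUCLEOTIDES)
    if denom == 0:
        return math.nan
    return (seq.count("G") + seq.count("C")) / denom


def codons_of(cds: str) -> list[str]:
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError("CDS must be non-empty and a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def codon_frequency(cds: str) -> dict[str, float]:
    """In-frame codon usage: occurrences / (len(cds)/3), over all 64 codons.

    Codons containing N are dropped from numerator and denominator.
    """
    cod = [c for c in codons_of(cds) if "N" not in c]
    n = len(cod)
    counts: dict[str, int] = {}
    for c in cod:
        counts[c] = counts.get(c, 0) + 1
    return {f"seq_codonfreq_{c}": (counts.get(c, 0) / n if n else math.nan) for c in CODONS}


def amino_acid_frequency(cds: str) -> dict[str, float]:
    """Per-amino-acid fraction of the translated CDS (standard code, stop = '*')."""
    cod = [c for c in codons_of(cds) if "N" not in c]
    aas = [str(Seq(c).translate()) for c in cod]
    n = len(aas)
    counts: dict[str, int] = {}
    for a in aas:
        counts[a] = counts.get(a, 0) + 1
    return {
        f"seq_aafreq_{'stop' if a == '*' else a}": (counts.get(a, 0) / n if n else math.nan)
        for a in AMINO_ACIDS
    }


def repetitive_rate(symbols: Sequence[str]) -> float:
    """Fraction of adjacent identical pairs: (# i with s[i]==s[i+1]) / (len-1).

    1 iff all symbols identical; 0 iff no adjacent repeats; nan for fewer
    than two symbols.
    """
    if len(symbols) < 2:
        return math.nan
    same = sum(1 for a, b in zip(symbols, symbols[1:]) if a == b)
    return same / (len(symbols) - 1)


def length_features(t: TranscriptModel) -> dict[str, float]:
    return {
        "seq_len_utr5": float(t.len_utr5),
        "seq_len_cds": float(t.len_cds),
        "seq_len_utr3": float(t.len_utr3),
        "seq_len_total": float(t.length),
    }


def sequence_feature_names(registry: Mapping[str, object] | None = None) -> list[str]:
    """Deterministic feature-name order for a registry (default: 111 names)."""
    registry = DEFAULT_REGISTRY if registry is None else registry
    names: list[str] = []
    for family, cfg in registry.items():
        if family not in _KNOWN_FAMILIES:
            raise ValueError(f"unknown feature family {family!r}")
        if not cfg:
            continue
        if family == "nucleotide_frequency":
            names += [f"seq_nucfreq_{s}_{b}" for s in cfg for b in NUCLEOTIDES]
        elif family == "gc_content":
            names += [f"seq_gc_{s}" for s in cfg]
        elif family == "codon_frequency":
            names += [f"seq_codonfreq_{c}" for c in CODONS]
        elif family == "amino_acid_frequency":
            names += [f"seq_aafreq_{'stop' if a == '*' else a}" for a in AMINO_ACIDS]
        elif family == "codon_repetitive_rate":
            names.append("seq_codon_repeat_rate")
        elif family == "amino_acid_repetitive_rate":
            names.append("seq_aa_repeat_rate")
        elif family == "lengths":
            names += ["seq_len_utr5", "seq_len_cds", "seq_len_utr3", "seq_len_total"]
    return names


def assemble_sequence_features(
    t: TranscriptModel, registry: Mapping[str, object] | None = None
) -> dict[str, float]:
    """All sequence features of one transcript, in registry order."""
    registry = DEFAULT_REGISTRY if registry is None else registry
    values: dict[str, float] = {}
    has_cds = t.len_cds >= 3
    cod = codons_of(t.cds) if has_cds else []
    for family, cfg in registry.items():
        if family not in _KNOWN_FAMILIES:
            raise ValueError(f"unknown feature family {family!r}")
        if not cfg:
            continue
        if family == "nucleotide_frequency":
            for s in cfg:
                values.update(nucleotide_frequency(t.region_seq(s), s))
        elif family == "gc_content":
            for s in cfg:
                values[f"seq_gc_{s}"] = gc_content(t.region_seq(s))
        elif family == "codon_frequency":
            if has_cds:
                values.update(codon_frequency(t.cds))
            else:
                values.update({f"seq_codonfreq_{c}": math.nan for c in CODONS})
        elif family == "amino_acid_frequency":
            if has_cds:
                values.update(amino_acid_frequency(t.cds))
            else:
                values.update(
                    {f"seq_aafreq_{'stop' if a == '*' else a}": math.nan for a in AMINO_ACIDS}
                )
        elif family == "codon_repetitive_rate":
            values["seq_codon_repeat_rate"] = repetitive_rate(cod)
        elif family == "amino_acid_repetitive_rate":
            aas = [str(Seq(c).translate()) for c in cod]
            values["seq_aa_repeat_rate"] = repetitive_rate(aas)
        elif family == "lengths":
            values.update(length_features(t))
    return values


def sequence_feature_table(
    transcripts: Iterable[TranscriptModel], registry: Mapping[str, object] | None = None
) -> pd.DataFrame:
    """Transcripts x sequence-features DataFrame (index: transcript_id)."""
    names = sequence_feature_names(registry)
    rows = {t.transcript_id: assemble_sequence_features(t, registry) for t in transcripts}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "transcript_id"
    return df[names]
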