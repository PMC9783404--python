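"""Structural features: meta-gene binned reactivities and folding energies.

A transcript of arbitrary length is compressed to a fixed 60-bin profile
(20 bins per region: bins 0-19 = 5'UTR, 20-39 = CDS, 40-59 = 3'UTR) so
that transcripts of different lengths are comparable; each bin holds the
mean reactivity of the nucleotides it covers. The CDS head (first six
codons, 18 nt) gets its own summary feature per probing condition, the
region classically tied to initiation-limited translation.

In silico features come from a built-in base-pair-maximization folder
(Watson-Crick + G.U wobble pairs, hairpin loops of at least ``min_loop``
unpaired nucleotides, energy = -1 per pair). An adapter accepts a table
of externally computed minimum free energies (e.g. from a thermodynamic
nearest-neighbor folder) which then replaces the built-in values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .iolib import REGIONS, ReactivityTrack, TranscriptModel, ValidationError

logger = logging.getLogger("ribofold_te")

BINS_PER_REGION = 20
N_CODONS_HEAD = 6
MFE_SCOPES = ("whole", "utr5", "cds", "utr3", "cds_head")


@dataclass(frozen=True)
class MetaGeneProfile:
    """Length-normalized reactivity profile: ``bins_per_region`` bins per region."""

    transcript_id: str
    condition: str
    bins: np.ndarray  # length 3 * bins_per_region, nan = missing

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        if b.ndim != 1 or b.size % 3 != 0:
            raise ValidationError("profile must be 1-D with a multiple of 3 bins")
        if np.any(b[~np.isnan(b)] < 0):
            raise ValidationError("negative bin reactivity")
        object.__setattr__(self, "bins", b)

    @property
    def bins_per_region(self) -> int:
        return self.bins.size // 3


def bin_edges(length: int, n_bins: int) -> np.ndarray:
    """Floor-based bin boundaries: bin k covers [floor(kL/B), floor((k+1)L/B)).

    The edges partition [0, length) exactly; bins may be empty when
    length < n_bins.
    """
    return np.floor(np.arange(n_bins + 1) * length / n_bins).astype(int)


def bin_profile(
    track: ReactivityTrack, t: TranscriptModel, bins_per_region: int = BINS_PER_REGION
) -> MetaGeneProfile:
    """Average a per-nucleotide track into the fixed meta-gene bins.

    A bin with no nucleotides (region shorter than ``bins_per_region``) or
    with only missing values is missing (nan).
    """
    if len(track) != t.length:
        raise ValidationError(
            f"{t.transcript_id}: track length {len(track)} != transcript length {t.length}"
        )
    out = np.full(3 * bins_per_region, np.nan)
    for r_idx, region in enumerate(REGIONS):
        start, end = t.region_bounds(region)
        L = end - start
        if L == 0:
            continue
        edges = bin_edges(L, bins_per_region) + start
        for k in range(bins_per_region):
            chunk = track.values[edges[k] : edges[k + 1]]
            if chunk.size and not np.all(np.isnan(chunk)):
                out[r_idx * bins_per_region + k] = np.nanmean(chunk)
    return MetaGeneProfile(t.transcript_id, track.condition, out)


def cds_head_reactivity(
    track: ReactivityTrack, t: TranscriptModel, n_codons: int = N_CODONS_HEAD
) -> float:
    """Mean reactivity over the first ``n_codons`` codons (3*n nt) of the CDS."""
    n_nt = 3 * n_codons
    if t.len_cds < n_nt:
        return math.nan
    start, _ = t.region_bounds("cds")
    chunk = track.values[start : start + n_nt]
    if np.all(np.isnan(chunk)):
        return math.nan
    return float(np.nanmean(chunk))


# ---------------------------------------------------------------------------
# built-in folder: base-pair maximization
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
# Watson-Crick + G.U wobble
_PAIRS = ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2))


def _nussinov_kernel(can: np.ndarray, min_loop: int) -> int:
    """Max number of nested pairs given the pairability matrix ``can``.

    Plain nested loops so the kernel can be jit-compiled; ``M`` is padded
    by one row/column so M[k+1, j] is valid at k == j.
    """
    n = can.shape[0]
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = M[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can[i, k]:
                    cand = 1 + M[i + 1, k - 1] + M[k + 1, j]
                    if cand > best:
                        best = cand
            M[i, j] = best
    return int(M[0, n - 1])


try:  # jit the DP when numba is around; the pure-Python kernel is identical
    from numba import njit as _njit

    _nussinov_fast = _njit(cache=False)(_nussinov_kernel)
except ImportError:  # pragma: no cover
    _nussinov_fast = _nussinov_kernel


def fold_mfe(seq: str, min_loop: int = 3) -> float:
    """Minimum 'energy' of ``seq`` under base-pair maximization: -(max pairs).

    Dynamic program over nested (pseudoknot-free) structures; a pair
    (i, j) requires at least ``min_loop`` unpaired positions between i and
    j. Sequences too short to pair fold to 0.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    code = np.array([_BASE_CODE[b] for b in seq.upper()], dtype=np.int8)
    can = np.zeros((n, n), dtype=np.bool_)
    for a, b in _PAIRS:
        can |= (code[:, None] == a) & (code[None, :] == b)
    return -float(_nussinov_fast(can, min_loop))


def mfe_features(
    t: TranscriptModel,
    min_loop: int = 3,
    n_codons_head: int = N_CODONS_HEAD,
    external: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-scope folding energies, raw and per-nucleotide (10 features).

    Scopes: whole transcript, the three regions, and the CDS head. When
    ``external`` provides a scope's energy (from an external folder's
    output table) it replaces the built-in value.
    """
    values: dict[str, float] = {}
    cds_start, _ = t.region_bounds("cds")
    head_len = 3 * n_codons_head
    for scope in MFE_SCOPES:
        if scope == "cds_head":
            seq = t.sequence[cds_start : cds_start + head_len] if t.len_cds >= head_len else ""
        else:
            seq = t.region_seq(scope)
        if external is not None and scope in external:
            e = float(external[scope])
        elif seq:
            e = fold_mfe(seq, min_loop=min_loop)
        else:
            e = math.nan
        values[f"insilico_mfe_{scope}"] = e
        values[f"insilico_mfe_{scope}_per_nt"] = e / len(seq) if seq else math.nan
    return values


def import_external_mfe(table_path: str | Path) -> dict[str, dict[str, float]]:
    """Read externally computed per-scope MFEs (kcal/mol) keyed by transcript.

    TSV columns: ``transcript_id`` plus ``mfe_<scope>`` for each scope in
    :data:`MFE_SCOPES`. Positive energies are invalid.
    """
    df = pd.read_csv(table_path, sep="\t", dtype={"transcript_id": str})
    missing = [s for s in MFE_SCOPES if f"mfe_{s}" not in df.columns]
    if missing:
        raise ValidationError(f"{table_path}: missing MFE columns for scopes {missing}")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        energies = {s: float(getattr(row, f"mfe_{s}")) for s in MFE_SCOPES}
        for s, e in energies.items():
            if not math.isnan(e) and e > 0:
                raise ValidationError(f"{table_path}: positive MFE {e} for {row.transcript_id}/{s}")
        out[row.transcript_id] = energies
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def structural_feature_names(bins_per_region: int = BINS_PER_REGION) -> list[str]:
    """Default structural registry: 60+60 bins, 2 CDS heads, 10 MFEs = 132."""
    n = 3 * bins_per_region
    names = [f"vivo_bin_{k:02d}" for k in range(n)]
    names += [f"vitro_bin_{k:02d}" for k in range(n)]
    names += ["vivo_cds_head", "vitro_cds_head"]
    for scope in MFE_SCOPES:
        names += [f"insilico_mfe_{scope}", f"insilico_mfe_{scope}_per_nt"]
    return names


def assemble_structural_features(
    t: TranscriptModel,
    tracks: Mapping[str, ReactivityTrack],
    bins_per_region: int = BINS_PER_REGION,
    n_codons_head: int = N_CODONS_HEAD,
    min_loop: int = 3,
    external_mfe: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """All structural features of one transcript.

    ``tracks`` maps condition -> ReactivityTrack; an absent condition
    leaves its features missing (imputed downstream).
    """
    n = 3 * bins_per_region
    values: dict[str, float] = {}
    for cond in ("vivo", "vitro"):
        track = tracks.get(cond)
        if track is None:
            values.update({f"{cond}_bin_{k:02d}": math.nan for k in range(n)})
            values[f"{cond}_cds_head"] = math.nan
        else:
            profile = bin_profile(track, t, bins_per_region)
            values.update({f"{cond}_bin_{k:02d}": profile.bins[k] for k in range(n)})
            values[f"{cond}_cds_head"] = cds_head_reactivity(track, t, n_codons_head)
    values.update(
        mfe_features(t, min_loop=min_loop, n_codons_head=n_codons_head, external=external_mfe)
    )
    return values


def structural_feature_table(
    transcripts: Iterable[TranscriptModel],
    vivo: Sequence[ReactivityTrack] = (),
    vitro: Sequence[ReactivityTrack] = (),
    bins_per_region: int = BINS_PER_REGION,
    n_codons_head: int = N_CODONS_HEAD,
    min_loop: int = 3,
    external_mfe: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Transcripts x structural-features DataFrame.

    Transcripts lacking a reactivity track in a condition simply carry
    missing values for that condition's features (logged).
    """
    vivo_by_id = {tr.transcript_id: tr for tr in vivo}
    vitro_by_id = {tr.transcript_id: tr for tr in vitro}
    rows = {}
    n_dropped = 0
    for t in transcripts:
        tracks = {}
        if t.transcript_id in vivo_by_id:
            tracks["vivo"] = vivo_by_id[t.transcript_id]
        if t.transcript_id in vitro_by_id:
            tracks["vitro"] = vitro_by_id[t.transcript_id]
        if len(tracks) < 2:
            n_dropped += 1
        ext = external_mfe.get(t.transcript_id) if external_mfe else None
        rows[t.transcript_id] = assemble_structural_features(
            t, tracks, bins_per_region, n_codons_head, min_loop, ext
        )
    if n_dropped:
        logger.warning("%d transcripts missing a reactivity condition; features left missing", n_dropped)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "transcript_id"
    return df[structural_feature_names(bins_per_region)]


def profile_matrix(
    transcripts: Iterable[TranscriptModel],
    tracks: Sequence[ReactivityTrack],
    bins_per_region: int = BINS_PER_REGION,
) -> pd.DataFrame:
    """Stack per-transcript bin profiles into a transcripts x bins matrix."""
    by_id = {tr.transcript_id: tr for tr in tracks}
    rows = {}
    for t in transcripts:
        if t.transcript_id in by_id:
            rows[t.transcript_id] = bin_profile(by_id[t.transcript_id], t, bins_per_region).bins
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "transcript_id"
    df.columns = [f"bin_{k:02d}" for k in range(3 * bins_per_region)]
    return df
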