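"""Synthetic datasets with plantable TE-structure coupling.

The generator emulates the structure of a paired probing + profiling
study: three-region transcripts, negative-binomially distributed
Ribo-seq/RNA-seq counts whose ratio encodes a planted translation
efficiency, and bounded per-nucleotide reactivities (Beta baseline) with
region-, condition- and class-specific additive effects. Three scenarios
are provided:

``mesc_like``
    High-TE transcripts get elevated in vivo reactivity in the 3'UTR
    with a front-loaded profile peaking just after the stop codon, and
    depressed in vitro 3'UTR reactivity — so the in vivo/in vitro
    contrast (delta reactivity) is strongest at the 5' end of the 3'UTR.
``zebrafish_like``
    High-TE transcripts get the same elevation in both conditions at the
    3'UTR (delta stays near zero there) plus a small in vivo boost in
    the 5'UTR and proximal CDS.
``null``
    No planted TE effect and no planted reactivity effect; the negative
    control for both the classifier and the per-bin statistics.

Every artifact passes the iolib validators and round-trips through the
text formats; generation is fully deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .iolib import (
    CountRecord,
    ReactivityTrack,
    TranscriptModel,
    write_counts,
    write_reactivity,
    write_table,
    write_transcripts,
)

SCENARIOS = ("mesc_like", "zebrafish_like", "null")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Region-length ranges are inclusive in nucleotides; the CDS draw is
    rounded down to a multiple of 3. Counts: rna ~ NB(mean, dispersion);
    ribo ~ NB(mean * 2**te, dispersion) with te = +/- ``te_effect`` per
    the planted class tendency. Reactivity baseline ~ Beta(a, b) with
    additive planted shifts delta by scenario; values are clipped at 0.
    """

    n_transcripts: int = 400
    seed: int = 0
    scenario: str = "mesc_like"
    utr5_range: tuple[int, int] = (40, 80)
    cds_range: tuple[int, int] = (90, 180)
    utr3_range: tuple[int, int] = (60, 120)
    rna_mean: float = 500.0
    dispersion: float = 0.1
    te_effect: float = 2.0
    beta_a: float = 2.0
    beta_b: float = 5.0
    delta_vivo: float = 0.15  # mesc: + on vivo 3'UTR of high TE (front-loaded)
    delta_vitro: float = 0.05  # mesc: - on vitro 3'UTR of high TE
    delta_zebra: float = 0.15  # zebrafish: + on both conditions' 3'UTR of high TE
    delta_zebra_5p: float = 0.05  # zebrafish: + on vivo 5'UTR + proximal CDS
    missing_rate: float = 0.05
    library_inflation: float = 50.0
    gc_shift: float = 0.0  # optional class-coupled GC bias (+/- per class)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        for name in ("utr5_range", "cds_range", "utr3_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        if self.cds_range[0] < 18:
            raise ValueError("cds_range minimum must be >= 18 nt (six codons)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_transcripts < 4 or self.n_transcripts % 2:
            raise ValueError("n_transcripts must be an even integer >= 4")
        if self.dispersion <= 0 or self.rna_mean <= 0:
            raise ValueError("rna_mean and dispersion must be positive")
        for d in (self.delta_vivo, self.delta_vitro, self.delta_zebra, self.delta_zebra_5p):
            if d < 0 or d > 1:
                raise ValueError("planted deltas must lie in [0, 1]")


def scenario_config(scenario: str, n_transcripts: int = 400, seed: int = 0, **overrides) -> SyntheticConfig:
    """Preset config for a named scenario (null forces no planted effects)."""
    kwargs: dict = dict(n_transcripts=n_transcripts, seed=seed, scenario=scenario)
    if scenario == "null":
        kwargs.update(te_effect=0.0, delta_vivo=0.0, delta_vitro=0.0, delta_zebra=0.0, delta_zebra_5p=0.0)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def generate_truth(cfg: SyntheticConfig) -> pd.DataFrame:
    """Per-transcript planted class and TE multiplier (half high, half low)."""
    rng = np.random.default_rng(cfg.seed % 2**31)
    n = cfg.n_transcripts
    ids = [f"t{i:04d}" for i in range(n)]
    classes = np.array(["high"] * (n // 2) + ["low"] * (n // 2))
    rng.shuffle(classes)
    te = np.where(classes == "high", cfg.te_effect, -cfg.te_effect)
    truth = pd.DataFrame({"transcript_id": ids, "true_class": classes, "te_multiplier": te})
    return truth.set_index("transcript_id")


def _random_cds(rng: np.random.Generator, length: int, p: np.ndarray) -> str:
    """Random CDS: starts ATG, ends with a stop codon, interior i.i.d."""
    interior = "".join(rng.choice(list("ACGT"), size=length - 6, p=p))
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + interior + stop


def generate_transcripts(cfg: SyntheticConfig, truth: pd.DataFrame | None = None) -> list[TranscriptModel]:
    """Random transcripts with uniform region lengths in the config ranges."""
    if truth is None:
        truth = generate_truth(cfg)
    rng = np.random.default_rng((cfg.seed + 1) % 2**31)
    out = []
    for tid, row in truth.iterrows():
        l5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        lc = int(rng.integers(cfg.cds_range[0], cfg.cds_range[1] + 1)) // 3 * 3
        lc = max(lc, (cfg.cds_range[0] + 2) // 3 * 3)
        l3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        shift = cfg.gc_shift if row.true_class == "high" else -cfg.gc_shift
        p = np.array([0.25 - shift / 2, 0.25 + shift / 2, 0.25 + shift / 2, 0.25 - shift / 2])
        utr5 = "".join(rng.choice(list("ACGT"), size=l5, p=p))
        utr3 = "".join(rng.choice(list("ACGT"), size=l3, p=p))
        cds = _random_cds(rng, lc, p)
        out.append(TranscriptModel(tid, utr5 + cds + utr3, l5, lc, l3))
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with Var = mean + dispersion * mean**2."""
    size = 1.0 / dispersion
    p = size / (size + np.asarray(mean, dtype=float))
    return rng.negative_binomial(size, p)


def generate_counts(
    cfg: SyntheticConfig, truth: pd.DataFrame
) -> tuple[list[CountRecord], int, int]:
    """NB count pairs whose ratio encodes the planted TE; plus library sizes.

    Library totals are the column sums times ``library_inflation``
    (libraries contain many features beyond the simulated transcripts).
    """
    rng = np.random.default_rng((cfg.seed + 2) % 2**31)
    rna_mu = np.full(len(truth), cfg.rna_mean)
    ribo_mu = cfg.rna_mean * np.power(2.0, truth["te_multiplier"].to_numpy())
    rna = _nb_draw(rng, rna_mu, cfg.dispersion)
    ribo = _nb_draw(rng, ribo_mu, cfg.dispersion)
    records = [
        CountRecord(tid, int(rb), int(rn))
        for tid, rb, rn in zip(truth.index, ribo, rna)
    ]
    ribo_total = max(1, int(round(ribo.sum() * cfg.library_inflation)))
    rna_total = max(1, int(round(rna.sum() * cfg.library_inflation)))
    return records, ribo_total, rna_total


def _front_loaded_weight(n: int, peak: float = 0.12, width: float = 0.18) -> np.ndarray:
    """Positional weight along a region, peaking in its first third."""
    u = (np.arange(n) + 0.5) / n
    return np.exp(-(((u - peak) / width) ** 2))


def _planted_shift(cfg: SyntheticConfig, t: TranscriptModel, condition: str, is_high: bool) -> np.ndarray:
    """Additive per-nucleotide shift for one transcript/condition."""
    shift = np.zeros(t.length)
    if not is_high or cfg.scenario == "null":
        return shift
    a3, b3 = t.region_bounds("utr3")
    if cfg.scenario == "mesc_like":
        if condition == "vivo":
            shift[a3:b3] += cfg.delta_vivo * _front_loaded_weight(b3 - a3)
        else:
            shift[a3:b3] -= cfg.delta_vitro
    elif cfg.scenario == "zebrafish_like":
        shift[a3:b3] += cfg.delta_zebra
        if condition == "vivo":
            a5, b5 = t.region_bounds("utr5")
            ac, bc = t.region_bounds("cds")
            prox = ac + max(1, int(0.3 * (bc - ac)))
            shift[a5:b5] += cfg.delta_zebra_5p
            shift[ac:prox] += cfg.delta_zebra_5p
    return shift


def generate_reactivity(
    cfg: SyntheticConfig, truth: pd.DataFrame, transcripts: Sequence[TranscriptModel]
) -> tuple[list[ReactivityTrack], list[ReactivityTrack]]:
    """Beta-baseline reactivity tracks for both conditions with planted shifts."""
    rng = np.random.default_rng((cfg.seed + 3) % 2**31)
    vivo, vitro = [], []
    for t in transcripts:
        is_high = truth.loc[t.transcript_id, "true_class"] == "high"
        for condition, store in (("vivo", vivo), ("vitro", vitro)):
            base = rng.beta(cfg.beta_a, cfg.beta_b, size=t.length)
            vals = np.clip(base + _planted_shift(cfg, t, condition, is_high), 0.0, None)
            if cfg.missing_rate > 0:
                mask = rng.random(t.length) < cfg.missing_rate
                vals[mask] = np.nan
            store.append(ReactivityTrack(t.transcript_id, condition, vals))
    return vivo, vitro


def generate_dataset(cfg: SyntheticConfig) -> dict:
    """Everything the pipeline consumes, keyed by artifact name."""
    truth = generate_truth(cfg)
    transcripts = generate_transcripts(cfg, truth)
    counts, ribo_total, rna_total = generate_counts(cfg, truth)
    vivo, vitro = generate_reactivity(cfg, truth, transcripts)
    return {
        "config": cfg,
        "truth": truth,
        "transcripts": transcripts,
        "counts": counts,
        "ribo_total": ribo_total,
        "rna_total": rna_total,
        "vivo": vivo,
        "vitro": vitro,
    }


def write_dataset(dataset: dict, outdir: str | Path) -> None:
    """Write tx.fa, regions.tsv, counts.tsv, vivo.tsv, vitro.tsv, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_transcripts(dataset["transcripts"], outdir / "tx.fa", outdir / "regions.tsv")
    write_counts(dataset["counts"], outdir / "counts.tsv", dataset["ribo_total"], dataset["rna_total"])
    write_reactivity(dataset["vivo"], outdir / "vivo.tsv")
    write_reactivity(dataset["vitro"], outdir / "vitro.tsv")
    write_table(dataset["truth"], outdir / "truth.tsv")
    cfg = dataclasses.asdict(dataset["config"])
    with open(outdir / "config.yaml", "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k}: {list(v) if isinstance(v, tuple) else v}\n")
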