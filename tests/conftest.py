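import numpy as np
import pytest

from ribofold_te import pipeline
from ribofold_te import synthetic_data as sd
from ribofold_te.iolib import ReactivityTrack, TranscriptModel

#: reduced random-forest grid used in the scaled recovery runs
SMALL_RF_GRID = {"n_estimators": [100], "max_features": ["sqrt"], "min_samples_leaf": [1, 5]}


def make_transcript(tid="t1", len_utr5=20, len_cds=24, len_utr3=22, seed=0):
    rng = np.random.default_rng(seed)
    total = len_utr5 + len_cds + len_utr3
    seq = "".join(rng.choice(list("ACGT"), size=total))
    return TranscriptModel(tid, seq, len_utr5, len_cds, len_utr3)


def constant_track(t, value, condition="vivo"):
    return ReactivityTrack(t.transcript_id, condition, np.full(t.length, float(value)))


@pytest.fixture
def transcript():
    return make_transcript()


@pytest.fixture(scope="session")
def mesc_study():
    """The mESC-like recovery run: n=400, planted delta 0.15, TE effect +/-2,
    20 stratified 70/30 splits with a reduced forest grid."""
    cfg = sd.scenario_config("mesc_like", n_transcripts=400, seed=7)
    ds = sd.generate_dataset(cfg)
    return pipeline.run_study(
        ds, n_splits=20, cv_folds=10, base_seed=7, rf_grid=SMALL_RF_GRID, models=("rf",)
    )
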