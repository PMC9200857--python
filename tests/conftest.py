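"""Shared fixtures: small synthetic recordings reused across test modules."""

import numpy as np
import pytest

from maiju.annotations import AnnotationSet, frames_from_annotations
from maiju.io import RawPacketStream, preprocess
from maiju.simulate import SimConfig, simulate_state_sequence, synthesize_imu


def make_recording(age_months=10.0, duration_s=120.0, seed=0, **cfg_kwargs):
    cfg = SimConfig(age_months=age_months, duration_s=duration_s, seed=seed,
                    **cfg_kwargs)
    seq = simulate_state_sequence(cfg)
    rec = synthesize_imu(seq, cfg)
    return cfg, seq, rec


def streams_of(rec):
    return {k: RawPacketStream(k, v) for k, v in rec.streams.items()}


def truth_annotations(seq, n_raters=2):
    """AnnotationSet where every rater equals the ground truth."""
    return AnnotationSet(
        raters=[f"r{i}" for i in range(n_raters)],
        data={"posture": np.tile(seq.posture, (n_raters, 1)),
              "movement": np.tile(seq.movement, (n_raters, 1)),
              "carrying": np.tile(seq.carrying, (n_raters, 1))})


@pytest.fixture(scope="session")
def small_corpus():
    """Three preprocessed 2-minute recordings with ground-truth frame labels."""
    out = []
    for s in range(3):
        cfg, seq, rec = make_recording(age_months=8.0 + 2 * s, seed=s)
        fa = preprocess(streams_of(rec))
        labels = {
            track: frames_from_annotations(truth_annotations(seq), fa, track)
            for track in ("posture", "movement", "carrying")}
        out.append(dict(cfg=cfg, seq=seq, rec=rec, frames=fa, labels=labels))
    return out
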