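"""Convenience glue: sessions -> preprocessed epochs -> feature pool."""

from __future__ import annotations

from .auth import EpochFeatures
from .features import StftConfig, SubbandScheme, assemble_features
from .preprocess import PreprocessConfig, extract_epochs
from .synth import RawSession

__all__ = ["build_feature_pool"]


def build_feature_pool(sessions: list[RawSession],
                       pre_cfg: PreprocessConfig | None = None,
                       stft_cfg: StftConfig | None = None,
                       scheme: SubbandScheme | None = None,
                       mode: str = "all_channels") -> list[EpochFeatures]:
    """Run preprocessing and feature extraction over whole sessions.

    Returns one :class:`EpochFeatures` per event, in session order, carrying
    provenance (subject, day, task, arm) for the evaluation harness.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    stft_cfg = stft_cfg or StftConfig()
    scheme = scheme or SubbandScheme()
    pool = []
    for session in sessions:
        for epoch in extract_epochs(session, pre_cfg):
            fm = assemble_features(epoch, stft_cfg, scheme, mode=mode)
            pool.append(EpochFeatures(
                subject_id=epoch.subject_id, day_index=epoch.day_index,
                task=epoch.task, arm=epoch.arm, features=fm))
    return pool
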