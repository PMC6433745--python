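"""End-to-end glue: records -> preprocessing -> BEMD -> feature matrix."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bemd import BivariateSignal, IMFSet, SiftConfig, bemd
from .features import extract_features, feature_names
from .io import CTGRecord, Label, PreprocessConfig, preprocess
from .pipeline import CESAREAN, VAGINAL, FeatureMatrix

LABEL_CODE = {Label.VAGINAL: VAGINAL, Label.CESAREAN: CESAREAN}


def decompose_record(rec: CTGRecord, sift_cfg: SiftConfig | None = None) -> IMFSet:
    return bemd(BivariateSignal.from_channels(rec.fhr, rec.uc, rec.fs), sift_cfg)


def record_features(rec: CTGRecord, sift_cfg: SiftConfig | None = None,
                    pre_cfg: PreprocessConfig | None = None,
                    do_preprocess: bool = True, n_imfs: int = 5,
                    trim_frac: float = 0.05) -> pd.Series:
    """Preprocess (optional), decompose and summarise one record."""
    if do_preprocess and not rec.preprocessed:
        rec = preprocess(rec, pre_cfg)
    cfg = sift_cfg or SiftConfig(max_imfs=n_imfs)
    return extract_features(decompose_record(rec, cfg), n_imfs=n_imfs,
                            trim_frac=trim_frac, record_id=rec.record_id,
                            label=rec.label)


def dataset_features(records: Iterable[CTGRecord],
                     sift_cfg: SiftConfig | None = None,
                     pre_cfg: PreprocessConfig | None = None,
                     do_preprocess: bool = True, n_imfs: int = 5,
                     trim_frac: float = 0.05) -> FeatureMatrix:
    """Feature matrix for a labeled record collection (vaginal=0, cesarean=1)."""
    rows, labels = [], []
    for rec in records:
        s = record_features(rec, sift_cfg, pre_cfg, do_preprocess, n_imfs, trim_frac)
        rows.append(s.to_numpy())
        labels.append(LABEL_CODE.get(rec.label, -1))
    return FeatureMatrix(np.vstack(rows), np.asarray(labels, int),
                         feature_names(n_imfs))


def features_frame(records: Sequence[CTGRecord], **kwargs) -> pd.DataFrame:
    """Same as :func:`dataset_features` but as a DataFrame with ids/labels."""
    rows = []
    for rec in records:
        s = record_features(rec, **kwargs)
        d = s.to_dict()
        d["record_id"] = rec.record_id
        d["label"] = rec.label.value
        rows.append(d)
    return pd.DataFrame(rows)
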