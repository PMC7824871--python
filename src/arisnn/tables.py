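"""Loaders for the packaged study-summary fixture tables.

The fixtures mirror the printed participant-characteristics, questionnaire,
loudness-change, and classification-confusion tables and serve as inputs to
the behavioural and summary-statistics stages.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def _read(name: str) -> pd.DataFrame:
    return pd.read_csv(str(resources.files("arisnn.data") / name))


def load_tinnitus_characteristics() -> pd.DataFrame:
    """Per-participant tinnitus duration, pitch, level and masking levels."""
    return _read("table1_tinnitus_characteristics.csv")


def load_questionnaires() -> pd.DataFrame:
    """Per-participant TFI / TSNS / DASS / PANAS questionnaire scores."""
    return _read("table2_questionnaires.csv")


def load_loudness_changes() -> pd.DataFrame:
    """Per-participant loudness change scores and printed responder labels."""
    return _read("table3_loudness_change.csv")


def load_confusion_counts() -> dict[str, np.ndarray]:
    """Printed LOOCV confusion matrices per condition (rows actual:
    responder, non-responder; columns predicted likewise)."""
    df = _read("table4_confusion_counts.csv")
    out: dict[str, np.ndarray] = {}
    for condition, sub in df.groupby("condition"):
        sub = sub.set_index("actual_class").loc[["responder", "nonresponder"]]
        out[condition] = sub[["pred_responder", "pred_nonresponder"]].to_numpy(dtype=np.int64)
    return out
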