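"""Participant table ingestion, cohort summaries and the CST FA ratio.

The packaged fixture (``data/participants.csv``) transcribes the study
cohort: sixteen chronic-stroke participants with demographics, lesion side
and volume, corticospinal-tract (CST) fractional-anisotropy (FA) ratio and
clinical scores — TULIA (Test of Upper Limb Apraxia, max 260), UE FM (Upper
Extremity Fugl-Meyer, max 66), Box and Blocks counts for the more- and
less-impaired arms, and the Stroke Impact Scale hand domain (0-100).

Note: the published table's printed UE FM column mean (43.3) is inconsistent
with its own sixteen row values (which average 42.0); the fixture keeps the
row values, so ``summarize_cohort`` reproduces every printed column mean
except that one.

The FA ratio divides mean ipsilesional (lesioned) peduncle FA by the
contralesional mean, each restricted to voxels with FA > 0.2; a value below
1 indicates lower FA — reduced tract integrity — on the lesioned side.
Values slightly above 1 occur and are permitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FA_THRESHOLD = 0.2

_SCHEMA = [
    "subject_id",
    "sex",
    "age",
    "months_post_stroke",
    "lesion_side",
    "lesion_volume_cc",
    "cst_fa_ratio",
    "tulia",
    "ue_fm",
    "bbt_more",
    "bbt_less",
    "sis_hand",
]
_NUMERIC = [c for c in _SCHEMA if c not in ("subject_id", "sex", "lesion_side")]


@dataclass(frozen=True)
class ParticipantRecord:
    subject_id: int
    sex: str
    age: float
    months_post_stroke: float
    lesion_side: str  # "L" or "R"
    lesion_volume_cc: float
    cst_fa_ratio: float
    tulia: float
    ue_fm: float
    bbt_more: float
    bbt_less: float
    sis_hand: float

    def __post_init__(self) -> None:
        if self.lesion_side not in ("L", "R"):
            raise ValueError(f"lesion_side must be 'L' or 'R', got {self.lesion_side!r}")
        if self.cst_fa_ratio <= 0:
            raise ValueError("cst_fa_ratio must be positive")
        checks = [
            ("ue_fm", self.ue_fm, 66),
            ("tulia", self.tulia, 260),
            ("sis_hand", self.sis_hand, 100),
        ]
        for name, value, cap in checks:
            if not 0 <= value <= cap:
                raise ValueError(f"{name}={value} outside [0, {cap}]")


def packaged_table_path() -> Path:
    """Path to the packaged participant-table fixture."""
    return Path(resources.files("actionselect") / "data" / "participants.csv")


def read_participant_table(path: Optional[str | Path] = None) -> list[ParticipantRecord]:
    """Parse a participant table; defaults to the packaged fixture.

    Rows violating record invariants are rejected with a row-numbered
    message, as are malformed numeric fields.
    """
    path = Path(path) if path is not None else packaged_table_path()
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unparseable participant table") from exc
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        values = {}
        for col in _NUMERIC + ["subject_id"]:
            raw = row[col]
            try:
                values[col] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: row {i + 2}, column {col!r}: cannot parse {raw!r}"
                ) from exc
        try:
            records.append(
                ParticipantRecord(
                    subject_id=int(values["subject_id"]),
                    sex=str(row["sex"]),
                    lesion_side=str(row["lesion_side"]),
                    **{c: values[c] for c in _NUMERIC},
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero-ward at .5, matching printed-table style."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(
    records: Sequence[ParticipantRecord], column: str, decimals: int = 1
) -> float:
    """Arithmetic mean of a numeric column, rounded half-up."""
    if not records:
        raise ValueError("no records to summarize")
    if column not in _NUMERIC:
        raise ValueError(f"column {column!r} is not numeric; choose from {_NUMERIC}")
    values = [getattr(r, column) for r in records]
    return round_half_up(float(np.mean(values)), decimals)


@dataclass
class FaInputs:
    """Pre-extracted peduncle FA values for the two hemispheres."""

    lesioned_fa: np.ndarray
    nonlesioned_fa: np.ndarray
    threshold: float = FA_THRESHOLD

    def __post_init__(self) -> None:
        self.lesioned_fa = np.asarray(self.lesioned_fa, dtype=float)
        self.nonlesioned_fa = np.asarray(self.nonlesioned_fa, dtype=float)
        for name, arr in (("lesioned", self.lesioned_fa), ("nonlesioned", self.nonlesioned_fa)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} FA values must lie in [0, 1]")


def fa_ratio(inputs: FaInputs) -> float:
    """mean(lesioned FA > threshold) / mean(nonlesioned FA > threshold)."""
    les = inputs.lesioned_fa[inputs.lesioned_fa > inputs.threshold]
    non = inputs.nonlesioned_fa[inputs.nonlesioned_fa > inputs.threshold]
    if les.size == 0 or non.size == 0:
        raise ValueError(f"no FA values above threshold {inputs.threshold}")
    return float(les.mean() / non.mean())


def split_by_lesion_side(
    records: Sequence[ParticipantRecord],
    metrics: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (LBD, RBD) frames, optionally joined to behavioural
    metrics keyed by ``subject``."""
    df = pd.DataFrame([r.__dict__ for r in records])
    bad = df.loc[~df["lesion_side"].isin(["L", "R"]), "lesion_side"]
    if len(bad):
        raise ValueError(f"unknown lesion side codes: {sorted(bad.unique())}")
    if metrics is not None:
        df = df.merge(metrics, left_on="subject_id", right_on="subject", how="left")
    lbd = df[df["lesion_side"] == "L"].reset_index(drop=True)
    rbd = df[df["lesion_side"] == "R"].reset_index(drop=True)
    return lbd, rbd
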