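"""Scoring of the four self-report clinical instruments.

* **PHQ-9** — 9 depression items scored 0-3; total 0-27.  Severity bands
  open at 5 (mild), 10 (moderate), 15 (moderately severe) and 20 (severe);
  the binary split used for cohort description is mild (< 10) versus
  moderate-to-severe (>= 10).
* **GAD-7** — 7 generalized-anxiety items scored 0-3; total 0-21; the same
  binary split at >= 10.
* **SWLS** — 5 life-satisfaction items scored 1-7; total 5-35 with 20 the
  neutral point.  Bands: 5-9 extremely dissatisfied, 10-14 dissatisfied,
  15-19 slightly dissatisfied, 20 neutral, 21-25 slightly satisfied,
  26-30 satisfied, 31-35 extremely satisfied.
* **QOLIBRI** — 37 brain-injury quality-of-life items scored 1-5; the raw
  total (37-185) is rescaled linearly to 0-100 and scaled scores below 60
  flag low or impaired health-related quality of life.

All scorers are strict: a wrong item count or an out-of-range response
raises, naming the item.  No proration of missing items is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "InstrumentSpec",
    "INSTRUMENTS",
    "ScoredMeasures",
    "score_phq9",
    "score_gad7",
    "score_swls",
    "score_qolibri",
    "score_measures",
    "cronbach_alpha",
    "PHQ9_BANDS",
    "SWLS_BANDS",
]


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    n_items: int
    item_min: int
    item_max: int

    @property
    def total_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def total_max(self) -> int:
        return self.n_items * self.item_max


INSTRUMENTS = {
    "PHQ9": InstrumentSpec("PHQ9", 9, 0, 3),
    "GAD7": InstrumentSpec("GAD7", 7, 0, 3),
    "SWLS": InstrumentSpec("SWLS", 5, 1, 7),
    "QOLIBRI": InstrumentSpec("QOLIBRI", 37, 1, 5),
}

# (lower total bound, band label); bands are contiguous and exhaustive
PHQ9_BANDS = (
    (0, "minimal"),
    (5, "mild"),
    (10, "moderate"),
    (15, "moderately_severe"),
    (20, "severe"),
)
SWLS_BANDS = (
    (5, "extremely_dissatisfied"),
    (10, "dissatisfied"),
    (15, "slightly_dissatisfied"),
    (20, "neutral"),
    (21, "slightly_satisfied"),
    (26, "satisfied"),
    (31, "extremely_satisfied"),
)

_BINARY_CUTOFF = 10  # moderate-to-severe threshold for PHQ-9 and GAD-7
QOLIBRI_LOW_HRQOL_CUTOFF = 60.0  # scaled score below this flags low HRQoL


def _check_items(name: str, items: Sequence[int], spec: InstrumentSpec) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (spec.n_items,):
        raise ValueError(
            f"{name} expects exactly {spec.n_items} items, got {arr.size}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            bad = int(np.argmax(arr != np.floor(arr)))
            raise ValueError(f"{name} item {bad + 1}: non-integer response {arr[bad]!r}")
        arr = arr.astype(int)
    out = (arr < spec.item_min) | (arr > spec.item_max)
    if out.any():
        bad = int(np.argmax(out))
        raise ValueError(
            f"{name} item {bad + 1}: response {arr[bad]} outside "
            f"[{spec.item_min}, {spec.item_max}]"
        )
    return arr


def _band(total: int, bands) -> str:
    label = bands[0][1]
    for lo, name in bands:
        if total >= lo:
            label = name
    return label


class Phq9Score(NamedTuple):
    total: int
    band: str
    binary: str


class Gad7Score(NamedTuple):
    total: int
    binary: str


class SwlsScore(NamedTuple):
    total: int
    band: str


class QolibriScore(NamedTuple):
    raw: int
    scaled: float
    low_hrqol: bool


def score_phq9(items: Sequence[int]) -> Phq9Score:
    """Total, severity band and mild vs moderate-to-severe dichotomy."""
    arr = _check_items("PHQ-9", items, INSTRUMENTS["PHQ9"])
    total = int(arr.sum())
    binary = "moderate_to_severe" if total >= _BINARY_CUTOFF else "mild"
    return Phq9Score(total, _band(total, PHQ9_BANDS), binary)


def score_gad7(items: Sequence[int]) -> Gad7Score:
    arr = _check_items("GAD-7", items, INSTRUMENTS["GAD7"])
    total = int(arr.sum())
    binary = "moderate_to_severe" if total >= _BINARY_CUTOFF else "mild"
    return Gad7Score(total, binary)


def score_swls(items: Sequence[int]) -> SwlsScore:
    arr = _check_items("SWLS", items, INSTRUMENTS["SWLS"])
    total = int(arr.sum())
    return SwlsScore(total, _band(total, SWLS_BANDS))


def score_qolibri(items: Sequence[int]) -> QolibriScore:
    """Raw total, 0-100 scaled score and the low-HRQoL flag (< 60).

    The scaling is the linear min-max transform forced by the instrument's
    anchors: raw 37 -> 0 and raw 185 -> 100.
    """
    spec = INSTRUMENTS["QOLIBRI"]
    arr = _check_items("QOLIBRI", items, spec)
    raw = int(arr.sum())
    scaled = (raw - spec.total_min) / (spec.total_max - spec.total_min) * 100.0
    return QolibriScore(raw, scaled, scaled < QOLIBRI_LOW_HRQOL_CUTOFF)


@dataclass
class ScoredMeasures:
    """All instrument scores for one participant."""

    participant_id: str
    phq9_total: int
    phq9_band: str
    phq9_binary: str
    gad7_total: int
    gad7_binary: str
    swls_total: int
    swls_band: str
    qolibri_raw: int
    qolibri_scaled: float
    low_hrqol: bool


def _item_block(df, prefix: str, n: int):
    cols = [f"{prefix}_{i}" for i in range(1, n + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"measures table missing columns: {missing}")
    return df[cols].to_numpy()


def score_measures(df) -> "pandas.DataFrame":
    """Score a measures table (one row per participant, item columns
    ``phq9_1..9, gad7_1..7, swls_1..5, qolibri_1..37``) into a tidy scored
    table."""
    import pandas as pd

    phq = _item_block(df, "phq9", 9)
    gad = _item_block(df, "gad7", 7)
    swls = _item_block(df, "swls", 5)
    qol = _item_block(df, "qolibri", 37)
    rows = []
    for k, pid in enumerate(df["participant_id"]):
        p = score_phq9(phq[k])
        g = score_gad7(gad[k])
        s = score_swls(swls[k])
        q = score_qolibri(qol[k])
        rows.append(
            {
                "participant_id": pid,
                "phq9_total": p.total,
                "phq9_band": p.band,
                "phq9_binary": p.binary,
                "gad7_total": g.total,
                "gad7_binary": g.binary,
                "swls_total": s.total,
                "swls_band": s.band,
                "qolibri_raw": q.raw,
                "qolibri_scaled": q.scaled,
                "low_hrqol": q.low_hrqol,
            }
        )
    return pd.DataFrame(rows)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    ``item_matrix`` is participants x items, no missing values.  Uses the
    standard formula ``alpha = k/(k-1) * (1 - sum(item variances) /
    variance(total score))`` with sample (ddof=1) variances.  Returns NaN
    when the total-score variance is zero (alpha undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 items")
    if not np.isfinite(x).all():
        raise ValueError("item matrix contains missing/non-finite values")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var / total_var))
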