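"""Clinical and laboratory feature definitions plus reader-agreement statistics.

CA19-9 response follows the common clinical convention for pancreatic cancer
treatment monitoring: a reduction of more than 50 % from baseline, or
normalization below 37 U/mL, counts as a response.  Eligibility requires a
baseline above the 37 U/mL normal limit so that non-secretors and
normal-range patients are not mis-scored.

ECV categorization for the risk score uses three bins (< 16 %, 16-20 %,
>= 20 %); higher ECV carries a *better* prognosis here, so the top bin
scores negative points.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TumorMarkerPair",
    "ca199_change",
    "ca199_response",
    "ecv_points",
    "cohens_kappa",
    "icc",
    "agreement_band",
    "CA199_NORMAL_LIMIT",
]

CA199_NORMAL_LIMIT = 37.0  # U/mL


@dataclass(frozen=True)
class TumorMarkerPair:
    """Baseline and post-treatment serum CA19-9 (U/mL)."""

    baseline: float
    post: float

    def __post_init__(self) -> None:
        if not (self.baseline > 0 and self.post > 0):
            raise ValueError("CA19-9 values must be positive")


def ca199_change(pair: TumorMarkerPair) -> float:
    """Signed percent change (post - baseline) / baseline * 100; negative = decline."""
    if pair.baseline <= 0:
        raise ValueError("baseline CA19-9 must be positive")
    return (pair.post - pair.baseline) / pair.baseline * 100.0


def ca199_response(pair: TumorMarkerPair) -> bool:
    """True for responders: > 50 % decline, or normalization below 37 U/mL.

    Requires an elevated baseline (> 37 U/mL); records that fail the
    eligibility criterion raise rather than silently classify.
    """
    if pair.baseline <= CA199_NORMAL_LIMIT:
        raise ValueError(
            f"baseline CA19-9 must exceed {CA199_NORMAL_LIMIT} U/mL for response grading"
        )
    return ca199_change(pair) < -50.0 or pair.post < CA199_NORMAL_LIMIT


def ecv_points(ecv: float) -> int:
    """Risk-score points for the ECV category: >=20 % -> -2, [16, 20) -> 0, <16 % -> 1."""
    ecv = float(ecv)
    if not np.isfinite(ecv) or ecv < 0:
        raise ValueError(f"ECV must be finite and non-negative, got {ecv}")
    if ecv >= 20.0:
        return -2
    if ecv >= 16.0:
        return 0
    return 1


# ---------------------------------------------------------------------------
# Reader agreement


def cohens_kappa(reader1: Sequence, reader2: Sequence) -> float:
    """Cohen's kappa for two readers' categorical calls, (po - pe) / (1 - pe)."""
    from sklearn.metrics import cohen_kappa_score

    r1 = np.asarray(reader1)
    r2 = np.asarray(reader2)
    if r1.shape != r2.shape:
        raise ValueError("reader vectors must have equal length")
    if r1.size < 2:
        raise ValueError("need at least two rated items")
    if np.unique(np.concatenate([r1, r2])).size < 2:
        raise ValueError("kappa undefined: a single category was used throughout")
    return float(cohen_kappa_score(r1, r2))


def icc(reader1: Sequence[float], reader2: Sequence[float]) -> float:
    """Intraclass correlation for two readers' continuous measurements.

    Two-way random effects, absolute agreement, single measure — ICC(2,1) in
    the Shrout–Fleiss taxonomy.  Equals 1 for identical readings with
    non-zero between-subject variance.
    """
    import pingouin as pg

    r1 = np.asarray(reader1, dtype=float)
    r2 = np.asarray(reader2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("reader vectors must have equal length")
    if r1.size < 3:
        raise ValueError("need at least three subjects for the ICC")
    if np.var(np.concatenate([r1, r2])) == 0.0:
        raise ValueError("ICC undefined: zero total variance")
    n = r1.size
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "reader": np.repeat(["r1", "r2"], n),
            "rating": np.concatenate([r1, r2]),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # perfect agreement yields 0/0 F-ratios internally; the ICC itself is fine
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=df, targets="subject", raters="reader", ratings="rating"
        ).set_index("Type")
    for label in ("ICC2", "ICC(A,1)"):  # pingouin renamed the type across versions
        if label in table.index:
            return float(table.loc[label, "ICC"])
    raise RuntimeError("absolute-agreement single-measure ICC not found in pingouin output")


def agreement_band(value: float) -> str:
    """Interpretation band for kappa / ICC values.

    < 0.20 poor, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80 good,
    0.81-1.00 excellent; values falling in the printed bands' gap
    (0.20, 0.21) are mapped to 'fair'.
    """
    if value < 0.20:
        return "poor"
    if value <= 0.40:
        return "fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "good"
    return "excellent"
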