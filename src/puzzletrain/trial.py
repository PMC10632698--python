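"""Crossover-trial analysis: fixtures, summaries and the statistical tests.

The pilot that motivates this package enrolled 12 healthy adults (one
further enrollee was excluded for incomplete measurements) in a two-phase
crossover: each phase lasted 8 weeks, with assessment waves before, between
and after. The participant characteristics (age, gender, handedness, MoCA,
TMT-A/B, SMT) and the post-study questionnaire subscales (Intrinsic
Motivation Inventory and NASA Task Load Index) ship with the package as
checksummed CSV fixtures; everything downstream — wave summaries, normality
checks, paired t tests, one-way repeated-measures ANOVA and correlations —
is recomputed from them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .adaptive import PretestScores

_CHECKSUMS = {
    "participants.csv": "8d8ceb41458749756e17c5f9407eb236ef27273794ed56dccb65df5992e9c6b3",
    "imi.csv": "e5e309042fc471d8383349db41198020296454551acef571c91cfd72770d0d73",
    "tlx.csv": "414a002678c8bee65c6ae4b8884f58ace3d0edb7f5ac66757bdd3e6030685b21",
}

IMI_SUBSCALES = (
    "competence_effort",
    "interest_enjoyment",
    "value_usefulness",
    "pressure_tension",
)
TLX_SUBSCALES = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "performance",
    "effort",
    "frustration",
)

#: published mid/post wave summaries, kept for report display only — the
#: individual wave-level measurements behind them were never released, so
#: nothing in this package recomputes them.
WAVE_REFERENCE = {
    ("moca", "mid"): (26.92, 2.43),
    ("moca", "post"): (27.58, 2.64),
    ("tmt_a_s", "mid"): (31.50, 12.99),
    ("tmt_a_s", "post"): (30.08, 10.88),
    ("tmt_b_s", "mid"): (63.75, 30.36),
    ("tmt_b_s", "post"): (66.75, 27.48),
    ("smt_s", "mid"): (19.75, 9.55),
    ("smt_s", "post"): (16.50, 8.12),
}


@dataclass(frozen=True)
class ParticipantRecord:
    id: str
    group: str
    age: float
    gender: str
    handedness: str
    moca: float
    tmt_a_s: float
    tmt_b_s: float
    smt_s: float

    @property
    def pretest(self) -> PretestScores:
        return PretestScores(
            moca=self.moca, tmt_a=self.tmt_a_s, tmt_b=self.tmt_b_s, smt=self.smt_s
        )


@dataclass(frozen=True)
class SubscaleTable:
    imi: pd.DataFrame
    tlx: pd.DataFrame


def _read_fixture(name: str) -> pd.DataFrame:
    data = (resources.files("puzzletrain") / "data" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"fixture {name} corrupted: checksum {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(data), dtype={"id": str})


def load_fixtures() -> tuple[list[ParticipantRecord], SubscaleTable]:
    """Participant characteristics plus the IMI and TLX subscale tables."""
    participants = [
        ParticipantRecord(**row) for row in _read_fixture("participants.csv").to_dict("records")
    ]
    table = SubscaleTable(
        imi=_read_fixture("imi.csv").set_index("id"),
        tlx=_read_fixture("tlx.csv").set_index("id"),
    )
    return participants, table


def participants_frame() -> pd.DataFrame:
    return _read_fixture("participants.csv").set_index("id")


def reference_pretests() -> list[PretestScores]:
    """The fixture cohort as the reference population for initial levels."""
    participants, _ = load_fixtures()
    return [p.pretest for p in participants]


# -- summaries -----------------------------------------------------------


def summarize(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n−1 denominator), unrounded."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least 2 values for an SD")
    return float(arr.mean()), float(arr.std(ddof=1))


def round_half_up(value: float, decimals: int = 2) -> float:
    """Report-layer rounding: half-up at the given number of decimals."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# -- statistical tests ---------------------------------------------------


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test for small samples (3 ≤ n ≤ 50)."""
    arr = np.asarray(values, dtype=float)
    if not (3 <= len(arr) <= 50):
        raise ValueError(f"Shapiro–Wilk supported for 3 <= n <= 50, got {len(arr)}")
    if np.allclose(arr, arr[0]):
        raise ValueError("constant sample: W undefined")
    res = _stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def paired_t(pre: Sequence[float], post: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired t test: returns (t, df, p)."""
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of differences: t undefined")
    res = _stats.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


def rm_anova(
    matrix: np.ndarray | pd.DataFrame, correction: str = "none"
) -> tuple[float, float, float, float]:
    """One-way within-subject ANOVA over waves: returns (F, df1, df2, p).

    ``matrix`` is participants × conditions with complete cases. By default
    no sphericity correction is applied; ``correction='gg'`` adjusts the
    degrees of freedom by the Greenhouse–Geisser epsilon.
    """
    data = np.asarray(matrix, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a participants x conditions matrix with >= 2 conditions")
    if np.isnan(data).any():
        raise ValueError("missing cells: complete cases required")
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 participants")
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = float(k - 1), float((n - 1) * (k - 1))
    if correction == "gg":
        eps = _greenhouse_geisser_epsilon(data)
        df1, df2 = df1 * eps, df2 * eps
    ms_err = ss_err / ((n - 1) * (k - 1))
    if np.isclose(ms_err, 0):
        if np.isclose(ss_cond, 0):
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f_stat = (ss_cond / (k - 1)) / ms_err
    p = float(_stats.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, df2, p


def _greenhouse_geisser_epsilon(data: np.ndarray) -> float:
    k = data.shape[1]
    cov = np.cov(data, rowvar=False, ddof=1)
    mean_diag = np.trace(cov) / k
    mean_all = cov.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(cov**2) - 2 * k * np.sum(cov.mean(axis=1) ** 2) + k**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p via the t transform."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("x and y must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(a.std(), 0) or np.allclose(b.std(), 0):
        raise ValueError("zero variance input")
    res = _stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


# -- questionnaire report ------------------------------------------------


def subscale_report(table: SubscaleTable) -> pd.DataFrame:
    """Totals and within-instrument ranks (1 = highest total) of every IMI
    and NASA-TLX subscale across the cohort."""
    rows = []
    for instrument, frame, names in (
        ("imi", table.imi, IMI_SUBSCALES),
        ("tlx", table.tlx, TLX_SUBSCALES),
    ):
        totals = frame[list(names)].sum(axis=0)
        ranks = totals.rank(ascending=False, method="min").astype(int)
        for name in names:
            rows.append(
                {
                    "instrument": instrument,
                    "subscale": name,
                    "total": int(totals[name]),
                    "rank": int(ranks[name]),
                }
            )
    return pd.DataFrame(rows)


def pretest_summary_table() -> pd.DataFrame:
    """Cohort demographics and pretest wave summaries recomputed from the
    participant fixtures, rounded half-up to 2 decimals."""
    frame = participants_frame()
    rows = []
    for label, column in (
        ("age", "age"),
        ("moca", "moca"),
        ("tmt_a_s", "tmt_a_s"),
        ("tmt_b_s", "tmt_b_s"),
        ("smt_s", "smt_s"),
    ):
        mean, sd = summarize(frame[column])
        rows.append(
            {
                "measure": label,
                "wave": "pre",
                "mean": round_half_up(mean),
                "sd": round_half_up(sd),
            }
        )
    return pd.DataFrame(rows)
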