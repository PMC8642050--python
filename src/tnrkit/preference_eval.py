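"""Paired-comparison experimental machinery.

Two renderings of the same sentence are presented in succession; the
listener places a slider on a ±3 continuum ("1 much better" ... "equal"
... "2 much better").  The raw slider is negative when the first-presented
interval is preferred.  Scores are sign-corrected to a canonical
convention — positive means the pair's canonical first condition (e.g. RNN
in "RNN vs NP") is preferred, regardless of presentation order — then
averaged over sentences and orders per (participant, comparison, STR).

Group-level inference uses the exact Wilcoxon signed-rank test: W is the
smaller of the positive- and negative-rank sums (midranks for tied
magnitudes, exact zeros dropped) and the two-tailed p-value comes from full
enumeration of the 2^n equiprobable sign assignments.  For n = 10 this
reproduces the printed pairs W=4 -> p=.014, W=1 -> .004, W=8 -> .049.

A simulated listener (true preference + Gaussian slider noise) stands in
for human participants so the whole pipeline is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DEFAULT_PAIRS",
    "Trial",
    "PreferenceScore",
    "TestResult",
    "build_trial_list",
    "score_trial",
    "trials_to_frame",
    "aggregate",
    "wilcoxon_exact",
    "simulate_listener",
    "holm",
]

#: The three pair-wise comparisons, in canonical order.
DEFAULT_PAIRS = (("RNN", "NP"), ("RNN", "MCTR"), ("MCTR", "NP"))
SUBJECTIVE_STRS_DB = (-10.0, -15.0)


@dataclass(frozen=True)
class Trial:
    """One paired presentation of a sentence under two conditions."""

    comparison: tuple  # canonical (first, second) condition labels
    presentation: tuple  # actual playback order
    sentence: int
    str_db: float
    part: str = "intelligibility"

    def __post_init__(self) -> None:
        if len(self.comparison) != 2 or self.comparison[0] == self.comparison[1]:
            raise ValueError("comparison must be two distinct conditions")
        if sorted(self.presentation) != sorted(self.comparison):
            raise ValueError("presentation must be an ordering of the comparison")
        if self.part not in ("intelligibility", "comfort"):
            raise ValueError(f"unknown part {self.part!r}")

    @property
    def label(self) -> str:
        return f"{self.comparison[0]} vs {self.comparison[1]}"

    @property
    def reversed_order(self) -> bool:
        return self.presentation != self.comparison


@dataclass(frozen=True)
class PreferenceScore:
    """Aggregated order-corrected score on the ±3 continuum."""

    participant: int
    comparison: str
    str_db: float
    score: float

    def __post_init__(self) -> None:
        if abs(self.score) > 3.0 + 1e-12:
            raise ValueError("scores lie in [-3, 3]")


@dataclass(frozen=True)
class TestResult:
    """Exact Wilcoxon signed-rank outcome."""

    W: float
    n: int
    p_two_tailed: float

    def __post_init__(self) -> None:
        if not (0 <= self.W <= self.n * (self.n + 1) / 2):
            raise ValueError("W outside the achievable range")
        if not (0 < self.p_two_tailed <= 1):
            raise ValueError("p must lie in (0, 1]")


def build_trial_list(
    pairs=DEFAULT_PAIRS,
    n_sentences: int = 12,
    strs=SUBJECTIVE_STRS_DB,
    part: str = "intelligibility",
    seed: int = 0,
) -> list:
    """Balanced trial list: every (pair, order, sentence, STR) cell exactly
    once, shuffled with a seed.  Defaults give 3*2*12*2 = 144 trials."""
    if n_sentences < 1 or len(pairs) < 1 or len(strs) < 1:
        raise ValueError("counts must be positive")
    trials = []
    for pair, flip, sentence, str_db in product(pairs, (False, True), range(n_sentences), strs):
        presentation = (pair[1], pair[0]) if flip else tuple(pair)
        trials.append(Trial(tuple(pair), presentation, sentence, float(str_db), part))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return [trials[k] for k in order]


def score_trial(slider: float, trial: Trial) -> float:
    """Canonical order-corrected score for one response.

    The raw slider is negative when the first-presented interval is
    preferred; canonically, positive means the comparison's first condition
    is preferred.  So the sign flips when the canonical first condition was
    presented first, and is kept when it was presented second.
    """
    if abs(slider) > 3.0:
        raise ValueError("slider positions lie in [-3, 3]")
    return float(slider) if trial.reversed_order else -float(slider)


def trials_to_frame(trials) -> pd.DataFrame:
    """Trial list as a tidy table (the CSV export layout)."""
    return pd.DataFrame(
        {
            "comparison": [t.label for t in trials],
            "first": [t.presentation[0] for t in trials],
            "second": [t.presentation[1] for t in trials],
            "sentence": [t.sentence for t in trials],
            "str_db": [t.str_db for t in trials],
            "part": [t.part for t in trials],
        }
    )


def aggregate(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant preference scores: mean canonical score over the
    sentences and both presentation orders of each (comparison, STR).

    ``responses`` needs columns participant, comparison, str_db, sentence,
    reversed_order, canonical_score.  Incomplete designs raise an error
    naming the missing cells.
    """
    required = {"participant", "comparison", "str_db", "sentence", "reversed_order", "canonical_score"}
    missing_cols = required - set(responses.columns)
    if missing_cols:
        raise ValueError(f"responses table lacks columns {sorted(missing_cols)}")

    cells = responses.groupby(
        ["participant", "comparison", "str_db", "sentence", "reversed_order"]
    ).size()
    participants = responses["participant"].unique()
    comparisons = responses["comparison"].unique()
    strs = responses["str_db"].unique()
    sentences = responses["sentence"].unique()
    expected = product(participants, comparisons, strs, sentences, (False, True))
    absent = [cell for cell in expected if cell not in cells.index]
    if absent:
        raise ValueError(f"incomplete trial set; missing cells: {absent[:5]}"
                         + ("..." if len(absent) > 5 else ""))

    out = (
        responses.groupby(["participant", "comparison", "str_db"], as_index=False)["canonical_score"]
        .mean()
        .rename(columns={"canonical_score": "score"})
    )
    return out


def _signed_rank_tail(doubled_ranks: np.ndarray, doubled_w: int) -> float:
    """P(T+ <= W) under the null by exact enumeration of sign assignments.

    Dynamic programming over the subset-sum distribution of the (doubled,
    hence integer) ranks — equivalent to walking all 2^n assignments.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return float(counts[: doubled_w + 1].sum() / 2.0 ** len(doubled_ranks))


def wilcoxon_exact(values, mu0: float = 0.0) -> TestResult:
    """Exact two-tailed Wilcoxon signed-rank test of median == ``mu0``.

    Exact zero differences are dropped (standard convention; the effective
    n is reported), tied magnitudes get midranks, W is the smaller rank
    sum, and p = min(1, 2*P(T+ <= W)) by full enumeration.
    """
    d = np.asarray(values, dtype=np.float64) - mu0
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the test is degenerate")
    ranks = rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks.sum() - t_plus)
    W = min(t_plus, t_minus)
    doubled = np.round(2.0 * ranks).astype(int)
    p = min(1.0, 2.0 * _signed_rank_tail(doubled, int(round(2.0 * W + 1e-9))))
    return TestResult(W=W, n=n, p_two_tailed=p)


def simulate_listener(
    true_preferences: dict,
    noise_sd: float,
    seed: int,
    trials,
    participant: int = 0,
) -> pd.DataFrame:
    """Slider responses of a synthetic participant for a trial list.

    ``true_preferences`` maps a comparison label ("RNN vs NP") or
    (label, str_db) to the participant's canonical preference.  The raw
    slider is the order-signed preference plus Gaussian noise, clipped to
    ±3; with ``noise_sd = 0`` aggregation recovers the preferences exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for trial in trials:
        key = (trial.label, trial.str_db)
        pref = true_preferences.get(key, true_preferences.get(trial.label, 0.0))
        sign = 1.0 if trial.reversed_order else -1.0
        slider = float(np.clip(sign * pref + rng.normal(0.0, noise_sd), -3.0, 3.0))
        rows.append(
            {
                "participant": participant,
                "comparison": trial.label,
                "str_db": trial.str_db,
                "sentence": trial.sentence,
                "reversed_order": trial.reversed_order,
                "part": trial.part,
                "slider": slider,
                "canonical_score": score_trial(slider, trial),
            }
        )
    return pd.DataFrame(rows)


def holm(p_values) -> np.ndarray:
    """Holm step-down adjustment (off by default in the analyses here)."""
    p = np.asarray(p_values, dtype=np.float64)
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, k in enumerate(order):
        running = max(running, (m - rank) * p[k])
        adjusted[k] = min(1.0, running)
    return adjusted
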