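"""Ranking and regression metrics, aggregation, and conformer selection.

Early enrichment is measured with BEDROC (Boltzmann-enhanced discrimination of
ROC) in the discrete Truchon–Bayly formulation.  With N ranked items, n of
which are positives at 1-based ranks r_i, and exponent alpha:

    RIE    = (1/n) * sum_i exp(-alpha * r_i / N)
             / [ (1/N) * (1 - exp(-alpha)) / (exp(alpha/N) - 1) ]
    BEDROC = RIE * Ra * sinh(alpha/2)
             / (cosh(alpha/2) - cosh(alpha/2 - alpha*Ra))
             + 1 / (1 - exp(alpha * (1 - Ra)))          with Ra = n/N.

At alpha = 20 the items ranked in the top 8% carry 80% of the score mass,
which is what makes the metric an *early* enrichment measure.  BEDROC_bio-like
treats bioactive-like conformers as positives (high is good); BEDROC_non-bio
treats non-bioactive conformers as positives (low is good — early
impoverishment).  Intermediate conformers count as negatives on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, cosh, exp, sinh
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError

__all__ = [
    "BEDROC_ALPHA",
    "regression_metrics",
    "eligible_for_ranking",
    "scaled_rank",
    "bedroc",
    "exponential_weight_fraction",
    "bedroc_pair",
    "hard_subset_flag",
    "mcs_size_bin",
    "evaluate_ranking",
    "summarize",
    "select_top_fraction",
]

#: Default BEDROC exponent.
BEDROC_ALPHA = 20.0


def regression_metrics(predictions: Sequence[float], truths: Sequence[float]) -> tuple[float, float]:
    """Root-mean-square error and coefficient of determination R^2."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and truths must have equal non-zero length")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined for zero-variance truths")
    r2 = 1.0 - float(np.sum((p - t) ** 2)) / ss_tot
    return rmse, r2


def eligible_for_ranking(ensemble) -> bool:
    """True when ranking can help: some, but not only, bioactive-like conformers."""
    return 1 <= ensemble.n_bio_like < ensemble.n_conformers


def scaled_rank(rank: int, n_conformers: int) -> float:
    """1-based rank divided by ensemble size; lies in (0, 1]."""
    if not 1 <= rank <= n_conformers:
        raise ValueError(f"rank {rank} outside [1, {n_conformers}]")
    return rank / n_conformers


def bedroc(ordered_labels: Sequence[bool], alpha: float = BEDROC_ALPHA) -> float:
    """BEDROC of a binary label sequence given in rank order (rank 1 first)."""
    labels = np.asarray(ordered_labels, dtype=bool)
    big_n = labels.size
    n = int(labels.sum())
    if n == 0 or n == big_n:
        raise UndefinedMetricError(
            f"BEDROC undefined: {n} positives of {big_n} items"
        )
    ranks = np.flatnonzero(labels) + 1  # 1-based
    ra = n / big_n
    rie = (np.exp(-alpha * ranks / big_n).sum() / n) / (
        (1.0 / big_n) * (1.0 - exp(-alpha)) / (exp(alpha / big_n) - 1.0)
    )
    value = rie * ra * sinh(alpha / 2.0) / (
        cosh(alpha / 2.0) - cosh(alpha / 2.0 - alpha * ra)
    ) + 1.0 / (1.0 - exp(alpha * (1.0 - ra)))
    # guard against floating-point overshoot at the boundaries
    return float(min(max(value, 0.0), 1.0))


def exponential_weight_fraction(alpha: float, top_fraction: float) -> float:
    """Fraction of the exponential rank-weight mass in the top ``top_fraction``.

    F(x) = (1 - exp(-alpha x)) / (1 - exp(-alpha)); at alpha = 20 the top 8%
    of ranks carry 80% of the weight.
    """
    if not 0.0 <= top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in [0, 1]")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return (1.0 - exp(-alpha * top_fraction)) / (1.0 - exp(-alpha))


def bedroc_pair(ranking, ensemble, alpha: float = BEDROC_ALPHA) -> tuple[float | None, float | None]:
    """(BEDROC_bio-like, BEDROC_non-bio) for one ranking of one ensemble.

    A side with no positives (or no negatives) is undefined and reported as
    None so downstream medians exclude it rather than counting a zero.
    """
    label_by_conf = {c.conf_id: lab for c, lab in zip(ensemble.conformers, ensemble.labels)}
    ordered = [label_by_conf[cid] for cid in ranking.order]

    def side(positive: str) -> float | None:
        flags = [lab == positive for lab in ordered]
        try:
            return bedroc(flags, alpha=alpha)
        except UndefinedMetricError:
            return None

    return side("bio_like"), side("non_bio")


def hard_subset_flag(ensemble, max_n: int = 250, frac_threshold: float = 0.05) -> bool:
    """Full-size ensembles with under 5% bioactive-like conformers."""
    return ensemble.n_conformers == max_n and ensemble.frac_bio_like < frac_threshold


def mcs_size_bin(n_heavy: int, width: int = 10) -> str:
    """Half-open decade bin label for an MCS heavy-atom count, e.g. "[30, 40[" """
    if n_heavy < 0:
        raise ValueError("n_heavy must be >= 0")
    lo = (n_heavy // width) * width
    return f"[{lo}, {lo + width}["


@dataclass
class EvalRow:
    mol_id: str
    ranker: str
    bedroc_bio_like: float | None
    bedroc_non_bio: float | None
    scaled_rank_first_bio_like: float | None
    scaled_rank_first_non_bio: float | None
    n_conformers: int
    frac_bio_like: float
    eligible: bool
    hard_subset: bool


def evaluate_ranking(
    ranking,
    ensemble,
    alpha: float = BEDROC_ALPHA,
    hard_max_n: int = 250,
    hard_frac: float = 0.05,
) -> EvalRow:
    """Per-molecule evaluation of one ranker's ordering of one ensemble."""
    b_bio, b_non = bedroc_pair(ranking, ensemble, alpha=alpha)
    label_by_conf = {c.conf_id: lab for c, lab in zip(ensemble.conformers, ensemble.labels)}
    ordered = [label_by_conf[cid] for cid in ranking.order]
    n = len(ordered)

    def first_rank(positive: str) -> float | None:
        for i, lab in enumerate(ordered):
            if lab == positive:
                return scaled_rank(i + 1, n)
        return None

    return EvalRow(
        mol_id=ensemble.mol_id,
        ranker=ranking.ranker_name,
        bedroc_bio_like=b_bio,
        bedroc_non_bio=b_non,
        scaled_rank_first_bio_like=first_rank("bio_like"),
        scaled_rank_first_non_bio=first_rank("non_bio"),
        n_conformers=n,
        frac_bio_like=ensemble.frac_bio_like,
        eligible=eligible_for_ranking(ensemble),
        hard_subset=hard_subset_flag(ensemble, hard_max_n, hard_frac),
    )


_METRIC_COLUMNS = [
    "bedroc_bio_like",
    "bedroc_non_bio",
    "scaled_rank_first_bio_like",
    "scaled_rank_first_non_bio",
]


def rows_to_frame(rows: Sequence[EvalRow], extra: Mapping[str, Mapping[str, object]] | None = None) -> pd.DataFrame:
    """EvalRows as a DataFrame; ``extra`` maps mol_id to additional group keys."""
    frame = pd.DataFrame([vars(r) for r in rows])
    if extra:
        for key in {k for cols in extra.values() for k in cols}:
            frame[key] = frame["mol_id"].map(
                lambda m: extra.get(m, {}).get(key) if extra else None
            )
    return frame


def summarize(
    frame: pd.DataFrame,
    group_by: Sequence[str] = (),
    split_column: str | None = "split_seed",
) -> pd.DataFrame:
    """Medians over eligible molecules, then mean +/- sd across splits.

    Returns one row per (ranker, group, metric) with columns ``median_mean``
    and ``median_std`` (std is NaN with a single split).  Medians ignore
    undefined (missing) metric values.
    """
    eligible = frame[frame["eligible"]].copy()
    if eligible.empty:
        raise ValueError("no eligible molecules to summarize")
    keys = ["ranker", *group_by]
    if split_column and split_column in eligible.columns:
        per_split = (
            eligible.groupby([*keys, split_column], dropna=False)[_METRIC_COLUMNS]
            .median()
            .reset_index()
        )
        out = (
            per_split.groupby(keys, dropna=False)[_METRIC_COLUMNS]
            .agg(["mean", "std"])
        )
        out.columns = [f"{m}_median_{stat}" for m, stat in out.columns]
        return out.reset_index()
    out = eligible.groupby(keys, dropna=False)[_METRIC_COLUMNS].median()
    out.columns = [f"{m}_median" for m in out.columns]
    return out.reset_index()


def select_top_fraction(ranking, fraction: float) -> list[int]:
    """conf_ids of the top ceil(fraction * n) conformers (at least one)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(ranking.order)
    k = max(1, ceil(fraction * n))
    return list(ranking.order[:k])
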