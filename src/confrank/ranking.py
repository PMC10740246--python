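"""Shared ranking types: scores to orderings with a reproducible tie rule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformers import LabelledEnsemble

__all__ = ["RankingResult", "order_by_scores", "ConformerRanker"]


@dataclass
class RankingResult:
    """An ordering of one molecule's conformers produced by one ranker."""

    mol_id: str
    ranker_name: str
    order: list[int]  # conf_ids, best first
    scores: np.ndarray  # aligned with ``order`` (score of the k-th ranked conformer)
    direction: str = "ascending"
    flags: dict = field(default_factory=dict)

    def score_of(self, conf_id: int) -> float:
        return float(self.scores[self.order.index(conf_id)])


def order_by_scores(
    ensemble: LabelledEnsemble,
    scores: np.ndarray,
    ranker_name: str,
    direction: str = "ascending",
    flags: dict | None = None,
) -> RankingResult:
    """Sort conformers by score; ties broken by generation order (stable)."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != ensemble.n_conformers:
        raise ValueError("one score per conformer required")
    key = scores if direction == "ascending" else -scores
    idx = np.lexsort((ensemble.gen_orders, key))
    return RankingResult(
        mol_id=ensemble.mol_id,
        ranker_name=ranker_name,
        order=[ensemble.conformers[i].conf_id for i in idx],
        scores=scores[idx],
        direction=direction,
        flags=flags or {},
    )


class ConformerRanker:
    """Base interface: optional fit on reference data, then rank ensembles."""

    name = "base"
    direction = "ascending"

    def fit(self, references=None) -> "ConformerRanker":
        return self

    def score(self, ensemble: LabelledEnsemble) -> np.ndarray:
        raise NotImplementedError

    def rank(self, ensemble: LabelledEnsemble) -> RankingResult:
        return order_by_scores(ensemble, self.score(ensemble), self.name, self.direction)
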