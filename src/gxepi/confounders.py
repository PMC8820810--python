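"""Change-in-estimate confounder selection with a BIC clause.

A candidate covariate enters the model only if (a) adding it changes at least
one of the three group odds ratios (exposed/wild, exposed/carrier,
unexposed/carrier, each versus the doubly-unexposed reference) by at least the
threshold (default 10%, relative), and (b) the Bayesian Information Criterion
strictly improves.  The search is forward: each round every remaining
candidate is refitted on top of the current model, the qualifying candidate
with the largest change is added, and the procedure stops when no candidate
qualifies.  Every evaluation is recorded in an audit trail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .effects import FittedModel

__all__ = ["CandidateEvaluation", "SelectionResult", "select_confounders"]


@dataclass
class CandidateEvaluation:
    round: int
    candidate: str
    ors_before: dict[str, float]
    ors_after: dict[str, float] | None
    change: float | None
    bic_before: float
    bic_after: float | None
    bic_improved: bool | None
    qualifies: bool
    selected: bool
    note: str = ""


@dataclass
class SelectionResult:
    selected: list[str]
    audit: list[CandidateEvaluation]


def _group_ors(model: FittedModel, group_terms: Sequence[str]) -> dict[str, float]:
    return {t: math.exp(model.coef(t)) for t in group_terms}


def _change_score(before: dict[str, float], after: dict[str, float]) -> float:
    return max(abs(after[t] - before[t]) / before[t] for t in before)


def select_confounders(
    fit_fn: Callable[[Sequence[str]], FittedModel],
    base_terms: Sequence[str],
    candidates: Sequence[str],
    group_terms: Sequence[str] = ("g1", "g2", "g3"),
    threshold: float = 0.10,
) -> SelectionResult:
    """Forward change-in-estimate selection over ``candidates``.

    ``fit_fn(terms)`` must fit the configured model with the given covariate
    terms (the group indicators are always part of the model) and return a
    :class:`FittedModel`.  Deterministic: ties in the change score are broken
    by candidate order; a fit failure skips the candidate for that round and
    is logged rather than raised.
    """
    base_terms = list(base_terms)
    remaining = list(candidates)
    selected: list[str] = []
    audit: list[CandidateEvaluation] = []
    current_model = fit_fn(base_terms)
    round_no = 0
    while remaining:
        round_no += 1
        ors_before = _group_ors(current_model, group_terms)
        bic_before = current_model.bic
        evaluations: list[tuple[float, str, FittedModel, CandidateEvaluation]] = []
        for candidate in remaining:
            terms = base_terms + selected + [candidate]
            try:
                model = fit_fn(terms)
            except Exception as exc:  # fit failure: log, do not abort selection
                audit.append(CandidateEvaluation(
                    round=round_no, candidate=candidate, ors_before=ors_before,
                    ors_after=None, change=None, bic_before=bic_before,
                    bic_after=None, bic_improved=None, qualifies=False,
                    selected=False, note=f"fit failed: {exc}",
                ))
                continue
            ors_after = _group_ors(model, group_terms)
            change = _change_score(ors_before, ors_after)
            bic_improved = model.bic < bic_before
            qualifies = change >= threshold - 1e-12 and bic_improved
            evaluation = CandidateEvaluation(
                round=round_no, candidate=candidate, ors_before=ors_before,
                ors_after=ors_after, change=change, bic_before=bic_before,
                bic_after=model.bic, bic_improved=bic_improved,
                qualifies=qualifies, selected=False,
                note="" if model.converged else "fit did not converge",
            )
            audit.append(evaluation)
            if qualifies:
                evaluations.append((change, candidate, model, evaluation))
        if not evaluations:
            break
        # largest change wins; ties resolved by candidate order (stable max)
        best = max(evaluations, key=lambda item: item[0])
        _, winner, winner_model, winner_eval = best
        winner_eval.selected = True
        selected.append(winner)
        remaining.remove(winner)
        current_model = winner_model
    return SelectionResult(selected=selected, audit=audit)
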