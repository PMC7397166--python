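"""Successful-soldier filtering and greedy non-deteriorating majority-vote ensembles.

Candidates are ranked by selection rho (ties: MCC, then accuracy, then
stable input order) after discarding everything with MCC <= 0 — a model no
better than random guessing never enters an ensemble. The greedy builder
seeds the ensemble with the top candidate and tentatively adds each next
one, recomputing the ensemble's rho on the same selection protocol the
members were scored on; an addition is kept only if rho does not
deteriorate (>=, or strictly > with ``strict=True``). By construction the
rho trajectory is non-decreasing and the final ensemble's selection rho is
at least the best single member's.

The final (two-phase) ensemble supports three build strategies:

a. pool both phase ensembles' members with no re-selection;
b. start from the lower-rho phase ensemble and greedily admit members of
   the other whose rho is at least the current ensemble rho;
c. (default) merge both filtered candidate lists, re-rank by rho, and run
   the greedy builder from scratch.

Voting is by per-sample majority; an exact tie goes to the member with the
highest selection rho.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import EvaluationResult, epsilon_for_fraction


class EnsembleError(RuntimeError):
    pass


def majority_vote(member_predictions, member_rhos) -> np.ndarray:
    """Per-sample modal prediction; exact ties decided by the highest-rho member."""
    P = np.asarray(member_predictions, dtype=int)
    if P.ndim != 2 or P.shape[0] == 0:
        raise EnsembleError("need a members x samples prediction matrix")
    m = P.shape[0]
    ones = P.sum(axis=0)
    out = (2 * ones > m).astype(int)
    tie = 2 * ones == m
    if tie.any():
        leader = int(np.argmax(member_rhos))
        out[tie] = P[leader, tie]
    return out


def rank_soldiers(soldiers) -> list:
    """Descending by selection rho, ties by MCC then accuracy, stably."""
    return sorted(
        soldiers,
        key=lambda s: (s.selection_eval.rho, s.selection_eval.mcc, s.selection_eval.accuracy),
        reverse=True,
    )


def filter_successful(soldiers, epsilon: float | None = None, fraction: float = 0.33) -> list:
    """Keep soldiers with MCC > 0 and rho above threshold, ranked.

    ``epsilon`` is an explicit threshold override; otherwise the threshold
    admits at least the top ``fraction`` of eligible members (boundary ties
    included).
    """
    eligible = [s for s in soldiers if s.selection_eval.mcc > 0]
    if not eligible:
        return []
    if epsilon is None:
        epsilon, _ = epsilon_for_fraction([s.selection_eval.rho for s in eligible], fraction)
    passing = [s for s in eligible if s.selection_eval.rho > epsilon]
    return rank_soldiers(passing)


def _vote_eval(members, y_selection: np.ndarray) -> EvaluationResult:
    votes = np.vstack([m.selection_predictions for m in members])
    rhos = [m.selection_eval.rho for m in members]
    return EvaluationResult.from_predictions(majority_vote(votes, rhos), y_selection)


@dataclass(eq=False)
class Ensemble:
    """Ordered majority-vote ensemble with its greedy rho trajectory."""

    members: list
    rho_trajectory: list
    selection_eval: EvaluationResult
    strategy: str
    holdout_eval: EvaluationResult | None = None

    @property
    def member_rhos(self) -> list:
        return [m.selection_eval.rho for m in self.members]

    def predict(self, dataset) -> np.ndarray:
        if not self.members:
            raise EnsembleError("empty ensemble")
        votes = np.vstack([m.predict(dataset) for m in self.members])
        return majority_vote(votes, self.member_rhos)

    def to_dict(self, member_ids=None) -> dict:
        return {
            "strategy": self.strategy,
            "members": list(member_ids) if member_ids is not None else list(range(len(self.members))),
            "rho_trajectory": [float(r) for r in self.rho_trajectory],
            "selection": self.selection_eval.to_dict(),
            "holdout": None if self.holdout_eval is None else self.holdout_eval.to_dict(),
        }


def build_greedy_ensemble(candidates, y_selection, strategy_tag: str = "lig", strict: bool = False) -> Ensemble:
    """Greedy non-deteriorating construction from a ranked candidate list."""
    if not candidates:
        raise EnsembleError("no successful soldiers to ensemble")
    members = [candidates[0]]
    current = _vote_eval(members, y_selection)
    trajectory = [current.rho]
    for cand in candidates[1:]:
        trial = _vote_eval(members + [cand], y_selection)
        accept = trial.rho > current.rho if strict else trial.rho >= current.rho
        if accept:
            members.append(cand)
            current = trial
            trajectory.append(current.rho)
    return Ensemble(
        members=members,
        rho_trajectory=trajectory,
        selection_eval=current,
        strategy=strategy_tag,
    )


def build_final_ensemble(
    lig_filtered,
    ft_filtered,
    strategy: str,
    y_selection,
    lig_ensemble: Ensemble | None = None,
    ft_ensemble: Ensemble | None = None,
    strict: bool = False,
    tag: str | None = None,
) -> Ensemble:
    """Two-phase combination of filtered LIG and FT soldiers."""
    if strategy not in ("a", "b", "c"):
        raise EnsembleError(f"unknown final-ensemble strategy {strategy!r}")
    if not lig_filtered and not ft_filtered:
        raise EnsembleError("both candidate lists are empty")
    tag = tag or f"final_{strategy}"

    if strategy == "c":
        merged = rank_soldiers(list(lig_filtered) + list(ft_filtered))
        ens = build_greedy_ensemble(merged, y_selection, strategy_tag=tag, strict=strict)
        return ens

    # (a) and (b) operate on the two phase ensembles
    if lig_ensemble is None and lig_filtered:
        lig_ensemble = build_greedy_ensemble(list(lig_filtered), y_selection, "lig", strict)
    if ft_ensemble is None and ft_filtered:
        ft_ensemble = build_greedy_ensemble(list(ft_filtered), y_selection, "ft", strict)
    phase = [e for e in (lig_ensemble, ft_ensemble) if e is not None]

    if strategy == "a":
        members = [m for e in phase for m in e.members]
        ev = _vote_eval(members, y_selection)
        return Ensemble(members=members, rho_trajectory=[ev.rho], selection_eval=ev, strategy=tag)

    # strategy b: start from the lower-rho phase ensemble (starting from the
    # higher one admits nothing, since every other-phase member must reach
    # the current ensemble's rho)
    if len(phase) == 1:
        start, other_members = phase[0], []
    else:
        phase.sort(key=lambda e: e.selection_eval.rho)
        start = phase[0]
        other_members = rank_soldiers(phase[1].members)
    members = list(start.members)
    current = _vote_eval(members, y_selection)
    trajectory = [current.rho]
    for cand in other_members:
        if cand.selection_eval.rho < current.rho:
            continue
        trial = _vote_eval(members + [cand], y_selection)
        accept = trial.rho > current.rho if strict else trial.rho >= current.rho
        if accept:
            members.append(cand)
            current = trial
            trajectory.append(current.rho)
    return Ensemble(members=members, rho_trajectory=trajectory, selection_eval=current, strategy=tag)
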