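"""Stepwise covariate selection with a collinearity pre-screen.

Candidate covariate–parameter pairs are screened in three stages:

1. *Collinearity screen*: among continuous covariates, any pair with squared
   Pearson correlation above 0.5 keeps only the higher-priority member
   (weight over height over BMI; total protein over albumin; AST over ALT),
   so strongly redundant covariates never compete in the stepwise search.
2. *Forward inclusion*: at each step every remaining candidate is added to
   the current model and refitted; the candidate with the largest OFV drop
   is accepted if the drop exceeds the chi-square threshold 6.635
   (p < 0.01, 1 df). Ties break deterministically (larger drop, then fewer
   added parameters, then name).
3. *Backward elimination*: covariates are deleted one at a time; the
   covariate whose removal costs the least OFV is removed when that cost is
   at most 10.828 (p < 0.001, 1 df), i.e. a covariate survives only if its
   removal worsens the fit by more than 10.828.

Screening fits use the ``fast`` optimizer preset warm-started from the
parent model; an accepted model is refitted before serving as the next
parent so that OFV differences stay accurate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .data import PopPKDataset
from .estimation import CovariateEffect, PopPKModel, PopPKResults, lrt_threshold

__all__ = [
    "DEFAULT_PRIORITY",
    "CollinearityResult",
    "SelectionTrace",
    "collinearity_screen",
    "forward_step",
    "backward_step",
    "stepwise",
]

#: when two covariates are collinear, the earlier name in this list wins
DEFAULT_PRIORITY = ("WT", "HT", "BMI", "TP", "ALB", "AST", "ALT")

FORWARD_THRESHOLD = lrt_threshold(0.01, 1)      # 6.635 to 3 d.p.
BACKWARD_THRESHOLD = lrt_threshold(0.001, 1)    # 10.828 to 3 d.p.


@dataclass(frozen=True)
class CollinearityResult:
    retained: tuple[str, ...]
    dropped: tuple[tuple[str, str, float], ...]   # (dropped, kept, r2)
    r2_matrix: pd.DataFrame


def _priority_rank(name: str, priority: Sequence[str]) -> tuple[int, str]:
    try:
        return (priority.index(name), name)
    except ValueError:
        return (len(priority), name)


def collinearity_screen(covariate_table: pd.DataFrame,
                        columns: Optional[Sequence[str]] = None,
                        threshold: float = 0.5,
                        priority: Sequence[str] = DEFAULT_PRIORITY) -> CollinearityResult:
    """Drop one member of every continuous-covariate pair with r² above the
    threshold. Categorical (0/1) covariates are not screened. Constant
    columns are excluded with a warning (correlation undefined)."""
    if len(covariate_table) < 3:
        raise ValueError("collinearity screen needs at least 3 subjects")
    if columns is None:
        columns = [c for c in covariate_table.columns
                   if covariate_table[c].dtype.kind in "fi"
                   and covariate_table[c].nunique() > 2]
    cols = []
    for c in columns:
        if covariate_table[c].nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; excluded from screen")
            continue
        cols.append(c)
    sub = covariate_table[cols].astype(float)
    r2 = sub.corr() ** 2

    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if r2.loc[a, b] > threshold:
                pairs.append((float(r2.loc[a, b]), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    retained = list(cols)
    dropped = []
    for val, a, b in pairs:
        if a in retained and b in retained:
            keep, drop = sorted((a, b), key=lambda n: _priority_rank(n, priority))
            retained.remove(drop)
            dropped.append((drop, keep, val))
    return CollinearityResult(tuple(retained), tuple(dropped), r2)


@dataclass
class SelectionStep:
    step: int
    action: str            # base | add | remove | stop
    pair: Optional[str]
    covariates: str
    ofv: float
    delta_ofv: float
    comment: str = ""


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.steps.append(SelectionStep(step=len(self.steps) + 1, **kw))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"Step": s.step, "Action": s.action,
              "Covariate screening": s.covariates, "OFV": s.ofv,
              "dOFV": s.delta_ofv, "Comments": s.comment} for s in self.steps])


def _effects_label(effects: Sequence[CovariateEffect]) -> str:
    return "/".join(f"{e.parameter}-{e.covariate}" for e in effects) or "None"


def _fit_with_effects(dataset: PopPKDataset, template: PopPKModel,
                      effects: Sequence[CovariateEffect],
                      start: dict, maxiter: Optional[int]) -> PopPKResults:
    model = PopPKModel(dataset, structural=template.structural,
                       covariate_effects=effects, iiv=template.iiv,
                       fixed_omega2=template.fixed_omega2,
                       residual=template.residual)
    st = {k: v for k, v in start.items() if k in model.param_names}
    for e in effects:
        st.setdefault(e.name, 0.0)
    return model.fit(start=st, preset="fast", maxiter=maxiter, compute_se=False)


def _refit(fit: PopPKResults) -> PopPKResults:
    """Polish an accepted screening fit at the standard tolerance so the
    next round's OFV differences are anchored to a converged parent."""
    model = fit.model
    return _fit_with_effects(model.dataset, model,
                             list(model.covariate_effects),
                             dict(fit.params), None)


def forward_step(current: PopPKResults, candidates: Iterable[CovariateEffect],
                 threshold: float = FORWARD_THRESHOLD,
                 screen_maxiter: int = 60):
    """Try each remaining candidate; return ``(augmented_fit, effect, scores)``
    for the largest OFV drop above the threshold, else ``(None, None,
    scores)``. Candidates whose fit fails are skipped with a warning."""
    model = current.model
    present = {e.name for e in model.covariate_effects}
    scores = []
    fits = {}
    for cand in candidates:
        if cand.name in present:
            continue
        try:
            fit = _fit_with_effects(model.dataset, model,
                                    list(model.covariate_effects) + [cand],
                                    dict(current.params), screen_maxiter)
        except Exception as exc:  # noqa: BLE001 - candidate failure is data-driven
            warnings.warn(f"candidate {cand.name} failed to fit: {exc}")
            continue
        scores.append((cand, current.ofv - fit.ofv))
        fits[cand.name] = fit
    if not scores:
        return None, None, scores
    scores.sort(key=lambda t: (-t[1], t[0].name))
    best, delta = scores[0]
    if delta > threshold:
        return fits[best.name], best, scores
    return None, None, scores


def backward_step(current: PopPKResults,
                  protected: Sequence[str] = (),
                  threshold: float = BACKWARD_THRESHOLD,
                  screen_maxiter: int = 60):
    """Delete the covariate whose removal costs the least OFV, provided the
    cost does not exceed the threshold (strictly greater cost retains it).
    Returns ``(reduced_fit, removed_effect, scores)`` or ``(None, None,
    scores)`` when every remaining covariate is needed."""
    model = current.model
    removable = [e for e in model.covariate_effects if e.name not in protected]
    scores = []
    fits = {}
    for eff in removable:
        rest = [e for e in model.covariate_effects if e is not eff]
        try:
            fit = _fit_with_effects(model.dataset, model, rest,
                                    dict(current.params), screen_maxiter)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"removal of {eff.name} failed to fit: {exc}")
            continue
        scores.append((eff, fit.ofv - current.ofv))
        fits[eff.name] = fit
    if not scores:
        return None, None, scores
    scores.sort(key=lambda t: (t[1], t[0].name))
    eff, cost = scores[0]
    if cost <= threshold:
        return fits[eff.name], eff, scores
    return None, None, scores


def stepwise(dataset: PopPKDataset, candidates: Sequence[CovariateEffect],
             structural: str = "two_compartment",
             base_effects: Sequence[CovariateEffect] = (),
             iiv: Optional[Sequence[str]] = None,
             residual: str = "multiplicative",
             forward_threshold: float = FORWARD_THRESHOLD,
             backward_threshold: float = BACKWARD_THRESHOLD,
             start: Optional[dict] = None,
             screen_maxiter: int = 60,
             base_preset: str = "fast"):
    """Full forward-inclusion / backward-elimination search.

    Returns ``(final_fit, trace)`` where the trace mirrors a published
    stepwise report: one row per accepted step with model OFV and the OFV
    change the decision was based on."""
    base_model = PopPKModel(dataset, structural=structural,
                            covariate_effects=base_effects, iiv=iiv,
                            residual=residual)
    current = base_model.fit(start=start, preset=base_preset, compute_se=False)
    trace = SelectionTrace()
    trace.append(action="base", pair=None,
                 covariates=_effects_label(base_effects),
                 ofv=current.ofv, delta_ofv=np.nan, comment="Base model")

    while True:
        fit, eff, _ = forward_step(current, candidates,
                                   threshold=forward_threshold,
                                   screen_maxiter=screen_maxiter)
        if fit is None:
            break
        fit = _refit(fit)
        delta = current.ofv - fit.ofv
        current = fit
        trace.append(action="add", pair=eff.name,
                     covariates=_effects_label(current.model.covariate_effects),
                     ofv=current.ofv, delta_ofv=delta, comment="")
    if trace.steps:
        trace.steps[-1].comment = "Full model" if len(trace.steps) > 1 else "Base model"

    protected = tuple(e.name for e in base_effects)
    while True:
        fit, eff, _ = backward_step(current, protected=protected,
                                    threshold=backward_threshold,
                                    screen_maxiter=screen_maxiter)
        if fit is None:
            break
        fit = _refit(fit)
        delta = fit.ofv - current.ofv
        current = fit
        trace.append(action="remove", pair=eff.name,
                     covariates=_effects_label(current.model.covariate_effects),
                     ofv=current.ofv, delta_ofv=delta, comment="")
    if trace.steps and trace.steps[-1].action == "remove":
        trace.steps[-1].comment = "Final model"
    else:
        trace.append(action="stop", pair=None,
                     covariates=_effects_label(current.model.covariate_effects),
                     ofv=current.ofv, delta_ofv=np.nan, comment="Final model")
    return current, trace
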