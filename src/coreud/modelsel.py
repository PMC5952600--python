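"""AIC-based model selection: Akaike weights, the nested-model exclusion rule,
and relative variable importance.

Operates on candidate-model summaries (name, term set, df, AIC) supplied by
any fitting backend — the statistical fits themselves (GAMM/GLMM or the
bundled ordinary-least-squares backend for synthetic end-to-end runs) live
outside this module. The final model set keeps candidates with ΔAIC < 6 that
are not nested versions of a simpler model with equal-or-lower AIC, which
prevents retaining needlessly complex models.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DELTA_AIC_CUTOFF = 6.0


@dataclass(frozen=True)
class ModelRecord:
    name: str
    terms: frozenset
    df: int
    aic: float
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not np.isfinite(self.aic):
            raise ValueError("aic must be finite")


def expand_terms(terms: frozenset) -> frozenset:
    """Term set augmented with the main effects implied by interactions.

    Interaction labels use ':' (a smooth wrapper ``s(...)`` is stripped), so
    "s(Season:Sex)" implies "Season" and "Sex" for nesting comparisons.
    """
    out = set()
    for t in terms:
        label = t[2:-1] if t.startswith("s(") and t.endswith(")") else t
        out.add(label)
        if ":" in label:
            out.update(label.split(":"))
    return frozenset(out)


def _bare(term: str) -> str:
    return term[2:-1] if term.startswith("s(") and term.endswith(")") else term


def contains_predictor(model: ModelRecord, predictor: str) -> bool:
    """Literal membership: the predictor label matches a (bare) model term."""
    return any(_bare(t) == predictor or t == predictor for t in model.terms)


def akaike_weights(models: list[ModelRecord]) -> list[ModelRecord]:
    """Fill Akaike weights w_i = exp(-ΔAIC_i / 2) / Σ exp(-ΔAIC_j / 2)."""
    if not models:
        raise ValueError("need at least one model")
    aics = np.array([m.aic for m in models])
    rel = np.exp(-(aics - aics.min()) / 2.0)
    w = rel / rel.sum()
    return [replace(m, weight=float(wi)) for m, wi in zip(models, w)]


def richards_final_set(models: list[ModelRecord]) -> list[ModelRecord]:
    """Final model set: ΔAIC < 6, excluding nested versions of simpler models.

    A model is excluded when some other candidate whose (interaction-expanded)
    term set is a strict subset of its own has equal-or-lower AIC. Output is
    sorted by AIC.
    """
    if not models:
        return []
    amin = min(m.aic for m in models)
    kept = []
    for m in models:
        if m.aic - amin >= DELTA_AIC_CUTOFF:
            continue
        em = expand_terms(m.terms)
        nested_over_simpler = any(
            expand_terms(o.terms) < em and o.aic <= m.aic
            for o in models
            if o is not m
        )
        if not nested_over_simpler:
            kept.append(m)
    return sorted(kept, key=lambda m: (m.aic, m.name))


def relative_importance(
    final_set: list[ModelRecord],
    predictors: list[str] | None = None,
    recompute_weights: bool = True,
) -> dict[str, float]:
    """Relative importance: sum of final-set weights of models with the term.

    With ``recompute_weights=True`` (default) Akaike weights are renormalized
    over the final set before summing; with False the weights already on the
    records (e.g. published, rounded values) are passed through, which can
    make a term present in every model score slightly below 1.
    """
    if recompute_weights:
        final_set = akaike_weights(list(final_set))
    if any(m.weight is None for m in final_set):
        raise ValueError("final-set models need weights")
    if predictors is None:
        predictors = sorted({_bare(t) for m in final_set for t in m.terms})
    scores = {}
    for p in predictors:
        hit = [m for m in final_set if contains_predictor(m, p)]
        if not hit:
            logger.warning("predictor %r appears in no final-set model", p)
        scores[p] = float(sum(m.weight for m in hit))
    return scores


def ols_candidates(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    max_terms: int | None = None,
) -> list[ModelRecord]:
    """Minimal OLS backend: all-subsets candidate models from a data frame.

    Fits ordinary least squares for every subset of ``terms`` (plus the
    intercept-only model) via statsmodels formulas and returns AIC records,
    for end-to-end synthetic model-selection runs.
    """
    import statsmodels.formula.api as smf

    records = []
    limit = len(terms) if max_terms is None else max_terms
    for k in range(0, limit + 1):
        for combo in itertools.combinations(terms, k):
            rhs = " + ".join(combo) if combo else "1"
            fit = smf.ols(f"{response} ~ {rhs}", data=data).fit()
            records.append(ModelRecord(
                name=rhs,
                terms=frozenset(combo),
                df=int(fit.df_model) + 2,  # coefficients + residual variance
                aic=float(fit.aic),
            ))
    return records
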