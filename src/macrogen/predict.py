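"""Projection of the most parsimonious GD model onto all grid cells.

The best model (minimal AICc; ties broken by parsimony then lexicographic
variable order) is evaluated for every cell with complete predictor data.
Because the model is fit on square-root transformed GD, predictions are
back-transformed by squaring the linear predictor after clipping it at
zero; no retransformation (smearing) correction is applied by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import FittedModel, ModelSet, NoValidModelsError

log = logging.getLogger(__name__)


def select_best_model(models: ModelSet) -> FittedModel:
    """Model with minimal AICc; ties go to fewer variables, then name order."""
    if not models.models:
        raise NoValidModelsError("empty model set")
    best = min(
        models.models,
        key=lambda f: (round(f.aicc, 10), len(f.variables), f.variables),
    )
    runner_ups = [f for f in models.models
                  if round(f.aicc, 10) == round(best.aicc, 10)]
    if len(runner_ups) > 1:
        log.info("AICc tie among %s; selected %s by parsimony",
                 [f.variables for f in runner_ups], best.variables)
    return best


def predict_gd(model: FittedModel, predictors: pd.DataFrame,
               training_ids=None, square_backtransform: bool = True
               ) -> pd.DataFrame:
    """Predict GD for every row of ``predictors`` with complete model inputs.

    ``predictors`` must be indexed by cell/unit id.  Rows missing any model
    variable are skipped (logged).  Returns a DataFrame indexed by unit id
    with columns sqrt_gd_pred, gd_pred and is_training.
    """
    cols = list(model.variables)
    complete = predictors[cols].notna().all(axis=1)
    n_skip = int((~complete).sum())
    if n_skip:
        log.info("skipping %d unit(s) with incomplete predictors", n_skip)
    sub = predictors.loc[complete, cols]
    yhat = model.predict(sub)
    if square_backtransform:
        gd_hat = np.maximum(yhat, 0.0) ** 2
    else:
        gd_hat = yhat
    training = set(training_ids or [])
    return pd.DataFrame(
        {
            "sqrt_gd_pred": yhat,
            "gd_pred": gd_hat,
            "is_training": [i in training for i in sub.index],
        },
        index=sub.index,
    )
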