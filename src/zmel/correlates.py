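"""Burden-covariate statistics: Pearson correlation and count GLMs.

The burden table holds, per sample, substitution/indel/copy-number event
counts together with the engineered driver count and age at collection
(months).  Mutation burden is expected to rise with age (a uniform basal
mutational clock) and fall with the number of engineered drivers (fewer
somatic events needed when more initiating lesions are pre-configured);
these directions are tested by Pearson correlation and by Poisson
log-link GLMs with a quasi-Poisson fallback under overdispersion.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import MutationRecord, SampleMetadata, count_drivers

__all__ = ["build_burden_table", "correlate", "burden_glm"]

logger = logging.getLogger(__name__)


def build_burden_table(
    samples: Sequence[SampleMetadata],
    mutations: Iterable[MutationRecord],
    cna_events_per_sample: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-sample burden table: counts, driver count, age, ploidy.

    ``cna_events_per_sample`` counts each amplified or homozygously deleted
    segment as one event.
    """
    mutations = list(mutations)
    rows = []
    for m in samples:
        subs = sum(1 for r in mutations if r.sample_id == m.sample_id and r.is_snv)
        indels = sum(
            1 for r in mutations if r.sample_id == m.sample_id and not r.is_snv
        )
        rows.append(
            {
                "sample_id": m.sample_id,
                "substitution_count": subs,
                "indel_count": indels,
                "cna_event_count": (cna_events_per_sample or {}).get(m.sample_id, 0),
                "driver_count": count_drivers(m),
                "age": m.age,
                "ploidy": m.ploidy,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def correlate(
    burden_table: pd.DataFrame, x: str, y: str
) -> tuple[float | None, float | None]:
    """Pearson product-moment correlation with two-sided p.

    Rows with a missing value in either column are excluded listwise.
    Returns (None, None) with a warning when fewer than 3 complete pairs
    remain or either column has zero variance.
    """
    sub = burden_table[[x, y]].dropna()
    if len(sub) < 3:
        logger.warning("correlate(%s, %s): fewer than 3 complete pairs", x, y)
        return None, None
    if sub[x].nunique() < 2 or sub[y].nunique() < 2:
        logger.warning("correlate(%s, %s): zero variance", x, y)
        return None, None
    r, p = stats.pearsonr(sub[x], sub[y])
    return float(r), float(p)


def burden_glm(
    burden_table: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
    dispersion_threshold: float = 2.0,
):
    """Poisson log-link GLM of a count response on covariates.

    Fitted by IRLS through statsmodels; returns the statsmodels results
    object (coefficients, Wald p-values, deviance).  When the Pearson
    dispersion of the Poisson fit exceeds ``dispersion_threshold`` the
    model is refitted quasi-Poisson style (Wald tests scaled by the
    estimated dispersion).  Rows with missing values are dropped listwise;
    a rank-deficient design is an error.
    """
    cols = [response, *covariates]
    sub = burden_table[cols].dropna()
    y = sub[response].to_numpy()
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError(f"response {response!r} must be a count column")
    X = sm.add_constant(sub[list(covariates)].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (constant covariate?)")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit()
    dispersion = res.pearson_chi2 / res.df_resid if res.df_resid > 0 else 1.0
    if dispersion > dispersion_threshold:
        logger.info(
            "Pearson dispersion %.2f > %.1f; refitting quasi-Poisson",
            dispersion, dispersion_threshold,
        )
        res = model.fit(scale="X2")
    return res
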