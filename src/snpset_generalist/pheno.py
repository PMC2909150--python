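"""Phenotype preparation: standardization, covariate residualization and
composite scores.

Every analysis measure is (i) residualized on sex and age-at-testing by
ordinary least squares on complete cases, then (ii) re-standardized to mean 0
and SD 1 (sample SD, n-1 denominator), so downstream correlations are
scale-free.  Composites follow the standardize - average - re-standardize
recipe; a composite may either fall back to the single available component or
require all components, depending on its spec.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .io import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositeSpec:
    """Recipe for a composite measure.

    ``fallback_single``: individuals with a single available component enter
    with that standardized component.  ``require_all``: any missing component
    makes the composite missing.  With neither, the mean of whatever
    standardized components are present is used.
    """

    name: str
    components: tuple[str, ...]
    fallback_single: bool = False
    require_all: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) < 2:
            raise ConfigError(f"{self.name}: composite needs >= 2 components")
        if self.fallback_single and self.require_all:
            raise ConfigError(
                f"{self.name}: fallback_single and require_all are exclusive")


def standardize(v: pd.Series) -> pd.Series:
    """Z-score the non-missing entries (mean 0, sample SD 1); keep NaN."""
    obs = v.dropna()
    if len(obs) < 2:
        raise DegenerateInputError(
            f"{v.name}: need >= 2 non-missing values to standardize")
    sd = obs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError(f"{v.name}: constant vector")
    return (v - obs.mean()) / sd


def residualize(v: pd.Series, covariates, restandardize: bool = True,
                drop_constant: bool = True) -> pd.Series:
    """OLS residuals of ``v`` on the covariates (with intercept), computed on
    complete cases and re-standardized by default.

    Rows missing ``v`` or any covariate come back NaN.  Constant covariates
    are dropped with a warning when ``drop_constant`` (an all-constant age
    column carries no information); a genuinely rank-deficient design raises.
    """
    if isinstance(covariates, pd.Series):
        covariates = [covariates]
    if isinstance(covariates, pd.DataFrame):
        covariates = [covariates[c] for c in covariates.columns]
    X = pd.concat(covariates, axis=1)
    X.columns = [c.name if c.name is not None else f"cov{i}"
                 for i, c in enumerate(covariates)]
    X = X.reindex(v.index)

    if drop_constant:
        keep = []
        for c in X.columns:
            obs = X[c].dropna()
            if len(obs) and obs.nunique() > 1:
                keep.append(c)
            else:
                logger.warning("covariate %r is constant; dropped from design", c)
        X = X[keep]

    complete = v.notna() & X.notna().all(axis=1)
    n, k = int(complete.sum()), X.shape[1]
    if n < k + 2:
        raise DegenerateInputError(
            f"{v.name}: only {n} complete cases for {k} covariates")

    design = np.column_stack([np.ones(n), X.loc[complete].to_numpy(float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise DegenerateInputError(f"{v.name}: rank-deficient covariate design")
    y = v.loc[complete].to_numpy(float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if np.var(resid) <= 1e-20 * max(np.var(y), 1e-30):
        raise DegenerateInputError(
            f"{v.name}: residuals are numerically zero (measure lies in the "
            f"covariate span)")

    out = pd.Series(np.nan, index=v.index, name=v.name)
    out.loc[complete] = resid
    if restandardize:
        out = standardize(out)
    return out


def build_composite(table: PhenotypeTable, spec: CompositeSpec) -> pd.Series:
    """Composite of standardized components, re-standardized.

    Each component is standardized over its own observed sample; per
    individual the available standardized components are averaged subject to
    the spec's availability rule; the averaged vector is standardized again.
    """
    comps = []
    for c in spec.components:
        comps.append(standardize(table.measure(c)))
    Z = pd.concat(comps, axis=1)
    n_avail = Z.notna().sum(axis=1)

    if spec.require_all:
        usable = n_avail == len(spec.components)
    elif spec.fallback_single:
        usable = n_avail >= 1
    else:
        usable = n_avail >= 1
    mean = Z.mean(axis=1).where(usable)
    if mean.notna().sum() < 2:
        raise DegenerateInputError(f"{spec.name}: no usable rows")
    out = standardize(mean)
    out.name = spec.name
    return out


def prepare_measures(table: PhenotypeTable,
                     composites: list[CompositeSpec] | None = None,
                     measures: list[str] | None = None,
                     restandardize: bool = True) -> PhenotypeTable:
    """Build composites, then residualize every analysis measure on sex and
    its age-at-testing column and re-standardize.

    Composites inherit the age column of their first component that has one.
    Returns a new table whose measure columns are analysis-ready.
    """
    table = table.copy()
    for spec in (composites or []):
        table.data[spec.name] = build_composite(table, spec)
        table.measures.append(spec.name)
        for c in spec.components:
            if c in table.age_by_measure:
                table.age_by_measure[spec.name] = table.age_by_measure[c]
                break

    targets = measures if measures is not None else list(table.measures)
    adjusted = table.copy()
    sex = table.sex()
    for m in targets:
        covs = [sex]
        age = table.age_for(m)
        if age is not None:
            covs.append(age)
        adjusted.data[m] = residualize(table.measure(m), covs,
                                       restandardize=restandardize)
    return adjusted
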