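"""Full-subset additive-model selection of clonal-richness drivers.

Candidate environmental predictors (cyclone-exposure probability, dugong
grazing-hotspot presence, mean SST, KD490 turbidity, distance from shore,
latitude) are screened for collinearity (|r| > 0.8 drops a predictor;
predictor pairs with |r| > 0.28 are never combined in one model), then
every admissible model of at most two predictors is fitted as a
Gaussian-response additive model: continuous predictors as regression
splines (basis dimension 4), the grazing hotspot as a factor, and
optionally a smooth-by-factor interaction. Models are ranked by AICc;
Akaike weights give per-predictor variable importance, and the selected
model is the most parsimonious within two AICc units of the best.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

#: Table-style display names for the study's standard predictors.
DISPLAY_NAMES = {
    "cyclone_pr": "cyclone",
    "sst": "SST",
    "kd490": "KD490",
    "dist_shore": "Dist.shore",
    "latitude": "latitude",
    "dugong": "dugong",
}

#: Default transforms: square root for skewed non-negative predictors,
#: log for SST. Response R is never transformed.
DEFAULT_TRANSFORMS = {
    "cyclone_pr": "sqrt",
    "sst": "log",
    "kd490": "sqrt",
    "dist_shore": "sqrt",
}

_TRANSFORM_FUNCS = {"sqrt": np.sqrt, "log": np.log, "identity": lambda x: x}


@dataclass
class DriverConfig:
    """Tunable knobs of the driver-selection pipeline."""

    transforms: dict = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    basis_df: int = 3          # spline columns per smooth; dimension 4 with intercept
    r_max: float = 0.8         # prefilter: drop predictor vs retained set
    pair_r_max: float = 0.28   # within-model pairing rule
    delta_cutoff: float = 2.0  # candidate set: delta AICc <= cutoff
    max_vars: int = 2
    include_interactions: bool = True
    factor_predictors: tuple = ("dugong",)
    keep_priority: tuple = (
        "cyclone_pr", "dugong", "sst", "kd490", "dist_shore", "latitude"
    )
    location_random_intercept: bool = False


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which predictors, and how each enters.

    ``terms`` is a tuple of (kind, payload): ("smooth", predictor),
    ("factor", predictor), or ("by_factor", (continuous, factor)).
    """

    terms: tuple

    @property
    def predictors(self) -> frozenset:
        out = set()
        for kind, payload in self.terms:
            if kind == "by_factor":
                out.update(payload)
            else:
                out.add(payload)
        return frozenset(out)

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    def label(self, transforms: dict = None) -> str:
        transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
        if not self.terms:
            return "null"

        def name(p):
            base = DISPLAY_NAMES.get(p, p)
            t = transforms.get(p, "identity")
            return base if t == "identity" else f"{base}.{t}"

        parts = []
        for kind, payload in self.terms:
            if kind == "by_factor":
                cont, fac = payload
                parts.append(f"{name(cont)}.by.{DISPLAY_NAMES.get(fac, fac)}")
            else:
                parts.append(name(payload))
        return "+".join(parts)


NULL_SPEC = ModelSpec(terms=())


@dataclass
class ModelFit:
    spec: ModelSpec
    label: str
    n: int
    k: float
    loglik: float
    aicc: float
    r2: float
    delta: float = math.nan
    weight: float = math.nan


@dataclass
class ModelTable:
    """Ranked fits plus the candidate set and the parsimonious selection."""

    fits: list
    delta_cutoff: float = 2.0

    @property
    def candidate_set(self) -> list:
        return [f for f in self.fits if f.delta <= self.delta_cutoff]

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    @property
    def parsimonious(self) -> ModelFit:
        return min(
            self.candidate_set,
            key=lambda f: (f.spec.n_predictors, f.aicc, f.label),
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"model": f.label, "AICc": f.aicc, "delta.AICc": f.delta,
              "wi.AICc": f.weight, "r2": f.r2, "n": f.n, "k": f.k}
             for f in self.fits]
        )


class ModelSizeError(ValueError):
    """Too few sites for the requested basis: fit refused, never shrunk."""


def aicc(loglik: float, k: float, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1).

    Infinite when n <= k + 1 (the correction blows up at the boundary).
    """
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def apply_transforms(df: pd.DataFrame, transforms: dict = None) -> pd.DataFrame:
    """Add transformed predictor columns ``<name>_t``, applied exactly once.

    Binary factors pass through as-is; an already-present ``<name>_t``
    column is left untouched so transforms never stack.
    """
    transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
    out = df.copy()
    for col, tname in transforms.items():
        tcol = f"{col}_t"
        if col in out.columns and tcol not in out.columns:
            out[tcol] = _TRANSFORM_FUNCS[tname](out[col].astype(float))
    for col in out.columns:
        if col not in transforms and not col.endswith("_t") and \
                pd.api.types.is_numeric_dtype(out[col]) and f"{col}_t" not in out.columns:
            out[f"{col}_t"] = out[col]
    return out


def _tcol(p: str) -> str:
    return f"{p}_t"


def predictor_correlations(df: pd.DataFrame, predictors: "list[str]",
                           factor_predictors=("dugong",)) -> pd.DataFrame:
    """Pairwise Pearson correlations on transformed predictors.

    The binary factor enters 0/1-coded, which makes its entries
    point-biserial correlations.
    """
    cols = {}
    for p in predictors:
        if p in factor_predictors:
            v = df[p]
            if v.dtype == object:
                v = (v.astype(str) == "present").astype(float)
            cols[p] = v.astype(float)
        else:
            cols[p] = df[_tcol(p)].astype(float)
    return pd.DataFrame(cols).corr()


def prefilter_predictors(
    df: pd.DataFrame,
    candidates: "list[str]",
    keep_priority: "tuple[str, ...]" = DriverConfig().keep_priority,
    r_max: float = 0.8,
    factor_predictors=("dugong",),
):
    """Drop collinear predictors (|r| > r_max) walking a priority order.

    Returns (retained predictors in priority order, drop log). A constant
    predictor has no defined correlation and is dropped with a warning.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate predictors")
    ordered = [p for p in keep_priority if p in candidates]
    ordered += [p for p in candidates if p not in ordered]
    corr = None
    non_constant = []
    for p in ordered:
        col = df[p] if p in factor_predictors and df[p].dtype == object else None
        vals = ((col.astype(str) == "present").astype(float)
                if col is not None else df[_tcol(p)].astype(float))
        if vals.nunique() <= 1:
            logger.warning("predictor %r is constant; dropped", p)
            continue
        non_constant.append(p)
    corr = predictor_correlations(df, non_constant, factor_predictors)
    retained, drop_log = [], []
    for p in non_constant:
        offending = [
            (q, corr.loc[p, q]) for q in retained if abs(corr.loc[p, q]) > r_max
        ]
        if offending:
            q, r = max(offending, key=lambda t: abs(t[1]))
            drop_log.append({"dropped": p, "against": q, "r": float(r)})
            logger.info("dropped %r: |r|=%.3f with retained %r", p, abs(r), q)
        else:
            retained.append(p)
    return retained, drop_log


def build_candidate_models(
    retained: "list[str]",
    correlations: pd.DataFrame,
    max_vars: int = 2,
    pair_r_max: float = 0.28,
    include_interactions: bool = False,
    factor_predictors=("dugong",),
) -> "list[ModelSpec]":
    """Enumerate the null, single-predictor, and admissible two-predictor
    models, plus factor/smooth-by-factor interaction variants when enabled.

    A two-predictor model is admissible when |pairwise r| <= pair_r_max.
    """
    if not retained:
        raise ValueError("no retained predictors")
    if max_vars > 2:
        raise ValueError("models are limited to two explanatory variables")

    def term(p):
        return ("factor", p) if p in factor_predictors else ("smooth", p)

    specs = [NULL_SPEC]
    specs += [ModelSpec(terms=(term(p),)) for p in retained]
    if max_vars >= 2:
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                p, q = retained[i], retained[j]
                if abs(correlations.loc[p, q]) > pair_r_max:
                    continue
                specs.append(ModelSpec(terms=(term(p), term(q))))
                if include_interactions:
                    fac = next((x for x in (p, q) if x in factor_predictors), None)
                    cont = q if fac == p else p
                    if fac is not None and cont not in factor_predictors:
                        specs.append(ModelSpec(terms=(
                            ("factor", fac), ("by_factor", (cont, fac)))))
    return specs


def _formula(spec: ModelSpec, basis_df: int, response: str = "R") -> str:
    if not spec.terms:
        return f"{response} ~ 1"
    parts = []
    for kind, payload in spec.terms:
        if kind == "smooth":
            parts.append(f"bs({_tcol(payload)}, df={basis_df}, degree=3)")
        elif kind == "factor":
            parts.append(f"C({payload})")
        else:
            cont, fac = payload
            parts.append(f"C({fac}):bs({_tcol(cont)}, df={basis_df}, degree=3)")
    return f"{response} ~ " + " + ".join(parts)


def fit_additive_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    config: DriverConfig = None,
    response: str = "R",
) -> ModelFit:
    """Fit one Gaussian additive model and score it.

    Continuous predictors enter as cubic regression splines with basis
    dimension 4 (three basis columns plus the shared intercept); the
    dugong factor is dummy-coded; smooth-by-factor terms give each factor
    level its own spline. k counts all mean parameters plus the residual
    scale. A fit whose sample size cannot support the basis is refused
    outright — the basis is never silently shrunk.
    """
    config = config or DriverConfig()
    data = apply_transforms(data, config.transforms)
    n = len(data)
    formula = _formula(spec, config.basis_df, response)

    if config.location_random_intercept and spec.terms:
        return _fit_mixed(data, spec, formula, n, config)

    model = smf.ols(formula, data=data)
    p_mean = model.exog.shape[1]
    k = p_mean + 1  # + residual scale
    if n < k + 2:
        raise ModelSizeError(
            f"{spec.label(config.transforms)}: n={n} cannot support "
            f"k={k} parameters (need n >= k + 2); refusing to shrink the basis"
        )
    if np.linalg.matrix_rank(model.exog) < p_mean:
        raise ValueError(
            f"{spec.label(config.transforms)}: rank-deficient design matrix"
        )
    res = model.fit()
    r2 = 0.0 if not spec.terms else float(res.rsquared)
    return ModelFit(
        spec=spec, label=spec.label(config.transforms), n=n, k=k,
        loglik=float(res.llf), aicc=aicc(float(res.llf), k, n), r2=r2,
    )


def _fit_mixed(data, spec, formula, n, config):
    """Optional location random intercept (ML, not REML, so AICc is
    comparable across mean structures)."""
    if "location" not in data.columns:
        raise ValueError("location column required for the random intercept")
    model = smf.mixedlm(formula, data=data, groups=data["location"])
    p_mean = model.exog.shape[1]
    k = p_mean + 2  # + random-intercept variance + residual scale
    if n < k + 2:
        raise ModelSizeError(
            f"{spec.label(config.transforms)}: n={n} cannot support k={k}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    fitted = res.fittedvalues
    y = data[formula.split("~")[0].strip()].astype(float)
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    return ModelFit(
        spec=spec, label=spec.label(config.transforms), n=n, k=k,
        loglik=float(res.llf), aicc=aicc(float(res.llf), k, n), r2=r2,
    )


def rank_models(fits: "list[ModelFit]", delta_cutoff: float = 2.0) -> ModelTable:
    """Rank by AICc; attach delta AICc and Akaike weights.

    wi = exp(-delta/2) / sum exp(-delta/2). Fits with non-finite AICc are
    excluded with a warning (they cannot carry weight).
    """
    usable = []
    for f in fits:
        if math.isfinite(f.aicc):
            usable.append(f)
        else:
            logger.warning("model %r has non-finite AICc; excluded", f.label)
    if not usable:
        raise ValueError("no model with finite AICc")
    usable = sorted(usable, key=lambda f: (f.aicc, f.label))
    best = usable[0].aicc
    rel = np.array([math.exp(-(f.aicc - best) / 2.0) for f in usable])
    weights = rel / rel.sum()
    ranked = [
        replace(f, delta=f.aicc - best, weight=float(w))
        for f, w in zip(usable, weights)
    ]
    return ModelTable(fits=ranked, delta_cutoff=delta_cutoff)


def variable_importance(table: ModelTable) -> dict:
    """importance(p) = sum of Akaike weights over models containing p.

    A smooth-by-factor term credits both participating predictors. A
    predictor in no fitted model gets importance 0.
    """
    out: dict = {}
    for f in table.fits:
        for p in f.spec.predictors:
            out[p] = out.get(p, 0.0) + f.weight
    return out


# -- label arithmetic on published-style tables -----------------------------

_LABEL_BASE = {
    "cyclone": "cyclone_pr", "SST": "sst", "KD490": "kd490",
    "Dist.shore": "dist_shore", "dugong": "dugong", "latitude": "latitude",
}


def parse_model_label(label: str) -> frozenset:
    """Predictor set from a table-style model label.

    ``"SST.log+dugong"`` -> {sst, dugong}; ``"dugong+SST.log.by.dugong"``
    -> {dugong, sst}; ``"null"`` -> {}. Transform suffixes (.log, .sqrt)
    are stripped; ``X.by.Y`` credits both X and Y.
    """
    if label.strip().lower() == "null":
        return frozenset()
    preds = set()
    for part in label.split("+"):
        part = part.strip()
        for chunk in part.split(".by."):
            base = chunk
            for suffix in (".log", ".sqrt"):
                if base.endswith(suffix):
                    base = base[: -len(suffix)]
            key = _LABEL_BASE.get(base, _LABEL_BASE.get(base.capitalize(), base))
            preds.add(key)
    return frozenset(preds)


def importance_from_weights(models: "list[tuple[str, float]]") -> dict:
    """Variable importance directly from (label, weight) rows of a ranked
    table — the arithmetic used to cross-check published importances."""
    out: dict = {}
    for label, w in models:
        for p in parse_model_label(label):
            out[p] = out.get(p, 0.0) + float(w)
    return out


def run_driver_analysis(
    covariates: pd.DataFrame,
    config: DriverConfig = None,
    response: str = "R",
) -> dict:
    """Full pipeline per species: prefilter -> enumerate -> fit -> rank ->
    importance. Returns {species: {"table": ModelTable, "importance": dict,
    "retained": [...], "dropped": [...]}}.
    """
    config = config or DriverConfig()
    results = {}
    for species, sub in covariates.groupby("species", sort=True):
        sub = apply_transforms(sub.reset_index(drop=True), config.transforms)
        candidates = [
            p for p in config.keep_priority if p in sub.columns
        ]
        retained, drop_log = prefilter_predictors(
            sub, candidates, keep_priority=config.keep_priority,
            r_max=config.r_max, factor_predictors=config.factor_predictors,
        )
        corr = predictor_correlations(sub, retained, config.factor_predictors)
        specs = build_candidate_models(
            retained, corr, max_vars=config.max_vars,
            pair_r_max=config.pair_r_max,
            include_interactions=config.include_interactions,
            factor_predictors=config.factor_predictors,
        )
        fits = []
        for spec in specs:
            try:
                fits.append(fit_additive_model(sub, spec, config, response))
            except ModelSizeError as exc:
                logger.warning("skipping %s", exc)
            except ValueError as exc:
                # e.g. a by-factor smooth whose sparse level cannot
                # identify its own spline: drop that model, keep the sweep
                logger.warning("skipping %s: %s",
                               spec.label(config.transforms), exc)
        table = rank_models(fits, config.delta_cutoff)
        results[species] = {
            "table": table,
            "importance": variable_importance(table),
            "retained": retained,
            "dropped": drop_log,
        }
    return results
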