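"""Missing-data handling: complete cases, rule-based inference, and
ten-fold model-based multiple imputation.

Three analysis datasets are constructed from the raw villager table:

(i)   complete cases only (rows with no missing required field);
(ii)  complete cases after inferring missing values that are logically
      forced by other answers (e.g. a respondent who saw no orangutan in
      the last year must have seen zero); this is the default dataset for
      the downstream analyses;
(iii) as (ii), with the remaining missing values filled by ten-fold
      model-based imputation: in each of ten rounds a bootstrap resample of
      the complete rows is drawn, a prediction model per variable is fit on
      it, and every missing cell is predicted from the observed covariates;
      the final value is the mean of the ten predictions (majority /
      thresholded for categorical semantics) with a per-cell variance
      reflecting imputation uncertainty.

Every cell carries provenance: observed, rule_inferred or imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression

__all__ = [
    "InferenceRule",
    "DEFAULT_RULES",
    "complete_cases",
    "infer_obvious",
    "BootstrapImputer",
    "ImputedDataset",
    "impute_tenfold",
    "build_datasets",
    "DEFAULT_REQUIRED_FIELDS",
    "DEFAULT_IMPUTATION_COVARIATES",
]

#: fields a row must have observed to count as complete for the analyses
DEFAULT_REQUIRED_FIELDS = (
    "sex",
    "trips_category",
    "nights_category",
    "ever_seen",
    "seen_last_year",
)

#: default predictors: demographics, trip variables, and the sighting
#: answers themselves — the rule-based inference step resolves the cells
#: other answers force, so the cells reaching the imputer are informative
#: about (e.g.) the longer-timeframe answers and must be conditioned on them
DEFAULT_IMPUTATION_COVARIATES = (
    "age",
    "sex",
    "ethnicity",
    "years_in_village",
    "trips_category",
    "nights_category",
    "ever_seen",
    "seen_last_year",
)


class RuleConflictError(ValueError):
    """Two inference rules imply different values for the same cell."""


@dataclass(frozen=True)
class InferenceRule:
    """``if <if_field> == <if_value> and <then_field> is missing, set it``.

    Only logically forced implications belong here — the rule table encodes
    the nesting of the sighting timeframes and count/indicator consistency,
    not statistical guesses.
    """

    rule_id: str
    if_field: str
    if_value: object
    then_field: str
    then_value: object


DEFAULT_RULES: tuple[InferenceRule, ...] = (
    InferenceRule("no_sighting_zero_count", "seen_last_year", "no", "n_seen_last_year", 0.0),
    InferenceRule("never_seen_not_last_year", "ever_seen", "no", "seen_last_year", "no"),
    InferenceRule("never_seen_not_last_month", "ever_seen", "no", "seen_last_month", "no"),
    InferenceRule("never_seen_not_last_week", "ever_seen", "no", "seen_last_week", "no"),
    InferenceRule("not_last_year_not_month", "seen_last_year", "no", "seen_last_month", "no"),
    InferenceRule("not_last_month_not_week", "seen_last_month", "no", "seen_last_week", "no"),
    InferenceRule("seen_last_year_implies_ever", "seen_last_year", "yes", "ever_seen", "yes"),
)


def rules_from_config(path) -> tuple[InferenceRule, ...]:
    """Load an inference rule table from a YAML or JSON file.

    Expected structure: a list of mappings with keys ``rule_id``,
    ``if_field``, ``if_value``, ``then_field``, ``then_value``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(InferenceRule(**entry) for entry in raw)


def complete_cases(villagers: pd.DataFrame, required_fields=DEFAULT_REQUIRED_FIELDS) -> pd.DataFrame:
    """Rows with no missing value among the required fields (dataset (i))."""
    required_fields = list(required_fields)
    if not required_fields:
        raise ValueError("required field list must be non-empty")
    present = [f for f in required_fields if f in villagers.columns]
    return villagers[villagers[present].notna().all(axis=1)].copy()


def infer_obvious(
    villagers: pd.DataFrame, rules: tuple[InferenceRule, ...] = DEFAULT_RULES
) -> tuple[pd.DataFrame, list[dict]]:
    """Fill missing cells that other answers logically force (dataset (ii)).

    Rules are applied to a fixpoint so that an inferred value can trigger
    further inferences (never-seen -> not seen last year -> zero count).
    Returns the completed table and a change log of
    ``{row, field, rule_id, value}``.  Two rules firing different values
    into the same cell raise :class:`RuleConflictError`.
    """
    out = villagers.copy()
    log: list[dict] = []
    changed = True
    while changed:
        changed = False
        fired: dict[tuple, tuple] = {}
        for rule in rules:
            if rule.if_field not in out.columns or rule.then_field not in out.columns:
                continue
            hit = (out[rule.if_field] == rule.if_value) & out[rule.then_field].isna()
            for idx in out.index[hit]:
                cell = (idx, rule.then_field)
                if cell in fired and fired[cell][1] != rule.then_value:
                    raise RuleConflictError(
                        f"rules {fired[cell][0]!r} and {rule.rule_id!r} disagree on "
                        f"row {idx}, field {rule.then_field!r}"
                    )
                fired[cell] = (rule.rule_id, rule.then_value)
        for (idx, col), (rule_id, value) in fired.items():
            if out[col].dtype == object or isinstance(value, str):
                out[col] = out[col].astype(object)
            out.at[idx, col] = value
            log.append({"row": int(idx) if isinstance(idx, (int, np.integer)) else idx,
                        "field": col, "rule_id": rule_id, "value": value})
            changed = True
    return out, log


@dataclass
class ImputedDataset:
    """Completed table plus per-cell provenance and imputation variance."""

    values: pd.DataFrame
    #: long-format per-imputed-cell record: row, column, variance
    imputation_variance: pd.DataFrame
    #: same shape as values, entries in {observed, rule_inferred, imputed,
    #: missing} (missing = no model was asked to fill the cell)
    provenance: pd.DataFrame
    #: long-format mean of the ten predictions for binary/continuous cells
    #: (row, column, mean_prediction); for binary cells this is the mean
    #: predicted probability *before* thresholding — prevalence estimates
    #: should use it, since majority-vote labels are biased toward the
    #: majority class
    mean_predictions: pd.DataFrame | None = None

    def binary_prevalence(self, column: str) -> float:
        """Prevalence of ``column == "yes"`` combining observed labels with
        the mean predicted probabilities of the imputed cells."""
        obs = self.provenance[column] != "imputed"
        total = float((self.values.loc[obs, column] == "yes").sum())
        if self.mean_predictions is not None and len(self.mean_predictions):
            mp = self.mean_predictions
            total += float(mp.loc[mp["column"] == column, "mean_prediction"].sum())
        return total / len(self.values)


class ImputationModelError(ValueError):
    """A variable has missing values but no viable prediction model."""


class BootstrapImputer(BaseEstimator):
    """Ten-fold model-based imputer (bootstrap, predict, average).

    Each round resamples the rows complete in (covariates + target) with
    replacement, fits a family-appropriate model (binary -> logistic,
    categorical -> multinomial logistic, continuous -> linear), and predicts
    every missing cell from its observed covariates.  Cells whose covariates
    are themselves missing fall back to the round's marginal model
    (intercept only).  The final imputation is the mean of the ten round
    predictions — majority class for categoricals, probability thresholded
    at 0.5 (ties to "no") for binaries — with the spread across rounds
    reported as the per-cell variance.

    Parameters
    ----------
    n_imputations : int
        Number of bootstrap-predict rounds (default 10).
    covariates : sequence of str
        Predictor fields; defaults to demographics plus trip variables.
    variables : sequence of str or None
        Fields to impute; by default every non-identifier, non-covariate
        column with at least one missing value.
    seed : int
        Seed for the bootstrap resampling.
    """

    def __init__(self, n_imputations: int = 10,
                 covariates=DEFAULT_IMPUTATION_COVARIATES,
                 variables=None, seed: int = 0):
        self.n_imputations = n_imputations
        self.covariates = covariates
        self.variables = variables
        self.seed = seed

    # -- internal helpers ---------------------------------------------------

    @staticmethod
    def _family(series: pd.Series) -> str:
        obs = series.dropna()
        if set(obs.unique()) <= {"yes", "no"}:
            return "binary"
        if obs.dtype == object:
            # masked numeric columns come back as object dtype
            converted = pd.to_numeric(obs, errors="coerce")
            if converted.notna().all():
                return "continuous"
            return "categorical"
        return "continuous"

    def _design(self, df: pd.DataFrame, covs: list[str]) -> pd.DataFrame:
        work = {}
        for c in covs:
            col = df[c]
            if col.dtype == object:
                # masked numeric columns come back as object; recover them
                converted = pd.to_numeric(col, errors="coerce")
                if converted.notna().sum() >= 0.9 * col.notna().sum():
                    col = converted
            work[c] = col
        return pd.get_dummies(pd.DataFrame(work), dummy_na=False, dtype=float)

    def fit(self, X: pd.DataFrame, y=None):
        del y
        covs = [c for c in self.covariates if c in X.columns]
        if self.variables is not None:
            targets = list(self.variables)
        else:
            # covariates with missing values are themselves imputed (a
            # variable is only ever excluded from its *own* design)
            skip = {"respondent_id", "village_id"}
            targets = []
            for c in X.columns:
                if c in skip or not X[c].isna().any():
                    continue
                # free-text / timestamp columns are not imputable categories
                if X[c].dtype == object and X[c].nunique() > 20:
                    continue
                targets.append(c)
        self.covariates_ = covs
        self.variables_ = targets
        self.families_ = {t: self._family(X[t]) for t in targets}
        for t in targets:
            if X[t].notna().sum() == 0:
                raise ImputationModelError(f"variable {t!r} has no observed rows to model")
        return self

    def transform(self, X: pd.DataFrame) -> ImputedDataset:
        rng = np.random.default_rng(self.seed)
        out = X.copy()
        provenance = pd.DataFrame("observed", index=X.index, columns=X.columns)
        provenance[X.isna()] = "missing"
        var_records: list[dict] = []
        mean_records: list[dict] = []

        for t in self.variables_:
            miss = X[t].isna()
            if not miss.any():
                continue
            # a variable never predicts itself
            covs_t = [c for c in self.covariates_ if c != t]
            design_t = self._design(X, covs_t)
            cov_complete = (
                X[covs_t].notna().all(axis=1) if covs_t else pd.Series(True, index=X.index)
            )
            family = self.families_[t]
            fit_rows = X.index[X[t].notna() & cov_complete]
            predict_rows = X.index[miss]
            preds = self._rounds(X, t, family, fit_rows, predict_rows,
                                 design_t, cov_complete, rng)
            final, variance, mean_pred = self._combine(preds, family)
            out[t] = out[t].astype(object) if family != "continuous" else out[t]
            for i, idx in enumerate(predict_rows):
                out.at[idx, t] = final[i]
                provenance.at[idx, t] = "imputed"
                var_records.append({"row": idx, "column": t, "variance": float(variance[i])})
                if mean_pred is not None:
                    mean_records.append(
                        {"row": idx, "column": t, "mean_prediction": float(mean_pred[i])}
                    )

        # cells that were missing but not in any target variable stay missing
        var_df = pd.DataFrame(var_records, columns=["row", "column", "variance"])
        mean_df = pd.DataFrame(mean_records, columns=["row", "column", "mean_prediction"])
        return ImputedDataset(values=out, imputation_variance=var_df,
                              provenance=provenance, mean_predictions=mean_df)

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> ImputedDataset:
        return self.fit(X, y).transform(X)

    def _rounds(self, X, t, family, fit_rows, predict_rows, full_design,
                cov_complete, rng):
        if len(fit_rows) == 0:
            raise ImputationModelError(
                f"variable {t!r}: no rows complete in covariates and target"
            )
        preds = []
        pred_design = full_design.loc[predict_rows].to_numpy(float)
        pred_cov_ok = cov_complete.loc[predict_rows].to_numpy(bool)
        y_all = X[t]
        for _ in range(self.n_imputations):
            boot = rng.choice(fit_rows, size=len(fit_rows), replace=True)
            yb = y_all.loc[boot]
            Xb = full_design.loc[boot].to_numpy(float)
            preds.append(self._predict_one(family, Xb, yb, pred_design, pred_cov_ok))
        return preds

    @classmethod
    def _predict_one(cls, family, Xb, yb, pred_design, pred_cov_ok):
        # bootstrap resamples routinely separate perfectly on dummy designs;
        # the resulting saturated fits are fine for prediction
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            return cls._predict_one_inner(family, Xb, yb, pred_design, pred_cov_ok)

    @staticmethod
    def _predict_one_inner(family, Xb, yb, pred_design, pred_cov_ok):
        n_pred = pred_design.shape[0]
        if family == "continuous":
            yb_num = pd.to_numeric(yb, errors="coerce").to_numpy(float)
            marginal = float(np.nanmean(yb_num))
            out = np.full(n_pred, marginal)
            if np.ptp(yb_num) > 0 and Xb.shape[1] > 0 and pred_cov_ok.any():
                model = LinearRegression().fit(Xb, yb_num)
                out[pred_cov_ok] = model.predict(pred_design[pred_cov_ok])
            return out
        # binary / categorical: work with class probabilities
        yvals = yb.astype(str).to_numpy()
        classes = np.unique(yvals)
        if family == "binary":
            marginal = float(np.mean(yvals == "yes"))
            out = np.full(n_pred, marginal)
            if len(classes) > 1 and Xb.shape[1] > 0 and pred_cov_ok.any():
                model = LogisticRegression(max_iter=1000).fit(Xb, yvals)
                p_yes = model.predict_proba(pred_design[pred_cov_ok])[:, list(model.classes_).index("yes")]
                out[pred_cov_ok] = p_yes
            return out
        # categorical: predicted class label per round
        counts = pd.Series(yvals).value_counts()
        marginal_class = counts.index[0]
        out = np.full(n_pred, marginal_class, dtype=object)
        if len(classes) > 1 and Xb.shape[1] > 0 and pred_cov_ok.any():
            model = LogisticRegression(max_iter=1000).fit(Xb, yvals)
            out[pred_cov_ok] = model.predict(pred_design[pred_cov_ok])
        return out

    @staticmethod
    def _combine(preds, family):
        if family == "continuous":
            arr = np.asarray(preds, dtype=float)  # rounds x cells
            mean = arr.mean(axis=0)
            return mean, arr.var(axis=0, ddof=0), mean
        if family == "binary":
            arr = np.asarray(preds, dtype=float)
            mean_p = arr.mean(axis=0)
            final = np.where(mean_p > 0.5, "yes", "no")  # ties -> "no"
            return final, arr.var(axis=0, ddof=0), mean_p
        # categorical: majority vote, variance = disagreement fraction
        arr = np.asarray(preds, dtype=object)  # rounds x cells
        final, variance = [], []
        for j in range(arr.shape[1]):
            vals, cnt = np.unique(arr[:, j].astype(str), return_counts=True)
            final.append(vals[np.argmax(cnt)])
            variance.append(1.0 - cnt.max() / cnt.sum())
        return np.asarray(final, dtype=object), np.asarray(variance), None


def impute_tenfold(
    villagers: pd.DataFrame,
    covariates=DEFAULT_IMPUTATION_COVARIATES,
    variables=None,
    n_imputations: int = 10,
    seed: int = 0,
) -> ImputedDataset:
    """Functional wrapper over :class:`BootstrapImputer` (dataset (iii))."""
    imp = BootstrapImputer(
        n_imputations=n_imputations, covariates=covariates, variables=variables, seed=seed
    )
    return imp.fit_transform(villagers)


def build_datasets(
    villagers: pd.DataFrame,
    required_fields=DEFAULT_REQUIRED_FIELDS,
    rules: tuple[InferenceRule, ...] = DEFAULT_RULES,
    seed: int = 0,
) -> dict:
    """The three analysis datasets keyed ``"i"``, ``"ii"``, ``"iii"``.

    ``"ii"`` (rule-inferred, then complete-case filtered) is the default
    input for the downstream modelling stages.
    """
    ds1 = complete_cases(villagers, required_fields)
    inferred, log = infer_obvious(villagers, rules)
    ds2 = complete_cases(inferred, required_fields)
    imputed = impute_tenfold(inferred, seed=seed)
    # merge rule-inference provenance into the imputed dataset's tags
    for entry in log:
        imputed.provenance.at[entry["row"], entry["field"]] = "rule_inferred"
    return {"i": ds1, "ii": ds2, "iii": imputed, "inference_log": log}
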