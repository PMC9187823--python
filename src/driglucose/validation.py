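"""Cohort validation: diabetes classification, odds ratios, logistic suites.

The index is validated against individual-level diabetes status with three
sets of logistic regression models — (a) bivariate: each predictor alone;
(b) semi-adjusted: index + age, sex, BMI, household income, urbanicity;
(c) fully adjusted: (b) + smoking, alcohol, diet score, physical activity —
reporting odds ratios with Wald 95% CIs, plus a stratified 80/20 split and
tenfold cross-validation of classification performance (accuracy,
sensitivity, specificity, Youden J, AROC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

Z95 = stats.norm.ppf(0.975)  # 1.959964...

#: glucose threshold (mmol/l) at or above which fasting glucose marks diabetes
FPG_THRESHOLD_MMOL_L = 7.0

MODEL_B_COVARIATES = ("age", "female", "bmi", "income_cat", "urban")
MODEL_C_EXTRAS = ("smoker", "drinker", "ahei", "met_high")


class MissingDataError(ValueError):
    pass


class ZeroCellError(ValueError):
    pass


def classify_diabetes(self_report, meds, fpg) -> bool:
    """Diabetes iff self-reported diagnosis, diabetes medication, or FPG >= 7.0.

    The fasting-glucose boundary is inclusive. All-missing inputs raise
    :class:`MissingDataError` so the participant is flagged and excluded
    with a log entry rather than silently classified.
    """
    vals = (self_report, meds, fpg)
    if all(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        raise MissingDataError("all diabetes-status inputs missing")
    if self_report:
        return True
    if meds:
        return True
    if fpg is not None and not (isinstance(fpg, float) and np.isnan(fpg)):
        if fpg < 0:
            raise ValueError("fasting plasma glucose cannot be negative")
        return bool(fpg >= FPG_THRESHOLD_MMOL_L)
    return False


def classify_cohort(df: pd.DataFrame) -> pd.Series:
    """Vectorized classification over a cohort frame (see classify_diabetes)."""
    sr = df["self_report_diabetes"].fillna(0).astype(bool)
    meds = df["diabetes_meds"].fillna(0).astype(bool)
    fpg_high = df["fpg_mmol_l"] >= FPG_THRESHOLD_MMOL_L
    all_missing = (
        df["self_report_diabetes"].isna() & df["diabetes_meds"].isna() & df["fpg_mmol_l"].isna()
    )
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} participants lack all diabetes inputs; excluded",
            stacklevel=2,
        )
    out = (sr | meds | fpg_high.fillna(False)).astype(float)
    out[all_missing] = np.nan
    return out


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float


def odds_ratio_2x2(a: float, b: float, c: float, d: float,
                   continuity_correction: bool = False) -> OddsRatioResult:
    """2x2 odds ratio with Wald 95% CI.

    ``a, b`` are case / non-case counts in the exposed group and ``c, d`` in
    the reference group: OR = (a/b)/(c/d). The CI is
    ``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``. Zero cells raise
    unless the Haldane continuity correction (+0.5 everywhere) is enabled.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (cells == 0).any():
        if not continuity_correction:
            raise ZeroCellError("zero cell; enable continuity_correction")
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log((a / b) / (c / d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        pvalue=float(2 * stats.norm.sf(abs(z))),
    )


class SeparationError(RuntimeError):
    pass


def fit_logistic(X: pd.DataFrame, y, add_constant: bool = True) -> pd.DataFrame:
    """Maximum-likelihood logistic fit; returns an OR table with Wald CIs.

    Columns: ``coef, se, odds_ratio, ci_low, ci_high, pvalue``. Separation
    (diverging coefficients) and rank deficiency raise rather than return
    garbage estimates.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y).astype(float)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must contain both classes")
    design = sm.add_constant(X, has_constant="add") if add_constant else X
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=False, maxiter=200, tol=1e-8)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise SeparationError("separation detected in logistic fit") from err
        except np.linalg.LinAlgError as err:  # singular Hessian <=> quasi-separation
            raise SeparationError("singular Hessian in logistic fit") from err
    if np.abs(fit.params).max() > 50:
        raise SeparationError("diverging coefficients suggest separation")
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "odds_ratio": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "pvalue": fit.pvalues,
        }
    )


def stratified_split(y, test_fraction: float = 0.2, seed: int = 0):
    """Random train/test split preserving the outcome prevalence.

    Per-class test counts are the rounded class share of ``test_fraction``
    (within +/-1 of exact); returns disjoint, exhaustive index arrays.
    """
    y = np.asarray(y).astype(int)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 5:
            raise ValueError(f"class {cls} has fewer than 5 members")
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def auc_score(probabilities, outcomes) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) method, ties averaged."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AROC undefined for single-class outcomes")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def youden_threshold(probabilities, outcomes) -> float:
    """Probability cut maximizing Youden J = sensitivity + specificity - 1.

    Ties resolve to the lowest qualifying threshold (most sensitive rule).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes).astype(int)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(p):
        pred = p >= t
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_t, best_j = float(t), j
    return best_t


def classification_metrics(probabilities, outcomes, threshold: float = 0.5) -> dict:
    """Accuracy, sensitivity, specificity, Youden J and AROC at one threshold."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(outcomes).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("metrics undefined for single-class outcomes")
    pred = p >= threshold
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    sens = tp / (y == 1).sum()
    spec = tn / (y == 0).sum()
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": float(sens),
        "specificity": float(spec),
        "youden_j": float(sens + spec - 1),
        "aroc": auc_score(p, y),
    }


def cross_validate(X: pd.DataFrame, y, k: int = 10, seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold CV of a logistic model; per-metric mean and SD.

    Each fold is scored at the Youden-optimal threshold chosen on that
    fold's *training* data only. Folds are stratified, so no fold can end
    up single-class as long as ``k`` does not exceed the minority count.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    minority = min(np.bincount(y))
    if k > minority:
        raise ValueError(f"k = {k} exceeds minority class count {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    rows = []
    for train_idx, test_idx in skf.split(X, y):
        table = fit_logistic(X.iloc[train_idx], y[train_idx])
        design_tr = sm.add_constant(X.iloc[train_idx].astype(float), has_constant="add")
        design_te = sm.add_constant(X.iloc[test_idx].astype(float), has_constant="add")
        p_tr = expit(design_tr.to_numpy() @ table["coef"].to_numpy())
        p_te = expit(design_te.to_numpy() @ table["coef"].to_numpy())
        t = youden_threshold(p_tr, y[train_idx])
        rows.append(classification_metrics(p_te, y[test_idx], threshold=t))
    folds = pd.DataFrame(rows)
    return pd.DataFrame({"mean": folds.mean(), "sd": folds.std(ddof=1)})


def _design_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate design from the documented cohort column dictionary.

    Household income enters adjusted models as the ordered 6-level score
    (1 = <20k ... 6 = >90k); sex and urbanicity become indicators.
    """
    out = pd.DataFrame(index=cohort.index)
    out["age"] = cohort["age"].astype(float)
    out["female"] = (cohort["sex"].astype(str).str.lower() == "female").astype(float)
    out["bmi"] = cohort["bmi"].astype(float)
    out["income_cat"] = cohort["income_cat"].astype(float)
    out["urban"] = (cohort["urbanicity"].astype(str).str.lower() == "urban").astype(float)
    out["smoker"] = cohort["smoker"].astype(float)
    out["drinker"] = cohort["drinker"].astype(float)
    out["ahei"] = cohort["ahei"].astype(float)
    out["met_high"] = (
        cohort["met_class"].astype(str).str.contains(">=525|≥525", regex=True)
    ).astype(float)
    if "whr" in cohort.columns:
        out["whr"] = cohort["whr"].astype(float)
    return out


@dataclass
class ValidationReport:
    """Coefficient tables and classification performance of the model suite."""

    bivariate: dict = field(default_factory=dict)   # predictor -> OR table
    semi_adjusted: pd.DataFrame | None = None
    fully_adjusted: pd.DataFrame | None = None
    cv_metrics: dict = field(default_factory=dict)   # model label -> mean/sd frame
    test_metrics: dict = field(default_factory=dict)  # model label -> metric dict
    split_seed: int = 0
    n_train: int = 0
    n_test: int = 0
    errors: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Validation report",
            "=" * 60,
            f"train n = {self.n_train}, test n = {self.n_test} "
            f"(stratified 80/20, seed {self.split_seed})",
        ]
        for label, table in (("semi-adjusted", self.semi_adjusted),
                             ("fully adjusted", self.fully_adjusted)):
            if table is None:
                continue
            lines.append(f"\n{label} model (odds ratios, Wald 95% CI):")
            for name, row in table.iterrows():
                if name == "const":
                    continue
                lines.append(
                    f"  {name:<12} OR {row['odds_ratio']:.2f} "
                    f"({row['ci_low']:.2f}-{row['ci_high']:.2f}, p = {row['pvalue']:.3g})"
                )
        for label, metrics in self.test_metrics.items():
            lines.append(
                f"\n{label}: out-of-sample accuracy {metrics['accuracy']:.2f}, "
                f"sens {metrics['sensitivity']:.2f}, spec {metrics['specificity']:.2f}, "
                f"J {metrics['youden_j']:.2f}, AROC {metrics['aroc']:.2f}"
            )
            cv = self.cv_metrics.get(label)
            if cv is not None:
                lines.append(
                    f"{label}: tenfold CV accuracy {cv.loc['accuracy', 'mean']:.2f} "
                    f"(SD {cv.loc['accuracy', 'sd']:.2f}), "
                    f"AROC {cv.loc['aroc', 'mean']:.2f} (SD {cv.loc['aroc', 'sd']:.2f})"
                )
        if self.errors:
            lines.append("\nmodel errors: " + "; ".join(f"{k}: {v}" for k, v in self.errors.items()))
        return "\n".join(lines)


class DiabetesModelSuite:
    """Model object: logistic validation of index scores against diabetes status.

    Parameters
    ----------
    cohort : participant frame with the documented column dictionary.
    index_scores : per-participant index values (aligned with ``cohort``).
    adiposity : "bmi" (default) or "whr" — which adiposity measure enters
        the adjusted models.
    """

    def __init__(self, cohort: pd.DataFrame, index_scores, adiposity: str = "bmi"):
        if adiposity not in ("bmi", "whr"):
            raise ValueError("adiposity must be 'bmi' or 'whr'")
        cohort = cohort.reset_index(drop=True)
        scores = np.asarray(index_scores, dtype=float)
        if len(scores) != len(cohort):
            raise ValueError("index_scores length != cohort rows")
        design = _design_frame(cohort)
        if adiposity == "whr":
            if "whr" not in design.columns:
                raise KeyError("cohort has no 'whr' column")
            design = design.drop(columns=["bmi"])
        self.adiposity = adiposity
        self.design = design
        self.design.insert(0, "index", scores)
        if "diabetes" in cohort.columns:
            y = cohort["diabetes"].astype(float)
        else:
            y = classify_cohort(cohort)
        keep = y.notna() & self.design.notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(f"{dropped} rows dropped (missing outcome/covariates)", stacklevel=2)
        self.design = self.design.loc[keep].reset_index(drop=True)
        self.y = y.loc[keep].to_numpy().astype(int)

    def _adjusted_columns(self, model: str) -> list[str]:
        adip = "whr" if self.adiposity == "whr" else "bmi"
        cols = ["index", "age", "female", adip, "income_cat", "urban"]
        if model == "c":
            cols += list(MODEL_C_EXTRAS)
        return cols

    def fit(self, seed: int = 0, test_fraction: float = 0.2, k: int = 10) -> ValidationReport:
        """Fit suites (a), (b), (c) and evaluate the split + tenfold CV."""
        report = ValidationReport(split_seed=seed)
        for col in self.design.columns:
            try:
                report.bivariate[col] = fit_logistic(self.design[[col]], self.y)
            except (SeparationError, np.linalg.LinAlgError, ValueError) as err:
                report.errors[f"bivariate:{col}"] = str(err)

        train_idx, test_idx = stratified_split(self.y, test_fraction, seed)
        report.n_train, report.n_test = len(train_idx), len(test_idx)
        for label, model in (("semi_adjusted", "b"), ("fully_adjusted", "c")):
            cols = self._adjusted_columns(model)
            X = self.design[cols]
            try:
                table = fit_logistic(X.iloc[train_idx], self.y[train_idx])
                setattr(report, label, table)
                design_tr = sm.add_constant(X.iloc[train_idx].astype(float), has_constant="add")
                design_te = sm.add_constant(X.iloc[test_idx].astype(float), has_constant="add")
                beta = table["coef"].to_numpy()
                p_tr = expit(design_tr.to_numpy() @ beta)
                p_te = expit(design_te.to_numpy() @ beta)
                t = youden_threshold(p_tr, self.y[train_idx])
                report.test_metrics[label] = classification_metrics(
                    p_te, self.y[test_idx], threshold=t
                )
                report.cv_metrics[label] = cross_validate(
                    X.iloc[train_idx], self.y[train_idx], k=k, seed=seed
                )
            except (SeparationError, np.linalg.LinAlgError, ValueError) as err:
                report.errors[label] = str(err)
        return report


def model_suite(cohort: pd.DataFrame, index_scores, seed: int = 0,
                adiposity: str = "bmi") -> ValidationReport:
    """Functional wrapper around :class:`DiabetesModelSuite`."""
    return DiabetesModelSuite(cohort, index_scores, adiposity=adiposity).fit(seed=seed)
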