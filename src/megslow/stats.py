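"""Group comparisons, connection-level permutation tests and longitudinal models.

Four model families, all mirroring how longitudinal resting-state cohorts
are analyzed in this field:

* connection-level two-sided permutation tests (difference of group means
  per connection, label exchange for independent groups or within-subject
  condition swaps for paired designs) with Benjamini-Hochberg FDR control
  across the 4005 unique connections of a 90-region adjacency matrix;
* baseline group comparisons of whole-brain (cortical / subcortical
  averaged) measures with group dummies and demographic covariates,
  Bonferroni-thresholded at 0.05/6 per frequency-band family;
* longitudinal progression models: linear mixed models with a subject
  random intercept, visit treated as categorical dummies, and baseline
  covariates -- missingness from dropout is handled by likelihood, with
  no imputation and no listwise deletion across visits;
* clinical-association models relating spectral measures to cognition
  (CAMCOG) and motor impairment (UPDRS-III) over time, one spectral
  predictor per model (the spectral measures are too collinear to combine).

Mixed models are estimated by REML via statsmodels with a random intercept
only; p-values are large-sample Wald tests, recorded in the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .connectivity import ConnectivityMatrix

BONFERRONI_FAMILY = 6  # three group/time contrasts x two brain-region sets
BONFERRONI_ALPHA = 0.05 / BONFERRONI_FAMILY

PATIENT_GROUPS = ("de_novo", "treated")


# ---------------------------------------------------------------------------
# results containers


@dataclass
class ModelResult:
    """Coefficient table plus metadata for one fitted model.

    ``params`` is indexed by term with columns ``estimate``, ``ci_low``,
    ``ci_high`` and ``p``.
    """

    dependent: str
    formula: str
    params: pd.DataFrame
    n_obs: int
    n_subjects: int | None
    method: str
    converged: bool
    alpha: float = 0.05
    fit_warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = ~(
            (self.params["ci_low"] <= self.params["estimate"])
            & (self.params["estimate"] <= self.params["ci_high"])
        )
        if bad.any():
            raise ValueError(
                f"confidence interval excludes the estimate for terms "
                f"{self.params.index[bad].tolist()}"
            )

    def term(self, name: str) -> pd.Series:
        """Row for one term, matched by exact name or unique substring."""
        if name in self.params.index:
            return self.params.loc[name]
        hits = [t for t in self.params.index if name in t]
        if len(hits) != 1:
            raise KeyError(
                f"term {name!r} not found uniquely in {list(self.params.index)}"
            )
        return self.params.loc[hits[0]]

    def significant(self, alpha: float | None = None) -> pd.Series:
        return self.params["p"] <= (self.alpha if alpha is None else alpha)

    def summary(self) -> str:
        lines = [
            f"Model: {self.method}",
            f"Dependent: {self.dependent}",
            f"Formula: {self.formula}",
            f"Observations: {self.n_obs}"
            + (f"  Subjects: {self.n_subjects}" if self.n_subjects else ""),
            f"Converged: {self.converged}  (alpha = {self.alpha:g})",
            "-" * 86,
            f"{'term':<40}{'estimate':>10}  {'95% CI':>22}  {'p':>8}",
        ]
        for t, row in self.params.iterrows():
            ci = f"[{row.ci_low:.3g}, {row.ci_high:.3g}]"
            lines.append(
                f"{t:<40}{row.estimate:>10.4g}  {ci:>22}  {row.p:>8.3g}"
            )
        return "\n".join(lines)


@dataclass
class PermutationResult:
    """Connection-level permutation test outcome.

    All arrays run over the unique off-diagonal connections; ``region_i`` /
    ``region_j`` are 0-based indices (1-based in `to_frame` reports).
    """

    region_i: np.ndarray
    region_j: np.ndarray
    stat: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    n_permutations: int
    paired: bool
    seed: int | None
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        """Edge list with 1-based region numbers (regions 1-78 cortical)."""
        return pd.DataFrame(
            {
                "region_i": self.region_i + 1,
                "region_j": self.region_j + 1,
                "stat": self.stat,
                "p": self.p,
                "q": self.q,
                "significant": self.significant,
            }
        )


# ---------------------------------------------------------------------------
# permutation tests


def _stack_matrices(
    matrices: Sequence[ConnectivityMatrix] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle vectors (n_subjects, n_connections) plus (i, j) indices."""
    if isinstance(matrices, np.ndarray) and matrices.ndim == 2:
        raise ValueError("expected a sequence of matrices, got a single 2-D array")
    arrays = []
    n_regions = None
    for m in matrices:
        vals = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("each subject matrix must be square")
        if n_regions is None:
            n_regions = vals.shape[0]
        elif vals.shape[0] != n_regions:
            raise ValueError("subject matrices differ in region count")
        arrays.append(vals)
    if not arrays:
        raise ValueError("empty matrix set")
    i, j = np.triu_indices(n_regions, k=1)
    data = np.stack([a[i, j] for a in arrays])
    return data, i, j


def permutation_connection_test(
    matrices_a: Sequence[ConnectivityMatrix] | np.ndarray,
    matrices_b: Sequence[ConnectivityMatrix] | np.ndarray,
    n_permutations: int = 50_000,
    paired: bool = False,
    seed: int | None = None,
    subjects_a: Sequence[str] | None = None,
    subjects_b: Sequence[str] | None = None,
    alpha: float = 0.05,
    chunk: int = 2000,
) -> PermutationResult:
    """Two-sided permutation test of every connection between two conditions.

    The statistic is the difference of group means per connection.  The
    null is built by random relabelling: full label exchange between the
    two independent groups (unpaired), or random within-subject condition
    swaps (paired; both sets must then hold the same subjects in the same
    order).  P-values use the add-one correction p = (b + 1) / (N + 1) and
    are Benjamini-Hochberg adjusted across the unique connections.
    Deterministic given ``seed``.
    """
    data_a, i_idx, j_idx = _stack_matrices(matrices_a)
    data_b, _, _ = _stack_matrices(matrices_b)
    if data_a.shape[1] != data_b.shape[1]:
        raise ValueError("matrix sets differ in connection count")
    if paired:
        if data_a.shape[0] != data_b.shape[0]:
            raise ValueError(
                "paired test requires equally many matrices per condition"
            )
        if subjects_a is not None and subjects_b is not None:
            if list(subjects_a) != list(subjects_b):
                raise ValueError(
                    "paired test requires the same subjects in both "
                    "conditions, in the same order"
                )
    rng = np.random.default_rng(seed)
    m = data_a.shape[1]

    if paired:
        diffs = data_a - data_b  # (n, m)
        n = diffs.shape[0]
        obs = diffs.mean(axis=0)
        exceed = np.zeros(m, dtype=np.int64)
        done = 0
        while done < n_permutations:
            k = min(chunk, n_permutations - done)
            signs = rng.integers(0, 2, size=(k, n)) * 2.0 - 1.0
            null = (signs @ diffs) / n
            exceed += (np.abs(null) >= np.abs(obs)[None, :] - 1e-15).sum(axis=0)
            done += k
    else:
        n_a, n_b = data_a.shape[0], data_b.shape[0]
        pooled = np.vstack([data_a, data_b])
        n = n_a + n_b
        obs = data_a.mean(axis=0) - data_b.mean(axis=0)
        exceed = np.zeros(m, dtype=np.int64)
        done = 0
        while done < n_permutations:
            k = min(chunk, n_permutations - done)
            ranks = np.argsort(rng.random((k, n)), axis=1)
            w = np.where(ranks < n_a, 1.0 / n_a, -1.0 / n_b)
            null = w @ pooled
            exceed += (np.abs(null) >= np.abs(obs)[None, :] - 1e-15).sum(axis=0)
            done += k

    p = (exceed + 1.0) / (n_permutations + 1.0)
    flags, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return PermutationResult(
        i_idx, j_idx, obs, p, q, flags,
        n_permutations, paired, seed, alpha,
    )


# ---------------------------------------------------------------------------
# mixed-model helpers


def _extract_params(res, drop_random: bool = True) -> pd.DataFrame:
    ci = res.conf_int()
    tab = pd.DataFrame(
        {
            "estimate": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": res.pvalues,
        }
    )
    if drop_random:
        tab = tab[~tab.index.str.contains("Group Var")]
    return tab


def _fit_mixedlm(
    formula: str,
    data: pd.DataFrame,
    groups: pd.Series,
    dependent: str,
    alpha: float,
    method_label: str,
) -> ModelResult:
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=data, groups=groups)
        res = model.fit(reml=True)
    for w in wlist:
        if issubclass(w.category, (ConvergenceWarning, RuntimeWarning, UserWarning)):
            caught.append(str(w.message))
    params = _extract_params(res)
    return ModelResult(
        dependent=dependent,
        formula=formula,
        params=params,
        n_obs=int(res.nobs),
        n_subjects=int(groups.nunique()),
        method=method_label,
        converged=bool(getattr(res, "converged", True)),
        alpha=alpha,
        fit_warnings=tuple(caught),
    )


def _require_columns(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")


def _patients_only(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["group"].isin(PATIENT_GROUPS)].copy()


# ---------------------------------------------------------------------------
# model families


def fit_progression_model(table: pd.DataFrame, dependent: str) -> ModelResult:
    """Longitudinal change of a measure across visits in the patient groups.

    Linear mixed model with a subject random intercept; visit enters as
    categorical dummies (baseline reference), with baseline age, baseline
    disease duration, sex, dichotomized education (ISCED) and LEDD as
    covariates.  Subjects with missing visits contribute the visits they
    have (likelihood-based handling, no imputation).  Bonferroni threshold
    0.05/6 is attached for the significance flags.
    """
    _require_columns(
        table,
        ["subject", "group", "visit", "age", "disease_duration",
         "sex", "ISCED", "LEDD", dependent],
    )
    data = _patients_only(table).dropna(subset=[dependent])
    if data["visit"].nunique() < 2:
        raise ValueError("progression model needs at least two visits")
    if data[dependent].nunique() <= 1:
        raise ValueError(f"dependent {dependent!r} is constant")
    formula = (
        f"{dependent} ~ C(visit, Treatment('BL')) + age + disease_duration"
        " + C(sex) + ISCED + LEDD"
    )
    return _fit_mixedlm(
        formula, data, data["subject"], dependent,
        alpha=BONFERRONI_ALPHA,
        method_label="linear mixed model (REML, random intercept, Wald)",
    )


def fit_baseline_group_model(table: pd.DataFrame, dependent: str) -> ModelResult:
    """Baseline comparison of a measure across HC / de novo / treated groups.

    Group enters as dummies with healthy controls as reference, adjusted
    for age, sex and dichotomized education.  At baseline each subject
    contributes exactly one observation, so a subject random intercept is
    not identifiable; the model is fitted by OLS, whose fixed-effect
    estimates coincide with the degenerate mixed model.  Significance
    flags use the Bonferroni threshold 0.05/6.
    """
    _require_columns(
        table, ["subject", "group", "visit", "age", "sex", "ISCED", dependent]
    )
    data = table[table["visit"] == "BL"].dropna(subset=[dependent]).copy()
    for g in ("HC",) + PATIENT_GROUPS:
        if (data["group"] == g).sum() == 0:
            raise ValueError(f"baseline comparison: group {g!r} is empty")
    if data[dependent].nunique() <= 1:
        raise ValueError(f"dependent {dependent!r} is constant")
    formula = (
        f"{dependent} ~ C(group, Treatment('HC')) + age + C(sex) + ISCED"
    )
    res = smf.ols(formula, data=data).fit()
    ci = res.conf_int()
    params = pd.DataFrame(
        {
            "estimate": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": res.pvalues,
        }
    )
    return ModelResult(
        dependent=dependent,
        formula=formula,
        params=params,
        n_obs=int(res.nobs),
        n_subjects=int(data["subject"].nunique()),
        method="OLS (one observation per subject at baseline)",
        converged=True,
        alpha=BONFERRONI_ALPHA,
    )


def fit_interaction_model(table: pd.DataFrame, measure: str) -> ModelResult:
    """Does the de novo deviation from controls differ by brain location?

    Baseline-only mixed model in long form: each subject contributes a
    cortical and a subcortical row of ``measure``; fixed effects are group
    (HC reference), location (cortical reference), their interaction --
    the term of interest -- and the age/sex/ISCED covariates, with a
    subject random intercept tying the two rows together.
    """
    cort_col, sub_col = f"{measure}_cortical", f"{measure}_subcortical"
    _require_columns(
        table,
        ["subject", "group", "visit", "age", "sex", "ISCED", cort_col, sub_col],
    )
    data = table[
        (table["visit"] == "BL") & table["group"].isin(["HC", "de_novo"])
    ].copy()
    if data.empty:
        raise ValueError("no baseline HC / de novo rows available")
    if data[[cort_col, sub_col]].isna().any().any():
        bad = data.loc[
            data[[cort_col, sub_col]].isna().any(axis=1), "subject"
        ].tolist()
        raise ValueError(f"missing location rows for subjects {bad}")
    long = data.melt(
        id_vars=["subject", "group", "age", "sex", "ISCED"],
        value_vars=[cort_col, sub_col],
        var_name="location",
        value_name="value",
    )
    long["location"] = np.where(
        long["location"] == cort_col, "cortical", "subcortical"
    )
    formula = (
        "value ~ C(group, Treatment('HC')) * C(location, Treatment('cortical'))"
        " + age + C(sex) + ISCED"
    )
    return _fit_mixedlm(
        formula, long, long["subject"], measure,
        alpha=0.05,
        method_label="linear mixed model (REML, random intercept, Wald)",
    )


def fit_clinical_association(
    table: pd.DataFrame,
    dependent: str,
    predictor: str,
    location: str,
) -> ModelResult:
    """Longitudinal association between one spectral measure and a clinical score.

    ``dependent`` is ``"CAMCOG"`` or ``"UPDRS_III"``; the predictor column is
    ``f"{predictor}_{location}"`` (e.g. ``peak_frequency_cortical``).
    Covariates are baseline age, baseline disease duration, sex, LEDD and
    the recording system (derived from the visit: the last follow-up was
    recorded on a different MEG system); education (ISCED) is included for
    CAMCOG only, as in the analysis this mirrors.  Patients only; one
    spectral predictor per model (collinearity forbids combining them).
    """
    if dependent not in ("CAMCOG", "UPDRS_III"):
        raise ValueError("dependent must be 'CAMCOG' or 'UPDRS_III'")
    if location not in ("cortical", "subcortical"):
        raise ValueError("location must be 'cortical' or 'subcortical'")
    col = f"{predictor}_{location}"
    _require_columns(
        table,
        ["subject", "group", "visit", "age", "disease_duration",
         "sex", "LEDD", dependent, col],
    )
    data = _patients_only(table).dropna(subset=[dependent, col])
    data["recording_system"] = np.where(
        data["visit"] == "FU2", "Elekta", "CTF"
    )
    isced_term = " + ISCED" if dependent == "CAMCOG" else ""
    if dependent == "CAMCOG":
        _require_columns(data, ["ISCED"])
    formula = (
        f"{dependent} ~ {col} + age + disease_duration + C(sex) + LEDD"
        f" + C(recording_system){isced_term}"
    )
    return _fit_mixedlm(
        formula, data, data["subject"], dependent,
        alpha=0.05,
        method_label="linear mixed model (REML, random intercept, Wald)",
    )
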