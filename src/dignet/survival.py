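"""Prognostic-index survival evaluation of a gene biomarker.

The prognostic index of a sample is PI = beta_1 x_1 + ... + beta_p x_p,
with x_p the expression of the p-th biomarker gene and beta_p its Cox
proportional-hazards coefficient.  Samples are split at the median PI into
equal-size high- and low-risk groups; the split is scored with a two-sample
log-rank test and Harrell's concordance index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance

from .errors import FitError, ParameterError


@dataclass
class SurvivalCohort:
    """Follow-up time (months), event flag (1 observed, 0 censored) and
    biomarker-gene covariates per sample."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame  # samples x genes

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time < 0):
            raise ParameterError("follow-up times must be non-negative")
        n = len(self.sample_ids)
        if not (len(self.time) == len(self.event) == len(self.covariates) == n):
            raise ParameterError("cohort fields must share one length")
        if not np.isin(self.event, (0, 1)).all():
            raise ParameterError("event flags must be 0 or 1")
        self.covariates = self.covariates.set_axis(self.sample_ids, axis=0)

    @property
    def genes(self) -> list[str]:
        return list(self.covariates.columns)

    def to_tsv(self, path: str | Path) -> None:
        df = self.covariates.copy()
        df.insert(0, "time", self.time)
        df.insert(1, "event", self.event)
        df.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SurvivalCohort":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            list(df.index),
            df["time"].to_numpy(),
            df["event"].to_numpy(),
            df.drop(columns=["time", "event"]),
        )


def fit_cox(cohort: SurvivalCohort, penalizer: float = 0.0) -> pd.Series:
    """Cox proportional-hazards coefficients for the cohort covariates.

    Newton-type optimization to 1e-7 tolerance on the log partial
    likelihood.  A rank-deficient design triggers a collinearity warning and
    a small ridge penalty so the fit still returns.
    """
    if int(cohort.event.sum()) < 1:
        raise FitError("no observed events; Cox model cannot be fit")
    X = cohort.covariates.to_numpy(dtype=float)
    p = X.shape[1]
    if p >= int(cohort.event.sum()):
        warnings.warn(
            f"{p} covariates with only {int(cohort.event.sum())} events; "
            "estimates may be unstable",
            stacklevel=2,
        )
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < p:
        warnings.warn(
            "collinear covariates detected; adding a small ridge penalty",
            stacklevel=2,
        )
        penalizer = max(penalizer, 1e-4)
    df = cohort.covariates.copy()
    df["time"] = cohort.time
    df["event"] = cohort.event
    fitter = CoxPHFitter(penalizer=penalizer)
    try:
        fitter.fit(
            df,
            duration_col="time",
            event_col="event",
            fit_options={"precision": 1e-7},
        )
    except ConvergenceError as exc:  # pragma: no cover - defensive
        raise FitError(f"Cox fit did not converge: {exc}") from exc
    return fitter.params_.rename("beta")


def prognostic_index(betas: Mapping[str, float] | pd.Series, cohort: SurvivalCohort) -> np.ndarray:
    """PI_s = sum_p beta_p * x_{p,s} for every sample s."""
    betas = pd.Series(betas, dtype=float)
    missing = [g for g in betas.index if g not in cohort.covariates.columns]
    if missing:
        raise ParameterError(f"betas name genes absent from cohort: {missing[:5]}")
    X = cohort.covariates[list(betas.index)].to_numpy(dtype=float)
    return X @ betas.to_numpy()


def median_split(pi_per_sample: Sequence[float]) -> np.ndarray:
    """Split samples at the median PI into 'high' and 'low' risk groups.

    Strictly-above-median samples are high risk, strictly-below are low
    risk; exact-median ties are dealt one by one (low first) to whichever
    group is smaller, keeping group sizes within one of each other.
    """
    pi = np.asarray(pi_per_sample, dtype=float)
    if len(pi) < 2:
        raise ParameterError("median_split needs at least 2 samples")
    med = float(np.median(pi))
    groups = np.empty(len(pi), dtype=object)
    groups[pi > med] = "high"
    groups[pi < med] = "low"
    n_low = int((pi < med).sum())
    n_high = int((pi > med).sum())
    for i in np.flatnonzero(pi == med):
        if n_low <= n_high:
            groups[i] = "low"
            n_low += 1
        else:
            groups[i] = "high"
            n_high += 1
    return groups


def logrank_test(groups: Sequence[str], cohort: SurvivalCohort) -> float:
    """Two-sided p-value of the two-sample log-rank test (chi^2, 1 df)."""
    groups = np.asarray(groups, dtype=object)
    high = groups == "high"
    low = groups == "low"
    if not high.any() or not low.any():
        raise ParameterError("both risk groups must be non-empty")
    if int(cohort.event.sum()) < 1:
        raise ParameterError("log-rank test needs at least one event")
    res = _ll_logrank(
        cohort.time[high],
        cohort.time[low],
        event_observed_A=cohort.event[high],
        event_observed_B=cohort.event[low],
    )
    return float(res.p_value)


def concordance_index(pi_per_sample: Sequence[float], cohort: SurvivalCohort) -> float:
    """Harrell's C: fraction of comparable pairs where the higher-PI sample
    fails earlier (PI ties count 0.5)."""
    pi = np.asarray(pi_per_sample, dtype=float)
    try:
        # higher PI = higher risk = shorter survival, so negate for lifelines'
        # "higher score, longer survival" convention
        return float(_ll_concordance(cohort.time, -pi, cohort.event))
    except ZeroDivisionError as exc:
        raise FitError("no comparable pairs; concordance undefined") from exc


@dataclass
class PIResult:
    betas: pd.Series
    pi_per_sample: np.ndarray
    median_pi: float
    groups: np.ndarray
    logrank_p: float
    concordance: float

    def as_dict(self) -> dict:
        return {
            "betas": {g: float(b) for g, b in self.betas.items()},
            "median_pi": self.median_pi,
            "n_high": int((self.groups == "high").sum()),
            "n_low": int((self.groups == "low").sum()),
            "logrank_p": self.logrank_p,
            "concordance_index": self.concordance,
        }


def evaluate_biomarker(cohort: SurvivalCohort, penalizer: float = 0.0) -> PIResult:
    """The full chain: fit Cox, compute PI, median split, log-rank, C-index.

    Coefficients are fit on the same cohort that is split (no train/test
    separation), mirroring single-cohort biomarker evaluation.
    """
    betas = fit_cox(cohort, penalizer=penalizer)
    pi = prognostic_index(betas, cohort)
    groups = median_split(pi)
    p = logrank_test(groups, cohort)
    ci = concordance_index(pi, cohort)
    return PIResult(betas, pi, float(np.median(pi)), groups, p, ci)
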