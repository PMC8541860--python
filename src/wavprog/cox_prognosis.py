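"""Cox screening, prognostic risk score, Kaplan-Meier and time-dependent ROC.

Univariate Cox regression (Efron tie handling, Wald statistics) screens
candidate genes; bidirectional AIC-minimizing stepwise selection prunes
them; the multivariate fit defines the prognostic model whose risk score is
PRS = sum_i beta_i * Exp_i.  Samples are split at the median training PRS
into high/low risk groups, compared by Kaplan-Meier curves with a log-rank
test, and the score's discrimination is summarized by time-dependent
ROC/AUC at fixed horizons (36 and 60 months by default): cases are samples
with an event by the horizon, controls are samples followed beyond it, and
samples censored earlier are excluded.

Model fitting is delegated to lifelines; this module owns the screening
logic, the risk-score construction and the ROC estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "SurvivalData",
    "CoxFit",
    "PrognosticModel",
    "univariate_cox",
    "screen_univariate",
    "stepwise_select",
    "multivariate_cox",
    "prognostic_risk_score",
    "median_split",
    "km_logrank",
    "time_dependent_roc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored follow-up: months of follow-up and 0/1 event flags."""

    sample_ids: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        e = np.asarray(self.event)
        if len(t) != len(self.sample_ids) or len(e) != len(self.sample_ids):
            raise ValueError("time/event not aligned with sample ids")
        if not np.isfinite(t).all() or (t <= 0).any():
            raise ValueError("survival times must be positive and finite")
        if set(np.unique(e)) - {0, 1}:
            raise ValueError("event indicator must be 0/1")

    @classmethod
    def from_clinical(cls, clinical: pd.DataFrame) -> "SurvivalData":
        return cls(
            tuple(str(s) for s in clinical.index),
            clinical["time_months"].to_numpy(float),
            clinical["event"].to_numpy(int),
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event},
            index=pd.Index(self.sample_ids),
        )


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate Wald summary of a Cox partial-likelihood fit."""

    covariates: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n: int
    n_events: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        """(low, high) columns: exp(beta -/+ 1.96 se)."""
        return np.column_stack(
            [np.exp(self.beta - 1.959963984540054 * self.se),
             np.exp(self.beta + 1.959963984540054 * self.se)]
        )

    @property
    def aic(self) -> float:
        return 2 * len(self.covariates) - 2 * self.log_likelihood


@dataclass
class PrognosticModel:
    """The final gene signature: coefficients and the training PRS threshold."""

    gene_ids: tuple[str, ...]
    beta: np.ndarray
    prs_median: float

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.beta):
            raise ValueError("one coefficient per gene required")
        if not np.isfinite(self.beta).all():
            raise ValueError("coefficients must be finite")


def _fit_cox(x: pd.DataFrame, surv: SurvivalData) -> CoxFit:
    """Efron-ties Cox fit of the given covariate frame via lifelines."""
    df = x.copy()
    df["time"] = surv.time
    df["event"] = surv.event
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df,
            duration_col="time",
            event_col="event",
            # tight Newton tolerances: the default relative-likelihood stop
            # leaves ~1e-5 slack in beta, visible against exact oracles
            fit_options={"precision": 1e-12, "r_precision": 1e-18, "max_steps": 500},
        )
    s = cph.summary
    return CoxFit(
        covariates=tuple(str(c) for c in s.index),
        beta=s["coef"].to_numpy(),
        se=s["se(coef)"].to_numpy(),
        z=s["z"].to_numpy(),
        p=s["p"].to_numpy(),
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(surv.event.sum()),
    )


def univariate_cox(expr_row: pd.Series | np.ndarray, surv: SurvivalData) -> CoxFit:
    """Single-covariate Cox fit with Wald statistics.

    Requires at least two events and a non-constant covariate; convergence
    failures surface as errors rather than silent garbage.
    """
    x = np.asarray(expr_row, float)
    if len(x) != len(surv.sample_ids):
        raise ValueError("covariate not aligned with survival data")
    if surv.event.sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate cannot be fit")
    name = expr_row.name if isinstance(expr_row, pd.Series) else "x"
    try:
        return _fit_cox(pd.DataFrame({str(name): x}), surv)
    except Exception as exc:  # lifelines ConvergenceError and kin
        raise RuntimeError(f"Cox fit failed for {name!r}: {exc}") from exc


def screen_univariate(
    expr: pd.DataFrame,
    surv: SurvivalData,
    alpha: float = 0.05,
    fits: dict[str, CoxFit] | None = None,
) -> list[tuple[str, CoxFit]]:
    """Per-gene univariate screen; keep Wald p < alpha, ordered by p ascending.

    Genes whose fit fails are skipped with a warning.  Pre-computed fits may
    be passed to avoid refitting (e.g. when hazard ratios were already
    extracted for the step matrix).
    """
    hits: list[tuple[str, CoxFit]] = []
    for gene in expr.index:
        gene = str(gene)
        try:
            fit = (fits or {}).get(gene) or univariate_cox(expr.loc[gene], surv)
        except (ValueError, RuntimeError) as exc:
            logger.warning("skipping %s: %s", gene, exc)
            continue
        if fit.p[0] < alpha:
            hits.append((gene, fit))
    hits.sort(key=lambda gf: (gf[1].p[0], gf[0]))
    return hits


def stepwise_select(
    candidates: list[str], expr: pd.DataFrame, surv: SurvivalData
) -> list[str]:
    """Bidirectional stepwise AIC minimization over the multivariate Cox model.

    Starts from the full candidate set; at each round considers dropping any
    member or re-adding any dropped candidate, taking the move with the
    largest AIC improvement (ties by gene id).  Deterministic in the input
    order.
    """
    if not candidates:
        raise ValueError("stepwise selection needs at least one candidate")
    if len(candidates) == 1:
        return list(candidates)

    def aic_of(genes: tuple[str, ...]) -> float:
        if not genes:
            return np.inf
        return _fit_cox(expr.loc[list(genes)].T, surv).aic

    current = tuple(candidates)
    cache: dict[tuple[str, ...], float] = {}

    def cached_aic(genes: tuple[str, ...]) -> float:
        key = tuple(sorted(genes))
        if key not in cache:
            try:
                cache[key] = aic_of(key)
            except Exception:
                cache[key] = np.inf
        return cache[key]

    best_aic = cached_aic(current)
    while True:
        moves: list[tuple[float, str, tuple[str, ...]]] = []
        for g in current:
            if len(current) > 1:
                trial = tuple(x for x in current if x != g)
                moves.append((cached_aic(trial), g, trial))
        for g in candidates:
            if g not in current:
                trial = current + (g,)
                moves.append((cached_aic(trial), g, trial))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        if moves[0][0] < best_aic - 1e-9:
            best_aic, _, current = moves[0]
        else:
            break
    return [g for g in candidates if g in current]


def multivariate_cox(
    expr_subset: pd.DataFrame, surv: SurvivalData, alpha: float = 0.05
) -> tuple[CoxFit, PrognosticModel]:
    """Joint fit of the selected genes; the model keeps every fitted covariate.

    Per-covariate Wald significance is reported but non-significant genes
    are not dropped here — the signature is the stepwise-selected set.  The
    returned model carries the median training PRS as its split threshold.
    """
    genes = [str(g) for g in expr_subset.index]
    if not genes:
        raise ValueError("no genes to fit")
    if surv.event.sum() <= len(genes):
        raise ValueError(
            f"{int(surv.event.sum())} events cannot support {len(genes)} covariates"
        )
    x = expr_subset.T
    rank = np.linalg.matrix_rank(np.column_stack([x.to_numpy(), np.ones(len(x))]))
    if rank <= x.shape[1]:
        corr = np.corrcoef(expr_subset.to_numpy())
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            f"singular design; most collinear pair: {genes[i]}, {genes[j]}"
        )
    fit = _fit_cox(x, surv)
    prs = expr_subset.to_numpy().T @ fit.beta
    model = PrognosticModel(tuple(genes), fit.beta.copy(), float(np.median(prs)))
    return fit, model


def prognostic_risk_score(model: PrognosticModel, expr: pd.DataFrame) -> pd.Series:
    """PRS = sum_i beta_i * Exp_i per sample (columns of ``expr``).

    Expression must be on the scale the model was fitted on.
    """
    missing = [g for g in model.gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"expression lacks model gene(s) {missing}")
    sub = expr.loc[list(model.gene_ids)].to_numpy(float)
    return pd.Series(sub.T @ model.beta, index=expr.columns, name="prs")


def median_split(prs: pd.Series, threshold: float | None = None) -> pd.Series:
    """Label samples ``high``/``low`` by the median (ties at the median → low)."""
    if len(prs) < 2:
        raise ValueError("need at least 2 samples to split")
    if np.ptp(prs.to_numpy()) == 0:
        raise ValueError("degenerate split: all risk scores identical")
    thr = float(np.median(prs)) if threshold is None else threshold
    return pd.Series(np.where(prs > thr, "high", "low"), index=prs.index, name="risk")


def km_logrank(
    groups: pd.Series, surv: SurvivalData
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns ({group: curve with columns time, survival}, chi-square, p).
    """
    g = groups.reindex(list(surv.sample_ids))
    labels = [lbl for lbl in pd.unique(g) if pd.notna(lbl)]
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    masks = {lbl: (g == lbl).to_numpy() for lbl in labels}
    if any(m.sum() == 0 for m in masks.values()):
        raise ValueError("both groups must be non-empty")
    if surv.event.sum() == 0:
        raise ValueError("no events in either group")
    curves = {}
    for lbl, m in masks.items():
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[m], surv.event[m])
        sf = kmf.survival_function_
        curves[lbl] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    a, b = labels
    res = _lifelines_logrank(
        surv.time[masks[a]], surv.time[masks[b]],
        surv.event[masks[a]], surv.event[masks[b]],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def time_dependent_roc(
    prs: pd.Series, surv: SurvivalData, horizon: float
) -> tuple[pd.DataFrame, float]:
    """ROC of the risk score for event-by-horizon status.

    Cases: event with time <= horizon.  Controls: followed beyond the
    horizon without an earlier event.  Censored-before-horizon samples are
    excluded.  The curve sweeps every score threshold; AUC by trapezoid.
    """
    scores = prs.reindex(list(surv.sample_ids)).to_numpy(float)
    case = (surv.event == 1) & (surv.time <= horizon)
    control = surv.time > horizon
    keep = case | control
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(
            f"horizon {horizon}: need at least one case and one control "
            f"(got {int(case.sum())}/{int(control.sum())})"
        )
    s, y = scores[keep], case[keep].astype(int)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # merge tied scores into single threshold steps
    distinct = np.r_[True, np.diff(s) != 0]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    idx = np.r_[np.flatnonzero(np.r_[distinct[1:], True])]
    tpr = np.r_[0.0, tp[idx] / y.sum()]
    fpr = np.r_[0.0, fp[idx] / (len(y) - y.sum())]
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return curve, auc
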