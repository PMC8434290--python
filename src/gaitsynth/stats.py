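"""Accuracy metrics, summary tables, and the training-variant comparison.

Per test cycle and per degree of freedom three metrics are computed between
predicted and reference joint angles: Pearson r, RMSE in degrees, and nRMSE
in percent of the reference's per-cycle range (range normalisation is the
dominant convention in this literature; it makes small-range DoF such as
internal-external rotation show large nRMSE, as expected).

Training-set variants (measured / synthetic / measured+synthetic) are
compared with a one-way MANOVA (Wilks' lambda, F approximation) on the
six-dimensional per-cycle RMSE vectors, followed by per-DoF one-way ANOVA
with Tukey HSD post-hoc contrasts at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial import InputError

VARIANTS = ("measured", "synthetic", "measured+synthetic")
DOF_NAMES = ("flex_ext", "add_abd", "int_ext")


@dataclass
class EvalRecord:
    """Per-cycle, per-joint accuracy metrics (arrays of length 3, one entry
    per DoF)."""

    cycle_id: str
    subject_id: str
    variant: str
    joint: str
    r: np.ndarray
    rmse: np.ndarray
    nrmse: np.ndarray
    nrmse_valid: np.ndarray  # False where the reference was constant


def cycle_metrics(pred: np.ndarray, ref: np.ndarray,
                  mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(r, RMSE, nRMSE, nrmse_valid) per DoF over the unmasked samples.

    nRMSE = 100 * RMSE / (max(ref) - min(ref)) per DoF per cycle; a constant
    reference leaves nRMSE undefined (flagged invalid, excluded from
    aggregates).
    """
    pred, ref = np.asarray(pred, float), np.asarray(ref, float)
    if pred.shape != ref.shape:
        raise InputError("prediction/reference shape mismatch")
    valid = np.asarray(mask).astype(bool)
    if valid.sum() < 3:
        raise InputError("need at least 3 valid samples")
    p, q = pred[valid], ref[valid]
    rmse = np.sqrt(np.mean((p - q) ** 2, axis=0))
    rng = q.max(axis=0) - q.min(axis=0)
    ok = rng > 1e-12
    nrmse = np.full(p.shape[1], np.nan)
    nrmse[ok] = 100.0 * rmse[ok] / rng[ok]
    r = np.full(p.shape[1], np.nan)
    for j in range(p.shape[1]):
        sp, sq = p[:, j].std(), q[:, j].std()
        if sp > 1e-12 and sq > 1e-12:
            r[j] = np.corrcoef(p[:, j], q[:, j])[0, 1]
    if not np.all(ok):
        warnings.warn("constant reference DoF; nRMSE undefined for that DoF")
    return r, rmse, nrmse, ok


def aggregate_table(records: list[EvalRecord]) -> pd.DataFrame:
    """Mean +/- sample std (ddof=1) of each metric per variant, joint and
    DoF, plus a per-joint average row (mean of the three DoF means)."""
    if not records:
        raise InputError("no evaluation records")
    rows = []
    for rec in records:
        for d, dof in enumerate(DOF_NAMES):
            rows.append(dict(
                variant=rec.variant, joint=rec.joint, dof=dof,
                r=rec.r[d], rmse=rec.rmse[d],
                nrmse=rec.nrmse[d] if rec.nrmse_valid[d] else np.nan,
            ))
    df = pd.DataFrame(rows)
    out = []
    for (variant, joint), grp in df.groupby(["variant", "joint"]):
        dof_means = {}
        for dof, g in grp.groupby("dof"):
            row = dict(variant=variant, joint=joint, dof=dof)
            for m in ("r", "rmse", "nrmse"):
                row[f"{m}_mean"] = g[m].mean()
                row[f"{m}_std"] = g[m].std(ddof=1) if len(g) > 1 else 0.0
            dof_means[dof] = row
            out.append(row)
        avg = dict(variant=variant, joint=joint, dof="average")
        for m in ("r", "rmse", "nrmse"):
            avg[f"{m}_mean"] = float(np.mean([dof_means[d][f"{m}_mean"] for d in DOF_NAMES]))
            avg[f"{m}_std"] = float(np.mean([dof_means[d][f"{m}_std"] for d in DOF_NAMES]))
        out.append(avg)
    return pd.DataFrame(out)


def wilks_lambda(X: np.ndarray, labels: np.ndarray) -> float:
    """Wilks' lambda det(W) / det(W + B) for a one-way layout."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(W)
    for g in np.unique(labels):
        Xg = X[labels == g]
        mg = Xg.mean(axis=0)
        W += (Xg - mg).T @ (Xg - mg)
        B += len(Xg) * np.outer(mg - grand, mg - grand)
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular within-group covariance")
    _, logdet_t = np.linalg.slogdet(W + B)
    return float(np.exp(logdet_w - logdet_t))


def _manova_wilks(df: pd.DataFrame, dof_cols: list[str]):
    """One-way MANOVA via statsmodels; returns Wilks' lambda row values."""
    from statsmodels.multivariate.manova import MANOVA

    safe = {c: f"y{i}" for i, c in enumerate(dof_cols)}
    data = df.rename(columns=safe)
    formula = " + ".join(safe.values()) + " ~ C(variant)"
    res = MANOVA.from_formula(formula, data=data).mv_test()
    row = res.results["C(variant)"]["stat"].loc["Wilks' lambda"]
    return (float(row["Value"]), float(row["F Value"]),
            float(row["Num DF"]), float(row["Den DF"]), float(row["Pr > F"]))


@dataclass
class ComparisonResult:
    wilks_lambda: float | None
    f_stat: float | None
    df: tuple | None
    p_value: float | None
    manova_ok: bool
    anova: pd.DataFrame
    tukey: pd.DataFrame


def manova_tukey(records: list[EvalRecord], alpha: float = 0.05) -> ComparisonResult:
    """Compare training variants on the per-cycle RMSE vectors.

    Dependent variables are the six per-DoF RMSEs (hip and knee records of
    the same cycle are joined); the training variant is the factor.  If the
    within-group covariance is singular the MANOVA is skipped with a
    diagnostic and only the per-DoF ANOVA + Tukey HSD tables are returned.
    """
    from scipy import stats as sps
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = _rmse_matrix(records)
    dof_cols = [c for c in df.columns if c not in ("variant", "cycle_id", "subject_id")]
    variants = sorted(df["variant"].unique())
    if len(variants) < 2 or df.groupby("variant").size().min() < 3:
        raise InputError("need >= 2 variants with >= 3 records each")

    labels = df["variant"].to_numpy()
    try:
        # reject singular within-group covariance up front; statsmodels'
        # failure mode on such designs is less predictable
        lam0 = wilks_lambda(df[dof_cols].to_numpy(), labels)
        if 1.0 - lam0 < 1e-12:
            # no between-group variance at all: Lambda = 1, nothing to test
            lam, F, pval = lam0, 0.0, 1.0
            df1 = df2 = float("nan")
        else:
            lam, F, df1, df2, pval = _manova_wilks(df, dof_cols)
        manova_ok = True
    except np.linalg.LinAlgError:
        warnings.warn("singular within-group covariance; MANOVA skipped")
        lam = F = pval = None
        df1 = df2 = None
        manova_ok = False

    anova_rows, tukey_rows = [], []
    for col in dof_cols:
        groups = [df.loc[df["variant"] == v, col].to_numpy() for v in variants]
        f, p = sps.f_oneway(*groups)
        anova_rows.append(dict(dof=col, F=f, p=p))
        res = pairwise_tukeyhsd(df[col].to_numpy(), labels, alpha=alpha)
        tab = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        tab.insert(0, "dof", col)
        tukey_rows.append(tab)
    return ComparisonResult(
        wilks_lambda=lam, f_stat=F,
        df=(df1, df2) if manova_ok else None,
        p_value=pval, manova_ok=manova_ok,
        anova=pd.DataFrame(anova_rows),
        tukey=pd.concat(tukey_rows, ignore_index=True),
    )


def _rmse_matrix(records: list[EvalRecord]) -> pd.DataFrame:
    """Wide per-cycle RMSE table; hip and knee rows of one cycle merge into
    a six-column vector when both joints are present."""
    rows: dict[tuple, dict] = {}
    for rec in records:
        key = (rec.variant, rec.cycle_id)
        row = rows.setdefault(key, dict(variant=rec.variant, cycle_id=rec.cycle_id,
                                        subject_id=rec.subject_id))
        for d, dof in enumerate(DOF_NAMES):
            row[f"{rec.joint}_{dof}"] = rec.rmse[d]
    df = pd.DataFrame(list(rows.values())).dropna(axis=0)
    return df
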