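"""Generic linear speed model: feature selection, LASSO training, LOSO.

The model predicts step-level running speed from normalized stride
features.  Candidate features are screened by greedy forward stepwise
selection (ordinary least squares, scored by the mean MSE over
leave-one-subject-out folds of a development set, stopping when the
relative MSE gain drops below 1 %).  Final coefficients are trained with
the LASSO on inputs scaled to zero mean and unit variance; along the
regularization path the sparsest model is kept unless a denser one
improves the MSE by at least 2 %.  Class imbalance over the speed range is
handled by random under-sampling (RUS) over five 0.8-m/s bins spanning
1.4-5.4 m/s, repeated ten times with independent draws.

:class:`LinearSpeedModel` follows the Model -> ``fit()`` -> Results
pattern; :func:`loso_harness` runs the full leave-one-subject-out
train/test protocol over a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from strideforge.features import StrideFeatureTable

__all__ = [
    "RUS_BIN_EDGES",
    "RUSPlan",
    "random_undersample",
    "forward_stepwise_select",
    "LinearSpeedModel",
    "LinearSpeedResults",
    "loso_harness",
    "moving_average_output",
]

RUS_BIN_EDGES = np.array([1.4, 2.2, 3.0, 3.8, 4.6, 5.4])


@dataclass
class RUSPlan:
    """Random under-sampling plan: equal step counts per speed bin."""

    bin_edges: np.ndarray
    retained: list[np.ndarray]  # per non-empty bin, row indices kept
    seed: int
    n_excluded: int = 0  # labels outside the bin range

    @property
    def indices(self) -> np.ndarray:
        return np.sort(np.concatenate(self.retained)) if self.retained else np.array([], dtype=int)

    @property
    def per_bin_count(self) -> int:
        return len(self.retained[0]) if self.retained else 0


def random_undersample(
    labels: np.ndarray, seed: int, bin_edges: np.ndarray = RUS_BIN_EDGES
) -> RUSPlan:
    """Down-sample every speed bin to the least-populated bin's count.

    Labels outside [bin_edges[0], bin_edges[-1]) are excluded and counted.
    Sampling is without replacement; non-empty bins end up with exactly
    equal counts.
    """
    labels = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    which = np.digitize(labels, bin_edges) - 1
    inside = (which >= 0) & (which < len(bin_edges) - 1)
    groups = [np.flatnonzero(inside & (which == b)) for b in range(len(bin_edges) - 1)]
    groups = [g for g in groups if g.size > 0]
    if not groups:
        raise ValueError("no labels fall inside the RUS bin range")
    m = min(g.size for g in groups)
    retained = [rng.choice(g, size=m, replace=False) for g in groups]
    return RUSPlan(bin_edges=bin_edges, retained=retained, seed=seed,
                   n_excluded=int((~inside).sum()))


def _ols_mse(X_tr, y_tr, X_te, y_te) -> float:
    A = np.column_stack([np.ones(len(X_tr)), X_tr])
    coef, *_ = np.linalg.lstsq(A, y_tr, rcond=None)
    pred = np.column_stack([np.ones(len(X_te)), X_te]) @ coef
    return float(np.mean((pred - y_te) ** 2))


def forward_stepwise_select(
    X: pd.DataFrame,
    y: np.ndarray,
    subjects: np.ndarray,
    stop_frac: float = 0.01,
    max_features: int = 40,
) -> tuple[list[str], list[float]]:
    """Greedy forward selection scored by leave-one-subject-out OLS MSE.

    Starts from an empty set and adds, at each step, the candidate column
    (a base feature or one of its transforms) that minimizes the average
    held-out-subject MSE; stops when the relative gain is below
    ``stop_frac`` (1 %).  Candidates containing NaN or constant values in
    the development data are excluded up front.  Returns the ordered
    selection and the MSE trace.
    """
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("stepwise selection needs at least 2 development subjects")
    cols = [c for c in X.columns
            if np.isfinite(X[c].to_numpy()).all() and X[c].nunique() > 1]
    Xv = X[cols].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    folds = [(subjects != s, subjects == s) for s in uniq]

    selected: list[int] = []
    trace: list[float] = []
    best_mse = np.inf
    while len(selected) < min(max_features, len(cols)):
        best_cand, best_cand_mse = None, np.inf
        for j in range(len(cols)):
            if j in selected:
                continue
            use = selected + [j]
            mses = []
            for tr, te in folds:
                try:
                    mses.append(_ols_mse(Xv[tr][:, use], y[tr], Xv[te][:, use], y[te]))
                except np.linalg.LinAlgError:
                    mses = None
                    break
            if mses is None:
                continue
            m = float(np.mean(mses))
            if m < best_cand_mse:
                best_cand, best_cand_mse = j, m
        if best_cand is None:
            break
        gain = (best_mse - best_cand_mse) / best_mse if np.isfinite(best_mse) else 1.0
        if np.isfinite(best_mse) and gain < stop_frac:
            break
        selected.append(best_cand)
        trace.append(best_cand_mse)
        best_mse = best_cand_mse
        if best_mse <= 1e-15:
            break
    return [cols[j] for j in selected], trace


@dataclass
class LinearSpeedResults:
    """Fitted generic speed model: standardized-scale coefficients."""

    features: list[str]
    coef: np.ndarray  # on the standardized input scale
    intercept: float
    x_mean: np.ndarray
    x_std: np.ndarray
    alpha: float
    train_mse: float
    n_train: int
    meta: dict = field(default_factory=dict)

    @property
    def selected_features(self) -> list[str]:
        """Features with nonzero LASSO weight (beyond solver round-off)."""
        return [f for f, c in zip(self.features, self.coef) if abs(c) > 1e-12]

    def predict(self, rows: pd.DataFrame, avg_steps: int = 1) -> np.ndarray:
        """Per-step speed; optional centered moving average over the output."""
        X = rows[self.features].to_numpy(dtype=float)
        Z = (X - self.x_mean) / self.x_std
        v = self.intercept + Z @ self.coef
        return moving_average_output(v, avg_steps)

    def summary(self) -> str:
        lines = [
            "Linear speed model (LASSO)",
            f"  features offered : {len(self.features)}",
            f"  features kept    : {len(self.selected_features)}",
            f"  alpha            : {self.alpha:.5g}",
            f"  train MSE        : {self.train_mse:.5g} (m/s)^2",
            f"  n train steps    : {self.n_train}",
            "  coefficients (standardized inputs):",
            f"    {'(intercept)':<28s} {self.intercept:+.4f}",
        ]
        for f, c in zip(self.features, self.coef):
            if c != 0.0:
                lines.append(f"    {f:<28s} {c:+.4f}")
        return "\n".join(lines)


def moving_average_output(v: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average of the predicted speed sequence."""
    v = np.asarray(v, dtype=float)
    if k <= 1:
        return v
    n = v.size
    half_lo = (k - 1) // 2
    half_hi = k // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


class LinearSpeedModel:
    """Generic step-speed model over a stride feature table.

    Parameters
    ----------
    table : StrideFeatureTable or DataFrame
        Training rows with the candidate features and a ``label`` column.
    features : list of str
        Candidate feature columns offered to the LASSO (e.g. the stepwise
        selection ``P_auto``, the comprehensive ``P_manual``, or a preset).
    """

    def __init__(self, table: StrideFeatureTable | pd.DataFrame, features: list[str]):
        df = table.df if isinstance(table, StrideFeatureTable) else table
        keep = np.isfinite(df[features].to_numpy(dtype=float)).all(axis=1)
        keep &= np.isfinite(df["label"].to_numpy(dtype=float))
        self.df = df[keep].reset_index(drop=True)
        self.features = list(features)

    def fit(
        self,
        rus_plan: RUSPlan | None = None,
        size_rule: float = 0.02,
        n_alphas: int = 60,
        eps: float = 1e-4,
        tol: float = 1e-6,
        meta: dict | None = None,
    ) -> LinearSpeedResults:
        """LASSO fit with the smallest-model-within-2 % size rule.

        Inputs are scaled to zero mean and unit variance.  Along the
        regularization path, models are ranked by support size; the
        sparsest model is kept unless the next denser one improves the
        training MSE by at least ``size_rule`` (2 %).
        """
        df = self.df if rus_plan is None else self.df.iloc[rus_plan.indices]
        X = df[self.features].to_numpy(dtype=float)
        y = df["label"].to_numpy(dtype=float)
        if len(y) == 0:
            raise ValueError("no training rows")
        x_mean = X.mean(axis=0)
        x_std = X.std(axis=0)
        x_std[x_std == 0] = 1.0
        Z = (X - x_mean) / x_std
        y_mean = float(y.mean())
        alphas, coefs, _ = lasso_path(
            Z, y - y_mean, alphas=n_alphas, eps=eps, tol=tol, max_iter=10_000
        )
        if coefs.size == 0:
            raise ValueError("empty LASSO path")
        mses = np.mean((Z @ coefs - (y - y_mean)[:, None]) ** 2, axis=0)
        sizes = (coefs != 0).sum(axis=0)

        best_at_size: dict[int, int] = {}
        for i, s in enumerate(sizes):
            if s not in best_at_size or mses[i] < mses[best_at_size[s]]:
                best_at_size[int(s)] = i
        order = sorted(best_at_size)
        pick = order[0]
        for s, s_next in zip(order[:-1], order[1:]):
            cur, nxt = mses[best_at_size[s]], mses[best_at_size[s_next]]
            if cur > 0 and (cur - nxt) / cur >= size_rule:
                pick = s_next
            else:
                break
        i_pick = best_at_size[pick]
        return LinearSpeedResults(
            features=self.features,
            coef=coefs[:, i_pick].copy(),
            intercept=y_mean,
            x_mean=x_mean,
            x_std=x_std,
            alpha=float(alphas[i_pick]),
            train_mse=float(mses[i_pick]),
            n_train=len(y),
            meta=meta or {},
        )


def loso_harness(
    table: StrideFeatureTable,
    features: list[str],
    n_repetitions: int = 10,
    master_seed: int = 0,
    dev_subjects: list[str] | None = None,
    avg_steps: int = 1,
) -> pd.DataFrame:
    """Leave-one-subject-out evaluation with RUS repetitions.

    For each pool subject and each of ``n_repetitions`` RUS draws, the
    model is trained on every other pool subject's steps and applied to
    the held-out subject.  ``dev_subjects`` (used for feature selection)
    must be disjoint from the pool; overlap is a hard error -- the
    leakage guard.

    Returns one row per (subject, repetition, step) with ``label`` and
    ``pred`` columns.
    """
    df = table.df
    pool = [s for s in pd.unique(df["subject"])]
    if dev_subjects:
        overlap = set(dev_subjects) & set(pool)
        if overlap:
            raise ValueError(f"subjects in both development and pool: {sorted(overlap)}")
    rng = np.random.default_rng(master_seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_repetitions)
    out = []
    for subject in pool:
        train_df = df[df["subject"] != subject]
        test_df = df[df["subject"] == subject].sort_values("ic")
        model = LinearSpeedModel(train_df, features)
        for rep, seed in enumerate(rep_seeds):
            plan = random_undersample(
                model.df["label"].to_numpy(), seed=int(seed) ^ hash(subject) % 2**16
            )
            res = model.fit(rus_plan=plan, meta={"subject": subject, "repetition": rep})
            keep = np.isfinite(test_df[features].to_numpy(dtype=float)).all(axis=1)
            te = test_df[keep]
            pred = res.predict(te, avg_steps=avg_steps)
            out.append(pd.DataFrame({
                "subject": subject, "repetition": rep, "ic": te["ic"].to_numpy(),
                "label": te["label"].to_numpy(), "pred": pred,
            }))
    return pd.concat(out, ignore_index=True)
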