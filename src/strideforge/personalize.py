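"""Online personalization by recursive least squares (RLS).

The personalized estimator models *stride length* as a linear function of
the stride features: with feature vector ``p_n = [1, p1, ..., pQ]`` and
reference stride length ``sl_n = v_ref[n] * STR_n`` (speed times stride
time), the coefficients ``beta`` and dispersion matrix ``D`` are updated
per stride:

    K_n    = p_n^T D_{n-1} p_n
    D_n    = D_{n-1} (I - p_n (I + K_n)^{-1} p_n^T D_{n-1})
    beta_n = beta_{n-1} + D_n p_n (sl_n - p_n^T beta_{n-1})

which is algebraically the Sherman-Morrison update of the ridge-initialized
normal equations, so the recursion tracks the batch least-squares solution
exactly.  Running speed is recovered as ``(p^T beta) / STR``.

Ten strides initialize the recursion; per-subject cross-validation splits
the strides into consecutive 10-stride bouts assigned randomly half to
training and half to testing, emulating sporadic GNSS availability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RLSState",
    "rls_init",
    "rls_update",
    "bout_split",
    "personalize_stream",
    "PersonalizedSpeedModel",
    "PersonalizationResults",
]

RIDGE = 1e-6
INIT_STRIDES = 10
BOUT_SIZE = 10


@dataclass
class RLSState:
    """Recursive-least-squares state: coefficients and dispersion matrix."""

    beta: np.ndarray  # length Q+1, intercept first
    D: np.ndarray  # (Q+1, Q+1) dispersion (inverse normal matrix)
    n: int  # samples consumed (including initialization)
    feature_names: list[str] = field(default_factory=list)
    forgetting: float = 1.0  # lambda < 1 enables exponential forgetting

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if not np.all(np.isfinite(self.beta)) or not np.all(np.isfinite(self.D)):
            raise ValueError("RLS state must be finite")

    def check_spd(self) -> bool:
        """Dispersion matrix symmetric positive-definite (probabilistic check)."""
        if not np.allclose(self.D, self.D.T, atol=1e-9 * max(np.abs(self.D).max(), 1)):
            return False
        try:
            np.linalg.cholesky(self.D + 0.0)
        except np.linalg.LinAlgError:
            return False
        return True

    def predict_sl(self, p: np.ndarray) -> float:
        return float(np.atleast_1d(p) @ self.beta)


def _design(features: np.ndarray) -> np.ndarray:
    """Prepend the intercept column of ones."""
    F = np.atleast_2d(np.asarray(features, dtype=float))
    return np.column_stack([np.ones(len(F)), F])


def rls_init(
    features: np.ndarray,
    stride_lengths: np.ndarray,
    feature_names: list[str] | None = None,
    ridge: float = RIDGE,
) -> RLSState:
    """Initialize the recursion from the first 10 training strides.

    ``beta_0`` is the ridge-stabilized least-squares solution on those
    strides and ``D_0 = (P^T P + ridge I)^{-1}``.
    """
    P = _design(features)
    sl = np.asarray(stride_lengths, dtype=float)
    if len(P) != INIT_STRIDES:
        raise ValueError(f"initialization requires exactly {INIT_STRIDES} strides")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(sl))):
        raise ValueError("initialization strides contain non-finite values")
    A = P.T @ P + ridge * np.eye(P.shape[1])
    # the ridge bounds the smallest eigenvalue, so only a pathological
    # feature scale leaves the system unsolvable
    if np.linalg.cond(A) > 1e15:
        raise ValueError("initialization strides are rank-deficient even with ridge")
    D = np.linalg.inv(A)
    beta = D @ (P.T @ sl)
    return RLSState(beta=beta, D=0.5 * (D + D.T), n=INIT_STRIDES,
                    feature_names=list(feature_names or []))


def rls_update(state: RLSState, p_n: np.ndarray, sl_n: float) -> RLSState:
    """One RLS step; non-finite inputs leave the state unchanged.

    Implemented in the general matrix form so ``p_n`` may also be a batch
    of rows (K_n then a matrix and (I + K_n)^{-1} a true inverse); for a
    single stride K_n is scalar and the inverse reduces to 1/(1 + K_n).
    """
    p_n = np.asarray(p_n, dtype=float)
    if p_n.shape[-1] == state.beta.size:  # already carries the leading 1
        P = np.atleast_2d(p_n)
    else:
        P = _design(p_n)
    sl = np.atleast_1d(np.asarray(sl_n, dtype=float))
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(sl))):
        return state
    lam = state.forgetting
    D_prev = state.D / lam
    K = P @ D_prev @ P.T  # scalar for a single stride
    M = np.linalg.inv(np.eye(len(sl)) + K)
    D_new = D_prev @ (np.eye(len(state.beta)) - P.T @ M @ P @ D_prev)
    D_new = 0.5 * (D_new + D_new.T)
    innov = sl - P @ state.beta
    beta_new = state.beta + D_new @ P.T @ innov
    return RLSState(beta=beta_new, D=D_new, n=state.n + len(sl),
                    feature_names=state.feature_names, forgetting=lam)


def bout_split(
    n_strides: int, seed: int, bout_size: int = BOUT_SIZE
) -> tuple[np.ndarray, np.ndarray]:
    """Split stride indices into consecutive bouts, half train / half test.

    Trailing strides that do not complete a bout are dropped.  With an odd
    bout count the training half gets the extra bout.  Returns
    ``(train_idx, test_idx)``.
    """
    n_bouts = n_strides // bout_size
    if n_bouts < 2:
        raise ValueError("need at least 2 complete bouts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_bouts)
    n_train = (n_bouts + 1) // 2
    train_b = np.sort(order[:n_train])
    test_b = np.sort(order[n_train:])
    idx = lambda bouts: np.concatenate(
        [np.arange(b * bout_size, (b + 1) * bout_size) for b in bouts]
    )
    return idx(train_b), idx(test_b)


def personalize_stream(
    train_features: np.ndarray,
    train_sl: np.ndarray,
    test_features: np.ndarray,
    test_str: np.ndarray,
    test_speed: np.ndarray,
    feature_names: list[str] | None = None,
    score_every: int = 1,
) -> tuple[RLSState, pd.DataFrame]:
    """Feed training strides one-by-one; score the test set as we go.

    The first 10 strides initialize the recursion; each subsequent stride
    updates it, after which the full test set is scored with
    ``v = (p^T beta) / STR``.  Returns the final state and the
    RMSE-versus-strides-consumed curve.
    """
    train_features = np.atleast_2d(np.asarray(train_features, dtype=float))
    if len(train_features) < INIT_STRIDES + 1:
        raise ValueError("need more than 10 training strides")
    ok = np.asarray(test_str) > 0
    Pte = _design(np.atleast_2d(test_features)[ok])
    str_te = np.asarray(test_str, dtype=float)[ok]
    v_te = np.asarray(test_speed, dtype=float)[ok]

    state = rls_init(train_features[:INIT_STRIDES], train_sl[:INIT_STRIDES],
                     feature_names)
    curve = []
    for i in range(INIT_STRIDES, len(train_features)):
        if train_sl[i] <= 0:
            continue
        state = rls_update(state, train_features[i], float(train_sl[i]))
        if (i - INIT_STRIDES) % score_every == 0:
            v_hat = (Pte @ state.beta) / str_te
            rmse = float(np.sqrt(np.mean((v_hat - v_te) ** 2)))
            curve.append((state.n, rmse))
    return state, pd.DataFrame(curve, columns=["strides", "rmse"])


@dataclass
class PersonalizationResults:
    """Per-subject outcome of RLS personalization."""

    state: RLSState
    curve: pd.DataFrame  # rmse vs strides consumed
    test_pred: np.ndarray
    test_ref: np.ndarray

    @property
    def bias(self) -> float:
        return float(np.mean(self.test_pred - self.test_ref))

    @property
    def precision(self) -> float:
        return float(np.std(self.test_pred - self.test_ref, ddof=1))

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean((self.test_pred - self.test_ref) ** 2)))

    def summary(self) -> str:
        return (
            "Personalized speed model (RLS)\n"
            f"  strides consumed : {self.state.n}\n"
            f"  test bias        : {self.bias:+.4f} m/s\n"
            f"  test precision   : {self.precision:.4f} m/s\n"
            f"  test RMSE        : {self.rmse:.4f} m/s"
        )


class PersonalizedSpeedModel:
    """Per-subject stride-length model personalized online against GNSS.

    Built from one subject's feature rows (typically the comprehensive
    feature set), their stride times and reference speeds.  ``fit()``
    performs the bout split, streams the training strides through the RLS
    and scores the held-out bouts.
    """

    def __init__(
        self,
        features: pd.DataFrame | np.ndarray,
        stride_time: np.ndarray,
        ref_speed: np.ndarray,
        feature_names: list[str] | None = None,
    ):
        if isinstance(features, pd.DataFrame):
            feature_names = feature_names or list(features.columns)
            features = features.to_numpy(dtype=float)
        self.X = np.atleast_2d(np.asarray(features, dtype=float))
        self.stride_time = np.asarray(stride_time, dtype=float)
        self.ref_speed = np.asarray(ref_speed, dtype=float)
        self.feature_names = list(feature_names or [])
        good = (
            np.isfinite(self.X).all(axis=1)
            & np.isfinite(self.stride_time) & (self.stride_time > 0)
            & np.isfinite(self.ref_speed)
        )
        self.X, self.stride_time, self.ref_speed = (
            self.X[good], self.stride_time[good], self.ref_speed[good]
        )
        # per-subject constant features (e.g. anthropometrics) are collinear
        # with the intercept within one subject: absorb them into it
        if len(self.X):
            varying = np.ptp(self.X, axis=0) > 0
            self.X = self.X[:, varying]
            if self.feature_names:
                self.feature_names = [
                    f for f, v in zip(self.feature_names, varying) if v
                ]

    def fit(self, seed: int = 0, bout_size: int = BOUT_SIZE,
            score_every: int = 1,
            max_train_strides: int | None = None) -> PersonalizationResults:
        """Bout split, stream the training strides, score the test bouts.

        ``max_train_strides`` caps the personalization stream (emulating a
        GNSS receiver switched off once the model has converged).
        """
        train_idx, test_idx = bout_split(len(self.X), seed, bout_size)
        if max_train_strides is not None:
            train_idx = train_idx[:max_train_strides]
        sl = self.ref_speed * self.stride_time  # stride length labels
        state, curve = personalize_stream(
            self.X[train_idx], sl[train_idx],
            self.X[test_idx], self.stride_time[test_idx],
            self.ref_speed[test_idx],
            feature_names=self.feature_names, score_every=score_every,
        )
        Pte = _design(self.X[test_idx])
        pred = (Pte @ state.beta) / self.stride_time[test_idx]
        return PersonalizationResults(
            state=state, curve=curve, test_pred=pred,
            test_ref=self.ref_speed[test_idx],
        )
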