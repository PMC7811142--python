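"""PLS1 regression with VIP scores, LOOCV and permutation assessment.

The regression of a single response (e.g. carbon export efficiency) on the
CLR marker profiles is fitted by NIPALS on autoscaled predictors:

    for a = 1..A:
        w_a = X_a' y / ||X_a' y||          (unit-norm weight)
        t_a = X_a w_a                      (score)
        p_a = X_a' t_a / (t_a' t_a)        (X loading)
        q_a = y' t_a / (t_a' t_a)          (y loading)
        X_{a+1} = X_a - t_a p_a'           (deflation)

Regression coefficients on the standardized scale are
beta = W (P'W)^{-1} q, and predictions are X_std beta + y_mean.

Model quality is assessed by leave-one-out cross-validation (autoscaling
re-estimated inside every fold; marker pre-selection deliberately is not —
see the methods note for the optimism this shares with the original
workflow) and by a permutation test whose statistic is the Pearson
correlation between a permuted response and its own LOOCV predictions.

Variable importance in the projection (VIP) for marker j:

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ),
    SS_a = q_a^2 t_a' t_a

so that the mean squared VIP is exactly 1. Markers with VIP above a
threshold (2 by convention here) are the model's key predictors ("VIPs"),
split by the sign of their regression coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError, UndefinedStatisticError

_EPS = 1e-15


@dataclass
class PLSModel:
    """Fitted PLS1 model (see module docstring for the algorithm)."""

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray       # p x A, unit-norm columns
    x_loadings: np.ndarray    # p x A
    y_loadings: np.ndarray    # A
    scores: np.ndarray        # n x A, mutually orthogonal columns
    coef: np.ndarray          # p, on the standardized-X scale
    marker_ids: pd.Index | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) / self.x_scale @ self.coef + self.y_mean

    @property
    def component_y_ss(self) -> np.ndarray:
        """Response sum of squares captured per component, q_a^2 t_a't_a."""
        tt = np.einsum("na,na->a", self.scores, self.scores)
        return self.y_loadings**2 * tt


@dataclass
class Assessment:
    """Observed-vs-predicted fit statistics; R2 = 1 - SSE/SST."""

    r: float
    r2: float
    sse: float
    sst: float


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    null: np.ndarray
    n_perm: int
    statistic: str = "r"


def _validate_xy(X, y, A):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DataError("X must be samples x markers aligned with y")
    if np.isnan(X).any() or np.isnan(y).any():
        raise DataError("missing values are not allowed in PLS inputs")
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ParameterError(
            f"n_components={A} must be in [1, min(n-1, p)] = "
            f"[1, {min(n - 1, p)}]"
        )
    return X, y


def _autoscale(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    return mu, sd


def fit_pls(X, y, n_components: int = 2, marker_ids=None) -> PLSModel:
    """Fit a PLS1 model via NIPALS on autoscaled X and centered y."""
    X, y = _validate_xy(X, y, n_components)
    mu, sd = _autoscale(X)
    if (sd <= 0).any():
        j = int(np.flatnonzero(sd <= 0)[0])
        name = marker_ids[j] if marker_ids is not None else f"column {j}"
        raise DataError(f"zero-variance predictor: {name}")
    Xs = (X - mu) / sd
    y_mean = float(y.mean())
    yc = y - y_mean

    n, p = Xs.shape
    A = n_components
    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    T = np.empty((n, A))
    Xa = Xs.copy()
    achieved = A
    for a in range(A):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            # residual X carries no covariance with y: the fit is already
            # exact (or y is orthogonal to X); later components would be
            # numerically meaningless, so truncate
            achieved = a
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt < _EPS:
            achieved = a
            break
        W[:, a] = w
        T[:, a] = t
        P[:, a] = Xa.T @ t / tt
        q[a] = float(yc @ t) / tt
        Xa = Xa - np.outer(t, P[:, a])
    if achieved < A:
        logging.getLogger(__name__).warning(
            "PLS fit truncated to %d of %d components (no residual "
            "covariance with y)", achieved, A,
        )
        if achieved == 0:
            raise DataError("X carries no covariance with y; nothing to fit")
        W, P, T, q = W[:, :achieved], P[:, :achieved], T[:, :achieved], q[:achieved]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_components=achieved,
        x_mean=mu,
        x_scale=sd,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        marker_ids=None if marker_ids is None else pd.Index(marker_ids),
    )


def _loocv_batch(X: np.ndarray, Y: np.ndarray, A: int) -> np.ndarray:
    """LOOCV predictions for B response columns sharing one X.

    X is n x p; Y is n x B. Returns an n x B prediction matrix. Autoscaling
    and the full NIPALS fit are re-estimated inside every fold; the fold's
    standardized X is shared across the B columns, which is what makes the
    permutation test affordable.
    """
    n, p = X.shape
    B = Y.shape[1]
    preds = np.empty((n, B))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xtr = X[tr]
        mu, sd = _autoscale(Xtr)
        sd = np.where(sd > 0, sd, 1.0)  # constant-in-fold columns carry no signal
        Xs = (Xtr - mu) / sd
        Ytr = Y[tr]
        ym = Ytr.mean(axis=0)
        Yc = Ytr - ym
        m = n - 1
        Xa = np.broadcast_to(Xs, (B, m, p)).copy()
        W = np.empty((B, p, A))
        P = np.empty((B, p, A))
        q = np.empty((B, A))
        for a in range(A):
            w = np.einsum("bmp,mb->bp", Xa, Yc)
            nw = np.linalg.norm(w, axis=1, keepdims=True)
            w /= np.maximum(nw, _EPS)
            t = np.einsum("bmp,bp->bm", Xa, w)
            tt = np.maximum(np.einsum("bm,bm->b", t, t), _EPS)
            pl = np.einsum("bmp,bm->bp", Xa, t) / tt[:, None]
            q[:, a] = np.einsum("bm,mb->b", t, Yc) / tt
            W[:, :, a] = w
            P[:, :, a] = pl
            Xa -= t[:, :, None] * pl[:, None, :]
        R = np.einsum("bpa,bpc->bac", P, W)
        z = np.linalg.solve(R, q[:, :, None])[:, :, 0]
        coef = np.einsum("bpa,ba->bp", W, z)
        xs = (X[i] - mu) / sd
        preds[i] = coef @ xs + ym
    return preds


def loocv(X, y, n_components: int = 2) -> np.ndarray:
    """Leave-one-out cross-validated predictions for one response."""
    X, y = _validate_xy(X, y, n_components)
    return _loocv_batch(X, y[:, None], n_components)[:, 0]


def assess(y, y_hat) -> Assessment:
    """Pearson r and R2 = 1 - SSE/SST between observed and predicted."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise DataError("y and y_hat must have equal length")
    if np.ptp(y) == 0:
        raise UndefinedStatisticError("R2 undefined for constant response")
    sse = float(np.sum((y - y_hat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if np.ptp(y_hat) == 0:
        r = 0.0  # degenerate predictions carry no linear association
    else:
        r = float(stats.pearsonr(y, y_hat).statistic)
    return Assessment(r=r, r2=1.0 - sse / sst, sse=sse, sst=sst)


def _null_statistic(Yperm, preds, statistic):
    Yc = Yperm - Yperm.mean(axis=0)
    Pc = preds - preds.mean(axis=0)
    if statistic == "r":
        denom = np.sqrt((Yc**2).sum(axis=0) * (Pc**2).sum(axis=0))
        return np.where(
            denom > 0, (Yc * Pc).sum(axis=0) / np.maximum(denom, _EPS), 0.0
        )
    if statistic == "r2":
        sse = ((Yperm - preds) ** 2).sum(axis=0)
        sst = (Yc**2).sum(axis=0)
        return 1.0 - sse / sst
    raise ParameterError(f"unknown permutation statistic {statistic!r}")


def permutation_test(
    X,
    y,
    n_components: int = 2,
    n_perm: int = 10_000,
    seed=None,
    statistic: str = "r",
    batch_size: int = 512,
) -> PermutationResult:
    """Permutation significance of the LOOCV association.

    The response is permuted uniformly at random ``n_perm`` times; for each
    permutation the full LOOCV loop is recomputed and the statistic
    (LOOCV Pearson r by default, LOOCV R2 with ``statistic="r2"``) is
    evaluated against the permuted response. The one-sided p-value uses the
    add-one rule, p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm), with
    ties counted against the observed value.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be at least 1")
    X, y = _validate_xy(X, y, n_components)
    rng = np.random.default_rng(seed)
    obs_pred = _loocv_batch(X, y[:, None], n_components)[:, 0]
    if statistic == "r":
        obs = assess(y, obs_pred).r
    else:
        obs = _null_statistic(y[:, None], obs_pred[:, None], statistic)[0]
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        Yperm = np.empty((y.size, b))
        for k in range(b):
            Yperm[:, k] = rng.permutation(y)
        preds = _loocv_batch(X, Yperm, n_components)
        null[done : done + b] = _null_statistic(Yperm, preds, statistic)
        done += b
    p = (1.0 + np.count_nonzero(null >= obs)) / (1.0 + n_perm)
    return PermutationResult(
        p_value=float(p), observed=float(obs), null=null, n_perm=n_perm,
        statistic=statistic,
    )


def vip_scores(model: PLSModel, threshold: float = 2.0) -> pd.DataFrame:
    """VIP score, coefficient sign and VIP flag per marker.

    ``is_vip`` uses a strict comparison (VIP > threshold); a marker at
    exactly the threshold is excluded.
    """
    ss = model.component_y_ss
    wnorm = model.weights / np.maximum(
        np.linalg.norm(model.weights, axis=0, keepdims=True), _EPS
    )
    p = model.weights.shape[0]
    vip = np.sqrt(p * (wnorm**2 @ ss) / ss.sum())
    sign = np.where(model.coef >= 0, "+", "-")
    index = (
        model.marker_ids
        if model.marker_ids is not None
        else pd.RangeIndex(p)
    )
    return pd.DataFrame(
        {
            "vip": vip,
            "coef": model.coef,
            "sign": sign,
            "is_vip": vip > threshold,
        },
        index=index,
    ).rename_axis("marker_id")


def explained_variance(model: PLSModel, y) -> np.ndarray:
    """Fraction of the response variance captured by each component."""
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise UndefinedStatisticError("variance fractions undefined for constant y")
    sst = float(np.sum((y - y.mean()) ** 2))
    return model.component_y_ss / sst


def compare_predictor_overlap(set_a, set_b, denom_a: int, denom_b: int):
    """Pooled two-proportion z-test between |set_a|/denom_a and |set_b|/denom_b.

    ``set_a``/``set_b`` may be collections or plain counts. Returns
    ``(z, p)`` with a two-sided normal p-value.
    """
    k_a = set_a if isinstance(set_a, (int, np.integer)) else len(set_a)
    k_b = set_b if isinstance(set_b, (int, np.integer)) else len(set_b)
    if denom_a <= 0 or denom_b <= 0:
        raise ParameterError("denominators must be positive")
    if k_a > denom_a or k_b > denom_b:
        raise ParameterError("counts exceed their denominators")
    p_a, p_b = k_a / denom_a, k_b / denom_b
    pooled = (k_a + k_b) / (denom_a + denom_b)
    se = np.sqrt(pooled * (1 - pooled) * (1 / denom_a + 1 / denom_b))
    if se == 0:
        return 0.0, 1.0
    z = (p_a - p_b) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class ResponseModelResult:
    """All artifacts of one response's filter-fit-assess run."""

    response: str
    filter_table: pd.DataFrame
    model: PLSModel
    loocv_predictions: np.ndarray
    assessment: Assessment
    vip_table: pd.DataFrame
    permutation: PermutationResult | None = None
    explained: np.ndarray | None = None

    @property
    def vip_set(self) -> set:
        return set(self.vip_table.index[self.vip_table["is_vip"]])


def run_response_models(
    matrix,
    metadata: pd.DataFrame,
    responses=("CEE",),
    n_components: int = 2,
    n_perm: int | None = None,
    vip_threshold: float = 2.0,
    seed=None,
    filter_kwargs: dict | None = None,
) -> tuple[dict[str, ResponseModelResult], pd.DataFrame]:
    """Fit one PLS model per response and compare their VIP sets.

    Each response gets its own Spearman filter gate (against that response),
    PLS fit, LOOCV assessment, VIP table and — when ``n_perm`` is set — a
    permutation test. The second return value tabulates pairwise VIP-set
    overlaps with the two-proportion z-test (denominators = each model's
    filtered marker count).
    """
    from .compositional import select_markers

    filter_kwargs = dict(filter_kwargs or {})
    seed_seq = np.random.SeedSequence(seed)
    results: dict[str, ResponseModelResult] = {}
    for i, resp in enumerate(responses):
        if resp not in metadata.columns:
            raise DataError(f"response column {resp!r} missing from metadata")
        yser = metadata[resp].dropna()
        rel, table = select_markers(matrix, yser, **filter_kwargs)
        kept = table.index[table["kept"]]
        if len(kept) < n_components + 1:
            raise DataError(
                f"only {len(kept)} markers survive the filter for {resp!r}"
            )
        samples = rel.values.columns.intersection(yser.index)
        X = rel.values.loc[kept, samples].to_numpy().T
        y = yser.loc[samples].to_numpy(dtype=float)
        model = fit_pls(X, y, n_components, marker_ids=kept)
        preds = loocv(X, y, n_components)
        result = ResponseModelResult(
            response=resp,
            filter_table=table,
            model=model,
            loocv_predictions=preds,
            assessment=assess(y, preds),
            vip_table=vip_scores(model, vip_threshold),
            explained=explained_variance(model, y),
        )
        if n_perm:
            sub_seed = seed_seq.spawn(len(responses))[i]
            result.permutation = permutation_test(
                X, y, n_components, n_perm=n_perm, seed=sub_seed
            )
        results[resp] = result

    rows = []
    resp_list = list(results)
    for i in range(len(resp_list)):
        for j in range(i + 1, len(resp_list)):
            a, b = results[resp_list[i]], results[resp_list[j]]
            shared = a.vip_set & b.vip_set
            denom_a = int(a.filter_table["kept"].sum())
            denom_b = int(b.filter_table["kept"].sum())
            rows.append(
                {
                    "response_a": resp_list[i],
                    "response_b": resp_list[j],
                    "n_vip_a": len(a.vip_set),
                    "n_vip_b": len(b.vip_set),
                    "n_shared": len(shared),
                    "denom_a": denom_a,
                    "denom_b": denom_b,
                }
            )
    overlap = pd.DataFrame(
        rows,
        columns=[
            "response_a", "response_b", "n_vip_a", "n_vip_b",
            "n_shared", "denom_a", "denom_b",
        ],
    )
    return results, overlap
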