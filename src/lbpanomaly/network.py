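"""Auto-associative feed-forward network trained by Bayesian-regularized LM.

Architecture (fixed by the analysis design): ``n_in`` inputs, a 20-unit
tanh hidden layer, a 20-unit logistic-sigmoid hidden layer and a linear
output layer of ``n_out`` units.  The network is used *auto-associatively*:
its target is the subject's own standardized feature vector, so the
trained map captures the cohort's inter-variable structure and subjects
whose profiles break that structure reconstruct poorly.

Training is Levenberg-Marquardt on the regularized objective

    F(w) = beta * E_D + alpha * E_W,

with ``E_D`` the sum of squared reconstruction errors over the training
split and ``E_W = sum(w^2)``.  After each accepted LM step the
hyperparameters are re-estimated with the evidence-framework updates

    gamma = N_w - 2*alpha*tr(H^-1),   H = 2*beta*J'J + 2*alpha*I
    alpha <- gamma / (2*E_W),         beta <- (n - gamma) / (2*E_D)

where ``gamma`` is the effective number of parameters and ``n`` the
number of training residuals.  The damping factor ``mu`` is multiplied by
``mu_inc`` whenever a step fails to decrease F and by ``mu_dec`` when it
succeeds; training stops at the MSE goal, the epoch cap, or when ``mu``
exceeds ``mu_max`` (no downhill step exists at any damping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from lbpanomaly.errors import ValidationError

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureMatrix",
    "NetworkParams",
    "TrainConfig",
    "TrainingReport",
    "build_feature_matrix",
    "init_network",
    "forward",
    "jacobian",
    "split_train_test",
    "train",
    "save_model",
    "load_model",
]

# Input feature set, fixed order.  Sex is coded female=1, male=0.
FEATURE_COLUMNS = (
    "age", "sex", "body_mass", "height", "bmi",
    "odi_pct", "dass_stress", "dass_anxiety", "dass_depression",
    "pcs_total",
)

HIDDEN_1 = 20
HIDDEN_2 = 20


@dataclass
class FeatureMatrix:
    """Standardized subject-by-feature matrix with inversion constants."""

    values: np.ndarray          # n_subjects x n_features, standardized
    columns: tuple[str, ...]
    mean: np.ndarray            # per-column raw mean
    sd: np.ndarray              # per-column raw SD; 0 marks constant cols
    ids: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def destandardize(self, z: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd == 0.0, 1.0, self.sd)
        return z * sd + self.mean


def build_feature_matrix(cohort: pd.DataFrame,
                         scores: pd.DataFrame) -> FeatureMatrix:
    """Assemble the standardized 10-column input matrix.

    ``cohort`` supplies demographics, ``scores`` the instrument scores
    (one row per subject, joined on ``id``).  Columns follow
    :data:`FEATURE_COLUMNS`; each is centred and scaled to unit SD, with
    constant columns mapped to all-zero and their SD recorded as 0 so
    standardization remains invertible.
    """
    merged = cohort.merge(scores, on="id", how="left", validate="1:1")
    needed = ["odi_pct", "dass_stress", "dass_anxiety", "dass_depression",
              "pcs_total"]
    if merged[needed].isna().any().any():
        missing = merged.loc[merged[needed].isna().any(axis=1), "id"]
        raise ValidationError(
            f"missing scores for subject ids {list(missing[:5])}...")
    raw = np.column_stack([
        merged["age"].to_numpy(float),
        (merged["sex"] == "F").to_numpy(float),
        merged["body_mass"].to_numpy(float),
        merged["height"].to_numpy(float),
        merged["bmi"].to_numpy(float),
        merged["odi_pct"].to_numpy(float),
        merged["dass_stress"].to_numpy(float),
        merged["dass_anxiety"].to_numpy(float),
        merged["dass_depression"].to_numpy(float),
        merged["pcs_total"].to_numpy(float),
    ])
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    # columns constant up to float rounding count as constant
    sd = np.where(sd <= (np.abs(mean) + 1.0) * 1e-12, 0.0, sd)
    z = np.where(sd > 0.0, (raw - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    return FeatureMatrix(values=z, columns=FEATURE_COLUMNS, mean=mean,
                         sd=np.where(sd > 0.0, sd, 0.0),
                         ids=merged["id"].to_numpy())


@dataclass
class NetworkParams:
    """Weights and biases of the 3-layer network."""

    W1: np.ndarray  # h1 x n_in
    b1: np.ndarray  # h1
    W2: np.ndarray  # h2 x h1
    b2: np.ndarray  # h2
    W3: np.ndarray  # n_out x h2
    b3: np.ndarray  # n_out

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_out(self) -> int:
        return self.W3.shape[0]

    @property
    def n_weights(self) -> int:
        return sum(a.size for a in self._arrays())

    def _arrays(self) -> tuple[np.ndarray, ...]:
        return (self.W1, self.b1, self.W2, self.b2, self.W3, self.b3)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self._arrays()])

    @classmethod
    def from_vector(cls, w: np.ndarray, n_in: int, n_out: int,
                    h1: int = HIDDEN_1, h2: int = HIDDEN_2
                    ) -> "NetworkParams":
        sizes = [h1 * n_in, h1, h2 * h1, h2, n_out * h2, n_out]
        if w.size != sum(sizes):
            raise ValidationError(
                f"weight vector length {w.size} != {sum(sizes)}")
        parts = np.split(w, np.cumsum(sizes)[:-1])
        return cls(W1=parts[0].reshape(h1, n_in), b1=parts[1],
                   W2=parts[2].reshape(h2, h1), b2=parts[3],
                   W3=parts[4].reshape(n_out, h2), b3=parts[5])


def init_network(n_in: int, n_out: int, seed: int = 0) -> NetworkParams:
    """Deterministic initialization: Nguyen-Widrow hidden layers, small
    uniform output layer."""
    if n_in < 1 or n_out < 1:
        raise ValidationError("n_in and n_out must be >= 1")
    rng = np.random.default_rng(seed)

    def nguyen_widrow(h: int, fan_in: int) -> tuple[np.ndarray, np.ndarray]:
        scale = 0.7 * h ** (1.0 / fan_in)
        w = rng.uniform(-1.0, 1.0, size=(h, fan_in))
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        w = scale * w / np.where(norms == 0, 1.0, norms)
        b = scale * np.linspace(-1.0, 1.0, h) * np.sign(w[:, 0])
        return w, b

    W1, b1 = nguyen_widrow(HIDDEN_1, n_in)
    W2, b2 = nguyen_widrow(HIDDEN_2, HIDDEN_1)
    W3 = rng.uniform(-0.1, 0.1, size=(n_out, HIDDEN_2))
    b3 = rng.uniform(-0.1, 0.1, size=n_out)
    return NetworkParams(W1, b1, W2, b2, W3, b3)


def _logsig(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_cache(p: NetworkParams, X: np.ndarray):
    a1 = np.tanh(X @ p.W1.T + p.b1)
    a2 = _logsig(a1 @ p.W2.T + p.b2)
    y = a2 @ p.W3.T + p.b3
    return y, a1, a2


def forward(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Network outputs for each row of ``X`` (linear output layer)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.n_in:
        raise ValidationError(
            f"X must be 2-D with {params.n_in} columns, got {X.shape}")
    y, _, _ = _forward_cache(params, X)
    return y


def jacobian(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d(outputs)/d(weights).

    Rows are (sample, output) pairs in C order — sample-major — columns
    follow the flattened parameter order of
    :meth:`NetworkParams.to_vector`.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    m = params.n_out
    h1, h2 = params.W1.shape[0], params.W2.shape[0]
    _, a1, a2 = _forward_cache(params, X)

    a2p = a2 * (1.0 - a2)                      # n x h2
    delta2 = params.W3[None, :, :] * a2p[:, None, :]       # n x m x h2
    back1 = np.einsum("nkj,ji->nki", delta2, params.W2)    # n x m x h1
    delta1 = back1 * (1.0 - a1 * a1)[:, None, :]           # n x m x h1

    dW1 = np.einsum("nki,np->nkip", delta1, X).reshape(n, m, h1 * params.n_in)
    db1 = delta1
    dW2 = np.einsum("nkj,ni->nkji", delta2, a1).reshape(n, m, h2 * h1)
    db2 = delta2
    dW3 = np.zeros((n, m, m, h2))
    db3 = np.zeros((n, m, m))
    for k in range(m):
        dW3[:, k, k, :] = a2
        db3[:, k, k] = 1.0
    J = np.concatenate([dW1, db1, dW2, db2,
                        dW3.reshape(n, m, m * h2), db3], axis=2)
    return J.reshape(n * m, params.n_weights)


def split_train_test(n: int, train_frac: float = 0.8,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split into round(train_frac*n) train and the rest."""
    if n < 2:
        raise ValidationError("need at least 2 samples to split")
    if not 0.0 < train_frac < 1.0:
        raise ValidationError("train_frac must lie in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_frac * n))
    return perm[:n_train], perm[n_train:]


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg-Marquardt / Bayesian-regularization settings."""

    max_epochs: int = 1000
    mse_goal: float = 0.001
    train_frac: float = 0.8
    mu0: float = 0.005
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    bayesian: bool = True   # False freezes alpha at 0 (plain LM)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_frac < 1.0:
            raise ValidationError("train_frac must lie in (0, 1)")
        for name in ("mu0", "mu_inc", "mu_dec", "mu_max"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class TrainingReport:
    """Trace and summary of one training run."""

    epochs: int
    stop_reason: str
    final_mse: float
    alpha: float
    beta: float
    gamma: float
    alpha_trace: list[float] = field(default_factory=list)
    beta_trace: list[float] = field(default_factory=list)
    gamma_trace: list[float] = field(default_factory=list)
    mse_trace: list[float] = field(default_factory=list)
    # objective F before/after each accepted LM step, at that epoch's
    # (alpha, beta) — F must decrease within every accepted step
    f_before_trace: list[float] = field(default_factory=list)
    f_after_trace: list[float] = field(default_factory=list)
    r_train: float = float("nan")
    r_test: float = float("nan")
    r_all: float = float("nan")
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None


def _pooled_r(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.ravel(), b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def train(features: FeatureMatrix | np.ndarray,
          cfg: TrainConfig | None = None,
          targets: np.ndarray | None = None
          ) -> tuple[NetworkParams, TrainingReport]:
    """Train the auto-associative network on a standardized feature matrix.

    ``targets`` defaults to the inputs themselves (auto-association).
    Returns the trained parameters and a :class:`TrainingReport` holding
    the hyperparameter trace and pooled train/test/all Pearson R.
    """
    cfg = cfg or TrainConfig()
    X = features.values if isinstance(features, FeatureMatrix) else (
        np.asarray(features, dtype=float))
    T = X if targets is None else np.asarray(targets, dtype=float)
    if X.shape != T.shape and T.shape[0] != X.shape[0]:
        raise ValidationError("targets must align with inputs row-wise")
    n, n_in = X.shape
    n_out = T.shape[1]
    if n < 10:
        raise ValidationError("need at least 10 subjects to train")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(T)):
        raise ValidationError("non-finite values in training data")

    train_idx, test_idx = split_train_test(n, cfg.train_frac, cfg.seed)
    Xtr, Ttr = X[train_idx], T[train_idx]
    params = init_network(n_in, n_out, seed=cfg.seed)
    w = params.to_vector()
    Nw = w.size
    n_resid = Xtr.shape[0] * n_out

    alpha, beta = 0.0, 1.0
    mu = cfg.mu0
    report = TrainingReport(epochs=0, stop_reason="max_epochs",
                            final_mse=np.inf, alpha=alpha, beta=beta,
                            gamma=float(Nw))

    def unpack(wv: np.ndarray) -> NetworkParams:
        return NetworkParams.from_vector(wv, n_in, n_out)

    def data_error(wv: np.ndarray) -> float:
        y = forward(unpack(wv), Xtr)
        return float(np.sum((y - Ttr) ** 2))

    e_d = data_error(w)
    e_w = float(w @ w)
    identity = np.eye(Nw)

    for epoch in range(1, cfg.max_epochs + 1):
        p = unpack(w)
        y, _, _ = _forward_cache(p, Xtr)
        r = (y - Ttr).ravel()
        J = jacobian(p, Xtr)
        if not np.all(np.isfinite(J)) or not np.all(np.isfinite(r)):
            report.stop_reason = "non_finite"
            break
        JtJ = J.T @ J
        g = 2.0 * (beta * (J.T @ r) + alpha * w)
        f_cur = beta * e_d + alpha * e_w

        # LM inner loop: grow mu until a step decreases F
        accepted = False
        while mu <= cfg.mu_max:
            A = 2.0 * beta * JtJ + (2.0 * alpha + mu) * identity
            try:
                c = cho_factor(A, check_finite=False)
                step = cho_solve(c, -g, check_finite=False)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_inc
                continue
            w_new = w + step
            e_d_new = data_error(w_new)
            e_w_new = float(w_new @ w_new)
            f_new = beta * e_d_new + alpha * e_w_new
            if np.isfinite(f_new) and f_new < f_cur:
                accepted = True
                break
            mu *= cfg.mu_inc
        if not accepted:
            report.stop_reason = "mu_max"
            break

        w, e_d, e_w = w_new, e_d_new, e_w_new
        mu = max(mu * cfg.mu_dec, 1e-20)
        report.f_before_trace.append(f_cur)
        report.f_after_trace.append(f_new)

        # evidence-framework hyperparameter re-estimation
        if cfg.bayesian:
            gamma = _effective_params(JtJ, alpha, beta, Nw)
            alpha = gamma / (2.0 * e_w) if e_w > 0 else 0.0
            beta = max(n_resid - gamma, 1e-3) / (2.0 * e_d) if e_d > 0 else (
                beta)
        else:
            gamma = float(Nw)

        mse = e_d / n_resid
        report.epochs = epoch
        report.alpha_trace.append(alpha)
        report.beta_trace.append(beta)
        report.gamma_trace.append(gamma)
        report.mse_trace.append(mse)
        if mse <= cfg.mse_goal:
            report.stop_reason = "mse_goal"
            break

    params = unpack(w)
    report.final_mse = e_d / n_resid
    report.alpha, report.beta = alpha, beta
    report.gamma = report.gamma_trace[-1] if report.gamma_trace else float(Nw)
    report.train_idx, report.test_idx = train_idx, test_idx

    y_all = forward(params, X)
    report.r_train = _pooled_r(y_all[train_idx], T[train_idx])
    report.r_test = _pooled_r(y_all[test_idx], T[test_idx])
    report.r_all = _pooled_r(y_all, T)
    return params, report


def _effective_params(JtJ: np.ndarray, alpha: float, beta: float,
                      n_weights: int) -> float:
    """Effective number of parameters gamma = N_w - 2*alpha*tr(H^-1).

    Evaluated through the spectral identity
    ``gamma = sum_i h_i / (h_i + 2*alpha)`` with ``h_i`` the eigenvalues
    of ``2*beta*J'J`` — algebraically the same quantity, but stable when
    the Gauss-Newton Hessian is rank-deficient (more weights than
    residuals) and well defined in the alpha -> 0 limit, where it counts
    the nonzero curvature directions.
    """
    lam = np.clip(np.linalg.eigvalsh(JtJ), 0.0, None)
    h = 2.0 * beta * lam
    if alpha <= 0.0:
        top = h.max(initial=0.0)
        return float(np.sum(h > top * 1e-12)) if top > 0 else 0.0
    return float(np.clip(np.sum(h / (h + 2.0 * alpha)), 0.0, n_weights))


MODEL_FORMAT_VERSION = 1


def save_model(path: str | Path, params: NetworkParams,
               fm: FeatureMatrix, report: TrainingReport | None = None
               ) -> None:
    """Serialize a trained model plus standardization constants to JSON."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_in": params.n_in,
        "n_out": params.n_out,
        "hidden": [params.W1.shape[0], params.W2.shape[0]],
        "weights": params.to_vector().tolist(),
        "columns": list(fm.columns),
        "mean": fm.mean.tolist(),
        "sd": fm.sd.tolist(),
    }
    if report is not None:
        payload["training"] = {
            "epochs": report.epochs,
            "stop_reason": report.stop_reason,
            "final_mse": report.final_mse,
            "alpha": report.alpha,
            "beta": report.beta,
            "gamma": report.gamma,
            "r_train": report.r_train,
            "r_test": report.r_test,
            "r_all": report.r_all,
        }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_model(path: str | Path) -> tuple[NetworkParams, FeatureMatrix, dict]:
    """Load a model written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format {payload.get('format_version')}")
    h1, h2 = payload["hidden"]
    params = NetworkParams.from_vector(
        np.asarray(payload["weights"], dtype=float),
        payload["n_in"], payload["n_out"], h1, h2)
    fm = FeatureMatrix(values=np.zeros((0, payload["n_in"])),
                       columns=tuple(payload["columns"]),
                       mean=np.asarray(payload["mean"], dtype=float),
                       sd=np.asarray(payload["sd"], dtype=float))
    return params, fm, payload.get("training", {})
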