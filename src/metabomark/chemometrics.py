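"""PCA and OPLS-DA with cross-validated Q², VIP, S-plot and permutation test.

The discriminant core of the pipeline.  PCA gives an unsupervised view of the
sample distribution with per-component explained variance (R²X) and a 7-fold
cross-validated predicted variance (Q²).  OPLS-DA (orthogonal projections to
latent structures, Trygg & Wold formulation) splits X-variation into one
predictive component — correlated with class membership — and k orthogonal
components of structured within-class variation, giving interpretable scores,
per-feature VIP importances, S-plot coordinates, and a SIMCA-style label
permutation test to flag overfitting.

Both models follow the Model/Results convention: construct from data, call
``fit()``, read estimates and diagnostics off the returned results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import ScaledMatrix


class ChemometricsError(ValueError):
    pass


def _as_matrix(x) -> tuple[np.ndarray, list[str], list[str] | None]:
    if isinstance(x, ScaledMatrix):
        return np.asarray(x.values, dtype=float), list(x.feature_ids), (
            list(x.sample_ids) if x.sample_ids is not None else None
        )
    arr = np.asarray(x, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])], None


def fold_assignment(
    n: int, n_folds: int, sample_ids: list[str] | None = None
) -> np.ndarray:
    """Deterministic interleaved fold labels (SIMCA-style round robin).

    Assignment follows the rank of each sample id in sorted order, so the
    result is invariant to the row order of the matrix.
    """
    if n_folds < 2:
        raise ChemometricsError("need at least 2 folds")
    order = np.argsort(np.asarray(sample_ids)) if sample_ids else np.arange(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % n_folds
    return folds


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResults:
    """Fitted principal components of a scaled matrix."""

    n_components: int
    scores: np.ndarray              # samples x PCs
    loadings: np.ndarray            # features x PCs, orthonormal columns
    r2x_per_component: np.ndarray
    q2_cum: float
    cv_folds: int
    feature_ids: list[str] = field(default_factory=list)

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x_per_component.sum())

    def summary(self) -> str:
        lines = [
            "PCA results",
            "=" * 46,
            f"{'components':<22}{self.n_components:>8d}",
            f"{'R2X(cum)':<22}{self.r2x_cum:>12.4f}",
            f"{'Q2(cum), %d-fold CV' % self.cv_folds:<22}{self.q2_cum:>12.4f}",
            "-" * 46,
            "  PC    R2X      R2X(cum)",
        ]
        cum = 0.0
        for a, r in enumerate(self.r2x_per_component, 1):
            cum += r
            lines.append(f"  {a:<4d}{r:8.4f}   {cum:8.4f}")
        return "\n".join(lines)


class PCAModel:
    """PCA of a centred (Pareto-scaled) matrix via SVD.

    R²X per component is the component's share of the total sum of squares;
    Q² comes from row-wise k-fold cross-validation: each fold's rows are held
    out, loadings are refit on the rest, held-out rows are projected and the
    squared reconstruction error accumulates into PRESS, with
    ``Q2 = 1 - PRESS / SS``.
    """

    def __init__(self, x: ScaledMatrix | np.ndarray):
        self.x, self.feature_ids, self.sample_ids = _as_matrix(x)

    def fit(self, n_components: int, cv_folds: int = 7) -> PCAResults:
        x = self.x
        n, p = x.shape
        if not 1 <= n_components <= min(n - 1, p):
            raise ChemometricsError(
                f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
            )
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        scores = u[:, :n_components] * s[:n_components]
        loadings = vt[:n_components].T
        ss_total = float((xc**2).sum())
        r2x = (s[:n_components] ** 2) / ss_total
        q2 = self._cross_validated_q2(n_components, cv_folds)
        return PCAResults(
            n_components=n_components,
            scores=scores,
            loadings=loadings,
            r2x_per_component=r2x,
            q2_cum=q2,
            cv_folds=cv_folds,
            feature_ids=self.feature_ids,
        )

    def _cross_validated_q2(self, n_components: int, cv_folds: int) -> float:
        x = self.x
        n = x.shape[0]
        folds = fold_assignment(n, cv_folds, self.sample_ids)
        press = 0.0
        ss = 0.0
        for k in range(cv_folds):
            test = folds == k
            train = ~test
            mean = x[train].mean(axis=0)
            xtr = x[train] - mean
            a = min(n_components, min(xtr.shape) - 1) if min(xtr.shape) > 1 else 1
            _, _, vt = np.linalg.svd(xtr, full_matrices=False)
            pk = vt[:a].T
            xte = x[test] - mean
            resid = xte - (xte @ pk) @ pk.T
            press += float((resid**2).sum())
            ss += float((xte**2).sum())
        return 1.0 - press / ss


def fit_pca(
    x: ScaledMatrix | np.ndarray, n_components: int, cv_folds: int = 7
) -> PCAResults:
    """Functional wrapper around :class:`PCAModel`."""
    return PCAModel(x).fit(n_components, cv_folds)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclass
class _OplsCore:
    """Raw fitted quantities of one OPLS decomposition (internal)."""

    w_pred: np.ndarray
    t_pred: np.ndarray
    p_pred: np.ndarray
    q_pred: float
    w_orth: np.ndarray  # features x k
    t_orth: np.ndarray  # samples x k
    p_orth: np.ndarray  # features x k
    k_orth: int


def _fit_opls_core(x: np.ndarray, y: np.ndarray, k_orth: int) -> _OplsCore:
    """Trygg-Wold O-PLS on a centred X and centred y.

    Per orthogonal component: take the PLS loading p of the current X, strip
    the part collinear with the predictive weight w, normalise; the resulting
    orthogonal score is removed from X.  The final single-component PLS on the
    filtered X gives the predictive score/loading/regression coefficient.
    """
    n, p = x.shape
    xr = x.copy()
    w_os, t_os, p_os = [], [], []
    for _ in range(k_orth):
        w = xr.T @ y
        w /= np.linalg.norm(w)
        t = xr @ w
        p_load = xr.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:  # no orthogonal variation left
            break
        w_o /= norm
        t_o = xr @ w_o
        p_o = xr.T @ t_o / (t_o @ t_o)
        xr = xr - np.outer(t_o, p_o)
        w_os.append(w_o)
        t_os.append(t_o)
        p_os.append(p_o)

    w = xr.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ChemometricsError("X carries no covariance with y")
    w /= nw
    t = xr @ w
    p_load = xr.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    k = len(w_os)
    stack = lambda vs, m: (np.column_stack(vs) if vs else np.zeros((m, 0)))
    return _OplsCore(
        w_pred=w,
        t_pred=t,
        p_pred=p_load,
        q_pred=float(q),
        w_orth=stack(w_os, p),
        t_orth=stack(t_os, n),
        p_orth=stack(p_os, p),
        k_orth=k,
    )


def _opls_predict(core: _OplsCore, x_new: np.ndarray) -> np.ndarray:
    """Apply the orthogonal filter, then the predictive regression."""
    xr = x_new.copy()
    for a in range(core.k_orth):
        t_o = xr @ core.w_orth[:, a]
        xr = xr - np.outer(t_o, core.p_orth[:, a])
    return (xr @ core.w_pred) * core.q_pred


@dataclass
class PermutationResult:
    """SIMCA-style label-permutation validation of an OPLS-DA model.

    The regression lines through the (|corr(y_perm, y)|, statistic) points —
    including the unpermuted model at correlation 1 — give the R² and Q²
    intercepts at correlation 0; intercepts near or below zero indicate the
    original model is not explained by chance correlation.
    """

    n_permutations: int
    r2_perm: np.ndarray
    q2_perm: np.ndarray
    y_correlations: np.ndarray
    r2_original: float
    q2_original: float
    r2_intercept: float
    q2_intercept: float

    def empirical_p_q2(self) -> float:
        """Fraction of permutations with Q² >= the original (plus-one rule)."""
        return (1 + int((self.q2_perm >= self.q2_original).sum())) / (
            self.n_permutations + 1
        )


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA model for a two-class design."""

    t_pred: np.ndarray
    p_pred: np.ndarray
    w_pred: np.ndarray
    t_orth: np.ndarray
    p_orth: np.ndarray
    w_orth: np.ndarray
    k_orth: int
    r2x_cum: float
    r2y_cum: float
    q2_cum: float
    vip: pd.Series
    s_plot: pd.DataFrame      # columns p1 (covariance), pcorr1 (correlation)
    classes: tuple[str, str]  # (label encoded +1, label encoded -1)
    cv_folds: int
    feature_ids: list[str]
    _model: "OPLSDA" = field(repr=False, default=None)

    def vip_selection(self, threshold: float = 1.0) -> list[str]:
        """Feature ids with VIP above ``threshold`` (default 1)."""
        return list(self.vip.index[self.vip > threshold])

    def permutation_test(
        self, n_permutations: int = 200, seed: int = 0
    ) -> PermutationResult:
        return self._model.permutation_test(
            k_orth=self.k_orth,
            cv_folds=self.cv_folds,
            n_permutations=n_permutations,
            seed=seed,
        )

    def summary(self) -> str:
        lines = [
            "OPLS-DA results",
            "=" * 50,
            f"{'classes (+1 / -1)':<26}{self.classes[0]} / {self.classes[1]}",
            f"{'components (pred + orth)':<26}1 + {self.k_orth}",
            f"{'R2X(cum)':<26}{self.r2x_cum:>10.4f}",
            f"{'R2Y(cum)':<26}{self.r2y_cum:>10.4f}",
            f"{'Q2(cum), %d-fold CV' % self.cv_folds:<26}{self.q2_cum:>10.4f}",
            f"{'features with VIP > 1':<26}{len(self.vip_selection()):>10d}",
        ]
        return "\n".join(lines)


class OPLSDA:
    """OPLS-DA model of a Pareto-scaled matrix against a two-level class vector.

    Parameters
    ----------
    x : ScaledMatrix or ndarray
        Samples x features, already centred/scaled (use
        :func:`~metabomark.preprocessing.pareto_scale`).
    y : array-like
        One class label per sample, exactly two distinct values.  Internally
        the alphabetically first label is encoded +1, the other -1, and the
        encoded vector is centred.
    """

    def __init__(self, x: ScaledMatrix | np.ndarray, y):
        self.x, self.feature_ids, self.sample_ids = _as_matrix(x)
        y = np.asarray(y)
        levels = sorted(map(str, set(y.tolist())))
        if len(levels) != 2:
            raise ChemometricsError(f"y must have exactly two levels, got {levels}")
        self.classes = (levels[0], levels[1])
        self.y_pm1 = np.where(np.asarray([str(v) for v in y]) == levels[0], 1.0, -1.0)
        if self.x.shape[0] != self.y_pm1.shape[0]:
            raise ChemometricsError("x and y have different sample counts")

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        k_orth: int | str = "auto",
        cv_folds: int = 7,
        vip_mode: str = "total",
    ) -> OPLSDAResults:
        n = self.x.shape[0]
        if k_orth == "auto":
            k_orth = self._select_k_orth(cv_folds)
        k_orth = int(k_orth)
        if not 0 <= k_orth < n - 2:
            raise ChemometricsError(f"k_orth must be in [0, {n - 3}]")

        yc = self.y_pm1 - self.y_pm1.mean()
        core = _fit_opls_core(self.x, yc, k_orth)

        ssx = float((self.x**2).sum())
        ssx_pred = float((np.outer(core.t_pred, core.p_pred) ** 2).sum())
        ssx_orth = sum(
            float((np.outer(core.t_orth[:, a], core.p_orth[:, a]) ** 2).sum())
            for a in range(core.k_orth)
        )
        r2x = (ssx_pred + ssx_orth) / ssx
        resid_y = yc - core.t_pred * core.q_pred
        r2y = 1.0 - float((resid_y**2).sum()) / float((yc**2).sum())
        q2 = self._cross_validated_q2(k_orth, cv_folds)
        vip = self._vip(core, yc, mode=vip_mode)

        # S-plot: covariance and correlation of each (scaled) feature with t_pred
        t = core.t_pred
        xc = self.x - self.x.mean(axis=0)
        tc = t - t.mean()
        cov = xc.T @ tc / (n - 1)
        denom = np.sqrt((xc**2).sum(axis=0) / (n - 1)) * np.sqrt(
            (tc**2).sum() / (n - 1)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, cov / denom, 0.0)
        s_plot = pd.DataFrame(
            {"p1": cov, "pcorr1": corr}, index=pd.Index(self.feature_ids, name="feature_id")
        )

        return OPLSDAResults(
            t_pred=core.t_pred,
            p_pred=core.p_pred,
            w_pred=core.w_pred,
            t_orth=core.t_orth,
            p_orth=core.p_orth,
            w_orth=core.w_orth,
            k_orth=core.k_orth,
            r2x_cum=r2x,
            r2y_cum=r2y,
            q2_cum=q2,
            vip=vip,
            s_plot=s_plot,
            classes=self.classes,
            cv_folds=cv_folds,
            feature_ids=self.feature_ids,
            _model=self,
        )

    def _vip(self, core: _OplsCore, yc: np.ndarray, mode: str = "total") -> pd.Series:
        """VIP over all components, each weighted by the y-sum-of-squares its
        score explains (the "VIP total" convention); orthogonal components
        explain essentially no y-variance, so they carry near-zero weight.

        ``mode="pred"`` restricts to the predictive component.
        """
        p = len(self.feature_ids)
        comps = [(core.w_pred, core.t_pred)]
        if mode == "total":
            comps += [
                (core.w_orth[:, a], core.t_orth[:, a]) for a in range(core.k_orth)
            ]
        elif mode != "pred":
            raise ChemometricsError("vip_mode must be 'total' or 'pred'")
        num = np.zeros(p)
        denom = 0.0
        for w, t in comps:
            ssy = float((t @ yc) ** 2 / (t @ t))
            wn = w / np.linalg.norm(w)
            num += ssy * wn**2
            denom += ssy
        vip = np.sqrt(p * num / denom)
        return pd.Series(vip, index=pd.Index(self.feature_ids, name="feature_id"), name="vip")

    def _cross_validated_q2(self, k_orth: int, cv_folds: int) -> float:
        """Q² from row-wise k-fold CV of the full orthogonal-filter + predict
        composite, refit on each training split."""
        x, y = self.x, self.y_pm1
        folds = fold_assignment(x.shape[0], cv_folds, self.sample_ids)
        press = 0.0
        ss = float(((y - y.mean()) ** 2).sum())
        for k in range(cv_folds):
            test = folds == k
            train = ~test
            y_mean = y[train].mean()
            core = _fit_opls_core(x[train], y[train] - y_mean, k_orth)
            y_hat = _opls_predict(core, x[test]) + y_mean
            press += float(((y[test] - y_hat) ** 2).sum())
        return 1.0 - press / ss

    def _select_k_orth(self, cv_folds: int, min_gain: float = 0.01) -> int:
        """SIMCA-like rule: add orthogonal components while Q² improves by
        more than ``min_gain``."""
        n = self.x.shape[0]
        k_max = max(0, min(n - 3, self.x.shape[1] - 1, 10))
        best_k = 0
        q2_prev = self._cross_validated_q2(0, cv_folds)
        for k in range(1, k_max + 1):
            q2_k = self._cross_validated_q2(k, cv_folds)
            if q2_k - q2_prev > min_gain:
                best_k, q2_prev = k, q2_k
            else:
                break
        return best_k

    # -- validation --------------------------------------------------------

    def permutation_test(
        self,
        k_orth: int,
        cv_folds: int = 7,
        n_permutations: int = 200,
        seed: int = 0,
    ) -> PermutationResult:
        """Refit under shuffled class labels with identical hyperparameters.

        Records R²Y, Q² and |corr(y_perm, y)| per permutation; the intercepts
        come from the least-squares line through all points plus the
        unpermuted model at correlation 1.
        """
        if n_permutations < 20:
            raise ChemometricsError("need at least 20 permutations")
        rng = np.random.default_rng(seed)
        original = self.fit(k_orth=k_orth, cv_folds=cv_folds)
        r2_list, q2_list, corr_list = [], [], []
        y = self.y_pm1
        labels = np.asarray(
            [self.classes[0] if v > 0 else self.classes[1] for v in y]
        )
        for _ in range(n_permutations):
            perm = rng.permutation(len(y))
            y_perm = labels[perm]
            model = OPLSDA(self.x, y_perm)
            model.sample_ids = self.sample_ids
            res = model.fit(k_orth=k_orth, cv_folds=cv_folds)
            r2_list.append(res.r2y_cum)
            q2_list.append(res.q2_cum)
            yc = y - y.mean()
            ypc = model.y_pm1 - model.y_pm1.mean()
            corr_list.append(
                abs(float(yc @ ypc) / np.sqrt(float(yc @ yc) * float(ypc @ ypc)))
            )
        r2_perm = np.asarray(r2_list)
        q2_perm = np.asarray(q2_list)
        corrs = np.asarray(corr_list)

        xs = np.concatenate([corrs, [1.0]])
        r2_line = np.polyfit(xs, np.concatenate([r2_perm, [original.r2y_cum]]), 1)
        q2_line = np.polyfit(xs, np.concatenate([q2_perm, [original.q2_cum]]), 1)
        return PermutationResult(
            n_permutations=n_permutations,
            r2_perm=r2_perm,
            q2_perm=q2_perm,
            y_correlations=corrs,
            r2_original=original.r2y_cum,
            q2_original=original.q2_cum,
            r2_intercept=float(np.polyval(r2_line, 0.0)),
            q2_intercept=float(np.polyval(q2_line, 0.0)),
        )


def fit_oplsda(
    x: ScaledMatrix | np.ndarray,
    y,
    k_orth: int | str = "auto",
    cv_folds: int = 7,
) -> OPLSDAResults:
    """Functional wrapper around :class:`OPLSDA`."""
    return OPLSDA(x, y).fit(k_orth=k_orth, cv_folds=cv_folds)


def vip_scores(results: OPLSDAResults) -> pd.Series:
    """Per-feature VIP of a fitted OPLS-DA model."""
    return results.vip


def permutation_test(
    x: ScaledMatrix | np.ndarray,
    y,
    k_orth: int,
    cv_folds: int = 7,
    n_permutations: int = 200,
    seed: int = 0,
) -> PermutationResult:
    """Functional wrapper around :meth:`OPLSDA.permutation_test`."""
    return OPLSDA(x, y).permutation_test(
        k_orth=k_orth,
        cv_folds=cv_folds,
        n_permutations=n_permutations,
        seed=seed,
    )
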