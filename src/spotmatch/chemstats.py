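"""Two-group differential metabolite statistics via OPLS-DA.

Orthogonal projections to latent structures discriminant analysis
(OPLS-DA) splits the predictive variation that separates two groups from
orthogonal (within-group) variation.  The model here follows the
orthogonal-signal-corrected NIPALS scheme for a single binary response:

    w  = X'y / y'y, normalised          (predictive weights)
    t  = X w                            (predictive scores)
    p  = X't / t't                      (predictive loadings)
    w_o = p - (w'p) w, normalised       (orthogonal weights)
    t_o = X w_o;  p_o = X't_o / t_o't_o
    X  <- X - t_o p_o'                  (deflate, repeat for each component)

Diagnostics are the chemometrics standards: R2X/R2Y (cumulative explained
variance of X and of the group response), Q2 (cross-validated predicted
variance, stratified k-fold), and a label-permutation null for Q2.  VIP
(variable importance in projection) scores average to 1 in square; the
significance call is the conjunction VIP > 1 and p < 0.05, with the
univariate p from a Welch t-test on log intensities by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .integration import SpotMetaboliteMatrix

__all__ = [
    "GroupDesign",
    "OplsDaModel",
    "fit_oplsda",
    "vip_scores",
    "permutation_test",
    "differential_metabolites",
]


@dataclass
class GroupDesign:
    """Two-group labelling of observations (spots or samples)."""

    labels: np.ndarray
    case: str
    control: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        present = set(self.labels.tolist())
        if present != {self.case, self.control}:
            raise ValueError(
                f"labels must be exactly {{{self.case!r}, {self.control!r}}}, "
                f"got {sorted(map(str, present))}"
            )
        for g in (self.case, self.control):
            if (self.labels == g).sum() < 3:
                raise ValueError(f"group {g!r} has fewer than 3 members")

    @property
    def y(self) -> np.ndarray:
        """Binary coding: +1 for case, -1 for control."""
        return np.where(self.labels == self.case, 1.0, -1.0)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class OplsDaModel:
    """Fitted OPLS-DA model (one predictive + k orthogonal components)."""

    w_pred: np.ndarray          # predictive weights, unit norm (kept vars)
    t_pred: np.ndarray          # predictive scores
    p_pred: np.ndarray          # predictive loadings
    q_pred: float               # y-loading of the predictive component
    w_orth: np.ndarray          # (k, p) orthogonal weights
    t_orth: np.ndarray          # (n, k) orthogonal scores
    p_orth: np.ndarray          # (k, p) orthogonal loadings
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    R2X_cum: float
    R2Y_cum: float
    Q2_cum: float
    kept_columns: np.ndarray    # indices into the input metabolite axis
    n_obs: int

    @property
    def n_orth(self) -> int:
        return self.w_orth.shape[0]


def _scale_x(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    return (x - mean) / std, mean, std


def _fit_core(
    xc: np.ndarray, yc: np.ndarray, n_orth: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS OPLS on centred/scaled X and centred y."""
    x = xc.copy()
    w_os, t_os, p_os = [], [], []
    for _ in range(n_orth):
        w = x.T @ yc / (yc @ yc)
        w /= np.linalg.norm(w)
        t = x @ w
        p = x.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o /= norm
        t_o = x @ w_o
        p_o = x.T @ t_o / (t_o @ t_o)
        x = x - np.outer(t_o, p_o)
        w_os.append(w_o)
        t_os.append(t_o)
        p_os.append(p_o)
    w = x.T @ yc / (yc @ yc)
    w /= np.linalg.norm(w)
    t = x @ w
    p = x.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    k = len(w_os)
    pdim = xc.shape[1]
    return (
        w,
        t,
        p,
        q,
        np.array(w_os).reshape(k, pdim),
        np.array(t_os).reshape(k, len(xc)).T if k else np.zeros((len(xc), 0)),
        np.array(p_os).reshape(k, pdim),
    )


def _predict(
    x_new: np.ndarray, w: np.ndarray, q: float, w_orth: np.ndarray, p_orth: np.ndarray
) -> np.ndarray:
    """Orthogonal-filter new (already scaled) observations, then project."""
    x = x_new.copy()
    for w_o, p_o in zip(w_orth, p_orth):
        t_o = x @ w_o
        x = x - np.outer(t_o, p_o)
    return (x @ w) * q


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index lists for stratified k-fold (both groups represented per fold)."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for g in np.unique(y):
        idx = np.nonzero(y == g)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.array(sorted(f)) for f in folds]


def fit_oplsda(
    matrix: SpotMetaboliteMatrix | np.ndarray,
    design: GroupDesign,
    n_orth: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
) -> OplsDaModel:
    """Fit OPLS-DA with one predictive and ``n_orth`` orthogonal components.

    X is column-centred and unit-variance scaled internally; constant
    columns are dropped with a warning.  Q2 comes from stratified k-fold
    cross-validation (default 7-fold) of the predicted residuals:
    ``Q2 = 1 - PRESS / SS(y)``.
    """
    x = matrix.intensity if isinstance(matrix, SpotMetaboliteMatrix) else np.asarray(matrix, float)
    n, p = x.shape
    if p < 1:
        raise ValueError("need at least one metabolite")
    if len(design) != n:
        raise ValueError("design length does not match observation count")
    if n < cv_folds:
        raise ValueError(f"{n} observations < {cv_folds} CV folds")

    std = x.std(axis=0, ddof=1)
    kept = np.nonzero(std > 0)[0]
    if kept.size < x.shape[1]:
        warnings.warn(
            f"dropping {x.shape[1] - kept.size} constant metabolite columns",
            stacklevel=2,
        )
    if kept.size < 1:
        raise ValueError("all metabolite columns are constant")
    x = x[:, kept]

    xc, x_mean, x_std = _scale_x(x)
    y = design.y
    y_mean = float(y.mean())
    yc = y - y_mean

    w, t, pl, q, w_os, t_os, p_os = _fit_core(xc, yc, n_orth)

    ssx = (xc**2).sum()
    modelled = np.outer(t, pl)
    for k in range(w_os.shape[0]):
        modelled = modelled + np.outer(t_os[:, k], p_os[k])
    r2x = float((modelled**2).sum() / ssx)
    ssy = (yc**2).sum()
    resid_y = yc - t * q
    r2y = float(1.0 - (resid_y**2).sum() / ssy)

    rng = np.random.default_rng(seed)
    press = 0.0
    for test_idx in _stratified_folds(y, cv_folds, rng):
        train = np.setdiff1d(np.arange(n), test_idx)
        xt = x[train]
        std_t = xt.std(axis=0, ddof=1)
        std_t[std_t == 0] = 1.0
        mean_t = xt.mean(axis=0)
        xct = (xt - mean_t) / std_t
        yt = y[train]
        yct = yt - yt.mean()
        wf, tf, plf, qf, wof, tof, pof = _fit_core(xct, yct, n_orth)
        x_test = (x[test_idx] - mean_t) / std_t
        yhat = _predict(x_test, wf, qf, wof, pof) + yt.mean()
        press += ((y[test_idx] - yhat) ** 2).sum()
    q2 = float(1.0 - press / ssy)

    return OplsDaModel(
        w_pred=w,
        t_pred=t,
        p_pred=pl,
        q_pred=q,
        w_orth=w_os,
        t_orth=t_os,
        p_orth=p_os,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        R2X_cum=r2x,
        R2Y_cum=r2y,
        Q2_cum=q2,
        kept_columns=kept,
        n_obs=n,
    )


def vip_scores(model: OplsDaModel, n_variables: int | None = None) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt( p * sum_a w_ja^2 SSY_a / sum_a SSY_a ); with a single
    predictive component and unit-norm weights this is sqrt(p) * |w_j|,
    so the mean of VIP^2 equals 1 by construction.  Dropped (constant)
    columns receive VIP 0 when ``n_variables`` covers the original axis.
    """
    if model.w_pred is None:
        raise ValueError("model is not fitted")
    p = model.w_pred.size
    ssy = (model.t_pred @ model.t_pred) * model.q_pred**2
    vip_kept = np.sqrt(p * (model.w_pred**2) * ssy / ssy)
    if n_variables is None or n_variables == p:
        return vip_kept
    vip = np.zeros(n_variables)
    vip[model.kept_columns] = vip_kept
    return vip


def permutation_test(
    matrix: SpotMetaboliteMatrix | np.ndarray,
    design: GroupDesign,
    n_perm: int = 200,
    seed: int = 0,
    n_orth: int = 1,
    cv_folds: int = 7,
) -> tuple[float, np.ndarray, float]:
    """Label-permutation null distribution of Q2.

    Returns ``(observed_q2, permuted_q2, empirical_p)`` with
    ``empirical_p = (1 + #{perm Q2 >= observed}) / (n_perm + 1)``.  A
    sound model on real signal has permuted Q2 centred at or below zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} is small; p-values are coarse", stacklevel=2)
    model = fit_oplsda(matrix, design, n_orth=n_orth, cv_folds=cv_folds, seed=seed)
    rng = np.random.default_rng(seed)
    perm_q2 = np.empty(n_perm)
    for i in range(n_perm):
        labels = rng.permutation(design.labels)
        # permutations can starve a group below the 3-member floor only if
        # the original design was already minimal; labels stay balanced
        perm_design = GroupDesign(labels, design.case, design.control)
        m = fit_oplsda(
            matrix, perm_design, n_orth=n_orth, cv_folds=cv_folds,
            seed=int(rng.integers(2**31 - 1)),
        )
        perm_q2[i] = m.Q2_cum
    p = (1 + int((perm_q2 >= model.Q2_cum).sum())) / (n_perm + 1)
    return model.Q2_cum, perm_q2, float(p)


def _log_transform(x: np.ndarray) -> np.ndarray:
    pos = x[x > 0]
    eps = 0.5 * pos.min() if pos.size else 1.0
    return np.log(x + eps)


def differential_metabolites(
    matrix: SpotMetaboliteMatrix | np.ndarray,
    design: GroupDesign,
    mz_values: np.ndarray | None = None,
    test: str = "welch",
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    n_orth: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-metabolite VIP, p-value, fold change and significance call.

    VIP comes from the fitted OPLS-DA model; the univariate p from a
    two-sided Welch t-test on log intensities (``test="wilcoxon"`` for a
    rank-sum alternative); log2FC is the log2 ratio of group means.  A
    metabolite is significant iff VIP strictly exceeds ``vip_threshold``
    and p < ``alpha``.  Zero-variance metabolites are reported with
    ``note="zero_variance"`` and never significant.  Results are sorted
    by VIP descending.
    """
    if test not in ("welch", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    x = matrix.intensity if isinstance(matrix, SpotMetaboliteMatrix) else np.asarray(matrix, float)
    if mz_values is None:
        mz_values = (
            matrix.mz_values
            if isinstance(matrix, SpotMetaboliteMatrix)
            else np.arange(x.shape[1], dtype=float)
        )
    model = fit_oplsda(x, design, n_orth=n_orth, cv_folds=cv_folds, seed=seed)
    vip = vip_scores(model, n_variables=x.shape[1])

    case_mask = design.labels == design.case
    xl = _log_transform(x)
    pvals = np.full(x.shape[1], np.nan)
    l2fc = np.full(x.shape[1], np.nan)
    notes = np.array([""] * x.shape[1], dtype=object)
    for j in range(x.shape[1]):
        a, b = xl[case_mask, j], xl[~case_mask, j]
        if np.std(x[:, j]) == 0:
            notes[j] = "zero_variance"
            continue
        if test == "welch":
            pvals[j] = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        mu_a, mu_b = x[case_mask, j].mean(), x[~case_mask, j].mean()
        if mu_a > 0 and mu_b > 0:
            l2fc[j] = np.log2(mu_a / mu_b)

    p_eff = pvals.copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = ~np.isnan(pvals)
        p_eff[ok] = multipletests(pvals[ok], method="fdr_bh")[1]

    significant = (vip > vip_threshold) & (p_eff < alpha)
    significant &= notes == ""
    out = pd.DataFrame(
        {
            "mz": np.asarray(mz_values, dtype=float),
            "VIP": vip,
            "p_value": pvals,
            "p_adjusted" if fdr else "p_value_used": p_eff,
            "log2FC": l2fc,
            "significant": significant,
            "note": notes,
        }
    )
    if not fdr:
        out = out.drop(columns=["p_value_used"])
    return out.sort_values("VIP", ascending=False, kind="stable").reset_index(drop=True)
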