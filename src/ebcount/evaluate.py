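"""Benchmark evaluation: FDR curves, ROC curves, and an overdispersion test.

FDR curves report, for each list depth N, the fraction of the top-N ranked
tuples that are not truly differentially expressed. ROC curves are the
standard empirical curves (ties grouped into a single step). Curves from
repeated simulations are averaged pointwise with a Monte-Carlo standard
error; ROC replicates are first interpolated onto a common false-positive-
rate grid since their thresholds differ.

``overdispersion_lrt`` is the diagnostic used to justify the negative
binomial over the Poisson: per tuple, a Poisson model with library-size
offsets and a group mean per condition is tested against a negative binomial
alternative with one shared dispersion, via a likelihood-ratio statistic
referred to a chi-squared with 1 df. Because phi = 0 lies on the boundary of
the parameter space, the default p-value uses the 50:50 mixture of a point
mass at zero and chi-squared_1 (i.e. the one-sided p is halved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from sklearn import metrics as _skm

from .data import CountData, ReplicateStructure
from .priors import _ml_mean_groups

__all__ = [
    "FDRCurve",
    "ROCCurve",
    "fdr_curve",
    "roc_curve",
    "mean_curves",
    "overdispersion_lrt",
    "overdispersion_lrt_table",
    "LRTResult",
    "plot_curves",
]


@dataclass
class FDRCurve:
    """False discovery rate against list depth N."""

    depths: np.ndarray
    fdr: np.ndarray
    fp_count: np.ndarray
    se: np.ndarray | None = None  # present on averaged curves

    def __post_init__(self):
        self.depths = np.asarray(self.depths)
        self.fdr = np.asarray(self.fdr, dtype=float)
        self.fp_count = np.asarray(self.fp_count, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        d = {"depth": self.depths, "fdr": self.fdr, "fp_count": self.fp_count}
        if self.se is not None:
            d["se"] = self.se
        return pd.DataFrame(d)


@dataclass
class ROCCurve:
    """Empirical receiver-operating characteristic."""

    fpr: np.ndarray
    tpr: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self):
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)

    @property
    def auc(self) -> float:
        return float(_skm.auc(self.fpr, self.tpr))

    def to_frame(self) -> pd.DataFrame:
        d = {"fpr": self.fpr, "tpr": self.tpr}
        if self.se is not None:
            d["se"] = self.se
        return pd.DataFrame(d)


def fdr_curve(ranking, truth, depths=None) -> FDRCurve:
    """FDR of the top-N tuples of a ranked list against known labels.

    Parameters
    ----------
    ranking : sequence of tuple ids, best first
    truth : mapping/Series of tuple id -> bool (True = differentially
        expressed)
    depths : grid of list depths, default 1..min(3000, len(ranking))
    """
    ids = list(ranking)
    t = pd.Series(truth)
    missing = [i for i in ids if i not in t.index]
    if missing:
        raise KeyError(f"ranking contains unlabeled tuple ids, e.g. {missing[0]!r}")
    is_de = t.loc[ids].to_numpy(dtype=bool)
    fp_cum = np.cumsum(~is_de)
    if depths is None:
        depths = np.arange(1, min(3000, len(ids)) + 1)
    depths = np.asarray(depths, dtype=int)
    if np.any(depths < 1) or np.any(depths > len(ids)):
        raise ValueError("depths must lie in 1..len(ranking)")
    fp = fp_cum[depths - 1]
    return FDRCurve(depths=depths, fdr=fp / depths, fp_count=fp)


def roc_curve(scores, truth) -> ROCCurve:
    """Empirical ROC of scores against boolean labels (higher = more DE)."""
    if isinstance(scores, pd.Series) and isinstance(truth, pd.Series):
        truth = truth.loc[scores.index]
    y = np.asarray(truth, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("truth must contain both DE and non-DE tuples")
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr)


_ROC_GRID = np.linspace(0.0, 1.0, 512)


def mean_curves(curves):
    """Pointwise mean and standard error across replicate curves.

    FDR curves must share a depth grid; ROC curves are interpolated onto a
    fixed 512-point FPR grid first. SE is the standard deviation across
    replicates divided by sqrt(#replicates).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    R = len(curves)
    if isinstance(curves[0], FDRCurve):
        grid = curves[0].depths
        for c in curves[1:]:
            if not np.array_equal(c.depths, grid):
                raise ValueError("FDR curves have mismatched depth grids")
        fp = np.vstack([c.fp_count for c in curves])
        fdr = np.vstack([c.fdr for c in curves])
        se = fp.std(axis=0, ddof=1) / np.sqrt(R) if R > 1 else np.zeros(len(grid))
        return FDRCurve(
            depths=grid, fdr=fdr.mean(axis=0), fp_count=fp.mean(axis=0), se=se
        )
    if isinstance(curves[0], ROCCurve):
        tprs = np.vstack(
            [np.interp(_ROC_GRID, c.fpr, c.tpr) for c in curves]
        )
        se = tprs.std(axis=0, ddof=1) / np.sqrt(R) if R > 1 else np.zeros(_ROC_GRID.size)
        return ROCCurve(fpr=_ROC_GRID.copy(), tpr=tprs.mean(axis=0), se=se)
    raise TypeError(f"cannot average curves of type {type(curves[0])!r}")


@dataclass
class LRTResult:
    """Poisson-vs-NB likelihood-ratio test for one tuple."""

    statistic: float
    pvalue: float
    log10_pvalue: float
    phi_hat: float
    mean_expression: float


def _group_cols(groups) -> list[list[int]]:
    seen: dict = {}
    for i, g in enumerate(groups):
        seen.setdefault(g, []).append(i)
    return list(seen.values())


def _poisson_loglik_batch(counts, l, cols):
    """Per-tuple Poisson log-likelihood, one free mean per group."""
    ll = np.zeros(counts.shape[0])
    for c in cols:
        u = counts[:, c]
        lc = l[c]
        mu = u.sum(axis=1) / lc.sum()
        m = lc[None, :] * mu[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(u > 0, u * np.log(np.where(m > 0, m, 1.0)), 0.0)
        ll += t.sum(axis=1) - m.sum(axis=1) - gammaln(u + 1.0).sum(axis=1)
    return ll


def _nb_profile_loglik_batch(counts, l, cols, phis):
    """Per-tuple NB log-likelihood with means profiled out at phi_c."""
    mus = _ml_mean_groups(counts, l, phis, cols)  # (C, G)
    ll = np.zeros(counts.shape[0])
    r = 1.0 / phis
    for g, c in enumerate(cols):
        ok = mus[:, g] > 0  # all-zero groups contribute 0 in the limit
        if not np.any(ok):
            continue
        uo = counts[ok][:, c]
        mo = l[c][None, :] * mus[ok, g][:, None]
        ro = r[ok, None]
        term = (
            gammaln(uo + ro) - gammaln(ro) - gammaln(uo + 1.0)
            + uo * (np.log(mo) - np.log(mo + ro))
            - ro * np.log1p(mo / ro)
        )
        ll[ok] += term.sum(axis=1)
    return ll


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _lrt_batch(counts, l, cols, n_iter: int = 40):
    """Vectorized LR statistics via golden-section search over log phi.

    Maximises the profile log-likelihood over phi in [1e-8, 1e3] for all
    tuples simultaneously; returns (statistic, phi_hat) arrays.
    """
    C = counts.shape[0]
    ll_pois = _poisson_loglik_batch(counts, l, cols)
    a = np.full(C, np.log(1e-8))
    b = np.full(C, np.log(1e3))
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1 = _nb_profile_loglik_batch(counts, l, cols, np.exp(x1))
    f2 = _nb_profile_loglik_batch(counts, l, cols, np.exp(x2))
    for _ in range(n_iter):
        left = f1 >= f2  # maximum lies in [a, x2]
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
        x_eval = np.where(left, b - _GOLDEN * (b - a), a + _GOLDEN * (b - a))
        f_eval = _nb_profile_loglik_batch(counts, l, cols, np.exp(x_eval))
        # shrinking left: old x1 becomes the new x2; right: old x2 the new x1
        x1, x2, f1, f2 = (
            np.where(left, x_eval, x2),
            np.where(left, x1, x_eval),
            np.where(left, f_eval, f2),
            np.where(left, f1, f_eval),
        )
    phi_hat = np.exp(0.5 * (a + b))
    ll_nb = _nb_profile_loglik_batch(counts, l, cols, phi_hat)
    stat = np.maximum(0.0, 2.0 * (ll_nb - ll_pois))
    at_floor = phi_hat <= 2e-8  # optimum at the Poisson boundary: no signal
    phi_hat = np.where(at_floor, 0.0, phi_hat)
    stat = np.where(at_floor | (stat <= 1e-10), 0.0, stat)
    return stat, phi_hat


def overdispersion_lrt(
    tuple_counts, lib_sizes, groups, boundary_correction: bool = True
) -> LRTResult:
    """Test one tuple for overdispersion relative to the Poisson.

    Both models allow a separate mean per condition group with library-size
    offsets; the alternative adds one shared NB dispersion. Returns the LR
    statistic, its (boundary-corrected) p-value, and the tuple's mean
    normalized expression (mean of u_i/l_i) for plotting.
    """
    u = np.asarray(tuple_counts, dtype=float)
    l = np.asarray(lib_sizes, dtype=float)
    if u.ndim != 1 or u.shape != l.shape or u.shape[0] < 2:
        raise ValueError("need matching count/lib_size vectors of length >= 2")
    cols = _group_cols(groups)
    mean_expr = float(np.mean(u / l))
    if u.sum() == 0:
        return LRTResult(0.0, 1.0, 0.0, 0.0, mean_expr)
    stat, phi_hat = _lrt_batch(u[None, :], l, cols)
    return _lrt_result(float(stat[0]), float(phi_hat[0]), mean_expr,
                       boundary_correction)


def _lrt_result(stat, phi_hat, mean_expr, boundary_correction) -> LRTResult:
    if stat <= 0.0:
        return LRTResult(0.0, 1.0, 0.0, phi_hat, mean_expr)
    p = float(chi2.sf(stat, 1))
    if boundary_correction:
        p *= 0.5
    p = min(p, 1.0)
    return LRTResult(stat, p, float(np.log10(max(p, 1e-300))), phi_hat, mean_expr)


def overdispersion_lrt_table(
    data: CountData, groups, boundary_correction: bool = True
) -> pd.DataFrame:
    """Overdispersion LRT for every tuple of a dataset (vectorized).

    Returns a DataFrame (tuple_id, statistic, pvalue, log10_pvalue, phi_hat,
    mean_expression) — the per-sequence material of the log-p versus mean
    expression diagnostic plot.
    """
    cols = _group_cols(groups)
    counts = data.counts.astype(float)
    stat, phi_hat = _lrt_batch(counts, data.lib_sizes, cols)
    zero = counts.sum(axis=1) == 0
    stat = np.where(zero, 0.0, stat)
    phi_hat = np.where(zero, 0.0, phi_hat)
    mean_expr = (counts / data.lib_sizes[None, :]).mean(axis=1)
    rows = [
        _lrt_result(float(s), float(ph), float(me), boundary_correction)
        for s, ph, me in zip(stat, phi_hat, mean_expr)
    ]
    return pd.DataFrame(
        {
            "tuple_id": data.tuple_ids,
            "statistic": [r.statistic for r in rows],
            "pvalue": [r.pvalue for r in rows],
            "log10_pvalue": [r.log10_pvalue for r in rows],
            "phi_hat": [r.phi_hat for r in rows],
            "mean_expression": [r.mean_expression for r in rows],
        }
    )


def plot_curves(curves, labels=None, path=None, kind=None, title=None):
    """Render FDR or ROC curves to a matplotlib figure (optionally saved)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = list(curves)
    labels = labels or [f"curve {i}" for i in range(len(curves))]
    fig, ax = plt.subplots(figsize=(5, 4))
    for c, lab in zip(curves, labels):
        if isinstance(c, FDRCurve):
            ax.plot(c.depths, c.fdr, label=lab)
            ax.set_xlabel("tuples selected")
            ax.set_ylabel("false discovery rate")
        else:
            ax.plot(c.fpr, c.tpr, label=lab)
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
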