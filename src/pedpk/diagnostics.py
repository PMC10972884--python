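"""Model evaluation: goodness-of-fit tables, conditional weighted
residuals and normalized prediction distribution errors.

CWRES follows the FOCE convention: the residual vector is linearized
about each subject's MAP random effects and decorrelated by the Cholesky
factor of the linearized marginal covariance.  NPDE decorrelates the
observed vector against K simulated replicates of the same design and
maps the resulting rank to the standard-normal scale; under a correct
model the NPDE sample is standard normal, which is tested globally
(mean, variance, normality) with a Bonferroni-adjusted alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (
    Dataset,
    map_etas,
    residual_variance,
    subject_predictions,
)
from .model import PopulationParameters

__all__ = ["NpdeResult", "gof_table", "npde", "render_diagnostics"]

GLOBAL_ALPHA = 0.05  # split over the three tests (Bonferroni)


@dataclass
class NpdeResult:
    table: pd.DataFrame  # id, time, tad, dv, npde
    K: int
    seed: int
    p_mean: float
    p_var: float
    p_normal: float
    passed: bool

    @property
    def npde(self) -> np.ndarray:
        return self.table["npde"].to_numpy()


def _fd_jacobian(pop, subject, eta, h=1e-5):
    cols = []
    for i in range(2):
        ep = eta.copy()
        em = eta.copy()
        ep[i] += h
        em[i] -= h
        cols.append(
            (subject_predictions(pop, subject, ep) - subject_predictions(pop, subject, em))
            / (2 * h)
        )
    return np.column_stack(cols)


def gof_table(
    dataset: Dataset,
    pop: PopulationParameters,
    etas: dict | None = None,
) -> pd.DataFrame:
    """One row per observation: PRED, IPRED and FOCE conditional weighted residual.

    ``etas`` maps subject id to (eta_cl, eta_v); omitted entries are
    recomputed by MAP estimation at ``pop``.
    """
    omega = pop.omega_matrix()
    rows = []
    for s in dataset.observed_subjects():
        if etas is not None and s.id in etas:
            eta = np.asarray(etas[s.id], dtype=float)
        else:
            mp = map_etas(pop, s)
            eta = mp.eta
        # canonical (time, dv) order: the Cholesky whitening is sequential,
        # so a fixed ordering makes CWRES invariant to stored obs order
        order = sorted(range(s.n_obs), key=lambda j: (s.observations[j].time,
                                                      s.observations[j].dv))
        obs = [s.observations[j] for j in order]
        dv = np.array([o.dv for o in obs])
        pred = subject_predictions(pop, s, np.zeros(2))[order]
        ipred = subject_predictions(pop, s, eta)[order]
        G = _fd_jacobian(pop, s, eta)[order, :]
        r = dv - ipred + G @ eta
        cov = G @ omega @ G.T + np.diag(residual_variance(pop, ipred))
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"subject {s.id}: non-invertible linearized covariance"
            ) from exc
        cwres = np.linalg.solve(L, r)
        for j, o in enumerate(obs):
            rows.append(
                dict(
                    id=s.id, time=o.time, tad=o.tad, dv=o.dv,
                    pred=pred[j], ipred=ipred[j], cwres=cwres[j],
                )
            )
    return pd.DataFrame(rows)


def npde(
    dataset: Dataset,
    pop: PopulationParameters,
    K: int = 1000,
    seed: int = 0,
) -> NpdeResult:
    """Normalized prediction distribution errors from K design-preserving simulations.

    Each subject's observation vector is compared with K simulations under
    ``pop`` using the subject's exact doses, times and covariates.
    Observed and simulated vectors are decorrelated with the empirical
    mean and Cholesky factor of the simulated covariance; ranks get a
    half-count continuity correction and extreme ranks are pulled into
    (0, 1) by 1/(2K) so the normal quantile stays finite.
    """
    if K < 100:
        raise ValueError("K must be >= 100")
    rng = np.random.default_rng(seed)
    rows = []
    for s in dataset.observed_subjects():
        n = s.n_obs
        dv = np.array([o.dv for o in s.observations])
        etas = np.column_stack(
            [
                rng.normal(0.0, math.sqrt(pop.omega2_cl), size=K),
                rng.normal(0.0, math.sqrt(pop.omega2_v), size=K),
            ]
        )
        f = subject_predictions(pop, s, etas)  # (K, n)
        eps1 = rng.normal(0.0, math.sqrt(pop.sigma2_prop), size=(K, n))
        sims = f * (1.0 + eps1)
        if pop.sigma2_add > 0:
            sims = sims + rng.normal(0.0, math.sqrt(pop.sigma2_add), size=(K, n))

        m = sims.mean(axis=0)
        if n > 1:
            V = np.cov(sims, rowvar=False)
            try:
                L = np.linalg.cholesky(V)
                y_star = np.linalg.solve(L, dv - m)
                s_star = np.linalg.solve(L, (sims - m).T).T
            except np.linalg.LinAlgError:
                warnings.warn(
                    f"subject {s.id}: singular simulated covariance, "
                    "falling back to uncorrelated prediction discrepancies",
                    stacklevel=2,
                )
                sd = sims.std(axis=0, ddof=1)
                y_star = (dv - m) / sd
                s_star = (sims - m) / sd
        else:
            sd = sims.std(axis=0, ddof=1)
            y_star = (dv - m) / sd
            s_star = (sims - m) / sd

        counts = np.sum(s_star < y_star[None, :], axis=0)
        pde = (counts + 0.5) / K
        pde = np.clip(pde, 1.0 / (2 * K), 1.0 - 1.0 / (2 * K))
        vals = stats.norm.ppf(pde)
        for o, v in zip(s.observations, vals):
            rows.append(dict(id=s.id, time=o.time, tad=o.tad, dv=o.dv, npde=v))

    table = pd.DataFrame(rows)
    x = table["npde"].to_numpy()
    N = x.size
    p_mean = float(stats.ttest_1samp(x, 0.0).pvalue)
    chi2 = (N - 1) * np.var(x, ddof=1)
    p_var = float(2 * min(stats.chi2.cdf(chi2, N - 1), stats.chi2.sf(chi2, N - 1)))
    p_normal = float(stats.shapiro(x).pvalue) if N <= 5000 else float(
        stats.normaltest(x).pvalue
    )
    alpha = GLOBAL_ALPHA / 3
    passed = p_mean > alpha and p_var > alpha and p_normal > alpha
    return NpdeResult(
        table=table, K=K, seed=seed,
        p_mean=p_mean, p_var=p_var, p_normal=p_normal, passed=passed,
    )


def render_diagnostics(
    out_dir,
    gof: pd.DataFrame | None = None,
    npde_result: NpdeResult | None = None,
    fmt: str = "png",
) -> list[Path]:
    """Write the standard diagnostic figures; returns the created paths.

    GOF input yields DV-vs-IPRED, DV-vs-PRED, CWRES-vs-PRED and
    CWRES-vs-TAD; an NPDE result yields a histogram and a Q-Q plot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if (gof is None or gof.empty) and (npde_result is None or npde_result.table.empty):
        raise ValueError("nothing to plot: empty diagnostic input")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    def scatter(x, y, xlab, ylab, name, identity=False, zero=False):
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.scatter(x, y, s=14, alpha=0.7, edgecolor="none")
        if identity:
            lim = [0, max(float(np.max(x)), float(np.max(y))) * 1.05]
            ax.plot(lim, lim, "k--", lw=1)
            ax.set_xlim(lim)
            ax.set_ylim(lim)
        if zero:
            ax.axhline(0.0, color="k", ls="--", lw=1)
            ax.axhline(2.0, color="0.6", ls=":", lw=1)
            ax.axhline(-2.0, color="0.6", ls=":", lw=1)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        fig.tight_layout()
        p = out_dir / f"{name}.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    if gof is not None and not gof.empty:
        scatter(gof["ipred"], gof["dv"], "IPRED (ug/L)", "DV (ug/L)", "dv_vs_ipred", identity=True)
        scatter(gof["pred"], gof["dv"], "PRED (ug/L)", "DV (ug/L)", "dv_vs_pred", identity=True)
        scatter(gof["pred"], gof["cwres"], "PRED (ug/L)", "CWRES", "cwres_vs_pred", zero=True)
        scatter(gof["tad"], gof["cwres"], "TAD (h)", "CWRES", "cwres_vs_tad", zero=True)

    if npde_result is not None and not npde_result.table.empty:
        x = npde_result.npde
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.hist(x, bins=max(10, int(np.sqrt(x.size))), density=True, alpha=0.7)
        grid = np.linspace(-4, 4, 200)
        ax.plot(grid, stats.norm.pdf(grid), "k-", lw=1)
        ax.set_xlabel("NPDE")
        ax.set_ylabel("density")
        fig.tight_layout()
        p = out_dir / f"npde_hist.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

        fig, ax = plt.subplots(figsize=(4.5, 4))
        stats.probplot(x, dist="norm", plot=ax)
        ax.set_title("")
        fig.tight_layout()
        p = out_dir / f"npde_qq.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    return paths
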