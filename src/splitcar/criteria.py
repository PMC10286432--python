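"""Model comparison: DIC, WAIC and forward stepwise covariate selection.

Both criteria are defined on the Gaussian observation model of the fitted
summaries (only observed areas enter the deviance), with the linear
predictor ``eta`` as the focus parameter.  Because the per-grid-point
posteriors are Gaussian, every expectation has a closed form in the mixture
moments; a seeded Monte Carlo path is provided as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "gaussian_dic",
    "gaussian_waic",
    "dic",
    "waic",
    "ComparisonReport",
    "compare",
    "stepwise_select",
]

_LOG2PI = math.log(2.0 * math.pi)


def _mixture_moments(eta_mean, eta_sd, weights):
    m = weights @ eta_mean
    second = weights @ (eta_sd**2 + eta_mean**2)
    return m, second - m**2


def gaussian_dic(y, var, eta_mean, eta_sd, weights) -> tuple[float, float]:
    """DIC for Gaussian observations, closed form in the mixture moments.

    ``D(eta) = -2 sum_j log N(y_j; eta_j, var_j)``; ``p_dic = E[D] - D(E[eta])``
    equals ``sum_j Var[eta_j]/var_j``; ``dic = D(E[eta]) + 2 p_dic``.
    """
    y = np.asarray(y, dtype=float)
    var = np.asarray(var, dtype=float)
    if y.size == 0:
        raise ValueError("DIC undefined with no observed areas")
    m, s2 = _mixture_moments(np.atleast_2d(eta_mean), np.atleast_2d(eta_sd), np.asarray(weights))
    d_at_mean = float(np.sum(np.log(2.0 * np.pi * var) + (y - m) ** 2 / var))
    p_dic = float(np.sum(s2 / var))
    return d_at_mean + 2.0 * p_dic, p_dic


def gaussian_waic(y, var, eta_mean, eta_sd, weights) -> tuple[float, float]:
    """WAIC for Gaussian observations, closed form per mixture component.

    ``lppd_j = log E[N(y_j; eta_j, var_j)]`` uses the exact convolution
    ``N(y_j; m_g, var_j + s_g^2)`` per component; the pointwise variance of
    the log-density uses the Gaussian fourth-moment identities.
    """
    y = np.asarray(y, dtype=float)
    var = np.asarray(var, dtype=float)
    if y.size == 0:
        raise ValueError("WAIC undefined with no observed areas")
    m = np.atleast_2d(eta_mean)          # (G, n)
    s2 = np.atleast_2d(eta_sd) ** 2
    w = np.asarray(weights, dtype=float)

    # lppd: mixture of Gaussian convolutions
    tot = var[None, :] + s2
    comp_log = -0.5 * (np.log(2.0 * np.pi * tot) + (y[None, :] - m) ** 2 / tot)
    cmax = comp_log.max(axis=0)
    lppd = float(np.sum(cmax + np.log(np.einsum("g,gj->j", w, np.exp(comp_log - cmax)))))

    # p_waic: Var[log N(y; eta, var)] = Var[(y-eta)^2] / (4 var^2) mixture-wide
    q1 = (y[None, :] - m) ** 2 + s2                       # E_g[(y-eta)^2]
    var_g = 4.0 * (y[None, :] - m) ** 2 * s2 + 2.0 * s2**2  # Var_g[(y-eta)^2]
    e_q = np.einsum("g,gj->j", w, q1)
    e_q2 = np.einsum("g,gj->j", w, var_g + q1**2)
    var_q = np.maximum(e_q2 - e_q**2, 0.0)
    p_waic = float(np.sum(var_q / (4.0 * var**2)))
    return -2.0 * (lppd - p_waic), p_waic


def _mc_eta(fit, n_draws, seed):
    y, var, eta_mean, eta_sd, w = fit.observed_eta_moments()
    rng = np.random.default_rng(seed)
    g = rng.choice(len(w), size=n_draws, p=w)
    z = rng.standard_normal((n_draws, eta_mean.shape[1]))
    return y, var, eta_mean[g] + eta_sd[g] * z


def dic(fit, method: str = "exact", n_draws: int = 5000, seed: int = 20150101):
    """(dic, p_dic) of a fit; ``method='mc'`` uses seeded posterior draws."""
    if method == "exact":
        return gaussian_dic(*fit.observed_eta_moments())
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    y, var, eta = _mc_eta(fit, n_draws, seed)
    dev = np.sum(np.log(2.0 * np.pi * var)[None, :] + (y[None, :] - eta) ** 2 / var[None, :], axis=1)
    m = eta.mean(axis=0)
    d_at_mean = float(np.sum(np.log(2.0 * np.pi * var) + (y - m) ** 2 / var))
    p_dic = float(dev.mean() - d_at_mean)
    return d_at_mean + 2.0 * p_dic, p_dic


def waic(fit, method: str = "exact", n_draws: int = 5000, seed: int = 20150101):
    """(waic, p_waic) of a fit; ``method='mc'`` uses seeded posterior draws."""
    if method == "exact":
        return gaussian_waic(*fit.observed_eta_moments())
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    y, var, eta = _mc_eta(fit, n_draws, seed)
    logdens = -0.5 * (np.log(2.0 * np.pi * var)[None, :] + (y[None, :] - eta) ** 2 / var[None, :])
    cmax = logdens.max(axis=0)
    lppd = float(np.sum(cmax + np.log(np.exp(logdens - cmax).mean(axis=0))))
    p_waic = float(np.sum(logdens.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


@dataclass
class ComparisonReport:
    """Table of per-model criteria with the DIC-selected model."""

    table: pd.DataFrame
    selected_model: str

    def __str__(self):
        cols = ["dic", "p_dic", "waic", "p_waic", "delta_dic"]
        lines = [f"{'model':<28}" + "".join(f"{c:>12}" for c in cols)]
        for label, row in self.table.iterrows():
            mark = " *" if label == self.selected_model else ""
            lines.append(
                f"{str(label):<28}"
                + "".join(f"{row[c]:>12.2f}" for c in cols)
                + mark
            )
        return "\n".join(lines)

    def to_csv(self, path):
        self.table.to_csv(path, index_label="model")


def compare(fits: dict) -> ComparisonReport:
    """DIC/WAIC comparison of fitted models; lower DIC wins."""
    rows = []
    for label, fit in fits.items():
        d, p_d = dic(fit)
        w, p_w = waic(fit)
        rows.append({"model": label, "dic": d, "p_dic": p_d, "waic": w, "p_waic": p_w})
    tab = pd.DataFrame(rows).set_index("model")
    tab["delta_dic"] = tab["dic"] - tab["dic"].min()
    return ComparisonReport(table=tab, selected_model=tab["dic"].idxmin())


def stepwise_select(
    base_spec,
    graph,
    summaries,
    covariate_table: pd.DataFrame,
    candidates=None,
    include_interactions: bool = True,
    threshold: float = 0.0,
    fit_kwargs: dict | None = None,
):
    """Forward stepwise covariate selection by DIC.

    Each round fits the current model plus every remaining candidate (and,
    optionally, its covariate-by-region interaction) and accepts the single
    addition with the largest DIC decrease if it exceeds ``threshold``
    (default: any improvement); rounds repeat until no candidate improves.
    Returns ``(report, best_fit)`` where the report lists every fit tried.
    """
    from .infer import fit_model

    fit_kwargs = fit_kwargs or {}
    if candidates is None:
        candidates = list(covariate_table.columns)
    terms = []
    for c in candidates:
        terms.append(c)
        if include_interactions and graph.n_components > 1:
            terms.append(f"{c}:region")

    current = base_spec
    best_fit = fit_model(current, graph, summaries, covariate_table, **fit_kwargs)
    best_dic = dic(best_fit)[0]
    best_label = "base"
    rows = [_report_row("base", best_fit)]
    remaining = list(terms)
    rnd = 0
    while remaining:
        rnd += 1
        scores = []
        for term in remaining:
            spec_t = current.with_covariates(current.covariates + (term,))
            fit_t = fit_model(spec_t, graph, summaries, covariate_table, **fit_kwargs)
            d = dic(fit_t)[0]
            label_t = f"round{rnd}:+{term}"
            rows.append(_report_row(label_t, fit_t))
            scores.append((d, term, label_t, spec_t, fit_t))
        d_best, term_best, label_b, spec_best, fit_best = min(scores, key=lambda t: t[0])
        if best_dic - d_best > threshold:
            current, best_fit, best_dic, best_label = spec_best, fit_best, d_best, label_b
            base = term_best.split(":")[0]
            remaining = [t for t in remaining if t.split(":")[0] != base]
        else:
            break
    tab = pd.DataFrame(rows).set_index("model")
    tab["delta_dic"] = tab["dic"] - tab["dic"].min()
    return ComparisonReport(table=tab, selected_model=best_label), best_fit


def _report_row(label, fit):
    d, p_d = dic(fit)
    w, p_w = waic(fit)
    return {"model": label, "dic": d, "p_dic": p_d, "waic": w, "p_waic": p_w}
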