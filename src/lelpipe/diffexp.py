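"""Paired differential expression with empirical-Bayes variance moderation.

The paired design (each subject measured once per condition) is analysed
on within-subject log2 differences: for probe g the effect estimate is
the mean difference (logFC), the residual variance is the sample variance
of the differences (df = n_subjects - 1), and the per-probe variances are
shrunk toward a global scaled inverse-chi-square prior (d0, s0^2)
estimated by moment matching on log s^2.  The moderated t statistic

    t_g = logFC_g / sqrt(s_tilde_g^2 / n),
    s_tilde_g^2 = (d0 s0^2 + df s_g^2) / (d0 + df)

is referred to a t distribution on d0 + df degrees of freedom (normal in
the d0 = infinity limit).  Raw p-values are corrected by the
Benjamini-Hochberg step-up procedure and differential probes selected by
the adjusted-p and absolute-log2-fold-change cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionDataset

__all__ = [
    "VariancePrior",
    "SelectionThresholds",
    "fit_linear_paired",
    "fit_variance_prior",
    "moderated_t",
    "bh_adjust",
    "select_de",
    "de_table",
]

_P_FLOOR = 1e-300  # avoid exact zeros in downstream log reporting


class DesignError(ValueError):
    """The sample sheet does not describe a complete paired design."""


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior on residual variances.

    ``d0`` is the prior degrees of freedom (``inf`` when the observed
    log-variances show no excess dispersion) and ``s0_sq`` the prior
    variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


@dataclass(frozen=True)
class SelectionThresholds:
    """Cutoffs defining the differential list: adjusted p and |log2 FC|."""

    adj_p_cut: float = 0.01
    abs_lfc_cut: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.adj_p_cut <= 1.0:
            raise ValueError("adj_p_cut must lie in (0, 1]")
        if self.abs_lfc_cut < 0:
            raise ValueError("abs_lfc_cut must be >= 0")


def fit_linear_paired(normalized: ExpressionDataset) -> pd.DataFrame:
    """Per-probe paired effect estimates.

    Returns a DataFrame indexed by probe_id with columns ``logFC`` (mean
    within-subject treated - reference difference), ``s2`` (sample
    variance of the differences, ddof=1), ``df_resid`` and the unit
    variance scale ``v`` = 1/n_subjects.
    """
    sheet = normalized.sample_sheet
    subjects = list(dict.fromkeys(sheet["subject_id"]))
    if len(subjects) < 2:
        raise DesignError("paired analysis needs at least 2 subjects")
    cols_by = {}
    for subject in subjects:
        sub = sheet[sheet["subject_id"] == subject]
        for cond in ("reference", "treated"):
            match = sub.loc[sub["condition"] == cond, "sample_id"]
            if len(match) != 1:
                raise DesignError(
                    f"subject {subject!r} lacks exactly one {cond} sample"
                )
            cols_by[(subject, cond)] = match.iloc[0]
    mat = normalized.intensities
    diffs = np.column_stack([
        mat[cols_by[(s, "treated")]].to_numpy()
        - mat[cols_by[(s, "reference")]].to_numpy()
        for s in subjects
    ])
    n = len(subjects)
    out = pd.DataFrame(
        {
            "logFC": diffs.mean(axis=1),
            "s2": diffs.var(axis=1, ddof=1),
            "df_resid": n - 1,
            "v": 1.0 / n,
        },
        index=mat.index,
    )
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (monotone Newton iteration)."""
    if x <= 0:
        return np.inf
    # trigamma(y) ~ 1/y + 1/(2y^2); start from the 1/y asymptote
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(polygamma(1, y))
        delta = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df_resid: int) -> VariancePrior:
    """Moment-match (d0, s0^2) on the log residual variances.

    Under s^2 ~ s0^2 F(df, d0), z = log s^2 satisfies
    E z = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2) and
    Var z = psi'(df/2) + psi'(d0/2).  The excess of the empirical
    variance of z over psi'(df/2) determines d0; non-positive excess
    means no dispersion beyond sampling noise and d0 = infinity.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValueError("need at least 10 finite positive variances")
    df = float(df_resid)
    if np.ptp(s2) == 0:
        # exactly constant variances: no dispersion at all, the common
        # value is the prior
        return VariancePrior(d0=np.inf, s0_sq=float(s2[0]))
    z = np.log(s2)
    e = z - float(polygamma(0, df / 2)) + np.log(df / 2)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2))
    if evar <= 0:
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(np.mean(e))))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(np.mean(e) + float(polygamma(0, half_d0)) - np.log(half_d0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    logFC: np.ndarray,
    s2: np.ndarray,
    df_resid: int,
    prior: VariancePrior,
    v: float,
) -> pd.DataFrame:
    """Moderated t statistics, two-sided p-values and total df.

    Returns a DataFrame with columns ``t``, ``p``, ``df_total`` and an
    ``underflow`` flag for probes whose posterior variance is exactly
    zero (t reported as signed infinity with p = 0).
    """
    logFC = np.asarray(logFC, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = float(df_resid)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    underflow = s2_post == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logFC / np.sqrt(s2_post * v)
    t[underflow & (logFC > 0)] = np.inf
    t[underflow & (logFC < 0)] = -np.inf
    t[underflow & (logFC == 0)] = 0.0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[underflow & (logFC != 0)] = 0.0
    return pd.DataFrame(
        {"t": t, "p": p, "df_total": df_total, "underflow": underflow}
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(np.maximum(p, _P_FLOOR), method="fdr_bh")[1]


def de_table(normalized: ExpressionDataset) -> pd.DataFrame:
    """Full paired moderated-t analysis of a normalized dataset.

    Convenience wrapper: paired fit, variance-prior estimation,
    moderated t and BH adjustment, returning one row per probe with
    columns probe_id (index), gene, logFC, s2, df_resid, t, p, adj_p,
    df_total.
    """
    fit = fit_linear_paired(normalized)
    df_resid = int(fit["df_resid"].iloc[0])
    prior = fit_variance_prior(fit["s2"].to_numpy(), df_resid)
    mod = moderated_t(
        fit["logFC"].to_numpy(), fit["s2"].to_numpy(), df_resid, prior,
        float(fit["v"].iloc[0]),
    )
    out = fit.copy()
    out["gene"] = normalized.probe_annotation.reindex(out.index)
    out["t"] = mod["t"].to_numpy()
    out["p"] = mod["p"].to_numpy()
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["df_total"] = mod["df_total"].to_numpy()
    return out[["gene", "logFC", "s2", "df_resid", "t", "p", "adj_p", "df_total"]]


def select_de(
    results: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
    collapse_genes: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DE table into up- and down-regulated lists.

    Up: adj_p < cut and logFC >= abs_lfc_cut; down: adj_p < cut and
    logFC <= -abs_lfc_cut.  Selection is probe-level (duplicate gene
    symbols retained); with ``collapse_genes`` each symbol keeps its
    best-adjusted-p probe only.
    """
    if results.empty:
        return results.copy(), results.copy()
    sig = results["adj_p"] < thresholds.adj_p_cut
    up = results[sig & (results["logFC"] >= thresholds.abs_lfc_cut)]
    down = results[sig & (results["logFC"] <= -thresholds.abs_lfc_cut)]
    if collapse_genes:
        up = up.sort_values("adj_p").drop_duplicates(subset="gene")
        down = down.sort_values("adj_p").drop_duplicates(subset="gene")
    return (
        up.sort_values("logFC", ascending=False),
        down.sort_values("logFC"),
    )
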