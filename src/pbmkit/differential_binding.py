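"""Binding and differential-binding calls with an empirical-Bayes moderated t.

Each sequence's binding values across slides are summarized by ordinary least
squares (a one-group mean tested against zero, or a two-group difference of
means with pooled variance).  Per-sequence residual variances s2 are then
shrunk toward a prior s0^2 estimated across all sequences:

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)

with the prior degrees of freedom d0 and prior variance s0^2 obtained by
moment matching of log s2 against a scaled F distribution (the hierarchical
model s2 | sigma2 ~ sigma2 * chi2_df / df, sigma2 ~ s0^2 * d0 / chi2_d0).
The moderated statistic t = effect / (sqrt(s2_post) * c) is referred to a t
distribution with df + d0 degrees of freedom, and p-values are adjusted by
the Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError

__all__ = [
    "DesignSpec",
    "ModerationModel",
    "fit_group_model",
    "moderate_variances",
    "moderated_t_test",
    "bh_adjust",
    "select_bound",
    "select_differential",
    "differential_pipeline",
]


@dataclass(frozen=True)
class DesignSpec:
    """Slide-to-group assignment and the contrast to test.

    ``contrast=None`` requests the one-group test of mean M against zero
    (binding call); ``contrast=(g1, g2)`` tests g1 - g2 (differential call).
    Each tested group needs at least 2 slides for variance estimation.
    """

    groups: tuple[str, ...]
    contrast: tuple[str, str] | None = None

    @property
    def is_two_group(self) -> bool:
        return self.contrast is not None

    def validate(self, n_slides: int) -> None:
        if len(self.groups) != n_slides:
            raise ContractError(
                f"design lists {len(self.groups)} slides, matrix has {n_slides}"
            )
        labels = pd.Series(self.groups)
        if self.contrast is None:
            if n_slides < 2:
                raise ContractError("one-group test needs >= 2 slides")
            return
        g1, g2 = self.contrast
        for g in (g1, g2):
            if (labels == g).sum() < 2:
                raise ContractError(
                    f"group '{g}' has fewer than 2 slides; variance not estimable"
                )


@dataclass(frozen=True)
class ModerationModel:
    """Empirical-Bayes prior for the per-sequence variances.

    d0 is the prior degrees of freedom (``inf`` collapses every posterior
    variance to s0_sq; 0 disables moderation), s0_sq the prior variance.
    """

    d0: float
    s0_sq: float
    method: str = "moment-matching on log s2"

    def posterior(self, s2: np.ndarray, df: np.ndarray) -> np.ndarray:
        s2 = np.asarray(s2, dtype=float)
        df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
        if math.isinf(self.d0):
            return np.full_like(s2, self.s0_sq)
        if self.d0 == 0:
            return s2.copy()
        return (self.d0 * self.s0_sq + df * s2) / (self.d0 + df)


def fit_group_model(matrix: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Per-sequence OLS summaries of a binding matrix (sequences x slides).

    Returns a frame indexed like ``matrix`` with columns ``effect`` (group
    mean, or difference of group means), ``A`` (mean binding level over tested
    slides), ``s2`` (residual variance), ``df`` and ``c`` (the standard-error
    multiplier of the effect).  Rows with missing values in tested slides are
    excluded; the count is reported via a warning.
    """
    design.validate(matrix.shape[1])
    labels = np.asarray(design.groups)
    if design.contrast is None:
        cols = np.ones(matrix.shape[1], dtype=bool)
    else:
        cols = (labels == design.contrast[0]) | (labels == design.contrast[1])
    sub = matrix.loc[:, cols]
    sub_labels = labels[cols]
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        warnings.warn(
            f"excluding {int((~complete).sum())} sequences with missing values",
            stacklevel=2,
        )
    sub = sub.loc[complete]
    X = sub.to_numpy(dtype=float)

    if design.contrast is None:
        n = X.shape[1]
        effect = X.mean(axis=1)
        s2 = X.var(axis=1, ddof=1)
        df = n - 1
        c = 1.0 / math.sqrt(n)
        A = effect.copy()
    else:
        g1, g2 = design.contrast
        m1 = sub_labels == g1
        m2 = sub_labels == g2
        n1, n2 = int(m1.sum()), int(m2.sum())
        mean1 = X[:, m1].mean(axis=1)
        mean2 = X[:, m2].mean(axis=1)
        effect = mean1 - mean2
        v1 = X[:, m1].var(axis=1, ddof=1)
        v2 = X[:, m2].var(axis=1, ddof=1)
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        c = math.sqrt(1.0 / n1 + 1.0 / n2)
        A = X.mean(axis=1)

    return pd.DataFrame(
        {"effect": effect, "A": A, "s2": s2, "df": float(df), "c": c},
        index=sub.index,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def moderate_variances(
    s2: np.ndarray,
    df: float | np.ndarray,
    prior_df: float | None = None,
) -> tuple[ModerationModel, np.ndarray]:
    """Estimate the variance prior and return posterior (shrunk) variances.

    Hyperparameters are estimated by matching the first two moments of
    log s2 to those implied by s2 / s0^2 ~ F(df, d0): with
    e = log s2 - digamma(df/2) + log(df/2),

        var(e)  = trigamma(df/2) + trigamma(d0/2)
        mean(e) = log s0^2 + digamma(d0/2) - log(d0/2).

    ``prior_df`` forces d0 (0 disables moderation, ``inf`` shrinks fully);
    when all s2 are equal there is no spread to shrink and a d0 = inf model
    with s0^2 = s2 is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if prior_df is not None:
        if prior_df == 0:
            model = ModerationModel(0.0, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0)
            return model, model.posterior(s2, df_arr)
        if math.isinf(prior_df):
            s0 = float(np.exp(np.mean(np.log(s2[s2 > 0]))))
            model = ModerationModel(math.inf, s0)
            return model, model.posterior(s2, df_arr)

    if s2.size >= 2 and np.allclose(s2, s2.flat[0], rtol=1e-12, atol=1e-300):
        # degenerate: no spread to shrink (includes the all-zero case)
        model = ModerationModel(
            math.inf, float(s2.flat[0]), method="degenerate (all s2 equal)"
        )
        return model, model.posterior(s2, df_arr)

    ok = (s2 > 0) & np.isfinite(s2) & (df_arr >= 1)
    n_ok = int(ok.sum())
    if n_ok < 2:
        raise ContractError("variance moderation needs >= 2 positive variances")
    if n_ok < 50:
        warnings.warn(
            f"only {n_ok} variances available; hyperparameter estimates may be "
            "unstable (>= 50 recommended)",
            stacklevel=2,
        )
    s2_ok = s2[ok]
    df_ok = df_arr[ok]
    z = np.log(s2_ok)
    e = z - special.digamma(df_ok / 2.0) + np.log(df_ok / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    rhs = e_var - float(np.mean(special.polygamma(1, df_ok / 2.0)))
    if prior_df is not None:
        d0 = float(prior_df)
    elif rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
    else:
        d0 = math.inf
    if math.isinf(d0):
        s0_sq = float(np.exp(e_mean))
    else:
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    model = ModerationModel(d0, s0_sq)
    return model, model.posterior(s2, df_arr)


def moderated_t_test(
    fit: pd.DataFrame, model: ModerationModel, adjust: bool = True
) -> pd.DataFrame:
    """Moderated t statistics, two-sided p-values and BH-adjusted q-values.

    Sequences with zero posterior variance and zero effect are assigned
    t = 0, p = 1 (no evidence either way, not NaN).
    """
    s2_post = model.posterior(fit["s2"].to_numpy(), fit["df"].to_numpy())
    se = np.sqrt(s2_post) * fit["c"].to_numpy()
    effect = fit["effect"].to_numpy()
    t = np.zeros_like(effect)
    nonzero_se = se > 0
    t[nonzero_se] = effect[nonzero_se] / se[nonzero_se]
    t[~nonzero_se & (effect != 0)] = np.sign(effect[~nonzero_se & (effect != 0)]) * np.inf

    df_total = fit["df"].to_numpy() + model.d0
    p = np.empty_like(effect)
    finite_df = np.isfinite(df_total)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
    p = np.clip(p, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "effect": fit["effect"],
            "A": fit["A"],
            "s2": fit["s2"],
            "s2_post": s2_post,
            "t_mod": t,
            "df_total": df_total,
            "p": p,
        },
        index=fit.index,
    )
    out["q"] = bh_adjust(p) if adjust else p
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ContractError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_bound(
    records: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = True
) -> set[str]:
    """Sequences significantly bound: positive effect, significance < alpha.

    Binding is directional — the protein signal must exceed the DNA baseline —
    so only positive effects are selected after the two-sided test.  By
    default significance is judged on BH-adjusted values (~6000 simultaneous
    tests); ``use_adjusted=False`` switches to raw p-values.
    """
    sig = records["q"] if use_adjusted else records["p"]
    mask = (records["effect"] > 0) & (sig < alpha)
    return set(records.index[mask])


def select_differential(
    records: pd.DataFrame,
    m_cutoff: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> tuple[set[str], set[str]]:
    """Differentially bound sequences by effect size and significance.

    Selection requires |effect| > ``m_cutoff`` (default 1 log2 unit, i.e. a
    2-fold difference between groups) *and* significance below ``alpha``.
    Also returns the |effect|-only superset used for MA-plot rendering.
    """
    if "effect" not in records or "q" not in records:
        raise ContractError("records must come from moderated_t_test")
    fold_only = set(records.index[records["effect"].abs() > m_cutoff])
    sig = records["q"] if use_adjusted else records["p"]
    selected = set(
        records.index[(records["effect"].abs() > m_cutoff) & (sig < alpha)]
    )
    return selected, fold_only


def differential_pipeline(
    matrix: pd.DataFrame,
    design: DesignSpec,
    prior_df: float | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Convenience chain: fit -> moderate -> test on a binding matrix."""
    fit = fit_group_model(matrix, design)
    model, _ = moderate_variances(fit["s2"].to_numpy(), fit["df"].to_numpy(), prior_df=prior_df)
    return moderated_t_test(fit, model, adjust=adjust)
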