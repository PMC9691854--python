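"""Factorial statistics for the behavioral and electrophysiology readouts.

The study design is a 2 x 2 between-subjects factorial (sex x genotype,
unbalanced: n = 18/19/10/11) with session day as a repeated (within-subject)
factor in the learning tasks. This module provides the matching classical
tests in a statsmodels-style Model/Results idiom:

* :class:`FactorialAnova` — two-way between-subjects ANOVA with Type III
  sums of squares (sum-to-zero contrasts; Type II by flag), or, when a
  within factor and subject column are given, a two-way mixed
  repeated-measures ANOVA with Greenhouse-Geisser sphericity correction of
  the within-factor degrees of freedom (reported fractionally, e.g.
  F(1.87, 65.45)).
* Sidak-adjusted pairwise comparisons on a caller-chosen contrast family
  (family size is never inferred silently) and Tukey HSD over all group
  pairs, both using the pooled error term.

The between-subjects ANOVA delegates to statsmodels OLS; the mixed
repeated-measures ANOVA is computed from the classical split-plot sums of
squares so the epsilon-corrected degrees of freedom are under direct
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# adjustment helpers
# ---------------------------------------------------------------------------


def sidak_adjust(p_values: Sequence[float] | float, m: int | None = None) -> np.ndarray | float:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m.

    ``m`` defaults to the number of p-values supplied; it is the size of the
    comparison family and must be chosen by the caller when the family is
    larger than the p-values at hand.
    """
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    adj = np.clip(1.0 - np.power(1.0 - p, m), 0.0, 1.0)
    return float(adj[0]) if scalar else adj


def gg_epsilon(wide: np.ndarray, group_labels: Sequence | None = None) -> float:
    """Greenhouse-Geisser epsilon-hat from a subjects x levels score matrix.

    The covariance of the within-subject scores is pooled within groups when
    ``group_labels`` is given (mixed design). epsilon = 1 exactly for two
    levels and is bounded below by 1/(k-1).
    """
    x = np.asarray(wide, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least two within-factor levels")
    if group_labels is None:
        centered = x - x.mean(axis=0)
        dof = n - 1
    else:
        labels = np.asarray(group_labels)
        centered = np.empty_like(x)
        dof = 0
        for g in np.unique(labels):
            mask = labels == g
            centered[mask] = x[mask] - x[mask].mean(axis=0)
            dof += mask.sum() - 1
    S = centered.T @ centered / dof
    # orthonormal contrasts spanning the within-factor differences
    C = np.linalg.qr(np.eye(k) - 1.0 / k, mode="complete")[0][:, : k - 1].T
    M = C @ S @ C.T
    eps = np.trace(M) ** 2 / ((k - 1) * np.trace(M @ M))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class AnovaResults:
    """Fitted factorial ANOVA: effect table, epsilon, and post-hoc access.

    ``table`` has one row per effect with columns ``effect, ss, df1, df2, F,
    p``; for sphericity-corrected within effects ``df1``/``df2`` are the
    epsilon-multiplied (fractional) degrees of freedom.
    """

    table: pd.DataFrame
    model: "FactorialAnova"
    epsilon: float | None = None
    residual_ms: float | None = None
    residual_df: float | None = None

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return hit.iloc[0]

    def p_value(self, name: str) -> float:
        return float(self.effect(name)["p"])

    def pairwise(
        self,
        method: str = "sidak",
        factor: str | Sequence[str] | None = None,
        pairs: Sequence[tuple] | None = None,
        family_size: int | None = None,
    ) -> pd.DataFrame:
        """Adjusted pairwise comparisons between group cells.

        ``factor`` selects the grouping (default: all between factors
        crossed). For ``sidak`` the family is the requested ``pairs`` (all
        pairs when omitted) and ``family_size`` may enlarge it explicitly;
        ``tukey`` always spans all group pairs.
        """
        data, dv = self.model.data, self.model.dv
        if factor is None:
            factor = self.model.between
        if isinstance(factor, str):
            groups = data[factor].astype(str)
        else:
            groups = data[list(factor)].astype(str).agg(":".join, axis=1)
        if method == "tukey":
            return tukey_pairwise(data[dv].to_numpy(), groups.to_numpy())
        if method == "sidak":
            return pairwise_sidak(
                data[dv].to_numpy(), groups.to_numpy(), pairs=pairs, family_size=family_size
            )
        raise ValueError(f"unknown post-hoc method {method!r}")

    def summary(self) -> str:
        lines = [
            "Factorial ANOVA"
            + (
                "  (repeated measures, Greenhouse-Geisser corrected)"
                if self.epsilon is not None
                else "  (between subjects, Type %s SS)" % self.model.ss_type
            ),
            f"dv: {self.model.dv}   n obs: {len(self.model.data)}",
        ]
        if self.epsilon is not None:
            lines.append(f"epsilon-hat (GG): {self.epsilon:.4f}")
        lines.append("")
        lines.append(f"{'effect':<28}{'F':>10}{'df1':>10}{'df2':>10}{'p':>12}")
        for _, row in self.table.iterrows():
            lines.append(
                f"{row['effect']:<28}{row['F']:>10.4g}{row['df1']:>10.4f}"
                f"{row['df2']:>10.4f}{row['p']:>12.4g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class FactorialAnova:
    """Two-way factorial ANOVA model over a tidy data frame.

    Parameters
    ----------
    data : tidy DataFrame, one row per observation.
    dv : response column.
    between : one or two between-subject factor columns (e.g. ["sex",
        "genotype"]).
    within : optional within-subject factor column (e.g. "day"); requires
        ``subject``. Each subject must be observed at every within level;
        incomplete subjects are dropped listwise.
    subject : subject-identifier column for repeated measures.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        between: str | Sequence[str],
        within: str | None = None,
        subject: str | None = None,
    ) -> None:
        self.between = [between] if isinstance(between, str) else list(between)
        self.within = within
        self.subject = subject
        self.dv = dv
        self.ss_type = 3
        cols = [dv, *self.between] + ([within] if within else []) + (
            [subject] if subject else []
        )
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        data = data.dropna(subset=[dv]).copy()
        if within is not None:
            if subject is None:
                raise ValueError("repeated measures require a subject column")
            if len(self.between) != 1:
                raise ValueError("mixed design supports one between factor")
            k = data[within].nunique()
            counts = data.groupby(subject)[within].nunique()
            keep = counts[counts == k].index
            data = data[data[subject].isin(keep)]
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, dv: str, **kwargs) -> "FactorialAnova":
        return cls(data, dv, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self, ss_type: int = 3, gg: str = "always") -> AnovaResults:
        """Fit and return :class:`AnovaResults`.

        ``ss_type`` (2 or 3) applies to the between-subjects design;
        ``gg`` ∈ {"always", "never"} controls the Greenhouse-Geisser
        correction of within-factor degrees of freedom in the mixed design.
        """
        self.ss_type = ss_type
        if self.within is None:
            return self._fit_between(ss_type)
        return self._fit_mixed(gg)

    def _fit_between(self, ss_type: int) -> AnovaResults:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        if len(self.between) not in (1, 2):
            raise ValueError("between-subjects design supports one or two factors")
        df = self.data.rename(columns={self.dv: "_y"})
        for f in self.between:
            if df[f].nunique() < 2:
                raise ValueError(f"factor {f!r} needs at least two levels")
        cells = df.groupby(self.between).size()
        if len(self.between) == 2:
            a, b = self.between
            expected = df[a].nunique() * df[b].nunique()
            if len(cells) < expected or (cells < 1).any():
                raise ValueError("every factorial cell needs at least one observation")
            formula = f"_y ~ C({a}, Sum) * C({b}, Sum)"
        else:
            formula = f"_y ~ C({self.between[0]}, Sum)"
        model = smf.ols(formula, data=df).fit()
        if model.df_resid <= 0:
            raise ValueError("zero residual degrees of freedom")
        aov = sm.stats.anova_lm(model, typ=ss_type)
        rows = []
        resid_df = float(aov.loc["Residual", "df"])
        resid_ss = float(aov.loc["Residual", "sum_sq"])
        name_map = {}
        if len(self.between) == 2:
            a, b = self.between
            name_map = {
                f"C({a}, Sum)": a,
                f"C({b}, Sum)": b,
                f"C({a}, Sum):C({b}, Sum)": f"{a} x {b}",
            }
        else:
            name_map = {f"C({self.between[0]}, Sum)": self.between[0]}
        for raw, pretty in name_map.items():
            if raw not in aov.index:
                continue
            ss = float(aov.loc[raw, "sum_sq"])
            df1 = float(aov.loc[raw, "df"])
            F = float(aov.loc[raw, "F"])
            p = float(aov.loc[raw, "PR(>F)"])
            rows.append(
                {"effect": pretty, "ss": ss, "df1": df1, "df2": resid_df, "F": F, "p": p}
            )
        table = pd.DataFrame(rows)
        return AnovaResults(
            table=table,
            model=self,
            epsilon=None,
            residual_ms=resid_ss / resid_df,
            residual_df=resid_df,
        )

    def _fit_mixed(self, gg: str) -> AnovaResults:
        if gg not in ("always", "never"):
            raise ValueError("gg must be 'always' or 'never'")
        group_col = self.between[0]
        wide = self.data.pivot_table(
            index=self.subject, columns=self.within, values=self.dv, aggfunc="mean"
        )
        if wide.isna().any().any():
            raise ValueError("missing within-factor cells after listwise deletion")
        groups = (
            self.data.drop_duplicates(self.subject)
            .set_index(self.subject)[group_col]
            .loc[wide.index]
        )
        x = wide.to_numpy(dtype=float)
        n, k = x.shape
        glabels = groups.to_numpy()
        unique_groups = pd.unique(glabels)
        G = len(unique_groups)
        if G < 2:
            raise ValueError("between factor needs at least two groups")
        if n - G <= 0 or k < 2:
            raise ValueError("insufficient subjects or within levels")

        grand = x.mean()
        subj_means = x.mean(axis=1)
        group_means = {g: x[glabels == g].mean() for g in unique_groups}
        n_g = {g: int((glabels == g).sum()) for g in unique_groups}

        # between-subjects stratum (equivalently: one-way ANOVA on subject means)
        ss_subjects = k * float(((subj_means - grand) ** 2).sum())
        ss_group = k * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in unique_groups)
        ss_subj_err = ss_subjects - ss_group
        df_group, df_subj_err = G - 1, n - G

        # within-subjects stratum
        level_means = x.mean(axis=0)
        ss_within_total = float(((x - subj_means[:, None]) ** 2).sum())
        ss_time = n * float(((level_means - grand) ** 2).sum())
        ss_inter = 0.0
        for g in unique_groups:
            xg = x[glabels == g]
            cell = xg.mean(axis=0)
            ss_inter += n_g[g] * float(
                ((cell - group_means[g] - level_means + grand) ** 2).sum()
            )
        ss_err_within = ss_within_total - ss_time - ss_inter
        df_time, df_inter = k - 1, (G - 1) * (k - 1)
        df_err_within = (n - G) * (k - 1)

        ms = lambda ss, df: ss / df
        F_group = ms(ss_group, df_group) / ms(ss_subj_err, df_subj_err)
        F_time = ms(ss_time, df_time) / ms(ss_err_within, df_err_within)
        F_inter = ms(ss_inter, df_inter) / ms(ss_err_within, df_err_within)

        eps = gg_epsilon(x, glabels)
        e = eps if gg == "always" else 1.0
        rows = [
            {
                "effect": group_col,
                "ss": ss_group,
                "df1": float(df_group),
                "df2": float(df_subj_err),
                "F": F_group,
                "p": float(sps.f.sf(F_group, df_group, df_subj_err)),
            },
            {
                "effect": self.within,
                "ss": ss_time,
                "df1": e * df_time,
                "df2": e * df_err_within,
                "F": F_time,
                "p": float(sps.f.sf(F_time, e * df_time, e * df_err_within)),
            },
            {
                "effect": f"{self.within} x {group_col}",
                "ss": ss_inter,
                "df1": e * df_inter,
                "df2": e * df_err_within,
                "F": F_inter,
                "p": float(sps.f.sf(F_inter, e * df_inter, e * df_err_within)),
            },
        ]
        return AnovaResults(
            table=pd.DataFrame(rows),
            model=self,
            epsilon=eps,
            residual_ms=ms(ss_err_within, df_err_within),
            residual_df=float(df_err_within),
        )


# ---------------------------------------------------------------------------
# convenience functions mirroring the operations
# ---------------------------------------------------------------------------


def anova_two_way(
    data: pd.DataFrame,
    dv: str,
    factors: Sequence[str],
    ss_type: int = 3,
) -> AnovaResults:
    """Two-way between-subjects ANOVA (Type III default, unbalanced-capable)."""
    return FactorialAnova(data, dv, between=list(factors)).fit(ss_type=ss_type)


def rm_anova_gg(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
    gg: str = "always",
) -> AnovaResults:
    """Two-way mixed RM ANOVA with Greenhouse-Geisser corrected within df."""
    return FactorialAnova(data, dv, between=between, within=within, subject=subject).fit(
        gg=gg
    )


def pairwise_sidak(
    values: Sequence[float],
    groups: Sequence,
    pairs: Sequence[tuple] | None = None,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Sidak-adjusted pairwise comparisons with the pooled error term.

    Each comparison uses t = diff / sqrt(MSe (1/n1 + 1/n2)) with the pooled
    within-group mean square and its df; the family is exactly the supplied
    ``pairs`` (all pairs by default), optionally enlarged via
    ``family_size``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    stats = {g: values[groups == g] for g in names}
    for g, v in stats.items():
        if len(v) < 1:
            raise ValueError(f"group {g!r} has no observations")
    n_total = len(values)
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in stats.values())
    df_err = n_total - len(names)
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom for the pooled error")
    mse = sse / df_err
    if pairs is None:
        pairs = list(combinations(names, 2))
    m = family_size if family_size is not None else len(pairs)
    rows = []
    for a, b in pairs:
        va, vb = stats[a], stats[b]
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(mse * (1.0 / len(va) + 1.0 / len(vb)))
        t = diff / se if se > 0 else np.inf
        p_raw = 2.0 * float(sps.t.sf(abs(t), df_err))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": diff,
                "t": t,
                "p_raw": min(p_raw, 1.0),
                "p_adj": float(sidak_adjust(min(p_raw, 1.0), m)),
                "method": "sidak",
            }
        )
    return pd.DataFrame(rows)


def tukey_pairwise(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """Tukey HSD over all group pairs (studentized range, pooled MS error)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(str)
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    res = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
    )
    out = pd.DataFrame(
        {
            "group_a": frame["group1"],
            "group_b": frame["group2"],
            "mean_diff": frame["meandiff"].astype(float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "method": "tukey",
        }
    )
    return out
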