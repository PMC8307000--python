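"""Summary statistics for generation durations.

Factorial ANOVA with stepwise backward elimination of non-significant terms,
normality and homoscedasticity checks, Tukey HSD within a grouping factor
with a compact letter display, and the jackknife standard error of the mean.

The ANOVA engine computes sequential (Type I) sums of squares from nested
least-squares fits, with term degrees of freedom taken from the rank increase
the term contributes. This keeps the bookkeeping honest for nested factor
layouts (e.g. area within province), where naive dummy-count df are wrong.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InsufficientDataError, InvalidInputError, SingularDesignError
from .segmentation import GenerationDurationRecord

__all__ = [
    "AnovaTermResult",
    "AnovaResult",
    "TukeyGroups",
    "anova_stepwise",
    "tukey_by_province",
    "jackknife_se",
    "sequential_anova",
]

ALPHA = 0.05


# --------------------------------------------------------------------------
# jackknife
# --------------------------------------------------------------------------

def jackknife_se(values, statistic=np.mean) -> float:
    """Leave-one-out jackknife standard error of ``statistic``.

    SE = sqrt((n-1)/n * sum_i (theta_(i) - theta_bar)^2) where theta_(i) is
    the statistic on the sample with observation i deleted. For the mean this
    equals s/sqrt(n) exactly.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError("jackknife needs at least 2 observations")
    loo = np.array([statistic(np.delete(x, i)) for i in range(n)])
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


# --------------------------------------------------------------------------
# sequential ANOVA engine
# --------------------------------------------------------------------------

def _term_design(df: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    """Full one-hot design block for a term (factor or interaction)."""
    key = df[term[0]].astype(str)
    for f in term[1:]:
        key = key + "\x1f" + df[f].astype(str)
    return pd.get_dummies(key, dtype=float).to_numpy()


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of least-squares fit and design rank."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def _fit(df: pd.DataFrame, response: str, terms: list[tuple[str, ...]]):
    y = df[response].to_numpy(float)
    x = np.ones((len(df), 1))
    for t in terms:
        x = np.hstack([x, _term_design(df, t)])
    rss, rank = _rss(x, y)
    return rss, rank, x, y


def sequential_anova(
    df: pd.DataFrame, response: str, terms: list[tuple[str, ...]]
) -> pd.DataFrame:
    """Type I (sequential) ANOVA table for ``terms`` in the given order.

    Each term's SS is the drop in residual sum of squares when it enters the
    model after all preceding terms; its df is the rank it adds.
    """
    y = df[response].to_numpy(float)
    x = np.ones((len(df), 1))
    rss_prev, rank_prev = _rss(x, y)
    rows = []
    for t in terms:
        x = np.hstack([x, _term_design(df, t)])
        rss, rank = _rss(x, y)
        rows.append((":".join(t), rss_prev - rss, rank - rank_prev))
        rss_prev, rank_prev = rss, rank
    df_resid = len(y) - rank_prev
    if df_resid <= 0:
        raise SingularDesignError("saturated model: no residual degrees of freedom")
    mse = rss_prev / df_resid
    table = []
    for name, ss, dfn in rows:
        if dfn == 0:
            table.append((name, ss, 0, np.nan, np.nan))
        else:
            f = (ss / dfn) / mse
            table.append((name, ss, dfn, f, sps.f.sf(f, dfn, df_resid)))
    out = pd.DataFrame(table, columns=["term", "sum_sq", "df", "F", "p"])
    out.loc[len(out)] = ("Residual", rss_prev, df_resid, np.nan, np.nan)
    return out


@dataclass(frozen=True)
class AnovaTermResult:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float
    sum_sq: float


@dataclass
class AnovaResult:
    """Outcome of the stepwise ANOVA.

    ``retained`` holds the final model's sequential table; ``removed`` lists
    (term, p-at-removal) in removal order. ``shapiro`` is the (statistic, p)
    of the Shapiro-Wilk test on the final residuals; ``bartlett`` maps each
    retained main factor to its (statistic, p) homoscedasticity check.
    """

    retained: list[AnovaTermResult]
    removed: list[tuple[str, float]]
    shapiro: tuple[float, float]
    bartlett: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_df: int = 0

    @property
    def retained_factors(self) -> list[str]:
        return [t.term for t in self.retained]

    def summary(self) -> str:
        lines = ["Stepwise ANOVA", "=" * 40]
        for t in self.retained:
            lines.append(
                f"  {t.term:<28s} F_{t.df_num},{t.df_den} = {t.F:8.3f}  p = {t.p:.4g}"
            )
        if not self.retained:
            lines.append("  (no term retained)")
        if self.removed:
            lines.append("Removed (in order):")
            for name, p in self.removed:
                lines.append(f"  {name:<28s} p = {p:.4g}")
        lines.append(f"Shapiro-Wilk on residuals: W = {self.shapiro[0]:.4f}, p = {self.shapiro[1]:.4g}")
        for fac, (stat, p) in self.bartlett.items():
            lines.append(f"Bartlett across {fac}: K2 = {stat:.4f}, p = {p:.4g}")
        return "\n".join(lines)


def _records_frame(records: list[GenerationDurationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "province": [r.province for r in records],
            "area": [r.area for r in records],
            "year": [r.year for r in records],
            "flight_order": [r.flight_order for r in records],
            "duration_dd": [r.duration_dd for r in records],
        }
    )


def _drop_one_p(df, response, terms, target) -> tuple[float, int]:
    """(p-value, numerator df) of the F test for dropping ``target``.

    df 0 means the term is fully aliased given the rest of the model (it
    carries no testable variation of its own, e.g. a factor whose groups are
    unions of a nested factor's groups).
    """
    rss_full, rank_full, _, y = _fit(df, response, terms)
    reduced = [t for t in terms if t != target]
    rss_red, rank_red, _, _ = _fit(df, response, reduced)
    df_num = rank_full - rank_red
    df_den = len(y) - rank_full
    if df_num == 0:
        return float("nan"), 0
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    return float(sps.f.sf(f, df_num, df_den)), df_num


def anova_stepwise(
    records: list[GenerationDurationRecord],
    factors: tuple[str, ...] = ("province", "area", "year", "flight_order"),
    alpha: float = ALPHA,
    interactions: bool = True,
) -> AnovaResult:
    """Backward-stepwise factorial ANOVA on generation durations.

    Starts from all main effects plus pairwise interactions, repeatedly
    removes the least significant removable term with p >= ``alpha``
    (interactions before the main effects they contain), refitting after each
    removal, and reports the sequential table of the final model together
    with Shapiro-Wilk and Bartlett assumption checks.
    """
    if not records:
        raise InsufficientDataError("no duration records")
    df = _records_frame(records)

    usable = []
    for f in factors:
        if f not in df.columns:
            raise InvalidInputError(f"unknown factor {f!r}")
        if df[f].nunique() >= 2:
            usable.append(f)
        else:
            warnings.warn(f"factor {f!r} has a single level; dropped from the model", stacklevel=2)
    if not usable:
        raise InsufficientDataError("no factor has >= 2 levels")

    terms: list[tuple[str, ...]] = [(f,) for f in usable]

    # a main effect adding no rank beyond the preceding ones is genuinely
    # confounded (e.g. two factors with identical groupings)
    seq_main = sequential_anova(df, "duration_dd", terms)
    aliased = seq_main.loc[
        (seq_main["df"] == 0) & (seq_main["term"] != "Residual"), "term"
    ].tolist()
    if aliased:
        raise SingularDesignError(
            f"confounded factors in the design: {aliased}", aliased_terms=aliased
        )

    if interactions:
        # keep only interactions that add rank; nested layouts (area within
        # province) alias some interactions with main effects, which is a
        # property of the layout, not an error
        for pair in combinations(usable, 2):
            trial = terms + [tuple(pair)]
            try:
                seq = sequential_anova(df, "duration_dd", trial)
                adds_rank = int(seq.loc[seq["term"] == ":".join(pair), "df"].iloc[0]) > 0
            except SingularDesignError:
                adds_rank = False  # would saturate the model
            if adds_rank:
                terms = trial
            else:
                warnings.warn(
                    f"interaction {':'.join(pair)} aliased by the design; omitted",
                    stacklevel=2,
                )

    removed: list[tuple[str, float]] = []
    while terms:
        in_interaction = {f for t in terms if len(t) > 1 for f in t}
        removable = [t for t in terms if len(t) > 1 or t[0] not in in_interaction]
        if not removable:
            break
        tests = {t: _drop_one_p(df, "duration_dd", terms, t) for t in removable}
        testable = {t: p for t, (p, dfn) in tests.items() if dfn > 0}
        bad = {t: p for t, p in testable.items() if p >= alpha}
        if bad:
            # least significant first; interactions before main effects on ties
            worst = max(bad, key=lambda t: (bad[t], len(t)))
            terms.remove(worst)
            removed.append((":".join(worst), bad[worst]))
            continue
        untestable = [t for t, (p, dfn) in tests.items() if dfn == 0]
        if untestable:
            # aliased given the retained terms: no variation of its own left
            worst = untestable[-1]
            terms.remove(worst)
            removed.append((":".join(worst), float("nan")))
            continue
        break

    retained: list[AnovaTermResult] = []
    resid_df = len(df) - 1
    if terms:
        # report main effects before interactions, in the requested factor order
        terms = sorted(terms, key=lambda t: (len(t), [usable.index(f) for f in t]))
        table = sequential_anova(df, "duration_dd", terms)
        resid_df = int(table.iloc[-1]["df"])
        for _, row in table.iloc[:-1].iterrows():
            retained.append(
                AnovaTermResult(
                    term=row["term"],
                    F=float(row["F"]),
                    df_num=int(row["df"]),
                    df_den=resid_df,
                    p=float(row["p"]),
                    sum_sq=float(row["sum_sq"]),
                )
            )
        _, _, x, y = _fit(df, "duration_dd", terms)
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        residuals = y - x @ beta
    else:
        y = df["duration_dd"].to_numpy(float)
        residuals = y - y.mean()

    shapiro = sps.shapiro(residuals)
    bartlett = {}
    for t in terms:
        if len(t) > 1:
            continue
        fac = t[0]
        groups = [g.to_numpy(float) for _, g in df.groupby(fac)["duration_dd"] if len(g) >= 2]
        if len(groups) >= 2:
            stat, p = sps.bartlett(*groups)
            bartlett[fac] = (float(stat), float(p))

    return AnovaResult(
        retained=retained,
        removed=removed,
        shapiro=(float(shapiro.statistic), float(shapiro.pvalue)),
        bartlett=bartlett,
        residual_df=resid_df,
    )


# --------------------------------------------------------------------------
# Tukey HSD with compact letter display
# --------------------------------------------------------------------------

@dataclass
class TukeyGroups:
    """Per-level means, SEs and significance letters for one province."""

    province: str
    table: pd.DataFrame  # columns: flight_order, n, mean, se, letters
    alpha: float = ALPHA

    def letters_of(self, level) -> str:
        row = self.table[self.table["flight_order"] == level]
        return row["letters"].iloc[0] if len(row) else ""


def compact_letter_display(
    levels: list, significant: set[tuple[int, int]]
) -> dict:
    """Greedy insert-absorb compact letter display.

    ``significant`` holds index pairs (i < j) of levels that differ. Starts
    from one group containing every level; each significant pair splits the
    groups containing both; subset groups are absorbed. Deterministic for a
    fixed level order.
    """
    groups: list[set[int]] = [set(range(len(levels)))]
    for i, j in sorted(significant):
        new_groups = []
        for g in groups:
            if i in g and j in g:
                new_groups.extend([g - {i}, g - {j}])
            else:
                new_groups.append(g)
        # absorb: drop any group contained in another (strict subset, or
        # duplicate appearing later)
        groups = []
        for gi, g in enumerate(new_groups):
            absorbed = any(
                g < h or (g == h and hi < gi) for hi, h in enumerate(new_groups) if hi != gi
            )
            if not absorbed and g:
                groups.append(g)
    groups.sort(key=lambda g: min(g) if g else len(levels))
    letters = {k: "" for k in range(len(levels))}
    for gi, g in enumerate(groups):
        ch = chr(ord("a") + gi)
        for k in sorted(g):
            letters[k] += ch
    return {levels[k]: v for k, v in letters.items()}


def tukey_by_province(
    records: list[GenerationDurationRecord],
    province: str,
    alpha: float = ALPHA,
) -> TukeyGroups:
    """Tukey HSD over flight orders within one province.

    All pairwise comparisons use the studentized range distribution at
    ``alpha``; levels with fewer than 2 observations are excluded with a
    warning. Levels sharing a letter are not significantly different.
    """
    df = _records_frame(records)
    df = df[df["province"] == province]
    if df.empty:
        raise InsufficientDataError(f"no records for province {province!r}")

    counts = df.groupby("flight_order")["duration_dd"].count()
    thin = counts[counts < 2].index.tolist()
    if thin:
        warnings.warn(
            f"{province}: flight orders {thin} have < 2 observations; excluded", stacklevel=2
        )
        df = df[~df["flight_order"].isin(thin)]
    levels = sorted(df["flight_order"].unique())
    if len(levels) < 2:
        raise InsufficientDataError(f"{province}: need >= 2 flight-order levels for Tukey")

    res = pairwise_tukeyhsd(
        df["duration_dd"].to_numpy(float), df["flight_order"].to_numpy(), alpha=alpha
    )
    sig = set()
    for (g1, g2), rej in zip(combinations(res.groupsunique, 2), res.reject):
        if rej:
            sig.add((levels.index(g1), levels.index(g2)))
    letters = compact_letter_display(levels, sig)

    rows = []
    for lv in levels:
        vals = df.loc[df["flight_order"] == lv, "duration_dd"].to_numpy(float)
        rows.append(
            {
                "flight_order": lv,
                "n": len(vals),
                "mean": float(vals.mean()),
                "se": float(np.std(vals, ddof=1) / np.sqrt(len(vals))),
                "letters": letters[lv],
            }
        )
    return TukeyGroups(province=province, table=pd.DataFrame(rows), alpha=alpha)
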