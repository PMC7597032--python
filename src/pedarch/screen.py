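"""Exhaustive Pearson correlation screening of skeletal vs loading variables.

The screen evaluates, within each patient group (the pooled ALL group and
the neuropathic / non-neuropathic subgroups N and D):

* inter-variable pairs: each of the 84 skeletal (3D) variables against the
  12 LOAD, 2 FUNC (CT, AI), 2 BIOL (age, BMI) and 2 CLIN (YOD, NS-VPT)
  variables -> 84 x 18 = 1512 pairs;
* intra-variable pairs: C(84, 2) = 3486 within the 3D variables and
  C(12, 2) = 66 within LOAD, 3552 in total.

Each pair yields the sample Pearson r, R^2 = r^2, a two-sided p-value from
the t distribution with n - 2 degrees of freedom, and a strength class
(weak R^2 <= 0.30, moderate 0.30 < R^2 <= 0.70, strong R^2 > 0.70).
Missing values are removed pairwise; the paired n is reported.  The screen
uses a plain p < alpha filter by default (no multiple-testing correction),
with an optional Benjamini-Hochberg adjustment.

The screen is exposed statsmodels-style: build a :class:`CorrelationScreen`
from a wide table (rows = feet/patients, columns = the 102 variables plus a
group label), call :meth:`~CorrelationScreen.fit`, and inspect the returned
:class:`CorrelationScreenResults` (`.frame`, `.family_summary()`,
`.summary()`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import InsufficientDataError, PedarchError
from .pressure import LOAD_VARIABLES
from .skeletal import VARIABLE_NAMES_3D

VAR_3D = tuple(VARIABLE_NAMES_3D)
VAR_LOAD = tuple(LOAD_VARIABLES)
VAR_FUNC = ("CT", "AI")
VAR_BIOL = ("AGE", "BMI")
VAR_CLIN = ("YOD", "NS_VPT")
VAR_OTHER = VAR_LOAD + VAR_FUNC + VAR_BIOL + VAR_CLIN
ALL_VARIABLES = VAR_3D + VAR_OTHER
assert len(ALL_VARIABLES) == 102

WEAK_MAX = 0.30
MODERATE_MAX = 0.70

#: Skeletal-variable families used in the screening summary.
FAMILIES_3D = {
    "lateral_angles": tuple(n for n in VAR_3D if n.startswith(("IL_", "RL_"))),
    "transverse_angles": tuple(n for n in VAR_3D if n.startswith(("IT_", "RT_"))),
    "frontal_angles": tuple(n for n in VAR_3D if n.startswith(("IF_", "RF_"))),
    "angles_3d": tuple(n for n in VAR_3D if n.startswith(("I3_", "R3_"))),
    "forefoot_heights": tuple(
        n for n in VAR_3D if n.startswith(("Hg_", "Hgr_")) and n[-2] in "MP"
    ),
    "midfoot_heights": tuple(
        n for n in VAR_3D if n.endswith(("CUB", "NAV"))
    ),
}


@dataclass
class PearsonResult:
    r: float
    r2: float
    p: float
    n: int
    flag: str | None = None


def pearson_r2(x, y) -> PearsonResult:
    """Sample Pearson correlation with pairwise deletion.

    The p-value is two-sided, from ``t = r sqrt((n-2) / (1-r^2))`` on
    n - 2 degrees of freedom.  Fewer than 3 complete pairs flags
    ``insufficient_data``; zero variance in either vector flags
    ``zero_variance``; flagged results carry NaN statistics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return PearsonResult(np.nan, np.nan, np.nan, n, "insufficient_data")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx <= 0 or syy <= 0:
        return PearsonResult(np.nan, np.nan, np.nan, n, "zero_variance")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    r2 = r * r
    if r2 >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r2))
        p = float(2.0 * _stats.t.sf(abs(t), n - 2))
    return PearsonResult(r, r2, p, n)


def classify_strength(r2: float) -> str:
    """Strength class of a coefficient of determination."""
    if not 0.0 <= r2 <= 1.0:
        raise PedarchError(f"R^2 must lie in [0, 1], got {r2}")
    if r2 <= WEAK_MAX:
        return "weak"
    if r2 <= MODERATE_MAX:
        return "moderate"
    return "strong"


def group_ttest(
    table: pd.DataFrame,
    var: str,
    groups: tuple[str, str] = ("N", "D"),
    group_col: str = "group",
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample two-sided Student's t-test of one variable between groups.

    Pooled-variance (classic Student) by default; ``equal_var=False``
    switches to Welch's approximation.
    """
    samples = []
    for g in groups:
        v = table.loc[table[group_col] == g, var].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise InsufficientDataError(f"group {g}: fewer than 2 values for {var}")
        samples.append(v)
    a, b = samples
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    if se == 0:
        return (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    t = float(diff / se)
    p = float(2.0 * _stats.t.sf(abs(t), df))
    return t, p


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def correlation_pairs() -> list[tuple[str, str, str]]:
    """The screening design: (var_a, var_b, category) triples."""
    pairs: list[tuple[str, str, str]] = []
    for a in VAR_3D:
        for b in VAR_OTHER:
            pairs.append((a, b, "inter"))
    for a, b in combinations(VAR_3D, 2):
        pairs.append((a, b, "intra3D"))
    for a, b in combinations(VAR_LOAD, 2):
        pairs.append((a, b, "intraLOAD"))
    return pairs


class CorrelationScreen:
    """Exhaustive correlation screen over a wide variable table.

    Parameters
    ----------
    table : DataFrame with the 102 variable columns and a group column.
    group_col : name of the group-label column (values among N, D, LADA).
    alpha : significance level of the screen (default 0.05).
    multiple_testing : 'none' (the default screen) or 'bh'.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        group_col: str = "group",
        alpha: float = 0.05,
        multiple_testing: str = "none",
    ) -> None:
        missing = [c for c in ALL_VARIABLES if c not in table.columns]
        if missing:
            raise PedarchError(
                f"table is missing {len(missing)} variable columns "
                f"(first: {missing[:3]})"
            )
        if group_col not in table.columns:
            raise PedarchError(f"group column {group_col!r} missing")
        if not 0.0 < alpha < 1.0:
            raise PedarchError(f"alpha must lie in (0, 1), got {alpha}")
        if multiple_testing not in ("none", "bh"):
            raise PedarchError(f"unknown multiple_testing {multiple_testing!r}")
        self.table = table
        self.group_col = group_col
        self.alpha = alpha
        self.multiple_testing = multiple_testing

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CorrelationScreen":
        return cls(df, **kwargs)

    def _group_rows(self, group: str) -> pd.DataFrame:
        if group == "ALL":
            return self.table
        return self.table[self.table[self.group_col] == group]

    def fit(self, groups: tuple[str, ...] = ("ALL", "N", "D")) -> "CorrelationScreenResults":
        """Run the screen for each group and return the results object."""
        pairs = correlation_pairs()
        records: list[dict] = []
        for group in groups:
            sub = self._group_rows(group)
            if len(sub) == 0:
                raise InsufficientDataError(f"group {group!r} has no rows")
            data = sub[list(ALL_VARIABLES)].to_numpy(dtype=float)
            col = {name: i for i, name in enumerate(ALL_VARIABLES)}
            for a, b, cat in pairs:
                res = pearson_r2(data[:, col[a]], data[:, col[b]])
                records.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "group": group,
                        "category": cat,
                        "n": res.n,
                        "r": res.r,
                        "r2": res.r2,
                        "p": res.p,
                        "flag": res.flag,
                    }
                )
        frame = pd.DataFrame.from_records(records)
        if self.multiple_testing == "bh":
            frame["p_adj"] = np.concatenate(
                [
                    _bh_adjust(frame.loc[frame["group"] == g, "p"].to_numpy())
                    for g in groups
                ]
            )
            pcol = "p_adj"
        else:
            pcol = "p"
        frame["significant"] = frame[pcol] < self.alpha
        frame["strength"] = [
            classify_strength(v) if np.isfinite(v) else None for v in frame["r2"]
        ]
        return CorrelationScreenResults(frame, self.alpha, tuple(groups), self)


def summarize(frame: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Per-group, per-family summary of the LOAD-vs-skeletal screen.

    For each group and each skeletal-variable family (the four angle
    planes, forefoot heights, midfoot heights): the number of LOAD pairs,
    the number significant at ``alpha``, and the percentage.
    """
    inter = frame[(frame["category"] == "inter") & frame["var_b"].isin(VAR_LOAD)]
    rows = []
    for group in inter["group"].unique():
        g = inter[inter["group"] == group]
        for fam, members in FAMILIES_3D.items():
            sel = g[g["var_a"].isin(members)]
            n_pairs = len(sel)
            n_sig = int(sel["significant"].sum())
            rows.append(
                {
                    "group": group,
                    "family": fam,
                    "n_pairs": n_pairs,
                    "n_significant": n_sig,
                    "pct_significant": 100.0 * n_sig / n_pairs if n_pairs else np.nan,
                }
            )
    return pd.DataFrame(rows)


class CorrelationScreenResults:
    """Results of a fitted :class:`CorrelationScreen`.

    Attributes
    ----------
    frame : long-format DataFrame, one row per variable pair per group.
    alpha : the significance level used.
    groups : the groups screened.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        alpha: float,
        groups: tuple[str, ...],
        model: CorrelationScreen,
    ) -> None:
        self.frame = frame
        self.alpha = alpha
        self.groups = groups
        self.model = model

    def counts(self, group: str | None = None) -> dict[str, int]:
        """Pair counts per category (per single group when given)."""
        f = self.frame if group is None else self.frame[self.frame["group"] == group]
        if group is None and len(self.groups) > 0:
            f = f[f["group"] == self.groups[0]]
        return f["category"].value_counts().to_dict()

    def significant_pairs(self, category: str | None = None) -> pd.DataFrame:
        sel = self.frame[self.frame["significant"]]
        if category is not None:
            sel = sel[sel["category"] == category]
        return sel.reset_index(drop=True)

    def family_summary(self) -> pd.DataFrame:
        return summarize(self.frame, self.alpha)

    def r2_distribution(self, group: str) -> dict[str, float]:
        """Median and quartiles of R^2 over the significant LOAD-vs-3D
        correlations of one group."""
        sel = self.frame[
            (self.frame["group"] == group)
            & self.frame["significant"]
            & (self.frame["category"] == "inter")
            & self.frame["var_b"].isin(VAR_LOAD)
        ]["r2"]
        if len(sel) == 0:
            return {"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan}
        return {
            "n": int(len(sel)),
            "median": float(sel.median()),
            "q1": float(sel.quantile(0.25)),
            "q3": float(sel.quantile(0.75)),
        }

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            "Correlation screen summary",
            "=" * 60,
            f"alpha = {self.alpha}   groups = {', '.join(self.groups)}",
        ]
        c = self.counts()
        lines.append(
            "pairs per group: "
            + ", ".join(f"{k} = {v}" for k, v in sorted(c.items()))
        )
        for g in self.groups:
            gg = self.frame[self.frame["group"] == g]
            nsig = int(gg["significant"].sum())
            d = self.r2_distribution(g)
            lines.append(
                f"group {g}: n rows = {gg['n'].max()}, significant = {nsig}; "
                f"LOAD-vs-3D significant R2 median [Q1-Q3] = "
                f"{d['median']:.2f} [{d['q1']:.2f}-{d['q3']:.2f}] (n={d['n']})"
                if d["n"]
                else f"group {g}: n rows = {gg['n'].max()}, significant = {nsig}; "
                "no significant LOAD-vs-3D correlations"
            )
        lines.append("-" * 60)
        fam = self.family_summary()
        lines.append(fam.to_string(index=False))
        return "\n".join(lines)
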