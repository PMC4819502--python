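"""Inference on the blocked transect data.

Covers the study's inferential layer:

* linear mixed models with a random block (shrub cluster) intercept,
  compared by maximum-likelihood likelihood-ratio tests (LRT) for the
  species, distance and interaction fixed effects;
* per-species distance tests;
* Tukey–Kramer all-pairs comparisons between distance classes, which
  handle the design's unequal cell sizes, plus a compact letter display;
* ordinary least-squares regressions of shoot delta15N between each
  pair of focal species, matched on (block, distance);
* Shapiro–Wilk and Levene screens, reported as diagnostics only.

Models are estimated by ML (not REML) because the compared models
differ in their fixed effects; the LRT statistic is referred to a
chi-square distribution with df equal to the difference in fixed-effect
parameter count.  A boundary fit with (near-)zero block variance is
reported with a ``singular`` flag rather than an error.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .io import REF, SPECIES, distance_sort_key

__all__ = [
    "LRTResult",
    "fit_lmm_lrt",
    "per_species_distance_lrt",
    "TukeyKramer",
    "tukey_kramer",
    "compact_letter_display",
    "pairwise_species_regression",
    "normality_homoscedasticity_screen",
]

logger = logging.getLogger(__name__)

_SINGULAR_TOL = 1e-8


@dataclass
class LRTResult:
    """One likelihood-ratio test of a fixed effect in the block-random model."""

    response: str
    effect: str
    statistic: float
    df: int
    p_value: float
    singular: bool = False

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "effect": self.effect,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "singular": self.singular,
        }


def _prepare(plants: pd.DataFrame, response: str) -> pd.DataFrame:
    if response not in ("n_pct", "d15n"):
        raise ValueError("response must be 'n_pct' or 'd15n'")
    df = plants.copy()
    df["distance"] = df["distance"].astype(str)
    order = sorted(df["distance"].unique(), key=lambda s: distance_sort_key(s if s == REF else int(s)))
    df["distance"] = pd.Categorical(df["distance"], categories=order)
    df["species"] = pd.Categorical(df["species"], categories=[s for s in SPECIES if s in set(df["species"])])
    return df


def _fit_ml(formula: str, df: pd.DataFrame) -> Tuple[float, int, bool]:
    """ML log-likelihood, fixed-effect count and singularity flag for one model."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["block"])
        try:
            res = model.fit(reml=False, maxiter=200)
            if not np.isfinite(res.llf):
                raise ValueError("non-finite log-likelihood")
        except Exception:
            res = model.fit(reml=False, method="powell", maxiter=500)
    singular = bool(np.asarray(res.cov_re).ravel()[0] <= _SINGULAR_TOL)
    return float(res.llf), int(res.k_fe), singular


def _lrt(full_llf, full_k, red_llf, red_k, response, effect, singular) -> LRTResult:
    stat = max(0.0, 2.0 * (full_llf - red_llf))
    df = full_k - red_k
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return LRTResult(response, effect, stat, df, p, singular)


def fit_lmm_lrt(plants: pd.DataFrame, response: str) -> List[LRTResult]:
    """LRTs for species, distance and their interaction on one response.

    The full model has species, distance and species x distance fixed
    effects with a random block intercept.  Each main effect is tested
    by comparing the additive model against the model without it; the
    interaction by comparing the full model against the additive one.
    All fits use ML so the likelihoods are comparable.

    A response with zero variance yields statistic 0 and p = 1 for all
    effects (flagged singular) rather than a failed fit.
    """
    df = _prepare(plants, response)
    if df["block"].nunique() < 2:
        raise ValueError("need >= 2 blocks for the mixed model")
    if df["species"].nunique() < 2 or df["distance"].nunique() < 2:
        raise ValueError("both species and distance need >= 2 levels")

    if np.isclose(df[response].var(ddof=0), 0.0):
        k_sp = df["species"].nunique() - 1
        k_di = df["distance"].nunique() - 1
        return [
            LRTResult(response, "species", 0.0, k_sp, 1.0, True),
            LRTResult(response, "distance", 0.0, k_di, 1.0, True),
            LRTResult(response, "species:distance", 0.0, k_sp * k_di, 1.0, True),
        ]

    inter_llf, inter_k, inter_sing = _fit_ml(f"{response} ~ species * distance", df)
    add_llf, add_k, add_sing = _fit_ml(f"{response} ~ species + distance", df)
    sp_llf, sp_k, _ = _fit_ml(f"{response} ~ species", df)
    di_llf, di_k, _ = _fit_ml(f"{response} ~ distance", df)
    return [
        _lrt(add_llf, add_k, di_llf, di_k, response, "species", add_sing),
        _lrt(add_llf, add_k, sp_llf, sp_k, response, "distance", add_sing),
        _lrt(inter_llf, inter_k, add_llf, add_k, response, "species:distance", inter_sing),
    ]


def per_species_distance_lrt(plants: pd.DataFrame, species: str, response: str) -> LRTResult:
    """Distance-effect LRT within one species (distance the only fixed effect)."""
    sub = plants[plants["species"] == species]
    if sub.empty:
        raise ValueError(f"no observations for species {species!r}")
    df = _prepare(sub, response)
    if df["block"].nunique() < 2:
        raise ValueError("need >= 2 blocks for the mixed model")
    if np.isclose(df[response].var(ddof=0), 0.0):
        return LRTResult(response, f"distance|{species}", 0.0, df["distance"].nunique() - 1, 1.0, True)
    full_llf, full_k, full_sing = _fit_ml(f"{response} ~ distance", df)
    null_llf, null_k, _ = _fit_ml(f"{response} ~ 1", df)
    return _lrt(full_llf, full_k, null_llf, null_k, response, f"distance|{species}", full_sing)


# ---------------------------------------------------------------------------
# Tukey–Kramer


class TukeyKramer:
    """All-pairs comparisons between groups with unequal sizes.

    Uses the studentized-range distribution with the Kramer adjustment
    for unequal n: the comparison of groups *i*, *j* uses standard error
    ``sqrt(s2/2 * (1/n_i + 1/n_j))`` with the pooled one-way residual
    variance ``s2`` on N - k df.  With equal n this reduces to the
    classical Tukey HSD.

    Parameters
    ----------
    alpha : float
        Family-wise significance level for the letter display.

    Attributes
    ----------
    groups_ : list — group labels in presentation order
    means_, ns_ : dict — group means and sizes
    pvalues_ : DataFrame — symmetric matrix of adjusted p-values
    letters_ : DataFrame — columns group, mean, n, letters
    df_resid_ : int
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def get_params(self, deep=True):
        return {"alpha": self.alpha}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, values, groups):
        values = np.asarray(values, dtype=float)
        groups = np.asarray(groups, dtype=object)
        labels = [g for g in _ordered_unique(groups)]
        data = {}
        for g in labels:
            v = values[groups == g]
            if v.size == 0:
                warnings.warn(f"group {g!r} has no observations; excluded")
                continue
            data[g] = v
        labels = [g for g in labels if g in data]
        if len(labels) < 2:
            raise ValueError("need >= 2 non-empty groups")
        ns = {g: data[g].size for g in labels}
        N, k = sum(ns.values()), len(labels)
        df_resid = N - k
        if df_resid < 1:
            raise ValueError("no residual degrees of freedom (all groups have n = 1)")
        means = {g: float(data[g].mean()) for g in labels}
        sse = sum(float(((data[g] - means[g]) ** 2).sum()) for g in labels)
        s2 = sse / df_resid

        pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
        for a, b in itertools.combinations(labels, 2):
            if s2 == 0.0:
                p = 1.0 if means[a] == means[b] else 0.0
            else:
                se = np.sqrt(s2 / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
                q = abs(means[a] - means[b]) / se
                p = float(stats.studentized_range.sf(q, k, df_resid))
            pmat.loc[a, b] = pmat.loc[b, a] = p

        self.groups_ = labels
        self.means_ = means
        self.ns_ = ns
        self.df_resid_ = df_resid
        self.s2_ = s2
        self.pvalues_ = pmat
        letters = compact_letter_display(pmat, self.alpha)
        self.letters_ = pd.DataFrame(
            {
                "group": labels,
                "mean": [means[g] for g in labels],
                "n": [ns[g] for g in labels],
                "letters": [letters[g] for g in labels],
            }
        )
        return self


def _ordered_unique(seq):
    seen = set()
    out = []
    for x in seq:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def tukey_kramer(values, groups, alpha: float = 0.05) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper: returns (p-value matrix, letters table)."""
    tk = TukeyKramer(alpha=alpha).fit(values, groups)
    return tk.pvalues_, tk.letters_


def compact_letter_display(pvalues: pd.DataFrame, alpha: float = 0.05) -> Dict:
    """Assign letters so groups sharing a letter are not significantly different.

    Insert-and-absorb: start with one column containing every group; for
    each significant pair occurring in a column, split the column into
    two (each missing one member of the pair), then absorb columns that
    are subsets of others.  Letters are assigned to the surviving
    columns in the order of the input index.
    """
    groups = list(pvalues.index)
    sig_pairs = [
        (a, b)
        for a, b in itertools.combinations(groups, 2)
        if pvalues.loc[a, b] < alpha
    ]
    columns: List[set] = [set(groups)]
    for a, b in sig_pairs:
        new_cols: List[set] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        columns = []
        for col in new_cols:
            if not any(col < other for other in new_cols if col is not other):
                if col and col not in columns:
                    columns.append(col)
    # order columns by first member appearance for stable lettering
    columns.sort(key=lambda col: min(groups.index(g) for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, col in enumerate(columns):
        letter = alphabet[i] if i < len(alphabet) else f"({i})"
        for g in groups:
            if g in col:
                out[g] += letter
    return out


# ---------------------------------------------------------------------------
# species-pair regressions and diagnostics


def pairwise_species_regression(plants: pd.DataFrame) -> pd.DataFrame:
    """OLS of shoot delta15N between each species pair, matched on (block, distance).

    Complete-case: cells missing in either species are dropped.  Returns
    one row per ordered pair with slope, intercept, r**2, p and n.
    """
    rows = []
    present = [s for s in SPECIES if (plants["species"] == s).any()]
    for sx, sy in itertools.combinations(present, 2):
        x = plants[plants["species"] == sx].set_index(["block", "distance"])["d15n"]
        y = plants[plants["species"] == sy].set_index(["block", "distance"])["d15n"]
        joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
        if len(joined) < 3:
            raise ValueError(
                f"species pair ({sx}, {sy}) has {len(joined)} matched observations; need >= 3"
            )
        if np.isclose(joined["x"].var(ddof=0), 0.0):
            # degenerate predictor: slope undefined; report 0 slope at the mean
            rows.append(
                {
                    "species_x": sx,
                    "species_y": sy,
                    "slope": 0.0,
                    "intercept": float(joined["y"].mean()),
                    "r2": 0.0,
                    "p_value": 1.0,
                    "n": len(joined),
                }
            )
            continue
        res = stats.linregress(joined["x"], joined["y"])
        rows.append(
            {
                "species_x": sx,
                "species_y": sy,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r2": float(res.rvalue**2),
                "p_value": float(res.pvalue),
                "n": len(joined),
            }
        )
    return pd.DataFrame(rows)


def normality_homoscedasticity_screen(plants: pd.DataFrame, response: str) -> dict:
    """Shapiro–Wilk and Levene diagnostics, reported only (never gating).

    Shapiro–Wilk is applied to the pooled per-cell residuals; Levene
    tests equality of variance across distance classes.
    """
    df = plants.copy()
    resid = df.groupby(["species", "distance"], observed=True)[response].transform(
        lambda v: v - v.mean()
    )
    groups = [
        g[response].to_numpy()
        for _, g in df.groupby("distance", observed=True)
        if len(g) >= 2
    ]
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if resid.notna().sum() >= 3 and resid.var(ddof=0) > 0:
            w, p = stats.shapiro(resid.dropna())
            out["shapiro_w"], out["shapiro_p"] = float(w), float(p)
        if len(groups) >= 2 and any(np.var(g) > 0 for g in groups):
            w, p = stats.levene(*groups)
            out["levene_w"], out["levene_p"] = float(w), float(p)
    return out
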