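"""Phenotype-level comparisons of metric trajectories and cellular traits.

Metric trajectories are compared with a repeated-measures linear mixed
model: value ~ group + timepoint with a random intercept per fragment,
fit by REML, followed by all pairwise group contrasts with Bonferroni
adjustment within each (metric, wavelength) family. The grouping factor is
either the light-response phenotype (per metric x wavelength) or the
excitation wavelength (per metric x phenotype). When the mixed fit is
singular or fails, a two-stage fallback (fragment means, pairwise Welch
t-tests) is used and flagged.

Cellular traits are compared across phenotypes with a Shapiro-Wilk
normality gate: one-way ANOVA with Tukey HSD when normal, Kruskal-Wallis
with Bonferroni-adjusted pairwise Mann-Whitney tests otherwise. Group
differences are summarized as a compact letter display (groups sharing a
letter are pairwise non-significant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ContrastResult",
    "TraitComparison",
    "compare_profiles",
    "compare_cellular_traits",
    "compact_letter_display",
]

_ALPHA = 0.05


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise contrast within a Bonferroni family."""

    metric: str
    family: str  # e.g. "wavelength=442" or "phenotype=1"
    pair: tuple
    estimate: float
    p_raw: float
    p_adjusted: float
    significant: bool
    family_size: int
    fallback: bool = False


def _pairs(levels: Sequence) -> list[tuple]:
    levels = list(levels)
    return [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]


def _two_stage_contrasts(df: pd.DataFrame) -> list[tuple[tuple, float, float]]:
    """Fragment-mean pairwise Welch t-tests: (pair, estimate, p)."""
    means = df.groupby(["sample_id", "group"], observed=True)["value"].mean().reset_index()
    out = []
    for a, b in _pairs(sorted(means["group"].unique())):
        xa = means.loc[means["group"] == a, "value"].to_numpy()
        xb = means.loc[means["group"] == b, "value"].to_numpy()
        est = float(xb.mean() - xa.mean())
        if len(xa) < 2 or len(xb) < 2:
            out.append(((a, b), est, np.nan))
            continue
        if est == 0 and np.ptp(np.concatenate([xa, xb])) == 0:
            out.append(((a, b), 0.0, 1.0))
            continue
        p = float(stats.ttest_ind(xb, xa, equal_var=False).pvalue)
        out.append(((a, b), est, p))
    return out


def _mixed_contrasts(df: pd.DataFrame) -> list[tuple[tuple, float, float]]:
    """REML mixed-model pairwise group contrasts: (pair, estimate, p)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ C(group) + C(timepoint_index)", df, groups=df["sample_id"]
        )
        fit = model.fit(reml=True)
    levels = sorted(df["group"].unique())
    names = list(fit.fe_params.index)
    coef_of = {levels[0]: None}
    for lev in levels[1:]:
        name = f"C(group)[T.{lev}]"
        if name not in names:
            raise RuntimeError(f"missing coefficient {name}")
        coef_of[lev] = name
    if not np.isfinite(fit.bse[[coef_of[lev] for lev in levels[1:]]]).all():
        raise RuntimeError("singular mixed fit")
    out = []
    for a, b in _pairs(levels):
        L = np.zeros((1, len(names)))
        if coef_of[b] is not None:
            L[0, names.index(coef_of[b])] += 1.0
        if coef_of[a] is not None:
            L[0, names.index(coef_of[a])] -= 1.0
        tt = fit.t_test(L)
        out.append(((a, b), float(np.squeeze(tt.effect)), float(np.squeeze(tt.pvalue))))
    return out


def compare_profiles(
    tidy: pd.DataFrame,
    assignment: pd.Series,
    factor: str = "phenotype",
    alpha: float = _ALPHA,
) -> pd.DataFrame:
    """Repeated-measures contrasts of metric trajectories.

    ``tidy`` is the long metric table (sample_id, metric, wavelength_nm,
    timepoint_index, value); ``assignment`` maps sample id to phenotype.
    With ``factor='phenotype'`` phenotypes are contrasted within each
    (metric, wavelength); with ``factor='wavelength'`` the wavelengths are
    contrasted within each (metric, phenotype). Returns a tidy table of
    Bonferroni-adjusted pairwise contrasts.
    """
    if factor not in ("phenotype", "wavelength"):
        raise ValueError("factor must be 'phenotype' or 'wavelength'")
    df = tidy.copy()
    df["phenotype"] = df["sample_id"].map(assignment)
    if df["phenotype"].isna().any():
        raise ValueError("assignment missing for some samples")
    group_col = "phenotype" if factor == "phenotype" else "wavelength_nm"
    within_col = "wavelength_nm" if factor == "phenotype" else "phenotype"

    rows = []
    for (metric, within), sub in df.groupby(["metric", within_col], sort=True):
        sub = sub.dropna(subset=["value"]).rename(columns={group_col: "group"})
        sizes = sub.groupby("group", observed=True)["sample_id"].nunique()
        if (sizes < 3).any() or len(sizes) < 2:
            warnings.warn(
                f"{metric}/{within}: groups with <3 samples, skipped", stacklevel=2
            )
            continue
        fallback = False
        try:
            contrasts = _mixed_contrasts(sub)
            if any(not np.isfinite(p) for _, _, p in contrasts):
                raise RuntimeError("non-finite contrast p-value")
        except Exception:
            contrasts = _two_stage_contrasts(sub)
            fallback = True
        fam_size = len(contrasts)
        for pair, est, p in contrasts:
            p_adj = min(p * fam_size, 1.0) if np.isfinite(p) else np.nan
            rows.append(ContrastResult(
                metric=metric, family=f"{within_col}={within}", pair=pair,
                estimate=est, p_raw=p, p_adjusted=p_adj,
                significant=bool(np.isfinite(p_adj) and p_adj < alpha),
                family_size=fam_size, fallback=fallback,
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Cellular traits
# ---------------------------------------------------------------------------


def compact_letter_display(
    levels: Sequence, significant_pairs: set[tuple]
) -> dict:
    """Compact letter display via the insert-and-absorb algorithm.

    Returns {level: letters}; levels sharing any letter are pairwise
    non-significant, and every non-significant pair shares a letter.
    """
    levels = list(levels)
    columns: list[set] = [set(levels)]
    for a, b in significant_pairs:
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb columns contained in another
        columns = [
            c for i, c in enumerate(new_cols)
            if c and not any(c < d or (c == d and i > j) for j, d in enumerate(new_cols))
        ]
    columns.sort(key=lambda c: min(levels.index(x) for x in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lev: "" for lev in levels}
    for i, col in enumerate(columns):
        for lev in levels:
            if lev in col:
                out[lev] += alphabet[i % len(alphabet)]
    return out


@dataclass
class TraitComparison:
    trait: str
    test: str  # "anova_tukey" | "kruskal_bonferroni" | "skipped"
    p_omnibus: float
    pairwise: pd.DataFrame  # pair, estimate, p_adjusted, significant
    letters: dict


def compare_cellular_traits(
    traits: pd.DataFrame,
    assignment: pd.Series,
    trait_columns: Optional[Sequence[str]] = None,
    alpha: float = _ALPHA,
) -> list[TraitComparison]:
    """Compare cellular traits across phenotypes with a normality gate.

    ``traits`` holds one row per sample (indexed or keyed by sample_id);
    the phenotype of each sample comes from ``assignment``. Normal traits
    (Shapiro-Wilk on residuals) use one-way ANOVA + Tukey HSD; non-normal
    traits use Kruskal-Wallis with Bonferroni-adjusted pairwise
    Mann-Whitney tests. Each trait gets a compact letter display ordered by
    descending group mean.
    """
    df = traits.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    groups = assignment.reindex(df.index)
    if groups.isna().any():
        raise ValueError("assignment missing for some samples")
    sizes = groups.value_counts()
    if len(sizes) < 2 or (sizes < 3).any():
        raise ValueError("need >= 2 phenotypes with >= 3 samples each")
    if trait_columns is None:
        trait_columns = [c for c in df.columns if df[c].dtype.kind in "fi" and c != "colony_id"]

    garr = groups.to_numpy()
    levels_all = sorted(pd.unique(garr))
    out = []
    for trait in trait_columns:
        x = df[trait].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xv, gv = x[ok], garr[ok]
        if len(xv) == 0 or np.ptp(xv) == 0:
            warnings.warn(f"trait {trait}: constant, skipped", stacklevel=2)
            out.append(TraitComparison(trait, "skipped", np.nan, pd.DataFrame(), {}))
            continue
        samples = {g: xv[gv == g] for g in levels_all}
        resid = np.concatenate([s - s.mean() for s in samples.values()])
        normal = np.ptp(resid) == 0 or stats.shapiro(resid).pvalue >= alpha
        # order levels by descending group mean for the letter display
        levels = sorted(levels_all, key=lambda g: -samples[g].mean())
        pairs = _pairs(levels)
        rows = []
        if normal:
            p_omni = float(stats.f_oneway(*samples.values()).pvalue)
            tk = pairwise_tukeyhsd(xv, gv, alpha=alpha)
            gu = list(tk.groupsunique)
            tk_map = {}
            k = 0
            for i in range(len(gu)):
                for j in range(i + 1, len(gu)):
                    est, p = float(tk.meandiffs[k]), float(tk.pvalues[k])
                    tk_map[(gu[i], gu[j])] = (est, p)
                    tk_map[(gu[j], gu[i])] = (-est, p)
                    k += 1
            for a, b in pairs:
                est, p = tk_map[(a, b)]
                rows.append({"pair": (a, b), "estimate": est, "p_adjusted": p,
                             "significant": p < alpha})
            test = "anova_tukey"
        else:
            p_omni = float(stats.kruskal(*samples.values()).pvalue)
            fam = len(pairs)
            for a, b in pairs:
                p = float(stats.mannwhitneyu(samples[a], samples[b],
                                             alternative="two-sided").pvalue)
                p_adj = min(p * fam, 1.0)
                rows.append({
                    "pair": (a, b),
                    "estimate": float(np.median(samples[a]) - np.median(samples[b])),
                    "p_adjusted": p_adj, "significant": p_adj < alpha,
                })
            test = "kruskal_bonferroni"
        pw = pd.DataFrame(rows)
        sig_pairs = {tuple(r["pair"]) for _, r in pw.iterrows() if r["significant"]}
        letters = compact_letter_display(levels, sig_pairs)
        out.append(TraitComparison(trait, test, p_omni, pw, letters))
    return out
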