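"""Patch/FRAP decision layer: group statistics and interaction classification.

The patch/FRAP readout compares the lateral mobility of a Fab'-labeled
receptor between cells where a coexpressed partner is free and cells where
the partner has been immobilized by IgG crosslinking.  Complexes whose
lifetime exceeds the characteristic FRAP time co-immobilize the labeled
receptor, lowering its mobile fraction R_f without changing D ("stable");
complexes that exchange many times during the measurement slow the labeled
receptor instead, lowering the apparent D without changing R_f ("transient").

The stable-complex fraction is the relative reduction of the mobile
fraction, ``C = 100 * (R_f,free - R_f,CL) / R_f,free`` (percent), computed
on group means.  Group contrasts use Student's t test for two groups and
one-way ANOVA with Bonferroni-adjusted all-pairs post-hoc tests for more,
reported as mean ± SEM with the conventional significance stars.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionGroup",
    "GroupComparison",
    "InteractionCall",
    "complex_fraction",
    "bootstrap_complex_fraction",
    "compare_groups",
    "classify_interaction",
    "ligand_effect",
    "groups_from_results",
    "p_to_stars",
]

#: significance tiers for star annotation
STAR_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def p_to_stars(p: float) -> str:
    if np.isnan(p):
        return "na"
    for thr, stars in STAR_TIERS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class ConditionGroup:
    """Per-cell fitted mobility values for one experimental condition.

    ``D_values`` contains only cells whose curves recovered enough for a
    reliable D estimate, so ``n_D <= n_Rf``.
    """

    label: dict
    Rf_values: np.ndarray
    D_values: np.ndarray

    def __post_init__(self) -> None:
        self.Rf_values = np.asarray(self.Rf_values, dtype=float)
        self.D_values = np.asarray(self.D_values, dtype=float)
        if self.n_D > self.n_Rf:
            raise ValueError("n_D cannot exceed n_Rf")
        if np.any((self.Rf_values < 0) | (self.Rf_values > 1)):
            raise ValueError("Rf_values must lie in [0, 1]")
        if np.any(self.D_values <= 0):
            raise ValueError("D_values must be > 0")

    @property
    def n_Rf(self) -> int:
        return int(self.Rf_values.size)

    @property
    def n_D(self) -> int:
        return int(self.D_values.size)

    def values(self, variable: str) -> np.ndarray:
        if variable == "Rf":
            return self.Rf_values
        if variable == "D":
            return self.D_values
        raise ValueError(f"variable must be 'Rf' or 'D', got {variable!r}")

    @property
    def name(self) -> str:
        return "|".join(str(self.label.get(k, "")) for k in ("condition", "crosslinked", "ligand"))


def groups_from_results(df: pd.DataFrame) -> dict[str, ConditionGroup]:
    """Build ConditionGroups from a per-cell results table.

    Groups are keyed ``condition|crosslinked|ligand``.  Non-converged fits
    are dropped entirely; fits flagged ``d_reliable == False`` contribute
    R_f but not D.
    """
    out: dict[str, ConditionGroup] = {}
    df = df[df.get("converged", True) != False]  # noqa: E712 - pandas elementwise
    for keys, g in df.groupby(["condition", "crosslinked", "ligand"], sort=False, dropna=False):
        label = dict(zip(("condition", "crosslinked", "ligand"), (str(k) for k in keys)))
        d_ok = g["d_reliable"].astype(bool) if "d_reliable" in g else pd.Series(True, index=g.index)
        grp = ConditionGroup(
            label=label,
            Rf_values=g["Rf_hat"].to_numpy(float),
            D_values=g.loc[d_ok, "D_hat_um2_per_s"].to_numpy(float),
        )
        out[grp.name] = grp
    return out


def complex_fraction(Rf_free: float, Rf_CL: float) -> float:
    """Stable-complex fraction in percent: ``100 (R_f,free - R_f,CL) / R_f,free``.

    Both arguments may be on any common scale (percent or fraction); the
    statistic is scale-invariant.  A crosslinked mobile fraction exceeding
    the free one leaves no mobility reduction to attribute to complexes.
    """
    if not (0.0 < Rf_free):
        raise ValueError(f"Rf_free must be > 0, got {Rf_free}")
    if Rf_CL < 0:
        raise ValueError(f"Rf_CL must be >= 0, got {Rf_CL}")
    if Rf_CL > Rf_free:
        raise ValueError("no mobility reduction; complex fraction undefined")
    return 100.0 * (Rf_free - Rf_CL) / Rf_free


def bootstrap_complex_fraction(
    Rf_free_values: np.ndarray,
    Rf_CL_values: np.ndarray,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the complex fraction over cohort means."""
    rng = np.random.default_rng(seed)
    a = np.asarray(Rf_free_values, float)
    b = np.asarray(Rf_CL_values, float)
    m_free = rng.choice(a, size=(n_boot, a.size)).mean(axis=1)
    m_cl = rng.choice(b, size=(n_boot, b.size)).mean(axis=1)
    cf = 100.0 * (m_free - m_cl) / m_free
    lo, hi = np.quantile(cf, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class GroupComparison:
    """Pairwise contrasts of one variable across condition groups."""

    variable: str
    alpha: float
    omnibus_p: float  # one-way ANOVA p for > 2 groups; NaN for 2 groups
    contrasts: pd.DataFrame  # group_a, group_b, means, SEMs, n, p_raw, p_adj, stars

    def p_adj(self, name_a: str, name_b: str) -> float:
        c = self.contrasts
        m = ((c.group_a == name_a) & (c.group_b == name_b)) | (
            (c.group_a == name_b) & (c.group_b == name_a)
        )
        if not m.any():
            raise KeyError(f"no contrast {name_a} vs {name_b}")
        return float(c.loc[m, "p_adj"].iloc[0])


def _sem(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")


def _pooled_t(v1: np.ndarray, v2: np.ndarray, mse: float, df_err: int) -> float:
    """Post-hoc t test using the ANOVA pooled error variance (Bonferroni family)."""
    denom = math.sqrt(mse * (1.0 / v1.size + 1.0 / v2.size))
    if denom == 0:
        return 1.0 if np.mean(v1) == np.mean(v2) else 0.0
    t = (np.mean(v1) - np.mean(v2)) / denom
    return float(2.0 * stats.t.sf(abs(t), df_err))


def compare_groups(groups: list[ConditionGroup], variable: str, alpha: float = 0.05) -> GroupComparison:
    """Group statistics on R_f or D: t test (2 groups) or ANOVA + Bonferroni (> 2).

    Only cells with reliable estimates enter the D comparison.  Groups with
    fewer than 2 usable values are rejected.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if not (0 < alpha <= 0.5):
        raise ValueError(f"alpha must be in (0, 0.5], got {alpha}")
    samples = [g.values(variable) for g in groups]
    for g, v in zip(groups, samples):
        if v.size < 2:
            raise ValueError(f"group {g.name!r} has n < 2 for {variable}")

    k = len(groups)
    if k == 2:
        omnibus_p = float("nan")
        if np.std(samples[0]) == 0 and np.std(samples[1]) == 0:
            p = 1.0 if np.mean(samples[0]) == np.mean(samples[1]) else 0.0
        else:
            p = float(stats.ttest_ind(samples[0], samples[1], equal_var=True).pvalue)
        p_raw = [p]
        p_adj = [p]
        pairs = [(0, 1)]
    else:
        omnibus_p = float(stats.f_oneway(*samples).pvalue)
        n_total = sum(v.size for v in samples)
        df_err = n_total - k
        mse = sum(float(np.sum((v - v.mean()) ** 2)) for v in samples) / df_err
        pairs = list(itertools.combinations(range(k), 2))
        p_raw = [_pooled_t(samples[i], samples[j], mse, df_err) for i, j in pairs]
        # Bonferroni over all pairwise contrasts
        from statsmodels.stats.multitest import multipletests

        p_adj = list(multipletests(p_raw, alpha=alpha, method="bonferroni")[1])

    rows = []
    for (i, j), pr, pa in zip(pairs, p_raw, p_adj):
        rows.append(
            {
                "group_a": groups[i].name,
                "group_b": groups[j].name,
                "mean_a": float(np.mean(samples[i])),
                "sem_a": _sem(samples[i]),
                "n_a": samples[i].size,
                "mean_b": float(np.mean(samples[j])),
                "sem_b": _sem(samples[j]),
                "n_b": samples[j].size,
                "p_raw": pr,
                "p_adj": pa,
                "stars": p_to_stars(pa),
            }
        )
    return GroupComparison(variable=variable, alpha=alpha, omnibus_p=omnibus_p,
                           contrasts=pd.DataFrame(rows))


@dataclass
class InteractionCall:
    """Classification of one free-vs-crosslinked condition pair."""

    pair: str
    classification: str  # stable | transient | mixed | none
    complex_fraction: float  # percent, from group mean R_f values
    p_Rf: float
    p_D: float
    alpha: float
    mean_Rf_free: float
    mean_Rf_CL: float
    mean_D_free: float
    mean_D_CL: float
    notes: str = ""

    @property
    def stars_Rf(self) -> str:
        return p_to_stars(self.p_Rf)

    @property
    def stars_D(self) -> str:
        return p_to_stars(self.p_D)


def _meta_matches(a: dict, b: dict) -> bool:
    return a.get("condition") == b.get("condition") and a.get("ligand") == b.get("ligand")


def classify_interaction(free: ConditionGroup, crosslinked: ConditionGroup,
                         alpha: float = 0.05, strict: bool = True) -> InteractionCall:
    """Call the interaction stable / transient / mixed / none.

    Decision table on the crosslinked-vs-free contrasts: a significantly
    lower R_f with no significant D change marks stable complexes (their
    fraction computed from the group means); a significantly lower D with
    unchanged R_f marks transient complexes; both significant is reported as
    mixed; neither as none.  "Significantly lower" means adjusted p < alpha
    together with a mean decrease.  ``strict=False`` permits arms whose
    condition labels differ (e.g., an extra coexpressed untagged partner in
    the crosslinked arm).
    """
    if strict and not _meta_matches(free.label, crosslinked.label):
        raise ValueError(
            f"groups must share condition and ligand, got {free.label} vs {crosslinked.label}"
        )

    cmp_rf = compare_groups([free, crosslinked], "Rf", alpha)
    p_rf = float(cmp_rf.contrasts["p_adj"].iloc[0])
    mean_rf_free = float(np.mean(free.Rf_values))
    mean_rf_cl = float(np.mean(crosslinked.Rf_values))
    rf_lower = p_rf < alpha and mean_rf_cl < mean_rf_free

    notes = ""
    mean_d_free = float(np.mean(free.D_values)) if free.n_D else float("nan")
    mean_d_cl = float(np.mean(crosslinked.D_values)) if crosslinked.n_D else float("nan")
    if free.n_D >= 2 and crosslinked.n_D >= 2:
        cmp_d = compare_groups([free, crosslinked], "D", alpha)
        p_d = float(cmp_d.contrasts["p_adj"].iloc[0])
        d_lower = p_d < alpha and mean_d_cl < mean_d_free
    else:
        p_d, d_lower = float("nan"), False
        notes = "too few reliable D estimates for a D contrast"

    if rf_lower and d_lower:
        call = "mixed"
    elif rf_lower:
        call = "stable"
    elif d_lower:
        call = "transient"
    else:
        call = "none"

    if mean_rf_cl <= mean_rf_free:
        cf = complex_fraction(100.0 * mean_rf_free, 100.0 * mean_rf_cl)
    else:
        cf = 0.0
        notes = (notes + "; " if notes else "") + "no mobility reduction"

    return InteractionCall(
        pair=f"{free.name} vs {crosslinked.name}",
        classification=call,
        complex_fraction=cf,
        p_Rf=p_rf,
        p_D=p_d,
        alpha=alpha,
        mean_Rf_free=mean_rf_free,
        mean_Rf_CL=mean_rf_cl,
        mean_D_free=mean_d_free,
        mean_D_CL=mean_d_cl,
        notes=notes,
    )


def ligand_effect(base: ConditionGroup, plus_ligand: ConditionGroup,
                  alpha: float = 0.05, variable: str = "Rf") -> GroupComparison:
    """Two-group contrast of a ± ligand pair, labeled as a ligand effect."""
    cmp = compare_groups([base, plus_ligand], variable, alpha)
    cmp.contrasts["contrast"] = "ligand"
    return cmp
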