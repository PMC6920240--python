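"""qPCR and ChIP-qPCR statistics.

Expression: delta-Ct normalization against housekeeping assays (arithmetic
mean on the Ct scale, i.e. the geometric mean of linear-scale abundances),
then a per-timepoint two-way genotype x treatment ANOVA with interaction,
Type II sums of squares for unbalanced cells, and tiered significance:
high p < 0.0005, medium p < 0.005, low p < 0.05, none otherwise.

ChIP: percent-input enrichment from dilution-adjusted Ct differences, and
a two-way antibody x region ANOVA with Tukey-Kramer all-pairs comparisons
(studentized-range adjusted p, pooled within-cell variance).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ConfigurationError, CtMatrix, ValidationError

logger = logging.getLogger("tfsigkit")

# significance tiers on raw ANOVA p-values (strict upper cuts)
TIER_CUTS = {"high": 0.0005, "medium": 0.005, "low": 0.05}
# star mapping for Tukey-adjusted pairwise p-values
STAR_CUTS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def assign_tier(p: float) -> str:
    """Map a raw p-value to the tier labels used for factorial effects."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < TIER_CUTS["high"]:
        return "high"
    if p < TIER_CUTS["medium"]:
        return "medium"
    if p < TIER_CUTS["low"]:
        return "low"
    return "none"


def assign_stars(p_adj: float) -> str:
    """Map a Tukey-adjusted p to the figure-legend star convention."""
    for cut, stars in STAR_CUTS:
        if p_adj < cut:
            return stars
    return "ns"


# --------------------------------------------------------------------------
# Delta-Ct normalization
# --------------------------------------------------------------------------

@dataclass
class NormalizedCt:
    """Per-sample delta-Ct values for target assays, with metadata.

    delta_ct = Ct_target - mean(housekeeping Ct of the sample); lower
    delta-Ct means higher expression.
    """

    values: pd.DataFrame  # samples x target assays
    metadata: pd.DataFrame


def normalize_ct(ct: CtMatrix, housekeeping: list[str] | None = None) -> NormalizedCt:
    """Subtract each sample's mean housekeeping Ct from its target Cts.

    The arithmetic mean on the Ct scale equals the geometric mean of
    linear-scale (2^-Ct) abundances. Samples whose housekeeping Cts are
    all missing are dropped with a warning.
    """
    hk = list(housekeeping) if housekeeping is not None else ct.housekeeping_assays
    if not hk:
        raise ConfigurationError("no housekeeping assays specified or declared")
    missing = [a for a in hk if a not in ct.values.columns]
    if missing:
        raise ConfigurationError(f"housekeeping assays absent from Ct matrix: {missing}")
    ref = ct.values[hk].mean(axis=1, skipna=True)
    dead = ref.index[ref.isna()]
    if len(dead):
        logger.warning(
            "normalize_ct: dropping %d samples with no housekeeping signal: %s",
            len(dead), list(dead),
        )
    keep = ref.index[ref.notna()]
    targets = [a for a in ct.values.columns if a not in hk]
    delta = ct.values.loc[keep, targets].sub(ref.loc[keep], axis=0)
    return NormalizedCt(values=delta, metadata=ct.metadata.loc[keep])


# --------------------------------------------------------------------------
# Two-way factorial ANOVA (Type II)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectResult:
    F: float
    p: float
    tier: str


@dataclass
class AnovaResult:
    assay: str
    timepoint: str
    genotype: EffectResult
    treatment: EffectResult
    interaction: EffectResult | None  # None when an empty cell forced its removal
    n: int

    def effects(self) -> dict[str, EffectResult | None]:
        return {
            "genotype": self.genotype,
            "treatment": self.treatment,
            "interaction": self.interaction,
        }


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(
    values: np.ndarray | pd.Series,
    genotype: np.ndarray | pd.Series,
    treatment: np.ndarray | pd.Series,
    assay: str = "",
    timepoint: str = "",
) -> AnovaResult:
    """2x2 factorial ANOVA with interaction, Type II sums of squares.

    Type II tests each main effect adjusted for the other main effect
    (the conventional default for unbalanced factorials); the interaction
    is tested against the full model. With an empty design cell the
    interaction term is dropped and reported as None. Zero total variance
    yields F = 0, p = 1 for every effect by convention.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(genotype)
    t = np.asarray(treatment)
    ok = ~np.isnan(y)
    y, g, t = y[ok], g[ok], t[ok]
    g_levels, t_levels = np.unique(g), np.unique(t)
    if len(g_levels) < 2:
        raise ValidationError("factor 'genotype' has a single level")
    if len(t_levels) < 2:
        raise ValidationError("factor 'treatment' has a single level")
    if len(g_levels) > 2 or len(t_levels) > 2:
        raise ValidationError("two_way_anova expects 2x2 designs")
    n = len(y)

    gi = (g == g_levels[1]).astype(float)
    ti = (t == t_levels[1]).astype(float)
    cell_counts = [
        int(np.sum((gi == a) & (ti == b))) for a in (0, 1) for b in (0, 1)
    ]
    with_interaction = min(cell_counts) >= 1
    if not with_interaction:
        logger.warning(
            "two_way_anova(%s, %s): empty design cell, interaction term dropped",
            assay, timepoint,
        )

    ones = np.ones(n)
    X_g = np.column_stack([ones, gi])
    X_t = np.column_stack([ones, ti])
    X_gt = np.column_stack([ones, gi, ti])
    X_full = np.column_stack([ones, gi, ti, gi * ti]) if with_interaction else X_gt

    df_resid = n - (4 if with_interaction else 3)
    if df_resid < 1:
        raise ValidationError(f"zero residual degrees of freedom (n={n})")

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0 or math.isclose(sst, 0.0, abs_tol=1e-12):
        eff = EffectResult(F=0.0, p=1.0, tier="none")
        return AnovaResult(assay, timepoint, eff, eff,
                           eff if with_interaction else None, n)

    rss_full = _rss(y, X_full)
    rss_gt = _rss(y, X_gt)
    ms_resid = rss_full / df_resid

    def _effect(ss: float) -> EffectResult:
        ss = max(ss, 0.0)
        if ms_resid <= 0:
            # perfect fit: infinite evidence unless the effect SS is 0 too
            F = 0.0 if ss == 0 else math.inf
            p = 1.0 if ss == 0 else 0.0
        else:
            F = ss / ms_resid
            p = float(stats.f.sf(F, 1, df_resid))
        return EffectResult(F=F, p=p, tier=assign_tier(p))

    geno = _effect(_rss(y, X_t) - rss_gt)   # SS(G | T)
    treat = _effect(_rss(y, X_g) - rss_gt)  # SS(T | G)
    inter = _effect(rss_gt - rss_full) if with_interaction else None
    return AnovaResult(assay, timepoint, geno, treat, inter, n)


def anova_by_timepoint(
    norm: NormalizedCt,
    fdr: bool = False,
) -> pd.DataFrame:
    """Run the 2x2 genotype x treatment ANOVA for every assay at every
    timepoint; one row per (assay, timepoint, effect) with F, p and tier.

    ``fdr`` adds BH-adjusted p-value columns (across all rows) without
    changing the tiers, which are assigned on raw p-values.
    """
    rows = []
    for tp in sorted(norm.metadata["timepoint"].unique()):
        sel = norm.metadata.index[norm.metadata["timepoint"] == tp]
        meta = norm.metadata.loc[sel]
        for assay in norm.values.columns:
            res = two_way_anova(
                norm.values.loc[sel, assay],
                meta["genotype"], meta["treatment"],
                assay=assay, timepoint=str(tp),
            )
            for effect, er in res.effects().items():
                if er is None:
                    continue
                rows.append(
                    {"assay": assay, "timepoint": str(tp), "effect": effect,
                     "F": er.F, "p": er.p, "tier": er.tier, "n": res.n}
                )
    df = pd.DataFrame(rows, columns=["assay", "timepoint", "effect", "F", "p", "tier", "n"])
    if fdr and len(df):
        from statsmodels.stats.multitest import multipletests
        _, p_adj, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["p_adj"] = p_adj
    return df


# --------------------------------------------------------------------------
# ChIP-qPCR percent input and binding comparison
# --------------------------------------------------------------------------

def percent_input(ip_ct: float, input_ct: float, input_fraction: float = 0.01) -> float:
    """Percent of input chromatin recovered by the immunoprecipitation.

    The input Ct is first adjusted for the dilution (a 1% input would
    have amplified log2(100) cycles earlier had the full sample been
    used): adjusted_input = input_ct - log2(1/input_fraction), then
    percent_input = 100 * 2^(adjusted_input - ip_ct).
    """
    if not (0.0 < input_fraction <= 1.0):
        raise ConfigurationError(f"input_fraction must be in (0, 1], got {input_fraction}")
    if math.isnan(ip_ct) or math.isnan(input_ct):
        raise ValidationError("percent_input requires non-missing Ct values")
    adjusted_input = input_ct - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - ip_ct)


@dataclass(frozen=True)
class ChipEnrichment:
    antibody: str      # "target_antibody" | "control_IgG"
    region_kind: str   # "binding" | "nonbinding"
    region: str
    percent_input: float

    def __post_init__(self):
        if self.percent_input <= 0:
            raise ValidationError("percent_input must be > 0")
        if self.antibody not in ("target_antibody", "control_IgG"):
            raise ValidationError(f"unknown antibody {self.antibody!r}")
        if self.region_kind not in ("binding", "nonbinding"):
            raise ValidationError(f"unknown region kind {self.region_kind!r}")


def tukey_hsd(groups: list[np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer all-pairs comparisons.

    For each pair (i, j): q = |mean_i - mean_j| / sqrt(s2/2 * (1/ni + 1/nj))
    with s2 the pooled within-group variance, referred to the studentized
    range distribution with k groups and the pooled residual df. Unequal
    group sizes use the Kramer correction (the harmonic form above).
    """
    groups = [np.asarray(gr, dtype=float) for gr in groups]
    k = len(groups)
    if k < 2:
        raise ValidationError("tukey_hsd needs >= 2 groups")
    for i, gr in enumerate(groups):
        if len(gr) < 2:
            raise ValidationError(f"group {i} has fewer than 2 values")
    ns = np.array([len(gr) for gr in groups])
    means = np.array([gr.mean() for gr in groups])
    df_resid = int(ns.sum()) - k
    if df_resid < 1:
        raise ValidationError("pooled residual degrees of freedom < 1")
    s2 = sum(float(np.sum((gr - gr.mean()) ** 2)) for gr in groups) / df_resid
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = math.sqrt(s2 / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            q = 0.0 if diff == 0 else math.inf
        else:
            q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df_resid))
        p_adj = min(max(p_adj, 0.0), 1.0)
        rows.append(
            {"group_i": i, "group_j": j, "diff": diff, "q": q,
             "p_adj": p_adj, "stars": assign_stars(p_adj)}
        )
    return pd.DataFrame(rows, columns=["group_i", "group_j", "diff", "q", "p_adj", "stars"])


def compare_binding(enrichments: list[ChipEnrichment]) -> tuple[AnovaResult, pd.DataFrame]:
    """Two-way antibody x region ANOVA on percent-input with Tukey-Kramer
    pairwise comparisons of the four design cells.

    Returns the ANOVA result (factors relabelled genotype->antibody,
    treatment->region internally) and a pairwise table whose cells are
    labelled "<antibody>:<region_kind>".
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for e in enrichments:
        cells.setdefault((e.antibody, e.region_kind), []).append(e.percent_input)
    thin = {cell: v for cell, v in cells.items() if len(v) < 2}
    if thin:
        raise ValidationError(
            f"cells with fewer than 2 replicates: {sorted(thin)}"
        )
    y = np.array([v for vals in cells.values() for v in vals])
    ab = np.array([c[0] for c, vals in cells.items() for _ in vals])
    rg = np.array([c[1] for c, vals in cells.items() for _ in vals])
    anova = two_way_anova(y, ab, rg, assay="percent_input", timepoint="chip")

    labels = sorted(cells)
    pair = tukey_hsd([np.array(cells[lab]) for lab in labels])
    pair = pair.assign(
        cell_i=[f"{labels[i][0]}:{labels[i][1]}" for i in pair["group_i"]],
        cell_j=[f"{labels[j][0]}:{labels[j][1]}" for j in pair["group_j"]],
    )[["cell_i", "cell_j", "diff", "q", "p_adj", "stars"]]
    return anova, pair
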