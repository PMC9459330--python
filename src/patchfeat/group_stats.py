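"""Two-group statistics for the extracted features.

The layer mirrors the statistical recipe of the study this package
reproduces: per-feature two-group tests gated on normality (Shapiro–Wilk on
each group, α = 0.05) plus an equal-variance check (Levene), choosing an
unpaired Student's t when both pass and a two-sided Mann–Whitney U
otherwise; a mixed-design ANOVA (between: genotype; within: current step;
subject: cell) for the F–I data; an ANCOVA slope-homogeneity test for the
rebound regression; two-sample Kolmogorov–Smirnov tests for pooled event
distributions; and Bonferroni adjustment for post-hoc use.  No correction is
applied across the feature family (per-feature p-values are reported as-is).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .trace_model import CellRecord, apply_inclusion_criteria
from . import intrinsic_features as feat
from . import psc_events as psc

__all__ = [
    "GroupComparison",
    "AncovaResult",
    "MixedAnovaResult",
    "StudyReport",
    "gated_two_group_test",
    "fi_mixed_anova",
    "ancova_slopes",
    "ks_two_sample",
    "bonferroni_adjust",
    "run_study",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    feature: str
    test_used: str  # students_t | mann_whitney | ks
    statistic: float
    p_value: float
    group_summaries: Dict[str, dict] = field(default_factory=dict)
    alpha: float = ALPHA
    gate: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _summary(v: np.ndarray) -> dict:
    n = len(v)
    return {
        "n": int(n),
        "mean": float(np.mean(v)) if n else float("nan"),
        "sem": float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
    }


def gated_two_group_test(
    x: Sequence[float],
    y: Sequence[float],
    feature: str = "",
    alpha: float = ALPHA,
    variance_gate: bool = True,
    labels: Tuple[str, str] = ("WT", "Tg"),
) -> GroupComparison:
    """Normality-gated unpaired two-group test.

    Shapiro–Wilk is run on each group; if both pass at ``alpha`` and (when
    ``variance_gate``) Levene's test finds no variance difference, an
    unpaired Student's t-test is used, otherwise a two-sided Mann–Whitney U.
    The gate outcome is recorded on the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    for v, lab in ((x, labels[0]), (y, labels[1])):
        if len(v) < 3:
            raise ValueError(f"group {lab!r} has n={len(v)} < 3 for feature {feature!r}")
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    normal = sw_x > alpha and sw_y > alpha
    lev_p = stats.levene(x, y).pvalue if variance_gate else float("nan")
    equal_var = (lev_p > alpha) if variance_gate else True
    gate = {"shapiro_p_x": float(sw_x), "shapiro_p_y": float(sw_y), "levene_p": float(lev_p)}
    if normal and equal_var:
        res = stats.ttest_ind(x, y)
        test, stat, p = "students_t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        test, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
    return GroupComparison(
        feature=feature, test_used=test, statistic=stat, p_value=p,
        group_summaries={labels[0]: _summary(x), labels[1]: _summary(y)},
        alpha=alpha, gate=gate,
    )


@dataclass
class MixedAnovaResult:
    F_genotype: float
    p_genotype: float
    df_genotype: Tuple[int, int]
    F_interaction: float
    p_interaction: float
    df_interaction: Tuple[int, int]
    n_cells: Dict[str, int]


def fi_mixed_anova(fi: pd.DataFrame) -> MixedAnovaResult:
    """Mixed-design ANOVA on the F–I table (between: genotype, within: step).

    ``fi`` is long format with columns cell_id, genotype, step_pA, n_spikes.
    Cells missing any step level are dropped (the design must be complete per
    subject).  Returns F and p for the genotype main effect and the
    genotype × step interaction.
    """
    import pingouin as pg

    required = {"cell_id", "genotype", "step_pA", "n_spikes"}
    if not required.issubset(fi.columns):
        raise ValueError(f"F–I table must have columns {sorted(required)}")
    steps = fi["step_pA"].unique()
    if len(steps) < 2:
        raise ValueError("at least 2 current steps required")
    complete = fi.groupby("cell_id")["step_pA"].nunique()
    keep = complete[complete == len(steps)].index
    data = fi[fi["cell_id"].isin(keep)].copy()
    counts = data.groupby("genotype")["cell_id"].nunique()
    if len(counts) != 2 or counts.min() < 2:
        raise ValueError("need >= 2 complete cells in each of two genotype groups")
    aov = pg.mixed_anova(
        data=data, dv="n_spikes", within="step_pA", subject="cell_id", between="genotype"
    )
    aov = aov.set_index("Source")
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    g = aov.loc["genotype"]
    ix = aov.loc["Interaction"]
    return MixedAnovaResult(
        F_genotype=float(g["F"]),
        p_genotype=float(g[pcol]),
        df_genotype=(int(g["DF1"]), int(g["DF2"])),
        F_interaction=float(ix["F"]),
        p_interaction=float(ix[pcol]),
        df_interaction=(int(ix["DF1"]), int(ix["DF2"])),
        n_cells={k: int(v) for k, v in counts.items()},
    )


@dataclass
class AncovaResult:
    slopes: Dict[str, float]
    intercepts: Dict[str, float]
    F_interaction: float
    p_interaction: float
    df: Tuple[int, int]
    n_points: Dict[str, int]

    @property
    def significant(self) -> bool:
        return bool(self.p_interaction < ALPHA)


def ancova_slopes(
    points_g1: pd.DataFrame | np.ndarray,
    points_g2: pd.DataFrame | np.ndarray,
    labels: Tuple[str, str] = ("WT", "Tg"),
) -> AncovaResult:
    """Per-group OLS slopes of V_rebound on V_SS plus a slope-homogeneity test.

    Each ``points_g*`` is an (n, 2) array or a DataFrame with columns
    ``V_ss_mV`` and ``V_rebound_mV``.  The slope difference is tested by the
    F-test on the interaction term of y ~ x·group (two-tailed ANCOVA).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    def _xy(p) -> Tuple[np.ndarray, np.ndarray]:
        if isinstance(p, pd.DataFrame):
            return p["V_ss_mV"].to_numpy(float), p["V_rebound_mV"].to_numpy(float)
        arr = np.asarray(p, dtype=float)
        return arr[:, 0], arr[:, 1]

    x1, y1 = _xy(points_g1)
    x2, y2 = _xy(points_g2)
    for x, lab in ((x1, labels[0]), (x2, labels[1])):
        if len(x) < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 points")
    long = pd.DataFrame(
        {
            "x": np.concatenate([x1, x2]),
            "y": np.concatenate([y1, y2]),
            "group": [labels[0]] * len(x1) + [labels[1]] * len(x2),
        }
    )
    model = smf.ols("y ~ x * C(group)", data=long).fit()
    table = anova_lm(model, typ=2)
    F = float(table.loc["x:C(group)", "F"])
    p = float(table.loc["x:C(group)", "PR(>F)"])
    df = (int(table.loc["x:C(group)", "df"]), int(table.loc["Residual", "df"]))
    if math.isnan(F):  # zero residual variance (exact collinearity): no slope difference
        F, p = 0.0, 1.0
    s1, i1 = np.polyfit(x1, y1, 1)
    s2, i2 = np.polyfit(x2, y2, 1)
    return AncovaResult(
        slopes={labels[0]: float(s1), labels[1]: float(s2)},
        intercepts={labels[0]: float(i1), labels[1]: float(i2)},
        F_interaction=F,
        p_interaction=p,
        df=df,
        n_points={labels[0]: len(x1), labels[1]: len(x2)},
    )


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], feature: str = "",
    labels: Tuple[str, str] = ("WT", "Tg"),
) -> GroupComparison:
    """Two-sided two-sample Kolmogorov–Smirnov test on pooled values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    res = stats.ks_2samp(x, y, alternative="two-sided")
    return GroupComparison(
        feature=feature, test_used="ks", statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries={labels[0]: _summary(x), labels[1]: _summary(y)},
    )


def bonferroni_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p·k)."""
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(1.0, p * len(p))


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

#: Current-clamp features put through the normality-gated test.
GATED_FEATURES = (
    "rmp_mV", "rin_MOhm", "rheobase_pA", "vthresh_mV", "ap_height_mV",
    "ap_fwhm_ms", "sag_ratio", "mahp_mV", "sahp_auc_mVs",
)
#: PSC per-cell summaries, compared by Mann–Whitney (the prescribed test).
PSC_FEATURES = ("psc_amp_pA", "psc_freq_hz")


@dataclass
class StudyReport:
    features: pd.DataFrame
    comparisons: Dict[str, GroupComparison]
    fi: Optional[MixedAnovaResult]
    rebound: Optional[AncovaResult]
    ks: Dict[str, GroupComparison]
    qc: Dict[str, dict]
    alpha: float = ALPHA

    @property
    def flagged(self) -> List[str]:
        """Names of analyses significant at ``alpha``."""
        out = [name for name, c in self.comparisons.items() if c.significant]
        if self.fi is not None and self.fi.p_genotype < self.alpha:
            out.append("fi_genotype")
        if self.fi is not None and self.fi.p_interaction < self.alpha:
            out.append("fi_interaction")
        if self.rebound is not None and self.rebound.significant:
            out.append("rebound_slope")
        out.extend(f"ks_{name}" for name, c in self.ks.items() if c.significant)
        return out

    def to_dict(self) -> dict:
        def comp(c: GroupComparison) -> dict:
            return {
                "test": c.test_used, "statistic": c.statistic, "p": c.p_value,
                "groups": c.group_summaries,
            }

        d: dict = {
            "alpha": self.alpha,
            "qc": self.qc,
            "features": {k: comp(v) for k, v in self.comparisons.items()},
            "ks": {k: comp(v) for k, v in self.ks.items()},
            "flagged": self.flagged,
        }
        if self.fi is not None:
            d["fi_mixed_anova"] = {
                "F_genotype": self.fi.F_genotype, "p_genotype": self.fi.p_genotype,
                "df_genotype": list(self.fi.df_genotype),
                "F_interaction": self.fi.F_interaction,
                "p_interaction": self.fi.p_interaction,
                "df_interaction": list(self.fi.df_interaction),
            }
        if self.rebound is not None:
            d["rebound_ancova"] = {
                "slopes": self.rebound.slopes,
                "F": self.rebound.F_interaction, "p": self.rebound.p_interaction,
                "df": list(self.rebound.df),
            }
        return d

    def to_text(self) -> str:
        lines = ["Two-group study report", "=" * 22, ""]
        for name, c in self.comparisons.items():
            gs = c.group_summaries
            parts = [
                f"{lab}: {s['mean']:.3g} ± {s['sem']:.2g} (n={s['n']})"
                for lab, s in gs.items()
            ]
            mark = " *" if c.significant else ""
            lines.append(f"{name}: {'; '.join(parts)}; {c.test_used}, p={c.p_value:.3g}{mark}")
        if self.fi is not None:
            lines.append(
                f"F-I mixed ANOVA: genotype F{self.fi.df_genotype}={self.fi.F_genotype:.3g}, "
                f"p={self.fi.p_genotype:.3g}; interaction "
                f"F{self.fi.df_interaction}={self.fi.F_interaction:.3g}, "
                f"p={self.fi.p_interaction:.3g}"
            )
        if self.rebound is not None:
            sl = ", ".join(f"{k}: {v:.3g}" for k, v in self.rebound.slopes.items())
            lines.append(
                f"Rebound ANCOVA slopes ({sl}); F{self.rebound.df}="
                f"{self.rebound.F_interaction:.3g}, p={self.rebound.p_interaction:.3g}"
            )
        for name, c in self.ks.items():
            lines.append(f"KS {name}: D={c.statistic:.3g}, p={c.p_value:.3g}")
        lines.append("")
        lines.append(f"Flagged at alpha={self.alpha}: {', '.join(self.flagged) or 'none'}")
        return "\n".join(lines)


def run_study(
    records: Iterable[CellRecord],
    alpha: float = ALPHA,
    psc_threshold_pA: float = psc.DETECTION_THRESHOLD_PA,
    labels: Tuple[str, str] = ("WT", "Tg"),
) -> StudyReport:
    """Full pipeline: QC → feature extraction → per-feature group statistics.

    Excitability-gated cells feed the current-clamp features, F–I mixed ANOVA
    and rebound ANCOVA; PSC-gated cells feed event detection, per-cell
    summaries (Mann–Whitney) and pooled KS comparisons.  The pipeline is
    deterministic: the same records always produce the same report.

    ``records`` may be any iterable — in particular a cohort *generator* —
    and is consumed in a single pass, so sweep arrays are released as soon as
    each cell has been measured.
    """
    qc_info: Dict[str, dict] = {}
    feature_rows: List[dict] = []
    fi_frames: List[pd.DataFrame] = []
    reb_frames: List[pd.DataFrame] = []
    psc_rows: List[dict] = []
    pooled_amp: Dict[str, list] = {lab: [] for lab in labels}
    pooled_freq: Dict[str, list] = {lab: [] for lab in labels}

    for rec in records:
        q_ex = apply_inclusion_criteria(rec, excitability_qc=True, psc_qc=False)
        has_psc = bool(rec.sweeps.get("psc"))
        q_ps = (
            apply_inclusion_criteria(rec, excitability_qc=False, psc_qc=True)
            if has_psc else None
        )
        qc_info[rec.cell_id] = {
            "excitability_included": q_ex.included,
            "psc_included": None if q_ps is None else q_ps.included,
            "reasons": sorted(set(q_ex.reasons + (q_ps.reasons if q_ps else []))),
        }
        if q_ex.included:
            row = feat.extract_cell_features(rec)
            row["qc_flags"] = ";".join(qc_info[rec.cell_id]["reasons"])
            feature_rows.append(row)
            fi_frames.append(feat.fi_table([rec]))
            reb_frames.append(feat.rebound_table([rec]))
        if q_ps is not None and q_ps.included:
            ev = psc.detect_events(rec.sweeps["psc"][0], threshold_pA=psc_threshold_pA)
            s = psc.summarize_cell(ev)
            psc_rows.append(
                {"cell_id": rec.cell_id, "genotype": rec.genotype,
                 "psc_amp_pA": s.mean_amplitude_pA, "psc_freq_hz": s.mean_inst_freq_hz,
                 "psc_n_events": s.n_events}
            )
            if rec.genotype in pooled_amp and len(ev):
                pooled_amp[rec.genotype].extend(ev.amplitudes_pA)
                pooled_freq[rec.genotype].extend(psc.instantaneous_frequency(ev))

    table = pd.DataFrame(feature_rows)
    if len(table) == 0 or any(
        (table.genotype == lab).sum() == 0 for lab in labels
    ):
        raise ValueError("a genotype group is empty after QC")

    psc_table = pd.DataFrame(
        psc_rows, columns=["cell_id", "genotype", "psc_amp_pA", "psc_freq_hz", "psc_n_events"]
    )
    table = table.merge(psc_table.drop(columns="psc_n_events"), on=["cell_id", "genotype"],
                        how="outer")

    comparisons: Dict[str, GroupComparison] = {}
    for name in GATED_FEATURES:
        g1 = table.loc[table.genotype == labels[0], name].to_numpy(float)
        g2 = table.loc[table.genotype == labels[1], name].to_numpy(float)
        g1, g2 = g1[np.isfinite(g1)], g2[np.isfinite(g2)]
        if len(g1) >= 3 and len(g2) >= 3:
            comparisons[name] = gated_two_group_test(g1, g2, feature=name,
                                                     alpha=alpha, labels=labels)
    for name in PSC_FEATURES:
        if name not in table.columns:
            continue
        g1 = table.loc[table.genotype == labels[0], name].to_numpy(float)
        g2 = table.loc[table.genotype == labels[1], name].to_numpy(float)
        g1, g2 = g1[np.isfinite(g1)], g2[np.isfinite(g2)]
        if len(g1) >= 3 and len(g2) >= 3:
            res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
            comparisons[name] = GroupComparison(
                feature=name, test_used="mann_whitney",
                statistic=float(res.statistic), p_value=float(res.pvalue),
                group_summaries={labels[0]: _summary(g1), labels[1]: _summary(g2)},
                alpha=alpha,
            )

    fi_res: Optional[MixedAnovaResult] = None
    fi = pd.concat(fi_frames, ignore_index=True) if fi_frames else pd.DataFrame()
    if len(fi):
        try:
            fi_res = fi_mixed_anova(fi)
        except ValueError:
            fi_res = None

    reb_res: Optional[AncovaResult] = None
    reb = pd.concat(reb_frames, ignore_index=True) if reb_frames else pd.DataFrame()
    if len(reb):
        p1 = reb[reb.genotype == labels[0]]
        p2 = reb[reb.genotype == labels[1]]
        if len(p1) >= 3 and len(p2) >= 3:
            reb_res = ancova_slopes(p1, p2, labels=labels)

    ks: Dict[str, GroupComparison] = {}
    if len(pooled_amp[labels[0]]) and len(pooled_amp[labels[1]]):
        ks["amplitude"] = ks_two_sample(pooled_amp[labels[0]], pooled_amp[labels[1]],
                                        feature="psc_amplitude", labels=labels)
        ks["inst_freq"] = ks_two_sample(pooled_freq[labels[0]], pooled_freq[labels[1]],
                                        feature="psc_inst_freq", labels=labels)

    return StudyReport(features=table, comparisons=comparisons, fi=fi_res,
                       rebound=reb_res, ks=ks, qc=qc_info, alpha=alpha)
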