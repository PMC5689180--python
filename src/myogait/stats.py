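"""Cross-species comparison statistics, regressions and sensitivity driver.

Per homologous muscle pair, species cohorts are compared with a two-sample
t-test (Welch by default — cohorts are small and unequal, e.g. 16 mice vs
5 humans) and the family of p-values is corrected with the Holm-Bonferroni
step-down procedure at alpha = 0.05.  Fat-fraction regressions relate
cohort-mean fiber excursions to imaging-derived fat fractions by ordinary
least squares, separately for upper-leg and lower-leg muscles.  The
sensitivity driver re-runs the excursion pipeline with one muscle
parameter perturbed at a time (optimal fiber length and tendon slack
length by +/- 1 reported SD; tendon reference strain at its 2 % and 9 %
extremes) and reports mean +/- SD of the absolute normalized excursion
change across the compared muscles.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .curves import CurveSet
from .excursion import muscle_excursion
from .model import HomologMap, JointKinematics, MusculoskeletalModel

__all__ = [
    "ComparisonRow",
    "RegressionResult",
    "SensitivityReport",
    "two_sample_t",
    "holm_bonferroni",
    "compare_species",
    "comparison_summary",
    "fat_fraction_regression",
    "sensitivity_analysis",
    "SENSITIVITY_PARAMETERS",
]


@dataclass
class ComparisonRow:
    """One homolog pair's cross-species test result."""

    mouse_muscle: str
    human_muscle: str
    mean_mouse: float
    sd_mouse: float
    mean_human: float
    sd_human: float
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool
    direction: str  # mouse_larger | human_larger | none


@dataclass
class RegressionResult:
    """OLS fit of fat fraction against cohort-mean fiber excursion."""

    group: str
    slope: float
    intercept: float
    r2: float
    p: float  # slope F-test (== two-sided t on the slope for simple OLS)
    n: int
    excluded: list[str] = field(default_factory=list)


@dataclass
class SensitivityReport:
    """Excursion sensitivity to one perturbed parameter, one species."""

    parameter: str
    species: str
    per_muscle_delta: dict  # muscle -> |delta E| (normalized by nominal L_o)
    mean_delta: float
    sd_delta: float
    skipped: list[str] = field(default_factory=list)


def two_sample_t(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default).

    Returns ``(t, p)``.  Degenerate case: both samples with zero variance
    and equal means gives ``(0, 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x) == 0.0 and np.var(y) == 0.0 and np.mean(x) == np.mean(y):
        return 0.0, 1.0
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def holm_bonferroni(p_raw, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Bonferroni step-down correction.

    Sorts p ascending and rejects p_(i) while p_(i) <= alpha/(m - i + 1);
    adjusted p-values are the running maximum of (m - i + 1) * p_(i),
    capped at 1, returned in input order.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return np.asarray(p_adj, dtype=float), np.asarray(reject, dtype=bool)


def compare_species(
    mouse_table,
    human_table,
    homologs: HomologMap,
    metric: str = "excursion",
    alpha: float = 0.05,
    equal_var: bool = False,
    joint: str | None = None,
) -> list[ComparisonRow]:
    """Per-homolog-pair Welch t-tests with Holm-Bonferroni correction.

    ``metric`` selects the compared quantity: ``excursion`` (normalized
    fiber excursion E), ``moment_arm`` (magnitude of the cycle-averaged
    normalized moment arm; requires ``joint``), or ``joint_excursion``
    (pairs are joint names in both species).
    """
    def samples(table, muscle):
        if metric == "excursion":
            df = table.excursions
            v = df.loc[df["muscle"] == muscle, "E"]
        elif metric == "moment_arm":
            df = table.moment_arms
            sel = df["muscle"] == muscle
            if joint is not None:
                sel &= df["joint"] == joint
            v = df.loc[sel].groupby("subject_id")["r_mean_normalized_abs"].mean()
        elif metric == "joint_excursion":
            df = table.joint_excursions
            v = df.loc[df["joint"] == muscle, "excursion_deg"]
        else:
            raise ValueError(f"unknown metric '{metric}'")
        return v.to_numpy(dtype=float)

    raw = []
    for mouse_m, human_m in homologs:
        x = samples(mouse_table, mouse_m)
        y = samples(human_table, human_m)
        if x.size == 0 or y.size == 0:
            raise KeyError(
                f"homolog pair ({mouse_m}, {human_m}): muscle missing from a "
                "cohort table"
            )
        t, p = two_sample_t(x, y, equal_var=equal_var)
        raw.append((mouse_m, human_m, x, y, t, p))

    p_adj, reject = holm_bonferroni([r[5] for r in raw], alpha=alpha)
    rows = []
    for (mouse_m, human_m, x, y, t, p), pa, rej in zip(raw, p_adj, reject):
        if not rej:
            direction = "none"
        elif np.mean(x) > np.mean(y):
            direction = "mouse_larger"
        else:
            direction = "human_larger"
        rows.append(
            ComparisonRow(
                mouse_muscle=mouse_m,
                human_muscle=human_m,
                mean_mouse=float(np.mean(x)),
                sd_mouse=float(np.std(x, ddof=1)),
                mean_human=float(np.mean(y)),
                sd_human=float(np.std(y, ddof=1)),
                t=t, p_raw=p, p_adjusted=float(pa),
                significant=bool(rej), direction=direction,
            )
        )
    return rows


def comparison_summary(rows: list[ComparisonRow]) -> dict:
    """Family summaries: direction counts, differences and mean ratio.

    Over pairs significantly larger in humans, reports the mean +/- SD of
    the human-minus-mouse difference and of the mouse/human ratio of
    cohort means (the latter in percent).
    """
    n_human = [r for r in rows if r.direction == "human_larger"]
    n_mouse = [r for r in rows if r.direction == "mouse_larger"]
    n_none = [r for r in rows if r.direction == "none"]
    diffs = np.array([r.mean_human - r.mean_mouse for r in n_human])
    ratios = np.array(
        [r.mean_mouse / r.mean_human for r in n_human if r.mean_human != 0]
    )
    return {
        "n_pairs": len(rows),
        "n_human_larger": len(n_human),
        "n_mouse_larger": len(n_mouse),
        "n_not_significant": len(n_none),
        "mean_difference_human_minus_mouse": float(diffs.mean()) if diffs.size else float("nan"),
        "sd_difference_human_minus_mouse": float(diffs.std(ddof=1)) if diffs.size > 1 else float("nan"),
        "mean_ratio_mouse_over_human_pct": float(ratios.mean() * 100) if ratios.size else float("nan"),
        "sd_ratio_mouse_over_human_pct": float(ratios.std(ddof=1) * 100) if ratios.size > 1 else float("nan"),
    }


def fat_fraction_regression(
    excursions: dict,
    fat: dict,
    group_map: dict,
    exclusions: list[str] | None = None,
    merges: list[tuple[list[str], str]] | None = None,
) -> list[RegressionResult]:
    """Per-group OLS of fat fraction on cohort-mean fiber excursion.

    ``merges`` entries average the excursions of several muscles into one
    merged predictor before regression (e.g. the two peroneus heads whose
    fat fraction was imaged as one muscle).  ``exclusions`` removes
    muscles (outliers, or muscles without imaging data) before fitting.
    Each group needs n >= 3 after filtering.
    """
    exclusions = list(exclusions or [])
    merges = list(merges or [])
    exc = dict(excursions)
    groups = dict(group_map)
    for members, merged_name in merges:
        present = [m for m in members if m in exc]
        if not present:
            continue
        exc[merged_name] = float(np.mean([exc[m] for m in present]))
        groups.setdefault(merged_name, groups.get(present[0]))
        for m in present:
            exc.pop(m, None)

    results = []
    for group in ("upper_leg", "lower_leg"):
        candidates = [m for m in exc if groups.get(m) == group]
        if not candidates:  # group not represented in the data at all
            continue
        xs, ys = [], []
        for muscle in candidates:
            if muscle in exclusions or muscle not in fat:
                continue
            xs.append(exc[muscle])
            ys.append(fat[muscle])
        if len(xs) < 3:
            raise ValueError(
                f"group '{group}': {len(xs)} muscles after exclusions/merges; "
                "need at least 3 for a regression"
            )
        excluded = [m for m in exclusions if groups.get(m) == group]
        if np.var(ys) == 0.0:  # flat response: no explainable variance
            results.append(
                RegressionResult(group=group, slope=0.0,
                                 intercept=float(np.mean(ys)), r2=0.0, p=1.0,
                                 n=len(xs), excluded=excluded)
            )
            continue
        X = sm.add_constant(np.asarray(xs))
        fit = sm.OLS(np.asarray(ys), X).fit()
        results.append(
            RegressionResult(
                group=group,
                slope=float(fit.params[1]),
                intercept=float(fit.params[0]),
                r2=float(fit.rsquared),
                p=float(fit.f_pvalue),
                n=len(xs),
                excluded=excluded,
            )
        )
    return results


#: one-at-a-time perturbations applied by :func:`sensitivity_analysis`
SENSITIVITY_PARAMETERS = (
    "L_o_plus_sd", "L_o_minus_sd", "L_s_plus_sd", "L_s_minus_sd",
    "eps_2pct", "eps_9pct",
)


def _perturbed(model: MusculoskeletalModel, parameter: str):
    """Deep-copied model with one architecture parameter shifted; lists
    muscles skipped for missing SDs."""
    m = copy.deepcopy(model)
    skipped = set()
    sign = 1.0 if parameter.endswith("plus_sd") else -1.0
    for u in m.units:
        if parameter in ("L_o_plus_sd", "L_o_minus_sd"):
            if u.L_o_sd is None:  # SD not reported for this unit
                skipped.add(u.parent_muscle)
                continue
            u.L_o = max(u.L_o + sign * u.L_o_sd, 1e-6)
        elif parameter in ("L_s_plus_sd", "L_s_minus_sd"):
            if u.L_s_sd is None:
                skipped.add(u.parent_muscle)
                continue
            u.L_s = max(u.L_s + sign * u.L_s_sd, 0.0)
    if skipped:
        warnings.warn(
            f"{parameter}: skipped muscles without a reported SD: "
            f"{sorted(skipped)}", stacklevel=3,
        )
    return m, skipped


def sensitivity_analysis(
    model: MusculoskeletalModel,
    curves: CurveSet,
    mean_kin: JointKinematics,
    muscles: list[str] | None = None,
    parameters=SENSITIVITY_PARAMETERS,
) -> list[SensitivityReport]:
    """One-at-a-time parameter sensitivity of fiber excursions.

    Runs the dual-activation excursion on the cohort-mean kinematics with
    nominal parameters, then once per perturbation (other parameters held
    at defaults), and reports per-muscle |delta E| normalized by the
    nominal optimal fiber length, with mean +/- SD across the muscle set.
    Muscles without a reported SD are skipped with a warning for the SD
    perturbations.
    """
    if muscles is None:
        muscles = list(model.muscles)

    def run(m: MusculoskeletalModel, c: CurveSet, muscle: str) -> float:
        return muscle_excursion(m, c, mean_kin, muscle).E

    nominal = {m: run(model, curves, m) for m in muscles}
    # E is normalized by each unit's own L_o; to normalize the change by
    # the *nominal* L_o, rescale perturbed-L_o excursions accordingly.
    nominal_L_o = {m: model.muscles[m][0].L_o for m in muscles}

    reports = []
    for parameter in parameters:
        if parameter.startswith("eps"):
            eps = 0.02 if parameter == "eps_2pct" else 0.09
            pert_model, skipped = model, set()
            pert_curves = CurveSet(eps_o=eps)
        else:
            pert_model, skipped = _perturbed(model, parameter)
            pert_curves = curves
        deltas = {}
        for m in muscles:
            if m in skipped:
                continue
            E_pert = run(pert_model, pert_curves, m)
            scale = pert_model.muscles[m][0].L_o / nominal_L_o[m]
            deltas[m] = abs(E_pert * scale - nominal[m])
        vals = np.array(list(deltas.values()))
        reports.append(
            SensitivityReport(
                parameter=parameter,
                species=model.species,
                per_muscle_delta=deltas,
                mean_delta=float(vals.mean()) if vals.size else float("nan"),
                sd_delta=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                skipped=sorted(skipped),
            )
        )
    return reports
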