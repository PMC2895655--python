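"""Enhancer co-regulation logic from dual-luciferase titration assays.

Each enhancer drives a firefly luciferase reporter co-transfected with
a Renilla normalisation control and expression constructs for two
transcription factors at 1 ng / 10 ng doses, alone or in combination.
Replicate activities (firefly/Renilla) are normalised to the
reporter-only condition, giving fold changes f_A, f_B and f_AB. The
baseline-corrected additive expectation is

    E_add = f_A + f_B - 1

(excess activities over the reporter-only baseline of 1 add). An
enhancer is classified *cooperative* when f_AB significantly exceeds
E_add, *repressive* (X on Y) when X alone is inactive, Y alone
activates, and the combination falls significantly below Y alone —
with dose dependence checked across the repressor titration — and
*additive* when at least one factor activates and f_AB is statistically
indistinguishable from E_add. Tests are unpaired two-tailed t-tests on
log activities; significance tiers follow the conventional star
annotation (p < 0.05 / 0.01 / 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "summarize_fold_changes",
    "additive_expectation",
    "classify_mode",
    "star_annotation",
    "classify_sufficiency",
    "ModeCall",
    "SufficiencyRecord",
]

REQUIRED_COLUMNS = (
    "enhancer",
    "dose_A_ng",
    "dose_B_ng",
    "replicate",
    "activity_firefly",
    "activity_renilla",
)


@dataclass
class ModeCall:
    """Classified co-regulation mode of one enhancer."""

    enhancer: str
    mode: str
    p_value: float
    stars: str
    dose_dependence: bool = False
    f_A: float = float("nan")
    f_B: float = float("nan")
    f_AB: float = float("nan")
    expected_additive: float = float("nan")


@dataclass
class SufficiencyRecord:
    """Ectopic-induction outcome of one gene under three conditions."""

    gene: str
    induced_by_A_alone: bool
    induced_by_B_alone: bool
    induced_by_both: bool
    attenuated: bool = False
    cls: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.attenuated and (self.induced_by_A_alone or self.induced_by_B_alone):
            # combination weaker than the active single factor
            self.cls = "attenuated_by_A" if self.induced_by_B_alone else "attenuated_by_B"
        elif self.induced_by_A_alone:
            self.cls = "A_sufficient"
        elif self.induced_by_B_alone:
            self.cls = "B_sufficient"
        elif self.induced_by_both:
            self.cls = "both_required"
        else:
            self.cls = "never_induced"


def _normalized(assay: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(assay.columns)
    if missing:
        raise ValueError(f"assay table is missing columns: {sorted(missing)}")
    if (assay["dose_A_ng"] < 0).any() or (assay["dose_B_ng"] < 0).any():
        raise ValueError("doses must be non-negative")
    if (assay["activity_firefly"] <= 0).any() or (assay["activity_renilla"] <= 0).any():
        raise ValueError("activities must be positive")
    out = assay.copy()
    out["activity"] = out["activity_firefly"] / out["activity_renilla"]
    return out


def _condition_groups(assay: pd.DataFrame) -> dict[tuple[float, float], np.ndarray]:
    groups: dict[tuple[float, float], np.ndarray] = {}
    for (a, b), g in assay.groupby(["dose_A_ng", "dose_B_ng"], sort=True):
        groups[(float(a), float(b))] = g["activity"].to_numpy(dtype=float)
    return groups


def summarize_fold_changes(assay: pd.DataFrame) -> pd.DataFrame:
    """Per-condition fold changes relative to the reporter-only control.

    ``assay`` holds one enhancer's replicate table. Fold change is the
    condition mean of firefly/Renilla activity divided by the
    reporter-only mean; the standard error combines both conditions'
    replicate variances by the delta method:

        se(f)^2 = f^2 * (var_c / (n_c * m_c^2) + var_0 / (n_0 * m_0^2))
    """
    norm = _normalized(assay)
    groups = _condition_groups(norm)
    if (0.0, 0.0) not in groups:
        raise ValueError("no reporter-only (dose 0/0) condition present")
    ctrl = groups[(0.0, 0.0)]
    m0, n0 = ctrl.mean(), len(ctrl)
    v0 = ctrl.var(ddof=1) if n0 > 1 else 0.0
    rows = []
    for (a, b), values in sorted(groups.items()):
        m, n = values.mean(), len(values)
        v = values.var(ddof=1) if n > 1 else 0.0
        f = m / m0
        se = abs(f) * math.sqrt(v / (n * m**2) + v0 / (n0 * m0**2))
        rows.append(
            {
                "dose_A_ng": a,
                "dose_B_ng": b,
                "fold": f,
                "se": se,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def additive_expectation(f_A: float, f_B: float) -> float:
    """Baseline-corrected additive expectation for the combination.

    Each factor's excess activity over the reporter-only baseline of 1
    is additive: E_add = f_A + f_B - 1. A factor at baseline (f = 1)
    contributes nothing, so additive_expectation(f, 1) = f, and the
    published single-factor folds 3.6 and 2.4 combine to 5.0.
    """
    if f_A <= 0 or f_B <= 0:
        raise ValueError("fold changes must be positive")
    return f_A + f_B - 1.0


def uncorrected_sum(f_A: float, f_B: float) -> float:
    """Plain sum of fold changes; looser additive reference."""
    if f_A <= 0 or f_B <= 0:
        raise ValueError("fold changes must be positive")
    return f_A + f_B


_DEGENERATE_VAR = 1e-20


def _welch_t(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> float:
    """Welch t-test p-value robust to zero-variance degenerate inputs."""
    vx = x.var(ddof=1) if len(x) > 1 else 0.0
    vy = y.var(ddof=1) if len(y) > 1 else 0.0
    if vx <= _DEGENERATE_VAR and vy <= _DEGENERATE_VAR:
        same = math.isclose(x.mean(), y.mean(), rel_tol=1e-9, abs_tol=1e-12)
        if alternative == "two-sided":
            return 1.0 if same else 0.0
        diff = x.mean() - y.mean()
        if alternative == "greater":
            return 1.0 if same or diff < 0 else 0.0
        return 1.0 if same or diff > 0 else 0.0
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def _t_vs_constant(
    f_obs: float, se_obs: float, n_obs: int, const: float, se_const: float, df_extra: int
) -> tuple[float, float]:
    """Two-tailed t of an estimated fold against a derived constant.

    The constant (the additive expectation) carries its own delta-method
    standard error from the single-factor conditions.
    """
    se_tot = math.sqrt(se_obs**2 + se_const**2)
    diff = f_obs - const
    if se_tot <= 1e-10:
        same = math.isclose(f_obs, const, rel_tol=1e-9, abs_tol=1e-12)
        return 0.0, (1.0 if same else 0.0)
    t = diff / se_tot
    df = max(n_obs - 1 + df_extra, 1)
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, min(p, 1.0)


def star_annotation(p: float) -> str:
    """Significance stars at the conventional 0.05 / 0.01 / 0.001 tiers."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _pick_primary_doses(
    groups: dict[tuple[float, float], np.ndarray]
) -> tuple[float, float] | None:
    """Choose the combined condition with matched single-factor doses.

    Prefers the highest total dose among combinations (a, b) for which
    both (a, 0) and (0, b) were assayed.
    """
    best = None
    for (a, b) in groups:
        if a > 0 and b > 0 and (a, 0.0) in groups and (0.0, b) in groups:
            if best is None or (a + b) > sum(best):
                best = (a, b)
    return best


def classify_mode(
    assay: pd.DataFrame,
    alpha: float = 0.05,
    additive_rule: str = "baseline_corrected",
) -> ModeCall:
    """Classify one enhancer's co-regulation mode.

    Decision sequence on the primary dose combination (a, b):

    1. each factor is an *activator* iff its alone-fold exceeds 1 and
       the unpaired two-tailed t-test of log activities against the
       reporter-only replicates gives p < alpha;
    2. *cooperative* iff f_AB exceeds the additive expectation
       significantly (t against E_add with delta-method se);
    3. *repressive_X_on_Y* iff X alone is inactive, Y alone activates,
       and f_AB falls significantly below f_Y; dose dependence is a
       one-sided Welch t showing lower combined activity at the higher
       repressor dose;
    4. *additive* iff at least one factor activates and f_AB is not
       significantly different from E_add (sub-additive combinations
       with both factors active also land here);
    5. otherwise *single_factor* (one activator, combination deviating
       from expectation without a repression pattern) or *inactive*.
    """
    norm = _normalized(assay)
    enhancer = str(norm["enhancer"].iloc[0]) if len(norm) else ""
    groups = _condition_groups(norm)
    if (0.0, 0.0) not in groups:
        raise ValueError("no reporter-only (dose 0/0) condition present")
    primary = _pick_primary_doses(groups)
    if primary is None:
        raise ValueError(
            "need A-alone, B-alone and combined conditions at matched doses"
        )
    a, b = primary
    for key in ((a, 0.0), (0.0, b), (a, b), (0.0, 0.0)):
        if len(groups[key]) < 3:
            raise ValueError(
                f"condition {key} has fewer than 3 replicates"
            )

    ctrl = groups[(0.0, 0.0)]
    x_A, x_B, x_AB = groups[(a, 0.0)], groups[(0.0, b)], groups[(a, b)]
    m0 = ctrl.mean()
    f_A, f_B, f_AB = x_A.mean() / m0, x_B.mean() / m0, x_AB.mean() / m0

    log_ctrl = np.log(ctrl)
    p_act_A = _welch_t(np.log(x_A), log_ctrl)
    p_act_B = _welch_t(np.log(x_B), log_ctrl)
    active_A = f_A > 1 and p_act_A < alpha
    active_B = f_B > 1 and p_act_B < alpha

    if additive_rule == "baseline_corrected":
        e_add = additive_expectation(f_A, f_B)
    elif additive_rule == "uncorrected":
        e_add = uncorrected_sum(f_A, f_B)
    else:
        raise ValueError(f"unknown additive_rule {additive_rule!r}")

    def _se_fold(x: np.ndarray) -> float:
        v = x.var(ddof=1) if len(x) > 1 else 0.0
        v0 = ctrl.var(ddof=1) if len(ctrl) > 1 else 0.0
        f = x.mean() / m0
        return abs(f) * math.sqrt(
            v / (len(x) * x.mean() ** 2) + v0 / (len(ctrl) * m0**2)
        )

    se_AB = _se_fold(x_AB)
    se_E = math.sqrt(_se_fold(x_A) ** 2 + _se_fold(x_B) ** 2)
    _, p_add = _t_vs_constant(
        f_AB, se_AB, len(x_AB), e_add, se_E, df_extra=len(x_A) + len(x_B) - 2
    )

    call = ModeCall(
        enhancer=enhancer,
        mode="inactive",
        p_value=1.0,
        stars="",
        f_A=f_A,
        f_B=f_B,
        f_AB=f_AB,
        expected_additive=e_add,
    )

    if f_AB > e_add and p_add < alpha:
        call.mode = "cooperative"
        call.p_value = p_add
    else:
        repressed = None
        if not active_A and active_B:
            p_rep = _welch_t(np.log(x_AB), np.log(x_B), alternative="less")
            if p_rep < alpha and f_AB < f_B:
                repressed = ("repressive_A_on_B", p_rep, "A", b)
        if repressed is None and not active_B and active_A:
            p_rep = _welch_t(np.log(x_AB), np.log(x_A), alternative="less")
            if p_rep < alpha and f_AB < f_A:
                repressed = ("repressive_B_on_A", p_rep, "B", a)
        if repressed is not None:
            mode, p_rep, repressor, fixed_dose = repressed
            call.mode = mode
            call.p_value = p_rep
            call.dose_dependence = _dose_dependence(
                groups, repressor, fixed_dose, alpha
            )
        elif active_A or active_B:
            if p_add >= alpha:
                call.mode = "additive"
                call.p_value = min(p_act_A, p_act_B)
            elif active_A and active_B:
                # sub-additive but both factors contribute
                call.mode = "additive"
                call.p_value = min(p_act_A, p_act_B)
            else:
                call.mode = "single_factor"
                call.p_value = p_act_A if active_A else p_act_B
        else:
            call.mode = "inactive"
            call.p_value = min(p_act_A, p_act_B)

    call.stars = star_annotation(call.p_value)
    return call


def _dose_dependence(
    groups: dict[tuple[float, float], np.ndarray],
    repressor: str,
    fixed_dose: float,
    alpha: float,
) -> bool:
    """One-sided Welch t: combined activity decreases with repressor dose."""
    if repressor == "A":
        combos = sorted(
            (a, vals) for (a, b), vals in groups.items() if a > 0 and b == fixed_dose
        )
    else:
        combos = sorted(
            (b, vals) for (a, b), vals in groups.items() if b > 0 and a == fixed_dose
        )
    if len(combos) < 2:
        return False
    low, high = combos[0][1], combos[-1][1]
    p = _welch_t(np.log(high), np.log(low), alternative="less")
    return p < alpha


def classify_sufficiency(
    records: list[dict] | pd.DataFrame,
) -> tuple[list[SufficiencyRecord], int]:
    """Encode ectopic-induction outcomes and count dual-induction genes.

    Each record carries a gene and the three induction booleans (A
    alone, B alone, both), plus an optional ``attenuated`` flag for
    genes whose combined induction is weaker than the single active
    factor. Returns the classified records and the number of genes
    inducible when both factors are present.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    out = []
    for rec in records:
        for key in ("gene", "induced_by_A_alone", "induced_by_B_alone", "induced_by_both"):
            if key not in rec:
                raise ValueError(f"record missing field {key!r}: {rec}")
        out.append(
            SufficiencyRecord(
                gene=str(rec["gene"]),
                induced_by_A_alone=bool(rec["induced_by_A_alone"]),
                induced_by_B_alone=bool(rec["induced_by_B_alone"]),
                induced_by_both=bool(rec["induced_by_both"]),
                attenuated=bool(rec.get("attenuated", False)),
            )
        )
    count = sum(r.induced_by_both for r in out)
    return out, count
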