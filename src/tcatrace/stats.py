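"""Hypothesis testing for tracing and steady-state metabolomics.

Per-metabolite two-sided t-tests on log10-transformed values (paired for
control/treated designs on the same patient sample, unpaired for
disease/normal comparisons), corrected for multiple comparisons with the
two-stage step-up ("sharpened") adaptive FDR procedure of Benjamini,
Krieger and Yekutieli at Q = 10 %:

  stage 1  linear step-up at q' = q/(1+q); r1 rejections;
  stage 2  estimate the null count m0 = m − r1 and rerun the step-up at
           level q'·m/m0 (equivalently with m0 in place of m).

Per-test q-values are the smallest Q at which the test is rejected, holding
m0 fixed from stage 1 — the semantics in which "q < 0.05" (strong) and
"q < 0.1" (weak) significance tiers are read on volcano plots.  A plain
Benjamini–Hochberg step-up is also exposed (it is stage 1 of the adaptive
procedure) for analyses that used the unsharpened correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BkyResult",
    "paired_log_t",
    "bky_two_stage",
    "bh_step_up",
    "assign_tier",
    "volcano_table",
    "compare_table",
    "STRONG_Q",
    "WEAK_Q",
]

STRONG_Q = 0.05
WEAK_Q = 0.10


@dataclass(frozen=True)
class TestResult:
    """One metabolite's test: effect size, p, bookkeeping flags."""

    log10_fc: float
    p_value: float
    n_used: int
    n_dropped: int = 0
    degenerate: bool = False


def _drop_invalid(control: np.ndarray, treated: np.ndarray, paired: bool):
    """Drop non-finite / non-positive entries (pairwise when paired)."""
    if paired:
        ok = (
            np.isfinite(control)
            & np.isfinite(treated)
            & (control > 0)
            & (treated > 0)
        )
        return control[ok], treated[ok], int((~ok).sum())
    okc = np.isfinite(control) & (control > 0)
    okt = np.isfinite(treated) & (treated > 0)
    return control[okc], treated[okt], int((~okc).sum() + (~okt).sum())


def paired_log_t(
    control,
    treated,
    paired: bool = True,
    log_transform: bool = True,
) -> TestResult:
    """Two-sided t-test on log10 values with a log10 fold-change estimate.

    ``log10_fc`` = mean(log10 treated) − mean(log10 control).  Pairs (or
    entries) that are non-finite or non-positive are dropped with their
    count reported.  Degenerate zero-variance cases are resolved
    explicitly rather than silently:

    * all paired differences identically 0 → p = 1;
    * all differences identical and nonzero (t undefined) → the exact
      two-sided sign-test bound p = 2^(1−n), flagged ``degenerate``;
    * unpaired, both arms constant → p = 1 if equal else the analogous
      exhaustive-permutation bound 2/C(n1+n2, n1), flagged.

    Set ``log_transform=False`` for inputs already on a log-like scale
    (e.g. glog-transformed steady-state matrices); positivity is then not
    required and the effect is the plain mean difference.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if paired and control.shape != treated.shape:
        raise ValueError("paired mode requires equal-length aligned vectors")
    if log_transform:
        control, treated, n_dropped = _drop_invalid(control, treated, paired)
        lc, lt = np.log10(control), np.log10(treated)
    else:
        if paired:
            ok = np.isfinite(control) & np.isfinite(treated)
            lc, lt = control[ok], treated[ok]
            n_dropped = int((~ok).sum())
        else:
            lc = control[np.isfinite(control)]
            lt = treated[np.isfinite(treated)]
            n_dropped = int(control.size - lc.size + treated.size - lt.size)

    if paired:
        n = lc.size
        if n < 2:
            warnings.warn(
                f"fewer than 2 complete pairs (n={n}); p undefined", stacklevel=2
            )
            return TestResult(np.nan, np.nan, n, n_dropped)
        fc = float(lt.mean() - lc.mean())
        d = lt - lc
        if np.ptp(d) == 0:  # all differences identical
            if d[0] == 0:
                return TestResult(0.0, 1.0, n, n_dropped)
            return TestResult(fc, float(2.0 ** (1 - n)), n, n_dropped, True)
        t = sps.ttest_rel(lt, lc)
        return TestResult(fc, float(t.pvalue), n, n_dropped)

    n1, n2 = lc.size, lt.size
    if n1 < 2 or n2 < 2:
        warnings.warn(
            f"fewer than 2 values per arm (n={n1},{n2}); p undefined",
            stacklevel=2,
        )
        return TestResult(np.nan, np.nan, n1 + n2, n_dropped)
    fc = float(lt.mean() - lc.mean())
    if np.ptp(lc) == 0 and np.ptp(lt) == 0:
        if lc[0] == lt[0]:
            return TestResult(0.0, 1.0, n1 + n2, n_dropped)
        # exhaustive two-sided permutation bound for two constant arms
        p = min(1.0, 2.0 / math.comb(n1 + n2, n1))
        return TestResult(fc, p, n1 + n2, n_dropped, True)
    t = sps.ttest_ind(lt, lc)
    return TestResult(fc, float(t.pvalue), n1 + n2, n_dropped)


@dataclass(frozen=True)
class BkyResult:
    """Two-stage adaptive FDR output for one family of tests."""

    q_values: np.ndarray
    rejected: np.ndarray
    m0_hat: int
    r1: int


def _stepup_count(p_sorted: np.ndarray, level: float, m0: int) -> int:
    """Largest k with p_(k) <= k·level/m0 (linear step-up), else 0."""
    m = p_sorted.size
    thresh = level * np.arange(1, m + 1) / m0
    ok = np.nonzero(p_sorted <= thresh)[0]
    return int(ok[-1]) + 1 if ok.size else 0


def bh_step_up(p_values, q: float = WEAK_Q) -> BkyResult:
    """Plain Benjamini–Hochberg linear step-up with standard q-values."""
    p = _check_p(p_values)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    r = _stepup_count(ps, q, m)
    c = np.minimum.accumulate((m * ps / np.arange(1, m + 1))[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(c, 1.0)
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:r]] = True
    return BkyResult(qvals, rejected, m, r)


def _check_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bky_two_stage(p_values, q: float = WEAK_Q) -> BkyResult:
    """Two-stage step-up (Benjamini–Krieger–Yekutieli) adaptive FDR.

    Stage 1 runs the linear step-up at q' = q/(1+q) giving r1 rejections;
    with 0 < r1 < m the null count is estimated as m0 = m − r1 and stage 2
    reruns the step-up at q' with m0 in the denominator.  r1 = 0 rejects
    nothing, r1 = m rejects everything (per the procedure's definition).

    q-values hold m0 fixed and invert the stage-2 threshold: with
    c_i = min_{j>=i} m0·p_(j)/j (the step-up transform), the smallest q at
    which test i is rejected satisfies c_i = q/(1+q), i.e. q_i =
    c_i/(1−c_i), capped at 1.  Rejection at level q is exactly q_i <= q,
    and q-values are non-decreasing in p.
    """
    if not 0 < q < 1:
        raise ValueError(f"q={q} outside (0, 1)")
    p = _check_p(p_values)
    m = p.size
    qprime = q / (1.0 + q)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    r1 = _stepup_count(ps, qprime, m)
    m0 = max(m - r1, 1)
    r2 = _stepup_count(ps, qprime, m0)
    c = np.minimum.accumulate((m0 * ps / np.arange(1, m + 1))[::-1])[::-1]
    c = np.minimum(c, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q_sorted = np.where(c < 1.0, c / (1.0 - c), np.inf)
    q_sorted = np.minimum(q_sorted, 1.0)
    qvals = np.empty(m)
    qvals[order] = q_sorted
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:r2]] = True
    return BkyResult(qvals, rejected, m0, r1)


def assign_tier(
    q_value: float, strong: float = STRONG_Q, weak: float = WEAK_Q
) -> str:
    """Volcano significance tier: strong (q<0.05), weak (q<0.1) or ns."""
    if np.isnan(q_value):
        return "ns"
    if q_value < strong:
        return "strong"
    if q_value < weak:
        return "weak"
    return "ns"


def volcano_table(
    records: pd.DataFrame, strong: float = STRONG_Q, weak: float = WEAK_Q
) -> pd.DataFrame:
    """Plot-ready volcano table: log10_fc, −log10(q) and tier columns."""
    out = records.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_q"] = -np.log10(out["q_value"])
    out["tier"] = [assign_tier(qv, strong, weak) for qv in out["q_value"]]
    return out


def compare_table(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    value_col: str,
    paired: bool = True,
    q: float = WEAK_Q,
    fdr_method: str = "bky",
    control_condition: str = "control",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-metabolite differential test over a tidy value table.

    ``values`` has columns (sample_id, metabolite, <value_col>); metadata
    supplies condition and, for paired mode, pair_id.  Exactly two
    conditions must be present; the non-control one is "treated".
    Metabolites with undefined tests (too few complete pairs, or NaN-only
    values such as undefined PC/PDH ratios) are excluded with a warning and
    do not enter the FDR family.
    """
    meta = metadata.set_index("sample_id")
    conditions = sorted(meta["condition"].unique())
    if control_condition not in conditions or len(conditions) != 2:
        raise ValueError(
            f"need exactly two conditions incl. {control_condition!r}, got "
            f"{conditions}"
        )
    treated_condition = next(c for c in conditions if c != control_condition)

    df = values.merge(
        meta[["condition"] + (["pair_id"] if paired else [])],
        left_on="sample_id",
        right_index=True,
    )
    rows = []
    excluded = []
    for met, grp in df.groupby("metabolite", sort=True):
        if paired:
            wide = grp.pivot_table(
                index="pair_id", columns="condition", values=value_col,
                aggfunc="mean",
            )
            if (
                control_condition not in wide
                or treated_condition not in wide
            ):
                excluded.append(met)
                continue
            ctl = wide[control_condition].to_numpy()
            trt = wide[treated_condition].to_numpy()
        else:
            ctl = grp.loc[grp["condition"] == control_condition, value_col]
            trt = grp.loc[grp["condition"] == treated_condition, value_col]
            ctl, trt = ctl.to_numpy(), trt.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = paired_log_t(ctl, trt, paired=paired, log_transform=log_transform)
        if not np.isfinite(res.p_value):
            excluded.append(met)
            continue
        rows.append(
            {
                "metabolite": met,
                "log10_fc": res.log10_fc,
                "p_value": res.p_value,
                "n_used": res.n_used,
                "n_dropped": res.n_dropped,
                "degenerate": res.degenerate,
            }
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} metabolite(s) excluded (undefined test): "
            f"{excluded}",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no testable metabolites")
    out = pd.DataFrame(rows)
    if fdr_method == "bky":
        fdr = bky_two_stage(out["p_value"].to_numpy(), q)
    elif fdr_method == "bh":
        fdr = bh_step_up(out["p_value"].to_numpy(), q)
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    out["q_value"] = fdr.q_values
    out["rejected"] = fdr.rejected
    return volcano_table(out)
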