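"""Group statistics and report rendering.

Cross-sectional group tests, longitudinal within-group tests, and pointwise
curve comparisons, all via the two-sample Student's t-test (pooled variance,
two-sided; Welch available behind a flag).  Group values are reported as
mean +- SEM.  Significance tiers 0.05 / 0.01 / 0.001 render as * / ** / ***
for between-group contrasts and # / ## / ### for between-timepoint
contrasts, mirroring the usual figure conventions.

Pointwise curve tests apply no multiplicity correction by default (per-point
stars); a Benjamini-Hochberg option exists and is labeled in the results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    InsufficientSampleError,
    MissingDataError,
)
from .kinematics import NormalizedCurve
from .parameters import PARAMETER_COLUMNS

TIER_LEVELS = (0.05, 0.01, 0.001)


def significance_tier(p: float, marker: str = "*") -> str:
    """'' / '*' / '**' / '***' (or '#'-style) at 0.05 / 0.01 / 0.001."""
    n = sum(p < level for level in TIER_LEVELS)
    return marker * n


@dataclass
class GroupComparison:
    """One two-sample comparison of a scalar parameter."""

    parameter: str
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    df: float
    p_value: float
    alpha: float
    marker: str = "*"
    label_a: str = "group_a"
    label_b: str = "group_b"
    timepoint: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value, self.marker)


def student_t_test(
    sample_a,
    sample_b,
    alpha: float = 0.05,
    equal_var: bool = True,
    parameter: str = "",
    marker: str = "*",
) -> GroupComparison:
    """Two-sample Student's t-test (pooled variance, two-sided).

    t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a + 1/n_b)), with
    s_p^2 the pooled variance and df = n_a + n_b - 2; p from the t
    distribution.  With ``equal_var=False`` the Welch statistic and
    Satterthwaite df are used instead.

    Degenerate cases: zero pooled variance with equal means yields t = 0,
    p = 1 (no evidence of a difference); zero pooled variance with unequal
    means raises :class:`DegenerateVarianceError` (the statistic is
    infinite and the model assumptions are violated).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientSampleError(
            f"t-test needs n >= 2 per group, got n_a={len(a)}, n_b={len(b)}"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise MissingDataError("t-test requires finite values in both samples")

    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0.0:
            if ma == mb:
                t, p = 0.0, 1.0
            else:
                raise DegenerateVarianceError(
                    f"{parameter or 'samples'}: zero pooled variance with "
                    "unequal means"
                )
        else:
            t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            p = 2.0 * sps.t.sf(abs(t), df)
    else:
        sa2, sb2 = va / na, vb / nb
        if sa2 + sb2 == 0.0:
            if ma == mb:
                t, p, df = 0.0, 1.0, na + nb - 2
            else:
                raise DegenerateVarianceError(
                    f"{parameter or 'samples'}: zero variance with unequal means"
                )
        else:
            t = (ma - mb) / np.sqrt(sa2 + sb2)
            df = (sa2 + sb2) ** 2 / (
                sa2**2 / (na - 1) + sb2**2 / (nb - 1)
            )
            p = 2.0 * sps.t.sf(abs(t), df)

    return GroupComparison(
        parameter=parameter,
        n_a=na,
        n_b=nb,
        mean_a=float(ma),
        sem_a=float(np.sqrt(va / na)),
        mean_b=float(mb),
        sem_b=float(np.sqrt(vb / nb)),
        t_statistic=float(t),
        df=float(df),
        p_value=float(p),
        alpha=alpha,
        marker=marker,
    )


def _as_table(params) -> pd.DataFrame:
    if isinstance(params, pd.DataFrame):
        return params
    from .parameters import parameter_table

    return parameter_table(list(params))


def compare_groups(
    params_a,
    params_b,
    alpha: float = 0.05,
    marker: str = "*",
    parameters: Sequence[str] | None = None,
    label_a: str = "group_a",
    label_b: str = "group_b",
    timepoint: str = "",
) -> dict[str, GroupComparison]:
    """Per-parameter t-tests between two groups of ParameterSets/tables."""
    ta, tb = _as_table(params_a), _as_table(params_b)
    if len(ta) == 0 or len(tb) == 0:
        raise InsufficientSampleError("both groups must be non-empty")
    cols = list(parameters) if parameters else [
        c for c in PARAMETER_COLUMNS if c in ta.columns and c in tb.columns
    ]
    out = {}
    for col in cols:
        cmp = student_t_test(
            ta[col].to_numpy(), tb[col].to_numpy(), alpha=alpha,
            parameter=col, marker=marker,
        )
        out[col] = replace(cmp, label_a=label_a, label_b=label_b,
                           timepoint=timepoint)
    return out


def compare_timepoints(
    params_t1,
    params_t2,
    alpha: float = 0.05,
    parameters: Sequence[str] | None = None,
    label_a: str = "t1",
    label_b: str = "t2",
) -> dict[str, GroupComparison]:
    """Within-group comparison of two timepoints (unpaired; '#' tiers).

    The tests are unpaired two-sample tests; a paired design would require
    subject matching and is intentionally not assumed.
    """
    return compare_groups(
        params_t1, params_t2, alpha=alpha, marker="#",
        parameters=parameters, label_a=label_a, label_b=label_b,
    )


@dataclass
class CurveComparison:
    """Pointwise group contrast of normalized joint-angle curves."""

    joint: str
    percent: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    mask: np.ndarray  # True where pointwise p < alpha
    mean_a: np.ndarray
    sd_a: np.ndarray
    mean_b: np.ndarray
    sd_b: np.ndarray
    n_a: int
    n_b: int
    alpha: float
    corrected: bool = False  # Benjamini-Hochberg applied to the mask


def compare_curves(
    curves_a: Sequence[NormalizedCurve],
    curves_b: Sequence[NormalizedCurve],
    alpha: float = 0.05,
    correction: str | None = None,
) -> CurveComparison:
    """t-test at each of the 101 grid points; mask of significant points.

    ``correction=None`` (default) flags raw pointwise p < alpha, matching
    per-point star conventions; ``correction="bh"`` applies
    Benjamini-Hochberg FDR across the grid and labels the result.
    """
    if len(curves_a) < 2 or len(curves_b) < 2:
        raise InsufficientSampleError(
            "curve comparison needs >= 2 subjects per group, got "
            f"{len(curves_a)} and {len(curves_b)}"
        )
    joints = {c.joint for c in list(curves_a) + list(curves_b)}
    if len(joints) != 1:
        raise ValueError(f"cannot compare mixed joints: {sorted(joints)}")
    A = np.vstack([c.angle for c in curves_a])
    B = np.vstack([c.angle for c in curves_b])

    t = np.empty(101)
    p = np.empty(101)
    for i in range(101):
        try:
            cmp = student_t_test(A[:, i], B[:, i], alpha=alpha)
            t[i], p[i] = cmp.t_statistic, cmp.p_value
        except DegenerateVarianceError:
            t[i], p[i] = np.inf, 0.0

    if correction is None:
        mask = p < alpha
        corrected = False
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests

        mask = multipletests(p, alpha=alpha, method="fdr_bh")[0]
        corrected = True
    else:
        raise ValueError(f"unknown correction {correction!r}")

    return CurveComparison(
        joint=joints.pop(),
        percent=curves_a[0].percent.copy(),
        t_statistic=t,
        p_value=p,
        mask=mask,
        mean_a=A.mean(axis=0),
        sd_a=A.std(axis=0, ddof=1),
        mean_b=B.mean(axis=0),
        sd_b=B.std(axis=0, ddof=1),
        n_a=A.shape[0],
        n_b=B.shape[0],
        alpha=alpha,
        corrected=corrected,
    )


RESULT_COLUMNS = [
    "parameter", "timepoint", "group_a", "group_b", "n_a", "n_b",
    "mean_a", "sem_a", "mean_b", "sem_b", "t", "df", "p", "tier",
]


def results_table(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Machine-readable results: one row per comparison."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "parameter": c.parameter,
                "timepoint": c.timepoint,
                "group_a": c.label_a,
                "group_b": c.label_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "mean_a": c.mean_a,
                "sem_a": c.sem_a,
                "mean_b": c.mean_b,
                "sem_b": c.sem_b,
                "t": c.t_statistic,
                "df": c.df,
                "p": c.p_value,
                "tier": c.tier,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _plot_curve_comparison(cc: CurveComparison, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for mean, sd, label, style in (
        (cc.mean_a, cc.sd_a, f"group A (n={cc.n_a})", "-"),
        (cc.mean_b, cc.sd_b, f"group B (n={cc.n_b})", "--"),
    ):
        ax.plot(cc.percent, mean, style, color="k", label=label)
        ax.plot(cc.percent, mean + sd, style, color="k", lw=0.5)
        ax.plot(cc.percent, mean - sd, style, color="k", lw=0.5)
    if cc.mask.any():
        ymax = max((cc.mean_a + cc.sd_a).max(), (cc.mean_b + cc.sd_b).max())
        ax.plot(cc.percent[cc.mask], np.full(cc.mask.sum(), ymax + 3), "k*", ms=3)
    ax.set_xlabel("% of gait cycle")
    ax.set_ylabel(f"{cc.joint} angle (deg)")
    label = "pointwise p<alpha" + (", BH-corrected" if cc.corrected else "")
    ax.set_title(f"{cc.joint} ({label})", fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_timecourse(df: pd.DataFrame, parameter: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    sub = df[df.parameter == parameter]
    x = np.arange(len(sub))
    ax.errorbar(x - 0.05, sub["mean_a"], yerr=sub["sem_a"], fmt="o-",
                color="k", label=sub["group_a"].iloc[0], capsize=3)
    ax.errorbar(x + 0.05, sub["mean_b"], yerr=sub["sem_b"], fmt="s--",
                color="gray", label=sub["group_b"].iloc[0], capsize=3)
    for xi, (_, row) in zip(x, sub.iterrows()):
        if row["tier"]:
            y = max(row["mean_a"] + row["sem_a"], row["mean_b"] + row["sem_b"])
            ax.annotate(row["tier"], (xi, y), ha="center", va="bottom")
    ax.set_xticks(x, [str(t) for t in sub["timepoint"]])
    ax.set_xlabel("timepoint (weeks)")
    ax.set_ylabel(parameter)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(
    out_dir: str | Path,
    group_results: Iterable[GroupComparison] = (),
    curve_results: Iterable[CurveComparison] = (),
) -> list[Path]:
    """Write a results CSV and figures; returns the file manifest.

    Deterministic for a fixed input: the CSV is byte-identical across runs.
    An empty comparison set still produces a (stub) report and succeeds.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest: list[Path] = []

        group_results = list(group_results)
        curve_results = list(curve_results)
        table = results_table(group_results)
        csv_path = out_dir / "results.csv"
        table.to_csv(csv_path, index=False, float_format="%.10g")
        manifest.append(csv_path)

        if not group_results and not curve_results:
            stub = out_dir / "report.txt"
            stub.write_text("no comparisons\n")
            manifest.append(stub)
            return manifest

        for cc in curve_results:
            path = out_dir / f"curve_{cc.joint}.png"
            _plot_curve_comparison(cc, path)
            manifest.append(path)

        if group_results:
            multi_tp = table["timepoint"].nunique() > 1 or table["timepoint"].iloc[0] != ""
            if multi_tp:
                for parameter in table["parameter"].unique():
                    path = out_dir / f"timecourse_{parameter}.png"
                    _plot_timecourse(table, parameter, path)
                    manifest.append(path)
        return manifest
    except OSError as exc:
        raise OSError(f"cannot write report to {out_dir}: {exc}") from exc
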